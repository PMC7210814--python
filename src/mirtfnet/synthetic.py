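"""Synthetic cohorts with planted ground truth.

Every input the pipeline consumes can be generated here with a known answer:
log2-scale two-group expression matrices with a minority of differential
features and co-expressed gene modules driven by latent factors correlated
with tumor status, probe-to-gene maps exercising the three collapsing
regimes, promoters with planted motif instances, miRNA-TF candidate tables
with controlled cross-database overlap, and term-to-gene annotations. The
planted truth travels alongside each output so downstream stages can be
tested for parameter recovery rather than merely for not crashing.

Generators emulate normalized beadchip cohorts: values live on the log2
scale around a gene-specific baseline, differential features shift their
tumor-group mean by a fixed log2 effect, and module genes are noisy linear
readouts of one latent factor per module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirtfnet.motifscan import PFMRecord, consensus
from mirtfnet.preprocess import ExpressionProfile

__all__ = [
    "PlantedTruth",
    "generate_expression_cohort",
    "generate_probe_table",
    "generate_promoters",
    "generate_mirna_tf_candidates",
    "generate_pfms",
    "generate_annotation",
    "write_truth",
    "read_truth",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators.

    ``motif_positive`` maps (gene, tf) to the 0-based start offset of the
    planted consensus; ``motif_strand`` records the strand it was written on.
    ``latent_factors`` stores each planted module's per-sample driver so
    module-trait correlations can be recomputed independently.
    """

    de_features: set = field(default_factory=set)
    module_members: dict = field(default_factory=dict)
    module_trait_r: float = 0.0
    motif_positive: dict = field(default_factory=dict)
    motif_strand: dict = field(default_factory=dict)
    true_mirna_tf: set = field(default_factory=set)
    shared_de_mirnas: set = field(default_factory=set)
    latent_factors: dict = field(default_factory=dict)

    def merge(self, other: "PlantedTruth") -> "PlantedTruth":
        """Union of two truth records (module/motif maps must not collide)."""
        return PlantedTruth(
            de_features=self.de_features | other.de_features,
            module_members={**self.module_members, **other.module_members},
            module_trait_r=other.module_trait_r or self.module_trait_r,
            motif_positive={**self.motif_positive, **other.motif_positive},
            motif_strand={**self.motif_strand, **other.motif_strand},
            true_mirna_tf=self.true_mirna_tf | other.true_mirna_tf,
            shared_de_mirnas=self.shared_de_mirnas | other.shared_de_mirnas,
            latent_factors={**self.latent_factors, **other.latent_factors},
        )


def generate_expression_cohort(
    n_features: int,
    n_tumor: int,
    n_normal: int,
    n_de: int,
    effect: float,
    n_modules: int = 0,
    module_size: int = 0,
    module_trait_r: float = 0.0,
    noise_sd: float = 1.0,
    de_noise_sd: float | None = None,
    seed: int = 0,
    module_loading: tuple[float, float] = (1.5, 2.5),
    feature_prefix: str = "G",
    sample_prefix: str = "S",
    feature_ids: list[str] | None = None,
    de_ids: list[str] | None = None,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionProfile, PlantedTruth]:
    """Two-group log2 expression matrix with planted DE features and modules.

    Differential features shift their tumor-group mean by ``effect`` log2
    units; ``de_noise_sd`` (default ``noise_sd``) sets their residual spread
    separately, since dysregulated genes carry gene-specific biological
    variance beyond array noise — raising it decorrelates the differential
    background from trait-driven modules. Each of ``n_modules`` modules of ``module_size`` genes is a noisy
    linear readout (loadings ~ U(*module_loading*), default U(1.5, 2.5) so
    intra-module correlations land near 0.8 at unit noise) of one latent
    factor per sample whose correlation with the 0/1 tumor label is
    ``module_trait_r`` in expectation; pass a sequence to drive each module
    at its own strength (latent factors of trait-driven modules correlate
    with each other through the shared trait, exactly as disease modules do). Remaining features are independent noise around their
    baselines. Identical seed and parameters give identical output.

    ``feature_ids`` and ``de_ids`` let twin cohorts share a namespace and a
    controlled set of shared differential features.
    """
    if np.isscalar(module_trait_r):
        trait_vals = [float(module_trait_r)]
        trait_r = trait_vals * n_modules
    else:
        trait_vals = [float(r) for r in module_trait_r]
        trait_r = trait_vals
        if n_modules and len(trait_r) != n_modules:
            raise ValueError("module_trait_r must be scalar or one value per module")
    if any(abs(r) > 1 for r in trait_vals):
        raise ValueError("|module_trait_r| must be <= 1")
    if n_tumor < 3 or n_normal < 3:
        raise ValueError("need >= 3 samples per group")
    if n_de + n_modules * module_size > n_features:
        raise ValueError("n_de + n_modules * module_size exceeds n_features")

    rng = np.random.default_rng(seed)
    n_samples = n_tumor + n_normal
    if feature_ids is None:
        width = len(str(n_features))
        feature_ids = [f"{feature_prefix}{i:0{width}d}" for i in range(n_features)]
    elif len(feature_ids) != n_features:
        raise ValueError("feature_ids length must equal n_features")
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    group = pd.Series([1] * n_tumor + [0] * n_normal, index=sample_ids)
    g = group.to_numpy(dtype=float)
    g_std = (g - g.mean()) / g.std()

    baselines = rng.normal(baseline_mean, baseline_sd, size=n_features)
    values = baselines[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_samples))

    if de_ids is None:
        de_ids = feature_ids[:n_de]
    else:
        if len(de_ids) != n_de or not set(de_ids) <= set(feature_ids):
            raise ValueError("de_ids must be n_de ids drawn from feature_ids")
    id_pos = {f: i for i, f in enumerate(feature_ids)}
    de_rows = [id_pos[f] for f in de_ids]
    values[de_rows] += effect * g[None, :]
    if de_noise_sd is not None and de_noise_sd != noise_sd and de_rows:
        extra = np.sqrt(max(de_noise_sd**2 - noise_sd**2, 0.0))
        values[de_rows] += rng.normal(0.0, extra, size=(len(de_rows), n_samples))

    truth = PlantedTruth(
        de_features=set(de_ids), module_trait_r=max(trait_r, key=abs, default=0.0)
    )
    free = [i for i in range(n_features) if i not in set(de_rows)]
    cursor = 0
    for m in range(n_modules):
        rows = free[cursor : cursor + module_size]
        cursor += module_size
        r_m = trait_r[m]
        z = r_m * g_std + np.sqrt(1 - r_m**2) * rng.normal(size=n_samples)
        loadings = rng.uniform(*module_loading, size=module_size)
        values[rows] = (
            baselines[rows][:, None]
            + loadings[:, None] * z[None, :]
            + rng.normal(0.0, noise_sd, size=(module_size, n_samples))
        )
        module_id = f"mod{m + 1}"
        truth.module_members[module_id] = {feature_ids[i] for i in rows}
        truth.latent_factors[module_id] = z

    profile = ExpressionProfile(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), group
    )
    return profile, truth


def generate_probe_table(
    genes: list[str],
    frac_multi_probe: float = 0.0,
    frac_multi_gene: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe->gene map covering the three collapsing regimes.

    Every gene gets one unique probe; a ``frac_multi_probe`` fraction of the
    genes get a second probe; ``frac_multi_gene`` x n additional ambiguous
    probes each map to two genes.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    for frac in (frac_multi_probe, frac_multi_gene):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if frac_multi_probe + frac_multi_gene > 1:
        raise ValueError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n = len(genes)
    rows = [{"probe": f"P{i:05d}", "genes": gene} for i, gene in enumerate(genes)]
    next_probe = n

    n_mp = int(round(frac_multi_probe * n))
    multi_probe_genes = (
        list(rng.choice(genes, size=n_mp, replace=False)) if n_mp else []
    )
    if frac_multi_probe > 0 and not multi_probe_genes:
        multi_probe_genes = [genes[0]]
    for gene in multi_probe_genes:
        rows.append({"probe": f"P{next_probe:05d}", "genes": gene})
        next_probe += 1

    n_mg = int(round(frac_multi_gene * n))
    if frac_multi_gene > 0 and n_mg == 0:
        n_mg = 1
    for _ in range(n_mg):
        pair = rng.choice(genes, size=min(2, n), replace=False)
        rows.append({"probe": f"P{next_probe:05d}", "genes": ",".join(pair)})
        next_probe += 1
    return pd.DataFrame(rows, columns=["probe", "genes"])


def generate_promoters(
    genes: list[str],
    pfms: list[PFMRecord],
    planted: dict,
    length: int = 2000,
    gc: float = 0.5,
    seed: int = 0,
    strand_choice: str = "+",
) -> tuple[dict[str, str], PlantedTruth]:
    """Promoter sequences with planted consensus motif instances.

    Background bases are i.i.d. with the requested GC fraction. For each
    planted (gene, tf) key that is truthy, the TF's consensus (per-column
    argmax of its PFM) is written at a recorded offset; an integer value in
    ``planted`` pins the offset, True draws it at random. ``strand_choice``
    is "+", "-" or "random"; minus-strand plants write the reverse
    complement. Returns the promoters and a PlantedTruth carrying
    motif_positive / motif_strand.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    pfm_by_id = {p.tf_id: p for p in pfms}
    longest = max((p.length for p in pfms), default=1)
    if length < longest:
        raise ValueError("promoter length shorter than the longest motif")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    promoters = {
        gene: "".join(rng.choice(bases, size=length, p=probs)) for gene in genes
    }
    truth = PlantedTruth()
    for (gene, tf_id), value in sorted(planted.items()):
        if value is False or value is None:
            continue
        motif = consensus(pfm_by_id[tf_id])
        max_offset = length - len(motif)
        offset = int(value) if not isinstance(value, bool) else int(
            rng.integers(0, max_offset + 1)
        )
        if not 0 <= offset <= max_offset:
            raise ValueError(f"offset {offset} out of range for motif {tf_id}")
        strand = (
            strand_choice
            if strand_choice in "+-"
            else ("+" if rng.integers(2) == 0 else "-")
        )
        insert = motif if strand == "+" else motif.translate(_COMPLEMENT)[::-1]
        seq = promoters[gene]
        promoters[gene] = seq[:offset] + insert + seq[offset + len(insert) :]
        truth.motif_positive[(gene, tf_id)] = offset
        truth.motif_strand[(gene, tf_id)] = strand
    return promoters, truth


def generate_mirna_tf_candidates(
    mirnas: list[str],
    tfs: list[str],
    n_primary: int,
    frac_val1: float = 0.5,
    frac_val2: float = 0.5,
    n_decoys: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, set]:
    """Primary and two validation miRNA-TF candidate tables plus truth.

    The primary table holds ``n_primary`` distinct pairs; validation table i
    contains each primary pair independently with probability ``frac_val_i``,
    plus decoy pairs absent from the primary table. Returns the three tables
    and the set of primary pairs present in at least one validation table.
    """
    universe = len(mirnas) * len(tfs)
    if n_primary > universe:
        raise ValueError("n_primary exceeds the miRNA x TF universe")
    rng = np.random.default_rng(seed)
    flat = rng.choice(universe, size=n_primary, replace=False)
    primary_pairs = [(mirnas[i // len(tfs)], tfs[i % len(tfs)]) for i in sorted(flat)]
    primary_set = set(primary_pairs)

    def validation_table(frac: float) -> tuple[pd.DataFrame, set]:
        keep = [p for p in primary_pairs if rng.random() < frac]
        decoys = []
        attempts = 0
        while len(decoys) < n_decoys and attempts < 50 * n_decoys:
            attempts += 1
            pair = (
                mirnas[rng.integers(len(mirnas))],
                tfs[rng.integers(len(tfs))],
            )
            if pair not in primary_set and pair not in decoys:
                decoys.append(pair)
        table = pd.DataFrame(keep + decoys, columns=["mirna", "tf"])
        return table, set(keep)

    val1, kept1 = validation_table(frac_val1)
    val2, kept2 = validation_table(frac_val2)
    primary = pd.DataFrame(primary_pairs, columns=["mirna", "tf"])
    return primary, val1, val2, kept1 | kept2


def generate_pfms(
    tf_ids: list[str],
    length: int = 10,
    dominant: int = 12,
    minor: int = 1,
    seed: int = 0,
) -> list[PFMRecord]:
    """Strongly informative random PFMs, one per TF id.

    Each column has one dominant base (count ``dominant``) and ``minor``
    counts elsewhere, so the consensus is a unique argmax per column.
    """
    rng = np.random.default_rng(seed)
    out = []
    for tf_id in tf_ids:
        counts = np.full((4, length), float(minor))
        winners = rng.integers(0, 4, size=length)
        counts[winners, np.arange(length)] = float(dominant)
        out.append(PFMRecord(tf_id=tf_id, counts=counts))
    return out


def generate_annotation(
    genes: list[str],
    n_terms: int = 20,
    term_size: tuple[int, int] = (5, 30),
    seed: int = 0,
) -> dict[str, tuple[str, set[str]]]:
    """Random term->gene annotation in the in-memory GMT shape."""
    rng = np.random.default_rng(seed)
    annotation = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        term_id = f"TERM:{t:04d}"
        annotation[term_id] = (f"synthetic term {t}", members)
    return annotation


def write_truth(truth: PlantedTruth, path) -> None:
    """Serialize a PlantedTruth to a single JSON document."""
    doc = {
        "de_features": sorted(truth.de_features),
        "module_members": {k: sorted(v) for k, v in truth.module_members.items()},
        "module_trait_r": truth.module_trait_r,
        "motif_positive": {
            f"{g}|{t}": int(off) for (g, t), off in truth.motif_positive.items()
        },
        "motif_strand": {
            f"{g}|{t}": s for (g, t), s in truth.motif_strand.items()
        },
        "true_mirna_tf": sorted(map(list, truth.true_mirna_tf)),
        "shared_de_mirnas": sorted(truth.shared_de_mirnas),
        "latent_factors": {
            k: [float(x) for x in v] for k, v in truth.latent_factors.items()
        },
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)


def read_truth(path) -> PlantedTruth:
    with open(path) as handle:
        doc = json.load(handle)
    return PlantedTruth(
        de_features=set(doc["de_features"]),
        module_members={k: set(v) for k, v in doc["module_members"].items()},
        module_trait_r=doc["module_trait_r"],
        motif_positive={
            tuple(key.split("|")): off for key, off in doc["motif_positive"].items()
        },
        motif_strand={
            tuple(key.split("|")): s for key, s in doc["motif_strand"].items()
        },
        true_mirna_tf={tuple(p) for p in doc["true_mirna_tf"]},
        shared_de_mirnas=set(doc["shared_de_mirnas"]),
        latent_factors={
            k: np.array(v, dtype=float) for k, v in doc["latent_factors"].items()
        },
    )
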