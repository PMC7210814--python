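"""Probe-to-gene collapsing and expression-matrix hygiene.

Microarray matrices arrive at probe resolution. Collapsing follows the three
standard rules for beadchip annotation: a probe mapping to exactly one gene is
renamed to that gene; a probe mapping to several genes is ambiguous and
dropped; several probes mapping to one gene are averaged (arithmetic mean on
the stored log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionProfile", "collapse_probes", "validate_profile"]


@dataclass
class ExpressionProfile:
    """A log2-scale feature x sample expression matrix with binary group labels.

    Parameters
    ----------
    values
        DataFrame of log2 expression, rows indexed by feature id, columns by
        sample id.
    group
        Series of 0/1 labels indexed by sample id; 0 = non-tumor, 1 = tumor.
    """

    values: pd.DataFrame
    group: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "ExpressionProfile":
        """Restrict to the given features, preserving their matrix order."""
        keep = [f for f in self.values.index if f in set(feature_ids)]
        return ExpressionProfile(self.values.loc[keep], self.group)


class ProbeMapError(KeyError):
    """A probe in the matrix is absent from the probe->gene map."""


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    group: pd.Series | None = None,
) -> ExpressionProfile:
    """Collapse a probe x sample matrix to a gene x sample ExpressionProfile.

    Rules, applied in order: (1) a probe mapping to a single gene is renamed
    to that gene; (2) a probe mapping to more than one gene is removed;
    (3) several probes mapping to one gene are replaced by their per-sample
    arithmetic mean on the stored (log2) scale.

    Parameters
    ----------
    probe_matrix
        Probe x sample log2 expression.
    probe_map
        Two columns: ``probe`` and ``genes`` (comma-separated gene ids).
    group
        Optional per-sample 0/1 labels; a dummy all-zero label is attached
        when omitted so the result can still be validated structurally.
    """
    mapping = {
        str(row["probe"]): [g for g in str(row["genes"]).split(",") if g]
        for _, row in probe_map.iterrows()
    }
    missing = [p for p in probe_matrix.index if p not in mapping]
    if missing:
        raise ProbeMapError(f"probes missing from map: {missing[:5]}")

    gene_rows: dict[str, list[np.ndarray]] = {}
    gene_order: list[str] = []
    for probe in probe_matrix.index:
        genes = mapping[probe]
        if len(genes) != 1:  # rule 2: ambiguous probe removed
            continue
        gene = genes[0]
        if gene not in gene_rows:
            gene_rows[gene] = []
            gene_order.append(gene)
        gene_rows[gene].append(probe_matrix.loc[probe].to_numpy(dtype=float))

    if not gene_rows:
        raise ValueError("collapsing removed every probe; matrix is empty")

    collapsed = pd.DataFrame(
        {g: np.mean(gene_rows[g], axis=0) for g in gene_order},
        index=probe_matrix.columns,
    ).T
    if group is None:
        group = pd.Series(0, index=probe_matrix.columns)
    return ExpressionProfile(collapsed, group)


def validate_profile(profile: ExpressionProfile) -> list[str]:
    """Check ExpressionProfile invariants; return a list of violations.

    Reports rather than raises: an empty list means the profile is clean.
    """
    violations: list[str] = []
    vals = profile.values
    if vals.index.has_duplicates:
        for fid in vals.index[vals.index.duplicated()].unique():
            violations.append(f"duplicate feature id: {fid}")
    if vals.columns.has_duplicates:
        for sid in vals.columns[vals.columns.duplicated()].unique():
            violations.append(f"duplicate sample id: {sid}")
    bad = ~np.isfinite(vals.to_numpy(dtype=float))
    if bad.any():
        rows, cols = np.nonzero(bad)
        for r, c in zip(rows[:10], cols[:10]):
            violations.append(
                f"non-finite value at (feature={vals.index[r]}, sample={vals.columns[c]})"
            )
    if len(profile.group) != vals.shape[1] or profile.group.isna().any():
        violations.append("group labels do not cover every sample")
    else:
        counts = profile.group.value_counts()
        for label in (0, 1):
            if counts.get(label, 0) == 0:
                violations.append(f"group {label} is empty")
    return violations
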