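"""Key-miRNA nomination against an independent validation cohort.

The second miRNA cohort is screened at FDR < 0.05 with no fold-change cut,
and its differential miRNAs are intersected with the miRNAs of the refined
triple network. miRNA identifiers are harmonized (lower-cased, "hsa-" prefix
normalized) before set operations, since public annotations mix spellings
like "hsa-miR-106b", "hsa-mir-106b" and "miR-106b".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from mirtfnet.diffexpr import differential_expression
from mirtfnet.preprocess import ExpressionProfile

__all__ = ["KeyMiRNAReport", "harmonize_mirna_id", "validate_key_mirnas"]


def harmonize_mirna_id(mirna_id: str) -> str:
    """Canonical lower-case 'hsa-'-prefixed form of a miRNA id.

    Also repairs the common 'has-' typo seen in published tables.
    """
    out = mirna_id.strip().lower()
    if out.startswith("has-"):
        out = "hsa-" + out[4:]
    if not out.startswith("hsa-"):
        out = "hsa-" + out
    return out


@dataclass
class KeyMiRNAReport:
    """Sets entering and leaving the validation intersection (harmonized ids)."""

    cohort2_de: set[str]
    network_mirnas: set[str]
    key_mirnas: set[str]

    def as_dict(self) -> dict:
        return {
            "cohort2_de": sorted(self.cohort2_de),
            "network_mirnas": sorted(self.network_mirnas),
            "key_mirnas": sorted(self.key_mirnas),
        }


def validate_key_mirnas(
    second_profile: ExpressionProfile,
    network_mirnas: set[str],
    fdr_max: float = 0.05,
) -> KeyMiRNAReport:
    """Intersect the network's miRNAs with the second cohort's DE miRNAs.

    Differential screening of the second cohort uses only the FDR cut
    (no |logFC| threshold). Ids on both sides are harmonized first.
    """
    results = differential_expression(second_profile)
    # FDR cut only: no fold-change threshold for the validation cohort
    cohort2_de = {
        harmonize_mirna_id(m) for m in results.index[results["fdr"] < fdr_max]
    }
    net = {harmonize_mirna_id(m) for m in network_mirnas}
    key = net & cohort2_de
    if net and cohort2_de and not key:
        warnings.warn("zero overlap between network miRNAs and validation DE miRNAs")
    return KeyMiRNAReport(cohort2_de=cohort2_de, network_mirnas=net, key_mirnas=key)
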