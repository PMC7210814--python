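"""Bundled example data.

A published hepatocellular-carcinoma miRNA-mRNA interaction list is shipped
with the package as a ragged TSV: one miRNA per line followed by its
interacting mRNAs, exactly as printed in the source table (including two
"has-" spelling variants, which the validation module's id harmonization is
designed to repair).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_hcc_interaction_pairs"]


def load_hcc_interaction_pairs() -> pd.DataFrame:
    """Long-format miRNA-mRNA pair table from the bundled interaction list.

    Returns one row per (mirna, gene) pair with the identifiers verbatim.
    """
    path = resources.files("mirtfnet.data").joinpath("hcc_mirna_mrna_pairs.tsv")
    rows = []
    for line in path.read_text().splitlines():
        fields = [f for f in line.rstrip().split("\t") if f]
        if not fields:
            continue
        mirna, mrnas = fields[0], fields[1:]
        rows.extend({"mirna": mirna, "gene": g} for g in mrnas)
    return pd.DataFrame(rows, columns=["mirna", "gene"])
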