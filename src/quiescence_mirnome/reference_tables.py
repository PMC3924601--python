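"""Bundled reference tables.

Currently: the published list of experimentally determined miR-29
targets in dermal fibroblasts (gene, overexpression log2 fold change,
functional annotation), used as a worked-example fixture by the
acceptance checks and CLI demos.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_ECM_LABELS = {"ECM", "ECM?"}


def load_mir29_targets() -> pd.DataFrame:
    """The experimentally determined miR-29 target list.

    Columns: ``gene_id``, ``log2_fold_change``, ``function``; one row per
    experimentally supported target gene.
    """
    with resources.files("quiescence_mirnome.data").joinpath(
        "mir29_experimental_targets.tsv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def ecm_related(table: pd.DataFrame) -> pd.DataFrame:
    """Rows annotated as (possibly) extracellular-matrix related."""
    return table[table["function"].isin(_ECM_LABELS)]
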