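"""Experimental target calling from overexpression fold-change arrays.

A gene is "changing" when it is repressed beyond the fold cutoff at the
requested FDR (one-sided one-sample t test on replicate log2 fold
changes, Benjamini-Hochberg across all tested genes); an experimental
target is a changing gene that also carries a predicted binding site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from quiescence_mirnome.core_io import (
    ExpressionMatrix,
    TargetPredictionTable,
    bh_fdr,
)
from quiescence_mirnome.errors import ValidationError


def well_conserved_targets(
    table: TargetPredictionTable, family: str, pct_threshold: float = 0.5
) -> set[str]:
    """Genes predicted for ``family`` with conservation P_CT strictly
    above ``pct_threshold``."""
    sub = table.for_family(family)
    if sub.empty:
        raise ValidationError(f"family {family!r} absent from target table")
    keep = sub["pct"] > pct_threshold
    return set(sub.loc[keep.fillna(False), "gene_id"])


@dataclass
class TargetCallTable:
    """Per-gene repression calls plus bookkeeping of excluded genes."""

    table: pd.DataFrame
    excluded_genes: list[str]

    @property
    def experimental_targets(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_experimental_target"], "gene_id"])

    @property
    def changing_genes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["is_changing"], "gene_id"])


def call_targets(
    fc: ExpressionMatrix,
    predicted: Iterable[str],
    fdr: float = 0.05,
    fold_cutoff_log2: float = -1.0,
) -> TargetCallTable:
    """Call repressed genes and intersect with the predicted target set.

    Columns of ``fc`` are replicate log2 fold changes.  Genes with any
    missing replicate or zero variance are excluded (listed in
    ``excluded_genes``).  ``is_changing`` requires BH q <= ``fdr`` and
    mean log2 FC <= ``fold_cutoff_log2``.
    """
    if fc.n_samples < 2:
        raise ValidationError("need >= 2 replicate columns")
    if not 0 < fdr < 1:
        raise ValidationError("fdr must be in (0, 1)")
    predicted = set(predicted)
    n_rep = fc.n_samples
    complete = ~fc.missing_mask.any(axis=1)
    sds = np.where(complete, fc.values.std(axis=1, ddof=1), np.nan)
    ok = complete & (sds > 0)
    excluded = [g for g, keep in zip(fc.feature_ids, ok) if not keep]
    genes = [g for g, keep in zip(fc.feature_ids, ok) if keep]
    vals = fc.values[ok]
    means_arr = vals.mean(axis=1)
    ts = means_arr / (vals.std(axis=1, ddof=1) / np.sqrt(n_rep))
    ps = stats.t.cdf(ts, n_rep - 1)
    qvals, _ = bh_fdr(ps, fdr)
    changing = (qvals <= fdr) & (means_arr <= fold_cutoff_log2)
    is_pred = np.array([g in predicted for g in genes], dtype=bool)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_log2_fc": means_arr,
            "t": ts,
            "p_one_sided": ps,
            "qvalue": qvals,
            "is_changing": changing,
            "is_predicted_target": is_pred,
            "is_experimental_target": changing & is_pred,
        }
    )
    return TargetCallTable(table, excluded)


def ecdf_compare(
    fc_targets: Sequence[float], fc_nontargets: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Two-sample ECDF comparison with a Kolmogorov-Smirnov test.

    Returns the two right-continuous ECDF step tables (columns ``x`` and
    ``F``), the KS statistic, and its asymptotic p-value.
    """
    a = np.asarray(fc_targets, dtype=float)
    b = np.asarray(fc_nontargets, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")

    def ecdf_table(x: np.ndarray) -> pd.DataFrame:
        xs = np.sort(x)
        uniq, counts = np.unique(xs, return_counts=True)
        return pd.DataFrame({"x": uniq, "F": np.cumsum(counts) / x.size})

    ks = stats.ks_2samp(a, b, method="asymp")
    return ecdf_table(a), ecdf_table(b), float(ks.statistic), float(ks.pvalue)


def percent_repression(log2_fc: float) -> float:
    """Convert a log2 fold change to percent repression: 100*(1 - 2^x)."""
    if not np.isfinite(log2_fc):
        raise ValidationError("log2 fold change must be finite")
    return 100.0 * (1.0 - 2.0**log2_fc)


def quiescence_pattern_of_targets(
    targets: Iterable[str], timecourse: ExpressionMatrix
) -> pd.DataFrame:
    """Mean target-gene log2 value at each timecourse array, in order."""
    targets = set(targets)
    rows = [i for i, g in enumerate(timecourse.feature_ids) if g in targets]
    if not rows:
        raise ValidationError("targets do not intersect the timecourse genes")
    sub = timecourse.values[rows]
    mask = timecourse.missing_mask[rows]
    with np.errstate(invalid="ignore"):
        means = np.where(mask, 0.0, sub).sum(axis=0) / (~mask).sum(axis=0)
    return pd.DataFrame(
        {"sample_id": timecourse.sample_ids, "mean_log2_fc": means}
    )
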