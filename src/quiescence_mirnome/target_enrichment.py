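"""Bootstrap enrichment of predicted target sets on the proliferation index.

Each family's filtered target set is scored by its mean proliferation
index; the two-tailed p-value comes from comparing the statistic and its
additive inverse against mean projections of same-size gene sets sampled
uniformly without replacement from the expression universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from quiescence_mirnome.core_io import TargetPredictionTable
from quiescence_mirnome.errors import ValidationError


@dataclass
class BootstrapEnrichment:
    """Bootstrap test result for one family's target set."""

    mirna_family: str
    set_size: int
    mean_projection: float
    n_resamples: int
    n_as_or_more_extreme: int
    pvalue: float  # count / n_resamples; 0.0 when below resolution
    below_resolution: bool
    pvalue_bound: float  # max(count, 1) / n_resamples — reportable bound
    pvalue_corrected: float  # (count + 1) / (n_resamples + 1)
    n_dropped_genes: int
    seed: int

    def pvalue_label(self) -> str:
        if self.below_resolution:
            return f"< {1.0 / self.n_resamples:g}"
        return f"{self.pvalue:g}"


def filter_target_sets(
    table: TargetPredictionTable,
    universe: Iterable[str],
    context_threshold: float = -0.5,
) -> dict[str, set[str]]:
    """Per-family target sets after the context-score confidence filter.

    Keeps predictions with ``context_score <= context_threshold`` (more
    negative = more confident) whose gene is in ``universe``; families
    left empty are dropped.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    if not np.isfinite(context_threshold):
        raise ValidationError("context_threshold must be finite")
    df = table.records
    kept = df[
        (df["context_score"] <= context_threshold) & df["gene_id"].isin(universe)
    ]
    out: dict[str, set[str]] = {}
    for fam, sub in kept.groupby("mirna_family"):
        genes = set(sub["gene_id"])
        if genes:
            out[str(fam)] = genes
    return out


def mean_projection(
    gene_set: Iterable[str], index: Mapping[str, float]
) -> tuple[float, int]:
    """Mean proliferation index over set genes present in the index.

    Returns ``(mean, n_dropped)`` where ``n_dropped`` counts set genes
    absent from the index domain.
    """
    gene_set = set(gene_set)
    present = [g for g in gene_set if g in index]
    dropped = len(gene_set) - len(present)
    if not present:
        raise ValidationError("gene set does not intersect the index domain")
    return float(np.mean([index[g] for g in present])), dropped


def bootstrap_pvalue(
    gene_set: Iterable[str],
    index: Mapping[str, float],
    n_resamples: int = 10_000,
    seed: int = 0,
    family: str = "",
) -> BootstrapEnrichment:
    """Two-tailed bootstrap p-value for a target set's mean projection.

    Null statistics are mean projections of ``n_resamples`` same-size
    gene sets drawn uniformly without replacement from the index domain;
    the two-tailed count is ``#{null >= |obs|} + #{null <= -|obs|}``.
    A zero count is reported as the bound ``1 / n_resamples`` with
    ``below_resolution`` set.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    obs, dropped = mean_projection(gene_set, index)
    # draws depend only on the sorted index values, making the p-value
    # invariant to gene relabelling and universe ordering
    values = np.sort(np.fromiter(index.values(), dtype=float))
    size = len(set(gene_set)) - dropped
    if size > values.size:
        raise ValidationError("gene set larger than universe")
    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    for b in range(n_resamples):
        pick = rng.choice(values.size, size=size, replace=False)
        null[b] = values[pick].mean()
    a = abs(obs)
    count = int((null >= a).sum() + (null <= -a).sum())
    below = count == 0
    return BootstrapEnrichment(
        mirna_family=family,
        set_size=size,
        mean_projection=obs,
        n_resamples=n_resamples,
        n_as_or_more_extreme=count,
        pvalue=count / n_resamples,
        below_resolution=below,
        pvalue_bound=max(count, 1) / n_resamples,
        pvalue_corrected=(count + 1) / (n_resamples + 1),
        n_dropped_genes=dropped,
        seed=seed,
    )


def enrichment_volcano(
    table: TargetPredictionTable,
    index: Mapping[str, float],
    n_resamples: int = 10_000,
    seed: int = 0,
    context_threshold: float = -0.5,
) -> pd.DataFrame:
    """Per-family mean projection and bootstrap p, sorted by significance.

    Rows are ordered by reportable p-value bound, then by decreasing
    |mean projection|.  Each family's resampling stream is derived from
    ``seed`` and the family's rank so results are order-invariant.
    """
    sets = filter_target_sets(table, index.keys(), context_threshold)
    rows = []
    for k, fam in enumerate(sorted(sets)):
        res = bootstrap_pvalue(
            sets[fam], index, n_resamples=n_resamples, seed=seed + 1000 * k, family=fam
        )
        rows.append(
            {
                "mirna_family": fam,
                "set_size": res.set_size,
                "mean_projection": res.mean_projection,
                "n_as_or_more_extreme": res.n_as_or_more_extreme,
                "pvalue": res.pvalue,
                "pvalue_bound": res.pvalue_bound,
                "pvalue_corrected": res.pvalue_corrected,
                "below_resolution": res.below_resolution,
                "pvalue_label": res.pvalue_label(),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["_absproj"] = df["mean_projection"].abs()
    df = df.sort_values(
        ["pvalue_bound", "_absproj"], ascending=[True, False], kind="mergesort"
    ).drop(columns="_absproj")
    return df.reset_index(drop=True)
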