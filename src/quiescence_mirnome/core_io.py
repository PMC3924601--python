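"""Shared domain types, TSV readers/writers, probe preprocessing, and
generic statistical utilities.

All expression data is held in :class:`ExpressionMatrix`, a thin wrapper
around a dense float matrix (features x samples) with an explicit
missing-value mask.  TSV formats:

* expression: first column ``feature_id``, remaining columns sample ids,
  missing cells written as ``NA`` (empty cells also accepted on read);
* annotation: ``sample_id, condition, timepoint_h, isolate, replicate``;
* target table: ``mirna_family, gene_id, pct, context_score``;
* phase counts: ``timepoint_h, transfection, day_batch, replicate,
  g0g1, s, g2m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from quiescence_mirnome.errors import (
    DegenerateInputError,
    FormatError,
    ValidationError,
)

CONDITIONS = ("proliferating", "serum_starved", "contact_inhibited", "restimulated")

PHASES = ("g0g1", "s", "g2m")

_NA_VALUES = ("", "NA")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense log2-scale expression matrix with an explicit missing mask.

    Parameters
    ----------
    values:
        ``(n_features, n_samples)`` float array.  Entries flagged missing
        may hold any payload (typically NaN) and are never interpreted.
    feature_ids, sample_ids:
        Ordered, duplicate-free identifier lists matching the axes.
    missing_mask:
        Boolean array of the same shape; ``True`` marks a missing cell.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("non-missing entries must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def complete_rows(self) -> np.ndarray:
        """Boolean vector marking features without any missing entry."""
        return ~self.missing_mask.any(axis=1)

    def subset_features(self, keep: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[keep],
            feature_ids=[self.feature_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            missing_mask=self.missing_mask[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.astype(object)
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(
            vals.astype(float), index=self.feature_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-array experimental annotation."""

    sample_id: str
    condition: str
    isolate: str
    replicate: int = 1
    timepoint_h: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )


@dataclass
class TargetPredictionTable:
    """Records of (miRNA family, gene, conservation P_CT, context score)."""

    records: pd.DataFrame

    REQUIRED = ("mirna_family", "gene_id", "pct", "context_score")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"target table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["mirna_family"] = df["mirna_family"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        if df.duplicated(["mirna_family", "gene_id"]).any():
            raise FormatError("duplicate (family, gene) pairs in target table")
        pct = pd.to_numeric(df["pct"], errors="coerce")
        if ((pct < 0) | (pct > 1)).any():
            raise ValidationError("pct values must lie in [0, 1]")
        df["pct"] = pct
        df["context_score"] = pd.to_numeric(df["context_score"], errors="coerce")
        self.records = df.reset_index(drop=True)

    @property
    def families(self) -> list[str]:
        return sorted(self.records["mirna_family"].unique())

    def for_family(self, family: str) -> pd.DataFrame:
        return self.records[self.records["mirna_family"] == family]


@dataclass
class PhaseCountTable:
    """Flow-cytometry phase counts, one row per replicate measurement."""

    records: pd.DataFrame

    REQUIRED = ("timepoint_h", "transfection", "day_batch", "replicate") + PHASES

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phase count table missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        for phase in PHASES:
            col = pd.to_numeric(df[phase], errors="raise")
            if (col < 0).any():
                raise ValidationError("phase counts must be non-negative")
            if not np.allclose(col, np.round(col)):
                raise ValidationError("phase counts must be integers")
            df[phase] = col.astype(int)
        key = ["timepoint_h", "transfection", "day_batch", "replicate"]
        if df.duplicated(key).any():
            raise FormatError("duplicate (timepoint, transfection, day, replicate) rows")
        self.records = df.reset_index(drop=True)

    def counts(self) -> np.ndarray:
        return self.records.loc[:, list(PHASES)].to_numpy(dtype=int)

    def group(self, timepoint_h: float, transfection: str) -> "PhaseCountTable":
        df = self.records
        sel = (df["timepoint_h"] == timepoint_h) & (df["transfection"] == transfection)
        return PhaseCountTable(df[sel].reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path, annotation_path: str | Path | None = None
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Read an expression TSV and (optionally) its annotation sheet.

    The first column must be ``feature_id``; remaining column headers are
    sample ids.  Empty cells and literal ``NA`` are flagged missing.  When
    ``annotation_path`` is given, every sample column must have a matching
    annotation row (extra annotation rows are an error too).
    """
    with open(path, "r", encoding="utf-8") as fh:
        cols = fh.readline().rstrip("\n").split("\t")
    if len(cols) < 2:
        raise FormatError(f"{path}: expected feature_id plus >=1 sample column")
    sample_cols = cols[1:]
    if len(set(sample_cols)) != len(sample_cols):
        raise FormatError(f"{path}: duplicated sample column header")
    df = pd.read_csv(
        path, sep="\t", dtype={cols[0]: str}, na_values=list(_NA_VALUES),
        keep_default_na=False, float_precision="round_trip",
    )
    feature_ids = df.iloc[:, 0].tolist()
    if len(set(feature_ids)) != len(feature_ids):
        raise FormatError(f"{path}: duplicated feature ids")
    vals = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    mask = ~np.isfinite(vals)
    expr = ExpressionMatrix(vals, feature_ids, sample_cols, mask)
    annotations: list[SampleAnnotation] = []
    if annotation_path is not None:
        annotations = read_annotation_tsv(annotation_path)
        by_id = {a.sample_id: a for a in annotations}
        missing = [s for s in sample_cols if s not in by_id]
        if missing:
            raise FormatError(f"annotation missing samples: {missing}")
        annotations = [by_id[s] for s in sample_cols]
    return expr, annotations


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix; missing cells are emitted as ``NA``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(expr.sample_ids) + "\n")
        for i, fid in enumerate(expr.feature_ids):
            cells = [
                "NA" if expr.missing_mask[i, j] else repr(float(expr.values[i, j]))
                for j in range(expr.n_samples)
            ]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_annotation_tsv(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=list(_NA_VALUES),
                     keep_default_na=False)
    required = {"sample_id", "condition", "isolate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        tp = row.get("timepoint_h")
        tp_val = None if tp is None or (isinstance(tp, float) and math.isnan(tp)) else float(tp)
        rep = row.get("replicate")
        rep_val = 1 if rep is None or (isinstance(rep, float) and math.isnan(rep)) else int(float(rep))
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                isolate=str(row["isolate"]),
                replicate=rep_val,
                timepoint_h=tp_val,
            )
        )
    if len({a.sample_id for a in out}) != len(out):
        raise FormatError(f"{path}: duplicate sample_id rows")
    return out


def write_annotation_tsv(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\ttimepoint_h\tisolate\treplicate\n")
        for a in annotations:
            tp = "NA" if a.timepoint_h is None else repr(float(a.timepoint_h))
            fh.write(f"{a.sample_id}\t{a.condition}\t{tp}\t{a.isolate}\t{a.replicate}\n")


def read_target_table_tsv(path: str | Path) -> TargetPredictionTable:
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_VALUES), keep_default_na=False)
    return TargetPredictionTable(df)


def write_target_table_tsv(table: TargetPredictionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phase_counts_tsv(path: str | Path) -> PhaseCountTable:
    df = pd.read_csv(path, sep="\t", na_values=list(_NA_VALUES), keep_default_na=False)
    return PhaseCountTable(df)


def write_phase_counts_tsv(table: PhaseCountTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe preprocessing
# ---------------------------------------------------------------------------


def collapse_probes_to_genes(
    expr: ExpressionMatrix,
    probe_gene_map: Mapping[str, str],
    detection_fraction: float = 0.8,
) -> ExpressionMatrix:
    """Filter probes by detection rate and average probes per gene.

    A probe is considered detected in a sample iff its entry is
    non-missing.  Probes detected in fewer than ``detection_fraction`` of
    samples are dropped, as are probes absent from ``probe_gene_map``.
    Surviving probes mapping to the same gene are averaged per sample over
    their non-missing entries; a gene entry is missing only where all its
    probes are missing.
    """
    if not 0 < detection_fraction <= 1:
        raise ValidationError("detection_fraction must be in (0, 1]")
    n = expr.n_samples
    detected = (~expr.missing_mask).sum(axis=1)
    keep = detected >= detection_fraction * n
    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(expr.feature_ids):
        if not keep[i]:
            continue
        gene = probe_gene_map.get(probe)
        if gene is None:
            continue
        gene_rows.setdefault(gene, []).append(i)
    genes = sorted(gene_rows)
    if not genes:
        import warnings

        warnings.warn("no probes survived detection/mapping filters", stacklevel=2)
        return ExpressionMatrix(
            np.empty((0, n)), [], list(expr.sample_ids), np.empty((0, n), dtype=bool)
        )
    out = np.full((len(genes), n), np.nan)
    mask = np.ones((len(genes), n), dtype=bool)
    for g, gene in enumerate(genes):
        rows = gene_rows[gene]
        sub = expr.values[rows]
        sub_mask = expr.missing_mask[rows]
        counts = (~sub_mask).sum(axis=0)
        sums = np.where(sub_mask, 0.0, sub).sum(axis=0)
        has_obs = counts > 0
        # avoid 0/0; cells with no observed probe stay missing
        out[g, has_obs] = sums[has_obs] / counts[has_obs]
        mask[g] = ~has_obs
    return ExpressionMatrix(out, genes, list(expr.sample_ids), mask)


# ---------------------------------------------------------------------------
# generic statistics
# ---------------------------------------------------------------------------


def one_sided_t_test(samples: Sequence[float], alternative: str = "less") -> tuple[float, float]:
    """One-sample t test of mean 0 with a one-sided alternative.

    Returns ``(t, p)`` where ``p`` is the lower-tail probability for
    ``alternative='less'`` and the upper tail for ``'greater'``, on a t
    distribution with ``n - 1`` degrees of freedom.
    """
    if alternative not in ("less", "greater"):
        raise ValidationError("alternative must be 'less' or 'greater'")
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero sample variance")
    t = x.mean() / (sd / math.sqrt(x.size))
    df = x.size - 1
    p = stats.t.cdf(t, df) if alternative == "less" else stats.t.sf(t, df)
    return float(t), float(p)


def bh_fdr(pvalues: Sequence[float], q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance calls.

    q-values are ``p * m / rank`` with monotonicity enforced from the
    largest p downward; ``significant[i]`` iff ``qvalues[i] <= q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError("q must be in (0, 1)")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(ranked, 1.0)
    return qvals, qvals <= q


def pearson_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Pearson correlation with a Fisher z-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise DegenerateInputError("need equal-length vectors with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant vector")
    if not 0 < confidence < 1:
        raise ValidationError("confidence must be in (0, 1)")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:  # CI degenerate at the boundary
        return r, r, r
    z = math.atanh(r)
    se = 1.0 / math.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    return r, math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
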