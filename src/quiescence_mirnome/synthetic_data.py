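"""Synthetic pipeline inputs with planted, recoverable structure.

Every generator is a pure function of its :class:`SyntheticConfig`: the
config's ``seed`` (offset by a fixed per-generator constant so stages
draw independent streams) fully determines the output.  The planted
quantities are returned in a :class:`GroundTruth` record so downstream
stages can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from quiescence_mirnome.core_io import (
    PHASES,
    ExpressionMatrix,
    PhaseCountTable,
    SampleAnnotation,
    TargetPredictionTable,
)
from quiescence_mirnome.errors import ConfigError

# per-generator seed offsets: keeps the five streams independent while the
# whole pipeline stays a function of one integer seed
_STREAM = {
    "mirna": 11,
    "mrna": 23,
    "targets": 37,
    "overexpression": 51,
    "phase": 67,
}

# smooth quiescence-depth profile over the 16-array timecourse:
# rises through serum starvation (6 arrays), falls back through serum
# restimulation (6 arrays), maximal in contact inhibition (4 arrays).
TIMECOURSE_SAMPLES = (
    "SS_1h", "SS_2h", "SS_4h", "SS_8h", "SS_24h", "SS_96h",
    "SR_1h", "SR_2h", "SR_4h", "SR_8h", "SR_24h", "SR_48h",
    "CI_7d_a", "CI_7d_b", "CI_14d_a", "CI_14d_b",
)

QUIESCENCE_DEPTH = np.array(
    [0.05, 0.10, 0.20, 0.35, 0.70, 1.00,
     0.95, 0.85, 0.70, 0.50, 0.20, 0.05,
     1.05, 1.10, 1.15, 1.20]
)


@dataclass
class SyntheticConfig:
    """Knobs for all synthetic generators; see each generator's docs."""

    seed: int = 0
    n_mirnas: int = 200
    n_genes: int = 2000
    frac_quiescence_responsive: float = 0.3
    effect_size_log2: float = 1.5
    noise_sd: float = 0.3
    surrogate_effect_sd: float = 0.5
    n_isolates: int = 3
    prolif_pattern_share: float = 0.4
    target_set_sizes: list[int] = field(default_factory=lambda: [40] * 10)
    planted_family: str = "miR-29"
    overexpression_repression_log2: float = -1.5
    overexpression_noise_sd: float = 0.2
    # overall fraction of genes planted as repressed (family targets plus
    # extras).  With triplicate arrays the one-sided t floor is ~3e-3, so
    # recall >= 0.9 at 5% FDR needs a sizeable repressed fraction.
    overexpression_frac_repressed: float = 0.2
    dirichlet_alphas: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"NC": (30.0, 12.0, 8.0), "miR-29": (18.0, 24.0, 8.0)}
    )
    cells_per_sample: int = 5000

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_isolates", "cells_per_sample"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.frac_quiescence_responsive <= 1:
            raise ConfigError("frac_quiescence_responsive must be in [0, 1]")
        if self.effect_size_log2 <= 0:
            raise ConfigError("effect_size_log2 must be > 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.surrogate_effect_sd < 0:
            raise ConfigError("surrogate_effect_sd must be >= 0")
        if not 0 < self.prolif_pattern_share < 1:
            raise ConfigError("prolif_pattern_share must be in (0, 1)")
        if self.overexpression_repression_log2 >= 0:
            raise ConfigError("overexpression_repression_log2 must be < 0")
        if not 0 <= self.overexpression_frac_repressed < 1:
            raise ConfigError("overexpression_frac_repressed must be in [0, 1)")
        if any(s <= 0 for s in self.target_set_sizes):
            raise ConfigError("target_set_sizes must be positive")
        for label, alpha in self.dirichlet_alphas.items():
            if len(alpha) != 3 or any(a <= 0 for a in alpha):
                raise ConfigError(f"dirichlet_alphas[{label!r}] must be a positive triple")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted quantities recorded by the generators."""

    responsive_mirnas: dict[str, float] = field(default_factory=dict)
    surrogate_vector: np.ndarray | None = None
    gene_class: dict[str, str] = field(default_factory=dict)
    true_targets: dict[str, set[str]] = field(default_factory=dict)
    repressed_genes: set[str] = field(default_factory=set)
    alphas: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _orthogonalize(v: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the span of ``basis`` columns from ``v`` (least squares)."""
    coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
    return v - basis @ coef


def gen_mirna_arrays(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Simulate the 3-condition x n-isolate one-channel miRNA design.

    Each feature follows the additive model: baseline + quiescence effect
    (for a planted responsive fraction, magnitude ``effect_size_log2``
    with random sign, shared by both quiescence conditions) + per-isolate
    offsets + a hidden surrogate effect + Gaussian noise.  The surrogate
    pattern is a random sign vector orthogonalized against the design so
    the planted coefficients stay identifiable.
    """
    if cfg.n_isolates < 2:
        raise ConfigError("need >= 2 isolates for an identifiable design")
    rng = np.random.default_rng(cfg.seed + _STREAM["mirna"])
    conditions = ("proliferating", "serum_starved", "contact_inhibited")
    isolates = [f"iso{k + 1}" for k in range(cfg.n_isolates)]
    sample_ids, annotations = [], []
    for iso in isolates:
        for cond in conditions:
            sid = f"{iso}_{cond}"
            sample_ids.append(sid)
            annotations.append(SampleAnnotation(sid, cond, iso))
    n_samples = len(sample_ids)

    x_q = np.array([a.condition != "proliferating" for a in annotations], float)
    x_s = np.array([a.condition == "serum_starved" for a in annotations], float)
    iso_cols = np.column_stack(
        [[float(a.isolate == iso) for a in annotations] for iso in isolates[1:]]
    )
    design = np.column_stack([np.ones(n_samples), x_q, x_s, iso_cols])

    surrogate = rng.choice([-1.0, 1.0], size=n_samples)
    surrogate = _orthogonalize(surrogate, design)
    norm = np.linalg.norm(surrogate)
    surrogate = surrogate / norm if norm > 0 else surrogate

    feature_ids = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    n_resp = int(round(cfg.frac_quiescence_responsive * cfg.n_mirnas))
    resp_idx = rng.choice(cfg.n_mirnas, size=n_resp, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_resp)

    baseline = rng.uniform(6.0, 12.0, size=cfg.n_mirnas)
    b_q = np.zeros(cfg.n_mirnas)
    b_q[resp_idx] = signs * cfg.effect_size_log2
    iso_effects = rng.normal(0.0, 0.25, size=(cfg.n_mirnas, cfg.n_isolates - 1))
    sva_loading = rng.normal(0.0, cfg.surrogate_effect_sd, size=cfg.n_mirnas)

    values = (
        baseline[:, None]
        + b_q[:, None] * x_q[None, :]
        + iso_effects @ iso_cols.T
        + sva_loading[:, None] * surrogate[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirnas, n_samples))
    )
    truth = GroundTruth(
        responsive_mirnas={feature_ids[i]: float(b_q[i]) for i in resp_idx},
        surrogate_vector=surrogate,
    )
    expr = ExpressionMatrix(values, feature_ids, sample_ids)
    return expr, annotations, truth


def gen_mrna_timecourse(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Simulate the 16-array log-ratio timecourse with one dominant pattern.

    A fixed quiescence-depth profile carries ``prolif_pattern_share`` of
    the total variance.  Quiescence-class genes load positively on it,
    proliferation-class genes negatively, neutral genes near zero; the
    rest of the variance comes from two weak secondary patterns plus
    isotropic noise.
    """
    rng = np.random.default_rng(cfg.seed + _STREAM["mrna"])
    n_arrays = len(TIMECOURSE_SAMPLES)
    gene_ids = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]

    classes = rng.choice(
        ["proliferation", "quiescence", "neutral"], size=cfg.n_genes, p=[0.25, 0.25, 0.5]
    )
    loading = np.zeros(cfg.n_genes)
    magnitude = np.abs(rng.normal(1.0, 0.3, size=cfg.n_genes))
    loading[classes == "quiescence"] = magnitude[classes == "quiescence"]
    loading[classes == "proliferation"] = -magnitude[classes == "proliferation"]

    pattern = QUIESCENCE_DEPTH - QUIESCENCE_DEPTH.mean()
    pattern = pattern / np.linalg.norm(pattern)
    primary = np.outer(loading, pattern)

    # secondary structure: two random orthogonal array patterns
    sec = rng.normal(size=(n_arrays, 2))
    sec -= np.outer(pattern, pattern @ sec)
    sec, _ = np.linalg.qr(sec)
    sec_load = rng.normal(0.0, 0.4, size=(cfg.n_genes, 2))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_arrays))
    rest = sec_load @ sec.T + noise

    # rescale so the primary pattern carries the requested variance share
    share = cfg.prolif_pattern_share
    p_ss, r_ss = (primary**2).sum(), (rest**2).sum()
    scale = np.sqrt(share / (1 - share) * r_ss / p_ss)
    values = primary * scale + rest

    annotations = []
    tps = [1, 2, 4, 8, 24, 96, 1, 2, 4, 8, 24, 48, 168, 168, 336, 336]
    conds = ["serum_starved"] * 6 + ["restimulated"] * 6 + ["contact_inhibited"] * 4
    for sid, tp, cond in zip(TIMECOURSE_SAMPLES, tps, conds):
        annotations.append(SampleAnnotation(sid, cond, "iso1", timepoint_h=float(tp)))

    truth = GroundTruth(gene_class=dict(zip(gene_ids, classes.tolist())))
    expr = ExpressionMatrix(values, gene_ids, list(TIMECOURSE_SAMPLES))
    return expr, annotations, truth


def gen_target_predictions(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[TargetPredictionTable, GroundTruth]:
    """Build a target-prediction table with one planted responsive family.

    The planted family's targets are drawn from quiescence-class genes;
    decoy families draw uniformly from all genes.  Context scores are
    drawn so the configured set sizes survive a -0.5 cutoff, and P_CT
    values are enriched above 0.5 for the planted family.
    """
    rng = np.random.default_rng(cfg.seed + _STREAM["targets"])
    genes = list(truth.gene_class)
    if not genes:
        raise ConfigError("ground truth lacks gene classes; run gen_mrna_timecourse first")
    quiescence_genes = [g for g, c in truth.gene_class.items() if c == "quiescence"]
    sizes = list(cfg.target_set_sizes)
    if sizes[0] > len(quiescence_genes):
        raise ConfigError(
            f"planted set size {sizes[0]} exceeds {len(quiescence_genes)} quiescence genes"
        )
    families = [cfg.planted_family] + [f"decoy-{k}" for k in range(1, len(sizes))]
    rows = []
    for fam, size in zip(families, sizes):
        pool = quiescence_genes if fam == cfg.planted_family else genes
        chosen = rng.choice(len(pool), size=size, replace=False)
        for gi in chosen:
            gene = pool[gi]
            # all planted/decoy predictions pass the context filter
            context = -0.5 - rng.exponential(0.3)
            if fam == cfg.planted_family:
                pct = rng.uniform(0.5, 1.0)
            else:
                pct = rng.uniform(0.0, 1.0)
            rows.append((fam, gene, round(pct, 4), round(context, 4)))
        # plus some low-confidence predictions that the filter must drop
        n_weak = max(1, size // 4)
        weak = rng.choice(len(genes), size=n_weak, replace=False)
        seen = {r[1] for r in rows if r[0] == fam}
        for gi in weak:
            gene = genes[gi]
            if gene in seen:
                continue
            rows.append((fam, gene, round(rng.uniform(0, 1), 4),
                         round(rng.uniform(-0.45, -0.05), 4)))
    df = pd.DataFrame(rows, columns=["mirna_family", "gene_id", "pct", "context_score"])
    table = TargetPredictionTable(df)
    truth.true_targets = {
        fam: set(
            df[(df["mirna_family"] == fam) & (df["context_score"] <= -0.5)]["gene_id"]
        )
        for fam in families
    }
    return table, truth


def gen_overexpression_arrays(
    cfg: SyntheticConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate triplicate overexpression log2 fold-change arrays.

    Planted repressed genes (a subset of the planted family's true
    targets plus a few extras) have mean log2 FC equal to
    ``overexpression_repression_log2``; all other genes have mean 0.
    Replicate noise is Gaussian.
    """
    rng = np.random.default_rng(cfg.seed + _STREAM["overexpression"])
    genes = list(truth.gene_class)
    if not genes:
        raise ConfigError("ground truth lacks genes; run gen_mrna_timecourse first")
    family_targets = sorted(truth.true_targets.get(cfg.planted_family, set()))
    n_core = max(1, int(round(0.8 * len(family_targets))))
    core = set(
        np.array(family_targets)[rng.choice(len(family_targets), n_core, replace=False)]
    ) if family_targets else set()
    others = [g for g in genes if g not in core]
    n_target = int(round(cfg.overexpression_frac_repressed * len(genes)))
    n_extra = max(max(1, len(core) // 5) if core else 5, n_target - len(core))
    n_extra = min(n_extra, len(others))
    extra = set(np.array(others)[rng.choice(len(others), n_extra, replace=False)])
    repressed = core | extra

    mean_fc = np.array(
        [cfg.overexpression_repression_log2 if g in repressed else 0.0 for g in genes]
    )
    values = mean_fc[:, None] + rng.normal(
        0.0, cfg.overexpression_noise_sd, size=(len(genes), 3)
    )
    expr = ExpressionMatrix(values, genes, ["iso1_fc", "iso2_fc", "iso3_fc"])
    truth.repressed_genes = repressed
    return expr, truth


def gen_phase_counts(cfg: SyntheticConfig) -> tuple[PhaseCountTable, GroundTruth]:
    """Simulate Dirichlet-multinomial cell-cycle phase counts.

    For each (timepoint, transfection) group, six replicates (triplicate
    on each of two day batches) draw a proportion triple from the group's
    Dirichlet and then a multinomial of ``cells_per_sample`` cells.
    """
    rng = np.random.default_rng(cfg.seed + _STREAM["phase"])
    timepoints = (20.0, 24.0, 28.0, 32.0)
    rows = []
    for tp in timepoints:
        for label, alpha in cfg.dirichlet_alphas.items():
            for day in ("day1", "day2"):
                for rep in (1, 2, 3):
                    props = rng.dirichlet(alpha)
                    counts = rng.multinomial(cfg.cells_per_sample, props)
                    rows.append((tp, label, day, rep, *counts.tolist()))
    df = pd.DataFrame(
        rows,
        columns=["timepoint_h", "transfection", "day_batch", "replicate", *PHASES],
    )
    truth = GroundTruth(alphas={k: tuple(v) for k, v in cfg.dirichlet_alphas.items()})
    return PhaseCountTable(df), truth
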