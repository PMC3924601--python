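"""Dirichlet maximum likelihood and likelihood-ratio tests for
cell-cycle phase compositions.

Phase count triples (G0/G1, S, G2/M) are converted to open-simplex
proportions, fit by an alternating mean/precision maximum-likelihood
scheme (digamma fixed point for the mean at fixed precision; safeguarded
Newton on the precision profile), and two transfection groups are
compared with D = -2 logL(H0) + 2 logL(Ha) on chi-squared with three
degrees of freedom (the alternative fits two three-parameter Dirichlets
instead of one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, polygamma, psi

from quiescence_mirnome.core_io import PHASES, PhaseCountTable
from quiescence_mirnome.errors import DegenerateInputError, ValidationError

LRT_DF = 3  # a three-phase Dirichlet has three free parameters

_ASCENT_SLACK = 1e-8  # numerical tolerance on the monotone-loglik assertion


@dataclass
class DirichletFit:
    """Maximum-likelihood Dirichlet fit in mean/precision form."""

    alpha: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def precision(self) -> float:
        return float(self.alpha.sum())


@dataclass
class LrtResult:
    """Two-group Dirichlet likelihood-ratio test."""

    D: float
    df: int
    pvalue: float
    fit_null: DirichletFit
    fit_a: DirichletFit
    fit_b: DirichletFit
    clipped: bool = False


def counts_to_proportions(
    counts: PhaseCountTable, pseudocount: float = 0.5
) -> np.ndarray:
    """Replicate-wise proportions with additive smoothing.

    ``(count + pseudocount) / (total + 3 * pseudocount)`` keeps every
    proportion strictly inside the simplex when ``pseudocount > 0``.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    c = counts.counts().astype(float)
    totals = c.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("replicate with zero total count")
    return (c + pseudocount) / (totals + 3 * pseudocount)[:, None]


def _check_open_simplex(props: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(np.asarray(props, dtype=float))
    if p.shape[1] != 3:
        raise ValidationError("expected proportion triples")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("proportions must sum to 1")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValidationError("proportions must lie strictly inside the simplex")
    return p


def dirichlet_loglik(alpha: np.ndarray, props: np.ndarray) -> float:
    """Sum of log Dirichlet densities over replicate proportion triples."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (3,) or np.any(alpha <= 0):
        raise ValidationError("alpha must be a strictly positive triple")
    p = _check_open_simplex(props)
    n = p.shape[0]
    const = gammaln(alpha.sum()) - gammaln(alpha).sum()
    return float(n * const + ((alpha - 1.0) * np.log(p)).sum())


def _inv_psi(y: np.ndarray) -> np.ndarray:
    """Inverse digamma by Newton iteration (vectorized)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y >= -2.22, np.exp(y) + 0.5, -1.0 / (y - psi(1.0)))
    for _ in range(6):
        x = x - (psi(x) - y) / polygamma(1, x)
        x = np.maximum(x, 1e-12)
    return x


def _mom_init(p: np.ndarray) -> tuple[np.ndarray, float]:
    """Method-of-moments mean and precision."""
    m = p.mean(axis=0)
    v = p.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_k = m * (1 - m) / v - 1.0
    s_k = s_k[np.isfinite(s_k) & (s_k > 0)]
    s = float(np.exp(np.mean(np.log(s_k)))) if s_k.size else 100.0
    return m, float(np.clip(s, 1e-2, 1e7))


def _mean_step(m: np.ndarray, s: float, logp_bar: np.ndarray) -> np.ndarray:
    """Digamma fixed-point update of the mean at fixed precision."""
    target = logp_bar + float(np.dot(m, psi(s * m) - logp_bar))
    m_new = _inv_psi(target) / s
    m_new = np.maximum(m_new, 1e-12)
    return m_new / m_new.sum()


def _precision_step(m: np.ndarray, s: float, logp_bar: np.ndarray, n: int) -> float:
    """Safeguarded Newton update of log-precision on the profile loglik."""
    d1 = n * (psi(s) - float(np.dot(m, psi(s * m))) + float(np.dot(m, logp_bar)))
    d2 = n * (polygamma(1, s) - float(np.dot(m**2, polygamma(1, s * m))))
    g = s * d1  # gradient in u = log s
    h = s * s * d2 + s * d1  # Hessian in u
    if h < 0:
        step = -g / h
    else:
        step = np.sign(g)  # fall back to a unit gradient-sign step
    step = float(np.clip(step, -4.0, 4.0))
    return float(np.clip(s * np.exp(step), 1e-8, 1e9))


def dirichlet_mle(
    props: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> DirichletFit:
    """Fit a Dirichlet by alternating mean and precision updates.

    Both sub-steps are backtracked against the log-likelihood so the
    recorded ``loglik_path`` is non-decreasing; iteration stops when an
    outer round improves the log-likelihood by less than ``tol``.
    """
    p = _check_open_simplex(props)
    if p.shape[0] < 2:
        raise DegenerateInputError("need >= 2 replicates")
    n = p.shape[0]
    logp_bar = np.log(p).mean(axis=0)
    m, s = _mom_init(p)
    ll = dirichlet_loglik(s * m, p)
    path = [ll]

    def try_accept(m_cand: np.ndarray, s_cand: float, current: float):
        cand_ll = dirichlet_loglik(s_cand * m_cand, p)
        return (cand_ll, True) if cand_ll >= current - _ASCENT_SLACK else (current, False)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll_round_start = ll

        m_cand = _mean_step(m, s, logp_bar)
        t = 1.0
        for _ in range(30):
            trial = (1 - t) * m + t * m_cand
            trial = trial / trial.sum()
            cand_ll, ok = try_accept(trial, s, ll)
            if ok:
                m, ll = trial, cand_ll
                break
            t *= 0.5
        path.append(ll)

        s_cand = _precision_step(m, s, logp_bar, n)
        u, u_cand = np.log(s), np.log(s_cand)
        t = 1.0
        for _ in range(30):
            trial_s = float(np.exp((1 - t) * u + t * u_cand))
            cand_ll, ok = try_accept(m, trial_s, ll)
            if ok:
                s, ll = trial_s, cand_ll
                break
            t *= 0.5
        path.append(ll)

        if ll - ll_round_start < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Dirichlet MLE hit max_iter without converging", stacklevel=2)
    return DirichletFit(
        alpha=s * m, loglik=ll, n_iterations=it, converged=converged, loglik_path=path
    )


def lrt_two_groups(props_a: np.ndarray, props_b: np.ndarray, **fit_kwargs) -> LrtResult:
    """Likelihood-ratio test of one shared vs two group Dirichlets.

    ``D = -2 logL(H0) + 2 (logL(A) + logL(B))`` referred to chi-squared
    with three degrees of freedom; tiny negative D from numerics is
    clipped to 0 and flagged.
    """
    a = _check_open_simplex(props_a)
    b = _check_open_simplex(props_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DegenerateInputError("each group needs >= 2 replicates")
    fit_null = dirichlet_mle(np.vstack([a, b]), **fit_kwargs)
    fit_a = dirichlet_mle(a, **fit_kwargs)
    fit_b = dirichlet_mle(b, **fit_kwargs)
    D = -2.0 * fit_null.loglik + 2.0 * (fit_a.loglik + fit_b.loglik)
    clipped = D < 0
    D = max(D, 0.0)
    p = float(stats.chi2.sf(D, LRT_DF))
    return LrtResult(D=float(D), df=LRT_DF, pvalue=p, fit_null=fit_null,
                     fit_a=fit_a, fit_b=fit_b, clipped=clipped)


def phase_summary(counts: PhaseCountTable, normalize_se: bool = False) -> pd.DataFrame:
    """Per (timepoint, transfection) mean phase percentages and errors.

    The default error is the square root of the total sum of squared
    residuals from each day's mean percentage, pooled over days;
    ``normalize_se=True`` instead divides the pooled residual sum by its
    degrees of freedom (replicates minus days) before the square root.
    """
    df = counts.records.copy()
    totals = df[list(PHASES)].sum(axis=1)
    for phase in PHASES:
        df[f"pct_{phase}"] = 100.0 * df[phase] / totals
    rows = []
    for (tp, tf), grp in df.groupby(["timepoint_h", "transfection"], sort=True):
        row: dict = {"timepoint_h": tp, "transfection": tf, "n_replicates": len(grp)}
        for phase in PHASES:
            pcts = grp[f"pct_{phase}"]
            row[f"mean_pct_{phase}"] = float(pcts.mean())
            rss = 0.0
            n_days = grp["day_batch"].nunique()
            for _, day_grp in grp.groupby("day_batch"):
                day_pcts = day_grp[f"pct_{phase}"]
                rss += float(((day_pcts - day_pcts.mean()) ** 2).sum())
            if len(grp) <= n_days:
                warnings.warn("single replicate per day: se reported as 0", stacklevel=2)
                row[f"se_pct_{phase}"] = 0.0
            elif normalize_se:
                row[f"se_pct_{phase}"] = float(np.sqrt(rss / (len(grp) - n_days)))
            else:
                row[f"se_pct_{phase}"] = float(np.sqrt(rss))
        rows.append(row)
    return pd.DataFrame(rows)


def phase_lrt_report(
    counts: PhaseCountTable,
    control: str = "NC",
    pseudocount: float = 0.5,
    **fit_kwargs,
) -> pd.DataFrame:
    """LRT of every transfection against the control at each timepoint."""
    df = counts.records
    if control not in set(df["transfection"]):
        raise ValidationError(f"control transfection {control!r} absent")
    rows = []
    for tp in sorted(df["timepoint_h"].unique()):
        ctrl = counts.group(tp, control)
        ctrl_props = counts_to_proportions(ctrl, pseudocount)
        for tf in sorted(df.loc[df["timepoint_h"] == tp, "transfection"].unique()):
            if tf == control:
                continue
            grp = counts.group(tp, tf)
            res = lrt_two_groups(ctrl_props, counts_to_proportions(grp, pseudocount),
                                 **fit_kwargs)
            rows.append(
                {
                    "timepoint_h": tp,
                    "transfection": tf,
                    "control": control,
                    "D": res.D,
                    "df": res.df,
                    "pvalue": res.pvalue,
                    "alpha_null": list(np.round(res.fit_null.alpha, 6)),
                    "alpha_control": list(np.round(res.fit_a.alpha, 6)),
                    "alpha_group": list(np.round(res.fit_b.alpha, 6)),
                }
            )
    return pd.DataFrame(rows)
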