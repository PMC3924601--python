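"""SVD eigengene decomposition, proliferation index, and gene clustering.

Genes are rows; eigengenes (right singular vectors) live in array space.
The first eigengene is sign-oriented so that the deepest quiescence array
has a negative coordinate, making positive gene projections
proliferation-associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from quiescence_mirnome.core_io import ExpressionMatrix
from quiescence_mirnome.errors import ValidationError


@dataclass
class EigengeneDecomposition:
    """Thin SVD of a complete genes x arrays matrix."""

    eigengenes: np.ndarray  # arrays x n_components, orthonormal columns
    singular_values: np.ndarray
    variance_fractions: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    gene_loadings: np.ndarray  # genes x n_components (left vectors)
    orientation_flag: str = "unoriented"

    @property
    def n_components(self) -> int:
        return self.eigengenes.shape[1]


def filter_complete_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene with a missing value in any array."""
    keep = expr.complete_rows()
    if not keep.any():
        raise ValidationError("no gene has complete data")
    return expr.subset_features(keep)


def compute_svd(
    expr: ExpressionMatrix, orient_sample: str | None = None
) -> EigengeneDecomposition:
    """Thin SVD with the quiescent-pole sign convention.

    ``orient_sample`` names the array whose first-eigengene coordinate is
    forced negative (the deepest quiescence array; defaults to the last
    serum-starvation-style sample if named ``SS_96h``, else no flip).
    """
    if expr.missing_mask.any():
        raise ValidationError("matrix must be complete; run filter_complete_genes")
    if expr.n_samples < 2:
        raise ValidationError("need >= 2 arrays")
    u, s, vt = np.linalg.svd(expr.values, full_matrices=False)
    total = (s**2).sum()
    fractions = (s**2) / total if total > 0 else np.zeros_like(s)
    if len(s) > 1 and s[0] > 0 and abs(s[0] - s[1]) < 1e-12:
        warnings.warn("leading singular values tied; orientation arbitrary", stacklevel=2)
    flag = "unoriented"
    if orient_sample is None and "SS_96h" in expr.sample_ids:
        orient_sample = "SS_96h"
    if orient_sample is not None:
        j = expr.sample_index(orient_sample)
        if vt[0, j] > 0:
            vt = vt.copy()
            u = u.copy()
            vt[0] *= -1
            u[:, 0] *= -1
        flag = f"{orient_sample}-negative"
    return EigengeneDecomposition(
        eigengenes=vt.T,
        singular_values=s,
        variance_fractions=fractions,
        gene_ids=list(expr.feature_ids),
        sample_ids=list(expr.sample_ids),
        gene_loadings=u,
        orientation_flag=flag,
    )


def proliferation_index(
    decomp: EigengeneDecomposition, expr: ExpressionMatrix
) -> dict[str, float]:
    """Project each complete gene's profile onto the first eigengene."""
    e1 = decomp.eigengenes[:, 0]
    out: dict[str, float] = {}
    for i, gene in enumerate(expr.feature_ids):
        if expr.missing_mask[i].any():
            continue
        out[gene] = float(expr.values[i] @ e1)
    return out


def variance_explained(decomp: EigengeneDecomposition, k: int) -> float:
    """Fraction of total variance carried by the k-th eigengene (1-based)."""
    if not 1 <= k <= decomp.n_components:
        raise ValidationError(f"k={k} out of range 1..{decomp.n_components}")
    return float(decomp.variance_fractions[k - 1])


def hierarchical_cluster(expr: ExpressionMatrix, n_clusters: int = 4) -> dict[str, int]:
    """Centroid-linkage clustering of centered, L2-normalized gene rows.

    Rows are mean-centered and scaled to unit norm so squared Euclidean
    distance is a monotone transform of (1 - Pearson); the centroid-
    linkage tree is cut into ``n_clusters`` flat clusters (labels 1-based).
    """
    if expr.missing_mask.any():
        raise ValidationError("matrix must be complete")
    n = expr.n_features
    if not 1 <= n_clusters <= n:
        raise ValidationError("n_clusters must be in [1, n_genes]")
    rows = expr.values - expr.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rows = rows / norms
    if n == 1:
        return {expr.feature_ids[0]: 1}
    Z = linkage(rows, method="centroid")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return {gene: int(lab) for gene, lab in zip(expr.feature_ids, labels)}
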