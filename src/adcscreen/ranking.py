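"""Filter-based feature-selection statistics for two-group expression data.

Three rankers, all operating on a genes × samples log2 expression matrix and
two disjoint sample groups:

* ``moderated_t_qvalues`` — empirical-Bayes moderated t-statistic with
  Benjamini–Hochberg q-values. Per-gene variances are shrunk toward a prior
  estimated by the method of moments on log sample variances, which
  stabilises ranking when group sizes are small.
* ``ovl_rank`` — the overlapping coefficient of the two groups' adaptive
  kernel density estimates; small overlap = discriminative gene.
* ``svm_weight_rank`` — absolute weights of a linear soft-margin SVM trained
  to separate the groups on standardized expression.

``select_top_features`` takes the 2^k best genes of a ranking, the grid of
feature-set sizes used by the classification ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .kde import ovl

__all__ = [
    "RankMethod",
    "FeatureRanking",
    "moderated_t_qvalues",
    "ovl_rank",
    "svm_weight_rank",
    "select_top_features",
    "fit_variance_prior",
]


class RankMethod(str, Enum):
    MODT_Q = "modt"
    OVL = "ovl"
    SVM_WEIGHT = "svmw"


@dataclass
class FeatureRanking:
    """An ordered gene list with the per-gene statistic that produced it.

    ``gene_ids`` is sorted best-first according to the method's own sort
    direction (q ascending, OVL ascending, |weight| descending).
    ``statistic`` and ``direction`` (sign of the group-a minus group-b mean
    difference) are aligned with ``gene_ids``.
    """

    method: RankMethod
    gene_ids: list = field(default_factory=list)
    statistic: np.ndarray = field(default_factory=lambda: np.empty(0))
    direction: np.ndarray = field(default_factory=lambda: np.empty(0))
    extra: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene_id": self.gene_ids,
            "statistic": self.statistic,
            "rank": np.arange(1, len(self.gene_ids) + 1),
            "direction": self.direction,
        })
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _split(matrix: pd.DataFrame, group_a, group_b):
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    return a, b


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a convex decreasing map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Given per-gene sample variances ``s2`` on ``df`` degrees of freedom,
    returns (d0, s0_sq): the prior degrees of freedom and prior variance
    such that posterior variances (d0·s0² + df·s²)/(d0 + df) shrink each
    gene toward the common value. Genes with zero variance are excluded
    from estimation. d0 may be ``inf`` (variances consistent with a single
    common value).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 genes with positive variance to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    resid = var_e - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        # variances consistent with one common value: the prior is that
        # value (moment estimate = plain mean) with infinite weight
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_qvalues(matrix: pd.DataFrame, group_a, group_b,
                        prior: tuple[float, float] | None = None) -> FeatureRanking:
    """Moderated t-test ranking with BH q-values.

    Per gene: ordinary two-group t with pooled variance s_g² on
    d_g = n_a + n_b − 2 degrees of freedom; the posterior variance
    s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) replaces s_g² in the t-statistic,
    which then has d₀ + d_g degrees of freedom. (d₀, s₀²) come from
    :func:`fit_variance_prior` unless pinned via ``prior``. Genes are
    ranked by q ascending, ties by |t| descending, then gene id.
    """
    a, b = _split(matrix, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = (a - mean_a[:, None]) ** 2
    ss = ss.sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg
    if prior is None:
        d0, s0_sq = fit_variance_prior(s2, dg)
    else:
        d0, s0_sq = prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    delta = mean_a - mean_b
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = multipletests(p, method="fdr_bh")[1]
    genes = np.asarray(matrix.index)
    order = np.lexsort((genes, -np.abs(t), q))
    extra = pd.DataFrame({"t": t[order], "p": p[order], "q": q[order]},
                         index=genes[order])
    return FeatureRanking(
        method=RankMethod.MODT_Q,
        gene_ids=list(genes[order]),
        statistic=q[order],
        direction=np.sign(delta[order]),
        extra=extra,
    )


def ovl_rank(matrix: pd.DataFrame, group_a, group_b) -> FeatureRanking:
    """Rank genes by the overlapping coefficient of the two group densities.

    Smallest OVL first (least overlap = most discriminative). Ties break by
    |mean difference| descending, then gene id. Zero-spread genes fall back
    to the point-mass convention.
    """
    a, b = _split(matrix, group_a, group_b)
    coeffs = np.array([
        ovl(a[i], b[i], point_mass_convention=True).coefficient
        for i in range(a.shape[0])
    ])
    delta = a.mean(axis=1) - b.mean(axis=1)
    genes = np.asarray(matrix.index)
    order = np.lexsort((genes, -np.abs(delta), coeffs))
    return FeatureRanking(
        method=RankMethod.OVL,
        gene_ids=list(genes[order]),
        statistic=coeffs[order],
        direction=np.sign(delta[order]),
    )


def svm_weight_rank(matrix: pd.DataFrame, group_a, group_b, C: float = 1.0) -> FeatureRanking:
    """Rank genes by |weight| of a linear soft-margin SVM (largest first).

    Gene values are standardized (zero mean, unit variance; constant genes
    left at zero) before training so weights are comparable across genes.
    """
    a, b = _split(matrix, group_a, group_b)
    X = np.hstack([a, b]).T  # samples x genes
    y = np.r_[np.ones(a.shape[1]), -np.ones(b.shape[1])]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xs, y)
    w = np.abs(clf.coef_.ravel())
    delta = a.mean(axis=1) - b.mean(axis=1)
    genes = np.asarray(matrix.index)
    order = np.lexsort((genes, -w))
    return FeatureRanking(
        method=RankMethod.SVM_WEIGHT,
        gene_ids=list(genes[order]),
        statistic=w[order],
        direction=np.sign(delta[order]),
    )


def select_top_features(ranking: FeatureRanking, k: int) -> list:
    """Return the top 2^k gene ids of a ranking, 1 <= k <= 10."""
    if not 1 <= k <= 10:
        raise ValueError("k must be in 1..10")
    n = 2 ** k
    if len(ranking) < n:
        raise ValueError(f"ranking has {len(ranking)} genes, need {n}")
    return list(ranking.gene_ids[:n])


_RANKERS = {
    RankMethod.MODT_Q: moderated_t_qvalues,
    RankMethod.OVL: ovl_rank,
    RankMethod.SVM_WEIGHT: svm_weight_rank,
}


def rank_features(matrix: pd.DataFrame, group_a, group_b,
                  method: RankMethod | str) -> FeatureRanking:
    """Dispatch to one of the three rankers by name."""
    return _RANKERS[RankMethod(method)](matrix, group_a, group_b)
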