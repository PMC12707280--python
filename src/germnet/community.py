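"""Permutation-based multivariate statistics on sample distance matrices.

Provides Euclidean beta-diversity distances, PCA scores on transformed data,
a sequential (Type-I) PERMANOVA, a Spearman Mantel test, and the one-sided
slope test used to compare taxon abundances between sequencing platforms.

PERMANOVA partitions the Gower-centered squared-distance matrix with hat
matrices of nested design matrices, so multi-term models use sequential sums
of squares in the user-given term order.  All permutation p-values use the
add-one convention ``(1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .matrices import AbundanceMatrix


@dataclass
class PermTestResult:
    """Outcome of one permutation test (one PERMANOVA term, or a Mantel run)."""

    statistic: float
    permutation_p: float
    n_permutations: int
    seed: int
    term: str | None = None
    R2: float | None = None
    df: int | None = None


class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.data = pd.DataFrame(values, index=data.index, columns=data.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def euclidean_distance(matrix: AbundanceMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples (columns)."""
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    values = data.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in abundance matrix")
    if data.shape[1] < 2:
        raise ValueError("need at least two samples")
    dist = squareform(pdist(values.T, metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(dist, index=data.columns, columns=data.columns))


def pca_scores(
    matrix: AbundanceMatrix | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the leading principal axes of the centered data.

    Returns ``(scores, explained_variance_ratio)`` with samples as rows.
    """
    data = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    X = data.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n_components > min(p, n - 1):
        raise ValueError("n_components exceeds min(features, samples-1)")
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(X) > 1e-12):
        raise ValueError("matrix has no variance")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    evr = (S**2) / (S**2).sum()
    scores = U[:, :n_components] * S[:n_components]
    frame = pd.DataFrame(
        scores, index=data.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return frame, evr[:n_components]


def _gower_center(dist_values: np.ndarray) -> np.ndarray:
    a = -0.5 * dist_values**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy columns for a factor or an a:b interaction term."""
    parts = term.split(":")
    for part in parts:
        if part not in design.columns:
            raise ValueError(f"unknown design factor {part!r}")
        if design[part].nunique() < 2:
            raise ValueError(f"term {part!r} has fewer than two levels")
    combined = design[parts[0]].astype(str)
    for part in parts[1:]:
        combined = combined + ":" + design[part].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> list[PermTestResult]:
    """Sequential PERMANOVA of a distance matrix on design factors.

    ``terms`` are added in order (Type-I sums of squares); interaction terms
    are written ``"a:b"``.  Significance is by permuting sample identities of
    the distance matrix.  ``permutations`` may supply explicit permutation
    index arrays (e.g. for exhaustive enumeration); otherwise ``n_perm``
    random permutations are drawn from ``seed``.

    Returns one :class:`PermTestResult` per term plus a residual row (with
    statistic/p set to NaN).
    """
    meta = design.loc[dist.sample_ids]
    n = len(meta)
    g = _gower_center(dist.values)
    ss_total = np.trace(g)

    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    ranks = [1]
    x = ones
    for term in terms:
        x = np.hstack([x, _design_columns(meta, term)])
        hats.append(_hat(x))
        ranks.append(int(np.round(np.trace(hats[-1]))))
    df_terms = np.diff(ranks)
    if (df_terms < 1).any():
        bad = terms[int(np.argmin(df_terms))]
        raise ValueError(f"term {bad!r} adds no degrees of freedom")
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    def f_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        traces = np.array([np.sum(h * gmat) for h in hats])  # tr(H G), H symmetric
        ss = np.diff(traces)
        ss_res = np.trace(gmat) - traces[-1]
        f = (ss / df_terms) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = f_stats(g)

    rng = np.random.default_rng(seed)
    if permutations is None:
        perms = [rng.permutation(n) for _ in range(n_perm)]
    else:
        perms = [np.asarray(p) for p in permutations]
    exceed = np.zeros(len(terms))
    for perm in perms:
        gp = g[np.ix_(perm, perm)]
        _, f_perm = f_stats(gp)
        exceed += f_perm >= f_obs - 1e-12
    if permutations is None:
        # add-one convention: the observed labeling counts as one permutation
        pvals = (1.0 + exceed) / (1.0 + len(perms))
    else:
        # explicit (exhaustive) permutation set: it already includes the
        # observed labeling, so the p-value is the plain exceedance fraction
        pvals = exceed / len(perms)

    results = [
        PermTestResult(
            statistic=float(f_obs[i]),
            permutation_p=float(pvals[i]),
            n_permutations=len(perms),
            seed=seed,
            term=terms[i],
            R2=float(ss_obs[i] / ss_total),
            df=int(df_terms[i]),
        )
        for i in range(len(terms))
    ]
    ss_res = ss_total - ss_obs.sum()
    results.append(
        PermTestResult(
            statistic=float("nan"),
            permutation_p=float("nan"),
            n_permutations=len(perms),
            seed=seed,
            term="Residual",
            R2=float(ss_res / ss_total),
            df=df_res,
        )
    )
    return results


def permanova_table(results: list[PermTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "df": [r.df for r in results],
            "pseudo_F": [r.statistic for r in results],
            "R2": [r.R2 for r in results],
            "p": [r.permutation_p for r in results],
            "n_perm": [r.n_permutations for r in results],
            "seed": [r.seed for r in results],
        }
    )


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 5000, seed: int = 0
) -> PermTestResult:
    """Spearman Mantel test between two distance matrices (one-sided, greater).

    Permutes the sample order of the second matrix (rows and columns jointly).
    """
    if list(d1.sample_ids) != list(d2.sample_ids):
        raise ValueError("distance matrices must share the same sample order")
    v1 = d1.condensed()
    m2 = d2.values
    iu = np.triu_indices(m2.shape[0], k=1)
    v2 = m2[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero variance in a distance matrix")
    r1 = stats.rankdata(v1)
    r_obs = float(np.corrcoef(r1, stats.rankdata(v2))[0, 1])

    rng = np.random.default_rng(seed)
    n = m2.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = m2[np.ix_(perm, perm)][iu]
        r_perm = np.corrcoef(r1, stats.rankdata(v2p))[0, 1]
        if r_perm >= r_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermTestResult(
        statistic=r_obs, permutation_p=p, n_permutations=n_perm, seed=seed, term="mantel"
    )


def platform_slope_test(
    mean_abund_ref: np.ndarray | pd.Series, mean_abund_alt: np.ndarray | pd.Series
) -> tuple[float, float, float, float]:
    """Test whether the alt-vs-ref abundance slope falls below 1.

    OLS of alt on ref with an intercept; ``t = (b - 1) / SE(b)`` with n-2 df,
    one-sided p = P(T <= t).  Returns ``(slope, t, p, spearman_rho)``.
    """
    ref = np.asarray(mean_abund_ref, dtype=float)
    alt = np.asarray(mean_abund_alt, dtype=float)
    if ref.shape != alt.shape or ref.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = len(ref)
    if n < 3:
        raise ValueError("need at least three shared taxa")
    if np.ptp(ref) == 0:
        raise ValueError("zero variance in reference abundances")
    fit = stats.linregress(ref, alt)
    slope = float(fit.slope)
    se = float(fit.stderr)
    if se == 0.0:
        t = float("-inf") if slope < 1 else (float("inf") if slope > 1 else 0.0)
        p = 0.0 if slope < 1 else (1.0 if slope > 1 else 0.5)
    else:
        t = (slope - 1.0) / se
        p = float(stats.t.cdf(t, df=n - 2))
    rho = float(stats.spearmanr(ref, alt).statistic)
    return slope, float(t), p, rho
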