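"""Cross-kingdom differential correlation via the Fisher z-test.

Pairwise Spearman correlations between plant and microbial features are
computed separately within two sample conditions (intra-kingdom pairs are
never tested).  For each pair the two correlations are Fisher-transformed,
their difference ``delta_z = z_B - z_A`` is scored against
``SE = sqrt(1/(n_A - 3) + 1/(n_B - 3))`` with a two-tailed normal test, and
Benjamini-Hochberg adjusted q-values are computed over all testable pairs.
A pair is significant when ``q < q_threshold`` and ``|delta_z| > dz_threshold``.

Also here: bipartite network extraction above a correlation threshold and the
one-tailed hypergeometric overlap test.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrices import AbundanceMatrix, CountMatrix

logger = logging.getLogger(__name__)

Matrix = AbundanceMatrix | CountMatrix | pd.DataFrame


def _frame(matrix: Matrix) -> pd.DataFrame:
    return matrix.data if hasattr(matrix, "data") else matrix


def _rank_rows_unit(values: np.ndarray) -> np.ndarray:
    """Midrank each row, center and scale to unit norm; constant rows -> NaN."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ranks / norms
    out[norms.ravel() == 0, :] = np.nan
    return out


def pairwise_spearman(
    plant: Matrix, microbe: Matrix, sample_subset: list | None = None
) -> pd.DataFrame:
    """Spearman rho (midranks for ties) for every plant x microbe pair.

    Returns a plant-feature x microbial-feature table.  Features constant
    within the subset yield NaN for all their pairs; the count of such
    features is logged.
    """
    p = _frame(plant)
    m = _frame(microbe)
    if sample_subset is not None:
        p = p[list(sample_subset)]
        m = m[list(sample_subset)]
    if list(p.columns) != list(m.columns):
        raise ValueError("plant and microbe matrices must share sample order")
    if p.shape[1] < 4:
        raise ValueError("need at least four samples")
    rp = _rank_rows_unit(p.to_numpy(dtype=float))
    rm = _rank_rows_unit(m.to_numpy(dtype=float))
    n_const = int(np.isnan(rp[:, 0]).sum() + np.isnan(rm[:, 0]).sum())
    if n_const:
        logger.warning("%d constant feature(s); their correlations are missing", n_const)
    rho = np.clip(np.nan_to_num(rp) @ np.nan_to_num(rm).T, -1.0, 1.0)
    rho[np.isnan(rp[:, 0]), :] = np.nan
    rho[:, np.isnan(rm[:, 0])] = np.nan
    return pd.DataFrame(rho, index=p.index, columns=m.index)


def fisher_z(rho: float | np.ndarray, clamp: bool = False) -> float | np.ndarray:
    """Variance-stabilizing transform ``z = 0.5 * ln((1 + rho) / (1 - rho))``.

    ``|rho| >= 1`` raises unless ``clamp`` is set, in which case rho is
    clipped to ``1 - 1e-7`` in magnitude.
    """
    arr = np.asarray(rho, dtype=float)
    if clamp:
        arr = np.clip(arr, -1.0 + 1e-7, 1.0 - 1e-7)
    elif np.any(np.abs(arr[~np.isnan(arr)]) >= 1.0):
        raise ValueError("|rho| >= 1 has no finite Fisher z (pass clamp=True to clip)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(rho) else out


def fisher_z_test(
    rho_a: float | np.ndarray,
    rho_b: float | np.ndarray,
    n_a: int,
    n_b: int,
    clamp: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """The z-difference chain: returns ``(z_a, z_b, se, Z, p)``.

    ``Z = (z_b - z_a) / sqrt(1/(n_a-3) + 1/(n_b-3))``; the two-tailed p uses
    the complementary error function, stable far into the tail.
    """
    if n_a < 4 or n_b < 4:
        raise ValueError("each condition needs at least four samples")
    z_a = fisher_z(rho_a, clamp=clamp)
    z_b = fisher_z(rho_b, clamp=clamp)
    se = math.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    z_stat = (np.asarray(z_b) - np.asarray(z_a)) / se
    p = special.erfc(np.abs(z_stat) / math.sqrt(2.0))
    return z_a, z_b, se, z_stat, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_correlation(
    plant: Matrix,
    microbe: Matrix,
    samples_a: list,
    samples_b: list,
    q_threshold: float = 0.05,
    dz_threshold: float = 1.0,
) -> pd.DataFrame:
    """Fisher-z differential correlation between two sample conditions.

    Returns one row per testable cross-kingdom pair with columns
    ``plant_feature, microbial_feature, rho_a, rho_b, n_a, n_b, z_a, z_b,
    delta_z, se, z_stat, p, q, significant``.  Pairs whose correlation is
    missing in either condition are excluded from testing and from the BH
    family.
    """
    n_a, n_b = len(samples_a), len(samples_b)
    if n_a < 4 or n_b < 4:
        raise ValueError("each condition needs at least four samples")
    rho_a = pairwise_spearman(plant, microbe, samples_a)
    rho_b = pairwise_spearman(plant, microbe, samples_b)

    long = pd.DataFrame(
        {
            "plant_feature": np.repeat(rho_a.index.to_numpy(), rho_a.shape[1]),
            "microbial_feature": np.tile(rho_a.columns.to_numpy(), rho_a.shape[0]),
            "rho_a": rho_a.to_numpy().ravel(),
            "rho_b": rho_b.to_numpy().ravel(),
        }
    )
    testable = long.dropna(subset=["rho_a", "rho_b"]).reset_index(drop=True)
    n_dropped = len(long) - len(testable)
    if n_dropped:
        logger.warning("%d pair(s) untestable (missing correlation); excluded", n_dropped)

    # sample correlations can hit +/-1 (monotone pairs at small n): clamp
    z_a, z_b, se, z_stat, p = fisher_z_test(
        testable["rho_a"].to_numpy(), testable["rho_b"].to_numpy(), n_a, n_b, clamp=True
    )
    testable["n_a"] = n_a
    testable["n_b"] = n_b
    testable["z_a"] = z_a
    testable["z_b"] = z_b
    testable["delta_z"] = z_b - z_a
    testable["se"] = se
    testable["z_stat"] = z_stat
    testable["p"] = p
    testable["q"] = bh_adjust(p) if len(testable) else np.array([])
    testable["significant"] = (testable["q"] < q_threshold) & (
        testable["delta_z"].abs() > dz_threshold
    )
    return testable


def bipartite_network(
    corr_table: pd.DataFrame,
    rho_threshold: float = 0.7,
    condition: str = "",
    restrict_to: str | set | None = None,
    use_abs: bool = False,
) -> pd.DataFrame:
    """Edges with correlation above a threshold, as a long table.

    ``corr_table`` is the wide plant x microbe output of
    :func:`pairwise_spearman`.  By default the rule is ``rho > threshold``
    (signed); ``use_abs`` switches to ``|rho| > threshold``.  ``restrict_to``
    keeps only edges touching the given microbial feature(s) — e.g. one
    pathway and its partners, which yields a star.
    """
    table = corr_table
    if restrict_to is not None:
        wanted = {restrict_to} if isinstance(restrict_to, str) else set(restrict_to)
        table = table.loc[:, [c for c in table.columns if c in wanted]]
    values = table.abs() if use_abs else table
    mask = values > rho_threshold
    rows, cols = np.nonzero(mask.to_numpy())
    edges = pd.DataFrame(
        {
            "plant_feature": table.index.to_numpy()[rows],
            "microbial_feature": table.columns.to_numpy()[cols],
            "condition": condition,
            "rho": table.to_numpy()[rows, cols],
        }
    )
    return edges


def degree_summary(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-node degree counts for a bipartite edge list."""
    plant = edges.groupby("plant_feature").size().rename("degree").reset_index()
    plant["side"] = "plant"
    plant = plant.rename(columns={"plant_feature": "feature"})
    microbe = edges.groupby("microbial_feature").size().rename("degree").reset_index()
    microbe["side"] = "microbe"
    microbe = microbe.rename(columns={"microbial_feature": "feature"})
    return pd.concat([plant, microbe], ignore_index=True)[["feature", "side", "degree"]]


def to_networkx(edges: pd.DataFrame):
    """Edge list -> :class:`networkx.Graph` with a bipartite attribute."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.plant_feature, bipartite="plant")
        g.add_node(row.microbial_feature, bipartite="microbe")
        g.add_edge(
            row.plant_feature,
            row.microbial_feature,
            rho=float(row.rho),
            condition=str(row.condition),
        )
    return g


def overlap_hypergeom(
    set_a: set, set_b: set, universe: set, tail: str = "lower"
) -> tuple[int, float]:
    """One-tailed hypergeometric test of the overlap between two feature sets.

    With ``X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|)`` and observed
    overlap ``k = |A & B|``: lower tail gives ``P(X <= k)`` (fewer shared
    features than independence predicts), upper gives ``P(X >= k)``.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be contained in the universe")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    k = len(set_a & set_b)
    dist = stats.hypergeom(M=len(universe), n=len(set_a), N=len(set_b))
    p = float(dist.cdf(k)) if tail == "lower" else float(dist.sf(k - 1))
    return k, p
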