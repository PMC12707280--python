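"""Trait-association models and the three-method consensus.

For each trait the pipeline runs a univariate Spearman prefilter, an elastic
net (L1/L2 mixture 0.5, lambda by 10-fold cross-validation), and a
regression random forest (2000 trees, top-k features by importance per
feature-type stratum).  Features identified by two or more of
{diffcorr, elastic_net, random_forest} for a trait form the consensus, and a
cross-trait tally (the "k of methods x traits tests" count) is reported per
feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

METHODS = ("diffcorr", "elastic_net", "random_forest")
DEFAULT_TRAITS = ("shoot_biomass", "root_volume", "heat_score")


@dataclass
class TraitSpec:
    """A named response vector over the modeled samples."""

    name: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any():
            raise ValueError(f"trait {self.name!r} has missing responses")


def _as_series(trait: TraitSpec | pd.Series) -> pd.Series:
    return trait.values if isinstance(trait, TraitSpec) else trait


def univariate_prefilter(
    features: pd.DataFrame, trait: TraitSpec | pd.Series, rho_min: float = 0.05
) -> list[str]:
    """Feature ids with ``|Spearman rho(feature, trait)| > rho_min``.

    ``features`` is samples x features.  Constant features are dropped;
    a constant trait is an error.
    """
    y = _as_series(trait).loc[features.index].to_numpy(dtype=float)
    if features.shape[0] < 4:
        raise ValueError("need at least four samples")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    x = features.to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranks, axis=0)
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    ry /= np.linalg.norm(ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks / norms).T @ ry
    keep = np.abs(rho) > rho_min
    keep &= norms > 0
    return list(features.columns[keep])


def _standardize(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (x - x.mean(axis=0)) / sd


def elastic_net_associate(
    X: pd.DataFrame,
    y: TraitSpec | pd.Series,
    alpha_mix: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
) -> pd.DataFrame:
    """Nonzero elastic-net coefficients at the CV-selected penalty.

    ``X`` is samples x features and is standardized internally (idempotent on
    already-standardized input).  ``lambda_`` bypasses cross-validation and
    fits at a fixed penalty.  Returns a ``(feature, coefficient)`` table.
    """
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    if X.shape[0] < folds and lambda_ is None:
        raise ValueError("fewer samples than cross-validation folds")
    Xs = _standardize(X).to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        return pd.DataFrame(columns=["feature", "coefficient"])
    if lambda_ is not None:
        model = ElasticNet(alpha=lambda_, l1_ratio=alpha_mix, max_iter=50_000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # alpha=0 emits a convergence notice
            model.fit(Xs, yv)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        model = ElasticNetCV(
            l1_ratio=alpha_mix, cv=cv, alphas=100, max_iter=50_000, random_state=seed
        )
        model.fit(Xs, yv)
    coefs = model.coef_
    nz = np.nonzero(coefs)[0]
    return pd.DataFrame(
        {"feature": X.columns.to_numpy()[nz], "coefficient": coefs[nz]}
    ).sort_values("coefficient", key=np.abs, ascending=False, ignore_index=True)


def random_forest_associate(
    X: pd.DataFrame,
    y: TraitSpec | pd.Series,
    n_trees: int = 2000,
    top_k: int = 25,
    seed: int = 0,
    feature_types: pd.Series | None = None,
) -> pd.DataFrame:
    """Top-k features of a regression forest by impurity importance.

    When ``feature_types`` maps feature -> type (e.g. plant gene vs microbial
    pathway), the top-k cut is applied within each type separately, so each
    stratum contributes up to ``top_k`` features.
    """
    if X.shape[0] < 5:
        raise ValueError("need at least five samples")
    yv = _as_series(y).loc[X.index].to_numpy(dtype=float)
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(dtype=float), yv)
    table = pd.DataFrame({"feature": X.columns, "importance": forest.feature_importances_})
    if feature_types is not None:
        table["feature_type"] = table["feature"].map(feature_types)
    else:
        table["feature_type"] = "all"
    if top_k > len(table):
        warnings.warn("top_k exceeds available features; returning all", stacklevel=2)
    table = table.sort_values("importance", ascending=False)
    out = (
        table.groupby("feature_type", group_keys=False)[table.columns]
        .head(top_k)
        .sort_values("importance", ascending=False, ignore_index=True)
    )
    return out


def consensus_features(
    per_method_sets: dict[str, dict[str, set]], min_methods: int = 2
) -> pd.DataFrame:
    """Cross-method consensus per trait, plus a cross-trait hit tally.

    ``per_method_sets`` maps trait -> method -> selected feature set.
    Returns one row per (feature, trait) in the union, with ``methods_hit``
    (comma-joined), ``n_hits``, ``selected`` (n_hits >= min_methods), and
    ``total_hits`` — the feature's hit count across every (method, trait)
    cell, i.e. the "k of methods x traits" tally.
    """
    if not per_method_sets or all(not m for m in per_method_sets.values()):
        raise ValueError("empty method map")
    rows = []
    for trait, methods in per_method_sets.items():
        union: set = set()
        for feats in methods.values():
            union |= set(feats)
        for feature in sorted(union):
            hit = sorted(m for m, feats in methods.items() if feature in feats)
            rows.append(
                {
                    "feature": feature,
                    "trait": trait,
                    "methods_hit": ",".join(hit),
                    "n_hits": len(hit),
                    "selected": len(hit) >= min_methods,
                }
            )
    table = pd.DataFrame(rows)
    totals = table.groupby("feature")["n_hits"].sum().rename("total_hits")
    return table.merge(totals, on="feature")


def run_trait_models(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    traits: tuple[str, ...] = DEFAULT_TRAITS,
    diffcorr_features: set | None = None,
    feature_types: pd.Series | None = None,
    rho_min: float = 0.05,
    alpha_mix: float = 0.5,
    folds: int = 10,
    n_trees: int = 2000,
    top_k: int = 25,
    min_methods: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Prefilter + elastic net + random forest + consensus for each trait.

    ``features`` is samples x features.  ``diffcorr_features`` (features in
    at least one significant differential pair) contributes the third method
    when given.  Returns ``(consensus, en_tables, rf_tables)``.
    """
    per_trait: dict[str, dict[str, set]] = {}
    en_tables: dict[str, pd.DataFrame] = {}
    rf_tables: dict[str, pd.DataFrame] = {}
    for i, trait in enumerate(traits):
        y = metadata.loc[features.index, trait]
        kept = univariate_prefilter(features, y, rho_min=rho_min)
        sub = features[kept]
        en = elastic_net_associate(sub, y, alpha_mix=alpha_mix, folds=folds, seed=seed + i)
        rf = random_forest_associate(
            sub, y, n_trees=n_trees, top_k=top_k, seed=seed + i,
            feature_types=feature_types,
        )
        en_tables[trait] = en
        rf_tables[trait] = rf
        methods = {
            "elastic_net": set(en["feature"]),
            "random_forest": set(rf["feature"]),
        }
        if diffcorr_features is not None:
            methods["diffcorr"] = set(diffcorr_features) & set(features.columns)
        per_trait[trait] = methods
    consensus = consensus_features(per_trait, min_methods=min_methods)
    if feature_types is not None:
        consensus["feature_type"] = consensus["feature"].map(feature_types)
    return consensus, en_tables, rf_tables
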