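"""Factorial-design synthetic data with a known truth registry.

Generates plant and microbial count matrices for a fully crossed
genotype x soil x temperature x replicate design, together with a
gene -> pathway annotation and per-sample phenotypes.  Everything planted —
temperature-responsive features, cross-kingdom correlated pairs, and
trait-driving features — is recorded in a :class:`TruthRegistry` so that
downstream statistics can be scored against ground truth.

Generative model
----------------
* Plant counts are negative binomial around per-gene means that carry
  log-fold factor effects (genotype / soil / temperature).
* Microbial counts are compositional: per-sample log-normal latent
  abundances are closed to proportions and sampled multinomially at a drawn
  library depth, so column sums equal the depths exactly.
* Cross-kingdom correlated pairs share a bivariate-normal latent factor on
  the log scale (a Gaussian copula) whose correlation switches with the
  temperature condition.
* Phenotypes: an ordinal 0-4 heat score from a thresholded latent stress
  variable, and continuous traits built as linear combinations of planted
  feature abundances plus Gaussian noise.

One seed drives four documented substreams (plant, microbe, coupling,
phenotypes) via :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import CountMatrix

TRAIT_NAMES = ("heat_score", "shoot_biomass", "root_volume", "root_shoot_ratio")

# Latent-factor scales for planted cross-kingdom pairs (log units).  The
# plant side is large so negative-binomial noise barely attenuates the target
# rank correlation; the microbe side is kept smaller because big abundance
# swings in a compositional matrix bleed correlation into other features
# through closure.
_COUPLING_SD_PLANT = 2.0
_COUPLING_SD_MICROBE = 0.85
# Extra independent log-normal variation given to planted trait features so
# they remain separable predictors despite sharing a temperature response.
_TRAIT_FEATURE_SD = 0.5


@dataclass(frozen=True)
class DesignSpec:
    """Fully crossed factorial design: genotypes x soils x temperatures x reps."""

    n_genotypes: int = 3
    n_soils: int = 2
    n_temperatures: int = 2
    n_reps: int = 4
    temperature_levels: tuple[str, ...] = ("28C", "38C")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_soils", "n_temperatures", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.temperature_levels) < self.n_temperatures:
            raise ValueError("not enough temperature level labels")

    @property
    def n_samples(self) -> int:
        return self.n_genotypes * self.n_soils * self.n_temperatures * self.n_reps


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs for the count, coupling, and phenotype generators."""

    n_plant_genes: int = 400
    n_microbial_genes: int = 200
    n_pathways: int = 40
    plant_depth_range: tuple[int, int] = (100_000, 200_000)
    microbe_depth_range: tuple[int, int] = (50_000, 100_000)
    nb_dispersion: float = 0.1
    frac_de_temperature: float = 0.1
    effect_size_logfc: float = 1.0
    n_diffcorr_pairs: int = 20
    rho_condition_A: float = 0.8
    rho_condition_B: float = -0.8
    n_trait_features_plant: int = 5
    n_trait_features_microbe: int = 5
    trait_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_de_temperature <= 1.0):
            raise ValueError("frac_de_temperature must be in [0, 1]")
        for name in ("rho_condition_A", "rho_condition_B"):
            if not abs(getattr(self, name)) < 1.0:
                raise ValueError(f"|{name}| must be < 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be non-negative")
        if self.n_diffcorr_pairs > min(self.n_plant_genes, self.n_microbial_genes):
            raise ValueError("n_diffcorr_pairs exceeds available features")
        if self.n_trait_features_plant > self.n_plant_genes:
            raise ValueError("n_trait_features_plant exceeds n_plant_genes")
        if self.n_trait_features_microbe > self.n_microbial_genes:
            raise ValueError("n_trait_features_microbe exceeds n_microbial_genes")
        for rng_name in ("plant_depth_range", "microbe_depth_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{rng_name} must be a positive interval")


@dataclass
class TruthRegistry:
    """Everything the generator planted, for scoring downstream inference."""

    de_genes: list[tuple[str, str, str]] = field(default_factory=list)
    planted_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    trait_features: list[tuple[str, str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat, factor, direction in self.de_genes:
            rows.append(("de_gene", feat, factor, direction))
        for pf, mf, rho_a, rho_b in self.planted_pairs:
            rows.append(("planted_pair", pf, mf, f"{rho_a}|{rho_b}"))
        for feat, trait, coef in self.trait_features:
            rows.append(("trait_feature", feat, trait, str(coef)))
        return pd.DataFrame(rows, columns=["record", "field1", "field2", "field3"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """One row per sample of the fully crossed design, indexed by sample id."""
    genotypes = [f"G{i + 1}" for i in range(spec.n_genotypes)]
    soils = (["field", "autoclaved"] + [f"soil{i + 1}" for i in range(2, spec.n_soils)])[
        : spec.n_soils
    ]
    temperatures = list(spec.temperature_levels[: spec.n_temperatures])
    rows = []
    for g, s, t, r in product(genotypes, soils, temperatures, range(1, spec.n_reps + 1)):
        rows.append(
            {
                "sample_id": f"{g}_{s}_{t}_r{r}",
                "genotype": g,
                "soil": s,
                "temperature": t,
                "replicate": r,
            }
        )
    design = pd.DataFrame(rows).set_index("sample_id")
    assert len(design) == spec.n_samples
    return design


def _factor_effects(
    rng: np.random.Generator,
    design: pd.DataFrame,
    n_features: int,
    params: GeneratorParams,
    prefix: str,
    truth: TruthRegistry,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Log-scale effect matrix (features x samples) and temperature-up gene indices."""
    n_samples = len(design)
    effects = np.zeros((n_features, n_samples))
    ln2 = np.log(2.0)

    temps = design["temperature"].to_numpy()
    levels = pd.unique(temps)
    hot = (temps == levels[-1]).astype(float) if len(levels) > 1 else np.zeros(n_samples)

    pool = np.arange(n_features)
    if exclude is not None and len(exclude):
        pool = np.setdiff1d(pool, exclude)
    n_de = min(int(round(params.frac_de_temperature * n_features)), len(pool))
    de_idx = rng.choice(pool, size=n_de, replace=False) if n_de else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    up_idx: list[int] = []
    for i, sign in zip(de_idx, signs):
        effects[i] += sign * params.effect_size_logfc * ln2 * hot
        direction = "up" if sign > 0 else "down"
        truth.de_genes.append((f"{prefix}{i + 1:04d}", "temperature", direction))
        if sign > 0:
            up_idx.append(int(i))

    # Untracked nuisance structure: mild genotype and soil effects on a
    # random 5% of features each, so factors other than temperature also
    # shape the matrices.
    for factor in ("genotype", "soil"):
        labels = design[factor].to_numpy()
        lvls = pd.unique(labels)
        if len(lvls) < 2 or len(pool) == 0:
            continue
        n_fx = min(max(1, n_features // 20), len(pool))
        idx = rng.choice(pool, size=n_fx, replace=False)
        for i in idx:
            shifts = rng.normal(0.0, 0.5 * params.effect_size_logfc * ln2, size=len(lvls))
            shifts -= shifts.mean()
            lut = dict(zip(lvls, shifts))
            effects[i] += np.array([lut[l] for l in labels])
            truth.de_genes.append((f"{prefix}{i + 1:04d}", factor, "mixed"))
    return effects, up_idx


def _coupling_latents(
    rng: np.random.Generator, design: pd.DataFrame, params: GeneratorParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair, per-sample bivariate-normal latents with condition-switched rho."""
    n_samples = len(design)
    temps = design["temperature"].to_numpy()
    levels = pd.unique(temps)
    rho = np.where(
        temps == levels[0], params.rho_condition_A,
        params.rho_condition_B if len(levels) > 1 else params.rho_condition_A,
    )
    u = rng.standard_normal((params.n_diffcorr_pairs, n_samples))
    e = rng.standard_normal((params.n_diffcorr_pairs, n_samples))
    v = rho * u + np.sqrt(1.0 - rho**2) * e
    return u, v


def generate_counts(
    design: pd.DataFrame, params: GeneratorParams, seed: int = 0
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, TruthRegistry]:
    """Draw plant and microbial count matrices with planted structure.

    Returns ``(plant, microbe, annotation, truth)``.  Identical seeds give
    identical output.
    """
    if design.empty:
        raise ValueError("design has no samples")
    if len(design) < 2 and params.n_diffcorr_pairs > 0:
        raise ValueError("planted correlations are undefined for a single sample")

    ss = np.random.SeedSequence(seed)
    rng_plant, rng_microbe, rng_couple, _ = [np.random.default_rng(s) for s in ss.spawn(4)]
    truth = TruthRegistry()
    n_samples = len(design)
    samples = design.index

    plant_ids = [f"PG{i + 1:04d}" for i in range(params.n_plant_genes)]
    microbe_ids = [f"MG{i + 1:04d}" for i in range(params.n_microbial_genes)]

    # --- planted cross-kingdom pairs: disjoint feature slots per kingdom ---
    pair_plant = rng_couple.choice(
        params.n_plant_genes, size=params.n_diffcorr_pairs, replace=False
    )
    pair_microbe = rng_couple.choice(
        params.n_microbial_genes, size=params.n_diffcorr_pairs, replace=False
    )
    u, v = _coupling_latents(rng_couple, design, params)
    for k in range(params.n_diffcorr_pairs):
        truth.planted_pairs.append(
            (
                plant_ids[pair_plant[k]],
                microbe_ids[pair_microbe[k]],
                params.rho_condition_A,
                params.rho_condition_B,
            )
        )

    # --- plant counts: NB around depth * proportion * exp(effects) ---
    weights = rng_plant.lognormal(mean=0.0, sigma=1.5, size=params.n_plant_genes)
    # keep planted features well expressed so count noise stays small
    floor = np.quantile(weights, 0.25)
    weights[pair_plant] = np.maximum(weights[pair_plant], floor)
    effects, _up_idx = _factor_effects(
        rng_plant, design, params.n_plant_genes, params, "PG", truth, exclude=pair_plant
    )
    for k in range(params.n_diffcorr_pairs):
        effects[pair_plant[k]] += _COUPLING_SD_PLANT * u[k]

    # --- trait features: drawn from planted pair members where possible ---
    trait_plant = _pick_trait_features(
        rng_plant, pair_plant, params.n_trait_features_plant, params.n_plant_genes,
        effects, design, params, truth, plant_ids,
    )

    props = weights / weights.sum()
    depths = rng_plant.integers(*params.plant_depth_range, size=n_samples, endpoint=True)
    mu = props[:, None] * depths[None, :] * np.exp(effects)
    r = 1.0 / params.nb_dispersion
    plant_counts = rng_plant.negative_binomial(r, r / (r + mu))
    plant = CountMatrix(
        data=pd.DataFrame(plant_counts, index=plant_ids, columns=samples),
        kind="plant_gene",
    )

    # --- microbial counts: log-normal latents closed + multinomial depth ---
    m_weights = rng_microbe.lognormal(mean=0.0, sigma=1.5, size=params.n_microbial_genes)
    # planted microbe genes sit at a modest weight: abundant enough for low
    # sampling noise, small enough that their latent swings contribute
    # little common-mode variance to the compositional denominator
    m_weights[pair_microbe] = np.quantile(m_weights, 0.3)
    m_effects, _m_up_idx = _factor_effects(
        rng_microbe, design, params.n_microbial_genes, params, "MG", truth,
        exclude=pair_microbe,
    )
    for k in range(params.n_diffcorr_pairs):
        m_effects[pair_microbe[k]] += _COUPLING_SD_MICROBE * v[k]
    trait_microbe = _pick_trait_features(
        rng_microbe, pair_microbe, params.n_trait_features_microbe, params.n_microbial_genes,
        m_effects, design, params, truth, microbe_ids,
    )
    latent = (
        np.log(m_weights)[:, None]
        + m_effects
        + rng_microbe.normal(0.0, 0.15, size=(params.n_microbial_genes, n_samples))
    )
    latent -= latent.max(axis=0, keepdims=True)
    p = np.exp(latent)
    p /= p.sum(axis=0, keepdims=True)
    m_depths = rng_microbe.integers(
        *params.microbe_depth_range, size=n_samples, endpoint=True
    )
    microbe_counts = np.column_stack(
        [rng_microbe.multinomial(int(m_depths[j]), p[:, j]) for j in range(n_samples)]
    )
    microbe = CountMatrix(
        data=pd.DataFrame(microbe_counts, index=microbe_ids, columns=samples),
        kind="microbial_gene",
    )

    # --- annotation: genes assigned to pathways; ~5% unannotated, ~5% multi ---
    annotation = _make_annotation(rng_microbe, microbe_ids, params.n_pathways)

    _ = (trait_plant, trait_microbe)  # registered in truth
    return plant, microbe, annotation, truth


def _pick_trait_features(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n_wanted: int,
    n_features: int,
    effects: np.ndarray,
    design: pd.DataFrame,
    params: GeneratorParams,
    truth: TruthRegistry,
    ids: list[str],
) -> list[int]:
    """Select trait-driving features, preferring planted pair members.

    Trait-linked features double as cross-kingdom correlated features (the
    temperature-shifted pairs are the trait-relevant biology), so the
    consensus stage can find them through the differential-correlation route
    as well as through the regression models.  If there are not enough pair
    members, extra features are drafted at random.  Every chosen feature is
    given an upward temperature response (recorded in the truth registry), a
    small independent log-normal wiggle (drafted features only), and
    negative coefficients on the biomass-like traits — the planted sign structure that makes heat score
    anticorrelate with biomass.
    """
    temps = design["temperature"].to_numpy()
    levels = pd.unique(temps)
    hot = (temps == levels[-1]).astype(float) if len(levels) > 1 else np.zeros(len(design))
    chosen = [int(i) for i in candidates[:n_wanted]]
    drafted: set[int] = set()
    if len(chosen) < n_wanted:
        pool = np.setdiff1d(np.arange(n_features), np.asarray(chosen, dtype=int))
        extra = rng.choice(pool, size=n_wanted - len(chosen), replace=False)
        chosen.extend(int(i) for i in extra)
        drafted = {int(i) for i in extra}
    for i in chosen:
        effects[i] += params.effect_size_logfc * np.log(2.0) * hot
        truth.de_genes.append((ids[i], "temperature", "up"))
        if i in drafted:
            # pair members are already decorrelated by their coupling
            # latents; only drafted features need their own variation
            effects[i] += rng.normal(0.0, _TRAIT_FEATURE_SD, size=len(design))
        coef_biomass = -float(rng.uniform(1.0, 2.0))
        coef_root = -float(rng.uniform(1.0, 2.0))
        truth.trait_features.append((ids[i], "shoot_biomass", coef_biomass))
        truth.trait_features.append((ids[i], "root_volume", coef_root))
    return chosen


def _make_annotation(
    rng: np.random.Generator, gene_ids: list[str], n_pathways: int
) -> pd.DataFrame:
    pathway_ids = [f"PWY{i + 1:03d}" for i in range(n_pathways)]
    rows = []
    for gene in gene_ids:
        roll = rng.random()
        if roll < 0.05:
            continue  # unannotated -> "unassigned" bin at collapse time
        primary = pathway_ids[int(rng.integers(n_pathways))]
        rows.append((gene, primary))
        if roll > 0.95 and n_pathways > 1:
            secondary = pathway_ids[int(rng.integers(n_pathways))]
            if secondary != primary:
                rows.append((gene, secondary))
    return pd.DataFrame(rows, columns=["gene_id", "pathway_id"])


def _scaled_abundance(counts: CountMatrix, features: list[str]) -> pd.DataFrame:
    """Per-feature z-scored log1p counts (samples x features)."""
    sub = np.log1p(counts.data.loc[features].astype(float)).T
    sd = sub.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (sub - sub.mean(axis=0)) / sd


def generate_phenotypes(
    design: pd.DataFrame,
    plant: CountMatrix,
    microbe: CountMatrix,
    truth: TruthRegistry,
    params: GeneratorParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill phenotype columns: heat_score (0-4), shoot_biomass, root_volume, root:shoot.

    Continuous traits are linear combinations of planted trait-feature
    abundances plus N(0, trait_noise_sd) noise; heat score is a thresholded
    latent stress variable increasing with temperature exposure.
    """
    by_trait: dict[str, list[tuple[str, float]]] = {"shoot_biomass": [], "root_volume": []}
    all_ids = set(plant.feature_ids) | set(microbe.feature_ids)
    for feat, trait, coef in truth.trait_features:
        if feat not in all_ids:
            raise ValueError(f"trait feature {feat} missing from matrices")
        by_trait.setdefault(trait, []).append((feat, coef))

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    meta = design.copy()
    n = len(design)

    def combo(trait: str) -> np.ndarray:
        total = np.zeros(n)
        for feat, coef in by_trait.get(trait, []):
            source = plant if feat in plant.feature_ids else microbe
            total += coef * _scaled_abundance(source, [feat]).to_numpy().ravel()
        return total

    noise = params.trait_noise_sd
    biomass = combo("shoot_biomass") + rng.normal(0.0, noise, size=n)
    root = combo("root_volume") + rng.normal(0.0, noise, size=n)

    temps = design["temperature"].to_numpy()
    levels = pd.unique(temps)
    hot = (temps == levels[-1]).astype(float) if len(levels) > 1 else np.zeros(n)
    genotypes = pd.unique(design["genotype"])
    susceptibility = dict(zip(genotypes, np.linspace(-0.5, 0.5, len(genotypes))))
    latent_stress = (
        1.8 * hot
        + np.array([susceptibility[g] for g in design["genotype"]]) * hot
        + rng.normal(0.0, 0.5, size=n)
    )
    heat_score = np.digitize(latent_stress, bins=[-0.25, 0.5, 1.25, 2.0])

    meta["heat_score"] = heat_score.astype(int)
    meta["shoot_biomass"] = biomass
    meta["root_volume"] = root
    # masses live on a log-like scale; the ratio trait exponentiates first
    meta["root_shoot_ratio"] = np.exp(root - biomass)
    return meta


def simulate_dataset(
    spec: DesignSpec, params: GeneratorParams
) -> tuple[pd.DataFrame, CountMatrix, CountMatrix, pd.DataFrame, TruthRegistry]:
    """Convenience wrapper: design + counts + annotation + phenotypes + truth."""
    design = generate_design(spec)
    plant, microbe, annotation, truth = generate_counts(design, params, seed=spec.seed)
    meta = generate_phenotypes(design, plant, microbe, truth, params, seed=spec.seed)
    return meta, plant, microbe, annotation, truth
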