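"""End-to-end orchestration: simulate -> preprocess -> community stats ->
differential correlation -> trait models -> consensus, from one config.

Every stage writes plain-text tables into the output directory and records
its outputs (with SHA-256 checksums), seed, and timestamps in a run manifest
written last.  Rerunning with an unchanged config skips stages whose outputs
already match their recorded checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import euclidean_distance, mantel, permanova, permanova_table
from .diffcorr import bipartite_network, differential_correlation, pairwise_spearman
from .matrices import CountMatrix, read_annotation, read_metadata
from .preprocess import (
    FilterRule,
    clr_transform,
    collapse_pathways,
    filter_low_expression,
    median_ratio_normalize,
    relative_abundance,
)
from .simulate import DesignSpec, GeneratorParams, generate_counts, generate_design, generate_phenotypes
from .traits import run_trait_models

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (usually loaded from YAML)."""

    outdir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    plant_filter: tuple[int, int] = (75, 4)
    microbe_filter: tuple[int, int] = (250, 3)
    clr_pseudocount: float = 0.5
    condition_col: str = "temperature"
    condition_levels: tuple[str, str] = ("28C", "38C")
    n_perm_permanova: int = 999
    n_perm_mantel: int = 5000
    fdr: float = 0.05
    min_dz: float = 1.0
    edge_rho: float = 0.7
    traits: tuple[str, ...] = ("shoot_biomass", "root_volume", "heat_score")
    alpha_mix: float = 0.5
    folds: int = 10
    n_trees: int = 2000
    top_k: int = 25
    min_methods: int = 2

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0.0 < self.fdr <= 1.0):
            raise ValueError("fdr must be in (0, 1]")
        if self.min_dz < 0:
            raise ValueError("min_dz must be non-negative")
        if not (-1.0 <= self.edge_rho <= 1.0):
            raise ValueError("edge_rho must be in [-1, 1]")
        if self.n_perm_permanova < 1 or self.n_perm_mantel < 1:
            raise ValueError("permutation counts must be >= 1")
        if not (0.0 <= self.alpha_mix <= 1.0):
            raise ValueError("alpha_mix must be in [0, 1]")
        if not self.simulate and not self.inputs:
            raise ValueError("config needs either a simulate block or input paths")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input {key!r} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("plant_filter", "microbe_filter", "condition_levels", "traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, Path):
                value = str(value)
            elif isinstance(value, tuple):
                value = list(value)
            out[name] = value
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {name: int(child.generate_state(1)[0]) for name, child in zip(names, children)}


class _Manifest:
    def __init__(self, config: RunConfig):
        self.path = config.outdir / "manifest.json"
        self.config = config
        self.previous = {}
        if self.path.exists():
            try:
                old = json.loads(self.path.read_text())
                if old.get("config_digest") == config.digest():
                    self.previous = old.get("stages", {})
            except (json.JSONDecodeError, OSError):
                pass
        self.stages: dict[str, dict] = {}

    def can_skip(self, stage: str, outputs: list[Path]) -> bool:
        record = self.previous.get(stage)
        if not record:
            return False
        checks = record.get("outputs", {})
        if set(checks) != {str(p) for p in outputs}:
            return False
        for path_str, digest in checks.items():
            path = Path(path_str)
            if not path.exists() or _sha256(path) != digest:
                return False
        self.stages[stage] = record
        return True

    def record(self, stage: str, outputs: list[Path], seed: int, started: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seed": seed,
            "started": started,
            "finished": time.time(),
        }

    def write(self) -> None:
        payload = {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "stages": self.stages,
        }
        self.path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest payload as a dict."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed, ["simulate", "preprocess", "community", "diffcorr", "traits"]
    )
    manifest = _Manifest(config)

    # ---- stage: simulate (or load provided inputs) ----
    sim_outputs = [
        out / name
        for name in (
            "plant_counts.tsv",
            "microbe_counts.tsv",
            "annotation.tsv",
            "metadata.csv",
            "truth.tsv",
        )
    ]
    if config.simulate:
        started = time.time()
        if manifest.can_skip("simulate", sim_outputs):
            logger.info("simulate: outputs up to date, skipped")
        else:
            sim = dict(config.simulate)
            spec_kwargs = {
                k: sim.pop(k)
                for k in list(sim)
                if k in DesignSpec.__dataclass_fields__
            }
            spec = DesignSpec(**{**spec_kwargs, "seed": seeds["simulate"]})
            params = GeneratorParams(**sim)
            design = generate_design(spec)
            plant, microbe, annotation, truth = generate_counts(
                design, params, seed=spec.seed
            )
            meta = generate_phenotypes(design, plant, microbe, truth, params, seed=spec.seed)
            plant.to_tsv(out / "plant_counts.tsv")
            microbe.to_tsv(out / "microbe_counts.tsv")
            annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
            meta.to_csv(out / "metadata.csv")
            truth.write_tsv(out / "truth.tsv")
            manifest.record("simulate", sim_outputs, seeds["simulate"], started)
        plant = CountMatrix.from_tsv(out / "plant_counts.tsv", kind="plant_gene")
        microbe = CountMatrix.from_tsv(out / "microbe_counts.tsv", kind="microbial_gene")
        annotation = read_annotation(out / "annotation.tsv")
        meta = read_metadata(out / "metadata.csv")
    else:
        plant = CountMatrix.from_tsv(config.inputs["plant_counts"], kind="plant_gene")
        microbe = CountMatrix.from_tsv(
            config.inputs["microbe_counts"], kind="microbial_gene"
        )
        annotation = read_annotation(config.inputs["annotation"])
        meta = read_metadata(config.inputs["metadata"])

    # ---- stage: preprocess ----
    started = time.time()
    plant_f = filter_low_expression(plant, FilterRule(*config.plant_filter))
    microbe_f = filter_low_expression(microbe, FilterRule(*config.microbe_filter))
    if plant_f.shape[0] == 0 or microbe_f.shape[0] == 0:
        raise RuntimeError("preprocess: filtering removed every feature")
    pathways = collapse_pathways(microbe_f, annotation)
    pathway_clr = clr_transform(relative_abundance(pathways), pseudocount=config.clr_pseudocount)
    microbe_clr = clr_transform(relative_abundance(microbe_f), pseudocount=config.clr_pseudocount)
    plant_norm, size_factors = median_ratio_normalize(plant_f)
    pre_outputs = {
        "plant_normalized.tsv": plant_norm.data,
        "plant_size_factors.tsv": size_factors.to_frame(),
        "pathway_counts.tsv": pathways.data,
        "pathway_clr.tsv": pathway_clr.data,
        "microbe_clr.tsv": microbe_clr.data,
    }
    for name, frame in pre_outputs.items():
        frame.to_csv(out / name, sep="\t")
    manifest.record(
        "preprocess", [out / n for n in pre_outputs], seeds["preprocess"], started
    )

    # ---- stage: community statistics ----
    started = time.time()
    plant_log = np.log1p(plant_norm.data)
    d_plant = euclidean_distance(plant_log)
    d_microbe = euclidean_distance(microbe_clr)
    mantel_res = mantel(
        d_plant, d_microbe, n_perm=config.n_perm_mantel, seed=seeds["community"]
    )
    terms = ["genotype", "soil", config.condition_col]
    perm_tables = []
    for label, dist in (("plant", d_plant), ("microbe", d_microbe)):
        res = permanova(
            dist, meta, terms, n_perm=config.n_perm_permanova, seed=seeds["community"]
        )
        table = permanova_table(res)
        table.insert(0, "matrix", label)
        perm_tables.append(table)
    community = pd.concat(perm_tables, ignore_index=True)
    community.to_csv(out / "permanova.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "statistic": mantel_res.statistic,
                "p": mantel_res.permutation_p,
                "n_perm": mantel_res.n_permutations,
                "seed": mantel_res.seed,
            }
        ]
    ).to_csv(out / "mantel.tsv", sep="\t", index=False)
    manifest.record(
        "community",
        [out / "permanova.tsv", out / "mantel.tsv"],
        seeds["community"],
        started,
    )

    # ---- stage: differential correlation + networks ----
    started = time.time()
    level_a, level_b = config.condition_levels
    cond = meta[config.condition_col]
    samples_a = list(cond.index[cond == level_a])
    samples_b = list(cond.index[cond == level_b])
    records = differential_correlation(
        plant_norm,
        pathway_clr,
        samples_a,
        samples_b,
        q_threshold=config.fdr,
        dz_threshold=config.min_dz,
    )
    records.to_csv(out / "diffcorr.tsv", sep="\t", index=False)
    edges = []
    for label, subset in (("A", samples_a), ("B", samples_b)):
        rho = pairwise_spearman(plant_norm, pathway_clr, subset)
        edges.append(bipartite_network(rho, rho_threshold=config.edge_rho, condition=label))
    network = pd.concat(edges, ignore_index=True)
    network.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    manifest.record(
        "diffcorr",
        [out / "diffcorr.tsv", out / "network_edges.tsv"],
        seeds["diffcorr"],
        started,
    )

    # ---- stage: trait models + consensus ----
    started = time.time()
    features = pd.concat([plant_log.T, pathway_clr.data.T], axis=1)
    feature_types = pd.Series(
        ["plant_gene"] * plant_log.shape[0] + ["pathway"] * pathway_clr.shape[0],
        index=features.columns,
    )
    sig = records[records["significant"]]
    diffcorr_hits = set(sig["plant_feature"]) | set(sig["microbial_feature"])
    consensus, en_tables, rf_tables = run_trait_models(
        features,
        meta,
        traits=config.traits,
        diffcorr_features=diffcorr_hits,
        feature_types=feature_types,
        alpha_mix=config.alpha_mix,
        folds=config.folds,
        n_trees=config.n_trees,
        top_k=config.top_k,
        min_methods=config.min_methods,
        seed=seeds["traits"],
    )
    consensus.to_csv(out / "consensus.tsv", sep="\t", index=False)
    en_all = pd.concat(
        [t.assign(trait=trait) for trait, t in en_tables.items()], ignore_index=True
    )
    rf_all = pd.concat(
        [t.assign(trait=trait) for trait, t in rf_tables.items()], ignore_index=True
    )
    en_all.to_csv(out / "elastic_net.tsv", sep="\t", index=False)
    rf_all.to_csv(out / "random_forest.tsv", sep="\t", index=False)
    manifest.record(
        "traits",
        [out / "consensus.tsv", out / "elastic_net.tsv", out / "random_forest.tsv"],
        seeds["traits"],
        started,
    )

    manifest.write()
    return json.loads(manifest.path.read_text())
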