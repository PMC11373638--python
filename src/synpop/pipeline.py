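"""End-to-end pipeline: generate -> filter/impute -> diversity -> simulate ->
predict, with a reproducibility manifest.

The pipeline is configured by a plain dictionary (usually loaded from YAML);
a single master seed is split into named per-stage substreams so replicate
structure is reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genio, gpred, popdiv, synsim, synthdata

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("synthdata", "filter", "impute", "popdiv", "simulate", "predict")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    founder: dict = dataclasses.field(default_factory=dict)
    noise: dict = dataclasses.field(default_factory=dict)
    filter: dict = dataclasses.field(default_factory=dict)
    impute: dict = dataclasses.field(default_factory=lambda: {"l": 30, "k": 10})
    design: dict = dataclasses.field(default_factory=dict)
    trait: dict = dataclasses.field(default_factory=dict)
    cv: dict = dataclasses.field(default_factory=lambda: {"folds": 4, "reps": 10})
    popdiv: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {key!r} not found: {path}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(d)
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic, named per-stage substream seed (below 2**31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and write a manifest.

    Returns the manifest dictionary (also written to ``manifest.json`` in the
    output directory).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: _stage_seed(config.seed, stage) for stage in STAGES}
    manifest: dict = {
        "synpop_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": [],
        "parameters": {
            "founder": config.founder,
            "noise": config.noise,
            "filter": config.filter,
            "impute": config.impute,
            "design": config.design,
            "trait": config.trait,
            "cv": config.cv,
            "popdiv": config.popdiv,
        },
        "input_checksums": {k: _sha256(v) for k, v in config.inputs.items()},
        "outputs": [],
    }

    def emit(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    geno: genio.GenotypeMatrix | None = None
    labels: pd.Series | None = None
    pool = None

    def current_genotypes() -> genio.GenotypeMatrix:
        nonlocal geno
        if geno is None:
            src = config.inputs.get("genotypes")
            if src is None:
                raise StageError("no genotype matrix available: run the "
                                 "synthdata stage or provide inputs.genotypes")
            geno = (genio.read_vcf(src) if str(src).endswith(".vcf")
                    else genio.read_tsv(src, config.inputs.get("map")))
        return geno

    for stage in config.stages:
        try:
            if stage == "synthdata":
                spec = synthdata.FounderPoolSpec(
                    **{**config.founder, "seed": seeds["synthdata"]})
                noise = synthdata.NoiseSpec(**config.noise)
                pool = synthdata.generate_founder_pool(spec)
                complete = pool.to_genotype_matrix()
                geno, _ = synthdata.degrade_to_gbs(complete, noise,
                                                   seed=seeds["synthdata"])
                genio.write_tsv(geno, out / "genotypes.tsv",
                                map_path=out / "genetic_map.tsv")
                emit(out / "genotypes.tsv")
                emit(out / "genetic_map.tsv")
                labels = pd.Series("Founder", index=geno.individual_ids)
            elif stage == "filter":
                params = genio.FilterParams(**config.filter)
                geno, report = genio.filter_genotypes(current_genotypes(), params)
                (out / "filter_report.json").write_text(report.to_json())
                emit(out / "filter_report.json")
            elif stage == "impute":
                geno = genio.ld_knni_impute(current_genotypes(),
                                            **config.impute)
                genio.write_tsv(geno, out / "genotypes_imputed.tsv")
                emit(out / "genotypes_imputed.tsv")
            elif stage == "popdiv":
                g = current_genotypes()
                if "labels" in config.inputs:
                    lab_df = pd.read_csv(config.inputs["labels"], sep="\t",
                                         dtype=str)
                    labels = pd.Series(lab_df["group"].to_numpy(),
                                       index=lab_df["individual_id"])
                if labels is None or labels.nunique() < 2:
                    # single-group fallback: split in half for the two-group
                    # statistics so the stage still produces its tables
                    half = g.n_individuals // 2
                    labels = pd.Series(
                        ["A"] * half + ["B"] * (g.n_individuals - half),
                        index=g.individual_ids)
                summary = popdiv.diversity_summary(g, labels)
                summary.to_csv(out / "diversity_summary.tsv", sep="\t",
                               float_format="%.6g")
                emit(out / "diversity_summary.tsv")
                pca = popdiv.pca_structure(g)
                pca.frame().iloc[:, :10].to_csv(out / "pca_coordinates.tsv",
                                                sep="\t", float_format="%.6g")
                emit(out / "pca_coordinates.tsv")
                ld_kwargs = dict(config.popdiv)
                ld = popdiv.ld_decay(g, labels=labels, **ld_kwargs)
                decay = {g_: {"mean_r2": res.mean_r2,
                              "decay_distance_bp": res.decay_distance_bp,
                              "n_pairs": res.n_pairs}
                         for g_, res in ld.items()}
                (out / "ld_decay.json").write_text(json.dumps(decay, indent=2,
                                                              allow_nan=True))
                emit(out / "ld_decay.json")
            elif stage == "simulate":
                design = synsim.SimulationDesign(
                    **{**config.design, "seed": seeds["simulate"]})
                if pool is None:
                    spec = synthdata.FounderPoolSpec(
                        **{**config.founder, "seed": seeds["synthdata"]})
                    pool = synthdata.generate_founder_pool(spec)
                table = synsim.run_synthetic_experiment(design, pool)
                table.to_tsv(out / "variance_table.tsv")
                emit(out / "variance_table.tsv")
                agg = table.aggregate()
                agg.to_csv(out / "variance_summary.tsv", sep="\t", index=False,
                           float_format="%.6g")
                emit(out / "variance_summary.tsv")
                letters = {}
                for h2 in design.h2_levels:
                    tk = table.tukey_by_parent_count(h2)
                    letters[str(h2)] = {"hsd": tk.hsd, "letters": tk.letters,
                                        "means": tk.means}
                (out / "tukey_parent_counts.json").write_text(
                    json.dumps(letters, indent=2))
                emit(out / "tukey_parent_counts.json")
            elif stage == "predict":
                if pool is None:
                    raise StageError("predict stage requires the synthdata "
                                     "stage (synthetic training population)")
                rng_seed = seeds["predict"]
                trait_cfg = dict(config.trait)
                trait = synsim.sample_qtl_effects(
                    pool,
                    n_qtl=trait_cfg.get("n_qtl", min(200, pool.n_loci // 2)),
                    target_mean=trait_cfg.get("target_mean", 1.0),
                    v0=trait_cfg.get("v0", 0.3),
                    target_h2=trait_cfg.get("target_h2", 0.6),
                    rng=rng_seed,
                )
                noise = synthdata.NoiseSpec(**config.noise)
                ph = synthdata.generate_phenotypes(pool, trait, noise,
                                                   years=2, seed=rng_seed)
                g_complete = pool.to_genotype_matrix()
                syn = pool
                targets = {}
                rng = np.random.default_rng(rng_seed)
                for gen in range(1, 5):
                    syn = synsim.advance_generation(
                        syn, n_crosses=50, progeny_per_cross=2, rng=rng,
                        generation=f"SYN{gen}")
                    targets[f"SYN{gen}"] = syn.to_genotype_matrix()
                result = gpred.predict_populations(
                    ph, g_complete, targets,
                    reps=config.cv.get("reps", 10), seed=rng_seed)
                result.predictions.to_csv(out / "predictions.tsv", sep="\t",
                                          index=False, float_format="%.6g")
                emit(out / "predictions.tsv")
                cv = gpred.cross_validate(ph, g_complete,
                                          folds=config.cv.get("folds", 4),
                                          reps=config.cv.get("reps", 10),
                                          seed=rng_seed)
                cv_summary = {
                    "mean_ability": cv.mean_ability,
                    "per_rep": cv.per_rep.round(6).to_dict(),
                    "tukey_letters": result.tukey.letters,
                    "hsd": result.tukey.hsd,
                }
                (out / "cv_summary.json").write_text(
                    json.dumps(cv_summary, indent=2))
                emit(out / "cv_summary.json")
            manifest["stages_run"].append(stage)
        except Exception as exc:
            manifest["failed_stage"] = {"stage": stage, "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
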