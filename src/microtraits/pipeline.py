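"""End-to-end orchestration: condense -> filter -> temperature-adjust ->
correlations -> model suite -> PGLS -> contours, with a run log and
seeded, hash-stamped outputs. Reruns with the same configuration are
byte-identical."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .condense import RANKS, condense_records, filter_taxa
from .stats_suite import (
    contours_to_frame,
    density_contours,
    fit_model_suite,
    group_separation,
    pairwise_r2,
    variance_partition,
)
from .synthetic_data import SyntheticConfig, generate_dataset
from .taxo_phylo import build_tree, covariance, ols_fit, pgls_fit
from .temp_adjust import adjust_table

logger = logging.getLogger(__name__)

DEFAULT_HABITATS = (
    "soil",
    "fresh_water",
    "marine_water",
    "thermal",
    "host_endotherm",
    "host_ectotherm",
    "host_other",
    "other",
)

_PGLS_PAIRS = (
    ("g_adj", "genome_size_bp"),
    ("g_adj", "cell_diameter_um"),
    ("genome_size_bp", "cell_diameter_um"),
)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run (unknown keys are rejected)."""

    input_path: str | None = None  # record-level CSV; None -> simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    outdir: str = "results"
    seed: int = 0
    include_intracellular: bool = False
    temp_adjust_mode: str = "refit"  # or "fixed"
    traits: tuple = ("g_adj", "cell_diameter_um", "genome_size_bp", "rrn_copies")
    habitat_levels: tuple | None = DEFAULT_HABITATS
    run_models: bool = True
    run_pgls: bool = True
    run_contours: bool = True
    contour_levels: tuple = (0.25, 0.5, 0.75)
    strict_io: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("traits", "habitat_levels", "contour_levels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage(name: str, fn, counts: dict):
    try:
        return fn()
    except Exception as e:
        raise RuntimeError(
            f"pipeline stage '{name}' failed (row counts so far: {counts}): {e}"
        ) from e


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Outputs: the condensed species table, a correlation-matrix pair of CSVs
    (r^2 and pairwise n), the nine-model AIC table, the variance-partition
    JSON, an OLS-vs-PGLS comparison, trophic-group separation, density
    contour polylines, and a run log recording the seed, versions, and row
    counts at every stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_dict.pop("outdir")  # output location is not part of the analysis identity
    cfg_hash = io.config_hash(cfg_dict)
    seed = config.seed

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("microtraits")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    counts: dict[str, int] = {}
    bundle: dict = {"config_hash": cfg_hash, "seed": seed}
    try:
        logger.info("microtraits v%s; seed=%d; config=%s", __version__, seed, cfg_hash)

        def load():
            if config.input_path is not None:
                return io.read_trait_table(config.input_path, strict=config.strict_io)
            syn = dict(config.synthetic)
            syn.setdefault("seed", seed)
            _, records = generate_dataset(SyntheticConfig.from_dict(syn))
            return records

        records = _stage("read", load, counts)
        counts["records"] = len(records)

        species = _stage("condense", lambda: condense_records(records), counts)
        counts["species"] = len(species)
        if config.habitat_levels is not None and "habitat" in species.columns:
            known = species["habitat"].isna() | species["habitat"].isin(config.habitat_levels)
            n_unknown = int((~known).sum())
            if n_unknown:
                logger.warning("%d species with habitat outside vocabulary -> missing", n_unknown)
                species.loc[~known, "habitat"] = np.nan

        species = _stage(
            "filter_taxa", lambda: filter_taxa(species, config.include_intracellular), counts
        )
        counts["species_after_filter"] = len(species)

        species, temp_model = _stage(
            "temp_adjust", lambda: adjust_table(species, mode=config.temp_adjust_mode), counts
        )
        counts["species_with_g_adj"] = int(species["g_adj"].notna().sum())
        logger.info(
            "temperature model: slope=%.4f intercept=%.4f r2=%.3f n=%d",
            temp_model.slope, temp_model.intercept, temp_model.r2, temp_model.n,
        )
        io.write_table(species, outdir / "species.csv", seed, cfg_hash)
        bundle["species"] = species
        bundle["temp_model"] = temp_model

        corr = _stage("pairwise_r2", lambda: pairwise_r2(species, config.traits), counts)
        io.write_correlation_outputs(corr, str(outdir / "correlations"), seed, cfg_hash)
        bundle["correlations"] = corr

        if config.run_models:
            suite = _stage("model_suite", lambda: fit_model_suite(species), counts)
            io.write_table(suite.to_frame(), outdir / "model_suite.csv", seed, cfg_hash)
            bundle["model_suite"] = suite
            if len(suite.models) == 9:
                part = variance_partition(suite)
                part["best_model"] = suite.best_label
                (outdir / "variance_partition.json").write_text(
                    json.dumps({"seed": seed, "config": cfg_hash, **part}, indent=2) + "\n"
                )
                bundle["variance_partition"] = part

        if config.run_pgls:
            rows = _stage("pgls", lambda: _pgls_comparison(species), counts)
            io.write_table(rows, outdir / "pgls_comparison.csv", seed, cfg_hash)
            bundle["pgls_comparison"] = rows

        if "trophic" in species.columns:
            labs = species["trophic"].astype(str)
            if (labs == "oligotroph").sum() >= 2 and (labs == "copiotroph").sum() >= 2:
                sep = {
                    t: group_separation(species, t)
                    for t in config.traits
                    if t in species.columns
                }
                (outdir / "trophic_separation.json").write_text(
                    json.dumps({"seed": seed, "config": cfg_hash, **sep}, indent=2) + "\n"
                )
                bundle["trophic_separation"] = sep

        if config.run_contours:
            def contours():
                sub = species.dropna(subset=["cell_diameter_um", "genome_size_bp"])
                return density_contours(
                    np.log10(sub["cell_diameter_um"].to_numpy(dtype=float)),
                    np.log10(sub["genome_size_bp"].to_numpy(dtype=float)),
                    levels=config.contour_levels,
                )

            cts = _stage("contours", contours, counts)
            io.write_table(contours_to_frame(cts), outdir / "contours.csv", seed, cfg_hash)
            bundle["contours"] = cts

        logger.info("row counts: %s", counts)
        bundle["counts"] = counts
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()


def _pgls_comparison(species: pd.DataFrame) -> pd.DataFrame:
    """OLS vs PGLS simple regressions for the main trait pairs.

    Each pair is fit on its own complete-case subset; the taxonomy tree and
    Brownian covariance are rebuilt per subset so rows stay aligned.
    """
    from .stats_suite import analysis_scale

    rows = []
    for resp, pred in _PGLS_PAIRS:
        sub = species.dropna(subset=[resp, pred] + list(RANKS))
        if len(sub) < 10:
            continue
        tree = build_tree(list(zip(*[sub[r] for r in RANKS])))
        V = covariance(tree)
        Xs = analysis_scale(sub, (resp, pred))
        y = Xs[resp].to_numpy()
        x = Xs[pred].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        ols = ols_fit(y, X, terms=("const", pred))
        pgls = pgls_fit(y, X, V, terms=("const", pred))
        rows.append(
            {
                "response": resp,
                "predictor": pred,
                "n": len(sub),
                "ols_slope": ols.beta[1],
                "ols_r2": ols.r2,
                "pgls_slope": pgls.beta[1],
                "pgls_r2": pgls.r2,
            }
        )
    return pd.DataFrame(rows)
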