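"""End-to-end orchestration of the four analyses on one dataset.

Sequence: feature construction → inter-variable correlations → binned
frequency curves → classification sweep (+ optional combination comparison
and permutation null) → laminar correlations and partial correlations →
topology. Every output table is written as CSV into one run directory and
carries the number of projections it was computed on; the summary log
records every seed and flag so reruns are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import features as feat
from . import frequency as freq
from . import io
from . import synthetic
from . import topology as topo
from .stats import partial_correlation, pearson

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """One pipeline run: exactly one data source (files xor synthetic)."""

    out_dir: Path
    area_table: Path | None = None
    projection_table: Path | None = None
    synthetic_config: synthetic.SyntheticConfig | None = None
    seed: int = 0
    run_frequency: bool = True
    run_classification: bool = True
    run_permutation: bool = True
    run_laminar: bool = True
    run_topology: bool = True
    cv_rounds: int = 100
    permutation_rounds: int = 100
    n_folds: int = 5
    laminar_count_threshold: int = 20
    compare_combinations: bool = False
    prediction_threshold: float = 0.85

    def __post_init__(self) -> None:
        have_files = self.area_table is not None and self.projection_table is not None
        have_synth = self.synthetic_config is not None
        if have_files == have_synth:
            raise ValueError("configure exactly one data source: CSV tables xor a synthetic config")


def _load(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.synthetic_config is not None:
        ds = synthetic.generate_dataset(config.synthetic_config.with_seed(config.seed))
        return ds.areas, ds.projections
    return io.read_areas(config.area_table), io.read_projections(config.projection_table)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses; returns a manifest of written files."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "outputs": {}}

    def emit(name: str, df: pd.DataFrame, n: int | None = None) -> None:
        path = io.write_table(df, out / f"{name}.csv")
        manifest["outputs"][name] = {"path": str(path), "n": int(n if n is not None else len(df))}

    stage = "load"
    try:
        areas, projections = _load(config)
        emit("areas", areas)
        emit("projections", projections)

        stage = "features"
        features, laminar = feat.build_feature_table(
            areas, projections, config.laminar_count_threshold
        )
        emit("features", features)
        dens = features[features["density_available"]]
        corr_rows = [
            ("abs_log_ratio_density~distance",
             pearson(dens["abs_log_ratio_density"], dens["distance"]), len(dens)),
            ("abs_log_ratio_thickness~distance",
             pearson(features["abs_log_ratio_thickness"], features["distance"]), len(features)),
            ("abs_log_ratio_density~abs_log_ratio_thickness",
             pearson(dens["abs_log_ratio_density"], dens["abs_log_ratio_thickness"]), len(dens)),
            ("ln_density~thickness",
             pearson(np.log(areas["density"].dropna()),
                     areas["thickness"][areas["density"].notna()]),
             int(areas["density"].notna().sum())),
        ]
        emit("variable_correlations", _stat_frame(corr_rows))

        if config.run_frequency:
            stage = "frequency"
            for var, width in freq.DEFAULT_BIN_WIDTHS.items():
                subset = dens if var.endswith("density") else features
                binned = freq.bin_relative_frequency(
                    subset[var], subset["present"].to_numpy(), width, variable=var
                )
                trend = freq.frequency_trend(binned)
                tab = binned.to_frame()
                tab["trend_rho"] = trend.statistic
                tab["trend_p"] = trend.p_value
                emit(f"frequency_{var}", tab, n=len(subset))

        if config.run_classification:
            stage = "classification"
            fs = ("abs_log_ratio_density", "distance")
            X = dens.loc[:, list(fs)].to_numpy(float)
            y = dens["present"].to_numpy(bool)
            summary = clf.cross_validate(
                X, y, fs, n_folds=config.n_folds, rounds=config.cv_rounds, seed=config.seed
            )
            emit("classification_sweep", summary.to_frame(), n=len(dens))
            emit(
                "classification_rounds",
                pd.DataFrame({"round": np.arange(config.cv_rounds), "mean_youden": summary.mean_youden}),
                n=len(dens),
            )
            if config.compare_combinations:
                comparison = clf.compare_feature_combinations(
                    dens, y, rounds=config.cv_rounds, seed=config.seed
                )
                emit("combination_ranking", comparison.ranking, n=len(dens))
            if config.run_permutation:
                stage = "permutation"
                null = clf.permutation_null(
                    X, y, fs, n_folds=config.n_folds,
                    rounds=config.permutation_rounds, seed=config.seed + 1,
                )
                emit("permutation_sweep", null.to_frame(), n=len(dens))
            stage = "prediction"
            model = clf.train(X, y, fs)
            unknown = feat.unknown_pair_features(areas, projections)
            predictions = clf.predict_unknown(model, unknown, config.prediction_threshold)
            emit("unknown_predictions", predictions)

        if config.run_laminar:
            stage = "laminar"
            lam = laminar[laminar["density_available"]]
            rows = []
            if len(lam) >= 4:
                rows = [
                    ("nsg~log_ratio_density",
                     pearson(lam["nsg_percent"], lam["log_ratio_density"]), len(lam)),
                    ("nsg~log_ratio_thickness",
                     pearson(lam["nsg_percent"], lam["log_ratio_thickness"]), len(lam)),
                    ("nsg~log_ratio_density|thickness",
                     partial_correlation(lam["nsg_percent"], lam["log_ratio_density"],
                                         lam["log_ratio_thickness"]), len(lam)),
                    ("nsg~log_ratio_thickness|density",
                     partial_correlation(lam["nsg_percent"], lam["log_ratio_thickness"],
                                         lam["log_ratio_density"]), len(lam)),
                    ("nsg~distance", pearson(lam["nsg_percent"], lam["distance"]), len(lam)),
                    ("nsg_inequality~distance",
                     pearson(lam["nsg_inequality"], lam["distance"]), len(lam)),
                ]
            emit("laminar_correlations", _stat_frame(rows), n=len(lam))

        if config.run_topology:
            stage = "topology"
            injected = areas.loc[areas["injected"], "area_id"].tolist()
            degrees = topo.area_degree(projections, injected)
            emit("degree", degrees.rename("degree").reset_index(), n=len(injected))
            rows = []
            dens_series = areas.set_index("area_id")["density"]
            try:
                rel = topo.degree_density_relation(degrees, dens_series, leave_one_out=False)
                rows += [("degree~density_pearson", rel.pearson, rel.pearson.n),
                         ("degree~density_spearman", rel.spearman, rel.spearman.n)]
            except ValueError as exc:
                logger.warning("degree-density relation skipped: %s", exc)
            inj = areas[areas["injected"]]
            try:
                core_cmp = topo.core_density_comparison(inj)
                rows.append(("core_vs_noncore_density", core_cmp.test,
                             core_cmp.n_core + core_cmp.n_noncore))
            except ValueError as exc:
                logger.warning("core comparison skipped: %s", exc)
            for prop in ("density", "thickness"):
                try:
                    mod_cmp = topo.module_architecture_comparison(inj, prop)
                    rows.append((f"modules_{prop}_omnibus", mod_cmp.omnibus, mod_cmp.omnibus.n))
                    rows += [(f"modules_{prop}_{a}_vs_{b}", res, res.n)
                             for a, b, res in mod_cmp.posthoc]
                except ValueError as exc:
                    logger.warning("module comparison (%s) skipped: %s", prop, exc)
            emit("topology_tests", _stat_frame(rows))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stat_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": name,
                "statistic_name": res.statistic_name,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "effect_size_r": res.effect_size_r,
                "alpha_corrected": res.alpha_corrected,
                "n": n,
            }
            for name, res, n in rows
        ],
        columns=["analysis", "statistic_name", "statistic", "df", "p_value",
                 "effect_size_r", "alpha_corrected", "n"],
    )
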