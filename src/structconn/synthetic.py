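"""Synthetic cortices and connectomes with the statistical structure the
analyses assume.

The generator emulates a tract-tracing study design: ``n_areas`` cortical
areas of which ``n_injected`` received retrograde tracer injections, so that
connection status is known for every ordered pair whose *target* was
injected, and the injected-by-injected block is an edge-complete subgraph.
Pairs whose target was never injected are untested ('unknown').

Generative structure
--------------------
* Neuron densities are log-normal; cortical thickness is affine in
  ln(density) plus Gaussian noise, with the noise weight solved so the
  population correlation between ln(density) and thickness equals
  ``thickness_coupling`` (negative: denser areas are thinner).
* Area positions are uniform in a 3D box — only pairwise Euclidean
  distances matter downstream.
* A directed projection from source to target exists with probability
  ``sigmoid(beta0 + beta_density * |Δ ln density| + beta_distance * d)``,
  so presence decays with architectonic dissimilarity and with distance.
  ``beta0`` is calibrated numerically to a target prevalence among the
  tested pairs.
* Present projections carry a log-normal labeled-neuron count (>= 1) whose
  supragranular share follows a clipped affine function of the directed
  density log-ratio: projections from denser (more strongly differentiated)
  areas originate predominantly in supragranular layers.
* Among the injected areas, the lowest-density ones are flagged as the
  network core, and spatially coherent module labels are assigned by
  k-means on positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.cluster import KMeans

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "default_config",
    "classifier_benchmark_config",
    "generate_areas",
    "generate_connectome",
    "generate_laminar_counts",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cortex/connectome generator.

    Defaults emulate the macaque study design: 91 areas, 29 injected,
    density-thickness coupling of -0.69, presence probability decaying in
    architectonic dissimilarity and distance, calibrated to a prevalence of
    0.66 among tested pairs.
    """

    n_areas: int = 91
    n_injected: int = 29
    #: mean and sd of ln(density); exp(11.0) ~ 6e4 neurons/mm^3
    density_log_mean: float = 11.0
    density_log_sd: float = 0.35
    #: target Pearson correlation of ln(density) with thickness (negative)
    thickness_coupling: float = -0.69
    thickness_mean_mm: float = 2.4
    thickness_sd_mm: float = 0.35
    #: side of the cubic volume areas are scattered in, mm
    spatial_extent: float = 40.0
    #: logistic presence model; beta0=None -> calibrated to target_prevalence
    beta0: float | None = None
    beta_density: float = -4.0
    beta_distance: float = -0.1
    target_prevalence: float = 0.66
    #: laminar-origin model: E[N_SG%] = 50 + nsg_slope * log_ratio_density
    nsg_slope: float = 30.0
    nsg_noise_sd: float = 20.0
    #: ln-scale labeled-neuron count distribution (counts rounded, >= 1)
    count_log_mean: float = 4.5
    count_log_sd: float = 2.0
    #: fraction of pairs with non-injected target recorded as 'unknown'
    unknown_fraction: float = 1.0
    n_core: int | None = None  # default: 17/29 of the injected areas
    n_modules: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError(f"need at least 2 areas, got {self.n_areas}")
        if not 1 <= self.n_injected <= self.n_areas:
            raise ValueError("n_injected must satisfy 1 <= n_injected <= n_areas")
        for name in ("density_log_sd", "thickness_sd_mm", "nsg_noise_sd", "count_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.unknown_fraction <= 1.0:
            raise ValueError("unknown_fraction must lie in [0, 1]")
        if not -1.0 < self.thickness_coupling < 1.0:
            raise ValueError("thickness_coupling must lie in (-1, 1)")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticDataset:
    """A generated cortex + connectome.

    ``areas`` and ``projections`` follow the standard table schemas;
    ``generative_probabilities`` records, per tested pair, the presence
    probability the generator actually used (ground truth for parameter-
    recovery checks).
    """

    areas: pd.DataFrame
    projections: pd.DataFrame
    generative_probabilities: pd.DataFrame
    config: SyntheticConfig


def default_config(seed: int = 0) -> SyntheticConfig:
    """The full study-design emulation: 91 areas, 29 injected."""
    return SyntheticConfig(seed=seed)


def classifier_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """Smaller cortex giving ~1500 tested pairs with complete features.

    29 injected targets x 51 possible sources = 1479 known pairs — the
    scale used for the classification and permutation benchmarks.
    """
    return SyntheticConfig(n_areas=52, n_injected=29, seed=seed)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_areas(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the area table: densities, thicknesses, positions, labels.

    Thickness is built as ``rho * z + sqrt(1 - rho^2) * eps`` on the
    standardized ln(density) ``z``, so its sample correlation with
    ln(density) converges to ``thickness_coupling``.
    """
    rng = rng if rng is not None else _rng(config, 0)
    n = config.n_areas
    ln_density = rng.normal(config.density_log_mean, config.density_log_sd, size=n)
    density = np.exp(ln_density)

    if config.density_log_sd > 0:
        z = (ln_density - ln_density.mean()) / ln_density.std()
    else:
        z = np.zeros(n)
    rho = config.thickness_coupling
    eps = rng.standard_normal(n)
    t_std = rho * z + np.sqrt(1.0 - rho**2) * eps
    thickness = config.thickness_mean_mm + config.thickness_sd_mm * t_std
    thickness = np.clip(thickness, 0.5, None)  # keep strictly positive

    pos = rng.uniform(0.0, config.spatial_extent, size=(n, 3))
    injected = np.zeros(n, dtype=bool)
    injected[: config.n_injected] = True

    areas = pd.DataFrame(
        {
            "area_id": [f"A{i:03d}" for i in range(n)],
            "density": density,
            "thickness": thickness,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "injected": injected,
        }
    )

    # network core: lowest-density injected areas (documented convention)
    n_core = config.n_core
    if n_core is None:
        n_core = int(round(17 / 29 * config.n_injected))
    n_core = min(n_core, config.n_injected)
    inj_idx = np.flatnonzero(injected)
    core_idx = inj_idx[np.argsort(density[inj_idx])[:n_core]]
    areas["core"] = False
    areas.loc[core_idx, "core"] = True

    # spatially coherent modules over the injected subgraph
    areas["module"] = ""
    k = min(config.n_modules, config.n_injected)
    if k >= 1:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(pos[inj_idx])
        areas.loc[inj_idx, "module"] = [f"M{l + 1}" for l in labels]
    return areas


def _pair_covariates(areas: pd.DataFrame) -> pd.DataFrame:
    """Ordered (source, target) pairs with target injected, plus covariates."""
    density = areas["density"].to_numpy(float)
    pos = areas[["x", "y", "z"]].to_numpy(float)
    injected = areas["injected"].to_numpy(bool)
    ids = areas["area_id"].to_numpy()

    tgt_idx = np.flatnonzero(injected)
    src_idx = np.arange(len(areas))
    s, t = np.meshgrid(src_idx, tgt_idx, indexing="ij")
    s, t = s.ravel(), t.ravel()
    keep = s != t
    s, t = s[keep], t[keep]

    lr = np.log(density[s] / density[t])
    d = np.linalg.norm(pos[s] - pos[t], axis=1)
    return pd.DataFrame(
        {
            "source": ids[s],
            "target": ids[t],
            "log_ratio_density": lr,
            "abs_log_ratio_density": np.abs(lr),
            "distance": d,
        }
    )


def calibrate_beta0(
    abs_log_ratio: np.ndarray,
    distance: np.ndarray,
    beta_density: float,
    beta_distance: float,
    prevalence: float,
) -> float:
    """Solve the intercept so mean presence probability equals ``prevalence``."""
    lin = beta_density * abs_log_ratio + beta_distance * distance

    def gap(b0: float) -> float:
        return float(expit(b0 + lin).mean() - prevalence)

    return brentq(gap, -50.0, 50.0, xtol=1e-10)


def generate_laminar_counts(
    log_ratio_density: np.ndarray,
    total_count: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    nsg_intercept: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split labeled-neuron counts into supra-/infragranular compartments.

    The expected supragranular percentage is
    ``clip(intercept + nsg_slope * log_ratio_density + noise, 0, 100)`` and
    counts are drawn binomially, so ``supra + infra == total``.
    """
    total = np.atleast_1d(np.asarray(total_count, dtype=int))
    lr = np.atleast_1d(np.asarray(log_ratio_density, dtype=float))
    if np.any(total < 1):
        raise ValueError("labeled-neuron counts must be >= 1")
    noise = rng.normal(0.0, config.nsg_noise_sd, size=total.shape)
    pct = np.clip(nsg_intercept + config.nsg_slope * lr + noise, 0.0, 100.0)
    supra = rng.binomial(total, pct / 100.0)
    return supra, total - supra


def generate_connectome(
    areas: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Draw the projection table over the injected-target pairs.

    Every ordered pair with an injected target gets a present/absent status
    (edge-complete over the injected block); pairs whose target was not
    injected are recorded as 'unknown' with probability
    ``unknown_fraction`` and omitted otherwise.
    """
    if areas.empty:
        raise ValueError("area table is empty")
    rng = rng if rng is not None else _rng(config, 1)

    pairs = _pair_covariates(areas)
    beta0 = config.beta0
    if beta0 is None:
        beta0 = calibrate_beta0(
            pairs["abs_log_ratio_density"].to_numpy(),
            pairs["distance"].to_numpy(),
            config.beta_density,
            config.beta_distance,
            config.target_prevalence,
        )
    p_present = expit(
        beta0
        + config.beta_density * pairs["abs_log_ratio_density"].to_numpy()
        + config.beta_distance * pairs["distance"].to_numpy()
    )
    present = rng.random(len(pairs)) < p_present

    n_total = np.zeros(len(pairs), dtype=int)
    n_supra = np.zeros(len(pairs), dtype=int)
    n_infra = np.zeros(len(pairs), dtype=int)
    if present.any():
        counts = rng.lognormal(config.count_log_mean, config.count_log_sd, size=int(present.sum()))
        counts = np.maximum(1, np.round(counts).astype(int))
        supra, infra = generate_laminar_counts(
            pairs.loc[present, "log_ratio_density"].to_numpy(), counts, config, rng
        )
        n_total[present] = counts
        n_supra[present] = supra
        n_infra[present] = infra

    known = pd.DataFrame(
        {
            "source": pairs["source"],
            "target": pairs["target"],
            "status": np.where(present, "present", "absent"),
            "n_total": n_total,
            "n_supra": n_supra,
            "n_infra": n_infra,
        }
    )
    # FLN over present sources of each injected target
    known["fln"] = np.nan
    pres = known["status"] == "present"
    totals = known.loc[pres, "n_total"].astype(float)
    known.loc[pres, "fln"] = totals / totals.groupby(known.loc[pres, "target"]).transform("sum")

    unknown = _unknown_pairs(areas, config, rng)
    if unknown.empty:
        projections = known.reset_index(drop=True)
    else:
        projections = pd.concat([known, unknown], ignore_index=True)

    probs = pairs[["source", "target"]].copy()
    probs["p_present"] = p_present
    return SyntheticDataset(areas=areas, projections=projections, generative_probabilities=probs, config=config)


def _unknown_pairs(
    areas: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    ids = areas["area_id"].to_numpy()
    injected = areas["injected"].to_numpy(bool)
    tgt_idx = np.flatnonzero(~injected)
    if tgt_idx.size == 0 or config.unknown_fraction == 0.0:
        return pd.DataFrame(
            columns=["source", "target", "status", "n_total", "n_supra", "n_infra", "fln"]
        )
    src_idx = np.arange(len(areas))
    s, t = np.meshgrid(src_idx, tgt_idx, indexing="ij")
    s, t = s.ravel(), t.ravel()
    keep = s != t
    s, t = s[keep], t[keep]
    sampled = rng.random(s.size) < config.unknown_fraction
    return pd.DataFrame(
        {
            "source": ids[s[sampled]],
            "target": ids[t[sampled]],
            "status": "unknown",
            "n_total": 0,
            "n_supra": 0,
            "n_infra": 0,
            "fln": np.nan,
        }
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Areas + connectome in one call; bit-reproducible from ``config.seed``."""
    areas = generate_areas(config)
    return generate_connectome(areas, config)
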