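"""Per-area and per-pair anatomical variables.

Every predictor used downstream is derived here from two tidy tables:

* an **area table** — one row per cortical area with neuron density
  (neurons/mm^3), cortical thickness (mm), a 3D mass-center position (mm)
  and optional ``injected`` / ``core`` / ``module`` annotations;
* a **projection table** — one row per directed source→target projection
  with a status in ``{present, absent, unknown}`` and labeled-neuron counts
  split into supragranular and infragranular compartments.

Similarity of two areas in density or thickness is expressed as the natural
log-ratio ``ln(source/target)`` — antisymmetric, so its absolute value is an
undirected (dis)similarity. Spatial proximity is the Euclidean distance
between mass centers.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "log_ratio",
    "euclidean_distance",
    "nsg_fraction",
    "nsg_inequality",
    "compute_fln",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

#: Canonical predictor columns of a feature table, in the order the
#: classifier expects them.
FEATURE_COLUMNS = ("abs_log_ratio_density", "distance", "abs_log_ratio_thickness")


def log_ratio(source_value: float, target_value: float) -> float:
    """Directed log-ratio ``ln(source / target)`` of two positive quantities.

    Antisymmetric: ``log_ratio(a, b) == -log_ratio(b, a)``.
    """
    if source_value <= 0 or target_value <= 0:
        raise ValueError(
            f"log_ratio requires strictly positive values, got "
            f"({source_value}, {target_value})"
        )
    return math.log(source_value / target_value)


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean (L2) distance between two 3D mass centers, in mm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def nsg_fraction(n_supra: int, n_infra: int) -> float:
    """Percentage of labeled neurons in supragranular layers, N_SG%.

    ``100 * n_supra / (n_supra + n_infra)``, in [0, 100].
    """
    if n_supra < 0 or n_infra < 0:
        raise ValueError("neuron counts must be non-negative")
    total = n_supra + n_infra
    if total == 0:
        raise ValueError("N_SG% undefined: no labeled neurons")
    return 100.0 * n_supra / total


def nsg_inequality(nsg_percent: float) -> float:
    """Undirected laminar-imbalance measure ``|N_SG%| = |N_SG% - 50| * 2``.

    0 means origins balanced across compartments, 100 fully unilaminar.
    """
    if not 0.0 <= nsg_percent <= 100.0:
        raise ValueError(f"N_SG% must lie in [0, 100], got {nsg_percent}")
    return abs(nsg_percent - 50.0) * 2.0


def compute_fln(projections: pd.DataFrame) -> pd.DataFrame:
    """Fraction of labeled neurons (FLN) per injected target.

    For each target, each present projection's ``n_total`` is normalized by
    the summed labeled neurons over all present sources of that target, so
    per-target FLNs sum to one. Absent/unknown rows get FLN = NaN.
    """
    proj = projections.copy()
    proj["fln"] = np.nan
    present = proj["status"] == "present"
    if not present.any():
        raise ValueError("no present projections: FLN undefined")
    totals = proj.loc[present, "n_total"].astype(float)
    denom = totals.groupby(proj.loc[present, "target"]).transform("sum")
    if (denom <= 0).any():
        bad = proj.loc[present, "target"][denom <= 0].unique()
        raise ValueError(f"all-zero labeled-neuron counts for targets {sorted(bad)}")
    proj.loc[present, "fln"] = totals / denom
    return proj


def build_feature_table(
    areas: pd.DataFrame,
    projections: pd.DataFrame,
    laminar_count_threshold: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-pair predictor table and the laminar (N_SG) subset.

    Parameters
    ----------
    areas : DataFrame
        Area table indexed or keyed by ``area_id`` with columns ``density``,
        ``thickness``, ``x``, ``y``, ``z``. Density and thickness may be NaN.
    projections : DataFrame
        Projection table with ``source``, ``target``, ``status`` and the
        laminar counts ``n_total``, ``n_supra``, ``n_infra``.
    laminar_count_threshold : int
        A projection enters the laminar subset only if its labeled-neuron
        count strictly exceeds this value (default 20; weaker projections
        give unreliable laminar fractions).

    Returns
    -------
    (features, laminar) : tuple of DataFrame
        ``features`` has one row per projection with known status: directed
        and absolute log-ratios of density and thickness, Euclidean
        distance, a boolean ``present`` label, and ``density_available``
        flagging rows where both areas have a density measure (rows without
        are retained for distance/thickness analyses). ``laminar`` is the
        subset of present rows with ``n_total > laminar_count_threshold``,
        augmented with ``nsg_percent`` and ``nsg_inequality``.
    """
    area_tab = areas.set_index("area_id") if "area_id" in areas.columns else areas
    missing = set(projections["source"]) | set(projections["target"])
    missing -= set(area_tab.index)
    if missing:
        raise KeyError(f"projection table references unknown areas: {sorted(missing)}")

    known = projections[projections["status"].isin(["present", "absent"])].copy()

    src = area_tab.loc[known["source"]]
    tgt = area_tab.loc[known["target"]]
    pos_s = src[["x", "y", "z"]].to_numpy(float)
    pos_t = tgt[["x", "y", "z"]].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        lr_density = np.log(src["density"].to_numpy(float) / tgt["density"].to_numpy(float))
        lr_thickness = np.log(
            src["thickness"].to_numpy(float) / tgt["thickness"].to_numpy(float)
        )

    features = pd.DataFrame(
        {
            "source": known["source"].to_numpy(),
            "target": known["target"].to_numpy(),
            "log_ratio_density": lr_density,
            "log_ratio_thickness": lr_thickness,
            "abs_log_ratio_density": np.abs(lr_density),
            "abs_log_ratio_thickness": np.abs(lr_thickness),
            "distance": np.linalg.norm(pos_s - pos_t, axis=1),
            "density_available": np.isfinite(lr_density),
            "present": (known["status"] == "present").to_numpy(),
            "n_total": known["n_total"].to_numpy(),
            "n_supra": known["n_supra"].to_numpy(),
            "n_infra": known["n_infra"].to_numpy(),
        }
    ).reset_index(drop=True)

    laminar = features[
        features["present"] & (features["n_total"] > laminar_count_threshold)
    ].copy()
    denom = laminar["n_supra"] + laminar["n_infra"]
    laminar["nsg_percent"] = 100.0 * laminar["n_supra"] / denom
    laminar["nsg_inequality"] = (laminar["nsg_percent"] - 50.0).abs() * 2.0
    return features, laminar.reset_index(drop=True)


def unknown_pair_features(areas: pd.DataFrame, projections: pd.DataFrame) -> pd.DataFrame:
    """Predictor rows for projections whose status is 'unknown'.

    Same columns as :func:`build_feature_table` minus the label; used to
    score untested pairs with a trained classifier.
    """
    unknown = projections[projections["status"] == "unknown"]
    if unknown.empty:
        return pd.DataFrame(
            columns=[
                "source", "target", "log_ratio_density", "log_ratio_thickness",
                "abs_log_ratio_density", "abs_log_ratio_thickness", "distance",
                "density_available",
            ]
        )
    fake = unknown.copy()
    fake["status"] = "absent"
    fake[["n_total", "n_supra", "n_infra"]] = 0
    feats, _ = build_feature_table(areas, fake, laminar_count_threshold=0)
    return feats.drop(columns=["present", "n_total", "n_supra", "n_infra"])
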