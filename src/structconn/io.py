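"""Reading and writing the standard area / projection / feature tables.

All interchange is plain CSV with documented column schemas:

* area table: ``area_id, density, thickness, x, y, z, injected, core, module``
* projection table: ``source, target, status, n_total, n_supra, n_infra[, fln]``
* feature table: output of :func:`structconn.features.build_feature_table`
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

AREA_COLUMNS = ["area_id", "density", "thickness", "x", "y", "z", "injected", "core", "module"]
PROJECTION_COLUMNS = ["source", "target", "status", "n_total", "n_supra", "n_infra"]
_STATUSES = {"present", "absent", "unknown"}


def read_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str, "module": str})
    missing = [c for c in AREA_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"area table {path} lacks columns {missing}")
    df["injected"] = df["injected"].astype(bool)
    if "core" in df.columns:
        df["core"] = df["core"].fillna(False).astype(bool)
    else:
        df["core"] = False
    if "module" not in df.columns:
        df["module"] = ""
    df["module"] = df["module"].fillna("")
    bad = df[(df["density"] <= 0) | (df["thickness"] <= 0)].dropna(subset=["density", "thickness"], how="all")
    if ((df["density"].dropna() <= 0).any()) or ((df["thickness"].dropna() <= 0).any()):
        raise ValueError("density and thickness must be strictly positive where present")
    return df


def read_projections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source": str, "target": str, "status": str})
    missing = [c for c in PROJECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"projection table {path} lacks columns {missing}")
    bad = set(df["status"]) - _STATUSES
    if bad:
        raise ValueError(f"unknown projection statuses: {sorted(bad)}")
    if (df["source"] == df["target"]).any():
        raise ValueError("self-projections are not allowed")
    absent = df["status"] == "absent"
    if (df.loc[absent, "n_total"] != 0).any():
        raise ValueError("absent projections must have n_total = 0")
    if (df["n_supra"] + df["n_infra"] != df["n_total"]).any():
        raise ValueError("n_supra + n_infra must equal n_total")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
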