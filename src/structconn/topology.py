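"""Degree, core/periphery and module analyses of the injected subgraph.

The degree of an area is the number of its afferent plus efferent present
projections restricted to pairs of injected areas (reciprocal connections
count twice). Core and module labels are inputs on the area table; the
analyses here relate them to architecture: do core areas have lower neuron
density, does density track degree, do modules differ in density or
thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import (
    StatResult,
    kruskal_wallis,
    pairwise_posthoc_ttests,
    pearson,
    spearman,
    t_test_independent,
)

__all__ = [
    "area_degree",
    "core_density_comparison",
    "degree_density_relation",
    "module_architecture_comparison",
]


def area_degree(projections: pd.DataFrame, injected_areas) -> pd.Series:
    """Afferent + efferent present projections per injected area.

    Restricted to the injected-by-injected subgraph, which must be
    edge-complete: an 'unknown' status inside it is an error.
    """
    injected = list(injected_areas)
    inside = projections["source"].isin(injected) & projections["target"].isin(injected)
    sub = projections[inside]
    if (sub["status"] == "unknown").any():
        bad = sub.loc[sub["status"] == "unknown", ["source", "target"]].head()
        raise ValueError(
            f"'unknown' status inside the injected subgraph violates edge-completeness: "
            f"{bad.to_records(index=False).tolist()}"
        )
    present = sub[sub["status"] == "present"]
    out_deg = present["source"].value_counts()
    in_deg = present["target"].value_counts()
    degree = pd.Series(0, index=pd.Index(injected, name="area_id"), dtype=int)
    degree = degree.add(out_deg.reindex(injected, fill_value=0), fill_value=0)
    degree = degree.add(in_deg.reindex(injected, fill_value=0), fill_value=0)
    return degree.astype(int)


@dataclass
class CoreComparison:
    """Non-core vs core density contrast, with an outlier-sensitivity rerun."""

    test: StatResult
    test_without_outlier: StatResult | None
    n_core: int
    n_noncore: int


def core_density_comparison(areas: pd.DataFrame, sensitivity: bool = True) -> CoreComparison:
    """Independent t-test of non-core vs core neuron densities.

    Positive ``t`` means non-core areas are denser than core areas. When
    ``sensitivity`` is on and the non-core group has >= 3 areas, the test
    is rerun with the most extreme non-core density (largest |z| within
    the group) removed; both results are reported, never silently swapped.
    """
    with_density = areas.dropna(subset=["density"])
    core = with_density.loc[with_density["core"] == True, "density"].to_numpy(float)  # noqa: E712
    noncore = with_density.loc[with_density["core"] == False, "density"].to_numpy(float)  # noqa: E712
    if core.size < 2 or noncore.size < 2:
        raise ValueError("need at least 2 core and 2 non-core areas with densities")
    test = t_test_independent(noncore, core)
    rerun = None
    if sensitivity and noncore.size >= 3:
        z = np.abs(noncore - noncore.mean()) / noncore.std()
        trimmed = np.delete(noncore, int(np.argmax(z)))
        rerun = t_test_independent(trimmed, core)
    return CoreComparison(test, rerun, n_core=core.size, n_noncore=noncore.size)


@dataclass
class DegreeDensityRelation:
    pearson: StatResult
    spearman: StatResult
    leave_one_out: pd.DataFrame | None  # per-area Pearson r with that area removed


def degree_density_relation(
    degrees: pd.Series, densities: pd.Series, leave_one_out: bool = True
) -> DegreeDensityRelation:
    """Correlation between neuron density and connection degree.

    Reports Pearson r alongside Spearman rho (robust to magnitude), plus an
    optional leave-one-out influence table giving the Pearson r after
    removing each single area.
    """
    joined = pd.concat({"degree": degrees, "density": densities}, axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 areas with both degree and density")
    x = joined["density"].to_numpy(float)
    y = joined["degree"].to_numpy(float)
    res_p = pearson(x, y)
    res_s = spearman(x, y)
    loo = None
    if leave_one_out and len(joined) > 3:
        rows = []
        for i, area in enumerate(joined.index):
            mask = np.arange(len(joined)) != i
            rows.append((area, pearson(x[mask], y[mask]).statistic))
        loo = pd.DataFrame(rows, columns=["removed_area", "pearson_r"])
    return DegreeDensityRelation(res_p, res_s, loo)


@dataclass
class ModuleComparison:
    property_name: str
    omnibus: StatResult
    posthoc: list[tuple[str, str, StatResult]]


def module_architecture_comparison(
    areas: pd.DataFrame, property_name: str = "density"
) -> ModuleComparison:
    """Do network modules differ in an architectonic property?

    Kruskal-Wallis omnibus across modules followed by Bonferroni-corrected
    pairwise t-tests (correction over the number of module pairs).
    """
    if property_name not in ("density", "thickness"):
        raise ValueError("property must be 'density' or 'thickness'")
    labelled = areas[(areas["module"] != "") & areas["module"].notna()]
    labelled = labelled.dropna(subset=[property_name])
    groups = {
        str(mod): grp[property_name].to_numpy(float)
        for mod, grp in labelled.groupby("module")
    }
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 modules with >= 2 measured areas each")
    omnibus = kruskal_wallis(list(groups.values()))
    posthoc = pairwise_posthoc_ttests(groups)
    return ModuleComparison(property_name, omnibus, posthoc)
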