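"""Relative frequency of present projections across an anatomical variable.

Each variable (|log-ratio| of density or thickness, Euclidean distance) is
partitioned into fixed-width bins; the number of present projections per bin
is normalized by the total number of tested projections falling in the bin.
This makes the frequency profile robust to uneven sampling across the
variable's range. A Spearman rank correlation of the per-bin frequencies
against bin order quantifies the monotone trend.

Bins are half-open ``[lo, hi)`` with the last bin closed (numpy histogram
convention), anchored at the data minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import StatResult, spearman

__all__ = ["BinnedFrequency", "bin_relative_frequency", "frequency_trend", "DEFAULT_BIN_WIDTHS"]

#: Default bin widths per variable, chosen to give roughly ten bins over the
#: typical range of each predictor.
DEFAULT_BIN_WIDTHS = {
    "abs_log_ratio_density": 0.1,
    "distance": 5.0,
    "abs_log_ratio_thickness": 0.05,
}


@dataclass
class BinnedFrequency:
    """Per-bin present/absent counts and relative frequency of presence."""

    variable: str
    bin_edges: np.ndarray  # length n_bins + 1, half-open [lo, hi), last closed
    n_present: np.ndarray
    n_absent: np.ndarray

    @property
    def n_total(self) -> np.ndarray:
        return self.n_present + self.n_absent

    @property
    def rel_freq(self) -> np.ndarray:
        """n_present / (n_present + n_absent); NaN for empty bins."""
        total = self.n_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.n_present / total, np.nan)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "n_present": self.n_present,
                "n_absent": self.n_absent,
                "rel_freq": self.rel_freq,
            }
        )


def bin_relative_frequency(
    values, statuses, bin_width: float, variable: str = ""
) -> BinnedFrequency:
    """Bin a variable and compute the per-bin relative frequency of presence.

    Parameters
    ----------
    values : array-like
        The anatomical variable, one value per tested projection.
    statuses : array-like
        'present'/'absent' strings or booleans aligned with ``values``.
    bin_width : float
        Width of the half-open bins covering the data range.
    """
    values = np.asarray(values, dtype=float)
    statuses = np.asarray(statuses)
    if statuses.dtype.kind == "b":
        present = statuses
    else:
        bad = ~np.isin(statuses, ["present", "absent"])
        if bad.any():
            raise ValueError("statuses must be 'present' or 'absent'")
        present = statuses == "present"
    if values.size == 0:
        raise ValueError("no tested projections to bin")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    lo = values.min()
    n_bins = max(1, int(np.ceil((values.max() - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < values.max():  # guard against fp shortfall
        edges[-1] = values.max()

    n_present, _ = np.histogram(values[present], bins=edges)
    n_all, _ = np.histogram(values, bins=edges)
    return BinnedFrequency(
        variable=variable,
        bin_edges=edges,
        n_present=n_present,
        n_absent=n_all - n_present,
    )


def frequency_trend(binned: BinnedFrequency) -> StatResult:
    """Spearman rank correlation of relative frequency against bin order.

    Empty bins are excluded. A constant frequency profile has no defined
    rank correlation; the returned statistic is NaN in that case (ties make
    the coefficient 0/0).
    """
    freq = binned.rel_freq
    centers = binned.bin_centers
    keep = np.isfinite(freq)
    if keep.sum() < 3:
        raise ValueError("need at least 3 nonempty bins for a trend")
    freq, centers = freq[keep], centers[keep]
    if np.all(freq == freq[0]):
        return StatResult("rho", float("nan"), float(freq.size - 2), float("nan"), n=freq.size)
    order = np.argsort(centers)
    return spearman(np.arange(freq.size), freq[order])
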