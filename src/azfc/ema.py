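"""Exponential-moving-average depth profiling against control samples.

A confirmatory view of the copy-number landscape: per-base depth over the
AZFc region is smoothed with an exponential moving average (window n,
stepped 1 bp), then divided position-wise by the mean smoothed depth of
control samples.  A normalised value of ~1 inside an amplicon indicates the
reference copy number; ~2 marks a doubled family, ~0 a deleted one.

The smoothing follows the usual financial-time-series convention: ratio
alpha = 2/(n+1), seeded with the simple mean of the first n values, output
defined from position n-1 onward (burn-in excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .depth import DepthProfile
from .model import Interval

__all__ = ["SmoothedProfile", "ema", "normalize_by_controls", "export_profile"]


@dataclass
class SmoothedProfile:
    """EMA-smoothed (or control-normalised) depth at ordered positions."""

    sample_id: str
    chrom: str
    positions: np.ndarray  # 0-based, strictly increasing
    values: np.ndarray
    window_bp: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values differ in length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def segment_mean(self, interval: Interval) -> float:
        """Mean profile value over the positions falling inside ``interval``."""
        mask = (self.positions >= interval.start) & (self.positions < interval.end)
        if not mask.any():
            raise ValueError(
                f"no profile positions inside {interval.chrom}:{interval.start}-{interval.end}"
            )
        return float(np.nanmean(self.values[mask]))


def ema(
    profile: DepthProfile, region: Interval, window_bp: int = 50_000
) -> SmoothedProfile:
    """Exponential moving average of per-base depth over ``region``.

    Recursive smoothing y[i] = alpha*x[i] + (1-alpha)*y[i-1] with
    alpha = 2/(window_bp+1), seeded by the simple mean of the first
    ``window_bp`` values; the first window_bp-1 positions (burn-in) are
    excluded from the output.
    """
    if len(region) < window_bp:
        raise ValueError(
            f"region length {len(region)} is shorter than the window ({window_bp})"
        )
    x = np.asarray(profile.values(region), dtype=float)
    alpha = 2.0 / (window_bp + 1)
    seed = float(np.mean(x[:window_bp]))
    # IIR filter continues the recursion from the seed
    rest, _ = lfilter(
        [alpha], [1.0, alpha - 1.0], x[window_bp:], zi=[(1.0 - alpha) * seed]
    )
    values = np.concatenate(([seed], rest))
    positions = np.arange(region.start + window_bp - 1, region.end)
    return SmoothedProfile(profile.sample_id, region.chrom, positions, values, window_bp)


def normalize_by_controls(
    sample: SmoothedProfile, controls: Sequence[SmoothedProfile]
) -> SmoothedProfile:
    """Divide a sample's smoothed depth position-wise by the mean of controls.

    All profiles must share positions.  Positions where the control mean is
    zero are flagged NaN with a warning rather than failing.
    """
    if not controls:
        raise ValueError("at least one control profile is required")
    for control in controls:
        if control.chrom != sample.chrom or not np.array_equal(
            control.positions, sample.positions
        ):
            raise ValueError(
                f"control {control.sample_id} positions do not match sample positions"
            )
    control_mean = np.mean([c.values for c in controls], axis=0)
    zero = control_mean <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} positions have zero control depth; set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, np.nan, sample.values / control_mean)
    return SmoothedProfile(
        sample.sample_id, sample.chrom, sample.positions.copy(), ratio, sample.window_bp
    )


def export_profile(
    profile: SmoothedProfile,
    path: str | Path,
    stride: int = 1,
    plot_path: str | Path | None = None,
) -> None:
    """Write the profile as bedGraph; optionally save a simple line plot.

    With ``stride`` > 1 only every stride-th position is exported (profiles
    stepped 1 bp are large).  Runs of consecutive positions with equal value
    are merged into single bedGraph rows.
    """
    pos = profile.positions[::stride]
    val = profile.values[::stride]
    with open(path, "w") as handle:
        i = 0
        while i < len(pos):
            j = i
            # merge a run of equal values at consecutive exported positions
            while (
                j + 1 < len(pos)
                and val[j + 1] == val[i]
                and pos[j + 1] == pos[j] + stride
            ):
                j += 1
            handle.write(
                f"{profile.chrom}\t{pos[i]}\t{pos[j] + 1}\t{val[i]:g}\n"
            )
            i = j + 1
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(pos, val, lw=0.8)
        ax.set_xlabel(f"{profile.chrom} position (bp)")
        ax.set_ylabel("normalized EMA depth")
        ax.set_title(profile.sample_id)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
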