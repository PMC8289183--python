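"""Colorimetric reaction monitoring from RGB frames.

The developing plasmon resonance turns the colloid red, so the red channel's
share of the total RGB signal tracks the reaction.  The red fraction — the
per-pixel mean of R/(R+G+B) over a frame — is normalised between its start
value and its plateau and used as the reaction progression.  The initial
reduction rate is the initial slope of that progression scaled by the
starting precursor concentration (progress 1 corresponds to full
conversion), and the TA reaction order comes from ordinary least squares on
log initial rate vs log TA concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ZeroDynamicRangeError(ValueError):
    """The red fraction never moves: plateau equals the starting value."""


@dataclass
class FrameSeries:
    """Time-stamped RGB frames (n, H, W, 3), channel range 0-255."""

    timestamps: np.ndarray
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (n, H, W, 3), got {self.frames.shape}")
        if self.frames.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.size

    def crop(self, top: int, bottom: int, left: int, right: int) -> "FrameSeries":
        """Rectangular region-of-interest crop (e.g. to mask flask/background)."""
        return FrameSeries(self.timestamps, self.frames[:, top:bottom, left:right, :])


@dataclass
class ProgressCurve:
    """Red-fraction trace and its normalised reaction progression."""

    t: np.ndarray
    red_fraction: np.ndarray
    normalized_progress: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.red_fraction = np.asarray(self.red_fraction, dtype=float)
        self.normalized_progress = np.asarray(self.normalized_progress, dtype=float)


def red_fraction(frame: np.ndarray, method: str = "pixel_mean") -> float:
    """Red share of the RGB signal of one frame.

    ``pixel_mean`` (default) averages R/(R+G+B) over pixels; ``channel_mean``
    takes mean(R)/(mean(R)+mean(G)+mean(B)).  Pixels with R+G+B == 0 carry
    no colour information and are excluded.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"frame must be (H, W, 3), got {frame.shape}")
    totals = frame.sum(axis=-1)
    mask = totals > 0
    if not mask.any():
        raise ValueError("all pixels are black: no colour signal in frame")
    if method == "pixel_mean":
        return float(np.mean(frame[..., 0][mask] / totals[mask]))
    if method == "channel_mean":
        means = frame[mask].mean(axis=0)
        return float(means[0] / means.sum())
    raise ValueError(f"unknown method {method!r}")


def progress_curve(
    series: FrameSeries,
    plateau_frames: int = 5,
    method: str = "pixel_mean",
) -> ProgressCurve:
    """Per-frame red fraction, normalised between start and plateau.

    normalized_progress(t) = (f(t) - f(t0)) / (f_plateau - f(t0)), with the
    plateau estimated as the mean red fraction of the final
    ``plateau_frames`` frames.

    Raises
    ------
    ZeroDynamicRangeError
        If the plateau equals the starting red fraction (nothing happened).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 frames")
    fractions = np.array([red_fraction(f, method=method) for f in series.frames])
    f0 = fractions[0]
    plateau = fractions[-min(plateau_frames, len(series)):].mean()
    span = plateau - f0
    if span == 0.0:
        raise ZeroDynamicRangeError("red fraction plateau equals its start value")
    return ProgressCurve(
        t=series.timestamps,
        red_fraction=fractions,
        normalized_progress=(fractions - f0) / span,
    )


def estimate_initial_rate(
    curve: ProgressCurve,
    c_au_0: float,
    window_fraction: float = 0.1,
) -> float:
    """Initial reduction rate (mol/L/s) from the normalised progression.

    Fits a straight line to normalized progress over the initial window —
    the points where progress has covered at most ``window_fraction`` of the
    dynamic range (default first 10%) — and scales the slope by the starting
    precursor concentration, progress 1 being full conversion.

    Raises
    ------
    ValueError
        If fewer than 3 points fall inside the initial window.
    """
    if c_au_0 <= 0:
        raise ValueError(f"initial precursor concentration must be > 0, got {c_au_0}")
    mask = curve.normalized_progress <= window_fraction
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} points inside the initial window "
            f"(progress <= {window_fraction}); need >= 3"
        )
    t = curve.t[mask]
    p = curve.normalized_progress[mask]
    slope = stats.linregress(t, p).slope
    return slope * c_au_0


def fit_reaction_order(
    rates: np.ndarray, concentrations: np.ndarray
) -> tuple[float, float]:
    """Reaction order from OLS of log10(rate) against log10(concentration).

    Returns ``(order, log10_intercept)``; the intercept is the log10 of the
    effective rate coefficient at unit concentration.
    """
    rates = np.asarray(rates, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if rates.shape != concentrations.shape:
        raise ValueError("rates and concentrations must have the same length")
    if rates.size < 2:
        raise ValueError(f"need at least 2 points, got {rates.size}")
    if np.any(rates <= 0) or np.any(concentrations <= 0):
        raise ValueError("rates and concentrations must be strictly positive")
    fit = stats.linregress(np.log10(concentrations), np.log10(rates))
    return float(fit.slope), float(fit.intercept)
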