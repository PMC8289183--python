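"""Synthetic raw-data generators: kinetic traces, reaction videos, sizes.

Every analysis stage in the package can be exercised without laboratory
data: :func:`generate_trace` produces (optionally noisy) solutions of the
reduction mechanism, :func:`generate_frames` renders an RGB frame series
whose red fraction follows a prescribed progress curve, and
:func:`generate_size_distribution` draws TEM-style unimodal size samples.
All generators are bit-reproducible under a fixed seed.

These emulate the *structure* of the real observations (noise shape,
colour-progress coupling, unimodal sizes), not their physics: frame colour
is a palette interpolation, not a plasmon model, and size samples carry no
shape anisotropy or aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ugnp.colorimetry import FrameSeries
from ugnp.kinetics import KineticTrace, RateParameters, ReactionState, simulate_reduction

_NOISE_KINDS = ("none", "multiplicative-gaussian", "additive-gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: kind, relative/absolute level, RNG seed."""

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.level < 0:
            raise ValueError(f"noise level must be >= 0, got {self.level}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.level == 0.0:
            return values
        if self.kind == "multiplicative-gaussian":
            return values * (1.0 + self.level * rng.standard_normal(values.shape))
        return values + self.level * rng.standard_normal(values.shape)


@dataclass(frozen=True)
class SizeDistributionSpec:
    """A TEM-style unimodal size distribution: mean/sd in nm, count, family."""

    mean: float
    sd: float
    n: int
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"mean diameter must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValueError(f"sample count must be >= 1, got {self.n}")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"family must be normal|lognormal, got {self.family!r}")


def generate_trace(
    params: RateParameters,
    initial: ReactionState,
    t_grid: np.ndarray,
    noise: NoiseSpec = NoiseSpec(),
) -> KineticTrace:
    """Simulate the mechanism and overlay observation noise on concentrations.

    With ``noise.kind == "none"`` the output is exactly the simulator's; the
    noisy path perturbs every concentration column independently (clipped at
    zero) and is reproducible from ``noise.seed``.
    """
    trace = simulate_reduction(initial, params, t_grid)
    if noise.kind == "none" or noise.level == 0.0:
        return trace
    rng = np.random.default_rng(noise.seed)
    noisy = {}
    for col in ("c_precursor", "c_passivated", "c_reduced", "c_ta", "c_cit_reactive"):
        noisy[col] = np.clip(noise.apply(getattr(trace, col), rng), 0.0, None)
    return KineticTrace(
        t=trace.t,
        c_oh=trace.c_oh,
        provenance="synthetic-noisy",
        c_reduced_ta=trace.c_reduced_ta,
        **noisy,
    )


def generate_frames(
    curve: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    t_grid: np.ndarray,
    size: tuple[int, int] = (32, 32),
    palette: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (150.0, 150.0, 150.0),
        (230.0, 110.0, 110.0),
    ),
    noise: NoiseSpec = NoiseSpec(),
) -> FrameSeries:
    """Render an RGB frame series whose colour follows a progress curve.

    ``curve`` maps times to progress values in [0, 1] (or is an array of
    such values, one per time point); each frame is uniformly coloured by
    linear interpolation between the palette endpoints.  The default palette
    endpoints share the same channel sum, which makes the red fraction an
    affine function of progress (exact round trip through the colorimetry
    stage); endpoints with different sums give a monotone but curved
    response, closer to a real colloid.  Channel noise is applied before
    integer quantisation and then clipped to 0-255, so heavy noise near the
    palette extremes is biased inward by the clip.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    progress = np.asarray(curve(t_grid) if callable(curve) else curve, dtype=float)
    if progress.shape != t_grid.shape:
        raise ValueError("progress values must match the time grid")
    if np.any(progress < 0) or np.any(progress > 1):
        raise ValueError("progress values must lie in [0, 1]")
    start, end = (np.asarray(p, dtype=float) for p in palette)
    if start.shape != (3,) or end.shape != (3,):
        raise ValueError("palette endpoints must be RGB triples")
    if np.any(start < 0) or np.any(start > 255) or np.any(end < 0) or np.any(end > 255):
        raise ValueError("palette channels must lie in 0-255")

    h, w = size
    rng = np.random.default_rng(noise.seed)
    colors = start[None, :] + progress[:, None] * (end - start)[None, :]
    frames = np.broadcast_to(colors[:, None, None, :], (len(t_grid), h, w, 3)).copy()
    frames = noise.apply(frames, rng)
    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return FrameSeries(timestamps=t_grid, frames=frames)


def generate_size_distribution(spec: SizeDistributionSpec, seed: int = 0) -> np.ndarray:
    """Draw ``spec.n`` particle diameters (nm) from the stated family.

    The lognormal family is parameterised by the *distribution's* mean and
    sd (moment-matched to the underlying normal), so the two families are
    directly comparable at the same spec.
    """
    rng = np.random.default_rng(seed)
    if spec.sd == 0.0:
        return np.full(spec.n, spec.mean)
    if spec.family == "normal":
        return rng.normal(spec.mean, spec.sd, spec.n)
    sigma2 = np.log(1.0 + (spec.sd / spec.mean) ** 2)
    mu = np.log(spec.mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), spec.n)
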