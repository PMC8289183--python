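"""Selectivity and final-diameter prediction for seeded growth.

The fate of the Au(III) precursor is decided by the competition between
reduction (TA route + citrate route) and passivation to AuCl3(OH)^-.  The
selectivity is the ratio of the total reduction rate to the passivation
rate.  With first-order precursor dependence in every route the precursor
concentration cancels, and evaluating the remaining factors at their
quasi-equilibrium values (which change little over the run) gives

    sigma = (k_ta * c_TA,0^l + k_cit * c_CtH2-,0) / (k_pass * c_OH-,0)

Only the fraction sigma/(1 + sigma) of dosed precursor is reduced onto the
seeds; the rest is passivated.  Mass conservation with spherical particles
then sets the final core diameter by a cube-root law:

    d_final = d_seed * (1 + g * sigma/(1 + sigma))^(1/3)

where g is the mol Au dosed per mol Au already in the seeds (per particle,
no secondary nucleation).
"""

from __future__ import annotations

from dataclasses import dataclass

from ugnp.kinetics import RateParameters

#: Denominators below this raise instead of returning a silent infinity.
_DENOM_FLOOR = 1e-300


class InfiniteSelectivityError(ZeroDivisionError):
    """Passivation rate is (numerically) zero: selectivity is unbounded."""


@dataclass(frozen=True)
class SelectivityInputs:
    """Quasi-equilibrium concentrations (mol/L) entering the selectivity.

    Defaults to the initial recipe concentrations; optionally sampled from a
    simulated trace at a chosen time via :func:`from_trace`.
    """

    c_ta_0: float
    c_cit_reactive_0: float
    c_oh_0: float

    def __post_init__(self) -> None:
        for name in ("c_ta_0", "c_cit_reactive_0", "c_oh_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def from_trace(cls, trace, t: float) -> "SelectivityInputs":
        """Sample quasi-equilibrium concentrations from a kinetic trace at time t."""
        import numpy as np

        i = int(np.argmin(np.abs(trace.t - t)))
        return cls(
            c_ta_0=max(float(trace.c_ta[i]), 0.0),
            c_cit_reactive_0=max(float(trace.c_cit_reactive[i]), 0.0),
            c_oh_0=trace.c_oh,
        )


@dataclass(frozen=True)
class SizePrediction:
    """Predicted final core diameter (nm) for a seed under selectivity sigma."""

    d_seed: float
    sigma: float
    d_final: float


def selectivity(inputs: SelectivityInputs, params: RateParameters) -> float:
    """Ratio of total reduction rate to passivation rate (dimensionless).

    Assumes first-order precursor dependence in all routes so the precursor
    concentration cancels between numerator and denominator.

    Raises
    ------
    InfiniteSelectivityError
        If the passivation rate is numerically zero (k_pass*c_OH- below
        1e-300) — an unbounded selectivity, never a silent ``inf``.
    """
    denominator = params.k_pass * inputs.c_oh_0
    r_ta = params.k_ta * inputs.c_ta_0**params.l if inputs.c_ta_0 > 0 else 0.0
    r_cit = params.k_cit * inputs.c_cit_reactive_0
    if r_ta == 0.0 and r_cit == 0.0:
        return 0.0
    if denominator < _DENOM_FLOOR:
        raise InfiniteSelectivityError(
            f"passivation rate {denominator:.3e} is numerically zero; "
            "selectivity is unbounded"
        )
    return (r_ta + r_cit) / denominator


def predict_final_diameter(
    d_seed: float, sigma: float, gold_ratio: float
) -> SizePrediction:
    """Final core diameter after dosing ``gold_ratio`` mol Au per mol seed Au.

    The reduced fraction sigma/(1 + sigma) of the dose deposits uniformly on
    the existing particles; the diameter follows the cube root of the gold
    mass per particle.  ``gold_ratio = 0`` or ``sigma = 0`` returns the seed
    diameter unchanged.
    """
    if d_seed <= 0:
        raise ValueError(f"seed diameter must be > 0, got {d_seed}")
    if sigma < 0:
        raise ValueError(f"selectivity must be >= 0, got {sigma}")
    if gold_ratio < 0:
        raise ValueError(f"gold_ratio must be >= 0, got {gold_ratio}")
    incorporated = gold_ratio * sigma / (1.0 + sigma)
    d_final = d_seed * (1.0 + incorporated) ** (1.0 / 3.0)
    return SizePrediction(d_seed=d_seed, sigma=sigma, d_final=d_final)
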