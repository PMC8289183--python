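"""Seeded-growth process bookkeeping: particle numbers, areas, dosing.

The synthesis runs in rounds: part of the colloid is extracted and replaced
with fresh citrate solution, then Au(III) stock is dosed to a target total
gold concentration.  With secondary nucleation suppressed, every dosed gold
atom deposits on an existing particle, so the particle count only changes
through extraction and the core diameter follows the cube root of the gold
mass per particle.

Unit conventions: volumes in mL, concentrations in mol/L, diameters in nm
(TEM-equivalent core diameters; hydrodynamic diameters run ~1 nm larger,
see :func:`hydrodynamic_diameter`), particle numbers per mL, surface areas
in nm^2 per mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: Atomic mass of gold, g/mol.
M_AU = 196.97
#: Density of bulk gold, g/cm^3.
RHO_AU = 19.3
#: DLS hydrodynamic diameters exceed TEM core diameters by about 1 nm.
DLS_OFFSET_NM = 1.0

#: Cumulative Au(III) concentration (mol/L) after each synthesis round,
#: keyed by sample label, together with the nominal core diameters (nm).
#: The first entry is the seed batch.
TABLE1_LABELS = ("uGNP_3", "uGNP_5", "uGNP_6", "uGNP_7", "uGNP_8", "uGNP_10", "uGNP_12", "uGNP_15")
TABLE1_C_AU_M = (1.25e-4, 1.5e-4, 1.75e-4, 2.0e-4, 2.25e-4, 2.5e-4, 2.75e-4, 3.0e-4)
NOMINAL_DIAMETERS_NM = (3.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0, 15.0)

_BALANCE_RTOL = 1e-9


class PlanningError(ValueError):
    """A synthesis round is infeasible (e.g. target below residual gold)."""


def gold_per_particle_mol(d_core: float) -> float:
    """Moles of gold in one spherical particle of core diameter ``d_core`` nm."""
    if d_core <= 0:
        raise ValueError(f"core diameter must be > 0, got {d_core}")
    volume_cm3 = (math.pi / 6.0) * (d_core * 1e-7) ** 3
    return RHO_AU * volume_cm3 / M_AU


def particle_number_concentration(c_au: float, d_core: float) -> float:
    """Particles per mL given total gold ``c_au`` (mol/L) and core diameter (nm).

    N = c_au * M_Au / (rho_Au * (pi/6) d^3), with unit bookkeeping to
    particles per millilitre.
    """
    if c_au < 0:
        raise ValueError(f"gold concentration must be >= 0, got {c_au}")
    return (c_au / 1000.0) / gold_per_particle_mol(d_core)


def total_surface_area(n_conc: float, d_core: float) -> float:
    """Total particle surface area per mL of colloid: S = N * pi * d^2 (nm^2/mL)."""
    if n_conc < 0 or d_core < 0:
        raise ValueError("inputs must be >= 0")
    return n_conc * math.pi * d_core**2


def hydrodynamic_diameter(d_core: float) -> float:
    """Estimated DLS (hydrodynamic) diameter: core diameter + ~1 nm."""
    return d_core + DLS_OFFSET_NM


@dataclass(frozen=True)
class ColloidState:
    """A colloid batch: volume, particle number, core size, gold content.

    The gold per particle implied by ``c_au_total`` and ``n_conc`` must be
    consistent with ``d_core`` through the bulk-gold density relation;
    construct via :meth:`from_concentration` to guarantee it.
    """

    volume: float
    n_conc: float
    d_core: float
    c_au_total: float

    def __post_init__(self) -> None:
        if self.volume < 0 or self.n_conc < 0 or self.c_au_total < 0:
            raise ValueError("colloid fields must be >= 0")
        if self.d_core <= 0:
            raise ValueError(f"core diameter must be > 0, got {self.d_core}")
        expected = particle_number_concentration(self.c_au_total, self.d_core)
        if expected > 0 and abs(self.n_conc - expected) / expected > 1e-9:
            raise ValueError(
                "gold per particle inconsistent with d_core: "
                f"n_conc={self.n_conc:.6e}, expected {expected:.6e} /mL"
            )

    @classmethod
    def from_concentration(
        cls, c_au: float, d_core: float, volume: float
    ) -> "ColloidState":
        """Build a consistent state from gold concentration and core diameter."""
        return cls(
            volume=volume,
            n_conc=particle_number_concentration(c_au, d_core),
            d_core=d_core,
            c_au_total=c_au,
        )

    @property
    def s_total(self) -> float:
        """Total surface area per mL, nm^2/mL."""
        return total_surface_area(self.n_conc, self.d_core)


@dataclass(frozen=True)
class SynthesisRound:
    """One seeded-growth round: extract, replace with citrate, dose gold."""

    index: int
    v_extract: float = 10.0
    v_replace: float = 10.0
    c_cit_replace: float = 2.2e-3
    c_au_final_target: float = 0.0

    def __post_init__(self) -> None:
        if self.v_extract < 0 or self.v_replace < 0:
            raise ValueError("volumes must be >= 0")
        if self.c_au_final_target < 0:
            raise ValueError("target concentration must be >= 0")


@dataclass(frozen=True)
class Recipe:
    """Seed conditions plus an ordered list of growth rounds.

    Defaults reproduce the reference protocol: a 25 mL seed batch at
    0.125 mM Au3+ (2.2 mM NaCit, 0.1 mM TA, 6 mM K2CO3), grown with 10 mL
    extraction/replacement rounds dosed from 20 mM stock to cumulative
    targets 0.15 ... 0.30 mM.
    """

    seed_volume: float = 25.0
    seed_c_au: float = 1.25e-4
    seed_c_nacit: float = 2.2e-3
    seed_c_ta: float = 1.0e-4
    seed_c_k2co3: float = 6.0e-3
    c_au_stock: float = 0.02
    rounds: tuple[SynthesisRound, ...] = ()


def default_recipe() -> Recipe:
    """The reference growth series (cumulative targets 0.15-0.30 mM)."""
    rounds = tuple(
        SynthesisRound(index=i + 1, c_au_final_target=c)
        for i, c in enumerate(TABLE1_C_AU_M[1:])
    )
    return Recipe(rounds=rounds)


def simulate_recipe(
    recipe: Recipe,
    seed: ColloidState,
    reduction_yield: float = 1.0,
) -> list[ColloidState]:
    """Forward-simulate the growth rounds; one ColloidState per round.

    Each round retains the fraction (V - v_extract)/V of particles and gold,
    restores the volume with citrate solution, then doses gold stock to the
    round's cumulative target.  Dosed gold times ``reduction_yield``
    partitions equally over the particles (no secondary nucleation) and the
    core diameter grows by the cube root of the gold-per-particle ratio.
    The small stock-addition volume is tracked exactly.

    Raises
    ------
    PlanningError
        Naming the round, if its target is below the residual concentration
        or at/above the stock concentration, or extraction exceeds volume.
    """
    if not 0 < reduction_yield <= 1:
        raise ValueError(f"reduction yield must be in (0, 1], got {reduction_yield}")
    volume = seed.volume
    n_total = seed.n_conc * volume
    au_total = seed.c_au_total * volume / 1000.0  # mol
    d_core = seed.d_core
    states: list[ColloidState] = []
    for rnd in recipe.rounds:
        if rnd.v_extract > volume:
            raise PlanningError(
                f"round {rnd.index}: extraction {rnd.v_extract} mL exceeds volume {volume} mL"
            )
        retain = (volume - rnd.v_extract) / volume
        n_total *= retain
        au_total *= retain
        volume = volume - rnd.v_extract + rnd.v_replace
        c_res = au_total / (volume / 1000.0)
        target = rnd.c_au_final_target
        if target < c_res * (1 - 1e-12):
            raise PlanningError(
                f"round {rnd.index}: target {target:.4e} M below residual {c_res:.4e} M"
            )
        if target >= recipe.c_au_stock:
            raise PlanningError(
                f"round {rnd.index}: target {target:.4e} M not below stock "
                f"{recipe.c_au_stock:.4e} M"
            )
        v_add = volume * (target - c_res) / (recipe.c_au_stock - target)
        dosed = recipe.c_au_stock * v_add / 1000.0
        gpp_old = au_total / n_total
        au_total += reduction_yield * dosed
        volume += v_add
        d_core *= (au_total / n_total / gpp_old) ** (1.0 / 3.0)
        states.append(
            ColloidState(
                volume=volume,
                n_conc=n_total / volume,
                d_core=d_core,
                c_au_total=au_total / (volume / 1000.0),
            )
        )
    return states


def plan_dosing(
    d_targets: list[float],
    seed: ColloidState,
    round_template: SynthesisRound = SynthesisRound(index=0),
    c_au_stock: float = 0.02,
) -> Recipe:
    """Inverse of :func:`simulate_recipe`: dosing targets for a diameter series.

    Returns a recipe whose per-round cumulative Au targets make the forward
    simulation reproduce ``d_targets`` (round-trip accurate to solver
    precision).  Targets must be non-decreasing and start at or above the
    seed diameter; a shrinking target would require removing gold from the
    particles and raises :class:`PlanningError`.
    """
    if not d_targets:
        raise ValueError("need at least one target diameter")
    if d_targets[0] < seed.d_core * (1 - 1e-12):
        raise PlanningError(
            f"first target {d_targets[0]} nm below seed diameter {seed.d_core} nm"
        )
    for a, b in zip(d_targets, d_targets[1:]):
        if b < a:
            raise PlanningError(f"targets must be non-decreasing, got {a} then {b}")

    volume = seed.volume
    n_total = seed.n_conc * volume
    au_total = seed.c_au_total * volume / 1000.0
    rounds: list[SynthesisRound] = []
    for i, d_t in enumerate(d_targets, start=1):
        if round_template.v_extract > volume:
            raise PlanningError(f"round {i}: extraction exceeds volume {volume} mL")
        retain = (volume - round_template.v_extract) / volume
        n_total *= retain
        au_total *= retain
        volume = volume - round_template.v_extract + round_template.v_replace
        au_needed = gold_per_particle_mol(d_t) * n_total
        if au_needed < au_total * (1 - 1e-12):
            raise PlanningError(
                f"round {i}: target {d_t} nm would require removing gold"
            )
        v_add = max(au_needed - au_total, 0.0) / (c_au_stock / 1000.0)
        au_total = au_total + c_au_stock * v_add / 1000.0
        volume += v_add
        c_target = au_total / (volume / 1000.0)
        rounds.append(replace(round_template, index=i, c_au_final_target=c_target))
    return Recipe(
        seed_volume=seed.volume,
        seed_c_au=seed.c_au_total,
        c_au_stock=c_au_stock,
        rounds=tuple(rounds),
    )


@dataclass
class SampleSummary:
    """Per-sample bookkeeping row used for surface-area equalisation."""

    label: str
    c_au: float
    d_core: float
    n_conc: float
    s_total: float
    df: float | None = None


def summaries_from_concentrations(
    labels: list[str], c_au: list[float], d_core: list[float]
) -> list[SampleSummary]:
    """Build sample summaries from gold concentrations and core diameters."""
    out = []
    for label, c, d in zip(labels, c_au, d_core, strict=True):
        n = particle_number_concentration(c, d)
        out.append(
            SampleSummary(
                label=label, c_au=c, d_core=d, n_conc=n,
                s_total=total_surface_area(n, d),
            )
        )
    return out


def dilution_factors(samples: list[SampleSummary]) -> list[SampleSummary]:
    """Dilution factor per sample so all reach the smallest total surface area.

    DF_i = S_i / min_j S_j; the sample with the least surface area is the
    reference with DF = 1.  Dividing each sample's surface-area concentration
    by its DF equalises them exactly.
    """
    if not samples:
        raise ValueError("need at least one sample")
    if any(s.s_total <= 0 for s in samples):
        raise ValueError("all samples need a positive total surface area")
    s_min = min(s.s_total for s in samples)
    return [replace(s, df=s.s_total / s_min) for s in samples]


def ligand_surface_density(n_ligands: float, s_total: float) -> float:
    """Ligands per nm^2 of particle surface (e.g. ~3.3 for full PEG coverage)."""
    if s_total <= 0:
        raise ValueError(f"total surface area must be > 0, got {s_total}")
    if n_ligands < 0:
        raise ValueError(f"ligand count must be >= 0, got {n_ligands}")
    return n_ligands / s_total
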