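"""Citrate acid-base speciation and the electron stoichiometry of TA reduction.

Sodium citrate in the reaction medium distributes over four protonation
states — CtH3, CtH2^-, CtH^2- and Ct^3- — according to the standard
triprotic equilibrium.  The CtH2^- anion is treated elsewhere in the
package as the citrate species active in Au(III) reduction.

Tannic acid (TA) reduces Au(III) through its phenolic groups: each phenol
donates two electrons on oxidation to the quinone, so a TA molecule with
ten phenolic groups supplies twenty electrons, and with three electrons
needed per Au(III) -> Au(0) the stoichiometric requirement is 3/20 mol TA
per mol Au.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Literature acid dissociation constants of citric acid (25 degC, pKa1-3).
DEFAULT_PKA = (3.13, 4.76, 6.40)


@dataclass(frozen=True)
class CitrateSpeciationState:
    """Equilibrium concentrations of the four citrate protonation states.

    All concentrations in mol/L.  ``c_CtH3 + c_CtH2_minus + c_CtH_2minus +
    c_Ct_3minus`` equals ``total_citrate`` by construction.
    """

    total_citrate: float
    pH: float
    c_CtH3: float
    c_CtH2_minus: float
    c_CtH_2minus: float
    c_Ct_3minus: float

    def fractions(self) -> np.ndarray:
        """Mole fractions (CtH3, CtH2-, CtH2-, Ct3-); sums to 1 for c > 0."""
        if self.total_citrate == 0.0:
            return np.zeros(4)
        return (
            np.array(
                [self.c_CtH3, self.c_CtH2_minus, self.c_CtH_2minus, self.c_Ct_3minus]
            )
            / self.total_citrate
        )


@dataclass(frozen=True)
class StoichiometryConstants:
    """Fixed electron bookkeeping of the TA reduction route.

    ``ta_per_au`` is the mol TA consumed per mol Au reduced via the TA
    route and must equal ``electrons_per_au / (electrons_per_phenol *
    phenols_per_ta)`` (3/20 = 0.15 for the defaults).
    """

    electrons_per_phenol: int = 2
    phenols_per_ta: int = 10
    electrons_per_au: int = 3

    @property
    def ta_per_au(self) -> float:
        capacity = ta_electron_capacity(self.phenols_per_ta, self.electrons_per_phenol)
        if capacity == 0:
            raise ZeroDivisionError("TA electron capacity is zero")
        return self.electrons_per_au / capacity


def speciate_citrate(
    total_citrate: float,
    pH: float,
    pKa: tuple[float, float, float] = DEFAULT_PKA,
) -> CitrateSpeciationState:
    """Distribute total citrate over its four protonation states.

    Closed-form triprotic distribution: with ``h = 10**-pH`` and acidity
    constants ``K1..K3``, the species concentrations are proportional to
    ``h^3 : h^2 K1 : h K1 K2 : K1 K2 K3``.

    Parameters
    ----------
    total_citrate : float
        Analytical citrate concentration, mol/L (>= 0).
    pH : float
        Solution pH in [0, 14].
    pKa : tuple of three floats
        pKa1 < pKa2 < pKa3; defaults to citric-acid literature values.

    Raises
    ------
    ValueError
        Negative concentration, pH outside [0, 14], or non-increasing pKa.
    """
    if total_citrate < 0:
        raise ValueError(f"total_citrate must be >= 0, got {total_citrate}")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {pH}")
    pka1, pka2, pka3 = pKa
    if not (pka1 < pka2 < pka3):
        raise ValueError(f"pKa values must be strictly increasing, got {pKa}")

    h = 10.0 ** (-pH)
    k1, k2, k3 = (10.0 ** (-p) for p in (pka1, pka2, pka3))
    terms = np.array([h**3, h**2 * k1, h * k1 * k2, k1 * k2 * k3])
    alphas = terms / terms.sum()
    c = total_citrate * alphas
    return CitrateSpeciationState(
        total_citrate=total_citrate,
        pH=pH,
        c_CtH3=c[0],
        c_CtH2_minus=c[1],
        c_CtH_2minus=c[2],
        c_Ct_3minus=c[3],
    )


def ta_electron_capacity(n_phenolic_groups: int, electrons_per_phenol: int = 2) -> int:
    """Electrons one TA molecule can donate: 2 per phenolic group.

    A full TA molecule (10 phenols) provides 20 electrons.
    """
    if n_phenolic_groups < 0:
        raise ValueError(f"phenol count must be >= 0, got {n_phenolic_groups}")
    if int(n_phenolic_groups) != n_phenolic_groups:
        raise ValueError(f"phenol count must be an integer, got {n_phenolic_groups}")
    return electrons_per_phenol * int(n_phenolic_groups)


def ta_au_stoichiometric_ratio(
    constants: StoichiometryConstants | None = None,
) -> float:
    """mol TA consumed per mol Au(III) reduced via the TA route.

    With the default constants this is 3/20 = 0.15: three electrons reduce
    one Au(III) and one TA supplies twenty.
    """
    if constants is None:
        constants = DEFAULT_STOICHIOMETRY
    return constants.ta_per_au


#: Default stoichiometry: 10 phenols x 2 e- per TA, 3 e- per Au.
DEFAULT_STOICHIOMETRY = StoichiometryConstants()
#: mol TA consumed per mol Au reduced via the TA route (= 3/20).
TA_PER_AU = DEFAULT_STOICHIOMETRY.ta_per_au
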