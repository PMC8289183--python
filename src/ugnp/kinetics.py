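"""Mass-action kinetics of the competing reduction/passivation mechanism.

The Au(III) precursor (AuCl4^-) is consumed by three parallel routes:

* TA reduction:       r_ta   = k_ta * c_Au^a * c_TA^l        (a = 1, l ~ 1.1)
* citrate reduction:  r_cit  = k_cit * c_Au * c_CtH2-
* passivation:        r_pass = k_pass * c_Au * c_OH-          (-> AuCl3(OH)^-)

d[Au3+]/dt   = -(r_ta + r_cit + r_pass)
d[AuCl3OH-]/dt =  r_pass
d[Au0]/dt    =   r_ta + r_cit
d[TA]/dt     = -(3/20) r_ta
d[CtH2-]/dt  = -(3/2)  r_cit

TA consumption follows the 3/20 electron stoichiometry (20 electrons per TA,
3 per Au); the citrate route consumes 3/2 CtH2^- per Au (2 electrons per
citrate oxidised to dicarboxyacetone).  [OH-] is held constant (buffered
medium).  The model is isothermal; temperature never enters.

Rate-coefficient defaults are CALIBRATED, not measured: they are chosen so
that the TA route dominates the initial rate and equilibrates quickly, and
so that varying the NaCit/Au ratio over 6-25 leaves the precursor profile
nearly unchanged.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from ugnp.speciation import TA_PER_AU

#: CtH2^- consumed per Au reduced via the citrate route (2 e- per citrate).
CIT_PER_AU = 1.5

_GOLD_CONSERVATION_RTOL = 1e-9


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successfully computed state."""

    def __init__(self, message: str, last_state: "ReactionState | None" = None):
        super().__init__(message)
        self.last_state = last_state


class FitError(RuntimeError):
    """Rate-constant fit did not converge."""

    def __init__(self, message: str, residual: float, n_iterations: int):
        super().__init__(f"{message} (residual={residual:.3e}, iterations={n_iterations})")
        self.residual = residual
        self.n_iterations = n_iterations


@dataclass(frozen=True)
class RateParameters:
    """Rate coefficients and orders of the three precursor routes.

    ``k_ta`` has units (mol/L)^(1 - au_order_ta - l) / s, ``k_cit`` and
    ``k_pass`` are bimolecular (L/mol/s).  Defaults are calibrated, not
    printed values (see module docstring).
    """

    k_ta: float = 2.5e3
    l: float = 1.1
    k_cit: float = 2.0
    k_pass: float = 1.0e4
    au_order_ta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_ta", "k_cit", "k_pass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.l <= 0:
            raise ValueError(f"TA reaction order l must be > 0, got {self.l}")


@dataclass(frozen=True)
class ReactionState:
    """Instantaneous concentrations (mol/L) of the mechanism's species."""

    t: float
    c_precursor: float
    c_passivated: float
    c_reduced: float
    c_ta: float
    c_cit_reactive: float
    c_oh: float

    def __post_init__(self) -> None:
        for name in (
            "c_precursor",
            "c_passivated",
            "c_reduced",
            "c_ta",
            "c_cit_reactive",
            "c_oh",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def total_gold(self) -> float:
        return self.c_precursor + self.c_passivated + self.c_reduced


@dataclass
class KineticTrace:
    """Time-ordered concentration profiles of one reaction run.

    Column arrays share a common length; times are strictly increasing.
    ``c_reduced_ta`` tracks the gold reduced via the TA route only (used to
    verify the 3/20 TA:Au stoichiometry along the trajectory); it is NaN for
    traces not produced by the simulator.
    """

    t: np.ndarray
    c_precursor: np.ndarray
    c_passivated: np.ndarray
    c_reduced: np.ndarray
    c_ta: np.ndarray
    c_cit_reactive: np.ndarray
    c_oh: float
    provenance: str = "simulated"
    c_reduced_ta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if self.c_reduced_ta is None:
            self.c_reduced_ta = np.full_like(self.t, np.nan)

    def __len__(self) -> int:
        return self.t.size

    def state_at(self, i: int) -> ReactionState:
        return ReactionState(
            t=float(self.t[i]),
            c_precursor=max(float(self.c_precursor[i]), 0.0),
            c_passivated=max(float(self.c_passivated[i]), 0.0),
            c_reduced=max(float(self.c_reduced[i]), 0.0),
            c_ta=max(float(self.c_ta[i]), 0.0),
            c_cit_reactive=max(float(self.c_cit_reactive[i]), 0.0),
            c_oh=self.c_oh,
        )

    @property
    def states(self) -> list[ReactionState]:
        return [self.state_at(i) for i in range(len(self))]

    @property
    def initial_state(self) -> ReactionState:
        return self.state_at(0)

    def total_gold(self) -> np.ndarray:
        return self.c_precursor + self.c_passivated + self.c_reduced


def reduction_rate_ta(state: ReactionState, params: RateParameters) -> float:
    """Rate of Au(III) reduction by TA: k_ta * c_Au^a * c_TA^l (mol/L/s)."""
    if state.c_precursor == 0.0 or state.c_ta == 0.0:
        return 0.0
    return params.k_ta * state.c_precursor**params.au_order_ta * state.c_ta**params.l


def reduction_rate_citrate(state: ReactionState, params: RateParameters) -> float:
    """Rate of Au(III) reduction by CtH2^-: k_cit * c_Au * c_CtH2- (mol/L/s)."""
    return params.k_cit * state.c_precursor * state.c_cit_reactive


def passivation_rate(state: ReactionState, params: RateParameters) -> float:
    """Rate of AuCl4^- -> AuCl3(OH)^- conversion: k_pass * c_Au * c_OH-."""
    return params.k_pass * state.c_precursor * state.c_oh


def _rhs(t: float, y: np.ndarray, params: RateParameters, c_oh: float) -> np.ndarray:
    # y = [precursor, passivated, reduced, ta, cit_reactive, reduced_via_ta]
    c_prec, _, _, c_ta, c_cit = np.maximum(y[:5], 0.0)
    if c_prec > 0.0 and c_ta > 0.0:
        r_ta = params.k_ta * c_prec**params.au_order_ta * c_ta**params.l
    else:
        r_ta = 0.0
    r_cit = params.k_cit * c_prec * c_cit
    r_pass = params.k_pass * c_prec * c_oh
    return np.array(
        [
            -(r_ta + r_cit + r_pass),
            r_pass,
            r_ta + r_cit,
            -TA_PER_AU * r_ta,
            -CIT_PER_AU * r_cit,
            r_ta,
        ]
    )


def simulate_reduction(
    initial: ReactionState,
    params: RateParameters,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> KineticTrace:
    """Integrate the mechanism over ``t_grid`` (stiff-safe adaptive LSODA).

    ``t_grid`` must be strictly increasing and start at ``initial.t``.
    Gold is conserved along the trajectory to ~1e-9 relative; negative
    concentrations are prevented by solver tolerance, not clipping.

    Raises
    ------
    IntegrationError
        If the solver fails; the exception carries the last good state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2:
        raise ValueError("t_grid needs at least two points")
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    if not np.isclose(t_grid[0], initial.t):
        raise ValueError(
            f"t_grid must start at the initial state's time {initial.t}, got {t_grid[0]}"
        )

    y0 = np.array(
        [
            initial.c_precursor,
            initial.c_passivated,
            initial.c_reduced,
            initial.c_ta,
            initial.c_cit_reactive,
            0.0,
        ]
    )
    sol = solve_ivp(
        _rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        args=(params, initial.c_oh),
    )
    if not sol.success:
        last = None
        if sol.t.size:
            i = sol.t.size - 1
            y = np.maximum(sol.y[:, i], 0.0)
            last = ReactionState(
                t=float(sol.t[i]),
                c_precursor=y[0],
                c_passivated=y[1],
                c_reduced=y[2],
                c_ta=y[3],
                c_cit_reactive=y[4],
                c_oh=initial.c_oh,
            )
        raise IntegrationError(f"ODE integration failed: {sol.message}", last_state=last)

    y = sol.y
    total0 = initial.total_gold
    if total0 > 0:
        drift = np.max(np.abs(y[0] + y[1] + y[2] - total0)) / total0
        if drift > 100 * _GOLD_CONSERVATION_RTOL:
            raise IntegrationError(
                f"gold conservation drift {drift:.2e} exceeds tolerance"
            )
    return KineticTrace(
        t=sol.t,
        c_precursor=y[0],
        c_passivated=y[1],
        c_reduced=y[2],
        c_ta=y[3],
        c_cit_reactive=y[4],
        c_oh=initial.c_oh,
        provenance="simulated",
        c_reduced_ta=y[5],
    )


_FIT_PARAM_NAMES = ("k_ta", "l", "k_cit", "k_pass")


def fit_rate_constants(
    traces: list[KineticTrace],
    initial_guess: RateParameters,
    fixed: dict[str, bool] | None = None,
    max_nfev: int = 200,
) -> RateParameters:
    """Least-squares fit of rate coefficients to one or more traces.

    Residuals are the differences between each observed trace and a fresh
    simulation from that trace's initial state, over the precursor, reduced
    gold and TA profiles, normalised by the initial total gold.  ``fixed``
    maps parameter names (``k_ta``, ``l``, ``k_cit``, ``k_pass``) to True to
    hold them at the guess.  Positive rate coefficients are optimised in
    log10 space; the TA order ``l`` linearly.

    Raises
    ------
    FitError
        On non-convergence (reports residual norm and iteration count).
    """
    if not traces:
        raise ValueError("need at least one trace")
    fixed = fixed or {}
    free = [n for n in _FIT_PARAM_NAMES if not fixed.get(n, False)]
    if not free:
        return initial_guess

    def encode(params: RateParameters) -> np.ndarray:
        out = []
        for n in free:
            v = getattr(params, n)
            if n == "l":
                out.append(v)
            else:
                # floor keeps log finite when the guess is a structural zero
                out.append(np.log10(max(v, 1e-12)))
        return np.array(out)

    def decode(x: np.ndarray) -> RateParameters:
        kwargs = {}
        for n, v in zip(free, x):
            kwargs[n] = v if n == "l" else 10.0**v
        return replace(initial_guess, **kwargs)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = decode(x)
        res = []
        for trace in traces:
            total0 = max(trace.initial_state.total_gold, 1e-300)
            try:
                sim = simulate_reduction(
                    trace.initial_state, params, trace.t, rtol=1e-8, atol=1e-12
                )
            except IntegrationError:
                return np.full(3 * sum(len(tr) for tr in traces), 1e3)
            for col in ("c_precursor", "c_reduced", "c_ta"):
                res.append((getattr(sim, col) - getattr(trace, col)) / total0)
        return np.concatenate(res)

    x0 = encode(initial_guess)
    lower = np.array([0.01 if n == "l" else -12.0 for n in free])
    upper = np.array([5.0 if n == "l" else 12.0 for n in free])
    result = least_squares(
        residuals, np.clip(x0, lower, upper), method="trf",
        bounds=(lower, upper), max_nfev=max_nfev,
    )
    if not result.success:
        raise FitError(
            "rate-constant fit did not converge",
            residual=float(np.sqrt(2 * result.cost)),
            n_iterations=int(result.nfev),
        )
    return decode(result.x)
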