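"""Validated run configuration shared by the CLI, pipeline and scripts.

The configuration is a strict schema (unknown keys rejected) covering the
speciation constants, the kinetic rate parameters with their provenance
(``printed`` if transcribed from a source, ``calibrated`` if chosen to match
qualitative behaviour), the colorimetry settings, the growth recipe and the
random seed.  Loadable from YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ugnp.kinetics import RateParameters, ReactionState
from ugnp.planner import Recipe, SynthesisRound, default_recipe
from ugnp.speciation import DEFAULT_PKA, speciate_citrate


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeciationConfig(_Strict):
    """Citrate speciation inputs.

    The working pH of the carbonate-buffered reaction medium is not a
    measured quantity here — it is an exposed parameter (default 6.0, a
    typical citrate-synthesis medium) that sets both the reactive CtH2^-
    concentration and [OH-].
    """

    pH: float = 6.0
    pKa: tuple[float, float, float] = DEFAULT_PKA
    total_citrate: float = 2.2e-3

    @property
    def c_oh(self) -> float:
        return 10.0 ** (-(14.0 - self.pH))


class RatesConfig(_Strict):
    """Rate coefficients with per-parameter provenance flags."""

    k_ta: float = 2.5e3
    l: float = 1.1
    k_cit: float = 2.0
    k_pass: float = 1.0e4
    au_order_ta: float = 1.0
    provenance: dict[str, str] = Field(
        default_factory=lambda: {
            "k_ta": "calibrated",
            "l": "printed",
            "k_cit": "calibrated",
            "k_pass": "calibrated",
            "au_order_ta": "assumed",
        }
    )

    @model_validator(mode="after")
    def _check_provenance(self) -> "RatesConfig":
        allowed = {"printed", "calibrated", "assumed"}
        bad = {v for v in self.provenance.values()} - allowed
        if bad:
            raise ValueError(f"provenance flags must be in {allowed}, got {bad}")
        return self

    def to_parameters(self) -> RateParameters:
        return RateParameters(
            k_ta=self.k_ta,
            l=self.l,
            k_cit=self.k_cit,
            k_pass=self.k_pass,
            au_order_ta=self.au_order_ta,
        )


class ColorimetryConfig(_Strict):
    """Red-fraction extraction settings."""

    roi: tuple[int, int, int, int] | None = None  # top, bottom, left, right
    window_fraction: float = 0.1
    plateau_frames: int = 5
    method: str = "pixel_mean"


class RoundConfig(_Strict):
    v_extract: float = 10.0
    v_replace: float = 10.0
    c_cit_replace: float = 2.2e-3
    c_au_final_target: float


class RecipeConfig(_Strict):
    """Seed conditions and growth rounds; defaults are the reference protocol."""

    seed_volume: float = 25.0
    seed_c_au: float = 1.25e-4
    seed_c_nacit: float = 2.2e-3
    seed_c_ta: float = 1.0e-4
    seed_c_k2co3: float = 6.0e-3
    seed_d_core: float = 3.0
    c_au_stock: float = 0.02
    rounds: list[RoundConfig] | None = None

    def to_recipe(self) -> Recipe:
        if self.rounds is None:
            base = default_recipe()
            rounds = base.rounds
        else:
            rounds = tuple(
                SynthesisRound(
                    index=i + 1,
                    v_extract=r.v_extract,
                    v_replace=r.v_replace,
                    c_cit_replace=r.c_cit_replace,
                    c_au_final_target=r.c_au_final_target,
                )
                for i, r in enumerate(self.rounds)
            )
        return Recipe(
            seed_volume=self.seed_volume,
            seed_c_au=self.seed_c_au,
            seed_c_nacit=self.seed_c_nacit,
            seed_c_ta=self.seed_c_ta,
            seed_c_k2co3=self.seed_c_k2co3,
            c_au_stock=self.c_au_stock,
            rounds=rounds,
        )


class RunConfig(_Strict):
    """Top-level configuration for a pipeline run."""

    speciation: SpeciationConfig = Field(default_factory=SpeciationConfig)
    rates: RatesConfig = Field(default_factory=RatesConfig)
    colorimetry: ColorimetryConfig = Field(default_factory=ColorimetryConfig)
    recipe: RecipeConfig = Field(default_factory=RecipeConfig)
    seed: int = 0
    output_dir: str = "results"

    def initial_reaction_state(self) -> ReactionState:
        """Seed-recipe initial concentrations with speciated reactive citrate."""
        spec = speciate_citrate(
            self.recipe.seed_c_nacit, self.speciation.pH, self.speciation.pKa
        )
        return ReactionState(
            t=0.0,
            c_precursor=self.recipe.seed_c_au,
            c_passivated=0.0,
            c_reduced=0.0,
            c_ta=self.recipe.seed_c_ta,
            c_cit_reactive=spec.c_CtH2_minus,
            c_oh=self.speciation.c_oh,
        )

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance headers."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)
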