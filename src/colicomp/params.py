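"""Model parameters, site states and scenario definitions.

The simulation tracks five site states on a square lattice: empty agar,
reproducing producer cells (C), toxin-producing cells (C_on, committed to
lysis), viable competitor cells (X) and growth-inhibited competitor cells
(X_stop).  All rates are per hour; lengths are in micrometres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum, IntEnum

__all__ = [
    "Site",
    "ModelParams",
    "ScenarioMode",
    "ScenarioSpec",
    "apply_scenario",
    "auto_dt",
    "MAX_EVENT_PROB",
]

#: hard cap on the probability of any single reaction event per update step
MAX_EVENT_PROB = 0.05

#: largest dt (hours) ever used, regardless of how small the rates are
_DT_CEILING = 0.05


class Site(IntEnum):
    """Lattice site states."""

    AGAR = 0
    C = 1
    C_ON = 2
    X = 3
    X_STOP = 4


class ScenarioMode(str, Enum):
    STOCHASTIC = "stochastic"
    SYNC_I = "sync_i"
    SYNC_II = "sync_ii"
    ALL_OFF = "all_off"
    NON_LYSING_ALL_ON = "non_lysing_all_on"


def auto_dt(r_C: float, r_X: float, s_C: float, d_Con: float) -> float:
    """Largest update step satisfying the single-event probability cap.

    The binding events are per-neighbor replication (rate r per orthogonal
    empty neighbor), switching (s_C) and lysis (d_Con).
    """
    max_rate = max(r_C, r_X, s_C, d_Con)
    if max_rate <= 0:
        return _DT_CEILING
    return min(MAX_EVENT_PROB / max_rate, _DT_CEILING)


@dataclass(frozen=True)
class ModelParams:
    """All reaction rates and toxin parameters.

    Parameters
    ----------
    r_C, r_X : float
        Replication rates (per hour, per orthogonal empty Moore neighbor)
        of the producer strain C and the competitor strain X.  Defaults are
        calibrated so that an unperturbed single-strain colony spotted at
        standard density reaches ~4.9 mm diameter after 48 h.
    diag_factor : float
        Down-weighting of replication into diagonal neighbors (1/2).
    s_C : float
        Switching rate C -> C_on (per hour).  The steady-state producer
        ratio is C_on/C = s_C/d_Con.
    d_Con : float
        Lysis rate of producing cells (per hour).  The default 1.2
        corresponds to a mean producing time of ~50 min before lysis.
    sigma_x : float
        Toxin sensitivity of X: the inhibition hazard is
        sigma_x * (local cumulative toxin) per hour.
    n_tox : float
        Toxin amount (dimensionless) deposited per lysis event.
    lambda_tox : float
        Decay length (um) of the exponential toxin profile.
    base_pixel_um : float
        Physical pixel size at zoom level 0.
    dt : float or None
        Update time step (hours).  ``None`` (default) resolves to the
        largest step satisfying the single-event probability cap
        (``MAX_EVENT_PROB``); an explicit value is validated against it.
    t_end : float
        Simulation horizon (hours).
    seed : int
        Seed for the run's random number generator.
    """

    r_C: float = 5.4
    r_X: float = 5.4
    diag_factor: float = 0.5
    s_C: float = 0.015
    d_Con: float = 1.2
    sigma_x: float = 1500.0
    n_tox: float = 1.0
    lambda_tox: float = 150.0
    base_pixel_um: float = 2.0
    dt: float | None = None
    t_end: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_C", "r_X", "d_Con", "n_tox", "lambda_tox", "base_pixel_um", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)!r})")
        if self.s_C < 0 or self.sigma_x < 0:
            raise ValueError("s_C and sigma_x must be >= 0")
        if not 0 < self.diag_factor <= 1:
            raise ValueError("diag_factor must be in (0, 1]")
        if self.dt is None:
            object.__setattr__(self, "dt", auto_dt(self.r_C, self.r_X, self.s_C, self.d_Con))
        else:
            if self.dt <= 0:
                raise ValueError("dt must be > 0")
            if self.dt > auto_dt(self.r_C, self.r_X, self.s_C, self.d_Con) + 1e-12:
                raise ValueError(
                    f"dt={self.dt} violates the single-event probability cap: "
                    f"largest admissible step is {auto_dt(self.r_C, self.r_X, self.s_C, self.d_Con):.4g} h"
                )

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario variants for the C strain's toxin-production program.

    In the SYNC scenarios, C dynamics are deterministic: cells grow without
    switching for ``sync_grow_minutes``, optionally pause (no replication)
    for ``sync_pause_minutes``, and then every C cell releases its toxin
    simultaneously and lyses.  ALL_OFF disables switching (s_C = 0).
    NON_LYSING_ALL_ON has every C cell release n_tox/2 toxin at each
    replication, with replication rate halved and no switching or lysis.
    """

    mode: ScenarioMode = ScenarioMode.STOCHASTIC
    sync_grow_minutes: float = 50.0
    sync_pause_minutes: float = 50.0

    @classmethod
    def stochastic(cls) -> "ScenarioSpec":
        return cls(mode=ScenarioMode.STOCHASTIC)

    @classmethod
    def sync_i(cls) -> "ScenarioSpec":
        return cls(mode=ScenarioMode.SYNC_I, sync_grow_minutes=50.0, sync_pause_minutes=50.0)

    @classmethod
    def sync_ii(cls) -> "ScenarioSpec":
        return cls(mode=ScenarioMode.SYNC_II, sync_grow_minutes=100.0, sync_pause_minutes=0.0)

    @classmethod
    def all_off(cls) -> "ScenarioSpec":
        return cls(mode=ScenarioMode.ALL_OFF)

    @classmethod
    def non_lysing_all_on(cls) -> "ScenarioSpec":
        return cls(mode=ScenarioMode.NON_LYSING_ALL_ON)

    @property
    def release_time_h(self) -> float:
        """Time of the collective toxin release (SYNC modes only)."""
        return (self.sync_grow_minutes + self.sync_pause_minutes) / 60.0


def apply_scenario(params: ModelParams, scenario: ScenarioSpec | None) -> ModelParams:
    """Return params adjusted for the scenario.

    ALL_OFF forces s_C = 0; NON_LYSING_ALL_ON halves r_C and n_tox relative
    to the stochastic reference and disables switching.
    """
    if scenario is None or scenario.mode is ScenarioMode.STOCHASTIC:
        return params
    if scenario.mode is ScenarioMode.ALL_OFF:
        return params.replace(s_C=0.0, dt=None)
    if scenario.mode is ScenarioMode.NON_LYSING_ALL_ON:
        return params.replace(r_C=params.r_C / 2.0, n_tox=params.n_tox / 2.0, s_C=0.0, dt=None)
    if scenario.mode in (ScenarioMode.SYNC_I, ScenarioMode.SYNC_II):
        return params.replace(s_C=0.0, dt=None)
    raise ValueError(f"unknown scenario mode: {scenario.mode!r}")
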