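"""Hybrid Euler / Monte Carlo integration engine.

The deterministic fluxes are advanced by explicit Euler with an exact
latent-period delay buffer.  Rare genotype-creation events — a spacer-
acquiring survivor entering ``B_{i+1}``, or an escape-mutant particle
entering ``P_{j+1}`` — are layered on as discrete stochastic increments of
one individual per culture volume.

Two event modes are supported:

``"unit"``
    One uniform draw per channel per step against probability ``p``; the
    engine aborts if any per-step ``p`` reaches 1 (the step size must then be
    reduced, or ``"poisson"`` mode used).
``"poisson"``
    A Poisson count with the same per-step expectation; required whenever
    production fluxes make per-step expectations exceed 1.

Runs are pure functions of (scenario, seed): the channel draw order is fixed
(spacer-acquisition channels by ascending pair index, then escape-mutation
channels), so identical seeds give bit-identical trajectories and event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    CommunityState,
    DelayBuffer,
    DimensionError,
    DomainError,
    ModelParams,
    basic_rhs,
)
from .extended import (
    ExtendedParams,
    ExtendedState,
    extended_rhs,
    n_persister_orders,
)

__all__ = [
    "StepSizeError",
    "NumericsError",
    "SimulationControl",
    "TransferSchedule",
    "EventRecord",
    "TimeSeries",
    "Simulation",
    "bim_event_probability",
    "cem_event_probability",
    "draw_events",
    "step",
    "run",
    "serial_transfer",
]

EVENT_MODES = ("unit", "poisson")

# Below this expected number of surviving individuals, dilution at transfer
# is resampled binomially instead of applied deterministically.
STOCHASTIC_ROUNDING_THRESHOLD = 10.0


class StepSizeError(RuntimeError):
    """A per-step event probability reached 1 in "unit" mode."""


class NumericsError(RuntimeError):
    """The integration produced a non-finite state variable."""


@dataclass(frozen=True)
class SimulationControl:
    """Step size, horizon, seed and discreteness settings for one run."""

    dt: float = 1e-3
    duration: float = 24.0
    seed: int = 0
    volume: float = 1.0
    event_mode: str = "unit"
    output_every: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError("SimulationControl.dt must be positive")
        if self.duration <= 0:
            raise DomainError("SimulationControl.duration must be positive")
        if self.volume <= 0:
            raise DomainError("SimulationControl.volume must be positive")
        if self.event_mode not in EVENT_MODES:
            raise DomainError(f"event_mode must be one of {EVENT_MODES}")
        if self.output_every <= 0:
            raise DomainError("SimulationControl.output_every must be positive")


@dataclass(frozen=True)
class TransferSchedule:
    """Serial-transfer protocol: periodic dilution into fresh medium."""

    period: float = 24.0
    dilution: float = 100.0
    resource: float = 350.0
    n_transfers: int = 1
    stochastic_rounding: bool = False

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise DomainError("TransferSchedule.period must be positive")
        if self.dilution < 1:
            raise DomainError("TransferSchedule.dilution must be >= 1")
        if self.resource < 0:
            raise DomainError("TransferSchedule.resource must be non-negative")
        if self.n_transfers < 0:
            raise DomainError("TransferSchedule.n_transfers must be >= 0")


@dataclass(frozen=True)
class EventRecord:
    """One discrete genotype-creation event."""

    time: float
    kind: str  # "BIM-creation" | "CEM-creation"
    source_order: int
    destination_order: int

    def __post_init__(self) -> None:
        if self.destination_order != self.source_order + 1:
            raise DomainError("event destination must be source order + 1")


class TimeSeries:
    """Sampled trajectory plus event log and run metadata."""

    def __init__(
        self,
        columns: Sequence[str],
        times: np.ndarray,
        values: np.ndarray,
        events: list[EventRecord],
        meta: dict,
    ) -> None:
        self.columns = list(columns)
        self.times = times
        self.values = values  # shape (n_samples, n_columns)
        self.events = events
        self.meta = meta

    def __len__(self) -> int:
        return len(self.times)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.values, columns=self.columns)
        frame.insert(0, "time_h", self.times)
        return frame

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "time_h": ev.time,
                    "kind": ev.kind,
                    "from_order": ev.source_order,
                    "to_order": ev.destination_order,
                }
                for ev in self.events
            ],
            columns=["time_h", "kind", "from_order", "to_order"],
        )


def bim_event_probability(
    m: float, lagged_flux: float, dt: float, volume: float, mode: str = "unit"
) -> float:
    """Per-step probability (or expectation) of one spacer-acquisition event.

    ``p = m * lagged_flux * volume * dt``: the lagged infection flux is the
    cohort completing its latent period this step, of which a fraction ``m``
    acquires a spacer; with individuals of size 1/volume this product is the
    expected number of new-genotype cells created in the step.
    """
    if min(m, lagged_flux, dt, volume) < 0:
        raise DomainError("event-probability inputs must be non-negative")
    p = m * lagged_flux * volume * dt
    if mode == "unit" and p >= 1.0:
        raise StepSizeError(
            f"per-step BIM probability {p:.3g} >= 1; reduce dt or use "
            "event_mode='poisson'"
        )
    return p


def cem_event_probability(
    mu: float,
    lagged_flux: float,
    beta: float,
    dt: float,
    volume: float,
    mode: str = "unit",
) -> float:
    """Per-step probability (or expectation) of one escape-mutation event.

    ``p = mu * lagged_flux * (beta - 1) * volume * dt`` — the mutation
    probability per released particle times the particle production rate.
    """
    if min(mu, lagged_flux, dt, volume) < 0 or beta <= 1:
        raise DomainError("event-probability inputs out of domain")
    p = mu * lagged_flux * (beta - 1.0) * volume * dt
    if mode == "unit" and p >= 1.0:
        raise StepSizeError(
            f"per-step CEM probability {p:.3g} >= 1; reduce dt or use "
            "event_mode='poisson'"
        )
    return p


def draw_events(
    probabilities: Sequence[float],
    rng: np.random.Generator,
    mode: str = "unit",
) -> np.ndarray:
    """Event counts per channel, in the order the probabilities were given.

    In "unit" mode each channel gets one uniform draw and yields 0 or 1
    event; probabilities must lie in [0, 1).  In "poisson" mode each entry
    is treated as an expectation and a Poisson count is drawn.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=np.int64)
    if not np.all(np.isfinite(p)) or (p < 0).any():
        raise DomainError("event probabilities must be finite and non-negative")
    if mode == "unit":
        if (p >= 1.0).any():
            raise StepSizeError("unit-mode probabilities must be < 1")
        return (rng.random(p.size) < p).astype(np.int64)
    if mode == "poisson":
        return rng.poisson(p)
    raise DomainError(f"unknown event mode {mode!r}")


def serial_transfer(
    state: CommunityState,
    schedule: TransferSchedule,
    rng: np.random.Generator | None = None,
    buffer: DelayBuffer | None = None,
    volume: float = 1.0,
) -> CommunityState:
    """Dilute the whole community into fresh medium (in place).

    Every density — cells, phage, infected cohorts, persisters, compound —
    is divided by the dilution factor and the resource is reset to the fresh
    concentration.  With ``stochastic_rounding`` on, any population whose
    expected number of surviving individuals is below
    ``STOCHASTIC_ROUNDING_THRESHOLD`` is resampled from a binomial with
    retention probability ``1/dilution`` (draw order: B ascending, P
    ascending, persisters ascending).
    """
    f = 1.0 / schedule.dilution

    def dilute_population(density: float) -> float:
        if not schedule.stochastic_rounding:
            return density * f
        if density * volume * f >= STOCHASTIC_ROUNDING_THRESHOLD:
            return density * f
        if rng is None:
            raise DomainError("stochastic_rounding requires an rng")
        n = int(round(density * volume))
        return rng.binomial(n, f) / volume

    for arr in (state.B, state.P):
        for i in range(len(arr)):
            arr[i] = dilute_population(arr[i])
    if isinstance(state, ExtendedState) and state.BP is not None:
        for i in range(len(state.BP)):
            state.BP[i] = dilute_population(state.BP[i])
        state.LY *= f
    state.M *= f
    if buffer is not None:
        buffer.scale(f)
    state.r = schedule.resource
    return state


class Simulation:
    """Stateful integrator for one scenario.

    Construct from a :class:`phagedyn.scenarios.Scenario` (any object with
    ``params``, ``control``, optional ``ext_params``/``schedule`` and initial
    densities), then call :meth:`run`, or drive it step by step.
    """

    def __init__(self, scenario) -> None:
        self.params: ModelParams = scenario.params
        self.control: SimulationControl = scenario.control
        self.ext: ExtendedParams | None = getattr(scenario, "ext_params", None)
        self.schedule: TransferSchedule | None = getattr(scenario, "schedule", None)

        dt = self.control.dt
        self.pairs = self.params.replicative_pairs()
        self.buffer = DelayBuffer(dt, self.params.lam, len(self.pairs))
        self.rng = np.random.default_rng(self.control.seed)
        self.state = self._initial_state(scenario)
        self.state.validate(self.params)
        self.events: list[EventRecord] = []
        self.clip_count = 0

        # Event channels in fixed draw order: spacer-acquisition (BIM) per
        # replicative pair whose host can still gain a spacer, then escape
        # mutation (CEM) per pair whose phage can still gain a mutation.
        self.bim_channels = [
            (idx, i, j)
            for idx, (i, j) in enumerate(self.pairs)
            if i + 1 < self.params.n_orders
        ]
        self.cem_channels = [
            (idx, i, j)
            for idx, (i, j) in enumerate(self.pairs)
            if j + 1 < self.params.n_phage
        ]
        n_channels = len(self.bim_channels) + len(self.cem_channels)
        self.has_events = bool(
            (self.params.m > 0 and self.bim_channels)
            or (self.params.mu > 0 and self.cem_channels)
        )
        self.expected_events = np.zeros(n_channels)
        self._bim_idx = np.array([idx for idx, _, _ in self.bim_channels], dtype=int)
        self._cem_idx = np.array([idx for idx, _, _ in self.cem_channels], dtype=int)

        self._steps_per_output = _exact_multiple(
            self.control.output_every, dt, "output_every", "dt"
        )
        if self.schedule is not None:
            self._steps_per_period = _exact_multiple(
                self.schedule.period, dt, "transfer period", "dt"
            )
        else:
            self._steps_per_period = 0
        self._transfers_done = 0
        self._step_index = 0

    # -- construction helpers -------------------------------------------------

    def _initial_state(self, scenario) -> CommunityState:
        B = np.asarray(scenario.init_B, dtype=float).copy()
        P = np.asarray(scenario.init_P, dtype=float).copy()
        M = np.zeros(len(self.pairs))
        if self.ext is not None:
            n_pers = n_persister_orders(self.params)
            BP = getattr(scenario, "init_BP", None)
            BP = np.zeros(n_pers) if BP is None else np.asarray(BP, dtype=float).copy()
            return ExtendedState(
                0.0, float(scenario.init_r), B, P, M,
                LY=float(getattr(scenario, "init_LY", 0.0)), BP=BP,
            )
        return CommunityState(0.0, float(scenario.init_r), B, P, M)

    # -- stepping -------------------------------------------------------------

    def step(self) -> CommunityState:
        """Advance the state by one Euler step plus Monte Carlo events."""
        params, control, state = self.params, self.control, self.state
        dt, volume = control.dt, control.volume

        lagged = self.buffer.lagged()

        # Current infection fluxes (from the pre-step state) feed the buffer.
        flux_now = np.empty(len(self.pairs))
        for idx, (i, j) in enumerate(self.pairs):
            flux_now[idx] = params.delta * state.B[i] * state.P[j]

        if self.ext is not None:
            dr, dB, dP, dM, dLY, dBP = extended_rhs(
                state, params, self.ext, lagged, check=False
            )
        else:
            dr, dB, dP, dM = basic_rhs(state, params, lagged, check=False)
            dLY = 0.0
            dBP = None

        state.r = self._clip(state.r + dr * dt)
        state.B += dB * dt
        state.P += dP * dt
        state.M += dM * dt
        self._clip_array(state.B)
        self._clip_array(state.P)
        self._clip_array(state.M)
        if self.ext is not None:
            state.LY = self._clip(state.LY + dLY * dt)
            state.BP += dBP * dt
            self._clip_array(state.BP)

        self.buffer.push(flux_now)

        if self.has_events:
            self._apply_events(lagged, state)

        state.t = round((self._step_index + 1) * dt, 12)
        self._step_index += 1

        if not (
            math.isfinite(state.r)
            and math.isfinite(float(state.B.sum()))
            and math.isfinite(float(state.P.sum()))
        ):
            raise NumericsError(f"non-finite state at t={state.t:.6g} h")
        return state

    def _apply_events(self, lagged: np.ndarray, state: CommunityState) -> None:
        params, control = self.params, self.control
        mode = control.event_mode
        scale = control.volume * control.dt
        probs = np.concatenate(
            [
                params.m * lagged[self._bim_idx] * scale,
                params.mu * (params.beta - 1.0) * lagged[self._cem_idx] * scale,
            ]
        )
        if mode == "unit" and (probs >= 1.0).any():
            raise StepSizeError(
                f"per-step event probability reached "
                f"{probs.max():.3g} >= 1 at t={state.t:.4g} h; reduce dt or "
                "use event_mode='poisson'"
            )
        self.expected_events += probs
        counts = (
            (self.rng.random(probs.size) < probs).astype(np.int64)
            if mode == "unit"
            else self.rng.poisson(probs)
        )
        unit = 1.0 / control.volume
        t = round((self._step_index + 1) * control.dt, 12)
        n_bim = len(self.bim_channels)
        for ch, (idx, i, j) in enumerate(self.bim_channels):
            c = int(counts[ch])
            if c:
                state.B[i + 1] += c * unit
                self.events.append(EventRecord(t, "BIM-creation", i, i + 1))
        for ch, (idx, i, j) in enumerate(self.cem_channels):
            c = int(counts[n_bim + ch])
            if c:
                state.P[j + 1] += c * unit
                state.P[j] = max(state.P[j] - c * unit, 0.0)
                self.events.append(EventRecord(t, "CEM-creation", j, j + 1))

    def _clip(self, x: float) -> float:
        if x < 0:
            self.clip_count += 1
            return 0.0
        return x

    def _clip_array(self, arr: np.ndarray) -> None:
        neg = arr < 0
        if neg.any():
            self.clip_count += int(neg.sum())
            arr[neg] = 0.0

    # -- full run -------------------------------------------------------------

    def run(self) -> TimeSeries:
        """Integrate over the control horizon, sampling and transferring."""
        n_steps = _exact_multiple(self.control.duration, self.control.dt, "duration", "dt")
        times = [0.0]
        rows = [self._snapshot_row()]
        for s in range(1, n_steps + 1):
            self.step()
            # Sample first, so boundary samples show end-of-transfer densities.
            if s % self._steps_per_output == 0:
                times.append(self.state.t)
                rows.append(self._snapshot_row())
            if (
                self._steps_per_period
                and self.schedule is not None
                and s % self._steps_per_period == 0
                and self._transfers_done < self.schedule.n_transfers
                and s < n_steps
            ):
                serial_transfer(
                    self.state,
                    self.schedule,
                    rng=self.rng,
                    buffer=self.buffer,
                    volume=self.control.volume,
                )
                self._transfers_done += 1
        meta = {
            "clips": self.clip_count,
            "transfers": self._transfers_done,
            "seed": self.control.seed,
            "expected_events": {
                **{
                    f"BIM_{i}to{i + 1}_via_P{j}": float(self.expected_events[c])
                    for c, (idx, i, j) in enumerate(self.bim_channels)
                },
                **{
                    f"CEM_{j}to{j + 1}_on_B{i}": float(
                        self.expected_events[len(self.bim_channels) + c]
                    )
                    for c, (idx, i, j) in enumerate(self.cem_channels)
                },
            },
        }
        return TimeSeries(
            self.column_names(),
            np.asarray(times),
            np.asarray(rows),
            self.events,
            meta,
        )

    def column_names(self) -> list[str]:
        cols = ["r_ug_ml"]
        cols += [f"B{i}" for i in range(self.params.n_orders)]
        cols += [f"P{j}" for j in range(self.params.n_phage)]
        cols += [f"M{i}{j}" for (i, j) in self.pairs]
        if self.ext is not None:
            cols.append("LY")
            cols += [f"BP{i}" for i in range(n_persister_orders(self.params))]
        return cols

    def _snapshot_row(self) -> list[float]:
        s = self.state
        row = [s.r, *s.B.tolist(), *s.P.tolist(), *s.M.tolist()]
        if self.ext is not None:
            row.append(s.LY)
            row.extend(s.BP.tolist())
        return row


def step(state, params, control, rng):  # pragma: no cover - thin convenience
    """One-off single step for an ad-hoc state (convenience wrapper).

    For anything beyond a single step build a :class:`Simulation`, which owns
    the delay buffer and event log.
    """
    from .scenarios import Scenario

    scen = Scenario(
        name="adhoc", params=params, control=control,
        init_r=state.r, init_B=state.B, init_P=state.P,
    )
    sim = Simulation(scen)
    sim.rng = rng
    sim.state = state.copy()
    return sim.step()


def run(scenario) -> TimeSeries:
    """Simulate a scenario end to end and return its sampled trajectory."""
    return Simulation(scenario).run()


def _exact_multiple(value: float, unit: float, name: str, unit_name: str) -> int:
    ratio = value / unit
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise DomainError(
            f"{name}={value} must be a positive integer multiple of {unit_name}={unit}"
        )
    return n
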