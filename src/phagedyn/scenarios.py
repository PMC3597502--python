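"""Scenario presets and synthetic-assay fixture generators.

Presets bundle the parameter sets used throughout the package's validation
runs: short-term lysis of a sensitive culture, immune-host / escape-mutant
invasions, the lysis-compound extension with daily serial transfer, and the
one-step growth protocol.  The ``synth_*`` generators produce seeded,
metadata-carrying synthetic assay data for exercising the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import DomainError, ModelParams
from .engine import Simulation, SimulationControl, TransferSchedule, serial_transfer
from .estimators import GrowthCurve, OneStepDesign
from .extended import ExtendedParams

__all__ = [
    "Scenario",
    "PRESET_NAMES",
    "preset",
    "list_presets",
    "growth_scenario",
    "synth_growth_curve",
    "synth_one_step",
    "synth_lysate",
    "LysateResult",
]

# OD per cell/ml used by the linear density->OD conversion of the synthetic
# growth fixtures (5e8 cells/ml ~ OD 0.2).
OD_PER_CELL = 4e-10


@dataclass(frozen=True)
class Scenario:
    """Parameters + initial state + control settings: one reproducible run."""

    name: str
    params: ModelParams
    control: SimulationControl
    init_r: float = 350.0
    init_B: tuple[float, ...] = (2e6,)
    init_P: tuple[float, ...] = (0.0,)
    ext_params: ExtendedParams | None = None
    init_LY: float = 0.0
    init_BP: tuple[float, ...] | None = None
    schedule: TransferSchedule | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.init_r < 0 or self.init_LY < 0:
            raise DomainError("initial resource and compound must be non-negative")
        if min(self.init_B, default=0.0) < 0 or min(self.init_P, default=0.0) < 0:
            raise DomainError("initial densities must be non-negative")
        if self.init_BP is not None and min(self.init_BP, default=0.0) < 0:
            raise DomainError("initial persister densities must be non-negative")

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, control=replace(self.control, seed=seed))


# Reference parameterisation for the wild-type host/phage pair: growth and
# infection constants estimated from batch growth, one-step growth, and a
# fitted adsorption constant.
_BASE = dict(v=1.4, k=1.0, e=5e-7, delta=8e-8, beta=80.0, lam=0.4)

_EXT = ExtendedParams(v_L=1e-6, K_L=1e6, eta=1.4, g=0.01, h=0.01)


def _fig2() -> Scenario:
    return Scenario(
        name="fig2",
        params=ModelParams(**_BASE, m=0.0, mu=0.0, n_orders=1),
        control=SimulationControl(dt=1e-3, duration=24.0, output_every=0.01),
        init_B=(2e6,),
        init_P=(2e6,),
        note="sensitive culture vs. lytic phage, no immunity channels",
    )


def _figS3a() -> Scenario:
    return Scenario(
        name="figS3a",
        params=ModelParams(**_BASE, m=0.0, mu=0.0, n_orders=2),
        control=SimulationControl(dt=1e-3, duration=24.0, output_every=0.05),
        init_B=(0.0, 2e6),
        init_P=(2e6, 1.0),
        note="single-spacer host with dominant non-replicating phage and one escape particle",
    )


def _figS3b() -> Scenario:
    return Scenario(
        name="figS3b",
        params=ModelParams(**_BASE, m=0.0, mu=1e-6, n_orders=2),
        control=SimulationControl(
            dt=1e-3, duration=24.0, output_every=0.05, event_mode="poisson"
        ),
        init_B=(2e6, 2e6),
        init_P=(2e6, 0.0),
        note="equal sensitive/immune hosts, escape mutants arise by mutation",
    )


def _fig10a() -> Scenario:
    return Scenario(
        name="fig10a",
        params=ModelParams(**_BASE, m=1e-6, mu=1e-6, n_orders=3, n_phage_orders=2),
        control=SimulationControl(
            dt=1e-3, duration=24.0, output_every=0.1, event_mode="poisson"
        ),
        init_B=(2e6, 0.0, 2e6),
        init_P=(2e6, 0.0),
        ext_params=replace(_EXT, v_L=0.0),
        note="extension with compound production switched off",
    )


def _fig10bcd() -> Scenario:
    return Scenario(
        name="fig10bcd",
        params=ModelParams(**_BASE, m=1e-6, mu=1e-6, n_orders=3, n_phage_orders=2),
        control=SimulationControl(
            dt=1e-3, duration=240.0, output_every=0.2, event_mode="poisson"
        ),
        init_B=(2e6, 0.0, 2e6),
        init_P=(2e6, 0.0),
        ext_params=_EXT,
        schedule=TransferSchedule(period=24.0, dilution=100.0, resource=350.0, n_transfers=9),
        note="extension with compound killing/persistence, 10 daily passes",
    )


def _fig11_serial() -> Scenario:
    return Scenario(
        name="fig11-serial",
        params=ModelParams(**_BASE, m=1e-6, mu=1e-6, n_orders=3, n_phage_orders=2),
        control=SimulationControl(
            dt=1e-3, duration=240.0, output_every=0.2, event_mode="poisson"
        ),
        init_B=(2e6, 0.0, 0.0),
        init_P=(2e6, 0.0),
        ext_params=_EXT,
        schedule=TransferSchedule(period=24.0, dilution=100.0, resource=350.0, n_transfers=9),
        note="wild-type cells + phage under daily serial transfer (run one seed per replicate)",
    )


def _onestep_protocol() -> Scenario:
    return Scenario(
        name="onestep-protocol",
        params=ModelParams(**_BASE, m=0.0, mu=0.0, n_orders=1),
        control=SimulationControl(dt=1 / 1200, duration=1.0, output_every=1 / 12),
        init_B=(2e8,),
        init_P=(1e6,),
        note=(
            "one-step growth: 15-min high-density adsorption phase, then "
            "1e4-fold dilution; drive via synth_one_step for protocol sampling"
        ),
    )


_PRESETS = {
    "fig2": _fig2,
    "figS3a": _figS3a,
    "figS3b": _figS3b,
    "fig10a": _fig10a,
    "fig10bcd": _fig10bcd,
    "fig11-serial": _fig11_serial,
    "onestep-protocol": _onestep_protocol,
}

PRESET_NAMES = tuple(_PRESETS)


def list_presets() -> tuple[str, ...]:
    return PRESET_NAMES


def preset(name: str) -> Scenario:
    """Return a fully specified named scenario."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
    return builder()


def growth_scenario(
    v: float = 1.37,
    B0: float = 2e6,
    r0: float = 350.0,
    duration: float = 2.0,
    dt: float = 0.005,
    output_every: float = 0.25,
) -> Scenario:
    """Phage-free batch growth scenario (fixture for the rate estimator)."""
    base = dict(_BASE)
    base["v"] = v
    return Scenario(
        name="phage-free-growth",
        params=ModelParams(**base, m=0.0, mu=0.0, n_orders=1),
        control=SimulationControl(dt=dt, duration=duration, output_every=output_every),
        init_r=r0,
        init_B=(B0,),
        init_P=(0.0,),
        note="phage-free Monod batch growth",
    )


def synth_growth_curve(
    v: float = 1.37,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 2.0,
    sample_every: float = 0.25,
    kind: str = "od",
) -> GrowthCurve:
    """Simulated growth curve with multiplicative lognormal noise.

    The noise-free trajectory is the phage-free model; readings are either
    raw densities or a linear OD conversion, multiplied by
    ``exp(N(0, noise_sd**2))`` i.i.d. per sample.
    """
    if v <= 0:
        raise DomainError("v must be positive")
    scen = growth_scenario(v=v, duration=duration, output_every=sample_every)
    ts = Simulation(scen).run()
    densities = ts.column("B0")
    readings = densities * OD_PER_CELL if kind == "od" else densities.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        readings = readings * np.exp(rng.normal(0.0, noise_sd, size=readings.shape))
    return GrowthCurve(
        ts.times,
        readings,
        kind=kind,
        meta={
            "v": v,
            "noise_sd": noise_sd,
            "seed": seed,
            "od_per_cell": OD_PER_CELL if kind == "od" else None,
            "generator": "synth_growth_curve",
        },
    )


def synth_one_step(
    params: ModelParams | None = None,
    design: OneStepDesign = OneStepDesign(),
    noise_sd: float = 0.0,
    seed: int = 0,
    adsorption_time: float = 0.25,
    dilution: float = 1e4,
    sample_every: float = 1 / 12,
    duration: float = 1.0,
    plating_dilution: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate the one-step growth protocol and return a sampled PFU series.

    High-density adsorption for ``adsorption_time`` hours, then a
    ``dilution``-fold transfer into fresh medium that freezes further
    adsorption; plaque-forming units are free phage plus infected cells,
    sampled on the post-dilution grid.  With ``noise_sd > 0`` plaque
    counting noise is applied: counts at the plating dilution are drawn
    Poisson and rescaled (``noise_sd`` only gates the switch; the noise law
    is Poisson counting).
    """
    scen = preset("onestep-protocol")
    if params is not None:
        scen = replace(scen, params=params)
    scen = replace(scen, control=replace(scen.control, duration=duration))
    sim = Simulation(scen)
    dt = scen.control.dt
    n_dilute = round(adsorption_time / dt)
    n_total = round(duration / dt)
    n_sample = round(sample_every / dt)
    times, pfu = [], []
    for s in range(1, n_total + 1):
        sim.step()
        if s == n_dilute:
            serial_transfer(
                sim.state,
                TransferSchedule(
                    period=adsorption_time, dilution=dilution, resource=scen.init_r
                ),
                buffer=sim.buffer,
            )
        if s >= n_dilute and s % n_sample == 0:
            times.append(sim.state.t)
            pfu.append(float(sim.state.P.sum() + sim.state.M.sum()))
    times = np.asarray(times)
    pfu = np.asarray(pfu)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pfu = rng.poisson(pfu / plating_dilution) * plating_dilution
    meta = {
        "params": scen.params,
        "design": design,
        "seed": seed,
        "dilution": dilution,
        "adsorption_time": adsorption_time,
        "generator": "synth_one_step",
    }
    return times, pfu, meta


@dataclass(frozen=True)
class LysateResult:
    """Genotype-resolved outcome of a simulated single-plaque lysate."""

    p0: float
    p1: float
    frequency: float
    seed: int


def synth_lysate(
    mu: float = 1e-6,
    B0_init: float = 2e6,
    P0_init: float = 1e3,
    seed: int = 0,
    duration: float = 24.0,
    dt: float = 1e-3,
) -> LysateResult:
    """Grow a lysate from a small phage inoculum and resolve mutant phage.

    Runs the basic model (two phage orders, Poisson event mode) to lysis
    completion and reports the escape-mutant frequency ``P1 / (P0 + P1)``.
    """
    scen = Scenario(
        name="lysate",
        params=ModelParams(**_BASE, m=0.0, mu=mu, n_orders=2),
        control=SimulationControl(
            dt=dt, duration=duration, output_every=duration, seed=seed,
            event_mode="poisson",
        ),
        init_B=(B0_init, 0.0),
        init_P=(P0_init, 0.0),
        note="simulated single-plaque lysate",
    )
    ts = Simulation(scen).run()
    p0 = float(ts.column("P0")[-1])
    p1 = float(ts.column("P1")[-1])
    total = p0 + p1
    freq = p1 / total if total > 0 else 0.0
    return LysateResult(p0, p1, freq, seed)
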