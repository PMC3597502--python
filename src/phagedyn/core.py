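"""Core domain types and the deterministic flux terms of the basic model.

The community consists of ``n_orders`` bacterial populations ``B_0..B_{n-1}``
(order = number of CRISPR spacers carried) and up to ``n_phage_orders`` phage
populations ``P_0..P_{n-1}`` (order = number of protospacer/PAM escape
mutations).  A phage of order ``j`` adsorbs to every bacterium but replicates
only on hosts of order ``i <= j``; adsorption to a higher-order (immune) host
destroys the phage and leaves the cell alive.  Infected cells enter a fated
cohort ``M_ij`` and lyse one latent period later, releasing ``beta - 1`` new
particles per cell (the infecting particle is consumed); a fraction ``m`` of
those cohorts instead yields a spacer-acquiring survivor, handled discretely
by the engine.

Everything in this module is pure computation: no randomness, no stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache as _functools_lru_cache

import numpy as np

__all__ = [
    "DomainError",
    "DimensionError",
    "ModelParams",
    "CommunityState",
    "DelayBuffer",
    "monod_psi",
    "infection_flux",
    "burst_release",
    "basic_rhs",
]


class DomainError(ValueError):
    """A quantity is outside its physical domain (negative density, etc.)."""


@_functools_lru_cache(maxsize=None)
def _replicative_pairs(n_orders: int, n_phage: int) -> tuple[tuple[int, int], ...]:
    return tuple(
        (i, j) for i in range(n_orders) for j in range(i, n_phage)
    )


class DimensionError(ValueError):
    """State and parameters disagree on the number of orders/cohorts."""


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the basic model.

    Parameters
    ----------
    v : float
        Maximum per-capita growth rate (per hour).
    k : float
        Half-saturation (Monod) resource concentration (µg/ml).
    e : float
        Conversion efficiency: µg of resource consumed per new cell.
    delta : float
        Adsorption rate constant (ml per cell per phage per hour).
    beta : float
        Burst size, phage particles per infected cell (> 1).
    lam : float
        Latent period between adsorption and lysis (hours, > 0).
    m : float
        Probability that a replicative infection yields a spacer-acquiring
        survivor instead of a burst (dimensionless, in [0, 1]).
    mu : float
        Probability per released particle of an escape (CEM) mutation
        (dimensionless, in [0, 1]).
    n_orders : int
        Number of bacterial orders (>= 1).
    n_phage_orders : int, optional
        Number of phage orders; defaults to ``n_orders``.  May be smaller,
        in which case top-order bacteria are immune to every phage.
    """

    v: float
    k: float
    e: float
    delta: float
    beta: float
    lam: float
    m: float = 0.0
    mu: float = 0.0
    n_orders: int = 3
    n_phage_orders: int | None = None

    def __post_init__(self) -> None:
        for name in ("v", "k", "e", "delta", "m", "mu"):
            if getattr(self, name) < 0:
                raise DomainError(f"ModelParams.{name} must be non-negative")
        if self.k <= 0:
            raise DomainError("ModelParams.k must be positive")
        if self.beta <= 1:
            raise DomainError("ModelParams.beta must exceed 1")
        if self.lam <= 0:
            raise DomainError("ModelParams.lam must be positive")
        if not (self.m <= 1 and self.mu <= 1):
            raise DomainError("ModelParams.m and .mu are probabilities (<= 1)")
        if self.n_orders < 1:
            raise DomainError("ModelParams.n_orders must be >= 1")
        if self.n_phage_orders is None:
            object.__setattr__(self, "n_phage_orders", self.n_orders)
        if not (1 <= self.n_phage_orders <= self.n_orders):
            raise DomainError("n_phage_orders must be in [1, n_orders]")

    @property
    def n_phage(self) -> int:
        return int(self.n_phage_orders)  # type: ignore[arg-type]

    def replicative_pairs(self) -> tuple[tuple[int, int], ...]:
        """(host order i, phage order j) pairs with j >= i, in fixed order.

        Only these pairs carry infected cohorts; the ordering defines the
        layout of every per-cohort array in the package.
        """
        return _replicative_pairs(self.n_orders, self.n_phage)


@dataclass
class CommunityState:
    """Densities of every population at one instant.

    ``M`` is laid out along :meth:`ModelParams.replicative_pairs`.
    """

    t: float
    r: float
    B: np.ndarray
    P: np.ndarray
    M: np.ndarray

    def copy(self) -> "CommunityState":
        return CommunityState(self.t, self.r, self.B.copy(), self.P.copy(), self.M.copy())

    def validate(self, params: ModelParams) -> None:
        if len(self.B) != params.n_orders:
            raise DimensionError(
                f"state has {len(self.B)} bacterial orders, params expect {params.n_orders}"
            )
        if len(self.P) != params.n_phage:
            raise DimensionError(
                f"state has {len(self.P)} phage orders, params expect {params.n_phage}"
            )
        if len(self.M) != len(params.replicative_pairs()):
            raise DimensionError("infected-cohort vector has wrong length")
        if self.r < 0 or (self.B < 0).any() or (self.P < 0).any() or (self.M < 0).any():
            raise DomainError("densities and resource must be non-negative")


class DelayBuffer:
    """Circular record of infection fluxes over the last latent period.

    One row per replicative (i, j) pair; ``n_slots = lam / dt`` columns of
    infection fluxes (cells/ml/hour).  The flux written ``n_slots`` steps ago
    is the cohort bursting now, and ``sum(row) * dt`` equals the standing
    infected density ``M_ij`` exactly.  ``lam`` must be an integer multiple
    of ``dt`` so the delay bookkeeping stays exact (no interpolation).
    """

    def __init__(self, dt: float, lam: float, n_pairs: int) -> None:
        if dt <= 0:
            raise DomainError("dt must be positive")
        ratio = lam / dt
        n_slots = round(ratio)
        if n_slots < 1 or abs(ratio - n_slots) > 1e-9 * max(1.0, ratio):
            raise DomainError(
                f"latent period lam={lam} must be a positive integer multiple of dt={dt}"
            )
        self.dt = dt
        self.n_slots = n_slots
        self._data = np.zeros((n_pairs, n_slots))
        self._head = 0  # column holding the oldest (about-to-burst) fluxes

    @property
    def n_pairs(self) -> int:
        return self._data.shape[0]

    def lagged(self) -> np.ndarray:
        """Infection fluxes recorded one latent period ago (view-safe copy)."""
        return self._data[:, self._head].copy()

    def push(self, flux: np.ndarray) -> None:
        """Overwrite the oldest slot with the current fluxes and advance."""
        if (flux < 0).any():
            raise DomainError("infection fluxes must be non-negative")
        self._data[:, self._head] = flux
        self._head = (self._head + 1) % self.n_slots

    def totals(self) -> np.ndarray:
        """Standing infected-cohort densities M_ij = sum(fluxes) * dt."""
        return self._data.sum(axis=1) * self.dt

    def scale(self, factor: float) -> None:
        """Multiply all stored fluxes (used at serial transfer dilution)."""
        if factor < 0:
            raise DomainError("scale factor must be non-negative")
        self._data *= factor


def monod_psi(r: float, v: float, k: float) -> float:
    """Per-capita growth rate on resource ``r``: ``v * r / (r + k)``.

    Monotone non-decreasing in ``r``, equal to ``v/2`` at ``r = k``, and
    bounded above by ``v``.
    """
    if r < 0:
        raise DomainError("resource concentration must be non-negative")
    if v < 0 or k <= 0:
        raise DomainError("require v >= 0 and k > 0")
    return v * r / (r + k)


def infection_flux(Bi: float, Pj: float, delta: float) -> float:
    """Mass-action infection rate ``delta * Bi * Pj`` (cells/ml/hour)."""
    if Bi < 0 or Pj < 0 or delta < 0:
        raise DomainError("densities and delta must be non-negative")
    return delta * Bi * Pj


def burst_release(flux_at_lag: float, m: float, beta: float) -> float:
    """Phage production rate from a cohort infected one latent period ago.

    A fraction ``1 - m`` of the cohort bursts, each cell releasing
    ``beta - 1`` particles (the infecting particle was consumed).
    """
    if flux_at_lag < 0:
        raise DomainError("lagged flux must be non-negative")
    return (1.0 - m) * (beta - 1.0) * flux_at_lag


def basic_rhs(
    state: CommunityState,
    params: ModelParams,
    lagged_flux: np.ndarray,
    check: bool = True,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic time-derivatives (dr, dB, dP, dM) of the basic model.

    ``lagged_flux`` holds, per replicative pair, the infection flux one
    latent period ago (the cohort lysing now).  Discrete spacer-acquisition
    and escape-mutation increments are NOT applied here; the hybrid engine
    layers them on as Monte Carlo unit events.  ``check=False`` skips state
    validation (the engine validates once and clips every step).
    """
    pairs = params.replicative_pairs()
    if check:
        state.validate(params)
        if len(lagged_flux) != len(pairs):
            raise DimensionError("lagged_flux has wrong length")

    B, P = state.B, state.P
    psi = monod_psi(state.r, params.v, params.k)
    b_total = float(B.sum())

    dr = -params.e * psi * b_total
    dB = psi * B
    # Phage are adsorbed (and lost) by bacteria of every order.
    dP = -params.delta * P * b_total
    dM = np.empty(len(pairs))
    gain = (1.0 - params.m) * (params.beta - 1.0)
    for idx, (i, j) in enumerate(pairs):
        f = params.delta * B[i] * P[j]
        dB[i] -= f  # cells lost only to phage that replicate on them
        dP[j] += gain * lagged_flux[idx]
        dM[idx] = f - lagged_flux[idx]
    return dr, dB, dP, dM
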