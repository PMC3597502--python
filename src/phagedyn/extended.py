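"""Extension of the basic model with a lysis-released compound.

The compound (concentration ``LY``, µg/ml) is produced in proportion to the
product of replicating-phage and sensitive-host densities.  It acts through a
saturating effect fraction ``E = min(LY / K_L, 1)`` on two channels:

* killing of dividing cells at per-capita rate ``eta * E``;
* entry of low-order dividing cells into a non-dividing persister pool at
  rate ``g * E`` (return at constant rate ``h``).

Persisters do not grow, do not take up resource, are not adsorbed by phage
and are not killed by the compound.  There is no spontaneous decay of LY:
it is removed only by dilution at serial transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CommunityState,
    DimensionError,
    DomainError,
    ModelParams,
    basic_rhs,
)

__all__ = [
    "ExtendedParams",
    "ExtendedState",
    "n_persister_orders",
    "ly_production_rate",
    "ly_effect",
    "extended_rhs",
]


@dataclass(frozen=True)
class ExtendedParams:
    """Rate constants governing the lysis-released compound.

    v_L : production rate constant (µg·ml per cell per phage per hour).
    K_L : concentration of maximal effect (µg/ml, > 0).
    eta : maximum per-capita kill rate of dividing cells (per hour).
    g   : persistence-entry rate at full effect (per hour).
    h   : persistence-exit rate (per hour).
    """

    v_L: float
    K_L: float
    eta: float
    g: float
    h: float

    def __post_init__(self) -> None:
        for name in ("v_L", "K_L", "eta", "g", "h"):
            if getattr(self, name) < 0:
                raise DomainError(f"ExtendedParams.{name} must be non-negative")
        if self.K_L <= 0:
            raise DomainError("ExtendedParams.K_L must be positive")


def n_persister_orders(params: ModelParams) -> int:
    """Orders that carry a persister compartment: 0 and 1 (capped by n_orders)."""
    return min(2, params.n_orders)


@dataclass
class ExtendedState(CommunityState):
    """Community state plus compound concentration and persister pools."""

    LY: float = 0.0
    BP: np.ndarray | None = None

    def copy(self) -> "ExtendedState":
        return ExtendedState(
            self.t, self.r, self.B.copy(), self.P.copy(), self.M.copy(),
            self.LY, None if self.BP is None else self.BP.copy(),
        )

    def validate(self, params: ModelParams) -> None:
        super().validate(params)
        if self.LY < 0:
            raise DomainError("LY concentration must be non-negative")
        if self.BP is None or len(self.BP) != n_persister_orders(params):
            raise DimensionError(
                f"expected {n_persister_orders(params)} persister pools"
            )
        if (self.BP < 0).any():
            raise DomainError("persister densities must be non-negative")


def ly_production_rate(state: ExtendedState, params: ModelParams, v_L: float) -> float:
    """dLY/dt = v_L * sum over replicative (i, j) pairs of B_i * P_j."""
    if v_L < 0:
        raise DomainError("v_L must be non-negative")
    total = 0.0
    for i, j in params.replicative_pairs():
        total += state.B[i] * state.P[j]
    return v_L * total


def ly_effect(LY: float, K_L: float) -> float:
    """Saturating effect fraction: LY/K_L, capped at 1 once LY exceeds K_L."""
    if LY < 0 or K_L <= 0:
        raise DomainError("require LY >= 0 and K_L > 0")
    return min(LY / K_L, 1.0)


def extended_rhs(
    state: ExtendedState,
    params: ModelParams,
    ext: ExtendedParams,
    lagged_flux: np.ndarray,
    check: bool = True,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """Derivatives (dr, dB, dP, dM, dLY, dBP) of the extended model.

    Builds on :func:`phagedyn.core.basic_rhs`; the kill term ``-eta * E``
    applies to every dividing bacterial population, and the g/h persistence
    exchange conserves cells order by order.
    """
    if check:
        state.validate(params)
    dr, dB, dP, dM = basic_rhs(state, params, lagged_flux, check=check)
    E = ly_effect(state.LY, ext.K_L)

    dB -= ext.eta * E * state.B

    n_pers = n_persister_orders(params)
    dBP = np.empty(n_pers)
    for i in range(n_pers):
        entry = ext.g * E * state.B[i]
        exit_ = ext.h * state.BP[i]
        dBP[i] = entry - exit_
        dB[i] += exit_ - entry

    dLY = ly_production_rate(state, params, ext.v_L)
    return dr, dB, dP, dM, dLY, dBP
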