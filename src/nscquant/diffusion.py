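"""Closed-form diffusion of a secreted enzyme in brain extracellular space.

The free-solution diffusion coefficient D of a macromolecule is slowed
in tissue by the tortuosity lambda of the extracellular space:

    D* = D / lambda**2

For a non-depleting point source with first-order elimination at rate
k_e (= ln 2 / t_half), the steady-state concentration relative to the
source falls off exponentially with distance x:

    C/C0 = exp(-x * sqrt(k_e / D*))

Distances are in micrometres and rates in 1/s throughout; diffusion
coefficients are accepted in cm^2/s (the conventional unit) and
converted internally.  k_e has no universal value and must always be
supplied, directly or via a half-life.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiffusionParams",
    "effective_diffusion",
    "ke_from_half_life",
    "relative_concentration",
    "distance_for_fraction",
    "concentration_profile",
    "CE_D_FREE_CM2_S",
    "BRAIN_TORTUOSITY",
    "UM2_PER_CM2",
]

UM2_PER_CM2 = 1e8

#: Free-solution diffusion coefficient of carboxylesterase (~60 kDa).
CE_D_FREE_CM2_S = 4.3e-7
#: Tortuosity characteristic of high-molecular-weight solutes in brain.
BRAIN_TORTUOSITY = 2.25


def effective_diffusion(d_free_cm2_s: float, lambda_tortuosity: float) -> float:
    """Tortuosity-adjusted diffusion coefficient D* = D / lambda^2 (cm^2/s)."""
    if d_free_cm2_s <= 0:
        raise ValueError("free diffusion coefficient must be positive")
    if lambda_tortuosity < 1:
        raise ValueError("tortuosity < 1 is unphysical in tissue")
    return d_free_cm2_s / lambda_tortuosity**2


def ke_from_half_life(t_half_s: float) -> float:
    """First-order elimination rate k_e = ln(2) / t_half (1/s)."""
    if t_half_s <= 0:
        raise ValueError("half-life must be positive")
    return np.log(2) / t_half_s


def _decay_per_um(ke_per_s: float, d_star_cm2_s: float) -> float:
    if ke_per_s < 0:
        raise ValueError("elimination rate must be non-negative")
    if d_star_cm2_s <= 0:
        raise ValueError("effective diffusion coefficient must be positive")
    return np.sqrt(ke_per_s / (d_star_cm2_s * UM2_PER_CM2))


def relative_concentration(
    x_um: float | np.ndarray, ke_per_s: float, d_star_cm2_s: float
) -> float | np.ndarray:
    """Steady-state C/C0 at distance x (um) from a non-depleting source."""
    x = np.asarray(x_um, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-x * _decay_per_um(ke_per_s, d_star_cm2_s))
    return float(out) if out.ndim == 0 else out


def distance_for_fraction(
    fraction: float, ke_per_s: float, d_star_cm2_s: float
) -> float:
    """Distance (um) at which C/C0 falls to ``fraction`` (inverse relation)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if ke_per_s <= 0:
        raise ValueError("elimination rate must be positive for a finite distance")
    return float(-np.log(fraction) / _decay_per_um(ke_per_s, d_star_cm2_s))


@dataclass(frozen=True)
class DiffusionParams:
    """Bundle of diffusion parameters with derived quantities.

    Supply ``ke_per_s`` directly or via ``t_half_s``; neither is
    defaulted because elimination of a secreted enzyme is
    preparation-specific.
    """

    d_free_cm2_s: float = CE_D_FREE_CM2_S
    lambda_tortuosity: float = BRAIN_TORTUOSITY
    ke_per_s: float | None = None
    t_half_s: float | None = None

    def __post_init__(self) -> None:
        if self.ke_per_s is None and self.t_half_s is None:
            raise ValueError("supply ke_per_s or t_half_s")
        if self.ke_per_s is not None and self.t_half_s is not None:
            if not np.isclose(self.ke_per_s, ke_from_half_life(self.t_half_s)):
                raise ValueError("ke_per_s and t_half_s are inconsistent")

    @property
    def d_star_cm2_s(self) -> float:
        return effective_diffusion(self.d_free_cm2_s, self.lambda_tortuosity)

    @property
    def ke(self) -> float:
        if self.ke_per_s is not None:
            return self.ke_per_s
        return ke_from_half_life(self.t_half_s)


def concentration_profile(
    distances_um: np.ndarray | list[float], params: DiffusionParams
) -> pd.DataFrame:
    """Tabulated C/C0 over distances; columns distance_um, relative_concentration."""
    x = np.asarray(distances_um, dtype=float)
    rel = relative_concentration(x, params.ke, params.d_star_cm2_s)
    return pd.DataFrame({"distance_um": x, "relative_concentration": rel})
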