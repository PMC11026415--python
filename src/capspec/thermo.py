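"""Standard thermodynamics of ion-pair formation from equilibrium constants.

dG0 = -RT ln K; the two-temperature van't Hoff relation for dH0; dS0 from
the Gibbs-Helmholtz identity; and a linear fit of dG(T) = dH - T dS for
multi-temperature series.  Energies in kJ/mol, entropies in J/(K mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import R, BindingConstants

__all__ = [
    "ThermoTriple",
    "delta_g",
    "vant_hoff_enthalpy",
    "entropy",
    "linear_gibbs_fit",
    "thermo_from_two_temperatures",
]


@dataclass(frozen=True)
class ThermoTriple:
    """dG0 (kJ/mol), dH0 (kJ/mol), dS0 (J/K/mol) at a reference temperature."""

    dg0: float
    dh0: float
    ds0: float
    t_ref: float = 298.15

    def __post_init__(self) -> None:
        gap = self.dg0 - (self.dh0 - self.t_ref * self.ds0 / 1000.0)
        if abs(gap) > 1e-9:
            raise ValueError(
                f"inconsistent triple: dG - (dH - T dS) = {gap:g} kJ/mol"
            )


def delta_g(K: float, T: float) -> float:
    """Standard free energy of association, kJ/mol: dG0 = -R T ln K."""
    if not (K > 0 and math.isfinite(K)):
        raise ValueError(f"K must be positive and finite, got {K}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return -R * T * math.log(K) / 1000.0


def vant_hoff_enthalpy(k_a: float, t_a: float, k_b: float, t_b: float) -> float:
    """Two-point van't Hoff standard enthalpy, kJ/mol.

    dH0 = R ln(K_b/K_a) / (1/T_a - 1/T_b).  Equal constants at the two
    temperatures give exactly zero.
    """
    if t_a == t_b:
        raise ValueError("temperatures must differ for a van't Hoff slope")
    if k_a <= 0 or k_b <= 0:
        raise ValueError("equilibrium constants must be positive")
    return R * math.log(k_b / k_a) / (1.0 / t_a - 1.0 / t_b) / 1000.0


def entropy(dg0: float, dh0: float, T: float) -> float:
    """Standard entropy, J/(K mol): dS0 = 1000 (dH0 - dG0) / T."""
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    return 1000.0 * (dh0 - dg0) / T


def linear_gibbs_fit(temperatures, dg0_values) -> tuple[float, float]:
    """(dH0, dS0) from a least-squares line dG(T) = dH - T dS.

    With exactly two points this reproduces the van't Hoff + entropy
    composition algebraically.  Returns dH0 in kJ/mol, dS0 in J/(K mol).
    """
    T = np.asarray(temperatures, dtype=float)
    g = np.asarray(dg0_values, dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("need >= 2 distinct temperatures")
    slope, intercept = np.polyfit(T, g, 1)
    return float(intercept), float(-slope * 1000.0)


def thermo_from_two_temperatures(
    K_a: BindingConstants, K_b: BindingConstants
) -> dict[str, ThermoTriple]:
    """Full thermodynamic triples for the three ion pairs from constant sets
    at two temperatures, referenced to the first set's temperature."""
    t_a, t_b = K_a.temperature, K_b.temperature
    out = {}
    for name in ("k1", "k2", "k3"):
        ka, kb = getattr(K_a, name), getattr(K_b, name)
        dg = delta_g(ka, t_a)
        dh = vant_hoff_enthalpy(ka, t_a, kb, t_b)
        ds = entropy(dg, dh, t_a)
        out[name] = ThermoTriple(dg0=dg, dh0=dh, ds0=ds, t_ref=t_a)
    return out
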