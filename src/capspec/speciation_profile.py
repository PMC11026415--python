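"""Ion-pair speciation across pH: which calcium-phosphate pair dominates.

For a fixed solution composition the equilibrium is solved on a pH grid and
summarised two ways: the mole fraction of each ion pair among all pairs
(the conventional speciation diagram) and the fraction of total calcium
bound into pairs.  Comparing the revised constants with the reconstructed
historical ("legacy") set shows the headline consequence of the revision:
the neutral [CaHPO4]0 pair, not [CaPO4]-, dominates the near-neutral to
mildly basic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_core import _equilibrate_arrays
from .constants import AcidConstants, BindingConstants

__all__ = [
    "SpeciationProfile",
    "pair_speciation_vs_ph",
    "bound_fraction_vs_ph",
    "crossover_ph",
]

PAIR_NAMES = ("CaH2PO4+", "CaHPO4", "CaPO4-")


@dataclass
class SpeciationProfile:
    """Per-pH pair mole fractions (of total pairs) and bound-Ca fraction."""

    ph: np.ndarray
    pair_fractions: np.ndarray  # shape (3, n): CaH2PO4+, CaHPO4, CaPO4-
    bound_fraction: np.ndarray
    ionic_strength: np.ndarray
    total_ca: float
    total_p: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ph": self.ph,
                "f_cah2po4": self.pair_fractions[0],
                "f_cahpo4": self.pair_fractions[1],
                "f_capo4": self.pair_fractions[2],
                "bound_ca_fraction": self.bound_fraction,
                "ionic_strength": self.ionic_strength,
            }
        )

    def dominant_pair(self) -> np.ndarray:
        """Name of the majority pair at each grid point."""
        return np.asarray(PAIR_NAMES)[np.argmax(self.pair_fractions, axis=0)]

    def plot(self, ax=None, **kwargs):
        """Speciation diagram (requires matplotlib; optional dependency)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, frac in zip(PAIR_NAMES, self.pair_fractions):
            ax.plot(self.ph, frac, label=name, **kwargs)
        ax.set_xlabel("pH")
        ax.set_ylabel("mole fraction of total ion pairs")
        ax.legend()
        return ax


def pair_speciation_vs_ph(
    K: BindingConstants,
    acid: AcidConstants,
    total_ca: float = 5.0e-4,
    total_p: float = 1.0e-2,
    grid=None,
) -> SpeciationProfile:
    """Equilibrium speciation profile over a pH grid.

    ``total_ca`` / ``total_p`` are molar concentrations (the calculation
    runs in 1 L); the default 0.5 mM Ca in 10 mM phosphate corresponds to
    the early pre-nucleation regime of the titrations.  Pair mole fractions
    are normalised to the total amount of pairs, so at low pH a large
    [CaH2PO4]+ fraction does not imply a large absolute concentration.
    """
    if grid is None:
        grid = np.linspace(2.0, 12.0, 201)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 2.0 - 1e-9) or np.any(grid > 12.0 + 1e-9):
        raise ValueError("pH grid must lie within [2, 12]")
    if total_ca <= 0 or total_p <= 0:
        raise ValueError("totals must be positive")

    fracs = np.zeros((3, grid.size))
    bound = np.zeros(grid.size)
    I_out = np.zeros(grid.size)
    for j, ph in enumerate(grid):
        try:
            st = _equilibrate_arrays(total_ca, total_p, float(ph), 1.0, K, acid)
        except Exception as exc:  # tag the failing grid point
            raise RuntimeError(f"equilibration failed at pH {ph:g}: {exc}") from exc
        pairs = np.array([float(p) for p in st["n_pairs"]])
        tot = pairs.sum()
        fracs[:, j] = pairs / tot if tot > 0 else np.nan
        bound[j] = float(st["n_bound"]) / total_ca
        I_out[j] = float(st["ionic_strength"])
    return SpeciationProfile(
        ph=grid,
        pair_fractions=fracs,
        bound_fraction=bound,
        ionic_strength=I_out,
        total_ca=total_ca,
        total_p=total_p,
    )


def bound_fraction_vs_ph(
    K: BindingConstants,
    acid: AcidConstants,
    total_ca: float = 5.0e-4,
    total_p: float = 1.0e-2,
    grid=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(pH grid, fraction of total calcium bound into ion pairs)."""
    profile = pair_speciation_vs_ph(K, acid, total_ca, total_p, grid)
    return profile.ph, profile.bound_fraction


def crossover_ph(profile: SpeciationProfile, i: int, j: int) -> float:
    """pH where pair ``i`` hands over dominance to pair ``j`` (linear
    interpolation of the fraction difference's sign change); indices follow
    :data:`PAIR_NAMES`.  Raises if the two fractions never cross."""
    d = profile.pair_fractions[i] - profile.pair_fractions[j]
    sign = np.sign(d)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        raise ValueError(f"pairs {i} and {j} never cross on this grid")
    k = int(flips[0])
    x0, x1 = profile.ph[k], profile.ph[k + 1]
    y0, y1 = d[k], d[k + 1]
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
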