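"""pKa extraction from acid-base titration curves.

The classical potentiometric workflow: locate the equivalence points as the
largest maxima of the smoothed derivative dpH/dV, then read the pKa of each
deprotonation step at the half-equivalence point.  The half-equivalence
reading is corrected for free protons/hydroxide — without the correction the
first pKa of phosphoric acid (pKa1 ~ 2.6 at 0.01 M) is biased high by almost
0.3 units, because the acid is appreciably dissociated there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmax, savgol_filter

from .chem_core import davies_log10_gamma
from .constants import KW

__all__ = [
    "AcidTitrationCurve",
    "EquivalenceDetectionError",
    "find_equivalence_points",
    "pka_from_half_equivalence",
]


class EquivalenceDetectionError(RuntimeError):
    """Fewer equivalence points detected than expected."""


@dataclass
class AcidTitrationCurve:
    """Ordered (added base volume, pH) series with the dosing bookkeeping
    needed for the analysis (base strength, initial acid, co-dosed acid)."""

    volume_ml: np.ndarray
    ph: np.ndarray
    base_conc: float
    initial_acid_mol: float
    initial_volume_l: float = 0.050
    co_dose_rate: float = 0.0  # mol acid per L of dosed base (co-dosing)

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.volume_ml.size != self.ph.size:
            raise ValueError("volume and pH series must have equal length")
        if np.any(np.diff(self.volume_ml) <= 0):
            raise ValueError("volumes must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.volume_ml.size)

    def total_volume_l(self, v_ml) -> np.ndarray:
        v = np.asarray(v_ml, dtype=float) * 1e-3
        co = v if self.co_dose_rate > 0 else 0.0
        return self.initial_volume_l + v + co

    def acid_mol(self, v_ml) -> np.ndarray:
        return self.initial_acid_mol + self.co_dose_rate * np.asarray(v_ml) * 1e-3


def find_equivalence_points(
    curve: AcidTitrationCurve, n_expected: int, smooth_window: int = 5
) -> np.ndarray:
    """Equivalence volumes (mL) from the derivative of the titration curve.

    The derivative dpH/dV is smoothed with a local-quadratic
    (Savitzky-Golay) filter of the given odd window; the ``n_expected``
    largest local maxima are refined by parabolic interpolation and returned
    in volume order.
    """
    if n_expected not in (1, 2):
        raise ValueError(f"n_expected must be 1 or 2, got {n_expected}")
    if curve.n_points < 10:
        raise ValueError(f"need >= 10 points, got {curve.n_points}")
    if smooth_window % 2 == 0 or smooth_window < 3:
        raise ValueError("smooth_window must be odd and >= 3")
    v = curve.volume_ml
    deriv = np.gradient(curve.ph, v)
    deriv = savgol_filter(deriv, min(smooth_window, len(deriv) // 2 * 2 - 1), 2)
    idx = argrelmax(deriv, order=3)[0]
    idx = idx[(idx > 0) & (idx < v.size - 1)]
    if idx.size < n_expected:
        raise EquivalenceDetectionError(
            f"found {idx.size} derivative maxima, expected {n_expected}"
        )
    # n_expected tallest peaks, then volume order.
    top = idx[np.argsort(deriv[idx])[::-1][:n_expected]]
    top = np.sort(top)
    out = []
    for i in top:
        # parabolic vertex through (i-1, i, i+1) for sub-step resolution
        y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
        denom = y0 - 2 * y1 + y2
        offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        offset = float(np.clip(offset, -1.0, 1.0))
        if offset >= 0:
            out.append(v[i] + offset * (v[min(i + 1, v.size - 1)] - v[i]))
        else:
            out.append(v[i] + offset * (v[i] - v[i - 1]))
    return np.asarray(out)


def _proton_correction(ph: float, c_half: float, c_na: float) -> float:
    """log10([HA]/[A]) at the half-equivalence point (pKa = pH + this).

    [A] = c/2 + [H+] - [OH-], [HA] = c/2 - [H+] + [OH-].  The free-proton
    concentration is estimated from the electrode reading with a Davies
    activity coefficient at the locally estimated ionic strength
    (I ~ c_Na + c_H for the acid branch of the curve).
    """
    a_h = 10.0 ** -ph
    c_h = a_h
    for _ in range(30):
        I = max(c_na + c_h, 1e-12)
        g1 = 10.0 ** davies_log10_gamma(1, I)
        c_h_new = a_h / g1
        if abs(c_h_new - c_h) < 1e-15:
            c_h = c_h_new
            break
        c_h = c_h_new
    c_oh = KW / a_h / g1
    x = c_h - c_oh
    num = 0.5 * c_half - x
    den = 0.5 * c_half + x
    if num <= 0 or den <= 0:
        raise ValueError(
            "free-proton correction exceeds the buffer capacity at the "
            "half-equivalence point"
        )
    return float(np.log10(num / den))


def pka_from_half_equivalence(
    curve: AcidTitrationCurve, equivalence_volumes_ml: np.ndarray
) -> np.ndarray:
    """pKa estimates: pH at each half-equivalence point, proton-corrected.

    The half point of step j is where the dosed base equals (j - 1/2) times
    the acid present — for a plain titration that is the midpoint of
    successive equivalence volumes, while with acid co-dosing (the
    dilution-compensated protocols) the acid amount grows during the run and
    the half point must be solved in the amount domain:

        c_b v = (j - 1/2) (n0_j + r v),   n0_j = v_eq,j (c_b - j r) / j,

    with r the co-dose rate (mol acid per L base).  The pH there is
    interpolated piecewise-linearly in volume and corrected by
    log10([HA]/[A]) for the free protons.
    """
    eq = np.sort(np.asarray(equivalence_volumes_ml, dtype=float))
    v = curve.volume_ml
    c_b = curve.base_conc
    r = curve.co_dose_rate
    out = []
    for j, v_eq in enumerate(eq, start=1):
        n0_eff = v_eq * (c_b - j * r) / j  # per-mL amount, consistent units
        denom = c_b - (j - 0.5) * r
        if n0_eff <= 0 or denom <= 0:
            raise ValueError(
                f"equivalence volume {v_eq:.4g} mL inconsistent with the "
                "dosing bookkeeping"
            )
        v_half = (j - 0.5) * n0_eff / denom
        if v_half < v[0] or v_half > v[-1]:
            raise ValueError(
                f"half-equivalence volume {v_half:.4g} mL outside the data range"
            )
        ph_half = float(np.interp(v_half, v, curve.ph))
        V = float(curve.total_volume_l(v_half))
        c_t = float(curve.acid_mol(v_half)) / V
        c_na = curve.base_conc * v_half * 1e-3 / V
        out.append(ph_half + _proton_correction(ph_half, c_t, c_na))
    return np.asarray(out)
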