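"""Shared physical constants, domain dataclasses and named presets.

The two small value types defined here — :class:`AcidConstants` and
:class:`BindingConstants` — are the parameters of the whole analysis: the
acidity constants of phosphoric acid control which phosphate anion is
available at a given pH, and the three ion-association constants control how
strongly each anion binds a free calcium ion.  Both are expressed on the
activity scale (dimensionless, standard concentration c0 = 1 M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: Gas constant, J/(K mol).
R = 8.314

#: Ion product of water on the activity scale (25 degC value; the sub-percent
#: temperature dependence is neglected, see docs/methods.md).
KW = 1.0e-14

#: Standard concentration c0 = 1 M used to make activities dimensionless.
C_STANDARD = 1.0

#: Davies equation coefficient (log10 basis) and linear-term factor.
DAVIES_A = 0.5085
DAVIES_LINEAR = 0.3


@dataclass(frozen=True)
class AcidConstants:
    """Acidity constants of phosphoric acid at one temperature.

    ``pka1`` and ``pka2`` are conditional constants valid at the working ionic
    strength of the titration experiments (I ~ 0.015-0.03), where they were
    measured potentiometrically; ``pka3`` is the literature value on the
    activity scale (the third deprotonation is not accessible to the glass
    electrode).  When ``pka3_thermodynamic`` is true, routines that know the
    local ionic strength convert pKa3 to the matching conditional value via
    the Davies equation; at I = 0 no correction is applied.
    """

    pka1: float = 2.58
    pka2: float = 6.98
    pka3: float = 12.32
    temperature: float = 298.15
    pka3_thermodynamic: bool = True

    def __post_init__(self) -> None:
        vals = (self.pka1, self.pka2, self.pka3)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"pKa values must be finite, got {vals}")
        if not (self.pka1 < self.pka2 < self.pka3):
            raise ValueError(f"require pKa1 < pKa2 < pKa3, got {vals}")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class BindingConstants:
    """Activity-based 1:1 ion-association constants at one temperature.

    k1:  Ca2+ + H2PO4-  <=> [CaH2PO4]+
    k2:  Ca2+ + HPO42-  <=> [CaHPO4]0
    k3:  Ca2+ + PO43-   <=> [CaPO4]-

    A value of exactly zero switches the corresponding ion pair off, which is
    convenient for limiting-case checks.
    """

    k1: float
    k2: float
    k3: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name, v in (("k1", self.k1), ("k2", self.k2), ("k3", self.k3)):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)


# --------------------------------------------------------------------------
# Named presets
# --------------------------------------------------------------------------

#: Revised constants at 25 degC, the central experimental result.
REVISED_25C = BindingConstants(k1=4.5, k2=470.0, k3=50_000.0, temperature=298.15)

#: Best-fit constants at 37 degC (near-physiological temperature).
REVISED_37C = BindingConstants(k1=4.5, k2=480.0, k3=69_500.0, temperature=310.15)

#: Default acid constants (25 degC measurement set + literature pKa3).
DEFAULT_ACID = AcidConstants()


def legacy_constants(
    temperature: float = 298.15,
    ddg_k3_k2_kj: float = 21.4,
    base: BindingConstants | None = None,
) -> BindingConstants:
    """Synthetic reconstruction of the historical ("legacy") constant set.

    The historical third constant is anchored to the widely reported free
    energy gap of 21.4 kJ/mol between the second and third association steps:
    K3_legacy = K2 * exp(ddG / RT).  K1 and K2 keep the revised magnitudes.
    This is a reconstruction for comparison diagrams, not a literature-exact
    set; override ``base`` or the gap to explore alternatives.
    """
    if base is None:
        base = replace(REVISED_25C, temperature=temperature)
    k3 = base.k2 * math.exp(ddg_k3_k2_kj * 1000.0 / (R * temperature))
    return BindingConstants(k1=base.k1, k2=base.k2, k3=k3, temperature=temperature)


PRESETS = {
    "revised": REVISED_25C,
    "revised_37c": REVISED_37C,
}


def get_preset(name: str, temperature: float | None = None) -> BindingConstants:
    """Resolve a binding-constant preset by name (``revised``, ``revised_37c``
    or ``legacy``)."""
    if name == "legacy":
        return legacy_constants(temperature or 298.15)
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS) + ['legacy']}"
        ) from None
    if temperature is not None and temperature != preset.temperature:
        preset = replace(preset, temperature=temperature)
    return preset
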