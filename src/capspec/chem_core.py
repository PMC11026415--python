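"""Foundational solution chemistry for the calcium-phosphate system.

Implements phosphate acid-base speciation, ionic strength, Davies activity
coefficients and a self-consistent equilibration of the three 1:1
calcium-phosphate ion-pair equilibria at clamped pH:

    Ca2+ + H2PO4-  <=> [CaH2PO4]+      (K1)
    Ca2+ + HPO42-  <=> [CaHPO4]0       (K2)
    Ca2+ + PO43-   <=> [CaPO4]-        (K3)

All equilibrium constants are activity based; activities are made
dimensionless with c0 = 1 M.  The neutral pair has unit activity coefficient
(it carries no charge, and the Davies expression reduces to gamma = 1 at
z = 0).

Self-consistency: the activity coefficients depend on the ionic strength,
which itself depends on the speciation.  :func:`equilibrate` iterates the
I -> gamma -> speciation loop (damped fixed point) until the ionic strength
is stationary to 1e-10 relative, so the returned state satisfies mass
balance, charge balance and every mass-action law simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    DAVIES_A,
    DAVIES_LINEAR,
    KW,
    AcidConstants,
    BindingConstants,
)

__all__ = [
    "SPECIES_CHARGES",
    "IonInventory",
    "ActivitySet",
    "PhosphateFractions",
    "ConvergenceError",
    "phosphate_fractions",
    "ionic_strength",
    "davies_log10_gamma",
    "davies_gamma",
    "activities",
    "equilibrate",
]


#: Elementary charge of every species the inventory tracks.
SPECIES_CHARGES: dict[str, int] = {
    "na": +1,
    "cl": -1,
    "ca": +2,  # free calcium
    "h3po4": 0,
    "h2po4": -1,
    "hpo4": -2,
    "po4": -3,
    "cah2po4": +1,
    "cahpo4": 0,
    "capo4": -1,
    "h": +1,
    "oh": -1,
}

PHOSPHATE_SPECIES = ("h3po4", "h2po4", "hpo4", "po4")
PAIR_SPECIES = ("cah2po4", "cahpo4", "capo4")


class ConvergenceError(RuntimeError):
    """Raised when the self-consistency loop fails to converge."""

    def __init__(self, message: str, last_ionic_strength: float | None = None):
        super().__init__(message)
        self.last_ionic_strength = last_ionic_strength


@dataclass
class IonInventory:
    """Molar amounts (mol) of every tracked species plus the total volume (L).

    Produced by :func:`equilibrate`; can also be constructed directly to
    describe a background electrolyte (e.g. the NaCl content of an acidified
    titrant).  Amounts must be non-negative and the volume positive.
    """

    volume: float
    na: float = 0.0
    cl: float = 0.0
    ca: float = 0.0
    h3po4: float = 0.0
    h2po4: float = 0.0
    hpo4: float = 0.0
    po4: float = 0.0
    cah2po4: float = 0.0
    cahpo4: float = 0.0
    capo4: float = 0.0
    h: float = 0.0
    oh: float = 0.0

    def __post_init__(self) -> None:
        if not (self.volume > 0 and np.isfinite(self.volume)):
            raise ValueError(f"volume must be positive, got {self.volume}")
        for name in SPECIES_CHARGES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"amount of {name} must be finite and >= 0, got {v}")

    def amount(self, species: str) -> float:
        return float(getattr(self, species))

    def concentration(self, species: str) -> float:
        """Molar concentration of one species (mol/L)."""
        return self.amount(species) / self.volume

    def concentrations(self) -> dict[str, float]:
        return {s: self.concentration(s) for s in SPECIES_CHARGES}

    def total_calcium(self) -> float:
        return self.ca + self.cah2po4 + self.cahpo4 + self.capo4

    def total_phosphate(self) -> float:
        return (
            sum(self.amount(s) for s in PHOSPHATE_SPECIES)
            + self.cah2po4
            + self.cahpo4
            + self.capo4
        )

    def bound_calcium(self) -> float:
        return self.cah2po4 + self.cahpo4 + self.capo4

    def charge_imbalance(self) -> float:
        """Net charge concentration (mol charge / L); ~0 for equilibrated states."""
        return sum(
            z * self.concentration(s) for s, z in SPECIES_CHARGES.items()
        )


@dataclass
class ActivitySet:
    """Ionic strength, activity coefficients by |z| and per-species activities."""

    ionic_strength: float
    gamma: tuple[float, float, float, float]  # indexed by |z| = 0..3
    activities: dict[str, float] = field(default_factory=dict)

    def gamma_for(self, species: str) -> float:
        return self.gamma[abs(SPECIES_CHARGES[species])]


@dataclass
class PhosphateFractions:
    """Mole fractions of total (unbound) phosphate at a given pH."""

    f_h3po4: float
    f_h2po4: float
    f_hpo4: float
    f_po4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_h3po4, self.f_h2po4, self.f_hpo4, self.f_po4])


# --------------------------------------------------------------------------
# Activity coefficients
# --------------------------------------------------------------------------

def davies_log10_gamma(z: int, ionic_strength):
    """log10 of the Davies activity coefficient for charge z at ionic strength I.

    log10(gamma) = -0.5085 z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)
    """
    I = np.asarray(ionic_strength, dtype=float)
    if np.any(I < 0) or not np.all(np.isfinite(I)):
        raise ValueError(f"ionic strength must be finite and >= 0, got {ionic_strength}")
    s = np.sqrt(I)
    return -DAVIES_A * z * z * (s / (1.0 + s) - DAVIES_LINEAR * I)


def davies_gamma(z: int, ionic_strength):
    """Davies activity coefficient; exactly 1 for neutral species (z = 0)."""
    out = 10.0 ** davies_log10_gamma(z, ionic_strength)
    if np.ndim(ionic_strength) == 0:
        return float(out)
    return out


def _gamma_by_charge(I):
    """Activity coefficients for |z| = 0..3, stacked on axis 0."""
    return np.stack([np.ones_like(np.asarray(I, float))] + [
        10.0 ** davies_log10_gamma(z, I) for z in (1, 2, 3)
    ])


# --------------------------------------------------------------------------
# Acid-base speciation
# --------------------------------------------------------------------------

def _fraction_arrays(ph, acid: AcidConstants, ionic_strength=0.0):
    """Triprotic partition fractions (vectorised over pH / ionic strength)."""
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError(f"pH must be finite, got {ph}")
    if np.any(ph < 0.0) or np.any(ph > 14.0):
        raise ValueError(f"pH outside [0, 14]: {ph}")
    ka1 = 10.0 ** -acid.pka1
    ka2 = 10.0 ** -acid.pka2
    ka3 = 10.0 ** -acid.pka3
    I = np.asarray(ionic_strength, dtype=float)
    if acid.pka3_thermodynamic and np.any(I > 0):
        # pKa3 is on the activity scale; convert to the conditional constant at
        # the local ionic strength:  c_PO4/c_HPO4 = Ka3 * gamma2/gamma3 / a_H.
        g2 = 10.0 ** davies_log10_gamma(2, I)
        g3 = 10.0 ** davies_log10_gamma(3, I)
        ka3 = ka3 * g2 / g3
    h = 10.0 ** -ph
    d0 = h * h * h
    d1 = h * h * ka1
    d2 = h * ka1 * ka2
    d3 = ka1 * ka2 * ka3
    denom = d0 + d1 + d2 + d3
    return d0 / denom, d1 / denom, d2 / denom, d3 / denom


def phosphate_fractions(
    ph: float, acid: AcidConstants, ionic_strength: float = 0.0
) -> PhosphateFractions:
    """Closed-form mole fractions of H3PO4 / H2PO4- / HPO42- / PO43- at a pH.

    With the default ``ionic_strength = 0`` the partition uses the acid
    constants exactly as given (the convention in which the experimental
    pKa values were read off).  Passing the working ionic strength corrects
    the activity-scale pKa3 to its conditional value there, which matters
    above pH ~10.
    """
    f0, f1, f2, f3 = _fraction_arrays(ph, acid, ionic_strength)
    return PhosphateFractions(float(f0), float(f1), float(f2), float(f3))


# --------------------------------------------------------------------------
# Ionic strength and activities
# --------------------------------------------------------------------------

def ionic_strength(inv: IonInventory) -> float:
    """I = 1/2 sum_i z_i^2 c_i / c0 over every charged species tracked."""
    return 0.5 * sum(
        z * z * inv.concentration(s) for s, z in SPECIES_CHARGES.items() if z != 0
    )


def activities(inv: IonInventory, I: float | None = None) -> ActivitySet:
    """Per-species activities a_i = gamma(|z_i|, I) * c_i / c0.

    If ``I`` is omitted it is computed from the inventory itself.
    """
    if I is None:
        I = ionic_strength(inv)
    gam = tuple(float(g) for g in _gamma_by_charge(I))
    acts = {
        s: gam[abs(z)] * inv.concentration(s) for s, z in SPECIES_CHARGES.items()
    }
    return ActivitySet(ionic_strength=float(I), gamma=gam, activities=acts)


# --------------------------------------------------------------------------
# Self-consistent equilibration
# --------------------------------------------------------------------------

def _pair_weights(K: BindingConstants, gam, fracs):
    """Per-molar binding strengths w_i = K_i gamma_anion_i f_i / gamma_pair_i.

    gam is the gamma stack by |z|; fracs the phosphate fraction arrays.
    The total bound amount then satisfies
        n_b = (gamma_Ca * sum w_i / V) (n_Ca - n_b)(n_P - n_b).
    """
    _, f1, f2, f3 = fracs
    w1 = K.k1 * gam[1] * f1 / gam[1]  # [CaH2PO4]+ : anion z=1, pair z=1
    w2 = K.k2 * gam[2] * f2 / gam[0]  # [CaHPO4]0  : anion z=2, pair z=0
    w3 = K.k3 * gam[3] * f3 / gam[1]  # [CaPO4]-   : anion z=3, pair z=1
    return w1, w2, w3


def _solve_bound(total_ca, total_p, coeff):
    """Smaller (physical) root of  A x^2 - (A(Ca+P)+1) x + A Ca P = 0.

    coeff = A = gamma_Ca * sum(w) / V.  Numerically stable form; 0 when A = 0.
    """
    a = coeff
    b = a * (total_ca + total_p) + 1.0
    c = a * total_ca * total_p
    disc = b * b - 4.0 * a * c
    disc = np.maximum(disc, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.where(b > 0, 2.0 * c / (b + np.sqrt(disc)), 0.0)
    return np.minimum(root, np.minimum(total_ca, total_p))


def _equilibrate_arrays(
    total_ca,
    total_p,
    ph: float,
    volume,
    K: BindingConstants,
    acid: AcidConstants,
    na_background=0.0,
    cl_background=0.0,
    tol: float = 1e-10,
    damping: float = 0.5,
    max_iter: int = 400,
):
    """Vectorised equilibration core shared by the scalar API, the titration
    models and the fitting objective.

    Parameters are broadcastable arrays of total amounts (mol) and volumes
    (L) at a single clamped pH.  Returns a dict of arrays describing the
    converged state.  The Na+/Cl- content is the background plus whatever
    counter-ion the (implicit) counter-titration must have supplied to keep
    the solution electroneutral at the clamped pH.
    """
    total_ca, total_p, volume, na0, cl0 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float)
          for x in (total_ca, total_p, volume, na_background, cl_background))
    )
    if np.any(total_ca < 0) or np.any(total_p < 0):
        raise ValueError("total amounts must be >= 0")
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")

    a_h = 10.0 ** -ph
    # Initial ionic strength guess: ideal-solution speciation, no binding.
    f_ideal = _fraction_arrays(ph, acid, 0.0)
    cp = total_p / volume
    anion_charge = f_ideal[1] * cp + 2 * f_ideal[2] * cp + 3 * f_ideal[3] * cp
    cation = 2 * total_ca / volume + a_h
    oh_c0 = KW / a_h
    na_c = np.maximum(anion_charge + oh_c0 - cation + cl0 / volume, 0.0)
    I = 0.5 * (
        na_c + cl0 / volume + 4 * total_ca / volume
        + f_ideal[1] * cp + 4 * f_ideal[2] * cp + 9 * f_ideal[3] * cp
        + a_h + oh_c0
    )
    I = np.maximum(I, 1e-12)

    state = None
    for _ in range(max_iter):
        gam = _gamma_by_charge(I)
        fracs = _fraction_arrays(ph, acid, I)
        w1, w2, w3 = _pair_weights(K, gam, fracs)
        wsum = w1 + w2 + w3
        coeff = gam[2] * wsum / volume
        nb = _solve_bound(total_ca, total_p, coeff)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(wsum > 0, 1.0 / np.where(wsum > 0, wsum, 1.0), 0.0)
        n_pairs = (nb * w1 * share, nb * w2 * share, nb * w3 * share)
        p_free = total_p - nb
        ca_free = total_ca - nb

        c_h = a_h / gam[1]
        c_oh = KW / a_h / gam[1]
        c_phos = [f * p_free / volume for f in fracs]
        c_pairs = [n / volume for n in n_pairs]
        c_ca = ca_free / volume

        # Electroneutrality: top up with Na+ or Cl- (the counter-titration).
        net = (
            c_h + 2 * c_ca + c_pairs[0]
            + (na0 - cl0) / volume
            - c_phos[1] - 2 * c_phos[2] - 3 * c_phos[3]
            - c_pairs[2] - c_oh
        )
        c_na = na0 / volume + np.maximum(-net, 0.0)
        c_cl = cl0 / volume + np.maximum(net, 0.0)

        I_new = 0.5 * (
            c_na + c_cl + 4 * c_ca
            + c_phos[1] + 4 * c_phos[2] + 9 * c_phos[3]
            + c_pairs[0] + c_pairs[2]
            + c_h + c_oh
        )
        state = {
            "ionic_strength": I_new,
            "gamma": gam,
            "fractions": fracs,
            "n_bound": nb,
            "n_pairs": n_pairs,
            "n_ca_free": ca_free,
            "n_p_free": p_free,
            "c_ca_free": c_ca,
            "c_na": c_na,
            "c_cl": c_cl,
            "c_h": c_h,
            "c_oh": c_oh,
            "c_phosphates": c_phos,
        }
        err = np.abs(I_new - I) / np.maximum(I_new, 1e-12)
        if np.all((err < tol) | (I_new < 1e-12)):
            state["ionic_strength"] = I_new
            return state
        I = I + damping * (I_new - I)

    raise ConvergenceError(
        f"ionic-strength loop did not converge in {max_iter} iterations "
        f"(max relative change {float(np.max(err)):.3e})",
        last_ionic_strength=float(np.max(state["ionic_strength"])),
    )


def equilibrate(
    total_ca: float,
    total_p: float,
    background: IonInventory,
    ph: float,
    K: BindingConstants,
    acid: AcidConstants,
    tol: float = 1e-10,
    damping: float = 0.5,
    max_iter: int = 400,
) -> tuple[IonInventory, ActivitySet]:
    """Fully self-consistent equilibrium state at clamped pH.

    ``background`` supplies the solution volume and any Na+/Cl- already
    present (buffer counter-ions beyond charge balance, titrant chloride,
    added NaCl).  Additional Na+ or Cl- is included automatically so that the
    returned inventory is electroneutral — physically, the counter-titration
    that clamps the pH.

    Returns the equilibrated :class:`IonInventory` and the matching
    :class:`ActivitySet`.  Mass balances for calcium and phosphate hold to
    machine precision by construction; the ionic strength is converged to
    ``tol`` relative.
    """
    st = _equilibrate_arrays(
        total_ca,
        total_p,
        ph,
        background.volume,
        K,
        acid,
        na_background=background.na,
        cl_background=background.cl,
        tol=tol,
        damping=damping,
        max_iter=max_iter,
    )
    V = background.volume
    fr = st["fractions"]
    inv = IonInventory(
        volume=V,
        na=float(st["c_na"]) * V,
        cl=float(st["c_cl"]) * V,
        ca=float(st["n_ca_free"]),
        h3po4=float(fr[0] * st["n_p_free"]),
        h2po4=float(fr[1] * st["n_p_free"]),
        hpo4=float(fr[2] * st["n_p_free"]),
        po4=float(fr[3] * st["n_p_free"]),
        cah2po4=float(st["n_pairs"][0]),
        cahpo4=float(st["n_pairs"][1]),
        capo4=float(st["n_pairs"][2]),
        h=float(st["c_h"]) * V,
        oh=float(st["c_oh"]) * V,
    )
    aset = activities(inv, float(st["ionic_strength"]))
    return inv, aset
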