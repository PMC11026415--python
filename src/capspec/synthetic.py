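"""Synthetic titration data with the structure the analysis assumes.

Emulates the potentiometric protocol the binding analysis was designed for:
CaCl2 titrant dosed slowly into a stirred sodium-phosphate buffer at clamped
pH, with the free-calcium concentration read by an ion-selective electrode
(ISE) calibrated at matched ionic strength (so it reads concentration, not
activity).  Three deliberately modelled non-idealities:

* multiplicative log-normal ISE noise (the electrode response is log-linear
  in activity), default 1 % coefficient of variation;
* a hard ion-activity-product (IAP) cut-off that ends the curve at
  nucleation, mimicking the truncation of real curves just before solids
  form;
* an optional *premature phase separation* artifact: a local
  overconcentration of calcium at the dosing tip sequesters part of each
  dose into a separated phase once the locally enriched IAP exceeds a
  threshold, bending the curve downward from early on — the mechanism that
  historically inflated apparent ion association.

Acid-base titrations of phosphoric acid with NaOH (for the pKa workflow) are
generated from an exact proton/charge balance with Davies corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem_core import _equilibrate_arrays, _gamma_by_charge, davies_log10_gamma
from .constants import KW, AcidConstants, BindingConstants

__all__ = [
    "TitrationProtocol",
    "ArtifactModel",
    "AcidTitrationProtocol",
    "PKA_METHODS",
    "simulate_titration",
    "simulate_acid_titration",
]


@dataclass(frozen=True)
class TitrationProtocol:
    """Dosing protocol for a calcium-into-phosphate titration.

    Defaults reproduce the reference experiment: 0.005 M CaCl2 dosed at
    0.01 mL/min into 50.00 g of 0.010 M phosphate buffer at constant pH,
    with 0.1 M counter-titrant, in triplicate.  The dose step is the
    recorded sampling interval; the rate only sets the (physically
    irrelevant, quasi-static) time axis.
    """

    target_ph: float = 9.8
    buffer_mass_g: float = 50.0
    buffer_conc: float = 0.010
    titrant_conc: float = 0.005
    dose_rate_ml_min: float = 0.01
    dose_step_ml: float = 0.04
    n_steps: int = 50
    temperature: float = 298.15
    acidified_titrant: bool = True
    titrant_hcl_conc: float = 0.05
    counter_conc: float = 0.1
    replicates: int = 3
    density_g_ml: float = 1.000

    def __post_init__(self) -> None:
        for name in ("buffer_mass_g", "buffer_conc", "titrant_conc",
                     "dose_rate_ml_min", "dose_step_ml", "counter_conc",
                     "density_g_ml"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    @property
    def initial_volume_l(self) -> float:
        return self.buffer_mass_g / self.density_g_ml / 1000.0

    @property
    def n_p_total(self) -> float:
        return self.buffer_conc * self.initial_volume_l


@dataclass(frozen=True)
class ArtifactModel:
    """Dosing-tip premature-phase-separation model.

    When active, each dose sees a locally enriched ion-activity product
    IAP_local = enrichment * a_Ca * (a_HPO4 + a_PO4); above
    ``sequestration_iap`` a fraction

        f = fraction_cap * (1 - sequestration_iap / IAP_local)

    of that dose's calcium (and matching phosphate, 1:1) is removed to the
    separated phase before equilibration.  The progressive form makes the
    biased curve monotonically convex — it "bends early and proceeds directly
    to the plateau" instead of showing a linear regime.

    ``nucleation_iap`` is the bulk a_Ca * a_PO4 product at which the clean
    curve ends (nucleation of solids); it applies in every mode.
    """

    mode: str = "none"  # "none" | "premature_separation"
    enrichment: float = 50.0
    sequestration_iap: float = 2.5e-7
    fraction_cap: float = 0.6
    nucleation_iap: float = 2.0e-9

    def __post_init__(self) -> None:
        if self.mode not in ("none", "premature_separation"):
            raise ValueError(f"unknown artifact mode {self.mode!r}")
        if not 0.0 <= self.fraction_cap <= 1.0:
            raise ValueError("fraction_cap must be in [0, 1]")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if self.sequestration_iap <= 0 or self.nucleation_iap <= 0:
            raise ValueError("IAP thresholds must be positive")


def _noise_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-preserving multiplicative log-normal factors with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n)) / math.sqrt(1.0 + cv * cv)


def _chemistry_trajectory(
    protocol: TitrationProtocol,
    K: BindingConstants,
    acid: AcidConstants,
    artifact: ArtifactModel,
    nucleation_cutoff: float,
):
    """Noise-free equilibrium trajectory along the dosing schedule.

    Returns per-step arrays (possibly truncated at the nucleation cut-off)
    plus the sequestration bookkeeping.  Counter-titrant volume is included
    by a two-pass lag: the stoichiometric Na+/Cl- demand of step k updates
    the volume used from step k on (the demand is <1 % of the dose volume,
    so one refinement pass suffices).
    """
    V0 = protocol.initial_volume_l
    n_p0 = protocol.n_p_total
    ph = protocol.target_ph
    steps = protocol.n_steps
    v_tit = np.arange(1, steps + 1) * protocol.dose_step_ml * 1e-3  # L
    dosed = protocol.titrant_conc * v_tit  # cumulative mol Ca
    hcl = protocol.titrant_hcl_conc * v_tit if protocol.acidified_titrant else np.zeros(steps)
    # Explicit background: titrant chloride (+ neutralised HCl -> NaCl).
    cl_bg = 2.0 * dosed + hcl
    na_bg = hcl.copy()

    if steps == 0:
        empty = np.zeros(0)
        return dict(added=empty, free_conc=empty, volume=empty, na=empty,
                    cl=empty, seq_ca=empty, seq_p=empty, iap=empty,
                    bound=empty)

    # Baseline counter-ion content of the plain buffer (no dosing volume).
    base = _equilibrate_arrays(0.0, n_p0, ph, V0, K, acid)
    na_base = float(base["c_na"]) * V0
    cl_base = float(base["c_cl"]) * V0

    def counter_volume(c_na, c_cl, V, na_explicit, cl_explicit):
        extra = (c_na * V - na_explicit - na_base) + (c_cl * V - cl_explicit - cl_base)
        return np.maximum(extra, 0.0) / protocol.counter_conc

    sequential = artifact.mode == "premature_separation"
    seq_ca = np.zeros(steps)
    seq_p = np.zeros(steps)

    if not sequential:
        V = V0 + v_tit
        st = _equilibrate_arrays(dosed, n_p0, ph, V, K, acid,
                                 na_background=na_bg, cl_background=cl_bg)
        vc = counter_volume(st["c_na"], st["c_cl"], V, na_bg, cl_bg)
        # counter-titrant demand acts from the next recorded point (same
        # one-step lag as the sequential artifact path)
        V = V0 + v_tit + np.concatenate([[0.0], vc[:-1]])
        st = _equilibrate_arrays(dosed, n_p0, ph, V, K, acid,
                                 na_background=na_bg, cl_background=cl_bg)
        gam = st["gamma"]
        fr = st["fractions"]
        a_ca = gam[2] * st["c_ca_free"]
        a_po4 = gam[3] * st["c_phosphates"][3]
        iap = a_ca * a_po4
        free_conc = st["c_ca_free"]
        na = st["c_na"] * V
        cl = st["c_cl"] * V
        bound = np.asarray(st["n_bound"])
    else:
        V = np.empty(steps)
        free_conc = np.empty(steps)
        iap = np.empty(steps)
        na = np.empty(steps)
        cl = np.empty(steps)
        bound = np.empty(steps)
        prev_iap_local = 0.0
        cum_seq = 0.0
        v_counter = 0.0
        for k in range(steps):
            delta = protocol.titrant_conc * protocol.dose_step_ml * 1e-3
            if prev_iap_local > artifact.sequestration_iap:
                f = artifact.fraction_cap * (
                    1.0 - artifact.sequestration_iap / prev_iap_local
                )
                cum_seq += f * delta
            seq_ca[k] = cum_seq
            seq_p[k] = cum_seq
            Vk = V0 + v_tit[k] + v_counter
            st = _equilibrate_arrays(
                dosed[k] - cum_seq, n_p0 - cum_seq, ph, Vk, K, acid,
                na_background=na_bg[k], cl_background=cl_bg[k],
            )
            v_counter = float(
                counter_volume(st["c_na"], st["c_cl"], Vk, na_bg[k], cl_bg[k])
            )
            gam = st["gamma"]
            a_ca = float(gam[2] * st["c_ca_free"])
            a_hpo4 = float(gam[2] * st["c_phosphates"][2])
            a_po4 = float(gam[3] * st["c_phosphates"][3])
            prev_iap_local = artifact.enrichment * a_ca * (a_hpo4 + a_po4)
            V[k] = Vk
            free_conc[k] = float(st["c_ca_free"])
            iap[k] = a_ca * a_po4
            na[k] = float(st["c_na"]) * Vk
            cl[k] = float(st["c_cl"]) * Vk
            bound[k] = float(st["n_bound"])

    keep = steps
    exceeded = np.nonzero(iap >= nucleation_cutoff)[0]
    if exceeded.size:
        keep = int(exceeded[0])  # truncate just before nucleation
    sl = slice(0, keep)
    return dict(
        added=dosed[sl], free_conc=np.asarray(free_conc)[sl],
        volume=np.asarray(V)[sl],
        na=np.asarray(na)[sl], cl=np.asarray(cl)[sl],
        seq_ca=seq_ca[sl], seq_p=seq_p[sl], iap=np.asarray(iap)[sl],
        bound=np.asarray(bound)[sl],
    )


def simulate_titration(
    protocol: TitrationProtocol,
    K: BindingConstants,
    acid: AcidConstants,
    noise_cv: float = 0.01,
    artifact: ArtifactModel | None = None,
    seed: int = 0,
    nucleation_cutoff: float | None = None,
):
    """Generate replicate titration curves for one protocol.

    Chemistry is deterministic given the protocol; replicates differ only in
    the multiplicative ISE noise (independent streams spawned from ``seed``).
    Readings are clipped at the zero-binding line, which the calibrated
    electrode cannot exceed.  Returns a list of
    :class:`~capspec.titration_model.TitrationCurve`.
    """
    from .titration_model import TitrationCurve  # circular-import guard

    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if artifact is None:
        artifact = ArtifactModel(mode="none")
    if nucleation_cutoff is None:
        nucleation_cutoff = artifact.nucleation_iap

    traj = _chemistry_trajectory(protocol, K, acid, artifact, nucleation_cutoff)
    n = traj["added"].size
    no_binding = np.divide(
        traj["added"], traj["volume"], out=np.zeros(n), where=traj["volume"] > 0
    )
    curves = []
    for r in range(protocol.replicates):
        rng = np.random.default_rng([abs(int(seed)), r])
        reading = traj["free_conc"] * _noise_factors(rng, n, noise_cv)
        reading = np.minimum(reading, no_binding)
        curve = TitrationCurve(
            added_ca=traj["added"].copy(),
            free_ca=reading,
            volume=traj["volume"].copy(),
            ph=protocol.target_ph,
            temperature=protocol.temperature,
            replicate=f"r{r + 1}",
            n_p_total=protocol.n_p_total,
            na_background=traj["na"].copy(),
            cl_background=traj["cl"].copy(),
        )
        curve.meta = {
            "seed": int(seed),
            "replicate_index": r,
            "noise_cv": noise_cv,
            "artifact_mode": artifact.mode,
            "sequestered_ca_mol": traj["seq_ca"].copy(),
            "sequestered_p_mol": traj["seq_p"].copy(),
            "iap": traj["iap"].copy(),
            "bound_ca_mol": traj["bound"].copy(),
            "free_ca_mol": (traj["free_conc"] * traj["volume"]).copy(),
        }
        curves.append(curve)
    return curves


# --------------------------------------------------------------------------
# Acid-base titrations (pKa workflow)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcidTitrationProtocol:
    """NaOH-into-phosphoric-acid titration protocol.

    ``co_dose_acid_conc`` > 0 reproduces the dilution-compensated variants:
    a second burette adds that concentration of phosphoric acid at the same
    volumetric rate as the base.
    """

    acid_conc: float = 0.010
    initial_volume_l: float = 0.050
    base_conc: float = 0.1
    dose_step_ml: float = 0.02
    n_steps: int = 600
    co_dose_acid_conc: float = 0.0
    added_nacl: float = 0.0  # mol/L in the initial solution
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.acid_conc <= 0 or self.base_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.initial_volume_l <= 0 or self.dose_step_ml <= 0:
            raise ValueError("volumes must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def initial_acid_mol(self) -> float:
        return self.acid_conc * self.initial_volume_l


#: The six dosing-protocol presets of the pKa study: base strength, sampling
#: interval and (methods 5/6) dilution compensation by acid co-dosing.
PKA_METHODS: dict[int, AcidTitrationProtocol] = {
    1: AcidTitrationProtocol(base_conc=0.1, dose_step_ml=0.02, n_steps=600),
    2: AcidTitrationProtocol(base_conc=0.1, dose_step_ml=0.05, n_steps=240),
    3: AcidTitrationProtocol(base_conc=1.0, dose_step_ml=0.002, n_steps=600),
    4: AcidTitrationProtocol(base_conc=1.0, dose_step_ml=0.005, n_steps=240),
    # Co-dosing 0.020 M acid at the base's rate shifts the equivalences to
    # n0/(c_base - co) and 2 n0/(c_base - 2 co): longer schedules needed.
    5: AcidTitrationProtocol(base_conc=0.1, dose_step_ml=0.02, n_steps=950,
                             co_dose_acid_conc=0.020),
    6: AcidTitrationProtocol(base_conc=1.0, dose_step_ml=0.002, n_steps=650,
                             co_dose_acid_conc=0.020),
}


def _effective_pkas(acid: AcidConstants, I, i_ref: float):
    """Conditional pKa set at ionic strength I, anchored at the reference
    ionic strength where the constants were measured.

    For deprotonation step j (product anion charge j) the conditional
    constant shifts as Ka_j(I) = Ka_j(i_ref) * [g_{j-1}/g_j](I) /
    [g_{j-1}/g_j](i_ref), i.e. pKa decreases with increasing I.
    """
    out = []
    for j, pka in enumerate((acid.pka1, acid.pka2, acid.pka3), start=1):
        d_i = davies_log10_gamma(j - 1, I) - davies_log10_gamma(j, I)
        d_ref = davies_log10_gamma(j - 1, i_ref) - davies_log10_gamma(j, i_ref)
        out.append(pka - (d_i - d_ref))
    return out


def _solve_ph_grid(c_na, c_p, c_extra_ion, acid: AcidConstants,
                   ionic_strength_effects: bool, i_ref: float):
    """Vectorised pH from the exact charge balance, self-consistent in I.

    c_na, c_p: sodium / total phosphate concentrations per dose point;
    c_extra_ion: inert 1:1 salt concentration (counts twice in I).
    The electrode reading is -log10(gamma1 * c_H).
    """
    shape = np.broadcast(c_na, c_p).shape
    I = np.full(shape, max(i_ref, 1e-4))
    ph = None
    for _ in range(60):
        g1 = 10.0 ** davies_log10_gamma(1, I)
        if ionic_strength_effects:
            pk1, pk2, pk3 = _effective_pkas(acid, I, i_ref)
        else:
            pk1, pk2, pk3 = acid.pka1, acid.pka2, acid.pka3
        ka1, ka2, ka3 = 10.0 ** -np.asarray(pk1), 10.0 ** -np.asarray(pk2), 10.0 ** -np.asarray(pk3)
        kw_c = KW / (g1 * g1)

        def fractions_q(c_h):
            # mixed-constant convention: Ka = a_H c_A / c_HA with a_H = g1 c_h
            a_h = g1 * c_h
            d0 = a_h**3
            d1 = a_h**2 * ka1
            d2 = a_h * ka1 * ka2
            d3 = ka1 * ka2 * ka3
            den = d0 + d1 + d2 + d3
            return (d1 + 2 * d2 + 3 * d3) / den, (d1, d2, d3, den)

        def balance(log_ch):
            c_h = 10.0 ** log_ch
            q, _ = fractions_q(c_h)
            return c_na + c_h - kw_c / c_h - q * c_p

        lo = np.full(shape, -14.0)
        hi = np.full(shape, 0.0)
        for _ in range(80):  # bisection: balance is increasing in c_h
            mid = 0.5 * (lo + hi)
            g = balance(mid)
            hi = np.where(g > 0, mid, hi)
            lo = np.where(g > 0, lo, mid)
        c_h = 10.0 ** (0.5 * (lo + hi))
        q, (d1, d2, d3, den) = fractions_q(c_h)
        c_oh = kw_c / c_h
        f1, f2, f3 = d1 / den, d2 / den, d3 / den
        I_new = 0.5 * (
            c_na + c_h + c_oh + 2.0 * c_extra_ion
            + (f1 + 4 * f2 + 9 * f3) * c_p
        )
        ph = -np.log10(g1 * c_h)
        if np.max(np.abs(I_new - I) / np.maximum(I_new, 1e-12)) < 1e-10:
            return ph
        I = 0.5 * (I + I_new)
    return ph


def simulate_acid_titration(
    acid: AcidConstants,
    protocol: AcidTitrationProtocol | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ionic_strength_effects: bool = False,
    i_ref: float = 0.0225,
):
    """One NaOH-into-H3PO4 titration curve from exact charge balance.

    ``ionic_strength_effects=True`` evolves the conditional acidity
    constants with the local ionic strength (Davies), anchored at ``i_ref``
    — the mid-point of the window where the reference constants were
    measured; the default holds them fixed, matching an experiment whose
    ionic strength stays inside that window.
    """
    from .pka_analysis import AcidTitrationCurve  # circular-import guard

    if protocol is None:
        protocol = AcidTitrationProtocol()
    v = np.arange(1, protocol.n_steps + 1) * protocol.dose_step_ml * 1e-3  # L
    v = np.concatenate([[0.0], v])
    co = protocol.co_dose_acid_conc
    V = protocol.initial_volume_l + v + (v if co > 0 else 0.0)
    n_na = protocol.base_conc * v
    n_p = protocol.initial_acid_mol + co * v
    c_extra = protocol.added_nacl * protocol.initial_volume_l / V
    ph = _solve_ph_grid(n_na / V, n_p / V, c_extra, acid,
                        ionic_strength_effects, i_ref)
    if noise_sigma > 0:
        rng = np.random.default_rng([abs(int(seed)), 977])
        ph = ph + noise_sigma * rng.standard_normal(ph.shape)
    return AcidTitrationCurve(
        volume_ml=v * 1e3,
        ph=np.asarray(ph),
        base_conc=protocol.base_conc,
        initial_acid_mol=protocol.initial_acid_mol,
        initial_volume_l=protocol.initial_volume_l,
        co_dose_rate=co,
    )
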