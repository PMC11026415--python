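"""The two ion-pairing models used to analyse calcium-into-phosphate titrations.

Direct Calculation
    Uses the *measured* free-calcium concentration: the experimentally bound
    calcium fixes the free-phosphate pool, anion activities follow from the
    pH partition, and the free-calcium activity is the algebraically exact
    solution of the resulting mole balance,

        a_Ca = gamma_Ca (n_added / V) / (1 + gamma_Ca S),
        S    = sum_i K_i a_anion_i / gamma_pair_i.

Predictive Calculation
    Uses only the dosed amounts: the three coupled mass-action relations for
    the pair amounts are solved simultaneously (bounded multivariate
    root-finding), giving the full solution composition with no measured
    input beyond the clamped pH.

Both models share the Davies activity machinery of :mod:`capspec.chem_core`;
on noise-free data they coincide pointwise, which is used as a standing
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .chem_core import (
    ActivitySet,
    ConvergenceError,
    _equilibrate_arrays,
    _fraction_arrays,
    _gamma_by_charge,
)
from .constants import KW, AcidConstants, BindingConstants

__all__ = [
    "TitrationCurve",
    "ModelPrediction",
    "SlopeFit",
    "InconsistentMeasurementError",
    "EmptyPrenucleationRegime",
    "direct_free_calcium",
    "predictive_solve",
    "predict_curve",
    "prenucleation_slope",
    "truncate_prenucleation",
]


class InconsistentMeasurementError(ValueError):
    """Measured free calcium incompatible with the dosed amounts."""


class EmptyPrenucleationRegime(RuntimeError):
    """No linear pre-nucleation prefix could be identified."""


@dataclass
class TitrationCurve:
    """One calcium-into-phosphate dosing series at fixed pH and temperature.

    added_ca
        Cumulative dosed calcium (mol), strictly increasing.
    free_ca
        Measured (or simulated) free-calcium concentration (mol/L).
    volume
        Total solution volume at each point (L), non-decreasing.
    n_p_total
        Total phosphate in the vessel (mol); constant along the titration.
    na_background / cl_background
        Sodium / chloride inventory per point (mol) from buffer, acidified
        titrant and counter-titration, used for ionic-strength bookkeeping.
    """

    added_ca: np.ndarray
    free_ca: np.ndarray
    volume: np.ndarray
    ph: float
    temperature: float = 298.15
    replicate: str = "r1"
    n_p_total: float = 5.0e-4
    na_background: np.ndarray | None = None
    cl_background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.added_ca = np.asarray(self.added_ca, dtype=float)
        self.free_ca = np.asarray(self.free_ca, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.added_ca.size
        if self.free_ca.size != n or self.volume.size != n:
            raise ValueError("added_ca, free_ca and volume must have equal length")
        if self.na_background is None:
            self.na_background = np.zeros(n)
        if self.cl_background is None:
            self.cl_background = np.zeros(n)
        self.na_background = np.asarray(self.na_background, dtype=float)
        self.cl_background = np.asarray(self.cl_background, dtype=float)
        if n == 0:
            return
        if np.any(np.diff(self.added_ca) <= 0):
            raise ValueError("added_ca must be strictly increasing")
        if np.any(np.diff(self.volume) < -1e-15):
            raise ValueError("volume must be non-decreasing")
        if np.any(self.volume <= 0):
            raise ValueError("volume must be positive")
        slack = 1e-9 * np.maximum(self.added_ca, 1e-30)
        if np.any(self.free_ca * self.volume > self.added_ca + slack):
            raise ValueError(
                "measured free calcium exceeds the added amount (zero-binding line)"
            )

    @property
    def n_points(self) -> int:
        return int(self.added_ca.size)

    def free_amount(self) -> np.ndarray:
        """Free calcium as an amount (mol)."""
        return self.free_ca * self.volume

    def bound_amount(self) -> np.ndarray:
        return self.added_ca - self.free_amount()

    def head(self, n: int) -> "TitrationCurve":
        """First ``n`` points as a new curve."""
        return replace(
            self,
            added_ca=self.added_ca[:n].copy(),
            free_ca=self.free_ca[:n].copy(),
            volume=self.volume[:n].copy(),
            na_background=self.na_background[:n].copy(),
            cl_background=self.cl_background[:n].copy(),
        )


@dataclass
class ModelPrediction:
    """Per-point model output for one curve (or one point)."""

    free_ca_activity: np.ndarray
    free_ca_conc: np.ndarray
    n_pairs: np.ndarray  # shape (3, n): [CaH2PO4]+, [CaHPO4]0, [CaPO4]-
    ionic_strength: np.ndarray

    @property
    def n_bound(self) -> np.ndarray:
        return self.n_pairs.sum(axis=0)


# --------------------------------------------------------------------------
# Direct Calculation
# --------------------------------------------------------------------------

def direct_free_calcium(
    curve: TitrationCurve,
    K: BindingConstants,
    acid: AcidConstants,
    tol: float = 1e-10,
    max_iter: int = 400,
) -> ModelPrediction:
    """Predicted free-calcium activity from the measured bound calcium.

    Vectorised over the whole curve.  The experimentally bound amount
    (added - measured free) fixes the free-phosphate pool; the activity
    coefficients are made self-consistent with the ionic strength of the
    *measured* composition; the free-calcium activity is then the exact
    closed-form solution of the mole balance.
    """
    added = curve.added_ca
    V = curve.volume
    bound = curve.bound_amount()
    if np.any(bound < -1e-9 * np.maximum(added, 1e-30)):
        raise InconsistentMeasurementError("measured free calcium exceeds added")
    bound = np.maximum(bound, 0.0)
    p_free = curve.n_p_total - bound
    if np.any(p_free < 0):
        raise InconsistentMeasurementError(
            "measured bound calcium exceeds the total phosphate"
        )

    a_h = 10.0 ** -curve.ph
    I = np.full(added.shape, 0.03)
    err = np.inf
    for _ in range(max_iter):
        gam = _gamma_by_charge(I)
        fr = _fraction_arrays(curve.ph, acid, I)
        a_an = (gam[1] * fr[1], gam[2] * fr[2], gam[3] * fr[3])
        a_an = tuple(a * p_free / V for a in a_an)
        S = K.k1 * a_an[0] / gam[1] + K.k2 * a_an[1] / gam[0] + K.k3 * a_an[2] / gam[1]
        a_ca = gam[2] * (added / V) / (1.0 + gam[2] * S)
        # Pair split of the measured bound amount for the ionic strength.
        w = np.stack([K.k1 * a_an[0] / gam[1], K.k2 * a_an[1] / gam[0],
                      K.k3 * a_an[2] / gam[1]])
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            split = np.where(wsum > 0, w / np.where(wsum > 0, wsum, 1.0), 0.0)
        n_pairs = split * bound
        c_h = a_h / gam[1]
        c_oh = KW / a_h / gam[1]
        c_ca_meas = curve.free_ca
        c_p = [f * p_free / V for f in fr]
        net = (
            c_h + 2 * c_ca_meas + n_pairs[0] / V
            + (curve.na_background - curve.cl_background) / V
            - c_p[1] - 2 * c_p[2] - 3 * c_p[3] - n_pairs[2] / V - c_oh
        )
        c_na = curve.na_background / V + np.maximum(-net, 0.0)
        c_cl = curve.cl_background / V + np.maximum(net, 0.0)
        I_new = 0.5 * (
            c_na + c_cl + 4 * c_ca_meas
            + c_p[1] + 4 * c_p[2] + 9 * c_p[3]
            + (n_pairs[0] + n_pairs[2]) / V + c_h + c_oh
        )
        err = np.max(np.abs(I_new - I) / np.maximum(I_new, 1e-12))
        if err < tol:
            I = I_new
            break
        I = I + 0.5 * (I_new - I)
    else:
        raise ConvergenceError(
            f"direct-model ionic strength did not converge ({err:.2e})",
            last_ionic_strength=float(np.max(I)),
        )

    # Model pair amounts from the predicted activity (Eq. of mass action).
    gam = _gamma_by_charge(I)
    fr = _fraction_arrays(curve.ph, acid, I)
    a_an = (gam[1] * fr[1] * p_free / V, gam[2] * fr[2] * p_free / V,
            gam[3] * fr[3] * p_free / V)
    n_pairs_model = np.stack([
        K.k1 * a_ca * a_an[0] / gam[1] * V,
        K.k2 * a_ca * a_an[1] / gam[0] * V,
        K.k3 * a_ca * a_an[2] / gam[1] * V,
    ])
    return ModelPrediction(
        free_ca_activity=a_ca,
        free_ca_conc=a_ca / gam[2],
        n_pairs=n_pairs_model,
        ionic_strength=I,
    )


# --------------------------------------------------------------------------
# Predictive Calculation
# --------------------------------------------------------------------------

def _predictive_residuals(n_pairs, n_ca, n_p, V, kvals, g_an, g_pair, g_ca, fr):
    """Relative residuals of the three mass-action relations,
    gamma_pair n_i V = K_i gamma_Ca gamma_an,i f_i (n_Ca - n_b)(n_P - n_b)."""
    nb = n_pairs.sum()
    ca_free = n_ca - nb
    p_free = n_p - nb
    res = np.empty(3)
    for i in range(3):
        if kvals[i] == 0.0:
            res[i] = n_pairs[i] / max(n_ca, n_p, 1e-300)
            continue
        lhs = g_pair[i] * n_pairs[i] * V
        rhs = kvals[i] * g_ca * g_an[i] * fr[i] * ca_free * p_free
        res[i] = (lhs - rhs) / max(abs(lhs), abs(rhs), 1e-300)
    return res


def predictive_solve(
    n_ca_added: float,
    n_p_total: float,
    ph: float,
    volume: float,
    K: BindingConstants,
    acid: AcidConstants,
    gammas: ActivitySet,
    tol: float = 1e-10,
) -> ModelPrediction:
    """Solve the three coupled mass-action relations for the pair amounts.

    Activity coefficients are frozen at the supplied :class:`ActivitySet`
    (callers refresh them against the evolving ionic strength; see
    :func:`predict_curve`).  The solution is constrained to the physical box
    0 <= n_i, sum n_i <= min(n_Ca, n_P); deterministic multi-starts guard
    against convergence to unphysical roots of the cubic-like system.
    """
    if n_ca_added < 0 or n_p_total < 0:
        raise ValueError("amounts must be >= 0")
    I = gammas.ionic_strength
    gam = gammas.gamma
    fr = _fraction_arrays(ph, acid, I)
    kvals = K.as_tuple()
    g_an = (gam[1], gam[2], gam[3])
    g_pair = (gam[1], gam[0], gam[1])
    g_ca = gam[2]
    f_an = (fr[1], fr[2], fr[3])
    lim = min(n_ca_added, n_p_total)

    if lim == 0.0 or all(k == 0 for k in kvals):
        c_free = n_ca_added / volume
        return ModelPrediction(
            free_ca_activity=np.asarray(g_ca * c_free),
            free_ca_conc=np.asarray(c_free),
            n_pairs=np.zeros(3),
            ionic_strength=np.asarray(I),
        )

    scale = lim * max(volume, lim)

    def raw(n_pairs):
        nb = n_pairs.sum()
        lhs = np.array([g_pair[i] * n_pairs[i] * volume for i in range(3)])
        rhs = np.array([
            kvals[i] * g_ca * g_an[i] * f_an[i]
            * (n_ca_added - nb) * (n_p_total - nb)
            for i in range(3)
        ])
        return lhs, rhs

    def fun(y):
        lhs, rhs = raw(y * lim)
        return (lhs - rhs) / scale

    def jac_raw(n_pairs):
        nb = n_pairs.sum()
        J = np.empty((3, 3))
        for i in range(3):
            dr = (
                kvals[i] * g_ca * g_an[i] * f_an[i]
                * ((n_ca_added - nb) + (n_p_total - nb))
            )
            for j in range(3):
                J[i, j] = (g_pair[i] * volume if i == j else 0.0) + dr
        return J

    def rel_residual(n_pairs) -> float:
        lhs, rhs = raw(n_pairs)
        out = 0.0
        for i in range(3):
            denom = max(abs(lhs[i]), abs(rhs[i]), 1e-300)
            out = max(out, abs(lhs[i] - rhs[i]) / denom)
        return out

    starts = [np.full(3, 0.1 / 3.0)]
    # 8 deterministic fall-back starts spanning the physical box.
    for frac in (0.01, 0.3, 0.6, 0.9):
        starts.append(np.full(3, frac / 3.0))
    starts.append(np.array([0.5, 0.25, 0.25]) * 0.8)
    starts.append(np.array([0.25, 0.5, 0.25]) * 0.8)
    starts.append(np.array([0.25, 0.25, 0.5]) * 0.8)
    starts.append(np.full(3, 1e-6))

    best = None
    for y0 in starts:
        sol = optimize.least_squares(
            fun, y0, bounds=(np.zeros(3), np.ones(3)), method="trf",
        )
        n = np.clip(sol.x, 0.0, 1.0) * lim
        # Newton polish on the raw system (quadratic convergence near the
        # root; the bounded solve above only needs to land in its basin).
        for _ in range(60):
            lhs, rhs = raw(n)
            F = lhs - rhs
            try:
                step = np.linalg.solve(jac_raw(n), -F)
            except np.linalg.LinAlgError:
                break
            n_new = n + step
            nb_new = n_new.sum()
            if np.any(n_new < 0) or nb_new > lim:
                # damped step back into the physical box
                alpha = 1.0
                for _ in range(50):
                    alpha *= 0.5
                    n_new = n + alpha * step
                    if np.all(n_new >= 0) and n_new.sum() <= lim:
                        break
            n = n_new
            if rel_residual(n) < 0.1 * tol:
                break
        resid = rel_residual(n)
        physical = np.all(n >= -1e-30) and n.sum() <= lim * (1 + 1e-9)
        if physical and (best is None or resid < best[0]):
            best = (resid, n)
        if best is not None and best[0] < tol:
            break
    if best is None or best[0] >= tol:
        worst = np.inf if best is None else best[0]
        raise ConvergenceError(
            f"no physical root of the coupled mass-action system "
            f"(best residual {worst:.2e} at n_Ca={n_ca_added:.3e})"
        )
    n_pairs = best[1]
    ca_free = n_ca_added - n_pairs.sum()
    c_free = ca_free / volume
    return ModelPrediction(
        free_ca_activity=np.asarray(g_ca * c_free),
        free_ca_conc=np.asarray(c_free),
        n_pairs=n_pairs,
        ionic_strength=np.asarray(I),
    )


def predict_curve(
    protocol,
    K: BindingConstants,
    acid: AcidConstants,
    replicate: str = "model",
) -> TitrationCurve:
    """Noise-free model titration curve for a dosing protocol.

    Thin quasi-static wrapper: every dose step is an independent equilibrium
    (addition rate cannot matter), with the volume updated for titrant and
    counter-titrant.  Equivalent to the synthetic generator with zero noise,
    no dosing-tip artifact and no nucleation cut-off.
    """
    from .synthetic import ArtifactModel, simulate_titration  # lazy, avoids cycle

    proto = replace(protocol, replicates=1)
    curves = simulate_titration(
        proto, K, acid, noise_cv=0.0,
        artifact=ArtifactModel(mode="none"),
        seed=0, nucleation_cutoff=np.inf,
    )
    curve = curves[0]
    curve.replicate = replicate
    return curve


# --------------------------------------------------------------------------
# Pre-nucleation regime analysis
# --------------------------------------------------------------------------

@dataclass
class SlopeFit:
    """OLS fit of free-Ca amount vs added-Ca amount over the linear regime."""

    slope: float
    intercept: float
    r_value: float
    stderr: float
    rms_residual: float
    n_points: int


def prenucleation_slope(curve: TitrationCurve) -> SlopeFit:
    """Least-squares slope of free vs added calcium, the standard one-number
    summary of a binding curve (1 = no binding, 0 = complete binding)."""
    if curve.n_points < 3:
        raise ValueError(f"need >= 3 points for a slope, got {curve.n_points}")
    x = curve.added_ca
    y = curve.free_amount()
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=curve.n_points,
    )


def truncate_prenucleation(
    curve: TitrationCurve, window: int = 10, threshold: float = 0.01
) -> TitrationCurve:
    """Longest linear prefix of a titration curve.

    Grows the prefix while the OLS fit over it keeps a relative residual
    (RMS residual / max |free amount|) below ``threshold``; the first
    violating point ends the pre-nucleation regime.  Raises
    :class:`EmptyPrenucleationRegime` when even the minimal prefix
    (``window + 2`` points) is not linear — the signature of the
    premature-phase-separation artifact, which bends the curve from the
    start.
    """
    n = curve.n_points
    min_pts = window + 2
    if n < min_pts:
        raise ValueError(f"need >= window+2 = {min_pts} points, got {n}")
    x = curve.added_ca
    y = curve.free_amount()

    def rel_resid(m: int) -> float:
        A = np.vstack([x[:m], np.ones(m)]).T
        coef, *_ = np.linalg.lstsq(A, y[:m], rcond=None)
        resid = y[:m] - A @ coef
        scale = np.max(np.abs(y[:m]))
        if scale == 0:
            return 0.0
        return float(np.sqrt(np.mean(resid**2)) / scale)

    if rel_resid(min_pts) >= threshold:
        raise EmptyPrenucleationRegime(
            f"no linear prefix of length {min_pts} (relative residual "
            f"{rel_resid(min_pts):.3g} >= {threshold:g})"
        )
    keep = min_pts
    for m in range(min_pts + 1, n + 1):
        if rel_resid(m) >= threshold:
            break
        keep = m
    return curve.head(keep)
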