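"""Estimation of the ion-association constants K1-K3 from titration curves.

Two routes, mirroring how the constants are determined in practice:

* :func:`direct_k1` — at pH <= 5 essentially all phosphate is H2PO4-, so K1
  follows point-by-point from the law of mass action with no fitting.
* :func:`global_fit` — K1-K3 by least squares over all points of all curves
  across pH, in log-K space (the constants span five orders of magnitude),
  with deterministic multi-starts.  Residuals are in free-calcium
  *concentration*, the quantity the matched-ionic-strength ISE actually
  reads.

Error bounds follow the tolerance-scan philosophy under which the reference
constants were reported: the interval over which the worst per-curve
relative deviation between model and data stays below a tolerance (default
5 %, the typical within-set curve-to-curve scatter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .chem_core import _equilibrate_arrays, _fraction_arrays, _gamma_by_charge
from .constants import KW, AcidConstants, BindingConstants
from .titration_model import TitrationCurve, direct_free_calcium

__all__ = [
    "DirectK1Result",
    "FitResult",
    "direct_k1",
    "global_fit",
    "error_bounds",
    "fit_pipeline",
]


@dataclass
class DirectK1Result:
    """Point-wise law-of-mass-action K1 estimates from a low-pH curve."""

    k1: float
    std: float
    per_point: np.ndarray
    n_used: int
    n_skipped: int


@dataclass
class FitResult:
    """Global-fit output: estimates, tolerance-scan bounds and diagnostics."""

    constants: BindingConstants
    model: str
    cost: float
    per_curve_rms: dict[str, float]
    bounds: tuple[float, float, float] | None = None
    one_sided: tuple[bool, bool, bool] | None = None
    k1_fixed: bool = False
    start_costs: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""


def _model_free_conc(
    curve: TitrationCurve, K: BindingConstants, acid: AcidConstants, model: str
) -> np.ndarray:
    """Model free-calcium concentration at the curve's dosing points."""
    if model == "predictive":
        st = _equilibrate_arrays(
            curve.added_ca, curve.n_p_total, curve.ph, curve.volume, K, acid,
            na_background=curve.na_background, cl_background=curve.cl_background,
        )
        return np.asarray(st["c_ca_free"])
    if model == "direct":
        return direct_free_calcium(curve, K, acid).free_ca_conc
    raise ValueError(f"unknown model {model!r}; use 'direct' or 'predictive'")


def direct_k1(curve: TitrationCurve, acid: AcidConstants) -> DirectK1Result:
    """K1 by direct application of the law of mass action at low pH.

    Every titration point gives K1 = a_pair / (a_Ca a_H2PO4) with the bound
    amount taken from the measurement (added - free) and the whole bound
    pool assigned to [CaH2PO4]+ (the only pair with an appreciable anion at
    pH <= 5).  Points with non-positive bound amount are skipped with a
    warning; the mean and standard deviation over the rest are returned.
    """
    if curve.ph > 5.0:
        raise ValueError(
            f"direct K1 determination requires pH <= 5, curve is at pH {curve.ph}"
        )
    added = curve.added_ca
    V = curve.volume
    bound = curve.bound_amount()
    usable = bound > 0
    n_skipped = int(np.sum(~usable))
    if n_skipped:
        warnings.warn(
            f"direct_k1: skipped {n_skipped} points with non-positive bound calcium",
            stacklevel=2,
        )
    if not np.any(usable):
        raise ValueError("no usable points: bound calcium <= 0 everywhere")
    p_free = curve.n_p_total - bound
    if np.any(p_free[usable] <= 0):
        raise ValueError("bound calcium exceeds total phosphate")

    a_h = 10.0 ** -curve.ph
    I = np.full(added.shape, 0.01)
    for _ in range(200):
        gam = _gamma_by_charge(I)
        fr = _fraction_arrays(curve.ph, acid, I)
        c_p = [f * p_free / V for f in fr]
        c_pair = bound / V  # all bound as [CaH2PO4]+
        c_h = a_h / gam[1]
        c_oh = KW / a_h / gam[1]
        net = (
            c_h + 2 * curve.free_ca + c_pair
            + (curve.na_background - curve.cl_background) / V
            - c_p[1] - 2 * c_p[2] - 3 * c_p[3] - c_oh
        )
        c_na = curve.na_background / V + np.maximum(-net, 0.0)
        c_cl = curve.cl_background / V + np.maximum(net, 0.0)
        I_new = 0.5 * (
            c_na + c_cl + 4 * curve.free_ca
            + c_p[1] + 4 * c_p[2] + 9 * c_p[3] + c_pair + c_h + c_oh
        )
        if np.max(np.abs(I_new - I) / np.maximum(I_new, 1e-12)) < 1e-12:
            I = I_new
            break
        I = I + 0.5 * (I_new - I)

    gam = _gamma_by_charge(I)
    fr = _fraction_arrays(curve.ph, acid, I)
    a_pair = gam[1] * bound / V
    a_ca = gam[2] * curve.free_ca
    a_h2po4 = gam[1] * fr[1] * p_free / V
    with np.errstate(divide="ignore", invalid="ignore"):
        k1_points = a_pair / (a_ca * a_h2po4)
    vals = k1_points[usable]
    return DirectK1Result(
        k1=float(np.mean(vals)),
        std=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        per_point=k1_points,
        n_used=int(vals.size),
        n_skipped=n_skipped,
    )


def global_fit(
    curves: list[TitrationCurve],
    model: str = "predictive",
    acid: AcidConstants | None = None,
    init: BindingConstants | None = None,
    fix_k1: float | None = None,
    inverse_variance_weights: bool = False,
    n_starts: int = 3,
    log10_bounds: tuple[float, float] = (-2.0, 8.0),
    **least_squares_kwargs,
) -> FitResult:
    """Global least-squares fit of the association constants.

    Minimises the summed squared residual between measured and model
    free-calcium concentration over every point of every curve.  Constants
    are parameterised as log10 K (positivity built in); three deterministic
    starts around ``init`` guard against local minima.  ``fix_k1`` pins the
    first constant (customary when a low-pH curve has determined it
    directly).  Per-curve inverse-variance weighting is available but off by
    default (plain SSE).
    """
    if acid is None:
        acid = AcidConstants()
    if init is None:
        init = BindingConstants(k1=10.0, k2=100.0, k3=10_000.0)
    if len(curves) < 2 or len({round(c.ph, 3) for c in curves}) < 2:
        raise ValueError("need >= 2 curves spanning >= 2 pH values")
    if not any(c.ph >= 9.0 for c in curves):
        warnings.warn(
            "no curve at pH >= 9: K3 is essentially unidentifiable "
            "(expect a wide or one-sided bound)",
            stacklevel=2,
        )

    temperature = curves[0].temperature
    weights = {}
    for c in curves:
        if inverse_variance_weights:
            resid_scale = max(float(np.std(np.diff(c.free_ca))), 1e-12)
            weights[id(c)] = 1.0 / resid_scale
        else:
            weights[id(c)] = 1.0

    if fix_k1 is not None:
        names = ("k2", "k3")
        x0 = np.log10([init.k2, init.k3])
    else:
        names = ("k1", "k2", "k3")
        x0 = np.log10([init.k1, init.k2, init.k3])

    def constants_from(x) -> BindingConstants:
        vals = dict(zip(names, 10.0 ** np.asarray(x)))
        if fix_k1 is not None:
            vals["k1"] = fix_k1
        return BindingConstants(temperature=temperature, **vals)

    def residuals(x):
        K = constants_from(x)
        out = []
        for c in curves:
            pred = _model_free_conc(c, K, acid, model)
            out.append((pred - c.free_ca) * weights[id(c)])
        return np.concatenate(out)

    def cost(x) -> float:
        r = residuals(x)
        return float(0.5 * np.dot(r, r))

    starts = [x0]
    for shift in (+0.7, -0.7):
        if len(starts) >= n_starts:
            break
        starts.append(x0 + shift)
    starts = starts[:n_starts]

    lo = np.full(x0.size, log10_bounds[0])
    hi = np.full(x0.size, log10_bounds[1])
    best = None
    start_costs = []
    for s in starts:
        s = np.clip(s, lo, hi)
        c0 = cost(s)
        opts = dict(xtol=1e-10, ftol=1e-10)
        opts.update(least_squares_kwargs)
        sol = optimize.least_squares(
            residuals, s, bounds=(lo, hi), method="trf", **opts
        )
        start_costs.append((c0, float(sol.cost)))
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success:
        raise RuntimeError(f"global fit did not converge: {best.message}")

    K_best = constants_from(best.x)
    per_curve = {}
    for c in curves:
        pred = _model_free_conc(c, K_best, acid, model)
        per_curve[f"pH{c.ph:g}/{c.replicate}"] = float(
            np.sqrt(np.mean((pred - c.free_ca) ** 2))
        )
    return FitResult(
        constants=K_best,
        model=model,
        cost=float(best.cost),
        per_curve_rms=per_curve,
        k1_fixed=fix_k1 is not None,
        start_costs=start_costs,
        message=str(best.message),
    )


def _worst_curve_deviation(
    curves, K: BindingConstants, acid: AcidConstants, model: str
) -> float:
    """Largest per-curve mean relative deviation between model and data."""
    worst = 0.0
    for c in curves:
        pred = _model_free_conc(c, K, acid, model)
        meas = np.maximum(c.free_ca, 1e-30)
        worst = max(worst, float(np.mean(np.abs(pred - c.free_ca) / meas)))
    return worst


def error_bounds(
    curves: list[TitrationCurve],
    model: str,
    acid: AcidConstants,
    best: BindingConstants,
    tolerance: float = 0.05,
    span_decades: float = 1.0,
    n_grid: int = 81,
) -> tuple[tuple[float, float, float], tuple[bool, bool, bool]]:
    """Tolerance-scan bounds on each constant.

    One constant at a time is swept on a log grid around the best estimate
    (others fixed); the acceptable interval is where the worst per-curve
    mean relative deviation stays below ``tolerance``.  Returns the
    half-widths (K units) and flags marking intervals that ran into a grid
    edge (one-sided).
    """
    half_widths = []
    one_sided = []
    for name in ("k1", "k2", "k3"):
        k_best = getattr(best, name)
        grid = k_best * 10.0 ** np.linspace(-span_decades, span_decades, n_grid)
        ok = np.zeros(n_grid, dtype=bool)
        centre = n_grid // 2
        for direction in (range(centre, n_grid), range(centre, -1, -1)):
            for i in direction:
                K_try = replace(best, **{name: float(grid[i])})
                ok[i] = _worst_curve_deviation(curves, K_try, acid, model) < tolerance
                if not ok[i]:
                    break  # contiguous interval around the optimum
        inside = np.nonzero(ok)[0]
        if inside.size == 0:
            half_widths.append(float("nan"))
            one_sided.append(True)
            continue
        lo_i, hi_i = int(inside[0]), int(inside[-1])
        at_edge = lo_i == 0 or hi_i == n_grid - 1
        half_widths.append(0.5 * float(grid[hi_i] - grid[lo_i]))
        one_sided.append(bool(at_edge))
    return tuple(half_widths), tuple(one_sided)


def fit_pipeline(
    curves: list[TitrationCurve],
    acid: AcidConstants | None = None,
    model: str = "predictive",
    init: BindingConstants | None = None,
    compute_bounds: bool = False,
    tolerance: float = 0.05,
) -> FitResult:
    """Standard analysis chain: direct K1 from any low-pH curve, then the
    global fit of the remaining constants (all three if no low-pH curve is
    present), optionally followed by tolerance-scan bounds."""
    if acid is None:
        acid = AcidConstants()
    low = [c for c in curves if c.ph <= 5.0]
    fix = None
    if low:
        fix = float(np.mean([direct_k1(c, acid).k1 for c in low]))
    result = global_fit(curves, model=model, acid=acid, init=init, fix_k1=fix)
    if compute_bounds:
        hw, edge = error_bounds(
            curves, model, acid, result.constants, tolerance=tolerance
        )
        result.bounds = hw
        result.one_sided = edge
    return result
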