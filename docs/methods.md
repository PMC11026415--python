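# Methods

## Model

All calculations treat the solution as a set of coupled mass-action
equilibria at fixed temperature and externally clamped pH (the experimental
counter-titration holds the pH; the counter-ion demand is included in the
ionic-strength bookkeeping and in the dosed volume).

Species tracked: Na⁺, Cl⁻, free Ca²⁺, the four phosphate protonation
states, the three 1:1 calcium-phosphate ion pairs ([CaH2PO4]⁺, [CaHPO4]⁰,
[CaPO4]⁻), H⁺ and OH⁻.  Association constants are activity based
(K_i = a_pair / (a_Ca a_anion), c⁰ = 1 M).  Activity coefficients depend
only on |z| (Davies, coefficient 0.5085, linear term 0.3 I); neutral
species have γ = 1 exactly.  The ionic strength sums every charged
species, including the two charged ion pairs; H⁺/OH⁻ enter through the pH
with γ(z=1); K_w = 10⁻¹⁴ throughout (its temperature dependence is below
every tolerance used here).

Given total calcium, total phosphate, volume and pH, the three pair
amounts are determined by one scalar unknown: writing n_b for the total
bound calcium, each mass-action relation gives the pair amount explicitly,
and their sum reduces to a quadratic in n_b whose smaller root is the
physical one.  `chem_core.equilibrate` wraps this closed form in a damped
fixed point over the ionic strength (damping 0.5 on I, relative tolerance
1e-10), so activity coefficients, acid-base partition and pairing are
mutually consistent at return.  `titration_model.predictive_solve` solves
the same three relations instead by bounded multivariate root-finding
(trust-region least squares with deterministic multi-starts and an
analytic-Jacobian Newton polish); the two formulations agree to better
than 1e-10 relative and serve as standing cross-checks of each other.

The Direct model replaces the predicted bound calcium with the measured
one (added − measured free) and returns the algebraically exact free-ion
activity a_Ca = γ_Ca (n_added/V) / (1 + γ_Ca Σ K_i a_anion,i / γ_pair,i).
On noise-free model data the two models coincide pointwise.

## Acidity constants and their ionic-strength convention

The default set is pKa1 = 2.58, pKa2 = 6.98 and pKa3 = 12.32.  The first
two are *conditional* constants, valid at the working ionic strength of
the titrations (I ≈ 0.015–0.03) where they were determined with electrodes
calibrated at matched ionic strength; across that window they are flat to
within the measurement scatter, so no further correction is applied.  The
third is a literature value on the activity scale (the third equivalence
is not reachable potentiometrically).  Routines that know the local ionic
strength therefore convert only pKa3 to its conditional form,
pKa3_eff = pKa3 − log10(γ₂/γ₃).  Two consequences worth knowing:

* `phosphate_fractions(ph, acid)` with the default `ionic_strength = 0`
  reproduces the conventional closed-form percentages (e.g. PO4³⁻ is
  0.95 / 2.9 / 8.7 % of total phosphate at pH 10.3 / 10.8 / 11.3);
* the equilibrium solver passes its converged I, which raises the PO4³⁻
  share at high pH and is what places the speciation-diagram crossovers
  where a full geochemical speciation code puts them.  Without the
  correction the [CaHPO4]⁰ → [CaPO4]⁻ handover would sit ~0.35 pH units
  higher and the predicted free-calcium fraction at pH 11.3 would double.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| K1, K2, K3 (`revised`) | 4.5, 470, 50 000 | — | 25 °C experimental set |
| K set (`revised_37c`) | 4.5, 480, 69 500 | — | 37 °C best-fit set |
| `legacy` preset | K3 = K2·exp(21.4/RT·10³) ≈ 2.64e6 | — | reconstruction of the historical set, anchored to the 21.4 kJ/mol literature gap between the second and third association free energies; K1/K2 keep the revised magnitudes. A *reconstruction*, not a literature-exact set |
| buffer | 50.00 g of 0.010 M phosphate | | reference protocol; mass→volume with density 1.000 g/mL |
| titrant | 0.005 M CaCl2, 0.04 mL steps × 50 | | spans the pre-nucleation regime (≤ 0.2 mM added Ca) |
| ISE noise | multiplicative log-normal, CV 1 % | | electrode response is log-linear in activity; mean-preserving |
| nucleation cut-off | a_Ca·a_PO4 ≥ 2e-9 | — | ends the simulated curve "just before nucleation"; chosen so high-pH curves truncate within the dosing window while pH ≤ 8.3 curves run to completion, matching the observed pH trend |
| artifact model | enrichment 50, threshold 2.5e-7 on E·a_Ca·(a_HPO4+a_PO4), cap 0.6 | — | dosing-tip premature phase separation; see below |
| temperatures | 298.15 / 310.15 K | K | 25 / 37 °C with the .15 offset; R = 8.314 J/(K mol) |

## Fitting

The global objective is the unweighted sum of squared residuals in
free-calcium *concentration* (what a matched-ionic-strength ISE reads)
over all points of all curves; per-curve inverse-variance weighting is
available behind a flag.  Optimisation runs in log10 K (the constants span
five orders of magnitude) from three deterministic starts around the
initial guess.  When a low-pH (≤ 5) curve is present the pipeline first
determines K1 point-wise from the law of mass action and holds it fixed —
at pH 4.3 the H2PO4⁻ ion dominates and no fitting is needed.  That direct
estimate carries an inherent mild positive bias (~+0.6 on 4.5) because the
neutral pair still contributes ~13 % of the binding at pH 4.3; the bias is
well inside the ±2.4 uncertainty attached to K1.  With curves only above
pH 7, K3 (and below pH 9, even more so K1) is weakly identified; the fit
warns accordingly, and the two-temperature recovery holds K1 fixed at its
temperature-independent value.

Error bounds follow the tolerance-scan definition: each constant is swept
on a log grid (±1 decade, 81 points) with the others fixed, and the
acceptable interval is where the worst per-curve mean relative deviation
between model and data stays below 5 % — the typical within-set
curve-to-curve scatter.  On 1 %-noise synthetic sets this yields
half-widths of order ±6 / ±30 / ±1500 for K1/K2/K3, the same orders as the
reported ±2.4 / ±50 / ±8000.

## pKa analysis

Equivalence points are the largest local maxima of dpH/dV after a 5-point
local-quadratic (Savitzky–Golay) smoothing; peak positions are refined by
parabolic interpolation.  The pKa is read at the half-equivalence point
*in the amount domain* — with acid co-dosing (the dilution-compensated
protocols) the acid inventory grows during the run and the volume midpoint
is biased by ~+0.1 units.  The reading is corrected for free protons,
pKa = pH + log10((c/2 − x)/(c/2 + x)) with x = [H⁺] − [OH⁻]; without this
correction the first pKa of 0.01 M phosphoric acid comes out ~0.27 units
high, because the acid is appreciably dissociated near pH 2.6.  [H⁺] is
estimated from the electrode reading with a Davies coefficient at an
ionic strength reconstructed from the dosing recipe.

## What the generator emulates — and what it does not

The simulator reproduces the statistical structure the analysis assumes:
quasi-static dosing (each point an independent equilibrium, so addition
rate is irrelevant), volume tracking for titrant and counter-titrant,
seeded mean-preserving multiplicative ISE noise, triplicates, truncation
before nucleation, and a dosing-tip artifact in which a locally enriched
ion-activity product sequesters a progressively growing fraction
f = f_max(1 − threshold/IAP_local) of each dose (with matching phosphate,
1:1).  The progressive form makes the biased curve convex from early on —
it bends directly toward a plateau with no linear regime, which is the
fingerprint used to detect the artifact.  The true magnitude of the tip
enrichment is not knowable from bulk data; the default (50) is chosen only
to reproduce that qualitative dichotomy.

Not modelled: post-nucleation solubility plateaus and supersaturation
peaks, nucleation kinetics, liquid-liquid demixing, electrode drift or
calibration error, CO2 uptake, and any ligand beyond
orthophosphate/chloride/sodium.  Passing recovery tests therefore shows
the *analysis chain* is unbiased under its own assumptions — not that real
electrodes or real buffers are this well behaved.

## Numerical choices and degenerate inputs

* Ionic-strength fixed point: damping 0.5, relative tolerance 1e-10,
  maximum 400 iterations, `ConvergenceError` carries the last I.
* Quadratic root for the bound amount in the numerically stable
  2c/(b+√(b²−4ac)) form; zero constants or zero totals short-circuit to
  the unbound state.
* Physical-root selection in `predictive_solve`: solutions constrained to
  0 ≤ n_i, Σn_i ≤ min(n_Ca, n_P); nine deterministic starts spanning the
  box; acceptance requires per-equation relative residual < 1e-10.
* Pre-nucleation truncation: longest prefix whose OLS fit keeps
  RMS residual / max|free amount| below 1 % (window 10); a violation at
  the minimal prefix raises `EmptyPrenucleationRegime`.
* Curve invariants are enforced at construction (strictly increasing
  doses, free ≤ added, non-decreasing volume); simulated ISE readings are
  clipped at the zero-binding line, which a calibrated electrode cannot
  exceed.
* Problem sizes: simulations use 50 dose steps per curve (20–25 in the
  heaviest Monte-Carlo recovery tests), 100-seed Monte-Carlo loops for
  noise-stability claims, and a 201-point pH grid for diagrams.

## Known limitations

* The `legacy` preset is a reconstruction; with it, "essentially complete"
  calcium binding is reached near pH 10 rather than pH 9, and the
  [CaPO4]⁻ dominance onset computes to pH 8.50 — at the upper edge of
  where the historical constants place it.  Both would move with the exact
  (unpublished here) historical values.
* The van't Hoff enthalpy from two closely spaced temperatures inherits
  the full relative error of both constants; the third-pair value
  (21.1 kJ/mol from the printed constants) should be read with its large
  uncertainty in mind.
* Davies coefficients are charge-specific only; ion-size effects
  (extended Debye–Hückel) would shift speciation boundaries by a few
  hundredths of a pH unit.
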