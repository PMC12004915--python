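# Methods

## The measurement being modelled

A demicellization ITC run titrates a micellar surfactant stock (syringe
concentration C_syr ≈ 12× the CMC) into a perfusion-type cell of active
volume V₀ = 1.4 mL in 32 injections of 8 μL spaced 300 s apart. Early
injections dissolve the injected micelles (heat ≈ ΔH_demic per mole of
micellar surfactant delivered); once the cell passes the CMC the heats
drop to the dilution baseline. The per-injection molar heat plotted
against cell concentration — the enthalpogram — is sigmoidal, and its
transition locates the CMC.

## Concentration bookkeeping

The cell is overfilled: each injection of volume v expels an equal
volume of mixed cell content, so the total concentration after i
injections is C_i = C_syr·[1 − (1 − v/V₀)^i]. The naive additive
bookkeeping C_i = C_syr·iv/(V₀ + iv) is available behind a flag; the
two agree per injection to O(v/V₀) but diverge cumulatively like
(iv/V₀)²/2, reaching ≈ 8% by injection 32 at v/V₀ ≈ 0.006 — the
displacement form is the physically correct one for this cell type.

Moles delivered per injection are taken as C_syr·v, with no
displacement correction on the injectant (second-order at this v/V₀).

**Concentration assigned to each heat.** A per-injection heat is an
average of the underlying heat curve over the concentration step
(C_{i−1}, C_i]. Assigning it to the post-injection concentration — the
instrument-vendor convention — biases the apparent transition upward by
about half an injection step (≈ +3% of the CMC at this protocol), which
is larger than the pipeline's other error sources combined. The package
therefore assigns heats to the midpoint ½(C_{i−1} + C_i) by default
(second-order accurate for a step-average quantity) and offers the
post-injection convention behind `assignment="post"`, in both the
simulator and the peak integrator.

## Aggregation models

* **Pseudophase**: micelles are a separate phase; monomer = min(C, CMC).
  Produces a step enthalpogram — the sharp-transition reference.
* **Mass action**: n·S ⇌ Mₙ with equilibrium constant K. The free
  monomer x solves x + nKx ⁿ = C, computed by bracketed root finding in
  reduced units y = x/CMC with the dimensionless constant
  k_red = nK·CMCⁿ⁻¹ (safe for large n, where K itself can overflow a
  double). Default aggregation number 55, typical of dodecyl-chain
  micelles.

**Where is the CMC of a smooth model?** For a finite aggregation number
the transition has width, and "the CMC" depends on convention: the
textbook choice k_red = 1 (CMC = (nK)^(−1/(n−1))) places the operational
transition ~5–8% below the nominal value at n = 55. The package instead
*calibrates* k_red by root finding so that the operational CMC — the
first-derivative extremum of the six-parameter sigmoid fitted to the
ideal, noise-free continuum heat curve over the protocol's concentration
range — equals the nominal `cmc_true`. This makes parameter recovery
well-posed: the discrete 32-injection pipeline is then tested against a
truth defined by the same extraction rule the field uses, and any
residual error reflects finite sampling, noise and fit behaviour (it is
+0.06% noise-free at the DPS protocol). The textbook convention remains
available by setting `k_reduced = 1.0` explicitly.

The syringe content is partitioned as CMC monomer + (C_syr − CMC)
micellar when computing the demicellized amount, consistent with the
micelle-dominated stock. Per injection,

q_i = ΔH_demic · Δn_demic,i /(C_syr·v) + q_dil + baseline terms,

where Δn_demic,i is the micellar amount of the mixed-but-unequilibrated
cell minus the equilibrium micellar amount after injection i. Noise is
iid Gaussian on the integrated heats (σ expressed as a fraction of
|ΔH_demic|), applied with an explicit seed; raw-trace noise is optional.
Internal units are J mol⁻¹ throughout (1 cal = 4.184 J on I/O).

## Peak integration

Raw traces are rendered/ingested as time–power series with injection
markers. Each injection window runs to the next injection; the local
baseline is the linear interpolant between the quiet tails (last 10% of
each inter-injection interval, where the signal has returned to
baseline) flanking the peak, and the heat is the trapezoidal integral
of power minus baseline. The 10% quiet fraction and trapezoidal
quadrature are deliberate, simple choices; vendor software baselines are
proprietary, and round-trip tests against the simulator hold to <1% of
the largest heat including a linear instrument drift.

## Sigmoid fit and extraction

The fitted form is the Boltzmann sigmoid bridging two lines (parameters
a₁…a₆; a₅ centre, a₆ > 0 width). Fitting is least squares with unit
weights (per-injection uncertainties are rarely available), via lmfit's
least-squares engine at tight tolerances (1e-14), from a deterministic
initialization — a₅ at the steepest data slope, a₆ at 10% of the span,
baselines from the first/last quarter of points — plus four
deterministically jittered restarts (seeded); the lowest-RSS converged
solution wins, and non-convergence raises with diagnostics rather than
returning parameters silently. Bounds keep a₅ inside the data range and
a₆ ∈ (10⁻⁶·span, span] to exclude degenerate step/flat solutions.

The CMC is the extremum of the analytic |dq/dC| located by a dense-grid
scan (4096 points; ties broken by magnitude when sloping baselines give
two local extrema) polished by bounded scalar minimisation; an extremum
at the data boundary is flagged (transition not bracketed).
ΔH_demic is the baseline gap at the CMC.

**Known bias of the gap estimator.** The gap measures
ΔH_demic·(1 − CMC/C_syr) even for a perfectly sharp transition — the
monomer fraction of the injectant contributes no demicellization heat —
i.e. ≈ −9% at C_syr = 11×CMC; broad transitions droop the fitted
pre-baseline and lower it further (≈ −19% at n = 55). This mirrors the
real experimental procedure, which reports the same apparent quantity;
the simulator is the tool for quantifying it.

## Thermodynamics

ΔH°_mic = −ΔH_demic (sign convention of the demicellization design);
ΔG° = RT·ln(CMC/c°) with R = 8.314 J mol⁻¹ K⁻¹, the counterion-free
form appropriate for zwitterionic and nonionic surfactants; −TΔS° =
ΔG° − ΔH°, closed exactly by construction and asserted to 1e-9 relative
on every record. c° = 1 mol L⁻¹ by default; the mole-fraction standard
state (55.5 M) only shifts ΔG° by an additive constant and is available
by flag. ΔC_p,mic is the OLS slope of ΔH°_mic against T (exact line for
two points), and T_H = −intercept/slope is the athermal temperature —
reported from the same fit, undefined (NaN) for zero slope, and flagged
when more than 50 K outside the measured range. Negative ΔC_p makes
micellization endothermic below T_H and exothermic above, the
hydrophobic-effect signature the temperature-series generator
reproduces.

## What the synthetic data do and do not show

The generator emulates the protocol geometry, the displacement
dilution, the smooth mass-action transition, temperature-linear
enthalpies and seeded Gaussian heat noise. It does **not** model
instrument response/feedback dynamics, mixing kinetics, activity
corrections at finite ionic strength (salts are condition labels only),
premicellar aggregates other than the single n-mer, or concentration
errors in stock preparation. Passing recovery tests therefore
demonstrates the correctness of the analysis chain under the stated
measurement model, not robustness to every instrumental artefact of
real data.

## Problem sizes and numerical choices

Tests and the acceptance script run at the experiment's own scale
(32-injection titrations; 100-replicate Monte-Carlo per condition at 2%
heat noise; 50–200 random draws for oracle-equivalence checks; 10⁵-point
grids for the derivative-extremum oracle) — small enough to run in
seconds, large enough that every stage is exercised end to end. Root
finding uses scipy's brentq at machine-precision tolerances; the
monomer solve is bracketed on [0, C] and cannot escape the physical
branch.

## Known limitations

* The mass-action model converges to the pseudophase step only like
  1/n: the post-CMC tail (monomer still rising as ≈ CMC·(C/CMC)^{1/n})
  leaves per-injection deviations of several % of |ΔH| at n = 100,
  reaching 2% only around n ≈ 300–500. Tests assert the measured
  convergence trend rather than a fixed small bound at n = 100.
* The gap ΔH estimator's −(CMC/C_syr) and transition-broadening biases
  (above) are inherent to the procedure, not removed by the package.
* Unit-weight fitting ignores heteroscedastic injection noise; weights
  can be supplied to `fit_sigmoid` if known.
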