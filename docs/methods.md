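# Methods

## Reaction model

The measurement reaction is strand exchange over a shared complement Z:

    X + YZ ⇌ Y + XZ,   ΔG°rxn = ΔG°f(XZ) − ΔG°f(YZ) = −RT ln Keq

X and Y are designed to differ only by the motif being interrogated
(terminal fluorophore, or fluorophore + dangle), and to have no
secondary structure, so the single-strand free energies cancel and the
reaction ΔG° is reported directly as the motif ΔG°. R is fixed at
1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹; all free energies are kept in kcal/mol
and entropies in kcal/mol/K internally, with the common cal/mol/K
entropy convention applied only at I/O. Temperatures enter in °C and
are converted once. Activity coefficients are taken as 1 throughout
(ideal dilute solution; the working concentration is 1× = 300 nM).

## Equilibrium solver

`equilibrium_network.solve_equilibrium` finds the unique minimum of the
ideal-dilute Gibbs free energy over mass-balanced compositions. It
works in log free-strand concentrations: every complex concentration is
eliminated through detailed balance ([S₁…Sₖ] = e^(−ΔG°f/RT)·Π[Sᵢ]),
leaving one mass-balance equation per strand, solved by damped Newton
iteration (backtracking line search, log-scale residual tolerance
1e-12, max 200 iterations). Because realistic duplex depths
(ΔG°f ≈ −30 kcal/mol for a ~25-bp duplex at 25 °C) put the
fully-dissociated starting point 15+ orders of magnitude from the
solution — where the Newton matrix is numerically rank-deficient — the
iteration is preconditioned by a damped log-space fixed point
(u ← u − ½ log(computedTotals/targetTotals)) until the residual is
O(1). The combination converges in ≲20 iterations across duplex depths
−3 to −45 kcal/mol, asymmetric totals, and catalyst loads 0–0.5×.
A brute-force oracle (grid scan of the Gibbs energy over the 2-D
reaction-extent space with staged refinement) verifies the solver in
the test suite; the two-strand limit is additionally checked against
the binding quadratic.

The three-strand intermediates CXZ/CYZ can be declared as complexes
with user-supplied formation ΔG°, but the default network omits them:
the gel evidence for the method is precisely that they are short-lived
and low in concentration.

## Catalyst-bias analysis

The gel analysis infers ΔG° while ignoring catalyst-bound Z (the CZ
intermediate). Sequestered Z inflates the inferred [YZ] by [CZ] and
deflates the inferred [Y] by the same amount, so the apparent ΔG° is
always an overestimate. `bias_scan` quantifies this by solving the full
network (CZ included) and pushing the true equilibrium [XZ] through the
CZ-blind mass-balance algebra. With 0.1× catalyst and CZ constrained to
be at least 1 kcal/mol less stable than either product duplex, the
worst case over motif ΔG° ∈ [−2, +2] kcal/mol is ≈0.036 kcal/mol —
comfortably inside the 0.2 kcal/mol worst-case budget the method
claims. The unconstrained corner is larger: if CZ is artificially
clamped at the full 0.1× (complete sequestration), closed-form algebra
gives a bias of ≈0.24 kcal/mol; the 0.2 budget therefore presumes
equilibrium-consistent (not fully sequestered) CZ, which the constraint
grid enforces. Bias is monotone in CZ stability and identically zero
without catalyst; both properties are asserted in the tests.

In subtraction (dangle) measurements the bias largely cancels, since
both reactions share the catalyst and Z strand.

## Kinetics

`kinetics_sim` integrates mass-action ODEs (LSODA, rtol 1e-8, atol
1e-12 × 300 nM) for: strand association of every declared two-strand
complex, the direct exchange, and — when CZ exists — the two
coarse-grained catalysed displacements C + YZ ⇌ Y + CZ and
C + XZ ⇌ X + CZ. Every reverse rate is set by detailed balance from the
formation ΔG°s, so the kinetic endpoint and the equilibrium solver
share one thermodynamic ground truth (asserted to 1e-5 relative in the
tests).

Rate defaults: direct exchange k = 1 M⁻¹s⁻¹ (four-way branch
migration); toehold-mediated steps k = 3×10⁵ M⁻¹s⁻¹ (hybridization-like
binding for a sufficiently long toehold). The branch-migration
resolution rate (k_branch, default 1 s⁻¹) does not enter the ODEs: at
300 nM the pseudo-first-order binding rate is ~0.1 s⁻¹, so displacement
is binding-limited and every binding event resolves; k_branch is kept
in `RateModel` to document the regime in which this coarse-graining is
valid. No literature value pins the catalysed second-order constant;
both defaults are order-of-magnitude choices and are configurable.

These numbers give the central kinetic contrast: uncatalysed, the
standard lane ([XZ]₀ = [Y]₀ = 1×) is <1% equilibrated after 3 h
(half-life ~116 days at 100 nM), while 0.1× catalyst reaches >99.99%.

## Gel pipeline

Only X-containing species carry the fluorophore, so a lane yields two
band intensities, I(X) and I(XZ). The chain per catalysed lane:

1. **Quantum-yield calibration.** The ssDNA/dsDNA per-state yield
   ratio is estimated from the two control lanes as
   (I_X/[X]₀) ÷ (I_XZ/[XZ]₀). The effect is real (dyes fluoresce
   differently in single- and double-stranded context) but its
   magnitude must be calibrated per experiment.
2. **Loading correction.** Intensities are rescaled so the labelled
   strand is conserved: [X] + [XZ] = [X]₀ + [XZ]₀. This absorbs the
   per-lane pipetting factor and makes the result invariant to any
   common intensity scale.
3. **Mass balance.** [Y] and [YZ] follow from the two remaining strand
   conservation laws. Observations may overshoot a feasibility bound by
   ≤2% of the labelled total (band-quantitation noise) and are clipped;
   larger violations are errors, as is complete conversion (unbounded
   Keq).
4. **ΔG°.** From the reaction quotient at the reconstructed
   equilibrium.

Step 2 settles a genuine design choice: in principle the lane gives two
redundant estimates (from I(X) and from I(XZ)) that disagree under
loading error. The conservation-enforcing rescale makes the two
inferences *identical by construction*, which is this package's
interpretation of "correcting for loading error in the mathematical
analysis"; each lane therefore emits one estimate. Replicates are
pooled as an unweighted mean of per-lane ΔG° values (not Keq values),
with the s.d. of the mean under a Gaussian error model.

## Consensus statistics

Dangle ΔG°s are differences of two reactions (variances add). Each
motif is measured with two independent strand sets (ROX, Alexa532) and
combined by the inverse-variance weighted mean — the minimizer of the
summed squared z-scores — with consensus sd (Σσᵢ⁻²)^(−1/2). The
Consensus Score is

    CS = 10 − Σ zᵢ²,   zᵢ = (μᵢ − consensus)/σᵢ,

which for two inputs collapses to 10 − (μ₁−μ₂)²/(σ₁²+σ₂²). CS = 10 for
perfect agreement; CS = 8 when each input sits exactly 1 s.d. from the
consensus; CS = 0 at 2.236 s.d. The implementation generalizes to k ≥ 2
inputs with the same formula.

**Gaussian failure expectation.** `expected_cs_failures` converts a CS
threshold t into the symmetric per-measurement boundary
z\* = √((10−t)/2) and applies the two-sided normal tail per parameter:
at t = 0, 2(1−Φ(√5)) ≈ 2.5% of parameters — about 4 in a 160-parameter
panel. One subtlety is documented rather than hidden: this expectation
treats each measurement's deviation from the consensus, in units of its
own σ, as standard normal. Under fully independent measurement errors
the two z-scores about the *fitted* consensus are perfectly
anti-correlated with variance ½, and P(CS ≤ 0) drops to
2(1−Φ(√10)) ≈ 0.16%. `simulate_cs_failure_rate` exposes both draws: the
default realises the expectation model (and converges to 2.5%); the
`independent_errors=True` variant realises the fully-propagated model.
The expectation-model figure is the appropriate yardstick for judging
an observed failure count against the method's own error model, and is
deliberately conservative (it over-predicts failures).

## van't Hoff fitting

Because each temperature's mean ΔG° carries a different uncertainty, a
plain least-squares line is inappropriate; the fit minimizes the summed
squared z-scores Σ((ΔH° − TᵢΔS° − μᵢ)/σᵢ)², solved in closed form by
weighted normal equations in the basis (1, −T). Parameter s.d.s come
from the inverse normal matrix (measurement-error propagation; no
residual rescaling). The weighted residual sum is reported as
`sum_sq_z` but no goodness-of-fit p-value is attached: linear ΔG°(T)
fits of hybridization motifs are known to fit poorly if ΔH°/ΔS° are
themselves temperature-dependent, and only the temperature-invariant
model is implemented. Interpretation is left to the user.

## Melt-curve (HRM) branch

The comparison method melts the XZ and YZ duplexes separately with a
duplex-sensitive dye. Analysis: linear baselines least-squares fitted
over the coolest and warmest 15% of the ramp (the windows are not
standardized anywhere; 15% is this package's default and is
configurable), hybridization yield θ(T) = (F − lower)/(upper − lower)
clipped to [10⁻⁴, 1−10⁻⁴], bimolecular equal-totals association
constant Keq = θ/(c(1−θ)²), and an unweighted OLS van't Hoff line of
ln Keq against 1/T restricted to θ ∈ [0.15, 0.85] (outside, the yield
is baseline-dominated). The motif ΔG° at the requested temperature is
the difference of the XZ and YZ fits. The two-state melting temperature
obeys Tm = ΔH°/(ΔS° + R ln(c/2)) for per-strand total c.

Two honest caveats. First, even noiseless plateaus carry residual
two-state contamination (1−θ ≈ 3×10⁻⁷ in the cool window for the
reference duplex, θ ≈ 2×10⁻⁵ in the hot window), so fitted-baseline
recovery is tight but not exact; exact recovery holds when the true
baselines are supplied. Second — and this is the point of the branch —
the chain amplifies noise: with 1% fluorescence noise, triplicate melt
pairs on the reference system spread over ~2.6 kcal/mol per pair,
versus ~0.12 kcal/mol per catalysed gel lane on matched truth, an
order-of-magnitude-plus precision gap in favour of the isothermal
method.

## Dangle length model

The motif-sum prediction treats a duplex ΔG° as initiation + stacks +
dangle terms + fluorophore terms, with 5′ and 3′ dangles keyed
separately (no symmetry is assumed; 3′ first-nucleotide stabilization
is weaker). Motif tables are user-supplied TSVs; the repository ships
no fabricated per-motif values.

Multinucleotide dangles destabilize relative to the single-nucleotide
dangle with a saturating trend. The empirical data behind that trend is
a lookup table in origin; this package adopts the parametric form

    correction(L) = A·(1 − e^(−(L−1)/λ)),  L ≥ 1 nt,

which is zero at L = 1 by definition, monotone, and approaches the
asymptote A (+0.56 kcal/mol for poly-T at 25 °C). λ defaults to 2.0 nt,
which puts 97% saturation at L = 8 — consistent with a plateau by
roughly 8 nt. Fitting is weighted nonlinear least squares over
(baseline, A, λ) with A bounded below by 0, standard errors from the
Jacobian covariance, and a derived `saturation_length` (smallest L
reaching 95% of A). Only homopolymer dangles are supported: mixed
sequences could fold and add confounding structure terms.

## Synthetic data

The generators emulate the experimental layouts at their stated
conditions: 1× = 300 nM; six-lane gels (two controls, two 3 h
uncatalysed lanes produced by actually integrating the kinetics — not
by sampling an arbitrary partial extent — and two catalysed lanes at
the solved equilibrium, run from the two opposite starting mixes with
0.1× catalyst); melt ramps 95 → 30 °C in 1 °C steps; dangle series over
L = 1..21. Default duplex depth is −30 kcal/mol (a realistic ~25-bp
duplex at 25 °C), which makes free Z negligible at the 10⁻⁹ level the
mass-balance algebra assumes. The catalyst's CZ intermediate is
thermodynamically negligible by default (matching the analysis
assumption) and configurable for bias studies.

Noise structure: lognormal per-lane loading factor (σ = 0.05),
multiplicative Gaussian band quantitation (CV = 0.02), relative
Gaussian stoichiometry error on the true initial concentrations
(σ = 0.03) — the analysis sees only the nominal initials — and additive
melt fluorescence noise (1% of plateau span). The gel magnitudes are a
*calibration*, not a measurement: they were chosen so the per-lane ΔG°
spread sits near 0.12 kcal/mol and ~10 replicate lanes pool to a mean
s.d. of ~0.04–0.05 kcal/mol, the precision scale the catalysed-gel
method achieves in practice. Dangle series default to 4 measurements
per length with per-measurement s.d. 0.07 kcal/mol, the typical
replication and spread of per-dangle parameters. Temperature error and
oligonucleotide synthesis error are *not* modelled (no mechanism for
either is specified), and no gel-image pixels are synthesized —
generation starts at the intensity table, as the analysis starts there.
Every generator draws from a single seeded `numpy.random.Generator` and
embeds its full ground truth and seed in the output metadata; tests
read truth only from metadata. Incubation time is a parameter (buffers
differ in how long they were incubated in practice; 3 h is the
default).

Passing recovery tests on these generators shows the *analysis chain*
is correct and well-calibrated under its own noise model; it cannot
validate effects the generators do not emulate (synthesis errors,
temperature drift, non-linear band response, dye–thermodynamics
coupling in melts).

## Numerical choices, in one place

- Equilibrium: log-residual tolerance 1e-12, ≤200 Newton iterations,
  fixed-point preconditioning threshold 0.5 (log units).
- ODEs: LSODA, rtol 1e-8, atol 3e-19 M (1e-12 of 1×).
- Feasibility clipping in mass-balance inference: 2% of labelled total.
- Yield clipping: ε = 10⁻⁴; van't Hoff window θ ∈ [0.15, 0.85];
  baseline windows 15% of the ramp at each end.
- Length-model fit: scipy `curve_fit` (TRF with bounds A ≥ 0,
  λ ∈ [10⁻³, 10³]), absolute sigma.
- Melting temperature: linear interpolation at the first θ = 0.5
  crossing of the temperature-sorted curve.

## Known limitations

- No salt-correction model: parameters are native to their buffer, and
  no cross-buffer extrapolation is attempted.
- No partition function over secondary structures; complexes are
  discrete declared species, and dangles must be homopolymers.
- Single-temperature ΔH°/ΔS° decompositions inherit the
  temperature-invariance assumption; the fit quality statistic is
  surfaced so the user can judge it.
- The acceptance-scale studies run at desk scale (hundreds of synthetic
  gels, tens of fits); the real parameter panels behind the method
  require wet-lab gels and are out of scope.
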