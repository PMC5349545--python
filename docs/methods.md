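# Methods

`biasdx` quantifies and diagnoses biased agonism — a ligand's differential
efficacy for coupling a receptor (typically a GPCR) to distinct transduction
proteins — from concentration–response (CR) data, while guarding against
*system bias*: apparent response imbalance created by nonlinear amplification
or assay readout rather than by the ligand's chemistry. It implements nine
diagnostics side by side: seven classical receptor-theory bias-factor
calculators and two model-free tests on intrinsic activities, together with a
synthetic data generator that produces the canonical negative control (system
bias with no ligand bias) and positive control (an injected efficacy
perturbation in one pathway).

## Models fitted to CR curves

All regressions run on ln-concentration, which is numerically better behaved
than the plain-concentration forms, by bounded trust-region least squares
(SciPy `least_squares`, analytic Jacobians, objective tolerance 1e-10) with
multi-start seeding from plateau/half-max heuristics. A start whose converged
objective already matches a benchmark for the attainable minimum (1.5× the
curve's stated noise, or the 3-parameter-logistic objective for operational
fits) is accepted without running the remaining starts, so the estimator is
unchanged while typical fits cost one optimizer run.

* **3-parameter logistic** `r = E_max / (1 + (EC50/[L])^n)` — the workhorse
  for E_max/EC50 ratios, curve inversion and intrinsic activities.
* **2-parameter logistic** (maximum pinned at 1) — reference-agonist curves
  only; its asymptotic 95% band feeds the trajectory construction.
* **Operational (Black–Leff) model**
  `E = r_max (τ[L])^n / (([L]+K_d)^n + (τ[L])^n)` with transduction
  coefficient τ = R_t/K_E. R_t and K_E are not separately identifiable and
  exist only inside τ. Identities used throughout:
  `E_max = r_max τ^n/(1+τ^n)`, `EC50 = K_d/((2+τ^n)^{1/n} − 1)`; at n = 1
  these give `EC50 = K_d/(1+τ)` and `E_max/EC50 = r_max τ/K_d`.

Parameter covariance and confidence bands come from the standard asymptotic
linearization (Gauss–Newton J at the optimum, RSS/dof scaling, t quantiles).
Slope factors are bounded to [0.2, 5] and ln τ to [−12, 12] to keep the
ill-identified regime finite; bound hits are reported as warnings. Fits are
unweighted by default (curves are replicate means); inverse-variance weighting
is a config flag. The input `resp_sd` column is treated as the standard
deviation *of the stored mean response* — the quantity that is fitted,
resampled and perturbed everywhere downstream.

### Identifiability and the global panel fit

A single curve cannot identify all operational parameters. With K_d free, τ
and K_d ride a ridge and only τ/K_d survives in the strong-agonist limit;
with K_d fixed, a *partial* agonist's curve still leaves (r_max, τ)
under-determined, because its EC50 loses its τ-dependence as τ → 0 and its
own plateau cannot pin the system maximum. Since r_max and the transducer
slope are system properties — identical for every ligand measured in the same
assay — methods 1 and 2 therefore estimate their per-ligand efficacy
parameters from a **global fit of the whole panel** with (r_max, n) shared:
per-ligand ln τ when K_d is fixed (method 1), per-ligand (ln τ/K_d, ln K_d)
when free (method 2). This is the construction that makes the per-ligand
composites well identified; fitted curve-by-curve, both methods produced
spurious nonzero "bias" on noiseless no-bias data. The per-curve
`fit_operational` remains available and documents the same caveat.

## Bias factors (methods 1–7)

All seven express, per ligand, `bias = log10( rel_A / rel_B )` where `rel` is
a relative-efficacy quantity scaled to the shared reference agonist within
each assay; the reference ligand's bias is identically 0 and swapping the two
panels negates every factor. Base-10 logs follow the ΔΔlog convention of the
bias literature.

1. τ ratios (global fit, K_d fixed from binding data).
2. τ/K_d ratios (global fit, K_d free).
3. E_max/EC50 ratios from logistic fits; equals method 2 exactly only at unit
   slope, so any ligand with |n − 1| > 0.3 (configurable) carries a warning.
4–6. Null-method (Stephenson–Furchgott) equi-effective occupancy ratios: at
   equal response, ε_r O_r = ε_t O_t, so O_r/O_t at equi-effective
   concentrations (computed by inverting the logistic fits; occupancy
   `[L]/([L]+K_d)`) estimates ε_t/ε_r. The variants differ in the response
   levels used — 4: one level at 50% of the smallest fitted E_max in the
   panel; 5: ten levels spanning 20–80% of the range common to all agonists;
   6: ten levels spanning 10–90% of each reference/test pair's own overlap.
   Ratios from multiple levels are combined as geometric means (the quantity
   is a ratio). In exact data all three coincide.
7. Double-reciprocal (Furchgott-plot) slopes: at equi-effective
   concentrations `1/[L_t] = slope·1/[L_r] + intercept` with
   `slope = (ε_t/K_t)/(ε_r/K_r)`; the slope is estimated by least squares
   with a free intercept over ≥5 levels and the bias factor is the log10
   ratio of the two panels' slopes.

### Significance: the Monte Carlo null band

A common 95% band about zero bias is obtained by parametric bootstrap under
the no-bias null: each curve's responses are resampled from
Normal(fitted value, resp_sd), all bias factors recomputed, and each draw
centred at the ligand's point estimate (the basic-bootstrap pivot b* − b̂) so
the pooled draws describe the estimator's dispersion about zero rather than
about the input panels' own noise offsets. The 2.5th/97.5th percentiles of
the pooled distribution give the band; a per-ligand variant is a config
option. The resampling is deterministic given its seed, and at least 100
draws are required. Per-ligand error-propagation tests are deliberately not
provided — the pooled Monte Carlo band is the package's single significance
criterion for methods 1–7.

## Model-free diagnostics (methods 8–9)

Both start from intrinsic activities (IA): each ligand's fitted maximum as a
fraction of the reference maximum, with its asymptotic SE. The **reference
trajectory** is the curve traced in the (IA_A, IA_B) plane by the reference
agonist's two fitted 2-parameter logistics (midpoints c, c′; slopes b, b′):

    Y′(Y) = 1 / (1 + (c′/c)^{b′} · ((1−Y)/Y)^{b′/b})

a monotone curve from (0,0) to (1,1) on which every unbiased ligand's IA pair
must lie — system bias bends the trajectory but, being a monotone map, cannot
reorder unbiased ligands. Its pointwise 95% band is propagated from the two
regressions' covariances by the delta method.

An observed IA pair is projected onto the trajectory by minimizing the
anisotropic (inverse-variance-weighted) distance
`d²(Y) = (Y−IA_A)²/sd_A² + (Y′(Y)−IA_B)²/sd_B²` over Y ∈ (0,1), via a coarse
512-point grid followed by bounded 1-D refinement (validated in the tests
against a 100 000-point grid search).

**Method 8 (rank order).** Projected points trace the identity line in rank
space. Their coordinates are perturbed with each ligand's own uncorrelated
Gaussian SDs (default 500 000 iterations; reduced scales are used in tests),
re-ranked per iteration, and the joint rank frequencies accumulated. The 95%
envelope is the highest-density region of the *pooled* joint density on the
integer rank lattice (cells sorted by descending frequency, included until
cumulative mass ≥ 0.95) — one contour per comparison, a band about the
diagonal; a ligand whose observed rank pair falls outside is called biased.
Per-ligand-position frequencies are retained in the result for diagnostics.
Ties in IA are broken by stable ligand-id order.

**Method 9 (trajectory distance).** Each observed pair gets an axis-aligned
95% ellipse with semi-axes √(χ²₂,0.95)·sd ≈ 2.45·sd (a 1-df convention,
1.96·sd, is a config option); its projection gets an ellipse whose semi-axes
are the trajectory band's half-widths along each axis at the projected point
(the x half-width via the inverse trajectory). The ligand is called biased
when the two ellipses are disjoint. Intersection is decided exactly (to
optimizer tolerance) by mapping one ellipse to the unit circle and minimizing
the scaled distance to the other's boundary; the verdicts are cross-checked
in the tests against 3600-point boundary sampling. The test works for a
single test ligand and its flags are invariant under swapping the assays.

Neither method quantifies the magnitude of bias; outputs are categorical
flags plus distances. Method 9's criterion — two 95% regions must separate
entirely — is conservative by construction: its false-positive rate on
unbiased panels sits well below the nominal 5% (method 8's pooled-envelope
rate is near nominal). Method 8 has a further structural property worth
knowing: a strongly biased ligand displaces the observed ranks of ligands
between its biased and unbiased positions by one, so when perturbation SDs
are small relative to IA spacing those neighbours can fall outside the
envelope too. This is a property of rank statistics with a contaminated
panel, not an implementation artefact; the method is designed for panels in
which most ligands are unbiased.

## The simulator

The generator emulates a panel of agonists with graded intrinsic efficacies
observed through two different saturating transfer functions:
occupancy `O = [L]/([L]+K_d)`, stimulus `s = ε·O` (times an optional injected
bias multiplier in pathway B — the ground truth), response `r = f(s)` with
`f(s) = r_max s^n/(K_E^n + s^n)`. With this hyperbolic f the curves satisfy
the operational model exactly (τ = ε/K_E), so methods 1–2 are well specified
on synthetic data; a logarithmic (non-saturating) transfer is available to
emulate model misspecification. Replicate noise is additive homoscedastic
Gaussian on the normalized response; curves store replicate means and
`resp_sd = noise_sd/√n_replicates`.

Default study conditions, fixed once: 12 ligands (reference ε = 1, test
efficacies geometric over 0.05–0.95), K_d geometric over 10⁻⁷–10⁻⁵ M, ten
log-spaced concentrations over 10⁻¹¹–10⁻³ M, 3 replicates, noise SD 0.02, and
transfer functions of unit slope differing 10-fold in sensitivity
(K_E = 0.1 vs 1.0) — strong system bias, no ligand bias. What the generator
does **not** emulate: heteroscedastic or non-Gaussian error, slow response
kinetics, receptor internalization, constitutive activity, inter-day drift.
Tests passing on these data therefore certify the statistical machinery under
its own assumptions, not robustness to every failure mode of real bioassays.

## Numerical choices and scales

* Normalization divides a panel by the reference agonist's fitted E_max; it
  is idempotent and scale-equivariant, and all bias factors are invariant to
  it (every method is reference-scaled).
* Monte Carlo defaults: 500 draws for the null band (methods 1–7; minimum
  100), 500 000 iterations for the rank-order test (minimum 1000). The test
  suite and the reproduction script run 200 band draws (150 for method 2,
  whose draws each refit a global model) and 20 000 rank iterations over 200
  repeated panels — scales chosen so the full suite runs on a laptop core in
  minutes while keeping Monte Carlo error well inside the asserted windows.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  stochastic output (fixtures, bands, rank densities) is bit-reproducible
  given its seed, and reports carry a provenance block (config hash, seed,
  version).
* Degenerate inputs: monotone-decreasing curves are rejected (antagonist mode
  unsupported); zero IA uncertainty is an error for projection (the metric is
  undefined); a projected point at a trajectory extreme triggers a warning
  (the band is undefined there); fitted maxima extrapolated beyond the top
  tested concentration are warned about, not excluded.

## Known limitations

* Methods 4–6 need measured K_d values; without them only methods 2, 3, 7, 8,
  9 run (the report logs the skip).
* The fixed-level strategies depend on the weakest ligand in the panel (the
  common level is a fraction of the smallest fitted E_max), so adding or
  removing a weak partial agonist changes methods 4–5 for every ligand.
* The null band is calibrated under the Gaussian replicate-noise model the
  simulator itself uses; on real data with heavier-tailed errors it will be
  anticonservative to an unknown degree.
* Method 8 requires a reasonably large, mostly unbiased panel spanning a wide
  IA range; it degrades (and warns) below ~6 ligands and cannot see bias that
  does not change rank order.
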