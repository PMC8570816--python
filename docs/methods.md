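# Methods

## Model

Scaled prediction scores x ∈ (0, 1) are modelled as a two-component beta
mixture g(x) = π_t f(x; α_t, β_t) + π_f f(x; α_f, β_f), π_t + π_f = 1. The
identification is fixed by construction: the component with the lower mean is
the *true* (binder) component, because low IC50 means strong predicted
binding. The model assumes (i) a single HLA allele per table — binding
preferences, and hence score distributions, are allele-specific; (ii) that
both the binder and the non-binder score populations are adequately described
by beta densities on the scaled axis; and (iii) that every record is a draw
from one of the two populations.

## Score scaling

x = clamp(log10(IC50), 0, B) / B, then clamped into [1e-6, 1 − 1e-6].

* `dataset_max` (default): B is the table's own maximum log10(IC50). This is
  the scaling under which the mixture is fitted per dataset.
* `fixed_bound`: B = log10(50 000) ≈ 4.699, the theoretical maximum of the
  NetMHCpan affinity scale, for cross-dataset comparability. Values above the
  bound are clamped to 1 − ε and counted, not rejected.

The endpoint clamp (ε = 1e-6) exists because beta densities are zero or
unbounded at 0 and 1 for many shapes; sub-1 nM predictions (log10 < 0) are
clamped to 0 before division so extremely strong binders map near 0 rather
than to negative values.

## Fitting

**Initialization.** Records are sorted by scaled score and split; each part's
raw moments are inverted to (α, β) by Pearson's method of moments
(α = ((1−μ)/σ² − 1/μ)·μ², β = α(1/μ − 1)) and the weights start at the split
fractions. EM is started from sorted splits at fractions 0.25, 0.5 and 0.75
and the run with the highest final log-likelihood is kept. The halving start
alone is not reliable: on weakly separated samples it can settle into a
degenerate optimum in which one component becomes near-uniform and absorbs
half the weight — the overall density still matches, but the component
attribution (and therefore every FDR/PEP value) is wrong. The three-start
scheme is fully deterministic and picked the correct basin in every condition
we evaluated.

**E-step.** Responsibilities W[i,j] = π_j f(x_i; α_j, β_j) / Σ_k π_k f(x_i;
α_k, β_k), computed from log densities with row-wise max subtraction. Rows
where both weighted densities underflow get (0.5, 0.5) and are counted.

**MM-step.** π_j is the mean responsibility; each component's weighted mean
and variance are inverted by method of moments. Degenerate moments
(σ² ≥ μ(1−μ)) are clamped to 0.999·μ(1−μ) — transient degeneracy can occur
early on skewed data — and a variance floor of 1e-12 guards single-support
components. Weights are renormalized each step.

**Constraints.** Two projection mechanisms keep the components attached to
their roles; projection (clipping into the admissible interval) is applied at
every MM iteration, which keeps the iteration well defined:

* *False component*: optional admissible (α_f, β_f) intervals, normally the
  min/max envelope of method-of-moments estimates from decoy score samples at
  several sizes (`constraints_from_samples`; JSON-serializable so users can
  precompute allele-specific ranges from their own decoy runs, for NetMHCpan
  or MHCflurry alike). When no decoy run exists, `--auto-false-constraints`
  derives a range from the input's own records with IC50 > 10 000 nM; note
  that this tail is a truncated sample of the false population, so the
  derived range is biased toward the tail and is an opt-in fallback, not the
  default.
* *True component*: when the input is essentially all decoys, the true
  component must not wander onto the decoy distribution. If the estimated
  π_t reaches zero while records above 10 000 nM exist, (α_t, β_t) are
  restricted to ±25% around the method-of-moments estimate from the records
  with IC50 ≤ 10 000 nM, and the restriction stays active for the rest of
  the fit.

**Termination.** The maximal relative change across all six parameters,
max |θ_new − θ_old| / max(|θ_new|, |θ_old|), below 1e-5 (a parameter zero in
both steps contributes 0); hard cap of 1000 iterations with a `converged`
flag rather than an exception.

**Imbalance detection.** The zero-weight trigger above cannot actually fire
under stable log-space arithmetic: a free component always sits inside the
data mass, so its mean responsibility stays bounded away from zero even on
pure-decoy input (the EM then simply splits the single population between
both components). The package therefore decides "is this really a mixture?"
explicitly: after EM, a single-component method-of-moments beta fit is
compared with the mixture by BIC (2 vs 5 free parameters). A genuinely
bimodal sample favours the mixture by a huge margin; if the single model
wins, the input is declared essentially one-sided. Direction: all-false when
records above 10 000 nM exist and the single fit's mean lies above the
scaled analog of 1000 nM, all-true otherwise. The dominant component is then
fitted to the whole sample with weight 1, the vanishing component keeps its
shape with weight 0, and in the all-false direction the true component is
additionally projected into the ±25% band described above. With π_t = 0 the
weighted statistics degrade gracefully: FDR = PEP = 1 everywhere, the right
answer for pure decoys.

## FDR and PEP

With F the beta CDF and f the PDF of the fitted components:

* FDR(x) = π_f F_f(x) / (π_t F_t(x) + π_f F_f(x)) — expected false fraction
  among all records with scores at or below x.
* PEP(x) = π_f f_f(x) / (π_t f_t(x) + π_f f_f(x)) — posterior probability
  that this record is false; reported alongside its complement, the true
  probability 1 − PEP.

Both ratios multiply each term by its mixture proportion — they are posterior
probabilities, and omitting the proportions makes the quantities depend only
on shape, not on how much true and false data there is. An unweighted
variant (the bare CDF/PDF ratios) is retained behind `weighted=False` /
`--literal-equations` for comparison; the mode used is recorded in the run
manifest. These two definitions satisfy an internal consistency identity —
FDR(t) equals the mixture-density-weighted mean of PEP over (0, t] — which
the test suite verifies by numeric integration.

No q-value-style monotonization is applied: reported FDR values are the raw
ratio above (monotone anyway whenever the components are stochastically
ordered).

## Synthetic data

`generate_synthetic` emulates the engineered benchmark mixtures used to
develop and evaluate the method: n_true draws from the true component and
n_false from the false component at a 1000:4000 default ratio, with decoy
draws below the scaled analog of IC50 1000 nM redrawn (decoys that strong
would plausibly be genuine binders; the redraw preserves counts and is
rejected as degenerate if fewer than 1% of draws would be accepted). Default
shapes are Beta(1.5, 8) for true and Beta(6, 2.5) for false — a strongly
left-shifted binder peak against a broad high-IC50 decoy peak, matching the
qualitative shape of real predicted-score histograms. Records carry
synthetic 9-mer peptides (structural realism only; the letters carry no
binding semantics), back-transformed IC50 values, and hidden truth labels;
rows are shuffled.

What the generator does *not* emulate: predictor-specific artifacts (score
discretization, per-length biases, the spike of decoys at the scale
maximum), contamination of "true" sets by misidentified spectra, and
non-beta-shaped populations. Passing tests on this generator therefore show
that the estimator recovers the model it assumes, under realistic sizes and
separations — not that real datasets satisfy those assumptions.

## Evaluation conditions and problem sizes

The evaluation battery (tests/test_acceptance.py, scripts/acceptance.py)
uses n = 5000 tables (1250 true : 3750 false), mirroring the benchmark
construction at desk scale:

* parameter recovery: true Beta(1.5, 8), false Beta(6, 2.5), π_f = 0.75, 10
  seeds — mean |π̂_f − 0.75| and per-shape mean relative errors;
* self-consistency: true Beta(2, 6) (mean 0.25), false Beta(7, 2) (mean
  0.78), 10 seeds — generate → fit → simulate from the fitted parameters →
  sorted-quantile (Q-Q) OLS R², slope, intercept, and two-sample KS;
* FDR calibration: the same labeled mixtures, estimated FDR at the 5%
  selection cut versus the empirical false fraction among selected records;
* imbalance: all-true (1000:0), all-false (0:4000), and 1000:8000 fits.

The recovery and self-consistency conditions sample their components
untruncated (no decoy exclusion): those evaluations measure recovery of
known beta parameters, which the exclusion would redefine. The Q-Q
regression realizes the "linear regression between real and simulated data"
diagnostic: it is the standard construction in which R² ≈ 1 measures shape
agreement while slope ≈ 1 / intercept ≈ 0 expose scale and location
mismatch.

## Known limitations

* A *truncated* decoy population (e.g. a pure-decoy set built with the
  1000 nM exclusion applied) is genuinely not a beta distribution; the BIC
  comparison then correctly prefers the two-component fit and no imbalance is
  declared, leaving the truncation shoulder modelled as a spurious "true"
  component. Pure-decoy inputs should be untruncated, or be fitted with
  explicit false-component constraints.
* The model assumes two populations; datasets dominated by an intermediate
  ("weak binder") population violate it silently.
* Constraint envelopes from decoy samples are point-wise min/max over a few
  sample sizes — narrow by construction; they are a stabilizer, not a
  confidence region.
* FDR/PEP quality is bounded by fit quality: on alleles whose binder score
  distribution is strongly right-skewed into the decoy region, component
  attribution is intrinsically uncertain.
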