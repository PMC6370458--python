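# Methods

`effconn` estimates directed, possibly cyclic, effective-connectivity
graphs from region × time BOLD matrices. This note documents the models,
the estimation procedures, the synthetic-data generator and its
calibration, the numerical choices, and the limitations a user should
weigh before trusting a result.

## The structural model

All search procedures target a linear causal system over `v` measured
nodes. In the i.i.d. view the records satisfy

    x = B x + e,        y = (I − B) x,

with `B` a `v × v` connection matrix (zero diagonal, cycles and 2-cycles
allowed) and `e` mutually independent non-Gaussian noise. In the dynamical
view the neuronal signals follow

    dz/dt = σ A z + C u,

with `A` carrying −1 on the diagonal (self-decay) and the causal
coefficients off it, `C = I`, and `u` external input. A directed edge
X → Y asserts that intervening on X while holding the other measured
regions fixed would change Y. A 2-cycle is the pair X → Y and Y → X —
direct feedback, the hard case for most estimators.

## Search procedures

### FAS-stable (adjacency search)

The skeleton phase of the PC-stable family. Conditional independence
X ⊥ Y | S is decided by comparing the penalized Gaussian scores

    BIC* = −2 ln ML + c·k·ln n

of the nested regressions X ← S and X ← {Y} ∪ S; `c ≥ 1` (penalty
discount) forces extra sparsity, `c = 1` is ordinary BIC. Ties keep the
edge (conservative). Conditioning sets of size `d` are drawn from
neighbor sets frozen at the start of each depth, which makes the output
provably independent of the column order. `k` counts covariates only; the
intercept is unpenalized. The single-direction regression (always the
first argument) is used; the symmetric variant would differ only on
near-tie decisions.

### FASK (orientation by skewness)

For every FAS-stable adjacency, FASK chooses among X → Y, X ← Y and
X ⇄ Y using second moments on the positive half-samples of the centered
data:

* **left-right rule** — orient X → Y iff
  E(XY|X>0)/√(E(X²|X>0)E(Y²|X>0)) − E(XY|Y>0)/√(E(X²|Y>0)E(Y²|Y>0)) > 0;
  the statistic is antisymmetric in its arguments.
* **2-cycle test** — declare X ⇄ Y when corr(X,Y) differs from both
  corr(X,Y|X>0) and corr(X,Y|Y>0) by a Fisher-z contrast significant at
  level α, with variance 1/(n₁−3) + 1/(n₂−3). Because truncation alone
  attenuates the correlation of any near-symmetric pair on both
  half-samples, the contrast is additionally evaluated as *partial*
  correlations given every subset (size ≤ 2 by default) of the variables
  adjacent to X or Y, and all subsets must be significant. This screened
  form is what keeps the false-2-cycle count near zero on simulated
  networks whose embedded nodes are only mildly skewed.
* **fallback** — a 2-cycle with near-cancelling opposite-sign
  coefficients can be marginally near-independent and invisible to the
  adjacency search; any non-adjacent pair whose two conditional
  correlations differ by more than 0.3 is re-added and oriented by the
  same rules.

The information source is the skewness of the BOLD signal. On symmetric
(e.g. Gaussian or uniform) data the conditional-moment contrasts carry no
orientation signal and FASK is not guaranteed correct; this is inherent
to the method, not an implementation artifact. Defaults: `c = 2`,
`α = 10⁻⁶`.

### Two-Step (constrained sparse ICA)

Step 1 learns the undirected support of `B` — either FAS-stable or
adaptive-lasso neighborhood regressions (each standardized column on all
others, per-coefficient weights 1/|β_init| from an unpenalized fit,
regularization multiplier ln(N)/2, a pair freed if either direction
survives). Step 2 maximizes the penalized ICA log-likelihood

    N ln|det(I − B)| + Σₜ Σᵢ [ln p(y_ti / hᵢ) − ln hᵢ] − λ ln(N) Σ|B_free|

over the free entries only, by L-BFGS from uniform-in-[−0.01, 0.01]
initialization. The source density `p` is the hyperbolic secant
(log-cosh score); a per-component scale `hᵢ` is profiled jointly, which
removes the bias a fixed-scale density would otherwise impose on cyclic
coefficients (the true `B` is then a stationary point of the likelihood).
Small initialization plus the sparsity penalty selects the stable cyclic
solution and sidesteps the ICA permutation ambiguity. Final estimates are
thresholded: |B_ij| ≥ τ becomes the edge j → i. `B` is reported on the
standardized (correlation) scale, so the thresholded graph is invariant
to rescaling the input. Presets: λ = 64 (FAS step 1) or 32 (ALasso) with
τ = 0.15 for simulated-data regimes; λ = 2, τ = 0.10 for the empirical
protocol. The L1 term is smoothed as √(B² + 10⁻⁸) so a quasi-Newton
optimizer applies; entries this close to zero are far below any useful τ.
Finite-sample note: at penalty ln(N)/2 the adaptive lasso occasionally
frees a spurious pair whose initial coefficient was chance-inflated
(probability ≈ P(χ²₁ > ln N) per coefficient); exact support recovery is
asymptotic.

### Lag-based baselines

* **MVGC** — full-conditional Granger causality: VAR order selected by
  BIC, per ordered pair an F-test of joint nullity of the source's lag
  coefficients in the target's full equation, Benjamini–Hochberg FDR at α
  over all v(v−1) tests (default α = 10⁻⁵). Both directions may survive,
  so 2-cycles are expressible.
* **MVARp** — lag-1 MVAR coefficients from the Yule–Walker relation
  Q₁ = A Q₀; each A_ij judged against a permutation null built by
  independently shuffling every column over time (defaults: 1,000
  permutations, two-sided α = 10⁻³). The diagonal is excluded from the
  graph.

Both assume the causal dynamics are visible at the sampling interval —
the assumption the undersampling experiment deliberately violates.

## Evaluation

Precision = TP/(TP+FP) and recall = TP/(TP+FN) at three levels:
adjacencies over unordered pairs (a 2-cycle is one adjacency),
orientations over ordered pairs (a 2-cycle is two directed edges; a
wrongly oriented edge is one FP plus one FN), and 2-cycles over unordered
pairs with both directions present. Ratios with empty denominators are
reported as NaN and excluded from averages. Matthews correlation over all
possible (un)ordered pairs summarizes the precision/recall trade-off for
tuning; ties between grid points go to the sparsest setting.

## The synthetic-data generator

The generator emulates resting-state BOLD from the standard DCM chain:
two-state Poisson inputs (exponential sojourns, mean 2.5 s up / 10 s
down) drive the linear neuronal ODE, whose output passes through the
balloon hemodynamic model (vasodilatory signal, inflow, volume,
deoxyhemoglobin; κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s, α = 0.32,
E₀ = 0.34, V₀ = 0.02), is sampled every TR, corrupted with Gaussian
measurement noise (SD 1), and high-pass filtered at 1/200 Hz by
Gaussian-weighted running-line detrending (the FSL convention; a DCT
filter is available behind a flag). Both the noise-free and observed
variants of every session are retained. Sessions are centered
individually before concatenation — without centering, differences
between per-session means manufacture covariance that none of the
sessions contain, an exact algebraic fact the tests assert.

Integration is explicit Euler at dt = 5 ms for both stages; the balloon's
positive states are integrated in log space so they cannot cross zero.
Ground-truth coefficients are sampled per session from a truncated
Gaussian (rejection, not clipping; test regime mean 0.5 in [0.3, 0.7],
training regime mean 0.4 in [0.2, 0.6]), signs flipped to build control
(inhibitory) cycle variants, and every draw is screened for linear
stability (all eigenvalues of σA in the left half-plane) and redrawn if
unstable — cyclic structures make instability easy to hit.

### Calibration (frozen constants)

Three constants are not dictated by the model and were calibrated once by
`scripts/calibrate_simulator.py`, then frozen:

* `sigma = 13.2 s⁻¹` — bisected so the mean lag of the peak
  cross-correlation between directly connected neuronal signals is
  ~50 ms. "Neuronal lag" is operationalized as the parabolic-interpolated
  peak of the lagged cross-correlation; a model-implied reading (1/σ)
  would give a similar order.
* `bold_gain = 5.86` — the BOLD signal is reported in arbitrary units;
  the gain fixes them so the mean per-node SD of the noise-free signal
  across the simple-network conditions is ~2 against unit-SD noise (SNR
  ~2/1). The *input amplitude* is deliberately not used as this knob: it
  is held at 1.0 so neuronal excursions (~0.1–0.3) keep the balloon in
  its quasi-linear regime. Driving it harder saturates the hemodynamic
  response, which measurably erases the skewness of multi-parent nodes —
  the very signal the non-Gaussian methods need — and sustained strongly
  negative drive (below ≈ −γ) collapses the modelled blood flow entirely.
* `transit_sd = 0.51 s` — per-node Gaussian jitter of the balloon transit
  time, scaled by the measured latency sensitivity (dlatency/dτ ≈ 0.97)
  so the SD of the impulse-response peak latency across nodes is ~0.5 s.
  Transit times are floored at 0.2 s.

The spectral-density summary (`spectral_exponent`) fits a line to the
log-log Welch spectrum between the model's two corner frequencies — the
input-process corner (1/2.5 + 1/10)/2π ≈ 0.08 Hz and the neuronal cutoff
σ/2π ≈ 2.1 Hz — the band in which the spectrum is power-law-like
(exponent ≈ 2.3–2.4). Below the first corner the telegraph input is flat;
well above the second the two Lorentzians compound toward slope −4.

### What the generator does and does not emulate

It reproduces the statistical regime that matters to these estimators:
hemodynamic blurring with node-to-node delay variability, realistic SNR,
mildly skewed marginals, session-to-session coefficient variability, and
the measurement-noise-induced partial-correlation leakage that creates
false adjacencies (conditioning on a noisy mediator does not block a
path; clean data show none of these false edges). It does not model
spatial mixing between neighboring regions, physiological (cardiac/
respiratory) noise, nonstationary task designs, or tract-length
transmission delays. Passing tests therefore certify behavior under this
generative model, not under empirical fMRI; on real data the skewness
assumption in particular must be checked before trusting FASK
orientations.

A synthetic stand-in for the macaque tracer-derived long-range cortical
subnetwork is provided (`synthetic_long_range_network`: 67 nodes, 161
edges of which 19 reciprocal pairs arranged over a random node order so
the cycle census stays in the low hundreds, base coefficients 0.05–0.1,
per-session heterogeneity +N(0.01, 0.01) on half the coefficients). It
reproduces the regime — tiny effects, sparse reciprocity — not the
empirical wiring; analyses that depend on the published table's exact
counts require the table itself (core-nets.org), which is not
redistributed here.

## Experiment harness

`run_study` implements the batch protocol: simulate a pool of sessions
(fresh coefficient draw per session), per repetition concatenate a random
subset of 10 after centering, search, score; report means and SDs with
failed repetitions counted and excluded. `sensitivity_experiment` reports
100·(treatment − baseline)/baseline per metric, averaging over
repetitions before differencing; manipulable factors are measurement
noise (on/off) and TR (with session duration extended to hold 500
datapoints). `tune_parameters` selects grid points by mean
orientation-level MCC. `subsample_stability` runs the search on k random
half-subsamples (default k = 100) and keeps edges appearing in more than
a proportion t of them; when t is not given it is set from the
stability-selection error bound E[FP] ≤ q²/((2t−1)p) at a tolerated count
of 5%·p (small problems) or 1 edge.

All randomness flows from one seed through `numpy.random.Generator`;
study pipelines and the CLI are bit-reproducible from (config, seed), and
batch outputs carry a manifest recording parameters, input hashes and the
seed.

## Known limitations

* FASK's orientation and 2-cycle machinery needs skewness; symmetric
  non-Gaussianity defeats it (Two-Step does not share this restriction).
* Measurement noise at SNR 2 leaves adjacency false positives that no
  conditioning can remove (noisy mediators); adjacency precision on the
  densest cyclic toys sits near 0.7–0.8 rather than 1.
* The BIC* test assumes i.i.d. records; BOLD autocorrelation inflates
  the effective evidence, which is visible as occasional extra edges in
  the tiny-coefficient regime.
* Control (inhibitory) 2-cycles with near-cancelling coefficients are
  detectable only through the fallback scan and remain the hardest case.
* The MVGC undersampling degradation reproduces in direction but is
  milder here (~25–35% recall loss at TR 3 s) than the steepest published
  characterizations; the residual lag signal at TR 3 s rides on the wide
  hemodynamic response and the long-memory input process, and its size is
  sensitive to the calibrated lag and delay-jitter constants.
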