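# Methods

This note documents the statistical models implemented by `oligocount`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Cluster composition model

A diffraction-limited cluster is modeled as holding `i` monomers and `j`
oligomers of fixed size K, with `i ~ Poisson(m)` and `j ~ Poisson(k)` drawn
independently; the observable copy number is `N = i + K·j`. The predicted
distribution is the superposition

    P_Total(N) = Σ_{j=0}^{⌊N/K⌋} Poisson(j; k) · Poisson(N − K·j; m).

Assumptions: one oligomer size at a time (no simultaneous trimer + hexamer
mixtures), no interaction between clusters, and cluster assignment of
molecules that is memoryless enough for Poisson statistics to hold.

**Fitting.** Clusters with `N < K` cannot contain a K-mer, so on those bins
the model reduces to `e^{−k}·Poisson(N; m)`. The monomer mean m minimizes
the squared deviation of that sub-K prediction from the observed
frequencies, with k tied to the mean constraint `k(m) = max(0, (mean_N −
m)/K)` inside the objective — this keeps K = 2, which has a single sub-K
bin, solvable, where a shape-only fit would be underdetermined. The search
is a 256-point grid on `(0, mean_N]` refined by a bounded scalar
minimization between the best grid point's neighbours; this is
deterministic and immune to the objective's occasional multimodality. Once
m is fixed, k follows from the observed mean without any fit. K = 1 is the
single-Poisson null model with mean `mean_N`.

The observed mean is taken over observable clusters (N ≥ 1), matching how a
counting experiment measures it; empty clusters are invisible. The
generators retain zero-copy draws so that the truncation bias (observed
mean ≈ 6.77 when the full-ensemble mean is 6.6 under the default wild-type
condition, since P_Total(0) ≈ 0.025) is quantifiable in tests. Predicted
and observed distributions are compared without conditioning P_Total on
N ≥ 1; a sensitivity flag is not needed because the effect is part of what
the recovery tests measure.

**Scoring and selection.** Two goodness-of-fit statistics are computed over
N = 1..N_max (default 10):

    V = 1 / Σ (P_obs(N) − P_Total(N))²
    O = 1 / Σ (P_obs(N) − P_Total(N))² / P_obs(N)

Both increase as the fit improves; a perfect fit is represented by an
+infinity sentinel that orders above all finite scores. In the O sum, bins
with `P_obs = 0` are excluded — the `P_obs` weight exists precisely so that
large relative errors on rare events cannot dominate, and an empty bin is
the limit of that situation. Ties in the K scan break toward the smaller K
(parsimony); this makes an exactly-Poisson histogram select K = 1 even
though every K with k → 0 fits it equally well. A candidate K whose sub-K
bins are all empty cannot be fitted; it is recorded with NaN scores and
skipped rather than aborting the scan, since neighbouring K remain
informative. Prediction vectors extend to mean + 12 SD so the truncated
tail is below 1e-9.

Observed bins above N_max do not enter the scores; with default settings
the scored window covers ≥ 97% of the probability mass under the wild-type
condition.

## Photobleaching copy-number estimation

Each fluorophore survives each frame with probability `1 − q` (geometric
lifetime; photoblinking is not modeled), so the ensemble intensity decays
as `a·N·(1 − q)^t` above baseline, where a is the unit brightness of one
fluorophore.

**Step counting (small N).** Steps are located by a penalized
piecewise-constant change-point fit: optimal partitioning by dynamic
programming on the residual sum of squares with penalty `2σ̂²·log T`, σ̂
estimated from the MAD of first differences. Segment levels are then
quantized to integer fluorophore counts anchored at the baseline
(round-half-away-from-zero) and constrained to be non-increasing in time,
since bleaching never adds fluorophores. This quantization is what rejects
spurious sub-`min_step_fraction·a` steps (default fraction 0.5) and makes a
drop of height ≈ 2a count as a simultaneous double bleach. On noise-free
traces the count is exact for any N; at noise SD = 0.2a the per-trace exact
recovery rate is ≥ 95% for N ≤ 6 (measured at 200 traces per N).

**Exponential branch (large N).** When step counting finds more than
`stepwise_max` copies (default 6, the inclusive end of the small-cluster
regime) or fits the trace worse than an exponential decay does, the copy
number is `N = round(I₀/a)` with I₀ the first-frame intensity minus the
baseline (median of the final 10% of frames unless supplied). Using the
measured initial intensity rather than the fitted amplitude keeps the
noise-free case exact and the noisy case unbiased; the exponential fit
(`scipy.optimize.curve_fit` on `I₀e^{−rt} + b`) supplies the rate and the
residual used for branch adjudication. How smooth-vs-stepwise profiles are
adjudicated near the boundary is not something the counting procedure
itself pins down; the residual-comparison rule here is a documented choice.

**Unit-step calibration.** a is the median of single-step heights across
the experiment's stepwise traces, where "single" means within
`[0.5a₀, 1.5a₀)` of a running estimate seeded by the mode of all step
heights and iterated to convergence; heights near 2a (double bleaches) are
thereby excluded. At least 5 stepwise traces are required. All estimates
are scale-equivariant: multiplying traces and a by the same constant leaves
counts unchanged.

Labeling efficiency is not deconvolved: measured counts are applied
directly, appropriate when labeling exceeds ~90%.

## Latent-oligomer posterior and vesicle capture

Under the fitted mixture, the number of oligomers n in a cluster of N
copies has posterior

    P_n(N) = Poisson(n; k)·Poisson(N − K·n; m) / Σ_j Poisson(j; k)·Poisson(N − K·j; m)

over n = 0..⌊N/K⌋. If n oligomers capture a vesicle with probability p_n,
the cluster-level capture probability is `P_bind(N) = Σ_{n≥1} p_n·P_n(N)`.
p₀ is fixed at 0 (clusters without oligomers do not capture), and p_n
saturates at p_{n_max} beyond the highest distinguished count n_max,
mirroring the "n_max or more oligomers" grouping of capture data. Capture
is a single Bernoulli event per cluster; multiple-vesicle occupancy and
arrival kinetics are out of scope.

The p_n are fitted by maximizing the Bernoulli log-likelihood over
`[0, 1]^{n_max}` with multistart L-BFGS-B (analytic gradient; probabilities
clipped at 1e-10 inside the logs). Because P_bind is linear in p with
nonnegative posterior coefficients, the likelihood is well behaved and the
multistart is insurance rather than necessity. A count-weighted
least-squares-on-curve mode is provided for procedural comparison with
curve-matching analyses; the two agree within sampling error on simulated
data. No monotonicity constraint is imposed on p_n.

## Domain imaging and quench-corrected enrichment

The generator rasterizes non-overlapping disk domains with gamma-distributed
areas (defaults: mean 1.7 µm², SD 0.2 µm², 12 domains on a 256×256 field at
0.16 µm/pixel) into a pixel mask. The without-lipopeptide image carries
uniform reporter density d₀; the with-lipopeptide image carries `E·d₀`
inside domains and a compensating lower density outside so the total
molecule count is identical between the pair. Per-molecule brightness
inside domains is multiplied by a uniform quench factor `q ∈ (0, 1]`; the
lipopeptide channel is nonzero only inside domains.

Segmentation thresholds the lipopeptide channel (Otsu by default — the
choice of threshold on well-separated bimodal data is uncritical), labels
8-connected regions, and drops regions below 0.1 µm² (sub-resolution
single-pixel noise). The enrichment estimator computes, after background
subtraction,

    ΔF   = F_total_without − F_total_with          (quench deficit)
    fold = [(F_domain + ΔF)/A_dom] / (F_total_without/A_total)

Under the model's assumptions (uniform in-domain quenching, molecule
conservation, uniform enrichment), `F_domain + ΔF = c·E·d₀·A_dom` exactly,
so the estimator returns the true fold to floating-point accuracy on
noise-free pairs — verified across an (E, q) grid — and is invariant to
global intensity rescaling. A negative deficit beyond a small tolerance
(inconsistent pair) is clamped to zero with a warning. Whether enrichment
is actually uniform inside a domain is below optical resolution; the
estimator reports only the mean fold. No PSF, camera gain/EMCCD noise,
drift, or flat-field effects are modeled; passing tests therefore validate
the estimator's algebra and its noise robustness only to additive Gaussian
pixel noise, not to instrument-specific artifacts.

## Synthetic conditions and problem sizes

The default wild-type condition is a monomer + trimer mixture with m = 2.2
and k = 4.4/3 ≈ 1.467 (full-ensemble mean 6.6 copies/cluster) at n = 878
clusters, with per-trimer capture probabilities (0.17, 0.55, 1); the
hexamer condition is m = 2.0, k = 1.0, K = 6 at n = 226 with capture
probabilities (0.8, 1); the C2C-mutant capture condition uses per-trimer
probabilities (0, 0.09, 0.23, 0.43, 0.53). Parameter-recovery checks run at
n = 10⁵ clusters, where capture probabilities are recovered to within ±0.01
and model selection is essentially deterministic; at the experimental
n = 878, K = 3 is selected by the O statistic in ≈ 94% of replicates (V:
≈ 89%) and the fitted m is unbiased to within 0.2. Bleaching-trace studies
use 200 frames at q = 0.04 per frame so that residual unbleached
fluorophores are negligible (survival ≈ 3·10⁻⁴).

## Reproducibility

Every generator takes an explicit seed; pipeline stages derive per-stage
substreams as `root_seed XOR sha256(stage_name)` (mod 2³¹), so adding a
stage does not perturb the draws of the others, and identical configs give
byte-identical reports. `scripts/acceptance.py` recomputes the headline
quantities from scratch at 10⁵ clusters per stochastic item in a few
seconds on one CPU.

## Known limitations

- One oligomer size at a time; no Bayesian posterior over K.
- No photoblinking or dark-state correction in trace simulation/counting.
- Cluster detection (spot finding) is upstream of this package; cluster
  tables start downstream of detection.
- The enrichment estimator assumes uniform in-domain enrichment and
  quenching; nanoscale heterogeneity is not modeled.
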