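# oligocount

Single-molecule copy-number counting and oligomer-state inference for
membrane-bound protein clusters imaged by TIRF microscopy.

When a protein such as the synaptic priming factor Munc13-1 assembles on a
supported bilayer, each diffraction-limited cluster holds some number *N* of
copies, but *N* alone does not reveal the oligomeric state: a cluster of four
copies could be four monomers, a monomer plus a trimer, or two dimers. This
package implements the statistical machinery that resolves this ambiguity:

- **Photobleaching step counting** (`oligocount.bleach`). The copy number of
  a small cluster is read off its bleaching trace: a penalized
  piecewise-constant change-point fit locates the steps, and a drop of height
  *h* contributes `round(h/a)` copies, where *a* is the unit intensity of one
  fluorophore calibrated from single steps. Large clusters bleach smoothly;
  there *N = I₀/a* with *I₀* the initial intensity above baseline and the
  decay checked against an exponential fit.
- **Dual Poisson mixture model** (`oligocount.oligomer`). Monomers and
  fixed-size K-mers per cluster each follow independent Poisson laws (means
  *m* and *k*), so the predicted copy-number distribution is
  `P_Total(N) = Σ_j Poisson(j; k)·Poisson(N − Kj; m)`. *m* is fitted on the
  sub-K histogram bins (which cannot contain a K-mer) and *k* follows without
  a fit from the observed mean: `k = (mean_N − m)/K`. Candidate K are scored
  by two goodness-of-fit statistics — `V = 1/Σ(P_obs − P_Total)²` and
  `O = 1/Σ(P_obs − P_Total)²/P_obs` — and the K maximizing them is selected.
- **Cooperative vesicle capture** (`oligocount.capture`). The latent number
  of oligomers *n* in a cluster of *N* copies has posterior `P_n(N)`; if *n*
  oligomers capture a vesicle with probability *p_n*, the per-cluster capture
  probability is `P_bind(N) = Σ p_n·P_n(N)`. The *p_n* are fitted from
  per-cluster (N, bound) data by constrained maximum likelihood.
- **Quench-corrected domain enrichment** (`oligocount.imaging`). Lipid
  reporter dyes self-quench inside dense domains, so in-domain fluorescence
  underestimates density. Comparing total fluorescence against a matched
  uniform bilayer, redistributing the deficit over the domain area, and
  adding it back to the measured in-domain signal recovers the true
  enrichment fold exactly under uniform in-domain quenching.
- **Synthetic data with ground truth** (`oligocount.synthetic`). Generators
  for cluster compositions, Bernoulli capture outcomes, stepwise bleaching
  traces, and with/without-lipopeptide image pairs, so every estimator can be
  validated by parameter recovery without any raw microscope data.

## Worked example

Simulate a wild-type-like experiment — 878 clusters of a monomer + trimer
mixture (*m* = 2.2, *k* ≈ 1.47) with per-trimer capture probabilities
(0.17, 0.55, 1) — and run the full analysis:

```yaml
# run.yaml
seed: 7
synthetic:
  oligomer_size: 3
  monomer_mean: 2.2
  oligomer_mean: 1.4667
  n_clusters: 878
  capture_probs: [0.0, 0.17, 0.55, 1.0]
```

```sh
oligocount run-all --config run.yaml --out demo
# selected K=3 (m=1.89, k=1.68); report in demo/report.json
```

The K scan written to `demo/k_scan.tsv`:

```
 K     m     k        V       O
 1 6.923 0.000   95.747   7.306
 2 2.000 2.461  431.588  30.359
 3 1.886 1.679 1081.950 119.199
 4 2.752 1.043  270.239  22.844
 5 5.049 0.375  270.446  21.485
 ...
```

Both statistics peak at K = 3: the simulated population is correctly
identified as a monomer + trimer mixture, with monomer mean 1.89 and trimer
mean 1.68 per cluster (sampling noise around the generating 2.2 and 1.47;
the observed mean here was 6.92 copies/cluster). The refitted capture
probabilities in `demo/report.json` are (0.12, 0.52, 0.98) for 1, 2, and
≥3 trimers against the generating (0.17, 0.55, 1). At n = 10⁵ clusters the
recovery tightens to within ±0.01 (see `tests/test_capture.py`).

The same stages are available individually (`oligocount simulate`, `count`,
`fit-oligomer`, `fit-capture`, `enrichment`) and as library functions.

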