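# immunopred

Peripheral-blood immunophenotyping is one of the few assays that can be
run before a cancer patient ever receives therapy, which makes it an
attractive source of predictive biomarkers for neoadjuvant immunotherapy.
In a multi-tube flow-cytometry design, each blood sample yields percent
abundances over thousands of *marker combinations* — full +/- sign
assignments over the ~10 surface markers of each tube (e.g.
`CD3+CD19-CD56+...`) — and the analytical question is which of those cell
phenotypes predict **major pathological response** (MPR, ≤10% viable
malignant cells in the resected tumor) to checkpoint-inhibitor therapy.

`immunopred` is a tested, reproducible implementation of that analysis
chain for biostatisticians and computational immunologists:

* **Synthetic cohorts** — a generative model of the trial population
  (stage, histology, PD-L1 tumor proportion score, EGFR/ALK status,
  surgery and resection branches, a viable-tumor mixture with a pCR atom,
  exponential survival) and of the immunome itself: a latent
  cell-population mixture with exact per-tube compositional closure,
  limit-of-detection zero inflation, and planted effects with an honest
  Cohen's-d contract. Nothing downstream needs access-restricted data.
* **Feature construction** — observed-phenotype enumeration,
  impossible-combination exclusion rules (`CD3+CD19+` cannot exist),
  inclusive ≥50% detection filtering, and the ≥85% prevalence split.
* **I-index selection** — extreme-cohort construction (13 strongest
  regressors vs 13 strongest progressors), rank normalization, and a
  random-subsampling importance ranking: *B* subsets of *m* = 30 features
  are drawn, each feature scored by the Jensen–Shannon divergence between
  its per-class histograms, and importance is null-centered by label
  permutation so that "importance > 0" is a meaningful retention rule.
* **GAM–LASSO** — a logistic generalized additive model with cubic-spline
  smooths and a group-lasso penalty that zeroes whole smooths,

  minimize&nbsp;&nbsp; (1/n) Σᵢ log(1 + e^(−yᵢ ηᵢ)) + λ Σ_g √p_g ‖β_g‖₂,
  &nbsp;&nbsp; η = β₀ + Σ_g B_g β_g,

  fitted by FISTA, with the penalty chosen by cross-validated AUC under a
  parsimony rule and with at most one *prevalent* feature admitted to the
  additive part (enforced exactly by singleton refits).
* **Endpoint statistics** — response classification, Clopper–Pearson /
  Wilson rates, 2×2 Fisher and Freeman–Halton r×c exact tests, Welch's
  t with Satterthwaite df, tumor mutational burden (mutations per Mb of
  ≥7× covered coding sequence), Kaplan–Meier / log-rank, exact binomial
  design power, and exact small-sample permutation correlations.

## Worked example

```bash
python examples/05_endpoint_statistics.py
```

prints, among other things:

```
MPR rate: 20% (29 of 143; 95% CI 14-28%, Clopper-Pearson)
MPR by PD-L1 TPS group (<1% / 1-49% / >=50%): Freeman-Halton P = 0.01
MPR by TMB <10 vs >=16 mut/Mb: Fisher P = 0.12
  MPR vs non-MPR: p = 8.6e-06
  exact binomial power 0.9974 (critical value: 15 responders)
```

— the MPR rate among the 143 evaluable patients with its exact interval,
the exact test linking PD-L1 expression strata to response, and the
single-arm design calculation (with 180 patients, 15 observed responders
reject a 5% null at one-sided α = 0.05 with 99.7% power against a 15%
alternative). The modeling side:

```bash
python examples/04_fit_and_predict.py
```

```
feature space: 183 combinations; 5 causal planted at d = 1.0
causal features and their importance ranks:
  rank   0  T07:CD45-CD8+CD3-PD1+TIM3-
  ...
model selected 7 smooths, 4 of them causal
training AUC 0.977 (apparent), held-out AUC 0.933
```

shows the pipeline recovering planted immunophenotype effects from a
synthetic 300-patient cohort and the expected apparent-vs-held-out gap.

The `immunopred` CLI chains the stages from a shell
(`immunopred simulate | features | select | fit | predict | endpoints |
run`); `immunopred run --seed 1 --out-dir run1` executes the whole
pipeline and writes a manifest whose outputs regenerate byte-identically
under the same seed.

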