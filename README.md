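# lineaburst

Species delimitation and diversification-rate-shift analysis on
time-calibrated phylogenies, built around the workflow used for
single-marker (COI-type) surveys of protist diversity such as the
Hyalospheniidae testate amoebae: collapse redundant sequences, delimit
putative species both by a 99% K2P-similarity threshold and by the
general mixed Yule-coalescent (GMYC) model, then ask when the delimited
lineages changed their diversification rate and how fast they net
diversified.

The intended users are molecular ecologists and systematists who have an
alignment and dated trees (e.g. from a Bayesian dating run) and want the
delimitation + diversification analysis to be scripted, seeded, and
testable — including synthetic data with known truth for every stage, so
the whole pipeline can be validated without any external downloads.

## What it computes

* **Deduplication** — sequences identical up to undetermined residues
  (N) are collapsed, keeping the one with the most determinate sites.
* **K2P distances & threshold clustering** — pairwise-deleted Kimura
  2-parameter distances, d = −½ln(1−2P−Q) − ¼ln(1−2Q), with saturated
  pairs flagged; single-linkage clusters at d ≤ 0.01 (the 99% rule).
* **GMYC** — single- and multiple-threshold maximum-likelihood fits of
  the mixed model b_i = λ₁k_i^p₁ + λ₂Σ_j[n_ij(n_ij−1)]^p₂ on a
  chronogram, the LR test against the single-process null (df = 3), and
  the delimited entities (clusters + singletons).
* **Rate-shift model selection** — pure-birth, constant birth–death and
  yule-2/3-rate fits on branching times; ΔAICrc = AIC(best constant) −
  AIC(best variable), with the critical value simulated under the fitted
  rate-constant null; lineage-through-time curves; ensemble analysis
  over a posterior tree sample with pooled shift-age intervals.
* **Net diversification** — Magallón–Sanderson stem and crown (their
  eq. 7) estimators r̂(n, t, ε) for extinction fractions ε ∈ [0, 1).
* **Simulators** — seeded Yule, piecewise-Yule, birth–death,
  multispecies-coalescent and GTR+Γ sequence generators that emulate the
  statistical structure each stage assumes.

## Worked example

Simulate a gene tree for 10 species sampled 4× each, with species
divergences far older than the within-species coalescent, then delimit:

```sh
$ lineaburst simulate gmyc --n-species 10 --samples-per-species 4 \
      --coalescent-scale 0.05 --seed 2 --out gene.nwk
$ lineaburst gmyc --tree gene.nwk --method single --out fit.json
10 entities (10 clusters, 0 singletons); LR p = 2.535e-14
```

The fit places the threshold at 0.667 Myr — between the oldest
within-species coalescence and the youngest species divergence — and
recovers all 10 species as entities; the LR statistic of 66.4 on 3 df
overwhelmingly rejects the single-process null, as it should when
coalescent structure is real. The JSON report carries the threshold age,
the four process parameters, both log-likelihoods and the full entity
membership.

Net diversification for 47 delimited entities in a 140-Myr-old crown
group, bracketing extinction:

```sh
$ lineaburst msrate --n 47 --age 140 --epsilon 0,0.9
epsilon=0	r=0.022550
epsilon=0.9	r=0.011935
```

i.e. about 0.023 net speciation events per lineage per Myr assuming no
extinction, falling to 0.012 if 90% of speciation is offset by
extinction — extinction always lowers the rate inferred from standing
diversity.

The same steps are available as library calls
(`lineaburst.gmyc.fit_gmyc_single`, `lineaburst.divshift.*`), and
`lineaburst pipeline` runs dedup → distances → clustering → GMYC →
ensemble shift analysis → rate estimates in one seeded, byte-reproducible
bundle.

## Documentation

`docs/methods.md` describes the models, likelihood conventions, the
synthetic-data generators and their limitations, and the numerical
choices in detail.
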