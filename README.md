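# colocpriors

Bayesian colocalisation of two association studies from summary
statistics, with **variant-specific prior probabilities of causality**.

Statistical colocalisation asks whether the association signals of two
traits in a genomic region — say a GWAS hit and an eQTL for a nearby gene
— are driven by the same causal variant. The classical single-causal-
variant model computes posterior probabilities of five hypotheses from
per-variant approximate Bayes factors:

* H0 — no association with either trait
* H1 / H2 — association with trait 1 / trait 2 only
* H3 — both traits associated, distinct causal variants
* H4 — both traits associated, a shared causal variant

and it conventionally assumes every variant in the region is equally
likely to be causal a priori. `colocpriors` drops that assumption: given
non-negative weights w₁ᵢ, w₂ᵢ (from any source of prior information), the
per-variant priors become

```
p_{k,i} = Q · p_k · w_{k,i} / Σ_j w_{k,j}          k ∈ {1,2}
p_{12,i} = (p12 / (p1·p2)) · p_{1,i} · p_{2,i}
```

with base priors (p1, p2, p12) = (1e-4, 1e-4, 5e-6) by default. The
normalisation guarantees that the *hypothesis-level* prior masses
(Σᵢ p_{k,i} = Q·p_k, and Σᵢ p_{12,i} = Q·p12 when one trait at a time is
weighted) are identical to the uniform-prior model — the weights move
prior mass between variants, never between hypotheses.

The package provides:

* **`coloc_engine`** — the weighted five-hypothesis posterior from
  summary statistics (`coloc_abf`) or per-variant log Bayes factors
  (`coloc_from_lbf`), plus a brute-force configuration-enumeration oracle
  used by the test suite.
* **`bayes_factors`** — Wakefield approximate Bayes factors and weighted
  single-trait fine-mapping with credible sets.
* **`prior_sources`** — weight builders for four kinds of prior
  information: empirical eQTL–TSS distance densities (Gaussian KDE,
  Sheather–Jones bandwidth ×8, 512-point grid over ±500 kb),
  activity-by-contact enhancer–gene scores, Gnocchi non-coding constraint
  scores, and PolyFun per-SNP heritability tables.
* **`gwas_simulator`** — synthetic case-control summary statistics under
  H3/H4 with causal variants drawn from a supplied distance density
  (2,000 cases / 2,000 controls; effect = max of 100 N(0, 0.0025) draws;
  regions accepted once min p < 5×10⁻⁶).
* **`benchmark_eval`** — recall/precision and ROC sweeps against
  ground-truth gene-pair labels, GWAS peak merging, and
  significance-change reports.
* **`fixtures`** — deterministic synthetic bundles of every input format.
* a `colocpriors` CLI wiring all of the above.

## Worked example

Simulate a shared-causal (H4) pair in a 500-variant high-LD region whose
causal variant is drawn from a Laplace density centred at the TSS, then
colocalise with and without that density as the trait-1 prior:

```python
import numpy as np
import colocpriors as cp

config = cp.SimConfig.high_ld(n_variants=500)
rng = np.random.default_rng(7)
_, ld, maf = cp.simulate_haplotypes(config, rng)
tss = 1_000_000
positions = np.sort(rng.choice(np.arange(tss - 500_000, tss + 500_000),
                               size=500, replace=False))
density = cp.shape_density("laplace_at_tss")
pair = cp.simulate_pair("H4", density, tss, "+", positions, ld, maf, config, rng)

weights = cp.density_to_weights(density, positions, tss, "+",
                                variant_ids=ld.variant_ids)
uniform = cp.coloc_abf(pair.stats1, pair.stats2)
weighted = cp.coloc_abf(pair.stats1, pair.stats2, weights1=weights)

print("true causal variant:", pair.causal1)
print("uniform priors: ", {k: round(v, 4) for k, v in uniform.pp_dict().items()})
print("density priors: ", {k: round(v, 4) for k, v in weighted.pp_dict().items()})
print("top shared-causal variant:", weighted.snp_h4.argmax(),
      "posterior", round(weighted.snp_h4.max(), 3))
```

prints

```
true causal variant: 257
uniform priors:  {'PP.H0': 0.0023, 'PP.H1': 0.0023, 'PP.H2': 0.0048, 'PP.H3': 0.0023, 'PP.H4': 0.9883}
density priors:  {'PP.H0': 0.0, 'PP.H1': 0.0018, 'PP.H2': 0.0001, 'PP.H3': 0.0014, 'PP.H4': 0.9966}
top shared-causal variant: 257 posterior 0.998
```

The true causal variant sits 797 bp from the TSS, where the density prior
is largest: weighting raises Pr(H4) from 0.988 to 0.997 and the
per-variant shared-causal posterior singles out the true variant. The
same machinery is available from the shell — see `colocpriors --help`
(`coloc`, `finemap`, `make-prior`, `estimate-density`, `simulate`,
`evaluate`, `fixtures`).

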