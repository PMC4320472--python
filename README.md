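# xpopacc

Accuracy of **across-population genomic prediction**: deterministic
predictors, an empirical GREML/GBLUP validation pipeline, and a
multi-breed genotype simulator.

Genomic prediction estimates breeding values of genotyped selection
candidates from a reference population with phenotypes and marker
genotypes.  When the candidates belong to a *different* population (a
small cattle breed borrowing information from a large one, lines, or
human subpopulations), differences in linkage disequilibrium, allele
frequencies and allele substitution effects limit the achievable
accuracy.  `xpopacc` implements, for that setting:

- a **selection-index accuracy** per candidate,
  `r_i = r_G sqrt( g_i' [G_B + R_B se2/sa2]^-1 g_i )`, with genomic
  relationships built from **population-specific allele frequencies**
  (`x = (g-2p)/sqrt(2p(1-p))`, Yang-style `G = XX'/n`), including the
  two-reference-population block form;
- a **population-parameter accuracy**,
  `r_P = r_G sqrt( N h^2 / (N h^2 + Me) )`, with the effective number of
  chromosome segments `Me = 1/Var(G_ij - A_ij)` over within- or
  across-population pairs;
- the **empirical pipeline**: trait simulation with correlated allele
  substitution effects across populations, single-trait GREML with breed
  fixed effects on an adjusted pooled-frequency GRM, BLUP prediction of
  unphenotyped candidates, EBV-TBV correlations, and a bivariate GREML
  model that estimates the genetic correlation between two populations;
- a **gene-dropping simulator** producing breeds that diverged from a
  common ancestral haplotype pool, with shared short-range LD, drifted
  allele frequencies and paternal half-sib family structure, plus the
  matching pedigree (numerator relationship matrix by the tabular
  method, 7-generation truncation).

The genetic correlation `r_G` between populations — the correlation of
allele substitution effects — caps what across-population prediction can
achieve: both predictors and the empirical accuracy scale linearly with
it, which is the package's central validated property.

## Worked example

```python
import numpy as np
from xpopacc import (
    SynthConfig, simulate_multibreed_panel, build_grm,
    VarianceComponents,
)
from xpopacc.genotype_io import marker_qc, partition_candidates
from xpopacc.accuracy_determ import si_accuracy_per_candidate, pp_accuracy
from xpopacc.relationships import (
    truncate_pedigree, pedigree_nrm, effective_segments,
)

config = SynthConfig(n_populations=2, final_panel_sizes=(400, 100), seed=1)
panel, pedigree = simulate_multibreed_panel(config)
panel, report = marker_qc(panel)
part = partition_candidates(panel, 1000, seed=77)

grm = build_grm(panel, scheme="own_population", locus_subset=part.marker_indices)
ref = list(panel.ids[panel.populations == "POP1"])
cand = list(panel.ids[panel.populations == "POP2"])
vc = VarianceComponents.from_heritability(0.95, ["POP1", "POP2"])

det = si_accuracy_per_candidate(grm, ref, cand, vc, "POP1", r_g=1.0)
nrm = pedigree_nrm(truncate_pedigree(pedigree, focal_ids=list(panel.ids)))
me = effective_segments(grm, nrm, ref, cand, mode="across_population")
print(f"selection-index accuracy: {det.mean:.3f} +/- {det.se:.3f}")
print(f"Me across populations:    {me.me:.0f}")
print(f"population-parameter:     {pp_accuracy(len(ref), 0.95, me.me):.3f}")
```

prints

```
selection-index accuracy: 0.591 +/- 0.006
Me across populations:    482
population-parameter:     0.664
```

The mean selection-index accuracy over the 100 candidates of the second
population is 0.591 (standard error over candidates 0.006): with 400
reference individuals from the other breed and a near-unit heritability,
about a third of the candidate genetic variance is recoverable.  The
across-population effective number of segments is ~480 for these recently
diverged synthetic breeds, and the simpler population-parameter formula —
which assumes the markers capture all candidate genetic variance —
predicts 0.664, noticeably above the selection-index value, mirroring its
known optimism.  Running the same panel at `r_g=0.6` scales every
selection-index accuracy by exactly 0.6.

A command-line interface covers the same pipeline
(`xpopacc simulate-genotypes | qc | partition | grm | nrm | me |
simulate-trait | run`); `xpopacc run --config config.yaml --out results/`
executes configured scenarios end to end and writes a summary table.

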