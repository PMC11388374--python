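# kindred

Community reconstruction from low-coverage ancient genomes and skeletal
isotopes.

Early-medieval cemetery studies increasingly combine paleogenomes captured at
~1.2 M SNPs ("1240K") with strontium and collagen isotope measurements to ask
who founded a burial community, how its families were organised, and how
mobile its members were.  At ~1× coverage hard genotype calls are unreliable,
so everything here works directly on **genotype likelihoods** — the
probability of the observed reads given 0, 1 or 2 copies of an allele.
`kindred` packages the full analysis chain for such a study, together with a
synthetic-cohort generator that knows the truth for every quantity the chain
estimates.

## What it computes

* **Supervised admixture** — for admixture proportions *q* on the simplex and
  panel allele frequencies *f_k(s)*, the model maximises

  ℓ(q) = Σ_s log Σ_g GL(s,g)·Binom(g; 2, h(s)),  h(s) = Σ_k q_k f_k(s)

  by an accelerated EM with multiple restarts.  Confidence intervals come
  from a simple nonoverlapping block bootstrap (10 Mb physical blocks
  resampled with replacement); weakly differentiated panel populations swap
  ancestry between replicates, and pooling such a pair demonstrably narrows
  the interval.
* **Pairwise kinship** — maximum likelihood over the IBD coefficients
  (k0, k1, k2) using the Hardy–Weinberg conditional genotype-pair tables,
  evaluated directly on two individuals' genotype likelihoods.  π̂ = k1/2 + k2;
  degrees are binned on the kinship coefficient φ = π̂/2 at the power-of-two
  thresholds.  Pairs sharing < 10,000 SNPs are disregarded.  Calls are
  reconciled with independent estimators and assembled into pedigrees as
  connected components over edges of degree ≤ 3.
* **IBD-sharing networks** — segments > 12 cM (strict), edge weight
  π̂ = Σ lengths / genome cM with known siblings forced to 0.5, min–max
  rescaling to [0, 1], isolated nodes dropped, and topology summaries
  (nodes, edges, average degree = 2E/N).
* **Isotope analyses** — a two-tier local ⁸⁷Sr/⁸⁶Sr baseline (strict
  "local center" = nonadult mean ± 2 SD nested in a wider all-human ± 2 SD
  range, cross-checked against environmental samples), collagen quality
  control (%C > 13, %N > 4.8, atomic C/N in [2.9, 3.6]) and permutation
  contrasts of δ13C/δ15N between groups.
* **Mortuary statistics** — Cramér's V for grave-good × group contingency
  tables and two-sided permutation tests on group means, with the add-one
  p-value correction.

## Worked example

```python
import numpy as np
from kindred import (AdmixtureModel, PairKinshipModel,
                     emit_genotype_likelihoods, simulate_pedigree_genotypes,
                     simulate_reference_panel)
from kindred.simulate import PedigreeSpec

panel = simulate_reference_panel(K=3, S=20_000, F=0.1, seed=7)
spec = PedigreeSpec(
    founders={"F1": np.array([0.7, 0.2, 0.1]), "F2": np.array([0.1, 0.8, 0.1])},
    children=[("KID", "F1", "F2")],
)
haps, truth = simulate_pedigree_genotypes(panel, spec, seed=8)
gl = emit_genotype_likelihoods(haps, panel.gmap, depth=1.0, eps=0.005, seed=9)

res = AdmixtureModel.from_matrix(gl, panel, "KID").fit(restarts=10, seed=10)
print(res.summary())
```

```
Supervised admixture (genotype-likelihood EM)
=============================================
individual:        KID
informative sites: 12627
log-likelihood:    -11443.475
restarts:          10
converged:         True
---------------------------------------------
population       proportion
POP1                 0.3907
POP2                 0.4808
POP3                 0.1285
```

The child's true admixture is the parental average (0.4, 0.5, 0.1); at 1×
coverage the estimate lands within ~0.03 of it.  Block-bootstrap SDs
(`res.bootstrap(B=20, seed=11).sd`) are ≈ 0.016–0.019 per component here.
The same likelihoods drive kinship:

```python
kin = PairKinshipModel.from_matrix(
    gl, panel.pooled(["POP1", "POP2", "POP3"]), "F1", "KID").fit()
print(kin.summary())
```

```
Pairwise relatedness (genotype-likelihood ML)
=============================================
pair:            F1 - KID
co-covered SNPs: 7948
k0, k1, k2:      0.0071, 0.9929, 0.0000
pi_hat:          0.4964
degree class:    parent-offspring
```

A parent–offspring pair expects (k0, k1, k2) = (0, 1, 0) and π̂ = 0.5.

The whole synthetic-to-report workflow (simulate → ancestry → kinship →
ibd-net → isotope → mortuary → report) runs from the command line:

```
kindred pipeline --seed 1 --out myrun
```

writing plain-text intermediates plus `report.json`; every stage can be rerun
in isolation from the on-disk files.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and its
deliberate simplifications, numerical choices, and known limitations.
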