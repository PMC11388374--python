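# Methods

This note records the models implemented in `kindred`, the assumptions they
make, the defaults and why, and what the synthetic validation does and does
not demonstrate.

## Supervised admixture from genotype likelihoods

**Model.** One target individual, K fixed reference populations with
derived-allele frequencies f_k(s).  Given admixture proportions q on the
simplex, the derived-allele probability at site s is h(s) = Σ_k q_k f_k(s),
the genotype is Binomial(2, h(s)) under Hardy–Weinberg, and the data enter
as normalized genotype likelihoods GL(s, g):

    ℓ(q) = Σ_s log Σ_{g∈{0,1,2}} GL(s,g) · Binom(g; 2, h(s)).

Sites are treated as independent (no LD modelling), which is the standard
assumption for supervised clustering of capture data; its main cost is that
the naive likelihood-based intervals would be too tight, which is why the
uncertainty comes from a block bootstrap instead (below).

**Fitting.** EM: at each site the two allele copies are allocated to
population k with probability q_k f_k/h (derived copy) or q_k(1−f_k)/(1−h)
(ancestral copy), weighted by the genotype posterior; q is updated to the
mean allocation over 2S copies.  Plain EM mixes very slowly on weakly
differentiated panels, so each iteration cycle applies SQUAREM-style
extrapolation (two EM steps, a step-length extrapolation, one stabilizing
EM step) with a fallback to the plain double step whenever extrapolation
would lower the likelihood — the likelihood is therefore nondecreasing, and
the plain EM map is exposed separately (`_em_step`) and property-tested for
monotonicity.  Convergence: Δℓ < 1e-6 per cycle or 2,000 steps.  Restarts:
Dirichlet(1,…,1) initializations from a seeded generator, best likelihood
kept; 50 restarts by default (the convention for this analysis), far fewer
are adequate on well-differentiated panels.  Panel frequencies are clamped
to [1e-5, 1−1e-5] so fixed sites cannot produce infinite terms.  Sites with
no reads carry the uniform triple (1/3, 1/3, 1/3); they shift ℓ by a
constant and are skipped during fitting.

**Block bootstrap.** Chromosomes are partitioned by physical position into
contiguous nonoverlapping 10 Mb blocks (the trailing short block is kept);
each replicate draws N_blocks blocks with replacement from the pooled list
and re-estimates q with 5 restarts, the first warm-started at the point
estimate.  The warm start preserves mode identity while the remaining
random restarts still allow label switching between confusable ancestries —
the mechanism that inflates per-component intervals and that pooling
(summing two components within each replicate before summarizing) removes.
Default B = 100 replicates; per-component SD and 2.5/97.5 percentile
intervals are reported.

## Pairwise kinship

**Model.** For coefficients k = (k0, k1, k2) — the probabilities of sharing
0/1/2 alleles IBD at a random autosomal locus —

    L(k) = Π_s Σ_{gi,gj} GL_i(s,gi) GL_j(s,gj) Σ_m k_m P(gi,gj | m, f_s),

with the standard Hardy–Weinberg conditional genotype-pair tables (m = 0:
independent genotypes; m = 1: one shared allele plus one independent draw
each; m = 2: identical genotypes).  Only sites where both individuals have
reads contribute; the co-covered count is reported and pairs under 10,000
shared SNPs are disregarded as unreliable.

**Optimisation.** The per-site mixture weights A_m(s) are precomputed, so
any L(k) evaluation is a 3-vector dot product per site.  A coarse simplex
grid (step 0.02) locates the basin; SLSQP refines within the simplex.  The
grid step is exposed because the exhaustive 0.01-grid oracle used in tests
must remain independent of the production path.

**Degrees.** π̂ = k1/2 + k2 (0.5 for parent–offspring and siblings).  Degree
bins operate on the kinship coefficient φ = k1/4 + k2/2, using the
power-of-two convention: φ > 0.354 duplicate; (0.177, 0.354] 1st degree —
split into parent–offspring (k0 < 0.1; PO expects k0 = 0, the margin
tolerates low-coverage noise) versus sibling; (0.0884, 0.177] 2nd;
(0.0442, 0.0884] 3rd; below that unrelated.  These cuts are the geometric
midpoints of the expected per-degree values, so misclassification is driven
by realized (Mendelian) variance in sharing plus estimation noise; on a
~3,500 cM genome at 1× and 100,000 sites both are small (≥ 95% of 1st–3rd
degree pairs classified at their pedigree degree in validation).

**Reconciliation and assembly.** The likelihood call is primary; calls from
independent estimators (e.g. an IBD-segment-based degree) are compared at
±0 levels for 1st degree and ±1 level for 2nd/3rd.  With at least half the
secondaries agreeing the call stands unflagged, otherwise it is flagged
discordant; with no secondary it is flagged single-source.  Pedigrees are
connected components over edges of degree ≤ 3 (pairs beyond 3rd degree are
listed as "distant connections" rather than merged).  Parent–offspring
edges orient older→younger only where age classes differ (adult → nonadult;
numeric ages are not modelled); generation depth is 1 + the longest
directed parent–offspring path, and the undirected parent–offspring span
(longest simple PO chain) is reported alongside because most adult-only
components cannot be oriented.

## IBD networks

Segments strictly longer than 12 cM survive; per pair, π̂ = Σ lengths /
genome length (default 3,540 cM, the sex-averaged autosomal map; the
synthetic pipeline uses its own simulated map length).  Unphased
low-coverage segment callers cannot separate IBD2 from IBD1, so sharing for
known siblings is systematically undercounted — their π̂ is set to 0.5,
with the sibling list supplied externally (from the kinship consensus).
Edge weights are min–max rescaled to [0, 1]; if all raw weights coincide
(including a single edge) every weight maps to 1, preserving "connected"
semantics.  Nodes without edges are dropped.  Average degree is defined as
2E/N for the undirected graph; note that one published network reports
43 nodes, 107 edges and an average degree of 5.08, whereas 2·107/43 = 4.98 —
the convention behind the printed 5.08 is not stated, and this package
sticks to 2E/N.

## Isotopes

**Strontium.** The strict "local center" is the nonadult mean ± 2 SD
(nonadults formed their enamel locally by construction); the wider local
range is the all-human mean ± 2 SD.  Environmental samples serve as a
consistency check (a warning flags any environmental value outside the
wider range) rather than as the primary definition, because a formula over
human values is always computable while environmental samples may be few.
The center is clipped into the wider range; with fewer than two nonadults
it falls back to the wider range, flagged.  Classification is exhaustive:
local_center / wider_local / nonlocal / unknown (missing ratio).  Sample
SDs use ddof = 1.

**Collagen QC.** Atomic C/N = (%C/12.011)/(%N/14.007); acceptance requires
%C > 13, %N > 4.8 and C/N within [2.9, 3.6], both ends inclusive (the
conventional collagen-preservation window).  %N = 0 fails with "undefined
ratio".  The screen is idempotent and order-independent.

**Diet contrasts.** Two-sided permutation test on the difference of group
means over QC-passing records; groups under 2 members get means but no
p-value.

## Permutation test and Cramér's V

The permutation p-value is (1 + #{|T_perm| ≥ |T_obs|})/(B + 1) with ties
counting as exceedances, so p ∈ (0, 1] and constant data give exactly 1.
Default B = 10,000.  Label permutations are drawn uniformly via seeded
random keys.  Cramér's V uses the Pearson χ² without continuity correction,
V = sqrt(χ²/(n·(min(r,c)−1))); no small-sample bias correction is applied.
For 2×2 tables V equals |φ|, which is cross-checked in the tests.

## Synthetic-data generator

The generator emulates exactly the features the estimators consume:

* **Panels** follow the Balding–Nichols model — ancestral frequency uniform
  on [0.05, 0.95], population frequency Beta(p(1−F)/F, (1−p)(1−F)/F) —
  validated against the Hudson F_ST estimator.
* **Founder haplotypes** are per-site Bernoulli(h) draws with
  h = Σ_k q_k f_k: admixture without linkage, matching the likelihood's own
  assumption.  **Meiosis** is Haldane (Poisson crossovers, uniform in
  genetic distance, no interference).  Transmission is recorded as
  piecewise-constant founder labels, so true IBD segments and realized
  k-coefficients are exact, and k1/2 + k2 equals the IBD1/2-weighted
  segment sum by construction (asserted to 1e-9).
* **Reads** are Poisson(depth) per site; each read reports the derived
  allele with probability g/2·(1−ε) + (1−g/2)·ε; likelihoods come from the
  binomial read model; zero-read sites are flagged missing.  Postmortem
  damage, contamination and reference bias are *not* simulated — the
  generator validates the estimators under their own model, not the full
  messiness of ancient libraries.
* **Isotopes**: local Sr is Normal(0.7090, 4e-4) with planted nonlocals
  offset by 10 local SDs; δ13C/δ15N are Normal with per-group offsets;
  collagen %N is Normal(15, 0.8) and the atomic C/N ratio is drawn directly
  (Normal(3.25, 0.08)) because stoichiometry in well-preserved collagen is
  tight — planted QC failures get degraded %C/%N instead.
* **Grave goods** are Bernoulli flags strongly enriched (p ≈ 0.86 vs 0.02)
  in a designated elite group, mirroring status-linked mortuary treatment.

Genome model: equal-length chromosomes with a uniform 1 cM/Mb map,
configurable count — desk-scale runs use 4–6 chromosomes of 100 Mb, while
kinship-variance-sensitive checks use 22 × 160 Mb (~3,520 cM), since
realized sharing variance scales inversely with map length.

## The synthetic pipeline and its defaults

The end-to-end workflow simulates a community of a five-generation
"founding family" (15 members, one predominant ancestry), a small
contrasting family, and unrelated individuals with mixed ancestry vectors;
founders of the main family are planted nonlocal and its members get a
+1.2‰ δ13C offset.  Default sizes: 20,000 sites over six chromosomes,
K = 4 populations at F = 0.1, 1.4× mean depth (the typical capture coverage
for this kind of cohort; it also leaves pair overlaps comfortably above the
10,000-SNP filter), base error 0.005.  Thresholds default to the analysis
conventions: min 10,000 shared SNPs, IBD length > 12 cM, 10 Mb blocks,
50 EM restarts, B = 10,000 permutations.  Every output file carries the
package version, seed and a configuration hash; reruns with an identical
configuration are byte-identical, and each stage restarts from the on-disk
intermediates.  Tests and the acceptance script run reduced configurations
(8,000–10,000 sites, fewer restarts and bootstrap replicates) — the
recovery checks reported are computed at the sizes stated alongside them.

## Known limitations

* No LD in founders and no damage/contamination in reads: passing tests
  show correctness of the estimators under their stated models, not
  robustness to every artefact of real ancient-DNA libraries.
* The admixture bootstrap resamples blocks of sites, not individuals; it
  captures genomic sampling noise and ancestry switching, not panel
  misspecification.
* Degree classification beyond 3rd degree is not attempted (calls collapse
  to "unrelated"), matching the pedigree-membership rule.
* Pedigree orientation uses age classes only; adult-only components report
  an undirected parent–offspring span instead of a directed depth.
* The IBD stage consumes segment tables; segment calling itself (HMM over
  imputed haplotypes) is out of scope.
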