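# Methods

## The model

`blocklmm` tests predefined SNP-sets — typically haplotype blocks — for
association with a quantitative trait by adding a set-specific random
effect to the standard polygenic mixed model.  For set *i*:

    y = X b + Z_c u_c + Z_ri u_ri + e
    u_c  ~ N(0, K_c  s_c^2)      polygenic background, K_c = additive GRM
    u_ri ~ N(0, K_ri s_ri^2)     set effect, K_ri a Gram matrix of the member SNPs
    e    ~ N(0, I s_e^2)

`X` holds the intercept, structure covariates (by default the top two
eigenvectors of the GRM) and any user covariates.  Genotypes are coded
−1/0/1 (homozygous reference / heterozygous / homozygous alternative).

### Kernels

* **K_c**: VanRaden method-1 GRM — columns centered by twice the deviation
  of the alternative-allele frequency from 1/2, cross-product scaled by
  2 Σ p_j (1 − p_j) over polymorphic markers.  The model description cites
  the additive relationship matrix without a formula; VanRaden method 1 is
  the field standard and is what we implement.
* **K_ri**: linear (`W W'/s`), Gaussian (`exp(−d²/2h²)`), or exponential
  (`exp(−d/h)`) kernel on the member-marker codes, with `d` the Euclidean
  distance between genotype rows.  The bandwidth `h` defaults to the median
  of nonzero pairwise distances ("median heuristic"); no bandwidth rule is
  prescribed by the method itself, so this is our default and it is
  overridable.  Set kernels are scaled (1/s for linear) and normalized to
  mean diagonal 1 so that weight estimates are comparable across set sizes;
  whether the reference implementation normalizes is not documented, so
  this is a deliberate choice here.
* Numerical PSD repair: when round-off drives the smallest eigenvalue below
  −1e−8 × (mean diagonal), a diagonal jitter restoring that bound is added
  and logged.

### Two-step variance estimation

The two genetic variances are re-parameterized through kernel weights.
Because the combined kernel enters the likelihood only up to a global scale
absorbed by the common variance s_s², the weights are constrained to the
simplex w_c + w_ri = 1 and one free parameter is optimized:

1. initialize w_c = w_ri = 1/2;
2. build K_s = Z_c K_c Z_c' w_c + Z_ri K_ri Z_ri' w_ri;
3. fit the single-kernel LMM y = X b + u_s + e, u_s ~ N(0, K_s s_s²), by
   the EMMA/GEMMA spectral device (below);
4. score the candidate by the restricted (default) or full log-likelihood;
5. optimize the free weight over [0, 1] with bounded L-BFGS, then refit at
   the optimum and report s_c² = ŵ_c s_s², s_ri² = ŵ_ri s_s².

Because a one-dimensional bounded L-BFGS can stall on flat or
boundary-pinned likelihoods, the optimum is guarded by an 11-point grid on
[0, 1] plus local bounded refinement; this also guarantees the nested null
(w_ri = 0) is always reachable, which keeps the deviance nonnegative up to
solver tolerance.  Whether the reference implementation optimizes the full
or the restricted likelihood is ambiguous; we standardize on REML (valid
for likelihood-ratio comparison here because X is identical in null and
alternative models) and expose ML as an option.

### Single-kernel solver

With H = K_s + δI and δ = s_e²/s_s², a one-time eigendecomposition of K_s
makes H diagonal in the rotated basis, so the profile ML/REML
log-likelihood over δ costs O(n·p) per evaluation.  δ is searched on a
100-point log-spaced grid over [1e−5, 1e5] followed by Brent refinement
(xatol 1e−6 on log₁₀ δ); β̂ is the GLS estimate at δ̂ and s_s² has the
closed-form profile estimate (q/n for ML, q/(n−p) for REML).  Estimates at
the δ bounds are returned as-is with a `boundary` flag; s_s² is floored at
1e−12 to keep δ defined.

### The set test

The null model drops the set term and is fitted once per phenotype, then
reused for every set.  The test statistic is the REML deviance
D = 2(l̂_R,model − l̂_R,null), clamped at 0 (REML noise can make it
infinitesimally negative).  Because s_ri² = 0 lies on the boundary of the
parameter space, D is referred to the mixture ½χ²₀ + ½χ²₁: p = ½·S_χ²₁(D)
for D > 0 and p = 1 at D = 0.

### Single-SNP baseline

Per marker, the marker enters as a fixed effect in the polygenic model and
is tested with an F-test (1 numerator df) on its coefficient.  Variance
components are estimated once under the no-marker model and reused for all
markers (the P3D/EMMAX device); exact per-marker REML is available behind a
flag and agrees with the approximation to within 0.2 −log₁₀p units at
n = 200 in our checks.  The exact statistic used by published single-SNP
baselines varies; the F-test is our stand-in and is flagged as such.

## Synthetic data

The generator emulates the properties of a structured inbred diversity
panel that the method's evaluation depends on; it is a first-class, tested
module, not a fixture.

* **Structure**: individuals belong to `n_subpops` subpopulations (default
  3).  Each haplotype block carries a pool of `ancestral_haplotypes_per_block`
  (default 4) ancestral haplotypes whose frequencies diverge across
  subpopulations via a Dirichlet with dispersion set by `fst` (default 0.1).
* **Within-block LD**: founder haplotypes (8 per subpopulation) are mutated
  copies (`founder_mutation_rate` = 0.03 per site) of an ancestral
  haplotype.  A fraction `tag_split_fraction` = 0.8 of sites are
  "tag" splits — thresholds on the ancestral index — so they are strong
  mutual proxies (the texture that produces synthetic associations);
  the rest are arbitrary bi-allelic splits of the pool, giving
  heterogeneous within-block r².
* **Between-block LD**: a founder's ancestral pick persists across adjacent
  blocks with probability 1 − `inter_block_remix_rate` (default 0.9), so
  block-level LD decays over roughly 2–4 blocks.  With 2 kb marker spacing
  inside blocks and 30 kb gaps between them, the LD reach is on the order
  of the 300 kb window used by the evaluation rules, as in the dense crop
  panels those rules were designed for.
* **Individuals** are mosaics of their subpopulation's founders with a
  founder switch probability of 0.02 per SNP; the two haplotypes of an
  individual are drawn independently (random mating within subpopulation).
  Markers with MAF < 0.025 are dropped, and the true block partition is
  returned re-indexed against the filtered panel.

Typical realized panels (n = 300, 50 blocks of 4–10 SNPs) show mean
within-block r² ≈ 0.2–0.3 versus ≈ 0.03–0.05 between blocks, and a causal
QTN pair correlation |ρ₁₂| averaging ≈ 0.5.

What the generator does **not** emulate: coalescent genealogies,
recombination maps in centimorgans, rare-variant site-frequency spectra,
and the specific LD profile of any real panel.  Passing tests therefore
demonstrate correctness of the machinery and the direction of the
set-vs-single-SNP contrast under block LD, not effect sizes on any
particular organism.

### Phenotypes

y = X₁β₁ + X₂β₂ + X₃β₃ + u + e with QTN1/QTN2 drawn without replacement
from one randomly chosen block with more than 4 members (read strictly as
≥ 5) and QTN3 uniform over the remaining markers.  |β₁| = |β₂|; the sign
of β₁ follows the scenario: **coupling** aligns it with the sign of the
in-sample correlation ρ₁₂ of the two QTN code vectors, **repulsion**
opposes it.

Scaling: effect magnitudes are calibrated in-sample under the sign-aligned
configuration so that (i) the combined QTN1+QTN2 term has realized variance
exactly 4× the QTN3 term, and (ii) the variance fractions of QTN block,
polygenic term (drawn MVN(0, GRM)) and residual are exactly
(`h2_qtn`, `h2_polygenic`, remainder) = (0.3, 0.3, 0.4) by default.  The
repulsion scenario reuses those magnitudes, the same polygenic draw and the
same residual draw, flipping only the sign of β₁ — so its realized QTN
signal is genuinely smaller, which is precisely the contrast the two
scenarios probe.  The exact scaling used in the original evaluation is not
published; these defaults are ours and are explicit parameters.  All
randomness flows from one integer seed; per-component substreams are
derived deterministically (SeedSequence spawn keys).

## Evaluation statistics

* **Inflator**: mean −log₁₀p of the L = 10 most significant false-positive
  units, where false positives are units outside every causal LD-set; the
  adjusted score is −log₁₀(p_a) = −log₁₀(p) − inflator (allowed to go
  negative).  A causal is "detected" when the adjusted score is ≥ 1.5.
* **LD collapsing**: two units merge when their genomic distance is
  ≤ 300 kb and their squared Pearson correlation is ≥ 0.35; blocks are
  represented by the per-sample mean of member codes (the block-level
  correlation is otherwise undefined), and block distance is the minimum
  gap between spans.  Causal units seed their own LD-sets first; the
  remaining units are collapsed greedily from the most significant
  unassigned unit — a choice of ours, since no collapsing algorithm for
  non-causal units is prescribed.  Each set is scored by its best member.
* **Recall / precision / F-measure** over collapsed sets at the BH-FDR 0.01
  and Bonferroni α = 0.01 thresholds; precision is defined 0 when nothing
  is called, F is the harmonic mean (0 when recall + precision = 0).
* **Causal-neighborhood AUC**: rank (Mann–Whitney) AUC of the causal unit
  against the non-causal units inside its own LD region (ties count ½);
  it measures whether a method finds the causal itself rather than its LD
  shadow.  For single-SNP results the statistic is averaged over QTN1 and
  QTN2, as is the pair's −log₁₀p.  An empty neighborhood leaves the AUC
  undefined for that iteration and it is skipped in the mean.
* p-values are floored at 1e−300 before logs.

## Study orchestration and problem sizes

`run_study` repeats: simulate a panel, plant the QTNs, simulate the trait
per scenario, run each method, evaluate.  The default desk-scale study uses
20 iterations of an n = 300, 50-block panel (the original evaluation used
100 iterations on a 414-accession, 112k-SNP panel; the statistics here are
means of the same per-iteration quantities at reduced scale).  A master
seed fans out to per-iteration seeds through SeedSequence spawn keys, so
iterations are independent and individually re-runnable; failed iterations
are recorded and skipped, and more than 20% failures aborts the study.

## Known limitations

* Set sizes much larger than n make the set kernel nearly singular; the
  spectral solver handles it, but weight estimates become diffuse.
* The P3D single-SNP approximation understates very large marker effects
  (exact mode exists but is slower).
* The type-I error of the mixture test is conservative in finite samples
  (the point mass at D = 0 exceeds ½), which our calibration checks
  accept by design.
* Missing genotypes are refused rather than imputed; impute upstream.
* Dominance/epistasis kernels, SKAT-style weighted rare-variant kernels,
  and fixed-effect haplotype-group tests are out of scope.
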