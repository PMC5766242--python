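# Methods

This note records the models, numerical choices and limitations behind
chaperoscope, at the level of detail a maintainer or reviewer needs to
re-derive the behavior of each stage.

## Expression preprocessing

Raw counts are transformed to log2 counts-per-million with small-count
offsets,

    logCPM(g, s) = log2((count(g,s) + 0.5) / (libsize(s) + 1) * 1e6),

the convention of the voom transform. The precision weights that voom
additionally estimates are not computed: no downstream stage consumes
them. Genes with all-zero counts in a tissue are retained (the offsets
keep logCPM finite), so gene-set membership is stable across tissues.

Gene-wise centering defaults to per-tissue scope, because both GSA and
Meta-PCA step 1 operate within one tissue at a time; global centering is
available (`scope="global"`). Centering a single-sample group yields zeros
with a warning. Matrices read/write transparently through gzip by file
extension. Pre-logged matrices (e.g. microarray sets) bypass the transform
via `--already-logged`.

## ΔGSA

Per-gene scores are pooled-variance two-sample t statistics (Welch is not
the default because the gene-set analysis literature's reference
implementation pools); genes with zero pooled variance score 0. The set
statistic is maxmean: the mean of the positive or of the negative member
scores, whichever is larger in magnitude, with ties resolved to the
positive side (covered by a test).

Significance combines two nulls:

* **Permutation**: condition labels are permuted `n_perm` times (default
  100). When the number of distinct label assignments is ≤ `n_perm`, all
  assignments are enumerated instead (logged).
* **Restandardization**: the permutation null values are rescaled to the
  mean/sd of maxmean over `n_perm` random gene sets of the same size drawn
  from all scored genes *on the observed scores*:
  `null_i = μ_rand + σ_rand · (m_i − μ_perm)/σ_perm`. This keeps
  genome-wide structure in the null, so a set is only significant relative
  to what arbitrary same-size sets do. When either spread is numerically
  zero (e.g. the set is the whole universe), the plain permutation null is
  used.

p-values use the add-one estimator `p = (1 + #{null ≥ obs})/(n_perm + 1)`,
so p = 0 cannot occur and the floor is 1/(n_perm+1); ΔGSA = p_down − p_up.
Permutations and random draws are index-shuffles generated independently
of the labels, and the t computation canonicalizes each permutation mask
on its first element, which makes the label-swap antisymmetry
ΔGSA → −ΔGSA bit-exact for a fixed seed (up to the measure-zero maxmean
tie). A single seed drives separate, spawned RNG streams for permutations
and gene-set draws.

Under the null, each ΔGSA cell is approximately uniform on [−1, +1] by
construction (it is a monotone transform of a uniform permutation
p-value), so calibration statements are about the *signed mean* across
cells and the tail uniformity of p_up, not about per-cell |ΔGSA|.

The genome-background scan draws, per sampling, as many non-chaperome
genes as there are chaperome genes (default 100 samplings × 100
permutations) and computes the chaperome's ΔGSA inside that reduced
universe, averaging over samplings; background draws never intersect the
chaperome.

## Differential expression and clustering

`de_test` fits the two-group model per gene. With moderation on, gene
variances are shrunk empirical-Bayes style: the prior (d0, s0²) of a
scaled inverse-chi-square distribution is fitted by moment matching on
log s²_g (solving trigamma(d0/2) = excess spread by bisection), the
posterior variance is the d0/df-weighted mix, and the moderated t gains d0
degrees of freedom. When the observed spread of log-variances is at the
sampling floor, shrinkage is complete and a normal reference is used.
Moderation off gives the ordinary pooled t, which is also the independent
oracle in the tests. BH adjustment is the standard step-up procedure
(via statsmodels). `signed_significance` is sign(effect)·(1 − p) from the
per-gene plain t.

Hierarchical clustering defaults to average linkage on Euclidean distance
(the source figures do not state the linkage; complete/ward are flags).
k-means uses 50 restarts; the reported statistic is the *median*
silhouette width. Cluster stability uses ordinary bootstrap over columns
with exact-membership reproduction as the support criterion — multiscale
(AU) bootstrap p-values are deliberately not implemented; ordinary support
answers the same stability question at a fraction of the machinery, so AU
figures from other tools are not comparable numbers.

## Meta-PCA

Step 1 computes PC1 of the per-gene-centered samples × family-genes
matrix per tissue (SVD; covariance PCA — genes are not scaled to unit
variance because inputs are centered logCPM; `--scale-genes` would be the
correlation variant). Loadings are unit-norm; family genes absent from a
tissue's matrix are masked and recorded. Step 2 retains tissues whose PC1
sample scores separate tumor from normal at p ≤ 10⁻⁴ (Student's t);
this filter is the method's noise gate, and its specificity on null
tissues is part of the acceptance suite.

Step 3 must resolve the sign ambiguity of PCA. The reference tissue is the
retained tissue with the smallest separation p; other tissues flip to a
positive dot product with it. The *global* orientation anchors the
reference vector to the expression axis — the bundle is flipped so the
reference's total loading mass is positive. Consequently an M-score
increase means increased family expression, and a family genuinely
downregulated in tumors keeps tumor M-scores below normal M-scores. The
alternative anchor (force tumor > normal in the reference) was rejected:
it would erase genuine downregulation and destroy the signed
parameter-recovery property the tests assert. The universal W_x is the
per-gene mean over retained tissues (per-gene denominators under masks),
renormalized to unit norm so M-score scales are comparable across families
with different tissue counts.

Scoring is the dot product over family genes; missing genes contribute 0,
and families with more than 50% of genes missing are flagged
`low-coverage`. M-scores are reported raw (not z-scored). Polar summaries
use empirical type-7 (linear-interpolation) quantiles at 5%/95%.
Validation (step 3') is a stratified 80/20 split with a 200-tree random
forest; any nonparametric ensemble satisfies the contract — the specific
classifier is a validation detail, not part of the data model.

## Interactome curation

Records are kept if the interaction type is PSI-MI 'physical association'
(MI:0915; exact term by default, descendants by flag) and both endpoints
resolve to Entrez ids within the node universe; UniProt accessions resolve
through the mapping table, bare numeric tokens are taken as Entrez ids,
everything else is dropped and counted. Self-interactions are retained
(`--drop-self` to exclude). Parse/filter counts are logged per stage so
the curation funnel is auditable.

The PSI-MI vocabulary is a DAG; "level" is defined as minimum depth from
the root, and up-propagation follows a minimum-depth path (ties broken by
term id) — this reproduces tree-like behavior deterministically on
multi-parent terms. Effective-method deduplication applies the pairwise
rule to a method set until stable: equal level + different id → distinct;
different levels → the deeper term up-propagates to the shallower level
and is discarded if the ids then coincide. A method is *binary* if its
ancestor closure meets a configurable branch-root set (default: two hybrid
MI:0018 and protein complementation assay MI:0090); the authors mark
"(binary)" without enumerating ids, so the set is config, not constant.

Curation levels follow the eight-row table (1 vs >1 effective method ×
binary involvement × 1 vs >1 PMID); tiers derive as SE = all edges,
ME = >1 PMID or >1 effective method, MM = >1 effective method, giving
MM ⊆ ME ⊆ SE by construction. Database-snapshot totals (hundreds of
thousands of raw edges) are version-bound quantities and are out of scope;
the shipped evidence corpus is a synthetic stand-in constructed to the
documented tier structure (666/220, 222/128, 132/96 with all ten families
in ME and a connected family meta-network) and includes decoy rows (wrong
type, unmappable ids, out-of-universe pairs, duplicates) so the counts are
genuinely recomputed by the pipeline, not read off the input.

## Meta-network and surfaces

Collapse conserves edges exactly: every gene-level edge becomes either one
unit of a meta-edge weight (endpoints in different families) or one unit
of its family's intra-count (kept on the meta-node, not drawn as a
self-loop). Kamada–Kawai target distances are shortest paths over edge
lengths 1/weight — strongly coupled families sit closer; the layout is
deterministic given the node order (circular initialization, no random
state), disconnected components are laid out independently and offset.
The topographic surface is a Gaussian radial-basis mixture
`z(x,y) = Σ_f v_f exp(−‖(x,y)−(x_f,y_f)‖²/(2bw²))` with default bandwidth
0.25 × median inter-node distance; it is linear in the family values and
its sign at each meta-node matches that family's value. Figure colour
scales are symmetric about zero (ΔGSA heatmaps fixed to [−1, +1]).

## Synthetic cohorts

`simulate_cohort` draws negative-binomial counts with gene-level
baselines log2-uniform on [3, 9] and dispersion α = 0.15
(var = μ + αμ²), the standard overdispersion surrogate for bulk RNA-seq
counts. Tumor samples multiply the mean of family genes by 2^δ(family,
tissue), homogeneous within the family, with optional per-gene jitter.
The reference study conditions used by the tests and the acceptance
script are 5 tissues × 30+30 samples per arm, 10 families × 12 genes with
δ cycling through {−2, −1, 0, +1, +2}, plus unprogrammed background genes.

What the generator does *not* emulate: tumor purity and subclonal
heterogeneity, batch effects, gene–gene correlation beyond the shared
family shift, microarray noise, and — importantly — composition-aware
normalization. Because logCPM is not TMM-corrected, programmed family
shifts change tumor library sizes and push unshifted genes slightly in the
opposite direction; restandardized ΔGSA then measures change *relative to
the genome*, which can move a δ = 0 family away from 0 when the
genome-wide shift is asymmetric. Passing tests therefore demonstrate
recovery of programmed relative effects under NB noise, not robustness to
the full messiness of real cohorts.

`simulate_ppi_corpus` draws per-pair evidence profiles and reports the
tier composition implied by its own draws, which the curation pipeline
must reproduce exactly. `simulate_mi_ontology` builds fixed-branching
trees with an optional multi-parent cross-link for the DAG rule.

## Determinism and problem sizes

Every stochastic component takes a seed and derives independent streams
from it (numpy SeedSequence spawning); the pipeline run from one config
and seed is byte-reproducible, including SVG output (fixed hash salt, no
date metadata). Test and acceptance problem sizes (e.g. 200 null repeats
at 100 permutations; 20 recovery seeds; 1000 oracle instances) were
chosen to keep the whole suite in the minutes range on a single core
while leaving the binomial noise of each check well inside its asserted
band.
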