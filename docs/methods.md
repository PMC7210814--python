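# Methods

## Statistical model and procedure

The pipeline treats a cohort as a log2-scale feature × sample matrix with a
binary tumor label g ∈ {0, 1} per sample (0 = non-tumor throughout, which
fixes the sign of logFC and of module–trait correlations).

**Differential screening.** Each feature is tested with an ordinary
pooled-variance two-sample t test, two-sided, with logFC = mean(tumor) −
mean(normal). This deliberately replaces the moderated t of empirical-Bayes
frameworks: at the sample sizes the pipeline targets (tens of samples per
group) variance moderation changes little, and the plain test keeps the
screening semantics exact and auditable. An optional variance floor guards
zero-variance features (a feature with identical constant groups gets t = 0,
p = 1; a constant-but-shifted feature is called with p = 0). FDR control is
Benjamini–Hochberg step-up; selection uses strict inequalities
(fdr < 0.01, |logFC| > 1) because that is how the thresholds are printed
wherever this style of screen is described. Whether the miRNA cohort should
also face the |logFC| cut is genuinely ambiguous in the literature this
pipeline follows; both thresholds are exposed (`mirna_fdr`, `mirna_lfc`) and
default to the mRNA values.

**Co-expression (WGCNA core).** Unsigned network: a_ij = |cor|^β, zero
diagonal, connectivity k_i = Σ_j a_ij. The scale-free fit index is the R² of
the log10–log10 regression of bin occupancy p(k) on mean bin connectivity,
sign-corrected by the negative of the slope, over 10 equal-width
connectivity bins (empty bins dropped; the bin count is config because it
moves R² and must be pinned). β is the smallest candidate power reaching
fit ≥ 0.85 (common WGCNA guidance), else the argmax of the fit — note the
argmax fallback can land on a large power and thin the network; restricting
the candidate list (e.g. 1..12 for small cohorts) is the practical remedy.

Topological overlap is the standard TOM; mutually isolated pairs
(denominator ≤ 0) get overlap 0 with a warning. Module detection is
average-linkage clustering of 1 − TOM with a deterministic three-rule
descent from the dendrogram root — a node is split when (a) it completes
above the static cut (0.995 × top merge height), (b) it completes above the
absolute cohesion height `max_cluster_height` = 0.99 on the 1 − TOM scale
(the analogue of dynamicTreeCut's cutHeight; without this rule,
average-linkage "ladders" of one module plus accreted noise genes survive
whole and are then discarded wholesale), or (c) its merge height stands
clear of both children by more than `gap_frac` = 0.10 of itself. Surviving
clusters need ≥ `min_module_size` = 20 genes; everything else is grey.
This is a simplification of dynamicTreeCut's hybrid algorithm chosen for
determinism and testability; it has no PAM-like reassignment stage, so a
handful of true module members can end grey at aggressive β (visible as
trait-module Jaccard 0.75–1.0 across seeds in the default scenario).

Module eigengenes are the first right singular vector of the standardized
module submatrix (unit norm over samples), sign-aligned to correlate
non-negatively with the module's mean standardized expression.
Module–trait significance uses the exact t transform
t = r√((n−2)/(1−r²)) with n − 2 df. The trait module is the non-grey module
maximizing |r| (ties: larger module, then lexicographic id).

**Motif scanning.** PFM → PWM per column: p_b = (count_b + 0.8·q_b)/(Σ +
0.8), PWM = log2(p_b/q_b), with uniform background q and total pseudocount
0.8 distributed by background — the Biostrings/TFBSTools convention. Every
window on both strands is scored; windows containing N score −∞; ties
resolve to the smallest forward coordinate, then the + strand. Pair ranking
uses the relative score (score − min)/(max − min) over each PWM's achievable
range, because raw bits are incomparable across motif lengths. The top-5%
cut retains ceil(0.05·N) pairs plus everything tied with the last retained
score; with consensus-planted synthetic promoters the tie block can exceed
the nominal count, which is reported, not suppressed.

**Triple network and shared-TF statistic.** The network is tripartite by
construction: only mRNA–TF and miRNA–TF edges, duplicates collapsed, and any
id claimed by two node classes is an error rather than a silent merge. For a
miRNA–mRNA pair sharing k ≥ 1 TFs the significance is the hypergeometric
upper tail P(X ≥ k) with universe N = the TF nodes present in the network
(a config switch substitutes the full motif-library size; the network
reading is the self-consistent one since both neighborhoods live there).
A `paper_literal` mode evaluates the single-term complement
1 − C(m,k)C(N−m,n−k)/C(N,n) for fidelity experiments; it is not a tail
probability and is not the default. No multiplicity correction is applied
at this stage (raw p < 0.05), matching the practice the pipeline
reproduces; BH across pairs is available. The saturated case k = m = n = N
evaluates to p = 1: a pair sharing everything in a universe with nothing
else to share carries no enrichment evidence.

**Enrichment and validation.** ORA re-uses the identical hypergeometric
tail (one implementation serves both modules) over GMT annotations, with
the annotation universe as background and BH across tested terms; a miRNA's
query set is its refined mRNA partners plus the TFs it shares with them —
the only network-derivable definition. The validation cohort is screened at
FDR < 0.05 with no fold-change cut, and miRNA ids are harmonized
(lower-case, "hsa-" prefix enforced, the published "has-" typo repaired)
before intersection, because public tables mix spellings freely enough to
produce spurious empty intersections otherwise.

## Synthetic study conditions

The generator emulates normalized two-group beadchip cohorts on the log2
scale. Defaults of the end-to-end scenario (all config):

| parameter | value | rationale |
|---|---|---|
| mRNA cohort | 2,000 genes, 60+60 samples | desk-scale stand-in for a ~450-sample, 18k-gene cohort |
| planted DE genes | 200 at effect 2.0 log2-units | a minority of features, comfortably detectable |
| noise_sd / de_noise_sd | 1.0 / 2.0 | DE genes carry gene-specific biological variance beyond array noise; without it the DE background forms a pseudo-module as trait-coherent as the planted module |
| modules | 3 × 40 genes, loadings U(1.5, 2.5) | intra-module correlation ≈ 0.8 at unit noise, typical of disease modules tight enough for soft-thresholding |
| module–trait r | 0.9 (first), 0.5 (others) | one strongly trait-driven module among weaker ones; driving all modules at 0.9 makes their latents correlate at r² = 0.81 through the shared trait and merges them |
| miRNA cohorts | 300 features; 68+21 and 78+88 samples | the two miRNA cohort shapes being emulated |
| DE miRNAs | 60 per cohort, 30 shared | shared set drives the validation-intersection test |
| TF motifs | 30 PFMs, length 10, dominant count 12:1 | JASPAR-typical length; at 8 bp the consensus recurs by chance in 2-kb promoters often enough to tie planted against unplanted pairs |
| promoters | 2,000 bp, GC 0.41 | the conventional upstream span; human-genome GC |
| miRNA–TF candidates | 150 primary, validation rates 0.6 / 0.5 | moderate cross-database agreement |

Planted motifs are the consensus sequence (per-column argmax), not
PFM-sampled instances, so top-rank recovery is deterministic; a consequence
is that planted pairs all hit the PWM maximum and tie at relative score 1.0.
Probe tables cover the three collapsing regimes; probe-level matrices add
0.05 log2-units of probe noise.

What the generator does **not** model: probe-level backgrounds and batch
effects, paired tumor/adjacent designs (groups are independent),
clinical covariates, correlated annotation terms, PFM-sampled (degenerate)
motif instances, and any coupling between a miRNA's expression and its TF
partners. Passing recovery tests therefore demonstrates that each stage
inverts its own generative assumption at realistic signal levels — not that
the pipeline is robust to the full messiness of public cohorts.

## Numerical choices

- BH adjustment delegates to statsmodels (`fdr_bh`); the test suite checks
  it against an independent step-up implementation, exactly.
- Scale-free fit needs ≥ 2 non-empty bins, else the fit is undefined for
  that β and skipped.
- Eigengene sign ties (exactly orthogonal mean expression) keep the SVD's
  orientation.
- The hypergeometric tail is scipy's survival function (`sf(k−1, N, m, n)`);
  counts are validated (k ≤ min(m, n), m, n ≤ N) before evaluation.
- Degenerate inputs fail loudly and early: empty collapsed matrices,
  groups with < 2 samples, zero-variance genes entering adjacency,
  promoters shorter than a motif, identity clashes between node classes.
- All randomness flows from one seed through SHA-256-derived per-stage
  substreams (each below 2³¹), so stages are individually reproducible and
  two runs with one seed are byte-identical.

## Null behavior

Under a null cohort (effect 0) the t-test p-values are uniform and the raw
p < 0.05 rate matches nominal within binomial error. The ORA positive rate
at strict p < 0.05 sits *below* nominal (≈ 0.032–0.035 at the default term
sizes): an exact discrete test cannot achieve its nominal size with a
strict threshold. The test suite therefore checks the ORA null rate against
the analytically exact size of the discrete test, plus conservativeness
against 0.05 — not against 0.05 two-sided, which no faithful implementation
could meet.

## Known limitations

- No empirical-Bayes variance moderation, paired designs, or covariates.
- The tree cut is a deterministic simplification; module boundaries at
  aggressive β lose a few members to grey rather than reassigning them.
- Motif scanning keeps only the best window per pair; no p-value
  calibration, multi-site aggregation, or conservation filtering.
- ORA ignores the GO DAG; terms are tested independently.
- The network is undirected and unweighted; feed-forward-loop enumeration
  is out of scope.
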