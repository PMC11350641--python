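# Methods

This note records the exact definitions, defaults and numerical choices
behind `trophicniche`, including every place where the literature
offers more than one convention.

## 1. Input model and rank resolution

Inputs are three TSV tables: an abundance matrix (taxa × samples,
non-negative integer read counts), an identity table (per taxon: best
percent identity, whether the best hit was unique, and an optional flag
for local occurrence), and sample metadata (sample id, consumer
species, elevation in metres, marker ∈ {COI, RbcL}).  Lineages are
parsed from either greengenes-style prefixed strings
(`k__...;p__...;...;g__...;s__...`) or bare semicolon-separated names;
a lineage must be prefix-consistent (no gaps above the deepest named
rank, except for an explicit `unresolved_gap`).

Rank resolution from identity evidence:

| condition | assignment |
|---|---|
| identity ≥ 99 and single best hit and not flagged non-local | species |
| identity > 98 | genus |
| otherwise | unresolved_below_genus (lineage truncated above genus) |

The species rule's extra requirements reflect that a ≥ 99 % match to
multiple reference species, or to a species not known to occur locally,
does not justify a species-level claim.  Thresholds are `RunConfig`
fields (`species_identity_min = 99`, `genus_identity_min = 98`).

Aggregation to a rank sums counts over all taxa sharing the named taxon
at that rank; taxa unresolved at that rank are pooled per deepest-known
ancestor under an `Unassigned@` prefix and are **excluded from niche
profiles and biomarker features** (they are retained in the table so
totals are conserved).  Group (consumer-species) compositions pool raw
counts across the group's samples by default (`pooling =
"pooled_counts"`); a mean-of-per-sample-proportions alternative is
available since the two differ when depths are unequal.

## 2. Niche indices

**Levins breadth** `B = 1 / Σᵢ Pᵢ²` with `Pᵢ` the group's diet
proportions at the analysis rank (default genus).  `1 ≤ B ≤ n`.

**Pianka overlap** `O_jk = Σ P_ij P_ik / √(Σ P_ij² Σ P_ik²)` on the
union of the two groups' items, `0 ≤ O ≤ 1`, symmetric.  Qualitative
categories use strict inequalities: `O ≤ 0.3` → *none*,
`0.3 < O ≤ 0.6` → *meaningful*, `O > 0.6` → *significant*; so 0.3 and
0.6 exactly fall into the lower category.  Both thresholds are
configurable (`overlap_thresholds`).

**Feasibility interval.**  Given only the k largest proportions
`p₁ ≥ … ≥ p_k` of an otherwise unknown composition, the tail mass is
`m = 1 − Σ pᵢ` and every tail item is ≤ `p_k`.  Σ P² is minimised by
spreading the tail infinitely thin (tail contribution → 0), giving the
supremum `B_max = 1 / Σ pᵢ²`; it is maximised by concentrating the tail
greedily into `⌊m/p_k⌋` items of size `p_k` plus one remainder, giving
`B_min`.  The interval is sharp up to the open upper end: any true
breadth consistent with the printed top proportions satisfies
`B_min ≤ B < B_max` (we report closed bounds; the supremum is not
attained by finite compositions but is the correct comparison bound at
reporting precision).  Inputs must be non-increasing, positive, and
leave a non-negative tail.

Numerics: both indices are computed in float64 with compensated
(pairwise) summation via NumPy; the test suite checks agreement with
exact `Fraction` arithmetic and 50-digit `Decimal` oracles to 1e-12
over 1,000 random profiles.

## 3. Alpha diversity and rank tests

- **Chao1**: `S_obs + F₁²/(2F₂)`; when `F₂ = 0` the bias-corrected
  form `S_obs + F₁(F₁−1)/2` is used.
- **Shannon**: `−Σ pᵢ ln pᵢ` (base e by default, `shannon_base`
  configurable), zero-count categories dropped.
- **Simpson**: the Gini–Simpson form `1 − Σ pᵢ²`, chosen because it is
  the complement of the Levins reciprocal (`simpson = 1 − 1/B`), an
  identity the tests verify exactly.

Group differences per diversity metric use Kruskal–Wallis with the
midrank tie correction.  The H statistic is computed in-package (it
doubles as the permutation engine elsewhere); p-values come from the
chi-square approximation, except that designs with ≤ 9 total
observations use exact enumeration of group assignments
(`exact_max_n`).  The chi-square approximation is anticonservative for
two groups of five (exact critical attained level 0.0556 > 0.05) but
adequate from three groups of five upwards (0.044); the study-sized
design (3 groups, 4–5 samples) is therefore tested with the
approximation and the calibration suite verifies uniform null p-values
at 3 × 15.

## 4. Ordination and ANOSIM

Distances are Jaccard on presence/absence, with presence defined as
count ≥ `presence_min_count` (default 1).  NMDS minimises Kruskal
stress-1,

`stress = √( Σ (d̂ᵢⱼ − dᵢⱼ)² / Σ dᵢⱼ² )`,

where `d̂` are monotone-regressed disparities (scikit-learn isotonic
regression) and `d` the embedded distances, via SMACOF/Guttman updates.
Initialisation is classical (Torgerson) scaling plus
`nmds_restarts = 4` seeded random restarts; the best configuration is
returned, centred.  Stress < 0.1 is flagged *favorable*, otherwise
*unfavorable*; non-convergence within `nmds_max_iter` raises a warning
but returns the best configuration found.

ANOSIM uses `R = (r̄_B − r̄_W) / (M/2)` with `M = n(n−1)/2` the number
of sample pairs, so `R ∈ [−1, 1]` — the denominator that actually
normalises mean rank differences to that range.  P-values are exact
(full enumeration of distinct label arrangements) when there are
≤ 10,000 of them, otherwise Monte-Carlo with the add-one estimator
`(b+1)/(m+1)` and `permutations = 999` by default.  The tests
cross-check R against scikit-bio and exact against long Monte-Carlo
runs.

## 5. Biomarker screen

A deterministic LEfSe-style procedure, run independently at each rank
from phylum to genus:

1. scale each sample's rank-level abundances to a total of 10⁶;
2. keep features with Kruskal–Wallis p < α (default 0.05);
3. require direction consistency: the candidate enriched class (largest
   mean) must show a positive Wilcoxon rank-sum shift against **every**
   other class (strict mode; lenient mode checks only the extreme
   pair).  Comparisons among non-candidate classes carry no information
   about the candidate and are deliberately not part of the gate;
4. effect size = `log10 |(g_raw + g_proj)/2|`, where `g_raw` is the gap
   between extreme class means of the feature's scaled abundance and
   `g_proj` the extreme-class-mean gap of sample projections on the
   first linear-discriminant axis fit over all surviving features of
   that rank (within-class scatter ridge-regularised at 1e-6 of its
   mean diagonal, axis normalised to unit coefficient norm);
5. pass iff effect size ≥ `lda_cutoff` (default 2.0).

This replaces the original LEfSe's bootstrapped, perturbation-seeded
LDA with a closed-form equivalent: output is labelled "LEfSe-style" and
is exactly reproducible.  The calibration suite checks that the
empirical false-positive rate of the full screen on label-permuted null
data stays at or below α, and that a planted 4-fold genus enrichment in
one of three groups (n = 10 each) is recovered with sensitivity ≥ 0.9.

## 6. Synthetic-data generator

`SyntheticDietSpec` defines a study: consumer groups (default the three
rodent species), elevations (2000–3600 m in 400 m steps), missing
group × elevation cells (two by default, giving 13 samples), a marker,
`n_genera = 60` food genera in a nested taxonomy, and generation
parameters.

Per-group **true compositions** are deterministic given the spec (no
RNG): each group gets a private geometric-decay block (`decay = 0.6`)
plus a shared geometric block, mixed as
`(1 − λ)·private + λ·shared` with `overlap_lambda = 0.35`.  The decay
constant was fixed a priori so that the default genus-level true
breadth (≈ 7.3) sits inside the range typically reported for
generalist rodent diets; λ monotonically controls pairwise Pianka
overlap (λ = 0 → disjoint, λ = 1 → identical), a property the tests
verify.  Planted biomarkers multiply one genus in one group by a fold
factor and renormalise; the *effective* composition after planting is
the ground truth.

Per sample, counts are Dirichlet-multinomial: a Dirichlet draw around
the group's effective composition with `dirichlet_concentration = 200`
models biological and amplification variability, and the sequencing
depth is truncated-normal per marker (COI 138,467 ± 3,978;
RbcL 95,973 ± 17,516; floor 1,000), matching typical per-marker run
summaries.  Identity annotations mark about 20 % of taxa as
species-resolvable.  `truth.json` records true compositions, breadths
and overlaps — computed by the same `niche` functions the pipeline
uses, so generator and analysis cannot drift apart silently.

**Scope and limitations.**  The generator models compositional noise
and depth variation but not chimeras, index hopping, reference-database
gaps, or elevation-dependent diet shifts (elevation is recorded in
metadata but does not alter compositions).  It is a calibration and
regression harness, not an ecological simulator.

## 7. Determinism and seeds

All randomness flows from a single integer seed through
`numpy.random.default_rng`; derived stream seeds are kept below 2³¹.
Given the same seed, dataset generation and the full pipeline are
byte-reproducible, which the test suite asserts at file level.

## 8. Resolved conventions

Choices where conventions differ, and what this package does:

- Host-taxon filtering: **off by default** (consumer reads are assumed
  already removed upstream); a `host_filter` config hook exists.
- Shannon base: **natural log** (nats), configurable.
- Simpson variant: **Gini–Simpson** (`1 − Σp²`), for the exact Levins
  identity.
- Unassigned/unresolved mass: **excluded** from niche profiles and
  biomarker features, retained in aggregated tables.
- Overlap category boundaries: **strict** (`>`), so threshold values
  fall in the lower category.
- ANOSIM denominator: **M/2** with `M = n(n−1)/2`, the normalisation
  that bounds R in [−1, 1].
- Group composition: **pooled counts** by default, sample-mean
  proportions optional.
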