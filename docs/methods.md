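# Methods

## The pair-ratio statistic

RT-qPCR reports a quantification cycle Cq per target; one cycle corresponds
to a two-fold concentration difference, so Cq is a base-2 log scale read in
reverse (lower Cq = more template). For two miRNAs measured in the same
plasma sample the package's unit of analysis is

    r = 2^-(Cq_num - Cq_den) * 100,

the within-sample concentration ratio scaled by 100. The modelling
assumption that justifies it: sample-level nuisances — RNA extraction yield,
reverse-transcription efficiency, PCR inhibitors carried over from blood —
act (approximately) multiplicatively on every measured concentration of a
subject, i.e. additively on every Cq. Such a per-subject constant cancels
exactly in every ΔCq, so pair ratios need no reference gene, no spike-in and
no global normalization. Ratios are carried on the linear scale; log10 is a
display transform only (all screening statistics are rank-based and
monotone-invariant, so this is a presentation choice, not an analysis one).

A "sum" variant (several miRNAs in the numerator and/or denominator) sums
linear-scale amounts, Σ 2^-Cq, before taking the ratio — amounts add, log
cycles do not.

## Replicate aggregation and missingness

Triplicate RT reactions are collapsed to a consensus Cq per (subject, miRNA):

* method: **median** (default; robust to one aberrant replicate) or mean;
* a cell needs ≥ `min_replicates` (default 2) non-missing replicates,
  otherwise it is missing;
* Cq ≥ `max_cycles` (default 40) is a non-detect → missing, never numeric;
* `"NA"`/empty cells are silently missing; any other unparseable token
  (e.g. the instrument's `Undetermined`) is missing *and* counted in a
  parse-warning tally, since it usually marks a non-detect worth auditing.

Subjects missing a consensus value for either member of a pair are dropped
from that pair's comparison only (pairwise deletion). This maximizes data
use and matches the per-pair structure of the analysis; the cost is that
each pair can have its own n, which the results table reports explicitly.

## The exhaustive screen

Every unordered pair (m(m−1)/2 for an m-miRNA panel) is tested between two
subject groups with a two-sided Mann–Whitney U test:

* **exact** null distribution when min(n₁, n₂) ≤ 10 and the pooled values are
  tie-free — group sizes of ~10 per disease sit exactly where exact
  computation is cheap;
* otherwise the **normal approximation** with midrank tie correction and
  continuity correction;
* two identical samples (zero pooled variance) return p = 1.

The family-wise threshold is α divided by the *full* combinatorial pair
count of the panel analyzed (0.05/28 for 8 miRNAs, 0.05/153 for 18), even
when some pairs are unusable after missing-data filters — the correction
describes the search space, not the surviving tests. No FDR alternative is
offered by design.

Pairs are reported in the orientation whose AUC ≥ 0.5 (cases tend to the
higher ratio); the reverse orientation is the reciprocal (r_ab · r_ba = 10⁴)
and carries identical evidence. Results are ordered by ascending p-value
with alphabetical tie-break for deterministic output; analytically, a pair
"ranks first" when no pair has a strictly smaller p — at complete separation
(U = n₁n₂) several pairs can share the identical p-value ceiling, and the
alphabetical layout rule is not evidence ranking.

### Sample-size helper

The case-control planning helper uses the classical equal-allocation
normal-approximation formula, n per group = ⌈2(z_{1−α/2} + z_{power})² / d²⌉
with d the standardized mean difference; the result object carries the
formula string so reports are auditable. Published studies in this area
sometimes quote sizes from other (uncited or unavailable) formulas; this
implementation makes no attempt to reproduce numbers whose derivation is not
stated.

## ROC curves and the operating point

AUC is the tie-adjusted concordance probability (ties ½), computed via
midranks — identically U/(n₁n₂), and identically the trapezoid area under
the empirical curve; both identities are enforced by tests.

Candidate thresholds are the midpoints between adjacent distinct pooled
scores, plus two sentinels beyond the extremes (multiplicative, score/2 and
score×2, when all scores are positive — keeping ratio cutoffs positive —
else ±1). The reported cutoff maximizes overall accuracy (TP+TN)/N with
preference order:

1. higher accuracy;
2. interior midpoints before sentinels — a sentinel classifies everyone
   identically and is accepted only when that *strictly* beats every
   interior split (heavily imbalanced or degenerate inputs);
3. higher sensitivity (screening favors not missing cases);
4. lower threshold.

Degenerate input with a single distinct pooled value falls through to the
sentinels and resolves deterministically by the same rules.

## Combining pairs

How multiple biomarker pairs should be merged into one decision is genuinely
open; the shipped default is the **standardized-log-mean**: each member
pair's log10 ratios are centered and scaled by the pooled mean/SD of the
fitting set, sign-oriented so higher = more case-like (orientation from the
member's own AUC), and averaged with equal weights. Properties that motivate
it: a single member reproduces that pair's ranking (hence AUC) exactly;
duplicated members change nothing; averaging independent informative members
raises AUC (verified by simulation). A majority-vote rule over the members'
individual best-accuracy cutoffs ships as a secondary option behind the same
interface. Standardization constants, orientations and the cutoff are frozen
at fit time, so held-out subjects are scored with the training calibration.
A zero-SD member (constant ratio in the fitting set) contributes a zero
z-score rather than an infinity.

## The hierarchical workflow

Four decision nodes: GI vs control and pulmonary vs control (each screened
over its organ-enriched + ubiquitous sub-panel — with the default 17-miRNA
panel, 9 miRNAs → 36 pairs per system node), GI vs pulmonary, and cancer vs
inflammation (both over the full panel). Per node: screen, keep the top
`pairs_per_node` (default 3, matching the 3–4 pairs per comparison typical
of this design) Bonferroni-significant pairs, fit the combination and its
best-accuracy cutoff. A node with no significant pair is left untrained with
a warning; the model still fits and applies with the remaining nodes.

Applying the model, the two system nodes vote independently — a subject may
be flagged for one, both, or neither system. Only flagged subjects are typed
cancer/inflammation (hierarchical gating: a type call without a detected
pathology is meaningless in a screening context). A subject missing any
detector miRNA causes that node to abstain, recorded per call. Node cutoffs
live on the combined-score scale (dimensionless); the per-pair cutoffs in
the training summary are in ratio units.

Training involves no randomness: identical data and parameters give
bit-identical models. Both resubstitution accuracy (same subjects used to
select pairs and cutoffs — optimistic, but the standard reporting mode for
small feasibility cohorts) and held-out accuracy (a fresh simulated cohort)
are computed and labelled as such.

### Population projection

For a screening scenario (population N, prevalence π, sensitivity se,
specificity sp): TP = N·π·se, FP = N·(1−π)·(1−sp), PPV = TP/(TP+FP)
(missing when no positives at all). This is the arithmetic that makes
disease-by-disease screening of rare conditions impractical — e.g. a
100%-sensitive, 99%-specific test for a 1-in-10,000 disease applied to one
million people yields 100 true and ~10,000 false positives (PPV ≈ 1%) — and
motivates organ-level screening with few tests.

## The synthetic cohort generator

    Cq(s, m, r) = baseline_m + offset_s + effect_{group(s), m} + eps_{s,m,r}

* `baseline_m` — per-miRNA mean Cq, defaults spanning 26–34 cycles;
  ubiquitous miRNAs abundant (26.5–27.5), organ-enriched scarce in plasma
  (30–33), matching the observation that tissue-enriched species circulate
  well below ubiquitous ones;
* `offset_s ~ N(0, subject_offset_sd)` (default SD 1.0 cycle) — the global
  per-subject nuisance (extraction yield, inhibition). This is the term the
  ratio approach exists to cancel;
* `effect` — additive Cq shift per (group, miRNA), negative = elevated
  concentration; multiplicative on concentration, matching fold-type changes
  in plasma levels;
* `eps ~ N(0, noise_sd)` (default SD 0.25 cycles per replicate, triplicates)
  — technical noise on the log scale, the standard qPCR error model;
* Cq ≥ `dropout_cq` (default 40) → missing.

The default panel holds 17 miRNAs (6 GI-enriched, 6
pulmonary-enriched, 3 ubiquitous, 2 cancer/inflammation-associated); the
assay's 18th slot is configurable (the Monte-Carlo error studies add a
broadly disease-associated miR-21 to reach 18).

The demonstration scenario (`demo_scenario`) uses a realistic
feasibility-cohort layout:
30 controls and seven disease groups of 10 (esophageal, gastric, colon
cancer and Crohn's disease in the GI system; asthma, pneumonia and NSCLC in
the pulmonary system; 100 subjects). Effects: each GI group shifts five
GI-enriched miRNAs by −1 to −2 cycles (miR-145 deliberately left unshifted
so GI-vs-GI pairs like miR-215/miR-145 carry signal); each pulmonary group
shifts four pulmonary-enriched miRNAs by −1.5 to −2; cancers shift miR-126
and miR-31 by −2; inflammatory diseases shift miR-155 by −2 and miR-146b-5p
by −1.5. True per-disease effect sizes in patients are unknown — no public
Cq-level dataset exists for this panel — so these are demonstrative: 1–2 cycles
(2–4-fold) against ~0.2-cycle effective pair noise, sized for clear signal
at n = 10 per group. "Planted pair" studies split the effect ±1 cycle across
the two members so the signal is specific to that pair rather than shared by
every pair containing one shifted miRNA.

What the generator does **not** emulate: hemolysis contamination (organ-
enriched miRNAs are low in blood cells; modeled as its absence), correlated
miRNA co-regulation, age/sex/smoking covariate structure, batch effects
beyond the global offset, amplification-efficiency deviations from 2, and
heavy-tailed outlier samples. Passing tests therefore demonstrate that the
*pipeline* behaves correctly under its stated model — offset cancellation,
error control, power against planted multiplicative effects — not that real
plasma cohorts will reach the demonstration accuracies.

## Monte-Carlo problem sizes

The error and power studies run at: 500 null cohorts (18 miRNAs, 10 vs 10)
for the family-wise error rate against 0.05 + 2 Monte-Carlo SEs; 100 seeded
screens (n = 20+20, replicate noise 0.5) for planted-pair detection; 30
seeded cohorts (n = 30+30) for log2-shift recovery within 15%; 200
simulations (n = 30+30, member AUC ≈ 0.8) for the combination-improvement
property. These sizes put the Monte-Carlo standard errors comfortably below
the margins being tested.

## Known limitations

* Resubstitution accuracy is optimistic; the held-out evaluation uses a
  fresh draw of the *same* generative scenario, which is still easier than
  an independent clinical cohort.
* The Bonferroni guarantee is verified marginally per screen; the workflow's
  four nodes are fitted without cross-node multiplicity control (each node
  is its own family, as in the original design).
* No confidence intervals on AUC and no covariate adjustment — out of scope
  by design.
* Amplification efficiency is fixed at 2 per cycle; efficiency-corrected
  models are deliberately not implemented.
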