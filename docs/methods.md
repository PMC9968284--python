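# Methods

This note records the models, rules and numerical choices behind
`viromeflow`, and what the synthetic cohort does and does not emulate.

## Screening and presence rules

Contig screening applies three rules in order: a length filter (discard
<1 kb; the 1 kb boundary itself is kept), a length-stratified pVOG-hit
threshold (3/4/5/6/7/8 hits for length classes [1 kb, 5 kb), [5, 10),
[10, 20), [20, 40), [40, 60) kb and ≥60 kb — half-open classes, longer
contigs must show more viral protein families to exclude bacterial
contaminants), and greedy dereplication. Dereplication visits contigs by
descending length (ties broken lexicographically by id so results are
independent of input order) and discards a contig iff it has a pairwise hit
with identity **and** coverage strictly exceeding 90% against an
already-retained contig. "Coverage" of a pairwise hit means coverage of the
shorter sequence: the rule exists to remove contained/near-duplicate
sequences, and containment is what shorter-sequence coverage measures.
Chains (A~B, B~C, no A~C) therefore resolve from the longest down: B is
absorbed by A, C survives. Strict inequality at 90.0 and greedy-by-length
transitivity are deliberate; both are boundary behaviours a clustering-based
dereplicator would get differently.

Presence calling is deliberately conservative: a virus is present in a
sample iff ≥10 mapped reads span ≥50% of contigs <5 kb, ≥30% of contigs in
[5, 20) kb, or ≥10% of contigs ≥20 kb. All comparisons are inclusive (≥).
The breadth bar decreases with contig length because a fixed number of reads
covers a small fraction of a long genome even when the detection is real,
while a handful of reads can easily cover a tenth of a short contig by
chance. Presence is evaluated per sample independently; there is no
cross-sample rescue. Whether "reads" are pairs or mates is a contract of
the upstream counter, not of this package.

## Diversity statistics

Shannon diversity is computed in natural log (nats), matching the default of
the standard community-ecology implementations. Pielou's J = H/ln S is
undefined (reported as missing) at observed richness 1. Rarefied richness
subsamples without replacement (multivariate hypergeometric) at a depth
defaulting to the smallest per-sample total, with 100 replicates by default;
the estimator is validated against the closed form
E[S] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d)).

Canberra distance (Σ over coordinates with xᵢ+yᵢ>0 of |xᵢ−yᵢ|/(xᵢ+yᵢ)) is
the default β-diversity metric — it weights rare taxa heavily, which suits
catalogues where most viruses are rare — with Bray-Curtis
(1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ)) for abundance-weighted questions. PCoA is
classical metric scaling: double-centre −d²/2, eigendecompose, scale
eigenvectors by √λ. Only axes with positive eigenvalues carry coordinates;
negative eigenvalues (expected for non-Euclidean dissimilarities) are
reported unchanged rather than corrected, so the caller can judge their
magnitude. Eigenvalues within 1e-10·λ₁ of zero are clipped to zero to keep
round-off from fabricating axes.

PERMANOVA partitions squared distances: SS_total = Σ_{i<j} d²ᵢⱼ/n,
SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g, pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)). The permutation p-value uses the
(1 + #{F_perm ≥ F_obs})/(1 + n_perm) estimator, which cannot return zero;
an exact mode enumerates every distinct assignment of the label multiset
(identity included) for small designs. Note that permutations occasionally
reproduce the observed partition, tying F exactly — so the minimal p of
1/(1+n_perm) is attained only when no such collision occurs.

α-diversity/condition association uses Spearman rank correlation with
average-rank ties and the t-approximation p-value. Conditions are encoded
Control=0, UC=1, CD=2 by default (severity-ordered; configurable — the
encoding is a modelling choice, not a fact of the data). Multiple-comparison
adjustment is Bonferroni throughout. Centroids are coordinate-wise means on
the first two ordination axes; the "extreme-α" centroids average the ten
highest- and ten lowest-Shannon samples, ties at the boundary broken by
sample id.

All-zero samples (no viral counts) are flagged and excluded from
relative-abundance and diversity computations with a logged warning — they
are never silently normalised.

## Communal sharing

Subject-level carriage has two named modes, kept deliberately distinct:
**union** over the subject's time points (used for total-cohort sharing
fractions and communal flags) and **single-time-point** (one random visit
per subject, used inside the bootstrap so that subjects with different
numbers of visits contribute equally). A virus is communal when detected in
≥2 subjects. The bootstrap draws 10 subjects per condition without
replacement, 20 times; each replicate's random choices come from an
independent sub-stream spawned from the master seed, so raising the
replicate count extends, never rewrites, earlier replicates. Replicate-level
spectra are retained so between-condition comparisons can use the replicate
distribution (two-sided Wilcoxon rank-sum per k). Sharing strata are
left-open/right-closed bins of the total-cohort sharing fraction —
(0, 0.1], (0.1, 0.2], (0.2, 0.3], (0.3, 0.4], (0.4, 1] — with per-virus
assignment unique; per stratum and condition the summary reports the mean
and sum over member viruses of each virus's average relative abundance
across that condition's samples, plus Student's t-tests between conditions
with Bonferroni adjustment. Subset filters (lysogenic-only, single family)
commute with stratification.

## Temporal dynamics

Persistence percentages use the subject's union of detected viruses as the
denominator. The all-three-time-points class is computed only for subjects
with exactly three samples; the two- and one-time-point classes also cover
two-visit subjects (for whom "in 2" means "in both"). Single-sample
subjects are excluded with a log message. Ternary coordinates divide a
virus's within-sample relative abundances at T1/T2/T3 by their sum —
multiplying any one sample's raw counts by a positive scalar cancels in the
within-sample normalisation. Intra- vs inter-personal dissimilarity
enumerates all within-subject and between-subject sample pairs
(Bray-Curtis by default) and compares the two sets with a two-sided
Wilcoxon rank-sum test (the unpaired variant, as the sets are not matched);
a condition-stratified variant restricts to one cohort first.

## The synthetic cohort

The generator's defaults reproduce the modelled study design exactly where
that design is fixed: 40 control, 19 CD and 20 UC subjects; 2/1/1 of them
respectively donate only two samples, giving 233 samples (118/56/59) with 75
three-visit subjects (225 samples); visit intervals are Normal(96, 25) days
(rounded, floored at 30, cumulative). Catalogue marginals: log-uniform
lengths on [1, 200] kb, 26.6% of records taxonomically assigned (tailed
phage families dominating), 13.7% flagged as carrying lysogeny genes, with
lifecycle and taxonomy "unknown" a first-class state distinct from
known-lytic.

Each subject's virome is the union of three exclusive classes per virus:

* **communal** — drawn per subject from a shared 300-virus pool with
  condition-specific carriage probability (defaults 0.15/0.07/0.09 for
  Control/CD/UC), each carried virus detected at any given visit with
  probability 0.55;
* **persistent personal virome** — 10 (control) or 7 (IBD) private viruses,
  each present at each visit with probability 0.85;
* **transient** — 14 (control) or 18 (IBD) fresh private viruses per visit,
  present at that visit only.

Effect *directions* (controls carry more of the communal pool, have larger
persistent viromes and fewer transients; lysogens get a +0.7 log-abundance
boost in IBD subjects) reflect the biology being modelled; the *magnitudes*
are free parameters chosen once so the emergent summaries are in the
qualitative regime reported for real unamplified viromes — persistent
personal virome around 10% of a subject's detected viruses, a majority of
single-visit transients, condition explaining ~1% of β-diversity variance —
and are not themselves claims. Private viruses come from disjoint
per-subject catalogue blocks, so inter-subject sharing arises only through
the communal pool; at a 5000-virus desk-scale catalogue, uniform private
draws would instead produce substantial accidental sharing (≈0.6 expected
shared viruses per subject pair) and destroy the mostly-unshared structure.

Abundances are heavy-tailed: each (virus, subject) has a lognormal base
(σ_between = 2.0 log units) with per-visit multiplicative noise
(σ_within = 1.0), so even persistent viruses fluctuate strongly between
visits. Counts are multinomial draws of 50 000 reads per sample over the
present viruses. Coverage evidence places 150 bp reads uniformly along each
contig; breadth is the exact interval union, whose expectation follows
Lander–Waterman 1 − exp(−Rℓ/L) up to edge effects (reads cannot start
within ℓ of the contig end, which depresses breadth by <1% at 10×
coverage on a 5 kb contig). Reads longer than a contig are truncated to it.

Randomness is hierarchical — master seed → catalogue / per-subject /
per-sample streams — so enlarging the cohort (appending subjects to a
condition) or adding bootstrap replicates never changes previously generated
data.

What the simulator does **not** emulate: sequence content (no FASTA/FASTQ),
strain-level evolution, phage–host dynamics, compositional coupling between
viruses, batch effects, or contamination. Passing tests on simulated
cohorts therefore validate the *statistical machinery* — thresholds,
estimators, resampling, determinism — not the biological fidelity of any
particular real dataset.

## Problem sizes and numerical choices

Default end-to-end runs use the full study-scale design (79 subjects, 233
samples, 5000 viruses) and complete in seconds; unit tests use smaller
cohorts (2–20 subjects, hundreds of viruses) chosen to make closed-form
oracles exact or enumerable. PERMANOVA's exact mode is intended for n ≲ 10.
Monte-Carlo validations (rarefaction, bootstrap spectra, read placement) are
checked against closed-form expectations at 3 standard errors, computed with
exact variances (including pairwise detection covariances for rarefaction
and carriage-realisation covariance for bootstrap spectra); where a family
of such checks is asserted at once, the expected number of chance 3σ
exceedances is tolerated with a hard 5σ cap.

## Known limitations

* Viral-cluster (VC) construction is out of scope; `cluster_id` is consumed
  as catalogue input and all analyses can be run at either resolution by
  aggregating counts upstream.
* Pairwise-hit coverage of the shorter sequence is a convention; BLAST
  tabular input computes it from alignment length, which over-counts when
  alignments overlap.
* The read-count threshold of 10 is applied to whatever the upstream counter
  emits (pairs vs mates is its contract).
* PERMANOVA is one-way only; no strata/blocking, and no correction for
  repeated measures — time points enter as independent samples, as in the
  modelled analysis.
* The t-approximation Spearman p-value and the normal-approximation rank-sum
  p-value are asymptotic; for very small groups use the exact enumeration
  paths instead.
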