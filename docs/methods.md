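# Methods

This note documents the models, rules, and numerical choices behind
`eaemap`, and what the synthetic-data experiments do and do not
demonstrate.

## Clinical-score preprocessing

Mice are scored daily over a configurable observation window (default
days 5–50 post-induction, closed interval; day indexing is 1-based
calendar days) on two integer 0–5 scales, classic and axial-rotary
(AR). The reader accepts comma- or tab-delimited long-format tables and
enforces score range, uniqueness of (mouse, day), and consistent
metadata. Missing leading days are treated as healthy (score 0);
missing interior *and trailing* days are filled by carrying the
previous day's record forward and logged as imputed — silent zeros
would fabricate remissions, and death-truncated records must still
reach the endpoint rules.

Endpoint rules, in order:

1. **72-hour maximal score.** Three consecutive recorded days at score
   5 on either scale (scoring is daily, so 3 days operationalizes 72 h)
   trigger the humane endpoint: that scale is set to 5 for every later
   day and status becomes `endpoint`. If both scales trigger, both are
   carried forward (the simultaneous case is not otherwise specified;
   carrying both avoids guessing an exclusive rule).
2. **Death after established disease** (> 2 consecutive days of any
   clinical signs while alive): the presenting scale — the one with the
   higher score on the last day observed alive, ties to classic — is
   set to 5 from the day of death onward.
3. **Death without established disease** (no signs, or ≤ 2 days):
   the mouse is excluded with reason `death-without-established-EAE`.

The operation is idempotent, preserves mouse counts
(|input| = |kept| + |newly excluded|), and the decision inputs (last
alive day's scores) are never themselves overwritten, which is what
makes re-application a no-op.

## Trait variables and course classes

The combined daily score is the mean of the two scales on days when
both are positive, otherwise the nonzero value; CDS sums it over the
window (so CDS ≠ classic-CDS + AR-CDS when simultaneous days exist).
Incidence requires ≥ 2 consecutive days of positive combined score;
onset is the first day of the first qualifying run. Subtype is
mutually exclusive: single-presentation mice take their only scale;
combined-type mice are assigned by comparing classic-only versus
AR-only day counts with simultaneous days excluded, ties to classic
with a logged flag.

Course classification runs on the combined series (the only series
defined for every mouse). The initial bout is the maximal positive run
containing onset. Monophasic: every day after the bout is zero (and
the bout ends before the window does — disease persisting to
termination is chronic even though the "days after the bout" set is
empty). RR: a remission of ≥ 3 consecutive zero days after the bout,
followed at any later point by a relapse of ≥ 2 consecutive positive
days; later cycles do not change the class. Chronic is the explicit
catch-all, which makes 1–2-day zero dips inside a bout chronic rather
than remissions. Mice carried at 5 by the endpoint rules are
necessarily chronic. A brute-force rule checker that enumerates all
runs independently agrees with the classifier on 10,000 random series
in the test suite.

Strain summaries (incidence, subtype and course percentages, mean CDS,
endpoint fraction) are computed over post-exclusion mice only; the two
subtype percentages sum to the total incidence by construction. Note
one deliberate asymmetry: CDS is *not* monotone in every single-day
score change — raising a scale from 0 to 1 on a day where the other
scale is high switches the combination rule from pass-through to
averaging and can lower the combined score. This is a direct
consequence of the averaging definition, not a bug.

## QTL mapping

Phenotypes are prepared by least-squares residualization on experimental
batch (cohort) indicators, then rank-based inverse normal
transformation Φ⁻¹((r − ½)/n) with average ranks for ties (the offset
½ is the common convention; the transform is named but not
parameterized in the source protocol). For mouse-level traits (CDS)
individual mice are the units; incidence-type traits use per-strain
percentages.

At each marker the phenotype is regressed on the 8 founder dosages
plus intercept (one dosage dropped; dosages sum to 1). The scan is
computed through batched normal equations with a Moore–Penrose
pseudoinverse, which is exact under rank deficiency (collinear dosage
columns are implicitly dropped, never an error), and
LOD = (n/2)·log10(RSS₀/RSS₁) with RSS₁ floored at 10⁻¹²·Var(y)·n so a
perfect fit yields a large finite LOD. LOD is invariant to affine
transforms of the phenotype and nonnegative by construction.

**Kinship (optional, off by default).** K = (1/M) Σ_m D_m D_mᵀ over
founder dosage vectors, rescaled to unit average diagonal; `loco`
excludes the scanned chromosome. The mixed model y = Xβ + g + e with
g ~ N(0, σ²_g K) is fit by estimating h² = σ²_g/(σ²_g+σ²_e) once under
the null (bounded scalar ML on the rotated model) and whitening both
models by (h²K + (1−h²)I)^{−1/2}. Whether every published scan used
the derived kinship matrices is not stated in the protocol this
follows, so both paths are exposed (`--kinship {none,overall,loco}`).

**Permutations.** Thresholds are (1 − α) quantiles (α = 0.15, 0.20 by
default, 1,000 permutations by default) of the genome-wide max LOD
under strain-level phenotype exchange: mouse rows move with their
strain, preserving within-strain replicate correlation. The unit of
exchange is not stated in the protocol; strain-level exchange is the
choice that keeps the null honest for replicated inbred genomes
(mouse-level exchange would be anti-conservative). Balanced designs
use a fully vectorized value-permutation path; unbalanced mouse-level
designs permute the genotype assignment instead.

**Peaks.** Per chromosome, the maximum-LOD marker is reported with a
Bayesian credible interval: normalize 10^LOD over the chromosome, take
the smallest contiguous marker interval containing the peak with mass
≥ 0.95, and report the positions of its flanking markers (clipped at
chromosome ends) — a single dominant peak therefore yields its two
neighbors. Founder effects at a peak are least-squares coefficients of
the 8 dosages under a sum-to-zero reparameterization (orthonormal
Helmert basis against an intercept), i.e. deviations from the
population mean, with the same whitening applied when kinship is used.
Genotype-by-phenotype tables assign each strain its argmax-dosage
founder, reporting all founders tied within 10⁻⁹.

## Candidate-gene prioritization

A gene's feature vector holds its network connection weights to each
positive training gene (0 without an edge; a positive's self-entry is
0). Genes with all-zero vectors are trimmed; since trimming a positive
removes a feature column, the trim iterates to a fixed point. Each of
100 rounds samples |positives| negatives without replacement from the
negative pool and fits a linear SVM (C = 1, raw weights — weights
share a scale within one network, and the kernel is otherwise
unspecified upstream). Candidates are always excluded from training.

Per round, a candidate's FPR compares its decision value with that
round's own sampled negatives, counting ties as false positives (the
cutoff equals the candidate's score, placing it on the positive side
of its own cutoff). The final score is −log₁₀(mean FPR over rounds),
floored at 1/(n_rounds·m + 1) with m negatives per round, so a
candidate beating every negative in every round scores finitely
(≈ 4.0 at 100 rounds × 100 negatives). Two readings of "−log of the
FPR averaged across SVMs" are grammatical; we take −log₁₀ of the mean
FPR, under which occasional zero-FPR rounds dilute rather than
dominate. Because the FPR is a rank statistic, the final score is
invariant under any strictly monotone transform applied jointly to
candidate and negative decision values, and the whole procedure is
bit-reproducible given a seed. Candidates trimmed for lacking
connectivity are reported as unrankable rather than scored.

The coding-variant shortlist keeps rows whose consequence is
missense/nonsynonymous, whose alleles differ between the two named
founders (those with the strongest opposing allele effects at the
locus), and whose position lies in the closed Mb interval, optionally
restricted to a gene subset. Gene-list overlap translates mouse genes
through a provided two-column orthology table before intersecting;
no live database is consulted.

## Synthetic data: what it emulates, and what it does not

Score trajectories are piecewise-linear archetype templates (ramp to
peak, hold, ramp down) rounded to integers — the simplest family that
realizes every course class exactly: chronic and AR-chronic hold the
peak to termination, monophasic decays to zero, RR inserts a ≥ 3-day
zero gap before a second bout, progressive ramps to 5 and triggers the
72-hour endpoint rule. Penetrance is Bernoulli per mouse; onset is
normal (rounded, clipped into the window). Score noise jitters
*disease-day* scores by ±1 at the given rate (clipped to 0–5); healthy
days are unambiguous and not perturbed, which models inter-rater
uncertainty on a sick animal rather than spontaneous false positives.
Each strain contributes n mice per sex (default 5), matching the
few-replicates-per-strain design the generators emulate, with cohorts
assigned round-robin.

Genomes are Markov founder chains per chromosome (uniform start,
switch probability 0.05/marker at 1 Mb spacing, giving ~20 Mb founder
blocks; dosage `certainty` 1.0 = one-hot). Planted QTL add
beta · (summed high-founder dosage) to a polygenic term (summed random
founder effects over all markers, standardized, contributing fraction
`h2_poly` of the non-QTL variance) and iid strain noise; incidence
traits map through a logistic link to percentages. Planted networks
draw edges at a uniform density with exponential weights whose mean is
higher inside a planted module; positives are sampled from the module
and the held-out module genes are the true candidates. Variant tables
track the qualifying count (in-interval ∧ missense ∧ segregating) at
generation time, independently of the filter under test.

None of this reproduces real CC recombination maps, linkage to real
markers, real network topology, or real effect architectures. Passing
recovery tests therefore demonstrates that the *pipeline* is correct
and calibrated under its stated model, not that any particular real
locus or gene would be found.

## Simulation sizes and observed operating characteristics

The validation experiments use: 60 mice per archetype for course
recovery (100% noise-free, ≥ 95% at jitter rate 0.15); 10,000 random
short series for oracle agreement; a 12-strain × 5-marker fixture for
exact LOD agreement (≤ 10⁻⁸) with an independent two-regression
computation; 50 null datasets (40 strains, 3 × 100 markers, 200
permutations) for threshold calibration (expected ~20% exceedance of
the 20% threshold); 25 planted-QTL replicates (40 strains, 5
mice/strain, QTL at ~40% of strain variance, polygenic share 0.1 of
the non-QTL variance, within-strain sd 0.3, mapping on
batch-residualized rank-Z strain means); and a 2,000-gene network with
a 150-gene module (100 positives, weight means 1.0 vs 0.05, density
0.15) for prioritization recovery.

One operating characteristic deserves emphasis: at a QTL explaining
~40% of strain variance in a 40-strain panel, the expected peak LOD
(~6.6, sd ~1.5) sits only about one LOD unit above the genome-wide 20%
permutation threshold (~5.6), so detection power is ~0.7, not ~1. The
founder-effect sign pattern is recovered essentially always, and the
credible interval covers the planted marker in ~95% of the replicates
in which the peak is detected. Larger panels or larger effects are
needed before genome-wide detection itself becomes near-certain; this
is a property of the design, not of the implementation.

## Known limitations

- The course classifier assumes complete (carried-forward) daily
  records; irregular scoring beyond single-day gaps is not modeled.
- Kinship permutation thresholds reuse the observed-data whitening
  (overall kinship) or the unrotated model (LOCO); re-estimating
  variance components per permutation would be slower and was not
  needed at these scales.
- The SVM ensemble uses each round's training negatives as its FPR
  reference set (no held-out draw is specified upstream); scores of
  candidates resembling trained negatives are therefore slightly
  conservative.
- X-chromosome inheritance is not special-cased; a chromosome is a
  chromosome.
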