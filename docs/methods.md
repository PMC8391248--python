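# Methods

## Scope and model

aimkit implements the statistical computations used to develop and
evaluate a small forensic ancestry-informative SNP (AIM) panel: marker
informativeness and cumulative-divergence balancing, naive-Bayes
population assignment, supervised admixture estimation, genotype
concordance auditing, and the associated evaluation summaries. All
analyses operate on unphased, unordered genotype calls at unlinked
biallelic or tri-allelic SNPs, under Hardy–Weinberg proportions within
reference populations and independence across loci (the naive-Bayes
assumptions). No inbreeding coefficient, linkage or strand
disambiguation is modelled.

## Informativeness statistics

Rosenberg's informativeness for assignment is computed in nats,

    In = Σ_alleles [ −p̄_a ln p̄_a + (1/K) Σ_pops p_ia ln p_ia ],

with 0·ln 0 := 0 and p̄ the unweighted mean across populations; 0 ≤ In ≤
ln K, and In = 0 iff all population vectors coincide. Population-specific
divergence (PSD) of a target group is the two-group In between that
group's vector and the *unweighted* mean vector of the remaining groups
— pooling weights populations equally, not by sample size, matching the
equal-population treatment of the ancestry workflows this statistic
comes from. Delta differentials are max over alleles of
(p_target − comparator mean); the comparator defaults to all other
populations and is configurable because regional rankings (e.g. South
Asian vs European only) conventionally use restricted comparators.

Cumulative PSD supports two accumulation modes. `assigned_only=True`
sums each group's PSD over the SNPs assigned to that group — the natural
per-set bookkeeping. `assigned_only=False` accumulates each group's PSD
over *every* panel SNP; this is the mode used for panel-wide balance
reporting, because a two-group In is bounded by ln 2 ≈ 0.693, so
per-group totals of order 10+ nats are only reachable when every marker
contributes its (usually small) divergence to every group's running
total.

Panel balancing is a deterministic hill-climb: each group is filled to
its budget with its highest-PSD candidates, then single swaps
(remove one selected, add one unused, same group) are applied greedily,
always choosing the swap that most reduces the max−min spread of
cumulative totals, until no swap improves it. Ties break by ascending
rsID; protected SNPs are never removed. The procedure formalises what
panel designers do by manual curation; it is a local search and carries
no global-optimality guarantee.

## Classification

Profile likelihoods are products over non-missing loci of HWE genotype
probabilities from per-population allele frequencies estimated with a
pseudo-count: freq = (count + s)/(2N + sA) with A the declared allele
count. The default is s = 1 for classification (no zero likelihoods;
any s > 0 preserves rankings at fixed N) and s = 0 (plain MLE) for
frequency reporting. Missing loci are skipped, not imputed. Priors are
uniform by default and configurable. The reported strength is the
likelihood ratio between the best and second-best population, with a
verbose rendering at the 10³/10⁶/10⁹ thresholds alongside the numeric
value; exact ties report both populations at ratio 1. Leave-one-out
cross-validation re-estimates every group's allele counts with the held
sample's alleles removed before classifying it, so each fold is honest.

## Co-ancestry estimation

The supervised estimator fixes reference allele frequencies (from
POPFLAG = 1 profiles, smoothed) and maximises

    Σ_allele copies ln( Σ_k q_k f_k,allele )

over the K-simplex by EM, starting from uniform q, with tolerance 1e-6
on the log-likelihood and at most 1000 iterations (non-convergence is
flagged, not raised). The log-likelihood is non-decreasing by
construction and the update is deterministic, so no seed is involved.
This replaces MCMC cluster inference: with reference-anchored clusters
the quantity of interest is the per-individual proportion vector, which
supervised maximum likelihood estimates consistently at a fraction of
the cost. Admixture analyses of two- and three-way mixed cohorts are run
against the four major continental references (AFR/EUR/AMR/EAS, "K:4")
to keep the clusters simple; including the weakly drifted SAS reference
lets small minor components be absorbed by the near-ancestral group.

The GDA-style screen computes each population's mean expected
allele-sharing distance d_k = mean over loci of
(1 − ½ Σ_copies f_k,allele). Raw d_k carries a heterozygosity baseline
(~0.3–0.4) common to all populations that swamps the between-population
signal, so proportions are formed from the excess distance over the
nearest reference: q_k ∝ 1/(d_k − min d + 0.05)², with components below
0.01 truncated and the simplex renormalised, and a population at zero
raw distance taking the whole simplex. The bandwidth 0.05 sets how
sharply weight collapses onto the nearest reference. The screen is
deliberately crude: it systematically shrinks genuine minor co-ancestry
relative to the EM estimate, which is exactly why a distance screen
must be checked against a model-based estimator before admixture is
reported.

The allele-sharing distance between two profiles is Σ over jointly
non-missing loci of (2 − shared allele count); pairs with no jointly
observed loci are reported missing rather than zero.

## Concordance auditing

Cells enter a comparison only when called in both sets; genotypes are
compared as unordered multisets, and half-calls are treated as no-calls
(their handling is otherwise unspecified in practice). Samples or loci
present in only one call set are excluded and listed. Percentages are
carried at full precision internally and rounded half-up to the printed
precision only for display. Outlier flagging sorts loci by descending
discordance count with rsID tie-breaks.

## Synthetic data generator

Population allele frequencies follow the Balding–Nichols model: a locus
has an ancestral frequency (biallelic p ~ U(0.1, 0.9); tri-allelic from
a Dirichlet), and each population draws its vector from a Dirichlet with
that mean and concentration (1−F)/F, giving Var(p_pop) = F·p(1−p).
Loci are assigned a target group and the group's informative allele is
pushed toward fixation (the other groups drifting around a low ancestral
frequency) with rejection sampling until the locus's PSD clears the
group's floor — mimicking how real AIMs are ascertained from the tails
of the divergence distribution. Genotypes are two independent allele
draws per locus; admixed individuals draw each allele copy's origin
population from their co-ancestry simplex q. All generators are
bit-reproducible given the mandatory seed, and frequencies are kept
strictly inside (0, 1) so tables can be used directly in likelihoods.

Defaults mirror the study conditions of a six-group, ~115-AIM panel
design: 88 binary loci split 7/15/16/20/13/17 across
AFR/EUR/EAS/SAS/OCE/AMR plus 15 tri-allelic loci assigned round-robin; a
520-sample reference set (108/99/103/103/28/79 per group); drift
F = 0.30/0.20/0.20/0.08/0.35/0.35 and PSD floors of 0.40 nats (0.12 for
SAS). These values were chosen so the panel-wide cumulative PSD per
group lands in the 10–16 nat range with SAS trailing as the weakly
differentiated outlier — the divergence scale a balanced panel of this
size attains — and are not tuned per analysis.

Admixed-cohort truth is recorded as *realised* ancestry: the fraction of
an individual's allele copies actually drawn from each population, which
scatters binomially (sd ≈ √(q(1−q)/2L) ≈ 0.02 at 103 loci) around the
design q. Estimates are benchmarked against realised ancestry because
that is what a genome-wide comparator measures; benchmarking against the
nominal design q would charge the estimator for variance it cannot
remove.

What the generator does not emulate: linkage between loci, genotyping
error correlated by locus or sample, population substructure within
reference groups, and real-world ascertainment quirks. Passing tests
therefore demonstrate the correctness and calibration of the arithmetic
and the estimators under the stated model, not performance on any
particular real cohort.

## Evaluation utilities

Percentile comparison sorts samples by one method's chosen component
(ties by sample id), splits them into 10 near-equal bins (remainders to
the earliest bins), and reports per-bin mean proportion vectors for both
methods plus per-component r² — the squared Pearson correlation over
individuals, identical to the r² of an ordinary least-squares fit of one
method on the other. The sort component defaults to the cohort's
expected major co-ancestry and is configurable. Detection summaries bin
individuals by true component (<5%, 5–10%, ≥10%) and report the fraction
with estimates ≥ 5%. The Evanno table computes mean and sd of L(K) over
replicates, first and absolute second differences, and
ΔK = |L″(K)|/sd L(K), defined only at interior K with sd > 0. Diplotype
recoding sorts the haplotype combinations of a 2-SNP pair
alphabetically and maps them onto A/C/G/T (extending with numbered
symbols, flagged, when a tri-allelic member yields more than four
combinations); the mapping is a bijection, so pseudo-genotypes decode
back to haplotype pairs.

## Problem sizes and numerical choices

The acceptance script and the heavier tests use: 520 reference samples
× 103 loci for cross-validation (runs in a few seconds via incremental
count subtraction), 200 two-way admixed individuals for recovery, and
120 ACB-like individuals for the screen-vs-EM comparison — sizes at
which every statistic of interest is stable across seeds while the whole
suite stays desk-scale. EM tolerance 1e-6, frequency-boundary clip 1e-4,
likelihood-ratio overflow capped at exp(700) before reporting infinity.

## Known limitations

* The greedy balancer is a local search; pathological PSD landscapes
  could leave a reducible spread.
* The GDA screen is a qualitative stand-in for distance-based
  co-ancestry screens generally; its numeric output is not calibrated to
  any particular implementation.
* The VCF reader assumes panel alleles are reported on the VCF forward
  strand and errors on mismatches rather than attempting strand flips;
  A/T and C/G ambiguity is out of scope.
* Snipper-grid genotype strings are canonicalised alphabetically; any
  ordering information in the input is deliberately discarded.
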