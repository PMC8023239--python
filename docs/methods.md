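# Methods

## Homologous Virus (HV) grouping

Assembled viral contigs are fragments and variants: two contigs that share a
strong nucleotide alignment are best treated as the same or closely related
virus. The pipeline filters the directed all-vs-all hit table with three
rules — e-value ≤ `max_evalue` (default 1e-20, inclusive), alignment length
divided by the *query* contig's length ≥ `min_hsp_query_ratio` (default 0.5,
inclusive; the ratio is asymmetric and an undirected edge exists if either
direction qualifies), and both contigs ≥ `min_contig_length` (default
3000 bp) — drops self-hits, and takes connected components of the remaining
graph. Components of size ≥ 2 are HV groups; everything else is a singleton.

Connected components implement single-linkage semantics: membership is
transitive, so a group may chain contigs that never align to each other
directly. A stricter clique-like criterion would split such chains; we chose
components because the grouping is meant to absorb assembly fragmentation,
where chaining through a shared middle fragment is exactly the desired
behavior. Group ids are deterministic (descending size, ties broken by the
lexicographically smallest member), so reruns are stable.

Taxonomy from marker-gene calls is extended to whole groups only when all
classified members agree; discordant groups are labeled `conflict` with the
taxa listed, never silently resolved.

## Abundance normalization

Counts are rarefied per sample to a constant depth (default 1,367,462 reads)
by a multivariate hypergeometric draw — an exact uniform subsample without
replacement, so expectation is proportional to the original counts and the
target depth is hit exactly. Samples already at or below the depth pass
through with a warning rather than being dropped: small studies should not
silently lose samples. RPKM is count / (length/10³) / (total/10⁶); presence
is strictly > 7 RPKM. 16S-flagged contigs are eliminated after rarefaction
(reads are subsampled as sequenced, contaminants removed afterwards).

HV-group abundance is the **sum** of member-contig RPKM. Members are
fragments of the same virus, so mass adds; a mean would punish
well-assembled groups. The presence rule is applied twice: at the contig
level (absent contigs contribute no mass to their group) and again at the
HV level, which is the presence notion used by transfer tracking. Diversity
summaries (richness, Shannon H = −Σ pᵢ ln pᵢ over present rows) are
computed over HV groups by default, since singletons are by construction
uninformative about between-subject structure; a flag includes them.

## Transfer categories

Categories are fixed at baseline: with R₀ and D₀ the presence sets of the
recipient and its paired donor at week 0 and P the union of post-FMT
presence, every virus the recipient ever carries receives exactly one of
shared (R₀∩D₀), unique (R₀∖D₀), invading ((D₀∖R₀)∩P), new (P∖(R₀∪D₀)).
A donor virus never detected in the recipient gets no label — it is not part
of the recipient's community. Controls received their own stool, so D₀ = ∅
by design and only unique/new can occur. "Viruses" here are HV groups plus
singletons (default; flag-controlled), because community-composition
fractions describe the whole virome, whereas the ordination and biomarker
stages use HV groups only. Missing intermediate weeks are simply absent; no
imputation. Weekly category fractions are relative to the summed abundance
of *present* viruses, so they partition to 1 wherever anything is present.

The donor-vs-recipient establishment fit regresses each invading virus's
mean post-FMT abundance in the recipient on its donor week-0 abundance
(OLS; adjusted R² = 1−(1−R²)(n−1)/(n−2)); recipients with fewer than three
invading viruses or a degenerate predictor are skipped with a warning.

## Ordination statistics

Bray-Curtis, PCO, PERMANOVA and SIMPER are implemented from first
principles (they are the analytic core, and the SIMPER/PERMANOVA
permutation machinery must share one seeded generator for reproducibility);
scikit-bio and scipy serve as independent cross-checks in the test suite.

* PCO double-centers −d²/2 and eigendecomposes; axes are scaled by
  √eigenvalue with a deterministic sign convention; negative eigenvalues
  (non-Euclidean input) are reported, not corrected.
* PERMANOVA uses the standard distance-based partition
  (SS_T = Σ_{i<j} d²/N, SS_W per group / group size) and permutes sample
  labels freely. The study has repeated measures per subject; unrestricted
  permutation therefore overstates the effective sample size, which is a
  known limitation — the exported tidy distance tables allow restricted
  permutation in external tools.
* SIMPER's per-virus contribution is the mean over between-group pairs of
  |xᵢ−yᵢ|/Σⱼ(xⱼ+yⱼ), so contributions sum to the mean between-group
  Bray-Curtis distance to machine precision (asserted at 1e-12 in tests).
* All permutation p-values use the add-one estimator
  (1+#{perm ≥ obs})/(1+n_perm), never zero at finite permutation counts.

The ordination operates on *raw* (RPKM, not relative) abundances of the HV
groups present in a donor at week 0 and in that donor's paired recipient at
any week ("donor-shared" groups).

## Biomarker selection and clinical association

From the responder vs non-responder SIMPER, HV groups with cumulative
fraction < 0.7 and permutation p < 0.05 (both strict) are selected. Member
contigs are scored for assay design: R-score = (summed RPKM over
responder+donor samples) × (number of responder/donor subjects carrying the
contig), N-score analogously over non-responders, and
Score = R-score/(N-score+1) × median_r. We read "median_r" as the median of
the contig's per-sample abundance across responder+donor samples *where it
is present* (0 if present in none): this is the only reading that yields a
per-contig quantity on the same scale as the other factors. A subject
"has" a contig if it is present in any of that subject's samples.
Optional config filters restrict assay candidates to groups absent from all
non-responders and/or to a taxonomy label.

The clinical outcome is the percent increase in glucose disappearance rate
(%Rd), an insulin-sensitivity measure; responders exceed a configurable
+10% threshold. Week-6 HV abundance is regressed on %Rd by OLS (two-sided
slope t-test, adjusted R²; named outliers excludable). ROC/AUC uses the
rank (Mann-Whitney) form with ties counted ½; the p-value is exact for ≤ 20
subjects without ties and normal-approximate otherwise. The prevalence
contingency flags a subject "high" when ≥ `min_markers` (default 2) marker
groups exceed a configurable abundance threshold, and reports
integer-rounded responder percentages per stratum.

## Synthetic study generator

The generator emulates the trial design: 5 donors (sampled at week 0 only),
3 self-stool controls, 3 responders and 3 non-responders sampled at weeks
0/3/6/12/18, each sample at exactly 1,367,462 reads. One donor serves two
recipients, so donor reuse is exercised. Desk-scale community sizes — 120 HV
groups of 2–6 contigs (3–40 kb), 60 singletons, 18 viruses per recipient —
keep the full suite fast while leaving every structure non-trivial.

Each recipient draws a disjoint virus set split into the four categories;
arm-specific target fractions default to treatment
shared/unique/invading/new = 0.24/0.35/0.16/0.25 and control 0.8/0.2 on
unique/new. These are *count* fractions, so realized abundance fractions
only approximate them (abundances are random). Within-group contig pairs
receive symmetric similarity hits guaranteed to pass the clustering filters
in at least one direction, plus self-hits; decoy cross-group pairs receive
only sub-threshold hits (half fail the e-value rule, half the
alignment-ratio rule). Per sample, present viruses draw log-normal relative
abundances (μ=0, σ=1) floored at 0.005 — the floor guarantees every present
virus clears 7 RPKM at the default depth, giving the noise-free regime in
which transfer classification must recover ground truth exactly. Reads are
allocated multinomially over member contigs proportional to length;
`noise_overdispersion` > 0 gamma-perturbs the cell probabilities
(Dirichlet-multinomial-like), 0 is pure multinomial. Two 16S "contaminant"
contigs are present at floor level in every sample to exercise the
elimination rule.

Three designated biomarker HV groups are planted as shared viruses of every
responder (hence present in responders' donors) and withheld from all
non-responders. %Rd is baseline (5) + effect (8 per SD) × standardized
log₁₀ week-6 biomarker relative abundance + N(0, 2) noise, which separates
responders (>10%) from everyone else and makes the planted groups both
SIMPER-discriminant and Rd-correlated. The log-normal abundance model and
these effect sizes are modeling choices (no generative parameters exist for
real viromes); all are exposed on `SimParams`.

What the generator does **not** emulate: real nucleotide sequences (hits are
tabulated, not aligned), phage–host infection dynamics, strain-level
within-group divergence, library-preparation biases, or temporal abundance
drift within a category. Passing recovery tests therefore demonstrates the
correctness of the analysis logic under the stated noise model, not
robustness to every failure mode of real virome data.

## Numerical and degenerate-input conventions

Empty samples have richness 0 and Shannon 0 (logged). A sample pair with no
abundance at all gets Bray-Curtis 0 with a warning. PERMANOVA on all-zero
distances returns (0, 1). Weeks with no present viruses yield missing
category fractions. Ties in SIMPER ordering break by virus id; group ids,
sort orders and float formats (`%.10g`/`%.17g`) are fixed so that a rerun
with the same config and seed is byte-identical. Every stochastic step
(subsampling, permutations, simulation) draws from one seeded generator
passed in stage order.

## Evaluation sizes

The evaluation suite (`viromefmt.evaluation`, driven by
`scripts/acceptance.py`) uses 100 random graphs (≤ 50 nodes) for the
clustering oracle, 100 random cohorts (≤ 20 subjects) for the AUC oracle,
100 random tables for the SIMPER identity, 1000 null simulations × 999
permutations for PERMANOVA calibration, 1000 null OLS fits, 100 seeded
synthetic studies for discriminant-HV recovery, and two full pipeline runs
for the determinism check. The calibration bands are ~95% binomial
intervals around the nominal 5% level, so a borderline value on a
particular seed reflects Monte-Carlo variation, not miscalibration.
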