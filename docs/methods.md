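# Methods

## Report model and cleaning

A spontaneous report is a case ID, a set of suspect drugs, a set of
MedDRA-preferred-term adverse events (ADEs), sex, optional age, an optional
receipt date, and a literature flag. Drug names from both the
suspect-product and active-ingredient columns are unioned and passed
through a case-insensitive synonym map (shipped defaults:
Lipitor→atorvastatin, Zocor/Flolipid→simvastatin,
Mevacor/Altoprev→lovastatin, Crestor/Ezallor→rosuvastatin,
Pravachol→pravastatin); unknown products are kept verbatim, lowercased.
ADE terms are treated as opaque labels after whitespace/case
normalisation — no MedDRA hierarchy mapping, since the analysis operates
at preferred-term level only.

Dashboard exports carry no explicit literature flag, so a report counts as
literature-derived when its report-source field matches a configurable
pattern set (default: contains "literature"). Cleaning removes those
reports, then collapses duplicate case IDs keeping the latest receipt
date; when dates tie or are missing, the row appearing last in file order
wins, making the operation deterministic and idempotent. Same-patient
duplicates hiding under *different* case IDs cannot be detected without
record linkage and are out of scope; only exact case-ID collapsing plus
the literature exclusion is performed.

Cohort inclusion follows the published rule: a drug qualifies only when
its post-cleaning report count strictly exceeds 5000 (configurable). The
monotherapy restriction keeps reports whose drug set is exactly the one
statin. Sex strings "M"/"Male" and "F"/"Female" map to the two analysed
levels; everything else is unknown and is excluded only from the
male-vs-female contrast (the published sex-table row sums are smaller than
the all-report totals, implying exactly this handling).

## Disproportionality

Every contrast is a 2×2 table: exposure group vs reference group ×
event vs no event. The reporting odds ratio is `OR = (a·d)/(b·c)` with
Woolf's interval, `SE[ln OR] = √(1/a+1/b+1/c+1/d)`,
`CI = exp(ln OR ± 1.96·SE)` (normal quantile, matching the convention of
the common online 2×2 calculators), and a two-sided normal p on
`ln OR / SE`. The signal criterion is `ci_low > 1.0`, nothing else. A
report naming both the exposure and the reference drug contributes to both
groups: per-drug marginal totals are what dashboard exports provide, and
the published tables are reproducible from them without cross-exclusion.

Zero cells make the estimate undefined; the Haldane–Anscombe +0.5
correction is applied to all four cells only when some cell is zero, and
the result is flagged (`correction_applied`). With correction disabled, a
zero cell raises a structured error instead. Rendered tables round odds
ratios to 4 decimals and print p-values below 1e-4 as "<0.0001",
mirroring the published formatting; full precision is kept in the
unrounded columns.

Age is exposed as an optional band-stratified contrast using the same 2×2
machinery; no default bands are defined because no published banding
exists to mirror.

## Association-rule mining

A transaction is one report; items are namespaced (`drug:`, `ade:`) so the
two universes stay disjoint. Metrics are the classic ones — support =
joint count / total, confidence = joint / antecedent, lift =
support(X,Y)/(support(X)·support(Y)) — computed by direct counting.
The Apriori miner is level-wise with prefix-join candidate generation,
downward-closure pruning, and vertical transaction-id-set intersection for
counting; it is property-tested to equal exhaustive enumeration.

Both screens condition on the per-statin report subset: the denominator of
every support is the number of reports naming that statin. The published
framing is per-statin but never states the denominator; conditioning on
the subset makes lifts comparable across statins of very different report
volume, and a flag (`within_subset=False`) exposes the whole-corpus
alternative. Importantly, reports with no ADE items still count in the
denominator (their drug items keep the transaction non-empty) — dropping
them would inflate every lift by the reciprocal of the ADE-bearing
fraction.

The co-reported-ADE screen ranks, for every other ADE term, the lift
between the target event and that term, retaining lift ≥ 1.5 (the
published cutoff) and returning the top 5. The DDI screen builds
`{statin, co-medication} → {target event}` rules and returns the top 10 at
the same cutoff. Ties break by descending joint count, then
alphabetically. A minimum joint count (default 10 reports, configurable)
suppresses single-report noise; no statistical test is attached to lifts —
the raw cutoff is the published decision rule. The miner operates on raw
item labels by default so brand and generic rows (furosemide vs Lasix)
stay distinct as they do in dashboard exports; an optional synonym map
merges them.

## Differential expression

Input is a log2-scale genes × samples matrix with ≥2 replicates per group
(a log-CPM helper with offset 0.5 covers raw-count input; the original
assay normalisation is not otherwise modelled). Per gene, the pooled
two-group variance s²_g with d_g = n1+n2−2 df is shrunk toward a prior:

    s²_post = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t = logFC / (s_post·√(1/n1 + 1/n2)),  df = d0 + d_g.

The hyperparameters (d0, s0²) come from moment-matching the observed
variance distribution against a scaled F on the log scale: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess variance of e over
ψ′(d_g/2) determines d0 through a Newton trigamma inverse, and its mean
determines s0². This is the standard empirical-Bayes fit for a scaled
inverse-chi-square variance prior; the implementation agrees with
Bioconductor limma's moderated statistics to ~1e-13 relative error (tested
via Rscript on a shared fixture). Limiting cases hold exactly: d0 = 0
recovers the ordinary equal-variance t test, d0 = ∞ a z statistic with the
common prior variance. Zero-variance genes are assigned the prior variance
so their statistics stay finite.

Calls use BH-adjusted p < 0.05 and |log2 FC| ≥ 1.5. The fold-change
threshold is interpreted on the log2 scale (the convention of moderated-t
workflows); both α and the threshold are arguments. The BH step-up
adjustment delegates to statsmodels and is tested against a hand
computation. The default contrast is treatment vs the vehicle (DMSO-style)
control arm.

Enrichment is a one-sided hypergeometric test per gene set after
intersecting each set with the background (default background: all genes
in the matrix — the original web tool's internal background is not
reproducible offline). Fold enrichment is (k/n)/(K/N); FDR is BH across
tested sets; empty-overlap sets report fold 0 and p 1. Gene sets are read
from GMT.

## Synthetic-data generator

The cohort generator emulates a dashboard export: each report draws one
statin from report-volume weights (the five statins' published volumes by
default), independent co-medications at fixed rates, sex
(0.48/0.47/0.05 male/female/unknown), and age (normal(62, 12) clipped to
18–95, 10% missing). Exactly one statin per report makes the planted
per-statin log-odds equal the estimand of the per-drug-marginal 2×2 — and
matches the clinical reality that statins are not co-prescribed with each
other; co-medications remain independently sampled.

The target event follows a logistic model: baseline logit
log(0.10/0.90) for the simvastatin reference (near the published
simvastatin rhabdomyolysis reporting rate), per-statin shifts equal to the
log of the published odds ratios, a male shift of ln 2 (the published
"twice as likely" summary), and ln(odds factor) for each planted
interaction when statin and co-medication co-occur (defaults:
furosemide×simvastatin and pantoprazole×rosuvastatin at factor 3).

Background ADEs use the recurring published vocabulary (myalgia, asthenia,
blood creatine phosphokinase increased, fall, myopathy, acute kidney
injury, …) at rates of a few percent. Pairwise lift between the target
event and a partner ADE is planted by exact conditional construction:
given the realized target-event rate p̄ in the conditioning subset, the
partner fires with probability L·q when the event occurred and
q·(1−L·p̄)/(1−p̄) otherwise, so the subset lift equals L and the marginal
stays q. Targets with L·q > 1 or L·p̄ > 1 are mathematically infeasible
and raise an error naming the pair — at small cohort sizes the realized p̄
can cross that bound for aggressive targets, which is a property of the
construction, not a bug. A forced-co-occurrence mixture was chosen over a
copula because it tunes in closed form and keeps exact truth bookkeeping.

Duplicates (5%) are re-emissions of non-literature reports with the same
case ID and an earlier receipt date; literature flags (3%, the published
share of literature-derived records) are sampled independently. The truth
record stores every planted parameter plus realized counts — per-statin
contingency cells, monotherapy cells, sex cells, realized subset lifts —
computed on the post-cleaning cohort, so cleaning and every downstream
estimate can be checked exactly.

The expression generator plants mean shifts of |log2 FC| = 2 on 100 of
2000 genes (balanced up/down) over Gaussian noise with σ = 0.5, 4
replicates per arm — the assay's replicate structure. What the generator
does *not* model: FAERS reporting dynamics over time, stimulated
reporting, masking, correlated co-medication patterns, RNA-seq
count-level noise (mean–variance dependence), or batch effects. Passing
tests therefore demonstrate correctness of the estimators under clean
planted structure, not robustness to those real-data pathologies.

## Numerical and design choices

- Normal quantile 1.96 (not t) for Woolf intervals; two-sided p from the
  normal tail of |ln OR|/SE.
- Apriori tie-handling and rule ranking are fully deterministic
  (lift desc, joint count desc, alphabetical).
- Trigamma inverse: Newton iteration from x = 0.5 + 1/y, 50-iteration cap,
  relative tolerance 1e-8; closed forms at the y → 0 and y → ∞ ends.
- Published-table verification uses |OR − printed| < 1e-4; one published
  sex-contrast odds ratio appears truncated rather than rounded at the
  fourth decimal, and one published sex-contrast p-value bound ("<0.0001")
  is not supported by the printed cells (Woolf p = 0.0057 for the
  lovastatin contrast); the re-computed values are reported as computed.
- Pipeline outputs are byte-deterministic for a fixed config and input;
  the manifest records a config hash, input checksum and stage counts, and
  partial outputs are removed on failure.
- Analysis drivers use cohorts of 50,000 reports and matrices of 2000
  genes — sizes at which every planted effect is comfortably detectable
  and the whole analysis runs in seconds on one CPU.

## Known limitations

- The published aggregate tables are reproducible exactly from their
  printed cells, but the underlying report-level FAERS extraction is not
  redistributable, so end-to-end numbers on real data are out of scope;
  the synthetic cohort is the acceptance surface.
- The published expression dataset's exact DE counts depend on the
  original preprocessing of the external accession and are not reproduced;
  the caller's operating characteristics are established on planted truth
  instead, with limma as an independent oracle for the statistics.
- No Bayesian disproportionality (BCPNN/EBGM), no PRR, no multivariate
  confounder adjustment: the implemented estimator set is exactly the 2×2
  odds-ratio family the published analysis used.
- Lift screens carry no significance test; with few reports the lift
  estimate is noisy, which the minimum-joint-count floor only partially
  mitigates.
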