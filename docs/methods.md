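# Methods

## The analysis model

`dmrescue` quantifies, per individual, how far an intervention (here: a
training program) moved transcriptomic defects of DM1 muscle back toward
unaffected-control levels. The design has three arms: untrained controls
sampled once (baseline), and patients sampled before (pre) and after (post)
the program. All statistics treat the controls as a fixed reference.

**Percent rescue.** For a unit *u* (gene or skipped-exon event) in patient
*p*,

    rescue%(u, p) = 100 · (pre − post) / (pre − control_ref)

computed on the PSI scale for splicing events (control_ref = mean control
PSI) and on the log2FC-vs-control scale for genes (control_ref = 0, so the
numerator is the pre-vs-post log2FC). The value is defined only for units
significantly dysregulated pre-training; a denominator below 1e-12 makes the
unit's rescue undefined and it is excluded and counted. Categories partition
the real line: *rescued* (10 < r < 110), *overrescued* (r ≥ 110),
*misrescued* (r < −10), *unchanged* (−10 ≤ r ≤ 10). Two printed definitions
of misrescue circulate ("less than 10% in the direction opposite of control"
vs "less than −10%"); this package implements r < −10. The share of a
subject's defined units in the *rescued* category ("% DEGs rescued") counts
overrescued units only when `include_overrescued` is set.

**Dysregulation scores.** A subject's global splicing (or expression) defect
is the mean absolute deviation from controls — |ΔPSI| or |log2FC| — over the
units significant pre-training; the post score reuses exactly that unit set
with post-vs-control deviations. Scores are reported per subject and for the
pooled ("grouped") contrast, whose comparison with the per-subject scores
exposes the masking effect: antisymmetric individual changes cancel in a
pooled contrast (the package's masking test constructs a two-subject
counterexample with individual |Δlog2FC| ≥ 1 and grouped |Δlog2FC| ≈ 0).

**Significance thresholds.** Strict inequalities throughout. Presets:
`strength` (genes |log2FC| > 2, p < 0.05; events |ΔPSI| > 0.2, FDR < 0.05;
genes with < 10 counts in every sample dropped; PSI cells with ≤ 5
supporting reads set missing) and `cycling` (genes |log2FC| > 1.5,
p < 0.005; events |ΔPSI| > 0.05, FDR < 0.05, p < 0.0002). "Fewer than 10
counts in each sample" is read as *every* sample (configurable to *any*).

**Significance surrogate.** Real-data workflows feed externally computed
effect/p/FDR tables (edgeR-, rMATS-style) via `method="external"`. The
synthetic path uses a documented surrogate: group-vs-group contrasts use a
two-sided Welch t test per unit; an individual patient contributes a single
sample, so the patient's value is z-scored against the control mean and SD
(borrowing the control group's dispersion — with n = 1 per side there is no
within-patient variance). Benjamini–Hochberg FDR across units. A variance
floor (`sd_floor`, 0.05 log2 units for genes, 0.01 PSI units) bounds the
control SD away from zero so that the noise-free limit of the generator
remains testable; with the floor at 0, zero-variance units are flagged
untestable and excluded with a warning.

**Gene normalization.** `estimate_log2fc` defaults to CPM; the pipeline
defaults to median-of-ratios size factors (the composition-robust choice,
matching standard count-model practice) because a cohort where ~15% of genes
shift several log2 units in one direction inflates library totals and under
CPM leaks a common offset into every gene's fold change. The effect is
log2((mean + pseudocount)/(mean + pseudocount)) with pseudocount 0.5.

**YGCY enrichment.** MBNL binds YGCY tetramers (TGCT, TGCC, CGCT, CGCC)
position-dependently, so aberrantly included events should carry elevated
density upstream of / within the regulated exon and aberrantly excluded
events downstream. Regions are the exon plus 250-bp flanks, strand-aware
(upstream = 5′ on the coding strand; minus-strand regions are
reverse-complemented and the flank labels swapped). Motif windows overlap
and all are counted. Each misregulated event is matched to the k = 5
background events (detected, not misregulated, same assay) nearest in
Euclidean distance on mononucleotide frequencies of the concatenated
exon+flank sequence; ties break by a seeded shuffle then stable order.
Densities are per-nucleotide, pooled across events before the ratio (raw
counts would confound event length), and the report is
log2((fg + ε)/(bg + ε)) with pseudo-density ε = 0.5 motifs/kb. The
similarity metric, pooling rule and ε are this package's choices — the
underlying study names none of them — so numeric agreement with any
particular published enrichment value is not expected. Note also that
composition matching deliberately absorbs composition-driven signal: on
planted fixtures the recovered enrichment sits slightly below the planted
density ratio because motif-enriched sequences drag their matched
backgrounds' composition with them.

**Clinical metrics.** Per test: percent change = 100 · (post − pre)/pre.
SEMT derives from the cohort's baseline SD and the test's literature ICC;
the standard psychometric form SD·√(1−ICC) is the default and a linear
variant SD·(1−ICC) is selectable (both forms appear in the rehabilitation
literature; printed SEMT values alone cannot distinguish them, so neither is
endorsed). MDC = 1.96·SEMT·√2; a change is *meaningful* when the raw-unit
change strictly exceeds the MDC. The four 1-RM exercises (leg extension,
leg press, hip abduction, squat) average into the clinical outcome; 1-RM has
no published SEMT, so those rows carry no MDC screen.

**Correlation.** Spearman = Pearson on average ranks, two-sided p via the t
approximation with n−2 df (exact permutation enumeration available for
n ≤ 10). Age-controlled association uses the first-order partial correlation
on ranks, r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), p via t with
n−3 df. The grouped-descending analysis intersects rescued-gene sets in
order of decreasing clinical improvement until the running intersection
empties, reporting each step, the last non-empty set and its depth.

## The synthetic cohort generator

The generator produces the downstream structure the analysis consumes —
counts, PSI, support reads, metadata, clinical tests, event coordinates and
sequences — with full ground truth; no external data is required anywhere.

* **Counts**: negative binomial, shared dispersion α (default 0.1), means =
  per-gene baseline (log-normal, floor 100) × 2^offset × log-normal library
  factor (sd 0.15). A DM gene's pre-training offset is sign·(2.5 +
  severity_p) plus N(0, 0.25) jitter; severity (default evenly spread
  0.2–0.95) is the analogue of the CTG repeat-length spectrum.
* **PSI**: DM events shift from the control baseline toward 1 (inclusion) or
  0 (exclusion) by 0.3 + 0.3·severity, truncated to [0,1]; measurement noise
  is additive Gaussian (default sd 0.03) with truncation — chosen over a
  logit-normal model because it keeps the limit arithmetic exact. In
  stochastic mode a core (20%, P(active) = 0.85) / idiosyncratic (80%,
  P(active) = 0.15) structure decides which DM events are misspliced in
  which patient, emulating the heterogeneity of per-individual
  significant-event sets.
* **Rescue**: post = pre + ρ·(control − pre) (PSI scale; log2 scale for
  genes) with per-unit ρ = fraction_p^γ_u and log-uniform exponents
  (genes γ ∈ [0.5, 7], events γ ∈ [0.5, 2.5]). The power law keeps the
  limits exact — fraction 0 ⇒ no unit moves, fraction 1 ⇒ every unit lands
  exactly on the control mean — while spreading per-unit rescue within a
  patient. Default fractions: expression 0.3–0.7 across patients (strongly
  heterogeneous response), splicing 0.55–0.85 (more uniform, averaging near
  two-thirds rescue).
* **Clinical**: subject 1-RM gain = 80 + 45·(λ·z(mean gene rescue) +
  (1−λ)·η) percent, λ = `clinical_link_strength` (default 0.8), η standard
  normal; per-test values add jitter. Gains are generated directly on the
  percent-change scale because that is what the correlation consumes.
* **Sequences**: one contig per event (exon ± 250-bp flank), i.i.d. uniform
  composition; planted regions (upstream+exon for inclusion, downstream for
  exclusion) receive YGCY 4-mers at Poisson positions at a rate inflated by
  1/(1 − 7·D₀) to compensate for windows the insertions overwrite, so the
  realized density hits `density_ratio` × background. Half the events sit on
  the minus strand so strand handling is always exercised.
* **Determinism**: one seed per run; sub-streams are spawned per matrix so
  results do not depend on call order. `noise_sd_psi = 0` selects the full
  deterministic limit: PSI noise off, counts = rounded expected values with
  unit library factors, clinical noise off, and gene rescue exponents placed
  on an even grid that keeps every unit's implied percent rescue at least
  two points away from the +10% category boundary (so pseudocount and
  integer-rounding distortion cannot flip a category in the limit tests).

**What the generator does not emulate**: read-level sampling, isoform
complexity beyond two-isoform cassette exons, batch effects, real
composition/GC structure of genomic sequence, correlated gene modules, and
dropout structure beyond sporadic low-support PSI cells. Passing tests
demonstrate the pipeline's arithmetic and inference on data with this
generative structure, not performance on real RNA-seq.

## Numerical choices and degenerate inputs

* All threshold comparisons are strict, matching the printed inequalities;
  boundary values are excluded.
* Missing PSI (no/low read support) is NaN, never 0; events missing in a
  subject's pre sample leave that subject's universe ("no reads"
  downstream).
* Serialized tables carry 12 significant digits; reruns with the same seed
  are byte-identical apart from the timestamp in the JSON summary.
* Degenerate correlations (zero rank variance, control perfectly correlated
  with an input) raise typed errors; the pipeline catches them, logs, and
  omits the affected result instead of failing the run.
* The integer count matrix limits log2 recovery of planted offsets to the
  rounding scale (~0.08 at 10 counts); PSI truth recovery is exact to 1e-9.

## Problem sizes

Default cohorts are 6 controls + 9 patients, 1,000 genes, 400 events. The
calibration checks use 20 replicate cohorts of 2,000 genes for rescue-
fraction recovery and 200 cohorts of 400 genes × 100 events for the
severed-link false-positive rate — sizes chosen to give stable empirical
rates while keeping a full run in the order of a minute.
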