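# Methods

## Coordinates and interval arithmetic

All interval arithmetic is 0-based half-open internally; text I/O is 1-based
inclusive (the display convention of CNV coordinate strings), with
conversion confined to the I/O layer. The two supported file dialects must
be declared explicitly — silent auto-detection of coordinate conventions is
deliberately refused, because an undetected off-by-one shifts every overlap
fraction in a benchmark.

The matching statistic is the combined-span overlap fraction
`|A ∩ B| / |A ∪ B|`, symmetric in its arguments and equal to the Jaccard
index of the two basepair sets. For overlapping pairs the set-union length
equals the bounding-box span, and for disjoint pairs the fraction is zero
either way, so the union-vs-span ambiguity in the phrase "length spanned
together" is observationally irrelevant; union is used. Matching thresholds
are 0.25 for truth-set recovery and 0.50 for cross-program common-CNV
grouping (one qPCR probe must interrogate every grouped call, so grouping
is stricter); both are configurable.

## Recovery evaluation

A reference CNV is recovered when ≥ 1 non-diploid call in the same sample
passes the threshold (existential, many-to-many; no one-to-one assignment).
Two criteria are always computed: any-direction recovery, and recovery with
direction consistency (call state must equal reference state). The
consistency criterion is a strict subset of the other, so switching it on
can only lower rates — this monotonicity, along with monotonicity in the
threshold, is enforced by tests.

Probe-count strata default to 1 / 2–5 / 6–10 / 11–20 / ≥ 21 probes. The
conventional printed strata "6–10" and "10–20" share the value 10; the
implementation uses [11, 20] so the strata partition the integers and bin
counts are disjoint. References spanning zero probes of the manifest are
excluded from the binned table and reported separately: an array caller
cannot in principle detect them, and scoring them in the single-probe
stratum would conflate platform blindness with algorithm error.

Frequency strata are (0, 0.2] … (0.8, 1.0] of region carrier frequency.
Regions are built by single-linkage clustering of per-sample reference CNVs
with ≥ 1 bp overlap on the same chromosome (a sorted sweep); each reference
inherits its region's frequency, and the per-bin rate is recovered/total
over references, the form consistent with printed per-bin counts. How
published reference lists were grouped into "regions" is genuinely open;
any-overlap single linkage is the default and a 25%-combined-span linkage
rule is available as a config option for sensitivity analysis.

The per-region sensitivity summary reports the share of regions with
carrier-level recovery > 0.9 and ≤ 0.1, capturing the empirically bimodal
(all-or-nothing) locus behaviour of array CNV callers.

## Singletons and cross-caller classification

A singleton is a deletion or duplication called exactly once in the whole
cohort that overlaps (≥ 1 bp, any sample) no other non-diploid call from
the same caller. The disqualifying overlap considers calls of either class
by default — the strictest reproducible reading of "did not overlap any
other CNVs" — with a same-class-only switch. Cross-caller sharing of
singletons uses any-basepair overlap, deliberately distinct from the
fractional recovery rule: the two constants live separately in the API so
neither silently inherits the other.

## qPCR quantification and scoring

ΔΔCt = (Ct_target − Ct_control)_sample − (Ct_target − Ct_control)_calibrator,
with replicate wells averaged before differencing; relative quantity
2^−ΔΔCt; copy number 2·2^−ΔΔCt against the two-copy calibrator.
Classification thresholds are the midpoints 1.5 and 2.5 (no published
boundary exists, so they are config defaults); inequalities are strict, so
a boundary estimate stays diploid — the conservative call for the most
noise-exposed values. Copy numbers above 3 all classify as duplication.

Accuracy metrics use the standard confusion-matrix definitions: PPV =
TP/(TP+FP); FP rate = FP/(FP+TN) over qPCR-normal samples; FN rate =
FN/(FN+TP) over qPCR-variant samples (equivalently sensitivity = 1−FNR,
specificity = 1−FPR). Direction is collapsed to variant-vs-normal when
scoring a region: a single qPCR assay interrogates dosage change, not its
sign, at the tested locus. Undefined ratios (empty denominators) are NaN,
never zero.

## Plate-effect scan

For each region and each plate, a two-sided Fisher exact test on the 2×2
table carriers/non-carriers × on-plate/off-plate; a region is flagged when
any plate's p-value falls below α, defaulting to 0.05 divided by the number
of plates (Bonferroni within region, one test per plate). α is exposed
because no canonical flagging threshold exists for this screen. The exact
test is conservative for sparse tables: at 48-sample plates its attained
size at nominal 0.05 is ≈ 0.035 for carrier frequencies near 0.2 and
≈ 0.048 near 0.5 — calibration statements about the scan are therefore made
at intermediate frequencies where the null distribution is least discrete.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* **truth**: non-overlapping regions (each chromosome divided into equal
  slots, one region per slot, log-uniform size clipped to 80% of the slot,
  uniform placement). Non-overlap keeps region frequency well-defined;
  real data contain nested events, a documented limitation. Carrier
  spectrum: a singleton fraction (default 0.8 — reference CNV lists are
  rare-variant dominated) and Beta(1, 3)-distributed frequency for the
  remainder; 40% duplications; each region keeps ≥ 1 carrier.
* **probes**: uniform random positions at one probe per 1.5 kb, the density
  scale of a genome-wide SNP/CNV array.
* **callers**: each truth carrier emitted with probability equal to the
  per-probe-count-bin sensitivity, times a duplication penalty if
  configured (a deletion is a 2-fold intensity change, a duplication only
  1.5-fold, so duplications are systematically harder); Gaussian breakpoint
  jitter (calls collapsing below 1 bp are dropped as misses); direction
  flips; Poisson false calls at non-truth loci; log-normal LOD scores;
  optional plate artifact adding carrier probability for one region on one
  plate. Zero-probe truth regions use the single-probe-bin sensitivity.
* **qPCR**: Ct tables built by inverting the ΔΔCt law
  (ΔΔCt = −log2(CN/2) + N(0, σ)) around a noise-free two-copy calibrator;
  CN 0 is floored at 0.25 copies (a true null cannot give a finite Ct).
* **cohort**: default 96 samples on 48-sample plates — the smallest design
  with a defined plate contrast; analyses choose their own sizes (e.g.
  2,000 samples for plate-scan power studies, 8–90 for recovery studies).

One master seed drives named child streams per stage (truth, each caller,
qPCR), so stages are independently reproducible and adding a caller does
not perturb the truth set. All outputs are byte-identical under a fixed
seed.

What passing tests on this generator do **not** show: robustness to nested
or overlapping real CNVs, wave/GC intensity artifacts, population
stratification of CNV frequency, or probe-level intensity noise — the
generator works at the call level, not the intensity level, and the four
real detection algorithms are out of scope.

## Numerical and testing choices

Interval operations, matching and confusion counts are verified against
per-basepair set-membership brute force on randomized inputs. Measured
caller sensitivities are checked with exact (Clopper–Pearson) binomial CIs;
coverage is asserted per (replicate, caller) event at ≥ 93% — a
joint all-must-cover criterion would have ≈ 0.81 expected pass rate by
construction. Simulation-based checks use 40–100 seeded replicates with
problem sizes (≈ 400 regions, 12–24 samples; 2,000 samples for the plate
power study) chosen as the smallest designs whose binomial error bars still
separate the effects under test. The injected plate artifact doubles a
baseline carrier frequency of 0.4 on one 48-sample plate in a 2,000-sample
cohort; a design-time power analysis put the Bonferroni-corrected Fisher
detection power near 1.0 there, against ≈ 0.93 at baseline 0.35.

## Known limitations

* Region frequency assumes non-overlapping truth regions; overlapping or
  nested truth events would require fuzzy region membership.
* The concordance table's last size stratum is open-ended in the
  implementation (an overflow stratum appears only when occupied).
* `match_common_cnv` is quadratic per caller pair; intended for the handful
  of common regions a qPCR study tests, not genome-wide call sets.
* LOD-missing calls pass LOD filters by default (strict mode inverts
  this); this matches callers that emit no score but means a mixed call
  set is not uniformly thresholded.
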