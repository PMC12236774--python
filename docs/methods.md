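# Methods

## Problem

Copy-number variants (CNVs) are called from SNP-array intensity data
(B-allele frequency, BAF; log-R ratio, LRR) by HMM-based callers such as
PennCNV. Because those signals cannot be imputed, joint CNV analysis of
cohorts genotyped on different array products has traditionally been
restricted to the *exact match* (consensus) probe set — the intersection
of the products' manifests — which can discard the vast majority of
probes when the arrays differ in design, crippling resolution and
sensitivity. `markermatch` implements a proximity-based alternative:
instead of requiring the same probe on both arrays, it pairs each probe
of one array with a *nearby* probe of the other, on the premise that two
probes in the same small genomic neighbourhood almost always sit in the
same copy-number state.

## Matching algorithm

Given two annotated manifests (probe name, chromosome, position, BAF,
LRR mean, LRR sd), the smaller is the **reference** and the larger the
**matching** manifest (ties break by label). Matching proceeds in two
stages and returns a strict 1:1 pairing:

1. **Exact matching** — every reference probe whose (chromosome,
   position) occurs in the matching manifest is paired. Co-located
   candidates prefer an identical probe name, then the lexicographically
   smallest name. Coordinates, not names, are the default identity key,
   because array products name co-located assays inconsistently; a
   name-keyed mode is available.
2. **Nearby matching** — remaining reference probes are visited in
   ascending (chromosome order, position, name). For each, the
   candidates are the not-yet-consumed matching probes on the same
   chromosome within `d_max` base pairs (inclusive bound). The candidate
   minimizing the chosen **Method** metric is selected and consumed:
   genomic distance, |ΔBAF|, |ΔLRR mean|, or |ΔLRR sd| (`position` is
   accepted as an alias for `distance`). Candidates missing the required
   annotation are skipped and counted. Ties break by smaller distance,
   then smaller name.

The greedy outcome depends on the reference iteration order, which the
underlying procedure leaves open; pinning it to sorted genomic order
makes results deterministic and reproducible, at the cost of possibly
differing from other implementations on contested candidates. The
candidate search is a per-chromosome binary-searched window over sorted
positions, so a genome-scale run (10⁵–10⁶ probes) is minutes, not hours;
an O(R·M) full-rescan reference implementation lives in the test suite
and the optimized matcher is required to agree with it exactly.

Key parameters:

| parameter | meaning | default |
|---|---|---|
| `d_max` | maximum allowable pairing distance, bp | 10 000 (sweep grid 10 bp – 5 Mb, 12 points) |
| `method` | metric minimized among candidates | `distance` |

A 10 kb default radius reflects where coverage and downstream validation
metrics plateau in the sweep analyses this package supports; the sweep
and selection tools exist precisely so users can re-derive the operating
point for their own array pair.

## Callset validation

Test and truth callsets (PennCNV rawcnv dialect; 1-based inclusive
coordinates, `length = end − start + 1`) are compared with a **partial
confusion matrix**: true negatives are undefined because the genome's
true copy-number state is unknown. A test call is TP when a truth call
of the same sample and CNV type covers at least `min_fraction` of it
(default 0, i.e. any ≥1 bp overlap); otherwise FP. A truth call no test
call validates is FN. Counting TP/FP on the test side and FN on the
truth side makes `tp + fp` equal the evaluated test-call count exactly,
with many-to-one overlaps allowed on both sides and FN counted per truth
call (not per base pair). The exact overlap criterion behind published
CNV concordance studies varies and is often unstated, so the rule object
keeps sample-identity, type-identity and the coverage fraction all
configurable.

Derived metrics: sensitivity, FNR, PPV, FDR, F1 (harmonic mean of PPV
and sensitivity), Fowlkes–Mallows index (geometric mean), and Jaccard
index `tp/(tp+fp+fn)`. A zero denominator yields a missing value (NaN),
never 0. These satisfy `fnr = 1 − sens`, `fdr = 1 − ppv`,
`f1 = 2·ji/(1+ji)` and `fmi ≥ f1 ≥ ji`, which the test suite asserts on
random counts.

Stratified evaluation filters *both* callsets identically (size bins,
CNV type, region sets) and re-runs classification per stratum. Size bins
are half-open `(lo, hi]`: a call of length exactly 100 kb belongs to the
`<100kb` bin, making strict-inequality bin labels unambiguous. Region
sets are merged 1-based inclusive intervals (BED input is converted from
0-based half-open); a call belongs to a region given ≥1 bp overlap, and
`overlapping`/`excluding` modes partition the callset.

Sample-wise analysis aggregates TP/FP per sample into per-sample PPV
(descending order, the layout of per-sample performance plots) and
attributes the FP load to samples with PPV strictly below a cutoff,
returning both the flagged-sample fraction and the FP fraction they
contribute, plus the retained counts after excluding them — the basis of
PPV-threshold curves. Excluding a flagged sample does not change the FN
count passed through, since the uncovered truth calls of retained
samples are unaffected.

## QC tiers

Call-level thresholds (min probes, min length, min confidence) and
sample-level thresholds (max LRR sd, BAF drift, waviness factor, call
count) are plain configuration; comparisons are inclusive on the passing
side, and a call with missing confidence fails an active confidence
threshold (the conservative reading). The shipped `low` (≥10 probes,
≥20 kb) and `medium` (adds confidence ≥10 and sample caps lrr_sd ≤ 0.30,
baf_drift ≤ 0.01, wf ≤ 0.05, ≤200 calls/sample) presets are provisional
placeholders for study-specific stringency tiers: the filtering
machinery, not the constants, is the contract. `apply_qc` is idempotent
and monotone (a strictly stricter tier never keeps more calls).

## Parameter-selection curves

For each Method, metrics over the `d_max` grid are smoothed with lowess
on the log10(d_max) axis and scaled against a **Full Set** reference
callset (the callset from the complete manifest) as a ratio
`metric / full-set metric`; the scaling function is pluggable since
other normalizations (difference, normalized difference) are defensible.
`select_dmax` returns the smallest grid point whose smoothed, scaled
value is within a tolerance (default 5%) of the curve maximum — a
numerical stand-in for visual peak/plateau/inflection inspection, and
documented as a heuristic.

Smoothing span: the default is **0.4** with no robustness iterations.
On the canonical 12-point grid, a span of 0.75 puts 9 of the 12 points
in every local window; measured on step, linear-rise and sigmoid test
curves this displaces the plateau onset by at least one grid point,
which would systematically bias the plateau-selection heuristic the
smoothing feeds. A ~5-point window preserves saturation while still
damping point-to-point noise, and robustness iterations are pointless on
a dozen noiseless metric values. Curves with fewer than 4 points skip
smoothing with a warning.

## Synthetic data

`simulate_array_pair` draws a base set of probe positions uniformly
without replacement per chromosome (proportional to length), subsamples
a sparse reference, and builds a dense matching manifest from (a) one
counterpart per reference probe — an exact-position copy with
probability `shared_fraction`, otherwise a collision-free Gaussian
jittered neighbour — and (b) independent extras. Defaults (6,000 vs
24,000 probes over a 60 Mb three-chromosome genome, 15% exact overlap,
2 kb jitter) emulate the regime of a sparse screening array matched
against a much denser product, where exact matching retains only a small
probe fraction but a 10 kb radius recovers nearly everything. BAF is a
mixture of point masses near 0/1 and a Beta bulk (so BAF-based matching
has real variation); LRR means are Normal(−0.002, 0.002) and LRR sds
log-normal with median 0.10, keeping annotation scales realistic.

`simulate_callset_pair` draws per-sample truth CNVs (Poisson count,
log-uniform sizes 20 kb–2 Mb, 35% duplications, non-overlapping within
sample), detects each with probability `detection_sensitivity`
(boundaries optionally jittered but clamped to preserve the overlap with
the source call and no other), and adds false positives placed clear of
every truth call. Defaults — 500 samples × rate 10 ≈ 5,000 truth calls,
sensitivity 0.80, FP rate 10·0.8/9 per sample targeting PPV 0.90 — give
a recovery benchmark with binomial sampling error ≈ 0.005, and with zero
jitter the generator's bookkeeping must be reproduced *exactly* by the
classifier.

What the generators do not model: raw intensity signal along the genome,
LD structure, probe-design clustering (real inter-marker gaps are far
from uniform), array-specific batch effects, and the CNV caller itself.
Passing tests therefore demonstrate correctness of matching, filtering
and scoring machinery under controlled conditions — not end-to-end CNV
calling performance on real cohorts.

## Numerical conventions

- Chromosomes: `1`–`22`, `X`, `Y`, `MT`, in that sort order; `chr`
  prefixes stripped; other contigs dropped with a logged count.
- Quantiles: linear interpolation (type 7) for all medians/IQRs.
- Missing BAF/LRR annotations are NaN, never 0 (0 is a legal BAF).
- Duplicate (chromosome, position) with distinct names is legal;
  duplicate names within a manifest are an error (names are join keys).
- Copy number 2 is rejected on parse (not a CNV); states above 4 are
  rejected with a warning.
- `run_markermatch` on identical inputs is bit-reproducible; both
  simulators are fully determined by their seed.

## Problem sizes

The test suite and the acceptance script run the matcher at up to
6,000 × 24,000 probes, oracle comparisons at up to 300 × 600 probes
across 108 random instances, and callset benchmarks at ~5,000 truth
calls — sizes chosen so the full pipeline re-runs from scratch in well
under a minute per analysis while leaving the measured rates within
about ±0.01 of their configured targets.

## Known limitations

- The greedy pairing is order-dependent and not globally optimal; an
  assignment-problem solver could pair more probes in adversarial
  configurations, but sequential greedy is the defined behaviour.
- `select_dmax` encodes one reasonable plateau definition; curves with
  genuine double plateaus or slow drift deserve visual inspection.
- The rawcnv writer emits a canonical field layout; exotic PennCNV
  variants (extra annotations) round-trip through parsing but not
  byte-for-byte.
- Sample-wise FP attribution treats per-sample PPV as independent of
  sample exclusion order; it does not re-classify after each exclusion.
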