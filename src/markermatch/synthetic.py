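"""Synthetic array manifests and CNV callsets with known ground truth.

Two generators make the whole toolchain testable without proprietary
array products or cohort data:

* :func:`simulate_array_pair` builds a sparse *reference* and a dense
  *matching* manifest over a small multi-chromosome genome, with a
  controllable fraction of exact-position overlap and positional jitter
  for the remaining counterparts. It returns the intended probe
  correspondence, so matcher output can be checked pair by pair. The
  defaults emulate the regime of a screening array matched against a
  much denser product: ~6k reference probes vs ~24k matching probes over
  60 Mb with ~15% exact overlap.

* :func:`simulate_callset_pair` draws per-sample truth CNVs and derives
  a test callset with controllable detection sensitivity, false-positive
  load, and boundary jitter, returning the generator's own confusion
  bookkeeping. The defaults target ~5,000 truth calls detected at
  sensitivity 0.80 with a false-positive load sized for precision 0.90.

BAF annotations are drawn from a mixture — point masses near 0 and 1
plus a Beta bulk — so that BAF-based matching has meaningful variation;
LRR means are near-zero Gaussian and LRR sds log-normal around 0.10,
matching how these annotations look on real arrays. Neither generator
models raw intensities, signal along the genome, or the CNV-calling
HMM itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cnv_io import Callset, CNVCall
from .manifest_io import Manifest
from .validation import ConfusionCounts

DEFAULT_CHROM_LENGTHS = {"1": 30_000_000, "2": 20_000_000, "3": 10_000_000}


@dataclass(frozen=True)
class ArraySimConfig:
    """Paired-manifest generator settings.

    ``n_base_probes`` positions are drawn uniformly without replacement
    per chromosome (proportional to length). The reference manifest is a
    ``ref_fraction`` subsample of the base set. The matching manifest
    holds one counterpart per reference probe — an exact-position copy
    with probability ``shared_fraction``, otherwise a Gaussian-jittered
    neighbour (sd ``jitter_sd_bp``, collision-free) — plus independent
    extras drawn from the remaining base positions at
    ``matching_fraction``.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_base_probes: int = 30_000
    ref_fraction: float = 0.2
    matching_fraction: float = 0.75
    shared_fraction: float = 0.15
    jitter_sd_bp: float = 2_000.0
    baf_point_mass: float = 0.30      # probability of a homozygous-like BAF near 0/1
    baf_beta_a: float = 0.8
    baf_beta_b: float = 2.0
    lrr_mean_loc: float = -0.002
    lrr_mean_scale: float = 0.002
    lrr_sd_log_loc: float = float(np.log(0.10))
    lrr_sd_log_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_fraction", "matching_fraction", "shared_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0) and not (name == "shared_fraction" and v == 0.0):
                raise ValueError(f"{name} must lie in (0,1] (shared_fraction may be 0)")
        if self.jitter_sd_bp < 0:
            raise ValueError("jitter_sd_bp must be >= 0")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_base_probes > sum(self.chrom_lengths.values()):
            raise ValueError("n_base_probes exceeds total genome length")


def _draw_annotations(rng: np.random.Generator, n: int, cfg: ArraySimConfig):
    extreme = rng.random(n) < cfg.baf_point_mass
    baf = rng.beta(cfg.baf_beta_a, cfg.baf_beta_b, size=n)
    edge = np.where(rng.random(n) < 0.5, rng.uniform(0, 0.01, n), rng.uniform(0.99, 1.0, n))
    baf = np.where(extreme, edge, baf)
    lrr_mean = rng.normal(cfg.lrr_mean_loc, cfg.lrr_mean_scale, size=n)
    lrr_sd = rng.lognormal(cfg.lrr_sd_log_loc, cfg.lrr_sd_log_scale, size=n)
    return baf, lrr_mean, lrr_sd


def simulate_array_pair(
    cfg: ArraySimConfig = ArraySimConfig(),
) -> tuple[Manifest, Manifest, pd.DataFrame]:
    """Generate (reference, matching, truth_pairs); reproducible from the seed.

    ``truth_pairs`` records the intended correspondence with columns
    ref_name, match_name, chrom, ref_pos, match_pos, distance_bp, kind
    ("shared" or "jittered").
    """
    rng = np.random.default_rng(cfg.seed)
    total = sum(cfg.chrom_lengths.values())

    base_rows = []
    taken: dict[str, set[int]] = {}
    remaining = cfg.n_base_probes
    items = list(cfg.chrom_lengths.items())
    for k, (chrom, length) in enumerate(items):
        if k == len(items) - 1:
            n_chrom = remaining
        else:
            n_chrom = int(round(cfg.n_base_probes * length / total))
            n_chrom = min(n_chrom, remaining)
        remaining -= n_chrom
        pos = rng.choice(length, size=n_chrom, replace=False) + 1
        pos.sort()
        taken[chrom] = set(int(p) for p in pos)
        for p in pos:
            base_rows.append((chrom, int(p)))

    n_base = len(base_rows)
    ref_idx = rng.choice(n_base, size=int(round(cfg.ref_fraction * n_base)), replace=False)
    ref_mask = np.zeros(n_base, dtype=bool)
    ref_mask[ref_idx] = True

    baf, lmean, lsd = _draw_annotations(rng, n_base, cfg)
    ref_rows = []
    for i in np.flatnonzero(ref_mask):
        chrom, pos = base_rows[i]
        ref_rows.append((f"R_{chrom}_{pos}", chrom, pos, baf[i], lmean[i], lsd[i]))

    # counterparts: exact copies or jittered neighbours, never colliding
    match_rows = []
    truth = []
    shared = rng.random(len(ref_rows)) < cfg.shared_fraction
    cb, cl, cs = _draw_annotations(rng, len(ref_rows), cfg)
    for j, (rname, chrom, pos, *_ann) in enumerate(ref_rows):
        if shared[j]:
            mpos = pos
            kind = "shared"
        else:
            length = cfg.chrom_lengths[chrom]
            for _ in range(100):
                cand = int(round(pos + rng.normal(0, cfg.jitter_sd_bp))) if cfg.jitter_sd_bp else pos + 1
                cand = min(max(cand, 1), length)
                if cand not in taken[chrom]:
                    break
            else:  # pragma: no cover - pathological density
                raise RuntimeError("could not place a collision-free jittered probe")
            taken[chrom].add(cand)
            mpos = cand
            kind = "jittered"
        mname = f"M_{chrom}_{mpos}"
        match_rows.append((mname, chrom, mpos, cb[j], cl[j], cs[j]))
        truth.append((rname, mname, chrom, pos, mpos, abs(mpos - pos), kind))

    # independent extras from the base positions not used by the reference
    extra_pool = np.flatnonzero(~ref_mask)
    n_extra = int(round(cfg.matching_fraction * len(extra_pool)))
    extra_idx = rng.choice(extra_pool, size=n_extra, replace=False)
    eb, el, es = _draw_annotations(rng, n_extra, cfg)
    for t, i in enumerate(extra_idx):
        chrom, pos = base_rows[i]
        name = f"M_{chrom}_{pos}"
        match_rows.append((name, chrom, pos, eb[t], el[t], es[t]))

    cols = ["name", "chrom", "pos", "baf", "lrr_mean", "lrr_sd"]
    reference = Manifest("sim-reference", pd.DataFrame(ref_rows, columns=cols))
    matching = Manifest("sim-matching", pd.DataFrame(match_rows, columns=cols))
    truth_pairs = pd.DataFrame(
        truth,
        columns=["ref_name", "match_name", "chrom", "ref_pos", "match_pos",
                 "distance_bp", "kind"],
    ).sort_values(["chrom", "ref_pos"]).reset_index(drop=True)
    return reference, matching, truth_pairs


@dataclass(frozen=True)
class CallsetSimConfig:
    """Truth/test callset generator settings.

    Per sample, the truth call count is Poisson(``cnv_rate_per_sample``),
    sizes are log-uniform over ``size_dist`` and placements
    non-overlapping within a sample. Each truth call is detected with
    probability ``detection_sensitivity`` (boundaries jittered by
    ``boundary_jitter_sd_bp`` while preserving the overlap); false
    positives arrive at Poisson(``fp_rate_per_sample``) placed clear of
    every truth call. Defaults: 500 samples × rate 10 → ~5,000 truth
    calls, sensitivity 0.80, and an FP rate of 10·0.8/9 ≈ 0.889 per
    sample, which targets a precision of 0.90.
    """

    n_samples: int = 500
    cnv_rate_per_sample: float = 10.0
    size_dist: tuple[int, int] = (20_000, 2_000_000)
    dup_fraction: float = 0.35
    detection_sensitivity: float = 0.8
    fp_rate_per_sample: float = 10.0 * 0.8 / 9.0
    boundary_jitter_sd_bp: float = 0.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    snp_density_bp: float = 5_000.0   # one probe per this many bp, for numsnp
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dup_fraction", "detection_sensitivity"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        lo, hi = self.size_dist
        if not (0 < lo < hi):
            raise ValueError("size_dist bounds must satisfy 0 < lo < hi")
        if self.fp_rate_per_sample < 0 or self.cnv_rate_per_sample < 0:
            raise ValueError("rates must be >= 0")


def _place_call(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    size: int,
    occupied: dict[str, list[tuple[int, int]]],
    max_tries: int = 200,
) -> Optional[tuple[str, int, int]]:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        length = chrom_lengths[chrom]
        if size >= length:
            continue
        start = int(rng.integers(1, length - size + 1))
        end = start + size - 1
        if all(e < start or s > end for s, e in occupied.get(chrom, [])):
            occupied.setdefault(chrom, []).append((start, end))
            return chrom, start, end
    return None


def simulate_callset_pair(
    cfg: CallsetSimConfig = CallsetSimConfig(),
) -> tuple[Callset, Callset, ConfusionCounts]:
    """Generate (truth, test, expected counts); reproducible from the seed.

    With zero boundary jitter the expected ConfusionCounts are exact:
    classifying test against truth under an any-overlap rule must
    reproduce them. Jittered test boundaries are clamped so a detected
    call still overlaps its source truth call and no other truth call of
    that sample, keeping the bookkeeping exact for small jitter too.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.size_dist
    truth_calls: list[CNVCall] = []
    test_calls: list[CNVCall] = []
    tp = fn = fp = 0

    for s in range(cfg.n_samples):
        sid = f"S{s:04d}"
        occupied: dict[str, list[tuple[int, int]]] = {}
        n_truth = int(rng.poisson(cfg.cnv_rate_per_sample))
        sample_truth: list[CNVCall] = []
        for _ in range(n_truth):
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            placed = _place_call(rng, cfg.chrom_lengths, size, occupied)
            if placed is None:
                continue
            chrom, start, end = placed
            dup = rng.random() < cfg.dup_fraction
            cn = (3 if rng.random() < 0.9 else 4) if dup else (1 if rng.random() < 0.9 else 0)
            call = CNVCall(
                sample_id=sid, chrom=chrom, start=start, end=end, copy_number=cn,
                num_snps=max(3, int(round(size / cfg.snp_density_bp))),
                confidence=float(np.round(rng.gamma(2.0, 15.0), 3)),
                start_snp=f"rs{chrom}_{start}", end_snp=f"rs{chrom}_{end}",
            )
            sample_truth.append(call)
            truth_calls.append(call)

        # detection: each truth call surfaces in the test set or is missed
        neighbours = sorted(
            [(c.chrom, c.start, c.end) for c in sample_truth]
        )
        for call in sample_truth:
            if rng.random() >= cfg.detection_sensitivity:
                fn += 1
                continue
            start, end = call.start, call.end
            if cfg.boundary_jitter_sd_bp > 0:
                js = int(round(rng.normal(0, cfg.boundary_jitter_sd_bp)))
                je = int(round(rng.normal(0, cfg.boundary_jitter_sd_bp)))
                start = max(1, call.start + js)
                end = min(cfg.chrom_lengths[call.chrom], call.end + je)
                # preserve ≥1 bp overlap with the source call
                start = min(start, call.end)
                end = max(end, call.start)
                if start > end:
                    start, end = call.start, call.end
                # clamp away from other truth calls of this sample
                for oc, os_, oe in neighbours:
                    if oc != call.chrom or (os_, oe) == (call.start, call.end):
                        continue
                    if oe < call.start:
                        start = max(start, oe + 1)
                    if os_ > call.end:
                        end = min(end, os_ - 1)
            size = end - start + 1
            test_calls.append(CNVCall(
                sample_id=sid, chrom=call.chrom, start=start, end=end,
                copy_number=call.copy_number,
                num_snps=max(3, int(round(size / cfg.snp_density_bp))),
                confidence=float(np.round(rng.gamma(2.0, 15.0), 3)),
                start_snp=f"rs{call.chrom}_{start}", end_snp=f"rs{call.chrom}_{end}",
            ))
            tp += 1

        # false positives: placed clear of every truth call of this sample
        n_fp = int(rng.poisson(cfg.fp_rate_per_sample))
        for _ in range(n_fp):
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            placed = _place_call(rng, cfg.chrom_lengths, size, occupied)
            if placed is None:
                continue
            chrom, start, end = placed
            dup = rng.random() < cfg.dup_fraction
            cn = 3 if dup else 1
            test_calls.append(CNVCall(
                sample_id=sid, chrom=chrom, start=start, end=end, copy_number=cn,
                num_snps=max(3, int(round(size / cfg.snp_density_bp))),
                confidence=float(np.round(rng.gamma(2.0, 15.0), 3)),
                start_snp=f"rs{chrom}_{start}", end_snp=f"rs{chrom}_{end}",
            ))
            fp += 1

    truth = Callset("sim-truth", truth_calls)
    test = Callset("sim-test", test_calls)
    return truth, test, ConfusionCounts(tp=tp, fp=fp, fn=fn)
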