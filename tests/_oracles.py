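"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's windowed/indexed search paths:
the matcher oracle rescans every unconsumed matching probe for every
reference probe, and the classifier oracle enumerates all call pairs.
They implement the same ordering and tie rules from scratch.
"""

from __future__ import annotations

import math

from markermatch.manifest_io import CHROM_RANK, Manifest
from markermatch.matcher import MatchedPair, MatchParams


def _sorted_probes(manifest: Manifest):
    return sorted(manifest, key=lambda p: (CHROM_RANK[p.chrom], p.pos, p.name))


def naive_markermatch(a: Manifest, b: Manifest, params: MatchParams) -> list[MatchedPair]:
    """Full-rescan two-stage greedy matcher; same ordering and tie rules."""
    # orientation: smaller manifest is the reference, ties by label
    if len(a) < len(b):
        ref, mat = a, b
    elif len(b) < len(a):
        ref, mat = b, a
    else:
        ref, mat = (a, b) if a.label <= b.label else (b, a)

    ref_probes = _sorted_probes(ref)
    mat_probes = _sorted_probes(mat)
    consumed: set[str] = set()
    pairs: list[MatchedPair] = []

    # stage 1: exact (chrom, pos) intersection, identical-name preference
    matched_ref: set[str] = set()
    for rp in ref_probes:
        cands = [
            mp for mp in mat_probes
            if mp.name not in consumed and mp.chrom == rp.chrom and mp.pos == rp.pos
        ]
        if not cands:
            continue
        same = [c for c in cands if c.name == rp.name]
        chosen = same[0] if same else min(cands, key=lambda c: c.name)
        consumed.add(chosen.name)
        matched_ref.add(rp.name)
        pairs.append(MatchedPair(
            rp.name, chosen.name, rp.chrom, rp.pos, rp.pos, "exact", 0, 0.0
        ))

    # stage 2: greedy nearby matching, full rescan per reference probe
    method = params.method
    for rp in ref_probes:
        if rp.name in matched_ref:
            continue
        best = None
        for mp in mat_probes:
            if mp.name in consumed or mp.chrom != rp.chrom:
                continue
            d = abs(mp.pos - rp.pos)
            if d > params.d_max:
                continue
            if method == "distance":
                diff = float(d)
            else:
                rv = getattr(rp, method)
                mv = getattr(mp, method)
                if rv is None or mv is None:
                    continue
                diff = abs(mv - rv)
            key = (diff, d, mp.name)
            if best is None or key < best[0]:
                best = (key, mp)
        if best is None:
            continue
        (diff, d, _), mp = best
        consumed.add(mp.name)
        pairs.append(MatchedPair(
            rp.name, mp.name, rp.chrom, rp.pos, mp.pos, "nearby", int(d), float(diff)
        ))
    return pairs


def naive_classify(test, truth, same_sample=True, same_type=True, min_fraction=0.0):
    """All-pairs interval-overlap confusion counts: (tp, fp, fn)."""
    def compatible(a, b):
        if same_sample and a.sample_id != b.sample_id:
            return False
        if same_type and a.cnv_type != b.cnv_type:
            return False
        return a.chrom == b.chrom

    def validates(t, g):
        ov = min(t.end, g.end) - max(t.start, g.start) + 1
        if ov < 1:
            return False
        return min_fraction == 0.0 or ov / t.length_bp >= min_fraction

    tp = fp = 0
    covered = [False] * len(truth.calls)
    for t in test:
        hit = False
        for i, g in enumerate(truth.calls):
            if compatible(t, g) and validates(t, g):
                hit = True
                covered[i] = True
        if hit:
            tp += 1
        else:
            fp += 1
    fn = covered.count(False)
    return tp, fp, fn


def quantile_linear(values, q):
    """Type-7 (linear interpolation) quantile, written out longhand."""
    xs = sorted(values)
    if not xs:
        return math.nan
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
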