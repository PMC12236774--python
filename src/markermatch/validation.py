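"""Callset validation: partial confusion matrix, metrics, curves, selection.

A test callset is compared against a truth callset. True negatives are
undefined (the true copy-number state of the genome is unknown), so the
confusion matrix is *partial*: TP and FP are counted on the test side
(a test call is TP when a truth call of the same sample and type covers
enough of it) and FN on the truth side (truth calls no test call
overlaps). From TP/FP/FN the seven standard concordance metrics follow:

    sensitivity = TP/(TP+FN)        FNR = 1 - sensitivity
    PPV         = TP/(TP+FP)        FDR = 1 - PPV
    F1  = 2·PPV·sens/(PPV+sens)     (harmonic mean)
    FMI = sqrt(PPV·sens)            (geometric mean, Fowlkes–Mallows)
    JI  = TP/(TP+FP+FN)             (Jaccard)

A metric whose denominator is zero is reported as NaN, never 0.

The parameter-selection utilities smooth metric-vs-d_max curves with
lowess on the log10 distance axis, scale them against a Full-Set
reference callset, and pick the plateau onset as the recommended
maximum matching distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cnv_io import (
    DEFAULT_SIZE_BINS,
    Callset,
    GenomicRegionSet,
    restrict_to_regions,
    size_bin_label,
    stratify_by_size,
)

METRIC_NAMES = ("sensitivity", "fnr", "ppv", "fdr", "f1", "fmi", "ji")


@dataclass(frozen=True)
class OverlapRule:
    """When does a truth call validate a test call?

    With ``min_fraction == 0`` any ≥1 bp overlap counts; otherwise a
    single truth call must cover at least that fraction of the test
    call's length. Sample and type identity are required by default.
    """

    same_sample: bool = True
    same_type: bool = True
    min_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_fraction <= 1.0):
            raise ValueError("min_fraction must lie in [0,1]")


@dataclass(frozen=True)
class ConfusionCounts:
    """Partial confusion matrix: TP/FP on the test side, FN on the truth side."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    fnr: float
    ppv: float
    fdr: float
    f1: float
    fmi: float
    ji: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Derive the seven metrics; zero-denominator entries come back NaN."""
    tp, fp, fn = cc.tp, cc.fp, cc.fn
    sens = tp / (tp + fn) if tp + fn else math.nan
    ppv = tp / (tp + fp) if tp + fp else math.nan
    if math.isnan(sens) or math.isnan(ppv):
        f1 = fmi = math.nan
    else:
        f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else math.nan
        fmi = math.sqrt(ppv * sens)
    ji = tp / (tp + fp + fn) if tp + fp + fn else math.nan
    return MetricSet(
        sensitivity=sens,
        fnr=1 - sens if not math.isnan(sens) else math.nan,
        ppv=ppv,
        fdr=1 - ppv if not math.isnan(ppv) else math.nan,
        f1=f1,
        fmi=fmi,
        ji=ji,
    )


def _group_key(call, rule: OverlapRule) -> tuple:
    return (
        call.sample_id if rule.same_sample else None,
        call.chrom,
        call.cnv_type if rule.same_type else None,
    )


def _overlap_ok(test_call, truth_start: int, truth_end: int, rule: OverlapRule) -> bool:
    ov = min(test_call.end, truth_end) - max(test_call.start, truth_start) + 1
    if ov < 1:
        return False
    if rule.min_fraction == 0.0:
        return True
    return ov / test_call.length_bp >= rule.min_fraction


def classify_calls(
    test: Callset, truth: Callset, rule: OverlapRule = OverlapRule()
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Label every test call TP/FP and count uncovered truth calls as FN.

    Returns the counts and a per-test-call label table (sample_id, chrom,
    start, end, cnv_type, length_bp, label) for sample-wise analysis.
    Many-to-one overlaps are allowed on both sides, so tp + fp equals the
    number of test calls exactly. Test calls from samples absent from the
    truth set (when sample identity is required) are FP.
    """
    trees: dict[tuple, IntervalTree] = {}
    truth_index: dict[tuple, list] = {}
    for i, c in enumerate(truth):
        key = _group_key(c, rule)
        trees.setdefault(key, IntervalTree()).addi(c.start, c.end + 1, i)
    covered = np.zeros(len(truth.calls), dtype=bool)

    rows = []
    tp = fp = 0
    for c in test:
        tree = trees.get(_group_key(c, rule))
        hit = False
        if tree is not None:
            for iv in tree.overlap(c.start, c.end + 1):
                if _overlap_ok(c, iv.begin, iv.end - 1, rule):
                    hit = True
                    covered[iv.data] = True
        if hit:
            tp += 1
        else:
            fp += 1
        rows.append({
            "sample_id": c.sample_id, "chrom": c.chrom, "start": c.start,
            "end": c.end, "cnv_type": c.cnv_type, "length_bp": c.length_bp,
            "label": "TP" if hit else "FP",
        })
    fn = int(len(truth.calls) - covered.sum())
    labels = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "cnv_type", "length_bp", "label"],
    )
    return ConfusionCounts(tp=tp, fp=fp, fn=fn), labels


def evaluate_stratified(
    test: Callset,
    truth: Callset,
    rule: OverlapRule = OverlapRule(),
    size_bins: Sequence[tuple[float, float]] = DEFAULT_SIZE_BINS,
    by_type: bool = True,
    regions: Optional[Sequence[GenomicRegionSet]] = None,
) -> pd.DataFrame:
    """Re-run classification within each stratum; one tidy row per stratum.

    Strata: "all", each size bin, each CNV type (and each region set,
    restricted to overlapping calls). Both callsets are filtered
    identically before classification, so per-stratum counts conserve
    tp + fp = evaluated test calls.
    """
    strata: list[tuple[str, str, Callable[[Callset], Callset]]] = [
        ("all", "all", lambda cs: cs)
    ]
    for lo, hi in size_bins:
        lab = size_bin_label(lo, hi)
        strata.append((
            "size", lab,
            lambda cs, lo=lo, hi=hi: cs.filtered(lambda c: lo < c.length_bp <= hi),
        ))
    if by_type:
        for t in ("deletion", "duplication"):
            strata.append((
                "type", t, lambda cs, t=t: cs.filtered(lambda c: c.cnv_type == t)
            ))
    for reg in regions or []:
        strata.append((
            "region", reg.label,
            lambda cs, reg=reg: restrict_to_regions(cs, reg, "overlapping"),
        ))

    rows = []
    for kind, label, fltr in strata:
        cc, _ = classify_calls(fltr(test), fltr(truth), rule)
        row = {"stratum_kind": kind, "stratum": label,
               "tp": cc.tp, "fp": cc.fp, "fn": cc.fn}
        row.update(compute_metrics(cc).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def samplewise_ppv(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TP/FP/PPV from classify_calls labels, descending by PPV.

    Samples with no test calls are absent by construction.
    """
    grouped = labels.groupby("sample_id")["label"]
    tp = grouped.apply(lambda s: int((s == "TP").sum()))
    fp = grouped.apply(lambda s: int((s == "FP").sum()))
    out = pd.DataFrame({"sample_id": tp.index, "tp": tp.values, "fp": fp.values})
    out["ppv"] = out["tp"] / (out["tp"] + out["fp"])
    return out.sort_values(["ppv", "sample_id"], ascending=[False, True]).reset_index(drop=True)


@dataclass(frozen=True)
class FPAttribution:
    """How much of the FP load comes from samples below a PPV cutoff."""

    threshold: float
    n_samples: int
    n_flagged: int
    frac_samples_flagged: float
    frac_fp_attributed: float
    retained: ConfusionCounts  # counts after excluding the flagged samples


def fp_attribution(
    per_sample: pd.DataFrame, threshold: float, fn: int = 0
) -> FPAttribution:
    """Attribute false positives to samples with PPV strictly below ``threshold``.

    ``fn`` passes the truth-side count through so the retained
    ConfusionCounts stays a full partial matrix (removing test samples
    does not itself change which truth calls went undetected in the
    remaining samples).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    flagged = per_sample["ppv"] < threshold
    total_fp = int(per_sample["fp"].sum())
    fp_from_flagged = int(per_sample.loc[flagged, "fp"].sum())
    n = len(per_sample)
    retained = ConfusionCounts(
        tp=int(per_sample.loc[~flagged, "tp"].sum()),
        fp=int(per_sample.loc[~flagged, "fp"].sum()),
        fn=fn,
    )
    return FPAttribution(
        threshold=threshold,
        n_samples=n,
        n_flagged=int(flagged.sum()),
        frac_samples_flagged=flagged.sum() / n if n else math.nan,
        frac_fp_attributed=fp_from_flagged / total_fp if total_fp else 0.0,
        retained=retained,
    )


def threshold_curve(
    per_sample: pd.DataFrame, thresholds: Sequence[float], fn: int = 0
) -> pd.DataFrame:
    """Aggregate metrics after excluding samples below each PPV threshold."""
    rows = []
    for t in thresholds:
        att = fp_attribution(per_sample, t, fn=fn)
        row = {"threshold": t, "n_flagged": att.n_flagged,
               "frac_fp_attributed": att.frac_fp_attributed}
        row.update(compute_metrics(att.retained).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def ratio_scale(values: np.ndarray, reference: float) -> np.ndarray:
    """Default Full-Set scaling: metric divided by the reference metric."""
    if reference == 0 or math.isnan(reference):
        return np.full_like(values, np.nan, dtype=float)
    return values / reference


@dataclass
class MetricCurve:
    """Metric-vs-d_max curve for one Method: raw, smoothed, and scaled values."""

    method: str
    d_max: np.ndarray
    raw: pd.DataFrame       # one column per metric, one row per grid point
    smoothed: pd.DataFrame
    scaled: pd.DataFrame


def build_metric_curves(
    results: Sequence[tuple],  # (MatchParams-like with .d_max/.method, ConfusionCounts)
    full_set_reference: ConfusionCounts,
    span: float = 0.4,
    scale_fn: Callable[[np.ndarray, float], np.ndarray] = ratio_scale,
) -> dict[str, MetricCurve]:
    """Per-Method metric curves over the d_max grid.

    Raw metrics are lowess-smoothed on the log10(d_max) axis (skipped
    with a warning below 4 grid points) and then scaled against the
    Full-Set reference metrics — by ratio unless another strategy is
    plugged in.

    The default span of 0.4 keeps the local window to ~5 of the 12
    canonical grid points: a wider window (e.g. 0.75) mixes most of the
    rising flank into every fitted value and displaces a curve's plateau
    onset by a full grid point, which would defeat the downstream
    plateau-selection heuristic. Robustness iterations are off — the
    inputs are a handful of noiseless metric values, not outlier-laden
    scatter.
    """
    ref_metrics = compute_metrics(full_set_reference).to_dict()
    by_method: dict[str, list[tuple[int, ConfusionCounts]]] = {}
    for params, cc in results:
        by_method.setdefault(params.method, []).append((params.d_max, cc))

    curves: dict[str, MetricCurve] = {}
    for method, points in by_method.items():
        points.sort(key=lambda t: t[0])
        grid = np.array([d for d, _ in points], dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("d_max grid must be strictly increasing per method")
        raw = pd.DataFrame(
            [compute_metrics(cc).to_dict() for _, cc in points]
        )[list(METRIC_NAMES)]
        x = np.log10(grid)
        smoothed = raw.copy()
        if len(grid) >= 4:
            for col in METRIC_NAMES:
                y = raw[col].to_numpy(dtype=float)
                ok = ~np.isnan(y)
                if ok.sum() >= 4:
                    sm = lowess(y[ok], x[ok], frac=span, it=0, return_sorted=False)
                    out = np.full_like(y, np.nan)
                    out[ok] = sm
                    smoothed[col] = out
        else:
            import warnings

            warnings.warn("fewer than 4 grid points: smoothing skipped", stacklevel=2)
        scaled = smoothed.copy()
        for col in METRIC_NAMES:
            scaled[col] = scale_fn(smoothed[col].to_numpy(dtype=float), ref_metrics[col])
        curves[method] = MetricCurve(
            method=method, d_max=grid.astype(int), raw=raw,
            smoothed=smoothed, scaled=scaled,
        )
    return curves


def select_dmax(
    curve: MetricCurve, tolerance: float = 0.05, metric: str = "f1"
) -> int:
    """Plateau-onset heuristic for the operating maximum matching distance.

    Returns the smallest grid d_max whose smoothed, scaled metric is
    within ``tolerance`` of the curve maximum — a numerical stand-in for
    visual peak/plateau/inflection inspection.
    """
    if len(curve.d_max) < 2:
        raise ValueError("curve needs at least 2 grid points")
    vals = curve.scaled[metric].to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError(f"metric {metric!r} is undefined along the whole curve")
    cutoff = (1.0 - tolerance) * np.nanmax(vals)
    for d, v in zip(curve.d_max, vals):
        if not math.isnan(v) and v >= cutoff:
            return int(d)
    raise AssertionError("unreachable: the maximum always satisfies its own cutoff")
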