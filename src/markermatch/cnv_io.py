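"""CNV callsets: PennCNV rawcnv parsing, QC tiers, size strata, region filters.

A callset is a list of copy-number calls, one per sample × segment, in
the PennCNV one-line-per-call text convention::

    chr1:1000-2000 numsnp=10 length=1001 state2,cn=1 S1.txt startsnp=rs1 endsnp=rs2 conf=15.13

Coordinates are 1-based inclusive, so ``length = end - start + 1``.
Copy number 2 is not a CNV and is rejected on parse; copy numbers above
4 are rejected with a warning (the HMM states span 0–4). BED region
files are 0-based half-open on disk and converted to 1-based inclusive
on load.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .manifest_io import CHROM_RANK, normalize_chrom

logger = logging.getLogger(__name__)

_STATE_FOR_CN = {0: 1, 1: 2, 3: 5, 4: 6}

#: Default CNV size bins, half-open [lo, hi) in bp.
DEFAULT_SIZE_BINS: tuple[tuple[int, float], ...] = (
    (0, 100_000),
    (100_000, 500_000),
    (500_000, 1_000_000),
    (1_000_000, math.inf),
)


def size_bin_label(lo: float, hi: float) -> str:
    def fmt(x: float) -> str:
        if x >= 1_000_000:
            return f"{x / 1_000_000:g}Mb"
        if x >= 1_000:
            return f"{x / 1_000:g}kb"
        return f"{x:g}bp"

    if lo == 0:
        return f"<{fmt(hi)}"
    if math.isinf(hi):
        return f">={fmt(lo)}"
    return f"{fmt(lo)}-{fmt(hi)}"


@dataclass(frozen=True)
class CNVCall:
    """One copy-number segment for one sample, 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    num_snps: int
    confidence: Optional[float] = None
    start_snp: Optional[str] = None
    end_snp: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end: {self.start} > {self.end}")
        if self.copy_number == 2 or not (0 <= self.copy_number <= 4):
            raise ValueError(f"invalid CNV copy number {self.copy_number}")
        if self.num_snps < 1:
            raise ValueError("num_snps must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def cnv_type(self) -> str:
        return "deletion" if self.copy_number < 2 else "duplication"

    def to_rawcnv_line(self) -> str:
        state = _STATE_FOR_CN[self.copy_number]
        parts = [
            f"chr{self.chrom}:{self.start}-{self.end}",
            f"numsnp={self.num_snps}",
            f"length={self.length_bp:,}".replace(",", ""),
            f"state{state},cn={self.copy_number}",
            self.sample_id,
            f"startsnp={self.start_snp or 'NA'}",
            f"endsnp={self.end_snp or 'NA'}",
        ]
        if self.confidence is not None:
            parts.append(f"conf={self.confidence:g}")
        return " ".join(parts)


@dataclass
class Callset:
    """A labelled collection of CNV calls at a given QC stringency tier."""

    label: str
    calls: list[CNVCall] = field(default_factory=list)
    qc_tier: str = "raw"

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for c in self.calls:
            key = (c.sample_id, c.chrom, c.start, c.end, c.copy_number)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(c)
        deduped.sort(key=lambda c: (c.sample_id, CHROM_RANK[c.chrom], c.start, c.end))
        self.calls = deduped

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def samples(self) -> list[str]:
        return sorted({c.sample_id for c in self.calls})

    def filtered(self, pred, label: Optional[str] = None, qc_tier: Optional[str] = None) -> "Callset":
        return Callset(
            label or self.label,
            [c for c in self.calls if pred(c)],
            qc_tier or self.qc_tier,
        )


_RAWCNV_RE = re.compile(
    r"^(?P<loc>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+"
    r"length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
    r"(?:\s+startsnp=(?P<startsnp>\S+))?"
    r"(?:\s+endsnp=(?P<endsnp>\S+))?"
    r"(?:\s+conf=(?P<conf>[-\d.eE+]+))?"
    r"\s*$"
)


def parse_rawcnv(
    source: Union[str, Path, Iterable[str]],
    label: str = "rawcnv",
    qc_tier: str = "raw",
) -> tuple[Callset, list[tuple[int, str]]]:
    """Parse PennCNV rawcnv text into a Callset.

    ``source`` may be a path or an iterable of lines. Returns the callset
    and a list of (line number, reason) for rejected/malformed lines —
    copy number 2, copy number > 4, start > end, or unparseable layout.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [str(l) for l in source]

    calls: list[CNVCall] = []
    rejected: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        m = _RAWCNV_RE.match(line.strip())
        if not m:
            rejected.append((lineno, "unparseable line"))
            continue
        chrom = normalize_chrom(m["loc"])
        if chrom is None:
            rejected.append((lineno, f"non-canonical chromosome {m['loc']!r}"))
            continue
        start, end = int(m["start"]), int(m["end"])
        cn = int(m["cn"])
        if cn == 2:
            rejected.append((lineno, "cn=2 is not a CNV"))
            continue
        if cn > 4:
            rejected.append((lineno, f"copy number {cn} above 4"))
            continue
        if start > end:
            rejected.append((lineno, "start > end"))
            continue
        conf = float(m["conf"]) if m["conf"] is not None else None
        calls.append(CNVCall(
            sample_id=m["sample"],
            chrom=chrom,
            start=start,
            end=end,
            copy_number=cn,
            num_snps=int(m["numsnp"]),
            confidence=conf,
            start_snp=m["startsnp"],
            end_snp=m["endsnp"],
        ))
    if rejected:
        logger.warning("rejected %d rawcnv lines: %s", len(rejected), rejected[:5])
    return Callset(label, calls, qc_tier), rejected


def write_rawcnv(callset: Callset, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for call in callset:
            fh.write(call.to_rawcnv_line() + "\n")
    return path


@dataclass(frozen=True)
class SampleQC:
    """Per-sample PennCNV QC statistics."""

    sample_id: str
    lrr_mean: float = 0.0
    lrr_sd: float = 0.0
    baf_mean: float = 0.5
    baf_sd: float = 0.0
    baf_drift: float = 0.0
    wf: float = 0.0
    call_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lrr_sd < 0 or self.baf_drift < 0:
            raise ValueError("lrr_sd and baf_drift must be >= 0")
        if not (0.0 <= self.baf_mean <= 1.0):
            raise ValueError("baf_mean outside [0,1]")


SAMPLE_QC_COLUMNS = [
    "sample_id", "lrr_mean", "lrr_sd", "baf_mean", "baf_sd",
    "baf_drift", "wf", "call_count",
]


def read_sample_qc(path: Union[str, Path]) -> list[SampleQC]:
    """Read a TSV of per-sample QC statistics (columns as SAMPLE_QC_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_QC_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"sample QC table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        cc = getattr(row, "call_count", None)
        out.append(SampleQC(
            sample_id=str(row.sample_id),
            lrr_mean=float(row.lrr_mean),
            lrr_sd=float(row.lrr_sd),
            baf_mean=float(row.baf_mean),
            baf_sd=float(row.baf_sd),
            baf_drift=float(row.baf_drift),
            wf=float(row.wf),
            call_count=None if cc is None or pd.isna(cc) else int(cc),
        ))
    return out


def write_sample_qc(samples: Sequence[SampleQC], path: Union[str, Path]) -> Path:
    path = Path(path)
    pd.DataFrame([s.__dict__ for s in samples])[SAMPLE_QC_COLUMNS].to_csv(
        path, sep="\t", index=False
    )
    return path


@dataclass(frozen=True)
class QCTierConfig:
    """Call- and sample-level QC thresholds.

    All comparisons are boundary-inclusive on the passing side (a call
    with ``num_snps == min_num_snps`` survives). The permissive defaults
    make the tier an identity filter. The shipped ``low``/``medium``
    presets are provisional placeholders for study-specific stringency
    tiers — the machinery, not the constants, is the contract.
    """

    name: str = "raw"
    min_num_snps: int = 1
    min_length_bp: int = 1
    min_confidence: float = -math.inf
    max_sample_lrr_sd: float = math.inf
    max_sample_baf_drift: float = math.inf
    max_sample_wf: float = math.inf
    max_calls_per_sample: int = 10**9

    @property
    def sample_filters_active(self) -> bool:
        return (
            math.isfinite(self.max_sample_lrr_sd)
            or math.isfinite(self.max_sample_baf_drift)
            or math.isfinite(self.max_sample_wf)
            or self.max_calls_per_sample < 10**9
        )

    @classmethod
    def permissive(cls) -> "QCTierConfig":
        return cls()

    @classmethod
    def low(cls) -> "QCTierConfig":
        return cls(name="low", min_num_snps=10, min_length_bp=20_000)

    @classmethod
    def medium(cls) -> "QCTierConfig":
        return cls(
            name="medium",
            min_num_snps=10,
            min_length_bp=20_000,
            min_confidence=10.0,
            max_sample_lrr_sd=0.30,
            max_sample_baf_drift=0.01,
            max_sample_wf=0.05,
            max_calls_per_sample=200,
        )


QC_TIERS = {
    "raw": QCTierConfig.permissive,
    "low": QCTierConfig.low,
    "medium": QCTierConfig.medium,
}


def apply_qc(
    callset: Callset,
    tier: QCTierConfig,
    samples: Optional[Sequence[SampleQC]] = None,
) -> Callset:
    """Apply a QC tier; returns a new Callset with ``qc_tier`` set.

    Call-level thresholds (num_snps, length, confidence) drop individual
    calls; sample-level thresholds (lrr_sd, baf_drift, wf, call count)
    drop every call from a failing sample. A call with missing confidence
    fails an active confidence threshold. Removal counts are logged per
    criterion.
    """
    failed_samples: set[str] = set()
    if tier.sample_filters_active:
        if samples is None:
            raise ValueError("sample-level thresholds active but no sample QC table given")
        by_id = {s.sample_id: s for s in samples}
        counts: dict[str, int] = {}
        for c in callset:
            counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
        for sid in counts:
            if sid not in by_id:
                raise KeyError(f"sample {sid!r} absent from the sample QC table")
        for sid, count in counts.items():
            s = by_id[sid]
            call_count = s.call_count if s.call_count is not None else count
            if (
                s.lrr_sd > tier.max_sample_lrr_sd
                or s.baf_drift > tier.max_sample_baf_drift
                or s.wf > tier.max_sample_wf
                or call_count > tier.max_calls_per_sample
            ):
                failed_samples.add(sid)

    removed = {"num_snps": 0, "length": 0, "confidence": 0, "sample": 0}
    kept: list[CNVCall] = []
    for c in callset:
        if c.sample_id in failed_samples:
            removed["sample"] += 1
        elif c.num_snps < tier.min_num_snps:
            removed["num_snps"] += 1
        elif c.length_bp < tier.min_length_bp:
            removed["length"] += 1
        elif (c.confidence is None and tier.min_confidence > -math.inf) or (
            c.confidence is not None and c.confidence < tier.min_confidence
        ):
            removed["confidence"] += 1
        else:
            kept.append(c)
    if any(removed.values()):
        logger.info("QC tier %s removed calls: %s", tier.name, removed)
    return Callset(callset.label, kept, qc_tier=tier.name)


def stratify_by_size(
    callset: Callset,
    bins: Sequence[tuple[float, float]] = DEFAULT_SIZE_BINS,
    include_all: bool = True,
) -> dict[str, Callset]:
    """Partition calls into half-open (lo, hi] length bins (+ an "all" bin).

    A length exactly on a bin boundary belongs to the lower bin, so the
    strict-inequality bin labels (e.g. "100kb < CNV < 500kb") are
    unambiguous.
    """
    for (l1, h1), (l2, h2) in zip(bins, list(bins)[1:]):
        if h1 > l2:
            raise ValueError("size bins overlap")
    out: dict[str, Callset] = {}
    if include_all:
        out["all"] = Callset(callset.label, list(callset.calls), callset.qc_tier)
    for lo, hi in bins:
        lab = size_bin_label(lo, hi)
        out[lab] = callset.filtered(lambda c, lo=lo, hi=hi: lo < c.length_bp <= hi)
    return out


@dataclass
class GenomicRegionSet:
    """Merged 1-based inclusive intervals (telomeric / centromeric / segdup / custom)."""

    label: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            c = normalize_chrom(chrom)
            if c is None:
                continue
            if start > end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(c, []).append((start, end))
        for c in sorted(by_chrom, key=CHROM_RANK.get):
            ivs = sorted(by_chrom[c])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((c, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((c, cur_s, cur_e))
        self.intervals = merged

    @classmethod
    def from_bed(cls, path: Union[str, Path], label: Optional[str] = None) -> "GenomicRegionSet":
        """Load BED3 (0-based half-open) and convert to 1-based inclusive."""
        path = Path(path)
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start) + 1, int(end)))
        return cls(label or path.stem, intervals)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        return out


def restrict_to_regions(
    callset: Callset, regions: GenomicRegionSet, mode: str = "overlapping"
) -> Callset:
    """Keep calls with ≥1 bp overlap with any region (or the complement).

    ``overlapping`` ∪ ``excluding`` partitions the input.
    """
    if mode not in ("overlapping", "excluding"):
        raise ValueError(f"mode must be 'overlapping' or 'excluding', got {mode!r}")
    trees = regions.trees()

    def overlaps(c: CNVCall) -> bool:
        tree = trees.get(c.chrom)
        return bool(tree and tree.overlap(c.start, c.end + 1))

    keep = overlaps if mode == "overlapping" else (lambda c: not overlaps(c))
    return callset.filtered(keep, label=f"{callset.label}|{regions.label}:{mode}")


def callset_summary(callset: Callset) -> pd.DataFrame:
    """Descriptive statistics overall and split by CNV type.

    One row per type in {all, deletion, duplication}: total call count,
    per-sample mean count, mean/median size, mean confidence, and number
    of samples with ≥1 call.
    """
    rows = []
    for cnv_type in ("all", "deletion", "duplication"):
        calls = [
            c for c in callset
            if cnv_type == "all" or c.cnv_type == cnv_type
        ]
        samples = {c.sample_id for c in calls}
        sizes = np.array([c.length_bp for c in calls], dtype=float)
        confs = np.array(
            [c.confidence for c in calls if c.confidence is not None], dtype=float
        )
        rows.append({
            "cnv_type": cnv_type,
            "n_calls": len(calls),
            "per_sample_mean": len(calls) / len(samples) if samples else math.nan,
            "size_mean_bp": float(sizes.mean()) if sizes.size else math.nan,
            "size_median_bp": float(np.median(sizes)) if sizes.size else math.nan,
            "confidence_mean": float(confs.mean()) if confs.size else math.nan,
            "n_samples": len(samples),
        })
    return pd.DataFrame(rows)
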