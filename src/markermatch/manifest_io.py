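"""Reading, writing, and summarizing annotated array manifests.

A *manifest* is the table of probes on one genotyping-array product. For
CNV work each probe carries, besides its genomic coordinate, three
intensity-distribution annotations: a B-allele frequency (BAF) and the
mean and standard deviation of the log-R ratio (LRR). Two file dialects
are supported:

* annotated manifest — header ``Name Chr Position BAF LRR_mean LRR_sd``,
  tab- or comma-separated;
* PennCNV PFB — header ``Name Chr Position PFB``, tab-separated; the PFB
  column maps onto the BAF slot and the LRR annotations are missing.

Manifests are held as pandas DataFrames sorted by (chromosome order,
position, name) with missing annotations encoded as NaN — never 0, since
0 is a legal BAF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical chromosome labels in sort order: autosomes, then X, Y, MT.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

MANIFEST_COLUMNS = ["name", "chrom", "pos", "baf", "lrr_mean", "lrr_sd"]

_ANNOTATED_HEADER = ["Name", "Chr", "Position", "BAF", "LRR_mean", "LRR_sd"]
_PFB_HEADER = ["Name", "Chr", "Position", "PFB"]

DIALECTS = ("annotated_tsv", "annotated_csv", "pfb")


class ManifestFormatError(ValueError):
    """A manifest file violates the expected layout."""


def normalize_chrom(label: object) -> Optional[str]:
    """Map a chromosome label to its canonical form, or None if non-canonical.

    Strips a leading ``chr``/``CHR`` prefix and maps ``M`` to ``MT``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s == "M":
        s = "MT"
    return s if s in CHROM_RANK else None


@dataclass(frozen=True)
class Probe:
    """One array marker with coordinate and intensity annotations.

    ``baf``, ``lrr_mean``, ``lrr_sd`` are None when missing; a probe with
    a missing annotation is ineligible for the corresponding matching
    Method.
    """

    name: str
    chrom: str
    pos: int
    baf: Optional[float] = None
    lrr_mean: Optional[float] = None
    lrr_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("probe name must be non-empty")
        if self.chrom not in CHROM_RANK:
            raise ValueError(f"non-canonical chromosome {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.baf is not None and not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"BAF outside [0,1]: {self.baf}")
        if self.lrr_sd is not None and self.lrr_sd < 0:
            raise ValueError(f"negative LRR sd: {self.lrr_sd}")


@dataclass
class Manifest:
    """An ordered, deduplicated probe collection for one array.

    The backing frame is always sorted ascending by (chromosome order,
    position, name); probe names are unique. Duplicate (chrom, pos) with
    distinct names is allowed — arrays carry co-located probes.
    """

    label: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.df = _canonicalize_frame(self.df)

    @classmethod
    def from_probes(cls, label: str, probes: Iterable[Probe]) -> "Manifest":
        rows = [
            (p.name, p.chrom, p.pos, p.baf, p.lrr_mean, p.lrr_sd) for p in probes
        ]
        df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        return cls(label, df)

    @classmethod
    def empty(cls, label: str = "empty") -> "Manifest":
        return cls(label, pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Probe]:
        for row in self.df.itertuples(index=False):
            yield Probe(
                name=row.name,
                chrom=row.chrom,
                pos=int(row.pos),
                baf=None if pd.isna(row.baf) else float(row.baf),
                lrr_mean=None if pd.isna(row.lrr_mean) else float(row.lrr_mean),
                lrr_sd=None if pd.isna(row.lrr_sd) else float(row.lrr_sd),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Manifest):
            return NotImplemented
        if len(self) != len(other):
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if not (a["name"].equals(b["name"]) and a["chrom"].equals(b["chrom"])):
            return False
        if not np.array_equal(a["pos"].to_numpy(), b["pos"].to_numpy()):
            return False
        for col in ("baf", "lrr_mean", "lrr_sd"):
            x = a[col].to_numpy(dtype=float)
            y = b[col].to_numpy(dtype=float)
            if not np.allclose(x, y, rtol=0, atol=1e-9, equal_nan=True):
                return False
        return True

    def subset_by_names(self, names: Sequence[str], label: Optional[str] = None) -> "Manifest":
        """Probes whose names are in ``names``; raises on unknown names."""
        wanted = set(names)
        missing = wanted - set(self.df["name"])
        if missing:
            raise KeyError(f"names absent from manifest {self.label!r}: {sorted(missing)[:5]}")
        sub = self.df[self.df["name"].isin(wanted)]
        return Manifest(label or self.label, sub.copy())


def _canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestFormatError(f"manifest frame missing column {col!r}")
    df = df[MANIFEST_COLUMNS]
    if len(df) == 0:
        df = df.astype(
            {"name": str, "chrom": str, "pos": np.int64,
             "baf": float, "lrr_mean": float, "lrr_sd": float}
        )
        return df.reset_index(drop=True)

    chrom = df["chrom"].map(normalize_chrom)
    dropped = int(chrom.isna().sum())
    if dropped:
        logger.info("dropping %d probes on non-canonical chromosomes", dropped)
        df = df[chrom.notna()]
        chrom = chrom[chrom.notna()]
    df = df.assign(chrom=chrom)

    dup = df["name"].duplicated()
    if dup.any():
        raise ManifestFormatError(
            f"duplicate probe names: {sorted(df.loc[dup, 'name'].unique())[:5]}"
        )

    df["name"] = df["name"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "name"].iloc[0]
        raise ManifestFormatError(f"position < 1 for probe {bad!r}")
    for col in ("baf", "lrr_mean", "lrr_sd"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    baf = df["baf"]
    if ((baf < 0) | (baf > 1)).any():
        raise ManifestFormatError("BAF values outside [0,1]")
    if (df["lrr_sd"] < 0).any():
        raise ManifestFormatError("negative LRR sd values")

    rank = df["chrom"].map(CHROM_RANK)
    df = (
        df.assign(_rank=rank)
        .sort_values(["_rank", "pos", "name"], kind="mergesort")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    cols = [c.strip() for c in header.replace(",", "\t").split("\t") if c.strip()]
    lower = [c.lower() for c in cols]
    if "pfb" in lower:
        return "pfb"
    return "annotated_csv" if "," in header else "annotated_tsv"


def read_manifest(
    path: Union[str, Path],
    dialect: Optional[str] = None,
    label: Optional[str] = None,
) -> Manifest:
    """Read a manifest file into a sorted, validated :class:`Manifest`.

    Parameters
    ----------
    path : path to the manifest file.
    dialect : one of ``annotated_tsv``, ``annotated_csv``, ``pfb``;
        sniffed from the header when omitted.
    label : manifest label; defaults to the file stem.

    Raises
    ------
    ManifestFormatError
        On a missing required column, a duplicate probe name, or an
        unparseable position (reported with its line number).
    """
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    sep = "," if dialect == "annotated_csv" else "\t"
    expected = _PFB_HEADER if dialect == "pfb" else _ANNOTATED_HEADER

    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {c.lower(): c for c in raw.columns}
    for col in expected:
        if col.lower() not in colmap:
            raise ManifestFormatError(f"{path}: missing required column {col!r}")

    name = raw[colmap["name"]]
    chrom = raw[colmap["chr"]]
    pos_raw = raw[colmap["position"]]
    pos = pd.to_numeric(pos_raw, errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based, after header
        raise ManifestFormatError(
            f"{path}: unparseable position {pos_raw[bad].iloc[0]!r} at line {line}"
        )

    def _num(col: str) -> pd.Series:
        s = raw[colmap[col]].replace({"": np.nan, "NA": np.nan, "nan": np.nan})
        return pd.to_numeric(s, errors="raise")

    if dialect == "pfb":
        baf = _num("pfb")
        lrr_mean = pd.Series(np.nan, index=raw.index)
        lrr_sd = pd.Series(np.nan, index=raw.index)
    else:
        baf = _num("baf")
        lrr_mean = _num("lrr_mean")
        lrr_sd = _num("lrr_sd")

    df = pd.DataFrame(
        {"name": name, "chrom": chrom, "pos": pos.astype(np.int64),
         "baf": baf, "lrr_mean": lrr_mean, "lrr_sd": lrr_sd}
    )
    return Manifest(label or path.stem, df)


def write_manifest(manifest: Manifest, path: Union[str, Path], dialect: str = "annotated_tsv") -> Path:
    """Write a manifest; ``read_manifest(write_manifest(m)) == m`` for annotated dialects."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    sep = "," if dialect == "annotated_csv" else "\t"
    df = manifest.df
    if dialect == "pfb":
        out = pd.DataFrame(
            {"Name": df["name"], "Chr": df["chrom"],
             "Position": df["pos"], "PFB": df["baf"]}
        )
    else:
        out = pd.DataFrame(
            {"Name": df["name"], "Chr": df["chrom"], "Position": df["pos"],
             "BAF": df["baf"], "LRR_mean": df["lrr_mean"], "LRR_sd": df["lrr_sd"]}
        )
    out.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.10g")
    return path


@dataclass
class DistributionSummary:
    """Per-manifest coverage and distribution statistics.

    Gap statistics pool inter-marker gaps (between consecutive sorted
    positions, per chromosome) genome-wide. All medians/IQRs use linear
    interpolation (type-7 quantiles). Missing statistics are NaN.
    """

    coverage_rate: float
    n_probes: int
    gap_median_bp: float
    gap_iqr_bp: float
    gap_log10_median: float
    gap_log10_iqr: float
    baf_median: float
    baf_iqr: float
    lrr_mean_median: float
    lrr_mean_iqr: float
    lrr_sd_median: float
    lrr_sd_iqr: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return math.nan, math.nan
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(q50), float(q75 - q25)


def intermarker_gaps(manifest: Manifest) -> np.ndarray:
    """Gaps between consecutive probes, computed per chromosome and pooled."""
    gaps: list[np.ndarray] = []
    for _, grp in manifest.df.groupby("chrom", sort=False):
        p = grp["pos"].to_numpy()
        if p.size > 1:
            gaps.append(np.diff(p))
    if not gaps:
        return np.array([], dtype=np.int64)
    return np.concatenate(gaps)


def summarize_manifest(manifest: Manifest, parent_size: Optional[int] = None) -> DistributionSummary:
    """Distribution summary of a manifest (optionally as a subset of a parent).

    ``coverage_rate`` is 1.0 for a full manifest, or len(manifest)/parent_size
    when the size of the parent array is supplied.
    """
    n = len(manifest)
    if parent_size is not None:
        if parent_size < n:
            raise ValueError("parent_size smaller than the manifest itself")
        coverage = n / parent_size if parent_size else math.nan
    else:
        coverage = 1.0 if n else math.nan

    gaps = intermarker_gaps(manifest).astype(float)
    gap_med, gap_iqr = _median_iqr(gaps)
    if gaps.size:
        log_med, log_iqr = _median_iqr(np.log10(gaps[gaps > 0]))
    else:
        log_med = log_iqr = math.nan
    baf_med, baf_iqr = _median_iqr(manifest.df["baf"].to_numpy())
    lm_med, lm_iqr = _median_iqr(manifest.df["lrr_mean"].to_numpy())
    ls_med, ls_iqr = _median_iqr(manifest.df["lrr_sd"].to_numpy())
    return DistributionSummary(
        coverage_rate=coverage,
        n_probes=n,
        gap_median_bp=gap_med,
        gap_iqr_bp=gap_iqr,
        gap_log10_median=log_med,
        gap_log10_iqr=log_iqr,
        baf_median=baf_med,
        baf_iqr=baf_iqr,
        lrr_mean_median=lm_med,
        lrr_mean_iqr=lm_iqr,
        lrr_sd_median=ls_med,
        lrr_sd_iqr=ls_iqr,
    )
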