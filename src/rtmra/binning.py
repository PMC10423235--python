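"""Genome partitioning by replication timing and chromatin state.

Replication timing (RT) tracks assign one numeric value per genomic
interval (by default, higher = earlier replication).  The analysis
universe is restricted to constitutive-RT regions — regions replicating
at the same time across tissues — and then partitioned into ``n_bins``
bins of equal RT-value range (E1, E2, L1, L2 for the default four),
*not* equal genomic mass: the bins deliberately differ in megabases.

All coordinates are BED convention: 0-based, half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

RT_BIN_LABELS = ("E1", "E2", "L1", "L2")
EARLY_LABELS = ("E1", "E2")
LATE_LABELS = ("L1", "L2")

ACTIVE_SOURCE_LABELS = ("active", "active2")
INACTIVE_SOURCE_LABEL = "inactive"


class ValidationError(ValueError):
    """Input violates a structural invariant (overlap, bad label, ...)."""


class ParseError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _sorted_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start) and reject overlaps within a chromosome."""
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValidationError(
                f"overlapping intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        if np.any(starts >= ends):
            raise ValidationError(f"empty or inverted interval on {chrom}")
    return df


@dataclass
class RTTrack:
    """A replication-timing track: disjoint sorted intervals + one RT value each.

    Parameters
    ----------
    intervals
        DataFrame with columns ``chrom, start, end, rt``.
    early_is_high
        Orientation of the RT axis: ``True`` means a higher value is
        replicated earlier (the default convention of Repli-seq
        early/late log-ratios).
    source
        Free-text provenance note.
    """

    intervals: pd.DataFrame
    early_is_high: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "rt"}
        missing = required - set(self.intervals.columns)
        if missing:
            raise ValidationError(f"RTTrack frame missing columns {sorted(missing)}")
        if len(self.intervals) == 0:
            raise ValidationError("RTTrack must contain at least one interval")
        if not np.all(np.isfinite(self.intervals["rt"].to_numpy(dtype=float))):
            raise ValidationError("all rt values must be finite")
        self.intervals = _sorted_interval_frame(
            self.intervals[["chrom", "start", "end", "rt"]].copy()
        )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_span_bp(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def to_bedgraph(self, path: str) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


def load_rt_track(path: str, early_is_high: bool = True) -> RTTrack:
    """Load a 4-column bedGraph (chrom, start, end, value) as an :class:`RTTrack`.

    Lines starting with ``#`` or ``track`` are skipped.  A malformed line
    raises :class:`ParseError` with its 1-based line number; overlapping
    intervals raise :class:`ValidationError`.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ParseError(f"{path}: no data lines")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rt"])
    return RTTrack(df, early_is_high=early_is_high, source=str(path))


def load_bed3(path: str) -> pd.DataFrame:
    """Load a BED3 file into a validated (chrom, start, end) frame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2],
        dtype={0: str, 1: np.int64, 2: np.int64},
    )
    return _sorted_interval_frame(df)


def restrict_to_constitutive(track: RTTrack, regions: pd.DataFrame) -> RTTrack:
    """Intersect a track with a region set (e.g. constitutive-RT regions).

    Each output interval inherits the RT value of the enclosing track
    interval.  Raises :class:`ValidationError` if the intersection is empty.
    """
    regions = _sorted_interval_frame(regions[["chrom", "start", "end"]].copy())
    a = pr.PyRanges(
        track.intervals.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End"}
        )
    )
    b = pr.PyRanges(
        regions.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})
    )
    out = a.intersect(b).df
    if len(out) == 0:
        raise ValidationError("track and constitutive regions do not intersect")
    out = out.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end"}
    )[["chrom", "start", "end", "rt"]]
    out["chrom"] = out["chrom"].astype(str)
    return RTTrack(out, early_is_high=track.early_is_high, source=track.source)


def _bin_labels(n_bins: int) -> list[str]:
    if n_bins == 4:
        return list(RT_BIN_LABELS)
    # generalized labels, earliest to latest
    return [f"B{i + 1}" for i in range(n_bins)]


@dataclass
class RTBinning:
    """Partition of a track into equal-RT-range bins, earliest → latest.

    ``boundaries`` are ascending RT values (length ``n_bins + 1``);
    ``labels`` run earliest → latest; ``intervals`` carries a ``bin``
    column; ``bin_sizes_mb`` maps label → megabases of assigned span.
    """

    n_bins: int
    boundaries: np.ndarray
    labels: list[str]
    intervals: pd.DataFrame
    bin_sizes_mb: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValidationError("bin boundaries must be strictly increasing")
        span = (self.intervals["end"] - self.intervals["start"]) / 1e6
        sizes = span.groupby(self.intervals["bin"]).sum()
        self.bin_sizes_mb = {lab: float(sizes.get(lab, 0.0)) for lab in self.labels}
        if any(v <= 0 for v in self.bin_sizes_mb.values()):
            raise ValidationError("every bin must contain at least one interval")

    @property
    def total_mb(self) -> float:
        return float(sum(self.bin_sizes_mb.values()))

    def to_manifest(self, tsv_path: str, json_path: str | None = None) -> None:
        self.intervals.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "n_bins": self.n_bins,
                        "boundaries": [float(b) for b in self.boundaries],
                        "labels": self.labels,
                        "bin_sizes_mb": self.bin_sizes_mb,
                    },
                    fh,
                    indent=2,
                )


def make_rt_bins(track: RTTrack, n_bins: int = 4) -> RTBinning:
    """Split the RT value range into ``n_bins`` equal sub-ranges and assign
    each track interval to the sub-range containing its RT value.

    Assignment is left-closed / right-open on the ascending RT axis; the
    maximum RT value falls in the top sub-range.  Bin labels are ordered
    earliest → latest according to the track's orientation flag.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    rt = track.intervals["rt"].to_numpy(dtype=float)
    lo, hi = float(rt.min()), float(rt.max())
    if not lo < hi:
        raise ValidationError("degenerate RT range: all rt values equal")
    boundaries = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
    idx = np.clip(
        np.floor((rt - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1
    )
    labels = _bin_labels(n_bins)
    # idx counts from the low end of the rt axis; with early_is_high the
    # highest-rt bin is the earliest (label E1 / B1).
    if track.early_is_high:
        label_of_idx = list(reversed(labels))
    else:
        label_of_idx = labels
    intervals = track.intervals.copy()
    intervals["bin"] = [label_of_idx[i] for i in idx]
    return RTBinning(
        n_bins=n_bins,
        boundaries=boundaries,
        labels=labels,
        intervals=intervals,
    )


@dataclass
class ChromatinBinning:
    """Active vs inactive chromatin partition.

    ``intervals`` carries a ``bin`` column with labels ``active`` /
    ``inactive``; "active" and "active2" source annotations are merged.
    """

    intervals: pd.DataFrame
    labels: list[str] = field(default_factory=lambda: ["active", "inactive"])
    bin_sizes_mb: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        span = (self.intervals["end"] - self.intervals["start"]) / 1e6
        sizes = span.groupby(self.intervals["bin"]).sum()
        self.bin_sizes_mb = {lab: float(sizes.get(lab, 0.0)) for lab in self.labels}
        if any(v <= 0 for v in self.bin_sizes_mb.values()):
            raise ValidationError("need both active and inactive span > 0")
        # active and inactive region sets must not overlap
        _sorted_interval_frame(self.intervals[["chrom", "start", "end"]].copy())

    @property
    def total_mb(self) -> float:
        return float(sum(self.bin_sizes_mb.values()))


def make_chromatin_bins(annotation: str | pd.DataFrame) -> ChromatinBinning:
    """Build an active/inactive partition from a labeled BED4.

    "active" and "active2" intervals form the active class, "inactive"
    the inactive class; any other label is dropped (count logged).
    """
    if isinstance(annotation, str):
        df = pd.read_csv(
            annotation, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "label"], usecols=[0, 1, 2, 3],
            dtype={0: str, 3: str},
        )
    else:
        df = annotation.copy()
        df.columns = ["chrom", "start", "end", "label"]
    label = df["label"].str.strip().str.lower()
    keep_active = label.isin(ACTIVE_SOURCE_LABELS)
    keep_inactive = label == INACTIVE_SOURCE_LABEL
    n_dropped = int((~(keep_active | keep_inactive)).sum())
    if n_dropped:
        logger.info("make_chromatin_bins: dropped %d intervals with other labels",
                    n_dropped)
    out = df.loc[keep_active | keep_inactive, ["chrom", "start", "end"]].copy()
    out["bin"] = np.where(keep_active[keep_active | keep_inactive], "active",
                          "inactive")
    if not (out["bin"] == "active").any() or not (out["bin"] == "inactive").any():
        raise ValidationError("annotation must contain both active and inactive span")
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return ChromatinBinning(intervals=out)
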