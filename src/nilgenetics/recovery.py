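"""Recurrent-parent genome recovery from parent/offspring SNP calls.

Backcross-derived lines are mosaics of recurrent-parent and donor genome.
The analysis proceeds in four steps:

1. *Effective-SNP filter*: keep only sites where both parents are homozygous
   for different alleles (i.e. the site distinguishes the parents).
2. *Scoring*: at each effective site the offspring call is scored 0 when it
   matches the recurrent-parent homozygote, 2 when it matches the donor
   homozygote, and 1 when heterozygous.  Missing calls are dropped.
3. *Sliding window*: windows of 15 consecutive SNPs advancing 1 SNP at a
   time are flagged recovered when their score sum is strictly below the
   breakpoint threshold of 8.  An all-heterozygous window (sum 15) is
   therefore not recovered -- heterozygous genome is not recurrent-parent
   genome.
4. *Regions and rate*: the SNP spans of consecutive recovered windows merge
   into recovery regions (outermost SNP positions; no extrapolation past
   flanking SNPs), and the recovery rate is total recovered length divided
   by the reference genome length.

Coordinates are 1-based inclusive internally; BED export is 0-based
half-open.  Chromosomes with fewer effective SNPs than one window are
unassessed and contribute zero recovered length.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Call",
    "RecoveryConfig",
    "RecoveryRegion",
    "RecoveryReport",
    "filter_effective_snps",
    "score_snps",
    "recovered_windows",
    "merge_regions",
    "recovery_rate",
    "analyze_line",
]


class Call(enum.Enum):
    """Biallelic SNP call relative to the alignment reference."""

    REF_HOM = "0/0"
    ALT_HOM = "1/1"
    HET = "0/1"
    MISSING = "./."

    @classmethod
    def from_string(cls, s: str) -> "Call":
        s = s.strip().replace("|", "/")
        if s in ("1/0",):
            s = "0/1"
        for c in cls:
            if c.value == s:
                return c
        raise ValueError(f"unrecognised SNP call {s!r}")


@dataclass(frozen=True)
class RecoveryConfig:
    """Sliding-window parameters: 15-SNP windows, 1-SNP step, threshold 8."""

    window_size: int = 15
    step: int = 1
    breakpoint_threshold: int = 8

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not 0 <= self.breakpoint_threshold <= 2 * self.window_size:
            raise ValueError("breakpoint_threshold outside [0, 2*window_size]")


@dataclass(frozen=True)
class RecoveryRegion:
    """A 1-based inclusive genomic interval of recovered recurrent genome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RecoveryReport:
    """Per-line summary: recovered bp, genome length, recovery rate."""

    line_id: str
    recovered_bp: int
    genome_length_bp: int
    regions: list[RecoveryRegion] = field(default_factory=list)
    n_effective_snps: int = 0
    n_dropped: int = 0
    unassessed_chroms: list[str] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        return self.recovered_bp / self.genome_length_bp


def _check_sorted(df: pd.DataFrame, label: str) -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{label}: positions not strictly increasing on {chrom}")


def _as_call_frame(calls: pd.DataFrame, column: str = "call") -> pd.DataFrame:
    df = calls.copy()
    if not {"chrom", "pos", column}.issubset(df.columns):
        raise ValueError(f"SNP call table needs columns chrom,pos,{column}")
    if not all(isinstance(c, Call) for c in df[column]):
        df[column] = [
            c if isinstance(c, Call) else Call.from_string(str(c)) for c in df[column]
        ]
    return df


def filter_effective_snps(
    child: pd.DataFrame, recurrent_parent: pd.DataFrame, donor_parent: pd.DataFrame
) -> pd.DataFrame:
    """Sites where both parents are homozygous for different alleles.

    Input frames have columns ``chrom,pos,call``; the three samples must
    share the coordinate system.  Returns a frame ``chrom,pos,rp_call``
    (the recurrent parent's homozygous call at each effective site),
    sorted by (chrom, pos).  Missing parental calls exclude a site.
    """
    rp = _as_call_frame(recurrent_parent)
    dn = _as_call_frame(donor_parent)
    _check_sorted(rp, "recurrent parent")
    _check_sorted(dn, "donor parent")
    merged = rp.merge(dn, on=["chrom", "pos"], suffixes=("_rp", "_dn"))
    hom = {Call.REF_HOM, Call.ALT_HOM}
    keep = merged[
        merged["call_rp"].isin(hom)
        & merged["call_dn"].isin(hom)
        & (merged["call_rp"] != merged["call_dn"])
    ]
    out = keep[["chrom", "pos"]].copy()
    out["rp_call"] = keep["call_rp"].to_numpy()
    return out.reset_index(drop=True)


def score_snps(
    child: pd.DataFrame, effective: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Score the offspring at effective sites: 0 recurrent / 1 het / 2 donor.

    ``effective`` is the output of :func:`filter_effective_snps`.  Missing
    offspring calls are dropped; calls inconsistent with both parental
    homozygotes would be dropped too, with the total returned as the second
    element and logged as a warning.
    """
    ch = _as_call_frame(child)
    _check_sorted(ch, "child")
    merged = effective.merge(ch, on=["chrom", "pos"], how="left")
    scores = np.full(len(merged), -1, dtype=int)
    n_dropped = 0
    for i, (call, rp_call) in enumerate(zip(merged["call"], merged["rp_call"])):
        if not isinstance(call, Call) or call is Call.MISSING:
            n_dropped += 1
            continue
        if call is Call.HET:
            scores[i] = 1
        elif call is rp_call:
            scores[i] = 0
        elif call in (Call.REF_HOM, Call.ALT_HOM):
            scores[i] = 2
        else:  # pragma: no cover - unreachable with biallelic Call enum
            n_dropped += 1
    if n_dropped:
        logger.warning("score_snps: dropped %d missing/inconsistent sites", n_dropped)
    out = merged.loc[scores >= 0, ["chrom", "pos"]].copy()
    out["score"] = scores[scores >= 0]
    return out.reset_index(drop=True), n_dropped


def recovered_windows(
    scores: Sequence[int] | np.ndarray, cfg: RecoveryConfig = RecoveryConfig()
) -> np.ndarray:
    """Boolean flag per sliding window: score sum strictly below threshold.

    ``scores`` are the 0/1/2 scores of consecutive SNPs on one chromosome.
    Fewer SNPs than one window yields an empty result (the chromosome is
    unassessed).
    """
    s = np.asarray(scores, dtype=int)
    if s.ndim != 1:
        raise ValueError("scores must be 1-dimensional")
    if np.any((s < 0) | (s > 2)):
        raise ValueError("scores must lie in {0, 1, 2}")
    w = cfg.window_size
    if s.size < w:
        return np.zeros(0, dtype=bool)
    csum = np.concatenate([[0], np.cumsum(s)])
    sums = csum[w:] - csum[:-w]            # sum of windows starting at 0..n-w
    starts = np.arange(0, s.size - w + 1, cfg.step)
    return sums[starts] < cfg.breakpoint_threshold


def merge_regions(
    flags: np.ndarray,
    positions: Sequence[int] | np.ndarray,
    cfg: RecoveryConfig = RecoveryConfig(),
    chrom: str = "chr",
) -> list[RecoveryRegion]:
    """Merge recovered windows into non-overlapping recovery regions.

    Each recovered window spans from its first to its last SNP position;
    overlapping or adjacent spans merge (consecutive recovered windows
    always overlap when the step is smaller than the window).  The result
    covers exactly the bases covered by at least one recovered window.
    """
    positions = np.asarray(positions, dtype=int)
    flags = np.asarray(flags, dtype=bool)
    w = cfg.window_size
    starts = np.arange(0, max(positions.size - w + 1, 0), cfg.step)
    if flags.size != starts.size:
        raise ValueError("window flags not aligned with positions/config")
    spans = [
        (int(positions[i]), int(positions[i + w - 1]))
        for i, f in zip(starts, flags)
        if f
    ]
    regions: list[RecoveryRegion] = []
    for start, end in spans:  # spans are sorted by construction
        if regions and start <= regions[-1].end + 1:
            last = regions.pop()
            regions.append(RecoveryRegion(chrom, last.start, max(last.end, end)))
        else:
            regions.append(RecoveryRegion(chrom, start, end))
    return regions


def recovery_rate(
    regions: Iterable[RecoveryRegion], genome_length_bp: int, line_id: str = ""
) -> RecoveryReport:
    """Total recovered length divided by the reference genome length."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    by_chrom: dict[str, list[RecoveryRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping recovery regions on {chrom}")
    recovered = sum(r.length for r in regions)
    if recovered > genome_length_bp:
        raise ValueError("recovered length exceeds genome length")
    return RecoveryReport(
        line_id=line_id,
        recovered_bp=int(recovered),
        genome_length_bp=int(genome_length_bp),
        regions=list(regions),
    )


def analyze_line(
    child: pd.DataFrame,
    recurrent_parent: pd.DataFrame,
    donor_parent: pd.DataFrame,
    genome_length_bp: int,
    cfg: RecoveryConfig = RecoveryConfig(),
    line_id: str = "",
) -> RecoveryReport:
    """Full pipeline: filter -> score -> windows -> regions -> rate."""
    effective = filter_effective_snps(child, recurrent_parent, donor_parent)
    scored, n_dropped = score_snps(child, effective)
    regions: list[RecoveryRegion] = []
    unassessed: list[str] = []
    for chrom, grp in scored.groupby("chrom", sort=True):
        s = grp["score"].to_numpy()
        if s.size < cfg.window_size:
            unassessed.append(str(chrom))
            continue
        flags = recovered_windows(s, cfg)
        regions.extend(merge_regions(flags, grp["pos"].to_numpy(), cfg, chrom=str(chrom)))
    report = recovery_rate(regions, genome_length_bp, line_id=line_id)
    report.n_effective_snps = len(scored)
    report.n_dropped = n_dropped
    report.unassessed_chroms = unassessed
    return report
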