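"""Hotspot annotation and enrichment: genomic-feature classification,
overlap with reference cluster sets, repeat-element tag fractions,
category comparisons by Fisher's exact test, and CpG density scans.

Overlap always means >= 1 shared bp.  Percentages are reported exactly
and rounded half-up only at formatting time, matching the 2-decimal style
of tabulated overlap reports (tiny fractions, like centromeric satellite
tag fractions, are meaningful at 3 decimals and must not be destroyed by
early rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .genome_tags import (
    DEFAULT_TAG_EXTENSION,
    IntervalSet,
    TagSet,
    extend_tags,
    overlaps_any,
)
from .hotspot_detection import HotspotSet

#: classification order when a hotspot touches several feature types
DEFAULT_PRECEDENCE = ("promoter", "exon", "intron", "gene")

INTERGENIC = "intergenic"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int | None = 2) -> float:
    """100*count/total, optionally rounded half-up."""
    if total <= 0:
        raise InvalidInputError("total must be > 0")
    p = 100.0 * count / total
    return p if ndigits is None else round_half_up(p, ndigits)


@dataclass
class OverlapReport:
    """Counts and percents-of-total against one reference feature set."""

    reference: str
    total: int
    counts: dict[str, int]
    percents_exact: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.percents_exact and self.total > 0:
            self.percents_exact = {
                k: 100.0 * v / self.total for k, v in self.counts.items()
            }

    @property
    def percents(self) -> dict[str, float]:
        """Half-up 2-decimal percents (sum to 100 up to rounding)."""
        return {k: round_half_up(v, 2) for k, v in self.percents_exact.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percents[k] for k in self.counts],
            }
        )


# ---------------------------------------------------------------------------
# Classification and overlap
# ---------------------------------------------------------------------------

def _merged_by_label(features: IntervalSet) -> dict[str, dict[str, tuple]]:
    if features.labels is None:
        raise InvalidInputError("feature set has no category labels")
    out: dict[str, dict[str, tuple]] = {}
    for label in pd.unique(features.labels):
        sel = features.labels == label
        sub = IntervalSet(
            features.chrom[sel], features.start[sel], features.end[sel]
        )
        per = {}
        for name in pd.unique(sub.chrom):
            per[name] = sub.merged_per_chrom(name)
        out[str(label)] = per
    return out


def _hits(intervals: IntervalSet, per_chrom: Mapping[str, tuple]) -> np.ndarray:
    hit = np.zeros(len(intervals), dtype=bool)
    for name, (ms, me) in per_chrom.items():
        sel = np.flatnonzero(intervals.chrom == name)
        if len(sel):
            hit[sel] = overlaps_any(
                intervals.start[sel], intervals.end[sel], ms, me
            )
    return hit


def classify_hotspots(
    hotspots: HotspotSet,
    features: IntervalSet,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> tuple[OverlapReport, np.ndarray]:
    """Assign each hotspot the highest-precedence feature it overlaps.

    Hotspots touching no feature are classified ``intergenic``; the
    resulting categories partition the hotspot set, so counts sum to the
    total and percents to 100 up to rounding.
    """
    ivs = hotspots.intervals()
    by_label = _merged_by_label(features)
    unknown = set(by_label) - set(precedence)
    if unknown:
        raise InvalidParameterError(
            f"precedence does not cover feature labels: {sorted(unknown)}"
        )
    labels = np.array([INTERGENIC] * len(ivs), dtype=object)
    assigned = np.zeros(len(ivs), dtype=bool)
    for cat in precedence:
        if cat not in by_label:
            continue
        hit = _hits(ivs, by_label[cat]) & ~assigned
        labels[hit] = cat
        assigned |= hit
    cats = list(precedence) + [INTERGENIC]
    counts = {c: int((labels == c).sum()) for c in cats}
    report = OverlapReport("features", len(ivs), counts)
    return report, labels


def overlap_with_clusters(
    hotspots: HotspotSet, clusters: IntervalSet
) -> tuple[int, float | None]:
    """(count, percent) of hotspots overlapping any reference cluster.

    Percent is half-up 2 decimals; ``None`` for an empty hotspot set.
    """
    ivs = hotspots.intervals()
    per = {}
    for name in pd.unique(clusters.chrom):
        per[name] = clusters.merged_per_chrom(name)
    count = int(_hits(ivs, per).sum())
    if len(ivs) == 0:
        return 0, None
    return count, percent(count, len(ivs))


def repeat_tag_fractions(
    tags: TagSet,
    repeats: IntervalSet,
    extension: int = DEFAULT_TAG_EXTENSION,
) -> pd.DataFrame:
    """Per repeat family: tags whose ``extension``-bp fragment overlaps it.

    Tags are extended to the fixed fragment length by strand before the
    overlap test (>= 1 bp).  Returns a frame with exact (unrounded)
    percents of the total tag count; a tag may count for several families.
    """
    if repeats.labels is None:
        raise InvalidInputError("repeat set has no family labels")
    frags = extend_tags(tags, extension)
    by_label = _merged_by_label(repeats)
    rows = []
    for family in sorted(by_label):
        n = int(_hits(frags, by_label[family]).sum())
        pct = 100.0 * n / tags.total_count if tags.total_count else 0.0
        rows.append({"family": family, "count": n, "percent": pct})
    return pd.DataFrame(rows, columns=["family", "count", "percent"])


# ---------------------------------------------------------------------------
# Fisher's exact test (exact integer enumeration)
# ---------------------------------------------------------------------------

def category_fisher(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher's exact p for [[a, ta-a], [b, tb-b]].

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  The
    comparison is done on integer numerators over the common denominator,
    so ties are exact (no floating-point epsilon).
    """
    for c, t in ((count_a, total_a), (count_b, total_b)):
        if t <= 0:
            raise InvalidParameterError("totals must be > 0")
        if not 0 <= c <= t:
            raise InvalidParameterError("counts must satisfy 0 <= count <= total")
    r1, r2 = total_a, total_b
    c1 = count_a + count_b
    n = r1 + r2
    num_obs = comb(r1, count_a) * comb(r2, c1 - count_a)
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= num_obs:
            acc += num
    return acc / comb(n, c1)


# ---------------------------------------------------------------------------
# CpG scanning
# ---------------------------------------------------------------------------

def cpg_density_profile(
    hotspots: HotspotSet,
    sequences: Mapping[str, str],
    window: int = 10,
    span: int | None = None,
) -> np.ndarray:
    """Mean CpG count in a scanning window over center-aligned hotspots.

    All hotspots are overlaid on their centers across ``span`` bp (default:
    the shortest hotspot length, so every overlay is fully covered); for
    each offset the number of CG dinucleotides lying fully inside the
    ``window``-bp window starting there is counted and averaged over
    hotspots.  Hotspots whose overlay would run off the chromosome are
    dropped.  Raises on a chromosome missing from ``sequences``.
    """
    if window < 2:
        raise InvalidParameterError("window must be >= 2 bp")
    ivs = hotspots.intervals()
    if len(ivs) == 0:
        raise InvalidInputError("no hotspots to overlay")
    if span is None:
        span = int(ivs.lengths().min())
    if span < window:
        raise InvalidParameterError("span must be >= window")
    profiles = []
    for i in range(len(ivs)):
        name = str(ivs.chrom[i])
        if name not in sequences:
            raise InvalidInputError(f"no sequence for chromosome {name!r}")
        seq = sequences[name]
        center = int(ivs.start[i] + ivs.end[i]) // 2
        lo = center - span // 2
        hi = lo + span
        if lo < 0 or hi > len(seq):
            continue
        s = str(seq[lo:hi]).upper()
        arr = np.frombuffer(s.encode(), dtype="S1")
        cg = ((arr[:-1] == b"C") & (arr[1:] == b"G")).astype(float)
        # CG starts fully inside a window of `window` bp: window-1 start slots
        kernel = window - 1
        csum = np.concatenate([[0.0], np.cumsum(cg)])
        profiles.append(csum[kernel:] - csum[:-kernel])
    if not profiles:
        raise InvalidInputError("no hotspot overlay fits inside the sequences")
    return np.mean(profiles, axis=0)
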