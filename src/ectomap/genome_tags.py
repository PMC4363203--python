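"""Core data model: genomes, sequence tags, and genomic intervals.

A *tag* is the mapped 5' position of a sequencing read together with its
strand.  All coordinates are 0-based half-open, matching BED.  Tags are
exchanged as 6-column BED where ``start`` is the 5' position and
``end = start + 1``; intervals as BED3 with an optional label in column 4.

The module also implements the two tag-level computations the analysis
relies on throughout: strand-aware extension of tags to a fixed fragment
length (150 bp by default, the value used for every overlap computation),
and exact genome-coverage fractions from interval unions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .errors import (
    InvalidParameterError,
    ParseError,
    ReferenceMismatchError,
)

DEFAULT_TAG_EXTENSION = 150  # bp; strand-aware fragment length for overlaps

_STRANDS = frozenset({"+", "-"})


# ---------------------------------------------------------------------------
# Genome definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeDef(Mapping[str, int]):
    """Ordered mapping of chromosome name to length in bp."""

    sizes: dict[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise InvalidParameterError("genome must contain at least one chromosome")
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise InvalidParameterError(
                    f"chromosome {name!r} has non-positive length {length}"
                )

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeDef":
        """Read a 2-column ``chrom<TAB>length`` sizes file."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError("expected 'chrom length'", line_number=i)
                try:
                    length = int(parts[1])
                except ValueError:
                    raise ParseError(f"length {parts[1]!r} is not an integer", i)
                if parts[0] in sizes:
                    raise ParseError(f"duplicate chromosome {parts[0]!r}", i)
                sizes[parts[0]] = length
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Tag sets
# ---------------------------------------------------------------------------

class TagSet:
    """Strand-aware 5' tag positions for one sequencing sample.

    Parameters
    ----------
    genome
        Coordinate frame the tags live in.
    chrom, pos, strand
        Per-tag arrays (chromosome name, 0-based 5' position, ``+``/``-``).
    """

    def __init__(self, genome: GenomeDef, chrom, pos, strand, validate: bool = True):
        self.genome = genome
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.strand = np.asarray(strand, dtype="U1")
        if not (len(self.chrom) == len(self.pos) == len(self.strand)):
            raise InvalidParameterError("chrom/pos/strand arrays differ in length")
        self._by_chrom: dict[tuple[str, str | None], np.ndarray] | None = None
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = ~np.isin(self.strand, ["+", "-"])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(f"invalid strand {self.strand[i]!r}")
        for name in np.unique(self.chrom.astype(str)) if len(self.chrom) else []:
            if name not in self.genome:
                raise ReferenceMismatchError(f"unknown chromosome {name!r}")
            sel = self.chrom == name
            p = self.pos[sel]
            if len(p) and (p.min() < 0 or p.max() >= self.genome[name]):
                raise ReferenceMismatchError(
                    f"tag position outside {name!r} (length {self.genome[name]})"
                )

    @property
    def total_count(self) -> int:
        return len(self.pos)

    def __len__(self) -> int:
        return len(self.pos)

    def _index(self) -> dict:
        if self._by_chrom is None:
            idx: dict = {}
            for name in self.genome:
                sel = np.flatnonzero(self.chrom == name)
                p = self.pos[sel]
                order = np.argsort(p, kind="stable")
                idx[(name, None)] = p[order]
                s = self.strand[sel][order]
                idx[(name, "+")] = idx[(name, None)][s == "+"]
                idx[(name, "-")] = idx[(name, None)][s == "-"]
            self._by_chrom = idx
        return self._by_chrom

    def positions(self, chrom: str, strand: str | None = None) -> np.ndarray:
        """Sorted 5' positions on one chromosome (optionally one strand)."""
        if chrom not in self.genome:
            raise ReferenceMismatchError(f"unknown chromosome {chrom!r}")
        return self._index()[(chrom, strand)]

    def to_bed(self, path: str | Path, name_prefix: str = "tag") -> None:
        """Write 6-column BED: chrom, pos5, pos5+1, name, 0, strand."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                p = int(self.pos[i])
                fh.write(
                    f"{self.chrom[i]}\t{p}\t{p + 1}\t{name_prefix}{i}\t0\t{self.strand[i]}\n"
                )


def read_tags(path: str | Path, genome: GenomeDef) -> TagSet:
    """Read a TagSet from 6-column BED (``start`` = 5' position).

    Malformed lines raise :class:`ParseError` with the line number; records on
    unknown chromosomes or outside chromosome bounds raise
    :class:`ReferenceMismatchError`.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"expected 6 BED columns, got {len(parts)}", i)
            chrom, start_s, _end, _name, _score, strand = parts[:6]
            try:
                pos = int(start_s)
            except ValueError:
                raise ParseError(f"start {start_s!r} is not an integer", i)
            if strand not in _STRANDS:
                raise ParseError(f"invalid strand {strand!r}", i)
            if chrom not in genome:
                raise ReferenceMismatchError(
                    f"line {i}: unknown chromosome {chrom!r}"
                )
            if not 0 <= pos < genome[chrom]:
                raise ReferenceMismatchError(
                    f"line {i}: position {pos} outside {chrom!r} "
                    f"(length {genome[chrom]})"
                )
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
    return TagSet(genome, chroms, poss, strands, validate=False)


# ---------------------------------------------------------------------------
# Interval sets
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Half-open 0-based genomic intervals with optional labels/scores."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    labels: np.ndarray | None = None
    scores: np.ndarray | None = None
    genome: GenomeDef | None = field(default=None, repr=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.start >= self.end):
            raise InvalidParameterError("intervals must satisfy start < end")
        if self.genome is not None:
            for name in np.unique(self.chrom.astype(str)) if len(self.chrom) else []:
                if name not in self.genome:
                    raise ReferenceMismatchError(f"unknown chromosome {name!r}")
                sel = self.chrom == name
                if self.start[sel].min() < 0 or self.end[sel].max() > self.genome[name]:
                    raise ReferenceMismatchError(
                        f"interval outside {name!r} (length {self.genome[name]})"
                    )

    def __len__(self) -> int:
        return len(self.start)

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) arrays on one chromosome, sorted by start."""
        sel = np.flatnonzero(self.chrom == chrom)
        order = np.argsort(self.start[sel], kind="stable")
        return self.start[sel][order], self.end[sel][order]

    def merged_per_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        s, e = self.per_chrom(chrom)
        return merge_intervals(s, e)

    @classmethod
    def from_bed(cls, path: str | Path, genome: GenomeDef | None = None) -> "IntervalSet":
        """Read BED3(+label in col 4, +score in col 5)."""
        chroms, starts, ends, labels, scores = [], [], [], [], []
        any_label = any_score = False
        with open(path) as fh:
            for i, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"expected >=3 BED columns, got {len(parts)}", i)
                try:
                    s, e = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError("start/end must be integers", i)
                if s >= e:
                    raise ParseError(f"start {s} >= end {e}", i)
                chroms.append(parts[0])
                starts.append(s)
                ends.append(e)
                if len(parts) >= 4:
                    labels.append(parts[3])
                    any_label = True
                else:
                    labels.append("")
                if len(parts) >= 5:
                    try:
                        scores.append(float(parts[4]))
                        any_score = True
                    except ValueError:
                        scores.append(0.0)
                else:
                    scores.append(0.0)
        return cls(
            np.array(chroms, dtype=object),
            np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64),
            labels=np.array(labels, dtype=object) if any_label else None,
            scores=np.array(scores) if any_score else None,
            genome=genome,
        )

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                cols = [str(self.chrom[i]), str(int(self.start[i])), str(int(self.end[i]))]
                if self.labels is not None:
                    cols.append(str(self.labels[i]))
                    if self.scores is not None:
                        cols.append(repr(float(self.scores[i])))
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Interval arithmetic (exact, sorted-array sweeps)
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals; returns disjoint sorted (starts, ends).

    Touching intervals ([0,5) and [5,9)) are coalesced.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    run_max = np.maximum.accumulate(e)
    # a new block begins where the start exceeds every previous end
    new_block = np.ones(len(s), dtype=bool)
    new_block[1:] = s[1:] > run_max[:-1]
    block = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block
    return out_s, out_e


def overlaps_any(
    q_start: np.ndarray,
    q_end: np.ndarray,
    m_start: np.ndarray,
    m_end: np.ndarray,
) -> np.ndarray:
    """For each query, whether it overlaps (>=1 bp) any *merged* interval."""
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    if len(m_start) == 0:
        return np.zeros(len(q_start), dtype=bool)
    idx = np.searchsorted(m_start, q_start, side="right") - 1
    prev_hit = (idx >= 0) & (m_end[np.clip(idx, 0, None)] > q_start)
    nxt = idx + 1
    next_hit = (nxt < len(m_start)) & (m_start[np.clip(nxt, None, len(m_start) - 1)] < q_end)
    return prev_hit | next_hit


def extend_tags(tags: TagSet, length: int = DEFAULT_TAG_EXTENSION) -> IntervalSet:
    """Extend each tag to a fixed fragment length, strand-aware.

    A ``+`` tag at p becomes [p, p+length); a ``-`` tag at p becomes
    [p-length+1, p+1), so the 5' base is always the first base read.
    Intervals are clipped to chromosome bounds.
    """
    if length < 1:
        raise InvalidParameterError("extension length must be >= 1")
    plus = tags.strand == "+"
    start = np.where(plus, tags.pos, tags.pos - length + 1)
    end = np.where(plus, tags.pos + length, tags.pos + 1)
    lengths = np.array([tags.genome[c] for c in tags.chrom], dtype=np.int64) \
        if len(tags) else np.zeros(0, dtype=np.int64)
    start = np.clip(start, 0, None)
    end = np.minimum(end, lengths) if len(tags) else end
    return IntervalSet(tags.chrom.copy(), start, end, genome=tags.genome)


def genome_coverage_fraction(intervals: IntervalSet, genome: GenomeDef) -> float:
    """Percent of the genome covered by the union of the intervals."""
    covered = 0
    for name in genome:
        s, e = intervals.merged_per_chrom(name)
        covered += int((e - s).sum())
    return 100.0 * covered / genome.total_length


def count_tags_in_window(
    tags: TagSet,
    chrom: str,
    start: int,
    end: int,
    mode: str = "5prime",
    extension: int = DEFAULT_TAG_EXTENSION,
) -> int:
    """Count tags relative to a half-open window.

    ``5prime`` counts tags whose 5' position lies in [start, end);
    ``extended`` counts tags whose strand-aware ``extension``-bp fragment
    overlaps the window by at least 1 bp.
    """
    if start >= end:
        raise InvalidParameterError("window must satisfy start < end")
    if mode == "5prime":
        p = tags.positions(chrom)
        return int(np.searchsorted(p, end, "left") - np.searchsorted(p, start, "left"))
    if mode == "extended":
        # + fragment [p, p+L) overlaps iff start-L < p < end
        pp = tags.positions(chrom, "+")
        n = np.searchsorted(pp, end, "left") - np.searchsorted(pp, start - extension, "right")
        # - fragment [p-L+1, p+1) overlaps iff start <= p <= end+L-2
        pm = tags.positions(chrom, "-")
        n += np.searchsorted(pm, end + extension - 1, "left") - np.searchsorted(pm, start, "left")
        return int(n)
    raise InvalidParameterError(f"unknown counting mode {mode!r}")
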