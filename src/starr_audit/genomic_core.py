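"""Coordinate conventions, interval arithmetic and standard-format IO.

All coordinates are 0-based half-open (BED convention). Strand is parsed
where present but ignored by every overlap computation: the audit's
procedures are strand-agnostic.

The two primitives everything downstream builds on are

* :func:`reciprocal_overlap` — the element-level pairing rule ("two
  intervals overlap at least a fraction *t* of their respective lengths
  reciprocally"), and
* :class:`IntervalSet` — a normalized (sorted, optionally merged)
  collection supporting base-exact intersection, subtraction and union,
  the currency of the base-level genome partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeSpec",
    "reciprocal_overlap",
    "overlap_length",
    "intersect_length",
    "gc_content",
    "read_intervals",
    "write_bed",
    "read_fasta",
    "write_fasta",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    id: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:[{self.start},{self.end})")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:[{self.start},{self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def midpoint(self) -> int:
        """Lower-median base for even lengths."""
        return (self.start + self.end) // 2


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base overlap between two intervals; 0 on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, threshold: float = 0.5) -> bool:
    """True iff the intersection covers at least ``threshold`` of *both* lengths.

    The predicate is symmetric and inclusive at the threshold ("at least
    50%"). Intervals on different chromosomes never overlap.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ov = overlap_length(a, b)
    if ov == 0:
        return False
    return ov >= threshold * a.length() and ov >= threshold * b.length()


class IntervalSet:
    """A collection of :class:`GenomicInterval` with base-exact set algebra.

    Element identity (ids, scores, original boundaries) is preserved in
    :attr:`intervals`; the set-algebra operations (:meth:`merge`,
    :meth:`intersect`, :meth:`subtract`, :meth:`total_length`) act on the
    merged per-chromosome base sets.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):  # noqa: D107
        self.intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._merged_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    # -- basic container behaviour -----------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    # -- merged representation ---------------------------------------------
    def merged_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the merged base set."""
        if self._merged_cache is None:
            per: Dict[str, List[Tuple[int, int]]] = {}
            for iv in self.intervals:
                per.setdefault(iv.chrom, []).append((iv.start, iv.end))
            out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            for chrom, pairs in per.items():
                pairs.sort()
                starts: List[int] = []
                ends: List[int] = []
                for s, e in pairs:
                    if ends and s <= ends[-1]:  # book-ended intervals merge too
                        if e > ends[-1]:
                            ends[-1] = e
                    else:
                        starts.append(s)
                        ends.append(e)
                out[chrom] = (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                )
            self._merged_cache = out
        return self._merged_cache

    def merge(self) -> "IntervalSet":
        """A new set of the merged intervals (ids dropped)."""
        out = []
        for chrom, (starts, ends) in sorted(self.merged_arrays().items()):
            for s, e in zip(starts.tolist(), ends.tolist()):
                out.append(GenomicInterval(chrom, s, e))
        return IntervalSet(out)

    def total_length(self) -> int:
        """Number of distinct bases covered (merged length)."""
        return int(
            sum((e - s).sum() for s, e in self.merged_arrays().values())
        )

    def sum_element_lengths(self) -> int:
        """Sum of raw element lengths (double-counts overlaps)."""
        return sum(iv.length() for iv in self.intervals)

    # -- set algebra ---------------------------------------------------------
    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: List[GenomicInterval] = []
        mine = self.merged_arrays()
        theirs = other.merged_arrays()
        for chrom in sorted(set(mine) & set(theirs)):
            s1, e1 = mine[chrom]
            s2, e2 = theirs[chrom]
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    out.append(GenomicInterval(chrom, int(lo), int(hi)))
                if e1[i] <= e2[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: List[GenomicInterval] = []
        theirs = other.merged_arrays()
        for chrom, (s1, e1) in sorted(self.merged_arrays().items()):
            if chrom not in theirs:
                out.extend(
                    GenomicInterval(chrom, int(s), int(e)) for s, e in zip(s1, e1)
                )
                continue
            s2, e2 = theirs[chrom]
            j = 0
            for s, e in zip(s1.tolist(), e1.tolist()):
                cur = s
                while j < len(s2) and e2[j] <= cur:
                    j += 1
                k = j
                while k < len(s2) and s2[k] < e:
                    if s2[k] > cur:
                        out.append(GenomicInterval(chrom, cur, int(s2[k])))
                    cur = max(cur, int(e2[k]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out.append(GenomicInterval(chrom, cur, e))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self.intervals) + list(other.intervals)).merge()

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Bases of ``chrom:[start,end)`` covered by this set."""
        arrays = self.merged_arrays().get(chrom)
        if arrays is None:
            return 0
        starts, ends = arrays
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0
        return int(
            np.sum(
                np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
            )
        )

    def overlapping(self, query: GenomicInterval) -> List[GenomicInterval]:
        """Elements (unmerged) overlapping *query* by ≥1 bp."""
        return [
            iv
            for iv in self.intervals
            if iv.chrom == query.chrom and iv.start < query.end and iv.end > query.start
        ]


def intersect_length(set_a: IntervalSet, set_b: IntervalSet) -> int:
    """Number of bases present in both sets (commutative)."""
    return set_a.intersect(set_b).total_length()


@dataclass
class GenomeSpec:
    """Chromosome sizes plus the analyzable subset of the genome.

    ``analyzable_regions`` plays the role of the fraction of the genome for
    which the CRM/non-CRM annotation exists; peak bases outside it are
    reported separately, never silently dropped.
    """

    chrom_sizes: Dict[str, int]
    analyzable_regions: IntervalSet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.analyzable_regions is None:
            self.analyzable_regions = IntervalSet(
                GenomicInterval(c, 0, n) for c, n in self.chrom_sizes.items()
            )
        for iv in self.analyzable_regions:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"analyzable region on unknown chromosome {iv.chrom!r}")
            if iv.end > size:
                raise ValueError(
                    f"analyzable region {iv.chrom}:[{iv.start},{iv.end}) exceeds "
                    f"chromosome length {size}"
                )

    def total_analyzable(self) -> int:
        return self.analyzable_regions.total_length()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom_sizes": self.chrom_sizes,
            "analyzable_regions": [
                [iv.chrom, iv.start, iv.end] for iv in self.analyzable_regions
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenomeSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            chrom_sizes={c: int(n) for c, n in payload["chrom_sizes"].items()},
            analyzable_regions=IntervalSet(
                GenomicInterval(c, int(s), int(e))
                for c, s, e in payload["analyzable_regions"]
            ),
        )


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

GC_UNDEFINED = float("nan")


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T), case-insensitive; N excluded from the
    denominator. Returns NaN for empty/all-N sequences."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    if denom == 0:
        return GC_UNDEFINED
    return gc / denom


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | Path,
    genome: Optional[GenomeSpec] = None,
    chrom_aliases: Optional[Dict[str, str]] = None,
) -> IntervalSet:
    """Read a BED3/BED6/BED+ file into a sorted :class:`IntervalSet`.

    Coordinates must already be 0-based half-open. Malformed lines and
    ``start >= end`` raise with the offending line number. Chromosome names
    absent from *genome* (when given) are an error unless remapped through
    the explicit ``chrom_aliases`` map — no silent "1" vs "chr1" harmonizing.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            if chrom_aliases:
                chrom = chrom_aliases.get(chrom, chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start},{end})"
                )
            if genome is not None and chrom not in genome.chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(GenomicInterval(chrom, start, end, id=name, score=score, strand=strand))
    return IntervalSet(out)


def write_bed(intervals: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write sorted BED; emits BED6 columns when any id/score/strand is set."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    rich = any(iv.id is not None or iv.score is not None or iv.strand is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if rich:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t"
                    f"{0 if iv.score is None else iv.score:g}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Plain FASTA reader for synthetic genomes (small, uncompressed)."""
    seqs: Dict[str, List[str]] = {}
    name: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
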