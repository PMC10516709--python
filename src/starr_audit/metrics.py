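"""Per-category element statistics.

The structural complexity of a CRM or STARR peak combines its TFBS density
with how connected the underlying motifs are in a motif interaction
network::

    complexity = log(N_TFBS × D + 1)

where ``N_TFBS`` is the number of TFBS hits per 100 bp of the element and
``D`` the average network degree over the hits' unique motifs. Natural log
by default (any base preserves the ordering). An element with no hits, or
whose motifs are all isolated, scores 0.

Also here: TFBS density per 100 bp, length summaries, per-base conservation
score sampling, and STARR peak signal strength (per-bp mean fold enrichment
over input — the same definition as the state-caller features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genomic_core import GenomicInterval, IntervalSet, gc_content
from .tracks import SignalTrack, mean_fold_enrichment

__all__ = [
    "MotifNetwork",
    "TfbsHit",
    "HitIndex",
    "hits_in_element",
    "complexity_score",
    "tfbs_density",
    "length_summary",
    "conservation_distribution",
    "peak_signal_strength",
    "element_table",
]


@dataclass
class TfbsHit:
    interval: GenomicInterval
    motif_id: str


class MotifNetwork:
    """Undirected motif interaction graph; node degree feeds the
    complexity score. Motifs absent from the network have degree 0 and are
    recorded in :attr:`unknown_motifs` when queried."""

    def __init__(self, edges: Iterable[Tuple[str, str]]):
        self._degree: Dict[str, int] = {}
        self.n_edges = 0
        for a, b in edges:
            self._degree[a] = self._degree.get(a, 0) + 1
            self._degree[b] = self._degree.get(b, 0) + 1
            self.n_edges += 1
        self.unknown_motifs: Set[str] = set()

    def degree(self, motif_id: str) -> int:
        d = self._degree.get(motif_id)
        if d is None:
            self.unknown_motifs.add(motif_id)
            return 0
        return d

    @property
    def nodes(self) -> Set[str]:
        return set(self._degree)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MotifNetwork":
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                edges.append((a, b))
        return cls(edges)

class HitIndex:
    """Per-chromosome sorted index over TFBS hits for fast window queries."""

    def __init__(self, hits: Sequence[TfbsHit]):
        per: Dict[str, List[TfbsHit]] = {}
        for h in hits:
            per.setdefault(h.interval.chrom, []).append(h)
        self._hits: Dict[str, List[TfbsHit]] = {}
        self._starts: Dict[str, np.ndarray] = {}
        self.max_len = 1
        for chrom, hs in per.items():
            hs.sort(key=lambda h: h.interval.start)
            self._hits[chrom] = hs
            self._starts[chrom] = np.array([h.interval.start for h in hs], dtype=np.int64)
            self.max_len = max(self.max_len, max(h.interval.length() for h in hs))

    def overlapping(self, element: GenomicInterval) -> List[TfbsHit]:
        hs = self._hits.get(element.chrom)
        if not hs:
            return []
        starts = self._starts[element.chrom]
        lo = int(np.searchsorted(starts, element.start - self.max_len, side="left"))
        hi = int(np.searchsorted(starts, element.end, side="left"))
        return [
            h
            for h in hs[lo:hi]
            if h.interval.end > element.start and h.interval.start < element.end
        ]


def hits_in_element(
    element: GenomicInterval, hits: "Sequence[TfbsHit] | HitIndex"
) -> List[TfbsHit]:
    """Hits overlapping the element by ≥1 bp (boundary-spanning hits count once)."""
    if isinstance(hits, HitIndex):
        return hits.overlapping(element)
    return [
        h
        for h in hits
        if h.interval.chrom == element.chrom
        and h.interval.start < element.end
        and h.interval.end > element.start
    ]


def complexity_score(
    element: GenomicInterval,
    hits: Sequence[TfbsHit],
    network: MotifNetwork,
    log_base: float = math.e,
) -> float:
    """log(N_TFBS × D + 1): TFBS hits per 100 bp times mean unique-motif degree."""
    inside = hits_in_element(element, hits)
    if not inside:
        return 0.0
    n_per_100bp = len(inside) / (element.length() / 100.0)
    unique_motifs = sorted({h.motif_id for h in inside})
    mean_degree = float(np.mean([network.degree(m) for m in unique_motifs]))
    return math.log(n_per_100bp * mean_degree + 1.0, log_base)


def tfbs_density(intervals: IntervalSet, hits: Sequence[TfbsHit]) -> float:
    """Overlapping hits per 100 bp of total element length."""
    total = intervals.sum_element_lengths()
    if total == 0:
        raise ValueError("zero total element length")
    n = sum(len(hits_in_element(el, hits)) for el in intervals)
    return n / (total / 100.0)


def length_summary(elements: IntervalSet) -> Dict[str, float]:
    """Mean/median/count of raw element lengths (element identity preserved)."""
    if not elements:
        raise ValueError("empty element set")
    lengths = np.array([iv.length() for iv in elements], dtype=float)
    return {
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "n": int(len(lengths)),
    }


def conservation_distribution(
    elements: IntervalSet, cons_track: SignalTrack
) -> Tuple[np.ndarray, int]:
    """Per-base conservation scores over all element bases.

    Returns (scores, n_uncovered): uncovered bases are skipped and counted,
    not imputed.
    """
    samples = []
    uncovered = 0
    for el in elements:
        vals, mask = cons_track.per_base(el.chrom, el.start, el.end)
        samples.append(vals[mask])
        uncovered += int((~mask).sum())
    if samples:
        return np.concatenate(samples), uncovered
    return np.empty(0), uncovered


def peak_signal_strength(
    peak: GenomicInterval, starr_signal: SignalTrack, input_track: SignalTrack
) -> float:
    """Per-bp mean library-size-normalized STARR fold enrichment over input."""
    return mean_fold_enrichment(peak, starr_signal, input_track)


def element_table(
    elements: IntervalSet,
    category: Dict[str, str],
    hits: Sequence[TfbsHit],
    network: MotifNetwork,
    sequences: Optional[Dict[str, str]] = None,
    starr_signal: Optional[SignalTrack] = None,
    input_track: Optional[SignalTrack] = None,
) -> "object":
    """Per-element summary table: id, category, length, gc, complexity,
    signal_strength (NaN where the needed inputs are absent)."""
    import pandas as pd

    rows = []
    for k, el in enumerate(elements):
        eid = el.id or f"el{k}"
        gc = float("nan")
        if sequences is not None and el.chrom in sequences:
            gc = gc_content(sequences[el.chrom][el.start : el.end])
        strength = float("nan")
        if starr_signal is not None and input_track is not None:
            strength = peak_signal_strength(el, starr_signal, input_track)
        rows.append(
            {
                "id": eid,
                "category": category.get(eid, "NA"),
                "chrom": el.chrom,
                "start": el.start,
                "end": el.end,
                "length": el.length(),
                "gc": gc,
                "complexity": complexity_score(el, hits, network),
                "signal_strength": strength,
            }
        )
    return pd.DataFrame(rows)
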