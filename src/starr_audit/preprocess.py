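"""Build the analyzable CRM set and consensus replicate STARR peaks.

Candidate CRMs that behave like silencers or insulators are removed by
reciprocal overlap (≥50% of both lengths) with a silencer catalog or CTCF
peaks; promoter-proximal CRMs are removed when any TSS lies within 1000 bp
of the nearest CRM edge (distance 0 inside the CRM). The filters commute:
the retained set does not depend on application order. For the removal
report an element is counted once, in silencer → CTCF → promoter precedence.

Replicate STARR peak sets are reduced to a consensus: for each rep1 peak
overlapping rep2 by ≥1 bp, the base-level intersection with the union of
its rep2 partners. More than two replicates fold sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .genomic_core import GenomicInterval, IntervalSet, reciprocal_overlap

__all__ = [
    "FilterReport",
    "filter_silencer_insulator",
    "filter_promoter_proximal",
    "filter_crms",
    "consensus_replicate_peaks",
]


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_silencer: int = 0
    n_removed_ctcf: int = 0
    n_removed_promoter: int = 0
    n_retained: int = 0

    def to_dict(self) -> Dict[str, int]:
        return asdict(self)

    def check(self) -> None:
        removed = self.n_removed_silencer + self.n_removed_ctcf + self.n_removed_promoter
        if self.n_retained + removed != self.n_input:
            raise AssertionError("filter report does not balance")


def _hits_reciprocal(crm: GenomicInterval, catalog: IntervalSet, threshold: float) -> bool:
    return any(
        reciprocal_overlap(crm, other, threshold) for other in catalog.overlapping(crm)
    )


def filter_silencer_insulator(
    crms: IntervalSet,
    silencers: IntervalSet,
    ctcf_peaks: IntervalSet,
    threshold: float = 0.5,
) -> Tuple[IntervalSet, FilterReport]:
    """Drop CRMs reciprocally overlapping (≥ threshold) any silencer or CTCF peak."""
    report = FilterReport(n_input=len(crms))
    kept: List[GenomicInterval] = []
    for crm in crms:
        if _hits_reciprocal(crm, silencers, threshold):
            report.n_removed_silencer += 1
        elif _hits_reciprocal(crm, ctcf_peaks, threshold):
            report.n_removed_ctcf += 1
        else:
            kept.append(crm)
    report.n_retained = len(kept)
    report.check()
    return IntervalSet(kept), report


def min_tss_distance(crm: GenomicInterval, tss_by_chrom: Dict[str, np.ndarray]) -> float:
    """Edge distance from a CRM to the nearest TSS (0 if a TSS falls inside)."""
    positions = tss_by_chrom.get(crm.chrom)
    if positions is None or len(positions) == 0:
        return float("inf")
    idx = int(np.searchsorted(positions, crm.start))
    best = float("inf")
    for j in (idx - 1, idx):
        if 0 <= j < len(positions):
            t = int(positions[j])
            if crm.start <= t < crm.end:
                return 0.0
            # gap between the interval boundary coordinate and the TSS
            best = min(best, t - crm.end if t >= crm.end else crm.start - t)
    return best


def _index_tss(tss: Sequence[Tuple[str, int]]) -> Dict[str, np.ndarray]:
    per: Dict[str, List[int]] = {}
    for chrom, pos in tss:
        per.setdefault(chrom, []).append(int(pos))
    return {c: np.asarray(sorted(p), dtype=np.int64) for c, p in per.items()}


def filter_promoter_proximal(
    crms: IntervalSet,
    tss: Sequence[Tuple[str, int]],
    max_dist: int = 1000,
) -> Tuple[IntervalSet, FilterReport]:
    """Drop CRMs whose nearest-edge distance to any TSS is ≤ ``max_dist``."""
    if not tss:
        raise ValueError("TSS list is empty")
    index = _index_tss(tss)
    report = FilterReport(n_input=len(crms))
    kept = []
    for crm in crms:
        if min_tss_distance(crm, index) <= max_dist:
            report.n_removed_promoter += 1
        else:
            kept.append(crm)
    report.n_retained = len(kept)
    report.check()
    return IntervalSet(kept), report


def filter_crms(
    crms: IntervalSet,
    silencers: IntervalSet,
    ctcf_peaks: IntervalSet,
    tss: Sequence[Tuple[str, int]],
    threshold: float = 0.5,
    max_dist: int = 1000,
) -> Tuple[IntervalSet, FilterReport]:
    """All three filters, reported with silencer → CTCF → promoter precedence."""
    index = _index_tss(tss) if tss else {}
    report = FilterReport(n_input=len(crms))
    kept = []
    for crm in crms:
        if _hits_reciprocal(crm, silencers, threshold):
            report.n_removed_silencer += 1
        elif _hits_reciprocal(crm, ctcf_peaks, threshold):
            report.n_removed_ctcf += 1
        elif index and min_tss_distance(crm, index) <= max_dist:
            report.n_removed_promoter += 1
        else:
            kept.append(crm)
    report.n_retained = len(kept)
    report.check()
    return IntervalSet(kept), report


def consensus_replicate_peaks(*replicates: IntervalSet) -> IntervalSet:
    """Per-base intersection of any-overlap-supported peaks across replicates.

    With two replicates: for each rep1 peak overlapping ≥1 rep2 peak, the
    intersection of the peak with the union of its rep2 partners. Additional
    replicates fold left sequentially, so every consensus base is present in
    all replicates.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicate peak sets")
    current = replicates[0]
    for nxt in replicates[1:]:
        pieces: List[GenomicInterval] = []
        for peak in current:
            partners = nxt.overlapping(peak)
            if not partners:
                continue
            partner_set = IntervalSet(partners)
            clipped = partner_set.intersect(IntervalSet([peak]))
            for k, frag in enumerate(clipped):
                pid = peak.id if peak.id is None or len(clipped) == 1 else f"{peak.id}.{k}"
                pieces.append(
                    GenomicInterval(
                        frag.chrom, frag.start, frag.end, id=pid, score=peak.score
                    )
                )
        current = IntervalSet(pieces)
    return current
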