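"""Base-level partition of the analyzable genome into categories A–F.

Every analyzable base falls in exactly one of three element classes —
active CRM, non-active CRM, non-CRM — and either overlaps a STARR peak or
does not. Crossing the two gives six exclusive categories:

====  =====================  ============
cat   element class          STARR peak?
====  =====================  ============
A     non-active CRM         no
B     active CRM             no
C     active CRM             yes
D     non-active CRM         yes
E     non-CRM                yes
F     non-CRM                no
====  =====================  ============

Base labels use direct base intersection (a peak base inside an active CRM
is C regardless of element-level pairing); the 50% reciprocal-overlap rule
governs only element-level statistics (containment, peaks-per-CRM). An
optional strict mode applies the reciprocal rule to the C/D base labels as
a sensitivity analysis; its counts no longer satisfy the peak-base sum
identity by construction.

Peak bases outside the analyzable regions are reported as a separate
``unassessed`` count, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomic_core import (
    GenomicInterval,
    GenomeSpec,
    IntervalSet,
    intersect_length,
    reciprocal_overlap,
)

__all__ = [
    "CATEGORIES",
    "PartitionResult",
    "partition_genome",
    "match_peaks_to_crms",
    "containment_class",
    "peaks_per_crm",
    "cross_sample_activity",
]

CATEGORIES = ("A", "B", "C", "D", "E", "F")


@dataclass
class PartitionResult:
    sample_id: str
    base_counts: Dict[str, int]
    unassessed_peak_bases: int
    label_track: List[GenomicInterval]  # run-length category segments (id = letter)
    peak_assignments: "Optional[object]" = None  # pandas DataFrame
    crm_assignments: "Optional[object]" = None  # pandas DataFrame
    derived: Dict[str, float] = field(default_factory=dict)

    def check_identities(
        self,
        analyzable_bases: int,
        peak_bases_in_region: int,
        active_bases: int,
        nonactive_bases: int,
        noncrm_bases: int,
    ) -> None:
        bc = self.base_counts
        assert sum(bc[c] for c in CATEGORIES) == analyzable_bases
        assert bc["C"] + bc["D"] + bc["E"] == peak_bases_in_region
        assert bc["B"] + bc["C"] == active_bases
        assert bc["A"] + bc["D"] == nonactive_bases
        assert bc["E"] + bc["F"] == noncrm_bases

    def ratios(self) -> Dict[str, float]:
        """The audit's headline base-share ratios, as percentages."""
        bc = self.base_counts
        peak = bc["C"] + bc["D"] + bc["E"]
        active = bc["B"] + bc["C"]
        nonactive = bc["A"] + bc["D"]
        crm = active + nonactive
        out: Dict[str, float] = {}

        def pct(num: int, den: int) -> float:
            return 100.0 * num / den if den else float("nan")

        out["C_of_peak"] = pct(bc["C"], peak)
        out["D_of_peak"] = pct(bc["D"], peak)
        out["E_of_peak"] = pct(bc["E"], peak)
        out["C_of_active"] = pct(bc["C"], active)
        out["B_of_active"] = pct(bc["B"], active)
        out["D_of_nonactive"] = pct(bc["D"], nonactive)
        out["nonactive_of_crm"] = pct(nonactive, crm)
        total_peak = peak + self.unassessed_peak_bases
        out["peak_share_unassessed"] = pct(self.unassessed_peak_bases, total_peak)
        return out


def _validate_partition_inputs(
    genome: GenomeSpec,
    active: IntervalSet,
    nonactive: IntervalSet,
    noncrms: IntervalSet,
) -> None:
    pairs = [("active/non-active", active, nonactive),
             ("active/non-CRM", active, noncrms),
             ("non-active/non-CRM", nonactive, noncrms)]
    for name, a, b in pairs:
        ov = a.intersect(b)
        if ov.total_length() > 0:
            offending = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in list(ov)[:5]]
            raise ValueError(f"{name} element sets overlap at {offending}")
    covered = active.union(nonactive).union(noncrms)
    analyzable = genome.analyzable_regions.merge()
    gap = analyzable.subtract(covered)
    if gap.total_length() > 0:
        offending = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in list(gap)[:5]]
        raise ValueError(f"element sets leave analyzable gaps at {offending}")
    extra = covered.subtract(analyzable)
    if extra.total_length() > 0:
        offending = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in list(extra)[:5]]
        raise ValueError(f"element sets extend outside analyzable regions at {offending}")


def _element_split(
    elements: IntervalSet, parts: Dict[str, IntervalSet]
) -> "object":
    """Per-element base split over named part sets (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for k, el in enumerate(elements):
        row = {"id": el.id or f"el{k}", "chrom": el.chrom, "start": el.start,
               "end": el.end, "length": el.length()}
        for name, part in parts.items():
            row[name] = part.overlap_bp(el.chrom, el.start, el.end)
        rows.append(row)
    return pd.DataFrame(rows)


def partition_genome(
    genome: GenomeSpec,
    active_crms: IntervalSet,
    nonactive_crms: IntervalSet,
    noncrms: IntervalSet,
    peaks: IntervalSet,
    sample_id: str = "sample",
    strict_element_rule: bool = False,
    reciprocal_threshold: float = 0.5,
    with_assignments: bool = True,
) -> PartitionResult:
    """Assign every analyzable base to exactly one category A–F.

    ``strict_element_rule=True`` restricts C/D labels to peak∩CRM bases of
    reciprocally matched pairs (sensitivity mode).
    """
    _validate_partition_inputs(genome, active_crms, nonactive_crms, noncrms)
    analyzable = genome.analyzable_regions.merge()
    peaks_merged = peaks.merge()
    peaks_in = peaks_merged.intersect(analyzable)
    unassessed = peaks_merged.total_length() - peaks_in.total_length()

    if strict_element_rule:
        crm_catalog = IntervalSet(list(active_crms) + list(nonactive_crms))
        pairs = match_peaks_to_crms(peaks, crm_catalog, reciprocal_threshold)
        c_pieces: List[GenomicInterval] = []
        d_pieces: List[GenomicInterval] = []
        for pk, crm in pairs:
            lo, hi = max(pk.start, crm.start), min(pk.end, crm.end)
            piece = GenomicInterval(pk.chrom, lo, hi)
            (c_pieces if _in_set(crm, active_crms) else d_pieces).append(piece)
        c_set = IntervalSet(c_pieces).intersect(analyzable)
        d_set = IntervalSet(d_pieces).intersect(analyzable)
    else:
        c_set = active_crms.intersect(peaks_in)
        d_set = nonactive_crms.intersect(peaks_in)
    e_set = noncrms.intersect(peaks_in)
    b_set = active_crms.merge().subtract(c_set)
    a_set = nonactive_crms.merge().subtract(d_set)
    f_set = noncrms.merge().subtract(e_set)

    cat_sets = {"A": a_set, "B": b_set, "C": c_set, "D": d_set, "E": e_set, "F": f_set}
    base_counts = {k: v.total_length() for k, v in cat_sets.items()}

    label_track: List[GenomicInterval] = sorted(
        (
            GenomicInterval(iv.chrom, iv.start, iv.end, id=cat)
            for cat, cs in cat_sets.items()
            for iv in cs
        ),
        key=lambda iv: (iv.chrom, iv.start),
    )

    peak_assignments = crm_assignments = None
    if with_assignments:
        peak_assignments = _element_split(
            peaks, {"C": c_set, "D": d_set, "E": e_set}
        )
        if peak_assignments is not None and len(peaks):
            peak_assignments["outside_analyzable"] = peak_assignments["length"] - (
                peak_assignments[["C", "D", "E"]].sum(axis=1)
            )
        crms_all = IntervalSet(list(active_crms) + list(nonactive_crms))
        crm_assignments = _element_split(
            crms_all, {"A": a_set, "B": b_set, "C": c_set, "D": d_set}
        )

    result = PartitionResult(
        sample_id=sample_id,
        base_counts=base_counts,
        unassessed_peak_bases=unassessed,
        label_track=label_track,
        peak_assignments=peak_assignments,
        crm_assignments=crm_assignments,
    )
    if not strict_element_rule:
        result.check_identities(
            analyzable_bases=analyzable.total_length(),
            peak_bases_in_region=peaks_in.total_length(),
            active_bases=active_crms.total_length(),
            nonactive_bases=nonactive_crms.total_length(),
            noncrm_bases=noncrms.total_length(),
        )
    result.derived = result.ratios()
    return result


def _in_set(iv: GenomicInterval, s: IntervalSet) -> bool:
    return s.overlap_bp(iv.chrom, iv.start, iv.end) == iv.length()


def match_peaks_to_crms(
    peaks: IntervalSet,
    crms: IntervalSet,
    threshold: float = 0.5,
) -> List[Tuple[GenomicInterval, GenomicInterval]]:
    """All (peak, CRM) pairs overlapping ≥ threshold of both lengths
    reciprocally — the element-level pairing behind containment and
    peaks-per-CRM statistics."""
    pairs = []
    for peak in peaks:
        for crm in crms.overlapping(peak):
            if reciprocal_overlap(peak, crm, threshold):
                pairs.append((peak, crm))
    return pairs


def containment_class(peak: GenomicInterval, crm: GenomicInterval) -> str:
    """'full' iff the CRM lies entirely within the peak, else 'partial'."""
    return "full" if peak.contains(crm) else "partial"


def peaks_per_crm(
    crm: GenomicInterval,
    matched_pairs: Sequence[Tuple[GenomicInterval, GenomicInterval]],
) -> int:
    """Number of distinct matched peaks for one CRM."""
    seen = set()
    for peak, c in matched_pairs:
        if c.chrom == crm.chrom and c.start == crm.start and c.end == crm.end:
            seen.add((peak.chrom, peak.start, peak.end))
    return len(seen)


def cross_sample_activity(
    category_d: Dict[str, set],
    category_c: Dict[str, set],
) -> "object":
    """Matrix of percentages: entry (x, y) = share of sample-x category-D
    CRMs (non-active, peak-overlapped) that are in category C (active,
    peak-overlapped) in sample y. Diagonal 0; rows with empty D are NaN.
    """
    import pandas as pd

    samples = sorted(set(category_d) | set(category_c))
    mat = np.full((len(samples), len(samples)), np.nan)
    for i, x in enumerate(samples):
        d = category_d.get(x, set())
        for j, y in enumerate(samples):
            if x == y:
                mat[i, j] = 0.0
            elif d:
                mat[i, j] = 100.0 * len(d & category_c.get(y, set())) / len(d)
    return pd.DataFrame(mat, index=samples, columns=samples)
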