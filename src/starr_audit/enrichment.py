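"""Matched random backgrounds and fold-change enrichment.

Foreground elements (CRMs or STARR peaks of one category) are compared to
randomly placed genomic intervals with the matched number and length
distribution — optionally GC-matched by rejection sampling against a
sequence source. Enrichment of an annotation label (a ChromHMM state, a
transposable-element class) is::

    fold change = (N − M) / M

where N is the foreground quantity and M the same quantity on the matched
background (averaged over draws). ``mode="length"`` counts covered bp (the
ChromHMM convention); ``mode="count"`` counts annotation elements
overlapping by ≥1 bp (the TE convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomic_core import GenomeSpec, GenomicInterval, IntervalSet, gc_content

__all__ = [
    "MatchSpec",
    "sample_matched",
    "fold_change",
    "state_enrichment",
    "FOLD_CHANGE_UNDEFINED",
]

FOLD_CHANGE_UNDEFINED = float("nan")


@dataclass
class MatchSpec:
    """How to draw length- (and optionally GC-) matched random intervals."""

    length_list: List[int]
    gc_match: bool = False
    gc_list: Optional[List[float]] = None  # template GC, required if gc_match
    gc_tolerance: float = 0.02
    exclusion: Optional[IntervalSet] = None
    n_draws: int = 10
    max_attempts: int = 10_000
    seed: int = 0

    @property
    def n_elements(self) -> int:
        return len(self.length_list)

    @classmethod
    def from_templates(
        cls,
        templates: IntervalSet,
        sequences: Optional[Dict[str, str]] = None,
        gc_match: bool = False,
        **kwargs,
    ) -> "MatchSpec":
        lengths = [iv.length() for iv in templates]
        gcs = None
        if gc_match:
            if sequences is None:
                raise ValueError("gc_match requires a sequence source")
            gcs = [
                gc_content(sequences[iv.chrom][iv.start : iv.end]) for iv in templates
            ]
        return cls(length_list=lengths, gc_match=gc_match, gc_list=gcs, **kwargs)


def sample_matched(
    genome: GenomeSpec,
    spec: MatchSpec,
    sequences: Optional[Dict[str, str]] = None,
) -> List[IntervalSet]:
    """One IntervalSet per draw; each reproduces ``spec.length_list`` exactly.

    Intervals are placed uniformly over chromosomes proportional to length,
    rejecting placements crossing chromosome ends or the exclusion set;
    with ``gc_match`` a placement is also rejected unless its GC is within
    ``gc_tolerance`` of the template's. Deterministic given ``spec.seed``.
    """
    if spec.gc_match and sequences is None:
        raise ValueError("gc_match requires a sequence source")
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    draws: List[IntervalSet] = []
    for d in range(spec.n_draws):
        placed: List[GenomicInterval] = []
        for t, length in enumerate(spec.length_list):
            target_gc = spec.gc_list[t] if spec.gc_match else None
            ok = False
            for _ in range(spec.max_attempts):
                ci = int(rng.choice(len(chroms), p=probs))
                chrom = chroms[ci]
                max_start = genome.chrom_sizes[chrom] - length
                if max_start < 0:
                    continue
                start = int(rng.integers(0, max_start + 1))
                end = start + length
                if spec.exclusion is not None and spec.exclusion.overlap_bp(
                    chrom, start, end
                ):
                    continue
                if target_gc is not None:
                    gc = gc_content(sequences[chrom][start:end])
                    if not (abs(gc - target_gc) <= spec.gc_tolerance):
                        continue
                placed.append(GenomicInterval(chrom, start, end, id=f"bg{d}_{t}"))
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place background interval of length {length}"
                    + (f" at GC {target_gc:.3f}" if target_gc is not None else "")
                    + f" after {spec.max_attempts} attempts"
                )
        draws.append(IntervalSet(placed))
    return draws


def fold_change(n: float, m: float) -> float:
    """(N − M)/M; NaN with a warning when M == 0."""
    if m == 0:
        warnings.warn("fold change undefined: background quantity M is 0", stacklevel=2)
        return FOLD_CHANGE_UNDEFINED
    return (n - m) / m


def _label_sets(annotation: Sequence[GenomicInterval]) -> Dict[str, IntervalSet]:
    per: Dict[str, List[GenomicInterval]] = {}
    for iv in annotation:
        per.setdefault(iv.id or "NA", []).append(iv)
    return {label: IntervalSet(ivs) for label, ivs in per.items()}


def _quantity(fg: IntervalSet, label_set: IntervalSet, mode: str) -> float:
    if mode == "length":
        return float(fg.intersect(label_set).total_length())
    if mode == "count":
        fg_merged = fg.merge()
        return float(
            sum(
                1
                for iv in label_set
                if fg_merged.overlap_bp(iv.chrom, iv.start, iv.end) > 0
            )
        )
    raise ValueError(f"unknown mode {mode!r}")


def state_enrichment(
    foreground: IntervalSet,
    annotation: Sequence[GenomicInterval],
    background_draws: Sequence[IntervalSet],
    mode: str = "length",
) -> "object":
    """Per-label fold change table (pandas DataFrame: label, N, M,
    fold_change, n_draws, mode). M is the mean over background draws;
    labels with M == 0 in every draw get NaN."""
    import pandas as pd

    labels = _label_sets(annotation)
    if not labels:
        raise ValueError("annotation has no labels")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # M==0 rows are visible as NaN in the table
        for label, lset in sorted(labels.items()):
            n = _quantity(foreground, lset, mode)
            ms = [_quantity(bg, lset, mode) for bg in background_draws]
            m = float(np.mean(ms))
            rows.append(
                {
                    "label": label,
                    "N": n,
                    "M": m,
                    "fold_change": fold_change(n, m),
                    "n_draws": len(background_draws),
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)
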