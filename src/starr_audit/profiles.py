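"""Element-centered chromatin-signal profile matrices.

For each element, a window (default 6 kb) centered on its midpoint is tiled
into non-overlapping bins (default 100 bp); each bin holds the mean
library-size-normalized fold enrichment of the signal over input across
the bin's bases — the same fold-enrichment definition used everywhere else
in the package. Bins extending past a chromosome end are masked, not
zero-filled, and masked entries are excluded from column means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .genomic_core import GenomicInterval, GenomeSpec, IntervalSet
from .tracks import SignalTrack, fold_enrichment_values
from .partition import PartitionResult

__all__ = ["ProfileMatrix", "profile_matrix", "profile_mean", "sample_category_rows"]


@dataclass
class ProfileMatrix:
    row_ids: List[str]
    values: np.ndarray  # n_elements × n_bins
    mask: np.ndarray  # True where the bin is valid (on-chromosome)
    window: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> "object":
        import pandas as pd

        half = self.window // 2
        cols = [f"bin_{-half + i * self.bin_size}" for i in range(self.n_bins)]
        df = pd.DataFrame(np.where(self.mask, self.values, np.nan), columns=cols)
        df.insert(0, "id", self.row_ids)
        return df


def profile_matrix(
    elements: IntervalSet,
    signal: SignalTrack,
    input_track: SignalTrack,
    genome: Optional[GenomeSpec] = None,
    window: int = 6000,
    bin_size: int = 100,
) -> ProfileMatrix:
    """Per-element binned fold-enrichment profile around element midpoints."""
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin size")
    if not elements:
        raise ValueError("empty element set")
    n_bins = window // bin_size
    half = window // 2
    rows = []
    masks = []
    ids = []
    for k, el in enumerate(elements):
        if not (signal.covers(el.chrom) or input_track.covers(el.chrom)):
            raise ValueError(f"element {el.id or k} on chromosome {el.chrom} absent from tracks")
        mid = el.midpoint()
        w_start = mid - half
        w_end = mid + half
        chrom_len = None
        if genome is not None:
            chrom_len = genome.chrom_sizes.get(el.chrom)
        lo = max(w_start, 0)
        hi = min(w_end, chrom_len) if chrom_len is not None else w_end
        vals = np.zeros(window, dtype=np.float64)
        valid = np.zeros(window, dtype=bool)
        if lo < hi:
            fe = fold_enrichment_values(el.chrom, lo, hi, signal, input_track)
            vals[lo - w_start : hi - w_start] = fe
            valid[lo - w_start : hi - w_start] = True
        binned = vals.reshape(n_bins, bin_size)
        vmask = valid.reshape(n_bins, bin_size)
        bin_ok = vmask.all(axis=1)  # a bin is valid only if fully on-chromosome
        with np.errstate(invalid="ignore"):
            bin_vals = np.where(bin_ok, binned.mean(axis=1), 0.0)
        rows.append(bin_vals)
        masks.append(bin_ok)
        ids.append(el.id or f"el{k}")
    return ProfileMatrix(
        row_ids=ids,
        values=np.vstack(rows),
        mask=np.vstack(masks),
        window=window,
        bin_size=bin_size,
    )


def profile_mean(matrix: ProfileMatrix) -> np.ndarray:
    """Per-bin mean over unmasked entries; NaN for fully masked columns."""
    counts = matrix.mask.sum(axis=0)
    sums = (matrix.values * matrix.mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def sample_category_rows(
    category_elements: Dict[str, IntervalSet],
    category: str,
    caps: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> IntervalSet:
    """Row-sampling rules for the per-category profile heatmaps.

    All elements for C, D and E; up to a cap (default 10 000) uniformly at
    random for A and B; F downsampled to the number of category-E peaks.
    Deterministic given the seed.
    """
    caps = caps or {}
    elements = list(category_elements.get(category, IntervalSet()))
    rng = np.random.default_rng(seed)
    if category in ("A", "B"):
        cap = caps.get(category, 10_000)
        if len(elements) > cap:
            idx = rng.choice(len(elements), size=cap, replace=False)
            elements = [elements[i] for i in sorted(idx)]
    elif category == "F":
        n_e = len(category_elements.get("E", IntervalSet()))
        if len(elements) > n_e:
            idx = rng.choice(len(elements), size=n_e, replace=False)
            elements = [elements[i] for i in sorted(idx)]
    return IntervalSet(elements)
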