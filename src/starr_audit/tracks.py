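"""Per-base signal tracks with bedGraph semantics.

A :class:`SignalTrack` is piecewise constant per chromosome with a
library-size normalizer (total signal mass by default). Uncovered bases
read as 0 and are flagged through a coverage mask.

One fold-enrichment definition is shared by the functional-state features,
the peak signal strengths and the profile matrices::

    fe(base) = (signal/L_sig) / (input/L_inp)

with a pseudocount of one read-equivalent applied at zero-input bases
(numerator ``signal+1``, denominator ``1``), so fold enrichment stays
bounded where the input library has no coverage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .genomic_core import GenomicInterval

__all__ = ["SignalTrack", "fold_enrichment_values", "mean_fold_enrichment"]


class SignalTrack:
    """Piecewise-constant non-negative coverage over chromosomes."""

    def __init__(
        self,
        data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: Optional[float] = None,
        allow_negative: bool = False,
    ):
        """``data`` maps chrom -> (starts, ends, values), sorted, non-overlapping.

        ``allow_negative`` admits signed tracks (conservation scores); the
        default rejects negative coverage values.
        """
        self.data = {}
        for chrom, (s, e, v) in data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if not allow_negative and np.any(v < 0):
                raise ValueError(f"negative signal values on {chrom}")
            if np.any(e <= s) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"track intervals on {chrom} unsorted or overlapping")
            self.data[chrom] = (s, e, v)
        if library_size is None:
            library_size = float(
                sum(((e - s) * v).sum() for s, e, v in self.data.values())
            )
        self.library_size = library_size

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dense(
        cls,
        arrays: Dict[str, np.ndarray],
        step: int = 1,
        library_size: Optional[float] = None,
        allow_negative: bool = False,
    ) -> "SignalTrack":
        """Build from per-chromosome dense arrays of per-``step``-bp values."""
        data = {}
        for chrom, vals in arrays.items():
            vals = np.asarray(vals, dtype=np.float64)
            starts = np.arange(len(vals), dtype=np.int64) * step
            ends = starts + step
            data[chrom] = (starts, ends, vals)
        return cls(data, library_size=library_size, allow_negative=allow_negative)

    @classmethod
    def read_bedgraph(cls, path: str | Path, library_size: Optional[float] = None) -> "SignalTrack":
        per: Dict[str, list] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
                per.setdefault(fields[0], []).append(
                    (int(fields[1]), int(fields[2]), float(fields[3]))
                )
        data = {}
        for chrom, rows in per.items():
            rows.sort()
            s, e, v = (np.asarray(x) for x in zip(*rows))
            data[chrom] = (s.astype(np.int64), e.astype(np.int64), v.astype(np.float64))
        return cls(data, library_size=library_size)

    @classmethod
    def read_bigwig(cls, path: str | Path, library_size: Optional[float] = None) -> "SignalTrack":
        """Optional bigWig entry point (requires pyBigWig)."""
        import pyBigWig  # local import: optional dependency

        bw = pyBigWig.open(str(path))
        data = {}
        try:
            for chrom, size in bw.chroms().items():
                ivs = bw.intervals(chrom, 0, size) or []
                if not ivs:
                    continue
                s, e, v = (np.asarray(x) for x in zip(*ivs))
                data[chrom] = (s.astype(np.int64), e.astype(np.int64), v.astype(np.float64))
        finally:
            bw.close()
        return cls(data, library_size=library_size)

    def write_bedgraph(self, path: str | Path) -> None:
        """Run-length-compressed bedGraph (adjacent equal values merged,
        zero runs dropped)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                starts, ends, vals = self.data[chrom]
                cur_s = cur_e = None
                cur_v = 0.0
                for s, e, v in zip(starts.tolist(), ends.tolist(), vals.tolist()):
                    if cur_s is not None and s == cur_e and v == cur_v:
                        cur_e = e
                        continue
                    if cur_s is not None and cur_v != 0.0:
                        fh.write(f"{chrom}\t{cur_s}\t{cur_e}\t{cur_v:g}\n")
                    cur_s, cur_e, cur_v = s, e, v
                if cur_s is not None and cur_v != 0.0:
                    fh.write(f"{chrom}\t{cur_s}\t{cur_e}\t{cur_v:g}\n")

    # -- queries -------------------------------------------------------------
    def covers(self, chrom: str) -> bool:
        return chrom in self.data

    def per_base(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """(values, covered-mask) for every base of ``chrom:[start,end)``.

        Bases outside any track interval read 0 with mask False.
        """
        n = end - start
        vals = np.zeros(n, dtype=np.float64)
        mask = np.zeros(n, dtype=bool)
        entry = self.data.get(chrom)
        if entry is None:
            return vals, mask
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            vals[a:b] = values[i]
            mask[a:b] = True
        return vals, mask

    def mean_over(self, interval: GenomicInterval) -> float:
        """Mean raw value over the interval (uncovered bases count as 0)."""
        vals, _ = self.per_base(interval.chrom, interval.start, interval.end)
        return float(vals.mean())


def fold_enrichment_values(
    chrom: str,
    start: int,
    end: int,
    signal: SignalTrack,
    input_track: SignalTrack,
) -> np.ndarray:
    """Per-base library-size-normalized fold enrichment over an interval."""
    s_vals, _ = signal.per_base(chrom, start, end)
    i_vals, _ = input_track.per_base(chrom, start, end)
    ls = signal.library_size
    li = input_track.library_size
    if ls <= 0 or li <= 0:
        raise ValueError("library sizes must be positive")
    fe = np.empty(end - start, dtype=np.float64)
    pos = i_vals > 0
    fe[pos] = (s_vals[pos] / ls) / (i_vals[pos] / li)
    # zero-input pseudocount: one read-equivalent in numerator and denominator
    fe[~pos] = ((s_vals[~pos] + 1.0) / ls) / (1.0 / li)
    return fe


def mean_fold_enrichment(
    element: GenomicInterval, signal: SignalTrack, input_track: SignalTrack
) -> float:
    """Per-bp mean fold enrichment over an element — the shared definition
    behind state-caller features and peak signal strength."""
    if not signal.covers(element.chrom) and not input_track.covers(element.chrom):
        raise ValueError(f"element {element.id or element.chrom} outside track coverage")
    return float(
        fold_enrichment_values(
            element.chrom, element.start, element.end, signal, input_track
        ).mean()
    )
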