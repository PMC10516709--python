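"""Closest-gene assignment and per-category expression comparison.

Each sequence element is associated with the gene whose TSS is nearest on
the linear chromosome (edge distance; 0 if the TSS falls inside the
element; ties broken by lexicographically smaller gene id). Per category,
the expression values of all associated genes form the distribution
compared across categories with a two-tailed Mann–Whitney U test and a
two-sample Kolmogorov–Smirnov test.

The MWU p-value uses the exact null when the smaller sample has ≤8
observations and there are no ties; with ties and a small total sample it
falls back to full enumeration over label assignments (midranks), and
otherwise to the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import GenomicInterval, IntervalSet

__all__ = [
    "GeneRecord",
    "GeneIndex",
    "closest_gene",
    "category_gene_sets",
    "category_expression",
    "mwu_test",
    "ks_test",
    "pairwise_tests",
]


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    expression: float = 0.0


class GeneIndex:
    """Sorted per-chromosome TSS index for nearest-gene queries."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes = list(genes)
        per: Dict[str, List[Tuple[int, str]]] = {}
        self.by_id: Dict[str, GeneRecord] = {}
        for g in self.genes:
            per.setdefault(g.chrom, []).append((g.tss, g.gene_id))
            self.by_id[g.gene_id] = g
        self._pos: Dict[str, np.ndarray] = {}
        self._ids: Dict[str, List[str]] = {}
        for chrom, pairs in per.items():
            pairs.sort()
            self._pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._ids[chrom] = [gid for _, gid in pairs]

    @classmethod
    def read_tsv(
        cls, genes_path: str | Path, expression_path: Optional[str | Path] = None
    ) -> "GeneIndex":
        """genes TSV: gene_id, chrom, tss, strand; expression TSV: gene_id, TPM."""
        gdf = pd.read_csv(genes_path, sep="\t")
        expr: Dict[str, float] = {}
        if expression_path is not None:
            edf = pd.read_csv(expression_path, sep="\t")
            expr = dict(zip(edf.iloc[:, 0], edf.iloc[:, 1].astype(float)))
        return cls(
            GeneRecord(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                tss=int(r.tss),
                strand=str(getattr(r, "strand", "+")),
                expression=float(expr.get(str(r.gene_id), 0.0)),
            )
            for r in gdf.itertuples()
        )

    def closest(self, element: GenomicInterval) -> Optional[str]:
        pos = self._pos.get(element.chrom)
        if pos is None or len(pos) == 0:
            return None
        ids = self._ids[element.chrom]
        idx = int(np.searchsorted(pos, element.start))
        best: Optional[Tuple[float, str]] = None
        for j in range(max(0, idx - 1), min(len(pos), idx + 2)):
            t = int(pos[j])
            if element.start <= t < element.end:
                dist = 0.0
            elif t >= element.end:
                dist = float(t - element.end)
            else:
                dist = float(element.start - t)
            cand = (dist, ids[j])
            if best is None or cand < best:
                best = cand
        # a TSS inside the element may sit past idx+1; scan the containment span
        lo = int(np.searchsorted(pos, element.start, side="left"))
        hi = int(np.searchsorted(pos, element.end - 1, side="right"))
        for j in range(lo, hi):
            cand = (0.0, ids[j])
            if best is None or cand < best:
                best = cand
        return best[1] if best else None


def closest_gene(element: GenomicInterval, genes: GeneIndex) -> Optional[str]:
    """Gene id minimizing edge distance to the TSS; None when the element's
    chromosome carries no gene (undefined-value sentinel)."""
    return genes.closest(element)


def category_gene_sets(
    element_catalogs: Dict[str, IntervalSet],
    genes: GeneIndex,
) -> Dict[str, Set[str]]:
    """Per category, ids of genes closest to ≥1 element of that category.
    A gene counts once within a category but may appear under several."""
    out: Dict[str, Set[str]] = {}
    for cat, elements in element_catalogs.items():
        gene_ids: Set[str] = set()
        for el in elements:
            gid = genes.closest(el)
            if gid is not None:
                gene_ids.add(gid)
        out[cat] = gene_ids
    return out


def category_expression(
    element_catalogs: Dict[str, IntervalSet],
    genes: GeneIndex,
) -> Dict[str, np.ndarray]:
    """Per category, expression values of the associated genes (see
    :func:`category_gene_sets`)."""
    return {
        cat: np.array(sorted(genes.by_id[g].expression for g in ids), dtype=float)
        for cat, ids in category_gene_sets(element_catalogs, genes).items()
    }


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

_ENUM_MAX_TOTAL = 20


def _enumerate_mwu_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided p by enumerating all label assignments (midranks)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    center = nx * ny / 2.0
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        u = float(ranks[list(combo)].sum() - nx * (nx + 1) / 2)
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def mwu_test(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Two-tailed Mann–Whitney U test. Returns {"U": ..., "p": ...}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = min(len(x), len(y)) <= 8
    if small and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return {"U": float(res.statistic), "p": float(res.pvalue)}
    if small and has_ties and len(pooled) <= _ENUM_MAX_TOTAL:
        u, p = _enumerate_mwu_p(x, y)
        return {"U": u, "p": p}
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def ks_test(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test. Returns {"D": ..., "p": ...}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def pairwise_tests(
    distributions: Dict[str, np.ndarray],
    test: str = "mwu",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """All pairwise category comparisons (raw p by default; optional BH column)."""
    cats = sorted(distributions)
    rows = []
    for a, b in itertools.combinations(cats, 2):
        xa, xb = distributions[a], distributions[b]
        if len(xa) == 0 or len(xb) == 0:
            rows.append({"a": a, "b": b, "stat": np.nan, "p": np.nan})
            continue
        r = mwu_test(xa, xb) if test == "mwu" else ks_test(xa, xb)
        stat = r.get("U", r.get("D"))
        rows.append({"a": a, "b": b, "stat": stat, "p": r["p"]})
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        mask = df["p"].notna()
        p = df.loc[mask, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, p[i] * m / (rank_pos + 1))
            adj[i] = prev
        df.loc[mask, "p_bh"] = adj
    return df
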