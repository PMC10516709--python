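"""Seeded synthetic scenarios with the statistical structure the audit assumes.

A scenario is a small multi-chromosome genome carrying:

* a planted CRM / non-CRM partition of the analyzable regions, with a
  configurable fraction of CRMs active;
* STARR peaks drawn with a configurable base-share mixture over the three
  peak categories (C: inside active CRMs, D: inside non-active CRMs,
  E: inside non-CRMs), each peak placed fully inside a host element;
* six epigenetic-mark tracks plus input and STARR signal, with
  category-specific profiles (active-enhancer marks bump over active CRMs,
  heterochromatin mark over E-like peaks), and a conservation track
  elevated inside CRMs;
* genes/expression with a multiplicative boost for genes nearest an active
  CRM; TFBS hits with class-specific rates and a degree-annotated motif
  network (high-degree motifs concentrated in peak-overlapped CRMs);
* a ChromHMM-like segmentation with a heterochromatin state planted over
  E-like peaks, and TE-like intervals with LTR elements enriched in them.

Everything derives from one :class:`numpy.random.Generator` seed, so a
given config + seed reproduces the bundle byte-for-byte on disk. Ground
truth (intended category per element, intended state per CRM, intended
boost per gene) is kept alongside.

The null scenario keeps the same geometry but plants no effects at all:
identical mark statistics, expression, conservation and TFBS rates across
categories — the substrate for type-I-error and AUROC calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomic_core import (
    GenomeSpec,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_fasta,
)
from .metrics import MotifNetwork, TfbsHit
from .tracks import SignalTrack

__all__ = ["ScenarioConfig", "SyntheticBundle", "generate_scenario", "generate_null_scenario"]

MARKS = ("atac", "h3k4me1", "h3k4me3", "h3k27ac", "h3k9me3", "h3k27me3")
TRACK_STEP = 10  # bp per piecewise-constant step; keeps bedGraphs compact


def _default_mark_effects() -> Dict[str, Dict[str, float]]:
    # amplitude of the planted bump over the noise floor (~1.0), per class
    return {
        "atac": {"active_crm": 6.0, "nonactive_crm": 0.5, "e_peak": 0.0},
        "h3k4me1": {"active_crm": 4.0, "nonactive_crm": 0.5, "e_peak": 0.0},
        "h3k4me3": {"active_crm": 2.5, "nonactive_crm": 0.3, "e_peak": 0.0},
        "h3k27ac": {"active_crm": 5.0, "nonactive_crm": 0.3, "e_peak": 0.0},
        "h3k9me3": {"active_crm": 0.0, "nonactive_crm": 0.0, "e_peak": 4.0},
        "h3k27me3": {"active_crm": 0.0, "nonactive_crm": 1.5, "e_peak": 0.0},
    }


def _default_tfbs_rates() -> Dict[str, float]:
    # hits per kb
    return {"c_like": 6.0, "other_crm": 3.0, "e_like": 2.0, "background": 0.5}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    n_chroms: int = 4
    chrom_length: int = 1_200_000
    margin_fraction: float = 0.02  # chromosome tail outside the analyzable regions
    crm_count: int = 1200
    crm_length_mean: float = 1181.0  # log-normal target mean, bp
    crm_length_sigma: float = 0.4
    crm_length_min: int = 150
    noncrm_piece_median: float = 1000.0
    active_fraction: float = 0.3
    peak_count: int = 1000
    peak_length_median: float = 500.0  # log-normal median, bp
    peak_length_sigma: float = 0.25
    peak_length_min: int = 120
    peak_category_mix: Tuple[float, float, float] = (0.23, 0.28, 0.49)  # C, D, E
    out_of_region_fraction: float = 0.012  # E-like peaks straddling the margin
    on_infeasible_mix: str = "reallocate"  # or "error"
    mark_effects: Dict[str, Dict[str, float]] = field(default_factory=_default_mark_effects)
    starr_effects: Dict[str, float] = field(
        default_factory=lambda: {"C": 6.0, "D": 4.0, "E": 4.0}
    )
    # gamma noise floor, mean = shape*scale = 1.0; shape > 2 keeps the
    # per-base fold-enrichment variance finite when this track is the input
    noise_shape: float = 4.0
    noise_scale: float = 0.25
    n_genes: int = 600
    tpm_log_mean: float = np.log(10.0)
    tpm_log_sigma: float = 1.0
    expression_effect: float = 4.0  # multiplicative TPM boost near active CRMs
    tfbs_rates: Dict[str, float] = field(default_factory=_default_tfbs_rates)
    n_motifs: int = 80
    n_network_edges: int = 300
    conservation_effect: float = 1.0  # mean shift inside CRMs
    gc_level: float = 0.41
    gc_gradient: float = 0.0  # GC spans gc_level ± gradient/2 along each chromosome
    with_sequence: bool = True
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.peak_category_mix) - 1.0) > 1e-9:
            raise ValueError("peak_category_mix must sum to 1")
        if any(m < 0 for m in self.peak_category_mix):
            raise ValueError("peak_category_mix entries must be >= 0")
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in [0, 1]")
        expected_mass = self.crm_count * self.crm_length_mean
        analyzable = self.n_chroms * self.chrom_length * (1 - self.margin_fraction)
        if expected_mass > 0.8 * analyzable:
            raise ValueError(
                f"infeasible packing: expected CRM mass {expected_mass:.0f} bp "
                f"exceeds 80% of the {analyzable:.0f} bp analyzable genome"
            )


@dataclass
class SyntheticBundle:
    config: ScenarioConfig
    genome: GenomeSpec
    sequences: Dict[str, str]
    crms: IntervalSet  # ids crm_*; truth state in truth_crm_state
    noncrms: IntervalSet  # ids ncr_*
    peaks: IntervalSet  # ids peak_*
    truth_crm_state: Dict[str, str]  # crm id -> "active" | "non-active"
    truth_peak_category: Dict[str, str]  # peak id -> "C" | "D" | "E"
    truth_gene_boosted: Dict[str, bool]
    tracks: Dict[str, SignalTrack]  # MARKS + "input" + "starr" + "conservation"
    genes: pd.DataFrame  # gene_id, chrom, tss, strand
    expression: pd.DataFrame  # gene_id, tpm
    tfbs_hits: List[TfbsHit]
    network_edges: List[Tuple[str, str]]
    chromhmm: List[GenomicInterval]  # labeled (id = state)
    tes: List[GenomicInterval]  # labeled (id = class)

    @property
    def network(self) -> MotifNetwork:
        return MotifNetwork(self.network_edges)

    # -- derived element catalogs -------------------------------------------
    def active_crms(self) -> IntervalSet:
        return IntervalSet(
            [c for c in self.crms if self.truth_crm_state[c.id] == "active"]
        )

    def nonactive_crms(self) -> IntervalSet:
        return IntervalSet(
            [c for c in self.crms if self.truth_crm_state[c.id] == "non-active"]
        )

    def category_elements(self) -> Dict[str, IntervalSet]:
        """Intended per-category element catalogs (CRMs for A–D, peaks for E,
        peak-free non-CRMs for F)."""
        hosted: Dict[str, str] = {}
        for pk in self.peaks:
            host = self._host_of(pk)
            if host is not None:
                hosted[host] = self.truth_peak_category[pk.id]
        cats: Dict[str, List[GenomicInterval]] = {c: [] for c in "ABCDEF"}
        for crm in self.crms:
            active = self.truth_crm_state[crm.id] == "active"
            if crm.id in hosted:
                cats["C" if active else "D"].append(crm)
            else:
                cats["B" if active else "A"].append(crm)
        noncrm_hosts = set()
        for pk in self.peaks:
            if self.truth_peak_category[pk.id] == "E":
                cats["E"].append(pk)
                host = self._host_of(pk)
                if host:
                    noncrm_hosts.add(host)
        for nc in self.noncrms:
            if nc.id not in noncrm_hosts:
                cats["F"].append(nc)
        return {c: IntervalSet(v) for c, v in cats.items()}

    def _host_of(self, peak: GenomicInterval) -> Optional[str]:
        pool = self.crms if self.truth_peak_category[peak.id] in "CD" else self.noncrms
        for el in pool.overlapping(peak):
            return el.id
        return None

    # -- persistence ----------------------------------------------------------
    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        self.genome.to_json(out / "genome.json")
        if self.sequences:
            write_fasta(self.sequences, out / "genome.fa")
        write_bed(self.crms, out / "crms.bed")
        write_bed(self.noncrms, out / "noncrms.bed")
        write_bed(self.peaks, out / "starr_peaks.bed")
        write_bed(self.active_crms(), out / "active_crms.bed")
        write_bed(self.nonactive_crms(), out / "nonactive_crms.bed")
        for name, track in self.tracks.items():
            track.write_bedgraph(out / f"{name}.bedgraph")
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        write_bed(
            IntervalSet(
                GenomicInterval(
                    h.interval.chrom, h.interval.start, h.interval.end, id=h.motif_id
                )
                for h in self.tfbs_hits
            ),
            out / "tfbs_hits.bed",
        )
        with open(out / "motif_network.tsv", "w") as fh:
            for a, b in self.network_edges:
                fh.write(f"{a}\t{b}\n")
        write_bed(IntervalSet(self.chromhmm), out / "chromhmm.bed")
        write_bed(IntervalSet(self.tes), out / "te.bed")
        pd.DataFrame(
            [(k, v) for k, v in sorted(self.truth_crm_state.items())],
            columns=["crm_id", "state"],
        ).to_csv(out / "truth" / "crm_state.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(k, v) for k, v in sorted(self.truth_peak_category.items())],
            columns=["peak_id", "category"],
        ).to_csv(out / "truth" / "peak_category.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(k, int(v)) for k, v in sorted(self.truth_gene_boosted.items())],
            columns=["gene_id", "boosted"],
        ).to_csv(out / "truth" / "gene_boosted.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_lengths(
    rng: np.random.Generator, n: int, mu: float, sigma: float, minimum: int
) -> np.ndarray:
    lengths = np.maximum(
        rng.lognormal(mean=mu, sigma=sigma, size=n).astype(np.int64), minimum
    )
    return lengths


def _place_elements(
    rng: np.random.Generator, cfg: ScenarioConfig, genome: GenomeSpec
) -> Tuple[IntervalSet, IntervalSet]:
    """Tile each analyzable span with alternating non-CRM gaps and CRMs."""
    mu = np.log(cfg.crm_length_mean) - cfg.crm_length_sigma**2 / 2
    crm_lengths = _draw_lengths(rng, cfg.crm_count, mu, cfg.crm_length_sigma, cfg.crm_length_min)
    analyzable_total = genome.total_analyzable()
    gap_mass = analyzable_total - int(crm_lengths.sum())
    if gap_mass <= cfg.crm_count * 50:
        raise ValueError("infeasible packing: requested CRM mass leaves no room for non-CRMs")
    crms: List[GenomicInterval] = []
    gaps: List[Tuple[str, int, int]] = []
    # the shrinking safety factor leaves slack at chromosome ends so random
    # gap draws cannot overrun the genome before every CRM is placed
    for safety in (0.85, 0.6, 0.4, 0.2, 0.05):
        crms.clear()
        gaps.clear()
        mean_gap = safety * gap_mass / (cfg.crm_count + cfg.n_chroms)
        li = 0
        for region in genome.analyzable_regions:
            pos = region.start
            while li < len(crm_lengths):
                gap = int(mean_gap * rng.uniform(0.3, 1.7))
                length = int(crm_lengths[li])
                if pos + gap + length > region.end:
                    break
                if gap > 0:
                    gaps.append((region.chrom, pos, pos + gap))
                start = pos + gap
                crms.append(
                    GenomicInterval(region.chrom, start, start + length, id=f"crm_{li:05d}")
                )
                pos = start + length
                li += 1
            if pos < region.end:
                gaps.append((region.chrom, pos, region.end))
        if li == len(crm_lengths):
            break
    else:
        raise ValueError(
            f"infeasible packing: placed only {li}/{cfg.crm_count} CRMs"
        )

    # split gaps into non-CRM elements
    nc_mu = np.log(cfg.noncrm_piece_median)
    noncrms: List[GenomicInterval] = []
    k = 0
    for chrom, g0, g1 in gaps:
        pos = g0
        while pos < g1:
            piece = int(rng.lognormal(nc_mu, 0.5))
            piece = max(piece, 200)
            end = min(pos + piece, g1)
            if g1 - end < 200:  # absorb a short remainder
                end = g1
            noncrms.append(GenomicInterval(chrom, pos, end, id=f"ncr_{k:05d}"))
            pos = end
            k += 1
    return IntervalSet(crms), IntervalSet(noncrms)


def _mix_counts(
    rng: np.random.Generator,
    cfg: ScenarioConfig,
    n_active: int,
    n_nonactive: int,
    n_noncrm: int,
) -> Dict[str, int]:
    mix = dict(zip("CDE", cfg.peak_category_mix))
    counts = {c: int(round(mix[c] * cfg.peak_count)) for c in "CDE"}
    counts["E"] = cfg.peak_count - counts["C"] - counts["D"]
    avail = {"C": n_active, "D": n_nonactive, "E": n_noncrm}
    shortfall = 0
    for c in "CD":
        if counts[c] > avail[c]:
            if cfg.on_infeasible_mix == "error":
                raise ValueError(
                    f"cannot host {counts[c]} category-{c} peaks with only "
                    f"{avail[c]} candidate host elements"
                )
            shortfall += counts[c] - avail[c]
            counts[c] = avail[c]
    counts["E"] += shortfall
    if counts["E"] > avail["E"]:
        raise ValueError("not enough non-CRM elements to host E-like peaks")
    return counts


def _gaussian_bump(n: int, amplitude: float, rel_sigma: float) -> np.ndarray:
    x = np.arange(n) - (n - 1) / 2.0
    sigma = max(n * rel_sigma, 1.0)
    return amplitude * np.exp(-(x**2) / (2 * sigma**2))


def generate_scenario(
    config: ScenarioConfig, out_dir: Optional[str | Path] = None
) -> SyntheticBundle:
    """Generate a complete scenario; write all files when ``out_dir`` given."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # -- genome ---------------------------------------------------------------
    chrom_sizes = {f"chr{i+1}": cfg.chrom_length for i in range(cfg.n_chroms)}
    margin = int(cfg.chrom_length * cfg.margin_fraction)
    genome = GenomeSpec(
        chrom_sizes=chrom_sizes,
        analyzable_regions=IntervalSet(
            GenomicInterval(c, 0, n - margin) if margin else GenomicInterval(c, 0, n)
            for c, n in chrom_sizes.items()
        ),
    )

    sequences: Dict[str, str] = {}
    if cfg.with_sequence:
        base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        for chrom, size in chrom_sizes.items():
            block = 1000
            n_blocks = (size + block - 1) // block
            frac = (np.arange(n_blocks) + 0.5) / n_blocks
            p_gc = np.clip(cfg.gc_level + cfg.gc_gradient * (frac - 0.5), 0.05, 0.95)
            per_base_pgc = np.repeat(p_gc, block)[:size]
            u = rng.random(size)
            is_gc = u < per_base_pgc
            u2 = rng.random(size)
            codes = np.where(is_gc, np.where(u2 < 0.5, 1, 2), np.where(u2 < 0.5, 0, 3))
            sequences[chrom] = base_lut[codes].tobytes().decode("ascii")

    # -- elements -------------------------------------------------------------
    crms, noncrms = _place_elements(rng, cfg, genome)
    active_mask = rng.random(len(crms)) < cfg.active_fraction
    truth_state = {
        crm.id: ("active" if active_mask[i] else "non-active")
        for i, crm in enumerate(crms)
    }
    active_ids = [c.id for c in crms if truth_state[c.id] == "active"]
    nonactive_ids = [c.id for c in crms if truth_state[c.id] == "non-active"]

    # -- peaks ----------------------------------------------------------------
    counts = _mix_counts(rng, cfg, len(active_ids), len(nonactive_ids), len(noncrms))
    by_id = {c.id: c for c in crms}
    by_id.update({n.id: n for n in noncrms})
    # the trailing gap of each chromosome is reserved for margin-straddling
    # peaks so no two peaks can overlap
    a_end = cfg.chrom_length - margin
    trailing = {
        n.chrom: n for n in noncrms if n.end == a_end and n.length() >= cfg.peak_length_min
    }
    n_out = int(round(cfg.out_of_region_fraction * counts["E"]))
    straddle_hosts = (
        [trailing[c] for c in sorted(trailing)][:n_out] if margin > 0 else []
    )
    reserved = {t.id for t in straddle_hosts}

    # hosts must fit a typical peak, or clipping deflates the E base share
    eligible_nc = [
        n.id
        for n in noncrms
        if n.length() >= 1.2 * cfg.peak_length_median and n.id not in reserved
    ]

    host_ids: List[Tuple[str, str]] = []  # (category, host element id)
    n_regular_e = counts["E"] - len(straddle_hosts)
    for cat, pool, n_cat in (
        ("C", active_ids, counts["C"]),
        ("D", nonactive_ids, counts["D"]),
        ("E", eligible_nc, n_regular_e),
    ):
        chosen = rng.choice(len(pool), size=n_cat, replace=False)
        host_ids.extend((cat, pool[i]) for i in sorted(chosen))

    pk_mu = np.log(cfg.peak_length_median)
    peaks: List[GenomicInterval] = []
    truth_peak: Dict[str, str] = {}
    for k, (cat, hid) in enumerate(host_ids):
        host = by_id[hid]
        length = int(
            max(rng.lognormal(pk_mu, cfg.peak_length_sigma), cfg.peak_length_min)
        )
        pid = f"peak_{k:05d}"
        length = min(length, host.length())
        start = host.start + int(rng.integers(0, host.length() - length + 1))
        peaks.append(GenomicInterval(host.chrom, start, start + length, id=pid))
        truth_peak[pid] = cat
    for j, host in enumerate(straddle_hosts):
        # straddle the analyzable margin: part of the peak is unassessed
        length = int(
            max(rng.lognormal(pk_mu, cfg.peak_length_sigma), cfg.peak_length_min)
        )
        half = min(length // 2, margin)
        in_region = min(length - half, host.length())
        pid = f"peak_{len(host_ids) + j:05d}"
        peaks.append(
            GenomicInterval(host.chrom, a_end - in_region, a_end + half, id=pid)
        )
        truth_peak[pid] = "E"
    peak_set = IntervalSet(peaks)

    # -- tracks ---------------------------------------------------------------
    n_steps = {c: size // TRACK_STEP for c, size in chrom_sizes.items()}
    dense: Dict[str, Dict[str, np.ndarray]] = {
        name: {
            c: rng.gamma(cfg.noise_shape, cfg.noise_scale, size=n)
            for c, n in n_steps.items()
        }
        for name in list(MARKS) + ["input", "starr"]
    }
    dense["conservation"] = {
        c: rng.normal(0.0, 0.5, size=n) for c, n in n_steps.items()
    }

    def add_bump(track: str, el: GenomicInterval, amplitude: float, rel_sigma: float) -> None:
        if amplitude == 0.0:
            return
        s, e = el.start // TRACK_STEP, max(el.end // TRACK_STEP, el.start // TRACK_STEP + 1)
        e = min(e, n_steps[el.chrom])
        if e > s:
            dense[track][el.chrom][s:e] += _gaussian_bump(e - s, amplitude, rel_sigma)

    for crm in crms:
        cls = "active_crm" if truth_state[crm.id] == "active" else "nonactive_crm"
        for mark in MARKS:
            amp = cfg.mark_effects[mark].get(cls, 0.0)
            # chromatin accessibility is narrow; histone marks broad
            add_bump(mark, crm, amp, 0.125 if mark == "atac" else 0.3)
        if cfg.conservation_effect:
            s, e = crm.start // TRACK_STEP, crm.end // TRACK_STEP
            dense["conservation"][crm.chrom][s:e] += cfg.conservation_effect
    for pk in peaks:
        cat = truth_peak[pk.id]
        add_bump("starr", pk, cfg.starr_effects.get(cat, 0.0), 0.3)
        if cat == "E":
            for mark in MARKS:
                add_bump(mark, pk, cfg.mark_effects[mark].get("e_peak", 0.0), 0.3)

    tracks = {
        name: SignalTrack.from_dense(arrays, step=TRACK_STEP)
        for name, arrays in dense.items()
        if name != "conservation"
    }
    # conservation is signed (phyloP-like)
    tracks["conservation"] = SignalTrack.from_dense(
        dense["conservation"], step=TRACK_STEP, allow_negative=True
    )

    # -- genes / expression ---------------------------------------------------
    gene_hosts = rng.choice(len(noncrms), size=min(cfg.n_genes, len(noncrms)), replace=False)
    gene_rows = []
    base_tpms = []
    for j, hi in enumerate(sorted(gene_hosts)):
        host = list(noncrms)[hi]
        tss = int(rng.integers(host.start, host.end))
        gene_rows.append(
            {
                "gene_id": f"gene_{j:04d}",
                "chrom": host.chrom,
                "tss": tss,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        base_tpms.append(float(rng.lognormal(cfg.tpm_log_mean, cfg.tpm_log_sigma)))
    genes_df = pd.DataFrame(gene_rows)

    # the planted expression effect boosts the genes that active CRMs are
    # closest to — the association the audit later recovers
    from .association import GeneIndex, GeneRecord

    gindex = GeneIndex(
        GeneRecord(r["gene_id"], r["chrom"], r["tss"], r["strand"]) for r in gene_rows
    )
    boosted_ids = set()
    if cfg.expression_effect != 1.0:
        for aid in active_ids:
            gid = gindex.closest(by_id[aid])
            if gid is not None:
                boosted_ids.add(gid)
    truth_boost = {r["gene_id"]: r["gene_id"] in boosted_ids for r in gene_rows}
    expr_df = pd.DataFrame(
        {
            "gene_id": genes_df["gene_id"],
            "tpm": [
                t * cfg.expression_effect if truth_boost[g] else t
                for g, t in zip(genes_df["gene_id"], base_tpms)
            ],
        }
    )

    # -- motif network and TFBS hits -----------------------------------------
    motifs = [f"motif_{m:03d}" for m in range(cfg.n_motifs)]
    w = 1.0 / (np.arange(cfg.n_motifs) + 1.0)  # preferential: early motifs are hubs
    w /= w.sum()
    edges: List[Tuple[str, str]] = []
    seen = set()
    while len(edges) < cfg.n_network_edges:
        a, b = rng.choice(cfg.n_motifs, size=2, replace=False, p=w)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((motifs[key[0]], motifs[key[1]]))
    hub_pool = np.arange(cfg.n_motifs // 5)  # highest-degree motifs
    low_pool = np.arange(cfg.n_motifs // 2, cfg.n_motifs)
    all_pool = np.arange(cfg.n_motifs)

    hosted_crm = {hid for cat, hid in host_ids if cat in "CD"}
    hosted_nc = {hid for cat, hid in host_ids if cat == "E"}
    hits: List[TfbsHit] = []
    hk = 0

    def _plant_hits(el: GenomicInterval, rate: float, pool: np.ndarray) -> None:
        nonlocal hk
        n = int(rng.poisson(rate * el.length() / 1000.0))
        if n == 0:
            return
        starts = rng.integers(el.start, max(el.end - 10, el.start + 1), size=n)
        motif_idx = rng.choice(pool, size=n)
        for s, mi in zip(starts.tolist(), motif_idx.tolist()):
            hits.append(
                TfbsHit(
                    GenomicInterval(el.chrom, int(s), int(s) + 10, id=f"tfbs_{hk:06d}"),
                    motifs[int(mi)],
                )
            )
            hk += 1

    rates = cfg.tfbs_rates
    uniform_rates = len(set(rates.values())) == 1
    for crm in crms:
        if crm.id in hosted_crm and truth_state[crm.id] == "active":
            _plant_hits(crm, rates["c_like"], all_pool if uniform_rates else hub_pool)
        else:
            _plant_hits(crm, rates["other_crm"], all_pool)
    for nc in noncrms:
        if nc.id in hosted_nc:
            _plant_hits(nc, rates["e_like"], all_pool if uniform_rates else low_pool)
        else:
            _plant_hits(nc, rates["background"], all_pool if uniform_rates else low_pool)

    # -- ChromHMM-like segmentation and TEs ----------------------------------
    states = ["TssA", "Tx", "EnhA1", "EnhWk", "ReprPC", "ZNF/Rpts", "Quies"]
    state_p = np.array([0.03, 0.2, 0.05, 0.07, 0.1, 0.05, 0.5])
    state_p = state_p / state_p.sum()
    chromhmm: List[GenomicInterval] = []
    e_peaks = IntervalSet([p for p in peaks if truth_peak[p.id] == "E"])
    seg = 2000
    planted_het = cfg.mark_effects["h3k9me3"].get("e_peak", 0.0) > 0
    genome_bp = cfg.n_chroms * cfg.chrom_length
    het_target = 0.10  # genome-wide heterochromatin density
    e_frac = e_peaks.total_length() / genome_bp if planted_het else 0.0
    # tile rate solved so planted (0.6 inside E peaks) plus background tiles
    # (trimmed around E peaks) give the target genome-wide density
    het_bg = max((het_target - 0.6 * e_frac) / (1.0 - e_frac), 0.01) if planted_het else het_target
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, seg):
            e = min(s + seg, size)
            u = rng.random()
            if u < het_bg:
                # background heterochromatin, trimmed around planted E peaks
                if planted_het and e_peaks.overlap_bp(chrom, s, e) > 0:
                    pieces = IntervalSet([GenomicInterval(chrom, s, e)]).subtract(e_peaks)
                    chromhmm.extend(
                        GenomicInterval(p.chrom, p.start, p.end, id="Het") for p in pieces
                    )
                else:
                    chromhmm.append(GenomicInterval(chrom, s, e, id="Het"))
            else:
                chromhmm.append(
                    GenomicInterval(chrom, s, e, id=states[int(rng.choice(len(states), p=state_p))])
                )
    if planted_het:
        # plant Het over the central 60% of every E-like peak
        for pk in e_peaks:
            ln = pk.length()
            pad = int(round(ln * 0.2))
            if ln - 2 * pad > 0:
                chromhmm.append(
                    GenomicInterval(pk.chrom, pk.start + pad, pk.end - pad, id="Het")
                )

    te_classes = ["LINE", "SINE", "LTR", "DNA"]
    tes: List[GenomicInterval] = []
    tk = 0
    for chrom, size in chrom_sizes.items():
        n_te = size // 8000
        starts = np.sort(rng.integers(0, size - 300, size=n_te))
        for s in starts.tolist():
            cls = te_classes[int(rng.integers(0, len(te_classes)))]
            tes.append(GenomicInterval(chrom, int(s), int(s) + 300, id=cls))
            tk += 1
    if planted_het:
        for pk in e_peaks:  # LTR excess inside E-like peaks
            if rng.random() < 0.5 and pk.length() >= 320:
                s = pk.start + int(rng.integers(0, pk.length() - 300))
                tes.append(GenomicInterval(pk.chrom, s, s + 300, id="LTR"))

    bundle = SyntheticBundle(
        config=cfg,
        genome=genome,
        sequences=sequences,
        crms=crms,
        noncrms=noncrms,
        peaks=peak_set,
        truth_crm_state=truth_state,
        truth_peak_category=truth_peak,
        truth_gene_boosted=truth_boost,
        tracks=tracks,
        genes=genes_df,
        expression=expr_df,
        tfbs_hits=hits,
        network_edges=edges,
        chromhmm=chromhmm,
        tes=tes,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def generate_null_scenario(
    config: Optional[ScenarioConfig] = None, out_dir: Optional[str | Path] = None, **overrides
) -> SyntheticBundle:
    """Same geometry, no planted effects: marks, expression, conservation,
    TFBS rates and annotation statistics are identical across categories."""
    cfg = dataclasses.replace(config) if config is not None else ScenarioConfig()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    zero = {m: {"active_crm": 0.0, "nonactive_crm": 0.0, "e_peak": 0.0} for m in MARKS}
    cfg.mark_effects = zero
    cfg.starr_effects = {"C": 0.0, "D": 0.0, "E": 0.0}
    cfg.expression_effect = 1.0
    cfg.conservation_effect = 0.0
    rate = _default_tfbs_rates()["background"]
    cfg.tfbs_rates = {k: rate for k in _default_tfbs_rates()}
    return generate_scenario(cfg, out_dir=out_dir)
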