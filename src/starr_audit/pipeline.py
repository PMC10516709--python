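"""End-to-end audit orchestration for one or many samples.

Composes the stages — preprocess → functional-state calling (or oracle
labels) → base-level partition → per-category metrics → enrichment →
expression association → signal profiles — into a machine-readable
:class:`AuditReport`. Every threshold and seed used is logged; reruns with
the same inputs and config are bit-identical.

Pooling across samples is the unweighted mean of per-sample ratios (the
mean-percentage convention); base-weighted pooling is available behind a
flag. Pooled distribution analyses concatenate per-sample values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .association import GeneIndex, GeneRecord, category_expression, pairwise_tests
from .enrichment import MatchSpec, sample_matched, state_enrichment
from .genomic_core import GenomeSpec, IntervalSet
from .metrics import HitIndex, MotifNetwork, element_table
from .partition import (
    CATEGORIES,
    PartitionResult,
    containment_class,
    cross_sample_activity,
    match_peaks_to_crms,
    partition_genome,
)
from .synthetic_data import SyntheticBundle

logger = logging.getLogger("starr_audit")

__all__ = ["RunConfig", "AuditReport", "run_audit", "audit_bundle", "summarize_across_samples"]


@dataclass
class RunConfig:
    sample_id: str = "sample"
    overlap_threshold: float = 0.5
    promoter_max_dist: int = 1000
    state_threshold: float = 0.5
    n_background_draws: int = 10
    seed: int = 0
    out_dir: Optional[str] = None


@dataclass
class AuditReport:
    sample_id: str
    base_counts: Dict[str, int]
    unassessed_peak_bases: int
    ratios: Dict[str, float]
    containment: Dict[str, float]  # % of matched peaks with full/partial CRM
    enrichment_chromhmm: Optional[object] = None  # DataFrame
    enrichment_te: Optional[object] = None  # DataFrame
    expression_tests: Optional[object] = None  # DataFrame
    category_expression_medians: Dict[str, float] = field(default_factory=dict)
    element_metrics: Optional[object] = None  # DataFrame

    def check_self_consistency(self) -> None:
        """Every derived ratio must re-derive from base_counts (tol 1e-12)."""
        recomputed = PartitionResult(
            sample_id=self.sample_id,
            base_counts=self.base_counts,
            unassessed_peak_bases=self.unassessed_peak_bases,
            label_track=[],
        ).ratios()
        for key, val in self.ratios.items():
            ref = recomputed[key]
            if np.isnan(val) and np.isnan(ref):
                continue
            assert abs(val - ref) <= 1e-12, f"ratio {key} inconsistent"

    def to_json_dict(self) -> Dict:
        return {
            "sample_id": self.sample_id,
            "base_counts": self.base_counts,
            "unassessed_peak_bases": self.unassessed_peak_bases,
            "ratios": self.ratios,
            "containment": self.containment,
            "category_expression_medians": self.category_expression_medians,
        }


def _containment_stats(pairs) -> Dict[str, float]:
    if not pairs:
        return {"full_pct": float("nan"), "partial_pct": float("nan"), "n_pairs": 0}
    full = sum(1 for pk, crm in pairs if containment_class(pk, crm) == "full")
    return {
        "full_pct": 100.0 * full / len(pairs),
        "partial_pct": 100.0 * (len(pairs) - full) / len(pairs),
        "n_pairs": len(pairs),
    }


def audit_bundle(
    bundle: SyntheticBundle,
    config: Optional[RunConfig] = None,
    use_oracle_states: bool = True,
    with_enrichment: bool = True,
    with_metrics: bool = True,
) -> AuditReport:
    """Run the audit on an in-memory scenario.

    ``use_oracle_states`` takes the generator's planted CRM states; set
    False to call states with a UFSP model trained on the planted labels
    (a self-training sanity path — real use supplies an external model).
    """
    cfg = config or RunConfig()
    logger.info(
        "audit sample=%s overlap=%.2f seed=%d", cfg.sample_id, cfg.overlap_threshold, cfg.seed
    )

    if use_oracle_states:
        active = bundle.active_crms()
        nonactive = bundle.nonactive_crms()
    else:
        from .functional_state import extract_feature_matrix, ufsp_predict, ufsp_train

        marks = {m: bundle.tracks[m] for m in ("atac", "h3k4me1", "h3k4me3", "h3k27ac")}
        ids, X = extract_feature_matrix(list(bundle.crms), marks, bundle.tracks["input"])
        labels = np.array(
            [bundle.truth_crm_state[i] == "active" for i in ids], dtype=bool
        )
        model = ufsp_train(X[labels], X[~labels], threshold=cfg.state_threshold)
        calls = {c.element_id: c.state for c in ufsp_predict(model, ids, X)}
        active = IntervalSet([c for c in bundle.crms if calls[c.id] == "active"])
        nonactive = IntervalSet([c for c in bundle.crms if calls[c.id] == "non-active"])

    part = partition_genome(
        bundle.genome,
        active,
        nonactive,
        bundle.noncrms,
        bundle.peaks,
        sample_id=cfg.sample_id,
        reciprocal_threshold=cfg.overlap_threshold,
    )

    pairs = match_peaks_to_crms(
        bundle.peaks,
        IntervalSet(list(active) + list(nonactive)),
        cfg.overlap_threshold,
    )
    containment = _containment_stats(pairs)

    cats = bundle.category_elements()
    genes = GeneIndex(
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            expression=float(e),
        )
        for r, e in zip(bundle.genes.itertuples(), bundle.expression["tpm"])
    )
    expr = category_expression(cats, genes)
    tests = pairwise_tests(expr, test="mwu")
    medians = {
        c: (float(np.median(v)) if len(v) else float("nan")) for c, v in expr.items()
    }

    enrich_hmm = enrich_te = None
    if with_enrichment:
        e_peaks = cats["E"]
        if len(e_peaks):
            spec = MatchSpec.from_templates(
                e_peaks, n_draws=cfg.n_background_draws, seed=cfg.seed
            )
            draws = sample_matched(bundle.genome, spec)
            enrich_hmm = state_enrichment(e_peaks, bundle.chromhmm, draws, mode="length")
            enrich_te = state_enrichment(e_peaks, bundle.tes, draws, mode="count")

    metrics_df = None
    if with_metrics:
        cat_of: Dict[str, str] = {}
        elements = []
        for c in CATEGORIES:
            for el in cats[c]:
                cat_of[el.id] = c
                elements.append(el)
        metrics_df = element_table(
            IntervalSet(elements),
            cat_of,
            HitIndex(bundle.tfbs_hits),
            bundle.network,
            sequences=bundle.sequences or None,
            starr_signal=bundle.tracks["starr"],
            input_track=bundle.tracks["input"],
        )

    report = AuditReport(
        sample_id=cfg.sample_id,
        base_counts=part.base_counts,
        unassessed_peak_bases=part.unassessed_peak_bases,
        ratios=part.ratios(),
        containment=containment,
        enrichment_chromhmm=enrich_hmm,
        enrichment_te=enrich_te,
        expression_tests=tests,
        category_expression_medians=medians,
        element_metrics=metrics_df,
    )
    report.check_self_consistency()
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{cfg.sample_id}.report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1)
        )
        for name, df in (
            ("chromhmm_enrichment", enrich_hmm),
            ("te_enrichment", enrich_te),
            ("expression_tests", tests),
            ("element_metrics", metrics_df),
        ):
            if df is not None:
                df.to_csv(out / f"{cfg.sample_id}.{name}.tsv", sep="\t", index=False)
    return report


def run_audit(
    bundles: Sequence[SyntheticBundle],
    config: Optional[RunConfig] = None,
    **kwargs,
) -> List[AuditReport]:
    """Audit several samples (bundles) with one config; per-sample ids are
    suffixed with the bundle index."""
    cfg = config or RunConfig()
    reports = []
    for i, bundle in enumerate(bundles):
        sub = dataclasses.replace(cfg, sample_id=f"{cfg.sample_id}{i}")
        reports.append(audit_bundle(bundle, sub, **kwargs))
    return reports


def summarize_across_samples(
    reports: Sequence[AuditReport], base_weighted: bool = False
) -> Dict[str, float]:
    """Unweighted mean of each ratio across samples (default), or a
    base-weighted pooled recomputation."""
    if not reports:
        raise ValueError("need at least one report")
    if base_weighted:
        totals = {c: sum(r.base_counts[c] for r in reports) for c in CATEGORIES}
        pooled = PartitionResult(
            sample_id="pooled",
            base_counts=totals,
            unassessed_peak_bases=sum(r.unassessed_peak_bases for r in reports),
            label_track=[],
        )
        return pooled.ratios()
    keys = reports[0].ratios.keys()
    return {
        k: float(np.mean([r.ratios[k] for r in reports])) for k in keys
    }
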