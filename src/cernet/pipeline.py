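"""End-to-end orchestration: simulate -> preprocess -> differential ->
reference filter -> correlation network -> nine-quadrant -> enrichment.

:func:`run_analysis` executes every stage in memory and returns an
:class:`AnalysisResult`; :func:`run_all` additionally writes each stage's
intermediate TSV plus a ``manifest.json`` (config echo, per-stage counts,
seed, version) into the output directory so any stage can be inspected or
re-run in isolation. Identical config and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dataio import (
    ExpressionMatrix,
    write_edge_list,
    write_expression_matrix,
    write_sample_sheet,
)
from .differential import (
    classify_de,
    differential_methylation,
    results_to_frame,
    significant_ids,
    student_t_de,
)
from .enrichment import (
    gsea_to_frame,
    guilt_by_association,
    ora_batch,
    ora_to_frame,
)
from .correlation_network import (
    PAIR_LNCRNA_MRNA,
    PAIR_MIRNA_LNCRNA,
    PAIR_MIRNA_MRNA,
    assemble_cerna_triads,
    intersect_with_predictions,
    pairs_to_frame,
    pearson_pairs,
    threshold_pairs,
    triads_to_frame,
)
from .methylation_integration import (
    nine_quadrant,
    quadrant_counts,
    select_hypomethylated_upregulated,
)
from .preprocess import filter_probes, quantile_normalize
from .reference_filter import filter_cohort_specific, paired_reference_test
from .synthetic_data import (
    SimulationConfig,
    simulate_cohort,
    simulate_gene_sets,
    simulate_reference_pairs,
    simulate_target_database,
)

logger = logging.getLogger("cernet")

EXPRESSION_LAYERS = ("mRNA", "miRNA", "lncRNA")


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a single run seed out to per-stage seeds via a fixed name hash."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (global_seed & 0x7FFFFFFF)) % (2 ** 31)


@dataclass
class RunConfig:
    """One run's thresholds and simulation conditions; unknown keys rejected."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str = "cernet_run"
    seed: int = 0
    adj_p_max: float = 0.05
    min_fold_change: float = 2.0
    min_delta_beta: float = 0.2
    min_detection: float = 0.60
    already_normalized: bool = True
    moderated: bool = False
    pair_r_cut: float = 0.5
    pair_alpha: float = 0.05
    pair_alpha_on: str = "p"
    require_lncrna_mrna_edge: bool = False
    decoy_fraction: float = 0.3
    n_perm: int = 1000
    weight_p: float = 1.0
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.adj_p_max <= 1) or not (0 < self.pair_alpha <= 1):
            raise ValueError("alpha thresholds must lie in (0, 1]")
        if self.min_fold_change < 1:
            raise ValueError("min_fold_change must be >= 1")
        if not (0 <= self.pair_r_cut < 1):
            raise ValueError("pair_r_cut must lie in [0, 1)")
        if self.pair_alpha_on not in ("p", "fdr"):
            raise ValueError("pair_alpha_on must be 'p' or 'fdr'")
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known_sim = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim) - known_sim
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=SimulationConfig(**sim), **d)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    counts: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class AnalysisResult:
    """Everything one run computed, keyed for downstream inspection."""

    cohort: object
    reference: ExpressionMatrix
    reference_sheet: object
    predictions: object
    collection: object
    layers: dict
    de: dict
    dm: list
    kept: dict
    pairs: dict          # pair_type -> thresholded (+ intersected) pairs
    triads: list
    assignments: list
    hypo_up: list
    ora: list
    gba: list
    counts: dict


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Execute every stage on a simulated cohort, in memory."""
    counts: dict = {}
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.simulation)
        reference, ref_sheet = simulate_reference_pairs(config.simulation)
        predictions = simulate_target_database(
            cohort.truth, config.simulation, decoy_fraction=config.decoy_fraction)
        collection = simulate_gene_sets(
            cohort.truth, config.simulation,
            seed=stage_seed(config.seed, "gene_sets"))
        counts["simulate"] = {
            "n_samples": cohort.mrna.n_samples,
            "features": {layer: cohort.layer(layer).n_features
                         for layer in EXPRESSION_LAYERS + ("methylation",)},
            "predictions": len(predictions),
            "gene_sets": len(collection),
        }

        stage = "preprocess"
        layers: dict[str, ExpressionMatrix] = {}
        for layer in EXPRESSION_LAYERS:
            filtered = filter_probes(cohort.layer(layer), None, cohort.annotation,
                                     min_detection=config.min_detection)
            # the generator emits post-normalization log2 intensities, so
            # re-normalizing is skipped unless explicitly requested
            layers[layer] = (filtered if config.already_normalized
                             else quantile_normalize(filtered))
        counts["preprocess"] = {layer: layers[layer].n_features
                                for layer in EXPRESSION_LAYERS}

        stage = "differential"
        de: dict[str, list] = {}
        for layer in EXPRESSION_LAYERS:
            raw = student_t_de(layers[layer], cohort.samples,
                               moderated=config.moderated)
            de[layer] = classify_de(raw, adj_p_max=config.adj_p_max,
                                    min_fold_change=config.min_fold_change)
        dm = differential_methylation(cohort.methylation, cohort.samples,
                                      adj_p_max=config.adj_p_max,
                                      min_delta_beta=config.min_delta_beta,
                                      moderated=config.moderated)
        counts["differential"] = {
            layer: {"tested": len(de[layer]),
                    "significant": len(significant_ids(de[layer]))}
            for layer in EXPRESSION_LAYERS
        }
        counts["differential"]["methylation"] = {
            "tested": len(dm), "significant": len(significant_ids(dm))}

        stage = "reference_filter"
        ref_results = paired_reference_test(reference, ref_sheet)
        kept = {layer: filter_cohort_specific(de[layer], ref_results)
                for layer in EXPRESSION_LAYERS}
        counts["reference_filter"] = {
            layer: {"before": len(significant_ids(de[layer])),
                    "after": len(kept[layer])}
            for layer in EXPRESSION_LAYERS
        }

        stage = "network"
        def subset(layer: str) -> ExpressionMatrix | None:
            return layers[layer].subset_features(kept[layer]) if kept[layer] else None

        mirna_m, mrna_m, lncrna_m = subset("miRNA"), subset("mRNA"), subset("lncRNA")
        sample_order = cohort.samples.sample_ids

        def correlate(a, b, pair_type):
            if a is None or b is None:
                return []
            return pearson_pairs(a, b, pair_type, sample_ids=sample_order)

        thr = dict(alpha=config.pair_alpha, r_cut=config.pair_r_cut,
                   alpha_on=config.pair_alpha_on)
        mm_thr = threshold_pairs(correlate(mirna_m, mrna_m, PAIR_MIRNA_MRNA),
                                 PAIR_MIRNA_MRNA, **thr)
        ml_thr = threshold_pairs(correlate(mirna_m, lncrna_m, PAIR_MIRNA_LNCRNA),
                                 PAIR_MIRNA_LNCRNA, **thr)
        lm_thr = threshold_pairs(correlate(lncrna_m, mrna_m, PAIR_LNCRNA_MRNA),
                                 PAIR_LNCRNA_MRNA, **thr)
        mm_pred = intersect_with_predictions(list(mm_thr), predictions)
        ml_pred = intersect_with_predictions(list(ml_thr), predictions)
        triads = assemble_cerna_triads(
            mm_pred, ml_pred, lm_thr,
            require_lncrna_mrna_edge=config.require_lncrna_mrna_edge)
        counts["network"] = {
            "pairs_thresholded": {"mirna_mrna": len(mm_thr),
                                  "mirna_lncrna": len(ml_thr),
                                  "lncrna_mrna": len(lm_thr)},
            "pairs_predicted": {"mirna_mrna": len(mm_pred),
                                "mirna_lncrna": len(ml_pred)},
            "triads": len(triads),
        }

        stage = "quadrant"
        assignments = nine_quadrant(dm, de["mRNA"])
        hypo_up = select_hypomethylated_upregulated(assignments)
        counts["quadrant"] = {
            "matched_genes": len(assignments),
            "counts": {str(q): n for q, n in quadrant_counts(assignments).items()},
            "hypo_up": hypo_up,
        }

        stage = "enrichment"
        ora = []
        gba = []
        if config.run_enrichment:
            universe = layers["mRNA"].feature_ids
            query = sorted(kept["mRNA"])
            if query:
                ora = ora_batch(query, collection, universe)
            counts["enrichment"] = {
                "ora_sets": len(ora),
                "ora_significant": sum(r.adj_p < config.adj_p_max for r in ora),
            }
            if cohort.truth.triads:
                hub = cohort.truth.triads[0][1]  # a planted miRNA
                gba = guilt_by_association(
                    hub, layers["miRNA"], layers["mRNA"], collection,
                    n_perm=config.n_perm, weight_p=config.weight_p,
                    seed=stage_seed(config.seed, "gba"))
                counts["enrichment"]["gba_hub"] = hub
                counts["enrichment"]["gba_sets"] = len(gba)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return AnalysisResult(
        cohort=cohort, reference=reference, reference_sheet=ref_sheet,
        predictions=predictions, collection=collection, layers=layers,
        de=de, dm=dm, kept=kept,
        pairs={"mirna_mrna": mm_pred, "mirna_lncrna": ml_pred,
               "lncrna_mrna": lm_thr},
        triads=triads, assignments=assignments, hypo_up=hypo_up,
        ora=ora, gba=gba, counts=counts,
    )


def run_all(config: RunConfig, write_outputs: bool = True) -> RunManifest:
    """Run the full analysis; optionally write all intermediates + manifest.

    Any stage error aborts with the stage named; partial outputs stay on
    disk next to a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    try:
        result = run_analysis(config)
    except RuntimeError as exc:
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(str(exc) + "\n")
        raise
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed,
                           version=__version__, counts=result.counts)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(result, outdir)
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _write_outputs(result: AnalysisResult, outdir: Path) -> None:
    import pandas as pd

    cohort = result.cohort
    for layer in EXPRESSION_LAYERS + ("methylation",):
        write_expression_matrix(cohort.layer(layer), outdir / f"{layer}.tsv")
    write_expression_matrix(result.reference, outdir / "reference.tsv")
    write_sample_sheet(cohort.samples, outdir / "samples.tsv")
    write_sample_sheet(result.reference_sheet, outdir / "reference_samples.tsv")
    result.predictions.table.to_csv(outdir / "predictions.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    (outdir / "truth.json").write_text(cohort.truth.to_json() + "\n")
    for layer in EXPRESSION_LAYERS:
        results_to_frame(result.de[layer]).to_csv(
            outdir / f"de_{layer}.tsv", sep="\t", index=False, lineterminator="\n")
    results_to_frame(result.dm).to_csv(outdir / "dm_methylation.tsv", sep="\t",
                                       index=False, lineterminator="\n")
    all_pairs = (result.pairs["mirna_mrna"] + result.pairs["mirna_lncrna"]
                 + result.pairs["lncrna_mrna"])
    pairs_to_frame(all_pairs).to_csv(outdir / "pairs.tsv", sep="\t",
                                     index=False, lineterminator="\n")
    triads_to_frame(result.triads).to_csv(outdir / "triads.tsv", sep="\t",
                                          index=False, lineterminator="\n")
    write_edge_list(all_pairs, outdir / "edges.tsv")
    pd.DataFrame([a.__dict__ for a in result.assignments]).to_csv(
        outdir / "quadrants.tsv", sep="\t", index=False, lineterminator="\n")
    if result.ora:
        ora_to_frame(result.ora).to_csv(outdir / "ora.tsv", sep="\t",
                                        index=False, lineterminator="\n")
    if result.gba:
        gsea_to_frame(result.gba).to_csv(outdir / "gba.tsv", sep="\t",
                                         index=False, lineterminator="\n")
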