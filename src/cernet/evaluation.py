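"""Planted-truth evaluation harness.

Runs the full pipeline across replicate synthetic cohorts and scores what it
recovered against the ground truth the generator planted: ceRNA-triad
recall, tissue-confound removal, collateral loss of true differential
features, and hypomethylated-upregulated gene recovery. Also provides the
global-null calibration checks (type-I error of the differential screen,
uniformity of GSEA permutation p-values).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataio import GeneSetCollection
from .differential import significant_ids
from .enrichment import RankedList, gsea_permutation
from .pipeline import RunConfig, run_analysis
from .synthetic_data import SimulationConfig, simulate_cohort


def evaluate_recovery(base_config: RunConfig | None = None,
                      n_seeds: int = 20, seed_offset: int = 0) -> dict:
    """Score the full pipeline against planted truth over replicate cohorts.

    Returns per-seed lists and their means:

    * ``triad_recall`` — fraction of planted triads present in the output;
    * ``unsupported_false_triads`` — triads emitted without prediction
      support on either edge (structurally impossible; counted as a check);
    * ``confound_removal`` — fraction of planted tissue-confounded features,
      among those called differential, that the reference filter removed;
    * ``collateral_loss`` — fraction of planted true DE features, among
      those called differential, lost to the reference filter;
    * ``hypo_up_recovered`` — per seed, whether every planted
      hypomethylated-upregulated gene was returned by the quadrant selector.
    """
    base = base_config or RunConfig(outdir="unused")
    triad_recall, unsupported, removal, collateral, hypo_hits = [], [], [], [], []
    for i in range(n_seeds):
        seed = seed_offset + i
        cfg = dataclasses.replace(base, seed=seed, run_enrichment=False)
        res = run_analysis(cfg)
        truth = res.cohort.truth
        found = {(t.lncrna_id, t.mirna_id, t.mrna_id) for t in res.triads}
        if truth.triads:
            triad_recall.append(
                len(set(truth.triads) & found) / len(truth.triads))
        unsupported.append(sum(
            1 for t in res.triads
            if not (t.mirna_mrna_edge.predicted and t.mirna_lncrna_edge.predicted)))
        kept_all = set().union(*res.kept.values())
        called_all = set().union(
            *[significant_ids(res.de[layer]) for layer in res.de])
        confounded_called = truth.all_confounded() & called_all
        if confounded_called:
            removal.append(
                1 - len(confounded_called & kept_all) / len(confounded_called))
        true_de = {f for layer in truth.de_features.values() for f in layer}
        true_called = true_de & called_all
        if true_called:
            collateral.append(len(true_called - kept_all) / len(true_called))
        hypo_hits.append(set(truth.hypo_up_genes) <= set(res.hypo_up))
    return {
        "n_seeds": n_seeds,
        "triad_recall": triad_recall,
        "triad_recall_mean": float(np.mean(triad_recall)) if triad_recall else float("nan"),
        "unsupported_false_triads_total": int(np.sum(unsupported)),
        "confound_removal": removal,
        "confound_removal_mean": float(np.mean(removal)) if removal else float("nan"),
        "collateral_loss": collateral,
        "collateral_loss_mean": float(np.mean(collateral)) if collateral else float("nan"),
        "hypo_up_recovered": hypo_hits,
        "hypo_up_recovery_rate": float(np.mean(hypo_hits)) if hypo_hits else float("nan"),
    }


def null_simulation_config() -> SimulationConfig:
    """A cohort with no planted signal of any kind (the global null)."""
    return SimulationConfig(
        n_case=10, n_control=10, n_mrna=100, n_mirna=4, n_lncrna=4,
        n_cpg_genes=4, n_planted_de=0, n_planted_triads=0,
        n_planted_hypo_up=0, n_confounded=0)


def evaluate_null_calibration(n_seeds: int = 50, seed_offset: int = 0) -> dict:
    """Type-I error of the differential screen under the global null.

    Returns the pooled fraction of raw p-values below 0.05 (nominally 5%)
    and the pooled fraction of features called significant after BH and
    fold-change thresholds (nominally ~0).
    """
    from .differential import classify_de, student_t_de

    base = null_simulation_config()
    n_raw = n_called = n_total = 0
    for i in range(n_seeds):
        cohort = simulate_cohort(dataclasses.replace(base, seed=seed_offset + i))
        results = student_t_de(cohort.mrna, cohort.samples)
        n_raw += sum(r.p < 0.05 for r in results)
        n_called += len(significant_ids(classify_de(results)))
        n_total += len(results)
    return {
        "n_features_tested": n_total,
        "raw_p_below_05_fraction": n_raw / n_total,
        "bh_called_fraction": n_called / n_total,
    }


def evaluate_gsea_null_uniformity(n_reps: int = 50, n_genes: int = 100,
                                  set_size: int = 10, n_perm: int = 500,
                                  seed_offset: int = 0) -> dict:
    """Rejection rate of GSEA for random sets on random rankings.

    With uniform p-values the fraction below 0.05 should sit near the
    nominal level (the add-one permutation correction is mildly
    conservative).
    """
    n_sig = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed_offset + rep)
        ids = [f"g{i}" for i in range(n_genes)]
        ranked = RankedList.from_scores(dict(zip(ids, rng.normal(size=n_genes))))
        members = list(rng.choice(ids, size=set_size, replace=False))
        coll = GeneSetCollection({"rand": ("null set", members)})
        (res,) = gsea_permutation(ranked, coll, n_perm=n_perm,
                                  seed=seed_offset + rep)
        n_sig += res.p < 0.05
    return {"n_reps": n_reps, "gsea_rejection_rate_at_05": n_sig / n_reps}
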