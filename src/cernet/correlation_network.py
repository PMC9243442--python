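"""Cross-layer correlation pairs, prediction intersection, and ceRNA triads.

The competing-endogenous-RNA model predicts a specific sign pattern: a lncRNA
that sponges a miRNA de-represses that miRNA's mRNA targets, so across
samples miRNA–mRNA and miRNA–lncRNA correlations are negative while the
lncRNA–mRNA correlation is positive. This module computes pooled-sample
Pearson correlations between layers, keeps strong pairs, intersects the
miRNA-anchored pairs with a target-prediction table, and enumerates the
(lncRNA, miRNA, mRNA) triads consistent with sponging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, TargetPredictionTable
from .differential import bh_adjust

logger = logging.getLogger("cernet")

PAIR_MIRNA_MRNA = "mirna_mrna"
PAIR_MIRNA_LNCRNA = "mirna_lncrna"
PAIR_LNCRNA_MRNA = "lncrna_mrna"
PAIR_TYPES = (PAIR_MIRNA_MRNA, PAIR_MIRNA_LNCRNA, PAIR_LNCRNA_MRNA)


@dataclass
class CorrelationPair:
    source_id: str
    target_id: str
    pair_type: str
    r: float
    p: float
    fdr: float = float("nan")
    predicted: bool = False


@dataclass
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    mirna_mrna_edge: CorrelationPair = field(repr=False, default=None)
    mirna_lncrna_edge: CorrelationPair = field(repr=False, default=None)
    lncrna_mrna_edge: CorrelationPair | None = field(repr=False, default=None)


def pearson_pairs(matA: ExpressionMatrix, matB: ExpressionMatrix,
                  pair_type: str, sample_ids: list[str] | None = None
                  ) -> list[CorrelationPair]:
    """All-vs-all Pearson correlations between two layers, pooled over samples.

    Correlations are computed across every shared sample (cases and controls
    together). The p-value is the exact two-sided t transform
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; the fdr column is
    BH over all pairs of this pair_type. Constant rows have undefined
    correlation and are skipped with a log line.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    if sample_ids is None:
        sample_ids = [s for s in matA.sample_ids if s in set(matB.sample_ids)]
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    A = matA.values[sample_ids].to_numpy(float)
    B = matB.values[sample_ids].to_numpy(float)
    n = len(sample_ids)
    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A_c ** 2).sum(axis=1))
    sb = np.sqrt((B_c ** 2).sum(axis=1))
    const_a = sa == 0
    const_b = sb == 0
    for fid in np.asarray(matA.feature_ids)[const_a]:
        logger.info("constant source row %s: correlations skipped", fid)
    for fid in np.asarray(matB.feature_ids)[const_b]:
        logger.info("constant target row %s: correlations skipped", fid)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (A_c @ B_c.T) / np.outer(sa, sb)
    R = np.clip(R, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(df / (1.0 - R ** 2))
    P = 2.0 * stats.t.sf(np.abs(t), df)
    P = np.where(np.abs(R) >= 1.0, 0.0, P)
    pairs: list[CorrelationPair] = []
    a_ids, b_ids = matA.feature_ids, matB.feature_ids
    for i in range(len(a_ids)):
        if const_a[i]:
            continue
        for j in range(len(b_ids)):
            if const_b[j]:
                continue
            if a_ids[i] == b_ids[j]:
                continue  # self-pair (same feature in both layers)
            pairs.append(CorrelationPair(a_ids[i], b_ids[j], pair_type,
                                         float(R[i, j]), float(P[i, j])))
    if pairs:
        fdr = bh_adjust([p.p for p in pairs])
        for pair, q in zip(pairs, fdr):
            pair.fdr = float(q)
    return pairs


def threshold_pairs(pairs: list[CorrelationPair], pair_type: str,
                    alpha: float = 0.05, r_cut: float = 0.5,
                    alpha_on: str = "p") -> list[CorrelationPair]:
    """Keep the pairs that meet the per-layer correlation rule.

    miRNA–mRNA: r < -r_cut (sponge targets are repressed); miRNA–lncRNA:
    |r| > r_cut (either sign is reported, only negative edges feed triads);
    lncRNA–mRNA: r > r_cut (confirmation edges). All comparisons are strict,
    and the significance cut (on raw p by default, BH fdr optionally) is
    strict as well.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    if alpha_on not in ("p", "fdr"):
        raise ValueError("alpha_on must be 'p' or 'fdr'")
    def sig(pair: CorrelationPair) -> bool:
        return (pair.p if alpha_on == "p" else pair.fdr) < alpha
    if pair_type == PAIR_MIRNA_MRNA:
        kept = [p for p in pairs if p.r < -r_cut and sig(p)]
    elif pair_type == PAIR_MIRNA_LNCRNA:
        kept = [p for p in pairs if abs(p.r) > r_cut and sig(p)]
    else:
        kept = [p for p in pairs if p.r > r_cut and sig(p)]
    logger.info("threshold_pairs(%s): %d of %d pairs kept", pair_type,
                len(kept), len(pairs))
    return kept


def intersect_with_predictions(pairs: list[CorrelationPair],
                               predictions: TargetPredictionTable
                               ) -> list[CorrelationPair]:
    """Keep only correlation pairs with target-prediction support.

    Logs the Venn counts (correlated-only / predicted-only / both) of the
    correlation circle against the prediction circle.
    """
    predicted = predictions.pairs()
    kept = []
    for p in pairs:
        if (p.source_id, p.target_id) in predicted:
            p.predicted = True
            kept.append(p)
    correlated_only = len(pairs) - len(kept)
    predicted_only = len(predicted) - len(kept)
    logger.info("prediction intersect: correlated-only=%d predicted-only=%d both=%d",
                correlated_only, predicted_only, len(kept))
    return kept


def assemble_cerna_triads(mm_pairs: list[CorrelationPair],
                          ml_pairs: list[CorrelationPair],
                          lm_pairs: list[CorrelationPair] | None = None,
                          require_lncrna_mrna_edge: bool = False
                          ) -> list[CeRNATriad]:
    """Enumerate sponge triads from thresholded, prediction-supported edges.

    For each miRNA m, every lncRNA with a negative predicted m–lncRNA edge is
    combined with every mRNA with a negative predicted m–mRNA edge. Positive
    miRNA–lncRNA correlations (retained by threshold_pairs as network edges)
    are not sponge edges and never enter triads. With
    ``require_lncrna_mrna_edge`` a positive lncRNA–mRNA edge must also exist.
    Output is sorted by (mirna_id, lncrna_id, mrna_id).
    """
    mm_by_mirna: dict[str, list[CorrelationPair]] = {}
    for p in mm_pairs:
        if p.r < 0 and p.predicted:
            mm_by_mirna.setdefault(p.source_id, []).append(p)
    ml_by_mirna: dict[str, list[CorrelationPair]] = {}
    for p in ml_pairs:
        if p.r < 0 and p.predicted:
            ml_by_mirna.setdefault(p.source_id, []).append(p)
    lm_index: dict[tuple[str, str], CorrelationPair] = {}
    if lm_pairs:
        for p in lm_pairs:
            if p.r > 0:
                lm_index[(p.source_id, p.target_id)] = p
    triads: list[CeRNATriad] = []
    for mirna in sorted(set(mm_by_mirna) & set(ml_by_mirna)):
        for ml in ml_by_mirna[mirna]:
            for mm in mm_by_mirna[mirna]:
                lm = lm_index.get((ml.target_id, mm.target_id))
                if require_lncrna_mrna_edge and lm is None:
                    continue
                triads.append(CeRNATriad(ml.target_id, mirna, mm.target_id,
                                         mirna_mrna_edge=mm,
                                         mirna_lncrna_edge=ml,
                                         lncrna_mrna_edge=lm))
    triads.sort(key=lambda t: (t.mirna_id, t.lncrna_id, t.mrna_id))
    return triads


def pairs_to_frame(pairs: list[CorrelationPair]):
    import pandas as pd

    return pd.DataFrame(
        {
            "source_id": [p.source_id for p in pairs],
            "target_id": [p.target_id for p in pairs],
            "pair_type": [p.pair_type for p in pairs],
            "r": [p.r for p in pairs],
            "p": [p.p for p in pairs],
            "fdr": [p.fdr for p in pairs],
            "predicted": [p.predicted for p in pairs],
        }
    )


def triads_to_frame(triads: list[CeRNATriad]):
    import pandas as pd

    return pd.DataFrame(
        {
            "lncrna_id": [t.lncrna_id for t in triads],
            "mirna_id": [t.mirna_id for t in triads],
            "mrna_id": [t.mrna_id for t in triads],
            "mirna_mrna_r": [t.mirna_mrna_edge.r for t in triads],
            "mirna_lncrna_r": [t.mirna_lncrna_edge.r for t in triads],
            "lncrna_mrna_r": [
                t.lncrna_mrna_edge.r if t.lncrna_mrna_edge is not None else float("nan")
                for t in triads
            ],
        }
    )
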