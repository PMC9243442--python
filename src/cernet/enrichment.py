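"""Over-representation analysis, GSEA, and guilt-by-association prediction.

Three ways of asking "which annotated gene sets does this signal concentrate
in":

* ORA — upper-tail hypergeometric test of a discrete query list (e.g. the
  differentially expressed genes) against each set within a universe, with
  BH correction across the collection.
* GSEA — the weighted Kolmogorov–Smirnov running-sum statistic over a ranked
  gene list. Hits advance the sum by their |score|^p share, misses retreat it
  uniformly; the enrichment score (ES) is the signed maximal deviation. The
  null is gene-label permutation at matched set size; the normalized score
  (NES) divides ES by the mean |null ES| of matching sign, and the
  permutation p-value carries an add-one correction.
* Guilt by association — a hub feature's function is predicted by ranking
  all mRNAs by their Pearson correlation with the hub and running GSEA on
  that ranking: sets enriched at either extreme co-vary with the hub.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, GeneSetCollection
from .differential import bh_adjust

logger = logging.getLogger("cernet")


@dataclass
class RankedList:
    """Gene ids with scores, sorted descending; ties broken by id."""

    ids: list[str]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls([k for k, _ in items], np.array([v for _, v in items], float))

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("ranked list has duplicate ids")
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores length mismatch")
        d = np.diff(self.scores)
        if np.any(d > 0):
            raise ValueError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class OraResult:
    set_name: str
    overlap: int
    set_size_in_universe: int
    query_size: int
    universe_size: int
    p: float
    adj_p: float = float("nan")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float = float("nan")
    leading_edge: list[str] = field(default_factory=list)
    n_hits: int = 0


def hypergeometric_ora(query, gene_set, universe, set_name: str = "") -> OraResult:
    """Upper-tail hypergeometric probability of the observed overlap or more.

    The gene set is intersected with the universe before testing; the query
    must be a subset of the universe.
    """
    query, universe = set(query), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    set_in_universe = set(gene_set) & universe
    overlap = len(query & set_in_universe)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                 len(set_in_universe), len(query)))
    return OraResult(set_name, overlap, len(set_in_universe), len(query),
                     len(universe), min(p, 1.0))


def ora_batch(query, collection: GeneSetCollection, universe) -> list[OraResult]:
    """ORA of one query against every set, BH-corrected across the collection.

    Results are sorted by p ascending, ties by set name.
    """
    results = [hypergeometric_ora(query, collection.members(name), universe, name)
               for name in collection.names()]
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adj_p = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def gsea_es(ranked: RankedList, members, weight_p: float = 1.0):
    """Weighted KS enrichment score for one gene set on one ranked list.

    Returns (es, running_sum, leading_edge). Hits increment the running sum
    by |score|^weight_p normalized over in-list members; misses decrement by
    1/(N - n_hits); es is the running-sum value of maximal absolute
    deviation. The leading edge contains the members at or before the
    extremum for positive es, and strictly after it for negative es.
    """
    members = set(members)
    N = len(ranked)
    hits = np.array([g in members for g in ranked.ids], bool)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("no gene-set members present in the ranked list")
    if n_hits == N:
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    w = np.abs(ranked.scores) ** weight_p
    running = _running_sum(hits, w)
    k = int(np.argmax(np.abs(running)))
    es = float(running[k])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.ids) if hits[i] and i <= k]
    else:
        leading = [g for i, g in enumerate(ranked.ids) if hits[i] and i > k]
    return es, running, leading


def _running_sum(hits: np.ndarray, w: np.ndarray) -> np.ndarray:
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all in-list members carry zero weight; fall back to unweighted hits
        hit_w = hits.astype(float)
        total = hit_w.sum()
    inc = hit_w / total
    n_miss = (~hits).sum()
    dec = np.where(hits, 0.0, 1.0 / n_miss)
    return np.cumsum(inc - dec)


def _es_batch(hit_matrix: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized ES over many membership draws (rows of hit_matrix)."""
    hw = hit_matrix * w[None, :]
    totals = hw.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0
    if degenerate.any():
        hw[degenerate] = hit_matrix[degenerate].astype(float)
        totals = hw.sum(axis=1, keepdims=True)
    inc = hw / totals
    n_miss = (~hit_matrix).sum(axis=1, keepdims=True)
    dec = (~hit_matrix) / n_miss
    running = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def gsea_permutation(ranked: RankedList, collection: GeneSetCollection,
                     n_perm: int = 1000, weight_p: float = 1.0,
                     seed: int = 0, min_hits: int = 2) -> list[GseaResult]:
    """GSEA with a gene-label permutation null, per set.

    Scores stay attached to their ranked positions; membership is resampled
    uniformly at matched set size, ``n_perm`` times. nes = es / mean(|null
    es| of matching sign); p = (b + 1) / (m + 1) where b counts same-sign
    null scores at least as extreme and m the same-sign draws. Sets with
    fewer than ``min_hits`` in-list members are skipped (logged); sets with
    no same-sign null draws keep nes = nan (logged, not dropped). Output is
    sorted by |nes| descending.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    N = len(ranked)
    w = np.abs(ranked.scores) ** weight_p
    in_list = set(ranked.ids)
    null_cache: dict[int, np.ndarray] = {}
    results: list[GseaResult] = []
    for name in collection.names():
        members = set(collection.members(name)) & in_list
        k = len(members)
        if k < min_hits:
            logger.info("set %s: %d in-list members (<%d); skipped", name, k, min_hits)
            continue
        if k >= N:
            logger.info("set %s covers the whole ranked list; skipped", name)
            continue
        es, _, leading = gsea_es(ranked, members, weight_p)
        if k not in null_cache:
            keys = rng.random((n_perm, N))
            picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
            hit_matrix = np.zeros((n_perm, N), bool)
            np.put_along_axis(hit_matrix, picks, True, axis=1)
            null_cache[k] = _es_batch(hit_matrix, w)
        null = null_cache[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        m = int(same_sign.sum())
        if m == 0:
            logger.info("set %s: no same-sign null draws; nes undefined", name)
            nes, p = float("nan"), 1.0
        else:
            mean_abs = float(np.abs(null[same_sign]).mean())
            nes = es / mean_abs if mean_abs > 0 else float("nan")
            b = int((np.abs(null[same_sign]) >= abs(es)).sum())
            p = (b + 1) / (m + 1)
        results.append(GseaResult(name, es, nes, float(p),
                                  leading_edge=leading, n_hits=k))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.fdr = float(q)
    results.sort(key=lambda r: (-(abs(r.nes) if np.isfinite(r.nes) else -np.inf),
                                r.set_name))
    return results


def correlation_ranking(hub_vector: np.ndarray, mrna_matrix: ExpressionMatrix,
                        exclude: str | None = None) -> RankedList:
    """Rank all mRNAs by Pearson correlation with a hub expression vector."""
    hub = np.asarray(hub_vector, float)
    if np.ptp(hub) == 0:
        raise ValueError("constant hub vector: correlation undefined")
    X = mrna_matrix.values.to_numpy(float)
    ids = mrna_matrix.feature_ids
    hub_c = hub - hub.mean()
    X_c = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((X_c ** 2).sum(axis=1)) * np.sqrt((hub_c ** 2).sum())
    scores: dict[str, float] = {}
    for i, g in enumerate(ids):
        if exclude is not None and g == exclude:
            continue
        if denom[i] == 0:
            logger.info("constant mRNA row %s excluded from ranking", g)
            continue
        scores[g] = float((X_c[i] @ hub_c) / denom[i])
    return RankedList.from_scores(scores)


def guilt_by_association(hub_id: str, hub_matrix: ExpressionMatrix,
                         mrna_matrix: ExpressionMatrix,
                         collection: GeneSetCollection,
                         n_perm: int = 1000, weight_p: float = 1.0,
                         seed: int = 0) -> list[GseaResult]:
    """Predict a hub feature's function from its co-expression profile.

    The hub's expression vector (from its own layer's matrix) is correlated
    with every mRNA across the shared samples; GSEA on the resulting ranked
    list reports which sets track the hub, ordered by |nes| descending. An
    mRNA hub is excluded from its own ranked list.
    """
    if hub_id not in hub_matrix.feature_ids:
        raise ValueError(f"hub {hub_id!r} not found in its layer's matrix")
    shared = [s for s in mrna_matrix.sample_ids if s in set(hub_matrix.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    hub_vec = hub_matrix.values.loc[hub_id, shared].to_numpy(float)
    mrna = ExpressionMatrix(mrna_matrix.values[shared], mrna_matrix.layer)
    exclude = hub_id if hub_matrix.layer == "mRNA" else None
    ranked = correlation_ranking(hub_vec, mrna, exclude=exclude)
    return gsea_permutation(ranked, collection, n_perm=n_perm,
                            weight_p=weight_p, seed=seed)


def ora_to_frame(results: list[OraResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])


def gsea_to_frame(results: list[GseaResult]):
    import pandas as pd

    rows = []
    for r in results:
        d = dict(r.__dict__)
        d["leading_edge"] = ",".join(d["leading_edge"])
        rows.append(d)
    return pd.DataFrame(rows)
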