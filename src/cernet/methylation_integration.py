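"""Nine-quadrant integration of differential methylation with expression.

Genes are cross-classified by methylation state (hypo / none / hyper, from
the delta-beta significance calls) and expression state (down / none / up,
from the log2 fold-change calls) into a fixed 3x3 grid. Quadrant 3 — the
hypomethylated, upregulated cell — flags candidate epigenetically activated
genes: promoter demethylation that plausibly drives the expression gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .differential import CALL_DOWN, CALL_UP, DifferentialResult

logger = logging.getLogger("cernet")

METH_STATES = ("hypo", "none", "hyper")
EXPR_STATES = ("down", "none", "up")


@dataclass
class QuadrantAssignment:
    gene_id: str
    delta_beta: float
    expr_effect: float
    meth_state: str
    expr_state: str
    quadrant: int


def _meth_state(call: str) -> str:
    return {CALL_DOWN: "hypo", CALL_UP: "hyper"}.get(call, "none")


def _expr_state(call: str) -> str:
    return {CALL_DOWN: "down", CALL_UP: "up"}.get(call, "none")


def quadrant_of(meth_state: str, expr_state: str) -> int:
    """Fixed grid: rows = meth (hypo, none, hyper), cols = expr (down, none, up)."""
    return 3 * METH_STATES.index(meth_state) + EXPR_STATES.index(expr_state) + 1


def nine_quadrant(dm: list[DifferentialResult],
                  de: list[DifferentialResult]) -> list[QuadrantAssignment]:
    """Assign each gene measured in both layers to one of nine quadrants.

    Genes present in only one result list are excluded (counts logged);
    states come from the upstream significance calls, not raw effect signs.
    """
    de_by_id = {r.feature_id: r for r in de}
    dm_by_id = {r.feature_id: r for r in dm}
    matched = [g for g in dm_by_id if g in de_by_id]
    n_dm_only = len(dm_by_id) - len(matched)
    n_de_only = len(de_by_id) - len(matched)
    if n_dm_only or n_de_only:
        logger.info("nine_quadrant: %d methylation-only and %d expression-only "
                    "genes excluded", n_dm_only, n_de_only)
    out = []
    for g in matched:
        ms = _meth_state(dm_by_id[g].call)
        es = _expr_state(de_by_id[g].call)
        out.append(QuadrantAssignment(g, dm_by_id[g].effect, de_by_id[g].effect,
                                      ms, es, quadrant_of(ms, es)))
    return out


def select_hypomethylated_upregulated(assignments: list[QuadrantAssignment]
                                      ) -> list[str]:
    """Genes in the hypo-up quadrant, most severely hypomethylated first."""
    hits = [a for a in assignments if a.meth_state == "hypo" and a.expr_state == "up"]
    hits.sort(key=lambda a: (a.delta_beta, a.gene_id))
    return [a.gene_id for a in hits]


def quadrant_counts(assignments: list[QuadrantAssignment]) -> dict[int, int]:
    counts = {q: 0 for q in range(1, 10)}
    for a in assignments:
        counts[a.quadrant] += 1
    return counts
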