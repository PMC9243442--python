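"""Two-group differential testing with BH correction and fold-change calls.

The screen is a two-sided, equal-variance (pooled) Student t per feature,
with case-minus-control effects: log2 fold change for expression layers,
delta-beta for methylation. An optional moderated variant shrinks per-feature
variances toward the across-feature mean variance with a fixed prior degree
of freedom, for cohorts small enough that per-feature variances are noisy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, SampleSheet

logger = logging.getLogger("cernet")

#: variance floor guarding the t denominator for (near-)constant features
VARIANCE_FLOOR = 1e-12

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "not_significant"


@dataclass
class DifferentialResult:
    feature_id: str
    effect: float  # log2FC (expression) or delta-beta (methylation), case - control
    statistic: float
    p: float
    adj_p: float = float("nan")
    call: str = CALL_NS


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending ordering, capped at 1.
    Tied p-values receive identical adjusted values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _group_arrays(matrix: ExpressionMatrix, samples: SampleSheet):
    samples.require_two_per_group()
    case_ids = [s for s in samples.samples_in("case") if s in matrix.sample_ids]
    ctrl_ids = [s for s in samples.samples_in("control") if s in matrix.sample_ids]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples present in the matrix")
    x = matrix.values[case_ids].to_numpy(float)
    y = matrix.values[ctrl_ids].to_numpy(float)
    return x, y


def student_t_de(matrix: ExpressionMatrix, samples: SampleSheet,
                 moderated: bool = False, prior_df: float = 4.0
                 ) -> list[DifferentialResult]:
    """Per-feature pooled-variance two-sample t against the sample sheet.

    Returns results without significance calls (see :func:`classify_de`).
    With ``moderated=True``, pooled variances are shrunk toward their
    across-feature mean with ``prior_df`` pseudo-observations before the
    statistic, and the reference t distribution gains those degrees of
    freedom.
    """
    x, y = _group_arrays(matrix, samples)
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    mx, my = x.mean(axis=1), y.mean(axis=1)
    effect = mx - my
    ssx = ((x - mx[:, None]) ** 2).sum(axis=1)
    ssy = ((y - my[:, None]) ** 2).sum(axis=1)
    s2 = (ssx + ssy) / df
    if moderated:
        s2_prior = float(np.mean(s2))
        s2 = (prior_df * s2_prior + df * s2) / (prior_df + df)
        t_df = df + prior_df
    else:
        t_df = df
    se = np.sqrt(np.maximum(s2, VARIANCE_FLOOR) * (1.0 / n1 + 1.0 / n2))
    t = effect / se
    p = 2.0 * stats.t.sf(np.abs(t), t_df)
    # both groups constant and equal: no evidence either way
    degenerate = (s2 <= VARIANCE_FLOOR) & (effect == 0.0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return [
        DifferentialResult(fid, float(effect[i]), float(t[i]), float(p[i]))
        for i, fid in enumerate(matrix.feature_ids)
    ]


def classify_de(results: list[DifferentialResult], adj_p_max: float = 0.05,
                min_fold_change: float = 2.0,
                min_effect: float | None = None) -> list[DifferentialResult]:
    """Attach BH-adjusted p-values and up/down calls.

    A feature is called up when adj_p < ``adj_p_max`` and its effect is at
    least the log2 of ``min_fold_change`` (down symmetrically). For
    methylation pass ``min_effect`` directly as the delta-beta magnitude.
    """
    threshold = float(min_effect) if min_effect is not None else float(np.log2(min_fold_change))
    adj = bh_adjust([r.p for r in results])
    out = []
    for r, q in zip(results, adj):
        call = CALL_NS
        if q < adj_p_max:
            if r.effect >= threshold:
                call = CALL_UP
            elif r.effect <= -threshold:
                call = CALL_DOWN
        out.append(DifferentialResult(r.feature_id, r.effect, r.statistic,
                                      r.p, float(q), call))
    return out


def differential_methylation(beta_matrix: ExpressionMatrix, samples: SampleSheet,
                             adj_p_max: float = 0.05, min_delta_beta: float = 0.2,
                             moderated: bool = False) -> list[DifferentialResult]:
    """Delta-beta screen on a methylation matrix.

    Same t machinery as expression; the effect is mean(case) - mean(control)
    of the beta values, and the magnitude threshold is ``min_delta_beta``
    rather than a fold change. Hypomethylated genes are the ``down`` calls.
    """
    if beta_matrix.layer != "methylation":
        raise ValueError("differential_methylation expects the methylation layer")
    results = student_t_de(beta_matrix, samples, moderated=moderated)
    return classify_de(results, adj_p_max=adj_p_max, min_effect=min_delta_beta)


def results_to_frame(results: list[DifferentialResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "effect": [r.effect for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "adj_p": [r.adj_p for r in results],
            "call": [r.call for r in results],
        }
    )


def significant_ids(results: list[DifferentialResult]) -> set[str]:
    return {r.feature_id for r in results if r.call in (CALL_UP, CALL_DOWN)}
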