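"""Tissue-confound filtering against a paired reference cohort.

A case-vs-control contrast that compares hippocampal tissue against cortical
tissue confounds disease with brain region. Features whose expression already
differs between normal hippocampus and cortex in a paired reference atlas are
therefore removed from the differential signature list: what remains is
plausibly disease-specific rather than tissue-site-specific.

Per feature the within-pair (hippocampus minus cortex) differences are
tested: a Shapiro–Wilk check decides between the paired t-test (differences
normally distributed) and the Wilcoxon signed-rank test (otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, SampleSheet
from .differential import CALL_DOWN, CALL_UP, DifferentialResult

logger = logging.getLogger("cernet")

TEST_PAIRED_T = "paired_t"
TEST_WILCOXON = "wilcoxon_signed_rank"


@dataclass
class PairedTestResult:
    feature_id: str
    test_used: str
    normality_p: float
    p: float
    significant: bool


def paired_reference_test(reference: ExpressionMatrix, pairs: SampleSheet,
                          normality_alpha: float = 0.05,
                          alpha: float = 0.05) -> list[PairedTestResult]:
    """Per-feature paired test of hippocampus vs cortex reference samples.

    ``pairs`` must carry pair_id linking one 'case' (hippocampus) and one
    'control' (cortex) sample per donor. Features with all-zero differences
    get p = 1 under the Wilcoxon label (the signed-rank statistic is undefined
    without nonzero differences).
    """
    pair_list = pairs.pairs()
    pair_list = [(a, b) for a, b in pair_list
                 if a in reference.sample_ids and b in reference.sample_ids]
    if len(pair_list) < 3:
        raise ValueError(f"paired tests need at least 3 complete pairs, got {len(pair_list)}")
    hip = reference.values[[a for a, _ in pair_list]].to_numpy(float)
    ctx = reference.values[[b for _, b in pair_list]].to_numpy(float)
    diffs = hip - ctx
    results = []
    for i, fid in enumerate(reference.feature_ids):
        d = diffs[i]
        if np.all(d == 0):
            logger.info("feature %s: all paired differences zero; p set to 1", fid)
            results.append(PairedTestResult(fid, TEST_WILCOXON, 1.0, 1.0, False))
            continue
        if np.ptp(d) == 0:
            # constant nonzero difference: Shapiro undefined; treat as non-normal
            norm_p = 0.0
        else:
            norm_p = float(stats.shapiro(d).pvalue)
        if norm_p >= normality_alpha:
            p = float(stats.ttest_rel(hip[i], ctx[i]).pvalue)
            test = TEST_PAIRED_T
        else:
            nz = d[d != 0]
            if nz.size == 0:
                p = 1.0
            else:
                p = float(stats.wilcoxon(nz, zero_method="wilcox",
                                         correction=True, method="auto").pvalue)
            test = TEST_WILCOXON
        results.append(PairedTestResult(fid, test, norm_p, p, p < alpha))
    return results


def filter_cohort_specific(cohort_de: list[DifferentialResult],
                           reference: list[PairedTestResult],
                           keep_unmeasured: bool = True) -> set[str]:
    """Keep cohort-significant features that the reference cohort does not flag.

    A feature survives when it is called up or down in the study cohort and
    either shows no significant hippocampus-vs-cortex difference in the
    reference, or is absent from the reference (kept when ``keep_unmeasured``,
    since silently discarding unmeasured features would shrink the result set).
    """
    ref_by_id = {r.feature_id: r for r in reference}
    kept: set[str] = set()
    n_removed = n_unmeasured = 0
    for r in cohort_de:
        if r.call not in (CALL_UP, CALL_DOWN):
            continue
        ref = ref_by_id.get(r.feature_id)
        if ref is None:
            if keep_unmeasured:
                kept.add(r.feature_id)
                n_unmeasured += 1
            else:
                n_removed += 1
        elif not ref.significant:
            kept.add(r.feature_id)
        else:
            n_removed += 1
    logger.info("reference filter: kept %d (%d unmeasured), removed %d",
                len(kept), n_unmeasured, n_removed)
    return kept
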