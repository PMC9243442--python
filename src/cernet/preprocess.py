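"""Probe filtering, quantile normalization and log2 transformation.

Mirrors the standard expression-array preprocessing contract: drop probes on
sex chromosomes and probes detected in fewer than 60% of samples (strict
less-than), force all samples onto a common intensity distribution, then move
to log2 scale. Methylation beta matrices are deliberately left untouched by
normalization and log transformation — they are analyzed on the [0, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, FeatureAnnotation, SEX_CHROMOSOMES

logger = logging.getLogger("cernet")


@dataclass
class DetectionMatrix:
    """Boolean feature x sample table: probe detected above background."""

    values: pd.DataFrame

    def matches(self, matrix: ExpressionMatrix) -> bool:
        return (list(self.values.index) == matrix.feature_ids
                and list(self.values.columns) == matrix.sample_ids)


def filter_probes(matrix: ExpressionMatrix,
                  detection: DetectionMatrix | None,
                  annotation: FeatureAnnotation,
                  min_detection: float = 0.60,
                  keep_sex_chromosomes: bool = False) -> ExpressionMatrix:
    """Remove sex-chromosome probes and poorly detected probes.

    A probe is removed when its chromosome is chrX/chrY, or when its detection
    fraction is strictly below ``min_detection``. Probes with unknown
    chromosome are kept: the filter removes only what is provably on a sex
    chromosome. Row order of survivors is preserved.
    """
    chrom = annotation.chromosome_map()
    keep = pd.Series(True, index=matrix.values.index)
    if not keep_sex_chromosomes:
        on_sex = matrix.values.index.map(
            lambda f: chrom.get(f, "unknown") in SEX_CHROMOSOMES)
        n_sex = int(np.sum(on_sex))
        keep &= ~np.asarray(on_sex, dtype=bool)
    else:
        n_sex = 0
    n_low = 0
    if detection is not None:
        if not detection.matches(matrix):
            raise ValueError("detection matrix ids do not match expression matrix")
        frac = detection.values.mean(axis=1)
        low = frac < min_detection  # strict: exactly min_detection is kept
        n_low = int(low.sum())
        keep &= ~low
    logger.info("filter_probes: removed %d sex-chromosome and %d low-detection probes",
                n_sex, n_low)
    kept = matrix.values.loc[keep.values]
    return ExpressionMatrix(kept, matrix.layer)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (rank-mean) reference distribution.

    The reference is the vector of row-wise means of the per-sample sorted
    values. Each sample's values are replaced by the reference value at their
    rank; ties within a sample receive the mean of the reference values over
    the tied positions.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("missing values present")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the assigned reference values over tied entries
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < col.size:
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.layer,
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0,
                   already_log2: bool = False) -> ExpressionMatrix:
    """value -> log2(value + offset); a no-op when input is declared log-scale."""
    if already_log2:
        return matrix
    X = matrix.values.to_numpy(float)
    shifted = X + offset
    if np.any(shifted <= 0):
        bad = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"value + offset <= 0 at feature {matrix.feature_ids[bad[0]]!r}, "
            f"sample {matrix.sample_ids[bad[1]]!r}"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(shifted), index=matrix.values.index,
                     columns=matrix.values.columns),
        matrix.layer,
    )
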