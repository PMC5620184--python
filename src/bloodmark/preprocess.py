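"""Raw bead-array preprocessing: background offset, log2, sample QC.

The adjustment mirrors the usual bead-array text-export workflow: a single
additive background offset is estimated from the control probes (a low
quantile of their pooled intensities), subtracted from every value with a
positive floor, and the matrix is then log2-transformed. A light sample QC
removes arrays with too few detected probes or poor correlation to the
rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SCALE_LOG2, SCALE_RAW, ExpressionMatrix, ValidationError

__all__ = ["background_adjust", "log2_transform", "qc_filter_samples",
           "preprocess", "QcReport", "DEFAULT_QUANTILE", "DEFAULT_FLOOR"]

DEFAULT_QUANTILE = 0.05
#: Raw-intensity floor applied after offset subtraction (keeps log2 >= 0).
DEFAULT_FLOOR = 1.0


def background_adjust(raw: ExpressionMatrix, quantile: float = DEFAULT_QUANTILE,
                      floor: float = DEFAULT_FLOOR,
                      per_sample: bool = False) -> ExpressionMatrix:
    """Subtract the control-probe quantile offset from all intensities.

    The offset is the *quantile*-th quantile of the control-probe
    intensities pooled over all samples (or computed per sample when
    ``per_sample=True``). Values at or below the offset are floored at
    *floor* so the subsequent log2 transform is defined.
    """
    if raw.scale != SCALE_RAW:
        raise ValidationError("background_adjust expects a raw-scale matrix")
    if not 0 < quantile < 1:
        raise ValidationError(f"quantile must be in (0, 1), got {quantile}")
    ctrl = raw.values.loc[raw.is_control.to_numpy()]
    if ctrl.empty:
        raise ValidationError("matrix has no control probes")
    if per_sample:
        offset = ctrl.quantile(quantile, axis=0)  # per-sample Series
        adjusted = raw.values.sub(offset, axis=1)
    else:
        offset = float(np.quantile(ctrl.to_numpy().ravel(), quantile))
        adjusted = raw.values - offset
    adjusted = adjusted.clip(lower=floor)
    return ExpressionMatrix(adjusted, raw.gene_symbols, raw.is_control,
                            SCALE_RAW)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2; requires a strictly positive raw-scale matrix."""
    if matrix.scale == SCALE_LOG2:
        raise ValidationError("matrix is already log2-scaled")
    if (matrix.values.to_numpy() <= 0).any():
        raise ValidationError(
            "non-positive values; run background_adjust first")
    return ExpressionMatrix(np.log2(matrix.values), matrix.gene_symbols,
                            matrix.is_control, SCALE_LOG2)


@dataclass
class QcReport:
    """Per-sample QC metrics and the exclusion verdicts."""

    table: pd.DataFrame  # sample_id, detection, median_correlation, kept, reason

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "sample_id"])

    @property
    def excluded(self) -> list[str]:
        return list(self.table.loc[~self.table["kept"], "sample_id"])


def qc_filter_samples(matrix: ExpressionMatrix,
                      min_detection_fraction: float = 0.5,
                      min_median_correlation: float = 0.8,
                      floor: float = DEFAULT_FLOOR
                      ) -> tuple[list[str], QcReport]:
    """Keep samples with enough detected probes and cohort agreement.

    A probe is *detected* in a sample when its log2 value exceeds the
    background floor. A sample is kept iff its detected fraction is at
    least ``min_detection_fraction`` and its median Pearson correlation
    with every other sample is at least ``min_median_correlation``.
    """
    if matrix.scale != SCALE_LOG2:
        raise ValidationError("qc_filter_samples expects a log2 matrix")
    if matrix.n_samples < 3:
        raise ValidationError(
            "need at least 3 samples for correlation-based QC")
    vals = matrix.values.to_numpy()
    detection = (vals > np.log2(floor) + 1e-9).mean(axis=0)
    corr = np.corrcoef(vals.T)
    np.fill_diagonal(corr, np.nan)
    # constant samples yield NaN correlations; treat as zero agreement
    median_corr = np.nanmedian(np.nan_to_num(corr, nan=0.0), axis=1)
    if np.allclose(vals, vals[:, [0]]):
        median_corr = np.ones(matrix.n_samples)  # identical arrays agree fully
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        reasons = []
        if detection[i] < min_detection_fraction:
            reasons.append(
                f"detection {detection[i]:.3f} < {min_detection_fraction}")
        if median_corr[i] < min_median_correlation:
            reasons.append(
                f"median correlation {median_corr[i]:.3f} < "
                f"{min_median_correlation}")
        rows.append(dict(sample_id=sid, detection=detection[i],
                         median_correlation=median_corr[i],
                         kept=not reasons, reason="; ".join(reasons)))
    report = QcReport(pd.DataFrame(rows))
    return report.kept, report


def preprocess(raw: ExpressionMatrix, quantile: float = DEFAULT_QUANTILE,
               floor: float = DEFAULT_FLOOR, per_sample: bool = False,
               qc: bool = False, min_detection_fraction: float = 0.5,
               min_median_correlation: float = 0.8
               ) -> tuple[ExpressionMatrix, QcReport | None]:
    """background_adjust → log2_transform → optional sample QC."""
    log2 = log2_transform(background_adjust(raw, quantile, floor, per_sample))
    if not qc:
        return log2, None
    kept, report = qc_filter_samples(log2, min_detection_fraction,
                                     min_median_correlation, floor)
    return log2.subset_samples(kept), report
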