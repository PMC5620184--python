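"""qPCR relative quantification (ΔCt) and array-vs-qPCR validation.

Relative expression uses the cycle-threshold method against two reference
genes: on the log2 scale, ``log2rel = mean(Ct of references) - Ct of
target`` — i.e. ``2**-ΔCt`` with the geometric mean of the reference
expressions as the normalizer. Replicate wells are averaged first;
missing wells drop the sample with a warning.

Validation follows the two-step logic of a discovery table: a gene is
*qPCR-validated* when its array and qPCR values correlate positively
(one-tailed Pearson), and *survival-selected* when its qPCR expression
correlates with survival months (one-tailed Spearman in the direction of
the observed sign) after multiple-testing correction across the validated
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CtTable, ValidationError

__all__ = ["relative_expression", "validate_ma_qpcr", "spearman_survival",
           "survival_correlation_select", "ValidationRecord"]


def relative_expression(ct: CtTable, target: str,
                        refs: tuple[str, str] = ("OXSR1", "PBGD")
                        ) -> pd.Series:
    """Per-sample log2 relative expression of *target* against *refs*.

    Samples missing the target or any reference well are omitted with a
    warning. Replicates are averaged before the ΔCt.
    """
    mean_ct = ct.mean_ct()
    needed = [target, *refs]
    missing_cols = [g for g in needed if g not in mean_ct.columns]
    if missing_cols:
        raise ValidationError(f"genes absent from Ct table: {missing_cols}")
    sub = mean_ct[needed]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        dropped = list(sub.index[~complete])
        warnings.warn(f"samples omitted for missing wells: {dropped}",
                      stacklevel=2)
    sub = sub[complete]
    log2rel = sub[list(refs)].mean(axis=1) - sub[target]
    return log2rel.rename(f"log2rel_{target}")


def validate_ma_qpcr(ma_values: pd.Series, qpcr_values: pd.Series,
                     alpha: float = 0.05
                     ) -> tuple[float, float, bool]:
    """One-tailed Pearson test that array and qPCR values agree (r > 0).

    Returns (r, one-tailed p, pass). A zero-variance vector makes r
    undefined and fails the validation.
    """
    joined = pd.concat([pd.Series(ma_values), pd.Series(qpcr_values)],
                       axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValidationError(
            f"need >= 4 paired observations, got {len(joined)}")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan"), False
    res = stats.pearsonr(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue), bool(
        res.pvalue < alpha and res.statistic > 0)


def spearman_survival(values: pd.Series, survival_months: pd.Series
                      ) -> tuple[float, float]:
    """Spearman rho of expression vs survival with a one-tailed p in the
    direction of the observed sign."""
    joined = pd.concat([pd.Series(values), pd.Series(survival_months)],
                       axis=1, join="inner").dropna()
    rho, p_two = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    if np.isnan(rho):
        return float("nan"), float("nan")
    return float(rho), float(p_two / 2.0)


@dataclass
class ValidationRecord:
    gene: str
    pearson_r: float
    pearson_p: float
    qpcr_validated: bool
    spearman_rho: float = float("nan")
    spearman_p: float = float("nan")
    adjusted_p: float = float("nan")
    survival_selected: bool = False


def survival_correlation_select(records: pd.DataFrame, alpha: float = 0.05,
                                method: str = "bh") -> pd.DataFrame:
    """Flag survival-selected genes after multiple-testing correction.

    *records* needs columns ``gene``, ``rho`` and ``p`` (one-tailed
    Spearman p-values of qPCR expression vs survival for the
    qPCR-validated genes). p-values are adjusted across the entering genes
    (Benjamini–Hochberg by default, ``method="bonferroni"`` available) and
    a gene is selected when its adjusted p is below *alpha*. The sign of
    rho records the direction of the association.
    """
    if records.empty:
        out = records.copy()
        out["adjusted_p"] = pd.Series(dtype=float)
        out["survival_selected"] = pd.Series(dtype=bool)
        return out
    methods = {"bh": "fdr_bh", "bonferroni": "bonferroni"}
    if method not in methods:
        raise ValidationError(f"unknown correction method: {method!r}")
    out = records.copy()
    _, adj, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha,
                                 method=methods[method])
    out["adjusted_p"] = adj
    out["survival_selected"] = out["adjusted_p"] < alpha
    out["direction"] = np.where(out["rho"] >= 0, "positive", "negative")
    return out
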