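"""Clinical-value evaluation of a single biomarker gene.

Given per-sample (qPCR-scale) expression, survival months and censoring
flags, this module quantifies how well *low* expression identifies short
survivors:

* :func:`center_normalize` — subtract each treatment center's median so
  multi-center data can be pooled;
* :func:`roc_short_survivor` — ROC of "low expression predicts death
  before the survival window", AUC by pair counting with Hanley–McNeil
  standard error;
* :func:`sweep_survival_window` — AUC across candidate windows (the
  10–18-month grid) with the best window reported;
* :func:`choose_cutoff` — Youden-optimal or specificity-constrained
  operating point;
* :func:`km_logrank` — Kaplan–Meier strata above/below the cutoff with a
  two-group log-rank test (via lifelines);
* :func:`delta_expression` — longitudinal change from baseline and its
  Spearman association with survival;
* :func:`ml_concordance` — Fisher-exact 2×2 test that expression changes
  oppose myeloid/lymphoid-balance changes.

Patients censored before the window contribute no class label and are
excluded from the ROC (``censored_as_negative=True`` keeps them as
negatives instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .io import ValidationError
from .qpcr import spearman_survival

__all__ = [
    "center_normalize", "RocCurve", "roc_short_survivor",
    "sweep_survival_window", "choose_cutoff", "km_logrank",
    "delta_expression", "ml_concordance", "EvaluationReport",
    "evaluate_biomarker", "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = tuple(range(10, 19))


def center_normalize(values: pd.Series, centers: pd.Series) -> pd.Series:
    """Subtract each center's median value; per-center medians become 0."""
    values = pd.Series(values)
    centers = pd.Series(centers).loc[values.index]
    small = centers.value_counts()
    small = small[small < 3]
    if len(small):
        warnings.warn(
            f"centers with fewer than 3 samples: {sorted(small.index)}",
            stacklevel=2)
    medians = values.groupby(centers).transform("median")
    return values - medians


@dataclass
class RocCurve:
    """ROC of "expression below cutoff predicts short survival"."""

    cutoffs: np.ndarray        # candidate cutoffs on the expression scale
    sensitivity: np.ndarray    # P(value < cutoff | short survivor)
    specificity: np.ndarray    # P(value >= cutoff | long survivor)
    auc: float
    se: float
    n_pos: int
    n_neg: int
    window_months: float
    excluded: list = field(default_factory=list)


def _pair_count_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos < neg) with ties counting 1/2 — low values flag positives."""
    less = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (less + 0.5 * ties) / (len(pos) * len(neg))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_short_survivor(values: pd.Series, survival_months: pd.Series,
                       event: pd.Series, window_months: float,
                       censored_as_negative: bool = False) -> RocCurve:
    """ROC for identifying death before *window_months* by low expression.

    Positives are patients with an observed death before the window;
    negatives are patients known to survive (or censored) beyond it.
    Patients censored before the window have an unknown class and are
    excluded (or counted as negatives when ``censored_as_negative``).
    Candidate cutoffs sit midway between consecutive distinct values, with
    sentinels below and above the data range.
    """
    values = pd.Series(values, dtype=float)
    months = pd.Series(survival_months, dtype=float).loc[values.index]
    ev = pd.Series(event).astype(bool).loc[values.index]
    pos_mask = ev & (months < window_months)
    neg_mask = months >= window_months
    unknown = (~ev) & (months < window_months)
    if censored_as_negative:
        neg_mask = neg_mask | unknown
        unknown = pd.Series(False, index=values.index)
    excluded = list(values.index[unknown])
    pos = values[pos_mask].to_numpy()
    neg = values[neg_mask].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError(
            f"window {window_months} months leaves an empty class "
            f"(n_pos={len(pos)}, n_neg={len(neg)})")
    auc = _pair_count_auc(pos, neg)
    se = _hanley_mcneil_se(auc, len(pos), len(neg))
    included = np.sort(np.unique(np.r_[pos, neg]))
    mid = (included[:-1] + included[1:]) / 2.0
    cutoffs = np.r_[included[0] - 1.0, mid, included[-1] + 1.0]
    sens = np.array([np.mean(pos < c) for c in cutoffs])
    spec = np.array([np.mean(neg >= c) for c in cutoffs])
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                    auc=float(auc), se=se, n_pos=len(pos), n_neg=len(neg),
                    window_months=float(window_months), excluded=excluded)


def sweep_survival_window(values: pd.Series, survival_months: pd.Series,
                          event: pd.Series,
                          windows=DEFAULT_WINDOWS
                          ) -> tuple[pd.DataFrame, float]:
    """AUC per candidate survival window; best = argmax (ties → smaller).

    Windows leaving an empty class are skipped and annotated in the
    returned table.
    """
    windows = list(windows)
    if len(windows) < 1:
        raise ValidationError("need at least one candidate window")
    rows = []
    for w in windows:
        try:
            roc = roc_short_survivor(values, survival_months, event, w)
            rows.append(dict(window=w, auc=roc.auc, se=roc.se,
                             n_pos=roc.n_pos, n_neg=roc.n_neg, note=""))
        except ValidationError as exc:
            rows.append(dict(window=w, auc=np.nan, se=np.nan, n_pos=0,
                             n_neg=0, note=str(exc)))
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["auc"])
    if valid.empty:
        raise ValidationError("no window yields both classes")
    best_auc = valid["auc"].max()
    best = float(valid.loc[valid["auc"] == best_auc, "window"].min())
    return table, best


def choose_cutoff(curve: RocCurve, policy: str = "youden",
                  min_specificity: float = 0.89
                  ) -> tuple[float, float, float]:
    """Operating point on a ROC curve.

    ``policy="youden"`` maximizes sensitivity + specificity - 1 (ties go
    to the higher-specificity, then lower cutoff). ``policy=
    "min_specificity"`` maximizes sensitivity subject to specificity >=
    *min_specificity*, the high-specificity style of a rule-out biomarker.
    Returns (cutoff, sensitivity, specificity).
    """
    sens, spec, cuts = curve.sensitivity, curve.specificity, curve.cutoffs
    if policy == "youden":
        j = sens + spec - 1.0
        best = np.lexsort((cuts, -spec, -j))[0]
    elif policy == "min_specificity":
        ok = spec >= min_specificity
        if not ok.any():
            raise ValidationError(
                f"no cutoff attains specificity {min_specificity}; "
                f"maximum attainable is {spec.max():.3f}")
        idx = np.flatnonzero(ok)
        best = idx[np.lexsort((cuts[idx], -spec[idx], -sens[idx]))[0]]
    else:
        raise ValidationError(f"unknown cutoff policy: {policy!r}")
    return float(cuts[best]), float(sens[best]), float(spec[best])


@dataclass
class KmResult:
    below: pd.DataFrame   # KM curve of the low-expression stratum
    above: pd.DataFrame
    n_below: int
    n_above: int
    chi2: float
    p: float


def km_logrank(values: pd.Series, cutoff: float,
               survival_months: pd.Series, event: pd.Series) -> KmResult:
    """Kaplan–Meier curves for expression below vs at/above *cutoff* with
    the unstratified two-group log-rank test."""
    values = pd.Series(values, dtype=float)
    months = pd.Series(survival_months, dtype=float).loc[values.index]
    ev = pd.Series(event).astype(bool).loc[values.index]
    low = values < cutoff
    if not low.any() or low.all():
        raise ValidationError("cutoff leaves an empty stratum")

    def fit(mask: pd.Series) -> pd.DataFrame:
        kmf = KaplanMeierFitter()
        kmf.fit(months[mask], event_observed=ev[mask])
        sf = kmf.survival_function_
        sf.columns = ["survival"]
        return sf

    res = logrank_test(months[low], months[~low], event_observed_A=ev[low],
                       event_observed_B=ev[~low])
    return KmResult(below=fit(low), above=fit(~low),
                    n_below=int(low.sum()), n_above=int((~low).sum()),
                    chi2=float(res.test_statistic), p=float(res.p_value))


@dataclass
class DeltaResult:
    deltas: pd.DataFrame       # patient_id, timepoint, delta
    delta_final: pd.Series     # last available timepoint minus baseline
    rho: float
    p: float
    degenerate: bool


def delta_expression(long_values: pd.DataFrame, baseline: str = "pre",
                     survival_months: pd.Series | None = None,
                     timepoint_order: list[str] | None = None
                     ) -> DeltaResult:
    """Per-patient change from baseline and its survival association.

    *long_values* has columns ``patient_id``, ``timepoint``, ``value``.
    Δ = later − baseline (log2 units) for every post-baseline timepoint;
    patients without a baseline measurement are excluded with a warning.
    When *survival_months* (indexed by patient) is given, the Spearman rho
    of the final Δ (last available timepoint) vs survival is computed with
    a one-tailed p in the direction of the observed sign. If all Δ are
    equal the correlation is undefined and reported as degenerate.
    """
    df = long_values.copy()
    for col in ("patient_id", "timepoint", "value"):
        if col not in df.columns:
            raise ValidationError(f"missing column: {col}")
    if timepoint_order is None:
        timepoint_order = [baseline] + sorted(
            t for t in df["timepoint"].unique() if t != baseline)
    order = {t: i for i, t in enumerate(timepoint_order)}
    base = df[df["timepoint"] == baseline].set_index("patient_id")["value"]
    later = df[df["timepoint"] != baseline]
    missing = sorted(set(later["patient_id"]) - set(base.index))
    if missing:
        warnings.warn(f"patients lacking a baseline excluded: {missing}",
                      stacklevel=2)
        later = later[~later["patient_id"].isin(missing)]
    if later.empty:
        raise ValidationError("no post-baseline measurements")
    deltas = later.assign(
        delta=later["value"].to_numpy()
        - base.loc[later["patient_id"]].to_numpy())
    deltas = deltas.sort_values(["patient_id", "timepoint"],
                                key=lambda s: s.map(order)
                                if s.name == "timepoint" else s)
    final = (deltas.sort_values("timepoint", key=lambda s: s.map(order))
             .groupby("patient_id")["delta"].last())
    degenerate = bool(np.allclose(final, final.iloc[0]))
    rho = p = float("nan")
    if survival_months is not None and not degenerate:
        rho, p = spearman_survival(final, pd.Series(survival_months))
    return DeltaResult(deltas=deltas[["patient_id", "timepoint", "delta"]],
                       delta_final=final, rho=rho, p=p,
                       degenerate=degenerate)


def ml_concordance(delta_expr: pd.Series, delta_ml: pd.Series
                   ) -> tuple[np.ndarray, float]:
    """2×2 sign table of Δexpression vs ΔM/L with a two-sided Fisher test.

    Zero changes carry no direction and are excluded; rows index the sign
    of the expression change (+, −), columns the sign of the M/L change.
    """
    joined = pd.concat([pd.Series(delta_expr), pd.Series(delta_ml)], axis=1,
                       join="inner").dropna()
    a = joined.iloc[:, 0].to_numpy()
    b = joined.iloc[:, 1].to_numpy()
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValidationError("all changes are zero; no signs to compare")
    table = np.array([
        [int(((a > 0) & (b > 0)).sum()), int(((a > 0) & (b < 0)).sum())],
        [int(((a < 0) & (b > 0)).sum()), int(((a < 0) & (b < 0)).sum())],
    ])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


@dataclass
class EvaluationReport:
    """End-to-end single-gene evaluation artifacts."""

    normalized: pd.Series
    rho: float
    rho_p: float
    window_table: pd.DataFrame
    best_window: float
    roc: RocCurve
    cutoff: float
    sensitivity: float
    specificity: float
    km: KmResult


def evaluate_biomarker(values: pd.Series, centers: pd.Series,
                       survival_months: pd.Series, event: pd.Series,
                       windows=DEFAULT_WINDOWS,
                       cutoff_policy: str = "youden",
                       min_specificity: float = 0.89) -> EvaluationReport:
    """Center-normalize, correlate, sweep windows, pick a cutoff, stratify."""
    normalized = center_normalize(values, centers)
    rho, rho_p = spearman_survival(normalized,
                                   pd.Series(survival_months))
    window_table, best = sweep_survival_window(normalized, survival_months,
                                               event, windows)
    roc = roc_short_survivor(normalized, survival_months, event, best)
    cutoff, sens, spec = choose_cutoff(roc, cutoff_policy, min_specificity)
    km = km_logrank(normalized, cutoff, survival_months, event)
    return EvaluationReport(normalized=normalized, rho=rho, rho_p=rho_p,
                            window_table=window_table, best_window=best,
                            roc=roc, cutoff=cutoff, sensitivity=sens,
                            specificity=spec, km=km)
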