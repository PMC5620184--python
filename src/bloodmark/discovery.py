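"""Three-arm candidate discovery: SAM, survival SAM, PLS-DA, two-pass SAM.

The discovery stage screens a probe-level expression matrix for
survival-associated biomarker candidates along three independent arms and
intersects them:

1. **Survival SAM** — a permutation-calibrated Cox-score statistic per
   probe against censored survival months, called at "90th-percentile
   FDR = 0" (in at least 90% of permutations no permuted statistic
   exceeds the calling thresholds).
2. **PLS-DA** — partial least squares against survival-class indicators
   with VIP-score variable selection.
3. **Two-pass SAM** — a paired PBMC-vs-DC two-class SAM ("vaccination
   signature") gating an unpaired long-vs-short two-class SAM.

Every arm is finished with a linear-scale fold-change filter (long/short
mean ratio at least 2, or at most 1/2), and the final candidate panel is
the gene-level intersection of the three arms.

The SAM statistic is ``d = r / (s + s0)`` with the fudge factor ``s0``
chosen by the standard coefficient-of-variation recipe over the gene-wise
scatter percentiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .io import SCALE_LOG2, ExpressionMatrix, ValidationError

__all__ = [
    "SamResult", "CandidatePanel", "survival_class", "sam_two_class",
    "sam_survival", "call_at_percentile_fdr_zero", "fold_change_filter",
    "plsda_select", "two_pass_select", "intersect_candidates",
]

DEFAULT_N_PERM = 1000
DEFAULT_FOLD_CUTOFF = 2.0


# ---------------------------------------------------------------------------
# survival classes
# ---------------------------------------------------------------------------

def survival_class(survival_months):
    """Map survival months to short (<12), medium (12-24 incl.), long (>24).

    Accepts a scalar or an array-like; the 12- and 24-month boundaries are
    assigned to the medium class.
    """
    arr = np.asarray(survival_months, dtype=float)
    if (arr < 0).any():
        raise ValidationError("survival_months must be non-negative")
    out = np.where(arr < 12.0, "short",
                   np.where(arr <= 24.0, "medium", "long"))
    if np.isscalar(survival_months) or arr.ndim == 0:
        return str(out)
    if isinstance(survival_months, pd.Series):
        return pd.Series(out, index=survival_months.index)
    return out


# ---------------------------------------------------------------------------
# SAM core
# ---------------------------------------------------------------------------


@dataclass
class SamResult:
    """Per-probe SAM statistics plus the permutation null.

    ``d = r / (s + s0)``; ``perm_d`` holds one row of statistics per
    permutation. ``called``/``cutlow``/``cutup``/``delta_table`` are filled
    by :func:`call_at_percentile_fdr_zero`.
    """

    d: pd.Series
    r: pd.Series
    s: pd.Series
    s0: float
    perm_d: np.ndarray
    exhaustive: bool
    called: list[str] = field(default_factory=list)
    cutlow: float = -np.inf
    cutup: float = np.inf
    delta: float = np.nan
    delta_table: pd.DataFrame | None = None

    @property
    def probe_ids(self) -> pd.Index:
        return self.d.index



def _d_stat(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """d = r/(s+s0), defined as 0 where both numerator and scatter vanish."""
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = r / denom
    return np.where(denom > 0, d, 0.0)

def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor by the standard SAM recipe.

    Candidate values are the percentiles 0, 5, ..., 100 of the gene-wise
    scatter ``s``; the winner minimizes the coefficient of variation of the
    windowed median-absolute-deviation of ``d`` across quantile windows of
    ``s``.
    """
    s = np.asarray(s, dtype=float)
    if np.allclose(s, s[0]):
        return float(s[0]) * 0.0  # homoscedastic: no stabilization needed
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_windows = int(min(100, max(2, len(s) // 5)))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    which = np.clip(np.searchsorted(edges, s, side="right") - 1,
                    0, n_windows - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = _d_stat(r, s, s0)
        mads = []
        for w in range(n_windows):
            dw = d[which == w]
            if len(dw) == 0:
                continue
            mads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = mads.std() / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _two_class_rs(x: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired SAM numerator (mean2 - mean1) and pooled scatter."""
    n1, n2 = len(idx1), len(idx2)
    x1, x2 = x[:, idx1], x[:, idx2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = (((x1 - m1[:, None]) ** 2).sum(axis=1)
          + ((x2 - m2[:, None]) ** 2).sum(axis=1))
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m2 - m1, s


def _paired_rs(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired SAM numerator (mean difference) and its standard error."""
    k = diff.shape[1]
    r = diff.mean(axis=1)
    s = diff.std(axis=1, ddof=1) / np.sqrt(k)
    return r, s


def sam_two_class(matrix: ExpressionMatrix, labels: pd.Series,
                  paired: bool = False,
                  pairs: list[tuple[str, str]] | None = None,
                  n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> SamResult:
    """Two-class SAM d-statistics with a permutation null.

    *labels* maps sample id → class (exactly two classes; class order is
    alphabetical, and ``r = mean(class2) - mean(class1)``). When
    ``paired=True``, *pairs* must list ``(class1_sample, class2_sample)``
    tuples covering a complete pairing; the null then flips pair signs.
    The permutation space is enumerated exhaustively whenever it is no
    larger than *n_perm*.
    """
    labels = pd.Series(labels)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    x = matrix.values[labels.index].to_numpy()
    rng = np.random.default_rng(seed)

    if paired:
        if not pairs:
            raise ValidationError("paired SAM requires pairs")
        col = {sid: j for j, sid in enumerate(labels.index)}
        for a, b in pairs:
            if labels[a] == labels[b]:
                raise ValidationError(
                    f"pair ({a}, {b}) does not span both classes")
        # orient every pair as (class1, class2)
        oriented = [(a, b) if labels[a] == classes[0] else (b, a)
                    for a, b in pairs]
        in_pairs = {s for p in oriented for s in p}
        if in_pairs != set(labels.index):
            raise ValidationError("pairing does not cover all samples")
        i1 = np.array([col[a] for a, _ in oriented])
        i2 = np.array([col[b] for _, b in oriented])
        diff = x[:, i2] - x[:, i1]
        k = diff.shape[1]
        if k < 2:
            raise ValidationError("need at least 2 pairs")
        r, s = _paired_rs(diff)
        s0 = _choose_s0(r, s)
        d = _d_stat(r, s, s0)
        exhaustive = 2 ** k <= n_perm
        if exhaustive:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
        else:
            signs = rng.choice([1.0, -1.0], size=(n_perm, k))
        perm_d = np.empty((len(signs), matrix.n_probes))
        for b, sg in enumerate(signs):
            pr, ps = _paired_rs(diff * sg[None, :])
            perm_d[b] = _d_stat(pr, ps, s0)
    else:
        idx1 = np.flatnonzero((labels == classes[0]).to_numpy())
        idx2 = np.flatnonzero((labels == classes[1]).to_numpy())
        if len(idx1) < 2 or len(idx2) < 2:
            raise ValidationError("each class needs at least 2 samples")
        r, s = _two_class_rs(x, idx1, idx2)
        s0 = _choose_s0(r, s)
        d = _d_stat(r, s, s0)
        n, n1 = x.shape[1], len(idx1)
        n_assign = math.comb(n, n1)
        exhaustive = n_assign <= n_perm
        if exhaustive:
            assignments = [np.array(c)
                           for c in itertools.combinations(range(n), n1)]
        else:
            assignments = []
            for _ in range(n_perm):
                perm = rng.permutation(n)
                assignments.append(np.sort(perm[:n1]))
        perm_d = np.empty((len(assignments), matrix.n_probes))
        all_idx = np.arange(n)
        for b, a1 in enumerate(assignments):
            a2 = np.setdiff1d(all_idx, a1, assume_unique=True)
            pr, ps = _two_class_rs(x, a1, a2)
            perm_d[b] = _d_stat(pr, ps, s0)

    index = matrix.probe_ids
    return SamResult(d=pd.Series(d, index=index, name="d"),
                     r=pd.Series(r, index=index, name="r"),
                     s=pd.Series(s, index=index, name="s"),
                     s0=s0, perm_d=perm_d, exhaustive=exhaustive)


def _cox_score_layout(time: np.ndarray, event: np.ndarray):
    """Precompute the risk-set layout for the Cox score statistic.

    Returns (order, event_positions, riskset_end) where samples are sorted
    by descending time; the risk set of the event at ordered position j is
    the prefix 0..riskset_end[j] (ties share the same risk set).
    """
    order = np.argsort(-time, kind="stable")
    t_ord = time[order]
    n = len(t_ord)
    riskset_end = np.empty(n, dtype=int)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and t_ord[k + 1] == t_ord[j]:
            k += 1
        riskset_end[j:k + 1] = k
        j = k + 1
    event_pos = np.flatnonzero(event[order])
    return order, event_pos, riskset_end


def _cox_score_rs(x: np.ndarray, order: np.ndarray, event_pos: np.ndarray,
                  riskset_end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe Cox score numerator and its square-root variance.

    The numerator is the Cox partial-likelihood score at beta=0 (Breslow
    tie handling): sum over deaths of (x_death - risk-set mean). The
    variance accumulates the risk-set population variance once per death.
    """
    xo = x[:, order]
    cs = np.cumsum(xo, axis=1)
    cs2 = np.cumsum(xo ** 2, axis=1)
    ends = riskset_end[event_pos]
    nrisk = ends + 1.0
    means = cs[:, ends] / nrisk[None, :]
    variances = cs2[:, ends] / nrisk[None, :] - means ** 2
    r = (xo[:, event_pos] - means).sum(axis=1)
    v = np.maximum(variances, 0.0).sum(axis=1)
    return r, np.sqrt(v)


def sam_survival(matrix: ExpressionMatrix, survival_months: pd.Series,
                 event: pd.Series, n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0) -> SamResult:
    """Survival SAM: Cox-score d-statistics against censored survival.

    ``r_i`` is the Cox partial-likelihood score at beta=0 for probe i (sum
    over observed deaths of the probe value minus its risk-set mean) and
    ``s_i`` the square root of the accumulated risk-set variance;
    ``d_i = r_i / (s_i + s0)``. The null shuffles the (survival, event)
    pairs against the sample axis.
    """
    survival_months = pd.Series(survival_months)
    event = pd.Series(event).astype(bool)
    if (survival_months < 0).any():
        raise ValidationError("survival_months must be non-negative")
    if not event.any():
        raise ValidationError("survival SAM needs at least one observed event")
    samples = list(survival_months.index)
    x = matrix.values[samples].to_numpy()
    time = survival_months.to_numpy(dtype=float)
    ev = event.loc[samples].to_numpy()

    order, event_pos, riskset_end = _cox_score_layout(time, ev)
    r, s = _cox_score_rs(x, order, event_pos, riskset_end)
    s0 = _choose_s0(r, s)
    d = _d_stat(r, s, s0)

    rng = np.random.default_rng(seed)
    n = x.shape[1]
    perm_d = np.empty((n_perm, matrix.n_probes))
    for b in range(n_perm):
        shuf = rng.permutation(n)
        # permuting (time, event) against samples == permuting columns of x
        pr, ps = _cox_score_rs(x[:, shuf], order, event_pos, riskset_end)
        perm_d[b] = _d_stat(pr, ps, s0)

    index = matrix.probe_ids
    return SamResult(d=pd.Series(d, index=index, name="d"),
                     r=pd.Series(r, index=index, name="r"),
                     s=pd.Series(s, index=index, name="s"),
                     s0=s0, perm_d=perm_d, exhaustive=False)


def _cuts_for_delta(d_sorted: np.ndarray, dbar: np.ndarray,
                    delta: float) -> tuple[float, float]:
    """SAM calling thresholds for a given delta.

    cutup is the smallest positive observed statistic whose excess over the
    permutation-expected order statistic reaches delta; cutlow mirrors it
    on the negative side.
    """
    diff = d_sorted - dbar
    up = (diff >= delta) & (d_sorted > 0)
    low = (diff <= -delta) & (d_sorted < 0)
    cutup = d_sorted[up].min() if up.any() else np.inf
    cutlow = d_sorted[low].max() if low.any() else -np.inf
    return cutlow, cutup


def _false_counts(perm_d: np.ndarray, cutlow: float, cutup: float
                  ) -> np.ndarray:
    return ((perm_d >= cutup) | (perm_d <= cutlow)).sum(axis=1)


def _fdr90(counts: np.ndarray) -> float:
    return float(np.quantile(counts, 0.9, method="inverted_cdf"))


def call_at_percentile_fdr_zero(result: SamResult) -> list[str]:
    """Call probes at the smallest delta whose 90th-percentile false-call
    count over permutations is zero.

    Returns the called probe ids (possibly empty) and annotates *result*
    with the thresholds, the chosen delta and a diagnostic delta table
    (median and 90th-percentile false counts alongside the call count).
    """
    d = result.d.to_numpy()
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = np.sort(result.perm_d, axis=1).mean(axis=0)
    deltas = np.unique(np.abs(d_sorted - dbar))
    deltas = deltas[deltas > 0]

    def ok(delta: float) -> bool:
        cutlow, cutup = _cuts_for_delta(d_sorted, dbar, delta)
        return _fdr90(_false_counts(result.perm_d, cutlow, cutup)) == 0

    chosen = None
    if len(deltas) and ok(deltas[-1]):
        # binary search the smallest admissible delta (fdr90 is monotone)
        lo, hi = 0, len(deltas) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if ok(deltas[mid]):
                hi = mid
            else:
                lo = mid + 1
        chosen = float(deltas[lo])

    if chosen is None:
        result.called = []
        result.cutlow, result.cutup = -np.inf, np.inf
        result.delta = np.nan
    else:
        cutlow, cutup = _cuts_for_delta(d_sorted, dbar, chosen)
        called_mask = (d >= cutup) | (d <= cutlow)
        result.called = list(result.d.index[called_mask])
        result.cutlow, result.cutup = cutlow, cutup
        result.delta = chosen

    # diagnostic table over a coarse delta grid
    grid = deltas[np.linspace(0, len(deltas) - 1,
                              min(25, len(deltas)), dtype=int)] \
        if len(deltas) else np.array([])
    rows = []
    for delta in grid:
        cutlow, cutup = _cuts_for_delta(d_sorted, dbar, delta)
        counts = _false_counts(result.perm_d, cutlow, cutup)
        rows.append(dict(delta=delta,
                         n_called=int(((d >= cutup) | (d <= cutlow)).sum()),
                         false_median=float(np.median(counts)),
                         false_q90=_fdr90(counts),
                         cutlow=cutlow, cutup=cutup))
    result.delta_table = pd.DataFrame(rows)
    return result.called


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def fold_change_filter(matrix: ExpressionMatrix, long_ids: list[str],
                       short_ids: list[str],
                       cutoff: float = DEFAULT_FOLD_CUTOFF,
                       probes: list[str] | None = None
                       ) -> tuple[list[str], pd.Series]:
    """Linear-scale fold change (mean long / mean short) with a symmetric
    cut-off: retain probes with fold >= cutoff or fold <= 1/cutoff.

    Log2 matrices are un-logged before averaging, per the convention of
    dividing mean linear expression values.
    """
    if not long_ids or not short_ids:
        raise ValidationError("both survivor groups must be non-empty")
    values = matrix.values if probes is None else matrix.values.loc[probes]
    if matrix.scale == SCALE_LOG2:
        values = np.exp2(values)
    mean_long = values[long_ids].mean(axis=1)
    mean_short = values[short_ids].mean(axis=1)
    if (mean_long <= 0).any() or (mean_short <= 0).any():
        raise ValidationError("non-positive linear group mean")
    fold = mean_long / mean_short
    retained = fold.index[(fold >= cutoff) | (fold <= 1.0 / cutoff)]
    return list(retained), fold.rename("fold")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _vip_scores(pls: PLSRegression, n_features: int) -> np.ndarray:
    """Variable-importance-in-projection from a fitted PLS2 model."""
    t = pls.x_scores_          # (n, A)
    w = pls.x_weights_         # (p, A)
    q = pls.y_loadings_        # (m, A)
    ssy = (t ** 2).sum(axis=0) * (q ** 2).sum(axis=0)  # per-component
    wnorm = w / np.linalg.norm(w, axis=0, keepdims=True)
    return np.sqrt(n_features * (wnorm ** 2 @ ssy) / ssy.sum())


def plsda_select(matrix: ExpressionMatrix, class_labels: pd.Series,
                 n_components: int = 2, vip_threshold: float = 1.0,
                 fold_cutoff: float = DEFAULT_FOLD_CUTOFF
                 ) -> tuple[list[str], pd.Series]:
    """PLS-DA variable selection: VIP >= threshold, then fold filtering.

    Expression (samples × probes, centered by the PLS fit) is regressed on
    the one-hot class indicator matrix with NIPALS PLS2; probes are ranked
    by VIP and those at or above *vip_threshold* are kept, then filtered by
    the long-vs-short linear fold-change cut-off. Returns the selected
    probe list and the full VIP series.
    """
    class_labels = pd.Series(class_labels)
    classes = sorted(class_labels.unique())
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    counts = class_labels.value_counts()
    if (counts < 2).any():
        raise ValidationError("each class needs at least 2 samples")
    x = matrix.values[class_labels.index].to_numpy().T  # samples × probes
    if n_components >= min(x.shape):
        raise ValidationError(
            f"n_components={n_components} must be < min(samples, probes)"
            f"={min(x.shape)}")
    y = pd.get_dummies(class_labels).astype(float).to_numpy()
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, y)
    vip = pd.Series(_vip_scores(pls, x.shape[1]), index=matrix.probe_ids,
                    name="vip")
    candidates = list(vip.index[vip >= vip_threshold])
    short_ids = list(class_labels.index[class_labels == "short"])
    long_ids = list(class_labels.index[class_labels == "long"])
    if short_ids and long_ids and candidates:
        selected, _ = fold_change_filter(matrix, long_ids, short_ids,
                                         fold_cutoff, probes=candidates)
    else:
        selected = candidates
    return selected, vip


# ---------------------------------------------------------------------------
# two-pass SAM and the intersection
# ---------------------------------------------------------------------------


def two_pass_select(pbmc: ExpressionMatrix, dc: ExpressionMatrix,
                    pairs: list[tuple[str, str]],
                    survival_classes: pd.Series,
                    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                    fold_cutoff: float = DEFAULT_FOLD_CUTOFF
                    ) -> tuple[list[str], dict]:
    """Vaccination-signature gating followed by long-vs-short selection.

    Pass 1 runs a paired PBMC-vs-DC two-class SAM over *pairs* and keeps
    probes called at 90th-percentile FDR 0. Pass 2 reruns an unpaired
    long-vs-short two-class SAM restricted to the pass-1 probes and applies
    the fold-change cut-off. Returns the selected probes and a provenance
    dict with both pass results.
    """
    pbmc_ids = [a for a, _ in pairs]
    dc_ids = [b for _, b in pairs]
    combined = pd.concat([pbmc.values[pbmc_ids], dc.values[dc_ids]], axis=1)
    merged = ExpressionMatrix(combined, pbmc.gene_symbols, pbmc.is_control,
                              pbmc.scale)
    labels1 = pd.Series(["PBMC"] * len(pbmc_ids) + ["DC"] * len(dc_ids),
                        index=[*pbmc_ids, *dc_ids])
    res1 = sam_two_class(merged, labels1, paired=True,
                         pairs=list(zip(pbmc_ids, dc_ids)),
                         n_perm=n_perm, seed=seed)
    pass1 = call_at_percentile_fdr_zero(res1)
    info: dict = {"pass1": res1, "pass1_called": pass1}
    if not pass1:
        info["pass2"] = None
        return [], info

    cls = pd.Series(survival_classes)
    keep = cls[cls.isin(["short", "long"])]
    sub = pbmc.subset_probes(pass1).subset_samples(list(keep.index))
    res2 = sam_two_class(sub, keep, paired=False, n_perm=n_perm,
                         seed=seed + 1)
    pass2 = call_at_percentile_fdr_zero(res2)
    info["pass2"] = res2
    info["pass2_called"] = pass2
    if not pass2:
        return [], info
    long_ids = list(keep.index[keep == "long"])
    short_ids = list(keep.index[keep == "short"])
    selected, folds = fold_change_filter(pbmc, long_ids, short_ids,
                                         fold_cutoff, probes=pass2)
    info["folds"] = folds
    return selected, info


@dataclass
class CandidatePanel:
    """Gene-level intersection of the three discovery arms."""

    genes: list[str]
    arm_survival: list[str]
    arm_plsda: list[str]
    arm_twopass: list[str]

    def provenance(self) -> pd.DataFrame:
        all_genes = sorted(set(self.arm_survival) | set(self.arm_plsda)
                           | set(self.arm_twopass))
        return pd.DataFrame({
            "gene": all_genes,
            "in_survival": [g in set(self.arm_survival) for g in all_genes],
            "in_plsda": [g in set(self.arm_plsda) for g in all_genes],
            "in_twopass": [g in set(self.arm_twopass) for g in all_genes],
            "in_panel": [g in set(self.genes) for g in all_genes],
        })


def _collapse_probes(probes: list[str], probe_to_gene: pd.Series,
                     scores: pd.Series | None = None) -> list[str]:
    """Probe list → gene list; empty symbols are dropped. When *scores*
    are given the best probe per gene is implicit (only membership matters
    for the intersection)."""
    genes = []
    for p in probes:
        g = probe_to_gene.get(p, "")
        if g:
            genes.append(g)
    return sorted(set(genes))


def intersect_candidates(arm_survival: list[str], arm_plsda: list[str],
                         arm_twopass: list[str],
                         probe_to_gene: pd.Series) -> CandidatePanel:
    """Intersect the three arms at gene-symbol level."""
    g1 = _collapse_probes(arm_survival, probe_to_gene)
    g2 = _collapse_probes(arm_plsda, probe_to_gene)
    g3 = _collapse_probes(arm_twopass, probe_to_gene)
    panel = sorted(set(g1) & set(g2) & set(g3))
    return CandidatePanel(genes=panel, arm_survival=g1, arm_plsda=g2,
                          arm_twopass=g3)
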