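"""Reference-gene selection from the array: invariance, trend absence, geNorm.

qPCR normalization needs reference genes that are stable in the tissue at
hand; the commonly recycled ones behave poorly on PBMCs, so candidates are
mined from the expression matrix itself in three stages:

1. :func:`invariance_screen` — keep genes whose log2 coefficient of
   variation is below 5% and whose mean expression sits clearly above
   background (so silent genes are not mistaken for stable ones).
2. :func:`trend_screen` — require the absence of any long/short-survivor
   trend: non-small t-test and Mann–Whitney p-values, a near-zero
   regression slope on the group indicator, and high overlap between the
   two groups' value ranges; candidates are ranked by a composite of the
   four diagnostics.
3. :func:`genorm_rank` — pairwise-stability ranking with stepwise
   elimination: each gene's M value is the mean standard deviation of its
   log2 ratios against every other candidate, and the least stable gene is
   removed each round until a final pair remains.

"standard deviation < 5%" is read as a coefficient of variation of the
log2 expression below 0.05 — the only unitless reading of the 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SCALE_LOG2, ExpressionMatrix, ValidationError

__all__ = ["StabilityRanking", "invariance_screen", "trend_screen",
           "genorm_rank", "select_reference_pair"]

DEFAULT_CV_MAX = 0.05
#: Trend screen: both test p-values must exceed this for "no trend".
DEFAULT_P_MIN = 0.3


def _gene_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene × sample log2 values, one row per symbol (highest-mean probe),
    control probes and empty symbols excluded."""
    if matrix.scale != SCALE_LOG2:
        raise ValidationError("reference-gene screens expect a log2 matrix")
    keep = (~matrix.is_control) & (matrix.gene_symbols != "")
    vals = matrix.values.loc[keep.to_numpy()]
    sym = matrix.gene_symbols[keep]
    means = vals.mean(axis=1)
    best = means.groupby(sym).idxmax()
    out = vals.loc[best]
    out.index = best.index
    return out.sort_index()


def invariance_screen(matrix: ExpressionMatrix,
                      cv_max: float = DEFAULT_CV_MAX,
                      background_level: float | None = None) -> list[str]:
    """Genes with log2 CV below *cv_max* and mean above *background_level*.

    *background_level* defaults to the matrix-wide median log2 value.
    """
    if cv_max <= 0:
        raise ValidationError(f"cv_max must be positive, got {cv_max}")
    genes = _gene_matrix(matrix)
    if background_level is None:
        background_level = float(np.median(matrix.values.to_numpy()))
    mean = genes.mean(axis=1)
    sd = genes.std(axis=1, ddof=1)
    cv = sd / mean.where(mean != 0, np.nan)
    keep = (cv < cv_max) & (mean > background_level)
    return sorted(genes.index[keep.fillna(False)])


def trend_screen(matrix: ExpressionMatrix, short_ids: list[str],
                 long_ids: list[str], p_min: float = DEFAULT_P_MIN,
                 genes: list[str] | None = None) -> pd.DataFrame:
    """Rank candidate genes by absence of a long/short survivor trend.

    Per gene: Welch t-test p, Mann–Whitney p (exact for small groups),
    the slope of expression regressed on the group indicator (short=0,
    long=1), and the overlap (mean fraction of each group's values lying
    inside the other group's range). Genes whose t OR Mann–Whitney p is
    at most *p_min* show a trend and are excluded. The remainder are
    ranked by composite rank of (large min-p, small |slope|, large
    overlap), ties broken by gene name.
    """
    if len(short_ids) < 2 or len(long_ids) < 2:
        raise ValidationError("both survivor groups need >= 2 samples")
    gm = _gene_matrix(matrix)
    if genes is not None:
        missing = set(genes) - set(gm.index)
        if missing:
            raise ValidationError(f"genes not on matrix: {sorted(missing)}")
        gm = gm.loc[sorted(genes)]
    xs = gm[short_ids].to_numpy()
    xl = gm[long_ids].to_numpy()
    indicator = np.r_[np.zeros(len(short_ids)), np.ones(len(long_ids))]
    rows = []
    for i, gene in enumerate(gm.index):
        a, b = xs[i], xl[i]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and a[0] == b[0]:
            t_p, mw_p = 1.0, 1.0
        else:
            t_p = stats.ttest_ind(a, b, equal_var=False).pvalue
            mw_p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        if np.isnan(t_p):
            t_p = 1.0
        slope = stats.linregress(indicator, np.r_[a, b]).slope
        overlap = 0.5 * (np.mean((a >= b.min()) & (a <= b.max()))
                         + np.mean((b >= a.min()) & (b <= a.max())))
        rows.append(dict(gene=gene, t_p=float(t_p), mw_p=float(mw_p),
                         slope=float(slope), overlap=float(overlap),
                         min_p=float(min(t_p, mw_p))))
    df = pd.DataFrame(rows).set_index("gene")
    df["trend_free"] = (df["t_p"] > p_min) & (df["mw_p"] > p_min)
    # composite: average of the three criterion ranks (higher = better)
    r_p = df["min_p"].rank(ascending=False)
    r_slope = df["slope"].abs().rank(ascending=True)
    r_overlap = df["overlap"].rank(ascending=False)
    df["composite_rank"] = (r_p + r_slope + r_overlap) / 3.0
    # best (lowest composite rank) first; ties broken by gene name
    return df.sort_index(kind="stable").sort_values("composite_rank",
                                                    kind="stable")


@dataclass
class StabilityRanking:
    """geNorm audit trail: per-round M values and the elimination order."""

    candidates: list[str]
    rounds: list[pd.Series]        # M values at the start of each round
    elimination_order: list[str]   # most unstable first
    final_pair: tuple[str, str]
    pairwise_variation: pd.Series  # V(n/n+1) indexed by n


def _genorm_m(values: pd.DataFrame) -> pd.Series:
    """M_j = mean over k != j of SD across samples of (log2_j - log2_k)."""
    x = values.to_numpy()
    g = x.shape[0]
    m = np.empty(g)
    for j in range(g):
        diffs = x[j][None, :] - x          # g × samples
        sds = diffs.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=values.index, name="M")


def genorm_rank(matrix: ExpressionMatrix,
                candidates: list[str] | None = None) -> StabilityRanking:
    """Stepwise geNorm elimination down to the most stable pair.

    Works on log2 values (differences of log2 values are log ratios of
    linear expression). Ties on the maximal M are broken by removing the
    lexicographically last gene, which makes the elimination order
    deterministic. The pairwise variation V(n/n+1) — the SD across samples
    of the difference between normalization factors built from the top n
    and top n+1 genes — is recorded for reporting; elimination always
    proceeds to a final pair.
    """
    gm = _gene_matrix(matrix)
    if candidates is not None:
        missing = set(candidates) - set(gm.index)
        if missing:
            raise ValidationError(f"genes not on matrix: {sorted(missing)}")
        gm = gm.loc[sorted(candidates)]
    if len(gm) < 3:
        raise ValidationError("geNorm needs at least 3 candidate genes")

    remaining = gm.copy()
    rounds: list[pd.Series] = []
    eliminated: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(remaining)
        rounds.append(m)
        worst_val = m.max()
        worst = sorted(m.index[m == worst_val])[-1]
        eliminated.append(worst)
        remaining = remaining.drop(index=worst)
    rounds.append(_genorm_m(remaining))
    final = tuple(sorted(remaining.index))

    # stability order, most stable first: final pair (by M), then reversed
    # elimination order
    order = list(rounds[-1].sort_values().index) + eliminated[::-1]
    pv = {}
    for n in range(2, len(gm)):
        nf_n = gm.loc[order[:n]].mean(axis=0)
        nf_n1 = gm.loc[order[:n + 1]].mean(axis=0)
        pv[n] = float((nf_n - nf_n1).std(ddof=1))
    return StabilityRanking(candidates=list(gm.index), rounds=rounds,
                            elimination_order=eliminated,
                            final_pair=final,
                            pairwise_variation=pd.Series(pv, name="V"))


@dataclass
class ReferencePairReport:
    pair: tuple[str, str]
    invariant_genes: list[str]
    trend_table: pd.DataFrame
    trend_free_genes: list[str]
    ranking: StabilityRanking
    p_min_used: float = DEFAULT_P_MIN

    def stage_counts(self) -> dict[str, int]:
        return {"invariance": len(self.invariant_genes),
                "trend_free": len(self.trend_free_genes),
                "final_pair": 2}


def select_reference_pair(matrix: ExpressionMatrix, short_ids: list[str],
                          long_ids: list[str],
                          cv_max: float = DEFAULT_CV_MAX,
                          p_min: float = DEFAULT_P_MIN,
                          background_level: float | None = None,
                          relax_p_min: bool = False
                          ) -> ReferencePairReport:
    """invariance_screen → trend_screen → genorm_rank, with an audit trail.

    A strong center-survival confound can shift every candidate at once and
    make the trend screen reject everything even though pairwise stability
    (which cancels per-sample offsets) is intact. With ``relax_p_min=True``
    the trend threshold is progressively relaxed (p_min → 0.05 → 0) until
    at least three candidates remain, and the relaxation is recorded in the
    report.
    """
    invariant = invariance_screen(matrix, cv_max, background_level)
    if len(invariant) < 3:
        raise ValidationError(
            f"only {len(invariant)} genes pass the invariance screen; "
            "relax cv_max or background_level")
    thresholds = [p_min]
    if relax_p_min:
        thresholds += [t for t in (0.05, 0.0) if t < p_min]
    trend = None
    trend_free: list[str] = []
    used_p_min = p_min
    for threshold in thresholds:
        trend = trend_screen(matrix, short_ids, long_ids, threshold,
                             genes=invariant)
        trend_free = list(trend.index[trend["trend_free"]])
        used_p_min = threshold
        if len(trend_free) >= 3:
            break
    if len(trend_free) < 3:
        raise ValidationError(
            f"only {len(trend_free)} genes pass the trend screen; "
            "relax p_min")
    ranking = genorm_rank(matrix, trend_free)
    return ReferencePairReport(pair=ranking.final_pair,
                               invariant_genes=invariant,
                               trend_table=trend,
                               trend_free_genes=trend_free,
                               ranking=ranking,
                               p_min_used=used_p_min)
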