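"""Anchor-gene co-expression ranking and preranked gene-set enrichment.

To place a biomarker in its transcriptional context, every other probe is
correlated with the anchor gene across samples, probes are collapsed to
genes, and the resulting correlation-ranked list is tested for enrichment
of curated gene sets (e.g. blood transcriptional modules) with a
preranked GSEA:

* hits advance a running sum by ``|score|**p`` (normalized to sum 1 over
  the set), misses retreat it uniformly; the enrichment score ES is the
  maximum signed deviation;
* the null redistributes gene labels (gene permutation), giving a
  normalized score NES = ES / mean(|null ES| of the same sign) and an FDR
  q per sign from the pooled permuted NES distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = ["correlate_to_anchor", "gsea_preranked", "two_direction_report",
           "EnrichmentResult", "enrichment_score"]

DEFAULT_MIN_SIZE = 10
DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000


def correlate_to_anchor(matrix: ExpressionMatrix, anchor_gene: str
                        ) -> pd.DataFrame:
    """Pearson correlation of every other probe with the anchor gene.

    Probes are collapsed to gene symbols keeping the probe with the
    largest |r| (empty symbols dropped); the table is sorted by r,
    descending. Needs at least 4 samples and a non-constant anchor.
    """
    if matrix.n_samples < 4:
        raise ValidationError("need at least 4 samples")
    anchor = matrix.gene_row(anchor_gene).to_numpy(dtype=float)
    if anchor.std() == 0:
        raise ValidationError(f"anchor gene {anchor_gene!r} has zero variance")
    vals = matrix.values.to_numpy(dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.sqrt((vc ** 2).sum(axis=1)) * np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ ac) / denom
    df = pd.DataFrame({"probe_id": matrix.probe_ids,
                       "gene": matrix.gene_symbols.to_numpy(),
                       "r": r})
    anchor_probes = set(matrix.probes_for_gene(anchor_gene))
    df = df[~df["probe_id"].isin(anchor_probes)]
    df = df[(df["gene"] != "") & df["r"].notna()]
    best = df.loc[df.groupby("gene")["r"].apply(
        lambda s: s.abs().idxmax())]
    return (best[["gene", "r"]].sort_values("r", ascending=False)
            .reset_index(drop=True))


def enrichment_score(scores: np.ndarray, hit_mask: np.ndarray,
                     weight_p: float = DEFAULT_WEIGHT
                     ) -> tuple[float, int]:
    """Weighted Kolmogorov–Smirnov-style running-sum enrichment score.

    *scores* are the ranking scores in list order; *hit_mask* flags set
    members. Returns (ES, peak index). ES is the running sum's maximum
    deviation from zero, signed.
    """
    n = len(scores)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValidationError("gene set is empty or spans the whole list")
    w = np.abs(scores) ** weight_p
    nr = w[hit_mask].sum()
    if nr == 0:
        # all member scores are zero: fall back to unweighted hits
        incr = hit_mask / nh
    else:
        incr = np.where(hit_mask, w / nr, 0.0)
    decr = np.where(hit_mask, 0.0, 1.0 / (n - nh))
    running = np.cumsum(incr - decr)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the permutation machinery's summary."""

    table: pd.DataFrame          # set, size, es, nes, q, leading_edge
    ranked_genes: list[str]
    n_perm: int
    min_size: int

    def __len__(self) -> int:
        return len(self.table)


def _null_es(scores: np.ndarray, size: int, n_perm: int,
             weight_p: float, rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution for a set of *size* random genes."""
    n = len(scores)
    out = np.empty(n_perm)
    w = np.abs(scores) ** weight_p
    decr_unit = 1.0
    for b in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        nr = w[mask].sum()
        incr = (np.where(mask, w / nr, 0.0) if nr > 0
                else mask / size)
        decr = np.where(mask, 0.0, decr_unit / (n - size))
        running = np.cumsum(incr - decr)
        out[b] = running[np.argmax(np.abs(running))]
    return out


def gsea_preranked(ranked: pd.DataFrame, gene_sets: GeneSetCollection,
                   min_size: int = DEFAULT_MIN_SIZE,
                   weight_p: float = DEFAULT_WEIGHT,
                   n_perm: int = DEFAULT_N_PERM,
                   seed: int = 0) -> EnrichmentResult:
    """Preranked GSEA over *ranked* (columns ``gene``, ``r``; sorted by
    score descending) with a gene-permutation null.

    Sets are first restricted to genes present in the list; sets smaller
    than *min_size* after filtering are excluded. NES divides ES by the
    mean magnitude of same-sign null scores; FDR q compares each set's NES
    against the pooled null NES of its sign, normalized by the fraction of
    observed sets at least as extreme (the usual preranked convention),
    clipped to [0, 1].
    """
    genes = list(ranked["gene"])
    scores = ranked["r"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    kept = []
    for name in gene_sets:
        members = [g for g in gene_sets[name] if g in pos]
        if len(members) >= min_size:
            kept.append((name, members))
    if not kept:
        return EnrichmentResult(
            table=pd.DataFrame(columns=["set", "size", "es", "nes", "q",
                                        "leading_edge"]),
            ranked_genes=genes, n_perm=n_perm, min_size=min_size)

    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in kept:
        mask = np.zeros(len(genes), dtype=bool)
        mask[[pos[g] for g in members]] = True
        es, peak = enrichment_score(scores, mask, weight_p)
        size = len(members)
        if size not in null_by_size:
            null_by_size[size] = _null_es(scores, size, n_perm, weight_p,
                                          rng)
        null = null_by_size[size]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = (np.abs(null[null < 0]).mean()
                    if (null < 0).any() else np.nan)
        if es >= 0:
            nes = es / pos_mean if pos_mean and not np.isnan(pos_mean) \
                else np.nan
        else:
            nes = es / neg_mean if neg_mean and not np.isnan(neg_mean) \
                else np.nan
        null_nes = np.where(null >= 0,
                            null / pos_mean if pos_mean else np.nan,
                            null / neg_mean if neg_mean else np.nan)
        null_nes_pool.append(null_nes)
        if es >= 0:
            leading = [g for g in genes[:peak + 1] if g in set(members)]
        else:
            leading = [g for g in genes[peak:] if g in set(members)]
        rows.append(dict(set=name, size=size, es=es, nes=float(nes),
                         leading_edge=leading))

    table = pd.DataFrame(rows)
    pooled = np.concatenate(null_nes_pool)
    pooled = pooled[np.isfinite(pooled)]
    obs = table["nes"].to_numpy()
    qvals = np.empty(len(obs))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            qvals[i] = np.nan
            continue
        if nes >= 0:
            null_frac = ((pooled >= nes).sum()
                         / max((pooled >= 0).sum(), 1))
            obs_frac = ((obs >= nes).sum()
                        / max((obs >= 0).sum(), 1))
        else:
            null_frac = ((pooled <= nes).sum()
                         / max((pooled <= 0).sum(), 1))
            obs_frac = ((obs <= nes).sum()
                        / max((obs <= 0).sum(), 1))
        qvals[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    table["q"] = qvals
    table = table[["set", "size", "es", "nes", "q", "leading_edge"]]
    return EnrichmentResult(table=table, ranked_genes=genes, n_perm=n_perm,
                            min_size=min_size)


def two_direction_report(result: EnrichmentResult, q_max: float = 0.05
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split enriched sets into positive- and negative-NES tables, each
    sorted by |NES| descending and filtered at *q_max*."""
    t = result.table
    if t.empty:
        return t.copy(), t.copy()
    pos = t[(t["nes"] > 0) & (t["q"] <= q_max)]
    neg = t[(t["nes"] < 0) & (t["q"] <= q_max)]
    key = lambda df: df.reindex(df["nes"].abs()
                                .sort_values(ascending=False).index)
    return key(pos).reset_index(drop=True), key(neg).reset_index(drop=True)
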