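import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodmark import discovery
from bloodmark.io import ValidationError
from bloodmark.preprocess import preprocess
from bloodmark.simulate import SimulationConfig, simulate_cohort

from conftest import make_matrix

SMALL = dict(n_probes=120, n_control_probes=10, n_dc_signature=10,
             n_reference=3)


class TestSurvivalClass:
    @pytest.mark.parametrize("months,expected", [
        (6, "short"), (30, "long"), (12.0, "medium"), (24.0, "medium"),
        (11.99, "short"), (24.01, "long"), (0.0, "short"),
    ])
    def test_boundaries(self, months, expected):
        assert discovery.survival_class(months) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            discovery.survival_class(-1.0)

    def test_vectorized(self):
        s = pd.Series([6.0, 18.0, 40.0], index=list("abc"))
        out = discovery.survival_class(s)
        assert list(out) == ["short", "medium", "long"]
        assert list(out.index) == list("abc")


def _oracle_unpaired_d(x, idx1, idx2, s0):
    """Straight transcription of the two-sample SAM statistic."""
    n1, n2 = len(idx1), len(idx2)
    d = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        a, b = x[i, idx1], x[i, idx2]
        num = b.mean() - a.mean()
        pooled = (((a - a.mean()) ** 2).sum()
                  + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
        s = np.sqrt((1 / n1 + 1 / n2) * pooled)
        d[i] = num / (s + s0)
    return d


class TestSamTwoClass:
    def test_identical_classes_give_zero_d(self, rng):
        x = rng.normal(8, 1, size=(10, 4))
        m = make_matrix(np.c_[x, x])
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=10, seed=0)
        assert np.allclose(res.d, 0.0)

    def test_d_matches_direct_formula_oracle(self, rng):
        m = make_matrix(rng.normal(8, 1, size=(20, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=10, seed=0)
        oracle = _oracle_unpaired_d(m.values.to_numpy(),
                                    np.arange(4), np.arange(4, 8), res.s0)
        assert np.allclose(res.d.to_numpy(), oracle, atol=1e-12)

    def test_exhaustive_null_matches_enumeration(self, rng):
        """4v4 permutation null equals the 70 explicit label assignments."""
        m = make_matrix(rng.normal(0, 1, size=(12, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=1000, seed=0)
        assert res.exhaustive
        assert res.perm_d.shape == (70, 12)
        x = m.values.to_numpy()
        expected = []
        for combo in itertools.combinations(range(8), 4):
            idx1 = np.array(combo)
            idx2 = np.setdiff1d(np.arange(8), idx1)
            expected.append(_oracle_unpaired_d(x, idx1, idx2, res.s0))
        assert np.allclose(res.perm_d, np.array(expected), atol=1e-12)

    def test_sample_order_invariance(self, rng):
        x = rng.normal(8, 1, size=(15, 10))
        m = make_matrix(x)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=20, seed=1)
        perm = rng.permutation(10)
        m2 = m.subset_samples([m.sample_ids[i] for i in perm])
        res2 = discovery.sam_two_class(m2, labels[m2.sample_ids],
                                       n_perm=20, seed=1)
        assert np.allclose(res.d, res2.d)

    def test_paired_requires_complete_pairing(self, rng):
        m = make_matrix(rng.normal(8, 1, size=(5, 6)))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=m.sample_ids)
        pairs = [(m.sample_ids[0], m.sample_ids[3])]  # incomplete
        with pytest.raises(ValidationError, match="cover"):
            discovery.sam_two_class(m, labels, paired=True, pairs=pairs)

    def test_small_class_rejected(self, rng):
        m = make_matrix(rng.normal(8, 1, size=(5, 4)))
        labels = pd.Series(["a", "b", "b", "b"], index=m.sample_ids)
        with pytest.raises(ValidationError, match="at least 2"):
            discovery.sam_two_class(m, labels)

    def test_paired_exhaustive_sign_flips(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(6, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        pairs = list(zip(m.sample_ids[:4], m.sample_ids[4:]))
        res = discovery.sam_two_class(m, labels, paired=True, pairs=pairs,
                                      n_perm=100, seed=0)
        assert res.exhaustive
        assert res.perm_d.shape == (16, 6)


def _cox_logpl(beta, x, time, event):
    """Breslow partial log-likelihood for one covariate."""
    ll = 0.0
    for t in np.unique(time[event]):
        deaths = (time == t) & event
        risk = time >= t
        ll += beta * x[deaths].sum() \
            - deaths.sum() * np.log(np.exp(beta * x[risk]).sum())
    return ll


class TestSamSurvival:
    def _matrix(self, rng, n=30, p=20):
        return make_matrix(rng.normal(8, 1, size=(p, n)))

    @pytest.mark.parametrize("censor", [False, True])
    def test_score_is_cox_derivative(self, rng, censor):
        """The numerator equals the numerical derivative of the Cox log
        partial likelihood at beta=0."""
        m = self._matrix(rng)
        time = rng.uniform(1, 40, 30)
        event = np.ones(30, dtype=bool)
        if censor:
            event[rng.choice(30, 8, replace=False)] = False
        months = pd.Series(time, index=m.sample_ids)
        ev = pd.Series(event, index=m.sample_ids)
        res = discovery.sam_survival(m, months, ev, n_perm=5, seed=0)
        h = 1e-5
        for i, probe in enumerate(m.probe_ids):
            x = m.values.loc[probe].to_numpy()
            deriv = (_cox_logpl(h, x, time, event)
                     - _cox_logpl(-h, x, time, event)) / (2 * h)
            assert res.r[probe] == pytest.approx(deriv, abs=1e-8)

    def test_constant_probe_scores_zero(self, rng):
        m = make_matrix(np.full((3, 20), 7.0))
        months = pd.Series(rng.uniform(1, 40, 20), index=m.sample_ids)
        ev = pd.Series(True, index=m.sample_ids)
        res = discovery.sam_survival(m, months, ev, n_perm=5, seed=0)
        assert np.allclose(res.r, 0.0)

    def test_zero_events_rejected(self, rng):
        m = self._matrix(rng, n=10, p=3)
        months = pd.Series(rng.uniform(1, 40, 10), index=m.sample_ids)
        ev = pd.Series(False, index=m.sample_ids)
        with pytest.raises(ValidationError, match="event"):
            discovery.sam_survival(m, months, ev)

    def test_planted_gene_ranks_top_percent(self):
        """A strongly planted gene (beta=1) lands in the top 1% of |d|."""
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(n_probes=500, n_control_probes=20,
                                   n_dc_signature=10, n_reference=3,
                                   beta=1.0, seed=seed)
            cohort = simulate_cohort(cfg)
            log2, _ = preprocess(cohort.pbmc)
            months, event = cohort.samples.survival(
                cohort.samples.pbmc_ids())
            res = discovery.sam_survival(log2, months, event, n_perm=20,
                                         seed=seed)
            probe = log2.probes_for_gene(cohort.planted_genes[0])[0]
            planted_probes = [q for g in cohort.planted_genes
                              for q in log2.probes_for_gene(g)]
            background = res.d.drop(planted_probes).abs()
            hits += abs(res.d[probe]) > background.quantile(0.99)
        assert hits >= 4


class TestCallAtPercentileFdrZero:
    def test_dominant_probe_called(self, rng):
        x = rng.normal(0, 1, size=(30, 12))
        x[0] += np.r_[np.full(6, -3.0), np.full(6, 3.0)]  # huge separation
        m = make_matrix(x)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=500, seed=0)
        called = discovery.call_at_percentile_fdr_zero(res)
        assert m.probe_ids[0] in called

    def test_call_set_matches_threshold_scan_oracle(self, rng):
        """The chosen delta is the smallest over a brute-force scan whose
        90th-percentile false-call count is zero, and the call set follows
        from its thresholds."""
        x = rng.normal(0, 1, size=(40, 12))
        x[:3] += np.r_[np.full(6, -2.0), np.full(6, 2.0)]
        m = make_matrix(x)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.sample_ids)
        res = discovery.sam_two_class(m, labels, n_perm=800, seed=3)
        called = discovery.call_at_percentile_fdr_zero(res)

        d = res.d.to_numpy()
        d_sorted = np.sort(d)
        dbar = np.sort(res.perm_d, axis=1).mean(axis=0)
        best = None
        for delta in np.unique(np.abs(d_sorted - dbar)):
            if delta <= 0:
                continue
            diff = d_sorted - dbar
            up = d_sorted[(diff >= delta) & (d_sorted > 0)]
            low = d_sorted[(diff <= -delta) & (d_sorted < 0)]
            cutup = up.min() if len(up) else np.inf
            cutlow = low.max() if len(low) else -np.inf
            counts = ((res.perm_d >= cutup)
                      | (res.perm_d <= cutlow)).sum(axis=1)
            if np.quantile(counts, 0.9, method="inverted_cdf") == 0:
                best = (delta, cutlow, cutup)
                break
        if best is None:
            assert called == []
        else:
            _, cutlow, cutup = best
            expected = list(res.d.index[(d >= cutup) | (d <= cutlow)])
            assert called == expected

    def test_pure_null_mostly_empty(self, rng):
        empties = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            m = make_matrix(r.normal(0, 1, size=(60, 12)))
            labels = pd.Series(["a"] * 6 + ["b"] * 6, index=m.sample_ids)
            res = discovery.sam_two_class(m, labels, n_perm=500, seed=seed)
            called = discovery.call_at_percentile_fdr_zero(res)
            empties += len(called) <= 1
        assert empties >= 4


class TestFoldChangeFilter:
    def _linear(self, rows):
        return make_matrix(np.asarray(rows, dtype=float), scale="raw")

    def test_fold_two_retained(self):
        m = self._linear([[10, 10, 5, 5]])
        kept, fold = discovery.fold_change_filter(
            m, long_ids=list(m.sample_ids[:2]),
            short_ids=list(m.sample_ids[2:]))
        assert fold.iloc[0] == pytest.approx(2.0)
        assert kept == [m.probe_ids[0]]

    def test_equal_means_dropped(self):
        m = self._linear([[7, 7, 7, 7]])
        kept, fold = discovery.fold_change_filter(
            m, list(m.sample_ids[:2]), list(m.sample_ids[2:]))
        assert fold.iloc[0] == pytest.approx(1.0)
        assert kept == []

    def test_log2_input_unlogged_first(self):
        # log2 means 4.0 vs 3.0 -> linear 16/8 = 2.0
        m = make_matrix([[4.0, 4.0, 3.0, 3.0]])
        kept, fold = discovery.fold_change_filter(
            m, list(m.sample_ids[:2]), list(m.sample_ids[2:]))
        assert fold.iloc[0] == pytest.approx(2.0)
        assert kept == [m.probe_ids[0]]

    def test_halving_also_retained(self):
        m = self._linear([[5, 5, 10, 10]])
        kept, _ = discovery.fold_change_filter(
            m, list(m.sample_ids[:2]), list(m.sample_ids[2:]))
        assert kept == [m.probe_ids[0]]

    def test_empty_group_rejected(self):
        m = self._linear([[1, 2]])
        with pytest.raises(ValidationError, match="non-empty"):
            discovery.fold_change_filter(m, [], list(m.sample_ids))


class TestPlsdaSelect:
    def test_separating_probe_attains_max_vip(self, rng):
        n = 24
        x = rng.normal(0, 1, size=(30, n))
        classes = np.array(["short"] * 8 + ["medium"] * 8 + ["long"] * 8)
        x[0] = np.where(classes == "short", -3.0, 3.0) \
            + rng.normal(0, 0.05, n)
        m = make_matrix(x + 8.0)
        labels = pd.Series(classes, index=m.sample_ids)
        selected, vip = discovery.plsda_select(m, labels, vip_threshold=1.0)
        assert vip.idxmax() == m.probe_ids[0]
        assert m.probe_ids[0] in selected

    def test_score_vectors_orthogonal(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        x = rng.normal(0, 1, size=(20, 40))
        y = pd.get_dummies(
            pd.Series(rng.choice(["a", "b", "c"], 20))).to_numpy(float)
        pls = PLSRegression(n_components=3, scale=False).fit(x, y)
        t = pls.x_scores_
        off = t.T @ t - np.diag(np.diag(t.T @ t))
        assert np.abs(off).max() < 1e-10

    def test_null_selection_is_sparse(self):
        """Shuffled class labels select at most a few percent of probes."""
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            m = make_matrix(r.normal(8, 1, size=(200, 30)))
            labels = pd.Series(r.permutation(["short"] * 10 + ["medium"] * 10
                                             + ["long"] * 10),
                               index=m.sample_ids)
            selected, _ = discovery.plsda_select(m, labels)
            hits += len(selected) <= 0.05 * m.n_probes
        assert hits >= 4

    def test_too_many_components_rejected(self, rng):
        m = make_matrix(rng.normal(8, 1, size=(30, 6)))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=m.sample_ids)
        with pytest.raises(ValidationError, match="n_components"):
            discovery.plsda_select(m, labels, n_components=6)


class TestTwoPass:
    def _cohort(self, seed=0, **kw):
        cfg = SimulationConfig(**{**SMALL, "seed": seed, **kw})
        cohort = simulate_cohort(cfg)
        log2, _ = preprocess(cohort.pbmc)
        dc_log2, _ = preprocess(cohort.dc)
        months, _ = cohort.samples.survival(cohort.samples.pbmc_ids())
        classes = discovery.survival_class(months)
        return cohort, log2, dc_log2, classes

    def test_gating_excludes_survival_only_probe(self, rng):
        """A probe separating long/short but identical in PBMC vs DC never
        reaches pass 2."""
        n_pairs = 16
        pbmc_vals = rng.normal(8, 0.5, size=(25, n_pairs))
        survival_probe = 0
        group = np.r_[np.full(8, -2.0), np.full(8, 2.0)]
        pbmc_vals[survival_probe] += group
        dc_vals = pbmc_vals + rng.normal(0, 0.5, size=pbmc_vals.shape)
        dc_vals[survival_probe] = pbmc_vals[survival_probe]  # no DC shift
        pbmc = make_matrix(pbmc_vals, sample_prefix="B")
        dc = make_matrix(dc_vals, sample_prefix="D")
        pairs = list(zip(pbmc.sample_ids, dc.sample_ids))
        classes = pd.Series(["short"] * 8 + ["long"] * 8,
                            index=pbmc.sample_ids)
        selected, info = discovery.two_pass_select(
            pbmc, dc, pairs, classes, n_perm=200, seed=0)
        assert pbmc.probe_ids[survival_probe] not in selected
        assert pbmc.probe_ids[survival_probe] not in info["pass1_called"]

    def test_planted_probe_retained(self):
        """Planted genes carry both the vaccination signature and the
        survival split, so at least one passes both gates."""
        cohort, log2, dc_log2, classes = self._cohort(seed=1)
        pairs = cohort.samples.pbmc_dc_pairs()
        selected, _ = discovery.two_pass_select(log2, dc_log2, pairs,
                                                classes, n_perm=300, seed=1)
        genes = {log2.gene_symbols[p] for p in selected}
        assert genes & set(cohort.planted_genes)

    def test_empty_pass1_returns_empty(self, rng):
        """Identical PBMC and DC values: pass 1 calls nothing, no error."""
        vals = rng.normal(8, 1, size=(30, 10))
        pbmc = make_matrix(vals, sample_prefix="B")
        dc = make_matrix(vals + rng.normal(0, 1e-3, vals.shape),
                         sample_prefix="D")
        pairs = list(zip(pbmc.sample_ids, dc.sample_ids))
        classes = pd.Series(["short"] * 5 + ["long"] * 5,
                            index=pbmc.sample_ids)
        selected, info = discovery.two_pass_select(pbmc, dc, pairs, classes,
                                                   n_perm=200, seed=0)
        assert selected == []


class TestIntersectCandidates:
    def _map(self, probes):
        return pd.Series({p: p.replace("PR_", "") for p in probes})

    def test_set_algebra(self):
        p2g = pd.Series({"p1": "A", "p2": "B", "p3": "C", "p4": "D"})
        panel = discovery.intersect_candidates(
            ["p1", "p2", "p3"], ["p2", "p3", "p4"], ["p2", "p3"], p2g)
        assert panel.genes == ["B", "C"]

    def test_empty_arm_empties_panel(self):
        p2g = pd.Series({"p1": "A"})
        panel = discovery.intersect_candidates(["p1"], [], ["p1"], p2g)
        assert panel.genes == []

    def test_provenance_bookkeeping(self):
        p2g = pd.Series({"p1": "A", "p2": "B"})
        panel = discovery.intersect_candidates(["p1"], ["p1", "p2"], ["p1"],
                                               p2g)
        prov = panel.provenance().set_index("gene")
        assert bool(prov.loc["A", "in_panel"])
        assert not bool(prov.loc["B", "in_panel"])

    def test_empty_symbols_dropped(self):
        p2g = pd.Series({"p1": "", "p2": "B"})
        panel = discovery.intersect_candidates(["p1", "p2"], ["p1", "p2"],
                                               ["p1", "p2"], p2g)
        assert panel.genes == ["B"]
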