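"""Mann-Whitney mechanics and condition-level comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from catrace.errors import ValidationError
from catrace.extraction import process_cohort
from catrace.groupstats import compare_conditions, mann_whitney_u, pool_groups
from catrace.kinetics import extract_cell_metrics
from catrace.protocol import AnalysisConfig
from catrace.simulate import generate_cohort
from tests.test_simulate import _preset


def brute_force_mwu(x, y):
    """Independent oracle: exact two-tailed p by enumerating every rank split."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    ranks = {}
    i = 0
    while i < len(pooled):  # midranks for ties
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        for k in range(i, j):
            ranks.setdefault(pooled[i], (i + j + 1) / 2)
        i = j
    n1, n2 = len(x), len(y)

    def u1_of(sample):
        r1 = sum(ranks[v] for v in sample)
        return r1 - n1 * (n1 + 1) / 2

    obs = u1_of(x)
    us = [u1_of(combo) for combo in itertools.combinations(pooled, n1)]
    us = np.array(us)
    p_low = np.mean(us <= obs)
    p_high = np.mean(us >= obs)
    return min(obs, n1 * n2 - obs), min(1.0, 2 * min(p_low, p_high))


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_degenerate_constant_samples(self):
        u, p = mann_whitney_u([5.0] * 4, [5.0] * 6)
        assert u == 12.0 and p == 1.0

    def test_u_statistics_sum_to_n1n2(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=7)
        u, _ = mann_whitney_u(x, y)
        assert 0 <= u <= 8 * 7
        # U is reported on the min convention, so U + U' = n1*n2 with U <= U'
        assert u <= 8 * 7 - u

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 5), (4, 6), (5, 7), (2, 9)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        """Exact-mode p equals brute-force enumeration over all C(n1+n2, n1) splits."""
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.8
        u_ref, p_ref = brute_force_mwu(x, y)
        u, p = mann_whitney_u(x, y, mode="exact")
        assert u == pytest.approx(u_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_p_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=15), rng.normal(size=15) + 0.5
        _, p0 = mann_whitney_u(x, y)
        _, p1 = mann_whitney_u(scale * x + shift, scale * y + shift)
        assert p1 == pytest.approx(p0, rel=1e-9)
        _, p2 = mann_whitney_u(np.exp(x), np.exp(y))  # nonlinear monotone
        assert p2 == pytest.approx(p0, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestPooling:
    def _two_group_metrics(self, protocol):
        parts = []
        for group, seed in (("ASD", 21), ("control", 22)):
            preset = _preset(
                group=group, mu_peak=2.5 if group == "ASD" else 2.2,
                responder_frac=0.6, n_cells_per_replicate=10,
            )
            cohort = generate_cohort(preset, protocol, seed)
            parts.append(
                extract_cell_metrics(process_cohort(cohort, protocol), protocol)
            )
        return pd.concat(parts, ignore_index=True)

    def test_cell_level_pool_sizes(self, protocol):
        metrics = self._two_group_metrics(protocol)
        samples = pool_groups(metrics, "max_rmr_fold", unit="cell")
        assert {k: v.size for k, v in samples.items()} == {"ASD": 60, "control": 60}

    def test_replicate_level_pool_sizes(self, protocol):
        metrics = self._two_group_metrics(protocol)
        samples = pool_groups(metrics, "max_rmr_fold", unit="replicate")
        assert {k: v.size for k, v in samples.items()} == {"ASD": 6, "control": 6}

    def test_line_relabel_leaves_pool_unchanged(self, protocol):
        metrics = self._two_group_metrics(protocol)
        ref = pool_groups(metrics, "max_rmr_fold")["ASD"]
        relabeled = metrics.copy()
        relabeled["line_id"] = relabeled["line_id"].map(
            lambda s: s.replace("1", "9")
        )
        got = pool_groups(relabeled, "max_rmr_fold")["ASD"]
        assert sorted(got) == sorted(ref)

    def test_missing_group_rejected(self, protocol):
        metrics = self._two_group_metrics(protocol)
        only_asd = metrics[metrics["group"] == "ASD"]
        with pytest.raises(ValidationError):
            compare_conditions(only_asd)


class TestCompareConditions:
    def test_five_results_per_condition(self, protocol):
        metrics = TestPooling()._two_group_metrics(protocol)
        results = compare_conditions(metrics)
        assert len(results) == 5
        assert {r.metric for r in results} == {
            "max_rmr_fold", "time_to_max_rmr", "max_iono_fold",
            "time_to_max_iono", "responder_percent",
        }
        frac = next(r for r in results if r.metric == "responder_percent")
        assert frac.test_unit == "replicate" and frac.n_per_group == (6, 6)

    def test_separated_presets_reach_significance(self, protocol):
        """Cohorts generated from the two pluripotent-stage presets separate
        decisively at cell level (the published direction, ASD > control)."""
        parts = []
        for group, seed in (("ASD", 31), ("control", 32)):
            preset = _preset(
                group=group, stage="iPSC",
                mu_peak=4.23 if group == "ASD" else 3.71,
                mu_ttp=82.59 if group == "ASD" else 49.87,
                responder_frac=1.0, mu_iono_peak=3.6, mu_iono_ttp=50.0,
                n_cells_per_replicate=50,
            )
            cohort = generate_cohort(preset, protocol, seed)
            parts.append(extract_cell_metrics(process_cohort(cohort, protocol), protocol))
        metrics = pd.concat(parts, ignore_index=True)
        res = next(
            r for r in compare_conditions(metrics) if r.metric == "max_rmr_fold"
        )
        means = {gs.group: gs.mean for gs in res.summaries}
        assert means["ASD"] > means["control"]
        assert res.p_two_tailed <= 1e-4

    def test_identical_presets_rarely_significant(self, protocol):
        """Null calibration: with both groups drawn from one preset, spurious
        p < 0.01 calls are rare across seeded repetitions."""
        clean = 0
        n_runs = 40
        for run in range(n_runs):
            parts = []
            for group, seed in (("ASD", 1000 + run), ("control", 5000 + run)):
                preset = _preset(
                    group=group, responder_frac=0.6, mu_peak=2.5,
                    n_cells_per_replicate=10, n_replicates=2,
                )
                cohort = generate_cohort(preset, protocol, seed)
                parts.append(
                    extract_cell_metrics(process_cohort(cohort, protocol), protocol)
                )
            results = compare_conditions(pd.concat(parts, ignore_index=True))
            if all(r.p_two_tailed >= 0.01 for r in results):
                clean += 1
        assert clean / n_runs >= 0.85

    def test_bh_adjustment_is_monotone(self, protocol):
        metrics = TestPooling()._two_group_metrics(protocol)
        results = compare_conditions(metrics, adjust="bh")
        ps = [r.p_two_tailed for r in results]
        qs = [r.p_adjusted for r in results]
        assert all(q >= p for p, q in zip(ps, qs))
        order_p = np.argsort(ps)
        assert np.all(np.diff(np.array(qs)[order_p]) >= -1e-12)
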