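"""Group statistics: exactness, invariances, calibration, summaries."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ercargo.metrics import MetricsTable
from ercargo.stats import (
    TestMethod as MWMethod,

    bh_adjust,
    compare_groups,
    mann_whitney,
    student_t,
    summarize,
)


# ---------------------------------------------------------------------------
# independent enumeration oracle for the exact Mann-Whitney p-value

def enumeration_p(x, y) -> tuple[float, float]:
    """(U, two-sided p) by enumerating every labeling of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx, ny = len(x), len(y)

    def u_x(indices):
        return ranks[list(indices)].sum() - nx * (nx + 1) / 2

    observed = u_x(range(nx))
    all_u = np.array(
        [u_x(c) for c in itertools.combinations(range(nx + ny), nx)]
    )
    lo = np.mean(all_u <= observed)
    hi = np.mean(all_u >= observed)
    return min(observed, nx * ny - observed), min(1.0, 2 * min(lo, hi))


class TestMannWhitneyExact:
    def test_textbook_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 labelings
        assert res.method is MWMethod.EXACT

    def test_exhaustive_agreement_with_enumeration(self):
        """Exact p equals full enumeration for every tie-free partition
        with pooled size <= 8 (ranks are sufficient: enumerate subsets)."""
        for n in range(2, 9):
            values = np.arange(1.0, n + 1)
            for nx in range(1, n):
                for subset in itertools.combinations(range(n), nx):
                    x = values[list(subset)]
                    y = np.delete(values, list(subset))
                    res = mann_whitney(x, y)
                    u_ref, p_ref = enumeration_p(x, y)
                    assert res.method is MWMethod.EXACT
                    assert res.U == u_ref
                    assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_singletons_degenerate(self):
        res = mann_whitney([5.0], [5.0])
        assert res.p == 1.0
        assert res.method is MWMethod.DEGENERATE

    def test_all_identical_values_degenerate(self):
        res = mann_whitney([2.0] * 5, [2.0] * 7)
        assert res.p == 1.0 and res.method is MWMethod.DEGENERATE


class TestMannWhitneyApprox:
    def test_ties_force_normal_approximation(self):
        res = mann_whitney([1, 2, 2], [2, 3, 4])
        assert res.method is MWMethod.NORMAL_APPROX
        assert 0 < res.p <= 1

    def test_approximation_close_to_exact_at_20_20(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            p_exact = sps.mannwhitneyu(x, y, method="exact").pvalue
            res = mann_whitney(x, y)  # 40 > exact limit -> approx
            assert res.method is MWMethod.NORMAL_APPROX
            assert abs(res.p - p_exact) <= 0.01

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(2024)
        n_reps = 1000
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            if mann_whitney(x, y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


class TestMannWhitneyProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_u_complement_and_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        y = rng.normal(size=6)
        res_xy = mann_whitney(x, y)
        res_yx = mann_whitney(y, x)
        assert res_xy.U == res_yx.U  # min convention is symmetric
        assert res_xy.p == pytest.approx(res_yx.p)
        assert 0 <= res_xy.U <= len(x) * len(y)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=12)
        y = rng.normal(size=15)
        base = mann_whitney(x, y)
        trans = mann_whitney(np.exp(x), np.exp(y))
        assert trans.U == base.U
        assert trans.p == pytest.approx(base.p)


class TestStudentT:
    def test_hand_computed_example(self):
        # means 2 vs 5, pooled variance 1, se = sqrt(2/3)
        res = student_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3 / math.sqrt(2 / 3), rel=1e-9)
        assert res.df == 4
        assert res.p == pytest.approx(0.02131, abs=5e-4)

    def test_identical_samples(self):
        res = student_t([1.0, 2.0], [1.0, 2.0])
        assert res.t == 0 and res.p == 1.0

    def test_zero_variance_branches(self):
        same = student_t([3.0, 3.0], [3.0, 3.0])
        assert same.p == 1.0 and same.degenerate
        apart = student_t([3.0, 3.0], [5.0, 5.0])
        assert apart.p == 0.0 and apart.degenerate

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 12))
        y = rng.normal(2.0, 1.5, size=rng.integers(3, 12))
        res = student_t(x, y)
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (
            nx + ny - 2
        )
        t_ref = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
        p_ref = 2 * sps.t.sf(abs(t_ref), nx + ny - 2)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)


def make_table(values_by_group, metric="bonds_per_100aa"):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "accession": f"{group}{i}",
                    "cargo_class": "secreted",
                    "induction_group": group,
                    metric: v,
                }
            )
    return MetricsTable(
        per_protein=pd.DataFrame(rows),
        bond_ranges=pd.DataFrame(
            columns=["accession", "cargo_class", "induction_group", "bond_range"]
        ),
    )


class TestCompareGroups:
    def test_summaries_and_test(self):
        t = make_table({"induced": [1, 2, 3, 10], "noninduced": [4, 5, 6, 7]})
        c = compare_groups(t, "bonds_per_100aa", "secreted")
        assert c.summary_a.n == 4 and c.summary_b.n == 4
        assert c.summary_a.mean == pytest.approx(4.0)
        ref = np.array([1, 2, 3, 10])
        assert c.summary_a.sem == pytest.approx(
            ref.std(ddof=1) / 2.0
        )
        assert c.summary_a.q25 <= c.summary_a.median <= c.summary_a.q75
        assert 0 < c.p <= 1

    def test_empty_group_is_explicit_error(self):
        t = make_table({"induced": [1.0, 2.0]})
        with pytest.raises(ValueError, match="empty group"):
            compare_groups(t, "bonds_per_100aa", "secreted")

    def test_shared_constant_is_degenerate(self):
        t = make_table({"induced": [2.0, 2.0], "noninduced": [2.0, 2.0, 2.0]})
        c = compare_groups(t, "bonds_per_100aa", "secreted")
        assert c.p == 1.0 and c.method is MWMethod.DEGENERATE

    def test_undefined_fractions_are_omitted_and_counted(self):
        t = make_table(
            {"induced": [0.5, np.nan, 0.8], "noninduced": [0.2, 0.3]},
            metric="fraction_cys_bonded",
        )
        c = compare_groups(t, "fraction_cys_bonded", "secreted")
        assert c.summary_a.n == 2
        assert c.n_omitted == 1


def test_bh_adjustment_is_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
    assert np.all(adj <= 1.0)


def test_summarize_rejects_empty():
    with pytest.raises(ValueError):
        summarize([])
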