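"""Agreement statistics against independent direct-formula oracles.

The oracles below share no code with the implementation: midranks are
computed by explicit sorting, mean squares by explicit sums.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from punctafiber import (
    build_report,
    dice,
    dunn_posthoc,
    icc_band,
    icc_two_way_mixed_absolute,
    iou,
    kruskal_wallis,
    spearman_rho,
)
from punctafiber.stats import AgreementReport, MethodTable

# ---------------------------------------------------------------------------
# oracle helpers


def oracle_midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_spearman(x, y):
    return oracle_pearson(oracle_midranks(x), oracle_midranks(y))


def oracle_icc_a1(table):
    n, k = len(table), len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def oracle_kruskal(groups):
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = oracle_midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        rbar = sum(r) / len(r)
        h += len(g) * (rbar - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else h


def oracle_dunn_z(groups, i, j):
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = oracle_midranks(pooled)
    means, sizes = [], []
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        means.append(sum(r) / len(r))
        sizes.append(len(g))
        start += len(g)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values())
    var = (n * (n + 1) / 12 - tie_term / (12 * (n - 1))) * (1 / sizes[i] + 1 / sizes[j])
    return (means[i] - means[j]) / math.sqrt(var)


# ---------------------------------------------------------------------------


class TestOverlap:
    def test_identical_masks(self, rng):
        m = rng.random((16, 16)) < 0.5
        assert iou(m, m) == 1.0
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert iou(a, b) == 0.0
        assert dice(a, b) == 0.0

    def test_partial_overlap(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a.ravel()[:4] = True
        b.ravel()[2:6] = True
        assert iou(a, b) == pytest.approx(2 / 6)
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty(self):
        z = np.zeros((4, 4), dtype=bool)
        assert iou(z, z) == 1.0
        assert dice(z, z) == 1.0

    def test_dice_iou_identity(self, rng):
        for _ in range(30):
            a = rng.random((12, 12)) < rng.random()
            b = rng.random((12, 12)) < rng.random()
            i, d = iou(a, b), dice(a, b)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestSpearman:
    def test_monotone_increasing(self):
        rho, p = spearman_rho([1, 2, 3], [2, 4, 6])
        assert rho == 1.0 and p == 0.0

    def test_monotone_decreasing(self):
        rho, p = spearman_rho([1, 2, 3], [6, 4, 2])
        assert rho == -1.0 and p == 0.0

    def test_tied_data_matches_oracle(self):
        x, y = [1, 2, 2, 3], [1, 3, 2, 4]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(oracle_spearman(list(x), list(y)), abs=1e-10)

    def test_scipy_p_value(self, rng):
        from scipy import stats as sps

        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_series_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestICC:
    def test_identical_columns(self, rng):
        col = rng.normal(size=8)
        est, p, band = icc_two_way_mixed_absolute(np.column_stack([col, col]))
        assert est == pytest.approx(1.0)
        assert band == "excellent"

    def test_offset_penalized(self, rng):
        col = rng.normal(size=10)
        est, _, _ = icc_two_way_mixed_absolute(np.column_stack([col, col + 2.0]))
        assert est < 1.0

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 5))
            table = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            est, _, _ = icc_two_way_mixed_absolute(table)
            assert est == pytest.approx(oracle_icc_a1(table.tolist()), abs=1e-10)

    def test_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        table = rng.normal(size=(9, 3)) + rng.normal(size=(9, 1)) * 3
        est, _, _ = icc_two_way_mixed_absolute(table)
        esta, _, _ = icc_two_way_mixed_absolute(table, average_measure=True)
        long = pd.DataFrame(
            {
                "s": np.repeat(np.arange(9), 3),
                "r": list("abc") * 9,
                "v": table.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="s", raters="r", ratings="v")
        ref = ref.set_index("Type")["ICC"]
        assert est == pytest.approx(ref["ICC(A,1)"], abs=1e-8)
        assert esta == pytest.approx(ref["ICC(A,k)"], abs=1e-8)

    def test_common_affine_invariance(self, rng):
        table = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        est1, _, _ = icc_two_way_mixed_absolute(table)
        est2, _, _ = icc_two_way_mixed_absolute(3.5 * table - 11.0)
        assert est1 == pytest.approx(est2, abs=1e-10)

    def test_degenerate_all_identical(self):
        est, p, band = icc_two_way_mixed_absolute(np.full((5, 3), 4.0))
        assert est == 1.0 and band == "excellent"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed_absolute(np.zeros((2, 2)))


class TestICCBand:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.795, "good"),
            (0.977, "excellent"),
            (0.859, "good"),
            (0.5, "moderate"),
            (0.4999, "poor"),
            (0.75, "good"),
            (0.9, "excellent"),
            (-0.3, "poor"),
        ],
    )
    def test_bands(self, value, expected):
        assert icc_band(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            icc_band(1.1)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert h == 0.0 and p == 1.0 and df == 2

    def test_hand_computed_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-12)
        assert df == 2

    def test_tie_correction_oracle(self, rng):
        for _ in range(100):
            groups = [
                rng.integers(0, 4, size=int(rng.integers(2, 6))).astype(float).tolist()
                for _ in range(int(rng.integers(2, 4)))
            ]
            pooled = [v for g in groups for v in g]
            if len(set(pooled)) == 1:
                continue
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_kruskal(groups), abs=1e-10)

    def test_scipy_cross_check(self, rng):
        from scipy import stats as sps

        groups = [rng.integers(0, 10, size=8).astype(float) for _ in range(3)]
        h, _, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=6).tolist() for _ in range(3)]
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])


class TestDunn:
    def test_identical_groups(self):
        out = dunn_posthoc([[3, 3], [3, 3], [3, 3]])
        assert (out["z"] == 0).all()
        assert (out["p_raw"] == 1).all()
        assert (out["p_adjusted"] == 1).all()

    def test_z_matches_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        out = dunn_posthoc(groups)
        for row, (i, j) in zip(out.itertuples(), itertools.combinations(range(3), 2)):
            assert row.z == pytest.approx(oracle_dunn_z(groups, i, j), abs=1e-10)

    def test_oracle_with_ties(self, rng):
        for _ in range(50):
            groups = [
                rng.integers(0, 4, size=5).astype(float).tolist() for _ in range(3)
            ]
            if len({v for g in groups for v in g}) == 1:
                continue
            out = dunn_posthoc(groups)
            for row, (i, j) in zip(out.itertuples(), itertools.combinations(range(3), 2)):
                assert row.z == pytest.approx(oracle_dunn_z(groups, i, j), abs=1e-10)

    def test_bonferroni_arithmetic(self, rng):
        groups = [rng.normal(size=6).tolist() for _ in range(3)]
        out = dunn_posthoc(groups)
        for row in out.itertuples():
            assert row.p_adjusted == pytest.approx(min(1.0, 3 * row.p_raw), abs=1e-12)


class TestMethodTable:
    def test_from_long_drops_incomplete(self, caplog):
        df = pd.DataFrame(
            {
                "image_id": ["a", "a", "b", "b", "c"],
                "method": ["m1", "m2", "m1", "m2", "m1"],
                "n_puncta": [1, 2, 3, 4, 5],
            }
        )
        mt = MethodTable.from_long(df, "n_puncta")
        assert mt.image_ids == ["a", "b"]
        assert mt.values.shape == (2, 2)


class TestBuildReport:
    def _quant(self, rng, n=10, noise=0.0):
        base = rng.integers(5, 40, size=n).astype(float)
        rows = []
        for method, offset in (("rf", 0.0), ("external", noise)):
            jitter = rng.normal(0, noise, size=n) if noise else np.zeros(n)
            for i in range(n):
                rows.append(
                    {
                        "image_id": f"img{i:03d}",
                        "method": method,
                        "n_puncta": base[i] + jitter[i],
                        "mfi_au": 100 + base[i] + jitter[i],
                        "fiber_area_um2": 200 + base[i] + jitter[i],
                        "threshold": 200,
                        "pixel_size_um": 0.16,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_methods(self, rng):
        report = build_report(self._quant(rng, noise=0.0))
        for measure in ("n_puncta", "mfi_au", "fiber_area_um2"):
            assert report.icc[measure]["estimate"] == pytest.approx(1.0)
        assert report.kruskal["p"] == pytest.approx(1.0, abs=0.05)

    def test_icc_decreases_with_noise(self, rng):
        estimates = []
        for noise in (0.0, 2.0, 8.0, 30.0):
            r = build_report(self._quant(np.random.default_rng(4), noise=noise))
            estimates.append(r.icc["n_puncta"]["estimate"])
        assert estimates == sorted(estimates, reverse=True)

    def test_manual_counts_included(self, rng):
        quant = self._quant(rng)
        manual = pd.DataFrame(
            {
                "image_id": [f"img{i:03d}" for i in range(10) for _ in range(3)],
                "rater": ["r1", "r2", "r3"] * 10,
                "n_puncta": rng.integers(5, 40, size=30),
            }
        )
        report = build_report(quant, manual_counts=manual)
        assert "manual" in report.methods
        assert any("manual" in k for k in report.spearman)
        assert set(report.icc) == {"n_puncta", "mfi_au", "fiber_area_um2"}

    def test_json_round_trip(self, rng, tmp_path):
        report = build_report(self._quant(rng, noise=1.0))
        path = tmp_path / "report.json"
        report.to_json(path)
        back = AgreementReport.from_json(path)
        assert back.to_dict() == report.to_dict()

    def test_insufficient_overlap(self):
        df = pd.DataFrame(
            {
                "image_id": ["a", "b"],
                "method": ["rf", "external"],
                "n_puncta": [1, 2],
                "mfi_au": [1, 2],
                "fiber_area_um2": [1, 2],
            }
        )
        with pytest.raises(ValueError, match="insufficient overlap"):
            build_report(df)
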