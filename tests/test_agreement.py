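import math
from fractions import Fraction

import numpy as np
import pytest

import hrdquant as hq
from hrdquant import agreement as ag


# ----------------------------------------------------- brute-force oracles

def dice_oracle(a, b):
    """Exact rational Dice on integer sets."""
    sa = {tuple(p) for p in np.argwhere(np.asarray(a) > 0)}
    sb = {tuple(p) for p in np.argwhere(np.asarray(b) > 0)}
    if not sa and not sb:
        return Fraction(1)
    return Fraction(2 * len(sa & sb), len(sa) + len(sb))


def icc21_oracle(x, y):
    """ICC(2,1) from two-way ANOVA mean squares, computed from scratch."""
    n, k = len(x), 2
    table = [[float(a), float(b)] for a, b in zip(x, y)]
    grand = sum(sum(r) for r in table) / (n * k)
    rowm = [sum(r) / k for r in table]
    colm = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in rowm)
    ssc = n * sum((m - grand) ** 2 for m in colm)
    sst = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else math.inf
    from scipy import stats
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 3, (2, 8, 8))
        assert ag.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((1, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((1, 4, 4)); b[0, 3, 3] = 1
        assert ag.dice(a, b) == 0.0

    def test_small_overlap_exact(self):
        a = np.zeros((1, 4, 4)); a[0, 0, :3] = 1
        b = np.zeros((1, 4, 4)); b[0, 0, 1:4] = 1
        assert ag.dice(a, b) == pytest.approx(2 / 3, rel=1e-15)

    def test_both_empty_is_one(self):
        z = np.zeros((1, 4, 4))
        assert ag.dice(z, z) == 1.0

    def test_matches_exact_rational_oracle(self, rng):
        for _ in range(100):
            a = rng.integers(0, 3, (8, 8))
            b = rng.integers(0, 3, (8, 8))
            assert abs(ag.dice(a, b) - float(dice_oracle(a, b))) < 1e-12
            for lbl in (1, 2):
                oracle = dice_oracle(a == lbl, b == lbl)
                assert abs(ag.dice(a, b, lbl) - float(oracle)) < 1e-12

    def test_symmetry(self, rng):
        a, b = rng.integers(0, 2, (6, 6)), rng.integers(0, 2, (6, 6))
        assert ag.dice(a, b) == ag.dice(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ag.dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestICC:
    def test_identical_columns_give_one(self):
        s = ag.PairedSeries(np.array([1.0, 2, 3, 4, 5]), np.array([1.0, 2, 3, 4, 5]))
        assert ag.icc(s)["icc"] == pytest.approx(1.0)

    def test_toy_table_matches_anova_oracle(self):
        x = [9.0, 6.0, 8.0, 7.0, 10.0, 6.0]
        y = [2.0, 1.0, 4.0, 1.0, 5.0, 2.0]
        s = ag.PairedSeries(np.array(x), np.array(y))
        assert ag.icc(s)["icc"] == pytest.approx(icc21_oracle(x, y), abs=1e-8)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0, 0.5, n)
            s = ag.PairedSeries(x, y)
            assert ag.icc(s)["icc"] == pytest.approx(icc21_oracle(x, y), abs=1e-8)

    def test_constant_offset_decreases_absolute_agreement(self, rng):
        x = rng.normal(0, 1, 20)
        base = ag.icc(ag.PairedSeries(x, x.copy()))["icc"]
        shifted = ag.icc(ag.PairedSeries(x, x + 1.0))["icc"]
        assert shifted < base
        # consistency form is blind to the constant shift
        cons = ag.icc(ag.PairedSeries(x, x + 1.0), model="consistency")["icc"]
        assert cons == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_undefined(self):
        s = ag.PairedSeries(np.full(6, 2.0), np.full(6, 2.0))
        out = ag.icc(s)
        assert not out["defined"]
        assert math.isnan(out["icc"])

    def test_against_pingouin(self, rng):
        """Independent cross-check of estimate and CI against pingouin ICC2."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        x = rng.normal(10, 3, 15)
        y = x + rng.normal(0, 1, 15) + 0.5
        df = pd.DataFrame({
            "targets": list(range(15)) * 2,
            "raters": ["a"] * 15 + ["b"] * 15,
            "scores": np.concatenate([x, y]),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type")
        mine = ag.icc(ag.PairedSeries(x, y))
        assert mine["icc"] == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-6)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds the CI to 2 dp
        assert mine["ci95"][0] == pytest.approx(lo, abs=0.02)
        assert mine["ci95"][1] == pytest.approx(hi, abs=0.02)

    def test_symmetric_under_rater_exchange(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        assert ag.icc(ag.PairedSeries(x, y))["icc"] == \
            pytest.approx(ag.icc(ag.PairedSeries(y, x))["icc"], abs=1e-12)


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        out = ag.pearson(ag.PairedSeries(x, 2 * x + 1))
        assert out["r"] == pytest.approx(1.0)

    def test_ten_pair_series_matches_textbook_formula(self, rng):
        x = rng.normal(0, 2, 10)
        y = 0.5 * x + rng.normal(0, 1, 10)
        out = ag.pearson(ag.PairedSeries(x, y))
        r_ref, p_ref = pearson_oracle(list(x), list(y))
        assert out["r"] == pytest.approx(r_ref, abs=1e-10)
        assert out["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_affine_invariance(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        r1 = ag.pearson(ag.PairedSeries(x, y))["r"]
        r2 = ag.pearson(ag.PairedSeries(3 * x + 5, 0.1 * y - 2))["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_undefined(self):
        out = ag.pearson(ag.PairedSeries(np.ones(5), np.arange(5.0)))
        assert not out["defined"]


class TestBlandAltman:
    def test_identical_series_loa_zero(self):
        x = np.array([1.0, 2, 3])
        out = ag.bland_altman(ag.PairedSeries(x, x.copy()))
        assert out["loa_lower"] == out["loa_upper"] == 0.0

    def test_hand_computed_example(self):
        s = ag.PairedSeries(np.array([1.0, 2, 3]), np.array([1.2, 1.8, 3.1]))
        out = ag.bland_altman(s)
        assert out["mean_diff"] == pytest.approx(-0.0333, abs=1e-4)
        assert out["loa_lower"] == pytest.approx(-0.441, abs=1e-3)
        assert out["loa_upper"] == pytest.approx(0.375, abs=1e-3)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        ab = ag.bland_altman(ag.PairedSeries(x, y))
        ba = ag.bland_altman(ag.PairedSeries(y, x))
        assert ab["mean_diff"] == pytest.approx(-ba["mean_diff"], abs=1e-12)
        assert ab["loa_lower"] == pytest.approx(-ba["loa_upper"], abs=1e-12)

    def test_matches_direct_formula_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
            out = ag.bland_altman(ag.PairedSeries(x, y))
            d = x - y
            mean = sum(d) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1)) if n > 1 else 0.0
            assert out["mean_diff"] == pytest.approx(mean, abs=1e-10)
            assert out["loa_upper"] == pytest.approx(mean + 1.96 * sd, abs=1e-10)


class TestDiceAreaCorrelation:
    def test_constant_dice_undefined(self):
        out = ag.dice_area_correlation([0.7] * 6, [1.0, 2, 3, 4, 5, 6])
        assert not out["defined"]

    def test_size_dependent_noise_gives_positive_r(self):
        rng = np.random.default_rng(0)
        areas = rng.uniform(0.1, 2.0, 20)
        dice_vals = 0.5 + 0.2 * areas / 2 + rng.normal(0, 0.02, 20)
        out = ag.dice_area_correlation(dice_vals, areas)
        assert out["r"] > 0

    def test_joint_permutation_invariance(self, rng):
        d = rng.uniform(0.3, 0.9, 10)
        a = rng.uniform(0.1, 1.0, 10)
        perm = rng.permutation(10)
        assert ag.dice_area_correlation(d, a)["r"] == \
            pytest.approx(ag.dice_area_correlation(d[perm], a[perm])["r"], abs=1e-12)


class TestBuildReport:
    @pytest.fixture(scope="class")
    def report_inputs(self):
        rng = np.random.default_rng(42)
        masks, sums = [], []
        for s in range(6):
            spec = hq.PhantomSpec(shape=(2, 256, 256), seed=500 + s)
            vol, mask, _ = hq.generate_volume(spec)
            _, comps = hq.hrd_classify.classify_all(mask.labels > 0, vol, vol.spacing_um)
            sums.append(hq.summarize(
                [c for c in comps if c.hrd_class is not hq.HRDClass.NOISE],
                vol.spacing_um, vol.shape))
            masks.append(mask)
        return masks, sums

    def test_self_comparison_is_perfect(self, report_inputs):
        masks, sums = report_inputs
        rep = ag.build_report(list(zip(masks, masks)), sums, sums)
        for mean, sd in rep.dice_mean_sd.values():
            assert mean == 1.0
        for roi in rep.per_parameter.values():
            for st in roi.values():
                assert st["icc"]["icc"] == pytest.approx(1.0) or \
                    math.isnan(st["icc"]["icc"])  # zero-variance params undefined
                assert st["bland_altman"]["loa_lower"] == 0.0
                assert st["bland_altman"]["loa_upper"] == 0.0

    def test_schema_covers_six_parameters_three_rois(self, report_inputs):
        masks, sums = report_inputs
        rep = ag.build_report(list(zip(masks, masks)), sums, sums)
        assert set(rep.per_parameter) == {"full_6x6", "circle_3mm", "circle_1mm"}
        for roi in rep.per_parameter.values():
            assert len(roi) == 6
        df = rep.to_frame()
        assert len(df) == 18

    def test_deterministic(self, report_inputs):
        import json
        masks, sums = report_inputs
        r1 = ag.build_report(list(zip(masks, masks)), sums, sums).to_dict()
        r2 = ag.build_report(list(zip(masks, masks)), sums, sums).to_dict()
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
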