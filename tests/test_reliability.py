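"""ICC correctness against independent oracles, bands, discrepancy audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corelex import (ModalityMismatchError, compare_modalities,
                     error_proportion, icc_two_way_random_agreement,
                     interpret_icc)
from corelex.reliability import RatingsMatrix
from corelex.scoring import ChecklistScore, ScoreTable

# Classic 6 targets x 4 judges worked example (Shrout & Fleiss).
SF_MATRIX = np.array([[9, 2, 5, 8],
                      [6, 1, 3, 2],
                      [8, 4, 6, 8],
                      [7, 1, 2, 6],
                      [10, 5, 6, 9],
                      [6, 2, 4, 7]], dtype=float)


def anova_oracle(x):
    """Brute-force two-way ANOVA by explicit loops (independent oracle)."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(x[i, :]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(x[:, j]) / n - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def table(values, task="T", items=("a", "b", "c", "d"), hash_="h"):
    rows = []
    for sid, per in values.items():
        rows.append(ChecklistScore(sample_id=sid, task_id=task,
                                   per_item=dict(zip(items, per)),
                                   lexicon_hash=hash_))
    return ScoreTable(rows=rows, task_id=task)


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([[3, 3], [7, 7], [11, 11], [5, 5]], float)
        res = icc_two_way_random_agreement(RatingsMatrix(values=x))
        assert res.icc == 1.0

    def test_all_equal_cells_flagged_degenerate(self):
        x = np.full((4, 2), 6.0)
        res = icc_two_way_random_agreement(RatingsMatrix(values=x))
        assert res.icc == 1.0 and res.degenerate

    def test_shrout_fleiss_example(self):
        res = icc_two_way_random_agreement(RatingsMatrix(values=SF_MATRIX))
        assert res.icc == pytest.approx(0.2898, abs=5e-4)
        assert res.ci_low == pytest.approx(0.019, abs=2e-3)
        assert res.ci_high == pytest.approx(0.761, abs=2e-3)
        assert res.icc == pytest.approx(anova_oracle(SF_MATRIX), abs=1e-12)

    def test_agreement_penalizes_offset(self):
        base = np.arange(1.0, 11.0)
        x = np.column_stack([base, base + 5])
        res = icc_two_way_random_agreement(RatingsMatrix(values=x))
        # consistency-type ICC on the same data ignores the column offset
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) \
            / ((n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc < icc_consistency

    def test_adding_offset_strictly_decreases_icc(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, (12, 2))
        base = icc_two_way_random_agreement(RatingsMatrix(values=x)).icc
        x2 = x.copy()
        x2[:, 1] += 4
        shifted = icc_two_way_random_agreement(RatingsMatrix(values=x2)).icc
        assert shifted < base

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 2, (9, 3))
        res = icc_two_way_random_agreement(RatingsMatrix(values=x)).icc
        perm = rng.permutation(9)
        res_p = icc_two_way_random_agreement(RatingsMatrix(values=x[perm])).icc
        assert res == pytest.approx(res_p, abs=1e-12)

    @pytest.mark.parametrize("trial", range(200))
    def test_closed_form_matches_loop_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 21))
        k = int(rng.integers(2, 4))
        x = rng.normal(5, 2, (n, k)) + rng.normal(0, 1.5, (n, 1))
        res = icc_two_way_random_agreement(RatingsMatrix(values=x))
        assert abs(res.icc - anova_oracle(x)) <= 1e-10

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_pingouin(self, trial):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1000 + trial)
        n, k = int(rng.integers(6, 15)), int(rng.integers(2, 4))
        x = rng.normal(5, 2, (n, k)) + rng.normal(0, 1, (n, 1))
        res = icc_two_way_random_agreement(RatingsMatrix(values=x))
        resk = icc_two_way_random_agreement(RatingsMatrix(values=x),
                                            average=True)
        df = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                           "raters": np.tile(np.arange(k), n),
                           "score": x.ravel()})
        icc = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score").set_index("Type")
        assert res.icc == pytest.approx(icc.loc["ICC(A,1)"].ICC, abs=1e-9)
        assert resk.icc == pytest.approx(icc.loc["ICC(A,k)"].ICC, abs=1e-9)
        lo, hi = icc.loc["ICC(A,1)"].CI95
        if lo > -0.9:  # away from the transform singularity
            assert res.ci_low == pytest.approx(lo, abs=6e-3)
            assert res.ci_high == pytest.approx(hi, abs=6e-3)


    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 2**20),
           shift=st.floats(-20, 20, allow_nan=False),
           scale=st.floats(0.1, 10, allow_nan=False))
    def test_affine_invariance_and_bound(self, seed, shift, scale):
        # ICC is a variance ratio: shared affine rescaling of all cells
        # cannot change it, and it never exceeds 1.
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 2, (8, 3)) + rng.normal(0, 1.5, (8, 1))
        r0 = icc_two_way_random_agreement(RatingsMatrix(values=x))
        r1 = icc_two_way_random_agreement(
            RatingsMatrix(values=x * scale + shift))
        assert r0.icc <= 1.0
        assert r1.icc == pytest.approx(r0.icc, abs=1e-8)


class TestBands:
    @pytest.mark.parametrize("value,band", [
        (0.978, "excellent"), (0.9, "excellent"), (0.899, "good"),
        (0.75, "good"), (0.749, "moderate"), (0.5, "moderate"),
        (0.49, "poor"), (0.0, "poor"), (-0.2, "poor"), (1.0, "excellent"),
    ])
    def test_cutpoints(self, value, band):
        assert interpret_icc(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_icc(1.01)


class TestCompareModalities:
    def test_identical_tables_empty_report(self):
        a = table({"s1": (1, 0, 1, 1), "s2": (0, 0, 1, 0)})
        report = compare_modalities(a, a)
        assert len(report) == 0

    def test_single_omission_direction(self):
        a = table({"s1": (1, 0, 1, 1)})
        b = table({"s1": (1, 0, 0, 1)})
        report = compare_modalities(a, b)
        assert len(report) == 1
        entry = report.entries[0]
        assert (entry.sample_id, entry.item) == ("s1", "c")
        assert entry.direction == "a_only"
        assert report.counts == {"a_only": 1, "b_only": 0}

    def test_antisymmetry(self):
        a = table({"s1": (1, 0, 1, 1), "s2": (0, 1, 1, 0)})
        b = table({"s1": (1, 1, 0, 1), "s2": (0, 0, 1, 0)})
        fwd = compare_modalities(a, b)
        rev = compare_modalities(b, a)
        assert {(e.sample_id, e.item, e.direction) for e in fwd} == \
            {(e.sample_id, e.item,
              "a_only" if e.direction == "b_only" else "b_only")
             for e in rev}

    def test_sample_mismatch_rejected(self):
        a = table({"s1": (1, 0, 1, 1)})
        b = table({"s2": (1, 0, 1, 1)})
        with pytest.raises(ModalityMismatchError, match="sample"):
            compare_modalities(a, b)

    def test_checklist_version_mismatch_rejected(self):
        a = table({"s1": (1, 0, 1, 1)}, hash_="v1")
        b = table({"s1": (1, 0, 1, 1)}, hash_="v2")
        with pytest.raises(ModalityMismatchError, match="checklist"):
            compare_modalities(a, b)


class TestErrorProportion:
    @pytest.mark.parametrize("errors,items,samples,expected", [
        (5, 10, 10, 0.05),
        (0, 34, 48, 0.0),
        (13, 24, 48, 13 / (24 * 48)),
    ])
    def test_formula(self, errors, items, samples, expected):
        assert error_proportion(errors, items, samples) \
            == pytest.approx(expected)

    def test_broken_window_cell_rounds_to_1_1_percent(self):
        # 13 hand-scoring errors over 24 items x 48 samples
        assert round(100 * error_proportion(13, 24, 48), 1) == 1.1

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            error_proportion(1, 0, 5)
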