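"""Clock engine: table loading, probe policies, linear scoring, Horvath transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfaging.clocks import (
    ClockDefinition,
    ClockFormatError,
    MissingProbeError,
    compute_dnam_age,
    horvath_forward,
    horvath_inverse,
    intersect_probes,
    linear_predictor,
    load_clock_table,
)


def write_table(tmp_path, rows, name="clock.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["probe_id", "coefficient"]).to_csv(path, index=False)
    return path


class TestLoadClockTable:
    def test_intercept_separated_from_probes(self, tmp_path):
        path = write_table(tmp_path, [("(Intercept)", 1.5), ("cg1", 2.0), ("cg2", -0.5)])
        clock = load_clock_table(path, name="toy")
        assert clock.intercept == 1.5
        assert clock.coefficients == {"cg1": 2.0, "cg2": -0.5}

    def test_intercept_only_table_rejected(self, tmp_path):
        path = write_table(tmp_path, [("(Intercept)", 1.0)])
        with pytest.raises(ClockFormatError):
            load_clock_table(path, name="toy")

    def test_duplicate_probe_rejected(self, tmp_path):
        path = write_table(tmp_path, [("(Intercept)", 0.0), ("cg1", 1.0), ("cg1", 2.0)])
        with pytest.raises(ClockFormatError, match="duplicated"):
            load_clock_table(path, name="toy")

    def test_missing_intercept_rejected(self, tmp_path):
        path = write_table(tmp_path, [("cg1", 1.0)])
        with pytest.raises(ClockFormatError, match="Intercept"):
            load_clock_table(path, name="toy")


def toy_clock(coeffs, intercept=0.0, **kw):
    return ClockDefinition(name="toy", intercept=intercept, coefficients=coeffs, **kw)


def beta_frame(data, samples=None):
    return pd.DataFrame(data, index=list(data.keys()) if isinstance(data, dict) else None)


class TestIntersectProbes:
    def test_all_probes_present(self):
        clock = toy_clock({"a": 1, "b": 1, "c": 1})
        m = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["s1"])
        avail = intersect_probes(clock, {"CSF": m, "blood": m})
        assert avail.n_retained == 3 and avail.n_missing == 0

    def test_probe_missing_in_one_tissue(self):
        clock = toy_clock({"a": 1, "b": 1, "c": 1})
        csf = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["s1"])
        blood = pd.DataFrame(0.5, index=["a", "b"], columns=["s2"])
        avail = intersect_probes(clock, {"CSF": csf, "blood": blood})
        assert avail.n_retained == 2 and avail.missing == ("c",)

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"cg{i}" for i in range(50)]
        for _ in range(20):
            clock_probes = list(rng.choice(universe, size=15, replace=False))
            mats = {
                t: pd.DataFrame(0.5, index=rng.choice(universe, size=30, replace=False), columns=["s"])
                for t in ("CSF", "blood")
            }
            clock = toy_clock({p: 1.0 for p in clock_probes})
            avail = intersect_probes(clock, mats)
            expected = set(clock_probes) & set(mats["CSF"].index) & set(mats["blood"].index)
            assert set(avail.retained) == expected
            assert set(avail.missing) == set(clock_probes) - expected


class TestLinearPredictor:
    def test_worked_example(self):
        clock = toy_clock({"cg1": 2.0}, intercept=0.5)
        betas = pd.DataFrame({"s1": [0.25]}, index=["cg1"])
        assert linear_predictor(clock, betas)["s1"] == pytest.approx(1.0)

    def test_zero_coefficients_give_intercept(self):
        clock = toy_clock({"cg1": 0.0, "cg2": 0.0}, intercept=3.25)
        betas = pd.DataFrame(np.random.default_rng(1).random((2, 4)), index=["cg1", "cg2"])
        assert np.allclose(linear_predictor(clock, betas), 3.25)

    def test_matches_bruteforce_dot_product(self):
        rng = np.random.default_rng(2)
        probes = [f"cg{i}" for i in range(50)]
        coeffs = dict(zip(probes, rng.normal(size=50)))
        clock = toy_clock(coeffs, intercept=rng.normal())
        betas = pd.DataFrame(rng.random((50, 7)), index=probes, columns=[f"s{j}" for j in range(7)])
        got = linear_predictor(clock, betas)
        for s in betas.columns:
            expected = clock.intercept + sum(coeffs[p] * betas.loc[p, s] for p in probes)
            assert abs(got[s] - expected) < 1e-12

    def test_beta_out_of_range_rejected(self):
        clock = toy_clock({"cg1": 1.0})
        betas = pd.DataFrame({"s1": [1.5]}, index=["cg1"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            linear_predictor(clock, betas)

    def test_empty_probe_set_rejected(self):
        clock = toy_clock({"cg1": 1.0})
        betas = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        with pytest.raises(ValueError, match="empty"):
            linear_predictor(clock, betas, probe_set=[])

    def test_per_sample_standardization_shift_invariance(self):
        """Adding a constant to all of a sample's betas leaves its score unchanged."""
        rng = np.random.default_rng(3)
        probes = [f"cg{i}" for i in range(20)]
        clock = toy_clock(dict(zip(probes, rng.normal(size=20))), standardize_per_sample=True)
        base = rng.uniform(0.2, 0.5, size=(20, 3))
        b1 = pd.DataFrame(base, index=probes)
        b2 = pd.DataFrame(base + 0.3, index=probes)
        assert np.allclose(linear_predictor(clock, b1), linear_predictor(clock, b2), atol=1e-10)


class TestHorvathTransform:
    def test_boundary_maps_to_adult_age(self):
        assert horvath_inverse(0.0) == pytest.approx(20.0)

    def test_unit_score_maps_to_41(self):
        # forward transform of age 41 is (41-20)/21 = 1
        assert horvath_inverse(1.0) == pytest.approx(41.0)

    def test_forward_inverse_round_trip(self):
        for age in (0.0, 5.0, 20.0, 60.0, 100.0):
            assert horvath_inverse(horvath_forward(age)) == pytest.approx(age, abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            horvath_inverse(float("nan"))

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo < 1e-9:  # below float resolution of the transform
            return
        assert horvath_inverse(lo) < horvath_inverse(hi)


class TestComputeDnamAge:
    def test_drop_missing_policy_counts(self):
        clock = toy_clock({"cg1": 2.0, "cg2": 5.0}, intercept=1.0)
        betas = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        out = compute_dnam_age(clock, betas, probe_policy="drop_missing")
        assert out.loc["s1", "n_probes_used"] == 1
        assert out.loc["s1", "n_probes_missing"] == 1
        assert out.loc["s1", "dnam_age"] == pytest.approx(1.0 + 2.0 * 0.5)

    def test_strict_policy_raises_on_missing(self):
        clock = toy_clock({"cg1": 2.0, "cg2": 5.0})
        betas = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        with pytest.raises(MissingProbeError):
            compute_dnam_age(clock, betas, probe_policy="strict")

    def test_transform_compositionality(self):
        rng = np.random.default_rng(4)
        probes = [f"cg{i}" for i in range(10)]
        coeffs = dict(zip(probes, rng.normal(scale=0.2, size=10)))
        betas = pd.DataFrame(rng.random((10, 5)), index=probes, columns=list("abcde"))
        ident = toy_clock(coeffs, intercept=0.1)
        horv = ClockDefinition(name="h", intercept=0.1, coefficients=coeffs, transform="horvath_inverse")
        raw = compute_dnam_age(ident, betas)["dnam_age"].to_numpy()
        years = compute_dnam_age(horv, betas)["dnam_age"].to_numpy()
        assert np.allclose(years, horvath_inverse(raw), atol=1e-12)

    def test_probe_accounting_invariant(self, small_cohort):
        clock = small_cohort["clock"].clock
        out = compute_dnam_age(clock, small_cohort["betas"])
        assert (out["n_probes_used"] + out["n_probes_missing"] == clock.n_probes).all()

    def test_matches_per_sample_loop_oracle(self):
        """Vectorised scoring equals a naive per-sample loop within 1e-10."""
        rng = np.random.default_rng(5)
        probes = [f"cg{i}" for i in range(30)]
        coeffs = dict(zip(probes, rng.normal(size=30)))
        clock = ClockDefinition(name="h", intercept=rng.normal(), coefficients=coeffs,
                                transform="horvath_inverse")
        betas = pd.DataFrame(rng.random((30, 8)), index=probes, columns=[f"s{j}" for j in range(8)])
        out = compute_dnam_age(clock, betas)
        for s in betas.columns:
            score = clock.intercept + sum(coeffs[p] * betas.loc[p, s] for p in probes)
            assert abs(out.loc[s, "dnam_age"] - horvath_inverse(score)) < 1e-10
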