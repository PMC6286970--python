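import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from profalign import (
    ASYMMETRIC,
    NoAdmissiblePathError,
    StepPattern,
    StructureProfile,
    brute_force_dtw,
    dtw_obe,
    dtw_standard,
    gen_profile,
    local_cost,
    normalize_distance,
    perturb_profile,
)

from conftest import random_profile


class TestLocalCost:
    @pytest.mark.parametrize(
        "x,y,expected", [(0.7, 0.7, 0.0), (1, -1, 2.0), (-0.3, 0.4, 0.7)]
    )
    def test_manhattan(self, x, y, expected):
        assert local_cost(x, y) == pytest.approx(expected)


class TestNormalization:
    def test_modes(self):
        assert normalize_distance(6, 2, 4, "sum_lengths") == 1.0
        assert normalize_distance(6, 2, 4, "query_length") == 3.0
        assert normalize_distance(6, 2, 4, "reference_length") == 1.5
        for mode in ("sum_lengths", "query_length", "reference_length"):
            assert normalize_distance(0, 3, 5, mode) == 0.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_distance(1, 1, 1, "bogus")


class TestStepPattern:
    def test_asymmetric_steps(self):
        assert set(ASYMMETRIC.steps) == {(1, 0), (1, 1), (1, 2)}

    def test_rejects_non_query_advancing_steps(self):
        with pytest.raises(ValueError):
            StepPattern(name="bad", steps=((0, 1), (1, 1)))


class TestStandard:
    def test_self_alignment_is_zero_with_diagonal_path(self, rng):
        p = random_profile(rng, 40)
        res = dtw_standard(p, p)
        assert res.normalized_distance == 0.0
        assert res.raw_distance == 0.0
        assert res.path == tuple((i, i) for i in range(1, 41))
        assert res.ref_interval == (1, 40)

    def test_two_point_example(self):
        q = StructureProfile("q", [1.0, 1.0])
        r = StructureProfile("r", [1.0, -1.0])
        res = dtw_standard(q, r)
        assert res.raw_distance == pytest.approx(2.0)
        assert res.raw_distance == pytest.approx(brute_force_dtw(q, r, "standard"))

    def test_unreachable_reference_errors(self):
        q = StructureProfile("q", [1.0, 1.0])
        r = StructureProfile("r", [1.0] * 5)
        with pytest.raises(NoAdmissiblePathError, match="no admissible warping path"):
            dtw_standard(q, r)

    def test_length_ratio_warning(self):
        q = StructureProfile("q", [1.0] * 30)
        r = StructureProfile("r", [1.0] * 10)
        with pytest.warns(UserWarning, match="consider OBE"):
            dtw_standard(q, r)

    def test_standard_ref_interval_spans_reference(self, rng):
        q = random_profile(rng, 20, "q")
        r = random_profile(rng, 30, "r")
        res = dtw_standard(q, r)
        assert res.ref_interval == (1, 30)


class TestObe:
    def test_embedded_slice_found_exactly(self, rng):
        ref = random_profile(rng, 60, "ref")
        s, e = 21, 35  # 1-based inclusive
        query = StructureProfile("q", ref.scores[s - 1 : e])
        res = dtw_obe(query, ref)
        assert res.normalized_distance == 0.0
        assert res.ref_interval == (s, e)

    def test_full_reference_query_matches_standard(self, rng):
        p = random_profile(rng, 25, "p")
        r = random_profile(rng, 25, "r")
        assert dtw_obe(p, r).raw_distance <= dtw_standard(p, r).raw_distance

    def test_auto_swap_records_flag(self, rng):
        short = random_profile(rng, 10, "short")
        long = random_profile(rng, 40, "long")
        res = dtw_obe(long, short)
        assert res.swapped is True
        assert res.query_length == 10 and res.reference_length == 40
        res2 = dtw_obe(short, long)
        assert res2.swapped is False
        assert res2.raw_distance == pytest.approx(res.raw_distance)

    def test_auto_swap_disabled_errors(self, rng):
        with pytest.raises(ValueError, match="auto_swap"):
            dtw_obe(random_profile(rng, 5), random_profile(rng, 3), auto_swap=False)


class TestOracle:
    """dtw results must equal exhaustive path enumeration on tiny instances."""

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        q=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=6),
        r=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=6),
    )
    def test_standard_equals_brute_force(self, q, r):
        qp = StructureProfile("q", q)
        rp = StructureProfile("r", r)
        if len(r) > 2 * len(q) - 1:
            with pytest.raises(NoAdmissiblePathError):
                dtw_standard(qp, rp)
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dtw_standard(qp, rp)
        assert res.raw_distance == pytest.approx(
            brute_force_dtw(qp, rp, "standard"), abs=1e-12
        )

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        q=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=6),
        r=st.lists(st.floats(-2, 2, allow_nan=False), min_size=1, max_size=6),
    )
    def test_obe_equals_brute_force(self, q, r):
        qp = StructureProfile("q", q)
        rp = StructureProfile("r", r)
        short, long = (qp, rp) if len(q) <= len(r) else (rp, qp)
        res = dtw_obe(qp, rp)
        assert res.raw_distance == pytest.approx(
            brute_force_dtw(short, long, "obe"), abs=1e-12
        )

    def test_single_vs_single(self):
        a = StructureProfile("a", [0.3])
        b = StructureProfile("b", [-0.4])
        assert brute_force_dtw(a, b) == pytest.approx(local_cost(0.3, -0.4))
        assert dtw_standard(a, b).raw_distance == pytest.approx(0.7)

    def test_too_large_instance_rejected(self, rng):
        with pytest.raises(ValueError, match="too large"):
            brute_force_dtw(random_profile(rng, 8), random_profile(rng, 20))


class TestPathValidity:
    @pytest.mark.parametrize("mode", ["standard", "obe"])
    def test_path_respects_step_set(self, rng, mode):
        for _ in range(20):
            n, m = int(rng.integers(2, 30)), int(rng.integers(2, 30))
            if mode == "standard":
                m = min(m, 2 * n - 1)
            q, r = random_profile(rng, n, "q"), random_profile(rng, m, "r")
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = dtw_standard(q, r) if mode == "standard" else dtw_obe(q, r)
            path = res.path
            assert path[0][0] == 1 and path[-1][0] == res.query_length
            for (i1, j1), (i2, j2) in zip(path, path[1:]):
                assert i2 - i1 == 1
                assert j2 - j1 in (0, 1, 2)

    def test_raw_cost_equals_cost_along_path(self, rng):
        q, r = random_profile(rng, 15, "q"), random_profile(rng, 20, "r")
        res = dtw_obe(q, r)
        accum = sum(abs(q.scores[i - 1] - r.scores[j - 1]) for i, j in res.path)
        assert res.raw_distance == pytest.approx(accum)


class TestMonotoneNoiseResponse:
    def test_median_distance_nondecreasing_in_noise(self):
        levels = [0.0, 0.1, 0.3, 0.6]
        medians = []
        for sd in levels:
            dists = []
            for seed in range(10):
                p = gen_profile(150, 0.5, seed=seed)
                noisy = perturb_profile(p, noise_sd=sd, seed=1000 + seed)
                dists.append(dtw_standard(p, noisy).normalized_distance)
            medians.append(np.median(dists))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))


class TestSerialization:
    def test_json_and_path_tsv(self, tmp_path, rng):
        q, r = random_profile(rng, 8, "q"), random_profile(rng, 10, "r")
        res = dtw_obe(q, r)
        jf = tmp_path / "res.json"
        res.to_json(jf)
        import json

        payload = json.loads(jf.read_text())
        assert payload["normalized_distance"] == res.normalized_distance
        assert payload["ref_interval"] == list(res.ref_interval)
        tf = tmp_path / "path.tsv"
        res.path_to_tsv(tf)
        lines = tf.read_text().strip().split("\n")
        assert len(lines) == len(res.path) + 1
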