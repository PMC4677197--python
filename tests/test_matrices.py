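"""Position-matrix construction, window scoring and information content."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from promotif.matrices import (
    BASES,
    PFM,
    PPM,
    information_content,
    logo_matrix,
    pfm_to_ppm,
    pfm_to_pwm,
    ppm_to_pwm,
    relative_score,
    reverse_complement_pwm,
    score_window,
)

pfm_counts = st.lists(
    st.lists(st.integers(0, 30), min_size=4, max_size=4).filter(lambda c: sum(c) > 0),
    min_size=1,
    max_size=6,
).map(lambda cols: np.array(cols).T)


class TestPfmToPpm:
    def test_uniform_column_stays_uniform(self):
        pfm = PFM("m", "", np.array([[1], [1], [1], [1]]))
        ppm = pfm_to_ppm(pfm)  # defaults: pseudocount 0.8, uniform background
        assert np.allclose(ppm.probs[:, 0], 0.25)

    def test_peaked_column_with_default_pseudocount(self):
        pfm = PFM("m", "", np.array([[10], [0], [0], [0]]))
        ppm = pfm_to_ppm(pfm)
        assert ppm.probs[0, 0] == pytest.approx(10.2 / 10.8, abs=1e-12)
        assert np.allclose(ppm.probs[1:, 0], 0.2 / 10.8, atol=1e-12)

    def test_zero_pseudocount_gives_ml_frequencies(self):
        pfm = PFM("m", "", np.array([[2], [2], [0], [0]]))
        ppm = pfm_to_ppm(pfm, pseudocount_total=0.0)
        assert np.allclose(ppm.probs[:, 0], [0.5, 0.5, 0.0, 0.0])

    @given(counts=pfm_counts)
    def test_pseudocount_limit_converges_to_ml(self, counts):
        pfm = PFM("m", "", counts)
        ml = counts / counts.sum(axis=0, keepdims=True)
        for pc in (1e-3, 1e-6, 1e-9):
            probs = pfm_to_ppm(pfm, pseudocount_total=pc).probs
            assert np.max(np.abs(probs - ml)) < 10 * pc

    def test_bad_background_rejected(self):
        pfm = PFM("m", "", np.array([[1], [1], [1], [1]]))
        with pytest.raises(ValueError):
            pfm_to_ppm(pfm, background=np.array([0.5, 0.5, 0.5, 0.5]))
        with pytest.raises(ValueError):
            pfm_to_ppm(pfm, pseudocount_total=-1.0)


class TestPpmToPwm:
    def test_background_probs_give_zero_weights(self):
        ppm = PPM("m", np.full((4, 3), 0.25))
        pwm = ppm_to_pwm(ppm)
        assert np.allclose(pwm.weights, 0.0)
        assert pwm.s_min == pwm.s_max == 0.0

    def test_double_background_gives_weight_one(self):
        ppm = PPM("m", np.array([[0.5], [0.5], [0.0], [0.0]]),
                  background=np.array([0.25, 0.25, 0.25, 0.25]))
        # zero probs against positive background are rejected without pseudocount
        with pytest.raises(ValueError, match="pseudocount"):
            ppm_to_pwm(ppm)
        ppm2 = PPM("m", np.array([[0.5], [0.25], [0.125], [0.125]]))
        pwm = ppm_to_pwm(ppm2)
        assert pwm.weights[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_continues_pseudocounted_example(self):
        pfm = PFM("m", "", np.array([[10], [0], [0], [0]]))
        pwm = ppm_to_pwm(pfm_to_ppm(pfm))
        assert pwm.weights[0, 0] == pytest.approx(math.log2((10.2 / 10.8) / 0.25), abs=1e-12)
        assert pwm.weights[0, 0] == pytest.approx(1.917538, abs=1e-6)


class TestScoring:
    def test_consensus_and_anticonsensus_hit_score_range(self, strong_pfm):
        pwm = pfm_to_pwm(strong_pfm)
        consensus = "".join(BASES[i] for i in pwm.weights.argmax(axis=0))
        anti = "".join(BASES[i] for i in pwm.weights.argmin(axis=0))
        assert score_window(pwm, consensus) == pytest.approx(pwm.s_max, abs=1e-12)
        assert score_window(pwm, anti) == pytest.approx(pwm.s_min, abs=1e-12)
        assert relative_score(pwm, pwm.s_max) == pytest.approx(1.0)
        assert relative_score(pwm, pwm.s_min) == pytest.approx(0.0)
        mid = 0.5 * (pwm.s_min + pwm.s_max)
        assert relative_score(pwm, mid) == pytest.approx(0.5)

    def test_exhaustive_oracle_all_windows_L3(self, simple_pfm):
        """Vector scoring equals a per-position lookup sum over all 4^3 windows."""
        pwm = pfm_to_pwm(simple_pfm)
        lookup = {b: pwm.weights[i] for i, b in enumerate(BASES)}
        for window in map("".join, itertools.product(BASES, repeat=3)):
            expected = sum(lookup[b][j] for j, b in enumerate(window))
            assert score_window(pwm, window) == pytest.approx(expected, abs=1e-12)

    @given(st.data())
    def test_relative_score_in_unit_interval_iff_consensus(self, data):
        counts = data.draw(
            pfm_counts.filter(lambda c: any(len(set(col)) > 1 for col in c.T))
        )
        pfm = PFM("m", "", counts)
        pwm = pfm_to_pwm(pfm)
        window = data.draw(
            st.lists(st.sampled_from(BASES), min_size=pfm.length, max_size=pfm.length)
        )
        window = "".join(window)
        rel = relative_score(pwm, score_window(pwm, window))
        assert -1e-12 <= rel <= 1 + 1e-12
        is_consensus = all(
            pwm.weights[BASES.index(b), j] == pwm.weights[:, j].max()
            for j, b in enumerate(window)
        )
        assert math.isclose(rel, 1.0, abs_tol=1e-9) == is_consensus

    def test_window_length_mismatch_and_n_rejected(self, simple_pfm):
        pwm = pfm_to_pwm(simple_pfm)
        with pytest.raises(ValueError):
            score_window(pwm, "ACGT")
        with pytest.raises(ValueError):
            score_window(pwm, "ANG")

    def test_uninformative_motif_rejected(self):
        ppm = PPM("flat", np.full((4, 2), 0.25))
        pwm = ppm_to_pwm(ppm)
        with pytest.raises(ValueError, match="uninformative"):
            relative_score(pwm, 0.0)

    def test_reverse_complement_pwm_scores_rc_window(self, strong_pfm):
        pwm = pfm_to_pwm(strong_pfm)
        rc = reverse_complement_pwm(pwm)
        comp = dict(zip("ACGT", "TGCA"))
        window = "ATGATGAT"
        rc_window = "".join(comp[b] for b in reversed(window))
        assert score_window(rc, window) == pytest.approx(
            score_window(pwm, rc_window), abs=1e-12
        )
        assert (rc.s_min, rc.s_max) == (pwm.s_min, pwm.s_max)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column, bits",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
        ],
    )
    def test_closed_form_columns(self, column, bits):
        ppm = PPM("m", np.array(column).reshape(4, 1))
        assert information_content(ppm)[0] == pytest.approx(bits, abs=1e-12)

    @given(
        probs=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        perm=st.permutations(range(4)),
    )
    def test_invariant_under_base_permutation(self, probs, perm):
        p = np.array(probs) / np.sum(probs)
        ppm_a = PPM("m", p.reshape(4, 1))
        ppm_b = PPM("m", p[list(perm)].reshape(4, 1))
        assert information_content(ppm_a)[0] == pytest.approx(
            information_content(ppm_b)[0], abs=1e-12
        )

    def test_logo_matrix_layout(self, strong_pfm):
        ppm = pfm_to_ppm(strong_pfm)
        logo = logo_matrix(ppm)
        assert list(logo.columns) == ["position", "A", "C", "G", "T", "ic_bits"]
        assert len(logo) == strong_pfm.length
        assert np.allclose(logo[["A", "C", "G", "T"]].sum(axis=1), 1.0)


class TestPfmValidation:
    def test_rejects_bad_shapes_and_values(self):
        with pytest.raises(ValueError):
            PFM("m", "", np.zeros((3, 2), dtype=int))
        with pytest.raises(ValueError, match="negative"):
            PFM("m", "", np.array([[-1, 1], [1, 1], [1, 1], [1, 1]]))
        with pytest.raises(ValueError, match="all-zero"):
            PFM("m", "", np.array([[1, 0], [0, 0], [0, 0], [1, 0]]))

    def test_consensus(self, simple_pfm):
        assert simple_pfm.consensus == "ACG"
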