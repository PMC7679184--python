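"""Zernike basis: Noll indexing, normalization, synthesis and decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phaseret import (
    AmplitudeVector,
    PupilGrid,
    WavefrontMap,
    decompose_wavefront,
    evaluate_mode,
    nm_to_noll,
    noll_to_nm,
    rms_error,
    synthesize_wavefront,
    DEFAULT_INDEX_LIST,
    EVEN_MODES_5_15,
    ODD_MODES_5_15,
)


class TestNollIndexing:
    @pytest.mark.parametrize(
        "j, n, m, name, parity",
        [
            (1, 0, 0, "piston", "even"),
            (4, 2, 0, "defocus", "even"),
            (5, 2, -2, "oblique astigmatism", "even"),
            (6, 2, 2, "vertical astigmatism", "even"),
            (7, 3, -1, "vertical coma", "odd"),
            (8, 3, 1, "horizontal coma", "odd"),
            (11, 4, 0, "primary spherical", "even"),
            (15, 4, -4, "oblique quadrafoil", "even"),
        ],
    )
    def test_known_modes(self, j, n, m, name, parity):
        mode = noll_to_nm(j)
        assert (mode.n, mode.m) == (n, m)
        assert mode.name == name
        assert mode.parity == parity

    def test_roundtrip_bijective_first_100(self):
        for j in range(1, 101):
            mode = noll_to_nm(j)
            assert nm_to_noll(mode.n, mode.m) == j
            assert abs(mode.m) <= mode.n and (mode.n - abs(mode.m)) % 2 == 0

    def test_parity_follows_azimuthal_frequency(self):
        for j in range(1, 40):
            mode = noll_to_nm(j)
            assert mode.parity == ("even" if mode.m % 2 == 0 else "odd")

    def test_parity_classes_within_default_modes(self):
        assert EVEN_MODES_5_15 == (5, 6, 11, 12, 13, 14, 15)
        assert ODD_MODES_5_15 == (7, 8, 9, 10)

    @pytest.mark.parametrize("j", [0, -3])
    def test_invalid_index_rejected(self, j):
        with pytest.raises(ValueError):
            noll_to_nm(j)


class TestModeEvaluation:
    def test_piston_is_constant_one(self, dense_grid):
        w = evaluate_mode(1, dense_grid)
        assert np.allclose(w.phase[dense_grid.mask], 1.0)

    def test_unit_rms_normalization(self, dense_grid):
        # mean of Z^2 over the disk is 1 for every mode up to Noll 15
        for j in range(1, 16):
            z = evaluate_mode(j, dense_grid).phase[dense_grid.mask]
            assert abs(np.mean(z**2) - 1.0) < 0.01, f"mode {j}"

    def test_orthogonality_all_pairs(self, dense_grid):
        zs = {j: evaluate_mode(j, dense_grid).phase[dense_grid.mask] for j in range(1, 16)}
        for i in range(1, 16):
            for j in range(i + 1, 16):
                assert abs(np.mean(zs[i] * zs[j])) < 0.01, (i, j)

    def test_point_parity_on_symmetric_grid(self):
        # odd grid: point reflection about the center is an exact index map
        grid = PupilGrid(n=129, dk=1.0 / 64, cutoff=1.0)
        for j in range(2, 16):
            mode = noll_to_nm(j)
            z = evaluate_mode(mode, grid).phase
            flipped = z[::-1, ::-1]
            sign = 1.0 if mode.parity == "even" else -1.0
            np.testing.assert_allclose(flipped, sign * z, atol=1e-12)

    def test_degenerate_cutoff_rejected(self):
        with pytest.raises(ValueError):
            PupilGrid(n=16, dk=1.0, cutoff=0.0)


class TestSynthesisDecomposition:
    def test_zero_amplitudes_give_zero_phase(self, grid128):
        w = synthesize_wavefront(AmplitudeVector.zeros(), grid128)
        assert np.all(w.phase == 0)

    def test_single_mode_rms_equals_amplitude(self, dense_grid):
        a = AmplitudeVector.single(5, 0.075)
        assert synthesize_wavefront(a, dense_grid).rms() == pytest.approx(
            0.075, abs=0.001
        )

    def test_linearity(self, grid128):
        rng = np.random.default_rng(0)
        u = AmplitudeVector(rng.normal(size=11) * 0.05)
        v = AmplitudeVector(rng.normal(size=11) * 0.05)
        lhs = synthesize_wavefront(u + v, grid128).phase
        rhs = synthesize_wavefront(u, grid128).phase + synthesize_wavefront(v, grid128).phase
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_roundtrip_recovers_amplitudes(self, grid128):
        rng = np.random.default_rng(1)
        a = AmplitudeVector(rng.uniform(-0.075, 0.075, 11))
        rec = decompose_wavefront(synthesize_wavefront(a, grid128))
        assert np.abs(rec.values - a.values).max() < 1e-3

    def test_decompose_zero_map(self, grid128):
        w = WavefrontMap(np.zeros((128, 128)), grid128)
        assert np.all(decompose_wavefront(w).values == 0)

    def test_decompose_isolates_single_mode(self, grid128):
        w = WavefrontMap(0.05 * evaluate_mode(7, grid128).phase, grid128)
        a = decompose_wavefront(w)
        i7 = a.index_list.index(7)
        assert a.values[i7] == pytest.approx(0.05, abs=1e-3)
        others = np.delete(a.values, i7)
        assert np.abs(others).max() < 1e-3

    def test_mask_too_small_for_modes_rejected(self):
        grid = PupilGrid(n=8, dk=1.0, cutoff=2.5)  # handful of mask samples
        w = WavefrontMap(np.zeros((8, 8)), grid)
        with pytest.raises(ValueError):
            decompose_wavefront(w, index_list=tuple(range(1, 40)))


class TestRmsError:
    def test_identical_vectors_give_zero(self, grid128):
        a = AmplitudeVector.single(5, 0.03)
        assert rms_error(a, a, grid128) == 0.0

    def test_single_mode_difference(self, grid128):
        a = AmplitudeVector.single(5, 0.03)
        b = AmplitudeVector.zeros()
        assert rms_error(a, b, grid128) == pytest.approx(0.030, abs=0.0003)

    def test_uniform_difference_across_modes(self, grid128):
        a = AmplitudeVector(np.full(11, 0.075))
        b = AmplitudeVector.zeros()
        # sqrt(11) * 0.075 = 0.2487
        assert rms_error(a, b, grid128) == pytest.approx(0.2487, abs=0.003)

    def test_mismatched_index_lists_rejected(self, grid128):
        a = AmplitudeVector.zeros((5, 6, 7))
        b = AmplitudeVector.zeros((5, 6, 8))
        with pytest.raises(ValueError):
            rms_error(a, b, grid128)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-0.075, max_value=0.075),
            min_size=11, max_size=11,
        )
    )
    def test_agrees_with_analytic_norm(self, grid128, values):
        """The bridge between amplitude space and wavefront space: RMSE on
        the sampled pupil equals sqrt(sum da^2) within 1% at N=128."""
        a = AmplitudeVector(np.array(values))
        analytic = a.norm()
        measured = rms_error(a, AmplitudeVector.zeros(), grid128)
        assert measured == pytest.approx(analytic, rel=0.01, abs=1e-9)
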