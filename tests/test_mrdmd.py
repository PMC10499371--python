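"""Dyadic window bookkeeping, the recursion, and library assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrdmdcc as m
from mrdmdcc.dmd import reconstruct


class TestWindowSchedule:
    def test_default_ladder_4096_by_10(self):
        schedule = m.window_schedule(4096, 10)
        for level in range(1, 11):
            windows = [(s, e) for lv, s, e in schedule if lv == level]
            assert len(windows) == 2 ** (level - 1)
            assert all(e - s == 4096 // 2 ** (level - 1) for s, e in windows)

    def test_small_even_example(self):
        assert m.window_schedule(16, 2) == [(1, 0, 16), (2, 0, 8), (2, 8, 16)]

    def test_odd_length_floor_split(self):
        schedule = m.window_schedule(10, 2)
        assert schedule == [(1, 0, 10), (2, 0, 5), (2, 5, 10)]

    def test_too_fine_ladder_rejected(self):
        with pytest.raises(ValueError, match="finest"):
            m.window_schedule(8, 5)

    @settings(deadline=None, max_examples=60)
    @given(M=st.integers(8, 2000), L=st.integers(1, 6))
    def test_each_level_tiles_the_training_window(self, M, L):
        if M < 2**(L - 1) * 2:
            return
        schedule = m.window_schedule(M, L)
        for level in range(1, L + 1):
            windows = sorted((s, e) for lv, s, e in schedule if lv == level)
            assert windows[0][0] == 0 and windows[-1][1] == M
            assert all(w1[1] == w2[0] for w1, w2 in zip(windows, windows[1:]))
            assert sum(e - s for s, e in windows) == M


def _constant_field(n_rows=4, n_cols=4, T=64, value=7.0):
    geometry = m.GridGeometry(n_rows, n_cols, np.arange(n_rows * n_cols))
    X = np.full((geometry.n_cells, T), value)
    X[0, :] = 2 * value  # give the constant a spatial pattern
    return m.FieldMatrix(X=X, geometry=geometry)


class TestDecomposition:
    def test_constant_field_captured_at_level_one(self):
        field = _constant_field()
        config = m.DecompositionConfig(levels=4, training_window=64)
        tree = m.mrdmd_decompose(field, config)
        root_rec = reconstruct(tree.slow, 64)
        energy = np.linalg.norm(root_rec) ** 2 / np.linalg.norm(field.X) ** 2
        assert energy >= 0.999
        assert np.linalg.norm(tree.final_residual) <= 1e-6 * np.linalg.norm(field.X)

    def test_field_shorter_than_training_window_rejected(self):
        field = _constant_field(T=32)
        with pytest.raises(ValueError, match="snapshots"):
            m.mrdmd_decompose(field, m.DecompositionConfig(levels=2, training_window=64))

    def test_decomposes_last_training_window(self):
        """With n_times > M the recursion consumes the most recent M snapshots."""
        geometry = m.GridGeometry(2, 2, np.arange(4))
        X = np.ones((4, 100))
        X[:, :36] = 999.0  # garbage outside the final 64-day window
        field = m.FieldMatrix(X=X, geometry=geometry)
        tree = m.mrdmd_decompose(field, m.DecompositionConfig(levels=2, training_window=64))
        assert tree.window == (0, 64)
        assert np.linalg.norm(tree.final_residual) <= 1e-8

    def test_deeper_decomposition_reduces_final_residual(self, two_tone):
        """The slow-mode subtraction is a model fit rather than an orthogonal
        projection, so the residual need not shrink at every single level;
        over the full ladder it must shrink substantially."""
        field = two_tone["field"]
        norms = []
        for L in (1, 7):
            tree = m.mrdmd_decompose(field, m.DecompositionConfig(levels=L, training_window=512))
            norms.append(np.linalg.norm(tree.final_residual))
        assert norms[1] < 0.5 * norms[0]
        assert norms[1] < np.linalg.norm(field.X)

    def test_deterministic_bit_identical_library(self, two_tone):
        config = two_tone["config"]
        field = two_tone["field"]
        lib1 = m.build_library(m.mrdmd_decompose(field, config), config)
        lib2 = m.build_library(m.mrdmd_decompose(field, config), config)
        assert np.array_equal(lib1.matrix, lib2.matrix)
        assert lib1.provenance.equals(lib2.provenance)


class TestTimescaleSeparation:
    """Two-tone fixture: annual sinusoid + one 8-day transient."""

    def _level_reconstruction(self, tree, levels, n_cells, T):
        out = np.zeros((n_cells, T))
        for node in tree.walk():
            if node.level in levels and not node.slow.is_empty:
                s, e = node.window
                out[:, s:e] += reconstruct(node.slow, e - s)
        return out

    def test_coarse_levels_capture_the_smooth_component(self, two_tone):
        coarse = self._level_reconstruction(two_tone["tree"], {1, 2, 3}, 256, 512)
        smooth = two_tone["smooth"]
        rel_err = np.linalg.norm(coarse - smooth) / np.linalg.norm(smooth)
        assert rel_err <= 0.25

    def test_transient_absent_from_coarse_levels(self, two_tone):
        coarse = self._level_reconstruction(two_tone["tree"], {1, 2, 3}, 256, 512)
        smooth = two_tone["smooth"]
        i = two_tone["center_flat"]
        s0, d = two_tone["start"], two_tone["duration"]
        deviation = np.abs(coarse[i, s0 : s0 + d] - smooth[i, s0 : s0 + d]).max()
        assert deviation <= 0.05 * two_tone["amplitude"]

    def test_transient_captured_at_fine_levels_at_center(self, two_tone):
        fine = self._level_reconstruction(two_tone["tree"], {4, 5, 6, 7}, 256, 512)
        i = two_tone["center_flat"]
        s0, d = two_tone["start"], two_tone["duration"]
        captured = fine[i, s0 : s0 + d].mean()
        assert captured >= 0.5 * two_tone["amplitude"]

    def test_finest_node_containing_event_peaks_at_planted_center(self, two_tone):
        s0 = two_tone["start"]
        for node in two_tone["tree"].walk():
            if node.level == 7 and node.window[0] <= s0 < node.window[1]:
                assert not node.slow.is_empty
                dominant = int(np.argmax(np.abs(node.slow.amplitudes)))
                argmax = int(np.argmax(np.abs(node.slow.modes[:, dominant])))
                assert argmax == two_tone["center_flat"]
                return
        pytest.fail("no finest-level node contains the event")


class TestLibrary:
    def test_single_real_mode_gives_one_column(self):
        field = _constant_field(T=64)
        config = m.DecompositionConfig(levels=1, training_window=64, rank_rule=m.RankRule(max_rank=1))
        tree = m.mrdmd_decompose(field, config)
        library = m.build_library(tree, config)
        assert library.r_total == 1
        assert library.provenance["component"].tolist() == ["re"]

    def test_conjugate_pair_gives_re_and_im_columns(self):
        geometry = m.GridGeometry(3, 3, np.arange(9))
        t = np.arange(64, dtype=float)
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=9), rng.normal(size=9)
        # oscillation slow enough (1 cycle per window) to be retained at level 1
        X = 5.0 + a[:, None] * np.cos(2 * np.pi * t / 64) + b[:, None] * np.sin(2 * np.pi * t / 64)
        field = m.FieldMatrix(X=X, geometry=geometry)
        config = m.DecompositionConfig(levels=1, training_window=64)
        library = m.build_library(m.mrdmd_decompose(field, config), config)
        pair = library.provenance[library.provenance["frequency"] > 1e-6]
        assert sorted(pair["component"].tolist()) == ["im", "re"]

    def test_unit_weighting_normalizes_columns(self, two_tone):
        library = m.build_library(two_tone["tree"], two_tone["config"])
        np.testing.assert_allclose(np.linalg.norm(library.matrix, axis=0), 1.0, atol=1e-10)

    def test_default_city_library_exceeds_800_columns(self, default_library):
        assert default_library.r_total > 800

    def test_csv_round_trip(self, two_tone, tmp_path):
        library = m.build_library(two_tone["tree"], two_tone["config"], two_tone["field"].geometry)
        lib_path, prov_path = tmp_path / "lib.csv", tmp_path / "prov.csv"
        library.to_csv(lib_path, prov_path)
        loaded = m.ModalLibrary.from_csv(lib_path, prov_path)
        np.testing.assert_allclose(loaded.matrix, library.matrix, atol=1e-12)
        assert loaded.geometry.n_cells == library.geometry.n_cells
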