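"""Digital reference wave, residual-tilt search, and the end-to-end
conventional reconstruction oracle."""

import numpy as np
import pytest

from holophase import (
    ReferenceWaveParams,
    apply_compensation,
    digital_reference_wave,
    make_rbc_phase,
    random_scene,
    reconstruct,
    search_reference_wave,
    synthesize_hologram,
)
from holophase.compensation import compensation_score
from holophase.metrics import normalize_wrapped_phase, tsm
from holophase.pipeline import ReconstructionSettings
from holophase.simulate import Hologram

from conftest import STUDY_CARRIER, piston_free_rmse, wrapped


def final_grid_step(span, levels=3, points=11):
    step = span
    for _ in range(levels):
        step = 2 * step / (points - 1)
    return step


def planted_field(seed, residual):
    """Simulator scene times a residual carrier, as after coarse recentring."""
    gt = make_rbc_phase(random_scene(seed))
    n = gt.shape[0]
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    return np.exp(1j * gt) * np.exp(2j * np.pi * (residual[0] * cols + residual[1] * rows)), gt


class TestDigitalReferenceWave:
    def test_zero_tilt_is_all_ones(self):
        rd = digital_reference_wave(ReferenceWaveParams(fx=0.0, fy=0.0), (32, 32))
        assert np.allclose(rd, 1.0)

    def test_unit_modulus_for_any_params(self):
        rd = digital_reference_wave(ReferenceWaveParams(fx=0.13, fy=-0.21), (32, 48))
        assert np.allclose(np.abs(rd), 1.0, rtol=1e-12)
        assert np.allclose(rd * np.conj(rd), 1.0, rtol=1e-12)

    def test_compensating_its_own_conjugate_gives_zero_phase(self):
        p = ReferenceWaveParams(fx=0.07, fy=-0.11)
        field = np.conj(digital_reference_wave(p, (64, 64)))
        assert np.allclose(apply_compensation(field, p), 0.0, atol=1e-12)

    def test_compensation_with_opposite_params_round_trips(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-3.0, 3.0, (32, 32))
        field = np.exp(1j * phase)
        p = ReferenceWaveParams(fx=0.04, fy=0.09)
        once = apply_compensation(field, p)
        back = apply_compensation(np.exp(1j * once), ReferenceWaveParams(fx=-p.fx, fy=-p.fy))
        assert np.allclose(back, wrapped(phase), atol=1e-10)

    def test_correct_params_give_flattest_background(self):
        residual = (0.013, -0.008)
        field, _ = planted_field(21, residual)
        exact = ReferenceWaveParams(fx=-residual[0], fy=-residual[1])
        off = ReferenceWaveParams(fx=-residual[0] + 2 / 256, fy=-residual[1])
        bg = np.s_[200:248, 8:56]  # cell-free corner patch
        std_exact = np.std(apply_compensation(field, exact)[bg])
        std_off = np.std(apply_compensation(field, off)[bg])
        assert std_exact < std_off


class TestSearchReferenceWave:
    def test_recovers_planted_residual_within_final_grid_step(self):
        residual = (0.013, -0.008)
        field, _ = planted_field(3, residual)
        res = search_reference_wave(field, grid_levels=3, span=0.02)
        step = final_grid_step(0.02)
        assert abs(-res.params.fx - residual[0]) <= step
        assert abs(-res.params.fy - residual[1]) <= step

    def test_already_compensated_field_optimum_near_origin(self):
        field, _ = planted_field(4, (0.0, 0.0))
        res = search_reference_wave(field)  # default span: 2 bins
        step = final_grid_step(2 / 256)
        assert np.hypot(res.params.fx, res.params.fy) <= np.hypot(step, step)

    def test_returned_score_is_minimum_of_trace(self):
        field, _ = planted_field(5, (0.004, 0.002))
        res = search_reference_wave(field)
        assert res.score == min(s for _, s in res.search_trace)

    def test_monotone_refinement_across_levels(self):
        field, _ = planted_field(6, (0.006, -0.003))
        per_level = 11 * 11
        bests = []
        res = search_reference_wave(field, grid_levels=3)
        for level in range(3):
            scores = [s for _, s in res.search_trace[level * per_level : (level + 1) * per_level]]
            bests.append(min(min(scores), bests[-1] if bests else np.inf))
        assert bests[0] >= bests[1] >= bests[2]

    def test_flat_zero_field_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            search_reference_wave(np.zeros((64, 64), dtype=complex))

    def test_tsm_rises_away_from_optimum(self):
        """A tilt several final grid steps off the optimum binarizes to a mix
        of black and white pixels, so the thresholded metric alone already
        exceeds its value at the optimum."""
        residual = (0.009, -0.006)
        field, _ = planted_field(8, residual)
        span = 2 / 256
        step = final_grid_step(span)
        opt = ReferenceWaveParams(fx=-residual[0], fy=-residual[1])
        tsm_at = lambda p: tsm(normalize_wrapped_phase(apply_compensation(field, p)))
        for steps_off in (8, 40, 200):
            off = ReferenceWaveParams(fx=opt.fx + steps_off * step, fy=opt.fy)
            assert tsm_at(off) > tsm_at(opt)

    def test_objective_includes_concentration_term(self):
        field, _ = planted_field(9, (0.0, 0.0))
        p = ReferenceWaveParams(fx=0.0, fy=0.0)
        phase = apply_compensation(field, p)
        conc = np.abs(np.mean(np.exp(1j * phase)))
        expected = tsm(normalize_wrapped_phase(phase)) + (1 - conc)
        assert compensation_score(field, p) == pytest.approx(expected, rel=1e-12)


class TestEndToEndReconstruction:
    SETTINGS = ReconstructionSettings(mask_radius=60)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_ground_truth_phase(self, seed):
        scene = random_scene(seed)
        gt = make_rbc_phase(scene)
        holo = synthesize_hologram(
            gt, 1.0, STUDY_CARRIER, noise_sigma=0.02, seed=100 + seed, background_drift=0.05
        )
        res = reconstruct(holo, self.SETTINGS)
        assert piston_free_rmse(res.phase, wrapped(gt)) <= 0.05

    def test_ideal_compensation_tsm_small_and_tilted_tsm_large(self, study_phase):
        ideal = wrapped(study_phase)
        assert tsm(normalize_wrapped_phase(ideal)) <= 0.02
        n = ideal.shape[0]
        tilt = 2 * np.pi * 0.01 * np.arange(n)[None, :]
        assert tsm(normalize_wrapped_phase(wrapped(ideal + tilt))) >= 0.10

    def test_rotated_hologram_reconstructs_to_rotated_phase(self, study_hologram):
        res0 = reconstruct(study_hologram, self.SETTINGS)
        rot = Hologram(intensity=np.rot90(study_hologram.intensity).copy())
        res90 = reconstruct(rot, self.SETTINGS)
        assert piston_free_rmse(res90.phase, np.rot90(res0.phase)) <= 0.05
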