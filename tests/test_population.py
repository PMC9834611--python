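"""Monte Carlo virtual populations: sampling, correlation, envelopes."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vinpbpk import studies
from vinpbpk.calibrate import _get_by_path
from vinpbpk.population import (
    PopulationSpec,
    run_population,
    sample_population,
)


PATHS = ("phys.body_weight", "drug.Vmax_met", "drug.PC.kidney")


def _draw_matrix(subjects, paths):
    return np.array(
        [[_get_by_path(phys, drug, p) for p in paths] for drug, phys in subjects]
    )


class TestSampling:
    def test_zero_sd_gives_identical_subjects(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=5, varied_parameters=PATHS,
                              sd_log_default=0.0, seed=1)
        subjects = sample_population(spec, st.drug, st.physiology)
        mat = _draw_matrix(subjects, PATHS)
        base = [st.physiology.body_weight, st.drug.Vmax_met,
                st.drug.PC["kidney"]]
        assert np.allclose(mat, np.array(base)[None, :])

    def test_seeded_determinism(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=20, varied_parameters=PATHS, seed=9)
        m1 = _draw_matrix(sample_population(spec, st.drug, st.physiology), PATHS)
        m2 = _draw_matrix(sample_population(spec, st.drug, st.physiology), PATHS)
        assert np.array_equal(m1, m2)

    def test_lognormal_moments_at_large_n(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=10000, varied_parameters=PATHS, seed=5)
        mat = _draw_matrix(sample_population(spec, st.drug, st.physiology),
                           PATHS)
        logs = np.log(mat)
        medians = np.array([st.physiology.body_weight, st.drug.Vmax_met,
                            st.drug.PC["kidney"]])
        geo_mean = np.exp(logs.mean(axis=0))
        assert np.allclose(geo_mean / medians, 1.0, atol=0.01)
        assert np.allclose(logs.std(axis=0), 0.2, atol=0.006)

    def test_identity_correlation_gives_independence(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=10000, varied_parameters=PATHS, seed=6)
        mat = _draw_matrix(sample_population(spec, st.drug, st.physiology),
                           PATHS)
        for i in range(3):
            for j in range(i + 1, 3):
                rho = spearmanr(mat[:, i], mat[:, j]).statistic
                assert abs(rho) < 0.05

    def test_rank_correlation_imposed(self):
        st = studies.dog_trial()
        corr = np.array(
            [[1.0, 0.7, 0.0], [0.7, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        spec = PopulationSpec(n_subjects=4000, varied_parameters=PATHS,
                              rank_correlation=corr, seed=7)
        mat = _draw_matrix(sample_population(spec, st.drug, st.physiology),
                           PATHS)
        rho = spearmanr(mat[:, 0], mat[:, 1]).statistic
        assert rho == pytest.approx(0.7, abs=0.05)

    def test_non_psd_matrix_rejected_with_suggestion(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="nearest PSD"):
            PopulationSpec(n_subjects=3, varied_parameters=PATHS,
                           rank_correlation=bad)

    def test_asymmetric_matrix_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            PopulationSpec(n_subjects=3, varied_parameters=PATHS,
                           rank_correlation=bad)


class TestRunPopulation:
    def test_single_subject_envelope_collapses(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=1, varied_parameters=PATHS, seed=2)
        subjects = sample_population(spec, st.drug, st.physiology)
        res = run_population(subjects, st.dose, t_end=24.0, n_out=120,
                             varied_parameters=PATHS)
        env = res.envelope["blood"]
        assert np.allclose(env["min"], env["max"])
        assert np.allclose(env["mean"], res.simulations[0].concentrations["blood"])

    def test_envelope_ordering_and_nca(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=8, varied_parameters=PATHS, seed=3)
        subjects = sample_population(spec, st.drug, st.physiology)
        res = run_population(subjects, st.dose, t_end=24.0, n_out=120,
                             varied_parameters=PATHS)
        env = res.envelope["blood"]
        assert np.all(env["min"] <= env["mean"] + 1e-12)
        assert np.all(env["mean"] <= env["max"] + 1e-12)
        assert res.n_failed == 0
        nca = res.subject_nca("blood", 0.0, 24.0)
        assert len(nca) == 8
        assert (nca["auc"] > 0).all()
        assert res.draws.shape == (8, 3)

    def test_small_variability_tracks_base_trajectory(self):
        st = studies.dog_trial()
        spec = PopulationSpec(n_subjects=6, varied_parameters=PATHS,
                              sd_log_default=1e-4, seed=4)
        subjects = sample_population(spec, st.drug, st.physiology)
        res = run_population(subjects, st.dose, t_end=24.0, n_out=120,
                             varied_parameters=PATHS)
        from vinpbpk.simulate import simulate_iv_bolus

        base = simulate_iv_bolus(st.physiology, st.drug, st.dose, 24.0,
                                 n_out=120)
        mean = res.envelope["blood"]["mean"].to_numpy()[1:]
        ref = base.concentrations["blood"][1:]
        assert np.allclose(mean, ref, rtol=0.01)
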