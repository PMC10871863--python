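import numpy as np
import pytest

from seqdecide import (
    NeuronGroundTruth,
    NumberDecisionSubspace,
    PlaneGeometry,
    condition_cells,
    condition_mean_matrix,
    enumerate_conditions,
    generate_trials,
    pca_basis,
    project_plane_geometry,
    simulate_spikes,
)


@pytest.fixture(scope="module")
def cells(design):
    trials = generate_trials(enumerate_conditions(design), 4, p_correct=1.0, seed=0)
    return trials, condition_cells(trials, "num1", design)


class TestConditionMeans:

    def test_six_cells_all_occupied(self, cells):
        trials, cc = cells
        assert len(cc) == 6
        assert all(ix.size > 0 for _, ix in cc)

    def test_identical_rates_center_to_zero(self, cells, rng):
        trials, cc = cells
        rates = np.tile(rng.random((5, 1)), (1, len(trials)))
        X, rbar = condition_mean_matrix(rates, cc)
        assert X == pytest.approx(np.zeros_like(X), abs=1e-12)

    def test_column_means_zero_after_centering(self, cells, rng):
        trials, cc = cells
        rates = rng.random((8, len(trials)))
        X, _ = condition_mean_matrix(rates, cc)
        assert X.mean(axis=0) == pytest.approx(np.zeros(8), abs=1e-12)

    def test_additive_number_decision_code_has_low_rank(self, cells, rng):
        trials, cc = cells
        n_neurons = 30
        num_ax = rng.normal(size=n_neurons)
        dec_ax = rng.normal(size=n_neurons)
        f = {1: 0.0, 3: 1.0, 9: 2.0}
        rates = np.empty((n_neurons, len(trials)))
        for j, (n1, dec) in enumerate(zip(trials.first_num, trials.decision)):
            rates[:, j] = f[n1] * num_ax + (dec == "same") * dec_ax
        X, _ = condition_mean_matrix(rates, cc)
        s = np.linalg.svd(X, compute_uv=False)
        assert s[2] < 1e-10 * s[0]  # rank <= 2 for a purely additive code

    def test_missing_cell_rejected(self, design):
        trials = generate_trials(enumerate_conditions(design), 2, p_correct=1.0, seed=0)
        broken = trials[~((trials.first_num == 1) & (trials.decision == "same"))]
        with pytest.raises(ValueError, match="empty condition cell"):
            condition_cells(broken.reset_index(drop=True), "num1", design)


class TestPCABasis:
    def test_rank2_matrix_explained_by_two_components(self, rng):
        u = rng.normal(size=(6, 2))
        v = rng.normal(size=(2, 40))
        X = u @ v
        X -= X.mean(axis=0)
        basis = pca_basis(X, K=2)
        assert basis.variance_explained[:2].sum() == pytest.approx(1.0)

    def test_orthonormal_basis_and_sorted_spectrum(self, rng):
        X = rng.normal(size=(6, 25))
        X -= X.mean(axis=0)
        b = pca_basis(X, K=3)
        assert b.components.T @ b.components == pytest.approx(np.eye(3), abs=1e-10)
        assert (np.diff(b.variance_explained) <= 1e-12).all()
        assert b.variance_explained.sum() == pytest.approx(1.0)

    def test_rotation_invariance_of_spectrum(self, rng):
        X = rng.normal(size=(6, 20))
        X -= X.mean(axis=0)
        q, _ = np.linalg.qr(rng.normal(size=(20, 20)))
        s1 = pca_basis(X, 3).eigenvalues
        s2 = pca_basis(X @ q, 3).eigenvalues
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_k_beyond_rank_rejected(self, rng):
        u = rng.normal(size=(6, 2))
        X = u @ rng.normal(size=(2, 15))
        X -= X.mean(axis=0)
        with pytest.raises(ValueError, match="rank"):
            pca_basis(X, K=4)


class TestPlaneGeometry:
    def test_unit_right_triangle_area(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        g = PlaneGeometry.from_vertices(v, v + [0, 0, 2.0])
        assert g.area_same == pytest.approx(0.5)
        assert g.area_different == pytest.approx(0.5)

    def test_collinear_vertices_zero_area_nan_cos(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        g = PlaneGeometry.from_vertices(v, v)
        assert g.area_same == 0.0
        assert np.isnan(g.cos_theta)

    def test_area_scales_quadratically(self, rng):
        v1 = rng.normal(size=(3, 3))
        v2 = rng.normal(size=(3, 3))
        g1 = PlaneGeometry.from_vertices(v1, v2)
        g2 = PlaneGeometry.from_vertices(3.0 * v1, 3.0 * v2)
        assert g2.area_same == pytest.approx(9.0 * g1.area_same)
        assert g2.cos_theta == pytest.approx(g1.cos_theta)

    @pytest.mark.parametrize(
        "angle_deg,expected",
        [(0.0, 1.0), (90.0, 0.0), (60.0, 0.5)],
    )
    def test_planted_dihedral_angles(self, angle_deg, expected):
        a = np.deg2rad(angle_deg)
        same = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        diff = np.array(
            [[0, 0, 0], [1, 0, 0], [0, np.cos(a), np.sin(a)]], float
        )
        g = PlaneGeometry.from_vertices(same, diff)
        assert g.cos_theta == pytest.approx(expected, abs=1e-6)

    def test_projection_pipeline_recovers_known_geometry(self, rng):
        # embed known 3-D vertices in a rotated 12-D neuron space
        z = np.array(
            [[0, 0, 0], [0, 0, 1], [2, 0, 0], [2, 0, 1], [0, 2, 0], [0, 2, 1]], float
        )  # (num, dec) rows: number plane xy, decision axis z
        q, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        R = z @ q[:3, :]
        X = R - R.mean(axis=0)
        basis = pca_basis(X, 3)
        keys = [(n, d) for n in (1, 3, 9) for d in ("same", "different")]
        geom = project_plane_geometry(basis, R, R.mean(axis=0), keys)
        assert geom.area_same == pytest.approx(2.0, abs=1e-9)
        assert abs(geom.cos_theta) == pytest.approx(1.0, abs=1e-9)


class TestSubspaceModel:
    def test_offset_invariance_of_area_and_cos(self, design):
        trials = generate_trials(enumerate_conditions(design), 4, seed=0)
        rng = np.random.default_rng(2)
        truth = [
            NeuronGroundTruth(
                baseline_hz=5.0, pref_num=int(rng.choice([1, 3, 9])),
                gain1_hz=20.0, latency1_s=0.55, duration1_s=1.0,
            )
            for _ in range(20)
        ]
        spikes = simulate_spikes(truth, trials, design, seed=3)
        m = NumberDecisionSubspace(trials, spikes, "num1", design=design)
        win = np.array([15, 20])
        res = m.fit(n_boot=30, seed=4, windows=win)
        m2 = NumberDecisionSubspace(trials, spikes, "num1", design=design)
        m2.rates.rates = m2.rates.rates + 50.0  # condition-independent offset
        res2 = m2.fit(n_boot=30, seed=4, windows=win)
        assert res2.area_mean("same") == pytest.approx(res.area_mean("same"), rel=1e-9)
        assert np.nanmean(res2.cos_theta) == pytest.approx(np.nanmean(res.cos_theta), rel=1e-9)

    def test_area_peaks_in_number_epoch_for_transient_code(self, design):
        trials = generate_trials(enumerate_conditions(design), 6, seed=5)
        rng = np.random.default_rng(6)
        truth = [
            NeuronGroundTruth(
                baseline_hz=5.0, pref_num=int(rng.choice([1, 3, 9])),
                gain1_hz=25.0, latency1_s=0.6, duration1_s=0.45,
            )
            for _ in range(25)
        ]
        spikes = simulate_spikes(truth, trials, design, seed=7)
        res = NumberDecisionSubspace(trials, spikes, "num1", design=design).fit(
            n_boot=60, seed=8
        )
        peak_t = res.times[np.nanargmax(res.area_mean("same") + res.area_mean("different"))]
        assert design.number1_onset < peak_t < design.delay1_onset + 0.3
        # untuned epochs sit at the noise floor well below the peak
        pre = res.times <= design.number1_onset
        total = res.area_mean("same") + res.area_mean("different")
        assert total[pre].mean() < 0.35 * np.nanmax(total)

    def test_single_bootstrap_has_no_se(self, design, small_dataset):
        trials, spikes, _ = small_dataset
        res = NumberDecisionSubspace(trials, spikes, "num1", design=design).fit(
            n_boot=1, seed=0, windows=np.array([30])
        )
        assert np.isnan(res.area_se("same")).all()
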