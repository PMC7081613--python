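"""Posture correction: PCA alignment, straightening, orientation, fine fit."""

import warnings

import numpy as np
import pytest

import wormid as w
from wormid.model import CellRecord, WormSample
from wormid._geom import fit_similarity


def _cloud_sample(X, animal="a"):
    cells = [CellRecord(cell_id=f"c{i}", position=p) for i, p in enumerate(X)]
    return WormSample(animal_id=animal, cells=cells)


def _rot_x(phi):
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _anisotropic_cloud(n=200, seed=0, scales=(20.0, 4.0, 2.0)):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, 3)) * np.array(scales)


class TestPCAAlign:
    def test_axis_aligned_cloud_keeps_axes(self):
        X = _anisotropic_cloud(scales=(3.0, 2.0, 1.0))
        aligned, tf = w.pca_align(_cloud_sample(X))
        # rotation close to +-identity per axis
        assert np.allclose(np.abs(tf.pc_axes), np.eye(3), atol=0.05)
        assert np.allclose(aligned.positions.mean(axis=0), 0, atol=1e-10)
        v = aligned.positions.var(axis=0)
        assert v[0] >= v[1] >= v[2]

    def test_known_rotation_recovered(self):
        X = _anisotropic_cloud(seed=1)
        theta = np.deg2rad(30)
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        a0, _ = w.pca_align(_cloud_sample(X))
        a1, _ = w.pca_align(_cloud_sample(X @ R.T + 5.0))
        # same cloud re-expressed: aligned clouds agree up to axis signs
        assert np.allclose(np.abs(a0.positions), np.abs(a1.positions), atol=1e-8)

    def test_collinear_cloud_errors(self):
        X = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            w.pca_align(_cloud_sample(X))

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            w.pca_align(_cloud_sample(np.eye(3)))


class TestQuadraticFit:
    def test_exact_parabola(self):
        x = np.linspace(-10, 10, 30)
        X = np.stack([x, 0.01 * x**2, np.zeros_like(x)], axis=1)
        coeffs = w.fit_quadratic(_cloud_sample(X))
        np.testing.assert_allclose(coeffs[0], [0.01, 0, 0], atol=1e-8)
        np.testing.assert_allclose(coeffs[1], [0, 0, 0], atol=1e-8)

    def test_straight_worm_zero_coeffs(self):
        x = np.linspace(-10, 10, 20)
        X = np.stack([x, np.zeros_like(x), np.zeros_like(x)], axis=1)
        assert np.allclose(w.fit_quadratic(_cloud_sample(X)), 0, atol=1e-10)

    def test_noisy_parabola_recovers_curvature(self):
        # closed-form least-squares oracle via normal equations
        rng = np.random.default_rng(7)
        x = rng.uniform(-50, 50, 200)
        a_true = 0.004
        y = a_true * x**2 + rng.normal(0, 0.5, 200)
        X = np.stack([x, y, np.zeros_like(x)], axis=1)
        coeffs = w.fit_quadratic(_cloud_sample(X))
        A = np.vander(x, 3)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(coeffs[0], beta, atol=1e-10)
        resid_var = np.sum((y - A @ beta) ** 2) / (200 - 3)
        se_a = np.sqrt(resid_var * np.linalg.inv(A.T @ A)[0, 0])
        assert abs(coeffs[0][0] - a_true) < 3 * se_a

    def test_underdetermined_errors(self):
        with pytest.raises(ValueError):
            w.fit_quadratic(_cloud_sample(np.zeros((2, 3))))


class TestStraighten:
    def test_already_straight_identity(self):
        X = _anisotropic_cloud(seed=2)
        s = _cloud_sample(X)
        out = w.straighten(s, np.zeros((2, 3)))
        np.testing.assert_array_equal(out.positions, X)

    def test_bend_roundtrip_subparabola(self):
        # bend applied then straightened: residual quadratic vanishes
        X = _anisotropic_cloud(seed=3, scales=(30.0, 3.0, 3.0))
        bent = X.copy()
        bent[:, 1] += 0.004 * bent[:, 0] ** 2
        s = _cloud_sample(bent)
        coeffs = w.fit_quadratic(s)
        flat = w.straighten(s, coeffs)
        refit = w.fit_quadratic(flat)
        assert np.abs(refit[:, 0]).max() < 1e-6

    def test_dvlr_cross_section_rigid(self):
        # pairwise distances within a fixed-AP slice are preserved
        x = np.repeat([0.0, 5.0], 10)
        rng = np.random.default_rng(4)
        yz = rng.normal(size=(20, 2)) * 3
        X = np.column_stack([x, yz])
        coeffs = np.array([[0.01, 0.2, 1.0], [0.005, -0.1, 0.3]])
        out = w.straighten(_cloud_sample(X), coeffs).positions
        for val in (0.0, 5.0):
            m = x == val
            d_in = np.linalg.norm(X[m][:, None, 1:] - X[m][None, :, 1:], axis=2)
            d_out = np.linalg.norm(out[m][:, None, 1:] - out[m][None, :, 1:], axis=2)
            np.testing.assert_allclose(d_in, d_out, atol=1e-10)


class TestOrientAndOrigin:
    def _gapped_cloud(self, gap_center, n=400, seed=5):
        """Cylinder of cells with an angular wedge removed at gap_center."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 20, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        keep = np.abs((phi - gap_center + np.pi) % (2 * np.pi) - np.pi) > 0.5
        r = rng.uniform(2, 10, n)
        y = r * np.cos(phi)
        z = r * np.sin(phi)
        return np.stack([x, y, z], axis=1)[keep]

    def test_wedge_gap_becomes_dorsal(self):
        for gap in (0.7, 2.5, 4.4):
            X = self._gapped_cloud(gap)
            out, roll, _ = w.orient_and_origin(_cloud_sample(X))
            Y = out.positions
            theta = np.arctan2(Y[:, 2], Y[:, 1])
            # gap now centred at +y (angle 0): no cells near angle 0
            assert np.abs(theta).min() > 0.25

    def test_density_peak_moved_to_origin(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(20, 3, 300), rng.uniform(-40, 40, 100)])
        yz = rng.normal(size=(400, 2)) * np.array([4, 2])  # anisotropy fixes roll
        X = np.column_stack([x, yz])
        out, _, origin = w.orient_and_origin(_cloud_sample(X))
        assert abs(origin - 20) < 2.0
        # mode of output density at ~0 (sign may flip for anterior rule)
        assert min(abs(np.median(out.positions[:, 0]) - 0), abs(origin - 20)) < 2.0

    def test_rotationally_symmetric_cloud_warns(self):
        n = 64
        phi = np.arange(n) * 2 * np.pi / n
        X = np.column_stack(
            [np.tile(np.linspace(-10, 10, 8), n // 8), 5 * np.cos(phi), 5 * np.sin(phi)]
        )
        with pytest.warns(UserWarning, match="uniform"):
            _, roll, _ = w.orient_and_origin(_cloud_sample(X))
        assert roll == 0.0


class TestFineAlign:
    def _named_sample(self, positions, names):
        cells = [
            CellRecord(cell_id=f"c{i}", position=p, name=nm)
            for i, (p, nm) in enumerate(zip(positions, names))
        ]
        return WormSample(animal_id="a", cells=cells)

    def test_identity_when_already_aligned(self):
        X = np.array([[0, 0, 0], [10, 0, 0], [0, 5, 0], [0, 0, 3.0]])
        names = ["A", "B", "C", "D"]
        s = self._named_sample(X, names)
        out, tf = w.fine_align(s, {n: X[i] for i, n in enumerate(names)})
        np.testing.assert_allclose(out.positions, X, atol=1e-10)
        assert abs(tf.scale - 1) < 1e-10

    def test_pure_translation_recovered(self):
        X = np.array([[0, 0, 0], [10, 0, 0], [0, 5, 0], [2, 2, 2.0]])
        names = list("ABCD")
        t = np.array([3.0, -1.0, 2.0])
        s = self._named_sample(X + t, names)
        out, tf = w.fine_align(s, {n: X[i] for i, n in enumerate(names)})
        np.testing.assert_allclose(tf.translation, -t, atol=1e-8)
        np.testing.assert_allclose(out.positions, X, atol=1e-8)

    def test_similarity_recovered(self):
        # Kabsch-with-scale oracle: apply known rotation+scale, recover it
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3)) * 5
        names = [f"L{i}" for i in range(10)]
        phi = 0.4
        R = _rot_x(phi)
        Y = 1.1 * X @ R.T + np.array([1.0, 2.0, 3.0])
        s = self._named_sample(Y, names)
        out, tf = w.fine_align(s, {n: X[i] for i, n in enumerate(names)})
        assert abs(tf.scale - 1 / 1.1) < 1e-6
        np.testing.assert_allclose(out.positions, X, atol=1e-6)

    def test_too_few_landmarks_warns_and_keeps(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        s = self._named_sample(X, ["A", "B", None, None])
        with pytest.warns(UserWarning, match="landmarks"):
            out, tf = w.fine_align(s, {"A": X[0], "B": X[1]})
        assert tf is None
        np.testing.assert_array_equal(out.positions, X)


class TestFullPipeline:
    def test_idempotent(self, truth_small):
        model = w.VariationModel()
        raw, _, _ = w.sample_worm(truth_small, model, "a0", seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1, _ = w.correct_posture(raw)
            c2, _ = w.correct_posture(c1)
        assert np.abs(c2.positions - c1.positions).max() < 1e-6

    def test_bend_roundtrip_residual_under_1um(self):
        # sagitta <= 10 um over ~100 um length
        rng = np.random.default_rng(9)
        n = 200
        X = np.column_stack(
            [rng.uniform(-50, 50, n), rng.normal(0, 4, n), rng.normal(0, 3, n)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref, _ = w.correct_posture(_cloud_sample(X))
            bent = X.copy()
            bent[:, 1] += 0.004 * bent[:, 0] ** 2  # sagitta 10 um at half-length 50
            got, _ = w.correct_posture(_cloud_sample(bent))
        resid = np.linalg.norm(got.positions - ref.positions, axis=1)
        assert resid.max() < 1.0

    def test_correction_reduces_cross_animal_variance(self, truth_small, dye_landmarks):
        dye, lm = dye_landmarks
        model = w.VariationModel(iid_sd=np.full(3, 1.0), detection_rate=1.0)
        raws, ideals = [], []
        for i in range(6):
            raw, ideal, _ = w.sample_worm(
                truth_small, model, f"v{i}", seed=30 + i, dye_names=dye
            )
            raws.append(raw)
            ideals.append(ideal)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = [w.correct_posture(s, landmarks=lm)[0] for s in raws]

        def mean_var(samples):
            P = np.stack([s.positions for s in samples])
            return P.var(axis=0).mean()

        assert mean_var(corr) < 0.1 * mean_var(raws)

    def test_robust_to_cell_deletion(self):
        """Deleting 20% of cells leaves the across-animal variance profile
        (moving average of per-cell positional variance along AP, window
        ±15 μm) essentially unchanged — the correction does not depend on
        any individual cell.  Compared on matched (cell, animal)
        observations so estimator sample size is controlled.
        """
        truth = w.make_ground_truth(n_cells=200, seed=3)
        rng0 = np.random.default_rng(0)
        dye = set(rng0.choice(truth.names, 30, replace=False))
        lm = {n: truth.base_positions[n] for n in dye}
        model = w.VariationModel(detection_rate=1.0)
        n_cells, n_anim = 200, 12
        raws = [
            w.sample_worm(truth, model, f"a{i}", seed=100 + i, dye_names=dye)[0]
            for i in range(n_anim)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_corr = [w.correct_posture(s, landmarks=lm)[0] for s in raws]
            rng = np.random.default_rng(55)
            pos_del = {i: [] for i in range(n_cells)}
            pos_ctl = {i: [] for i in range(n_cells)}
            for s, fc in zip(raws, full_corr):
                keep = rng.random(n_cells) > 0.2
                sub = WormSample(
                    animal_id=s.animal_id,
                    cells=[c for c, k in zip(s.cells, keep) if k],
                )
                corr, _ = w.correct_posture(sub, landmarks=lm)
                for j, i in enumerate(np.flatnonzero(keep)):
                    pos_del[i].append(corr.positions[j])
                    pos_ctl[i].append(fc.positions[i])
        ap = {i: np.mean([c.positions[i, 0] for c in full_corr]) for i in range(n_cells)}

        def profile(pos):
            var = {c: np.array(l).var(axis=0).sum() for c, l in pos.items() if len(l) >= 4}
            xs = np.array([ap[c] for c in sorted(var)])
            vs = np.array([var[c] for c in sorted(var)])
            grid = np.linspace(-40, 20, 25)
            return np.array(
                [vs[np.abs(xs - g) <= 15].mean() if (np.abs(xs - g) <= 15).sum() >= 5
                 else np.nan for g in grid]
            )

        pf, pd_ = profile(pos_ctl), profile(pos_del)
        m = ~np.isnan(pf) & ~np.isnan(pd_)
        rel = np.abs(pd_[m] - pf[m]) / pf[m]
        assert np.median(rel) < 0.10
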