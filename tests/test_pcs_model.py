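"""PCS forward model, tensor algebra and Q-factor."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import glycopcs as g
from glycopcs.pcs import PolarPosition, pcs_basis
from glycopcs.shift_tables import Nucleus, PCSMeasurement, ResonanceAssignment
from glycopcs.synthetic import build_conformer, default_ring_template

MAGIC_ANGLE = np.degrees(np.arccos(1 / np.sqrt(3)))


def _polar_via_eigenframe(v, tensor):
    """Independent route: eigendecompose, rotate into the principal frame,
    evaluate the polar closed form."""
    p = tensor.principal()
    R = Rotation.from_euler("ZYZ", p.euler_zyz_deg, degrees=True).as_matrix()
    w = R.T @ np.asarray(v, float)
    r = np.linalg.norm(w)
    theta = np.degrees(np.arccos(np.clip(w[2] / r, -1, 1)))
    phi = np.degrees(np.arctan2(w[1], w[0]))
    return g.pcs_polar(PolarPosition(r, theta, phi),
                       p.delta_chi_ax, p.delta_chi_rh)


class TestPcsPolar:
    def test_magic_angle_null(self):
        for r in (5.0, 10.0, 25.0):
            assert g.pcs_polar(PolarPosition(r, MAGIC_ANGLE, 77.0),
                               3.7, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_axial_hand_value(self):
        # 2 * 1e4 / (12 pi 1000) = 0.53052 ppm
        assert g.pcs_polar(PolarPosition(10.0, 0.0, 0.0), 1.0, 0.0) == \
            pytest.approx(0.53052, abs=1e-5)

    def test_rhombic_hand_value(self):
        # 1.5 * 1e4 / (12 pi 1000) = 0.39789 ppm
        assert g.pcs_polar(PolarPosition(10.0, 90.0, 0.0), 0.0, 1.0) == \
            pytest.approx(0.39789, abs=1e-5)

    def test_inverse_cube_distance_law(self):
        a = g.pcs_polar(PolarPosition(8.0, 30.0, 10.0), 2.0, 0.5)
        b = g.pcs_polar(PolarPosition(16.0, 30.0, 10.0), 2.0, 0.5)
        assert a == pytest.approx(8.0 * b, rel=1e-12)

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            PolarPosition(0.0, 0.0, 0.0)


class TestPcsCartesian:
    def test_principal_frame_consistency(self):
        tensor = g.ChiTensor(np.diag([-2 / 3, -2 / 3, 4 / 3]))  # ax=2, rh=0
        val = g.pcs_cartesian(np.array([0.0, 0.0, 10.0]), np.zeros(3), tensor)
        assert val == pytest.approx(
            g.pcs_polar(PolarPosition(10.0, 0.0, 0.0), 2.0, 0.0), rel=1e-12
        )

    def test_equivalence_with_polar_over_random_draws(self):
        """Cartesian quadratic form ≡ eigendecomposition + polar form."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tensor = g.ChiTensor.from_components(*rng.normal(size=5) * 10)
            v = rng.normal(size=3) * rng.uniform(3, 30)
            a = g.pcs_cartesian(v, np.zeros(3), tensor)
            b = _polar_via_eigenframe(v, tensor)
            assert abs(a - b) <= 1e-12 * max(1.0, abs(a))

    def test_double_distance_eighth_pcs(self, rng):
        tensor = g.ChiTensor.from_components(*rng.normal(size=5))
        v = rng.normal(size=3) * 10
        assert g.pcs_cartesian(2 * v, np.zeros(3), tensor) == pytest.approx(
            g.pcs_cartesian(v, np.zeros(3), tensor) / 8.0, rel=1e-12
        )

    def test_coincident_positions_rejected(self):
        tensor = g.ChiTensor.from_principal(1.0, 0.0)
        with pytest.raises(ValueError, match="coincides"):
            g.pcs_cartesian(np.zeros(3), np.zeros(3), tensor)

    def test_frame_invariance(self):
        """Rotating coordinates and tensor together leaves Δδ unchanged."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            tensor = g.ChiTensor.from_components(*rng.normal(size=5) * 5)
            v = rng.normal(size=3) * 12
            R = Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**16))
            ).as_matrix()
            rotated = g.ChiTensor(R @ tensor.matrix @ R.T)
            assert g.pcs_cartesian(R @ v, np.zeros(3), rotated) == \
                pytest.approx(g.pcs_cartesian(v, np.zeros(3), tensor),
                              rel=1e-10, abs=1e-10)

    def test_basis_contraction_matches_forward(self, rng):
        tensor = g.ChiTensor.from_components(*rng.normal(size=5))
        v = rng.normal(size=(20, 3)) * 10
        direct = g.pcs_cartesian(v, np.zeros(3), tensor)
        assert np.allclose(pcs_basis(v) @ tensor.components, direct,
                           rtol=1e-14)


class TestChiTensor:
    def test_axial_tensor_principal(self):
        p = g.ChiTensor(np.diag([-1.0, -1.0, 2.0])).principal()
        assert p.delta_chi_ax == pytest.approx(3.0)
        assert p.delta_chi_rh == pytest.approx(0.0)

    def test_rhombic_ordering(self):
        # |zz| >= |yy| >= |xx| puts yy = -1.5, xx = -0.5
        p = g.ChiTensor(np.diag([-0.5, -1.5, 2.0])).principal()
        assert p.delta_chi_ax == pytest.approx(3.0)
        assert p.delta_chi_rh == pytest.approx(1.0)

    def test_principal_round_trip(self, rng):
        for _ in range(25):
            ax, rh = rng.normal() * 10, rng.normal() * 2
            euler = rng.uniform(-90, 90, size=3)
            t = g.ChiTensor.from_principal(ax, rh, euler)
            p = t.principal()
            back = g.ChiTensor.from_principal(
                p.delta_chi_ax, p.delta_chi_rh, p.euler_zyz_deg
            )
            assert np.allclose(back.matrix, t.matrix, atol=1e-10)

    def test_rhombicity_bound(self, rng):
        for _ in range(50):
            t = g.ChiTensor.from_components(*rng.normal(size=5) * 4)
            p = t.principal()
            assert abs(p.delta_chi_rh) <= (2 / 3) * abs(p.delta_chi_ax) + 1e-9

    def test_non_symmetric_rejected(self):
        m = np.diag([1.0, 1.0, -2.0])
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            g.ChiTensor(m)

    def test_non_traceless_rejected(self):
        with pytest.raises(ValueError, match="traceless"):
            g.ChiTensor(np.eye(3))

    def test_json_round_trip(self, tmp_path, rng):
        t = g.ChiTensor.from_components(*rng.normal(size=5))
        p = tmp_path / "t.json"
        t.to_json(p)
        assert np.allclose(g.ChiTensor.from_json(p).matrix, t.matrix)

    def test_magic_angle_cone_is_zero_set(self):
        """For an axial tensor the PCS vanishes on the magic-angle cone."""
        tensor = g.ChiTensor.from_principal(5.0, 0.0)
        for phi in np.linspace(-170, 170, 9):
            pos = 12.0 * np.array([
                np.sin(np.radians(MAGIC_ANGLE)) * np.cos(np.radians(phi)),
                np.sin(np.radians(MAGIC_ANGLE)) * np.sin(np.radians(phi)),
                np.cos(np.radians(MAGIC_ANGLE)),
            ])
            assert g.pcs_cartesian(pos, np.zeros(3), tensor) == \
                pytest.approx(0.0, abs=1e-12)


def _nuclei(conf, n=12):
    from glycopcs.synthetic import default_nuclei

    return default_nuclei(conf, n)


class TestEnsemblePcs:
    def _tagged(self, torsions):
        return g.place_metal(build_conformer(torsions), default_ring_template())

    def test_single_conformer_equals_direct(self):
        conf = self._tagged({"Gal-Glc": (-34, -32), "GalNAc-Gal": (30, 17),
                             "Neu5Ac-Gal": (-174, -32)})
        tensor = g.ChiTensor.from_principal(-20.0, -5.0)
        nuclei = _nuclei(conf)
        preds = g.ensemble_pcs(g.Ensemble.uniform([conf]), tensor, nuclei)
        for p in preds:
            pos = conf.position(p.assignment.residue_label,
                                p.assignment.atom_label)
            assert p.delta_delta_calc_ppm == pytest.approx(
                g.pcs_cartesian(pos, conf.metal_position, tensor), rel=1e-12
            )

    def test_two_conformer_average(self):
        a = self._tagged({"Gal-Glc": (-34, -32), "GalNAc-Gal": (30, 17),
                          "Neu5Ac-Gal": (-174, -32)})
        b = self._tagged({"Gal-Glc": (40, -4), "GalNAc-Gal": (30, 17),
                          "Neu5Ac-Gal": (-69, -6)})
        tensor = g.ChiTensor.from_principal(-20.0, -5.0)
        nuclei = _nuclei(a)
        pa = g.ensemble_pcs(g.Ensemble.uniform([a]), tensor, nuclei)
        pb = g.ensemble_pcs(g.Ensemble.uniform([b]), tensor, nuclei)
        pab = g.ensemble_pcs(g.Ensemble.uniform([a, b]), tensor, nuclei)
        for x, y, xy in zip(pa, pb, pab):
            assert xy.delta_delta_calc_ppm == pytest.approx(
                0.5 * (x.delta_delta_calc_ppm + y.delta_delta_calc_ppm),
                rel=1e-12,
            )

    def test_concatenation_linearity(self, small_ensemble):
        """Blending two sub-ensembles by weight equals predicting on the
        concatenated, renormalized ensemble."""
        tensor = g.ChiTensor.from_principal(-20.0, -5.0)
        nuclei = _nuclei(small_ensemble.conformers[0])
        half = len(small_ensemble) // 2
        e1 = g.Ensemble.uniform(small_ensemble.conformers[:half])
        e2 = g.Ensemble.uniform(small_ensemble.conformers[half:])
        w1 = half / len(small_ensemble)
        p1 = g.ensemble_pcs(e1, tensor, nuclei)
        p2 = g.ensemble_pcs(e2, tensor, nuclei)
        pall = g.ensemble_pcs(small_ensemble, tensor, nuclei)
        for a, b, c in zip(p1, p2, pall):
            assert c.delta_delta_calc_ppm == pytest.approx(
                w1 * a.delta_delta_calc_ppm + (1 - w1) * b.delta_delta_calc_ppm,
                rel=1e-10,
            )

    def test_missing_metal_position_named(self):
        conf = build_conformer({"Gal-Glc": (-34, -32), "GalNAc-Gal": (30, 17),
                                "Neu5Ac-Gal": (-174, -32)})
        tensor = g.ChiTensor.from_principal(1.0, 0.0)
        with pytest.raises(ValueError, match="conformer 0"):
            g.ensemble_pcs(g.Ensemble.uniform([conf]), tensor, _nuclei(conf))


def _obs(values):
    return [
        PCSMeasurement(
            ResonanceAssignment("Glc", f"H{i+1}", Nucleus.H1), "Tm", "La", v
        )
        for i, v in enumerate(values)
    ]


def _calc(values):
    return [
        g.PCSPrediction(
            ResonanceAssignment("Glc", f"H{i+1}", Nucleus.H1), v
        )
        for i, v in enumerate(values)
    ]


class TestQFactor:
    def test_perfect_agreement(self):
        assert g.q_factor(_obs([1.0, -2.0, 0.5]), _calc([1.0, -2.0, 0.5])) == 0.0

    def test_null_model_gives_one(self):
        assert g.q_factor(_obs([1.0, -2.0, 0.5]), _calc([0.0, 0.0, 0.0])) == \
            pytest.approx(1.0)

    def test_hand_example(self):
        # rms(0.1, -0.1)/rms(1, 2) = 0.1/1.58114 = 0.06325
        assert g.q_factor(_obs([1.0, 2.0]), _calc([1.1, 1.9])) == \
            pytest.approx(0.06325, abs=1e-5)

    def test_scale_covariance(self):
        q1 = g.q_factor(_obs([1.0, 2.0, -1.5]), _calc([1.2, 1.8, -1.0]))
        q2 = g.q_factor(_obs([3.0, 6.0, -4.5]), _calc([3.6, 5.4, -3.0]))
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_no_matches_rejected(self):
        calc = [g.PCSPrediction(
            ResonanceAssignment("Gal", "H1", Nucleus.H1), 1.0)]
        with pytest.raises(ValueError, match="no matched"):
            g.q_factor(_obs([1.0]), calc)

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            g.q_factor(_obs([0.0, 0.0]), _calc([1.0, 1.0]))
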