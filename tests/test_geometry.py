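"""Ensemble I/O, subsampling, ring superposition, metal placement, dihedrals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import glycopcs as g
from glycopcs.geometry import kabsch, subsample_plan
from glycopcs.synthetic import build_conformer, default_ring_template

GM2_TORSIONS = {
    "Gal-Glc": (-34.0, -32.0),
    "GalNAc-Gal": (30.0, 17.0),
    "Neu5Ac-Gal": (-174.0, -32.0),
}


class TestSubsamplePlan:
    def test_study_protocol_yields_2000(self):
        plan = subsample_plan(10, 12000, 1, 2000, 50)
        assert plan.count == 2000
        assert all(idx.size == 200 for idx in plan.indices)

    def test_single_run(self):
        assert subsample_plan(1, 12000, 1, 2000, 50).count == 200

    def test_identity_subsampling(self):
        assert subsample_plan(3, 1000, 10, 0, 1).count == 3 * 100

    @pytest.mark.parametrize("stride_pair", [(1, 5), (5, 25), (25, 50)])
    def test_count_monotone_in_stride(self, stride_pair):
        lo, hi = stride_pair
        assert (subsample_plan(4, 9000, 1, 1000, hi).count
                <= subsample_plan(4, 9000, 1, 1000, lo).count)

    def test_count_monotone_in_discard(self):
        counts = [subsample_plan(2, 10000, 1, d, 50).count
                  for d in (0, 1000, 5000, 9000)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            subsample_plan(1, 1000, 1, 100, 0)
        with pytest.raises(ValueError):
            subsample_plan(1, 1000, 1, 1000, 10)


class TestSuperposition:
    def test_identity(self):
        template = default_ring_template()
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels], template.coords
        )
        tf = g.superpose_ring(conf, template)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)
        assert tf.rmsd < 1e-9

    def test_pure_translation(self):
        template = default_ring_template()
        t = np.array([1.0, 2.0, 3.0])
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels], template.coords + t
        )
        tf = g.superpose_ring(conf, template)
        assert np.allclose(tf.translation, t, atol=1e-9)
        assert tf.rmsd < 1e-9

    def test_rotation_recovered_exactly(self):
        template = default_ring_template()
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels],
            template.coords @ R.T,
        )
        tf = g.superpose_ring(conf, template)
        assert np.allclose(tf.rotation, R, atol=1e-9)
        assert tf.rmsd < 1e-9

    def test_transform_composes_to_identity(self, rng):
        """Applying the recovered transform to the template reproduces the
        rigidly moved ring exactly."""
        template = default_ring_template()
        R = Rotation.random(random_state=np.random.RandomState(4)).as_matrix()
        t = rng.normal(size=3) * 5
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels],
            template.coords @ R.T + t,
        )
        tf = g.superpose_ring(conf, template)
        assert np.allclose(tf.apply(template.coords), conf.coords, atol=1e-9)

    def test_missing_ring_atom_named(self):
        template = default_ring_template()
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels[:-1]],
            template.coords[:-1],
        )
        with pytest.raises(ValueError, match="O5"):
            g.superpose_ring(conf, template)

    def test_distorted_ring_warns(self, rng):
        template = default_ring_template()
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels],
            template.coords + rng.normal(scale=1.0, size=(6, 3)),
        )
        with pytest.warns(UserWarning, match="rmsd"):
            g.superpose_ring(conf, template)


class TestPlaceMetal:
    def test_identity_gives_offset(self):
        template = default_ring_template()
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels], template.coords
        )
        tagged = g.place_metal(conf, template)
        assert np.allclose(tagged.metal_position, template.metal_offset, atol=1e-9)

    def test_translation_equivariance(self):
        template = default_ring_template()
        t = np.array([-3.0, 0.5, 7.0])
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels], template.coords + t
        )
        tagged = g.place_metal(conf, template)
        assert np.allclose(tagged.metal_position, template.metal_offset + t,
                           atol=1e-9)

    def test_known_rotation_oracle(self):
        """Metal position equals R·offset + t computed by hand."""
        template = default_ring_template()
        R = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        t = np.array([2.0, -1.0, 4.0])
        conf = g.Conformer(
            [("Glc", a) for a in template.atom_labels],
            template.coords @ R.T + t,
        )
        tagged = g.place_metal(conf, template)
        assert np.allclose(tagged.metal_position,
                           R @ template.metal_offset + t, atol=1e-9)


class TestDihedral:
    def test_cis_is_zero(self):
        assert g.dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_trans_is_180(self):
        assert g.dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)) == \
            pytest.approx(180.0, abs=1e-12)

    def test_plus_60_reference_case(self):
        ang = g.dihedral(
            (1, 0, 0), (0, 0, 0), (0, 0, 1),
            (np.cos(np.pi / 3), np.sin(np.pi / 3), 1),
        )
        assert ang == pytest.approx(60.0, abs=1e-9)

    def test_reversal_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 3
        assert g.dihedral(*pts) == pytest.approx(
            g.dihedral(*pts[::-1]), abs=1e-9
        )

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 4
        R = Rotation.random(random_state=np.random.RandomState(seed % 2**16))
        moved = pts @ R.as_matrix().T + rng.normal(size=3) * 10
        assert g.dihedral(*moved) == pytest.approx(
            g.dihedral(*pts), abs=1e-8
        )

    def test_negates_under_mirror(self, rng):
        pts = rng.normal(size=(4, 3)) * 4
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert g.dihedral(*mirrored) == pytest.approx(
            -g.dihedral(*pts), abs=1e-9
        )

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            g.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_coincident_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            g.dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))


class TestEnsembleIO:
    def test_two_model_round_trip(self, tmp_path):
        confs = [
            g.place_metal(build_conformer(GM2_TORSIONS), default_ring_template()),
            g.place_metal(
                build_conformer({**GM2_TORSIONS, "Gal-Glc": (40.0, -4.0)}),
                default_ring_template(),
            ),
        ]
        ens = g.Ensemble.uniform(confs)
        path = tmp_path / "two.pdb"
        g.write_ensemble(ens, path)
        back = g.read_ensemble(path)
        assert len(back) == 2
        assert np.allclose(back.weights, 0.5)
        assert back.conformers[0].labels == confs[0].labels
        for a, b in zip(back.conformers, confs):
            assert np.abs(a.coords - b.coords).max() < 1e-3  # PDB precision
            assert np.abs(a.metal_position - b.metal_position).max() < 1e-3

    def test_single_model_round_trip(self, tmp_path):
        conf = build_conformer(GM2_TORSIONS)
        path = tmp_path / "one.pdb"
        g.write_ensemble(g.Ensemble.uniform([conf]), path)
        back = g.read_ensemble(path)
        assert len(back) == 1 and back.weights[0] == 1.0
        assert back.conformers[0].metal_position is None

    def test_inconsistent_models_rejected(self, tmp_path):
        conf = build_conformer(GM2_TORSIONS)
        path = tmp_path / "bad.pdb"
        g.write_ensemble(g.Ensemble.uniform([conf, conf]), path)
        # drop one atom from MODEL 2 only
        lines = path.read_text().splitlines(keepends=True)
        in_m2 = False
        dropped = False
        out = []
        for ln in lines:
            if ln.startswith("MODEL") and "2" in ln:
                in_m2 = True
            if in_m2 and not dropped and ln.startswith("ATOM"):
                dropped = True
                continue
            out.append(ln)
        path.write_text("".join(out))
        with pytest.raises(ValueError, match="inconsistent"):
            g.read_ensemble(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            g.read_ensemble(tmp_path / "nope.pdb")


class TestGlycosidicTorsions:
    def test_constant_ensemble_has_zero_variance(self):
        conf = build_conformer(GM2_TORSIONS)
        ens = g.Ensemble.uniform([conf] * 5)
        for name, ts in g.glycosidic_torsions(ens).items():
            assert np.ptp(ts.phi_deg) == 0.0
            assert np.ptp(ts.psi_deg) == 0.0

    def test_builder_round_trip(self):
        """Torsions recomputed from built coordinates equal the request."""
        ens = g.Ensemble.uniform([build_conformer(GM2_TORSIONS)])
        series = g.glycosidic_torsions(ens)
        for name, (phi, psi) in GM2_TORSIONS.items():
            assert series[name].phi_deg[0] == pytest.approx(phi, abs=1e-6)
            assert series[name].psi_deg[0] == pytest.approx(psi, abs=1e-6)

    def test_missing_atom_names_linkage_and_conformer(self):
        conf = build_conformer(GM2_TORSIONS)
        keep = [i for i, (r, a) in enumerate(conf.labels)
                if not (r == "Gal" and a == "O3")]
        broken = g.Conformer([conf.labels[i] for i in keep], conf.coords[keep])
        ens = g.Ensemble.uniform([broken])
        with pytest.raises(ValueError, match="Neu5Ac-Gal.*conformer 0"):
            g.glycosidic_torsions(ens)


def test_kabsch_rejects_mismatched_shapes():
    with pytest.raises(ValueError):
        kabsch(np.zeros((3, 3)), np.zeros((4, 3)))


def test_ensemble_weight_validation():
    conf = build_conformer(GM2_TORSIONS)
    with pytest.raises(ValueError, match="sum to 1"):
        g.Ensemble([conf, conf], np.array([0.7, 0.7]))
    with pytest.raises(ValueError, match="non-negative"):
        g.Ensemble([conf, conf], np.array([1.5, -0.5]))
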