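"""Kabsch-Sander secondary structure and Shrake-Rupley SAS."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import binom

from idpens.ensemble_io import ConformationalEnsemble, EnsembleError, Topology
from idpens.structure_metrics import (
    assign_secondary_structure,
    basin_structure_report,
    helical_content_summary,
    shrake_rupley_sas,
)
from idpens.synthetic import EnsembleSpec, generate_ensemble

from conftest import make_chain_ensemble, make_point_ensemble


def helix_classes(labels):
    return np.where(np.isin(labels, ("H", "G", "I")), labels, "x")


def mdtraj_dssp(ensemble, tmp_path):
    import mdtraj as md

    from idpens.ensemble_io import write_multimodel_pdb

    path = tmp_path / "ens.pdb"
    write_multimodel_pdb(ensemble, path)
    return md.compute_dssp(md.load(str(path)), simplified=False)


IDEAL = {"alpha": (-57.0, -47.0), "three10": (-49.0, -26.0),
         "pi": (-57.0, -70.0), "extended": (-140.0, 135.0)}


class TestSecondaryStructure:
    def test_ideal_alpha_helix_core(self):
        n = 20
        phi = np.full(n, IDEAL["alpha"][0])
        psi = np.full(n, IDEAL["alpha"][1])
        ens = make_chain_ensemble([(phi, psi)], "A" * n)
        ss = assign_secondary_structure(ens).assignments[0]
        assert (ss == "H").sum() >= 14
        assert not np.isin(ss, ("G", "I")).any()

    def test_fully_extended_chain_has_no_helix(self):
        n = 20
        ens = make_chain_ensemble([(np.full(n, -180.0), np.full(n, 180.0))],
                                  "A" * n)
        ss = assign_secondary_structure(ens).assignments[0]
        assert not np.isin(ss, ("H", "G", "I")).any()

    @pytest.mark.parametrize("construct", ["alpha", "three10", "pi", "extended"])
    def test_agreement_with_reference_implementation(self, construct, tmp_path):
        n = 20
        phi0, psi0 = IDEAL[construct]
        ens = make_chain_ensemble([(np.full(n, phi0), np.full(n, psi0))],
                                  "A" * n)
        ref = mdtraj_dssp(ens, tmp_path)[0]
        mine = assign_secondary_structure(ens).assignments[0]
        agreement = (helix_classes(ref) == helix_classes(mine)).mean()
        assert agreement >= 0.95

    def test_planted_occupancy_recovered(self):
        spec = EnsembleSpec(n_residues=30, n_frames=200,
                            helical_segments=[(8, 20, 0.5)],
                            coordinate_noise_sigma=0.01, seed=6)
        ens, truth = generate_ensemble(spec)
        profile = assign_secondary_structure(ens)
        # interior residues of the segment (ends are rounded by the
        # two-consecutive-turns rule)
        interior = slice(9, 18)
        measured = (profile.assignments[:, interior] == "H").mean(axis=0)
        realized = truth.helix_mask[:, interior].mean(axis=0)
        assert np.abs(measured - realized).max() <= 0.05
        lo, hi = binom.ppf([0.005, 0.995], 200, 0.5) / 200
        assert lo <= measured.mean() <= hi

    def test_persistence_rows_sum_to_one(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        pers = assign_secondary_structure(ens).persistence()
        np.testing.assert_allclose(pers.sum(axis=1), 1.0)

    def test_missing_backbone_atom_rejected(self):
        top = Topology(["N", "CA", "C"], ["ALA"] * 3, [1] * 3, ["N", "C", "C"])
        ens = ConformationalEnsemble(top, np.zeros((1, 3, 3)))
        with pytest.raises(EnsembleError, match="residue 1"):
            assign_secondary_structure(ens)


class TestHelicalSummary:
    def test_all_coil_profile(self):
        n = 20
        ens = make_chain_ensemble([(np.full(n, -180.0), np.full(n, 180.0))],
                                  "A" * n)
        s = helical_content_summary(assign_secondary_structure(ens))
        assert s["mean_alpha"] == s["mean_310"] == s["mean_pi"] == 0
        assert s["total_helical_pct"] == 0.0

    def test_constant_helix_count_arithmetic(self):
        # 70-residue chain with a segment yielding a fixed helix count
        spec = EnsembleSpec(n_residues=70, n_frames=4,
                            helical_segments=[(10, 27, 1.0)],
                            coordinate_noise_sigma=0.002, seed=8)
        ens, _ = generate_ensemble(spec)
        profile = assign_secondary_structure(ens)
        counts = (profile.assignments == "H").sum(axis=1)
        s = helical_content_summary(profile)
        assert s["mean_alpha"] == pytest.approx(counts.mean())
        assert s["max_alpha"] == counts.max()
        assert s["pct_alpha"] == pytest.approx(100.0 * counts.mean() / 70)
        assert s["total_helical_pct"] >= s["pct_alpha"]

    def test_empty_subset_rejected(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        profile = assign_secondary_structure(ens)
        with pytest.raises(EnsembleError):
            helical_content_summary(profile, frames=[])


def single_atom_ensemble(radius_key="O"):
    top = Topology(["O"], ["HOH"], [1], [radius_key])
    return ConformationalEnsemble(top, np.zeros((1, 1, 3)))


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        ens = single_atom_ensemble()
        sas = shrake_rupley_sas(ens, probe_radius=0.14, n_points=960,
                                radii={"O": 0.15})
        exact = 4.0 * np.pi * 0.29 ** 2
        assert sas.total_sas[0] == pytest.approx(exact, rel=0.005)

    def test_disjoint_spheres_additive(self):
        top = Topology(["O", "O"], ["HOH"] * 2, [1, 2], ["O", "O"])
        coords = np.array([[[0.0, 0, 0], [10.0, 0, 0]]])
        ens = ConformationalEnsemble(top, coords)
        sas = shrake_rupley_sas(ens, n_points=960, radii={"O": 0.15})
        single = shrake_rupley_sas(single_atom_ensemble(), n_points=960,
                                   radii={"O": 0.15})
        assert sas.total_sas[0] == pytest.approx(2 * single.total_sas[0],
                                                 rel=1e-9)

    def test_overlapping_spheres_match_integration_oracle(self):
        d = 0.2
        top = Topology(["O", "O"], ["HOH"] * 2, [1, 2], ["O", "O"])
        ens = ConformationalEnsemble(top, np.array([[[0.0, 0, 0], [d, 0, 0]]]))
        sas = shrake_rupley_sas(ens, n_points=960, radii={"O": 0.15})
        # fine-lattice integration oracle: dense band sampling in cos(theta)
        R = 0.15 + 0.14
        n = 2_000_000
        z = (np.arange(n) + 0.5) / n * 2.0 - 1.0  # cos-theta lattice
        # point on sphere A at (R z, ...) is buried iff within R of center B
        dist2 = R ** 2 + d ** 2 - 2 * R * d * z
        frac_accessible = (dist2 > R ** 2).mean()
        oracle = 2 * 4.0 * np.pi * R ** 2 * frac_accessible  # symmetric pair
        assert sas.total_sas[0] == pytest.approx(oracle, rel=0.01)

    def test_translation_invariance_exact(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sub = ens.subset([0, 1])
        moved = ConformationalEnsemble(sub.topology,
                                       sub.frames + np.array([5.0, -3.0, 1.0]))
        a = shrake_rupley_sas(sub, n_points=240)
        b = shrake_rupley_sas(moved, n_points=240)
        assert np.abs(a.total_sas - b.total_sas).max() <= 1e-9

    def test_rotation_invariance_within_quadrature(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sub = ens.subset([0])
        rot = Rotation.from_euler("xyz", [30, 60, 15], degrees=True).as_matrix()
        moved = ConformationalEnsemble(sub.topology, sub.frames @ rot.T)
        a = shrake_rupley_sas(sub, n_points=960)
        b = shrake_rupley_sas(moved, n_points=960)
        assert abs(a.total_sas[0] - b.total_sas[0]) / a.total_sas[0] <= 0.005

    def test_quadrature_converges_monotonically(self):
        ens = single_atom_ensemble()
        top2 = Topology(["O", "O"], ["HOH"] * 2, [1, 2], ["O", "O"])
        pair = ConformationalEnsemble(top2,
                                      np.array([[[0.0, 0, 0], [0.25, 0, 0]]]))
        # against the two-sphere closed form (spherical cap area)
        R = 0.29
        d = 0.25
        cap_height = R - d / 2
        exact = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * cap_height)
        errs = []
        for n in (240, 960, 3840):
            sas = shrake_rupley_sas(pair, n_points=n, radii={"O": 0.15})
            errs.append(abs(sas.total_sas[0] - exact))
        assert errs[2] <= errs[0]          # finer quadrature beats coarser
        assert max(errs) <= 0.005 * exact  # all within 0.5% of closed form

    def test_per_residue_sums_to_total(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        sas = shrake_rupley_sas(ens.subset([0, 1]), n_points=240)
        np.testing.assert_allclose(sas.per_residue_sas.sum(axis=1),
                                   sas.total_sas, rtol=1e-9)

    def test_unknown_element_rejected(self):
        top = Topology(["X"], ["UNK"], [1], ["Xx"])
        ens = ConformationalEnsemble(top, np.zeros((1, 1, 3)))
        with pytest.raises(EnsembleError, match="radius"):
            shrake_rupley_sas(ens)


class TestBasinReport:
    def test_single_basin_equals_global_summary(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        ss = assign_secondary_structure(ens)
        sas = shrake_rupley_sas(ens, n_points=120)
        table = basin_structure_report(["A"] * ens.n_frames, ss, sas)
        assert len(table) == 1
        s = helical_content_summary(ss)
        row = table.iloc[0]
        assert row["mean_alpha"] == pytest.approx(s["mean_alpha"])
        assert row["total_helical_pct"] == pytest.approx(s["total_helical_pct"])
        assert row["sas_mean"] == pytest.approx(sas.total_sas.mean())
        assert row["sas_min"] == pytest.approx(sas.total_sas.min())

    def test_compact_basin_has_smaller_sas(self, two_state_ensemble):
        ens, truth = two_state_ensemble
        ss = assign_secondary_structure(ens)
        sas = shrake_rupley_sas(ens, n_points=120)
        labels = list(truth.state_labels)
        table = basin_structure_report(labels, ss, sas).set_index("basin")
        assert table.loc["compact", "sas_mean"] < table.loc["extended", "sas_mean"]

    def test_unassigned_frames_skipped(self, two_state_ensemble):
        ens, _ = two_state_ensemble
        ss = assign_secondary_structure(ens)
        sas = shrake_rupley_sas(ens, n_points=120)
        labels = ["unassigned"] * ens.n_frames
        labels[0] = "A"
        table = basin_structure_report(labels, ss, sas)
        assert list(table["basin"]) == ["A"]
        assert int(table["n_frames"].iloc[0]) == 1
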