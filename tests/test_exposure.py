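import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from statescan import (RadiusSet, StructureModel, Trajectory, TwoStateSpec,
                       detect_hbonds, detect_salt_bridges, ligand_sasa_series,
                       percent_change, shrake_rupley_sasa,
                       simulate_two_state_trajectory, water_mediated_bridges,
                       catalytic_site_report)
from statescan.exposure import CatalyticSiteConfig, sphere_points
from statescan.geometry import DistanceSeries
from conftest import make_topology
from oracles import contacts_loops, two_sphere_sasa_caps, water_bridges_loops

RADII = RadiusSet(radii={"C": 1.7}, probe_radius=1.4, default_radius=1.7)


def _carbon_model(coords):
    coords = np.asarray(coords, float)
    return StructureModel(make_topology(len(coords)), coords)


class TestShrakeRupley:
    def test_isolated_atom_is_full_sphere(self):
        model = _carbon_model([[0.0, 0.0, 0.0]])
        res = shrake_rupley_sasa(model, RADII, n_points=960, target_sel=np.array([0]))
        exact = 4.0 * np.pi * 3.1 ** 2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_is_zero(self):
        shell = 2.0 * sphere_points(60)
        model = _carbon_model(np.vstack([[0.0, 0.0, 0.0], shell]))
        res = shrake_rupley_sasa(model, RADII, n_points=960,
                                 target_sel=np.array([0]),
                                 context_sel=np.arange(1, 61))
        assert res.total == 0.0

    def test_two_sphere_cap_formula(self):
        model = _carbon_model([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        res = shrake_rupley_sasa(model, RADII, n_points=960, target_sel=np.arange(2))
        exact = two_sphere_sasa_caps(1.7, 1.4, 2.0)
        assert res.per_atom[0] == pytest.approx(exact, rel=0.01)
        assert res.per_atom[1] == pytest.approx(exact, rel=0.01)

    def test_additivity_of_selection_total(self, rng):
        model = _carbon_model(rng.uniform(-4, 4, (8, 3)))
        res = shrake_rupley_sasa(model, RADII, n_points=240, target_sel=np.arange(8))
        assert res.total == pytest.approx(float(res.per_atom.sum()), abs=1e-9)

    def test_quadrature_convergence(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            model = _carbon_model(r.uniform(-3, 3, (6, 3)))
            coarse = shrake_rupley_sasa(model, RADII, 960, target_sel=np.arange(6)).total
            fine = shrake_rupley_sasa(model, RADII, 3840, target_sel=np.arange(6)).total
            assert abs(coarse - fine) / fine < 0.005

    def test_rigid_transform_invariance(self, rng):
        coords = rng.uniform(-3, 3, (6, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        a = shrake_rupley_sasa(_carbon_model(coords), RADII, 960,
                               target_sel=np.arange(6)).per_atom
        b = shrake_rupley_sasa(_carbon_model(coords @ rot.T + 5.0), RADII, 960,
                               target_sel=np.arange(6)).per_atom
        # same deterministic point lattice, rotated occluders: small quadrature drift
        assert np.allclose(a, b, rtol=0.02, atol=0.5)

    def test_missing_radius_raises_without_default(self):
        strict = RadiusSet(radii={"N": 1.55}, probe_radius=1.4, default_radius=None)
        model = _carbon_model([[0.0, 0.0, 0.0]])
        with pytest.raises(KeyError):
            shrake_rupley_sasa(model, strict, 960, target_sel=np.array([0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley_sasa(_carbon_model([[0, 0, 0]]), RADII, n_points=6,
                               target_sel=np.array([0]))


class TestLigandSASA:
    def test_empty_context_equals_isolated(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        with_ctx = ligand_sasa_series(traj, ligand_sel="resname GTP", context_sel=None)
        isolated = shrake_rupley_sasa(base_model, target_sel="resname GTP").total
        assert with_ctx.values[0] == pytest.approx(isolated, abs=1e-9)

    def test_open_state_more_exposed_than_closed(self, base_model):
        spec = TwoStateSpec.from_base(base_model, n_frames=2, seed=1, sigma=0.0)
        closed = StructureModel(base_model.topology, spec.closed_centroid)
        opened = StructureModel(base_model.topology, spec.open_centroid)
        sasa_closed = shrake_rupley_sasa(closed, target_sel="resname GTP",
                                         context_sel="protein").total
        sasa_open = shrake_rupley_sasa(opened, target_sel="resname GTP",
                                       context_sel="protein").total
        assert sasa_open > sasa_closed

    def test_percent_change_of_self_is_zero(self):
        series = DistanceSeries("s", np.array([3.0, 4.0]))
        assert percent_change(series, series) == 0.0


class TestContacts:
    def test_cutoff_edges(self):
        model = _carbon_model([[0, 0, 0], [2.9, 0, 0], [3.8, 0, 0]])
        close = detect_hbonds(model, np.array([0]), np.array([1, 2]))
        assert len(close) == 1 and close[0].distance == pytest.approx(2.9)
        far = detect_salt_bridges(model, np.array([0]), np.array([2]), cutoff=3.5)
        assert far == []

    def test_hbond_and_salt_bridge_match_bruteforce(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            coords = r.uniform(0, 8, (14, 3))
            model = _carbon_model(coords)
            ia, ib = np.arange(7), np.arange(7, 14)
            found = {(e.atom_a, e.atom_b)
                     for e in detect_hbonds(model, ia, ib, cutoff=3.5)}
            assert found == contacts_loops(coords, ia, ib, 3.5)
            found = {(e.atom_a, e.atom_b)
                     for e in detect_salt_bridges(model, ia, ib, cutoff=4.0)}
            assert found == contacts_loops(coords, ia, ib, 4.0)

    def test_water_bridge_requires_both_legs(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0], [3.0, 0, 0], [0.0, 3.0, 0]])
        model = _carbon_model(coords)
        events = water_mediated_bridges(model, np.array([0]), np.array([1]),
                                        np.array([2, 3]), cutoff=3.5)
        assert len(events) == 1 and events[0].water == 2

    def test_water_bridges_match_bruteforce(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed + 50)
            coords = r.uniform(0, 7, (15, 3))
            model = _carbon_model(coords)
            ia, ib, iw = np.arange(5), np.arange(5, 10), np.arange(10, 15)
            found = {e.water for e in water_mediated_bridges(model, ia, ib, iw, cutoff=3.5)}
            assert found == water_bridges_loops(coords, ia, ib, iw, 3.5)


class TestCatalyticReport:
    def test_competent_construction_full_occupancy(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        report = catalytic_site_report(traj)
        assert report.occupancies == {
            "q61_pg_contact": 1.0, "arg_alpha_salt_bridge": 1.0,
            "arg_gamma_salt_bridge": 1.0, "catalytic_water_bridge": 1.0}
        assert report.q61_pg_distance.values[0] == pytest.approx(4.0, abs=1e-6)

    def test_displaced_arginine_finger_zero_occupancy(self, base_model):
        coords = base_model.coords.copy()
        top = base_model.topology
        arg = (top.residue_seqs == 789)
        coords[arg] += np.array([7.0, 7.0, 0.0])
        traj = Trajectory(top, coords[None])
        report = catalytic_site_report(traj)
        assert report.occupancies["arg_alpha_salt_bridge"] == 0.0
        assert report.occupancies["arg_gamma_salt_bridge"] == 0.0

    def test_histidine_style_config_needs_no_code_change(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        site = CatalyticSiteConfig(q61_carbonyl="resseq 61 and name NE2",
                                   q61_amide="resseq 61 and name OE1")
        report = catalytic_site_report(traj, site)
        assert len(report.q61_pg_distance.values) == 1
        assert 0.0 <= report.q61_angle.values[0] <= 180.0

    def test_unresolved_atoms_reported_by_name(self, base_model):
        traj = Trajectory(base_model.topology, base_model.coords[None])
        site = CatalyticSiteConfig(arg_nh="resseq 999 and name NH1")
        with pytest.raises(ValueError, match="resseq 999"):
            catalytic_site_report(traj, site)
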