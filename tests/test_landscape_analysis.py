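import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from rdcens.errors import SelectionError
from rdcens.io_formats import KB_KJ_MOL_K, Conformation, Ensemble
from rdcens.landscape_analysis import (
    BasinPartition,
    LandscapeGrid,
    RegionDefinition,
    basin_population,
    breathing_angle,
    contact_occupancy,
    free_energy_surface,
    potential_energy_profile,
    rmsd_to_reference,
)


def _ca_conf(points):
    n = len(points)
    return Conformation(
        chain_ids=np.full(n, "A"),
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "ALA"),
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
        coords=np.asarray(points, float),
    )


THREE_REGIONS = RegionDefinition(region_1=[1], region_2=[2], region_3=[3])


class TestBreathingAngle:
    def test_collinear_is_180(self):
        conf = _ca_conf([[-5, 0, 0], [0, 0, 0], [7, 0, 0]])
        assert breathing_angle(conf, THREE_REGIONS) == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        conf = _ca_conf([[1, 0, 0], [0, 0, 0], [0, 1, 0]])
        assert breathing_angle(conf, THREE_REGIONS) == pytest.approx(90.0)

    def test_rigid_motion_invariance(self, system, rng):
        conf = system.conformation
        theta0 = breathing_angle(conf, system.regions)
        for _ in range(5):
            R = Rotation.random(random_state=int(rng.integers(2**31)))
            moved = conf.with_coords(R.apply(conf.coords) + rng.normal(size=3) * 20)
            assert breathing_angle(moved, system.regions) == pytest.approx(
                theta0, abs=1e-10
            )

    def test_regions_must_be_disjoint(self):
        with pytest.raises(SelectionError):
            RegionDefinition(region_1=[1, 2], region_2=[2], region_3=[3])


class TestRmsd:
    def test_identical_structures_are_zero(self, system):
        conf = system.conformation
        assert rmsd_to_reference(conf, conf, system.rmsd_selection) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rigid_motion_removed_by_superposition(self, system, rng):
        conf = system.conformation
        R = Rotation.random(random_state=3)
        moved = conf.with_coords(R.apply(conf.coords) + [10, -4, 2])
        assert rmsd_to_reference(moved, conf, system.rmsd_selection) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_matches_brute_force_rotation_minimisation(self, rng):
        """The closed-form superposition equals an independent numerical
        minimisation of RMSD over rotation vectors."""
        a = _ca_conf(rng.normal(size=(10, 3)) * 5)
        b = _ca_conf(rng.normal(size=(10, 3)) * 5)
        sel = np.arange(10)
        rmsd = rmsd_to_reference(a, b, sel)

        pa = a.coords - a.coords.mean(axis=0)
        pb = b.coords - b.coords.mean(axis=0)

        def cost(rotvec):
            moved = Rotation.from_rotvec(rotvec).apply(pa)
            return np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead",
                     options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000)).fun
            for x0 in [np.zeros(3), [1, 0, 0], [0, 2, 0], [0, 0, 3], [2, 2, -1]]
        )
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_mismatched_selection_sizes_rejected(self, system):
        small = _ca_conf(np.eye(3))
        with pytest.raises(SelectionError):
            rmsd_to_reference(system.conformation, small, np.arange(2))


class TestFreeEnergySurface:
    def test_identical_conformations_occupy_single_bin(self, system):
        ens = Ensemble([system.conformation.with_coords(system.conformation.coords)
                        for _ in range(7)])
        grid = free_energy_surface(
            ens, system.regions, system.conformation, system.rmsd_selection,
            temperature_K=310.0,
        )
        assert grid.counts.sum() == 7
        assert (grid.counts > 0).sum() == 1
        f = grid.free_energy
        assert np.nanmin(f) == pytest.approx(-KB_KJ_MOL_K * 310.0 * np.log(7))

    def test_counts_conserve_ensemble_size(self, system, two_state):
        ensemble, _ = two_state
        grid = free_energy_surface(
            ensemble, system.regions, system.conformation, system.rmsd_selection
        )
        assert grid.counts.sum() == len(ensemble)

    def test_uniform_histogram_has_flat_free_energy(self):
        grid = LandscapeGrid(
            theta_edges=np.arange(5.0), rmsd_edges=np.arange(4.0),
            counts=np.full((4, 3), 11), temperature_K=310.0,
        )
        f = grid.free_energy
        assert np.nanmax(f) - np.nanmin(f) == pytest.approx(0.0)

    def test_two_bin_free_energy_difference_is_analytic(self):
        grid = LandscapeGrid(
            theta_edges=np.array([0.0, 1.0, 2.0]),
            rmsd_edges=np.array([0.0, 1.0]),
            counts=np.array([[870], [130]]),
            temperature_K=310.0,
        )
        f = grid.free_energy
        df = f[1, 0] - f[0, 0]
        assert df == pytest.approx(-KB_KJ_MOL_K * 310.0 * np.log(130 / 870))

    def test_rescaling_counts_shifts_free_energy_uniformly(self):
        counts = np.array([[10, 20], [40, 5]])
        g1 = LandscapeGrid(np.arange(3.0), np.arange(3.0), counts, 310.0)
        g9 = LandscapeGrid(np.arange(3.0), np.arange(3.0), counts * 9, 310.0)
        diff = g9.free_energy - g1.free_energy
        assert np.nanmax(diff) - np.nanmin(diff) == pytest.approx(0.0, abs=1e-12)


class TestBasinPopulation:
    def test_single_basin_ensemble(self, system):
        ens = Ensemble([system.state_conformation("ground") for _ in range(5)])
        out = basin_population(ens, system.regions, BasinPartition())
        frac = dict(zip(out["basin"], out["fraction"]))
        assert frac["locked"] == 1.0
        assert frac["unlocked"] == 0.0

    def test_counting_matches_construction(self, system, rng):
        confs = [system.state_conformation("minor") for _ in range(130)]
        confs += [system.state_conformation("ground") for _ in range(870)]
        out = basin_population(Ensemble(confs), system.regions, BasinPartition())
        frac = dict(zip(out["basin"], out["fraction"]))
        assert frac["unlocked"] == pytest.approx(0.13)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_reports_basin_centres(self, system, two_state):
        ensemble, _ = two_state
        out = basin_population(ensemble, system.regions, BasinPartition())
        locked = out[out["basin"] == "locked"].iloc[0]
        assert locked["theta_mean"] == pytest.approx(58.0, abs=1.0)
        assert "theta_mode" in out.columns


class TestContactOccupancy:
    def test_always_formed_and_never_formed(self, system, two_state):
        ensemble, _ = two_state
        ref = ensemble[0]
        # an intra-residue pair is always ~1 A apart; a cross-domain CA pair
        # is far beyond any hydrogen-bond cutoff
        always = contact_occupancy(
            ensemble, donors=[(1, "N")], acceptors=[(1, "H")],
            distance_cutoff_ang=3.5,
        )
        assert always["occupancy"].iloc[0] == 1.0
        never = contact_occupancy(
            ensemble, donors=[(1, "CA")],
            acceptors=[(system.domain_b_res[-1], "CA")],
            distance_cutoff_ang=3.5,
        )
        assert never["occupancy"].iloc[0] == 0.0

    def test_occupancy_split_by_basin_label(self, system, two_state):
        ensemble, truth = two_state
        labels = np.where(truth.labels == "minor", "unlocked", "locked")
        out = contact_occupancy(
            ensemble, donors=[(1, "N")], acceptors=[(1, "H")],
            distance_cutoff_ang=3.5, labels=labels,
        )
        assert out["occupancy_locked"].iloc[0] == 1.0
        assert out["occupancy_unlocked"].iloc[0] == 1.0

    def test_empty_selection_rejected(self, two_state):
        ensemble, _ = two_state
        with pytest.raises(SelectionError):
            contact_occupancy(ensemble, donors=[], acceptors=[])


class TestPotentialEnergyProfile:
    def test_constant_energy_gives_flat_profile(self, rng):
        thetas = rng.uniform(40, 70, 500)
        prof = potential_energy_profile(thetas, np.full(500, -3.5), 1.0)
        assert np.allclose(prof["e_pot_mean"], -3.5)

    def test_linear_energy_tracks_bin_centres(self, rng):
        thetas = rng.uniform(40, 70, 5000)
        prof = potential_energy_profile(thetas, thetas.copy(), 1.0)
        assert np.all(
            np.abs(prof["e_pot_mean"] - prof["theta_bin"]) <= 0.5 + 1e-9
        )

    def test_empty_bins_are_absent_not_zero(self):
        thetas = np.array([40.2, 40.3, 70.1])
        prof = potential_energy_profile(thetas, np.array([1.0, 2.0, 3.0]), 1.0)
        assert len(prof) == 2  # the gap between 41 and 70 is not reported

    def test_missing_energy_is_an_error(self):
        with pytest.raises(ValueError):
            potential_energy_profile(
                np.array([50.0, 51.0]), np.array([1.0, np.nan]), 1.0
            )


class TestPolygonPartition:
    def test_polygon_region_classifies_points(self):
        # triangle covering small theta and small RMSD
        part = BasinPartition(
            polygon=[(45.0, 0.0), (52.0, 0.0), (45.0, 3.0)]
        )
        thetas = np.array([46.0, 51.0, 46.0, 60.0])
        rmsds = np.array([0.5, 2.5, 2.0, 0.5])
        labels = part.classify(thetas, rmsds)
        assert list(labels) == ["unlocked", "locked", "unlocked", "locked"]

    def test_polygon_requires_rmsd_values(self):
        part = BasinPartition(polygon=[(45.0, 0.0), (52.0, 0.0), (45.0, 3.0)])
        with pytest.raises(ValueError):
            part.classify(np.array([46.0]))
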