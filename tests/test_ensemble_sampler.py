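import math

import numpy as np
import pytest
from scipy.integrate import quad

from rdcens.alignment_tensor import predict_tensor
from rdcens.ensemble_sampler import (
    AnnealingSchedule,
    EnsembleSampler,
    MoveSet,
    RestraintModel,
    count_collected_frames,
    count_integrator_steps,
    total_energy,
)
from rdcens.errors import ScheduleError
from rdcens.io_formats import KB_KJ_MOL_K
from rdcens.rdc_restraints import ReplicaSet
from rdcens.workflow import desk_schedule


class TestScheduleArithmetic:
    def test_full_protocol_collects_24000_frames(self):
        schedule = AnnealingSchedule()  # 50 cycles, 1/ps, last 50 ps of last 30
        assert count_collected_frames(schedule, n_replicas=16) == 24000

    def test_full_protocol_cycle_is_125000_steps(self):
        assert count_integrator_steps(AnnealingSchedule()) == 125000

    def test_small_schedule_arithmetic(self):
        schedule = AnnealingSchedule(
            cycles=1, cycle_ps=10.0, collect_window_ps=5.0, retain_last_cycles=1
        )
        assert count_collected_frames(schedule, n_replicas=1) == 5
        one_ps = AnnealingSchedule(
            cycles=1, cycle_ps=1.0, timestep_fs=2.0,
            collect_window_ps=0.5, retain_last_cycles=1,
        )
        assert count_integrator_steps(one_ps) == 500

    def test_non_divisible_timestep_rejected(self):
        with pytest.raises(ScheduleError):
            count_integrator_steps(AnnealingSchedule(cycle_ps=1.0, timestep_fs=3.0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_high_K=300.0, t_low_K=310.0),
            dict(cycles=5, retain_last_cycles=6),
            dict(cycle_ps=10.0, collect_window_ps=8.0),  # low segment is 5 ps
        ],
    )
    def test_inconsistent_schedules_rejected(self, kwargs):
        with pytest.raises(ScheduleError):
            AnnealingSchedule(**kwargs)


class TestTotalEnergy:
    def _replicas(self, system, labels):
        confs = [system.state_conformation(s) for s in labels]
        tensors = {
            m: [predict_tensor(c, spec) for c in confs]
            for m, spec in system.media.items()
        }
        return ReplicaSet(conformations=confs, tensors=tensors)

    def test_zero_weight_reduces_to_potential_sum(self, system, rdc_table):
        reps = self._replicas(system, ["ground", "minor", "ground"])
        e_tot, e_pot, e_rdc = total_energy(
            reps, system.potential, rdc_table, system.bonds, alpha=0.0,
            d_max_hz=-21700.0,
        )
        assert e_rdc == 0.0
        assert e_tot == pytest.approx(e_pot)
        assert e_pot == pytest.approx(
            sum(system.potential.energy(c.coords) for c in reps.conformations)
        )

    def test_restraint_part_is_linear_in_alpha(self, system, rdc_table):
        reps = self._replicas(system, ["ground", "ground"])
        _, e_pot, e1 = total_energy(
            reps, system.potential, rdc_table, system.bonds, 1.0, -21700.0
        )
        e_tot2, _, e2 = total_energy(
            reps, system.potential, rdc_table, system.bonds, 2.0, -21700.0
        )
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)
        assert e_tot2 == pytest.approx(e_pot + e2, rel=1e-12)


class _Well1D:
    """Tilted 1-D double well acting on the x coordinate of a single atom."""

    def __init__(self, barrier=6.0, tilt=1.5, k_trans=5.0):
        self.barrier = barrier
        self.tilt = tilt
        self.k_trans = k_trans

    def energy(self, coords):
        x, y, z = coords[0]
        return (
            self.barrier * (x * x - 1.0) ** 2
            + self.tilt * x
            + self.k_trans * (y * y + z * z)
        )


class TestMetropolisSampler:
    def test_zero_magnitude_proposal_always_accepted(self):
        sampler = EnsembleSampler(_Well1D(), MoveSet(sigma_atom_ang=0.0))
        state = sampler.init_state([np.array([[1.0, 0.0, 0.0]])], seed=0)
        before = state.coords[0].copy()
        assert sampler.mc_move(state, 0, T=310.0)
        np.testing.assert_array_equal(state.coords[0], before)

    def test_nonpositive_temperature_rejected(self):
        sampler = EnsembleSampler(_Well1D(), MoveSet())
        state = sampler.init_state([np.array([[1.0, 0.0, 0.0]])], seed=0)
        with pytest.raises(ValueError):
            sampler.mc_move(state, 0, T=0.0)

    def test_unrestrained_occupancies_match_boltzmann(self):
        """Basin occupancies on a tilted double well agree with the analytic
        Boltzmann ratio within three standard errors (independent replicas)."""
        T = 310.0
        beta = 1.0 / (KB_KJ_MOL_K * T)
        well = _Well1D()
        sampler = EnsembleSampler(well, MoveSet(sigma_atom_ang=0.35))
        n_rep = 48
        rng = np.random.default_rng(123)
        init = [
            np.array([[x, 0.0, 0.0]])
            for x in np.where(rng.random(n_rep) < 0.5, -1.0, 1.0)
        ]
        state = sampler.init_state(init, seed=42)
        burn, n_sweeps = 1500, 5000
        frac = np.zeros(n_rep)
        for sweep in range(burn + n_sweeps):
            for m in range(n_rep):
                sampler.mc_move(state, m, T)
            if sweep >= burn:
                for m in range(n_rep):
                    frac[m] += state.coords[m][0, 0] < 0.0
        frac /= n_sweeps
        v = lambda x: well.barrier * (x * x - 1) ** 2 + well.tilt * x
        num = quad(lambda x: math.exp(-beta * v(x)), -6, 0)[0]
        den = quad(lambda x: math.exp(-beta * v(x)), -6, 6)[0]
        expected = num / den
        se = frac.std(ddof=1) / math.sqrt(n_rep)
        assert abs(frac.mean() - expected) < 3.0 * se

    def test_same_seed_reproduces_frames_exactly(self, system):
        schedule = AnnealingSchedule(
            cycles=2, cycle_ps=4.0, collect_window_ps=2.0, retain_last_cycles=1,
            moves_per_ps=5, equilibration_ps=2.0,
        )
        moves = MoveSet(
            rotate_indices=system.rotate_indices,
            pivot_indices=system.pivot_indices,
            hop_delta=system.hop_delta,
        )
        sampler = EnsembleSampler(
            system.potential, moves=moves, template=system.conformation
        )
        init = [system.conformation.coords.copy() for _ in range(3)]
        r1 = sampler.run_annealing(init, schedule, seed=9, thermalize_ps=1.0)
        r2 = sampler.run_annealing(
            [c.copy() for c in init], schedule, seed=9, thermalize_ps=1.0
        )
        np.testing.assert_array_equal(
            r1.ensemble.coords_stack(), r2.ensemble.coords_stack()
        )
        assert len(r1.ensemble) == count_collected_frames(schedule, 3)


@pytest.fixture(scope="module")
def short_runs(system, rdc_table):
    """Short restrained runs at increasing alpha on shared data."""
    moves = MoveSet(
        rotate_indices=system.rotate_indices,
        pivot_indices=system.pivot_indices,
        hop_delta=system.hop_delta,
    )
    schedule = AnnealingSchedule(
        cycles=3, cycle_ps=16.0, high_fraction=0.25, collect_window_ps=4.0,
        retain_last_cycles=2, moves_per_ps=15, equilibration_ps=16.0,
    )
    out = {}
    for alpha in (0.0, 2.0, 10.0):
        restraint = RestraintModel(
            bonds=system.bonds, rdc=rdc_table, media=system.media,
            n_orientations=200,
        )
        sampler = EnsembleSampler(
            system.potential, moves=moves, restraint=restraint,
            template=system.conformation,
        )
        init = [system.conformation.coords.copy() for _ in range(8)]
        result = sampler.run_annealing(
            init, schedule, seed=5, alpha_target=alpha, thermalize_ps=4.0
        )
        if alpha == 0.0:
            # caches go stale when the restraint is off; evaluate afresh
            sampler._refresh_all(result.state)
        out[alpha] = (sampler, result, restraint)
    return out

class TestRestrainedSampler:
    def test_energy_caches_match_recomputation(self, short_runs):
        sampler, result, _ = short_runs[10.0]
        e_tot, e_pot, e_rdc = sampler.recompute_energies(result.state)
        assert float(result.state.e_pot.sum()) == pytest.approx(e_pot, rel=1e-9)
        assert result.state.e_rdc == pytest.approx(e_rdc, rel=1e-9, abs=1e-9)

    def test_raising_alpha_reduces_data_mismatch(self, short_runs):
        mism = {
            alpha: rest.mismatch(result.state.d_calc)
            for alpha, (sampler, result, rest) in short_runs.items()
        }
        assert mism[10.0] < mism[0.0]
        assert mism[2.0] < mism[0.0]

    def test_tensor_refresh_interval_is_not_load_bearing(self, system, rdc_table):
        """Mismatch levels with tensor refresh every accepted move vs every 20
        agree within a factor of three on a short run."""
        moves = MoveSet(
            rotate_indices=system.rotate_indices,
            pivot_indices=system.pivot_indices,
            hop_delta=system.hop_delta,
        )
        schedule = AnnealingSchedule(
            cycles=2, cycle_ps=12.0, high_fraction=0.25, collect_window_ps=3.0,
            retain_last_cycles=1, moves_per_ps=15, equilibration_ps=12.0,
        )
        mism = {}
        for interval in (1, 20):
            restraint = RestraintModel(
                bonds=system.bonds, rdc=rdc_table, media=system.media,
                tensor_update_interval=interval, n_orientations=200,
            )
            sampler = EnsembleSampler(
                system.potential, moves=moves, restraint=restraint,
                template=system.conformation,
            )
            init = [system.conformation.coords.copy() for _ in range(8)]
            result = sampler.run_annealing(
                init, schedule, seed=3, alpha_target=5.0, thermalize_ps=3.0
            )
            mism[interval] = restraint.mismatch(result.state.d_calc)
        ratio = mism[20] / mism[1]
        assert 1 / 3 < ratio < 3
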