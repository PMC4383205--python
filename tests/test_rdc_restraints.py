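import numpy as np
import pandas as pd
import pytest

from rdcens.alignment_tensor import AlignmentTensor, predict_tensor
from rdcens.errors import MappingError, UndefinedQError
from rdcens.io_formats import Conformation, RDCTable
from rdcens.rdc_restraints import (
    BondVectorSet,
    ReplicaSet,
    calc_rdc,
    q_factor,
    replica_average_rdc,
    restraint_energy,
    restraint_gradient,
)

D_MAX = -21700.0


def _bond_conf(direction):
    """Two atoms forming a single bond along ``direction``."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    return Conformation(
        chain_ids=["A", "A"],
        res_ids=[1, 1],
        res_names=["ALA", "ALA"],
        atom_names=["N", "H"],
        elements=["N", "H"],
        coords=np.stack([np.zeros(3), 1.02 * direction]),
    )


BONDS = BondVectorSet(
    pd.DataFrame(dict(res_id=[1], pair=["N-H"], atom_from=["N"], atom_to=["H"]))
)
AXIAL = AlignmentTensor(np.diag([-0.005, -0.005, 0.01]), "steric")


class TestCalcRdc:
    def test_bond_along_unique_axis_gives_d_max_times_azz(self):
        d = calc_rdc(_bond_conf([0, 0, 1]), AXIAL, BONDS, D_MAX)
        assert d[0] == pytest.approx(D_MAX * 0.01)

    def test_magic_angle_bond_vanishes_by_tracelessness(self):
        d = calc_rdc(_bond_conf([1, 1, 1]), AXIAL, BONDS, D_MAX)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_tensor_gives_zero_couplings(self, system):
        zero = AlignmentTensor(np.zeros((3, 3)), "steric")
        d = calc_rdc(system.conformation, zero, system.bonds, D_MAX)
        np.testing.assert_array_equal(d, 0.0)


class TestReplicaAverage:
    def _replicas(self, confs, tensors):
        return ReplicaSet(conformations=confs, tensors={"steric": tensors})

    def test_identical_replicas_reduce_to_single_structure(self, system):
        t = predict_tensor(system.conformation, system.media["steric"])
        reps = self._replicas([system.conformation] * 4, [t] * 4)
        avg = replica_average_rdc(reps, system.bonds, D_MAX, "steric")
        single = calc_rdc(system.conformation, t, system.bonds, D_MAX)
        np.testing.assert_allclose(avg, single, rtol=1e-12)

    def test_opposite_couplings_cancel(self, system):
        t = predict_tensor(system.conformation, system.media["steric"])
        minus = AlignmentTensor(-t.A, "steric")
        reps = self._replicas([system.conformation] * 2, [t, minus])
        avg = replica_average_rdc(reps, system.bonds, D_MAX, "steric")
        np.testing.assert_allclose(avg, 0.0, atol=1e-10)

    def test_permutation_invariance(self, system):
        t1 = predict_tensor(system.conformation, system.media["steric"])
        t2 = predict_tensor(
            system.state_conformation("minor"), system.media["steric"]
        )
        confs = [system.conformation, system.state_conformation("minor")]
        fwd = self._replicas(confs, [t1, t2])
        rev = self._replicas(confs[::-1], [t2, t1])
        np.testing.assert_allclose(
            replica_average_rdc(fwd, system.bonds, D_MAX, "steric"),
            replica_average_rdc(rev, system.bonds, D_MAX, "steric"),
            rtol=1e-12,
        )


def _table_for(system, d_by_medium, sigma=0.3):
    rows = []
    for medium, d in d_by_medium.items():
        for r, p, v in zip(system.bonds.df["res_id"], system.bonds.df["pair"], d):
            rows.append(
                dict(res_id=int(r), pair=p, medium=medium, d_exp=float(v), sigma=sigma)
            )
    return RDCTable(pd.DataFrame(rows))


class TestRestraintEnergy:
    def test_zero_at_perfect_agreement(self, system):
        t = predict_tensor(system.conformation, system.media["steric"])
        d = calc_rdc(system.conformation, t, system.bonds, D_MAX)
        table = _table_for(system, {"steric": d})
        assert restraint_energy({"steric": d}, table, system.bonds, alpha=2.0) == 0.0

    def test_zero_weight_kills_any_mismatch(self, system):
        t = predict_tensor(system.conformation, system.media["steric"])
        d = calc_rdc(system.conformation, t, system.bonds, D_MAX)
        table = _table_for(system, {"steric": d + 5.0})
        assert restraint_energy({"steric": d}, table, system.bonds, alpha=0.0) == 0.0

    def test_single_bond_quadratic(self):
        conf = _bond_conf([0, 0, 1])
        d = calc_rdc(conf, AXIAL, BONDS, D_MAX)
        table = RDCTable(
            pd.DataFrame(
                dict(res_id=[1], pair=["N-H"], medium=["steric"],
                     d_exp=[float(d[0]) + 3.0], sigma=[0.3])
            )
        )
        e = restraint_energy({"steric": d}, table, BONDS, alpha=1.7)
        assert e == pytest.approx(1.7 * 9.0)

    def test_quadratic_is_minimised_at_experimental_values(self, system, rng):
        t = predict_tensor(system.conformation, system.media["steric"])
        d_exp = calc_rdc(system.conformation, t, system.bonds, D_MAX)
        table = _table_for(system, {"steric": d_exp})
        e0 = restraint_energy({"steric": d_exp}, table, system.bonds, 1.0)
        for _ in range(5):
            shifted = d_exp + rng.normal(0, 1.0, d_exp.shape)
            assert restraint_energy({"steric": shifted}, table, system.bonds, 1.0) > e0

    def test_unmatched_row_is_a_hard_error(self, system):
        t = predict_tensor(system.conformation, system.media["steric"])
        d = calc_rdc(system.conformation, t, system.bonds, D_MAX)
        table = _table_for(system, {"steric": d})
        bad = table.df.copy()
        bad.loc[0, "res_id"] = 999
        with pytest.raises(MappingError):
            restraint_energy({"steric": d}, RDCTable(bad), system.bonds, 1.0)


class TestRestraintGradient:
    def test_matches_central_finite_differences(self, system, rng):
        media = system.media
        confs = [system.conformation, system.state_conformation("minor")]
        tensors = {
            m: [predict_tensor(c, media[m]) for c in confs] for m in media
        }
        reps = ReplicaSet(conformations=confs, tensors=tensors)
        d_calc = {
            m: replica_average_rdc(reps, system.bonds, D_MAX, m) for m in media
        }
        table = _table_for(
            system, {m: d + rng.normal(0, 1.0, d.shape) for m, d in d_calc.items()}
        )
        alpha = 2.5
        grads = restraint_gradient(reps, table, system.bonds, alpha, D_MAX)

        def energy_at(replica, atom, axis, delta):
            coords = confs[replica].coords.copy()
            coords[atom, axis] += delta
            moved = confs[replica].with_coords(coords)
            shifted = ReplicaSet(
                conformations=[moved if i == replica else c for i, c in enumerate(confs)],
                tensors=tensors,
            )
            d = {m: replica_average_rdc(shifted, system.bonds, D_MAX, m) for m in media}
            return restraint_energy(d, table, system.bonds, alpha)

        h = 1e-6
        # probe atoms that actually carry bond vectors
        i_from, i_to = system.bonds.atom_indices(confs[0])
        probes = [(0, int(i_to[3]), 0), (0, int(i_from[7]), 2), (1, int(i_to[11]), 1)]
        for rep, atom, axis in probes:
            fd = (energy_at(rep, atom, axis, h) - energy_at(rep, atom, axis, -h)) / (
                2 * h
            )
            ana = grads[rep][atom, axis]
            assert ana == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestQFactor:
    def test_perfect_agreement_is_zero(self, system, rdc_table):
        d = {
            m: rdc_table.for_medium(m)["d_exp"].to_numpy()
            for m in rdc_table.media
        }
        # rebuild full-length arrays indexed by bond
        full = {}
        for m in rdc_table.media:
            rows = rdc_table.for_medium(m)
            idx = system.bonds.match_rows(rows)
            arr = np.zeros(len(system.bonds))
            arr[idx] = rows["d_exp"].to_numpy()
            full[m] = arr
        q = q_factor(full, rdc_table, system.bonds)
        assert all(v == pytest.approx(0.0) for v in q.values())

    def test_zero_prediction_gives_unity(self, system, rdc_table):
        zero = {m: np.zeros(len(system.bonds)) for m in rdc_table.media}
        q = q_factor(zero, rdc_table, system.bonds)
        assert q["pooled"] == pytest.approx(1.0)

    def test_scale_invariance(self, system, rdc_table):
        d = {m: np.full(len(system.bonds), 2.0) for m in rdc_table.media}
        q1 = q_factor(d, rdc_table, system.bonds)
        scaled_table = RDCTable(
            rdc_table.df.assign(d_exp=rdc_table.df["d_exp"] * 3.0)
        )
        d3 = {m: arr * 3.0 for m, arr in d.items()}
        q3 = q_factor(d3, scaled_table, system.bonds)
        for m in q1:
            assert q1[m] == pytest.approx(q3[m], rel=1e-12)

    def test_all_zero_experimental_is_undefined(self, system):
        table = _table_for(system, {"steric": np.zeros(len(system.bonds))})
        with pytest.raises(UndefinedQError):
            q_factor({"steric": np.ones(len(system.bonds))}, table, system.bonds)


class TestCalculatedExport:
    def test_round_trips_with_added_column(self, system, rdc_table, tmp_path):
        from rdcens.rdc_restraints import export_calculated

        d_calc = {
            m: np.arange(len(system.bonds), dtype=float) + (1 if m == "steric" else 100)
            for m in rdc_table.media
        }
        path = tmp_path / "calc.tsv"
        out = export_calculated(d_calc, rdc_table, system.bonds, path)
        assert len(out) == len(rdc_table)
        back = pd.read_csv(path, sep="\t")
        assert "d_calc" in back.columns
        # each row's d_calc is the bond-matched calculated value
        for _, row in back.iterrows():
            idx = system.bonds.match_rows(pd.DataFrame([row]))[0]
            assert row["d_calc"] == d_calc[row["medium"]][idx]
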