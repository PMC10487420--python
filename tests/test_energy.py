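"""Energy terms: restraint potentials vs independent oracles, STAP tables,
surrogate terms, additivity and rigid-body invariance."""

import math

import numpy as np
import pytest

from noesa.energy import (
    EnergyBreakdown,
    EnergyEvaluator,
    NOEParams,
    STAPTable,
    Weights,
    build_stap_table,
    default_tables,
    dihedral_energy,
    effective_distance,
    noe_energy,
    reference_table,
    solv_energy,
    stap_energy,
    stereo_energy,
    total_energy,
)
from noesa.geometry import random_rotation
from noesa.restraints import AtomSelection, NOERestraint, RestraintSet
from noesa.structures import AtomRecord, StructureModel, TorsionSet, rebuild_from_torsions


def oracle_noe(r, lower, upper, k, r_switch, f_max):
    """Independent piecewise soft-asymptote implementation."""
    slope = min(f_max, 2.0 * k * r_switch)
    if r < lower:
        return k * (lower - r) ** 2
    if r <= upper:
        return 0.0
    if r <= upper + r_switch:
        return k * (r - upper) ** 2
    return k * r_switch ** 2 + slope * (r - upper - r_switch)


def oracle_dihedral(theta, theta0, delta, k):
    dev = (theta - theta0) % 360.0
    if dev > 180.0:
        dev -= 360.0
    dev = abs(dev)
    return 0.0 if dev <= delta else k * (dev - delta) ** 2


class TestNoePotential:
    def test_flat_bottom_zero(self):
        assert noe_energy(3.0, 2.0, 4.0) == 0.0

    def test_harmonic_branch(self):
        p = NOEParams(k_noe=1.0, r_switch=1.0)
        assert noe_energy(4.5, 2.0, 4.0, p) == pytest.approx(0.25)

    def test_linear_asymptote_constant_slope(self):
        p = NOEParams(k_noe=1.0, r_switch=1.0)
        upper = 4.0
        s1 = noe_energy(upper + 2.0 + 1e-4, 2.0, upper, p) - noe_energy(upper + 2.0, 2.0, upper, p)
        s2 = noe_energy(upper + 3.0 + 1e-4, 2.0, upper, p) - noe_energy(upper + 3.0, 2.0, upper, p)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_oracle_equivalence_1000_random(self, rng):
        for _ in range(1000):
            lower = rng.uniform(0.5, 4.0)
            upper = lower + rng.uniform(0.0, 3.0)
            k = rng.uniform(0.1, 5.0)
            rs = rng.uniform(0.2, 2.0)
            fm = rng.uniform(0.1, 10.0)
            p = NOEParams(k_noe=k, r_switch=rs, f_max=fm)
            r = rng.uniform(0.0, 15.0)
            assert noe_energy(r, lower, upper, p) == pytest.approx(
                oracle_noe(r, lower, upper, k, rs, fm), abs=1e-9
            )

    def test_continuity_and_c1(self):
        p = NOEParams(k_noe=1.3, r_switch=0.8)
        lower, upper = 2.0, 4.0
        h = 1e-6
        for x in (upper, upper + p.r_switch):
            left = noe_energy(x - h, lower, upper, p)
            right = noe_energy(x + h, lower, upper, p)
            assert right - left == pytest.approx(0.0, abs=1e-5)
        # C1 at both branch points by central finite differences
        for x in (upper, upper + p.r_switch):
            d_left = (noe_energy(x, lower, upper, p) - noe_energy(x - h, lower, upper, p)) / h
            d_right = (noe_energy(x + h, lower, upper, p) - noe_energy(x, lower, upper, p)) / h
            assert d_left == pytest.approx(d_right, abs=1e-5)


class TestDihedralPotential:
    @pytest.mark.parametrize(
        "theta,theta0,delta,k,expected",
        [(-55.0, -60.0, 20.0, 1.0, 0.0), (-90.0, -60.0, 20.0, 1.0, 100.0), (175.0, -175.0, 5.0, 2.0, 50.0)],
    )
    def test_examples(self, theta, theta0, delta, k, expected):
        assert dihedral_energy(theta, theta0, delta, k) == pytest.approx(expected)

    def test_oracle_equivalence_1000_random(self, rng):
        for _ in range(1000):
            theta = rng.uniform(-360, 360)
            theta0 = rng.uniform(-180, 180)
            delta = rng.uniform(0, 60)
            k = rng.uniform(0.01, 2.0)
            assert dihedral_energy(theta, theta0, delta, k) == pytest.approx(
                oracle_dihedral(theta, theta0, delta, k), abs=1e-9
            )


def _two_atom_model(d, elements=("C", "C"), res_sep=3):
    """Two atoms far apart in sequence so they count as nonbonded."""
    atoms = []
    for r in range(res_sep + 1):
        for j, nm in enumerate(["N", "CA", "C", "O"]):
            atoms.append(AtomRecord(
                serial=r * 4 + j, name=nm, element=nm[0], residue_index=r,
                residue_name="GLY", chain_id="A",
                position=np.array([r * 100.0 + j, 0.0, 0.0]), residue_seq=r + 1,
            ))
    return StructureModel(atoms)


class TestEffectiveDistance:
    def _model(self):
        atoms = [
            AtomRecord(serial=1, name="HA", element="H", residue_index=0, residue_name="ALA",
                       chain_id="A", position=np.zeros(3), residue_seq=1),
            AtomRecord(serial=2, name="HB1", element="H", residue_index=1, residue_name="ALA",
                       chain_id="A", position=np.array([3.0, 0, 0]), residue_seq=2),
            AtomRecord(serial=3, name="HB2", element="H", residue_index=1, residue_name="ALA",
                       chain_id="A", position=np.array([8.0, 0, 0]), residue_seq=2),
        ]
        return StructureModel(atoms)

    def test_single_pair_is_distance(self):
        m = self._model()
        r = NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "HB1"),), 4.0, 2.0, 1.0)
        assert effective_distance(m, r) == pytest.approx(3.0)

    def test_two_equal_pairs_analytic(self):
        m = self._model()
        m.atoms[2].position = np.array([0.0, 3.0, 0.0])
        r = NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "HB#"),), 4.0, 2.0, 1.0)
        assert effective_distance(m, r) == pytest.approx(3.0 * 2 ** (-1 / 6))

    def test_unequal_pairs_brute_force(self):
        m = self._model()
        r = NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "HB#"),), 4.0, 2.0, 1.0)
        assert effective_distance(m, r) == pytest.approx((3.0 ** -6 + 8.0 ** -6) ** (-1 / 6))


class TestStapTable:
    def test_zero_observations_uniform_zero(self, topo):
        t = build_stap_table([], "phi_psi", topology=topo)
        assert np.allclose(t.grid, 0.0)

    def test_single_loaded_bin_no_smoothing(self, helix, topo):
        t = build_stap_table([helix], "phi_psi", smoothing_sigma=0.0, pseudocount=1.0, topology=topo)
        # all interior residues share one (phi, psi) bin
        loaded = t.grid == t.grid.min()
        assert loaded.sum() == 1
        others = t.grid[~loaded]
        assert np.allclose(others, others[0])
        assert others[0] > 0

    def test_smoothing_preserves_normalization(self, helix, topo):
        t = build_stap_table([helix], "phi_psi", smoothing_sigma=15.0, topology=topo)
        p = np.exp(-(t.grid - (-np.log(np.exp(-t.grid).sum()))))  # reconstruct up to shift
        assert np.isfinite(t.grid).all() and t.grid.min() == 0.0

    def test_interpolation_at_node_and_midpoint(self):
        t = reference_table("phi_psi")
        ax = -180.0 + (np.arange(t.n_bins) + 0.5) * t.bin_width
        i, j = 5, 11
        assert stap_energy((ax[i], ax[j]), t) == pytest.approx(t.grid[i, j], abs=1e-12)
        mid = stap_energy(((ax[i] + ax[i + 1]) / 2, ax[j]), t)
        assert mid == pytest.approx((t.grid[i, j] + t.grid[i + 1, j]) / 2, abs=1e-12)

    def test_grid_nonnegative_min_zero_on_fine_sampling(self):
        t = reference_table("phi_psi")
        xs = np.linspace(-180, 180, 181)
        vals = np.array([[stap_energy((x, y), t) for y in xs[::6]] for x in xs[::6]])
        assert vals.min() >= 0.0
        assert t.grid.min() == 0.0

    def test_serialize_round_trip(self, tmp_path, helix, topo):
        for k in range(3):
            t = build_stap_table([helix], "phi_psi", bin_width=15.0, pseudocount=0.5 + k,
                                 smoothing_sigma=5.0, topology=topo, provenance=f"trial {k}")
            path = tmp_path / f"t{k}.stap"
            t.save(path)
            back = STAPTable.load(path)
            assert back.pair_type == t.pair_type
            assert back.bin_width == t.bin_width
            np.testing.assert_allclose(back.grid, t.grid, rtol=0, atol=1e-12)


class TestSurrogates:
    def test_extended_chain_no_overlap(self, topo):
        t = TorsionSet()
        for i in range(8):
            if i > 0:
                t[(i, "phi")] = 180.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = 180.0
        m = rebuild_from_torsions(t, topo, "A" * 8)
        assert stereo_energy(m, topo) == 0.0

    def test_two_carbons_at_half_rmin(self, topo):
        m = _two_atom_model(0.0)
        # place CA of residue 0 and CA of residue 3 at r_min/2
        rmin = 2 * 1.50
        m.atoms[1].position = np.array([0.0, 0.0, 0.0])
        m.atoms[13].position = np.array([rmin / 2, 0.0, 0.0])
        for i, a in enumerate(m.atoms):
            if i not in (1, 13):
                a.position = np.array([500.0 + i * 50.0, 0.0, 0.0])
        assert stereo_energy(m, topo) == pytest.approx(0.25)

    def test_boundary_exactly_rmin_is_zero(self, topo):
        m = _two_atom_model(0.0)
        m.atoms[1].position = np.array([0.0, 0.0, 0.0])
        m.atoms[13].position = np.array([3.0, 0.0, 0.0])
        for i, a in enumerate(m.atoms):
            if i not in (1, 13):
                a.position = np.array([500.0 + i * 50.0, 0.0, 0.0])
        assert stereo_energy(m, topo) == 0.0

    def test_isolated_atom_no_burial(self, topo):
        m = _two_atom_model(0.0)
        for i, a in enumerate(m.atoms):
            a.position = np.array([i * 100.0, 0.0, 0.0])
        assert solv_energy(m, topo) == 0.0

    def test_scaling_apart_never_increases_burial(self, fixture, topo):
        _, truth, _, _ = fixture
        e0 = solv_energy(truth, topo)
        scaled = truth.copy()
        scaled.set_coords(truth.coords * 2.0)
        # burial counts can only drop, and the (negative-dominated) sum rises toward 0
        assert solv_energy(scaled, topo) >= e0


class TestTotalEnergy:
    def test_weights_isolate_terms(self, fixture, topo):
        _, truth, rset, _ = fixture
        w = Weights(w_stereo=1.0, w_solv=0.0, w_noe=0.0, w_dihe=0.0, w_stap=0.0)
        eb = total_energy(truth, rset, default_tables(), w, topology=topo)
        assert eb.E_tot == eb.E_stereo
        assert eb.E_solv == eb.E_exp_noe == eb.E_exp_dihe == eb.E_stap == 0.0

    def test_satisfied_restraints_zero_exp(self, fixture, topo):
        _, truth, rset, _ = fixture
        eb = total_energy(truth, rset, [], topology=topo)
        assert eb.E_exp_noe == 0.0

    def test_hand_summed_toy(self, topo, helix):
        noes = [
            NOERestraint((AtomSelection(2, "HA"),), (AtomSelection(6, "H"),), 3.0, 1.0, 0.5),
            NOERestraint((AtomSelection(3, "HA"),), (AtomSelection(7, "H"),), 2.0, 1.0, 0.1),
            NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "H"),), 5.0, 2.0, 1.0),
        ]
        rset = RestraintSet(noes=noes)
        params = NOEParams()
        by_hand = sum(
            noe_energy(effective_distance(helix, r), r.lower, r.upper, params) for r in noes
        )
        eb = total_energy(helix, rset, [], Weights(w_stereo=0, w_solv=0, w_dihe=0, w_stap=0), params, topo)
        assert eb.E_exp_noe == pytest.approx(by_hand, abs=1e-12)
        assert eb.E_tot == pytest.approx(by_hand, abs=1e-12)

    def test_additivity_exact(self, fixture, topo):
        _, truth, rset, start = fixture
        for model in (truth, start):
            eb = total_energy(model, rset, default_tables(), topology=topo)
            assert eb.E_tot == eb.E_stereo + eb.E_solv + eb.E_exp_noe + eb.E_exp_dihe + eb.E_stap

    def test_breakdown_type_rejects_wrong_total(self):
        with pytest.raises(ValueError):
            EnergyBreakdown(1.0, 1.0, 1.0, 1.0, 1.0, 999.0)

    def test_rigid_body_invariance(self, fixture, topo, rng):
        _, truth, rset, _ = fixture
        ev = EnergyEvaluator(truth, rset, default_tables(), topology=topo)
        eb0 = ev.evaluate(truth.coords)
        for _ in range(3):
            R = random_rotation(rng)
            t = rng.uniform(-20, 20, size=3)
            eb = ev.evaluate(truth.coords @ R.T + t)
            for name in ("E_stereo", "E_solv", "E_exp_noe", "E_exp_dihe", "E_stap", "E_tot"):
                assert getattr(eb, name) == pytest.approx(getattr(eb0, name), abs=1e-8)
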