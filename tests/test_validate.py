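"""Violation statistics, geometry scores and MCC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from noesa.restraints import AtomSelection, DihedralRestraintRec, NOERestraint
from noesa.structures import AtomRecord, Ensemble, StructureModel, TorsionSet, rebuild_from_torsions
from noesa.validate import (
    BINS,
    ConfusionCounts,
    binding_residues,
    clash_score,
    confusion,
    default_region_map,
    dihedral_violation_stats,
    mcc,
    noe_violation,
    ramachandran_pct,
    secondary_structure_ratio,
    violation_stats,
)


def _chain(positions, names=None, resname="GLY"):
    atoms = []
    for r, pos in enumerate(positions):
        nm = (names or ["CA"] * len(positions))[r]
        atoms.append(AtomRecord(
            serial=r + 1, name=nm, element=nm.lstrip("0123456789")[0], residue_index=r,
            residue_name=resname, chain_id="A", position=np.asarray(pos, dtype=float),
            residue_seq=r + 1,
        ))
    return StructureModel(atoms)


def _restraint_at(dist_model, upper_offset):
    """One-pair restraint whose upper bound sits upper_offset below/above the true distance."""
    m = _chain([(0, 0, 0), (dist_model, 0, 0)], names=["HA", "HA"])
    upper = dist_model - upper_offset
    lower = min(1.0, upper)
    d = (lower + upper) / 2
    r = NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "HA"),), d, d - lower, upper - d)
    return m, r


class TestNoeViolation:
    def test_satisfied_is_zero(self):
        m, r = _restraint_at(4.0, -0.1)
        assert noe_violation(m, r) == 0.0

    def test_excess_reported(self):
        m, r = _restraint_at(4.0, 0.7)
        assert noe_violation(m, r) == pytest.approx(0.7)

    def test_short_side_excluded(self):
        m = _chain([(0, 0, 0), (1.0, 0, 0)], names=["HA", "HA"])
        r = NOERestraint((AtomSelection(1, "HA"),), (AtomSelection(2, "HA"),), 2.5, 0.5, 0.5)
        assert noe_violation(m, r) == 0.0


def _stats_model_and_restraints(violations):
    """Build a model + restraints with prescribed upper-bound violations."""
    n = len(violations)
    positions = []
    names = []
    restraints = []
    atoms = []
    serial = 1
    for k, v in enumerate(violations):
        base = np.array([0.0, k * 100.0, 0.0])
        atoms.append(AtomRecord(serial=serial, name="HA", element="H", residue_index=2 * k,
                                residue_name="GLY", chain_id="A", position=base,
                                residue_seq=2 * k + 1))
        serial += 1
        d = 4.0 + max(0.0, v)
        atoms.append(AtomRecord(serial=serial, name="HA", element="H", residue_index=2 * k + 1,
                                residue_name="GLY", chain_id="A", position=base + [d, 0, 0],
                                residue_seq=2 * k + 2))
        serial += 1
        restraints.append(NOERestraint(
            (AtomSelection(2 * k + 1, "HA"),), (AtomSelection(2 * k + 2, "HA"),),
            3.5, 0.5, 0.5,  # upper bound 4.0
        ))
    return StructureModel(atoms), restraints


class TestViolationStats:
    def test_example_counts_and_max(self):
        model, rs = _stats_model_and_restraints([0.0, 0.3, 0.6, 1.2])
        stats = violation_stats(model, rs).all
        assert stats.max_violation == pytest.approx(1.2)
        assert stats.counts_exceeding == {0.0: 3, 0.5: 2, 1.0: 1, 2.0: 0}

    def test_example_rms(self):
        model, rs = _stats_model_and_restraints([0.0, 0.3, 0.6, 1.2])
        stats = violation_stats(model, rs).all
        assert stats.rms_violation == pytest.approx(math.sqrt((0 + 0.09 + 0.36 + 1.44) / 4))

    def test_all_satisfied(self):
        model, rs = _stats_model_and_restraints([0.0, 0.0])
        stats = violation_stats(model, rs).all
        assert stats.max_violation == 0.0
        assert stats.rms_violation == 0.0
        assert all(c == 0 for c in stats.counts_exceeding.values())

    def test_bruteforce_oracle_on_random_sets(self, rng):
        for _ in range(100):
            viols = rng.uniform(-0.5, 2.5, size=rng.integers(1, 12)).tolist()
            model, rs = _stats_model_and_restraints(viols)
            stats = violation_stats(model, rs).all
            expected = [max(0.0, v) for v in viols]
            assert stats.n_restraints == len(expected)
            assert stats.max_violation == pytest.approx(max(expected), abs=1e-9)
            assert stats.rms_violation == pytest.approx(
                math.sqrt(sum(v * v for v in expected) / len(expected)), abs=1e-9
            )
            for b in BINS:
                assert stats.counts_exceeding[b] == sum(1 for v in expected if v > b)

    def test_counts_monotone_nonincreasing(self, rng):
        for _ in range(50):
            viols = rng.uniform(-1.0, 4.0, size=rng.integers(1, 20)).tolist()
            model, rs = _stats_model_and_restraints(viols)
            counts = [violation_stats(model, rs).all.counts_exceeding[b] for b in BINS]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ensemble_mean_aggregation(self):
        m1, rs = _stats_model_and_restraints([1.0])
        m2, _ = _stats_model_and_restraints([0.0])
        ens = Ensemble(models=[m1, m2], entry_id="e")
        stats = violation_stats(ens, rs).all
        assert stats.max_violation == pytest.approx(0.5)

    def test_category_breakdown_sums_to_all(self, fixture):
        _, _, rset, start = fixture
        vs = violation_stats(start, rset.noes)
        n_by_cat = sum(vs[c].n_restraints for c in ("intraresidual", "sequential", "medium", "long"))
        assert n_by_cat == vs.all.n_restraints == len(rset.noes)


class TestDihedralViolationStats:
    def _model(self):
        t = TorsionSet()
        for i in range(4):
            if i > 0:
                t[(i, "phi")] = -60.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = -45.0
        return rebuild_from_torsions(t, None, "AAAA")

    def _phi_restraint(self, theta0, delta):
        sels = (AtomSelection(1, "C"), AtomSelection(2, "N"),
                AtomSelection(2, "CA"), AtomSelection(2, "C"))
        return DihedralRestraintRec(sels, theta0=theta0, delta=delta, k=1.0)

    def test_inside_flat_bottom(self):
        stats = dihedral_violation_stats(self._model(), [self._phi_restraint(-65.0, 10.0)])
        assert stats.max_violation == 0.0

    def test_single_violation(self):
        stats = dihedral_violation_stats(self._model(), [self._phi_restraint(-80.0, 8.0)])
        assert stats.max_violation == pytest.approx(12.0, abs=1e-6)
        assert stats.rms_violation == pytest.approx(12.0, abs=1e-6)

    def test_wrap_case(self):
        # true phi = -60; target 178 with delta 2: wrapped deviation 122 -> violation 120
        stats = dihedral_violation_stats(self._model(), [self._phi_restraint(178.0, 2.0)])
        assert stats.max_violation == pytest.approx(120.0, abs=1e-6)


class TestClashScore:
    def test_no_overlap_zero(self, helix):
        t = TorsionSet()
        for i in range(6):
            if i > 0:
                t[(i, "phi")] = 180.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = 180.0
        m = rebuild_from_torsions(t, None, "A" * 6)
        assert clash_score(m) == 0.0

    def test_one_clash_rate(self):
        # 2 clashing atoms among n atoms -> 1000/n
        positions = [(0, 0, 0), (100, 0, 0), (200, 0, 0), (300, 0, 0), (300.5, 0, 0)]
        m = _chain(positions, names=["CA"] * 5)
        score = clash_score(m)
        assert score == pytest.approx(1000.0 * 1 / 5)

    def test_bonded_pair_not_counted(self, fixture):
        _, truth, _, _ = fixture
        # bonded atoms sit at ~1.0-1.5 A, far below any clash threshold,
        # yet a clash-free conformation keeps a low score
        assert clash_score(truth) < 60.0

    def test_invariant_under_rigid_transform(self, fixture, rng):
        from noesa.geometry import random_rotation

        _, truth, _, _ = fixture
        s0 = clash_score(truth)
        moved = truth.copy()
        moved.set_coords(truth.coords @ random_rotation(rng).T + rng.uniform(-9, 9, 3))
        assert clash_score(moved) == pytest.approx(s0)


class TestRamachandran:
    def test_helix_fully_allowed(self, helix):
        assert ramachandran_pct(helix) == pytest.approx(100.0)

    def test_all_allowed_map(self, fixture):
        _, _, _, start = fixture
        rmap = default_region_map(threshold=np.inf)
        assert ramachandran_pct(start, rmap) == pytest.approx(100.0)

    def test_fractional_count(self, topo):
        t = TorsionSet()
        n = 12
        for i in range(n):
            if i > 0:
                t[(i, "phi")] = -57.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = -47.0
        t[(5, "phi")] = 20.0  # far outside every basin
        t[(5, "psi")] = -120.0
        m = rebuild_from_torsions(t, topo, "A" * n)
        # 10 assignable residues (1..10), one disallowed
        assert ramachandran_pct(m) == pytest.approx(90.0)

    def test_too_few_residues_error(self, topo):
        t = TorsionSet()
        m = rebuild_from_torsions(t, topo, "AA")
        with pytest.raises(ValueError):
            ramachandran_pct(m)


class TestSecondaryStructure:
    def test_helix_interior(self, helix):
        h, e, c = secondary_structure_ratio(helix)
        assert h == pytest.approx(100.0)

    def test_strand(self, topo):
        t = TorsionSet()
        for i in range(8):
            if i > 0:
                t[(i, "phi")] = -120.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = 130.0
        m = rebuild_from_torsions(t, topo, "A" * 8)
        h, e, c = secondary_structure_ratio(m)
        assert e == pytest.approx(100.0)

    def test_alternating_breaks_runs(self, topo):
        t = TorsionSet()
        for i in range(10):
            if i > 0:
                t[(i, "phi")] = -57.0 if i % 2 else -120.0
                t[(i, "omega")] = 180.0
            t[(i, "psi")] = -47.0 if i % 2 else 130.0
        m = rebuild_from_torsions(t, topo, "A" * 10)
        h, e, c = secondary_structure_ratio(m)
        assert c == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, fixture):
        _, truth, _, start = fixture
        for m in (truth, start):
            h, e, c = secondary_structure_ratio(m)
            assert h + e + c == pytest.approx(100.0, abs=0.01)


class TestBindingResidues:
    def test_far_ligand_empty(self, fixture):
        _, truth, _, _ = fixture
        lig = truth.coords.mean(axis=0) + np.array([500.0, 0.0, 0.0])
        assert binding_residues(truth, [lig]) == set()

    def test_contact_below_cutoff(self, fixture):
        _, truth, _, _ = fixture
        cb = truth.atoms[truth.atom_index(5, "CB")].position
        assert 5 in binding_residues(truth, [cb + np.array([4.0, 0, 0])])

    def test_exactly_at_cutoff_excluded(self):
        m = _chain([(0.0, 0, 0)], names=["CA"])
        lig = np.array([[4.5, 0.0, 0.0]])
        assert binding_residues(m, lig, cutoff=4.5) == set()

    def test_empty_ligand_error(self, fixture):
        _, truth, _, _ = fixture
        with pytest.raises(ValueError):
            binding_residues(truth, [])


def mcc_direct(tp, tn, fp, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


class TestMcc:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,expected",
        [
            (5, 5, 0, 0, 1.0),
            (0, 3, 0, 3, 0.0),  # empty predicted-positive margin: 0 by convention
            (0, 0, 3, 3, -1.0),  # all cells wrong: the formula itself gives -1
            (3, 5, 1, 1, 14 / math.sqrt(4 * 4 * 6 * 6)),
        ],
    )
    def test_examples(self, tp, tn, fp, fn, expected):
        assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(expected)

    def test_in_range_and_matches_direct_formula(self, rng):
        for _ in range(2000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 21, size=4))
            v = mcc(ConfusionCounts(tp, tn, fp, fn))
            assert -1.0 <= v <= 1.0
            assert v == pytest.approx(mcc_direct(tp, tn, fp, fn), abs=1e-12)

    def test_symmetric_under_class_swap(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 15, size=4))
            assert mcc(ConfusionCounts(tp, tn, fp, fn)) == pytest.approx(
                mcc(ConfusionCounts(tn, tp, fn, fp)), abs=1e-12
            )

    def test_confusion_partition(self):
        uni = set(range(10))
        counts = confusion({1, 2, 3}, {2, 3, 4}, uni)
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (2, 1, 1, 6)
        assert counts.total == 10

    def test_complementary_sets(self):
        uni = set(range(8))
        pred = {0, 1, 2, 3}
        ref = uni - pred
        assert mcc(confusion(pred, ref, uni)) == pytest.approx(-1.0)
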