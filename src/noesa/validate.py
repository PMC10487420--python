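"""Evaluation statistics for refined structures.

Covers NOE and dihedral restraint-violation analysis (maximum, RMS and
exceedance counts over 0.0/0.5/1.0/2.0 A cutoffs, broken out by sequence
separation category), an all-atom steric clash score per 1000 atoms, a
Ramachandran allowed-region percentage, a torsion-window secondary-structure
ratio, and the Matthews correlation coefficient over predicted vs reference
ligand-binding residue sets.

An NOE violation is the excess of the (r^-6-averaged) model distance over the
restraint upper bound; short-side deviations are not counted.  For an
ensemble, the per-restraint violation is averaged over models before the
statistics are taken (per-model statistics are available via ``per_model``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .energy import CONTACT_RADII, STAPTable, effective_distance, reference_table
from .geometry import wrap_angle, dihedral
from .restraints import CATEGORIES, DihedralRestraintRec, NOERestraint, classify
from .structures import Ensemble, StructureModel, bond_graph, graph_distance_mask, torsions_of
from .topology import Topology, default_topology

__all__ = [
    "BINS",
    "CategoryStats",
    "ViolationStats",
    "DihedralViolationStats",
    "ConfusionCounts",
    "GeometryScores",
    "RamachandranMap",
    "noe_violation",
    "violation_stats",
    "dihedral_violation_stats",
    "clash_score",
    "default_region_map",
    "ramachandran_pct",
    "secondary_structure_ratio",
    "binding_residues",
    "confusion",
    "mcc",
    "geometry_scores",
]

BINS = (0.0, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class CategoryStats:
    n_restraints: int
    max_violation: float
    rms_violation: float
    counts_exceeding: dict[float, int]

    def __post_init__(self):
        counts = [self.counts_exceeding[b] for b in BINS]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("exceedance counts must be nonincreasing in the cutoff")


@dataclass(frozen=True)
class ViolationStats:
    per_category: dict[str, CategoryStats]

    def __getitem__(self, cat: str) -> CategoryStats:
        return self.per_category[cat]

    @property
    def all(self) -> CategoryStats:
        return self.per_category["all"]


@dataclass(frozen=True)
class DihedralViolationStats:
    n_restraints: int
    max_violation: float
    rms_violation: float


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class GeometryScores:
    clash_score: float
    rama_allowed_pct: float
    ss_ratio: tuple[float, float, float]  # helix %, sheet %, coil %


# ---------------------------------------------------------------------------
# NOE / dihedral violations
# ---------------------------------------------------------------------------


def noe_violation(model: StructureModel, restraint: NOERestraint) -> float:
    """Upper-bound excess of the effective distance (0 when satisfied)."""
    return max(0.0, effective_distance(model, restraint) - restraint.upper)


def _stats_from_violations(viol: np.ndarray) -> CategoryStats:
    n = len(viol)
    if n == 0:
        return CategoryStats(0, 0.0, 0.0, {b: 0 for b in BINS})
    return CategoryStats(
        n_restraints=n,
        max_violation=float(np.max(viol)),
        rms_violation=float(np.sqrt(np.mean(viol ** 2))),
        counts_exceeding={b: int(np.sum(viol > b)) for b in BINS},
    )


def violation_stats(
    structure: StructureModel | Ensemble,
    restraints: list[NOERestraint],
    per_model: bool = False,
    rms_violated_only: bool = False,
) -> ViolationStats | list[ViolationStats]:
    """NOE violation statistics per category and pooled ("all").

    For an ensemble the per-restraint violation is the mean over models;
    ``per_model=True`` instead returns one ViolationStats per member.  The RMS
    is taken over all restraints (satisfied ones contribute 0) unless
    ``rms_violated_only``.
    """
    models = structure.models if isinstance(structure, Ensemble) else [structure]
    if per_model and isinstance(structure, Ensemble):
        return [violation_stats(m, restraints, rms_violated_only=rms_violated_only) for m in models]
    viol = np.zeros(len(restraints))
    for j, r in enumerate(restraints):
        viol[j] = float(np.mean([noe_violation(m, r) for m in models]))
    cats = np.array([classify(r) for r in restraints])
    out: dict[str, CategoryStats] = {}
    for cat in ("all",) + CATEGORIES:
        sel = viol if cat == "all" else viol[cats == cat]
        if rms_violated_only:
            sel_rms = sel[sel > 0]
            stats = _stats_from_violations(sel)
            rms = float(np.sqrt(np.mean(sel_rms ** 2))) if len(sel_rms) else 0.0
            stats = CategoryStats(stats.n_restraints, stats.max_violation, rms, stats.counts_exceeding)
        else:
            stats = _stats_from_violations(sel)
        out[cat] = stats
    return ViolationStats(per_category=out)


def dihedral_violation_stats(
    model: StructureModel, dihedrals: list[DihedralRestraintRec]
) -> DihedralViolationStats:
    """Max/RMS of flat-bottom dihedral violations, degrees."""
    from .energy import resolve_selection  # local import to avoid cycle at module load

    viols = []
    for d in dihedrals:
        idx = []
        for s in d.atoms:
            hits = resolve_selection(model, s)
            idx.append(hits[0])
        theta = dihedral(*(model.atoms[i].position for i in idx))
        dev = abs(float(wrap_angle(theta - d.theta0)))
        viols.append(max(0.0, dev - d.delta))
    v = np.array(viols) if viols else np.zeros(0)
    if len(v) == 0:
        return DihedralViolationStats(0, 0.0, 0.0)
    return DihedralViolationStats(len(v), float(np.max(v)), float(np.sqrt(np.mean(v ** 2))))


# ---------------------------------------------------------------------------
# Geometry scores
# ---------------------------------------------------------------------------


def clash_score(
    model: StructureModel,
    overlap_threshold: float = 0.4,
    topology: Topology | None = None,
) -> float:
    """Sterically overlapping nonbonded pairs per 1000 atoms.

    A pair (graph distance > 3 bonds) clashes when its distance is below the
    summed contact radii minus ``overlap_threshold``.
    """
    topology = topology or default_topology()
    n = len(model.atoms)
    if n == 0:
        return 0.0
    adj = bond_graph(model, topology)
    excl = graph_distance_mask(adj, 3)
    radii = np.array([CONTACT_RADII.get(a.element, 1.6) for a in model.atoms])
    rmin = radii[:, None] + radii[None, :] - overlap_threshold
    coords = model.coords
    d = cdist(coords, coords)
    clash = (d < rmin) & ~excl
    count = int(np.triu(clash, k=1).sum())
    return 1000.0 * count / n


@dataclass(frozen=True)
class RamachandranMap:
    """Boolean allowed-region grid over (phi, psi)."""

    allowed: np.ndarray
    bin_width: float
    threshold: float

    def contains(self, phi: float, psi: float) -> bool:
        n = self.allowed.shape[0]
        i = int(np.floor((phi + 180.0) / self.bin_width)) % n
        j = int(np.floor((psi + 180.0) / self.bin_width)) % n
        return bool(self.allowed[i, j])


def default_region_map(threshold: float = 4.0, table: STAPTable | None = None) -> RamachandranMap:
    """Allowed regions by thresholding a phi-psi torsion-pair potential."""
    table = table or reference_table("phi_psi")
    return RamachandranMap(allowed=table.grid <= threshold, bin_width=table.bin_width, threshold=threshold)


def ramachandran_pct(
    model: StructureModel,
    region_map: RamachandranMap | None = None,
    topology: Topology | None = None,
) -> float:
    """Percentage of non-terminal residues with (phi, psi) in an allowed bin."""
    region_map = region_map or default_region_map()
    topology = topology or default_topology()
    tset = torsions_of(model, topology)
    pairs = []
    for r in model.residues:
        phi = tset.get((r.index, "phi"))
        psi = tset.get((r.index, "psi"))
        # terminal residues lack a true phi or psi partner
        if phi is None or r.index == model.n_residues - 1:
            continue
        if psi is None:
            continue
        pairs.append((phi, psi))
    if len(pairs) < 1 or model.n_residues < 3:
        raise ValueError("Ramachandran percentage needs at least 3 residues")
    ok = sum(1 for phi, psi in pairs if region_map.contains(phi, psi))
    return 100.0 * ok / len(pairs)


_HELIX_WINDOW = ((-100.0, -30.0), (-80.0, -5.0))
_SHEET_WINDOWS = (
    ((-180.0, -90.0), (90.0, 180.0)),
    ((-180.0, -90.0), (-180.0, -170.0)),
)


def _in_window(phi, psi, window):
    (p0, p1), (s0, s1) = window
    return p0 <= phi <= p1 and s0 <= psi <= s1


def secondary_structure_ratio(
    model: StructureModel, topology: Topology | None = None
) -> tuple[float, float, float]:
    """(helix %, sheet %, coil %) from a torsion-window heuristic.

    A residue is helix if its (phi, psi) lies in the alpha window for a run of
    >= 3 consecutive residues, sheet for a beta-window run of >= 2; everything
    else is coil.  Percentages are over residues with both torsions defined.
    This is deliberately not DSSP: no hydrogen-bond analysis is done, and
    outputs should be labeled "SS (torsion heuristic)".
    """
    topology = topology or default_topology()
    tset = torsions_of(model, topology)
    marks = []  # per assignable residue: 'h', 's' or '-'
    for r in model.residues:
        phi = tset.get((r.index, "phi"))
        psi = tset.get((r.index, "psi"))
        if phi is None or psi is None or r.index == model.n_residues - 1:
            continue
        if _in_window(phi, psi, _HELIX_WINDOW):
            marks.append("h")
        elif any(_in_window(phi, psi, w) for w in _SHEET_WINDOWS):
            marks.append("s")
        else:
            marks.append("-")
    if not marks:
        return (0.0, 0.0, 100.0)
    assigned = ["c"] * len(marks)
    i = 0
    while i < len(marks):
        j = i
        while j < len(marks) and marks[j] == marks[i]:
            j += 1
        run = j - i
        if marks[i] == "h" and run >= 3:
            assigned[i:j] = ["H"] * run
        elif marks[i] == "s" and run >= 2:
            assigned[i:j] = ["E"] * run
        i = j
    n = len(assigned)
    h = 100.0 * assigned.count("H") / n
    e = 100.0 * assigned.count("E") / n
    return (h, e, 100.0 - h - e)


# ---------------------------------------------------------------------------
# Binding residues and MCC
# ---------------------------------------------------------------------------


def binding_residues(
    model: StructureModel, ligand_atoms, cutoff: float = 4.5
) -> set[int]:
    """Global residue indices with >= 1 heavy atom strictly within ``cutoff``
    of >= 1 ligand (heavy) atom position."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
    if lig.size == 0:
        raise ValueError("empty ligand")
    out: set[int] = set()
    coords = model.coords
    for r in model.residues:
        if r.is_hetero:
            continue
        idx = [i for i in r.atom_indices if model.atoms[i].element != "H"]
        if not idx:
            continue
        d = cdist(coords[idx], lig)
        if np.any(d < cutoff):
            out.add(r.index)
    return out


def confusion(predicted: set, reference: set, universe: set) -> ConfusionCounts:
    """Confusion counts of a predicted binding-residue set vs the reference."""
    if not predicted <= universe or not reference <= universe:
        raise ValueError("sets must be subsets of the universe")
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any margin is 0."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def geometry_scores(
    model: StructureModel,
    region_map: RamachandranMap | None = None,
    topology: Topology | None = None,
) -> GeometryScores:
    """Bundle clash score, Ramachandran % and SS ratio for one model."""
    return GeometryScores(
        clash_score=clash_score(model, topology=topology),
        rama_allowed_pct=ramachandran_pct(model, region_map, topology),
        ss_ratio=secondary_structure_ratio(model, topology),
    )
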