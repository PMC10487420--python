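"""Composite refinement energy: E_tot = E_stereo + E_solv + E_exp + E_STAP.

All terms are in reduced (dimensionless) units; the annealer's temperature
schedule is interpreted relative to this scale, so no physical energy unit is
needed.  The experimental term E_exp is the sum of an NOE part (soft-asymptote
distance restraint potential: flat inside the bounds, harmonic just outside
the upper bound, linear with bounded slope far outside) and a flat-bottom
harmonic dihedral part.  E_STAP is a knowledge-based torsion-pair potential
(-ln of a smoothed 2-D torsion histogram) over the phi-psi, phi-chi1, psi-chi1
and chi1-chi2 pairs.  E_stereo is a soft-core nonbonded repulsion (bond
lengths and angles are held ideal by the torsion-space representation, so
overlap is the only stereochemical degree of freedom left to penalize).
E_solv is a contact-burial surrogate for implicit solvation: it rewards burial
of hydrophobic atoms and penalizes burial of polar ones.  It is deliberately
not a generalized-Born model.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .errors import SelectionError
from .geometry import dihedral_many, wrap_angle
from .restraints import AtomSelection, DihedralRestraintRec, NOERestraint, RestraintSet
from .structures import StructureModel, bond_graph, graph_distance_mask, torsions_of
from .topology import Topology, default_topology

__all__ = [
    "NOEParams",
    "Weights",
    "EnergyBreakdown",
    "STAPTable",
    "PAIR_TYPES",
    "CONTACT_RADII",
    "SOLVATION_PREFERENCE",
    "resolve_selection",
    "effective_distance",
    "noe_energy",
    "dihedral_energy",
    "build_stap_table",
    "stap_energy",
    "stereo_energy",
    "solv_energy",
    "total_energy",
    "EnergyEvaluator",
]

PAIR_TYPES = ("phi_psi", "phi_chi1", "psi_chi1", "chi1_chi2")

# Soft-core contact radii per element (Angstrom); r_min of a pair is the sum.
# Chosen below van der Waals so that intrinsic short 1-5 backbone contacts of
# regular conformations (e.g. O(i)...H(i) at 2.3 A) are not penalized.
CONTACT_RADII = {"C": 1.50, "N": 1.40, "O": 1.25, "S": 1.75, "H": 0.90}

# Burial preference per element for the solvation surrogate (reduced units per
# neighbor): hydrophobic atoms gain on burial, polar atoms pay.
SOLVATION_PREFERENCE = {"C": -0.02, "S": -0.02, "N": 0.01, "O": 0.01}
BURIAL_RADIUS = 6.5  # Angstrom


@dataclass(frozen=True)
class NOEParams:
    k_noe: float = 1.0  # energy / A^2
    r_switch: float = 1.0  # width of the harmonic region beyond the upper bound, A
    f_max: float | None = None  # max asymptotic slope, energy / A; default 2*k*r_switch

    def __post_init__(self):
        if self.k_noe <= 0 or self.r_switch <= 0:
            raise ValueError("k_noe and r_switch must be positive")
        if self.f_max is not None and self.f_max <= 0:
            raise ValueError("f_max must be positive")

    @property
    def slope(self) -> float:
        cap = 2.0 * self.k_noe * self.r_switch
        return cap if self.f_max is None else min(self.f_max, cap)


@dataclass(frozen=True)
class Weights:
    w_stereo: float = 1.0
    w_solv: float = 1.0
    w_noe: float = 1.0
    w_dihe: float = 1.0
    w_stap: float = 1.0

    def __post_init__(self):
        if any(w < 0 for w in (self.w_stereo, self.w_solv, self.w_noe, self.w_dihe, self.w_stap)):
            raise ValueError("weights must be nonnegative")


@dataclass(frozen=True)
class EnergyBreakdown:
    E_stereo: float
    E_solv: float
    E_exp_noe: float
    E_exp_dihe: float
    E_stap: float
    E_tot: float

    def __post_init__(self):
        terms = (self.E_stereo, self.E_solv, self.E_exp_noe, self.E_exp_dihe, self.E_stap)
        if not all(math.isfinite(t) and t >= -1e6 for t in terms):
            raise ValueError("energy term out of range")
        if self.E_tot != sum(terms):
            raise ValueError("E_tot must equal the exact sum of its terms")

    @classmethod
    def from_terms(cls, E_stereo, E_solv, E_exp_noe, E_exp_dihe, E_stap) -> "EnergyBreakdown":
        terms = (float(E_stereo), float(E_solv), float(E_exp_noe), float(E_exp_dihe), float(E_stap))
        return cls(*terms, E_tot=sum(terms))


# ---------------------------------------------------------------------------
# Restraint potentials
# ---------------------------------------------------------------------------


def noe_energy(r_eff: float, lower: float, upper: float, params: NOEParams | None = None) -> float:
    """Soft-asymptote NOE potential (scalar or array ``r_eff``).

    Zero inside [lower, upper]; harmonic k*(r-upper)^2 up to upper+r_switch;
    beyond that a straight line with slope min(f_max, 2*k*r_switch), continuous
    and C1 at the switch when the slope is uncapped.  Short-side violations are
    harmonic only.
    """
    params = params or NOEParams()
    r = np.asarray(r_eff, dtype=float)
    k = params.k_noe
    rs = params.r_switch
    s = params.slope
    e_switch = k * rs * rs
    out = np.where(
        r < lower,
        k * (lower - r) ** 2,
        np.where(
            r <= upper,
            0.0,
            np.where(
                r <= upper + rs,
                k * (r - upper) ** 2,
                e_switch + s * (r - upper - rs),
            ),
        ),
    )
    return float(out) if np.isscalar(r_eff) else out


def dihedral_energy(theta: float, theta0: float, delta: float, k: float) -> float:
    """Flat-bottom harmonic dihedral potential; angles in degrees."""
    dev = np.abs(wrap_angle(np.asarray(theta, dtype=float) - theta0))
    excess = np.maximum(0.0, dev - delta)
    out = k * excess * excess
    return float(out) if np.isscalar(theta) else out


# ---------------------------------------------------------------------------
# Selection resolution and effective distance
# ---------------------------------------------------------------------------


def resolve_selection(model: StructureModel, sel: AtomSelection) -> list[int]:
    """Expand one selection to atom indices (wildcards against the model)."""
    target = None
    for r in model.residues:
        if r.seq == sel.residue_id:
            target = r
            break
    if target is None:
        raise SelectionError(f"no residue with id {sel.residue_id}")
    hits = [i for i in target.atom_indices if sel.matches(model.atoms[i].name)]
    if not hits:
        raise SelectionError(
            f"no atom matching {sel.atom_pattern!r} in residue {target.name} {sel.residue_id}"
        )
    return hits


def _restraint_pairs(model: StructureModel, restraint: NOERestraint) -> tuple[np.ndarray, np.ndarray]:
    try:
        ia = sorted({i for s in restraint.group_a for i in resolve_selection(model, s)})
        ib = sorted({i for s in restraint.group_b for i in resolve_selection(model, s)})
    except SelectionError as e:
        raise SelectionError(f"{e} (restraint at line {restraint.source_line})") from None
    pairs = [(a, b) for a in ia for b in ib if a != b]
    if not pairs:
        raise SelectionError(f"restraint at line {restraint.source_line} resolves to no pairs")
    arr = np.array(pairs, dtype=int)
    return arr[:, 0], arr[:, 1]


def effective_distance(model: StructureModel, restraint: NOERestraint) -> float:
    """r^-6-summed effective distance over all resolved atom pairs."""
    ia, ib = _restraint_pairs(model, restraint)
    coords = model.coords
    d = np.linalg.norm(coords[ia] - coords[ib], axis=1)
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# Statistical torsion-pair potential
# ---------------------------------------------------------------------------


@dataclass
class STAPTable:
    pair_type: str
    bin_width: float
    grid: np.ndarray  # (n, n) of -ln P, min shifted to 0
    residue_class: str = "ALL"
    pseudocount: float = 1.0
    smoothing_sigma: float = 10.0
    provenance: str = ""

    def __post_init__(self):
        n = int(round(360.0 / self.bin_width))
        if abs(n * self.bin_width - 360.0) > 1e-9:
            raise ValueError("bin_width must divide 360")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (n, n):
            raise ValueError(f"grid must be {n}x{n}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]

    def save(self, path) -> None:
        buf = io.StringIO()
        buf.write("# STAP table v1\n")
        buf.write(f"pair_type {self.pair_type}\n")
        buf.write(f"residue_class {self.residue_class}\n")
        buf.write(f"bin_width {self.bin_width:.6g}\n")
        buf.write(f"pseudocount {self.pseudocount:.6g}\n")
        buf.write(f"smoothing_sigma {self.smoothing_sigma:.6g}\n")
        buf.write(f"provenance {self.provenance or '-'}\n")
        np.savetxt(buf, self.grid, fmt="%.17e")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "STAPTable":
        meta: dict[str, str] = {}
        rows: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split(None, 1)
                if parts[0] in ("pair_type", "residue_class", "bin_width", "pseudocount", "smoothing_sigma", "provenance"):
                    meta[parts[0]] = parts[1].strip()
                else:
                    rows.append(line)
        grid = np.loadtxt(io.StringIO("".join(rows)))
        return cls(
            pair_type=meta["pair_type"],
            bin_width=float(meta["bin_width"]),
            grid=grid,
            residue_class=meta.get("residue_class", "ALL"),
            pseudocount=float(meta.get("pseudocount", 1.0)),
            smoothing_sigma=float(meta.get("smoothing_sigma", 10.0)),
            provenance=meta.get("provenance", ""),
        )


def _pair_angles(models, pair_type: str, residue_class: str, topology: Topology):
    t1, t2 = pair_type.split("_")
    out = []
    for m in models:
        tset = torsions_of(m, topology)
        for r in m.residues:
            if residue_class != "ALL" and r.name != residue_class:
                continue
            a = tset.get((r.index, t1))
            b = tset.get((r.index, t2))
            if a is not None and b is not None:
                out.append((a, b))
    return np.array(out, dtype=float).reshape(-1, 2)


def build_stap_table(
    models: list[StructureModel],
    pair_type: str,
    bin_width: float = 10.0,
    pseudocount: float = 1.0,
    smoothing_sigma: float = 10.0,
    residue_class: str = "ALL",
    topology: Topology | None = None,
    provenance: str = "",
) -> STAPTable:
    """Histogram observed torsion pairs into a -ln P potential.

    The 2-D periodic histogram (plus ``pseudocount`` per bin) is smoothed with
    a wrapped Gaussian of ``smoothing_sigma`` degrees, normalized, and
    converted to -ln P shifted so the minimum is 0.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair type {pair_type!r}")
    topology = topology or default_topology()
    n = int(round(360.0 / bin_width))
    angles = _pair_angles(models, pair_type, residue_class, topology)
    hist = np.zeros((n, n), dtype=float)
    if angles.size:
        idx = np.floor((angles + 180.0) / bin_width).astype(int) % n
        np.add.at(hist, (idx[:, 0], idx[:, 1]), 1.0)
    hist += pseudocount
    if smoothing_sigma > 0:
        hist = gaussian_filter(hist, sigma=smoothing_sigma / bin_width, mode="wrap")
    p = hist / hist.sum()
    grid = -np.log(p)
    grid -= grid.min()
    return STAPTable(
        pair_type=pair_type,
        bin_width=bin_width,
        grid=grid,
        residue_class=residue_class,
        pseudocount=pseudocount,
        smoothing_sigma=smoothing_sigma,
        provenance=provenance,
    )


def _wrapped_gaussian_grid(centers_weights_sigmas, bin_width: float) -> np.ndarray:
    """Mixture of periodically wrapped 2-D Gaussians evaluated at bin centers."""
    n = int(round(360.0 / bin_width))
    ax = -180.0 + (np.arange(n) + 0.5) * bin_width
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    dens = np.zeros((n, n))
    for (cx, cy), w, (sx, sy) in centers_weights_sigmas:
        gx = np.zeros_like(X)
        gy = np.zeros_like(Y)
        for k in (-360.0, 0.0, 360.0):
            gx += np.exp(-0.5 * ((X - cx + k) / sx) ** 2)
            gy += np.exp(-0.5 * ((Y - cy + k) / sy) ** 2)
        dens += w * gx * gy
    return dens


_CHI_PEAKS = ((-60.0, 0.5), (180.0, 0.3), (60.0, 0.2))
_PHI_PEAKS = ((-63.0, 15.0, 0.45), (-120.0, 20.0, 0.45), (55.0, 12.0, 0.10))
_PSI_PEAKS = ((-43.0, 15.0, 0.45), (130.0, 20.0, 0.45), (45.0, 12.0, 0.10))


def _peaks_2d(px, py):
    return [((cx, cy), wx * wy, (sx, sy)) for cx, sx, wx in px for cy, sy, wy in py]


def reference_table(pair_type: str, bin_width: float = 10.0) -> STAPTable:
    """Deterministic analytic torsion-pair prior used as the default potential.

    Built from wrapped-Gaussian mixtures at the canonical conformational
    basins (alpha, beta, polyproline-II and left-handed alpha for the
    backbone; the -60/180/+60 staggered rotamers for chi), with a uniform
    floor so energies stay bounded.  This synthetic prior stands in for a
    database-derived statistical torsion-angle potential; tables built from a
    real structure set via :func:`build_stap_table` can be used instead.
    """
    if pair_type == "phi_psi":
        comps = [
            ((-63.0, -43.0), 0.35, (15.0, 15.0)),
            ((-120.0, 130.0), 0.35, (20.0, 20.0)),
            ((-65.0, 145.0), 0.15, (15.0, 15.0)),
            ((55.0, 45.0), 0.10, (12.0, 12.0)),
        ]
    elif pair_type == "phi_chi1":
        comps = _peaks_2d(_PHI_PEAKS, tuple((c, 15.0, w) for c, w in _CHI_PEAKS))
    elif pair_type == "psi_chi1":
        comps = _peaks_2d(_PSI_PEAKS, tuple((c, 15.0, w) for c, w in _CHI_PEAKS))
    elif pair_type == "chi1_chi2":
        chi = tuple((c, 15.0, w) for c, w in _CHI_PEAKS)
        comps = _peaks_2d(chi, chi)
    else:
        raise ValueError(f"unknown pair type {pair_type!r}")
    dens = _wrapped_gaussian_grid(comps, bin_width)
    dens = 0.9 * dens / dens.sum() + 0.1 / dens.size
    grid = -np.log(dens)
    grid -= grid.min()
    return STAPTable(
        pair_type=pair_type,
        bin_width=bin_width,
        grid=grid,
        provenance="analytic basin prior",
        pseudocount=0.0,
        smoothing_sigma=0.0,
    )


def default_tables(bin_width: float = 10.0) -> list[STAPTable]:
    """The four default torsion-pair potentials (phi-psi, phi-chi1, psi-chi1,
    chi1-chi2) from the analytic basin prior."""
    return [reference_table(pt, bin_width) for pt in PAIR_TYPES]


def stap_energy(angles: tuple[float, float], table: STAPTable) -> float:
    """Periodic bilinear interpolation of the table at (theta1, theta2) degrees."""
    th1, th2 = angles
    return float(_stap_interp(table, np.atleast_1d(th1), np.atleast_1d(th2))[0])


def _stap_interp(table: STAPTable, th1: np.ndarray, th2: np.ndarray) -> np.ndarray:
    n = table.n_bins
    bw = table.bin_width
    # continuous bin coordinate: bin centers at -180 + (k + 0.5) * bw
    x = (np.asarray(th1, dtype=float) + 180.0) / bw - 0.5
    y = (np.asarray(th2, dtype=float) + 180.0) / bw - 0.5
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    x0 %= n
    y0 %= n
    x1 = (x0 + 1) % n
    y1 = (y0 + 1) % n
    g = table.grid
    return (
        g[x0, y0] * (1 - fx) * (1 - fy)
        + g[x1, y0] * fx * (1 - fy)
        + g[x0, y1] * (1 - fx) * fy
        + g[x1, y1] * fx * fy
    )


# ---------------------------------------------------------------------------
# Stereochemical and solvation surrogates
# ---------------------------------------------------------------------------


def _contact_rmin(elements: list[str]) -> np.ndarray:
    r = np.array([CONTACT_RADII.get(e, 1.6) for e in elements])
    return r[:, None] + r[None, :]


def stereo_energy(model: StructureModel, topology: Topology | None = None) -> float:
    """Soft-core repulsion over nonbonded pairs (graph distance > 3 bonds)."""
    topology = topology or default_topology()
    adj = bond_graph(model, topology)
    excl = graph_distance_mask(adj, 3)
    return float(_stereo_from_parts(model.coords, _contact_rmin([a.element for a in model.atoms]), excl))


def _stereo_from_parts(coords: np.ndarray, rmin: np.ndarray, excl: np.ndarray) -> float:
    d = cdist(coords, coords)
    with np.errstate(divide="ignore", invalid="ignore"):
        pen = ((rmin - d) / rmin) ** 2
    mask = (d < rmin) & ~excl
    return 0.5 * float(pen[mask].sum())  # each unordered pair counted once


def solv_energy(model: StructureModel, topology: Topology | None = None) -> float:
    """Contact-burial solvation surrogate over heavy atoms.

    burial(atom) = number of heavy atoms within 6.5 A excluding the atom itself
    and its bonded neighbors; the per-atom energy is burial times an element
    preference (negative for C/S, positive for N/O).
    """
    topology = topology or default_topology()
    adj = bond_graph(model, topology)
    heavy = [i for i, a in enumerate(model.atoms) if a.element != "H"]
    if not heavy:
        return 0.0
    bonded = np.zeros((len(model.atoms), len(model.atoms)), dtype=bool)
    for i, nb in enumerate(adj):
        for j in nb:
            bonded[i, j] = True
    hidx = np.array(heavy)
    s = np.array([SOLVATION_PREFERENCE.get(model.atoms[i].element, 0.0) for i in heavy])
    coords = model.coords[hidx]
    d = cdist(coords, coords)
    neigh = (d < BURIAL_RADIUS) & ~np.eye(len(heavy), dtype=bool) & ~bonded[np.ix_(hidx, hidx)]
    burial = neigh.sum(axis=1)
    return float(np.sum(s * burial))


# ---------------------------------------------------------------------------
# Full evaluator
# ---------------------------------------------------------------------------


class EnergyEvaluator:
    """Precompiled evaluator of the composite energy on one topology.

    Resolves every restraint selection once, precomputes nonbonded masks and
    torsion atom quadruples, then evaluates all terms from a coordinate array.
    This is the hot path of the annealer.
    """

    def __init__(
        self,
        model: StructureModel,
        restraints: RestraintSet | None = None,
        tables: list[STAPTable] | None = None,
        weights: Weights | None = None,
        params: NOEParams | None = None,
        topology: Topology | None = None,
    ):
        self.model = model
        self.weights = weights or Weights()
        self.params = params or NOEParams()
        self.topology = topology or default_topology()
        restraints = restraints or RestraintSet()
        tables = tables or []

        n = len(model.atoms)
        adj = bond_graph(model, self.topology)
        excl = graph_distance_mask(adj, 3)
        rmin = _contact_rmin([a.element for a in model.atoms])
        # full-matrix form: excluded / lower-triangle entries can never trigger
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        allowed = upper & ~excl
        self._st_rmin = rmin
        self._st_rmin2 = np.where(allowed, rmin ** 2, -1.0)

        heavy = np.array([i for i, a in enumerate(model.atoms) if a.element != "H"], dtype=int)
        self._heavy = heavy
        s_atom = np.array(
            [SOLVATION_PREFERENCE.get(model.atoms[i].element, 0.0) for i in heavy]
        )
        bonded = np.zeros((n, n), dtype=bool)
        for i, nb in enumerate(adj):
            for j in nb:
                bonded[i, j] = True
        nh = len(heavy)
        h_upper = np.triu(np.ones((nh, nh), dtype=bool), k=1)
        h_ok = h_upper & ~bonded[np.ix_(heavy, heavy)]
        # burial contributes s_i + s_j per unordered in-range heavy pair
        self._sv_w = np.where(h_ok, s_atom[:, None] + s_atom[None, :], 0.0)

        # NOE restraints -> flat pair arrays with reduceat segments
        pair_i: list[np.ndarray] = []
        pair_j: list[np.ndarray] = []
        starts: list[int] = []
        total = 0
        lowers: list[float] = []
        uppers: list[float] = []
        for r in restraints.noes:
            ia, ib = _restraint_pairs(model, r)
            starts.append(total)
            total += len(ia)
            pair_i.append(ia)
            pair_j.append(ib)
            lowers.append(r.lower)
            uppers.append(r.upper)
        self.noe_restraints = list(restraints.noes)
        self._noe_i = np.concatenate(pair_i) if pair_i else np.empty(0, dtype=int)
        self._noe_j = np.concatenate(pair_j) if pair_j else np.empty(0, dtype=int)
        self._noe_starts = np.array(starts, dtype=int)
        self._noe_lower = np.array(lowers)
        self._noe_upper = np.array(uppers)

        # dihedral restraints -> atom index quads
        quads = []
        self._dihe_theta0 = np.array([d.theta0 for d in restraints.dihedrals])
        self._dihe_delta = np.array([d.delta for d in restraints.dihedrals])
        self._dihe_k = np.array([d.k for d in restraints.dihedrals])
        for d in restraints.dihedrals:
            idx = []
            for s in d.atoms:
                hits = resolve_selection(model, s)
                if len(hits) != 1:
                    raise SelectionError(
                        f"dihedral selection {s.atom_pattern!r} is not unique"
                    )
                idx.append(hits[0])
            quads.append(idx)
        self._dihe_quads = np.array(quads, dtype=int).reshape(-1, 4)
        self.dihedral_restraints = list(restraints.dihedrals)

        # STAP: per residue and table, quads for both torsions of the pair
        self._stap_terms: list[tuple[STAPTable, np.ndarray, np.ndarray]] = []
        tor_defs = self._torsion_quads()
        for table in tables:
            t1, t2 = table.pair_type.split("_")
            q1 = []
            q2 = []
            for r in model.residues:
                if table.residue_class != "ALL" and r.name != table.residue_class:
                    continue
                a = tor_defs.get((r.index, t1))
                b = tor_defs.get((r.index, t2))
                if a is not None and b is not None:
                    q1.append(a)
                    q2.append(b)
            if q1:
                self._stap_terms.append(
                    (table, np.array(q1, dtype=int), np.array(q2, dtype=int))
                )
        self.tables = list(tables)

    def _torsion_quads(self) -> dict[tuple[int, str], list[int]]:
        """Atom index quadruples for phi/psi/chi1/chi2 of every residue."""
        model = self.model
        out: dict[tuple[int, str], list[int]] = {}
        reslist = [r for r in model.residues if not r.is_hetero and r.name in self.topology]
        for k, r in enumerate(reslist):
            prev_r = reslist[k - 1] if k > 0 and reslist[k - 1].chain_id == r.chain_id and reslist[k - 1].chain_index == r.chain_index - 1 else None
            next_r = (
                reslist[k + 1]
                if k + 1 < len(reslist)
                and reslist[k + 1].chain_id == r.chain_id
                and reslist[k + 1].chain_index == r.chain_index + 1
                else None
            )

            def ai(res, name):
                return model.atom_index(res.index, name) if res is not None else None

            tmpl = self.topology.template(r.name)
            cand: dict[str, list[int | None]] = {}
            if prev_r is not None:
                cand["phi"] = [ai(prev_r, "C"), ai(r, "N"), ai(r, "CA"), ai(r, "C")]
            if next_r is not None:
                cand["psi"] = [ai(r, "N"), ai(r, "CA"), ai(r, "C"), ai(next_r, "N")]
            for chi in tmpl.chi_names:
                cand[chi] = [ai(r, x) for x in tmpl.chi_atoms(chi)]
            for name, idx in cand.items():
                if all(i is not None for i in idx):
                    out[(r.index, name)] = idx
        return out

    # -- term evaluations ---------------------------------------------------

    def noe_distances(self, coords: np.ndarray) -> np.ndarray:
        if len(self._noe_starts) == 0:
            return np.empty(0)
        diff = coords[self._noe_i] - coords[self._noe_j]
        inv6 = np.einsum("ij,ij->i", diff, diff) ** -3.0
        sums = np.add.reduceat(inv6, self._noe_starts)
        return sums ** (-1.0 / 6.0)

    def dihedral_angles(self, coords: np.ndarray) -> np.ndarray:
        if len(self._dihe_quads) == 0:
            return np.empty(0)
        q = self._dihe_quads
        return dihedral_many(coords[q[:, 0]], coords[q[:, 1]], coords[q[:, 2]], coords[q[:, 3]])

    def evaluate(self, coords: np.ndarray) -> EnergyBreakdown:
        w = self.weights
        d2 = None
        if w.w_stereo or w.w_solv:
            d2 = cdist(coords, coords, "sqeuclidean")
        # stereo: one full squared-distance matrix, penalty on the few overlaps
        if w.w_stereo:
            ci, cj = np.nonzero(d2 < self._st_rmin2)
            if len(ci):
                d = np.sqrt(d2[ci, cj])
                rm = self._st_rmin[ci, cj]
                e_stereo = w.w_stereo * float(np.sum(((rm - d) / rm) ** 2))
            else:
                e_stereo = 0.0
        else:
            e_stereo = 0.0
        # solvation
        if w.w_solv and len(self._heavy):
            d2h = d2[np.ix_(self._heavy, self._heavy)]
            e_solv = w.w_solv * float(np.sum(self._sv_w * (d2h < BURIAL_RADIUS ** 2)))
        else:
            e_solv = 0.0
        # NOE
        if w.w_noe and len(self._noe_starts):
            r = self.noe_distances(coords)
            e_noe = w.w_noe * float(
                np.sum(noe_energy(r, self._noe_lower, self._noe_upper, self.params))
            )
        else:
            e_noe = 0.0
        # dihedral restraints
        if w.w_dihe and len(self._dihe_quads):
            th = self.dihedral_angles(coords)
            e_dihe = w.w_dihe * float(
                np.sum(dihedral_energy(th, self._dihe_theta0, self._dihe_delta, self._dihe_k))
            )
        else:
            e_dihe = 0.0
        # STAP
        e_stap = 0.0
        if w.w_stap:
            for table, q1, q2 in self._stap_terms:
                th1 = dihedral_many(coords[q1[:, 0]], coords[q1[:, 1]], coords[q1[:, 2]], coords[q1[:, 3]])
                th2 = dihedral_many(coords[q2[:, 0]], coords[q2[:, 1]], coords[q2[:, 2]], coords[q2[:, 3]])
                e_stap += float(np.sum(_stap_interp(table, th1, th2)))
            e_stap *= w.w_stap
        return EnergyBreakdown.from_terms(e_stereo, e_solv, e_noe, e_dihe, e_stap)


def total_energy(
    model: StructureModel,
    restraints: RestraintSet | None = None,
    tables: list[STAPTable] | None = None,
    weights: Weights | None = None,
    params: NOEParams | None = None,
    topology: Topology | None = None,
) -> EnergyBreakdown:
    """Evaluate the composite energy of a model; returns the full breakdown."""
    ev = EnergyEvaluator(model, restraints, tables, weights, params, topology)
    return ev.evaluate(model.coords)
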