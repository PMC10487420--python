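"""Structure data model, multi-model PDB I/O and preprocessing.

The in-memory model is a flat list of atoms grouped into residues and chains,
one ``StructureModel`` per NMR MODEL record.  Preprocessing mirrors a typical
NMR-refinement pipeline: ensemble-size/sequence-length entry filtering,
disulfide detection, removal of non-standard residues and atoms, and
translation between PDB version-3 and CHARMM atom-name dialects.

Coordinates are Angstroms.  Residue indices are 0-based in memory; the PDB
residue sequence number from disk is kept alongside for restraint matching and
for writing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .errors import ParseError, TopologyError
from .geometry import dihedral, place_atom, wrap_angle
from .topology import (
    BACKBONE,
    H_BOND,
    ONE_TO_THREE,
    STANDARD_RESIDUES,
    Topology,
    default_topology,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "Ensemble",
    "TorsionSet",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "passes_entry_filter",
    "detect_disulfides",
    "strip_nonstandard",
    "map_atom_names",
    "torsions_of",
    "rebuild_from_torsions",
    "bond_graph",
    "graph_distance_mask",
]


def element_of(name: str) -> str:
    """Element symbol from a protein atom name (C, N, O, S or H)."""
    stripped = name.lstrip("0123456789")
    return stripped[0].upper() if stripped else "X"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int  # 0-based within chain
    residue_name: str
    chain_id: str
    position: np.ndarray  # (3,) Angstrom
    is_hetero: bool = False
    residue_seq: int = 0  # PDB residue number on disk (1-based)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not self.name:
            raise ValueError("empty atom name")


@dataclass(frozen=True)
class Residue:
    """A view of one residue: global index plus atom indices into the model."""

    index: int  # global 0-based index across the model
    chain_id: str
    chain_index: int  # 0-based within chain
    name: str
    seq: int  # PDB numbering
    atom_indices: tuple[int, ...]
    is_hetero: bool


class StructureModel:
    """One conformer: an ordered list of atoms with residue/chain grouping."""

    def __init__(self, atoms: list[AtomRecord], disulfides: list[tuple[int, int]] | None = None):
        self.atoms = list(atoms)
        self.disulfides = list(disulfides or [])
        self._index()

    def _index(self) -> None:
        residues: list[Residue] = []
        lookup: dict[tuple[str, int], int] = {}
        groups: dict[tuple[str, int], list[int]] = {}
        order: list[tuple[str, int]] = []
        meta: dict[tuple[str, int], AtomRecord] = {}
        prev_idx: dict[str, int] = {}
        for i, at in enumerate(self.atoms):
            key = (at.chain_id, at.residue_index)
            if key not in groups:
                if at.chain_id in prev_idx and at.residue_index <= prev_idx[at.chain_id]:
                    raise TopologyError(
                        f"residue numbering not strictly increasing in chain {at.chain_id!r} "
                        f"at residue index {at.residue_index}"
                    )
                prev_idx[at.chain_id] = at.residue_index
                groups[key] = []
                order.append(key)
                meta[key] = at
            groups[key].append(i)
        for gidx, key in enumerate(order):
            at = meta[key]
            residues.append(
                Residue(
                    index=gidx,
                    chain_id=at.chain_id,
                    chain_index=at.residue_index,
                    name=at.residue_name,
                    seq=at.residue_seq,
                    atom_indices=tuple(groups[key]),
                    is_hetero=at.is_hetero,
                )
            )
            lookup[key] = gidx
        self.residues = residues
        self._res_lookup = lookup
        self._atom_lookup = {
            (self.residues[self.residue_of(i)].index, at.name): i
            for i, at in enumerate(self.atoms)
        }
        self._res_of_atom = np.empty(len(self.atoms), dtype=int)
        for r in residues:
            for i in r.atom_indices:
                self._res_of_atom[i] = r.index
        for a, b in self.disulfides:
            if self.residues[a].name != "CYS" or self.residues[b].name != "CYS":
                raise TopologyError("disulfide pair references a non-CYS residue")

    def residue_of(self, atom_index: int) -> int:
        at = self.atoms[atom_index]
        return self._res_lookup[(at.chain_id, at.residue_index)]

    def atom_index(self, residue: int, name: str) -> int | None:
        return self._atom_lookup.get((residue, name))

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(self.atoms, coords):
            a.position = xyz.copy()

    @property
    def res_of_atom(self) -> np.ndarray:
        return self._res_of_atom

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def sequence(self, protein_only: bool = True) -> list[str]:
        return [r.name for r in self.residues if not (protein_only and r.is_hetero)]

    def copy(self) -> "StructureModel":
        return StructureModel(
            [replace(a, position=a.position.copy()) for a in self.atoms],
            list(self.disulfides),
        )

    def __repr__(self) -> str:
        return f"<StructureModel {len(self.atoms)} atoms, {self.n_residues} residues>"


@dataclass
class Ensemble:
    models: list[StructureModel]
    entry_id: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.models:
            raise TopologyError("ensemble has no models")
        ref = [(a.name, a.residue_index, a.residue_name, a.chain_id) for a in self.models[0].atoms]
        for k, m in enumerate(self.models[1:], start=2):
            sig = [(a.name, a.residue_index, a.residue_name, a.chain_id) for a in m.atoms]
            if sig != ref:
                raise TopologyError(
                    f"model {k} topology differs from model 1 "
                    f"({len(sig)} vs {len(ref)} atoms or differing names)"
                )

    def __len__(self) -> int:
        return len(self.models)


class TorsionSet(dict):
    """Ordered map (global residue index, torsion name) -> angle in [-180, 180)."""

    def __setitem__(self, key, value):
        super().__setitem__(key, float(wrap_angle(value)))

    def copy(self) -> "TorsionSet":
        t = TorsionSet()
        t.update(self)
        return t

    def update(self, other):
        for k, v in dict(other).items():
            self[k] = v


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _validate_pdb_text(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError("truncated ATOM/HETATM record", lineno)
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ParseError("unparseable coordinates in ATOM/HETATM record", lineno) from None


def read_pdb_ensemble(path: str | Path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    A file without MODEL records yields a 1-model ensemble.  HETATM records are
    retained and flagged ``is_hetero``.
    """
    path = Path(path)
    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    models: list[StructureModel] = []
    for gm in st:
        atoms: list[AtomRecord] = []
        for chain in gm:
            for ridx, res in enumerate(chain):
                het = res.het_flag == "H"
                for at in res:
                    atoms.append(
                        AtomRecord(
                            serial=at.serial,
                            name=at.name,
                            element=at.element.name if at.element else element_of(at.name),
                            residue_index=ridx,
                            residue_name=res.name,
                            chain_id=chain.name,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            is_hetero=het,
                            residue_seq=res.seqid.num,
                        )
                    )
        models.append(StructureModel(atoms))
    ens = Ensemble(models=models, entry_id=st.name or path.stem)
    return ens


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB with SSBOND records for detected disulfides."""
    lines: list[str] = []
    model0 = ensemble.models[0]
    for n, (a, b) in enumerate(model0.disulfides, start=1):
        ra, rb = model0.residues[a], model0.residues[b]
        lines.append(
            f"SSBOND{n:4d} CYS {ra.chain_id:>1}{ra.seq:5d}    CYS {rb.chain_id:>1}{rb.seq:5d}"
        )
    multi = len(ensemble.models) > 1
    for k, model in enumerate(ensemble.models, start=1):
        if multi:
            lines.append(f"MODEL {k:8d}")
        for at in model.atoms:
            rec = "HETATM" if at.is_hetero else "ATOM  "
            name = at.name if len(at.name) == 4 else f" {at.name:<3s}"
            x, y, z = at.position
            lines.append(
                f"{rec}{at.serial:5d} {name}{'':1s}{at.residue_name:>3s} "
                f"{at.chain_id:1s}{at.residue_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {at.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def passes_entry_filter(ensemble: Ensemble, min_models: int = 10, min_residues: int = 20) -> bool:
    """Entry filter: strictly more than ``min_models`` conformers and strictly
    more than ``min_residues`` protein residues."""
    n_res = sum(1 for r in ensemble.models[0].residues if not r.is_hetero)
    return len(ensemble.models) > min_models and n_res > min_residues


def detect_disulfides(model: StructureModel, cutoff: float = 2.5) -> list[tuple[int, int]]:
    """Greedy nearest-first pairing of CYS SG atoms within ``cutoff`` Angstrom.

    Each residue joins at most one pair.  Returns global residue index pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sgs = [
        (r.index, model.atoms[i].position)
        for r in model.residues
        if r.name == "CYS"
        for i in r.atom_indices
        if model.atoms[i].name == "SG"
    ]
    cands = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                cands.append((d, sgs[i][0], sgs[j][0]))
    cands.sort()
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, a, b in cands:
        if a not in used and b not in used:
            pairs.append((min(a, b), max(a, b)))
            used.update((a, b))
    return pairs


def strip_nonstandard(
    model: StructureModel,
    keep_ligands: bool = False,
    topology: Topology | None = None,
) -> StructureModel:
    """Drop residues outside the 20 standard amino acids (hetero residues are
    kept when ``keep_ligands``) and atoms absent from the residue template."""
    topology = topology or default_topology()
    keep: list[AtomRecord] = []
    for r in model.residues:
        if r.name not in STANDARD_RESIDUES:
            if r.is_hetero and keep_ligands:
                keep.extend(model.atoms[i] for i in r.atom_indices)
            continue
        allowed = set(topology.template(r.name).atom_names()) | {"OXT", "H1", "H2", "H3"}
        for i in r.atom_indices:
            if model.atoms[i].name in allowed:
                keep.append(model.atoms[i])
            else:
                logger.debug("dropping unknown atom %s in %s", model.atoms[i].name, r.name)
    return StructureModel([replace(a, position=a.position.copy()) for a in keep])


# ---------------------------------------------------------------------------
# Atom-name dialects
# ---------------------------------------------------------------------------

_DIALECTS = ("pdb3", "charmm")
_dialect_cache: dict[str, dict[tuple[str, str], str]] = {}


def _load_dialect_table() -> tuple[dict[tuple[str, str], str], dict[tuple[str, str], str]]:
    """Packaged dialect table -> (pdb3->charmm, charmm->pdb3) maps keyed by
    (residue-or-*, name)."""
    if _dialect_cache:
        return _dialect_cache["fwd"], _dialect_cache["rev"]
    fwd: dict[tuple[str, str], str] = {}
    rev: dict[tuple[str, str], str] = {}
    text = resources.files("noesa.data").joinpath("atom_dialects_v1.txt").read_text()
    for line in text.splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        res, pdb3, charmm = line.split()
        fwd[(res, pdb3)] = charmm
        rev[(res, charmm)] = pdb3
    _dialect_cache["fwd"] = fwd
    _dialect_cache["rev"] = rev
    return fwd, rev


def map_atom_names(model: StructureModel, dialect: str) -> StructureModel:
    """Rename atoms into the requested dialect (``pdb3`` or ``charmm``).

    The packaged table is bijective per residue context, so a round trip is the
    identity.  Names absent from the table pass through unchanged (warned when
    they are clearly dialect-specific is out of scope: passthrough is logged at
    debug level only for hetero atoms).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    fwd, rev = _load_dialect_table()
    table = fwd if dialect == "charmm" else rev
    atoms = []
    for a in model.atoms:
        new = table.get((a.residue_name, a.name)) or table.get(("*", a.name))
        if new is None:
            new = a.name
        atoms.append(replace(a, name=new, position=a.position.copy()))
    return StructureModel(atoms, list(model.disulfides))


# ---------------------------------------------------------------------------
# Torsions <-> Cartesian
# ---------------------------------------------------------------------------

_BB = BACKBONE


def torsions_of(model: StructureModel, topology: Topology | None = None) -> TorsionSet:
    """Measure phi/psi/omega and side-chain chi torsions, degrees in [-180, 180).

    psi of the final residue of a chain is measured from the carbonyl O
    (dihedral N-CA-C-O shifted by 180 deg) so that a rebuilt model round-trips.
    Torsions with missing atoms are omitted and listed in ``result.missing``.
    """
    topology = topology or default_topology()
    tset = TorsionSet()
    missing: list[tuple[int, str]] = []

    def pos(res: int, name: str):
        i = model.atom_index(res, name)
        return None if i is None else model.atoms[i].position

    chains: dict[str, list[Residue]] = {}
    for r in model.residues:
        if r.is_hetero or r.name not in topology:
            continue
        chains.setdefault(r.chain_id, []).append(r)

    for reslist in chains.values():
        for k, r in enumerate(reslist):
            prev_r = reslist[k - 1] if k > 0 and reslist[k - 1].chain_index == r.chain_index - 1 else None
            next_r = (
                reslist[k + 1]
                if k + 1 < len(reslist) and reslist[k + 1].chain_index == r.chain_index + 1
                else None
            )
            n, ca, c, o = (pos(r.index, x) for x in ("N", "CA", "C", "O"))
            defs: list[tuple[str, list]] = []
            if prev_r is not None:
                c_prev = pos(prev_r.index, "C")
                ca_prev = pos(prev_r.index, "CA")
                defs.append(("phi", [c_prev, n, ca, c]))
                defs.append(("omega", [ca_prev, c_prev, n, ca]))
            if next_r is not None:
                defs.append(("psi", [n, ca, c, pos(next_r.index, "N")]))
            else:
                defs.append(("psi", [n, ca, c, o], 180.0) if o is not None else ("psi", [n, ca, c, None]))
            tmpl = topology.template(r.name)
            for chi in tmpl.chi_names:
                defs.append((chi, [pos(r.index, x) for x in tmpl.chi_atoms(chi)]))
            for item in defs:
                name, pts = item[0], item[1]
                shift = item[2] if len(item) > 2 else 0.0
                if any(p is None for p in pts):
                    missing.append((r.index, name))
                    continue
                tset[(r.index, name)] = wrap_angle(dihedral(*pts) + shift)
    tset.missing = missing
    return tset


def rebuild_from_torsions(
    torsions: TorsionSet,
    topology: Topology | None = None,
    sequence: list[str] | str | None = None,
    chain_id: str = "A",
    add_hydrogens: bool = True,
) -> StructureModel:
    """Build an ideal-geometry Cartesian model for a single chain.

    ``sequence`` is a list of 3-letter codes or a 1-letter string.  Missing
    torsions default to omega=180, psi=180 and chi=-60; phi of residue 0 is
    not a degree of freedom.
    """
    topology = topology or default_topology()
    if sequence is None:
        raise ValueError("sequence is required")
    if isinstance(sequence, str):
        try:
            seq = [ONE_TO_THREE[c] for c in sequence]
        except KeyError as e:
            raise KeyError(f"unknown residue code {e.args[0]!r}") from None
    else:
        seq = list(sequence)
    for code in seq:
        if code not in topology:
            raise KeyError(f"unknown residue code {code!r}")

    def tor(i: int, name: str, default: float) -> float:
        return torsions.get((i, name), default)

    bb = topology.backbone
    heavy: list[tuple[int, str, np.ndarray]] = []  # (res, name, pos)
    pos_map: dict[tuple[int, str], np.ndarray] = {}

    def put(res: int, name: str, p: np.ndarray) -> None:
        heavy.append((res, name, p))
        pos_map[(res, name)] = p

    for i, code in enumerate(seq):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([bb["N_CA"], 0.0, 0.0])
            c = place_atom([0.0, 0.0, 1.0], n, ca, bb["CA_C"], bb["ANG_N_CA_C"], 60.0)
        else:
            n_prev = pos_map[(i - 1, "N")]
            ca_prev = pos_map[(i - 1, "CA")]
            c_prev = pos_map[(i - 1, "C")]
            psi_prev = tor(i - 1, "psi", 180.0)
            n = place_atom(n_prev, ca_prev, c_prev, bb["C_N"], bb["ANG_CA_C_N"], psi_prev)
            ca = place_atom(ca_prev, c_prev, n, bb["N_CA"], bb["ANG_C_N_CA"], tor(i, "omega", 180.0))
            c = place_atom(c_prev, n, ca, bb["CA_C"], bb["ANG_N_CA_C"], tor(i, "phi", -120.0))
        put(i, "N", n)
        put(i, "CA", ca)
        put(i, "C", c)
        psi = tor(i, "psi", 180.0)
        put(i, "O", place_atom(n, ca, c, bb["C_O"], bb["ANG_CA_C_O"], wrap_angle(psi + 180.0)))
        tmpl = topology.template(code)
        for z in tmpl.side_chain:
            t = z.offset if z.chi is None else wrap_angle(tor(i, z.chi, -60.0) + z.offset)
            p = place_atom(pos_map[(i, z.a3)], pos_map[(i, z.a2)], pos_map[(i, z.a1)], z.bond, z.angle, t)
            put(i, z.name, p)
        if i == len(seq) - 1:
            put(i, "OXT", place_atom(n, ca, c, 1.249, bb["ANG_CA_C_O"], psi))

    atoms: list[AtomRecord] = []
    serial = 1
    for i, code in enumerate(seq):
        names = [nm for (r, nm, _) in heavy if r == i]
        for nm in names:
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=nm,
                    element=element_of(nm),
                    residue_index=i,
                    residue_name=code,
                    chain_id=chain_id,
                    position=pos_map[(i, nm)],
                    residue_seq=i + 1,
                )
            )
            serial += 1
    model = StructureModel(atoms)
    if add_hydrogens:
        model = _place_hydrogens(model, topology)
    return model


def _place_hydrogens(model: StructureModel, topology: Topology) -> StructureModel:
    """Add hydrogens at ideal positions determined by the heavy-atom frame."""
    adj = bond_graph(model, topology, include_hydrogens=False)
    coords = model.coords
    new_atoms: list[AtomRecord] = []

    def unit(v):
        return v / np.linalg.norm(v)

    def heavy_neighbors(i: int) -> list[int]:
        return sorted(adj[i])

    half = np.radians(109.5 / 2.0)

    for r in model.residues:
        for i in r.atom_indices:
            new_atoms.append(model.atoms[i])
        if r.is_hetero or r.name not in topology:
            continue
        tmpl = topology.template(r.name)
        hs: list[tuple[str, str]] = []
        if r.name != "PRO":
            hs.append(("H", "N"))
        if r.name == "GLY":
            hs += [("HA2", "CA"), ("HA3", "CA")]
        else:
            hs.append(("HA", "CA"))
        hs += list(tmpl.hydrogens)

        grouped: dict[str, list[str]] = {}
        for hname, parent in hs:
            grouped.setdefault(parent, []).append(hname)

        placed: list[tuple[str, np.ndarray]] = []
        for parent, hnames in grouped.items():
            pi = model.atom_index(r.index, parent)
            if pi is None:
                continue
            p = coords[pi]
            elem = model.atoms[pi].element
            bond = H_BOND.get(elem, 1.09)
            nbrs = heavy_neighbors(pi)
            us = [unit(coords[j] - p) for j in nbrs]
            nH = len(hnames)
            if len(us) == 3 and nH == 1:
                placed.append((hnames[0], p - bond * unit(us[0] + us[1] + us[2])))
            elif len(us) == 2 and nH == 1:
                placed.append((hnames[0], p - bond * unit(us[0] + us[1])))
            elif len(us) == 2 and nH == 2:
                axis = -unit(us[0] + us[1])
                perp = unit(np.cross(us[0] - us[1], axis))
                for hname, s in zip(hnames, (1.0, -1.0)):
                    placed.append((hname, p + bond * (np.cos(half) * axis + s * np.sin(half) * perp)))
            elif len(us) == 1:
                nb = nbrs[0]
                gp = [j for j in heavy_neighbors(nb) if j != pi]
                ref = coords[gp[0]] if gp else p + np.array([0.0, 0.0, 1.0])
                if nH == 3:
                    for hname, t in zip(hnames, (180.0, -60.0, 60.0)):
                        placed.append((hname, place_atom(ref, coords[nb], p, bond, 109.5, t)))
                elif nH == 2:  # planar amide / guanidinium NH2
                    for hname, t in zip(hnames, (0.0, 180.0)):
                        placed.append((hname, place_atom(ref, coords[nb], p, bond, 120.0, t)))
                else:  # hydroxyl, thiol, simplified N-terminus
                    ang = {"O": 109.5, "S": 96.0, "N": 118.0}.get(elem, 109.5)
                    placed.append((hname := hnames[0], place_atom(ref, coords[nb], p, bond, ang, 180.0)))
            else:
                logger.debug("cannot place %s on %s/%s", hnames, r.name, parent)
        for hname, hpos in placed:
            new_atoms.append(
                AtomRecord(
                    serial=0,
                    name=hname,
                    element="H",
                    residue_index=r.chain_index,
                    residue_name=r.name,
                    chain_id=r.chain_id,
                    position=hpos,
                    residue_seq=r.seq,
                )
            )
    for s, a in enumerate(new_atoms, start=1):
        a.serial = s
    return StructureModel(new_atoms, list(model.disulfides))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def bond_graph(
    model: StructureModel,
    topology: Topology | None = None,
    include_hydrogens: bool = True,
) -> list[set[int]]:
    """Adjacency sets over atom indices: template bonds, ring closures, peptide
    bonds, OXT, hydrogens to their parents, and disulfide SG-SG bonds."""
    topology = topology or default_topology()
    adj: list[set[int]] = [set() for _ in model.atoms]

    def link(i: int | None, j: int | None) -> None:
        if i is None or j is None:
            return
        adj[i].add(j)
        adj[j].add(i)

    prev_c: dict[str, tuple[int, int]] = {}
    for r in model.residues:
        if r.is_hetero or r.name not in topology:
            continue
        tmpl = topology.template(r.name)
        idx = {model.atoms[i].name: i for i in r.atom_indices}
        link(idx.get("N"), idx.get("CA"))
        link(idx.get("CA"), idx.get("C"))
        link(idx.get("C"), idx.get("O"))
        link(idx.get("C"), idx.get("OXT"))
        for z in tmpl.side_chain:
            link(idx.get(z.name), idx.get(z.a1))
        for a, b in tmpl.closures:
            link(idx.get(a), idx.get(b))
        if include_hydrogens:
            link(idx.get("H"), idx.get("N"))
            for h in ("H1", "H2", "H3"):
                link(idx.get(h), idx.get("N"))
            if r.name == "GLY":
                link(idx.get("HA2"), idx.get("CA"))
                link(idx.get("HA3"), idx.get("CA"))
            else:
                link(idx.get("HA"), idx.get("CA"))
            for hname, parent in tmpl.hydrogens:
                link(idx.get(hname), idx.get(parent))
        if r.chain_id in prev_c and prev_c[r.chain_id][0] == r.chain_index - 1:
            link(prev_c[r.chain_id][1], idx.get("N"))
        if "C" in idx:
            prev_c[r.chain_id] = (r.chain_index, idx["C"])
    for a, b in model.disulfides:
        ia = model.atom_index(a, "SG")
        ib = model.atom_index(b, "SG")
        link(ia, ib)
    return adj


def graph_distance_mask(adj: list[set[int]], max_sep: int = 3) -> np.ndarray:
    """Boolean (n, n) matrix: True where the bond-graph distance is <= max_sep
    (including the diagonal).  Used to exclude bonded/1-3/1-4 pairs."""
    n = len(adj)
    near = np.eye(n, dtype=bool)
    for i in range(n):
        frontier = {i}
        seen = {i}
        for _ in range(max_sep):
            nxt = set()
            for j in frontier:
                nxt |= adj[j]
            nxt -= seen
            seen |= nxt
            frontier = nxt
        near[i, list(seen)] = True
    return near
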