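"""Idealized amino-acid topology: per-residue heavy-atom internal-coordinate
templates, hydrogen lists, connectivity, and rotatable-torsion definitions.

The templates use fixed ideal bond lengths and angles; only torsion angles are
degrees of freedom.  Branch geometry (e.g. the CB improper, the split between
CG1/CG2) was calibrated against MMFF-optimized L-amino acids, so chirality and
prochirality follow the biological convention.  Fused and five-membered rings
are built from one spanning path of the ring with fixed torsions; the closing
bond is recorded in the connectivity but not used for placement, so ring
closure is approximate at the 0.1 A level -- adequate for a statistics-driven
torsion-space refiner that has no bonded energy terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Topology",
    "ZEntry",
    "ResidueTemplate",
    "STANDARD_RESIDUES",
    "default_topology",
    "BACKBONE",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Backbone ideal internal geometry (Engh/Huber-like values, Angstrom / degrees).
BACKBONE = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "ANG_N_CA_C": 111.2,
    "ANG_CA_C_N": 116.2,
    "ANG_C_N_CA": 121.7,
    "ANG_CA_C_O": 120.8,
    "ANG_N_CA_CB": 110.5,
    "CA_CB": 1.530,
    # improper torsion dihedral(C, N, CA, CB) fixing L-chirality
    "CB_IMPROPER": -122.5,
}

H_BOND = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}


@dataclass(frozen=True)
class ZEntry:
    """One side-chain heavy atom placed from three previously known atoms.

    Position satisfies |X - a1| = bond, angle(X, a1, a2) = angle and
    dihedral(a3, a2, a1, X) = torsion, where torsion is `offset` plus the named
    chi angle (or just `offset` when chi is None).
    """

    name: str
    a1: str
    a2: str
    a3: str
    bond: float
    angle: float
    chi: str | None
    offset: float


def _z(name, a1, a2, a3, bond, angle, chi, offset) -> ZEntry:
    return ZEntry(name, a1, a2, a3, bond, angle, chi, offset)


def _cb(angle=110.5):
    return _z("CB", "CA", "N", "C", BACKBONE["CA_CB"], angle, None, BACKBONE["CB_IMPROPER"])


# Per-residue side chain templates (heavy atoms beyond the backbone).
_SIDE: dict[str, list[ZEntry]] = {
    "GLY": [],
    "ALA": [_cb()],
    "SER": [_cb(), _z("OG", "CB", "CA", "N", 1.417, 111.1, "chi1", 0.0)],
    "CYS": [_cb(), _z("SG", "CB", "CA", "N", 1.808, 113.8, "chi1", 0.0)],
    "THR": [
        _cb(),
        _z("OG1", "CB", "CA", "N", 1.433, 109.6, "chi1", 0.0),
        _z("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1", 120.0),
    ],
    "VAL": [
        _cb(),
        _z("CG1", "CB", "CA", "N", 1.521, 110.5, "chi1", 0.0),
        _z("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1", 122.0),
    ],
    "LEU": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.530, 116.3, "chi1", 0.0),
        _z("CD1", "CG", "CB", "CA", 1.521, 110.7, "chi2", 0.0),
        _z("CD2", "CG", "CB", "CA", 1.521, 110.7, "chi2", 122.5),
    ],
    "ILE": [
        _cb(),
        _z("CG1", "CB", "CA", "N", 1.530, 110.4, "chi1", 0.0),
        _z("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1", 122.0),
        _z("CD1", "CG1", "CB", "CA", 1.513, 113.8, "chi2", 0.0),
    ],
    "MET": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.520, 114.1, "chi1", 0.0),
        _z("SD", "CG", "CB", "CA", 1.803, 112.7, "chi2", 0.0),
        _z("CE", "SD", "CG", "CB", 1.791, 100.9, "chi3", 0.0),
    ],
    "PRO": [
        _cb(103.0),
        _z("CG", "CB", "CA", "N", 1.492, 104.5, None, -28.0),
        _z("CD", "CG", "CB", "CA", 1.503, 106.1, None, 38.0),
    ],
    "PHE": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.502, 113.8, "chi1", 0.0),
        _z("CD1", "CG", "CB", "CA", 1.384, 120.8, "chi2", 0.0),
        _z("CD2", "CG", "CB", "CA", 1.384, 120.8, "chi2", 180.0),
        _z("CE1", "CD1", "CG", "CB", 1.382, 120.8, None, 180.0),
        _z("CE2", "CD2", "CG", "CB", 1.382, 120.8, None, 180.0),
        _z("CZ", "CE1", "CD1", "CG", 1.382, 120.0, None, 0.0),
    ],
    "TYR": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.512, 113.9, "chi1", 0.0),
        _z("CD1", "CG", "CB", "CA", 1.389, 120.8, "chi2", 0.0),
        _z("CD2", "CG", "CB", "CA", 1.389, 120.8, "chi2", 180.0),
        _z("CE1", "CD1", "CG", "CB", 1.382, 121.1, None, 180.0),
        _z("CE2", "CD2", "CG", "CB", 1.382, 121.1, None, 180.0),
        _z("CZ", "CE1", "CD1", "CG", 1.378, 119.5, None, 0.0),
        _z("OH", "CZ", "CE1", "CD1", 1.376, 119.9, None, 180.0),
    ],
    "TRP": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.498, 113.6, "chi1", 0.0),
        _z("CD1", "CG", "CB", "CA", 1.365, 126.9, "chi2", 0.0),
        _z("CD2", "CG", "CB", "CA", 1.433, 126.6, "chi2", 180.0),
        _z("NE1", "CD1", "CG", "CB", 1.374, 110.2, None, 180.0),
        _z("CE2", "CD2", "CG", "CB", 1.409, 107.2, None, 180.0),
        _z("CE3", "CD2", "CG", "CB", 1.398, 133.9, None, 0.0),
        _z("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, None, 180.0),
        _z("CZ3", "CE3", "CD2", "CG", 1.382, 118.6, None, 180.0),
        _z("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, None, 180.0),
    ],
    "HIS": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.504, 113.8, "chi1", 0.0),
        _z("ND1", "CG", "CB", "CA", 1.378, 122.7, "chi2", 0.0),
        _z("CD2", "CG", "CB", "CA", 1.354, 131.0, "chi2", 180.0),
        _z("CE1", "ND1", "CG", "CB", 1.321, 109.3, None, 180.0),
        _z("NE2", "CD2", "CG", "CB", 1.374, 107.2, None, 180.0),
    ],
    "ASP": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.516, 112.6, "chi1", 0.0),
        _z("OD1", "CG", "CB", "CA", 1.249, 118.4, "chi2", 0.0),
        _z("OD2", "CG", "CB", "CA", 1.249, 118.4, "chi2", 180.0),
    ],
    "ASN": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.516, 112.6, "chi1", 0.0),
        _z("OD1", "CG", "CB", "CA", 1.231, 120.8, "chi2", 0.0),
        _z("ND2", "CG", "CB", "CA", 1.328, 116.4, "chi2", 180.0),
    ],
    "GLU": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.520, 114.1, "chi1", 0.0),
        _z("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2", 0.0),
        _z("OE1", "CD", "CG", "CB", 1.249, 118.4, "chi3", 0.0),
        _z("OE2", "CD", "CG", "CB", 1.249, 118.4, "chi3", 180.0),
    ],
    "GLN": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.520, 114.1, "chi1", 0.0),
        _z("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2", 0.0),
        _z("OE1", "CD", "CG", "CB", 1.231, 120.8, "chi3", 0.0),
        _z("NE2", "CD", "CG", "CB", 1.328, 116.4, "chi3", 180.0),
    ],
    "LYS": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.520, 114.1, "chi1", 0.0),
        _z("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2", 0.0),
        _z("CE", "CD", "CG", "CB", 1.520, 111.3, "chi3", 0.0),
        _z("NZ", "CE", "CD", "CG", 1.489, 111.9, "chi4", 0.0),
    ],
    "ARG": [
        _cb(),
        _z("CG", "CB", "CA", "N", 1.520, 114.1, "chi1", 0.0),
        _z("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2", 0.0),
        _z("NE", "CD", "CG", "CB", 1.460, 112.0, "chi3", 0.0),
        _z("CZ", "NE", "CD", "CG", 1.329, 124.2, "chi4", 0.0),
        _z("NH1", "CZ", "NE", "CD", 1.326, 120.0, None, 0.0),
        _z("NH2", "CZ", "NE", "CD", 1.326, 120.0, None, 180.0),
    ],
}

# Ring-closing bonds that are part of the connectivity but not of the build path.
_CLOSURES: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CZ", "CE2")],
    "TYR": [("CZ", "CE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "HIS": [("CE1", "NE2")],
    "PRO": [("CD", "N")],
}

# Hydrogens: (name, parent heavy atom).  Backbone H/HA handled generically.
_HYDROGENS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("HB1", "CB"), ("HB2", "CB"), ("HB3", "CB")],
    "SER": [("HB2", "CB"), ("HB3", "CB"), ("HG", "OG")],
    "CYS": [("HB2", "CB"), ("HB3", "CB"), ("HG", "SG")],
    "THR": [("HB", "CB"), ("HG1", "OG1"), ("HG21", "CG2"), ("HG22", "CG2"), ("HG23", "CG2")],
    "VAL": [("HB", "CB")]
    + [(f"HG1{i}", "CG1") for i in "123"]
    + [(f"HG2{i}", "CG2") for i in "123"],
    "LEU": [("HB2", "CB"), ("HB3", "CB"), ("HG", "CG")]
    + [(f"HD1{i}", "CD1") for i in "123"]
    + [(f"HD2{i}", "CD2") for i in "123"],
    "ILE": [("HB", "CB"), ("HG12", "CG1"), ("HG13", "CG1")]
    + [(f"HG2{i}", "CG2") for i in "123"]
    + [(f"HD1{i}", "CD1") for i in "123"],
    "MET": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG")]
    + [(f"HE{i}", "CE") for i in "123"],
    "PRO": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"), ("HD2", "CD"), ("HD3", "CD")],
    "PHE": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HD2", "CD2"), ("HE1", "CE1"), ("HE2", "CE2"), ("HZ", "CZ")],
    "TYR": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HD2", "CD2"), ("HE1", "CE1"), ("HE2", "CE2"), ("HH", "OH")],
    "TRP": [("HB2", "CB"), ("HB3", "CB"), ("HD1", "CD1"), ("HE1", "NE1"), ("HE3", "CE3"), ("HZ2", "CZ2"), ("HZ3", "CZ3"), ("HH2", "CH2")],
    "HIS": [("HB2", "CB"), ("HB3", "CB"), ("HD2", "CD2"), ("HE1", "CE1"), ("HE2", "NE2")],
    "ASP": [("HB2", "CB"), ("HB3", "CB")],
    "ASN": [("HB2", "CB"), ("HB3", "CB"), ("HD21", "ND2"), ("HD22", "ND2")],
    "GLU": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG")],
    "GLN": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"), ("HE21", "NE2"), ("HE22", "NE2")],
    "LYS": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"), ("HD2", "CD"), ("HD3", "CD"), ("HE2", "CE"), ("HE3", "CE")]
    + [(f"HZ{i}", "NZ") for i in "123"],
    "ARG": [("HB2", "CB"), ("HB3", "CB"), ("HG2", "CG"), ("HG3", "CG"), ("HD2", "CD"), ("HD3", "CD"), ("HE", "NE"), ("HH11", "NH1"), ("HH12", "NH1"), ("HH21", "NH2"), ("HH22", "NH2")],
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    side_chain: tuple[ZEntry, ...]
    hydrogens: tuple[tuple[str, str], ...]
    closures: tuple[tuple[str, str], ...]

    @property
    def heavy_atoms(self) -> tuple[str, ...]:
        return ("N", "CA", "C", "O") + tuple(z.name for z in self.side_chain)

    @property
    def chi_names(self) -> tuple[str, ...]:
        """Rotatable side-chain torsions in order chi1, chi2, ..."""
        return tuple(z.chi for z in self.side_chain if z.chi is not None and z.offset == 0.0)

    def chi_atoms(self, chi: str) -> tuple[str, str, str, str]:
        """The four heavy atoms defining a chi torsion (IUPAC chain order)."""
        for z in self.side_chain:
            if z.chi == chi and z.offset == 0.0:
                return (z.a3, z.a2, z.a1, z.name)
        raise KeyError(f"{self.name} has no torsion {chi}")

    def atom_names(self) -> tuple[str, ...]:
        hs = ["H", "HA"] if self.name != "GLY" else ["H", "HA2", "HA3"]
        if self.name == "PRO":
            hs = ["HA"]
        return self.heavy_atoms + tuple(hs) + tuple(h for h, _ in self.hydrogens)


@dataclass(frozen=True)
class Topology:
    """Collection of residue templates plus backbone geometry constants."""

    residues: dict[str, ResidueTemplate] = field(default_factory=dict)
    backbone: dict[str, float] = field(default_factory=lambda: dict(BACKBONE))

    def template(self, resname: str) -> ResidueTemplate:
        try:
            return self.residues[resname]
        except KeyError:
            raise KeyError(f"unknown residue code {resname!r}") from None

    def __contains__(self, resname: str) -> bool:
        return resname in self.residues


def default_topology() -> Topology:
    residues = {
        name: ResidueTemplate(
            name,
            tuple(_SIDE[name]),
            tuple(_HYDROGENS[name]),
            tuple(_CLOSURES.get(name, ())),
        )
        for name in _SIDE
    }
    return Topology(residues=residues)
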