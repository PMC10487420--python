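"""Experimental restraint handling.

Reads the XPLOR/CNS ``assign`` dialect for NOE distance and dihedral restraint
tables, classifies NOEs by sequence separation, removes duplicates in the
spirit of the AQUA restraint-checking tool, and writes a CHARMM-style NOE
block.

Grammar accepted for NOE tables (``!`` starts a comment, case-insensitive)::

    assign (resid I and name X [and segid S]) (resid J and name Y) d dminus dplus
        [or (resid K and name Z) [(resid L and name W)]] ...

Each ``assign`` yields one restraint with bounds [d - dminus, d + dplus];
``or`` continuations append selections to the same (ambiguous) restraint: with
two selections they extend both sides, with one they extend the second side.
Atom-name wildcards (terminal ``#``, ``*`` or ``%``) are stored verbatim and
expanded against a model only at energy-evaluation time.

Dihedral tables use the XPLOR form::

    assign (sel1) (sel2) (sel3) (sel4) k theta0 delta ed

with exactly one atom per selection (wildcards are rejected).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import ParseError, RestraintConflictError
from .geometry import wrap_angle

__all__ = [
    "AtomSelection",
    "NOERestraint",
    "DihedralRestraintRec",
    "RestraintSet",
    "parse_xplor_noe",
    "parse_dihedral_table",
    "classify",
    "deduplicate",
    "write_charmm_noe",
    "parse_charmm_noe",
    "CATEGORIES",
]

CATEGORIES = ("intraresidual", "sequential", "medium", "long")

_WILDCARDS = ("#", "*", "%")


@dataclass(frozen=True)
class AtomSelection:
    residue_id: int
    atom_pattern: str
    segment: str | None = None

    def __post_init__(self):
        if not self.atom_pattern:
            raise ValueError("empty atom pattern")
        core = self.atom_pattern[:-1] if self.atom_pattern.endswith(_WILDCARDS) else self.atom_pattern
        if any(w in core for w in _WILDCARDS):
            raise ValueError(f"wildcard must be terminal in {self.atom_pattern!r}")

    @property
    def is_wildcard(self) -> bool:
        return self.atom_pattern.endswith(_WILDCARDS)

    def matches(self, name: str) -> bool:
        if self.is_wildcard:
            return name.startswith(self.atom_pattern[:-1])
        return name == self.atom_pattern


@dataclass
class NOERestraint:
    group_a: tuple[AtomSelection, ...]
    group_b: tuple[AtomSelection, ...]
    d: float
    dminus: float
    dplus: float
    source_line: int = 0

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError("empty selection group")
        if self.dminus < 0 or self.dplus < 0:
            raise ValueError("dminus/dplus must be nonnegative")
        if self.lower < 0:
            raise ValueError("negative lower bound")

    @property
    def lower(self) -> float:
        return self.d - self.dminus

    @property
    def upper(self) -> float:
        return self.d + self.dplus

    @property
    def category(self) -> str:
        return classify(self)


@dataclass
class DihedralRestraintRec:
    atoms: tuple[AtomSelection, AtomSelection, AtomSelection, AtomSelection]
    theta0: float
    delta: float
    k: float
    source_line: int = 0

    def __post_init__(self):
        if len(self.atoms) != 4:
            raise ValueError("dihedral restraint needs exactly 4 atoms")
        if any(a.is_wildcard for a in self.atoms):
            raise ValueError("wildcards not allowed in dihedral selections")
        self.theta0 = float(wrap_angle(self.theta0))
        if not (0.0 <= self.delta <= 180.0):
            raise ValueError("delta must be in [0, 180]")


@dataclass
class RestraintSet:
    noes: list[NOERestraint] = field(default_factory=list)
    dihedrals: list[DihedralRestraintRec] = field(default_factory=list)
    provenance: str = ""


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_SEL_RE = re.compile(
    r"\(\s*(?P<body>[^()]*)\s*\)",
)
_RESID_RE = re.compile(r"\bresid(?:ue)?\s+(-?\d+)", re.I)
_NAME_RE = re.compile(r"\bname\s+(\S+)", re.I)
_SEGID_RE = re.compile(r"\bsegid\s+(\S+)", re.I)
_NUM_RE = re.compile(r"-?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _strip_comments(text: str) -> list[tuple[int, str]]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        out.append((lineno, line.split("!")[0]))
    return out


def _parse_selection(body: str, lineno: int) -> AtomSelection:
    m_res = _RESID_RE.search(body)
    m_name = _NAME_RE.search(body)
    if m_res is None or m_name is None:
        raise ParseError(f"selection {body!r} needs 'resid N and name X'", lineno)
    m_seg = _SEGID_RE.search(body)
    try:
        return AtomSelection(
            residue_id=int(m_res.group(1)),
            atom_pattern=m_name.group(1).upper(),
            segment=m_seg.group(1) if m_seg else None,
        )
    except ValueError as e:
        raise ParseError(str(e), lineno) from None


def _statements(text: str) -> list[tuple[int, str]]:
    """Group physical lines into logical assign/or statements."""
    stmts: list[tuple[int, str]] = []
    current: list[str] = []
    start = 0
    for lineno, line in _strip_comments(text):
        token = line.strip().lower()
        if token.startswith("assign") or token.startswith("or"):
            if current:
                stmts.append((start, " ".join(current)))
            current = [line.strip()]
            start = lineno
        elif token:
            if current:
                current.append(line.strip())
            elif token:
                raise ParseError(f"unexpected text {line.strip()!r}", lineno)
    if current:
        stmts.append((start, " ".join(current)))
    return stmts


def parse_xplor_noe(text: str) -> list[NOERestraint]:
    """Parse an XPLOR/CNS NOE ``assign`` table into restraints."""
    restraints: list[NOERestraint] = []
    for lineno, stmt in _statements(text):
        low = stmt.lower()
        sels = [_parse_selection(m.group("body"), lineno) for m in _SEL_RE.finditer(stmt)]
        tail = _SEL_RE.sub("", stmt)
        nums = _NUM_RE.findall(tail.split(None, 1)[1] if len(tail.split(None, 1)) > 1 else "")
        if low.startswith("assign"):
            if len(sels) != 2:
                raise ParseError(
                    f"NOE assign needs exactly 2 selections, got {len(sels)}", lineno
                )
            if len(nums) < 3:
                raise ParseError("NOE assign needs d, dminus, dplus", lineno)
            d, dminus, dplus = (float(x) for x in nums[:3])
            if dminus < 0 or dplus < 0:
                raise ParseError("negative dminus/dplus", lineno)
            try:
                restraints.append(
                    NOERestraint((sels[0],), (sels[1],), d, dminus, dplus, source_line=lineno)
                )
            except ValueError as e:
                raise ParseError(str(e), lineno) from None
        elif low.startswith("or"):
            if not restraints:
                raise ParseError("'or' continuation before any assign", lineno)
            r = restraints[-1]
            if len(sels) == 2:
                restraints[-1] = replace(r, group_a=r.group_a + (sels[0],), group_b=r.group_b + (sels[1],))
            elif len(sels) == 1:
                restraints[-1] = replace(r, group_b=r.group_b + (sels[0],))
            else:
                raise ParseError("'or' continuation needs 1 or 2 selections", lineno)
    return restraints


def parse_dihedral_table(text: str) -> list[DihedralRestraintRec]:
    """Parse an XPLOR dihedral restraint table."""
    records: list[DihedralRestraintRec] = []
    for lineno, stmt in _statements(text):
        if not stmt.lower().startswith("assign"):
            raise ParseError("dihedral tables do not take 'or' continuations", lineno)
        sels = [_parse_selection(m.group("body"), lineno) for m in _SEL_RE.finditer(stmt)]
        if len(sels) != 4:
            raise ParseError(f"dihedral assign needs 4 selections, got {len(sels)}", lineno)
        tail = _SEL_RE.sub("", stmt)
        nums = _NUM_RE.findall(tail.split(None, 1)[1] if len(tail.split(None, 1)) > 1 else "")
        if len(nums) < 3:
            raise ParseError("dihedral assign needs k, theta0, delta", lineno)
        k, theta0, delta = (float(x) for x in nums[:3])
        try:
            records.append(
                DihedralRestraintRec(tuple(sels), theta0=theta0, delta=delta, k=k, source_line=lineno)
            )
        except ValueError as e:
            raise ParseError(str(e), lineno) from None
    return records


# ---------------------------------------------------------------------------
# Classification and deduplication
# ---------------------------------------------------------------------------


def classify(restraint: NOERestraint, mode: str = "min") -> str:
    """Sequence-separation category of an NOE restraint.

    The separation is the minimum (or maximum, ``mode='max'``) |resid_a -
    resid_b| over all selection pairs; 0 -> intraresidual, 1 -> sequential,
    2-4 -> medium, >=5 -> long.
    """
    seps = [
        abs(a.residue_id - b.residue_id)
        for a in restraint.group_a
        for b in restraint.group_b
    ]
    s = min(seps) if mode == "min" else max(seps)
    if s == 0:
        return "intraresidual"
    if s == 1:
        return "sequential"
    if s <= 4:
        return "medium"
    return "long"


def _sel_key(sel: AtomSelection):
    return (sel.residue_id, sel.atom_pattern, sel.segment)


def _restraint_key(r: NOERestraint):
    a = frozenset(_sel_key(s) for s in r.group_a)
    b = frozenset(_sel_key(s) for s in r.group_b)
    return frozenset((a, b))


def deduplicate(restraints: list[NOERestraint], mode: str = "tightest") -> list[NOERestraint]:
    """Merge restraints with identical selection sets (side-swap insensitive).

    ``mode='tightest'`` keeps the tightest bounds (max lower, min upper);
    ``'first'`` keeps the first occurrence; ``'error'`` raises on any
    duplicate.  A tightest-merge whose bounds cross raises
    :class:`RestraintConflictError`.
    """
    if mode not in ("tightest", "first", "error"):
        raise ValueError(f"unknown deduplication mode {mode!r}")
    out: list[NOERestraint] = []
    index: dict = {}
    for r in restraints:
        key = _restraint_key(r)
        if key not in index:
            index[key] = len(out)
            out.append(r)
            continue
        if mode == "first":
            continue
        if mode == "error":
            raise RestraintConflictError(
                f"duplicate restraint at lines {out[index[key]].source_line} and {r.source_line}"
            )
        prev = out[index[key]]
        lower = max(prev.lower, r.lower)
        upper = min(prev.upper, r.upper)
        if lower > upper + 1e-9:
            raise RestraintConflictError(
                f"conflicting duplicate bounds at lines {prev.source_line} and {r.source_line}: "
                f"[{prev.lower:.3f}, {prev.upper:.3f}] vs [{r.lower:.3f}, {r.upper:.3f}]"
            )
        d = prev.d if lower <= prev.d <= upper else 0.5 * (lower + upper)
        out[index[key]] = replace(prev, d=d, dminus=d - lower, dplus=upper - d)
    return out


# ---------------------------------------------------------------------------
# XPLOR-dialect writers (used for fixtures and export)
# ---------------------------------------------------------------------------


def _xplor_sel(s: AtomSelection) -> str:
    seg = f" and segid {s.segment}" if s.segment else ""
    return f"(resid {s.residue_id} and name {s.atom_pattern}{seg})"


def write_xplor_noe(restraints: list[NOERestraint]) -> str:
    """Emit an XPLOR/CNS NOE table that :func:`parse_xplor_noe` inverts."""
    lines = ["! NOE distance restraints (XPLOR/CNS dialect)"]
    for r in restraints:
        lines.append(
            f"assign {_xplor_sel(r.group_a[0])} {_xplor_sel(r.group_b[0])} "
            f"{r.d:.3f} {r.dminus:.3f} {r.dplus:.3f}"
        )
        extra_a = r.group_a[1:]
        extra_b = r.group_b[1:]
        for k in range(max(len(extra_a), len(extra_b))):
            if k < len(extra_a) and k < len(extra_b):
                lines.append(f"  or {_xplor_sel(extra_a[k])} {_xplor_sel(extra_b[k])}")
            elif k < len(extra_b):
                lines.append(f"  or {_xplor_sel(extra_b[k])}")
            else:  # a-side surplus pairs with the primary b selection
                lines.append(f"  or {_xplor_sel(extra_a[k])} {_xplor_sel(r.group_b[0])}")
    return "\n".join(lines) + "\n"


def write_xplor_dihedral(dihedrals: list[DihedralRestraintRec]) -> str:
    """Emit an XPLOR dihedral table that :func:`parse_dihedral_table` inverts."""
    lines = ["! dihedral restraints (XPLOR dialect)"]
    for d in dihedrals:
        sels = " ".join(_xplor_sel(s) for s in d.atoms)
        lines.append(f"assign {sels} {d.k:.4f} {d.theta0:.3f} {d.delta:.3f} 2")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CHARMM NOE block dialect
# ---------------------------------------------------------------------------


def _format_sel(group: tuple[AtomSelection, ...]) -> str:
    parts = [
        f"(ATOM {s.segment or 'PROT'} {s.residue_id} {s.atom_pattern})" for s in group
    ]
    return "SELE " + " .OR. ".join(parts) + " END"


_CH_ATOM_RE = re.compile(r"\(ATOM\s+(\S+)\s+(-?\d+)\s+(\S+)\)", re.I)
_CH_SELE_RE = re.compile(r"SELE\s+(.*?)\s+END", re.I)


def write_charmm_noe(restraints: RestraintSet, params=None) -> str:
    """Emit a CHARMM-style NOE block (one ASSIGN per restraint).

    RMIN/RMAX carry the lower/upper bounds; KMIN/KMAX the harmonic force
    constant; FMAX the maximum asymptotic force.  The numeric format is 3
    decimals, and :func:`parse_charmm_noe` inverts the writer exactly at that
    precision.
    """
    k = getattr(params, "k_noe", 1.0)
    fmax = getattr(params, "f_max", 2.0 * k * getattr(params, "r_switch", 1.0))
    lines = ["NOE", "RESET"]
    for r in restraints.noes:
        lines.append(
            f"ASSIGN {_format_sel(r.group_a)} {_format_sel(r.group_b)} -"
        )
        lines.append(
            f"    KMIN {k:.3f} RMIN {r.lower:.3f} KMAX {k:.3f} RMAX {r.upper:.3f} FMAX {fmax:.3f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def parse_charmm_noe(text: str) -> list[NOERestraint]:
    """Parse the NOE block dialect produced by :func:`write_charmm_noe`."""
    restraints: list[NOERestraint] = []
    logical: list[tuple[int, str]] = []
    pending: str | None = None
    pending_line = 0
    for lineno, raw in _strip_comments(text):
        line = raw.strip()
        if not line or line.upper() in ("NOE", "RESET", "END"):
            continue
        if pending is not None:
            logical.append((pending_line, pending.rstrip("-").rstrip() + " " + line))
            pending = None
            continue
        if line.endswith("-"):
            pending = line
            pending_line = lineno
            continue
        logical.append((lineno, line))
    if pending is not None:
        raise ParseError("dangling continuation", pending_line)
    for lineno, stmt in logical:
        if not stmt.upper().startswith("ASSIGN"):
            raise ParseError(f"unexpected statement {stmt[:30]!r}", lineno)
        sels = _CH_SELE_RE.findall(stmt)
        if len(sels) != 2:
            raise ParseError("ASSIGN needs two SELE ... END groups", lineno)
        groups = []
        for body in sels:
            atoms = _CH_ATOM_RE.findall(body)
            if not atoms:
                raise ParseError("empty SELE group", lineno)
            groups.append(
                tuple(
                    AtomSelection(residue_id=int(res), atom_pattern=name.upper(), segment=seg)
                    for seg, res, name in atoms
                )
            )
        m_rmin = re.search(r"RMIN\s+(-?\d+\.?\d*)", stmt, re.I)
        m_rmax = re.search(r"RMAX\s+(-?\d+\.?\d*)", stmt, re.I)
        if not (m_rmin and m_rmax):
            raise ParseError("ASSIGN needs RMIN and RMAX", lineno)
        lower = float(m_rmin.group(1))
        upper = float(m_rmax.group(1))
        d = 0.5 * (lower + upper)
        restraints.append(
            NOERestraint(groups[0], groups[1], d, d - lower, upper - d, source_line=lineno)
        )
    return restraints
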