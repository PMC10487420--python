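"""Simulated-annealing refinement by Metropolis Monte Carlo in torsion space.

The schedule is heat / hold / cool: the system is heated from 100 to 1000
(reduced temperature units labeled in kelvin) over 3200 steps, held at 1000
for 4000 steps, and relaxed from 1000 to 25 over 8000 steps.  Because the
energy is dimensionless, temperature enters only through the ratio T/T_high:
at the hold plateau the Metropolis acceptance is exp(-dE), and cooling sharpens
it by a factor of up to 40.

A Monte Carlo move perturbs one randomly chosen rotatable torsion (phi, psi
and side-chain chi angles; omega is frozen at its current value by default)
with Gaussian noise and rotates the downstream part of the chain rigidly, which
is exactly equivalent to rebuilding from the updated torsion set but costs one
small matrix multiply.  Acceptance follows the Metropolis rule
min(1, exp(-dE * T_ref / T)) with T_ref = T_high, and every run is a pure
function of (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import EnergyBreakdown, EnergyEvaluator, NOEParams, STAPTable, Weights
from .errors import ConfigError
from .geometry import rotation_about_axis, wrap_angle
from .restraints import RestraintSet
from .structures import Ensemble, StructureModel, TorsionSet, bond_graph, torsions_of
from .topology import Topology, default_topology

__all__ = [
    "Schedule",
    "MoveSet",
    "RefinementResult",
    "temperature_at",
    "mc_step",
    "refine_model",
    "refine_ensemble",
    "Refinement",
]

TRACE_COLUMNS = ["step", "T", "E_stereo", "E_solv", "E_exp_noe", "E_exp_dihe", "E_stap", "E_tot", "accepted"]


@dataclass(frozen=True)
class Schedule:
    T_start: float = 100.0
    T_high: float = 1000.0
    T_end: float = 25.0
    heat_steps: int = 3200
    hold_steps: int = 4000
    cool_steps: int = 8000

    def __post_init__(self):
        if min(self.heat_steps, self.hold_steps, self.cool_steps) <= 0:
            raise ConfigError("all phase step counts must be positive")
        if min(self.T_start, self.T_high, self.T_end) <= 0:
            raise ConfigError("temperatures must be positive")

    @property
    def total_steps(self) -> int:
        return self.heat_steps + self.hold_steps + self.cool_steps


@dataclass(frozen=True)
class MoveSet:
    sigma: float = 8.0  # Gaussian torsion perturbation, degrees
    moves_per_step: int = 1
    backbone: bool = True
    side_chain: bool = True
    freeze_omega: bool = True

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.moves_per_step < 1:
            raise ConfigError("moves_per_step must be >= 1")


def temperature_at(step: int, schedule: Schedule) -> float:
    """Temperature at an integer step: linear heat, constant hold, linear cool.

    Step 0 is exactly T_start; every hold step is exactly T_high; the final
    step is exactly T_end.
    """
    s = schedule
    if not 0 <= step < s.total_steps:
        raise ValueError(f"step {step} outside schedule of {s.total_steps} steps")
    if step < s.heat_steps:
        return s.T_start + (s.T_high - s.T_start) * step / s.heat_steps
    if step < s.heat_steps + s.hold_steps:
        return s.T_high
    frac = (step - s.heat_steps - s.hold_steps + 1) / s.cool_steps
    return s.T_high + (s.T_end - s.T_high) * frac


def mc_step(
    torsions: TorsionSet,
    energy_fn,
    T: float,
    moveset: MoveSet,
    rng: np.random.Generator,
    t_ref: float = 1000.0,
) -> tuple[TorsionSet, bool]:
    """One generic Metropolis step on a torsion set.

    ``energy_fn`` maps a TorsionSet to a scalar energy; acceptance probability
    is min(1, exp(-dE * t_ref / T)).  The caller owns the rng, so a fixed seed
    fixes the trajectory.
    """
    keys = _movable_keys(torsions, moveset)
    if not keys:
        return torsions, False
    e0 = energy_fn(torsions)
    proposal = torsions.copy()
    for _ in range(moveset.moves_per_step):
        key = keys[rng.integers(len(keys))]
        proposal[key] = wrap_angle(proposal[key] + rng.normal(0.0, moveset.sigma))
    e1 = energy_fn(proposal)
    if _metropolis_accept(e1 - e0, T, t_ref, rng):
        return proposal, True
    return torsions, False


def _movable_keys(torsions: TorsionSet, moveset: MoveSet) -> list:
    keys = []
    for key in sorted(torsions):
        name = key[1]
        if name == "omega":
            if not moveset.freeze_omega:
                keys.append(key)
        elif name in ("phi", "psi"):
            if moveset.backbone:
                keys.append(key)
        elif moveset.side_chain:
            keys.append(key)
    return keys


def _metropolis_accept(dE: float, T: float, t_ref: float, rng: np.random.Generator) -> bool:
    if dE <= 0:
        rng.random()  # keep the rng stream aligned across branches
        return True
    return rng.random() < math.exp(-dE * t_ref / max(T, 1e-12))


@dataclass
class RefinementResult:
    """Outcome of one simulated-annealing run."""

    final_model: StructureModel
    best_model: StructureModel
    energy_trace: pd.DataFrame
    acceptance_rate: float
    seed: int
    initial_energy: EnergyBreakdown = None
    final_energy: EnergyBreakdown = None
    best_energy: EnergyBreakdown = None
    n_violations_initial: int = 0
    n_violations_best: int = 0

    def __post_init__(self):
        if self.best_energy is not None and self.final_energy is not None:
            assert self.best_energy.E_tot <= self.final_energy.E_tot + 1e-9

    def phase_acceptance(self, schedule: Schedule | None = None) -> dict[str, float]:
        """Acceptance rate per schedule phase, from the energy trace."""
        s = schedule or Schedule()
        acc = self.energy_trace["accepted"].to_numpy()
        h, d = s.heat_steps, s.hold_steps
        return {
            "heat": float(acc[:h].mean()),
            "hold": float(acc[h:h + d].mean()),
            "cool": float(acc[h + d:].mean()),
        }

    def summary(self) -> str:
        rows = [
            ("E_tot", self.initial_energy.E_tot, self.best_energy.E_tot),
            ("E_stereo", self.initial_energy.E_stereo, self.best_energy.E_stereo),
            ("E_solv", self.initial_energy.E_solv, self.best_energy.E_solv),
            ("E_exp_noe", self.initial_energy.E_exp_noe, self.best_energy.E_exp_noe),
            ("E_exp_dihe", self.initial_energy.E_exp_dihe, self.best_energy.E_exp_dihe),
            ("E_stap", self.initial_energy.E_stap, self.best_energy.E_stap),
        ]
        lines = [
            "Simulated-annealing refinement",
            "==============================",
            f"seed: {self.seed}   steps: {len(self.energy_trace)}   "
            f"acceptance rate: {self.acceptance_rate:.3f}",
            f"NOE restraints violated (start -> best): "
            f"{self.n_violations_initial} -> {self.n_violations_best}",
            "",
            f"{'term':<12}{'initial':>12}{'best':>12}",
        ]
        for name, a, b in rows:
            lines.append(f"{name:<12}{a:>12.3f}{b:>12.3f}")
        return "\n".join(lines)


class _TorsionMover:
    """Precompiled rotatable torsions of a model: axis atoms and moving sets."""

    def __init__(self, model: StructureModel, topology: Topology, moveset: MoveSet):
        adj = bond_graph(model, topology)
        tset = torsions_of(model, topology)
        moves: list[tuple[tuple, int, int, np.ndarray]] = []
        for key in sorted(_movable_keys(tset, moveset)):
            res_idx, name = key
            quad = _torsion_atoms(model, topology, res_idx, name)
            if quad is None:
                continue
            _, b, c, _ = quad
            moving = _downstream(adj, b, c)
            if moving is None or len(moving) == 0:
                continue  # cyclic (e.g. proline ring) or degenerate
            moves.append((key, b, c, np.fromiter(moving, dtype=int)))
        self.moves = moves

    def __len__(self) -> int:
        return len(self.moves)


def _torsion_atoms(model: StructureModel, topology: Topology, res_idx: int, name: str):
    res = model.residues[res_idx]
    reslist = model.residues

    def ai(r, nm):
        return model.atom_index(r.index, nm)

    if name == "phi":
        if res_idx == 0:
            return None
        prev = reslist[res_idx - 1]
        quad = (ai(prev, "C"), ai(res, "N"), ai(res, "CA"), ai(res, "C"))
    elif name == "psi":
        quad = (ai(res, "N"), ai(res, "CA"), ai(res, "C"), ai(res, "O"))
    elif name == "omega":
        if res_idx == 0:
            return None
        prev = reslist[res_idx - 1]
        quad = (ai(prev, "CA"), ai(prev, "C"), ai(res, "N"), ai(res, "CA"))
    else:
        tmpl = topology.template(res.name)
        if name not in tmpl.chi_names:
            return None
        quad = tuple(ai(res, nm) for nm in tmpl.chi_atoms(name))
    return None if any(q is None for q in quad) else quad


def _downstream(adj: list[set[int]], b: int, c: int):
    """Atoms on the c-side when bond b-c is cut; None if b and c stay connected."""
    seen = {c}
    frontier = [c]
    while frontier:
        nxt = []
        for i in frontier:
            for j in adj[i]:
                if i == c and j == b:
                    continue
                if j not in seen:
                    if j == b:
                        return None
                    seen.add(j)
                    nxt.append(j)
        frontier = nxt
    seen.discard(c)
    return seen


def refine_model(
    model: StructureModel,
    restraints: RestraintSet,
    tables: list[STAPTable] | None = None,
    weights: Weights | None = None,
    params: NOEParams | None = None,
    schedule: Schedule | None = None,
    moveset: MoveSet | None = None,
    seed: int = 0,
    topology: Topology | None = None,
) -> RefinementResult:
    """Anneal one model under the heat/hold/cool schedule; fully deterministic
    per seed.  Returns the final and the best-by-E_tot structures plus the full
    per-step energy trace."""
    topology = topology or default_topology()
    schedule = schedule or Schedule()
    moveset = moveset or MoveSet()
    ev = EnergyEvaluator(model, restraints, tables, weights, params, topology)
    mover = _TorsionMover(model, topology, moveset)
    if len(mover) == 0:
        raise ConfigError("no rotatable torsions available for the move set")
    rng = np.random.default_rng(seed)

    coords = np.ascontiguousarray(model.coords)
    energy = ev.evaluate(coords)
    initial_energy = energy
    best_coords = coords.copy()
    best_energy = energy
    n_accept = 0
    total = schedule.total_steps
    trace = np.empty((total, 9))

    for step in range(total):
        T = temperature_at(step, schedule)
        saved = []
        for _ in range(moveset.moves_per_step):
            key, b, c, moving = mover.moves[rng.integers(len(mover.moves))]
            delta = rng.normal(0.0, moveset.sigma)
            axis = coords[c] - coords[b]
            R, t = rotation_about_axis(coords[c], axis, delta)
            saved.append((moving, coords[moving].copy()))
            coords[moving] = coords[moving] @ R.T + t
        proposal = ev.evaluate(coords)
        accepted = _metropolis_accept(proposal.E_tot - energy.E_tot, T, schedule.T_high, rng)
        if accepted:
            energy = proposal
            n_accept += 1
            if energy.E_tot < best_energy.E_tot:
                best_energy = energy
                best_coords = coords.copy()
        else:
            for moving, old in reversed(saved):
                coords[moving] = old
        trace[step] = (
            step, T, energy.E_stereo, energy.E_solv, energy.E_exp_noe,
            energy.E_exp_dihe, energy.E_stap, energy.E_tot, float(accepted),
        )

    final_model = model.copy()
    final_model.set_coords(coords)
    best_model = model.copy()
    best_model.set_coords(best_coords)
    df = pd.DataFrame(trace, columns=TRACE_COLUMNS)
    df["step"] = df["step"].astype(int)
    df["accepted"] = df["accepted"].astype(bool)

    def _nviol(c):
        if len(ev._noe_starts) == 0:
            return 0
        r = ev.noe_distances(c)
        return int(np.sum(r > ev._noe_upper))

    return RefinementResult(
        final_model=final_model,
        best_model=best_model,
        energy_trace=df,
        acceptance_rate=n_accept / total,
        seed=seed,
        initial_energy=initial_energy,
        final_energy=energy,
        best_energy=best_energy,
        n_violations_initial=_nviol(np.ascontiguousarray(model.coords)),
        n_violations_best=_nviol(best_coords),
    )


def refine_ensemble(
    ensemble: Ensemble,
    restraints: RestraintSet,
    tables: list[STAPTable] | None = None,
    weights: Weights | None = None,
    params: NOEParams | None = None,
    schedule: Schedule | None = None,
    moveset: MoveSet | None = None,
    base_seed: int = 0,
    topology: Topology | None = None,
) -> tuple[list[RefinementResult], int]:
    """Refine every ensemble member (seed = base_seed + model index) and pick
    the representative: lexicographic minimum of (violated-restraint count,
    E_tot) over the best models."""
    results = [
        refine_model(m, restraints, tables, weights, params, schedule, moveset,
                     seed=base_seed + i, topology=topology)
        for i, m in enumerate(ensemble.models)
    ]
    rep = min(
        range(len(results)),
        key=lambda i: (results[i].n_violations_best, results[i].best_energy.E_tot),
    )
    return results, rep


class Refinement:
    """Model-object facade: bundle data and configuration, then ``fit()``.

    ``Refinement(model_or_ensemble, restraints, ...).fit(seed)`` runs the
    annealer and returns a :class:`RefinementResult` (or a list of results and
    a representative index for an ensemble).
    """

    def __init__(
        self,
        structure: StructureModel | Ensemble,
        restraints: RestraintSet,
        tables: list[STAPTable] | None = None,
        weights: Weights | None = None,
        params: NOEParams | None = None,
        schedule: Schedule | None = None,
        moveset: MoveSet | None = None,
        topology: Topology | None = None,
    ):
        self.structure = structure
        self.restraints = restraints
        self.tables = tables
        self.weights = weights
        self.params = params
        self.schedule = schedule
        self.moveset = moveset
        self.topology = topology

    def fit(self, seed: int = 0):
        args = (self.restraints, self.tables, self.weights, self.params,
                self.schedule, self.moveset)
        if isinstance(self.structure, Ensemble):
            return refine_ensemble(self.structure, *args, base_seed=seed, topology=self.topology)
        return refine_model(self.structure, *args, seed=seed, topology=self.topology)
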