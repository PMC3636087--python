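"""Sequence optimization over designed positions against energy tables.

The design engine replaces a full-atom scoring function with a pluggable
per-state energy table contract: each structural state (one antibody/antigen
complex) contributes ``E(column, amino acid)`` in REU-like units, with an
optional pairwise coupling term. Single-state design minimizes one state's
energy; multi-state design minimizes the unweighted sum across all states,
threading the identical sequence through every state via the alignment
correspondence. The optimizer is Metropolis simulated annealing over
single-position substitutions with a geometric temperature schedule,
finished by a deterministic greedy quench to a local optimum (the global
optimum whenever tables are additive). ``n_trajectories`` independent runs
(default 100, seeded ``base_seed + i``) form a :class:`DesignEnsemble`.

:func:`enumerate_exact` provides an independent brute-force/closed-form
oracle for small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS, N_AA


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class StateEnergyTable:
    """Per-position, per-amino-acid energies for one state.

    ``energies[i, a]`` is the energy of amino acid ``AMINO_ACIDS[a]`` at the
    designed column ``columns[i]``. ``pairwise[(i, j)]`` (i < j, positional
    indices) optionally couples two columns with a 20x20 matrix.
    """

    state_id: str
    columns: tuple[int, ...]
    energies: np.ndarray
    pairwise: Mapping[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (len(self.columns), N_AA):
            raise DesignError(
                f"energy table for {self.state_id!r} must be "
                f"({len(self.columns)}, {N_AA}); got {e.shape}"
            )
        if not np.all(np.isfinite(e)):
            raise DesignError(f"non-finite energies in state {self.state_id!r}")
        object.__setattr__(self, "energies", e)
        for (i, j), m in self.pairwise.items():
            if not (0 <= i < j < len(self.columns)):
                raise DesignError(f"bad pairwise index pair {(i, j)}")
            if np.asarray(m).shape != (N_AA, N_AA):
                raise DesignError("pairwise terms must be 20x20")

    def energy_of(self, seq_idx: np.ndarray) -> float:
        """Table energy of a sequence given as amino-acid indices."""
        total = float(self.energies[np.arange(len(self.columns)), seq_idx].sum())
        for (i, j), m in self.pairwise.items():
            total += float(m[seq_idx[i], seq_idx[j]])
        return total


@dataclass(frozen=True)
class DesignTask:
    columns: tuple[int, ...]
    states: tuple[StateEnergyTable, ...]
    mode: str  # "single" | "multi"
    target_state: str | None = None
    n_trajectories: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multi"):
            raise DesignError(f"unknown mode {self.mode!r}")
        if self.mode == "multi" and len(self.states) < 2:
            raise DesignError("multi-state design requires >=2 states")
        if self.mode == "single":
            if self.target_state is None:
                raise DesignError("single-state design requires target_state")
            if self.target_state not in {s.state_id for s in self.states}:
                raise DesignError(f"unknown target state {self.target_state!r}")
        for s in self.states:
            if s.columns != self.columns:
                raise DesignError(
                    f"state {s.state_id!r} columns differ from the task's"
                )

    @property
    def active_states(self) -> tuple[StateEnergyTable, ...]:
        if self.mode == "single":
            return tuple(s for s in self.states if s.state_id == self.target_state)
        return self.states

    @property
    def has_pairwise(self) -> bool:
        return any(s.pairwise for s in self.active_states)

    def combined_table(self) -> np.ndarray:
        """Summed additive table of the active states."""
        return np.sum([s.energies for s in self.active_states], axis=0)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric Metropolis schedule; all knobs config-overridable."""

    t_start: float = 5.0
    t_end: float = 0.05
    n_rungs: int = 30
    steps_per_rung_per_column: int = 50
    quench_max_sweeps: int = 20

    def temperatures(self) -> np.ndarray:
        ratio = (self.t_end / self.t_start) ** (1.0 / (self.n_rungs - 1))
        return self.t_start * ratio ** np.arange(self.n_rungs)


@dataclass(frozen=True)
class DesignEnsemble:
    columns: tuple[int, ...]
    sequences: tuple[str, ...]
    fitnesses: tuple[float, ...]
    mode: str
    state_ids: tuple[str, ...]
    base_seed: int

    def __post_init__(self) -> None:
        n = len(self.columns)
        if any(len(s) != n for s in self.sequences):
            raise DesignError("ensemble sequences must cover all designed columns")

    @property
    def n(self) -> int:
        return len(self.sequences)


def seq_to_idx(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as exc:
        raise DesignError(f"unknown amino acid {exc.args[0]!r}") from exc


def idx_to_seq(idx: Iterable[int]) -> str:
    return "".join(AMINO_ACIDS[i] for i in idx)


def fitness(seq: str, task: DesignTask) -> float:
    """Design fitness: target-state energy (single) or summed energy (multi)."""
    if len(seq) != len(task.columns):
        raise DesignError(
            f"sequence length {len(seq)} != {len(task.columns)} designed columns"
        )
    idx = seq_to_idx(seq)
    return float(sum(s.energy_of(idx) for s in task.active_states))


def _quench_additive(seq: np.ndarray, table: np.ndarray) -> np.ndarray:
    # per-column argmin; independent columns, so one pass suffices
    seq = seq.copy()
    seq[:] = np.argmin(table, axis=1)[None, :]
    return seq


def _local_energy(states, pos: int, idx: np.ndarray) -> float:
    e = 0.0
    for s in states:
        e += float(s.energies[pos, idx[pos]])
        for (i, j), m in s.pairwise.items():
            if i == pos or j == pos:
                e += float(m[idx[i], idx[j]])
    return e


def _anneal_pairwise(task: DesignTask, schedule: AnnealSchedule, rng) -> np.ndarray:
    n_cols = len(task.columns)
    states = task.active_states
    idx = rng.integers(0, N_AA, size=n_cols)
    steps = schedule.steps_per_rung_per_column * n_cols
    for t in schedule.temperatures():
        cols = rng.integers(0, n_cols, size=steps)
        offs = rng.integers(1, N_AA, size=steps)
        us = rng.random(size=steps)
        for pos, off, u in zip(cols, offs, us):
            old = idx[pos]
            new = (old + off) % N_AA
            e_old = _local_energy(states, pos, idx)
            idx[pos] = new
            e_new = _local_energy(states, pos, idx)
            delta = e_new - e_old
            if delta > 0 and u >= math.exp(-delta / t):
                idx[pos] = old
    # greedy quench to a local optimum
    for _ in range(schedule.quench_max_sweeps):
        changed = False
        for pos in range(n_cols):
            best, best_e = idx[pos], _local_energy(states, pos, idx)
            for a in range(N_AA):
                idx[pos] = a
                e = _local_energy(states, pos, idx)
                if e < best_e:
                    best, best_e = a, e
            if idx[pos] != best:
                changed = True
            idx[pos] = best
        if not changed:
            break
    return idx


def design(task: DesignTask, schedule: AnnealSchedule | None = None) -> DesignEnsemble:
    """Run ``n_trajectories`` independent annealing trajectories.

    Trajectory ``i`` draws all of its randomness from a generator seeded
    ``base_seed + i``, so reruns with the same base seed are bit-identical.
    Additive tasks are run vectorized across trajectories; the per-trajectory
    random streams are identical either way.
    """
    schedule = schedule or AnnealSchedule()
    n_cols = len(task.columns)
    n_traj = task.n_trajectories
    rngs = [np.random.default_rng(task.base_seed + i) for i in range(n_traj)]

    if task.has_pairwise:
        seqs = np.stack([_anneal_pairwise(task, schedule, rng) for rng in rngs])
    else:
        table = task.combined_table()
        steps = schedule.steps_per_rung_per_column * n_cols
        seqs = np.stack([rng.integers(0, N_AA, size=n_cols) for rng in rngs])
        rows = np.arange(n_traj)
        for t in schedule.temperatures():
            cols = np.stack([rng.integers(0, n_cols, size=steps) for rng in rngs])
            offs = np.stack([rng.integers(1, N_AA, size=steps) for rng in rngs])
            us = np.stack([rng.random(size=steps) for rng in rngs])
            for s in range(steps):
                c = cols[:, s]
                old = seqs[rows, c]
                new = (old + offs[:, s]) % N_AA
                delta = table[c, new] - table[c, old]
                accept = (delta <= 0) | (us[:, s] < np.exp(-np.maximum(delta, 0) / t))
                seqs[rows, c] = np.where(accept, new, old)
            seqs = seqs.astype(np.intp)
        seqs = _quench_additive(seqs, table)

    sequences = tuple(idx_to_seq(s) for s in seqs)
    # fitness recomputed exactly from the tables, never accumulated
    fits = tuple(fitness(s, task) for s in sequences)
    return DesignEnsemble(
        columns=task.columns,
        sequences=sequences,
        fitnesses=fits,
        mode=task.mode,
        state_ids=tuple(s.state_id for s in task.active_states),
        base_seed=task.base_seed,
    )


@dataclass(frozen=True)
class ExactResult:
    sequence: str
    fitness: float
    tie: bool


def enumerate_exact(task: DesignTask, max_size: int = 10**7) -> ExactResult:
    """Global optimum by closed form (additive) or brute force (pairwise).

    Additive tables factorize per column, so the optimum is the per-column
    argmin regardless of instance size. With pairwise terms the full
    ``20^n`` space is enumerated and must not exceed ``max_size``. Ties are
    broken toward the lexicographically smaller sequence and flagged.
    """
    n_cols = len(task.columns)
    if not task.has_pairwise:
        table = task.combined_table()
        idx = np.argmin(table, axis=1)
        mins = table[np.arange(n_cols), idx]
        tie = bool(np.any(np.sum(np.isclose(table, mins[:, None], atol=0.0), axis=1) > 1))
        return ExactResult(idx_to_seq(idx), float(mins.sum()), tie)
    if N_AA**n_cols > max_size:
        raise DesignError(
            f"instance of size 20^{n_cols} exceeds the enumeration bound"
        )
    best_idx = None
    best_e = math.inf
    tie = False
    for combo in np.ndindex(*([N_AA] * n_cols)):
        idx = np.array(combo, dtype=np.intp)
        e = float(sum(s.energy_of(idx) for s in task.active_states))
        if e < best_e:
            best_idx, best_e, tie = idx, e, False
        elif e == best_e:
            tie = True  # lexicographic order of ndindex keeps the smaller
    return ExactResult(idx_to_seq(best_idx), best_e, tie)


# ---------------------------------------------------------------------------
# I/O: TSV energy tables and FASTA/TSV ensembles
# ---------------------------------------------------------------------------

def read_energy_tables(path: str | Path) -> list[StateEnergyTable]:
    """Read a ``state<TAB>column<TAB>aa<TAB>energy`` table (one or many states)."""
    df = pd.read_csv(path, sep="\t")
    required = {"state", "column", "aa", "energy"}
    if not required.issubset(df.columns):
        raise DesignError(f"{path}: energy TSV needs columns {sorted(required)}")
    tables = []
    for state_id, group in df.groupby("state", sort=True):
        cols = tuple(sorted(group["column"].unique()))
        e = np.full((len(cols), N_AA), np.nan)
        cpos = {c: i for i, c in enumerate(cols)}
        for _, row in group.iterrows():
            aa = str(row["aa"])
            if aa not in AA_INDEX:
                raise DesignError(f"unknown amino acid {aa!r} in {path}")
            e[cpos[int(row["column"])], AA_INDEX[aa]] = float(row["energy"])
        if np.isnan(e).any():
            raise DesignError(
                f"{path}: state {state_id!r} does not cover all 20 amino acids "
                "at every designed column"
            )
        tables.append(StateEnergyTable(state_id=str(state_id), columns=cols, energies=e))
    return tables


def write_energy_table(table: StateEnergyTable, path: str | Path) -> None:
    rows = [
        (table.state_id, col, AMINO_ACIDS[a], table.energies[i, a])
        for i, col in enumerate(table.columns)
        for a in range(N_AA)
    ]
    pd.DataFrame(rows, columns=["state", "column", "aa", "energy"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_ensemble(ensemble: DesignEnsemble, fasta_path: str | Path,
                   fitness_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for i, seq in enumerate(ensemble.sequences):
            fh.write(f">traj{i}\n{seq}\n")
    if fitness_path is not None:
        pd.DataFrame(
            {"trajectory": [f"traj{i}" for i in range(ensemble.n)],
             "fitness": ensemble.fitnesses}
        ).to_csv(fitness_path, sep="\t", index=False, float_format="%.6f")


def read_ensemble(fasta_path: str | Path, columns: Sequence[int],
                  mode: str = "multi", state_ids: Sequence[str] = (),
                  base_seed: int = 0) -> DesignEnsemble:
    from Bio import SeqIO

    seqs = tuple(str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta"))
    return DesignEnsemble(
        columns=tuple(columns),
        sequences=seqs,
        fitnesses=tuple(math.nan for _ in seqs),
        mode=mode,
        state_ids=tuple(state_ids),
        base_seed=base_seed,
    )
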