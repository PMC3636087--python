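"""Synthetic antibody/antigen ensembles with planted ground truth.

The generator emulates the statistical structure of a germline-gene test
set without any real structures or a physical energy function. One bundle
holds, for ``n_states`` toy antibody/antigen complexes sharing a germline:

* a gapless MSA (germline + one mature heavy-chain sequence per state),
  with a maturation gradient (``mutations_min``..``mutations_max`` somatic
  mutations across states);
* per-state additive energy tables over the designed columns, planting
  three position classes: flexibility positions (``flex``: the germline
  residue is the energy optimum in every state, margin ``g_flex``),
  specificity positions (``spec``: each mutated state's own mature residue
  is optimal in that state by construction, germline second at ``g_spec``;
  a small ``shared`` subset instead penalizes germline by
  ``shared_penalty`` REU in every state), and neutral positions
  (``neutral``: a tolerated set of residues within a fraction of an REU of
  one another, everything else expensive);
* toy backbones built from internal coordinates around ideal beta strand
  (phi -120°, psi 130°) with per-column angular jitter ``sigma_flex`` at
  flexibility columns and ``sigma_rigid`` elsewhere, plus a pseudo-atom
  antigen chain whose Cbeta-like atoms sit next to the planted interface
  columns of each state;
* a truth record of every planted quantity.

Additive (per-column) energies are the default so the exhaustive design
oracle stays available; glycine is excluded from generated sequences so
every residue carries a Cbeta neighbor center (glycine handling is
exercised with hand-built models in the tests).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .alignment import (
    AlignmentSet,
    PositionMap,
    select_designed_positions,
    write_alignment,
    write_numbering_map,
)
from .constants import AMINO_ACIDS
from .design import StateEnergyTable, write_energy_table
from .structure import Residue, StructureModel, write_structure

# generated sequences avoid glycine so every residue has a CB center
_GEN_AA = [a for a in AMINO_ACIDS if a != "G"]

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

# ideal backbone geometry (bond lengths in Angstrom, angles in degrees)
B_N_CA, B_CA_C, B_C_N, B_CA_CB = 1.458, 1.525, 1.329, 1.522
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_X_CA_CB = 110.5
OMEGA = 180.0
PHI_BETA, PSI_BETA = -120.0, 130.0


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic bundle (all units as documented)."""

    n_columns: int = 40
    n_states: int = 8
    n_flex: int = 10
    n_spec: int = 15
    n_shared: int = 2
    n_neutral: int = 5
    g_flex: float = 2.0          # REU margin of germline at flex columns
    g_spec: float = 1.0          # REU germline penalty in a mutated state at spec columns
    g_other: float = 3.0         # REU floor for disfavored residues
    shared_penalty: float = 1.5  # REU germline penalty at shared columns (every state)
    sigma_e: float = 0.1         # REU noise inside neutral tolerated sets
    tolerated_set_size: int = 4  # incl. germline
    mutations_min: int = 4
    mutations_max: int = 20
    sigma_flex: float = 20.0     # degrees of phi/psi jitter at flex columns
    sigma_rigid: float = 5.0     # degrees elsewhere
    antigen_distance: float = 5.0  # Angstrom from target CB to antigen atoms
    antigen_atoms_per_site: int = 2
    heavy_chain: str = "H"
    antigen_chain: str = "G"
    germline_id: str = "germline"
    seed: int = 1

    def __post_init__(self) -> None:
        designed = self.n_flex + self.n_spec + self.n_shared + self.n_neutral
        if designed > self.n_columns:
            raise GeneratorError("position classes exceed the column count")
        if min(self.g_flex, self.g_spec, self.g_other) <= 0:
            raise GeneratorError("energy gaps must be positive")
        if self.g_other <= self.g_spec:
            raise GeneratorError("g_other must exceed g_spec")
        if self.n_states * self.g_spec >= (self.n_states - 1) * self.g_other:
            raise GeneratorError(
                "g_spec too large: multi-state consensus would not prefer germline"
            )
        if self.mutations_min < 1:
            raise GeneratorError("mutations_min must be at least 1")
        mid = (self.mutations_min + self.mutations_max) / 2
        if mid <= self.n_shared:
            raise GeneratorError(
                "shared-column count too large for the maturation gradient"
            )
        if self.mutations_max > designed:
            raise GeneratorError("mutations_max exceeds the designed-column count")
        if self.n_states < 2:
            raise GeneratorError("need at least 2 states")
        if min(self.sigma_flex, self.sigma_rigid, self.sigma_e) < 0:
            raise GeneratorError("noise scales must be non-negative")

    @property
    def n_designed(self) -> int:
        return self.n_flex + self.n_spec + self.n_shared + self.n_neutral

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(f"mab{k + 1:02d}" for k in range(self.n_states))


@dataclass
class SyntheticBundle:
    spec: GeneratorSpec
    alignment: AlignmentSet
    position_map: PositionMap
    tables: list[StateEnergyTable]
    structures: dict[str, StructureModel]
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def designed_columns(self) -> tuple[int, ...]:
        return tuple(self.truth["designed_columns"])


# ---------------------------------------------------------------------------
# internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    ang = math.radians(angle_deg)
    tor = -math.radians(torsion_deg)  # frame below is left-handed w.r.t. IUPAC sign
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_chain(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone N/CA/C coordinates from phi/psi (degrees), ideal geometry.

    Returns an array of shape ``(n, 3, 3)``; ``phi[0]`` and ``psi[-1]`` are
    ignored (undefined at the termini). Recomputing dihedrals from the
    result reproduces the inputs to well under half a degree.
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    n = len(phi)
    if n == 0:
        return np.zeros((0, 3, 3))
    if len(psi) != n:
        raise GeneratorError("phi and psi must have equal length")
    coords = np.zeros((n, 3, 3))
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (B_N_CA, 0.0, 0.0)
    ang = math.radians(A_N_CA_C)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        pn, pca, pc = coords[i - 1]
        ni = _place_atom(pn, pca, pc, B_C_N, A_CA_C_N, psi[i - 1])
        cai = _place_atom(pca, pc, ni, B_N_CA, A_C_N_CA, OMEGA)
        ci = _place_atom(pc, ni, cai, B_CA_C, A_N_CA_C, phi[i])
        coords[i] = (ni, cai, ci)
    return coords


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized Cbeta position from the backbone frame of one residue."""
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    bis = u + v
    bis /= np.linalg.norm(bis)
    perp = np.cross(v, u)
    perp /= np.linalg.norm(perp)
    half = 0.5 * math.acos(float(np.clip(u @ v, -1.0, 1.0)))
    a = math.cos(math.radians(A_X_CA_CB)) / math.cos(half)
    b = math.sqrt(max(0.0, 1.0 - a * a))
    return ca + B_CA_CB * (a * bis + b * perp)


# ---------------------------------------------------------------------------
# planting helpers
# ---------------------------------------------------------------------------

def _assign_with_coverage(columns: list[int], quotas: list[int], rng) -> list[list[int]]:
    """Assign each state ``quotas[k]`` columns, covering least-picked first."""
    counts = {c: 0 for c in columns}
    out: list[list[int]] = []
    for q in quotas:
        q = min(q, len(columns))
        order = sorted(columns, key=lambda c: (counts[c], rng.random()))
        picked = order[:q]
        for c in picked:
            counts[c] += 1
        out.append(sorted(picked))
    return out


def _occurrence_plan(spec: GeneratorSpec, classes: dict[int, str], rng) -> dict[int, int]:
    """Planned interface-occurrence count per designed column.

    Interface sites are drawn from the germline-optimal classes (flex and
    spec) and kept at least 5 columns apart, so the antigen pseudo-atoms of
    one site can never push a neighboring non-site column past the
    Δneighbor threshold (the falloff reaches ±2 residues along a strand).
    A few flex sites appear in most states, a few spec sites in 2-4 states
    or exactly one, everything else never.
    """
    k = spec.n_states
    occ = {col: 0 for col in classes}
    # sites live on germline-optimal columns whose ±2 window is free of
    # neutral/shared columns, so antigen spillover onto a flanking residue
    # can only ever implicate another germline-optimal (or undesigned) one
    low_bit = {c for c, cl in classes.items() if cl in ("neutral", "shared")}
    pool = sorted(
        c for c, cl in classes.items()
        if cl in ("flex", "spec")
        and not any(abs(c - b) <= 2 for b in low_bit)
    )
    sites: list[int] = []
    for c in pool:  # maximal left-to-right spaced set
        if all(abs(c - x) >= 5 for x in sites):
            sites.append(c)
    sites = sites[:8]
    rng.shuffle(sites)
    lo = min(k, max(1, math.ceil(0.6 * k)))
    hi = min(4, k)
    plan = ["high", "mid", "single", "high", "mid", "high", "mid", "single"]
    for c, kind in zip(sites, plan):
        if kind == "high":
            occ[c] = int(rng.integers(lo, k + 1))
        elif kind == "mid":
            occ[c] = int(rng.integers(min(2, hi), hi + 1))
        else:
            occ[c] = 1
    return occ


def generate(spec: GeneratorSpec, out_dir: str | Path | None = None) -> SyntheticBundle:
    """Build one internally consistent bundle; same seed, same bytes."""
    rng = np.random.default_rng(spec.seed)
    cols_all = list(range(1, spec.n_columns + 1))
    designed = sorted(rng.choice(spec.n_columns, size=spec.n_designed, replace=False) + 1)
    # shared+neutral columns sit in one contiguous run of designed columns
    # (loop-like segment); flex/spec fill the remainder, which keeps long
    # germline-optimal stretches available for interface-site placement
    classes: dict[int, str] = {}
    n_low = spec.n_shared + spec.n_neutral
    start = int(rng.integers(0, spec.n_designed - n_low + 1)) if n_low else 0
    low_block = list(designed[start:start + n_low])
    rng.shuffle(low_block)
    for i, col in enumerate(low_block):
        classes[col] = "shared" if i < spec.n_shared else "neutral"
    rest = [c for c in designed if c not in classes]
    rng.shuffle(rest)
    for i, col in enumerate(rest):
        classes[col] = "flex" if i < spec.n_flex else "spec"
    flex_cols = sorted(c for c, cl in classes.items() if cl == "flex")
    spec_cols = sorted(c for c, cl in classes.items() if cl == "spec")
    shared_cols = sorted(c for c, cl in classes.items() if cl == "shared")
    neutral_cols = sorted(c for c, cl in classes.items() if cl == "neutral")

    germline = "".join(rng.choice(_GEN_AA) for _ in range(spec.n_columns))

    # maturation gradient: the more-mature half of the states carry the
    # shared mutations (their germline penalty is planted in every table
    # regardless); per-state budgets go ~70% to spec columns (every state
    # gets at least one, keeping a strict single-state mature preference),
    # the remainder to flex and neutral, capped by class size
    n_mut = np.round(np.linspace(spec.mutations_min, spec.mutations_max,
                                 spec.n_states)).astype(int)
    shared_states = set(range(spec.n_states - spec.n_states // 2, spec.n_states))
    q_spec, q_flex, q_neutral = [], [], []
    for k in range(spec.n_states):
        r = int(n_mut[k]) - (spec.n_shared if k in shared_states else 0)
        if r < 1:
            raise GeneratorError("maturation gradient leaves a state without mutations")
        qs = min(spec.n_spec, max(1, round(0.7 * r)))
        qf = min(spec.n_flex, max(1, round(0.6 * (r - qs))) if r > qs else 0)
        qn = min(spec.n_neutral, r - qs - qf)
        left = r - qs - qf - qn
        add = min(left, spec.n_spec - qs)
        qs += add
        qf += min(left - add, spec.n_flex - qf)
        q_spec.append(qs)
        q_flex.append(qf)
        q_neutral.append(qn)
    # every column of every class must be mutated somewhere, or it would
    # not qualify as a designed position; shift budget out of the spec
    # quota (always over-covered) where a class falls short
    for quota, size in ((q_flex, spec.n_flex), (q_neutral, spec.n_neutral)):
        while sum(quota) < size:
            k = max(range(spec.n_states),
                    key=lambda i: (q_spec[i] > 1) * q_spec[i])
            if q_spec[k] <= 1 or quota[k] >= size:
                raise GeneratorError(
                    "mutation budget too small to cover every position class"
                )
            q_spec[k] -= 1
            quota[k] += 1
    if sum(q_spec) < spec.n_spec:
        raise GeneratorError(
            "mutation budget too small to cover every position class"
        )
    flex_sets = _assign_with_coverage(flex_cols, q_flex, rng)
    neutral_sets = _assign_with_coverage(neutral_cols, q_neutral, rng)
    spec_sets = _assign_with_coverage(spec_cols, q_spec, rng)

    shared_mature = {c: rng.choice([a for a in _GEN_AA if a != germline[c - 1]])
                     for c in shared_cols}
    tolerated = {
        c: [germline[c - 1]] + list(rng.choice(
            [a for a in _GEN_AA if a != germline[c - 1]],
            size=spec.tolerated_set_size - 1, replace=False))
        for c in neutral_cols
    }

    # per-column shuffled residue pool so state-specific mature residues at a
    # spec column never repeat across states (keeps the consensus germline)
    spec_pools = {c: list(rng.permutation([a for a in _GEN_AA if a != germline[c - 1]]))
                  for c in spec_cols}

    state_ids = spec.state_ids
    mature: dict[str, str] = {}
    mutated: dict[str, list[int]] = {}
    mature_aa: dict[str, dict[int, str]] = {}
    spec_use = {c: 0 for c in spec_cols}
    for k, cid in enumerate(state_ids):
        seq = list(germline)
        muts: dict[int, str] = {}
        if k in shared_states:
            for c in shared_cols:
                muts[c] = shared_mature[c]
        for c in flex_sets[k]:
            muts[c] = rng.choice([a for a in _GEN_AA if a != germline[c - 1]])
        for c in neutral_sets[k]:
            muts[c] = rng.choice(tolerated[c][1:])
        for c in spec_sets[k]:
            pool = spec_pools[c]
            muts[c] = pool[spec_use[c] % len(pool)]
            spec_use[c] += 1
        for c, aa in muts.items():
            seq[c - 1] = aa
        mature[cid] = "".join(seq)
        mutated[cid] = sorted(muts)
        mature_aa[cid] = muts

    # energy tables over designed columns
    gidx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    tables: list[StateEnergyTable] = []
    for k, cid in enumerate(state_ids):
        e = np.zeros((spec.n_designed, len(AMINO_ACIDS)))
        for i, c in enumerate(designed):
            cl = classes[c]
            g = germline[c - 1]
            if cl == "flex":
                e[i, :] = spec.g_flex + rng.uniform(0.0, 1.0, size=20)
                e[i, gidx[g]] = 0.0
            elif cl == "shared":
                e[i, :] = spec.g_other + rng.uniform(0.0, 1.0, size=20)
                e[i, gidx[g]] = spec.shared_penalty
                e[i, gidx[shared_mature[c]]] = 0.0
            elif cl == "spec":
                e[i, :] = spec.g_other + rng.uniform(0.0, 1.0, size=20)
                if c in mature_aa[cid]:
                    e[i, gidx[g]] = spec.g_spec
                    e[i, gidx[mature_aa[cid][c]]] = 0.0
                else:
                    e[i, gidx[g]] = 0.0
            else:  # neutral
                e[i, :] = spec.g_other + rng.uniform(0.0, 1.0, size=20)
                noise = np.clip(rng.normal(0.0, spec.sigma_e, size=len(tolerated[c])),
                                -0.3, 0.3)
                for aa, de in zip(tolerated[c], noise):
                    e[i, gidx[aa]] = de
        tables.append(StateEnergyTable(state_id=cid, columns=tuple(designed), energies=e))

    # interface plan and structures
    occurrence = _occurrence_plan(spec, classes, rng)
    interface: dict[str, list[int]] = {cid: [] for cid in state_ids}
    for col in designed:
        if occurrence[col] > 0:
            chosen = rng.choice(spec.n_states, size=occurrence[col], replace=False)
            for k in chosen:
                interface[state_ids[k]].append(col)
    sigma = {c: (spec.sigma_flex if classes.get(c) == "flex" else spec.sigma_rigid)
             for c in cols_all}

    structures: dict[str, StructureModel] = {}
    for cid in state_ids:
        phi = np.array([PHI_BETA + rng.normal(0.0, sigma[c]) for c in cols_all])
        psi = np.array([PSI_BETA + rng.normal(0.0, sigma[c]) for c in cols_all])
        bb = build_chain(phi, psi)
        residues = []
        seq = mature[cid]
        for i, c in enumerate(cols_all):
            n_, ca, cc = bb[i]
            atoms = {"N": n_, "CA": ca, "C": cc}
            if seq[i] != "G":
                atoms["CB"] = place_cb(n_, ca, cc)
            residues.append(Residue(spec.heavy_chain, c, "", AA3[seq[i]], atoms))
        chains = {spec.heavy_chain: residues}
        ag_res = []
        num = 1
        for col in sorted(interface[cid]):
            r = residues[col - 1]
            ca, cb, cc, nn = r.atoms["CA"], r.atoms["CB"], r.atoms["C"], r.atoms["N"]
            u = cb - ca
            u /= np.linalg.norm(u)
            t = cc - nn
            t = t - (t @ u) * u
            t /= np.linalg.norm(t)
            base = cb + spec.antigen_distance * u
            for j in range(spec.antigen_atoms_per_site):
                pos = base + (j - (spec.antigen_atoms_per_site - 1) / 2.0) * t
                ag_res.append(Residue(spec.antigen_chain, num, "", "ALA", {"CB": pos}))
                num += 1
        if ag_res:
            chains[spec.antigen_chain] = ag_res
        structures[cid] = StructureModel(chains=chains, source=cid)

    sequences = [(spec.germline_id, germline)] + [(cid, mature[cid]) for cid in state_ids]
    alignment = AlignmentSet(germline_id=spec.germline_id, sequences=tuple(sequences))
    numbering = {cid: {c: (spec.heavy_chain, c) for c in cols_all} for cid in state_ids}
    pmap = select_designed_positions(alignment).with_numbering(
        numbering, scheme="alignment-column"
    )
    if list(pmap.designed_columns) != list(designed):
        raise GeneratorError("planted mutations do not realize the designed columns")

    truth = {
        "designed_columns": [int(c) for c in designed],
        "classes": {str(c): classes[c] for c in designed},
        "germline": germline,
        "mature": mature,
        "mutated_columns": {cid: [int(c) for c in v] for cid, v in mutated.items()},
        "interface_columns": {cid: sorted(int(c) for c in v)
                              for cid, v in interface.items()},
        "occurrence": {str(c): int(occurrence[c]) for c in designed},
        "sigma_deg": {str(c): float(sigma[c]) for c in cols_all},
        "tolerated": {str(c): list(map(str, v)) for c, v in tolerated.items()},
        "shared_mature": {str(c): str(a) for c, a in shared_mature.items()},
        "params": {k: (v if not isinstance(v, tuple) else list(v))
                   for k, v in asdict(spec).items()},
    }

    bundle = SyntheticBundle(
        spec=spec, alignment=alignment, position_map=pmap, tables=tables,
        structures=structures, truth=truth,
    )
    if out_dir is not None:
        bundle.paths = _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SyntheticBundle, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["msa"] = out_dir / "msa.fasta"
    write_alignment(bundle.alignment, paths["msa"])
    paths["germline"] = out_dir / "germline.fasta"
    with open(paths["germline"], "w") as fh:
        fh.write(f">{bundle.spec.germline_id}\n{bundle.truth['germline']}\n")
    for table in bundle.tables:
        p = out_dir / f"energies_{table.state_id}.tsv"
        write_energy_table(table, p)
        paths[f"energies_{table.state_id}"] = p
    for cid, model in bundle.structures.items():
        p = out_dir / f"{cid}.pdb"
        write_structure(model, p)
        paths[f"pdb_{cid}"] = p
    paths["numbering_map"] = out_dir / "numbering_map.tsv"
    write_numbering_map(bundle.position_map.residue_maps, paths["numbering_map"])
    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
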