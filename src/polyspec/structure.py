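"""Structure parsing, backbone dihedrals, neighbor-count burial, interfaces.

A :class:`StructureModel` is a light container over PDB ATOM records (parsed
with gemmi). Three geometric quantities drive the analysis:

* IUPAC phi/psi backbone dihedrals per residue, with a Ramachandran-region
  beta-strand assignment (a deliberate stand-in for hydrogen-bond-based
  secondary structure at this scale; a user-supplied SS string overrides it);
* a scalar neighbor count per residue: the distance-weighted number of
  Cbeta centers (Calpha for glycine) near the residue's own center, a proxy
  for burial;
* the interface classification: a residue is an interacting residue iff its
  neighbor count drops by strictly more than 1.0 when the antigen chains are
  deleted from the same coordinates (no repacking of the unbound form).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .constants import (
    INTERFACE_DELTA_THRESHOLD,
    NEIGHBOR_INNER_A,
    NEIGHBOR_OUTER_A,
    PEPTIDE_BOND_MAX_A,
)

log = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)


class StructureError(ValueError):
    pass


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def center(self) -> np.ndarray | None:
        """Neighbor-count center: Cbeta, or Calpha for glycine."""
        if "CB" in self.atoms:
            return self.atoms["CB"]
        if self.name == "GLY" and "CA" in self.atoms:
            return self.atoms["CA"]
        return self.atoms.get("CA")


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]]
    source: str = ""

    def residues(self, chain_ids: Iterable[str] | None = None) -> list[Residue]:
        ids = list(chain_ids) if chain_ids is not None else list(self.chains)
        out: list[Residue] = []
        for cid in ids:
            if cid not in self.chains:
                raise StructureError(f"chain {cid!r} not present in {self.source}")
            out.extend(self.chains[cid])
        return out

    def residue(self, key: ResidueKey) -> Residue:
        chain, number, icode = key
        for res in self.chains.get(chain, []):
            if res.number == number and res.icode == icode:
                return res
        raise KeyError(key)

    def without_chains(self, chain_ids: Iterable[str]) -> "StructureModel":
        drop = set(chain_ids)
        return StructureModel(
            chains={c: r for c, r in self.chains.items() if c not in drop},
            source=self.source,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply a rigid motion x -> R x + t to every atom."""
        new_chains = {}
        for cid, residues in self.chains.items():
            new_chains[cid] = [
                Residue(
                    r.chain_id,
                    r.number,
                    r.icode,
                    r.name,
                    {n: rotation @ xyz + translation for n, xyz in r.atoms.items()},
                )
                for r in residues
            ]
        return StructureModel(chains=new_chains, source=self.source)


@dataclass(frozen=True)
class DihedralRecord:
    key: ResidueKey
    phi: float | None  # degrees in (-180, 180], None when undefined
    psi: float | None
    ss_label: str  # "beta" | "other" | "unassigned"


@dataclass(frozen=True)
class BurialScore:
    key: ResidueKey
    neighbor_count: float


@dataclass(frozen=True)
class InterfaceAnnotation:
    key: ResidueKey
    delta_neighbor: float
    is_interface: bool


def read_structure(
    path: str | Path, required_chains: Sequence[str] | None = None
) -> StructureModel:
    """Parse ATOM records of a PDB file.

    Waters and heteroatom records are ignored; alternate locations resolve
    to the highest-occupancy conformer (ties keep the first encountered).
    Residues missing any of N/CA/C are kept but flagged via a log entry;
    :func:`compute_dihedrals` excludes them.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom.name not in atoms or atom.occ > occ[atom.name]:
                    # keep highest occupancy; ties keep first encountered
                    if atom.name in atoms and atom.occ == occ[atom.name]:
                        continue
                    atoms[atom.name] = pos
                    occ[atom.name] = atom.occ
            r = Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
                name=res.name,
                atoms=atoms,
            )
            if not r.has_backbone:
                log.warning(
                    "%s %s%d%s missing backbone atoms; excluded from dihedrals",
                    path,
                    r.chain_id,
                    r.number,
                    r.icode,
                )
            residues.append(r)
        if residues:
            chains[chain.name] = residues
    if required_chains:
        missing = [c for c in required_chains if c not in chains]
        if missing:
            raise StructureError(f"{path}: configured chains {missing} not found")
    return StructureModel(chains=chains, source=str(path))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM records only) for round-tripping."""
    st = gemmi.Structure()
    st.name = "polyspec"
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                gr.add_atom(atom)
            chain.add_residue(gr)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(y, x))


def is_beta(phi: float | None, psi: float | None) -> bool:
    """Ramachandran beta-region rule: phi in [-180, -45] and psi in the
    extended band [45, 180] or (-180, -135]."""
    if phi is None or psi is None:
        return False
    return (-180.0 <= phi <= -45.0) and (45.0 <= psi <= 180.0 or -180.0 < psi <= -135.0)


def compute_dihedrals(
    model: StructureModel,
    chain: str,
    ss_override: Mapping[ResidueKey, str] | None = None,
) -> list[DihedralRecord]:
    """Phi/psi per residue of one chain, with beta/other assignment.

    Chain breaks (C-N distance > 2.5 A) and residues missing backbone atoms
    leave the adjacent dihedrals undefined rather than fabricated.
    """
    residues = [r for r in model.residues([chain])]
    records: list[DihedralRecord] = []

    def bonded(a: Residue, b: Residue) -> bool:
        if not (a.has_backbone and b.has_backbone):
            return False
        return float(np.linalg.norm(b.atoms["N"] - a.atoms["C"])) <= PEPTIDE_BOND_MAX_A

    for i, res in enumerate(residues):
        phi = psi = None
        if res.has_backbone:
            if i > 0 and bonded(residues[i - 1], res):
                phi = dihedral(
                    residues[i - 1].atoms["C"],
                    res.atoms["N"],
                    res.atoms["CA"],
                    res.atoms["C"],
                )
            if i + 1 < len(residues) and bonded(res, residues[i + 1]):
                psi = dihedral(
                    res.atoms["N"],
                    res.atoms["CA"],
                    res.atoms["C"],
                    residues[i + 1].atoms["N"],
                )
        if ss_override is not None and res.key in ss_override:
            label = ss_override[res.key]
        elif phi is None and psi is None:
            label = "unassigned"
        else:
            label = "beta" if is_beta(phi, psi) else "other"
        records.append(DihedralRecord(key=res.key, phi=phi, psi=psi, ss_label=label))
    return records


def neighbor_weight(distance: float) -> float:
    """Cosine-smoothed neighbor weight: 1 at/below 3.3 A, 0 at/beyond 11.1 A."""
    if distance <= NEIGHBOR_INNER_A:
        return 1.0
    if distance >= NEIGHBOR_OUTER_A:
        return 0.0
    frac = (distance - NEIGHBOR_INNER_A) / (NEIGHBOR_OUTER_A - NEIGHBOR_INNER_A)
    return 0.5 * (math.cos(math.pi * frac) + 1.0)


def neighbor_count(
    model: StructureModel, subset: Iterable[ResidueKey] | None = None
) -> list[BurialScore]:
    """Weighted count of neighboring residue centers for each residue.

    Neighbors are all other residues in the model (any chain); the counted
    residues are restricted to ``subset`` when given.
    """
    all_res = model.residues()
    centers = [(r.key, r.center()) for r in all_res]
    centers = [(k, c) for k, c in centers if c is not None]
    keys = [k for k, _ in centers]
    coords = np.array([c for _, c in centers]) if centers else np.zeros((0, 3))
    wanted = set(subset) if subset is not None else None
    out = []
    for i, key in enumerate(keys):
        if wanted is not None and key not in wanted:
            continue
        d = np.linalg.norm(coords - coords[i], axis=1)
        score = sum(neighbor_weight(float(dj)) for j, dj in enumerate(d) if j != i)
        out.append(BurialScore(key=key, neighbor_count=score))
    return out


def annotate_interface(
    deltas: Mapping[ResidueKey, float],
    threshold: float = INTERFACE_DELTA_THRESHOLD,
) -> list[InterfaceAnnotation]:
    """Apply the strict Δneighbor > threshold interface rule to raw deltas."""
    return [
        InterfaceAnnotation(key=k, delta_neighbor=v, is_interface=v > threshold)
        for k, v in deltas.items()
    ]


def classify_interface(
    model: StructureModel,
    antibody_chains: Sequence[str],
    antigen_chains: Sequence[str],
    threshold: float = INTERFACE_DELTA_THRESHOLD,
) -> list[InterfaceAnnotation]:
    """Interface membership of antibody residues by bound-vs-unbound change.

    The unbound antibody is the same coordinates with antigen chains
    deleted; the neighbor count difference therefore isolates the antigen's
    contribution.
    """
    if set(antibody_chains) & set(antigen_chains):
        raise StructureError("antibody and antigen chain sets must be disjoint")
    for cid in antibody_chains:
        if cid not in model.chains:
            raise StructureError(f"antibody chain {cid!r} missing")
    present_antigen = [c for c in antigen_chains if c in model.chains]
    if not present_antigen and antigen_chains:
        log.warning("no antigen chains present; all interface deltas are 0")
    ab_keys = [r.key for r in model.residues(antibody_chains)]
    bound = {b.key: b.neighbor_count for b in neighbor_count(model, ab_keys)}
    unbound_model = model.without_chains(present_antigen)
    unbound = {
        b.key: b.neighbor_count for b in neighbor_count(unbound_model, ab_keys)
    }
    deltas = {k: bound[k] - unbound.get(k, 0.0) for k in ab_keys if k in bound}
    return annotate_interface(deltas, threshold=threshold)
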