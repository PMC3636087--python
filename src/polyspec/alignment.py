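"""Mature/germline heavy-chain alignment handling.

The multiple sequence alignment of the V-gene-encoded heavy-chain segments
(one mature sequence per antibody/antigen complex plus exactly one germline
reference) is the coordinate system of the whole analysis: alignment columns
are 1-based and every downstream quantity (energies, bit-scores, dihedral
deviations, interface occurrences) is indexed by column. Per-structure
residue numbering is carried only through explicit numbering maps; nothing
is renumbered automatically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AMINO_ACIDS, GAP

_VALID = set(AMINO_ACIDS) | {GAP}


class AlignmentFormatError(ValueError):
    """The alignment file violates the gapless-MSA contract."""


class ConfigurationError(ValueError):
    """A configured identifier does not match the inputs."""


@dataclass(frozen=True)
class AlignmentSet:
    """A gapless-width MSA of mature heavy-chain segments plus one germline.

    ``sequences`` preserves file order and includes the germline record.
    """

    germline_id: str
    sequences: tuple[tuple[str, str], ...]  # (label, aa string)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.sequences]
        if len(set(labels)) != len(labels):
            raise AlignmentFormatError("duplicate sequence labels in alignment")
        if self.germline_id not in labels:
            raise ConfigurationError(
                f"germline id {self.germline_id!r} not present in alignment"
            )
        lengths = {len(seq) for _, seq in self.sequences}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        for label, seq in self.sequences:
            bad = set(seq) - _VALID
            if bad:
                raise AlignmentFormatError(
                    f"sequence {label!r} contains nonstandard residues {sorted(bad)}"
                )
        if len(self.sequences) < 2:
            raise AlignmentFormatError("alignment needs >=2 records")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def germline(self) -> str:
        return dict(self.sequences)[self.germline_id]

    @property
    def mature(self) -> dict[str, str]:
        """Mature sequences keyed by complex label (germline excluded)."""
        return {l: s for l, s in self.sequences if l != self.germline_id}

    def column(self, col: int) -> dict[str, str]:
        """Residues of every record at 1-based column ``col``."""
        return {l: s[col - 1] for l, s in self.sequences}


@dataclass(frozen=True)
class PositionMap:
    """Designed alignment columns plus column <-> residue correspondence.

    ``residue_maps[complex][column] = (chain_id, residue_number)``; a column
    missing from a complex's map is treated as absent in that structure.
    """

    designed_columns: tuple[int, ...]
    residue_maps: Mapping[str, Mapping[int, tuple[str, int]]] = field(
        default_factory=dict
    )
    numbering_scheme: str = "alignment-column"

    def residue_for(self, complex_id: str, column: int) -> tuple[str, int] | None:
        return self.residue_maps.get(complex_id, {}).get(column)

    def column_for(self, complex_id: str, chain: str, resnum: int) -> int | None:
        for col, key in self.residue_maps.get(complex_id, {}).items():
            if key == (chain, resnum):
                return col
        return None

    def with_numbering(
        self, residue_maps: Mapping[str, Mapping[int, tuple[str, int]]], scheme: str
    ) -> "PositionMap":
        for cid, cmap in residue_maps.items():
            values = list(cmap.values())
            if len(set(values)) != len(values):
                raise ConfigurationError(
                    f"numbering map for {cid!r} is not one-to-one"
                )
        return replace(self, residue_maps=residue_maps, numbering_scheme=scheme)


@dataclass(frozen=True)
class MutationSummary:
    complex_id: str
    count: int
    percentage: float  # count / non-gap aligned columns * 100


def read_alignment(path: str | Path, germline_id: str) -> AlignmentSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return AlignmentSet(
        germline_id=germline_id,
        sequences=tuple((r.id, str(r.seq).upper()) for r in records),
    )


def write_alignment(aln: AlignmentSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in aln.sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def select_designed_positions(aln: AlignmentSet) -> PositionMap:
    """Columns where at least one mature sequence differs from germline.

    Conserved columns are excluded; columns gapped in any record are
    excluded from design and from all downstream statistics.
    """
    germ = aln.germline
    designed = []
    for col in range(1, aln.length + 1):
        residues = aln.column(col)
        if GAP in residues.values():
            continue
        if any(
            aa != germ[col - 1]
            for label, aa in residues.items()
            if label != aln.germline_id
        ):
            designed.append(col)
    return PositionMap(designed_columns=tuple(designed))


def mutation_summary(aln: AlignmentSet) -> dict[str, MutationSummary]:
    """Per-complex count and percentage of mutations away from germline.

    The percentage denominator is the number of alignment columns that are
    gap-free in every record (the V-gene-alignable region).
    """
    germ = aln.germline
    aligned_cols = [
        col for col in range(1, aln.length + 1) if GAP not in aln.column(col).values()
    ]
    out = {}
    for label, seq in aln.mature.items():
        count = sum(1 for col in aligned_cols if seq[col - 1] != germ[col - 1])
        out[label] = MutationSummary(
            complex_id=label,
            count=count,
            percentage=100.0 * count / len(aligned_cols) if aligned_cols else 0.0,
        )
    return out


def read_numbering_map(
    path: str | Path,
) -> dict[str, dict[int, tuple[str, int]]]:
    """Read a ``column<TAB>complex<TAB>chain<TAB>resnum`` mapping table."""
    maps: dict[str, dict[int, tuple[str, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "column":
                continue
            col, cid, chain, resnum = row[:4]
            maps.setdefault(cid, {})[int(col)] = (chain, int(resnum))
    return maps


def write_numbering_map(
    maps: Mapping[str, Mapping[int, tuple[str, int]]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["column", "complex", "chain", "resnum"])
        for cid in sorted(maps):
            for col in sorted(maps[cid]):
                chain, resnum = maps[cid][col]
                writer.writerow([col, cid, chain, resnum])


def subsequence(seq: str, columns: Iterable[int]) -> str:
    """Restrict a full-length aligned sequence to the given 1-based columns."""
    return "".join(seq[c - 1] for c in columns)
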