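"""Protein chain definitions and FASTA input.

Coordinates throughout the package are 1-based, inclusive, in construct
numbering: residue ``i`` of a chain is sequence position
``i - first_residue_number + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .constants import STANDARD_RESIDUES


@dataclass(frozen=True)
class ProteinChain:
    """One subunit of the construct under study.

    The default chains used across this package model the ISB heterotrimer
    (INCENP 1-58, Survivin, Borealin) whose phase-separation interfaces the
    differential HX pipeline localizes.
    """

    chain_id: str
    sequence: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_RESIDUES:
                raise ValueError(
                    f"chain {self.chain_id!r}: unknown residue {aa!r} at position {pos}"
                )
        if self.first_residue_number < 1:
            raise ValueError(f"chain {self.chain_id!r}: first_residue_number must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.sequence) - 1

    def subsequence(self, start: int, end: int) -> str:
        """Sequence of residues ``start..end`` (construct numbering, inclusive)."""
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        if start < self.first_residue_number or end > self.last_residue_number:
            raise ValueError(
                f"range {start}-{end} outside chain {self.chain_id!r} "
                f"({self.first_residue_number}-{self.last_residue_number})"
            )
        off = self.first_residue_number
        return self.sequence[start - off : end - off + 1]

    def index_of(self, residue_number: int) -> int:
        """0-based index into ``sequence`` for a construct residue number."""
        idx = residue_number - self.first_residue_number
        if not 0 <= idx < len(self.sequence):
            raise ValueError(f"residue {residue_number} outside chain {self.chain_id!r}")
        return idx


def read_fasta_chains(path: str | Path, first_residue_numbers: dict[str, int] | None = None) -> list[ProteinChain]:
    """Read chains from a FASTA file; record ids become chain ids.

    ``first_residue_numbers`` optionally maps chain id to the construct
    number of the first sequence position (default 1).
    """
    firsts = first_residue_numbers or {}
    chains = [
        ProteinChain(rec.id, str(rec.seq).upper(), firsts.get(rec.id, 1))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not chains:
        raise ValueError(f"no FASTA records in {path}")
    return chains


def write_fasta_chains(chains: list[ProteinChain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(f">{ch.chain_id}\n")
            for i in range(0, len(ch.sequence), 60):
                fh.write(ch.sequence[i : i + 60] + "\n")
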