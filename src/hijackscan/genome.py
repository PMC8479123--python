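"""Minimal genome container with origin-shifted coordinates.

A :class:`ToyGenome` holds a handful of contigs whose coordinates can be
shifted by a per-contig ``origin``, so a 200 kb toy sequence can stand in
for a genome-scale locus (e.g. the 3q26 *EVI1* region or the 8q24 *MYC*
super-enhancer region) while keeping genomic coordinates realistic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq

_VALID = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """One contig: a name, its sequence and the genomic coordinate of base 0."""

    name: str
    sequence: str
    origin: int = 0

    def __post_init__(self) -> None:
        if self.origin < 0:
            raise ValueError(f"contig {self.name!r}: origin must be >= 0")
        bad = set(self.sequence) - _VALID
        if bad:
            pos = next(i for i, b in enumerate(self.sequence) if b in bad)
            raise ValueError(
                f"contig {self.name!r}: invalid base {self.sequence[pos]!r} "
                f"at position {self.origin + pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        """First genomic coordinate covered (= origin)."""
        return self.origin

    @property
    def end(self) -> int:
        """One past the last genomic coordinate covered."""
        return self.origin + len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Sequence for genomic (origin-shifted) half-open interval [start, end)."""
        if start < self.origin or end > self.end:
            raise IndexError(
                f"[{start}, {end}) outside contig {self.name!r} "
                f"[{self.origin}, {self.end})"
            )
        return self.sequence[start - self.origin : end - self.origin]


@dataclass
class ToyGenome:
    """An ordered collection of uniquely named contigs."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("contig names must be unique")

    def __iter__(self) -> Iterator[Contig]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.contigs)

    def checksum(self) -> str:
        """MD5 over contig names, origins and sequences; identifies a digest's source."""
        h = hashlib.md5()
        for c in self.contigs:
            h.update(f"{c.name}:{c.origin}:".encode())
            h.update(c.sequence.encode())
        return h.hexdigest()

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.name} origin={c.origin}\n")
                for i in range(0, len(c.sequence), 80):
                    fh.write(c.sequence[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ToyGenome":
        """Load a genome from FASTA; an ``origin=N`` token in the description is honored."""
        contigs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            origin = 0
            for tok in rec.description.split():
                if tok.startswith("origin="):
                    origin = int(tok.split("=", 1)[1])
            contigs.append(Contig(rec.id, str(rec.seq).upper(), origin))
        return cls(contigs)


def as_genome(genome: "ToyGenome | str | Path") -> ToyGenome:
    """Accept a ToyGenome or a FASTA path."""
    if isinstance(genome, ToyGenome):
        return genome
    return ToyGenome.from_fasta(genome)


__all__ = ["Contig", "ToyGenome", "revcomp", "as_genome", "Seq"]
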