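"""Reference genome container and FASTA input/output.

All coordinates in this package are 0-based half-open; conversion to 1-based
happens only when VCF records are written.
"""

from __future__ import annotations

import re

from Bio import SeqIO

_BAD_CHAR = re.compile(r"[^ACGTN]")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


class ReferenceGenomeError(ValueError):
    pass


class ReferenceGenome:
    """Ordered collection of named chromosome sequences over {A,C,G,T,N}.

    The substrate of every simulation; immutable by convention.
    """

    def __init__(self, chromosomes):
        self.names: list[str] = []
        self._seqs: dict[str, str] = {}
        for name, seq in chromosomes:
            if name in self._seqs:
                raise ReferenceGenomeError(f"duplicate chromosome name: {name!r}")
            if not seq:
                raise ReferenceGenomeError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            m = _BAD_CHAR.search(seq)
            if m:
                raise ReferenceGenomeError(
                    f"invalid character {m.group()!r} in chromosome {name!r} "
                    f"at position {m.start()}"
                )
            self.names.append(name)
            self._seqs[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self._seqs[n]) for n in self.names}

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def items(self):
        for n in self.names:
            yield n, self._seqs[n]

    def __len__(self) -> int:
        return len(self.names)

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())


def load_reference(fasta_path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; any character outside {A,C,G,T,N} is an error
    naming the chromosome and offset.
    """
    with open(fasta_path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ReferenceGenomeError(
                f"{fasta_path}: not a FASTA file (line 1 does not start with '>')"
            )
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    if not records:
        raise ReferenceGenomeError(f"{fasta_path}: no FASTA records found")
    return ReferenceGenome(records)


def write_fasta(records, out_path, width: int = 60) -> None:
    """Write (name, sequence) pairs as wrapped FASTA."""
    with open(out_path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reference_fasta(genome: ReferenceGenome, out_path, width: int = 60) -> None:
    write_fasta(genome.items(), out_path, width=width)


def write_chrom_lengths(genome: ReferenceGenome, out_path) -> None:
    """Chromosome-length table: name<TAB>length."""
    with open(out_path, "w") as fh:
        for name in genome.names:
            fh.write(f"{name}\t{len(genome[name])}\n")
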