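"""Mutable tumor genome model: a multiset of chromosome copies.

Each chromosome copy carries its current nucleotide sequence together with an
interval map ("pieces") recording which stretch of which personal-genome
haplotype every base came from and in what orientation. Aneuploidy and SV
events rewrite sequence and pieces in lockstep, so the truth annotator can
always project a copy back onto reference coordinates through the germline
liftover maps. Foreign (novel) insertions are pieces with no source and hence
no reference projection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .germline import PersonalGenome, hap_to_ref_intervals
from .reference import ReferenceGenome, revcomp

FOREIGN_CHROM = "*"


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class Piece:
    """One contiguous stretch of a copy, mapped to haplotype coordinates.

    ``start``/``end`` are half-open coordinates on the (chrom, hap) personal
    haplotype; strand '-' means the copy holds the reverse complement.
    Foreign pieces use ``chrom == '*'`` and map to nothing.
    """

    chrom: str
    hap: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_foreign(self) -> bool:
        return self.chrom == FOREIGN_CHROM

    def sub(self, i: int, j: int) -> "Piece":
        """Sub-piece for copy-orientation offsets [i, j) within this piece."""
        if not (0 <= i <= j <= self.length):
            raise ModelError(f"bad sub-piece offsets ({i}, {j}) in piece of length {self.length}")
        if self.strand == "+":
            return Piece(self.chrom, self.hap, self.start + i, self.start + j, "+")
        return Piece(self.chrom, self.hap, self.end - j, self.end - i, "-")

    def rc(self) -> "Piece":
        return Piece(self.chrom, self.hap, self.start, self.end,
                     "-" if self.strand == "+" else "+")


def foreign_piece(n: int) -> Piece:
    return Piece(FOREIGN_CHROM, "*", 0, n, "+")


class Part:
    """An immutable (sequence, pieces) pair; all edits build new Parts."""

    __slots__ = ("seq", "pieces")

    def __init__(self, seq: str, pieces: list[Piece]):
        self.seq = seq
        self.pieces = list(pieces)
        if sum(p.length for p in self.pieces) != len(seq):
            raise ModelError("piece lengths do not sum to sequence length")

    @classmethod
    def from_haplotype(cls, chrom: str, hap: str, seq: str) -> "Part":
        return cls(seq, [Piece(chrom, hap, 0, len(seq), "+")])

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, a: int, b: int) -> "Part":
        if not (0 <= a <= b <= len(self)):
            raise ModelError(f"slice ({a}, {b}) out of bounds for part of length {len(self)}")
        pieces = []
        off = 0
        for p in self.pieces:
            s, e = off, off + p.length
            off = e
            if e <= a or s >= b:
                continue
            pieces.append(p.sub(max(a, s) - s, min(b, e) - s))
        return Part(self.seq[a:b], pieces)

    def rc(self) -> "Part":
        return Part(revcomp(self.seq), [p.rc() for p in reversed(self.pieces)])

    def __add__(self, other: "Part") -> "Part":
        return Part(self.seq + other.seq, self.pieces + other.pieces)

    def boundaries(self) -> list[int]:
        """Internal piece boundaries (junction positions) in copy coordinates."""
        out = []
        off = 0
        for p in self.pieces[:-1]:
            off += p.length
            out.append(off)
        return out


@dataclass
class ChromosomeCopy:
    """One physical copy of a chromosome in the tumor genome."""

    copy_id: str
    chrom: str
    parental_origin: str  # 'A' or 'B': the haplotype this copy started from
    part: Part

    @property
    def sequence(self) -> str:
        return self.part.seq

    def __len__(self) -> int:
        return len(self.part)


class GenomeModel:
    """The multiset of chromosome copies that aneuploidy and SVs mutate.

    Shares the (immutable) reference and germline liftover maps; ``clone()``
    duplicates the copy objects cheaply since Parts are never edited in place.
    """

    def __init__(self, reference: ReferenceGenome, liftover):
        self.reference = reference
        self.liftover = liftover
        self.copies: dict[str, list[ChromosomeCopy]] = {c: [] for c in reference.names}
        self.provenance: list = []
        self._counter = 0

    def new_copy_id(self) -> str:
        cid = f"c{self._counter:03d}"
        self._counter += 1
        return cid

    def add_copy(self, chrom: str, origin: str, part: Part) -> ChromosomeCopy:
        copy = ChromosomeCopy(self.new_copy_id(), chrom, origin, part)
        self.copies[chrom].append(copy)
        return copy

    def all_copies(self) -> list[ChromosomeCopy]:
        return [c for chrom in self.reference.names for c in self.copies[chrom]]

    def get(self, copy_id: str) -> ChromosomeCopy:
        for c in self.all_copies():
            if c.copy_id == copy_id:
                return c
        raise ModelError(f"no such copy: {copy_id}")

    def remove(self, copy_id: str) -> None:
        for chrom, lst in self.copies.items():
            for i, c in enumerate(lst):
                if c.copy_id == copy_id:
                    del lst[i]
                    return
        raise ModelError(f"no such copy: {copy_id}")

    def total_bases(self) -> int:
        return sum(len(c) for c in self.all_copies())

    def clone(self) -> "GenomeModel":
        other = GenomeModel(self.reference, self.liftover)
        other.copies = {
            chrom: [ChromosomeCopy(c.copy_id, c.chrom, c.parental_origin, c.part)
                    for c in lst]
            for chrom, lst in self.copies.items()
        }
        other.provenance = list(self.provenance)
        other._counter = self._counter
        return other

    def __deepcopy__(self, memo):
        return self.clone()

    # -- reference projection -------------------------------------------------

    def project_interval(self, part: Part, a: int, b: int):
        """Reference intervals covered by copy interval [a, b) as a list of
        (chrom, ref_start, ref_end, hap); foreign bases yield nothing."""
        out = []
        off = 0
        for p in part.pieces:
            s, e = off, off + p.length
            off = e
            if e <= a or s >= b:
                continue
            sp = p.sub(max(a, s) - s, min(b, e) - s)
            if sp.is_foreign:
                continue
            blocks = self.liftover[(sp.chrom, sp.hap)]
            for rs, re_ in hap_to_ref_intervals(blocks, sp.start, sp.end):
                out.append((sp.chrom, rs, re_, sp.hap))
        return out

    def project_point(self, part: Part, pos: int):
        """(chrom, ref_pos) of the base at copy position ``pos``, or None if
        the base is foreign or sits in germline-inserted sequence."""
        hits = self.project_interval(part, pos, pos + 1)
        if not hits:
            return None
        chrom, rs, _re, _hap = hits[0]
        return (chrom, rs)

    def reference_kmers(self, k: int = 30) -> set[int]:
        """2-bit-encoded k-mer set of the reference (cached on the reference
        object so every clone of this model shares it)."""
        cache = getattr(self.reference, "_kmer_cache", None)
        if cache is None:
            cache = {}
            self.reference._kmer_cache = cache
        if k not in cache:
            cache[k] = _kmer_set(self.reference, k)
        return cache[k]


_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


def _kmer_set(reference: ReferenceGenome, k: int) -> set[int]:
    mask = (1 << (2 * k)) - 1
    out: set[int] = set()
    strands = []
    for _name, seq in reference.items():
        strands.append(seq)
        strands.append(revcomp(seq))  # novelty must hold on both strands
    for seq in strands:
        val = 0
        run = 0  # bases since last N
        for byte in seq.encode():
            code = _CODE.get(byte)
            if code is None:
                run = 0
                val = 0
                continue
            val = ((val << 2) | code) & mask
            run += 1
            if run >= k:
                out.add(val)
    return out


def kmers_of(seq: str, k: int):
    """Iterate 2-bit-encoded k-mers of a sequence (skipping N windows)."""
    mask = (1 << (2 * k)) - 1
    val = 0
    run = 0
    for byte in seq.encode():
        code = _CODE.get(byte)
        if code is None:
            run = 0
            val = 0
            continue
        val = ((val << 2) | code) & mask
        run += 1
        if run >= k:
            yield val


def initial_model(pg: PersonalGenome) -> GenomeModel:
    """Diploid genome model: one copy per haplotype per chromosome."""
    model = GenomeModel(pg.reference, pg.liftover)
    for chrom in pg.reference.names:
        for hap in ("A", "B"):
            model.add_copy(chrom, hap, Part.from_haplotype(chrom, hap, pg.haplotypes[chrom][hap]))
    return model
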