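"""Self-contained synthetic references with planted repeat catalogs.

Real runs take a genome assembly plus a repeat annotation; for development and
testing this module builds both from scratch: random background sequence at a
chosen GC content, with repeat families planted as diverged copies of a random
consensus at recorded, non-overlapping coordinates. The returned catalog rows
match the planted coordinates exactly, so homology-mediated placement can be
exercised without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference import ReferenceGenome, revcomp
from .repeats import RepeatCatalog, RepeatElement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RepeatPlan:
    """One family to plant: copy count, element length, per-base divergence."""

    family: str
    copies: int
    length: int
    divergence: float = 0.05


def random_sequence(n: int, gc_fraction: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=n, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode()


def _diverge(consensus: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return consensus
    arr = np.frombuffer(consensus.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def make_synthetic_reference(
    n_chroms: int,
    chrom_length: int,
    gc_fraction: float = 0.41,
    repeat_plan: list[RepeatPlan | tuple] | None = None,
    seed: int = 0,
    chrom_prefix: str = "chr",
) -> tuple[ReferenceGenome, RepeatCatalog]:
    """Build a synthetic reference and its exactly-known repeat catalog.

    Repeats are placed uniformly at random without overlap (rejection
    sampling); an infeasible packing raises. Fully deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    plans = [p if isinstance(p, RepeatPlan) else RepeatPlan(*p) for p in (repeat_plan or [])]

    total_repeat = sum(p.copies * p.length for p in plans)
    if total_repeat > 0.8 * n_chroms * chrom_length:
        raise ValueError(
            f"repeat plan needs {total_repeat} bp but genome holds only "
            f"{n_chroms * chrom_length} bp"
        )

    chrom_names = [f"{chrom_prefix}{i + 1}" for i in range(n_chroms)]
    seqs = {name: bytearray(random_sequence(chrom_length, gc_fraction, rng), "ascii")
            for name in chrom_names}

    consensus = {p.family: random_sequence(p.length, gc_fraction, rng) for p in plans}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_names}
    elements = []
    for plan in plans:
        if plan.length > chrom_length:
            raise ValueError(f"element length {plan.length} exceeds chromosome length")
        for k in range(plan.copies):
            placed = False
            for _ in range(1000):
                chrom = chrom_names[rng.integers(n_chroms)]
                start = int(rng.integers(0, chrom_length - plan.length + 1))
                end = start + plan.length
                if any(s < end and start < e for s, e in occupied[chrom]):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                copy_seq = _diverge(consensus[plan.family], plan.divergence, rng)
                if strand == "-":
                    copy_seq = revcomp(copy_seq)
                seqs[chrom][start:end] = copy_seq.encode()
                occupied[chrom].append((start, end))
                elements.append(
                    RepeatElement(chrom, start, end, strand, plan.family,
                                  f"{plan.family}.{k}")
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place copy {k} of family {plan.family}: packing infeasible"
                )

    genome = ReferenceGenome((n, seqs[n].decode()) for n in chrom_names)
    elements.sort(key=lambda e: (e.chrom, e.start))
    return genome, RepeatCatalog(elements, consensus=consensus)
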