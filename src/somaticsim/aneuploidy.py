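"""Tumor aneuploidy: base ploidy and large-scale chromosome rearrangements.

The base ploidy replicates or drops whole haplotype copies of every
chromosome before any somatic SV is placed:

* 1n: one randomly chosen parental copy is kept;
* 2n: both parental copies;
* 3n: both, plus a duplicate of one randomly chosen copy;
* even n: each parental copy replicated n/2 times;
* odd n >= 5: each replicated (n-1)/2 times plus one random extra copy.

On top of that, a configurable number of whole or segmental chromosome
duplications/deletions is applied, mimicking chromosome-arm-scale instability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .germline import PersonalGenome
from .model import GenomeModel, ModelError, Part

log = logging.getLogger(__name__)


class AneuploidyError(RuntimeError):
    pass


@dataclass(frozen=True)
class AneuploidyEvent:
    kind: str  # whole_gain | whole_loss | segmental_dup | segmental_del
    chrom: str
    copy_id: str
    start: int | None = None  # copy coordinates at application time
    end: int | None = None
    ref_start: int | None = None  # reference projection of the interval span
    ref_end: int | None = None


def _ploidy_origins(n: int, rng: np.random.Generator) -> list[str]:
    if n < 1:
        raise AneuploidyError(f"ploidy must be >= 1, got {n}")
    if n == 1:
        return [("A", "B")[rng.integers(2)]]
    if n == 2:
        return ["A", "B"]
    if n == 3:
        return ["A", "B", ("A", "B")[rng.integers(2)]]
    if n % 2 == 0:
        return ["A", "B"] * (n // 2)
    return ["A", "B"] * ((n - 1) // 2) + [("A", "B")[rng.integers(2)]]


def set_base_ploidy(
    pg: PersonalGenome,
    ploidy: int,
    seed: int = 0,
    per_chrom_ploidy: dict[str, int] | None = None,
) -> GenomeModel:
    """Build the starting tumor genome at the requested base ploidy.

    Ploidy applies uniformly to all chromosomes unless overridden per
    chromosome via ``per_chrom_ploidy``.
    """
    rng = np.random.default_rng(seed)
    per_chrom = per_chrom_ploidy or {}
    model = GenomeModel(pg.reference, pg.liftover)
    for chrom in pg.reference.names:
        n = per_chrom.get(chrom, ploidy)
        origins = _ploidy_origins(n, rng)
        for origin in origins:
            part = Part.from_haplotype(chrom, origin, pg.haplotypes[chrom][origin])
            model.add_copy(chrom, origin, part)
        model.provenance.append(f"ploidy {chrom}: {n} copies ({''.join(origins)})")
    return model


def _uniform_fraction_size(rng: np.random.Generator, copy_len: int) -> int:
    return int(copy_len * rng.uniform(0.1, 0.5))


def apply_chromosome_rearrangements(
    model: GenomeModel,
    n_events: int,
    segmental_fraction: float = 0.5,
    size_dist=None,
    seed: int = 0,
) -> tuple[GenomeModel, list[AneuploidyEvent]]:
    """Apply ``n_events`` whole/segmental chromosome duplications or deletions.

    Whole-chromosome losses never remove the last remaining copy of a
    chromosome. Segmental sizes default to uniform between 10% and 50% of the
    copy length. Every event is recorded with copy coordinates and, where
    defined, the reference span it projects onto.
    """
    if n_events < 0:
        raise AneuploidyError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    sizer = size_dist or _uniform_fraction_size
    chroms = model.reference.names
    events: list[AneuploidyEvent] = []
    for _ in range(n_events):
        for _attempt in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            copies = model.copies[chrom]
            if not copies:
                continue
            segmental = rng.random() < segmental_fraction
            loss = rng.random() < 0.5
            copy = copies[rng.integers(len(copies))]
            if segmental:
                L = len(copy)
                size = int(sizer(rng, L))
                if size < 1 or size >= L:
                    continue
                a = int(rng.integers(0, L - size + 1))
                b = a + size
                proj = model.project_interval(copy.part, a, b)
                rs = min((p[1] for p in proj), default=None)
                re_ = max((p[2] for p in proj), default=None)
                if loss:
                    copy.part = copy.part.slice(0, a) + copy.part.slice(b, L)
                    kind = "segmental_del"
                else:
                    copy.part = (
                        copy.part.slice(0, b) + copy.part.slice(a, b) + copy.part.slice(b, L)
                    )
                    kind = "segmental_dup"
                ev = AneuploidyEvent(kind, chrom, copy.copy_id, a, b, rs, re_)
            else:
                if loss:
                    if len(copies) <= 1:
                        continue
                    ev = AneuploidyEvent("whole_loss", chrom, copy.copy_id)
                    model.remove(copy.copy_id)
                else:
                    new = model.add_copy(chrom, copy.parental_origin, copy.part)
                    ev = AneuploidyEvent("whole_gain", chrom, new.copy_id)
            events.append(ev)
            model.provenance.append(ev)
            break
        else:
            raise AneuploidyError(
                "could not realize a chromosome rearrangement after retries "
                "(would orphan a chromosome or no feasible segment)"
            )
    log.info("applied %d chromosome rearrangements", len(events))
    return model, events


def write_aneuploidy_log(events: list[AneuploidyEvent], out_path) -> None:
    with open(out_path, "w") as fh:
        fh.write("kind\tchrom\tcopy_id\tstart\tend\tref_start\tref_end\n")
        for e in events:
            fh.write(
                f"{e.kind}\t{e.chrom}\t{e.copy_id}\t"
                f"{'' if e.start is None else e.start}\t"
                f"{'' if e.end is None else e.end}\t"
                f"{'' if e.ref_start is None else e.ref_start}\t"
                f"{'' if e.ref_end is None else e.ref_end}\n"
            )
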