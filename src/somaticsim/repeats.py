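"""Repeat annotation: catalog container, rmsk-style readers, pair enumeration.

Homology-mediated rearrangements need pairs of elements from the same repeat
family that share homologous sequence; the catalog indexes elements by family
and by genomic interval so placement code can find such pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class RepeatCatalogError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatElement:
    """One repeat copy on the reference (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    name: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RepeatCatalogError(
                f"repeat element {self.name} on {self.chrom}: "
                f"invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise RepeatCatalogError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class RepeatCatalog:
    """Repeat elements indexed by family and by overlapping interval."""

    def __init__(self, elements, consensus: dict[str, str] | None = None):
        self.elements: list[RepeatElement] = list(elements)
        self.by_family: dict[str, list[RepeatElement]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for e in self.elements:
            self.by_family.setdefault(e.family, []).append(e)
            self._trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e)
        # per-family consensus sequences, known only for synthetic catalogs
        self.consensus = consensus or {}

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def families(self) -> list[str]:
        return sorted(self.by_family)

    def query(self, chrom: str, start: int, end: int) -> list[RepeatElement]:
        """Elements overlapping [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda e: (e.start, e.end, e.name))
        return hits


def _parse_ucsc_row(fields, row_no):
    """UCSC rmsk tab table row; tolerates the leading bin column or a minimal
    6-column (genoName, genoStart, genoEnd, strand, repName, repFamily) layout."""
    try:
        if len(fields) >= 13:  # bin swScore milliDiv milliDel milliIns genoName ...
            chrom, start, end = fields[5], int(fields[6]), int(fields[7])
            strand, name, family = fields[9], fields[10], fields[12]
        elif len(fields) == 12:  # same but without the bin column
            chrom, start, end = fields[4], int(fields[5]), int(fields[6])
            strand, name, family = fields[8], fields[9], fields[11]
        elif len(fields) == 6:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand, name, family = fields[3], fields[4], fields[5]
        else:
            raise ValueError(f"unexpected column count {len(fields)}")
    except (ValueError, IndexError) as exc:
        raise RepeatCatalogError(f"rmsk row {row_no}: cannot parse ({exc})") from exc
    return chrom, start, end, strand, name, family


def _parse_out_row(fields, row_no):
    """RepeatMasker .out row: 1-based inclusive start, strand 'C' for minus."""
    try:
        chrom = fields[4]
        start = int(fields[5]) - 1
        end = int(fields[6])
        strand = "-" if fields[8] in ("C", "-") else "+"
        name = fields[9]
        family = fields[10]
    except (ValueError, IndexError) as exc:
        raise RepeatCatalogError(f"rmsk row {row_no}: cannot parse ({exc})") from exc
    return chrom, start, end, strand, name, family


def load_repeat_mask(rmsk_path, reference=None) -> RepeatCatalog:
    """Load a repeat annotation table.

    Accepts both the UCSC rmsk tab table (0-based starts, optional bin column
    and '#' header) and RepeatMasker .out (1-based starts, whitespace columns,
    banner header); the dialect is auto-detected from the header shape. Rows on
    chromosomes absent from ``reference`` (when given) are dropped and counted.
    """
    with open(rmsk_path) as fh:
        lines = fh.read().splitlines()

    is_out = False
    body_start = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body_start = i + 1
            continue
        first_fields = stripped.split()
        if first_fields and first_fields[0] in ("SW", "score"):
            # RepeatMasker .out banner spans two header lines
            is_out = True
            body_start = i + 2
        else:
            body_start = i
        break

    elements = []
    dropped = 0
    for row_no, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if is_out:
            chrom, start, end, strand, name, family = _parse_out_row(line.split(), row_no)
        else:
            chrom, start, end, strand, name, family = _parse_ucsc_row(
                line.rstrip("\n").split("\t"), row_no
            )
        if reference is not None and chrom not in reference:
            dropped += 1
            continue
        if reference is not None and end > len(reference[chrom]):
            raise RepeatCatalogError(
                f"rmsk row {row_no}: element end {end} beyond {chrom} length"
            )
        try:
            elements.append(RepeatElement(chrom, start, end, strand, family, name))
        except RepeatCatalogError as exc:
            raise RepeatCatalogError(f"rmsk row {row_no}: {exc}") from exc
    if dropped:
        log.info("dropped %d rmsk rows on chromosomes absent from reference", dropped)
    return RepeatCatalog(elements)


def write_repeat_mask(catalog: RepeatCatalog, out_path) -> None:
    """Write the minimal 6-column tab table this package reads back."""
    with open(out_path, "w") as fh:
        fh.write("#genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepFamily\n")
        for e in catalog.elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.strand}\t{e.name}\t{e.family}\n")


def compatible_element_pairs(
    catalog: RepeatCatalog,
    min_shared: int,
    strand_rule: str = "any",
    max_span: int | None = None,
    inter_chrom: bool = False,
) -> list[tuple[RepeatElement, RepeatElement]]:
    """Enumerate same-family element pairs eligible to mediate a rearrangement.

    Each element must be at least ``min_shared`` bp long (the homologous tract
    a junction can share). ``strand_rule`` is one of ``same`` / ``opposite`` /
    ``any``. Same-chromosome pairs must be non-overlapping (first element
    entirely before the second) and span at most ``max_span``; with
    ``inter_chrom`` pairs on different chromosomes are returned instead and the
    span rule is vacuous. Output order is deterministic.
    """
    if strand_rule not in ("same", "opposite", "any"):
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    pairs = []
    for family in sorted(catalog.by_family):
        elems = [e for e in catalog.by_family[family] if e.length >= min_shared]
        elems.sort(key=lambda e: (e.chrom, e.start, e.end, e.name))
        for i, e1 in enumerate(elems):
            for e2 in elems[i + 1 :]:
                if inter_chrom:
                    if e1.chrom == e2.chrom:
                        continue
                else:
                    if e1.chrom != e2.chrom:
                        continue
                    if e2.start < e1.end:  # overlapping or out of order
                        continue
                    if max_span is not None and e2.end - e1.start > max_span:
                        continue
                if strand_rule == "same" and e1.strand != e2.strand:
                    continue
                if strand_rule == "opposite" and e1.strand == e2.strand:
                    continue
                pairs.append((e1, e2))
    return pairs
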