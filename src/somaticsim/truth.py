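"""Truth annotation: reference-projected copy number, BAF, LOH, and outputs.

Every chromosome copy of a clone genome is projected back onto reference
coordinates through its interval map and the germline liftover; maximal runs
of constant parental copy counts (copies_A, copies_B) become segments. A
segment is LOH when one parental count is zero while at least one copy
remains; its expected BAF for the allele on parental haplotype B is
copies_B / total. Foreign-insertion bases have no reference projection and
appear in the clone FASTA and event tables but not in segments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .germline import GermlineVariant, hap_to_ref_intervals
from .model import GenomeModel
from .reference import write_fasta
from .sv import SVEvent

log = logging.getLogger(__name__)


class TruthError(RuntimeError):
    pass


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    copies_A: int
    copies_B: int

    @property
    def total_cn(self) -> int:
        return self.copies_A + self.copies_B

    @property
    def loh(self) -> bool:
        return min(self.copies_A, self.copies_B) == 0 and self.total_cn >= 1

    @property
    def expected_baf_B(self) -> float | None:
        if self.total_cn < 1:
            return None
        return self.copies_B / self.total_cn


def perbase_copy_counts(genome: GenomeModel) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-base parental copy-count arrays (A, B) per reference chromosome."""
    ref = genome.reference
    counts = {
        c: (np.zeros(len(ref[c]), dtype=np.int32), np.zeros(len(ref[c]), dtype=np.int32))
        for c in ref.names
    }
    for copy in genome.all_copies():
        for p in copy.part.pieces:
            if p.is_foreign:
                continue
            blocks = genome.liftover[(p.chrom, p.hap)]
            arr = counts[p.chrom][0 if p.hap == "A" else 1]
            for rs, re_ in hap_to_ref_intervals(blocks, p.start, p.end):
                arr[rs:re_] += 1
    return counts


def derive_segments(clone_or_model) -> list[Segment]:
    """Segment the reference into maximal runs of constant (copies_A, copies_B).

    Accepts a Clone or a bare GenomeModel. Segments tile every chromosome
    exactly, with no gaps, overlaps, or zero-length segments.
    """
    genome = getattr(clone_or_model, "genome", clone_or_model)
    counts = perbase_copy_counts(genome)
    segments: list[Segment] = []
    for chrom in genome.reference.names:
        a, b = counts[chrom]
        n = len(a)
        change = np.nonzero((np.diff(a) != 0) | (np.diff(b) != 0))[0] + 1
        bounds = np.concatenate([[0], change, [n]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(chrom, int(s), int(e), int(a[s]), int(b[s])))
    return segments


def segments_to_frame(segments: list[Segment], clone_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": clone_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "copies_A": s.copies_A,
                "copies_B": s.copies_B,
                "total_cn": s.total_cn,
                "loh": s.loh,
                "expected_baf": np.nan if s.expected_baf_B is None else s.expected_baf_B,
            }
            for s in segments
        ]
    )


def annotate_baf(segments: list[Segment], het_loci: list[GermlineVariant]) -> pd.DataFrame:
    """Expected BAF of each phased heterozygous germline locus.

    The alternate allele sits on the locus's carrier haplotype; its expected
    BAF is (copies of carrier) / total. Loci falling in zero-copy segments get
    NaN (no sequence remains to carry either allele).
    """
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    starts = {c: np.array([s.start for s in lst]) for c, lst in by_chrom.items()}
    rows = []
    for v in het_loci:
        if v.zygosity != "het":
            raise TruthError(f"locus at {v.chrom}:{v.pos} is not heterozygous")
        lst = by_chrom.get(v.chrom)
        if lst is None:
            raise TruthError(f"locus on unknown chromosome {v.chrom}")
        i = int(np.searchsorted(starts[v.chrom], v.pos, side="right") - 1)
        seg = lst[i]
        carrier = seg.copies_A if v.carrier == "hapA" else seg.copies_B
        baf = carrier / seg.total_cn if seg.total_cn >= 1 else np.nan
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "carrier": v.carrier,
                "copies_A": seg.copies_A,
                "copies_B": seg.copies_B,
                "expected_baf": baf,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "carrier", "copies_A",
                                       "copies_B", "expected_baf"])


def events_to_frame(events: list[SVEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        e1 = e2 = ""
        if ev.mediating_elements:
            e1, e2 = (m.name for m in ev.mediating_elements)
        rows.append(
            {
                "event_id": ev.event_id,
                "type": ev.spec.sv_type,
                "mechanism": ev.spec.mechanism,
                "copy_id": ev.copy_id,
                "partner_copy_id": ev.partner_copy_id or "",
                "size": "" if ev.size_realized is None else ev.size_realized,
                "balanced": ev.balanced,
                "n_breakpoints": len(ev.breakpoints),
                "mediating_element_1": e1,
                "mediating_element_2": e2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "type", "mechanism", "copy_id", "partner_copy_id",
            "size", "balanced", "n_breakpoints",
            "mediating_element_1", "mediating_element_2",
        ],
    )


def _bedpe_side(proj):
    if proj is None:
        return (".", 0, 1)
    chrom, pos = proj
    return (chrom, pos, pos + 1)


def event_bedpe_rows(event: SVEvent) -> list[tuple]:
    """Junction rows for the BEDPE file.

    Accounting: DEL/TDUP/INS/CTX_UNBAL one row; INV one row spanning its two
    junctions' outer flanks; ITX two rows (excision + insertion site);
    CTX_BAL two rows (one per derived chromosome).
    """
    bps = [b for b in event.breakpoints if b.left_context or b.right_context]
    t = event.spec.sv_type
    rows = []

    def row(side1, side2, mh_len):
        c1, s1, e1 = _bedpe_side(side1)
        c2, s2, e2 = _bedpe_side(side2)
        return (c1, s1, e1, c2, s2, e2, event.event_id,
                f"{t}:{event.spec.mechanism}", mh_len)

    if t in ("DEL", "TDUP", "CTX_UNBAL"):
        bp = bps[0]
        rows.append(row(bp.ref_left, bp.ref_right, len(bp.microhomology)))
    elif t == "INS":
        rows.append(row(bps[0].ref_left, bps[1].ref_right, len(bps[0].microhomology)))
    elif t == "INV":
        rows.append(row(bps[0].ref_left, bps[1].ref_right, len(bps[0].microhomology)))
    elif t == "ITX":
        rows.append(row(bps[0].ref_left, bps[0].ref_right, len(bps[0].microhomology)))
        rows.append(row(bps[1].ref_left, bps[2].ref_right, len(bps[1].microhomology)))
    elif t == "CTX_BAL":
        for bp in bps[:2]:
            rows.append(row(bp.ref_left, bp.ref_right, len(bp.microhomology)))
    return rows


@dataclass
class TruthTables:
    fasta: str
    events: str
    breakpoints: str
    segments: str
    loh_bed: str
    baf: str | None
    aneuploidy: str
    segment_list: list[Segment]


def write_outputs(clone, out_dir, het_loci: list[GermlineVariant] | None = None) -> TruthTables:
    """Write a clone's FASTA and complete truth set into ``out_dir``.

    Files: genome.fa (one record per chromosome copy, named
    ``<chrom>_<copy_id>``), events.tsv, breakpoints.bedpe (0-based
    half-open), segments.tsv, loh.bed, baf.tsv (if het loci are supplied),
    aneuploidy.tsv.
    """
    from .aneuploidy import write_aneuploidy_log

    os.makedirs(out_dir, exist_ok=True)
    genome = clone.genome

    fasta_path = os.path.join(out_dir, "genome.fa")
    records = [
        (f"{c.chrom}_{c.copy_id}", c.sequence) for c in genome.all_copies()
    ]
    write_fasta(records, fasta_path)

    events_path = os.path.join(out_dir, "events.tsv")
    ev_df = events_to_frame(clone.events)
    ev_df.to_csv(events_path, sep="\t", index=False)

    bedpe_path = os.path.join(out_dir, "breakpoints.bedpe")
    n_bedpe = 0
    with open(bedpe_path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tevent_id\t"
            "type_mechanism\tmicrohomology_len\n"
        )
        for ev in clone.events:
            for r in event_bedpe_rows(ev):
                fh.write("\t".join(str(x) for x in r) + "\n")
                n_bedpe += 1

    segments = derive_segments(clone)
    seg_path = os.path.join(out_dir, "segments.tsv")
    segments_to_frame(segments, clone.clone_id).to_csv(seg_path, sep="\t", index=False)

    loh_path = os.path.join(out_dir, "loh.bed")
    with open(loh_path, "w") as fh:
        for s in segments:
            if s.loh:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tCN{s.total_cn}\n")

    baf_path = None
    if het_loci is not None:
        baf_path = os.path.join(out_dir, "baf.tsv")
        annotate_baf(segments, [v for v in het_loci if v.zygosity == "het"]).to_csv(
            baf_path, sep="\t", index=False
        )

    aneu_path = os.path.join(out_dir, "aneuploidy.tsv")
    write_aneuploidy_log(clone.aneuploidy_log, aneu_path)

    log.info(
        "clone %s: wrote %d copies, %d events, %d junction rows, %d segments",
        clone.clone_id, len(records), len(clone.events), n_bedpe, len(segments),
    )
    return TruthTables(fasta_path, events_path, bedpe_path, seg_path, loh_path,
                       baf_path, aneu_path, segments)
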