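"""Germline SNV/INDEL simulation and construction of a diploid personal genome.

Somatic copy-number analysis leans on B-allele frequencies at heterozygous
germline loci, so the tumor simulation starts from a personal genome: the
reference plus simulated SNVs and small INDELs (< 50 bp) at user-specified
transition/transversion, het/hom and INDEL/SNV ratios. The two resulting
haplotypes carry liftover maps back to reference coordinates, which later
stages use to project rearranged tumor chromosomes onto the reference.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceGenome

log = logging.getLogger(__name__)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class GermlineError(ValueError):
    pass


@dataclass
class GermlineParams:
    """Knobs of the germline simulation.

    Defaults approximate commonly reported human whole-genome statistics:
    transition/transversion ~2, het/hom ~1.5, one INDEL per ten SNVs, and a
    short-tailed (geometric, p=0.3) INDEL size distribution truncated at 49 bp.
    """

    snv_count: int = 10_000
    titv_ratio: float = 2.0
    het_hom_ratio: float = 1.5
    indel_snv_ratio: float = 0.1
    indel_size_p: float = 0.3
    indel_max_size: int = 49
    seed: int = 0

    def __post_init__(self):
        if self.snv_count < 0:
            raise GermlineError("snv_count must be >= 0")
        if self.titv_ratio <= 0 or self.het_hom_ratio <= 0:
            raise GermlineError("ratios must be positive")
        if self.indel_snv_ratio < 0:
            raise GermlineError("indel_snv_ratio must be >= 0")
        if not (1 <= self.indel_max_size < 50):
            raise GermlineError("INDEL sizes must stay below 50 bp")


@dataclass(frozen=True)
class GermlineVariant:
    """VCF-style anchored variant (0-based pos; alleles share the anchor base
    for INDELs). ``carrier`` is hapA/hapB for het, both for hom."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # "het" | "hom"
    carrier: str  # "hapA" | "hapB" | "both"

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise GermlineError("ref and alt alleles must differ")
        if self.zygosity == "het" and self.carrier not in ("hapA", "hapB"):
            raise GermlineError("het variant must name a single carrier haplotype")
        if self.zygosity == "hom" and self.carrier != "both":
            raise GermlineError("hom variant carrier must be 'both'")

    @property
    def footprint(self) -> int:
        return len(self.ref_allele)

    @property
    def indel_size(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


# A liftover block maps haplotype bases [hap_start, hap_start+length) onto
# reference bases [ref_start, ref_start+length); inserted bases fall between
# blocks and map to nothing.
Block = tuple[int, int, int]


@dataclass
class PersonalGenome:
    reference: ReferenceGenome
    haplotypes: dict[str, dict[str, str]]  # chrom -> {"A": seq, "B": seq}
    liftover: dict[tuple[str, str], list[Block]] = field(default_factory=dict)

    def hap_length(self, chrom: str, hap: str) -> int:
        return len(self.haplotypes[chrom][hap])


def hap_to_ref_intervals(blocks: list[Block], a: int, b: int) -> list[tuple[int, int]]:
    """Project haplotype interval [a, b) onto the reference (matched parts only)."""
    out = []
    starts = [blk[0] for blk in blocks]
    i = max(0, bisect_right(starts, a) - 1)
    for hs, rs, n in blocks[i:]:
        if hs >= b:
            break
        lo, hi = max(a, hs), min(b, hs + n)
        if lo < hi:
            out.append((rs + (lo - hs), rs + (hi - hs)))
    return out


def ref_to_hap_interval(blocks: list[Block], s: int, e: int) -> tuple[int, int] | None:
    """Haplotype interval for reference [s, e), or None unless it sits inside a
    single matched block (i.e. no germline INDEL interrupts it)."""
    for hs, rs, n in blocks:
        if rs <= s and e <= rs + n:
            return (hs + (s - rs), hs + (e - rs))
        if rs > s:
            break
    return None


def ref_to_hap_point(blocks: list[Block], pos: int) -> int | None:
    iv = ref_to_hap_interval(blocks, pos, pos + 1)
    return None if iv is None else iv[0]


def simulate_germline_variants(
    ref: ReferenceGenome, params: GermlineParams
) -> list[GermlineVariant]:
    """Draw SNVs and INDELs with non-overlapping reference footprints.

    Exactly ``snv_count`` SNVs and ``round(snv_count * indel_snv_ratio)``
    INDELs are placed uniformly over non-N positions; each SNV is a transition
    with probability titv/(titv+1), each variant heterozygous with probability
    hhr/(hhr+1), het carriers split evenly between the two haplotypes.
    """
    rng = np.random.default_rng(params.seed)
    n_indel = round(params.snv_count * params.indel_snv_ratio)
    n_total = params.snv_count + n_indel

    # (kind, size) specs in random order; sizes drawn up front so footprints
    # are known during placement
    specs: list[tuple[str, int]] = [("SNV", 0)] * params.snv_count
    for _ in range(n_indel):
        size = int(rng.geometric(params.indel_size_p))
        while size > params.indel_max_size:
            size = int(rng.geometric(params.indel_size_p))
        kind = "INS" if rng.random() < 0.5 else "DEL"
        specs.append((kind, size))
    order = rng.permutation(n_total)
    specs = [specs[i] for i in order]

    chrom_lens = [len(ref[c]) for c in ref.names]
    cum = np.concatenate([[0], np.cumsum(chrom_lens)])
    total_len = int(cum[-1])
    if total_len < n_total * 2:
        raise GermlineError("reference too small for requested variant count")

    # Greedy placement over a sorted batch of candidate positions; specs are
    # consumed in shuffled order so variant kind is independent of position.
    placements: list[tuple[str, int, str, int]] = []  # chrom, pos, kind, size
    for _attempt in range(10):
        m = min(total_len, 2 * n_total + 1024)
        offsets = np.sort(rng.choice(total_len, size=m, replace=False))
        placements = []
        last_ci, last_end = -1, -1
        si = 0
        for off in offsets:
            if si >= n_total:
                break
            ci = int(np.searchsorted(cum, off, side="right") - 1)
            pos = int(off - cum[ci])
            kind, size = specs[si]
            fp = size + 1 if kind == "DEL" else 1
            if ci == last_ci and pos < last_end:
                continue
            if pos + fp > chrom_lens[ci]:
                continue
            chrom = ref.names[ci]
            if "N" in ref[chrom][pos : pos + fp]:
                continue
            placements.append((chrom, pos, kind, size))
            last_ci, last_end = ci, pos + fp
            si += 1
        if si >= n_total:
            break
    else:
        raise GermlineError(
            f"could not place {n_total} variants after retry budget"
        )

    variants = []
    for chrom, pos, kind, size in placements:
        het = rng.random() < params.het_hom_ratio / (params.het_hom_ratio + 1.0)
        if het:
            zyg, carrier = "het", ("hapA" if rng.random() < 0.5 else "hapB")
        else:
            zyg, carrier = "hom", "both"
        base = ref[chrom][pos]
        if kind == "SNV":
            is_ts = rng.random() < params.titv_ratio / (params.titv_ratio + 1.0)
            if is_ts:
                alt = _TRANSITION[base]
            else:
                alt = _TRANSVERSIONS[base][rng.integers(2)]
            variants.append(GermlineVariant(chrom, pos, base, alt, zyg, carrier))
        elif kind == "INS":
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
            variants.append(GermlineVariant(chrom, pos, base, base + ins, zyg, carrier))
        else:  # DEL
            refal = ref[chrom][pos : pos + size + 1]
            variants.append(GermlineVariant(chrom, pos, refal, base, zyg, carrier))

    variants.sort(key=lambda v: (ref.names.index(v.chrom), v.pos))
    log.info("simulated %d SNVs + %d INDELs", params.snv_count, n_indel)
    return variants


def apply_germline(ref: ReferenceGenome, variants: list[GermlineVariant]) -> PersonalGenome:
    """Apply phased variants to build the two haplotype sequence sets.

    Variants must be sorted with non-overlapping footprints. Homozygous
    variants enter both haplotypes; heterozygous ones only their carrier.
    Liftover maps record matched blocks between haplotype and reference
    coordinates (SNVs do not break blocks; INDELs do).
    """
    by_chrom: dict[str, list[GermlineVariant]] = {c: [] for c in ref.names}
    prev_key = (-1, -1)
    for v in variants:
        if v.chrom not in by_chrom:
            raise GermlineError(f"variant on unknown chromosome {v.chrom}")
        if ref[v.chrom][v.pos : v.pos + len(v.ref_allele)] != v.ref_allele:
            raise GermlineError(
                f"ref allele mismatch for variant at {v.chrom}:{v.pos} "
                f"(expected {v.ref_allele!r})"
            )
        key = (ref.names.index(v.chrom), v.pos)
        if key < prev_key:
            raise GermlineError("variants must be sorted by chromosome and position")
        prev_key = key
        by_chrom[v.chrom].append(v)

    haplotypes: dict[str, dict[str, str]] = {}
    liftover: dict[tuple[str, str], list[Block]] = {}
    for chrom in ref.names:
        haplotypes[chrom] = {}
        for hap, hap_name in (("A", "hapA"), ("B", "hapB")):
            carried = [
                v for v in by_chrom[chrom] if v.carrier in ("both", hap_name)
            ]
            seq = bytearray(ref[chrom], "ascii")
            for v in carried:
                if v.is_snv:
                    seq[v.pos] = ord(v.alt_allele)
            parts: list[bytes] = []
            blocks: list[Block] = []
            cursor = 0  # reference coordinate
            hap_off = 0
            for v in carried:
                if v.is_snv:
                    continue
                # matched block up to and including the anchor base
                n = v.pos + 1 - cursor
                parts.append(bytes(seq[cursor : v.pos + 1]))
                blocks.append((hap_off, cursor, n))
                hap_off += n
                if len(v.alt_allele) > len(v.ref_allele):  # insertion
                    ins = v.alt_allele[1:]
                    parts.append(ins.encode())
                    hap_off += len(ins)
                    cursor = v.pos + 1
                else:  # deletion
                    cursor = v.pos + len(v.ref_allele)
            if cursor < len(seq):
                parts.append(bytes(seq[cursor:]))
                blocks.append((hap_off, cursor, len(seq) - cursor))
            haplotypes[chrom][hap] = b"".join(parts).decode()
            liftover[(chrom, hap)] = blocks
    return PersonalGenome(ref, haplotypes, liftover)


def write_personal_fasta(pg: PersonalGenome, out_path) -> None:
    from .reference import write_fasta

    records = []
    for chrom in pg.reference.names:
        records.append((f"{chrom}_hapA", pg.haplotypes[chrom]["A"]))
        records.append((f"{chrom}_hapB", pg.haplotypes[chrom]["B"]))
    write_fasta(records, out_path)


def write_germline_vcf(
    variants: list[GermlineVariant], out_path, reference: ReferenceGenome | None = None
) -> None:
    """Write variants as VCF 4.2 (1-based POS, GT phased to the carrier:
    hapA-het 1|0, hapB-het 0|1, hom 1|1)."""
    order = {} if reference is None else {c: i for i, c in enumerate(reference.names)}
    prev = None
    for v in variants:
        key = (order.get(v.chrom, 0), v.chrom, v.pos)
        if prev is not None and key < prev:
            raise GermlineError("variants must be sorted before writing VCF")
        prev = key
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if reference is not None:
            for chrom in reference.names:
                fh.write(f"##contig=<ID={chrom},length={len(reference[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in variants:
            if v.zygosity == "hom":
                gt = "1|1"
            else:
                gt = "1|0" if v.carrier == "hapA" else "0|1"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_germline_vcf(vcf_path, ref: ReferenceGenome) -> list[GermlineVariant]:
    """Reload a phased single-sample VCF into variant objects."""
    import pysam

    variants = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            gt = rec.samples[0]["GT"]
            if gt == (1, 1):
                zyg, carrier = "hom", "both"
            elif gt == (1, 0):
                zyg, carrier = "het", "hapA"
            elif gt == (0, 1):
                zyg, carrier = "het", "hapB"
            else:
                raise GermlineError(f"unsupported genotype {gt} at {rec.chrom}:{rec.pos}")
            variants.append(
                GermlineVariant(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], zyg, carrier)
            )
    variants.sort(key=lambda v: (ref.names.index(v.chrom), v.pos))
    return variants
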