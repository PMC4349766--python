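"""Somatic SV engine: planning, breakpoint placement, and sequence surgery.

Six event types are simulated — insertion (INS), deletion (DEL), inversion
(INV), tandem duplication (TDUP), balanced/unbalanced inter-chromosomal
translocation (CTX_BAL / CTX_UNBAL) and intra-chromosomal translocation with
inverted orientation (ITX) — under three breakpoint mechanisms:

* NONHOM: breakpoints drawn uniformly over eligible positions; each junction
  is given a micro-homology tract of a length drawn uniformly on [0, 20] bp,
  engineered into the junction-flanking sequence;
* HOM: both breakpoints fall at homologous offsets inside two compatible
  repeat elements of the same family (inversions need opposite strands,
  deletions/duplications the same strand, translocations elements on
  different chromosomes), producing long-homology junctions that are hard for
  split-read callers;
* FOREIGN: insertion of novel sequence sharing no 30-mer with the reference
  (insertions only — a comparatively rare mechanism).

Every event targets exactly one chromosome copy, which is what generates
allele-specific copy-number change and LOH.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ChromosomeCopy, GenomeModel, Part, foreign_piece, kmers_of
from .repeats import RepeatCatalog, RepeatElement, compatible_element_pairs

log = logging.getLogger(__name__)

SV_TYPES = ("INS", "DEL", "INV", "TDUP", "CTX_BAL", "CTX_UNBAL", "ITX")
MECHANISMS = ("NONHOM", "HOM", "FOREIGN")

MAX_MICROHOM = 20  # bp; ceiling for engineered non-homologous micro-homology
CONTEXT_LEN = 40  # bp of source context kept per junction side
MIN_FLANK = 50  # bp; breakpoints keep this distance from existing junctions

# number of novel junctions each event type creates, in canonical order
N_JUNCTIONS = {
    "DEL": 1, "TDUP": 1, "INV": 2, "INS": 2, "ITX": 3,
    "CTX_BAL": 2, "CTX_UNBAL": 1,
}

DEFAULT_MECHANISM_WEIGHTS = {"NONHOM": 0.6, "HOM": 0.35, "FOREIGN": 0.05}


class PlacementError(RuntimeError):
    pass


class StaleEventError(RuntimeError):
    pass


@dataclass(frozen=True)
class SVEventSpec:
    sv_type: str
    mechanism: str
    size: int

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "FOREIGN" and self.sv_type != "INS":
            raise ValueError("FOREIGN mechanism is only defined for insertions")
        if self.size < 1:
            raise ValueError("size must be >= 1")


@dataclass
class Breakpoint:
    """One realized junction (or broken end) on a chromosome copy.

    ``position`` is the post-event copy coordinate of the junction;
    ``ref_left``/``ref_right`` are (chrom, pos) reference projections of the
    bases flanking it (None where the base is foreign or unmapped). The
    context strings hold the source sequence that would have continued on
    either side, enabling independent recomputation of the micro-homology.
    """

    copy_id: str
    position: int
    microhomology: str = ""
    ref_left: tuple | None = None
    ref_right: tuple | None = None
    left_context: str = ""
    right_context: str = ""


@dataclass
class SVEvent:
    event_id: str
    spec: SVEventSpec
    copy_id: str
    interval: tuple | None = None  # (a, b) pre-event copy coords
    insert_pos: int | None = None
    partner_copy_id: str | None = None
    partner_pos: int | None = None
    donor_copy_id: str | None = None
    donor_interval: tuple | None = None
    inserted_sequence: str = ""
    mediating_elements: tuple | None = None
    mh_lengths: tuple | None = None  # per-junction engineered lengths (NONHOM)
    balanced: bool = True
    size_realized: int | None = None
    expected_len: int | None = None
    partner_expected_len: int | None = None
    breakpoints: list[Breakpoint] = field(default_factory=list)
    applied: bool = False


# -- planning -----------------------------------------------------------------


def log_uniform_size_dist(min_bp: int = 1000, max_bp: int = 1_000_000):
    """Log-uniform SV size sampler between min_bp and max_bp."""
    lo, hi = math.log(min_bp), math.log(max_bp)

    def sample(rng: np.random.Generator) -> int:
        return max(min_bp, int(round(math.exp(rng.uniform(lo, hi)))))

    return sample


def plan_events(
    n_events: int,
    type_weights: dict[str, float] | None = None,
    mechanism_weights: dict[str, float] | None = None,
    size_dist=None,
    seed: int = 0,
) -> list[SVEventSpec]:
    """Draw ``n_events`` event specs (type, mechanism, size) multinomially.

    The FOREIGN mechanism applies only to insertions; for other types the
    mechanism is drawn from NONHOM/HOM renormalized.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    tw = type_weights or {t: 1.0 for t in SV_TYPES}
    mw = mechanism_weights or dict(DEFAULT_MECHANISM_WEIGHTS)
    for weights, names in ((tw, SV_TYPES), (mw, MECHANISMS)):
        if any(weights.get(n, 0.0) < 0 for n in names):
            raise ValueError("weights must be non-negative")
    types = [t for t in SV_TYPES if tw.get(t, 0.0) > 0]
    if not types:
        raise ValueError("all type weights are zero")
    tp = np.array([tw[t] for t in types], dtype=float)
    tp /= tp.sum()
    mechs = [m for m in MECHANISMS if mw.get(m, 0.0) > 0]
    if not mechs:
        raise ValueError("all mechanism weights are zero")
    sizer = size_dist or log_uniform_size_dist()

    specs = []
    for _ in range(n_events):
        sv_type = types[rng.choice(len(types), p=tp)]
        cand = mechs if sv_type == "INS" else [m for m in mechs if m != "FOREIGN"]
        if not cand:
            cand = ["NONHOM"]
        mp = np.array([mw[m] for m in cand], dtype=float)
        mp /= mp.sum()
        mech = cand[rng.choice(len(cand), p=mp)]
        specs.append(SVEventSpec(sv_type, mech, sizer(rng)))
    return specs


# -- micro-homology oracle ----------------------------------------------------


def junction_homology(sequence: str, junction_pos: int, reference_context) -> int:
    """Longest tract at a junction explainable by either side's source context.

    ``reference_context`` is (left_continuation, right_preceding): the bases
    that would have continued past the junction on the left side's source, and
    the bases that preceded the right side's source. Returns max of the
    forward match of sequence[junction_pos:] against the continuation and the
    backward match of sequence[:junction_pos] against the preceding context.
    """
    lc, rc = reference_context
    if not (0 <= junction_pos <= len(sequence)):
        raise ValueError("junction position outside sequence")
    f = 0
    while (
        f < len(lc)
        and junction_pos + f < len(sequence)
        and sequence[junction_pos + f] == lc[f]
    ):
        f += 1
    b = 0
    while (
        b < len(rc)
        and junction_pos - 1 - b >= 0
        and sequence[junction_pos - 1 - b] == rc[len(rc) - 1 - b]
    ):
        b += 1
    return max(f, b)


def _homology_string(sequence: str, pos: int, lc: str, rc: str) -> str:
    n = junction_homology(sequence, pos, (lc, rc))
    f = junction_homology(sequence, pos, (lc, ""))
    if f == n:
        return sequence[pos : pos + n]
    return sequence[pos - n : pos]


# -- foreign sequence ---------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_foreign_insertion(
    length: int, model: GenomeModel, rng: np.random.Generator, k: int = 30,
    retries: int = 50,
) -> str:
    """Novel sequence sharing no exact ``k``-mer with either reference strand.

    Sequences shorter than ``k`` are novel by vacuous truth of the criterion.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    for _ in range(retries):
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if length < k:
            return seq
        ref_kmers = model.reference_kmers(k)
        if all(km not in ref_kmers for km in kmers_of(seq, k)):
            return seq
    raise PlacementError(f"could not draw a novel sequence of length {length}")


# -- placement ----------------------------------------------------------------


def _pos_ok(copy: ChromosomeCopy, pos: int, boundaries: list[int],
            min_flank: int = MIN_FLANK, check_n: bool = True) -> bool:
    L = len(copy)
    if pos < min_flank or pos > L - min_flank:
        return False
    i = bisect_left(boundaries, pos)
    for j in (i - 1, i):
        if 0 <= j < len(boundaries) and abs(boundaries[j] - pos) < min_flank:
            return False
    if check_n:
        w = copy.part.seq[max(0, pos - MAX_MICROHOM - 1) : pos + MAX_MICROHOM + 1]
        if "N" in w:
            return False
    return True


def place_nonhomologous(
    model: GenomeModel,
    spec: SVEventSpec,
    rng: np.random.Generator,
    min_flank: int = MIN_FLANK,
    retries: int = 1000,
) -> SVEvent:
    """Place an event with uniformly random breakpoints.

    Each junction gets a micro-homology length drawn uniformly on
    [0, MAX_MICROHOM]; the sequence surgery in :func:`apply_event` makes the
    junction flanks share exactly that many bases.
    """
    t = spec.sv_type
    copies = model.all_copies()
    if not copies:
        raise PlacementError("model has no chromosome copies")
    last_err = "no eligible placement"
    for _ in range(retries):
        mh = tuple(int(x) for x in rng.integers(0, MAX_MICROHOM + 1, size=N_JUNCTIONS[t]))
        if t in ("CTX_BAL", "CTX_UNBAL"):
            c1 = copies[rng.integers(len(copies))]
            others = [c for c in copies if c.chrom != c1.chrom]
            if not others:
                last_err = "translocation needs two distinct chromosomes"
                continue
            c2 = others[rng.integers(len(others))]
            if len(c1) < 2 * min_flank + 1 or len(c2) < 2 * min_flank + 1:
                last_err = "copy too short to host a translocation cut"
                continue
            b1, b2 = c1.part.boundaries(), c2.part.boundaries()
            if t == "CTX_UNBAL":
                # the lost terminal segment is the event's size
                if len(c1) < spec.size + 2 * min_flank:
                    last_err = "copy too short for the unbalanced segment loss"
                    continue
                p1 = len(c1) - spec.size
            else:
                p1 = int(rng.integers(min_flank, len(c1) - min_flank + 1))
            p2 = int(rng.integers(min_flank, len(c2) - min_flank + 1))
            if not (_pos_ok(c1, p1, b1, min_flank) and _pos_ok(c2, p2, b2, min_flank)):
                last_err = "translocation cut too close to an existing junction or N"
                continue
            return SVEvent(
                "", spec, c1.copy_id, partner_copy_id=c2.copy_id,
                insert_pos=p1, partner_pos=p2, mh_lengths=mh,
                balanced=(t == "CTX_BAL"),
                size_realized=(len(c1) - p1) if t == "CTX_UNBAL" else None,
                expected_len=len(c1), partner_expected_len=len(c2),
            )
        copy = copies[rng.integers(len(copies))]
        L = len(copy)
        bnd = copy.part.boundaries()
        if t == "INS":
            size = spec.size
            donor = copies[rng.integers(len(copies))]
            if len(donor) < size + 2 or L < 2 * min_flank + 1:
                last_err = "no copy long enough to donate or host the insertion"
                continue
            da = int(rng.integers(0, len(donor) - size + 1))
            p = int(rng.integers(min_flank, L - min_flank + 1))
            if not _pos_ok(copy, p, bnd, min_flank):
                last_err = "insertion site too close to an existing junction or N"
                continue
            return SVEvent(
                "", spec, copy.copy_id, insert_pos=p,
                donor_copy_id=donor.copy_id, donor_interval=(da, da + size),
                mh_lengths=mh, size_realized=size, expected_len=L,
            )
        if t == "ITX":
            size = spec.size
            if L < size + 4 * min_flank:
                last_err = "copy too short for intra-chromosomal translocation"
                continue
            a = int(rng.integers(min_flank, L - size - min_flank + 1))
            b = a + size
            tlen = L - size
            q = int(rng.integers(min_flank, tlen - min_flank + 1))
            q_orig = q if q <= a else q + size
            if abs(q - a) < min_flank:
                last_err = "reinsertion point too close to excision site"
                continue
            if not (
                _pos_ok(copy, a, bnd, min_flank)
                and _pos_ok(copy, b, bnd, min_flank)
                and _pos_ok(copy, q_orig, bnd, min_flank)
            ):
                last_err = "ITX breakpoint too close to an existing junction or N"
                continue
            return SVEvent(
                "", spec, copy.copy_id, interval=(a, b), insert_pos=q,
                mh_lengths=mh, size_realized=size, expected_len=L,
            )
        # DEL / INV / TDUP
        size = spec.size
        if L < size + 2 * min_flank:
            last_err = f"copy too short for {t} of size {size}"
            continue
        a = int(rng.integers(min_flank, L - size - min_flank + 1))
        b = a + size
        if not (_pos_ok(copy, a, bnd, min_flank) and _pos_ok(copy, b, bnd, min_flank)):
            last_err = f"{t} breakpoint too close to an existing junction or N"
            continue
        return SVEvent(
            "", spec, copy.copy_id, interval=(a, b), mh_lengths=mh,
            size_realized=size, expected_len=L,
        )
    raise PlacementError(f"non-homologous placement failed after {retries} tries: {last_err}")


def place_foreign(
    model: GenomeModel,
    spec: SVEventSpec,
    rng: np.random.Generator,
    min_flank: int = MIN_FLANK,
    retries: int = 1000,
) -> SVEvent:
    """Insertion of novel (non-template) sequence at a random breakpoint."""
    if spec.sv_type != "INS":
        raise PlacementError("foreign-sequence mechanism only applies to insertions")
    copies = model.all_copies()
    payload = make_foreign_insertion(spec.size, model, rng)
    for _ in range(retries):
        copy = copies[rng.integers(len(copies))]
        bnd = copy.part.boundaries()
        if len(copy) < 2 * min_flank + 1:
            continue
        p = int(rng.integers(min_flank, len(copy) - min_flank + 1))
        if not _pos_ok(copy, p, bnd, min_flank):
            continue
        return SVEvent(
            "", spec, copy.copy_id, insert_pos=p, inserted_sequence=payload,
            size_realized=spec.size, expected_len=len(copy),
        )
    raise PlacementError("foreign insertion placement failed after retries")


def _elem_copy_interval(model: GenomeModel, copy: ChromosomeCopy, elem: RepeatElement):
    """Copy-coordinate interval of a repeat element, if the element is still
    intact on this copy (inside a single forward piece with no germline INDEL
    interrupting it)."""
    from .germline import ref_to_hap_interval

    off = 0
    for p in copy.part.pieces:
        if p.chrom == elem.chrom and p.strand == "+" and not p.is_foreign:
            hi = ref_to_hap_interval(model.liftover[(p.chrom, p.hap)], elem.start, elem.end)
            if hi is not None and p.start <= hi[0] and hi[1] <= p.end:
                return (off + hi[0] - p.start, off + hi[1] - p.start)
        off += p.length
    return None


def _elem_breakpoint(interval: tuple[int, int], elem: RepeatElement, u: int) -> int:
    """Copy coordinate of the breakpoint at consensus offset ``u``."""
    ca, ce = interval
    return ca + u if elem.strand == "+" else ce - u


def place_homologous(
    model: GenomeModel,
    catalog: RepeatCatalog,
    spec: SVEventSpec,
    rng: np.random.Generator,
    min_shared: int = 100,
    min_flank: int = MIN_FLANK,
    retries: int = 100,
) -> SVEvent:
    """Place an event whose breakpoints sit at homologous offsets inside two
    compatible repeat elements of the same family.

    Strand rules: deletions and tandem duplications need same-strand pairs,
    inversions opposite strands, translocations same-strand pairs on different
    chromosomes; homology-mediated insertions copy the segment between a
    same-strand pair and paste it at the matching offset of a third family
    member. ITX has no homologous geometry here; callers should fall back to
    the non-homologous mechanism.
    """
    t = spec.sv_type
    if t == "ITX":
        raise PlacementError(
            "no homologous geometry for ITX; fall back to non-homologous placement"
        )
    if len(catalog) == 0:
        raise PlacementError("repeat catalog is empty; fall back to non-homologous")
    # keep the realized size near the requested one: the distance between the
    # mediating elements is the event size, so bound the pair span by it
    max_span = max(4 * spec.size, 10_000)
    if t == "INV":
        pairs = compatible_element_pairs(catalog, min_shared, "opposite", max_span=max_span)
    elif t in ("CTX_BAL", "CTX_UNBAL"):
        pairs = compatible_element_pairs(catalog, min_shared, "same", inter_chrom=True)
    else:  # DEL, TDUP, INS
        pairs = compatible_element_pairs(catalog, min_shared, "same", max_span=max_span)
        if t == "INS":
            pairs = [p for p in pairs if p[0].strand == "+" and p[1].strand == "+"]
    if not pairs:
        raise PlacementError(
            f"no compatible repeat pair for {t}; fall back to non-homologous placement"
        )

    all_copies = model.all_copies()  # translocations make copies mosaics, so
    # an element may reside on a copy housed under another chromosome
    order = rng.permutation(len(pairs))
    tried = 0
    for idx in order:
        if tried >= retries:
            break
        tried += 1
        e1, e2 = pairs[idx]
        u = int(rng.integers(1, min(e1.length, e2.length)))
        if t in ("CTX_BAL", "CTX_UNBAL"):
            cands1 = list(all_copies)
            cands2 = list(all_copies)
            rng.shuffle(cands1)
            rng.shuffle(cands2)
            for c1 in cands1:
                i1 = _elem_copy_interval(model, c1, e1)
                if i1 is None:
                    continue
                p1 = _elem_breakpoint(i1, e1, u)
                if not _pos_ok(c1, p1, c1.part.boundaries(), min_flank, check_n=False):
                    continue
                for c2 in cands2:
                    if c2.copy_id == c1.copy_id:
                        continue
                    i2 = _elem_copy_interval(model, c2, e2)
                    if i2 is None:
                        continue
                    p2 = _elem_breakpoint(i2, e2, u)
                    if not _pos_ok(c2, p2, c2.part.boundaries(), min_flank, check_n=False):
                        continue
                    return SVEvent(
                        "", spec, c1.copy_id, partner_copy_id=c2.copy_id,
                        insert_pos=p1, partner_pos=p2,
                        mediating_elements=(e1, e2),
                        balanced=(t == "CTX_BAL"),
                        size_realized=(len(c1) - p1) if t == "CTX_UNBAL" else None,
                        expected_len=len(c1), partner_expected_len=len(c2),
                    )
            continue
        # same-chromosome geometries: both elements must sit on one copy
        cands = list(all_copies)
        rng.shuffle(cands)
        for copy in cands:
            i1 = _elem_copy_interval(model, copy, e1)
            i2 = _elem_copy_interval(model, copy, e2)
            if i1 is None or i2 is None:
                continue
            b1 = _elem_breakpoint(i1, e1, u)
            b2 = _elem_breakpoint(i2, e2, u)
            a, b = min(b1, b2), max(b1, b2)
            if b - a < 2:
                continue
            bnd = copy.part.boundaries()
            if not (_pos_ok(copy, a, bnd, min_flank, check_n=False)
                    and _pos_ok(copy, b, bnd, min_flank, check_n=False)):
                continue
            if t in ("DEL", "INV", "TDUP"):
                return SVEvent(
                    "", spec, copy.copy_id, interval=(a, b),
                    mediating_elements=(e1, e2), size_realized=b - a,
                    expected_len=len(copy),
                )
            # INS: copy the segment between the pair, paste at a third element
            family = [
                e3 for e3 in catalog.by_family[e1.family]
                if e3 not in (e1, e2) and e3.strand == "+" and e3.length > u
            ]
            if not family:
                continue
            e3 = family[rng.integers(len(family))]
            targets = list(all_copies)
            rng.shuffle(targets)
            for tgt in targets:
                i3 = _elem_copy_interval(model, tgt, e3)
                if i3 is None:
                    continue
                p = _elem_breakpoint(i3, e3, u)
                if tgt.copy_id == copy.copy_id and a <= p <= b:
                    continue
                if not _pos_ok(tgt, p, tgt.part.boundaries(), min_flank, check_n=False):
                    continue
                ev = SVEvent(
                    "", spec, tgt.copy_id, insert_pos=p,
                    donor_copy_id=copy.copy_id, donor_interval=(a, b),
                    mediating_elements=(e1, e2), size_realized=b - a,
                    expected_len=len(tgt),
                )
                return ev
    raise PlacementError(
        f"homologous placement failed for {t} after {tried} candidate pairs; "
        "fall back to non-homologous placement"
    )


# -- application --------------------------------------------------------------


def _other_base(rng: np.random.Generator, avoid: str) -> int:
    choices = [b for b in b"ACGT" if chr(b) != avoid]
    return choices[rng.integers(len(choices))]


def _engineer(seq: bytearray, jpos: int, lc: str, rc: str, h: int,
              rng: np.random.Generator) -> str:
    """Force the junction at ``jpos`` to have micro-homology exactly ``h``.

    Writes the first ``h`` bases of the left side's continuation over the
    right side of the junction, then breaks any accidental extension on
    either side with a single substitution.
    """
    h = min(h, len(lc), len(seq) - jpos)
    if h == len(lc) and h > 0:
        h -= 1  # keep one context base available as the forced mismatch
    for i in range(h):
        seq[jpos + i] = ord(lc[i])
    if h < len(lc) and jpos + h < len(seq) and chr(seq[jpos + h]) == lc[h]:
        seq[jpos + h] = _other_base(rng, lc[h])
    if rc and jpos - 1 >= 0 and chr(seq[jpos - 1]) == rc[-1]:
        seq[jpos - 1] = _other_base(rng, rc[-1])
    return lc[:h]


def _ledger_delta(event: SVEvent) -> int:
    t = event.spec.sv_type
    if t == "DEL":
        return -(event.interval[1] - event.interval[0])
    if t == "TDUP":
        return event.interval[1] - event.interval[0]
    if t == "INS":
        if event.inserted_sequence:
            return len(event.inserted_sequence)
        return event.donor_interval[1] - event.donor_interval[0]
    if t == "CTX_UNBAL":
        return -(event.expected_len - event.insert_pos)
    return 0  # INV, ITX, CTX_BAL


def _build_fragments(model: GenomeModel, event: SVEvent):
    """Construct post-event Parts plus junction descriptors.

    Returns (new_parts: {copy_id: Part}, junctions: [(copy_id, pos, lc, rc)],
    extra_breakpoints). Junction order is the canonical order used by
    ``mh_lengths``.
    """
    K = CONTEXT_LEN
    t = event.spec.sv_type
    copy = model.get(event.copy_id)
    S = copy.part
    s = S.seq
    L = len(S)

    if t == "DEL":
        a, b = event.interval
        new = S.slice(0, a) + S.slice(b, L)
        junc = [(copy.copy_id, a, s[a : a + K], s[max(0, b - K) : b])]
        return {copy.copy_id: new}, junc, []

    if t == "TDUP":
        a, b = event.interval
        new = S.slice(0, b) + S.slice(a, b) + S.slice(b, L)
        junc = [(copy.copy_id, b, s[b : b + K], s[max(0, a - K) : a])]
        return {copy.copy_id: new}, junc, []

    if t == "INV":
        a, b = event.interval
        from .reference import revcomp

        new = S.slice(0, a) + S.slice(a, b).rc() + S.slice(b, L)
        junc = [
            (copy.copy_id, a, s[a : a + K], revcomp(s[b : b + K])),
            (copy.copy_id, b, revcomp(s[max(0, a - K) : a]), s[max(0, b - K) : b]),
        ]
        return {copy.copy_id: new}, junc, []

    if t == "INS":
        p = event.insert_pos
        if event.inserted_sequence:
            payload = Part(event.inserted_sequence, [foreign_piece(len(event.inserted_sequence))])
            d_lc, d_rc = "", ""
        else:
            donor = model.get(event.donor_copy_id)
            da, db = event.donor_interval
            payload = donor.part.slice(da, db)
            ds = donor.part.seq
            d_rc = ds[max(0, da - K) : da]
            d_lc = ds[db : db + K]
        new = S.slice(0, p) + payload + S.slice(p, L)
        junc = [
            (copy.copy_id, p, s[p : p + K], d_rc),
            (copy.copy_id, p + len(payload), d_lc, s[max(0, p - K) : p]),
        ]
        return {copy.copy_id: new}, junc, []

    if t == "ITX":
        from .reference import revcomp

        a, b = event.interval
        q = event.insert_pos  # position in post-excision coordinates
        mid = S.slice(a, b).rc()
        trunk = S.slice(0, a) + S.slice(b, L)
        new = trunk.slice(0, q) + mid + trunk.slice(q, len(trunk))
        exc_pos = a if a < q else a + len(mid)
        # excision junction joins s[a-1] to s[b]: continuation is the excised
        # start, preceding context is the excised end
        junc = [
            (copy.copy_id, exc_pos, s[a : a + K], s[max(0, b - K) : b]),
            (copy.copy_id, q, trunk.seq[q : q + K], revcomp(s[b : b + K])),
            (copy.copy_id, q + len(mid), revcomp(s[max(0, a - K) : a]),
             trunk.seq[max(0, q - K) : q]),
        ]
        return {copy.copy_id: new}, junc, []

    if t in ("CTX_BAL", "CTX_UNBAL"):
        partner = model.get(event.partner_copy_id)
        S2 = partner.part
        s2 = S2.seq
        p1, p2 = event.insert_pos, event.partner_pos
        new1 = S.slice(0, p1) + S2.slice(p2, len(S2))
        junc = [(copy.copy_id, p1, s[p1 : p1 + K], s2[max(0, p2 - K) : p2])]
        extra = []
        if t == "CTX_BAL":
            new2 = S2.slice(0, p2) + S.slice(p1, L)
            junc.append((partner.copy_id, p2, s2[p2 : p2 + K], s[max(0, p1 - K) : p1]))
        else:
            new2 = S2.slice(0, p2)
            # the donor's broken end: recorded as a breakpoint, not a junction
            extra.append(Breakpoint(partner.copy_id, p2))
        return {copy.copy_id: new1, partner.copy_id: new2}, junc, extra

    raise ValueError(f"unknown SV type {t!r}")


def apply_event(model: GenomeModel, event: SVEvent,
                rng: np.random.Generator | None = None) -> GenomeModel:
    """Apply one SV event, rewriting sequence and interval maps.

    Fills ``event.breakpoints`` with the realized junctions (engineered
    micro-homology for the non-homologous mechanism, the naturally occurring
    homology otherwise) and asserts the base-count ledger: the model's total
    base count changes by exactly +size for INS/TDUP, -size for DEL, the lost
    terminal for unbalanced CTX, and zero otherwise. Events must be applied at
    the coordinates they were placed at (stale coordinates raise).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    copy = model.get(event.copy_id)
    if event.expected_len is not None and len(copy) != event.expected_len:
        raise StaleEventError(
            f"event {event.event_id}: copy {event.copy_id} length changed since "
            "placement; events must be applied in issuance order"
        )
    if event.partner_copy_id is not None and event.partner_expected_len is not None:
        if len(model.get(event.partner_copy_id)) != event.partner_expected_len:
            raise StaleEventError(
                f"event {event.event_id}: partner copy length changed since placement"
            )
    before = model.total_bases()
    expected_delta = _ledger_delta(event)

    new_parts, junctions, extra_bps = _build_fragments(model, event)

    engineer = event.spec.mechanism == "NONHOM" and event.mh_lengths is not None
    seqs = {cid: bytearray(part.seq, "ascii") for cid, part in new_parts.items()}
    mh_iter = iter(event.mh_lengths or ())
    staged: list[tuple[str, int, str, str, str | None]] = []
    for cid, jpos, lc, rc in junctions:
        if engineer:
            h = next(mh_iter)
            mh_str = _engineer(seqs[cid], jpos, lc, rc, h, rng)
        else:
            mh_str = None
        staged.append((cid, jpos, lc, rc, mh_str))

    final_parts = {
        cid: Part(seqs[cid].decode(), new_parts[cid].pieces) for cid in new_parts
    }

    breakpoints: list[Breakpoint] = []
    for cid, jpos, lc, rc, mh_str in staged:
        part = final_parts[cid]
        if mh_str is None:
            mh_str = _homology_string(part.seq, jpos, lc, rc)
        breakpoints.append(
            Breakpoint(
                cid, jpos, mh_str,
                ref_left=model.project_point(part, jpos - 1) if jpos > 0 else None,
                ref_right=model.project_point(part, jpos) if jpos < len(part) else None,
                left_context=lc, right_context=rc,
            )
        )
    for bp in extra_bps:
        part = final_parts[bp.copy_id]
        bp.ref_left = model.project_point(part, bp.position - 1) if bp.position > 0 else None
        breakpoints.append(bp)

    for cid, part in final_parts.items():
        model.get(cid).part = part

    after = model.total_bases()
    if after - before != expected_delta:
        raise ModelLedgerError(
            f"event {event.event_id}: base ledger off by "
            f"{(after - before) - expected_delta}"
        )
    event.breakpoints = breakpoints
    event.applied = True
    return model


class ModelLedgerError(RuntimeError):
    pass


def realize_spec(
    model: GenomeModel,
    spec: SVEventSpec,
    rng: np.random.Generator,
    catalog: RepeatCatalog | None = None,
    event_id: str = "",
    min_shared: int = 100,
) -> SVEvent:
    """Place and apply one event, falling back from the homologous to the
    non-homologous mechanism when no compatible repeat pair is available."""
    mech = spec.mechanism
    if mech == "FOREIGN":
        event = place_foreign(model, spec, rng)
    elif mech == "HOM" and catalog is not None:
        try:
            event = place_homologous(model, catalog, spec, rng, min_shared=min_shared)
        except PlacementError as exc:
            log.debug("HOM placement fell back to NONHOM: %s", exc)
            event = place_nonhomologous(model, replace(spec, mechanism="NONHOM"), rng)
    elif mech == "HOM":
        event = place_nonhomologous(model, replace(spec, mechanism="NONHOM"), rng)
    else:
        event = place_nonhomologous(model, spec, rng)
    event.event_id = event_id
    apply_event(model, event, rng)
    return event
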