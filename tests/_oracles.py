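"""Independent oracles used by the test suite.

These deliberately take different computational routes than the package:
per-base arrays instead of interval arithmetic, naive string editing instead
of block splicing, O(n^2) enumeration instead of indexed lookup.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ref_pos_array(blocks, hap_len: int) -> np.ndarray:
    """For every haplotype base, its reference position (-1 if inserted)."""
    arr = np.full(hap_len, -1, dtype=np.int64)
    for hs, rs, n in blocks:
        arr[hs : hs + n] = np.arange(rs, rs + n)
    return arr


def oracle_perbase_counts(model):
    """Brute-force per-base parental copy counts via explicit position arrays."""
    ref = model.reference
    counts = {
        c: (np.zeros(len(ref[c]), dtype=np.int64), np.zeros(len(ref[c]), dtype=np.int64))
        for c in ref.names
    }
    pos_cache = {}
    for copy in model.all_copies():
        for p in copy.part.pieces:
            if p.is_foreign:
                continue
            key = (p.chrom, p.hap)
            if key not in pos_cache:
                blocks = model.liftover[key]
                # bases past the last matched block are inserted and map to
                # nothing, so sizing by the last block end is sufficient
                hap_len = max(hs + n for hs, _, n in blocks)
                pos_cache[key] = ref_pos_array(blocks, hap_len)
            positions = pos_cache[key][p.start : p.end]
            positions = positions[positions >= 0]
            arr = counts[p.chrom][0 if p.hap == "A" else 1]
            np.add.at(arr, positions, 1)
    return counts


def naive_haplotype(ref_seq: str, variants, hap_name: str) -> str:
    """Apply variants to a reference string by direct editing, end to start."""
    carried = sorted(
        (v for v in variants if v.carrier in ("both", hap_name)),
        key=lambda v: v.pos,
        reverse=True,
    )
    seq = ref_seq
    for v in carried:
        seq = seq[: v.pos] + v.alt_allele + seq[v.pos + len(v.ref_allele) :]
    return seq


def brute_force_pairs(catalog, min_shared, strand_rule, max_span=None, inter_chrom=False):
    """All-pairs enumeration of compatible repeat elements."""
    out = []
    elems = sorted(catalog.elements, key=lambda e: (e.family, e.chrom, e.start, e.end, e.name))
    for i, e1 in enumerate(elems):
        for e2 in elems:
            if e1 is e2 or e1.family != e2.family:
                continue
            if e1.length < min_shared or e2.length < min_shared:
                continue
            if inter_chrom:
                if e1.chrom == e2.chrom:
                    continue
                if (e2, e1) in out:
                    continue
            else:
                if e1.chrom != e2.chrom or e2.start < e1.end:
                    continue
                if max_span is not None and e2.end - e1.start > max_span:
                    continue
            if strand_rule == "same" and e1.strand != e2.strand:
                continue
            if strand_rule == "opposite" and e1.strand == e2.strand:
                continue
            out.append((e1, e2))
    return out


def binom_interval(n: int, p: float, alpha: float = 0.001):
    """Exact central binomial interval covering 1 - alpha."""
    lo = stats.binom.ppf(alpha / 2, n, p)
    hi = stats.binom.ppf(1 - alpha / 2, n, p)
    return int(lo), int(hi)


def string_kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
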