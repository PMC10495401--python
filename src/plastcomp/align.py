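"""Collinear pairwise genome alignment and variant extraction.

The two plastomes are assumed collinear after at most one round of block
reorientation (the biology of the study pair: identical gene content,
haplotypes differing only in block orientation). The aligner is anchor
based: k-mers unique in both genomes (on either strand) seed maximal
exact matches; anchors are chained; minus-strand blocks are flipped back
by an explicit query transform; the short inter-anchor segments are then
aligned globally with affine gap costs, yielding a base-level column map
from which SNVs and left-normalized indels are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .codons import revcomp

DEFAULT_K = 21
DEFAULT_MAX_GAP = 20_000

#: alignment scoring for inter-anchor segments (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = (1.0, -1.0, -4.0, -1.0)


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match. For strand -1, ``ref[ref_pos + t]`` pairs with
    the complement of ``qry[qry_pos + length - 1 - t]``."""

    ref_pos: int
    qry_pos: int
    length: int
    strand: int = 1

    @property
    def ref_end(self) -> int:
        return self.ref_pos + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_pos + self.length


@dataclass(frozen=True)
class Op:
    """One alignment segment. ``match``: equal-length, base-to-base columns;
    ``gap_ref``: extra query bases (insertion); ``gap_qry``: missing query
    bases (deletion); ``unaligned``: segment too large to align."""

    type: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int


@dataclass
class AlignmentMap:
    ops: list[Op]
    ref_len: int
    qry_len: int

    def validate(self) -> None:
        pos = 0
        for op in self.ops:
            if op.ref_start != pos:
                raise ValueError(f"ops do not tile the reference at {pos}")
            pos = op.ref_end
        if pos != self.ref_len:
            raise ValueError("ops do not reach the end of the reference")


@dataclass(frozen=True)
class Variant:
    vtype: str  # SNV | insertion | deletion
    ref_pos: int  # 0-based; for indels, position left of the event
    ref_allele: str
    alt_allele: str
    normalized: bool = True

    def key(self) -> tuple:
        return (self.vtype, self.ref_pos, self.ref_allele, self.alt_allele)


@dataclass
class QueryTransform:
    """Maps the deposited query to its reorientation (flipped intervals)."""

    qry_len: int
    flips: list[tuple[int, int]] = field(default_factory=list)

    def apply(self, qry: str) -> str:
        s = qry
        for a, b in self.flips:
            s = s[:a] + revcomp(s[a:b]) + s[b:]
        return s

    @property
    def is_identity(self) -> bool:
        return not self.flips


class CollinearityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Anchors


def _kmer_counts_and_pos(seq: str, k: int) -> tuple[dict, dict]:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
        if w not in pos:
            pos[w] = i
    return counts, pos


def find_anchors(ref_seq: str, qry_seq: str, k: int = DEFAULT_K) -> list[Anchor]:
    """Maximal exact matches seeded by k-mers unique in both genomes.

    A k-mer counts as unique in a genome when it occurs exactly once over
    both strands. Seeds on the same diagonal are merged and extended to
    maximal exact matches; anchors are returned sorted by ref_pos.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
    rc_ref, rc_qry = revcomp(ref_seq), revcomp(qry_seq)
    cr, _ = _kmer_counts_and_pos(ref_seq, k)
    crr, _ = _kmer_counts_and_pos(rc_ref, k)
    cq, pq = _kmer_counts_and_pos(qry_seq, k)
    cqr, _ = _kmer_counts_and_pos(rc_qry, k)
    nq = len(qry_seq)

    # raw seed matches: (ref_pos, qry_pos, strand)
    fwd: dict[int, list[int]] = {}  # diagonal j - i -> sorted ref positions
    rev: dict[int, list[int]] = {}  # anti-diagonal i + j -> sorted ref positions
    for i in range(len(ref_seq) - k + 1):
        w = ref_seq[i : i + k]
        if "N" in w:
            continue
        wrc = revcomp(w)
        if cr.get(w, 0) + crr.get(w, 0) != 1:
            continue
        total_q = cq.get(w, 0) + cqr.get(w, 0)
        if total_q != 1:
            continue
        if w in pq:
            j = pq[w]
            fwd.setdefault(j - i, []).append(i)
        else:
            # w appears on the reverse strand: revcomp(w) is forward in qry
            j = pq[wrc]
            rev.setdefault(i + j, []).append(i)

    anchors: list[Anchor] = []
    for diag, ivals in fwd.items():
        for i0, i1 in _runs(ivals):
            rs, re = i0, i1 + k  # ref interval
            qs = rs + diag
            # extend
            while rs > 0 and qs > 0 and ref_seq[rs - 1] == qry_seq[qs - 1] \
                    and ref_seq[rs - 1] != "N":
                rs -= 1
                qs -= 1
            qe = qs + (re - rs)
            while re < len(ref_seq) and qe < nq and ref_seq[re] == qry_seq[qe] \
                    and ref_seq[re] != "N":
                re += 1
                qe += 1
            anchors.append(Anchor(rs, qs, re - rs, 1))
    comp_qry = qry_seq.translate(str.maketrans("ACGTN", "TGCAN"))
    for anti, ivals in rev.items():
        for i0, i1 in _runs(ivals):
            rs, re = i0, i1 + k
            # ref[t] pairs with comp(qry[anti + k - 1 - t])
            off = anti + k - 1
            while rs > 0 and off - rs + 1 < nq and ref_seq[rs - 1] == comp_qry[off - rs + 1] \
                    and ref_seq[rs - 1] != "N":
                rs -= 1
            while re < len(ref_seq) and off - re >= 0 and ref_seq[re] == comp_qry[off - re] \
                    and ref_seq[re] != "N":
                re += 1
            qs = off - re + 1
            anchors.append(Anchor(rs, qs, re - rs, -1))
    anchors = sorted(set(anchors), key=lambda a: (a.ref_pos, a.qry_pos))
    if not anchors:
        raise CollinearityError(f"no unique {k}-mer anchors found; try a smaller k")
    return anchors


def _runs(sorted_vals: list[int]):
    """Maximal runs of consecutive integers, as (first, last) pairs."""
    vals = sorted(sorted_vals)
    start = prev = vals[0]
    for v in vals[1:]:
        if v == prev + 1:
            prev = v
            continue
        yield start, prev
        start = prev = v
    yield start, prev


# ---------------------------------------------------------------------------
# Orientation and chaining


def _chain_lis(anchors: list[Anchor]) -> list[Anchor]:
    """Max-weight chain monotone in both genomes (weight = anchor length).

    Deterministic: ties prefer the chain reaching further left in the
    reference (smaller ref_pos of the earliest anchor).
    """
    anchors = sorted(anchors, key=lambda a: (a.ref_pos, a.qry_pos))
    n = len(anchors)
    best = [0.0] * n
    prev = [-1] * n
    for i, a in enumerate(anchors):
        best[i] = float(a.length)
        for j in range(i):
            b = anchors[j]
            # strictly ordered starts/ends; chance extension may overlap a little
            if b.ref_pos < a.ref_pos and b.qry_pos < a.qry_pos \
                    and b.ref_end <= a.ref_pos + 30 and b.qry_end <= a.qry_pos + 30 \
                    and b.ref_end <= a.ref_end and b.qry_end <= a.qry_end:
                cand = best[j] + a.length
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -anchors[i].ref_pos))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def orient_and_chain(anchors: list[Anchor], ref_len: int, qry_len: int,
                     min_block: int = 100, slack: int = 30
                     ) -> tuple[list[Anchor], QueryTransform]:
    """Resolve block orientation and return a monotone anchor chain.

    Minus-strand anchor groups (contiguous in reference order, with at
    least ``min_block`` bp of anchor support) define intervals of the query
    to reverse-complement; boundaries are taken from the abutting
    plus-strand anchor extents, which pin the breakpoints exactly when the
    flanking sequence is anchored. The returned chain is expressed in
    reoriented-query coordinates. Interleaved blocks that cannot be laid
    out collinearly raise ``CollinearityError``.
    """
    big = [a for a in anchors if a.length >= min_block // 2]
    if not big:
        big = anchors
    minus_support = sum(a.length for a in big if a.strand == -1)
    if minus_support < min_block:
        chain = _chain_lis([a for a in anchors if a.strand == 1])
        return chain, QueryTransform(qry_len=qry_len)

    # contiguous minus groups in ref order
    groups: list[list[Anchor]] = []
    for a in sorted(big, key=lambda x: x.ref_pos):
        if a.strand == -1:
            if groups and groups[-1][-1].strand == -1 and _adjacent(groups[-1], a):
                groups[-1].append(a)
            else:
                groups.append([a])
    flips: list[tuple[int, int]] = []
    plus = [a for a in big if a.strand == 1]
    for g in groups:
        if sum(a.length for a in g) < min_block:
            continue
        qmin = min(a.qry_pos for a in g)
        qmax = max(a.qry_end for a in g)
        left_cands = [a.qry_end for a in plus if a.qry_end <= qmin + slack]
        right_cands = [a.qry_pos for a in plus if a.qry_pos >= qmax - slack]
        b1 = max(left_cands) if left_cands else qmin
        b2 = min(right_cands) if right_cands else qmax
        if b2 <= b1:
            raise CollinearityError("inverted block boundaries could not be resolved")
        flips.append((b1, b2))
    flips.sort()
    for (a1, b1_), (a2, _b2) in zip(flips, flips[1:]):
        if a2 < b1_:
            raise CollinearityError("interleaved inverted blocks cannot be reoriented")
    return [], QueryTransform(qry_len=qry_len, flips=flips)


def _adjacent(group: list[Anchor], a: Anchor, max_gap: int = 5000) -> bool:
    return a.ref_pos - group[-1].ref_end < max_gap


def orient_query(ref_seq: str, qry_seq: str, k: int = DEFAULT_K
                 ) -> tuple[list[Anchor], QueryTransform, str]:
    """Full orientation pass: anchors, transform, reoriented query, final chain.

    When a transform is needed, anchors are recomputed against the
    reoriented query; if minus-strand structure remains the pair is not
    collinear under a single round of reorientation.
    """
    anchors = find_anchors(ref_seq, qry_seq, k)
    chain, transform = orient_and_chain(anchors, len(ref_seq), len(qry_seq))
    if transform.is_identity:
        return chain, transform, qry_seq
    oriented = transform.apply(qry_seq)
    anchors2 = find_anchors(ref_seq, oriented, k)
    chain2, t2 = orient_and_chain(anchors2, len(ref_seq), len(oriented))
    if not t2.is_identity:
        raise CollinearityError(
            "query still contains inverted blocks after one reorientation round"
        )
    return chain2, transform, oriented


# ---------------------------------------------------------------------------
# Base-level alignment


def _aligner(scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    # first gap base costs open+extend, each further base costs extend
    al.open_gap_score = gap_open + gap_extend
    al.extend_gap_score = gap_extend
    return al


def _segment_ops(ref_seg: str, qry_seg: str, r0: int, q0: int,
                 aligner: Align.PairwiseAligner) -> list[Op]:
    if not ref_seg and not qry_seg:
        return []
    if not qry_seg:
        return [Op("gap_qry", r0, r0 + len(ref_seg), q0, q0)]
    if not ref_seg:
        return [Op("gap_ref", r0, r0, q0, q0 + len(qry_seg))]
    aln = aligner.align(ref_seg, qry_seg)[0]
    ops: list[Op] = []
    r_prev = q_prev = 0
    blocks_r, blocks_q = aln.aligned
    for (rs, re), (qs, qe) in zip(blocks_r, blocks_q):
        if rs > r_prev and qs > q_prev:
            # both sides advance without aligned columns: emit as two gaps
            ops.append(Op("gap_qry", r0 + r_prev, r0 + rs, q0 + q_prev, q0 + q_prev))
            ops.append(Op("gap_ref", r0 + rs, r0 + rs, q0 + q_prev, q0 + qs))
        elif rs > r_prev:
            ops.append(Op("gap_qry", r0 + r_prev, r0 + rs, q0 + q_prev, q0 + q_prev))
        elif qs > q_prev:
            ops.append(Op("gap_ref", r0 + rs, r0 + rs, q0 + q_prev, q0 + qs))
        ops.append(Op("match", r0 + rs, r0 + re, q0 + qs, q0 + qe))
        r_prev, q_prev = re, qe
    if r_prev < len(ref_seg) and q_prev < len(qry_seg):
        ops.append(Op("gap_qry", r0 + r_prev, r0 + len(ref_seg), q0 + q_prev, q0 + q_prev))
        ops.append(Op("gap_ref", r0 + len(ref_seg), r0 + len(ref_seg),
                      q0 + q_prev, q0 + len(qry_seg)))
    elif r_prev < len(ref_seg):
        ops.append(Op("gap_qry", r0 + r_prev, r0 + len(ref_seg), q0 + q_prev, q0 + q_prev))
    elif q_prev < len(qry_seg):
        ops.append(Op("gap_ref", r0 + len(ref_seg), r0 + len(ref_seg),
                      q0 + q_prev, q0 + len(qry_seg)))
    return ops


def align_collinear(ref_seq: str, oriented_qry: str, blocks: list[Anchor],
                    max_gap: int = DEFAULT_MAX_GAP,
                    scoring=DEFAULT_SCORING) -> AlignmentMap:
    """Base-level alignment map from a monotone anchor chain.

    Anchor intervals become match segments; inter-anchor segments up to
    ``max_gap`` bp are aligned globally with affine gaps; anything larger
    is recorded as unaligned.
    """
    aligner = _aligner(scoring)
    ops: list[Op] = []
    r_prev = q_prev = 0
    chain = []
    for a in blocks:  # trim chance overlaps between consecutive anchors
        if a.strand != 1:
            raise ValueError("align_collinear expects an oriented (+1) chain")
        trim = max(r_prev - a.ref_pos, q_prev - a.qry_pos, 0)
        if trim >= a.length:
            continue
        a = Anchor(a.ref_pos + trim, a.qry_pos + trim, a.length - trim, 1)
        chain.append(a)
        r_prev, q_prev = a.ref_end, a.qry_end
    r_prev = q_prev = 0
    for a in chain:
        ref_seg = ref_seq[r_prev : a.ref_pos]
        qry_seg = oriented_qry[q_prev : a.qry_pos]
        if max(len(ref_seg), len(qry_seg)) > max_gap:
            ops.append(Op("unaligned", r_prev, a.ref_pos, q_prev, a.qry_pos))
        else:
            ops.extend(_segment_ops(ref_seg, qry_seg, r_prev, q_prev, aligner))
        ops.append(Op("match", a.ref_pos, a.ref_end, a.qry_pos, a.qry_end))
        r_prev, q_prev = a.ref_end, a.qry_end
    ref_seg = ref_seq[r_prev:]
    qry_seg = oriented_qry[q_prev:]
    if max(len(ref_seg), len(qry_seg)) > max_gap:
        ops.append(Op("unaligned", r_prev, len(ref_seq), q_prev, len(oriented_qry)))
    else:
        ops.extend(_segment_ops(ref_seg, qry_seg, r_prev, q_prev, aligner))
    amap = AlignmentMap(ops=[o for o in ops if not (o.ref_start == o.ref_end
                                                    and o.qry_start == o.qry_end)],
                        ref_len=len(ref_seq), qry_len=len(oriented_qry))
    amap.validate()
    return amap


def align_genomes(ref_seq: str, qry_seq: str, k: int = DEFAULT_K,
                  max_gap: int = DEFAULT_MAX_GAP,
                  scoring=DEFAULT_SCORING) -> tuple[AlignmentMap, QueryTransform, str]:
    """Orient, chain and align; returns (map, transform, oriented query)."""
    chain, transform, oriented = orient_query(ref_seq, qry_seq, k)
    amap = align_collinear(ref_seq, oriented, chain, max_gap, scoring)
    return amap, transform, oriented


# ---------------------------------------------------------------------------
# Variant calling


def left_normalize(ref_seq: str, vtype: str, start: int, allele: str
                   ) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement on the reference.

    ``start`` is the 0-based position where the event begins (first deleted
    base, or the base before which the insertion falls). Returns the
    normalized (start, allele).
    """
    if vtype == "deletion":
        size = len(allele)
        while start > 0 and ref_seq[start - 1] == ref_seq[start + size - 1]:
            start -= 1
        return start, ref_seq[start : start + size]
    while start > 0 and allele and ref_seq[start - 1] == allele[-1]:
        allele = ref_seq[start - 1] + allele[:-1]
        start -= 1
    return start, allele


def call_variants(amap: AlignmentMap, ref_seq: str, qry_seq: str) -> list[Variant]:
    """SNVs from mismatch columns, indels from merged gap runs (left-aligned).

    ``qry_seq`` must be the oriented query the map was built against.
    Columns containing N are excluded.
    """
    variants: list[Variant] = []
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1")
    qry_arr = np.frombuffer(qry_seq.encode(), dtype="S1")
    pending: Op | None = None

    def flush(op: Op | None):
        if op is None:
            return
        if op.type == "gap_qry":
            allele = ref_seq[op.ref_start : op.ref_end]
            if "N" in allele:
                return
            start, allele = left_normalize(ref_seq, "deletion", op.ref_start, allele)
            variants.append(Variant("deletion", start - 1, allele, ""))
        elif op.type == "gap_ref":
            allele = qry_seq[op.qry_start : op.qry_end]
            if "N" in allele:
                return
            start, allele = left_normalize(ref_seq, "insertion", op.ref_start, allele)
            variants.append(Variant("insertion", start - 1, "", allele))

    for op in amap.ops:
        if op.type == "match":
            flush(pending)
            pending = None
            r = ref_arr[op.ref_start : op.ref_end]
            q = qry_arr[op.qry_start : op.qry_end]
            diff = np.flatnonzero((r != q) & (r != b"N") & (q != b"N"))
            for d in diff:
                variants.append(Variant(
                    "SNV", op.ref_start + int(d),
                    ref_seq[op.ref_start + int(d)],
                    qry_seq[op.qry_start + int(d)],
                ))
        elif op.type in ("gap_qry", "gap_ref"):
            if pending is not None and pending.type == op.type \
                    and pending.ref_end == op.ref_start and pending.qry_end == op.qry_start:
                pending = Op(op.type, pending.ref_start, op.ref_end,
                             pending.qry_start, op.qry_end)
            else:
                flush(pending)
                pending = op
        else:  # unaligned
            flush(pending)
            pending = None
    flush(pending)
    variants.sort(key=lambda v: (v.ref_pos, v.vtype))
    return variants
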