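"""Independent oracles: brute-force / closed-form re-implementations used to
validate the package's optimized code paths. Each oracle deliberately takes
a different algorithmic route from the implementation it checks."""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def comp(s: str) -> str:
    return s.translate(_COMP)


# ---------------------------------------------------------------------------
# SSRs: exhaustive primitive-run scanner


def _primitive(motif: str) -> bool:
    return all(motif != motif[:p] * (len(motif) // p)
               for p in range(1, len(motif)) if len(motif) % p == 0)


def ssr_scan(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """All maximal primitive-unit runs meeting the copy thresholds, as
    (start, end, motif) triples, by direct per-position comparison."""
    n = len(seq)
    out = set()
    for u, thr in thresholds.items():
        for i in range(n - u * thr + 1):
            motif = seq[i : i + u]
            if "N" in motif or not _primitive(motif):
                continue
            # left-maximality at period u
            if i > 0 and seq[i - 1] == seq[i - 1 + u]:
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            tract = j - i
            copies = tract // u
            if copies >= thr:
                out.add((i, i + u * copies, motif))
    return out


# ---------------------------------------------------------------------------
# Long repeats: per-diagonal full scan (quadratic overall)


def _diag_windows(match: np.ndarray, min_len: int, k: int, min_identity: float):
    """Maximal <=k-mismatch windows over one boolean match vector, trimmed to
    start/end on matches; yields (start, end, n_mismatch)."""
    mm = np.flatnonzero(~match)
    n = len(match)
    cands = []
    m = len(mm)
    if m <= k:
        cands.append((0, n))
    else:
        starts = np.concatenate(([0], mm[: m - k] + 1))
        ends = np.concatenate((mm[k:], [n]))
        ok = np.flatnonzero(ends - starts >= min_len)
        cands = [(int(starts[t]), int(ends[t])) for t in ok]
    for s, e in cands:
        i = int(np.searchsorted(mm, s))
        while i < len(mm) and s < e and mm[i] == s:
            s += 1
            i += 1
        j = int(np.searchsorted(mm, e)) - 1
        while j >= 0 and e > s and mm[j] == e - 1:
            e -= 1
            j -= 1
        c = int(np.searchsorted(mm, e) - np.searchsorted(mm, s))
        L = e - s
        if L >= min_len and c <= k and (L - c) / L > min_identity:
            yield s, e, c


def long_repeat_scan(seq: str, min_len: int = 30, max_mismatch: int = 3,
                     min_identity: float = 0.90) -> set[tuple]:
    """All maximal qualifying repeat pairs as (orientation, pos1, pos2,
    length, mismatches), by scanning every (anti)diagonal in full, then
    applying the same containment suppression rule."""
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype="S1")
    c = np.frombuffer(comp(seq).encode(), dtype="S1")
    valid = a != b"N"
    raw: dict[str, set[tuple]] = {o: set() for o in "FPRC"}
    for orient, other in (("F", a), ("C", c)):
        for d in range(1, n - min_len + 1):
            match = (a[: n - d] == other[d:]) & valid[: n - d] & valid[d:]
            for s, e, mmc in _diag_windows(match, min_len, max_mismatch, min_identity):
                raw[orient].add((s, s + d, e - s, mmc))
    for orient, other in (("R", a), ("P", c)):
        for t in range(min_len - 1, 2 * n - min_len):
            lo = max(0, t - n + 1)
            hi = min(n - 1, t)
            left = slice(lo, hi + 1)
            mirr = slice(t - hi, t - lo + 1)
            match = (a[left] == other[mirr][::-1]) & valid[left] & valid[mirr][::-1]
            for s, e, mmc in _diag_windows(match, min_len, max_mismatch, min_identity):
                x1, x2 = lo + s, lo + e - 1
                y1 = t - x2
                p1, p2 = min(x1, y1), max(x1, y1)
                raw[orient].add((p1, p2, e - s, mmc))
    out = set()
    for orient, reps in raw.items():
        reps = sorted(reps, key=lambda r: (-r[2], r[0], r[1]))
        kept = []
        for r in reps:
            if not any(k[0] <= r[0] and r[0] + r[2] <= k[0] + k[2]
                       and k[1] <= r[1] and r[1] + r[2] <= k[1] + k[2]
                       and k[2] > r[2] for k in kept):
                kept.append(r)
        out |= {(orient, *r) for r in kept}
    return out


# ---------------------------------------------------------------------------
# Synonymous / nonsynonymous: translate-and-compare

_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
TRANSLATE = dict(zip(_CODONS, _AA))


def translate(cds: str) -> str:
    return "".join(TRANSLATE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3))


def snv_label(cds: str, offset: int, alt: str) -> tuple[str, str]:
    """(label, notation) by translating the whole mutated CDS and diffing."""
    mutated = cds[:offset] + alt + cds[offset + 1:]
    p0, p1 = translate(cds), translate(mutated)
    assert len(p0) == len(p1)
    diffs = [i for i, (x, y) in enumerate(zip(p0, p1)) if x != y]
    if not diffs:
        return "synonymous", ""
    assert len(diffs) == 1
    i = diffs[0]
    return "nonsynonymous", f"{p0[i]}{i + 1}{p1[i]}"


# ---------------------------------------------------------------------------
# Jukes-Cantor: closed forms and exhaustive likelihood


def jc_dist(p: float) -> float:
    return -0.75 * math.log(1 - 4 * p / 3)


def jc_p_same(t: float) -> float:
    return 0.25 + 0.75 * math.exp(-4 * t / 3)


def jc_p(t: float, i: int, j: int) -> float:
    e = math.exp(-4 * t / 3)
    return 0.25 + 0.75 * e if i == j else 0.25 - 0.25 * e


def exhaustive_loglik(tree, msa: dict[str, str]) -> float:
    """Brute-force JC likelihood: sum over all internal-node state
    assignments, site by site (feasible only for tiny trees/alignments)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    nodes = list(tree.postorder())
    internal = [nd for nd in nodes if nd.children]
    leaves = [nd for nd in nodes if not nd.children]
    n_sites = len(next(iter(msa.values())))
    total = 0.0
    for site in range(n_sites):
        obs = {id(l): code.get(msa[l.name][site].upper(), None) for l in leaves}
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internal)):
            st = {id(nd): s for nd, s in zip(internal, states)}
            for l in leaves:
                st[id(l)] = obs[id(l)]
            p = 0.25  # root prior
            ok = True
            for nd in internal:
                for ch in nd.children:
                    s_child = st[id(ch)]
                    if s_child is None:  # missing: marginalize this leaf
                        continue
                    p *= jc_p(ch.length, st[id(nd)], s_child)
            if ok:
                site_lik += p
        total += math.log(site_lik)
    return total


# ---------------------------------------------------------------------------
# Global alignment score: quadratic affine-gap DP (Gotoh)


def affine_align_score(x: str, y: str, match=1.0, mismatch=-1.0,
                       gap_open=-4.0, gap_extend=-1.0) -> float:
    """Optimal global alignment score; a length-L gap costs open + L*extend."""
    NEG = -1e18
    n, m = len(x), len(y)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in y (x consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in x
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if x[i - 1] == y[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# Indel left-normalization by exhaustive shift


def leftmost_indel(ref: str, vtype: str, start: int, allele: str) -> tuple[int, str]:
    """Leftmost equivalent placement found by trying every shift and
    comparing the edited strings."""
    def edited(s: int, a: str) -> str:
        if vtype == "deletion":
            return ref[:s] + ref[s + len(a):]
        return ref[:s] + a + ref[s:]

    target = edited(start, allele)
    best = (start, allele)
    size = len(allele)
    for s in range(start - 1, -1, -1):
        a = ref[s : s + size] if vtype == "deletion" else target[s : s + size]
        if edited(s, a) == target:
            best = (s, a)
        else:
            # keep scanning: equivalence can persist through repeat structure
            continue
    return best
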