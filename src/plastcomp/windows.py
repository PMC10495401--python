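"""Repeat-masked sliding-window dissimilarity and divergence hotspots.

Percent dissimilarity between the two genomes is computed in reference
coordinates in sliding windows (defaults 1000 bp, 200 bp step). A
window's denominator is the number of comparable columns — aligned
columns minus masked, N-containing and unaligned ones; the numerator
counts SNV columns plus indel columns, each gap column once (insertion
columns, which have no reference coordinate of their own, are attributed
to the reference position immediately left of the event). Windows whose
dissimilarity exceeds a threshold (strictly greater; default 1.0%) are
merged into hotspots and annotated with their containing or flanking
genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .align import AlignmentMap, Variant
from .genome_io import GeneFeature
from .repeats import LongRepeat

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 200
DEFAULT_THRESHOLD = 1.0


@dataclass
class WindowStat:
    ref_start: int
    ref_end: int
    n_comparable: int
    n_diff: int
    masked_fraction: float

    @property
    def dissimilarity(self) -> float | None:
        """Percent dissimilarity; None when no column is comparable."""
        if self.n_comparable == 0:
            return None
        return 100.0 * self.n_diff / self.n_comparable


@dataclass
class Hotspot:
    ref_start: int
    ref_end: int
    peak: float
    left_gene: str | None
    right_gene: str | None

    @property
    def label(self) -> str:
        if self.left_gene and self.left_gene == self.right_gene:
            return self.left_gene
        return f"{self.left_gene or 'start'}-{self.right_gene or 'end'} intergenic"


def merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def mask_from_repeats(long_repeats: list[LongRepeat], ref_len: int,
                      mask_min: int = 30) -> list[tuple[int, int]]:
    """Union of both copies of every repeat of at least ``mask_min`` bp."""
    ivals = []
    for r in long_repeats:
        if r.length < mask_min:
            continue
        ivals.append((max(0, r.pos1), min(ref_len, r.pos1 + r.length)))
        ivals.append((max(0, r.pos2), min(ref_len, r.pos2 + r.length)))
    return merge_intervals(ivals)


def _column_arrays(amap: AlignmentMap, variants: list[Variant], ref_seq: str,
                   qry_seq: str, mask: list[tuple[int, int]] | None,
                   snv_only: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-reference-position (comparable, diff) counts.

    Each reference position carries the columns attributed to it: its own
    aligned column plus any insertion columns anchored immediately to its
    left side.
    """
    n = amap.ref_len
    comparable = np.zeros(n, dtype=np.int32)
    diff = np.zeros(n, dtype=np.int32)
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1")
    qry_arr = np.frombuffer(qry_seq.encode(), dtype="S1")
    for op in amap.ops:
        if op.type == "match":
            r = ref_arr[op.ref_start : op.ref_end]
            q = qry_arr[op.qry_start : op.qry_end]
            ok = (r != b"N") & (q != b"N")
            comparable[op.ref_start : op.ref_end] = ok
            diff[op.ref_start : op.ref_end] = ok & (r != q)
        elif op.type == "gap_qry" and not snv_only:
            r = ref_arr[op.ref_start : op.ref_end]
            ok = r != b"N"
            comparable[op.ref_start : op.ref_end] = ok
            diff[op.ref_start : op.ref_end] = ok
        elif op.type == "gap_ref" and not snv_only:
            ncols = op.qry_end - op.qry_start
            at = max(op.ref_start - 1, 0)
            comparable[at] += ncols
            diff[at] += ncols
        # unaligned: not comparable
    if mask:
        for s, e in mask:
            comparable[max(0, s) : min(n, e)] = 0
            diff[max(0, s) : min(n, e)] = 0
    return comparable, diff


def window_dissimilarity(
    amap: AlignmentMap,
    ref_seq: str,
    qry_seq: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    mask: list[tuple[int, int]] | None = None,
    variants: list[Variant] | None = None,
    snv_only: bool = False,
) -> list[WindowStat]:
    """Sliding-window statistics over the reference.

    Windows start at 0 with the given step; only full windows are emitted
    (the last window is the final full one). A reference shorter than one
    window yields a single whole-sequence window with a warning.
    """
    if not window >= step > 0:
        raise ValueError("need window >= step > 0")
    ref_len = amap.ref_len
    comparable, diff = _column_arrays(amap, variants or [], ref_seq, qry_seq,
                                      mask, snv_only)
    masked = np.zeros(ref_len, dtype=np.int32)
    for s, e in mask or []:
        masked[max(0, s) : min(ref_len, e)] = 1
    ccum = np.concatenate(([0], np.cumsum(comparable)))
    dcum = np.concatenate(([0], np.cumsum(diff)))
    mcum = np.concatenate(([0], np.cumsum(masked)))
    if ref_len < window:
        warnings.warn("reference shorter than one window; emitting a single window")
        starts = [0]
        window = ref_len
    else:
        starts = range(0, ref_len - window + 1, step)
    out = []
    for s in starts:
        e = s + window
        out.append(WindowStat(
            ref_start=s, ref_end=e,
            n_comparable=int(ccum[e] - ccum[s]),
            n_diff=int(dcum[e] - dcum[s]),
            masked_fraction=float(mcum[e] - mcum[s]) / (e - s),
        ))
    return out


def expected_n_windows(ref_len: int, window: int = DEFAULT_WINDOW,
                       step: int = DEFAULT_STEP) -> int:
    return (ref_len - window) // step + 1 if ref_len >= window else 1


def call_hotspots(windows: list[WindowStat], features: list[GeneFeature],
                  threshold: float = DEFAULT_THRESHOLD) -> list[Hotspot]:
    """Merge qualifying windows (> threshold) and annotate flanking genes.

    Fully masked (undefined) windows never qualify. The annotation names
    the nearest feature on each side, or the containing feature.
    """
    qual = [w for w in windows
            if w.dissimilarity is not None and w.dissimilarity > threshold]
    if not qual:
        return []
    merged = merge_intervals([(w.ref_start, w.ref_end) for w in qual])
    named = sorted((f for f in features if f.ftype in ("CDS", "tRNA", "rRNA")),
                   key=lambda f: f.start)
    out = []
    for s, e in merged:
        peak = max(w.dissimilarity for w in qual if s <= w.ref_start and w.ref_end <= e)
        containing = [f for f in named if f.start <= s and e <= f.end]
        if containing:
            left = right = containing[0].name
        else:
            # window quantization lets hotspots overlap flank-gene edges, so
            # flanks are the last gene starting at/before s and the first
            # ending at/after e
            lefts = [f for f in named if f.start <= s]
            rights = [f for f in named if f.end >= e]
            left = lefts[-1].name if lefts else None
            right = rights[0].name if rights else None
        out.append(Hotspot(s, e, float(peak), left, right))
    return out
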