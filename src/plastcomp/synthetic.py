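"""Synthetic plastome pairs with known ground truth.

The generator emulates the study system: an IRLC-style plastome of
50-150 kb carrying protein-coding ORFs, a few tRNA/rRNA loci and
AT-biased intergenic spacers; a derived genome with a controlled
synonymous/nonsynonymous substitution split, short intergenic indels and
an optional large block inversion; planted SSR arrays and long repeat
pairs of all four orientation classes; and per-gene expression levels
coupled, with configurable noise, to a codon-usage bias gradient (highly
expressed genes use "preferred" codons more, ribosomal-protein genes are
forced to the biased end so they can serve as the MELP reference).

Planted elements are kept clear of each other so every downstream finder
should report each plant exactly once with exact coordinates; intergenic
background remains random (mildly AT-biased), so incidental SSRs or
repeats above threshold can still occur and finders are compared against
oracle scans, not only the plant list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .codons import (
    AA_TO_CODONS, CODON_TO_AA, STOP_CODONS, complement, revcomp, translate_codon,
)
from .genome_io import CountsTable, GeneFeature, PlastomeRecord, write_fasta
from .phylo import Node, parse_newick

BASES = "ACGT"

#: plastome gene symbols, ordered so ribosomal-protein genes appear throughout
GENE_CATALOG = [
    "psbA", "rps2", "atpA", "ndhB", "rpl2", "petA", "rps3", "psaA", "rpoA",
    "rpl16", "ndhF", "rps4", "atpB", "psbB", "rpl14", "rpoB", "rps7", "ycf2",
    "petB", "rps8", "ndhH", "psbC", "rpl20", "rpoC1", "rps11", "atpE", "ndhA",
    "rpl22", "psaB", "rps14", "petD", "rpl23", "ndhC", "rps15", "atpF", "psbD",
    "rpl33", "rpoC2", "rps19", "ndhD", "psaC", "rpl36", "rps18", "atpH",
    "psbE", "ndhE", "petG", "psaI", "atpI", "psbF", "ndhG", "ccsA", "rbcL",
    "psbI", "ndhI", "cemA", "matK", "psbK", "ndhJ", "clpP1", "accD", "psaJ",
    "psbL", "ndhK", "ycf1", "psbM", "ycf3", "infA", "ycf4", "psbN",
]

DEFAULT_SSR_PLAN = [
    ("A", 12, None), ("T", 10, None), ("AT", 6, None), ("AAT", 5, None),
    ("AATT", 4, None), ("AAAAT", 3, None), ("AATGCC", 3, None),
]
DEFAULT_REPEAT_PLAN = [
    (40, "F", 0, None, None), (40, "P", 1, None, None),
    (36, "R", 0, None, None), (34, "C", 2, None, None),
]


@dataclass
class SyntheticConfig:
    genome_length: int = 80_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 1500)
    gc_content: float = 0.36
    n_snv: int = 200
    frac_nonsyn: float = 0.30
    n_intergenic_snv: int = 0
    intergenic_snv_region: tuple[int, int] | None = None
    n_indels: int = 20
    indel_size_range: tuple[int, int] = (1, 20)
    coding_indels: bool = False
    invert_block: tuple[int, int] | str | None = None  # (start, end), "auto", None
    ssr_plan: list | None = None   # (motif, copies, position|None)
    repeat_plan: list | None = None  # (length, orientation, mismatches, pos1|None, pos2|None)
    expression_model: tuple[float, float] = (1.0, 0.2)  # (bias-expression slope, dispersion)
    seed: int = 0

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class TruthVariant:
    vtype: str            # SNV | insertion | deletion
    ref_pos: int          # 0-based; for indels, position left of the event
    ref_allele: str
    alt_allele: str
    context: str = "intergenic"
    gene: str | None = None
    label: str | None = None       # synonymous | nonsynonymous (CDS SNVs)
    notation: str = ""             # e.g. "H447Y" (nonsynonymous only)
    codon_index: int | None = None  # 1-based
    codon_pos: int | None = None    # 1..3

    def key(self) -> tuple:
        return (self.vtype, self.ref_pos, self.ref_allele, self.alt_allele)


@dataclass
class PlantedSSR:
    start: int
    end: int
    motif: str
    copies: int


@dataclass
class PlantedRepeat:
    orientation: str
    pos1: int
    pos2: int
    length: int
    mismatches: int


@dataclass
class Truth:
    variants: list[TruthVariant] = field(default_factory=list)
    ssrs: list[PlantedSSR] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    bias_weight: dict[str, float] = field(default_factory=dict)
    inversion: tuple[int, int] | None = None
    cds: dict[str, str] = field(default_factory=dict)
    expression_model: tuple[float, float] = (1.0, 0.2)

    def gene_summary(self) -> dict[str, dict]:
        """Expected per-gene variant summary (Table-1 layout)."""
        out: dict[str, dict] = {}
        for v in self.variants:
            if v.context != "CDS" or v.vtype != "SNV":
                continue
            row = out.setdefault(
                v.gene, {"n_total": 0, "n_nonsyn": 0, "n_syn": 0, "notations": []}
            )
            row["n_total"] += 1
            if v.label == "nonsynonymous":
                row["n_nonsyn"] += 1
                row["notations"].append((v.codon_index, v.notation))
            else:
                row["n_syn"] += 1
        for row in out.values():
            row["notations"] = [n for _, n in sorted(row["notations"])]
        return out


# ---------------------------------------------------------------------------
# Reference generation


def _preferred_codon(aa: str) -> str:
    """Deterministic 'preferred' codon per family: the most AT-rich, then first."""
    codons = AA_TO_CODONS[aa]
    return max(codons, key=lambda c: (c.count("A") + c.count("T"), c[::-1]))


def _sample_codons(rng: np.random.Generator, n: int, w: float) -> list[str]:
    """Interior codons: uniform amino acids, biased-vs-uniform codon mixture."""
    aas = [aa for aa in AA_TO_CODONS if aa != "*"]
    out = []
    for aa in rng.choice(aas, size=n):
        codons = AA_TO_CODONS[aa]
        if len(codons) == 1 or rng.random() >= w:
            out.append(codons[rng.integers(len(codons))])
        else:
            out.append(_preferred_codon(aa))
    return out


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


class PackingError(ValueError):
    pass


def generate_reference(config: SyntheticConfig) -> tuple[PlastomeRecord, Truth]:
    """Build the reference plastome and its ground truth. Deterministic per seed."""
    rng = config.rng(0)
    truth = Truth(expression_model=tuple(config.expression_model))
    lo, hi = config.gene_length_range
    if lo < 9:
        raise ValueError("genes need at least 3 codons")

    # --- feature plan: CDS genes plus a few tRNA/rRNA loci
    plan: list[tuple[str, str, int]] = []  # (name, ftype, length)
    slope = config.expression_model[0]
    for i in range(config.n_genes):
        name = GENE_CATALOG[i] if i < len(GENE_CATALOG) else f"orf{i + 1}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        plan.append((name, "CDS", 3 * n_codons))
    if config.n_genes >= 2 and config.genome_length >= 20_000:
        for name in ("trnQ", "trnK", "trnE"):
            plan.append((name, "tRNA", 72))
        for name, length in (("rrn16", 1400), ("rrn23", 1500)):
            plan.append((name, "rRNA", length))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    total_feat = sum(l for _, _, l in plan)
    n_spacers = len(plan) + 1
    min_spacer = 200
    slack = config.genome_length - total_feat - n_spacers * min_spacer
    if slack < 0:
        raise PackingError(
            f"cannot pack {len(plan)} features totalling {total_feat} bp plus "
            f"{n_spacers} spacers of >= {min_spacer} bp into {config.genome_length} bp"
        )
    extra = rng.multinomial(slack, np.full(n_spacers, 1.0 / n_spacers)) if slack else [0] * n_spacers
    spacer_lengths = [min_spacer + int(e) for e in extra]

    # --- background, then write features
    ig_gc = max(0.05, config.gc_content - 0.08)
    seq = list(_random_seq(rng, config.genome_length, ig_gc))
    features: list[GeneFeature] = []
    pos = spacer_lengths[0]
    spacers: list[tuple[int, int]] = [(0, spacer_lengths[0])]
    for (name, ftype, length), sp in zip(plan, spacer_lengths[1:]):
        strand = 1 if rng.random() < 0.5 else -1
        if ftype == "CDS":
            n_codons = length // 3
            u = rng.uniform(0.75, 1.0) if name[:3] in ("rps", "rpl") else rng.random()
            w = float(np.clip(slope * u, 0.0, 1.0))
            level = float(10.0 ** (3.0 * u - 1.0))
            stop = ["TAA", "TGA", "TAG"][rng.integers(3)]
            cds = "ATG" + "".join(_sample_codons(rng, n_codons - 2, w)) + stop
            truth.cds[name] = cds
            truth.expression[name] = level
            truth.bias_weight[name] = w
            body = cds if strand == 1 else revcomp(cds)
        else:
            body = _random_seq(rng, length, 0.5)
            strand = 1
        seq[pos : pos + length] = body
        features.append(GeneFeature(name=name, ftype=ftype, parts=[(pos, pos + length)],
                                    strand=strand))
        pos += length
        spacers.append((pos, pos + sp))
        pos += sp

    # --- plant SSRs and long repeats in spacers
    occupied: list[tuple[int, int]] = []
    free: list[list[int]] = [[s + 12, e - 12] for s, e in spacers]

    def claim(length: int, want: int | None = None, pad: int = 12) -> int:
        if want is not None:
            occupied.append((want - pad, want + length + pad))
            return want
        idx = rng.permutation(len(free))
        for i in idx:
            s, e = free[i]
            if e - s >= length + 2 * pad:
                start = s + pad
                free[i][0] = start + length + pad
                occupied.append((start - pad, start + length + pad))
                return start
        raise PackingError(
            f"no intergenic room for a planted element of {length} bp; "
            f"planted so far: {len(truth.ssrs)} SSRs, {len(truth.repeats)} repeats"
        )

    ssr_plan = DEFAULT_SSR_PLAN if config.ssr_plan is None else config.ssr_plan
    if config.n_genes == 0 and config.ssr_plan is None:
        ssr_plan = []
    for motif, copies, want in ssr_plan:
        tract = motif * copies
        start = claim(len(tract), want)
        seq[start : start + len(tract)] = tract
        u = len(motif)
        # break the run at both flanks so the plant is maximal at its period
        if start > 0 and seq[start - 1] == motif[u - 1]:
            seq[start - 1] = _other_base(rng, motif[u - 1])
        end = start + len(tract)
        if end < len(seq) and seq[end] == motif[0]:
            seq[end] = _other_base(rng, motif[0])
        truth.ssrs.append(PlantedSSR(start, end, motif, copies))

    repeat_plan = DEFAULT_REPEAT_PLAN if config.repeat_plan is None else config.repeat_plan
    if config.n_genes == 0 and config.repeat_plan is None:
        repeat_plan = []
    for length, orientation, n_mm, want1, want2 in repeat_plan:
        if (length - n_mm) / length <= 0.90 or n_mm > 3:
            raise ValueError(f"planted repeat ({length},{orientation},{n_mm}) violates "
                             "the identity/hamming constraints")
        p1 = claim(length, want1)
        p2 = claim(length, want2)
        if p2 < p1:
            p1, p2 = p2, p1
        copy1 = _random_seq(rng, length, 0.45)
        seq[p1 : p1 + length] = copy1
        if orientation == "F":
            copy2 = list(copy1)
        elif orientation == "R":
            copy2 = list(copy1[::-1])
        elif orientation == "P":
            copy2 = list(revcomp(copy1))
        elif orientation == "C":
            copy2 = list(complement(copy1))
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        mm_sites = rng.choice(np.arange(3, length - 3, 2), size=n_mm, replace=False)
        for t in mm_sites:
            copy2[t] = _other_base(rng, copy2[t])
        seq[p2 : p2 + length] = copy2
        _saturate_repeat_flanks(seq, rng, orientation, p1, p2, length, n_mm)
        truth.repeats.append(PlantedRepeat(orientation, p1, p2, length, n_mm))

    record = PlastomeRecord(id="synthetic-ref", seq="".join(seq), features=features,
                            topology="circular")
    return record, truth


def _other_base(rng: np.random.Generator, base: str) -> str:
    alts = [b for b in BASES if b != base]
    return alts[rng.integers(3)]


def _saturate_repeat_flanks(seq: list[str], rng: np.random.Generator, orientation: str,
                            p1: int, p2: int, length: int, n_mm: int) -> None:
    """Force enough flanking mismatches that budget extension stops at the plant.

    With m planted interior mismatches and a budget of 3, any extension
    could absorb up to 3 - m further mismatches before reaching a match, so
    4 - m consecutive mismatching flank pairs on each side pin the maximal
    window exactly to the planted interval.
    """
    need = 4 - n_mm
    tf = (lambda b: b) if orientation in ("F", "R") else (lambda b: complement(b))
    for i in range(need):
        if orientation in ("F", "C"):
            pairs = [(p1 - 1 - i, p2 - 1 - i), (p1 + length + i, p2 + length + i)]
        else:  # R, P: anti-diagonal pairing
            pairs = [(p1 - 1 - i, p2 + length + i), (p1 + length + i, p2 - 1 - i)]
        for x, y in pairs:
            if 0 <= x < len(seq) and 0 <= y < len(seq):
                if seq[y] == tf(seq[x]):
                    forbidden = tf(seq[x])
                    seq[y] = _other_base(rng, forbidden)


# ---------------------------------------------------------------------------
# Derived genome


def mutate_genome(reference: PlastomeRecord, truth: Truth,
                  config: SyntheticConfig) -> tuple[PlastomeRecord, Truth]:
    """Apply the configured substitutions, indels and optional inversion.

    Exactly ``n_snv`` coding substitutions are planted, the realized
    nonsynonymous fraction within one substitution of ``frac_nonsyn``
    (labels chosen against the codon table, never creating a stop codon);
    indels fall in intergenic spans (unless ``coding_indels``); the block
    inversion, if any, is applied last. Truth records everything in
    reference coordinates, indels left-normalized.
    """
    rng = config.rng(1)
    ref = reference.seq
    cds_feats = [f for f in reference.features if f.ftype == "CDS"]

    # exclusion zones: planted SSR/repeat intervals (padded) and, if set,
    # the inversion breakpoints
    zones: list[tuple[int, int]] = []
    for s in truth.ssrs:
        zones.append((s.start - 30, s.end + 30))
    for r in truth.repeats:
        zones.append((r.pos1 - 30, r.pos1 + r.length + 30))
        zones.append((r.pos2 - 30, r.pos2 + r.length + 30))

    inversion = config.invert_block
    if inversion == "auto":
        inversion = _auto_inversion(reference, zones)
    if inversion is not None:
        inversion = (int(inversion[0]), int(inversion[1]))
        zones.append((inversion[0] - 120, inversion[0] + 120))
        zones.append((inversion[1] - 120, inversion[1] + 120))

    def blocked(pos: int, pad: int = 0) -> bool:
        return any(s - pad <= pos < e + pad for s, e in zones)

    # --- coding SNVs
    n_nonsyn = int(round(config.frac_nonsyn * config.n_snv))
    n_syn = config.n_snv - n_nonsyn
    used_codons: set[tuple[str, int]] = set()
    used_positions: set[int] = set()
    variants: list[TruthVariant] = []
    weights = np.array([f.spliced_length for f in cds_feats], dtype=float)
    if config.n_snv and not len(cds_feats):
        raise ValueError("coding SNVs requested but the reference has no CDS genes")
    if len(cds_feats):
        weights /= weights.sum()

    for want_label, n_want in (("nonsynonymous", n_nonsyn), ("synonymous", n_syn)):
        planted = 0
        attempts = 0
        while planted < n_want:
            attempts += 1
            if attempts > 200 * max(n_want, 1) + 1000:
                raise RuntimeError(
                    f"could not place {n_want} {want_label} substitutions "
                    f"(placed {planted}); genome too constrained"
                )
            fi = rng.choice(len(cds_feats), p=weights)
            feat = cds_feats[fi]
            cds = truth.cds[feat.name]
            n_codons = len(cds) // 3
            if n_codons <= 2:
                continue
            ci = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
            if (feat.name, ci) in used_codons:
                continue
            codon = cds[3 * ci : 3 * ci + 3]
            aa = translate_codon(codon)
            options = []
            for p in range(3):
                for b in BASES:
                    if b == codon[p]:
                        continue
                    alt_codon = codon[:p] + b + codon[p + 1:]
                    alt_aa = translate_codon(alt_codon)
                    if alt_aa == "*":
                        continue
                    if (want_label == "synonymous") == (alt_aa == aa):
                        options.append((p, b, alt_aa))
            if not options:
                continue
            p, b, alt_aa = options[rng.integers(len(options))]
            offset = 3 * ci + p
            s, _e = feat.parts[0]
            if feat.strand == 1:
                gpos = s + offset
                g_ref, g_alt = codon[p], b
            else:
                gpos = feat.parts[0][1] - 1 - offset
                g_ref, g_alt = complement(codon[p]), complement(b)
            if gpos in used_positions or blocked(gpos):
                continue
            assert ref[gpos] == g_ref
            used_codons.add((feat.name, ci))
            used_positions.add(gpos)
            notation = f"{aa}{ci + 1}{alt_aa}" if want_label == "nonsynonymous" else ""
            variants.append(TruthVariant(
                vtype="SNV", ref_pos=gpos, ref_allele=g_ref, alt_allele=g_alt,
                context="CDS", gene=feat.name, label=want_label, notation=notation,
                codon_index=ci + 1, codon_pos=p + 1,
            ))
            planted += 1

    # --- intergenic spans
    feat_ivals = sorted((f.start, f.end) for f in reference.features)
    spans = []
    prev = 0
    for s, e in feat_ivals:
        if s > prev:
            spans.append((prev, s))
        prev = max(prev, e)
    if prev < len(ref):
        spans.append((prev, len(ref)))

    # --- intergenic SNVs
    region = config.intergenic_snv_region
    planted = 0
    attempts = 0
    while planted < config.n_intergenic_snv:
        attempts += 1
        if attempts > 200 * config.n_intergenic_snv + 1000:
            raise RuntimeError("could not place the requested intergenic SNVs")
        span = spans[rng.integers(len(spans))]
        lo = span[0] + 5
        hi = span[1] - 5
        if region is not None:
            lo, hi = max(lo, region[0]), min(hi, region[1])
        if hi <= lo:
            continue
        gpos = int(rng.integers(lo, hi))
        if gpos in used_positions or blocked(gpos, pad=5):
            continue
        alt = _other_base(rng, ref[gpos])
        used_positions.add(gpos)
        variants.append(TruthVariant(vtype="SNV", ref_pos=gpos, ref_allele=ref[gpos],
                                     alt_allele=alt, context="intergenic"))
        planted += 1

    # --- indels
    indels: list[TruthVariant] = []
    size_lo, size_hi = config.indel_size_range
    attempts = 0
    while len(indels) < config.n_indels:
        attempts += 1
        if attempts > 200 * config.n_indels + 1000:
            raise RuntimeError("could not place the requested indels")
        span = spans[rng.integers(len(spans))]
        if span[1] - span[0] < 2 * (size_hi + 40):
            continue
        size = int(rng.integers(size_lo, size_hi + 1))
        gpos = int(rng.integers(span[0] + 30, span[1] - 30 - size))
        if blocked(gpos, pad=30) or blocked(gpos + size, pad=30):
            continue
        if any(abs(gpos - v.ref_pos) < 60 for v in indels):
            continue
        if any(abs(gpos - p) < 30 for p in used_positions):
            continue
        if rng.random() < 0.5:  # deletion of ref[gpos : gpos+size]
            d = gpos
            while d > 0 and ref[d - 1] == ref[d + size - 1]:
                d -= 1
            v = TruthVariant(vtype="deletion", ref_pos=d - 1,
                             ref_allele=ref[d : d + size], alt_allele="",
                             context="intergenic")
            v._apply_at = d  # type: ignore[attr-defined]
        else:
            ins = _random_seq(rng, size, 0.3)
            p = gpos
            while p > 0 and ref[p - 1] == ins[-1]:
                ins = ref[p - 1] + ins[:-1]
                p -= 1
            v = TruthVariant(vtype="insertion", ref_pos=p - 1, ref_allele="",
                             alt_allele=ins, context="intergenic")
            v._apply_at = p  # type: ignore[attr-defined]
        for p in range(gpos - 20, gpos + size + 20):
            used_positions.add(p)
        indels.append(v)

    # --- apply edits
    qry = list(ref)
    for v in variants:
        if v.vtype == "SNV":
            qry[v.ref_pos] = v.alt_allele
    for v in sorted(indels, key=lambda v: -v.ref_pos):
        at = v._apply_at  # type: ignore[attr-defined]
        if v.vtype == "deletion":
            del qry[at : at + len(v.ref_allele)]
        else:
            qry[at:at] = list(v.alt_allele)
    if inversion is not None:
        start, end = inversion
        off_s = _indel_offset(indels, start)
        off_e = _indel_offset(indels, end)
        qs, qe = start + off_s, end + off_e
        qry[qs:qe] = list(revcomp("".join(qry[qs:qe])))

    new_truth = Truth(
        variants=sorted(variants + indels, key=lambda v: v.ref_pos),
        ssrs=truth.ssrs, repeats=truth.repeats, expression=truth.expression,
        bias_weight=truth.bias_weight, inversion=inversion, cds=truth.cds,
        expression_model=truth.expression_model,
    )
    derived = PlastomeRecord(id="synthetic-derived", seq="".join(qry),
                             topology=reference.topology)
    return derived, new_truth


def _indel_offset(indels: list[TruthVariant], pos: int) -> int:
    off = 0
    for v in indels:
        if v.ref_pos < pos:
            off += len(v.alt_allele) - len(v.ref_allele)
    return off


def _auto_inversion(reference: PlastomeRecord, zones: list[tuple[int, int]]) -> tuple[int, int]:
    """Pick inversion breakpoints near 1/3 and 2/3 of the genome, in clear intergenic spans."""
    feats = sorted((f.start, f.end) for f in reference.features)

    def clear(pos: int) -> bool:
        if any(s - 150 <= pos < e + 150 for s, e in zones):
            return False
        return not any(s - 30 <= pos < e + 30 for s, e in feats)

    n = reference.length
    picks = []
    for target in (n // 3, 2 * n // 3):
        pos = next((target + d * sgn for d in range(0, n // 4, 13) for sgn in (1, -1)
                    if clear(target + d * sgn)), None)
        if pos is None:
            raise PackingError("no clear intergenic breakpoint for the inversion")
        picks.append(pos)
    return picks[0], picks[1]


# ---------------------------------------------------------------------------
# Expression counts


def simulate_counts(record: PlastomeRecord, truth: Truth, total_mapped: int = 1_000_000,
                    seed: int = 0, dispersion: float | None = None) -> CountsTable:
    """Simulated mapped-fragment counts per gene.

    Expected count is proportional to true expression level times gene
    length; ``dispersion`` (default: the config's expression-model noise) is
    a negative-binomial overdispersion (0 means deterministic expectation).
    """
    if dispersion is None:
        dispersion = truth.expression_model[1]
    rng = np.random.default_rng(seed)
    genes = sorted(truth.expression)
    lengths = {f.name: f.spliced_length for f in record.features if f.ftype == "CDS"}
    weights = np.array([truth.expression[g] * lengths[g] for g in genes], dtype=float)
    if weights.sum() == 0:
        mu = np.zeros(len(genes))
    else:
        mu = total_mapped * weights / weights.sum()
    if dispersion <= 0:
        counts = np.round(mu).astype(int)
    else:
        r = 1.0 / dispersion
        counts = np.array([
            rng.negative_binomial(r, r / (r + m)) if m > 0 else 0 for m in mu
        ])
    counts_d = {g: int(c) for g, c in zip(genes, counts)}
    # sampling noise can overshoot the nominal library size; keep the invariant
    return CountsTable(counts=counts_d,
                       total_mapped=max(int(total_mapped), sum(counts_d.values())))


# ---------------------------------------------------------------------------
# Alignment evolution (JC)


def evolve_alignment(tree: Node | str, n_sites: int, seed: int = 0) -> dict[str, str]:
    """Evolve an i.i.d. JC alignment down a tree with branch lengths.

    Branch lengths are expected substitutions per site; the root state is
    uniform. Returns leaf name -> sequence.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    bases = np.array(list("ACGT"))

    def walk(node: Node, state: np.ndarray) -> None:
        for child in node.children:
            e = np.exp(-4.0 * child.length / 3.0)
            child_state = state.copy()
            hit = rng.random(n_sites) >= e
            child_state[hit] = rng.integers(0, 4, int(hit.sum()))
            if child.is_leaf:
                out[child.name] = "".join(bases[child_state])
            else:
                walk(child, child_state)

    root_state = rng.integers(0, 4, n_sites)
    if tree.is_leaf:
        out[tree.name] = "".join(bases[root_state])
    else:
        walk(tree, root_state)
    return out


# ---------------------------------------------------------------------------
# Emission (CLI `simulate`)


def emit(record: PlastomeRecord, truth: Truth, outdir: str | Path,
         derived: PlastomeRecord | None = None) -> None:
    """Write FASTA, a feature TSV and a truth JSON into ``outdir``."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([record], outdir / "reference.fasta")
    if derived is not None:
        write_fasta([derived], outdir / "derived.fasta")
    rows = [
        {"name": f.name, "type": f.ftype, "start": f.start, "end": f.end,
         "strand": f.strand, "phase": f.phase}
        for f in record.features
    ]
    pd.DataFrame(rows).to_csv(outdir / "features.tsv", sep="\t", index=False)
    payload = {
        "variants": [asdict(v) for v in truth.variants],
        "ssrs": [asdict(s) for s in truth.ssrs],
        "repeats": [asdict(r) for r in truth.repeats],
        "expression": truth.expression,
        "bias_weight": truth.bias_weight,
        "inversion": truth.inversion,
        "expression_model": list(truth.expression_model),
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
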