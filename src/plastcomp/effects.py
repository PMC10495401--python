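"""Variant annotation: genomic context and synonymous/nonsynonymous calls.

Coding SNVs are classified against the plastid/bacterial genetic code
(translation table 11) by translating the reference and mutated codons;
a nonsynonymous change carries the conventional protein notation
ref-AA + codon index + alt-AA (e.g. ``H447Y``). Per-gene summaries mirror
the usual total/nonsynonymous/synonymous table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import Variant
from .codons import complement, translate_codon
from .genome_io import GeneFeature, PlastomeRecord, extract_cds


@dataclass
class VariantEffect:
    variant: Variant
    context: str  # CDS | intron | tRNA | rRNA | intergenic
    gene: str | None = None
    flanks: tuple[str | None, str | None] | None = None
    codon_index: int | None = None  # 1-based
    codon_pos: int | None = None    # 1..3
    ref_aa: str | None = None
    alt_aa: str | None = None
    label: str | None = None        # synonymous | nonsynonymous | coding-indel
    notation: str = ""
    start_stop: bool = False


@dataclass
class GeneVariantSummary:
    gene: str
    n_total: int = 0
    n_nonsyn: int = 0
    n_syn: int = 0
    notations: list[str] = field(default_factory=list)


def _spliced_offset(feat: GeneFeature, pos: int) -> int | None:
    """Offset of genome position ``pos`` within the spliced, stranded CDS."""
    off = 0
    for s, e in feat.parts:
        if s <= pos < e:
            if feat.strand == 1:
                return off + (pos - s) - feat.phase
            return off + (e - 1 - pos) - feat.phase
        off += e - s
    return None


def project_variant(variant: Variant, features: list[GeneFeature]
                    ) -> tuple[str, GeneFeature | None, tuple[str | None, str | None]]:
    """Context of a variant: (context, feature-or-None, flanking gene pair).

    CDS membership is decided on spliced coordinates; a position inside a
    gene's span but outside every part is intronic; otherwise intergenic
    with flanks reported in genome order.
    """
    pos = variant.ref_pos if variant.vtype == "SNV" else variant.ref_pos + 1
    in_span = []
    for f in features:
        if f.ftype not in ("CDS", "tRNA", "rRNA"):
            continue
        if any(s <= pos < e for s, e in f.parts):
            return f.ftype, f, (None, None)
        if f.start <= pos < f.end:
            in_span.append(f)
    if in_span:
        return "intron", in_span[0], (None, None)
    named = sorted((f for f in features if f.ftype in ("CDS", "tRNA", "rRNA")),
                   key=lambda f: f.start)
    left = next((f.name for f in reversed(named) if f.end <= pos), None)
    right = next((f.name for f in named if f.start > pos), None)
    return "intergenic", None, (left, right)


def classify_cds_snv(cds_seq: str, offset_in_cds: int, alt_base: str) -> dict:
    """Classify a single-base change within a strand-corrected CDS.

    ``alt_base`` must already be strand-corrected (complemented for
    minus-strand genes). Returns codon index (1-based), within-codon
    position (1..3), ref/alt amino acids, the synonymous/nonsynonymous
    label and the protein notation (empty for synonymous changes).
    """
    if not 0 <= offset_in_cds < len(cds_seq):
        raise ValueError("offset outside CDS")
    ci = offset_in_cds // 3
    p = offset_in_cds % 3
    codon = cds_seq[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        raise ValueError("offset falls in a trailing partial codon")
    if alt_base == codon[p]:
        raise ValueError("alternate base equals the reference; not a variant")
    alt_codon = codon[:p] + alt_base + codon[p + 1:]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    label = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    start_stop = ci == 0 or ref_aa == "*" or alt_aa == "*"
    return {
        "codon_index": ci + 1,
        "codon_pos": p + 1,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "label": label,
        "notation": f"{ref_aa}{ci + 1}{alt_aa}" if label == "nonsynonymous" else "",
        "start_stop": start_stop,
    }


def annotate_variants(variants: list[Variant], record: PlastomeRecord
                      ) -> list[VariantEffect]:
    """Project and classify every variant against a reference annotation."""
    cds_cache: dict[str, str] = {}
    out = []
    for v in variants:
        context, feat, flanks = project_variant(v, record.features)
        eff = VariantEffect(variant=v, context=context,
                            gene=feat.name if feat else None,
                            flanks=flanks if context == "intergenic" else None)
        if context == "CDS" and v.vtype == "SNV":
            if feat.name not in cds_cache:
                cds_cache[feat.name] = extract_cds(record, feat.name)
            cds = cds_cache[feat.name]
            off = _spliced_offset(feat, v.ref_pos)
            alt = v.alt_allele if feat.strand == 1 else complement(v.alt_allele)
            if off is None or not 0 <= off < len(cds):
                eff.label = None  # phase-trimmed edge base; leave unclassified
            else:
                info = classify_cds_snv(cds, off, alt)
                eff.codon_index = info["codon_index"]
                eff.codon_pos = info["codon_pos"]
                eff.ref_aa = info["ref_aa"]
                eff.alt_aa = info["alt_aa"]
                eff.label = info["label"]
                eff.notation = info["notation"]
                eff.start_stop = info["start_stop"]
        elif context == "CDS":
            eff.label = "coding-indel"
        out.append(eff)
    return out


def summarize_by_gene(effects: list[VariantEffect]) -> list[GeneVariantSummary]:
    """One row per gene with at least one classified CDS SNV, sorted by name.

    Nonsynonymous notations are ordered by codon index. The arithmetic
    invariant n_total = n_nonsyn + n_syn holds by construction.
    """
    rows: dict[str, GeneVariantSummary] = {}
    notes: dict[str, list[tuple[int, str]]] = {}
    for e in effects:
        if e.context != "CDS" or e.variant.vtype != "SNV" or e.label is None:
            continue
        row = rows.setdefault(e.gene, GeneVariantSummary(gene=e.gene))
        row.n_total += 1
        if e.label == "nonsynonymous":
            row.n_nonsyn += 1
            notes.setdefault(e.gene, []).append((e.codon_index, e.notation))
        else:
            row.n_syn += 1
    for gene, row in rows.items():
        row.notations = [n for _, n in sorted(notes.get(gene, []))]
    return sorted(rows.values(), key=lambda r: r.gene)


def effects_frame(effects: list[VariantEffect]) -> pd.DataFrame:
    rows = []
    for e in effects:
        v = e.variant
        rows.append({
            "pos": v.ref_pos + 1, "type": v.vtype, "ref": v.ref_allele,
            "alt": v.alt_allele, "context": e.context,
            "gene": e.gene or (f"{e.flanks[0]}-{e.flanks[1]}" if e.flanks else ""),
            "codon_index": e.codon_index, "aa_change": e.notation,
            "label": e.label or "",
        })
    return pd.DataFrame(rows, columns=["pos", "type", "ref", "alt", "context",
                                       "gene", "codon_index", "aa_change", "label"])


def summary_frame(summaries: list[GeneVariantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": s.gene, "n_total": s.n_total, "n_nonsyn": s.n_nonsyn,
          "n_syn": s.n_syn, "notations": ", ".join(s.notations)}
         for s in summaries],
        columns=["gene", "n_total", "n_nonsyn", "n_syn", "notations"],
    )
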