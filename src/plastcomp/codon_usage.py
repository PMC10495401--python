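"""Codon-usage statistics and expression: RSCU, MILC, MELP, FPKM.

RSCU (relative synonymous codon usage) for codon c in amino-acid family a:
``RSCU_c = o_c * r_a / sum_{c' in a} o_{c'}`` with r_a the family size, so
uniform within-family usage gives 1 for every codon and the family sum
always equals r_a.

MILC (Measure Independent of Length and Composition) scores the distance
of a gene's codon usage from a reference codon distribution g:

    MILC = (sum_a M_a) / L - C
    M_a  = 2 * sum_{c in a} o_c * ln(f_c / g_c)
    C    = (sum_a (r_a - 1)) / L - 0.5

with f_c the gene's within-family codon frequency, L the gene's codon
total over the families considered, and the family sum running over
families present in the gene. MELP (MILC-based Expression Level Predictor)
is the ratio MILC(gene | genome-wide usage) / MILC(gene | ribosomal-protein
usage); values above 1 flag genes whose usage resembles the highly
expressed ribosomal-protein set more than the genomic average.

FPKM = count / (length_bp / 1e3) / (total_mapped / 1e6).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AA_TO_CODONS, ALL_CODONS, CODON_TO_AA, FAMILY_SIZE
from .genome_io import CountsTable

#: amino-acid families used by MILC (stops excluded, single-codon families kept)
_MILC_FAMILIES = {aa: cods for aa, cods in AA_TO_CODONS.items() if aa != "*"}

DEFAULT_CATEGORY_PREFIXES = [
    ("atp", "ATP synthase"),
    ("rbc", "rubisco"),
    ("psa", "photosystem"),
    ("psb", "photosystem"),
    ("ndh", "NADH dehydrogenase"),
    ("pet", "cytochrome"),
    ("rps", "ribosomal"),
    ("rpl", "ribosomal"),
    ("rpo", "RNA polymerase"),
]

CATEGORY_ORDER = [
    "ATP synthase", "rubisco", "photosystem", "NADH dehydrogenase",
    "cytochrome", "ribosomal", "RNA polymerase", "other",
]


def default_category(gene: str) -> str:
    g = gene.lower()
    for prefix, cat in DEFAULT_CATEGORY_PREFIXES:
        if g.startswith(prefix):
            return cat
    return "other"


@dataclass
class CodonUsageTable:
    """Per-gene codon counts, plus genome-wide totals."""

    per_gene: dict[str, Counter] = field(default_factory=dict)

    @property
    def genome_counts(self) -> Counter:
        total: Counter = Counter()
        for c in self.per_gene.values():
            total.update(c)
        return total

    def total_codons(self, include_stops: bool = True) -> int:
        tot = self.genome_counts
        n = sum(tot.values())
        if not include_stops:
            n -= sum(tot[c] for c in ALL_CODONS if CODON_TO_AA[c] == "*")
        return n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {g: [c.get(cod, 0) for cod in ALL_CODONS] for g, c in self.per_gene.items()},
            index=list(ALL_CODONS),
        )
        df.index.name = "codon"
        return df


def count_codons(cds_by_gene: dict[str, str]) -> CodonUsageTable:
    """Codon counts from strand-corrected spliced CDS sequences.

    Sequences whose length is not a multiple of 3 are trimmed (with a
    warning); codons containing N are skipped.
    """
    table = CodonUsageTable()
    for gene, cds in cds_by_gene.items():
        if len(cds) % 3:
            warnings.warn(f"{gene}: CDS length not divisible by 3, trimming")
            cds = cds[: len(cds) - len(cds) % 3]
        counts: Counter = Counter()
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3].upper()
            if "N" not in codon:
                counts[codon] += 1
        table.per_gene[gene] = counts
    return table


# ---------------------------------------------------------------------------
# RSCU


def rscu(table: CodonUsageTable, level: str = "genome",
         gene: str | None = None) -> dict[str, float]:
    """RSCU vector at genome level or for a single gene.

    Families with zero total get ``nan`` (undefined); the single-codon
    families (ATG, TGG) are always exactly 1 when observed.
    """
    if level == "gene":
        if gene is None:
            raise ValueError("gene-level RSCU needs a gene name")
        counts = table.per_gene[gene]
    elif level == "genome":
        counts = table.genome_counts
    else:
        raise ValueError("level must be 'gene' or 'genome'")
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        fam_total = sum(counts.get(c, 0) for c in codons)
        r = len(codons)
        for c in codons:
            out[c] = (counts.get(c, 0) * r / fam_total) if fam_total else math.nan
    return out


def preferred_codon_fraction(table: CodonUsageTable, gene: str,
                             genome_rscu: dict[str, float] | None = None) -> float:
    """Share of a gene's codons whose genome-level RSCU exceeds 1.0."""
    if genome_rscu is None:
        genome_rscu = rscu(table, "genome")
    counts = table.per_gene[gene]
    total = sum(n for c, n in counts.items() if CODON_TO_AA.get(c, "*") != "*")
    if total == 0:
        return math.nan
    pref = sum(
        n for c, n in counts.items()
        if CODON_TO_AA.get(c, "*") != "*" and genome_rscu.get(c, 0) > 1.0
    )
    return pref / total


# ---------------------------------------------------------------------------
# MILC / MELP


def family_frequencies(counts: Counter) -> dict[str, float]:
    """Within-family codon frequencies g_c of a reference codon-count pool."""
    freqs: dict[str, float] = {}
    for aa, codons in _MILC_FAMILIES.items():
        fam_total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            freqs[c] = counts.get(c, 0) / fam_total if fam_total else 0.0
    return freqs


def milc(gene_counts: Counter, reference_freqs: dict[str, float]) -> float:
    """MILC of one gene against normalized reference frequencies.

    Families absent from the gene are skipped; codons with o_c = 0
    contribute nothing. Reference frequencies that are zero where the gene
    has observations are floored to a tiny value rather than producing an
    infinite distance (this only matters for degenerate references).
    """
    total_m = 0.0
    L = 0
    correction_families = 0
    for aa, codons in _MILC_FAMILIES.items():
        o = [gene_counts.get(c, 0) for c in codons]
        n_a = sum(o)
        if n_a == 0:
            continue
        L += n_a
        correction_families += len(codons) - 1
        m_a = 0.0
        for c, o_c in zip(codons, o):
            if o_c == 0:
                continue
            f_c = o_c / n_a
            g_c = reference_freqs.get(c, 0.0)
            if g_c <= 0.0:
                g_c = 1e-9
            m_a += o_c * math.log(f_c / g_c)
        total_m += 2.0 * m_a
    if L == 0:
        raise ValueError("gene has no codons in any amino-acid family")
    c_term = correction_families / L - 0.5
    return total_m / L - c_term


def melp(gene_counts: Counter, genome_freqs: dict[str, float],
         ribosomal_freqs: dict[str, float]) -> float:
    """MELP = MILC(gene|genome) / MILC(gene|ribosomal reference)."""
    denom = milc(gene_counts, ribosomal_freqs)
    return milc(gene_counts, genome_freqs) / denom


def ribosomal_reference(table: CodonUsageTable) -> Counter:
    """Pooled codon counts of ribosomal-protein genes (names rps*/rpl*)."""
    pool: Counter = Counter()
    for gene, counts in table.per_gene.items():
        g = gene.lower()
        if g.startswith("rps") or g.startswith("rpl"):
            pool.update(counts)
    if not pool:
        raise ValueError("no ribosomal-protein (rps*/rpl*) genes in the table")
    return pool


def bias_scores(table: CodonUsageTable) -> pd.DataFrame:
    """Per-gene MILC (vs genome), MELP and preferred-codon fraction."""
    genome_freqs = family_frequencies(table.genome_counts)
    ribo_freqs = family_frequencies(ribosomal_reference(table))
    genome_rscu = rscu(table, "genome")
    rows = []
    for gene, counts in table.per_gene.items():
        rows.append(
            {
                "gene": gene,
                "MILC": milc(counts, genome_freqs),
                "MELP": melp(counts, genome_freqs, ribo_freqs),
                "preferred_fraction": preferred_codon_fraction(table, gene, genome_rscu),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionRecord:
    gene: str
    count: int
    length_bp: int
    fpkm: float
    category: str


def fpkm(counts_table: CountsTable, gene_lengths: dict[str, int],
         category_map: dict[str, str] | None = None) -> list[ExpressionRecord]:
    """FPKM per gene from a counts table and gene lengths (bp)."""
    out = []
    for gene, count in counts_table.counts.items():
        if gene not in gene_lengths:
            warnings.warn(f"{gene}: no length available, skipping")
            continue
        length = gene_lengths[gene]
        value = count / (length / 1e3) / (counts_table.total_mapped / 1e6)
        cat = (category_map or {}).get(gene) or default_category(gene)
        out.append(ExpressionRecord(gene, count, length, value, cat))
    return out


def bias_expression_report(
    bias: pd.DataFrame,
    expression: list[ExpressionRecord],
    category_map: dict[str, str] | None = None,
) -> dict:
    """Bias-vs-expression summary.

    Returns the least-squares fit of preferred-codon fraction on MELP
    (slope, intercept, Pearson r), the Spearman correlation of MELP with
    log10(FPKM) over genes with positive FPKM, and the per-category mean
    FPKM table (categories with no genes are omitted with a warning).
    """
    expr = {e.gene: e for e in expression}
    merged = bias[bias["gene"].isin(expr)].copy()
    merged["FPKM"] = [expr[g].fpkm for g in merged["gene"]]
    merged["category"] = [
        (category_map or {}).get(g) or expr[g].category for g in merged["gene"]
    ]

    fit = stats.linregress(merged["MELP"], merged["preferred_fraction"])
    pos = merged[merged["FPKM"] > 0]
    if len(pos) >= 3:
        rho, pval = stats.spearmanr(pos["MELP"], np.log10(pos["FPKM"]))
    else:
        rho, pval = math.nan, math.nan

    cat_rows = []
    for cat in CATEGORY_ORDER:
        sub = merged[merged["category"] == cat]
        if sub.empty:
            warnings.warn(f"category {cat!r}: no genes, omitted")
            continue
        cat_rows.append({"category": cat, "mean_FPKM": float(sub["FPKM"].mean()),
                         "n_genes": int(len(sub))})
    return {
        "regression": {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r": float(fit.rvalue),
        },
        "spearman_melp_log10fpkm": {"rho": float(rho), "p": float(pval)},
        "category_means": pd.DataFrame(cat_rows),
        "table": merged,
    }
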