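"""Variant projection and synonymous/nonsynonymous classification."""

import numpy as np
import pytest

from oracles import snv_label
from plastcomp import effects as E
from plastcomp.align import Variant
from plastcomp.codons import STOP_CODONS, revcomp
from plastcomp.genome_io import GeneFeature, PlastomeRecord


def _random_cds(n_codons, seed):
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in STOP_CODONS and a + b + c != "ATG"]
    body = "".join(rng.choice(codons, size=n_codons - 2))
    return "ATG" + body + "TAA"


def test_project_variant_contexts():
    feats = [
        GeneFeature("geneA", "CDS", [(100, 400)]),
        GeneFeature("rrn23", "rRNA", [(600, 900)]),
        GeneFeature("geneB", "CDS", [(1000, 1300)]),
    ]
    ctx, f, _ = E.project_variant(Variant("SNV", 150, "A", "C"), feats)
    assert (ctx, f.name) == ("CDS", "geneA")
    ctx, f, _ = E.project_variant(Variant("SNV", 700, "A", "C"), feats)
    assert (ctx, f.name) == ("rRNA", "rrn23")
    ctx, _, flanks = E.project_variant(Variant("SNV", 950, "A", "C"), feats)
    assert ctx == "intergenic" and flanks == ("rrn23", "geneB")


def test_project_variant_intron():
    feats = [GeneFeature("g", "CDS", [(10, 40), (80, 110)])]
    ctx, f, _ = E.project_variant(Variant("SNV", 60, "A", "C"), feats)
    assert ctx == "intron" and f.name == "g"


def test_h447y_notation():
    """CAT->TAT at codon 447, first position: histidine to tyrosine."""
    cds = _random_cds(500, seed=1)
    cds = cds[: 446 * 3] + "CAT" + cds[446 * 3 + 3:]
    info = E.classify_cds_snv(cds, 446 * 3, "T")
    assert info["label"] == "nonsynonymous"
    assert info["notation"] == "H447Y"
    assert (info["codon_index"], info["codon_pos"]) == (447, 1)


def test_fourfold_site_synonymous_no_notation():
    cds = "ATG" + "GGA" + "TAA"
    info = E.classify_cds_snv(cds, 5, "G")  # GGA -> GGG
    assert info["label"] == "synonymous" and info["notation"] == ""


def test_alt_equal_ref_is_error():
    with pytest.raises(ValueError):
        E.classify_cds_snv("ATGAAATAA", 3, "A")


@pytest.mark.parametrize("seed", range(3))
def test_exhaustive_oracle_agreement(seed):
    """All 2700 single-base changes of a 300-codon CDS agree with the
    translate-and-compare oracle."""
    cds = _random_cds(300, seed=seed)
    for off in range(len(cds)):
        for alt in "ACGT":
            if alt == cds[off]:
                continue
            info = E.classify_cds_snv(cds, off, alt)
            label, notation = snv_label(cds, off, alt)
            assert info["label"] == label
            if label == "nonsynonymous":
                assert info["notation"] == notation


def test_strand_consistency():
    """Classification is invariant under reverse-complementing the genome
    with flipped annotations."""
    cds = _random_cds(60, seed=9)
    pad = "ACGT" * 10
    genome = pad + cds + pad
    fwd = PlastomeRecord("f", genome, [GeneFeature("g", "CDS", [(40, 40 + len(cds))], 1)])
    rev_genome = revcomp(genome)
    n = len(genome)
    s, e = n - (40 + len(cds)), n - 40
    rev = PlastomeRecord("r", rev_genome, [GeneFeature("g", "CDS", [(s, e)], -1)])
    rng = np.random.default_rng(1)
    for _ in range(30):
        gpos = int(rng.integers(40, 40 + len(cds)))
        ref_b = genome[gpos]
        alt_b = "ACGT"[(("ACGT".index(ref_b)) + 1 + int(rng.integers(3))) % 4]
        if alt_b == ref_b:
            continue
        v_f = Variant("SNV", gpos, ref_b, alt_b)
        gpos_r = n - 1 - gpos
        v_r = Variant("SNV", gpos_r, revcomp(ref_b), revcomp(alt_b))
        e_f = E.annotate_variants([v_f], fwd)[0]
        e_r = E.annotate_variants([v_r], rev)[0]
        assert (e_f.label, e_f.notation) == (e_r.label, e_r.notation)


def test_summarize_by_gene_table_row():
    cds = _random_cds(500, seed=2)
    cds = cds[: 446 * 3] + "CAT" + cds[446 * 3 + 3:]
    feats = [GeneFeature("ndhB", "CDS", [(0, len(cds))], 1)]
    rec = PlastomeRecord("r", cds, feats)
    # one nonsynonymous (H447Y) and one synonymous variant
    v1 = Variant("SNV", 446 * 3, "C", "T")
    syn_pos = next(
        off for off in range(6, len(cds) - 3, 3)
        for alt in "ACGT"
        if alt != cds[off + 2]
        and E.classify_cds_snv(cds, off + 2, alt)["label"] == "synonymous"
    )
    alt = next(a for a in "ACGT" if a != cds[syn_pos + 2]
               and E.classify_cds_snv(cds, syn_pos + 2, a)["label"] == "synonymous")
    v2 = Variant("SNV", syn_pos + 2, cds[syn_pos + 2], alt)
    effs = E.annotate_variants([v1, v2], rec)
    rows = E.summarize_by_gene(effs)
    assert len(rows) == 1
    r = rows[0]
    assert (r.gene, r.n_total, r.n_nonsyn, r.n_syn, r.notations) == \
        ("ndhB", 2, 1, 1, ["H447Y"])


def test_summarize_empty():
    assert E.summarize_by_gene([]) == []


def test_gene_summary_matches_planted_truth(small_pair):
    from plastcomp import align as A

    _, ref, qry, truth = small_pair
    amap, _, oriented = A.align_genomes(ref.seq, qry.seq)
    variants = A.call_variants(amap, ref.seq, oriented)
    effs = E.annotate_variants(variants, ref)
    got = {s.gene: (s.n_total, s.n_nonsyn, s.n_syn, s.notations)
           for s in E.summarize_by_gene(effs)}
    expected = {g: (d["n_total"], d["n_nonsyn"], d["n_syn"], d["notations"])
                for g, d in truth.gene_summary().items()}
    assert got == expected


def test_coding_indel_labelled_without_frame_analysis():
    cds = _random_cds(50, seed=3)
    rec = PlastomeRecord("r", cds, [GeneFeature("g", "CDS", [(0, len(cds))], 1)])
    v = Variant("deletion", 30, cds[31:34], "")
    eff = E.annotate_variants([v], rec)[0]
    assert eff.label == "coding-indel"
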