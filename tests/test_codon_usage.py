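"""RSCU, MILC/MELP, FPKM and the bias-expression report."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plastcomp import codon_usage as C
from plastcomp.codons import AA_TO_CODONS, FAMILY_SIZE
from plastcomp.genome_io import CountsTable


def test_count_codons_basic():
    table = C.count_codons({"g": "ATGAAATAA"})
    assert table.per_gene["g"] == Counter({"ATG": 1, "AAA": 1, "TAA": 1})
    assert table.total_codons() == 3
    assert table.total_codons(include_stops=False) == 2


def test_count_codons_empty():
    table = C.count_codons({})
    assert table.total_codons() == 0


def test_rscu_uniform_usage_is_one():
    counts: Counter = Counter()
    for aa, codons in AA_TO_CODONS.items():
        for c in codons:
            counts[c] = 5
    table = C.CodonUsageTable(per_gene={"g": counts})
    vec = C.rscu(table, "genome")
    assert all(v == pytest.approx(1.0) for v in vec.values())


def test_rscu_single_codon_used_in_sixfold_family():
    counts = Counter({"TTA": 7})  # leucine, family size 6
    table = C.CodonUsageTable(per_gene={"g": counts})
    vec = C.rscu(table, "genome")
    assert vec["TTA"] == pytest.approx(6.0)
    assert vec["CTC"] == 0.0


def test_rscu_atg_always_one():
    table = C.CodonUsageTable(per_gene={"g": Counter({"ATG": 123, "TGG": 1})})
    vec = C.rscu(table, "genome")
    assert vec["ATG"] == 1.0 and vec["TGG"] == 1.0


def test_rscu_family_sums_equal_family_size():
    rng = np.random.default_rng(0)
    counts = Counter({c: int(rng.integers(0, 50)) + 1
                      for codons in AA_TO_CODONS.values() for c in codons})
    table = C.CodonUsageTable(per_gene={"g": counts})
    vec = C.rscu(table, "gene", gene="g")
    for aa, codons in AA_TO_CODONS.items():
        assert sum(vec[c] for c in codons) == pytest.approx(len(codons))


def _random_counts(seed, lo=1, hi=40) -> Counter:
    rng = np.random.default_rng(seed)
    return Counter({c: int(rng.integers(lo, hi))
                    for codons in AA_TO_CODONS.values() for c in codons
                    if C.CODON_TO_AA[c] != "*"})


def test_milc_zero_distance_gives_minus_correction():
    counts = _random_counts(1)
    ref = C.family_frequencies(counts)
    L = sum(counts.values())
    families = {C.CODON_TO_AA[c] for c in counts}
    corr = sum(FAMILY_SIZE[aa] - 1 for aa in families) / L - 0.5
    assert C.milc(counts, ref) == pytest.approx(-corr, abs=1e-12)


def test_milc_distance_term_scale_invariant():
    """The distance term (sum_a M_a)/L is exactly invariant under uniform
    scaling; MILC itself changes only through the L-dependent correction."""
    counts = _random_counts(2)
    ref = C.family_frequencies(_random_counts(3))
    L = sum(counts.values())
    families = {C.CODON_TO_AA[c] for c in counts}
    corr1 = sum(FAMILY_SIZE[aa] - 1 for aa in families) / L - 0.5
    corr2 = sum(FAMILY_SIZE[aa] - 1 for aa in families) / (2 * L) - 0.5
    m1 = C.milc(counts, ref) + corr1
    doubled = Counter({c: 2 * n for c, n in counts.items()})
    m2 = C.milc(doubled, ref) + corr2
    assert m1 == pytest.approx(m2, abs=1e-9)


def test_milc_matches_independent_formula_transcription():
    counts = _random_counts(4)
    ref_counts = _random_counts(5)
    ref = C.family_frequencies(ref_counts)
    # direct transcription, structured differently from the implementation
    L = sum(counts.values())
    total = 0.0
    fams = 0
    for aa, codons in AA_TO_CODONS.items():
        if aa == "*":
            continue
        n_a = sum(counts[c] for c in codons)
        if n_a == 0:
            continue
        fams += len(codons) - 1
        total += 2 * sum(
            counts[c] * math.log((counts[c] / n_a) / ref[c])
            for c in codons if counts[c] > 0
        )
    expected = total / L - (fams / L - 0.5)
    assert C.milc(counts, ref) == pytest.approx(expected, abs=1e-12)


def test_milc_empty_gene_errors():
    with pytest.raises(ValueError):
        C.milc(Counter(), C.family_frequencies(_random_counts(6)))


def test_melp_above_one_when_gene_matches_ribosomal_usage():
    ribo = _random_counts(7, lo=1, hi=100)
    genome = _random_counts(8, lo=1, hi=100)
    gene = Counter(ribo)  # identical usage to the ribosomal reference
    m = C.melp(gene, C.family_frequencies(genome), C.family_frequencies(ribo))
    assert m > 1.0


def test_fpkm_unit_case_and_zero():
    ct = CountsTable(counts={"a": 10, "b": 0}, total_mapped=1_000_000)
    recs = {e.gene: e for e in C.fpkm(ct, {"a": 1000, "b": 500})}
    assert recs["a"].fpkm == pytest.approx(10.0)
    assert recs["b"].fpkm == 0.0


def test_bias_expression_perfectly_collinear():
    bias = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "MILC": [0.1, 0.2, 0.3, 0.4],
        "MELP": [0.5, 1.0, 1.5, 2.0],
        "preferred_fraction": [0.2, 0.4, 0.6, 0.8],
    })
    expr = [C.ExpressionRecord(g, 10, 100, f, "other")
            for g, f in zip("abcd", [1.0, 10.0, 100.0, 1000.0])]
    rep = C.bias_expression_report(bias, expr)
    assert rep["regression"]["r"] == pytest.approx(1.0)
    assert rep["spearman_melp_log10fpkm"]["rho"] == pytest.approx(1.0)


def test_bias_expression_missing_category_warns():
    bias = pd.DataFrame({"gene": ["a", "b", "c"], "MILC": [0.1] * 3,
                         "MELP": [1.0, 1.1, 1.2],
                         "preferred_fraction": [0.3, 0.4, 0.5]})
    expr = [C.ExpressionRecord(g, 5, 100, 2.0, "other") for g in "abc"]
    with pytest.warns(UserWarning):
        rep = C.bias_expression_report(bias, expr)
    assert set(rep["category_means"]["category"]) == {"other"}


def test_category_ranking_recovers_planted_expression_order():
    """ATP-synthase genes set highest, then rubisco, then photosystem."""
    from plastcomp.synthetic import SyntheticConfig, generate_reference, simulate_counts
    from plastcomp.genome_io import extract_cds

    cfg = SyntheticConfig(genome_length=90_000, n_genes=60, seed=21)
    ref, truth = generate_reference(cfg)
    for g in truth.expression:
        cat = C.default_category(g)
        truth.expression[g] = {"ATP synthase": 100.0, "rubisco": 30.0,
                               "photosystem": 10.0}.get(cat, 1.0)
    counts = simulate_counts(ref, truth, seed=1, dispersion=0.05)
    cds = {f.name: extract_cds(ref, f.name) for f in ref.cds_features()}
    table = C.count_codons(cds)
    bias = C.bias_scores(table)
    expr = C.fpkm(counts, {f.name: f.spliced_length for f in ref.cds_features()})
    rep = C.bias_expression_report(bias, expr)
    means = dict(zip(rep["category_means"]["category"],
                     rep["category_means"]["mean_FPKM"]))
    assert means["ATP synthase"] > means["rubisco"] > means["photosystem"]
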