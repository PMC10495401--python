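"""Sliding-window dissimilarity, masking and hotspot calling."""

import numpy as np
import pytest

from plastcomp import align as A
from plastcomp import windows as W
from plastcomp.genome_io import GeneFeature
from plastcomp.repeats import LongRepeat
from plastcomp.windows import Hotspot, WindowStat


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_expected_window_count_for_study_genome_size():
    assert W.expected_n_windows(122_855, 1000, 200) == 610


def test_identical_pair_all_windows_zero():
    s = _random_seq(6_000, seed=1)
    amap, _, oriented = A.align_genomes(s, s)
    wins = W.window_dissimilarity(amap, s, oriented)
    assert len(wins) == W.expected_n_windows(6_000)
    assert all(w.dissimilarity == 0.0 for w in wins)


def test_twelve_snvs_in_unmasked_window_is_1_2_percent():
    s = _random_seq(3_000, seed=2)
    q = list(s)
    rng = np.random.default_rng(3)
    for pos in rng.choice(np.arange(50, 950), size=12, replace=False):
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    q = "".join(q)
    amap, _, oriented = A.align_genomes(s, q)
    wins = W.window_dissimilarity(amap, s, oriented)
    assert wins[0].n_diff == 12 and wins[0].n_comparable == 1000
    assert wins[0].dissimilarity == pytest.approx(1.2)


def test_mask_from_repeats_examples():
    assert W.mask_from_repeats([], 1000) == []
    mask = W.mask_from_repeats([LongRepeat("F", 100, 500, 40, 0)], 1000)
    assert mask == [(100, 140), (500, 540)]
    mask = W.mask_from_repeats(
        [LongRepeat("F", 100, 120, 40, 0), LongRepeat("P", 130, 700, 35, 1)], 1000)
    assert mask[0] == (100, 165)  # overlapping copies merged


def test_fully_masked_window_undefined_and_not_hotspot():
    s = _random_seq(3_000, seed=4)
    q = list(s)
    for pos in range(100, 150):  # dense divergence, all masked
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    amap, _, oriented = A.align_genomes(s, "".join(q))
    wins = W.window_dissimilarity(amap, s, oriented, mask=[(0, 1400)])
    assert wins[0].dissimilarity is None
    assert wins[0].masked_fraction == 1.0
    assert W.call_hotspots(wins, [], threshold=1.0) == []


def test_masking_monotonicity(small_pair):
    _, ref, qry, _ = small_pair
    amap, _, oriented = A.align_genomes(ref.seq, qry.seq)
    w0 = W.window_dissimilarity(amap, ref.seq, oriented)
    w1 = W.window_dissimilarity(amap, ref.seq, oriented, mask=[(5_000, 9_000)])
    for a, b in zip(w0, w1):
        assert b.n_comparable <= a.n_comparable
        if b.ref_end <= 5_000 or b.ref_start >= 9_000:
            assert (a.n_comparable, a.n_diff) == (b.n_comparable, b.n_diff)


def test_window_oracle_recount(small_pair):
    """Window statistics equal a naive per-column recount from the ops."""
    _, ref, qry, _ = small_pair
    amap, _, oriented = A.align_genomes(ref.seq, qry.seq)
    wins = W.window_dissimilarity(amap, ref.seq, oriented)
    comparable = np.zeros(ref.length, int)
    diff = np.zeros(ref.length, int)
    for op in amap.ops:
        if op.type == "match":
            for t in range(op.ref_end - op.ref_start):
                rc = ref.seq[op.ref_start + t]
                qc = oriented[op.qry_start + t]
                if rc != "N" and qc != "N":
                    comparable[op.ref_start + t] += 1
                    diff[op.ref_start + t] += rc != qc
        elif op.type == "gap_qry":
            for t in range(op.ref_start, op.ref_end):
                if ref.seq[t] != "N":
                    comparable[t] += 1
                    diff[t] += 1
        elif op.type == "gap_ref":
            at = max(op.ref_start - 1, 0)
            comparable[at] += op.qry_end - op.qry_start
            diff[at] += op.qry_end - op.qry_start
    for w in wins:
        assert w.n_comparable == comparable[w.ref_start : w.ref_end].sum()
        assert w.n_diff == diff[w.ref_start : w.ref_end].sum()


def test_short_reference_single_window_warns():
    s = _random_seq(400, seed=5)
    amap, _, oriented = A.align_genomes(s, s, k=11)
    with pytest.warns(UserWarning):
        wins = W.window_dissimilarity(amap, s, oriented, window=1000, step=200)
    assert len(wins) == 1 and wins[0].ref_end == 400


def test_hotspot_merging_matches_reported_interval():
    """Two overlapping qualifying windows merge into one [50800, 52000) span."""
    wins = [
        WindowStat(50_800, 51_800, 1000, 15, 0.0),
        WindowStat(51_000, 52_000, 1000, 18, 0.0),
        WindowStat(60_000, 61_000, 1000, 2, 0.0),
    ]
    hots = W.call_hotspots(wins, [], threshold=1.0)
    assert len(hots) == 1
    assert (hots[0].ref_start, hots[0].ref_end) == (50_800, 52_000)
    assert hots[0].peak == pytest.approx(1.8)


def test_hotspot_threshold_is_strict():
    wins = [WindowStat(0, 1000, 1000, 10, 0.0)]  # exactly 1.0%
    assert W.call_hotspots(wins, [], threshold=1.0) == []


def test_hotspot_flanking_gene_names():
    feats = [GeneFeature("trnQ", "tRNA", [(49_000, 49_100)]),
             GeneFeature("accD", "CDS", [(52_500, 53_600)])]
    wins = [WindowStat(50_800, 51_800, 1000, 20, 0.0)]
    hots = W.call_hotspots(wins, feats, threshold=1.0)
    assert hots[0].label == "trnQ-accD intergenic"


def test_hotspot_from_planted_intergenic_cluster():
    from plastcomp.synthetic import SyntheticConfig, generate_reference, mutate_genome

    cfg = SyntheticConfig(genome_length=25_000, n_genes=10, n_snv=10, n_indels=0,
                          n_intergenic_snv=25, seed=77)
    ref, truth0 = generate_reference(cfg)
    # plant the intergenic cluster in the widest spacer
    feats = sorted(ref.features, key=lambda f: f.start)
    gaps = [(a.end, b.start, a.name, b.name) for a, b in zip(feats, feats[1:])]
    s, e, left, right = max(gaps, key=lambda g: g[1] - g[0])
    cfg.intergenic_snv_region = (s + 5, e - 5)
    qry, truth = mutate_genome(ref, truth0, cfg)
    amap, _, oriented = A.align_genomes(ref.seq, qry.seq)
    wins = W.window_dissimilarity(amap, ref.seq, oriented)
    hots = W.call_hotspots(wins, ref.features, threshold=1.0)
    labels = {h.label for h in hots}
    assert f"{left}-{right} intergenic" in labels
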