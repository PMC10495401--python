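"""SSR, long-repeat and tandem-repeat detection against brute-force oracles."""

import numpy as np
import pytest

from oracles import long_repeat_scan, ssr_scan
from plastcomp import repeats as R
from plastcomp.repeats import DEFAULT_SSR_THRESHOLDS
from plastcomp.synthetic import SyntheticConfig, generate_reference


def _random_seq(n, seed=0, gc=0.35):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# SSRs


def test_mono_run_at_threshold():
    s = _random_seq(200, seed=1) + "G" + "A" * 10 + "G" + _random_seq(200, seed=2)
    hits = [r for r in R.find_ssrs(s) if r.motif == "A"]
    assert len(hits) == 1
    r = hits[0]
    assert (r.copies, r.motif_class, r.end - r.start) == (10, "A/T", 10)


def test_mono_run_below_threshold_ignored():
    s = "G" + "A" * 9 + "G"
    assert [r for r in R.find_ssrs(s) if r.motif == "A"] == []


def test_dinucleotide_reported_at_its_own_period():
    s = "GGG" + "AT" * 5 + "GGG"
    hits = R.find_ssrs(s)
    assert len(hits) == 1
    assert (hits[0].motif, hits[0].copies, hits[0].motif_class) == ("AT", 5, "AT/AT")


def test_nonprimitive_unit_reported_once_at_true_period():
    s = "C" + "A" * 12 + "C"  # also matches period 2/3/4 with unit A^k
    hits = R.find_ssrs(s)
    assert len(hits) == 1 and hits[0].motif == "A" and hits[0].copies == 12


@pytest.mark.parametrize("motif,expected", [
    ("A", "A/T"), ("T", "A/T"), ("AT", "AT/AT"), ("AAAAT", "AAAAT/ATTTT"),
    ("GA", "AG/CT"),
])
def test_canonical_motif_class(motif, expected):
    assert R.canonical_motif_class(motif) == expected


@pytest.mark.parametrize("seed", range(10))
def test_ssr_oracle_equivalence_random(seed):
    s = _random_seq(2_000, seed=seed, gc=0.3)
    ours = {(r.start, r.end, r.motif) for r in R.find_ssrs(s)}
    assert ours == ssr_scan(s, DEFAULT_SSR_THRESHOLDS)


# ---------------------------------------------------------------------------
# Long repeats


def _plant_pair(seq, copy, pos1, pos2, orient="F", mismatches=()):
    from plastcomp.codons import complement, revcomp

    s = list(seq)
    s[pos1 : pos1 + len(copy)] = copy
    if orient == "F":
        c2 = list(copy)
    elif orient == "P":
        c2 = list(revcomp(copy))
    elif orient == "R":
        c2 = list(copy[::-1])
    else:
        c2 = list(complement(copy))
    for m in mismatches:
        c2[m] = {"A": "C", "C": "A", "G": "T", "T": "G"}[c2[m]]
    s[pos2 : pos2 + len(copy)] = c2
    return "".join(s)


def test_planted_exact_forward_duplicate():
    seq = _plant_pair(_random_seq(1_000, seed=3), _random_seq(40, seed=4),
                      200, 600, "F")
    ours = {(r.orientation, r.pos1, r.pos2, r.length, r.mismatches)
            for r in R.find_long_repeats(seq)}
    oracle = long_repeat_scan(seq)
    assert ours == oracle
    f = [r for r in ours if r[0] == "F" and r[1] <= 200 and r[2] >= 600]
    assert len(f) == 1 and f[0][3] >= 40  # covers the plant (flank extension allowed)


def test_planted_palindrome_with_mismatches():
    seq = _plant_pair(_random_seq(1_200, seed=5), _random_seq(35, seed=6),
                      100, 700, "P", mismatches=(10, 22))
    ours = {(r.orientation, r.pos1, r.pos2, r.length, r.mismatches)
            for r in R.find_long_repeats(seq)}
    assert ours == long_repeat_scan(seq)
    assert any(r[0] == "P" for r in ours)


def test_identity_strictly_above_90_percent():
    # 30 bp with 3 mismatches is exactly 90% identity -> must not qualify
    assert not R._qualifies(30, 3, 30, 3, 0.90)
    assert R._qualifies(31, 3, 30, 3, 0.90)
    assert R._qualifies(40, 0, 30, 3, 0.90)


@pytest.mark.parametrize("seed", range(6))
def test_long_repeat_oracle_equivalence_random(seed):
    s = _random_seq(1_500, seed=100 + seed, gc=0.3)
    ours = {(r.orientation, r.pos1, r.pos2, r.length, r.mismatches)
            for r in R.find_long_repeats(s)}
    assert ours == long_repeat_scan(s)


def test_four_orientation_classes_recovered_from_synthetic_genome():
    cfg = SyntheticConfig(genome_length=20_000, n_genes=8, seed=11)
    ref, truth = generate_reference(cfg)
    found = R.find_long_repeats(ref.seq)
    for p in truth.repeats:
        hits = [r for r in found
                if (r.orientation, r.pos1, r.pos2, r.length, r.mismatches)
                == (p.orientation, p.pos1, p.pos2, p.length, p.mismatches)]
        assert len(hits) == 1, p


def test_top_caps_per_orientation():
    cfg = SyntheticConfig(genome_length=20_000, n_genes=8, seed=11)
    ref, _ = generate_reference(cfg)
    capped = R.find_long_repeats(ref.seq, top=1)
    per = {}
    for r in capped:
        per[r.orientation] = per.get(r.orientation, 0) + 1
    assert all(v <= 1 for v in per.values())


# ---------------------------------------------------------------------------
# Tandem repeats


def test_tandem_unit_repeated_three_times():
    unit = _random_seq(20, seed=7)
    seq = _random_seq(300, seed=8) + unit * 3 + _random_seq(300, seed=9)
    calls = R.find_tandem_repeats(seq)
    hit = [t for t in calls if 280 <= t.start <= 320]
    assert len(hit) == 1
    assert hit[0].period == 20 and hit[0].copies == pytest.approx(3, abs=0.3)


def test_pure_ssr_not_called_as_tandem():
    assert R.find_tandem_repeats("G" + "A" * 30 + "G") == []


def test_noisy_partial_copies():
    unit = _random_seq(40, seed=10)
    tract = list(unit * 2 + unit[:20])
    tract[7] = "A" if tract[7] != "A" else "G"
    tract[53] = "A" if tract[53] != "A" else "G"
    seq = _random_seq(200, seed=11) + "".join(tract) + _random_seq(200, seed=12)
    calls = R.find_tandem_repeats(seq)
    hit = [t for t in calls if abs(t.start - 200) < 30]
    assert hit and hit[0].copies == pytest.approx(2.5, abs=0.3)
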