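"""Primer scoring, site search, amplicon extraction, and primer metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paleo16s as p
from paleo16s.insilico_pcr import (
    PENALTIES,
    PASS_THRESHOLD,
    THREE_PRIME_LEN,
    _scan_scores,
    _primer_masks,
    _target_masks,
    length_ci,
    median_lower,
    reverse_complement,
    score_primer_alignment,
)
from paleo16s.reference_io import ReferenceRecord, TaxonomyLineage

LIN = TaxonomyLineage.from_labels("Bacteria", "Testphylum")

# ---------------------------------------------------------------------------
# independent brute-force oracle: recursive enumeration of <=1-gap alignments

_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def _oracle_match(pb: str, tb: str) -> bool:
    if tb == "N":
        return False
    return bool(_SETS[pb] & _SETS[tb])


def _oracle_mismatch_pen(k: int, L: int) -> float:
    if k == L - 1:
        return PENALTIES["last_mismatch"]
    if k >= L - THREE_PRIME_LEN:
        return PENALTIES["three_mismatch"]
    return PENALTIES["non3_mismatch"]


def _oracle_gap_pen(n_primer_bases_3prime: int) -> float:
    if n_primer_bases_3prime < THREE_PRIME_LEN:
        return PENALTIES["three_gap"]
    return PENALTIES["non3_gap"]


def oracle_score(primer: str, window: str) -> float:
    """Minimum penalty over all global alignments with at most one gap."""
    L, W = len(primer), len(window)
    best = [np.inf]

    def walk(k, t, gaps, acc):
        if acc >= best[0]:
            return
        if k == L and t == W:
            best[0] = acc
            return
        if k < L and t < W:  # aligned column
            pen = 0.0 if _oracle_match(primer[k], window[t]) else _oracle_mismatch_pen(k, L)
            walk(k + 1, t + 1, gaps, acc + pen)
        if gaps == 0:
            if k < L:  # primer base k unaligned (gap in target)
                walk(k + 1, t, 1, acc + _oracle_gap_pen(L - 1 - k))
            if t < W:  # window base t unaligned (gap in primer before base k)
                walk(k, t + 1, 1, acc + _oracle_gap_pen(L - k))

    walk(0, 0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# penalty-scheme conformance

PRIMER16 = "ACGTACGTACGTACGT"


@pytest.mark.parametrize(
    "mutate,score,passed",
    [
        (lambda w: w, 0.0, True),
        # two mismatches outside the last 5 bases
        (lambda w: "TT" + w[2:], 0.80, True),
        # single mismatch at the final base
        (lambda w: w[:-1] + "C", 3.00, False),
        # one gap outside the 3' window (primer base 3 deleted from the window)
        (lambda w: w[:3] + w[4:], 1.00, True),
        # a 3' mismatch that is not the final base
        (lambda w: w[:-3] + "A" + w[-2:], 1.00, True),
    ],
)
def test_penalty_scheme_cases(mutate, score, passed):
    match = score_primer_alignment(PRIMER16, mutate(PRIMER16))
    assert match.score == pytest.approx(score, abs=1e-9)
    assert match.passed is passed


def test_breakdown_consistent_with_score():
    m = score_primer_alignment(PRIMER16, "TT" + PRIMER16[2:])
    total = sum(PENALTIES[k] * v for k, v in m.breakdown.items())
    assert m.score == pytest.approx(total)


def test_window_length_bounds():
    with pytest.raises(ValueError):
        score_primer_alignment(PRIMER16, PRIMER16[:-2])
    with pytest.raises(ValueError):
        score_primer_alignment(PRIMER16, PRIMER16 + "AC")


def test_scoring_matches_bruteforce_oracle_on_random_cases(rng):
    """1,000 random primer/window pairs agree with exhaustive enumeration."""
    bases = "ACGT"
    degenerate = "ACGTRYSWKMN"
    for _ in range(1000):
        L = int(rng.integers(6, 11))
        primer = "".join(degenerate[i] for i in rng.integers(0, len(degenerate), L))
        wl = L + int(rng.integers(-1, 2))
        window = "".join("ACGTN"[i] for i in rng.integers(0, 5, wl))
        got = score_primer_alignment(primer, window).score
        assert got == pytest.approx(oracle_score(primer, window), abs=1e-9), (
            primer,
            window,
        )


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_position_symmetry_of_non3_mismatches(seed):
    """Permuting non-3' mismatch positions leaves the score unchanged."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(8, 16))
    primer = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
    k_mm = int(rng.integers(1, 3))
    positions = rng.choice(L - THREE_PRIME_LEN, size=k_mm, replace=False)
    scores = set()
    for _ in range(3):
        positions = rng.choice(L - THREE_PRIME_LEN, size=k_mm, replace=False)
        w = list(primer)
        for pos in positions:
            w[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[w[pos]]
        scores.add(round(score_primer_alignment(primer, "".join(w)).score, 9))
    assert len(scores) == 1
    assert scores.pop() == pytest.approx(0.40 * k_mm)


def test_impossible_pass_combinations():
    """>= 3 non-3' mismatches or any 3' gap cannot pass."""
    w = "TTT" + PRIMER16[3:]  # 3 non-3' mismatches
    m = score_primer_alignment(PRIMER16, w)
    assert m.score == pytest.approx(1.20) and not m.passed
    w = PRIMER16[:-1]  # best single deletion still inside 3' window? force it:
    # deleting the final base is a 3' gap; any other deletion adds mismatches
    m = score_primer_alignment(PRIMER16[:6] + "G" * 5 + PRIMER16[11:], PRIMER16[:-1])
    assert m.score > PASS_THRESHOLD or m.breakdown["three_gap"] == 0


# ---------------------------------------------------------------------------
# site search

FWD = p.Primer("F", "GGATTAGATACCCTGGTA", "forward")


def _record(seq: str) -> ReferenceRecord:
    return ReferenceRecord("r", LIN, seq)


def test_find_best_site_planted_exact(rng):
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    seq = flank[:97] + FWD.sequence + flank[97:]
    m = p.find_best_site(FWD, _record(seq), "forward")
    assert m is not None and m.score == 0.0
    assert (m.target_start, m.target_end) == (97, 97 + len(FWD))


def test_find_best_site_none_when_nothing_passes():
    assert p.find_best_site(FWD, _record("A" * 300), "forward") is None


def test_find_best_site_prefers_lower_score_over_position(rng):
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    near = "TT" + FWD.sequence[2:]  # score 0.8 site, earlier position
    seq = flank[:50] + near + flank[50:150] + FWD.sequence + flank[150:]
    m = p.find_best_site(FWD, _record(seq), "forward")
    assert m.score == 0.0
    assert m.target_start == 50 + len(near) + 100


def test_reverse_primer_found_as_revcomp_on_sense(rng):
    rev = p.Primer("R", "ATTACCGCGGCTGCTGG", "reverse")
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    site = reverse_complement(rev.sequence)
    seq = flank[:200] + site + flank[200:]
    m = p.find_best_site(rev, _record(seq), "reverse")
    assert m is not None and m.score == 0.0
    assert (m.target_start, m.target_end) == (200, 217)
    assert m.strand == "sense-revcomp"


def test_target_n_never_matches():
    m = score_primer_alignment("ACGTAN", "ACGTAN")
    # primer N vs target N is still a (final-base) mismatch
    assert m.score == pytest.approx(3.0)


def test_scan_agrees_with_per_window_scoring(rng):
    """Vectorized all-site scan equals direct per-window scoring."""
    for _ in range(25):
        L = int(rng.integers(6, 12))
        primer = "".join("ACGTRY"[i] for i in rng.integers(0, 6, L))
        target = "".join("ACGTN"[i] for i in rng.integers(0, 5, 40))
        scan = {
            (s, wl): score
            for score, s, wl in _scan_scores(_primer_masks(primer), _target_masks(target))
        }
        for wl in (L - 1, L, L + 1):
            for s in range(0, 40 - wl + 1):
                direct = score_primer_alignment(primer, target[s : s + wl]).score
                assert scan[(s, wl)] == pytest.approx(direct, abs=1e-9)


# ---------------------------------------------------------------------------
# amplicon extraction

def _planted_template(pair, fwd_start_1based: int, rev_end_1based: int, total=1540, seed=5):
    """Template with exact sites; coordinates 1-based inclusive."""
    rng = np.random.default_rng(seed)
    fwd_site = pair.forward.sequence.replace("M", "A").replace("H", "A").replace("V", "A").replace("W", "A")
    rev_site = reverse_complement(
        pair.reverse.sequence.replace("M", "A").replace("H", "A").replace("V", "A").replace("W", "A")
    )
    fs = fwd_start_1based - 1
    re_ = rev_end_1based
    gap = re_ - len(rev_site) - (fs + len(fwd_site))
    assert gap >= 0
    rand = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    seq = rand(fs) + fwd_site + rand(gap) + rev_site + rand(total - re_)
    return ReferenceRecord("tpl", LIN, seq)


def test_extract_amplicon_v3_coordinates_give_194(v3_pair):
    rec = _planted_template(v3_pair, 341, 534)
    amp = p.extract_amplicon(v3_pair, rec)
    assert amp is not None
    assert amp.length == 194
    assert (amp.amp_start, amp.amp_end) == (340, 534)
    assert amp.sequence == rec.sequence[340:534]


def test_extract_amplicon_v4_coordinates_give_292(v4_pair):
    rec = _planted_template(v4_pair, 515, 806)
    amp = p.extract_amplicon(v4_pair, rec)
    assert amp is not None and amp.length == 292


def test_extract_amplicon_fails_on_final_base_mismatch(v3_pair):
    rec = _planted_template(v3_pair, 341, 534)
    # mutate the final 3' base of the forward site (0-based 340 + 16)
    pos = 340 + len(v3_pair.forward) - 1
    base = rec.sequence[pos]
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    mutated = ReferenceRecord("m", LIN, rec.sequence[:pos] + flip + rec.sequence[pos + 1 :])
    assert p.extract_amplicon(v3_pair, mutated) is None


def test_extract_amplicon_requires_forward_before_reverse(v3_pair, rng):
    fwd_site = v3_pair.forward.sequence
    rev_site = reverse_complement(v3_pair.reverse.sequence)
    rand = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    seq = rand(100) + rev_site + rand(50) + fwd_site + rand(100)
    assert p.extract_amplicon(v3_pair, ReferenceRecord("x", LIN, seq)) is None


def test_extract_amplicon_max_len_cap(v3_pair):
    rec = _planted_template(v3_pair, 341, 900, total=1540)
    assert p.extract_amplicon(v3_pair, rec, max_len=500) is None
    assert p.extract_amplicon(v3_pair, rec, max_len=600).length == 560


def test_extract_amplicon_revcomp_rescan(v3_pair):
    rec = _planted_template(v3_pair, 341, 534)
    flipped = ReferenceRecord("f", LIN, reverse_complement(rec.sequence))
    assert p.extract_amplicon(v3_pair, flipped) is None
    amp = p.extract_amplicon(v3_pair, flipped, scan_revcomp=True)
    assert amp is not None and amp.length == 194


# ---------------------------------------------------------------------------
# length summaries / CI / coverage / resolution

def test_amplicon_length_distribution_planted(three_clade_db, v3_pair):
    spec, db = three_clade_db
    summaries = {s.group: s for s in p.amplicon_length_distribution(db, v3_pair, "genus")}
    assert summaries["Methanobrevibacter"].median == 151
    assert summaries["Anaerolineae G-1"].median == 169
    assert summaries["Streptococcus"].median == 194
    for s in summaries.values():
        assert s.ci_low == s.median == s.ci_high  # planted constant lengths
        assert s.n == 3


def test_length_distribution_unknown_rank_errors(three_clade_db, v3_pair):
    _, db = three_clade_db
    with pytest.raises(KeyError):
        p.amplicon_length_distribution(db, v3_pair, "kingdom")


def test_lower_median_rule():
    assert median_lower([173, 190]) == 173
    assert median_lower([151]) == 151
    assert median_lower([1, 2, 3]) == 2


@pytest.mark.parametrize(
    "lengths,expected",
    [
        ([183] * 100, (183, 183)),
        (list(range(1, 1001)), (5, 995)),  # nearest-rank at 0.5% / 99.5%
        ([42], (42, 42)),
    ],
)
def test_length_ci_nearest_rank(lengths, expected):
    assert length_ci(lengths, 0.99) == expected


def test_length_ci_bounds_order_and_errors(rng):
    vals = rng.integers(150, 200, size=57).tolist()
    lo, hi = length_ci(vals)
    assert lo <= median_lower(vals) <= hi
    with pytest.raises(ValueError):
        length_ci([])


def test_taxonomic_coverage_full_and_partial(three_clade_db, v3_pair):
    _, db = three_clade_db
    cov = p.taxonomic_coverage(db, v3_pair)
    assert set(cov.rows["phylum"]) == {"Euryarchaeota", "Chloroflexi", "Firmicutes"}
    assert (cov.rows["fraction"] == 1.0).all()
    assert (cov.rows["n_amplified"] <= cov.rows["n_total"]).all()


def test_coverage_zero_for_defect_clade(v3_pair):
    clades = (
        p.CladeSpec(
            TaxonomyLineage.from_labels("Bacteria", "GoodPhylum", *[""] * 3, "Goodgenus"),
            n_otus=4, amplicon_length=180,
        ),
        p.CladeSpec(
            TaxonomyLineage.from_labels("Bacteria", "BadPhylum", *[""] * 3, "Badgenus"),
            n_otus=4, amplicon_length=180, primer_site_defect="last_base_mismatch",
        ),
    )
    spec = p.SyntheticDbSpec(clades=clades, seed=11)
    db = p.generate_reference_db(spec, v3_pair)
    cov = p.taxonomic_coverage(db, v3_pair)
    assert cov.fraction("GoodPhylum") == 1.0
    assert cov.fraction("BadPhylum") == 0.0


def test_coverage_invariant_under_shuffling(three_clade_db, v3_pair, rng):
    _, db = three_clade_db
    records = db.records
    rng.shuffle(records)
    shuffled = p.ReferenceDatabase(records)
    a = p.taxonomic_coverage(db, v3_pair).rows.set_index("phylum")["fraction"]
    b = p.taxonomic_coverage(shuffled, v3_pair).rows.set_index("phylum")["fraction"]
    assert a.sort_index().equals(b.sort_index())


def test_resolution_identical_sequences_one_otu(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
    rep = p.taxonomic_resolution([seq] * 50)
    assert rep.n_otus == 1 and rep.n_input == 50


def test_resolution_distinct_families(rng):
    families = ["".join("ACGT"[i] for i in rng.integers(0, 4, 120)) for _ in range(5)]
    seqs = [f for f in families for _ in range(20)]
    rng.shuffle(seqs)
    rep = p.taxonomic_resolution(seqs)
    assert rep.n_otus == 5


def test_resolution_all_dissimilar(rng):
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 100)) for _ in range(10)]
    rep = p.taxonomic_resolution(seqs, reference_total_otus=20)
    assert rep.n_otus == 10
    assert rep.resolution_fraction == pytest.approx(0.5)


def test_resolution_order_invariance(rng):
    seqs = {f"id{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 90)) for i in range(12)}
    a = p.taxonomic_resolution(seqs).n_otus
    b = p.taxonomic_resolution(dict(reversed(list(seqs.items())))).n_otus
    assert a == b


def test_resolution_empty_errors():
    with pytest.raises(ValueError):
        p.taxonomic_resolution([])
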