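"""Complementarity scoring vs a brute-force alignment enumerator."""

import itertools

import numpy as np
import pytest

from eumir.config import TargetConfig
from eumir.io import revcomp
from eumir.targets import complementarity_score, pair_kind, scan_transcriptome

CFG = TargetConfig()


def oracle_score(mirna: str, window: str, cfg: TargetConfig = CFG) -> float:
    """Exhaustive recursion over all global alignments with <= max_gaps.

    Written independently of the implementation: consumes the
    reversed miRNA and the window left to right, trying pair, miRNA
    bulge and target bulge at every step.
    """
    rev = mirna[::-1]
    L = len(rev)

    def factor(pos):
        return cfg.seed_factor if cfg.seed_start <= pos <= cfg.seed_end else 1.0

    def base_pen(kind):
        return {"|": cfg.wc, "o": cfg.wobble, ".": cfg.mismatch}[kind]

    def rec(i, j, gaps):
        if i == L and j == len(window):
            return 0.0
        best = np.inf
        if i < L and j < len(window):
            pen = base_pen(pair_kind(rev[i], window[j])) * factor(L - i)
            best = min(best, pen + rec(i + 1, j + 1, gaps))
        if gaps < cfg.max_gaps and i < L:  # miRNA base unpaired
            best = min(best, cfg.gap * factor(L - i) + rec(i + 1, j, gaps + 1))
        if gaps < cfg.max_gaps and j < len(window):  # target base unpaired
            pos = L - i if i < L else 1
            best = min(best, cfg.gap * factor(pos) + rec(i, j + 1, gaps + 1))
        return best

    return rec(0, 0, 0)


def test_perfect_complement_scores_zero():
    mirna = "TGACAGAAGAGAGTGAGCACA"
    aln = complementarity_score(mirna, revcomp(mirna))
    assert aln.score == 0.0
    assert aln.string == "|" * len(mirna)
    assert aln.n_gaps == 0


def test_wobble_position_dependent_penalty():
    mirna = "A" * 14 + "G" + "A" * 6  # 21 nt, G at position 15
    window = list(revcomp(mirna))
    # target base opposite miRNA position 15 sits at window index 21-15
    window[21 - 15] = "T"  # G:C -> G:T wobble
    aln = complementarity_score(mirna, "".join(window))
    assert aln.score == 0.5  # outside the seed

    mirna = "A" * 4 + "G" + "A" * 16  # G at position 5 (seed)
    window = list(revcomp(mirna))
    window[21 - 5] = "T"
    aln = complementarity_score(mirna, "".join(window))
    assert aln.score == pytest.approx(0.75)  # 0.5 x 1.5


def test_score_monotone_in_defects():
    mirna = "TGACAGAAGAGAGTGAGCACA"
    window = list(revcomp(mirna))
    prev = complementarity_score(mirna, "".join(window)).score
    for idx in (0, 3, 17):  # introduce mismatches one at a time
        window[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[window[idx]]
        score = complementarity_score(mirna, "".join(window)).score
        assert score > prev
        prev = score


def test_ambiguous_base_errors():
    with pytest.raises(ValueError):
        complementarity_score("ACGTN" + "A" * 16, "T" * 21)


@pytest.mark.parametrize("seed", range(20))
def test_dp_matches_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(8, 13))
    mirna = "".join(rng.choice(list("ACGT"), L))
    width = L + int(rng.integers(-1, 2))
    window = "".join(rng.choice(list("ACGT"), width))
    aln = complementarity_score(mirna, window)
    assert aln.score == pytest.approx(oracle_score(mirna, window))


def test_alignment_site_position_tracks_pos10():
    mirna = "TGACAGAAGAGAGTGAGCACA"
    aln = complementarity_score(mirna, revcomp(mirna))
    # ungapped: miRNA position 10 pairs window offset L - 10
    assert aln.target_offset_of(10) == len(mirna) - 10
    assert aln.kind_at(10) == "|"


def test_scan_finds_exact_complement_site():
    rng = np.random.default_rng(3)
    mirna = "".join(rng.choice(list("ACGT"), 21))
    flanks = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(2)]
    transcript = flanks[0] + revcomp(mirna) + flanks[1]
    hits = scan_transcriptome({"m1": mirna}, {"t1": transcript}, cutoff=0.0)
    assert len(hits) == 1
    row = hits.iloc[0]
    assert (row["start"], row["end"]) == (201, 221)
    assert row["score"] == 0.0
    assert row["site_pos"] == 201 + 21 - 10
    assert row["pos10_11_wc"]


def test_scan_scrambled_transcripts_no_perfect_hits():
    rng = np.random.default_rng(4)
    mirnas = {f"m{i}": "".join(rng.choice(list("ACGT"), 21))
              for i in range(5)}
    transcripts = {f"t{i}": "".join(rng.choice(list("ACGT"), 800))
                   for i in range(5)}
    hits = scan_transcriptome(mirnas, transcripts, cutoff=0.0)
    assert len(hits) == 0


def test_scan_order_invariant():
    rng = np.random.default_rng(5)
    mirna = "".join(rng.choice(list("ACGT"), 21))
    txs = {f"t{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(4)}
    txs["t2"] = txs["t2"][:100] + revcomp(mirna) + txs["t2"][121:]
    reordered = dict(reversed(list(txs.items())))
    a = scan_transcriptome({"m": mirna}, txs, cutoff=4.0)
    b = scan_transcriptome({"m": mirna}, reordered, cutoff=4.0)
    assert a.equals(b)


def test_scan_merges_overlapping_hits():
    rng = np.random.default_rng(6)
    mirna = "".join(rng.choice(list("ACGT"), 21))
    transcript = "".join(rng.choice(list("ACGT"), 100)) + revcomp(mirna) \
        + "".join(rng.choice(list("ACGT"), 100))
    hits = scan_transcriptome({"m": mirna}, {"t": transcript}, cutoff=5.0)
    perfect = hits[hits["score"] == 0.0]
    assert len(perfect) == 1  # gapped near-variants merged into the best
    spans = hits[["start", "end"]].to_numpy()
    for (s1, e1), (s2, e2) in itertools.combinations(spans, 2):
        assert e1 < s2 or e2 < s1  # surviving hits do not overlap


def test_scan_window_scores_match_single_alignment():
    rng = np.random.default_rng(7)
    mirna = "".join(rng.choice(list("ACGT"), 18))
    transcript = "".join(rng.choice(list("ACGT"), 300))
    hits = scan_transcriptome({"m": mirna}, {"t": transcript}, cutoff=12.0)
    assert len(hits) > 0
    for _, row in hits.head(10).iterrows():
        window = transcript[row["start"] - 1:row["end"]]
        assert complementarity_score(mirna, window).score == \
            pytest.approx(row["score"])
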