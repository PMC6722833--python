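"""T-plot construction and category 0-4 classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eumir.degradome import (DegradomeProfile, build_profile,
                             classify_category, tplot_data, validate_cleavage)
from eumir.io import revcomp
from eumir.targets import scan_transcriptome


def profile_from(counts):
    return DegradomeProfile("t1", np.array(counts, dtype=float))


def category_oracle(counts, site1):
    """Literal transcription of the five category definitions, each
    evaluated independently of the implementation's short-circuit
    order (category 4 takes precedence for single-read sites)."""
    counts = np.asarray(counts, dtype=float)
    x = counts[site1 - 1]
    assert x >= 1
    covered = counts[counts >= 1]
    maximum = counts.max()
    n_max = int((counts == maximum).sum())
    median = float(np.median(covered))
    if x == 1:
        return 4
    if x == maximum and n_max == 1:
        return 0
    if x == maximum and n_max > 1:
        return 1
    if x < maximum and x > median:
        return 2
    return 3


def test_category_printed_examples():
    assert classify_category(profile_from([5, 1, 1]), 1) == 0
    assert classify_category(profile_from([5, 5, 1]), 1) == 1
    p = profile_from([9, 3, 2, 2, 1])  # covered median 2
    assert classify_category(p, 2) == 2
    assert classify_category(p, 3) == 3
    assert classify_category(p, 5) == 4


def test_category_unsupported_site_errors():
    with pytest.raises(ValueError, match="support"):
        classify_category(profile_from([0, 5]), 1)


def test_single_read_unique_max_is_category_4():
    # "only one raw read at the position" wins over the maximum rule
    assert classify_category(profile_from([1, 0, 0]), 1) == 4


def test_category_exhaustive_oracle_agreement():
    seen = set()
    for counts in itertools.product(range(4), repeat=5):
        if sum(counts) == 0:
            continue
        profile = profile_from(counts)
        for site1 in range(1, 6):
            if counts[site1 - 1] == 0:
                continue
            got = classify_category(profile, site1)
            assert got == category_oracle(counts, site1)
            seen.add(got)
    assert seen == {0, 1, 2, 3, 4}


def test_build_profile_exact_match_positions():
    rng = np.random.default_rng(0)
    t = "".join(rng.choice(list("ACGT"), 300))
    tag = t[100:120]  # starts at 1-based position 101
    profiles, unmapped = build_profile([tag] * 7, {"tx": t})
    assert profiles["tx"][101] == 7
    assert unmapped == 0


def test_build_profile_mismatch_contributes_nothing():
    rng = np.random.default_rng(1)
    t = "".join(rng.choice(list("ACGT"), 300))
    tag = list(t[100:120])
    tag[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[5]]
    profiles, unmapped = build_profile(["".join(tag)], {"tx": t})
    assert profiles["tx"].counts.sum() == 0
    assert unmapped == 1


def test_build_profile_multimapping_tag_hits_both():
    rng = np.random.default_rng(2)
    core = "".join(rng.choice(list("ACGT"), 20))
    t1 = "".join(rng.choice(list("ACGT"), 100)) + core
    t2 = core + "".join(rng.choice(list("ACGT"), 100))
    profiles, _ = build_profile([core], {"t1": t1, "t2": t2})
    assert profiles["t1"][101] == 1
    assert profiles["t2"][1] == 1


def test_build_profile_rejects_bad_tag_length():
    with pytest.raises(ValueError):
        build_profile(["ACGT"], {"t": "ACGT" * 30})


def _hits_for(mirna, transcript, **kw):
    return scan_transcriptome({"m1": mirna}, {"tx": transcript}, **kw)


def test_validate_cleavage_category0_at_spike():
    rng = np.random.default_rng(3)
    mirna = "".join(rng.choice(list("ACGT"), 21))
    t = "".join(rng.choice(list("ACGT"), 200)) + revcomp(mirna) \
        + "".join(rng.choice(list("ACGT"), 200))
    site = 201 + 21 - 10
    tags = [t[site - 1:site + 19]] * 50 + [t[10:30], t[50:70]]
    profiles, _ = build_profile(tags, {"tx": t})
    hits = _hits_for(mirna, t, cutoff=5.0)
    events, rejected = validate_cleavage(hits, profiles)
    assert len(events) == 1
    row = events.iloc[0]
    assert row["site"] == site
    assert row["category"] == 0
    assert row["site_abundance"] == 50


def test_validate_rejects_mismatch_at_position_10():
    rng = np.random.default_rng(4)
    mirna = "".join(rng.choice(list("ACGT"), 21))
    window = list(revcomp(mirna))
    idx = 21 - 10  # target base opposite miRNA position 10
    window[idx] = {"A": "G", "G": "A", "C": "T", "T": "C"}[window[idx]]
    t = "".join(rng.choice(list("ACGT"), 100)) + "".join(window) \
        + "".join(rng.choice(list("ACGT"), 100))
    hits = _hits_for(mirna, t, cutoff=5.0)
    assert len(hits) == 1 and not hits.iloc[0]["pos10_11_wc"]
    profiles, _ = build_profile([t[0:20]], {"tx": t})
    profiles["tx"].counts[:] = 1  # support everywhere
    events, rejected = validate_cleavage(hits, profiles)
    assert len(events) == 0
    assert "10-11" in rejected.iloc[0]["reason"]


def test_validate_rejects_budget_exceeded():
    hits = pd.DataFrame([{
        "miRNA": "m1", "transcript": "tx", "start": 1, "end": 21,
        "score": 9.0, "gaps": 0, "mismatches": 6, "wobbles": 0,
        "pos10_11_wc": True, "site_pos": 12, "alignment": "." * 21,
    }])
    profiles = {"tx": profile_from([2] * 30)}
    events, rejected = validate_cleavage(hits, profiles)
    assert len(events) == 0
    assert rejected.iloc[0]["reason"] == "mismatch budget exceeded"


def test_validate_missing_profile_dropped_with_reason():
    hits = pd.DataFrame([{
        "miRNA": "m1", "transcript": "ghost", "start": 1, "end": 21,
        "score": 0.0, "gaps": 0, "mismatches": 0, "wobbles": 0,
        "pos10_11_wc": True, "site_pos": 12, "alignment": "|" * 21,
    }])
    events, rejected = validate_cleavage(hits, {})
    assert len(events) == 0
    assert "profile" in rejected.iloc[0]["reason"]


def test_wobbles_count_half_toward_budget():
    base = {
        "miRNA": "m1", "transcript": "tx", "start": 1, "end": 21,
        "score": 4.0, "gaps": 0, "pos10_11_wc": True, "site_pos": 12,
        "alignment": "|" * 21,
    }
    profiles = {"tx": profile_from([2] * 30)}
    ok = pd.DataFrame([{**base, "mismatches": 4, "wobbles": 2}])   # 5.0
    over = pd.DataFrame([{**base, "mismatches": 4, "wobbles": 3}])  # 5.5
    assert len(validate_cleavage(ok, profiles)[0]) == 1
    assert len(validate_cleavage(over, profiles)[0]) == 0


def test_tplot_series_and_markers():
    profile = profile_from([0, 3, 0, 7, 1])
    events = pd.DataFrame([{"miRNA": "m", "transcript": "t1", "site": 4,
                            "category": 0}])
    series, markers = tplot_data(profile, events)
    assert len(series) == 5
    assert markers == [(4, 7.0)]


def test_tplot_no_events_no_markers():
    series, markers = tplot_data(profile_from([1, 2]), pd.DataFrame())
    assert markers == []
    assert list(series["abundance"]) == [1.0, 2.0]


def test_tplot_rejects_foreign_events():
    events = pd.DataFrame([{"miRNA": "m", "transcript": "other", "site": 1}])
    with pytest.raises(ValueError):
        tplot_data(profile_from([1, 2]), events)
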