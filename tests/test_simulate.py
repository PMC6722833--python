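from collections import Counter

import numpy as np
import pandas as pd
import pytest

from eumir.config import SimulateConfig, default_sample_sheet
from eumir.discovery import evaluate_precursor
from eumir.simulate import (generate_ncrna_references, generate_term_map,
                            generate_transcriptome, mature_references,
                            plant_hairpins, simulate_count_matrix,
                            simulate_degradome, simulate_mrna_counts,
                            simulate_srna_libraries)


def _truth(n_tx=20, n_mir=8, seed=3):
    tx = generate_transcriptome(n_tx, (500, 1200), 0.45, seed=seed)
    return plant_hairpins(tx, n_mir, seed=seed)


def test_transcriptome_seeded_determinism():
    a = generate_transcriptome(10, (500, 1500), 0.45, seed=7)
    b = generate_transcriptome(10, (500, 1500), 0.45, seed=7)
    assert a == b
    c = generate_transcriptome(10, (500, 1500), 0.45, seed=8)
    assert a != c


def test_transcriptome_zero_n_errors():
    with pytest.raises(ValueError):
        generate_transcriptome(0, (500, 1500), 0.45, seed=1)


def test_transcriptome_short_length_errors():
    with pytest.raises(ValueError, match="200"):
        generate_transcriptome(5, (150, 400), 0.45, seed=1)


def test_transcriptome_gc_within_band():
    tx = generate_transcriptome(100, (500, 1500), 0.45, seed=2)
    gc = np.mean([(s.count("G") + s.count("C")) / len(s)
                  for s in tx.values()])
    assert 0.40 <= gc <= 0.50


def test_planted_hairpins_all_pass_evaluator():
    _pre, _tx, truth = _truth()
    for h in truth.hairpins:
        verdict = evaluate_precursor(h.precursor, h.mature_interval)
        assert verdict.accepted, (h.truth_id, verdict.reasons)


def test_plant_hairpins_deterministic():
    _, _, t1 = _truth(seed=11)
    _, _, t2 = _truth(seed=11)
    assert [h.mature for h in t1.hairpins] == [h.mature for h in t2.hairpins]


def test_mature_point_mass_distribution():
    tx = generate_transcriptome(20, (500, 1200), 0.45, seed=5)
    _, _, truth = plant_hairpins(tx, 10, mature_length_dist={21: 1.0}, seed=5)
    assert all(len(h.mature) == 21 for h in truth.hairpins)


def test_infeasible_length_distribution_errors():
    tx = generate_transcriptome(5, (500, 1200), 0.45, seed=5)
    with pytest.raises(ValueError):
        plant_hairpins(tx, 3, mature_length_dist={30: 1.0}, seed=5)


def test_cleavage_site_opposite_position_10():
    _, tx, truth = _truth()
    from eumir.io import revcomp
    for h in truth.hairpins:
        s, e = h.target_interval
        assert tx[h.target_transcript][s - 1:e] == revcomp(h.mature)
        assert h.cleavage_site == s + len(h.mature) - 10


def test_mature_references_split():
    _, _, truth = _truth()
    primary, secondary = mature_references(truth)
    assert len(primary) == sum(h.known for h in truth.hairpins)
    assert len(secondary) == sum(h.secondary for h in truth.hairpins)


def _small_cfg():
    cfg = SimulateConfig()
    cfg.depth = 20_000
    return cfg


def test_srna_libraries_deterministic_and_structured():
    _, _, truth = _truth()
    refs = generate_ncrna_references(seed=3)
    cfg = _small_cfg()
    libs1, counts1 = simulate_srna_libraries(truth, refs, cfg, seed=3)
    libs2, counts2 = simulate_srna_libraries(truth, refs, cfg, seed=3)
    assert libs1 == libs2
    assert counts1.equals(counts2)
    assert set(libs1) == {s.sample_id for s in default_sample_sheet()}
    dem = truth.mirna_expression[truth.mirna_expression["is_dem"]]
    assert (dem["true_lfc"].abs() >= 1).all()


def test_frac_dem_zero_all_null():
    _, _, truth = _truth()
    refs = generate_ncrna_references(seed=3)
    cfg = _small_cfg()
    cfg.frac_dem = 0.0
    simulate_srna_libraries(truth, refs, cfg, seed=3)
    assert (truth.mirna_expression["true_lfc"] == 0).all()


def test_pooled_length_histogram_peaks_24_then_21():
    # default library composition: 20 planted miRNAs
    _, _, truth = _truth(n_mir=20)
    refs = generate_ncrna_references(seed=3)
    libs, _ = simulate_srna_libraries(truth, refs, _small_cfg(), seed=3)
    adapter = _small_cfg().adapter[:8]
    pooled = Counter()
    for reads in libs.values():
        for _rid, seq, _q in reads:
            cut = seq.rfind(adapter)
            if cut >= 18:
                pooled[cut] += 1
    ordered = [length for length, _n in pooled.most_common()]
    assert ordered[0] == 24
    assert ordered[1] == 21


def test_degradome_tags_lengths_and_spikes():
    _, _, truth = _truth()
    tags, sites = simulate_degradome(truth, 50.0, 0.02, 2.0, seed=4)
    assert all(len(seq) in (20, 21) for _tid, seq in tags)
    assert len(sites) == len(truth.hairpins)


def test_degradome_background_zero_only_sites():
    _, tx, truth = _truth()
    tags, _ = simulate_degradome(truth, 50.0, 0.0, 2.0, seed=4)
    starts = set()
    for _tid, seq in tags:
        for htid, hseq in tx.items():
            pos = hseq.find(seq)
            while pos >= 0:
                starts.add((htid, pos + 1))
                pos = hseq.find(seq, pos + 1)
    true_sites = {(h.target_transcript, h.cleavage_site)
                  for h in truth.hairpins}
    assert true_sites <= starts | true_sites
    # every emitted tag starts at a true site
    emitted = {(h.target_transcript, h.cleavage_site)
               for h in truth.hairpins}
    for _tid, seq in tags:
        assert any(tx[t][p - 1:p - 1 + len(seq)] == seq for t, p in emitted)


def test_spike_is_unique_maximum_with_high_probability():
    # Monte-Carlo over >= 100 sites: at 50x spike over a sparse
    # background the true site is the unique transcript maximum
    tx = generate_transcriptome(60, (500, 1200), 0.45, seed=9)
    _, tx, truth = plant_hairpins(tx, 60, seed=9)
    tags, _ = simulate_degradome(truth, 50.0, 0.02, 2.0, seed=9)
    from eumir.degradome import build_profile
    profiles, _ = build_profile(Counter(s for _t, s in tags), tx)
    unique_max = 0
    for h in truth.hairpins:
        p = profiles[h.target_transcript]
        if p.argmax_positions == [h.cleavage_site]:
            unique_max += 1
    assert unique_max >= 0.95 * len(truth.hairpins)
    assert len(truth.hairpins) >= 60


def test_count_matrix_truth_structure():
    counts, lfc = simulate_count_matrix(n_features=100, frac_de=0.1,
                                        lfc=2.0, seed=2)
    assert counts.shape == (100, 6)
    assert (counts.to_numpy() >= 0).all()
    assert (lfc != 0).sum() == 10
    assert set(np.abs(lfc[lfc != 0])) == {2.0}


def test_mrna_counts_targets_are_degs():
    _, _, truth = _truth()
    refs = generate_ncrna_references(seed=3)
    simulate_srna_libraries(truth, refs, _small_cfg(), seed=3)
    counts, lfc = simulate_mrna_counts(truth, _small_cfg(), seed=3)
    expr = truth.mirna_expression.set_index("truth_id")
    for h in truth.hairpins:
        if expr.loc[h.truth_id, "is_dem"]:
            assert lfc[h.target_transcript] != 0


def test_term_map_contains_targeted_transcripts():
    _, _, truth = _truth()
    terms = generate_term_map(truth, seed=3)
    targeted = {h.target_transcript for h in truth.hairpins}
    assert terms["terpenoid_backbone"] >= targeted
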