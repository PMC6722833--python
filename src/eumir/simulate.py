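"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the structure of a two-condition leaf sRNA
study: six libraries (LR = low Eu-rubber content, 1.39%; HR = high,
4.80%; three replicates each), reads of 18-30 nt whose pooled length
histogram peaks at 24 nt with 21 nt second, planted stem-loop
precursors yielding mature miRNAs, negative-binomial counts with a
designated differential subset, and a degradome tag pool with an
abundance spike at the position opposite miRNA nucleotides 10-11 of
every true cleavage site.  Everything is seeded and byte-reproducible.

What it does not emulate: sequencing error models, realistic quality
strings, adapter read-through chemistry beyond a fixed literal
adapter suffix, or genome-scale transcript diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from eumir.config import DiscoveryConfig, SimulateConfig
from eumir.discovery import evaluate_precursor
from eumir.io import revcomp

BASES = np.array(list("ACGT"))

# family labels used for the designated "known" subset of planted miRNAs
KNOWN_FAMILIES = ["MIR156", "MIR396", "MIR166", "MIR172", "MIR403",
                  "MIR168", "MIR398", "MIR167_1", "MIR397", "MIR160"]

# background fragment length profile: 24 nt modal, 21 nt second, as in
# bulk plant sRNA pools (heterochromatic siRNAs dominate at 24 nt)
BACKGROUND_LENGTH_WEIGHTS = {
    18: 0.04, 19: 0.04, 20: 0.05, 21: 0.20, 22: 0.06, 23: 0.07,
    24: 0.25, 25: 0.07, 26: 0.06, 27: 0.05, 28: 0.04, 29: 0.03, 30: 0.04,
}

NCRNA_CLASS_WEIGHTS = {"rRNA": 0.5, "tRNA": 0.2, "snRNA": 0.1,
                       "snoRNA": 0.1, "repeat": 0.1}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


@dataclass
class PlantedHairpin:
    truth_id: str
    mature: str                 # DNA alphabet
    known: bool                 # matched by the miRBase-style reference
    secondary: bool             # matched by the published-set reference
    family: Optional[str]
    precursor_id: str
    precursor: str
    mature_interval: tuple[int, int]   # 1-based, 5' arm
    target_transcript: str
    target_interval: tuple[int, int]   # 1-based site interval
    cleavage_site: int                 # 1-based, opposite miRNA pos 10


@dataclass
class GroundTruth:
    transcripts: dict[str, str]
    precursors: dict[str, str]
    hairpins: list[PlantedHairpin]
    conditions: dict[str, float] = field(
        default_factory=lambda: {"LR": 1.39, "HR": 4.80})
    mirna_expression: Optional[pd.DataFrame] = None  # filled by the sRNA sim
    mrna_lfc: Optional[pd.Series] = None

    @property
    def cleavage_sites(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "truth_id": h.truth_id,
            "mature": h.mature,
            "transcript": h.target_transcript,
            "site": h.cleavage_site,
        } for h in self.hairpins])

    def check(self) -> None:
        for h in self.hairpins:
            s, e = h.mature_interval
            if not 1 <= s <= e <= len(h.precursor):
                raise AssertionError("mature interval outside precursor")
            if not 1 <= h.cleavage_site <= len(self.transcripts[h.target_transcript]):
                raise AssertionError("cleavage site outside transcript")
        if self.mirna_expression is not None:
            expr = self.mirna_expression
            dem = expr[expr["is_dem"]]
            if (dem["true_lfc"].abs() < 1).any():
                raise AssertionError("designated DEM with |true lfc| < 1")
            if (expr.loc[~expr["is_dem"], "true_lfc"] != 0).any():
                raise AssertionError("non-DEM with non-zero true lfc")


def generate_transcriptome(n_transcripts: int,
                           length_range: tuple[int, int] = (500, 1500),
                           gc: float = 0.45, seed: int = 0) -> dict[str, str]:
    """Random transcript set; reproducible for a fixed seed."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo < 200:
        raise ValueError("transcript length must be >= 200 "
                         "(too short to host a cleavage window)")
    rng = _rng(seed, 1)
    out = {}
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        out[f"unigene{i + 1:04d}"] = _random_seq(rng, length, gc)
    return out


def _lengths_from_dist(rng, dist: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    probs = np.array([dist[k] for k in lengths], dtype=float)
    if (lengths < 18).any() or (lengths > 25).any():
        raise ValueError("mature_length_dist must be supported on 18-25 nt")
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def plant_hairpins(transcripts: dict[str, str], n_mirnas: int,
                   mature_length_dist: Optional[dict[int, float]] = None,
                   seed: int = 0, known_fraction: float = 0.4,
                   n_secondary: int = 2,
                   discovery_config: Optional[DiscoveryConfig] = None,
                   ) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Plant hairpin precursors and matching target sites.

    Returns (precursor loci, transcripts with planted sites, truth).
    Each planted precursor is guaranteed to pass
    :func:`eumir.discovery.evaluate_precursor` under the given
    parameters (candidates are redrawn until they do), and each mature
    gets one perfect-complement target site written into a transcript,
    with the true cleavage site opposite miRNA positions 10-11.
    """
    dist = mature_length_dist or {20: 0.10, 21: 0.50, 22: 0.10, 24: 0.30}
    cfg = discovery_config or DiscoveryConfig()
    rng = _rng(seed, 2)
    lengths = _lengths_from_dist(rng, dist, n_mirnas)
    tx = dict(transcripts)
    tids = sorted(tx)
    n_known = int(round(known_fraction * n_mirnas))
    hairpins: list[PlantedHairpin] = []
    precursors: dict[str, str] = {}
    matures_seen: set[str] = set()
    for i in range(n_mirnas):
        length = int(lengths[i])
        for _attempt in range(200):
            mature = _random_seq(rng, length, gc=0.5)
            if mature in matures_seen:
                continue
            flank5 = _random_seq(rng, 8)
            loop = _random_seq(rng, 8)
            flank3 = _random_seq(rng, 8)
            precursor = flank5 + mature + loop + revcomp(mature) + flank3
            interval = (9, 8 + length)
            if evaluate_precursor(precursor, interval, cfg).accepted:
                break
        else:
            raise RuntimeError("could not construct an acceptable hairpin")
        matures_seen.add(mature)
        known = i < n_known
        secondary = n_known <= i < n_known + n_secondary
        family = KNOWN_FAMILIES[i % len(KNOWN_FAMILIES)] if known else None
        pid = f"hairpin{i + 1:03d}"
        precursors[pid] = precursor

        # plant one perfect-complement target site per mature
        tid = tids[i % len(tids)]
        seq = tx[tid]
        start0 = int(rng.integers(60, len(seq) - 60 - length))
        tx[tid] = seq[:start0] + revcomp(mature) + seq[start0 + length:]
        start1 = start0 + 1
        hairpins.append(PlantedHairpin(
            truth_id=f"tru-miR{i + 1:03d}",
            mature=mature,
            known=known,
            secondary=secondary,
            family=family,
            precursor_id=pid,
            precursor=precursor,
            mature_interval=interval,
            target_transcript=tid,
            target_interval=(start1, start1 + length - 1),
            cleavage_site=start1 + length - 10,
        ))
    truth = GroundTruth(transcripts=tx, precursors=precursors,
                        hairpins=hairpins)
    truth.check()
    return precursors, tx, truth


def mature_references(truth: GroundTruth
                      ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """(primary miRBase-style, secondary published-set) reference FASTAs."""
    primary, secondary = [], []
    fam_serial: dict[str, int] = {}
    for h in truth.hairpins:
        if h.known and h.family:
            fam_serial[h.family] = fam_serial.get(h.family, 0) + 1
            primary.append((f"{h.family}-ref{fam_serial[h.family]}", h.mature))
        elif h.secondary:
            secondary.append((f"eumPub-{h.truth_id}", h.mature))
    return primary, secondary


def generate_ncrna_references(seed: int = 0) -> dict[str, list[tuple[str, str]]]:
    """Small reference sets for rRNA/tRNA/snRNA/snoRNA/repeat filtering."""
    rng = _rng(seed, 3)
    spec = {"rRNA": (3, 150), "tRNA": (4, 75), "snRNA": (2, 110),
            "snoRNA": (2, 90), "repeat": (2, 200)}
    return {
        cls: [(f"{cls}_{j + 1}", _random_seq(rng, length))
              for j in range(n)]
        for cls, (n, length) in spec.items()
    }


def _background_length(rng) -> int:
    lengths = np.array(sorted(BACKGROUND_LENGTH_WEIGHTS))
    probs = np.array([BACKGROUND_LENGTH_WEIGHTS[k] for k in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_srna_libraries(truth: GroundTruth,
                            ncrna_refs: dict[str, list[tuple[str, str]]],
                            config: Optional[SimulateConfig] = None,
                            samples: Optional[list] = None,
                            seed: int = 0,
                            ) -> tuple[dict[str, list[tuple[str, str, str]]],
                                       pd.DataFrame]:
    """Six FASTQ-ready libraries plus the true per-sample count table.

    Returns ({sample: [(read id, sequence, quality), ...]}, true counts
    indexed by truth miRNA id).  Fills ``truth.mirna_expression``.
    """
    cfg = config or SimulateConfig()
    from eumir.config import default_sample_sheet
    samples = samples or default_sample_sheet()
    rng = _rng(seed, 4)
    n_mir = len(truth.hairpins)
    depth = cfg.depth

    frac_bad = (cfg.frac_bad_n + cfg.frac_no_adapter
                + cfg.frac_bad_length + cfg.frac_low_quality)
    mirna_frac = (1.0 - cfg.background_ncrna_frac
                  - cfg.background_random_frac - frac_bad)
    if mirna_frac <= 0:
        raise ValueError("background fractions leave no miRNA reads")

    # per-miRNA means: lognormal spread, scaled to the miRNA read budget
    base = np.exp(rng.normal(0.0, 1.0, n_mir))
    base *= mirna_frac * depth / base.sum()
    n_dem = int(round(cfg.frac_dem * n_mir))
    if n_dem > 0 and mirna_frac * depth < 10 * n_dem:
        import logging
        logging.getLogger("eumir").warning(
            "depth too small to realize frac_dem reliably")
    is_dem = np.zeros(n_mir, dtype=bool)
    dem_idx = rng.choice(n_mir, size=n_dem, replace=False)
    is_dem[dem_idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_mir)
    true_lfc = np.where(is_dem, signs * cfg.lfc_magnitude, 0.0)
    mean_lr = base
    mean_hr = base * 2.0 ** true_lfc

    truth_ids = [h.truth_id for h in truth.hairpins]
    truth.mirna_expression = pd.DataFrame({
        "truth_id": truth_ids,
        "mature": [h.mature for h in truth.hairpins],
        "mean_LR": mean_lr,
        "mean_HR": mean_hr,
        "true_lfc": true_lfc,
        "is_dem": is_dem,
    })
    truth.check()

    nc_classes = sorted(NCRNA_CLASS_WEIGHTS)
    nc_probs = np.array([NCRNA_CLASS_WEIGHTS[c] for c in nc_classes])
    nc_probs = nc_probs / nc_probs.sum()

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    count_rows = {}
    for sample in samples:
        sid, cond = sample.sample_id, sample.condition
        mu = mean_hr if cond == "HR" else mean_lr
        counts = _nb_counts(rng, mu, cfg.dispersion)
        count_rows[sid] = counts
        reads: list[tuple[str, str]] = []  # (sequence, quality)
        for h, c in zip(truth.hairpins, counts):
            seq = h.mature + cfg.adapter
            reads.extend([(seq, "I" * len(seq))] * int(c))
        for _ in range(int(round(cfg.background_ncrna_frac * depth))):
            cls = nc_classes[int(rng.choice(len(nc_classes), p=nc_probs))]
            rid, rseq = ncrna_refs[cls][int(rng.integers(len(ncrna_refs[cls])))]
            length = _background_length(rng)
            start = int(rng.integers(0, len(rseq) - length + 1))
            seq = rseq[start:start + length] + cfg.adapter
            reads.append((seq, "I" * len(seq)))
        for _ in range(int(round(cfg.background_random_frac * depth))):
            seq = _random_seq(rng, 24) + cfg.adapter
            reads.append((seq, "I" * len(seq)))
        # deliberately defective reads, so preprocessing has work to do
        for _ in range(int(round(cfg.frac_bad_n * depth))):
            core = list(_random_seq(rng, 21))
            for pos in rng.choice(21, size=3, replace=False):
                core[pos] = "N"
            seq = "".join(core) + cfg.adapter
            reads.append((seq, "I" * len(seq)))
        for _ in range(int(round(cfg.frac_no_adapter * depth))):
            seq = _random_seq(rng, 21)
            reads.append((seq, "I" * len(seq)))
        for _ in range(int(round(cfg.frac_bad_length * depth))):
            length = 16 if rng.random() < 0.5 else 31
            seq = _random_seq(rng, length) + cfg.adapter
            reads.append((seq, "I" * len(seq)))
        for _ in range(int(round(cfg.frac_low_quality * depth))):
            seq = _random_seq(rng, 21) + cfg.adapter
            reads.append((seq, "#" * len(seq)))
        order = rng.permutation(len(reads))
        libraries[sid] = [
            (f"{sid}_r{j + 1:07d}", reads[k][0], reads[k][1])
            for j, k in enumerate(order)
        ]
    true_counts = pd.DataFrame(count_rows, index=truth_ids)
    return libraries, true_counts


def simulate_degradome(truth: GroundTruth,
                       site_spike_factor: float = 50.0,
                       background_rate: float = 0.02,
                       background_tag_mean: float = 2.0,
                       seed: int = 0,
                       ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Degradome tag pool (one FASTA record per tag copy) + site truth.

    Tags are 20-21 nt 5'-anchored transcript subsequences; the tag
    start equals the decay position.  Background positions are covered
    with probability ``background_rate`` and carry on average
    ``background_tag_mean`` tags; each true cleavage site carries a
    Poisson(spike x background mean) spike (at least 2 tags), making
    it the transcript maximum with overwhelming probability at the
    default 50x spike.
    """
    if site_spike_factor <= 1:
        raise ValueError("site_spike_factor must be > 1")
    rng = _rng(seed, 5)
    sites = {(h.target_transcript, h.cleavage_site): h.truth_id
             for h in truth.hairpins}
    tags: list[tuple[str, str]] = []
    serial = 0

    def emit(tid: str, pos1: int, count: int) -> None:
        nonlocal serial
        seq = truth.transcripts[tid]
        for _ in range(count):
            length = 20 if rng.random() < 0.5 else 21
            if pos1 - 1 + length > len(seq):
                length = 20
                if pos1 - 1 + length > len(seq):
                    continue
            serial += 1
            tags.append((f"deg{serial:06d}", seq[pos1 - 1:pos1 - 1 + length]))

    for tid in sorted(truth.transcripts):
        seq = truth.transcripts[tid]
        n_pos = len(seq) - 21 + 1
        if background_rate > 0:
            covered = np.nonzero(rng.random(n_pos) < background_rate)[0]
            for p0 in covered:
                pos1 = int(p0) + 1
                if (tid, pos1) in sites:
                    continue
                count = 1 + int(rng.poisson(max(background_tag_mean - 1, 0)))
                emit(tid, pos1, count)
        for (stid, site), _truth_id in sites.items():
            if stid != tid:
                continue
            spike = max(2, int(rng.poisson(site_spike_factor
                                           * background_tag_mean)))
            emit(tid, site, spike)
    site_truth = truth.cleavage_sites
    return tags, site_truth


def simulate_count_matrix(n_features: int = 500, frac_de: float = 0.1,
                          lfc: float = 2.0, dispersion: float = 0.1,
                          depth: int = 200_000, n_reps: int = 3,
                          seed: int = 0,
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Generic two-condition NB count table with known true log2FCs.

    Used for differential-expression calibration: ``frac_de`` of the
    features get |log2FC| = ``lfc`` (random sign) in HR vs LR.
    """
    rng = _rng(seed, 6)
    base = np.exp(rng.normal(np.log(depth / n_features), 1.0, n_features))
    base *= depth / base.sum()
    true_lfc = np.zeros(n_features)
    n_de = int(round(frac_de * n_features))
    idx = rng.choice(n_features, size=n_de, replace=False)
    true_lfc[idx] = rng.choice([-lfc, lfc], size=n_de)
    cols, data = [], []
    for rep in range(n_reps):
        cols.append(f"LR{rep + 1:02d}")
        data.append(_nb_counts(rng, base, dispersion))
    for rep in range(n_reps):
        cols.append(f"HR{rep + 1:02d}")
        data.append(_nb_counts(rng, base * 2.0 ** true_lfc, dispersion))
    index = [f"f{i + 1:04d}" for i in range(n_features)]
    counts = pd.DataFrame(np.column_stack(data), index=index, columns=cols)
    return counts, pd.Series(true_lfc, index=index, name="true_lfc")


def simulate_mrna_counts(truth: GroundTruth,
                         config: Optional[SimulateConfig] = None,
                         seed: int = 0,
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Unigene count table coherent with the miRNA truth.

    Transcripts targeted by a designated DEM become DEGs: with
    probability ``frac_anti`` their true log2FC opposes the miRNA's
    (cleavage-style anti-regulation), otherwise it follows it.  A few
    extra non-target transcripts are also differential.  Fills
    ``truth.mrna_lfc``.
    """
    cfg = config or SimulateConfig()
    if truth.mirna_expression is None:
        raise ValueError("run simulate_srna_libraries first (needs DEM truth)")
    rng = _rng(seed, 7)
    tids = sorted(truth.transcripts)
    n = len(tids)
    true_lfc = pd.Series(0.0, index=tids)
    expr = truth.mirna_expression.set_index("truth_id")
    targeted = set()
    for h in truth.hairpins:
        row = expr.loc[h.truth_id]
        if not row["is_dem"]:
            continue
        sign = np.sign(row["true_lfc"])
        anti = rng.random() < cfg.frac_anti
        true_lfc[h.target_transcript] = (-sign if anti else sign) \
            * cfg.lfc_magnitude
        targeted.add(h.target_transcript)
    others = [t for t in tids if t not in targeted]
    n_extra = int(round(cfg.frac_extra_deg * n))
    for t in rng.choice(others, size=min(n_extra, len(others)), replace=False):
        true_lfc[t] = float(rng.choice([-1, 1])) * cfg.lfc_magnitude
    base = np.exp(rng.normal(np.log(cfg.mrna_depth / n), 1.0, n))
    base *= cfg.mrna_depth / base.sum()
    base = np.maximum(base, 20.0)  # keep DEG calls reachable at 3v3
    cols, data = [], []
    for cond in ("LR", "HR"):
        for rep in (1, 2, 3):
            cols.append(f"{cond}{rep:02d}")
            mu = base * (2.0 ** true_lfc.to_numpy() if cond == "HR" else 1.0)
            data.append(_nb_counts(rng, mu, cfg.dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=tids, columns=cols)
    truth.mrna_lfc = true_lfc
    return counts, true_lfc


def generate_term_map(truth: GroundTruth, seed: int = 0,
                      n_terms: int = 10, term_size: int = 12
                      ) -> dict[str, set[str]]:
    """Synthetic term -> gene annotation map.

    One term ("terpenoid_backbone") collects every miRNA-targeted
    transcript (so DEM-target gene sets enrich for it); the rest are
    random gene sets.
    """
    rng = _rng(seed, 8)
    tids = sorted(truth.transcripts)
    targeted = sorted({h.target_transcript for h in truth.hairpins})
    terms = {"terpenoid_backbone": set(targeted)}
    for i in range(n_terms):
        size = min(term_size, len(tids))
        members = rng.choice(tids, size=size, replace=False)
        terms[f"term{i + 1:02d}"] = set(members)
    return terms
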