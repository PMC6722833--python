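"""Degradome (PARE) T-plots and cleavage-site categorization.

Degradome tags are 5'-monophosphate decay fragments: the 1-based
transcript position of a tag's 5' end marks a decay (candidate
cleavage) position.  Tags map by exact full-length substring match
only; a multi-mapping tag increments every exact locus.

A supported site (>= 1 tag) falls into one of five categories by the
classic scheme, evaluated in this order:

* 4 -- exactly one raw read at the position;
* 0 -- abundance equals the transcript maximum and the maximum is
  unique;
* 1 -- abundance equals the maximum, which is attained at more than
  one position;
* 2 -- below the maximum but above the median;
* 3 -- at or below the median.

The median is taken over covered positions (count >= 1) by default.
A single-read site that also happens to be the unique maximum is
category 4, because "only one raw read" describes it exactly.

Validated cleavage requires the guiding alignment to spend at most
five mismatches (G:U wobbles at a configurable half weight, gaps at
full weight) and miRNA positions 10 and 11 -- the bases flanking the
scissile bond -- to be Watson-Crick paired.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from eumir.config import DegradomeConfig

log = logging.getLogger("eumir")


@dataclass
class DegradomeProfile:
    transcript_id: str
    counts: np.ndarray  # index 0 = position 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("tag counts must be non-negative")

    def __getitem__(self, pos1: int) -> float:
        return float(self.counts[pos1 - 1])

    @property
    def covered_median(self) -> float:
        covered = self.counts[self.counts >= 1]
        if covered.size == 0:
            raise ValueError("profile has no covered position")
        return float(np.median(covered))

    @property
    def overall_median(self) -> float:
        return float(np.median(self.counts))

    @property
    def max_value(self) -> float:
        return float(self.counts.max(initial=0.0))

    @property
    def argmax_positions(self) -> list[int]:
        if self.max_value == 0:
            return []
        return [int(i) + 1 for i in
                np.nonzero(self.counts == self.max_value)[0]]


def build_profile(tags: list[str] | Counter,
                  transcripts: dict[str, str],
                  ) -> tuple[dict[str, DegradomeProfile], int]:
    """Per-transcript tag-start profiles; returns (profiles, n_unmapped).

    ``tags`` may be a sequence (one entry per tag copy) or a Counter
    of unique tag -> abundance.  Only exact full-length matches
    contribute; every occurrence of a multi-mapping tag is counted.
    """
    counter: Counter = tags if isinstance(tags, Counter) else Counter(tags)
    bad = [t for t in counter if not 20 <= len(t) <= 21]
    if bad:
        raise ValueError(
            f"{len(bad)} tags outside 20-21 nt (e.g. {bad[0]!r})")
    profiles = {
        tid: DegradomeProfile(tid, np.zeros(len(seq)))
        for tid, seq in transcripts.items()
    }
    unmapped = 0
    for tag, count in counter.items():
        mapped = False
        for tid, seq in transcripts.items():
            start = seq.find(tag)
            while start >= 0:
                profiles[tid].counts[start] += count
                mapped = True
                start = seq.find(tag, start + 1)
        if not mapped:
            unmapped += count
    return profiles, unmapped


def classify_category(profile: DegradomeProfile, site: int,
                      covered_only: bool = True) -> int:
    """Category 0-4 of a supported cleavage site (1-based position)."""
    if not 1 <= site <= len(profile.counts):
        raise ValueError(f"site {site} outside transcript "
                         f"{profile.transcript_id}")
    count = profile[site]
    if count == 0:
        raise ValueError("no degradome support at site")
    if count == 1:
        return 4
    maxima = profile.argmax_positions
    if count == profile.max_value:
        return 0 if len(maxima) == 1 else 1
    median = profile.covered_median if covered_only else profile.overall_median
    return 2 if count > median else 3


@dataclass
class CleavageEvent:
    mirna_id: str
    transcript_id: str
    site: int            # 1-based, target base opposite the miRNA 10/11 bond
    mismatches: float    # weighted budget actually spent
    wobbles: int
    site_abundance: float
    category: int


def validate_cleavage(hits: pd.DataFrame,
                      profiles: dict[str, DegradomeProfile],
                      config: Optional[DegradomeConfig] = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter predicted target hits by degradome evidence.

    ``hits`` is a :func:`eumir.targets.scan_transcriptome` table.  A
    hit survives when its weighted mismatch budget (mismatches + gaps
    + wobble_weight x wobbles) is within ``max_mm``, miRNA positions
    10-11 are Watson-Crick paired, and the profile supports the site
    with >= 1 tag.  Returns (events, rejected) tables; rejected rows
    carry the reason.
    """
    cfg = config or DegradomeConfig()
    events, rejected = [], []

    def reject(row, reason):
        rejected.append({"miRNA": row["miRNA"], "transcript": row["transcript"],
                         "site": row["site_pos"], "reason": reason})

    for _, row in hits.iterrows():
        budget = (row["mismatches"] + row["gaps"]
                  + cfg.wobble_weight * row["wobbles"])
        if budget > cfg.max_mm:
            reject(row, "mismatch budget exceeded")
            continue
        if not row["pos10_11_wc"]:
            reject(row, "miRNA positions 10-11 not Watson-Crick paired")
            continue
        profile = profiles.get(row["transcript"])
        if profile is None:
            reject(row, "no degradome profile for transcript")
            continue
        site = int(row["site_pos"])
        if site < 1 or profile[site] < 1:
            reject(row, "no degradome support at site")
            continue
        category = classify_category(profile, site,
                                     covered_only=cfg.median_covered_only)
        events.append({
            "miRNA": row["miRNA"],
            "transcript": row["transcript"],
            "site": site,
            "mismatches": budget,
            "wobbles": int(row["wobbles"]),
            "site_abundance": profile[site],
            "category": category,
        })
    cols = ["miRNA", "transcript", "site", "mismatches", "wobbles",
            "site_abundance", "category"]
    ev = pd.DataFrame(events, columns=cols)
    ev = ev.sort_values(["miRNA", "transcript", "site"],
                        kind="mergesort").reset_index(drop=True)
    rej = pd.DataFrame(rejected, columns=["miRNA", "transcript", "site",
                                          "reason"])
    return ev, rej


def tplot_data(profile: DegradomeProfile, events: pd.DataFrame
               ) -> tuple[pd.DataFrame, list[tuple[int, float]]]:
    """Plot-ready (position, abundance) series plus marked site positions."""
    own = events[events["transcript"] == profile.transcript_id] if len(events) \
        else events
    if len(events) and len(own) != len(events):
        raise ValueError("events contain foreign transcripts")
    series = pd.DataFrame({
        "position": np.arange(1, len(profile.counts) + 1),
        "abundance": profile.counts,
    })
    markers = sorted(
        (int(site), profile[int(site)]) for site in
        (own["site"] if len(own) else [])
    )
    return series, markers


def plot_tplot(profile: DegradomeProfile, events: pd.DataFrame, path) -> None:
    """Write a T-plot PNG (tag abundance by position, sites in red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series, markers = tplot_data(profile, events)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.vlines(series["position"], 0, series["abundance"], color="0.6", lw=1)
    for pos, abundance in markers:
        ax.vlines([pos], 0, [abundance], color="red", lw=1.5)
    ax.set_xlabel("site position of target cDNA")
    ax.set_ylabel("raw tag abundance")
    ax.set_title(profile.transcript_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
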