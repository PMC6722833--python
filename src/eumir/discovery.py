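"""Known- and novel-miRNA identification.

Known miRNAs: candidate reads are compared directly to a mature
reference set (miRBase-style ids formatted ``FAMILY-...``) allowing at
most three substitution mismatches, with a +/-2 nt terminal-shift
allowance to absorb isomiR-style end variation; a second published
reference set is matched exactly.  The best (fewest-mismatch)
reference wins, ties broken by lexicographically smallest reference
id, which makes the outcome independent of reference order.

Novel miRNAs: candidates are located by exact match inside hairpin
locus sequences (the genome-mapping step of the classic workflow,
replaced here by a precursor locus set) and the locus is accepted as a
precursor when its fold has exactly one terminal loop, the mature lies
on one arm without crossing the loop, enough of the mature is paired,
and the pseudo-MFE clears the ceiling observed for plant precursors
(-15.8 kcal/mol by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from eumir.config import DiscoveryConfig
from eumir.fold import fold_pseudo_mfe, hairpin_loops, paired_flags
from eumir.io import rna

log = logging.getLogger("eumir")


@dataclass
class MiRNARecord:
    id: str
    mature: str                     # DNA alphabet internally
    status: str                     # "known" | "novel"
    family: Optional[str] = None    # known only
    source_ref: Optional[str] = None
    matched_set: Optional[str] = None   # "primary" | "secondary"
    mismatches: Optional[float] = None
    precursor_id: Optional[str] = None
    precursor: Optional[str] = None
    structure: Optional[str] = None
    mfe: Optional[float] = None
    mature_interval: Optional[tuple[int, int]] = None  # 1-based inclusive
    tpm: dict[str, float] = field(default_factory=dict)

    @property
    def mature_rna(self) -> str:
        return rna(self.mature)


@dataclass
class FamilySummary:
    counts: dict[str, int]
    note: str = ""

    @property
    def total_members(self) -> int:
        return sum(self.counts.values())

    @property
    def n_families(self) -> int:
        return len(self.counts)


def family_from_ref(ref_id: str) -> str:
    return ref_id.split("-")[0]


def _overlap_mismatches(cand: str, ref: str, offset: int) -> Optional[float]:
    """Hamming distance over the aligned overlap, or None if degenerate.

    ``offset`` aligns candidate position 0 with reference position
    ``offset`` (may be negative).
    """
    start_c = max(0, -offset)
    start_r = max(0, offset)
    length = min(len(cand) - start_c, len(ref) - start_r)
    if length <= 0:
        return None
    a = cand[start_c:start_c + length]
    b = ref[start_r:start_r + length]
    return float(sum(x != y for x, y in zip(a, b)))


def _best_vs_ref(cand: str, ref: str, max_mm: int, max_shift: int
                 ) -> Optional[float]:
    """Fewest mismatches of candidate vs one reference, or None.

    Admissible alignments: equal length and offset 0, or a terminal
    shift of at most ``max_shift`` nt at either end (both the start
    offset and the end overhang bounded by ``max_shift``).
    """
    best: Optional[float] = None
    for offset in range(-max_shift, max_shift + 1):
        end_overhang = offset + len(cand) - len(ref)
        if abs(end_overhang) > max_shift:
            continue
        mm = _overlap_mismatches(cand, ref, offset)
        if mm is None or mm > max_mm:
            continue
        if best is None or mm < best:
            best = mm
    return best


def match_known(candidates: list[str],
                primary_refs: list[tuple[str, str]],
                max_mm: int = 3,
                secondary_refs: Optional[list[tuple[str, str]]] = None,
                max_mm2: int = 0,
                max_shift: int = 2) -> list[MiRNARecord]:
    """Match candidate reads against mature miRNA reference sets.

    The primary (miRBase-style) set allows ``max_mm`` substitutions and
    terminal shifts; candidates left unmatched are compared with the
    secondary published set at ``max_mm2`` mismatches without shifts.
    """
    if not primary_refs and not secondary_refs:
        log.info("no mature references supplied; no known miRNAs called")
    records: list[MiRNARecord] = []
    primary = sorted(primary_refs, key=lambda r: r[0])
    secondary = sorted(secondary_refs or [], key=lambda r: r[0])
    serial = 0
    for cand in candidates:
        best_mm: Optional[float] = None
        best_ref: Optional[tuple[str, str]] = None
        matched_set = "primary"
        for rid, rseq in primary:
            mm = _best_vs_ref(cand, rseq, max_mm, max_shift)
            if mm is not None and (best_mm is None or mm < best_mm):
                best_mm, best_ref = mm, (rid, rseq)
        if best_ref is None:
            matched_set = "secondary"
            for rid, rseq in secondary:
                mm = _best_vs_ref(cand, rseq, max_mm2, 0)
                if mm is not None and (best_mm is None or mm < best_mm):
                    best_mm, best_ref = mm, (rid, rseq)
        if best_ref is not None:
            serial += 1
            records.append(MiRNARecord(
                id=f"eu-{best_ref[0]}.{serial}",
                mature=cand,
                status="known",
                family=family_from_ref(best_ref[0]),
                source_ref=best_ref[0],
                matched_set=matched_set,
                mismatches=best_mm,
            ))
    return records


@dataclass
class PrecursorVerdict:
    accepted: bool
    reasons: list[str]
    structure: str
    mfe: float


def evaluate_precursor(precursor: str, mature_interval: tuple[int, int],
                       config: Optional[DiscoveryConfig] = None,
                       ) -> PrecursorVerdict:
    """Screen a candidate precursor; ``mature_interval`` is 1-based inclusive.

    Acceptance requires a single stem-loop: exactly one terminal loop
    in the fold, the mature entirely on one arm (not crossing the
    loop), >= ``min_paired_frac`` of mature bases paired, at most
    ``max_mature_bulge`` unpaired bases inside the mature, and
    pseudo-MFE <= ``mfe_max``.
    """
    cfg = config or DiscoveryConfig()
    start1, end1 = mature_interval
    if not (1 <= start1 <= end1 <= len(precursor)):
        raise ValueError(f"mature interval {mature_interval} out of bounds")
    structure, mfe = fold_pseudo_mfe(precursor, min_loop=cfg.min_hairpin_loop)
    reasons: list[str] = []
    loops = hairpin_loops(structure)
    if len(loops) == 0:
        reasons.append("no stem-loop")
    elif len(loops) > 1:
        reasons.append("multiple terminal loops")
    s0, e0 = start1 - 1, end1  # 0-based half-open
    if len(loops) == 1:
        loop_s, loop_e = loops[0]
        if s0 < loop_e and e0 > loop_s:
            reasons.append("crosses loop")
    paired = paired_flags(structure)[s0:e0]
    mature_len = e0 - s0
    if paired.sum() < cfg.min_paired_frac * mature_len:
        reasons.append("mature insufficiently paired")
    if mature_len - paired.sum() > cfg.max_mature_bulge:
        reasons.append("mature bulge too large")
    if mfe > cfg.mfe_max:
        reasons.append("pseudo-MFE above ceiling")
    return PrecursorVerdict(not reasons, reasons, structure, mfe)


def find_novel(candidates: list[str],
               precursor_loci: list[tuple[str, str]],
               config: Optional[DiscoveryConfig] = None,
               ) -> list[MiRNARecord]:
    """Novel-miRNA calls: exact hit inside a hairpin locus that passes
    :func:`evaluate_precursor`.  Loci are scanned in id order; the
    first accepting locus wins."""
    cfg = config or DiscoveryConfig()
    loci = sorted(precursor_loci, key=lambda r: r[0])
    records: list[MiRNARecord] = []
    serial = 0
    for cand in candidates:
        for lid, lseq in loci:
            pos = lseq.find(cand)
            if pos < 0:
                continue
            interval = (pos + 1, pos + len(cand))
            verdict = evaluate_precursor(lseq, interval, cfg)
            if verdict.accepted:
                serial += 1
                records.append(MiRNARecord(
                    id=f"n-eu-miR{serial}",
                    mature=cand,
                    status="novel",
                    precursor_id=lid,
                    precursor=lseq,
                    structure=verdict.structure,
                    mfe=verdict.mfe,
                    mature_interval=interval,
                ))
                break
    return records


def nucleotide_bias(matures: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-nucleotide bias by length and per-position composition.

    Returns (first_by_length, positional) frequency tables over the
    RNA alphabet; rows are normalized to sum to 1 and positions beyond
    a miRNA's length do not contribute to its tally.
    """
    if not matures:
        raise ValueError("empty mature set")
    bases = ["A", "C", "G", "U"]
    seqs = [rna(m) for m in matures]
    lengths = sorted({len(s) for s in seqs})
    first = pd.DataFrame(0.0, index=lengths, columns=bases)
    for s in seqs:
        first.loc[len(s), s[0]] += 1
    first = first.div(first.sum(axis=1), axis=0)
    max_pos = 25
    pos = pd.DataFrame(0.0, index=range(1, max_pos + 1), columns=bases)
    for s in seqs:
        for i, base in enumerate(s[:max_pos], start=1):
            pos.loc[i, base] += 1
    totals = pos.sum(axis=1)
    pos = pos.div(totals.where(totals > 0, other=np.nan), axis=0)
    pos = pos.dropna(how="all")
    return first, pos


def family_summary(known_records: list[MiRNARecord], note: str = ""
                   ) -> FamilySummary:
    counter = Counter(rec.family for rec in known_records
                      if rec.status == "known" and rec.family)
    return FamilySummary(dict(sorted(counter.items())), note)
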