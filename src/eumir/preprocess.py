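"""Small-RNA read cleaning and ncRNA classification.

Raw reads pass four filters, applied in order: 'N' content >= 10%,
absence of the 3'-adaptor, low mean base quality (Phred < 20, skipped
for FASTA input where no qualities exist), and trimmed length outside
18-30 nt.  Each removed read is charged to the first filter it fails,
so the report reconciles exactly: raw = clean + sum(removed).

Surviving reads are deduplicated per library to (sequence, count) and
classified against small ncRNA reference sets by exact substring
containment (read contained in reference), in fixed priority order
rRNA > tRNA > snRNA > snoRNA > repeat; anything unmatched is
"unannotated" and feeds miRNA discovery.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from eumir.io import SeqEntry

log = logging.getLogger("eumir")

NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass
class ReadFilterReport:
    raw: int = 0
    removed_n: int = 0
    removed_no_adaptor: int = 0
    removed_low_quality: int = 0
    removed_length: int = 0
    clean: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def removed_total(self) -> int:
        return (self.removed_n + self.removed_no_adaptor
                + self.removed_low_quality + self.removed_length)

    def check(self) -> None:
        if self.raw != self.clean + self.removed_total:
            raise AssertionError("filter report does not reconcile")
        if self.class_counts and sum(self.class_counts.values()) != self.clean:
            raise AssertionError("class counts do not sum to clean reads")


def filter_reads(reads: list[SeqEntry], adaptor: str,
                 min_len: int = 18, max_len: int = 30,
                 max_n_frac: float = 0.10, min_mean_q: float = 20.0,
                 ) -> tuple[Counter, ReadFilterReport]:
    """Trim the 3'-adaptor and filter; return unique clean reads + report.

    The adaptor is located by the rightmost exact occurrence of its
    first 8 nt (no mismatch tolerance); reads already free of adaptor
    sequence are charged to ``removed_no_adaptor``.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    probe = adaptor[:8]
    report = ReadFilterReport(raw=len(reads))
    clean: Counter = Counter()
    for rec in reads:
        seq = rec.seq
        cut = seq.rfind(probe)
        # N content judged on the insert (the read once the adaptor is
        # off); reads lacking an adaptor are judged whole.  Removal is
        # charged to the first failing filter: N, adaptor, quality, length.
        insert = seq[:cut] if cut >= 0 else seq
        if len(insert) and insert.count("N") >= max_n_frac * len(insert):
            report.removed_n += 1
            continue
        if cut < 0:
            report.removed_no_adaptor += 1
            continue
        if rec.quality is not None:
            qual = rec.quality[:cut]
            if qual and sum(qual) / len(qual) < min_mean_q:
                report.removed_low_quality += 1
                continue
        if not min_len <= len(insert) <= max_len:
            report.removed_length += 1
            continue
        clean[insert] += 1
    report.clean = sum(clean.values())
    report.check()
    return clean, report


def classify_ncrna(unique_reads: dict[str, int] | Counter,
                   references: dict[str, list[tuple[str, str]]],
                   ) -> dict[str, str]:
    """Label each unique read with its ncRNA class or "unannotated".

    A read matches a class when it is an exact substring of any
    reference sequence of that class; the first matching class in
    :data:`NCRNA_PRIORITY` order wins.
    """
    ref_seqs = {}
    for cls in NCRNA_PRIORITY:
        seqs = [seq for _rid, seq in references.get(cls, [])]
        if not seqs:
            log.info("ncRNA class %s has no references; never assigned", cls)
        ref_seqs[cls] = seqs
    labels: dict[str, str] = {}
    for read in unique_reads:
        label = "unannotated"
        for cls in NCRNA_PRIORITY:
            if any(read in ref for ref in ref_seqs[cls]):
                label = cls
                break
        labels[read] = label
    return labels


def class_counts(unique_reads: Counter, labels: dict[str, str]) -> dict[str, int]:
    """Per-class read totals (weighted by read count)."""
    counts = {cls: 0 for cls in NCRNA_PRIORITY + ("unannotated",)}
    for read, n in unique_reads.items():
        counts[labels[read]] += n
    return counts


def length_histogram(unique_reads: Counter) -> dict[int, float]:
    """Read-length frequencies (count-weighted); sums to 1 per library."""
    totals: Counter = Counter()
    for read, n in unique_reads.items():
        totals[len(read)] += n
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {length: totals[length] / grand for length in sorted(totals)}
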