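"""Transcriptome-wide miRNA target prediction by complementarity scoring.

The expectation-style score emulates the default schema of the
standard plant target-prediction tools: the miRNA is aligned 3'->5'
against the target site 5'->3'; a Watson-Crick pair costs 0, a G:U
wobble 0.5, a mismatch 1 and a gap 2, and penalties falling at miRNA
positions 2-13 (the seed) are multiplied by 1.5.  At most one gap is
allowed, so the optimal alignment is the exact minimum over all
single-gap placements; ties prefer fewer gaps, then the leftmost
placement.  Sites scoring at or below the cutoff (default 5.0) are
reported, with overlapping sites of the same miRNA merged keeping the
best score.

The "site position" carried by every hit is the target nucleotide
paired to miRNA position 10 -- the 5' end of the 3' cleavage fragment
-- which is where degradome tag starts accumulate for a true
cleavage event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from eumir.config import TargetConfig
from eumir.io import dna

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U in RNA


def pair_kind(mirna_base: str, target_base: str) -> str:
    """'|' Watson-Crick, 'o' G:U wobble, '.' mismatch (DNA alphabet)."""
    pair = (mirna_base, target_base)
    if pair in _WC:
        return "|"
    if pair in _WOBBLE:
        return "o"
    return "."


@dataclass
class TargetAlignment:
    """An alignment of one miRNA against one target window.

    ``steps`` lists (mirna_pos, target_off, kind): mirna_pos is
    1-based from the miRNA 5' end (None for a target bulge),
    target_off is the 0-based offset in the window (None for a miRNA
    bulge), kind is one of ``| o . -``.  Steps run along the target
    5'->3', i.e. along the miRNA 3'->5'.
    """

    score: float
    steps: list[tuple[Optional[int], Optional[int], str]]
    n_mismatch: int
    n_wobble: int
    n_gaps: int

    @property
    def string(self) -> str:
        return "".join(kind for _m, _t, kind in self.steps)

    def kind_at(self, mirna_pos: int) -> str:
        for m, _t, kind in self.steps:
            if m == mirna_pos:
                return kind
        return "-"

    def target_offset_of(self, mirna_pos: int) -> Optional[int]:
        for m, t, _kind in self.steps:
            if m == mirna_pos:
                return t
        return None


def _seed_factor(pos: int, cfg: TargetConfig) -> float:
    return cfg.seed_factor if cfg.seed_start <= pos <= cfg.seed_end else 1.0


def _base_penalty(kind: str, cfg: TargetConfig) -> float:
    return {"|": cfg.wc, "o": cfg.wobble, ".": cfg.mismatch}[kind]


def _gap_factor_pos(g: int, mirna_len: int) -> int:
    """miRNA position whose seed status a gap inherits.

    A gap placed after ``g`` consumed miRNA bases (3'->5') sits next to
    miRNA position L-g; a gap at the very 5' end inherits position 1.
    """
    return mirna_len - g if g < mirna_len else 1


def complementarity_score(mirna: str, window: str,
                          config: Optional[TargetConfig] = None,
                          ) -> TargetAlignment:
    """Optimal (minimum-penalty) alignment of ``mirna`` vs ``window``.

    ``mirna`` is 5'->3' (RNA or DNA), ``window`` is the target site
    5'->3'.  The window length must be within miRNA length +/-
    ``max_gaps``; ambiguous bases raise ``ValueError``.
    """
    cfg = config or TargetConfig()
    m = dna(mirna)
    t = dna(window)
    if "N" in m or "N" in t or set(m + t) - set("ACGT"):
        raise ValueError("ambiguous base in miRNA or target window")
    L, W = len(m), len(t)
    if not L - cfg.max_gaps <= W <= L + cfg.max_gaps:
        raise ValueError(
            f"window length {W} incompatible with miRNA length {L} "
            f"(+/- {cfg.max_gaps} gaps)"
        )
    rev = m[::-1]  # rev[j] is miRNA position L - j

    def diag(j: int, toff: int) -> tuple[float, tuple]:
        pos = L - j
        kind = pair_kind(rev[j], t[toff])
        return _base_penalty(kind, cfg) * _seed_factor(pos, cfg), (pos, toff, kind)

    best: Optional[TargetAlignment] = None
    if W == L:
        score, steps, nm, nw = 0.0, [], 0, 0
        for j in range(L):
            pen, step = diag(j, j)
            score += pen
            steps.append(step)
            nm += step[2] == "."
            nw += step[2] == "o"
        best = TargetAlignment(score, steps, nm, nw, 0)
    elif W == L + 1:
        # one unpaired target base (target bulge) after g miRNA bases
        for g in range(L + 1):
            score = cfg.gap * _seed_factor(_gap_factor_pos(g, L), cfg)
            steps: list[tuple] = []
            nm = nw = 0
            for j in range(g):
                pen, step = diag(j, j)
                score += pen
                steps.append(step)
                nm += step[2] == "."
                nw += step[2] == "o"
            steps.append((None, g, "-"))
            for j in range(g, L):
                pen, step = diag(j, j + 1)
                score += pen
                steps.append(step)
                nm += step[2] == "."
                nw += step[2] == "o"
            if best is None or score < best.score:
                best = TargetAlignment(score, steps, nm, nw, 1)
    else:  # W == L - 1: one unpaired miRNA base (miRNA bulge) at rev index g
        for g in range(L):
            score = cfg.gap * _seed_factor(_gap_factor_pos(g, L), cfg)
            steps = []
            nm = nw = 0
            for j in range(g):
                pen, step = diag(j, j)
                score += pen
                steps.append(step)
                nm += step[2] == "."
                nw += step[2] == "o"
            steps.append((L - g, None, "-"))
            for j in range(g + 1, L):
                pen, step = diag(j, j - 1)
                score += pen
                steps.append(step)
                nm += step[2] == "."
                nw += step[2] == "o"
            if best is None or score < best.score:
                best = TargetAlignment(score, steps, nm, nw, 1)
    assert best is not None
    return best


# -- vectorized transcriptome scan ----------------------------------------

def _penalty_table(mirna: str, cfg: TargetConfig) -> np.ndarray:
    """(L, 5) penalty of rev-miRNA base j vs each target base code.

    Column 4 (N) is +inf so windows containing ambiguous bases are
    never reported.
    """
    rev = dna(mirna)[::-1]
    L = len(rev)
    P = np.empty((L, 5))
    for j, mb in enumerate(rev):
        factor = _seed_factor(L - j, cfg)
        for base, code in _CODE.items():
            if base == "N":
                P[j, code] = np.inf
            else:
                P[j, code] = _base_penalty(pair_kind(mb, base), cfg) * factor
    return P


def _window_scores(P: np.ndarray, tcode: np.ndarray, width: int,
                   cfg: TargetConfig) -> np.ndarray:
    """Best score per window start for windows of the given width."""
    L = P.shape[0]
    n = len(tcode) - width + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(tcode, width)
    gapf = np.array([cfg.gap * _seed_factor(_gap_factor_pos(g, L), cfg)
                     for g in range(L + 1)])
    cols = np.arange(width)
    if width == L:
        return P[cols, win].sum(axis=1)
    if width == L + 1:  # target bulge after g miRNA bases, g in 0..L
        A = P[np.arange(L), win[:, :L]]        # j aligned to target col j
        B = P[np.arange(L), win[:, 1:]]        # j aligned to target col j+1
        prefA = np.concatenate([np.zeros((n, 1)), A.cumsum(axis=1)], axis=1)
        prefB = np.concatenate([np.zeros((n, 1)), B.cumsum(axis=1)], axis=1)
        totB = prefB[:, -1]
        scores = prefA + gapf[None, :] + (totB[:, None] - prefB)
        return scores.min(axis=1)
    if width == L - 1:  # miRNA bulge at rev index g, g in 0..L-1
        C = P[np.arange(L - 1), win]           # j < g: target col j
        D = P[np.arange(1, L), win]            # j > g: target col j-1
        prefC = np.concatenate([np.zeros((n, 1)), C.cumsum(axis=1)], axis=1)
        cumD = np.concatenate([np.zeros((n, 1)), D.cumsum(axis=1)], axis=1)
        totD = cumD[:, -1]
        # for gap index g, suffix = sum of D[j'] for j' >= g  (j' = j - 1)
        scores = prefC + gapf[None, :L] + (totD[:, None] - cumD[:, :L])
        return scores.min(axis=1)
    raise ValueError("window width incompatible with miRNA length")


def scan_transcriptome(mirnas: dict[str, str], transcripts: dict[str, str],
                       cutoff: float = 5.0,
                       config: Optional[TargetConfig] = None,
                       ) -> pd.DataFrame:
    """All target sites scoring <= ``cutoff``, sorted and merged.

    Returns a table with 1-based target intervals, score, alignment
    string, per-alignment mismatch/wobble/gap counts, whether miRNA
    positions 10-11 are Watson-Crick paired, and the cleavage-site
    position (target base opposite miRNA position 10).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    cfg = config or TargetConfig()
    rows = []
    for mid in sorted(mirnas):
        mseq = dna(mirnas[mid])
        L = len(mseq)
        P = _penalty_table(mseq, cfg)
        widths = [L]
        if cfg.max_gaps >= 1:
            widths += [L + 1, L - 1]
        for tid in sorted(transcripts):
            tseq = dna(transcripts[tid])
            tcode = np.array([_CODE.get(c, 4) for c in tseq])
            hits = []
            for width in widths:
                scores = _window_scores(P, tcode, width, cfg)
                for start0 in np.nonzero(scores <= cutoff)[0]:
                    aln = complementarity_score(
                        mseq, tseq[start0:start0 + width], cfg)
                    site_off = aln.target_offset_of(10)
                    hits.append({
                        "miRNA": mid,
                        "transcript": tid,
                        "start": int(start0) + 1,
                        "end": int(start0) + width,
                        "score": aln.score,
                        "gaps": aln.n_gaps,
                        "mismatches": aln.n_mismatch,
                        "wobbles": aln.n_wobble,
                        "pos10_11_wc": (aln.kind_at(10) == "|"
                                        and aln.kind_at(11) == "|"),
                        "site_pos": (int(start0) + 1 + site_off
                                     if site_off is not None else -1),
                        "alignment": aln.string,
                    })
            rows.extend(_merge_overlaps(hits))
    df = pd.DataFrame(rows, columns=[
        "miRNA", "transcript", "start", "end", "score", "gaps",
        "mismatches", "wobbles", "pos10_11_wc", "site_pos", "alignment",
    ])
    return df.sort_values(["miRNA", "transcript", "start"],
                          kind="mergesort").reset_index(drop=True)


def _merge_overlaps(hits: list[dict]) -> list[dict]:
    """Keep the best hit per cluster of overlapping intervals.

    Ties by score prefer fewer gaps, then the leftmost start.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h["start"], h["end"]))
    clusters: list[list[dict]] = [[hits[0]]]
    hi = hits[0]["end"]
    for h in hits[1:]:
        if h["start"] <= hi:
            clusters[-1].append(h)
        else:
            clusters.append([h])
            hi = h["end"]
        hi = max(hi, h["end"])
    return [min(c, key=lambda h: (h["score"], h["gaps"], h["start"]))
            for c in clusters]
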