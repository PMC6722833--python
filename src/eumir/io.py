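"""Readers and writers for the external formats the pipeline touches.

All sequences are normalized to the uppercase DNA alphabet on ingest
(U -> T, with the original alphabet remembered) so that downstream
string comparisons have one case to handle; mature miRNAs are written
back out as RNA.  Coordinates are 1-based inclusive in every report
and 0-based half-open internally; :func:`to_one_based` /
:func:`to_zero_based` are the only places the shift occurs.

The one tabular dialect is TSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("eumir")

_VALID = set("ACGTN")


class ParseError(ValueError):
    """A malformed sequence record, with its file location."""


@dataclass
class SeqEntry:
    """One sequence record (DNA alphabet internally)."""

    id: str
    seq: str
    quality: Optional[list[int]] = None  # Phred scores, FASTQ only
    was_rna: bool = False


def dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive (s, e)."""
    return start0 + 1, end0


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive (s, e) -> 0-based half-open [start0, end0)."""
    return start1 - 1, end1


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    raise ParseError(f"cannot infer sequence format from {path.name!r}")


def _fasta_header_line(path: Path, record_index: int) -> int:
    """Line number (1-based) of the n-th '>' header in a FASTA file."""
    n = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                n += 1
                if n == record_index:
                    return lineno
    return 0


def read_sequences(path: str | Path, fmt: Optional[str] = None) -> list[SeqEntry]:
    """Read FASTA or FASTQ into validated :class:`SeqEntry` records.

    RNA input (U) is normalized to T; illegal characters raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _guess_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {fmt!r}")
    entries: list[SeqEntry] = []
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        raw = str(rec.seq).upper()
        was_rna = "U" in raw
        seq = raw.replace("U", "T")
        bad = set(seq) - _VALID
        if bad:
            if fmt == "fastq":
                lineno = 4 * i + 2
            else:
                lineno = _fasta_header_line(path, i) + 1
            raise ParseError(
                f"{path.name}: illegal character(s) {sorted(bad)} in record "
                f"{rec.id!r} near line {lineno}"
            )
        qual = rec.letter_annotations.get("phred_quality")
        entries.append(SeqEntry(rec.id, seq, list(qual) if qual else None, was_rna))
    if not entries:
        log.warning("%s: no records parsed (empty file?)", path.name)
    return entries


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]],
                as_rna: bool = False) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{rna(seq) if as_rna else seq}\n")


def write_fastq(path: str | Path,
                entries: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, seq, quality-string) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in entries:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


# -- regulatory-network serialization -------------------------------------

@dataclass
class NetworkTables:
    nodes: pd.DataFrame  # id, type in {miRNA, target}, direction in {up, down}
    edges: pd.DataFrame  # miRNA, target, regulation in {anti, positive}


def write_network(edges: pd.DataFrame, nodes: pd.DataFrame,
                  node_path: str | Path, edge_path: str | Path) -> None:
    """Write node/edge TSVs for the DEM-DEG interaction network.

    ``nodes`` needs columns id/type/direction; ``edges`` needs
    miRNA/target/regulation.  Every edge endpoint must exist in the
    node table (dangling references are an error); rows are written in
    deterministic sorted order.
    """
    nodes = nodes[["id", "type", "direction"]].copy()
    edges = edges[["miRNA", "target", "regulation"]].copy()
    known = set(nodes["id"])
    dangling = (set(edges["miRNA"]) | set(edges["target"])) - known
    if dangling:
        raise ValueError(f"edges reference unknown node ids: {sorted(dangling)}")
    nodes = nodes.sort_values(["type", "id"], kind="mergesort").reset_index(drop=True)
    edges = edges.sort_values(["miRNA", "target"], kind="mergesort").reset_index(drop=True)
    write_table(nodes, node_path)
    write_table(edges, edge_path)


def read_network(node_path: str | Path, edge_path: str | Path) -> NetworkTables:
    return NetworkTables(read_table(node_path), read_table(edge_path))
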