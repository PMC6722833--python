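"""Dataset-level reporting: breakdown totals and packaged reference tables.

Headline numbers of a miRNA study are sums of their printed
components -- family sizes sum to the known-miRNA count, known plus
novel give the miRNA total, per-class cleavage pairs give the
degradome total, anti plus positive give the network total.  The
functions here are the single reporting path for those totals, used
both by the pipeline's run summary and on the packaged reference
tables for the *E. ulmoides* Eu-rubber study.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from eumir.discovery import FamilySummary


def data_path(name: str):
    """Path-like handle to a packaged reference table."""
    return resources.files("eumir.data").joinpath(name)


def load_known_family_sizes() -> FamilySummary:
    """Known-miRNA family sizes of the Eu-rubber study (16 families)."""
    with resources.as_file(data_path("known_family_sizes.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return FamilySummary(dict(zip(df["family"], df["members"])),
                         note="miRBase-matched members per family")


def load_terpenoid_table() -> pd.DataFrame:
    """Curated terpenoid-backbone-biosynthesis miRNA-target table."""
    with resources.as_file(data_path("terpenoid_backbone_targets.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def breakdown_total(components: dict[str, int]) -> int:
    """Total of a labelled breakdown (e.g. per-class pair counts)."""
    if any(v < 0 for v in components.values()):
        raise ValueError("breakdown components must be non-negative")
    return sum(components.values())


def known_mirna_total(primary_matched: int, secondary_matched: int) -> int:
    """Known miRNAs: primary-set matches plus secondary-set matches."""
    return breakdown_total({"primary": primary_matched,
                            "secondary": secondary_matched})


def mirna_total(known: int, novel: int) -> int:
    return breakdown_total({"known": known, "novel": novel})


def study_summary(family_sizes: FamilySummary, secondary_known: int,
                  novel: int, degradome_pairs: dict[str, int],
                  network_pairs: dict[str, int]) -> dict[str, int]:
    """Recompute every headline total from its components."""
    known = known_mirna_total(family_sizes.total_members, secondary_known)
    return {
        "families": family_sizes.n_families,
        "known_primary": family_sizes.total_members,
        "known_total": known,
        "mirna_total": mirna_total(known, novel),
        "degradome_pairs_total": breakdown_total(degradome_pairs),
        "network_pairs_total": breakdown_total(network_pairs),
    }
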