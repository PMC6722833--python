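"""DEM-DEG integration: signed regulatory network and term enrichment.

A regulatory edge joins a differentially expressed miRNA (DEM) to a
differentially expressed target gene (DEG) it is linked to by target
prediction or degradome evidence.  The edge is "anti" when the two
directions differ (the canonical cleavage signature) and "positive"
when they agree; anti + positive always equals the edge total.

Pathway/term enrichment is the exact hypergeometric upper tail:
p = P(X >= k) for X ~ Hypergeometric(N, K, n), with multiple-testing
correction across terms (Benjamini-Hochberg by default, Bonferroni
switchable).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from eumir.config import EnrichmentConfig

log = logging.getLogger("eumir")


def build_network(dem_results: pd.DataFrame, deg_results: pd.DataFrame,
                  links: pd.DataFrame) -> pd.DataFrame:
    """One signed edge per (DEM, DEG) pair present in ``links``.

    ``dem_results`` / ``deg_results`` are differential-expression
    tables indexed by feature with a ``call`` column; ``links`` needs
    miRNA/target columns and may carry an ``evidence`` column
    ("predicted" or "degradome"; degradome wins for duplicated pairs).
    """
    links = links.copy()
    if "evidence" not in links.columns:
        links["evidence"] = "predicted"
    dems = dem_results[dem_results["call"] != "ns"]["call"]
    degs = deg_results[deg_results["call"] != "ns"]["call"]
    rows = {}
    for _, row in links.iterrows():
        mir, tgt = row["miRNA"], row["target"]
        if mir not in dems.index or tgt not in degs.index:
            continue
        mdir, tdir = dems[mir], degs[tgt]
        key = (mir, tgt)
        evidence = row["evidence"]
        if key in rows and rows[key]["evidence"] == "degradome":
            evidence = "degradome"
        rows[key] = {
            "miRNA": mir,
            "target": tgt,
            "evidence": evidence,
            "miRNA_direction": mdir,
            "target_direction": tdir,
            "regulation": "anti" if mdir != tdir else "positive",
        }
    cols = ["miRNA", "target", "evidence", "miRNA_direction",
            "target_direction", "regulation"]
    edges = pd.DataFrame(list(rows.values()), columns=cols)
    return edges.sort_values(["miRNA", "target"],
                             kind="mergesort").reset_index(drop=True)


def network_nodes(edges: pd.DataFrame) -> pd.DataFrame:
    mirnas = edges[["miRNA", "miRNA_direction"]].drop_duplicates()
    targets = edges[["target", "target_direction"]].drop_duplicates()
    nodes = pd.concat([
        pd.DataFrame({"id": mirnas["miRNA"], "type": "miRNA",
                      "direction": mirnas["miRNA_direction"]}),
        pd.DataFrame({"id": targets["target"], "type": "target",
                      "direction": targets["target_direction"]}),
    ], ignore_index=True)
    return nodes.sort_values(["type", "id"],
                             kind="mergesort").reset_index(drop=True)


def hypergeom_enrich(sample: Iterable[str],
                     term_map: dict[str, set[str]],
                     population: Optional[Iterable[str]] = None,
                     config: Optional[EnrichmentConfig] = None,
                     ) -> pd.DataFrame:
    """Exact hypergeometric term enrichment of ``sample``.

    ``term_map`` maps term -> annotated gene set.  The population
    defaults to all annotated genes; sample members outside the
    population are dropped with a warning.  Terms annotating no
    population gene are skipped.
    """
    cfg = config or EnrichmentConfig()
    if population is None:
        population = set().union(*term_map.values()) if term_map else set()
    population = set(population)
    sample = set(sample)
    outside = sample - population
    if outside:
        log.warning("%d sample genes outside the population; dropped",
                    len(outside))
        sample &= population
    N, n = len(population), len(sample)
    rows = []
    for term in sorted(term_map):
        annotated = term_map[term] & population
        K = len(annotated)
        if K == 0:
            log.warning("term %s annotates no population gene; skipped", term)
            continue
        k = len(annotated & sample)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "p": p})
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method=cfg.method)[1]
        df["significant"] = df["p_adj"] < cfg.p_threshold
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def parse_pathway_table(table: pd.DataFrame | str | Path
                        ) -> tuple[int, int, list[tuple[str, str]]]:
    """Parse a target / miRNA-list / annotation table.

    Rows carry a target id, a ';'-separated miRNA list and an
    annotation.  Returns (unique target count, unique miRNA count,
    expanded (miRNA, target) pair list); dedup is whitespace-trimmed
    and case-sensitive.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    if table.shape[1] != 3:
        raise ValueError(
            f"pathway table must have 3 columns, got {table.shape[1]}")
    targets, mirnas, pairs = set(), set(), []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        tgt, mirs, _annot = row
        if pd.isna(tgt) or pd.isna(mirs) or not str(tgt).strip():
            raise ValueError(f"malformed pathway-table row {i}")
        tgt = str(tgt).strip()
        targets.add(tgt)
        for mir in str(mirs).split(";"):
            mir = mir.strip()
            if not mir:
                raise ValueError(f"empty miRNA entry in row {i}")
            mirnas.add(mir)
            pairs.append((mir, tgt))
    return len(targets), len(mirnas), pairs


def correlation_scatter_data(dem_results: pd.DataFrame,
                             deg_results: pd.DataFrame,
                             edges: pd.DataFrame) -> pd.DataFrame:
    """(x = miRNA log2FC, y = target log2FC) per network edge."""
    missing = [m for m in edges["miRNA"] if m not in dem_results.index]
    missing += [t for t in edges["target"] if t not in deg_results.index]
    if missing:
        raise ValueError(f"unresolved link endpoints: {sorted(set(missing))}")
    return pd.DataFrame({
        "miRNA": edges["miRNA"],
        "target": edges["target"],
        "x_mirna_log2fc": dem_results.loc[edges["miRNA"], "log2FC"].to_numpy(),
        "y_target_log2fc": deg_results.loc[edges["target"], "log2FC"].to_numpy(),
        "regulation": edges["regulation"],
    })
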