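"""Stage orchestration: file-to-file pipeline steps over one output dir.

Each stage reads its inputs from, and writes its products into, a
single run directory; `run_all` simply invokes the stages in order, so
a stage-by-stage invocation and the end-to-end command produce
byte-identical artifacts for the same seed.  All randomness derives
from the configured master seed through fixed per-purpose streams;
nothing written contains timestamps.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from eumir import degradome as deg
from eumir import discovery as disc
from eumir import expression as expr
from eumir import network as net
from eumir import preprocess as prep
from eumir import simulate as sim
from eumir import summary as summ
from eumir import targets as tgt
from eumir.config import PipelineConfig
from eumir.io import (dna, read_sequences, read_table, rna, write_fasta,
                      write_fastq, write_network, write_table)

STAGES = ("simulate", "preprocess", "discover", "quantify",
          "predict_targets", "degradome", "integrate")


def _out(outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# -- simulate --------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    s = cfg.simulate
    transcripts = sim.generate_transcriptome(
        s.n_transcripts, s.transcript_length, s.gc, seed=cfg.seed)
    precursors, transcripts, truth = sim.plant_hairpins(
        transcripts, s.n_mirnas, s.mature_length_dist, seed=cfg.seed,
        known_fraction=s.known_fraction, n_secondary=s.n_secondary_known,
        discovery_config=cfg.discovery)
    primary, secondary = sim.mature_references(truth)
    ncrna = sim.generate_ncrna_references(seed=cfg.seed)
    libraries, true_counts = sim.simulate_srna_libraries(
        truth, ncrna, s, samples=cfg.samples, seed=cfg.seed)
    tags, site_truth = sim.simulate_degradome(
        truth, s.site_spike_factor, s.background_rate,
        s.background_tag_mean, seed=cfg.seed)
    mrna_counts, mrna_lfc = sim.simulate_mrna_counts(truth, s, seed=cfg.seed)
    term_map = sim.generate_term_map(truth, seed=cfg.seed)

    write_fasta(out / "transcripts.fasta", sorted(transcripts.items()))
    write_fasta(out / "precursors.fasta", sorted(precursors.items()))
    write_fasta(out / "mature_ref_primary.fasta", primary, as_rna=True)
    write_fasta(out / "mature_ref_secondary.fasta", secondary, as_rna=True)
    for cls, refs in ncrna.items():
        write_fasta(out / f"ncrna_{cls}.fasta", refs)
    for sample in cfg.samples:
        write_fastq(out / f"srna_{sample.sample_id}.fastq",
                    libraries[sample.sample_id])
    write_fasta(out / "degradome_tags.fasta", tags)
    write_table(mrna_counts.reset_index(names="feature"),
                out / "mrna_counts.tsv")
    rows = [{"gene": g, "term": t}
            for t in sorted(term_map) for g in sorted(term_map[t])]
    write_table(pd.DataFrame(rows, columns=["gene", "term"]),
                out / "term_map.tsv")

    mir = truth.mirna_expression.copy()
    extra = pd.DataFrame([{
        "truth_id": h.truth_id, "known": h.known, "secondary": h.secondary,
        "family": h.family or "", "precursor_id": h.precursor_id,
        "target_transcript": h.target_transcript,
        "cleavage_site": h.cleavage_site,
    } for h in truth.hairpins])
    write_table(mir.merge(extra, on="truth_id"), out / "truth_mirna.tsv")
    write_table(site_truth, out / "truth_sites.tsv")
    write_table(mrna_lfc.rename("true_lfc").rename_axis("feature")
                .reset_index(), out / "truth_mrna_lfc.tsv")
    write_table(true_counts.reset_index(names="truth_id"),
                out / "truth_srna_counts.tsv")
    cfg.dump(out / "config_used.yaml")


# -- preprocess ------------------------------------------------------------

def _load_ncrna_refs(out: Path) -> dict[str, list[tuple[str, str]]]:
    refs = {}
    for cls in prep.NCRNA_PRIORITY:
        path = out / f"ncrna_{cls}.fasta"
        refs[cls] = ([(e.id, e.seq) for e in read_sequences(path)]
                     if path.exists() else [])
    return refs


def stage_preprocess(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    p = cfg.preprocess
    refs = _load_ncrna_refs(out)
    adapter = cfg.simulate.adapter
    report_rows, hist_rows = [], []
    for sample in cfg.samples:
        sid = sample.sample_id
        reads = read_sequences(out / f"srna_{sid}.fastq")
        clean, report = prep.filter_reads(
            reads, adapter, p.min_len, p.max_len, p.max_n_frac, p.min_mean_q)
        labels = prep.classify_ncrna(clean, refs)
        report.class_counts = prep.class_counts(clean, labels)
        report.check()
        df = pd.DataFrame(
            [(seq, n, labels[seq]) for seq, n in sorted(clean.items())],
            columns=["sequence", "count", "class"])
        write_table(df, out / f"unique_reads_{sid}.tsv")
        report_rows.append({
            "sample": sid, "raw": report.raw, "removed_n": report.removed_n,
            "removed_no_adaptor": report.removed_no_adaptor,
            "removed_low_quality": report.removed_low_quality,
            "removed_length": report.removed_length, "clean": report.clean,
            **{f"class_{c}": report.class_counts.get(c, 0)
               for c in prep.NCRNA_PRIORITY + ("unannotated",)},
        })
        for length, freq in prep.length_histogram(clean).items():
            hist_rows.append({"sample": sid, "length": length, "freq": freq})
    write_table(pd.DataFrame(report_rows), out / "filter_report.tsv")
    write_table(pd.DataFrame(hist_rows), out / "length_hist.tsv")


# -- discover --------------------------------------------------------------

def _pooled_unannotated(cfg: PipelineConfig, out: Path) -> Counter:
    pooled: Counter = Counter()
    for sample in cfg.samples:
        df = read_table(out / f"unique_reads_{sample.sample_id}.tsv")
        un = df[df["class"] == "unannotated"]
        for seq, n in zip(un["sequence"], un["count"]):
            pooled[seq] += int(n)
    return pooled


def stage_discover(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    d = cfg.discovery
    pooled = _pooled_unannotated(cfg, out)
    min_count = cfg.preprocess.min_candidate_count
    candidates = sorted((seq for seq, n in pooled.items() if n >= min_count),
                        key=lambda s: (-pooled[s], s))
    primary = [(e.id, e.seq)
               for e in read_sequences(out / "mature_ref_primary.fasta")]
    secondary = [(e.id, e.seq)
                 for e in read_sequences(out / "mature_ref_secondary.fasta")]
    known = disc.match_known(candidates, primary, d.max_mm, secondary,
                             d.max_mm2, d.max_shift)
    known_matures = {r.mature for r in known}
    remaining = [c for c in candidates if c not in known_matures]
    loci = [(e.id, e.seq) for e in read_sequences(out / "precursors.fasta")]
    novel = disc.find_novel(remaining, loci, d)
    records = known + novel
    rows = [{
        "id": r.id, "mature": rna(r.mature), "length": len(r.mature),
        "status": r.status, "family": r.family or "",
        "source_ref": r.source_ref or "", "matched_set": r.matched_set or "",
        "mismatches": "" if r.mismatches is None else r.mismatches,
        "precursor_id": r.precursor_id or "",
        "mfe": "" if r.mfe is None else r.mfe,
    } for r in records]
    write_table(pd.DataFrame(rows, columns=[
        "id", "mature", "length", "status", "family", "source_ref",
        "matched_set", "mismatches", "precursor_id", "mfe",
    ]), out / "mirnas.tsv")
    with open(out / "precursor_structures.txt", "w") as fh:
        for r in novel:
            fh.write(f">{r.id} {r.precursor_id} mfe={r.mfe:.1f}\n"
                     f"{r.precursor}\n{r.structure}\n")


# -- quantify --------------------------------------------------------------

def _mirna_counts(cfg: PipelineConfig, out: Path) -> tuple[pd.DataFrame, dict]:
    mirnas = read_table(out / "mirnas.tsv")
    matures = {row["id"]: dna(row["mature"]) for _, row in mirnas.iterrows()}
    report = read_table(out / "filter_report.tsv").set_index("sample")
    counts = {}
    for sample in cfg.samples:
        sid = sample.sample_id
        df = read_table(out / f"unique_reads_{sid}.tsv")
        lookup = dict(zip(df["sequence"], df["count"]))
        counts[sid] = [int(lookup.get(matures[mid], 0)) for mid in matures]
    table = pd.DataFrame(counts, index=list(matures))
    totals = {sid: int(report.loc[sid, "clean"]) for sid in table.columns}
    return table, totals


def stage_quantify(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    counts, totals = _mirna_counts(cfg, out)
    write_table(counts.reset_index(names="miRNA"), out / "mirna_counts.tsv")
    tpm = expr.tpm_matrix(counts, totals)
    write_table(tpm.reset_index(names="miRNA"), out / "mirna_tpm.tsv")
    conditions = {s.sample_id: s.condition for s in cfg.samples}
    de = expr.differential_expression(counts, conditions, cfg.expression)
    write_table(de.reset_index(), out / "de_mirna.tsv")
    dems = de[de["call"] != "ns"].index
    z = expr.zscore_rows(tpm.loc[dems]) if len(dems) else tpm.iloc[:0]
    write_table(z.reset_index(names="miRNA"), out / "zscore_dem.tsv")


# -- predict targets -------------------------------------------------------

def stage_predict_targets(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    mirnas = read_table(out / "mirnas.tsv")
    mseqs = {row["id"]: dna(row["mature"]) for _, row in mirnas.iterrows()}
    transcripts = {e.id: e.seq
                   for e in read_sequences(out / "transcripts.fasta")}
    hits = tgt.scan_transcriptome(mseqs, transcripts,
                                  cutoff=cfg.targets.cutoff,
                                  config=cfg.targets)
    write_table(hits, out / "target_hits.tsv")


# -- degradome -------------------------------------------------------------

def stage_degradome(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    entries = read_sequences(out / "degradome_tags.fasta")
    tags = Counter(e.seq for e in entries if 20 <= len(e.seq) <= 21)
    n_length_filtered = len(entries) - sum(tags.values())
    transcripts = {e.id: e.seq
                   for e in read_sequences(out / "transcripts.fasta")}
    profiles, unmapped = deg.build_profile(tags, transcripts)
    hits = read_table(out / "target_hits.tsv")
    events, rejected = deg.validate_cleavage(hits, profiles, cfg.degradome)
    write_table(events, out / "cleavage_events.tsv")
    write_table(rejected, out / "cleavage_rejected.tsv")
    series_rows = []
    for tid in sorted(set(events["transcript"])):
        series, markers = deg.tplot_data(
            profiles[tid], events[events["transcript"] == tid])
        covered = series[series["abundance"] > 0]
        for _, row in covered.iterrows():
            series_rows.append({
                "transcript": tid, "position": int(row["position"]),
                "abundance": row["abundance"],
                "is_site": int(row["position"]) in {m[0] for m in markers},
            })
    write_table(pd.DataFrame(
        series_rows, columns=["transcript", "position", "abundance",
                              "is_site"]), out / "tplot_series.tsv")
    write_table(pd.DataFrame([{
        "tags_total": len(entries),
        "tags_length_filtered": n_length_filtered,
        "tags_unmapped": unmapped,
    }]), out / "degradome_report.tsv")


# -- integrate -------------------------------------------------------------

def stage_integrate(cfg: PipelineConfig, outdir: str | Path) -> None:
    out = _out(outdir)
    mrna = read_table(out / "mrna_counts.tsv").set_index("feature")
    conditions = {s.sample_id: s.condition for s in cfg.samples}
    de_mrna = expr.differential_expression(mrna, conditions, cfg.expression)
    write_table(de_mrna.reset_index(), out / "de_mrna.tsv")
    de_mirna = read_table(out / "de_mirna.tsv").set_index("feature")

    hits = read_table(out / "target_hits.tsv")
    events = read_table(out / "cleavage_events.tsv")
    links = pd.concat([
        pd.DataFrame({"miRNA": hits["miRNA"], "target": hits["transcript"],
                      "evidence": "predicted"}),
        pd.DataFrame({"miRNA": events["miRNA"],
                      "target": events["transcript"],
                      "evidence": "degradome"}),
    ], ignore_index=True).drop_duplicates()
    edges = net.build_network(de_mirna, de_mrna, links)
    nodes = net.network_nodes(edges)
    write_network(edges, nodes, out / "network_nodes.tsv",
                  out / "network_edges.tsv")
    write_table(edges, out / "network_edges_full.tsv")

    term_df = read_table(out / "term_map.tsv")
    term_map = {t: set(g["gene"]) for t, g in term_df.groupby("term")}
    sample_genes = sorted(set(edges["target"]))
    enrich = net.hypergeom_enrich(sample_genes, term_map,
                                  config=cfg.enrichment)
    write_table(enrich, out / "enrichment.tsv")
    scatter = net.correlation_scatter_data(de_mirna, de_mrna, edges)
    write_table(scatter, out / "scatter.tsv")

    mirnas = read_table(out / "mirnas.tsv")
    known = mirnas[mirnas["status"] == "known"]
    fam = disc.FamilySummary(
        Counter(known[known["matched_set"] == "primary"]["family"]))
    n_secondary = int((known["matched_set"] == "secondary").sum())
    n_novel = int((mirnas["status"] == "novel").sum())
    status = dict(zip(mirnas["id"], mirnas["status"]))
    deg_pairs = Counter(
        status.get(m, "novel")
        for m, _t in events[["miRNA", "transcript"]]
        .drop_duplicates().itertuples(index=False))
    net_pairs = Counter(edges["regulation"])
    report = summ.study_summary(
        fam, n_secondary, n_novel,
        {k: int(v) for k, v in deg_pairs.items()},
        {k: int(v) for k, v in net_pairs.items()})
    report.update({
        "degradome_pairs_known": int(deg_pairs.get("known", 0)),
        "degradome_pairs_novel": int(deg_pairs.get("novel", 0)),
        "network_pairs_anti": int(net_pairs.get("anti", 0)),
        "network_pairs_positive": int(net_pairs.get("positive", 0)),
        "dems": int((de_mirna["call"] != "ns").sum()),
        "degs": int((de_mrna["call"] != "ns").sum()),
        "enriched_terms": int(enrich["significant"].sum()) if len(enrich) else 0,
    })
    (out / "run_summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "discover": stage_discover,
    "quantify": stage_quantify,
    "predict_targets": stage_predict_targets,
    "degradome": stage_degradome,
    "integrate": stage_integrate,
}


def run_stage(name: str, cfg: PipelineConfig, outdir: str | Path) -> None:
    _STAGE_FUNCS[name](cfg, outdir)


def run_all(cfg: PipelineConfig, outdir: str | Path) -> None:
    for name in STAGES:
        run_stage(name, cfg, outdir)


# -- truth-based evaluation ------------------------------------------------

def recovery_metrics(outdir: str | Path) -> dict[str, float]:
    """Compare a finished run against the generator's answer key.

    Reports the fraction of planted matures identified as miRNAs, the
    fraction of true cleavage sites recovered at the exact position by
    the right miRNA, and the fraction of recovered spike-supported
    sites classified category 0.
    """
    out = Path(outdir)
    truth = read_table(out / "truth_mirna.tsv")
    mirnas = read_table(out / "mirnas.tsv")
    found = {dna(m) for m in mirnas["mature"]}
    mature_rec = float(np.mean([dna(m) in found for m in truth["mature"]]))

    events = read_table(out / "cleavage_events.tsv")
    mature_of = dict(zip(mirnas["id"], (dna(m) for m in mirnas["mature"])))
    event_keys = {(mature_of.get(r["miRNA"]), r["transcript"], r["site"])
                  for _, r in events.iterrows()}
    cat_of = {(mature_of.get(r["miRNA"]), r["transcript"], r["site"]):
              r["category"] for _, r in events.iterrows()}
    hit, cat0, recovered = 0, 0, 0
    for _, row in truth.iterrows():
        key = (dna(row["mature"]), row["target_transcript"],
               row["cleavage_site"])
        if key in event_keys:
            hit += 1
            recovered += 1
            cat0 += cat_of[key] == 0
    n_sites = len(truth)
    return {
        "mature_recovery": mature_rec,
        "site_recovery": hit / n_sites if n_sites else float("nan"),
        "category0_fraction": cat0 / recovered if recovered else float("nan"),
        "n_mirnas_planted": float(n_sites),
        "n_sites_recovered": float(recovered),
    }
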