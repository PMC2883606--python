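"""End-to-end workflow: simulate -> scan -> align -> methylation -> quantify.

Runs the stages in dependency order on synthetic inputs with a single
seed, writes all stage outputs as plain-text files, and records a run
manifest (config snapshot, seed, output paths and hashes) so a run can
be replayed and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from teloepi import io as tio
from teloepi import synthetic as syn
from teloepi.bisulfite import align_clones, conversion_check, compare_genotypes, summarize
from teloepi.quantify import average_replicates, dotblot_methylation_index, panels_from_table
from teloepi.repeat_scan import (
    classify_sirnas,
    hits_to_frame,
    homology_distribution,
    library_crosstab,
)
from teloepi.subtel_align import (
    align_perfect,
    alignments_to_bed,
    build_index,
    filter_unique,
    telomere_proximity_report,
)

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(seed: int, out_dir: str | Path, config: syn.SimConfig | None = None) -> dict:
    """Full synthetic pipeline; returns the run manifest dict.

    Every output is a text file under ``out_dir``; the manifest
    (manifest.json) lists their paths and SHA-256 hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or syn.SimConfig(seed=seed)
    cfg.seed = seed
    outputs: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    refs, tract_truth = syn.simulate_subtelomeres(cfg.subtelomere, seed)
    reads, read_truth = syn.simulate_smallrna_library(cfg.smallrna, refs, seed)
    region = syn.region_1l0()
    probs = syn.preset_probabilities(region, cfg.bisulfite.preset)
    clones, clone_truth = syn.simulate_bisulfite_clones(
        region, probs, cfg.bisulfite.conversion, cfg.bisulfite.n_clones,
        seed, cfg.bisulfite.sample, cfg.bisulfite.error_rate,
    )
    dotblot_tbl, chip_tbl = syn.simulate_signal_panels(cfg.signals, seed)

    tio.write_fasta([(r.arm_id, r.sequence) for r in refs], out / "subtelomeres.fasta")
    tio.write_tsv(tract_truth, out / "tract_truth.tsv")
    tio.write_fasta([(r.read_id, r.sequence) for r in reads], out / "smallrna.fasta")
    tio.write_tsv(read_truth, out / "smallrna_truth.tsv")
    tio.write_fasta([(cid, seq) for cid, _s, seq in clones], out / "clones.fasta")
    tio.write_tsv(clone_truth, out / "clone_truth.tsv")
    tio.write_tsv(dotblot_tbl, out / "dotblot_signals.tsv")
    tio.write_tsv(chip_tbl, out / "chip_signals.tsv")
    for name in (
        "subtelomeres.fasta", "tract_truth.tsv", "smallrna.fasta",
        "smallrna_truth.tsv", "clones.fasta", "clone_truth.tsv",
        "dotblot_signals.tsv", "chip_signals.tsv",
    ):
        outputs[name] = out / name
    log.info("simulated %d arms, %d reads, %d clones", len(refs), len(reads), len(clones))

    # --- scan -------------------------------------------------------------
    hits = classify_sirnas(reads, min_homology=cfg.smallrna.min_homology)
    tio.write_tsv(hits_to_frame(hits), out / "sirna_hits.tsv")
    tio.write_tsv(homology_distribution(hits), out / "homology_distribution.tsv")
    tio.write_tsv(library_crosstab(hits).reset_index(), out / "library_crosstab.tsv")
    outputs |= {n: out / n for n in
                ("sirna_hits.tsv", "homology_distribution.tsv", "library_crosstab.tsv")}
    log.info("scan: %d telomeric siRNA hits", len(hits))

    # --- align ------------------------------------------------------------
    lo, hi = cfg.smallrna.read_length_range
    index = build_index(refs, (min(lo, 15), max(hi, 30)))
    placements = align_perfect(reads, index)
    unique = filter_unique(placements, refs)
    bed = alignments_to_bed(unique)
    bed.to_csv(out / "unique_alignments.bed", sep="\t", index=False, header=False)
    tio.write_tsv(telomere_proximity_report(unique), out / "proximity_report.tsv")
    outputs |= {n: out / n for n in ("unique_alignments.bed", "proximity_report.tsv")}
    log.info("align: %d placements, %d unique", len(placements), len(unique))

    # --- methylation ------------------------------------------------------
    matrix = align_clones(clones, region)
    summary = summarize(matrix)
    rate, status = conversion_check(matrix)
    summary_tbl = pd.DataFrame(
        {
            "metric": ["overall", "overall_repeat", "phase1", "phase2", "phase3",
                       "CG", "CHG", "CHH", "conversion_rate", "n_clones"],
            "value": [summary.overall, summary.overall_repeat,
                      summary.per_phase[1], summary.per_phase[2], summary.per_phase[3],
                      summary.per_context["CG"], summary.per_context["CHG"],
                      summary.per_context["CHH"],
                      rate if rate is not None else float("nan"),
                      summary.n_clones],
        }
    )
    tio.write_tsv(summary_tbl, out / "methylation_summary.tsv")
    calls = matrix.calls.copy()
    calls.insert(0, "clone_id", calls.index)
    tio.write_tsv(calls, out / "methylation_calls.tsv")
    outputs |= {n: out / n for n in ("methylation_summary.tsv", "methylation_calls.tsv")}
    log.info("methylation: overall %.3f (repeat %.3f), conversion %s (%s)",
             summary.overall, summary.overall_repeat, rate, status)

    # --- quantify ---------------------------------------------------------
    dot_rows = []
    for rep, grp in dotblot_tbl.groupby("replicate"):
        panels = {p.sample: p for p in panels_from_table(grp, "dotblot")}
        for probe in ("TTTAGGG_oligo", "TTTAGGG_long"):
            idx, fold = dotblot_methylation_index(panels["wt"], panels["bs_plasmid"], probe)
            dot_rows.append({"replicate": rep, "probe": probe, "index": idx, "fold": fold})
    dot_out = pd.DataFrame(dot_rows)
    tio.write_tsv(dot_out, out / "dotblot_indices.tsv")
    chip_panels = [
        panels_from_table(grp, "chip")[0] for _rep, grp in chip_tbl.groupby("replicate")
    ]
    chip_out = average_replicates(chip_panels, "H3").reset_index()
    tio.write_tsv(chip_out, out / "chip_enrichment.tsv")
    outputs |= {n: out / n for n in ("dotblot_indices.tsv", "chip_enrichment.tsv")}
    log.info("quantify: mean oligo-probe fold %.2f",
             dot_out.loc[dot_out["probe"] == "TTTAGGG_oligo", "fold"].mean())

    manifest = {
        "tool": "teloepi",
        "seed": seed,
        "config": asdict(cfg),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
        "stage_counts": {
            "n_reads": len(reads),
            "n_sirna_hits": len(hits),
            "n_placements": len(placements),
            "n_unique_alignments": len(unique),
            "n_clones": matrix.n_clones,
            "overall_repeat_methylation": summary.overall_repeat,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
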