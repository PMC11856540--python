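"""End-to-end orchestration: simulate/annotate -> discover -> classify ->
distribution statistics -> codon-position evolution, with a JSON manifest.

Every stage is a pure function of its inputs and the run configuration, so
rerunning the same config reproduces byte-identical reports; the manifest
echoes all thresholds and per-stage record counts for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import build_length_table, parse_mitogenome, write_fasta_gff3
from .classification import classified_to_frame, classify_candidates, identity_stats, summarize_filtering
from .discovery import (
    load_hits_tabular,
    make_candidates,
    apply_length_filter,
    dedup_exact,
    mito_coverage,
    read_chrom_meta,
    search_homology,
    candidates_to_frame,
    write_bed,
)
from .codon import estimate_integration_events
from .simulate import MitoGenome, SimulationConfig, implant_numts, simulate_mitogenome, write_fasta
from .stats import build_profiles, sex_vs_autosome_test

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mitogenome: str | None = None  # GenBank path (or FASTA with mito_gff3)
    mito_gff3: str | None = None
    nuclear_fasta: str | None = None
    hits_tsv: str | None = None
    chrom_meta: str | None = None
    species_id: str = "sample"
    e_value: float = 1e-4
    length_fraction: float = 0.7
    identity_threshold: float = 97.0
    alpha: float = 0.05
    min_total: int = 10
    pairing: str = "density"  # or "counts"
    correlation: str = "pearson"
    seed: int = 0
    out_dir: str = "numtkit_out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig,
                 sim_config: SimulationConfig | None = None) -> dict:
    """Execute the full pipeline and return the run manifest.

    With ``sim_config`` supplied, inputs are generated by the simulator and
    written under the output directory before the analysis stages run on
    them exactly as they would on real files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "numtkit", "version": __version__,
        "config": asdict(config), "stages": {},
    }

    # -- stage: inputs / simulation ----------------------------------------
    if sim_config is not None:
        mito = simulate_mitogenome(sim_config)
        nuclear, truth, meta = implant_numts(sim_config, mito)
        write_fasta({"mito": mito.seq}, out / "mito.fa")
        write_fasta_gff3(mito.records, mito.seq, out / "mito.fa", out / "mito.gff3")
        write_fasta(nuclear, out / "nuclear.fa")
        with open(out / "chrom_meta.tsv", "w") as fh:
            for m in meta.values():
                fh.write(f"{m.chrom}\t{m.length_bp}\t{m.category}\n")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        pcg_records = mito.records
        species = sim_config.species_id
        manifest["stages"]["simulate"] = {"n_genes": len(pcg_records),
                                          "n_implants": len(truth)}
    else:
        if config.mitogenome is None:
            raise PipelineError("annotate", "no mitogenome supplied")
        pcg_records = parse_mitogenome(config.mitogenome, config.species_id,
                                       gff3=config.mito_gff3)
        if config.chrom_meta is None:
            raise PipelineError(
                "discover",
                "chromosome metadata is required (chrom\\tlength\\tcategory TSV); "
                "pass chrom_meta in the run config")
        meta = read_chrom_meta(config.chrom_meta)
        nuclear = None
        if config.nuclear_fasta:
            from Bio import SeqIO
            nuclear = {r.id: str(r.seq).upper()
                       for r in SeqIO.parse(config.nuclear_fasta, "fasta")}
        mito = MitoGenome(seq="", records=pcg_records)
        species = config.species_id
    manifest["stages"]["annotate"] = {"n_pcgs": len(pcg_records)}

    # -- stage: discovery ---------------------------------------------------
    length_table = build_length_table(pcg_records)
    length_table.to_tsv(out / "gene_lengths.tsv")
    if config.hits_tsv:
        hits, dropped = load_hits_tabular(config.hits_tsv, meta,
                                          species_id=species,
                                          e_threshold=config.e_value)
    elif nuclear is not None:
        searchable = {c: s for c, s in nuclear.items()
                      if meta.get(c) and meta[c].category != "unplaced"}
        hits = search_homology(searchable, pcg_records, species_id=species,
                               e_threshold=config.e_value)
        dropped = {"non_chromosome": len(nuclear) - len(searchable)}
    else:
        raise PipelineError("discover", "neither nuclear FASTA nor hits TSV supplied")
    candidates = make_candidates(hits)
    kept, removed, length_report = apply_length_filter(
        candidates, length_table, fraction=config.length_fraction)
    unique, dup_map = dedup_exact(kept)
    coverage = None
    if mito.seq:
        coverage = mito_coverage(hits, len(mito.seq), mito.pcg_offsets)
    candidates_to_frame(unique).to_csv(out / "candidates.tsv", sep="\t", index=False)
    write_bed(unique, out / "numts.bed")
    length_report.to_csv(out / "length_filter.tsv", sep="\t", index=False)
    manifest["stages"]["discover"] = {
        "n_hits": len(hits), "dropped": dropped,
        "n_after_length_filter": len(kept),
        "n_removed_by_length": len(removed),
        "n_unique": len(unique),
        "mito_coverage": coverage,
    }

    # -- stage: classification ---------------------------------------------
    pcg_seqs = {r.gene: r.nt_seq for r in pcg_records}
    classified = classify_candidates(unique, pcg_seqs)
    cls_df = classified_to_frame(classified)
    cls_df.to_csv(out / "classified.tsv", sep="\t", index=False)
    filt = summarize_filtering(classified)
    idstats = identity_stats(classified, threshold=config.identity_threshold)
    _dump_json({"filtering": filt, "identity_ge_threshold": idstats},
               out / "classification_report.json")
    manifest["stages"]["classify"] = {
        "n_classified": len(classified),
        "per_class": filt["per_class"],
        "efficiency_mean_pct": filt["efficiency_mean"],
    }

    # -- stage: distribution statistics ------------------------------------
    stats_report: dict = {}
    if not cls_df.empty:
        meta_df = pd.DataFrame(
            [{"species_id": species, "chrom": m.chrom,
              "length_bp": m.length_bp, "category": m.category}
             for m in meta.values() if m.category != "unplaced"])
        profiles = build_profiles(cls_df.assign(species_id=species), meta_df)
        profiles.to_csv(out / "chromosome_profiles.tsv", sep="\t", index=False)
        sex = sex_vs_autosome_test(profiles, unit=config.pairing,
                                   alpha=config.alpha)
        stats_report["sex_vs_autosome"] = sex.to_dict(orient="records")
        c1 = cls_df[cls_df["numt_class"] == "C1"]
        counts = (c1.groupby("gene").size()
                  .reindex(sorted(pcg_seqs), fill_value=0))
        stats_report["c1_counts_per_gene"] = counts.to_dict()
    _dump_json(stats_report, out / "stats_report.json")
    manifest["stages"]["stats"] = {"n_tests": len(stats_report)}

    # -- stage: codon evolution --------------------------------------------
    events_report = {}
    for gene, sub in cls_df.groupby("gene"):
        ids = {}
        for cn in classified:
            if cn.candidate.hit.source_gene != gene:
                continue
            seq = cn.candidate.hit.hit_seq
            if cn.candidate.hit.strand == "-":
                from .genetic_code import reverse_complement
                seq = reverse_complement(seq)
            ids[cn.candidate.candidate_id] = seq
        if not ids:
            continue
        ev = estimate_integration_events(ids, pcg_seqs[gene],
                                         species_id=species, gene=gene,
                                         alpha=config.alpha,
                                         min_total=config.min_total)
        events_report[gene] = ev.to_report()
    _dump_json(events_report, out / "integration_events.json")
    manifest["stages"]["codon"] = {
        "genes_analyzed": sorted(events_report),
        "n_events_total": sum(v["n_events"] for v in events_report.values()),
    }

    _dump_json(manifest, out / "manifest.json")
    return manifest
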