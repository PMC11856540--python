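"""ORF-based classification of NUMTs against their source PCG.

Once integrated into the nucleus a mitochondrial gene copy decays: indels
break the reading frame, premature stops appear, start/stop codons erode.
Each NUMT is globally aligned to its source PCG and sorted into five
categories by the state of its open reading frame:

* C1 - length consistent with the PCG, correct start and stop codons;
* C2 - length differs by more than 2 amino acids, frame otherwise intact;
* C3 - in-frame internal stop codon(s);
* C4 - 1-2 amino acids shorter/longer, correct start and stop codons;
* C5 - small length difference (0-2 aa) with start or stop codon missing.

The decision tree is applied in the documented precedence order: internal
stops dominate, then large length difference, then the C1/C4/C5 split.
C2-C5 NUMTs carry overt decay signatures and are easy to screen out of
barcoding data; C1 NUMTs mimic the functional gene and are the dangerous
residue, so their identity distribution is summarized separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import Align

from .discovery import NumtCandidate
from .genetic_code import TABLE5, GeneticCode


@dataclass
class PairAlignment:
    """Global pairwise alignment, PCG row first."""

    pcg_aln: str
    numt_aln: str
    score: float

    def __post_init__(self):
        if len(self.pcg_aln) != len(self.numt_aln):
            raise ValueError("aligned rows differ in length")


def align_pair(
    pcg_nt: str,
    numt_nt: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairAlignment:
    """Needleman-Wunsch global alignment with affine gaps (EMBOSS-like
    defaults).  The first optimal alignment under Biopython's canonical
    traceback order is returned, making the result deterministic.
    """
    if not pcg_nt or not numt_nt:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(pcg_nt.upper(), numt_nt.upper())[0]
    return PairAlignment(pcg_aln=aln[0], numt_aln=aln[1], score=aln.score)


@dataclass
class OrfAnalysis:
    delta_aa: int
    frameshift_present: bool
    internal_stops: int
    start_present: bool
    stop_present: bool
    percent_identity: float


def _gap_runs(row: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(row):
        if row[i] == "-":
            j = i
            while j < len(row) and row[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def analyze_orf(alignment: PairAlignment, code: GeneticCode = TABLE5) -> OrfAnalysis:
    """Derive reading-frame features of the NUMT from the pairwise alignment.

    The codon frame is inherited from the PCG row (PCG position 0 = codon
    position 1).  ``delta_aa`` compares realized codon counts (floor of
    nucleotide length over 3); ``internal_stops`` counts in-frame stops in
    the NUMT translated in the inherited frame, excluding a terminal stop.
    """
    pcg_row, numt_row = alignment.pcg_aln, alignment.numt_aln
    numt_seq = numt_row.replace("-", "")
    pcg_seq = pcg_row.replace("-", "")
    if not numt_seq:
        raise ValueError("alignment has an empty NUMT row")

    frameshift = any((b - a) % 3 != 0
                     for a, b in _gap_runs(pcg_row) + _gap_runs(numt_row))

    # frame offset of the first NUMT base relative to PCG codon boundaries
    first_col = next(i for i, ch in enumerate(numt_row) if ch != "-")
    pcg_pos_at = sum(1 for ch in pcg_row[:first_col] if ch != "-")
    offset = (-pcg_pos_at) % 3  # bases to skip so codons start on a PCG boundary
    coding = numt_seq[offset:]
    codons = [coding[i : i + 3] for i in range(0, len(coding) - 2, 3)]
    stops = [i for i, c in enumerate(codons) if code.is_stop(c)]
    internal = [i for i in stops if i != len(codons) - 1]

    delta_aa = len(numt_seq) // 3 - len(pcg_seq) // 3

    start_present = code.is_start(numt_seq[:3])
    tail3 = numt_seq[-3:]
    rem = len(numt_seq) % 3
    stop_present = code.is_stop(tail3) or (
        rem > 0 and numt_seq[-rem:] in code.incomplete_stops
    )

    cols = len(pcg_row)
    matches = sum(1 for a, b in zip(pcg_row, numt_row)
                  if a == b and a != "-")
    pid = 100.0 * matches / cols if cols else 0.0

    return OrfAnalysis(
        delta_aa=delta_aa,
        frameshift_present=frameshift,
        internal_stops=len(internal),
        start_present=start_present,
        stop_present=stop_present,
        percent_identity=pid,
    )


CLASSES = ("C1", "C2", "C3", "C4", "C5")


def classify(analysis: OrfAnalysis) -> str:
    """Total, deterministic decision tree over the ORF features.

    Precedence: internal stops (C3) dominate; then length difference > 2 aa
    (C2); then the exact/near-length split with intact termini (C1/C4); any
    remaining small-length-difference NUMT with a missing start or stop is
    C5 (including the 0-aa-difference case).
    """
    if analysis.internal_stops > 0:
        return "C3"
    if abs(analysis.delta_aa) > 2:
        return "C2"
    termini = analysis.start_present and analysis.stop_present
    if analysis.delta_aa == 0 and termini:
        return "C1"
    if 1 <= abs(analysis.delta_aa) <= 2 and termini:
        return "C4"
    return "C5"


@dataclass
class ClassifiedNumt:
    candidate: NumtCandidate
    analysis: OrfAnalysis
    numt_class: str


def classify_candidates(
    candidates: Iterable[NumtCandidate],
    pcg_seqs: dict[str, str],
    code: GeneticCode = TABLE5,
) -> list[ClassifiedNumt]:
    """Align each candidate to its source PCG sequence and classify it."""
    out = []
    for c in candidates:
        gene = c.hit.source_gene
        if gene not in pcg_seqs:
            raise KeyError(f"no PCG sequence for gene {gene!r}")
        seq = c.hit.hit_seq if c.hit.strand == "+" else _revcomp(c.hit.hit_seq)
        aln = align_pair(pcg_seqs[gene], seq)
        ana = analyze_orf(aln, code)
        out.append(ClassifiedNumt(candidate=c, analysis=ana, numt_class=classify(ana)))
    return out


def _revcomp(seq: str) -> str:
    from .genetic_code import reverse_complement
    return reverse_complement(seq)


def classified_to_frame(classified: list[ClassifiedNumt]) -> pd.DataFrame:
    rows = []
    for cn in classified:
        h = cn.candidate.hit
        rows.append({
            "species_id": h.species_id, "gene": h.source_gene, "chrom": h.chrom,
            "start": h.chrom_start, "end": h.chrom_end, "strand": h.strand,
            "numt_class": cn.numt_class, "delta_aa": cn.analysis.delta_aa,
            "internal_stops": cn.analysis.internal_stops,
            "frameshift": cn.analysis.frameshift_present,
            "identity": round(cn.analysis.percent_identity, 3),
            "duplicate_count": cn.candidate.duplicate_count,
        })
    return pd.DataFrame(rows)


def summarize_filtering(classified: list[ClassifiedNumt]) -> dict:
    """Filtering report: removing C2-C5 leaves only the PCG-mimicking C1s.

    Per-gene efficiency = removed / total (percent); the report carries the
    mean +/- SD across genes and the number of species left with zero C1
    NUMTs ("cleared" of interference).
    """
    if not classified:
        return {"per_gene": {}, "per_class": {}, "efficiency_mean": None,
                "efficiency_sd": None, "species_cleared": 0, "n_species": 0}
    df = classified_to_frame(classified)
    per_class = df["numt_class"].value_counts().to_dict()
    per_gene = {}
    effs = []
    for gene, sub in df.groupby("gene"):
        total = len(sub)
        kept = int((sub["numt_class"] == "C1").sum())
        eff = 100.0 * (total - kept) / total
        per_gene[gene] = {"before": total, "after": kept,
                          "efficiency_pct": round(eff, 4)}
        effs.append(eff)
    cleared = 0
    for sp, sub in df.groupby("species_id"):
        if (sub["numt_class"] == "C1").sum() == 0:
            cleared += 1
    return {
        "per_gene": per_gene,
        "per_class": {k: int(v) for k, v in sorted(per_class.items())},
        "efficiency_mean": float(np.mean(effs)),
        "efficiency_sd": float(np.std(effs, ddof=1)) if len(effs) > 1 else 0.0,
        "species_cleared": cleared,
        "n_species": df["species_id"].nunique(),
    }


def identity_stats(classified: list[ClassifiedNumt], threshold: float = 97.0) -> dict[str, float | None]:
    """Per-gene proportion of C1 NUMTs at or above the identity threshold.

    Genes with no C1 NUMTs are reported as None (undefined), not zero.
    """
    df = classified_to_frame(classified)
    out: dict[str, float | None] = {}
    for gene, sub in df.groupby("gene"):
        c1 = sub[sub["numt_class"] == "C1"]
        out[gene] = None if c1.empty else float((c1["identity"] >= threshold).mean())
    return out
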