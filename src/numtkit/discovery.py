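"""NUMT candidate discovery from nuclear-vs-mitochondrial homology.

NUMTs are located by local similarity between the 13 mitochondrial PCGs and
nuclear chromosome sequences.  Two routes produce hits: an external BLASTN
run loaded from tabular output (``load_hits_tabular``), or the built-in
seed-and-extend searcher (``search_homology``) which is sufficient for
simulated genomes and small tasks.  Downstream filtering follows the
protocol: keep hits on assembled chromosomes only, drop hits shorter than a
fraction (default 70%) of the longest copy of the source gene across the
cohort, and collapse exact duplicate sequences, keeping duplicate counts
for distribution statistics.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import GeneLengthTable, PcgRecord
from .genetic_code import reverse_complement


class DiscoveryError(ValueError):
    pass


@dataclass
class ChromosomeMeta:
    chrom: str
    length_bp: int
    category: str  # autosome | X | Y | unplaced

    def __post_init__(self):
        if self.length_bp <= 0:
            raise DiscoveryError(f"{self.chrom}: non-positive length")
        if self.category not in {"autosome", "X", "Y", "unplaced"}:
            raise DiscoveryError(f"{self.chrom}: unknown category {self.category!r}")


def read_chrom_meta(path: str | Path) -> dict[str, ChromosomeMeta]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "length", "category"], header=None,
                     dtype={"chrom": str})
    # tolerate a header row
    if df.iloc[0]["chrom"] == "chrom":
        df = df.iloc[1:]
    return {
        str(r.chrom): ChromosomeMeta(str(r.chrom), int(r.length), str(r.category))
        for r in df.itertuples()
    }


def write_chrom_meta(meta: dict[str, ChromosomeMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in meta.values():
            fh.write(f"{m.chrom}\t{m.length_bp}\t{m.category}\n")


@dataclass
class HomologyHit:
    """One local alignment between a PCG (query) and a chromosome (subject)."""

    species_id: str
    source_gene: str
    chrom: str
    chrom_start: int  # 0-based half-open, chrom_start < chrom_end
    chrom_end: int
    strand: str
    mito_start: int  # 0-based half-open on the source PCG
    mito_end: int
    percent_identity: float
    e_value: float
    bit_score: float
    hit_seq: str = ""  # nuclear side, chromosome plus-strand orientation

    def __post_init__(self):
        if self.chrom_end <= self.chrom_start:
            raise DiscoveryError("chrom_end must exceed chrom_start")

    @property
    def length_nt(self) -> int:
        return self.chrom_end - self.chrom_start


@dataclass
class NumtCandidate:
    hit: HomologyHit
    passes_length_filter: bool = True
    duplicate_group: str | None = None
    duplicate_count: int = 1
    candidate_id: str = ""

    @property
    def length_nt(self) -> int:
        return self.hit.length_nt


# ---------------------------------------------------------------------------
# BLAST tabular loading

_OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def load_hits_tabular(
    path: str | Path,
    chrom_meta: dict[str, ChromosomeMeta],
    species_id: str = "",
    e_threshold: float = 1e-4,
) -> tuple[list[HomologyHit], dict[str, int]]:
    """Load BLAST ``outfmt 6`` rows (optionally with a 13th ``sseq`` column).

    Query is the PCG, subject the nuclear sequence.  Subject coordinates are
    converted to 0-based half-open with start < end and the strand recorded.
    Hits above the E-value threshold, or on sequences not annotated as
    chromosomes in ``chrom_meta``, are dropped and counted.
    """
    hits: list[HomologyHit] = []
    dropped = {"evalue": 0, "non_chromosome": 0}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) not in (12, 13):
            raise DiscoveryError(f"line {lineno}: expected 12 or 13 columns, got {len(cols)}")
        try:
            row = dict(zip(_OUTFMT6, cols))
            pident = float(row["pident"])
            qstart, qend = int(row["qstart"]), int(row["qend"])
            sstart, send = int(row["sstart"]), int(row["send"])
            evalue = float(row["evalue"])
            bits = float(row["bitscore"])
        except ValueError as exc:
            raise DiscoveryError(f"line {lineno}: malformed row: {exc}") from exc
        if evalue > e_threshold:
            dropped["evalue"] += 1
            continue
        chrom = row["sseqid"]
        meta = chrom_meta.get(chrom)
        if meta is None or meta.category == "unplaced":
            dropped["non_chromosome"] += 1
            continue
        if sstart <= send:
            strand, cs, ce = "+", sstart - 1, send
        else:
            strand, cs, ce = "-", send - 1, sstart
        seq = cols[12].replace("-", "").upper() if len(cols) == 13 else ""
        if seq and strand == "-":
            seq = reverse_complement(seq)  # store plus-strand orientation
        hits.append(HomologyHit(
            species_id=species_id, source_gene=row["qseqid"], chrom=chrom,
            chrom_start=cs, chrom_end=ce, strand=strand,
            mito_start=qstart - 1, mito_end=qend,
            percent_identity=pident, e_value=evalue, bit_score=bits, hit_seq=seq,
        ))
    return hits, dropped


# ---------------------------------------------------------------------------
# built-in seed-and-extend search

#: Ungapped Karlin-Altschul parameters for match=+2/mismatch=-3 scoring,
#: used to approximate BLASTN E-values for the built-in searcher.
_KA_LAMBDA = 0.625
_KA_K = 0.41


def _nuc_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "N" or b == "N":
                m[a, b] = mismatch  # N never counts as a match
            else:
                m[a, b] = match if a == b else mismatch
    return m


_CODE_LUT = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i


def _kmer_hashes(seq: str, word: int) -> np.ndarray:
    """2-bit rolling hashes of all words; windows containing non-ACGT get -1."""
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size
    if n < word:
        return np.empty(0, dtype=np.int64)
    m = n - word + 1
    h = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for k in range(word):
        window = codes[k : m + k]
        h = (h << 2) | np.maximum(window, 0)
        valid &= window >= 0
    h[~valid] = -1
    return h


def _index_query(query: str, word: int) -> dict[int, list[int]]:
    qh = _kmer_hashes(query, word)
    index: dict[int, list[int]] = defaultdict(list)
    for i, h in enumerate(qh):
        if h >= 0:
            index[int(h)].append(i)
    return dict(index)


def search_homology(
    nuclear: dict[str, str],
    pcgs: list[PcgRecord],
    species_id: str = "",
    min_word: int = 11,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    e_threshold: float = 1e-4,
    cluster_gap: int = 120,
) -> list[HomologyHit]:
    """Find local alignments of each PCG against nuclear sequences.

    Exact-word seeds are clustered by diagonal, each cluster window is
    refined with an affine-gap Smith-Waterman restricted to the window, and
    E-values are approximated with ungapped Karlin-Altschul statistics
    (lambda=0.625, K=0.41 for +2/-3 scoring).  Both strands are searched;
    each (chrom, interval, strand) is reported once.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nuc_matrix(match, mismatch)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    total_subject = sum(len(s) for s in nuclear.values())
    hits: list[HomologyHit] = []
    seen: set[tuple[str, int, int, str, str]] = set()
    query_indexes = {p.gene: _index_query(p.nt_seq, min_word)
                     for p in pcgs if p.nt_seq}
    for chrom, chrom_seq_raw in nuclear.items():
        chrom_seq = chrom_seq_raw.upper()
        for strand in ("+", "-"):
            subject = chrom_seq if strand == "+" else reverse_complement(chrom_seq)
            sh = _kmer_hashes(subject, min_word)
            for pcg in pcgs:
                query = pcg.nt_seq
                if not query:
                    continue
                qindex = query_indexes[pcg.gene]
                qh = np.fromiter(qindex.keys(), dtype=np.int64, count=len(qindex))
                cand = np.flatnonzero(np.isin(sh, qh)) if sh.size else np.empty(0, int)
                diags: dict[int, list[int]] = defaultdict(list)
                for j in cand:
                    for i in qindex[int(sh[j])]:
                        diags[int(j) - i].append(int(j))
                if not diags:
                    continue
                # ungapped pre-filter: best max-subarray score on each
                # diagonal (Kadane via cumulative sums); only diagonals
                # reaching the score needed for the E threshold go on to
                # gapped alignment.  Nearby diagonals (indels) are pooled
                # by taking windows around passing diagonals and merging.
                q_arr = np.frombuffer(query.encode(), dtype="S1")
                s_arr = np.frombuffer(subject.encode(), dtype="S1")
                min_bits = math.log2(len(query) * max(1, total_subject) / e_threshold)
                min_score = (min_bits * math.log(2) + math.log(_KA_K)) / _KA_LAMBDA
                windows: list[tuple[int, int]] = []
                for diag, positions in diags.items():
                    q_lo = max(0, -diag)
                    q_hi = min(len(query), len(subject) - diag)
                    if q_hi - q_lo < min_word:
                        continue
                    qs = q_arr[q_lo:q_hi]
                    ss = s_arr[q_lo + diag : q_hi + diag]
                    scores = np.where((qs == ss) & (qs != b"N"), match, mismatch)
                    cum = np.concatenate(([0.0], np.cumsum(scores)))
                    best = float(np.max(cum[1:] - np.minimum.accumulate(cum[:-1])))
                    # pass slightly below the final requirement so gapped
                    # alignment can rescue hits split across diagonals by
                    # indels; random seed extensions stay far below this
                    if best >= 0.8 * min_score:
                        positions.sort()
                        windows.append((positions[0], positions[-1]))
                if not windows:
                    continue
                # merge overlapping windows (with margin) to avoid re-alignment
                margin = len(query) + cluster_gap
                windows.sort()
                merged: list[list[int]] = []
                for a, b in windows:
                    lo, hi = max(0, a - margin), min(len(subject), b + margin + min_word)
                    if merged and lo <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], hi)
                    else:
                        merged.append([lo, hi])
                for lo, hi in merged:
                    window = subject[lo:hi]
                    alns = aligner.align(query, window)
                    try:
                        aln = alns[0]
                    except IndexError:
                        continue
                    score = aln.score
                    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
                    evalue = len(query) * total_subject * 2 ** (-bits)
                    if evalue > e_threshold:
                        continue
                    (qs, qe) = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
                    (ss, se) = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
                    # identity over aligned columns
                    s1, s2 = aln[0], aln[1]
                    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-" and x != "N")
                    pid = 100.0 * matches / max(1, len(s1))
                    sub_lo, sub_hi = lo + ss, lo + se
                    if strand == "+":
                        cs, ce = sub_lo, sub_hi
                    else:
                        cs, ce = len(chrom_seq) - sub_hi, len(chrom_seq) - sub_lo
                    key = (chrom, cs, ce, strand, pcg.gene)
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(HomologyHit(
                        species_id=species_id or pcg.species_id,
                        source_gene=pcg.gene, chrom=chrom,
                        chrom_start=cs, chrom_end=ce, strand=strand,
                        mito_start=qs, mito_end=qe,
                        percent_identity=round(pid, 3),
                        e_value=float(evalue), bit_score=round(bits, 2),
                        hit_seq=chrom_seq[cs:ce],
                    ))
    hits.sort(key=lambda h: (h.source_gene, h.chrom, h.chrom_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# filtering

def make_candidates(hits: list[HomologyHit]) -> list[NumtCandidate]:
    out = []
    for i, h in enumerate(hits):
        out.append(NumtCandidate(
            hit=h, candidate_id=f"{h.species_id}|{h.source_gene}|{h.chrom}:"
                                f"{h.chrom_start}-{h.chrom_end}{h.strand}|{i}"))
    return out


def apply_length_filter(
    candidates: list[NumtCandidate],
    length_table: GeneLengthTable,
    fraction: float = 0.7,
) -> tuple[list[NumtCandidate], list[NumtCandidate], pd.DataFrame]:
    """Partition candidates at ``fraction`` of the longest cohort PCG length.

    A candidate is kept iff its nuclear length is at least
    ``fraction * max_length_nt(source_gene)``.  Returns (kept, removed,
    per-gene before/after counts).
    """
    kept, removed = [], []
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for c in candidates:
        gene = c.hit.source_gene
        try:
            thr = fraction * length_table.max_for(gene)
        except KeyError as exc:
            raise DiscoveryError(f"unknown source gene {gene!r}") from exc
        ok = c.length_nt >= thr
        c = replace(c, passes_length_filter=ok)
        counts[gene][0] += 1
        if ok:
            counts[gene][1] += 1
            kept.append(c)
        else:
            removed.append(c)
    report = pd.DataFrame(
        [(g, b, a) for g, (b, a) in sorted(counts.items())],
        columns=["gene", "before", "after"],
    )
    return kept, removed, report


def dedup_exact(candidates: list[NumtCandidate]) -> tuple[list[NumtCandidate], dict[str, list[str]]]:
    """Collapse byte-identical hit sequences per (species, source gene).

    The representative is the candidate with the lexicographically smallest
    (chrom, chrom_start); the duplicate map records all member candidate ids
    per group so family sizes survive into distribution statistics.
    """
    groups: dict[tuple[str, str, str], list[NumtCandidate]] = defaultdict(list)
    for c in candidates:
        if not c.hit.hit_seq:
            raise DiscoveryError(f"{c.candidate_id}: hit_seq required for dedup")
        # strand-normalize to gene sense so identical insertions collapse
        # regardless of which chromosome strand they landed on
        seq = c.hit.hit_seq.upper()
        if c.hit.strand == "-":
            seq = reverse_complement(seq)
        groups[(c.hit.species_id, c.hit.source_gene, seq)].append(c)
    reps: list[NumtCandidate] = []
    dup_map: dict[str, list[str]] = {}
    for key, members in groups.items():
        members.sort(key=lambda c: (c.hit.chrom, c.hit.chrom_start))
        rep = replace(members[0],
                      duplicate_group=members[0].candidate_id,
                      duplicate_count=len(members))
        reps.append(rep)
        dup_map[rep.candidate_id] = [m.candidate_id for m in members]
    reps.sort(key=lambda c: (c.hit.source_gene, c.hit.chrom, c.hit.chrom_start))
    return reps, dup_map


def mito_coverage(
    hits: list[HomologyHit],
    mito_length: int,
    pcg_offsets: dict[str, tuple[int, int, str]] | None = None,
) -> float:
    """Fraction of the mitogenome covered by the union of hit intervals.

    Hit coordinates live on the source PCG; ``pcg_offsets`` maps each gene to
    its (start, end, strand) on the mitogenome so PCG-anchored intervals can
    be projected onto the mitogenome axis.  Without offsets, hit mito
    coordinates are taken as genome coordinates directly.
    """
    intervals = []
    for h in hits:
        if pcg_offsets is not None:
            gs, ge, strand = pcg_offsets[h.source_gene]
            if strand == "+":
                a, b = gs + h.mito_start, gs + h.mito_end
            else:
                a, b = ge - h.mito_end, ge - h.mito_start
        else:
            a, b = h.mito_start, h.mito_end
        if b > mito_length or a < 0:
            raise DiscoveryError(f"interval [{a},{b}) exceeds mitogenome length {mito_length}")
        intervals.append((a, b))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_a, cur_b = intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    covered += cur_b - cur_a
    return covered / mito_length


def write_bed(candidates: list[NumtCandidate], path: str | Path) -> None:
    """BED6: name = source gene, score = percent identity (0-1000 scaled)."""
    with open(path, "w") as fh:
        for c in candidates:
            h = c.hit
            fh.write("\t".join([
                h.chrom, str(h.chrom_start), str(h.chrom_end), h.source_gene,
                f"{min(1000, int(round(h.percent_identity * 10)))}", h.strand,
            ]) + "\n")


def candidates_to_frame(candidates: list[NumtCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        h = c.hit
        rows.append({
            "candidate_id": c.candidate_id, "species_id": h.species_id,
            "gene": h.source_gene, "chrom": h.chrom, "start": h.chrom_start,
            "end": h.chrom_end, "strand": h.strand, "length_nt": h.length_nt,
            "pident": h.percent_identity, "evalue": h.e_value,
            "duplicate_count": c.duplicate_count,
        })
    return pd.DataFrame(rows)
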