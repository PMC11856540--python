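"""Extraction and validation of mitochondrial protein-coding genes.

A metazoan mitogenome carries 13 protein-coding genes (PCGs): ND1-6, ND4L,
COX1-3, ATP6, ATP8 and CYTB.  This module parses existing annotations
(GenBank flat files, or FASTA plus GFF3), normalizes the many naming
conventions in circulation (COI vs COX1, COB vs CYTB, NAD4L vs ND4L, ...),
strand-corrects the coding sequences and validates start/stop codon usage
under the invertebrate mitochondrial code, including the truncated T/TA
stops completed post-transcriptionally.

Coordinates are held internally as 0-based half-open intervals; GFF3 and
GenBank locations are converted on the way in and out.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import TABLE5, GeneticCode, reverse_complement, translate

logger = logging.getLogger(__name__)

#: Canonical gene order around the typical insect mitogenome.
CANONICAL_GENES = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

_SYNONYMS = {
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1", "MT-CO1": "COX1", "COX1": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2", "MT-CO2": "COX2", "COX2": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3", "MT-CO3": "COX3", "COX3": "COX3",
    "COB": "CYTB", "CYTB": "CYTB", "CYB": "CYTB", "MT-CYB": "CYTB",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6", "MT-ATP6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8", "MT-ATP8": "ATP8",
    "NAD1": "ND1", "ND1": "ND1", "NADH1": "ND1", "MT-ND1": "ND1",
    "NAD2": "ND2", "ND2": "ND2", "NADH2": "ND2", "MT-ND2": "ND2",
    "NAD3": "ND3", "ND3": "ND3", "NADH3": "ND3", "MT-ND3": "ND3",
    "NAD4": "ND4", "ND4": "ND4", "NADH4": "ND4", "MT-ND4": "ND4",
    "NAD4L": "ND4L", "ND4L": "ND4L", "NADH4L": "ND4L", "MT-ND4L": "ND4L",
    "NAD5": "ND5", "ND5": "ND5", "NADH5": "ND5", "MT-ND5": "ND5",
    "NAD6": "ND6", "ND6": "ND6", "NADH6": "ND6", "MT-ND6": "ND6",
}


class AnnotationError(ValueError):
    """Raised for unreadable or invalid annotation input."""


def normalize_gene_name(raw: str) -> str | None:
    """Map an annotation gene label to its canonical PCG name, or None."""
    key = raw.strip().upper().replace("-", "").replace("_", "")
    key2 = raw.strip().upper()
    return _SYNONYMS.get(key2, _SYNONYMS.get(key))


@dataclass
class CodonReport:
    start_ok: bool
    stop_kind: str  # TAA, TAG, TA, T or "none"
    internal_stop_count: int
    nonstandard_start: str | None


@dataclass
class PcgRecord:
    """One mitochondrial protein-coding gene of one species."""

    gene: str
    species_id: str
    start: int  # 0-based half-open on the mitogenome
    end: int
    strand: str  # "+" or "-"
    nt_seq: str
    code: GeneticCode = field(default=TABLE5, repr=False)

    def __post_init__(self):
        self.nt_seq = self.nt_seq.upper()
        bad = set(self.nt_seq) - set("ACGTN")
        if bad:
            raise AnnotationError(
                f"{self.species_id}/{self.gene}: ambiguity codes other than N "
                f"are not supported: {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.nt_seq)

    @property
    def start_codon(self) -> str:
        return self.nt_seq[:3]

    @property
    def stop_codon(self) -> str:
        rem = len(self.nt_seq) % 3
        if rem:
            return self.nt_seq[-rem:]
        return self.nt_seq[-3:]

    @property
    def aa_seq(self) -> str:
        aa = translate(self.nt_seq, self.code)
        return aa[:-1] if aa.endswith("*") else aa


def validate_codons(record: PcgRecord, code: GeneticCode = TABLE5) -> CodonReport:
    """Check initiation/termination codon usage and scan for internal stops.

    ``stop_kind`` distinguishes complete stops (TAA/TAG) from the truncated
    T/TA signals found at the annotated terminus of many mitochondrial genes.
    """
    seq = record.nt_seq
    if len(seq) < 6:
        raise AnnotationError(f"{record.gene}: sequence shorter than 6 nt")
    first = seq[:3]
    start_ok = code.is_start(first)
    rem = len(seq) % 3
    if rem:
        tail = seq[-rem:]
        stop_kind = tail if tail in code.incomplete_stops else "none"
        coding = seq[: len(seq) - rem]
    else:
        stop_kind = seq[-3:] if code.is_stop(seq[-3:]) else "none"
        coding = seq
    aa = translate(coding, code)
    # exclude the terminal stop from the internal count
    if stop_kind in code.stop_codons and aa.endswith("*"):
        aa = aa[:-1]
    return CodonReport(
        start_ok=start_ok,
        stop_kind=stop_kind,
        internal_stop_count=aa.count("*"),
        nonstandard_start=None if start_ok else first,
    )


# ---------------------------------------------------------------------------
# parsing

def _records_from_features(seq: str, features, species_id: str, code: GeneticCode):
    records: list[PcgRecord] = []
    for name_raw, start, end, strand in features:
        gene = normalize_gene_name(name_raw)
        if gene is None:
            warnings.warn(f"unresolvable gene name {name_raw!r}; record skipped")
            continue
        sub = seq[start:end]
        if strand == "-":
            sub = reverse_complement(sub)
        records.append(
            PcgRecord(gene=gene, species_id=species_id, start=start, end=end,
                      strand=strand, nt_seq=sub, code=code)
        )
    return records


def parse_mitogenome(
    path: str | Path,
    species_id: str,
    gff3: str | Path | None = None,
    code: GeneticCode = TABLE5,
) -> list[PcgRecord]:
    """Parse an annotated mitogenome into up to 13 :class:`PcgRecord`.

    ``path`` is a GenBank flat file, or (when ``gff3`` is given) a FASTA
    whose CDS features are described by the GFF3 file.  Gene names are
    normalized through the synonym table; unresolvable names are skipped
    with a warning, and missing genes are reported via the log.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"cannot read {path}")
    if gff3 is None:
        try:
            rec = next(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # noqa: BLE001
            raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc
        feats = []
        for f in rec.features:
            if f.type != "CDS":
                continue
            name = (f.qualifiers.get("gene") or f.qualifiers.get("product") or ["?"])[0]
            feats.append(
                (name, int(f.location.start), int(f.location.end),
                 "-" if f.location.strand == -1 else "+")
            )
        seq = str(rec.seq).upper()
    else:
        rec = next(SeqIO.parse(str(path), "fasta"))
        seq = str(rec.seq).upper()
        feats = []
        for line in Path(gff3).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            if cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("gene") or attrs.get("Name") or attrs.get("ID", "?")
            feats.append((name, int(cols[3]) - 1, int(cols[4]), cols[6]))
    records = _records_from_features(seq, feats, species_id, code)
    found = {r.gene for r in records}
    missing = [g for g in CANONICAL_GENES if g not in found]
    if missing:
        logger.warning("%s: %d PCGs missing from annotation: %s",
                       species_id, len(missing), ",".join(missing))
    return records


def write_fasta_gff3(records: list[PcgRecord], genome_seq: str,
                     fasta_path: str | Path, gff3_path: str | Path,
                     seqid: str = "mito") -> None:
    """Write the mitogenome FASTA and a GFF3 with one CDS per gene."""
    SeqIO.write([SeqRecord(Seq(genome_seq), id=seqid, description="")],
                str(fasta_path), "fasta")
    lines = ["##gff-version 3"]
    for r in sorted(records, key=lambda r: r.start):
        lines.append("\t".join([
            seqid, "numtkit", "CDS", str(r.start + 1), str(r.end), ".",
            r.strand, "0", f"ID=cds-{r.gene};gene={r.gene}",
        ]))
    Path(gff3_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# length table and supermatrix export

@dataclass
class GeneLengthTable:
    """Per-(gene, species) nucleotide lengths with per-gene maxima."""

    lengths: pd.DataFrame  # index species_id, columns gene

    @property
    def max_length_nt(self) -> pd.Series:
        return self.lengths.max(axis=0, skipna=True).astype("Int64")

    def max_for(self, gene: str) -> int:
        if gene not in self.lengths.columns:
            raise KeyError(f"gene {gene!r} not present in length table")
        return int(self.lengths[gene].max())

    def to_tsv(self, path: str | Path) -> None:
        out = self.lengths.copy()
        out.loc["__max__"] = self.lengths.max(axis=0)
        out.to_csv(path, sep="\t")


def build_length_table(records: list[PcgRecord]) -> GeneLengthTable:
    """Tabulate gene lengths across species and compute per-gene maxima."""
    if not records:
        raise ValueError("no records supplied")
    rows = [(r.species_id, r.gene, r.length_nt) for r in records]
    df = pd.DataFrame(rows, columns=["species_id", "gene", "length_nt"])
    wide = df.pivot_table(index="species_id", columns="gene", values="length_nt",
                          aggfunc="max")
    absent = [g for g in CANONICAL_GENES if g not in wide.columns]
    if absent:
        warnings.warn(f"genes absent in all species omitted: {','.join(absent)}")
    order = [g for g in CANONICAL_GENES if g in wide.columns]
    return GeneLengthTable(lengths=wide[order])


def export_supermatrix(
    records: list[PcgRecord],
    gene_subset: list[str] | None = None,
    unit: str = "nt",
    fasta_path: str | Path | None = None,
    partition_path: str | Path | None = None,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate genes per species and emit partition ranges.

    Genes are concatenated in canonical mitogenome order; the partition list
    holds 1-based inclusive ranges in RAxML style.  Species missing any
    requested gene are dropped with a warning.  Note: sequences are exported
    as-is (unaligned) — alignment is downstream of this package.
    """
    genes = [g for g in CANONICAL_GENES if g in (gene_subset or CANONICAL_GENES)]
    by_species: dict[str, dict[str, PcgRecord]] = {}
    for r in records:
        by_species.setdefault(r.species_id, {})[r.gene] = r
    rows: dict[str, str] = {}
    for sp, gmap in sorted(by_species.items()):
        if any(g not in gmap for g in genes):
            warnings.warn(f"species {sp} missing requested genes; dropped")
            continue
        parts = []
        for g in genes:
            seq = gmap[g].nt_seq if unit == "nt" else gmap[g].aa_seq
            parts.append(seq)
        rows[sp] = "".join(parts)
    if not rows:
        raise ValueError("no species retained the full gene subset")
    first_sp = next(iter(rows))
    gmap0 = by_species[first_sp]
    partitions = []
    pos = 1
    for g in genes:
        seq = gmap0[g].nt_seq if unit == "nt" else gmap0[g].aa_seq
        partitions.append((g, pos, pos + len(seq) - 1))
        pos += len(seq)
    if any(len(s) != pos - 1 for s in rows.values()):
        warnings.warn("gene lengths differ across species; partition ranges "
                      "follow the first retained species (align before use)")
    if fasta_path is not None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=sp, description="") for sp, s in rows.items()],
            str(fasta_path), "fasta",
        )
    if partition_path is not None:
        kind = "DNA" if unit == "nt" else "PROT"
        Path(partition_path).write_text(
            "".join(f"{kind}, {g} = {a}-{b}\n" for g, a, b in partitions)
        )
    return rows, partitions
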