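"""Seeded simulation of mitogenomes and NUMT-bearing nuclear chromosomes.

The generator produces the study conditions end to end: a 13-PCG mitogenome
valid under the invertebrate mitochondrial code; nuclear chromosomes of
AT-rich background sequence (default GC 35%, beetle-like); NUMT insertions
descending from one or more mitochondrial lineages, with controllable
codon-position-specific substitution rates (a third-position rate
multiplier emulates divergence along a functional mitochondrial lineage),
indel rates, family duplication, and optional engineering to a target ORF
class (C1-C5); plus a complete ground-truth table so every pipeline stage
can be scored against what was implanted.

All randomness flows through one ``numpy`` generator derived from the
config seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CANONICAL_GENES, PcgRecord
from .discovery import ChromosomeMeta
from .genetic_code import TABLE5, GeneticCode, reverse_complement

#: Default per-gene codon counts (coding codons + stop), chosen near typical
#: chrysomelid beetle mitogenome gene lengths (e.g. COX3 789 bp = 263
#: codons, ATP8 156 bp = 52, ND5 1716 bp = 572).
DEFAULT_GENE_CODONS: dict[str, int] = {
    "ND2": 341, "COX1": 512, "COX2": 229, "ATP8": 52, "ATP6": 225,
    "COX3": 263, "ND3": 117, "ND5": 572, "ND4": 446, "ND4L": 98,
    "ND6": 165, "CYTB": 380, "ND1": 316,
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(list("ACGT"))


@dataclass
class EventSpec:
    """One nuclear integration event and its NUMT family."""

    gene: str
    lineage: str = "contemporary"  # or "diverged"
    divergence: float = 0.0  # mean per-site substitution probability
    third_multiplier: float = 1.0  # rate multiplier at codon position 3
    copies: int = 1
    within_family_divergence: float = 0.0  # neutral, uniform across positions
    indel_rate: float = 0.0
    target_class: str | None = None  # C1..C5 engineering, applied per copy
    chrom: str | None = None  # placement restricted to this chromosome
    truncate_to: int | None = None  # keep only the first N nt of the gene

    def __post_init__(self):
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if self.third_multiplier <= 0:
            raise ValueError("third_multiplier must be positive")


@dataclass
class SimulationConfig:
    seed: int = 0
    species_id: str = "sim"
    gene_codons: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_CODONS))
    chromosomes: list[tuple[str, int, str]] = field(default_factory=lambda: [
        ("chr1", 400_000, "autosome"),
        ("chr2", 300_000, "autosome"),
        ("chr3", 250_000, "autosome"),
        ("chrX", 200_000, "X"),
    ])
    events: list[EventSpec] = field(default_factory=list)
    kappa: float = 2.0  # transition/transversion rate ratio
    gc_content: float = 0.35
    intergenic_nt: int = 30


@dataclass
class MitoGenome:
    seq: str
    records: list[PcgRecord]

    @property
    def pcg_seqs(self) -> dict[str, str]:
        return {r.gene: r.nt_seq for r in self.records}

    @property
    def pcg_offsets(self) -> dict[str, tuple[int, int, str]]:
        return {r.gene: (r.start, r.end, r.strand) for r in self.records}


# ---------------------------------------------------------------------------
# mitogenome construction

def _random_codon(rng: np.random.Generator, code: GeneticCode) -> str:
    while True:
        codon = "".join(rng.choice(_BASES, 3))
        if not code.is_stop(codon):
            return codon


def simulate_gene(rng: np.random.Generator, n_codons: int,
                  code: GeneticCode = TABLE5) -> str:
    """One valid PCG: start codon, stop-free body, TAA/TAG terminus."""
    if n_codons < 3:
        raise ValueError("gene needs at least 3 codons")
    start = str(rng.choice(sorted(code.start_codons)))
    body = "".join(_random_codon(rng, code) for _ in range(n_codons - 2))
    stop = str(rng.choice(["TAA", "TAA", "TAG"]))  # TAA twice as common
    return start + body + stop


def simulate_mitogenome(config: SimulationConfig,
                        code: GeneticCode = TABLE5) -> MitoGenome:
    """Assemble 13 valid PCGs into a mitogenome, genes on both strands."""
    rng = np.random.default_rng(config.seed)
    missing = [g for g in config.gene_codons if g not in CANONICAL_GENES]
    if missing:
        raise ValueError(f"unknown genes in spec: {missing}")
    # minus-strand genes follow the typical insect arrangement
    minus = {"ND5", "ND4", "ND4L", "ND1"}
    parts: list[str] = []
    records: list[PcgRecord] = []
    pos = 0
    for gene in CANONICAL_GENES:
        n = config.gene_codons.get(gene)
        if n is None:
            continue
        spacer = "".join(rng.choice(_BASES, config.intergenic_nt))
        parts.append(spacer)
        pos += len(spacer)
        gene_seq = simulate_gene(rng, n, code)
        strand = "-" if gene in minus else "+"
        genomic = gene_seq if strand == "+" else reverse_complement(gene_seq)
        parts.append(genomic)
        records.append(PcgRecord(gene=gene, species_id=config.species_id,
                                 start=pos, end=pos + len(genomic),
                                 strand=strand, nt_seq=gene_seq, code=code))
        pos += len(genomic)
    parts.append("".join(rng.choice(_BASES, config.intergenic_nt)))
    return MitoGenome(seq="".join(parts), records=records)


# ---------------------------------------------------------------------------
# sequence evolution

@dataclass
class MutationLogEntry:
    position: int
    codon_position: int  # 1, 2 or 3
    old: str
    new: str


def mutate_sequence(
    seq: str,
    rates: tuple[float, float, float],
    kappa: float = 2.0,
    rng: np.random.Generator | int | None = None,
    code: GeneticCode = TABLE5,
    avoid_stops: bool = True,
    protect: tuple[int, int] = (0, 0),
) -> tuple[str, list[MutationLogEntry]]:
    """Substitute bases at codon-position-specific rates.

    Each site mutates independently with probability ``rates[k]`` for codon
    position k; the replacement is a transition with probability
    kappa/(kappa+2) (Kimura two-parameter scheme), else one of the two
    transversions.  With ``avoid_stops`` the substitution is resampled
    (bounded retries) whenever it would create an in-frame stop codon, and
    ``protect`` shields the first/last given number of bases (start/stop
    codons) from mutation.  The log records every realized change.
    """
    if any(not 0 <= r <= 1 for r in rates):
        raise ValueError("rates must lie in [0, 1]")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    arr = np.array(list(seq))
    n = len(seq)
    pos_class = np.arange(n) % 3
    site_rates = np.array(rates)[pos_class]
    hit = rng.random(n) < site_rates
    lo, hi = protect
    if lo:
        hit[:lo] = False
    if hi:
        hit[n - hi :] = False
    log: list[MutationLogEntry] = []
    p_ts = kappa / (kappa + 2.0)
    for i in np.flatnonzero(hit):
        old = arr[i]
        for _ in range(20):
            if rng.random() < p_ts:
                new = _TRANSITION[old]
            else:
                choices = [b for b in "ACGT" if b != old and b != _TRANSITION[old]]
                new = choices[int(rng.integers(2))]
            if not avoid_stops:
                break
            cstart = 3 * (i // 3)
            codon = "".join(arr[cstart : cstart + 3])
            trial = codon[: i % 3] + new + codon[i % 3 + 1 :]
            if not code.is_stop(trial):
                break
        else:
            continue
        cstart = 3 * (i // 3)
        codon = "".join(arr[cstart : cstart + 3])
        trial = codon[: i % 3] + new + codon[i % 3 + 1 :]
        if avoid_stops and code.is_stop(trial):
            continue
        arr[i] = new
        log.append(MutationLogEntry(position=int(i), codon_position=int(i % 3 + 1),
                                    old=str(old), new=str(new)))
    return "".join(arr), log


def _synonymous_substitution(codon: str, rng: np.random.Generator,
                             code: GeneticCode) -> str | None:
    aa = code.translate_codon(codon)
    options = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if code.translate_codon(mut) == aa and not code.is_stop(mut):
                options.append(mut)
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def degrade_to_class(
    seq: str,
    target: str,
    code: GeneticCode = TABLE5,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Engineer a copy of a valid PCG that classifies as the target class.

    C1: a few synonymous substitutions only.  C2: in-frame deletion of three
    or more codons.  C3: one engineered in-frame internal stop.  C4:
    in-frame deletion/insertion of 1-2 codons away from the termini.  C5:
    start (or stop) codon ablated, length preserved.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n_codons = len(seq) // 3
    if len(seq) % 3 or n_codons < 8:
        raise ValueError("need a valid PCG of at least 8 codons")
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]

    def some_syn_subs(codons, k=2):
        idxs = rng.choice(np.arange(1, n_codons - 1), size=min(k, n_codons - 2),
                          replace=False)
        for i in idxs:
            mut = _synonymous_substitution(codons[i], rng, code)
            if mut is not None:
                codons[i] = mut
        return codons

    if target == "C1":
        codons = some_syn_subs(codons)
        return "".join(codons)
    if target == "C2":
        k = 3 + int(rng.integers(3))  # delete 3-5 codons
        start = 1 + int(rng.integers(n_codons - 1 - k - 1))
        del codons[start : start + k]
        return "".join(codons)
    if target == "C3":
        i = 2 + int(rng.integers(n_codons - 4))
        codons[i] = "TAA" if rng.random() < 0.5 else "TAG"
        return "".join(codons)
    if target == "C4":
        k = 1 + int(rng.integers(2))  # 1 or 2 codons
        if rng.random() < 0.5:
            start = 1 + int(rng.integers(n_codons - 2 - k))
            del codons[start : start + k]
        else:
            at = 1 + int(rng.integers(n_codons - 2))
            ins = []
            for _ in range(k):
                c = _random_nonstop(rng, code)
                ins.append(c)
            codons[at:at] = ins
        return "".join(codons)
    if target == "C5":
        # ablate the start codon; keep length and frame
        first = codons[0]
        for b in "CCG":
            trial = b + first[1:]
            if not code.is_start(trial) and not code.is_stop(trial):
                codons[0] = trial
                break
        else:
            codons[0] = "CCC"
        return "".join(codons)
    raise ValueError(f"unknown target class {target!r}")


def _random_nonstop(rng: np.random.Generator, code: GeneticCode) -> str:
    while True:
        c = "".join(_BASES[rng.integers(4, size=3)])
        if not code.is_stop(c):
            return c


def apply_indels(seq: str, rate: float, rng: np.random.Generator,
                 frame_preserving: bool = True) -> str:
    """Sprinkle indels (geometric length, p = 0.5) along the sequence."""
    out = []
    i = 0
    while i < len(seq):
        if rng.random() < rate and 3 < i < len(seq) - 6:
            length = int(rng.geometric(0.5))
            if frame_preserving:
                length *= 3
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            out.append("".join(_BASES[rng.integers(4, size=length)]))
        out.append(seq[i])
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# implanting

def _lineage_rates(d: float, m: float) -> tuple[float, float, float]:
    """Per-position rates with mean d and third-position multiplier m."""
    base = 3.0 * d / (2.0 + m)
    return (base, base, min(0.95, m * base))


def implant_numts(
    config: SimulationConfig,
    mito: MitoGenome,
    code: GeneticCode = TABLE5,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, ChromosomeMeta]]:
    """Build nuclear chromosomes with implanted NUMTs and the truth table.

    For each event the source gene is first evolved along its mitochondrial
    lineage (divergence with third-position excess for "diverged" lineages;
    none for "contemporary"), then the family copies are derived from that
    founder with neutral (uniform-rate) within-family divergence, optional
    indels and optional class engineering, and implanted at uniformly drawn
    non-overlapping positions on randomly chosen strands.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    pcgs = mito.pcg_seqs
    meta = {name: ChromosomeMeta(name, length, cat)
            for name, length, cat in config.chromosomes}
    p_gc = config.gc_content
    probs = np.array([(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2])
    chrom_arrays = {
        name: rng.choice(_BASES, size=length, p=probs)
        for name, length, _ in config.chromosomes
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in chrom_arrays}
    truth_rows = []
    numt_idx = 0
    for event_id, ev in enumerate(config.events):
        if ev.gene not in pcgs:
            raise ValueError(f"event {event_id}: unknown gene {ev.gene}")
        founder = pcgs[ev.gene]
        if ev.lineage == "diverged":
            rates = _lineage_rates(ev.divergence, ev.third_multiplier)
            founder, _ = mutate_sequence(founder, rates, kappa=config.kappa,
                                         rng=rng, code=code, protect=(3, 3))
        elif ev.lineage != "contemporary":
            raise ValueError(f"unknown lineage {ev.lineage!r}")
        for copy in range(ev.copies):
            numt = founder
            if ev.within_family_divergence > 0:
                r = ev.within_family_divergence
                numt, _ = mutate_sequence(numt, (r, r, r), kappa=config.kappa,
                                          rng=rng, code=code, protect=(3, 3))
            if ev.indel_rate > 0:
                numt = apply_indels(numt, ev.indel_rate, rng)
            if ev.target_class is not None:
                numt = degrade_to_class(numt, ev.target_class, code, rng)
            if ev.truncate_to is not None:
                numt = numt[: ev.truncate_to]
            # placement
            chroms = [ev.chrom] if ev.chrom else list(chrom_arrays)
            placed = False
            for _ in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                arr = chrom_arrays[chrom]
                if len(arr) <= len(numt) + 2:
                    continue
                start = int(rng.integers(len(arr) - len(numt)))
                end = start + len(numt)
                if any(not (end <= a or start >= b) for a, b in occupied[chrom]):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                insert = numt if strand == "+" else reverse_complement(numt)
                arr[start:end] = list(insert)
                occupied[chrom].append((start, end))
                truth_rows.append({
                    "numt_id": f"numt{numt_idx:04d}", "event_id": event_id,
                    "gene": ev.gene, "lineage": ev.lineage,
                    "chrom": chrom, "start": start, "end": end,
                    "strand": strand, "true_class": ev.target_class,
                    "divergence": ev.divergence, "copy": copy,
                    "seq": numt,
                })
                numt_idx += 1
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"event {event_id} copy {copy}: placement collision persists")
    nuclear = {name: "".join(arr) for name, arr in chrom_arrays.items()}
    truth = pd.DataFrame(truth_rows)
    return nuclear, truth, meta


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
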