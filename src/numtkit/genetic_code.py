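"""Invertebrate mitochondrial genetic code (NCBI translation table 5).

Mitochondrial protein-coding genes of insects are translated with table 5,
under which AGA/AGG encode serine (not arginine/stop as in the standard code)
and ATA encodes methionine.  Insect mitogenomes additionally use a wider set
of initiation codons (ATN, TTG, GTG) and truncated stop codons (a terminal T
or TA completed to TAA by polyadenylation of the transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

#: Start codons commonly observed in insect mitochondrial PCGs.  Rarer codons
#: (e.g. ACC for COX1 in some beetles) are flagged by validation rather than
#: rejected; pass a custom set to :class:`GeneticCode` to accept them.
DEFAULT_START_CODONS = frozenset({"ATG", "ATA", "ATT", "ATC", "TTG", "GTG"})

#: Complete stop codons of translation table 5.
STOP_CODONS = frozenset({"TAA", "TAG"})

#: Truncated stops accepted at an annotated gene terminus only.
INCOMPLETE_STOPS = frozenset({"T", "TA"})

_BASES = "ACGT"


def _build_codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    mapping[codon] = "*"
                else:
                    mapping[codon] = table.forward_table[codon]
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus start/stop codon conventions.

    Parameters
    ----------
    table_id:
        NCBI translation table number.  Defaults to 5, the invertebrate
        mitochondrial code.
    start_codons:
        Trinucleotides accepted as initiation codons.
    """

    table_id: int = 5
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    stop_codons: frozenset[str] = STOP_CODONS
    incomplete_stops: frozenset[str] = INCOMPLETE_STOPS
    codon_to_aa: dict[str, str] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.codon_to_aa is None:
            object.__setattr__(self, "codon_to_aa", _build_codon_map(self.table_id))
        if len(self.codon_to_aa) != 64:
            raise ValueError("codon table must contain exactly 64 entries")

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; codons containing N (or any ambiguity) give X."""
        codon = codon.upper()
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        return "X"

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon.upper() in self.start_codons


#: Module-level default instance (table 5, default start set).
TABLE5 = GeneticCode()


def translate(nt_seq: str, code: GeneticCode = TABLE5, frame: int = 0) -> str:
    """Translate ``nt_seq`` in the given frame, marking stops with ``*``.

    Trailing bases that do not fill a codon are ignored; codons containing
    N translate to X.  An empty sequence gives an empty string.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = nt_seq.upper()
    n_codons = max(0, (len(seq) - frame) // 3)
    return "".join(
        code.translate_codon(seq[frame + 3 * i : frame + 3 * i + 3]) for i in range(n_codons)
    )


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]
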