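"""Codon-position substitution analysis, integration events and dN/dS.

The central idea: a NUMT evolves neutrally in the nucleus, so differences
between two sequences that share a single nuclear history accumulate at
roughly equal rates at the three codon positions.  Differences inherited
from divergent *mitochondrial* histories instead carry the functional
signature of protein-coding evolution - a strong excess at the third codon
position.  For each sequence pair we therefore

1. build a gapless in-frame "virtual" coding sequence by projecting out
   frame-shifting indel columns of the pairwise alignment,
2. count mismatches at codon positions 1/2/3 and test uniformity with a
   chi-square test (df = 2),
3. call the pair "independent integration events" only when uniformity is
   rejected AND the third position carries the excess (the directional
   check guards against rejections driven by first/second-position noise).

Clustering the pairwise same-event decisions (single-linkage connected
components) partitions a species' NUMTs into inferred nuclear integration
events.  A pairwise Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction
is provided as a selection-pressure diagnostic, and alignments can be
exported in PHYLIP/Newick form (stop codons gapped, branch labels attached)
for branch-model likelihood analysis in external tools.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .classification import PairAlignment, _gap_runs, align_pair
from .genetic_code import TABLE5, GeneticCode


class DegeneratePairError(ValueError):
    pass


@dataclass
class VirtualCds:
    """Gapless, in-frame pair of equal-length coding sequences."""

    seq1: str
    seq2: str
    id1: str = "seq1"
    id2: str = "seq2"
    removed_column_count: int = 0

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2):
            raise ValueError("virtual CDS rows differ in length")
        if len(self.seq1) % 3 != 0:
            raise ValueError("virtual CDS length must be a multiple of 3")
        if "-" in self.seq1 or "-" in self.seq2:
            raise ValueError("virtual CDS must be gapless")

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3


def _clean_codon_map(pcg_row: str, other_row: str) -> dict[int, str]:
    """Project ``other_row`` onto the PCG codon grid, dropping dirty codons.

    A PCG codon is dirty when any of its three columns carries a gap in
    either row.  Insertion columns (gaps in the PCG row) are always removed;
    a frame-shifting insertion run (length not a multiple of 3) additionally
    dirties its host codon.  Returns codon index -> other-row codon triple.
    """
    dirty: set[int] = set()
    pcg_pos = 0
    triples: dict[int, list[str]] = {}
    ins_runs = _gap_runs(pcg_row)
    for a, b in ins_runs:
        if (b - a) % 3 != 0:
            # host codon = codon containing the insertion point, when the
            # insertion interrupts a codon's interior
            pcg_before = sum(1 for ch in pcg_row[:a] if ch != "-")
            if pcg_before % 3 != 0:
                dirty.add(pcg_before // 3)
    for col, (p, o) in enumerate(zip(pcg_row, other_row)):
        if p == "-":
            continue
        codon_idx = pcg_pos // 3
        triples.setdefault(codon_idx, []).append(o)
        if o == "-":
            dirty.add(codon_idx)
        pcg_pos += 1
    out = {}
    for idx, bases in triples.items():
        if idx in dirty or len(bases) != 3:
            continue
        out[idx] = "".join(bases)
    return out


def build_virtual_cds(alignment: PairAlignment, id1: str = "pcg",
                      id2: str = "numt") -> VirtualCds:
    """Reduce a pairwise alignment to a gapless in-frame sequence pair.

    Codon columns are labeled by the PCG row (row 1); any codon touched by a
    gap in either row is removed whole, which excises in-frame indels as
    complete codons and restores the frame around frame-shifting indels.
    """
    pcg_row = alignment.pcg_aln
    other = alignment.numt_aln
    keep = _clean_codon_map(pcg_row, other)
    pcg_seq = pcg_row.replace("-", "")
    pcg_codons = {i: pcg_seq[3 * i : 3 * i + 3]
                  for i in range(len(pcg_seq) // 3)}
    idxs = sorted(i for i in keep if i in pcg_codons)
    s1 = "".join(pcg_codons[i] for i in idxs)
    s2 = "".join(keep[i] for i in idxs)
    if not s1:
        raise DegeneratePairError("no intact codon columns remain")
    removed = len(pcg_row) - len(s1)
    return VirtualCds(seq1=s1, seq2=s2, id1=id1, id2=id2,
                      removed_column_count=removed)


# ---------------------------------------------------------------------------
# codon-position mutation counting

@dataclass
class CodonMutationProfile:
    n1: int
    n2: int
    n3: int
    chi2: float | None
    p_value: float | None
    df: int = 2
    low_power: bool = False
    id1: str = "seq1"
    id2: str = "seq2"

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def third_position_excess(self) -> bool:
        return self.n3 > self.n1 and self.n3 > self.n2


def profile_from_counts(n1: int, n2: int, n3: int, **kw) -> CodonMutationProfile:
    """Chi-square uniformity test (df = 2) on given position counts."""
    total = n1 + n2 + n3
    if total == 0:
        return CodonMutationProfile(n1, n2, n3, chi2=None, p_value=None, **kw)
    res = sps.chisquare([n1, n2, n3])
    return CodonMutationProfile(n1, n2, n3, chi2=float(res.statistic),
                                p_value=float(res.pvalue), **kw)


def count_codon_mutations(vcds: VirtualCds, min_total: int = 10) -> CodonMutationProfile:
    """Count mismatching columns at each codon position and test uniformity.

    Columns where either sequence carries an ambiguity (N) are excluded.
    A profile with total mutations below ``min_total`` is flagged low-power:
    the chi-square call is still made, but the independence decision based
    on it deserves caution.
    """
    a = np.frombuffer(vcds.seq1.encode(), dtype="S1")
    b = np.frombuffer(vcds.seq2.encode(), dtype="S1")
    valid = (a != b"N") & (b != b"N")
    diff = (a != b) & valid
    pos = np.arange(a.size) % 3
    n1 = int(np.sum(diff & (pos == 0)))
    n2 = int(np.sum(diff & (pos == 1)))
    n3 = int(np.sum(diff & (pos == 2)))
    prof = profile_from_counts(n1, n2, n3, id1=vcds.id1, id2=vcds.id2)
    prof.low_power = prof.total < min_total
    return prof


def decide_same_event(profile: CodonMutationProfile, alpha: float = 0.05) -> bool:
    """True when the pair is consistent with a single integration event.

    The pair is called *independent* only when the uniformity test rejects
    (p < alpha) and the excess sits at the third codon position; identical
    pairs (no mutations) are same-event by definition.
    """
    if profile.p_value is None:
        return True
    independent = profile.p_value < alpha and profile.third_position_excess
    return not independent


# ---------------------------------------------------------------------------
# integration events

@dataclass
class IntegrationEventSet:
    species_id: str
    gene: str
    clusters: list[list[str]]
    pair_decisions: dict[tuple[str, str], bool]  # True = same event
    profiles: dict[tuple[str, str], CodonMutationProfile]
    contemporary_lineage: dict[str, bool] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.clusters)

    def to_report(self) -> dict:
        return {
            "species_id": self.species_id,
            "gene": self.gene,
            "n_numts": sum(len(c) for c in self.clusters),
            "n_events": self.n_events,
            "clusters": [sorted(c) for c in self.clusters],
            "contemporary_lineage": self.contemporary_lineage,
            "pairs": [
                {"id1": k[0], "id2": k[1], "n1": p.n1, "n2": p.n2, "n3": p.n3,
                 "chi2": p.chi2, "p": p.p_value,
                 "third_position_excess": p.third_position_excess,
                 "same_event": self.pair_decisions[k], "low_power": p.low_power}
                for k, p in sorted(self.profiles.items())
            ],
        }


def estimate_integration_events(
    numts: dict[str, str],
    pcg_seq: str,
    species_id: str = "",
    gene: str = "",
    alpha: float = 0.05,
    min_total: int = 10,
) -> IntegrationEventSet:
    """Partition a species' NUMTs (one gene) into inferred integration events.

    Each NUMT is aligned to the contemporary PCG once; pairwise NUMT-NUMT
    virtual CDSs are then formed on the shared intact PCG codon grid.  An
    edge joins two NUMTs when the pairwise decision is "same event"; events
    are the connected components (single linkage - conservative, merging on
    any evidence of shared history).  NUMTs whose profile against the
    contemporary PCG shows no independence signal are annotated as
    contemporary-lineage integrations.
    """
    ids = sorted(numts)
    if not ids:
        raise ValueError("no NUMTs supplied")
    codon_maps: dict[str, dict[int, str]] = {}
    contemporary: dict[str, bool] = {}
    for nid in ids:
        aln = align_pair(pcg_seq, numts[nid])
        codon_maps[nid] = _clean_codon_map(aln.pcg_aln, aln.numt_aln)
        vc = build_virtual_cds(aln, id1=gene or "PCG", id2=nid)
        prof = count_codon_mutations(vc, min_total=min_total)
        contemporary[nid] = decide_same_event(prof, alpha)

    profiles: dict[tuple[str, str], CodonMutationProfile] = {}
    decisions: dict[tuple[str, str], bool] = {}
    parent = {nid: nid for nid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(ids, 2):
        shared = sorted(set(codon_maps[i]) & set(codon_maps[j]))
        if not shared:
            raise DegeneratePairError(f"{i} vs {j}: no shared intact codons")
        s1 = "".join(codon_maps[i][k] for k in shared)
        s2 = "".join(codon_maps[j][k] for k in shared)
        vc = VirtualCds(seq1=s1, seq2=s2, id1=i, id2=j)
        prof = count_codon_mutations(vc, min_total=min_total)
        same = decide_same_event(prof, alpha)
        profiles[(i, j)] = prof
        decisions[(i, j)] = same
        if same:
            parent[find(i)] = find(j)

    comp: dict[str, list[str]] = {}
    for nid in ids:
        comp.setdefault(find(nid), []).append(nid)
    clusters = sorted((sorted(c) for c in comp.values()), key=lambda c: c[0])
    return IntegrationEventSet(species_id=species_id, gene=gene,
                               clusters=clusters, pair_decisions=decisions,
                               profiles=profiles,
                               contemporary_lineage=contemporary)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pairwise dN/dS

@dataclass
class DnDsResult:
    dN: float
    dS: float
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    omega: float | None
    method: str = "NG86+JC"


def _syn_fraction(codon: str, code: GeneticCode) -> list[float]:
    """Fraction of the three possible changes at each position that are
    synonymous.  Changes to stop codons count as non-synonymous."""
    aa = code.translate_codon(codon)
    fracs = []
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if code.translate_codon(mut) == aa and not code.is_stop(mut):
                syn += 1
        fracs.append(syn / 3.0)
    return fracs


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts for one codon pair,
    averaged over all mutational pathways that avoid stop codons."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    sd_tot, nd_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diffs):
        cur = c1
        sd, nd = 0.0, 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.translate_codon(cur) == code.translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            sd_tot += sd
            nd_tot += nd
            n_paths += 1
    if n_paths == 0:
        # all pathways pass through a stop; fall back to counting every
        # difference as non-synonymous
        return 0.0, float(len(diffs))
    return sd_tot / n_paths, nd_tot / n_paths


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise DegeneratePairError(f"proportion {p:.3f} too large for Jukes-Cantor correction")
    return abs(-0.75 * math.log(1 - 4.0 * p / 3.0))


def ng86_dnds(vcds: VirtualCds, code: GeneticCode = TABLE5) -> DnDsResult:
    """Pairwise dN/dS by the Nei-Gojobori (1986) counting method.

    Site counts are fractional per codon position (averaged over the two
    sequences); multi-hit codons average synonymous/non-synonymous counts
    over all stop-avoiding mutational pathways; the Jukes-Cantor formula
    corrects both proportions for multiple hits.  Codons containing a stop
    or an ambiguity in either sequence are masked out first.  ``omega`` is
    None when dS = 0.
    """
    N = S = Nd = Sd = 0.0
    used = 0
    for i in range(vcds.n_codons):
        c1 = vcds.seq1[3 * i : 3 * i + 3]
        c2 = vcds.seq2[3 * i : 3 * i + 3]
        if "N" in c1 or "N" in c2 or code.is_stop(c1) or code.is_stop(c2):
            continue
        used += 1
        f1, f2 = _syn_fraction(c1, code), _syn_fraction(c2, code)
        s_codon = sum((a + b) / 2 for a, b in zip(f1, f2))
        S += s_codon
        N += 3 - s_codon
        sd, nd = _pathway_counts(c1, c2, code)
        Sd += sd
        Nd += nd
    if used == 0:
        raise DegeneratePairError("all codons masked; cannot compute dN/dS")
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dN = _jc_correct(pN)
    dS = _jc_correct(pS)
    omega = dN / dS if dS > 0 else None
    return DnDsResult(dN=dN, dS=dS, N_sites=N, S_sites=S, Nd=Nd, Sd=Sd, omega=omega)


# ---------------------------------------------------------------------------
# CODEML input export

def mask_stops_as_gaps(seq: str, code: GeneticCode = TABLE5) -> str:
    """Replace every in-frame stop codon with '---' (CODEML convention)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("---" if code.is_stop(codon) else codon)
    out.append(seq[len(seq) - len(seq) % 3 :])
    return "".join(out)


def write_phylip(seqs: dict[str, str], path: str | Path) -> None:
    """Sequential PHYLIP (relaxed names) writer."""
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    (length,) = lengths
    with open(path, "w") as fh:
        fh.write(f" {len(seqs)} {length}\n")
        for name, s in seqs.items():
            fh.write(f"{name}  {s}\n")


def read_phylip(path: str | Path) -> dict[str, str]:
    lines = Path(path).read_text().splitlines()
    n, length = (int(x) for x in lines[0].split())
    out = {}
    for line in lines[1 : n + 1]:
        name, seq = line.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != length:
            raise ValueError(f"{name}: sequence length {len(seq)} != header {length}")
        out[name] = seq
    return out


def label_tree(newick: str, branch_classes: dict[str, int]) -> str:
    """Attach CODEML branch labels (#k) to taxa per a class map.

    Class 0 is the unlabeled background; taxa mapped to k > 0 get " #k"
    appended.  Every taxon in the tree must appear in the map.
    """
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    for leaf in tree.get_terminals():
        if leaf.name not in branch_classes:
            raise ValueError(f"taxon {leaf.name!r} missing from branch-class map")
        k = branch_classes[leaf.name]
        if k:
            leaf.name = f"{leaf.name} #{k}"
    out = io.StringIO()
    Phylo.write(tree, out, "newick", plain=True)
    return out.getvalue().strip()


CODEML_TEMPLATE = """\
seqfile = {seqfile}
treefile = {treefile}
outfile = mlc
noisy = 3
verbose = 1
runmode = 0
seqtype = 1
CodonFreq = 2
model = {model}
NSsites = 0
icode = 4
fix_kappa = 0
kappa = 2
fix_omega = 0
omega = 0.4
cleandata = 0
"""


def export_codeml_inputs(
    alignment: dict[str, str],
    newick: str,
    branch_classes: dict[str, int],
    out_dir: str | Path,
    code: GeneticCode = TABLE5,
) -> dict[str, Path]:
    """Write PHYLIP alignment (stops gapped), labeled Newick tree and a
    control-file template for branch-model dN/dS fitting in CODEML.

    ``model`` in the template is 0 (one ratio) when all branches share class
    0, else 2 (several ratios tied to the # labels).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masked = {k: mask_stops_as_gaps(v, code) for k, v in alignment.items()}
    phy = out_dir / "alignment.phy"
    write_phylip(masked, phy)
    tre = out_dir / "tree.nwk"
    tre.write_text(label_tree(newick, branch_classes) + "\n")
    n_classes = len({v for v in branch_classes.values() if v > 0})
    ctl = out_dir / "codeml.ctl"
    ctl.write_text(CODEML_TEMPLATE.format(
        seqfile=phy.name, treefile=tre.name, model=2 if n_classes else 0))
    return {"phylip": phy, "tree": tre, "ctl": ctl}
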