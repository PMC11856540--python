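"""Virtual CDS construction, codon-position chi-square, events, NG86 dN/dS."""

import itertools
import math

import numpy as np
import pytest

from numtkit.classification import PairAlignment, align_pair
from numtkit.codon import (
    DegeneratePairError,
    VirtualCds,
    build_virtual_cds,
    count_codon_mutations,
    decide_same_event,
    estimate_integration_events,
    export_codeml_inputs,
    label_tree,
    mask_stops_as_gaps,
    ng86_dnds,
    profile_from_counts,
    read_phylip,
    write_phylip,
)
from numtkit.genetic_code import TABLE5
from numtkit.simulate import (
    EventSpec,
    SimulationConfig,
    implant_numts,
    mutate_sequence,
    simulate_mitogenome,
)


class TestVirtualCds:
    def test_gapless_identity(self):
        aln = PairAlignment("ATGAAACCCTAA", "ATGAAACCGTAA", 0)
        vc = build_virtual_cds(aln)
        assert (vc.seq1, vc.seq2) == ("ATGAAACCCTAA", "ATGAAACCGTAA")
        assert vc.removed_column_count == 0

    def test_inframe_gap_removes_codon_triple(self):
        aln = PairAlignment("ATGAAACCCTAA", "ATG---CCCTAA", 0)
        vc = build_virtual_cds(aln)
        assert (vc.seq1, vc.seq2) == ("ATGCCCTAA", "ATGCCCTAA")

    def test_single_nt_gap_drops_containing_codon(self):
        """A 1-nt deletion removes its whole host codon; length drops 3."""
        aln = align_pair("ATGAAACCCGGGTAA", "ATGAACCCGGGTAA")
        vc = build_virtual_cds(aln)
        assert len(vc.seq1) == 12
        assert vc.seq1 == vc.seq2

    def test_no_gap_columns_remain(self):
        rng = np.random.default_rng(0)
        m = simulate_mitogenome(SimulationConfig(seed=0))
        pcg = m.records[0].nt_seq
        from numtkit.simulate import apply_indels
        numt = apply_indels(pcg, 0.01, rng, frame_preserving=False)
        vc = build_virtual_cds(align_pair(pcg, numt))
        assert "-" not in vc.seq1 and "-" not in vc.seq2
        assert len(vc.seq1) % 3 == 0

    def test_frameshift_insertion_restores_frame(self):
        # 1-nt insertion inside the second codon
        aln = PairAlignment("ATGAA-ACCCTAA", "ATGAATACCCTAA", 0)
        vc = build_virtual_cds(aln)
        assert len(vc.seq1) % 3 == 0
        assert "-" not in vc.seq2
        # downstream codons still pair correctly
        assert vc.seq1.endswith("CCCTAA") and vc.seq2.endswith("CCCTAA")

    def test_degenerate_pair_raises(self):
        aln = PairAlignment("AT-", "-TA", 0)
        with pytest.raises((DegeneratePairError, ValueError)):
            build_virtual_cds(aln)


def _chi2_sf_oracle(x):
    """df=2 chi-square survival function has the closed form exp(-x/2)."""
    return math.exp(-x / 2.0)


class TestCodonMutationProfile:
    def test_worked_example_1_2_7(self):
        """Counts (1,2,7): chi2 = 6.2, p ~ 0.045 -> uniformity rejected with
        a third-position excess."""
        prof = profile_from_counts(1, 2, 7)
        assert prof.chi2 == pytest.approx(6.2)
        assert prof.p_value == pytest.approx(0.0450, abs=5e-4)
        assert prof.third_position_excess

    def test_uniform_counts(self):
        prof = profile_from_counts(3, 3, 3)
        assert prof.chi2 == 0.0 and prof.p_value == pytest.approx(1.0)
        assert not prof.third_position_excess

    def test_extreme_third_position(self):
        prof = profile_from_counts(0, 0, 12)
        assert prof.chi2 == pytest.approx(24.0)
        assert prof.p_value == pytest.approx(_chi2_sf_oracle(24.0), rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_survival_function_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2, n3 = (int(x) for x in rng.integers(0, 30, size=3))
        if n1 + n2 + n3 == 0:
            n3 = 1
        prof = profile_from_counts(n1, n2, n3)
        assert prof.p_value == pytest.approx(_chi2_sf_oracle(prof.chi2), rel=1e-9)

    def test_counts_from_engineered_mutations(self):
        """Third-position-only mutation yields n1 = n2 = 0 and counts that
        match the realized mutation log exactly."""
        m = simulate_mitogenome(SimulationConfig(seed=1))
        pcg = m.records[1].nt_seq
        mut, log = mutate_sequence(pcg, (0.0, 0.0, 0.3), rng=5)
        assert all(e.codon_position == 3 for e in log)
        vc = VirtualCds(pcg, mut)
        prof = count_codon_mutations(vc)
        assert (prof.n1, prof.n2) == (0, 0)
        assert prof.n3 == len(log)

    def test_identical_pair_flagged(self):
        vc = VirtualCds("ATGAAA", "ATGAAA")
        prof = count_codon_mutations(vc)
        assert prof.p_value is None and prof.total == 0

    def test_n_columns_excluded(self):
        # N at position 1 is excluded; the C at the second codon's first
        # position is the only counted difference
        vc = VirtualCds("ATGAAA", "NTGCAA")
        prof = count_codon_mutations(vc)
        assert (prof.n1, prof.n2, prof.n3) == (1, 0, 0)


class TestDecideSameEvent:
    def test_third_position_bias_means_independent(self):
        assert decide_same_event(profile_from_counts(1, 2, 7)) is False

    def test_first_position_bias_stays_same_event(self):
        """The directional check: significant non-uniformity at position 1
        does NOT signal independent mitochondrial histories."""
        prof = profile_from_counts(7, 2, 1)
        assert prof.p_value < 0.05
        assert decide_same_event(prof) is True

    def test_no_mutations_same_event(self):
        assert decide_same_event(profile_from_counts(0, 0, 0)) is True

    def test_symmetry(self):
        """The decision depends only on the unordered pair: swapping the
        sequences swaps nothing in the counts."""
        vc1 = VirtualCds("ATGAAACCC", "ATGAAGCCG")
        vc2 = VirtualCds("ATGAAGCCG", "ATGAAACCC")
        p1 = count_codon_mutations(vc1)
        p2 = count_codon_mutations(vc2)
        assert (p1.n1, p1.n2, p1.n3) == (p2.n1, p2.n2, p2.n3)
        assert decide_same_event(p1) == decide_same_event(p2)


class TestIntegrationEvents:
    def _pcg(self, seed=3, gene="COX1"):
        m = simulate_mitogenome(SimulationConfig(seed=seed))
        return next(r for r in m.records if r.gene == gene).nt_seq

    def test_identical_copies_one_event(self):
        pcg = self._pcg()
        ev = estimate_integration_events({"a": pcg, "b": pcg, "c": pcg}, pcg)
        assert ev.n_events == 1

    def test_single_numt_one_event(self):
        pcg = self._pcg()
        ev = estimate_integration_events({"only": pcg}, pcg)
        assert ev.n_events == 1 and ev.clusters == [["only"]]

    def test_two_lineages_recovered(self):
        """A contemporary family and a 10x-third-position diverged family
        separate into two events; the diverged one is flagged as not of
        contemporary-lineage origin."""
        pcg = self._pcg()
        div, _ = mutate_sequence(pcg, (0.012, 0.012, 0.12), rng=11,
                                 protect=(3, 3))
        numts = {"c1": pcg, "c2": pcg, "d1": div, "d2": div}
        ev = estimate_integration_events(numts, pcg, gene="COX1")
        assert ev.n_events == 2
        assert sorted(map(sorted, ev.clusters)) == [["c1", "c2"], ["d1", "d2"]]
        assert ev.contemporary_lineage["c1"] is True
        assert ev.contemporary_lineage["d1"] is False

    def test_pair_decision_symmetric_in_matrix(self):
        pcg = self._pcg()
        div, _ = mutate_sequence(pcg, (0.01, 0.01, 0.1), rng=7, protect=(3, 3))
        ev = estimate_integration_events({"a": pcg, "b": div}, pcg)
        assert set(ev.pair_decisions) == {("a", "b")}

    def test_low_power_flag(self):
        pcg = self._pcg(gene="ATP8")
        mut, log = mutate_sequence(pcg, (0.01, 0.01, 0.01), rng=2, protect=(3, 3))
        ev = estimate_integration_events({"a": pcg, "b": mut}, pcg, min_total=10)
        prof = ev.profiles[("a", "b")]
        if prof.total < 10:
            assert prof.low_power


def _ng86_oracle(s1, s2, code=TABLE5):
    """Independent brute-force NG86: explicit site fractions and explicit
    pathway enumeration per codon, then Jukes-Cantor."""
    def syn_sites(codon):
        aa = code.translate_codon(codon)
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                m = codon[:pos] + b + codon[pos + 1:]
                if not code.is_stop(m) and code.translate_codon(m) == aa:
                    s += 1 / 3
        return s

    N = S = Nd = Sd = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if code.is_stop(c1) or code.is_stop(c2) or "N" in c1 + c2:
            continue
        sc = (syn_sites(c1) + syn_sites(c2)) / 2
        S += sc
        N += 3 - sc
        diffs = [k for k in range(3) if c1[k] != c2[k]]
        if not diffs:
            continue
        paths = []
        for order in itertools.permutations(diffs):
            cur, sd, nd, ok = c1, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if code.is_stop(nxt):
                    ok = False
                    break
                if code.translate_codon(nxt) == code.translate_codon(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((sd, nd))
        if paths:
            Sd += sum(p[0] for p in paths) / len(paths)
            Nd += sum(p[1] for p in paths) / len(paths)
        else:
            Nd += len(diffs)
    pS, pN = Sd / S, Nd / N
    dS = abs(-0.75 * math.log(1 - 4 * pS / 3))
    dN = abs(-0.75 * math.log(1 - 4 * pN / 3))
    return dN, dS


class TestNg86:
    def test_identical_sequences(self):
        vc = VirtualCds("ATGAAACCC", "ATGAAACCC")
        r = ng86_dnds(vc)
        assert r.dN == 0.0 and r.dS == 0.0 and r.omega is None

    def test_single_synonymous_change(self):
        r = ng86_dnds(VirtualCds("TTAGCT", "TTGGCT"))
        assert r.dN == 0.0 and r.dS > 0 and r.omega == 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        m = simulate_mitogenome(SimulationConfig(seed=4))
        pcg = m.records[2].nt_seq
        mut, _ = mutate_sequence(pcg, (0.05, 0.05, 0.05), rng=1, protect=(3, 3))
        vc = VirtualCds(pcg, mut)
        r = ng86_dnds(vc)
        n_counted = sum(
            1 for i in range(vc.n_codons)
            if not TABLE5.is_stop(vc.seq1[3 * i:3 * i + 3])
            and not TABLE5.is_stop(vc.seq2[3 * i:3 * i + 3]))
        assert r.N_sites + r.S_sites == pytest.approx(3 * n_counted)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        """50-codon random pairs: dN and dS match pathway enumeration to
        1e-9."""
        rng = np.random.default_rng(seed)
        m = simulate_mitogenome(SimulationConfig(seed=seed))
        pcg = m.records[seed % 13].nt_seq[:150]
        mut, _ = mutate_sequence(pcg, (0.06, 0.06, 0.06),
                                 rng=rng, avoid_stops=True)
        vc = VirtualCds(pcg, mut)
        r = ng86_dnds(vc)
        dn_o, ds_o = _ng86_oracle(vc.seq1, vc.seq2)
        assert r.dN == pytest.approx(dn_o, abs=1e-9)
        assert r.dS == pytest.approx(ds_o, abs=1e-9)

    def test_synonymous_only_evolution_gives_omega_zero(self):
        from numtkit.simulate import _synonymous_substitution

        rng = np.random.default_rng(9)
        m = simulate_mitogenome(SimulationConfig(seed=9))
        pcg = m.records[5].nt_seq
        codons = [pcg[i:i + 3] for i in range(0, len(pcg), 3)]
        for k in rng.choice(len(codons) - 2, size=15, replace=False):
            s = _synonymous_substitution(codons[k + 1], rng, TABLE5)
            if s:
                codons[k + 1] = s
        mut = "".join(codons)
        r = ng86_dnds(VirtualCds(pcg, mut))
        assert r.dN == 0.0 and r.omega == 0.0

    def test_neutral_omega_near_one(self):
        """Uniform-rate mutation is selectively neutral, so omega centers
        near 1 (median over 40 seeded 500-codon pairs within [0.8, 1.25])."""
        m = simulate_mitogenome(SimulationConfig(seed=13))
        pcg = next(r for r in m.records if r.gene == "ND5").nt_seq[:1500]
        omegas = []
        for seed in range(40):
            mut, _ = mutate_sequence(pcg, (0.04, 0.04, 0.04), rng=seed,
                                     kappa=1.0, avoid_stops=True)
            r = ng86_dnds(VirtualCds(pcg, mut))
            if r.omega is not None:
                omegas.append(r.omega)
        med = float(np.median(omegas))
        assert 0.8 <= med <= 1.25


class TestCodemlExport:
    def test_stop_codons_gapped(self):
        assert mask_stops_as_gaps("ATGTAACCC") == "ATG---CCC"

    def test_phylip_round_trip(self, tmp_path):
        seqs = {"sp1": "ATGAAACCC", "numt1": "ATGAAGCCC"}
        p = tmp_path / "a.phy"
        write_phylip(seqs, p)
        assert read_phylip(p) == seqs

    def test_branch_labels(self):
        nwk = "((a,b),(c,d));"
        labeled = label_tree(nwk, {"a": 0, "b": 0, "c": 1, "d": 2})
        assert labeled.count("#1") == 1 and labeled.count("#2") == 1
        assert "a #" not in labeled

    def test_unlabeled_taxon_errors(self):
        with pytest.raises(ValueError):
            label_tree("(a,b);", {"a": 1})

    def test_full_export(self, tmp_path):
        seqs = {"g1": "ATGTAAACT", "g2": "ATGCCCACT"}
        paths = export_codeml_inputs(seqs, "(g1,g2);", {"g1": 0, "g2": 1},
                                     tmp_path)
        back = read_phylip(paths["phylip"])
        assert back["g1"] == "ATG---ACT"  # stop gapped
        ctl = paths["ctl"].read_text()
        assert "model = 2" in ctl and "icode = 4" in ctl


class TestEventRecoverySimulation:
    @pytest.mark.parametrize("n_events", [1, 2, 3])
    def test_well_separated_lineages_recovered(self, n_events):
        """E lineages at >=10% divergence with a >=5x third-position
        multiplier: connected components recover E in >=95% of 20 seeded
        replicates (the 100-rep version runs in the acceptance suite)."""
        ok = 0
        reps = 20
        for rep in range(reps):
            cfg = SimulationConfig(
                seed=10_000 + 31 * rep + n_events,
                chromosomes=[("chr1", 60_000, "autosome")],
                events=[EventSpec(gene="COX1",
                                  lineage="contemporary" if e == 0 else "diverged",
                                  divergence=0.10 + 0.05 * e,
                                  third_multiplier=6.0,
                                  copies=2, within_family_divergence=0.005)
                        for e in range(n_events)],
            )
            m = simulate_mitogenome(cfg)
            _, truth, _ = implant_numts(cfg, m)
            numts = {r.numt_id: r.seq for r in truth.itertuples()}
            ev = estimate_integration_events(numts, m.pcg_seqs["COX1"])
            ok += ev.n_events == n_events
        assert ok / reps >= 0.95
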