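"""cpAAI, wpAAI, POCP, GANTC density and the built-in aligner."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import gantc_count, pairwise_identity, smith_waterman
from rhizotax.markers import ConcatenatedAlignment
from rhizotax.ogri import (
    CpaaiThresholds,
    HIT_COLUMNS,
    HitTable,
    PocpThresholds,
    Proteome,
    WpaaiThresholds,
    all_vs_all_hits,
    cpaai,
    gantc_frequency,
    local_align,
    pocp,
    read_hit_table,
    reciprocal_best_hits,
    wpaai,
    write_hit_table,
)
from rhizotax.seqio import GenomeAssembly, SeqRecord
from rhizotax.synth import expected_identity


def make_alignment(rows: dict) -> ConcatenatedAlignment:
    n = len(next(iter(rows.values())))
    return ConcatenatedAlignment(list(rows), list(rows.values()),
                                 {"m": (0, n)}, {k: 1.0 for k in rows})


class TestCpaai:
    def test_identical_rows(self):
        m = cpaai(make_alignment({"a": "ACDEF", "b": "ACDEF"}),
                  CpaaiThresholds(min_compared_sites=1))
        assert m.value("a", "b") == 100.0
        assert m.support[0, 1] == 5

    def test_single_difference(self):
        m = cpaai(make_alignment({"a": "ACDEF", "b": "ACDEY"}),
                  CpaaiThresholds(min_compared_sites=1))
        assert m.value("a", "b") == pytest.approx(80.0)

    def test_pairwise_deletion_of_gapped_column(self):
        m = cpaai(make_alignment({"a": "AC-EF", "b": "ACDEF"}),
                  CpaaiThresholds(min_compared_sites=1))
        assert m.value("a", "b") == 100.0
        assert m.support[0, 1] == 4

    def test_ambiguous_and_stop_excluded(self):
        m = cpaai(make_alignment({"a": "AXDE*", "b": "ACDEF"}),
                  CpaaiThresholds(min_compared_sites=1))
        assert m.support[0, 1] == 3

    def test_low_support_flagged_unreliable(self):
        m = cpaai(make_alignment({"a": "ACDEF", "b": "ACDEF"}),
                  CpaaiThresholds(min_compared_sites=100))
        assert m.unreliable[0, 1]

    def test_no_overlap_is_nan(self):
        m = cpaai(make_alignment({"a": "AC---", "b": "--DEF"}),
                  CpaaiThresholds(min_compared_sites=1))
        assert np.isnan(m.value("a", "b"))

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            cpaai(make_alignment({"a": "ACDEF"}))

    def test_symmetry_and_diagonal(self, small_dataset):
        from rhizotax.markers import build_supermatrix
        aln, _ = build_supermatrix(small_dataset.assemblies.values(),
                                   small_dataset.marker_set)
        m = cpaai(aln)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 100.0)

    def test_invariant_to_marker_order(self):
        rows_fwd = {"a": "ACDEFMKLVW", "b": "ACDEYMKIVW"}
        rows_rev = {"a": "MKLVWACDEF", "b": "MKIVWACDEY"}
        t = CpaaiThresholds(min_compared_sites=1)
        assert cpaai(make_alignment(rows_fwd), t).value("a", "b") == \
            cpaai(make_alignment(rows_rev), t).value("a", "b")

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_site_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chars = list("ACDEFGHIKL-X*")
        rows = {f"t{i}": "".join(rng.choice(chars, size=60)) for i in range(3)}
        m = cpaai(make_alignment(rows), CpaaiThresholds(min_compared_sites=1))
        for i, a in enumerate(rows):
            for j, b in enumerate(rows):
                if i >= j:
                    continue
                expect, sites = pairwise_identity(rows[a], rows[b])
                assert m.support[i, j] == sites
                if sites:
                    assert m.values[i, j] == pytest.approx(expect)

    @pytest.mark.parametrize("d", [0.02, 0.1, 0.4])
    def test_simulated_pair_matches_closed_form(self, d):
        """Two sequences at distance d: identity within 3 binomial SE."""
        from rhizotax.synth import _evolve_branch, _AA
        rng = np.random.default_rng(int(d * 1000))
        n_sites = 20_000
        root = _AA[rng.integers(0, 20, size=n_sites)]
        a = _evolve_branch(root, d / 2, rng).tobytes().decode()
        b = _evolve_branch(root, d / 2, rng).tobytes().decode()
        m = cpaai(make_alignment({"a": a, "b": b}))
        p = expected_identity(d)
        se = np.sqrt(p * (1 - p) / n_sites)
        assert abs(m.value("a", "b") - 100 * p) <= 3 * 100 * se

    def test_agrees_with_ape_dist_aa_on_gapfree_alignment(self, tmp_path):
        """Cross-check against the R routine the field uses (ape::dist.aa).

        Restricted to gap-free, unambiguous alignments, where counting
        substitutions is convention-free.
        """
        rng = np.random.default_rng(99)
        chars = list("ACDEFGHIKLMNPQRSTVWY")
        rows = {f"t{i}": "".join(rng.choice(chars, size=200)) for i in range(4)}
        fasta = tmp_path / "aln.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        script = textwrap.dedent("""
            suppressMessages(library(ape))
            a <- as.matrix(read.FASTA(commandArgs(TRUE)[1], type="AA"))
            m <- as.matrix(dist.aa(a, pairwise.deletion=TRUE, scaled=TRUE))
            write.table(m, stdout(), sep="\\t", quote=FALSE)
        """)
        try:
            out = subprocess.run(
                ["Rscript", "-e", script, str(fasta)],
                capture_output=True, text=True, timeout=120, check=True,
            ).stdout
        except (FileNotFoundError, subprocess.SubprocessError):
            pytest.skip("Rscript with ape not available")
        lines = [l.split("\t") for l in out.strip().splitlines()]
        header = lines[0]
        r_vals = {(row[0] if len(row) == len(header) + 1 else None): row for row in lines[1:]}
        m = cpaai(make_alignment(rows))
        for row in lines[1:]:
            label, *vals = row
            for other, v in zip(header, vals):
                expect = 100.0 * (1.0 - float(v))
                assert m.value(label, other) == pytest.approx(expect, abs=1e-6)


def hit_row(q, s, pident, length, evalue=1e-50, bitscore=100.0):
    return {"qseqid": q, "sseqid": s, "pident": pident, "length": length,
            "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": length,
            "sstart": 1, "send": length, "evalue": evalue, "bitscore": bitscore}


def table(query_genome, subject_genome, rows):
    return HitTable(query_genome, subject_genome,
                    pd.DataFrame(rows, columns=HIT_COLUMNS))


def proteome(genome_id, n, length=100):
    return Proteome(genome_id,
                    [SeqRecord(f"{genome_id}_p{i}", "A" * length)
                     for i in range(n)])


class TestRbhAndWpaai:
    def test_identical_proteomes_three_pairs(self):
        pa, pb = proteome("A", 3), proteome("B", 3)
        ab = table("A", "B", [hit_row(f"A_p{i}", f"B_p{i}", 100.0, 100)
                              for i in range(3)])
        ba = table("B", "A", [hit_row(f"B_p{i}", f"A_p{i}", 100.0, 100)
                              for i in range(3)])
        pairs = reciprocal_best_hits(ab, ba, pa, pb)
        assert len(pairs) == 3
        assert wpaai(pairs) == 100.0

    def test_non_reciprocal_best_excluded(self):
        pa, pb = proteome("A", 2), proteome("B", 2)
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 90.0, 100)])
        # B_p0's best hit is A_p1, not A_p0 -> no pair
        ba = table("B", "A", [hit_row("B_p0", "A_p1", 95.0, 100, bitscore=200),
                              hit_row("B_p0", "A_p0", 90.0, 100, bitscore=100)])
        assert reciprocal_best_hits(ab, ba, pa, pb) == []

    def test_identity_threshold_excludes(self):
        pa, pb = proteome("A", 1), proteome("B", 1)
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 25.0, 100)])
        ba = table("B", "A", [hit_row("B_p0", "A_p0", 25.0, 100)])
        assert reciprocal_best_hits(ab, ba, pa, pb) == []

    def test_coverage_threshold_excludes(self):
        pa, pb = proteome("A", 1), proteome("B", 1)  # proteins 100 aa
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 90.0, 60)])  # 60 < 70
        ba = table("B", "A", [hit_row("B_p0", "A_p0", 90.0, 60)])
        assert reciprocal_best_hits(ab, ba, pa, pb) == []

    def test_evalue_threshold_excludes(self):
        pa, pb = proteome("A", 1), proteome("B", 1)
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 90.0, 100, evalue=0.5)])
        ba = table("B", "A", [hit_row("B_p0", "A_p0", 90.0, 100, evalue=0.5)])
        assert reciprocal_best_hits(ab, ba, pa, pb) == []
        relaxed = WpaaiThresholds(ignore_evalue=True)
        assert len(reciprocal_best_hits(ab, ba, pa, pb, relaxed)) == 1

    def test_wpaai_is_unweighted_mean(self):
        from rhizotax.ogri import OrthologPair
        pairs = [OrthologPair("a", "b", 100.0), OrthologPair("c", "d", 90.0),
                 OrthologPair("e", "f", 80.0)]
        assert wpaai(pairs) == pytest.approx(90.0)
        assert wpaai([OrthologPair("a", "b", 86.5)]) == pytest.approx(86.5)

    def test_zero_pairs_is_missing(self):
        assert np.isnan(wpaai([]))

    def test_mismatched_tables_rejected(self):
        pa, pb = proteome("A", 1), proteome("B", 1)
        ab = table("A", "B", [])
        bc = table("B", "C", [])
        with pytest.raises(ValueError):
            reciprocal_best_hits(ab, bc, pa, pb)


class TestPocp:
    def test_hand_computed_example(self):
        """4+5 proteomes with 3 conserved each: 100*6/9 = 66.67."""
        pa, pb = proteome("A", 4), proteome("B", 5)
        ab = table("A", "B", [hit_row(f"A_p{i}", f"B_p{i}", 60.0, 80)
                              for i in range(3)])
        ba = table("B", "A", [hit_row(f"B_p{i}", f"A_p{i}", 60.0, 80)
                              for i in range(3)])
        assert pocp(ab, ba, pa, pb) == pytest.approx(100 * 6 / 9, abs=1e-9)

    def test_identical_proteomes_pocp_100(self):
        pa, pb = proteome("A", 3), proteome("B", 3)
        ab = table("A", "B", [hit_row(f"A_p{i}", f"B_p{i}", 100.0, 100)
                              for i in range(3)])
        ba = table("B", "A", [hit_row(f"B_p{i}", f"A_p{i}", 100.0, 100)
                              for i in range(3)])
        assert pocp(ab, ba, pa, pb) == 100.0

    def test_no_passing_hits_pocp_0(self):
        pa, pb = proteome("A", 3), proteome("B", 3)
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 30.0, 100)])  # < 40 %
        ba = table("B", "A", [])
        assert pocp(ab, ba, pa, pb) == 0.0

    def test_symmetry_in_argument_order(self):
        pa, pb = proteome("A", 4), proteome("B", 6)
        ab = table("A", "B", [hit_row(f"A_p{i}", f"B_p{i}", 60.0, 80)
                              for i in range(2)])
        ba = table("B", "A", [hit_row(f"B_p{i}", f"A_p{i}", 60.0, 80)
                              for i in range(4)])
        assert pocp(ab, ba, pa, pb) == pocp(ba, ab, pb, pa)

    def test_multiple_hits_count_query_once(self):
        pa, pb = proteome("A", 2), proteome("B", 2)
        ab = table("A", "B", [hit_row("A_p0", "B_p0", 60.0, 80),
                              hit_row("A_p0", "B_p1", 55.0, 80)])
        ba = table("B", "A", [])
        assert pocp(ab, ba, pa, pb) == pytest.approx(100 * 1 / 4)

    def test_empty_proteome_rejected(self):
        pa = proteome("A", 4)
        pb = Proteome("B", [])
        ab, ba = table("A", "B", []), table("B", "A", [])
        with pytest.raises(ValueError):
            pocp(ab, ba, pa, pb)


class TestHitTableIO:
    def test_round_trip(self, tmp_path):
        t = table("A", "B", [hit_row("A_p0", "B_p0", 77.5, 120)])
        p = tmp_path / "hits.tsv"
        write_hit_table(t, p)
        back = read_hit_table(p, "A", "B")
        assert back.hits["pident"].iloc[0] == 77.5
        assert back.hits["length"].iloc[0] == 120

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            table("A", "B", [hit_row("q", "s", 120.0, 50)])


class TestGantc:
    def test_single_site(self):
        g = GenomeAssembly("g", [SeqRecord("c", "GAATC")])
        report = gantc_frequency(g)
        assert report.site_count == 1
        assert report.sites_per_kb == pytest.approx(200.0)

    def test_two_sites_adjacent(self):
        g = GenomeAssembly("g", [SeqRecord("c", "GAATCGAGTC")])
        assert gantc_frequency(g).site_count == 2

    def test_middle_n_counts_outer_n_does_not(self):
        g = GenomeAssembly("g", [SeqRecord("c", "GANTCNAATC")])
        assert gantc_frequency(g).site_count == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gantc_frequency(GenomeAssembly("g", [SeqRecord("c", "GAT")]))

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_position_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=300))
        g = GenomeAssembly("g", [SeqRecord("c", seq)])
        assert gantc_frequency(g).site_count == gantc_count(seq)

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_invariance(self, seed):
        from rhizotax.markers import reverse_complement
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = gantc_frequency(GenomeAssembly("g", [SeqRecord("c", seq)]))
        rev = gantc_frequency(
            GenomeAssembly("g", [SeqRecord("c", reverse_complement(seq))]))
        assert fwd.site_count == rev.site_count

    def test_ten_kb_random_matches_oracle_exactly(self):
        rng = np.random.default_rng(12345)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        g = GenomeAssembly("g", [SeqRecord("c", seq)])
        assert gantc_frequency(g).site_count == gantc_count(seq)


class TestLocalAlign:
    def test_self_alignment(self):
        aln = local_align("HEAGAWGHEE", "HEAGAWGHEE")
        assert aln.identity == 100.0
        assert aln.length == 10

    def test_single_residue(self):
        aln = local_align("A", "A")
        assert aln.length == 1

    def test_score_matches_independent_dp(self):
        assert local_align("PAWHEAE", "HEAGAWGHEE").score == \
            smith_waterman("PAWHEAE", "HEAGAWGHEE")

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_random_pairs_match_independent_dp(self, seed):
        rng = np.random.default_rng(seed)
        chars = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(chars, size=int(rng.integers(5, 40))))
        b = "".join(rng.choice(chars, size=int(rng.integers(5, 40))))
        result = local_align(a, b)
        expected = smith_waterman(a, b)
        if result is None:
            assert expected == 0
        else:
            assert result.score == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "A")


class TestAllVsAllHits:
    def test_perfect_self_hits(self):
        rng = np.random.default_rng(3)
        prots = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
                 for _ in range(3)]
        pa = Proteome("A", [SeqRecord(f"A_p{i}", p) for i, p in enumerate(prots)])
        pb = Proteome("B", [SeqRecord(f"B_p{i}", p) for i, p in enumerate(prots)])
        t = all_vs_all_hits(pa, pb)
        self_hits = t.hits[t.hits.apply(
            lambda r: r["qseqid"][-1] == r["sseqid"][-1], axis=1)]
        assert (self_hits["pident"] == 100.0).all()
        pairs = reciprocal_best_hits(t, all_vs_all_hits(pb, pa), pa, pb,
                                     WpaaiThresholds(ignore_evalue=True))
        assert len(pairs) == 3
        assert wpaai(pairs) == 100.0


class TestCpaaiMonotonicity:
    def test_mean_cpaai_decreases_with_divergence(self):
        """Rank order of cpAAI means is exactly inverse to divergence."""
        from rhizotax.synth import _evolve_branch, _AA
        rng = np.random.default_rng(321)
        grid = [0.05, 0.1, 0.2, 0.4, 0.8]
        means = []
        for d in grid:
            vals = []
            for _ in range(3):
                root = _AA[rng.integers(0, 20, size=4_000)]
                a = _evolve_branch(root, d / 2, rng).tobytes().decode()
                b = _evolve_branch(root, d / 2, rng).tobytes().decode()
                m = cpaai(make_alignment({"a": a, "b": b}))
                vals.append(m.value("a", "b"))
            means.append(np.mean(vals))
        assert means == sorted(means, reverse=True)
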