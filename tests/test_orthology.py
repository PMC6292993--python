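"""Pairwise protein alignment and reciprocal-best-hit orthology."""

import numpy as np
import pytest

from gcaa import (
    GeneRecord,
    SimParams,
    align_proteins,
    read_blast_tab,
    reciprocal_best_hits,
    reciprocal_best_hits_blast,
    simulate_study,
)
from gcaa.orthology import best_blast_hits

from oracles import local_align_score_oracle


def _gene(gene_id, protein, genome="X"):
    return GeneRecord(gene_id, genome, gene_id, "ATG", protein)


class TestAlignProteins:
    def test_self_alignment_is_perfect(self):
        res = align_proteins("MKLVNQWERT", "MKLVNQWERT")
        assert res.identity_percent == 100.0
        assert res.aligned_fraction == 1.0

    def test_score_matches_dp_oracle_classic_pair(self):
        res = align_proteins("HEAGAWGHEE", "PAWHEAE")
        assert res.score == local_align_score_oracle("HEAGAWGHEE", "PAWHEAE")

    def test_score_matches_dp_oracle_random_pairs(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            a = "".join(rng.choice(aas, size=int(rng.integers(10, 40))))
            b = "".join(rng.choice(aas, size=int(rng.integers(10, 40))))
            assert align_proteins(a, b).score == local_align_score_oracle(a, b)

    def test_reverse_never_beats_self(self, rng):
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
        assert align_proteins(a, a[::-1]).score <= align_proteins(a, a).score

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_proteins("", "MKL")


class TestReciprocalBestHits:
    def test_self_comparison_pairs_identical_copies(self):
        prots = ["MKLVNQWERTYIPASDFGHK", "MAAAVVVLLLIIIKKKRRRE", "MWWWYYYFFFHHHNNNQQQD"]
        ref = [_gene(f"A{i}", p, "ga") for i, p in enumerate(prots)]
        target = [_gene(f"B{i}", p, "gb") for i, p in enumerate(prots)]
        pairs = reciprocal_best_hits(ref, target)
        assert [(p.ref_gene.gene_id, p.target_gene.gene_id) for p in pairs] == [
            ("A0", "B0"), ("A1", "B1"), ("A2", "B2")
        ]

    def test_nonreciprocal_best_hit_unpaired(self):
        base = "MKLVNQWERTYIPASDFGHKLMNQWERTYIPASDFGHKLV"
        mutated = "MALVNQWARTYIPASAFGHKLMNQWERTYAPASDFGHALV"  # diverged copy of base
        junk1 = "MCCCCCCCCCCWWWWWWWWWWHHHHHHHHHHPPPPPPPPP"
        junk2 = "MDDDDDDDDDDEEEEEEEEEEKKKKKKKKKKRRRRRRRRR"
        ref = [_gene("A1", mutated, "ga"), _gene("A2", base, "ga"), _gene("A3", junk1, "ga")]
        target = [_gene("B1", base, "gb"), _gene("B2", junk2, "gb")]
        # oracle: enumerate all scores to confirm the intended best-hit structure
        scores = {
            (r.gene_id, t.gene_id): local_align_score_oracle(r.protein, t.protein)
            for r in ref for t in target
        }
        assert max(("B1", "B2"), key=lambda t: scores[("A1", t)]) == "B1"
        assert max(("A1", "A2", "A3"), key=lambda r: scores[(r, "B1")]) == "A2"
        pairs = reciprocal_best_hits(ref, target, identity_min=0, coverage_min=0)
        paired_refs = {p.ref_gene.gene_id for p in pairs}
        assert "A1" not in paired_refs
        assert ("A2", "B1") in {(p.ref_gene.gene_id, p.target_gene.gene_id) for p in pairs}

    def test_identity_threshold_is_inclusive(self):
        a = "MKLVNQWERTYIPASDFGHK"
        b = "MKLVNQWERTYIPASDFAAA"  # mismatches only at the tail
        ref, target = [_gene("r", a, "ga")], [_gene("t", b, "gb")]
        ident = align_proteins(a, b).identity_percent
        assert reciprocal_best_hits(ref, target, identity_min=ident, coverage_min=0)
        assert not reciprocal_best_hits(ref, target, identity_min=ident + 0.1, coverage_min=0)

    def test_duplicate_ids_rejected(self):
        g = _gene("A1", "MKLV")
        with pytest.raises(ValueError, match="duplicate"):
            reciprocal_best_hits([g, g], [_gene("B1", "MKLV")])

    def test_symmetry_and_threshold_monotonicity(self, small_study):
        _, families = small_study
        ref = [f.descendants[0] for f in families]  # genome G000
        target = [f.descendants[5] for f in families]  # genome G005
        fwd = reciprocal_best_hits(ref, target)
        rev = reciprocal_best_hits(target, ref)
        assert {(p.ref_gene.gene_id, p.target_gene.gene_id) for p in fwd} == {
            (p.target_gene.gene_id, p.ref_gene.gene_id) for p in rev
        }
        counts = [
            len(reciprocal_best_hits(ref, target, identity_min=t))
            for t in (0.0, 30.0, 60.0, 90.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recovers_true_pairs_at_low_divergence(self):
        params = SimParams(
            n_codons=60, n_genomes=2, n_families=20, gc_span=(0.38, 0.48),
            branch_length=0.12, divergence_slope=0.0, seed=5,
        )
        families = simulate_study(params)
        g0 = [f.descendants[0] for f in families]
        g1 = [f.descendants[1] for f in families]
        pairs = reciprocal_best_hits(g0, g1)
        true = {(a.gene_id, b.gene_id) for a, b in zip(g0, g1)}
        found = {(p.ref_gene.gene_id, p.target_gene.gene_id) for p in pairs}
        assert len(found & true) >= 0.99 * len(true)


class TestBlastTabular:
    ROW = "qA\tsB\t97.5\t100\t2\t0\t1\t100\t1\t100\t1e-50\t200.0"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tab(p) == []

    def test_single_row_round_trip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW + "\n")
        (hit,) = read_blast_tab(p)
        assert (hit.qseqid, hit.sseqid, hit.pident, hit.bitscore) == ("qA", "sB", 97.5, 200.0)
        assert hit.evalue == 1e-50

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.ROW + "\n" + self.ROW + "\textra\n")
        with pytest.raises(ValueError, match="line 2"):
            read_blast_tab(p)

    def test_best_hit_tie_breaking(self):
        def hit(q, s, ev, bits):
            return read_blast_tab_row(q, s, ev, bits)

        hits = [hit("q", "sZ", 1e-30, 100.0), hit("q", "sA", 1e-30, 100.0),
                hit("q", "sB", 1e-40, 100.0)]
        assert best_blast_hits(hits)["q"].sseqid == "sB"  # min evalue wins the tie

    def test_rbh_with_evalue_filter(self):
        fwd = [read_blast_tab_row("r1", "t1", 1e-30, 100.0),
               read_blast_tab_row("r2", "t2", 1e-3, 90.0)]
        rev = [read_blast_tab_row("t1", "r1", 1e-30, 100.0),
               read_blast_tab_row("t2", "r2", 1e-3, 90.0)]
        pairs = reciprocal_best_hits_blast(fwd, rev)
        assert [(a, b) for a, b, _ in pairs] == [("r1", "t1")]  # r2 fails E < 1e-5


def read_blast_tab_row(q, s, evalue, bitscore):
    from gcaa.orthology import BlastHit

    return BlastHit(q, s, 95.0, 100, 2, 0, 1, 100, 1, 100, evalue, bitscore)
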