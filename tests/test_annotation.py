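"""R-gene classification rules, coiled-coil scanner, motifs, clusters."""

import math
import re

import numpy as np
import pytest

from polyrgene import annotation as ann
from polyrgene.core_io import DomainHit, GeneModel, MotifHit


def D(*names):
    return [DomainHit("g", n, 1, 10) for n in names]


def M(n=1):
    return [MotifHit("g", f"m{i}", i + 1, "XXXX") for i in range(n)]


# ---------------------------------------------------------------------------
# Coiled-coil
# ---------------------------------------------------------------------------

def brute_force_coil_scores(seq, window, profile):
    """Independent per-residue best geometric-mean score: direct loops over
    every window and register phase."""
    n = len(seq)
    best = [0.0] * n
    for phase in range(7):
        for start in range(0, n - window + 1):
            logs = []
            for i in range(start, start + window):
                pos = (i + phase) % 7
                logs.append(math.log(profile.get(seq[i], profile["X"])[pos]))
            gm = math.exp(sum(logs) / window)
            for i in range(start, start + window):
                best[i] = max(best[i], gm)
    return best


class TestCoiledCoil:
    def test_polyglycine_has_no_segment(self):
        assert ann.detect_coiled_coil("G" * 28) == []

    def test_empty_sequence(self):
        assert ann.detect_coiled_coil("") == []

    def test_perfect_heptads_give_one_covering_segment(self):
        seq = "LEALEGK" * 4
        segs = ann.detect_coiled_coil(seq, gene_id="g")
        assert len(segs) == 1
        assert (segs[0].protein_start, segs[0].protein_end) == (1, 28)
        assert segs[0].max_probability > 0.9

    def test_scores_match_brute_force_over_register_phases(self):
        profile = ann.load_coil_profile()
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            seq = "".join(rng.choice(aas, size=40)) + "LEALEGK" * 3
            expected = brute_force_coil_scores(seq, 21, profile)
            got = ann._coil_scores(seq, 21, profile)
            assert np.allclose(got, expected, atol=1e-12)

    def test_segment_emitted_as_cc_domain_hit(self):
        segs = ann.detect_coiled_coil("LEALEGK" * 4, gene_id="g")
        (hit,) = ann.coil_domain_hits(segs)
        assert hit.domain_name == "CC" and hit.gene_id == "g"


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

class TestMotifs:
    def test_exact_hit_position(self):
        motifs = {"GLPL": re.compile("GLPL")}
        (hit,) = ann.scan_motifs("AAGLPLAA", motifs, "g")
        assert (hit.protein_start, hit.match_string) == (3, "GLPL")

    def test_non_overlapping_leftmost_scan(self):
        motifs = {"ploop": ann.compile_motif("ploop", "GKTT")}
        hits = ann.scan_motifs("GGKTTGKTT", motifs)
        assert [h.protein_start for h in hits] == [2, 6]

    def test_absent_motif(self):
        assert ann.scan_motifs("AAAA", {"m": re.compile("WWW")}) == []

    def test_wildcard_and_sets(self):
        pat = ann.compile_motif("m", "Gx[ST]T")
        assert pat.fullmatch("GAST") and pat.fullmatch("GCTT")
        assert not pat.match("GAAT")

    def test_malformed_pattern_names_motif(self):
        with pytest.raises(ValueError, match="bad1"):
            ann.compile_motif("bad1", "G[ST")
        with pytest.raises(ValueError, match="bad2"):
            ann.compile_motif("bad2", "G7T")

    def test_default_motif_file_loads(self):
        motifs = ann.default_motifs()
        assert "P-loop" in motifs and len(motifs) >= 10


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

class TestClassifyGene:
    def test_canonical_domain_alone_is_rgene(self):
        call = ann.classify_gene(D("NB-ARC"), [])
        assert call.is_rgene and call.evidence == "canonical_domain"
        assert call.subtype == "NBS"

    def test_common_domain_without_motif_is_not_rgene(self):
        call = ann.classify_gene(D("LRR"), [])
        assert not call.is_rgene and call.subtype == "none"

    def test_lrr_kinase_plus_motif_is_rlk_like(self):
        call = ann.classify_gene(D("LRR", "kinase"), M(1))
        assert call.is_rgene
        assert call.subtype == "RLK-like" and call.family == "non-NLR"
        assert call.evidence == "common_domain_plus_motif"

    def test_curated_override(self):
        call = ann.classify_gene([], [], override=True)
        assert call.is_rgene and call.evidence == "curated_override"

    def test_adding_canonical_domain_is_monotone(self):
        rng = np.random.default_rng(1)
        pool = sorted(ann.CANONICAL_DOMAINS | ann.COMMON_DOMAINS | {"WRKY", "F-box"})
        for _ in range(100):
            names = list(rng.choice(pool, size=rng.integers(0, 4), replace=False))
            motifs = M(int(rng.integers(0, 2)))
            before = ann.classify_gene(D(*names), motifs).is_rgene
            after = ann.classify_gene(D(*(names + ["NB-ARC"])), motifs).is_rgene
            assert after >= before


# Hand-written truth table over presence flags (TIR, RPW8, CC, NBS, LRR).
# N-terminal precedence TIR > RPW8 > CC; LRR is recorded only on top of a
# nucleotide-binding domain; CC or LRR without an anchor is not an NLR.
EXPECTED_SUBTYPE = {
    (False, False, False, False, False): "none",
    (False, False, False, False, True): "none",
    (False, False, False, True, False): "NBS",
    (False, False, False, True, True): "NBS-LRR",
    (False, False, True, False, False): "none",
    (False, False, True, False, True): "none",
    (False, False, True, True, False): "CC-NBS",
    (False, False, True, True, True): "CC-NBS-LRR",
    (False, True, False, False, False): "RPW8",
    (False, True, False, False, True): "RPW8",
    (False, True, False, True, False): "RPW8-NBS",
    (False, True, False, True, True): "RPW8-NBS",
    (False, True, True, False, False): "RPW8",
    (False, True, True, False, True): "RPW8",
    (False, True, True, True, False): "RPW8-NBS",
    (False, True, True, True, True): "RPW8-NBS",
    (True, False, False, False, False): "TIR",
    (True, False, False, False, True): "TIR",
    (True, False, False, True, False): "TIR-NBS",
    (True, False, False, True, True): "TIR-NBS-LRR",
    (True, False, True, False, False): "TIR",
    (True, False, True, False, True): "TIR",
    (True, False, True, True, False): "TIR-NBS",
    (True, False, True, True, True): "TIR-NBS-LRR",
    (True, True, False, False, False): "TIR",
    (True, True, False, False, True): "TIR",
    (True, True, False, True, False): "TIR-NBS",
    (True, True, False, True, True): "TIR-NBS-LRR",
    (True, True, True, False, False): "TIR",
    (True, True, True, False, True): "TIR",
    (True, True, True, True, False): "TIR-NBS",
    (True, True, True, True, True): "TIR-NBS-LRR",
}


class TestSubtypeTaxonomy:
    @pytest.mark.parametrize("flags,expected", sorted(EXPECTED_SUBTYPE.items()))
    def test_exhaustive_truth_table(self, flags, expected):
        tir, rpw8, cc, nbs, lrr = flags
        names = set()
        if tir:
            names.add("TIR")
        if rpw8:
            names.add("RPW8")
        if cc:
            names.add("CC")
        if nbs:
            names.add("NB-ARC")
        if lrr:
            names.add("LRR")
        subtype, family = ann.assign_nlr_subtype(names)
        assert subtype == expected
        if expected == "none":
            assert family == "non-NLR"
        else:
            assert family == ann.FAMILY_OF_SUBTYPE[expected]

    def test_canonical_architecture_examples(self):
        assert ann.assign_nlr_subtype({"TIR", "NB-ARC", "LRR"}) == ("TIR-NBS-LRR", "TNL")
        assert ann.assign_nlr_subtype({"RPW8", "NB-ARC"}) == ("RPW8-NBS", "RPW8-type")
        assert ann.assign_nlr_subtype({"CC", "NB-ARC"}) == ("CC-NBS", "CNL")
        assert ann.assign_nlr_subtype({"LRR"}) == ("none", "non-NLR")

    def test_tir_and_rpw8_conflict_resolves_to_tnl(self, caplog):
        subtype, family = ann.assign_nlr_subtype({"TIR", "RPW8", "NB-ARC"})
        assert family == "TNL" and subtype.startswith("TIR")


class TestSubtypeTable:
    @staticmethod
    def calls_from_counts(counts):
        calls = []
        for subtype, n in counts.items():
            fam = ann.FAMILY_OF_SUBTYPE[subtype]
            calls += [ann.RGeneCall(f"{subtype}{i}", True, "canonical_domain", subtype, fam) for i in range(n)]
        return calls

    def test_family_counts_are_component_sums(self):
        from polyrgene.simulate import DEFAULT_SUBTYPE_COUNTS

        table = ann.subtype_table(self.calls_from_counts(DEFAULT_SUBTYPE_COUNTS))
        fam = table[table.level == "family"].set_index("label")["count"]
        sub = table[table.level == "subtype"].set_index("label")["count"]
        assert fam["NBS-only"] == sub["NBS"] + sub["NBS-LRR"] == 215
        assert fam["CNL"] == sub["CC-NBS"] + sub["CC-NBS-LRR"]
        assert table[table.level == "total"]["count"].iloc[0] == fam.sum()

    def test_subtype_percentages_partition(self):
        from polyrgene.simulate import DEFAULT_SUBTYPE_COUNTS

        table = ann.subtype_table(self.calls_from_counts(DEFAULT_SUBTYPE_COUNTS))
        subtype_pct = table[table.level == "subtype"]["pct"]
        assert subtype_pct.sum() == pytest.approx(100.0, abs=0.2)

    def test_family_summary_on_published_family_counts(self):
        df = ann.family_summary({"NBS-only": 215, "CNL": 192, "RPW8-type": 136, "TNL": 432})
        assert df.loc["Total", "count"] == 975
        assert df.loc["NBS-only", "pct"] == pytest.approx(22.1)
        assert df.loc["RPW8-type", "pct"] == pytest.approx(13.9)

    def test_empty_genome_zero_table(self):
        table = ann.subtype_table([])
        assert (table["count"] == 0).all()


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def brute_force_clusters(positions, max_gap, min_size):
    """O(n^2) segmentation oracle: every maximal window whose consecutive
    gaps all fit."""
    out = []
    by_chrom = {}
    for gid, chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append((pos, gid))
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom])
        n = len(pts)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and pts[j + 1][0] - pts[j][0] <= max_gap:
                j += 1
            if j - i + 1 >= min_size:
                out.append((chrom, tuple(g for _, g in pts[i : j + 1])))
            i = j + 1
    return out


class TestClusters:
    def test_three_near_one_far(self):
        pos = [("a", "c1", 10_000), ("b", "c1", 50_000), ("c", "c1", 90_000), ("d", "c1", 500_000)]
        (cluster,) = ann.detect_clusters(pos)
        assert cluster.members == ["a", "b", "c"]
        assert cluster.span_bp == 80_000

    def test_two_genes_below_min_size(self):
        assert ann.detect_clusters([("a", "c1", 10_000), ("b", "c1", 20_000)]) == []

    def test_all_far_apart(self):
        pos = [("a", "c1", 0), ("b", "c1", 200_000), ("c", "c1", 400_000)]
        assert ann.detect_clusters(pos) == []

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(1, 50))
            pos = [
                (f"g{i}", f"c{int(rng.integers(1, 4))}", int(rng.integers(0, 1_000_000)))
                for i in range(n)
            ]
            got = [(c.chromosome, tuple(c.members)) for c in ann.detect_clusters(pos)]
            assert got == brute_force_clusters(pos, 100_000, 3)


class TestExtractDomainSequence:
    GENE = GeneModel("g", "c1", "+", [(1, 15)], "ATGAAACGTCTGACT", "MKRLT")

    def test_inner_hit(self):
        ((name, seq),) = ann.extract_domain_sequence(
            self.GENE, [DomainHit("g", "NB-ARC", 2, 4)], "NB-ARC"
        )
        assert seq == "KRL" and name == "g|NB-ARC|2-4"

    def test_two_hits_two_records(self):
        hits = [DomainHit("g", "NB-ARC", 1, 2), DomainHit("g", "NB-ARC", 4, 5)]
        assert len(ann.extract_domain_sequence(self.GENE, hits, "NB-ARC")) == 2

    def test_no_hit_empty(self):
        assert ann.extract_domain_sequence(self.GENE, [], "NB-ARC") == []

    def test_overflow_errors(self):
        with pytest.raises(ValueError):
            ann.extract_domain_sequence(self.GENE, [DomainHit("g", "TIR", 2, 99)], "TIR")
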