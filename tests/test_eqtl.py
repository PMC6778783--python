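"""TPM, Box-Cox, marker QC, kinship, mixed-model association, eQTL calling."""

import numpy as np
import pandas as pd
import pytest

from polyrgene import eqtl
from polyrgene.core_io import ExpressionMatrix, Marker


class TestTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        out = eqtl.tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))
        assert out.values.loc["g1", "s1"] == pytest.approx(5e5)

    def test_doubling_length_halves_share(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        out = eqtl.tpm(counts, pd.Series([200, 100], index=["g1", "g2"]))
        assert out.values.loc["g1", "s1"] == pytest.approx(out.values.loc["g2", "s1"] / 2)

    def test_five_gene_fixture_matches_hand_computation(self):
        counts = pd.DataFrame({"s1": [12, 0, 30, 8, 50]}, index=list("abcde"))
        lengths = pd.Series([300, 500, 1000, 200, 2500], index=list("abcde"))
        out = eqtl.tpm(counts, lengths)
        rates = np.array([12 / 300, 0.0, 30 / 1000, 8 / 200, 50 / 2500])
        expected = rates / rates.sum() * 1e6
        assert np.allclose(out.values["s1"].to_numpy(), expected)

    def test_column_sums_are_one_million(self, population):
        counts = pd.DataFrame(
            np.random.default_rng(0).integers(0, 500, size=(40, 6)).astype(float)
        )
        counts.index = [f"g{i}" for i in range(40)]
        lengths = pd.Series(np.linspace(200, 3000, 40), index=counts.index)
        out = eqtl.tpm(counts, lengths)
        assert np.allclose(out.values.sum(axis=0), 1e6, atol=1.0)

    def test_zero_sum_sample_errors(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero-sum"):
            eqtl.tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))


class TestTissueSummary:
    @staticmethod
    def atlas(values, tissues):
        cols = [f"s{i}" for i in range(len(tissues))]
        vals = pd.DataFrame(values, index=["g1"], columns=cols)
        meta = pd.DataFrame({"tissue": tissues}, index=cols)
        return ExpressionMatrix(vals, meta)

    def test_below_threshold_everywhere_not_expressed(self):
        summary = eqtl.tissue_summary(self.atlas([[0.5, 0.5]], ["root", "leaf"]))
        assert summary.loc["global", "expressed_genes"] == 0

    def test_replicate_mean_crosses_threshold(self):
        summary = eqtl.tissue_summary(self.atlas([[0.0, 4.0]], ["root", "root"]))
        assert summary.loc["root", "expressed_genes"] == 1

    def test_generator_truth_exact_recovery(self, population):
        atlas = population.atlas
        summary = eqtl.tissue_summary(atlas)
        means = atlas.values.T.groupby(atlas.meta["tissue"]).mean().T
        assert summary.loc["root", "expressed_genes"] == int((means["root"] > 1.0).sum())
        assert summary.loc["global", "expressed_genes"] == int((means > 1.0).any(axis=1).sum())


class TestHcluster:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        Z, labels = eqtl.hcluster(df)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_height_two(self):
        x = np.linspace(-1, 1, 20)
        df = pd.DataFrame({"a": x, "b": -x})
        Z, _ = eqtl.hcluster(df)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("edcba"))
        Z, labels = eqtl.hcluster(df)
        X = df[labels].to_numpy()
        n = 5
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    dist[i, j] = 1 - np.corrcoef(X[:, i], X[:, j])[0, 1]
        merged = {i: [i] for i in range(n)}
        expected_heights = []
        while len(merged) > 1:
            best = None
            keys = sorted(merged)
            for ai in range(len(keys)):
                for bi in range(ai + 1, len(keys)):
                    a, b = keys[ai], keys[bi]
                    d = np.mean([dist[i, j] for i in merged[a] for j in merged[b]])
                    if best is None or d < best[0] - 1e-15:
                        best = (d, a, b)
            d, a, b = best
            expected_heights.append(d)
            merged[a] = merged[a] + merged.pop(b)
        assert np.allclose(sorted(Z[:, 2]), sorted(expected_heights), atol=1e-9)

    def test_constant_column_warns_and_runs(self, caplog):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0], "c": [2.0, 1.0, 0.0]})
        Z, _ = eqtl.hcluster(df)
        assert Z.shape == (2, 4)


class TestBoxCox:
    def test_lambda_one_is_shift(self):
        x = np.array([1.0, 2.0, 5.0])
        assert np.allclose(eqtl._boxcox_transform(x, 1.0), x - 1.0)

    def test_lambda_zero_limit_is_log(self):
        x = np.linspace(0.5, 9.0, 40)
        assert np.allclose(eqtl._boxcox_transform(x, 1e-9), np.log(x), atol=1e-6)

    def test_lognormal_data_recovers_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(size=500))
        _, params = eqtl.boxcox(x)
        assert abs(params.lmbda) < 0.1
        assert params.offset == 0.0

    def test_offset_applied_for_zeros(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([[0.0], np.exp(rng.normal(size=50))])
        _, params = eqtl.boxcox(x)
        assert params.offset == 1.0

    def test_transform_monotone_in_x(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0.1, 50, size=100))
        for lam in (-2.0, -0.5, 0.0, 0.7, 3.0):
            y = eqtl._boxcox_transform(x, lam)
            assert (np.diff(y) > 0).all()

    def test_constant_vector_identity_with_warning(self, caplog):
        x = np.full(10, 3.0)
        y, params = eqtl.boxcox(x)
        assert np.allclose(y, x) and params.lmbda == 1.0


def make_marker(mid, qc, calls, chrom="Fvb1", pos=100):
    m = Marker(mid, qc, chrom, pos, calls)
    m.recompute_maf()
    return m


class TestFilterMarkers:
    PED = {"c1": ("p1", "p2"), "c2": ("p1", "p2")}

    def test_otv_class_dropped(self):
        m = make_marker("m1", "OTV", {"p1": "AA", "p2": "AB", "c1": "AA", "c2": "AB"})
        kept, audit = eqtl.filter_markers([m], self.PED)
        assert kept == [] and audit["class_dropped"] == 1

    def test_impossible_cross_call_set_missing(self):
        m = make_marker("m1", "PHR", {"p1": "AA", "p2": "BB", "c1": "AA", "c2": "AB"})
        kept, audit = eqtl.filter_markers([m], self.PED)
        (out,) = kept
        assert out.calls["c1"] == "NA" and out.calls["c2"] == "AB"
        assert audit["mendelian_set_missing"] == 1

    def test_monomorphic_after_cleaning_dropped(self):
        m = make_marker("m1", "PHR", {"p1": "AA", "p2": "AA", "c1": "AB", "c2": "AA"})
        kept, audit = eqtl.filter_markers([m], self.PED)
        assert kept == [] and audit["monomorphic_dropped"] == 1

    def test_progeny_without_parents_retained_unchecked(self):
        m = make_marker("m1", "PHR", {"x1": "AA", "x2": "AB"})
        kept, _ = eqtl.filter_markers([m], self.PED)
        assert kept[0].calls == {"x1": "AA", "x2": "AB"}

    def test_generator_injected_errors_removed_no_false_removals(self, population):
        kept, _ = eqtl.filter_markers(population.markers, population.pedigree)
        kept_by_id = {m.marker_id: m for m in kept}
        original = {m.marker_id: m for m in population.markers}
        injected = set(population.mendelian_errors)
        removed = 0
        for mid, ind in injected:
            if mid not in kept_by_id or kept_by_id[mid].calls[ind] == "NA":
                removed += 1
        assert removed / len(injected) >= 0.99
        false_removals = 0
        for mid, m in kept_by_id.items():
            for ind, call in m.calls.items():
                if call == "NA" and original[mid].calls[ind] != "NA":
                    if (mid, ind) not in injected:
                        false_removals += 1
        assert false_removals == 0


class TestKinship:
    def test_identical_individuals_maximal_off_diagonal(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 3, size=200).astype(float)
        dos = pd.DataFrame([row, row, rng.integers(0, 3, size=200).astype(float)],
                           index=["a", "b", "c"])
        K = eqtl.kinship(dos)
        assert K.loc["a", "b"] > K.loc["a", "c"]
        assert K.loc["a", "b"] == pytest.approx(K.loc["a", "a"])

    def test_complementary_homozygotes_negative(self):
        dos = pd.DataFrame(
            [[0.0, 2.0, 0.0, 2.0], [2.0, 0.0, 2.0, 0.0], [0.0, 2.0, 2.0, 0.0]],
            index=["a", "b", "c"],
        )
        K = eqtl.kinship(dos)
        assert K.loc["a", "b"] < 0

    def test_independent_genotypes_near_zero_relatedness(self):
        rng = np.random.default_rng(6)
        dos = pd.DataFrame(rng.integers(0, 3, size=(50, 1000)).astype(float))
        K = eqtl.kinship(dos)
        off = K.to_numpy()[~np.eye(50, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_monomorphic_markers_excluded(self):
        dos = pd.DataFrame([[0.0, 1.0], [0.0, 2.0], [0.0, 0.0]], index=list("abc"))
        K = eqtl.kinship(dos)  # first marker monomorphic, must not produce NaN
        assert np.isfinite(K.to_numpy()).all()


class TestAssociate:
    def test_identity_kinship_reduces_to_plain_lm(self):
        rng = np.random.default_rng(7)
        n = 40
        dos = pd.DataFrame(rng.integers(0, 3, size=(n, 30)).astype(float),
                           index=[f"i{k}" for k in range(n)])
        y = pd.Series(rng.normal(size=n), index=dos.index)
        K = pd.DataFrame(np.eye(n), index=dos.index, columns=dos.index)
        mlm = eqtl.associate(y, dos, K=K)
        lm = eqtl.associate(y, dos, K=None)
        assert np.allclose(mlm["p"], lm["p"], atol=1e-6)

    def test_strong_marker_highly_significant(self):
        rng = np.random.default_rng(8)
        n = 60
        x = rng.integers(0, 3, size=n).astype(float)
        e = rng.normal(size=n)
        xc = x - x.mean()
        e -= xc * (e @ xc) / (xc @ xc)  # noise orthogonal to the marker
        e *= xc.std() / e.std()  # marker explains exactly half the variance
        y = pd.Series(x + e, index=[f"i{k}" for k in range(n)])
        dos = pd.DataFrame({"mk": x}, index=y.index)
        res = eqtl.associate(y, dos)
        assert res.loc["mk", "p"] < 1e-6

    def test_too_few_individuals_rejected(self):
        y = pd.Series(np.arange(5.0), index=[f"i{k}" for k in range(5)])
        dos = pd.DataFrame({"mk": np.arange(5.0)}, index=y.index)
        with pytest.raises(ValueError):
            eqtl.associate(y, dos)


class TestFdr:
    def test_single_p_unchanged(self):
        q = eqtl.fdr(pd.Series([0.03], index=["m"]))
        assert q["m"] == pytest.approx(0.03)

    def test_all_ones_stay_one(self):
        q = eqtl.fdr(pd.Series([1.0, 1.0, 1.0]))
        assert (q == 1.0).all()

    def test_hand_computed_bh(self):
        q = eqtl.fdr(pd.Series([0.01, 0.02, 0.03, 0.5], index=list("abcd")))
        assert np.allclose(q[list("abc")], 0.04)
        assert q["d"] == pytest.approx(0.5)

    def test_monotone_in_sorted_p_order(self):
        rng = np.random.default_rng(9)
        p = pd.Series(rng.uniform(size=50))
        q = eqtl.fdr(p)
        order = p.sort_values().index
        assert (np.diff(q[order]) >= -1e-12).all()


MARKER_MAP = pd.DataFrame(
    {
        "chromosome": ["Fvb1"] * 8 + ["Fvb2"] * 2,
        "position_bp": [1e6, 2e6, 3e6, 4e6, 5e6, 6e6, 7e6, 60e6, 1e6, 2e6],
    },
    index=[f"m{i}" for i in range(10)],
)


class TestCallAndPhase:
    def test_lone_significant_marker_is_not_a_locus(self):
        q = pd.Series(1.0, index=MARKER_MAP.index)
        q["m0"] = 0.001
        assert eqtl.call_eqtl(q, MARKER_MAP) == []

    def test_seven_colocating_markers_one_locus_peak_min_q(self):
        q = pd.Series(1.0, index=MARKER_MAP.index)
        for i in range(7):
            q[f"m{i}"] = 0.01
        q["m3"] = 0.0001
        (locus,) = eqtl.call_eqtl(q, MARKER_MAP)
        assert locus.n_markers == 7 and locus.peak_marker == "m3"

    def test_two_distant_clusters_two_loci(self):
        q = pd.Series(1.0, index=MARKER_MAP.index)
        q[["m0", "m1"]] = 0.01
        q[["m8", "m9"]] = 0.01
        loci = eqtl.call_eqtl(q, MARKER_MAP)
        assert len(loci) == 2
        assert {l.chromosome for l in loci} == {"Fvb1", "Fvb2"}

    def test_phase_cis_near_gene(self):
        locus = eqtl.Locus("Fvb1", "m1", 0.01, 2, ["m0", "m1"])
        phase = eqtl.phase_eqtl([locus], "Fvb1", 1_500_000, MARKER_MAP)
        assert phase == "cis" and locus.phase == "cis"

    def test_phase_trans_other_chromosome(self):
        locus = eqtl.Locus("Fvb2", "m8", 0.01, 2, ["m8", "m9"])
        assert eqtl.phase_eqtl([locus], "Fvb1", 1_500_000, MARKER_MAP) == "trans"

    def test_phase_cis_plus_trans(self):
        near = eqtl.Locus("Fvb1", "m1", 0.01, 2, ["m0", "m1"])
        far = eqtl.Locus("Fvb2", "m8", 0.01, 2, ["m8", "m9"])
        assert eqtl.phase_eqtl([near, far], "Fvb1", 1_500_000, MARKER_MAP) == "cis+trans"

    def test_unmapped_gene_phase_none(self):
        locus = eqtl.Locus("Fvb1", "m1", 0.01, 2, ["m0", "m1"])
        assert eqtl.phase_eqtl([locus], None, None, MARKER_MAP) == "none"

    def test_project_chromosome(self):
        assert eqtl.project_chromosome("Fvb5-2") == "Fvb5"
        assert eqtl.project_chromosome("scaffold_12") is None


class TestHeritability:
    @staticmethod
    def sim_kinship(rng, n=60, m=300):
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(n, m)).astype(float), index=[f"i{k}" for k in range(n)]
        )
        return dos, eqtl.kinship(dos)

    def test_pure_noise_phenotype_near_zero(self):
        rng = np.random.default_rng(10)
        dos, K = self.sim_kinship(rng)
        y = pd.Series(rng.normal(size=60), index=dos.index)
        assert eqtl.heritability(y, K=K) <= 0.25

    def test_noiseless_marker_effect_near_one(self):
        rng = np.random.default_rng(11)
        dos, K = self.sim_kinship(rng)
        y = pd.Series(dos.iloc[:, 0] * 2.0, index=dos.index)
        assert eqtl.heritability(y, peak_dosage=dos.iloc[:, 0]) > 0.99

    def test_simulated_h2_recovered_on_average(self):
        """h2 = 0.5 recovered on average in a family-structured population
        (relatedness is what makes the variance ratio identifiable at
        n = 60)."""
        rng = np.random.default_rng(12)
        n, m, fams = 60, 400, 6
        estimates = []
        for _ in range(30):
            p = rng.uniform(0.2, 0.8, size=m)
            rows = []
            for f in range(fams):  # full-sib families: relatedness 0.5
                h1 = (rng.random((2, m)) < p).astype(float)
                h2 = (rng.random((2, m)) < p).astype(float)
                for _k in range(n // fams):
                    gam1 = h1[(rng.random(m) < 0.5).astype(int), np.arange(m)]
                    gam2 = h2[(rng.random(m) < 0.5).astype(int), np.arange(m)]
                    rows.append(gam1 + gam2)
            dos = pd.DataFrame(np.array(rows), index=[f"i{k}" for k in range(n)])
            K = eqtl.kinship(dos)
            Kj = K.to_numpy() + 1e-6 * np.eye(n)
            g = np.linalg.cholesky(Kj) @ rng.normal(size=n)
            e = rng.normal(0, np.sqrt(np.mean(np.diag(Kj))), size=n)  # h2 = 0.5
            y = pd.Series(g + e, index=dos.index)
            estimates.append(eqtl.heritability(y, K=K))
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.15)
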