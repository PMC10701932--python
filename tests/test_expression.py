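import numpy as np
import pandas as pd
import pytest

from cystra.expression import (
    ReferenceLocus,
    SequenceSetMatcher,
    assign_reads,
    collapse_unique,
    compare_libraries,
    contamination_filter,
    length_filter,
    normalize_counts,
    tmm_factors,
)
from cystra.simulate import ReadSimSpec, make_reference_loci, simulate_reads


class TestCollapse:
    def test_basic_collapse(self):
        t = collapse_unique({"lib": ["AAAA" * 15, "AAAA" * 15, "CCGG" * 15]})
        assert t.loc["AAAA" * 15, "lib"] == 2
        assert t.loc["CCGG" * 15, "lib"] == 1

    def test_shared_sequence_across_libraries(self):
        t = collapse_unique({"a": ["ACGT"], "b": ["ACGT", "ACGT"]})
        assert t.shape == (1, 2)
        assert t.loc["ACGT"].tolist() == [1, 2]

    def test_totals_preserved_from_simulation(self, loci_panel):
        libs, _ = simulate_reads(
            loci_panel, ReadSimSpec(depth=2000, seed=3)
        )
        t = collapse_unique(libs)
        for lib, reads in libs.items():
            assert t[lib].sum() == len(reads)

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning):
            t = collapse_unique({"a": ["ACGT"], "b": []})
        assert t["b"].sum() == 0


class TestLengthFilter:
    def test_bounds_inclusive(self):
        reads = {55 - 1: "A" * 54, 55: "C" * 55, 110: "G" * 110, 111: "T" * 111}
        t = collapse_unique({"lib": list(reads.values())})
        kept = length_filter(t)
        assert set(kept.index) == {reads[55], reads[110]}

    def test_empty_table(self):
        t = pd.DataFrame({"lib": []}, index=pd.Index([], name="read_seq"))
        assert len(length_filter(t)) == 0

    def test_thousand_row_recount(self):
        rng = np.random.default_rng(8)
        seqs = ["A" * int(n) for n in rng.integers(30, 150, 1000)]
        t = collapse_unique({"lib": seqs})
        kept = length_filter(t, 55, 110)
        brute = sum(1 for s in t.index if 55 <= len(s) <= 110)
        assert len(kept) == brute

    def test_invalid_bounds(self):
        t = collapse_unique({"lib": ["ACGT"]})
        with pytest.raises(ValueError):
            length_filter(t, 0, 10)


def toy_matrices():
    """The five TMM oracle matrices (regenerated bit-identically)."""
    mats = {}
    r = np.random.default_rng(101)
    a = r.integers(1, 200, size=(20, 1))
    mats["identical"] = np.hstack([a, a]).astype(float)
    r = np.random.default_rng(102)
    a = r.integers(1, 500, size=(20, 1))
    mats["doubled"] = np.hstack([a, 2 * a]).astype(float)
    r = np.random.default_rng(103)
    m = r.integers(20, 300, size=(20, 2)).astype(float)
    m[:, 1] = np.round(m[:, 0] * r.uniform(0.95, 1.05, size=20))
    m[:2, 1] = np.round(m[:2, 1] * 8)
    mats["inflated"] = m
    r = np.random.default_rng(104)
    mats["nb3"] = r.negative_binomial(2, 0.05, size=(50, 3)).astype(float)
    r = np.random.default_rng(105)
    mats["gamma4"] = np.round(r.gamma(2, 50, size=(30, 4)) * np.array([1, 2, 0.5, 1.5]))
    return mats


# factors computed once with an independent reference implementation of
# trimmed-mean-of-M-values normalization (edgeR 4.0.16 calcNormFactors)
TMM_ORACLE = {
    "identical": [1.0000000000, 1.0000000000],
    "doubled": [1.0000000000, 1.0000000000],
    "inflated": [1.2309230931, 0.8123984395],
    "nb3": [1.0929796863, 0.9155046539, 0.9993724047],
    "gamma4": [1.0359902328, 1.0389640388, 1.0510034668, 0.8839743730],
}


class TestTMM:
    @pytest.mark.parametrize("name", sorted(TMM_ORACLE))
    def test_matches_reference_implementation(self, name):
        X = toy_matrices()[name]
        df = pd.DataFrame(X, columns=[f"L{i}" for i in range(X.shape[1])])
        got = list(tmm_factors(df).factors.values())
        assert got == pytest.approx(TMM_ORACLE[name], abs=1e-6)

    def test_identical_libraries_factor_one(self):
        X = toy_matrices()["identical"]
        df = pd.DataFrame(X, columns=["a", "b"])
        assert list(tmm_factors(df).factors.values()) == [1.0, 1.0]

    def test_row_permutation_invariance(self):
        X = toy_matrices()["gamma4"]
        df = pd.DataFrame(X, columns=list("abcd"))
        rng = np.random.default_rng(1)
        perm = df.iloc[rng.permutation(len(df))]
        assert list(tmm_factors(df).factors.values()) == pytest.approx(
            list(tmm_factors(perm).factors.values())
        )

    def test_library_swap_gives_reciprocal_factors(self):
        X = toy_matrices()["inflated"]
        df = pd.DataFrame(X, columns=["a", "b"])
        f1 = tmm_factors(df).factors
        f2 = tmm_factors(df[["b", "a"]]).factors
        # geometric mean is 1, so the two-library factors are (f, 1/f);
        # swapping the libraries swaps the pair
        assert f1["a"] == pytest.approx(f2["a"], rel=1e-9)
        assert f1["a"] * f1["b"] == pytest.approx(1.0)

    def test_no_common_positive_rows_errors(self):
        df = pd.DataFrame({"a": [5, 0, 3], "b": [0, 7, 0]})
        with pytest.raises(ValueError, match="positive"):
            tmm_factors(df)

    def test_normalized_zero_iff_raw_zero(self):
        X = toy_matrices()["nb3"]
        df = pd.DataFrame(X, columns=list("abc"))
        normed = normalize_counts(df, tmm_factors(df))
        assert ((normed == 0) == (df == 0)).all().all()


class TestContaminationFilter:
    def test_accept_all_is_identity(self):
        t = collapse_unique({"lib": ["ACGT" * 20, "GGCC" * 20]})
        kept, removed = contamination_filter(t, lambda s: True)
        assert kept.equals(t) and removed == []

    def test_reject_all_empties_table(self):
        t = collapse_unique({"lib": ["ACGT" * 20]})
        kept, removed = contamination_filter(t, lambda s: False)
        assert len(kept) == 0 and len(removed) == 1

    def test_oracle_matcher_removes_exactly_contaminants(self, loci_panel):
        spec = ReadSimSpec(depth=3000, error_rate=0.0, contaminant_fraction=0.1, seed=5)
        libs, truth = simulate_reads(loci_panel, spec)
        contaminants = {
            r for lib in libs for r, k in zip(libs[lib], truth.klass[lib])
            if k == "contaminant"
        }
        t = collapse_unique(libs)
        kept, removed = contamination_filter(t, lambda s: s not in contaminants)
        assert set(removed) == {s for s in t.index if s in contaminants}
        assert not any(s in contaminants for s in kept.index)

    def test_matcher_failure_raises(self):
        t = collapse_unique({"lib": ["ACGT" * 20]})

        def broken(_):
            raise OSError("db down")

        with pytest.raises(RuntimeError, match="matcher failed"):
            contamination_filter(t, broken)

    def test_sequence_set_matcher_separates_real_from_random(self, loci_panel):
        matcher = SequenceSetMatcher([l.precursor_ref for l in loci_panel])
        body = loci_panel[0].mature_ref[:-3]
        assert matcher(body)
        rng = np.random.default_rng(44)
        randoms = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)]) for _ in range(5)
        ]
        assert sum(matcher(r) for r in randoms) <= 1  # permissive screen, rare hits ok


def two_locus_pair(template_seed=1):
    """Two loci sharing a mature sequence but with distinct genomic flanks."""
    loci = make_reference_loci(seed=template_seed)
    pair = [l for l in loci if l.variant_id == "var01"]
    assert len(pair) == 2
    return pair


class TestAssignReads:
    def test_mature_read_of_shared_variant_is_variant_only(self):
        pair = two_locus_pair()
        t = collapse_unique({"control": [pair[0].mature_ref], "deacylated": []})
        expr = assign_reads(t, pair)
        assert expr.genes.sum().sum() == 0
        assert expr.variants.loc["var01", "control"] == 1
        assert expr.accounting["control"]["variant_only"] == 1

    def test_precursor_read_discriminates_loci(self):
        pair = two_locus_pair()
        body = pair[0].mature_ref[:-3]
        read = pair[0].precursor_ref[pair[0].leader : pair[0].leader + len(body) + 8]
        t = collapse_unique({"control": [read], "deacylated": []})
        expr = assign_reads(t, pair)
        assert expr.genes.loc[pair[0].gene_id, "control"] == 1
        assert expr.genes.loc[pair[1].gene_id, "control"] == 0
        assert expr.accounting["control"]["gene_assigned"] == 1

    def test_low_scoring_read_left_unassigned(self):
        pair = two_locus_pair()
        t = collapse_unique({"control": ["AT" * 30], "deacylated": []})
        expr = assign_reads(t, pair)
        assert expr.accounting["control"]["unassigned"] == 1

    def test_count_conservation_identity(self, loci_panel, clean_read_sim):
        libs, _ = clean_read_sim
        t = length_filter(collapse_unique(libs))
        expr = assign_reads(t, loci_panel)
        for lib, acct in expr.accounting.items():
            assert (
                acct["gene_assigned"] + acct["variant_only"] + acct["multimapped"]
                + acct["unassigned"]
                == acct["input"]
                == int(t[lib].sum())
            )

    def test_empty_loci_errors(self):
        t = collapse_unique({"lib": ["ACGT"]})
        with pytest.raises(ValueError):
            assign_reads(t, [])


class TestCompareLibraries:
    def _expr_table(self, control, deacylated):
        pair = two_locus_pair()
        expr = assign_reads(
            collapse_unique({"control": ["ACGT" * 20], "deacylated": []}), pair
        )
        idx = expr.variants.index
        expr.normalized_variants = pd.DataFrame(
            {"control": control, "deacylated": deacylated}, index=idx[: len(control)]
        )
        return expr

    def test_flag_semantics(self):
        expr = self._expr_table([0.0], [0.0])
        flags = compare_libraries(expr)
        assert flags["undetected"].iloc[0]
        expr = self._expr_table([10.0], [20.0])
        flags = compare_libraries(expr)
        assert flags["charged"].iloc[0] and not flags["undetected"].iloc[0]
        expr = self._expr_table([0.0], [5.0])
        flags = compare_libraries(expr)
        assert flags["ambiguous"].iloc[0]

    def test_missing_library_errors(self):
        expr = self._expr_table([1.0], [2.0])
        expr.normalized_variants = expr.normalized_variants.rename(
            columns={"deacylated": "other"}
        )
        with pytest.raises(ValueError, match="deacylated"):
            compare_libraries(expr)

    def test_charged_flags_recover_simulated_charging(self, loci_panel):
        # one strongly charged gene against an uncharged background
        expr_vec = {l.gene_id: 50.0 for l in loci_panel}
        charged = {l.gene_id: 1.0 for l in loci_panel}
        charged[loci_panel[5].gene_id] = 3.0
        spec = ReadSimSpec(
            expression=expr_vec, charged_factor=charged, error_rate=0.0,
            contaminant_fraction=0.0, depth=20000, seed=9,
        )
        libs, _ = simulate_reads(loci_panel, spec)
        t = collapse_unique(libs)
        factors = tmm_factors(t)
        expr = assign_reads(length_filter(t), loci_panel)
        expr.normalize(factors, t.sum(axis=0).to_dict())
        flags = compare_libraries(expr)
        charged_variant = loci_panel[5].variant_id
        assert flags.loc[charged_variant, "charged"]


class TestReferenceLocus:
    def test_mature_must_end_in_cca(self):
        with pytest.raises(ValueError, match="CCA"):
            ReferenceLocus("g", "v", "ACGT" * 18, "A" * 30 + "ACGT" * 18 + "A" * 30)

    def test_precursor_must_embed_body(self):
        body = "ACGT" * 18
        with pytest.raises(ValueError, match="offset"):
            ReferenceLocus("g", "v", body + "CCA", "A" * 30 + "GGGG" + "A" * 30)
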