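"""RPKM arithmetic, group-specific calls, trait filter, NB exact test
(with edgeR as the independent reference), dispersion estimation, BH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from silkgland import synthetic_data as synth
from silkgland.family_expression import (
    bh_fdr,
    de_families,
    estimate_common_dispersion,
    family_count_matrix,
    family_expression_matrix,
    family_rpkm,
    group_specific_families,
    nb_exact_test,
    normalize_counts,
    significant_families,
    trait_filter,
    transcript_rpkm,
)
from silkgland.phylo_tools import pic_correlation

SIX = [s for s in synth.SPECIES if s != "B.mori"]
GROUPS = {s: synth.DEFAULT_GROUPS[s] for s in SIX}


@pytest.fixture(scope="module")
def six_species_tree():
    tree = synth.make_species_tree()
    return tree.extract_tree_with_taxa_labels(SIX)


class TestRPKM:
    def test_unit_case(self):
        assert transcript_rpkm(100, 1000, 1e6) == pytest.approx(100.0)

    def test_doubling_library_halves(self):
        assert transcript_rpkm(100, 1000, 2e6) == pytest.approx(50.0)

    def test_zero_reads_zero(self):
        assert transcript_rpkm(0, 500, 1e6) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            transcript_rpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            transcript_rpkm(10, 100, 0)

    def test_family_rpkm_two_member_worked_example(self):
        # (500 bp, 10 reads) + (1500 bp, 30 reads) at 1e6 mapped reads:
        # 40 reads / (2 kb * 1 M) = 20
        assert family_rpkm([10, 30], [500, 1500], 1e6) == pytest.approx(20.0)

    def test_single_member_reduces_to_transcript_rpkm(self):
        assert family_rpkm([7], [800], 2e6) == pytest.approx(
            transcript_rpkm(7, 800, 2e6)
        )

    def test_no_members_zero(self):
        assert family_rpkm([], [], 1e6) == 0.0

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=1000),
                st.integers(min_value=200, max_value=5000),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_invariant_to_member_repartition(self, members):
        # splitting any member into two half-length/half-reads records
        # cannot change the family value (only the totals matter)
        reads = [r for r, _ in members]
        lengths = [l for _, l in members]
        whole = family_rpkm(reads, lengths, 1e6)
        split_reads = [r / 2 for r in reads for _ in (0, 1)]
        split_lengths = [l / 2 for l in lengths for _ in (0, 1)]
        assert family_rpkm(split_reads, split_lengths, 1e6) == pytest.approx(whole)


def _toy_dataset(seed=0, n_families=12, group_only=None):
    tree = synth.make_species_tree()
    fams, _, _ = synth.simulate_families(tree, n_families, 0.0, 0.0, seed=seed)
    fams = fams[fams["species"] != "B.mori"].reset_index(drop=True)
    if group_only:
        keep = []
        for fam, sub in fams.groupby("family", sort=False):
            if fam in group_only:
                sub = sub[sub["species"].map(GROUPS) == group_only[fam]]
            keep.append(sub)
        fams = pd.concat(keep).reset_index(drop=True)
    counts, truth = synth.simulate_counts(
        fams, groups=GROUPS, n_de=0, seed=seed + 1, mean_expression=300.0
    )
    return fams, counts, truth


class TestFamilyMatrix:
    def test_absent_family_species_pair_is_zero(self):
        fams, counts, _ = _toy_dataset(seed=3, group_only={"fam0000": "colored"})
        mat = family_expression_matrix(fams, counts)
        for sp in SIX:
            if GROUPS[sp] == "noncolored":
                assert mat.loc["fam0000", sp] == 0.0
            else:
                assert mat.loc["fam0000", sp] > 0.0

    def test_group_specific_recovery_exact(self):
        planted = {"fam0000": "colored", "fam0001": "colored", "fam0002": "noncolored"}
        fams, counts, _ = _toy_dataset(seed=5, group_only=planted)
        mat = family_expression_matrix(fams, counts)
        sets = group_specific_families(mat, GROUPS, presence_min=1.0)
        assert sets["colored"] == {"fam0000", "fam0001"}
        assert sets["noncolored"] == {"fam0002"}

    def test_ubiquitous_family_in_neither_set(self):
        fams, counts, _ = _toy_dataset(seed=7)
        mat = family_expression_matrix(fams, counts)
        sets = group_specific_families(mat, GROUPS, presence_min=1.0)
        assert not sets["colored"] and not sets["noncolored"]


class TestTraitFilter:
    TRAIT = {s: 1.0 if GROUPS[s] == "colored" else 0.0 for s in SIX}

    def test_trait_mirroring_family_retained(self, six_species_tree):
        mat = pd.DataFrame(
            {s: [10.0 if GROUPS[s] == "colored" else 0.0] for s in SIX},
            index=["famX"],
        )
        retained, excluded = trait_filter(mat, six_species_tree, self.TRAIT)
        assert retained == {"famX"}

    def test_constant_family_excluded(self, six_species_tree):
        mat = pd.DataFrame({s: [5.0] for s in SIX}, index=["famC"])
        retained, excluded = trait_filter(mat, six_species_tree, self.TRAIT)
        assert excluded == {"famC"}

    def test_null_exclusion_rate_matches_level(self, six_species_tree, rng):
        # random RPKM profiles independent of the trait: exclusion rate
        # should approach 1 - alpha
        n = 400
        mat = pd.DataFrame(
            rng.lognormal(2, 1, size=(n, len(SIX))), columns=SIX,
            index=[f"f{i}" for i in range(n)],
        )
        retained, excluded = trait_filter(mat, six_species_tree, self.TRAIT, alpha=0.05)
        assert 0.90 <= len(excluded) / n <= 0.99


class TestNBExactTest:
    def test_identical_group_sums_p_one(self):
        assert nb_exact_test([5, 5, 5], [5, 5, 5], 0.2) == 1.0

    def test_poisson_limit_doubled_binomial_tail(self):
        from scipy import stats

        p = nb_exact_test([10, 0, 0], [0, 0, 0], dispersion=0.0)
        assert p == pytest.approx(2 * stats.binom.pmf(10, 10, 0.5))

    def test_all_zero_counts_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.2) == 1.0

    def test_matches_edgeR_exact_test(self, rng):
        phi, mu = 0.15, 120.0
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(25, 6))
        ours = [nb_exact_test(row[:3], row[3:], phi) for row in counts]
        np.savetxt("/tmp/_counts_edger.tsv", counts, fmt="%d", delimiter="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim('/tmp/_counts_edger.tsv', header=FALSE))
            d <- DGEList(counts=x, group=factor(rep(c('a','b'), each=3)),
                         lib.size=rep(1e6, 6))
            et <- exactTest(d, dispersion=0.15)
            cat(et$table$PValue, sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        theirs = [float(x) for x in out.stdout.split()]
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_type_one_error_calibrated(self, rng):
        phi, mu, reps = 0.2, 100.0, 1000
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(reps, 6))
        pvals = np.array([nb_exact_test(row[:3], row[3:], phi) for row in counts])
        rate = (pvals < 0.05).mean()
        assert 0.02 <= rate <= 0.08


class TestDispersion:
    def test_recovery_at_truth(self, rng):
        mu, phi = 100.0, 0.2
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(500, 6))
        est = estimate_common_dispersion(counts, ["a"] * 3 + ["b"] * 3)
        assert 0.1 <= est <= 0.3

    def test_poisson_data_near_zero(self, rng):
        counts = rng.poisson(80.0, size=(400, 6))
        est = estimate_common_dispersion(counts, ["a"] * 3 + ["b"] * 3)
        assert est <= 0.02

    def test_invariant_to_family_order(self, rng):
        counts = rng.negative_binomial(5, 0.05, size=(100, 6))
        labels = ["a"] * 3 + ["b"] * 3
        a = estimate_common_dispersion(counts, labels)
        b = estimate_common_dispersion(counts[::-1], labels)
        assert a == pytest.approx(b, rel=1e-6)

    def test_all_equal_counts_zero(self):
        counts = np.full((50, 6), 42.0)
        assert estimate_common_dispersion(counts, ["a"] * 3 + ["b"] * 3) == 0.0


class TestBH:
    def test_step_up_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_matches_step_up_arithmetic(self, rng):
        p = rng.uniform(size=50)
        # independent step-up: sort, p*(n/rank), enforce monotonicity
        order = np.argsort(p)
        n = len(p)
        scaled = p[order] * n / np.arange(1, n + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        q_expected = np.empty(n)
        q_expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), q_expected)

    def test_q_dominates_p(self, rng):
        p = rng.uniform(size=30)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDEPipeline:
    def test_significant_subset_of_tested(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(60, 6)),
            columns=SIX, index=[f"f{i}" for i in range(60)],
        ).astype(float)
        results = de_families(counts, GROUPS)
        assert significant_families(results) <= {r.family for r in results}
        assert all(r.fdr >= r.p - 1e-12 for r in results)

    def test_normalization_scales_to_geometric_mean(self):
        counts = pd.DataFrame({"a": [100.0], "b": [400.0]})
        libs = {"a": 1e6, "b": 4e6}
        norm = normalize_counts(counts, libs)
        assert norm.loc[0, "a"] == pytest.approx(200.0)
        assert norm.loc[0, "b"] == pytest.approx(200.0)

    def test_null_false_discoveries_controlled(self, rng):
        mu, phi = 100.0, 0.2
        r = 1 / phi
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(300, 6)),
            columns=SIX, index=[f"f{i}" for i in range(300)],
        ).astype(float)
        results = de_families(counts, GROUPS)
        assert len(significant_families(results, 0.05)) <= 10

    def test_planted_eightfold_families_found(self, rng):
        mu, phi, fold = 100.0, 0.2, 8.0
        r = 1 / phi
        n, n_de = 200, 20
        base = rng.negative_binomial(r, r / (r + mu), size=(n, 6)).astype(float)
        colored_cols = [i for i, s in enumerate(SIX) if GROUPS[s] == "colored"]
        for row in range(n_de):
            base[row, colored_cols] = rng.negative_binomial(
                r, r / (r + mu * fold), size=3
            )
        counts = pd.DataFrame(base, columns=SIX, index=[f"f{i}" for i in range(n)])
        results = de_families(counts, GROUPS)
        found = significant_families(results, 0.05)
        planted = {f"f{i}" for i in range(n_de)}
        assert len(found & planted) / n_de >= 0.8
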