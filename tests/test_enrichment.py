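"""Extreme-group selection and binomial enrichment with the constructed null."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import rtmra
from rtmra._stats import binom_tail_ge
from rtmra.binning import ValidationError
from rtmra.mutation_io import MutationRecord


def mut(gene, deleterious="yes", consequence="Missense_Mutation"):
    return MutationRecord(chrom="chr1", pos=0, ref="A", alt="G",
                          mclass="SNV", consequence=consequence,
                          deleterious=deleterious, gene=gene)


def cohort_with_deleterious(per_tumor):
    """per_tumor: {tumor: [(gene, deleterious), ...]}"""
    return {t: [mut(g, d) for g, d in items] for t, items in per_tumor.items()}


class TestSelectExtremeGroups:
    def test_floor_arithmetic_20_tumors(self):
        scores = pd.Series(np.arange(20, dtype=float),
                           index=[f"t{i:02d}" for i in range(20)])
        weak, strong = rtmra.select_extreme_groups(scores, 0.35)
        assert len(weak) == len(strong) == 7
        assert set(weak).isdisjoint(strong)

    def test_half_split(self):
        scores = pd.Series(np.arange(10, dtype=float),
                           index=[f"t{i}" for i in range(10)])
        weak, strong = rtmra.select_extreme_groups(scores, 0.5)
        assert len(weak) == len(strong) == 5
        assert set(weak) | set(strong) == set(scores.index)

    def test_membership_matches_sorting_oracle(self):
        rng = np.random.default_rng(21)
        scores = pd.Series(rng.normal(size=57),
                           index=[f"t{i:02d}" for i in range(57)])
        weak, strong = rtmra.select_extreme_groups(scores, 0.35)
        ranked = scores.sort_values(kind="mergesort")
        n_sel = int(np.floor(57 * 0.35))
        assert weak == list(ranked.index[:n_sel])
        assert strong == list(ranked.index[-n_sel:])

    def test_invalid_fraction(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValidationError):
            rtmra.select_extreme_groups(scores, 0.7)


class TestNullP:
    def test_balanced_and_skewed(self):
        muts = cohort_with_deleterious({
            "w1": [("A", "yes")] * 3, "s1": [("B", "yes")] * 3})
        assert rtmra.compute_null_p(["w1"], ["s1"], muts) == 0.5
        muts = cohort_with_deleterious({
            "w1": [("A", "yes")] * 300, "s1": [("B", "yes")] * 100})
        assert rtmra.compute_null_p(["w1"], ["s1"], muts) == 0.75

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(22)
        per_tumor = {}
        for i in range(30):
            items = [(f"G{rng.integers(10)}", "yes" if rng.random() < 0.3
                      else "no") for _ in range(rng.integers(5, 40))]
            per_tumor[f"t{i:02d}"] = items
        muts = cohort_with_deleterious(per_tumor)
        weak = [f"t{i:02d}" for i in range(15)]
        strong = [f"t{i:02d}" for i in range(15, 30)]
        dw = sum(1 for t in weak for _, d in per_tumor[t] if d == "yes")
        ds = sum(1 for t in strong for _, d in per_tumor[t] if d == "yes")
        assert rtmra.compute_null_p(weak, strong, muts) == dw / (dw + ds)

    def test_no_deleterious_is_error(self):
        muts = cohort_with_deleterious({"w": [("A", "no")], "s": [("B", "no")]})
        with pytest.raises(ValidationError):
            rtmra.compute_null_p(["w"], ["s"], muts)


class TestBinomialTail:
    def test_worked_case(self):
        assert binom_tail_ge(8, 10, 0.5) == pytest.approx(56 / 1024,
                                                          abs=1e-15)

    def test_k_zero_tail_is_one(self):
        assert binom_tail_ge(0, 5, 0.5) == 1.0

    @pytest.mark.parametrize("null_p", [0.25, 0.5, 0.75])
    def test_matches_exhaustive_enumeration(self, null_p):
        for n in range(1, 13):
            for k in range(n + 1):
                expect = sum(comb(n, j) * null_p**j * (1 - null_p) ** (n - j)
                             for j in range(k, n + 1))
                assert binom_tail_ge(k, n, null_p) == pytest.approx(
                    expect, abs=1e-12)


class TestPathwayEnrichment:
    def test_worked_pathway_case(self):
        muts = cohort_with_deleterious(
            {f"w{i}": [("PATH_GENE", "yes")] for i in range(8)}
            | {f"s{i}": [("PATH_GENE", "yes")] for i in range(2)}
        )
        weak = [f"w{i}" for i in range(8)]
        strong = [f"s{i}" for i in range(2)]
        res = rtmra.pathway_enrichment(weak, strong, {"PW": {"PATH_GENE"}},
                                       muts, null_p=0.5)
        assert res.loc[0, "p"] == pytest.approx(0.0546875, abs=1e-12)

    def test_empty_pathway_untested_p_one(self):
        muts = cohort_with_deleterious({"w": [("A", "yes")],
                                        "s": [("B", "yes")]})
        res = rtmra.pathway_enrichment(["w"], ["s"], {"PW": {"ZZZ"}}, muts,
                                       null_p=0.5)
        assert not res.loc[0, "tested"] and res.loc[0, "p"] == 1.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(23)
        per_tumor = {}
        for i in range(20):
            per_tumor[f"t{i:02d}"] = [(f"G{rng.integers(20)}", "yes")
                                      for _ in range(rng.integers(1, 10))]
        muts = cohort_with_deleterious(per_tumor)
        weak = [f"t{i:02d}" for i in range(10)]
        strong = [f"t{i:02d}" for i in range(10, 20)]
        catalog = {"PW": {f"G{j}" for j in range(8)}}
        null_p = rtmra.compute_null_p(weak, strong, muts)
        fwd = rtmra.pathway_enrichment(weak, strong, catalog, muts, null_p)
        rev = rtmra.pathway_enrichment(strong, weak, catalog, muts, 1 - null_p)
        k, n = fwd.loc[0, "count_weak"], fwd.loc[0, "count_weak"] + \
            fwd.loc[0, "count_strong"]
        assert rev.loc[0, "count_weak"] == n - k
        # P_rev[X >= n-k | 1-p] = P_fwd[X <= k | p]; the two tails overlap
        # exactly on the P[X = k] atom
        total = fwd.loc[0, "p"] + rev.loc[0, "p"]
        atom = comb(int(n), int(k)) * null_p**k * (1 - null_p) ** (n - k)
        assert total == pytest.approx(1 + atom, abs=1e-12)

    def test_dedupe_counts_tumor_gene_pairs_once(self):
        muts = cohort_with_deleterious({"w": [("A", "yes"), ("A", "yes")],
                                        "s": [("A", "yes")]})
        res = rtmra.pathway_enrichment(["w"], ["s"], {"PW": {"A"}}, muts, 0.5)
        assert res.loc[0, "count_weak"] == 1

    def test_null_calibration_and_random_gene_control(self):
        # under a global null, raw p < 0.05 in ~5% of pathways, and a
        # 500-random-gene control set stays non-significant after BH
        rng = np.random.default_rng(24)
        null_p = 0.5
        n_catalogs, n_pathways = 200, 10
        hits = total = 0
        for _ in range(n_catalogs):
            n_events = rng.poisson(150, size=n_pathways)
            k = rng.binomial(n_events, null_p)
            p = binom_tail_ge(k, n_events, null_p)
            hits += (p < 0.05).sum()
            total += n_pathways
        assert 0.03 <= hits / total <= 0.07

    def test_subpathway_reruns_within_parent(self):
        muts = cohort_with_deleterious({
            "w": [("A", "yes"), ("B", "yes")], "s": [("A", "yes")]})
        catalog = {"child1": {"A"}, "child2": {"B"}}
        hierarchy = pd.DataFrame({"parent": ["DNA_repair"] * 2,
                                  "child": ["child1", "child2"]})
        res = rtmra.subpathway_enrichment(["w"], ["s"], catalog, hierarchy,
                                          muts, 0.5)
        assert set(res["parent"]) == {"DNA_repair"}
        assert len(res) == 2


class TestGeneEnrichment:
    def test_per_100k_normalization(self):
        per_tumor = {"w": [("TP53", "yes")] * 5 + [("OTHER", "no")] * 49995,
                     "s": [("TP53", "yes")] * 2 + [("OTHER", "no")] * 49998}
        muts = cohort_with_deleterious(per_tumor)
        res = rtmra.gene_enrichment(["w"], ["s"], muts, 0.5)
        row = res.set_index("unit").loc["TP53"]
        assert row["norm_weak_per_100k"] == pytest.approx(10.0)

    def test_planted_genes_rank_high(self):
        rng = np.random.default_rng(25)
        planted = {f"HOT{j}" for j in range(10)}
        background = [f"G{j}" for j in range(90)]
        per_tumor = {}
        for i in range(40):
            weak_tumor = i < 20
            items = []
            for _ in range(60):
                if rng.random() < 0.10:
                    g = rng.choice(sorted(planted))
                    # planted genes mutate 3x more often in weak tumors
                    if weak_tumor or rng.random() < 1 / 3:
                        items.append((g, "yes"))
                else:
                    items.append((rng.choice(background), "yes"))
            per_tumor[f"t{i:02d}"] = items
        muts = cohort_with_deleterious(per_tumor)
        weak = [f"t{i:02d}" for i in range(20)]
        strong = [f"t{i:02d}" for i in range(20, 40)]
        null_p = rtmra.compute_null_p(weak, strong, muts)
        res = rtmra.gene_enrichment(weak, strong, muts, null_p)
        top_decile = res.sort_values("p").head(len(res) // 10)["unit"]
        assert len(set(top_decile) & planted) >= 5


class TestNeoantigenCounting:
    def test_membership_counting(self):
        muts = [mut("A", consequence=c) for c in
                ["Missense_Mutation"] * 3 + ["Silent"] * 2]
        assert rtmra.count_neoantigen_mutations(muts) == 3
        assert rtmra.count_neoantigen_mutations([]) == 0

    def test_space_and_case_normalization(self):
        muts = [mut("A", consequence="Frame Shift Del"),
                mut("B", consequence="splice site")]
        assert rtmra.count_neoantigen_mutations(muts) == 2

    def test_random_labels_match_set_membership(self):
        from rtmra.mutation_io import NEOANTIGEN_CLASSES, \
            canonical_consequence
        rng = np.random.default_rng(26)
        vocab = ["Missense_Mutation", "Silent", "IGR", "Splice_Region",
                 "Nonsense_Mutation", "3'UTR", "Intron", "In_Frame_Del"]
        labels = rng.choice(vocab, size=500)
        muts = [mut("A", consequence=c) for c in labels]
        expect = sum(canonical_consequence(c) in NEOANTIGEN_CLASSES
                     for c in labels)
        assert rtmra.count_neoantigen_mutations(muts) == expect

    def test_missing_consequence_is_error(self):
        muts = [MutationRecord("chr1", 0, "A", "G", "SNV")]
        with pytest.raises(ValidationError):
            rtmra.count_neoantigen_mutations(muts)


class TestGroupCovariateTests:
    @staticmethod
    def table(vals_w, vals_s, project="P"):
        rows = []
        for i, v in enumerate(vals_w):
            rows.append({"tumor_id": f"w{i}", "project": project, "load": v})
        for i, v in enumerate(vals_s):
            rows.append({"tumor_id": f"s{i}", "project": project, "load": v})
        return pd.DataFrame(rows).set_index("tumor_id")

    def test_identical_groups_half(self):
        t = self.table([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        res = rtmra.group_covariate_tests(["w0", "w1", "w2"],
                                          ["s0", "s1", "s2"], t, "load")
        assert res.loc[0, "p"] == pytest.approx(0.5)

    def test_planted_shift_power(self):
        rng = np.random.default_rng(27)
        hits = 0
        n_seeds = 20
        for _ in range(n_seeds):
            t = self.table(rng.normal(2.0, 1.0, 30), rng.normal(0.0, 1.0, 30))
            res = rtmra.group_covariate_tests(
                [f"w{i}" for i in range(30)], [f"s{i}" for i in range(30)],
                t, "load")
            hits += res.loc[0, "p_adj"] < 0.1
        assert hits >= int(0.95 * n_seeds)

    def test_chi_square_symmetric_table(self):
        msi = pd.Series([True] * 10 + [False] * 10,
                        index=[f"w{i}" for i in range(10)]
                        + [f"s{i}" for i in range(10)])
        res = rtmra.msi_test([f"w{i}" for i in range(10)],
                             [f"s{i}" for i in range(10)], msi)
        assert res["chi2"] == pytest.approx(20.0)
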