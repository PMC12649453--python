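"""Genotype-group summaries, ANOVA, pairwise tests and letter displays."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flockgene.association import (
    anova_oneway,
    associate_all,
    associate_locus,
    group_summaries,
    letter_display,
    pairwise_comparisons,
)
from flockgene.simulate import PAPER_PANEL, twin_composition
from _oracles import anova_oracle, letters_consistent


def _letters_partition(letters: dict) -> set:
    """Groups sharing any letter merged into blocks (relabel-invariant),
    by union-find over the sharing relation."""
    labels = list(letters)
    parent = {g: g for g in labels}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, g in enumerate(labels):
        for h in labels[i + 1 :]:
            if set(letters[g]) & set(letters[h]):
                parent[find(h)] = find(g)
    blocks: dict = {}
    for g in labels:
        blocks.setdefault(find(g), set()).add(g)
    return {frozenset(b) for b in blocks.values()}


class TestGroupSummaries:
    @pytest.mark.parametrize(
        "locus,genotype,n,mean,sd",
        [
            ("g.18202368 A>T", "AA", 150, 1.52, 0.501),
            ("g.18202368 A>T", "AT", 7, 1.14, 0.378),
            ("g.18202372 G>A", "GG", 92, 1.27, 0.447),
            ("g.18202372 G>A", "GA", 59, 1.83, 0.378),
            ("g.18202372 G>A", "AA", 6, 1.83, 0.408),
        ],
    )
    def test_published_cells(self, paper_cohorts, locus, genotype, n, mean, sd):
        groups = {g.genotype: g for g in group_summaries(paper_cohorts[locus], locus)}
        g = groups[genotype]
        assert g.n == n
        assert round(g.mean, 2) == mean
        assert round(g.sd, 3) == sd

    def test_identical_litters_zero_sd(self, small_panel):
        from flockgene.model import Cohort

        ids = pd.Index([f"E{i}" for i in range(5)], name="animal_id")
        geno = pd.DataFrame(
            {small_panel[0].id: ["G/G"] * 5, small_panel[1].id: ["C/C"] * 5}, index=ids
        )
        pheno = pd.DataFrame({"litter_size": [2] * 5}, index=ids)
        cohort = Cohort(small_panel, geno, pheno)
        g = group_summaries(cohort, small_panel[0].id)[0]
        assert g.sd == 0.0

    def test_binary_sd_closed_form_on_all_cells(self, paper_cohorts):
        # for litter sizes in {1, 2}: sd = sqrt(n m (1-m) / (n-1)), m = twin share
        for lid, pl in PAPER_PANEL.items():
            twins, _ = twin_composition(lid)
            sizes = [n for n in pl.counts if n > 0]
            for g, (n, t) in zip(group_summaries(paper_cohorts[lid], lid), zip(sizes, twins)):
                m = t / n
                expect = np.sqrt(n * m * (1 - m) / (n - 1)) if n > 1 else 0.0
                assert g.sd == pytest.approx(expect, abs=1e-12)

    def test_weighted_group_means_reproduce_cohort_mean(self, paper_cohorts):
        for lid, cohort in paper_cohorts.items():
            groups = group_summaries(cohort, lid)
            weighted = sum(g.n * g.mean for g in groups) / sum(g.n for g in groups)
            assert weighted == pytest.approx(cohort.phenotypes["litter_size"].mean())


class TestAnova:
    def test_identical_groups(self):
        F, p = anova_oneway([np.array([1.0, 2.0, 1.0]), np.array([1.0, 2.0, 1.0])])
        assert (F, p) == (0.0, 1.0)

    def test_matches_scipy_and_oracle(self, rng):
        groups = [rng.normal(size=n) for n in (8, 12, 5)]
        F, p = anova_oneway(groups)
        F2, p2 = stats.f_oneway(*groups)
        assert F == pytest.approx(F2)
        assert p == pytest.approx(p2)
        assert F == pytest.approx(anova_oracle(groups))

    def test_reconstructed_association_is_highly_significant(self, paper_cohorts):
        lid = "g.18202372 G>A"
        table = associate_locus(paper_cohorts[lid], lid)
        assert table.anova_p < 0.01

    def test_type_one_error_calibration(self, rng):
        reps, alpha, hits = 2000, 0.05, 0
        for _ in range(reps):
            groups = [1 + (rng.random(n) < 0.5).astype(float) for n in (90, 60, 7)]
            _, p = anova_oneway(groups)
            hits += p < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 2.58 * se + 1e-9


class TestPairwise:
    def test_identical_groups_p_one(self):
        g = {"a": np.array([1.0, 2.0]), "b": np.array([1.0, 2.0])}
        pmat = pairwise_comparisons(g)
        assert pmat.loc["a", "b"] == 1.0

    def test_symmetric_unit_diagonal(self, rng):
        g = {k: rng.normal(size=10) for k in "abc"}
        pmat = pairwise_comparisons(g)
        assert np.allclose(pmat.values, pmat.values.T)
        assert np.allclose(np.diag(pmat.values), 1.0)

    def test_gg_vs_ga_contrast_highly_significant(self, paper_cohorts):
        lid = "g.18202372 G>A"
        df = paper_cohorts[lid].litter_sizes(lid)
        groups = {
            g: sub["litter_size"].to_numpy(dtype=float)
            for g, sub in df.groupby("genotype")
        }
        pmat = pairwise_comparisons(groups, method="lsd")
        assert pmat.loc["GG", "GA"] < 0.01

    def test_bonferroni_never_smaller_than_lsd(self, rng):
        g = {k: rng.normal(loc=i, size=6) for i, k in enumerate("abcd")}
        lsd = pairwise_comparisons(g, method="lsd")
        bon = pairwise_comparisons(g, method="bonferroni")
        assert (bon.values >= lsd.values - 1e-12).all()

    def test_tukey_matches_statsmodels(self, rng):
        from itertools import combinations

        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        g = {k: rng.normal(loc=i * 0.5, size=7) for i, k in enumerate("abc")}
        pmat = pairwise_comparisons(g, method="tukey")
        data = np.concatenate(list(g.values()))
        labels = np.repeat(list(g), [len(v) for v in g.values()])
        sm = pairwise_tukeyhsd(data, labels)
        for (a, b), p_sm in zip(combinations(sm.groupsunique, 2), sm.pvalues):
            assert pmat.loc[a, b] == pytest.approx(p_sm, abs=1e-6)


class TestLetterDisplay:
    def test_published_patterns(self, paper_cohorts):
        lid = "g.18202372 G>A"
        table = associate_locus(paper_cohorts[lid], lid)
        letters = {g.genotype: g.letters_01 for g in table.groups}
        assert _letters_partition(letters) == {
            frozenset({"GG"}),
            frozenset({"GA", "AA"}),
        }

    def test_no_significant_pairs_share_one_letter(self, paper_cohorts):
        lid = "g.18202426 C>T"
        table = associate_locus(paper_cohorts[lid], lid)
        letters = {g.genotype: g.letters_05 for g in table.groups if g.tested}
        assert len({v for v in letters.values()}) == 1

    def test_single_group_single_letter(self):
        pmat = pd.DataFrame([[1.0]], index=["x"], columns=["x"])
        assert letter_display(pmat, 0.05, {"x": 1.0}) == {"x": "a"}

    def test_random_matrices_match_sharing_relation(self, rng):
        for _ in range(300):
            k = rng.integers(2, 7)
            labels = [f"g{i}" for i in range(k)]
            pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
            means = {g: float(rng.normal()) for g in labels}
            for i in range(k):
                for j in range(i + 1, k):
                    p = float(rng.random())
                    pmat.iloc[i, j] = pmat.iloc[j, i] = p
            letters = letter_display(pmat, alpha=0.3, means=means)
            assert letters_consistent(pmat, letters, alpha=0.3)
            assert all(v for v in letters.values())  # everyone gets a letter


class TestExclusionRule:
    def test_small_groups_summarized_not_tested(self, small_panel):
        from flockgene.model import Cohort

        ids = pd.Index([f"E{i}" for i in range(12)], name="animal_id")
        geno = pd.DataFrame(
            {
                small_panel[0].id: ["G/G"] * 6 + ["G/A"] * 4 + ["A/A"] * 2,
                small_panel[1].id: ["C/C"] * 12,
            },
            index=ids,
        )
        pheno = pd.DataFrame({"litter_size": [1, 2] * 6}, index=ids)
        cohort = Cohort(small_panel, geno, pheno)
        table = associate_locus(cohort, small_panel[0].id, min_group_n=3)
        by_geno = {g.genotype: g for g in table.groups}
        assert table.excluded_groups == ("AA",)
        assert not by_geno["AA"].tested
        assert by_geno["AA"].letters_05 == ""
        assert by_geno["GG"].tested and by_geno["GA"].tested

    def test_published_min_group_rule(self, paper_cohorts):
        tables = associate_all(paper_cohorts["g.18202368 A>T"])
        at = {g.genotype: g for g in tables[0].groups}["AT"]
        assert at.n == 7 and at.tested  # n >= 3 is tested even if small

    def test_single_class_not_testable(self, small_panel):
        from flockgene.model import Cohort

        ids = pd.Index(["E0", "E1", "E2"], name="animal_id")
        geno = pd.DataFrame(
            {small_panel[0].id: ["G/G"] * 3, small_panel[1].id: ["C/C"] * 3}, index=ids
        )
        pheno = pd.DataFrame({"litter_size": [1, 2, 1]}, index=ids)
        table = associate_locus(Cohort(small_panel, geno, pheno), small_panel[0].id)
        assert not table.testable
        assert np.isnan(table.anova_F)

    def test_null_effect_false_positive_rate(self, rng):
        # per-locus false-positive rate of the full association stage
        from flockgene.model import Cohort

        reps, hits, alpha = 400, 0, 0.05
        for _ in range(reps):
            n = 120
            dosage = rng.binomial(2, 0.3, size=n)
            geno_str = np.array(["G/G", "G/A", "A/A"])[dosage]
            ids = pd.Index([f"E{i}" for i in range(n)], name="animal_id")
            geno = pd.DataFrame({"x G>A": geno_str}, index=ids)
            pheno = pd.DataFrame(
                {"litter_size": 1 + (rng.random(n) < 0.5).astype(int)}, index=ids
            )
            cohort = Cohort([type(self)._locus()], geno, pheno)
            table = associate_locus(cohort, "x G>A")
            if table.testable and table.anova_p < alpha:
                hits += 1
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 3 * se + 1e-9

    @staticmethod
    def _locus():
        from flockgene.model import Locus

        return Locus("x G>A", "G", "A")
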