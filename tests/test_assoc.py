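from math import comb

import numpy as np
import pandas as pd
import pytest

from lipdiff.assoc import (
    covariate_enrichment,
    fisher_exact_2x2,
    label_site_proximity,
    protein_contingency,
    ptm_proximity_fractions,
    site_contingency,
    site_level_frequency,
    topology_enrichment,
)


def fisher_p_by_enumeration(a, b, c, d):
    """Exhaustive hypergeometric oracle for the two-sided exact test:
    sum the probabilities of all tables with the same margins whose
    probability does not exceed the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):  # table with a = x
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return None
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        px = prob(x)
        if px is not None and px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestFisherExact:
    def test_worked_example(self):
        odds, p = fisher_exact_2x2(3, 1, 1, 3)
        assert odds == pytest.approx(9.0)
        assert p == pytest.approx(34 / 70, abs=1e-9)

    def test_balanced_table_is_null(self):
        for k in (1, 3, 10):
            odds, p = fisher_exact_2x2(k, k, k, k)
            assert odds == pytest.approx(1.0)
            assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        odds, p = fisher_exact_2x2(5, 0, 0, 5)
        assert np.isinf(odds)
        assert p == pytest.approx(2 / comb(10, 5), abs=1e-12)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)

    def test_matches_enumeration_sampled(self):
        """Spot-check against the exhaustive hypergeometric oracle across the
        N <= 30 simplex (the full sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(1, 31))
            cuts = np.sort(rng.integers(0, n + 1, 3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(
                fisher_p_by_enumeration(int(a), int(b), int(c), int(d)),
                abs=1e-9,
            )


class TestProteinContingency:
    def _calls(self, mapping):
        return pd.DataFrame(
            [{"protein": p, "call": c} for p, c in mapping.items()]
        )

    def test_marginal_frequencies_and_fold_ratio(self):
        # reference rows with call-frequencies 16% (called-in-B) and 6%
        calls_b = {}
        calls_a = {}
        for i in range(50):  # 50 proteins called in B, 8 of them called in A
            calls_b[f"N{i}"] = "called"
            calls_a[f"N{i}"] = "called" if i < 8 else "not_called"
        for i in range(100):  # 100 not called in B, 6 called in A
            calls_b[f"R{i}"] = "not_called"
            calls_a[f"R{i}"] = "called" if i < 6 else "not_called"
        table, marg = protein_contingency(
            self._calls(calls_a), self._calls(calls_b)
        )
        assert marg["frequency_a_called_given_b_called"] == pytest.approx(0.16)
        assert marg["frequency_a_called_given_not_b_called"] == pytest.approx(0.06)
        assert round(marg["fold_ratio"], 1) == 2.7

    def test_only_jointly_assessed_proteins_enter(self):
        a = self._calls({"X": "called", "Y": "called", "Z": "insufficient"})
        b = self._calls({"X": "not_called", "Z": "called", "W": "called"})
        table, marg = protein_contingency(a, b)
        assert marg["n_common"] == 1  # only X assessed in both

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError):
            protein_contingency(
                self._calls({"X": "called"}), self._calls({"Y": "called"})
            )

    def test_identical_calls_give_infinite_odds(self):
        calls = self._calls(
            {f"P{i}": ("called" if i < 5 else "not_called") for i in range(20)}
        )
        table, _ = protein_contingency(calls, calls)
        assert np.isinf(table.odds_ratio)

    def test_independent_calls_give_odds_near_one(self):
        rng = np.random.default_rng(42)
        odds = []
        for _ in range(20):
            a = {f"P{i}": ("called" if rng.random() < 0.3 else "not_called")
                 for i in range(300)}
            b = {f"P{i}": ("called" if rng.random() < 0.3 else "not_called")
                 for i in range(300)}
            t, _ = protein_contingency(self._calls(a), self._calls(b))
            if np.isfinite(t.odds_ratio) and t.odds_ratio > 0:
                odds.append(np.log(t.odds_ratio))
        assert abs(np.mean(odds)) < 0.15

    def test_fold_ratio_reciprocal_under_row_swap(self):
        a = self._calls({f"P{i}": ("called" if i % 3 == 0 else "not_called")
                         for i in range(60)})
        b = self._calls({f"P{i}": ("called" if i % 4 == 0 else "not_called")
                         for i in range(60)})
        _, m1 = protein_contingency(a, b)
        b_swapped = b.copy()
        b_swapped["call"] = b_swapped["call"].map(
            {"called": "not_called", "not_called": "called"}
        )
        _, m2 = protein_contingency(a, b_swapped)
        assert m1["fold_ratio"] == pytest.approx(1 / m2["fold_ratio"])


def brute_force_proximity(site, sig_refs, non_refs, window):
    near_sig = any(abs(site - r) <= window for r in sig_refs)
    near_non = any(abs(site - r) <= window for r in non_refs)
    return {
        (True, True): "both", (True, False): "uniquely_near_sig",
        (False, True): "uniquely_near_nonsig", (False, False): "neither",
    }[(near_sig, near_non)]


class TestSiteProximity:
    @pytest.mark.parametrize("site, sig, non, expected", [
        (100, [104], [120], "uniquely_near_sig"),
        (100, [104], [97], "both"),
        (100, [106], [], "neither"),      # 6 > 5
        (100, [105], [], "uniquely_near_sig"),  # boundary: 5 <= 5
        (100, [], [100], "uniquely_near_nonsig"),
    ])
    def test_examples(self, site, sig, non, expected):
        assert label_site_proximity(site, sig, non, window=5) == expected

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            site = int(rng.integers(1, 200))
            sig = rng.integers(1, 200, rng.integers(0, 5)).tolist()
            non = rng.integers(1, 200, rng.integers(0, 5)).tolist()
            w = int(rng.integers(0, 10))
            assert label_site_proximity(site, sig, non, w) == \
                brute_force_proximity(site, sig, non, w)

    def test_enlarging_window_never_loses_nearness(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            site = int(rng.integers(1, 100))
            sig = rng.integers(1, 100, 3).tolist()
            non = rng.integers(1, 100, 3).tolist()
            near_small = label_site_proximity(site, sig, non, 3) != "neither"
            near_large = label_site_proximity(site, sig, non, 8) != "neither"
            assert near_large >= near_small


def sites_frame(records):
    return pd.DataFrame(records, columns=["protein", "residue_index", "significant"])


class TestSiteContingency:
    def test_perfect_association_toy(self):
        query = sites_frame([("P", 100, True), ("P", 200, False)])
        ref = sites_frame([("P", 103, True), ("P", 198, False)])
        table, _ = site_contingency(query, ref, window=5)
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 1)
        assert np.isinf(table.odds_ratio)

    def test_both_and_neither_are_excluded(self):
        query = sites_frame([
            ("P", 100, True),   # near both -> excluded
            ("P", 300, True),   # near neither -> excluded
            ("P", 200, False),  # uniquely near nonsig
        ])
        ref = sites_frame([
            ("P", 102, True), ("P", 98, False), ("P", 203, False),
        ])
        table, summary = site_contingency(query, ref, window=5)
        assert table.a + table.b + table.c + table.d == 1
        row = summary.set_index("row")
        assert row.loc[True, "both"] == 1
        assert row.loc[True, "neither"] == 1

    def test_null_placement_gives_similar_row_fractions(self):
        rng = np.random.default_rng(3)
        q_rows, r_rows = [], []
        for p in range(200):
            prot = f"P{p}"
            for r in rng.integers(1, 400, 6):
                r_rows.append((prot, int(r), bool(rng.random() < 0.5)))
            for s in rng.integers(1, 400, 4):
                q_rows.append((prot, int(s), bool(rng.random() < 0.3)))
        table, summary = site_contingency(
            sites_frame(q_rows), sites_frame(r_rows), window=5
        )
        fr = summary.set_index("row")["fraction_uniquely_near_sig"]
        assert fr[True] == pytest.approx(fr[False], abs=0.08)
        assert table.p_two_sided > 1e-4

    def test_window_zero_is_a_subset_of_window_five(self):
        rng = np.random.default_rng(4)
        q_rows = [("P", int(r), True) for r in rng.integers(1, 100, 10)]
        r_rows = [("P", int(r), bool(i % 2)) for i, r in
                  enumerate(rng.integers(1, 100, 10))]
        t0, s0 = site_contingency(sites_frame(q_rows), sites_frame(r_rows), 0)
        t5, s5 = site_contingency(sites_frame(q_rows), sites_frame(r_rows), 5)
        included0 = t0.a + t0.b + t0.c + t0.d
        # widening the window can only move sites out of `neither`
        n_neither0 = s0.set_index("row")["neither"].sum()
        n_neither5 = s5.set_index("row")["neither"].sum()
        assert n_neither5 <= n_neither0


class TestPtmProximity:
    def _ptm(self, records):
        return pd.DataFrame(records, columns=["accession", "residue_index", "kind"])

    def test_window_boundary(self):
        sites = sites_frame([("P", 50, True), ("P", 50, False)])
        near = self._ptm([("P", 64, "phospho")])   # 14 <= 15
        far = self._ptm([("P", 66, "phospho")])    # 16 > 15
        out_near = ptm_proximity_fractions(sites, near).iloc[0]
        out_far = ptm_proximity_fractions(sites, far).iloc[0]
        assert out_near["fraction_significant_proximal"] == 1.0
        assert out_far["fraction_significant_proximal"] == 0.0

    def test_empty_ptm_list_gives_zero_fractions(self):
        sites = sites_frame([("P", 50, True), ("P", 80, False)])
        out = ptm_proximity_fractions(sites, self._ptm([])).iloc[0]
        assert out["fraction_significant_proximal"] == 0.0
        assert out["fraction_nonsignificant_proximal"] == 0.0

    def test_kinds_reported_separately(self):
        sites = sites_frame([("P", 50, True)])
        ptm = self._ptm([("P", 55, "phospho"), ("P", 300, "oxidation")])
        out = ptm_proximity_fractions(sites, ptm).set_index("kind")
        assert out.loc["phospho", "fraction_significant_proximal"] == 1.0
        assert out.loc["oxidation", "fraction_significant_proximal"] == 0.0


class TestCovariateEnrichment:
    def _annotation(self, n, rng):
        return pd.DataFrame({
            "accession": [f"P{i}" for i in range(n)],
            "percent_disorder": rng.uniform(0, 100, n),
        })

    def test_uniform_calls_are_independent(self):
        rng = np.random.default_rng(5)
        n = 600
        ann = self._annotation(n, rng)
        calls = pd.DataFrame({
            "protein": ann["accession"],
            "call": np.where(rng.random(n) < 0.25, "called", "not_called"),
        })
        per_bin, p = covariate_enrichment(calls, ann, "percent_disorder")
        assert p > 0.001
        assert per_bin["fraction_called"].std() < 0.15

    def test_planted_single_bin_enrichment_detected(self):
        rng = np.random.default_rng(6)
        n = 500
        ann = self._annotation(n, rng)
        in_first = ann["percent_disorder"] <= 10
        calls = pd.DataFrame({
            "protein": ann["accession"],
            "call": np.where(in_first, "called", "not_called"),
        })
        per_bin, p = covariate_enrichment(calls, ann, "percent_disorder")
        assert p < 1e-6

    def test_monotone_planted_trend_recovered(self):
        rng = np.random.default_rng(7)
        n = 6000
        ann = pd.DataFrame({
            "accession": [f"P{i}" for i in range(n)],
            "lifetime_days": rng.uniform(1, 64, n),
        })
        prob = 0.02 + 0.28 * (ann["lifetime_days"] / 64)
        calls = pd.DataFrame({
            "protein": ann["accession"],
            "call": np.where(rng.random(n) < prob, "called", "not_called"),
        })
        per_bin, p = covariate_enrichment(
            calls, ann, "lifetime_days", bins=(0, 4, 16, 32, 64)
        )
        fr = per_bin["fraction_called"].to_numpy()
        assert (np.diff(fr) > -0.02).all()
        assert fr[-1] > fr[0]

    def test_topology_memberships_tested_one_vs_rest(self):
        rng = np.random.default_rng(8)
        n = 300
        ann = pd.DataFrame({
            "accession": [f"P{i}" for i in range(n)],
            "topologies": [
                ("TIM-barrel",) if i < 100 else ("SH3",) if i < 200 else
                ("TIM-barrel", "SH3") for i in range(n)
            ],
        })
        calls = pd.DataFrame({
            "protein": ann["accession"],
            "call": ["called" if i < 100 else "not_called" for i in range(n)],
        })
        out = topology_enrichment(calls, ann).set_index("topology")
        assert out.loc["TIM-barrel", "chi2_p"] < 1e-6
        assert out.loc["TIM-barrel", "n_members"] == 200


class TestSiteLevelFrequency:
    def _peptides(self, sites_sig):
        return pd.DataFrame({
            "protein": [p for p, _, _ in sites_sig],
            "peptide": [f"PEP{i}K" for i in range(len(sites_sig))],
            "site": [s for _, s, _ in sites_sig],
            "significant": [b for _, _, b in sites_sig],
        })

    def _annotation(self, proteins):
        return pd.DataFrame({
            "accession": list(proteins),
            "percent_disorder": np.linspace(5, 95, len(proteins)),
        })

    def test_all_significant_gives_unit_fractions(self):
        pep = self._peptides([("P1", 10, True), ("P2", 20, True)])
        out = site_level_frequency(pep, self._annotation(["P1", "P2"]),
                                   "percent_disorder")
        assert (out["fraction_significant"] == 1.0).all()

    def test_none_significant_gives_zero_fractions(self):
        pep = self._peptides([("P1", 10, False), ("P2", 20, False)])
        out = site_level_frequency(pep, self._annotation(["P1", "P2"]),
                                   "percent_disorder")
        assert (out["fraction_significant"] == 0.0).all()

    def test_duplicate_sites_deduplicated_but_counted(self):
        pep = self._peptides([("P1", 10, True), ("P1", 10, False)])
        out = site_level_frequency(pep, self._annotation(["P1"]),
                                   "percent_disorder")
        assert out["n_sites"].sum() == 1
        assert out["n_site_records"].sum() == 2
        assert out["fraction_significant"].iloc[0] == 1.0

    def test_per_bin_probability_recovered(self):
        rng = np.random.default_rng(9)
        records = []
        proteins = []
        for i in range(400):
            prot = f"P{i}"
            proteins.append(prot)
            disorder = (i % 10) * 10 + 5.0
            p_sig = 0.05 + 0.004 * disorder  # linear in disorder
            for s in range(5):
                records.append((prot, 10 * (s + 1), bool(rng.random() < p_sig)))
        pep = self._peptides(records)
        ann = pd.DataFrame({
            "accession": proteins,
            "percent_disorder": [(int(p[1:]) % 10) * 10 + 5.0 for p in proteins],
        })
        out = site_level_frequency(pep, ann, "percent_disorder")
        out = out.sort_values("bin")
        for _, row in out.iterrows():
            lo = float(row["bin"].split(",")[0].strip("([ "))
            expected = 0.05 + 0.004 * (lo + 5.0)
            n = row["n_sites"]
            se = np.sqrt(expected * (1 - expected) / n)
            assert row["fraction_significant"] == pytest.approx(
                expected, abs=4 * se + 0.01
            )
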