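"""Frequency table, percentile selection, filter cascade, over-representation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protprio import (
    GeneSetCollection,
    StudyDesign,
    ValidationError,
    disease_frequency,
    filter_cascade,
    fold_changes,
    frequency_table,
    percentile_select,
    term_overrepresentation,
)


def _enr(components, significant=None):
    """Build an enrichment table from component member lists."""
    significant = significant or [True] * len(components)
    return pd.DataFrame(
        {
            "set": [f"S{i}" for i in range(len(components))],
            "significant": significant,
            "component": ["|".join(c) for c in components],
        }
    )


class TestFrequencyTable:
    def test_single_pathway_all_members_frequency_one(self):
        freq = frequency_table([_enr([["A", "B", "C"]])])
        assert freq.to_dict() == {"A": 1, "B": 1, "C": 1}

    def test_hand_counted_example(self):
        freq = frequency_table([_enr([["A", "B"], ["B", "C"], ["B"]])])
        assert freq.to_dict() == {"A": 1, "B": 3, "C": 1}

    def test_nonsignificant_pathways_ignored(self):
        freq = frequency_table([_enr([["A"], ["B"]], significant=[True, False])])
        assert freq.to_dict() == {"A": 1}

    def test_no_significant_pathways_empty(self):
        assert len(frequency_table([_enr([["A"]], significant=[False])])) == 0

    def test_matches_nested_loop_bruteforce(self):
        rng = np.random.default_rng(0)
        universe = [f"P{i}" for i in range(40)]
        tables = []
        for _ in range(5):
            comps = [
                list(rng.choice(universe, rng.integers(1, 10), replace=False))
                for _ in range(8)
            ]
            sig = list(rng.random(8) < 0.6)
            tables.append(_enr(comps, sig))
        freq = frequency_table(tables)
        expected: dict[str, int] = {}
        for t in tables:
            for _, row in t.iterrows():
                if row["significant"]:
                    for p in row["component"].split("|"):
                        expected[p] = expected.get(p, 0) + 1
        assert freq.to_dict() == expected


class TestPercentileSelect:
    def test_arithmetic_sequence_nearest_rank(self):
        freq = pd.Series(range(1, 101), index=[f"P{i}" for i in range(100)])
        sel = percentile_select(freq, 90)
        assert len(sel) == 11  # frequencies 90..100

    def test_all_equal_selects_all(self):
        freq = pd.Series([4, 4, 4], index=list("abc"))
        assert percentile_select(freq, 90) == {"a", "b", "c"}

    def test_single_protein(self):
        assert percentile_select(pd.Series({"x": 2}), 90) == {"x"}

    def test_percentile_out_of_range(self):
        with pytest.raises(ValidationError):
            percentile_select(pd.Series({"x": 1}), 100.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        freqs=st.lists(st.integers(0, 30), min_size=1, max_size=40),
        p1=st.floats(1, 98),
        delta=st.floats(0.5, 40),
    )
    def test_monotone_in_percentile(self, freqs, p1, delta):
        """Raising the percentile can only shrink the selected set."""
        p2 = min(p1 + delta, 99.5)
        freq = pd.Series(freqs, index=[f"P{i}" for i in range(len(freqs))])
        assert percentile_select(freq, p2) <= percentile_select(freq, p1)


def _two_group_design():
    samples = ["h1", "h2", "p1", "p2"]
    return StudyDesign(
        conditions=pd.Series(["H", "H", "T", "T"], index=samples),
        contrasts=[("H", "T")],
    )


class TestFoldChange:
    def test_equal_means_give_plus_one(self):
        counts = pd.DataFrame([[5, 5, 5, 5]], index=["A"],
                              columns=["h1", "h2", "p1", "p2"])
        fc = fold_changes(counts, _two_group_design(), ("H", "T"))
        assert fc["A"] == pytest.approx(1.0)

    def test_upregulated_boundary_plus_three(self):
        # ref mean 1, test mean 5 -> (5+1)/(1+1) = 3 exactly
        counts = pd.DataFrame([[1, 1, 5, 5]], index=["A"],
                              columns=["h1", "h2", "p1", "p2"])
        fc = fold_changes(counts, _two_group_design(), ("H", "T"))
        assert fc["A"] == pytest.approx(3.0)
        assert abs(fc["A"]) >= 3.0  # retained under the >= 3 rule

    def test_downregulated_boundary_minus_three(self):
        counts = pd.DataFrame([[5, 5, 1, 1]], index=["A"],
                              columns=["h1", "h2", "p1", "p2"])
        fc = fold_changes(counts, _two_group_design(), ("H", "T"))
        assert fc["A"] == pytest.approx(-3.0)

    def test_signed_convention_symmetric(self):
        counts = pd.DataFrame([[2, 2, 10, 10], [10, 10, 2, 2]], index=["up", "dn"],
                              columns=["h1", "h2", "p1", "p2"])
        fc = fold_changes(counts, _two_group_design(), ("H", "T"))
        assert fc["up"] == pytest.approx(-fc["dn"])

    def test_zero_reference_handled_by_pseudocount(self):
        counts = pd.DataFrame([[0, 0, 8, 8]], index=["A"],
                              columns=["h1", "h2", "p1", "p2"])
        fc = fold_changes(counts, _two_group_design(), ("H", "T"))
        assert np.isfinite(fc["A"]) and fc["A"] == pytest.approx(9.0)


class TestFilterCascade:
    def _fixture(self):
        """30 proteins engineered so exactly 10 pass all three filters."""
        rng = np.random.default_rng(1)
        ids = [f"P{i:02d}" for i in range(30)]
        freq = pd.Series(1, index=ids)
        winners = ids[:10]
        freq[winners] = 50  # top decile of frequencies
        fc = pd.Series(1.5, index=ids)
        fc[winners] = [4.0, -5.0, 3.0, -3.0, 6.0, 8.0, -4.5, 3.2, -3.7, 5.5]
        spectra = pd.Series(100, index=ids)
        # decoys failing exactly one filter each
        fc["P10"] = 9.0                      # high fc, low frequency
        spectra["P11"] = 200                 # high spectra, low frequency
        freq["P12"] = 50; fc["P12"] = 2.9    # top percentile but sub-threshold fc
        freq["P13"] = 50; fc["P13"] = 4.0; spectra["P13"] = 9  # too few spectra
        return freq, fc, spectra, set(winners)

    def test_exactly_ten_candidates(self):
        freq, fc, spectra, winners = self._fixture()
        out = filter_cascade(freq, fc, spectra, percentile=66.0)
        assert set(out.index[out["candidate"]]) == winners

    def test_filters_commute(self):
        freq, fc, spectra, winners = self._fixture()
        out = filter_cascade(freq, fc, spectra, percentile=66.0)
        # apply the three filters by hand in both orders
        from protprio import percentile_select

        perc = percentile_select(freq, 66.0)
        order1 = {p for p in perc if abs(fc[p]) >= 3.0 and spectra[p] >= 10}
        order2 = {p for p in freq.index if spectra[p] >= 10 and abs(fc[p]) >= 3.0}
        order2 &= perc
        assert order1 == order2 == winners
        assert set(out.index[out["candidate"]]) == order1

    def test_spectra_and_fc_exclusions(self):
        ids = ["ok", "few_spectra", "low_fc"]
        freq = pd.Series([10, 10, 10], index=ids)
        fc = pd.Series([4.0, 4.0, 2.9], index=ids)
        spectra = pd.Series([50, 9, 50], index=ids)
        out = filter_cascade(freq, fc, spectra)
        assert bool(out.loc["ok", "candidate"])
        assert not out.loc["few_spectra", "candidate"]
        assert not out.loc["low_fc", "candidate"]

    def test_direction_follows_fold_change_sign(self):
        freq = pd.Series([5, 5], index=["u", "d"])
        fc = pd.Series([3.5, -3.5], index=["u", "d"])
        spectra = pd.Series([20, 20], index=["u", "d"])
        out = filter_cascade(freq, fc, spectra)
        assert out.loc["u", "direction"] == "up"
        assert out.loc["d", "direction"] == "down"


class TestOverrepresentation:
    def _library(self, sets):
        lib = GeneSetCollection(label="lib")
        for name, members in sets.items():
            lib.add(name, members)
        return lib

    def test_disjoint_term_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        lib = self._library({"t": ["g10", "g11"]})
        out = term_overrepresentation({"g0", "g1"}, lib, universe)
        assert out.loc[0, "p"] == 1.0

    def test_term_equal_universe_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        lib = self._library({"t": sorted(universe)})
        out = term_overrepresentation({"g0", "g1"}, lib, universe)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_closed_form_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(100)}
        term = [f"g{i}" for i in range(20)]
        query = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        lib = self._library({"t": term})
        out = term_overrepresentation(query, lib, universe)
        expected = sum(
            math.comb(20, k) * math.comb(80, 10 - k) / math.comb(100, 10)
            for k in range(5, 11)
        )
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)

    def test_empty_query_rejected(self):
        lib = self._library({"t": ["g1"]})
        with pytest.raises(ValidationError):
            term_overrepresentation(set(), lib, {"g1"})


class TestDiseaseFrequency:
    def _libs(self):
        lib1 = GeneSetCollection(label="L1")
        lib1.add("asd", ["A", "B", "C"])
        lib1.add("id", ["D"])
        lib2 = GeneSetCollection(label="L2")
        lib2.add("epilepsy", ["B", "E"])
        return [lib1, lib2]

    def test_no_significant_terms_all_zero(self):
        libs = self._libs()
        tables = [
            pd.DataFrame({"term": ["asd", "id"], "significant": [False, False]}),
            pd.DataFrame({"term": ["epilepsy"], "significant": [False]}),
        ]
        out = disease_frequency({"A", "B"}, libs, tables)
        assert (out["n_disease_terms"] == 0).all()
        assert not out["clinically_related"].any()

    def test_single_significant_term_counts_members(self):
        libs = self._libs()
        tables = [
            pd.DataFrame({"term": ["asd", "id"], "significant": [True, False]}),
            pd.DataFrame({"term": ["epilepsy"], "significant": [False]}),
        ]
        out = disease_frequency({"A", "B", "C", "D"}, libs, tables).set_index("protein_id")
        assert out.loc[["A", "B", "C"], "n_disease_terms"].tolist() == [1, 1, 1]
        assert out.loc["D", "n_disease_terms"] == 0

    def test_multi_library_counts_match_bruteforce(self):
        libs = self._libs()
        tables = [
            pd.DataFrame({"term": ["asd", "id"], "significant": [True, True]}),
            pd.DataFrame({"term": ["epilepsy"], "significant": [True]}),
        ]
        cands = {"A", "B", "D", "E"}
        out = disease_frequency(cands, libs, tables).set_index("protein_id")
        expected = {"A": 1, "B": 2, "D": 1, "E": 1}
        for p, n in expected.items():
            assert out.loc[p, "n_disease_terms"] == n
        assert out["clinically_related"].all()
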