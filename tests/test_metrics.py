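"""Profile construction and the CAMI-style metric suite."""

import numpy as np
import pytest

from taxsieve.lca import classify_query
from taxsieve.metrics import (
    Profile,
    bray_curtis,
    contig_accuracy,
    diff_table,
    evaluate_profiles,
    l1_distance,
    pearson_abundance,
    percent,
    presence_metrics,
    profile_from_classifications,
    rank_share_summary,
    read_cami_profile,
    write_cami_profile,
)
from taxsieve.paf import QueryRefCoverage


def _classify(ref_taxid, taxonomy, query="q", exact=True):
    cov = QueryRefCoverage(query, "r", 1.0, 1, exact)
    return classify_query([cov], {"r": 1.0}, {"r": ref_taxid}, taxonomy)


class TestProfileFromClassifications:
    def test_single_species_gets_all_mass(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, f"q{i}") for i in range(4)]
        profile = profile_from_classifications(cls, toy_taxonomy)
        assert profile.at_rank("species") == {21: pytest.approx(1.0)}

    def test_count_basis_split(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, f"a{i}") for i in range(3)]
        cls.append(_classify(22, toy_taxonomy, "b0"))
        profile = profile_from_classifications(cls, toy_taxonomy)
        assert profile.at_rank("species")[21] == pytest.approx(0.75)
        assert profile.at_rank("species")[22] == pytest.approx(0.25)
        assert profile.at_rank("genus")[20] == pytest.approx(1.0)

    def test_shallow_classification_leaves_unclassified_mass(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, f"a{i}") for i in range(3)]
        cls.append(_classify(20, toy_taxonomy, "g0"))  # genus-level only
        profile = profile_from_classifications(cls, toy_taxonomy)
        assert sum(profile.at_rank("species").values()) == pytest.approx(0.75)
        assert sum(profile.at_rank("genus").values()) == pytest.approx(1.0)

    def test_length_weighted_basis(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, "a"), _classify(22, toy_taxonomy, "b")]
        profile = profile_from_classifications(
            cls, toy_taxonomy, basis="length-weighted", lengths={"a": 300, "b": 100}
        )
        assert profile.at_rank("species")[21] == pytest.approx(0.75)


class TestPresenceMetrics:
    def test_eleven_of_fourteen_genera_recall(self):
        truth = {f"g{i}": 1 / 14 for i in range(14)}
        pred = {f"g{i}": 0.05 for i in range(11)}
        pred.update({f"x{i}": 0.05 for i in range(4)})
        pm = presence_metrics(pred, truth)
        assert pm.recall == pytest.approx(100 * 11 / 14)
        assert round(pm.recall, 1) == 78.6
        assert pm.precision == pytest.approx(100 * 11 / 15)

    def test_identical_profiles_perfect(self):
        prof = {1: 0.6, 2: 0.4}
        pm = presence_metrics(prof, prof)
        assert (pm.precision, pm.recall, pm.f1) == (100.0, 100.0, 100.0)

    def test_all_prediction_below_threshold(self):
        pm = presence_metrics({1: 0.0005}, {1: 0.9, 2: 0.1})
        assert pm.pred_empty and pm.precision == 0.0 and pm.recall == 0.0

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            presence_metrics({1: 0.5}, {1: 0.0001})

    def test_f1_bounded_by_max_of_p_and_r(self):
        pm = presence_metrics({1: 0.5, 2: 0.5}, {1: 0.5, 3: 0.5})
        assert pm.f1 <= max(pm.precision, pm.recall)


class TestDistances:
    def test_identical_zero(self):
        prof = {1: 0.6, 2: 0.4}
        assert l1_distance(prof, prof) == 0.0
        assert bray_curtis(prof, prof) == 0.0

    def test_disjoint_normalized(self):
        a, b = {1: 0.5, 2: 0.5}, {3: 0.7, 4: 0.3}
        assert l1_distance(a, b) == pytest.approx(2.0)
        assert bray_curtis(a, b) == pytest.approx(1.0)

    def test_bray_curtis_symmetric_and_half_l1(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            pa = {i: float(v) for i, v in enumerate(a)}
            pb = {i: float(v) for i, v in enumerate(b)}
            assert bray_curtis(pa, pb) == pytest.approx(bray_curtis(pb, pa))
            assert bray_curtis(pa, pb) == pytest.approx(l1_distance(pa, pb) / 2)

    def test_pct_scale(self):
        assert l1_distance({1: 0.6}, {1: 0.5}, scale="pct") == pytest.approx(10.0)

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            bray_curtis({}, {})


class TestPearson:
    def test_identical_is_one(self):
        prof = {1: 0.5, 2: 0.3, 3: 0.2}
        assert pearson_abundance(prof, prof) == pytest.approx(1.0)

    def test_scale_invariance(self):
        truth = {1: 0.5, 2: 0.3, 3: 0.2}
        pred = {k: 0.37 * v for k, v in truth.items()}
        assert pearson_abundance(pred, truth) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        p = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
        q = {1: 0.35, 2: 0.35, 3: 0.1, 4: 0.2}
        pv = np.array([p[i] for i in (1, 2, 3, 4)])
        qv = np.array([q[i] for i in (1, 2, 3, 4)])
        expected = np.mean((pv - pv.mean()) * (qv - qv.mean())) / (
            np.std(pv) * np.std(qv)
        )
        assert pearson_abundance(p, q) == pytest.approx(float(expected))

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError):
            pearson_abundance({1: 0.5, 2: 0.5}, {1: 0.9, 2: 0.1})


class TestContigAccuracy:
    def test_all_correct_species(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, f"c{i}") for i in range(4)]
        truth = {f"c{i}": 21 for i in range(4)}
        for rank in ("species", "genus", "family", "superkingdom"):
            assert contig_accuracy(cls, truth, toy_taxonomy, rank) == 100.0

    def test_sister_species_confusion(self, toy_taxonomy):
        cls = [_classify(22, toy_taxonomy, f"c{i}") for i in range(4)]
        truth = {f"c{i}": 21 for i in range(4)}  # truth is the sister species
        assert contig_accuracy(cls, truth, toy_taxonomy, "species") == 0.0
        assert contig_accuracy(cls, truth, toy_taxonomy, "genus") == 100.0

    def test_unclassified_counts_as_incorrect(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, "c0"), _classify(21, toy_taxonomy, "c1")]
        truth = {"c0": 21, "c1": 21, "c2": 21, "c3": 21}
        assert contig_accuracy(cls, truth, toy_taxonomy, "species") <= 50.0

    def test_accuracy_non_decreasing_as_rank_coarsens(self, toy_taxonomy):
        cls = [
            _classify(22, toy_taxonomy, "c0"),
            _classify(21, toy_taxonomy, "c1"),
            _classify(31, toy_taxonomy, "c2"),
        ]
        truth = {"c0": 21, "c1": 21, "c2": 21}
        accs = [
            contig_accuracy(cls, truth, toy_taxonomy, r)
            for r in ("species", "genus", "family", "superkingdom")
        ]
        assert all(a <= b for a, b in zip(accs, accs[1:]))


class TestRankShare:
    def test_species_strain_share(self, toy_taxonomy):
        cls = [_classify(21, toy_taxonomy, f"s{i}") for i in range(54)]
        cls += [_classify(20, toy_taxonomy, f"g{i}") for i in range(18)]
        shares = rank_share_summary(cls)
        assert shares["species/strain"] == pytest.approx(75.0)
        assert shares["genus"] == pytest.approx(25.0)

    def test_percent_helper(self):
        assert percent(54, 72) == pytest.approx(75.00)
        assert round(percent(27, 61), 2) == 44.26
        assert percent(0, 10) == 0.0
        with pytest.raises(ValueError):
            percent(1, 0)


class TestDiffTable:
    def test_signed_difference_in_percentage_points(self):
        truth = {"Escherichia": 0.3439}
        pred = {"Escherichia": 0.3296}
        row = diff_table(pred, truth).iloc[0]
        assert row["diff_pp"] == pytest.approx(-1.43)

    def test_identical_profiles_zero_diff(self):
        prof = {1: 0.7, 2: 0.3}
        table = diff_table(prof, prof)
        assert (table["diff_pp"].abs() < 1e-12).all()

    def test_prediction_only_taxon_zero_filled(self):
        table = diff_table({1: 0.1, 2: 0.9}, {2: 1.0})
        row = table[table["taxon"] == 1].iloc[0]
        assert row["truth_pct"] == 0.0
        assert row["diff_pp"] == pytest.approx(10.0)

    def test_sorted_by_truth_descending(self):
        table = diff_table({}, {1: 0.2, 2: 0.5, 3: 0.3})
        assert table["taxon"].tolist() == [2, 3, 1]


class TestCamiProfileIO:
    def test_round_trip(self, toy_taxonomy, tmp_path):
        profile = Profile(
            per_rank={"genus": {20: 0.6, 30: 0.4}, "species": {21: 0.6, 31: 0.4}},
            sample_id="s1",
        )
        path = tmp_path / "profile.cami.tsv"
        write_cami_profile(profile, toy_taxonomy, path)
        back = read_cami_profile(path)
        assert back.sample_id == "s1"
        assert back.at_rank("genus")[20] == pytest.approx(0.6)
        assert back.at_rank("species")[31] == pytest.approx(0.4)

    def test_evaluate_profiles_mean_row(self, toy_taxonomy):
        profile = Profile(per_rank={"genus": {20: 1.0}, "species": {21: 1.0}})
        table = evaluate_profiles(profile, profile)
        mean = table[table["rank"] == "mean"].iloc[0]
        assert mean["f1"] == pytest.approx(100.0)
        assert mean["bray_curtis"] == pytest.approx(0.0)
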