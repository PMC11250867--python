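"""Percent-expressing, ontology correlation and zone scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ihcquant.expression import (
    correlate_ontologies,
    gene_zone_matrix,
    percent_expressing,
    zone_scores,
)
from ihcquant.synthetic import make_expression_table, make_logfc_matrix


def toy_table():
    table = pd.DataFrame({"Ripk3": [1.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0]})
    meta = pd.DataFrame({"ontology": ["T"] * 8, "tissue": ["spleen"] * 8})
    return table, meta


class TestPercentExpressing:
    def test_two_of_eight_positive(self):
        table, meta = toy_table()
        out = percent_expressing(table, meta, "Ripk3")
        assert out[("T", "spleen")] == 25.0

    def test_all_zero_gene(self):
        table, meta = toy_table()
        table["Mlkl"] = 0.0
        out = percent_expressing(table, meta, "Mlkl")
        assert (out == 0.0).all()

    def test_unknown_gene_rejected(self):
        table, meta = toy_table()
        with pytest.raises(KeyError):
            percent_expressing(table, meta, "Nope")

    def test_group_sums_conserve_positive_cells(self):
        rates = pd.DataFrame(
            {"Ripk3": [0.2, 0.6, 0.9]},
            index=pd.MultiIndex.from_tuples([("T", "s"), ("B", "s"), ("M", "l")]),
        )
        table, meta = make_expression_table(rates, 200, seed=1)
        out = percent_expressing(table, meta, "Ripk3")
        total_from_groups = (out / 100.0 * 200).sum()
        assert total_from_groups == pytest.approx((table["Ripk3"] > 0).sum())

    def test_planted_bernoulli_rates_within_99ci(self):
        planted = [0.05, 0.25, 0.5, 0.75, 0.95]
        rates = pd.DataFrame(
            {"Ripk3": planted},
            index=pd.MultiIndex.from_tuples([(f"o{i}", "t") for i in range(5)]),
        )
        n = 500
        table, meta = make_expression_table(rates, n, seed=2)
        out = percent_expressing(table, meta, "Ripk3").sort_index()
        z = stats.norm.ppf(0.995)
        for (key, got), p in zip(out.items(), sorted(zip(rates.index, planted))):
            p = p[1]
            half = z * np.sqrt(p * (1 - p) / n) * 100
            assert abs(got - 100 * p) <= half


class TestCorrelate:
    @staticmethod
    def _series(vals):
        idx = pd.MultiIndex.from_tuples([(f"o{i}", "t") for i in range(len(vals))])
        return pd.Series(vals, index=idx)

    def test_identity_gives_one(self):
        x = self._series([1.0, 2.0, 3.0])
        assert correlate_ontologies(x, x) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = self._series([1.0, 2.0, 3.0])
        y = self._series([5.0, 4.0, 3.0])
        assert correlate_ontologies(x, y) == pytest.approx(-1.0)

    def test_matches_closed_form_on_three_points(self):
        x = self._series([1.0, 2.0, 3.0])
        y = self._series([2.0, 3.0, 5.0])
        xv, yv = np.array([1, 2, 3.0]), np.array([2, 3, 5.0])
        r_hand = np.sum((xv - xv.mean()) * (yv - yv.mean())) / np.sqrt(
            np.sum((xv - xv.mean()) ** 2) * np.sum((yv - yv.mean()) ** 2)
        )
        assert correlate_ontologies(x, y) == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_rejected(self):
        x = self._series([1.0, 1.0, 1.0])
        y = self._series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate_ontologies(x, y)


def brute_force_selection(scores: pd.Series, percentile: int, top_k: int = 5):
    """Independent evaluation of the eligibility + top-k rule."""
    top = scores.max()
    if top <= 0:
        return []
    eligible = [c for c in scores.index if scores[c] >= percentile / 100.0 * top]
    ranked = sorted(eligible, key=lambda c: (-scores[c], str(c)))
    return [str(c) for c in ranked[:top_k]]


class TestZoneScores:
    def test_single_positive_cluster_selected(self):
        lf = pd.DataFrame({"0": [1.0, 2.0]}, index=["a", "b"])
        sel = zone_scores(lf, "z", ["a", "b"])
        assert sel.selected == ["0"]

    def test_hand_example_four_clusters(self):
        # per-cluster scores (10, 9, 4, 1); percentile 50 -> eligible {10, 9}
        lf = pd.DataFrame(
            [[4.0, 3.0, 2.0, 0.5], [3.0, 3.0, 1.0, 0.25], [3.0, 3.0, 1.0, 0.25]],
            index=["g1", "g2", "g3"], columns=["0", "1", "2", "3"],
        )
        sel = zone_scores(lf, "z", ["g1", "g2", "g3"], percentile=50)
        assert list(sel.scores.round(6)) == [10.0, 9.0, 4.0, 1.0]
        assert sel.selected == ["0", "1"]

    def test_all_equal_scores_tie_broken_by_cluster_id(self):
        lf = pd.DataFrame(np.ones((2, 7)), index=["a", "b"],
                          columns=[str(c) for c in range(7)])
        sel = zone_scores(lf, "z", ["a", "b"])
        assert sel.selected == ["0", "1", "2", "3", "4"]

    def test_nonpositive_maximum_flagged_empty(self):
        lf = pd.DataFrame({"0": [-1.0], "1": [-2.0]}, index=["a"])
        sel = zone_scores(lf, "z", ["a"])
        assert sel.selected == [] and sel.flagged

    def test_scale_invariance_of_selection(self):
        lf = make_logfc_matrix(seed=3)
        genes = ["Cd19", "Ms4a1", "Cd3e"]
        a = zone_scores(lf, "z", genes, percentile=75)
        b = zone_scores(3.7 * lf, "z", genes, percentile=75)
        assert a.selected == b.selected

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for seed in range(50):
            n_clusters = int(rng.integers(1, 7))
            lf = pd.DataFrame(
                rng.normal(0, 2, size=(3, n_clusters)),
                index=["g1", "g2", "g3"], columns=[str(c) for c in range(n_clusters)],
            )
            for pct in (50, 75):
                sel = zone_scores(lf, "z", ["g1", "g2", "g3"], percentile=pct)
                assert sel.selected == brute_force_selection(lf.sum(axis=0), pct)


class TestGeneZoneMatrix:
    def test_single_cluster_zone_equals_its_column(self):
        lf = make_logfc_matrix(seed=5)
        sel = zone_scores(lf, "marginal_zone", ["Marco", "Cd209b", "Sn"], percentile=75)
        assert sel.selected == ["4"]
        gz = gene_zone_matrix(lf, [sel], genes_of_interest=["Casp8", "Mlkl"])
        assert gz.loc["Casp8", "marginal_zone"] == pytest.approx(lf.loc["Casp8", "4"])

    def test_two_cluster_zone_sums(self):
        lf = pd.DataFrame({"0": [0.5], "1": [0.3]}, index=["Mlkl"])
        sel = zone_scores(lf, "z", ["Mlkl"], percentile=50)
        gz = gene_zone_matrix(lf, [sel], genes_of_interest=["Mlkl"])
        assert gz.loc["Mlkl", "z"] == pytest.approx(0.8)

    def test_planted_high_mlkl_zone_has_max_score(self):
        lf = make_logfc_matrix(
            zone_gene_sets={"hot": ["Mlkl"], "cold": ["Casp8"]},
            planted_zone_clusters={"hot": [0, 1], "cold": [4]},
            seed=6, planted_lfc=3.0,
        )
        sels = [zone_scores(lf, z, gs) for z, gs in
                (("hot", ["Mlkl"]), ("cold", ["Casp8"]))]
        gz = gene_zone_matrix(lf, sels, genes_of_interest=["Mlkl", "Casp8"])
        assert gz.loc["Mlkl"].idxmax() == "hot"

    def test_missing_gene_reported_as_nan(self):
        lf = pd.DataFrame({"0": [1.0]}, index=["Mlkl"])
        sel = zone_scores(lf, "z", ["Mlkl"])
        gz = gene_zone_matrix(lf, [sel], genes_of_interest=["Mlkl", "Ripk3"])
        assert np.isnan(gz.loc["Ripk3", "z"])
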