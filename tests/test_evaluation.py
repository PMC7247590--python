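"""Rank sensitivity/specificity, per-individual ROC/AUC, and cohort aggregation."""

import math
import random
import statistics

import numpy as np
import pytest

from gvburden import (
    ConfigError,
    DataError,
    DrugGeneMap,
    GoldStandard,
    GSMode,
    Relation,
    RelationType,
    Sample,
    compare_gene_categories,
    evaluate_cohort,
    roc_auc,
    sensitivity_specificity,
)
from oracles import pairwise_concordance_auc


def gs_of(drugs, sample_id="S1", mode=GSMode.NON_SPECIFIC):
    return GoldStandard(sample_id, mode, frozenset(drugs))


class TestSensitivitySpecificity:
    def test_hand_enumerated_case(self):
        ranked = ["d1", "d2", "d3", "d4"]
        sens, spec = sensitivity_specificity(ranked, {"d1", "d3"}, L=2)
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(0.5)

    def test_threshold_zero_and_full(self):
        ranked = ["d1", "d2", "d3", "d4"]
        assert sensitivity_specificity(ranked, {"d2"}, 0) == (0.0, 1.0)
        assert sensitivity_specificity(ranked, {"d2"}, 4) == (1.0, 0.0)

    def test_empty_or_total_gold_standard_is_error(self):
        with pytest.raises(DataError):
            sensitivity_specificity(["d1", "d2"], set(), 1)
        with pytest.raises(DataError):
            sensitivity_specificity(["d1", "d2"], {"d1", "d2"}, 1)

    def test_complement_identities_hold_along_the_sweep(self):
        rng = random.Random(5)
        ranked = [f"d{i}" for i in range(12)]
        gs = set(rng.sample(ranked, 4))
        for L in range(13):
            sens, spec = sensitivity_specificity(ranked, gs, L)
            DL = set(ranked[:L])
            assert sens + len(gs - DL) / len(gs) == pytest.approx(1.0)
            tn_fraction = len((set(ranked) - gs) - DL) / len(set(ranked) - gs)
            assert spec == pytest.approx(tn_fraction)


class TestRocAuc:
    def test_perfect_ranking_gives_auc_one(self):
        burdens = {"a": 0.1, "b": 0.2, "c": 0.8, "d": 0.9}
        assert roc_auc(burdens, gs_of({"a", "b"})).auc == pytest.approx(1.0)

    def test_single_tie_block_gives_half(self):
        burdens = {d: 1.0 for d in "abcd"}
        assert roc_auc(burdens, gs_of({"a"})).auc == pytest.approx(0.5)

    def test_tied_pair_counts_half(self):
        # pairs of the single GS drug d2: vs d1 discordant (0), vs d3 tied
        # (1/2), vs d4 concordant (1) -> (0 + 0.5 + 1) / 3
        burdens = {"d1": 0.1, "d2": 0.3, "d3": 0.3, "d4": 0.9}
        curve = roc_auc(burdens, gs_of({"d2"}))
        assert curve.auc == pytest.approx(0.5, abs=1e-12)
        assert curve.auc == pytest.approx(
            pairwise_concordance_auc(burdens, {"d2"}), abs=1e-12
        )

    def test_curve_endpoints_and_monotone_sensitivity(self):
        burdens = {"a": 0.2, "b": 0.5, "c": 0.5, "d": 0.7, "e": 1.0}
        curve = roc_auc(burdens, gs_of({"b", "d"}))
        assert curve.points[0] == (0, 0.0, 1.0)
        L, sens, spec = curve.points[-1]
        assert (L, sens, spec) == (5, 1.0, 0.0)
        sens_values = [p[1] for p in curve.points]
        assert sens_values == sorted(sens_values)

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = random.Random(77)
        for _ in range(150):
            n = rng.randint(2, 30)
            drugs = [f"d{i}" for i in range(n)]
            # coarse grid forces plenty of ties
            burdens = {d: rng.choice([0.0, 0.1, 0.25, 0.5, 0.5, 1.0]) for d in drugs}
            k = rng.randint(1, n - 1)
            gs = set(rng.sample(drugs, k))
            assert roc_auc(burdens, gs_of(gs)).auc == pytest.approx(
                pairwise_concordance_auc(burdens, gs), abs=1e-12
            )

    def test_agrees_with_sklearn_on_tie_free_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(3, 25)
            drugs = [f"d{i}" for i in range(n)]
            burdens = {d: rng.random() for d in drugs}
            gs = set(rng.sample(drugs, rng.randint(1, n - 1)))
            labels = [1 if d in gs else 0 for d in drugs]
            scores = [-burdens[d] for d in drugs]  # lower burden = positive
            assert roc_auc(burdens, gs_of(gs)).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = random.Random(2)
        burdens = {f"d{i}": rng.random() for i in range(20)}
        gs = {f"d{i}" for i in range(0, 20, 5)}
        base = roc_auc(burdens, gs_of(gs)).auc
        transformed = {d: math.sqrt(v) * 0.5 for d, v in burdens.items()}
        assert roc_auc(transformed, gs_of(gs)).auc == pytest.approx(base, abs=1e-12)

    def test_permutation_null_centers_on_half(self):
        rng = random.Random(123)
        burdens = {f"d{i}": rng.random() for i in range(40)}
        aucs = []
        for _ in range(400):
            gs = set(rng.sample(list(burdens), 6))
            aucs.append(roc_auc(burdens, gs_of(gs)).auc)
        assert statistics.fmean(aucs) == pytest.approx(0.5, abs=0.02)


def _singleton_cohort(ranks, n_drugs=11):
    """Samples whose GS is a single drug at a chosen rank.

    With distinct burdens and |D| = n, a singleton GS at (1-based) rank r
    has AUC (n - r) / (n - 1).
    """
    drugs = {f"d{i}": i / n_drugs for i in range(1, n_drugs + 1)}
    burdens, standards, samples = {}, {}, []
    for j, r in enumerate(ranks):
        sid = f"S{j}"
        samples.append(Sample(sid, "P", "EUR"))
        burdens[sid] = dict(drugs)
        standards[sid] = gs_of({f"d{r}"}, sample_id=sid)
    return burdens, standards, samples


class TestEvaluateCohort:
    def test_mean_and_sample_sd_aggregation(self):
        # ranks 5, 4, 3 of 11 -> AUCs 0.6, 0.7, 0.8
        burdens, standards, samples = _singleton_cohort([5, 4, 3])
        (summary,) = evaluate_cohort(burdens, standards, samples, "SIFT",
                                     GSMode.NON_SPECIFIC)
        assert summary.n_samples == 3
        assert summary.auc_mean == pytest.approx(0.7)
        assert summary.auc_sd == pytest.approx(0.1)

    def test_empty_gold_standard_samples_not_counted(self):
        burdens, standards, samples = _singleton_cohort([5, 4])
        samples.append(Sample("S9", "P", "EUR"))
        burdens["S9"] = dict(burdens["S0"])
        standards["S9"] = gs_of(set(), sample_id="S9")
        (summary,) = evaluate_cohort(burdens, standards, samples, "SIFT",
                                     GSMode.NON_SPECIFIC)
        assert summary.n_samples == 2

    def test_single_sample_stratum_flagged_with_zero_sd(self):
        burdens, standards, samples = _singleton_cohort([5])
        (summary,) = evaluate_cohort(burdens, standards, samples, "SIFT",
                                     GSMode.NON_SPECIFIC)
        assert summary.n_samples == 1
        assert summary.auc_sd == 0.0
        assert summary.flag == "degenerate_stratum"

    def test_population_strata_split_the_cohort(self):
        burdens, standards, samples = _singleton_cohort([5, 4, 3, 2])
        samples = [
            Sample(s.sample_id, "P", "AFR" if i < 2 else "EUR")
            for i, s in enumerate(samples)
        ]
        summaries = evaluate_cohort(
            burdens, standards, samples, "SIFT", GSMode.NON_SPECIFIC,
            strata=("superpopulation",),
        )
        by = {s.stratum: s for s in summaries}
        assert by["AFR"].auc_mean == pytest.approx(0.65)
        assert by["EUR"].auc_mean == pytest.approx(0.85)

    def test_atc_stratum_without_gold_standard_flagged(self):
        burdens, standards, samples = _singleton_cohort([5, 4])
        dgmap = DrugGeneMap(
            relations=frozenset(
                Relation(f"d{i}", "G1", RelationType.TARGET) for i in range(1, 12)
            ),
            # all GS drugs (d3..d5) sit in class L; class B holds none
            atc_main_group={f"d{i}": ("L" if i < 9 else "B") for i in range(1, 12)},
        )
        summaries = evaluate_cohort(
            burdens, standards, samples, "SIFT", GSMode.NON_SPECIFIC,
            strata=("atc",), dgmap=dgmap,
        )
        by = {s.stratum: s for s in summaries}
        assert by["B"].n_samples == 0
        assert by["B"].flag == "no_gold_standard"
        assert by["L"].n_samples == 2

    def test_atc_without_map_is_error(self):
        burdens, standards, samples = _singleton_cohort([5])
        with pytest.raises(ConfigError):
            evaluate_cohort(burdens, standards, samples, "SIFT",
                            GSMode.NON_SPECIFIC, strata=("atc",))


class TestCompareGeneCategories:
    def test_fully_separated_categories_highly_significant(self):
        rng = random.Random(4)
        means = {f"a{i}": rng.uniform(0.05, 0.15) for i in range(20)}
        means |= {f"b{i}": rng.uniform(0.85, 0.95) for i in range(20)}
        (result,) = compare_gene_categories(
            means,
            {"low": [f"a{i}" for i in range(20)], "high": [f"b{i}" for i in range(20)]},
        )
        assert result.p_value < 0.005
        assert result.mean_gvb_a < result.mean_gvb_b

    def test_exchangeable_categories_are_null(self):
        rng = random.Random(9)
        values = [rng.random() for _ in range(40)]
        means = {f"g{i}": v for i, v in enumerate(values)}
        # interleaved assignment: both categories sample the same distribution
        cats = {
            "a": [f"g{i}" for i in range(0, 40, 2)],
            "b": [f"g{i}" for i in range(1, 40, 2)],
        }
        (result,) = compare_gene_categories(means, cats)
        assert 0.05 < result.p_value < 0.95

    def test_tiny_category_is_error(self):
        means = {"g1": 0.5, "g2": 0.6, "g3": 0.7}
        with pytest.raises(DataError):
            compare_gene_categories(means, {"a": ["g1"], "b": ["g2", "g3"]})

    def test_overlapping_categories_are_error(self):
        means = {"g1": 0.5, "g2": 0.6, "g3": 0.7, "g4": 0.8}
        with pytest.raises(DataError, match="disjoint"):
            compare_gene_categories(
                means, {"a": ["g1", "g2"], "b": ["g2", "g3", "g4"]}
            )
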