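"""Gene- and drug-level geometric-mean burden computation."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gvburden import (
    AnnotatedVariant,
    CohortGenotypes,
    Consequence,
    DataError,
    DrugGeneMap,
    Relation,
    RelationType,
    Sample,
    drug_burden_profile,
    drug_burden_profiles,
    gene_burden_profile,
    gvb_drug,
    gvb_gene,
)
from gvburden.burden_core import read_burdens, write_burdens


def naive_geometric_mean(scores):
    if not scores:
        return 1.0
    product = 1.0
    for s in scores:
        product *= s
    return product ** (1.0 / len(scores))


class TestGvbGene:
    @pytest.mark.parametrize(
        "scores,expected",
        [([], 1.0), ([0.5], 0.5), ([0.2, 0.8], 0.4), ([0.0, 0.9], 0.0)],
    )
    def test_known_values(self, scores, expected):
        assert gvb_gene(scores) == pytest.approx(expected, abs=1e-12)

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(DataError):
            gvb_gene([0.5, 1.2])

    def test_matches_product_root_oracle_on_random_multisets(self):
        rng = random.Random(20)
        for _ in range(1000):
            n = rng.randint(0, 20)
            scores = [rng.random() for _ in range(n)]
            assert gvb_gene(scores) == pytest.approx(
                naive_geometric_mean(scores), abs=1e-12
            )

    @given(
        scores=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10),
        c=st.floats(0.05, 1.0),
    )
    def test_scaling_every_score_scales_the_burden(self, scores, c):
        assert gvb_gene([c * s for s in scores]) == pytest.approx(
            c * gvb_gene(scores), rel=1e-9
        )

    def test_adding_lower_score_strictly_lowers_burden(self):
        rng = random.Random(3)
        for _ in range(50):
            scores = [rng.uniform(0.05, 0.95) for _ in range(rng.randint(1, 8))]
            g = gvb_gene(scores)
            assert gvb_gene(scores + [g * 0.5]) < g
            assert gvb_gene(scores + [min(1.0, g * 1.5 + 0.01)]) > g


class TestGvbDrug:
    @pytest.mark.parametrize(
        "burdens,genes,expected",
        [
            ({"a": 1.0, "b": 1.0}, {"a", "b"}, 1.0),
            ({"a": 0.25, "b": 1.0}, {"a", "b"}, 0.5),
            ({"a": 0.1, "b": 0.2, "c": 0.4}, {"a", "b", "c"}, 0.2),
        ],
    )
    def test_known_values(self, burdens, genes, expected):
        assert gvb_drug(burdens, genes) == pytest.approx(expected, abs=1e-12)

    def test_empty_gene_set_is_error(self):
        with pytest.raises(DataError):
            gvb_drug({"a": 0.5}, set())

    def test_missing_gene_burden_is_error(self):
        with pytest.raises(DataError, match="b"):
            gvb_drug({"a": 0.5}, {"a", "b"})

    def test_permutation_invariant_in_gene_set(self):
        rng = random.Random(8)
        burdens = {f"g{i}": rng.random() for i in range(6)}
        genes = list(burdens)
        values = set()
        for _ in range(5):
            rng.shuffle(genes)
            values.add(gvb_drug(burdens, frozenset(genes)))
        assert len(values) == 1


def _toy_inputs():
    variants = [
        AnnotatedVariant("v1", "1", 100, "A", "G", "GA", Consequence.NONSYNONYMOUS_CODING,
                         {"SIFT": 0.1}),
        AnnotatedVariant("v2", "1", 200, "C", "T", "GA", Consequence.NONSYNONYMOUS_CODING,
                         {"SIFT": 0.9}),
        AnnotatedVariant("v3", "1", 300, "G", "A", "GB", Consequence.NONSYNONYMOUS_CODING,
                         {"SIFT": 0.4}),
        AnnotatedVariant("v4", "1", 400, "T", "C", "GC", Consequence.NONCODING, {}),
    ]
    samples = [Sample("S1", "P", "EUR"), Sample("S2", "P", "EUR"), Sample("S3", "P", "EUR")]
    carriers = {
        "v1": frozenset({"S1", "S2"}),
        "v2": frozenset({"S1"}),
        "v3": frozenset({"S2"}),
        "v4": frozenset({"S1", "S2", "S3"}),
    }
    return CohortGenotypes(samples, carriers), variants


class TestGeneBurdenProfile:
    def test_cutoff_excludes_high_scores_before_aggregation(self):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT", cutoff=0.7)
        # S1 carries v1 (0.1, kept) and v2 (0.9, excluded) in GA
        assert profile.value("S1", "GA") == pytest.approx(0.1)
        assert profile.value("S2", "GA") == pytest.approx(0.1)
        assert profile.value("S2", "GB") == pytest.approx(0.4)

    def test_sample_carrying_nothing_has_all_genes_at_one(self):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT")
        assert all(profile.value("S3", g) == 1.0 for g in ("GA", "GB", "GC"))

    def test_unknown_gene_lookup_is_error(self):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT")
        with pytest.raises(DataError, match="GZ"):
            profile.value("S1", "GZ")

    def test_identical_variant_sets_give_identical_profiles(self):
        cohort, variants = _toy_inputs()
        cohort.carriers = {v: frozenset({"S1", "S2"}) for v in cohort.carriers}
        profile = gene_burden_profile(cohort, variants, "SIFT")
        for g in ("GA", "GB", "GC"):
            assert profile.value("S1", g) == profile.value("S2", g)

    def test_cohort_means_count_unaffected_samples_as_one(self):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT")
        means = profile.gene_cohort_means()
        assert means["GA"] == pytest.approx((0.1 + 0.1 + 1.0) / 3)
        assert means["GC"] == pytest.approx(1.0)


def _toy_map():
    return DrugGeneMap(
        relations=frozenset(
            {
                Relation("D1", "GA", RelationType.TARGET),
                Relation("D2", "GA", RelationType.ENZYME),
                Relation("D2", "GB", RelationType.TARGET),
                Relation("D3", "GA", RelationType.TARGET),
                Relation("D3", "GA", RelationType.ENZYME),  # dedup to one gene
            }
        ),
        atc_main_group={"D1": "L", "D2": "N"},
    )


class TestDrugBurdenProfile:
    def test_one_burden_per_drug(self):
        dgmap = _toy_map()
        out = drug_burden_profile({"GA": 0.25, "GB": 1.0}, dgmap)
        assert set(out) == {"D1", "D2", "D3"}
        assert out["D1"] == pytest.approx(0.25)
        assert out["D2"] == pytest.approx(0.5)

    def test_gene_under_two_relation_types_counted_once(self):
        out = drug_burden_profile({"GA": 0.25, "GB": 1.0}, _toy_map())
        assert out["D3"] == pytest.approx(0.25)  # not 0.25^2 nor sqrt

    def test_drugs_sharing_gene_sets_get_equal_burdens(self):
        out = drug_burden_profile({"GA": 0.3, "GB": 1.0}, _toy_map())
        assert out["D1"] == out["D3"]

    def test_gene_absent_from_universe_is_error(self):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT")
        bad = DrugGeneMap(
            relations=frozenset({Relation("D1", "GX", RelationType.TARGET)})
        )
        with pytest.raises(DataError, match="GX"):
            drug_burden_profiles(profile, bad)

    def test_profile_round_trips_through_tsv(self, tmp_path):
        cohort, variants = _toy_inputs()
        profile = gene_burden_profile(cohort, variants, "SIFT")
        by_sample = drug_burden_profiles(profile, _toy_map())
        rows = [
            (s, d, "SIFT", v)
            for s in sorted(by_sample)
            for d, v in sorted(by_sample[s].items())
        ]
        path = tmp_path / "drug_burden.tsv"
        write_burdens(rows, path)
        df = read_burdens(path)
        for s, d, _, v in rows:
            got = df[(df.sample_id == s) & (df.entity_id == d)].gvb.iloc[0]
            assert got == pytest.approx(v, rel=1e-6)


class TestDrugGeneMapValidation:
    def test_bad_atc_letter_rejected(self):
        with pytest.raises(DataError):
            DrugGeneMap(
                relations=frozenset({Relation("D1", "G1", RelationType.TARGET)}),
                atc_main_group={"D1": "Z"},
            )

    def test_atc_lookup_unknown_letter_is_error(self, fixture_bundle):
        from gvburden import ConfigError

        _, bundle = fixture_bundle
        with pytest.raises(ConfigError):
            bundle.dgmap.drugs_in_atc("Z")
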