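"""Enrichment classification, cross-matching and resampling statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendrocost as dc
from dendrocost.screens import (
    NEURITE,
    SOMA,
    UNCLASSIFIED,
    bootstrap_groups,
    classify_enrichment,
    coding_length_to_aa,
    crossmatch,
    ranksum_test,
    rescale_counts,
    screen_panel_report,
)
from dendrocost.synthetic import ScreenConfig, synthetic_screen

from conftest import ranksum_enumeration


class TestClassifyEnrichment:
    @pytest.mark.parametrize(
        "enrichment, expected",
        [(2.5, NEURITE), (2.0, NEURITE), (0.4, SOMA), (0.5, SOMA),
         (1.5, UNCLASSIFIED), (0.7, UNCLASSIFIED)],
    )
    def test_two_fold_rule(self, enrichment, expected):
        frame = pd.DataFrame({"gene": ["g"], "enrichment": [enrichment]})
        out = classify_enrichment(frame, threshold_fold=2.0)
        assert out["label"].iloc[0] == expected

    def test_one_fold_threshold_has_no_middle_band(self):
        frame = pd.DataFrame({
            "gene": list("abc"), "enrichment": [0.9, 1.0, 1.1]
        })
        out = classify_enrichment(frame, threshold_fold=1.0)
        assert UNCLASSIFIED not in set(out["label"])

    def test_nonpositive_enrichment_rejected_with_log(self, caplog):
        frame = pd.DataFrame({"gene": list("ab"), "enrichment": [2.5, -1.0]})
        with caplog.at_level("WARNING"):
            out = classify_enrichment(frame)
        assert len(out) == 1
        assert "non-positive" in caplog.text

    def test_threshold_below_one_rejected(self):
        frame = pd.DataFrame({"gene": ["g"], "enrichment": [2.0]})
        with pytest.raises(dc.ConfigurationError):
            classify_enrichment(frame, threshold_fold=0.5)

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1,
                    max_size=50))
    @settings(derandomize=True, max_examples=50)
    def test_partition_is_disjoint_and_complete(self, scores):
        frame = pd.DataFrame({
            "gene": [f"g{i}" for i in range(len(scores))],
            "enrichment": scores,
        })
        out = classify_enrichment(frame, threshold_fold=2.0)
        assert len(out) == len(scores)
        assert set(out["label"]) <= {SOMA, NEURITE, UNCLASSIFIED}


class TestCrossmatch:
    def test_disjoint_sets_give_zero_matches(self):
        a = pd.DataFrame({"gene": ["A", "B"], "val": [1, 2]})
        b = pd.DataFrame({"gene": ["C", "D"], "val": [3, 4]})
        assert len(crossmatch(a, b)) == 0

    def test_identical_sets_give_n_matches(self):
        a = pd.DataFrame({"gene": ["A", "B", "C"], "val": [1, 2, 3]})
        b = pd.DataFrame({"gene": ["A", "B", "C"], "w": [4, 5, 6]})
        assert len(crossmatch(a, b)) == 3

    def test_case_fold_matching(self):
        a = pd.DataFrame({"gene": ["Camk2a", "Shank3"], "val": [1, 2]})
        b = pd.DataFrame({"gene": ["CAMK2A"], "w": [9]})
        joined = crossmatch(a, b)
        assert len(joined) == 1
        assert joined["val"].iloc[0] == 1

    def test_homologue_mapping_first_listed_wins(self, caplog):
        a = pd.DataFrame({"gene": ["mouseX"], "val": [1]})
        b = pd.DataFrame({"gene": ["ratY"], "w": [2]})
        hom = pd.DataFrame({
            "mouse": ["mouseX", "mouseX"], "rat": ["ratY", "ratZ"]
        })
        with caplog.at_level("WARNING"):
            joined = crossmatch(a, b, homologue_table=hom)
        assert len(joined) == 1
        assert "multiple homologues" in caplog.text

    def test_join_cardinality_symmetric(self):
        a = pd.DataFrame({"gene": ["A", "B", "C"], "val": [1, 2, 3]})
        b = pd.DataFrame({"gene": ["B", "C", "D"], "w": [4, 5, 6]})
        assert len(crossmatch(a, b)) == len(crossmatch(b, a))


class TestRanksum:
    def test_separated_triples_exact_p(self):
        """{1,2,3} vs {4,5,6}: full enumeration of the C(6,3)=20 rank
        assignments gives two-sided p = 0.1."""
        assert ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert ranksum_enumeration(
            np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        ) == pytest.approx(0.1)

    def test_identical_groups_p_is_one(self):
        assert ranksum_test([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=10)
        assert ranksum_test(x, y) == pytest.approx(ranksum_test(y, x))

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 5), (6, 6)])
    def test_exact_branch_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            assert ranksum_test(x, y) == pytest.approx(
                ranksum_enumeration(x, y), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(dc.ConfigurationError):
            ranksum_test([], [1.0])


class TestBootstrap:
    def test_deterministic_given_seed(self):
        groups = {"a": np.arange(10.0), "b": np.arange(5.0)}
        r1 = bootstrap_groups(groups, n_boot=50, seed=7)
        r2 = bootstrap_groups(groups, n_boot=50, seed=7)
        np.testing.assert_array_equal(r1["a"].boot_means, r2["a"].boot_means)

    def test_constant_group_all_resamples_equal_constant(self):
        out = bootstrap_groups({"c": np.full(20, 3.5)}, n_boot=200, seed=0)
        assert np.all(out["c"].boot_means == 3.5)
        assert out["c"].mean_ci == (3.5, 3.5)

    def test_two_point_distribution_clt(self):
        """Bootstrap mean-of-means stays within 3 SE of the sample mean."""
        rng = np.random.default_rng(5)
        sample = rng.choice([0.0, 1.0], size=400, p=[0.5, 0.5])
        out = bootstrap_groups({"g": sample}, n_boot=2000, seed=1)
        se = sample.std(ddof=1) / np.sqrt(len(sample))
        assert abs(out["g"].boot_means.mean() - sample.mean()) < 3 * se


class TestRescaleCounts:
    def test_full_detection_is_identity(self):
        np.testing.assert_array_equal(
            rescale_counts([1.0, 2.0], 1.0), [1.0, 2.0]
        )

    @pytest.mark.parametrize("p, factor", [(0.25, 4.0), (0.2, 5.0)])
    def test_reciprocal_scaling(self, p, factor):
        np.testing.assert_allclose(rescale_counts([10.0], p), [10.0 * factor])

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_probability_rejected(self, bad):
        with pytest.raises(dc.ConfigurationError):
            rescale_counts([1.0], bad)


class TestPanelPipeline:
    def test_effect_screen_reproduces_model_directions(self):
        """On a synthetic screen with the model's effect directions, the
        five panel comparisons are significant with the predicted sign,
        except spine copies (no effect)."""
        frame = synthetic_screen(ScreenConfig(n_soma=600, n_neurite=400),
                                 seed=12)
        report = screen_panel_report(frame, n_boot=200, seed=0)
        panels = report["panels"]
        assert panels["mrna_halflife_h"]["p_value"] < 1e-3
        assert (panels["mrna_halflife_h"]["median_neurite"]
                > panels["mrna_halflife_h"]["median_somata"])
        assert panels["transcript_nt"]["p_value"] < 1e-3
        assert (panels["transcript_nt"]["median_neurite"]
                > panels["transcript_nt"]["median_somata"])
        assert panels["protein_halflife_d"]["p_value"] < 1e-3
        assert (panels["protein_halflife_d"]["median_neurite"]
                < panels["protein_halflife_d"]["median_somata"])
        assert panels["protein_aa"]["p_value"] < 1e-3
        assert (panels["protein_aa"]["median_neurite"]
                > panels["protein_aa"]["median_somata"])
        assert panels["spine_copies"]["p_value"] > 0.05

    def test_missing_property_column_named_in_error(self):
        frame = pd.DataFrame({"gene": ["a"], "enrichment": [3.0]})
        with pytest.raises(dc.DataError, match="mrna_halflife_h"):
            screen_panel_report(frame, n_boot=10)


def test_coding_length_to_amino_acids():
    np.testing.assert_allclose(coding_length_to_aa([1434, 300]), [478, 100])
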