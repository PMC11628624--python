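"""Cohort scoring, tertile stratification and alteration classification."""

import numpy as np
import pandas as pd
import pytest

from notchsig import (
    ExpressionMatrix,
    GeneSignature,
    classify_notch_alteration,
    cross_stratify,
    median_dichotomize,
    quantile_dichotomize,
    signature_score,
    stratify_equal_groups,
)


def random_matrix(rng, n_genes=20, n_samples=30):
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(8, 2, size=(n_genes, n_samples)),
            index=[f"G{i:02d}" for i in range(n_genes)],
            columns=[f"s{i:02d}" for i in range(n_samples)],
        )
    )


class TestMedianDichotomize:
    def test_even_n_midpoint_median(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["G"], columns=list("abcd"))
        )
        calls = median_dichotomize(m, ["G"])
        assert calls.loc["G"].tolist() == [False, False, True, True]

    def test_constant_gene_all_low(self):
        m = ExpressionMatrix(
            pd.DataFrame([[5.0] * 4], index=["G"], columns=list("abcd"))
        )
        assert not median_dichotomize(m, ["G"]).values.any()

    def test_matches_brute_force_oracle(self, rng):
        m = random_matrix(rng)
        calls = median_dichotomize(m, list(m.genes))
        for g in m.genes:
            vals = sorted(m.values.loc[g])
            n = len(vals)
            med = (vals[n // 2 - 1] + vals[n // 2]) / 2  # even n
            for s in m.samples:
                assert calls.loc[g, s] == (m.values.loc[g, s] > med)

    def test_absent_genes_reported_not_fabricated(self, rng):
        m = random_matrix(rng)
        calls = median_dichotomize(m, ["G00", "NOPE"])
        assert list(calls.index) == ["G00"]
        assert calls.attrs["absent_genes"] == ["NOPE"]

    def test_no_genes_present_rejected(self, rng):
        with pytest.raises(ValueError, match="none of the requested"):
            median_dichotomize(random_matrix(rng), ["NOPE"])


class TestSignatureScore:
    def test_hand_tally(self, small_matrix):
        sig = GeneSignature("s", ("G1", "G2"))
        sv = signature_score(small_matrix, sig)
        # G1 medians at 2.5: HIGH for s3,s4; G2: HIGH for s1,s2
        assert sv.scores.tolist() == [1, 1, 1, 1]
        assert sv.coverage == 1.0

    def test_identical_samples_score_zero(self):
        m = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 5)), index=list("XYZ"), columns=list("abcde"))
        )
        sv = signature_score(m, GeneSignature("s", ("X", "Y", "Z")))
        assert (sv.scores == 0).all()

    def test_bounded_by_signature_size(self, rng):
        m = random_matrix(rng)
        sig = GeneSignature("s", tuple(m.genes[:7]))
        sv = signature_score(m, sig)
        assert sv.scores.between(0, 7).all()

    def test_invariant_under_monotone_transform(self, rng):
        m = random_matrix(rng)
        sig = GeneSignature("s", tuple(m.genes))
        transformed = ExpressionMatrix(np.exp(m.values * 0.3) + 5)
        sv1 = signature_score(m, sig)
        sv2 = signature_score(transformed, sig)
        pd.testing.assert_series_equal(sv1.scores, sv2.scores)

    def test_missing_value_gene_dropped_and_coverage(self, rng):
        m = random_matrix(rng, n_genes=4)
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        m2 = ExpressionMatrix(vals)
        sv = signature_score(m2, GeneSignature("s", tuple(m.genes)))
        assert sv.coverage == pytest.approx(3 / 4)
        assert m.genes[0] in sv.genes_missing


class TestStratifyEqualGroups:
    def test_exact_thirds(self):
        scores = pd.Series({f"s{i}": i for i in range(1, 10)})
        g = stratify_equal_groups(scores)
        assert g.counts().tolist() == [3, 3, 3]
        assert all(g.labels[f"s{i}"] == "LOW" for i in (1, 2, 3))
        assert all(g.labels[f"s{i}"] == "HIGH" for i in (7, 8, 9))

    def test_remainder_goes_low(self):
        scores = pd.Series({f"s{i}": i for i in range(10)})
        g = stratify_equal_groups(scores)
        assert g.counts().tolist() == [4, 3, 3]

    def test_ties_property_and_monotonicity(self, rng):
        scores = pd.Series(
            rng.integers(0, 5, size=200), index=[f"p{i:03d}" for i in range(200)]
        )
        g = stratify_equal_groups(scores)
        sizes = g.counts()
        assert sizes.max() - sizes.min() <= 1
        # label index is non-decreasing along the tie-broken order
        order = sorted(scores.index, key=lambda s: (scores[s], s))
        ranks = [("LOW", "INT", "HIGH").index(g.labels[s]) for s in order]
        assert ranks == sorted(ranks)

    def test_permutation_invariance(self, rng):
        scores = pd.Series(
            rng.integers(0, 4, size=50), index=[f"p{i}" for i in range(50)]
        )
        shuffled = scores.sample(frac=1, random_state=7)
        g1 = stratify_equal_groups(scores)
        g2 = stratify_equal_groups(shuffled)
        assert g1.labels.sort_index().equals(g2.labels.sort_index())

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratify_equal_groups(pd.Series({"a": 1, "b": 2}), k=3)


class TestQuantileDichotomize:
    def test_thirds_example(self):
        vals = pd.Series({f"s{i}": i for i in range(1, 10)})
        g = quantile_dichotomize(vals)
        assert set(g.labels[g.labels == "LOW"].index) == {"s1", "s2", "s3"}
        assert set(g.labels[g.labels == "HIGH"].index) == {"s7", "s8", "s9"}
        assert set(g.labels[g.labels == "EXCLUDED"].index) == {"s4", "s5", "s6"}

    def test_n3_floor_rule(self):
        g = quantile_dichotomize(pd.Series({"a": 1, "b": 2, "c": 3}))
        assert sorted(g.labels) == ["EXCLUDED", "HIGH", "LOW"]

    def test_tail_sizes_with_duplicates(self, rng):
        vals = pd.Series(
            rng.integers(0, 3, 100).astype(float), index=[f"p{i:03d}" for i in range(100)]
        )
        g = quantile_dichotomize(vals, q=1 / 3)
        counts = g.labels.value_counts()
        assert counts["LOW"] == counts["HIGH"] == 33
        assert counts.sum() == 100

    def test_rejects_tiny_cohort(self):
        with pytest.raises(ValueError):
            quantile_dichotomize(pd.Series({"a": 1, "b": 2}))


class TestCrossStratify:
    @staticmethod
    def make(labels_a, labels_b):
        from notchsig import GroupLabels

        idx = [f"s{i}" for i in range(len(labels_a))]
        a = GroupLabels(pd.Series(labels_a, index=idx), ("LOW", "INT", "HIGH"))
        b = GroupLabels(pd.Series(labels_b, index=idx), ("LOW", "EXCLUDED", "HIGH"))
        return a, b

    def test_combined_and_dropped(self):
        a, b = self.make(["HIGH", "INT", "LOW"], ["HIGH", "HIGH", "EXCLUDED"])
        combined = cross_stratify(a, b, a_name="NOTCH", b_name="SOX2")
        assert combined.labels["s0"] == "NOTCH_HIGH/SOX2_HIGH"
        assert set(combined.dropped) == {"s1", "s2"}

    def test_counts_match_crosstab_oracle(self, rng):
        la = rng.choice(["LOW", "INT", "HIGH"], 300)
        lb = rng.choice(["LOW", "EXCLUDED", "HIGH"], 300)
        a, b = self.make(list(la), list(lb))
        combined = cross_stratify(a, b)
        tab = pd.crosstab(la, lb)
        for x in ("LOW", "HIGH"):
            for y in ("LOW", "HIGH"):
                expect = tab.loc[x, y] if (x in tab.index and y in tab.columns) else 0
                assert (combined.labels == f"A_{x}/B_{y}").sum() == expect

    def test_mismatched_samples_rejected(self):
        a, b = self.make(["HIGH"], ["HIGH"])
        b2 = type(b)(pd.Series({"other": "HIGH"}), b.label_set)
        with pytest.raises(ValueError):
            cross_stratify(a, b2)


class TestClassifyNotchAlteration:
    def test_rules(self):
        table = pd.DataFrame(
            {
                "sample": ["p1", "p2", "p2", "p3", "p4"],
                "gene": ["NOTCH2", "NOTCH3", "NOTCH1", "TP53", "NOTCH4"],
                "missense": [True, False, True, True, False],
                "cna": [0, 2, 0, 2, 1],
            }
        )
        calls = classify_notch_alteration(table)
        assert calls["p1"] == "mutated"
        assert calls["p2"] == "mutated+amplified"
        assert calls["p3"] == "none"  # TP53 records don't count
        assert calls["p4"] == "none"  # gain (cna=1) is not high-level amplification

    def test_unknown_cna_code_rejected(self):
        table = pd.DataFrame(
            {"sample": ["p1"], "gene": ["NOTCH1"], "missense": [False], "cna": [3]}
        )
        with pytest.raises(ValueError, match="cna"):
            classify_notch_alteration(table)
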