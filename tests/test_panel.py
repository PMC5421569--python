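"""Tests for panel summaries, Fisher specificity testing and threshold sweeps."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixcall import (
    DEFAULT_THRESHOLDS,
    call_expression,
    fisher_exact_two_tailed,
    summarize_panel,
    sweep_from_callset,
    threshold_sweep,
    tissue_specificity,
)
from mixcall.calling import CallSet
from mixcall.mixture import EMConfig
from mixcall.panel import (
    format_percentage,
    panel_specificity,
    percentage,
    round_half_away,
)

from conftest import SMALL, tweak


def exact_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: two-sided Fisher p by exhaustive hypergeometric
    enumeration in exact rational arithmetic (minimum-likelihood convention,
    ties included at exact equality)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = math.comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom) for x in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (8, 52, 1, "15.4"),
            (332, 476, 1, "69.7"),
            (476, 968, 1, "49.2"),
            (56, 301, 1, "18.6"),
            (14, 474, 0, "3"),
        ],
    )
    def test_reported_percentage_formatting(self, num, den, decimals, expected):
        assert format_percentage(num, den, decimals) == expected

    def test_half_rounds_away_from_zero(self):
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3
        assert round_half_away(0.5, 0) == 1.0

    def test_zero_denominator_is_undefined(self):
        assert math.isnan(percentage(3, 0))
        assert format_percentage(3, 0) == "undefined"


class TestFisher:
    def test_printed_contingency_geometry_is_significant(self):
        p, odds = fisher_exact_two_tailed([[8, 44], [0, 916]])
        assert p < 1e-4
        assert odds == math.inf
        assert p == pytest.approx(exact_fisher_p(8, 44, 0, 916), abs=1e-12)

    def test_zero_column_margin_gives_p_one(self):
        p, _ = fisher_exact_two_tailed([[0, 52], [0, 916]])
        assert p == 1.0

    def test_three_outcome_enumeration_by_hand(self):
        # support x in {0,1,2}; P(obs)=0.2; tables with P<=0.2 are x=0, x=2
        p, _ = fisher_exact_two_tailed([[2, 1], [0, 3]])
        assert p == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize(
        "table,expected_odds",
        [
            ([[2, 3], [4, 5]], (2 * 5) / (3 * 4)),
            ([[2, 0], [0, 3]], math.inf),
            ([[0, 2], [3, 0]], 0.0),
        ],
    )
    def test_odds_ratio_conventions(self, table, expected_odds):
        _, odds = fisher_exact_two_tailed(table)
        assert odds == expected_odds

    def test_nan_odds_when_both_diagonals_zero(self):
        _, odds = fisher_exact_two_tailed([[0, 2], [0, 3]])
        assert math.isnan(odds)

    @pytest.mark.parametrize(
        "table", [[[1, 2]], [[-1, 2], [3, 4]], [[0, 0], [0, 0]], [[1.5, 2], [3, 4]]]
    )
    def test_invalid_tables_rejected(self, table):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(table)

    def test_exhaustive_agreement_with_oracle_small_totals(self):
        for n in range(1, 21):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        p, _ = fisher_exact_two_tailed([[a, b], [c, d]])
                        assert abs(p - exact_fisher_p(a, b, c, d)) < 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(
        cells=st.tuples(*(st.integers(0, 60) for _ in range(4))).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_random_tables_match_oracle(self, cells):
        a, b, c, d = cells
        p, _ = fisher_exact_two_tailed([[a, b], [c, d]])
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(exact_fisher_p(a, b, c, d), abs=1e-9)


def _manual_callset(post, labels, eff_post=None, threshold=0.95):
    post = pd.DataFrame(post)
    post.index = [f"G{i}" for i in range(post.shape[0])]
    post.columns = [f"S{j}" for j in range(post.shape[1])]
    if eff_post is None:
        eff_post = pd.DataFrame(np.zeros((0, post.shape[1])), columns=post.columns)
    else:
        eff_post = pd.DataFrame(eff_post, columns=post.columns)
        eff_post.index = [f"E{i}" for i in range(eff_post.shape[0])]
    return CallSet(
        posterior=post,
        effector_posterior=eff_post,
        tissue_labels=pd.Series(labels, index=post.columns),
        threshold_used=threshold,
    )


class TestSummarize:
    def test_hand_built_counts(self):
        # 4 samples: S0 expresses G0+G1 (+effector), S1 expresses G1 only
        # (no effector), S2 and S3 express nothing
        post = [
            [0.99, 0.10, 0.20, 0.94],
            [0.98, 0.97, 0.00, 0.50],
        ]
        eff = [[0.999, 0.10, 0.999, 0.10]]
        s = summarize_panel(_manual_callset(post, ["a", "a", "b", "b"], eff))
        assert s.n_panel_genes_tested == 2
        assert s.n_genes_expressed_anywhere == 2
        assert s.n_samples_total == 4
        assert s.n_samples_expressing_any == 2
        assert s.n_samples_expressing_exactly_one == 1
        assert s.n_expressing_with_effector == 1
        assert s.pct_samples_expressing_any == pytest.approx(50.0)
        assert s.pct_exactly_one_of_expressing == pytest.approx(50.0)
        assert s.effector_coexpression_pct == pytest.approx(50.0)

    def test_no_positives_leaves_conditional_percentages_undefined(self):
        s = summarize_panel(_manual_callset([[0.1, 0.2]], ["a", "b"]))
        assert s.n_samples_expressing_any == 0
        assert s.pct_samples_expressing_any == 0.0
        assert math.isnan(s.pct_exactly_one_of_expressing)
        assert s.to_dict()["fmt_exactly_one_of_expressing"] == "undefined"

    def test_synthetic_summary_reflects_planted_structure(
        self, small_calls, small_config, small_fixture
    ):
        _, truth = small_fixture
        s = summarize_panel(small_calls)
        n_pos = len(truth.planted_positive_samples)
        assert s.n_genes_expressed_anywhere == 1
        assert s.n_samples_expressing_any == n_pos
        assert s.n_samples_expressing_exactly_one == n_pos
        expected_eff = round(small_config.effector_coexpression_rate * n_pos)
        assert s.n_expressing_with_effector == expected_eff


class TestSpecificity:
    def test_planted_gene_table_matches_truth(
        self, small_calls, small_fixture, small_config
    ):
        _, truth = small_fixture
        res = tissue_specificity(
            small_calls, small_config.planted_gene_id, small_config.planted_tissue
        )
        n_pos = len(truth.planted_positive_samples)
        assert res.positives_in_focal == n_pos
        assert res.positives_elsewhere == 0
        assert res.table.sum() == len(small_calls.samples)
        assert res.p_two_tailed == pytest.approx(
            exact_fisher_p(*res.table.ravel()), abs=1e-12
        )

    def test_unknown_gene_and_tissue_raise_named_errors(self, small_calls):
        with pytest.raises(KeyError, match="NOPE"):
            tissue_specificity(small_calls, "NOPE", "melanoma")
        with pytest.raises(KeyError, match="liver"):
            tissue_specificity(small_calls, "OR2C3", "liver")

    def test_gene_with_no_positives_gives_p_one(self, small_calls, small_config):
        silent = small_config.panel_gene_ids()[1]
        res = tissue_specificity(small_calls, silent, "melanoma")
        assert res.positives_in_focal == 0 and res.positives_elsewhere == 0
        assert res.p_two_tailed == 1.0

    def test_sample_order_invariance(self, small_calls, small_config):
        import dataclasses

        perm = np.random.default_rng(0).permutation(len(small_calls.samples))
        cols = small_calls.samples[perm]
        shuffled = dataclasses.replace(
            small_calls,
            posterior=small_calls.posterior[cols],
            effector_posterior=small_calls.effector_posterior[cols],
            tissue_labels=small_calls.tissue_labels[cols],
        )
        a = tissue_specificity(small_calls, small_config.planted_gene_id, "melanoma")
        b = tissue_specificity(shuffled, small_config.planted_gene_id, "melanoma")
        assert np.array_equal(a.table, b.table)
        assert a.p_two_tailed == b.p_two_tailed

    def test_panel_table_has_one_row_per_gene(self, small_calls):
        df = panel_specificity(small_calls, "melanoma", bonferroni=True)
        assert len(df) == len(small_calls.panel_genes)
        assert (df["p_bonferroni"] >= df["p_two_tailed"] - 1e-15).all()

    def test_fisher_p_decreases_with_penetrance(self):
        # planted positives grow with penetrance while the rest stays empty
        p_values = []
        for pen in (0.1, 0.3, 0.5, 0.8):
            cfg = tweak(SMALL, planted_penetrance=pen, seed=21)
            from mixcall import generate_matrix

            matrix, _ = generate_matrix(cfg)
            calls = call_expression(
                matrix, cfg.panel_gene_ids(), em=EMConfig(seed=2)
            )
            res = tissue_specificity(calls, cfg.planted_gene_id, cfg.planted_tissue)
            p_values.append(res.p_two_tailed)
        assert all(b <= a + 1e-15 for a, b in zip(p_values, p_values[1:]))


class TestSweep:
    def test_flat_curve_on_cleanly_separated_fixture(
        self, small_calls, small_fixture, small_config
    ):
        _, truth = small_fixture
        curve = sweep_from_callset(
            small_calls, small_config.planted_gene_id, small_config.planted_tissue
        )
        n_pos = len(truth.planted_positive_samples)
        assert curve.thresholds == DEFAULT_THRESHOLDS
        assert np.all(curve.focal_counts == n_pos)
        assert np.all(curve.other_counts == 0)

    def test_counts_non_increasing_in_threshold(self, small_calls, small_config):
        for gene in list(small_calls.panel_genes[:5]):
            curve = sweep_from_callset(small_calls, gene, "melanoma")
            assert np.all(np.diff(curve.focal_counts) <= 0)
            assert np.all(np.diff(curve.other_counts) <= 0)

    def test_single_threshold_sweep_equals_call_composition(
        self, small_fixture, small_config
    ):
        matrix, _ = small_fixture
        em = EMConfig(seed=3)
        curve = threshold_sweep(
            matrix,
            small_config.panel_gene_ids(),
            list(small_config.effector_gene_ids),
            small_config.planted_gene_id,
            small_config.planted_tissue,
            em=em,
            thresholds=[0.95],
        )
        calls = call_expression(
            matrix,
            small_config.panel_gene_ids(),
            list(small_config.effector_gene_ids),
            em=em,
        )
        res = tissue_specificity(
            calls, small_config.planted_gene_id, small_config.planted_tissue
        )
        assert curve.focal_counts[0] == res.positives_in_focal
        assert curve.other_counts[0] == res.positives_elsewhere

    @pytest.mark.parametrize(
        "bad", [[], [0.5, 0.2], [0.0, 0.5], [0.5, 0.5], [0.5, 1.0]]
    )
    def test_invalid_ladders_rejected(self, small_calls, bad):
        with pytest.raises(ValueError):
            sweep_from_callset(small_calls, "OR2C3", "melanoma", bad)
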