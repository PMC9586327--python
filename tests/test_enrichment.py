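"""iBioID enrichment statistics: normalization, ratios, t test, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinetools import enrichment as en
from spinetools import simulate
from spinetools.errors import NormalizationError, ValidationError


def _table(bait_rows, ctrl_rows, protein_ids=None, controls=(50, 50)):
    """Build a table from per-protein (bait counts, ctrl counts) tuples."""
    n_bait = len(bait_rows[0])
    n_ctrl = len(ctrl_rows[0])
    samples = [f"bait_{i}" for i in range(n_bait)] + [f"ctrl_{i}" for i in range(n_ctrl)]
    data = [list(b) + list(c) for b, c in zip(bait_rows, ctrl_rows)]
    ids = protein_ids or [f"prot_{i}" for i in range(len(bait_rows))]
    frame = pd.DataFrame(data, index=ids, columns=samples, dtype=float)
    frame.loc["Pcca"] = controls[0]
    frame.loc["Pc"] = controls[1]
    groups = {s: ("bait" if s.startswith("bait") else "control") for s in samples}
    return en.PeptideCountTable(counts=frame, groups=groups)


class TestNormalization:
    def test_divides_by_control_sum(self):
        table = _table([(5, 5, 5, 5)], [(5, 5, 5)], controls=(4, 6))  # sum 10
        norm = en.normalize_by_endogenous(table)
        assert norm.counts.loc["prot_0", "bait_0"] == pytest.approx(0.5)
        # control rows retained, unscaled
        assert norm.counts.loc["Pcca", "bait_0"] == 4

    def test_scale_invariance_per_sample(self):
        table = _table([(8, 6, 7, 9), (3, 2, 4, 5)], [(2, 3, 1), (1, 1, 2)])
        scaled = table.counts.copy()
        scaled["bait_1"] *= 3.0  # controls included
        table3 = en.PeptideCountTable(counts=scaled, groups=table.groups)
        a = en.normalize_by_endogenous(table).counts
        b = en.normalize_by_endogenous(table3).counts
        pd.testing.assert_frame_equal(
            a.drop(index=["Pcca", "Pc"]), b.drop(index=["Pcca", "Pc"])
        )

    def test_missing_control_names_sample(self):
        table = _table([(1, 1, 1, 1)], [(1, 1, 1)])
        broken = table.counts.drop(index=["Pc"])
        t2 = en.PeptideCountTable(counts=broken, groups=table.groups)
        with pytest.raises(NormalizationError, match="Pc"):
            en.normalize_by_endogenous(t2)

    def test_zero_control_sum_names_sample(self):
        table = _table([(1, 1, 1, 1)], [(1, 1, 1)])
        zeroed = table.counts.copy()
        zeroed.loc[["Pcca", "Pc"], "ctrl_1"] = 0
        t2 = en.PeptideCountTable(counts=zeroed, groups=table.groups)
        with pytest.raises(NormalizationError, match="ctrl_1"):
            en.normalize_by_endogenous(t2)

    def test_input_table_untouched(self):
        table = _table([(5, 5, 5, 5)], [(5, 5, 5)])
        before = table.counts.copy()
        en.normalize_by_endogenous(table)
        pd.testing.assert_frame_equal(table.counts, before)


class TestEnrichmentRatio:
    def test_mean_ratio(self):
        frame = en.enrichment_ratio(_table([(4, 4, 4, 4)], [(2, 2, 2)]))
        assert frame.loc["prot_0", "ratio"] == pytest.approx(2.0)

    def test_identical_groups_ratio_one(self):
        frame = en.enrichment_ratio(_table([(3, 3, 3, 3)], [(3, 3, 3)]))
        assert frame.loc["prot_0", "ratio"] == pytest.approx(1.0)

    def test_zero_control_gives_infinite_flag(self):
        frame = en.enrichment_ratio(_table([(4, 4, 4, 4)], [(0, 0, 0)]))
        assert np.isinf(frame.loc["prot_0", "ratio"])

    def test_zero_over_zero_undefined(self):
        frame = en.enrichment_ratio(_table([(0, 0, 0, 0)], [(0, 0, 0)]))
        assert np.isnan(frame.loc["prot_0", "ratio"])


class TestTTest:
    def test_identical_groups_not_significant(self):
        res = en.test_enrichment(_table([(7, 7, 7, 7)], [(7, 7, 7)]))
        row = res.loc["prot_0"]
        assert (row.t_stat, row.p_value, row.significant) == (0.0, 1.0, False)

    def test_zero_variance_different_means_is_significant(self):
        res = en.test_enrichment(_table([(10, 10, 10, 10)], [(2, 2, 2)]))
        row = res.loc["prot_0"]
        assert row.p_value == 0.0 and row.significant

    def test_matches_scipy_pooled_t_on_random_counts(self):
        rng = np.random.default_rng(12)
        bait = rng.poisson(20, size=(50, 4))
        ctrl = rng.poisson(15, size=(50, 3))
        table = _table(list(map(tuple, bait)), list(map(tuple, ctrl)))
        res = en.test_enrichment(table)
        t_ref, p_ref = stats.ttest_ind(bait, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_stat"].to_numpy()[:50], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy()[:50], p_ref, rtol=1e-10)

    def test_significance_requires_enrichment_direction(self):
        # control-enriched protein: tiny p but ratio < 1 must never be called
        res = en.test_enrichment(_table([(2, 3, 2, 3)], [(40, 41, 42)]))
        row = res.loc["prot_0"]
        assert row.p_value < 0.01 and row.ratio < 1 and not row.significant

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(13)
        bait = rng.poisson(20, size=(20, 4))
        ctrl = rng.poisson(15, size=(20, 3))
        table = _table(list(map(tuple, bait)), list(map(tuple, ctrl)))
        res = en.test_enrichment(table)
        shuffled = table.counts.sample(frac=1, random_state=1)[
            list(table.counts.columns[::-1])
        ]
        res2 = en.test_enrichment(en.PeptideCountTable(counts=shuffled, groups=table.groups))
        pd.testing.assert_frame_equal(res.sort_index(), res2.sort_index())


class TestRunExperiment:
    def test_tiny_alpha_with_no_enrichment_gives_empty_set(self):
        table, _ = simulate.generate_proteomics_table(
            simulate.ProteomicsSimSpec(n_proteins=200, frac_enriched=0.0, seed=21)
        )
        res = en.run_experiment(table, alpha=1e-6)
        assert res.significant == set()

    def test_spiked_simulation_recall(self):
        spec = simulate.ProteomicsSimSpec(
            n_proteins=500, frac_enriched=0.05, log2_fc=2.0, baseline_mean=100.0, seed=22
        )
        table, truth = simulate.generate_proteomics_table(spec)
        res = en.run_experiment(table, "raw")
        recall = len(res.significant & set(truth)) / len(truth)
        assert recall >= 0.8

    def test_significant_set_respects_gates(self):
        table, _ = simulate.generate_proteomics_table(
            simulate.ProteomicsSimSpec(n_proteins=300, frac_enriched=0.1, seed=23)
        )
        res = en.run_experiment(table, "raw", alpha=0.1)
        sig = res.results.loc[sorted(res.significant)]
        assert (sig["p_value"] < 0.1).all() and (sig["ratio"] > 1).all()

    def test_controls_excluded_from_results(self):
        table, _ = simulate.generate_proteomics_table(
            simulate.ProteomicsSimSpec(n_proteins=50, seed=24)
        )
        res = en.run_experiment(table, "endogenous_normalized")
        assert not set(table.control_ids) & set(res.results.index)

    def test_power_monotone_in_effect_size(self):
        recalls = []
        for lfc in (0.5, 1.0, 2.0):
            spec = simulate.ProteomicsSimSpec(
                n_proteins=800, frac_enriched=0.1, log2_fc=lfc, seed=25
            )
            table, truth = simulate.generate_proteomics_table(spec)
            res = en.run_experiment(table, "raw")
            recalls.append(len(res.significant & set(truth)) / len(truth))
        assert recalls == sorted(recalls)

    def test_unknown_mode_rejected(self):
        table, _ = simulate.generate_proteomics_table(
            simulate.ProteomicsSimSpec(n_proteins=10, seed=26)
        )
        with pytest.raises(ValidationError):
            en.run_experiment(table, "fancy")


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, (1.0, 1.0)),
            ({"x"}, {"y"}, (0.0, 0.0)),
            ({"a", "b", "c"}, {"b", "c", "d", "e"}, (2 / 3, 1 / 2)),
        ],
    )
    def test_directional_fractions(self, a, b, expected):
        assert en.cross_experiment_overlap(a, b) == pytest.approx(expected)

    def test_empty_denominator_flagged_undefined(self):
        fa, fb = en.cross_experiment_overlap(set(), {"x"})
        assert np.isnan(fa) and fb == 0.0
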