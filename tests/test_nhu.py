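"""Native-holdup MS depletion statistics: normalization, imputation, testing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affinomap.affinity import BaitConcentration
from affinomap.nhu import (
    DEFAULT_BI_THRESHOLD,
    DEFAULT_P_CAP,
    IntensityTable,
    analyze_depletion,
    call_significant,
    compare_experiments,
    depletion_to_bi,
    impute_missing,
    interactome_similarity,
    normalize_median,
)
from affinomap.nhu import test_depletion as depletion_ttest
from affinomap.synthetic import generate_proteome, simulate_nhu_ms


def make_table(values, roles=None):
    values = pd.DataFrame(values)
    values.index = [f"P{i}" for i in range(len(values))]
    cols = list(values.columns)
    roles = roles or (["bait"] * (len(cols) // 2) + ["control"] * (len(cols) - len(cols) // 2))
    samples = pd.DataFrame(
        {"sample_id": cols, "role": roles, "replicate": range(1, len(cols) + 1)}
    )
    return IntensityTable(values, samples)


class TestIntensityTable:
    def test_requires_both_roles(self):
        with pytest.raises(ValueError, match="control"):
            make_table({"a": [1.0], "b": [2.0]}, roles=["bait", "bait"])

    def test_rejects_duplicate_protein_ids(self):
        values = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["P", "P"])
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "role": ["bait", "control"], "replicate": [1, 1]}
        )
        with pytest.raises(ValueError, match="unique"):
            IntensityTable(values, samples)


class TestNormalizeMedian:
    def test_doubled_sample_equalized(self):
        t = make_table({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = normalize_median(t)
        assert np.nanmedian(out.values["a"]) == pytest.approx(
            np.nanmedian(out.values["b"])
        )

    def test_three_by_three_hand_oracle(self):
        # detected values: a={1,2,3} med 2; b={10,20,30} med 20; c={2,4,6} med 4
        # grand median of all nine = 4; factors 2, 0.2, 1
        t = make_table(
            {"a": [1.0, 2.0, 3.0], "b": [10.0, 20.0, 30.0], "c": [2.0, 4.0, 6.0]},
            roles=["bait", "control", "control"],
        )
        out = normalize_median(t)
        assert list(out.values["a"]) == pytest.approx([2.0, 4.0, 6.0])
        assert list(out.values["b"]) == pytest.approx([2.0, 4.0, 6.0])
        assert list(out.values["c"]) == pytest.approx([2.0, 4.0, 6.0])

    def test_idempotent(self):
        t = make_table({"a": [1.0, 5.0, 9.0], "b": [4.0, 2.0, 7.0]})
        once = normalize_median(t)
        twice = normalize_median(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_missing_entries_untouched(self):
        t = make_table({"a": [1.0, np.nan, 3.0], "b": [2.0, 4.0, np.nan]})
        out = normalize_median(t)
        assert np.isnan(out.values.loc["P1", "a"])
        assert np.isnan(out.values.loc["P2", "b"])

    def test_all_missing_sample_is_named_error(self):
        t = make_table({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="b"):
            normalize_median(t)


class TestImputeMissing:
    def test_no_missing_identity(self):
        t = make_table({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = impute_missing(t, seed=0)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_imputed_values_from_low_pool_and_detected_bit_identical(self):
        rng = np.random.default_rng(1)
        vals = {
            "a": rng.lognormal(10, 1, 50),
            "b": rng.lognormal(10, 1, 50),
        }
        vals["a"][::7] = np.nan
        t = make_table(vals)
        out = impute_missing(t, low_fraction=0.10, seed=5)
        detected = t.values.to_numpy()[~np.isnan(t.values.to_numpy())]
        cutoff = np.quantile(detected, 0.10)
        was_missing = np.isnan(t.values.to_numpy())
        assert np.all(out.values.to_numpy()[was_missing] <= cutoff)
        # detected cells unchanged bit for bit
        assert np.array_equal(
            out.values.to_numpy()[~was_missing], t.values.to_numpy()[~was_missing]
        )

    def test_seed_determinism(self):
        vals = {"a": [1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
                "b": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]}
        t = make_table(vals)
        a = impute_missing(t, seed=42)
        b = impute_missing(t, seed=42)
        c = impute_missing(t, seed=43)
        pd.testing.assert_frame_equal(a.values, b.values)
        was_missing = np.isnan(t.values.to_numpy())
        # different seeds differ only at imputed cells
        assert np.array_equal(
            a.values.to_numpy()[~was_missing], c.values.to_numpy()[~was_missing]
        )


class TestDepletionTest:
    def test_identical_groups(self):
        fc, p = depletion_ttest([2.0, 4.0, 8.0], [2.0, 4.0, 8.0])
        assert fc == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_two_sample_oracle(self):
        bait, ctrl = [2.0, 4.0, 6.0], [4.0, 8.0, 12.0]
        fc, p = depletion_ttest(bait, ctrl)
        assert fc == pytest.approx(-1.0)
        # independent textbook computation with the t CDF
        lb, lc = np.log2(bait), np.log2(ctrl)
        sp2 = (lb.var(ddof=1) + lc.var(ddof=1)) / 2.0
        t = (lb.mean() - lc.mean()) / math.sqrt(sp2 * (2.0 / 3.0))
        p_oracle = 2.0 * stats.t.sf(abs(t), df=4)
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_zero_variance_separated_groups(self):
        fc, p = depletion_ttest([1.0, 1.0, 1.0], [4.0, 4.0, 4.0])
        assert fc == pytest.approx(-2.0)
        assert 0.0 < p < 1e-300  # representable positive, not zero

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            depletion_ttest([1.0], [2.0, 3.0])


class TestDepletionToBI:
    @pytest.mark.parametrize(
        "fc,bi", [(0.0, 0.0), (-1.0, 0.5), (1.0, 0.0)]
    )
    def test_reference_points(self, fc, bi):
        assert depletion_to_bi(fc).bi == pytest.approx(bi)

    def test_enrichment_clamped(self):
        assert depletion_to_bi(0.7).clamped

    def test_chain_to_apparent_affinity(self, bait10):
        """log2fc -2.1375 converts through BI and the hyperbola to pK ~5.53."""
        from affinomap.affinity import bi_to_kd, kd_to_pk

        bi = depletion_to_bi(-2.1375)
        assert bi.bi == pytest.approx(1.0 - 2.0**-2.1375)
        assert bi.bi == pytest.approx(0.7727, abs=1e-4)
        pk = kd_to_pk(bi_to_kd(bi, bait10))
        oracle = -math.log10(10e-6 * (2.0**-2.1375) / (1.0 - 2.0**-2.1375))
        assert pk == pytest.approx(oracle, rel=1e-12)
        assert pk == pytest.approx(5.53, abs=0.01)


class TestCallSignificant:
    def make_results(self, rows):
        return pd.DataFrame(
            rows, columns=["pvalue", "bi"], index=[f"P{i}" for i in range(len(rows))]
        )

    def test_conjunctive_gate(self):
        res = self.make_results([(0.5, 0.9), (1e-4, 0.5), (1e-4, 0.01)])
        out = call_significant(res)
        assert list(out["significant"]) == [False, True, False]
        assert out.attrs["p_cap"] == DEFAULT_P_CAP
        assert out.attrs["bi_threshold"] == DEFAULT_BI_THRESHOLD

    def test_empty_results(self):
        out = call_significant(self.make_results([]))
        assert len(out) == 0


def _results_frame(data):
    df = pd.DataFrame(
        data, columns=["protein_id", "pk", "bi", "pvalue", "significant"]
    ).set_index("protein_id")
    return df


class TestCompareExperiments:
    def test_self_comparison(self):
        a = _results_frame(
            [("P1", 5.0, 0.5, 1e-4, True), ("P2", 6.0, 0.8, 1e-5, True),
             ("P3", 4.7, 0.3, 1e-3, True), ("P4", 4.2, 0.05, 0.5, False)]
        )
        cmp = compare_experiments(a, a)
        assert cmp.recall_ab == 1.0 and cmp.recall_ba == 1.0
        assert cmp.pcc == pytest.approx(1.0)
        assert cmp.fit_slope == pytest.approx(1.0)

    def test_disjoint_significant_sets(self):
        a = _results_frame([("P1", 5.0, 0.5, 1e-4, True), ("P2", 4.0, 0.01, 0.9, False)])
        b = _results_frame([("P1", 4.0, 0.01, 0.9, False), ("P2", 5.0, 0.5, 1e-4, True)])
        cmp = compare_experiments(a, b)
        assert cmp.recall_ab == 0.0 and cmp.recall_ba == 0.0
        assert not cmp.correlation_defined

    def test_sub_significant_depletion_counts_as_recovered(self):
        a = _results_frame([("P1", 5.0, 0.5, 1e-4, True)])
        b = _results_frame([("P1", 5.0, 0.5, 0.2, False)])  # depleted, not significant
        assert compare_experiments(a, b).recall_ab == 1.0
        assert compare_experiments(a, b, recovered="significant").recall_ab == 0.0

    def test_synthetic_pair_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        ids = [f"P{i}" for i in range(40)]
        true_pk = rng.uniform(4.5, 6.5, 40)
        rows_a, rows_b = [], []
        for i, pid in enumerate(ids):
            for rows, seed_off in ((rows_a, 0), (rows_b, 1)):
                pk = true_pk[i] + rng.normal(0, 0.1)
                bi = rng.uniform(0.05, 0.95)
                sig = bool(rng.random() < 0.6)
                rows.append((pid, pk, bi, 1e-3 if sig else 0.5, sig))
        a, b = _results_frame(rows_a), _results_frame(rows_b)
        cmp = compare_experiments(a, b)
        # brute-force: recompute recall and pcc from first principles
        a_sig = [p for p in ids if a.loc[p, "significant"]]
        rec = np.mean(
            [b.loc[p, "significant"] or b.loc[p, "bi"] >= DEFAULT_BI_THRESHOLD for p in a_sig]
        )
        assert cmp.recall_ab == pytest.approx(rec)
        both = [p for p in ids if a.loc[p, "significant"] and b.loc[p, "significant"]]
        x, y = a.loc[both, "pk"], b.loc[both, "pk"]
        r = np.corrcoef(x, y)[0, 1]
        assert cmp.pcc == pytest.approx(r)
        t = r * math.sqrt((len(both) - 2) / (1 - r * r))
        assert cmp.correlation_pvalue == pytest.approx(2 * stats.t.sf(abs(t), len(both) - 2))
        assert cmp.band_lower.shape == cmp.band_x.shape


class TestInteractomeSimilarity:
    def test_affine_profiles_fully_correlated(self):
        a = _results_frame(
            [("P1", 5.0, 0.5, 1e-4, True), ("P2", 6.0, 0.6, 1e-4, True),
             ("P3", 7.0, 0.7, 1e-4, True)]
        )
        b = a.copy()
        b["pk"] = [5.1, 6.1, 7.1]
        out = interactome_similarity({"A": a, "B": b})
        ab = out[(out.bait_a == "A") & (out.bait_b == "B")].iloc[0]
        assert ab.pcc == pytest.approx(1.0)
        aa = out[(out.bait_a == "A") & (out.bait_b == "A")].iloc[0]
        assert aa.pcc == 1.0

    def test_insufficient_overlap_flagged(self):
        a = _results_frame([("P1", 5.0, 0.5, 1e-4, True), ("P2", 6.0, 0.6, 1e-4, True)])
        b = _results_frame([("P1", 5.0, 0.5, 1e-4, True), ("P2", 6.0, 0.6, 1e-4, False)])
        out = interactome_similarity({"A": a, "B": b})
        ab = out[(out.bait_a == "A") & (out.bait_b == "B")].iloc[0]
        assert not ab.defined and math.isnan(ab.pcc)

    def test_three_baits_match_brute_force(self):
        rng = np.random.default_rng(3)
        ids = [f"P{i}" for i in range(30)]
        frames = {}
        for bait in "ABC":
            rows = [
                (pid, rng.uniform(4.5, 6.5), rng.uniform(0.2, 0.9),
                 1e-3, bool(rng.random() < 0.7))
                for pid in ids
            ]
            frames[bait] = _results_frame(rows)
        out = interactome_similarity(frames)
        for x, y in [("A", "B"), ("B", "C"), ("A", "C")]:
            both = [
                p for p in ids
                if frames[x].loc[p, "significant"] and frames[y].loc[p, "significant"]
            ]
            r = np.corrcoef(frames[x].loc[both, "pk"], frames[y].loc[both, "pk"])[0, 1]
            row = out[(out.bait_a == x) & (out.bait_b == y)].iloc[0]
            assert row.pcc == pytest.approx(r)
            assert row.n == len(both)
            rev = out[(out.bait_a == y) & (out.bait_b == x)].iloc[0]
            assert rev.pcc == pytest.approx(row.pcc)  # symmetry


def test_false_positive_control_null_tables():
    """The conjunctive gate's null false-call rate matches its statistics.

    With no true binders, a two-sided t-test at p <= 0.05 places 2.5% of
    proteins in the depleted tail; at the generator's default
    injection-noise level nearly all of those also clear the BI >= 0.128
    gate, so the expected false-call fraction is just above 2%. Twenty
    simulated null extracts must stay below 3% in aggregate (the derived
    bound plus sampling error) and well below the uncontrolled two-sided 5%.
    """
    bait = BaitConcentration.from_micromolar(10.0)
    fracs = []
    for i in range(20):
        truth = generate_proteome(n_proteins=300, implant_rate=0.0, seed=500 + i)
        table = simulate_nhu_ms(truth, seed=600 + i)
        res = analyze_depletion(table, bait=bait, seed=700 + i)
        fracs.append(res["significant"].mean())
    assert float(np.mean(fracs)) <= 0.03
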