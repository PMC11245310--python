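"""Plate-readout conversion, affinity profiles, FL-vs-motif stats, logos."""

import math

import numpy as np
import pytest

from affinomap.affinity import AffinityValue, BaitConcentration, kd_to_bi, kd_to_pk
from affinomap.fragmentomics import (
    PlateReadout,
    build_profile,
    compare_fl_vs_motifs,
    plate_to_bi,
    specificity_logo,
)
from affinomap.synthetic import simulate_fragment_holdup


def readout(pid="pep", trp_s=100.0, trp_c=100.0, s1=50.0, s1c=50.0, s2=30.0, s2c=30.0):
    return PlateReadout(pid, trp_s, trp_c, s1, s1c, s2, s2c)


class TestPlateToBI:
    def test_equal_channels_zero_depletion(self):
        assert plate_to_bi(readout()).bi == pytest.approx(0.0)

    def test_halved_trp_is_half_depletion(self):
        assert plate_to_bi(readout(trp_s=50.0)).bi == pytest.approx(0.5)

    def test_loading_drift_corrected_by_standards(self):
        # all sample channels drifted x1.1; trp additionally halved
        r = readout(trp_s=100 * 1.1 * 0.5, s1=50 * 1.1, s2=30 * 1.1)
        assert plate_to_bi(r).bi == pytest.approx(0.5, rel=1e-12)

    def test_negative_depletion_clamped(self):
        r = readout(trp_s=110.0)
        bi = plate_to_bi(r)
        assert bi.bi == 0.0 and bi.clamped

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValueError):
            readout(trp_s=0.0)


class TestBuildProfile:
    def test_half_saturation_at_fragment_bait(self, bait4):
        prof = build_profile([readout(trp_s=50.0)], bait4, bi_threshold=0.128)
        assert prof.values[0].pk == pytest.approx(kd_to_pk(4e-6))
        assert not prof.values[0].censored

    def test_all_below_threshold_censored(self, bait4):
        prof = build_profile(
            [readout(pid=f"p{i}", trp_s=99.0) for i in range(3)],
            bait4, bi_threshold=0.128,
        )
        assert all(v.censored for v in prof.values)

    def test_missing_panel_members_flagged(self, bait4):
        prof = build_profile(
            [readout(pid="a", trp_s=50.0)], bait4, 0.128, panel=["a", "b"]
        )
        assert prof.missing == ["b"]
        assert prof.value_for("b").censored

    def test_duplicate_peptides_rejected(self, bait4):
        with pytest.raises(ValueError):
            build_profile([readout(pid="a"), readout(pid="a")], bait4, 0.128)

    def test_mixed_panel_matches_elementwise_oracle(self, bait4):
        kds = {"a": 1e-6, "b": 20e-6, "c": 500e-6}
        rds = simulate_fragment_holdup(kds, bait=bait4, cv=0.0, loading_sd=0.0, seed=0)
        prof = build_profile(rds, bait4, bi_threshold=0.05)
        for pid, kd in kds.items():
            bi = kd_to_bi(kd, bait4)
            v = prof.value_for(pid)
            if bi <= 0.05:
                assert v.censored
            else:
                assert v.pk == pytest.approx(kd_to_pk(kd), rel=1e-9)


class TestCompareFlVsMotifs:
    def test_identical_values_perfect_agreement(self, profile_factory):
        prof = profile_factory([5.0, 6.0, 7.0])
        fl = {f"prot{i}": AffinityValue(pk) for i, pk in enumerate([5.0, 6.0, 7.0])}
        mapping = {f"pep{i}": f"prot{i}" for i in range(3)}
        res = compare_fl_vs_motifs(fl, prof, mapping)
        assert res.pcc == pytest.approx(1.0)
        assert res.delta_mean == 0.0 and res.delta_median == 0.0
        assert res.fraction_fl_stronger == 0.0  # ties are not "stronger"

    def test_five_protein_toy_matches_hand_oracle(self, profile_factory):
        # two motifs for prot0 (best 5.6), one each for prot1..prot4
        pks = [5.2, 5.6, 4.8, 6.1, 5.0, 4.6]
        prof = profile_factory(pks)
        mapping = {
            "pep0": "A", "pep1": "A", "pep2": "B",
            "pep3": "C", "pep4": "D", "pep5": "E",
        }
        fl = {
            "A": AffinityValue(6.3), "B": AffinityValue(5.5),
            "C": AffinityValue(6.0), "D": AffinityValue(5.9),
            "E": AffinityValue(4.6),
        }
        res = compare_fl_vs_motifs(fl, prof, mapping)
        best = {"A": 5.6, "B": 4.8, "C": 6.1, "D": 5.0, "E": 4.6}
        deltas = np.array([fl[p].pk - best[p] for p in sorted(best)])
        fl_arr = np.array([fl[p].pk for p in sorted(best)])
        best_arr = np.array([best[p] for p in sorted(best)])
        assert res.n == 5
        assert res.delta_mean == pytest.approx(deltas.mean())
        assert res.delta_median == pytest.approx(np.median(deltas))
        assert res.fraction_fl_stronger == pytest.approx((deltas > 0).mean())
        assert res.pcc == pytest.approx(np.corrcoef(fl_arr, best_arr)[0, 1])

    def test_all_motifs_censored_excluded_and_undefined(self, profile_factory):
        prof = profile_factory([0, 0, 0], censored=[True, True, True])
        fl = {f"prot{i}": AffinityValue(5.0) for i in range(3)}
        mapping = {f"pep{i}": f"prot{i}" for i in range(3)}
        res = compare_fl_vs_motifs(fl, prof, mapping)
        assert not res.defined
        assert res.excluded_all_censored == ["prot0", "prot1", "prot2"]


class TestSpecificityLogo:
    def test_single_binder_gets_unit_columns(self, profile_factory):
        prof = profile_factory([5.0], detection_pk=4.0)
        logo = specificity_logo(prof, {"pep0": "PAKPAR"})
        for pos, aa in enumerate("PAKPAR", start=1):
            assert logo.loc[pos, aa] == pytest.approx(1.0)

    def test_equal_margins_split_evenly(self, profile_factory):
        prof = profile_factory([5.0, 5.0], detection_pk=4.0)
        logo = specificity_logo(prof, {"pep0": "PAKPAR", "pep1": "PGKPAR"})
        assert logo.loc[2, "A"] == pytest.approx(0.5)
        assert logo.loc[2, "G"] == pytest.approx(0.5)
        assert logo.loc[1, "P"] == pytest.approx(1.0)

    def test_ten_peptide_panel_matches_weighted_counting(self, profile_factory):
        rng = np.random.default_rng(6)
        pks = rng.uniform(4.2, 6.5, 10)
        censored = [bool(c) for c in rng.random(10) < 0.3]
        prof = profile_factory(list(pks), censored=censored, detection_pk=4.0)
        cores = {
            f"pep{i}": "".join(rng.choice(list("PARKGQS"), 6)) for i in range(10)
        }
        logo = specificity_logo(prof, cores)
        # brute-force weighted counting oracle
        for pos in range(6):
            col = {}
            for i in range(10):
                if censored[i]:
                    continue
                w = max(0.0, pks[i] - 4.0)
                aa = cores[f"pep{i}"][pos]
                col[aa] = col.get(aa, 0.0) + w
            total = sum(col.values())
            for aa, w in col.items():
                assert logo.loc[pos + 1, aa] == pytest.approx(w / total)

    def test_columns_sum_to_one(self, profile_factory):
        prof = profile_factory([4.5, 5.5, 6.5], detection_pk=4.0)
        cores = {"pep0": "PAKP", "pep1": "PGRP", "pep2": "PSKP"}
        logo = specificity_logo(prof, cores)
        assert np.allclose(logo.sum(axis=1), 1.0, atol=1e-12)

    def test_margin_scaling_invariance(self, profile_factory):
        """Multiplying every affinity margin by a constant leaves the logo fixed."""
        base = [4.5, 5.0, 6.0]
        cores = {"pep0": "PAKP", "pep1": "PGRP", "pep2": "PSKP"}
        logo1 = specificity_logo(profile_factory(base, detection_pk=4.0), cores)
        scaled = [4.0 + 3.0 * (pk - 4.0) for pk in base]
        logo2 = specificity_logo(profile_factory(scaled, detection_pk=4.0), cores)
        assert np.allclose(logo1.to_numpy(), logo2.to_numpy())

    def test_no_binders_is_error(self, profile_factory):
        prof = profile_factory([0.0], censored=[True], detection_pk=4.0)
        with pytest.raises(ValueError):
            specificity_logo(prof, {"pep0": "PAKP"})


def test_plate_recovery_follows_error_propagation(bait4):
    """Recovered pK error tracks the hyperbola's noise amplification.

    At 2% per-channel fluorescence noise the corrected depletion ratio has
    ~3.5% noise; propagated through the hyperbola the pK error sd is
    sd(BI) / (ln10 * BI * (1 - BI)), small for strong binders and steeply
    growing toward the weak end. Checks the two consequences: strong binders
    (Kd <= 5 uM at 4 uM bait) recover within 0.15 pK, and the expected
    panel-wide fraction within 0.15 (~87% for Kd log-uniform on 0.5-100 uM)
    is met within sampling error.
    """
    rng = np.random.default_rng(10)
    kds = {f"m{i}": 10 ** rng.uniform(np.log10(0.5e-6), np.log10(100e-6))
           for i in range(60)}
    rds = simulate_fragment_holdup(kds, bait=bait4, cv=0.02, seed=11)
    prof = build_profile(rds, bait4, bi_threshold=0.02)
    errs, strong_errs = [], []
    for pid, kd in kds.items():
        v = prof.value_for(pid)
        if v.censored:
            continue
        err = abs(v.pk - kd_to_pk(kd))
        errs.append(err)
        if kd <= 5e-6:
            strong_errs.append(err)
    assert len(errs) >= 50
    assert np.max(strong_errs) <= 0.15
    assert np.mean([e <= 0.15 for e in errs]) >= 0.75
    assert np.median(errs) <= 0.1
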