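"""Fragmentomic holdup: peptide-panel affinity profiling.

In a fragmentomic holdup the immobilized baits are a library of short
synthetic PRM peptides and the analyte is a purified SH3 domain whose
depletion is read out by intrinsic tryptophan fluorescence of the filtrate,
with fluorescein and mCherry spiked in as internal loading standards. Each
well yields a binding intensity, converted through the hyperbola to a
site-specific affinity; the panel of affinities for one bait is its
*affinity profile*. This module also compares full-length-protein apparent
affinities with the best isolated-motif affinity and computes
affinity-weighted specificity logos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import (
    AffinityValue,
    BaitConcentration,
    BindingIntensity,
    censor_affinity,
    detection_pk,
)
from .motifs import AMINO_ACIDS

__all__ = [
    "PlateReadout",
    "AffinityProfile",
    "FlMotifComparison",
    "plate_to_bi",
    "build_profile",
    "compare_fl_vs_motifs",
    "specificity_logo",
]


@dataclass(frozen=True)
class PlateReadout:
    """Fluorescence signals for one peptide well and its control well.

    ``trp`` is the intrinsic tryptophan fluorescence of the filtrate (the
    unbound analyte); ``std1``/``std2`` are the two internal standards
    (fluorescein, mCherry) that report loading and volume differences.
    """

    peptide_id: str
    trp_sample: float
    trp_control: float
    std1_sample: float
    std1_control: float
    std2_sample: float
    std2_control: float

    def __post_init__(self) -> None:
        for name in (
            "trp_sample", "trp_control", "std1_sample",
            "std1_control", "std2_sample", "std2_control",
        ):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.peptide_id}: {name} must be positive, got {v!r}")


def plate_to_bi(readout: PlateReadout) -> BindingIntensity:
    """Loading-corrected depletion from one well pair.

    The tryptophan sample/control ratio is divided by the geometric mean of
    the two internal-standard ratios (symmetric treatment of two independent
    loading controls), then BI = 1 - corrected ratio, clamped into [0, 1).
    """
    trp_ratio = readout.trp_sample / readout.trp_control
    std_ratio = math.sqrt(
        (readout.std1_sample / readout.std1_control)
        * (readout.std2_sample / readout.std2_control)
    )
    raw = 1.0 - trp_ratio / std_ratio
    if raw >= 1.0:  # unreachable with positive signals, kept for safety
        raw = math.nextafter(1.0, 0.0)
    return BindingIntensity.from_raw(raw)


@dataclass
class AffinityProfile:
    """Ordered vector of affinities over a fixed peptide panel for one bait."""

    bait_id: str
    panel: list[str]
    values: list[AffinityValue]
    detection_pk: float
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.values):
            raise ValueError("panel and values lengths differ")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("duplicate peptide ids in panel")

    def __len__(self) -> int:
        return len(self.panel)

    def pk_array(self) -> np.ndarray:
        return np.array([v.pk for v in self.values], dtype=float)

    def censored_array(self) -> np.ndarray:
        return np.array([v.censored for v in self.values], dtype=bool)

    def value_for(self, peptide_id: str) -> AffinityValue:
        return self.values[self.panel.index(peptide_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": self.panel,
                "pk": self.pk_array(),
                "censored": self.censored_array(),
            }
        )


def build_profile(
    readouts: list[PlateReadout],
    bait: BaitConcentration,
    bi_threshold: float,
    bait_id: str = "",
    panel: list[str] | None = None,
) -> AffinityProfile:
    """Assemble a censored affinity profile from plate readouts.

    The panel order is either given explicitly (peptides without a readout
    are censored at the detection threshold and listed in ``missing``) or
    taken from the readout order. Duplicate peptide ids are an error.
    """
    by_id: dict[str, PlateReadout] = {}
    for r in readouts:
        if r.peptide_id in by_id:
            raise ValueError(f"duplicate readout for peptide {r.peptide_id!r}")
        by_id[r.peptide_id] = r
    panel = list(panel) if panel is not None else list(by_id)
    thr_pk = detection_pk(bi_threshold, bait)
    values: list[AffinityValue] = []
    missing: list[str] = []
    for pid in panel:
        r = by_id.get(pid)
        if r is None:
            missing.append(pid)
            values.append(AffinityValue(pk=thr_pk, censored=True))
            continue
        values.append(censor_affinity(plate_to_bi(r), bi_threshold, bait))
    return AffinityProfile(
        bait_id=bait_id, panel=panel, values=values,
        detection_pk=thr_pk, missing=missing,
    )


@dataclass
class FlMotifComparison:
    """Full-length vs best-isolated-motif affinity statistics."""

    pcc: float
    delta_mean: float
    delta_median: float
    fraction_fl_stronger: float
    n: int
    defined: bool
    excluded_all_censored: list[str] = field(default_factory=list)


def compare_fl_vs_motifs(
    fl: dict[str, AffinityValue],
    profile: AffinityProfile,
    mapping: dict[str, str],
) -> FlMotifComparison:
    """Compare full-length apparent affinities with best-motif affinities.

    For each protein with a full-length affinity, the strongest (max pK)
    *uncensored* motif in the profile is selected; proteins whose motifs are
    all censored are excluded and reported separately. Statistics over the
    paired proteins: Pearson correlation, mean and median of
    (pK_FL - pK_bestmotif), and the fraction with a strictly positive
    difference (ties do not count as stronger).
    """
    best: dict[str, float] = {}
    seen: dict[str, bool] = {}
    for pid, aff in zip(profile.panel, profile.values):
        prot = mapping.get(pid)
        if prot is None or prot not in fl:
            continue
        seen.setdefault(prot, False)
        if aff.censored:
            continue
        seen[prot] = True
        if prot not in best or aff.pk > best[prot]:
            best[prot] = aff.pk
    excluded = sorted(p for p, ok in seen.items() if not ok)
    proteins = sorted(best)
    if len(proteins) < 3:
        return FlMotifComparison(
            math.nan, math.nan, math.nan, math.nan, len(proteins),
            defined=False, excluded_all_censored=excluded,
        )
    fl_pk = np.array([fl[p].pk for p in proteins])
    motif_pk = np.array([best[p] for p in proteins])
    delta = fl_pk - motif_pk
    if np.std(fl_pk) == 0.0 or np.std(motif_pk) == 0.0:
        pcc = math.nan
    else:
        pcc = float(stats.pearsonr(fl_pk, motif_pk).statistic)
    return FlMotifComparison(
        pcc=pcc,
        delta_mean=float(delta.mean()),
        delta_median=float(np.median(delta)),
        fraction_fl_stronger=float((delta > 0).mean()),
        n=len(proteins),
        defined=True,
        excluded_all_censored=excluded,
    )


def specificity_logo(
    profile: AffinityProfile,
    cores: dict[str, str],
) -> pd.DataFrame:
    """Affinity-weighted specificity logo over aligned peptide cores.

    Each uncensored binder contributes weight w = max(0, pK - detection pK),
    the affinity margin above the detection limit (proportional to the
    binding free-energy difference from that limit); censored peptides
    contribute nothing. Column weights are normalized to sum to 1, giving a
    positions x amino-acids matrix (rows 1-based positions, columns the 20
    residues). All cores must share one alignment frame (equal length);
    class-specific frames should be computed in separate calls.
    """
    lengths = {len(c) for c in cores.values()}
    if len(lengths) > 1:
        raise ValueError("aligned cores must all have the same length")
    if not cores:
        raise ValueError("no cores supplied")
    L = lengths.pop()
    weights = np.zeros((L, len(AMINO_ACIDS)))
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    any_binder = False
    for pid, core in cores.items():
        aff = profile.value_for(pid)
        if aff.censored:
            continue
        w = max(0.0, aff.pk - profile.detection_pk)
        if w <= 0.0:
            continue
        any_binder = True
        for j, aa in enumerate(core):
            if aa in aa_index:
                weights[j, aa_index[aa]] += w
    if not any_binder:
        raise ValueError("no uncensored binders with positive affinity margin")
    col_sums = weights.sum(axis=1, keepdims=True)
    col_sums[col_sums == 0.0] = 1.0
    weights = weights / col_sums
    return pd.DataFrame(
        weights, index=pd.RangeIndex(1, L + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )
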