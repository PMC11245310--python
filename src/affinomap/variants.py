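"""Interactome-scale variant perturbation scoring.

Domain variants are compared to the wild-type domain by the cumulative
Euclidean distance between their affinity profiles in pK space. Because
differences in pK are proportional to binding free-energy differences, this
distance quantifies the overall rewiring of binding energies across the
panel. Censored (below-detection) entries enter at the detection-threshold
pK, so whenever a censored value is used only a *lower bound* on the
distance is obtained; dimensions censored in both profiles carry no
information and contribute zero.

Variants are classed as LOF (loss of function: nearly all wild-type-
detectable motifs lost), PAP (perturbed affinity profile: distance above the
measurement-noise floor with binding retained) or WT-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .fragmentomics import AffinityProfile

__all__ = [
    "VariantComparison",
    "euclidean_affinity_distance",
    "classify_variant",
    "wt_noise_distance",
    "LABEL_WT_LIKE",
    "LABEL_PAP",
    "LABEL_LOF",
]

LABEL_WT_LIKE = "WT-like"
LABEL_PAP = "PAP"
LABEL_LOF = "LOF"


@dataclass
class VariantComparison:
    """Distance between a variant's affinity profile and the wild type's."""

    variant_id: str
    distance: float
    is_lower_bound: bool
    n_dims: int
    n_lost: int  # WT-detectable motifs censored in the variant
    n_gained: int  # variant-detectable motifs censored in WT
    n_wt_detectable: int
    per_motif_delta: np.ndarray = field(default_factory=lambda: np.empty(0))


def euclidean_affinity_distance(
    wt: AffinityProfile, var: AffinityProfile
) -> VariantComparison:
    """Censoring-aware Euclidean distance in pK space over a shared panel.

    Censored entries are substituted by the panel detection-threshold pK
    (setting ``is_lower_bound``); dimensions censored in both profiles
    contribute zero. Panels and detection thresholds must match exactly.
    """
    if wt.panel != var.panel:
        raise ValueError("profiles are on different panels")
    if not math.isclose(wt.detection_pk, var.detection_pk, rel_tol=0, abs_tol=1e-9):
        raise ValueError("profiles have different detection thresholds")
    wt_pk, var_pk = wt.pk_array(), var.pk_array()
    wt_c, var_c = wt.censored_array(), var.censored_array()
    # substitute the threshold wherever a value is censored
    wt_eff = np.where(wt_c, wt.detection_pk, wt_pk)
    var_eff = np.where(var_c, var.detection_pk, var_pk)
    delta = wt_eff - var_eff
    both = wt_c & var_c
    delta[both] = 0.0
    used_threshold = (wt_c ^ var_c)
    return VariantComparison(
        variant_id=var.bait_id,
        distance=float(np.sqrt(np.sum(delta**2))),
        is_lower_bound=bool(used_threshold.any()),
        n_dims=len(wt),
        n_lost=int((~wt_c & var_c).sum()),
        n_gained=int((wt_c & ~var_c).sum()),
        n_wt_detectable=int((~wt_c).sum()),
        per_motif_delta=delta,
    )


def classify_variant(
    cmp: VariantComparison,
    noise_distance: float,
    lof_fraction: float = 0.9,
) -> str:
    """Label a variant WT-like, PAP or LOF.

    LOF: at least ``lof_fraction`` of the wild-type-detectable motifs are
    censored in the variant. PAP: not LOF but the profile distance exceeds
    the noise floor (e.g. from replicate WT-vs-WT distances). Otherwise
    WT-like.
    """
    if noise_distance < 0:
        raise ValueError("noise_distance must be nonnegative")
    if cmp.n_wt_detectable > 0 and cmp.n_lost / cmp.n_wt_detectable >= lof_fraction:
        return LABEL_LOF
    if cmp.distance > noise_distance:
        return LABEL_PAP
    return LABEL_WT_LIKE


def wt_noise_distance(replicates: list[AffinityProfile], factor: float = 1.5) -> float:
    """Noise floor from replicate wild-type profiles.

    Mean pairwise replicate-to-replicate distance scaled by ``factor``
    (margin against the concentration of high-dimensional noise distances).
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicate profiles")
    dists = [
        euclidean_affinity_distance(a, b).distance
        for a, b in combinations(replicates, 2)
    ]
    return factor * float(np.mean(dists))
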