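"""Seed-deterministic synthetic data with the structure every stage assumes.

These generators emulate the statistical shape of the study conditions so the
whole pipeline can be exercised without any measured data: log-normally
distributed protein abundances with abundance-dependent missingness and
injection-replicate noise; specific depletion of true binders governed by the
hyperbolic binding law at 10 uM bait; peptide-plate readouts with
internal-standard loading variation; ortholog motif decay over taxonomic
depth; and benign / PAP / LOF variant profiles. Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .affinity import AffinityValue, BaitConcentration, kd_to_bi
from .conservation import LEVELS, DEFAULT_BACKGROUND, OrthologSeq, OrthologSet
from .fragmentomics import AffinityProfile, PlateReadout
from .motifs import AMINO_ACIDS, PRMRecord, ProteinRecord, design_peptide
from .nhu import IntensityTable
from .titration import TitrationCurve, partial_activity_model

__all__ = [
    "GroundTruth",
    "DropoutModel",
    "generate_proteome",
    "simulate_nhu_ms",
    "simulate_fragment_holdup",
    "simulate_titration",
    "simulate_orthologs",
    "simulate_variant_profile",
    "make_profile_from_kds",
    "random_motif_family",
]

_AA = np.array(list(AMINO_ACIDS))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=DEFAULT_BACKGROUND))


def _random_core(rng: np.random.Generator, class_id: int) -> str:
    x = lambda: str(rng.choice(_AA, p=DEFAULT_BACKGROUND))
    rk = lambda: str(rng.choice(["R", "K"]))
    if class_id == 1:  # [RK]..P..P
        return rk() + x() + x() + "P" + x() + x() + "P"
    return "P" + x() + x() + "P" + x() + rk()  # P..P.[RK]


@dataclass
class GroundTruth:
    """Planted proteome: sequences, motifs, true Kds and abundances."""

    proteins: list[ProteinRecord]
    motifs: list[PRMRecord]
    motif_kds: dict  # peptide_id -> Kd (molar)
    protein_kds: dict  # protein_id -> Kd (molar); +inf for non-binders
    abundances: dict  # protein_id -> arbitrary units

    def binder_ids(self) -> list[str]:
        return [p for p, kd in self.protein_kds.items() if math.isfinite(kd)]


def generate_proteome(
    n_proteins: int = 200,
    length_range: tuple[int, int] = (150, 400),
    implant_rate: float = 0.1,
    seed: int = 0,
    motif_kd_range: tuple[float, float] = (0.5e-6, 300e-6),
    avidity_range: tuple[float, float] = (1.0, 10.0),
    max_motifs_per_protein: int = 3,
) -> GroundTruth:
    """Random proteome with PxxP cores implanted inside disordered stretches.

    Each protein gets a disorder mask covering roughly 40% of its length in
    1-3 contiguous stretches. With probability ``implant_rate`` a protein
    receives 1-``max_motifs_per_protein`` class 1/2 cores inside disordered
    stretches, each with a log-uniform motif Kd; the protein-level apparent
    Kd is the best motif Kd divided by an avidity factor (log-uniform,
    default 1-10x), emulating full-length proteins binding stronger than
    their isolated motifs. Proteins without implanted motifs are non-binders
    (infinite Kd). Abundances are log-normal. The default implant rate keeps
    binder prevalence low, as in a real extract, so that median
    normalization of the downstream intensity table stays well-posed.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    motifs: list[PRMRecord] = []
    motif_kds: dict = {}
    protein_kds: dict = {}
    abundances: dict = {}
    lo_kd, hi_kd = math.log10(motif_kd_range[0]), math.log10(motif_kd_range[1])
    lo_av, hi_av = math.log10(avidity_range[0]), math.log10(avidity_range[1])
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(_random_sequence(rng, length))
        # disordered stretches covering ~40% of the sequence
        mask = np.zeros(length, dtype=bool)
        n_seg = int(rng.integers(1, 4))
        seg_len = max(20, int(0.4 * length / n_seg))
        for _ in range(n_seg):
            if seg_len >= length:
                mask[:] = True
                break
            s = int(rng.integers(0, length - seg_len))
            mask[s : s + seg_len] = True

        placed: list[tuple[int, int, str]] = []  # (start0, class_id, core)
        if rng.random() < implant_rate:
            n_mot = int(rng.integers(1, max_motifs_per_protein + 1))
            dis_idx = np.flatnonzero(mask)
            for _ in range(n_mot):
                class_id = int(rng.choice([1, 2]))
                core = _random_core(rng, class_id)
                cl = len(core)
                # candidate starts where the whole core stays disordered
                cand = [
                    s for s in dis_idx
                    if s + cl <= length and mask[s : s + cl].all()
                    and all(s + cl <= ps or ps + len(pc) <= s for ps, _, pc in placed)
                ]
                if not cand:
                    continue
                s = int(rng.choice(cand))
                seq[s : s + cl] = list(core)
                placed.append((s, class_id, core))
        rec = ProteinRecord(id=pid, sequence="".join(seq), disorder=mask)
        proteins.append(rec)
        abundances[pid] = float(rng.lognormal(mean=math.log(1e6), sigma=1.5))

        best_kd = math.inf
        for s, class_id, core in placed:
            prm = PRMRecord(protein_id=pid, class_id=class_id, start=s + 1, core_seq=core)
            prm.peptide15, prm.truncated = design_peptide(rec, prm)
            kd = 10.0 ** rng.uniform(lo_kd, hi_kd)
            motif_kds[prm.peptide_id] = kd
            motifs.append(prm)
            best_kd = min(best_kd, kd)
        if placed:
            avidity = 10.0 ** rng.uniform(lo_av, hi_av)
            protein_kds[pid] = best_kd / avidity
        else:
            protein_kds[pid] = math.inf
    return GroundTruth(proteins, motifs, motif_kds, protein_kds, abundances)


@dataclass(frozen=True)
class DropoutModel:
    """Logistic missing-not-at-random model in log10 intensity.

    P(missing) = 1 / (1 + exp((log10 I - loc) / scale)): missingness
    decreases with intensity around location ``loc``.
    """

    loc_log10: float = 4.5
    scale: float = 0.3

    def p_missing(self, intensity: np.ndarray) -> np.ndarray:
        z = (np.log10(intensity) - self.loc_log10) / self.scale
        return 1.0 / (1.0 + np.exp(z))


def simulate_nhu_ms(
    truth: GroundTruth,
    bait: BaitConcentration = BaitConcentration.from_micromolar(10.0),
    n_bait: int = 3,
    n_control: int = 3,
    cv: float = 0.15,
    dropout: DropoutModel | None = DropoutModel(),
    seed: int = 0,
) -> IntensityTable:
    """Simulate a role-annotated nHU-MS intensity table (bait + control arms).

    Control intensities are abundance x log-normal injection noise; bait-arm
    intensities are additionally multiplied by (1 - BI_true) where BI_true
    follows the hyperbola at the bait concentration (1 for non-binders).
    Missingness follows the logistic dropout model in intensity.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    pids = [p.id for p in truth.proteins]
    abund = np.array([truth.abundances[p] for p in pids])
    kds = [truth.protein_kds[p] for p in pids]
    bi_true = np.array(
        [kd_to_bi(k, bait) if math.isfinite(k) else 0.0 for k in kds]
    )
    cols, roles, reps = [], [], []
    data = {}
    for arm, n, factor in (("bait", n_bait, 1.0 - bi_true), ("control", n_control, 1.0)):
        for r in range(n):
            col = f"{arm}_{r + 1}"
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(pids))
            vals = abund * factor * noise
            if dropout is not None:
                missing = rng.random(len(pids)) < dropout.p_missing(vals)
                vals = np.where(missing, np.nan, vals)
            data[col] = vals
            cols.append(col)
            roles.append(arm)
            reps.append(r + 1)
    values = pd.DataFrame(data, index=pd.Index(pids, name="protein_id"))
    samples = pd.DataFrame({"sample_id": cols, "role": roles, "replicate": reps})
    return IntensityTable(values, samples)


def simulate_fragment_holdup(
    motif_kds: dict,
    bait: BaitConcentration = BaitConcentration.from_micromolar(4.0),
    cv: float = 0.02,
    loading_sd: float = 0.05,
    seed: int = 0,
) -> list[PlateReadout]:
    """Simulate peptide-plate readouts from true motif Kds.

    Each sample well has a log-normal loading factor (volume/pipetting) that
    multiplies all of its channels — tryptophan and both internal standards —
    so the internal-standard correction of ``plate_to_bi`` can remove it; on
    top of that every channel has independent fluorescence noise of the
    given CV. A non-binding peptide is encoded by an infinite Kd.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    load_sigma = math.sqrt(math.log(1.0 + loading_sd**2))
    trp0, f0, m0 = 1000.0, 500.0, 300.0  # arbitrary fluorescence bases
    out = []
    for pid, kd in motif_kds.items():
        bi = kd_to_bi(kd, bait) if math.isfinite(kd) else 0.0
        load = rng.lognormal(mean=-0.5 * load_sigma**2, sigma=load_sigma)
        noise = lambda: rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        out.append(
            PlateReadout(
                peptide_id=pid,
                trp_sample=trp0 * (1.0 - bi) * load * noise(),
                trp_control=trp0 * noise(),
                std1_sample=f0 * load * noise(),
                std1_control=f0 * noise(),
                std2_sample=m0 * load * noise(),
                std2_control=m0 * noise(),
            )
        )
    return out


def simulate_titration(
    kd: float,
    active_fraction: float,
    concentrations,
    sd: float = 0.03,
    seed: int = 0,
    label: str = "",
) -> TitrationCurve:
    """Titration curve from the partial-activity model plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    fb = partial_activity_model(conc, kd, active_fraction)
    fb = fb + rng.normal(0.0, sd, size=conc.shape)
    fb = np.clip(fb, -0.2, 1.2)
    return TitrationCurve(conc, fb, label=label)


def simulate_orthologs(
    reference_window: str,
    planted_depth: str,
    n_per_level: int = 5,
    sub_rate_conserved: float = 0.08,
    flank: int = 10,
    seed: int = 0,
    core_positions: tuple[int, ...] = (7, 10),
) -> OrthologSet:
    """Ortholog set in which the motif decays beyond a planted level.

    Levels up to and including ``planted_depth`` carry the reference motif
    with light substitution noise outside the fixed core positions; more
    distal levels carry a fully randomized window (the motif is destroyed).
    Flanking columns mutate freely at all levels. ``planted_depth`` may also
    be ``"human-only"`` to destroy the motif at every level.
    """
    if planted_depth != "human-only" and planted_depth not in LEVELS:
        raise ValueError(f"unknown level {planted_depth!r}")
    rng = np.random.default_rng(seed)
    ref_flank_l = _random_sequence(rng, flank)
    ref_flank_r = _random_sequence(rng, flank)
    ref_seq = ref_flank_l + reference_window + ref_flank_r
    depth_idx = -1 if planted_depth == "human-only" else LEVELS.index(planted_depth)
    core0 = {p - 1 for p in core_positions}
    orthologs: list[OrthologSeq] = []
    for li, level in enumerate(LEVELS):
        for k in range(n_per_level):
            if li <= depth_idx:
                win = list(reference_window)
                for j in range(len(win)):
                    if j not in core0 and rng.random() < sub_rate_conserved:
                        win[j] = str(rng.choice(_AA, p=DEFAULT_BACKGROUND))
                window = "".join(win)
            else:
                window = _random_sequence(rng, len(reference_window))
            seq = (
                _random_sequence(rng, flank) + window + _random_sequence(rng, flank)
            )
            orthologs.append(OrthologSeq(seq=seq, level=level, id=f"{level}_{k}"))
    return OrthologSet(
        reference_id="REF",
        reference_seq=ref_seq,
        motif_start=flank + 1,
        motif_end=flank + len(reference_window),
        orthologs=orthologs,
    )


def random_motif_family(
    n: int = 30,
    length: int = 15,
    seed: int = 0,
    class_id: int = 2,
) -> list[str]:
    """A family of 15-mer motif frames with the PxxP consensus at positions 7-10.

    Class 2 frames additionally carry the basic residue at position 12
    (PxxPx[RK] core starting at position 7); class 1 frames carry the basic
    residue at position 4 ([RK]xxPxxP core ending at position 10). Non-fixed
    positions are drawn from a biased residue pool so the family has
    learnable positional preferences.
    """
    rng = np.random.default_rng(seed)
    # biased pool: proline-rich context typical of PRM flanks
    pool = np.array(list("PASTRGKQL"))
    fam = []
    for _ in range(n):
        seq = [str(a) for a in rng.choice(pool, size=length)]
        seq[6] = "P"
        seq[9] = "P"
        if class_id == 2:
            seq[11] = str(rng.choice(["R", "K"]))
        else:
            seq[3] = str(rng.choice(["R", "K"]))
        fam.append("".join(seq))
    return fam


def make_profile_from_kds(
    motif_kds: dict,
    bait: BaitConcentration,
    bi_threshold: float,
    bait_id: str = "WT",
) -> AffinityProfile:
    """Noise-free affinity profile implied by true Kds (censored at threshold)."""
    from .affinity import censor_affinity, detection_pk, kd_to_bi as _fwd

    panel = list(motif_kds)
    values = []
    for pid in panel:
        kd = motif_kds[pid]
        bi = _fwd(kd, bait) if math.isfinite(kd) else 0.0
        values.append(censor_affinity(bi, bi_threshold, bait))
    return AffinityProfile(
        bait_id=bait_id,
        panel=panel,
        values=values,
        detection_pk=detection_pk(bi_threshold, bait),
    )


def simulate_variant_profile(
    wt: AffinityProfile,
    mode: str,
    seed: int = 0,
    benign_sd: float = 0.05,
    pap_shift: float = -0.8,
    pap_fraction: float = 0.6,
    variant_id: str | None = None,
) -> AffinityProfile:
    """Variant affinity profile of one of three classes.

    ``benign``: WT plus N(0, ``benign_sd``) pk noise on detectable motifs.
    ``PAP``: the benign noise plus a ``pap_shift`` pk shift on a random
    ``pap_fraction`` of the detectable motifs (interactome reshuffling with
    binding retained). ``LOF``: every motif censored. Values falling below
    the detection threshold are re-censored.
    """
    rng = np.random.default_rng(seed)
    vid = variant_id or f"{mode}_variant"
    thr = wt.detection_pk
    values: list[AffinityValue] = []
    if mode == "LOF":
        values = [AffinityValue(pk=thr, censored=True) for _ in wt.values]
        return AffinityProfile(vid, list(wt.panel), values, thr)
    if mode not in ("benign", "PAP"):
        raise ValueError(f"unknown variant mode {mode!r}")
    detectable = [i for i, v in enumerate(wt.values) if not v.censored]
    shifted: set[int] = set()
    if mode == "PAP":
        k = int(round(pap_fraction * len(detectable)))
        shifted = set(rng.choice(detectable, size=k, replace=False)) if k else set()
    for i, v in enumerate(wt.values):
        if v.censored:
            values.append(AffinityValue(pk=thr, censored=True))
            continue
        pk = v.pk + rng.normal(0.0, benign_sd)
        if i in shifted:
            pk += pap_shift
        if pk <= thr:
            values.append(AffinityValue(pk=thr, censored=True))
        else:
            values.append(AffinityValue(pk=pk, censored=False))
    return AffinityProfile(vid, list(wt.panel), values, thr)
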