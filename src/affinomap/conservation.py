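"""PSSM-based motif conservation scoring across taxonomic levels.

A position-specific scoring matrix is built from the set of experimentally
verified binding motifs (15-mer frames with the PxxP consensus at positions
7-10 for this panel) as pseudocount-smoothed log-odds against background
amino-acid frequencies:

    P[j, i] = ln( ((c_ij + B/20) / (m + B)) / D_i )

with c_ij the count of amino acid i at position j among the m motifs, B the
pseudocount (default 5) and D_i the background frequency of amino acid i.

Ortholog motif instances (from a multiple sequence alignment sharing the
human reference's frame) are scored with the PSSM and normalized by the
human motif's score. For each taxonomic level — Mammalia, Vertebrata,
Eumetazoa, Unicellular (eukaryotes only), in order of increasing distance
from human — the mean normalized score is computed from at least
``min_orthologs`` instances; a motif is conserved at a level if that score
exceeds the threshold (default 0.5), and its *conservation depth* is the
most distal conserved level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .motifs import AMINO_ACIDS

__all__ = [
    "LEVELS",
    "DEFAULT_BACKGROUND",
    "uniform_background",
    "PSSM",
    "OrthologSeq",
    "OrthologSet",
    "ConservationResult",
    "build_pssm",
    "score_window",
    "normalized_score",
    "conservation_depth",
]

#: Taxonomic levels in order of increasing evolutionary distance from human.
LEVELS = ("Mammalia", "Vertebrata", "Eumetazoa", "Unicellular")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Swiss-Prot-style eukaryotic amino-acid frequencies (fractions, renormalized).
_BG = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_bg_arr = np.array([_BG[aa] for aa in AMINO_ACIDS])
DEFAULT_BACKGROUND: np.ndarray = _bg_arr / _bg_arr.sum()


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


@dataclass
class PSSM:
    """Pseudocount-smoothed log-odds matrix over 20 amino acids."""

    scores: np.ndarray  # shape (length, 20), natural-log odds
    background: np.ndarray
    pseudocount_B: float
    n_motifs: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be a positions x 20 matrix")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def column_min(self) -> np.ndarray:
        return self.scores.min(axis=1)


def _coerce_background(background) -> np.ndarray:
    if background is None:
        return DEFAULT_BACKGROUND.copy()
    if isinstance(background, dict):
        return np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    return np.asarray(background, dtype=float)


def build_pssm(motifs: list[str], background=None, B: float = 5.0) -> PSSM:
    """Log-odds PSSM with pseudocount smoothing from equal-length motifs."""
    if len(motifs) < 2:
        raise ValueError("need at least two motifs")
    lengths = {len(m) for m in motifs}
    if len(lengths) != 1:
        raise ValueError("motifs must all have the same length")
    L = lengths.pop()
    bg = _coerce_background(background)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be strictly positive")
    m = len(motifs)
    counts = np.zeros((L, 20))
    for seq in motifs:
        seq = seq.upper()
        for j, aa in enumerate(seq):
            if aa not in _AA_INDEX:
                raise ValueError(f"invalid residue {aa!r} in motif {seq!r}")
            counts[j, _AA_INDEX[aa]] += 1
    smoothed = (counts + B / 20.0) / (m + B)
    scores = np.log(smoothed / bg[None, :])
    return PSSM(scores=scores, background=bg, pseudocount_B=B, n_motifs=m)


def score_window(pssm: PSSM, window: str) -> float:
    """Sum of per-position PSSM scores for one sequence window.

    Alignment gaps (``-``) and unknown residues (``X``) score the column
    minimum: they cannot support the motif.
    """
    window = window.upper()
    if len(window) != pssm.length:
        raise ValueError(
            f"window length {len(window)} != PSSM length {pssm.length}"
        )
    col_min = pssm.column_min()
    total = 0.0
    for j, aa in enumerate(window):
        idx = _AA_INDEX.get(aa)
        total += pssm.scores[j, idx] if idx is not None else col_min[j]
    return total


def normalized_score(pssm: PSSM, ortholog_window: str, human_window: str) -> float:
    """Ortholog PSSM score relative to the human reference motif's score.

    A nonpositive human score leaves the ratio undefined (NaN): the human
    motif then scores no better than background and cannot serve as a
    normalizer.
    """
    human = score_window(pssm, human_window)
    if human <= 0.0:
        return math.nan
    return score_window(pssm, ortholog_window) / human


@dataclass
class OrthologSeq:
    """One aligned ortholog sequence with its taxonomic level label."""

    seq: str
    level: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown taxonomic level {self.level!r}")


@dataclass
class OrthologSet:
    """Aligned orthologs of one reference protein plus motif coordinates.

    All sequences (reference included) share the alignment frame; the motif
    occupies alignment columns ``motif_start``..``motif_end`` (1-based,
    inclusive).
    """

    reference_id: str
    reference_seq: str
    motif_start: int
    motif_end: int
    orthologs: list[OrthologSeq] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.motif_start <= self.motif_end <= len(self.reference_seq)):
            raise ValueError("motif coordinates outside the alignment")
        for o in self.orthologs:
            if len(o.seq) != len(self.reference_seq):
                raise ValueError(
                    f"ortholog {o.id!r} is not in the reference alignment frame"
                )

    def window(self, seq: str) -> str:
        return seq[self.motif_start - 1 : self.motif_end]


@dataclass
class ConservationResult:
    """Per-level conservation scores and the resulting depth call."""

    level_scores: dict  # level -> mean normalized score (NaN if insufficient)
    level_n: dict  # level -> number of ortholog instances
    level_status: dict  # level -> "conserved" | "not-conserved" | "insufficient"
    depth: str  # most distal conserved level, or "human-only"
    human_score: float


def conservation_depth(
    oset: OrthologSet,
    pssm: PSSM,
    min_orthologs: int = 3,
    threshold: float = 0.5,
) -> ConservationResult:
    """Per-level conservation scores and depth for one reference motif.

    A level needs at least ``min_orthologs`` instances to be scored
    (otherwise flagged insufficient); it is conserved when its mean
    normalized score exceeds ``threshold``. Depth is the most distal
    conserved level in the fixed order; ``"human-only"`` when no level is
    conserved or scorable. A nonpositive human reference score leaves all
    levels undefined and the depth ``"undefined"``.
    """
    human_window = oset.window(oset.reference_seq)
    human_raw = score_window(pssm, human_window)
    scores: dict = {}
    ns: dict = {}
    status: dict = {}
    if human_raw <= 0.0:
        for level in LEVELS:
            scores[level] = math.nan
            ns[level] = sum(o.level == level for o in oset.orthologs)
            status[level] = "undefined"
        return ConservationResult(scores, ns, status, "undefined", human_raw)
    depth = "human-only"
    for level in LEVELS:
        inst = [o for o in oset.orthologs if o.level == level]
        ns[level] = len(inst)
        if len(inst) < min_orthologs:
            scores[level] = math.nan
            status[level] = "insufficient"
            continue
        vals = [normalized_score(pssm, oset.window(o.seq), human_window) for o in inst]
        s = float(np.mean(vals))
        scores[level] = s
        if s > threshold:
            status[level] = "conserved"
            depth = level  # levels iterate toward increasing distance
        else:
            status[level] = "not-conserved"
    return ConservationResult(scores, ns, status, depth, human_raw)
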