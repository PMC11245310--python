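"""Proline-rich motif (PRM) discovery and peptide design.

SH3 domains recognize PxxP motifs in two pseudo-symmetric orientations:
class 1, consensus ``[RK]xxPxxP`` (7 residues), and class 2, consensus
``PxxPx[RK]`` (6 residues) — the ELM LIG_SH3_1 / LIG_SH3_2 definitions. ``x``
means any residue, including P, R or K. Scanning is restricted (by default)
to disordered regions, where such short linear motifs are functional, and
every match is reported even when matches overlap: tandem PRMs are distinct
binding sites. Matched cores are expanded to 15-mer peptides for synthesis.

Coordinates are 1-based inclusive throughout, following biological
convention.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "PRMRecord",
    "EnrichmentResult",
    "CLASS_PATTERNS",
    "CORE_LENGTHS",
    "scan_prms",
    "design_peptide",
    "random_prm_expectation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = set(AMINO_ACIDS) | {"X"}

#: Overlap-tolerant consensus patterns (lookahead capture reports every window).
CLASS_PATTERNS = {
    1: re.compile(r"(?=([RK]..P..P))"),
    2: re.compile(r"(?=(P..P.[RK]))"),
}
CORE_LENGTHS = {1: 7, 2: 6}
#: 1-based offsets of the fixed consensus positions within each core.
CONSENSUS_POSITIONS = {1: (1, 4, 7), 2: (1, 4, 6)}


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue disorder annotation."""

    id: str
    sequence: str
    disorder: np.ndarray | None = None  # boolean, True = disordered
    lineage: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        if self.disorder is not None:
            self.disorder = np.asarray(self.disorder, dtype=bool)
            if self.disorder.size != len(self.sequence):
                raise ValueError(f"{self.id}: disorder mask length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PRMRecord:
    """One PxxP motif occurrence and its designed 15-mer peptide."""

    protein_id: str
    class_id: int
    start: int  # 1-based inclusive position of the core match
    core_seq: str
    peptide15: str = ""
    truncated: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.core_seq) - 1

    @property
    def peptide_id(self) -> str:
        return f"{self.protein_id}_{self.start}_c{self.class_id}"


def _core_in_disorder(
    protein: ProteinRecord, start0: int, class_id: int, scope: str
) -> bool:
    if protein.disorder is None:
        raise ValueError(f"{protein.id}: disorder restriction requested but no mask set")
    length = CORE_LENGTHS[class_id]
    if scope == "core":
        return bool(protein.disorder[start0 : start0 + length].all())
    if scope == "consensus":
        idx = [start0 + off - 1 for off in CONSENSUS_POSITIONS[class_id]]
        return bool(protein.disorder[idx].all())
    raise ValueError(f"unknown disorder scope {scope!r}")


def scan_prms(
    protein: ProteinRecord,
    require_disorder: bool = True,
    disorder_scope: str = "core",
    peptide_length: int = 15,
) -> list[PRMRecord]:
    """All class 1 and class 2 PxxP matches in a protein, with peptides.

    Overlapping matches are all reported, and a window matching both classes
    yields two records. With ``require_disorder`` the whole core (scope
    ``"core"``, default) or only the fixed consensus positions (scope
    ``"consensus"``) must fall in the disorder mask. Records are sorted by
    (start, class_id).
    """
    records: list[PRMRecord] = []
    for class_id, pattern in CLASS_PATTERNS.items():
        for m in pattern.finditer(protein.sequence):
            start0 = m.start()
            if require_disorder and not _core_in_disorder(
                protein, start0, class_id, disorder_scope
            ):
                continue
            rec = PRMRecord(
                protein_id=protein.id,
                class_id=class_id,
                start=start0 + 1,
                core_seq=m.group(1),
            )
            rec.peptide15, rec.truncated = design_peptide(protein, rec, peptide_length)
            records.append(rec)
    records.sort(key=lambda r: (r.start, r.class_id))
    return records


def design_peptide(
    protein: ProteinRecord, motif: PRMRecord, length: int = 15
) -> tuple[str, bool]:
    """Design the synthesis window for a motif: ``length``-mer centered on the core.

    The window is centered on the core midpoint (ties broken toward the
    N-terminus) and truncated — not shifted — at protein termini, so peptides
    near a terminus may be shorter (flagged). Returns ``(peptide, truncated)``.
    """
    core_len = len(motif.core_seq)
    if core_len > length:
        raise ValueError(f"core ({core_len}) longer than peptide length {length}")
    if motif.protein_id != protein.id:
        raise ValueError("motif does not belong to this protein")
    s0 = motif.start - 1
    if protein.sequence[s0 : s0 + core_len] != motif.core_seq:
        raise ValueError("motif coordinates do not match the protein sequence")
    mid = s0 + (core_len - 1) // 2  # tie toward N-terminus for even cores
    win_start = mid - (length - 1) // 2
    win_end = win_start + length  # exclusive
    lo = max(0, win_start)
    hi = min(len(protein.sequence), win_end)
    peptide = protein.sequence[lo:hi]
    return peptide, len(peptide) < length


@dataclass
class EnrichmentResult:
    """Observed-vs-chance PRM occurrence among interaction partners."""

    expected_count: float
    observed_count: int
    observed_fraction: float
    fold_enrichment: float
    infinite: bool = False


def random_prm_expectation(
    n_partners: int,
    proteome_prm_fraction: float,
    observed_count: int,
) -> EnrichmentResult:
    """Chance expectation and fold-enrichment of PRM-containing partners.

    With a fraction f of all proteome proteins containing a PRM, a random
    set of n partners is expected to contain n*f of them; fold enrichment is
    the observed fraction over f.
    """
    if not (0.0 <= proteome_prm_fraction <= 1.0):
        raise ValueError("proteome fraction must lie in [0, 1]")
    if n_partners <= 0:
        raise ValueError("need a positive number of partners")
    expected = n_partners * proteome_prm_fraction
    obs_frac = observed_count / n_partners
    if proteome_prm_fraction == 0.0:
        if observed_count > 0:
            return EnrichmentResult(expected, observed_count, obs_frac, math.inf, True)
        return EnrichmentResult(expected, observed_count, obs_frac, math.nan, True)
    return EnrichmentResult(
        expected, observed_count, obs_frac, obs_frac / proteome_prm_fraction
    )
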