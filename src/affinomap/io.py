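"""File formats and run configuration.

Everything on disk is plain text: FASTA for sequences (via Biopython),
tab-separated tables with a header row for all quantitative data (empty cell
= missing; ``.`` is *not* accepted as missing), YAML for configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .affinity import AffinityValue, BaitConcentration
from .fragmentomics import AffinityProfile, PlateReadout
from .motifs import PRMRecord, ProteinRecord
from .nhu import IntensityTable
from .titration import TitrationCurve

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_disorder_masks",
    "read_disorder_intervals",
    "read_intensity_table",
    "write_intensity_table",
    "read_plate_readouts",
    "read_titration",
    "read_profile",
    "write_profile",
    "write_prm_records",
]


@dataclass
class PipelineConfig:
    """Fixed constants of the end-to-end analysis, all config-exposed."""

    nhu_bait_uM: float = 10.0
    fragment_bait_uM: float = 4.0
    p_cap: float = 0.05
    bi_threshold: float = 0.128
    pseudocount_B: float = 5.0
    conservation_threshold: float = 0.5
    min_orthologs: int = 3
    lof_fraction: float = 0.9
    impute_low_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bi_threshold < 1):
            raise ValueError("bi_threshold must lie in (0, 1)")
        if not (0 < self.p_cap <= 1):
            raise ValueError("p_cap must lie in (0, 1]")
        if self.pseudocount_B < 0 or self.min_orthologs < 1:
            raise ValueError("invalid config value")

    @property
    def nhu_bait(self) -> BaitConcentration:
        return BaitConcentration.from_micromolar(self.nhu_bait_uM)

    @property
    def fragment_bait(self) -> BaitConcentration:
        return BaitConcentration.from_micromolar(self.fragment_bait_uM)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from FASTA (wrapped or unwrapped)."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, proteins: list[ProteinRecord]) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """TSV with a header row; empty cells are missing values."""
    df = pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=False)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_disorder_masks(path, proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach per-residue disorder masks (protein_id, position, disordered)."""
    df = read_table(path, required=["protein_id", "position", "disordered"])
    by_id = {p.id: p for p in proteins}
    for pid, grp in df.groupby("protein_id"):
        prot = by_id.get(pid)
        if prot is None:
            continue
        mask = np.zeros(len(prot), dtype=bool)
        pos = grp["position"].to_numpy(dtype=int)
        if pos.min() < 1 or pos.max() > len(prot):
            raise ValueError(f"{pid}: disorder position outside the sequence")
        mask[pos - 1] = grp["disordered"].to_numpy(dtype=int).astype(bool)
        prot.disorder = mask
    return proteins


def read_disorder_intervals(path, proteins: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach disorder masks from intervals (protein_id, start_1based, end_inclusive)."""
    df = read_table(path, required=["protein_id", "start_1based", "end_inclusive"])
    by_id = {p.id: p for p in proteins}
    for p in proteins:
        if p.disorder is None:
            p.disorder = np.zeros(len(p), dtype=bool)
    for _, row in df.iterrows():
        prot = by_id.get(row["protein_id"])
        if prot is None:
            continue
        s, e = int(row["start_1based"]), int(row["end_inclusive"])
        if not (1 <= s <= e <= len(prot)):
            raise ValueError(f"{row['protein_id']}: interval [{s}, {e}] out of range")
        prot.disorder[s - 1 : e] = True
    return proteins


def read_intensity_table(values_path, samples_path) -> IntensityTable:
    """Intensity TSV (first column protein id) plus sample sheet TSV."""
    values = read_table(values_path)
    values = values.set_index(values.columns[0])
    samples = read_table(samples_path, required=["sample_id", "role", "replicate"])
    return IntensityTable(values, samples)


def write_intensity_table(values_path, samples_path, table: IntensityTable) -> None:
    write_table(values_path, table.values.reset_index())
    write_table(samples_path, table.samples)


def read_plate_readouts(path) -> list[PlateReadout]:
    cols = [
        "peptide_id", "trp_sample", "trp_control",
        "std1_sample", "std1_control", "std2_sample", "std2_control",
    ]
    df = read_table(path, required=cols)
    return [PlateReadout(**{c: row[c] for c in cols}) for _, row in df.iterrows()]


def read_titration(path, label: str = "", conc_unit: str = "molar") -> TitrationCurve:
    """Titration TSV with conc_molar (or conc_uM with unit flag) and fraction_bound."""
    conc_col = {"molar": "conc_molar", "uM": "conc_uM"}.get(conc_unit)
    if conc_col is None:
        raise ValueError(f"unknown concentration unit {conc_unit!r}")
    df = read_table(path, required=[conc_col, "fraction_bound"])
    conc = df[conc_col].to_numpy(dtype=float)
    if conc_unit == "uM":
        conc = conc * 1e-6
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    return TitrationCurve(conc, df["fraction_bound"].to_numpy(dtype=float), label, sd)


def write_profile(path, profile: AffinityProfile) -> None:
    df = profile.to_frame()
    df.insert(0, "bait_id", profile.bait_id)
    df["detection_pk"] = profile.detection_pk
    write_table(path, df)


def read_profile(path) -> AffinityProfile:
    df = read_table(
        path, required=["bait_id", "peptide_id", "pk", "censored", "detection_pk"]
    )
    if df.empty:
        raise ValueError(f"{path}: empty profile")
    values = [
        AffinityValue(pk=float(r.pk), censored=bool(r.censored))
        for r in df.itertuples()
    ]
    return AffinityProfile(
        bait_id=str(df["bait_id"].iloc[0]),
        panel=[str(p) for p in df["peptide_id"]],
        values=values,
        detection_pk=float(df["detection_pk"].iloc[0]),
    )


def write_prm_records(path, records: list[PRMRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "class_id": r.class_id,
                "start": r.start,
                "end": r.end,
                "core_seq": r.core_seq,
                "peptide15": r.peptide15,
                "truncated": r.truncated,
            }
            for r in records
        ]
    )
    write_table(path, df)
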