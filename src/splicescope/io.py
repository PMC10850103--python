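"""File-format adapters: FASTA substrates, MGF spectra, TSV tables.

TSV (tab-separated, header row, UTF-8, '.' decimal) is the canonical
tabular dialect; writers produce canonical forms that round-trip through
the readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .quantification import KINETICS_COLUMNS, validate_kinetics
from .spectra import Spectrum
from .splice_space import ProductLocation, Substrate

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_psm_tsv",
    "write_psm_tsv",
    "write_products_tsv",
    "read_kinetics_tsv",
]

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "spectrum_id", "peptide", "is_decoy", "origin_flag", "base_score",
    "charge", "precursor_mz", "retention_time", "modifications",
]


@dataclass
class PipelineConfig:
    """Pipeline-wide settings with the defaults used throughout."""

    fdr_cutoff: float = 0.01
    fdr_level: str = "peptide"
    ident_length_window: tuple[int, int] = (7, 30)
    quant_length_window: tuple[int, int] = (5, 40)
    fragment_tolerance: float = 0.02
    fragment_tolerance_unit: str = "Th"
    precursor_tolerance_ppm: float = 6.0
    reference_time: float = 4.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for window in (self.ident_length_window, self.quant_length_window):
            if window[0] > window[1]:
                raise ValueError(f"invalid length window {window}")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")


def read_fasta(path: str | Path) -> list[Substrate]:
    substrates = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        substrates.append(
            Substrate(rec.id, str(rec.seq).upper(), rec.description)
        )
    if not substrates:
        raise ValueError(f"no FASTA records in {path}")
    return substrates


def write_fasta(substrates: list[Substrate], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=s.description)
        for s in substrates
    ]
    SeqIO.write(records, str(path), "fasta")


def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF peak file; unsorted peak lists are sorted with a
    warning, negative intensities are an error."""
    spectra: dict[str, Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            sid = str(params.get("title"))
            mz = np.asarray(entry["m/z array"], dtype=float)
            intensity = np.asarray(entry["intensity array"], dtype=float)
            if np.any(intensity < 0):
                raise ValueError(f"negative intensity in spectrum {sid}")
            if np.any(np.diff(mz) <= 0):
                logger.warning("peaks of %s not sorted; sorting", sid)
                order = np.argsort(mz)
                mz, intensity = mz[order], intensity[order]
            charge = int(params.get("charge", [2])[0])
            spectra[sid] = Spectrum(
                spectrum_id=sid,
                precursor_mz=float(params.get("pepmass", (0.0,))[0]),
                charge=charge,
                retention_time=float(params.get("rtinseconds", 0.0)) / 60.0,
                mz=mz,
                intensity=intensity,
            )
    return spectra


def write_mgf(spectra: dict[str, Spectrum], path: str | Path) -> None:
    entries = []
    for spec in spectra.values():
        entries.append(
            {
                "m/z array": spec.mz,
                "intensity array": spec.intensity,
                "params": {
                    "title": spec.spectrum_id,
                    "pepmass": spec.precursor_mz,
                    "charge": f"{spec.charge}+",
                    "rtinseconds": spec.retention_time * 60.0,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_psm_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks columns {missing}")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    if "modifications" in df.columns:
        df["modifications"] = df["modifications"].fillna("")
    return df


def write_psm_tsv(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def write_products_tsv(
    products: list[tuple[ProductLocation, str]], path: str | Path
) -> None:
    rows = [
        {
            "sequence": seq,
            "type": loc.product_type.value,
            "i": loc.sr1_start,
            "j": loc.sr1_end,
            "k": loc.sr2_start if loc.sr2_start is not None else "",
            "n": loc.sr2_end if loc.sr2_end is not None else "",
        }
        for loc, seq in products
    ]
    pd.DataFrame(rows, columns=["sequence", "type", "i", "j", "k", "n"]).to_csv(
        path, sep="\t", index=False
    )


def read_kinetics_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetics table {path} lacks columns {missing}")
    return validate_kinetics(df[KINETICS_COLUMNS].copy())
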