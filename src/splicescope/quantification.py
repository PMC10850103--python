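"""Label-free kinetic quantification of peptide products.

Per-peptide MS1 intensities measured over a digestion time course
(time points x biological x technical replicates) are cleaned in four
stages: substrate-contaminant removal, background-noise filtering anchored
on the 0 h time point, averaging of technical replicates, and a final
missing-value rule at a reference digestion time (default 4 h).
Multi-mapper peptides have their intensity split equally across substrate
origins before positional analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splice_space import PeptideProduct, Substrate, canonical_sequence, map_peptide

__all__ = [
    "KINETICS_COLUMNS",
    "validate_kinetics",
    "remove_substrate_contaminants",
    "background_noise_filter",
    "collapse_replicates",
    "finalize_quant",
    "multi_mapper_adjust",
    "BackgroundFilterResult",
    "QUANT_LENGTH_WINDOW",
]

logger = logging.getLogger(__name__)

KINETICS_COLUMNS = ["peptide", "time_h", "bio_rep", "tech_rep", "intensity"]

#: peptide lengths eligible for quantification (wider than the 7-30
#: identification window)
QUANT_LENGTH_WINDOW = (5, 40)


def validate_kinetics(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw kinetics table: required columns, non-negative
    intensities, unique (peptide, time, bio, tech) keys."""
    missing = [c for c in KINETICS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"kinetics table lacks columns {missing}")
    if (table["intensity"] < 0).any():
        raise ValueError("kinetics table contains negative intensities")
    if table.duplicated(["peptide", "time_h", "bio_rep", "tech_rep"]).any():
        raise ValueError("duplicate (peptide, time, bio, tech) measurements")
    return table


def remove_substrate_contaminants(
    products: dict[str, PeptideProduct],
    kinetics: pd.DataFrame,
    control_peptides: list[str],
    substrate: Substrate,
) -> tuple[dict[str, PeptideProduct], pd.DataFrame]:
    """Remove substrate-solution contaminants observed in control samples.

    Spliced products are removed when any of their splice-sites — the
    (j, k) junction coordinate pair — also occurs among control-detected
    peptides (which may be longer precursors of the identified product).
    Non-spliced products seen in controls are removed only when their
    maximal 0 h intensity exceeds every later time point.
    """
    control_sites: set[tuple[int, int]] = set()
    control_canon: set[str] = set()
    for pep in control_peptides:
        control_canon.add(canonical_sequence(pep))
        mapped = map_peptide(pep, substrate)
        if mapped is not None and mapped.is_spliced:
            for loc in mapped.locations:
                site = loc.splice_site
                if site is not None:
                    control_sites.add(site)

    zero = kinetics[kinetics["time_h"] == 0].groupby("peptide")["intensity"].max()
    later = kinetics[kinetics["time_h"] > 0].groupby("peptide")["intensity"].max()

    retained: dict[str, PeptideProduct] = {}
    removed = []
    for seq, product in products.items():
        if product.is_spliced:
            sites = {
                loc.splice_site
                for loc in product.locations
                if loc.splice_site is not None
            }
            if sites & control_sites:
                removed.append({"peptide": seq, "reason": "control_splice_site"})
                continue
        else:
            if canonical_sequence(seq) in control_canon:
                z = float(zero.get(seq, 0.0))
                l = float(later.get(seq, 0.0))
                if z > l:
                    removed.append({"peptide": seq, "reason": "control_kinetics"})
                    continue
        retained[seq] = product
    return retained, pd.DataFrame(removed, columns=["peptide", "reason"])


@dataclass
class BackgroundFilterResult:
    """Background-filtered kinetics plus the noise model that produced it."""

    table: pd.DataFrame
    peptide_background: pd.Series
    global_cutoff: float


def background_noise_filter(table: pd.DataFrame) -> BackgroundFilterResult:
    """Subtract per-peptide background noise anchored at 0 h.

    The background value of a peptide is its maximal 0 h intensity across
    all replicates; the median of these values over all peptides with a
    0 h measurement is a global cut-off.  Each measurement below
    ``max(peptide background, global cut-off)`` is removed; all others
    have that threshold subtracted.  Operates on raw tables only — the
    output is tagged and a second application refuses.
    """
    if table.attrs.get("background_filtered"):
        raise ValueError("table has already been background-filtered")
    validate_kinetics(table)
    zero = table[table["time_h"] == 0]
    background = zero.groupby("peptide")["intensity"].max()
    if background.empty:
        logger.warning("no 0 h measurements; background values default to 0")
        global_cutoff = 0.0
    else:
        global_cutoff = float(background.median())
    per_pep = table["peptide"].map(background).fillna(0.0)
    threshold = np.maximum(per_pep.to_numpy(), global_cutoff)
    intens = table["intensity"].to_numpy(dtype=float)
    keep = intens >= threshold
    out = table.loc[keep].copy()
    out["intensity"] = intens[keep] - threshold[keep]
    out = out.reset_index(drop=True)
    out.attrs["background_filtered"] = True
    full_bg = pd.Series(0.0, index=pd.Index(table["peptide"].unique(), name="peptide"))
    full_bg.update(background)
    return BackgroundFilterResult(out, full_bg, global_cutoff)


def collapse_replicates(filtered: pd.DataFrame) -> pd.DataFrame:
    """Mean intensity per (peptide, time, biological replicate) across the
    surviving technical replicates; cells with no surviving technical
    replicate are simply absent (missing)."""
    return (
        filtered.groupby(["peptide", "time_h", "bio_rep"], as_index=False)[
            "intensity"
        ]
        .mean()
        .sort_values(["peptide", "time_h", "bio_rep"])
        .reset_index(drop=True)
    )


def finalize_quant(
    collapsed: pd.DataFrame,
    reference_time: float = 4.0,
    time_grid: list[float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop peptides with no signal at the reference digestion time.

    A peptide is removed only when its intensity at ``reference_time`` is
    missing or zero in *every* biological replicate.  The reference time
    must be part of the measured time grid.
    """
    grid = set(time_grid) if time_grid is not None else set(collapsed["time_h"])
    if reference_time not in grid:
        raise ValueError(
            f"reference time {reference_time} h absent from the time grid {sorted(grid)}"
        )
    at_ref = collapsed[
        (collapsed["time_h"] == reference_time) & (collapsed["intensity"] > 0)
    ]
    keep = set(at_ref["peptide"])
    dropped = sorted(set(collapsed["peptide"]) - keep)
    for pep in dropped:
        logger.info("peptide %s missing at %.3g h in all replicates; dropped",
                    pep, reference_time)
    return collapsed[collapsed["peptide"].isin(keep)].reset_index(drop=True), dropped


def multi_mapper_adjust(intensity: float | np.ndarray, n_origins: int) -> np.ndarray:
    """Split a peptide's intensity equally across its substrate origins;
    the per-origin values sum exactly to the input."""
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    return np.asarray(intensity, dtype=float) / n_origins
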