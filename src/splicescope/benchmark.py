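"""Ground-truth benchmark construction and precision-recall evaluation.

High-confidence peptide identifications are embedded into an in
silico-only reference protein — either contiguously (truth: non-spliced)
or as two separated fragments mimicking the splice-reactants of a
cis-spliced peptide — yielding a dataset where the correct answer for
every spectrum is known.  Identification methods are then scored by
precision (correct / reported) and recall (correct / possible) per
product-type stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rescoring import _substring_mass_index
from .spectra import peptide_mass
from .splice_space import (
    ProductType,
    ResolvedType,
    Substrate,
    canonical_sequence,
    map_peptide,
)

__all__ = [
    "TruthEntry",
    "GroundTruthDataset",
    "PrCurve",
    "build_concatenated_reference",
    "embed_as_spliced",
    "evaluate_pr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthEntry:
    spectrum_id: str
    peptide: str
    intended_type: str  # "non_spliced" or "spliced"


@dataclass
class GroundTruthDataset:
    """A constructed reference sequence plus the spectrum-level truth map."""

    reference: Substrate
    truth: dict[str, TruthEntry]
    provenance: list[dict] = field(default_factory=list)

    def verify(self) -> None:
        """Check that every truth peptide is recoverable from the
        reference with its intended type."""
        for entry in self.truth.values():
            mapped = map_peptide(entry.peptide, self.reference)
            if mapped is None:
                raise AssertionError(
                    f"truth peptide {entry.peptide} unmappable on the reference"
                )
            if entry.intended_type == "non_spliced":
                if mapped.resolved_type is not ResolvedType.NON_SPLICED:
                    raise AssertionError(
                        f"{entry.peptide} should map non-spliced, "
                        f"got {mapped.resolved_type}"
                    )
            else:
                if mapped.resolved_type is ResolvedType.NON_SPLICED:
                    raise AssertionError(
                        f"{entry.peptide} should not map contiguously"
                    )


def _has_isobaric_nonspliced(
    peptide: str, masses: np.ndarray, seqs: list[str], tolerance_ppm: float
) -> bool:
    target = peptide_mass(peptide)
    tol = target * tolerance_ppm * 1e-6
    lo = np.searchsorted(masses, target - tol, side="left")
    hi = np.searchsorted(masses, target + tol, side="right")
    canon = canonical_sequence(peptide)
    return any(canonical_sequence(s) != canon for s in seqs[lo:hi])


def build_concatenated_reference(
    peptides: pd.DataFrame,
    min_spectral_angle: float = 0.7,
    source_substrate: Substrate | None = None,
    isobaric_tolerance_ppm: float = 6.0,
    seed: int = 0,
    reference_id: str = "constructed_reference",
) -> GroundTruthDataset:
    """Concatenate high-confidence peptides into a constructed reference.

    Rows need columns ``spectrum_id``, ``peptide``, ``spectral_angle``
    and optionally ``origin_flag``.  PSMs with spectral angle <= the
    threshold are excluded, as are spliced PSMs for which an isobaric
    non-spliced peptide exists in the source substrate.  The concatenation
    order is a seeded shuffle; every surviving peptide appears contiguously
    and is truth-typed non-spliced.
    """
    work = peptides[peptides["spectral_angle"] > min_spectral_angle]
    if source_substrate is not None and "origin_flag" in work.columns:
        masses, seqs = _substring_mass_index(source_substrate.sequence)
        keep = [
            not (
                rec["origin_flag"] == "spliced"
                and _has_isobaric_nonspliced(
                    rec["peptide"], masses, seqs, isobaric_tolerance_ppm
                )
            )
            for rec in work.to_dict("records")
        ]
        work = work[np.asarray(keep, dtype=bool)]
    work = work.drop_duplicates("peptide")
    if work.empty:
        raise ValueError("no peptides survive the high-confidence filters")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(work))
    records = work.iloc[order].to_dict("records")
    sequence = "".join(rec["peptide"] for rec in records)
    reference = Substrate(reference_id, sequence, "in silico-only constructed protein")
    truth, provenance = {}, []
    offset = 0
    for rec in records:
        truth[rec["spectrum_id"]] = TruthEntry(
            rec["spectrum_id"], rec["peptide"], "non_spliced"
        )
        provenance.append(
            {
                "spectrum_id": rec["spectrum_id"],
                "peptide": rec["peptide"],
                "embedding": "contiguous",
                "start": offset + 1,
            }
        )
        offset += len(rec["peptide"])
    dataset = GroundTruthDataset(reference, truth, provenance)
    dataset.verify()
    return dataset


def embed_as_spliced(
    peptide: str,
    spectrum_id: str,
    dataset: GroundTruthDataset,
    seed: int = 0,
    max_attempts: int = 100,
) -> GroundTruthDataset:
    """Embed a peptide into the reference as two separated fragments.

    The peptide is split at a seeded internal position and the two
    fragments inserted at non-adjacent reference positions; the placement
    is accepted only if the updated reference explains the peptide as
    (forward) cis-spliced and not contiguously.  Bounded retries guard
    against repeat-induced contiguous occurrences.
    """
    if len(peptide) < 2:
        raise ValueError("cannot split a single-residue peptide")
    rng = np.random.default_rng(seed)
    base = dataset.reference.sequence
    for _ in range(max_attempts):
        split = int(rng.integers(1, len(peptide)))
        frag1, frag2 = peptide[:split], peptide[split:]
        pos1 = int(rng.integers(0, len(base) + 1))
        lo2 = pos1 + len(frag1) + 1  # at least one intervening residue
        if lo2 > len(base) + len(frag1):
            continue
        pos2 = int(rng.integers(lo2, len(base) + len(frag1) + 1))
        candidate = base[:pos1] + frag1 + base[pos1:]
        candidate = candidate[:pos2] + frag2 + candidate[pos2:]
        reference = Substrate(dataset.reference.id, candidate,
                              dataset.reference.description)
        mapped = map_peptide(peptide, reference)
        if mapped is None or mapped.resolved_type is ResolvedType.NON_SPLICED:
            continue
        if not any(
            loc.product_type is ProductType.CIS_FORWARD for loc in mapped.locations
        ):
            continue
        # previously embedded peptides must remain recoverable
        updated = GroundTruthDataset(
            reference,
            {**dataset.truth,
             spectrum_id: TruthEntry(spectrum_id, peptide, "spliced")},
            dataset.provenance
            + [{
                "spectrum_id": spectrum_id,
                "peptide": peptide,
                "embedding": "split",
                "split": split,
                "insert_1": pos1 + 1,
                "insert_2": pos2 + 1,
            }],
        )
        try:
            updated.verify()
        except AssertionError:
            continue
        return updated
    raise RuntimeError(
        f"could not place {peptide} without a contiguous occurrence "
        f"after {max_attempts} attempts"
    )


@dataclass
class PrCurve:
    """Precision-recall triples over score thresholds, per stratum."""

    stratum: str
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    operating_point: tuple[float, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def _curve(
    results: pd.DataFrame,
    correct: np.ndarray,
    n_possible: int,
    stratum: str,
    accepted_mask: np.ndarray | None,
) -> PrCurve:
    order = np.argsort(-results["score"].to_numpy(), kind="mergesort")
    c = correct[order]
    cum_correct = np.cumsum(c)
    cum_total = np.arange(1, c.size + 1)
    precision = np.where(cum_total > 0, cum_correct / cum_total, 1.0)
    recall = cum_correct / max(n_possible, 1)
    thresholds = results["score"].to_numpy()[order]
    operating = None
    if accepted_mask is not None and accepted_mask.any():
        acc = accepted_mask[order]
        n_acc = int(np.flatnonzero(acc).max()) + 1
        operating = (
            float(cum_correct[n_acc - 1] / n_acc),
            float(cum_correct[n_acc - 1] / max(n_possible, 1)),
        )
    if c.size == 0:
        precision = np.array([1.0])
        recall = np.array([0.0])
        thresholds = np.array([np.inf])
        logger.info("empty result set for stratum %s; precision 1 by convention",
                    stratum)
    return PrCurve(stratum, thresholds, precision, recall, operating)


def evaluate_pr(
    results: pd.DataFrame,
    dataset: GroundTruthDataset,
    accepted_column: str | None = None,
) -> dict[str, PrCurve]:
    """Precision-recall curves of scored identifications against truth.

    ``results`` needs columns ``spectrum_id``, ``peptide``, ``score`` and
    optionally a stratum column ``origin_flag`` plus a boolean
    ``accepted_column`` marking the method's operating point.  An
    identification is correct when its sequence matches the truth peptide
    up to I/L equivalence; results for spectra absent from the truth map
    count as incorrect (logged).
    """
    results = results.reset_index(drop=True)
    correct = np.zeros(len(results), dtype=bool)
    for row, rec in enumerate(results.to_dict("records")):
        entry = dataset.truth.get(rec["spectrum_id"])
        if entry is None:
            logger.info("spectrum %s not in the truth map; counted incorrect",
                        rec["spectrum_id"])
            continue
        correct[row] = canonical_sequence(rec["peptide"]) == canonical_sequence(
            entry.peptide
        )
    accepted = (
        results[accepted_column].to_numpy(dtype=bool)
        if accepted_column is not None
        else None
    )
    curves = {
        "overall": _curve(results, correct, len(dataset.truth), "overall", accepted)
    }
    if "origin_flag" in results.columns:
        truth_types = {}
        for entry in dataset.truth.values():
            truth_types[entry.intended_type] = (
                truth_types.get(entry.intended_type, 0) + 1
            )
        for stratum, sub in results.groupby("origin_flag"):
            idx = sub.index.to_numpy()
            n_possible = truth_types.get(
                "spliced" if stratum == "spliced" else "non_spliced", 0
            )
            curves[str(stratum)] = _curve(
                sub.reset_index(drop=True),
                correct[idx],
                n_possible,
                str(stratum),
                accepted[idx] if accepted is not None else None,
            )
    return curves
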