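"""MS2 spectrum model, a deterministic mock fragment predictor, peak
matching, similarity metrics and indexed-retention-time calibration.

The spectrum predictor is a pluggable contract: anything exposing
``predict(peptide, charge) -> PredictedSpectrum`` with deterministic output
works.  The shipped implementation (:class:`MockSpectrumPredictor`)
computes exact singly-charged b/y fragment masses from monoisotopic
residue masses and draws reproducible pseudo-random intensities seeded by
the peptide string, so the full pipeline runs without any trained model.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass
from scipy import stats as _stats
from sklearn.model_selection import KFold

from .splice_space import AA_ALPHABET

__all__ = [
    "Spectrum",
    "PredictedSpectrum",
    "IrtCalibration",
    "MockSpectrumPredictor",
    "PredictorError",
    "peptide_mass",
    "fragment_mz",
    "match_peaks",
    "spectral_angle",
    "spearman_similarity",
    "fit_irt_calibration",
    "irt_error",
    "PROTON_MASS",
    "WATER_MASS",
]

logger = logging.getLogger(__name__)

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863
CARBAMIDOMETHYL_MASS = 57.02146

#: Monoisotopic residue masses; cysteine is carried carbamidomethylated
#: (fixed modification) throughout.
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in AA_ALPHABET}
RESIDUE_MASS_CAM = dict(RESIDUE_MASS)
RESIDUE_MASS_CAM["C"] += CARBAMIDOMETHYL_MASS

#: Fixed, dimensionless per-residue retention coefficients used by the mock
#: predictor's indexed retention time.  Loosely hydrophobicity-ordered so
#: that composition drives elution, as for real peptides.
IRT_COEFFICIENTS = {
    "A": 1.1, "C": 0.5, "D": -1.0, "E": -0.9, "F": 4.6, "G": 0.2,
    "H": -1.3, "I": 4.2, "K": -2.1, "L": 4.2, "M": 2.5, "N": -0.8,
    "P": 0.1, "Q": -0.7, "R": -1.8, "S": -0.4, "T": 0.3, "V": 3.3,
    "W": 4.9, "Y": 2.3,
}


class PredictorError(ValueError):
    """Raised when a peptide cannot be handled by the spectrum predictor."""


@dataclass
class Spectrum:
    """A centroided MS2 spectrum."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id} has no peaks")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError(f"negative intensity in spectrum {self.spectrum_id}")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError(
                f"peaks of spectrum {self.spectrum_id} must be strictly "
                "ascending in m/z"
            )


@dataclass
class PredictedSpectrum:
    """Predictor output: annotated b/y fragments with max-normalized
    intensities and a predicted indexed retention time."""

    peptide: str
    charge: int
    annotations: tuple[str, ...]
    mz: np.ndarray
    intensity: np.ndarray
    predicted_irt: float

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(set(self.annotations)) != len(self.annotations):
            raise ValueError("duplicate fragment annotations")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1):
            raise ValueError("predicted intensities must lie in [0, 1]")


def peptide_mass(peptide: str, cam_c: bool = True) -> float:
    """Monoisotopic neutral peptide mass (Da)."""
    table = RESIDUE_MASS_CAM if cam_c else RESIDUE_MASS
    try:
        return sum(table[aa] for aa in peptide) + WATER_MASS
    except KeyError as exc:
        raise PredictorError(f"unsupported residue {exc.args[0]!r}") from exc


def fragment_mz(peptide: str, series: str, index: int, cam_c: bool = True) -> float:
    """m/z of a singly protonated b- or y-ion."""
    table = RESIDUE_MASS_CAM if cam_c else RESIDUE_MASS
    if series == "b":
        return sum(table[aa] for aa in peptide[:index]) + PROTON_MASS
    if series == "y":
        return sum(table[aa] for aa in peptide[-index:]) + WATER_MASS + PROTON_MASS
    raise ValueError(f"unknown ion series {series!r}")


class MockSpectrumPredictor:
    """Deterministic stand-in for a learned MS2/iRT predictor.

    Fragment m/z values are exact (singly charged b1..b(n-1) and
    y1..y(n-1)); intensities come from a pseudo-random generator seeded by
    SHA-256 of ``peptide/charge``, so identical inputs always give
    identical spectra while distinct peptides give uncorrelated intensity
    patterns.  The predicted iRT is the sum of fixed per-residue
    coefficients plus a small length term.
    """

    #: length window the downstream identification pipeline enforces
    min_peptide_length = 7
    max_peptide_length = 30

    def __init__(self, min_intensity: float = 0.05, cam_c: bool = True):
        self.min_intensity = min_intensity
        self.cam_c = cam_c
        self._cache: dict[tuple[str, int], PredictedSpectrum] = {}

    def predict(self, peptide: str, charge: int = 2) -> PredictedSpectrum:
        key = (peptide, charge)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if len(peptide) < 2:
            raise PredictorError("peptide too short to fragment")
        if any(aa not in RESIDUE_MASS for aa in peptide):
            raise PredictorError(f"unsupported residues in {peptide!r}")
        n = len(peptide)
        annotations, mzs = [], []
        for idx in range(1, n):
            annotations.append(f"b{idx}+1")
            mzs.append(fragment_mz(peptide, "b", idx, self.cam_c))
            annotations.append(f"y{idx}+1")
            mzs.append(fragment_mz(peptide, "y", idx, self.cam_c))
        seed = int.from_bytes(
            hashlib.sha256(f"{peptide}/{charge}".encode()).digest()[:4], "big"
        )
        rng = np.random.default_rng(seed)
        intensity = rng.uniform(self.min_intensity, 1.0, size=len(mzs))
        intensity /= intensity.max()
        order = np.argsort(mzs)
        pred = PredictedSpectrum(
            peptide=peptide,
            charge=charge,
            annotations=tuple(annotations[i] for i in order),
            mz=np.asarray(mzs)[order],
            intensity=intensity[order],
            predicted_irt=self.predict_irt(peptide),
        )
        if len(self._cache) < 200_000:
            self._cache[key] = pred
        return pred

    @staticmethod
    def predict_irt(peptide: str) -> float:
        try:
            return sum(IRT_COEFFICIENTS[aa] for aa in peptide) + 0.35 * len(peptide)
        except KeyError as exc:
            raise PredictorError(f"unsupported residue {exc.args[0]!r}") from exc


def match_peaks(
    observed: Spectrum,
    predicted: PredictedSpectrum,
    tolerance: float = 0.02,
    unit: str = "Th",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair predicted fragments with observed peaks.

    Each predicted fragment is matched to at most one observed peak — the
    nearest in m/z within the tolerance (given in Thomson or ppm);
    unmatched fragments contribute zero observed intensity.  Returns
    ``(predicted_intensities, observed_intensities)`` of equal length.
    """
    pred_mz = predicted.mz
    obs_mz = observed.mz
    idx = np.searchsorted(obs_mz, pred_mz)
    left = np.clip(idx - 1, 0, obs_mz.size - 1)
    right = np.clip(idx, 0, obs_mz.size - 1)
    d_left = np.abs(pred_mz - obs_mz[left])
    d_right = np.abs(pred_mz - obs_mz[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    if unit == "Th":
        tol = np.full_like(pred_mz, float(tolerance))
    elif unit == "ppm":
        tol = pred_mz * tolerance * 1e-6
    else:
        raise ValueError("tolerance unit must be 'Th' or 'ppm'")
    matched = dist <= tol
    obs_vec = np.where(matched, observed.intensity[nearest], 0.0)
    return predicted.intensity.copy(), obs_vec


def spectral_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Normalized spectral contrast angle between two non-negative
    intensity vectors: ``1 - 2*arccos(cos(v1, v2))/pi``, ranging from 0
    (orthogonal) to 1 (positively proportional)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("intensity vectors must have equal length")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 and n2 == 0.0:
        raise ValueError("spectral angle undefined for two all-zero vectors")
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    cos = float(np.dot(v1, v2) / (n1 * n2))
    cos = min(max(cos, 0.0), 1.0)
    return 1.0 - 2.0 * np.arccos(cos) / np.pi


def spearman_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); returns NaN —
    the feature-missing sentinel — when either vector is constant."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = _stats.spearmanr(v1, v2).statistic
    return float(rho)


@dataclass
class IrtCalibration:
    """Linear map from predicted iRT to observed retention time (minutes)."""

    slope: float
    intercept: float
    n_points: int
    used_fallback: bool = False
    oof_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict_rt(self, predicted_irt: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(predicted_irt, dtype=float) + self.intercept


def fit_irt_calibration(
    predicted_irt: np.ndarray,
    observed_rt: np.ndarray,
    spectral_angles: np.ndarray,
    is_spliced: np.ndarray,
    sa_threshold: float = 0.9,
    min_points: int = 20,
    n_folds: int = 10,
    seed: int = 0,
) -> IrtCalibration:
    """Fit the iRT-to-RT line on high-confidence non-spliced PSMs.

    Only non-spliced PSMs with spectral angle above ``sa_threshold``
    qualify; if fewer than ``min_points`` do, the fit falls back to all
    non-spliced PSMs (logged).  Cross-validation selects nothing: the line
    is the plain least-squares fit on the qualifying subset, and the folds
    only provide out-of-fold residuals as a diagnostic.
    """
    predicted_irt = np.asarray(predicted_irt, dtype=float)
    observed_rt = np.asarray(observed_rt, dtype=float)
    spectral_angles = np.asarray(spectral_angles, dtype=float)
    is_spliced = np.asarray(is_spliced, dtype=bool)

    mask = (~is_spliced) & (spectral_angles > sa_threshold)
    used_fallback = False
    if mask.sum() < min_points:
        logger.warning(
            "only %d non-spliced PSMs with spectral angle > %.2f; "
            "falling back to all %d non-spliced PSMs",
            mask.sum(), sa_threshold, (~is_spliced).sum(),
        )
        mask = ~is_spliced
        used_fallback = True
    x, y = predicted_irt[mask], observed_rt[mask]
    if x.size < 2:
        raise ValueError("iRT calibration needs at least 2 points")
    slope, intercept = np.polyfit(x, y, 1)

    oof = np.full(x.size, np.nan)
    if x.size >= n_folds:
        for train, test in KFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        ).split(x):
            s, b = np.polyfit(x[train], y[train], 1)
            oof[test] = y[test] - (s * x[test] + b)
    return IrtCalibration(
        slope=float(slope),
        intercept=float(intercept),
        n_points=int(x.size),
        used_fallback=used_fallback,
        oof_residuals=oof,
    )


def irt_error(
    predicted_irt: float | np.ndarray,
    observed_rt: float | np.ndarray,
    calibration: IrtCalibration,
) -> float | np.ndarray:
    """Absolute deviation (minutes) of the observed retention time from
    the calibrated prediction."""
    return np.abs(np.asarray(observed_rt, dtype=float) - calibration.predict_rt(predicted_irt))
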