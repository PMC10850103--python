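"""Origin-aware PSM rescoring with target-decoy FDR control.

Candidate peptide-spectrum matches (PSMs) are rescored with a small,
interpretable feature set — spectral angle and Spearman correlation
against predicted MS2 spectra, absolute indexed-retention-time error, and
a flag for the peptide's origin (spliced vs non-spliced).  Including the
origin as a feature lets the discriminant penalize spliced PSMs, whose
sequence search space is orders of magnitude larger than the non-spliced
one, and yields stratified (group) FDR estimates from posterior error
probabilities.

The trainer is a Percolator-style iterative semi-supervised scheme
implemented as a scikit-learn estimator (:class:`PsmRescorer`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import spectra as _spectra
from .spectra import (
    IrtCalibration,
    MockSpectrumPredictor,
    PredictorError,
    Spectrum,
    fit_irt_calibration,
    irt_error,
    match_peaks,
    peptide_mass,
    spectral_angle,
    spearman_similarity,
)
from .splice_space import canonical_sequence

__all__ = [
    "FEATURE_COLUMNS",
    "SPLICED",
    "NON_SPLICED",
    "PsmRescorer",
    "FdrReport",
    "RescoringResult",
    "dedupe_origin",
    "filter_ptm_conflicts",
    "compute_features",
    "target_decoy_qvalues",
    "assign_qvalues",
    "estimate_pep",
    "estimate_pep_and_group_fdr",
    "isobaric_competitor_filter",
    "contaminant_arbitration",
    "rescore_psms",
]

logger = logging.getLogger(__name__)

SPLICED = "spliced"
NON_SPLICED = "non_spliced"

FEATURE_COLUMNS = ["spectral_angle", "spearman", "irt_abs_error", "origin_is_spliced"]

#: modification tokens the spectrum predictor cannot handle
RESTRICTED_MODS = ("deamidation", "acetyl")

MIN_PEPTIDE_LENGTH = 7
MAX_PEPTIDE_LENGTH = 30


def _has_restricted_mod(mods: str) -> bool:
    mods = (mods or "").lower()
    return any(tok in mods for tok in RESTRICTED_MODS)


def dedupe_origin(psms: pd.DataFrame) -> pd.DataFrame:
    """Where the same spectrum/peptide pair occurs as both spliced and
    non-spliced, keep only the non-spliced PSM."""
    psms = psms.copy()
    key = [
        psms["spectrum_id"],
        psms["peptide"].map(canonical_sequence),
        psms["is_decoy"],
    ]
    both = psms.groupby(key)["origin_flag"].transform("nunique") > 1
    drop = both & (psms["origin_flag"] == SPLICED)
    if drop.any():
        logger.info("dropped %d spliced duplicates of non-spliced PSMs", drop.sum())
    return psms.loc[~drop].reset_index(drop=True)


def filter_ptm_conflicts(
    psms: pd.DataFrame, score_fraction: float = 0.7
) -> pd.DataFrame:
    """Remove PSMs the predictor cannot model, arbitrating PTM conflicts.

    A spectrum is dropped entirely when a non-spliced candidate carrying a
    restricted modification (deamidation, N-terminal acetylation) scores
    within 30% of the spectrum's best spliced candidate
    (``base_score >= score_fraction * best_spliced``); otherwise only the
    modified candidates are dropped.
    """
    if "modifications" not in psms.columns:
        return psms.copy()
    psms = psms.copy()
    modded = psms["modifications"].fillna("").map(_has_restricted_mod)
    spliced_best = (
        psms.loc[psms["origin_flag"] == SPLICED]
        .groupby("spectrum_id")["base_score"]
        .max()
    )
    conflict = (
        modded
        & (psms["origin_flag"] == NON_SPLICED)
        & (
            psms["base_score"]
            >= score_fraction * psms["spectrum_id"].map(spliced_best)
        )
    )
    bad_spectra = set(psms.loc[conflict, "spectrum_id"])
    keep = ~psms["spectrum_id"].isin(bad_spectra) & ~modded
    if len(bad_spectra):
        logger.info("removed %d spectra with PTM conflicts", len(bad_spectra))
    return psms.loc[keep].reset_index(drop=True)


def compute_features(
    psms: pd.DataFrame,
    spectra: dict[str, Spectrum],
    predictor: MockSpectrumPredictor | None = None,
    tolerance: float = 0.02,
    unit: str = "Th",
    calibration: IrtCalibration | None = None,
    calibration_seed: int = 0,
) -> tuple[pd.DataFrame, IrtCalibration]:
    """Compute the rescoring feature set for every PSM.

    PSMs outside the predictor's 7–30 residue window or with residues the
    predictor cannot handle are flagged unscoreable and excluded (logged).
    Missing Spearman values (constant vectors) are imputed with the median
    of the PSM's origin stratum.  If no calibration is supplied, the
    iRT-to-RT line is fitted on the freshly computed spectral angles.
    """
    predictor = predictor or MockSpectrumPredictor()
    n_in = len(psms)
    rows = []
    for rec in psms.to_dict("records"):
        pep = rec["peptide"]
        if not (MIN_PEPTIDE_LENGTH <= len(pep) <= MAX_PEPTIDE_LENGTH):
            continue
        try:
            pred = predictor.predict(pep, int(rec.get("charge", 2)))
        except PredictorError:
            continue
        obs = spectra[rec["spectrum_id"]]
        v_pred, v_obs = match_peaks(obs, pred, tolerance, unit)
        if np.count_nonzero(v_obs) < 2:
            # a (near-)empty match is a bad match, not a missing feature
            sa = spectral_angle(v_pred, v_obs) if np.any(v_obs) else 0.0
            rho = 0.0
        else:
            sa = spectral_angle(v_pred, v_obs)
            rho = spearman_similarity(v_pred, v_obs)
        rec = dict(rec)
        rec["spectral_angle"] = sa
        rec["spearman"] = rho
        rec["predicted_irt"] = pred.predicted_irt
        rec["origin_is_spliced"] = float(rec["origin_flag"] == SPLICED)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out) < n_in:
        logger.info("excluded %d unscoreable PSMs", n_in - len(out))
    if out.empty:
        raise ValueError("no scoreable PSMs")

    if calibration is None:
        calibration = fit_irt_calibration(
            out["predicted_irt"].to_numpy(),
            out["retention_time"].to_numpy(),
            out["spectral_angle"].to_numpy(),
            (out["origin_flag"] == SPLICED).to_numpy(),
            seed=calibration_seed,
        )
    out["irt_abs_error"] = irt_error(
        out["predicted_irt"].to_numpy(),
        out["retention_time"].to_numpy(),
        calibration,
    )
    out["spearman"] = out.groupby("origin_flag")["spearman"].transform(
        lambda s: s.fillna(s.median())
    )
    out["spearman"] = out["spearman"].fillna(0.0)
    return out.reset_index(drop=True), calibration


def target_decoy_qvalues(scores: np.ndarray, is_target: np.ndarray) -> np.ndarray:
    """Target-decoy q-values: ``FDR(s) = (#decoys >= s + 1)/(#targets >= s)``,
    monotonized so q is non-increasing in score.  Tied scores share one
    q-value."""
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if (~is_target).sum() == 0:
        raise ValueError("q-values undefined without decoys")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = is_target[order]
    cum_t = np.cumsum(t)
    cum_d = np.cumsum(~t)
    fdr = (cum_d + 1) / np.maximum(cum_t, 1)
    # every member of a tie block gets the FDR at the block's last element
    block_last = np.r_[s[1:] != s[:-1], True]
    last_idx = np.where(block_last, np.arange(s.size), s.size)
    last_idx = np.minimum.accumulate(last_idx[::-1])[::-1]
    fdr = fdr[last_idx]
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


@dataclass
class FdrReport:
    """q-value report at PSM or peptide level."""

    level: str
    table: pd.DataFrame
    cutoff: float
    accepted_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return int(sum(self.accepted_counts.values()))


def assign_qvalues(
    psms: pd.DataFrame,
    level: str = "psm",
    cutoff: float = 0.01,
    score_column: str = "model_score",
) -> FdrReport:
    """Assign target-decoy q-values at PSM or peptide level.

    Peptide level keeps the best-scoring PSM per distinct (I/L-collapsed)
    peptide sequence, separately for targets and decoys, before computing
    q-values.
    """
    if level not in ("psm", "peptide"):
        raise ValueError("level must be 'psm' or 'peptide'")
    table = psms.copy()
    if level == "peptide":
        table["_canon"] = table["peptide"].map(canonical_sequence)
        idx = table.groupby(["is_decoy", "_canon"])[score_column].idxmax()
        table = table.loc[idx].drop(columns="_canon").reset_index(drop=True)
    table["q_value"] = target_decoy_qvalues(
        table[score_column].to_numpy(), ~table["is_decoy"].to_numpy()
    )
    accepted = table[(~table["is_decoy"]) & (table["q_value"] <= cutoff)]
    counts = accepted.groupby("origin_flag").size().to_dict()
    return FdrReport(level=level, table=table, cutoff=cutoff, accepted_counts=counts)


def estimate_pep(scores: np.ndarray, is_target: np.ndarray) -> np.ndarray:
    """Posterior error probabilities from the local decoy fraction.

    An isotonic regression (non-increasing in score) estimates
    P(decoy | score); the decoy/target density ratio follows as
    ``p/(1-p)`` scaled by the overall target/decoy count ratio, clamped to
    [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    n_t, n_d = int(is_target.sum()), int((~is_target).sum())
    if n_t == 0 or n_d == 0:
        raise ValueError("PEP estimation needs both targets and decoys")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False,
                             out_of_bounds="clip")
    p = iso.fit(scores, (~is_target).astype(float)).predict(scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p >= 1.0, np.inf, p / (1.0 - p))
    pep = ratio * (n_t / n_d)
    return np.clip(np.nan_to_num(pep, posinf=1.0), 0.0, 1.0)


def estimate_pep_and_group_fdr(
    psms: pd.DataFrame,
    accepted_mask: np.ndarray,
    score_column: str = "model_score",
) -> tuple[np.ndarray, dict[str, float]]:
    """PEPs for all PSMs and the mean-PEP group FDR per origin stratum,
    computed over accepted target members only.  Strata with no accepted
    members are absent from the result."""
    pep = estimate_pep(
        psms[score_column].to_numpy(), ~psms["is_decoy"].to_numpy()
    )
    accepted_mask = np.asarray(accepted_mask, dtype=bool) & ~psms["is_decoy"].to_numpy()
    group_fdr: dict[str, float] = {}
    for stratum in (NON_SPLICED, SPLICED):
        m = accepted_mask & (psms["origin_flag"] == stratum).to_numpy()
        if m.any():
            group_fdr[stratum] = float(pep[m].mean())
    return pep, group_fdr


class PsmRescorer(BaseEstimator):
    """Percolator-style semi-supervised linear rescorer.

    Starting from the spectral-angle ranking, each iteration (i) computes
    target-decoy q-values of the current score, (ii) takes targets at
    ``q <= train_fdr`` as positives (falling back to the top-k targets if
    none qualify), and (iii) fits an L2-regularized linear discriminant of
    positives versus decoys on z-scored features.  The final linear score
    is deterministic given the seed.

    Parameters
    ----------
    train_fdr : float
        q-value threshold selecting positive training examples.
    n_iterations : int
        Fixed number of refinement iterations.
    l2_lambda : float
        L2 penalty strength (inverse of sklearn's ``C``).  The default is
        deliberately strong: with a near-separable feature space a lightly
        regularized fit lets a handful of boundary PSMs dictate the weight
        of near-redundant features such as the origin flag, whereas heavy
        shrinkage makes the coefficients track the stratum composition of
        positives versus decoys; the ranking itself is insensitive to this
        choice.
    init_feature : str or int
        Feature providing the initial ranking (default spectral angle).
    random_state : int
        Seed for the discriminant solver.
    """

    def __init__(
        self,
        train_fdr: float = 0.01,
        n_iterations: int = 5,
        l2_lambda: float = 100.0,
        init_feature: str | int = "spectral_angle",
        random_state: int = 0,
    ):
        self.train_fdr = train_fdr
        self.n_iterations = n_iterations
        self.l2_lambda = l2_lambda
        self.init_feature = init_feature
        self.random_state = random_state

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                X = X[list(self.feature_names_in_)]
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y) -> "PsmRescorer":
        """Fit on PSM features ``X`` with ``y`` true for targets, false
        for decoys."""
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xm = self._as_matrix(X)
        y = np.asarray(y, dtype=bool)
        if Xm.shape[0] != y.size:
            raise ValueError("X and y disagree in length")
        if y.all() or not y.any():
            raise ValueError("need both targets and decoys to fit")
        self.scaler_ = StandardScaler().fit(Xm)
        Xs = self.scaler_.transform(Xm)

        if isinstance(self.init_feature, str):
            names = list(getattr(self, "feature_names_in_", FEATURE_COLUMNS))
            init_idx = names.index(self.init_feature)
        else:
            init_idx = int(self.init_feature)
        score = Xm[:, init_idx]

        clf = None
        for _ in range(int(self.n_iterations)):
            q = target_decoy_qvalues(score, y)
            positives = y & (q <= self.train_fdr)
            if not positives.any():
                k = max(50, int(0.01 * y.sum()))
                top = np.argsort(-score)
                top_targets = top[y[top]][:k]
                positives = np.zeros_like(y)
                positives[top_targets] = True
                logger.warning(
                    "no targets at train_fdr=%.3g; fell back to top-%d targets",
                    self.train_fdr, k,
                )
            train = positives | ~y
            clf = LogisticRegression(
                C=1.0 / self.l2_lambda,
                max_iter=2000,
                random_state=self.random_state,
            )
            clf.fit(Xs[train], positives[train].astype(int))
            score = clf.decision_function(Xs)

        self.coef_ = clf.coef_.ravel()
        self.intercept_ = float(clf.intercept_[0])
        self.n_features_in_ = Xm.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xs = self.scaler_.transform(self._as_matrix(X))
        return Xs @ self.coef_ + self.intercept_

    def feature_weights(self) -> dict[str, float]:
        """Learned weights in standardized feature space, by name."""
        check_is_fitted(self, "coef_")
        names = list(
            getattr(self, "feature_names_in_",
                    [f"x{i}" for i in range(self.n_features_in_)])
        )
        return dict(zip(names, map(float, self.coef_)))


def _substring_mass_index(
    substrate_sequence: str,
    length_window: tuple[int, int] = (MIN_PEPTIDE_LENGTH, MAX_PEPTIDE_LENGTH),
) -> tuple[np.ndarray, list[str]]:
    seqs: set[str] = set()
    lo, hi = length_window
    L = len(substrate_sequence)
    for n in range(lo, min(hi, L) + 1):
        for start in range(L - n + 1):
            seqs.add(substrate_sequence[start : start + n])
    seq_list = sorted(seqs)
    masses = np.array([peptide_mass(s) for s in seq_list])
    order = np.argsort(masses)
    return masses[order], [seq_list[i] for i in order]


def isobaric_competitor_filter(
    accepted: pd.DataFrame,
    substrate_sequence: str,
    model: PsmRescorer,
    spectra: dict[str, Spectrum],
    calibration: IrtCalibration,
    predictor: MockSpectrumPredictor | None = None,
    tolerance_ppm: float = 6.0,
    tolerance: float = 0.02,
    unit: str = "Th",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arbitrate accepted spliced peptides against isobaric non-spliced
    competitors.

    For each accepted spliced PSM, every substrate substring whose
    monoisotopic mass lies within ``tolerance_ppm`` of the peptide's mass
    is rescored against the same spectrum with the frozen model weights;
    the spliced PSM is removed iff a competitor scores strictly higher.
    Returns the filtered table and a competitor report with both scores.
    """
    predictor = predictor or MockSpectrumPredictor()
    masses, seqs = _substring_mass_index(substrate_sequence)
    report_rows = []
    keep = np.ones(len(accepted), dtype=bool)
    for pos, rec in enumerate(accepted.to_dict("records")):
        if rec["origin_flag"] != SPLICED:
            continue
        pep = rec["peptide"]
        target_mass = peptide_mass(pep)
        tol = target_mass * tolerance_ppm * 1e-6
        lo = np.searchsorted(masses, target_mass - tol, side="left")
        hi = np.searchsorted(masses, target_mass + tol, side="right")
        canon = canonical_sequence(pep)
        best_comp_score, best_comp = -np.inf, None
        obs = spectra[rec["spectrum_id"]]
        for comp in seqs[lo:hi]:
            if canonical_sequence(comp) == canon:
                continue
            pred = predictor.predict(comp, int(rec.get("charge", 2)))
            v_pred, v_obs = match_peaks(obs, pred, tolerance, unit)
            sa = spectral_angle(v_pred, v_obs) if np.any(v_obs) else 0.0
            rho = spearman_similarity(v_pred, v_obs) if np.any(v_obs) else 0.0
            if np.isnan(rho):
                rho = 0.0
            err = float(irt_error(pred.predicted_irt, rec["retention_time"],
                                  calibration))
            feats = pd.DataFrame(
                [[sa, rho, err, 0.0]], columns=FEATURE_COLUMNS
            )
            comp_score = float(model.decision_function(feats)[0])
            if comp_score > best_comp_score:
                best_comp_score, best_comp = comp_score, comp
        if best_comp is not None:
            removed = best_comp_score > rec["model_score"]
            report_rows.append(
                {
                    "spectrum_id": rec["spectrum_id"],
                    "peptide": pep,
                    "model_score": rec["model_score"],
                    "competitor": best_comp,
                    "competitor_score": best_comp_score,
                    "removed": removed,
                }
            )
            if removed:
                keep[pos] = False
    report = pd.DataFrame(
        report_rows,
        columns=["spectrum_id", "peptide", "model_score", "competitor",
                 "competitor_score", "removed"],
    )
    return accepted.loc[keep].reset_index(drop=True), report


def contaminant_arbitration(
    psms: pd.DataFrame, contaminant_psms: pd.DataFrame
) -> pd.DataFrame:
    """Drop assigned PSMs whose spectrum is better explained (strictly
    higher spectral angle) by a contaminant candidate."""
    if contaminant_psms.empty:
        return psms.copy()
    best = contaminant_psms.groupby("spectrum_id")["spectral_angle"].max()
    contam_sa = psms["spectrum_id"].map(best)
    drop = contam_sa.notna() & (contam_sa > psms["spectral_angle"])
    if drop.any():
        logger.info("removed %d PSMs better explained by contaminants", drop.sum())
    return psms.loc[~drop].reset_index(drop=True)


@dataclass
class RescoringResult:
    """End-to-end rescoring output."""

    psms: pd.DataFrame
    psm_report: FdrReport
    peptide_report: FdrReport
    model: PsmRescorer
    calibration: IrtCalibration
    group_fdr: dict[str, float]
    competitor_report: pd.DataFrame | None = None


def rescore_psms(
    psms: pd.DataFrame,
    spectra: dict[str, Spectrum],
    predictor: MockSpectrumPredictor | None = None,
    substrate_sequence: str | None = None,
    contaminant_psms: pd.DataFrame | None = None,
    fdr_cutoff: float = 0.01,
    train_fdr: float = 0.01,
    seed: int = 0,
    tolerance: float = 0.02,
    unit: str = "Th",
) -> RescoringResult:
    """Full rescoring pipeline: origin dedupe, PTM-conflict removal,
    feature computation with iRT calibration, semi-supervised rescoring,
    PSM- and peptide-level q-values, group FDR, and — when a substrate
    and/or contaminant candidates are supplied — isobaric-competitor and
    contaminant arbitration."""
    predictor = predictor or MockSpectrumPredictor()
    work = dedupe_origin(psms)
    work = filter_ptm_conflicts(work)
    feats, calibration = compute_features(
        work, spectra, predictor, tolerance, unit, calibration_seed=seed
    )
    model = PsmRescorer(train_fdr=train_fdr, random_state=seed)
    model.fit(feats[FEATURE_COLUMNS], ~feats["is_decoy"])
    feats["model_score"] = model.decision_function(feats[FEATURE_COLUMNS])

    if contaminant_psms is not None and not contaminant_psms.empty:
        if "spectral_angle" not in contaminant_psms.columns:
            contaminant_psms, _ = compute_features(
                contaminant_psms, spectra, predictor, tolerance, unit,
                calibration=calibration,
            )
        feats = contaminant_arbitration(feats, contaminant_psms)

    psm_report = assign_qvalues(feats, "psm", fdr_cutoff)
    feats = psm_report.table
    peptide_report = assign_qvalues(feats, "peptide", fdr_cutoff)
    pep, group_fdr = estimate_pep_and_group_fdr(
        feats, (feats["q_value"] <= fdr_cutoff).to_numpy()
    )
    feats["pep"] = pep

    competitor_report = None
    if substrate_sequence is not None:
        accepted = peptide_report.table[
            (~peptide_report.table["is_decoy"])
            & (peptide_report.table["q_value"] <= fdr_cutoff)
        ].reset_index(drop=True)
        filtered, competitor_report = isobaric_competitor_filter(
            accepted, substrate_sequence, model, spectra, calibration, predictor,
            tolerance=tolerance, unit=unit,
        )
        peptide_report = FdrReport(
            level="peptide",
            table=pd.concat(
                [
                    filtered,
                    peptide_report.table[
                        peptide_report.table["is_decoy"]
                        | (peptide_report.table["q_value"] > fdr_cutoff)
                    ],
                ],
                ignore_index=True,
            ),
            cutoff=fdr_cutoff,
            accepted_counts=filtered.groupby("origin_flag").size().to_dict(),
        )
    return RescoringResult(
        psms=feats,
        psm_report=psm_report,
        peptide_report=peptide_report,
        model=model,
        calibration=calibration,
        group_fdr=group_fdr,
        competitor_report=competitor_report,
    )
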