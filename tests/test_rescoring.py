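"""Target-decoy q-values, PEP estimation, the semi-supervised rescorer
and the arbitration filters."""

import numpy as np
import pandas as pd
import pytest

from splicescope import rescoring as resc
from splicescope import synthetic_data as synth
from splicescope.rescoring import (
    FEATURE_COLUMNS,
    PsmRescorer,
    assign_qvalues,
    contaminant_arbitration,
    dedupe_origin,
    estimate_pep,
    estimate_pep_and_group_fdr,
    filter_ptm_conflicts,
    target_decoy_qvalues,
)


def brute_force_qvalues(scores, is_target):
    """Independent oracle: evaluate the estimator definition literally."""
    scores = np.asarray(scores, float)
    is_target = np.asarray(is_target, bool)
    out = np.empty_like(scores)
    for idx, s in enumerate(scores):
        candidates = []
        for t in np.unique(scores):
            if t > s:
                continue
            n_d = np.sum((scores >= t) & ~is_target)
            n_t = np.sum((scores >= t) & is_target)
            candidates.append((n_d + 1) / max(n_t, 1))
        out[idx] = min(min(candidates), 1.0)
    return out


def test_qvalues_toy_case_matches_definition():
    scores = np.array([10.0, 9.0, 8.0, 7.0, 8.5, 6.0])
    is_target = np.array([True, True, True, True, False, False])
    q = target_decoy_qvalues(scores, is_target)
    assert np.allclose(q, brute_force_qvalues(scores, is_target))
    # monotonization pulls the top q down to 0.5 on this toy set
    assert q[0] == pytest.approx(0.5)


def test_qvalues_random_match_brute_force(rng):
    for _ in range(20):
        scores = np.round(rng.normal(0, 1, 40), 1)  # rounding forces ties
        is_target = rng.random(40) < 0.5
        if not (~is_target).any():
            is_target[0] = False
        assert np.allclose(
            target_decoy_qvalues(scores, is_target),
            brute_force_qvalues(scores, is_target),
        )


def test_qvalues_separated_case_and_monotonicity(rng):
    scores = np.r_[rng.uniform(10, 20, 8), rng.uniform(0, 5, 4)]
    is_target = np.r_[np.ones(8, bool), np.zeros(4, bool)]
    q = target_decoy_qvalues(scores, is_target)
    assert q[:8].min() == pytest.approx(1 / 8)
    order = np.argsort(-scores)
    assert np.all(np.diff(q[order]) >= 0)
    with pytest.raises(ValueError):
        target_decoy_qvalues(scores, np.ones(12, bool))


def test_peptide_level_uses_best_psm():
    psms = pd.DataFrame(
        {
            "spectrum_id": ["s1", "s2", "s3", "s4"],
            "peptide": ["AAAK", "AAAK", "CCCR", "DDDR"],
            "is_decoy": [False, False, False, True],
            "origin_flag": ["non_spliced"] * 4,
            "model_score": [5.0, 7.0, 6.0, 1.0],
        }
    )
    rep = assign_qvalues(psms, level="peptide", cutoff=0.99)
    targets = rep.table[~rep.table.is_decoy]
    assert len(targets) == 2  # duplicate peptide collapsed
    assert targets.loc[targets.peptide == "AAAK", "model_score"].item() == 7.0
    psm_rep = assign_qvalues(psms, level="psm", cutoff=0.99)
    assert rep.n_accepted <= psm_rep.n_accepted


def test_dedupe_origin_keeps_non_spliced():
    psms = pd.DataFrame(
        {
            "spectrum_id": ["s1", "s1", "s2"],
            "peptide": ["AAAK", "AAAK", "CCCR"],
            "is_decoy": [False] * 3,
            "origin_flag": ["spliced", "non_spliced", "spliced"],
        }
    )
    out = dedupe_origin(psms)
    assert len(out) == 2
    assert set(out.loc[out.peptide == "AAAK", "origin_flag"]) == {"non_spliced"}


def _ptm_frame(mod_score):
    return pd.DataFrame(
        {
            "spectrum_id": ["s1"] * 2 + ["s2"],
            "peptide": ["AAAK", "CCCR", "DDDR"],
            "origin_flag": ["non_spliced", "spliced", "non_spliced"],
            "is_decoy": [False] * 3,
            "base_score": [mod_score, 100.0, 90.0],
            "modifications": ["deamidation", "", ""],
        }
    )


def test_ptm_conflict_thirty_percent_rule():
    # modified non-spliced at 71 vs best spliced 100: whole spectrum goes
    out = filter_ptm_conflicts(_ptm_frame(71.0))
    assert set(out.spectrum_id) == {"s2"}
    # at 50 only the modified candidate goes
    out = filter_ptm_conflicts(_ptm_frame(50.0))
    assert set(out.spectrum_id) == {"s1", "s2"}
    assert "deamidation" not in set(out.modifications)
    # untouched spectra pass through
    clean = _ptm_frame(50.0).assign(modifications="")
    assert len(filter_ptm_conflicts(clean)) == 3


def test_pep_limit_cases(rng):
    scores = np.r_[rng.uniform(10, 20, 50), rng.uniform(0, 5, 50)]
    is_target = np.r_[np.ones(50, bool), np.zeros(50, bool)]
    pep = estimate_pep(scores, is_target)
    assert np.all((pep >= 0) & (pep <= 1))
    assert pep[:50].mean() < 0.05  # separated targets: PEP ~ 0
    # targets drawn from the decoy distribution: mean PEP near 1
    scores = rng.uniform(0, 5, 200)
    is_target = np.r_[np.ones(100, bool), np.zeros(100, bool)]
    pep = estimate_pep(scores, is_target)
    assert pep[is_target].mean() > 0.6


def test_group_fdr_is_mean_pep_of_accepted():
    psms = pd.DataFrame(
        {
            "model_score": [10.0, 9.0, 8.0, 2.0, 1.5, 1.0],
            "is_decoy": [False, False, False, True, True, True],
            "origin_flag": ["non_spliced", "spliced", "non_spliced",
                            "non_spliced", "spliced", "non_spliced"],
        }
    )
    accepted = np.array([True, True, True, False, False, False])
    pep, gfdr = estimate_pep_and_group_fdr(psms, accepted)
    for stratum, val in gfdr.items():
        mask = accepted & (~psms.is_decoy) & (psms.origin_flag == stratum)
        assert val == pytest.approx(pep[mask.to_numpy()].mean())
        assert pep[mask.to_numpy()].min() <= val <= pep[mask.to_numpy()].max()


def test_rescorer_separates_targets(rng):
    ds = synth.simulate_rescoring_dataset(n_targets=400, n_decoys=400, seed=7)
    feats, _ = resc.compute_features(ds.psms, ds.spectra)
    model = PsmRescorer(random_state=7)
    model.fit(feats[FEATURE_COLUMNS], ~feats.is_decoy)
    score = model.decision_function(feats[FEATURE_COLUMNS])
    y = (~feats.is_decoy).to_numpy()
    # ROC AUC by rank statistic
    ranks = pd.Series(score).rank().to_numpy()
    auc = (ranks[y].sum() - y.sum() * (y.sum() + 1) / 2) / (y.sum() * (~y).sum())
    assert auc > 0.9
    assert set(model.feature_weights()) == set(FEATURE_COLUMNS)


def test_rescorer_invariant_to_feature_rescaling(rng):
    ds = synth.simulate_rescoring_dataset(n_targets=300, n_decoys=300, seed=3)
    feats, _ = resc.compute_features(ds.psms, ds.spectra)
    X = feats[FEATURE_COLUMNS].copy()
    y = ~feats.is_decoy
    base = PsmRescorer(random_state=0).fit(X, y).decision_function(X)
    X2 = X.copy()
    X2["irt_abs_error"] = 100.0 * X2["irt_abs_error"] - 7.0
    rescaled = PsmRescorer(random_state=0).fit(X2, y).decision_function(X2)
    assert np.allclose(np.argsort(base), np.argsort(rescaled))


def test_rescorer_degenerate_features_keep_ranking():
    X = pd.DataFrame(
        {c: np.ones(40) for c in FEATURE_COLUMNS}
    )
    y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
    model = PsmRescorer(random_state=0).fit(X, y)
    score = model.decision_function(X)
    assert np.allclose(score, score[0])  # all tied, ranking unchanged


def test_isobaric_competitor_filter_rules(predictor):
    ds = synth.simulate_rescoring_dataset(n_targets=120, n_decoys=120, seed=5)
    res = resc.rescore_psms(ds.psms, ds.spectra, seed=5)
    accepted = res.peptide_report.table
    accepted = accepted[(~accepted.is_decoy)].reset_index(drop=True)
    # a substrate unrelated to any peptide: no isobaric competitor exists,
    # so everything is retained
    filtered, report = resc.isobaric_competitor_filter(
        accepted, "G" * 40, res.model, ds.spectra, res.calibration, predictor
    )
    assert len(filtered) == len(accepted)
    assert report.empty or not report.removed.any()


def test_isobaric_competitor_removes_better_scoring_substring(predictor):
    # build one spliced PSM whose spectrum is truly the substrate substring
    substrate = "LKNWDAEFGHYTRVMPQSCI"
    competitor = substrate[2:11]  # NWDAEFGHY
    # permuting two residues keeps the composition (hence the mass) but
    # changes the sequence, so the contiguous original is a competitor
    spliced = "NWDAGEFHY"
    pred = predictor.predict(competitor, 2)
    import splicescope.spectra as sp

    obs = sp.Spectrum("x1", 500.0, 2,
                      2.0 * predictor.predict_irt(competitor) + 5.0,
                      pred.mz, pred.intensity)
    calib = sp.IrtCalibration(slope=2.0, intercept=5.0, n_points=10)
    model = PsmRescorer(random_state=0)
    X = pd.DataFrame(
        np.array([[0.9, 0.9, 0.1, 0.0], [0.2, 0.1, 30.0, 1.0]] * 20),
        columns=FEATURE_COLUMNS,
    )
    model.fit(X, np.array([True, False] * 20))
    accepted = pd.DataFrame(
        [{
            "spectrum_id": "x1", "peptide": spliced, "origin_flag": "spliced",
            "is_decoy": False, "charge": 2,
            "retention_time": obs.retention_time,
            "model_score": float(model.decision_function(
                pd.DataFrame([[0.3, 0.2, 5.0, 1.0]], columns=FEATURE_COLUMNS)
            )[0]),
        }]
    )
    filtered, report = resc.isobaric_competitor_filter(
        accepted, substrate, model, {"x1": obs}, calib, predictor
    )
    assert report.removed.all()
    assert filtered.empty


def test_contaminant_arbitration_rules():
    psms = pd.DataFrame(
        {
            "spectrum_id": ["s1", "s2", "s3"],
            "peptide": ["AAAK", "CCCR", "DDDR"],
            "spectral_angle": [0.80, 0.90, 0.70],
        }
    )
    contams = pd.DataFrame(
        {
            "spectrum_id": ["s1", "s2"],
            "peptide": ["KKKK", "RRRR"],
            "spectral_angle": [0.95, 0.90],
        }
    )
    out = contaminant_arbitration(psms, contams)
    # s1 dropped (0.95 > 0.80); s2 retained on the tie; s3 untouched
    assert set(out.spectrum_id) == {"s2", "s3"}


def test_empirical_fdr_controlled_on_simulated_data():
    ds = synth.simulate_rescoring_dataset(
        n_targets=800, n_decoys=800, false_match_rate=0.1, seed=11
    )
    res = resc.rescore_psms(ds.psms, ds.spectra, seed=11)
    table = res.peptide_report.table.merge(
        ds.truth, on=["spectrum_id", "peptide"], how="left"
    )
    accepted = table[(~table.is_decoy) & (table.q_value <= 0.01)]
    assert len(accepted) > 400
    assert accepted.is_false.mean() <= 0.03
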