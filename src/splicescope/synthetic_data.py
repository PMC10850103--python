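"""Synthetic substrates, digestions, spectra and PSM tables.

Everything downstream of a mass spectrometer is emulated here with known
ground truth: substrates are i.i.d. residue strings; digestion products
are drawn with configurable residue-specific P1 propensities for
hydrolysis and splicing (spliced peptides a minority, as observed for
proteasomal processing); abundances follow saturating accumulation
kinetics with multiplicative lognormal noise; observed MS2 spectra are
the deterministic mock predictions perturbed by intensity and m/z noise,
with false matches injected at a configured rate by swapping peptide
assignments; decoys come from the reversed substrate.  All randomness
flows from a single seed through named child seeds, so every fixture is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantification import KINETICS_COLUMNS
from .rescoring import NON_SPLICED, SPLICED
from .spectra import (
    MockSpectrumPredictor,
    PROTON_MASS,
    Spectrum,
    peptide_mass,
)
from .splice_space import (
    AA_ALPHABET,
    PeptideProduct,
    Substrate,
    canonical_sequence,
    map_peptide,
)

__all__ = [
    "DigestionSimConfig",
    "DigestionResult",
    "PsmDataset",
    "simulate_substrate",
    "simulate_digestion",
    "simulate_psm_table",
    "simulate_rescoring_dataset",
    "child_seed",
]


def child_seed(seed: int, name: str) -> int:
    """Deterministic child seed derived from a master seed and a label."""
    h = np.uint32(seed & 0x7FFFFFFF)
    for ch in name:
        h = np.uint32((int(h) * 31 + ord(ch)) & 0x7FFFFFFF)
    return int(h)


@dataclass
class DigestionSimConfig:
    """Study conditions for a simulated in vitro digestion.

    Defaults mirror the structure of proteasomal protein digestions:
    spliced products are a minority, first splice-reactants are short,
    kinetics are measured at 0/1/2/4/24 h in 2 biological x 2 technical
    replicates, and a few percent of candidate PSMs are false matches.
    """

    seed: int
    substrate_length: int = 300
    n_products: int = 150
    spliced_fraction: float = 0.15
    trans_fraction: float = 0.01
    hydrolysis_propensity: dict[str, float] = field(default_factory=dict)
    splicing_propensity: dict[str, float] = field(default_factory=dict)
    length_range: tuple[int, int] = (7, 25)
    sr1_length_range: tuple[int, int] = (2, 6)
    max_intervening: int = 40
    time_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 24.0)
    n_bio: int = 2
    n_tech: int = 2
    intensity_cv: float = 0.3
    background_level: float = 0.002
    spectrum_noise_sd: float = 0.15
    mz_jitter_sd: float = 0.003
    rt_jitter_sd: float = 0.4
    false_match_rate: float = 0.05
    irt_slope: float = 2.0
    irt_intercept: float = 5.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 <= self.spliced_fraction <= 1:
            raise ValueError("spliced_fraction must lie in [0, 1]")
        if any(v < 0 for v in self.hydrolysis_propensity.values()):
            raise ValueError("propensities must be non-negative")
        if any(v < 0 for v in self.splicing_propensity.values()):
            raise ValueError("propensities must be non-negative")


@dataclass
class DigestionResult:
    substrate: Substrate
    products: list[PeptideProduct]
    truth: pd.DataFrame
    kinetics: pd.DataFrame


@dataclass
class PsmDataset:
    psms: pd.DataFrame
    spectra: dict[str, Spectrum]
    contaminants: pd.DataFrame
    truth: pd.DataFrame


def simulate_substrate(
    length: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
) -> Substrate:
    """An i.i.d. random substrate over the 20-letter alphabet."""
    if length < 5:
        raise ValueError("substrate must be at least 5 residues long")
    letters = list(AA_ALPHABET)
    if composition:
        weights = np.array([composition.get(aa, 0.0) for aa in letters], float)
        if weights.sum() <= 0:
            raise ValueError("composition has no mass")
    else:
        weights = np.ones(len(letters))
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(letters, size=length, p=weights))
    return Substrate(f"synthetic_{seed}", seq, f"simulated substrate (seed {seed})")


def _site_weights(sequence: str, propensity: dict[str, float]) -> np.ndarray:
    w = np.array([propensity.get(aa, 1.0) for aa in sequence], float)
    if w.sum() <= 0:
        raise ValueError("propensities leave no admissible P1 site")
    return w / w.sum()


def simulate_digestion(
    substrate: Substrate, config: DigestionSimConfig
) -> DigestionResult:
    """Draw peptide products and their abundance kinetics.

    Hydrolysis products end at P1 sites drawn proportionally to the
    hydrolysis propensity of the site residue; spliced products anchor
    the C-terminus of a short first splice-reactant at sites drawn from
    the splicing propensity and ligate a downstream second reactant
    (occasionally an overlapping one, giving trans products).  Expected
    abundances follow ``A_max * (1 - exp(-rate * t))`` with multiplicative
    lognormal replicate noise, plus a small 0 h background level.
    """
    rng = np.random.default_rng(child_seed(config.seed, "digestion"))
    seq = substrate.sequence
    L = substrate.length
    lo, hi = config.length_range
    if L < lo:
        raise ValueError("substrate shorter than the minimum product length")
    w_hyd = _site_weights(seq, config.hydrolysis_propensity)
    w_spl = _site_weights(seq, config.splicing_propensity)

    products: dict[str, PeptideProduct] = {}
    rows = []
    attempts = 0
    while len(products) < config.n_products and attempts < 200 * config.n_products:
        attempts += 1
        spliced = rng.random() < config.spliced_fraction
        if not spliced:
            j = int(rng.choice(L, p=w_hyd)) + 1
            n = int(rng.integers(lo, hi + 1))
            i = j - n + 1
            if i < 1:
                continue
            pep = seq[i - 1 : j]
        else:
            j = int(rng.choice(L, p=w_spl)) + 1
            len1 = int(rng.integers(*config.sr1_length_range))
            i = j - len1 + 1
            if i < 1:
                continue
            n_total = int(rng.integers(max(lo, len1 + 1), hi + 1))
            len2 = n_total - len1
            if len2 < 1:
                continue
            if rng.random() < config.trans_fraction:
                k_lo, k_hi = max(1, i - len2 + 1), min(j, L - len2 + 1)
            else:
                k_lo, k_hi = j + 2, min(j + 2 + config.max_intervening, L - len2 + 1)
            if k_hi < k_lo:
                continue
            k = int(rng.integers(k_lo, k_hi + 1))
            pep = seq[i - 1 : j] + seq[k - 1 : k + len2 - 1]
        if pep in products or not (lo <= len(pep) <= hi):
            continue
        mapped = map_peptide(pep, substrate)
        if mapped is None:
            continue
        if spliced and not mapped.is_spliced:
            continue
        products[pep] = mapped
        rows.append(
            {
                "peptide": pep,
                "type": mapped.resolved_type.value,
                "n_origins": mapped.n_origins,
                "a_max": float(10 ** rng.normal(6.0, 0.4)),
                "rate": float(rng.uniform(0.2, 1.5)),
            }
        )
    if len(products) < config.n_products:
        raise ValueError("could not realize the requested number of products")
    truth = pd.DataFrame(rows)

    krows = []
    for rec in rows:
        for t in config.time_grid:
            mean = rec["a_max"] * (1.0 - np.exp(-rec["rate"] * t))
            for bio in range(1, config.n_bio + 1):
                for tech in range(1, config.n_tech + 1):
                    noise = float(
                        np.exp(rng.normal(0.0, config.intensity_cv))
                    )
                    background = rec["a_max"] * config.background_level * float(
                        np.exp(rng.normal(0.0, 0.5))
                    )
                    krows.append(
                        {
                            "peptide": rec["peptide"],
                            "time_h": t,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "intensity": mean * noise + background,
                        }
                    )
    kinetics = pd.DataFrame(krows, columns=KINETICS_COLUMNS)
    return DigestionResult(substrate, list(products.values()), truth, kinetics)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _observed_spectrum(
    spectrum_id: str,
    source_peptide: str,
    charge: int,
    retention_time: float,
    predictor: MockSpectrumPredictor,
    rng: np.random.Generator,
    noise_sd: float,
    mz_jitter_sd: float,
) -> Spectrum:
    pred = predictor.predict(source_peptide, charge)
    intensity = pred.intensity * np.exp(rng.normal(0.0, noise_sd, pred.intensity.size))
    mz = pred.mz + rng.normal(0.0, mz_jitter_sd, pred.mz.size)
    order = np.argsort(mz)
    mz = mz[order]
    intensity = intensity[order]
    # enforce strictly ascending m/z after jitter
    mz = np.maximum.accumulate(mz + np.arange(mz.size) * 1e-9)
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=(peptide_mass(source_peptide) + charge * PROTON_MASS) / charge,
        charge=charge,
        retention_time=retention_time,
        mz=mz,
        intensity=intensity,
    )


def simulate_rescoring_dataset(
    n_targets: int = 1000,
    n_decoys: int = 1000,
    false_match_rate: float = 0.05,
    spliced_fraction: float = 0.3,
    spliced_all_false: bool = False,
    seed: int = 0,
    predictor: MockSpectrumPredictor | None = None,
    spectrum_noise_sd: float = 0.15,
    mz_jitter_sd: float = 0.003,
    rt_jitter_sd: float = 0.4,
    irt_slope: float = 2.0,
    irt_intercept: float = 5.0,
    length_range: tuple[int, int] = (8, 12),
) -> PsmDataset:
    """A standalone target/decoy PSM set with known false-match labels.

    Correct target PSMs observe a noisy rendition of their own predicted
    spectrum and elute on the retention-time calibration line; false
    targets (injected at ``false_match_rate``) and decoys observe spectra
    of unrelated peptides and elute at an unrelated time, making the two
    statistically exchangeable — the property target-decoy FDR estimation
    relies on.  ``spliced_all_false`` turns the whole spliced stratum into
    false matches, the stress case for origin-aware rescoring.
    """
    predictor = predictor or MockSpectrumPredictor()
    rng = np.random.default_rng(child_seed(seed, "rescoring"))
    rows, spectra, truth_rows = [], {}, []

    def _make(idx: int, is_decoy: bool) -> None:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pep = _random_peptide(rng, length)
        spliced = rng.random() < spliced_fraction
        sid = f"{'d' if is_decoy else 't'}{idx:06d}"
        is_false = is_decoy or rng.random() < false_match_rate
        if spliced and spliced_all_false and not is_decoy:
            is_false = True
        irt = predictor.predict_irt(pep)
        if is_false:
            source = _random_peptide(rng, length)
            rt = irt_slope * rng.uniform(-10, 60) + irt_intercept
        else:
            source = pep
            rt = irt_slope * irt + irt_intercept + rng.normal(0.0, rt_jitter_sd)
        spectra[sid] = _observed_spectrum(
            sid, source, 2, rt, predictor, rng, spectrum_noise_sd, mz_jitter_sd
        )
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": pep,
                "is_decoy": is_decoy,
                "origin_flag": SPLICED if spliced else NON_SPLICED,
                "base_score": float(rng.normal(55 if is_false else 70, 8)),
                "charge": 2,
                "precursor_mz": (peptide_mass(pep) + 2 * PROTON_MASS) / 2,
                "retention_time": rt,
                "modifications": "",
            }
        )
        truth_rows.append(
            {"spectrum_id": sid, "peptide": pep, "is_false": is_false}
        )

    for idx in range(n_targets):
        _make(idx, False)
    for idx in range(n_decoys):
        _make(idx, True)
    return PsmDataset(
        psms=pd.DataFrame(rows),
        spectra=spectra,
        contaminants=pd.DataFrame(
            columns=["spectrum_id", "peptide", "charge", "retention_time"]
        ),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_benchmark_psms(
    reference: Substrate,
    truth_peptides: dict[str, str],
    seed: int = 0,
    predictor: MockSpectrumPredictor | None = None,
    spectrum_noise_sd: float = 0.15,
    mz_jitter_sd: float = 0.003,
    rt_jitter_sd: float = 0.4,
    irt_slope: float = 2.0,
    irt_intercept: float = 5.0,
) -> PsmDataset:
    """Candidate PSMs for a constructed ground-truth dataset.

    Every truth spectrum (``spectrum_id -> peptide``) genuinely observes
    its own peptide; in addition each spectrum receives one spliced
    candidate drawn from the reference's cis-spliced search space
    (emulating the large spliced stratum a search engine would propose)
    plus one non-spliced and one spliced decoy from the reversed
    reference.
    """
    predictor = predictor or MockSpectrumPredictor()
    rng = np.random.default_rng(child_seed(seed, "benchmark"))
    seq = reference.sequence
    rev = seq[::-1]
    canon_ref = canonical_sequence(seq)
    window = (7, 14)
    rows, spectra, truth_rows = [], {}, []

    def _spliced_candidate() -> str | None:
        """A forward-cis sequence from the reference search space."""
        for _ in range(50):
            total = int(rng.integers(window[0], window[1] + 1))
            len1 = int(rng.integers(1, total))
            len2 = total - len1
            i = int(rng.integers(1, reference.length - len1 + 2))
            j = i + len1 - 1
            k_lo, k_hi = j + 2, reference.length - len2 + 1
            if k_hi < k_lo:
                continue
            k = int(rng.integers(k_lo, k_hi + 1))
            cand = seq[i - 1 : j] + seq[k - 1 : k + len2 - 1]
            if canonical_sequence(cand) not in canon_ref:
                return cand
        return None

    def _row(sid, pep, decoy, spliced, rt, is_false):
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": pep,
                "is_decoy": decoy,
                "origin_flag": SPLICED if spliced else NON_SPLICED,
                "base_score": float(rng.normal(55 if is_false else 70, 8)),
                "charge": 2,
                "precursor_mz": (peptide_mass(pep) + 2 * PROTON_MASS) / 2,
                "retention_time": rt,
                "modifications": "",
            }
        )

    for sid, pep in truth_peptides.items():
        rt = (
            irt_slope * predictor.predict_irt(pep)
            + irt_intercept
            + rng.normal(0.0, rt_jitter_sd)
        )
        spectra[sid] = _observed_spectrum(
            sid, pep, 2, rt, predictor, rng, spectrum_noise_sd, mz_jitter_sd
        )
        _row(sid, pep, False, False, rt, False)
        truth_rows.append({"spectrum_id": sid, "peptide": pep, "is_false": False})
        # one spliced competitor candidate per spectrum
        cand = _spliced_candidate()
        if cand is not None:
            _row(sid, cand, False, True, rt, True)
        # decoys from the reversed reference
        for spliced_decoy in (False, True):
            for _ in range(50):
                length = int(rng.integers(window[0], window[1] + 1))
                start = int(rng.integers(0, len(rev) - length + 1))
                dpep = rev[start : start + length]
                if canonical_sequence(dpep) not in canon_ref:
                    break
            else:
                continue
            did = f"{sid}_d{int(spliced_decoy)}"
            drt = irt_slope * rng.uniform(-10, 60) + irt_intercept
            spectra[did] = _observed_spectrum(
                did, _random_peptide(rng, length), 2, drt, predictor, rng,
                spectrum_noise_sd, mz_jitter_sd,
            )
            _row(did, dpep, True, spliced_decoy, drt, True)
    return PsmDataset(
        psms=pd.DataFrame(rows),
        spectra=spectra,
        contaminants=pd.DataFrame(
            columns=["spectrum_id", "peptide", "charge", "retention_time"]
        ),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_psm_table(
    digestion: DigestionResult,
    config: DigestionSimConfig,
    predictor: MockSpectrumPredictor | None = None,
    n_contaminants: int = 5,
) -> PsmDataset:
    """Candidate PSM table, spectra, decoys and contaminants for a
    simulated digestion.

    One target PSM per identified product (false matches injected by
    assignment swapping), an equal number of decoy PSMs drawn from the
    reversed substrate (decoy sequences colliding with true substrings
    are dropped and redrawn), and a small set of contaminant candidate
    PSMs that share spectrum ids with target PSMs and genuinely generated
    their spectra.
    """
    predictor = predictor or MockSpectrumPredictor()
    rng = np.random.default_rng(child_seed(config.seed, "psm"))
    substrate = digestion.substrate
    rev = substrate.sequence[::-1]
    canon_sub = canonical_sequence(substrate.sequence)
    rows, spectra, truth_rows, contam_rows = [], {}, [], []

    eligible = [
        p for p in digestion.products
        if predictor.min_peptide_length
        <= len(p.sequence)
        <= predictor.max_peptide_length
    ]
    contam_protein = _random_peptide(rng, 120)
    contam_spectra = set(
        rng.choice(len(eligible), size=min(n_contaminants, len(eligible)),
                   replace=False)
    )
    for idx, product in enumerate(eligible):
        pep = product.sequence
        sid = f"scan{idx:05d}"
        spliced = product.is_spliced
        is_false = rng.random() < config.false_match_rate
        irt = predictor.predict_irt(pep)
        if idx in contam_spectra:
            # the spectrum truly comes from a contaminant peptide
            start = int(rng.integers(0, len(contam_protein) - 11))
            source = contam_protein[start : start + 10]
            rt = config.irt_slope * rng.uniform(-10, 60) + config.irt_intercept
            is_false = True
            contam_rows.append(
                {
                    "spectrum_id": sid,
                    "peptide": source,
                    "is_decoy": False,
                    "origin_flag": NON_SPLICED,
                    "base_score": float(rng.normal(70, 8)),
                    "charge": 2,
                    "retention_time": rt,
                    "modifications": "",
                }
            )
        elif is_false:
            source = _random_peptide(rng, len(pep))
            rt = config.irt_slope * rng.uniform(-10, 60) + config.irt_intercept
        else:
            source = pep
            rt = (
                config.irt_slope * irt
                + config.irt_intercept
                + rng.normal(0.0, config.rt_jitter_sd)
            )
        spectra[sid] = _observed_spectrum(
            sid, source, 2, rt, predictor, rng,
            config.spectrum_noise_sd, config.mz_jitter_sd,
        )
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": pep,
                "is_decoy": False,
                "origin_flag": SPLICED if spliced else NON_SPLICED,
                "base_score": float(rng.normal(55 if is_false else 70, 8)),
                "charge": 2,
                "precursor_mz": (peptide_mass(pep) + 2 * PROTON_MASS) / 2,
                "retention_time": rt,
                "modifications": "",
            }
        )
        truth_rows.append({"spectrum_id": sid, "peptide": pep, "is_false": is_false})

    n_spliced = sum(p.is_spliced for p in eligible)
    for idx in range(len(eligible)):
        for _ in range(50):
            length = int(rng.integers(config.length_range[0],
                                      min(config.length_range[1], 25) + 1))
            start = int(rng.integers(0, len(rev) - length + 1))
            dpep = rev[start : start + length]
            if canonical_sequence(dpep) not in canon_sub:
                break
        else:
            continue
        sid = f"decoy{idx:05d}"
        rt = config.irt_slope * rng.uniform(-10, 60) + config.irt_intercept
        spectra[sid] = _observed_spectrum(
            sid, _random_peptide(rng, length), 2, rt, predictor, rng,
            config.spectrum_noise_sd, config.mz_jitter_sd,
        )
        rows.append(
            {
                "spectrum_id": sid,
                "peptide": dpep,
                "is_decoy": True,
                "origin_flag": SPLICED if idx < n_spliced else NON_SPLICED,
                "base_score": float(rng.normal(55, 8)),
                "charge": 2,
                "precursor_mz": (peptide_mass(dpep) + 2 * PROTON_MASS) / 2,
                "retention_time": rt,
                "modifications": "",
            }
        )
    return PsmDataset(
        psms=pd.DataFrame(rows),
        spectra=spectra,
        contaminants=pd.DataFrame(
            contam_rows,
            columns=["spectrum_id", "peptide", "is_decoy", "origin_flag",
                     "base_score", "charge", "retention_time", "modifications"],
        ),
        truth=pd.DataFrame(truth_rows),
    )
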