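"""Quantitative sequence-preference analytics for digestion products.

Given identified peptide products with reference-time MS1 intensities,
this module computes

* site-specific cleavage and splicing strengths (SCS-P1 / PSP-P1):
  per-residue summed product intensity at the P1 position, normalized
  within a local 29-residue window to a percentage profile;
* simulated background databases of spliced (rejection-sampled coordinate
  tuples) and non-spliced peptides, qualitatively and with sampled
  quantities, as the null model for sequence preferences;
* quantitative sequence logos whose letter heights derive from the
  Jensen–Shannon divergence (base 2) between two position-weight matrices;
* substrate coverage profiles (log10-summed intensities per residue,
  min/max-scaled and spline-smoothed) and their hotspot/non-hotspot
  partition, with Bayes-rule conditional motif matrices, P1 densities and
  per-type generation efficacies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .splice_space import (
    AA_ALPHABET,
    PeptideProduct,
    ProductType,
    ResolvedType,
    Substrate,
    classify_tuple,
    count_forward_cis,
    count_nonspliced,
    count_reverse_cis,
    count_trans,
    enumerate_products,
    map_peptide,
    SpaceParams,
)

__all__ = [
    "ResidueProfile",
    "CoverageProfile",
    "HotspotPartition",
    "HotspotMotifs",
    "BackgroundDatabase",
    "LogoMatrix",
    "compute_scs_psp",
    "sample_spliced_tuples",
    "simulate_background_qualitative",
    "simulate_background_nonspliced",
    "simulate_background_quantitative",
    "pwm_from_sites",
    "normalize_pwm",
    "product_pwm",
    "js_divergence",
    "quantitative_logo",
    "coverage_profile",
    "hotspot_split",
    "hotspot_conditional_pwm",
    "p1_density",
    "generation_efficacy",
    "IDENT_LENGTH_WINDOW",
]

IDENT_LENGTH_WINDOW = (7, 30)

SYMMETRIC_COLUMNS = tuple(
    [f"P{i}" for i in range(6, 0, -1)] + [f"P{i}'" for i in range(1, 7)]
)
HOTSPOT_COLUMNS = tuple(
    [f"P{i}" for i in range(6, 0, -1)] + [f"P-{i}" for i in range(1, 7)]
)


@dataclass
class ResidueProfile:
    """A per-residue value vector over a substrate."""

    substrate_id: str
    values: np.ndarray
    kind: str


@dataclass
class CoverageProfile:
    """Raw, scaled and smoothed substrate coverage."""

    substrate_id: str
    raw: np.ndarray
    scaled: np.ndarray
    smoothed: np.ndarray


@dataclass
class HotspotPartition:
    """Median split of detected P1 residues by coverage."""

    detected_p1: tuple[int, ...]
    hotspot_p1: tuple[int, ...]
    threshold: float
    hotspot_stretch: tuple[int, ...]
    non_hotspot_stretch: tuple[int, ...]

    @property
    def p_hotspot(self) -> float:
        return len(self.hotspot_p1) / len(self.detected_p1)


@dataclass
class BackgroundDatabase:
    """A simulated background peptide database."""

    products: list[PeptideProduct]
    size_factor: float
    tuples: list[tuple] = field(default_factory=list)
    intensities: np.ndarray | None = None


@dataclass
class LogoMatrix:
    """Per-position divergence heights and signed per-letter heights."""

    heights: pd.Series
    letter_heights: pd.DataFrame


@dataclass
class HotspotMotifs:
    """Conditional motif matrices inside/outside hotspots, with the
    randomized-background averages and the derived logos."""

    p_r: pd.DataFrame
    p_h_given_r: pd.DataFrame
    p_r_given_h: pd.DataFrame
    p_r_given_nh: pd.DataFrame
    p_r_given_h_rnd: pd.DataFrame
    p_r_given_nh_rnd: pd.DataFrame
    logos: dict[str, LogoMatrix]


# ---------------------------------------------------------------------------
# SCS-P1 / PSP-P1


def _per_origin_intensity(product: PeptideProduct, intensity: float) -> float:
    return intensity / product.n_origins


def compute_scs_psp(
    products_with_intensity: list[tuple[PeptideProduct, float]],
    substrate: Substrate,
    window: int = 29,
) -> tuple[ResidueProfile, ResidueProfile]:
    """Site-specific cleavage (SCS-P1) and splicing (PSP-P1) strengths.

    For every substrate residue, the intensities (multi-mapper-adjusted)
    of all non-spliced peptides with that residue at P1 (their C-terminus)
    are summed into the cleavage strength, and of all spliced peptides
    with that residue at the C-terminus of their first splice-reactant
    into the splicing strength.  Each value is then expressed as a
    percentage of the sum inside a centred window (truncated at the
    termini), default 29 residues.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of residues")
    L = substrate.length
    scs = np.zeros(L)
    psp = np.zeros(L)
    for product, intensity in products_with_intensity:
        share = _per_origin_intensity(product, intensity)
        target = psp if product.is_spliced else scs
        for loc in product.locations:
            target[loc.sr1_end - 1] += share

    half = window // 2

    def _normalize(raw: np.ndarray) -> np.ndarray:
        out = np.zeros_like(raw)
        for r in range(L):
            window_sum = raw[max(0, r - half) : r + half + 1].sum()
            if window_sum > 0:
                out[r] = 100.0 * raw[r] / window_sum
        return out

    return (
        ResidueProfile(substrate.id, _normalize(scs), "SCS_P1"),
        ResidueProfile(substrate.id, _normalize(psp), "PSP_P1"),
    )


# ---------------------------------------------------------------------------
# simulated background databases


def _tuple_is_valid(
    i: int, j: int, k: int, n: int, length_window: tuple[int, int], l_ext: int
) -> bool:
    if not (i <= j and k <= n):
        return False
    len1, len2 = j - i + 1, n - k + 1
    if len1 < l_ext or len2 < l_ext:
        return False
    if not (length_window[0] <= len1 + len2 <= length_window[1]):
        return False
    return classify_tuple(i, j, k, n) is not None


def sample_spliced_tuples(
    substrate_length: int,
    n_samples: int,
    rng: np.random.Generator,
    length_window: tuple[int, int] = IDENT_LENGTH_WINDOW,
    l_ext: int = 1,
    max_batches: int = 100_000,
) -> list[tuple[int, int, int, int]]:
    """Rejection-sample valid spliced coordinate tuples.

    Four positions are drawn uniformly with replacement from 1..L; the
    tuple is accepted iff it forms a valid forward/reverse cis- or
    trans-spliced peptide whose total length lies in the identification
    window.  Accepted tuples are uniform over the valid-tuple set.
    """
    L = substrate_length
    out: list[tuple[int, int, int, int]] = []
    batch = max(4 * n_samples, 4096)
    for _ in range(max_batches):
        d = rng.integers(1, L + 1, size=(batch, 4))
        i, j, k, n = d[:, 0], d[:, 1], d[:, 2], d[:, 3]
        len1 = j - i + 1
        len2 = n - k + 1
        total = len1 + len2
        ok = (
            (i <= j)
            & (k <= n)
            & (len1 >= l_ext)
            & (len2 >= l_ext)
            & (total >= length_window[0])
            & (total <= length_window[1])
            # forward-adjacent tuples duplicate non-spliced peptides; every
            # other ordering is forward/reverse cis or trans
            & (k != j + 1)
        )
        for row in d[ok]:
            out.append(tuple(int(x) for x in row))
            if len(out) == n_samples:
                return out
    raise ValueError(
        "rejection sampling failed; the substrate admits no (or almost no) "
        "valid spliced peptide in the length window"
    )


def simulate_background_qualitative(
    substrate: Substrate,
    identified_spliced: list[str] | list[PeptideProduct],
    factor: int = 50,
    seed: int = 0,
    length_window: tuple[int, int] = IDENT_LENGTH_WINDOW,
    l_ext: int = 1,
) -> BackgroundDatabase:
    """Qualitative spliced background database via rejection sampling.

    The database holds ``factor`` times as many sampled spliced sequences
    as there are identified spliced peptides; every sampled sequence is
    re-mapped onto the substrate to account for multi-mapping.
    """
    if not identified_spliced:
        raise ValueError("identified spliced set must be non-empty")
    n_samples = factor * len(identified_spliced)
    rng = np.random.default_rng(seed)
    tuples = sample_spliced_tuples(
        substrate.length, n_samples, rng, length_window, l_ext
    )
    seq = substrate.sequence
    products = []
    for i, j, k, n in tuples:
        pep = seq[i - 1 : j] + seq[k - 1 : n]
        mapped = map_peptide(pep, substrate, SpaceParams(len(pep), l_ext))
        assert mapped is not None
        products.append(mapped)
    return BackgroundDatabase(products, float(factor), tuples)


def simulate_background_nonspliced(
    substrate: Substrate,
    n_samples: int,
    seed: int = 0,
    length_window: tuple[int, int] = IDENT_LENGTH_WINDOW,
) -> BackgroundDatabase:
    """Non-spliced background: sample with replacement from the complete
    enumeration of in-window non-spliced peptides."""
    pool: list[str] = []
    for n in range(length_window[0], min(length_window[1], substrate.length) + 1):
        pool.extend(
            seq for _, seq in enumerate_products(
                substrate, SpaceParams(n), ProductType.NON_SPLICED
            )
        )
    if not pool:
        raise ValueError("substrate admits no non-spliced peptide in the window")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(pool), size=n_samples)
    products = [map_peptide(pool[p], substrate) for p in picks]
    return BackgroundDatabase([p for p in products if p is not None], 0.0)


_TYPE_GROUP = {
    ResolvedType.NON_SPLICED: "non_spliced",
    ResolvedType.CIS: "cis",
    ResolvedType.CIS_MULTI_MAPPER: "cis",
    ResolvedType.TRANS: "trans",
}


_COARSE_GROUP = {
    ResolvedType.NON_SPLICED: "non_spliced",
    ResolvedType.CIS: "spliced",
    ResolvedType.CIS_MULTI_MAPPER: "spliced",
    ResolvedType.TRANS: "spliced",
}


def simulate_background_quantitative(
    background: BackgroundDatabase,
    observed: pd.DataFrame,
    seed: int = 0,
    grouping: str = "fine",
) -> BackgroundDatabase:
    """Assign each background sequence an intensity drawn uniformly within
    the observed intensity range of peptides of the same product type.

    ``observed`` needs columns ``type`` and ``intensity`` (reference-time
    intensities of identified peptides).  With the default fine
    ``grouping`` the types are non_spliced/cis/trans; ``grouping='coarse'``
    pools all spliced products, for datasets where a rare type (typically
    trans) was never detected.
    """
    if grouping not in ("fine", "coarse"):
        raise ValueError("grouping must be 'fine' or 'coarse'")
    group_map = _TYPE_GROUP if grouping == "fine" else _COARSE_GROUP
    rng = np.random.default_rng(seed)
    ranges: dict[str, tuple[float, float]] = {}
    for group, sub in observed.groupby("type"):
        ranges[str(group)] = (float(sub["intensity"].min()),
                              float(sub["intensity"].max()))
    intensities = np.empty(len(background.products))
    for idx, product in enumerate(background.products):
        group = group_map[product.resolved_type]
        if group not in ranges:
            raise ValueError(
                f"no observed intensities for product type {group!r}"
            )
        lo, hi = ranges[group]
        intensities[idx] = rng.uniform(lo, hi)
    return BackgroundDatabase(
        background.products, background.size_factor, background.tuples, intensities
    )


# ---------------------------------------------------------------------------
# position-weight matrices and divergence logos


def pwm_from_sites(
    substrate: Substrate,
    sites: list[tuple[int, int, float]],
    columns: tuple[str, ...] = SYMMETRIC_COLUMNS,
) -> pd.DataFrame:
    """Accumulate per-(amino acid, position) weights around P1/P1' sites.

    ``sites`` are (p1 position, p1' position, weight) triples in substrate
    coordinates; the six columns left of the junction read upstream from
    P1 and the six right of it downstream from P1'.  Positions falling
    outside the substrate are skipped.  The result is unnormalized.
    """
    L = substrate.length
    n_flank = len(columns) // 2
    aa_idx = np.array([AA_ALPHABET.index(aa) for aa in substrate.sequence])
    acc = np.zeros((len(AA_ALPHABET), len(columns)))
    for p1, p1prime, weight in sites:
        for offset in range(n_flank):
            pos = p1 - offset  # P1 is the site residue itself
            if 1 <= pos <= L:
                acc[aa_idx[pos - 1], n_flank - 1 - offset] += weight
            pos = p1prime + offset
            if 1 <= pos <= L:
                acc[aa_idx[pos - 1], n_flank + offset] += weight
    return pd.DataFrame(acc, index=list(AA_ALPHABET), columns=list(columns))


def normalize_pwm(mat: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize so every position sums to 1 (all-zero columns are
    left at zero)."""
    sums = mat.sum(axis=0)
    out = mat.copy()
    nz = sums > 0
    out.loc[:, nz] = mat.loc[:, nz] / sums[nz]
    return out


def bayes_conditional(
    p_h_given_r: pd.DataFrame, p_r: pd.DataFrame, p_h: float
) -> pd.DataFrame:
    """Position-wise Bayes rule ``P(R|H) = P(H|R) * P(R) / P(H)``,
    column-normalized so each position is a distribution."""
    if p_h <= 0:
        raise ValueError("P(H) must be positive")
    return normalize_pwm(p_h_given_r * p_r / p_h)


def product_sites(
    products_with_intensity: list[tuple[PeptideProduct, float]],
    spliced: bool,
    log_transform: bool = True,
) -> list[tuple[int, int, float]]:
    """Extract (P1, P1', weight) site triples for one stratum.

    P1 is the C-terminus of the (first) splice-reactant; for non-spliced
    peptides P1' is simply the next substrate residue.  Weights are the
    log10-transformed multi-mapper-adjusted intensities (or 1 per origin
    when ``log_transform`` is off, for qualitative matrices).
    """
    sites = []
    for product, intensity in products_with_intensity:
        if product.is_spliced != spliced:
            continue
        share = _per_origin_intensity(product, intensity)
        weight = math.log10(share) if log_transform else 1.0
        for loc in product.locations:
            p1 = loc.sr1_end
            p1prime = loc.sr2_start if loc.sr2_start is not None else loc.sr1_end + 1
            sites.append((p1, p1prime, weight))
    return sites


def product_pwm(
    products_with_intensity: list[tuple[PeptideProduct, float]],
    substrate: Substrate,
    spliced: bool,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Column-normalized PWM of one stratum around the P1/P1' junction."""
    sites = product_sites(products_with_intensity, spliced, log_transform)
    return normalize_pwm(pwm_from_sites(substrate, sites))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence in bits between two distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    return 0.5 * _kl(p) + 0.5 * _kl(q)


def quantitative_logo(P: pd.DataFrame, Q: pd.DataFrame) -> LogoMatrix:
    """Divergence logo between two PWMs.

    Per position ``p`` the total height is the base-2 Jensen–Shannon
    divergence between the two columns; each letter receives the signed
    share ``(P_ap - Q_ap) / sum_a |P_ap - Q_ap|`` of that height (zero
    where the columns coincide), so positive letters are enriched in
    ``P`` and negative ones in ``Q``.
    """
    if P.shape != Q.shape or list(P.columns) != list(Q.columns):
        raise ValueError("P and Q must share shape and column labels")
    heights = pd.Series(0.0, index=P.columns)
    letters = pd.DataFrame(0.0, index=P.index, columns=P.columns)
    for col in P.columns:
        p = P[col].to_numpy()
        q = Q[col].to_numpy()
        if np.allclose(p, q):
            continue
        d = js_divergence(p, q)
        r = (p - q) / np.abs(p - q).sum()
        heights[col] = d
        letters[col] = d * r
    return LogoMatrix(heights, letters)


# ---------------------------------------------------------------------------
# coverage profiles and hotspots


def coverage_profile(
    products_with_intensity: list[tuple[PeptideProduct, float]],
    substrate: Substrate,
) -> CoverageProfile:
    """Per-residue quantitative substrate coverage.

    For each residue, the log10-transformed multi-mapper-adjusted
    intensities of all peptides covering it are summed; the profile is
    min/max-scaled, smoothed with a cubic smoothing spline (penalty chosen
    by generalized cross-validation), and min/max-scaled again into
    [0, 1].  A constant profile scales to all zeros.
    """
    L = substrate.length
    if L < 2:
        raise ValueError("coverage requires a substrate of length >= 2")
    raw = np.zeros(L)
    for product, intensity in products_with_intensity:
        share = _per_origin_intensity(product, intensity)
        if share <= 0:
            raise ValueError("coverage requires strictly positive intensities")
        contribution = math.log10(share)
        for loc in product.locations:
            raw[loc.sr1_start - 1 : loc.sr1_end] += contribution
            if loc.sr2_start is not None:
                raw[loc.sr2_start - 1 : loc.sr2_end] += contribution

    def _minmax(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    scaled = _minmax(raw)
    if np.all(scaled == 0):
        smoothed = scaled.copy()
    else:
        x = np.arange(L, dtype=float)
        spline = make_smoothing_spline(x, scaled)
        smoothed = _minmax(spline(x))
    return CoverageProfile(substrate.id, raw, scaled, smoothed)


def hotspot_split(
    coverage: np.ndarray, detected_p1: list[int]
) -> HotspotPartition:
    """Split detected P1 residues into hotspot/non-hotspot halves.

    The upper half by coverage becomes the hotspot set (ties at the
    threshold all count as hotspot; an odd count gives the extra residue
    to the hotspot side).  The lowest hotspot coverage is the cut-off that
    partitions the whole substrate into hotspot and non-hotspot sequence
    stretches.  All-equal coverages make the split meaningless and raise.
    """
    detected = sorted(set(int(p) for p in detected_p1))
    if len(detected) < 2:
        raise ValueError("need at least 2 detected P1 residues")
    cov = np.asarray(coverage, dtype=float)
    values = cov[np.asarray(detected) - 1]
    if np.all(values == values[0]):
        raise ValueError("all detected P1 coverages are equal; split is ambiguous")
    order = np.argsort(-values, kind="mergesort")
    n_hot = math.ceil(len(detected) / 2)
    threshold = float(values[order[n_hot - 1]])
    hotspot = tuple(p for p, v in zip(detected, values) if v >= threshold)
    hot_stretch = tuple(int(p) for p in np.flatnonzero(cov >= threshold) + 1)
    non_stretch = tuple(int(p) for p in np.flatnonzero(cov < threshold) + 1)
    return HotspotPartition(
        detected_p1=tuple(detected),
        hotspot_p1=hotspot,
        threshold=threshold,
        hotspot_stretch=hot_stretch,
        non_hotspot_stretch=non_stretch,
    )


def _conditional_matrices(
    substrate: Substrate,
    anchors: list[int],
    coverage: np.ndarray,
    hotspot_mask: np.ndarray,
    columns: tuple[str, ...] = HOTSPOT_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """P(R), P(H|R) and the Bayes-rule conditionals for one anchor set.

    ``hotspot_mask`` flags hotspot residues over the whole substrate; the
    fraction of hotspot anchors is taken as P(H).  All matrices are
    column-normalized; P(H) = 0.5 by construction of the median split.
    """
    L = substrate.length
    n_flank = len(columns) // 2
    aa_idx = np.array([AA_ALPHABET.index(aa) for aa in substrate.sequence])
    shape = (len(AA_ALPHABET), len(columns))
    counts = np.zeros(shape)
    hot_acc = np.zeros(shape)
    all_acc = np.zeros(shape)
    n_hot_anchors = 0
    for anchor in anchors:
        is_hot = bool(hotspot_mask[anchor - 1])
        n_hot_anchors += is_hot
        c = float(coverage[anchor - 1])
        for offset in range(-n_flank + 1, n_flank + 1):
            pos = anchor + offset
            if not (1 <= pos <= L):
                continue
            col = offset + n_flank - 1
            aa = aa_idx[pos - 1]
            counts[aa, col] += 1.0
            all_acc[aa, col] += c
            if is_hot:
                hot_acc[aa, col] += c
    index = list(AA_ALPHABET)
    p_r = pd.DataFrame(counts, index=index, columns=list(columns))
    cov_hot = pd.DataFrame(hot_acc, index=index, columns=list(columns))
    cov_all = pd.DataFrame(all_acc, index=index, columns=list(columns))
    p_h = n_hot_anchors / max(len(anchors), 1)
    p_r = normalize_pwm(p_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_h = (cov_hot / cov_all).fillna(0.0)
        ratio_nh = ((cov_all - cov_hot) / cov_all).fillna(0.0)
    p_h_given_r = normalize_pwm(ratio_h)
    p_nh_given_r = normalize_pwm(ratio_nh)
    p_r_given_h = normalize_pwm(p_h_given_r * p_r / max(p_h, 1e-12))
    p_r_given_nh = normalize_pwm(p_nh_given_r * p_r / max(1.0 - p_h, 1e-12))
    return p_r, p_h_given_r, p_r_given_h, p_r_given_nh


def hotspot_conditional_pwm(
    partition: HotspotPartition,
    anchors: list[int],
    substrate: Substrate,
    coverage: np.ndarray,
    n_randomizations: int = 100,
    seed: int = 0,
) -> HotspotMotifs:
    """Bayes-rule conditional motifs inside/outside hotspot regions.

    ``anchors`` are the detected P1 positions (one entry per origin, so
    multi-mapper origins all contribute).  Randomized backgrounds permute
    the coverage values over the substrate while keeping the sequence
    fixed, re-derive the hotspot split from the permuted upper half, and
    average the resulting conditionals over ``n_randomizations`` seeded
    repetitions; logos compare the observed conditionals against these
    backgrounds and against each other.
    """
    cov = np.asarray(coverage, dtype=float)
    L = substrate.length
    hot_mask = np.zeros(L, dtype=bool)
    hot_mask[np.asarray(partition.hotspot_stretch) - 1] = True
    p_r, p_h_given_r, p_r_given_h, p_r_given_nh = _conditional_matrices(
        substrate, anchors, cov, hot_mask
    )

    rng = np.random.default_rng(seed)
    acc_h = None
    acc_nh = None
    for _ in range(n_randomizations):
        perm = rng.permutation(cov)
        thr = float(np.median(perm))
        mask = perm >= thr
        _, _, rnd_h, rnd_nh = _conditional_matrices(
            substrate, anchors, perm, mask
        )
        acc_h = rnd_h if acc_h is None else acc_h + rnd_h
        acc_nh = rnd_nh if acc_nh is None else acc_nh + rnd_nh
    p_r_given_h_rnd = normalize_pwm(acc_h / n_randomizations)
    p_r_given_nh_rnd = normalize_pwm(acc_nh / n_randomizations)

    logos = {
        "hotspot_vs_random": quantitative_logo(p_r_given_h, p_r_given_h_rnd),
        "non_hotspot_vs_random": quantitative_logo(p_r_given_nh, p_r_given_nh_rnd),
        "hotspot_vs_non_hotspot": quantitative_logo(p_r_given_h, p_r_given_nh),
    }
    return HotspotMotifs(
        p_r, p_h_given_r, p_r_given_h, p_r_given_nh,
        p_r_given_h_rnd, p_r_given_nh_rnd, logos,
    )


def p1_density(
    partition: HotspotPartition,
    p1_hydrolysis: list[int],
    p1_splicing: list[int],
) -> dict[tuple[str, str], float]:
    """Distinct P1 residues per unit stretch length, per reaction and
    hotspot class."""
    out: dict[tuple[str, str], float] = {}
    for region, stretch in (
        ("hotspot", set(partition.hotspot_stretch)),
        ("non_hotspot", set(partition.non_hotspot_stretch)),
    ):
        if not stretch:
            raise ValueError(f"{region} sequence stretch is empty")
        for reaction, positions in (
            ("hydrolysis", p1_hydrolysis),
            ("splicing", p1_splicing),
        ):
            distinct = set(positions) & stretch
            out[(reaction, region)] = len(distinct) / len(stretch)
    return out


def generation_efficacy(
    identified_counts: dict[str, int],
    substrate_length: int,
    length_window: tuple[int, int] = IDENT_LENGTH_WINDOW,
    l_ext: int = 1,
) -> dict[str, float]:
    """Identified over theoretically possible products, per type.

    Theoretical counts sum the closed forms over the identification length
    window.  Supported keys: non_spliced, cis (forward + reverse), trans,
    cis_forward, cis_reverse.
    """
    lo, hi = length_window
    lengths = range(lo, hi + 1)
    theoretical = {
        "non_spliced": sum(count_nonspliced(substrate_length, n) for n in lengths),
        "cis_forward": sum(
            count_forward_cis(substrate_length, n, l_ext) for n in lengths
        ),
        "cis_reverse": sum(
            count_reverse_cis(substrate_length, n, l_ext) for n in lengths
        ),
        "trans": sum(count_trans(substrate_length, n, l_ext) for n in lengths),
    }
    theoretical["cis"] = theoretical["cis_forward"] + theoretical["cis_reverse"]
    out = {}
    for key, identified in identified_counts.items():
        if key not in theoretical:
            raise ValueError(f"unknown product type {key!r}")
        total = theoretical[key]
        if total == 0:
            raise ValueError(f"theoretical count for {key!r} is zero")
        if identified > total:
            raise ValueError(
                f"identified {key} count {identified} exceeds the theoretical "
                f"space {total}"
            )
        out[key] = identified / total
    return out
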