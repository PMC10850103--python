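"""Sequence-preference analytics: SCS/PSP windows, background sampling,
divergence-logo mathematics, coverage, hotspots and generation efficacy."""

import numpy as np
import pandas as pd
import pytest

from splicescope import product_analysis as pa
from splicescope.splice_space import (
    ProductType,
    SpaceParams,
    Substrate,
    count_forward_cis,
    count_nonspliced,
    count_reverse_cis,
    count_trans,
    map_peptide,
)
from splicescope.synthetic_data import simulate_substrate


def _pairs(substrate, specs):
    out = []
    for pep, intensity in specs:
        product = map_peptide(pep, substrate)
        assert product is not None
        out.append((product, float(intensity)))
    return out


def test_scs_window_normalization(toy_substrate):
    sub = simulate_substrate(80, seed=0)  # all 7-mers unique at this seed
    # a uniform raw profile: residues 7..80 are each P1 of exactly one
    # 7-mer of weight 1 -> fully-covered interior windows give 100/29
    pairs = []
    for j in range(7, sub.length + 1):
        product = map_peptide(sub.sequence[j - 7 : j], sub)
        assert product is not None and product.n_origins == 1
        pairs.append((product, 1.0))
    scs, psp = pa.compute_scs_psp(pairs, sub)
    interior = scs.values[20:66]
    assert np.allclose(interior, 100.0 / 29.0)
    assert np.all((scs.values >= 0) & (scs.values <= 100))
    assert np.allclose(psp.values, 0.0)


def test_scs_single_site_and_all_zero(toy_substrate):
    pairs = _pairs(toy_substrate, [("ACDEF", 50.0)])
    scs, _ = pa.compute_scs_psp(pairs, toy_substrate)
    assert scs.values[4] == pytest.approx(100.0)  # P1 at residue 5
    assert scs.values.sum() == pytest.approx(100.0)
    scs, psp = pa.compute_scs_psp([], toy_substrate)
    assert not scs.values.any() and not psp.values.any()
    with pytest.raises(ValueError):
        pa.compute_scs_psp(pairs, toy_substrate, window=4)


def test_scs_multi_mapper_intensity_is_split():
    sub = Substrate("s", "ACWACW")
    product = map_peptide("ACW", sub)
    assert product.n_origins == 2
    scs, _ = pa.compute_scs_psp([(product, 60.0)], sub, window=1)
    # raw shares 30/30 at residues 3 and 6; window=1 -> 100% each
    assert scs.values[2] == pytest.approx(100.0)
    assert scs.values[5] == pytest.approx(100.0)


def exhaustive_valid_tuples(L, window, l_ext=1):
    """Oracle: all coordinate tuples forming valid spliced peptides."""
    out = []
    for i in range(1, L + 1):
        for j in range(i, L + 1):
            for k in range(1, L + 1):
                for n in range(k, L + 1):
                    len1, len2 = j - i + 1, n - k + 1
                    if len1 < l_ext or len2 < l_ext:
                        continue
                    if not (window[0] <= len1 + len2 <= window[1]):
                        continue
                    if k == j + 1:
                        continue
                    out.append((i, j, k, n))
    return out


def test_background_sampler_validity_and_determinism():
    rng = np.random.default_rng(0)
    tuples = pa.sample_spliced_tuples(8, 2000, rng, length_window=(7, 16))
    valid = set(exhaustive_valid_tuples(8, (7, 16)))
    assert set(tuples) <= valid
    rng2 = np.random.default_rng(0)
    assert tuples == pa.sample_spliced_tuples(8, 2000, rng2, length_window=(7, 16))
    with pytest.raises(ValueError):
        pa.sample_spliced_tuples(3, 10, rng, length_window=(7, 16),
                                 max_batches=3)


def test_background_database_size_and_remapping():
    sub = simulate_substrate(60, seed=2)
    identified = ["ACDEFGH"] * 4  # size only depends on the count
    db = pa.simulate_background_qualitative(sub, identified, factor=50, seed=9)
    assert len(db.products) == 200
    assert db.size_factor == 50.0
    for product, (i, j, k, n) in zip(db.products, db.tuples):
        assert product.sequence == sub.sequence[i - 1 : j] + sub.sequence[k - 1 : n]
    again = pa.simulate_background_qualitative(sub, identified, factor=50, seed=9)
    assert [p.sequence for p in again.products] == [p.sequence for p in db.products]


def test_quantitative_background_ranges():
    sub = simulate_substrate(60, seed=2)
    db = pa.simulate_background_qualitative(sub, ["AAAA"] * 3, factor=50, seed=1)
    observed = pd.DataFrame(
        {"type": ["spliced", "spliced", "non_spliced"],
         "intensity": [100.0, 300.0, 50.0]}
    )
    out = pa.simulate_background_quantitative(db, observed, seed=4,
                                              grouping="coarse")
    spliced_mask = np.array([p.is_spliced for p in out.products])
    assert out.intensities[spliced_mask].min() >= 100.0
    assert out.intensities[spliced_mask].max() <= 300.0
    degenerate = pd.DataFrame(
        {"type": ["spliced", "non_spliced"], "intensity": [42.0, 42.0]}
    )
    out = pa.simulate_background_quantitative(db, degenerate, seed=4,
                                              grouping="coarse")
    assert np.allclose(out.intensities, 42.0)
    with pytest.raises(ValueError):
        pa.simulate_background_quantitative(
            db, pd.DataFrame({"type": ["cis"], "intensity": [1.0]})
        )


def _random_pwm(rng, columns=pa.SYMMETRIC_COLUMNS):
    m = rng.uniform(0.01, 1.0, size=(20, len(columns)))
    m /= m.sum(axis=0)
    return pd.DataFrame(m, index=list(pa.AA_ALPHABET), columns=list(columns))


def test_logo_zero_when_distributions_equal(rng):
    P = _random_pwm(rng)
    logo = pa.quantitative_logo(P, P.copy())
    assert not logo.heights.to_numpy().any()
    assert not logo.letter_heights.to_numpy().any()


def test_logo_disjoint_point_masses_give_one_bit(rng):
    P = _random_pwm(rng)
    Q = P.copy()
    col = P.columns[0]
    P[col] = 0.0
    P.loc["A", col] = 1.0
    Q[col] = 0.0
    Q.loc["C", col] = 1.0
    logo = pa.quantitative_logo(P, Q)
    assert logo.heights[col] == pytest.approx(1.0)
    assert logo.letter_heights.loc["A", col] == pytest.approx(0.5)
    assert logo.letter_heights.loc["C", col] == pytest.approx(-0.5)


def test_logo_properties_random_pwms(rng):
    for _ in range(50):
        P, Q = _random_pwm(rng), _random_pwm(rng)
        logo = pa.quantitative_logo(P, Q)
        back = pa.quantitative_logo(Q, P)
        h = logo.heights.to_numpy()
        assert np.all((h >= 0) & (h <= 1))
        assert np.allclose(h, back.heights.to_numpy())
        # sum of |letter shares| is 1 wherever the columns differ
        share = np.abs(logo.letter_heights.to_numpy()).sum(axis=0)
        nz = h > 0
        assert np.allclose(share[nz], h[nz])
    with pytest.raises(ValueError):
        pa.quantitative_logo(P, Q.iloc[:, :5])


def test_bayes_identity_uniform_hotspot_likelihood(rng):
    P_r = _random_pwm(rng, pa.HOTSPOT_COLUMNS)
    half = pd.DataFrame(0.5, index=P_r.index, columns=P_r.columns)
    out = pa.bayes_conditional(half, P_r, 0.5)
    assert np.allclose(out.to_numpy(), P_r.to_numpy())


def test_coverage_profile_spike_and_degenerate(toy_substrate):
    sub = simulate_substrate(120, seed=8)
    specs = []
    for start in range(1, 100, 7):
        pep = sub.sequence[start - 1 : start + 8]
        product = map_peptide(pep, sub)
        if product is not None:
            specs.append((product, 1e5))
    # one dominant product makes a spike near its span
    spike = map_peptide(sub.sequence[49:58], sub)
    specs.append((spike, 1e12))
    profile = pa.coverage_profile(specs, sub)
    assert profile.smoothed.min() == 0.0
    assert profile.smoothed.max() == 1.0
    assert 45 <= int(np.argmax(profile.smoothed)) <= 62
    with pytest.raises(ValueError):
        pa.coverage_profile([(spike, 1e5)], Substrate("one", "A"))


def test_hotspot_split_median_and_ties():
    coverage = np.linspace(0, 1, 100)
    detected = list(range(1, 101))
    part = pa.hotspot_split(coverage, detected)
    assert len(part.hotspot_p1) == 50
    assert part.threshold == pytest.approx(
        min(coverage[np.asarray(part.hotspot_p1) - 1])
    )
    assert part.p_hotspot == pytest.approx(0.5)
    # odd count: extra residue goes to the hotspot side
    part = pa.hotspot_split(coverage, detected[:101][: 99])
    assert len(part.hotspot_p1) == 50
    with pytest.raises(ValueError):
        pa.hotspot_split(np.full(10, 0.5), [1, 2, 3])
    with pytest.raises(ValueError):
        pa.hotspot_split(coverage, [5])


def test_hotspot_conditional_matrices_and_randomization():
    sub = simulate_substrate(80, seed=3)
    coverage = np.random.default_rng(3).uniform(0, 1, 80)
    detected = list(range(5, 76, 2))
    part = pa.hotspot_split(coverage, detected)
    motifs = pa.hotspot_conditional_pwm(part, detected, sub, coverage,
                                        n_randomizations=10, seed=4)
    for mat in (motifs.p_r, motifs.p_r_given_h, motifs.p_r_given_nh):
        sums = mat.sum(axis=0).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)
    again = pa.hotspot_conditional_pwm(part, detected, sub, coverage,
                                       n_randomizations=10, seed=4)
    assert np.allclose(
        motifs.p_r_given_h_rnd.to_numpy(), again.p_r_given_h_rnd.to_numpy()
    )
    assert set(motifs.logos) == {
        "hotspot_vs_random", "non_hotspot_vs_random", "hotspot_vs_non_hotspot"
    }


def test_p1_density_rules():
    part = pa.HotspotPartition(
        detected_p1=(1, 2, 3, 4),
        hotspot_p1=(1, 2),
        threshold=0.5,
        hotspot_stretch=tuple(range(1, 11)),
        non_hotspot_stretch=tuple(range(11, 21)),
    )
    dens = pa.p1_density(part, p1_hydrolysis=list(range(1, 9)),
                         p1_splicing=[15])
    assert dens[("hydrolysis", "hotspot")] == pytest.approx(0.8)
    assert dens[("splicing", "hotspot")] == 0.0
    assert dens[("splicing", "non_hotspot")] == pytest.approx(0.1)
    assert all(0 <= v <= 1 for v in dens.values())


def test_generation_efficacy_against_counts():
    L = 40
    window = (7, 9)
    expected_cis = sum(
        count_forward_cis(L, n) + count_reverse_cis(L, n) for n in range(7, 10)
    )
    out = pa.generation_efficacy(
        {"non_spliced": 2, "cis": expected_cis // 4, "trans": 5},
        L, length_window=window,
    )
    assert out["non_spliced"] == pytest.approx(
        2 / sum(count_nonspliced(L, n) for n in range(7, 10))
    )
    assert out["cis"] == pytest.approx((expected_cis // 4) / expected_cis)
    assert out["trans"] == pytest.approx(
        5 / sum(count_trans(L, n) for n in range(7, 10))
    )
    with pytest.raises(ValueError):
        pa.generation_efficacy({"cis": 10**9}, L, length_window=window)
    with pytest.raises(ValueError):
        pa.generation_efficacy({"non_spliced": 1}, 5, length_window=(7, 9))
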