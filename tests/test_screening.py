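"""Matching, binding-potential / fit-value scoring, and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbmscreen.mbm import MBM, build_mbm
from mbmscreen.pharmacophore import Pharmacophore, PharmacophoreFeature
from mbmscreen.screening import (
    KdObservation,
    ScoringParams,
    UnidentifiableError,
    binding_potential,
    calibrate,
    fit_value,
    match,
    report_to_dataframe,
    screen,
    screen_fit_values,
)
from mbmscreen.synthetic import (
    FixtureSpec,
    default_planted_features,
    make_kd_observations,
    make_pharmacophore_set,
    template_ligand_pose,
)

from conftest import brute_force_assignment

PAPER_PARAMS = ScoringParams()


def mbm_of(features, min_support=1):
    pose = template_ligand_pose()
    return MBM(list(features), [1] * len(features), 1, pose, min_support)


def pharm_of(features):
    return Pharmacophore(list(features), template_ligand_pose(), "file", "cand")


# ---------------------------------------------------------------------- match

def test_match_identical_is_perfect():
    feats = default_planted_features()
    extra = PharmacophoreFeature("hydrophobe", (3.0, 3.0, 3.0))
    m = match(pharm_of(feats + [extra]), mbm_of(feats + [extra]))
    assert m.n == 5
    assert m.rmsd == pytest.approx(0.0, abs=1e-9)
    assert m.unmatched_candidate == () and m.unmatched_mbm == ()


def test_match_disjoint_kinds_is_zero():
    cand = pharm_of([PharmacophoreFeature("hydrophobe", (0.0, 0.0, 0.0))])
    ref = mbm_of([PharmacophoreFeature("cation", (0.0, 0.0, 0.0))])
    m = match(cand, ref)
    assert m.n == 0 and m.rmsd == 0.0


def test_match_rmsd_modes_on_three_pairs():
    """Displacements (0, 0, 1): rms = 1/sqrt(3) = 0.5774, mean = 1/3."""
    ref_feats = [PharmacophoreFeature("cation", (0.0, 0.0, 0.0)),
                 PharmacophoreFeature("cation", (5.0, 0.0, 0.0)),
                 PharmacophoreFeature("cation", (10.0, 0.0, 0.0))]
    cand_feats = [PharmacophoreFeature("cation", (0.0, 0.0, 0.0)),
                  PharmacophoreFeature("cation", (5.0, 0.0, 0.0)),
                  PharmacophoreFeature("cation", (10.0, 1.0, 0.0))]
    m = match(pharm_of(cand_feats), mbm_of(ref_feats))
    assert m.n == 3
    assert m.rmsd == pytest.approx(0.57735, abs=1e-4)
    m2 = match(pharm_of(cand_feats), mbm_of(ref_feats), rmsd_mode="mean")
    assert m2.rmsd == pytest.approx(1.0 / 3.0, abs=1e-9)


def test_match_equals_brute_force_oracle():
    """On >= 200 random instances with <= 6 features per side, the assignment
    equals exhaustive enumeration (maximal n, then minimal total distance)."""
    rng = np.random.default_rng(123)
    kinds = ("cation", "aromatic_ring", "hydrophobe", "hbond_acceptor")
    for trial in range(200):
        nc, nm = rng.integers(1, 7), rng.integers(1, 7)
        cf = [PharmacophoreFeature(kinds[rng.integers(len(kinds))],
                                   rng.uniform(-4, 4, 3)) for _ in range(nc)]
        mf = [PharmacophoreFeature(kinds[rng.integers(len(kinds))],
                                   rng.uniform(-4, 4, 3)) for _ in range(nm)]
        cutoff = float(rng.uniform(1.0, 4.0))
        got = match(pharm_of(cf), mbm_of(mf), pair_cutoff=cutoff, align=False)
        n_exp, d_exp = brute_force_assignment(cf, mf, cutoff)
        assert got.n == n_exp, f"trial {trial}"
        assert got.total_distance == pytest.approx(d_exp, abs=1e-9)


def test_match_pairs_are_type_compatible_and_within_cutoff():
    rng = np.random.default_rng(7)
    kinds = ("cation", "aromatic_ring", "hydrophobe")
    cf = [PharmacophoreFeature(kinds[rng.integers(3)], rng.uniform(-3, 3, 3))
          for _ in range(5)]
    mf = [PharmacophoreFeature(kinds[rng.integers(3)], rng.uniform(-3, 3, 3))
          for _ in range(5)]
    m = match(pharm_of(cf), mbm_of(mf), pair_cutoff=2.0, align=False)
    for i, j in m.pairs:
        assert cf[i].kind == mf[j].kind
        assert np.linalg.norm(cf[i].position - mf[j].position) <= 2.0


# -------------------------------------------------------------------- scoring

@pytest.mark.parametrize("n,rmsd,expected", [
    (1, 1.0, 1.0),
    (2, 1.0, 2 ** 2.599),
    (3, 2.0, 3 ** 2.599 * 2 ** -5.234),
])
def test_binding_potential_values(n, rmsd, expected):
    assert binding_potential(n, rmsd, PAPER_PARAMS) == pytest.approx(expected, rel=1e-12)


def test_binding_potential_conventions():
    assert binding_potential(0, 1.0, PAPER_PARAMS) == 0.0
    # rmsd clamped at the floor: a perfect match stays finite and top-ranked
    assert binding_potential(3, 0.0) == binding_potential(3, 0.1)
    with pytest.raises(ValueError):
        binding_potential(-1, 1.0)


def test_fit_value_anchor_and_closed_forms():
    p = PAPER_PARAMS
    assert fit_value(p.bp0, p) == pytest.approx(0.5, abs=1e-15)
    assert fit_value(3 * p.bp0, p) == pytest.approx(0.75, abs=1e-12)
    assert fit_value(0.0, p) == 0.0
    b10 = ScoringParams(log_convention="base10")
    assert fit_value(b10.bp0, b10) == pytest.approx(0.5, abs=1e-15)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(bp1=st.floats(1e-6, 1e6), bp2=st.floats(1e-6, 1e6),
       bp0=st.floats(1e-3, 1e3), conv=st.sampled_from(["natural", "base10"]))
def test_fit_value_monotone_and_bounded(bp1, bp2, bp0, conv):
    p = ScoringParams(bp0=bp0, log_convention=conv)
    f1, f2 = fit_value(bp1, p), fit_value(bp2, p)
    assert 0.0 <= f1 < 1.0
    if bp1 < bp2:
        assert f1 < f2


def test_screen_orders_by_fit_and_flags_threshold():
    """BP = 2·BP0 gives fit 2/3 (HPT), BP = BP0/2 gives 1/3 (not)."""
    p = PAPER_PARAMS
    recs = screen_fit_values([("strong", 2 / 3), ("weak", 1 / 3)], p)
    assert [r.target_id for r in recs] == ["strong", "weak"]
    assert [r.is_hpt for r in recs] == [True, False]
    assert recs[0].bp == pytest.approx(2 * p.bp0, rel=1e-9)
    assert recs[1].bp == pytest.approx(p.bp0 / 2, rel=1e-9)


def test_screen_end_to_end_on_synthetic_set():
    phs, _ = make_pharmacophore_set(
        FixtureSpec(seed=5, n_targets=6, jitter_sigma=0.3, decoys_per_target=2))
    mbm = build_mbm(phs)
    records = screen([(p.source_id, p) for p in phs], mbm)
    assert len(records) == 6
    fits = [r.fit_value for r in records]
    assert fits == sorted(fits, reverse=True)
    bps = [r.bp for r in records]
    assert bps == sorted(bps, reverse=True)  # fit ordering == bp ordering
    for r in records:
        assert r.is_hpt == (r.fit_value >= 0.5)
        assert r.bp == pytest.approx(
            binding_potential(r.n, r.rmsd, PAPER_PARAMS), rel=1e-12)
    df = report_to_dataframe(records)
    assert list(df.columns) == ["target_id", "structure", "n", "rmsd", "bp",
                                "fit_value", "is_hpt"]


def test_screen_zero_match_candidate_not_hpt():
    cand = pharm_of([PharmacophoreFeature("anion", (50.0, 0.0, 0.0))])
    mbm = mbm_of(default_planted_features())
    (rec,) = screen([("null", cand)], mbm)
    assert rec.n == 0 and rec.fit_value == 0.0 and not rec.is_hpt


def test_screen_empty_candidates_gives_empty_report():
    assert screen([], mbm_of(default_planted_features())) == []


# ---------------------------------------------------------------- calibration

def test_calibrate_recovers_exactly_from_noiseless_data():
    obs, skipped = make_kd_observations(FixtureSpec(seed=3, n_observations=30))
    assert skipped == 0
    res = calibrate(obs)
    assert res.alpha == pytest.approx(2.599, abs=1e-8)
    assert res.beta == pytest.approx(-5.234, abs=1e-8)
    assert res.kappa == pytest.approx(-5.905, abs=1e-8)
    assert res.rss == pytest.approx(0.0, abs=1e-12)


def test_calibrate_recovers_under_seeded_noise():
    obs, _ = make_kd_observations(
        FixtureSpec(seed=11, n_observations=50, noise_sigma=0.05))
    res = calibrate(obs)
    assert res.alpha == pytest.approx(2.599, abs=0.1)
    assert res.beta == pytest.approx(-5.234, abs=0.1)
    assert res.kappa == pytest.approx(-5.905, abs=0.1)
    assert res.stderr is not None and all(s > 0 for s in res.stderr)
    assert "alpha" in res.summary()


def test_calibrate_underdetermined_and_degenerate():
    o = KdObservation("a", 4, 0.1, 1.0)
    with pytest.raises(UnidentifiableError):
        calibrate([o, o])
    same = [KdObservation(f"t{i}", 4, 0.1, 1.0 + 0.1 * i) for i in range(5)]
    with pytest.raises(UnidentifiableError):
        calibrate(same)


def test_end_to_end_parameter_recovery():
    """Planted motif → jittered candidates → match → self-consistent K_D →
    calibrate recovers the planted exponents."""
    phs, _ = make_pharmacophore_set(
        FixtureSpec(seed=8, n_targets=6, jitter_sigma=0.1, decoys_per_target=2))
    mbm = build_mbm(phs)
    p = PAPER_PARAMS
    obs = []
    for k, ph in enumerate(phs):
        m = match(ph, mbm)
        rmsd = max(m.rmsd, 0.05)
        bp = m.n ** p.alpha * rmsd ** p.beta
        resp = np.log10(bp) + p.kappa
        if resp > 0:
            obs.append(KdObservation(f"t{k}", m.n, rmsd, 1.0 / resp))
    # add spread in n so the design has full rank
    extra, _ = make_kd_observations(FixtureSpec(seed=4, n_observations=20))
    res = calibrate(obs + extra)
    assert res.alpha == pytest.approx(p.alpha, abs=1e-6)
    assert res.beta == pytest.approx(p.beta, abs=1e-6)
    assert res.kappa == pytest.approx(p.kappa, abs=1e-6)
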