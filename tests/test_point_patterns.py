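"""Estimator correctness: pcf, D, torus shift, null ensembles, SES."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

import spatrait as st
from spatrait.point_patterns import _batch_statistics
from conftest import random_pattern
from oracles import brute_pcf, brute_nn_fraction, torus_distance_multiset


# ---------------------------------------------------------------------------
# pcf and D against literal brute-force evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("r", [5.0, 12.0, 30.0])
def test_pcf_matches_brute_force_double_loop(seed, r, window):
    rng = np.random.default_rng(seed)
    pi = random_pattern(rng, window, int(rng.integers(5, 50)))
    pj = random_pattern(rng, window, int(rng.integers(5, 50)))
    bw = st.default_bandwidth(pj.intensity, r)
    fast = st.estimate_bivariate_pcf(pi, pj, r, bandwidth=bw)
    slow = brute_pcf(pi.points, pj.points, window, r, bw)
    assert fast.value == pytest.approx(slow, rel=1e-10, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("r", [5.0, 30.0])
def test_nn_distribution_matches_brute_force(seed, r, window):
    rng = np.random.default_rng(seed + 100)
    pi = random_pattern(rng, window, int(rng.integers(3, 50)))
    pj = random_pattern(rng, window, int(rng.integers(3, 50)))
    fast = st.estimate_nn_distribution(pi, pj, r)
    assert fast.value == brute_nn_fraction(pi.points, pj.points, r)


def test_nn_distribution_toy_examples():
    w = st.Window(0, 1000, 0, 500)
    pi = st.PointPattern([(0, 0), (10, 0)], w)
    pj = st.PointPattern([(1, 0), (50, 0)], w)
    # NN distances are 1 and 40
    assert st.estimate_nn_distribution(pi, pj, 5).value == 0.5
    assert st.estimate_nn_distribution(pi, pj, 45).value == 1.0
    # empirical CDF is monotone in r
    assert (
        st.estimate_nn_distribution(pi, pj, 30).value
        >= st.estimate_nn_distribution(pi, pj, 5).value
    )


def test_pcf_near_one_for_independent_poisson_pairs():
    """Monte-Carlo: cross-pcf of independent CSR patterns averages to ~1."""
    w = st.Window(0, 300, 0, 300)
    rng = np.random.default_rng(11)
    vals = []
    for _ in range(100):
        pi = st.simulate_poisson_pattern(0.01, w, rng)
        pj = st.simulate_poisson_pattern(0.01, w, rng)
        vals.append(st.estimate_bivariate_pcf(pi, pj, 10.0).value)
    assert abs(np.mean(vals) - 1.0) < 0.05


def test_pcf_is_order_free(window, rng):
    pi = random_pattern(rng, window, 30)
    pj = random_pattern(rng, window, 25)
    perm = rng.permutation(pj.n)
    pj_perm = st.PointPattern(pj.points[perm], window)
    a = st.estimate_bivariate_pcf(pi, pj, 10.0).value
    b = st.estimate_bivariate_pcf(pi, pj_perm, 10.0).value
    assert a == pytest.approx(b, rel=1e-12)


def test_estimator_errors(window, rng):
    pi = random_pattern(rng, window, 10)
    empty = st.PointPattern(np.empty((0, 2)), window)
    other_window = st.Window(0, 100, 0, 100)
    with pytest.raises(ValueError):
        st.estimate_bivariate_pcf(pi, empty, 10.0)
    with pytest.raises(ValueError):
        st.estimate_bivariate_pcf(pi, pi, 80.0)  # r > half the short side
    with pytest.raises(ValueError):
        st.estimate_nn_distribution(pi, empty, 10.0)
    pk = random_pattern(rng, other_window, 10)
    with pytest.raises(ValueError):
        st.estimate_bivariate_pcf(pi, pk, 10.0)


# ---------------------------------------------------------------------------
# toroidal shift
# ---------------------------------------------------------------------------


def test_toroidal_shift_wraps_modularly():
    w = st.Window(0, 1000, 0, 500)
    p = st.PointPattern([(999.0, 499.0)], w)
    shifted = st.toroidal_shift(p, 5.0, 5.0)
    assert shifted.points[0] == pytest.approx((4.0, 4.0))


def test_toroidal_shift_zero_is_identity(window, rng):
    p = random_pattern(rng, window, 20)
    assert np.allclose(st.toroidal_shift(p, 0.0, 0.0).points, p.points)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    dx=st_.floats(-2000, 2000, allow_nan=False),
    dy=st_.floats(-2000, 2000, allow_nan=False),
    seed=st_.integers(0, 1000),
)
def test_toroidal_shift_is_torus_isometry(dx, dy, seed):
    """Point count and the toroidal pairwise-distance multiset are preserved."""
    w = st.Window(0, 120, 0, 80)
    rng = np.random.default_rng(seed)
    p = random_pattern(rng, w, 12)
    q = st.toroidal_shift(p, dx, dy)
    assert q.n == p.n
    assert q.window == w
    assert np.allclose(
        torus_distance_multiset(p.points, w),
        torus_distance_multiset(q.points, w),
        atol=1e-8,
    )


# ---------------------------------------------------------------------------
# null ensemble and SES
# ---------------------------------------------------------------------------


def test_null_ensemble_length_and_determinism(window, rng):
    pi = random_pattern(rng, window, 30)
    pj = random_pattern(rng, window, 30)
    e1 = st.null_ensemble(pi, pj, "pcf", 10.0, n_sim=99, seed=5)
    e2 = st.null_ensemble(pi, pj, "pcf", 10.0, n_sim=99, seed=5)
    assert e1.n_sim == 99
    assert np.array_equal(e1.values, e2.values)
    with pytest.raises(ValueError):
        st.null_ensemble(pi, pj, "pcf", 10.0, n_sim=1, seed=5)


def test_observed_rank_uniform_under_null():
    """The observed statistic of an independent pair is exchangeable with its
    null replicates, so its rank should be uniform."""
    from scipy.stats import kstest

    w = st.Window(0, 100, 0, 100)
    rng = np.random.default_rng(99)
    n_sim = 49
    ranks = []
    for _ in range(120):
        pi = st.simulate_poisson_pattern(0.005, w, rng)
        pj = st.simulate_poisson_pattern(0.005, w, rng)
        if pi.n < 3 or pj.n < 3:
            continue
        obs = st.estimate_bivariate_pcf(pi, pj, 10.0).value
        ens = st.null_ensemble(pi, pj, "pcf", 10.0, n_sim=n_sim, seed=rng)
        ranks.append((ens.values < obs).mean() + 0.5 * (ens.values == obs).mean())
    assert kstest(ranks, "uniform").pvalue > 0.001


def test_ses_hand_arithmetic(window, rng):
    ens = st.NullEnsemble("pcf", 10.0, [1.0, 2.0, 3.0])
    obs = st.SummaryStatistic("pcf", 10.0, 4.0)
    assert st.ses(obs, ens) == pytest.approx(2.0)  # sample sd of {1,2,3} is 1
    assert st.ses(st.SummaryStatistic("pcf", 10.0, 2.0), ens) == 0.0
    mu, sd = ens.mean, ens.sd
    z196 = st.ses(st.SummaryStatistic("pcf", 10.0, mu + 1.96 * sd), ens)
    assert z196 == pytest.approx(1.96)
    with pytest.raises(ValueError):
        st.ses(st.SummaryStatistic("D", 10.0, 1.0), ens)


def test_ses_degenerate_null():
    ens = st.NullEnsemble("D", 5.0, [0.4, 0.4, 0.4])
    assert ens.degenerate
    assert st.ses(st.SummaryStatistic("D", 5.0, 0.4), ens) == 0.0
    assert st.ses(st.SummaryStatistic("D", 5.0, 0.9), ens) == np.inf
    assert st.ses(st.SummaryStatistic("D", 5.0, 0.1), ens) == -np.inf


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    a=st_.floats(0.01, 50, allow_nan=False),
    b=st_.floats(-100, 100, allow_nan=False),
)
def test_ses_invariant_to_shared_affine_rescaling(a, b):
    rng = np.random.default_rng(3)
    vals = rng.normal(2.0, 0.5, 99)
    s0 = 2.7
    z1 = st.ses(st.SummaryStatistic("pcf", 5.0, s0), st.NullEnsemble("pcf", 5.0, vals))
    z2 = st.ses(
        st.SummaryStatistic("pcf", 5.0, a * s0 + b),
        st.NullEnsemble("pcf", 5.0, a * vals + b),
    )
    assert z1 == pytest.approx(z2, rel=1e-6, abs=1e-9)


def test_classification_thresholds():
    assert st.classify_association(2.5) == "attraction"
    assert st.classify_association(-2.0) == "repulsion"
    # strict inequalities: the critical value itself is independence
    zc = 1.959963984540054
    assert st.classify_association(zc) == "independence"
    assert st.classify_association(-zc) == "independence"
    assert st.classify_association(0.0) == "independence"
    assert st.classify_association(np.inf) == "attraction"
    assert st.classify_association(3.0, alpha=0.001) == "independence"
    with pytest.raises(ValueError):
        st.classify_association(1.0, alpha=0.0)


# ---------------------------------------------------------------------------
# whole-community ordered-pair analysis
# ---------------------------------------------------------------------------


def test_pairwise_analysis_record_counts_and_determinism(window, rng):
    rows = []
    for k, sp in enumerate("ABCD"):
        pat = random_pattern(rng, window, 20)
        for x, y in pat.points:
            rows.append((sp, x, y, 2.0))
    census = pd.DataFrame(rows, columns=["species_id", "x", "y", "dbh"])
    recs = st.pairwise_association_analysis(
        census, window, radii=(5.0, 30.0), statistics=("pcf", "D"), n_sim=19, seed=1
    )
    # 4 species -> 12 ordered pairs, x 2 statistics x 2 radii
    assert len(recs) == 12 * 2 * 2
    frame = st.associations_to_frame(recs)
    assert set(frame["class"]).issubset({"attraction", "repulsion", "independence"})
    recs2 = st.pairwise_association_analysis(
        census, window, radii=(5.0, 30.0), statistics=("pcf", "D"), n_sim=19, seed=1
    )
    assert st.associations_to_frame(recs2).equals(frame)


def test_pairwise_analysis_single_species_returns_empty(window, rng):
    pat = random_pattern(rng, window, 15)
    census = pd.DataFrame(
        {"species_id": "A", "x": pat.points[:, 0], "y": pat.points[:, 1], "dbh": 2.0}
    )
    assert st.pairwise_association_analysis(census, window, n_sim=9, seed=0) == []


def test_batched_statistics_agree_with_single_estimators(window, rng):
    """The vectorised whole-community path equals the one-pair estimators."""
    pi = random_pattern(rng, window, 25)
    pj = random_pattern(rng, window, 35)
    out = _batch_statistics(
        pi.points, pj.points, window, [5.0, 30.0], ("pcf", "D"), np.zeros((1, 2))
    )
    for r in (5.0, 30.0):
        assert out[("pcf", r)][0] == pytest.approx(
            st.estimate_bivariate_pcf(pi, pj, r).value, rel=1e-10
        )
        assert out[("D", r)][0] == pytest.approx(
            st.estimate_nn_distribution(pi, pj, r).value
        )
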