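"""Voxel-wise pooled-variance t, t->Z conversion, and permutation threshold."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf

from lesionmap import (
    Cohort,
    SyntheticConfig,
    VlsmParams,
    eligible_voxels,
    generate_cohort,
    pooled_t,
    run_vlsm,
    t_to_z,
)
from lesionmap.vlsm import Z_CAP

from conftest import make_cohort


# --- independent oracles -------------------------------------------------

def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, written independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def t_pdf(x, df):
    c = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(df * math.pi)
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def z_oracle(t, df):
    """Quadrature of the t density + inversion of the erf-based normal CDF."""
    if t <= 0:
        p, _ = quad(t_pdf, -np.inf, t, args=(df,), epsabs=1e-14, epsrel=1e-13)
        return brentq(lambda z: 0.5 * (1 + erf(z / math.sqrt(2))) - p, -12, 12, xtol=1e-13)
    return -z_oracle(-t, df)


# --- pooled t -------------------------------------------------------------

def test_pooled_t_matches_textbook_formula_and_scipy():
    a = np.array([0.0, 100.0 / 6.0, 200.0 / 6.0])
    b = np.array([500.0 / 6.0, 100.0, 100.0, 400.0 / 6.0])
    t = pooled_t(a, b)
    assert t == pytest.approx(pooled_t_oracle(a, b), abs=1e-12)
    assert t == pytest.approx(stats.ttest_ind(a, b, equal_var=True).statistic, abs=1e-12)
    assert t < 0  # lesion group scores lower -> negative t


def test_pooled_t_antisymmetric_and_zero_for_equal_means():
    a, b = [50.0, 50.0], [50.0, 50.0]
    assert pooled_t(a, b) == 0.0
    a, b = [0.0, 50.0, 100.0], [50.0, 100.0]
    assert pooled_t(a, b) == pytest.approx(-pooled_t(b, a), abs=1e-12)


def test_pooled_t_degenerate_variance_unequal_means_is_infinite_sentinel():
    assert pooled_t([0.0, 0.0], [100.0, 100.0]) == -np.inf
    assert pooled_t([100.0, 100.0], [0.0, 0.0]) == np.inf


def test_pooled_t_requires_two_per_group():
    with pytest.raises(ValueError):
        pooled_t([50.0], [0.0, 100.0])


# --- t -> Z ---------------------------------------------------------------

def test_t_to_z_fixed_points_and_large_df_limit():
    assert t_to_z(0.0, 5) == 0.0
    assert t_to_z(1.5, 10000) == pytest.approx(1.5, abs=1e-3)


@pytest.mark.parametrize("t,df", [(-2.5, 10), (1.7, 4), (-0.3, 57), (3.2, 25), (-6.0, 8)])
def test_t_to_z_matches_quadrature_oracle(t, df):
    assert t_to_z(t, df) == pytest.approx(z_oracle(t, df), abs=1e-8)


def test_t_to_z_monotone_and_capped():
    df = 7
    ts = np.linspace(-60, 60, 401)
    zs = t_to_z(ts, df)
    assert np.all(np.diff(zs) >= 0)
    assert np.max(np.abs(zs)) <= Z_CAP
    assert t_to_z(np.inf, df) == Z_CAP
    assert t_to_z(-np.inf, df) == -Z_CAP


# --- eligibility ----------------------------------------------------------

def test_eligibility_requires_three_lesions_and_three_spared(small_grid):
    # voxel A: 2 lesions; voxel B: 3 lesions; voxel C: all 10 patients
    spec = []
    for i in range(10):
        voxels = [(0, 0, 0)]
        if i < 2:
            voxels.append((1, 1, 1))
        if i < 3:
            voxels.append((2, 2, 2))
        spec.append((voxels, 50.0, None))
    cohort = make_cohort(small_grid, spec)
    elig = eligible_voxels(cohort, VlsmParams())
    assert not elig[1, 1, 1]  # only 2 tumors
    assert elig[2, 2, 2]      # exactly 3 tumors
    assert not elig[0, 0, 0]  # complement group empty


# --- full pipeline --------------------------------------------------------

def _toy_cohort(seed=0, n=50):
    cfg = SyntheticConfig(grid_shape=(16, 16, 16), n_patients=n, seed=seed)
    return generate_cohort(cfg)[0]


def test_vectorized_t_equals_scalar_oracle_at_random_voxels():
    cohort = _toy_cohort(seed=4)
    params = VlsmParams(n_permutations=10, seed=1)
    res = run_vlsm(cohort, params=params)
    stack = cohort.mask_stack()
    scores = cohort.pre_scores()
    rng = np.random.default_rng(0)
    voxels = np.argwhere(res.eligible)
    for v in voxels[rng.choice(len(voxels), size=min(100, len(voxels)), replace=False)]:
        inside = stack[(slice(None), *v)]
        expected = pooled_t_oracle(scores[inside], scores[~inside])
        assert res.t_map.values[tuple(v)] == pytest.approx(expected, abs=1e-10)


def test_observed_maps_independent_of_seed_and_patient_order():
    cohort = _toy_cohort(seed=5)
    p1 = VlsmParams(n_permutations=50, seed=1)
    p2 = VlsmParams(n_permutations=50, seed=99)
    r1 = run_vlsm(cohort, params=p1)
    r2 = run_vlsm(cohort, params=p2)
    assert np.allclose(r1.z_map.values, r2.z_map.values, equal_nan=True)

    rng = np.random.default_rng(2)
    shuffled = Cohort(cohort.grid, [cohort.patients[i] for i in rng.permutation(len(cohort))])
    r3 = run_vlsm(shuffled, params=p1)
    assert np.allclose(r1.t_map.values, r3.t_map.values, equal_nan=True)
    assert np.array_equal(r1.eligible, r3.eligible)


def test_same_seed_reproduces_threshold_exactly():
    cohort = _toy_cohort(seed=6)
    params = VlsmParams(n_permutations=100, seed=42)
    r1 = run_vlsm(cohort, params=params)
    r2 = run_vlsm(cohort, params=params)
    assert r1.z_threshold == r2.z_threshold
    assert np.array_equal(r1.significant, r2.significant)


def test_significant_subset_of_eligible_and_negative():
    cohort = _toy_cohort(seed=7, n=80)
    res = run_vlsm(cohort, params=VlsmParams(n_permutations=200, seed=3))
    assert not np.any(res.significant & ~res.eligible)
    if res.n_significant_voxels:
        assert np.all(res.z_map.values[res.significant] <= res.z_threshold)
        assert np.all(res.z_map.values[res.significant] < 0)


def test_all_identical_scores_yield_no_significance(small_grid):
    spec = [([(1, 1, 1), (2, 2, 2)], 50.0, None) for _ in range(4)]
    spec += [([(3 + i % 2, 3, 3)], 50.0, None) for i in range(4)]
    cohort = make_cohort(small_grid, spec)
    res = run_vlsm(cohort, params=VlsmParams(n_permutations=50, seed=0))
    assert res.z_threshold == 0.0
    assert res.n_significant_voxels == 0


def test_single_eligible_voxel_threshold_equals_direct_permutation_quantile(small_grid):
    # 4 patients lesioned at one shared voxel, 5 patients elsewhere (each
    # private voxel has count 1, so exactly one voxel is eligible)
    lattice = np.arange(7) * 100.0 / 6.0
    scores = [0.0, 100.0 / 6.0, 50.0, 200.0 / 6.0, 100.0, 500.0 / 6.0, 400.0 / 6.0, 100.0, 50.0]
    spec = [([(2, 2, 2)], scores[i], None) for i in range(4)]
    spec += [([(4, (i % 3) + 1, 4)], scores[4 + i], None) for i in range(5)]
    cohort = make_cohort(small_grid, spec)
    params = VlsmParams(n_permutations=200, seed=11)
    res = run_vlsm(cohort, params=params)
    assert res.n_eligible_voxels == 1

    # direct single-voxel permutation test sharing the same seed stream
    s = np.asarray(scores)
    in_group = np.array([p.mask.voxels[2, 2, 2] for p in cohort.patients])
    rng = np.random.default_rng(params.seed)
    null = []
    for _ in range(params.n_permutations):
        sp = s[rng.permutation(len(s))]
        t = pooled_t(sp[in_group], sp[~in_group])
        null.append(t_to_z(t, len(s) - 2))
    k = math.ceil(params.alpha * params.n_permutations)
    expected = np.sort(null)[k - 1]
    assert res.z_threshold == pytest.approx(expected, abs=1e-12)


def test_no_eligible_voxel_raises_with_guidance(small_grid):
    cohort = make_cohort(small_grid, [([(1, 1, 1)], 50.0, None), ([(2, 2, 2)], 0.0, None)])
    with pytest.raises(ValueError, match="eligible"):
        run_vlsm(cohort, params=VlsmParams(min_lesion_patients=2, min_nonlesion_patients=2,
                                           n_permutations=10, seed=0))


def test_change_analysis_uses_followup_subset():
    cfg = SyntheticConfig(grid_shape=(16, 16, 16), n_patients=60, make_post=True, seed=9)
    cohort, _ = generate_cohort(cfg)
    res = run_vlsm(cohort, which="change", params=VlsmParams(n_permutations=50, seed=1))
    assert res.n_patients == len(cohort.with_post())
    assert res.which == "change"
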