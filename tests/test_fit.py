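"""Fitters: OLS closed form, IRLS fixed points, LMS search, diagnostics."""
import numpy as np
import pytest

from redescend import (
    DegenerateDesignError,
    RegressionData,
    TuningSpec,
    fit_irls,
    fit_lms,
    fit_ols,
    flag_outliers,
    get_family,
    subset_sse,
)
from redescend.families import PsiFamily


# ------------------------------------------------------------------- data

def test_data_validation():
    with pytest.raises(ValueError):
        RegressionData([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        RegressionData([1, 2], [1, 2])
    with pytest.raises(DegenerateDesignError):
        RegressionData([5, 5, 5, 5], [1, 2, 3, 4])


# -------------------------------------------------------------------- OLS

def test_ols_interpolates_exact_line(clean_line):
    f = fit_ols(clean_line)
    assert f.intercept == pytest.approx(3.0, abs=1e-12)
    assert f.slope == pytest.approx(2.0, abs=1e-12)
    assert np.max(np.abs(f.residuals)) < 1e-12


def test_ols_residuals_sum_to_zero(telephone):
    f = fit_ols(telephone)
    assert abs(f.residuals.sum()) < 1e-9
    assert abs((f.residuals * telephone.x).sum()) < 1e-7


def test_ols_telephone_matches_benchmark(telephone):
    f = fit_ols(telephone)
    assert f.intercept == pytest.approx(-26.01, abs=0.005)
    assert f.slope == pytest.approx(0.504, abs=0.0005)
    assert subset_sse(telephone, f, range(24)).sse_all == pytest.approx(695.44, abs=0.01)


def test_ols_china_matches_benchmark(china):
    f = fit_ols(china)
    assert f.slope == pytest.approx(24.85, abs=0.01)
    assert subset_sse(china, f, range(9)).sse_all == pytest.approx(78532.88, rel=1e-4)


# ------------------------------------------------------------------- IRLS

def test_irls_constant_weight_reproduces_ols(telephone):
    """A w ≡ 1 family must leave the OLS solution untouched."""
    const = PsiFamily(
        "const", False, TuningSpec("const", 1.0),
        _psi=lambda r, t: np.asarray(r, float),
        _weight=lambda r, t: np.ones_like(np.asarray(r, float)),
    )
    f = fit_irls(telephone, const, scale="none")
    o = fit_ols(telephone)
    assert f.intercept == pytest.approx(o.intercept, abs=1e-10)
    assert f.slope == pytest.approx(o.slope, abs=1e-10)


def test_irls_huge_k_matches_ols(seeded_sample):
    """With k far above the residual scale all weights are ~1."""
    f = fit_irls(seeded_sample, "proposed", TuningSpec("proposed", 1e6, a=6.0),
                 scale="none")
    o = fit_ols(seeded_sample)
    assert f.intercept == pytest.approx(o.intercept, abs=1e-6)
    assert f.slope == pytest.approx(o.slope, abs=1e-6)
    assert np.all(f.weights > 0.999999)


def test_irls_china_proposed_reproduces_benchmark(china):
    f = fit_irls(china, "proposed", TuningSpec("proposed", 2.0, a=8.0))
    assert f.converged
    assert f.intercept == pytest.approx(-2.6486, rel=0.02)
    assert f.slope == pytest.approx(0.10656, rel=0.02)
    assert subset_sse(china, f, range(7)).sse_retained == pytest.approx(0.611112, rel=0.02)


@pytest.mark.parametrize("family,k,a", [
    ("proposed", 2.0, 8.0), ("tukey", 2.0, None), ("andrew", 0.58, None),
    ("huber", 1.345, None),
])
def test_irls_fixed_point_satisfies_estimating_equations(china, family, k, a):
    """At convergence the weighted normal equations Σw·r = Σw·r·x = 0 hold."""
    t = TuningSpec(family, k, a=a)
    f = fit_irls(china, family, t, tol=1e-12)
    fam = get_family(family)
    s = np.median(np.abs(f.residuals - np.median(f.residuals))) / 0.6745
    w = fam.weight(f.residuals / s, t)
    scale_y = np.abs(china.y).max()
    assert abs((w * f.residuals).sum()) < 1e-6 * w.sum() * scale_y
    assert abs((w * f.residuals * china.x).sum()) < 1e-6 * w.sum() * scale_y * china.x.max()


def test_irls_weights_are_relative_in_unit_interval(telephone):
    # Alamgir's raw psi/r weight peaks at 4; stored weights are w/w(0)
    f = fit_irls(telephone, "alamgir", TuningSpec("alamgir", 3.0))
    assert np.all(f.weights >= 0) and np.all(f.weights <= 1 + 1e-12)


def test_irls_telephone_huber_agrees_with_statsmodels(telephone):
    """Independent oracle: statsmodels RLM with the same Huber ψ."""
    sm = pytest.importorskip("statsmodels.api")
    ours = fit_irls(telephone, "huber", TuningSpec("huber", 1.345), scale="mad")
    X = sm.add_constant(telephone.x)
    rlm = sm.RLM(telephone.y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    assert ours.slope == pytest.approx(rlm.params[1], rel=0.05)
    assert 0.15 < ours.slope < 0.25


def test_irls_nonconvergence_warns_not_raises(china):
    with pytest.warns(UserWarning, match="did not converge"):
        f = fit_irls(china, "proposed", TuningSpec("proposed", 2.0, a=8.0),
                     max_iter=2)
    assert not f.converged


def test_irls_total_rejection_raises():
    # every raw residual enormous relative to k, with hard-rejecting Tukey
    data = RegressionData([0, 1, 2, 3], [0, 1000, -2000, 500])
    from redescend import DegenerateWeightsError
    with pytest.raises(DegenerateWeightsError):
        fit_irls(data, "tukey", TuningSpec("tukey", 1e-6), scale="none",
                 start=(1e9, 0.0))


def test_irls_permutation_invariance(telephone):
    rng = np.random.default_rng(3)
    perm = rng.permutation(telephone.n)
    shuffled = RegressionData(telephone.x[perm], telephone.y[perm])
    t = TuningSpec("proposed", 3.5, a=6.0)
    f1 = fit_irls(telephone, "proposed", t)
    f2 = fit_irls(shuffled, "proposed", t)
    assert abs(f1.intercept - f2.intercept) < 1e-10
    assert abs(f1.slope - f2.slope) < 1e-10


def test_breakdown_single_gross_outlier(seeded_sample):
    """One y += 1e6 barely moves the proposed slope but wrecks OLS."""
    t = TuningSpec("proposed", 2.0, a=6.0)
    base_p = fit_irls(seeded_sample, "proposed", t).slope
    base_o = fit_ols(seeded_sample).slope
    y = seeded_sample.y.copy()
    y[10] += 1e6
    spiked = RegressionData(seeded_sample.x, y)
    assert abs(fit_irls(spiked, "proposed", t).slope - base_p) < 0.01
    assert abs(fit_ols(spiked).slope - base_o) > 1.0


# -------------------------------------------------------------------- LMS

def test_lms_exact_fit_breakdown():
    """13 of 24 points on y = 1 + 0.1x: LMS recovers the line exactly."""
    rng = np.random.default_rng(5)
    x = np.arange(24, dtype=float)
    y = 1.0 + 0.1 * x
    y[13:] = rng.uniform(50, 100, 11)  # 11 arbitrary outliers
    f = fit_lms(RegressionData(x, y))
    assert f.intercept == pytest.approx(1.0, abs=1e-10)
    assert f.slope == pytest.approx(0.1, abs=1e-10)
    assert np.median(f.residuals**2) == pytest.approx(0.0, abs=1e-20)


def test_lms_matches_bruteforce_oracle():
    """Exhaustive elemental-line search is the oracle for small n."""
    from itertools import combinations
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 8)
        y = rng.uniform(0, 10, 8)
        data = RegressionData(x, y)
        best = np.inf
        for i, j in combinations(range(8), 2):
            if x[i] == x[j]:
                continue
            sl = (y[j] - y[i]) / (x[j] - x[i])
            ic = y[i] - sl * x[i]
            best = min(best, np.median((y - ic - sl * x) ** 2))
        f = fit_lms(data)
        assert np.median(f.residuals**2) == pytest.approx(best, rel=1e-12)


def test_lms_beats_ols_on_its_own_criterion(telephone):
    f_lms = fit_lms(telephone)
    f_ols = fit_ols(telephone)
    assert np.median(f_lms.residuals**2) <= np.median(f_ols.residuals**2)


def test_lms_permutation_invariant(telephone):
    perm = np.random.default_rng(11).permutation(telephone.n)
    shuffled = RegressionData(telephone.x[perm], telephone.y[perm])
    f1, f2 = fit_lms(telephone), fit_lms(shuffled)
    assert abs(f1.intercept - f2.intercept) < 1e-10
    assert abs(f1.slope - f2.slope) < 1e-10


def test_lms_subsample_deterministic():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 100, 200)
    y = 2 + 0.5 * x + rng.normal(0, 1, 200)
    data = RegressionData(x, y)
    f1 = fit_lms(data, n_subsets=500, seed=42)
    f2 = fit_lms(data, n_subsets=500, seed=42)
    assert f1.coefficients == f2.coefficients


def test_lms_needs_four_points():
    with pytest.raises(ValueError):
        fit_lms(RegressionData([1, 2, 3], [1, 2, 3]))


# ------------------------------------------------------------- diagnostics

def test_flag_outliers_empty_when_all_weights_high(seeded_sample):
    f = fit_irls(seeded_sample, "proposed", TuningSpec("proposed", 50.0, a=6.0))
    assert flag_outliers(f).size == 0


def test_flag_outliers_china_raw_fit(china):
    """Raw-scale proposed fit flags exactly the 15.50 and 364.00 responses."""
    f = fit_irls(china, "proposed", TuningSpec("proposed", 2.0, a=8.0), scale="none")
    assert flag_outliers(f).tolist() == [7, 8]


def test_flag_outliers_telephone_proposed(china, telephone):
    """MAD-scaled proposed fit flags the 1963-1970 block, leaving 16."""
    f = fit_irls(telephone, "proposed", TuningSpec("proposed", 3.5, a=6.0))
    assert flag_outliers(f).tolist() == list(range(13, 21))


def test_flag_outliers_lms_residual_rule(telephone):
    f = fit_lms(telephone)
    assert flag_outliers(f, residual_cutoff=2.5).tolist() == list(range(13, 21))


def test_flag_outliers_cutoff_validation(telephone):
    f = fit_irls(telephone, "proposed", TuningSpec("proposed", 3.5, a=6.0))
    for bad in (0.0, 1.0, -0.5, 2.0):
        with pytest.raises(ValueError):
            flag_outliers(f, weight_cutoff=bad)


def test_subset_sse_telephone_and_errors(telephone):
    f = fit_ols(telephone)
    ss = subset_sse(telephone, f, range(24))
    assert ss.sse_all == pytest.approx(695.44, abs=0.01)
    assert ss.sse_retained == ss.sse_all
    assert ss.n_used == 24
    part = subset_sse(telephone, f, range(16))
    assert part.sse_retained <= part.sse_all
    with pytest.raises(ValueError):
        subset_sse(telephone, f, [])
    with pytest.raises(ValueError):
        subset_sse(telephone, f, [30])
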