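import numpy as np
import pytest
from scipy import stats

from ebm.event_distributions import (
    DistributionSet,
    EventDistribution,
    compute_cutpoint,
    event_likelihoods,
    fit_all_biomarkers,
    fit_constrained_gmm,
)
from ebm.exceptions import FitError, NumericalError, SchemaError


def two_mode_sample(seed, n=500, mu_hi=4.0):
    """0.5*N(0,1) + 0.5*N(mu_hi,1) with CN labels on the low mode, AD on the high."""
    rng = np.random.default_rng(seed)
    hi = rng.random(n) < 0.5
    x = np.where(hi, rng.normal(mu_hi, 1.0, n), rng.normal(0.0, 1.0, n))
    return x, ~hi, hi


def test_two_mode_recovery():
    x, cn, ad = two_mode_sample(seed=42)
    d = fit_constrained_gmm(x, cn, ad, "increase")
    assert abs(d.mu_normal - 0.0) < 0.2
    assert abs(d.mu_abnormal - 4.0) < 0.2
    assert abs(d.weight_normal - 0.5) < 0.1


def test_parameter_recovery_median_error():
    """Median |error| of all four means/SDs over 20 seeded replicates < 0.15."""
    errs = []
    for seed in range(20):
        x, cn, ad = two_mode_sample(seed=1000 + seed)
        d = fit_constrained_gmm(x, cn, ad, "increase")
        errs += [
            abs(d.mu_normal), abs(d.sd_normal - 1.0),
            abs(d.mu_abnormal - 4.0), abs(d.sd_abnormal - 1.0),
        ]
        assert d.sd_normal <= np.std(x[cn], ddof=1) + 1e-9
        assert d.sd_abnormal <= np.std(x[ad], ddof=1) + 1e-9
    assert np.median(errs) < 0.15


def test_sd_constraint_active_with_tight_cn_group():
    """A tiny CN-labelled spread pins the fitted sd_normal at the bound."""
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(0, 1.0, 200), rng.normal(4, 1.0, 200)])
    cn = np.zeros(400, bool)
    cn[:50] = True
    x[:50] = rng.normal(0, 0.1, 50)
    ad = np.zeros(400, bool)
    ad[200:] = True
    bound = np.std(x[cn], ddof=1)
    d = fit_constrained_gmm(x, cn, ad, "increase", sd_structure="free")
    assert d.sd_normal == pytest.approx(bound, abs=1e-12)


def test_mixture_beats_single_normal_on_single_mode_data():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 500)
    cn = np.zeros(500, bool)
    cn[:250] = True
    d = fit_constrained_gmm(x, cn, ~cn, "increase")
    ll2 = np.sum(
        np.log(
            d.weight_normal * d.pdf_normal(x) + (1 - d.weight_normal) * d.pdf_abnormal(x)
        )
    )
    ll1 = stats.norm.logpdf(x, x.mean(), x.std()).sum()
    assert ll2 >= ll1 - 1e-6


def test_em_trace_monotone_nondecreasing(small_cohort):
    _, ds, _ = small_cohort
    for struct in ("tied", "free"):
        dists = fit_all_biomarkers(ds, sd_structure=struct)
        for d in dists:
            assert np.all(np.diff(d.loglik_trace) >= -1e-8)


def test_fit_deterministic(small_cohort):
    _, ds, _ = small_cohort
    a = fit_all_biomarkers(ds)
    b = fit_all_biomarkers(ds)
    for da, db in zip(a, b):
        assert da.to_dict() == db.to_dict()


def test_direction_resolution_decrease():
    """With a 'decrease' biomarker the abnormal component sits below the normal."""
    rng = np.random.default_rng(3)
    lo = rng.normal(0, 1, 250)   # abnormal (decreased) values
    hi = rng.normal(4, 1, 250)   # normal values
    x = np.concatenate([lo, hi])
    ad = np.zeros(500, bool)
    ad[:250] = True
    d = fit_constrained_gmm(x, ~ad, ad, "decrease")
    assert d.mu_abnormal < d.mu_normal


def test_fit_errors():
    with pytest.raises(FitError, match="identical"):
        fit_constrained_gmm(np.ones(10), np.arange(10) < 5, np.arange(10) >= 5, "increase")
    x = np.arange(10, dtype=float)
    with pytest.raises(FitError, match="at least 2"):
        fit_constrained_gmm(x, np.zeros(10, bool), np.ones(10, bool), "increase")


def test_event_likelihoods_density_identities(small_cohort):
    _, ds, _ = small_cohort
    dists = fit_all_biomarkers(ds)
    lt = event_likelihoods(ds, dists)
    assert lt.like_event.shape == ds.values.shape
    assert np.all(lt.like_event > 0) and np.all(lt.like_noevent > 0)
    # Density at the abnormal mean equals the normal-density peak.
    d = dists[ds.biomarker_names[0]]
    ds2 = ds.subset([0])
    ds2.values[0, 0] = d.mu_abnormal
    lt2 = event_likelihoods(ds2, dists)
    assert lt2.like_event[0, 0] == pytest.approx(1 / (d.sd_abnormal * np.sqrt(2 * np.pi)))
    # Equal-SD components: the midpoint is equidistant, densities agree.
    eq = EventDistribution("m", 0.0, 1.0, 2.0, 1.0, 0.5, "increase")
    assert eq.pdf_normal(1.0) == pytest.approx(eq.pdf_abnormal(1.0))


def test_event_likelihoods_name_mismatch(small_cohort):
    _, ds, _ = small_cohort
    dists = DistributionSet(
        [EventDistribution("other", 0.0, 1.0, 2.0, 1.0, 0.5, "increase")]
    )
    with pytest.raises(SchemaError):
        event_likelihoods(ds, dists)


class TestCutpoint:
    def test_symmetric_closed_form(self):
        d = EventDistribution("m", 0.0, 1.0, 2.0, 1.0, 0.5, "increase")
        assert compute_cutpoint(d).value == pytest.approx(1.0, abs=1e-10)

    def test_unequal_weight_shifts_toward_abnormal_mean(self):
        """weight_normal 0.75 moves the posterior-0.5 point past the midpoint;
        agreement with a dense grid scan of the posterior."""
        d = EventDistribution("m", 0.0, 1.0, 2.0, 1.0, 0.75, "increase")
        cp = compute_cutpoint(d)
        assert cp.value > 1.0
        grid = np.linspace(0.0, 2.0, 200001)
        post = d.posterior_abnormal(grid)
        x_grid = grid[np.argmin(np.abs(post - 0.5))]
        assert cp.value == pytest.approx(x_grid, abs=1e-5)
        assert d.posterior_abnormal(cp.value) == pytest.approx(0.5, abs=1e-10)

    def test_sensitivity_specificity_from_labels(self):
        d = EventDistribution("m", 0.0, 1.0, 4.0, 1.0, 0.5, "increase")
        cn = np.array([-0.5, 0.2, 1.0, 5.0])   # one CN beyond the cut
        ad = np.array([3.5, 4.5, 1.0, 6.0])    # one AD on the normal side
        cp = compute_cutpoint(d, cn_values=cn, ad_values=ad)
        assert cp.value == pytest.approx(2.0, abs=1e-10)
        assert cp.sensitivity == pytest.approx(75.0)
        assert cp.specificity == pytest.approx(75.0)

    def test_identical_components_rejected(self):
        d = EventDistribution("m", 0.0, 1.0, 0.0, 1.0, 0.5, "increase")
        with pytest.raises(NumericalError):
            compute_cutpoint(d)


def test_distribution_set_yaml_roundtrip(tmp_path, small_cohort):
    _, ds, _ = small_cohort
    dists = fit_all_biomarkers(ds)
    path = tmp_path / "dists.yaml"
    dists.to_yaml(path)
    back = DistributionSet.from_yaml(path)
    for a, b in zip(dists, back):
        for k, v in a.to_dict().items():
            if isinstance(v, float):
                assert getattr(b, k) == pytest.approx(v, rel=1e-12)
            else:
                assert getattr(b, k) == v
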