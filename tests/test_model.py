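"""Model density, hyperprior estimation, design, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sparsesig.catalogue import COLUMNS, ExposureVector
from sparsesig.model import (
    HYPER_COLS,
    HyperpriorConstants,
    ModelParameters,
    PosteriorDraws,
    _UnconstrainedPosterior,
    build_design,
    estimate_hyperpriors,
    joint_log_density,
    load_draws,
    nb_log_pmf,
    save_draws,
    summarize_posterior,
    tail_draw_count,
)
from sparsesig.simulate import simulate_catalogue


# ---------------------------------------------------------------------------
# negative binomial pmf

def test_nb_pmf_matches_scipy_parameterization():
    # NB(mu, theta) is nbinom with size theta and p = theta/(theta+mu)
    n = np.arange(0, 50)
    for mu, theta in [(5.0, 2.0), (0.3, 10.0), (120.0, 0.5)]:
        ours = nb_log_pmf(n, mu, theta)
        ref = stats.nbinom.logpmf(n, theta, theta / (theta + mu))
        np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_nb_pmf_zero_count_closed_form():
    # P(0) = (theta/(mu+theta))^theta; with mu = theta = 1 that is 1/2
    assert nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)


def test_nb_pmf_normalizes_on_truncated_support():
    n = np.arange(0, 5000)
    total = np.exp(nb_log_pmf(n, 5.0, 2.0)).sum()
    assert abs(total - 1.0) < 1e-8


def test_nb_pmf_poisson_limit():
    # as theta -> inf the NB pmf converges to Poisson; at theta = 1e6 the
    # probabilities agree within 1e-4 over the whole support (log-pmf error
    # grows like n^2 / (2 theta) in the far tail where the mass is negligible)
    n = np.arange(0, 200)
    ours = np.exp(nb_log_pmf(n, 7.5, 1e6))
    poisson = stats.poisson.pmf(n, 7.5)
    assert np.max(np.abs(ours - poisson)) < 1e-4


def test_nb_pmf_domain_errors():
    with pytest.raises(ValueError):
        nb_log_pmf(-1, 1.0, 1.0)
    with pytest.raises(ValueError):
        nb_log_pmf(1.5, 1.0, 1.0)
    with pytest.raises(ValueError):
        nb_log_pmf(1, -2.0, 1.0)
    with pytest.raises(ValueError):
        nb_log_pmf(1, 1.0, 0.0)


# ---------------------------------------------------------------------------
# hyperprior constants

def test_prior_sd_is_twenty_percent_of_center_with_floor():
    h = HyperpriorConstants(lambda0=-2.0, lambda1=0.01, delta=0.5,
                            mu=4.0, psi=0.0, upsilon=1.0)
    assert h.prior_sd("lambda0") == pytest.approx(0.4)
    assert h.prior_sd("mu") == pytest.approx(0.8)
    # near-zero centers are floored, never degenerate
    assert h.prior_sd("lambda1") == h.sd_floor
    assert h.prior_sd("psi") == h.sd_floor


def test_hyperprior_trend_recovery_on_simulated_genes():
    # 500 genes simulated with trend sigma = 1.0 + 0.5 * mean log abundance
    table, truth = simulate_catalogue(
        G=500, C=1, R=1, samples_per_dataset=100,
        dataset_sd=0.0, trend=(1.0, 0.5, 0.05), missing_fraction=0.0,
        seed=77, abundance_skew=0.0, abundance_scale=1.0, library_log_sd=0.1,
    )
    exposure = ExposureVector(
        samples=list(truth.samples),
        tmm_factor=np.ones(len(truth.samples)),
        library_size=np.exp(truth.epsilon),
        epsilon=truth.epsilon,
    )
    h = estimate_hyperpriors(table, exposure)
    assert abs(h.lambda0 - 1.0) < 0.15
    assert abs(h.lambda1 - 0.5) < 0.15
    assert h.delta > 0


def test_skewness_estimator_is_calibrated_on_symmetric_log_means():
    # the skew-normal fit used for (mu*, psi*, upsilon*): on log-means drawn
    # from a symmetric normal the implied skewness of the fitted distribution
    # must be near zero, and clearly positive for right-skewed log-means.
    # (The shape parameter itself is not testable this way: the shape ->
    # skewness map is cubically flat at zero, so shape estimates on symmetric
    # samples legitimately scatter far from 0 while implying ~zero skewness.)
    rng = np.random.default_rng(123)
    sym = rng.normal(3.0, 1.5, size=1000)
    a, loc, scale = stats.skewnorm.fit(sym)
    implied = float(stats.skewnorm.stats(a, moments="s"))
    assert abs(implied) < 0.3

    skewed = stats.skewnorm.rvs(5.0, loc=3.0, scale=1.5, size=1000, random_state=rng)
    a2, *_ = stats.skewnorm.fit(skewed)
    implied2 = float(stats.skewnorm.stats(a2, moments="s"))
    assert implied2 > 0.3


def test_hyperprior_estimation_requires_enough_informative_genes():
    rows = [(f"s{i}", "g1", "ct0", "ds0", 5) for i in range(4)]
    table = pd.DataFrame(rows, columns=COLUMNS)
    exposure = ExposureVector(
        samples=[f"s{i}" for i in range(4)],
        tmm_factor=np.ones(4), library_size=np.full(4, 20.0),
    )
    with pytest.raises(ValueError, match="fewer than 10"):
        estimate_hyperpriors(table, exposure)


# ---------------------------------------------------------------------------
# design construction

def _small_design(seed=9, G=6, C=2, R=2, spd=2, missing=0.0):
    table, truth = simulate_catalogue(
        G=G, C=C, R=R, samples_per_dataset=spd,
        dataset_sd=0.3, missing_fraction=missing, seed=seed,
        library_log_mean=np.log(5e3), library_log_sd=0.2,
        mean_log_abundance=2.0, abundance_scale=0.8,
    )
    exposure = ExposureVector(
        samples=list(truth.samples),
        tmm_factor=np.ones(len(truth.samples)),
        library_size=np.exp(truth.epsilon),
        epsilon=truth.epsilon,
    )
    return table, truth, exposure


def test_design_shapes_and_indicators():
    table, truth, exposure = _small_design()
    d = build_design(table, exposure)
    assert (d.S, d.G, d.C, d.R) == (4, 6, 2, 2)
    assert d.X.shape == (4, 2) and d.Z.shape == (4, 2)
    np.testing.assert_array_equal(d.X.sum(axis=1), 1.0)
    np.testing.assert_array_equal(d.Z.sum(axis=1), 1.0)
    assert d.n_observed() == len(table)


def test_design_mask_marks_only_observed_pairs():
    table, truth, exposure = _small_design(missing=0.5)
    d = build_design(table, exposure)
    assert d.mask.sum() == len(table)
    # an unobserved pair stays masked and its y entry is inert
    observed = {(s, g) for s, g in zip(table["sample"], table["gene"])}
    for si, s in enumerate(d.samples):
        for gi, g in enumerate(d.genes):
            assert d.mask[si, gi] == ((s, g) in observed)


def test_design_requires_exposure_for_every_sample():
    table, truth, exposure = _small_design()
    short = ExposureVector(
        samples=truth.samples[:-1],
        tmm_factor=np.ones(len(truth.samples) - 1),
        library_size=np.exp(truth.epsilon[:-1]),
    )
    with pytest.raises(ValueError, match="exposure missing"):
        build_design(table, short)


def test_design_invariant_to_row_order():
    table, truth, exposure = _small_design()
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    d1 = build_design(table, exposure)
    d2 = build_design(shuffled, exposure)
    np.testing.assert_array_equal(d1.y, d2.y)
    np.testing.assert_array_equal(d1.mask, d2.mask)
    assert d1.samples == d2.samples and d1.genes == d2.genes


# ---------------------------------------------------------------------------
# joint density

def _params_for(design, rng):
    G, C, R = design.G, design.C, design.R
    return ModelParameters(
        alpha=rng.normal(2.0, 0.5, size=(G, C)),
        beta=rng.normal(0.0, 0.3, size=(G, R)),
        rho=rng.uniform(0.2, 0.8, size=G),
        sigma=rng.normal(1.0, 0.3, size=G),
        lambda0=1.1, lambda1=0.4, delta=0.5,
        mu=2.0, psi=-0.2, upsilon=1.0,
        omega=3.0, o=2.5,
    )


def _oracle_density(params, design, hyper):
    """Term-by-term transcription built on scipy only."""
    lp = 0.0
    for si in range(design.S):
        c, r = design.cell_of[si], design.dataset_of[si]
        for gi in range(design.G):
            if not design.mask[si, gi]:
                continue
            mu = np.exp(params.alpha[gi, c] + params.beta[gi, r] + design.epsilon[si])
            th = np.exp(params.sigma[gi])
            lp += stats.nbinom.logpmf(design.y[si, gi], th, th / (th + mu))
    for gi in range(design.G):
        for r in range(design.R):
            lp += stats.norm.logpdf(params.beta[gi, r], 0.0, params.rho[gi])
        lp += stats.gamma.logpdf(params.rho[gi], params.omega, scale=1.0 / params.o)
        abar = params.alpha[gi].mean()
        lp += stats.norm.logpdf(params.sigma[gi], params.lambda0 + params.lambda1 * abar, params.delta)
        for c in range(design.C):
            lp += stats.skewnorm.logpdf(
                params.alpha[gi, c], params.upsilon, loc=params.mu, scale=np.exp(params.psi)
            )
    for value, name in [
        (params.lambda0, "lambda0"), (params.lambda1, "lambda1"),
        (params.delta, "delta"), (params.mu, "mu"),
        (params.psi, "psi"), (params.upsilon, "upsilon"),
    ]:
        lp += stats.norm.logpdf(value, getattr(hyper, name), hyper.prior_sd(name))
    lp += stats.norm.logpdf(params.omega, hyper.omega_loc, hyper.omega_scale)
    lp += stats.norm.logpdf(params.o, hyper.omega_loc, hyper.omega_scale)
    return float(lp)


def _two_gene_instance():
    # 2 genes x 4 samples (2 cell types x 2 datasets), one pair missing
    rows = [
        ("s1", "gA", "ct0", "ds0", 12),
        ("s1", "gB", "ct0", "ds0", 40),
        ("s2", "gA", "ct1", "ds0", 7),
        ("s2", "gB", "ct1", "ds0", 55),
        ("s3", "gA", "ct0", "ds1", 20),
        ("s3", "gB", "ct0", "ds1", 31),
        ("s4", "gA", "ct1", "ds1", 9),
        # (s4, gB) unobserved: must contribute nothing
    ]
    table = pd.DataFrame(rows, columns=COLUMNS)
    exposure = ExposureVector(
        samples=["s1", "s2", "s3", "s4"],
        tmm_factor=np.ones(4),
        library_size=np.array([100.0, 120.0, 90.0, 110.0]),
    )
    hyper = HyperpriorConstants(lambda0=1.2, lambda1=0.35, delta=0.45,
                                mu=2.1, psi=-0.1, upsilon=0.9)
    return table, exposure, hyper


def test_joint_density_matches_term_by_term_oracle():
    table, exposure, hyper = _two_gene_instance()
    design = build_design(table, exposure)
    params = _params_for(design, np.random.default_rng(4))
    ours = joint_log_density(params, design, hyper)
    oracle = _oracle_density(params, design, hyper)
    assert abs(ours - oracle) < 1e-8


def test_joint_density_omits_missing_pairs():
    table, exposure, hyper = _two_gene_instance()
    design = build_design(table, exposure)
    params = _params_for(design, np.random.default_rng(4))
    lp_full = joint_log_density(params, design, hyper)
    # dropping one observed pair changes the density by exactly its NB term
    si, gi = design.samples.index("s1"), design.genes.index("gA")
    design.mask[si, gi] = False
    lp_less = joint_log_density(params, design, hyper)
    c, r = design.cell_of[si], design.dataset_of[si]
    mu = np.exp(params.alpha[gi, c] + params.beta[gi, r] + design.epsilon[si])
    term = float(nb_log_pmf(design.y[si, gi], mu, np.exp(params.sigma[gi])))
    assert lp_full - lp_less == pytest.approx(term, abs=1e-10)


def test_joint_density_rejects_non_finite_parameters():
    table, exposure, hyper = _two_gene_instance()
    design = build_design(table, exposure)
    params = _params_for(design, np.random.default_rng(4))
    params.alpha[0, 0] = np.nan
    with pytest.warns(RuntimeWarning):
        assert joint_log_density(params, design, hyper) == -np.inf


def test_unconstrained_gradient_matches_finite_differences():
    table, exposure, hyper = _two_gene_instance()
    design = build_design(table, exposure)
    post = _UnconstrainedPosterior(design, hyper)
    rng = np.random.default_rng(11)
    z = post.initial_point(rng)
    lp, grad = post.logp_grad(z)
    assert np.isfinite(lp)
    eps = 1e-6
    for k in rng.choice(z.size, size=12, replace=False):
        zp, zm = z.copy(), z.copy()
        zp[k] += eps
        zm[k] -= eps
        fd = (post.logp_grad(zp)[0] - post.logp_grad(zm)[0]) / (2 * eps)
        assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_unconstrained_density_consistent_with_constrained():
    # lp_unconstrained = lp_constrained + log-Jacobians + R * sum(log rho);
    # the last term converts the N(0, rho) prior on beta into the N(0, 1)
    # prior on btilde = beta / rho used by the non-centered parameterization
    table, exposure, hyper = _two_gene_instance()
    design = build_design(table, exposure)
    post = _UnconstrainedPosterior(design, hyper)
    rng = np.random.default_rng(21)
    z = post.initial_point(rng)
    lp_u, _ = post.logp_grad(z)
    params = post.to_constrained(z)
    lp_c = joint_log_density(params, design, hyper)
    t = np.log(params.rho)
    jac = t.sum() + np.log(params.delta) + np.log(params.omega - 1.0) + np.log(params.o - 1.0)
    recon = lp_c + jac + design.R * t.sum()
    assert lp_u == pytest.approx(recon, abs=1e-8)


# ---------------------------------------------------------------------------
# summaries

def _synthetic_draws(D, G=3, C=2, R=2, seed=0):
    rng = np.random.default_rng(seed)
    return PosteriorDraws(
        alpha=rng.normal(size=(D, G, C)),
        beta=rng.normal(size=(D, G, R)),
        rho=rng.uniform(0.1, 1.0, size=(D, G)),
        sigma=rng.normal(size=(D, G)),
        hypers=pd.DataFrame(rng.normal(size=(D, len(HYPER_COLS))), columns=HYPER_COLS),
        genes=[f"g{i}" for i in range(G)],
        cell_types=[f"ct{i}" for i in range(C)],
        datasets=[f"ds{i}" for i in range(R)],
        meta={"chains": 4},
    )


def test_tail_draw_counts():
    assert tail_draw_count(2000, 0.025) == 50
    assert tail_draw_count(2000, 0.975) == 50
    assert tail_draw_count(100, 0.10) == 10
    assert tail_draw_count(99, 0.025) == 2
    with pytest.raises(ValueError):
        tail_draw_count(100, 0.0)


def test_summary_quantiles_match_sort_oracle():
    draws = _synthetic_draws(D=101, seed=8)
    qs = [0.025, 0.5, 0.975]
    out = summarize_posterior(draws, qs)
    row = out[(out["parameter"] == "alpha") & (out["gene"] == "g1") & (out["level"] == "ct0")]
    gi, ci = 1, 0
    x = np.sort(draws.alpha[:, gi, ci])
    n = x.size
    for q in qs:
        h = (n - 1) * q
        lo = int(np.floor(h))
        oracle = x[lo] + (h - lo) * (x[min(lo + 1, n - 1)] - x[lo])
        assert row[f"q{q:g}"].iloc[0] == pytest.approx(oracle, abs=1e-12)
    assert out.attrs["tail_draws"][0.025] == tail_draw_count(101, 0.025)


def test_summary_requires_enough_draws():
    with pytest.raises(ValueError, match="at least 40"):
        summarize_posterior(_synthetic_draws(D=10), [0.5])
    with pytest.raises(ValueError, match="outside"):
        summarize_posterior(_synthetic_draws(D=50), [1.5])


def test_draws_roundtrip_through_disk(tmp_path):
    draws = _synthetic_draws(D=40, seed=3)
    save_draws(draws, tmp_path / "d")
    back = load_draws(tmp_path / "d")
    np.testing.assert_allclose(back.alpha, draws.alpha, atol=1e-12)
    np.testing.assert_allclose(back.beta, draws.beta, atol=1e-12)
    np.testing.assert_allclose(back.rho, draws.rho, atol=1e-12)
    np.testing.assert_allclose(back.sigma, draws.sigma, atol=1e-12)
    np.testing.assert_allclose(back.hypers.to_numpy(), draws.hypers.to_numpy(), atol=1e-12)
    assert back.genes == draws.genes
    assert back.meta["chains"] == 4
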