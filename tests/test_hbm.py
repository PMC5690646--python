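"""Hierarchical consensus model: likelihood, sampling, diagnostics, pooling."""

import numpy as np
import pandas as pd
import pytest

from crowdprior import (HbmModel, HyperParams, McmcConfig, PosteriorSamples,
                        ScalingRecord, SimulationTruth, ValidationError,
                        consensus_from_posterior, diagnostics, fit_hbm,
                        fit_question_mle, pooling_coefficient,
                        simulate_question, standardize_prompts)

FAST = dict(chains=3, warmup=500, draws=300, thin=2)


@pytest.fixture(scope="module")
def sim_fit():
    """One full fit at the 20-subject scale, shared across tests."""
    truth = SimulationTruth(seed=42)
    ds, result = simulate_question(truth)
    samples = fit_hbm(ds, McmcConfig(seed=7))
    priors, mle_fits = fit_question_mle(ds)
    return truth, ds, result, samples, mle_fits


def clean_truth(seed, tau=None, **over):
    """Simulation settings without boundary contaminants: shrinkage
    geometry is only well defined when the participant MLE and the
    hierarchical fit see the same responses as valid."""
    base = SimulationTruth(seed=seed, **over)
    hyper = HyperParams(mu_c=base.hyper.mu_c, sigma_c=base.hyper.sigma_c,
                        tau=tau if tau is not None else base.hyper.tau,
                        gamma=base.hyper.gamma,
                        phi=(0.0, 0.0, 1.0))
    fields = {f: getattr(base, f) for f in base.__dataclass_fields__}
    fields["hyper"] = hyper
    return SimulationTruth(**fields)


@pytest.fixture(scope="module")
def clean_fit():
    """A fit on uncontaminated, low-noise responses with clearly separated
    participants, for pooling-geometry tests."""
    ds, result = simulate_question(clean_truth(101, tau=0.8, kappa=100.0))
    samples = fit_hbm(ds, McmcConfig(seed=55))
    _, mle_fits = fit_question_mle(ds)
    return ds, result, samples, mle_fits


class TestStandardize:
    def test_two_point_standardization(self):
        from crowdprior import ElicitationRecord, QuestionDataset
        recs = []
        for pid, (lo, hi) in (("a", (0.0, 12.0)), ("b", (0.0, 12.0))):
            recs.append(ElicitationRecord(
                participant_id=pid, question_id="q", condition="control",
                best=5.0, lo=lo, hi=hi,
                prompts=(2.0, 6.0, 10.0), probs=(0.2, 0.5, 0.8),
            ))
        ds = QuestionDataset("q", recs)
        std, sc = standardize_prompts(ds)
        vals = np.array([c for r in std.records for c in r.prompts])
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_round_trip(self):
        ds, _ = simulate_question(SimulationTruth(seed=1, outcome_scale=(7.0, 3.0)))
        std, sc = standardize_prompts(ds)
        for rec, orig in zip(std.records, ds.records):
            back = sc.inverse(np.asarray(rec.prompts))
            assert back == pytest.approx(np.asarray(orig.prompts), abs=1e-12)

    def test_zero_sd_error(self):
        from crowdprior import ElicitationRecord, QuestionDataset
        rec = ElicitationRecord(
            participant_id="a", question_id="q", condition="control",
            best=5.0, lo=5.0, hi=5.0, prompts=(5.0, 5.0, 5.0),
            probs=(0.2, 0.5, 0.8),
        )
        with pytest.raises(ValidationError, match="SD is zero"):
            standardize_prompts(QuestionDataset("q", [rec]))


class TestLikelihood:
    def dataset_with_boundaries(self):
        truth = SimulationTruth(seed=13)  # default 10% contamination
        ds, _ = simulate_question(truth)
        probs = [p for r in ds.records for p in r.probs]
        assert 0.0 in probs and 1.0 in probs
        return ds

    def test_mixture_gives_boundary_responses_positive_density(self):
        ds = self.dataset_with_boundaries()
        cfg = McmcConfig(seed=0)
        model = HbmModel(ds, cfg)
        state = model.draw_from_prior(np.random.default_rng(5))
        assert np.isfinite(model.log_likelihood(state))

    def test_removing_mixture_zeroes_boundary_datasets(self):
        ds = self.dataset_with_boundaries()
        cfg = McmcConfig(seed=0)
        model = HbmModel(ds, cfg, include_mixture=False)
        state = model.draw_from_prior(np.random.default_rng(5))
        assert model.log_likelihood(state) == -np.inf


class TestDiagnostics:
    def iid_samples(self, jitter=1.0):
        rng = np.random.default_rng(0)
        draws = {"x": rng.normal(size=(4, 500)) * jitter}
        return PosteriorSamples(
            draws=draws, n_chains=4, n_draws=500,
            scaling=ScalingRecord(0.0, 1.0),
            conditions=("control",), participants=(),
            attrs={"hyper_names": ["x"]},
        )

    def test_iid_chains_look_converged(self):
        d = diagnostics(self.iid_samples())
        assert d.loc[0, "rhat"] < 1.01
        assert d.loc[0, "ess"] > 1000

    def test_stuck_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = {"x": np.stack([np.zeros(400) + 1e-9 * rng.normal(size=400),
                                np.ones(400) + 1e-9 * rng.normal(size=400)])}
        s = PosteriorSamples(
            draws=draws, n_chains=2, n_draws=400,
            scaling=ScalingRecord(0.0, 1.0),
            conditions=("control",), participants=(),
            attrs={"hyper_names": ["x"]},
        )
        d = diagnostics(s)
        assert d.loc[0, "rhat"] > 1.5

    def test_single_chain_error(self):
        s = self.iid_samples()
        one = PosteriorSamples(
            draws={"x": s.draws["x"][:1]}, n_chains=1, n_draws=500,
            scaling=s.scaling, conditions=s.conditions, participants=(),
        )
        with pytest.raises(ValidationError, match="two chains"):
            diagnostics(one)

    def test_split_rhat_matches_published_formula(self):
        """Oracle: split-R-hat computed directly from its definition."""
        rng = np.random.default_rng(42)
        arr = rng.normal(size=(3, 400)) + np.array([[0.0], [0.2], [0.5]])
        s = PosteriorSamples(
            draws={"x": arr}, n_chains=3, n_draws=400,
            scaling=ScalingRecord(0.0, 1.0),
            conditions=("control",), participants=(),
            attrs={"hyper_names": ["x"]},
        )
        d = diagnostics(s)
        # split each chain in half, then classic potential scale reduction
        half = arr.reshape(6, 200)
        n = half.shape[1]
        means = half.mean(axis=1)
        B = n * means.var(ddof=1)
        W = half.var(axis=1, ddof=1).mean()
        var_plus = (n - 1) / n * W + B / n
        rhat_oracle = np.sqrt(var_plus / W)
        assert d.loc[0, "rhat"] == pytest.approx(rhat_oracle, abs=1e-8)


class TestFit:
    def test_seeded_fit_is_deterministic(self, sim_fit):
        _, ds, _, samples, _ = sim_fit
        again = fit_hbm(ds, McmcConfig(seed=7))
        for name in samples.draws:
            assert np.array_equal(samples.draws[name], again.draws[name])

    def test_hyperparameters_near_truth(self, sim_fit):
        truth, _, _, samples, _ = sim_fit
        d = diagnostics(samples)
        assert d.attrs["converged"]
        cons = consensus_from_posterior(samples)
        for cond in ("control", "treatment"):
            assert cons[cond].method == "hbm"
            assert cons[cond].mu == pytest.approx(truth.hyper.mu_c[cond], abs=0.35)
            assert cons[cond].sigma == pytest.approx(truth.hyper.sigma_c[cond],
                                                     rel=0.45)

    def test_contamination_mass_recovered(self, sim_fit):
        truth, _, _, samples, _ = sim_fit
        contam = (samples.stacked("phi[zero]") + samples.stacked("phi[one]")).mean()
        true_contam = truth.hyper.phi[0] + truth.hyper.phi[1]
        assert contam == pytest.approx(true_contam, abs=0.07)
        assert samples.stacked("phi[zero]").mean() > 0.005
        assert samples.stacked("phi[one]").mean() > 0.005

    def test_draws_table_layout(self, sim_fit):
        _, _, _, samples, _ = sim_fit
        df = samples.to_dataframe()
        assert len(df) == samples.n_chains * samples.n_draws
        assert "mu_c[control]" in df.columns
        assert any(c.startswith("m[") for c in df.columns)

    def test_identity_scaling_when_not_standardizing(self):
        ds, _ = simulate_question(SimulationTruth(seed=6, n_subjects=8))
        samples = fit_hbm(ds, McmcConfig(seed=3, **FAST), standardize=False)
        assert samples.scaling == ScalingRecord(0.0, 1.0)
        cons = consensus_from_posterior(samples)
        med = float(np.median(samples.stacked("mu_c[control]")))
        assert cons["control"].mu == pytest.approx(med)

    def test_single_participant_warns(self):
        ds, _ = simulate_question(SimulationTruth(seed=6, n_subjects=1))
        from crowdprior import ConvergenceWarning
        with pytest.warns(ConvergenceWarning, match="single-participant"):
            HbmModel(ds, McmcConfig(seed=0))


class TestConsensus:
    def test_degenerate_posterior_unstandardized(self):
        draws = {name: np.full((2, 10), val) for name, val in [
            ("mu_c[control]", 0.5), ("sigma_c[control]", 1.2),
        ]}
        s = PosteriorSamples(
            draws=draws, n_chains=2, n_draws=10,
            scaling=ScalingRecord(10.0, 4.0),
            conditions=("control",), participants=(), question_id="q",
        )
        cons = consensus_from_posterior(s)
        assert cons["control"].mu == pytest.approx(10.0 + 4.0 * 0.5)
        assert cons["control"].sigma == pytest.approx(4.0 * 1.2)

    def test_missing_scaling_error(self):
        s = PosteriorSamples(
            draws={"mu_c[control]": np.zeros((2, 5)),
                   "sigma_c[control]": np.ones((2, 5))},
            n_chains=2, n_draws=5, scaling=None,
            conditions=("control",), participants=(),
        )
        with pytest.raises(ValidationError, match="scaling"):
            consensus_from_posterior(s)


class TestPooling:
    def test_exact_endpoints_on_constructed_posterior(self):
        """pooling = 0 when the posterior sits at the individual MLE,
        1 when it sits at the hyperparameter center."""
        draws = {
            "mu_c[control]": np.full((2, 10), 0.0),
            "sigma_c[control]": np.full((2, 10), 1.0),
            "m[at_mle,control]": np.full((2, 10), 2.0),
            "s[at_mle,control]": np.full((2, 10), 1.5),
            "m[at_center,control]": np.full((2, 10), 0.0),
            "s[at_center,control]": np.full((2, 10), 1.0),
        }
        samples = PosteriorSamples(
            draws=draws, n_chains=2, n_draws=10,
            scaling=ScalingRecord(0.0, 1.0),
            conditions=("control",),
            participants=("at_mle", "at_center"),
        )
        mle_fits = pd.DataFrame([
            {"participant_id": "at_mle", "condition": "control",
             "mu": 2.0, "sigma": 1.5},
            {"participant_id": "at_center", "condition": "control",
             "mu": 2.0, "sigma": 1.5},
        ])
        pool = pooling_coefficient(samples, mle_fits).set_index(
            ["participant_id", "parameter"])
        assert pool.loc[("at_mle", "m"), "pooling"] == 0.0
        assert pool.loc[("at_mle", "s"), "pooling"] == 0.0
        assert pool.loc[("at_center", "m"), "pooling"] == 1.0
        assert pool.loc[("at_center", "s"), "pooling"] == 1.0

    def test_endpoints(self, sim_fit):
        _, _, _, samples, mle_fits = sim_fit
        pool = pooling_coefficient(samples, mle_fits)
        assert set(pool["parameter"]) == {"m", "s"}
        assert ((pool["pooling"] >= 0) & (pool["pooling"] <= 1)).all()

    def test_missing_participant_error(self, sim_fit):
        _, _, _, samples, mle_fits = sim_fit
        trimmed = mle_fits[mle_fits.participant_id != "p000"]
        with pytest.raises(ValidationError, match="missing from the MLE"):
            pooling_coefficient(samples, trimmed)

    def test_shrinkage_direction(self, clean_fit):
        """Hierarchical estimates sit between the individual MLE and the
        grand mean for the overwhelming majority of participants.

        Betweenness is assessed with half a posterior SD of slack: the MLE
        minimizes squared error on CDF values while the hierarchical model
        conditions on the Beta response likelihood, so the two centers can
        differ by a fraction of the posterior spread even without pooling.
        """
        _, _, samples, mle_fits = clean_fit
        sc = samples.scaling
        fits = mle_fits.set_index(["participant_id", "condition"])
        n_between, n_total = 0, 0
        for cond in samples.conditions:
            grand = float(sc.inverse(np.median(samples.stacked(f"mu_c[{cond}]"))))
            for pid in samples.participants:
                unpooled = float(fits.loc[(pid, cond), "mu"])
                d = samples.stacked(f"m[{pid},{cond}]")
                post = float(sc.inverse(np.median(d)))
                slack = 0.5 * float(np.std(d)) * sc.scale
                lo, hi = sorted((unpooled, grand))
                n_total += 1
                n_between += (lo - slack <= post <= hi + slack)
        assert n_between / n_total >= 0.9

    def test_less_information_means_more_pooling(self):
        """Median pooling of m is larger with 3 responses per participant
        than with 9."""
        medians = {}
        for ppc in (3, 9):
            ds, _ = simulate_question(clean_truth(19, prompts_per_condition=ppc))
            samples = fit_hbm(ds, McmcConfig(seed=23, **FAST))
            _, mle_fits = fit_question_mle(ds)
            pool = pooling_coefficient(samples, mle_fits)
            medians[ppc] = float(pool.loc[pool.parameter == "m", "pooling"].median())
        assert medians[3] > medians[9]


def test_spread_prior_pull_is_small_with_adaptive_prompts():
    """The half-normal prior on the consensus spread barely moves the
    posterior here: prompts adapt to each participant's own interval, so
    sigma_c is well identified at 20 subjects.  A 10x flatter prior shifts
    the posterior median by only a few hundredths, in the loosening
    direction."""
    ds, _ = simulate_question(SimulationTruth(seed=42))
    medians = {}
    for scale in (1.0, 10.0):
        cfg = McmcConfig(seed=7, sigma_prior_scale=scale)
        samples = fit_hbm(ds, cfg, include_participants=False)
        medians[scale] = np.array([
            float(np.median(samples.stacked(f"sigma_c[{c}]")))
            * samples.scaling.scale
            for c in ("control", "treatment")
        ])
    shift = medians[10.0] - medians[1.0]
    assert np.all(shift > -0.02)   # flatter prior never tightens the spread
    assert np.all(np.abs(shift) < 0.05)


def test_hbm_and_mle_agree_on_homogeneous_population():
    """With negligible between-participant spread and low response noise the
    two aggregation routes give the same consensus."""
    hyper = HyperParams(
        mu_c={"control": -0.6, "treatment": 0.6},
        sigma_c={"control": 1.0, "treatment": 1.0},
        tau=0.05, gamma=0.05, phi=(0.0, 0.0, 1.0),
    )
    truth = SimulationTruth(hyper=hyper, n_subjects=15, kappa=200.0, seed=55)
    ds, _ = simulate_question(truth)
    mle_priors, _ = fit_question_mle(ds)
    samples = fit_hbm(ds, McmcConfig(seed=29, **FAST))
    hbm_priors = consensus_from_posterior(samples)
    for cond in ("control", "treatment"):
        assert hbm_priors[cond].mu == pytest.approx(mle_priors[cond].mu, abs=0.15)
        assert hbm_priors[cond].sigma == pytest.approx(
            mle_priors[cond].sigma, rel=0.35, abs=0.15
        )
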