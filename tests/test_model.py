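import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from ctscr.geometry import DomainError, TrapArray, build_grid
from ctscr.model import (
    ConfigurationError,
    DataError,
    LatentState,
    Params,
    SurveyData,
    density_surface,
    detection_intensity,
    expected_count,
    expected_count_numeric,
    full_loglik,
    lambda_integral,
    log_joint_obs_density,
    pi0,
    restricted_loglik,
    temporal_effect,
)
from ctscr.sampler import fast_loglik
from ctscr.schedule import Schedule, ScheduleError


def _params(beta=(0.0,), alpha=(0.0,), xi=(), sigma=1.0):
    return Params(beta=np.array(beta), alpha=np.array(alpha), xi=np.array(xi), sigma=sigma)


class TestDensitySurface:
    def test_constant_intensity(self):
        dom = build_grid((0, 0, 1, 1), 0.5)
        lam = density_surface(_params(beta=(np.log(2.0),)), dom)
        assert np.allclose(lam, 2.0)

    def test_log_linearity_ratio(self):
        dom = build_grid((0, 0, 1, 1), 0.5, covariate_fields=[lambda p: (p[:, 0] > 0.5) - 1.0])
        lam = density_surface(_params(beta=(0.0, 5.0)), dom)
        # cells with v=(1,-1) vs v=(1,0): ratio e^-5
        lo, hi = lam.min(), lam.max()
        assert lo / hi == pytest.approx(np.exp(-5.0))

    def test_dimension_mismatch(self):
        dom = build_grid((0, 0, 1, 1), 0.5)
        with pytest.raises(ConfigurationError):
            density_surface(_params(beta=(0.0, 1.0)), dom)


class TestLambdaIntegral:
    def test_constant_integrand_exact(self):
        dom = build_grid((0, 0, 1, 1), 0.25)
        assert lambda_integral(_params(beta=(np.log(2.0),)), dom) == pytest.approx(2.0)

    def test_quadrature_refinement_agreement(self):
        f = [lambda p: np.sin(p[:, 0]) * np.cos(p[:, 1])]
        par = _params(beta=(0.4, 0.8))
        coarse = lambda_integral(par, build_grid((0, 0, 3, 3), 0.1, covariate_fields=f))
        fine = lambda_integral(par, build_grid((0, 0, 3, 3), 0.05, covariate_fields=f))
        assert abs(coarse - fine) / fine < 0.005


class TestTemporalEffect:
    def test_daytime_rate_ratio(self):
        # a day effect of -1 gives a daytime rate ~37% of the nighttime rate
        gamma = temporal_effect(_params(xi=(-1.0,)), 1.0)
        assert gamma == pytest.approx(np.exp(-1.0))
        assert 0.36 < gamma < 0.38

    def test_zero_effect_and_empty_covariate(self):
        assert temporal_effect(_params(xi=(0.0,)), 1.0) == 1.0
        assert temporal_effect(_params(), 1.0) == 1.0
        assert temporal_effect(_params(xi=(0.3, -0.2)), (0.0, 0.0)) == 1.0


class TestDetectionIntensity:
    def test_zero_distance(self):
        phi = detection_intensity(_params(), z=(), s=(1.0, 1.0), x=(1.0, 1.0))
        assert phi == pytest.approx(1.0)

    def test_half_normal_decay(self):
        phi = detection_intensity(
            _params(sigma=0.4), z=(), s=(0.0, 0.0), x=(0.4, 0.0)
        )
        assert phi == pytest.approx(np.exp(-0.5))

    def test_sigma_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            _params(sigma=0.0)


class TestExpectedCount:
    def test_homogeneous_reduces_to_T_phi(self):
        par = _params(alpha=(np.log(0.3),))
        segs = np.array([[0.0, 10.0]])
        z = np.empty((1, 0))
        assert expected_count(par, segs, z, (0, 0), (0, 0)) == pytest.approx(3.0)

    def test_day_night_closed_form_vs_quadrature(self):
        # alpha0=-0.7, xi=-1, zero distance, 30 units split 15 day + 15 night
        par = _params(alpha=(-0.7,), xi=(-1.0,))
        segs = np.array([[0.0, 15.0], [15.0, 30.0]])
        z = np.array([[1.0], [0.0]])
        closed = expected_count(par, segs, z, (0, 0), (0, 0))
        gamma_t = lambda t: np.exp(-1.0) if t <= 15.0 else 1.0
        numeric, _ = quad(
            lambda t: np.exp(-0.7) * gamma_t(t), 0, 30, points=[15.0], limit=200
        )
        assert closed == pytest.approx(numeric, rel=1e-10)
        assert closed == pytest.approx(np.exp(-0.7) * (15 + 15 * np.exp(-1.0)))

    def test_random_configurations_match_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            nseg = rng.integers(1, 6)
            bounds = np.sort(rng.uniform(0.2, 20.0, size=nseg - 1)) if nseg > 1 else []
            edges = np.concatenate([[0.0], bounds, [rng.uniform(20.0, 30.0)]])
            segs = np.column_stack([edges[:-1], edges[1:]])
            z = rng.normal(size=(nseg, 1))
            par = _params(
                alpha=(rng.normal(),), xi=(rng.normal(scale=0.5),),
                sigma=rng.uniform(0.2, 2.0),
            )
            s = rng.uniform(-1, 1, 2)
            x = rng.uniform(-1, 1, 2)
            closed = expected_count(par, segs, z, s, x)

            def gamma_t(t):
                i = np.searchsorted(edges[1:], t, side="left")
                i = min(i, nseg - 1)
                return float(np.exp(par.xi[0] * z[i, 0]))

            oracle = expected_count_numeric(
                par, gamma_t, edges[-1], s, x, points=edges[1:-1].tolist(), limit=500
            )
            assert closed == pytest.approx(oracle, rel=1e-8)

    def test_gap_in_schedule_rejected(self):
        par = _params()
        with pytest.raises(ScheduleError):
            expected_count(
                par, np.array([[0.0, 1.0], [2.0, 3.0]]), np.zeros((2, 0)), (0, 0), (0, 0)
            )


class TestObservationDensity:
    def _setup(self):
        traps = TrapArray(locations=[[0.0, 0.0]], durations=[10.0])
        sched = Schedule.constant(traps.durations)
        return traps, sched

    def test_zero_count_gives_minus_phi(self):
        traps, sched = self._setup()
        par = _params(alpha=(np.log(0.3),))
        ll = log_joint_obs_density(par, 0, [], (0, 0), 0, traps, sched)
        assert ll == pytest.approx(-3.0)

    def test_closed_form_two_detections(self):
        traps, sched = self._setup()
        par = _params(alpha=(np.log(0.3),))
        ll = log_joint_obs_density(par, 2, [1.0, 4.0], (0, 0), 0, traps, sched)
        assert ll == pytest.approx(-3.0 + 2 * np.log(0.3) - np.log(2.0))

    def test_factorization_oracle_day_night(self):
        # joint = Poisson count density x product of conditional time densities phi/Phi
        traps = TrapArray(locations=[[0.2, 0.1]], durations=[8.0])
        sched = Schedule.alternating_day_night([8.0], period=2.0)
        par = _params(alpha=(0.1,), xi=(-0.9,), sigma=0.5)
        times = np.array([0.5, 2.6, 7.0])
        s = (0.6, 0.4)
        ll = log_joint_obs_density(par, 3, times, s, 0, traps, sched)
        Phi = expected_count(par, sched.segments[0], sched.z[0], s, traps.locations[0])
        count_ld = -Phi + 3 * np.log(Phi) - gammaln(4)
        time_ld = sum(
            np.log(
                detection_intensity(par, sched.z_at(0, [t])[0], s, traps.locations[0])
                / Phi
            )
            for t in times
        )
        assert ll == pytest.approx(count_ld + time_ld, rel=1e-12)

    def test_count_time_mismatch_rejected(self):
        traps, sched = self._setup()
        with pytest.raises(DataError):
            log_joint_obs_density(_params(), 2, [1.0], (0, 0), 0, traps, sched)

    def test_time_outside_window_rejected(self):
        traps, sched = self._setup()
        with pytest.raises(DataError):
            log_joint_obs_density(_params(), 1, [11.0], (0, 0), 0, traps, sched)


class TestPi0:
    def test_no_traps_gives_one(self):
        dom = build_grid((0, 0, 1, 1), 0.25)
        assert pi0(_params(), dom, None, None) == 1.0

    def test_saturated_trap_drives_pi0_to_zero(self):
        dom = build_grid((0, 0, 1, 1), 0.25)
        traps = TrapArray(locations=[[0.5, 0.5]], durations=[10.0])
        par = _params(alpha=(15.0,), sigma=5.0)
        assert pi0(par, dom, traps, Schedule.constant(traps.durations)) < 1e-10

    def test_three_cell_brute_force(self):
        dom = build_grid(
            (0, 0, 1.5, 0.5), 0.5,
            covariate_fields=[lambda p: p[:, 0]],
        )
        traps = TrapArray(locations=[[0.3, 0.2], [1.2, 0.3]], durations=[4.0, 6.0])
        sched = Schedule.constant(traps.durations)
        par = _params(beta=(0.2, 0.7), alpha=(-0.5,), sigma=0.6)
        # independent hand-rolled loop over the 3 cells and 2 traps
        num = 0.0
        den = 0.0
        for c in dom.active_centers:
            lam = np.exp(0.2 + 0.7 * c[0])
            tot = 0.0
            for k in range(2):
                d2 = np.sum((c - traps.locations[k]) ** 2)
                tot += traps.durations[k] * np.exp(-0.5) * np.exp(-d2 / (2 * 0.36))
            num += lam * np.exp(-tot) * 0.25
            den += lam * 0.25
        assert pi0(par, dom, traps, sched) == pytest.approx(num / den, rel=1e-12)

    def test_monotone_in_duration(self):
        dom = build_grid((0, 0, 1, 1), 0.25)
        par = _params(alpha=(0.0,), sigma=0.5)
        vals = []
        for T in (1.0, 2.0, 5.0):
            traps = TrapArray(locations=[[0.5, 0.5]], durations=[T])
            vals.append(pi0(par, dom, traps, Schedule.constant(traps.durations)))
        assert vals[0] > vals[1] > vals[2] > 0


class TestLogLikelihoods:
    def test_empty_survey_reduces_to_minus_lambda(self):
        dom = build_grid((0, 0, 1, 1), 0.25)
        traps = TrapArray(locations=[[0.5, 0.5]], durations=[1.0])
        data = SurveyData(traps, [])
        par = _params(beta=(0.3,))
        ll = full_loglik(
            par, LatentState(np.empty((0, 2)), 0), data, dom,
            Schedule.constant(traps.durations),
        )
        assert ll == pytest.approx(-lambda_integral(par, dom))

    def test_full_equals_restricted_plus_time_constant_at_zero_effect(self, tiny_survey):
        # with xi = 0 the times are uniform and only the counts are informative
        data = tiny_survey["data"]
        dom = tiny_survey["domain"]
        sched = tiny_survey["schedule"]
        centers = tiny_survey["centers"][tiny_survey["observed"]]
        latent = LatentState(centers, n0=3)
        par_full = Params(beta=[1.5, 0.6], alpha=[-0.3, 0.4], xi=[0.0], sigma=0.35)
        par_rest = Params(beta=[1.5, 0.6], alpha=[-0.3, 0.4], xi=[], sigma=0.35)
        lf = full_loglik(par_full, latent, data, dom, sched)
        lr = restricted_loglik(par_rest, latent, data, dom)
        offset = float((data.y * np.log(data.traps.durations)[None, :]).sum())
        assert lf == pytest.approx(lr - offset, abs=1e-10)

    def test_relabeling_invariance(self, tiny_survey):
        data = tiny_survey["data"]
        dom = tiny_survey["domain"]
        sched = tiny_survey["schedule"]
        par = tiny_survey["params"]
        centers = tiny_survey["centers"][tiny_survey["observed"]]
        latent = LatentState(centers, n0=2)
        base = full_loglik(par, latent, data, dom, sched)
        perm = np.random.default_rng(5).permutation(data.n)
        data_perm = SurveyData(
            data.traps, [data.times[i] for i in perm], ids=[data.ids[i] for i in perm]
        )
        latent_perm = LatentState(centers[perm], n0=2)
        assert full_loglik(par, latent_perm, data_perm, dom, sched) == pytest.approx(
            base, rel=1e-12
        )

    def test_two_individual_hand_transcription(self):
        # from-scratch evaluation of the observed-data likelihood, term by term
        dom = build_grid((0, 0, 2, 1), 0.5, covariate_fields=[lambda p: p[:, 1]])
        traps = TrapArray(
            locations=[[0.5, 0.5], [1.5, 0.5]], durations=[6.0, 4.0],
            w=[[1.0, 0.2], [1.0, -0.1]],
        )
        sched = Schedule.alternating_day_night(traps.durations, period=2.0)
        par = _params(beta=(0.5, -0.3), alpha=(-0.2, 0.6), xi=(-1.2,), sigma=0.45)
        times = [
            [np.array([0.4, 3.3]), np.array([2.2])],
            [np.empty(0), np.array([1.1])],
        ]
        data = SurveyData(traps, times)
        centers = np.array([[0.6, 0.6], [1.4, 0.3]])
        latent = LatentState(centers, n0=4)

        lam = density_surface(par, dom)
        Lam = float(lam.sum() * dom.cell_area)
        p0 = pi0(par, dom, traps, sched)
        expect = -Lam + 4 * np.log(p0 * Lam) - gammaln(5)
        for i in range(2):
            v = dom.covariates_at(centers[i : i + 1])[0]
            expect += float(v @ par.beta)
            for k in range(2):
                y = data.y[i, k]
                Phi = expected_count(
                    par, sched.segments[k], sched.z[k], centers[i],
                    traps.locations[k], traps.w[k],
                )
                expect += -Phi - gammaln(y + 1)
                for t in times[i][k]:
                    z = sched.z_at(k, [t])[0]
                    expect += np.log(
                        detection_intensity(par, z, centers[i], traps.locations[k], traps.w[k])
                    )
        got = full_loglik(par, latent, data, dom, sched)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_fast_path_matches_reference(self, tiny_survey):
        data = tiny_survey["data"]
        dom = tiny_survey["domain"]
        sched = tiny_survey["schedule"]
        par = tiny_survey["params"]
        centers = tiny_survey["centers"][tiny_survey["observed"]]
        latent = LatentState(centers, n0=5)
        slow = full_loglik(par, latent, data, dom, sched)
        fast = fast_loglik(par, latent, data, dom, sched, model="full")
        assert fast == pytest.approx(slow, rel=1e-10)
        par_r = Params(beta=par.beta, alpha=par.alpha, xi=[], sigma=par.sigma)
        slow_r = restricted_loglik(par_r, latent, data, dom)
        fast_r = fast_loglik(par_r, latent, data, dom, None, model="restricted")
        assert fast_r == pytest.approx(slow_r, rel=1e-10)

    def test_restricted_rejects_temporal_effects(self, tiny_survey):
        data = tiny_survey["data"]
        dom = tiny_survey["domain"]
        latent = LatentState(np.full((data.n, 2), 1.0), n0=0)
        with pytest.raises(ConfigurationError):
            restricted_loglik(tiny_survey["params"], latent, data, dom)

    def test_center_in_masked_cell_rejected(self):
        dom = build_grid((0, 0, 1, 1), 0.5, mask_predicate=lambda p: p[:, 0] < 0.5)
        traps = TrapArray(locations=[[0.25, 0.25]], durations=[1.0])
        data = SurveyData(traps, [[np.array([0.5])]])
        latent = LatentState(np.array([[0.75, 0.75]]), n0=0)
        with pytest.raises(DomainError):
            full_loglik(_params(), latent, data, dom, Schedule.constant(traps.durations))


class TestSurveyData:
    def test_invariants_enforced(self):
        traps = TrapArray(locations=[[0, 0]], durations=[2.0])
        with pytest.raises(DataError):
            SurveyData(traps, [[np.array([2.5])]])
        with pytest.raises(DataError):
            SurveyData(traps, [[np.array([-0.1])]])

    def test_tied_times_warn_but_pass(self):
        traps = TrapArray(locations=[[0, 0]], durations=[2.0])
        with pytest.warns(UserWarning):
            data = SurveyData(traps, [[np.array([1.0, 1.0])]])
        assert data.y[0, 0] == 2
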