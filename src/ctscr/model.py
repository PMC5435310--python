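"""Probability computations for the continuous-time SCR model.

The hierarchical model couples two point processes:

* a spatial Poisson process of latent activity centers over the region B,
  with log-linear intensity  log λ(s) = β'v(s),  so the population size
  N(B) is Poisson with mean Λ(B) = ∫_B λ(s) ds;
* for each individual i and trap k, an inhomogeneous temporal Poisson
  process of detection times on (0, T_k] with intensity

      φ(t, s_i, x_k) = ψ_k γ(t) exp(−||s_i − x_k||² / (2σ²)),

  where log ψ_k = α'w_k is the trap's baseline encounter rate and
  log γ(t) = ξ'z(t) modulates the rate by temporal covariates (a day/night
  indicator in the canonical analysis).

The observed-data likelihood augments the n detected individuals with the
latent count n0 of never-detected ones via the probability π0 that an
individual living in B produces no detections at any trap.

A restricted (time-homogeneous) variant drops γ(t) and uses only the
detection-count matrix; its per-pair term is the Poisson count likelihood
with mean T_k·φ(s_i, x_k).  The temporal parameters are then not
identifiable and must not be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln

from .geometry import Domain, DomainError, TrapArray, squared_distances
from .schedule import Schedule, ScheduleError

__all__ = [
    "Params",
    "SurveyData",
    "LatentState",
    "density_surface",
    "lambda_integral",
    "temporal_effect",
    "detection_intensity",
    "expected_count",
    "expected_count_numeric",
    "log_joint_obs_density",
    "pi0",
    "full_loglik",
    "restricted_loglik",
]


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class Params:
    """Model parameters θ = (β, α, ξ, σ).

    beta : density coefficients (log scale), matching Domain covariates.
    alpha : baseline-encounter-rate coefficients, matching trap covariates.
    xi : temporal-covariate effects; empty for the restricted model.
    sigma : Gaussian movement-scale (same length units as coordinates).
    """

    beta: np.ndarray
    alpha: np.ndarray
    xi: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.xi = np.asarray(self.xi, dtype=float).reshape(-1)
        self.sigma = float(self.sigma)
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")


@dataclass
class LatentState:
    """Latent activity centers of observed individuals and the count n0
    of never-detected individuals (N = n + n0)."""

    centers: np.ndarray
    n0: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.n0 = int(self.n0)
        if self.n0 < 0:
            raise ValueError("n0 must be nonnegative")


class SurveyData:
    """Detections of the n observed individuals across K traps.

    ``times[i][k]`` is the ascending array of detection times of individual
    i at trap k (trap-relative, in (0, T_k]); the count matrix ``y`` is
    derived from the sequence lengths.
    """

    def __init__(self, traps: TrapArray, times: list[list[np.ndarray]], ids=None):
        self.traps = traps
        K = traps.n_traps
        self.times: list[list[np.ndarray]] = []
        tied = False
        for i, row in enumerate(times):
            if len(row) != K:
                raise DataError(f"individual {i}: expected {K} per-trap sequences")
            clean = []
            for k, t in enumerate(row):
                t = np.sort(np.atleast_1d(np.asarray(t, dtype=float))) if np.size(t) else np.empty(0)
                if t.size:
                    if t.min() <= 0 or t.max() > traps.durations[k] + 1e-9:
                        raise DataError(
                            f"individual {i}, trap {k}: time outside (0, T_k]"
                        )
                    if np.any(np.diff(t) == 0):
                        tied = True
                clean.append(t)
            self.times.append(clean)
        if tied:
            warnings.warn(
                "tied detection times present; the Poisson process assigns "
                "them probability zero but the density product handles them",
                stacklevel=2,
            )
        self.y = np.array(
            [[t.size for t in row] for row in self.times], dtype=int
        ).reshape(len(self.times), K)
        self.ids = list(ids) if ids is not None else list(range(len(self.times)))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.y.sum())

    def z_sums(self, schedule: Schedule) -> np.ndarray:
        """Σ over all detection events of z(t_event)  (length-q vector)."""
        q = schedule.q
        total = np.zeros(q)
        for row in self.times:
            for k, t in enumerate(row):
                if t.size:
                    total += schedule.z_at(k, t).sum(axis=0)
        return total


# ---------------------------------------------------------------------------
# intensities and integrals
# ---------------------------------------------------------------------------


def density_surface(params: Params, domain: Domain) -> np.ndarray:
    """Activity-center intensity λ(s) = exp(β'v(s)) at habitat cell centers."""
    if params.beta.size != domain.n_covariates:
        raise ConfigurationError(
            f"beta has {params.beta.size} entries but domain has "
            f"{domain.n_covariates} covariates"
        )
    return np.exp(domain.active_v @ params.beta)


def lambda_integral(params: Params, domain: Domain) -> float:
    """Expected population size Λ(B) by midpoint quadrature over habitat cells."""
    return float(density_surface(params, domain).sum() * domain.cell_area)


def temporal_effect(params: Params, z) -> float:
    """Multiplicative temporal modulation γ = exp(ξ'z); 1 when ξ is empty."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if params.xi.size == 0:
        return 1.0
    if z.size != params.xi.size:
        raise ConfigurationError("temporal covariate dimension mismatch")
    return float(np.exp(params.xi @ z))


def baseline_rates(params: Params, traps: TrapArray) -> np.ndarray:
    """Per-trap baseline encounter rate ψ_k = exp(α'w_k)."""
    if params.alpha.size != traps.w.shape[1]:
        raise ConfigurationError("alpha/trap-covariate dimension mismatch")
    return np.exp(traps.w @ params.alpha)


def detection_intensity(params: Params, z, s, x, w=None) -> float:
    """Detection intensity φ = ψ γ(z) exp(−||s−x||²/(2σ²)) at one time point.

    ``w`` is the trap covariate vector (defaults to intercept-only).
    """
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.ones(params.alpha.size) if w is None else np.atleast_1d(np.asarray(w, float))
    psi = float(np.exp(params.alpha @ w))
    d2 = float(np.sum((s - x) ** 2))
    return psi * temporal_effect(params, z) * np.exp(-d2 / (2.0 * params.sigma**2))


def expected_count(params: Params, segments: np.ndarray, z: np.ndarray, s, x, w=None) -> float:
    """Expected detections Φ(T_k, s, x_k) = ∫_0^{T_k} φ(t) dt, closed form.

    For piecewise-constant temporal covariates the integral factorizes as
    ψ exp(−d²/2σ²) Σ_seg exp(ξ'z_seg)·len_seg; with γ constant this reduces
    to T_k·φ.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if not np.isclose(segments[0, 0], 0.0) or not np.allclose(
        segments[1:, 0], segments[:-1, 1]
    ):
        raise ScheduleError("schedule segments must tile (0, T_k] without gaps")
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.ones(params.alpha.size) if w is None else np.atleast_1d(np.asarray(w, float))
    psi = float(np.exp(params.alpha @ w))
    d2 = float(np.sum((s - x) ** 2))
    lens = segments[:, 1] - segments[:, 0]
    gamma = np.exp(z @ params.xi) if params.xi.size else np.ones_like(lens)
    return psi * np.exp(-d2 / (2.0 * params.sigma**2)) * float(gamma @ lens)


def expected_count_numeric(
    params: Params, gamma_of_t, T: float, s, x, w=None, **quad_kw
) -> float:
    """Numerical fallback for arbitrary γ(t): adaptive quadrature of φ over (0, T]."""
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.ones(params.alpha.size) if w is None else np.atleast_1d(np.asarray(w, float))
    psi = float(np.exp(params.alpha @ w))
    d2 = float(np.sum((s - x) ** 2))
    kern = psi * np.exp(-d2 / (2.0 * params.sigma**2))
    val, _ = quad(lambda t: kern * gamma_of_t(t), 0.0, T, **quad_kw)
    return float(val)


def log_joint_obs_density(
    params: Params,
    y_ik: int,
    t_ik: np.ndarray,
    s,
    trap_index: int,
    traps: TrapArray,
    schedule: Schedule,
) -> float:
    """Log joint density of (y_ik, t_ik) given the activity center:
    log[(1/y!) exp(−Φ) Π_j φ(t_j)].  Returns −Φ when y_ik = 0."""
    k = trap_index
    t_ik = np.atleast_1d(np.asarray(t_ik, dtype=float)) if np.size(t_ik) else np.empty(0)
    if int(y_ik) != t_ik.size:
        raise DataError("count y_ik must equal the number of detection times")
    T_k = traps.durations[k]
    if t_ik.size and (t_ik.min() <= 0 or t_ik.max() > T_k + 1e-9):
        raise DataError("detection time outside (0, T_k]")
    Phi = expected_count(
        params, schedule.segments[k], schedule.z[k], s, traps.locations[k], traps.w[k]
    )
    out = -Phi - gammaln(y_ik + 1)
    for t in t_ik:
        z = schedule.z_at(k, t)[0]
        out += np.log(
            detection_intensity(params, z, s, traps.locations[k], traps.w[k])
        )
    return float(out)


def _phi_matrix(
    params: Params, domain: Domain, traps: TrapArray, schedule: Schedule
) -> np.ndarray:
    """Φ(T_k, c_m, x_k) over habitat cells × traps (vectorized)."""
    d2 = squared_distances(domain, traps)
    psi = baseline_rates(params, traps)
    eff = schedule.effective_durations(params.xi)
    return np.exp(-d2 / (2.0 * params.sigma**2)) * (psi * eff)[None, :]


def pi0(
    params: Params, domain: Domain, traps: TrapArray | None, schedule: Schedule | None
) -> float:
    """Probability that an individual living in B is never detected.

    π0 = Λ(B)⁻¹ ∫_B λ(s) Π_k exp[−Φ(T_k, s, x_k)] ds  (midpoint quadrature).
    With no traps the empty product gives π0 = 1.
    """
    lam = density_surface(params, domain)
    Lam = lam.sum() * domain.cell_area
    if traps is None or traps.n_traps == 0:
        return 1.0
    E = _phi_matrix(params, domain, traps, schedule).sum(axis=1)
    return float((lam * np.exp(-E)).sum() * domain.cell_area / Lam)


# ---------------------------------------------------------------------------
# log-likelihoods
# ---------------------------------------------------------------------------


def _check_centers(domain: Domain, centers: np.ndarray) -> None:
    if centers.shape[0] and not np.all(domain.is_habitat(centers)):
        raise DomainError("an activity center lies in a masked or out-of-bounds cell")


def full_loglik(
    params: Params,
    latent: LatentState,
    data: SurveyData,
    domain: Domain,
    schedule: Schedule,
) -> float:
    """Observed-data log-likelihood of the continuous-time model.

    log L = −Λ(B) + n0·log(π0 Λ(B)) − log(n0!) + Σ_i log λ(s_i)
            + Σ_i Σ_k log[(1/y_ik!) exp(−Φ_ik) Π_j φ(t_ikj)]
    """
    _check_centers(domain, latent.centers)
    lam_cells = density_surface(params, domain)
    Lam = lam_cells.sum() * domain.cell_area
    p0 = pi0(params, domain, data.traps, schedule)
    out = -Lam - gammaln(latent.n0 + 1)
    if latent.n0 > 0:
        out += latent.n0 * np.log(p0 * Lam)
    if data.n:
        v_at = domain.covariates_at(latent.centers)
        out += float((v_at @ params.beta).sum())
        for i in range(data.n):
            for k in range(data.traps.n_traps):
                out += log_joint_obs_density(
                    params,
                    data.y[i, k],
                    data.times[i][k],
                    latent.centers[i],
                    k,
                    data.traps,
                    schedule,
                )
    return float(out)


def restricted_loglik(
    params: Params,
    latent: LatentState,
    data: SurveyData,
    domain: Domain,
) -> float:
    """Counts-only log-likelihood of the time-homogeneous restricted model.

    Detection times are ignored: y_ik | s_i ~ Poisson(T_k φ(s_i, x_k)).
    Temporal effects are not identifiable here; supplying them is an error.
    """
    if params.xi.size:
        raise ConfigurationError(
            "restricted model has no temporal effects: gamma cannot be "
            "identified separately from the baseline intercept"
        )
    _check_centers(domain, latent.centers)
    traps = data.traps
    lam_cells = density_surface(params, domain)
    Lam = lam_cells.sum() * domain.cell_area
    sched = Schedule.constant(traps.durations)
    p0 = pi0(params, domain, traps, sched)
    out = -Lam - gammaln(latent.n0 + 1)
    if latent.n0 > 0:
        out += latent.n0 * np.log(p0 * Lam)
    if data.n:
        v_at = domain.covariates_at(latent.centers)
        out += float((v_at @ params.beta).sum())
        d2 = np.sum(
            (latent.centers[:, None, :] - traps.locations[None, :, :]) ** 2, axis=2
        )
        phi = baseline_rates(params, traps)[None, :] * np.exp(
            -d2 / (2.0 * params.sigma**2)
        )
        mean = traps.durations[None, :] * phi
        with np.errstate(divide="ignore", invalid="ignore"):
            term = -mean + np.where(data.y > 0, data.y * np.log(mean), 0.0)
        out += float(term.sum() - gammaln(data.y + 1).sum())
    return float(out)
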