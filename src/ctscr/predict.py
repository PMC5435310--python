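"""Posterior prediction: unobserved activity centers, abundance maps, and
derived ecological quantities (density, home-range area).

An individual that was never detected carries spatial information through
the thinned intensity λ(s)·Π_k exp[−Φ(T_k, s, x_k)]: its activity center is
more likely to lie where density is high and trap exposure low.  Centers of
the n0 never-detected individuals are drawn from that density, discretized
at the quadrature grid with uniform jitter inside the chosen cell, freshly
for every retained MCMC iteration, so map summaries average over the full
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .geometry import Domain, TrapArray, squared_distances
from .model import Params, baseline_rates, density_surface
from .sampler import PosteriorChain
from .schedule import Schedule

__all__ = [
    "AbundanceMap",
    "sample_unobserved_centers",
    "abundance_map",
    "density_estimate",
    "home_range_area",
]


@dataclass
class AbundanceMap:
    """Gridded posterior summaries of cell abundance N(B_m)."""

    cell_centers: np.ndarray  # (M, 2)
    resolution: float
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.cell_centers.shape[0]),
                "x": self.cell_centers[:, 0],
                "y": self.cell_centers[:, 1],
                "mean": self.mean,
                "lo": self.lo,
                "hi": self.hi,
            }
        )


def _unobserved_weights(
    params: Params, domain: Domain, traps: TrapArray | None, schedule: Schedule | None
) -> np.ndarray:
    lam = density_surface(params, domain)
    if traps is not None and traps.n_traps:
        d2 = squared_distances(domain, traps)
        psi = baseline_rates(params, traps)
        eff = (
            schedule.effective_durations(params.xi)
            if schedule is not None
            else traps.durations
        )
        E = np.exp(-d2 / (2.0 * params.sigma**2)) @ (psi * eff)
    else:
        E = np.zeros(domain.n_active)
    return lam * np.exp(-E) * domain.cell_area


def sample_unobserved_centers(
    params: Params,
    n0: int,
    domain: Domain,
    traps: TrapArray | None,
    schedule: Schedule | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n0 activity centers from [s | never detected] ∝ λ(s) Π_k e^{−Φ}.

    Cell-discrete draw over habitat cells with uniform jitter within the
    chosen cell.
    """
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if n0 == 0:
        return np.empty((0, 2))
    w = _unobserved_weights(params, domain, traps, schedule)
    tot = w.sum()
    if tot <= 0 or not np.isfinite(tot):
        raise ValueError("degenerate unobserved-center distribution (all weights zero)")
    idx = rng.choice(domain.n_active, size=n0, p=w / tot)
    half = domain.resolution / 2.0
    jitter = rng.uniform(-half, half, size=(n0, 2))
    return domain.active_centers[idx] + jitter


def abundance_map(
    chain: PosteriorChain,
    domain: Domain,
    traps: TrapArray | None,
    schedule: Schedule | None,
    map_resolution: float,
    seed: int | None = None,
) -> AbundanceMap:
    """Posterior mean and 95% interval of per-cell abundance N(B_m).

    For each retained iteration the observed-individual centers from the
    chain are combined with a fresh draw of the n0 unobserved centers, and
    all centers are binned on a grid of ``map_resolution`` laid over the
    domain bounds.  Summaries are taken across iterations.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    if map_resolution < domain.resolution - 1e-12:
        raise ValueError(
            "map grid must be nested in (no finer than) the quadrature grid"
        )
    xmin, ymin, xmax, ymax = domain.bounds
    nx = int(np.ceil((xmax - xmin) / map_resolution - 1e-9))
    ny = int(np.ceil((ymax - ymin) / map_resolution - 1e-9))
    xs = xmin + map_resolution * (np.arange(nx) + 0.5)
    ys = ymin + map_resolution * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys)
    map_centers = np.column_stack([gx.ravel(), gy.ravel()])

    p_beta = sum(1 for s in chain.param_names if s.startswith("beta_"))
    p_alpha = sum(1 for s in chain.param_names if s.startswith("alpha_"))
    q = sum(1 for s in chain.param_names if s.startswith("xi_"))

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(chain), nx * ny))
    for i in range(len(chain)):
        params = chain.params_at(i, p_beta, p_alpha, q)
        pts = [chain.centers[i]]
        n0 = int(chain.n0[i])
        if n0:
            pts.append(
                sample_unobserved_centers(params, n0, domain, traps, schedule, rng)
            )
        allpts = np.vstack(pts) if pts else np.empty((0, 2))
        if allpts.shape[0]:
            ix = np.clip(
                np.floor((allpts[:, 0] - xmin) / map_resolution).astype(int), 0, nx - 1
            )
            iy = np.clip(
                np.floor((allpts[:, 1] - ymin) / map_resolution).astype(int), 0, ny - 1
            )
            np.add.at(counts[i], iy * nx + ix, 1)
    return AbundanceMap(
        cell_centers=map_centers,
        resolution=map_resolution,
        mean=counts.mean(axis=0),
        lo=np.percentile(counts, 2.5, axis=0),
        hi=np.percentile(counts, 97.5, axis=0),
    )


def density_estimate(
    chain: PosteriorChain, domain: Domain, area_unit: float = 1.0
) -> dict[str, float]:
    """Posterior mean and 95% interval of population density.

    Per iteration the density is (n + n0)/|B| scaled to ``area_unit``
    (e.g. 100 for individuals per 100 km² with km coordinates).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    dens = (chain.n_observed + chain.n0) / domain.total_area * area_unit
    return {
        "mean": float(dens.mean()),
        "lo": float(np.percentile(dens, 2.5)),
        "hi": float(np.percentile(dens, 97.5)),
    }


def home_range_area(sigma: float, quantile: float = 0.95) -> float:
    """Area of the circular home range containing the given probability mass
    of a bivariate Gaussian movement kernel: π σ² χ²_{2,q}."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.pi * sigma**2 * chi2.ppf(quantile, df=2))
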