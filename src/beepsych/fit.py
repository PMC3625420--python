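"""Bayesian estimation of psychometric-function parameters from choice counts.

The likelihood is binomial: at each relative intensity ``x_i`` the forager
made ``n_total_i`` visits of which ``n_sweeter_i`` went to the sweeter
option, with success probability ``Psi(x_i; m, s, pi_l)``.  Priors follow the
study protocol: threshold ~ Normal(1, 0.5) truncated to (0, inf), slope ~
Normal(2, 1) truncated to (0, inf) (optionally flat on (0, s_max]), lapse ~
Beta(2, 20) — a prior that tolerates the elevated lapse rates produced by
exploratory foraging.  Truncation renormalisation constants are omitted;
they shift the evidence, not the posterior.

Sampling runs on the transformed coordinates ``(ln m, ln s, logit pi_l)``
with the appropriate Jacobian, using an affine-invariant ensemble sampler.
A deterministic 3-D grid integration (`grid_posterior`) serves as an
independent brute-force check of the sampler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

import emcee

from .psychometric import PsychometricParams, psychometric_value

__all__ = [
    "ResponseRecord",
    "PriorSpec",
    "McmcConfig",
    "ParamEstimate",
    "PosteriorSummary",
    "log_posterior",
    "fit_psychometric",
    "grid_posterior",
    "read_response_csv",
    "write_response_csv",
    "GridResolutionError",
]

PARAM_NAMES = ("threshold", "slope", "lapse")


@dataclass(frozen=True)
class ResponseRecord:
    """One binomial observation: visits to the sweeter option out of all visits."""

    intensity_x: float
    n_sweeter: int
    n_total: int

    def __post_init__(self) -> None:
        if not self.intensity_x > 0:
            raise ValueError(f"intensity_x must be positive, got {self.intensity_x}")
        if self.n_total <= 0:
            raise ValueError(f"n_total must be positive, got {self.n_total}")
        if not 0 <= self.n_sweeter <= self.n_total:
            raise ValueError(
                f"n_sweeter must lie in [0, n_total], got {self.n_sweeter}/{self.n_total}"
            )

    @property
    def response(self) -> float:
        return self.n_sweeter / self.n_total


@dataclass(frozen=True)
class PriorSpec:
    """Priors for (threshold, slope, lapse).

    ``slope_flat=True`` replaces the normal slope prior with an improper
    uniform on (0, ``slope_max``], used to remove prior shrinkage when
    studying slope bias.
    """

    threshold_mean: float = 1.0
    threshold_sd: float = 0.5
    slope_mean: float = 2.0
    slope_sd: float = 1.0
    slope_flat: bool = False
    slope_max: float = 50.0
    lapse_a: float = 2.0
    lapse_b: float = 20.0

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0 or self.slope_sd <= 0:
            raise ValueError("prior standard deviations must be positive")
        if self.lapse_a <= 0 or self.lapse_b <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.slope_max <= 0:
            raise ValueError("slope_max must be positive")

    def log_density(self, m: float, s: float, pl: float) -> float:
        """Natural-scale log prior density; -inf outside support."""
        if not (m > 0 and s > 0 and 0.0 < pl < 1.0):
            return -np.inf
        lp = stats.norm.logpdf(m, self.threshold_mean, self.threshold_sd)
        if self.slope_flat:
            if s > self.slope_max:
                return -np.inf
        else:
            lp += stats.norm.logpdf(s, self.slope_mean, self.slope_sd)
        lp += stats.beta.logpdf(pl, self.lapse_a, self.lapse_b)
        return float(lp)


@dataclass(frozen=True)
class McmcConfig:
    """Ensemble-sampler settings.

    ``n_draws`` retained draws are pooled across ``n_walkers`` chains after
    discarding ``burn_in`` ensemble steps (default: 25 % of the kept steps,
    i.e. 20 % of the total chain).
    """

    n_draws: int = 5000
    n_walkers: int = 32
    burn_in: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ValueError("n_draws must be positive")
        if self.n_walkers < 8:
            raise ValueError("need at least 8 walkers for a 3-parameter ensemble")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")

    @property
    def keep_steps(self) -> int:
        return -(-self.n_draws // self.n_walkers)

    @property
    def burn_steps(self) -> int:
        return self.burn_in if self.burn_in is not None else -(-self.keep_steps // 4)


@dataclass(frozen=True)
class ParamEstimate:
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class PosteriorSummary:
    """Posterior means and central 95 % credible intervals per parameter."""

    threshold: ParamEstimate
    slope: ParamEstimate
    lapse: ParamEstimate
    draws: np.ndarray | None = None  # (n, 3) columns threshold, slope, lapse
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            est = getattr(self, name)
            if not est.ci_low <= est.mean <= est.ci_high:
                raise ValueError(f"{name}: mean outside credible interval")

    @property
    def mean_params(self) -> PsychometricParams:
        return PsychometricParams(
            self.threshold.mean, self.slope.mean, self.lapse.mean
        )

    def to_dict(self) -> dict:
        out = {
            name: vars(getattr(self, name)) for name in PARAM_NAMES
        }
        out["diagnostics"] = {
            k: (v if not isinstance(v, np.generic) else v.item())
            for k, v in self.diagnostics.items()
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _data_arrays(data: Sequence[ResponseRecord]):
    x = np.array([r.intensity_x for r in data], dtype=float)
    k = np.array([r.n_sweeter for r in data], dtype=float)
    n = np.array([r.n_total for r in data], dtype=float)
    return x, k, n


def log_posterior(
    params: PsychometricParams | tuple,
    data: Sequence[ResponseRecord],
    priors: PriorSpec,
    likelihood_weight: float = 1.0,
) -> float:
    """Unnormalised log posterior density on the natural parameter scale.

    Returns ``-inf`` (never raises) for parameter values outside the prior
    support.  ``likelihood_weight=0`` disables the data term, leaving the
    prior alone — useful for prior-recovery checks.
    """
    if isinstance(params, PsychometricParams):
        m, s, pl = params.threshold_m, params.slope_s, params.lapse_pi
    else:
        m, s, pl = params
    if not data:
        raise ValueError("data must be non-empty")
    lp = priors.log_density(m, s, pl)
    if not np.isfinite(lp):
        return -np.inf
    if likelihood_weight != 0.0:
        x, k, n = _data_arrays(data)
        psi = psychometric_value(x, PsychometricParams(m, s, pl))
        psi = np.clip(psi, 1e-300, 1.0 - 1e-16)
        lp += likelihood_weight * float(
            np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))
        )
    return lp


# ---------------------------------------------------------------------------
# transformed-space machinery

def _to_natural(theta: np.ndarray):
    m = np.exp(theta[..., 0])
    s = np.exp(theta[..., 1])
    pl = 1.0 / (1.0 + np.exp(-theta[..., 2]))
    return m, s, pl


def _log_prob_transformed(theta, x, k, n, priors, likelihood_weight):
    lm, ls, lpl = theta
    if abs(lm) > 30 or abs(ls) > 30 or abs(lpl) > 30:
        return -np.inf
    m, s = np.exp(lm), np.exp(ls)
    pl = 1.0 / (1.0 + np.exp(-lpl))
    lp = priors.log_density(m, s, pl)
    if not np.isfinite(lp):
        return -np.inf
    # Jacobian of (ln m, ln s, logit pi): m * s * pi * (1 - pi)
    lp += lm + ls + np.log(pl) + np.log1p(-pl)
    if likelihood_weight != 0.0:
        psi = psychometric_value(x, PsychometricParams(m, s, pl))
        psi = np.clip(psi, 1e-300, 1.0 - 1e-16)
        lp += likelihood_weight * float(
            np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi))
        )
    return lp


def _ensemble_ess(chain: np.ndarray) -> np.ndarray:
    """Effective sample size per parameter from a (steps, walkers, dim) chain."""
    import arviz as az

    ds = az.convert_to_dataset(
        {name: np.swapaxes(chain[:, :, i], 0, 1) for i, name in enumerate(PARAM_NAMES)}
    )
    ess = az.ess(ds)
    return np.array([float(ess[name]) for name in PARAM_NAMES])


def _summarize(draws: np.ndarray, diagnostics: dict) -> PosteriorSummary:
    ests = {}
    for i, name in enumerate(PARAM_NAMES):
        col = draws[:, i]
        lo, hi = np.percentile(col, [2.5, 97.5])
        ests[name] = ParamEstimate(float(col.mean()), float(lo), float(hi))
    return PosteriorSummary(
        ests["threshold"], ests["slope"], ests["lapse"], draws, diagnostics
    )


def fit_psychometric(
    data: Sequence[ResponseRecord],
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    likelihood_weight: float = 1.0,
) -> PosteriorSummary:
    """Sample the posterior over (threshold, slope, lapse) and summarize it.

    The ensemble is initialised in a small ball around the posterior mode
    (found by Nelder–Mead on the transformed coordinates), run for
    ``burn_steps + keep_steps`` steps, and the post-burn-in draws pooled
    across walkers.  Reproducible bit-for-bit given ``config.seed``.
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    if not data:
        raise ValueError("data must be non-empty")
    x, k, n = _data_arrays(data)
    diagnostics: dict = {"warnings": []}
    n_distinct = len(np.unique(x))
    if n_distinct < 3:
        msg = (
            f"only {n_distinct} distinct intensity value(s); "
            "the fit may be poorly conditioned"
        )
        warnings.warn(msg)
        diagnostics["warnings"].append(msg)
        if n_distinct == 1:
            diagnostics["prior_dominated"] = True

    args = (x, k, n, priors, likelihood_weight)
    rs = np.random.RandomState(config.seed)

    start = np.array([np.log(0.5), np.log(2.0), np.log(0.1 / 0.9)])
    res = optimize.minimize(
        lambda t: -_log_prob_transformed(t, *args),
        start,
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8},
    )
    mode = res.x if np.isfinite(res.fun) else start

    nw = config.n_walkers
    p0 = mode + 0.05 * rs.randn(nw, 3)
    # ensure every walker starts at finite posterior density
    for i in range(nw):
        for _ in range(100):
            if np.isfinite(_log_prob_transformed(p0[i], *args)):
                break
            p0[i] = mode + 0.05 * rs.randn(3)

    sampler = emcee.EnsembleSampler(nw, 3, _log_prob_transformed, args=args)
    state = emcee.State(p0, random_state=rs.get_state())
    total = config.burn_steps + config.keep_steps
    sampler.run_mcmc(state, total, progress=False)

    chain = sampler.get_chain(discard=config.burn_steps)  # (steps, walkers, 3)
    flat = chain.reshape(-1, 3)
    draws = np.column_stack(_to_natural(flat))[: config.n_draws]

    diagnostics["acceptance_fraction"] = float(sampler.acceptance_fraction.mean())
    nat_chain = np.stack(_to_natural(chain), axis=-1)
    try:
        diagnostics["ess"] = dict(zip(PARAM_NAMES, _ensemble_ess(nat_chain).tolist()))
    except Exception:  # pragma: no cover - diagnostics must never kill a fit
        diagnostics["ess"] = None
    diagnostics["n_draws"] = int(len(draws))
    diagnostics["burn_steps"] = int(config.burn_steps)
    diagnostics["seed"] = int(config.seed)
    return _summarize(draws, diagnostics)


# ---------------------------------------------------------------------------
# brute-force grid oracle

class GridResolutionError(RuntimeError):
    """Raised when halving the grid resolution shifts the posterior mass by >1 %."""


def _default_grid(priors: PriorSpec):
    m_hi = priors.threshold_mean + 5 * priors.threshold_sd
    if priors.slope_flat:
        s_hi = priors.slope_max
    else:
        s_hi = priors.slope_mean + 5 * priors.slope_sd
    return {
        "threshold": (1e-4, m_hi, 220),
        "slope": (1e-3, s_hi, 220),
        "lapse": (1e-5, 0.999, 160),
    }


def _grid_log_density(axes: dict, x, k, n, priors: PriorSpec) -> np.ndarray:
    """Log posterior on the outer product of the three axes."""
    M = axes["threshold"][:, None, None]
    S = axes["slope"][None, :, None]
    P = axes["lapse"][None, None, :]
    lp = stats.norm.logpdf(M, priors.threshold_mean, priors.threshold_sd)
    if priors.slope_flat:
        lp = lp + np.zeros_like(S)
    else:
        lp = lp + stats.norm.logpdf(S, priors.slope_mean, priors.slope_sd)
    lp = lp + stats.beta.logpdf(P, priors.lapse_a, priors.lapse_b)
    ln2 = np.log(2.0)
    for xi, ki, ni in zip(x, k, n):
        arg = (2.0 * S * M / ln2) * (np.log(xi) - np.log(M)) + np.log(ln2)
        arg = np.clip(arg, -700, 700)
        psi = 0.5 * (P + (1.0 - P) * (2.0 - np.exp(-np.exp(arg))))
        psi = np.clip(psi, 1e-300, 1 - 1e-16)
        lp = lp + ki * np.log(psi) + (ni - ki) * np.log1p(-psi)
    return lp


def _zoom_bounds(axes: dict, w: np.ndarray, tail: float = 1e-6) -> dict:
    """Per-axis interval holding all but a ``tail`` of the posterior mass."""
    out = {}
    for i, name in enumerate(PARAM_NAMES):
        marg = w.sum(axis=tuple(j for j in range(3) if j != i))
        cdf = np.cumsum(marg) / marg.sum()
        ax = axes[name]
        lo_i = int(np.searchsorted(cdf, tail))
        hi_i = int(np.searchsorted(cdf, 1.0 - tail))
        lo_i = max(lo_i - 2, 0)
        hi_i = min(hi_i + 2, len(ax) - 1)
        out[name] = (float(ax[lo_i]), float(ax[hi_i]))
    return out


def grid_posterior(
    data: Sequence[ResponseRecord],
    priors: PriorSpec | None = None,
    grid: dict | None = None,
    check_resolution: bool = True,
) -> PosteriorSummary:
    """Deterministic posterior summary by normalized summation on a 3-D grid.

    With ``grid=None`` (default) the posterior is first located on a coarse
    grid spanning well over 99.9 % of the prior mass per parameter, then
    re-evaluated at full resolution on the interval holding essentially all
    posterior mass — so resolution is spent where the density lives.  An
    explicit ``grid`` (name -> ``(low, high, n_points)``) is used as given.
    Posterior means and credible bounds come from the gridded density with
    midpoint weights; no sampling is involved.
    """
    priors = priors or PriorSpec()
    if not data:
        raise ValueError("data must be non-empty")
    x, k, n = _data_arrays(data)

    def build_axes(spec: dict) -> dict:
        axes = {}
        for name in PARAM_NAMES:
            lo, hi, npts = spec[name]
            if not (0 < lo < hi and npts >= 8):
                raise ValueError(f"bad grid for {name}: {spec[name]}")
            axes[name] = np.linspace(lo, hi, int(npts))
        return axes

    if grid is None:
        wide = _default_grid(priors)
        coarse = build_axes({nm: (lo, hi, 72) for nm, (lo, hi, _) in wide.items()})
        lp0 = _grid_log_density(coarse, x, k, n, priors)
        bounds = _zoom_bounds(coarse, np.exp(lp0 - lp0.max()))
        axes = build_axes(
            {nm: bounds[nm] + (wide[nm][2],) for nm in PARAM_NAMES}
        )
    else:
        axes = build_axes(grid)

    lp = _grid_log_density(axes, x, k, n, priors)
    lp -= lp.max()
    w = np.exp(lp)

    if check_resolution:
        # compare total mass (cell-weighted) against the half-resolution grid
        def mass(wa, ax):
            steps = [ax[name][1] - ax[name][0] for name in PARAM_NAMES]
            return wa.sum() * np.prod(steps)

        full = mass(w, axes)
        half_axes = {name: axes[name][::2] for name in PARAM_NAMES}
        half = mass(w[::2, ::2, ::2], half_axes)
        if abs(full - half) / full > 0.01:
            raise GridResolutionError(
                f"posterior mass changes by {abs(full - half) / full:.1%} when the "
                "grid is coarsened; increase the resolution"
            )

    w /= w.sum()
    ests = {}
    for i, name in enumerate(PARAM_NAMES):
        marg = w.sum(axis=tuple(j for j in range(3) if j != i))
        ax = axes[name]
        mean = float(np.sum(marg * ax))
        cdf = np.cumsum(marg)
        lo = float(np.interp(0.025, cdf, ax))
        hi = float(np.interp(0.975, cdf, ax))
        lo, hi = min(lo, mean), max(hi, mean)
        ests[name] = ParamEstimate(mean, lo, hi)
    diagnostics = {"method": "grid", "grid": {k2: tuple(map(float, (axes[k2][0], axes[k2][-1]))) + (len(axes[k2]),) for k2 in PARAM_NAMES}}
    return PosteriorSummary(
        ests["threshold"], ests["slope"], ests["lapse"], None, diagnostics
    )


# ---------------------------------------------------------------------------
# CSV interfaces

def read_response_csv(path) -> list[ResponseRecord]:
    """Read a response table (columns: intensity, n_sweeter, n_total)."""
    df = pd.read_csv(path)
    required = {"intensity", "n_sweeter", "n_total"}
    if not required.issubset(df.columns):
        raise ValueError(f"response CSV must have columns {sorted(required)}")
    return [
        ResponseRecord(float(r.intensity), int(r.n_sweeter), int(r.n_total))
        for r in df.itertuples()
    ]


def write_response_csv(records: Sequence[ResponseRecord], path) -> None:
    pd.DataFrame(
        {
            "intensity": [r.intensity_x for r in records],
            "n_sweeter": [r.n_sweeter for r in records],
            "n_total": [r.n_total for r in records],
        }
    ).to_csv(path, index=False)
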