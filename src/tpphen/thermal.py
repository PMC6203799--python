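"""Thermal response models: mean performance curves and TPP surfaces.

Two complementary descriptions of how development rate responds to
temperature:

* :class:`LactinTPC` -- the Lactin-1 thermal performance curve, a single
  population-mean rate at every temperature::

      r(T) = exp(rho * T) - exp(rho * t_max - (t_max - T) / delta)

  clamped at zero because development cannot regress.  ``t_max`` is the upper
  thermal limit (the rate is exactly zero there) and ``delta`` controls how
  abruptly performance collapses at high temperature.

* :class:`TPPSurface` -- the thermal performance *probability* surface.  At
  each rearing (anchor) temperature the observed rates are described by a
  two-component Gaussian mixture

      f(x) = lambda_1 N(mu_1, sigma_1^2) + lambda_2 N(mu_2, sigma_2^2)

  whose first component (lower mean rate) collects the slow individuals and
  whose second collects the fast ones.  Between anchors every mixture
  parameter is interpolated linearly in temperature; outside the anchor range
  parameters clamp to the nearest anchor.  Drawing rates from the mixture --
  or from a single component for a slow or fast individual -- is what turns
  the surface into an individual-based phenology model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .datasets import RearingDataset

Strategy = Literal["slow", "fast", "intermediate"]

__all__ = [
    "LactinTPC",
    "GaussianMixturePair",
    "TPPSurface",
    "FamilyComparison",
    "fit_lactin1",
    "eval_tpc",
    "fit_mixture_em",
    "compare_families",
    "interpolate_mixture",
    "sample_rate",
    "fit_tpp_surface",
    "save_surfaces",
    "load_surfaces",
    "save_tpcs",
    "load_tpcs",
]


# ---------------------------------------------------------------------------
# Model 1: Lactin-1 mean thermal performance curve
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LactinTPC:
    """Lactin-1 thermal performance curve parameters."""

    rho: float
    t_max: float
    delta: float
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be > 0")

    def rate(self, temp):
        """Mean development rate (1/day) at ``temp`` °C, clamped at zero."""
        t = np.asarray(temp, dtype=float)
        r = np.exp(self.rho * t) - np.exp(
            self.rho * self.t_max - (self.t_max - t) / self.delta
        )
        out = np.maximum(r, 0.0)
        return float(out) if np.isscalar(temp) else out


def eval_tpc(tpc: LactinTPC, temp: float) -> float:
    """Evaluate a Lactin-1 curve; never negative."""
    return tpc.rate(temp)


def fit_lactin1(temps, rates) -> LactinTPC:
    """Least-squares fit of the Lactin-1 curve to (temperature, rate) pairs.

    Rates are averaged per distinct temperature before fitting (the curve is a
    population-mean description).  A small multi-start grid guards against
    local minima; the best residual sum of squares wins.

    Raises
    ------
    ValueError
        Fewer than 4 distinct temperatures, or negative rates.
    RuntimeError
        No optimizer start converged (the best attempt is attached).
    """
    temps = np.asarray(temps, dtype=float).ravel()
    rates = np.asarray(rates, dtype=float).ravel()
    if temps.shape != rates.shape:
        raise ValueError("temps and rates must have the same length")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    uniq = np.unique(temps)
    if uniq.size < 4:
        raise ValueError(
            f"need >= 4 distinct temperatures to fit Lactin-1, got {uniq.size}"
        )
    mean_rates = np.array([rates[temps == t].mean() for t in uniq])

    def resid(p):
        rho, t_max, delta = p
        return (
            np.exp(rho * uniq) - np.exp(rho * t_max - (t_max - uniq) / delta)
        ) - mean_rates

    t_hi = uniq.max()
    best = None
    for rho0 in (0.005, 0.02, 0.08, 0.15):
        for dt in (1.0, 5.0, 12.0):
            for delta0 in (1.0, 4.0, 10.0):
                try:
                    sol = optimize.least_squares(
                        resid,
                        x0=[rho0, t_hi + dt, delta0],
                        bounds=([1e-6, uniq.min(), 1e-3], [1.0, t_hi + 60.0, 100.0]),
                        xtol=1e-15,
                        ftol=1e-15,
                        gtol=1e-12,
                        max_nfev=2000,
                    )
                except Exception:  # pragma: no cover - defensive
                    continue
                rss = float(2 * sol.cost)
                if sol.success and (best is None or rss < best[1]):
                    best = (sol.x, rss)
    if best is None:
        raise RuntimeError("Lactin-1 fit did not converge from any start")
    (rho, t_max, delta), rss = best
    return LactinTPC(rho=float(rho), t_max=float(t_max), delta=float(delta), rss=rss)


# ---------------------------------------------------------------------------
# Model 2: two-component Gaussian mixtures of development rates
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GaussianMixturePair:
    """Two-component Gaussian mixture of development rates at one temperature.

    Component 1 (``mu1 <= mu2``) is the slow component, component 2 the fast
    one.  Weights sum to 1.
    """

    lambda1: float
    lambda2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if abs(self.lambda1 + self.lambda2 - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.lambda1, self.lambda2) < 0:
            raise ValueError("mixture weights must be >= 0")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("component standard deviations must be > 0")
        if self.mu1 > self.mu2:
            raise ValueError("components must be ordered so that mu1 <= mu2")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2])

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2])

    @property
    def mean(self) -> float:
        """Mixture mean rate, lambda1*mu1 + lambda2*mu2."""
        return self.lambda1 * self.mu1 + self.lambda2 * self.mu2

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.lambda1 * stats.norm.pdf(x, self.mu1, self.sigma1) + (
            self.lambda2 * stats.norm.pdf(x, self.mu2, self.sigma2)
        )

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.lambda1 * stats.norm.cdf(x, self.mu1, self.sigma1) + (
            self.lambda2 * stats.norm.cdf(x, self.mu2, self.sigma2)
        )

    def loglik_of(self, x) -> float:
        return float(np.log(self.pdf(x)).sum())


def _em_run(x: np.ndarray, resp: np.ndarray, tol: float, max_iter: int, floor: float):
    """EM iterations from initial responsibilities.

    Returns ``(lam, mu, sig, loglik, trace)`` where ``trace`` holds the
    log-likelihood after every iteration (non-decreasing, up to the variance
    floor).
    """
    n = x.size
    trace: list[float] = []
    prev = -np.inf
    lam = mu = sig = None
    for _ in range(max_iter):
        # M step from current responsibilities
        nk = np.maximum(resp.sum(axis=0), 1e-12)
        lam = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sig = np.maximum(np.sqrt(var), floor)
        # E step (and log-likelihood of the just-updated parameters)
        logp = np.log(lam) - 0.5 * np.log(2 * np.pi) - np.log(sig) - 0.5 * (
            (x[:, None] - mu) / sig
        ) ** 2
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        if np.isfinite(prev) and ll - prev < tol:
            break
        prev = ll
    return lam, mu, sig, trace[-1], np.asarray(trace)


def fit_mixture_em(
    rates,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    return_trace: bool = False,
) -> GaussianMixturePair | tuple[GaussianMixturePair, np.ndarray]:
    """Fit a two-component Gaussian mixture to a rate sample by EM.

    The first restart is initialized by a hard split at the sample median
    (below -> component 1, above -> component 2); further restarts use random
    assignments drawn from ``seed``.  Convergence is declared when the
    log-likelihood improves by less than ``tol``.  Component standard
    deviations are floored at ``1e-6 x sample range`` to guard against
    singularities; components are relabelled so that ``mu1 <= mu2`` (slow
    first).

    Raises ``ValueError`` for samples smaller than 4, non-positive rates, or a
    zero-variance sample.
    """
    x = np.asarray(rates, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need >= 4 observations, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("rates must be > 0")
    span = float(np.ptp(x))
    if span == 0.0:
        raise ValueError("zero-variance sample")
    floor = 1e-6 * span

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(int(restarts), 1)):
        if r == 0:
            z = x > np.median(x)
            if z.all() or not z.any():
                # median tied with an extreme: fall back to a rank split
                z = np.zeros(x.size, dtype=bool)
                z[np.argsort(x)[x.size // 2 :]] = True
        else:
            z = rng.random(x.size) < 0.5
            if z.all() or not z.any():
                z[rng.integers(x.size)] ^= True
        resp = np.column_stack([~z, z]).astype(float)
        lam, mu, sig, ll, trace = _em_run(x, resp, tol, max_iter, floor)
        if best is None or ll > best[3]:
            best = (lam, mu, sig, ll, trace)
    lam, mu, sig, ll, trace = best
    order = np.argsort(mu, kind="stable")
    lam, mu, sig = lam[order], mu[order], sig[order]
    lam = lam / lam.sum()
    pair = GaussianMixturePair(
        lambda1=float(lam[0]),
        lambda2=float(lam[1]),
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        sigma1=float(sig[0]),
        sigma2=float(sig[1]),
        loglik=ll,
    )
    return (pair, trace) if return_trace else pair


@dataclasses.dataclass(frozen=True)
class FamilyComparison:
    """Maximized log-likelihoods of candidate rate distributions."""

    mixture2: float
    weibull: float
    lognormal: float

    @property
    def best(self) -> str:
        scores = {
            "mixture2": self.mixture2,
            "weibull": self.weibull,
            "lognormal": self.lognormal,
        }
        return max(scores, key=scores.get)


def compare_families(rates, seed: int = 0, restarts: int = 5) -> FamilyComparison:
    """Compare the two-component mixture against Weibull and lognormal fits.

    All three families are fitted by maximum likelihood (closed form for the
    lognormal, numerical for the Weibull, EM for the mixture) and their
    maximized log-likelihoods returned.
    """
    x = np.asarray(rates, dtype=float).ravel()
    mix = fit_mixture_em(x, seed=seed, restarts=restarts)

    logx = np.log(x)
    mhat = logx.mean()
    shat = math.sqrt(np.mean((logx - mhat) ** 2))
    shat = max(shat, 1e-12)
    ll_ln = float(stats.lognorm.logpdf(x, shat, scale=math.exp(mhat)).sum())

    c, _, scale = stats.weibull_min.fit(x, floc=0)
    ll_wb = float(stats.weibull_min.logpdf(x, c, loc=0, scale=scale).sum())

    return FamilyComparison(mixture2=mix.loglik, weibull=ll_wb, lognormal=ll_ln)


# ---------------------------------------------------------------------------
# TPP surface: anchored mixtures + parameter interpolation in temperature
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TPPSurface:
    """Thermal performance probability surface for one life stage.

    A mapping from anchor temperatures (the rearing temperatures) to fitted
    mixtures, with linear interpolation of every mixture parameter between
    anchors and clamping outside the anchor range.  A single-anchor surface is
    permitted for constant-temperature work (interpolation then degenerates to
    that anchor).
    """

    stage: str
    anchors: dict[float, GaussianMixturePair]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("surface needs at least one anchor")
        self.anchors = {float(t): p for t, p in sorted(self.anchors.items())}

    @property
    def anchor_temps(self) -> np.ndarray:
        return np.array(list(self.anchors))

    def at(self, temp: float) -> GaussianMixturePair:
        return interpolate_mixture(self, temp)


_PARAMS = ("lambda1", "mu1", "sigma1", "lambda2", "mu2", "sigma2")


def interpolate_mixture(surface: TPPSurface, temp: float) -> GaussianMixturePair:
    """Mixture parameters at an arbitrary temperature.

    Each of the six parameters is interpolated independently between the
    bracketing anchors::

        p(T_x) = p_T1 + (p_T2 - p_T1) * (1 - (T2 - T_x) / (T2 - T1))

    Outside the anchor range parameters clamp to the nearest anchor.  Weights
    are re-normalized to sum to one after interpolation.
    """
    temp = float(temp)
    temps = surface.anchor_temps
    if temp in surface.anchors:
        return surface.anchors[temp]
    if temp <= temps[0]:
        return surface.anchors[float(temps[0])]
    if temp >= temps[-1]:
        return surface.anchors[float(temps[-1])]
    j = int(np.searchsorted(temps, temp))
    t1, t2 = float(temps[j - 1]), float(temps[j])
    p1 = surface.anchors[t1]
    p2 = surface.anchors[t2]
    w = 1.0 - (t2 - temp) / (t2 - t1)
    vals = {
        name: getattr(p1, name) + (getattr(p2, name) - getattr(p1, name)) * w
        for name in _PARAMS
    }
    s = vals["lambda1"] + vals["lambda2"]
    vals["lambda1"] /= s
    vals["lambda2"] = 1.0 - vals["lambda1"]
    return GaussianMixturePair(**vals)


def sample_rate(
    mix: GaussianMixturePair,
    strategy: Strategy,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw development rate(s) from a mixture under a pace-of-life strategy.

    ``intermediate`` draws from the full mixture (component picked with
    probability ``lambda_k``), ``slow`` from component 1 only, ``fast`` from
    component 2 only.  Negative draws are truncated to zero.
    """
    n = 1 if size is None else int(size)
    if strategy == "slow":
        draws = rng.normal(mix.mu1, mix.sigma1, n)
    elif strategy == "fast":
        draws = rng.normal(mix.mu2, mix.sigma2, n)
    elif strategy == "intermediate":
        pick_fast = rng.random(n) >= mix.lambda1
        mu = np.where(pick_fast, mix.mu2, mix.mu1)
        sd = np.where(pick_fast, mix.sigma2, mix.sigma1)
        draws = rng.normal(mu, sd)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    draws = np.maximum(draws, 0.0)
    return float(draws[0]) if size is None else draws


def fit_tpp_surface(
    dataset: RearingDataset,
    stage: str,
    seed: int = 0,
    restarts: int = 10,
    min_samples: int = 4,
    on_degenerate: Literal["raise", "skip", "collapse"] = "raise",
) -> TPPSurface:
    """Fit a mixture at every rearing temperature with enough data for a stage.

    Temperatures with fewer than ``min_samples`` rates are skipped.  A
    zero-variance cell (every individual took the same number of days) either
    raises, is skipped, or is collapsed to a near-degenerate mixture centred
    on the common rate, depending on ``on_degenerate``.
    """
    anchors: dict[float, GaussianMixturePair] = {}
    for i, t in enumerate(dataset.temperatures):
        r = dataset.rates(t, stage)
        if r.size < min_samples:
            continue
        cell_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        try:
            anchors[t] = fit_mixture_em(r, seed=cell_seed, restarts=restarts)
        except ValueError:
            if on_degenerate == "collapse" and np.ptp(r) == 0:
                v = float(r[0])
                s = max(1e-6 * max(abs(v), 1.0), 1e-12)
                anchors[t] = GaussianMixturePair(0.5, 0.5, v, v, s, s)
            elif on_degenerate == "skip":
                continue
            else:
                raise
    if not anchors:
        raise ValueError(f"no temperature has enough data for stage {stage!r}")
    return TPPSurface(stage=stage, anchors=anchors)


# ---------------------------------------------------------------------------
# JSON serialization of fitted objects
# ---------------------------------------------------------------------------


def _surface_to_dict(surface: TPPSurface) -> dict:
    return {
        "stage": surface.stage,
        "anchors": [
            {"temp_c": t, **{k: getattr(p, k) for k in _PARAMS}, "loglik": p.loglik}
            for t, p in surface.anchors.items()
        ],
    }


def _surface_from_dict(d: Mapping) -> TPPSurface:
    anchors = {
        a["temp_c"]: GaussianMixturePair(
            **{k: a[k] for k in _PARAMS}, loglik=a.get("loglik", float("nan"))
        )
        for a in d["anchors"]
    }
    return TPPSurface(stage=d["stage"], anchors=anchors)


def save_surfaces(surfaces: Iterable[TPPSurface], path: str | Path) -> None:
    payload = [_surface_to_dict(s) for s in surfaces]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_surfaces(path: str | Path) -> dict[str, TPPSurface]:
    payload = json.loads(Path(path).read_text())
    surfaces = [_surface_from_dict(d) for d in payload]
    return {s.stage: s for s in surfaces}


def save_tpcs(tpcs: Mapping[str, LactinTPC], path: str | Path) -> None:
    payload = [
        {"stage": stage, "rho": t.rho, "t_max": t.t_max, "delta": t.delta, "rss": t.rss}
        for stage, t in tpcs.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_tpcs(path: str | Path) -> dict[str, LactinTPC]:
    payload = json.loads(Path(path).read_text())
    return {
        d["stage"]: LactinTPC(
            rho=d["rho"], t_max=d["t_max"], delta=d["delta"], rss=d.get("rss", float("nan"))
        )
        for d in payload
    }
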