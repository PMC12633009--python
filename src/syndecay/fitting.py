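"""Fitting block size models to empirical distributions by KL minimization.

For a genome pair with evolutionary distance ``t`` and observed block
size counts, each model's truncated PMF over the window
``[n_min, n_max]`` (``n_max`` being the largest observed block) is fitted
by minimizing the Kullback-Leibler divergence

    D_KL(Phat || P) = sum_n Phat(n) * log(Phat(n) / P(n; x))

with the convention ``0 * log 0 = 0``, both distributions renormalized
over the window.  Optimization is a multi-start bounded local search:
starting points are drawn uniformly within per-parameter bounds and each
is refined with SLSQP using numerically estimated gradients; the lowest
divergence wins, ties broken by the lowest start index.

Rates enter every PMF only through the products ``rate * t``, so with
``t`` supplied per pair the rates themselves are identified; absent ``t``
only the products would be.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from syndecay.models import (
    BlockSizePMF,
    MODEL_IDS,
    ModelParams,
    PARAM_FIELDS,
    log_pmf_vector,
    make_params,
)

__all__ = [
    "DEFAULT_N_MIN",
    "EmpiricalPMF",
    "FitConfig",
    "FitError",
    "FitResult",
    "empirical_pmf",
    "kl_divergence",
    "fit_model",
    "fit_all_models",
]

#: Default smallest block size retained for fitting.  Upstream synteny
#: callers typically cannot resolve blocks shorter than three genes, so
#: sizes 1-2 are unreliable in real data and are dropped by default.
DEFAULT_N_MIN = 3

_RATE_BOUNDS = (1e-8, 1e2)
_PROB_BOUNDS = (1e-8, 1.0)

#: Per-model box bounds in the order of ``PARAM_FIELDS``.
MODEL_BOUNDS: dict[str, tuple[tuple[float, float], ...]] = {
    "one_cut": (_RATE_BOUNDS,),
    "two_cut": (_RATE_BOUNDS, _RATE_BOUNDS),
    "combined": (_RATE_BOUNDS, _RATE_BOUNDS, _RATE_BOUNDS),
    "hotspot": (_RATE_BOUNDS, _RATE_BOUNDS, _PROB_BOUNDS, _PROB_BOUNDS),
}


class FitError(RuntimeError):
    """All restarts of a fit failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[list] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclasses.dataclass(frozen=True)
class EmpiricalPMF:
    """Normalized observed block size distribution for one genome pair.

    ``sizes`` are the distinct observed block sizes within
    ``[n_min, n_max]`` (ascending) with positive ``counts``; ``n_max`` is
    the largest observed block.  Probabilities are counts normalized over
    the retained sizes.
    """

    pair_id: str
    t: float
    sizes: np.ndarray
    counts: np.ndarray
    n_min: int

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=float)
        if sizes.ndim != 1 or sizes.shape != counts.shape or sizes.size == 0:
            raise ValueError("sizes and counts must be matching non-empty 1-d arrays")
        if np.any(np.diff(sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(counts <= 0):
            raise ValueError("retained counts must be positive")
        if sizes[0] < self.n_min:
            raise ValueError("sizes below n_min must have been dropped")
        if not float(self.t) >= 0:
            raise ValueError("evolutionary distance t must be non-negative")
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "t", float(self.t))
        object.__setattr__(self, "n_min", int(self.n_min))

    @property
    def n_max(self) -> int:
        """Largest observed block size (upper truncation for fitting)."""
        return int(self.sizes[-1])

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    def with_n_min(self, n_min: int) -> "EmpiricalPMF":
        """Re-truncate at a different minimum block size."""
        return empirical_pmf(
            dict(zip(self.sizes.tolist(), self.counts.tolist())),
            t=self.t,
            n_min=n_min,
            pair_id=self.pair_id,
        )


def empirical_pmf(
    data: Union[Mapping[int, float], Iterable[int]],
    t: float,
    n_min: int = DEFAULT_N_MIN,
    pair_id: str = "pair",
) -> EmpiricalPMF:
    """Build an :class:`EmpiricalPMF` from block sizes or a size->count map.

    Counts below ``n_min`` are dropped and the remainder renormalized over
    ``[n_min, max observed]``.  Raises ``ValueError`` if nothing survives
    the cutoff.
    """
    if isinstance(data, Mapping):
        items = {int(k): float(v) for k, v in data.items()}
    else:
        values, counts = np.unique(np.asarray(list(data), dtype=np.int64), return_counts=True)
        items = {int(v): float(c) for v, c in zip(values, counts)}
    for size, count in items.items():
        if size < 1:
            raise ValueError(f"block sizes must be >= 1, got {size}")
        if count < 0:
            raise ValueError(f"counts must be non-negative, got {count} for size {size}")
    kept = sorted((s, c) for s, c in items.items() if s >= n_min and c > 0)
    if not kept:
        raise ValueError(f"no blocks of size >= n_min={n_min} observed for {pair_id!r}")
    sizes = np.array([s for s, _ in kept], dtype=np.int64)
    counts = np.array([c for _, c in kept], dtype=float)
    return EmpiricalPMF(pair_id=pair_id, t=t, sizes=sizes, counts=counts, n_min=n_min)


def kl_divergence(empirical: EmpiricalPMF, model_pmf: BlockSizePMF) -> float:
    """D_KL(empirical || model) over the shared truncation window.

    Sizes with zero observed count contribute nothing (``0 * log 0 = 0``);
    if the model puts zero mass on an observed size the divergence is
    ``+inf`` (returned, not raised, so optimizers retreat from it).
    """
    if model_pmf.support_min != empirical.n_min or model_pmf.support_max != empirical.n_max:
        raise ValueError(
            "model PMF must be truncated to the empirical window "
            f"[{empirical.n_min}, {empirical.n_max}]"
        )
    p_hat = empirical.probabilities
    model_p = np.array([model_pmf.prob(int(s)) for s in empirical.sizes])
    if np.any(model_p <= 0.0):
        return float("inf")
    return float(np.sum(p_hat * (np.log(p_hat) - np.log(model_p))))


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Multi-start optimization settings.

    ``restarts`` independent starting points are drawn within each
    parameter's bounds and refined by bounded SLSQP with objective
    tolerance ``ftol`` and numerically estimated gradients; the lowest
    divergence over restarts wins.

    ``start_scale`` controls the start distribution: ``"mixed"``
    (default) draws half the starts uniformly on the linear scale and
    half log-uniformly, ``"linear"`` and ``"log"`` use one scale only.
    Rates far above ~1/t saturate the PMF at the window minimum, where
    the objective is numerically flat and linear-uniform starts stall;
    log-uniform draws cover the small-rate decades where the models are
    responsive, so the mixture is much more reliable at equal cost.
    """

    restarts: int = 50
    seed: int = 0
    ftol: float = 1e-10
    maxiter: int = 300
    start_scale: str = "mixed"
    bounds: Optional[Mapping[str, Sequence[tuple[float, float]]]] = None

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.start_scale not in ("mixed", "linear", "log"):
            raise ValueError("start_scale must be 'mixed', 'linear' or 'log'")

    def model_bounds(self, model_id: str) -> tuple[tuple[float, float], ...]:
        if self.bounds is not None and model_id in self.bounds:
            bounds = tuple(tuple(map(float, b)) for b in self.bounds[model_id])
        else:
            bounds = MODEL_BOUNDS[model_id]
        for lo, hi in bounds:
            if not lo <= hi:
                raise ValueError(f"invalid bound ({lo}, {hi}) for {model_id}")
        return bounds


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Best-of-restarts fit of one model to one empirical distribution."""

    model_id: str
    params: ModelParams
    kl: float
    restarts_converged: int
    best_start_index: int

    def params_dict(self) -> dict[str, float]:
        return {f: getattr(self.params, f) for f in PARAM_FIELDS[self.model_id]}


def _objective(model_id: str, empirical: EmpiricalPMF):
    """KL divergence as a function of the raw parameter vector."""
    window = np.arange(empirical.n_min, empirical.n_max + 1)
    obs_idx = empirical.sizes - empirical.n_min
    p_hat = empirical.probabilities
    log_p_hat = np.log(p_hat)

    def fun(x: np.ndarray) -> float:
        try:
            params = make_params(model_id, np.clip(x, a_min=0.0, a_max=None))
            log_p = log_pmf_vector(model_id, params, empirical.t, window)
        except ValueError:
            return float("inf")
        log_z = logsumexp(log_p)
        log_p_obs = log_p[obs_idx] - log_z
        if not np.all(np.isfinite(log_p_obs)):
            return float("inf")
        return float(np.sum(p_hat * (log_p_hat - log_p_obs)))

    return fun


def _draw_starts(
    config: FitConfig, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = config.restarts
    if config.start_scale == "linear":
        return rng.uniform(lo, hi, size=(n, lo.size))
    if config.start_scale == "log":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, lo.size)))
    n_linear = n // 2
    return np.vstack(
        [
            rng.uniform(lo, hi, size=(n_linear, lo.size)),
            np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n - n_linear, lo.size))),
        ]
    )


def fit_model(
    empirical: EmpiricalPMF,
    model_id: str,
    config: Optional[FitConfig] = None,
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
) -> FitResult:
    """Fit one model by multi-start bounded KL minimization.

    ``extra_starts`` appends deterministic warm starts (clipped to the
    bounds) after the random ones; :func:`fit_all_models` uses this to
    seed each model with the optimum of the models it nests, which makes
    the nesting inequality hold up to optimizer slack by construction.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")
    config = config or FitConfig()
    bounds = config.model_bounds(model_id)
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = _draw_starts(config, lo, hi, rng)
    if extra_starts is not None:
        extra = np.clip(np.asarray(extra_starts, dtype=float), lo, hi)
        starts = np.vstack([starts, extra])
    fun = _objective(model_id, empirical)

    best_fun = np.inf
    best_x: Optional[np.ndarray] = None
    best_index = -1
    converged = 0
    diagnostics = []
    for i, x0 in enumerate(starts):
        try:
            res = minimize(
                fun,
                x0,
                method="SLSQP",
                bounds=bounds,
                options={"ftol": config.ftol, "maxiter": config.maxiter},
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append((i, repr(exc)))
            continue
        if res.success:
            converged += 1
        else:
            diagnostics.append((i, res.message))
        if np.isfinite(res.fun) and res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = np.clip(res.x, lo, hi)
            best_index = i
    if best_x is None:
        raise FitError(
            f"all {config.restarts} restarts failed for model {model_id!r} "
            f"on pair {empirical.pair_id!r}",
            diagnostics,
        )
    params = make_params(model_id, best_x)  # hotspot canonicalized here
    return FitResult(
        model_id=model_id,
        params=params,
        kl=best_fun,
        restarts_converged=converged,
        best_start_index=best_index,
    )


def _moment_start(empirical: EmpiricalPMF) -> float:
    """Moment-matched one_cut rate: geometric mean block size on the window."""
    mean = float(np.sum(empirical.probabilities * empirical.sizes))
    excess = max(mean - empirical.n_min + 1.0, 1.0 + 1e-6)
    q = 1.0 / excess
    t = max(empirical.t, 1e-12)
    return float(-np.log1p(-q) / t)


def _warm_starts(model_id: str, fits: Mapping[str, FitResult], empirical: EmpiricalPMF) -> list:
    """Embeddings of already-fitted simpler models into ``model_id``.

    The combined model reduces to one_cut at gamma -> 0 and to two_cut at
    kappa -> 0; two_cut reduces to the one_cut shape at theta -> 0 (the
    two mixture components coincide); hotspot reduces to one_cut at
    kappa_h = kappa_c and approximates a two-geometric mixture in the
    rare-switch regime, where its eigenvalues are close to the per-state
    no-cut probabilities.
    """
    t = max(empirical.t, 1e-12)
    starts: list[list[float]] = []
    if model_id == "one_cut":
        starts.append([_moment_start(empirical)])
    if model_id == "two_cut" and "one_cut" in fits:
        kappa = fits["one_cut"].params.kappa
        starts.append([kappa, 1e-8])
        starts.append([kappa, 0.5])
    if model_id == "combined":
        if "one_cut" in fits:
            starts.append([fits["one_cut"].params.kappa, 1e-8, 0.5])
        if "two_cut" in fits:
            two = fits["two_cut"].params
            starts.append([1e-8, two.gamma, two.theta])
    if model_id == "hotspot":
        if "one_cut" in fits:
            kappa = fits["one_cut"].params.kappa
            starts.append([kappa, kappa, 0.5, 0.5])
        if "two_cut" in fits:
            two = fits["two_cut"].params
            starts.extend(_mixture_to_hotspot_starts(two.gamma * t + two.theta,
                                                     two.gamma * t, 0.5, t))
        if "combined" in fits:
            comb = fits["combined"].params
            fast = (comb.kappa + comb.gamma) * t + comb.theta
            slow = (comb.kappa + comb.gamma) * t
            w_fast = comb.gamma / (comb.kappa + 2.0 * comb.gamma)
            starts.extend(_mixture_to_hotspot_starts(fast, slow, w_fast, t))
    return starts


def _mixture_to_hotspot_starts(fast: float, slow: float, w_fast: float, t: float) -> list:
    """Map a two-geometric mixture onto rare-switch hotspot parameters.

    With infrequent state switches the survival eigenvalues approach the
    per-state no-cut probabilities, so the mixture exponents map to
    kappa_h = fast/t and kappa_c = slow/t, and the conditioning vector
    supplies the weight: sigma_H = w requires r_ch/r_hc =
    w/(1-w) * (1 - e^-slow)/(1 - e^-fast).
    """
    if not (fast > slow >= 0.0) or not (0.0 < w_fast < 1.0):
        return []
    kappa_h = fast / t
    kappa_c = max(slow, 1e-8) / t
    qh = -np.expm1(-fast)
    qc = -np.expm1(-max(slow, 1e-12))
    ratio = (w_fast / (1.0 - w_fast)) * (qc / qh)  # r_ch / r_hc
    starts = []
    for r_hc in (1e-2, 1e-3, 1e-4, 1e-5):
        r_ch = min(max(r_hc * ratio, 1e-8), 1.0)
        starts.append([kappa_h, kappa_c, r_hc, r_ch])
    return starts


def fit_all_models(
    empirical: EmpiricalPMF,
    config: Optional[FitConfig] = None,
    models: Sequence[str] = MODEL_IDS,
    warm_starts: bool = True,
) -> list[FitResult]:
    """Fit every requested model, returned in parameter-count order.

    With ``warm_starts`` (default) each model's restarts are augmented
    with deterministic embeddings of the simpler models already fitted,
    so a richer model never ends worse than one it nests beyond the
    optimizer tolerance.
    """
    order = [m for m in MODEL_IDS if m in models]
    unknown = set(models) - set(MODEL_IDS)
    if unknown:
        raise ValueError(f"unknown models: {sorted(unknown)}")
    done: dict[str, FitResult] = {}
    results = []
    for model_id in order:
        extra = _warm_starts(model_id, done, empirical) if warm_starts else None
        result = fit_model(empirical, model_id, config, extra_starts=extra or None)
        done[model_id] = result
        results.append(result)
    return results
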