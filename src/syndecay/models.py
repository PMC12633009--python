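"""Closed-form synteny block size distributions for four breakage models.

A synteny block is a run of ``n`` genes whose order is conserved between
two genomes.  Breakpoints ("cuts") disrupt ancestral gene adjacencies at
inter-gene regions along the evolutionary path joining the two genomes;
the path length ``t`` is measured in mean amino-acid substitutions per
site summed over both lineages.  Conditioning on a cut at a reference
inter-gene region, the block size distribution is the probability that
exactly ``n - 1`` consecutive inter-gene regions carry no cut, followed by
one that does.

Four nested models are implemented, ordered by parameter count:

``one_cut``
    Random breakage: cuts arrive as a Poisson process with uniform rate
    ``kappa`` per inter-gene region, so block sizes are geometric with
    success probability ``1 - exp(-kappa * t)``.
``two_cut``
    Correlated breakage: cuts arrive in pairs, mimicking inversions.  An
    initial cut forms at rate ``gamma``; its partner ("final" cut) lands a
    geometrically distributed span to the right, with per-region decay
    ``theta``.  The block size law is an equal mixture of two geometrics.
``combined``
    Both single cuts (rate ``kappa``) and paired cuts (rate ``gamma``,
    span decay ``theta``); mixture weights follow from the relative
    abundance of each cut type.
``hotspot``
    Fragile breakage: single cuts at rate ``kappa_h`` in hotspot regions
    and ``kappa_c`` elsewhere, the two region types arranged along the
    chromosome by a two-state Markov chain with switching probabilities
    ``r_hc`` (hot to cold) and ``r_ch`` (cold to hot).  The block size
    law is a matrix-product form over the hidden spot sequence.

All rates have units of cuts per substitution-per-site per inter-gene
region.  Probabilities that can underflow are computed in log space for
the geometric models; the 2x2 hotspot matrix products carry an explicit
running log-scale.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MODEL_IDS",
    "DegenerateModelError",
    "OneCutParams",
    "TwoCutParams",
    "CombinedParams",
    "HotspotParams",
    "HotspotMatrices",
    "BlockSizePMF",
    "make_params",
    "pmf_one_cut",
    "two_cut_span_pmf",
    "pmf_two_cut",
    "pmf_combined",
    "hotspot_stationary",
    "hotspot_condition_vector",
    "hotspot_matrices",
    "pmf_hotspot",
    "overlap_error",
    "multicut_error",
    "log_pmf_vector",
    "truncated_pmf",
]

#: Canonical model identifiers, ordered by parameter count.
MODEL_IDS = ("one_cut", "two_cut", "combined", "hotspot")


class DegenerateModelError(ValueError):
    """Raised when parameters imply zero cut probability.

    Every block size distribution here is obtained by conditioning on at
    least one cut having occurred; when no cut can ever occur the
    conditional distribution is undefined rather than defective.
    """


def _check_rate(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative real, got {value!r}")
    return value


@dataclasses.dataclass(frozen=True)
class OneCutParams:
    """Random breakage model: single cuts at uniform rate ``kappa``."""

    kappa: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", _check_rate(self.kappa, "kappa"))


@dataclasses.dataclass(frozen=True)
class TwoCutParams:
    """Correlated breakage model.

    ``gamma`` is the rate of initial cuts; ``theta`` the geometric decay
    of the span to the partner cut (mean span ``1 / (1 - exp(-theta))``
    genes).
    """

    gamma: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", _check_rate(self.gamma, "gamma"))
        object.__setattr__(self, "theta", _check_rate(self.theta, "theta"))


@dataclasses.dataclass(frozen=True)
class CombinedParams:
    """Single cuts at rate ``kappa`` plus paired cuts (``gamma``, ``theta``)."""

    kappa: float
    gamma: float
    theta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", _check_rate(self.kappa, "kappa"))
        object.__setattr__(self, "gamma", _check_rate(self.gamma, "gamma"))
        object.__setattr__(self, "theta", _check_rate(self.theta, "theta"))


@dataclasses.dataclass(frozen=True)
class HotspotParams:
    """Fragile breakage model parameters.

    The labelling of the two states is a gauge freedom: swapping
    ``(kappa_h, r_hc)`` with ``(kappa_c, r_ch)`` leaves the block size
    distribution unchanged.  The constructor canonicalizes to
    ``kappa_h >= kappa_c`` by performing that swap when needed, so any
    non-negative rate pair is accepted.
    """

    kappa_h: float
    kappa_c: float
    r_hc: float
    r_ch: float

    def __post_init__(self) -> None:
        kh = _check_rate(self.kappa_h, "kappa_h")
        kc = _check_rate(self.kappa_c, "kappa_c")
        rhc = float(self.r_hc)
        rch = float(self.r_ch)
        for name, r in (("r_hc", rhc), ("r_ch", rch)):
            if not (0.0 < r <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {r!r}")
        if kh < kc:  # label-switching symmetry: canonicalize
            kh, kc = kc, kh
            rhc, rch = rch, rhc
        object.__setattr__(self, "kappa_h", kh)
        object.__setattr__(self, "kappa_c", kc)
        object.__setattr__(self, "r_hc", rhc)
        object.__setattr__(self, "r_ch", rch)


_PARAM_CLASSES = {
    "one_cut": OneCutParams,
    "two_cut": TwoCutParams,
    "combined": CombinedParams,
    "hotspot": HotspotParams,
}

#: Free-parameter vector layout used by :func:`make_params` and the fitter.
PARAM_FIELDS = {
    "one_cut": ("kappa",),
    "two_cut": ("gamma", "theta"),
    "combined": ("kappa", "gamma", "theta"),
    "hotspot": ("kappa_h", "kappa_c", "r_hc", "r_ch"),
}

ModelParams = Union[OneCutParams, TwoCutParams, CombinedParams, HotspotParams]


def make_params(model_id: str, values: Union[Sequence[float], Mapping[str, float]]) -> ModelParams:
    """Build the parameter object for ``model_id`` from a vector or mapping."""
    if model_id not in _PARAM_CLASSES:
        raise ValueError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")
    cls = _PARAM_CLASSES[model_id]
    if isinstance(values, Mapping):
        return cls(**{k: values[k] for k in PARAM_FIELDS[model_id]})
    values = list(values)
    if len(values) != len(PARAM_FIELDS[model_id]):
        raise ValueError(
            f"model {model_id!r} takes {len(PARAM_FIELDS[model_id])} parameters, got {len(values)}"
        )
    return cls(*values)


# ---------------------------------------------------------------------------
# geometric building blocks (log space)
# ---------------------------------------------------------------------------


def _log1mexp(x: np.ndarray | float) -> np.ndarray | float:
    """log(1 - exp(-x)) for x > 0, accurate for both small and large x."""
    return np.log(-np.expm1(-np.asarray(x, dtype=float)))


def _log_geom(n: np.ndarray, x: float) -> np.ndarray:
    """Log PMF of the genes-remaining geometric with exponent x = -log(1-q)."""
    return -x * (n - 1.0) + _log1mexp(x)


def _as_n_array(n) -> tuple[np.ndarray, bool]:
    arr = np.asarray(n)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(float)
    if np.any(arr < 1) or np.any(arr != np.floor(arr)):
        raise ValueError("block size n must be a positive integer")
    return arr, scalar


def _maybe_scalar(values: np.ndarray, scalar: bool):
    return float(values[0]) if scalar else values


# ---------------------------------------------------------------------------
# one-cut (random breakage)
# ---------------------------------------------------------------------------


def pmf_one_cut(n, params: OneCutParams, t: float):
    """P(block size = n) under random breakage.

    Geometric law ``exp(-kappa*t*(n-1)) * (1 - exp(-kappa*t))``: the
    probability of ``n - 1`` uncut inter-gene regions followed by a cut,
    with per-region cut probability ``1 - exp(-kappa*t)``.
    """
    arr, scalar = _as_n_array(n)
    kt = params.kappa * float(t)
    if kt <= 0.0:
        raise DegenerateModelError("kappa * t must be positive: no cuts ever occur")
    return _maybe_scalar(np.exp(_log_geom(arr, kt)), scalar)


# ---------------------------------------------------------------------------
# two-cut (correlated breakage)
# ---------------------------------------------------------------------------


def two_cut_span_pmf(n, theta: float):
    """Distribution of the span (genes) between the two cuts of a pair.

    Geometric with per-region success ``1 - exp(-theta)``; the mean span
    is ``1 / (1 - exp(-theta))`` genes.
    """
    arr, scalar = _as_n_array(n)
    theta = float(theta)
    if theta <= 0.0:
        raise DegenerateModelError("theta must be positive: span distribution undefined")
    return _maybe_scalar(np.exp(_log_geom(arr, theta)), scalar)


def _two_cut_log_pmf(n: np.ndarray, gamma: float, theta: float, t: float) -> np.ndarray:
    gt = gamma * t
    if gt <= 0.0:
        raise DegenerateModelError("gamma * t must be positive: no cuts ever occur")
    # Conditioning on an initial cut (its partner lies theta-near) or on a
    # final cut (only an independent initial cut can end the block), each
    # with probability 1/2.
    log_half = -math.log(2.0)
    return np.logaddexp(log_half + _log_geom(n, gt + theta), log_half + _log_geom(n, gt))


def pmf_two_cut(n, params: TwoCutParams, t: float):
    """P(block size = n) under correlated breakage.

    Equal mixture of geometrics with exponents ``gamma*t + theta`` and
    ``gamma*t``, for conditioning on an initial or a final paired cut.
    """
    arr, scalar = _as_n_array(n)
    return _maybe_scalar(np.exp(_two_cut_log_pmf(arr, params.gamma, params.theta, float(t))), scalar)


def overlap_error(params: TwoCutParams, t: float) -> float:
    """Probability that a paired-cut span straddles the reference cut.

    The closed-form block size law treats the cut probability to the right
    of an initial cut as span-independent; this diagnostic,
    ``(1 - exp(-gamma*t)) * exp(-theta)``, bounds the error of that
    approximation.  Small values mean overlapping cut pairs are rare and
    the model is internally consistent.
    """
    return float(-np.expm1(-params.gamma * float(t)) * math.exp(-params.theta))


def multicut_error(params: TwoCutParams, t: float) -> float:
    """Probability of two or more initial paired cuts at one inter-gene region.

    ``1 - exp(-gamma*t) - gamma*t*exp(-gamma*t)``, the Poisson tail
    ``P(K >= 2)`` with mean ``gamma*t``; the model assumes at most one.
    """
    gt = params.gamma * float(t)
    return float(-np.expm1(-gt) - gt * math.exp(-gt))


# ---------------------------------------------------------------------------
# combined one-cut + two-cut
# ---------------------------------------------------------------------------


def _combined_log_pmf(n: np.ndarray, kappa: float, gamma: float, theta: float, t: float) -> np.ndarray:
    denom = kappa + 2.0 * gamma
    if denom <= 0.0:
        raise DegenerateModelError("kappa + 2*gamma must be positive: no cuts ever occur")
    both = (kappa + gamma) * t
    if both <= 0.0:
        raise DegenerateModelError("(kappa + gamma) * t must be positive")
    # Average cut counts: kappa*t singles, gamma*t initial and gamma*t final
    # pairs; conditioning weights follow.
    with np.errstate(divide="ignore"):
        log_w_initial = np.log(gamma / denom)
        log_w_other = np.log((kappa + gamma) / denom)
    return np.logaddexp(
        log_w_initial + _log_geom(n, both + theta),
        log_w_other + _log_geom(n, both),
    )


def pmf_combined(n, params: CombinedParams, t: float):
    """P(block size = n) when both single and paired cuts occur.

    Mixture with weight ``gamma / (kappa + 2*gamma)`` on the geometric
    with exponent ``(kappa + gamma)*t + theta`` and weight
    ``(kappa + gamma) / (kappa + 2*gamma)`` on the geometric with exponent
    ``(kappa + gamma)*t``.  Reduces to ``one_cut`` at ``gamma = 0`` and to
    ``two_cut`` at ``kappa = 0``.
    """
    arr, scalar = _as_n_array(n)
    return _maybe_scalar(
        np.exp(_combined_log_pmf(arr, params.kappa, params.gamma, params.theta, float(t))), scalar
    )


# ---------------------------------------------------------------------------
# hotspot (fragile breakage)
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class HotspotMatrices:
    """Matrix ingredients of the hotspot block size distribution.

    ``transition`` is the row-stochastic spot chain T; ``no_cut`` and
    ``cut`` hold per-destination no-cut / at-least-one-cut probabilities
    (U and C, with U + C all ones); ``condition_vector`` is the posterior
    [sigma_H, sigma_C] of the reference cut's spot type; ``stationary``
    is the chain's equilibrium (pi_H, pi_C).
    """

    transition: np.ndarray
    no_cut: np.ndarray
    cut: np.ndarray
    condition_vector: np.ndarray
    stationary: tuple[float, float]


def hotspot_stationary(params: HotspotParams) -> tuple[float, float]:
    """Equilibrium probabilities (pi_H, pi_C) of the two-state spot chain."""
    total = params.r_hc + params.r_ch
    if total <= 0.0:
        raise ValueError("r_hc + r_ch must be positive for a unique stationary law")
    return params.r_ch / total, params.r_hc / total


def hotspot_condition_vector(params: HotspotParams, t: float) -> np.ndarray:
    """Posterior spot-type probabilities [sigma_H, sigma_C] of a cut.

    Bayes' rule with the exact exponential cut probabilities:
    ``sigma_H = (1 - exp(-kappa_h*t)) * pi_H / Z``.  (For small ``kappa*t``
    this is approximately the rate-ratio form
    ``r_ch*kappa_h / (r_ch*kappa_h + r_hc*kappa_c)``; the exact form is
    used here.)
    """
    t = float(t)
    pi_h, pi_c = hotspot_stationary(params)
    qh = -np.expm1(-params.kappa_h * t)
    qc = -np.expm1(-params.kappa_c * t)
    denom = qh * pi_h + qc * pi_c
    if denom <= 0.0:
        raise DegenerateModelError("both kappa_h*t and kappa_c*t are zero: no cuts ever occur")
    sigma_h = qh * pi_h / denom
    return np.array([sigma_h, 1.0 - sigma_h])


def hotspot_matrices(params: HotspotParams, t: float) -> HotspotMatrices:
    """Assemble T, U, C, sigma and the stationary law for given params and t."""
    t = float(t)
    transition = np.array(
        [
            [1.0 - params.r_hc, params.r_hc],
            [params.r_ch, 1.0 - params.r_ch],
        ]
    )
    no_cut_row = np.array([math.exp(-params.kappa_h * t), math.exp(-params.kappa_c * t)])
    no_cut = np.tile(no_cut_row, (2, 1))
    cut = 1.0 - no_cut
    sigma = hotspot_condition_vector(params, t)
    return HotspotMatrices(
        transition=transition,
        no_cut=no_cut,
        cut=cut,
        condition_vector=sigma,
        stationary=hotspot_stationary(params),
    )


def _hotspot_log_pmf_vector(params: HotspotParams, t: float, n_max: int) -> np.ndarray:
    """Log PMF at n = 1..n_max via iterative row-vector propagation.

    P(n) = sigma (T o U)^(n-1) (T o C) 1, with o the elementwise product.
    One left-to-right pass yields every n in the range at O(n_max) cost;
    the propagated 2-vector is renormalized against underflow with an
    explicit log-scale accumulator.
    """
    mats = hotspot_matrices(params, t)
    survive = mats.transition * mats.no_cut  # T o U
    stop = (mats.transition * mats.cut).sum(axis=1)  # (T o C) 1
    m00, m01 = survive[0]
    m10, m11 = survive[1]
    c0, c1 = stop
    v0, v1 = mats.condition_vector
    out = np.empty(n_max)
    scales = np.empty(n_max)
    log_scale = 0.0
    for i in range(n_max):
        out[i] = v0 * c0 + v1 * c1
        scales[i] = log_scale
        v0, v1 = v0 * m00 + v1 * m10, v0 * m01 + v1 * m11
        total = v0 + v1
        if total < 1e-260 and total > 0.0:
            v0 /= total
            v1 /= total
            log_scale += math.log(total)
    with np.errstate(divide="ignore"):
        return np.log(out) + scales


def hotspot_spectrum(params: HotspotParams, t: float) -> tuple[float, float, float]:
    """Identifiable quantities (lambda_slow, lambda_fast, weight_slow).

    The hotspot block size law is exactly a two-geometric mixture
    ``P(n) = A * lam1**(n-1) + B * lam2**(n-1)`` whose ratios ``lam1 >
    lam2`` are the eigenvalues of the survival matrix T o U and whose
    second weight is fixed by normalization.  Only these three
    combinations are identifiable from a block size distribution: the
    map from the four parameters to ``(lam1, lam2, A)`` has
    one-dimensional fibers, so distinct parameter vectors can produce
    identical distributions.
    """
    mats = hotspot_matrices(params, t)
    survive = mats.transition * mats.no_cut
    tr = survive[0, 0] + survive[1, 1]
    det = survive[0, 0] * survive[1, 1] - survive[0, 1] * survive[1, 0]
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    lam1 = (tr + disc) / 2.0
    lam2 = (tr - disc) / 2.0
    p = np.exp(_hotspot_log_pmf_vector(params, t, 2))
    if lam1 - lam2 < 1e-14:
        return lam1, lam2, float(p[0])
    weight_slow = (p[1] - p[0] * lam2) / (lam1 - lam2)
    return lam1, lam2, float(weight_slow)


def pmf_hotspot(n, params: HotspotParams, t: float):
    """P(block size = n) under fragile breakage.

    Sums over hidden hotspot/coldspot sequences via the matrix-product
    form; exactly normalized over n >= 1 because T is row-stochastic and
    U + C is all ones.
    """
    arr, scalar = _as_n_array(n)
    log_p = _hotspot_log_pmf_vector(params, float(t), int(arr.max()))
    return _maybe_scalar(np.exp(log_p[arr.astype(int) - 1]), scalar)


# ---------------------------------------------------------------------------
# unified evaluation and truncation
# ---------------------------------------------------------------------------


def log_pmf_vector(model_id: str, params: ModelParams, t: float, n: np.ndarray) -> np.ndarray:
    """Log block size PMF of ``model_id`` at the (integer) sizes ``n``."""
    arr, _ = _as_n_array(n)
    t = float(t)
    if model_id == "one_cut":
        kt = params.kappa * t
        if kt <= 0.0:
            raise DegenerateModelError("kappa * t must be positive: no cuts ever occur")
        return _log_geom(arr, kt)
    if model_id == "two_cut":
        return _two_cut_log_pmf(arr, params.gamma, params.theta, t)
    if model_id == "combined":
        return _combined_log_pmf(arr, params.kappa, params.gamma, params.theta, t)
    if model_id == "hotspot":
        log_p = _hotspot_log_pmf_vector(params, t, int(arr.max()))
        return log_p[arr.astype(int) - 1]
    raise ValueError(f"unknown model {model_id!r}; expected one of {MODEL_IDS}")


@dataclasses.dataclass(frozen=True)
class BlockSizePMF:
    """A probability mass function over integer block sizes (genes).

    ``support`` is an ascending integer array; ``probabilities`` the
    matching masses.  Truncated PMFs produced by :func:`truncated_pmf`
    are renormalized to sum to one over their window.
    """

    support: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        probs = np.asarray(self.probabilities, dtype=float)
        if support.shape != probs.shape or support.ndim != 1 or support.size == 0:
            raise ValueError("support and probabilities must be matching non-empty 1-d arrays")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if support[0] < 1:
            raise ValueError("block sizes start at 1")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probabilities", probs)

    @property
    def support_min(self) -> int:
        return int(self.support[0])

    @property
    def support_max(self) -> int:
        return int(self.support[-1])

    def prob(self, n: int) -> float:
        """Probability mass at block size ``n`` (0 outside the support)."""
        idx = np.searchsorted(self.support, n)
        if idx < self.support.size and self.support[idx] == n:
            return float(self.probabilities[idx])
        return 0.0

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(p) for s, p in zip(self.support, self.probabilities)}


def truncated_pmf(
    model_id: str,
    params: ModelParams,
    t: float,
    n_min: int,
    n_max: int,
) -> BlockSizePMF:
    """Model PMF restricted to ``[n_min, n_max]`` and renormalized to one.

    This is the fitting convention: both model and empirical distributions
    are compared after renormalization over the shared window from the
    smallest retained block size to the largest observed one.
    """
    n_min, n_max = int(n_min), int(n_max)
    if not (1 <= n_min <= n_max):
        raise ValueError(f"need 1 <= n_min <= n_max, got [{n_min}, {n_max}]")
    ns = np.arange(n_min, n_max + 1)
    log_p = log_pmf_vector(model_id, params, t, ns)
    log_z = logsumexp(log_p)
    if not np.isfinite(log_z):
        raise ValueError("model places no mass on the truncation window")
    return BlockSizePMF(support=ns, probabilities=np.exp(log_p - log_z))
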