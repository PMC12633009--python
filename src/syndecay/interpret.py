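"""Interpretation of fitted parameters as biological quantities.

Fitted cut rates are converted into evolutionary breakpoint rates per
million years, mean spans (2-cut sizes, inter-cut distances within
hotspots), hotspot fractions and mean hotspot/coldspot lengths.  Lengths
in genes are converted to kilobases with a constant factor of 90 kb per
gene, the genome-wide mean spacing used throughout.

The breakpoint-rate denominator ``t_mya`` is the full path time between
the two genomes in millions of years, i.e. twice the one-way time to the
last common ancestor; :func:`full_path_time` doubles a one-way split
time.
"""

from __future__ import annotations

import dataclasses
import math

from syndecay.models import (
    CombinedParams,
    HotspotParams,
    ModelParams,
    OneCutParams,
    TwoCutParams,
    hotspot_stationary,
)

__all__ = [
    "KB_PER_GENE",
    "RateInputs",
    "breakpoint_rate",
    "mean_geometric_size",
    "hotspot_fraction",
    "spot_length_kb",
    "genes_to_kb",
    "round_half_up",
    "full_path_time",
    "unique_pair_count",
]

#: Mean kilobases of sequence per gene (genome length / gene count).
KB_PER_GENE = 90.0


@dataclasses.dataclass(frozen=True)
class RateInputs:
    """Pair-level inputs for breakpoint-rate conversion.

    ``syntenic_genes`` (S) is the total number of genes in synteny
    between the pair, a proxy for the number of ancestral inter-gene
    regions; ``t_mya`` is the full-path divergence time in millions of
    years (twice the one-way split time).
    """

    syntenic_genes: int
    t_mya: float

    def __post_init__(self) -> None:
        if int(self.syntenic_genes) < 1:
            raise ValueError("syntenic_genes must be >= 1")
        if not self.t_mya > 0:
            raise ValueError("t_mya must be positive")
        object.__setattr__(self, "syntenic_genes", int(self.syntenic_genes))
        object.__setattr__(self, "t_mya", float(self.t_mya))


def full_path_time(one_way_split_mya: float) -> float:
    """Full-path time (MYA) from a one-way time to the common ancestor."""
    if not one_way_split_mya > 0:
        raise ValueError("split time must be positive")
    return 2.0 * float(one_way_split_mya)


def breakpoint_rate(model_id: str, params: ModelParams, t: float, inputs: RateInputs) -> float:
    """Expected breakpoints per million years along the inter-species path.

    The expected number of cuts per inter-gene region over the path is
    ``kappa*t`` (one_cut), ``2*gamma*t`` (two_cut; each pair contributes
    two breakpoints), or ``(pi_H*kappa_h + pi_C*kappa_c)*t`` (hotspot);
    multiplied by the S syntenic genes and divided by the path time in
    million years.
    """
    t = float(t)
    if model_id == "one_cut":
        if not isinstance(params, OneCutParams):
            raise TypeError("one_cut rate needs OneCutParams")
        cuts_per_region = params.kappa * t
    elif model_id == "two_cut":
        if not isinstance(params, TwoCutParams):
            raise TypeError("two_cut rate needs TwoCutParams")
        cuts_per_region = 2.0 * params.gamma * t
    elif model_id == "hotspot":
        if not isinstance(params, HotspotParams):
            raise TypeError("hotspot rate needs HotspotParams")
        pi_h, pi_c = hotspot_stationary(params)
        cuts_per_region = (pi_h * params.kappa_h + pi_c * params.kappa_c) * t
    elif model_id == "combined":
        raise ValueError("no breakpoint-rate formula is defined for the combined model")
    else:
        raise ValueError(f"unknown model {model_id!r}")
    return cuts_per_region * inputs.syntenic_genes / inputs.t_mya


def mean_geometric_size(x: float) -> float:
    """Mean of the geometric size law with exponent ``x``: 1/(1 - e^-x).

    Used with ``x = theta`` for the mean 2-cut span and with
    ``x = kappa_h * t`` for the mean distance between cuts within a
    hotspot, both in genes.
    """
    x = float(x)
    if not x > 0:
        raise ValueError("x must be positive (x = 0 gives an infinite mean)")
    return 1.0 / -math.expm1(-x)


def hotspot_fraction(params: HotspotParams) -> float:
    """Stationary fraction of inter-gene regions that are hotspots."""
    return hotspot_stationary(params)[0]


def spot_length_kb(r: float, kb_per_gene: float = KB_PER_GENE) -> float:
    """Mean hotspot (or coldspot) tract length in kilobases.

    A run of same-type inter-gene regions has mean length ``1/r`` regions
    under the two-state chain, where ``r`` is the probability of leaving
    the state; converted at ``kb_per_gene``.
    """
    r = float(r)
    if not (0.0 < r <= 1.0):
        raise ValueError("transition probability r must lie in (0, 1]")
    return (1.0 / r) * kb_per_gene


def genes_to_kb(genes: float, kb_per_gene: float = KB_PER_GENE) -> float:
    """Convert a length in genes to kilobases (exact; round for display)."""
    genes = float(genes)
    if genes < 0:
        raise ValueError("gene count must be non-negative")
    return genes * kb_per_gene


def round_half_up(x: float) -> int:
    """Display rounding with halves rounded up (so 184.5 -> 185).

    The value is first snapped to 9 decimal places so that binary
    representation error (e.g. 184.49999999999997 for 2.05 * 90) does not
    flip a half-way case.
    """
    return int(math.floor(round(float(x), 9) + 0.5))


def unique_pair_count(n_genomes: int) -> int:
    """Number of unordered genome pairs among ``n_genomes`` assemblies."""
    n = int(n_genomes)
    if n < 2:
        raise ValueError("need at least two genomes")
    return math.comb(n, 2)


def combined_rate_params(params: CombinedParams) -> TwoCutParams:
    """The paired-cut component of a combined fit, for span diagnostics."""
    return TwoCutParams(gamma=params.gamma, theta=params.theta)
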