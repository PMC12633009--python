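"""Stochastic forward simulation of genome breakage.

A genome is a graph whose nodes are genes and whose edges are adjacencies
between consecutive genes on a chromosome; each chromosome is a path.
Rearrangement breakpoints remove edges, and the synteny block sizes at
time ``t`` are the connected-component sizes of the surviving graph.

Cut times are independent exponentials attached to the *original* edge
set, so a cut landing on an already-removed edge advances time but
changes nothing — this preserves the per-edge Poisson process the
analytical models assume.  The event loop samples the superposition of
those exponentials directly: waiting times are Exponential(total rate)
and the struck edge is chosen proportionally to its rate, which is
distributionally identical to taking the minimum over per-edge draws
(a naive per-edge implementation is kept as a cross-checking reference).

Under the correlated (``two_cut``) model each initial cut draws a partner
span ``n`` from the geometric span distribution and also removes the edge
``n`` positions to the right, provided that edge exists on the same
original chromosome.  Under the ``hotspot`` model every original edge is
first labelled hotspot or coldspot by the two-state Markov chain, and cut
rates depend on the label.

This module doubles as the package's synthetic-data generator: ensembles
of simulated block size distributions are the test bed for the analytical
models and the fitting machinery.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from syndecay.models import (
    HotspotParams,
    ModelParams,
    OneCutParams,
    TwoCutParams,
    hotspot_stationary,
)

__all__ = [
    "GenomeGraph",
    "SpotAssignment",
    "SimConfig",
    "EnsembleResult",
    "build_genome",
    "assign_spots",
    "simulate",
    "simulate_reference",
    "block_sizes",
    "run_ensemble",
]

#: Simulator models: the combined model is validated through its reductions,
#: matching the three simulated scenarios.
SIM_MODELS = ("one_cut", "two_cut", "hotspot")


@dataclasses.dataclass
class GenomeGraph:
    """Chromosomes as paths of genes with 1-based indexed inter-gene edges.

    Edge indices run contiguously ``1..edge_count`` in chromosome order;
    ``live[e]`` says whether edge ``e`` is intact (``live[0]`` is unused
    padding).  ``edge_chrom[e]`` maps each edge to its original
    chromosome, which is what decides whether a partner cut of a pair
    falls on the same chromosome.
    """

    chromosome_sizes: tuple[int, ...]
    live: np.ndarray
    edge_chrom: np.ndarray

    @property
    def node_count(self) -> int:
        return int(sum(self.chromosome_sizes))

    @property
    def edge_count(self) -> int:
        return int(self.live.size - 1)

    @property
    def live_edges(self) -> np.ndarray:
        """Ascending indices of intact edges."""
        return np.flatnonzero(self.live[1:]) + 1

    def copy(self) -> "GenomeGraph":
        return GenomeGraph(
            chromosome_sizes=self.chromosome_sizes,
            live=self.live.copy(),
            edge_chrom=self.edge_chrom,
        )


def build_genome(chromosome_sizes: Sequence[int]) -> GenomeGraph:
    """Create an intact genome graph from per-chromosome gene counts."""
    sizes = tuple(int(s) for s in chromosome_sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("chromosome_sizes must be a non-empty list of positive integers")
    edges_per_chrom = [s - 1 for s in sizes]
    n_edges = sum(edges_per_chrom)
    live = np.ones(n_edges + 1, dtype=bool)
    live[0] = False
    edge_chrom = np.empty(n_edges + 1, dtype=np.int64)
    edge_chrom[0] = -1
    edge_chrom[1:] = np.repeat(np.arange(len(sizes)), edges_per_chrom)
    return GenomeGraph(chromosome_sizes=sizes, live=live, edge_chrom=edge_chrom)


@dataclasses.dataclass(frozen=True)
class SpotAssignment:
    """Hotspot/coldspot label per original edge (``is_hot[0]`` unused)."""

    is_hot: np.ndarray

    @property
    def hotspot_edges(self) -> np.ndarray:
        return np.flatnonzero(self.is_hot[1:]) + 1

    @property
    def coldspot_edges(self) -> np.ndarray:
        return np.flatnonzero(~self.is_hot[1:]) + 1


def assign_spots(
    graph: GenomeGraph, params: HotspotParams, rng: np.random.Generator
) -> SpotAssignment:
    """Label every edge hotspot/coldspot by the two-state Markov chain.

    Labels are sampled chromosome by chromosome: the first edge of each
    chromosome is drawn from the stationary distribution (the equilibrium
    the analytical model assumes) and consecutive edges follow the
    transition probabilities ``r_hc`` and ``r_ch``.
    """
    pi_h, _ = hotspot_stationary(params)
    n_edges = graph.edge_count
    is_hot = np.zeros(n_edges + 1, dtype=bool)
    u = rng.random(n_edges)
    e = 1
    r_hc, r_ch = params.r_hc, params.r_ch
    for size in graph.chromosome_sizes:
        chrom_edges = size - 1
        if chrom_edges == 0:
            continue
        state = u[e - 1] < pi_h
        is_hot[e] = state
        for i in range(e + 1, e + chrom_edges):
            if state:
                state = not (u[i - 1] < r_hc)
            else:
                state = u[i - 1] < r_ch
            is_hot[i] = state
        e += chrom_edges
    return SpotAssignment(is_hot=is_hot)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """One simulation scenario: model, parameters, duration, seeding."""

    model_id: str
    params: ModelParams
    t_max: float
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.model_id not in SIM_MODELS:
            raise ValueError(f"simulator model must be one of {SIM_MODELS}, got {self.model_id!r}")
        expected = {"one_cut": OneCutParams, "two_cut": TwoCutParams, "hotspot": HotspotParams}
        if not isinstance(self.params, expected[self.model_id]):
            raise TypeError(
                f"model {self.model_id!r} needs {expected[self.model_id].__name__}, "
                f"got {type(self.params).__name__}"
            )
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _edge_rates(
    config: SimConfig, graph: GenomeGraph, spots: Optional[SpotAssignment]
):
    """Per-class cut machinery: (total rate, edge-sampling closure)."""
    n_edges = graph.edge_count
    if config.model_id == "hotspot":
        if spots is None:
            raise ValueError("hotspot simulation requires a SpotAssignment")
        hot = spots.hotspot_edges
        cold = spots.coldspot_edges
        rate_hot = hot.size * config.params.kappa_h
        rate_cold = cold.size * config.params.kappa_c
        total = rate_hot + rate_cold

        def sample_edge(rng: np.random.Generator) -> int:
            if rng.random() * total < rate_hot:
                return int(hot[rng.integers(hot.size)])
            return int(cold[rng.integers(cold.size)])

        return total, sample_edge

    rate = config.params.kappa if config.model_id == "one_cut" else config.params.gamma
    total = n_edges * rate

    def sample_uniform(rng: np.random.Generator) -> int:
        return int(rng.integers(1, n_edges + 1))

    return total, sample_uniform


def simulate(
    graph: GenomeGraph,
    config: SimConfig,
    spots: Optional[SpotAssignment] = None,
    rng: Optional[np.random.Generator] = None,
) -> GenomeGraph:
    """Evolve a copy of ``graph`` to ``t_max`` and return it.

    Event loop: waiting times are Exponential(total rate over the original
    edge set) and each event strikes an edge chosen proportionally to its
    rate; events whose time would reach or exceed ``t_max`` are not
    applied.  Removal is idempotent, so re-cutting a removed edge is a
    no-op by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = graph.copy()
    total_rate, sample_edge = _edge_rates(config, graph, spots)
    if total_rate <= 0.0:
        return out
    two_cut = config.model_id == "two_cut"
    if two_cut:
        span_p = -np.expm1(-config.params.theta)  # P(span = n) geometric
        if span_p <= 0.0:
            raise ValueError("two_cut simulation requires theta > 0")
    live = out.live
    edge_chrom = out.edge_chrom
    n_edges = out.edge_count
    t_now = 0.0
    t_max = float(config.t_max)
    while True:
        t_now += rng.exponential(1.0 / total_rate)
        if t_now >= t_max:
            break
        e = sample_edge(rng)
        live[e] = False
        if two_cut:
            span = int(rng.geometric(span_p))
            partner = e + span
            if partner <= n_edges and edge_chrom[partner] == edge_chrom[e]:
                live[partner] = False
    return out


def simulate_reference(
    graph: GenomeGraph,
    config: SimConfig,
    spots: Optional[SpotAssignment] = None,
    rng: Optional[np.random.Generator] = None,
) -> GenomeGraph:
    """Literal per-edge-minimum implementation, kept as a slow oracle.

    At every step an exponential waiting time is drawn for *each* original
    edge and the minimum decides the next event.  Distributionally
    identical to :func:`simulate`; used to cross-check the superposition
    sampling on small genomes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = graph.copy()
    n_edges = out.edge_count
    if config.model_id == "hotspot":
        if spots is None:
            raise ValueError("hotspot simulation requires a SpotAssignment")
        rates = np.where(spots.is_hot[1:], config.params.kappa_h, config.params.kappa_c)
    else:
        rate = config.params.kappa if config.model_id == "one_cut" else config.params.gamma
        rates = np.full(n_edges, rate)
    if not np.any(rates > 0):
        return out
    two_cut = config.model_id == "two_cut"
    if two_cut:
        span_p = -np.expm1(-config.params.theta)
    t_now = 0.0
    while True:
        with np.errstate(divide="ignore"):
            waits = rng.exponential(np.where(rates > 0, 1.0 / rates, np.inf))
        idx = int(np.argmin(waits))
        t_now += waits[idx]
        if t_now >= config.t_max:
            break
        e = idx + 1
        out.live[e] = False
        if two_cut:
            span = int(rng.geometric(span_p))
            partner = e + span
            if partner <= n_edges and out.edge_chrom[partner] == out.edge_chrom[e]:
                out.live[partner] = False
    return out


def block_sizes(graph: GenomeGraph) -> np.ndarray:
    """Connected-component sizes (genes) of the surviving adjacency graph.

    Components are maximal runs of genes joined by live edges, so sizes
    within a chromosome are the gaps between consecutive removed edges;
    they always sum to the total gene count.
    """
    sizes: list[np.ndarray] = []
    e = 1
    for size in graph.chromosome_sizes:
        chrom_edges = size - 1
        removed_local = np.flatnonzero(~graph.live[e : e + chrom_edges]) + 1
        bounds = np.concatenate(([0], removed_local, [size]))
        sizes.append(np.diff(bounds))
        e += chrom_edges
    return np.concatenate(sizes).astype(np.int64)


@dataclasses.dataclass(frozen=True)
class EnsembleResult:
    """Block size distributions across independent replicate simulations.

    ``support`` is the union of observed sizes; ``mean_prob`` and
    ``sd_prob`` are the mean and (population) standard deviation over
    replicates of each size's empirical probability, where a replicate's
    empirical probability is its count of blocks of that size divided by
    its total number of blocks.
    """

    replicate_block_sizes: tuple[np.ndarray, ...]
    support: np.ndarray
    mean_prob: np.ndarray
    sd_prob: np.ndarray

    def pooled_counts(self) -> dict[int, int]:
        """Total block count per size, summed over replicates."""
        pooled = np.concatenate(self.replicate_block_sizes)
        values, counts = np.unique(pooled, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def run_ensemble(config: SimConfig, chromosome_sizes: Sequence[int]) -> EnsembleResult:
    """Run ``config.replicates`` independent simulations and summarize them.

    Replicate generators are spawned from a single seed sequence, so the
    whole ensemble is reproducible from ``config.seed``.  For the hotspot
    model a fresh spot assignment is drawn per replicate.
    """
    template = build_genome(chromosome_sizes)
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    per_replicate: list[np.ndarray] = []
    for seq in child_seeds:
        rng = np.random.default_rng(seq)
        spots = None
        if config.model_id == "hotspot":
            spots = assign_spots(template, config.params, rng)
        evolved = simulate(template, config, spots=spots, rng=rng)
        per_replicate.append(block_sizes(evolved))

    support = np.unique(np.concatenate(per_replicate))
    probs = np.zeros((config.replicates, support.size))
    for i, blocks in enumerate(per_replicate):
        values, counts = np.unique(blocks, return_counts=True)
        idx = np.searchsorted(support, values)
        probs[i, idx] = counts / blocks.size
    return EnsembleResult(
        replicate_block_sizes=tuple(per_replicate),
        support=support,
        mean_prob=probs.mean(axis=0),
        sd_prob=probs.std(axis=0, ddof=0),
    )
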