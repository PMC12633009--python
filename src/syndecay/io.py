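"""Tabular file formats for block size data, fits and rates.

All tabular exchange is tab-separated text with a ``#``-prefixed metadata
header (tool version, seed, resolved configuration and its hash) so that
any artifact records how to regenerate it.  Nested fit records are
JSON-lines, one record per pair x model.

Block size tables
    columns ``pair_id, species_a, species_b, t_subs_per_site,
    block_size, count`` — one row per (pair, size); duplicate rows for
    the same pair and size are summed with a warning.
Ensemble summaries
    columns ``block_size, mean_prob, sd_prob``.
Divergence-time tables
    columns ``species_a, species_b, split_time_mya`` with optional
    ``syntenic_genes`` for breakpoint-rate conversion.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from syndecay.fitting import EmpiricalPMF, FitResult, empirical_pmf
from syndecay.simulate import EnsembleResult

logger = logging.getLogger("syndecay")

__all__ = [
    "metadata_header",
    "read_block_sizes",
    "write_block_sizes",
    "write_ensemble_summary",
    "write_replicate_blocks",
    "write_fits_jsonl",
    "read_fits_jsonl",
    "write_fit_summary",
    "read_divergence_times",
]

BLOCK_COLUMNS = [
    "pair_id",
    "species_a",
    "species_b",
    "t_subs_per_site",
    "block_size",
    "count",
]


class MalformedTableError(ValueError):
    """A tabular input failed validation; the message carries the line number."""


def metadata_header(config: Optional[Mapping] = None, seed: Optional[int] = None) -> str:
    """Build the ``#`` metadata block written at the top of every artifact."""
    from syndecay import __version__

    lines = [f"# syndecay {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        blob = json.dumps(dict(config), sort_keys=True, default=str)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
        lines.append(f"# config: {blob}")
        lines.append(f"# config_sha256: {digest}")
    return "\n".join(lines) + "\n"


def _write_table(path: Union[str, Path], frame: pd.DataFrame, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False)


def read_block_sizes(path: Union[str, Path]) -> list[EmpiricalPMF]:
    """Read a per-pair block size table into one EmpiricalPMF per pair.

    Rows are validated with their line numbers; duplicate (pair, size)
    rows are summed with a logged warning.  The returned distributions
    keep every observed size (``n_min = 1``); the fitting step applies
    its own truncation.
    """
    path = Path(path)
    pair_counts: dict[str, dict[int, float]] = {}
    pair_t: dict[str, float] = {}
    pair_species: dict[str, tuple[str, str]] = {}
    header: Optional[list[str]] = None
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in BLOCK_COLUMNS if c not in header]
                if missing:
                    raise MalformedTableError(
                        f"{path}:{lineno}: missing required columns {missing}"
                    )
                continue
            if len(row) != len(header):
                raise MalformedTableError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rec = dict(zip(header, row))
            pair = rec["pair_id"]
            try:
                t = float(rec["t_subs_per_site"])
                size = int(rec["block_size"])
                count = int(rec["count"])
            except ValueError as exc:
                raise MalformedTableError(f"{path}:{lineno}: {exc}") from exc
            if t < 0:
                raise MalformedTableError(f"{path}:{lineno}: negative distance {t}")
            if size < 1:
                raise MalformedTableError(f"{path}:{lineno}: block_size must be >= 1, got {size}")
            if count < 1:
                raise MalformedTableError(f"{path}:{lineno}: count must be >= 1, got {count}")
            if pair in pair_t and pair_t[pair] != t:
                raise MalformedTableError(
                    f"{path}:{lineno}: inconsistent t for pair {pair!r} "
                    f"({pair_t[pair]} vs {t})"
                )
            pair_t[pair] = t
            pair_species.setdefault(pair, (rec["species_a"], rec["species_b"]))
            counts = pair_counts.setdefault(pair, {})
            if size in counts:
                logger.warning(
                    "%s:%d: duplicate row for pair %r block_size %d; summing counts",
                    path,
                    lineno,
                    pair,
                    size,
                )
            counts[size] = counts.get(size, 0) + count
    if header is None:
        raise MalformedTableError(f"{path}: empty table")
    out = []
    for pair, counts in pair_counts.items():
        pmf = empirical_pmf(counts, t=pair_t[pair], n_min=1, pair_id=pair)
        out.append(pmf)
    return out


def write_block_sizes(
    path: Union[str, Path],
    pairs: Sequence[EmpiricalPMF],
    species: Optional[Mapping[str, tuple[str, str]]] = None,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write per-pair block size counts in the standard exchange format."""
    rows = []
    for pmf in pairs:
        sp_a, sp_b = (species or {}).get(pmf.pair_id, (pmf.pair_id, pmf.pair_id))
        for size, count in zip(pmf.sizes, pmf.counts):
            rows.append(
                {
                    "pair_id": pmf.pair_id,
                    "species_a": sp_a,
                    "species_b": sp_b,
                    "t_subs_per_site": pmf.t,
                    "block_size": int(size),
                    "count": int(count),
                }
            )
    frame = pd.DataFrame(rows, columns=BLOCK_COLUMNS)
    _write_table(path, frame, metadata_header(config, seed))


def write_ensemble_summary(
    path: Union[str, Path],
    result: EnsembleResult,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write per-size mean and SD of empirical probability over replicates."""
    frame = pd.DataFrame(
        {
            "block_size": result.support,
            "mean_prob": result.mean_prob,
            "sd_prob": result.sd_prob,
        }
    )
    _write_table(path, frame, metadata_header(config, seed))


def write_replicate_blocks(
    path: Union[str, Path],
    result: EnsembleResult,
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Write per-replicate block size counts (replicate, block_size, count)."""
    rows = []
    for rep, blocks in enumerate(result.replicate_block_sizes):
        values, counts = pd.Series(blocks).value_counts().sort_index().reset_index().values.T
        for size, count in zip(values, counts):
            rows.append({"replicate": rep, "block_size": int(size), "count": int(count)})
    frame = pd.DataFrame(rows, columns=["replicate", "block_size", "count"])
    _write_table(path, frame, metadata_header(config, seed))


def _fit_record(pmf: EmpiricalPMF, fit: FitResult) -> dict:
    from syndecay.models import TwoCutParams
    from syndecay.models import multicut_error, overlap_error

    record = {
        "pair_id": pmf.pair_id,
        "t_subs_per_site": pmf.t,
        "n_min": pmf.n_min,
        "n_max": pmf.n_max,
        "model": fit.model_id,
        "params": fit.params_dict(),
        "kl": fit.kl,
        "restarts_converged": fit.restarts_converged,
        "best_start_index": fit.best_start_index,
    }
    if fit.model_id in ("two_cut", "combined"):
        two = TwoCutParams(gamma=fit.params.gamma, theta=fit.params.theta)
        record["epsilon_overlap"] = overlap_error(two, pmf.t)
        record["epsilon_multicut"] = multicut_error(two, pmf.t)
    return record


def write_fits_jsonl(
    path: Union[str, Path],
    fits: Iterable[tuple[EmpiricalPMF, FitResult]],
) -> None:
    """Write fit records as JSON-lines, one per (pair, model)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for pmf, fit in fits:
            fh.write(json.dumps(_fit_record(pmf, fit), sort_keys=True) + "\n")


def read_fits_jsonl(path: Union[str, Path]) -> list[dict]:
    """Read fit records written by :func:`write_fits_jsonl`."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records


def write_fit_summary(
    path: Union[str, Path],
    records: Sequence[dict],
    config: Optional[Mapping] = None,
    seed: Optional[int] = None,
) -> None:
    """Flat TSV summary of fit records (one row per pair x model)."""
    rows = []
    for rec in records:
        row = {
            "pair_id": rec["pair_id"],
            "model": rec["model"],
            "t_subs_per_site": rec["t_subs_per_site"],
            "kl": rec["kl"],
        }
        for name, value in rec["params"].items():
            row[name] = value
        rows.append(row)
    frame = pd.DataFrame(rows)
    _write_table(path, frame, metadata_header(config, seed))


def read_divergence_times(path: Union[str, Path]) -> pd.DataFrame:
    """Read a divergence-time table (species_a, species_b, split_time_mya).

    The optional ``syntenic_genes`` column supplies S for rate
    conversion.  ``split_time_mya`` is a one-way time to the common
    ancestor; rate computations double it by default.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"species_a", "species_b", "split_time_mya"}
    missing = required - set(frame.columns)
    if missing:
        raise MalformedTableError(f"{path}: missing required columns {sorted(missing)}")
    if (frame["split_time_mya"] <= 0).any():
        raise MalformedTableError(f"{path}: split times must be positive")
    return frame
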