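"""End-to-end simulation drivers: ideal coverage curves, Monte Carlo runs with
errors, and parameter sweeps over the three error axes.

Randomness is managed so that parallel or sharded execution cannot change
results: a master seed spawns one independent substream per protein (keyed by
the protein's index in the proteome) and one per sweep combination, via
``numpy.random.SeedSequence``. Sharding a run over protein subsets and merging
the shard tries therefore reproduces the unsharded result exactly.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digestion import AnchorMode, Peptide, digest, filter_by_anchor, get_protease
from .encoding import encode_ideal, get_scheme, validate_scheme_anchor
from .errors import ErrorParams, halflife_to_decay_constant, simulate_batch
from .proteome import ProteinRecord
from .trie import (
    DEFAULT_MIN_COUNT,
    DEFAULT_RIVAL_FRACTION,
    AttributionTrie,
    CoverageSummary,
    merge,
    proteome_coverage,
)

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "effective_min_count",
    "anchored_peptides",
    "ideal_coverage",
    "ideal_coverage_curve",
    "run_monte_carlo",
    "parameter_sweep",
    "default_sweep_axes",
    "DEFAULT_DYE_FAILURE_VALUES",
    "DEFAULT_EDMAN_EFFICIENCY_VALUES",
    "DEFAULT_HALF_LIFE_CYCLES",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with every configuration problem listed at once."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Monte Carlo fluorosequencing experiment.

    Defaults follow the reference experiment: 30 Edman cycles, 10,000 simulated
    copies per peptide (use ``depth=100``–500 for desk-scale runs; outputs are
    then labeled scaled-down), and error-free chemistry unless ``params`` says
    otherwise. ``min_count=None`` scales the attribution threshold of 10 per
    10,000 copies proportionally with depth.
    """

    protease: str = "gluc"
    anchor: str = "cysteine"
    scheme: str = "K"
    cycles: int = 30
    depth: int = 10_000
    params: ErrorParams = field(default_factory=ErrorParams)
    seed: int = 0
    min_count: int | None = None
    rival_fraction: float = DEFAULT_RIVAL_FRACTION

    def validate(self) -> None:
        problems = []
        try:
            get_protease(self.protease)
        except KeyError as exc:
            problems.append(str(exc))
        try:
            AnchorMode(self.anchor)
        except ValueError:
            problems.append(f"unknown anchor mode {self.anchor!r}")
        try:
            scheme = get_scheme(self.scheme)
        except KeyError as exc:
            problems.append(str(exc))
            scheme = None
        if scheme is not None:
            try:
                validate_scheme_anchor(scheme, AnchorMode(self.anchor))
            except ValueError as exc:
                problems.append(str(exc))
        if self.cycles < 1:
            problems.append(f"cycles must be >= 1, got {self.cycles}")
        if self.depth < 1:
            problems.append(f"depth must be >= 1, got {self.depth}")
        if self.min_count is not None and self.min_count < 1:
            problems.append(f"min_count must be >= 1, got {self.min_count}")
        if not 0.0 < self.rival_fraction <= 1.0:
            problems.append(f"rival_fraction must be in (0, 1], got {self.rival_fraction}")
        if problems:
            raise ConfigError("; ".join(problems))


def effective_min_count(depth: int, min_count: int | None = None) -> int:
    """Attribution count threshold: 10 per 10,000 copies, scaled proportionally
    with simulation depth (floored at 1) unless given explicitly."""
    if min_count is not None:
        return min_count
    scaled = max(1, round(DEFAULT_MIN_COUNT * depth / 10_000))
    if depth != 10_000:
        log.info("scaled attribution min_count to %d for depth %d", scaled, depth)
    return scaled


def anchored_peptides(
    proteome: Sequence[ProteinRecord], protease: str, anchor: str
) -> list[list[Peptide]]:
    """Digest and anchor-filter each protein; one (possibly empty) peptide list
    per protein, aligned with the proteome order."""
    rule = get_protease(protease)
    mode = AnchorMode(anchor)
    return [filter_by_anchor(digest(prot, rule), mode) for prot in proteome]


# ---------------------------------------------------------------------------
# Ideal (error-free) mode — computed analytically, no sampling.
# ---------------------------------------------------------------------------

def _ideal_reads(
    proteome: Sequence[ProteinRecord], protease: str, anchor: str, scheme: str,
    cycles: int,
) -> list[list]:
    scheme_obj = get_scheme(scheme)
    validate_scheme_anchor(scheme_obj, anchor)
    return [
        [encode_ideal(pep, scheme_obj, cycles) for pep in peps]
        for peps in anchored_peptides(proteome, protease, anchor)
    ]


def _coverage_from_reads(
    proteome: Sequence[ProteinRecord], reads_per_protein: list[list]
) -> CoverageSummary:
    producers: dict = {}
    for prot, reads in zip(proteome, reads_per_protein):
        for read in reads:
            if read:  # empty reads are never attributable
                producers.setdefault(read, set()).add(prot.protein_id)
    identified = frozenset(
        next(iter(pids)) for pids in producers.values() if len(pids) == 1
    )
    return CoverageSummary(identified, len(proteome))


def ideal_coverage(
    proteome: Sequence[ProteinRecord],
    protease: str,
    anchor: str,
    scheme: str,
    cycles: int,
) -> CoverageSummary:
    """Error-free proteome coverage at one cycle budget: a protein is identified
    iff one of its anchored peptides yields a non-empty read produced by no
    other protein. Deterministic set arithmetic, no sampling."""
    if not proteome:
        raise ValueError("ideal_coverage requires a non-empty proteome")
    return _coverage_from_reads(
        proteome, _ideal_reads(proteome, protease, anchor, scheme, cycles)
    )


def ideal_coverage_curve(
    proteome: Sequence[ProteinRecord],
    protease: str,
    anchor: str,
    scheme: str,
    max_cycles: int,
) -> pd.DataFrame:
    """Coverage as a function of the cycle budget (0..max_cycles): columns
    ``cycles``, ``identified``, ``fraction``. Monotone non-decreasing."""
    if not proteome:
        raise ValueError("ideal_coverage_curve requires a non-empty proteome")
    full_reads = _ideal_reads(proteome, protease, anchor, scheme, max_cycles)
    rows = []
    for n in range(0, max_cycles + 1):
        truncated = [[read.truncated(n) for read in reads] for reads in full_reads]
        cov = _coverage_from_reads(proteome, truncated)
        rows.append({"cycles": n, "identified": len(cov.identified),
                     "fraction": cov.fraction})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte Carlo with errors
# ---------------------------------------------------------------------------

def _protein_rng(seed: int, protein_index: int) -> np.random.Generator:
    """Independent substream per protein, invariant to sharding."""
    return np.random.default_rng(np.random.SeedSequence([seed, protein_index]))


def run_monte_carlo(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    shards: int = 1,
) -> tuple[AttributionTrie, CoverageSummary]:
    """Full error-laden simulation: digest, anchor-filter, simulate ``depth``
    copies of every anchored peptide, collate reads into a trie, and score
    coverage via unique attributions.

    ``shards`` partitions the proteome round-robin and merges per-shard tries;
    because random substreams are keyed per protein, any shard count yields the
    identical result.
    """
    if not proteome:
        raise ValueError("run_monte_carlo requires a non-empty proteome")
    config.validate()
    peptides_per_protein = anchored_peptides(proteome, config.protease, config.anchor)
    scheme = get_scheme(config.scheme)

    shard_tries = []
    for shard in range(max(1, shards)):
        trie = AttributionTrie()
        for idx in range(shard, len(proteome), max(1, shards)):
            prot = proteome[idx]
            rng = _protein_rng(config.seed, idx)
            for pep in peptides_per_protein[idx]:
                counts = simulate_batch(
                    pep, scheme, config.params, config.cycles, config.depth, rng
                )
                for read, count in counts.items():
                    trie.insert(read, prot.protein_id, count)
        shard_tries.append(trie)
    master = shard_tries[0] if len(shard_tries) == 1 else merge(*shard_tries)

    coverage = proteome_coverage(
        master,
        proteome,
        min_count=effective_min_count(config.depth, config.min_count),
        rival_fraction=config.rival_fraction,
    )
    return master, coverage


# ---------------------------------------------------------------------------
# Parameter sweep
# ---------------------------------------------------------------------------

#: Default sweep axes (six values each). Dye-failure and Edman axes span the
#: reference ranges exactly; the photobleach half-life axis endpoints are
#: stated (infinity down to heavy bleaching) but the interior values are not
#: printed anywhere, so these are documented presets, freely overridable.
DEFAULT_DYE_FAILURE_VALUES = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
DEFAULT_EDMAN_EFFICIENCY_VALUES = (0.90, 0.92, 0.94, 0.96, 0.98, 1.00)
DEFAULT_HALF_LIFE_CYCLES = (math.inf, 5400.0, 1800.0, 600.0, 210.0, 70.0)


def default_sweep_axes() -> tuple[tuple, tuple, tuple]:
    return (
        DEFAULT_DYE_FAILURE_VALUES,
        DEFAULT_EDMAN_EFFICIENCY_VALUES,
        DEFAULT_HALF_LIFE_CYCLES,
    )


def _combo_seed(seed: int, index: int) -> int:
    """Derived per-combination seed (< 2^31), independent across combinations."""
    return int(np.random.SeedSequence([seed, 0x5EED, index]).generate_state(1)[0] >> 1)


def parameter_sweep(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    dye_failure_values: Iterable[float] = DEFAULT_DYE_FAILURE_VALUES,
    edman_efficiency_values: Iterable[float] = DEFAULT_EDMAN_EFFICIENCY_VALUES,
    half_life_cycles_values: Iterable[float] = DEFAULT_HALF_LIFE_CYCLES,
) -> pd.DataFrame:
    """Grid sweep over the three error axes; one row per combination with
    columns ``dye_failure``, ``edman_efficiency``, ``half_life_cycles``,
    ``coverage``, ``identified``, ``runtime_s``, ``depth``, ``scaled_down``.

    Rows are independent (per-combination derived seeds) and order-insensitive;
    the default 6x6x6 grid yields 216 combinations.
    """
    grid = list(
        itertools.product(
            list(dye_failure_values),
            list(edman_efficiency_values),
            list(half_life_cycles_values),
        )
    )
    if not grid:
        raise ValueError("parameter_sweep requires a non-empty grid")
    rows = []
    for index, (u, p, half_life) in enumerate(grid):
        combo_config = dataclasses.replace(
            config,
            params=ErrorParams(
                dye_failure_u=u,
                edman_success_p=p,
                photobleach_b=halflife_to_decay_constant(half_life),
                exposure_seconds_per_cycle=config.params.exposure_seconds_per_cycle,
            ),
            seed=_combo_seed(config.seed, index),
        )
        start = time.perf_counter()
        _trie, coverage = run_monte_carlo(proteome, combo_config)
        rows.append(
            {
                "dye_failure": u,
                "edman_efficiency": p,
                "half_life_cycles": half_life,
                "coverage": coverage.fraction,
                "identified": len(coverage.identified),
                "runtime_s": time.perf_counter() - start,
                "depth": config.depth,
                "scaled_down": config.depth != 10_000,
            }
        )
    return pd.DataFrame(rows)
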