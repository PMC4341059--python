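"""Stochastic error models for single-molecule Edman sequencing.

Three error processes corrupt an ideal read, applied in order:

1. **Dye failure** — each label independently never fluoresces with probability
   ``u`` (failed attachment or a dark fluorophore): an apparent substitution.
2. **Edman inefficiency** — each cycle removes the N-terminal residue with
   probability ``p``; failures (q = 1 − p) delay downstream removals, dilating
   inter-label intervals. An interval of ``d`` residues takes ``d + e`` cycles
   with negative-binomial probability C(d−1+e, e) · p^d · q^e.
3. **Photobleaching** — each fluorophore survives ``k`` cycles with probability
   e^(−b·k); a bleach before removal shifts the drop to an earlier cycle (an
   apparent upstream residue swap).

Edman chemistry cannot proceed past the surface anchor, so labels at or after
the anchor are never removed — but can still bleach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Counter as CounterT
from collections import Counter

import numpy as np
from scipy import stats

from .digestion import Peptide
from .encoding import Fluorosequence, LabelingScheme, get_scheme, label_positions

__all__ = [
    "ErrorParams",
    "halflife_to_decay_constant",
    "minutes_to_cycles",
    "dilation_pmf",
    "apply_dye_failure",
    "apply_edman_dilation",
    "apply_photobleaching",
    "simulate_observed_fluorosequence",
    "simulate_batch",
]


def halflife_to_decay_constant(half_life_cycles: float) -> float:
    """Photobleach decay constant b = ln 2 / half-life; infinite half-life → 0.

    With b, a fluorophore survives k cycles with probability e^(−b·k); at
    k = half-life the survival is exactly 0.5.
    """
    if half_life_cycles <= 0:
        raise ValueError("half-life must be positive")
    if math.isinf(half_life_cycles):
        return 0.0
    return math.log(2.0) / half_life_cycles


def minutes_to_cycles(minutes: float, exposure_seconds_per_cycle: float = 1.0) -> float:
    """Convert a photobleaching lifetime in minutes of illumination into
    experimental cycles: laser exposure is additive, so lifetime in cycles is
    minutes × 60 / exposure-per-cycle (e.g. 30 min at 1 s/cycle = 1800 cycles)."""
    if exposure_seconds_per_cycle <= 0:
        raise ValueError("exposure must be positive")
    return minutes * 60.0 / exposure_seconds_per_cycle


@dataclass(frozen=True)
class ErrorParams:
    """Error-model parameters.

    dye_failure_u : per-label probability of never fluorescing, in [0, 1].
    edman_success_p : per-cycle removal success probability, in (0, 1].
    photobleach_b : exponential decay constant per cycle (0 = no bleaching).
    exposure_seconds_per_cycle : only used to convert lifetimes in minutes.
    """

    dye_failure_u: float = 0.0
    edman_success_p: float = 1.0
    photobleach_b: float = 0.0
    exposure_seconds_per_cycle: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.dye_failure_u <= 1.0:
            raise ValueError(f"dye_failure_u={self.dye_failure_u} outside [0, 1]")
        if not 0.0 < self.edman_success_p <= 1.0:
            raise ValueError(f"edman_success_p={self.edman_success_p} outside (0, 1]")
        if self.photobleach_b < 0.0:
            raise ValueError(f"photobleach_b={self.photobleach_b} must be >= 0")
        if self.exposure_seconds_per_cycle <= 0.0:
            raise ValueError("exposure_seconds_per_cycle must be positive")

    @classmethod
    def from_halflife(
        cls,
        dye_failure_u: float = 0.0,
        edman_success_p: float = 1.0,
        photobleach_half_life_cycles: float = math.inf,
        exposure_seconds_per_cycle: float = 1.0,
    ) -> "ErrorParams":
        return cls(
            dye_failure_u,
            edman_success_p,
            halflife_to_decay_constant(photobleach_half_life_cycles),
            exposure_seconds_per_cycle,
        )


def dilation_pmf(d: int, e: int, p: float) -> float:
    """Probability that an inter-label interval of ``d`` residues takes ``d + e``
    cycles: C(d−1+e, e) · p^d · q^e (negative binomial — e failures interleaved
    before the d-th success, last trial a success)."""
    if d < 1:
        raise ValueError("interval length d must be >= 1")
    if e < 0:
        raise ValueError("extra cycles e must be >= 0")
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if p == 1.0:
        return 1.0 if e == 0 else 0.0
    return float(stats.nbinom.pmf(e, d, p))


def apply_dye_failure(
    labels: list[tuple[int, str]], u: float, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Independently delete each label with probability ``u`` (order preserved)."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"dye failure probability {u} outside [0, 1]")
    if u == 0.0:
        return list(labels)
    keep = rng.random(len(labels)) >= u
    return [lab for lab, k in zip(labels, keep) if k]


def apply_edman_dilation(
    labels: list[tuple[int, str]],
    p: float,
    anchor_index: int | None,
    rng: np.random.Generator,
) -> list[tuple[int, str, float]]:
    """Assign each surviving label its removal cycle under imperfect Edman
    chemistry.

    For consecutive labeled positions i1 < i2 < … the intervals are d1 = i1,
    dj = ij − i(j−1); each draws extra cycles e ~ NB(d, p) and removal cycles
    are the running sums of (d + e). Labels at or after the anchor are never
    removed (removal cycle = +inf).

    Returns (position, channel, removal_cycle) triples.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"Edman success probability {p} outside (0, 1]")
    out: list[tuple[int, str, float]] = []
    prev_pos = 0
    cycle = 0
    for pos, ch in labels:
        if anchor_index is not None and pos >= anchor_index:
            out.append((pos, ch, math.inf))
            continue
        d = pos - prev_pos
        e = 0 if p == 1.0 else int(rng.negative_binomial(d, p))
        cycle += d + e
        out.append((pos, ch, float(cycle)))
        prev_pos = pos
    return out


def apply_photobleaching(
    labels_with_removal: list[tuple[int, str, float]],
    b: float,
    budget: int,
    rng: np.random.Generator,
) -> Fluorosequence:
    """Draw a continuous bleach time T ~ Exponential(rate b) per fluorophore
    (infinite if b = 0); the observed drop lands at min(removal cycle, ⌈T⌉) and
    is discarded beyond the cycle budget. Duplicate (channel, cycle) events
    collapse to a single drop — a luminosity decrease is a binary per-channel
    observation."""
    if b < 0.0:
        raise ValueError(f"decay constant {b} must be >= 0")
    drops = []
    for _pos, ch, removal in labels_with_removal:
        bleach = math.inf if b == 0.0 else math.ceil(rng.exponential(1.0 / b))
        observed = min(removal, bleach)
        if observed <= budget:
            drops.append((ch, int(observed)))
    return Fluorosequence.from_drops(drops)


def simulate_observed_fluorosequence(
    peptide: Peptide,
    scheme: str | LabelingScheme,
    params: ErrorParams,
    budget: int,
    rng: np.random.Generator,
) -> Fluorosequence:
    """One simulated read of one peptide copy: label → dye failure → Edman
    dilation → photobleaching, in that order. Deterministic for a fixed rng
    state; with u=0, p=1, b=0 it equals :func:`~fluorosim.encoding.encode_ideal`."""
    scheme = get_scheme(scheme)
    labels = label_positions(peptide, scheme)
    survivors = apply_dye_failure(labels, params.dye_failure_u, rng)
    with_removal = apply_edman_dilation(
        survivors, params.edman_success_p, peptide.anchor_index, rng
    )
    return apply_photobleaching(with_removal, params.photobleach_b, budget, rng)


def simulate_batch(
    peptide: Peptide,
    scheme: str | LabelingScheme,
    params: ErrorParams,
    budget: int,
    depth: int,
    rng: np.random.Generator,
) -> CounterT[Fluorosequence]:
    """Simulate ``depth`` copies of a peptide at once; returns read → count
    (empty reads included).

    Vectorized equivalent of calling :func:`simulate_observed_fluorosequence`
    ``depth`` times: removal cycles are drawn over all removable labels — by
    negative-binomial additivity the joint law of the dye-surviving labels'
    removal cycles is identical to dilating survivor intervals only.
    """
    scheme = get_scheme(scheme)
    labels = label_positions(peptide, scheme)
    out: CounterT[Fluorosequence] = Counter()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    m = len(labels)
    if m == 0:
        out[Fluorosequence()] = depth
        return out

    anchor = peptide.anchor_index
    channels = [ch for _pos, ch in labels]
    p = params.edman_success_p

    removal = np.full((depth, m), np.inf)
    prev_pos = 0
    cum = np.zeros(depth, dtype=np.int64)
    for j, (pos, _ch) in enumerate(labels):
        if anchor is not None and pos >= anchor:
            continue  # anchored side: never removed
        d = pos - prev_pos
        if p < 1.0:
            cum = cum + rng.negative_binomial(d, p, size=depth)
        removal[:, j] = pos + cum
        prev_pos = pos

    u = params.dye_failure_u
    if u > 0.0:
        removal = np.where(rng.random((depth, m)) < u, np.nan, removal)

    b = params.photobleach_b
    if b > 0.0:
        bleach = np.ceil(rng.exponential(1.0 / b, size=(depth, m)))
        observed = np.minimum(removal, bleach)  # minimum propagates NaN (dye-failed)
    else:
        observed = removal
    observed = np.where(np.isnan(observed) | (observed > budget), 0, observed).astype(
        np.int64
    )

    for row in observed:
        out[Fluorosequence.from_drops(
            (channels[j], int(c)) for j, c in enumerate(row) if c > 0
        )] += 1
    return out
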