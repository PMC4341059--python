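"""Labeling schemes and the deterministic (error-free) fluorosequence encoder.

A labeling scheme maps residue types to fluorescent channels; several residues
may share a channel (Asp and Glu are chemically indistinguishable for labeling
and share the "E" channel in the four-label preset). Encoding a peptide under
ideal chemistry gives one luminosity drop per labeled residue, at the cycle
equal to its position — provided the position lies before the surface anchor
and within the cycle budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .digestion import AnchorMode, Peptide

__all__ = [
    "LabelingScheme",
    "SCHEMES",
    "get_scheme",
    "validate_scheme_anchor",
    "Fluorosequence",
    "label_positions",
    "encode_ideal",
]


@dataclass(frozen=True)
class LabelingScheme:
    """Map from residue code to channel identifier."""

    name: str
    channel_of: Mapping[str, str]

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.channel_of.values())))

    def relabeled(self, channel_map: Mapping[str, str]) -> "LabelingScheme":
        """Apply a bijection on channel identifiers (used to check that channel
        naming is purely cosmetic)."""
        return LabelingScheme(
            self.name + "#relabeled",
            {aa: channel_map[ch] for aa, ch in self.channel_of.items()},
        )


#: Presets. D and E share one channel ("E") in the four-label scheme because
#: their side-chain reactivity is indistinguishable for labeling purposes.
SCHEMES: dict[str, LabelingScheme] = {
    "K": LabelingScheme("K", {"K": "K"}),
    "K+Y": LabelingScheme("K+Y", {"K": "K", "Y": "Y"}),
    "K+Y+W": LabelingScheme("K+Y+W", {"K": "K", "Y": "Y", "W": "W"}),
    "K+Y+W+DE": LabelingScheme(
        "K+Y+W+DE", {"K": "K", "Y": "Y", "W": "W", "D": "E", "E": "E"}
    ),
}


def get_scheme(scheme: str | LabelingScheme) -> LabelingScheme:
    if isinstance(scheme, LabelingScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise KeyError(f"unknown scheme {scheme!r}; presets: {sorted(SCHEMES)}") from None


def validate_scheme_anchor(
    scheme: str | LabelingScheme, anchor: str | AnchorMode
) -> None:
    """Reject schemes that label the anchoring residue: in cysteine mode the Cys
    side chain is occupied by the surface thioether and cannot carry a dye."""
    scheme = get_scheme(scheme)
    anchor = AnchorMode(anchor)
    if anchor is AnchorMode.CYSTEINE and "C" in scheme.channel_of:
        raise ValueError(
            f"scheme {scheme.name!r} labels the cysteine anchor residue; "
            "the thioether anchor occupies the Cys side chain"
        )


_DROP_RE = re.compile(r"\(([^,()]+),(\d+)\)")


@dataclass(frozen=True)
class Fluorosequence:
    """An observed read: luminosity-drop events as (channel, cycle) pairs.

    Canonical form is sorted by (cycle, channel) with no duplicate pairs — a
    drop is a binary per-channel, per-cycle observation.
    """

    drops: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        keys = [(cycle, ch) for ch, cycle in self.drops]
        if any(cycle < 1 for cycle, _ in keys):
            raise ValueError("drop cycles must be >= 1")
        if keys != sorted(set(keys)):
            raise ValueError(
                "drops must be sorted by (cycle, channel) and duplicate-free; "
                "use Fluorosequence.from_drops to canonicalize"
            )

    @classmethod
    def from_drops(cls, drops: Iterable[tuple[str, int]]) -> "Fluorosequence":
        """Canonicalize: collapse duplicate (channel, cycle) pairs, sort by
        (cycle, channel)."""
        uniq = {(int(cycle), str(ch)) for ch, cycle in drops}
        return cls(tuple((ch, cycle) for cycle, ch in sorted(uniq)))

    def __bool__(self) -> bool:
        return bool(self.drops)

    def __len__(self) -> int:
        return len(self.drops)

    def __iter__(self):
        return iter(self.drops)

    def truncated(self, cycles: int) -> "Fluorosequence":
        """Restrict to drops within the first ``cycles`` experimental cycles."""
        return Fluorosequence(tuple(d for d in self.drops if d[1] <= cycles))

    def max_cycle(self) -> int:
        return max((cycle for _, cycle in self.drops), default=0)

    def to_string(self) -> str:
        """Canonical text form, e.g. ``(K,2),(K,4)``; empty read renders ``-``."""
        if not self.drops:
            return "-"
        return ",".join(f"({ch},{cycle})" for ch, cycle in self.drops)

    @classmethod
    def from_string(cls, text: str) -> "Fluorosequence":
        text = text.strip()
        if text in ("", "-"):
            return cls()
        matches = _DROP_RE.findall(text)
        expected = ",".join(f"({ch},{cy})" for ch, cy in matches)
        if not matches or expected != text.replace(" ", ""):
            raise ValueError(f"cannot parse fluorosequence string {text!r}")
        return cls.from_drops((ch, int(cy)) for ch, cy in matches)

    def pattern(self, cycles: int | None = None) -> str:
        """Human-readable per-cycle rendering, e.g. ``xKxxK``: one character per
        cycle, ``x`` for no drop, the channel's first character for a single
        drop, and ``*`` when several channels drop in the same cycle."""
        n = cycles if cycles is not None else self.max_cycle()
        per_cycle: dict[int, list[str]] = {}
        for ch, cycle in self.drops:
            per_cycle.setdefault(cycle, []).append(ch)
        out = []
        for cycle in range(1, n + 1):
            chans = per_cycle.get(cycle, [])
            if not chans:
                out.append("x")
            elif len(chans) == 1:
                out.append(chans[0][0])
            else:
                out.append("*")
        return "".join(out)


def label_positions(
    peptide: Peptide | str, scheme: str | LabelingScheme
) -> list[tuple[int, str]]:
    """All labeled positions of a peptide as (1-based position, channel), in
    N-to-C order."""
    scheme = get_scheme(scheme)
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    return [
        (i + 1, scheme.channel_of[aa])
        for i, aa in enumerate(seq)
        if aa in scheme.channel_of
    ]


def encode_ideal(
    peptide: Peptide, scheme: str | LabelingScheme, cycles: int
) -> Fluorosequence:
    """Error-free fluorosequence of a peptide under a cycle budget.

    A labeled position ``p`` produces a drop at cycle ``p`` iff ``p`` lies
    strictly before the anchor (Edman degradation cannot remove the anchor
    residue or anything at/after it) and within the budget. ``anchor_index``
    None means a free peptide: every position is removable.
    """
    if cycles < 0:
        raise ValueError("cycle budget must be >= 0")
    anchor = peptide.anchor_index
    drops = [
        (ch, pos)
        for pos, ch in label_positions(peptide, scheme)
        if (anchor is None or pos < anchor) and pos <= cycles
    ]
    return Fluorosequence.from_drops(drops)
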