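"""In-silico proteolysis, anchor filtering and per-peptide residue statistics.

Digestion is complete (no missed cleavages) and cuts C-terminal to the
protease's recognition residues, so the recognised residue stays at the
fragment's C-terminus. Anchoring either retains only cysteine-containing
peptides (surface attachment via the Cys thioether) or retains everything
(C-terminal attachment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .proteome import ProteinRecord

__all__ = [
    "ProteaseRule",
    "AnchorMode",
    "Peptide",
    "PROTEASES",
    "get_protease",
    "digest",
    "filter_by_anchor",
    "CountStats",
    "labelable_count_stats",
    "peptide_length_stats",
    "write_stats_tsv",
]


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage C-terminal to any residue in ``cleave_after``. The ``none``
    rule (empty set) performs no proteolysis."""

    name: str
    cleave_after: frozenset[str]


PROTEASES: dict[str, ProteaseRule] = {
    "gluc": ProteaseRule("gluc", frozenset("E")),       # GluC: after Glu
    "cnbr": ProteaseRule("cnbr", frozenset("M")),       # cyanogen bromide: after Met
    "trypsin": ProteaseRule("trypsin", frozenset("KR")),
    "none": ProteaseRule("none", frozenset()),
}


def get_protease(rule: str | ProteaseRule) -> ProteaseRule:
    if isinstance(rule, ProteaseRule):
        return rule
    try:
        return PROTEASES[rule.lower()]
    except KeyError:
        raise KeyError(
            f"unknown protease {rule!r}; presets: {sorted(PROTEASES)}"
        ) from None


class AnchorMode(str, Enum):
    """How peptides attach to the imaging surface."""

    CYSTEINE = "cysteine"
    C_TERMINUS = "c_terminus"


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment tied to its source protein.

    ``anchor_index`` is the 1-based position of the surface anchor: the first
    cysteine (cysteine mode), the peptide length (C-terminus mode), or None for
    a free peptide with no anchor constraint (sequencing can run to the end).
    """

    sequence: str
    source_protein_id: str = ""
    anchor_index: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def digest(protein: ProteinRecord | Peptide, rule: str | ProteaseRule) -> list[Peptide]:
    """Cut after every occurrence of a recognition residue (complete digestion).

    Order is preserved and concatenating the fragments reconstructs the input.
    Anchor indices are not assigned here; see :func:`filter_by_anchor`.
    """
    rule = get_protease(rule)
    seq = protein.sequence
    source = (
        protein.protein_id
        if isinstance(protein, ProteinRecord)
        else protein.source_protein_id
    )
    if not rule.cleave_after:
        return [Peptide(seq, source)]
    fragments = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in rule.cleave_after and i + 1 < len(seq):
            fragments.append(seq[start : i + 1])
            start = i + 1
    fragments.append(seq[start:])
    return [Peptide(frag, source) for frag in fragments]


def filter_by_anchor(
    peptides: Iterable[Peptide], anchor: str | AnchorMode
) -> list[Peptide]:
    """Keep peptides that can attach to the surface and set their anchor index.

    Cysteine mode keeps exactly the Cys-containing peptides (anchor at the
    first Cys); C-terminus mode keeps all (anchor at the last residue).
    """
    anchor = AnchorMode(anchor)
    kept = []
    for pep in peptides:
        if anchor is AnchorMode.CYSTEINE:
            pos = pep.sequence.find("C")
            if pos < 0:
                continue
            kept.append(Peptide(pep.sequence, pep.source_protein_id, pos + 1))
        else:
            kept.append(Peptide(pep.sequence, pep.source_protein_id, len(pep.sequence)))
    return kept


def _lower_median(values: Sequence[int]) -> int:
    """Median with the lower of the two central values for even-size samples,
    so length/count medians stay integers."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass(frozen=True)
class CountStats:
    """Histogram over integer values plus the (lower-convention) median."""

    histogram: dict[int, int]
    median: int
    n: int


def labelable_count_stats(
    peptides: Sequence[Peptide], residues: Iterable[str]
) -> CountStats:
    """Per-peptide counts of residues in the target set, e.g. how many lysines
    each peptide carries — the number of fluorophores a camera must resolve."""
    peptides = list(peptides)
    if not peptides:
        raise ValueError("labelable_count_stats requires a non-empty peptide collection")
    target = frozenset(residues)
    counts = [sum(1 for aa in pep.sequence if aa in target) for pep in peptides]
    return CountStats(dict(Counter(counts)), _lower_median(counts), len(counts))


def peptide_length_stats(peptides: Sequence[Peptide]) -> CountStats:
    """Histogram and median of peptide lengths."""
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptide_length_stats requires a non-empty peptide collection")
    lengths = [len(pep) for pep in peptides]
    return CountStats(dict(Counter(lengths)), _lower_median(lengths), len(lengths))


def write_stats_tsv(stats: CountStats, path: str | Path) -> None:
    """Export a histogram as two-column TSV (value, frequency)."""
    with open(path, "w") as fh:
        for value in sorted(stats.histogram):
            fh.write(f"{value}\t{stats.histogram[value]}\n")
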