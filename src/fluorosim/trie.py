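"""Prefix-trie collation of observed reads and protein attribution.

Every simulated read is inserted into a prefix trie keyed by its luminosity
drops; each node tallies how often each source protein produced the read ending
there. Normalising a node's counts gives the empirical attribution probability
mass function P[protein | read]. A read is *uniquely attributed* to its top
protein when that protein produced it often enough (sampling-error guard) and
all rivals combined hold less than a small share (confounding guard); a protein
is covered when it owns at least one uniquely attributed read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .encoding import Fluorosequence
from .proteome import ProteinRecord

__all__ = [
    "AttributionTrie",
    "AttributionPMF",
    "CoverageSummary",
    "merge",
    "proteome_coverage",
    "write_attributions_tsv",
]

#: Default attribution thresholds: at a simulation depth of 10,000 copies the
#: top protein must yield the read >= 10 times and rivals combined < 10%.
DEFAULT_MIN_COUNT = 10
DEFAULT_RIVAL_FRACTION = 0.10


class _Node:
    __slots__ = ("children", "counts")

    def __init__(self):
        self.children: dict[tuple[str, int], _Node] = {}
        self.counts: Counter[str] = Counter()


@dataclass(frozen=True)
class AttributionPMF:
    """Empirical posterior over source proteins at one trie node."""

    probabilities: dict[str, float]
    support_size: int
    top_protein: str
    top_share: float


@dataclass(frozen=True)
class CoverageSummary:
    """Proteins identified by at least one uniquely attributed read."""

    identified: frozenset[str]
    n_proteins: int

    @property
    def fraction(self) -> float:
        return len(self.identified) / self.n_proteins


class AttributionTrie:
    """Prefix trie over (channel, cycle) drop events with per-protein counts.

    Node keys carry absolute cycle indices, so shared trie prefixes encode
    shared read prefixes. A read's count lives at its final drop's node; a node
    may be terminal for one read and internal for longer ones. Empty reads go
    to a dedicated per-protein tally and are never attributable.
    """

    def __init__(self):
        self._root = _Node()
        self.empty_counts: Counter[str] = Counter()

    # -- construction -----------------------------------------------------

    def insert(
        self, fluorosequence: Fluorosequence | Sequence[tuple[str, int]],
        source_protein_id: str,
        count: int = 1,
    ) -> None:
        """Add ``count`` observations of a read from one source protein.

        The read must be canonical (sorted by (cycle, channel), no duplicates);
        non-canonical input raises rather than being silently reordered.
        """
        if count < 0:
            raise ValueError("count must be non-negative")
        if not isinstance(fluorosequence, Fluorosequence):
            fluorosequence = Fluorosequence(tuple(fluorosequence))  # validates
        if not fluorosequence:
            self.empty_counts[source_protein_id] += count
            return
        node = self._root
        for ch, cycle in fluorosequence:
            node = node.children.setdefault((ch, cycle), _Node())
        node.counts[source_protein_id] += count

    def update(self, other: "AttributionTrie") -> None:
        """In-place merge: adds ``other``'s per-node, per-protein counts."""

        def _merge(dst: _Node, src: _Node) -> None:
            dst.counts.update(src.counts)
            for key, child in src.children.items():
                _merge(dst.children.setdefault(key, _Node()), child)

        _merge(self._root, other._root)
        self.empty_counts.update(other.empty_counts)

    # -- queries ----------------------------------------------------------

    @property
    def total_observations(self) -> int:
        """All inserted observations, including the empty-read tally."""
        total = sum(self.empty_counts.values())
        stack = [self._root]
        while stack:
            node = stack.pop()
            total += sum(node.counts.values())
            stack.extend(node.children.values())
        return total

    def iter_reads(self) -> Iterator[tuple[Fluorosequence, Counter]]:
        """Yield (read, per-protein counts) for every observed non-empty read."""

        def _walk(node: _Node, path: tuple):
            if node.counts:
                yield Fluorosequence(path), node.counts
            for key in sorted(node.children):
                ch, cycle = key
                yield from _walk(node.children[key], path + ((ch, cycle),))

        yield from _walk(self._root, ())

    def _find(self, fluorosequence: Fluorosequence) -> _Node | None:
        node = self._root
        for ch, cycle in fluorosequence:
            node = node.children.get((ch, cycle))
            if node is None:
                return None
        return node

    def pmf_at(self, fluorosequence: Fluorosequence) -> AttributionPMF | None:
        """Attribution p.m.f. at a read's terminal node; None if the read was
        never observed (an "unobserved" signal, distinct from an error)."""
        node = self._find(fluorosequence)
        if node is None or not node.counts:
            return None
        total = sum(node.counts.values())
        probs = {pid: c / total for pid, c in node.counts.items()}
        top, top_count = max(node.counts.items(), key=lambda kv: (kv[1], kv[0]))
        return AttributionPMF(probs, len(probs), top, top_count / total)

    def unique_attributions(
        self,
        min_count: int = DEFAULT_MIN_COUNT,
        rival_fraction: float = DEFAULT_RIVAL_FRACTION,
    ) -> dict[Fluorosequence, str]:
        """Reads confidently attributable to a single protein.

        A read maps to its most frequent source protein iff that protein's
        count >= ``min_count`` and all other proteins combined account for
        strictly less than ``rival_fraction`` of the read's observations.
        """
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not 0.0 < rival_fraction <= 1.0:
            raise ValueError("rival_fraction must be in (0, 1]")
        attributed: dict[Fluorosequence, str] = {}
        for read, counts in self.iter_reads():
            total = sum(counts.values())
            top, top_count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if top_count >= min_count and (total - top_count) < rival_fraction * total:
                attributed[read] = top
        return attributed

    # -- serialization ----------------------------------------------------

    def dump(self, path: str | Path) -> None:
        """Write newline-delimited records ``read<TAB>protein<TAB>count`` (the
        empty read is rendered as ``-``), sorted — merge-friendly and diffable."""
        lines = []
        for read, counts in self.iter_reads():
            for pid in sorted(counts):
                lines.append(f"{read.to_string()}\t{pid}\t{counts[pid]}")
        for pid in sorted(self.empty_counts):
            lines.append(f"-\t{pid}\t{self.empty_counts[pid]}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def load(cls, path: str | Path) -> "AttributionTrie":
        trie = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                read_str, pid, count = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: expected 3 tab-separated fields")
            trie.insert(Fluorosequence.from_string(read_str), pid, int(count))
        return trie


def merge(*tries: AttributionTrie) -> AttributionTrie:
    """Merge shard tries into a master trie: union of paths, counts added."""
    out = AttributionTrie()
    for trie in tries:
        out.update(trie)
    return out


def proteome_coverage(
    trie: AttributionTrie,
    proteome: Sequence[ProteinRecord],
    min_count: int = DEFAULT_MIN_COUNT,
    rival_fraction: float = DEFAULT_RIVAL_FRACTION,
) -> CoverageSummary:
    """Fraction of the proteome owning at least one uniquely attributed read.

    The denominator is every protein in the input proteome, including those
    whose peptides all lacked an anchor.
    """
    if not proteome:
        raise ValueError("proteome_coverage requires a non-empty proteome")
    attributed = trie.unique_attributions(min_count, rival_fraction)
    identified = frozenset(attributed.values())
    return CoverageSummary(identified, len(proteome))


def write_attributions_tsv(
    trie: AttributionTrie,
    path: str | Path,
    min_count: int = DEFAULT_MIN_COUNT,
    rival_fraction: float = DEFAULT_RIVAL_FRACTION,
) -> None:
    """Attribution table as TSV: read, top protein, its count, node total, share."""
    attributed = trie.unique_attributions(min_count, rival_fraction)
    with open(path, "w") as fh:
        fh.write("fluorosequence\tprotein\tcount\ttotal\tshare\n")
        for read, counts in trie.iter_reads():
            if read not in attributed:
                continue
            pid = attributed[read]
            total = sum(counts.values())
            fh.write(
                f"{read.to_string()}\t{pid}\t{counts[pid]}\t{total}"
                f"\t{counts[pid] / total:.6f}\n"
            )
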