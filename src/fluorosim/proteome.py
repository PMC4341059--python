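"""Proteome I/O and synthetic proteome generation.

A proteome is simply a list of :class:`ProteinRecord` objects — identifier plus
amino-acid sequence — read from FASTA (UniProt-style headers are recognised) or
generated synthetically with a configurable residue composition and length
distribution, so that every downstream stage can be exercised without external
downloads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "generate_synthetic_proteome",
    "uniform_composition",
    "human_like_composition",
    "toy_fixtures",
    "STANDARD_RESIDUES",
    "UNKNOWN_RESIDUE",
]

log = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for nonstandard residues (U, B, Z, J, O and friends). Positions
#: holding it are unlabelable, non-cleavable and can never serve as an anchor.
UNKNOWN_RESIDUE = "X"

_STANDARD_SET = frozenset(STANDARD_RESIDUES)


class FastaError(ValueError):
    """Raised for malformed FASTA input or duplicate identifiers."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an opaque identifier and its amino-acid sequence."""

    protein_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _accession_from_header(token: str) -> str:
    """UniProt "sp|ACC|NAME" / "tr|ACC|NAME" headers yield the accession;
    anything else yields the token itself (already whitespace-delimited)."""
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def _sanitize(seq: str) -> tuple[str, int]:
    """Uppercase, strip '*' stop characters, and replace nonstandard residue
    codes with :data:`UNKNOWN_RESIDUE`. Returns (clean sequence, n replaced)."""
    seq = seq.upper().replace("*", "")
    n_replaced = 0
    out = []
    for ch in seq:
        if ch in _STANDARD_SET:
            out.append(ch)
        elif ch.isalpha():
            out.append(UNKNOWN_RESIDUE)
            if ch != UNKNOWN_RESIDUE:
                n_replaced += 1
        else:
            raise FastaError(f"invalid character {ch!r} in sequence")
    return "".join(out), n_replaced


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA proteome into a list of :class:`ProteinRecord`.

    UniProt-style headers (``>sp|P69905|HBA_HUMAN ...``) yield the accession as
    the identifier; other headers yield the first whitespace-delimited token.
    Nonstandard residues are replaced by ``X`` with a logged warning.

    Raises
    ------
    FastaError
        If sequence data precedes any header (the offending line number is
        reported) or if identifiers are duplicated (all duplicates listed).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    duplicates: list[str] = []
    n_nonstandard = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id = _accession_from_header(rec.id)
        sequence, n_repl = _sanitize(str(rec.seq))
        n_nonstandard += n_repl
        if not sequence:
            raise FastaError(f"{path}: record {protein_id!r} has an empty sequence")
        if protein_id in seen:
            duplicates.append(protein_id)
        seen.add(protein_id)
        records.append(ProteinRecord(protein_id, sequence))
    if duplicates:
        raise FastaError(f"{path}: duplicate identifiers: {sorted(set(duplicates))}")
    if n_nonstandard:
        log.warning(
            "%s: replaced %d nonstandard residue(s) with %r "
            "(treated as unlabelable, non-cleavable, non-anchor)",
            path, n_nonstandard, UNKNOWN_RESIDUE,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def uniform_composition() -> dict[str, float]:
    """Uniform frequencies over the 20 standard residues (assumption-free default)."""
    return {aa: 1.0 / 20.0 for aa in STANDARD_RESIDUES}


def human_like_composition() -> dict[str, float]:
    """Approximate Swiss-Prot average residue frequencies, for realistic synthetic
    proteomes (values renormalised to sum to 1)."""
    freq = {
        "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
        "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
        "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
        "S": 6.63, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
    }
    total = sum(freq.values())
    return {aa: v / total for aa, v in freq.items()}


LengthSampler = Callable[[np.random.Generator], int]


def _make_length_sampler(spec) -> LengthSampler:
    """Accepts a constant int, a (low, high) inclusive range, a callable
    rng -> int, or None for the default length model (lognormal with median 375
    residues, sigma 0.6, floored at 30 — roughly the shape of real protein
    length distributions)."""
    if spec is None:
        mu = math.log(375.0)

        def sampler(rng: np.random.Generator) -> int:
            return max(30, int(round(rng.lognormal(mean=mu, sigma=0.6))))

        return sampler
    if isinstance(spec, int):
        if spec < 1:
            raise ValueError("constant length must be >= 1")
        return lambda rng: spec
    if isinstance(spec, tuple) and len(spec) == 2:
        low, high = spec
        if low < 1 or high < low:
            raise ValueError("length range must satisfy 1 <= low <= high")
        return lambda rng: int(rng.integers(low, high + 1))
    if callable(spec):
        return spec
    raise TypeError(f"unsupported length sampler spec: {spec!r}")


def generate_synthetic_proteome(
    n_proteins: int,
    length_sampler=None,
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Generate a deterministic synthetic proteome.

    Residues are drawn i.i.d. from ``composition`` (default: uniform over the
    20 standard residues); lengths come from ``length_sampler`` (see
    :func:`_make_length_sampler`). Identifiers are ``SYN000001``-style.
    """
    if n_proteins < 0:
        raise ValueError(f"n_proteins must be non-negative, got {n_proteins}")
    composition = dict(composition) if composition is not None else uniform_composition()
    bad = set(composition) - _STANDARD_SET
    if bad:
        raise ValueError(f"composition contains nonstandard residues: {sorted(bad)}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition frequencies sum to {total!r}, expected 1")
    sampler = _make_length_sampler(length_sampler)

    rng = np.random.default_rng(seed)
    residues = np.array(sorted(composition), dtype="U1")
    probs = np.array([composition[aa] for aa in residues])
    probs = probs / probs.sum()

    records = []
    for i in range(n_proteins):
        length = int(sampler(rng))
        if length < 1:
            raise ValueError("length sampler produced a length < 1")
        seq = "".join(rng.choice(residues, size=length, p=probs))
        records.append(ProteinRecord(f"SYN{i + 1:06d}", seq))
    return records


def toy_fixtures() -> dict[str, str]:
    """Tiny named peptides used throughout the docs and tests.

    * ``X`` — GKEGC: Cys-anchored, single labeled lysine → read (K,2).
    * ``Y`` — GKGKEC: Cys-anchored, two labeled lysines → read (K,2),(K,4).
    * ``swap_demo`` — GKEGK: the error-model demonstration peptide whose true
      pattern is "xKxxK"; dye failure yields "xxxxK", photobleaching "xKKxx".
    * ``fig1`` — WKKAY: with W, K, Y labeled and sequenced freely its read is
      the "WKKxY" pattern.
    """
    return {
        "X": "GKEGC",
        "Y": "GKGKEC",
        "swap_demo": "GKEGK",
        "fig1": "WKKAY",
    }
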