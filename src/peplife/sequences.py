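"""Peptide sequences, validation, and half-life dataset I/O.

Peptides are restricted to the 20 standard amino acids (one-letter codes,
alphabetical order with Ala first). Chemically modified residues, D-amino
acids and ambiguity codes (B/J/O/U/X/Z) are rejected rather than imputed:
the downstream half-life models are only meaningful for unmodified
L-peptides.

Half-life datasets pair fixed- or mixed-length peptides with experimentally
determined half-lives in seconds (strictly positive).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The 20 standard amino acids in alphabetical one-letter order (Ala first).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class SequenceValidationError(ValueError):
    """Raised when a sequence contains characters outside the 20-letter alphabet."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence.

    Sequences are normalized to uppercase on construction; any character
    outside ``ACDEFGHIKLMNPQRSTVWY`` raises :class:`SequenceValidationError`
    naming the offending symbol and its 1-based position.
    """

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.strip().upper()
        if not seq:
            raise SequenceValidationError("empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in AMINO_ACID_SET:
                ident = f" in record '{self.name}'" if self.name else ""
                raise SequenceValidationError(
                    f"illegal character {ch!r} at position {pos}{ident}; "
                    f"allowed alphabet is {AMINO_ACIDS}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def __getitem__(self, item) -> str:
        return self.sequence[item]

    def __str__(self) -> str:
        return self.sequence


def terminal_region(p: Peptide, end: str, k: int) -> Peptide:
    """Return the N- or C-terminal window of ``k`` residues.

    ``end`` is ``"N"`` (first ``k`` residues) or ``"C"`` (last ``k``
    residues). The C-terminal window keeps N→C orientation (it is a suffix,
    not a reversal). ``k`` must not exceed the peptide length.
    """
    if k < 1:
        raise ValueError("terminal window length must be >= 1")
    if k > len(p):
        raise ValueError(
            f"terminal window exceeds peptide length ({k} > {len(p)})"
        )
    end = end.upper()
    if end == "N":
        return Peptide(p.sequence[:k], name=p.name)
    if end == "C":
        return Peptide(p.sequence[-k:], name=p.name)
    raise ValueError(f"end must be 'N' or 'C', got {end!r}")


def _looks_like_fasta(text: str) -> bool:
    for line in text.splitlines():
        if line.strip():
            return line.lstrip().startswith(">")
    return False


def parse_sequences(
    source: Union[str, Path, TextIO],
    mode: str = "peptide",
) -> list[Peptide]:
    """Parse peptides or a protein from FASTA or one-sequence-per-line text.

    ``source`` may be a path, a raw string, or an open text stream. FASTA is
    auto-detected from a leading ``>``; otherwise every non-empty line is
    read as one sequence. ``mode`` is ``"peptide"`` or ``"protein"`` (both
    share the same alphabet rules; it is recorded only for error messages).
    Input order is preserved; sequences are upper-cased; records with
    illegal characters raise :class:`SequenceValidationError` identifying
    the record.
    """
    if mode not in ("peptide", "protein"):
        raise ValueError(f"mode must be 'peptide' or 'protein', got {mode!r}")
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            text = Path(source).read_text()
        else:
            text = source
    else:
        text = source.read()

    peptides: list[Peptide] = []
    if _looks_like_fasta(text):
        for record in SeqIO.parse(io.StringIO(text), "fasta"):
            peptides.append(Peptide(str(record.seq), name=record.id))
    else:
        for i, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if line:
                peptides.append(Peptide(line, name=f"seq{i}"))
    if not peptides:
        raise SequenceValidationError("no sequences in input")
    return peptides


@dataclass
class HalfLifeDataset:
    """Aligned peptides and half-lives (seconds); the training/evaluation unit."""

    peptides: list[Peptide]
    half_lives: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.half_lives = np.asarray(self.half_lives, dtype=float)
        if len(self.peptides) != len(self.half_lives):
            raise ValueError("peptides and half_lives must have equal length")
        if np.any(self.half_lives <= 0):
            raise ValueError("half-lives must be strictly positive (seconds)")

    def __len__(self) -> int:
        return len(self.peptides)

    def scaled(self, factor: float) -> "HalfLifeDataset":
        """Same peptides with every half-life multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return HalfLifeDataset(list(self.peptides), self.half_lives * factor)

    def subset(self, indices: Sequence[int]) -> "HalfLifeDataset":
        idx = np.asarray(indices, dtype=int)
        return HalfLifeDataset(
            [self.peptides[i] for i in idx], self.half_lives[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [p.sequence for p in self.peptides],
                "half_life_s": self.half_lives,
            }
        )

    def to_csv(self, path: Union[str, Path], sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HalfLifeDataset":
        missing = {"sequence", "half_life_s"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        peptides = [Peptide(s) for s in df["sequence"].astype(str)]
        return cls(peptides, df["half_life_s"].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: Union[str, Path], sep: str | None = None) -> "HalfLifeDataset":
        """Read a TSV/CSV with header columns ``sequence`` and ``half_life_s``.

        The delimiter is sniffed (tab or comma) unless given explicitly.
        Lines starting with ``#`` are treated as comments.
        """
        if sep is None:
            with open(path) as fh:
                for line in fh:
                    if not line.startswith("#"):
                        sep = "\t" if "\t" in line else ","
                        break
            sep = sep or "\t"
        df = pd.read_csv(path, sep=sep, comment="#")
        return cls.from_frame(df)
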