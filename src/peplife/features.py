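"""Feature encoders: k-mer composition and positional binary profiles.

Two descriptor families are supported, optionally restricted to a terminal
window of the peptide:

* **k-mer composition** (k = 1, 2, 3): frequencies of the 20 amino acids,
  400 dipeptides or 8000 tripeptides over the (L − k + 1) overlapping
  windows of the sequence, in fixed lexicographic order. Rows are fractions
  summing to 1, which makes them scale-free for downstream learners.
* **binary profile**: positional one-hot encoding, 20 indicator cells per
  residue position (Ala first, alphabetical order), 20 × L features.
  Requires all peptides in a matrix to share one length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .sequences import AMINO_ACIDS, AA_INDEX, HalfLifeDataset, Peptide, terminal_region

#: encoder kinds: amino-acid / dipeptide / tripeptide composition, binary profile
ENCODER_KINDS = ("aac", "dpc", "tpc", "binary")
REGIONS = ("full", "nterm", "cterm")
_KIND_TO_K = {"aac": 1, "dpc": 2, "tpc": 3}


@lru_cache(maxsize=None)
def kmer_names(k: int) -> tuple[str, ...]:
    """All 20**k k-mers over the standard alphabet in lexicographic order."""
    return tuple(
        "".join(t) for t in itertools.product(AMINO_ACIDS, repeat=k)
    )


@dataclass(frozen=True)
class EncoderSpec:
    """Fully determines a feature space.

    ``kind`` is one of ``aac``/``dpc``/``tpc`` (k-mer composition, k = 1/2/3)
    or ``binary``. ``region`` selects the whole sequence or an N-/C-terminal
    window of ``region_length`` residues (5 and 10 are the windows used for
    the terminal-residue analyses). Dimensionality is 20**k for composition
    and 20 × region length for binary.
    """

    kind: str = "dpc"
    region: str = "full"
    region_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"kind must be one of {ENCODER_KINDS}, got {self.kind!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.region != "full":
            if self.region_length is None or self.region_length < 1:
                raise ValueError("region_length must be a positive integer for terminal regions")

    @property
    def k(self) -> int | None:
        return _KIND_TO_K.get(self.kind)

    def effective_region(self, p: Peptide) -> Peptide:
        if self.region == "full":
            return p
        end = "N" if self.region == "nterm" else "C"
        return terminal_region(p, end, self.region_length)

    def dimension(self, peptide_length: int | None = None) -> int:
        """Number of features; binary full-length encoding needs the length."""
        if self.kind != "binary":
            return 20 ** self.k
        if self.region != "full":
            return 20 * self.region_length
        if peptide_length is None:
            raise ValueError("binary full-region dimension depends on peptide length")
        return 20 * peptide_length

    def feature_names(self, peptide_length: int | None = None) -> list[str]:
        if self.kind != "binary":
            return list(kmer_names(self.k))
        n = self.region_length if self.region != "full" else peptide_length
        if n is None:
            raise ValueError("binary full-region names depend on peptide length")
        return [f"pos{i}_{aa}" for i in range(1, n + 1) for aa in AMINO_ACIDS]


def kmer_composition(
    p: Peptide,
    k: int,
    region: str = "full",
    region_length: int | None = None,
) -> np.ndarray:
    """Overlapping k-mer composition of a peptide (or terminal window).

    Feature i = count of k-mer i among the L − k + 1 overlapping windows,
    divided by L − k + 1, where L is the effective region length; all 20**k
    k-mers are present in lexicographic order, so the row sums to 1.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    spec = EncoderSpec(kind={1: "aac", 2: "dpc", 3: "tpc"}[k],
                       region=region, region_length=region_length)
    seq = spec.effective_region(p).sequence
    L = len(seq)
    if L < k:
        raise ValueError(f"sequence too short for k-mer: length {L} < k={k}")
    vec = np.zeros(20 ** k)
    n_windows = L - k + 1
    for i in range(n_windows):
        idx = 0
        for ch in seq[i : i + k]:
            idx = idx * 20 + AA_INDEX[ch]
        vec[idx] += 1.0
    vec /= n_windows
    return vec


def binary_profile(
    p: Peptide,
    region: str = "full",
    region_length: int | None = None,
) -> np.ndarray:
    """Positional one-hot profile: 20 indicator cells per position, Ala first."""
    spec = EncoderSpec(kind="binary", region=region, region_length=region_length)
    seq = spec.effective_region(p).sequence
    vec = np.zeros(20 * len(seq))
    for i, ch in enumerate(seq):
        vec[20 * i + AA_INDEX[ch]] = 1.0
    return vec


def decode_binary_profile(vec: np.ndarray) -> str:
    """Invert :func:`binary_profile`: reconstruct the sequence from one-hot blocks."""
    vec = np.asarray(vec)
    if vec.size % 20 != 0:
        raise ValueError("binary profile length must be a multiple of 20")
    chars = []
    for block in vec.reshape(-1, 20):
        hot = np.flatnonzero(block == 1.0)
        if hot.size != 1 or not np.all((block == 0) | (block == 1)):
            raise ValueError("not a valid one-hot block")
        chars.append(AMINO_ACIDS[hot[0]])
    return "".join(chars)


def encode_peptide(p: Peptide, spec: EncoderSpec) -> np.ndarray:
    if spec.kind == "binary":
        return binary_profile(p, spec.region, spec.region_length)
    return kmer_composition(p, spec.k, spec.region, spec.region_length)


@dataclass
class FeatureMatrix:
    """Named numeric descriptors per peptide, with the EncoderSpec that produced them."""

    feature_names: list[str]
    values: np.ndarray = field(repr=False)
    spec: EncoderSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"row length {self.values.shape[1]} != number of feature "
                f"names {len(self.feature_names)}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.feature_names)}
        unknown = [n for n in names if n not in lookup]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        return np.array([lookup[n] for n in names], dtype=int)

    def restrict(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = self.column_indices(names)
        return FeatureMatrix(list(names), self.values[:, idx], self.spec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def encode_dataset(
    data: Union[HalfLifeDataset, Sequence[Peptide]],
    spec: EncoderSpec,
) -> FeatureMatrix:
    """Encode every peptide of a dataset into one aligned feature matrix.

    Rows follow dataset order and the encoding is deterministic. For the
    binary encoder with ``region="full"`` all peptides must share one
    length; mixed lengths raise a ``ValueError``.
    """
    peptides = data.peptides if isinstance(data, HalfLifeDataset) else list(data)
    if not peptides:
        raise ValueError("cannot encode an empty dataset")
    if spec.kind == "binary" and spec.region == "full":
        lengths = {len(p) for p in peptides}
        if len(lengths) > 1:
            raise ValueError(
                "binary encoding requires uniform length; got lengths "
                f"{sorted(lengths)}"
            )
    names = spec.feature_names(peptide_length=len(peptides[0]))
    rows = np.empty((len(peptides), len(names)))
    for i, p in enumerate(peptides):
        try:
            rows[i] = encode_peptide(p, spec)
        except ValueError as exc:
            raise ValueError(f"record {i} ({p.sequence}): {exc}") from exc
    return FeatureMatrix(names, rows, spec)
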