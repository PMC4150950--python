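"""Peptide design workflows: mutant ranking, protein scanning, batch filtering.

Three computational workflows mirror how stability-guided peptide design
is done in practice:

* **mutant design** — enumerate all 19N single-point substitutions of a
  parent peptide, predict each mutant's half-life, and rank them so
  substitutions that improve predicted stability (and how they shift the
  physicochemical panel) are immediately visible;
* **protein scanning** — slide a fixed-length window over a protein and
  score every subsequence, locating segments predicted to survive longest;
* **batch filtering** — score a peptide library and keep candidates above
  a half-life threshold and inside user-set physicochemical bounds.

All reported coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .learners import RegressionModel
from .physchem import peptide_properties
from .sequences import AMINO_ACIDS, Peptide


@dataclass
class MutantRecord:
    """A single-point substitution of a parent peptide."""

    position: int  # 1-based
    original: str
    substituted: str
    mutant: Peptide
    predicted_half_life: float | None = None
    improves_parent: bool | None = None
    physchem_deltas: dict[str, float] | None = field(default=None, repr=False)


def generate_mutants(p: Peptide) -> list[MutantRecord]:
    """All 19N single-point mutants, position-major then residue-alphabetical.

    The parent itself is excluded (the substituted residue always differs
    from the original), so every mutant is at Hamming distance exactly 1.
    """
    seq = p.sequence
    mutants = []
    for pos, original in enumerate(seq, start=1):
        for aa in AMINO_ACIDS:
            if aa == original:
                continue
            mutated = seq[: pos - 1] + aa + seq[pos:]
            mutants.append(
                MutantRecord(
                    position=pos,
                    original=original,
                    substituted=aa,
                    mutant=Peptide(mutated, name=f"{p.name or 'parent'}_{original}{pos}{aa}"),
                )
            )
    return mutants


def rank_mutants(
    p: Peptide,
    model: RegressionModel,
    top: int | None = None,
) -> tuple[float, list[MutantRecord]]:
    """Score and rank all single-point mutants of ``p``.

    Returns the parent's predicted half-life and the mutants sorted by
    predicted half-life descending; ties are broken by (position,
    substituted residue) so the ordering is deterministic even under a
    constant predictor. Each record carries the physicochemical deltas
    (mutant − parent) for the full property panel and a flag marking
    mutants predicted to outlive the parent.
    """
    mutants = generate_mutants(p)
    preds = model.predict([p] + [m.mutant for m in mutants])
    parent_pred = float(preds[0])
    parent_props = peptide_properties(p)
    for rec, pred in zip(mutants, preds[1:]):
        rec.predicted_half_life = float(pred)
        rec.improves_parent = bool(pred > parent_pred)
        props = peptide_properties(rec.mutant)
        rec.physchem_deltas = {
            k: props[k] - parent_props[k] for k in parent_props
        }
    mutants.sort(key=lambda r: (-r.predicted_half_life, r.position, r.substituted))
    if top is not None:
        mutants = mutants[:top]
    return parent_pred, mutants


@dataclass
class ScanWindow:
    """One scored window of a protein scan (1-based inclusive coordinates)."""

    start: int
    end: int
    subsequence: Peptide
    predicted_half_life: float


def scan_protein(
    protein: Peptide,
    window: int,
    model: RegressionModel,
) -> tuple[list[ScanWindow], ScanWindow]:
    """Score every length-``window`` subsequence of a protein, step 1.

    Returns the L − w + 1 windows in order of start position together with
    the best-scoring window (first occurrence on ties).
    """
    L = len(protein)
    if window < 1 or window > L:
        raise ValueError(f"window must be in [1, {L}], got {window}")
    subsequences = [
        Peptide(protein.sequence[i : i + window], name=f"{protein.name}_{i + 1}")
        for i in range(L - window + 1)
    ]
    preds = model.predict(subsequences)
    windows = [
        ScanWindow(start=i + 1, end=i + window, subsequence=sub,
                   predicted_half_life=float(pred))
        for i, (sub, pred) in enumerate(zip(subsequences, preds))
    ]
    best = max(windows, key=lambda w: w.predicted_half_life)
    return windows, best


def batch_filter(
    peptides: Sequence[Peptide],
    model: RegressionModel,
    min_half_life: float = 0.0,
    property_constraints: Mapping[str, tuple[float | None, float | None]] | None = None,
) -> list[tuple[Peptide, float]]:
    """Score a peptide library and keep the candidates passing all filters.

    A peptide survives when its predicted half-life is ≥ ``min_half_life``
    and every constrained physicochemical property lies within its
    (lower, upper) bounds (``None`` = unbounded side). The result is sorted
    by predicted half-life descending (ties by sequence), which makes the
    operation idempotent: filtering its own output with the same thresholds
    changes nothing.
    """
    constraints = dict(property_constraints or {})
    for name, (lo, hi) in constraints.items():
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(
                f"contradictory bounds for {name!r}: lower {lo} > upper {hi}"
            )
    peptides = list(peptides)
    if not peptides:
        return []
    preds = model.predict(peptides)
    survivors = []
    for p, pred in zip(peptides, preds):
        if pred < min_half_life:
            continue
        if constraints:
            props = peptide_properties(p)
            ok = True
            for name, (lo, hi) in constraints.items():
                if name not in props:
                    raise KeyError(f"unknown property {name!r}")
                v = props[name]
                if (lo is not None and v < lo) or (hi is not None and v > hi):
                    ok = False
                    break
            if not ok:
                continue
        survivors.append((p, float(pred)))
    survivors.sort(key=lambda t: (-t[1], t[0].sequence))
    return survivors
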