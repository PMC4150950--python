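"""Physicochemical property panel for peptides.

Seventeen sequence-derived properties are computed per peptide: mean
per-residue scale values (hydropathy, hydrophobicity, hydrophilicity,
flexibility, side-chain volume), molecular weight, Henderson–Hasselbalch
net charge at pH 7 and isoelectric point, and residue-class fractions
(polar, non-polar, aromatic, aliphatic, tiny, small, amphipathic,
positively and negatively charged).

Scales are pinned to widely used published tables so results are
reproducible; the panel logic itself is scale-agnostic:

* hydropathy — Kyte & Doolittle (1982), J Mol Biol 157:105
* hydrophobicity — Eisenberg consensus scale (1984), J Mol Biol 179:125
* hydrophilicity — Hopp & Woods (1981), PNAS 78:3824
* flexibility — Bhaskaran & Ponnuswamy (1988) average flexibility index
* side-chain volume — Zamyatnin (1972), Prog Biophys Mol Biol 24:107 (Å³)
* ionizable-group pKa — EMBOSS pKa set (used by `iep`)

Molecular weight is the average isotopic mass from Biopython's ProtParam.
"""

from __future__ import annotations

import math
from typing import Mapping

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .sequences import AMINO_ACIDS, Peptide

# per-residue scales -------------------------------------------------------

KYTE_DOOLITTLE_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

EISENBERG_HYDROPHOBICITY = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HOPP_WOODS_HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

BHASKARAN_PONNUSWAMY_FLEXIBILITY = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
    "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
    "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
    "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
}

ZAMYATNIN_VOLUME = {  # residue volume, Å³
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# residue classes ----------------------------------------------------------

POSITIVE = frozenset("KRH")
NEGATIVE = frozenset("DE")
TINY = frozenset("ACGST")
SMALL = frozenset("ACDGNPSTV")
AROMATIC = frozenset("FWYH")
ALIPHATIC = frozenset("ILV")
POLAR = frozenset("CDEHKNQRSTWY")
NONPOLAR = frozenset(AMINO_ACIDS) - POLAR
#: residues carrying both a polar head and a substantial apolar moiety
AMPHIPATHIC = frozenset("KMRWY")

RESIDUE_CLASSES: dict[str, frozenset] = {
    "positive": POSITIVE,
    "negative": NEGATIVE,
    "neutral": frozenset(AMINO_ACIDS) - POSITIVE - NEGATIVE,
    "tiny": TINY,
    "small": SMALL,
    "aromatic": AROMATIC,
    "aliphatic": ALIPHATIC,
    "polar": POLAR,
    "nonpolar": NONPOLAR,
    "amphipathic": AMPHIPATHIC,
}

# EMBOSS pKa values: termini plus the ionizable side chains
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_SIDECHAIN = {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
_BASIC_SIDECHAINS = frozenset("HKR")  # positive when protonated


def net_charge(p: Peptide, pH: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at a given pH.

    Sums the fractional charge of the free N-terminus, the C-terminus and
    every ionizable side chain (C, D, E, H, K, R, Y). Monotonically
    non-increasing in pH.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must be in (0, 14), got {pH}")

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    charge = pos(PKA_NTERM) + neg(PKA_CTERM)
    for aa in p:
        pka = PKA_SIDECHAIN.get(aa)
        if pka is None:
            continue
        charge += pos(pka) if aa in _BASIC_SIDECHAINS else neg(pka)
    return charge


def isoelectric_point(p: Peptide, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection.

    The free termini guarantee a sign change on (0, 14): the charge is
    positive in the acidic limit and negative in the basic limit. Bisection
    runs until |charge| < ``tol``.
    """
    lo, hi = 1e-6, 14.0 - 1e-6
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if net_charge(p, mid) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(net_charge(p, mid)) >= tol:  # pragma: no cover - defensive
        raise ArithmeticError("bisection failed to reach the charge tolerance")
    return mid


def _mean_scale(p: Peptide, scale: Mapping[str, float]) -> float:
    return sum(scale[aa] for aa in p) / len(p)


def _class_fraction(p: Peptide, members: frozenset) -> float:
    return sum(1 for aa in p if aa in members) / len(p)


def peptide_properties(p: Peptide) -> dict[str, float]:
    """Compute the full physicochemical panel for one peptide.

    Returns an ordered mapping of ≥ 15 named properties. Mean-scale
    properties are simple averages over residues, so they are invariant
    under sequence permutation and equal the residue's scale value exactly
    for homopolymers. Class fractions are residue counts divided by length.
    """
    return {
        "hydropathy": _mean_scale(p, KYTE_DOOLITTLE_HYDROPATHY),
        "hydrophobicity": _mean_scale(p, EISENBERG_HYDROPHOBICITY),
        "hydrophilicity": _mean_scale(p, HOPP_WOODS_HYDROPHILICITY),
        "flexibility": _mean_scale(p, BHASKARAN_PONNUSWAMY_FLEXIBILITY),
        "volume": _mean_scale(p, ZAMYATNIN_VOLUME),
        "molecular_weight": ProteinAnalysis(p.sequence).molecular_weight(),
        "isoelectric_point": isoelectric_point(p),
        "net_charge_ph7": net_charge(p, 7.0),
        "amphipathicity": _class_fraction(p, AMPHIPATHIC),
        "polarity_fraction": _class_fraction(p, POLAR),
        "nonpolar_fraction": _class_fraction(p, NONPOLAR),
        "aromatic_fraction": _class_fraction(p, AROMATIC),
        "aliphatic_fraction": _class_fraction(p, ALIPHATIC),
        "tiny_fraction": _class_fraction(p, TINY),
        "small_fraction": _class_fraction(p, SMALL),
        "positive_fraction": _class_fraction(p, POSITIVE),
        "negative_fraction": _class_fraction(p, NEGATIVE),
    }


PROPERTY_NAMES: tuple[str, ...] = tuple(peptide_properties(Peptide("A")).keys())
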