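"""Interaction-severity inference from molecular-structure similarity.

The idea: if drug A is known to interact with drug B at some severity, and a
candidate drug C is structurally close to A, the predicted C-B interaction
is expected to carry a similar severity. Structure is compared through
hashed substructure fingerprints computed from SMILES, combined by the
weighted molecular-structure similarity

    MSSD(A, B) = alpha * Tanimoto + beta * Dice + (1 - alpha - beta) * cosine

over the fingerprint bit sets (alpha = 0.5, beta = 0.2 by default). Severity
is expressed on a 1-100 score banded into three levels:

    1-30 MINOR, 31-60 MODERATE, 61-100 MAJOR.

A candidate's score is the similarity-weighted average of the known severity
scores of B's interactors that are sufficiently similar to the candidate,
falling back to the single most-similar interactor (flagged low-confidence)
when none pass the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Fingerprint",
    "SeverityScale",
    "SeverityAssessment",
    "fingerprint_from_smiles",
    "mssd",
    "score_to_level",
    "infer_severity",
]

MINOR, MODERATE, MAJOR = "MINOR", "MODERATE", "MAJOR"


@dataclass(frozen=True)
class Fingerprint:
    """A hashed molecular fingerprint as a set of set-bit positions."""

    bits: frozenset[int]
    nbits: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.nbits < 1:
            raise ValueError("nbits must be >= 1")
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit position outside [0, nbits)")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class SeverityScale:
    """Contiguous score bands over [1, 100] plus the similarity weights."""

    bands: tuple[tuple[int, int, str], ...] = (
        (1, 30, MINOR),
        (31, 60, MODERATE),
        (61, 100, MAJOR),
    )
    alpha: float = 0.5
    beta: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1 and self.alpha + self.beta <= 1):
            raise ValueError("need alpha, beta in [0, 1] with alpha + beta <= 1")
        lo = 1
        for low, high, _ in self.bands:
            if low != lo or high < low:
                raise ValueError("bands must be contiguous and non-overlapping over [1, 100]")
            lo = high + 1
        if lo != 101:
            raise ValueError("bands must cover [1, 100]")


DEFAULT_SCALE = SeverityScale()


@dataclass
class SeverityAssessment:
    """An inferred severity with its supporting neighbours."""

    score: float
    level: str
    neighbors: list[tuple[str, float, float]] = field(default_factory=list)
    low_confidence: bool = False


def fingerprint_from_smiles(smiles: str, nbits: int = 2048) -> Fingerprint:
    """Hashed substructure (Morgan, radius 2) fingerprint of a SMILES string.

    The SMILES is parsed to a molecular graph first, so different spellings
    of the same molecule give identical fingerprints.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(fp.GetOnBits()), nbits, source=smiles)


def mssd(
    fpA: Fingerprint,
    fpB: Fingerprint,
    alpha: float = 0.5,
    beta: float = 0.2,
) -> float:
    """Weighted Tanimoto + Dice + cosine similarity of two fingerprints.

    Operates on the 0/1 bit vectors, so the cosine component equals
    |A n B| / sqrt(|A| |B|). Symmetric in its arguments and bounded in
    [0, 1] whenever alpha, beta >= 0 and alpha + beta <= 1.
    """
    if fpA.nbits != fpB.nbits:
        raise ValueError("fingerprints have different bit lengths")
    if not fpA.bits or not fpB.bits:
        raise ValueError("empty fingerprint: similarity components undefined")
    if not (0 <= alpha and 0 <= beta and alpha + beta <= 1):
        raise ValueError("need alpha, beta >= 0 with alpha + beta <= 1")
    a, b = fpA.bits, fpB.bits
    inter = len(a & b)
    union = len(a | b)
    tanimoto = inter / union
    dice = 2 * inter / (len(a) + len(b))
    cosine = inter / np.sqrt(len(a) * len(b))
    return float(alpha * tanimoto + beta * dice + (1 - alpha - beta) * cosine)


def score_to_level(score: float, scale: SeverityScale = DEFAULT_SCALE) -> str:
    """Band a 1-100 severity score into MINOR / MODERATE / MAJOR.

    Scores are real-valued internally and rounded half-up to integers for
    banding (the bands are integer ranges).
    """
    if not np.isfinite(score) or score < 1 or score > 100:
        raise ValueError(f"severity score {score} outside [1, 100]")
    rounded = int(np.floor(score + 0.5))
    for low, high, level in scale.bands:
        if low <= rounded <= high:
            return level
    raise AssertionError("bands cover [1, 100]")  # pragma: no cover


def infer_severity(
    drugC: str,
    drugB: str,
    known: Sequence[tuple[str, float]],
    fingerprints: Mapping[str, Fingerprint],
    sim_cutoff: float = 0.5,
    scale: SeverityScale = DEFAULT_SCALE,
) -> SeverityAssessment:
    """Severity of the predicted C-B interaction from B's known interactors.

    ``known`` lists (drug_A, severity score of the A-B interaction) for the
    drugs A already known to interact with B. The inferred score is the
    MSSD-weighted average over interactors with similarity >= ``sim_cutoff``
    to C; when none pass, the single most-similar interactor is used and the
    result flagged low-confidence. The output is clipped to [1, 100].
    """
    if not known:
        raise ValueError(f"no known interactors of {drugB!r} to transfer severity from")
    if drugC not in fingerprints:
        raise KeyError(f"no fingerprint for {drugC!r}")
    fpC = fingerprints[drugC]
    sims: list[tuple[str, float, float]] = []
    for drugA, score in known:
        if drugA not in fingerprints:
            continue
        sims.append((drugA, mssd(fpC, fingerprints[drugA], scale.alpha, scale.beta), float(score)))
    if not sims:
        raise ValueError(f"no fingerprints available for any interactor of {drugB!r}")

    passing = [t for t in sims if t[1] >= sim_cutoff]
    low_confidence = not passing
    if low_confidence:
        passing = [max(sims, key=lambda t: t[1])]
    wsum = sum(s for _, s, _ in passing)
    if wsum == 0:
        # All similarities exactly zero: fall back to a plain average.
        value = float(np.mean([v for _, _, v in passing]))
    else:
        value = sum(s * v for _, s, v in passing) / wsum
    value = float(np.clip(value, 1.0, 100.0))
    return SeverityAssessment(
        score=value,
        level=score_to_level(value, scale),
        neighbors=passing,
        low_confidence=low_confidence,
    )
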