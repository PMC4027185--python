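"""Exonic splicing enhancer/silencer motif detection.

Two motif families are supported: position weight matrices (PWMs) in the style
of SR-protein binding models, scored additively per position and called above a
threshold; and hexamer sets (enhancer sets scanned for presence/absence,
silencer sets carrying per-hexamer log-odds scores of pseudoexon-versus-exon
frequency).

Scanning is on the given (sense) strand only: pre-mRNA splicing signals are
strand-specific, so no reverse-complement symmetry is assumed.  Coordinates are
0-based half-open internally; textual reports convert to 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np

from splicescreen.errors import AmbiguousBaseError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# hit kinds
ESE_PWM = "ESE_PWM"
ESE_HEX = "ESE_HEX"
ESS_HEX = "ESS_HEX"


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a splicing-regulatory motif on a sequence.

    ``start``/``end`` are 0-based half-open on the scanned sequence.
    """

    seq_id: str
    start: int
    end: int
    motif_name: str
    score: float
    kind: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Pwm:
    """Position weight matrix over ACGT with a resolvable hit threshold.

    ``matrix`` is a width x 4 array of real scores (A, C, G, T column order).
    The threshold is either a fraction of the score range (``threshold_frac``,
    the default mode: cutoff = min_score + frac * (max_score - min_score)) or
    an absolute cutoff (``threshold_abs``) for users holding published
    per-matrix thresholds.
    """

    name: str
    matrix: np.ndarray
    threshold_frac: Optional[float] = None
    threshold_abs: Optional[float] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM cells must all be finite")
        if self.threshold_frac is not None and not 0.0 <= self.threshold_frac <= 1.0:
            raise ValueError("threshold_frac must lie in [0, 1]")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def resolve_cutoff(self, threshold_frac: Optional[float] = None) -> float:
        """Resolve the hit cutoff, optionally overriding the fraction mode."""
        frac = threshold_frac if threshold_frac is not None else self.threshold_frac
        if frac is not None:
            return self.min_score + frac * (self.max_score - self.min_score)
        if self.threshold_abs is not None:
            return self.threshold_abs
        raise ValueError(f"PWM {self.name!r} has no resolvable threshold")


@dataclass
class HexamerSet:
    """A named set of 6-mers with optional per-member log-odds scores.

    ``silencer=True`` marks silencer (ESS) sets; their hits are reported with
    kind ESS_HEX and carry the member's log-odds score.
    """

    name: str
    members: Set[str]
    scores: Optional[Dict[str, float]] = None
    silencer: bool = False

    def __post_init__(self):
        members = {m.upper() for m in self.members}
        for m in members:
            if len(m) != 6 or any(c not in BASE_INDEX for c in m):
                raise ValueError(f"hexamer {m!r} is not a 6-mer over ACGT")
        self.members = members
        if self.scores is not None:
            self.scores = {k.upper(): float(v) for k, v in self.scores.items()}

    @property
    def kind(self) -> str:
        return ESS_HEX if self.silencer else ESE_HEX

    def __len__(self) -> int:
        return len(self.members)


def pwm_score(pwm: Pwm, window: str) -> float:
    """Additive PWM score of one window of exactly ``pwm.width`` characters.

    Strict: any non-ACGT character raises :class:`AmbiguousBaseError` (the
    scanner, by contrast, silently skips ambiguous windows).
    """
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    total = 0.0
    for pos, base in enumerate(window):
        idx = BASE_INDEX.get(base)
        if idx is None:
            raise AmbiguousBaseError(
                f"non-ACGT character {base!r} at window position {pos}"
            )
        total += pwm.matrix[pos, idx]
    return float(total)


def scan_pwm(
    seq: str,
    pwm: Pwm,
    seq_id: str = "seq",
    threshold_frac: Optional[float] = None,
) -> List[MotifHit]:
    """All windows of ``seq`` scoring at or above the PWM's resolved cutoff.

    Hits are sorted by start; overlaps are allowed.  Windows containing
    non-ACGT characters (N, gaps) are skipped rather than errored.  A sequence
    shorter than the matrix yields an empty list.
    """
    seq = seq.upper()
    cutoff = pwm.resolve_cutoff(threshold_frac)
    w = pwm.width
    hits: List[MotifHit] = []
    for start in range(0, len(seq) - w + 1):
        window = seq[start:start + w]
        try:
            s = pwm_score(pwm, window)
        except AmbiguousBaseError:
            continue
        if s >= cutoff:
            hits.append(MotifHit(seq_id, start, start + w, pwm.name, s, ESE_PWM))
    return hits


def scan_hexamers(seq: str, hexset: HexamerSet, seq_id: str = "seq") -> List[MotifHit]:
    """All (possibly overlapping) occurrences of the set's members in ``seq``.

    Score is the member's log-odds if the set carries scores, else 0.
    """
    seq = seq.upper()
    hits: List[MotifHit] = []
    for member in hexset.members:
        score = 0.0
        if hexset.scores is not None and member in hexset.scores:
            score = hexset.scores[member]
        start = seq.find(member)
        while start != -1:
            hits.append(
                MotifHit(seq_id, start, start + 6, f"{hexset.name}:{member}",
                         score, hexset.kind)
            )
            start = seq.find(member, start + 1)
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def ess_logodds(freq_pseudoexon: float, freq_exon: float) -> float:
    """log2 odds of a hexamer's frequency in pseudoexons versus real exons.

    Positive scores mark hexamers enriched in pseudoexons, the hallmark of an
    exonic splicing silencer.
    """
    if freq_pseudoexon <= 0 or freq_exon <= 0:
        raise ValueError("frequencies must be > 0")
    return math.log2(freq_pseudoexon / freq_exon)


def motif_set_source(hit: MotifHit) -> str:
    """Name of the motif set a hit came from.

    PWM hits carry the matrix name directly; hexamer hits are named
    ``set:member`` and collapse to the set name, because presence of *any*
    member of the same set at a locus counts as the element being present.
    """
    if hit.kind == ESE_PWM:
        return hit.motif_name
    return hit.motif_name.split(":", 1)[0]
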