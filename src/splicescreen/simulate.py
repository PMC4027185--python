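"""Synthetic inputs for every pipeline stage.

Generators here emulate the study scenario end to end so the whole pipeline is
testable hermetically: splice-site training corpora drawn from known factored
distributions, paralog exon families with planted enhancers and controlled
weak/strong acceptor sites (the alkaline-phosphatase-family scenario: one
ancestral-like strong-site member without the enhancer, tissue-specific-like
weak-site members with it), and noisy Michaelis-Menten velocity datasets.

Design points:

* Background divergence between family members is synonymous-first, so the
  planted non-synonymous differences are exactly the ones the screen should
  find in an otherwise conserved region.
* Weak/strong is defined *in-model*: acceptor windows are rejection-sampled
  from weak/strong generating distributions until the trained model actually
  labels them as requested — no magic consensus strings.
* Every generator is a pure function of its spec + seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from splicescreen.codon_align import ExonRecord, translate
from splicescreen.kinetics import VelocityDataset, mm_velocity
from splicescreen.maxent import (
    ACCEPTOR_SPEC,
    DONOR_SPEC,
    SiteWindowSpec,
    SpliceSiteModel,
    classify_strength,
    train_maxent,
)
from splicescreen.motifs import BASES

_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]
_SYNONYMS: Dict[str, List[str]] = {}
for _c in _SENSE_CODONS:
    _SYNONYMS.setdefault(translate(_c + "AAA")[0], []).append(_c)
_CODON_AA = {c: translate(c + "AAA")[0] for c in _SENSE_CODONS}


# ---------------------------------------------------------------------------
# splice-window corpora

def _sample_product(probs: np.ndarray, n: int, rng: np.random.Generator) -> List[str]:
    width = probs.shape[0]
    out = np.empty((n, width), dtype="<U1")
    for j in range(width):
        out[:, j] = rng.choice(list(BASES), size=n, p=probs[j])
    return ["".join(row) for row in out]


def _sample_chain(p0: np.ndarray, trans: Sequence[np.ndarray], n: int,
                  rng: np.random.Generator) -> List[str]:
    width = len(trans) + 1
    idx = np.empty((n, width), dtype=np.int64)
    idx[:, 0] = rng.choice(4, size=n, p=p0)
    for j, T in enumerate(trans):
        for b in range(4):
            mask = idx[:, j] == b
            k = int(mask.sum())
            if k:
                idx[mask, j + 1] = rng.choice(4, size=k, p=T[b])
    return ["".join(BASES[i] for i in row) for row in idx]


def gen_splice_training(model_params: dict, n: int, seed: int) -> List[str]:
    """n i.i.d. windows from a factored distribution, deterministic per seed.

    ``model_params`` is either ``{"kind": "product", "probs": width x 4}`` or
    ``{"kind": "chain", "p0": 4, "trans": [4x4, ...]}`` (rows of each
    transition matrix are conditionals of position j+1 given position j).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kind = model_params["kind"]
    if kind == "product":
        probs = np.asarray(model_params["probs"], dtype=float)
        return _sample_product(probs, n, rng)
    if kind == "chain":
        p0 = np.asarray(model_params["p0"], dtype=float)
        trans = [np.asarray(T, dtype=float) for T in model_params["trans"]]
        return _sample_chain(p0, trans, n, rng)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _rows(*rows) -> np.ndarray:
    a = np.asarray(rows, dtype=float)
    return a / a.sum(axis=1, keepdims=True)


def acceptor_params(strength: str) -> dict:
    """Generating distribution of acceptor 23-mers (20 intronic + 3 exonic).

    ``strong``: pronounced polypyrimidine tract and near-invariant AG at the
    intron end; ``weak``: near-uniform tract with a degraded but present AG —
    a plausible yet enhancer-dependent site.
    """
    if strength == "strong":
        tract = [[0.06, 0.40, 0.06, 0.48]] * 18
        ag = [[0.94, 0.02, 0.02, 0.02], [0.02, 0.02, 0.94, 0.02]]
        exonic = [[0.30, 0.20, 0.30, 0.20]] * 3
    elif strength == "weak":
        tract = [[0.25, 0.25, 0.25, 0.25]] * 18
        ag = [[0.55, 0.15, 0.15, 0.15], [0.15, 0.15, 0.55, 0.15]]
        exonic = [[0.25, 0.25, 0.25, 0.25]] * 3
    else:
        raise ValueError("strength must be 'weak' or 'strong'")
    return {"kind": "product", "probs": _rows(*(tract + ag + exonic))}


def donor_params(strength: str) -> dict:
    """Generating distribution of donor 9-mers (3 exonic + 6 intronic)."""
    if strength == "strong":
        probs = [
            [0.30, 0.35, 0.20, 0.15],
            [0.60, 0.12, 0.14, 0.14],
            [0.10, 0.05, 0.80, 0.05],
            [0.02, 0.01, 0.95, 0.02],  # G
            [0.02, 0.01, 0.02, 0.95],  # T
            [0.60, 0.10, 0.15, 0.15],
            [0.70, 0.08, 0.12, 0.10],
            [0.10, 0.05, 0.80, 0.05],
            [0.15, 0.15, 0.20, 0.50],
        ]
    elif strength == "weak":
        probs = [[0.25] * 4] * 3 + [
            [0.15, 0.10, 0.60, 0.15],
            [0.15, 0.10, 0.15, 0.60],
        ] + [[0.25] * 4] * 4
    else:
        raise ValueError("strength must be 'weak' or 'strong'")
    return {"kind": "product", "probs": _rows(*probs)}


def train_reference_models(seed: int, n: int = 1500) -> Dict[str, SpliceSiteModel]:
    """Donor + acceptor models trained on generator-internal strong corpora.

    Signal windows come from the strong generating distributions; the
    background is uniform, so scores are bits of departure from random
    sequence.
    """
    acc_windows = gen_splice_training(acceptor_params("strong"), n, seed * 2 + 1)
    don_windows = gen_splice_training(donor_params("strong"), n, seed * 2 + 2)
    return {
        "acceptor": train_maxent(acc_windows, None, ACCEPTOR_SPEC),
        "donor": train_maxent(don_windows, None, DONOR_SPEC),
    }


# ---------------------------------------------------------------------------
# paralog family generator

@dataclass(frozen=True)
class PlantSpec:
    """One enhancer planted in-frame in one member."""

    member: str
    motif: str         # hexamer written at the plant site
    codon_pos: int     # first of the two codons the hexamer spans

    def __post_init__(self):
        m = self.motif.upper()
        if len(m) != 6 or any(c not in BASES for c in m):
            raise ValueError("planted motif must be a 6-mer over ACGT")
        object.__setattr__(self, "motif", m)


@dataclass
class FamilySimSpec:
    """Specification of a synthetic paralog exon family."""

    seed: int
    acceptor_strengths: Dict[str, str]  # member -> weak | strong
    exon_len_codons: int = 40
    identity_target: float = 0.90
    planted: List[PlantSpec] = field(default_factory=list)
    flank_len: int = 40

    def __post_init__(self):
        if not 0 < self.identity_target <= 1:
            raise ValueError("identity_target must be in (0, 1]")
        for label in self.acceptor_strengths.values():
            if label not in ("weak", "strong"):
                raise ValueError("acceptor strengths must be weak or strong")
        for p in self.planted:
            if p.member not in self.acceptor_strengths:
                raise ValueError(f"planted member {p.member!r} not in family")
            if not 1 <= p.codon_pos <= self.exon_len_codons - 3:
                raise ValueError(
                    "planted position must leave the first and last codons free"
                )
        if self.flank_len < ACCEPTOR_SPEC.intronic_len:
            raise ValueError("flank_len too short for an acceptor window")

    @property
    def members(self) -> List[str]:
        return list(self.acceptor_strengths)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _sample_labelled_window(rng, params, model, cutoffs, want_label,
                            fixed_exonic: str, max_tries: int = 1000) -> str:
    """Rejection-sample the intronic part of an acceptor window until the
    model labels the full window as requested; the 3 exonic nt are fixed by
    the member's exon."""
    probs = np.asarray(params["probs"], dtype=float)[:ACCEPTOR_SPEC.intronic_len]
    for _ in range(max_tries):
        intronic = _sample_product(probs, 1, rng)[0]
        window = intronic + fixed_exonic
        if classify_strength(model.score(window), cutoffs).label == want_label:
            return intronic
    raise RuntimeError(
        f"could not realise a {want_label!r} acceptor window in {max_tries} draws"
    )


def _synonymous_mutate(rng, codons: List[str], skip: set, p_mut: float) -> List[str]:
    out = list(codons)
    for k in range(len(codons)):
        if k in skip:
            continue
        if rng.random() < p_mut:
            alts = [c for c in _SYNONYMS[_CODON_AA[codons[k]]] if c != codons[k]]
            if alts:
                out[k] = alts[rng.integers(len(alts))]
    return out


def gen_family(spec: FamilySimSpec,
               models: Optional[Dict[str, SpliceSiteModel]] = None,
               cutoffs: Tuple[float, float] = (3.0, 6.0),
               ) -> Tuple[List[ExonRecord], dict]:
    """Generate a paralog exon family plus a truth ledger.

    Members share an ancestral coding sequence, diverge by synonymous codon
    swaps towards ``identity_target``, carry planted hexamers in-frame in the
    stated members, and have those loci ablated *non-synonymously* in all
    other members (so the amino-acid contrast the screen looks for exists by
    construction; the ablation mode is recorded in the ledger).  Acceptor
    windows are rejection-sampled until the model realises each member's
    requested weak/strong label; the donor window is shared by all members
    and strong.  The first and last codons are frozen so site windows differ
    only where the generator controls them.

    Returns (records, ledger); the ledger lists every plant, each ablation,
    and the (weak_member, strong_member) pairs a faithful screen must report.
    """
    rng = np.random.default_rng(spec.seed)
    if models is None:
        models = train_reference_models(int(rng.integers(2 ** 20)))
    n_codons = spec.exon_len_codons
    members = spec.members

    ancestor = [
        _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons)
    ]
    planted_codons = set()
    for p in spec.planted:
        planted_codons.update({p.codon_pos, p.codon_pos + 1})
    frozen = {0, n_codons - 1} | planted_codons
    p_mut = min(1.0, 3.0 * (1.0 - spec.identity_target))

    member_codons: Dict[str, List[str]] = {
        m: _synonymous_mutate(rng, ancestor, frozen, p_mut) for m in members
    }

    ledger: dict = {"members": members, "planted": [], "ablations": [],
                    "expected_candidates": []}

    plant_codons_of: Dict[str, set] = {m: set() for m in members}
    for p in spec.planted:
        plant_codons_of[p.member].update({p.codon_pos, p.codon_pos + 1})

    for p in spec.planted:
        c1, c2 = p.motif[:3], p.motif[3:]
        if c1 in _STOPS or c2 in _STOPS:
            raise ValueError(
                f"infeasible plant: motif {p.motif} introduces a stop codon"
            )
        member_codons[p.member][p.codon_pos] = c1
        member_codons[p.member][p.codon_pos + 1] = c2
        aa1, aa2 = _CODON_AA[c1], _CODON_AA[c2]
        ledger["planted"].append(
            {"member": p.member, "motif": p.motif, "codon_pos": p.codon_pos,
             "aa": aa1 + aa2}
        )
        # ablate in every other member (unless that member carries its own
        # plant at an overlapping locus): different amino acids, motif
        # locally absent
        for other in members:
            if other == p.member:
                continue
            if plant_codons_of[other] & {p.codon_pos, p.codon_pos + 1}:
                continue
            ok = False
            for _ in range(300):
                d1 = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
                d2 = _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))]
                if _CODON_AA[d1] == aa1 or _CODON_AA[d2] == aa2:
                    continue
                trial = list(member_codons[other])
                trial[p.codon_pos] = d1
                trial[p.codon_pos + 1] = d2
                seq = "".join(trial)
                lo = max(0, 3 * p.codon_pos - 5)
                hi = min(len(seq), 3 * p.codon_pos + 11)
                if p.motif in seq[lo:hi]:
                    continue
                member_codons[other] = trial
                ok = True
                break
            if not ok:
                raise ValueError(
                    f"infeasible plant: cannot ablate {p.motif} at codon "
                    f"{p.codon_pos} in member {other}"
                )
            ledger["ablations"].append(
                {"member": other, "codon_pos": p.codon_pos,
                 "mode": "nonsynonymous"}
            )

    # shared donor flank: identical across members (last codon frozen), so
    # donor windows are byte-identical and can never produce a weak/strong
    # contrast — the acceptor carries the family's strength structure
    don_probs = np.asarray(donor_params("strong")["probs"], dtype=float)[3:]
    donor_intronic = _sample_product(don_probs, 1, rng)[0]
    downstream = donor_intronic + _random_seq(
        rng, spec.flank_len - DONOR_SPEC.intronic_len)

    records: List[ExonRecord] = []
    for m in members:
        exon = "".join(member_codons[m])
        want = spec.acceptor_strengths[m]
        intronic = _sample_labelled_window(
            rng, acceptor_params(want), models["acceptor"], cutoffs, want,
            fixed_exonic=exon[:ACCEPTOR_SPEC.exonic_len],
        )
        upstream = _random_seq(
            rng, spec.flank_len - ACCEPTOR_SPEC.intronic_len) + intronic
        records.append(ExonRecord(
            seq_id=m, exon_seq=exon, upstream_flank=upstream,
            downstream_flank=downstream, phase=0,
            gene_meta={"acceptor_label": want},
        ))

    planted_weak = [p.member for p in spec.planted
                    if spec.acceptor_strengths[p.member] == "weak"]
    strong_members = [m for m in members
                      if spec.acceptor_strengths[m] == "strong"]
    for w in dict.fromkeys(planted_weak):
        for s in strong_members:
            ledger["expected_candidates"].append((w, s))
    return records, ledger


# ---------------------------------------------------------------------------
# kinetics data

def gen_mm_data(Vmax: float, Km: float, S_grid: Optional[Sequence[float]] = None,
                noise_cv: float = 0.0, n_replicates: int = 1, seed: int = 0,
                enzyme: str = "sim") -> VelocityDataset:
    """Noisy Michaelis-Menten velocities: v = Vmax*S/(Km+S) * (1 + eps).

    eps ~ Normal(0, noise_cv), deterministic per seed, negative draws
    truncated at 0.  The default substrate grid spans 0.01-20 mM (12
    log-spaced points), the range over which the assay varies pNPP.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if S_grid is None:
        S_grid = np.geomspace(0.01, 20.0, 12)
    rng = np.random.default_rng(seed)
    points = []
    for rep in range(n_replicates):
        for S in S_grid:
            v = mm_velocity(Vmax, Km, float(S))
            if noise_cv > 0:
                v *= 1.0 + rng.normal(0.0, noise_cv)
            points.append((float(S), max(v, 0.0), rep))
    return VelocityDataset(enzyme=enzyme, points=points)
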