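"""Maximum-entropy splice-site strength models.

A splice-site model is the maximum-entropy probability distribution over
fixed-width sequence windows whose marginals on a chosen set of position
subsets (the constraint set) match the empirical marginals of a training
corpus.  Strength is the log2 odds of a window under the signal model versus a
background model.  With singleton constraints only, the model collapses to the
classical position weight matrix; with adjacent-pair constraints it captures
first-order neighbour dependence, the standard parameterisation for donor
(9-mer: 3 exonic + 6 intronic nt) and acceptor (23-mer: 20 intronic + 3 exonic
nt) sites.

Fitting is iterative proportional fitting (IPF).  Three exact engines exist:

* ``table`` — full 4^width joint, arbitrary position subsets, width <= 10;
* ``chain`` — factored adjacent-pair model, any width, marginals and the
  normaliser computed exactly by transfer-matrix (forward-backward) recursion;
* ``product`` — per-position independent closed form for singleton-only
  constraints at widths where the full table is infeasible.

A pseudocount (default 0.5 per marginal cell) keeps every fitted probability
strictly positive so log-odds are always finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from splicescreen.errors import FlankTooShortError
from splicescreen.motifs import BASES, BASE_INDEX

_TABLE_MAX_WIDTH = 10


# ---------------------------------------------------------------------------
# window specs

@dataclass(frozen=True)
class SiteWindowSpec:
    """Geometry of a splice-site window around an exon/intron boundary."""

    site_type: str  # "donor" or "acceptor"
    exonic_len: int
    intronic_len: int

    def __post_init__(self):
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError("site_type must be 'donor' or 'acceptor'")
        if self.exonic_len < 0 or self.intronic_len < 0 or self.width < 1:
            raise ValueError("window lengths must be non-negative, width >= 1")

    @property
    def width(self) -> int:
        return self.exonic_len + self.intronic_len


#: donor 9-mer: last 3 exonic nt + first 6 intronic nt
DONOR_SPEC = SiteWindowSpec("donor", exonic_len=3, intronic_len=6)
#: acceptor 23-mer: last 20 intronic nt + first 3 exonic nt
ACCEPTOR_SPEC = SiteWindowSpec("acceptor", exonic_len=3, intronic_len=20)


def extract_site_window(exon_context, site_type: str,
                        spec: Optional[SiteWindowSpec] = None) -> str:
    """Cut the window straddling an exon boundary out of an exon + flanks.

    ``exon_context`` is anything with ``exon_seq``, ``upstream_flank`` and
    ``downstream_flank`` attributes (e.g. an ExonRecord).  The acceptor window
    is the last ``intronic_len`` nt of the upstream intron followed by the
    first ``exonic_len`` nt of the exon; the donor window is the last
    ``exonic_len`` nt of the exon followed by the first ``intronic_len`` nt of
    the downstream intron.
    """
    if spec is None:
        spec = DONOR_SPEC if site_type == "donor" else ACCEPTOR_SPEC
    if spec.site_type != site_type:
        raise ValueError("spec.site_type disagrees with site_type argument")
    exon = exon_context.exon_seq.upper()
    if site_type == "acceptor":
        flank = exon_context.upstream_flank.upper()
        if len(flank) < spec.intronic_len:
            raise FlankTooShortError(
                f"upstream flank has {len(flank)} nt, acceptor window needs "
                f"{spec.intronic_len} ({spec.intronic_len - len(flank)} missing)",
                deficit=spec.intronic_len - len(flank),
            )
        if len(exon) < spec.exonic_len:
            raise FlankTooShortError(
                f"exon has {len(exon)} nt, acceptor window needs "
                f"{spec.exonic_len} exonic nt",
                deficit=spec.exonic_len - len(exon),
            )
        return flank[len(flank) - spec.intronic_len:] + exon[:spec.exonic_len]
    flank = exon_context.downstream_flank.upper()
    if len(flank) < spec.intronic_len:
        raise FlankTooShortError(
            f"downstream flank has {len(flank)} nt, donor window needs "
            f"{spec.intronic_len} ({spec.intronic_len - len(flank)} missing)",
            deficit=spec.intronic_len - len(flank),
        )
    if len(exon) < spec.exonic_len:
        raise FlankTooShortError(
            f"exon has {len(exon)} nt, donor window needs "
            f"{spec.exonic_len} exonic nt",
            deficit=spec.exonic_len - len(exon),
        )
    return exon[len(exon) - spec.exonic_len:] + flank[:spec.intronic_len]


# ---------------------------------------------------------------------------
# window encoding

def encode_windows(windows: Sequence[str], width: int) -> np.ndarray:
    """Windows -> (n, width) int array over {0..3}; strict ACGT."""
    arr = np.empty((len(windows), width), dtype=np.int64)
    for i, w in enumerate(windows):
        w = w.upper()
        if len(w) != width:
            raise ValueError(f"window {w!r} has length {len(w)}, expected {width}")
        for j, c in enumerate(w):
            idx = BASE_INDEX.get(c)
            if idx is None:
                raise ValueError(f"non-ACGT character {c!r} in window {w!r}")
            arr[i, j] = idx
    return arr


def empirical_marginals(
    encoded: np.ndarray,
    constraint_set: Sequence[Tuple[int, ...]],
    pseudocount: float = 0.5,
) -> Dict[Tuple[int, ...], np.ndarray]:
    """Per-subset empirical marginal tables with an additive pseudocount.

    The pseudocount is added per cell of each *maximal* subset's table; a
    subset nested inside a larger constraint gets its target by marginalising
    the superset's pseudocounted table instead, so redundant constraints stay
    mutually consistent and IPF has an exact fixed point.
    """
    targets: Dict[Tuple[int, ...], np.ndarray] = {}
    subsets = [tuple(s) for s in constraint_set]

    def raw_target(subset):
        shape = (4,) * len(subset)
        counts = np.zeros(shape, dtype=float)
        cols = encoded[:, list(subset)]
        np.add.at(counts, tuple(cols[:, k] for k in range(len(subset))), 1.0)
        counts += pseudocount
        return counts / counts.sum()

    for subset in subsets:
        superset = next(
            (t for t in subsets if set(subset) < set(t)), None)
        if superset is None:
            targets[subset] = raw_target(subset)
    for subset in subsets:
        if subset in targets:
            continue
        superset = next(t for t in subsets if set(subset) < set(t))
        table = targets.get(superset)
        if table is None:
            table = raw_target(superset)
        axes = tuple(k for k, pos in enumerate(superset) if pos not in subset)
        targets[subset] = table.sum(axis=axes)
    return targets


def singleton_constraints(width: int) -> List[Tuple[int, ...]]:
    return [(i,) for i in range(width)]


def adjacent_pair_constraints(width: int) -> List[Tuple[int, ...]]:
    return [(i, i + 1) for i in range(width - 1)]


def _is_chain(constraint_set: Sequence[Tuple[int, ...]], width: int) -> bool:
    """True if every subset is a singleton or an adjacent pair and the pairs
    cover the whole chain (so transfer-matrix evaluation is exact)."""
    pairs = set()
    for s in constraint_set:
        s = tuple(s)
        if len(s) == 1:
            continue
        if len(s) == 2 and s[1] == s[0] + 1:
            pairs.add(s)
        else:
            return False
    return pairs == set(adjacent_pair_constraints(width)) and width >= 2


# ---------------------------------------------------------------------------
# distribution engines

class _TableDist:
    """Full joint over 4^width outcomes (width <= 10)."""

    engine = "table"

    def __init__(self, width: int, table: np.ndarray):
        self.width = width
        self.table = table

    @classmethod
    def fit(cls, width, targets, tol, max_iter):
        table = np.full((4,) * width, 4.0 ** -width)
        all_axes = set(range(width))
        disc = math.inf
        it = 0
        for it in range(1, max_iter + 1):
            for subset, target in targets.items():
                axes = tuple(sorted(all_axes - set(subset)))
                current = table.sum(axis=axes)
                # table axes are in position order; subset is sorted, so
                # `current` is indexed in subset order already
                ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
                expand = [slice(None) if i in subset else None for i in range(width)]
                table = table * ratio[tuple(expand)]
            disc = 0.0
            for subset, target in targets.items():
                axes = tuple(sorted(all_axes - set(subset)))
                disc = max(disc, float(np.abs(table.sum(axis=axes) - target).max()))
            if disc < tol:
                break
        s = table.sum()
        if s > 0:
            table = table / s
        return cls(width, table), it, disc < tol, disc

    def log2_prob(self, encoded_row: np.ndarray) -> float:
        p = float(self.table[tuple(encoded_row)])
        return math.log2(p) if p > 0 else -math.inf

    def marginal(self, subset: Tuple[int, ...]) -> np.ndarray:
        axes = tuple(sorted(set(range(self.width)) - set(subset)))
        return self.table.sum(axis=axes)

    def entropy(self) -> float:
        p = self.table[self.table > 0]
        return float(-(p * np.log2(p)).sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        flat = self.table.reshape(-1)
        idx = rng.choice(flat.size, size=n, p=flat / flat.sum())
        return np.stack(np.unravel_index(idx, self.table.shape), axis=1)

    def to_jsonable(self):
        return {"engine": self.engine, "width": self.width,
                "table": self.table.reshape(-1).tolist()}

    @classmethod
    def from_jsonable(cls, d):
        w = d["width"]
        return cls(w, np.asarray(d["table"], dtype=float).reshape((4,) * w))


class _ProductDist:
    """Independent per-position distribution (singleton constraints)."""

    engine = "product"

    def __init__(self, width: int, probs: np.ndarray):
        self.width = width
        self.probs = probs  # width x 4, rows sum to 1

    @classmethod
    def fit(cls, width, targets, tol, max_iter):
        probs = np.full((width, 4), 0.25)
        for subset, target in targets.items():
            probs[subset[0]] = target
        return cls(width, probs), 1, True, 0.0

    def log2_prob(self, encoded_row: np.ndarray) -> float:
        p = self.probs[np.arange(self.width), encoded_row]
        if np.any(p <= 0):
            return -math.inf
        return float(np.log2(p).sum())

    def marginal(self, subset):
        if len(subset) == 1:
            return self.probs[subset[0]].copy()
        m = self.probs[subset[0]]
        for pos in subset[1:]:
            m = np.multiply.outer(m, self.probs[pos])
        return m

    def entropy(self) -> float:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return float(-terms.sum())

    def sample(self, rng, n):
        out = np.empty((n, self.width), dtype=np.int64)
        for j in range(self.width):
            out[:, j] = rng.choice(4, size=n, p=self.probs[j])
        return out

    def to_jsonable(self):
        return {"engine": self.engine, "width": self.width,
                "probs": self.probs.tolist()}

    @classmethod
    def from_jsonable(cls, d):
        return cls(d["width"], np.asarray(d["probs"], dtype=float))


class _ChainDist:
    """Adjacent-pair factored model; exact via transfer-matrix recursions.

    Unnormalised density is prod_i psi_i[x_i, x_{i+1}]; the normaliser and all
    pair marginals come from scaled forward/backward messages, so the engine
    stays exact at acceptor width (23) where the full table is infeasible.
    """

    engine = "chain"

    def __init__(self, width: int, factors: List[np.ndarray]):
        self.width = width
        self.factors = factors  # width-1 matrices of shape (4, 4)
        self._messages_cache = None

    # -- message passing ---------------------------------------------------
    def _messages(self):
        if self._messages_cache is not None:
            return self._messages_cache
        w = self.width
        alphas = [None] * w
        log_scale_f = 0.0
        a = np.ones(4)
        alphas[0] = a / a.sum()
        log_scale_f += math.log(a.sum())
        for i in range(w - 1):
            a = alphas[i] @ self.factors[i]
            s = a.sum()
            alphas[i + 1] = a / s
            log_scale_f += math.log(s)
        betas = [None] * w
        b = np.ones(4)
        betas[w - 1] = b / b.sum()
        log_scale_b = math.log(b.sum())
        for i in range(w - 2, -1, -1):
            b = self.factors[i] @ betas[i + 1]
            s = b.sum()
            betas[i] = b / s
            log_scale_b += math.log(s)
        # the forward scale factors accumulate exactly log Z
        log_z = log_scale_f
        self._messages_cache = (alphas, betas, log_z)
        return self._messages_cache

    def log2_z(self) -> float:
        _, _, log_z = self._messages()
        return log_z / math.log(2.0)

    def pair_marginal(self, i: int) -> np.ndarray:
        alphas, betas, _ = self._messages()
        m = alphas[i][:, None] * self.factors[i] * betas[i + 1][None, :]
        return m / m.sum()

    def singleton_marginal(self, i: int) -> np.ndarray:
        if self.width == 1:
            return np.ones(4) / 4
        if i < self.width - 1:
            return self.pair_marginal(i).sum(axis=1)
        return self.pair_marginal(i - 1).sum(axis=0)

    def marginal(self, subset):
        subset = tuple(subset)
        if len(subset) == 1:
            return self.singleton_marginal(subset[0])
        if len(subset) == 2 and subset[1] == subset[0] + 1:
            return self.pair_marginal(subset[0])
        raise ValueError("chain engine only exposes singleton/adjacent-pair marginals")

    @classmethod
    def fit(cls, width, targets, tol, max_iter):
        pair_targets = {s: t for s, t in targets.items() if len(s) == 2}
        dist = cls(width, [np.ones((4, 4)) for _ in range(width - 1)])
        disc = math.inf
        it = 0
        for it in range(1, max_iter + 1):
            for (i, _j), target in sorted(pair_targets.items()):
                current = dist.pair_marginal(i)
                ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
                dist.factors[i] = dist.factors[i] * ratio
                dist._messages_cache = None
            disc = 0.0
            for (i, _j), target in pair_targets.items():
                disc = max(disc, float(np.abs(dist.pair_marginal(i) - target).max()))
            # singleton targets are implied by consistent pair targets; verify
            for s, t in targets.items():
                if len(s) == 1:
                    disc = max(disc, float(np.abs(dist.singleton_marginal(s[0]) - t).max()))
            if disc < tol:
                break
        return dist, it, disc < tol, disc

    def log2_prob(self, encoded_row: np.ndarray) -> float:
        log_p = 0.0
        for i in range(self.width - 1):
            f = self.factors[i][encoded_row[i], encoded_row[i + 1]]
            if f <= 0:
                return -math.inf
            log_p += math.log(f)
        _, _, log_z = self._messages()
        return (log_p - log_z) / math.log(2.0)

    def entropy(self) -> float:
        # H = -E[log2 p] = (log2 Z - E[sum log2 psi]); exact via pair marginals
        acc = 0.0
        for i in range(self.width - 1):
            m = self.pair_marginal(i)
            f = self.factors[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(m > 0, m * np.log2(np.where(f > 0, f, 1.0)), 0.0)
            acc += float(terms.sum())
        return self.log2_z() - acc

    def sample(self, rng, n):
        out = np.empty((n, self.width), dtype=np.int64)
        p0 = self.singleton_marginal(0)
        out[:, 0] = rng.choice(4, size=n, p=p0)
        for i in range(self.width - 1):
            pm = self.pair_marginal(i)
            cond = pm / pm.sum(axis=1, keepdims=True)
            for b in range(4):
                mask = out[:, i] == b
                k = int(mask.sum())
                if k:
                    out[mask, i + 1] = rng.choice(4, size=k, p=cond[b])
        return out

    def to_jsonable(self):
        return {"engine": self.engine, "width": self.width,
                "factors": [f.tolist() for f in self.factors]}

    @classmethod
    def from_jsonable(cls, d):
        return cls(d["width"], [np.asarray(f, dtype=float) for f in d["factors"]])


_ENGINES = {"table": _TableDist, "product": _ProductDist, "chain": _ChainDist}


def uniform_dist(width: int) -> _ProductDist:
    return _ProductDist(width, np.full((width, 4), 0.25))


def _fit_dist(width, targets, tol, max_iter):
    constraint_set = list(targets.keys())
    if all(len(s) == 1 for s in constraint_set):
        if width <= _TABLE_MAX_WIDTH:
            return _TableDist.fit(width, targets, tol, max_iter)
        return _ProductDist.fit(width, targets, tol, max_iter)
    if _is_chain(constraint_set, width):
        return _ChainDist.fit(width, targets, tol, max_iter)
    if width <= _TABLE_MAX_WIDTH:
        return _TableDist.fit(width, targets, tol, max_iter)
    raise ValueError(
        "constraint sets other than singletons/adjacent-pair chains require "
        f"width <= {_TABLE_MAX_WIDTH} (full-table fitting)"
    )


# ---------------------------------------------------------------------------
# the model

@dataclass
class StrengthCall:
    """A splice-site score with its weak/strong/intermediate label."""

    score: float
    label: str
    cutoffs: Tuple[float, float]


def classify_strength(score: float, cutoffs: Tuple[float, float]) -> StrengthCall:
    """Label a score weak (< weak_below), strong (>= strong_at_or_above) or
    intermediate."""
    weak_below, strong_at = cutoffs
    if weak_below > strong_at:
        raise ValueError("cutoffs inverted: weak_below must be <= strong_at_or_above")
    if score < weak_below:
        label = "weak"
    elif score >= strong_at:
        label = "strong"
    else:
        label = "intermediate"
    return StrengthCall(score=score, label=label, cutoffs=(weak_below, strong_at))


class SpliceSiteModel:
    """Signal/background maximum-entropy pair, scorable as log2 odds."""

    def __init__(self, spec: SiteWindowSpec, constraint_set, signal, background,
                 fit_meta: Optional[dict] = None):
        self.spec = spec
        self.constraint_set = [tuple(s) for s in constraint_set]
        self.signal = signal
        self.background = background
        self.fit_meta = fit_meta or {}

    @property
    def width(self) -> int:
        return self.spec.width

    def score(self, window: str) -> float:
        return score_site(self, window)

    def score_many(self, windows: Sequence[str]) -> np.ndarray:
        return np.array([self.score(w) for w in windows])

    def classify(self, window: str, cutoffs: Tuple[float, float]) -> StrengthCall:
        return classify_strength(self.score(window), cutoffs)

    # -- serialisation -----------------------------------------------------
    def to_jsonable(self) -> dict:
        return {
            "format": "splicescreen-site-model/1",
            "site_type": self.spec.site_type,
            "exonic_len": self.spec.exonic_len,
            "intronic_len": self.spec.intronic_len,
            "constraint_set": [list(s) for s in self.constraint_set],
            "signal": self.signal.to_jsonable(),
            "background": self.background.to_jsonable(),
            "fit_meta": self.fit_meta,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SpliceSiteModel":
        spec = SiteWindowSpec(d["site_type"], d["exonic_len"], d["intronic_len"])
        signal = _ENGINES[d["signal"]["engine"]].from_jsonable(d["signal"])
        background = _ENGINES[d["background"]["engine"]].from_jsonable(d["background"])
        return cls(spec, [tuple(s) for s in d["constraint_set"]], signal,
                   background, d.get("fit_meta", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SpliceSiteModel":
        with open(path) as fh:
            return cls.from_jsonable(json.load(fh))


def train_maxent(
    site_windows: Sequence[str],
    background_windows: Optional[Sequence[str]],
    spec: SiteWindowSpec,
    constraint_set: Optional[Sequence[Tuple[int, ...]]] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    pseudocount: float = 0.5,
) -> SpliceSiteModel:
    """Fit signal (and optionally background) maximum-entropy distributions.

    ``constraint_set`` defaults to adjacent pairs (first-order dependence).
    ``background_windows=None`` uses a uniform background, which keeps the
    model self-contained; pass decoy windows to train an explicit background.
    Non-convergence is reported via ``fit_meta['converged']`` plus a warning,
    never an exception; an empty signal corpus is an error.
    """
    import warnings

    if len(site_windows) == 0:
        raise ValueError("need at least one signal window")
    width = spec.width
    if constraint_set is None:
        constraint_set = adjacent_pair_constraints(width) if width > 1 \
            else singleton_constraints(width)
    constraint_set = [tuple(sorted(s)) for s in constraint_set]

    enc = encode_windows(site_windows, width)
    targets = empirical_marginals(enc, constraint_set, pseudocount)
    signal, it_s, conv_s, disc_s = _fit_dist(width, targets, tol, max_iter)

    if background_windows is None:
        background = uniform_dist(width)
        conv_b, it_b, disc_b = True, 0, 0.0
    else:
        if len(background_windows) == 0:
            raise ValueError("background window list is empty; pass None for uniform")
        enc_b = encode_windows(background_windows, width)
        targets_b = empirical_marginals(enc_b, constraint_set, pseudocount)
        background, it_b, conv_b, disc_b = _fit_dist(width, targets_b, tol, max_iter)

    converged = conv_s and conv_b
    if not converged:
        warnings.warn(
            f"IPF did not reach tol={tol} within {max_iter} iterations "
            f"(max discrepancy signal={disc_s:.2e}, background={disc_b:.2e})",
            RuntimeWarning,
        )
    meta = {
        "n_signal": len(site_windows),
        "n_background": 0 if background_windows is None else len(background_windows),
        "iterations": {"signal": it_s, "background": it_b},
        "max_discrepancy": {"signal": disc_s, "background": disc_b},
        "tol": tol,
        "pseudocount": pseudocount,
        "converged": converged,
    }
    return SpliceSiteModel(spec, constraint_set, signal, background, meta)


def score_site(model: SpliceSiteModel, window: str) -> float:
    """log2( P_signal(window) / P_background(window) ) in bits."""
    enc = encode_windows([window], model.width)[0]
    return float(model.signal.log2_prob(enc) - model.background.log2_prob(enc))
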