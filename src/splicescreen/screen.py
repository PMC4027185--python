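"""Candidate screen for splicing-constrained codons in paralog families.

The screen flags pairs of paralogous exons where (a) one member has a weak
splice site and the other a strong one, with a minimum strength contrast,
(b) the weak member carries exonic splicing enhancers whose aligned positions
in the strong member carry no same-set enhancer, and (c) the enhancer span
(plus a small codon adjacency window) contains non-synonymous differences —
i.e. amino-acid changes that could not be made without destroying the
enhancer the weak splice site depends on.  Silencer (ESS) hits inside the
enhancer span are attached as context only; they are never part of the
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from splicescreen.codon_align import (
    CodonAlignment,
    ColumnDiff,
    ExonRecord,
    align_pair,
    diff_columns,
)
from splicescreen.maxent import SpliceSiteModel, classify_strength, extract_site_window
from splicescreen.motifs import (
    ESS_HEX,
    HexamerSet,
    MotifHit,
    Pwm,
    motif_set_source,
    scan_hexamers,
    scan_pwm,
)

MotifSet = Union[Pwm, HexamerSet]


@dataclass
class ScreenConfig:
    """Tunable criteria of the candidate screen.

    ``min_delta`` (bits) is the minimum splice-site strength contrast between
    the paralogs and is deliberately required — no default contrast is
    assumed.  ``adjacency_window`` is how many codons away from an enhancer
    span an amino-acid difference may sit and still count: default 1, because
    a residue immediately adjacent to a predicted enhancer can be functionally
    part of the element.
    """

    motif_sets: List[MotifSet]
    min_delta: float
    strength_cutoffs: Tuple[float, float] = (3.0, 6.0)
    adjacency_window: int = 1
    site_of_interest: str = "both"  # acceptor | donor | both

    def __post_init__(self):
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")
        if self.adjacency_window < 0:
            raise ValueError("adjacency_window must be >= 0")
        if self.site_of_interest not in ("acceptor", "donor", "both"):
            raise ValueError("site_of_interest must be acceptor, donor or both")

    @property
    def sites(self) -> List[str]:
        if self.site_of_interest == "both":
            return ["acceptor", "donor"]
        return [self.site_of_interest]


@dataclass
class CandidateReport:
    """One screened locus that met every criterion."""

    weak_member: str
    strong_member: str
    site_type: str
    strength_weak: float
    strength_strong: float
    ese_hits_weak_only: List[MotifHit]
    overlapping_diffs: List[ColumnDiff]
    ess_hits_near: List[MotifHit]
    verdict_notes: List[str] = field(default_factory=list)

    def validate(self, config: ScreenConfig) -> None:
        assert self.strength_strong - self.strength_weak >= config.min_delta
        assert self.ese_hits_weak_only, "report without weak-only ESE hits"
        assert self.overlapping_diffs, "report without coincident aa differences"
        assert all(d.kind == "nonsynonymous" for d in self.overlapping_diffs)

    def hit_spans(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(sorted(h.span for h in self.ese_hits_weak_only))


def project_hits(alignment: CodonAlignment, hits: Sequence[MotifHit],
                 member: str) -> List[Tuple[int, int]]:
    """Map motif hits (exon nt coordinates) to nucleotide-alignment columns.

    Each hit becomes the half-open column interval covering its nucleotides;
    gap columns falling inside the interval are retained.  A hit extending
    outside the member's aligned complete-codon region is an error naming the
    hit.
    """
    out: List[Tuple[int, int]] = []
    for hit in hits:
        try:
            c0 = alignment.nt_column(member, hit.start)
            c1 = alignment.nt_column(member, hit.end - 1)
        except ValueError as exc:
            raise ValueError(
                f"hit {hit.motif_name} [{hit.start},{hit.end}) of {member} "
                f"lies outside the aligned region: {exc}"
            ) from exc
        out.append((c0, c1 + 1))
    return out


def _scan_member(record: ExonRecord, motif_sets: Sequence[MotifSet]) -> List[MotifHit]:
    hits: List[MotifHit] = []
    for ms in motif_sets:
        if isinstance(ms, Pwm):
            hits.extend(scan_pwm(record.exon_seq, ms, seq_id=record.seq_id))
        else:
            hits.extend(scan_hexamers(record.exon_seq, ms, seq_id=record.seq_id))
    return hits


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def screen_pair(a: ExonRecord, b: ExonRecord,
                models: Dict[str, SpliceSiteModel],
                config: ScreenConfig) -> List[CandidateReport]:
    """Screen one ordered pair of paralog exons in both orientations."""
    reports: List[CandidateReport] = []
    alignment: Optional[CodonAlignment] = None
    all_hits: Dict[str, List[MotifHit]] = {}

    for site in config.sites:
        model = models[site]
        calls = {}
        for rec in (a, b):
            window = extract_site_window(rec, site, model.spec)
            calls[rec.seq_id] = classify_strength(model.score(window),
                                                  config.strength_cutoffs)
        for weak, strong in ((a, b), (b, a)):
            cw, cs = calls[weak.seq_id], calls[strong.seq_id]
            if cw.label != "weak" or cs.label != "strong":
                continue
            if cs.score - cw.score < config.min_delta:
                continue
            if alignment is None:
                alignment = align_pair(a, b)
                for rec in (a, b):
                    all_hits[rec.seq_id] = _scan_member(rec, config.motif_sets)

            weak_hits = [h for h in all_hits[weak.seq_id] if h.kind != ESS_HEX]
            strong_hits = [h for h in all_hits[strong.seq_id] if h.kind != ESS_HEX]
            ess_hits = [h for h in all_hits[weak.seq_id] if h.kind == ESS_HEX]

            strong_cols = [
                (motif_set_source(h), span)
                for h, span in zip(
                    strong_hits,
                    project_hits(alignment, strong_hits, strong.seq_id))
            ]
            diffs = diff_columns(alignment, weak.seq_id, strong.seq_id)
            nonsyn = [d for d in diffs if d.kind == "nonsynonymous"]

            weak_only: List[MotifHit] = []
            coincident: List[ColumnDiff] = []
            ess_near: List[MotifHit] = []
            for hit, span in zip(
                    weak_hits,
                    project_hits(alignment, weak_hits, weak.seq_id)):
                source = motif_set_source(hit)
                present_in_strong = any(
                    src == source and _overlap(span, s)
                    for src, s in strong_cols
                )
                if present_in_strong:
                    continue
                # codon-column window around the hit, widened by adjacency
                c_lo = span[0] // 3 - config.adjacency_window
                c_hi = (span[1] + 2) // 3 + config.adjacency_window
                near = [d for d in nonsyn if c_lo <= d.column < c_hi]
                if not near:
                    continue
                weak_only.append(hit)
                for d in near:
                    if d not in coincident:
                        coincident.append(d)
                for eh in ess_hits:
                    if _overlap((eh.start, eh.end), (hit.start, hit.end)) \
                            and eh not in ess_near:
                        ess_near.append(eh)
            if weak_only:
                report = CandidateReport(
                    weak_member=weak.seq_id,
                    strong_member=strong.seq_id,
                    site_type=site,
                    strength_weak=cw.score,
                    strength_strong=cs.score,
                    ese_hits_weak_only=weak_only,
                    overlapping_diffs=coincident,
                    ess_hits_near=ess_near,
                    verdict_notes=[
                        f"{site} contrast {cs.score - cw.score:.2f} bits",
                        f"{len(weak_only)} ESE hit(s) absent in {strong.seq_id}",
                        f"{len(coincident)} coincident non-synonymous difference(s)",
                    ],
                )
                report.validate(config)
                reports.append(report)
    return reports


def screen_family(records: Sequence[ExonRecord],
                  models: Dict[str, SpliceSiteModel],
                  config: ScreenConfig) -> List[CandidateReport]:
    """Union of :func:`screen_pair` over all unordered member pairs.

    Reports are deduplicated by (weak member, strong member, site, hit spans)
    and returned in a deterministic order.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 family members")
    seen = set()
    out: List[CandidateReport] = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            for report in screen_pair(records[i], records[j], models, config):
                key = (report.weak_member, report.strong_member,
                       report.site_type, report.hit_spans())
                if key not in seen:
                    seen.add(key)
                    out.append(report)
    out.sort(key=lambda r: (r.weak_member, r.strong_member, r.site_type))
    return out
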