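"""Scan multi-species alignments with reconstructed ancestral sequences.

Input is an aligned set of extant (leaf) and reconstructed internal-node
sequences plus a matching tree — ancestral reconstruction itself is an
upstream tool; this module consumes its output.  The alignment is trimmed to a
reference exon with flanks, every node's row is scanned for enhancer motifs
and its splice-site windows are scored, and the per-node profiles are keyed
back onto the tree.

Exon boundaries in non-reference rows are projected through alignment columns
from the reference row; a node whose site window crosses a gap gets a flag and
a missing score rather than a guessed boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy

from splicescreen.maxent import SpliceSiteModel
from splicescreen.motifs import HexamerSet, MotifHit, Pwm, scan_hexamers, scan_pwm

logger = logging.getLogger(__name__)

MotifSet = Union[Pwm, HexamerSet]


@dataclass
class NodeAlignment:
    """Aligned leaf + internal-node rows with a coordinate-defining reference.

    ``ref_exon`` is 0-based half-open in *ungapped* reference coordinates.
    """

    rows: Dict[str, str]
    tree: str
    ref_label: str
    ref_exon: Tuple[int, int]
    flags: List[str] = field(default_factory=list)

    def __post_init__(self):
        if self.ref_label not in self.rows:
            raise ValueError(f"reference row {self.ref_label!r} missing")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = {k: v.upper().replace("U", "T") for k, v in self.rows.items()}

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.ref_label])

    def ref_ungapped_to_column(self) -> List[int]:
        """Column index of each ungapped reference position."""
        cols = []
        for col, c in enumerate(self.rows[self.ref_label]):
            if c != "-":
                cols.append(col)
        return cols


@dataclass
class NodeProfile:
    """Motif and splice-site summary of one node's sequence."""

    node_label: str
    acceptor_score: Optional[float] = None
    donor_score: Optional[float] = None
    pwm_hit_counts: Dict[str, int] = field(default_factory=dict)
    hexamer_hit_count: int = 0
    hits: List[MotifHit] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)


def trim_to_exon(na: NodeAlignment, flank: int) -> NodeAlignment:
    """Restrict the alignment to the reference exon +/- ``flank`` nt.

    The interval is taken in ungapped reference coordinates and mapped through
    the reference row's gaps, so gap columns inside the interval are kept.  A
    flank running off the reference is truncated and flagged (``short_flank``),
    not errored.  Applying the same trim twice is a no-op.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start, end = na.ref_exon
    cols = na.ref_ungapped_to_column()
    if not 0 <= start < end <= len(cols):
        raise ValueError("ref_exon outside the reference sequence")
    flags = list(na.flags)
    lo = start - flank
    hi = end + flank
    if lo < 0 or hi > len(cols):
        if "short_flank" not in flags:
            flags.append("short_flank")
        lo = max(lo, 0)
        hi = min(hi, len(cols))
    col_lo = cols[lo]
    col_hi = cols[hi - 1] + 1
    rows = {k: v[col_lo:col_hi] for k, v in na.rows.items()}
    return NodeAlignment(
        rows=rows,
        tree=na.tree,
        ref_label=na.ref_label,
        ref_exon=(start - lo, start - lo + (end - start)),
        flags=flags,
    )


def _window_from_columns(row: str, columns: Sequence[int]) -> Optional[str]:
    """Node characters at the given columns; None if any is a gap."""
    chars = [row[c] for c in columns]
    if "-" in chars:
        return None
    return "".join(chars)


def scan_nodes(na: NodeAlignment,
               motif_sets: Sequence[MotifSet],
               splice_models: Dict[str, SpliceSiteModel],
               threshold_frac: Optional[float] = None) -> List[NodeProfile]:
    """Per-node motif counts and splice-site scores.

    The exon body of each node is its degapped sequence over the reference
    exon's column span.  Site windows are read at the columns where the
    reference's window sits; a gap there yields a missing score plus a
    ``gap_in_site_window`` flag, a too-short flank a ``short_flank`` flag.
    Nothing is fatal per node.
    """
    start, end = na.ref_exon
    cols = na.ref_ungapped_to_column()
    profiles: List[NodeProfile] = []

    def site_columns(model: SpliceSiteModel, site: str) -> Optional[List[int]]:
        spec = model.spec
        if site == "acceptor":
            lo = start - spec.intronic_len
            hi = start + spec.exonic_len
        else:
            lo = end - spec.exonic_len
            hi = end + spec.intronic_len
        if lo < 0 or hi > len(cols):
            return None
        return [cols[p] for p in range(lo, hi)]

    acc_cols = site_columns(splice_models["acceptor"], "acceptor") \
        if "acceptor" in splice_models else None
    don_cols = site_columns(splice_models["donor"], "donor") \
        if "donor" in splice_models else None

    exon_cols = [cols[p] for p in range(start, end)]

    for label, row in na.rows.items():
        profile = NodeProfile(node_label=label)
        exon_seq = "".join(row[c] for c in exon_cols).replace("-", "")
        for ms in motif_sets:
            if isinstance(ms, Pwm):
                hits = scan_pwm(exon_seq, ms, seq_id=label,
                                threshold_frac=threshold_frac)
                profile.pwm_hit_counts[ms.name] = len(hits)
            else:
                hits = scan_hexamers(exon_seq, ms, seq_id=label)
                profile.hexamer_hit_count += len(hits)
            profile.hits.extend(hits)
        for site, columns, attr in (
                ("acceptor", acc_cols, "acceptor_score"),
                ("donor", don_cols, "donor_score")):
            if site not in splice_models:
                continue
            if columns is None:
                profile.flags.append(f"short_flank:{site}")
                continue
            window = _window_from_columns(row, columns)
            if window is None:
                profile.flags.append(f"gap_in_site_window:{site}")
                continue
            if any(c not in "ACGT" for c in window):
                profile.flags.append(f"ambiguous_site_window:{site}")
                continue
            setattr(profile, attr, splice_models[site].score(window))
        profiles.append(profile)
    return profiles


def annotate_tree(profiles: Sequence[NodeProfile], tree: str) -> Tuple[str, "object"]:
    """Attach per-node scores/counts to a newick tree as comment fields.

    Returns the annotated newick string and a pandas DataFrame companion
    table.  Labels in the profile set with no matching tree node (and vice
    versa) produce a warning, never an error.
    """
    import pandas as pd

    t = dendropy.Tree.get(data=tree, schema="newick",
                          suppress_internal_node_taxa=False)
    by_label = {p.node_label: p for p in profiles}
    annotated = set()
    for node in t.preorder_node_iter():
        label = None
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is None:
            continue
        label = label.replace(" ", "_")
        p = by_label.get(label) or by_label.get(label.replace("_", " "))
        if p is None:
            logger.warning("tree node %r has no profile; left unannotated", label)
            continue
        annotated.add(p.node_label)
        node.annotations.add_new(
            "acceptor", "NA" if p.acceptor_score is None else f"{p.acceptor_score:.4f}")
        node.annotations.add_new(
            "donor", "NA" if p.donor_score is None else f"{p.donor_score:.4f}")
        node.annotations.add_new("hex_hits", str(p.hexamer_hit_count))
        for name, count in sorted(p.pwm_hit_counts.items()):
            node.annotations.add_new(f"pwm_{name}", str(count))
    for p in profiles:
        if p.node_label not in annotated:
            logger.warning("profile %r has no tree node; dropped from newick",
                           p.node_label)
    newick = t.as_string(schema="newick", suppress_annotations=False,
                         suppress_rooting=True)
    rows = []
    for p in profiles:
        row = {
            "node": p.node_label,
            "acceptor_score": p.acceptor_score,
            "donor_score": p.donor_score,
            "hexamer_hits": p.hexamer_hit_count,
            "flags": ";".join(p.flags),
        }
        for name, count in p.pwm_hit_counts.items():
            row[f"pwm_{name}"] = count
        rows.append(row)
    return newick, pd.DataFrame(rows)


def read_annotated_scores(newick: str) -> Dict[str, Dict[str, str]]:
    """Parse back the per-node annotations written by :func:`annotate_tree`."""
    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=False)
    out: Dict[str, Dict[str, str]] = {}
    for node in t.preorder_node_iter():
        label = None
        if node.taxon is not None and node.taxon.label:
            label = node.taxon.label
        elif node.label:
            label = node.label
        if label is None:
            continue
        ann = {a.name: a.value for a in node.annotations}
        if ann:
            out[label.replace(" ", "_")] = ann
    return out
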