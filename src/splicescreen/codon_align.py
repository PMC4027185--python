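"""Codon-aware alignment of paralogous exon coding regions.

Paralog exons are compared at the protein level first — translate, globally
align the peptides (Needleman-Wunsch with affine gaps, BLOSUM62), then thread
the nucleotide codons back through the protein alignment — because paralog
families are conserved at the domain/protein level while their nucleotide
sequences carry the synonymous noise the downstream screen must see through.

A column in a :class:`CodonAlignment` is one aligned residue/codon; nucleotide
alignment columns are the 3x finer grid.  Leading/trailing partial codons at
exon edges (phase != 0 or trailing remainder) are excluded from translation but
retained in the underlying exon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

GAP_CODON = "---"


@dataclass
class ExonRecord:
    """One exon with flanking intronic context and reading-frame phase.

    ``phase`` is the nt offset into the first codon: that many leading
    nucleotides complete the previous exon's codon and are skipped by
    translation.
    """

    seq_id: str
    exon_seq: str
    upstream_flank: str = ""
    downstream_flank: str = ""
    phase: int = 0
    gene_meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        self.exon_seq = self.exon_seq.upper().replace("U", "T")
        self.upstream_flank = self.upstream_flank.upper().replace("U", "T")
        self.downstream_flank = self.downstream_flank.upper().replace("U", "T")

    @property
    def n_codons(self) -> int:
        return (len(self.exon_seq) - self.phase) // 3

    def codon(self, k: int) -> str:
        """k-th complete codon of the exon (0-based)."""
        if not 0 <= k < self.n_codons:
            raise IndexError(f"codon index {k} out of range")
        start = self.phase + 3 * k
        return self.exon_seq[start:start + 3]

    @property
    def protein(self) -> str:
        return translate(self.exon_seq, self.phase)


def translate(cds: str, phase: int = 0) -> str:
    """Standard-genetic-code translation of the complete codons of ``cds``.

    Skips ``phase`` leading nt, drops any trailing partial codon; stop codons
    become ``*`` and codons with ambiguous bases (N) become ``X``.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) - phase < 3:
        raise ValueError(
            f"need at least one complete codon after skipping phase={phase} nt"
        )
    usable = cds[phase:]
    usable = usable[: 3 * (len(usable) // 3)]
    return str(Seq(usable).translate())


@dataclass
class CodonAlignment:
    """Paired protein/nucleotide alignment of paralog exon regions.

    ``protein_rows[m]`` is the gapped amino-acid string of member ``m``;
    ``nucleotide_rows[m]`` the corresponding gapped codon string (gap codon
    ``---``), always exactly 3x as long.  ``codon_index`` maps each protein
    column to the member's codon number (or None at gaps), from which both
    exon-nt coordinates and nucleotide-alignment columns are derived.
    """

    members: List[str]
    protein_rows: Dict[str, str]
    nucleotide_rows: Dict[str, str]
    records: Dict[str, ExonRecord]
    codon_index: Dict[str, List[Optional[int]]]
    score: Optional[float] = None

    @property
    def n_columns(self) -> int:
        return len(self.protein_rows[self.members[0]])

    def validate(self) -> None:
        n = self.n_columns
        for m in self.members:
            prow, nrow = self.protein_rows[m], self.nucleotide_rows[m]
            assert len(prow) == n, "protein rows unequal length"
            assert len(nrow) == 3 * n, "nucleotide row not 3x protein row"
            degapped_nt = nrow.replace("-", "")
            degapped_aa = prow.replace("-", "")
            assert translate(degapped_nt, 0) == degapped_aa, \
                f"round-trip translation failed for {m}"

    def codon_at(self, member: str, column: int) -> str:
        return self.nucleotide_rows[member][3 * column: 3 * column + 3]

    def aa_at(self, member: str, column: int) -> str:
        return self.protein_rows[member][column]

    def nt_column(self, member: str, exon_nt_pos: int) -> int:
        """Nucleotide-alignment column holding the member's exon nt position.

        Positions inside the leading partial codon (``< phase``) or past the
        last complete codon are outside the aligned region and raise.
        """
        rec = self.records[member]
        k = (exon_nt_pos - rec.phase) // 3
        if exon_nt_pos < rec.phase or k >= rec.n_codons:
            raise ValueError(
                f"exon position {exon_nt_pos} of {member} lies outside the "
                "aligned complete-codon region"
            )
        offset = (exon_nt_pos - rec.phase) % 3
        col = self._column_of_codon(member, k)
        return 3 * col + offset

    def _column_of_codon(self, member: str, k: int) -> int:
        for col, idx in enumerate(self.codon_index[member]):
            if idx == k:
                return col
        raise ValueError(f"codon {k} of {member} not present in alignment")


def _default_aligner(sub_matrix=None, gap_open: float = -10.0,
                     gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        sub_matrix if sub_matrix is not None
        else substitution_matrices.load("BLOSUM62")
    )
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _backthread(record: ExonRecord, gapped_protein: str) -> Tuple[str, List[Optional[int]]]:
    codons: List[str] = [record.codon(k) for k in range(record.n_codons)]
    nt_row: List[str] = []
    codon_index: List[Optional[int]] = []
    k = 0
    for aa in gapped_protein:
        if aa == "-":
            nt_row.append(GAP_CODON)
            codon_index.append(None)
        else:
            nt_row.append(codons[k])
            codon_index.append(k)
            k += 1
    return "".join(nt_row), codon_index


def align_pair(a: ExonRecord, b: ExonRecord, sub_matrix=None,
               gap_open: float = -10.0, gap_extend: float = -0.5) -> CodonAlignment:
    """Global protein alignment of two exon records, codons back-threaded."""
    prot_a, prot_b = a.protein, b.protein
    if not prot_a or not prot_b:
        raise ValueError("empty translation; records must be translatable")
    aligner = _default_aligner(sub_matrix, gap_open, gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    nt_a, ci_a = _backthread(a, row_a)
    nt_b, ci_b = _backthread(b, row_b)
    out = CodonAlignment(
        members=[a.seq_id, b.seq_id],
        protein_rows={a.seq_id: row_a, b.seq_id: row_b},
        nucleotide_rows={a.seq_id: nt_a, b.seq_id: nt_b},
        records={a.seq_id: a, b.seq_id: b},
        codon_index={a.seq_id: ci_a, b.seq_id: ci_b},
        score=float(aln.score),
    )
    out.validate()
    return out


def align_family(records: List[ExonRecord], sub_matrix=None,
                 gap_open: float = -10.0, gap_extend: float = -0.5) -> CodonAlignment:
    """Progressive multiple alignment of >= 2 members against the first.

    Each member is pairwise-aligned to the anchor (first record) and the
    pairwise alignments are merged on anchor residues, inserting extra columns
    where members carry insertions relative to the anchor.  Adequate for the
    highly similar (>= 90% identity) families this screen targets; not a
    general multiple aligner.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    anchor = records[0]
    n_anchor = anchor.n_codons
    # per member: aligned residue index per anchor residue, and insertions
    matched: Dict[str, List[Optional[int]]] = {}
    inserts: Dict[str, List[List[int]]] = {}  # slot i = before anchor residue i
    for rec in records[1:]:
        pair = align_pair(anchor, rec, sub_matrix, gap_open, gap_extend)
        ca, cm = pair.codon_index[anchor.seq_id], pair.codon_index[rec.seq_id]
        match: List[Optional[int]] = [None] * n_anchor
        ins: List[List[int]] = [[] for _ in range(n_anchor + 1)]
        slot = 0
        for col in range(pair.n_columns):
            ka, km = ca[col], cm[col]
            if ka is not None:
                if km is not None:
                    match[ka] = km
                slot = ka + 1
            elif km is not None:
                ins[slot].append(km)
        matched[rec.seq_id] = match
        inserts[rec.seq_id] = ins

    member_ids = [r.seq_id for r in records]
    columns: List[Dict[str, Optional[int]]] = []
    for i in range(n_anchor + 1):
        width = max((len(inserts[m][i]) for m in member_ids[1:]), default=0)
        for j in range(width):
            col = {m: None for m in member_ids}
            for m in member_ids[1:]:
                block = inserts[m][i]
                if j < len(block):
                    col[m] = block[j]
            columns.append(col)
        if i < n_anchor:
            col = {anchor.seq_id: i}
            for m in member_ids[1:]:
                col[m] = matched[m][i]
            columns.append(col)

    protein_rows, nucleotide_rows, codon_index = {}, {}, {}
    recs = {r.seq_id: r for r in records}
    for m in member_ids:
        prow, nrow, ci = [], [], []
        prot = recs[m].protein
        for col in columns:
            k = col.get(m)
            if k is None:
                prow.append("-")
                nrow.append(GAP_CODON)
                ci.append(None)
            else:
                prow.append(prot[k])
                nrow.append(recs[m].codon(k))
                ci.append(k)
        protein_rows[m] = "".join(prow)
        nucleotide_rows[m] = "".join(nrow)
        codon_index[m] = ci
    out = CodonAlignment(member_ids, protein_rows, nucleotide_rows, recs,
                         codon_index)
    out.validate()
    return out


@dataclass(frozen=True)
class ColumnDiff:
    """One alignment column where two members' codons differ."""

    column: int
    kind: str  # synonymous | nonsynonymous | gap
    aa_i: str
    aa_j: str
    codon_i: str
    codon_j: str


def diff_columns(alignment: CodonAlignment, i: str, j: str) -> List[ColumnDiff]:
    """Columns whose codons differ between members ``i`` and ``j``.

    ``nonsynonymous`` iff the amino acids differ, ``synonymous`` iff the codons
    differ but the amino acids agree, ``gap`` if exactly one member is gapped.
    """
    for m in (i, j):
        if m not in alignment.protein_rows:
            raise ValueError(f"unknown member {m!r}")
    out: List[ColumnDiff] = []
    for col in range(alignment.n_columns):
        ci, cj = alignment.codon_at(i, col), alignment.codon_at(j, col)
        if ci == cj:
            continue
        ai, aj = alignment.aa_at(i, col), alignment.aa_at(j, col)
        if ai == "-" or aj == "-":
            kind = "gap"
        elif ai != aj:
            kind = "nonsynonymous"
        else:
            kind = "synonymous"
        out.append(ColumnDiff(col, kind, ai, aj, ci, cj))
    return out
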