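"""Shared file I/O: FASTA, newick, PWM/hexamer tables, BED/TSV reports.

Conventions: BED outputs are 0-based half-open per the BED standard; report
TSVs are 1-based inclusive with explicit column names.  All TSV outputs carry
a commented provenance header (tool version + parameter echo).  FASTA
sequences are uppercased with U normalised to T; gap characters are preserved
so alignment files round-trip.
"""

from __future__ import annotations

import io as _io
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

import splicescreen
from splicescreen.motifs import HexamerSet, MotifHit, Pwm


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[Tuple[str, str]]:
    """Order-preserving (id, sequence) pairs; duplicate ids are an error."""
    out: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return out


def write_fasta(path, records: Sequence[Tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# newick

def read_newick(path_or_string, auto_label: bool = True) -> dendropy.Tree:
    """Parse a newick tree keeping internal-node labels.

    Unlabelled internal nodes get deterministic preorder labels N1..Nk when
    ``auto_label`` is set.
    """
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=path_or_string, schema="newick",
                                 suppress_internal_node_taxa=False)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema="newick",
                                 suppress_internal_node_taxa=False)
    if auto_label:
        k = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            has_label = (node.taxon is not None and node.taxon.label) or node.label
            if not has_label:
                k += 1
                node.label = f"N{k}"
    return tree


def write_newick(path, tree: dendropy.Tree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def node_labels(tree: dendropy.Tree) -> List[str]:
    out = []
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.taxon.label:
            out.append(node.taxon.label.replace(" ", "_"))
        elif node.label:
            out.append(node.label)
    return out


# ---------------------------------------------------------------------------
# motif files

def read_pwm(path, threshold_frac: Optional[float] = 0.9) -> Pwm:
    """PWM TSV: header ``# name=<id> alphabet=ACGT``, one row per position
    with 4 tab-separated reals (A, C, G, T)."""
    name = None
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("name="):
                        name = tok[5:]
                    elif tok.startswith("alphabet=") and tok[9:] != "ACGT":
                        raise ValueError(f"{path}:{lineno}: unsupported alphabet")
                continue
            vals = line.split("\t")
            if len(vals) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated values, got {len(vals)}"
                )
            rows.append([float(v) for v in vals])
    if name is None:
        name = str(path)
    return Pwm(name=name, matrix=np.array(rows), threshold_frac=threshold_frac)


def write_pwm(path, pwm: Pwm) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={pwm.name} alphabet=ACGT\n")
        for row in pwm.matrix:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_hexamers(path, name: Optional[str] = None, silencer: bool = False) -> HexamerSet:
    """Hexamer TSV: ``hexamer<TAB>score`` with the score column optional."""
    members = set()
    scores: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("name=") and name is None:
                        name = tok[5:]
                continue
            parts = line.split("\t")
            hexamer = parts[0].strip().upper()
            members.add(hexamer)
            if len(parts) > 1 and parts[1].strip():
                scores[hexamer] = float(parts[1].replace(",", "."))
    if name is None:
        name = str(path)
    return HexamerSet(name=name, members=members,
                      scores=scores or None, silencer=silencer)


def write_hexamers(path, hexset: HexamerSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={hexset.name}\n")
        for m in sorted(hexset.members):
            if hexset.scores and m in hexset.scores:
                fh.write(f"{m}\t{hexset.scores[m]!r}\n")
            else:
                fh.write(f"{m}\n")


# ---------------------------------------------------------------------------
# outputs

def provenance_header(params: Optional[dict] = None) -> str:
    parts = [f"# splicescreen v{splicescreen.__version__}"]
    if params:
        echo = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        parts.append(f"# params: {echo}")
    return "\n".join(parts) + "\n"


def write_hits_bed(path, hits: Sequence[MotifHit],
                   params: Optional[dict] = None) -> None:
    """BED6: chrom=seq_id, 0-based half-open interval, name=motif, score, +."""
    with open(path, "w") as fh:
        fh.write(provenance_header(params))
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_name}\t"
                     f"{h.score:.4f}\t+\n")


def write_hits_tsv(path, hits: Sequence[MotifHit],
                   params: Optional[dict] = None) -> None:
    """TSV report, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(provenance_header(params))
        fh.write("seq_id\tstart_1based\tend_1based\tmotif\tscore\tkind\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.start + 1}\t{h.end}\t{h.motif_name}\t"
                     f"{h.score:.4f}\t{h.kind}\n")


def write_tsv(path, df: pd.DataFrame, params: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(params))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# tabular inputs

def read_exon_descriptors(path, sequences: Dict[str, str]):
    """Exon descriptor TSV -> ExonRecords.

    Columns: seq_id, exon_start, exon_end (1-based inclusive within the FASTA
    record), phase.  Flanks are whatever of the record lies outside the exon.
    """
    from splicescreen.codon_align import ExonRecord

    df = read_tsv(path)
    required = {"seq_id", "exon_start", "exon_end", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exon descriptor missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        seq = sequences.get(row.seq_id)
        if seq is None:
            raise ValueError(f"descriptor names unknown sequence {row.seq_id!r}")
        start, end = int(row.exon_start) - 1, int(row.exon_end)
        if not 0 <= start < end <= len(seq):
            raise ValueError(f"exon interval out of range for {row.seq_id!r}")
        records.append(ExonRecord(
            seq_id=row.seq_id,
            exon_seq=seq[start:end],
            upstream_flank=seq[:start],
            downstream_flank=seq[end:],
            phase=int(row.phase),
        ))
    return records


def read_velocity_tsv(path):
    """Kinetics TSV (enzyme, S_mM, v_uM_per_s, replicate) -> VelocityDatasets.

    Decimal commas and dots are both accepted on input; output always uses
    dots.
    """
    from splicescreen.kinetics import VelocityDataset

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"enzyme", "S_mM", "v_uM_per_s", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"velocity table missing columns: {sorted(missing)}")
    out: Dict[str, List] = {}
    for row in df.itertuples(index=False):
        S = float(str(row.S_mM).replace(",", "."))
        v = float(str(row.v_uM_per_s).replace(",", "."))
        out.setdefault(row.enzyme, []).append((S, v, int(row.replicate)))
    return [VelocityDataset(enzyme=e, points=pts) for e, pts in out.items()]


# ---------------------------------------------------------------------------
# packaged motif fixtures (synthetic stand-ins, see data/README note in docs)

def load_packaged_pwms(threshold_frac: float = 0.9) -> List[Pwm]:
    """The four packaged SR-protein-style PWMs (synthetic stand-ins)."""
    from importlib.resources import files

    out = []
    data = files("splicescreen") / "data"
    for name in sorted(p.name for p in data.iterdir()
                       if p.name.startswith("sr_pwm_") and p.name.endswith(".tsv")):
        out.append(read_pwm(data / name, threshold_frac=threshold_frac))
    return out


def load_packaged_hexamers(which: str = "ese") -> HexamerSet:
    """Packaged hexamer sets: 'ese' (238-member enhancer stand-in) or 'ess'
    (scored silencer stand-in)."""
    from importlib.resources import files

    data = files("splicescreen") / "data"
    if which == "ese":
        return read_hexamers(data / "rescue_ese_synthetic.tsv", name="rescue_ese")
    if which == "ess":
        return read_hexamers(data / "fas_hex3_synthetic.tsv", name="fas_hex3",
                             silencer=True)
    raise ValueError("which must be 'ese' or 'ess'")
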