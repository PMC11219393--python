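"""Standard-format I/O: FASTA (IUPAC-safe), Newick, headered TSV, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import HaplotypePair
from .phylo import Alignment


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta",
    )


def read_haplotype_pairs(path) -> list[HaplotypePair]:
    """Read haplotype FASTA with headers ``gene|H1`` / ``gene|H2``."""
    seqs = read_fasta(path)
    genes: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        parts = name.split("|")
        if len(parts) < 2 or parts[-1] not in ("H1", "H2"):
            raise ValueError(f"header {name!r} is not of the form gene|H1 or gene|H2")
        genes.setdefault("|".join(parts[:-1]), {})[parts[-1]] = seq
    pairs = []
    for gene, alleles in genes.items():
        if set(alleles) != {"H1", "H2"}:
            raise ValueError(f"gene {gene!r} is missing one haplotype record")
        pairs.append(HaplotypePair(gene_id=gene, h1=alleles["H1"], h2=alleles["H2"]))
    return pairs


def read_alignment(path) -> Alignment:
    seqs = read_fasta(path)
    return Alignment(names=list(seqs), seqs=list(seqs.values()))


def read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
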