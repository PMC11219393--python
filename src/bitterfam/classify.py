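"""Intact/disrupted classification of bitter-receptor coding sequences.

A TAS2R gene is an intronless ~900 bp coding unit for a seven-transmembrane
(7-TM) G-protein-coupled receptor. A sequence is called *intact* only when it
(i) carries an open reading frame of at least 750 bp (>= 250 codons, start
codon through the last sense codon) and (ii) its translation supports a 7-TM
architecture under a deterministic Kyte-Doolittle hydropathy scan. Anything
failing either test is *disrupted*.

Haplotype pairs coming out of the capture caller may carry two-fold IUPAC
degenerate codes at SNP sites whose phase could not be determined. Rather than
enumerating every combination across degenerate sites, the two "aligned"
resolutions are tested: alphabetically-first nucleotides throughout one
haplotype and alphabetically-second throughout the other, and the swap.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

# Two-fold degenerate IUPAC nucleotide codes (biallelic SNP codes).
TWOFOLD = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
MULTIFOLD = set("BDHVN")

# Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SequenceVerdict:
    """Outcome of the intactness tests for one resolved sequence."""

    orf_length: int
    tm_count: int
    status: str  # "intact" | "disrupted"


@dataclass(frozen=True)
class HaplotypePair:
    gene_id: str
    h1: str
    h2: str


@dataclass(frozen=True)
class ResolvedQuartet:
    h1_1: str
    h2_1: str
    h1_2: str
    h2_2: str


@dataclass(frozen=True)
class GeneStatusRecord:
    gene_id: str
    locus_call: str
    category: int | None
    status: str  # intact | disrupted | segregating_pseudogene | intact_and_disrupted


def max_orf_length(nt_seq: str) -> int:
    """Length in bp of the longest forward-strand ORF.

    An ORF is an ATG-initiated, in-frame, stop-terminated run; its length
    counts the start codon through the last sense codon (the stop codon is
    excluded), so 250 codons correspond to 750 bp. All three forward frames
    are scanned. Degenerate codes must be resolved first.
    """
    seq = nt_seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"degenerate/unknown codes present ({sorted(bad)}); resolve before ORF scan"
        )
    best = 0
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for idx, codon in enumerate(codons):
            if start is None:
                if codon == "ATG":
                    start = idx
            elif codon in STOPS:
                best = max(best, 3 * (idx - start))
                start = None
                # an ATG inside the ORF cannot start a longer ORF in this
                # frame, so resuming the scan after the stop is exhaustive
        # an unterminated run is not stop-terminated and does not count
    return best


def count_tm_segments(
    aa_seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 3,
) -> int:
    """Number of membrane-spanning segments from a hydropathy scan.

    A sliding window of ``window`` residues is averaged over the Kyte-
    Doolittle index; maximal runs of window positions exceeding ``threshold``
    are candidate transmembrane segments, and runs separated by fewer than
    ``min_gap`` sub-threshold positions are merged. Deterministic stand-in
    for a neural topology predictor, with declared constants.
    """
    seq = aa_seq.upper().rstrip("*")
    if len(seq) < window:
        return 0
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq]
    # direct per-window sums: no accumulator drift near the threshold
    above = [
        sum(vals[i : i + window]) / window > threshold
        for i in range(len(vals) - window + 1)
    ]
    # collapse to runs, merging short gaps
    segments = 0
    in_seg = False
    gap = 0
    for flag in above:
        if flag:
            if not in_seg:
                if segments and gap < min_gap:
                    segments -= 1  # continuation of the previous segment
                segments += 1
                in_seg = True
        else:
            if in_seg:
                gap = 0
                in_seg = False
            gap += 1
    return segments


def resolve_degenerate(pair: HaplotypePair) -> ResolvedQuartet:
    """Resolve two-fold IUPAC codes into the two tested haplotype pairs.

    At every degenerate site, H1-1/H2-1 carry the alphabetically first/second
    encoded nucleotide and H1-2/H2-2 the opposite assignment. Exactly two
    resolved pairs are produced however many degenerate sites there are.
    Three- and four-fold codes are rejected.
    """
    for label, seq in (("H1", pair.h1), ("H2", pair.h2)):
        hit = set(seq.upper()) & MULTIFOLD
        if hit:
            raise ValueError(
                f"{pair.gene_id} {label}: codes {sorted(hit)} are not biallelic "
                "SNP codes; only two-fold IUPAC codes can be phase-resolved"
            )

    def first(seq: str) -> str:
        return "".join(TWOFOLD[c][0] if c in TWOFOLD else c for c in seq.upper())

    def second(seq: str) -> str:
        return "".join(TWOFOLD[c][1] if c in TWOFOLD else c for c in seq.upper())

    return ResolvedQuartet(
        h1_1=first(pair.h1),
        h2_1=second(pair.h2),
        h1_2=second(pair.h1),
        h2_2=first(pair.h2),
    )


def classify_sequence(
    nt_seq: str,
    min_orf: int = 750,
    tm_required: int = 7,
    tm_at_least: bool = False,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 3,
) -> SequenceVerdict:
    """Apply the ORF and 7-TM tests to one unambiguous nucleotide sequence."""
    orf = max_orf_length(nt_seq)
    tm = 0
    if orf > 0:
        aa = str(Seq(_best_orf(nt_seq)).translate())
        tm = count_tm_segments(aa, window=window, threshold=threshold, min_gap=min_gap)
    tm_ok = tm >= tm_required if tm_at_least else tm == tm_required
    status = "intact" if (orf >= min_orf and tm_ok) else "disrupted"
    return SequenceVerdict(orf_length=orf, tm_count=tm, status=status)


def _best_orf(nt_seq: str) -> str:
    seq = nt_seq.upper()
    best = ""
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        start = None
        for idx, codon in enumerate(codons):
            if start is None:
                if codon == "ATG":
                    start = idx
            elif codon in STOPS:
                cand = "".join(codons[start:idx])
                if len(cand) > len(best):
                    best = cand
                start = None
    return best


def gene_status(
    verdicts: list[SequenceVerdict],
    locus_call: str,
    category: int | None = None,
    gene_id: str = "",
) -> GeneStatusRecord:
    """Combine per-sequence verdicts into a gene-level status.

    All intact -> intact; all disrupted -> disrupted. A mixture means either a
    segregating pseudogene (single-locus genes: one intact and one disrupted
    allele) or an unresolvable intact-and-disrupted congregate (category 1, 3
    or 4 loci, where allelic and paralogous reads are mixed).
    """
    if not verdicts:
        raise ValueError("gene_status requires at least one sequence verdict")
    states = {v.status for v in verdicts}
    if states == {"intact"}:
        status = "intact"
    elif states == {"disrupted"}:
        status = "disrupted"
    elif category in (1, 3, 4):
        status = "intact_and_disrupted"
    else:
        status = "segregating_pseudogene"
    return GeneStatusRecord(gene_id=gene_id, locus_call=locus_call, category=category, status=status)


def classify_gene(
    pair: HaplotypePair,
    locus_call: str = "single_locus",
    category: int | None = None,
    **kwargs,
) -> tuple[GeneStatusRecord, list[SequenceVerdict]]:
    """Resolve a haplotype pair and classify the gene.

    When no degenerate sites are present only H1 is tested if the alleles are
    identical, or H1 and H2 if they differ; otherwise all four resolved
    sequences (H1-1, H2-1, H1-2, H2-2) are tested.
    """
    has_degenerate = bool(set(pair.h1.upper() + pair.h2.upper()) & set(TWOFOLD))
    quartet = resolve_degenerate(pair)
    if not has_degenerate:
        seqs = [quartet.h1_1] if pair.h1.upper() == pair.h2.upper() else [quartet.h1_1, quartet.h2_1]
    else:
        seqs = [quartet.h1_1, quartet.h2_1, quartet.h1_2, quartet.h2_2]
    verdicts = [classify_sequence(s, **kwargs) for s in seqs]
    return gene_status(verdicts, locus_call, category, gene_id=pair.gene_id), verdicts
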