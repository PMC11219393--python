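"""Depth/SNP-density locus calling for targeted-capture gene families.

Reproduces the decision logic of the iterative mapping rounds used to resolve
paralogous bitter-receptor loci from capture summaries:

* round 2 - absence screen: mean per-site depth below 10 reads means the locus
  is not in the sample;
* round 3 - boxplot screens: loci far below the depth distribution of their
  class are possibly absent, short mappings are dropped, and loci whose depth
  or SNP density rises above the upper whisker become duplication candidates;
* rounds 4/5 - candidate resolution: candidates whose two assembled haplotypes
  share reads over more than ~10% of their length stay congregated (category
  1); otherwise the haplotypes are split into "-1"/"-2" daughter loci and
  re-screened, yielding separated single loci (category 2), still-congregated
  daughters (category 3) or SNP-only outliers whose copy number is left
  undecided (category 4).

Quartiles follow the median-inclusive Tukey-hinge convention and whiskers are
the most extreme data points within 1.5 IQR of the hinges (not the fences
themselves). All threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ABSENT_DEPTH = 10.0
SHORT_GENE_BP = 750
SHORT_NR_BP = 1000
LOW_DEPTH_FACTOR = 0.5
HIGH_DEPTH_FACTOR = 1.5
SHARED_THRESHOLD = 0.10


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    n: int


@dataclass(frozen=True)
class CaptureRecord:
    """Per-locus summary of a capture emission (one mapping-round snapshot)."""

    locus_id: str
    kind: str  # "gene" | "NR-A" | "NR-X"
    mapped_length: int
    mean_depth: float
    snp_sites: int

    @property
    def snp_density(self) -> float:
        return snp_density(self.snp_sites, self.mapped_length)


@dataclass(frozen=True)
class SplitCandidate:
    """A capture record together with what a further mapping round would see.

    ``h1``/``h2`` are the two assembled haplotype sequences of the locus,
    ``shared_fraction`` the fraction of read-length windows over which they
    are identical (the computable surrogate for reads mapping to both), and
    ``children`` the post-split records for the "-1"/"-2" daughters.
    """

    record: CaptureRecord
    h1: str | None = None
    h2: str | None = None
    shared_fraction: float | None = None
    children: tuple["SplitCandidate", ...] = ()


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    call: str  # absent|single_locus|duplicated_congregated|split_single_locus|high_snp_only
    category: int | None
    round_decided: int
    children: tuple[str, ...] = ()


@dataclass
class CallReport:
    calls: list[LocusCall] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    boxplots: dict = field(default_factory=dict)


def boxplot_stats(values) -> BoxplotSummary:
    """Median-inclusive Tukey-hinge five-number summary with data whiskers.

    For odd n the median element is included in both halves when computing
    the hinges. The whiskers are the most extreme observed values within
    [q1 - 1.5 IQR, q3 + 1.5 IQR].
    """
    data = np.sort(np.asarray(values, dtype=float))
    n = data.size
    if n == 0:
        raise ValueError("boxplot_stats requires at least one value")
    med = float(np.median(data))
    half = (n + 1) // 2  # median element included in both halves for odd n
    q1 = float(np.median(data[:half]))
    q3 = float(np.median(data[n - half:]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = data[(data >= lo_fence) & (data <= hi_fence)]
    # hinges are data medians, so at least the hinge region is inside the fences
    return BoxplotSummary(
        q1=q1, median=med, q3=q3, iqr=iqr,
        lower_whisker=float(inside.min()), upper_whisker=float(inside.max()), n=n,
    )


def snp_density(snp_sites: int, mapped_length: int) -> float:
    """SNP sites (indels excluded) per 1000 bp of mapped sequence."""
    if mapped_length <= 0:
        raise ValueError("mapped_length must be positive")
    if snp_sites < 0:
        raise ValueError("snp_sites must be non-negative")
    return 1000.0 * snp_sites / mapped_length


def screen_absent_round2(per_site_depth) -> str:
    """Round-2 absence screen: mean per-site depth < 10 means absent."""
    depth = np.asarray(per_site_depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    return "absent" if float(depth.mean()) < ABSENT_DEPTH else "retained"


def screen_round3(
    records: list[CaptureRecord],
    gene_depth_boxplot: BoxplotSummary,
    nr_a_depth_boxplot: BoxplotSummary,
) -> list[tuple[str, str]]:
    """Round-3 exclusion screen; returns (locus_id, reason) pairs.

    Genes are possibly absent when their depth falls below half the lower
    whisker of the per-species gene-depth boxplot or their mapping is shorter
    than 750 bp. Neutral references shorter than 1 kb are dropped, and
    autosomal neutral references with depth above 1.5x the upper whisker of
    the NR-A boxplot are excluded as potentially duplicated.
    """
    out: list[tuple[str, str]] = []
    for rec in records:
        if rec.kind == "gene":
            if rec.mapped_length < SHORT_GENE_BP:
                out.append((rec.locus_id, "short"))
            elif rec.mean_depth < LOW_DEPTH_FACTOR * gene_depth_boxplot.lower_whisker:
                out.append((rec.locus_id, "possibly_absent"))
        elif rec.kind in ("NR-A", "NR-X"):
            if rec.mapped_length < SHORT_NR_BP:
                out.append((rec.locus_id, "short"))
            elif rec.kind == "NR-A" and rec.mean_depth > HIGH_DEPTH_FACTOR * nr_a_depth_boxplot.upper_whisker:
                out.append((rec.locus_id, "duplicated"))
        else:
            raise ValueError(f"unknown locus kind {rec.kind!r} for {rec.locus_id}")
    return out


def flag_duplication_candidates(
    records: list[CaptureRecord],
    depth_boxplot: BoxplotSummary,
    snp_boxplot: BoxplotSummary,
) -> dict[str, str]:
    """Flag genes whose depth or SNP density exceeds the upper whisker.

    Returns ``single_locus`` (neither exceeds, strictly-above rule),
    ``candidate`` (depth above, duplication suspected) or ``high_snp_only``
    (SNP density above but depth not; routed toward category 4).
    """
    flags: dict[str, str] = {}
    for rec in records:
        depth_hi = rec.mean_depth > depth_boxplot.upper_whisker
        snp_hi = rec.snp_density > snp_boxplot.upper_whisker
        if depth_hi:
            flags[rec.locus_id] = "candidate"
        elif snp_hi:
            flags[rec.locus_id] = "high_snp_only"
        else:
            flags[rec.locus_id] = "single_locus"
    return flags


def resolve_candidate(
    candidate: SplitCandidate,
    depth_upper_whisker: float,
    snp_upper_whisker: float,
    shared_threshold: float = SHARED_THRESHOLD,
) -> list[LocusCall]:
    """Rounds 4/5: resolve a duplication candidate into categories 1-4.

    A shared-haplotype fraction above ``shared_threshold`` means allelic and
    paralogous reads cannot be separated: the congregated locus is category 1
    (decided at round 4). Otherwise the two haplotypes become "-1"/"-2"
    daughter loci and are re-screened: daughters inside both whiskers are
    separated single loci (source gene category 2); a daughter whose depth is
    again above the whisker survives one more split attempt and ends
    congregated as category 3 (round 5); a daughter with only a SNP-density
    excess is category 4 (copy number left undecided).
    """
    rec = candidate.record
    if candidate.h1 is None or candidate.h2 is None:
        raise ValueError(f"{rec.locus_id}: haplotype sequences required to resolve a candidate")
    if candidate.shared_fraction is None:
        shared = shared_window_fraction(candidate.h1, candidate.h2)
    else:
        shared = candidate.shared_fraction

    if shared > shared_threshold:
        return [LocusCall(rec.locus_id, "duplicated_congregated", 1, 4)]

    if len(candidate.children) != 2:
        raise ValueError(f"{rec.locus_id}: post-split records for both daughters are required")
    child_ids = tuple(c.record.locus_id for c in candidate.children)
    calls = [LocusCall(rec.locus_id, "split_single_locus", 2, 4, children=child_ids)]
    for child in candidate.children:
        crec = child.record
        depth_hi = crec.mean_depth > depth_upper_whisker
        snp_hi = crec.snp_density > snp_upper_whisker
        if depth_hi:
            # round-5 split attempt: these invariably end congregated
            calls.append(LocusCall(crec.locus_id, "duplicated_congregated", 3, 5))
        elif snp_hi:
            calls.append(LocusCall(crec.locus_id, "high_snp_only", 4, 4))
        else:
            calls.append(LocusCall(crec.locus_id, "single_locus", None, 4))
    return calls


def shared_window_fraction(h1: str, h2: str, read_len: int = 150) -> float:
    """Fraction of read-length windows over which two sequences are identical.

    Surrogate for the proportion of a reference over which the same reads map
    to both haplotypes: within a window shorter than a read, identical
    paralogs are indistinguishable to a read mapper.
    """
    n = min(len(h1), len(h2))
    if n < read_len:
        return 1.0 if h1[:n] == h2[:n] else 0.0
    starts = range(0, n - read_len + 1)
    same = sum(1 for s in starts if h1[s : s + read_len] == h2[s : s + read_len])
    return same / len(starts)


def call_loci(
    candidates: list[SplitCandidate],
    shared_threshold: float = SHARED_THRESHOLD,
) -> CallReport:
    """Run the full round-2-to-5 decision chain over one species' emission.

    ``candidates`` carries one entry per emitted locus (genes and neutral
    references); entries for genes that may need splitting should carry
    haplotypes, shared fractions and post-split daughter records.
    """
    report = CallReport()

    retained: list[SplitCandidate] = []
    for cand in candidates:
        if cand.record.mean_depth < ABSENT_DEPTH:
            report.calls.append(LocusCall(cand.record.locus_id, "absent", None, 2))
        else:
            retained.append(cand)

    genes = [c.record for c in retained if c.record.kind == "gene"]
    nr_a = [c.record for c in retained if c.record.kind == "NR-A"]
    if not genes:
        return report
    gene_bp = boxplot_stats([r.mean_depth for r in genes])
    nr_bp = boxplot_stats([r.mean_depth for r in nr_a]) if nr_a else gene_bp
    excluded = dict(screen_round3([c.record for c in retained], gene_bp, nr_bp))
    report.exclusions = sorted(excluded.items())
    kept = [c for c in retained if c.record.locus_id not in excluded]

    gene_cands = [c for c in kept if c.record.kind == "gene"]
    depth_bp = boxplot_stats([c.record.mean_depth for c in gene_cands])
    snp_bp = boxplot_stats([c.record.snp_density for c in gene_cands])
    report.boxplots = {"gene_depth": depth_bp, "gene_snp": snp_bp, "nr_a_depth": nr_bp}

    flags = flag_duplication_candidates([c.record for c in gene_cands], depth_bp, snp_bp)
    for cand in gene_cands:
        flag = flags[cand.record.locus_id]
        if flag == "single_locus":
            report.calls.append(LocusCall(cand.record.locus_id, "single_locus", None, 3))
        elif flag == "high_snp_only":
            report.calls.append(LocusCall(cand.record.locus_id, "high_snp_only", 4, 3))
        else:
            report.calls.extend(
                resolve_candidate(
                    cand, depth_bp.upper_whisker, snp_bp.upper_whisker, shared_threshold
                )
            )
    return report
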