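"""Forward simulation of a diploid gene family along a species tree.

The generator produces everything the downstream stages consume, so the whole
inference chain is exercisable without external data:

* a gene-family history - duplications (births), disruptive mutations
  (premature stops / frameshifts), physical losses and gene-conversion
  homogenization events drawn as a Gillespie process per branch;
* per-leaf diploid repertoires - each surviving gene carries two allele
  sequences; a disruption that arose on a terminal branch may be heterozygous
  (a segregating pseudogene);
* capture-style emissions - per-site depth with Gamma-Poisson (negative
  binomial) noise whose mean scales with copy number and ploidy, SNP counts,
  and a shared-window fraction for paralog pairs that a short-read mapper
  could not separate. Neutral reference loci (autosomal NR-A and
  X-chromosomal NR-X) calibrate ploidy and the neutral SNP density.

Intact genes evolve under purifying rejection: proposed substitutions that
destroy the >=750 bp open reading frame or the seven-transmembrane
architecture are discarded, which is what keeps a simulated intact gene
classifiable as intact under the downstream tests.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import classify
from .caller import CaptureRecord, SplitCandidate, shared_window_fraction
from .sptree import Node, SpeciesTree

NUC = "ACGT"
_IDX = {c: i for i, c in enumerate(NUC)}

# codon choices per amino acid, stop codons excluded
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "L": ["CTT", "CTC", "CTG", "TTA"],
    "K": ["AAA", "AAG"], "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA"],
    "S": ["TCT", "TCC", "AGC"], "T": ["ACT", "ACC", "ACA"], "W": ["TGG"],
    "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTG"],
}
_HYDROPHOBIC = "LIVFA"
_LOOP = "KEQNSTRDG"


@dataclass(frozen=True)
class TN93Params:
    """Substitution process: overall rate plus TN93 exchangeabilities."""

    rate: float = 0.005          # substitutions / site / time unit (neutral)
    alpha_ag: float = 2.0        # purine transition weight
    alpha_ct: float = 2.0        # pyrimidine transition weight
    beta: float = 1.0            # transversion weight
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SimulationConfig:
    birth_rate: float = 0.0          # duplications / gene / time unit
    disruption_rate: float = 0.0     # disruptive mutations / gene / time unit
    loss_rate: float = 0.0           # physical losses / gene / time unit
    conversion_rate: float = 0.0     # homogenizations / duplicate pair / time unit
    root_repertoire_size: int = 32
    subst_params: TN93Params = field(default_factory=TN93Params)
    gene_rate_multiplier: float = 0.5  # genes evolve slower than neutral refs
    heterozygosity: float = 0.002      # het SNPs / site at neutral loci
    unphased_prob: float = 0.2         # het site emitted as IUPAC code
    disruption_mix: float = 0.5        # P(premature stop); else 1-bp frameshift
    seg_pseudo_prob: float = 0.5       # terminal-branch disruption heterozygous
    depth_mean: float = 1000.0         # per-site depth, diploid single-copy autosome
    depth_dispersion: float = 10.0     # Gamma shape; smaller = more overdispersed
    read_len: int = 150
    coding_length: int = 900           # multiple of 3, incl. stop codon
    flank: int = 100
    evolve_sequences: bool = True
    seed: int | None = None

    def __post_init__(self):
        for name in ("birth_rate", "disruption_rate", "loss_rate", "conversion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("disruption_mix", "seg_pseudo_prob", "unphased_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.coding_length % 3:
            raise ValueError("coding_length must be a codon multiple")
        if self.seed is None:
            raise ValueError("seed is mandatory; the simulator has no implicit entropy")


@dataclass(frozen=True)
class HistoryEvent:
    branch_id: str
    event_type: str  # birth | disruption | loss | conversion
    gene_id: str
    parent_gene_id: str | None = None


@dataclass
class TrueHistory:
    events: list[HistoryEvent] = field(default_factory=list)

    def by_type(self, event_type: str) -> list[HistoryEvent]:
        return [e for e in self.events if e.event_type == event_type]


@dataclass
class GeneCopy:
    gene_id: str
    h1: str | None
    h2: str | None
    state: str  # intact | disrupted | segregating
    family: str
    snp_positions: tuple[int, ...] = ()
    disruption_tag: str | None = None  # identifies the originating mutation


@dataclass
class GeneRepertoire:
    species: str
    genes: list[GeneCopy]

    def count(self, *states: str) -> int:
        return sum(1 for g in self.genes if g.state in states)


@dataclass
class LocusEmission:
    locus_id: str
    kind: str  # gene | NR-A | NR-X
    per_site_depth: np.ndarray
    snp_sites: int
    h1: str | None = None
    h2: str | None = None
    shared_fraction: float | None = None
    children: tuple["LocusEmission", ...] = ()
    true_copy_number: int = 1

    @property
    def mapped_length(self) -> int:
        return int(self.per_site_depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.per_site_depth.mean())

    def record(self) -> CaptureRecord:
        return CaptureRecord(
            locus_id=self.locus_id, kind=self.kind,
            mapped_length=self.mapped_length, mean_depth=self.mean_depth,
            snp_sites=self.snp_sites,
        )

    def split_candidate(self) -> SplitCandidate:
        return SplitCandidate(
            record=self.record(), h1=self.h1, h2=self.h2,
            shared_fraction=self.shared_fraction,
            children=tuple(c.split_candidate() for c in self.children),
        )


@dataclass
class CaptureEmission:
    species: str
    sex: str
    records: list[LocusEmission]

    def candidates(self) -> list[SplitCandidate]:
        return [r.split_candidate() for r in self.records]


# ---------------------------------------------------------------------------
# internal gene state carried down the tree


@dataclass
class _Gene:
    gene_id: str
    family: str
    seq: list[str] | None
    state: str = "intact"          # intact | disrupted
    disruption: tuple | None = None  # (tag, kind, position) once disrupted
    segregating: bool = False


def _build_intact_gene(rng: np.random.Generator, cfg: SimulationConfig) -> list[str]:
    """Construct a coding sequence with a guaranteed 7-TM, >=750 bp ORF."""
    n_aa = cfg.coding_length // 3 - 1  # minus stop codon
    protein = ["M"]
    tm_len, loop_len = 21, 12
    blocks = 0
    while len(protein) < n_aa:
        if blocks < 7 and len(protein) + tm_len <= n_aa - 2:
            protein.extend(rng.choice(list(_HYDROPHOBIC), size=tm_len))
            blocks += 1
            protein.extend(
                rng.choice(list(_LOOP), size=min(loop_len, max(0, n_aa - len(protein))))
            )
        else:
            protein.append(str(rng.choice(list(_LOOP))))
    protein = protein[:n_aa]
    coding = "".join(str(rng.choice(_CODONS[a])) for a in protein) + "TAA"
    flank5 = "".join(rng.choice(list(NUC), size=cfg.flank))
    flank3 = "".join(rng.choice(list(NUC), size=cfg.flank))
    seq = list(flank5 + coding + flank3)
    assert _coding_is_intact(seq, cfg), "constructed gene failed its own intactness test"
    return seq


def _coding_is_intact(seq: list[str], cfg: SimulationConfig) -> bool:
    nt = "".join(seq)
    if classify.max_orf_length(nt) < 750:
        return False
    verdict = classify.classify_sequence(nt)
    return verdict.status == "intact"


def _substitute(
    seq: list[str], rng: np.random.Generator, rate: float, t: float,
    params: TN93Params, purify: bool, cfg: SimulationConfig,
) -> list[int]:
    """Apply TN93 substitutions over time t; returns mutated positions."""
    L = len(seq)
    n = rng.poisson(rate * L * t)
    changed: list[int] = []
    weights = _tn93_target_weights(params)
    for _ in range(n):
        pos = int(rng.integers(0, L))
        cur = seq[pos]
        if cur not in _IDX:
            continue
        w = weights[_IDX[cur]]
        new = NUC[rng.choice(4, p=w)]
        if new == cur:
            continue
        old = seq[pos]
        seq[pos] = new
        if purify and not _coding_is_intact(seq, cfg):
            seq[pos] = old
            continue
        changed.append(pos)
    return changed


def _tn93_target_weights(params: TN93Params) -> np.ndarray:
    fa, fc, fg, ft = params.freqs
    a1, a2, b = params.alpha_ag, params.alpha_ct, params.beta
    raw = np.array([
        [0, b * fc, a1 * fg, b * ft],
        [b * fa, 0, b * fg, a2 * ft],
        [a1 * fa, b * fc, 0, b * ft],
        [b * fa, a2 * fc, b * fg, 0],
    ])
    return raw / raw.sum(axis=1, keepdims=True)


def _disrupt_sequence(
    seq: list[str], rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[str], str, int]:
    """Introduce a premature stop or a 1-bp frameshift; guarantees ORF < 750."""
    start = cfg.flank
    if rng.random() < cfg.disruption_mix:
        kind = "stop"
        for _ in range(50):
            codon = int(rng.integers(50, 220))
            pos = start + 3 * codon
            cand = seq[:pos] + list("TAA") + seq[pos + 3 :]
            if classify.max_orf_length("".join(cand)) < 750:
                return cand, kind, pos
        cand = seq[: start + 150] + list("TAA") + seq[start + 153 :]
        return cand, kind, start + 150
    kind = "frameshift"
    for _ in range(50):
        pos = start + int(rng.integers(90, 450))
        cand = seq[:pos] + seq[pos + 1 :]
        if classify.max_orf_length("".join(cand)) < 750:
            return cand, kind, pos
    cand = seq[: start + 100] + seq[start + 101 :]
    return cand, kind, start + 100


# ---------------------------------------------------------------------------
# history simulation


def simulate_history(
    tree: SpeciesTree, cfg: SimulationConfig
) -> tuple[TrueHistory, dict[str, GeneRepertoire]]:
    """Simulate a gene-family history and per-leaf diploid repertoires.

    Events are drawn per branch as a Gillespie process: duplications copy an
    intact gene (the copy acquires a ``-k`` suffixed identifier within its
    family), disruptions pseudogenize an intact gene (heterozygously with
    probability ``seg_pseudo_prob`` when on a terminal branch), losses remove
    an intact gene from all descendants, and conversions overwrite one intact
    duplicate's coding region with its partner's. Deterministic for a fixed
    seed.
    """
    root_ss = np.random.SeedSequence(cfg.seed)
    init_rng = np.random.default_rng(root_ss.spawn(1)[0])
    genes: list[_Gene] = []
    width = max(3, len(str(cfg.root_repertoire_size)))
    for i in range(cfg.root_repertoire_size):
        gid = f"g{i + 1:0{width}d}"
        seq = _build_intact_gene(init_rng, cfg) if cfg.evolve_sequences else None
        genes.append(_Gene(gene_id=gid, family=gid, seq=seq))

    history = TrueHistory()
    repertoires: dict[str, GeneRepertoire] = {}
    counter = {"event": 0, "copy": {}}

    def walk(node: Node, state: list[_Gene], ss: np.random.SeedSequence):
        child_seeds = ss.spawn(len(node.children) + 1)
        rng = np.random.default_rng(child_seeds[0])
        state = _run_branch(node, state, rng, cfg, history, counter)
        if node.is_leaf:
            repertoires[node.name] = _realize_leaf(node.name, state, rng, cfg)
        else:
            for child, child_ss in zip(node.children, child_seeds[1:]):
                walk(child, [_copy.deepcopy(g) for g in state], child_ss)

    root = tree.root
    root_seeds = root_ss.spawn(len(root.children) + 2)[1:]
    # the root stem (branch above the root) carries no simulated time here;
    # the process starts at the crown ancestor
    for child, child_ss in zip(root.children, root_seeds):
        walk(child, [_copy.deepcopy(g) for g in genes], child_ss)
    if root.is_leaf:  # degenerate single-species tree
        rng = np.random.default_rng(root_seeds[0])
        repertoires[root.name] = _realize_leaf(root.name, genes, rng, cfg)
    return history, repertoires


def _run_branch(
    node: Node, state: list[_Gene], rng: np.random.Generator,
    cfg: SimulationConfig, history: TrueHistory, counter: dict,
) -> list[_Gene]:
    t = 0.0
    length = node.length
    branch_id = node.branch_id or (node.name or "?")
    while True:
        intact = [g for g in state if g.state == "intact"]
        fams: dict[str, list[_Gene]] = {}
        for g in intact:
            fams.setdefault(g.family, []).append(g)
        n_pairs = sum(len(v) * (len(v) - 1) // 2 for v in fams.values())
        props = np.array([
            cfg.birth_rate * len(intact),
            cfg.disruption_rate * len(intact),
            cfg.loss_rate * len(intact),
            cfg.conversion_rate * n_pairs,
        ])
        total = props.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= length:
            break
        kind = int(rng.choice(4, p=props / total))
        if kind == 0:  # birth
            parent = intact[int(rng.integers(len(intact)))]
            k = counter["copy"].get(parent.family, 0) + 1
            counter["copy"][parent.family] = k
            child = _Gene(
                gene_id=f"{parent.family}-{k}", family=parent.family,
                seq=None if parent.seq is None else list(parent.seq),
            )
            state.append(child)
            history.events.append(HistoryEvent(branch_id, "birth", child.gene_id, parent.gene_id))
        elif kind == 1:  # disruption
            target = intact[int(rng.integers(len(intact)))]
            counter["event"] += 1
            tag = f"d{counter['event']}"
            if target.seq is not None:
                newseq, mkind, pos = _disrupt_sequence(target.seq, rng, cfg)
            else:
                mkind, pos, newseq = ("stop", -1, None)
            segregating = node.is_leaf and rng.random() < cfg.seg_pseudo_prob
            target.state = "disrupted"
            target.segregating = segregating
            target.disruption = (tag, mkind, pos)
            if not segregating and newseq is not None:
                target.seq = newseq
            elif segregating:
                # the intact allele keeps evolving; the disrupted allele is
                # realized at the leaf from the stored mutation descriptor
                target._pending = (newseq, mkind, pos) if newseq is not None else None
            history.events.append(HistoryEvent(branch_id, "disruption", target.gene_id))
        elif kind == 2:  # loss
            target = intact[int(rng.integers(len(intact)))]
            state.remove(target)
            history.events.append(HistoryEvent(branch_id, "loss", target.gene_id))
        else:  # conversion
            pairs = [
                (a, b)
                for fam in sorted(fams)
                for i, a in enumerate(fams[fam])
                for b in fams[fam][i + 1 :]
            ]
            donor, acceptor = pairs[int(rng.integers(len(pairs)))]
            if rng.random() < 0.5:
                donor, acceptor = acceptor, donor
            if donor.seq is not None:
                lo, hi = cfg.flank, cfg.flank + cfg.coding_length
                acceptor.seq[lo:hi] = donor.seq[lo:hi]
            history.events.append(
                HistoryEvent(branch_id, "conversion", acceptor.gene_id, donor.gene_id)
            )
    if cfg.evolve_sequences:
        rate = cfg.subst_params.rate * cfg.gene_rate_multiplier
        for g in state:
            _substitute(
                g.seq, rng, rate, length, cfg.subst_params,
                purify=(g.state == "intact"), cfg=cfg,
            )
    return state


def _realize_leaf(
    species: str, state: list[_Gene], rng: np.random.Generator, cfg: SimulationConfig
) -> GeneRepertoire:
    genes: list[GeneCopy] = []
    for g in sorted(state, key=lambda x: x.gene_id):
        if not cfg.evolve_sequences:
            st = "segregating" if (g.state == "disrupted" and g.segregating) else g.state
            genes.append(GeneCopy(g.gene_id, None, None, st, g.family,
                                  disruption_tag=g.disruption[0] if g.disruption else None))
            continue
        h1 = list(g.seq)
        h2 = list(g.seq)
        rate = cfg.heterozygosity * (cfg.gene_rate_multiplier if g.state == "intact" else 1.0)
        purify = g.state == "intact" and not g.segregating
        het = _substitute(h2, rng, rate, 1.0, cfg.subst_params, purify=purify, cfg=cfg)
        state_label = g.state
        if g.state == "disrupted" and g.segregating:
            pending = getattr(g, "_pending", None)
            if pending is not None and pending[0] is not None:
                newseq, mkind, pos = pending
                h2 = list(newseq)
                if mkind == "stop":
                    het = sorted(set(het) | {pos, pos + 1, pos + 2})
            state_label = "segregating"
        snps = tuple(sorted({p for p in het if p < min(len(h1), len(h2))}))
        genes.append(
            GeneCopy(
                gene_id=g.gene_id, h1="".join(h1), h2="".join(h2),
                state=state_label, family=g.family, snp_positions=snps,
                disruption_tag=g.disruption[0] if g.disruption else None,
            )
        )
    return GeneRepertoire(species=species, genes=genes)


# ---------------------------------------------------------------------------
# capture emission


def _draw_depth(
    rng: np.random.Generator, mean: float, dispersion: float, length: int
) -> np.ndarray:
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=length)
    return rng.poisson(lam).astype(float)


def _count_het_snps(copy: GeneCopy) -> int:
    if copy.snp_positions:
        return len(copy.snp_positions)
    if copy.h1 is None or copy.h2 is None:
        return 0
    if len(copy.h1) == len(copy.h2):
        return sum(a != b for a, b in zip(copy.h1, copy.h2))
    # single-indel alleles: align around the first mismatch
    a, b = (copy.h1, copy.h2) if len(copy.h1) > len(copy.h2) else (copy.h2, copy.h1)
    d = len(a) - len(b)
    i = 0
    while i < len(b) and a[i] == b[i]:
        i += 1
    return sum(x != y for x, y in zip(a[:i], b[:i])) + sum(
        x != y for x, y in zip(a[i + d :], b[i:])
    )


def _pair_snps(a: GeneCopy, b: GeneCopy) -> int:
    n = min(len(a.h1), len(b.h1))
    between = sum(1 for i in range(n) if a.h1[i] != b.h1[i])
    allelic = len(set(a.snp_positions) | set(b.snp_positions))
    return between + allelic


def _apply_iupac(copy: GeneCopy, rng: np.random.Generator, prob: float) -> tuple[str, str]:
    """Emit the allele pair with a fraction of het sites left unphased."""
    if not copy.snp_positions or prob <= 0 or copy.h1 is None:
        return copy.h1, copy.h2
    pair_to_code = {frozenset(v): k for k, v in classify.TWOFOLD.items()}
    h1, h2 = list(copy.h1), list(copy.h2)
    for pos in copy.snp_positions:
        if pos >= min(len(h1), len(h2)):
            continue
        if h1[pos] != h2[pos] and rng.random() < prob:
            code = pair_to_code.get(frozenset((h1[pos], h2[pos])))
            if code:
                h1[pos] = h2[pos] = code
    return "".join(h1), "".join(h2)


def emit_capture(
    repertoires: dict[str, GeneRepertoire],
    cfg: SimulationConfig,
    sex: dict[str, str],
    seed: int | None = None,
) -> dict[str, CaptureEmission]:
    """Emit round-3-style capture summaries for each species' repertoire.

    Gene copies sharing a family map to a single congregated locus (the
    mapper cannot separate paralogs at this stage): depths sum over copies,
    SNP sites union allelic and paralogous variation, and the shared-window
    fraction between the two haplotype references is reported. Post-split
    daughter records (what mapping rounds 4/5 would see) are attached for
    multi-copy loci.
    """
    for sp in repertoires:
        if sex.get(sp) not in ("male", "female"):
            raise ValueError(f"unknown sex label for {sp!r}: {sex.get(sp)!r}")
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    out: dict[str, CaptureEmission] = {}
    for sp_ss, sp in zip(ss.spawn(len(repertoires)), sorted(repertoires)):
        rng = np.random.default_rng(sp_ss)
        rep = repertoires[sp]
        fams: dict[str, list[GeneCopy]] = {}
        for g in rep.genes:
            fams.setdefault(g.family, []).append(g)
        records = []
        for fam in sorted(fams):
            records.append(_emit_family(fam, fams[fam], rng, cfg))
        out[sp] = CaptureEmission(species=sp, sex=sex[sp], records=records)
    return out


def _emit_family(
    fam: str, copies: list[GeneCopy], rng: np.random.Generator, cfg: SimulationConfig
) -> LocusEmission:
    copies = sorted(copies, key=lambda c: c.gene_id)
    if len(copies) == 1:
        return _emit_single(copies[0].gene_id, copies[0], rng, cfg, cn=1)
    length = min(len(c.h1) for c in copies) if copies[0].h1 else cfg.coding_length + 2 * cfg.flank
    cn = len(copies)
    depth = _draw_depth(rng, cfg.depth_mean * cn, cfg.depth_dispersion, length)
    snp = 0
    for i, a in enumerate(copies):
        snp += len(a.snp_positions) if a.h1 else 0
        for b in copies[i + 1 :]:
            if a.h1 and b.h1:
                n = min(len(a.h1), len(b.h1), length)
                snp += sum(1 for k in range(n) if a.h1[k] != b.h1[k] and a.h1[k] in NUC and b.h1[k] in NUC)
    h1 = copies[0].h1
    h2 = copies[1].h1
    shared = shared_window_fraction(h1, h2, cfg.read_len) if h1 and h2 else None
    # post-split daughters: first copy vs. the (possibly still congregated) rest
    child1 = _emit_single(f"{fam}-1", copies[0], rng, cfg, cn=1)
    if len(copies) == 2:
        child2 = _emit_single(f"{fam}-2", copies[1], rng, cfg, cn=1)
    else:
        child2 = _emit_family(f"{fam}-2", copies[1:], rng, cfg)
        child2 = replace_locus_id(child2, f"{fam}-2")
    return LocusEmission(
        locus_id=fam, kind="gene", per_site_depth=depth, snp_sites=snp,
        h1=h1, h2=h2, shared_fraction=shared, children=(child1, child2),
        true_copy_number=cn,
    )


def replace_locus_id(rec: LocusEmission, locus_id: str) -> LocusEmission:
    rec.locus_id = locus_id
    return rec


def _emit_single(
    locus_id: str, copy_: GeneCopy, rng: np.random.Generator,
    cfg: SimulationConfig, cn: int,
) -> LocusEmission:
    length = len(copy_.h1) if copy_.h1 else cfg.coding_length + 2 * cfg.flank
    depth = _draw_depth(rng, cfg.depth_mean, cfg.depth_dispersion, length)
    snp = _count_het_snps(copy_)
    h1, h2 = _apply_iupac(copy_, rng, cfg.unphased_prob)
    return LocusEmission(
        locus_id=locus_id, kind="gene", per_site_depth=depth, snp_sites=snp,
        h1=h1, h2=h2,
        shared_fraction=None,
        true_copy_number=cn,
    )


def emit_neutral_reference_set(
    n_autosomal: int = 83,
    n_x: int = 3,
    lengths: list[int] | None = None,
    cfg: SimulationConfig | None = None,
    sex: str = "male",
    seed: int | None = None,
) -> list[LocusEmission]:
    """Emit single-copy neutral reference loci (NR-A and NR-X).

    NR loci are non-coding and evolve at the neutral rate, so their SNP
    density is the ceiling against which gene SNP densities are compared.
    Male samples carry one X, so NR-X depth is halved and (being hemizygous)
    NR-X loci show no heterozygous SNPs in males.
    """
    cfg = cfg or SimulationConfig(seed=0)
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex label: {sex!r}")
    if n_autosomal < 0 or n_x < 0:
        raise ValueError("reference counts must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed if seed is None else seed))
    if lengths is None:
        lengths = [int(rng.integers(1000, 2001)) for _ in range(n_autosomal + n_x)]
    if len(lengths) != n_autosomal + n_x:
        raise ValueError("one length per reference locus required")
    out: list[LocusEmission] = []
    for i, L in enumerate(lengths):
        is_x = i >= n_autosomal
        kind = "NR-X" if is_x else "NR-A"
        mean = cfg.depth_mean * (0.5 if (is_x and sex == "male") else 1.0)
        depth = _draw_depth(rng, mean, cfg.depth_dispersion, L)
        if is_x and sex == "male":
            snp = 0
        else:
            snp = int(rng.poisson(cfg.heterozygosity * L))
        out.append(
            LocusEmission(
                locus_id=f"{kind}{i + 1 if not is_x else i - n_autosomal + 1:03d}",
                kind=kind, per_site_depth=depth, snp_sites=snp,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ground-truth bridge to the event stage


def true_status_matrix(tree: SpeciesTree, history: TrueHistory,
                       repertoires: dict[str, GeneRepertoire]):
    """Build the ground-truth species x gene status matrix for a history.

    Gene copies appear as their own columns (duplicates as separated,
    category-2-style loci). Disruptions that are shared across species (same
    originating mutation) are annotated as shared-disruption groups, exactly
    the information the event placer is allowed to use.
    """
    from .events import StatusMatrix

    species = tree.leaf_names
    gene_ids: dict[str, str] = {}
    for rep in repertoires.values():
        for g in rep.genes:
            gene_ids.setdefault(g.gene_id, g.family)
    statuses = {sp: {} for sp in species}
    for sp in species:
        by_id = {g.gene_id: g for g in repertoires[sp].genes}
        for gid in gene_ids:
            g = by_id.get(gid)
            if g is None:
                statuses[sp][gid] = "absent"
            elif g.state == "segregating":
                statuses[sp][gid] = "segregating"
            else:
                statuses[sp][gid] = g.state
    shared: dict[str, list[frozenset]] = {}
    for gid in gene_ids:
        tags: dict[str, set[str]] = {}
        for sp in species:
            by_id = {g.gene_id: g for g in repertoires[sp].genes}
            g = by_id.get(gid)
            if g is not None and g.state == "disrupted" and g.disruption_tag:
                tags.setdefault(g.disruption_tag, set()).add(sp)
        groups = [frozenset(v) for v in tags.values() if len(v) > 1]
        if groups:
            shared[gid] = groups
    import pandas as pd

    df = pd.DataFrame(statuses).T.reindex(index=species, columns=sorted(gene_ids))
    meta = pd.DataFrame(
        {
            "group": {g: fam for g, fam in gene_ids.items()},
            "category": {g: (2 if "-" in g else None) for g in gene_ids},
            "birth_source": {g: "inferred" for g in gene_ids},
        }
    ).reindex(sorted(gene_ids))
    return StatusMatrix(statuses=df, gene_meta=meta, shared_disruptions=shared)
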