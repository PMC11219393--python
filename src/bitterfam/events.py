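"""Maximum-parsimony placement of gene births and deaths on a species tree.

Gene presence evolves under Dollo parsimony: each gene copy originates once
(a duplication "birth") and absences below the origin are explained by the
minimal set of losses. Because paralogous copies are frequently homogenized
by gene conversion, identical duplicate sequences in several lineages are
explained by a single ancestral duplication at the most recent common
ancestor of the duplicate-bearing species rather than by repeated
lineage-specific births.

Disruptions (pseudogenizations) are placed ancestrally only when the species
are annotated as sharing the same disruptive mutation; otherwise each lineage
receives its own disruption event, because identity of the mutation - not
mere co-occurrence - is the evidence for a shared ancestral death.

Counting convention for per-branch totals: every birth is +1; disruption or
loss of a single-locus, separated (category 2) or copy-number-undecided
(category 4) gene is -1; a congregated two-copy locus (category 1 or 3) that
is entirely disrupted or lost counts -2, and -1 when it retains an intact
sequence; category-4 loci mixing intact and disrupted sequences and
segregating pseudogenes are not deaths at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .sptree import Node, SpeciesTree

STATUSES = {"intact", "disrupted", "segregating", "intact_and_disrupted", "absent"}
INTACTISH = {"intact", "segregating"}


@dataclass(frozen=True)
class Event:
    branch_id: str
    event_type: str  # birth | disruption | loss
    gene_id: str
    provenance: str = "inferred"  # inferred | prior
    note: str = ""


@dataclass
class EventLedger:
    events: list[Event] = field(default_factory=list)

    def on_branch(self, branch_id: str, event_type: str | None = None) -> list[Event]:
        return [
            e for e in self.events
            if e.branch_id == branch_id and (event_type is None or e.event_type == event_type)
        ]

    def births(self) -> list[Event]:
        return [e for e in self.events if e.event_type == "birth"]


@dataclass
class PriorEvents:
    """Externally asserted events (e.g., from earlier comparative studies)."""

    events: list[Event] = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "PriorEvents":
        with open(path) as fh:
            data = json.load(fh)
        return cls(events=[
            Event(
                branch_id=str(e["branch_id"]), event_type=e["type"],
                gene_id=e["gene"], provenance="prior", note=e.get("note", ""),
            )
            for e in data["events"]
        ])


@dataclass
class StatusMatrix:
    """Species x gene status grid plus the gene metadata the placer needs.

    ``statuses``: DataFrame indexed by species, columns are gene copies,
    values in {intact, disrupted, segregating, intact_and_disrupted, absent}.
    ``gene_meta``: per-gene ``group`` (the ancestral gene family the copy
    descends from), ``category`` (duplication category 1-4, nullable) and
    ``birth_source`` ("inferred" or "prior" when the birth placement comes
    from outside evidence such as gene trees including database species).
    ``shared_disruptions``: per gene, sets of species known to carry the same
    disruptive mutation. ``group_ancestral_copies``: copies of each group
    already present above the root stem (outgroup polarity; default 1).
    """

    statuses: pd.DataFrame
    gene_meta: pd.DataFrame
    shared_disruptions: dict[str, list[frozenset]] = field(default_factory=dict)
    group_ancestral_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.statuses.values.ravel()) - STATUSES
        if bad:
            raise ValueError(f"unknown statuses: {sorted(bad)}")
        missing = set(self.statuses.columns) - set(self.gene_meta.index)
        if missing:
            raise ValueError(f"genes without metadata: {sorted(missing)}")

    @property
    def species(self) -> list[str]:
        return list(self.statuses.index)

    @property
    def genes(self) -> list[str]:
        return list(self.statuses.columns)

    def category(self, gene: str) -> int | None:
        if gene not in self.gene_meta.index:
            return None
        cat = self.gene_meta.loc[gene, "category"]
        return None if pd.isna(cat) else int(cat)

    def group(self, gene: str) -> str:
        return str(self.gene_meta.loc[gene, "group"])

    def bearing_species(self, gene: str) -> list[str]:
        col = self.statuses[gene]
        return list(col.index[col != "absent"])

    @classmethod
    def from_tsv(cls, path) -> "StatusMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"species", "gene", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"status matrix is missing columns: {sorted(missing)}")
        statuses = df.pivot(index="species", columns="gene", values="status").fillna("absent")
        meta_rows = {}
        shared: dict[str, dict[str, set]] = {}
        for _, row in df.iterrows():
            gene = row["gene"]
            meta_rows.setdefault(gene, {
                "group": row.get("group", gene) or gene,
                "category": float(row["category"]) if row.get("category") not in (None, "", "nan") and not pd.isna(row.get("category")) else None,
                "birth_source": row.get("birth_source") or "inferred",
            })
            sg = row.get("shared_group")
            if sg and not pd.isna(sg):
                shared.setdefault(gene, {}).setdefault(sg, set()).add(row["species"])
        meta = pd.DataFrame(meta_rows).T
        shared_sets = {
            g: [frozenset(v) for v in groups.values() if len(v) > 1]
            for g, groups in shared.items()
        }
        shared_sets = {g: v for g, v in shared_sets.items() if v}
        return cls(statuses=statuses, gene_meta=meta, shared_disruptions=shared_sets)


# ---------------------------------------------------------------------------


def place_births(matrix: StatusMatrix, tree: SpeciesTree) -> list[Event]:
    """Place one duplication birth per derived gene copy.

    Within each gene group, copies are ranked by the depth of the most recent
    common ancestor of their bearing species; the group's ancestral copies
    (present before the root, default one) are absorbed by the root-most
    copies and every remaining copy receives a birth on the stem branch of
    its MRCA. Copies whose placement comes from outside evidence
    (``birth_source == "prior"``) and category-4 copies (copy number
    undecided) are skipped.
    """
    groups: dict[str, list[str]] = {}
    for gene in matrix.genes:
        if matrix.gene_meta.loc[gene, "birth_source"] == "prior":
            continue
        if matrix.category(gene) == 4:
            continue
        groups.setdefault(matrix.group(gene), []).append(gene)

    events: list[Event] = []
    for group in sorted(groups):
        members = []
        for gene in sorted(groups[group]):
            bearing = matrix.bearing_species(gene)
            if not bearing:
                raise ValueError(f"gene {gene} has no bearing species and no prior birth")
            node = tree.mrca(bearing)
            members.append((tree.depth(node), gene, node))
        members.sort(key=lambda m: (m[0], m[1]))
        ancestral = matrix.group_ancestral_copies.get(group, 1)
        for _, gene, node in members[ancestral:]:
            events.append(Event(node.branch_id, "birth", gene))
    return events


def place_deaths(
    matrix: StatusMatrix, tree: SpeciesTree, births: list[Event]
) -> list[Event]:
    """Place losses and disruptions below each gene's origin (Dollo).

    Absences are covered by one loss per maximal all-absent subtree under
    the gene's origin. Disruptions shared across species (annotated identical
    mutations) are placed once at the common ancestor of the sharing group;
    unannotated disruptions are placed independently on terminal branches.
    Segregating pseudogenes generate no events.
    """
    birth_node: dict[str, Node] = {}
    for e in births:
        if e.event_type == "birth":
            birth_node[e.gene_id] = tree.node_for_branch(e.branch_id)

    events: list[Event] = []
    for gene in matrix.genes:
        col = matrix.statuses[gene]
        origin = birth_node.get(gene, tree.root)
        in_scope = set(origin.leaf_names())
        present = [sp for sp in matrix.species if col[sp] != "absent"]
        outside = set(present) - in_scope
        if outside:
            raise ValueError(
                f"gene {gene} present in {sorted(outside)} above its birth branch"
            )
        events.extend(
            Event(n.branch_id, "loss", gene) for n in _loss_nodes(origin, col)
        )

        disrupted = {
            sp for sp in present
            if col[sp] == "disrupted"
            or (col[sp] == "intact_and_disrupted" and matrix.category(gene) in (1, 3))
        }
        covered: set[str] = set()
        for group in matrix.shared_disruptions.get(gene, []):
            if not group <= disrupted:
                raise ValueError(
                    f"gene {gene}: shared-disruption group {sorted(group)} includes "
                    "species without a disrupted copy"
                )
            node = tree.mrca(group)
            under = set(node.leaf_names())
            if any(col[sp] in ("intact", "segregating") for sp in under & set(present) - group):
                raise ValueError(
                    f"gene {gene}: intact descendants under the shared disruption at "
                    f"{node.branch_id}"
                )
            events.append(Event(node.branch_id, "disruption", gene))
            covered |= group
        for sp in sorted(disrupted - covered):
            events.append(Event(tree._leaves[sp].branch_id, "disruption", gene))
    return events


def _loss_nodes(node: Node, col: pd.Series) -> list[Node]:
    names = [n for n in node.leaf_names() if n in col.index]
    if not names:
        return []
    if all(col[n] == "absent" for n in names):
        return [node]
    out: list[Node] = []
    for child in node.children:
        child_names = [n for n in child.leaf_names() if n in col.index]
        if child_names and any(col[n] == "absent" for n in child_names):
            out.extend(_loss_nodes(child, col))
    return out


def merge_prior(
    inferred: EventLedger, prior: PriorEvents, override: bool = False
) -> EventLedger:
    """Append prior-knowledge events to an inferred ledger.

    A prior event for a gene that already carries an inferred event of the
    same type on a different branch is a conflict: an error unless
    ``override`` is set, in which case the prior placement wins. Merging
    never moves inferred events otherwise.
    """
    merged = list(inferred.events)
    for pe in prior.events:
        clashes = [
            e for e in merged
            if e.gene_id == pe.gene_id and e.event_type == pe.event_type
            and e.provenance == "inferred"
        ]
        conflict = [e for e in clashes if e.branch_id != pe.branch_id]
        if conflict and not override:
            raise ValueError(
                f"prior event {pe.event_type} of {pe.gene_id} on branch {pe.branch_id} "
                f"conflicts with inferred placement on branch {conflict[0].branch_id}; "
                "pass override=True to prefer the prior"
            )
        if conflict:
            merged = [e for e in merged if e not in conflict]
        if any(
            e.branch_id == pe.branch_id and e.event_type == pe.event_type
            and e.gene_id == pe.gene_id for e in merged
        ):
            raise ValueError(
                f"duplicate event after merge: {pe.event_type} {pe.gene_id} on {pe.branch_id}"
            )
        merged.append(pe)
    return EventLedger(events=merged)


def count_branch_events(
    ledger: EventLedger, matrix: StatusMatrix, tree: SpeciesTree
) -> pd.DataFrame:
    """Per-branch (+births, -deaths) totals under the counting convention."""
    known = set(tree.branch_ids())
    rows = {b: {"births": 0, "deaths": 0} for b in known}
    for e in ledger.events:
        if e.branch_id not in known:
            raise ValueError(f"event on unknown branch {e.branch_id!r}")
        if e.event_type == "birth":
            rows[e.branch_id]["births"] += 1
        elif e.event_type in ("disruption", "loss"):
            rows[e.branch_id]["deaths"] += _death_weight(e, matrix, tree)
        elif e.event_type == "conversion":
            continue  # homogenization never changes copy number
        else:
            raise ValueError(f"unknown event type {e.event_type!r}")
    df = pd.DataFrame(rows).T
    df.index.name = "branch_id"
    df["net"] = df["births"] - df["deaths"]
    return df


def _death_weight(e: Event, matrix: StatusMatrix, tree: SpeciesTree) -> int:
    cat = matrix.category(e.gene_id)
    if cat not in (1, 3):
        return 1
    if e.event_type == "loss":
        return 2  # a congregated locus stands for two gene copies
    # disruption of a congregated locus: -2 when wholly disrupted, -1 when
    # an intact sequence remains in the congregate
    if e.gene_id in matrix.genes:
        covered = set(tree.node_for_branch(e.branch_id).leaf_names()) & set(matrix.species)
        col = matrix.statuses[e.gene_id]
        states = {col[sp] for sp in covered if col[sp] != "absent"}
        if states == {"disrupted"}:
            return 2
    return 1


def ancestral_counts(
    root_intact: int, counts: pd.DataFrame, tree: SpeciesTree
) -> dict[str, int]:
    """Intact-gene totals per node from the per-branch nets.

    ``root_intact`` is the intact count at the root node (events on the root
    stem, if any, are assumed already reflected in it). Each child node's
    total is its parent's total plus the net of the connecting branch. Leaf
    totals include segregating pseudogenes, which are never subtracted.
    """
    totals: dict[str, int] = {}

    def down(node: Node, value: int):
        key = node.branch_id or node.name
        totals[key] = value
        if value < 0:
            raise ValueError(f"negative intact count at {key}")
        for child in node.children:
            net = int(counts.loc[child.branch_id, "net"]) if child.branch_id in counts.index else 0
            down(child, value + net)

    down(tree.root, root_intact)
    return totals


def build_ancestral_set(
    design_inventory: pd.DataFrame, capture_statuses: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Construct the ancestral gene set from database and capture evidence.

    A gene belongs to the set when it is intact in at least one of the design
    whole-genome-assembly databases, or - though disrupted in every design
    database - it is intact in at least one captured species (direct evidence
    that the disruptions are lineage-specific and the ancestor was intact).
    Returns the sorted gene list and the genes excluded with neither form of
    support.
    """
    if design_inventory.empty:
        raise ValueError("empty design-database inventory")
    included: list[str] = []
    excluded: list[str] = []
    capture_genes = set(capture_statuses.columns)
    for gene, row in design_inventory.iterrows():
        states = set(row.astype(str))
        if "intact" in states:
            included.append(gene)
            continue
        db_disrupted = "disrupted" in states or "truncated" in states
        capture_intact = (
            gene in capture_genes and (capture_statuses[gene] == "intact").any()
        )
        if db_disrupted and capture_intact:
            included.append(gene)
        else:
            excluded.append(gene)
    return sorted(included), sorted(excluded)


def infer_events(
    matrix: StatusMatrix,
    tree: SpeciesTree,
    prior: PriorEvents | None = None,
    override: bool = False,
) -> EventLedger:
    """Full chain: place births, merge prior knowledge, place deaths."""
    births = place_births(matrix, tree)
    ledger = EventLedger(events=births)
    if prior is not None:
        ledger = merge_prior(ledger, prior, override=override)
    deaths = place_deaths(matrix, tree, ledger.births())
    return EventLedger(events=ledger.events + deaths)
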