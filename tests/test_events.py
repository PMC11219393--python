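"""Dollo/parsimony event placement, counting rules, ancestral bookkeeping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bitterfam import (
    Event,
    EventLedger,
    PriorEvents,
    StatusMatrix,
    ancestral_counts,
    build_ancestral_set,
    count_branch_events,
    infer_events,
    merge_prior,
    place_births,
    place_deaths,
    simulate_history,
    true_status_matrix,
)
from bitterfam.simulate import SimulationConfig

SPECIES4 = ["A", "B", "C", "D"]


def matrix(statuses: dict, categories=None, groups=None, shared=None,
           birth_source=None, ancestral=None) -> StatusMatrix:
    df = pd.DataFrame(statuses).reindex(SPECIES4 if set(statuses[next(iter(statuses))]) == set(SPECIES4) else None)
    genes = list(df.columns)
    meta = pd.DataFrame({
        "group": {g: (groups or {}).get(g, g) for g in genes},
        "category": {g: (categories or {}).get(g) for g in genes},
        "birth_source": {g: (birth_source or {}).get(g, "inferred") for g in genes},
    })
    return StatusMatrix(
        statuses=df, gene_meta=meta,
        shared_disruptions=shared or {},
        group_ancestral_copies=ancestral or {},
    )


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle on the 4-leaf tree


EDGES = ["r", "n1", "n2", "A", "B", "C", "D"]
PATHS = {"A": ("r", "n1", "A"), "B": ("r", "n1", "B"),
         "C": ("r", "n2", "C"), "D": ("r", "n2", "D")}
BELOW = {"r": set("ABCD"), "n1": {"A", "B"}, "n2": {"C", "D"},
         "A": {"A"}, "B": {"B"}, "C": {"C"}, "D": {"D"}}


def leaf_state(leaf, origin_edge, losses, disruptions):
    path = PATHS[leaf]
    if origin_edge not in path:
        return "absent"
    scope = path[path.index(origin_edge):]
    if any(e in losses for e in scope):
        return "absent"
    if any(e in disruptions for e in scope):
        return "disrupted"
    return "intact"


def min_events_oracle(pattern, origin_edge="r", annotated=False, count_birth=False):
    """Brute-force minimum event count explaining a single gene's pattern.

    Losses may sit on any edge at or below the origin; disruptions sit on
    terminal edges unless an identical shared mutation is annotated, in which
    case one internal placement is also allowed.
    """
    disrupted = {sp for sp in SPECIES4 if pattern[sp] == "disrupted"}
    loss_pool = [e for e in EDGES if BELOW[e] <= BELOW[origin_edge]
                 and any(pattern[sp] == "absent" for sp in BELOW[e])]
    term_pool = [e for e in EDGES if len(BELOW[e]) == 1 and e in disrupted]
    internal_pool = [e for e in EDGES if len(BELOW[e]) > 1] if annotated else []
    best = None
    for k_loss in range(len(loss_pool) + 1):
        for losses in itertools.combinations(loss_pool, k_loss):
            for internal in [()] + [(e,) for e in internal_pool]:
                for k_t in range(len(term_pool) + 1):
                    for terms in itertools.combinations(term_pool, k_t):
                        disruptions = set(internal) | set(terms)
                        states = {
                            sp: leaf_state(sp, origin_edge, set(losses), disruptions)
                            for sp in SPECIES4
                        }
                        if states == pattern:
                            total = len(losses) + len(disruptions) + (1 if count_birth else 0)
                            if best is None or total < best:
                                best = total
    return best


def inferred_event_count(pattern, quartet_tree, annotated=False):
    shared = {}
    disrupted = frozenset(sp for sp in SPECIES4 if pattern[sp] == "disrupted")
    if annotated and len(disrupted) > 1:
        shared = {"g": [disrupted]}
    m = matrix({"g": pattern}, shared=shared)
    ledger = infer_events(m, quartet_tree)
    return len(ledger.events)


class TestParsimonyOracle:
    def patterns(self):
        for states in itertools.product(["intact", "disrupted", "absent"], repeat=4):
            pattern = dict(zip(SPECIES4, states))
            if all(s == "absent" for s in states):
                continue
            yield pattern

    def test_single_ancestral_gene_matches_enumeration_minimum(self, quartet_tree):
        for pattern in self.patterns():
            ours = inferred_event_count(pattern, quartet_tree, annotated=False)
            oracle = min_events_oracle(pattern, annotated=False)
            assert ours == oracle, pattern

    def test_annotated_shared_disruptions_match_enumeration_minimum(self, quartet_tree):
        for pattern in self.patterns():
            disrupted = {sp for sp in SPECIES4 if pattern[sp] == "disrupted"}
            if len(disrupted) < 2:
                continue
            # annotation is only coherent when no intact leaf sits under the
            # sharing species' common ancestor
            mrca_below = BELOW["r"]
            if disrupted <= {"A", "B"}:
                mrca_below = BELOW["n1"]
            elif disrupted <= {"C", "D"}:
                mrca_below = BELOW["n2"]
            if any(pattern[sp] == "intact" for sp in mrca_below):
                continue
            ours = inferred_event_count(pattern, quartet_tree, annotated=True)
            oracle = min_events_oracle(pattern, annotated=True)
            assert ours == oracle, pattern

    def test_derived_copy_birth_and_losses_match_enumeration(self, quartet_tree):
        """Two-copy group: ancestral copy everywhere, derived copy varies."""
        for presence in itertools.product(["intact", "absent"], repeat=4):
            pattern = dict(zip(SPECIES4, presence))
            if all(s == "absent" for s in presence):
                continue
            m = matrix(
                {"g-1": {sp: "intact" for sp in SPECIES4}, "g-2": pattern},
                groups={"g-1": "g", "g-2": "g"},
                categories={"g-1": 2, "g-2": 2},
            )
            ledger = infer_events(m, quartet_tree)
            ours = len(ledger.events)
            # oracle: derived copy born at any node, one birth event
            bearing = {sp for sp in SPECIES4 if pattern[sp] != "absent"}
            oracle = min(
                v for e in EDGES if bearing <= BELOW[e]
                if (v := min_events_oracle(pattern, origin_edge=e, count_birth=True)) is not None
            )
            assert ours == oracle, pattern


class TestBirthPlacement:
    def test_shared_duplicate_gets_single_stem_birth(self, quartet_tree):
        m = matrix(
            {"g-1": {sp: "intact" for sp in SPECIES4},
             "g-2": {"A": "intact", "B": "intact", "C": "absent", "D": "absent"}},
            groups={"g-1": "g", "g-2": "g"}, categories={"g-1": 2, "g-2": 2},
        )
        births = place_births(m, quartet_tree)
        assert [(e.branch_id, e.gene_id) for e in births] == [("n1", "g-2")]

    def test_terminal_only_duplicate_gets_terminal_birth(self, quartet_tree):
        m = matrix(
            {"g-1": {sp: "intact" for sp in SPECIES4},
             "g-2": {"A": "intact", "B": "absent", "C": "absent", "D": "absent"}},
            groups={"g-1": "g", "g-2": "g"}, categories={"g-1": 2, "g-2": 2},
        )
        births = place_births(m, quartet_tree)
        assert [(e.branch_id, e.gene_id) for e in births] == [("A", "g-2")]

    def test_category4_genes_contribute_no_births(self, quartet_tree):
        m = matrix(
            {"g4": {sp: "intact_and_disrupted" for sp in SPECIES4}},
            categories={"g4": 4}, ancestral={"g4": 0},
        )
        assert place_births(m, quartet_tree) == []

    def test_no_bearing_species_rejected(self, quartet_tree):
        m = matrix({"g": {sp: "absent" for sp in SPECIES4}})
        with pytest.raises(ValueError, match="bearing"):
            place_births(m, quartet_tree)

    def test_prior_birth_source_skipped(self, quartet_tree):
        m = matrix(
            {"g": {"A": "intact", "B": "absent", "C": "absent", "D": "absent"}},
            birth_source={"g": "prior"}, ancestral={"g": 0},
        )
        assert place_births(m, quartet_tree) == []


class TestDeathPlacement:
    def test_clade_absence_is_one_stem_loss(self, quartet_tree):
        m = matrix({"g": {"A": "intact", "B": "intact", "C": "absent", "D": "absent"}})
        deaths = place_deaths(m, quartet_tree, [])
        assert [(e.branch_id, e.event_type) for e in deaths] == [("n2", "loss")]

    def test_different_mutations_stay_independent(self, quartet_tree):
        m = matrix({"g": {"A": "disrupted", "B": "disrupted", "C": "intact", "D": "intact"}})
        deaths = place_deaths(m, quartet_tree, [])
        assert sorted(e.branch_id for e in deaths) == ["A", "B"]

    def test_shared_mutation_is_one_ancestral_disruption(self, quartet_tree):
        m = matrix(
            {"g": {"A": "disrupted", "B": "disrupted", "C": "intact", "D": "intact"}},
            shared={"g": [frozenset({"A", "B"})]},
        )
        deaths = place_deaths(m, quartet_tree, [])
        assert [(e.branch_id, e.event_type) for e in deaths] == [("n1", "disruption")]

    def test_intact_everywhere_no_deaths(self, quartet_tree):
        m = matrix({"g": {sp: "intact" for sp in SPECIES4}})
        assert place_deaths(m, quartet_tree, []) == []

    def test_segregating_generates_no_events(self, quartet_tree):
        m = matrix({"g": {"A": "segregating", "B": "intact", "C": "intact", "D": "intact"}})
        assert place_deaths(m, quartet_tree, []) == []

    def test_presence_above_birth_is_inconsistent(self, quartet_tree):
        m = matrix({"g": {"A": "intact", "B": "intact", "C": "intact", "D": "absent"}})
        births = [Event("n1", "birth", "g")]
        with pytest.raises(ValueError, match="above its birth"):
            place_deaths(m, quartet_tree, births)


class TestMergePrior:
    def test_empty_prior_is_identity(self):
        ledger = EventLedger([Event("n1", "birth", "g")])
        merged = merge_prior(ledger, PriorEvents([]))
        assert merged.events == ledger.events

    def test_same_branch_birth_and_loss_net_zero(self, quartet_tree):
        prior = PriorEvents([
            Event("r", "birth", "gX", provenance="prior"),
            Event("r", "loss", "gX", provenance="prior"),
        ])
        merged = merge_prior(EventLedger([]), prior)
        m = matrix({"g": {sp: "intact" for sp in SPECIES4}})
        counts = count_branch_events(merged, m, quartet_tree)
        assert counts.loc["r", "net"] == 0
        assert counts.loc["r", "births"] == 1 and counts.loc["r", "deaths"] == 1

    def test_conflicting_placement_errors_without_override(self):
        inferred = EventLedger([Event("n1", "birth", "g")])
        prior = PriorEvents([Event("r", "birth", "g", provenance="prior")])
        with pytest.raises(ValueError, match="conflicts"):
            merge_prior(inferred, prior)
        merged = merge_prior(inferred, prior, override=True)
        assert [(e.branch_id, e.provenance) for e in merged.births()] == [("r", "prior")]

    def test_merge_never_moves_inferred_events(self, quartet_tree):
        m = matrix({"g": {"A": "intact", "B": "intact", "C": "absent", "D": "absent"}})
        base = infer_events(m, quartet_tree)
        prior = PriorEvents([Event("r", "disruption", "other", provenance="prior")])
        merged = infer_events(m, quartet_tree, prior)
        assert [e for e in merged.events if e.provenance == "inferred"] == base.events


class TestCountingRules:
    def test_congregated_all_disrupted_counts_minus_two(self, quartet_tree):
        m = matrix(
            {"g": {"A": "disrupted", "B": "intact", "C": "intact", "D": "intact"}},
            categories={"g": 1},
        )
        ledger = infer_events(m, quartet_tree)
        counts = count_branch_events(ledger, m, quartet_tree)
        assert counts.loc["A", "deaths"] == 2

    def test_congregated_mixed_counts_minus_one(self, quartet_tree):
        m = matrix(
            {"g": {"A": "intact_and_disrupted", "B": "intact", "C": "intact", "D": "intact"}},
            categories={"g": 1},
        )
        ledger = infer_events(m, quartet_tree)
        counts = count_branch_events(ledger, m, quartet_tree)
        assert counts.loc["A", "deaths"] == 1

    def test_category4_mixed_contributes_nothing(self, quartet_tree):
        m = matrix(
            {"g4": {"A": "intact_and_disrupted", "B": "intact", "C": "intact", "D": "intact"}},
            categories={"g4": 4}, ancestral={"g4": 1},
        )
        ledger = infer_events(m, quartet_tree)
        counts = count_branch_events(ledger, m, quartet_tree)
        assert counts["births"].sum() == 0 and counts["deaths"].sum() == 0

    def test_segregating_pseudogene_counts_zero(self, quartet_tree):
        m = matrix({"g": {"A": "segregating", "B": "intact", "C": "intact", "D": "intact"}})
        counts = count_branch_events(infer_events(m, quartet_tree), m, quartet_tree)
        assert counts["deaths"].sum() == 0

    def test_event_on_unknown_branch_rejected(self, quartet_tree):
        m = matrix({"g": {sp: "intact" for sp in SPECIES4}})
        with pytest.raises(ValueError, match="unknown branch"):
            count_branch_events(EventLedger([Event("zz", "birth", "g")]), m, quartet_tree)


class TestAncestralCounts:
    def test_plus_three_and_minus_four_arithmetic(self, quartet_tree):
        m = matrix({"g": {sp: "intact" for sp in SPECIES4}})
        ledger = EventLedger(
            [Event("n1", "birth", f"b{i}") for i in range(3)]
            + [Event("n2", "loss", f"l{i}") for i in range(4)]
        )
        counts = count_branch_events(ledger, m, quartet_tree)
        totals = ancestral_counts(32, counts, quartet_tree)
        assert totals["n1"] == 35 and totals["n2"] == 28
        assert totals["A"] == 35 and totals["C"] == 28

    def test_negative_totals_are_inconsistent(self, quartet_tree):
        m = matrix({"g": {sp: "intact" for sp in SPECIES4}})
        ledger = EventLedger([Event("n1", "loss", f"l{i}") for i in range(3)])
        counts = count_branch_events(ledger, m, quartet_tree)
        with pytest.raises(ValueError, match="negative"):
            ancestral_counts(2, counts, quartet_tree)

    @pytest.mark.parametrize("seed", range(30))
    def test_conservation_identity_on_simulated_histories(self, six_leaf_tree, seed):
        """Root count plus per-branch nets reproduces every leaf's total."""
        cfg = SimulationConfig(
            seed=seed, birth_rate=0.04, disruption_rate=0.06, loss_rate=0.04,
            conversion_rate=0.05, seg_pseudo_prob=0.3, root_repertoire_size=8,
            evolve_sequences=False,
        )
        hist, reps = simulate_history(six_leaf_tree, cfg)
        m = true_status_matrix(six_leaf_tree, hist, reps)
        ledger = infer_events(m, six_leaf_tree)
        counts = count_branch_events(ledger, m, six_leaf_tree)
        # a root gene lost in every leaf is invisible to inference (no
        # bearing species, no prior); the bookkeeping baseline is the
        # visible part of the root repertoire
        root_visible = len({m.group(g) for g in m.genes})
        totals = ancestral_counts(root_visible, counts, six_leaf_tree)
        for sp in six_leaf_tree.leaf_names:
            assert totals[sp] == reps[sp].count("intact", "segregating"), (seed, sp)

    def test_stem_duplicates_recovered_without_spurious_births(self, six_leaf_tree):
        """Converted duplicates present in all bearers give one stem birth."""
        hits = 0
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed, birth_rate=0.05, conversion_rate=0.3,
                root_repertoire_size=5, evolve_sequences=False,
            )
            hist, reps = simulate_history(six_leaf_tree, cfg)
            true_births = [e for e in hist.events if e.event_type == "birth"]
            if not true_births:
                continue
            m = true_status_matrix(six_leaf_tree, hist, reps)
            inferred = place_births(m, six_leaf_tree)
            # no losses simulated: every copy survives in all descendants, so
            # inferred birth count must equal the true one (no per-lineage
            # duplicates posited despite conversion shuffling sequences)
            assert len(inferred) == len(true_births)
            hits += 1
        assert hits > 10


class TestAncestralSet:
    def inventory(self):
        return pd.DataFrame(
            {
                "db1": {"gA": "intact", "gB": "disrupted", "gC": "disrupted", "gD": "absent"},
                "db2": {"gA": "disrupted", "gB": "intact", "gC": "disrupted", "gD": "absent"},
            }
        )

    def captures(self, gc_intact: bool):
        return pd.DataFrame(
            {
                "gC": {"sp1": "intact" if gc_intact else "disrupted", "sp2": "absent"},
                "gD": {"sp1": "absent", "sp2": "absent"},
            }
        )

    def test_intact_in_one_database_is_enough(self):
        included, _ = build_ancestral_set(self.inventory(), self.captures(False))
        assert {"gA", "gB"} <= set(included)

    def test_capture_rescues_database_disrupted_gene(self):
        included, excluded = build_ancestral_set(self.inventory(), self.captures(True))
        assert "gC" in included and "gD" in excluded

    def test_gene_without_support_is_excluded(self):
        included, excluded = build_ancestral_set(self.inventory(), self.captures(False))
        assert "gC" in excluded and "gD" in excluded
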