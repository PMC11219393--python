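"""Gene birth/death reconstruction on the packaged cercopithecid case study.

Loads the curated ten-species status matrix, the dated species tree and the
prior-knowledge ledger, constructs the ancestral gene set, places birth and
death events by Dollo parsimony under the gene-conversion assumption, and
prints the per-branch ledger with ancestral intact-gene totals.
"""

from bitterfam import (
    ancestral_counts,
    build_ancestral_set,
    count_branch_events,
    infer_events,
)
from bitterfam.fixtures import (
    load_capture_statuses,
    load_design_inventory,
    load_prior_events,
    load_species_tree,
    load_status_matrix,
)

included, excluded = build_ancestral_set(load_design_inventory(), load_capture_statuses())
print(f"ancestral gene set: {len(included)} genes "
      f"({len(excluded)} candidates excluded for lack of intact support)")

tree = load_species_tree()
matrix = load_status_matrix()
ledger = infer_events(matrix, tree, load_prior_events())

print("\nevents on the cercopithecid stem (branch 1):")
for e in ledger.on_branch("1"):
    print(f"  {e.event_type:<10} {e.gene_id:<12} [{e.provenance}]")
print("events on the colobine stem (branch 3):")
for e in ledger.on_branch("3"):
    print(f"  {e.event_type:<10} {e.gene_id:<12} [{e.provenance}]")

counts = count_branch_events(ledger, matrix, tree)
active = counts[(counts["births"] > 0) | (counts["deaths"] > 0)]
print("\nper-branch totals (+births / -deaths):")
print(active.to_string())

totals = ancestral_counts(len(included), counts, tree)
print("\nintact-gene totals (root = ancestral set size):")
print("  cercopithecid ancestor:", totals["1"])
print("  cercopithecine ancestor:", totals["2"])
print("  colobine ancestor:", totals["3"])
print("\nThe colobine stem loses four genes (one shared disruption, three "
      "losses) while no colobine-stem births occur - the repertoire "
      "contraction in the folivorous lineage.")
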