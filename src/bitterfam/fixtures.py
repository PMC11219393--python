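"""Packaged cercopithecid bitter-receptor case-study data.

A small curated data set for the ten-species cercopithecid study system
(eight cercopithecines, two colobines), reconstructed from published
species-level findings: the dated species tree with stable branch ids (1 =
cercopithecid stem, 2 = cercopithecine stem, 3 = colobine stem), the gene
status matrix for the duplicated gene groups with the colobine-shared
TAS2R403 disruption annotated, a prior-knowledge event ledger for placements
that rest on outside gene-tree evidence, the probe-design database inventory
used to delimit the ancestral gene set, and the per-species sequencing-depth
comparison between targeted capture and whole-genome-assembly databases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .events import PriorEvents, StatusMatrix
from .sptree import SpeciesTree


def _path(name: str):
    return resources.files("bitterfam") / "data" / name


def load_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(_path("cercopithecid_tree.nwk").read_text())


def load_status_matrix() -> StatusMatrix:
    with resources.as_file(_path("status_matrix.tsv")) as p:
        return StatusMatrix.from_tsv(p)


def load_prior_events() -> PriorEvents:
    with resources.as_file(_path("prior_events.json")) as p:
        return PriorEvents.from_json(p)


def load_design_inventory() -> pd.DataFrame:
    with resources.as_file(_path("design_db_inventory.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="gene", dtype=str)


def load_capture_statuses() -> pd.DataFrame:
    with resources.as_file(_path("capture_status.tsv")) as p:
        long = pd.read_csv(p, sep="\t", dtype=str)
    return long.pivot(index="species", columns="gene", values="status").fillna("absent")


def load_depth_table() -> pd.DataFrame:
    with resources.as_file(_path("depth_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"])
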