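import numpy as np
import pytest

from bitterfam import GeneCopy, GeneRepertoire, SpeciesTree


@pytest.fixture
def quartet_tree() -> SpeciesTree:
    """Balanced 4-leaf tree with named internal branches."""
    return SpeciesTree.from_newick("((A:1,B:1)n1:1,(C:1,D:1)n2:1)r:1;")


@pytest.fixture
def six_leaf_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(
        "(((A:1,B:1)n1:1,C:2)n2:1,((D:1,E:1)n3:1,F:2)n4:1)r:1;"
    )


def make_repertoire(
    species: str,
    n_single: int = 30,
    rng: np.random.Generator | None = None,
    length: int = 1100,
    extra: list[GeneCopy] | None = None,
) -> GeneRepertoire:
    """Hand-built diploid repertoire of single-copy intact genes plus extras."""
    rng = rng if rng is not None else np.random.default_rng(0)
    genes = []
    for i in range(n_single):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        genes.append(GeneCopy(f"s{i:03d}", seq, seq, "intact", f"s{i:03d}"))
    return GeneRepertoire(species, genes + list(extra or []))


def diverge(seq: str, fraction: float, rng: np.random.Generator) -> str:
    out = list(seq)
    k = max(1, int(round(fraction * len(out))))
    for i in rng.choice(len(out), size=k, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)
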