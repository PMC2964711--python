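import numpy as np
import pytest

from mtn1a.classify import load_clade_tree
from mtn1a.dating import MutationClassifier
from mtn1a.hvs_io import Haplotype, call_variants, load_fixture_table
from mtn1a.network import encode, extract_tree, reduced_median
from mtn1a.reference import load_reference
from mtn1a.simulate import (
    SimulationConfig,
    emit_sequences,
    n1a_like_newick,
    simulate_genealogy,
)


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def clade_tree(ref):
    return load_clade_tree(ref=ref)


@pytest.fixture(scope="session")
def classifier(ref):
    return MutationClassifier(ref)


@pytest.fixture()
def fixture_haps(ref):
    return load_fixture_table(ref)


SIM19_CLADES = {
    "N1a1a1": [f"T{i:02d}" for i in range(1, 11)],
    "N1a1a1a": ["T01", "T02", "T03"],
    "N1a1a2": ["T11", "T12", "T13", "T14"],
    "N1a1a3": ["T15", "T16"],
}


@pytest.fixture(scope="session")
def sim19(ref):
    """The packaged 19-genome demo run: ground truth, called variants, and
    the network-extracted rooted tree."""
    cfg = SimulationConfig(seed=13, topology=n1a_like_newick(),
                           n_tips=19, tmrca_years=18000)
    gt = simulate_genealogy(cfg, ref)
    records, truth = emit_sequences(gt, ref)
    haps = []
    for name, seq in records:
        h = Haplotype(id=name, hvs1=[], hvs2=[], count=1)
        h.coding = call_variants(seq, ref)
        haps.append(h)
    net = reduced_median(encode(haps, ref))
    tree = extract_tree(net)
    return {"gt": gt, "records": records, "truth": truth, "haps": haps,
            "net": net, "tree": tree}
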