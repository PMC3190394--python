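import numpy as np
import pytest

from coevoscan import evomodel as em
from coevoscan import synthdata as sd


@pytest.fixture(scope="session")
def wag():
    return em.load_aa_model("wag")


@pytest.fixture(scope="session")
def small_tree():
    return em.Phylogeny.from_newick(
        "((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.02);"
    )


@pytest.fixture(scope="session")
def small_protein_alignment():
    return em.ProteinAlignment(["A", "B", "C", "D"], ["ACD", "AFD", "GCW", "ACD"])


@pytest.fixture(scope="session")
def toy_codon_dataset():
    """Small simulated codon dataset reused across selection tests."""
    cfg = sd.SimulationConfig(n_taxa=8, n_codons=60, seed=11)
    return sd.simulate_dataset(cfg)


def brute_force_site_loglik(alignment, tree, model, rates=em.SINGLE_RATE):
    """Exhaustive ancestral-state enumeration oracle for small trees."""
    import itertools

    data = alignment.to_indices()[tree.leaf_order_for(alignment)]
    n_states = model.n_states
    internal = [v for v in range(tree.n_nodes) if v >= tree.n_leaves]
    out = []
    for site in range(data.shape[1]):
        total = 0.0
        for r, p in zip(rates.rates, rates.probs):
            Ps = {
                v: model.transition_matrix(tree.branch_lengths[v] * r)
                for v in tree.nonroot_nodes()
            }
            s = 0.0
            for assign in itertools.product(range(n_states), repeat=len(internal)):
                st = dict(zip(internal, assign))
                for leaf in range(tree.n_leaves):
                    st[leaf] = data[leaf, site]
                pr = model.pi[st[tree.root]]
                ok = True
                for v in tree.nonroot_nodes():
                    parent_state = st[tree.parent[v]]
                    child_state = st[v]
                    if child_state < 0:  # missing leaf: marginalize
                        continue
                    if parent_state < 0:
                        ok = False
                        break
                    pr *= Ps[v][parent_state, child_state]
                if ok:
                    s += pr
            total += p * s
        out.append(np.log(total))
    return np.array(out)
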