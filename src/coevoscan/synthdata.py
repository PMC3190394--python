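"""Synthetic data with planted signal: trees, codon alignments, structures.

The generator emulates the kind of data the downstream stages are designed
for: many small codon alignments of an essential, mostly purifying-selected
chloroplast gene (rbcL-like: 11-40 sequences, ~476 codons) on independent
phylogenies, with optional planted coevolving site pairs and positively
selected sites, plus toy single-chain structures and secondary-structure
annotations so the 3D and enrichment stages are testable without downloads.

Coupling model
--------------
No generative definition of "coevolution" is standard, so this module fixes
one explicitly.  A planted pair (a, b) evolves as a joint process in which
each site follows its GY94 codon process modified by two mutual couplings,
both controlled by ``coupling_lambda`` (lambda):

1. *Concerted compensation*: whenever one site substitutes with a change
   of the coupled property, the partner immediately makes one compensating
   substitution with probability 1 - 1/lambda, drawn from its own
   instantaneous rates restricted to single-nucleotide moves whose encoded
   amino acid comes closer to the *complement target* of the first site's
   new amino acid (the best available move when no strictly closer one
   exists; no event when every move is worse than staying).
2. *Drift suppression*: between such events each site follows its GY94
   rates with moves that take its property strictly farther from the
   complement target of the partner divided by lambda.

Charge-coupled pairs are created in complementary states (root codons
drawn from the stationary distribution restricted to oppositely charged
amino acids), mirroring the R-E / K-D pairing the method is meant to
recover; other properties draw both roots from the stationary
distribution.  The complement target is:

* charge: the opposite of the partner's current charge sign;
* polarity / volume: ``c - value(partner)`` where the conserved sum ``c`` is
  fixed at pair creation to the sum of the two root residues' values;
* grantham: any amino acid strictly closer to the partner in Grantham
  distance than the current one.

``coupling_lambda = 1`` disables both couplings and reduces exactly to
independent evolution; large lambda makes nearly every property-changing
substitution at a accompanied by a same-instant compensation at b, the
footprint a co-substitution detector is built to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import evomodel as em
from .properties import (
    AMINO_ACIDS,
    CHARGE,
    GRANTHAM_MATRIX,
    PROPERTY_NAMES,
    SCALAR_SCALES,
)
from .composition import SSAnnotation

# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a typical rbcL-like dataset: a few dozen sequences,
    476 codons, moderate divergence, strong purifying selection at
    background sites.  ``pair_omega`` is the marginal dN/dS of planted pair
    sites (None: use ``base_omega``); the default 1.0 makes planted pairs
    variable at the protein level so the coupling, not purifying selection,
    dominates their dynamics.
    """

    n_taxa: int = 30
    n_codons: int = 476
    tree_height: float = 0.8
    coupling_lambda: float = 1.0
    coupled_property: str = "charge"
    planted_pairs: list = field(default_factory=list)
    positive_sites: dict = field(default_factory=dict)  # site -> omega
    base_omega: float = 0.2
    pair_omega: float | None = 1.0
    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.coupling_lambda < 1:
            raise ValueError("coupling_lambda must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.base_omega < 0 or any(w < 0 for w in self.positive_sites.values()):
            raise ValueError("omega values must be >= 0")
        if self.coupled_property not in PROPERTY_NAMES:
            raise ValueError(f"coupled_property must be one of {PROPERTY_NAMES}")
        flat = [s for pair in self.planted_pairs for s in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("planted_pairs must be disjoint site pairs")
        for s in flat + list(self.positive_sites):
            if not (0 <= s < self.n_codons):
                raise ValueError(f"site index {s} out of range")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset for recovery tests."""

    coevolving_pairs: list
    positive_sites: list
    site_omega: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, tree_height: float = 0.8, seed: int = 0) -> em.Phylogeny:
    """Yule (pure-birth) topology with exponential branch lengths, rescaled
    so the mean root-to-tip path equals ``tree_height`` exactly.

    Deterministic given (n_taxa, tree_height, seed).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    # grow: active lineages split at rate 1 each
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]  # time the node's edge started
    t = 0.0
    active = [1, 2]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        v = active.pop(int(rng.integers(k)))
        # v becomes internal with two children
        for _ in range(2):
            parent.append(v)
            birth.append(t)
            active.append(len(parent) - 1)
    k = len(active)
    t += rng.exponential(1.0 / k)
    n = len(parent)
    parent = np.array(parent)
    birth = np.array(birth)
    end = np.full(n, t)
    has_child = np.zeros(n, dtype=bool)
    for v in range(n):
        if parent[v] >= 0:
            end[parent[v]] = birth[v]
            has_child[parent[v]] = True
    bl = end - birth
    bl[0] = 0.0
    # renumber: leaves first, labelled t1..tN in left-to-right order
    leaves = [v for v in range(n) if not has_child[v]]
    internals = [v for v in range(n) if has_child[v]]
    newidx = {v: i for i, v in enumerate(leaves)}
    newidx.update({v: len(leaves) + i for i, v in enumerate(internals)})
    new_parent = np.full(n, -1, dtype=np.int64)
    new_bl = np.zeros(n)
    for v in range(n):
        if parent[v] >= 0:
            new_parent[newidx[v]] = newidx[parent[v]]
        new_bl[newidx[v]] = bl[v]
    labels = [f"t{i + 1}" for i in range(len(leaves))]
    tree = em.Phylogeny(new_parent, new_bl, labels)
    depth = tree.root_to_tip_depths().mean()
    return tree.scale(tree_height / depth)


# ---------------------------------------------------------------------------
# Coupled-pair simulation
# ---------------------------------------------------------------------------


def _closer_mask(prop: str, target, current_aa: int) -> np.ndarray:
    """Boolean mask over the 61 codons: does the encoded amino acid move
    strictly closer to the target than ``current_aa``?"""
    aa_of = em.CODON_AA_INDEX
    if prop == "grantham":
        d = GRANTHAM_MATRIX[:, target]  # target: partner aa index
        return d[aa_of] < d[current_aa]
    vals = np.array([SCALAR_SCALES[prop][aa] for aa in AMINO_ACIDS])
    return np.abs(vals[aa_of] - target) < abs(vals[current_aa] - target)


def _farther_mask(prop: str, target, current_aa: int) -> np.ndarray:
    """Mask over the 61 codons: amino acid strictly farther from target."""
    aa_of = em.CODON_AA_INDEX
    if prop == "grantham":
        d = GRANTHAM_MATRIX[:, target]
        return d[aa_of] > d[current_aa]
    vals = np.array([SCALAR_SCALES[prop][aa] for aa in AMINO_ACIDS])
    return np.abs(vals[aa_of] - target) > abs(vals[current_aa] - target)


def _pair_target(prop: str, partner_aa: int, conserved_sum: float):
    if prop == "charge":
        return -CHARGE[AMINO_ACIDS[partner_aa]]
    if prop == "grantham":
        return partner_aa
    vals = SCALAR_SCALES[prop]
    return conserved_sum - vals[AMINO_ACIDS[partner_aa]]


class _PairProcess:
    """Joint simulation of one coupled codon-site pair (see module docs)."""

    def __init__(self, model: em.SubstModel, lam: float, prop: str):
        self.Q = model.Q
        self.pi = model.pi
        self.lam = lam
        self.prop = prop
        self._aa_prop = None
        if prop != "grantham":
            self._aa_prop = np.array(
                [SCALAR_SCALES[prop][aa] for aa in AMINO_ACIDS]
            )

    def _property_changed(self, c_old: int, c_new: int) -> bool:
        a0, a1 = em.CODON_AA_INDEX[c_old], em.CODON_AA_INDEX[c_new]
        if self.prop == "grantham":
            return a0 != a1
        return self._aa_prop[a0] != self._aa_prop[a1]

    def site_rates(self, c_self: int, c_partner: int, conserved_sum) -> np.ndarray:
        """Drift-suppressed GY94 rates given the partner's state."""
        row = self.Q[c_self].copy()
        row[c_self] = 0.0
        if self.lam != 1.0:
            target = _pair_target(
                self.prop, em.CODON_AA_INDEX[c_partner], conserved_sum
            )
            farther = _farther_mask(self.prop, target, em.CODON_AA_INDEX[c_self])
            row = np.where(farther, row / self.lam, row)
        return row

    def compensate(self, c_self: int, c_partner: int, conserved_sum, rng) -> int:
        """One concerted compensating move toward the partner's complement:
        a strictly closer single-step move when available, otherwise the
        best single-step move that is no worse than staying."""
        target = _pair_target(self.prop, em.CODON_AA_INDEX[c_partner], conserved_sum)
        row = self.Q[c_self].copy()
        row[c_self] = 0.0
        closer = _closer_mask(self.prop, target, em.CODON_AA_INDEX[c_self])
        cand = np.where(closer, row, 0.0)
        if cand.sum() <= 0:
            # best-available fallback: moves reaching the minimal distance
            aa_of = em.CODON_AA_INDEX
            if self.prop == "grantham":
                dist = GRANTHAM_MATRIX[aa_of, target]
                d_cur = GRANTHAM_MATRIX[aa_of[c_self], target]
            else:
                vals = self._aa_prop
                dist = np.abs(vals[aa_of] - target)
                d_cur = abs(vals[aa_of[c_self]] - target)
            reach = np.where(row > 0, dist, np.inf)
            best = reach.min()
            if not np.isfinite(best) or best > d_cur:
                return c_self
            cand = np.where(reach == best, row, 0.0)
        return int(em._sample_rows(cand[None, :] / cand.sum(), rng)[0])

    def evolve_branch(self, ca, cb, t, conserved_sum, rng, on_event=None):
        a_row = self.site_rates(ca, cb, conserved_sum)
        b_row = self.site_rates(cb, ca, conserved_sum)
        p_couple = 1.0 - 1.0 / self.lam
        clock = 0.0
        while True:
            total = a_row.sum() + b_row.sum()
            clock += rng.exponential(1.0 / total)
            if clock >= t:
                return ca, cb
            a_moves = rng.random() < a_row.sum() / total
            if a_moves:
                c_old, ca = ca, int(
                    em._sample_rows(a_row[None, :] / a_row.sum(), rng)[0]
                )
                if on_event:
                    on_event("a", c_old, ca)
                if self._property_changed(c_old, ca) and rng.random() < p_couple:
                    cb_old, cb = cb, self.compensate(cb, ca, conserved_sum, rng)
                    if on_event and cb != cb_old:
                        on_event("b", cb_old, cb)
            else:
                c_old, cb = cb, int(
                    em._sample_rows(b_row[None, :] / b_row.sum(), rng)[0]
                )
                if on_event:
                    on_event("b", c_old, cb)
                if self._property_changed(c_old, cb) and rng.random() < p_couple:
                    ca_old, ca = ca, self.compensate(ca, cb, conserved_sum, rng)
                    if on_event and ca != ca_old:
                        on_event("a", ca_old, ca)
            a_row = self.site_rates(ca, cb, conserved_sum)
            b_row = self.site_rates(cb, ca, conserved_sum)

    def root_states(self, rng):
        """Stationary root draw; charge pairs start complementary."""
        ca = int(em._sample_rows(self.pi[None, :], rng)[0])
        if self.prop == "charge" and self.lam != 1.0:
            charges = np.array(
                [CHARGE[AMINO_ACIDS[a]] for a in em.CODON_AA_INDEX]
            )
            pos, neg = self.pi * (charges > 0), self.pi * (charges < 0)
            ca = int(em._sample_rows((pos + neg)[None, :] / (pos + neg).sum(), rng)[0])
            opp = neg if charges[ca] > 0 else pos
            cb = int(em._sample_rows(opp[None, :] / opp.sum(), rng)[0])
        else:
            cb = int(em._sample_rows(self.pi[None, :], rng)[0])
        return ca, cb


def _simulate_pair(tree: em.Phylogeny, proc: _PairProcess, rng) -> np.ndarray:
    """Leaf codon states (n_leaves, 2) for one coupled pair."""
    ca0, cb0 = proc.root_states(rng)
    vals = None
    if proc.prop in ("polarity", "volume"):
        scale = SCALAR_SCALES[proc.prop]
        vals = (
            scale[AMINO_ACIDS[em.CODON_AA_INDEX[ca0]]]
            + scale[AMINO_ACIDS[em.CODON_AA_INDEX[cb0]]]
        )
    states = np.zeros((tree.n_nodes, 2), dtype=np.int64)
    states[tree.root] = (ca0, cb0)
    for v in tree.preorder:
        if v == tree.root:
            continue
        pa, pb = states[tree.parent[v]]
        states[v] = proc.evolve_branch(pa, pb, tree.branch_lengths[v], vals, rng)
    return states[: tree.n_leaves]


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, tree: em.Phylogeny = None):
    """Simulate one codon alignment with planted signal.

    Returns (CodonAlignment, Phylogeny, PlantedTruth).  Background sites
    evolve independently under GY94(kappa, base_omega); ``positive_sites``
    use their own omega; planted pairs evolve under the coupled process
    described in the module docstring.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_taxa, config.tree_height, seed=config.seed)
    pi = config.codon_freqs

    site_omega = np.full(config.n_codons, config.base_omega)
    for s, w in config.positive_sites.items():
        site_omega[s] = w
    pair_sites = [s for pair in config.planted_pairs for s in pair]
    pw = config.base_omega if config.pair_omega is None else config.pair_omega
    for s in pair_sites:
        if s not in config.positive_sites:
            site_omega[s] = pw

    states = np.empty((tree.n_leaves, config.n_codons), dtype=np.int64)
    # joint normalization across the site-omega distribution: one unit of
    # branch length is one expected substitution per site averaged over
    # sites, so high-omega sites genuinely substitute more (the standard
    # site-model convention)
    pi_arr = np.full(61, 1.0 / 61) if pi is None else np.asarray(pi, dtype=float)
    uniq, counts = np.unique(site_omega, return_counts=True)
    mean_rate = float(
        sum(
            (c / config.n_codons) * em.codon_mean_rate(config.kappa, float(w), pi_arr)
            for w, c in zip(uniq, counts)
        )
    )
    models = {
        float(w): em.build_codon_model(config.kappa, float(w), pi, mean_rate=mean_rate)
        for w in uniq
    }

    indep = np.setdiff1d(np.arange(config.n_codons), np.array(pair_sites, dtype=int))
    for w in np.unique(site_omega[indep]):
        sites = indep[site_omega[indep] == w]
        states[:, sites] = em.simulate_states(tree, models[float(w)], len(sites), rng)

    for a, b in config.planted_pairs:
        proc = _PairProcess(
            models[float(site_omega[a])],
            config.coupling_lambda,
            config.coupled_property,
        )
        pair_states = _simulate_pair(tree, proc, rng)
        states[:, a] = pair_states[:, 0]
        states[:, b] = pair_states[:, 1]

    alignment = em.indices_to_codon(states, tree.leaf_labels)
    truth = PlantedTruth(
        coevolving_pairs=[list(p) for p in config.planted_pairs],
        positive_sites=sorted(config.positive_sites),
        site_omega=[float(w) for w in site_omega],
    )
    return alignment, tree, truth


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "CG": "C",
             "CD": "C", "CE": "C"}


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element):
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name}{'':1s}{resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def simulate_structure(
    n_residues: int, close_pairs=(), seed: int = 0, close_distance: float = 8.0
) -> str:
    """Single-chain PDB text: residues are 3-8 atom clusters on a
    self-avoiding random walk; each close pair is placed with
    center-of-mass distance below ``close_distance`` Angstrom.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    close_pairs = [tuple(p) for p in close_pairs]
    for i, j in close_pairs:
        if not (0 <= i < n_residues and 0 <= j < n_residues) or i == j:
            raise ValueError(f"close_pair ({i}, {j}) out of range")
    rng = np.random.default_rng(seed)
    step = 3.8
    centers = np.zeros((n_residues, 3))
    for r in range(1, n_residues):
        for _ in range(200):
            d = rng.normal(size=3)
            cand = centers[r - 1] + step * d / np.linalg.norm(d)
            if r < 2 or np.min(np.linalg.norm(centers[: r - 1] - cand, axis=1)) > 3.0:
                break
        centers[r] = cand
    for i, j in close_pairs:
        for _ in range(500):
            d = rng.normal(size=3)
            cand = centers[i] + rng.uniform(3.5, close_distance - 2.0) * d / np.linalg.norm(d)
            others = np.delete(centers, j, axis=0)
            if np.min(np.linalg.norm(others - cand, axis=1)) > 2.5:
                centers[j] = cand
                break
        else:
            centers[j] = centers[i] + np.array([close_distance - 2.5, 0, 0])

    lines = []
    serial = 1
    for r in range(n_residues):
        n_atoms = int(rng.integers(3, 9))
        offsets = rng.normal(scale=0.9, size=(n_atoms, 3))
        offsets -= offsets.mean(axis=0)  # keep the cluster centred
        for k in range(n_atoms):
            name = _ATOM_NAMES[k]
            lines.append(
                _pdb_atom_line(
                    serial, name, "ALA", "A", r + 1, centers[r] + offsets[k],
                    _ELEMENTS[name],
                )
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Secondary-structure annotations
# ---------------------------------------------------------------------------

#: default class proportions (helix, strand, coil) of an rbcL-like chain
DEFAULT_SS_PROPORTIONS = (0.435, 0.264, 0.301)


def simulate_ss_annotation(
    n_residues: int, seed: int = 0, proportions=DEFAULT_SS_PROPORTIONS
) -> SSAnnotation:
    """Random H/E/C annotation with configurable class proportions."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    classes = np.array(["H", "E", "C"])
    labels = classes[rng.choice(3, size=n_residues, p=p)]
    return SSAnnotation({r + 1: str(c) for r, c in enumerate(labels)})
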