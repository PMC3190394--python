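"""Likelihood core: alignments, trees, substitution models, pruning.

Shared by the coevolution and selection stages.  Time-reversible amino-acid
(WAG/LG) and GY94-style codon models, discrete-Gamma rate heterogeneity,
Felsenstein pruning over all sites at once, and coordinate-wise Brent
branch-length optimization using outside/inside partial vectors.

Conventions
-----------
* Branch lengths are in expected substitutions per site under the model the
  tree is paired with (codon substitutions for codon models).
* Gaps and ambiguity codes are treated as fully missing data (an all-ones
  leaf partial), the standard convention.
* Matrix exponentials use the eigendecomposition of the pi-symmetrized
  generator, which is exact for reversible models.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from importlib import resources
from scipy import special
from scipy.optimize import minimize_scalar

from .properties import AMINO_ACIDS

# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _standard_code() -> dict:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    return {c: table[c] for c in sorted(table) if set(c) <= set(_BASES)}


#: codon -> amino acid for the 61 sense codons of the universal code
GENETIC_CODE = _standard_code()
#: the 61 sense codons in lexicographic order; stop codons are excluded from
#: the codon-model state space throughout
SENSE_CODONS = tuple(sorted(GENETIC_CODE))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
#: amino-acid index (into properties.AMINO_ACIDS) of each sense codon
CODON_AA_INDEX = np.array(
    [AMINO_ACIDS.index(GENETIC_CODE[c]) for c in SENSE_CODONS]
)

_PURINES = {"A", "G"}


def _codon_pairs():
    """Single-nucleotide codon pairs with transition/nonsynonymous flags."""
    ii, jj, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append((a in _PURINES) == (b in _PURINES))
            nonsyn.append(GENETIC_CODE[ci] != GENETIC_CODE[cj])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


_CODON_I, _CODON_J, _CODON_TS, _CODON_NONSYN = _codon_pairs()


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


class AlignmentError(ValueError):
    pass


class _Alignment:
    """Base container: ordered taxa with equal-length sequences."""

    def __init__(self, taxa, sequences):
        taxa = list(taxa)
        sequences = [str(s).upper() for s in sequences]
        if len(taxa) != len(sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(taxa)) != len(taxa):
            raise AlignmentError("duplicate taxon labels")
        if len({len(s) for s in sequences}) > 1:
            raise AlignmentError("sequences have unequal lengths")
        self.taxa = taxa
        self.sequences = sequences

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __len__(self) -> int:
        return self.n_taxa

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n" for t, s in zip(self.taxa, self.sequences))


class CodonAlignment(_Alignment):
    """In-frame codon alignment over the 61 sense codons plus gaps."""

    def __init__(self, taxa, sequences):
        super().__init__(taxa, sequences)
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise AlignmentError("alignment length is not a multiple of 3")
        for t, s in zip(self.taxa, self.sequences):
            for k in range(0, len(s), 3):
                codon = s[k : k + 3]
                if codon in _STOPS:
                    raise AlignmentError(
                        f"stop codon {codon} at codon position {k // 3 + 1} "
                        f"in {t}"
                    )

    @classmethod
    def from_fasta(cls, source) -> "CodonAlignment":
        from Bio import SeqIO

        handle = io.StringIO(source) if "\n" in str(source) or str(source).startswith(">") else open(source)
        with handle:
            records = list(SeqIO.parse(handle, "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codon(self, taxon_idx: int, site: int) -> str:
        return self.sequences[taxon_idx][3 * site : 3 * site + 3]

    def to_indices(self) -> np.ndarray:
        """(n_taxa, n_sites) indices into SENSE_CODONS; -1 for gap/ambiguous."""
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int64)
        for i, s in enumerate(self.sequences):
            for k in range(self.n_sites):
                out[i, k] = CODON_INDEX.get(s[3 * k : 3 * k + 3], -1)
        return out

    def translate(self) -> "ProteinAlignment":
        aa_seqs = []
        for s in self.sequences:
            aa = []
            for k in range(0, len(s), 3):
                aa.append(GENETIC_CODE.get(s[k : k + 3], "-"))
            aa_seqs.append("".join(aa))
        return ProteinAlignment(self.taxa, aa_seqs)


class ProteinAlignment(_Alignment):
    """Amino-acid alignment over the 20 residues plus gaps."""

    @classmethod
    def from_fasta(cls, source) -> "ProteinAlignment":
        from Bio import SeqIO

        handle = io.StringIO(source) if "\n" in str(source) or str(source).startswith(">") else open(source)
        with handle:
            records = list(SeqIO.parse(handle, "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_indices(self) -> np.ndarray:
        aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        out = np.full((self.n_taxa, self.n_sites), -1, dtype=np.int64)
        for i, s in enumerate(self.sequences):
            for k, ch in enumerate(s):
                out[i, k] = aa_index.get(ch, -1)
        return out


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted tree stored as flat arrays for vectorized pruning.

    Nodes are numbered 0..n_nodes-1 with leaves first (in the order of
    ``leaf_labels``); ``parent[root] == -1``.  ``branch_lengths[v]`` is the
    length of the edge above node v (0 for the root).
    """

    def __init__(self, parent, branch_lengths, leaf_labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.leaf_labels = list(leaf_labels)
        if np.any(self.branch_lengths[self.nonroot_nodes()] < 0):
            raise ValueError("negative branch length")
        self._index()

    def _index(self):
        n = len(self.parent)
        self.n_nodes = n
        self.n_leaves = len(self.leaf_labels)
        self.root = int(np.where(self.parent == -1)[0][0])
        self.children = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        # postorder: children before parents
        post = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(self.children[v])
        post.reverse()
        self.postorder = post
        self.preorder = post[::-1]

    def nonroot_nodes(self) -> np.ndarray:
        return np.where(self.parent >= 0)[0]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self.parent.copy(), self.branch_lengths.copy(), list(self.leaf_labels)
        )

    def total_length(self) -> float:
        return float(self.branch_lengths[self.nonroot_nodes()].sum())

    def root_to_tip_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.branch_lengths[v]
        return depth[: self.n_leaves]

    def scale(self, factor: float) -> "Phylogeny":
        t = self.copy()
        t.branch_lengths = t.branch_lengths * factor
        return t

    # -- Newick I/O ---------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        internal = [
            nd for nd in tree.preorder_node_iter() if not nd.is_leaf()
        ]
        for k, nd in enumerate(internal):
            index[id(nd)] = len(leaves) + k
        n = len(leaves) + len(internal)
        parent = np.full(n, -1, dtype=np.int64)
        bl = np.zeros(n)
        for nd in tree.preorder_node_iter():
            v = index[id(nd)]
            if nd.parent_node is not None:
                parent[v] = index[id(nd.parent_node)]
                bl[v] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent, bl, labels)

    def to_newick(self) -> str:
        def fmt(v):
            if v < self.n_leaves:
                name = self.leaf_labels[v]
            else:
                name = ""
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                name = f"({inner}){name}"
            if v == self.root:
                return name
            return f"{name}:{self.branch_lengths[v]:.10g}"

        return fmt(self.root) + ";"

    def check_taxa(self, alignment: _Alignment):
        if set(self.leaf_labels) != set(alignment.taxa):
            raise ValueError(
                "tree leaf labels do not match alignment taxa: "
                f"{sorted(set(self.leaf_labels) ^ set(alignment.taxa))[:5]} ..."
            )

    def leaf_order_for(self, alignment: _Alignment) -> np.ndarray:
        """Row index into the alignment for each leaf node."""
        pos = {t: i for i, t in enumerate(alignment.taxa)}
        return np.array([pos[lbl] for lbl in self.leaf_labels])


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


@dataclass
class SubstModel:
    """Time-reversible CTMC with stationary frequencies ``pi``.

    ``Q`` is scaled so that the mean rate -sum_i pi_i Q_ii equals
    ``mean_rate`` (1 by default; codon mixture classes share a joint
    normalization and carry their own value).
    """

    states: tuple
    Q: np.ndarray
    pi: np.ndarray
    kind: str  # "aa" | "codon"
    kappa: float | None = None
    omega: float | None = None
    _eig: tuple = field(default=None, repr=False, compare=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _eigen(self):
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            B = (B + B.T) / 2.0
            w, U = np.linalg.eigh(B)
            left = U.T * sqrt_pi[None, :]      # rows: U^T diag(sqrt_pi)
            right = U / sqrt_pi[:, None]       # diag(1/sqrt_pi) U
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        w, right, left = self._eigen()
        P = (right * np.exp(w * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        w, right, left = self._eigen()
        E = np.exp(np.multiply.outer(np.asarray(ts, dtype=float), w))
        P = np.einsum("ik,nk,kj->nij", right, E, left, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def _normalize(Q: np.ndarray, pi: np.ndarray) -> np.ndarray:
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


def build_aa_model(exchangeabilities: np.ndarray, freqs: np.ndarray) -> SubstModel:
    """Reversible 20-state model from a symmetric exchangeability matrix."""
    exch = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if exch.shape != (20, 20) or np.any(exch < 0) or not np.allclose(exch, exch.T):
        raise ValueError("exchangeabilities must be a symmetric nonnegative 20x20 matrix")
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("frequencies must be nonnegative and sum to 1")
    Q = exch * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstModel(states=AMINO_ACIDS, Q=_normalize(Q, pi), pi=pi, kind="aa")


# PAML .dat amino-acid order
_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PAML_TO_ALPHA = np.array([_PAML_ORDER.index(aa) for aa in AMINO_ACIDS])


def load_empirical_aa(name: str):
    """Load a bundled empirical matrix ("wag" or "lg") in PAML .dat layout.

    Returns (exchangeabilities, frequencies) reordered to the alphabetical
    amino-acid order used throughout.
    """
    name = name.lower()
    if name not in ("wag", "lg"):
        raise ValueError("bundled empirical matrices: 'wag', 'lg'")
    text = resources.files("coevoscan.data").joinpath(f"{name}.dat").read_text()
    numbers = [float(x) for x in text.split()]
    if len(numbers) < 210:
        raise ValueError(f"malformed {name}.dat: expected 210 numbers")
    exch = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            exch[i, j] = exch[j, i] = numbers[k]
            k += 1
    freqs = np.array(numbers[k : k + 20])
    # reorder PAML -> alphabetical
    order = _PAML_TO_ALPHA
    exch = exch[np.ix_(order, order)]
    freqs = freqs[order]
    return exch, freqs / freqs.sum()


def load_aa_model(name: str = "wag", freqs=None) -> SubstModel:
    exch, default_freqs = load_empirical_aa(name)
    return build_aa_model(exch, default_freqs if freqs is None else freqs)


def build_codon_model(
    kappa: float, omega: float, codon_freqs=None, mean_rate: float = None
) -> SubstModel:
    """GY94-style codon model over the 61 sense codons.

    Rates for single-nucleotide changes i->j are pi_j, multiplied by kappa
    for transitions and by omega for nonsynonymous changes; all others 0.
    ``mean_rate=None`` normalizes -sum pi_i Q_ii to 1; a float divides Q by
    that value instead (used for jointly-normalized mixture classes).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if codon_freqs is None:
        pi = np.full(61, 1.0 / 61)
    else:
        pi = np.asarray(codon_freqs, dtype=float)
        if pi.shape != (61,) or abs(pi.sum() - 1.0) > 1e-6 or np.any(pi < 0):
            raise ValueError("codon_freqs must be 61 nonnegative values summing to 1")
    rates = pi[_CODON_J] * np.where(_CODON_TS, kappa, 1.0)
    rates = rates * np.where(_CODON_NONSYN, omega, 1.0)
    Q = np.zeros((61, 61))
    Q[_CODON_I, _CODON_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if mean_rate is None:
        Q = _normalize(Q, pi)
    else:
        Q = Q / mean_rate
    return SubstModel(
        states=SENSE_CODONS, Q=Q, pi=pi, kind="codon", kappa=kappa, omega=omega
    )


def codon_mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Mean rate -sum pi_i Q_ii of the *unnormalized* GY94 generator."""
    rates = pi[_CODON_J] * np.where(_CODON_TS, kappa, 1.0)
    rates = rates * np.where(_CODON_NONSYN, omega, 1.0)
    return float(np.sum(pi[_CODON_I] * rates))


def f3x4_frequencies(alignment: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    A small pseudocount keeps every codon frequency strictly positive even
    on degenerate alignments (zero frequencies break the reversible-model
    symmetrization).
    """
    counts = np.full((3, 4), float(pseudocount))
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for s in alignment.sequences:
        for k in range(0, len(s), 3):
            for pos in range(3):
                b = s[k + pos]
                if b in base_idx:
                    counts[pos, base_idx[b]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            probs[0, base_idx[c[0]]] * probs[1, base_idx[c[1]]] * probs[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def f61_frequencies(alignment: CodonAlignment, pseudocount: float = 0.1) -> np.ndarray:
    idx = alignment.to_indices()
    counts = np.bincount(idx[idx >= 0], minlength=61).astype(float) + pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Gamma rate heterogeneity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaRates:
    """Equal-probability discrete Gamma rate categories (bin means)."""

    alpha: float
    rates: np.ndarray
    probs: np.ndarray

    @property
    def K(self) -> int:
        return len(self.rates)


SINGLE_RATE = GammaRates(alpha=float("inf"), rates=np.array([1.0]), probs=np.array([1.0]))


def discretize_gamma(alpha: float, K: int) -> GammaRates:
    """K equal-probability categories of Gamma(alpha, mean 1), bin means."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return GammaRates(alpha=alpha, rates=np.array([1.0]), probs=np.array([1.0]))
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], alpha * edges, [np.inf]])
    cdf1 = special.gammainc(alpha + 1.0, cuts)  # regularized, handles inf
    rates = K * np.diff(cdf1)
    rates = rates / np.sum(rates / K)  # exact mean 1
    return GammaRates(alpha=alpha, rates=rates, probs=np.full(K, 1.0 / K))


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods plus the tables needed for posterior sampling."""

    per_site: np.ndarray        # (n_sites,)
    total: float
    partials: list              # per category: (n_nodes, n_sites, S) inside vectors
    trans: list                 # per category: (n_nodes, S, S) transition matrices
    per_site_by_cat: np.ndarray  # (K, n_sites) site likelihoods per category
    rates: GammaRates
    leaf_rows: np.ndarray       # alignment row per leaf node


def _leaf_partials(data: np.ndarray, n_states: int) -> np.ndarray:
    """(n_leaves, n_sites, S) one-hot partials; missing (-1) -> all ones."""
    n_leaves, n_sites = data.shape
    L = np.zeros((n_leaves, n_sites, n_states))
    missing = data < 0
    obs = ~missing
    L[np.where(obs)[0], np.where(obs)[1], data[obs]] = 1.0
    L[missing] = 1.0
    return L


def _pruning_pass(tree: Phylogeny, leafL: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Inside vectors for one rate category.  P: (n_nodes, S, S)."""
    n_sites, S = leafL.shape[1], leafL.shape[2]
    L = np.empty((tree.n_nodes, n_sites, S))
    L[: tree.n_leaves] = leafL
    for v in tree.postorder:
        if v < tree.n_leaves:
            continue
        acc = None
        for c in tree.children[v]:
            msg = L[c] @ P[c].T
            acc = msg if acc is None else acc * msg
        L[v] = acc
    return L


def site_log_likelihood(
    alignment, tree: Phylogeny, model: SubstModel, rates: GammaRates = SINGLE_RATE
) -> SiteLikelihoods:
    """Felsenstein pruning per site, mixed over Gamma rate categories."""
    tree.check_taxa(alignment)
    data = alignment.to_indices()
    rows = tree.leaf_order_for(alignment)
    return _site_log_likelihood_idx(data[rows], tree, model, rates, leaf_rows=rows)


def _site_log_likelihood_idx(
    leaf_data: np.ndarray,
    tree: Phylogeny,
    model: SubstModel,
    rates: GammaRates = SINGLE_RATE,
    leaf_rows: np.ndarray = None,
) -> SiteLikelihoods:
    """Same as :func:`site_log_likelihood` on leaf-ordered index data."""
    S = model.n_states
    leafL = _leaf_partials(leaf_data, S)
    partials, trans, percat = [], [], []
    for r in rates.rates:
        P = model.transition_matrices(tree.branch_lengths * r)
        L = _pruning_pass(tree, leafL, P)
        partials.append(L)
        trans.append(P)
        percat.append(L[tree.root] @ model.pi)
    percat = np.array(percat)  # (K, n_sites)
    site_lik = rates.probs @ percat
    per_site = np.log(np.clip(site_lik, 1e-300, None))
    if leaf_rows is None:
        leaf_rows = np.arange(tree.n_leaves)
    return SiteLikelihoods(
        per_site=per_site,
        total=float(per_site.sum()),
        partials=partials,
        trans=trans,
        per_site_by_cat=percat,
        rates=rates,
        leaf_rows=leaf_rows,
    )


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

_BL_MIN, _BL_MAX = 1e-8, 20.0


def _edge_loglik(O_k, L_k, model, rates, t):
    """log-likelihood as a function of one branch length.

    O_k/L_k: per-category outside (parent-end) and inside (child-end)
    vectors for the edge, each (n_sites, S).
    """
    total = None
    for k, r in enumerate(rates.rates):
        P = model.transition_matrix(t * r)
        lk = np.einsum("ns,ns->n", O_k[k], L_k[k] @ P.T)
        total = rates.probs[k] * lk if total is None else total + rates.probs[k] * lk
    return float(np.log(np.clip(total, 1e-300, None)).sum())


def optimize_branch_lengths(
    tree: Phylogeny,
    alignment,
    model: SubstModel,
    rates: GammaRates = SINGLE_RATE,
    sweeps: int = 3,
    tol: float = 1e-6,
) -> Phylogeny:
    """Coordinate-wise Brent optimization of every branch length.

    Each sweep recomputes inside vectors, then walks the tree in preorder
    maximizing the likelihood of each edge with the other branches fixed.
    The returned tree's likelihood never falls below the input's.
    """
    tree.check_taxa(alignment)
    data = alignment.to_indices()[tree.leaf_order_for(alignment)]
    out = tree.copy()
    S = model.n_states
    leafL = _leaf_partials(data, S)
    K = rates.K

    def full_ll(t: Phylogeny) -> float:
        return _site_log_likelihood_idx(data, t, model, rates).total

    ll_in = full_ll(out)
    best = out.copy()
    best_ll = ll_in
    for _ in range(sweeps):
        prev = full_ll(out)
        # inside vectors and messages per category
        P = [model.transition_matrices(out.branch_lengths * r) for r in rates.rates]
        L = [_pruning_pass(out, leafL, P[k]) for k in range(K)]
        M = [
            {c: L[k][c] @ P[k][c].T for c in range(out.n_nodes) if c != out.root}
            for k in range(K)
        ]
        O = [dict() for _ in range(K)]
        for v in out.preorder:
            if v == out.root:
                continue
            p = out.parent[v]
            for k in range(K):
                if p == out.root:
                    base = np.broadcast_to(model.pi, L[k][p].shape).copy()
                else:
                    base = O[k][p] @ P[k][p]
                for sib in out.children[p]:
                    if sib != v:
                        base = base * M[k][sib]
                O[k][v] = base
            Ok = [O[k][v] for k in range(K)]
            Lk = [L[k][v] for k in range(K)]

            res = minimize_scalar(
                lambda t: -_edge_loglik(Ok, Lk, model, rates, t),
                bounds=(_BL_MIN, _BL_MAX),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if -res.fun >= _edge_loglik(Ok, Lk, model, rates, out.branch_lengths[v]):
                out.branch_lengths[v] = float(res.x)
                for k in range(K):
                    P[k][v] = model.transition_matrix(out.branch_lengths[v] * rates.rates[k])
                    M[k][v] = L[k][v] @ P[k][v].T
        cur = full_ll(out)
        if cur > best_ll:
            best_ll = cur
            best = out.copy()
        if cur - prev < tol:
            break
    return best if best_ll >= ll_in else tree.copy()


def fit_gamma_shape(
    alignment, tree: Phylogeny, model: SubstModel, K: int = 4,
    bounds=(0.05, 50.0),
) -> float:
    """ML estimate of the Gamma shape on a fixed tree (1-D Brent)."""
    tree.check_taxa(alignment)
    data = alignment.to_indices()[tree.leaf_order_for(alignment)]

    def nll(log_alpha):
        rates = discretize_gamma(float(np.exp(log_alpha)), K)
        return -_site_log_likelihood_idx(data, tree, model, rates).total

    res = minimize_scalar(
        nll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Simulation along a tree (shared by synthdata and the parametric bootstrap)
# ---------------------------------------------------------------------------


def _sample_rows(P_rows: np.ndarray, rng) -> np.ndarray:
    """Sample one category per row of a stochastic matrix (n, S)."""
    c = np.cumsum(P_rows, axis=1)
    u = rng.random(P_rows.shape[0]) * c[:, -1]
    return (c < u[:, None]).sum(axis=1)


def simulate_states(
    tree: Phylogeny,
    model: SubstModel,
    n_sites: int,
    rng: np.random.Generator,
    site_rates: np.ndarray = None,
) -> np.ndarray:
    """Simulate leaf states site-by-site down the tree.

    ``site_rates`` (n_sites,) multiplies branch lengths per site (Gamma
    categories); default all 1.  Returns (n_leaves, n_sites) state indices.
    """
    if site_rates is None:
        site_rates = np.ones(n_sites)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = _sample_rows(
        np.broadcast_to(model.pi, (n_sites, model.n_states)), rng
    )
    groups = {}
    for s, r in enumerate(site_rates):
        groups.setdefault(float(r), []).append(s)
    for v in tree.preorder:
        if v == tree.root:
            continue
        for r, sites in groups.items():
            sites = np.asarray(sites)
            P = model.transition_matrix(tree.branch_lengths[v] * r)
            states[v, sites] = _sample_rows(P[states[tree.parent[v], sites]], rng)
    return states[: tree.n_leaves]


def indices_to_protein(leaf_states: np.ndarray, labels) -> ProteinAlignment:
    seqs = ["".join(AMINO_ACIDS[i] for i in row) for row in leaf_states]
    return ProteinAlignment(list(labels), seqs)


def indices_to_codon(leaf_states: np.ndarray, labels) -> CodonAlignment:
    seqs = ["".join(SENSE_CODONS[i] for i in row) for row in leaf_states]
    return CodonAlignment(list(labels), seqs)
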