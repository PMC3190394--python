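"""Coevolving-site detection from property-weighted substitution mapping.

Pipeline per alignment: fit an empirical amino-acid model (WAG/LG) with
discrete-Gamma rates and ML branch lengths; sample joint substitution
histories per site from their posterior distribution (backward sampling of
ancestral states, then endpoint-conditioned path sampling by
uniformization); summarize each site as a vector over branches of
property-weighted substitution amounts (posterior mean over samples);
cluster sites by complete linkage on the correlation distance, treating
every dendrogram node as a candidate group with statistic rho = 1 - merge
height; and assess candidates against a parametric-bootstrap null of
independent evolution, conditioning p-values on the group's minimum site
variability N_min.  A bootstrap-based multiple-testing correction tightens
the significance threshold until the estimated false-discovery rate is at
most the nominal level.

Two modes are available: "correlated" (co-substitution: weights are
absolute property changes, or Grantham distances) and "compensatory"
(signed property changes; a group is compensatory when its vectors cancel,
measured by d = ||sum v_i|| / sum ||v_i||, statistic 1 - d).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import evomodel as em
from .properties import PropertyScale, PROPERTY_NAMES

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionSample:
    """One posterior draw of the substitution history at one site:
    per-branch ordered (from_state, to_state) event lists, keyed by the
    child node of the branch."""

    site: int
    events: dict

    def total_events(self) -> int:
        return sum(len(v) for v in self.events.values())


@dataclass
class WeightedVector:
    """Per-branch property-weighted substitution amounts for one site
    (posterior mean over samples); N is the posterior-mean unweighted
    substitution count."""

    site: int
    property_name: str
    mode: str
    vector: np.ndarray
    N: float


@dataclass
class CoevolGroup:
    """Candidate (or significant) group of coevolving sites."""

    sites: tuple
    property_name: str
    mode: str
    rho: float
    n_min: float
    p_value: float = float("nan")
    significant: bool = False


@dataclass
class NullDistribution:
    """Joint bootstrap null of (N_min, rho) over candidate groups."""

    n_min: np.ndarray
    rho: np.ndarray
    replicate: np.ndarray  # replicate index of each entry
    n_replicates: int

    def __len__(self):
        return len(self.rho)


@dataclass
class CoevolConfig:
    """Tunable parameters of the detection chain (defaults follow common
    practice for this method: WAG, 4 Gamma categories, 100 posterior draws
    per site, 1000 bootstrap replicates, 5% significance)."""

    aa_model: str = "wag"
    gamma_categories: int = 4
    fit_gamma_shape: bool = True
    optimize_branches: bool = True
    n_samples: int = 100
    n_bootstrap: int = 1000
    alpha: float = 0.05
    min_variability: float = 1.0
    modes: tuple = ("correlated",)
    nmin_pool_at: int = 10
    nmin_min_bin_count: int = 50
    seed: int = 0


@dataclass
class CoevolutionResult:
    """Everything the detection run produced, per property and mode."""

    groups: list                # all candidate CoevolGroup with p-values
    significant: list           # the significant subset
    null: dict                  # (property, mode) -> NullDistribution
    alpha_corrected: dict       # (property, mode) -> tightened threshold
    vectors: dict               # (property, mode) -> (V, N)
    tree: em.Phylogeny
    config: CoevolConfig

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "property": g.property_name,
                "mode": g.mode,
                "sites": ",".join(str(s + 1) for s in g.sites),
                "size": len(g.sites),
                "rho": g.rho,
                "n_min": g.n_min,
                "p_value": g.p_value,
                "significant": g.significant,
            }
            for g in self.groups
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Posterior sampling of substitution histories
# ---------------------------------------------------------------------------


def _poisson_pmf_table(mean: float, tol: float = 1e-12) -> np.ndarray:
    """Poisson pmf values 0..N where the truncated tail mass is < tol."""
    pmf = [np.exp(-mean)]
    n = 0
    cum = pmf[0]
    while cum < 1.0 - tol and n < 500:
        n += 1
        pmf.append(pmf[-1] * mean / n)
        cum += pmf[-1]
    return np.array(pmf)


def _sample_endpoint_paths(Q, t, a, b, P_t, rng, events_out, branch, sites, samples):
    """Uniformized endpoint-conditioned path sampling for one branch.

    a, b: (M,) endpoint state indices; appends events (branch, site, sample,
    from, to) to events_out lists.
    """
    S = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0 or t <= 0:
        return
    B = np.eye(S) + Q / mu
    mean_jumps = mu * t
    pmf = _poisson_pmf_table(mean_jumps)
    n_max = len(pmf) - 1
    # powers of B
    Bpow = np.empty((n_max + 1, S, S))
    Bpow[0] = np.eye(S)
    for n in range(1, n_max + 1):
        Bpow[n] = Bpow[n - 1] @ B
    # P(N = n | a, b) ~ pmf[n] * Bpow[n][a, b]
    w = pmf[:, None] * Bpow[:, a, b]  # (n_max+1, M)
    cw = np.cumsum(w, axis=0)
    u = rng.random(a.shape[0]) * cw[-1]
    njumps = (cw < u[None, :]).sum(axis=0)
    for n in np.unique(njumps):
        if n == 0:
            continue
        sel = np.where(njumps == n)[0]
        s_prev = a[sel]
        target = b[sel]
        for step in range(1, n + 1):
            if step == n:
                s_new = target
            else:
                p = B[s_prev] * Bpow[n - step][:, target].T  # (m, S)
                s_new = em._sample_rows(p, rng)
            changed = s_new != s_prev
            if np.any(changed):
                events_out[0].append(np.full(changed.sum(), branch))
                events_out[1].append(sites[sel[changed]])
                events_out[2].append(samples[sel[changed]])
                events_out[3].append(s_prev[changed])
                events_out[4].append(s_new[changed])
            s_prev = s_new


def _sample_histories_bulk(
    sl: em.SiteLikelihoods,
    tree: em.Phylogeny,
    model: em.SubstModel,
    n_samples: int,
    rng: np.random.Generator,
):
    """Joint posterior histories for all sites at once.

    Returns (events, n_entries) where events is a dict of flat arrays
    branch/site/sample/frm/to (branch = child-node index).
    """
    rates = sl.rates
    K = rates.K
    n_sites = sl.per_site.shape[0]
    M = n_sites * n_samples
    site_idx = np.repeat(np.arange(n_sites), n_samples)
    samp_idx = np.tile(np.arange(n_samples), n_sites)

    # 1. rate category per (site, sample) from the category posterior
    post_cat = (rates.probs[:, None] * sl.per_site_by_cat).T  # (n_sites, K)
    post_cat = post_cat / post_cat.sum(axis=1, keepdims=True)
    cats = em._sample_rows(post_cat[site_idx], rng)

    # 2. ancestral states by backward sampling, grouped by category
    states = np.empty((tree.n_nodes, M), dtype=np.int64)
    for k in range(K):
        sel = np.where(cats == k)[0]
        if sel.size == 0:
            continue
        L = sl.partials[k]
        P = sl.trans[k]
        sites_k = site_idx[sel]
        p_root = model.pi[None, :] * L[tree.root][sites_k]
        states[tree.root, sel] = em._sample_rows(p_root, rng)
        for v in tree.preorder:
            if v == tree.root:
                continue
            parent_states = states[tree.parent[v], sel]
            p = P[v][parent_states] * L[v][sites_k]
            states[v, sel] = em._sample_rows(p, rng)

    # 3. endpoint-conditioned paths per branch, grouped by category
    events_out = [[], [], [], [], []]
    for v in tree.nonroot_nodes():
        bl = tree.branch_lengths[v]
        if bl <= 0:
            continue
        for k in range(K):
            sel = np.where(cats == k)[0]
            if sel.size == 0:
                continue
            a = states[tree.parent[v], sel]
            b = states[v, sel]
            _sample_endpoint_paths(
                model.Q,
                bl * rates.rates[k],
                a,
                b,
                sl.trans[k][v],
                rng,
                events_out,
                v,
                site_idx[sel],
                samp_idx[sel],
            )
    if events_out[0]:
        events = {
            "branch": np.concatenate(events_out[0]),
            "site": np.concatenate(events_out[1]),
            "sample": np.concatenate(events_out[2]),
            "frm": np.concatenate(events_out[3]),
            "to": np.concatenate(events_out[4]),
        }
    else:
        empty = np.array([], dtype=np.int64)
        events = {k: empty for k in ("branch", "site", "sample", "frm", "to")}
    return events


def sample_substitution_histories(
    site: int,
    alignment,
    tree: em.Phylogeny,
    model: em.SubstModel,
    rates: em.GammaRates = em.SINGLE_RATE,
    n_samples: int = 100,
    seed: int = 0,
):
    """Posterior substitution histories for one alignment column.

    Returns a list of :class:`SubstitutionSample` (one per draw), each with
    per-branch chained event lists.
    """
    rng = np.random.default_rng(seed)
    sl = em.site_log_likelihood(alignment, tree, model, rates)
    sub = _slice_site(sl, site)
    events = _sample_histories_bulk(sub, tree, model, n_samples, rng)
    out = []
    for s in range(n_samples):
        mask = events["sample"] == s
        per_branch = {}
        for br, frm, to in zip(
            events["branch"][mask], events["frm"][mask], events["to"][mask]
        ):
            per_branch.setdefault(int(br), []).append((int(frm), int(to)))
        out.append(SubstitutionSample(site=site, events=per_branch))
    return out


def _slice_site(sl: em.SiteLikelihoods, site: int) -> em.SiteLikelihoods:
    return em.SiteLikelihoods(
        per_site=sl.per_site[site : site + 1],
        total=float(sl.per_site[site]),
        partials=[L[:, site : site + 1, :] for L in sl.partials],
        trans=sl.trans,
        per_site_by_cat=sl.per_site_by_cat[:, site : site + 1],
        rates=sl.rates,
        leaf_rows=sl.leaf_rows,
    )


# ---------------------------------------------------------------------------
# Weighted vectors and the correlation statistic
# ---------------------------------------------------------------------------


def weighted_vectors_bulk(events, n_sites, n_branch_nodes, n_samples, scale, mode):
    """(V, N): V (n_sites, n_nodes) posterior-mean weighted amounts per
    branch (indexed by child node; the root column stays zero), N
    (n_sites,) posterior-mean counts of *property-changing* events.

    N deliberately counts only events with nonzero weight: for the
    property-weighted statistic a site that substitutes freely but never
    changes the property carries no signal, and counting its neutral
    events as variability would admit near-zero vectors (single tiny
    posterior spikes) into the clustering, where they produce degenerate
    rho = 1 ties.  For the Grantham scale every amino-acid change has
    positive weight, so N coincides with the plain substitution count.
    """
    V = np.zeros((n_sites, n_branch_nodes))
    N = np.zeros(n_sites)
    if len(events["branch"]):
        w = scale.event_weights(events["frm"], events["to"], mode)
        np.add.at(V, (events["site"], events["branch"]), w)
        np.add.at(N, events["site"], (w != 0).astype(float))
    return V / n_samples, N / n_samples


def weighted_vector(
    samples, scale: PropertyScale, mode: str = "correlated", n_branches: int = None,
    branch_index: dict = None,
) -> WeightedVector:
    """Property-weighted substitution vector from per-site history samples.

    ``branch_index`` maps branch keys (child nodes) to vector positions;
    defaults to identity over 0..n_branches-1.
    """
    if not samples:
        raise ValueError("empty sample list")
    if n_branches is None:
        n_branches = 1 + max(
            (br for s in samples for br in s.events), default=0
        )
    if branch_index is None:
        branch_index = {b: b for b in range(n_branches)}
    vec = np.zeros(n_branches)
    total = 0.0
    for s in samples:
        for br, evts in s.events.items():
            for frm, to in evts:
                w = scale.event_weights(np.array([frm]), np.array([to]), mode)[0]
                vec[branch_index[br]] += w
                total += float(w != 0)
    return WeightedVector(
        site=samples[0].site,
        property_name=scale.name,
        mode=mode,
        vector=vec / len(samples),
        N=total / len(samples),
    )


def correlation_statistic(v1: WeightedVector, v2: WeightedVector) -> float:
    """Pearson correlation of two weighted substitution vectors across
    branches; nan if either vector is constant."""
    if v1.vector.shape != v2.vector.shape:
        raise ValueError("vectors cover different branch sets")
    if v1.property_name != v2.property_name or v1.mode != v2.mode:
        raise ValueError("vectors use different properties or modes")
    if np.std(v1.vector) == 0 or np.std(v2.vector) == 0:
        return float("nan")
    return float(np.corrcoef(v1.vector, v2.vector)[0, 1])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _compensation_distance_matrix(V: np.ndarray) -> np.ndarray:
    """d(i,j) = ||v_i + v_j|| / (||v_i|| + ||v_j||) on signed vectors."""
    norms = np.linalg.norm(V, axis=1)
    n = V.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        s = np.linalg.norm(V[i][None, :] + V[i + 1 :], axis=1)
        D[i, i + 1 :] = s / (norms[i] + norms[i + 1 :])
    return D + D.T


def cluster_candidates(
    V: np.ndarray,
    N: np.ndarray,
    property_name: str,
    mode: str = "correlated",
    min_variability: float = 1.0,
) -> list:
    """Complete-linkage candidate groups from weighted vectors.

    Correlated mode: distance 1 - Pearson rho.  Compensatory mode: the
    vector-cancellation distance.  Every internal dendrogram node yields a
    candidate with rho = 1 - complete-linkage height (the worst pairwise
    distance within the group) and N_min = min member N.  Sites with N
    below ``min_variability`` (or constant vectors in correlated mode) are
    excluded.

    Exact distance ties are common (sites whose substitutions concentrate
    on a single shared branch correlate exactly); the merge order among
    ties is broken deterministically in favor of pairs with higher minimum
    site variability, so an informative pair is not swallowed into a mixed
    low-variability clique before it can become a candidate.  The reported
    rho always comes from the raw distances.
    """
    keep = N >= min_variability
    if mode == "correlated":
        keep &= V.std(axis=1) > 0
    sites = np.where(keep)[0]
    if len(sites) < 2:
        return []
    Vk = V[sites]
    if mode == "correlated":
        C = np.corrcoef(Vk)
        D = 1.0 - C
    elif mode == "compensatory":
        D = _compensation_distance_matrix(Vk)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Nk = N[sites]
    pair_nmin = np.minimum(Nk[:, None], Nk[None, :])
    D_used = D + 1e-6 / (1.0 + pair_nmin)
    np.fill_diagonal(D_used, 0.0)
    Z = linkage(squareform(D_used, checks=False), method="complete")
    members = {i: [i] for i in range(len(sites))}
    out = []
    for step, (a, b, _, _) in enumerate(Z):
        group = members[int(a)] + members[int(b)]
        members[len(sites) + step] = group
        gsites = tuple(int(sites[g]) for g in sorted(group))
        idx = [int(g) for g in group]
        height = float(D[np.ix_(idx, idx)].max())
        out.append(
            CoevolGroup(
                sites=gsites,
                property_name=property_name,
                mode=mode,
                rho=float(1.0 - height),
                n_min=float(N[list(gsites)].min()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Parametric bootstrap null and p-values
# ---------------------------------------------------------------------------


def _candidates_for_states(
    leaf_states, tree, model, rates, n_samples, scales_modes, min_variability, rng
):
    """Sampling + weighting + clustering for one (possibly simulated)
    alignment given leaf state indices.  Returns {(prop, mode): candidates}."""
    sl = em._site_log_likelihood_idx(leaf_states, tree, model, rates)
    events = _sample_histories_bulk(sl, tree, model, n_samples, rng)
    n_sites = leaf_states.shape[1]
    out = {}
    for scale, mode in scales_modes:
        V, N = weighted_vectors_bulk(
            events, n_sites, tree.n_nodes, n_samples, scale, mode
        )
        out[(scale.name, mode)] = cluster_candidates(
            V, N, scale.name, mode, min_variability
        )
    return out


def null_distribution(
    tree: em.Phylogeny,
    model: em.SubstModel,
    rates: em.GammaRates,
    n_sites: int,
    properties=("charge",),
    modes=("correlated",),
    n_samples: int = 100,
    n_reps: int = 1000,
    seed: int = 0,
    min_variability: float = 1.0,
) -> dict:
    """Parametric-bootstrap null of (N_min, rho) over candidate groups.

    Each replicate simulates ``n_sites`` independent sites under the fitted
    model (with Gamma rates drawn per site), reruns sampling + weighting +
    clustering, and records every candidate.  Returns
    {(property, mode): NullDistribution}.
    """
    rng = np.random.default_rng(seed)
    scales_modes = [
        (PropertyScale.get(p), m) for p in properties for m in modes
        if not (p == "grantham" and m == "compensatory")
    ]
    acc = {
        (sc.name, m): {"n_min": [], "rho": [], "rep": []} for sc, m in scales_modes
    }
    for rep in range(n_reps):
        cat = rng.integers(rates.K, size=n_sites)
        leaf_states = em.simulate_states(
            tree, model, n_sites, rng, site_rates=rates.rates[cat]
        )
        cands = _candidates_for_states(
            leaf_states, tree, model, rates, n_samples, scales_modes,
            min_variability, rng,
        )
        for key, groups in cands.items():
            for g in groups:
                if np.isfinite(g.rho):
                    acc[key]["n_min"].append(g.n_min)
                    acc[key]["rho"].append(g.rho)
                    acc[key]["rep"].append(rep)
    return {
        key: NullDistribution(
            n_min=np.array(d["n_min"]),
            rho=np.array(d["rho"]),
            replicate=np.array(d["rep"], dtype=np.int64),
            n_replicates=n_reps,
        )
        for key, d in acc.items()
    }


def _nmin_bin(n_min, pool_at: int = 10):
    return np.minimum(np.round(np.asarray(n_min)).astype(int), pool_at)


def _bin_edges(null_nmin, pool_at: int = 10, min_count: int = 50) -> np.ndarray:
    """Lower bounds of adaptive N_min conditioning bins.

    Starts from integer-rounded bins (pooled above ``pool_at``) and merges
    sparse bins downward until every bin holds at least ``min_count`` null
    entries, so the conditional p-value floor 1/(bin size + 1) stays
    meaningfully small at desk-scale bootstrap sizes.
    """
    ints = _nmin_bin(null_nmin, pool_at)
    counts = np.bincount(ints, minlength=pool_at + 1)
    edges = []
    acc = 0
    for b in range(pool_at, -1, -1):
        acc += counts[b]
        if acc >= min_count or b == 0:
            edges.append(b)
            acc = 0
    return np.array(sorted(edges))


def _assign_bins(n_min, edges, pool_at: int = 10) -> np.ndarray:
    ints = _nmin_bin(n_min, pool_at)
    return np.clip(np.searchsorted(edges, ints, side="right") - 1, 0, None)


def group_pvalue(
    group: CoevolGroup, null: NullDistribution, pool_at: int = 10,
    min_bin_count: int = 50,
) -> float:
    """p = Pr(rho >= rho_obs | N_min) with a +1 pseudocount, conditioning
    on the integer-rounded N_min bin (values >= ``pool_at`` pooled).  Falls
    back to the nearest non-empty bin with a warning.

    Ties count against the candidate (>=, not >): candidate statistics are
    discrete at low site variability (e.g. exactly rho = 1 whenever two
    near-invariant sites change on a single shared branch), and a strict
    inequality would assign vanishing p-values to a common null outcome.
    """
    if len(null) == 0:
        raise ValueError("empty null distribution")
    edges = _bin_edges(null.n_min, pool_at, min_bin_count)
    bins = _assign_bins(null.n_min, edges, pool_at)
    target = int(_assign_bins([group.n_min], edges, pool_at)[0])
    sel = bins == target
    if not np.any(sel):
        available = np.unique(bins)
        nearest = int(available[np.argmin(np.abs(available - target))])
        warnings.warn(
            f"empty N_min bin {target}; falling back to nearest bin {nearest}"
        )
        sel = bins == nearest
    rho_null = null.rho[sel]
    return float((1 + np.sum(rho_null >= group.rho - 1e-12)) / (1 + rho_null.size))


def _fdr_threshold(p_obs: np.ndarray, null: NullDistribution, alpha: float,
                   pool_at: int = 10, min_bin_count: int = 50) -> float:
    """Bootstrap multiple-testing correction: tighten the threshold until
    the estimated FDR (mean null candidates per replicate at or below the
    threshold, over observed discoveries) is at most ``alpha``.

    Returns the corrected threshold (0 if nothing can be called).
    """
    if len(p_obs) == 0 or len(null) == 0:
        return 0.0
    # p-values of the null candidates against the pooled null itself
    edges = _bin_edges(null.n_min, pool_at, min_bin_count)
    bins = _assign_bins(null.n_min, edges, pool_at)
    p_null = np.empty(len(null))
    for b in np.unique(bins):
        sel = bins == b
        rho = null.rho[sel]
        rho_sorted = np.sort(rho)
        ge = rho.size - np.searchsorted(rho_sorted, rho - 1e-12, side="left")
        p_null[sel] = (1 + ge) / (1 + rho.size)
    for thr in np.sort(np.unique(p_obs))[::-1]:
        if thr > alpha:
            continue
        n_disc = int(np.sum(p_obs <= thr))
        e_fp = (
            np.bincount(null.replicate[p_null <= thr], minlength=null.n_replicates)
            .mean()
        )
        if e_fp / max(1, n_disc) <= alpha:
            return float(thr)
    return 0.0


# ---------------------------------------------------------------------------
# End-to-end detection
# ---------------------------------------------------------------------------


def detect_coevolution(
    alignment,
    tree: em.Phylogeny,
    properties=PROPERTY_NAMES,
    config: CoevolConfig = None,
) -> CoevolutionResult:
    """Full chain on one alignment: model fit, substitution mapping,
    clustering, bootstrap significance with FDR correction.

    ``alignment`` may be a codon alignment (translated internally) or a
    protein alignment.
    """
    config = config or CoevolConfig()
    if hasattr(alignment, "translate"):
        alignment = alignment.translate()
    tree.check_taxa(alignment)
    rng_master = np.random.SeedSequence(config.seed)
    s_hist, s_null = [int(s.generate_state(1)[0] % 2**31) for s in rng_master.spawn(2)]

    model = em.load_aa_model(config.aa_model)
    work_tree = tree.copy()
    if config.optimize_branches:
        work_tree = em.optimize_branch_lengths(work_tree, alignment, model)
    if config.fit_gamma_shape and config.gamma_categories > 1:
        alpha_hat = em.fit_gamma_shape(
            alignment, work_tree, model, K=config.gamma_categories
        )
        rates = em.discretize_gamma(alpha_hat, config.gamma_categories)
        if config.optimize_branches:
            work_tree = em.optimize_branch_lengths(
                work_tree, alignment, model, rates
            )
    else:
        rates = em.discretize_gamma(1.0, config.gamma_categories) \
            if config.gamma_categories > 1 else em.SINGLE_RATE

    data = alignment.to_indices()[work_tree.leaf_order_for(alignment)]
    sl = em._site_log_likelihood_idx(data, work_tree, model, rates)
    events = _sample_histories_bulk(
        sl, work_tree, model, config.n_samples, np.random.default_rng(s_hist)
    )

    scales_modes = [
        (PropertyScale.get(p), m)
        for p in properties
        for m in config.modes
        if not (p == "grantham" and m == "compensatory")
    ]
    vectors = {}
    observed = {}
    for scale, mode in scales_modes:
        V, N = weighted_vectors_bulk(
            events, alignment.n_sites, work_tree.n_nodes, config.n_samples,
            scale, mode,
        )
        vectors[(scale.name, mode)] = (V, N)
        observed[(scale.name, mode)] = cluster_candidates(
            V, N, scale.name, mode, config.min_variability
        )

    null = null_distribution(
        work_tree,
        model,
        rates,
        alignment.n_sites,
        properties=[p for p in properties],
        modes=config.modes,
        n_samples=config.n_samples,
        n_reps=config.n_bootstrap,
        seed=s_null,
        min_variability=config.min_variability,
    )

    groups, significant = [], []
    alpha_corrected = {}
    for key, cands in observed.items():
        nd = null[key]
        finite = [g for g in cands if np.isfinite(g.rho)]
        for g in finite:
            g.p_value = (
                group_pvalue(g, nd, config.nmin_pool_at, config.nmin_min_bin_count)
                if len(nd)
                else float("nan")
            )
        p_obs = np.array([g.p_value for g in finite])
        thr = (
            _fdr_threshold(p_obs, nd, config.alpha, config.nmin_pool_at,
                           config.nmin_min_bin_count)
            if len(nd)
            else 0.0
        )
        alpha_corrected[key] = thr
        for g in finite:
            g.significant = bool(g.p_value <= thr) if thr > 0 else False
            groups.append(g)
            if g.significant:
                significant.append(g)
    logger.info(
        "coevolution: %d candidates, %d significant", len(groups), len(significant)
    )
    return CoevolutionResult(
        groups=groups,
        significant=significant,
        null=null,
        alpha_corrected=alpha_corrected,
        vectors=vectors,
        tree=work_tree,
        config=config,
    )


def coevolving_site_union(result: CoevolutionResult, property_name: str = None):
    """Union of sites over significant groups (optionally one property)."""
    sites = set()
    for g in result.significant:
        if property_name is None or g.property_name == property_name:
            sites.update(g.sites)
    return sorted(sites)
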