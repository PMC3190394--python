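"""Site-specific codon-model positive-selection scan.

Fits the standard site-model family M0 (one ratio), M1a (nearly neutral),
M2a (positive selection), M3 (discrete, 3 classes), M7 (beta) and M8
(beta & omega) to a codon alignment on a fixed topology, runs the nested
likelihood-ratio tests (M0 vs M3, M1a vs M2a, M7 vs M8) and calls
positively selected sites by naive empirical Bayes (NEB) when the
corresponding LRT is significant.

Branch lengths are estimated by ML under M0 and then held fixed up to a
free tree-scale factor for the richer models; class rate matrices share a
joint normalization so that one unit of branch length is one expected
codon substitution under the fitted mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import evomodel as em

logger = logging.getLogger(__name__)

MODEL_NAMES = ("M0", "M1a", "M2a", "M3k3", "M7", "M8")
#: degrees of freedom of the recognized nested LRT pairs
LRT_DF = {("M0", "M3k3"): 4, ("M1a", "M2a"): 2, ("M7", "M8"): 2}
BETA_CATEGORIES = 10


@dataclass(frozen=True)
class CodonModelSpec:
    """Named member of the site-model family."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected {MODEL_NAMES}")

    @property
    def has_positive_class(self) -> bool:
        return self.name in ("M2a", "M3k3", "M8")


@dataclass
class SiteModelFit:
    """Maximized site-model fit."""

    spec: CodonModelSpec
    log_likelihood: float
    kappa: float
    tree_scale: float
    class_omegas: np.ndarray
    class_probs: np.ndarray
    extra: dict                      # model-specific parameters (p0, p, q, ...)
    site_class_lik: np.ndarray       # (n_sites, n_classes) likelihoods
    tree: em.Phylogeny
    converged: bool = True
    identifiability_warning: bool = False

    @property
    def n_params(self) -> int:
        return _N_FREE[self.spec.name] + 2  # + kappa + tree scale


_N_FREE = {"M0": 1, "M1a": 2, "M2a": 4, "M3k3": 5, "M7": 2, "M8": 4}


@dataclass
class LRTResult:
    null_name: str
    alt_name: str
    statistic: float  # 2 * delta log-likelihood
    df: int
    p_value: float


@dataclass
class SitePosteriors:
    """NEB posterior class memberships and positive-site calls."""

    class_omegas: np.ndarray
    posteriors: np.ndarray           # (n_sites, n_classes)
    positive_class: int | None
    positive_probability: np.ndarray  # (n_sites,) 0 when no positive class
    threshold: float
    positive_sites: list             # 0-based indices called at threshold


# ---------------------------------------------------------------------------
# Mixture likelihood machinery
# ---------------------------------------------------------------------------


def _mixture_models(kappa, omegas, probs, pi):
    """Per-class SubstModels with a joint mixture normalization."""
    mus = np.array([em.codon_mean_rate(kappa, w, pi) for w in omegas])
    mean = float(np.dot(probs, mus))
    return [
        em.build_codon_model(kappa, float(w), pi, mean_rate=mean) for w in omegas
    ]


def _compress_columns(leaf_data: np.ndarray):
    """Unique site patterns with counts and the inverse site -> pattern map."""
    patterns, inverse, counts = np.unique(
        leaf_data.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T.copy(), inverse, counts


def _class_site_liks(leaf_data, tree, models, scale=1.0):
    """(n_sites, n_classes) per-site likelihoods, pruning all classes in
    one batched pass over unique site patterns."""
    work = tree.scale(scale) if scale != 1.0 else tree
    C = len(models)
    S = models[0].n_states
    npat = leaf_data.shape[1]
    bl = work.branch_lengths
    P = np.stack([m.transition_matrices(bl) for m in models])  # (C, nodes, S, S)
    leafL = em._leaf_partials(leaf_data, S)                    # (leaves, npat, S)
    L = np.empty((C, work.n_nodes, npat, S))
    L[:, : work.n_leaves] = leafL[None, :, :, :]
    for v in work.postorder:
        if v < work.n_leaves:
            continue
        acc = None
        for c in work.children[v]:
            msg = np.matmul(L[:, c], np.swapaxes(P[:, c], 1, 2))
            acc = msg if acc is None else acc * msg
        L[:, v] = acc
    pis = np.stack([m.pi for m in models])
    out = np.einsum("cns,cs->nc", L[:, work.root], pis)
    return out  # (npat, C)


def _mixture_loglik(leaf_data, tree, kappa, omegas, probs, pi, scale,
                    pattern_counts=None):
    L = _class_site_liks(leaf_data, tree, _mixture_models(kappa, omegas, probs, pi), scale)
    mix = L @ np.asarray(probs)
    logs = np.log(np.clip(mix, 1e-300, None))
    if pattern_counts is None:
        return float(logs.sum()), L
    return float(np.dot(pattern_counts, logs)), L


def discretize_beta(p: float, q: float, K: int = BETA_CATEGORIES) -> np.ndarray:
    """K equal-probability bin means of Beta(p, q) (omega values in [0,1])."""
    edges = stats.beta.ppf(np.arange(K + 1) / K, p, q)
    upper = special.betainc(p + 1.0, q, edges)
    means = (p / (p + q)) * np.diff(upper) * K
    return np.clip(means, 1e-8, 1.0)


# parameter transforms: all free parameters live on the real line
def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-8, 1 - 1e-8)
    return np.log(p / (1 - p))


def _stick(break_xs):
    """Stick-breaking: k real values -> k+1 proportions."""
    probs = []
    rest = 1.0
    for x in break_xs:
        f = _sigmoid(x)
        probs.append(rest * f)
        rest *= 1.0 - f
    probs.append(rest)
    return np.array(probs)


def _unpack(name, x):
    """Transform the free-parameter vector to (kappa, scale, omegas, probs,
    extra) for the given model."""
    kappa = float(np.exp(x[0]))
    scale = float(np.exp(x[1]))
    r = x[2:]
    if name == "M0":
        w = float(np.exp(r[0]))
        return kappa, scale, np.array([w]), np.array([1.0]), {}
    if name == "M1a":
        w0 = float(_sigmoid(r[0]))
        p0 = float(_sigmoid(r[1]))
        return kappa, scale, np.array([w0, 1.0]), np.array([p0, 1 - p0]), {"p0": p0}
    if name == "M2a":
        w0 = float(_sigmoid(r[0]))
        w2 = float(1.0 + np.exp(r[1]))
        probs = _stick(r[2:4])
        return kappa, scale, np.array([w0, 1.0, w2]), probs, {}
    if name == "M3k3":
        ws = np.sort(np.exp(r[0:3]))
        probs = _stick(r[3:5])
        return kappa, scale, ws, probs, {}
    if name == "M7":
        p, q = float(np.exp(r[0])), float(np.exp(r[1]))
        ws = discretize_beta(p, q)
        K = len(ws)
        return kappa, scale, ws, np.full(K, 1.0 / K), {"p": p, "q": q}
    if name == "M8":
        p, q = float(np.exp(r[0])), float(np.exp(r[1]))
        ws_beta = discretize_beta(p, q)
        w_s = float(1.0 + np.exp(r[2]))
        p0 = float(_sigmoid(r[3]))
        K = len(ws_beta)
        ws = np.append(ws_beta, w_s)
        probs = np.append(np.full(K, p0 / K), 1 - p0)
        return kappa, scale, ws, probs, {"p": p, "q": q, "p0": p0}
    raise ValueError(name)


def _starts(name, kappa0=2.0):
    """Multi-start points: the omega-pattern starts 0.1 / 1 / 3."""
    base = [np.log(kappa0), 0.0]
    if name == "M0":
        return [base + [np.log(w)] for w in (0.1, 1.0, 3.0)]
    if name == "M1a":
        return [base + [_logit(w), _logit(0.7)] for w in (0.1, 0.5, 0.9)]
    if name == "M2a":
        return [
            base + [_logit(0.1), np.log(w2 - 1.0), _logit(0.6), _logit(0.75)]
            for w2 in (1.5, 2.0, 4.0)
        ]
    if name == "M3k3":
        return [
            base + list(np.log(ws)) + [_logit(0.5), _logit(0.5)]
            for ws in ([0.1, 0.5, 1.0], [0.1, 1.0, 3.0], [0.5, 1.0, 2.0])
        ]
    if name == "M7":
        return [base + [np.log(p), np.log(q)] for p, q in ((0.5, 2.0), (1.0, 1.0), (2.0, 0.5))]
    if name == "M8":
        return [
            base + [np.log(0.5), np.log(2.0), np.log(w2 - 1.0), _logit(0.9)]
            for w2 in (1.5, 2.0, 4.0)
        ]
    raise ValueError(name)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _optimize_m0_branches(alignment, tree, pi, kappa0=2.0):
    """Branch lengths (and a first kappa/omega look) under M0."""
    x0 = np.array([np.log(kappa0), np.log(0.3)])
    data = alignment.to_indices()[tree.leaf_order_for(alignment)]

    def nll(x):
        kappa, w = np.exp(x)
        model = em.build_codon_model(float(kappa), float(w), pi)
        return -em._site_log_likelihood_idx(data, tree, model).total

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-3, "maxfev": 120})
    kappa, w = np.exp(res.x)
    model = em.build_codon_model(float(kappa), float(w), pi)
    out = em.optimize_branch_lengths(tree, alignment, model, sweeps=2)
    return out, float(kappa), float(w)


def _embedding_start(name: str, null_fit: "SiteModelFit"):
    """Start vector embedding a fitted null model inside its alternative,
    guaranteeing the nested likelihood ordering up to optimizer noise."""
    k, s = np.log(null_fit.kappa), np.log(null_fit.tree_scale)
    if name == "M2a" and null_fit.spec.name == "M1a":
        w0 = float(null_fit.class_omegas[0])
        p0 = float(null_fit.class_probs[0])
        return [k, s, _logit(w0), np.log(0.001), _logit(p0), _logit(0.999)]
    if name == "M3k3" and null_fit.spec.name == "M0":
        w = max(float(null_fit.class_omegas[0]), 1e-4)
        return [k, s, np.log(w * 0.99), np.log(w), np.log(w * 1.01),
                _logit(0.34), _logit(0.5)]
    if name == "M8" and null_fit.spec.name == "M7":
        return [k, s, np.log(null_fit.extra["p"]), np.log(null_fit.extra["q"]),
                np.log(0.001), _logit(0.999)]
    return None


def fit_site_model(
    alignment: em.CodonAlignment,
    tree: em.Phylogeny,
    spec: CodonModelSpec | str,
    codon_freqs: str | np.ndarray = "f3x4",
    optimize_branches: bool = True,
    starts: int = 3,
    maxfev: int = 400,
    extra_starts: list = None,
) -> SiteModelFit:
    """ML fit of one site model.

    ``codon_freqs`` is "f3x4" (default), "f61", "uniform" or an explicit
    61-vector.  Branch lengths are optimized under M0 (then scaled by a
    free factor for richer models); pass ``optimize_branches=False`` to
    keep the input lengths.
    """
    if isinstance(spec, str):
        spec = CodonModelSpec(spec)
    tree.check_taxa(alignment)
    pi = _resolve_freqs(codon_freqs, alignment)
    data = alignment.to_indices()[tree.leaf_order_for(alignment)]

    # degenerate data: no variation -> omega unidentifiable
    observed = [np.unique(col[col >= 0]) for col in data.T]
    if all(len(o) <= 1 for o in observed):
        logger.warning("alignment has no variable codon columns; "
                       "omega is unidentifiable")
        ident_warn = True
    else:
        ident_warn = False

    if optimize_branches:
        work_tree, kappa0, _ = _optimize_m0_branches(alignment, tree, pi)
    else:
        work_tree, kappa0 = tree.copy(), 2.0

    patterns, inverse, counts = _compress_columns(data)

    def nll(x):
        kappa, scale, omegas, probs, _ = _unpack(spec.name, x)
        if not np.isfinite(kappa) or kappa > 1e3 or scale > 1e3:
            return 1e12
        ll, _ = _mixture_loglik(patterns, work_tree, kappa, omegas, probs, pi,
                                scale, pattern_counts=counts)
        return -ll

    # short exploration from each omega-pattern start, then polish the best
    explored = []
    for x0 in _starts(spec.name, kappa0)[:starts] + list(extra_starts or []):
        r = optimize.minimize(
            nll, np.array(x0), method="L-BFGS-B",
            options={"maxiter": 20, "eps": 1e-5},
        )
        explored.append((r.fun, tuple(r.x)))
    explored.sort()
    res = optimize.minimize(
        nll, np.array(explored[0][1]), method="L-BFGS-B",
        options={"maxiter": max(40, maxfev // 10), "eps": 1e-5, "ftol": 1e-11},
    )
    if not np.isfinite(res.fun) or res.fun > min(e[0] for e in explored):
        res = optimize.minimize(
            nll, np.array(explored[0][1]), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxfev": maxfev},
        )
    kappa, scale, omegas, probs, extra = _unpack(spec.name, res.x)
    ll, pat_lik = _mixture_loglik(patterns, work_tree, kappa, omegas, probs, pi,
                                  scale, pattern_counts=counts)
    site_lik = pat_lik[inverse]
    return SiteModelFit(
        spec=spec,
        log_likelihood=ll,
        kappa=kappa,
        tree_scale=scale,
        class_omegas=omegas,
        class_probs=probs,
        extra=extra,
        site_class_lik=site_lik,
        tree=work_tree.scale(scale),
        converged=bool(res.success or res.fun < 1e11),
        identifiability_warning=ident_warn,
    )


def _resolve_freqs(codon_freqs, alignment):
    if isinstance(codon_freqs, str):
        if codon_freqs == "f3x4":
            return em.f3x4_frequencies(alignment)
        if codon_freqs == "f61":
            return em.f61_frequencies(alignment)
        if codon_freqs == "uniform":
            return np.full(61, 1.0 / 61)
        raise ValueError(f"unknown codon_freqs {codon_freqs!r}")
    return np.asarray(codon_freqs, dtype=float)


def fit_model_set(
    alignment,
    tree,
    models=("M0", "M1a", "M2a", "M7", "M8"),
    codon_freqs="f3x4",
    starts: int = 3,
    maxfev: int = 400,
) -> dict:
    """Fit several site models sharing one M0 branch-length estimate."""
    pi = _resolve_freqs(codon_freqs, alignment)
    work_tree, _, _ = _optimize_m0_branches(alignment, tree, pi)
    nulls = {"M2a": "M1a", "M3k3": "M0", "M8": "M7"}
    fits = {}
    for name in models:
        extra = []
        null_name = nulls.get(name)
        if null_name in fits:
            e = _embedding_start(name, fits[null_name])
            if e is not None:
                extra.append(e)
        fits[name] = fit_site_model(
            alignment, work_tree, name, codon_freqs=pi,
            optimize_branches=False, starts=starts, maxfev=maxfev,
            extra_starts=extra,
        )
    return fits


# ---------------------------------------------------------------------------
# LRT and NEB
# ---------------------------------------------------------------------------


def lrt(null_fit: SiteModelFit, alt_fit: SiteModelFit) -> LRTResult:
    """Likelihood-ratio test of a recognized nested model pair."""
    pair = (null_fit.spec.name, alt_fit.spec.name)
    if pair not in LRT_DF:
        raise ValueError(f"unrecognized nested pair {pair}; known: {list(LRT_DF)}")
    stat = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if stat < -1e-6:
        logger.warning(
            "alternative model fit below null (2*dlnL = %.3g); check convergence",
            stat,
        )
    stat = max(stat, 0.0)
    df = LRT_DF[pair]
    return LRTResult(
        null_name=pair[0],
        alt_name=pair[1],
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def neb_posteriors(fit: SiteModelFit, threshold: float = 0.95) -> SitePosteriors:
    """Naive empirical Bayes site posteriors over omega classes.

    The positive-selection class is the class with omega > 1 (absent in
    M0/M1a/M7, in which case no site can be called).  The threshold is
    inclusive (>=).
    """
    prior = fit.class_probs
    w = fit.site_class_lik * prior[None, :]
    posteriors = w / np.clip(w.sum(axis=1, keepdims=True), 1e-300, None)
    positive = np.where(fit.class_omegas > 1.0)[0]
    if positive.size:
        pos_class = int(positive[-1])
        pos_prob = posteriors[:, positive].sum(axis=1)
        called = [int(s) for s in np.where(pos_prob >= threshold)[0]]
    else:
        pos_class, pos_prob, called = None, np.zeros(len(posteriors)), []
    return SitePosteriors(
        class_omegas=fit.class_omegas,
        posteriors=posteriors,
        positive_class=pos_class,
        positive_probability=pos_prob,
        threshold=threshold,
        positive_sites=called,
    )


def positive_sites(
    fit: SiteModelFit,
    lrt_result: LRTResult,
    alpha: float = 0.05,
    threshold: float = 0.95,
) -> list:
    """Positive-site calls gated on a significant LRT (0-based indices)."""
    if lrt_result.p_value > alpha:
        return []
    return neb_posteriors(fit, threshold).positive_sites


def read_site_list(source) -> list:
    """External positively-selected-site list (TSV with a ``site`` column,
    1-based reference numbering).  Returns 0-based indices."""
    df = pd.read_csv(source, sep="\t")
    if "site" not in df.columns:
        raise ValueError("site list must have a 'site' column (1-based)")
    return sorted(int(s) - 1 for s in df["site"])


def selection_report(fits: dict, lrts: list, posteriors: SitePosteriors = None):
    """Tidy DataFrames (models, LRTs, per-site posteriors) for output."""
    model_rows = [
        {
            "model": name,
            "log_likelihood": f.log_likelihood,
            "kappa": f.kappa,
            "tree_scale": f.tree_scale,
            "omegas": ",".join(f"{w:.4g}" for w in f.class_omegas),
            "proportions": ",".join(f"{p:.4g}" for p in f.class_probs),
        }
        for name, f in fits.items()
    ]
    lrt_rows = [
        {
            "null": r.null_name,
            "alt": r.alt_name,
            "stat_2dlnL": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
        }
        for r in lrts
    ]
    frames = {
        "models": pd.DataFrame(model_rows),
        "lrt": pd.DataFrame(lrt_rows),
    }
    if posteriors is not None:
        frames["sites"] = pd.DataFrame(
            {
                "site": np.arange(1, len(posteriors.positive_probability) + 1),
                "positive_posterior": posteriors.positive_probability,
                "called": [
                    s in set(posteriors.positive_sites)
                    for s in range(len(posteriors.positive_probability))
                ],
            }
        )
    return frames
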