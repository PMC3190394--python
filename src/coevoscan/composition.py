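"""Amino-acid composition, pairing-preference and secondary-structure stats.

Operates on arbitrary site sets (e.g. the union of coevolving sites, or
positively selected sites) pooled over one or many alignments: composition
tables with a chi-square test of independence against the background,
Pearson correlation of frequency vectors (with the conventional 0.8
similarity threshold reported alongside), 20x20 symmetric pairing matrices
for coevolving pairs, and helix/strand/coil enrichment with two-proportion
z-tests.

Counting conventions: gaps are never counted (neither as a 21st category
nor in totals); the pairing matrix counts one unordered amino-acid pair per
sequence per site pair, skipping pairs with a gap in either site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .properties import AMINO_ACIDS, AA_INDEX

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CompositionTable:
    """Amino-acid counts and frequencies of a pooled site set."""

    counts: np.ndarray  # (20,), alphabetical order
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20,) or np.any(self.counts < 0):
            raise ValueError("counts must be 20 nonnegative values")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(20)
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"amino_acid": list(AMINO_ACIDS), "count": self.counts.astype(int),
             "frequency": self.frequencies}
        )


class SSAnnotation:
    """Per-residue secondary-structure class in {H, E, C}, keyed by
    reference residue number (1-based)."""

    CLASSES = ("H", "E", "C")

    def __init__(self, classes: dict):
        for r, c in classes.items():
            if c not in self.CLASSES:
                raise ValueError(f"residue {r}: unknown class {c!r}")
        self.classes = dict(classes)

    def __len__(self):
        return len(self.classes)

    def __getitem__(self, residue: int) -> str:
        return self.classes[residue]

    def __contains__(self, residue: int) -> bool:
        return residue in self.classes

    @classmethod
    def from_tsv(cls, source) -> "SSAnnotation":
        df = pd.read_csv(source, sep="\t")
        return cls(dict(zip(df["residue_number"].astype(int), df["ss_class"])))

    def to_tsv(self) -> str:
        lines = ["residue_number\tss_class"]
        for r in sorted(self.classes):
            lines.append(f"{r}\t{self.classes[r]}")
        return "\n".join(lines) + "\n"


@dataclass
class PairingMatrix:
    """20x20 symmetric counts of coevolving residue pairs."""

    counts: np.ndarray
    property_label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (20, 20) or not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be a symmetric 20x20 matrix")

    @property
    def total(self) -> float:
        iu = np.triu_indices(20)
        return float(self.counts[iu].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
        )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def aa_composition(alignments, site_sets, label: str = "") -> CompositionTable:
    """Pooled amino-acid counts at the given sites of each alignment.

    ``alignments``: protein (or codon; translated) alignments.
    ``site_sets``: per-alignment iterable of 0-based site indices.
    Gaps and unknown characters are excluded from counts and totals.
    """
    counts = np.zeros(20)
    for aln, sites in zip(alignments, site_sets):
        aln = aln.translate() if hasattr(aln, "translate") else aln
        for s in sites:
            if not (0 <= s < aln.n_sites):
                raise ValueError(f"site index {s} out of range")
            for seq in aln.sequences:
                i = AA_INDEX.get(seq[s])
                if i is not None:
                    counts[i] += 1
    return CompositionTable(counts, label=label)


def _pool_rare(obs: np.ndarray, min_expected: float = 5.0):
    """Pool rarest categories of a 2xk table until all expected counts are
    at least ``min_expected``.  Returns the pooled table."""
    obs = obs.astype(float).copy()
    while obs.shape[1] > 2:
        colsum = obs.sum(axis=0)
        rowsum = obs.sum(axis=1)
        expected = np.outer(rowsum, colsum) / obs.sum()
        if expected.min() >= min_expected:
            break
        k = int(np.argmin(colsum))
        rest = np.delete(obs, k, axis=1)
        j = int(np.argmin(rest.sum(axis=0)))
        merged = rest.copy()
        merged[:, j] += obs[:, k]
        obs = merged
    return obs


def composition_chi2(
    subset: CompositionTable, background: CompositionTable, min_expected: float = 5.0
):
    """Chi-square test of independence of amino-acid counts between a site
    set and the background.  Rare amino acids are pooled until all expected
    counts reach ``min_expected``.  Returns (chi2, p)."""
    if subset.total == 0 or background.total == 0:
        raise ValueError("both tables must be non-empty")
    obs = np.vstack([subset.counts, background.counts])
    obs = obs[:, obs.sum(axis=0) > 0]
    obs = _pool_rare(obs, min_expected)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table after pooling")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def composition_correlation(f1: np.ndarray, f2: np.ndarray, threshold: float = 0.8):
    """Pearson correlation R of two 20-long frequency vectors plus the
    comparison against the conventional similarity threshold.

    Returns (R, "similar" | "different"); R is nan for a constant vector.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != (20,) or f2.shape != (20,):
        raise ValueError("expected two 20-long frequency vectors")
    if np.std(f1) < 1e-12 or np.std(f2) < 1e-12:
        return float("nan"), "undefined"
    r = float(np.corrcoef(f1, f2)[0, 1])
    return r, ("similar" if r >= threshold else "different")


# ---------------------------------------------------------------------------
# Pairing preference
# ---------------------------------------------------------------------------


def pairing_matrix(groups, alignments, property_label: str = "") -> PairingMatrix:
    """20x20 pairing counts of coevolving residue pairs.

    ``groups``: iterable of (alignment_index, site_indices) pairs; every
    group is expanded to all unordered site pairs; for each site pair and
    each sequence the observed unordered amino-acid pair increments the
    matrix (once per unordered pair, i.e. the diagonal counts A-A pairs
    singly).  Pairs with a gap in either site are skipped.
    """
    counts = np.zeros((20, 20))
    proteins = [
        aln.translate() if hasattr(aln, "translate") else aln for aln in alignments
    ]
    for aln_idx, sites in groups:
        aln = proteins[aln_idx]
        sites = sorted(sites)
        for a_pos in range(len(sites)):
            for b_pos in range(a_pos + 1, len(sites)):
                sa, sb = sites[a_pos], sites[b_pos]
                for seq in aln.sequences:
                    i = AA_INDEX.get(seq[sa])
                    j = AA_INDEX.get(seq[sb])
                    if i is None or j is None:
                        continue
                    lo, hi = min(i, j), max(i, j)
                    counts[lo, hi] += 1
    counts = counts + np.triu(counts, 1).T  # symmetrize; diagonal once
    return PairingMatrix(counts, property_label=property_label)


# ---------------------------------------------------------------------------
# Secondary-structure enrichment
# ---------------------------------------------------------------------------


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int):
    """Two-proportion z-test with pooled variance.  Returns (z, two-sided p)."""
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def ss_enrichment(site_set, annotation: SSAnnotation, background_sites) -> pd.DataFrame:
    """Helix/strand/coil proportions of a residue set vs a background set.

    Sites are reference residue numbers; every site must be annotated.
    Returns a DataFrame with one row per class: proportions, z statistic
    and two-sided p of the two-proportion test.
    """
    site_set = sorted(set(site_set))
    background_sites = sorted(set(background_sites))
    missing = [s for s in site_set + background_sites if s not in annotation]
    if missing:
        raise ValueError(f"unannotated residues: {sorted(set(missing))[:10]}")
    sub = [annotation[s] for s in site_set]
    bg = [annotation[s] for s in background_sites]
    rows = []
    for cls in SSAnnotation.CLASSES:
        k1 = sum(c == cls for c in sub)
        k2 = sum(c == cls for c in bg)
        if site_set == background_sites:
            z, p = 0.0, 1.0
        else:
            z, p = two_proportion_ztest(k1, len(sub), k2, len(bg))
        rows.append(
            {
                "ss_class": cls,
                "subset_count": k1,
                "subset_proportion": k1 / len(sub) if sub else float("nan"),
                "background_proportion": k2 / len(bg) if bg else float("nan"),
                "z": z,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
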