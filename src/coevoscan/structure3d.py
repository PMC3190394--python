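"""Residue center-of-mass distance analysis on protein structures.

Maps site sets onto single chains of PDB structures, computes mass-weighted
residue centers, pairwise center-of-mass distances (treating the residue
molecule as a whole rather than a single representative atom), per-pair
minima over conformational states (e.g. activated vs unactivated), a
one-sample Z-test comparing a site set's mean pair distance against the
chain background, and fixed-radius residue neighborhoods.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Structure reading
# ---------------------------------------------------------------------------

#: standard atomic masses by element symbol (crystal structures rarely
#: resolve hydrogens; they are excluded on reading)
def _atom_masses() -> dict:
    from Bio.Data import IUPACData

    return {el.upper(): w for el, w in IUPACData.atom_weights.items()}


ATOM_MASSES = _atom_masses()


@dataclass
class StructureModel:
    """One chain of one conformational state: per-residue atom records."""

    chain_id: str
    state: str
    residues: dict  # residue number -> list of (element, mass, xyz)

    @property
    def residue_numbers(self):
        return sorted(self.residues)

    def __len__(self):
        return len(self.residues)


@dataclass
class ResidueCOM:
    """Mass-weighted residue centers (Angstrom), keyed by residue number."""

    chain_id: str
    state: str
    centers: dict  # residue number -> np.ndarray (3,)

    @property
    def residue_numbers(self):
        return sorted(self.centers)

    def __getitem__(self, residue):
        return self.centers[residue]

    def __len__(self):
        return len(self.centers)


@dataclass
class DistanceSummary:
    """Pairwise distances for a set of residue pairs with summaries."""

    pairs: list            # list of (res_i, res_j)
    distances: np.ndarray  # (n_pairs,)
    label: str = ""

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("negative distance")
        if len(self.pairs) != len(self.distances):
            raise ValueError("pairs and distances differ in length")

    @property
    def mean(self):
        return float(np.mean(self.distances)) if len(self.distances) else float("nan")

    @property
    def median(self):
        return float(np.median(self.distances)) if len(self.distances) else float("nan")

    @property
    def sd(self):
        return float(np.std(self.distances, ddof=1)) if len(self.distances) > 1 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_i": [p[0] for p in self.pairs],
                "residue_j": [p[1] for p in self.pairs],
                "distance": self.distances,
            }
        )


def read_structure(pdb_text: str, chain: str = None, state: str = "") -> StructureModel:
    """Parse PDB ATOM records for one chain.

    Heteroatoms, waters and hydrogens are excluded; alternate locations are
    resolved to the highest-occupancy conformer.  ``chain=None`` takes the
    first chain in file order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )
    residues = {}
    for res in chains[chain].get_residues():
        hetflag, resseq, _ = res.get_id()
        if hetflag.strip():
            continue  # heteroatoms and waters
        atoms = []
        for atom in res.get_atoms():
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0)
            element = (atom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            if element not in ATOM_MASSES:
                raise ValueError(
                    f"unknown element {element!r} in atom {atom.get_full_id()}"
                )
            atoms.append((element, ATOM_MASSES[element], np.array(atom.coord, dtype=float)))
        if atoms:
            residues[int(resseq)] = atoms
    return StructureModel(chain_id=chain, state=state, residues=residues)


def residue_centers(structure: StructureModel) -> ResidueCOM:
    """Mass-weighted center of mass of every residue."""
    centers = {}
    for resnum, atoms in structure.residues.items():
        masses = np.array([m for _, m, _ in atoms])
        coords = np.array([xyz for _, _, xyz in atoms])
        centers[resnum] = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return ResidueCOM(chain_id=structure.chain_id, state=structure.state, centers=centers)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def pairwise_distances(coms: ResidueCOM, pairs="all", label: str = "") -> DistanceSummary:
    """Euclidean center-of-mass distances for residue pairs.

    ``pairs="all"``: every unordered pair within the chain.  An explicit
    pair list may reference residues missing from the structure; those
    pairs are excluded with a warning.
    """
    if pairs == "all":
        nums = coms.residue_numbers
        pts = np.array([coms[r] for r in nums])
        from scipy.spatial.distance import pdist

        d = pdist(pts)
        plist = [
            (nums[i], nums[j])
            for i in range(len(nums))
            for j in range(i + 1, len(nums))
        ]
        return DistanceSummary(pairs=plist, distances=d, label=label)
    kept, dists, missing = [], [], set()
    for i, j in pairs:
        if i not in coms.centers or j not in coms.centers:
            missing.update({r for r in (i, j) if r not in coms.centers})
            continue
        kept.append((i, j))
        dists.append(float(np.linalg.norm(coms[i] - coms[j])))
    if missing:
        warnings.warn(
            f"residues absent from structure, pairs excluded: {sorted(missing)}"
        )
    return DistanceSummary(pairs=kept, distances=np.array(dists), label=label)


def min_over_states(summaries: list, label: str = "") -> DistanceSummary:
    """Per-pair minimum distance across conformational states.

    Uses the intersection of the pair sets (with a warning when they
    differ); summaries are recomputed on the minima.
    """
    if not summaries:
        raise ValueError("no summaries given")
    pair_sets = [set(map(tuple, s.pairs)) for s in summaries]
    common = set.intersection(*pair_sets)
    if not common:
        raise ValueError("no residue pairs shared across states")
    if any(ps != common for ps in pair_sets):
        warnings.warn("pair sets differ across states; using the intersection")
    common = sorted(common)
    mins = []
    for pair in common:
        vals = []
        for s in summaries:
            idx = {tuple(p): k for k, p in enumerate(s.pairs)}
            vals.append(s.distances[idx[pair]])
        mins.append(min(vals))
    return DistanceSummary(pairs=list(common), distances=np.array(mins), label=label)


def proximity_ztest(subset: DistanceSummary, background: DistanceSummary):
    """One-sample Z-test of a site set's mean pair distance against the
    chain background.

    Z = (mean_subset - mean_background) / (sd_background / sqrt(n_subset)).
    Returns (Z, p_one_sided, p_two_sided, difference) where the one-sided
    p is for the subset being *closer* and difference = mean_background -
    mean_subset (positive when the subset is closer, as conventional for
    coevolving sites).
    """
    n = len(subset.distances)
    if n == 0:
        raise ValueError("empty subset")
    if len(background.distances) < 2:
        raise ValueError("background needs at least 2 pairs")
    if n == len(background.distances) and np.allclose(
        np.sort(subset.distances), np.sort(background.distances)
    ):
        return 0.0, 0.5, 1.0, 0.0
    z = (subset.mean - background.mean) / (background.sd / np.sqrt(n))
    p_one = float(stats.norm.cdf(z))
    p_two = float(2 * stats.norm.sf(abs(z)))
    return float(z), p_one, p_two, float(background.mean - subset.mean)


def neighbors_within(
    structure_or_coms, residue_number: int, radius: float, include_self: bool = False
):
    """Residues whose center of mass lies within ``radius`` Angstrom of the
    query residue's center (self excluded by default)."""
    coms = (
        structure_or_coms
        if isinstance(structure_or_coms, ResidueCOM)
        else residue_centers(structure_or_coms)
    )
    if residue_number not in coms.centers:
        raise ValueError(f"residue {residue_number} not in structure")
    ref = coms[residue_number]
    out = set()
    for r, xyz in coms.centers.items():
        if r == residue_number and not include_self:
            continue
        if np.linalg.norm(xyz - ref) <= radius:
            out.add(r)
    return sorted(out)


# ---------------------------------------------------------------------------
# Alignment-to-structure mapping
# ---------------------------------------------------------------------------


@dataclass
class SiteStructureMap:
    """Alignment column <-> reference residue number correspondence."""

    reference_taxon: str
    column_to_residue: dict  # 0-based column -> residue number (1-based)
    unmapped_columns: list

    def residues_for(self, columns):
        """Residue numbers for mapped columns (unmapped skipped)."""
        return [
            self.column_to_residue[c] for c in columns if c in self.column_to_residue
        ]


def map_sites_to_structure(alignment, reference_taxon: str, offset: int = 0) -> SiteStructureMap:
    """Map alignment columns to reference residue numbers by walking the
    ungapped reference sequence.

    Columns gapped in the reference are unmapped.  ``offset`` shifts the
    numbering when the structure's first residue is not number 1.
    """
    aln = alignment.translate() if hasattr(alignment, "translate") else alignment
    if reference_taxon not in aln.taxa:
        raise ValueError(f"reference taxon {reference_taxon!r} not in alignment")
    seq = aln.sequences[aln.taxa.index(reference_taxon)]
    mapping, unmapped = {}, []
    pos = 0
    for col, ch in enumerate(seq):
        if ch == "-" or ch == ".":
            unmapped.append(col)
        else:
            pos += 1
            mapping[col] = pos + offset
    return SiteStructureMap(
        reference_taxon=reference_taxon,
        column_to_residue=mapping,
        unmapped_columns=unmapped,
    )


def distance_histogram(summary: DistanceSummary, bin_width: float = 2.0) -> pd.DataFrame:
    """Histogram of pair distances as a table (bin edges + counts)."""
    if len(summary.distances) == 0:
        return pd.DataFrame({"bin_low": [], "bin_high": [], "count": []})
    top = np.ceil(summary.distances.max() / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(summary.distances, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
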