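"""End-to-end orchestration: config, seeding, stages, consolidated report.

A run is described by a declarative YAML config (or a :class:`RunConfig`
built in code): datasets (alignment + tree paths, or a synthetic-data
block), the properties to test for coevolution, the site models to fit,
optional structures and secondary-structure annotations, and the
significance thresholds.  Every stochastic stage is seeded from the master
seed through ``numpy.random.SeedSequence.spawn``, so identical config +
seed reproduces identical report tables.

Stages degrade gracefully: sections whose inputs are absent (no structures,
no annotation) are marked absent in the report instead of failing the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp
from . import coevolution as cv
from . import evomodel as em
from . import selection as sel
from . import structure3d as s3
from . import synthdata as sd
from .properties import PROPERTY_NAMES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """One dataset: either file paths or a synthetic block."""

    name: str
    alignment: str | None = None          # FASTA path (codon alignment)
    tree: str | None = None               # Newick path
    synthetic: dict | None = None         # SimulationConfig fields
    positive_site_list: str | None = None  # external TSV, 1-based sites


@dataclass
class StructureConfig:
    path: str
    chain: str | None = None
    state: str = ""
    species: str = ""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; thresholds default to the
    conventional values (cluster p <= 0.05, NEB >= 0.95, 1000 bootstrap
    replicates)."""

    datasets: list = field(default_factory=list)       # DatasetConfig
    properties: tuple = PROPERTY_NAMES
    selection_models: tuple = ("M0", "M1a", "M2a")
    structures: list = field(default_factory=list)     # StructureConfig
    ss_annotation: str | None = None                   # TSV path
    reference_taxon: str | None = None
    cluster_alpha: float = 0.05
    neb_threshold: float = 0.95
    n_bootstrap: int = 1000
    n_samples: int = 100
    coevol_modes: tuple = ("correlated",)
    run_selection: bool = True
    seed: int = 0

    def __post_init__(self):
        for thr in (self.cluster_alpha, self.neb_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError(f"threshold {thr} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetConfig(**d) for d in raw.pop("datasets", [])]
        structures = [StructureConfig(**s) for s in raw.pop("structures", [])]
        cfg = cls(datasets=datasets, structures=structures, **raw)
        cfg.validate()
        return cfg

    def validate(self):
        """Collect every violation; raise with the full list."""
        problems = []
        if not self.datasets:
            problems.append("no datasets configured")
        for d in self.datasets:
            if d.synthetic is None:
                for p in (d.alignment, d.tree):
                    if p is None:
                        problems.append(f"dataset {d.name}: missing alignment/tree")
                    elif not Path(p).exists():
                        problems.append(f"dataset {d.name}: path {p} does not exist")
        for s in self.structures:
            if not Path(s.path).exists():
                problems.append(f"structure path {s.path} does not exist")
        if self.ss_annotation and not Path(self.ss_annotation).exists():
            problems.append(f"ss annotation {self.ss_annotation} does not exist")
        if problems:
            raise ValueError("invalid config:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass
class ReportBundle:
    """Consolidated outputs of one run (DataFrames keyed by section)."""

    coevolution: pd.DataFrame | None = None
    selection: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None
    pairing: dict = field(default_factory=dict)      # property -> DataFrame
    ss_enrichment: pd.DataFrame | None = None
    structure: pd.DataFrame | None = None
    overlap: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def absent_sections(self):
        return [
            name
            for name in ("coevolution", "selection", "composition",
                         "ss_enrichment", "structure", "overlap")
            if getattr(self, name) is None
        ]

    def write(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("coevolution", "selection", "composition",
                     "ss_enrichment", "structure", "overlap"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                          float_format="%.6g")
        for prop, df in self.pairing.items():
            df.to_csv(out / f"pairing_{prop}.tsv", sep="\t", float_format="%.6g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str)
        )


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _load_dataset(dcfg: DatasetConfig, seed: int):
    if dcfg.synthetic is not None:
        params = dict(dcfg.synthetic)
        params.setdefault("seed", seed)
        simcfg = sd.SimulationConfig(**params)
        aln, tree, truth = sd.simulate_dataset(simcfg)
        return aln, tree, truth
    aln = em.CodonAlignment.from_fasta(dcfg.alignment)
    tree = em.Phylogeny.from_newick(Path(dcfg.tree).read_text())
    return aln, tree, None


def _spawn_seeds(master: int, n: int):
    return [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(master).spawn(n)
    ]


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every configured stage in dependency order."""
    t_start = time.time()
    config.validate()
    report = ReportBundle()
    report.manifest = {
        "seed": config.seed,
        "properties": list(config.properties),
        "selection_models": list(config.selection_models),
        "n_bootstrap": config.n_bootstrap,
        "n_samples": config.n_samples,
        "cluster_alpha": config.cluster_alpha,
        "neb_threshold": config.neb_threshold,
        "stages": {},
    }
    n_ds = len(config.datasets)
    ds_seeds = _spawn_seeds(config.seed, 2 * n_ds + 1)

    alignments, coevol_rows, sel_rows = [], [], []
    groups_for_pairing = {p: [] for p in config.properties}
    coevol_sites_by_ds, positive_sites_by_ds = {}, {}

    for i, dcfg in enumerate(config.datasets):
        t0 = time.time()
        aln, tree, truth = _load_dataset(dcfg, ds_seeds[2 * i])
        alignments.append(aln)

        # --- coevolution ---------------------------------------------------
        ccfg = cv.CoevolConfig(
            n_samples=config.n_samples,
            n_bootstrap=config.n_bootstrap,
            alpha=config.cluster_alpha,
            modes=config.coevol_modes,
            seed=ds_seeds[2 * i],
        )
        res = cv.detect_coevolution(aln, tree, config.properties, ccfg)
        df = res.to_frame()
        df.insert(0, "dataset", dcfg.name)
        coevol_rows.append(df)
        coevol_sites_by_ds[dcfg.name] = set(cv.coevolving_site_union(res))
        for g in res.significant:
            if g.mode == "correlated":
                groups_for_pairing[g.property_name].append((i, list(g.sites)))

        # --- selection -----------------------------------------------------
        called = []
        if dcfg.positive_site_list:
            called = sel.read_site_list(dcfg.positive_site_list)
            sel_rows.append(
                pd.DataFrame(
                    {
                        "dataset": dcfg.name,
                        "source": "external",
                        "site": [s + 1 for s in called],
                        "positive_posterior": np.nan,
                    }
                )
            )
        elif config.run_selection:
            models = tuple(config.selection_models)
            fits = sel.fit_model_set(aln, tree, models=models)
            pairs = [p for p in sel.LRT_DF if p[0] in fits and p[1] in fits]
            lrts = [sel.lrt(fits[a], fits[b]) for a, b in pairs]
            alt = "M8" if "M8" in fits else ("M2a" if "M2a" in fits else None)
            if alt is not None:
                gate = next((r for r in lrts if r.alt_name == alt), None)
                post = sel.neb_posteriors(fits[alt], config.neb_threshold)
                called = (
                    post.positive_sites
                    if gate is None or gate.p_value <= config.cluster_alpha
                    else []
                )
                sel_rows.append(
                    pd.DataFrame(
                        {
                            "dataset": dcfg.name,
                            "source": alt,
                            "site": [s + 1 for s in called],
                            "positive_posterior": [
                                post.positive_probability[s] for s in called
                            ],
                        }
                    )
                )
        positive_sites_by_ds[dcfg.name] = set(called)
        report.manifest["stages"][dcfg.name] = {
            "seconds": round(time.time() - t0, 2),
            "n_taxa": aln.n_taxa,
            "n_sites": aln.n_sites,
        }

    report.coevolution = (
        pd.concat(coevol_rows, ignore_index=True) if coevol_rows else None
    )
    if sel_rows:
        report.selection = pd.concat(sel_rows, ignore_index=True)
    elif config.run_selection:
        report.selection = pd.DataFrame(
            columns=["dataset", "source", "site", "positive_posterior"]
        )

    # --- pooled composition ------------------------------------------------
    all_sites = [list(range(a.n_sites)) for a in alignments]
    background = comp.aa_composition(alignments, all_sites, label="background")
    rows = [background.to_frame().assign(site_set="background")]
    coevol_site_sets = [
        sorted(coevol_sites_by_ds[d.name]) for d in config.datasets
    ]
    if any(coevol_site_sets):
        sub = comp.aa_composition(alignments, coevol_site_sets, label="coevolving")
        rows.append(sub.to_frame().assign(site_set="coevolving"))
        if sub.total:
            chi2, p = comp.composition_chi2(sub, background)
            r, verdict = comp.composition_correlation(
                sub.frequencies, background.frequencies
            )
            report.manifest["composition_coevolving"] = {
                "chi2": chi2, "p": p, "R": r, "vs_threshold_0.8": verdict,
            }
    pos_site_sets = [
        sorted(positive_sites_by_ds[d.name]) for d in config.datasets
    ]
    if any(pos_site_sets):
        sub = comp.aa_composition(alignments, pos_site_sets, label="positive")
        rows.append(sub.to_frame().assign(site_set="positive"))
    report.composition = pd.concat(rows, ignore_index=True)

    for prop, groups in groups_for_pairing.items():
        if groups:
            report.pairing[prop] = comp.pairing_matrix(
                groups, alignments, property_label=prop
            ).to_frame()

    # --- secondary-structure enrichment ------------------------------------
    if config.ss_annotation:
        ann = comp.SSAnnotation.from_tsv(config.ss_annotation)
        ref_sites = sorted(
            {s + 1 for sites in coevol_sites_by_ds.values() for s in sites}
        )
        bg_sites = [r for r in ann.classes]
        usable = [s for s in ref_sites if s in ann]
        skipped = sorted(set(ref_sites) - set(usable))
        if skipped:
            report.warnings.append(f"sites without SS annotation: {skipped[:20]}")
        if usable:
            report.ss_enrichment = comp.ss_enrichment(usable, ann, bg_sites)

    # --- structures ---------------------------------------------------------
    if config.structures:
        report.structure = _structure_stage(
            config, coevol_sites_by_ds, positive_sites_by_ds, alignments, report
        )

    # --- overlap ------------------------------------------------------------
    overlap_rows = []
    for d in config.datasets:
        both = sorted(
            coevol_sites_by_ds[d.name] & positive_sites_by_ds[d.name]
        )
        overlap_rows.append(
            {
                "dataset": d.name,
                "n_coevolving": len(coevol_sites_by_ds[d.name]),
                "n_positive": len(positive_sites_by_ds[d.name]),
                "n_both": len(both),
                "sites_both": ",".join(str(s + 1) for s in both),
            }
        )
    report.overlap = pd.DataFrame(overlap_rows)
    report.manifest["total_seconds"] = round(time.time() - t_start, 2)
    report.manifest["absent_sections"] = report.absent_sections()
    return report


def _structure_stage(config, coevol_sites_by_ds, positive_sites_by_ds,
                     alignments, report):
    """Distance summaries and proximity tests per structure + min over states."""
    rows = []
    by_species = {}
    # map coevolving/positive columns to residues via the reference taxon
    # (identity mapping when no reference is configured)
    coevol_union = sorted({s for v in coevol_sites_by_ds.values() for s in v})
    pos_union = sorted({s for v in positive_sites_by_ds.values() for s in v})
    col_to_res = None
    if config.reference_taxon and alignments:
        for aln in alignments:
            if config.reference_taxon in aln.taxa:
                col_to_res = s3.map_sites_to_structure(
                    aln, config.reference_taxon
                ).column_to_residue
                break
    if col_to_res is None:
        col_to_res = {}

    def residues(cols):
        return sorted({col_to_res.get(c, c + 1) for c in cols})

    for scfg in config.structures:
        text = Path(scfg.path).read_text()
        structure = s3.read_structure(text, chain=scfg.chain, state=scfg.state)
        coms = s3.residue_centers(structure)
        background = s3.pairwise_distances(coms, "all", label="background")
        entry = {
            "structure": Path(scfg.path).stem,
            "species": scfg.species,
            "state": scfg.state,
            "set": "background",
            "n_pairs": len(background.distances),
            "mean": background.mean,
            "median": background.median,
            "sd": background.sd,
            "z": np.nan, "p_one_sided": np.nan, "difference": np.nan,
        }
        rows.append(entry)
        by_species.setdefault(scfg.species or Path(scfg.path).stem, []).append(
            (background, coms)
        )
        for label, cols in (("coevolving", coevol_union), ("positive", pos_union)):
            res = [r for r in residues(cols) if r in coms.centers]
            if len(res) < 2:
                continue
            pairs = [
                (res[i], res[j])
                for i in range(len(res))
                for j in range(i + 1, len(res))
            ]
            summ = s3.pairwise_distances(coms, pairs, label=label)
            z, p1, p2, diff = s3.proximity_ztest(summ, background)
            rows.append(
                {
                    "structure": Path(scfg.path).stem,
                    "species": scfg.species,
                    "state": scfg.state,
                    "set": label,
                    "n_pairs": len(summ.distances),
                    "mean": summ.mean,
                    "median": summ.median,
                    "sd": summ.sd,
                    "z": z, "p_one_sided": p1, "difference": diff,
                }
            )
    # min over states per species
    for species, items in by_species.items():
        if len(items) < 2:
            continue
        combined = s3.min_over_states([bg for bg, _ in items], label="min")
        rows.append(
            {
                "structure": "min_over_states",
                "species": species,
                "state": "min",
                "set": "background",
                "n_pairs": len(combined.distances),
                "mean": combined.mean,
                "median": combined.median,
                "sd": combined.sd,
                "z": np.nan, "p_one_sided": np.nan, "difference": np.nan,
            }
        )
    return pd.DataFrame(rows)
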