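"""Seeded synthetic study generator.

The downstream pipeline was designed around a real two-herb study whose raw
inputs (database component tables, web-tool target predictions, docking runs,
expression data) cannot be bundled. This module generates synthetic datasets
with the same *shapes and statistical structure*, so every stage is testable
offline and parameter-recovery checks are possible against planted ground
truth:

* two herbs with unequal component counts and TCMSP-style ADME properties;
* a bipartite component–target network whose per-component degrees follow a
  negative binomial (heavy right tail: a few hub components), with a
  designated pool of "common" targets reachable from both herbs and wired
  with extra weight, so common targets end up with stochastically higher
  degree than herb-unique targets;
* log-normal doses with a small set of planted dominant components that also
  get above-average degree and edges concentrated on common targets — the
  planted core the synergy model is expected to recover;
* a docking table with several poses per component–protein pair, affinities
  from a normal distribution truncated above at −0.5 kcal/mol, and a set of
  planted strong binders (≤ −10 kcal/mol) on the core components;
* a differential-expression gene list and a GMT pathway annotation over the
  synthetic target universe.

All randomness flows through one ``numpy`` generator seeded from the config,
so a fixed seed reproduces the study byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .adme import (
    HERB_A,
    HERB_B,
    ComponentRecord,
    read_components,
    write_components,
)
from .dockrank import DOCKING_COLUMNS
from .enrich import Annotation, read_gene_list, read_gmt, write_gene_list, write_gmt

logger = logging.getLogger("synerkit.synthdata")

#: dispersion (number of successes) of the negative-binomial degree model;
#: mean 40 with r=2 gives variance 840, reproducing the 1–150 degree range a
#: hub-and-tail component–target network shows
NB_DISPERSION = 2.0

#: affinities never exceed this (weakest printed best pose)
AFFINITY_CEILING = -0.5

#: extra poses per component–protein pair before best-pose reduction
N_POSES = 3

#: docking panel size: genes and the PDB chains coding them
N_DOCK_GENES = 30
N_DOCK_PROTEINS = 85
N_DOCKED_COMPONENTS = 24

#: selection weight of a common-pool target relative to an own-herb target
COMMON_WEIGHT = 3.0
COMMON_WEIGHT_PLANTED = 10.0
#: planted-core degree floor, as a multiple of the mean degree
PLANTED_DEGREE_FACTOR = 2.0


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; defaults mirror the screened study scale
    (113 active components at a 92/21 herb split, 780 targets, ~4,600 edges,
    two dominant-dose components, affinities centred near −6.7 kcal/mol)."""

    n_components_herb_a: int = 92
    n_components_herb_b: int = 21
    n_targets: int = 780
    common_target_fraction: float = 0.32
    edge_density: float = 40.0
    dose_lognormal_params: tuple[float, float] = (0.0, 1.0)
    n_dominant_components: int = 2
    dominant_dose_multiplier: float = 25.0
    affinity_mean: float = -6.7
    affinity_sd: float = 1.6
    n_strong_binders: int = 20
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 60)
    deg_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_components_herb_a", "n_components_herb_b", "n_targets",
                     "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_dominant_components", "n_strong_binders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")
        for name in ("common_target_fraction", "deg_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.edge_density <= 0:
            raise ValueError("edge_density must be positive")
        if self.dominant_dose_multiplier <= 0:
            raise ValueError("dominant_dose_multiplier must be positive")
        if self.affinity_mean >= 0:
            raise ValueError("affinity_mean must be negative (kcal/mol)")
        if self.affinity_sd <= 0:
            raise ValueError("affinity_sd must be positive")
        if self.n_dominant_components > self.n_components_herb_a + self.n_components_herb_b:
            raise ValueError("n_dominant_components exceeds the total component count")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("pathway_size_range must satisfy 0 < min <= max")
        if self.dose_lognormal_params[1] <= 0:
            raise ValueError("dose_lognormal_params sigma must be positive")


@dataclass
class SyntheticStudy:
    components: list[ComponentRecord] = field(default_factory=list)
    edges: list[tuple[str, str]] = field(default_factory=list)
    doses: dict[str, float] = field(default_factory=dict)
    docking: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=DOCKING_COLUMNS)
    )
    deg_genes: set[str] = field(default_factory=set)
    annotation: dict[str, set[str]] = field(default_factory=dict)
    planted_core: set[str] = field(default_factory=set)

    def equals(self, other: "SyntheticStudy") -> bool:
        def comp_key(c: ComponentRecord):
            vec = tuple(c.descriptor) if c.descriptor is not None else None
            return (c.id, c.herb, c.name, c.mw, c.alogp, c.caco2, c.dl, vec, c.dose)

        return (
            [comp_key(c) for c in self.components] == [comp_key(c) for c in other.components]
            and self.edges == other.edges
            and self.doses == other.doses
            and self.docking.reset_index(drop=True).equals(other.docking.reset_index(drop=True))
            and self.deg_genes == other.deg_genes
            and self.annotation == other.annotation
            and self.planted_core == other.planted_core
        )


def _nb_degrees(rng: np.random.Generator, n: int, mean: float, cap: int) -> np.ndarray:
    """Per-component target counts: negative binomial around ``mean``."""
    p = NB_DISPERSION / (NB_DISPERSION + mean)
    k = rng.negative_binomial(NB_DISPERSION, p, size=n)
    return np.clip(k, 1, cap)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Draw one synthetic study; deterministic for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_components_herb_a, config.n_components_herb_b
    ids_a = [f"KS{i + 1}" for i in range(n_a)]
    ids_b = [f"BTL{i + 1}" for i in range(n_b)]
    all_ids = ids_a + ids_b
    herb_of = {cid: (HERB_A if cid in set(ids_a) else HERB_B) for cid in all_ids}

    # --- target pools ------------------------------------------------------
    targets = [f"T{i + 1:04d}" for i in range(config.n_targets)]
    n_common = int(round(config.common_target_fraction * config.n_targets))
    rest = config.n_targets - n_common
    n_pool_a = int(round(rest * n_a / (n_a + n_b)))
    common_pool = targets[:n_common]
    pool_a = targets[n_common:n_common + n_pool_a]
    pool_b = targets[n_common + n_pool_a:]

    # --- planted core: dominant dose + above-average degree ----------------
    planted = set(
        rng.choice(all_ids, size=config.n_dominant_components, replace=False).tolist()
    ) if config.n_dominant_components else set()

    # --- doses -------------------------------------------------------------
    mu, sigma = config.dose_lognormal_params
    base = rng.lognormal(mu, sigma, size=len(all_ids))
    doses = dict(zip(all_ids, base.tolist()))
    dom_scale = config.dominant_dose_multiplier * float(np.exp(mu + sigma**2 / 2))
    for cid in sorted(planted):
        doses[cid] = dom_scale * float(rng.uniform(0.9, 1.1))

    # --- edges -------------------------------------------------------------
    degrees = _nb_degrees(rng, len(all_ids), config.edge_density,
                          cap=config.n_targets)
    planted_floor = int(np.ceil(PLANTED_DEGREE_FACTOR * config.edge_density))
    edges: list[tuple[str, str]] = []
    for idx, cid in enumerate(all_ids):
        own_pool = pool_a if herb_of[cid] == HERB_A else pool_b
        candidates = common_pool + own_pool
        if not candidates:
            continue
        k = int(degrees[idx])
        if cid in planted:
            k = max(k, planted_floor)
        k = min(k, len(candidates))
        w_common = COMMON_WEIGHT_PLANTED if cid in planted else COMMON_WEIGHT
        w = np.concatenate(
            [np.full(len(common_pool), w_common), np.ones(len(own_pool))]
        )
        chosen = rng.choice(candidates, size=k, replace=False, p=w / w.sum())
        edges.extend((cid, t) for t in chosen.tolist())

    # --- ADME properties ---------------------------------------------------
    components: list[ComponentRecord] = []
    for cid in all_ids:
        if cid in planted:
            caco2 = float(rng.uniform(0.5, 1.5))
            dl = float(rng.uniform(0.3, 0.7))
        else:
            # candidate-active components: most clear the screen, a few fail
            caco2 = float(rng.normal(0.8, 0.6))
            dl = float(rng.beta(4.0, 6.0))
        components.append(
            ComponentRecord(
                id=cid,
                herb=herb_of[cid],
                name=f"cmpd_{cid}",
                mw=float(rng.lognormal(5.6, 0.3)),
                alogp=float(rng.normal(2.0, 1.5)),
                caco2=caco2,
                dl=dl,
                descriptor=rng.gamma(2.0, 0.5, size=8),
                dose=doses[cid],
            )
        )

    # --- docking -----------------------------------------------------------
    docking = _generate_docking(rng, config, all_ids, doses, planted,
                                common_pool or targets)

    # --- DEG list and annotation ------------------------------------------
    n_deg = int(round(config.deg_fraction * config.n_targets))
    deg_genes = set(
        rng.choice(targets, size=n_deg, replace=False).tolist()
    ) if n_deg else set()
    # disease genes the formula does not target at all
    deg_genes |= {f"DX{i + 1:04d}" for i in range(max(1, n_deg // 7))}

    lo, hi = config.pathway_size_range
    annotation: dict[str, set[str]] = {}
    deg_in_universe = sorted(deg_genes & set(targets))
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, config.n_targets)
        term = f"PW{i + 1:03d}"
        if i < 3 and deg_in_universe:
            # a few disease-linked terms: half their genes from the DEG list
            n_biased = min(size // 2, len(deg_in_universe))
            biased = rng.choice(deg_in_universe, size=n_biased, replace=False).tolist()
            remaining = sorted(set(targets) - set(biased))
            filler = rng.choice(remaining, size=size - n_biased, replace=False).tolist()
            annotation[term] = set(biased) | set(filler)
        else:
            annotation[term] = set(rng.choice(targets, size=size, replace=False).tolist())

    logger.info(
        "generated study: %d components, %d targets, %d edges, %d docking rows",
        len(components), config.n_targets, len(edges), len(docking),
    )
    return SyntheticStudy(
        components=components,
        edges=edges,
        doses=doses,
        docking=docking,
        deg_genes=deg_genes,
        annotation=annotation,
        planted_core=planted,
    )


def _generate_docking(
    rng: np.random.Generator,
    config: StudyConfig,
    all_ids: list[str],
    doses: dict[str, float],
    planted: set[str],
    gene_source: list[str],
) -> pd.DataFrame:
    """Raw pose table over a docking panel of core-candidate components."""
    genes = rng.choice(
        gene_source, size=min(N_DOCK_GENES, len(gene_source)), replace=False
    ).tolist()
    proteins = [f"P{i + 1:03d}" for i in range(N_DOCK_PROTEINS)]
    gene_of = {p: genes[i % len(genes)] for i, p in enumerate(proteins)}

    # dock the planted core plus the highest-dose remaining components
    by_dose = sorted((cid for cid in all_ids if cid not in planted),
                     key=lambda c: -doses[c])
    docked = sorted(planted) + by_dose[: max(0, N_DOCKED_COMPONENTS - len(planted))]

    rows = {"component_id": [], "protein_id": [], "gene": [], "affinity": []}
    b = (AFFINITY_CEILING - config.affinity_mean) / config.affinity_sd
    n_pairs = len(docked) * len(proteins)
    aff = truncnorm.rvs(
        -np.inf, b, loc=config.affinity_mean, scale=config.affinity_sd,
        size=n_pairs * N_POSES, random_state=rng,
    )
    i = 0
    for cid in docked:
        for p in proteins:
            for _ in range(N_POSES):
                rows["component_id"].append(cid)
                rows["protein_id"].append(p)
                rows["gene"].append(gene_of[p])
                rows["affinity"].append(round(float(aff[i]), 1))
                i += 1
    df = pd.DataFrame(rows, columns=DOCKING_COLUMNS)

    # planted strong binders: a tail of very favourable poses on the core
    if planted and config.n_strong_binders:
        pairs = [(cid, p) for cid in sorted(planted) for p in proteins]
        take = min(config.n_strong_binders, len(pairs))
        picked = rng.choice(len(pairs), size=take, replace=False)
        strong = pd.DataFrame(
            {
                "component_id": [pairs[j][0] for j in picked],
                "protein_id": [pairs[j][1] for j in picked],
                "gene": [gene_of[pairs[j][1]] for j in picked],
                "affinity": np.round(rng.uniform(-11.3, -10.0, size=take), 1),
            }
        )
        df = pd.concat([df, strong], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# persistence


def write_study(study: SyntheticStudy, directory: Path | str) -> list[Path]:
    """Write the study as plain-text tables; see :func:`read_study` to load."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []

    p = d / "components.tsv"
    write_components(study.components, p)
    paths.append(p)

    p = d / "edges.tsv"
    pd.DataFrame(study.edges, columns=["component_id", "target_id"]).to_csv(
        p, sep="\t", index=False
    )
    paths.append(p)

    p = d / "doses.tsv"
    pd.DataFrame(
        [(cid, study.doses[cid]) for cid in study.doses],
        columns=["component_id", "dose"],
    ).to_csv(p, sep="\t", index=False, float_format="%.17g")
    paths.append(p)

    p = d / "docking.tsv"
    study.docking.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = d / "deg.txt"
    write_gene_list(study.deg_genes, p)
    paths.append(p)

    p = d / "annotation.gmt"
    universe = set().union(*study.annotation.values()) if study.annotation else set()
    write_gmt(Annotation(terms=dict(study.annotation), universe=universe), p)
    paths.append(p)

    p = d / "planted_core.txt"
    write_gene_list(study.planted_core, p)
    paths.append(p)
    return paths


def read_study(directory: Path | str) -> SyntheticStudy:
    d = Path(directory)
    components = read_components(d / "components.tsv")
    edge_df = pd.read_csv(d / "edges.tsv", sep="\t", dtype=str)
    edges = list(zip(edge_df["component_id"], edge_df["target_id"])) if len(edge_df) else []
    dose_df = pd.read_csv(d / "doses.tsv", sep="\t", dtype={"component_id": str},
                          float_precision="round_trip")
    doses = dict(zip(dose_df["component_id"], dose_df["dose"].astype(float)))
    docking = pd.read_csv(d / "docking.tsv", sep="\t",
                          dtype={"component_id": str, "protein_id": str, "gene": str})
    deg_genes = read_gene_list(d / "deg.txt")
    annotation = read_gmt(d / "annotation.gmt").terms
    core_path = d / "planted_core.txt"
    planted = read_gene_list(core_path) if core_path.exists() else set()
    return SyntheticStudy(
        components=components,
        edges=edges,
        doses=doses,
        docking=docking,
        deg_genes=deg_genes,
        annotation=annotation,
        planted_core=planted,
    )
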