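"""Docking-table reduction and the CDI / TRI ranking models.

A virtual-docking run scores every component–protein pose with a binding
affinity in kcal/mol (more negative = stronger). This module reduces the raw
pose table to the best pose per component–protein pair, keeps only the highly
reliable docking relationships (HRDR: affinity strictly below the mean
best-pose affinity), and ranks components by a composite docking index (CDI)
and a therapeutic response index (TRI):

    R_i   = 2 − GI_i² / (mean(GI) · AI_i)
    CDI_i = Σ_j  NORM(R)_i · NORM(NI_j)_i        (j over 8 topology parameters)
    TRI_i = NORM(CDI)_i + NORM(SCD)_i ∈ [0, 2]

``GI_i`` counts the distinct genes a component binds within the HRDR (a gene
may code several PDB chains), ``AI_i`` is its mean HRDR affinity, and the
``NI_j`` are the eight NetworkAnalyzer-style topology parameters of the
component in the core-group C-T network (see
:data:`synerkit.ctnet.NI_PARAMETERS`). All NORM operations are min-max across
the component set, with a constant vector mapping to ones.

The grouping of the printed CDI expression is ambiguous in one place: whether
``AI`` enters with its (negative) sign or as a magnitude. Both readings are
implemented (``form='default'`` uses the signed value; ``form='abs-ai'`` its
absolute value) and the choice is recorded in the result metadata.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .ctnet import NI_PARAMETERS
from .scd import minmax_norm

logger = logging.getLogger("synerkit.dockrank")

DOCKING_COLUMNS = ["component_id", "protein_id", "gene", "affinity"]


def _check_docking(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DOCKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"docking table lacks columns {missing}")
    if df.empty:
        raise ValueError("docking table is empty")
    if not np.all(np.isfinite(df["affinity"].to_numpy(dtype=float))):
        raise ValueError("docking affinities must be finite")
    return df


def reduce_best_pose(records: pd.DataFrame) -> pd.DataFrame:
    """One record per (component, protein): the pose with minimum affinity.

    Ties keep the first-seen record; tied groups are counted and logged.
    """
    df = _check_docking(records).reset_index(drop=True)
    grp = df.groupby(["component_id", "protein_id"], sort=False)["affinity"]
    best_idx = grp.idxmin()  # first occurrence of the minimum
    n_ties = int((grp.agg(lambda s: (s == s.min()).sum()) > 1).sum())
    if n_ties:
        logger.info("%d component–protein pairs had tied best poses; kept first seen", n_ties)
    return df.loc[best_idx.sort_values().values].reset_index(drop=True)


def hrdr_filter(best: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Keep best poses with affinity strictly below the mean best-pose affinity.

    Returns the retained table and a stats record (mean affinity, retained
    count, distinct components / proteins / genes).
    """
    df = _check_docking(best)
    mean_aff = float(df["affinity"].mean())
    kept = df[df["affinity"] < mean_aff].reset_index(drop=True)
    stats = {
        "mean_affinity": mean_aff,
        "n_retained": int(len(kept)),
        "n_components": int(kept["component_id"].nunique()),
        "n_proteins": int(kept["protein_id"].nunique()),
        "n_genes": int(kept["gene"].nunique()),
    }
    logger.info(
        "HRDR: %(n_retained)d of %(total)d best poses below mean %(mean_affinity).3f "
        "(%(n_components)d components, %(n_proteins)d proteins, %(n_genes)d genes)",
        {**stats, "total": len(df)},
    )
    return kept, stats


def compute_cdi(
    hrdr: pd.DataFrame, topology: pd.DataFrame, form: str = "default"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Composite docking index per component.

    ``topology`` must provide the eight NI parameters (rows indexed by node)
    for every component appearing in ``hrdr`` — conventionally the extended
    topology of the core-group C-T network. Returns the per-component table
    (gi, ai, r, cdi) and a metadata record pinning the interpretation used.
    """
    if form not in ("default", "abs-ai"):
        raise ValueError(f"unknown cdi form {form!r}")
    df = _check_docking(hrdr)
    per = df.groupby("component_id").agg(
        gi=("gene", "nunique"), ai=("affinity", "mean")
    )
    missing = [c for c in per.index if c not in topology.index]
    if missing:
        raise ValueError(f"HRDR components missing from topology table: {missing[:5]}")
    lacking = [p for p in NI_PARAMETERS if p not in topology.columns]
    if lacking:
        raise ValueError(f"topology table lacks NI parameters: {lacking}")
    if (per["ai"] == 0).any():
        bad = list(per.index[per["ai"] == 0])
        raise ZeroDivisionError(f"mean affinity of zero for components {bad}")

    gi = per["gi"].to_numpy(dtype=float)
    ai = per["ai"].to_numpy(dtype=float)
    if form == "abs-ai":
        ai = np.abs(ai)
    mean_gi = gi.mean()
    r = 2.0 - (gi / (mean_gi * ai)) * gi
    norm_r = minmax_norm(r)
    ni = topology.loc[per.index, list(NI_PARAMETERS)].to_numpy(dtype=float)
    norm_ni = np.column_stack([minmax_norm(ni[:, j]) for j in range(ni.shape[1])])
    cdi = (norm_r[:, None] * norm_ni).sum(axis=1)

    out = per.copy()
    out["r"] = r
    out["cdi"] = cdi
    out.index.name = "id"
    meta = {"cdi_form": form, "ni_parameters": ",".join(NI_PARAMETERS)}
    return out.sort_values("cdi", ascending=False), meta


def compute_tri(cdi: pd.DataFrame, scd_table: pd.DataFrame) -> pd.DataFrame:
    """Therapeutic response index: NORM(CDI) + NORM(SCD) on the joined set.

    Components present in only one of the two tables are excluded (and
    logged). Ranks are descending competition ranks: ties share the smallest
    rank of their block.
    """
    common = cdi.index.intersection(scd_table.index)
    if common.empty:
        raise ValueError("no components shared between CDI and SCD tables")
    dropped = sorted(set(cdi.index).symmetric_difference(scd_table.index))
    if dropped:
        logger.info("TRI join excludes %d unmatched components: %s", len(dropped), dropped[:10])
    df = pd.DataFrame(
        {
            "gi": cdi.loc[common, "gi"],
            "ai": cdi.loc[common, "ai"],
            "cdi": cdi.loc[common, "cdi"],
            "scd": scd_table.loc[common, "scd"],
        }
    )
    df["tri"] = minmax_norm(df["cdi"].to_numpy()) + minmax_norm(df["scd"].to_numpy())
    df = df.sort_values(["tri", "cdi"], ascending=False, kind="stable")
    df["rank"] = df["tri"].rank(method="min", ascending=False).astype(int)
    df.index.name = "id"
    return df


def read_docking(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"component_id": str, "protein_id": str, "gene": str}
    )


def write_docking(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_tri(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None) -> None:
    """Write tri.tsv; interpretation metadata goes in leading ``#`` comments."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t")
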