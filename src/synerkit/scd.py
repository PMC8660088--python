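"""Synergy Contribution Degree (SCD) model and core-group selection.

The SCD quantifies how much one component contributes to the formula's joint
action on the disease network, combining network topology with dose:

    SCD(i) = Σ_j [ C_i · ( (Ce_i / Te_i + B_i) · T_j ) + NORM(d_i) ]

summed over the targets *j* of component *i*, where

* ``C_i``   — betweenness centrality of the component in the C-T network,
* ``Ce_i``  — the component's edge count,
* ``Te_i``  — summed edge count of its targets,
* ``T_j``   — betweenness centrality of target *j*,
* ``B_i``   — the inter-herb balance term ``|CB_i − CK_i| / (CB_i + CK_i)``,
  with ``CB``/``CK`` the component's betweenness within each single-herb
  subnetwork; a single-herb component scores 1 and an exactly balanced
  two-herb component is assigned 1e-6 rather than 0,
* ``NORM(d_i)`` — the component's dose after min-max normalisation.

Components are ranked by descending SCD share; the smallest prefix whose
cumulative share reaches a threshold (default 95%) forms the high-contribution
group of synergistic components (HCGSC). The group is validated by the
fraction of a reference gene or pathway set its targets cover.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .utils import round_half_up

logger = logging.getLogger("synerkit.scd")

BALANCE_FLOOR = 1e-6


def minmax_norm(values: Sequence[float]) -> np.ndarray:
    """Min-max normalisation to [0, 1].

    A constant vector maps to all ones (not zeros): a formula whose doses are
    all equal still credits every component with full dose weight.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("minmax_norm needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("minmax_norm requires finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones_like(v)
    return (v - lo) / (hi - lo)


def herb_balance(cb: float, ck: float, single_herb: bool) -> float:
    """Inter-herb betweenness balance term, in (0, 1].

    ``|cb − ck| / (cb + ck)`` for a chemical present in both herbs; exactly 1
    for a single-herb chemical. A zero quotient (perfectly balanced, or both
    centralities zero) is replaced by 1e-6 so the multiplicative structure of
    the SCD never collapses a component to zero through this term alone.
    """
    if cb < 0 or ck < 0:
        raise ValueError(f"herb balance needs non-negative centralities, got {cb}, {ck}")
    if single_herb:
        return 1.0
    tot = cb + ck
    if tot == 0:
        return BALANCE_FLOOR
    q = abs(cb - ck) / tot
    return q if q > 0 else BALANCE_FLOOR


def compute_scd(topology: pd.DataFrame, doses: Mapping[str, float]) -> pd.DataFrame:
    """Score every component and return the descending SCD table.

    ``topology`` is the per-node table from :func:`synerkit.ctnet.node_topology`;
    only its component rows are used. Each component needs a dose. The result
    has columns ``herb, scd, share, cumulative_share, hcgsc`` (hcgsc initially
    False; see :func:`select_hcgsc`), sorted by descending SCD with ties broken
    by id for reproducibility.
    """
    comp = topology[topology["kind"] == "component"]
    missing = [cid for cid in comp.index if cid not in doses]
    if missing:
        raise ValueError(f"missing dose for components: {missing[:5]}")
    ids = list(comp.index)
    dose_vec = np.array([float(doses[cid]) for cid in ids])
    norm_d = minmax_norm(dose_vec)

    scd = np.zeros(len(ids))
    for k, cid in enumerate(ids):
        row = comp.loc[cid]
        ce = float(row["Ce"])
        te = float(row["Te"])
        if ce == 0:
            # isolated component: empty sum over targets
            continue
        if te == 0:
            raise ValueError(
                f"component {cid!r} has edges but zero target edge count; "
                "topology table is internally inconsistent"
            )
        bal = herb_balance(float(row["CB"]), float(row["CK"]), bool(row["single_herb"]))
        c_i = float(row["betweenness"])
        t_sum = float(row["target_betweenness_sum"])
        # Σ_j [C·((Ce/Te + bal)·T_j) + NORM(d)] telescopes to the closed form:
        scd[k] = c_i * (ce / te + bal) * t_sum + ce * norm_d[k]

    df = pd.DataFrame(
        {"herb": comp["herb"].values, "scd": scd}, index=pd.Index(ids, name="id")
    )
    df = df.sort_values(["scd", "id"], ascending=[False, True], kind="stable")
    total = df["scd"].sum()
    df["share"] = df["scd"] / total if total > 0 else 0.0
    df["cumulative_share"] = df["share"].cumsum()
    df["hcgsc"] = False
    return df


def select_hcgsc(table: pd.DataFrame, cum_threshold: float = 0.95) -> set[str]:
    """Pick the high-contribution group: the smallest descending-share prefix
    whose cumulative share reaches ``cum_threshold``.

    Components tied in SCD with the component at the cut are all included.
    The ``hcgsc`` column of ``table`` is updated in place.
    """
    if not 0 < cum_threshold <= 1:
        raise ValueError(f"cum_threshold must lie in (0, 1], got {cum_threshold}")
    if table.empty:
        raise ValueError("cannot select HCGSC from an empty table")
    cum = table["cumulative_share"].to_numpy()
    # first index reaching the threshold (guard rounding at the top end)
    reached = np.nonzero(cum >= cum_threshold - 1e-12)[0]
    cut = reached[0] if reached.size else len(table) - 1
    cut_scd = table["scd"].iloc[cut]
    selected = set(table.index[: cut + 1])
    selected |= set(table.index[table["scd"] == cut_scd])
    table["hcgsc"] = table.index.isin(selected)
    logger.info(
        "HCGSC: %d of %d components reach %.2f%% cumulative share",
        len(selected), len(table), 100 * table.loc[table["hcgsc"], "share"].sum(),
    )
    return selected


def coverage_vs_reference(
    selected: Iterable[str], reference: Iterable[str]
) -> tuple[float, list[str]]:
    """Percent of a reference gene/term set covered by the selected set.

    Returns the percentage (rounded half-up to 2 decimals) and the sorted
    intersection listing.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("coverage needs a non-empty reference set")
    hit = sorted(set(selected) & ref)
    return round_half_up(100 * len(hit) / len(ref), 2), hit


def read_doses(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", dtype={"component_id": str},
                     float_precision="round_trip")
    return dict(zip(df["component_id"], df["dose"].astype(float)))


def write_doses(doses: Mapping[str, float], path) -> None:
    pd.DataFrame(
        sorted(doses.items()), columns=["component_id", "dose"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_scd(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_scd(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
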