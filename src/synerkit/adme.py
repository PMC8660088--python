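"""ADME screening of herbal components.

A two-herb formula contains hundreds of chemical components, of which only a
few have pharmacokinetic profiles compatible with an injectable or oral drug.
This module screens components on two properties:

* **Caco-2 permeability** — a cell-monolayer surrogate for intestinal
  epithelial permeability (TCMSP scale, unitless). Components with a score
  of −0.4 or below are considered non-permeable and are rejected; the bound
  is exclusive, so exactly −0.4 fails.
* **Drug-likeness (DL)** — the Tanimoto similarity between a component's
  molecular-descriptor vector and an average reference drug vector,
  ``f(A, B) = A·B / (|A|² + |B|² − A·B)``. Components with DL ≥ 0.18 pass;
  the bound is inclusive.

Components that fail the numeric screen but are well supported by the
pharmacological literature can be forced through via a whitelist; they are
kept in the passed set and reported separately so the override is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("synerkit.adme")

HERB_A = "A"  # Radix Sophorae Flavescentis ("KS" ids)
HERB_B = "B"  # Rhizoma Heterosmilacis ("BTL" ids)


@dataclass
class ComponentRecord:
    """One chemical component of the formula.

    ``descriptor`` is a non-negative molecular-property vector used when DL is
    computed from scratch rather than taken from a database column. ``dose``
    is the component's mass per formula unit (arbitrary but consistent units).
    Any of the numeric properties may be ``None`` when unknown; the screen
    insists on ``caco2``/``dl`` only for non-whitelisted components.
    """

    id: str
    herb: str
    name: str = ""
    mw: float | None = None
    alogp: float | None = None
    caco2: float | None = None
    dl: float | None = None
    descriptor: np.ndarray | None = None
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.herb not in (HERB_A, HERB_B):
            raise ValueError(
                f"component {self.id!r}: herb must be {HERB_A!r} or {HERB_B!r}, "
                f"got {self.herb!r}"
            )
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"component {self.id!r}: dl must lie in [0, 1], got {self.dl}")
        if self.dose is not None and not self.dose > 0:
            raise ValueError(f"component {self.id!r}: dose must be positive, got {self.dose}")
        if self.descriptor is not None:
            self.descriptor = np.asarray(self.descriptor, dtype=float)


@dataclass
class ScreenPolicy:
    """Thresholds and overrides for the ADME screen.

    ``caco2_min`` is exclusive (a value equal to the threshold fails) while
    ``dl_min`` is inclusive, matching how the two criteria are stated in the
    screening literature this pipeline follows.
    """

    caco2_min: float = -0.4
    dl_min: float = 0.18
    whitelist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not np.isfinite(self.caco2_min) or not np.isfinite(self.dl_min):
            raise ValueError("screen thresholds must be finite")
        self.whitelist = frozenset(self.whitelist)


@dataclass
class ScreenResult:
    passed: list[str]
    failed: list[str]
    whitelisted: list[str]


def tanimoto_dl(a: Sequence[float], b: Sequence[float]) -> float:
    """Tanimoto (Jaccard-extended) similarity of two descriptor vectors.

    ``f(A, B) = A·B / (|A|² + |B|² − A·B)``; for non-negative vectors the
    value lies in [0, 1] and is symmetric in its arguments.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"descriptor length mismatch: {a.shape} vs {b.shape}")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        raise ValueError("tanimoto_dl is undefined when both vectors are zero")
    return dot / denom


def screen_components(
    components: Iterable[ComponentRecord], policy: ScreenPolicy | None = None
) -> ScreenResult:
    """Partition components into passed / failed, honouring the whitelist.

    A component passes when ``caco2 > caco2_min`` and ``dl >= dl_min``.
    Whitelisted components are appended to the passed list regardless of their
    properties and additionally listed under ``whitelisted``. Input order is
    preserved within each list and ``passed + failed`` partitions the input.
    """
    policy = policy or ScreenPolicy()
    passed: list[str] = []
    failed: list[str] = []
    whitelisted: list[str] = []
    deferred: list[str] = []  # whitelisted failures appended after clean passes
    for comp in components:
        on_list = comp.id in policy.whitelist
        if comp.caco2 is None or comp.dl is None:
            if not on_list:
                raise ValueError(
                    f"component {comp.id!r} lacks caco2/dl and is not whitelisted"
                )
            ok = False
        else:
            ok = comp.caco2 > policy.caco2_min and comp.dl >= policy.dl_min
        if ok:
            passed.append(comp.id)
            if on_list:
                whitelisted.append(comp.id)
        elif on_list:
            deferred.append(comp.id)
            whitelisted.append(comp.id)
        else:
            failed.append(comp.id)
    passed.extend(deferred)
    logger.info(
        "ADME screen: %d passed (%d via whitelist), %d failed",
        len(passed), len(deferred), len(failed),
    )
    return ScreenResult(passed=passed, failed=failed, whitelisted=whitelisted)


# ---------------------------------------------------------------------------
# tabular I/O


def components_to_frame(components: Iterable[ComponentRecord]) -> pd.DataFrame:
    rows = []
    for c in components:
        rows.append(
            {
                "id": c.id,
                "herb": c.herb,
                "name": c.name,
                "mw": c.mw,
                "alogp": c.alogp,
                "caco2": c.caco2,
                "dl": c.dl,
                "descriptor": ",".join(repr(float(v)) for v in c.descriptor)
                if c.descriptor is not None
                else "",
                "dose": c.dose,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "herb", "name", "mw", "alogp", "caco2", "dl", "descriptor", "dose"],
    )


def frame_to_components(df: pd.DataFrame) -> list[ComponentRecord]:
    out = []
    for row in df.itertuples(index=False):
        desc = getattr(row, "descriptor", "")
        vec = (
            np.array([float(v) for v in str(desc).split(",")])
            if isinstance(desc, str) and desc
            else None
        )
        out.append(
            ComponentRecord(
                id=str(row.id),
                herb=str(row.herb),
                name=str(row.name) if pd.notna(row.name) else "",
                mw=None if pd.isna(row.mw) else float(row.mw),
                alogp=None if pd.isna(row.alogp) else float(row.alogp),
                caco2=None if pd.isna(row.caco2) else float(row.caco2),
                dl=None if pd.isna(row.dl) else float(row.dl),
                descriptor=vec,
                dose=None if pd.isna(row.dose) else float(row.dose),
            )
        )
    return out


def read_components(path: Path | str) -> list[ComponentRecord]:
    """Read a components.tsv table written by :func:`write_components`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"id": str, "herb": str, "name": str},
        float_precision="round_trip",
    )
    return frame_to_components(df)


def write_components(components: Iterable[ComponentRecord], path: Path | str) -> None:
    # %.17g keeps doubles bit-exact across a write/read cycle
    components_to_frame(components).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_screen_report(
    components: Iterable[ComponentRecord], result: ScreenResult, path: Path | str
) -> pd.DataFrame:
    """Write screen_report.tsv: one row per component with its screen status."""
    status = {cid: "failed" for cid in result.failed}
    status.update({cid: "passed" for cid in result.passed})
    status.update({cid: "whitelisted" for cid in result.whitelisted})
    rows = [
        {"id": c.id, "herb": c.herb, "caco2": c.caco2, "dl": c.dl, "status": status[c.id]}
        for c in components
    ]
    df = pd.DataFrame(rows, columns=["id", "herb", "caco2", "dl", "status"])
    df.to_csv(path, sep="\t", index=False)
    return df
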