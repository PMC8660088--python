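"""Over-representation analysis (ORA) and set-overlap analytics.

Pathway/GO validation stages test whether a query gene set (e.g. the targets
of the high-contribution component group) is enriched in annotated terms. The
test is the one-sided upper-tail hypergeometric probability of drawing at
least the observed overlap when ``query_size`` genes are sampled from the
annotation universe, with Benjamini–Hochberg control of the FDR across all
tested terms. The universe is the union of all annotated genes in the
supplied annotation (configurable), which keeps the tested family explicit
and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

import pandas as pd

from .utils import round_half_up

logger = logging.getLogger("synerkit.enrich")


@dataclass
class Annotation:
    """Term → gene-set mapping over an explicit gene universe."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        for term, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has genes outside the universe: {sorted(extra)[:5]}"
                )


def ora_hypergeometric(
    query: Iterable[str],
    annotation: Annotation,
    fdr_cut: float = 0.05,
    min_term_size: int = 2,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA with BH correction.

    Query genes outside the universe are dropped with a warning. Terms
    smaller than ``min_term_size`` or larger than ``max_term_size`` are
    excluded from the tested family (and from the BH correction). The result
    is sorted by FDR and carries a ``significant`` flag at ``fdr <= fdr_cut``.
    """
    q = set(query)
    dropped = q - annotation.universe
    if dropped:
        logger.warning("dropping %d query genes outside the universe", len(dropped))
        q &= annotation.universe
    if not q:
        raise ValueError("query is empty after intersecting with the annotation universe")

    m_univ = len(annotation.universe)
    n_query = len(q)
    rows = []
    n_excluded = 0
    for term, genes in annotation.terms.items():
        k_term = len(genes)
        if not (min_term_size <= k_term <= max_term_size):
            n_excluded += 1
            continue
        overlap = len(q & genes)
        # P(X >= overlap), X ~ Hypergeom(M=universe, K=term, n=query draws)
        p = float(hypergeom.sf(overlap - 1, m_univ, k_term, n_query))
        rows.append(
            {
                "term": term,
                "overlap": overlap,
                "term_size": k_term,
                "query_size": n_query,
                "universe_size": m_univ,
                "p": min(p, 1.0),
            }
        )
    if n_excluded:
        logger.info("excluded %d terms outside size bounds [%d, %d]",
                    n_excluded, min_term_size, max_term_size)
    if not rows:
        return pd.DataFrame(
            columns=["term", "overlap", "term_size", "query_size",
                     "universe_size", "p", "fdr", "significant"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_cut
    return df.sort_values(["fdr", "p", "term"], kind="stable").reset_index(drop=True)


def overlap_proportions(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[float, float, float]:
    """Percent of the union that is common / unique to a / unique to b.

    Percentages are rounded half-up to 2 decimals and sum to 100 up to
    rounding slack.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("overlap of two empty sets is undefined")
    n = len(union)
    return (
        round_half_up(100 * len(a & b) / n, 2),
        round_half_up(100 * len(a - b) / n, 2),
        round_half_up(100 * len(b - a) / n, 2),
    )


# ---------------------------------------------------------------------------
# GMT / gene-list I/O


def read_gmt(path: Path | str) -> Annotation:
    """Read a GMT annotation: ``term<TAB>description<TAB>gene...`` per line."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
    return Annotation(terms=terms)


def write_gmt(annotation: Annotation, path: Path | str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            genes = "\t".join(sorted(annotation.terms[term]))
            fh.write(f"{term}\t{description}\t{genes}\n" if genes else f"{term}\t{description}\n")


def read_gene_list(path: Path | str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: Path | str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
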