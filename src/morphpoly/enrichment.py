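"""Gene-set enrichment: the eye-expression Fisher test and a hypergeometric
term-enrichment over a user-supplied annotation map.

The central 2x2 test asks whether genes carrying a radical mutation on one
lineage are more often annotated as expressed in a category (e.g. the eye)
than genes mutated on the other lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import hypergeom

__all__ = [
    "AnnotationMap",
    "fisher_exact_2x2",
    "eye_enrichment_report",
    "term_enrichment",
    "round_percent",
]


@dataclass
class AnnotationMap:
    """gene -> set of category labels, over an explicit gene universe."""

    labels: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        extra = set(self.labels) - set(self.universe)
        if extra:
            raise ValueError(f"annotated genes outside universe: {sorted(extra)[:5]}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationMap":
        """Build from a table with columns ``gene`` and ``labels``
        (comma-separated; empty labels = unannotated but in the universe)."""
        labels: dict[str, frozenset[str]] = {}
        universe = set()
        for gene, lab in zip(df["gene"], df["labels"].fillna("")):
            universe.add(str(gene))
            parts = frozenset(x for x in str(lab).split(",") if x)
            if parts:
                labels[str(gene)] = parts
        return cls(labels, frozenset(universe))

    def genes_with(self, label: str) -> frozenset[str]:
        return frozenset(g for g, ls in self.labels.items() if label in ls)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Two-sidedness by the standard "sum of tables at most as probable"
    rule over all tables with the observed margins.  A table with an empty
    row or column margin carries no information: p = 1 with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0 or (a + b) * (c + d) == 0 or (a + c) * (b + d) == 0:
        warnings.warn("degenerate 2x2 margin; p-value defined as 1.0")
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def round_percent(numerator: int, denominator: int) -> float | None:
    """Percentage rounded half-up to one decimal; None for a zero denominator."""
    if denominator == 0:
        return None
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentReport:
    """Per-lineage gene bookkeeping plus the two-lineage Fisher p."""

    rows: pd.DataFrame
    table: tuple[tuple[int, int], tuple[int, int]] | None
    p_value: float | None


def eye_enrichment_report(
    genes_by_lineage: Mapping[str, Iterable[str]],
    annotation: AnnotationMap | None,
    category: str = "eye",
    lineages: tuple[str, str, str] = ("pop1", "pop2", "unoriented"),
) -> EnrichmentReport:
    """Category-expression report for genes with radical mutations.

    ``genes_by_lineage`` maps each lineage to the genes carrying at least
    one radical mutation assigned to it; a gene mutated on both lineages
    appears in (and is counted in) both rows.  For each lineage the report
    gives the gene count, how many have any annotation, how many carry the
    category label, and the category percentage of annotated and of total
    genes (half-up, one decimal).  The Fisher test contrasts the two
    oriented lineages on annotated x category.  Without an annotation map
    the counts are reported with no p-value.
    """
    rows = []
    cells: dict[str, tuple[int, int]] = {}
    for lin in lineages:
        genes = sorted(set(genes_by_lineage.get(lin, ())))
        n = len(genes)
        if annotation is None:
            rows.append((lin, n, None, None, None, None, None))
            continue
        annotated = [g for g in genes if annotation.labels.get(g)]
        positive = [g for g in annotated
                    if category in annotation.labels.get(g, frozenset())]
        n_ann, n_pos = len(annotated), len(positive)
        rows.append((
            lin, n, n - n_ann, n_ann, n_pos,
            round_percent(n_pos, n_ann), round_percent(n_pos, n),
        ))
        cells[lin] = (n_pos, n_ann - n_pos)
    frame = pd.DataFrame(rows, columns=[
        "lineage", "n_genes", "n_unannotated", "n_annotated",
        f"n_{category}", f"pct_{category}_of_annotated",
        f"pct_{category}_of_total",
    ])
    if annotation is None or lineages[0] not in cells or lineages[1] not in cells:
        return EnrichmentReport(frame, None, None)
    table = (cells[lineages[0]], cells[lineages[1]])
    return EnrichmentReport(frame, table, fisher_exact_2x2(table))


def term_enrichment(
    gene_set: Iterable[str],
    annotation: AnnotationMap,
    correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every label in a gene set.

    For a label carried by K of the N universe genes, the p-value is
    P(X >= k) for X ~ Hypergeom(N, K, n) with k carriers observed in the
    n-gene set.  Terms are ordered by p.  ``correct=True`` appends
    Benjamini-Hochberg adjusted values.
    """
    genes = sorted(set(gene_set))
    outside = set(genes) - set(annotation.universe)
    if outside:
        raise ValueError(f"genes outside universe: {sorted(outside)[:5]}")
    N = len(annotation.universe)
    n = len(genes)
    terms = sorted({t for ls in annotation.labels.values() for t in ls})
    rows = []
    for term in terms:
        carriers = annotation.genes_with(term)
        K = len(carriers)
        k = len(carriers & set(genes))
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df = df.sort_values(["p", "term"]).reset_index(drop=True)
    if correct and len(df):
        m = len(df)
        ranked = df["p"].rank(method="max")
        adj = (df["p"] * m / ranked)[::-1].cummin()[::-1].clip(upper=1.0)
        df["p_bh"] = adj
    return df
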