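"""Over-representation analysis, term clustering, and pathway selection.

Gene-set enrichment here is the classical one-sided hypergeometric
(Fisher) over-representation test with Benjamini-Hochberg control across
terms.  Term collections are GMT files extended with a hierarchy level
(roots = 1); shallow, overly general terms are excluded before testing.
Redundant enriched terms are grouped by Jaccard overlap of their gene
sets.  A separate two-criterion filter selects pathways well covered by
the predicted module and populated by early-ranked proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermGeneSet:
    """A named gene set with a hierarchy depth (roots at level 1)."""

    term_id: str
    name: str
    level: int
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"{self.term_id}: empty gene set")
        if self.level < 1:
            raise ValueError(f"{self.term_id}: level must be >= 1")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    level: int
    overlap_genes: frozenset[str]
    p_value: float
    q_value: float
    fold_enrichment: float


@dataclass(frozen=True)
class PathwaySelection:
    term_id: str
    coverage: float
    mean_rank: float | None
    selected: bool


# ---------------------------------------------------------------------------
# GMT I/O.  Format: term_id <TAB> description <TAB> gene1 <TAB> gene2 ...
# The description field carries the hierarchy depth as "level=<n>"; an
# unadorned description defaults to level 1.


def read_gmt(path: str | Path) -> list[TermGeneSet]:
    terms = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term_id, desc = parts[0], parts[1]
            level = 1
            name = desc
            for field in desc.split(";"):
                field = field.strip()
                if field.startswith("level="):
                    level = int(field[len("level="):])
                else:
                    name = field
            genes = frozenset(g for g in parts[2:] if g)
            terms.append(TermGeneSet(term_id=term_id, name=name, level=level, genes=genes))
    return terms


def write_gmt(terms: Iterable[TermGeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in terms:
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.name};level={t.level}\t{genes}\n")


# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up false-discovery-rate adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_genes: Iterable[str],
    collection: Sequence[TermGeneSet],
    background_genes: Iterable[str] | None = None,
    min_level: int = 3,
    q_threshold: float | None = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of each term.

    For a term with K background genes, a query of n genes drawn from a
    background of N, and an observed overlap x, the p-value is
    P(X >= x) with X ~ Hypergeometric(N, K, n).  Terms shallower than
    ``min_level`` are excluded *before* testing, and Benjamini-Hochberg
    adjustment runs across all tested terms.  ``background_genes``
    defaults to the union of the collection's genes.  Results are sorted
    by (q, p); ``q_threshold=None`` returns all tested terms.
    """
    query = {g for g in query_genes}
    if background_genes is None:
        background = set().union(*(t.genes for t in collection)) if collection else set()
        background |= query
    else:
        background = set(background_genes)
        offenders = query - background
        if offenders:
            raise ValueError(f"query genes outside background: {sorted(offenders)}")
    N, n = len(background), len(query & background)
    tested = [t for t in collection if t.level >= min_level and (t.genes & background)]
    rows = []
    for t in tested:
        term_bg = t.genes & background
        overlap = frozenset(term_bg & query)
        K, x = len(term_bg), len(overlap)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        expected = K * n / N if N else 0.0
        fold = (x / expected) if expected > 0 else float("nan")
        rows.append((t, overlap, min(p, 1.0), fold))
    q = benjamini_hochberg([r[2] for r in rows]) if rows else np.array([])
    results = [
        EnrichmentResult(
            term_id=t.term_id,
            name=t.name,
            level=t.level,
            overlap_genes=overlap,
            p_value=p,
            q_value=float(qv),
            fold_enrichment=fold,
        )
        for (t, overlap, p, fold), qv in zip(rows, q)
    ]
    if q_threshold is not None:
        results = [r for r in results if r.q_value <= q_threshold]
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.term_id))


def cluster_terms(
    results: Sequence[EnrichmentResult], similarity_threshold: float = 0.5
) -> list[list[str]]:
    """Group redundant terms by gene-set overlap.

    Terms whose overlap gene sets have Jaccard similarity >= threshold are
    linked; clusters are the connected components of the link graph, so
    every term lands in exactly one cluster.  Clusters are returned sorted
    by size (largest first), members sorted by term id.
    """
    g = nx.Graph()
    g.add_nodes_from(r.term_id for r in results)
    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            if _jaccard(a.overlap_genes, b.overlap_genes) >= similarity_threshold:
                g.add_edge(a.term_id, b.term_id)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    return sorted(clusters, key=lambda c: (-len(c), c[0]))


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def select_pathways_for_module(
    collection: Sequence[TermGeneSet],
    predicted_list: Sequence[str],
    coverage_min: float = 0.30,
    mean_rank_max: float = 300.0,
) -> list[PathwaySelection]:
    """Two-criterion pathway filter over the ranked predicted module.

    coverage = |term genes among the predictions| / |term genes|;
    mean_rank = average prediction rank (1 = first pulled in) of those
    genes.  A pathway is selected when coverage >= ``coverage_min`` AND
    mean_rank <= ``mean_rank_max`` — i.e., it is both well covered and
    populated by early-ranked proteins.  Terms with no predicted gene get
    coverage 0, an undefined mean rank, and are never selected.
    """
    ranks = {p: i for i, p in enumerate(predicted_list, start=1)}
    out = []
    for t in collection:
        hit_ranks = sorted(ranks[g] for g in t.genes if g in ranks)
        coverage = len(hit_ranks) / len(t.genes)
        mean_rank = float(np.mean(hit_ranks)) if hit_ranks else None
        selected = (
            mean_rank is not None
            and coverage >= coverage_min
            and mean_rank <= mean_rank_max
        )
        out.append(
            PathwaySelection(
                term_id=t.term_id, coverage=coverage, mean_rank=mean_rank, selected=selected
            )
        )
    return out
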