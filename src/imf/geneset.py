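"""Gene-set (GO/KEGG) enrichment of DEGs and candidate-gene selection.

Enrichment of a DEG list against user-supplied annotation terms uses the
hypergeometric upper tail: with a universe of N expressed genes, a term of
K members (restricted to the universe) and n DEGs, the term's p-value is
P(X >= overlap). Terms with p <= 0.05 (inclusive) are significant. Genes
recurring in at least ``min_terms`` significant terms of an ontology are
the per-ontology candidates; candidate sets from different ontologies are
merged and deduplicated into a stable, lexicographically ordered core-gene
list. Term p-values are raw by default (an adjusted column is available)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .expression import bh_adjust

DEFAULT_LIPID_KEYWORDS = ("lipid", "fatty acid", "adipo")

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "filter_terms_by_keyword",
    "hypergeom_enrich",
    "select_multiterm_genes",
    "merge_dedup",
    "DEFAULT_LIPID_KEYWORDS",
]


@dataclass(frozen=True)
class GeneSet:
    """One annotation term: id, human-readable name, ontology tag, members."""

    term_id: str
    name: str
    ontology: str
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path: str | Path, ontology: str = "") -> list[GeneSet]:
    """Read GMT: one term per tab-separated line, `id <tab> description <tab>
    gene...`. The description field carries the term name used for keyword
    selection (the stock one-call parsers drop it, so this is done here)."""
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs id, description and >=1 gene")
            sets.append(GeneSet(fields[0], fields[1], ontology, frozenset(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.name, *sorted(s.genes)]) + "\n")


def filter_terms_by_keyword(
    sets: Iterable[GeneSet], keywords: Sequence[str] = DEFAULT_LIPID_KEYWORDS
) -> list[GeneSet]:
    """Terms whose name contains any keyword (case-insensitive substring);
    the default keyword list targets lipid-metabolism terminology."""
    kws = [k.lower() for k in keywords]
    return [s for s in sets if any(k in s.name.lower() for k in kws)]


def hypergeom_enrich(
    degs: Iterable[str],
    annotation: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    DEGs must be a subset of the universe (typically all expressed genes).
    Returns one row per term with the overlap, sizes, raw p = P(X >= k),
    a BH-adjusted column, and the inclusive significance flag p <= alpha.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    degs = frozenset(degs)
    stray = degs - universe
    if stray:
        raise ValueError(f"DEGs outside the universe: {sorted(stray)[:5]}")
    rows = []
    for term in annotation:
        members = term.genes & universe
        overlap = len(members & degs)
        # P(X >= overlap): sf is P(X > k), so shift by one
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(degs)))
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "ontology": term.ontology,
                "overlap": overlap,
                "term_size": len(members),
                "n_degs": len(degs),
                "universe_size": len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p"])
        table["significant"] = table["p"] <= alpha
    return table


def select_multiterm_genes(
    enrichment: pd.DataFrame,
    annotation: Sequence[GeneSet],
    degs: Iterable[str],
    min_terms: int = 5,
    ontology: str | None = None,
) -> set:
    """DEGs appearing in at least ``min_terms`` significant terms.

    Lowering min_terms can only grow the result (monotone selection). An
    ontology tag restricts which significant terms are counted.
    """
    if min_terms < 1:
        raise ValueError("min_terms must be >= 1")
    degs = frozenset(degs)
    sig = enrichment.loc[enrichment["significant"]]
    if ontology is not None:
        sig = sig.loc[sig["ontology"] == ontology]
    sig_ids = set(sig["term_id"])
    counts: dict[str, int] = {}
    for term in annotation:
        if term.term_id in sig_ids:
            for gene in term.genes & degs:
                counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c >= min_terms}


def merge_dedup(sets: Iterable[Iterable[str]]) -> list[str]:
    """Set union of candidate gene lists in stable lexicographic order."""
    merged: set[str] = set()
    for s in sets:
        merged.update(s)
    return sorted(merged)
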