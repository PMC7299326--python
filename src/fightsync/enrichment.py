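"""Hypergeometric over-representation analysis against a gene annotation.

A generic stand-in for GO/KEGG term enrichment: terms come from a
two-column TSV (gene<TAB>term) or a GMT-like file, and each term with at
least ``min_overlap`` genes in the test set is scored with the upper-tail
hypergeometric test against the chosen universe. By default the universe
is all tested (post-filter) genes; restricting it to annotated genes is a
caller choice and changes the p-values accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .diffexpr import GeneSet, bh_fdr, overlap_hypergeometric

__all__ = ["AnnotationTable", "read_annotation", "ora",
           "collapse_identical_terms"]


@dataclass
class AnnotationTable:
    """term id -> (name, member genes) mapping."""

    terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise ValueError(f"empty annotation terms: {empty[:5]}")

    @property
    def annotated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


def read_annotation(path, format: str = "two_column_tsv") -> AnnotationTable:
    """Parse a gene→term table (``two_column_tsv``: gene<TAB>term) or GMT.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate memberships collapse; malformed lines raise with their line
    number.
    """
    lines = Path(path).read_text().splitlines()
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_rows = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if format == "two_column_tsv":
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, term = fields
            terms.setdefault(term, set()).add(gene)
        elif format == "gmt":
            if len(fields) < 3 or not fields[0].strip():
                raise ValueError(f"{path}:{lineno}: expected "
                                 "'term<TAB>desc<TAB>gene...'")
            term, desc, *genes = fields
            terms.setdefault(term, set()).update(g for g in genes if g)
            names[term] = desc
        else:
            raise ValueError(f"unknown annotation format {format!r}")
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"annotation file {path} holds no records")
    return AnnotationTable({t: frozenset(g) for t, g in terms.items()}, names)


def collapse_identical_terms(annotation: AnnotationTable) -> AnnotationTable:
    """Merge terms with identical gene sets (ids joined with '|')."""
    by_genes: dict[frozenset[str], list[str]] = {}
    for term, genes in annotation.terms.items():
        by_genes.setdefault(genes, []).append(term)
    terms, names = {}, {}
    for genes, ids in by_genes.items():
        merged = "|".join(sorted(ids))
        terms[merged] = genes
        names[merged] = "|".join(annotation.names.get(t, t) for t in sorted(ids))
    return AnnotationTable(terms, names)


def ora(test_set: GeneSet, annotation: AnnotationTable, universe: GeneSet,
        min_overlap: int = 2, alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``test_set`` in every annotation term.

    Terms overlapping the test set by fewer than ``min_overlap`` genes are
    omitted. Term sizes are computed within the universe. Output is sorted
    by p; ``significant`` flags p < alpha (strict).
    """
    uni = set(universe.genes)
    outside = set(test_set.genes) - uni
    if outside:
        raise ValueError(f"test genes outside the universe: {sorted(outside)[:10]}")
    n_uni = len(uni)
    n_set = len(test_set.genes)
    rows = []
    for term, genes in annotation.terms.items():
        members = genes & uni
        overlap = members & set(test_set.genes)
        if len(overlap) < min_overlap or not members:
            continue
        res = overlap_hypergeometric(len(members), n_set, len(overlap), n_uni)
        rows.append((term, annotation.names.get(term, term), len(overlap),
                     len(members), n_set, n_uni, res.p, res.log10_p,
                     ",".join(sorted(overlap))))
    out = pd.DataFrame(rows, columns=["term", "name", "overlap", "term_size",
                                      "set_size", "universe_size", "p_value",
                                      "log10_p", "genes"])
    out = out.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["p_value"] < alpha
    return out
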