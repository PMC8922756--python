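"""Per-edge gene-tree concordance bookkeeping.

For every internal edge (bipartition) of a species tree, each gene tree
is classified as concordant, in conflict (reporting which alternative
bipartition it carries), or uninformative — the pie-chart summary style
popularized by PhyParts.  Gene trees missing taxa are handled by
restricting the species bipartition to the shared tip set; gene-tree
edges below an optional support cutoff are treated as unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .genetrees import splits, splits_with_support, tip_labels

__all__ = ["EdgeSummary", "ConcordanceSummary", "classify_edge", "summarize"]


@dataclass
class EdgeSummary:
    """Counts for one species-tree bipartition; the four categories always
    sum to the number of gene trees."""

    bipartition: frozenset[str]
    n_concordant: int = 0
    n_top_alternative: int = 0
    top_alternative_bipartition: frozenset[str] | None = None
    n_other_conflict: int = 0
    n_uninformative: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_concordant
            + self.n_top_alternative
            + self.n_other_conflict
            + self.n_uninformative
        )


@dataclass
class ConcordanceSummary:
    species_tips: frozenset[str]
    edges: list[EdgeSummary] = field(default_factory=list)
    n_gene_trees: int = 0


def _restrict(side: frozenset[str], shared: frozenset[str]) -> frozenset[str]:
    return side & shared


def _compatible(a_side: frozenset, b_side: frozenset, tips: frozenset) -> bool:
    """Two splits on the same tip set are compatible iff one of the four
    side intersections is empty."""
    a2, b2 = tips - a_side, tips - b_side
    return not (a_side & b_side) or not (a_side & b2) or not (a2 & b_side) or not (a2 & b2)


def _canon(side: frozenset[str], tips: frozenset[str]) -> frozenset[str]:
    lowest = min(tips)
    return side if lowest not in side else tips - side


def classify_edge(
    gene_tree: dendropy.Tree,
    species_bipartition: frozenset[str],
    species_tips: frozenset[str],
    support_cutoff: float = 0.0,
):
    """Classify one gene tree against one species-tree bipartition.

    Returns ``("concordant", None)``, ``("conflict", gene_bipartition)``
    or ``("uninformative", None)``.  ``species_bipartition`` is one side
    of the split over ``species_tips``.  Gene-tree edges whose declared
    support is below ``support_cutoff`` (0-100 scale; probabilities are
    rescaled) do not count as resolved.
    """
    gtips = frozenset(tip_labels(gene_tree))
    shared = gtips & species_tips
    if not shared:
        raise ValueError("gene tree and species tree share no tips")
    side = _restrict(species_bipartition, shared)
    other = shared - side
    if len(side) < 2 or len(other) < 2:
        return "uninformative", None
    factor = 100.0 if getattr(gene_tree, "support_scale", None) == "probability" else 1.0
    gene_splits = []
    for gside, sup in splits_with_support(gene_tree).items():
        if support_cutoff > 0 and (sup is None or sup * factor < support_cutoff):
            continue
        rside = _restrict(gside, shared)
        rother = shared - rside
        if len(rside) < 2 or len(rother) < 2:
            continue
        gene_splits.append(_canon(rside, shared))
    target = _canon(side, shared)
    if target in gene_splits:
        return "concordant", None
    conflicting = sorted(
        (g for g in set(gene_splits) if not _compatible(g, target, shared)),
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    if conflicting:
        return "conflict", conflicting[0]
    return "uninformative", None


def summarize(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    support_cutoff: float = 0.0,
) -> ConcordanceSummary:
    """Per-edge concordance counts with the modal conflicting bipartition
    as the top alternative (ties broken by canonical bipartition order)."""
    if not gene_trees:
        raise ValueError("need at least 1 gene tree")
    tips = frozenset(tip_labels(species_tree))
    summary = ConcordanceSummary(tips, n_gene_trees=len(gene_trees))
    for bip in sorted(splits(species_tree), key=lambda s: (len(s), tuple(sorted(s)))):
        edge = EdgeSummary(bip)
        conflicts: dict[frozenset[str], int] = {}
        n_conc = n_uninf = 0
        per_gene = []
        for gt in gene_trees:
            kind, alt = classify_edge(gt, bip, tips, support_cutoff)
            per_gene.append((kind, alt))
            if kind == "concordant":
                n_conc += 1
            elif kind == "uninformative":
                n_uninf += 1
            else:
                conflicts[alt] = conflicts.get(alt, 0) + 1
        edge.n_concordant = n_conc
        edge.n_uninformative = n_uninf
        if conflicts:
            top = min(conflicts.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))))
            edge.top_alternative_bipartition = top[0]
            edge.n_top_alternative = top[1]
            edge.n_other_conflict = sum(conflicts.values()) - top[1]
        summary.edges.append(edge)
    return summary
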