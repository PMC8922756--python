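"""Gene-tree inference and comparison.

Distance-based tree building (p / JC69 / K2P distances + neighbor joining),
non-parametric bootstrap supports, collapsing of poorly supported edges
into polytomies, Robinson-Foulds distances on bipartition sets, and a
quartet-score species-tree estimator (exhaustive for small taxon sets,
greedy NNI hill climbing otherwise).

Trees are ``dendropy.Tree`` objects; newick files produced by external
ML/Bayesian software are first-class inputs, with the support scale
(bootstrap percentage vs posterior probability) declared at read time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from ._seeding import derive_rng
from .alignment import GeneAlignment

__all__ = [
    "DistanceMatrix",
    "read_newick",
    "write_newick",
    "tip_labels",
    "splits",
    "splits_with_support",
    "rf_distance",
    "prune_to_shared",
    "distance_matrix",
    "nj_tree",
    "star_tree",
    "bootstrap_supports",
    "collapse_low_support",
    "quartet_score",
    "estimate_species_tree",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("matrix not symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


# --------------------------------------------------------------------------
# newick I/O and split utilities
# --------------------------------------------------------------------------
def read_newick(text: str, support_scale: str | None = None) -> dendropy.Tree:
    """Parse one newick string; internal node labels become edge supports.

    ``support_scale`` declares how internal labels are to be read:
    ``"bootstrap"`` (percent, 0-100) or ``"probability"`` (0-1).
    """
    tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    tree.support_scale = support_scale
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            nd.support = None
            continue
        try:
            nd.support = float(nd.label) if nd.label not in (None, "") else None
        except ValueError:
            nd.support = None
    return tree


def write_newick(tree: dendropy.Tree, with_supports: bool = True) -> str:
    if with_supports:
        for nd in tree.preorder_node_iter():
            sup = getattr(nd, "support", None)
            if not nd.is_leaf() and sup is not None:
                nd.label = f"{sup:g}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick_list(text: str, support_scale: str | None = None) -> list[dendropy.Tree]:
    """One newick per non-empty line."""
    return [read_newick(line, support_scale) for line in text.splitlines() if line.strip()]


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def _clades(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    below: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    return below


def splits(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side *not*
    containing the lexicographically smallest tip label."""
    labels = tip_labels(tree)
    full, lowest, n = frozenset(labels), labels[0], len(labels)
    below = _clades(tree)
    out = set()
    for nd, side in below.items():
        if nd.parent_node is None or not (2 <= len(side) <= n - 2):
            continue
        out.add(side if lowest not in side else full - side)
    return frozenset(out)


def splits_with_support(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Canonical non-trivial split -> edge support (None if undeclared).

    Where a rooted tree expresses one unrooted split on both root edges,
    the maximum declared support is kept.
    """
    labels = tip_labels(tree)
    full, lowest, n = frozenset(labels), labels[0], len(labels)
    below = _clades(tree)
    out: dict[frozenset[str], float | None] = {}
    for nd, side in below.items():
        if nd.parent_node is None or not (2 <= len(side) <= n - 2):
            continue
        key = side if lowest not in side else full - side
        sup = getattr(nd, "support", None)
        if key in out and out[key] is not None:
            sup = out[key] if sup is None else max(sup, out[key])
        out[key] = sup
    return out


def prune_to_shared(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Copies of both trees restricted to their shared tip set."""
    shared = set(tip_labels(t1)) & set(tip_labels(t2))
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared tips")
    out = []
    for t in (t1, t2):
        c = t.clone(depth=1)
        keep = [lf.taxon for lf in c.leaf_node_iter() if lf.taxon.label in shared]
        c.retain_taxa(keep)
        c.support_scale = getattr(t, "support_scale", None)
        out.append(c)
    return out[0], out[1]


def rf_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = False
) -> int | float:
    """Robinson-Foulds symmetric difference of non-trivial bipartitions.

    Trees must share the same tip set (use :func:`prune_to_shared` first
    otherwise); rooted trees are compared as unrooted.
    """
    l1, l2 = tip_labels(t1), tip_labels(t2)
    if l1 != l2:
        only1 = sorted(set(l1) - set(l2))
        only2 = sorted(set(l2) - set(l1))
        raise ValueError(f"tip sets differ (only in first: {only1}; only in second: {only2})")
    d = len(splits(t1) ^ splits(t2))
    if normalized:
        denom = 2 * (len(l1) - 3)
        return d / denom if denom > 0 else 0.0
    return d


# --------------------------------------------------------------------------
# distances and neighbor joining
# --------------------------------------------------------------------------
def _encode(aln: GeneAlignment) -> np.ndarray:
    arr = np.full((aln.n_taxa, aln.aligned_length), 255, dtype=np.uint8)
    for i, row in enumerate(aln.rows):
        arr[i] = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    out = np.full_like(arr, 255)
    for ch, code in _ENC.items():
        out[arr == ord(ch)] = code
    return out


def distance_matrix(aln: GeneAlignment, model: str = "JC69") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites.

    model: ``p`` (raw proportion), ``JC69`` (Jukes-Cantor
    ``d = -3/4 ln(1 - 4p/3)``), or ``K2P`` (Kimura two-parameter).
    Saturated pairs (log argument <= 0) get ``inf``.
    """
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 rows")
    if model not in {"p", "JC69", "K2P"}:
        raise ValueError(f"unknown model {model!r}")
    enc = _encode(aln)
    n = aln.n_taxa
    mat = np.zeros((n, n))
    purine = (enc == 0) | (enc == 2)
    for i, j in itertools.combinations(range(n), 2):
        ok = (enc[i] < 4) & (enc[j] < 4)
        m = int(ok.sum())
        if m == 0:
            mat[i, j] = mat[j, i] = math.inf
            continue
        diff = ok & (enc[i] != enc[j])
        p = diff.sum() / m
        if model == "p":
            d = p
        elif model == "JC69":
            arg = 1 - 4 * p / 3
            d = -0.75 * math.log(arg) if arg > 0 else math.inf
        else:  # K2P
            ts = (diff & (purine[i] == purine[j])).sum() / m
            tv = p - ts
            a1, a2 = 1 - 2 * ts - tv, 1 - 2 * tv
            d = (-0.5 * math.log(a1) - 0.25 * math.log(a2)) if a1 > 0 and a2 > 0 else math.inf
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(aln.taxa), mat)


def star_tree(labels: list[str]) -> dendropy.Tree:
    newick = "(" + ",".join(sorted(labels)) + ");"
    return read_newick(newick)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining (via scikit-bio) on a finite matrix."""
    bad = [
        (dm.labels[i], dm.labels[j])
        for i in range(len(dm.labels))
        for j in range(i + 1, len(dm.labels))
        if not math.isfinite(dm.matrix[i, j])
    ]
    if bad:
        raise ValueError(f"non-finite distances for pairs: {bad}")
    if len(dm.labels) == 3:
        # closed form: x = (d_ab + d_ac - d_bc)/2 etc.
        a, b, c = dm.labels
        dab, dac, dbc = dm.value(a, b), dm.value(a, c), dm.value(b, c)
        x = max((dab + dac - dbc) / 2, 0.0)
        y = max(dab - x, 0.0)
        z = max(dac - x, 0.0)
        return read_newick(f"({a}:{x:.10g},{b}:{y:.10g},{c}:{z:.10g});")
    sk = _skbio_nj(_SkbioDM(dm.matrix, ids=dm.labels))
    return read_newick(str(sk))


def bootstrap_supports(
    aln: GeneAlignment, n_reps: int = 1000, seed: int = 0, model: str = "JC69"
) -> dendropy.Tree:
    """NJ tree with bootstrap percentages on internal edges.

    Columns are resampled with replacement; support = percentage of
    replicate trees containing each bipartition of the base tree.  An
    alignment with no variation yields an unresolved star tree.
    """
    base_dm = distance_matrix(aln, model)
    if np.allclose(base_dm.matrix, 0):
        return star_tree(list(aln.taxa))
    tree = nj_tree(base_dm)
    counts: dict[frozenset[str], int] = {s: 0 for s in splits(tree)}
    rng = derive_rng(seed, "bootstrap", aln.gene_name)
    L = aln.aligned_length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = GeneAlignment(
            aln.gene_name, list(aln.taxa), ["".join(r[c] for c in cols) for r in aln.rows]
        )
        rep_dm = distance_matrix(rep, model)
        if not np.all(np.isfinite(rep_dm.matrix)):
            continue
        for s in splits(nj_tree(rep_dm)):
            if s in counts:
                counts[s] += 1
    labels = tip_labels(tree)
    full, lowest, n = frozenset(labels), labels[0], len(labels)
    below = _clades(tree)
    for nd, side in below.items():
        if nd.parent_node is None or nd.is_leaf() or not (2 <= len(side) <= n - 2):
            continue
        key = side if lowest not in side else full - side
        nd.support = 100.0 * counts.get(key, 0) / n_reps
    tree.support_scale = "bootstrap"
    return tree


def collapse_low_support(
    tree: dendropy.Tree, threshold: float = 33.0, scale: str | None = None
) -> dendropy.Tree:
    """Contract internal edges with support < ``threshold`` into polytomies.

    ``threshold`` is on a 0-100 scale; posterior probabilities declared via
    ``scale="probability"`` are rescaled by 100 before comparison.  The
    bootstrap threshold 33 is the conventional cutoff for marking a gene
    tree edge as effectively unresolved.
    """
    scale = scale or getattr(tree, "support_scale", None)
    if scale not in {"bootstrap", "probability"}:
        raise ValueError("support scale must be declared ('bootstrap' or 'probability')")
    factor = 100.0 if scale == "probability" else 1.0
    out = tree.clone(depth=1)
    out.support_scale = scale
    labels = tip_labels(out)
    n = len(labels)
    below = _clades(out)
    to_collapse = []
    for nd, side in below.items():
        if nd.parent_node is None or nd.is_leaf() or not (2 <= len(side) <= n - 2):
            continue
        sup = getattr(nd, "support", None)
        if sup is None:
            raise ValueError("internal edge without declared support")
        if sup * factor < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return out


# --------------------------------------------------------------------------
# quartet-score species-tree estimation
# --------------------------------------------------------------------------
def _quartet_resolution(split_set, quartet: frozenset[str]):
    """Induced resolution of a 4-taxon subset, or None if unresolved."""
    for s in split_set:
        inter = quartet & s
        if len(inter) == 2:
            return frozenset([frozenset(inter), quartet - inter])
    return None


def _gene_quartet_maps(gene_trees, labels):
    """Per gene tree: dict quartet -> resolution, over tips shared with labels."""
    maps = []
    for gt in gene_trees:
        tips = set(tip_labels(gt)) & set(labels)
        ss = splits(gt)
        qm = {}
        for q in itertools.combinations(sorted(tips), 4):
            fq = frozenset(q)
            res = _quartet_resolution(ss, fq)
            if res is not None:
                qm[fq] = res
        maps.append(qm)
    return maps


def _score_splits(cand_splits, gene_maps):
    score = 0
    for qm in gene_maps:
        for q, res in qm.items():
            if _quartet_resolution(cand_splits, q) == res:
                score += 1
    return score


def quartet_score(candidate: dendropy.Tree, gene_trees: list[dendropy.Tree]) -> int:
    """Total number of resolved gene-tree quartets agreeing with the candidate."""
    labels = tip_labels(candidate)
    return _score_splits(splits(candidate), _gene_quartet_maps(gene_trees, labels))


def _enumerate_tuple_trees(labels: list[str]):
    """All unrooted binary topologies as nested tuples with a 3-way root."""

    def insert(sub, x):
        out = [(sub, x)]
        if isinstance(sub, tuple):
            a, b = sub
            out += [(a2, b) for a2 in insert(a, x)]
            out += [(a, b2) for b2 in insert(b, x)]
        return out

    trees = [tuple(labels[:3])]
    for x in labels[3:]:
        nxt = []
        for t in trees:
            a, b, c = t
            nxt += [(a2, b, c) for a2 in insert(a, x)]
            nxt += [(a, b2, c) for b2 in insert(b, x)]
            nxt += [(a, b, c2) for c2 in insert(c, x)]
        trees = nxt
    return trees


def _tuple_splits(t, full: frozenset[str], lowest: str) -> frozenset[frozenset[str]]:
    out = set()

    def leafset(sub):
        if isinstance(sub, str):
            return frozenset([sub])
        ls = frozenset().union(*(leafset(c) for c in sub))
        if 2 <= len(ls) <= len(full) - 2:
            out.add(ls if lowest not in ls else full - ls)
        return ls

    for child in t:
        leafset(child)
    return frozenset(out)


def _clades_rooted_at_lowest(split_set, labels):
    """Splits as clades in the view rooted at the smallest label."""
    lowest = labels[0]
    rest = frozenset(labels) - {lowest}
    return {s if lowest not in s else frozenset(labels) - s for s in split_set}, rest


def _newick_from_splits(split_set, labels, supports=None) -> str:
    clades, rest = _clades_rooted_at_lowest(split_set, labels)
    fam = sorted(clades | {rest}, key=len)

    def render(cl):
        members = set(cl)
        children = []
        for sub in sorted((c for c in fam if c < cl), key=len, reverse=True):
            if sub <= members:
                children.append(sub)
                members -= sub
        parts = [render(c) for c in children] + sorted(members)
        label = ""
        if supports is not None and cl in supports and supports[cl] is not None:
            label = f"{supports[cl]:g}"
        return "(" + ",".join(parts) + ")" + label

    return f"({labels[0]},{render(rest)});"


def _nni_neighbors(split_set, labels):
    """All NNI-neighbor split sets of an unrooted binary topology."""
    clades, rest = _clades_rooted_at_lowest(split_set, labels)
    fam = sorted(clades | {rest}, key=len)

    def children_of(cl):
        members, kids = set(cl), []
        for sub in sorted((c for c in fam if c < cl), key=len, reverse=True):
            if sub <= members:
                kids.append(sub)
                members -= sub
        return kids + [frozenset([m]) for m in sorted(members)]

    parent = {}
    for cl in fam:
        for kid in children_of(cl):
            parent[kid] = cl
    lowest = labels[0]
    full = frozenset(labels)
    out = []
    for x in clades:  # each internal edge
        kids = children_of(x)
        if len(kids) != 2:  # polytomy below this edge: no binary NNI here
            continue
        c1, c2 = kids
        par = parent[x]
        sibs = [k for k in children_of(par) if k != x]
        if not sibs:
            continue
        s = sibs[0]
        for keep, move in ((c1, c2), (c2, c1)):
            new_clade = keep | s
            nc = (clades - {x}) | {new_clade}
            canon = frozenset(
                c if lowest not in c else full - c for c in nc if 2 <= len(c) <= len(full) - 2
            )
            out.append(canon)
    return out


def estimate_species_tree(
    gene_trees: list[dendropy.Tree], mode: str = "auto"
) -> dendropy.Tree:
    """Species tree maximizing total gene-tree quartet agreement.

    mode ``exhaustive`` enumerates all unrooted topologies (refused above
    9 taxa); ``greedy-NNI`` hill-climbs from the best-scoring input gene
    tree; ``auto`` picks exhaustive up to 9 taxa.  The returned tree
    carries the per-edge quartet-support fraction (agreeing / resolved
    quartets around the edge) as edge support on a 0-1 scale.
    """
    if len(gene_trees) < 2:
        raise ValueError("need at least 2 gene trees")
    labels = sorted(set().union(*(tip_labels(t) for t in gene_trees)))
    n = len(labels)
    if mode == "auto":
        mode = "exhaustive" if n <= 9 else "greedy-NNI"
    gene_maps = _gene_quartet_maps(gene_trees, labels)
    full, lowest = frozenset(labels), labels[0]

    if mode == "exhaustive":
        if n > 9:
            raise ValueError(
                f"exhaustive search over {n} taxa is intractable; use mode='greedy-NNI'"
            )
        best, best_score = None, -1
        for t in _enumerate_tuple_trees(labels):
            ss = _tuple_splits(t, full, lowest)
            sc = _score_splits(ss, gene_maps)
            if sc > best_score:
                best, best_score = ss, sc
    elif mode == "greedy-NNI":
        starts = [splits(t) for t in gene_trees if set(tip_labels(t)) == set(labels)]
        if not starts:
            raise ValueError("greedy-NNI needs at least one gene tree covering all taxa")
        best = max(starts, key=lambda ss: _score_splits(ss, gene_maps))
        best_score = _score_splits(best, gene_maps)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(best, labels):
                sc = _score_splits(nb, gene_maps)
                if sc > best_score:
                    best, best_score, improved = nb, sc, True
        # hill climbing assumes binary starts; polytomous starts stay put
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # per-edge quartet-support fraction
    clades, rest = _clades_rooted_at_lowest(best, labels)
    supports = {}
    for cl in clades:
        x, y = sorted(cl), sorted(full - cl)
        agree = total = 0
        for px in itertools.combinations(x, 2):
            for py in itertools.combinations(y, 2):
                q = frozenset(px + py)
                res = frozenset([frozenset(px), frozenset(py)])
                for qm in gene_maps:
                    got = qm.get(q)
                    if got is not None:
                        total += 1
                        if got == res:
                            agree += 1
        supports[cl] = (agree / total) if total else None
    tree = read_newick(_newick_from_splits(best, labels, supports), support_scale="probability")
    tree.quartet_score = best_score
    return tree
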