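"""Synthetic data with known ground truth for every downstream stage.

The generator emulates the statistical structure of a plastome
phylogenomics study: a Yule species tree; per-gene trees derived from it
with a controlled number of subtree-prune-regraft (SPR) perturbations per
discordance regime; nucleotide alignments evolved under an HKY model with
a target GC content; codon alignments with a controlled dN/dS (omega) via
proposal/acceptance thinning of nonsynonymous changes; and quadripartite
plastomes with a planted exact inverted repeat, planted microsatellites,
and an optional single-gene deletion (the analogue of a naturally lost
ribosomal-protein gene).

Determinism: one integer seed governs everything; each stage and gene
draws from a stream derived by stable hashing of (seed, stage, index), so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm

from ._seeding import derive_pyrandom, derive_rng
from .alignment import GeneAlignment
from .molevol import SENSE_CODONS, STOP_CODONS, translate_codon
from .plastome import Feature, PlastomeRecord, revcomp, write_plastome
from .seqstats import DEFAULT_SSR_MIN_UNITS, find_ssrs

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "simulate_gene_trees",
    "simulate_alignment",
    "simulate_codon_alignment",
    "simulate_plastome",
    "simulate_plastome_set",
    "write_dataset",
    "FUNCTIONAL_GROUPS",
]

_BASES = np.array(list("ACGT"))

# the 11 conventional plastid functional groups
FUNCTIONAL_GROUPS = ["ATP", "NDH", "PET", "PSA", "PSB", "RBC", "RPL", "RPO", "RPS", "YCF", "OG"]

# plastid-style gene names used for synthetic plastome annotation
DEFAULT_GENE_NAMES = [
    "psbA", "matK", "atpA", "atpF", "atpH", "atpI", "rps2", "rpoC2", "rpoC1", "rpoB",
    "petN", "psbM", "psbD", "psbC", "psaB", "psaA", "ycf3", "rps4", "ndhJ", "ndhK",
    "ndhC", "atpE", "atpB", "rbcL", "rpl33", "accD", "psaI", "ycf4", "cemA", "petA",
    "psbJ", "psbL", "psbF", "psbE", "petL", "petG", "psaJ", "rps18", "rpl20", "clpP",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the kind
    of data the pipeline targets (tens of taxa, tens of genes, AT-rich
    plastomes with a ~25 kb inverted repeat)."""

    seed: int = 0
    n_taxa: int = 12
    # (n_genes, spr_moves) per discordance regime
    regimes: list[tuple[int, int]] = field(default_factory=lambda: [(20, 0), (20, 2), (20, 6)])
    gene_length_range: tuple[int, int] = (600, 1200)
    gc_target: float = 0.38
    subst_rate: float = 0.05
    omega: float = 0.2
    kappa: float = 2.0
    # plastome construction
    plastome_length: int = 160_000
    ir_length: int = 25_000
    ir_contraction: int = 0
    n_plastome_genes: int = 30
    plastome_gene_length: int = 600
    n_ir_genes: int = 2
    ssr_plan: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("A", 12, 2_000), ("AT", 8, 4_500), ("ATAG", 4, 6_000)]
    )
    delete_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ValueError("regimes must be non-empty")
        if not (0 < self.gc_target < 1):
            raise ValueError("gc_target must be in (0,1)")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        for motif, units, pos in self.ssr_plan:
            if not (1 <= len(motif) <= 6):
                raise ValueError(f"motif {motif!r} not of length 1-6")
            for d in range(1, len(motif)):
                if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
                    raise ValueError(f"motif {motif!r} is periodic")
        if self.ir_length < 1000:
            raise ValueError("ir_length must be >= 1000 bp")
        if self.plastome_length <= 2 * self.ir_length + 2000:
            raise ValueError("plastome too short for two IR copies")
        if self.delete_gene is not None:
            planted = DEFAULT_GENE_NAMES[: self.n_plastome_genes]
            if self.delete_gene not in planted:
                raise ValueError(
                    f"delete_gene {self.delete_gene!r} is not among the "
                    f"{self.n_plastome_genes} planted genes"
                )

    @property
    def n_genes(self) -> int:
        return sum(n for n, _ in self.regimes)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------
def _tree_height(tree: dendropy.Tree) -> float:
    return max(
        sum(nd.edge.length or 0.0 for nd in [lf, *lf.ancestor_iter()] if nd.parent_node)
        for lf in tree.leaf_node_iter()
    )


def _scale_tree(tree: dendropy.Tree, height: float) -> None:
    h = _tree_height(tree)
    if h > 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= height / h


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Binary rooted Yule (pure-birth) tree scaled to height 1, tips
    labelled t1..tN."""
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4 (no informative unrooted bipartition below)")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=derive_pyrandom(seed, "yule", n_taxa),
    )
    # the final birth leaves two zero-length tip edges; extend all tips by
    # the same amount to keep the tree ultrametric with positive lengths
    ext = 0.1 * _tree_height(tree) + 0.01
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + ext
    tree.seed_node.edge.length = None
    for i, lf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label), 1):
        lf.taxon.label = f"t{i}"
    _scale_tree(tree, 1.0)
    tree.support_scale = None
    return tree


def _random_spr(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random subtree-prune-regraft move, in place.

    The pruned subtree is never regrafted onto the edge it came from, so
    the unrooted topology almost always changes.
    """
    total = len(tree.leaf_nodes())
    candidates = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    while True:
        u = candidates[int(rng.integers(len(candidates)))]
        # leave >= 3 leaves behind: a 2-leaf remainder has a single unrooted
        # edge, and regrafting there can only restore the original topology
        if total - len(u.leaf_nodes()) >= 3:
            break
    p = u.parent_node
    p.remove_child(u)
    forbidden: list = []
    remaining = p.child_nodes()
    if len(remaining) == 1:
        c = remaining[0]
        if p.parent_node is None:
            p.remove_child(c)
            c.parent_node = None
            tree.seed_node = c
            c.edge.length = None
            # c is now a degree-2 root: its two child edges are one unrooted
            # edge, the one u came from — regrafting there restores topology
            forbidden = list(c.child_nodes())
        else:
            g = p.parent_node
            total_len = (c.edge.length or 0.0) + (p.edge.length or 0.0)
            p.remove_child(c)
            g.remove_child(p)
            g.add_child(c)
            c.edge.length = total_len
            forbidden = [c]
    targets = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd not in forbidden
    ]
    v = targets[int(rng.integers(len(targets)))]
    pv = v.parent_node
    vlen = v.edge.length or 0.0
    mid = dendropy.Node()
    pv.remove_child(v)
    pv.add_child(mid)
    mid.edge.length = vlen / 2
    mid.add_child(v)
    v.edge.length = vlen / 2
    mid.add_child(u)


def simulate_gene_trees(
    species_tree: dendropy.Tree, regimes: list[tuple[int, int]], seed: int
) -> list[dendropy.Tree]:
    """Per-gene trees with regime-controlled topological discordance.

    Every gene tree in a regime is the species tree with exactly
    ``spr_moves`` random SPR perturbations; the moves are drawn once per
    regime (from a regime-specific stream), so genes within a regime
    share a topology and regimes form distinct, separable locations in
    tree space — the structure the downstream clustering analysis
    assumes.  Branch lengths are re-jittered multiplicatively per gene.

    Each returned tree carries ``gene_name`` (g001, ...) and ``regime``
    (index into ``regimes``) attributes.
    """
    out = []
    gene_idx = 0
    for r_idx, (n_genes, spr_moves) in enumerate(regimes):
        if spr_moves < 0:
            raise ValueError("spr_moves must be >= 0")
        regime_rng = derive_rng(seed, "regime", r_idx)
        backbone = species_tree.clone(depth=1)
        for _ in range(spr_moves):
            _random_spr(backbone, regime_rng)
        for _ in range(n_genes):
            gene_idx += 1
            name = f"g{gene_idx:03d}"
            rng = derive_rng(seed, "genetree", gene_idx)
            gt = backbone.clone(depth=1)
            for e in gt.preorder_edge_iter():
                if e.length is not None:
                    e.length *= float(rng.lognormal(0.0, 0.25))
            gt.gene_name = name
            gt.regime = r_idx
            gt.support_scale = None
            out.append(gt)
    return out


# --------------------------------------------------------------------------
# nucleotide alignments (HKY)
# --------------------------------------------------------------------------
def _hky_matrix(gc: float, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
        q[i, i] = -q[i].sum()
    mu = -(freqs * np.diag(q)).sum()
    return q / mu, freqs


def simulate_alignment(
    tree: dendropy.Tree,
    length: int,
    gc_target: float,
    subst_rate: float,
    seed: int,
    kappa: float = 2.0,
    name: str = "gene",
) -> GeneAlignment:
    """Sequences evolved along ``tree`` under HKY with stationary GC =
    ``gc_target``; branch lengths are rescaled so the root-to-tip height
    equals ``subst_rate`` expected substitutions per site."""
    if length < 30:
        raise ValueError("length must be >= 30")
    rng = derive_rng(seed, "alignment", name)
    q, freqs = _hky_matrix(gc_target, kappa)
    height = _tree_height(tree)
    degenerate = height == 0 or subst_rate == 0
    states: dict[dendropy.Node, np.ndarray] = {}
    root_state = rng.choice(4, size=length, p=freqs)
    pmat_cache: dict[float, np.ndarray] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[nd] = root_state
            continue
        t = 0.0 if degenerate else (nd.edge.length or 0.0) / height * subst_rate
        if t == 0.0:
            states[nd] = states[nd.parent_node]
            continue
        if t not in pmat_cache:
            pmat_cache[t] = np.cumsum(expm(q * t), axis=1)
        cum = pmat_cache[t]
        u = rng.random(length)
        states[nd] = (u[:, None] > cum[states[nd.parent_node]]).sum(axis=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: (len(n.taxon.label), n.taxon.label))
    taxa = [lf.taxon.label for lf in leaves]
    rows = ["".join(_BASES[states[lf]]) for lf in leaves]
    aln = GeneAlignment(name, taxa, rows)
    aln.degenerate = degenerate
    return aln


# --------------------------------------------------------------------------
# codon alignments (proposal/acceptance thinning)
# --------------------------------------------------------------------------
def simulate_codon_alignment(
    tree: dendropy.Tree,
    n_codons: int,
    omega: float,
    seed: int,
    subst_rate: float | None = None,
    name: str = "codon_gene",
) -> GeneAlignment:
    """Codon sequences evolved by proposing uniform single-nucleotide
    changes and accepting nonsynonymous ones with probability ``omega``.

    Proposals creating stop codons are always rejected, so no sequence
    ever contains an internal stop.  Branch lengths are proposal
    intensities per nucleotide site (rescaled to ``subst_rate`` height
    when given).  Counting-method omega estimates recover the input
    because the proposal process is symmetric and untransformed.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = derive_rng(seed, "codons", name)
    work = tree.clone(depth=1)
    if subst_rate is not None:
        _scale_tree(work, subst_rate)
    root = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    states: dict[dendropy.Node, list[str]] = {}
    for nd in work.preorder_node_iter():
        if nd.parent_node is None:
            states[nd] = root
            continue
        t = nd.edge.length or 0.0
        parent = states[nd.parent_node]
        n_events = rng.poisson(3.0 * t, size=n_codons)
        seq = list(parent)
        for ci in np.nonzero(n_events)[0]:
            codon = seq[ci]
            for _ in range(n_events[ci]):
                pos = int(rng.integers(3))
                old = codon[pos]
                new = "ACGT".replace(old, "")[int(rng.integers(3))]
                cand = codon[:pos] + new + codon[pos + 1 :]
                if cand in STOP_CODONS:
                    continue
                syn = translate_codon(cand) == translate_codon(codon)
                # thin whichever class is the slower one so the realized
                # rate ratio is omega on both sides of 1
                if omega <= 1.0:
                    accept = 1.0 if syn else omega
                else:
                    accept = 1.0 / omega if syn else 1.0
                if accept >= 1.0 or rng.random() < accept:
                    codon = cand
            seq[ci] = codon
        states[nd] = seq
    leaves = sorted(work.leaf_node_iter(), key=lambda n: (len(n.taxon.label), n.taxon.label))
    aln = GeneAlignment(name, [lf.taxon.label for lf in leaves], ["".join(states[lf]) for lf in leaves])
    return aln


# --------------------------------------------------------------------------
# plastomes
# --------------------------------------------------------------------------
def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random internal sense codons + stop; no qualifying SSR inside."""
    assert length % 3 == 0 and length >= 9
    internal = [c for c in SENSE_CODONS if c != "ATG"]
    while True:
        body = "".join(
            internal[int(i)] for i in rng.integers(0, len(internal), size=length // 3 - 2)
        )
        seq = "ATG" + body + "TAA"
        if not find_ssrs(seq):
            return seq


def simulate_plastome(
    config: SimulationConfig, taxon_id: str = "syn1", delete_gene: str | None = None
) -> tuple[PlastomeRecord, dict]:
    """One synthetic circular plastome plus its ground truth.

    Layout: LSC + IRb + SSC + IRa with IRa the exact reverse complement
    of IRb (optionally contracted by ``ir_contraction`` bp at its SSC
    end).  Genes are planted in the single-copy regions and (in duplicate)
    in the IR; microsatellites from ``ssr_plan`` are overwritten into
    intergenic single-copy background, with flanking bases adjusted so
    each run is exactly as long as planted; accidental background runs
    meeting the reporting thresholds are broken.  The truth dict records
    IR boundaries, every gene's location and sequence, every planted SSR,
    and the deleted gene (if any).
    """
    cfg = config
    rng = derive_rng(cfg.seed, "plastome", taxon_id)
    nominal, ir = cfg.plastome_length, cfg.ir_length
    matched = ir - cfg.ir_contraction  # realized IRa length
    lsc_len = int(round(0.8 * (nominal - 2 * ir)))
    ssc_len = (nominal - 2 * ir) - lsc_len
    b0 = lsc_len  # IRb start
    ssc0 = b0 + ir
    a0 = ssc0 + ssc_len  # IRa start
    total = a0 + matched  # realized genome length

    arr = _random_seq(rng, a0 + ir, cfg.gc_target)
    seq = list("".join(_BASES[arr]))

    # ---- genes ------------------------------------------------------------
    gene_names = list(DEFAULT_GENE_NAMES[: cfg.n_plastome_genes])
    if len(gene_names) < cfg.n_plastome_genes:
        gene_names += [f"orf{i}" for i in range(cfg.n_plastome_genes - len(gene_names))]
    n_ir = min(cfg.n_ir_genes, cfg.n_plastome_genes)
    n_ssc = min(2, cfg.n_plastome_genes - n_ir)
    glen = cfg.plastome_gene_length - cfg.plastome_gene_length % 3
    features: list[Feature] = []
    truth_genes: dict[str, dict] = {}
    occupied: list[tuple[int, int]] = []

    def plant(name: str, start: int, region: str) -> None:
        gseq = _random_cds(rng, glen)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = gseq if strand == "+" else revcomp(gseq)
        seq[start : start + glen] = placed
        in_ir = region == "IR"
        features.append(Feature(name, "CDS", strand, [(start, start + glen)], in_ir=in_ir))
        occupied.append((start, start + glen))
        truth_genes[name] = {
            "intervals": [(start, start + glen)],
            "strand": strand,
            "seq": gseq,
            "region": region,
        }
        if in_ir:  # mirrored copy in IRa (IRa position p maps to IRb b0+ir-1-p)
            m_start = a0 - cfg.ir_contraction + (b0 + ir - (start + glen))
            m_end = m_start + glen
            if a0 <= m_start and m_end <= total:
                features.append(
                    Feature(name, "CDS", "-" if strand == "+" else "+", [(m_start, m_end)], in_ir=True)
                )
                occupied.append((m_start, m_end))

    margin = 60
    skip = {delete_gene} if delete_gene else set()
    # single-copy LSC genes
    lsc_slots = cfg.n_plastome_genes - n_ir - n_ssc
    gap = (lsc_len - 2 * margin) // max(lsc_slots, 1)
    gap_s_chk = (ssc_len - 2 * margin) // max(n_ssc, 1)
    gap_i_chk = (ir - 2 * margin) // max(n_ir, 1)
    used = [g for g, n in ((gap, lsc_slots), (gap_s_chk, n_ssc), (gap_i_chk, n_ir)) if n > 0]
    if used and min(used) < glen + 2:
        raise ValueError("planted genes would overlap; reduce n_plastome_genes or gene length")
    idx = 0
    for i in range(lsc_slots):
        name = gene_names[idx]
        idx += 1
        if name in skip:
            continue
        plant(name, margin + i * gap, "LSC")
    # SSC genes
    gap_s = (ssc_len - 2 * margin) // max(n_ssc, 1)
    for i in range(n_ssc):
        name = gene_names[idx]
        idx += 1
        if name in skip:
            continue
        plant(name, ssc0 + margin + i * gap_s, "SSC")
    # IR genes (inside IRb, mirrored automatically below)
    gap_i = (ir - 2 * margin) // max(n_ir, 1)
    for i in range(n_ir):
        name = gene_names[idx]
        idx += 1
        if name in skip:
            continue
        plant(name, b0 + margin + i * gap_i, "IR")

    # ---- inverted repeat: IRa := revcomp(IRb), optionally contracted ------
    irb_seq = "".join(seq[b0 : b0 + ir])
    ira_seq = revcomp(irb_seq)[cfg.ir_contraction :]
    seq = seq[:a0] + list(ira_seq)  # realized genome: LSC+IRb+SSC+IRa
    assert len(seq) == total
    # prevent inward extension of the exact-repeat match: the matched pair
    # is IRb[0:matched] vs IRa; its inward flanks are seq[b0+matched] and
    # the last SSC base, which must not be reverse complements
    if seq[a0 - 1] == _COMP[seq[b0 + matched]]:
        seq[a0 - 1] = next(c for c in "ACGT" if c != seq[a0 - 1] and c != seq[a0 - 2])

    # ---- SSRs -------------------------------------------------------------
    truth_ssrs = []
    for motif, units, pos in cfg.ssr_plan:
        end = pos + len(motif) * units
        if not (end < b0 or (ssc0 <= pos and end < a0)):
            raise ValueError(f"SSR at {pos} not inside a single-copy region")
        if any(pos < oe + 1 and os_ - 1 < end for os_, oe in occupied):
            raise ValueError(f"SSR at {pos} overlaps a planted gene")
        seq[pos:end] = motif * units
        # flanks must break the run exactly at the planted extent
        before, after = motif[-1], motif[0]
        if seq[pos - 1] == before:
            seq[pos - 1] = "ACGT".replace(before, "")[0]
        if seq[end] == after:
            seq[end] = "ACGT".replace(after, "")[0]
        occupied.append((pos - 1, end + 1))
        # record the canonical (smallest-rotation) motif, matching the scanner
        canon = min(motif[i:] + motif[:i] for i in range(len(motif)))
        truth_ssrs.append({"motif": canon, "unit_count": units, "start": pos, "end": end})

    # ---- break accidental SSRs in intergenic background -------------------
    def protected(i: int) -> bool:
        if b0 <= i < b0 + ir or a0 <= i:
            return True  # never touch the IR (symmetry)
        return any(s <= i < e for s, e in occupied)

    for _ in range(8):
        text = "".join(seq)
        planted = {(r["start"], r["end"]) for r in truth_ssrs}
        accidental = [
            r for r in find_ssrs(text) if (r.start, r.end) not in planted
        ]
        accidental = [
            r for r in accidental if not protected((r.start + r.end) // 2)
        ]
        if not accidental:
            break
        for r in accidental:
            mid = (r.start + r.end) // 2
            seq[mid] = "ACGT".replace(seq[mid], "")[0]
    record = PlastomeRecord(taxon_id, "".join(seq), features)
    truth = {
        "taxon": taxon_id,
        "ir": {"irb": (b0, b0 + ir), "ira": (a0, total), "matched_length": matched,
               "lsc": (0, b0), "ssc": (ssc0, a0)},
        "genes": truth_genes,
        "ssrs": truth_ssrs,
        "deleted_gene": delete_gene,
    }
    return record, truth


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def simulate_plastome_set(
    config: SimulationConfig, n_records: int = 5
) -> tuple[list[PlastomeRecord], list[dict]]:
    """A set of plastomes; when ``config.delete_gene`` is set, the gene is
    deleted from exactly one record (the last)."""
    records, truths = [], []
    for i in range(n_records):
        delete = config.delete_gene if i == n_records - 1 else None
        rec, truth = simulate_plastome(config, taxon_id=f"syn{i + 1}", delete_gene=delete)
        records.append(rec)
        truths.append(truth)
    return records, truths


# --------------------------------------------------------------------------
# full dataset
# --------------------------------------------------------------------------
def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write a complete synthetic study to ``outdir``.

    Emits the species tree and gene trees (newick), per-gene nucleotide
    and codon FASTA alignments, synthetic plastome GenBank files, a
    functional-group map, and a machine-readable TSV truth file.  Returns
    the in-memory truth bundle.
    """
    from .genetrees import write_newick

    out = Path(outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "codon_alignments").mkdir(exist_ok=True)
    (out / "genbank").mkdir(exist_ok=True)

    cfg = config
    sp = simulate_species_tree(cfg.n_taxa, cfg.seed)
    gts = simulate_gene_trees(sp, cfg.regimes, cfg.seed)
    (out / "species_tree.nwk").write_text(write_newick(sp) + "\n")
    (out / "gene_trees.nwk").write_text("".join(write_newick(t) + "\n" for t in gts))

    lo, hi = cfg.gene_length_range
    groups = {}
    regime_of = {}
    for i, gt in enumerate(gts):
        rng = derive_rng(cfg.seed, "genelen", i + 1)
        length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        aln = simulate_alignment(
            gt, length, cfg.gc_target, cfg.subst_rate, cfg.seed, cfg.kappa, name=gt.gene_name
        )
        aln.to_fasta(out / "alignments" / f"{gt.gene_name}.fasta")
        caln = simulate_codon_alignment(
            gt, max(length // 3, 50), cfg.omega, cfg.seed, subst_rate=cfg.subst_rate,
            name=gt.gene_name,
        )
        caln.to_fasta(out / "codon_alignments" / f"{gt.gene_name}.fasta")
        groups[gt.gene_name] = FUNCTIONAL_GROUPS[i % len(FUNCTIONAL_GROUPS)]
        regime_of[gt.gene_name] = gt.regime

    records, truths = simulate_plastome_set(cfg)
    for rec in records:
        (out / "genbank" / f"{rec.id}.gb").write_text(write_plastome(rec))

    with open(out / "functional_groups.tsv", "w") as fh:
        fh.write("gene\tgroup\n")
        for g, grp in sorted(groups.items()):
            fh.write(f"{g}\t{grp}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("category\tname\tvalue\n")
        for g, r in sorted(regime_of.items()):
            fh.write(f"gene_regime\t{g}\t{r}\n")
        for t in truths:
            fh.write(f"ir_boundaries\t{t['taxon']}\t{json.dumps(t['ir'])}\n")
            for s in t["ssrs"]:
                fh.write(f"ssr\t{t['taxon']}\t{json.dumps(s)}\n")
            if t["deleted_gene"]:
                fh.write(f"deleted_gene\t{t['taxon']}\t{t['deleted_gene']}\n")
    return {
        "species_tree": sp,
        "gene_trees": gts,
        "groups": groups,
        "regimes": regime_of,
        "plastome_truths": truths,
    }
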