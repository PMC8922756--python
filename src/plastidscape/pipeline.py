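"""End-to-end orchestration: characterization, gene statistics, rates,
trees, concordance and tree-space, driven by one config.

Each stage writes tabular outputs into its own subdirectory of the
output folder and records a manifest entry (stage parameters + output
checksums).  A rerun with an unchanged config skips completed stages
unless forced; outputs are deterministic given the seed, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .alignment import GeneAlignment
from . import seqstats, molevol, genetrees, concordance as concord_mod, treespace
from .plastome import (
    detect_quadripartite,
    junction_report,
    presence_absence,
    read_plastome,
)

log = logging.getLogger("plastidscape")

__all__ = ["PipelineConfig", "run_all", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Defaults follow the conventional choices for this analysis: 600/100
    sliding window, pi screening threshold 0.006, 33% bootstrap collapse,
    1000 bootstrap replicates, JC69 distances, SSR class minima
    10/5/4/3/3/3.
    """

    alignments: str = ""
    codon_alignments: str = ""
    genbank: str = ""
    functional_groups: str = ""
    output: str = "out"
    reference_taxon: str = "t1"
    window: int = 600
    step: int = 100
    pi_threshold: float = 0.006
    collapse_threshold: float = 33.0
    min_ir_len: int = 1000
    distance_model: str = "JC69"
    bootstrap_reps: int = 1000
    k_max: int = 8
    seed: int = 0
    ssr_min_units: dict = field(default_factory=lambda: dict(seqstats.DEFAULT_SSR_MIN_UNITS))

    def validate(self) -> None:
        for name in ("alignments", "codon_alignments", "genbank", "functional_groups"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured path {name} = {p!r} does not exist")
        if not self.alignments:
            raise ValueError("an alignments directory is required")


def load_config(path: str | Path) -> PipelineConfig:
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f for f in PipelineConfig.__dataclass_fields__}
    cfg = PipelineConfig(**{k: v for k, v in data.items() if k in known})
    if "ssr_min_units" in data:
        cfg.ssr_min_units = {int(k): int(v) for k, v in data["ssr_min_units"].items()}
    return cfg


# --------------------------------------------------------------------------
def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_alignments(folder: str) -> dict[str, GeneAlignment]:
    files = sorted(Path(folder).glob("*.fasta"))
    if not files:
        raise ValueError(f"no FASTA alignments found in {folder}")
    return {f.stem: GeneAlignment.from_fasta(f) for f in files}


class _Stages:
    """Stage runner with manifest-based skipping."""

    def __init__(self, config: PipelineConfig, force: bool):
        self.cfg = config
        self.force = force
        self.out = Path(config.output)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        self.cfg_hash = hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()

    def done(self, stage: str) -> bool:
        entry = self.manifest.get(stage)
        if self.force or not entry or entry.get("config") != self.cfg_hash:
            return False
        return all(
            (self.out / f).exists() and _sha(self.out / f) == h
            for f, h in entry["outputs"].items()
        )

    def record(self, stage: str, files: list[Path]) -> None:
        self.manifest[stage] = {
            "config": self.cfg_hash,
            "seed": self.cfg.seed,
            "outputs": {str(f.relative_to(self.out)): _sha(f) for f in files},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# --------------------------------------------------------------------------
def stage_characterize(cfg: PipelineConfig, out: Path) -> list[Path]:
    records = [
        read_plastome(p.read_text()) for p in sorted(Path(cfg.genbank).glob("*.gb"))
    ]
    if not records:
        raise ValueError(f"no GenBank records in {cfg.genbank}")
    structures = [detect_quadripartite(r, cfg.min_ir_len) for r in records]
    files = []
    rows = []
    for rec, st in zip(records, structures):
        if st is None:
            rows.append({"taxon": rec.id, "ir_length": 0, "detected": False})
        else:
            rows.append(
                {
                    "taxon": rec.id,
                    "ir_length": st.ir_length,
                    "detected": True,
                    "irb_start": st.irb[0],
                    "irb_end": st.irb[1],
                    "ira_start": st.ira[0],
                    "ira_end": st.ira[1],
                }
            )
    files.append(_write(pd.DataFrame(rows), out / "characterize" / "quadripartite.tsv"))
    files.append(
        _write(junction_report(structures, records), out / "characterize" / "junctions.tsv")
    )
    pam = presence_absence(records)
    files.append(
        _write(
            pd.DataFrame(pam.matrix, index=pam.genes, columns=pam.taxa).reset_index(names="gene"),
            out / "characterize" / "presence_absence.tsv",
        )
    )
    files.append(
        _write(
            pd.DataFrame(pam.loss_events, columns=["gene", "taxon"]),
            out / "characterize" / "loss_events.tsv",
        )
    )
    ssr_rows = [
        {"taxon": rec.id, "motif": r.motif, "unit_count": r.unit_count, "start": r.start,
         "end": r.end}
        for rec in records
        for r in seqstats.find_ssrs(rec.sequence, rec.id, cfg.ssr_min_units)
    ]
    files.append(_write(pd.DataFrame(ssr_rows), out / "characterize" / "ssrs.tsv"))
    return files


def stage_genestats(cfg: PipelineConfig, out: Path) -> list[Path]:
    alns = _load_alignments(cfg.alignments)
    rows = []
    for g, aln in sorted(alns.items()):
        s, pv = seqstats.segregating_stats(aln)
        rows.append(
            {
                "gene": g,
                "gc": seqstats.gc_content(aln),
                "aligned_length": aln.aligned_length,
                "S": s,
                "pv": pv,
                "pi": seqstats.nucleotide_diversity(aln),
            }
        )
    files = [_write(pd.DataFrame(rows), out / "genestats" / "per_gene.tsv")]
    concat = GeneAlignment.concatenate([alns[g] for g in sorted(alns)])
    profile = seqstats.sliding_window_pi(concat, cfg.window, cfg.step)
    files.append(
        _write(
            pd.DataFrame(
                {"start": profile.starts, "midpoint": profile.midpoints, "pi": profile.pi_values}
            ),
            out / "genestats" / "window_pi.tsv",
        )
    )
    hot = seqstats.screen_hotspots(profile, cfg.pi_threshold)
    files.append(
        _write(
            pd.DataFrame(hot, columns=["start", "end", "max_pi"]),
            out / "genestats" / "hotspots.tsv",
        )
    )
    return files


def stage_rates(cfg: PipelineConfig, out: Path) -> list[Path]:
    calns = _load_alignments(cfg.codon_alignments)
    nalns = _load_alignments(cfg.alignments)
    missing = sorted(set(nalns) - set(calns))
    if missing:
        raise ValueError(f"codon alignment missing for genes: {missing}")
    rates = molevol.per_gene_dnds(calns, cfg.reference_taxon)
    df = pd.DataFrame(
        [
            {"gene": g, "dn": r.dn, "ds": r.ds, "omega": r.omega, "low_dn": r.low_dn_flag}
            for g, r in sorted(rates.items())
        ]
    )
    files = [_write(df, out / "rates" / "per_gene_rates.tsv")]
    taxon_rates = molevol.pairwise_dnds_vs_reference(calns, cfg.reference_taxon)
    files.append(
        _write(
            pd.DataFrame(
                [
                    {"taxon": t, "dn": r.dn, "ds": r.ds, "omega": r.omega}
                    for t, r in sorted(taxon_rates.items())
                ]
            ),
            out / "rates" / "per_taxon_rates.tsv",
        )
    )
    if cfg.functional_groups:
        groups = pd.read_csv(cfg.functional_groups, sep="\t").set_index("gene")["group"].to_dict()
        omegas = {g: r.omega for g, r in rates.items()}
        try:
            summary, tests = molevol.group_rate_compare(omegas, groups)
        except ValueError as exc:
            log.warning("group rate comparison skipped: %s", exc)
        else:
            files.append(_write(summary, out / "rates" / "group_summary.tsv"))
            files.append(_write(tests, out / "rates" / "group_tests.tsv"))
    return files


def stage_trees(cfg: PipelineConfig, out: Path) -> list[Path]:
    alns = _load_alignments(cfg.alignments)
    inferred, collapsed = [], []
    for g in sorted(alns):
        tree = genetrees.bootstrap_supports(
            alns[g], n_reps=cfg.bootstrap_reps, seed=cfg.seed, model=cfg.distance_model
        )
        tree.gene_name = g
        inferred.append(tree)
        ctree = genetrees.collapse_low_support(tree, cfg.collapse_threshold, "bootstrap")
        ctree.gene_name = g
        collapsed.append(ctree)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    f1 = out / "trees" / "gene_trees.nwk"
    f1.write_text("".join(genetrees.write_newick(t) + "\n" for t in inferred))
    f2 = out / "trees" / "gene_trees_collapsed.nwk"
    f2.write_text("".join(genetrees.write_newick(t) + "\n" for t in collapsed))
    mode = "exhaustive" if len(alns[sorted(alns)[0]].taxa) <= 9 else "greedy-NNI"
    sp = genetrees.estimate_species_tree(collapsed, mode=mode)
    f3 = out / "trees" / "species_tree.nwk"
    f3.write_text(genetrees.write_newick(sp) + "\n")
    return [f1, f2, f3]


def stage_concord(cfg: PipelineConfig, out: Path) -> list[Path]:
    species = genetrees.read_newick(
        (out / "trees" / "species_tree.nwk").read_text(), support_scale="probability"
    )
    gene_trees = genetrees.read_newick_list(
        (out / "trees" / "gene_trees_collapsed.nwk").read_text(), support_scale="bootstrap"
    )
    summary = concord_mod.summarize(species, gene_trees)
    rows = [
        {
            "bipartition": "|".join(sorted(e.bipartition)),
            "concordant": e.n_concordant,
            "top_alternative": e.n_top_alternative,
            "top_alternative_bipartition": "|".join(sorted(e.top_alternative_bipartition))
            if e.top_alternative_bipartition
            else "",
            "other_conflict": e.n_other_conflict,
            "uninformative": e.n_uninformative,
        }
        for e in summary.edges
    ]
    return [_write(pd.DataFrame(rows), out / "concord" / "per_edge.tsv")]


def stage_space(cfg: PipelineConfig, out: Path) -> list[Path]:
    gene_trees = genetrees.read_newick_list(
        (out / "trees" / "gene_trees.nwk").read_text(), support_scale="bootstrap"
    )
    alns = _load_alignments(cfg.alignments)
    names = sorted(alns)
    for t, g in zip(gene_trees, names):
        t.gene_name = g
    species = genetrees.read_newick(
        (out / "trees" / "species_tree.nwk").read_text(), support_scale="probability"
    )
    species.gene_name = "species"
    dm = treespace.tree_distance_matrix(gene_trees + [species])
    emb = treespace.pcoa(dm)
    files = []
    ncoord = emb.coordinates.shape[1]
    files.append(
        _write(
            pd.DataFrame(
                {"label": emb.labels}
                | {f"axis{i + 1}": emb.coordinates[:, i] for i in range(min(ncoord, 4))}
            ),
            out / "space" / "embedding.tsv",
        )
    )
    clusters = treespace.find_clusters(
        dm, k_range=range(2, cfg.k_max + 1), exclude_labels=["species"]
    )
    gd = treespace.gene_discordance(emb, "species")
    per_gene = pd.read_csv(out / "genestats" / "per_gene.tsv", sep="\t").set_index("gene")
    rates = pd.read_csv(out / "rates" / "per_gene_rates.tsv", sep="\t").set_index("gene")
    table = pd.DataFrame(
        {
            "gene": names,
            "gc": [per_gene.loc[g, "gc"] for g in names],
            "aligned_length": [per_gene.loc[g, "aligned_length"] for g in names],
            "pv": [per_gene.loc[g, "pv"] for g in names],
            "pi": [per_gene.loc[g, "pi"] for g in names],
            "omega": [rates.loc[g, "omega"] for g in names],
            "dn": [rates.loc[g, "dn"] for g in names],
            "ds": [rates.loc[g, "ds"] for g in names],
            "cluster": [clusters.assignment[g] for g in names],
            "gd": [gd[g] for g in names],
            "silhouette": [clusters.silhouette.get(g, float("nan")) for g in names],
        }
    )
    files.append(_write(table, out / "space" / "gene_properties.tsv"))
    summary, tests = treespace.cluster_property_report(table)
    files.append(_write(summary, out / "space" / "cluster_summary.tsv"))
    files.append(_write(tests, out / "space" / "cluster_tests.tsv"))
    retree = treespace.cluster_concatenate_and_retree(
        alns, clusters, {"species": species}, cfg.distance_model
    )
    files.append(
        _write(
            pd.DataFrame(
                [
                    {
                        "cluster": c,
                        "n_genes": len(info["genes"]),
                        "rf_to_species": info["rf_to_reference"]["species"],
                    }
                    for c, info in retree.items()
                ]
            ),
            out / "space" / "cluster_trees.tsv",
        )
    )
    return files


_STAGE_FUNCS = {
    "characterize": stage_characterize,
    "genestats": stage_genestats,
    "rates": stage_rates,
    "trees": stage_trees,
    "concord": stage_concord,
    "space": stage_space,
}


def run_all(config: PipelineConfig, force: bool = False) -> dict[str, list[str]]:
    """Run every applicable stage; returns stage -> output files.

    Stages already completed under the same config are skipped unless
    ``force``.  A stage failure aborts the run naming the stage.
    """
    config.validate()
    runner = _Stages(config, force)
    report: dict[str, list[str]] = {}
    for stage, func in _STAGE_FUNCS.items():
        if stage == "characterize" and not config.genbank:
            continue
        if stage in ("rates", "space") and not config.codon_alignments:
            # the tree-space property tables need the per-gene rates
            continue
        if runner.done(stage):
            log.info("stage %s: up to date, skipped", stage)
            report[stage] = sorted(runner.manifest[stage]["outputs"])
            continue
        log.info("stage %s: running", stage)
        try:
            files = func(config, runner.out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        runner.record(stage, files)
        report[stage] = sorted(str(f.relative_to(runner.out)) for f in files)
    return report
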