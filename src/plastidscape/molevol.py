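"""Counting-method dN/dS estimation and group-level rate comparison.

Implements the Nei-Gojobori (1986) pathway-counting estimator with the
Jukes-Cantor multiple-hit correction: per-codon synonymous/nonsynonymous
site fractions from the universal genetic code, all minimal mutational
pathways between differing codons averaged (pathways through stop codons
excluded), and ``d = -3/4 ln(1 - 4p/3)`` applied to the proportions.

This is a deterministic, dependency-free stand-in for ML codon-model
fitting (codeml-style): adequate for rank-level comparisons between genes,
taxa and functional groups, which is how it is used here.  Externally
computed rate tables can be supplied wherever these results are consumed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .alignment import GeneAlignment

__all__ = [
    "NG86Result",
    "SubstitutionRates",
    "ng86_pair",
    "pairwise_dnds_vs_reference",
    "per_gene_dnds",
    "group_rate_compare",
    "significance_stars",
    "DN_FLOOR",
]

# genes with mean dN below this are flagged: their omega is numerically unstable
DN_FLOOR = 0.0003

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _CODON_TABLE[_b1 + _b2 + _b3] = ""
# universal code laid out in TCAG order
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate(_CODON_TABLE):
    _CODON_TABLE[_codon] = _AA[_i]

STOP_CODONS = frozenset(c for c, a in _CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(c for c in _CODON_TABLE if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    At each position the fraction of the three possible single-nucleotide
    changes that preserve the amino acid is the synonymous fraction;
    changes creating a stop codon count as nonsynonymous, so the two
    counts always sum to 3.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa and alt not in STOP_CODONS:
                syn += 1 / 3
    return syn, 3.0 - syn


_SITES_CACHE = {c: _codon_sites(c) for c in SENSE_CODONS}


def _pair_diffs(a: str, b: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal mutational pathways that avoid stops.

    None when every pathway passes through a stop codon (the codon pair
    is then skipped as uncountable).
    """
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(pos):
        cur = a
        syn = nsyn = 0
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, nsyn_tot / n_paths


_DIFFS_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


@dataclass
class NG86Result:
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    dn: float
    ds: float
    omega: float  # NaN when dS == 0 or saturated
    n_codons_compared: int
    saturated: bool = False


@dataclass
class SubstitutionRates:
    """Per-subject (gene or taxon) substitution rates."""

    subject: str
    dn: float
    ds: float
    omega: float
    low_dn_flag: bool = False


def _jc_correct(p: float) -> float:
    arg = 1 - 4 * p / 3
    return -0.75 * math.log(arg) if arg > 0 else float("inf")


def ng86_pair(codon_seq_a: str, codon_seq_b: str) -> NG86Result:
    """Nei-Gojobori dN/dS between two in-frame nucleotide sequences.

    Codons containing a gap, N, or a stop in either sequence are skipped
    pairwise.  ``omega`` is NaN when dS is zero or either proportion is
    saturated (p >= 3/4, where the Jukes-Cantor correction diverges).
    """
    a, b = codon_seq_a.upper(), codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("length not divisible by 3")
    n_sites = s_sites = n_diffs = s_diffs = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca not in _SITES_CACHE or cb not in _SITES_CACHE:
            continue  # gap/N/stop codon: pairwise skip
        key = (ca, cb)
        if key not in _DIFFS_CACHE:
            _DIFFS_CACHE[key] = _pair_diffs(ca, cb)
        diffs = _DIFFS_CACHE[key]
        if diffs is None:
            continue
        sa, na = _SITES_CACHE[ca]
        sb, nb = _SITES_CACHE[cb]
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        s_diffs += diffs[0]
        n_diffs += diffs[1]
        n_codons += 1
    if n_codons == 0:
        return NG86Result(0, 0, 0, 0, float("nan"), float("nan"), float("nan"), 0)
    pn = n_diffs / n_sites if n_sites else 0.0
    ps = s_diffs / s_sites if s_sites else 0.0
    dn, ds = _jc_correct(pn), _jc_correct(ps)
    saturated = not (math.isfinite(dn) and math.isfinite(ds))
    omega = dn / ds if (not saturated and ds > 0) else float("nan")
    return NG86Result(n_sites, s_sites, n_diffs, s_diffs, dn, ds, omega, n_codons, saturated)


def _common_genes(per_gene_alignments: dict[str, GeneAlignment]) -> tuple[list[str], list[str]]:
    names = sorted(per_gene_alignments)
    taxa = set(per_gene_alignments[names[0]].taxa)
    for g in names[1:]:
        taxa &= set(per_gene_alignments[g].taxa)
    common = [g for g in names if set(per_gene_alignments[g].taxa) >= taxa]
    return common, sorted(taxa)


def pairwise_dnds_vs_reference(
    per_gene_alignments: dict[str, GeneAlignment], reference_taxon: str
) -> dict[str, SubstitutionRates]:
    """One (dN, dS, omega) per non-reference taxon on the concatenation of
    genes shared by all taxa, in fixed (sorted) gene-name order."""
    for g, aln in sorted(per_gene_alignments.items()):
        if reference_taxon not in aln.taxa:
            raise ValueError(f"reference taxon {reference_taxon!r} missing from gene {g}")
    genes, taxa = _common_genes(per_gene_alignments)
    out = {}
    for taxon in taxa:
        if taxon == reference_taxon:
            continue
        ref_cat = "".join(per_gene_alignments[g].row(reference_taxon) for g in genes)
        tax_cat = "".join(per_gene_alignments[g].row(taxon) for g in genes)
        r = ng86_pair(ref_cat, tax_cat)
        out[taxon] = SubstitutionRates(taxon, r.dn, r.ds, r.omega)
    return out


def per_gene_dnds(
    per_gene_alignments: dict[str, GeneAlignment],
    reference_taxon: str,
    dn_floor: float = DN_FLOOR,
) -> dict[str, SubstitutionRates]:
    """Per-gene rates as means over (taxon vs reference) pairs.

    omega is the ratio of mean dN to mean dS.  Genes whose mean dN falls
    below ``dn_floor`` are flagged: their omega is too noisy to plot.
    """
    out = {}
    for g in sorted(per_gene_alignments):
        aln = per_gene_alignments[g]
        if reference_taxon not in aln.taxa:
            raise ValueError(f"reference taxon {reference_taxon!r} missing from gene {g}")
        ref = aln.row(reference_taxon)
        dns, dss = [], []
        for taxon in aln.taxa:
            if taxon == reference_taxon:
                continue
            r = ng86_pair(ref, aln.row(taxon))
            if math.isfinite(r.dn) and math.isfinite(r.ds):
                dns.append(r.dn)
                dss.append(r.ds)
        dn = float(np.mean(dns)) if dns else float("nan")
        ds = float(np.mean(dss)) if dss else float("nan")
        omega = dn / ds if ds and ds > 0 else float("nan")
        out[g] = SubstitutionRates(g, dn, ds, omega, low_dn_flag=bool(dn < dn_floor))
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_t(x, y) -> tuple[float, float]:
    """Welch unequal-variance two-sided t-test; degenerate zero-variance
    pairs resolve to (0, 1) for equal means and (inf, 0) otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (float("inf"), 0.0)
    t, p = _stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def group_rate_compare(
    values: dict[str, float], grouping: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means plus pairwise Welch t-tests on a per-subject statistic.

    Returns (summary, tests): summary has one row per group (n, mean,
    median); tests has one row per group pair (t, p, stars).  Groups with
    fewer than 2 finite values are excluded with a warning.
    """
    groups: dict[str, list[float]] = {}
    for subject, v in values.items():
        g = grouping.get(subject)
        if g is not None and np.isfinite(v):
            groups.setdefault(g, []).append(float(v))
    dropped = [g for g, vs in groups.items() if len(vs) < 2]
    for g in dropped:
        warnings.warn(f"group {g!r} has n < 2; excluded from comparison")
        del groups[g]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    summary = pd.DataFrame(
        [
            {"group": g, "n": len(vs), "mean": np.mean(vs), "median": np.median(vs)}
            for g, vs in sorted(groups.items())
        ]
    )
    rows = []
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        t, p = welch_t(groups[g1], groups[g2])
        rows.append(
            {"group1": g1, "group2": g2, "t": t, "p": p, "stars": significance_stars(p)}
        )
    return summary, pd.DataFrame(rows)
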