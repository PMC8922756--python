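"""Annotated plastome records: GenBank I/O, coding-sequence extraction,
quadripartite-structure detection and gene presence/absence.

Coordinates are 0-based half-open internally; the GenBank flat file's
1-based inclusive convention exists only at the I/O boundary (Biopython
handles the conversion).  A plastome is circular; a feature spanning the
origin is stored as two intervals whose total length is preserved.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .molevol import STOP_CODONS, translate_codon

__all__ = [
    "Feature",
    "PlastomeRecord",
    "QuadripartiteStructure",
    "PresenceAbsenceMatrix",
    "read_plastome",
    "write_plastome",
    "extract_pcgs",
    "detect_quadripartite",
    "junction_report",
    "presence_absence",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Feature:
    gene_name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # + | -
    intervals: list[tuple[int, int]]
    in_ir: bool = False

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def non_triplet(self) -> bool:
        return self.kind == "CDS" and self.length % 3 != 0


@dataclass
class PlastomeRecord:
    """Annotated circular plastid genome."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"ambiguity codes other than N not supported: {sorted(bad)}")
        for f in self.features:
            if not f.gene_name:
                raise ValueError("feature with empty gene name")
            for s, e in f.intervals:
                if not (0 <= s < e <= len(self.sequence)):
                    raise ValueError(
                        f"feature {f.gene_name}: interval ({s},{e}) outside sequence "
                        f"of length {len(self.sequence)}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feature: Feature) -> str:
        raw = "".join(self.sequence[s:e] for s, e in feature.intervals)
        return revcomp(raw) if feature.strand == "-" else raw


@dataclass
class QuadripartiteStructure:
    """LSC / IRb / SSC / IRa intervals; a segment with start > end wraps
    through the origin."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_length: int

    def junctions(self) -> dict[str, int]:
        return {
            "JLB": self.irb[0],
            "JSB": self.irb[1],
            "JSA": self.ira[0],
            "JLA": self.ira[1],
        }


@dataclass
class PresenceAbsenceMatrix:
    genes: list[str]
    taxa: list[str]
    matrix: list[list[bool]]  # gene x taxon
    loss_events: list[tuple[str, str]]


# --------------------------------------------------------------------------
# GenBank I/O
# --------------------------------------------------------------------------
_KINDS = {"CDS", "tRNA", "rRNA"}


def read_plastome(genbank_text: str) -> PlastomeRecord:
    """Parse a GenBank flat file into a PlastomeRecord.

    CDS/tRNA/rRNA features are captured with join intervals preserved in
    annotation order; other feature types are ignored.
    """
    rec = SeqIO.read(io.StringIO(genbank_text), "genbank")
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"record {rec.id}: missing sequence")
    features = []
    for f in rec.features:
        if f.type not in _KINDS:
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or [""])[0]
        if not name:
            raise ValueError(f"record {rec.id}: {f.type} feature without a gene name")
        intervals = [(int(p.start), int(p.end)) for p in f.location.parts]
        for s, e in intervals:
            if e > len(seq):
                raise ValueError(f"feature {name}: interval beyond sequence end")
        strand = "-" if f.location.strand == -1 else "+"
        in_ir = "in_ir" in f.qualifiers.get("note", [])
        features.append(Feature(name, f.type, strand, intervals, in_ir=in_ir))
    circular = rec.annotations.get("topology", "circular") == "circular"
    return PlastomeRecord(rec.id, seq, features, circular=circular)


def write_plastome(record: PlastomeRecord) -> str:
    """Render a PlastomeRecord as GenBank flat-file text."""
    strand_code = {"+": 1, "-": -1}
    feats = []
    for f in record.features:
        locs = [SimpleLocation(s, e, strand=strand_code[f.strand]) for s, e in f.intervals]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.gene_name]}
        if f.in_ir:
            quals["note"] = ["in_ir"]
        feats.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="synthetic plastome",
        features=feats,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()


# --------------------------------------------------------------------------
# coding-sequence extraction
# --------------------------------------------------------------------------
def extract_pcgs(record: PlastomeRecord) -> dict[str, str]:
    """gene name -> spliced coding nucleotide sequence (5'->3').

    Minus-strand features are reverse-complemented; exons joined in
    annotation order.  IR-duplicated genes with identical copies are
    emitted once; diverged copies are kept with numeric suffixes and a
    warning.  Internal stop codons trigger a warning but the sequence is
    still returned.
    """
    by_name: dict[str, list[str]] = {}
    for f in record.features:
        if f.kind != "CDS":
            continue
        by_name.setdefault(f.gene_name, []).append(record.feature_seq(f))
    out: dict[str, str] = {}
    for name, seqs in by_name.items():
        uniq = sorted(set(seqs))
        if len(uniq) == 1:
            out[name] = uniq[0]
        else:
            warnings.warn(f"{record.id}: copies of {name} differ; keeping all with suffixes")
            for k, s in enumerate(seqs, 1):
                out[f"{name}_{k}"] = s
    for name, s in out.items():
        if len(s) % 3 == 0:
            internal = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]
            if any(c in STOP_CODONS for c in internal):
                warnings.warn(f"{record.id}: internal stop codon in {name}")
    return out


# --------------------------------------------------------------------------
# quadripartite structure
# --------------------------------------------------------------------------
def detect_quadripartite(
    record: PlastomeRecord, min_ir_len: int = 1000, k: int = 31
) -> QuadripartiteStructure | None:
    """Locate the inverted repeat as the longest pair of exact
    reverse-complement repeats of length >= ``min_ir_len``.

    Seed-and-extend on ``k``-mers; the shorter enclosed single-copy
    segment is labelled SSC, the longer LSC.  Returns None when no such
    repeat exists (a valid "no IR" outcome for IR-less plastomes).
    """
    seq = record.sequence
    L = len(seq)
    if L < 10_000:
        raise ValueError("record too short for IR detection (< 10 kb)")
    index: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    rcseq = revcomp(seq)
    seen: set[int] = set()
    best: tuple[int, int, int] | None = None  # (length, start1, start2)
    for j in range(L - k + 1):
        kmer = rcseq[L - j - k : L - j]  # revcomp of seq[j:j+k]
        for i in index.get(kmer, ()):
            if i + k > j:  # keep copies ordered and non-overlapping
                continue
            if (i + j) in seen:
                continue
            a, b, m = i, j, k
            # left of copy1 pairs with right of copy2
            while a > 0 and b + m < L and seq[a - 1] == rcseq[L - (b + m) - 1]:
                a -= 1
                m += 1
            # right of copy1 pairs with left of copy2
            while b > 0 and a + m <= b - 1 and seq[a + m] == rcseq[L - b]:
                b -= 1
                m += 1
            seen.add(a + b + m - k)
            if m >= min_ir_len and (best is None or m > best[0]):
                best = (m, a, b)
    if best is None:
        return None
    m, i, j = best
    irb, ira = (i, i + m), (j, j + m)
    seg_mid = (i + m, j)  # between the copies
    seg_out = ((j + m) % L, i if i > 0 else L)  # wraps through origin when needed
    len_mid = j - (i + m)
    len_out = (L - (j + m)) + i
    if len_mid <= len_out:
        ssc, lsc = seg_mid, seg_out
    else:
        ssc, lsc = seg_out, seg_mid
        irb, ira = ira, irb  # IRb is the copy preceding the SSC
    return QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira, ir_length=m)


def junction_report(
    structures: list[QuadripartiteStructure | None], records: list[PlastomeRecord]
):
    """Per-taxon table of the four IR/SC junctions.

    Columns: taxon, junction (JLB/JSB/JSA/JLA), nearest gene, signed
    offset in bp (negative when the gene's nearest portion lies inside
    the IR), and the within-gene overlap when a junction cuts a gene.
    Records without a detected IR are skipped with a warning.
    """
    import pandas as pd

    rows = []
    for struct, rec in zip(structures, records):
        if struct is None:
            warnings.warn(f"{rec.id}: no IR detected; skipped in junction report")
            continue
        ir_spans = [struct.irb, struct.ira]
        for jname, pos in struct.junctions().items():
            best = None  # (abs distance, feature, edge, inside)
            for f in rec.features:
                for s, e in f.intervals:
                    if s < pos < e:
                        cand = (0, f, pos, True)
                    else:
                        d = min(abs(pos - s), abs(pos - e))
                        cand = (d, f, s if abs(pos - s) <= abs(pos - e) else e, False)
                    if best is None or cand[0] < best[0]:
                        best = cand
            if best is None:
                continue
            d, f, edge, inside = best
            overlap = 0
            if inside:
                # bp of the cut gene lying inside the IR across this junction
                for s, e in f.intervals:
                    for irs, ire in ir_spans:
                        overlap += max(0, min(e, ire) - max(s, irs))
            in_ir_side = inside or any(s <= edge <= e for s, e in ir_spans)
            offset = -d if in_ir_side else d
            rows.append(
                {
                    "taxon": rec.id,
                    "junction": jname,
                    "position": pos,
                    "gene": f.gene_name,
                    "offset_bp": offset,
                    "inside_gene": inside,
                    "overlap_bp": overlap,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# presence/absence
# --------------------------------------------------------------------------
def presence_absence(records: list[PlastomeRecord]) -> PresenceAbsenceMatrix:
    """Gene x taxon presence matrix over the union of annotated gene names.

    IR-duplicated copies count once.  A loss event is a (gene, taxon)
    cell that is False for a gene present in at least one taxon.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    taxa = [r.id for r in records]
    per_taxon = [{f.gene_name for f in r.features} for r in records]
    genes = sorted(set().union(*per_taxon))
    matrix = [[g in pt for pt in per_taxon] for g in genes]
    losses = [
        (g, taxa[j])
        for gi, g in enumerate(genes)
        for j in range(len(taxa))
        if not matrix[gi][j]
    ]
    return PresenceAbsenceMatrix(genes, taxa, matrix, losses)


def record_checks(records: list[PlastomeRecord]) -> dict:
    """Summary used to verify published record statistics: per-record
    sequence length and distinct PCG count, plus the count of PCGs common
    to all records."""
    per = {
        r.id: {
            "length": r.length,
            "n_pcgs": len({f.gene_name for f in r.features if f.kind == "CDS"}),
        }
        for r in records
    }
    common = set.intersection(
        *({f.gene_name for f in r.features if f.kind == "CDS"} for r in records)
    )
    return {"records": per, "n_common_pcgs": len(common)}
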