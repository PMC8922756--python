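"""Sequence variability statistics and microsatellite scanning.

Per-gene nucleotide diversity (pi), segregating sites (S) and proportion
of variability (PV = S / aligned length), sliding-window pi profiles with
hotspot screening, GC content, and a perfect-tandem-repeat (SSR) scanner
with per-motif-class minimum unit counts.

Conventions follow the common population-genetics tools: pi uses pairwise
deletion of gap/N sites (as DnaSP does), the sliding window defaults to
600 bp with a 100 bp step, hotspots are screened at pi > 0.006, and SSR
unit-count minima are 10/5/4/3/3/3 for mono- through hexanucleotides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alignment import GeneAlignment

__all__ = [
    "SlidingWindowProfile",
    "SSRRecord",
    "nucleotide_diversity",
    "segregating_stats",
    "sliding_window_pi",
    "screen_hotspots",
    "gc_content",
    "find_ssrs",
    "DEFAULT_SSR_MIN_UNITS",
]

DEFAULT_SSR_MIN_UNITS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SlidingWindowProfile:
    """Windowed pi series; midpoint of window i is ``starts[i] + window/2``."""

    window_length: int
    step: int
    starts: list[int]
    midpoints: list[float]
    pi_values: list[float]
    whole_alignment_fallback: bool = False


@dataclass
class SSRRecord:
    """One perfect microsatellite run.

    ``motif`` is the lexicographically smallest rotation of the repeat
    unit; ``start``/``end`` are 0-based half-open over whole units.
    """

    sequence_id: str
    motif: str
    unit_count: int
    start: int
    end: int

    @property
    def motif_length(self) -> int:
        return len(self.motif)


def _encode_rows(aln: GeneAlignment) -> np.ndarray:
    arr = np.full((aln.n_taxa, aln.aligned_length), 255, dtype=np.uint8)
    for i, row in enumerate(aln.rows):
        raw = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        for ch, code in _CODE.items():
            arr[i][raw == ord(ch)] = code
    return arr


def nucleotide_diversity(aln: GeneAlignment) -> float:
    """Mean pairwise per-site difference with pairwise deletion.

    For each unordered row pair, columns where either row carries a gap
    or N are excluded; pi is the average of (differences / compared
    sites) over all pairs.  NaN if no pair has a comparable site.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 rows")
    enc = _encode_rows(aln)
    vals = []
    for i, j in itertools.combinations(range(aln.n_taxa), 2):
        ok = (enc[i] < 4) & (enc[j] < 4)
        m = int(ok.sum())
        if m:
            vals.append(float((ok & (enc[i] != enc[j])).sum()) / m)
    return float(np.mean(vals)) if vals else float("nan")


def segregating_stats(aln: GeneAlignment) -> tuple[int, float]:
    """(S, PV): segregating columns and S / aligned length.

    A column segregates when it holds >= 2 distinct non-gap, non-N states.
    The PV denominator is the full aligned length, gap columns included.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 rows")
    enc = _encode_rows(aln)
    s = 0
    for col in range(aln.aligned_length):
        states = set(enc[:, col][enc[:, col] < 4].tolist())
        if len(states) >= 2:
            s += 1
    return s, s / aln.aligned_length if aln.aligned_length else 0.0


def sliding_window_pi(
    aln: GeneAlignment, window: int = 600, step: int = 100
) -> SlidingWindowProfile:
    """Pi computed in overlapping column windows.

    When the alignment is shorter than one window, a single whole-
    alignment window is returned and flagged.
    """
    L = aln.aligned_length
    if L < window:
        return SlidingWindowProfile(
            L, L, [0], [L / 2], [nucleotide_diversity(aln)], whole_alignment_fallback=True
        )
    starts = list(range(0, L - window + 1, step))
    pis = [nucleotide_diversity(aln.slice_columns(s, s + window)) for s in starts]
    mids = [s + window / 2 for s in starts]
    return SlidingWindowProfile(window, step, starts, mids, pis)


def screen_hotspots(
    profile: SlidingWindowProfile, threshold: float = 0.006
) -> list[tuple[int, int, float]]:
    """Maximal runs of adjacent windows with pi strictly above threshold.

    Returns (region_start, region_end, max_pi) per run, where the region
    spans from the first qualifying window's start to the last one's end.
    """
    if not profile.starts:
        return []
    regions = []
    run: list[int] = []
    for i, pi in enumerate(profile.pi_values):
        if not np.isnan(pi) and pi > threshold:
            run.append(i)
        elif run:
            regions.append(run)
            run = []
    if run:
        regions.append(run)
    out = []
    for idx in regions:
        start = profile.starts[idx[0]]
        end = profile.starts[idx[-1]] + profile.window_length
        out.append((start, end, max(profile.pi_values[i] for i in idx)))
    return out


def gc_content(seq_or_aln) -> float:
    """(G+C)/(A+C+G+T); gaps and N excluded.  NaN for empty denominator."""
    if isinstance(seq_or_aln, GeneAlignment):
        seq = "".join(seq_or_aln.rows)
    else:
        seq = str(seq_or_aln).upper()
    gc = sum(seq.count(c) for c in "GC")
    total = gc + sum(seq.count(c) for c in "AT")
    return gc / total if total else float("nan")


def _smallest_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_aperiodic(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    sequence_id: str = "seq",
    min_units: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """Scan for perfect microsatellites of unit length 1-6.

    Maximal tandem runs are reported under their shortest period; motifs
    are canonicalized to the lexicographically smallest rotation; motifs
    containing N are skipped; overlapping candidates are resolved greedily
    longest-run-first.  Output is sorted by start and non-overlapping.
    """
    min_units = dict(DEFAULT_SSR_MIN_UNITS if min_units is None else min_units)
    seq = sequence.upper()
    L = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    candidates = []
    for m, min_u in sorted(min_units.items()):
        if L < m * min_u:
            continue
        eq = arr[: L - m] == arr[m:]
        # runs of True of length r encode a tandem stretch of r + m bases
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for i, j in zip(edges[::2], edges[1::2]):
            total = (j - i) + m
            units = total // m
            if units < min_u:
                continue
            motif = seq[i : i + m]
            if "N" not in motif and _is_aperiodic(motif):
                candidates.append((units * m, int(i), m, units, motif))
    # greedy longest-first overlap resolution
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    taken: list[tuple[int, int]] = []
    records = []
    for span, start, m, units, motif in candidates:
        end = start + units * m
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        records.append(SSRRecord(sequence_id, _smallest_rotation(motif), units, start, end))
    records.sort(key=lambda r: r.start)
    return records
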