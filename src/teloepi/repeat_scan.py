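"""Rotation-aware detection and strand classification of telomeric small RNAs.

A small RNA "contains telomeric sequence" when one of its substrings is a
perfect substring of the infinite periodic repeat on the G-rich strand
(…TTTAGGGTTTAGGG…) or the C-rich strand (…CCCTAAACCCTAAA…), at any
rotation (phase) of the 7-mer unit.  The scanner reports the maximal such
homology per read, classifies the read as a G- or C-siRNA by the strand
achieving the maximum, and tabulates hits per library and per homology
extent.  No mismatches are tolerated inside the homology run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from teloepi.motif import RepeatMotif, TELOMERE_MOTIF, normalize_sequence

log = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class SmallRNA:
    """One small-RNA read with its library of origin (e.g. AGO4, total)."""

    read_id: str
    sequence: str
    library: str = "total"


@dataclass(frozen=True)
class TelomericSiRNAHit:
    """A read classified as telomeric, with its maximal homology run.

    strand_class is 'G', 'C', or 'ambiguous' (equal maximal homology on
    both strands); match_offset is the 0-based start of the maximal
    matching substring within the read.
    """

    read_id: str
    strand_class: str
    homology_length: int
    match_offset: int
    library: str
    sequence: str = ""


def enumerate_telomeric_kmers(k: int, strand: str, motif: RepeatMotif = TELOMERE_MOTIF) -> set[str]:
    """All distinct length-k substrings of the infinite repeat on a strand.

    For k >= period this is exactly the ``period`` rotations extended to
    length k; for smaller k the set can be smaller because distinct
    phases share short prefixes.
    """
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    unit = motif.unit(strand)
    tandem = unit * (k // motif.period + 2)
    return {tandem[i : i + k] for i in range(motif.period)}


def _max_run(sequence: str, unit: str) -> tuple[int, int]:
    """Longest substring of ``sequence`` that is periodic-consistent with
    ``unit`` at some phase.  Returns (length, offset); (0, 0) if none.
    O(period * len) with early exit on a full-length run.
    """
    n = len(sequence)
    p = len(unit)
    best_len, best_off = 0, 0
    for phase in range(p):
        run = 0
        for i in range(n):
            if sequence[i] == unit[(phase + i) % p]:
                run += 1
                if run > best_len:
                    best_len, best_off = run, i - run + 1
            else:
                run = 0
        if best_len == n:
            break
    return best_len, best_off


def max_telomeric_homology(
    sequence: str, motif: RepeatMotif = TELOMERE_MOTIF
) -> tuple[str, int, int]:
    """Maximal telomeric homology of a read on either strand.

    Returns ``(strand_class, homology_length, match_offset)`` where
    strand_class is 'G', 'C', or 'ambiguous' when both strands reach the
    same maximal length.  N never matches.  The sequence must already be
    normalized (uppercase, U->T).
    """
    if not sequence:
        raise ValueError("empty sequence")
    g_len, g_off = _max_run(sequence, motif.unit_g)
    c_len, c_off = _max_run(sequence, motif.unit_c)
    if g_len > c_len:
        return "G", g_len, g_off
    if c_len > g_len:
        return "C", c_len, c_off
    return "ambiguous", g_len, min(g_off, c_off)


def classify_sirnas(
    reads: Iterable[SmallRNA],
    min_homology: int = 12,
    motif: RepeatMotif = TELOMERE_MOTIF,
    collapse_identical: bool = False,
) -> list[TelomericSiRNAHit]:
    """Scan reads and keep those with telomeric homology >= min_homology.

    Each distinct read record counts once; with ``collapse_identical``
    identical sequences within a library are collapsed to a single hit.
    Reads with characters outside A/C/G/T/N are skipped with a warning.
    """
    if min_homology < 1:
        raise ValueError(f"min_homology must be >= 1, got {min_homology}")
    hits: list[TelomericSiRNAHit] = []
    seen: set[tuple[str, str]] = set()
    for read in reads:
        seq = normalize_sequence(read.sequence)
        if not seq or set(seq) - VALID_CHARS:
            warnings.warn(
                f"read {read.read_id}: invalid characters, skipped", stacklevel=2
            )
            continue
        if collapse_identical:
            key = (read.library, seq)
            if key in seen:
                continue
            seen.add(key)
        strand, length, offset = max_telomeric_homology(seq, motif)
        if length >= min_homology:
            hits.append(
                TelomericSiRNAHit(read.read_id, strand, length, offset, read.library, seq)
            )
    return hits


def hits_to_frame(hits: Sequence[TelomericSiRNAHit]) -> pd.DataFrame:
    """Hits as a tidy DataFrame (one row per hit)."""
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "library": h.library,
                "strand_class": h.strand_class,
                "homology_length": h.homology_length,
                "match_offset": h.match_offset,
                "sequence": h.sequence,
            }
            for h in hits
        ],
        columns=[
            "read_id",
            "library",
            "strand_class",
            "homology_length",
            "match_offset",
            "sequence",
        ],
    )


def homology_distribution(hits: Sequence[TelomericSiRNAHit]) -> pd.DataFrame:
    """Counts of hits per (strand_class, homology_length)."""
    df = hits_to_frame(hits)
    if df.empty:
        return pd.DataFrame(columns=["strand_class", "homology_length", "count"])
    out = (
        df.groupby(["strand_class", "homology_length"], observed=True)
        .size()
        .reset_index(name="count")
        .sort_values(["strand_class", "homology_length"], ignore_index=True)
    )
    return out


def library_crosstab(hits: Sequence[TelomericSiRNAHit]) -> pd.DataFrame:
    """Counts of hits per library x strand_class (libraries as rows)."""
    df = hits_to_frame(hits)
    if df.empty:
        return pd.DataFrame()
    tab = pd.crosstab(df["library"], df["strand_class"])
    tab.index.name = "library"
    return tab


def find_telomeric_tracts(
    sequence: str, min_units: int = 1, motif: RepeatMotif = TELOMERE_MOTIF
) -> list[tuple[int, int, str]]:
    """Maximal non-overlapping perfect telomeric tracts in a sequence.

    A tract is a substring that is periodic-consistent with the G- or
    C-strand unit at some phase and at least ``min_units * period`` long.
    Returns 0-based half-open ``(start, end, strand)`` intervals sorted
    by start; overlapping candidates (possible only below one full
    period of overlap) are resolved longest-first.
    """
    if min_units < 1:
        raise ValueError(f"min_units must be >= 1, got {min_units}")
    seq = normalize_sequence(sequence)
    min_len = min_units * motif.period
    candidates: list[tuple[int, int, str]] = []
    for strand in ("G", "C"):
        unit = motif.unit(strand)
        p = len(unit)
        runs: list[tuple[int, int]] = []
        for phase in range(p):
            start = None
            for i in range(len(seq) + 1):
                ok = i < len(seq) and seq[i] == unit[(phase + i) % p]
                if ok and start is None:
                    start = i
                elif not ok and start is not None:
                    runs.append((start, i))
                    start = None
        # drop runs contained in a longer run of another phase
        runs.sort(key=lambda r: (r[0], -(r[1] - r[0])))
        kept: list[tuple[int, int]] = []
        for s, e in runs:
            if any(s >= ks and e <= ke for ks, ke in kept):
                continue
            kept.append((s, e))
        candidates.extend((s, e, strand) for s, e in kept if e - s >= min_len)
    # greedy longest-first non-overlap resolution
    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    chosen: list[tuple[int, int, str]] = []
    for s, e, strand in candidates:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, strand))
    chosen.sort()
    return chosen
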