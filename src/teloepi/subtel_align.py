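"""Full-length perfect-match alignment of small RNAs to subtelomeric references.

Subtelomeres are the unique sequences immediately internal to the
terminal telomeric tract of each chromosome arm.  Reads are placed only
where the full read equals a reference substring exactly (forward
strand) or equals its reverse complement (minus strand); reads mapping
to more than one location across the whole reference set are discarded,
so every retained placement is genome-unique within the supplied
references.  Coordinates are 0-based half-open on the forward reference.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from teloepi.motif import normalize_sequence, reverse_complement
from teloepi.repeat_scan import SmallRNA


@dataclass(frozen=True)
class SubtelomereRef:
    """One subtelomeric reference window.

    ``telomere_side`` says which end of the sequence abuts the telomere
    ('left' or 'right'); distances to the telomere are measured from
    that end.
    """

    arm_id: str
    sequence: str
    telomere_side: str = "right"
    MAX_LEN = 20_000

    def __post_init__(self) -> None:
        if self.telomere_side not in ("left", "right"):
            raise ValueError(f"telomere_side must be left/right: {self.telomere_side!r}")
        if len(self.sequence) > self.MAX_LEN:
            raise ValueError(
                f"reference {self.arm_id} exceeds {self.MAX_LEN} nt "
                f"({len(self.sequence)} nt)"
            )
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass(frozen=True)
class Placement:
    """One exact full-length placement of a read (possibly one of many)."""

    read_id: str
    arm_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class UniqueAlignment:
    """A placement retained after the genome-uniqueness filter."""

    read_id: str
    arm_id: str
    start: int
    end: int
    strand: str
    distance_to_telomere: int


class SubtelomereIndex:
    """Seed-and-verify exact-match index over both strands of a reference set.

    Seeds are the ``min_len``-mers of every forward reference; a query of
    length in [min_len, max_len] is placed by looking up its first
    min_len bases (and those of its reverse complement) and verifying
    the full-length match.
    """

    def __init__(self, refs: Sequence[SubtelomereRef], k_range: tuple[int, int] = (15, 40)):
        min_len, max_len = k_range
        if min_len < 12:
            raise ValueError(f"minimum query length must be >= 12, got {min_len}")
        if max_len < min_len:
            raise ValueError(f"invalid k_range {k_range}")
        refs = list(refs)
        if not refs:
            raise ValueError("empty reference set")
        ids = [r.arm_id for r in refs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate arm_id in reference set")
        self.refs = {r.arm_id: r for r in refs}
        self.min_len, self.max_len = min_len, max_len
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for r in refs:
            seq = r.sequence
            for i in range(len(seq) - min_len + 1):
                self._seeds[seq[i : i + min_len]].append((r.arm_id, i))

    def lookup(self, query: str) -> list[tuple[str, int, str]]:
        """All (arm_id, start, strand) where the full query matches exactly."""
        q = normalize_sequence(query)
        if not self.min_len <= len(q) <= self.max_len:
            raise ValueError(
                f"query length {len(q)} outside [{self.min_len}, {self.max_len}]"
            )
        out: list[tuple[str, int, str]] = []
        for target, strand in ((q, "+"), (reverse_complement(q), "-")):
            for arm_id, i in self._seeds.get(target[: self.min_len], ()):
                if self.refs[arm_id].sequence[i : i + len(target)] == target:
                    out.append((arm_id, i, strand))
        return sorted(set(out))


def build_index(
    refs: Sequence[SubtelomereRef], k_range: tuple[int, int] = (15, 40)
) -> SubtelomereIndex:
    """Build an exact-match index for queries with length in k_range."""
    return SubtelomereIndex(refs, k_range)


def align_perfect(reads: Iterable[SmallRNA], index: SubtelomereIndex) -> list[Placement]:
    """All full-length exact placements of each read on both strands.

    Reads containing N or outside the indexed length range get no
    placements (exact semantics); multiple placements per read are all
    reported.
    """
    placements: list[Placement] = []
    for read in reads:
        seq = normalize_sequence(read.sequence)
        if "N" in seq or not index.min_len <= len(seq) <= index.max_len:
            continue
        for arm_id, start, strand in index.lookup(seq):
            placements.append(Placement(read.read_id, arm_id, start, start + len(seq), strand))
    return placements


def _distance_to_telomere(ref: SubtelomereRef, start: int, end: int) -> int:
    if ref.telomere_side == "left":
        return start
    return len(ref.sequence) - end


def filter_unique(
    placements: Sequence[Placement], refs: Sequence[SubtelomereRef] | dict[str, SubtelomereRef]
) -> list[UniqueAlignment]:
    """Keep only reads with exactly one placement across all references.

    A read hitting two arms, two loci on one arm, or one locus on both
    strands (reverse-complement palindrome) is discarded.
    """
    if not isinstance(refs, dict):
        refs = {r.arm_id: r for r in refs}
    by_read: dict[str, list[Placement]] = defaultdict(list)
    for p in placements:
        by_read[p.read_id].append(p)
    unique: list[UniqueAlignment] = []
    for read_id, ps in by_read.items():
        if len(ps) != 1:
            continue
        p = ps[0]
        ref = refs[p.arm_id]
        unique.append(
            UniqueAlignment(
                read_id, p.arm_id, p.start, p.end, p.strand,
                _distance_to_telomere(ref, p.start, p.end),
            )
        )
    unique.sort(key=lambda a: (a.arm_id, a.start, a.read_id))
    return unique


def telomere_proximity_report(
    alignments: Sequence[UniqueAlignment], window: int = 5000
) -> pd.DataFrame:
    """Unique alignments within ``window`` nt of the telomere, per arm.

    One row per retained read with its arm, coordinates, strand, and
    distance to the telomere-abutting end of the reference.
    """
    rows = [
        {
            "arm_id": a.arm_id,
            "read_id": a.read_id,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "distance_to_telomere": a.distance_to_telomere,
        }
        for a in alignments
        if a.distance_to_telomere <= window
    ]
    return pd.DataFrame(
        rows,
        columns=["arm_id", "read_id", "start", "end", "strand", "distance_to_telomere"],
    )


def alignments_to_bed(alignments: Sequence[UniqueAlignment]) -> pd.DataFrame:
    """Unique alignments as a BED6 table (score = read length)."""
    return pd.DataFrame(
        [
            {
                "chrom": a.arm_id,
                "chromStart": a.start,
                "chromEnd": a.end,
                "name": a.read_id,
                "score": a.end - a.start,
                "strand": a.strand,
            }
            for a in alignments
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
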