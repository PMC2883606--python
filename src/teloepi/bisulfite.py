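"""Bisulfite methylation calling over a telomeric tandem-repeat region.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as
T after PCR) and leaves 5-methylcytosine untouched, so comparing a
sequenced clone against the unconverted top-strand reference calls each
reference cytosine as methylated (clone C) or converted (clone T).
Telomeric (CCCTAAA)n repeats carry cytosines exclusively in the
asymmetric CHH context; each repeat unit has three cytosines, numbered
phase 1-3, and methylation is summarized per position, per sequence
context (CG / CHG / CHH), and per repeat phase.  Conversion efficiency
is estimated from control cytosines known to be unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from teloepi.motif import RepeatMotif, TELOMERE_MOTIF, normalize_sequence, reverse_complement

CALL_METHYLATED = "M"
CALL_CONVERTED = "C"
CALL_MISSING = "."


@dataclass(frozen=True)
class BisulfiteRegion:
    """A sequenced amplicon with annotated CCCTAAA repeat units.

    Parameters
    ----------
    name : str
        Region label, e.g. ``1L-0'``.
    sequence : str
        Unconverted top-strand reference.
    unit_starts : tuple of int
        0-based start of each annotated repeat unit; the sequence at
        each start must equal the C-strand unit (CCCTAAA).
    control_positions : tuple of int
        Reference cytosines known to be unmethylated, used for the
        conversion-efficiency check.
    downstream_context : str
        Genomic bases following the region end, used to classify the
        context of cytosines within 2 nt of the edge (optional).
    """

    name: str
    sequence: str
    unit_starts: tuple[int, ...] = ()
    control_positions: tuple[int, ...] = ()
    downstream_context: str = ""
    motif: RepeatMotif = TELOMERE_MOTIF

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "unit_starts", tuple(sorted(self.unit_starts)))
        object.__setattr__(self, "control_positions", tuple(sorted(self.control_positions)))
        object.__setattr__(
            self, "downstream_context", normalize_sequence(self.downstream_context)
        )
        unit = self.motif.unit_c
        prev_end = -1
        for s in self.unit_starts:
            if s <= prev_end:
                raise ValueError(f"{self.name}: overlapping repeat units at {s}")
            if seq[s : s + len(unit)] != unit:
                raise ValueError(
                    f"{self.name}: no {unit} unit at annotated position {s}"
                )
            prev_end = s + len(unit) - 1
        for p in self.control_positions:
            if seq[p] != "C":
                raise ValueError(f"{self.name}: control position {p} is not a cytosine")

    @property
    def cytosine_positions(self) -> list[int]:
        """All reference cytosine positions (0-based)."""
        return [i for i, b in enumerate(self.sequence) if b == "C"]

    @property
    def repeat_cytosine_positions(self) -> list[int]:
        """Cytosines lying on the CCC triplet of an annotated unit."""
        return sorted(s + k for s in self.unit_starts for k in range(3))

    def repeat_phase(self, position: int) -> int | None:
        """Phase 1-3 for a cytosine of an annotated unit, else None."""
        for s in self.unit_starts:
            if s <= position < s + 3:
                return position - s + 1
        return None


@dataclass(frozen=True)
class ContextCall:
    """Sequence context and repeat phase of one reference cytosine."""

    position: int
    context: str  # CG / CHG / CHH / NA
    repeat_phase: int | None


def classify_context(region: BisulfiteRegion, position: int) -> ContextCall:
    """Context of the cytosine at ``position`` (CG, CHG, CHH, or NA).

    CG if the next base is G; CHG if the next is H (A/C/T) and the one
    after is G; CHH if both following bases are H.  Cytosines within
    2 nt of the region end use the supplied downstream context, else NA.
    """
    seq = region.sequence + region.downstream_context
    if position < 0 or position >= len(region.sequence):
        raise ValueError(f"position {position} outside region {region.name}")
    if region.sequence[position] != "C":
        raise ValueError(f"position {position} is not a cytosine in {region.name}")
    phase = region.repeat_phase(position)
    if position + 1 >= len(seq):
        return ContextCall(position, "NA", phase)
    nxt = seq[position + 1]
    if nxt == "G":
        return ContextCall(position, "CG", phase)
    if position + 2 >= len(seq):
        return ContextCall(position, "NA", phase)
    nxt2 = seq[position + 2]
    if nxt2 == "G":
        return ContextCall(position, "CHG", phase)
    return ContextCall(position, "CHH", phase)


def classify_region_contexts(region: BisulfiteRegion) -> list[ContextCall]:
    """Context calls for every reference cytosine of the region."""
    return [classify_context(region, p) for p in region.cytosine_positions]


def _bisulfite_score(clone: str, ref: str, offset: int) -> tuple[int, int]:
    """(matches, non-cytosine mismatches) for a gap-free overlay of the
    clone on the reference at ``offset``; reference C accepts clone C or T.
    """
    matches = mismatches = 0
    for j, base in enumerate(clone):
        i = offset + j
        if i < 0 or i >= len(ref):
            continue
        r = ref[i]
        if r == "C":
            if base in "CT":
                matches += 1
        elif base == r:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches


def _best_offset(clone: str, ref: str) -> tuple[int, int, int]:
    """Best gap-free offset of clone on ref: (offset, matches, mismatches).

    Offset 0 (full-amplicon clone) is tried first and short-circuits the
    sweep when it already matches every overlapping position.
    """
    m0, mm0 = _bisulfite_score(clone, ref, 0)
    if m0 == min(len(clone), len(ref)):
        return 0, m0, mm0
    best = (0, m0, mm0)
    for off in range(-len(clone) + 1, len(ref)):
        if off == 0:
            continue
        m, mm = _bisulfite_score(clone, ref, off)
        if m > best[1]:
            best = (off, m, mm)
    return best


@dataclass
class CloneAlignment:
    """Result of aligning one clone: per-position calls or a rejection."""

    clone_id: str
    sample: str
    calls: dict[int, str] | None
    rejected: bool = False
    reason: str = ""
    reoriented: bool = False


def align_clone(
    clone_seq: str,
    region: BisulfiteRegion,
    max_mismatch: int = 5,
    clone_id: str = "clone",
    sample: str = "wt",
) -> CloneAlignment:
    """Call methylation for one Sanger clone against the region reference.

    The clone is overlaid gap-free at the best-scoring offset, in the
    orientation (as given, or reverse complement) that scores better.
    At each reference cytosine: clone C -> methylated, clone T ->
    converted, anything else or not covered -> missing.  Clones with
    more than ``max_mismatch`` mismatches at non-cytosine reference
    positions are rejected, not silently dropped.
    """
    seq = normalize_sequence(clone_seq)
    if not seq:
        return CloneAlignment(clone_id, sample, None, True, "empty sequence")
    ref = region.sequence
    fwd = _best_offset(seq, ref)
    if fwd[1] == len(seq):  # perfect forward overlay; reverse cannot beat it
        rev = (0, -1, len(ref))
        rev_seq = ""
    else:
        rev_seq = reverse_complement(seq)
        rev = _best_offset(rev_seq, ref)
    if rev[1] > fwd[1]:
        seq, (offset, _, mismatches), reoriented = rev_seq, rev, True
    else:
        offset, _, mismatches = fwd
        reoriented = False
    if mismatches > max_mismatch:
        return CloneAlignment(
            clone_id, sample, None, True,
            f"{mismatches} non-cytosine mismatches > {max_mismatch}", reoriented,
        )
    calls: dict[int, str] = {}
    for pos in region.cytosine_positions:
        j = pos - offset
        if 0 <= j < len(seq):
            base = seq[j]
            calls[pos] = (
                CALL_METHYLATED if base == "C"
                else CALL_CONVERTED if base == "T"
                else CALL_MISSING
            )
        else:
            calls[pos] = CALL_MISSING
    return CloneAlignment(clone_id, sample, calls, False, "", reoriented)


@dataclass
class MethylationMatrix:
    """Clones x reference-cytosine calls with per-clone sample labels.

    ``calls`` is a DataFrame indexed by clone id with one column per
    reference cytosine position; cells are 'M' (methylated), 'C'
    (converted) or '.' (missing).
    """

    region: BisulfiteRegion
    calls: pd.DataFrame
    samples: pd.Series
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["clone_id", "sample", "reason"])
    )

    def __post_init__(self) -> None:
        expected = set(self.region.cytosine_positions)
        if set(self.calls.columns) != expected:
            raise ValueError("call matrix columns must be the region's cytosines")
        bad = ~self.calls.isin([CALL_METHYLATED, CALL_CONVERTED, CALL_MISSING])
        if bad.to_numpy().any():
            raise ValueError("call matrix contains invalid cells")

    @property
    def n_clones(self) -> int:
        return len(self.calls)

    def subset(self, sample: str) -> "MethylationMatrix":
        keep = self.samples[self.samples == sample].index
        return MethylationMatrix(
            self.region, self.calls.loc[keep], self.samples.loc[keep]
        )


def align_clones(
    clones: Iterable[tuple[str, str, str]],
    region: BisulfiteRegion,
    max_mismatch: int = 5,
) -> MethylationMatrix:
    """Align a batch of ``(clone_id, sample, sequence)`` records.

    Accepted clones form the methylation matrix; rejected ones are
    reported in ``matrix.rejects``.
    """
    rows, samples, rejects = {}, {}, []
    for clone_id, sample, seq in clones:
        res = align_clone(seq, region, max_mismatch, clone_id, sample)
        if res.rejected:
            rejects.append({"clone_id": clone_id, "sample": sample, "reason": res.reason})
        else:
            rows[clone_id] = res.calls
            samples[clone_id] = sample
    calls = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=region.cytosine_positions
    )
    if calls.empty:
        calls = pd.DataFrame(columns=region.cytosine_positions, dtype=object)
    return MethylationMatrix(
        region,
        calls,
        pd.Series(samples, dtype=object),
        pd.DataFrame(rejects, columns=["clone_id", "sample", "reason"]),
    )


@dataclass
class MethylationSummary:
    """Per-position, per-context, per-phase and overall methylation rates.

    Frequencies are the methylated fraction of non-missing calls, raw
    (no correction for incomplete conversion).  ``overall`` covers all
    reference cytosines; ``overall_repeat`` restricts to cytosines of
    annotated repeat units.
    """

    region_name: str
    n_clones: int
    per_position: pd.Series
    per_context: pd.Series
    per_phase: pd.Series
    overall: float
    overall_repeat: float
    conversion_rate: float | None = None


def summarize(matrix: MethylationMatrix) -> MethylationSummary:
    """Summarize a methylation matrix by position, context, and phase.

    All-missing positions get NaN per-position frequency and are
    excluded from the overall rates.
    """
    if matrix.n_clones == 0:
        raise ValueError("empty methylation matrix")
    calls = matrix.calls
    region = matrix.region
    meth = (calls == CALL_METHYLATED).sum(axis=0)
    informative = (calls != CALL_MISSING).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_position = meth / informative.replace(0, np.nan)
    per_position.name = "methylation_frequency"

    contexts = {c.position: c for c in classify_region_contexts(region)}
    ctx_rows = {}
    for ctx in ("CG", "CHG", "CHH"):
        pos = [p for p, c in contexts.items() if c.context == ctx]
        m, n = meth[pos].sum(), informative[pos].sum()
        ctx_rows[ctx] = m / n if n else np.nan
    per_context = pd.Series(ctx_rows, name="methylation_frequency")

    phase_rows = {}
    for phase in (1, 2, 3):
        pos = [p for p, c in contexts.items() if c.repeat_phase == phase]
        m, n = meth[pos].sum(), informative[pos].sum()
        phase_rows[phase] = m / n if n else np.nan
    per_phase = pd.Series(phase_rows, name="methylation_frequency")

    overall = meth.sum() / informative.sum() if informative.sum() else np.nan
    rep = region.repeat_cytosine_positions
    n_rep = informative[rep].sum()
    overall_repeat = meth[rep].sum() / n_rep if n_rep else np.nan

    return MethylationSummary(
        region.name, matrix.n_clones, per_position, per_context, per_phase,
        float(overall), float(overall_repeat),
    )


def conversion_check(
    matrix: MethylationMatrix, min_rate: float = 0.95
) -> tuple[float | None, str]:
    """Conversion efficiency from control (known-unmethylated) cytosines.

    Returns ``(rate, status)`` where status is 'pass', 'fail', or
    'no conversion control' when the region defines no control
    positions or no informative control cells exist.
    """
    controls = list(matrix.region.control_positions)
    if not controls:
        return None, "no conversion control"
    cells = matrix.calls[controls]
    converted = int((cells == CALL_CONVERTED).sum().sum())
    methylated = int((cells == CALL_METHYLATED).sum().sum())
    if converted + methylated == 0:
        return None, "no conversion control"
    rate = converted / (converted + methylated)
    return rate, "pass" if rate >= min_rate else "fail"


def compare_genotypes(
    summary_a: MethylationSummary, summary_b: MethylationSummary
) -> pd.DataFrame:
    """Side-by-side per-context and per-phase frequencies with differences.

    Both summaries must come from the same region.  No hypothesis test
    is attached; the table reports raw frequency differences (a - b).
    """
    if summary_a.region_name != summary_b.region_name:
        raise ValueError(
            f"summaries are from different regions: "
            f"{summary_a.region_name!r} vs {summary_b.region_name!r}"
        )
    rows = []
    for ctx in ("CG", "CHG", "CHH"):
        a, b = summary_a.per_context[ctx], summary_b.per_context[ctx]
        rows.append({"stratum": f"context:{ctx}", "a": a, "b": b, "difference": a - b})
    for phase in (1, 2, 3):
        a, b = summary_a.per_phase[phase], summary_b.per_phase[phase]
        rows.append({"stratum": f"phase:{phase}", "a": a, "b": b, "difference": a - b})
    for name, a, b in (
        ("overall", summary_a.overall, summary_b.overall),
        ("overall_repeat", summary_a.overall_repeat, summary_b.overall_repeat),
    ):
        rows.append({"stratum": name, "a": a, "b": b, "difference": a - b})
    return pd.DataFrame(rows, columns=["stratum", "a", "b", "difference"])


def matrix_diagram(matrix: MethylationMatrix) -> str:
    """Plain-text per-clone methylation diagram (one row per clone).

    'M' = methylated, 'c' = converted, '.' = missing, in reference
    cytosine order; a simple textual stand-in for a CyMATE-style plot.
    """
    lines = []
    width = max((len(i) for i in matrix.calls.index), default=5)
    for clone_id, row in matrix.calls.iterrows():
        cells = "".join(
            "M" if v == CALL_METHYLATED else "c" if v == CALL_CONVERTED else "."
            for v in row
        )
        lines.append(f"{clone_id:<{width}}  {cells}")
    return "\n".join(lines)
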