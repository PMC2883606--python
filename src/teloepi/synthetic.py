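"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study's inputs at desk scale: Argonaute-IP
small-RNA libraries with planted telomeric G-/C-siRNAs of controlled
homology extent plus labeled background and subtelomere-derived reads;
subtelomeric reference windows with a terminal telomeric tract and
optional interstitial repeats; bisulfite clones of a 13-unit CCCTAAA
amplicon with per-position methylation probabilities and a
conversion-efficiency parameter; and dot-blot / ChIP signal panels with
multiplicative log-normal noise.  All randomness flows from one seed
through per-stage substreams, so outputs are byte-identical under a
fixed seed and stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from teloepi.bisulfite import BisulfiteRegion
from teloepi.motif import RepeatMotif, TELOMERE_MOTIF, reverse_complement
from teloepi.repeat_scan import SmallRNA, find_telomeric_tracts, max_telomeric_homology
from teloepi.subtel_align import SubtelomereRef

_BASES = np.array(list("ACGT"))

# Stream labels keep per-stage substreams stable regardless of which
# stages a run actually generates.
_STREAMS = ("subtelomere", "smallrna", "bisulfite", "signals")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream derived from the global seed."""
    if stage not in _STREAMS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STREAMS}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stage),))
    return np.random.default_rng(ss)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# Configuration blocks
# ---------------------------------------------------------------------------

@dataclass
class SubtelomereSim:
    """Synthetic subtelomere geometry.

    Arms are ~15 kb windows, mirroring the window size used for real
    chromosome-end references; each carries one terminal telomeric
    tract on its telomere side and optionally short interstitial
    repeats in the interior.
    """

    n_arms: int = 2
    length: int = 15_000
    tract_units: int = 20
    n_interstitial: int = 1
    interstitial_units: int = 3
    telomere_sides: tuple[str, ...] = ("right", "left")
    min_units_clean: int = 2  # background kept free of tracts >= this size


@dataclass
class SmallRNASim:
    """One synthetic AGO-IP library.

    Defaults reflect an AGO4-like library: mostly G-siRNAs spanning a
    broad homology range, a few C-siRNAs capped at 14 nt of homology,
    23-25 nt reads, plus background and subtelomere-derived reads.
    """

    library: str = "AGO4"
    g_homologies: tuple[int, ...] = (12, 14, 15, 16, 18, 20, 21, 23, 24, 25)
    c_homologies: tuple[int, ...] = (12, 13, 14)
    read_length_range: tuple[int, int] = (23, 25)
    n_background: int = 50
    n_subtelomeric: int = 10
    min_homology: int = 12  # background guaranteed below this
    max_attempts: int = 10_000


@dataclass
class BisulfiteSim:
    """Bisulfite clone set for one sample."""

    preset: str = "wt-1L0"
    sample: str = "wt"
    n_clones: int = 30
    conversion: float = 0.99
    error_rate: float = 0.0


@dataclass
class SignalSim:
    """Dot-blot / ChIP signal panels with multiplicative noise."""

    true_fold: float = 4.0
    background_index: float = 0.025
    chip_enrichments: Mapping[str, float] = field(
        default_factory=lambda: {"H3K4me3": 0.5, "H3K9me2": 2.0, "H3K27me1": 3.0}
    )
    noise_sd: float = 0.1
    n_replicates: int = 3


@dataclass
class SimConfig:
    """Full simulation configuration with one global seed."""

    seed: int = 0
    subtelomere: SubtelomereSim = field(default_factory=SubtelomereSim)
    smallrna: SmallRNASim = field(default_factory=SmallRNASim)
    bisulfite: BisulfiteSim = field(default_factory=BisulfiteSim)
    signals: SignalSim = field(default_factory=SignalSim)


# ---------------------------------------------------------------------------
# The 1L-0' amplicon presets
# ---------------------------------------------------------------------------

# Fixed unique flanks for the synthetic 1L-0' amplicon (anchor sequence
# for clone alignment; free of telomeric repeats).
_FLANK_LEFT = "ATGACTGAGCTTGACCATCGGATAGCTTGAACGGTTCAGATCCGATTGCA"
_FLANK_RIGHT = "GATCAGTTCGACCTGATAGCATTCGGAACTGATCGGTACAGTTCGATCAG"
_DOWNSTREAM = "ATC"

N_UNITS_1L0 = 13

#: Repeat-phase methylation probabilities of the wild-type preset.
#: Mean over the three phases is 0.45, enriched at the third cytosine
#: of each CCCTAAA unit.
WT_PHASE_PROBS = (0.35, 0.35, 0.65)
#: Flat, strongly reduced profile for the RdDM-deficient preset.
RDR2_PHASE_PROBS = (0.05, 0.05, 0.05)


def region_1l0(motif: RepeatMotif = TELOMERE_MOTIF) -> BisulfiteRegion:
    """The synthetic 1L-0' amplicon: 13 CCCTAAA units between unique flanks.

    Flank cytosines are annotated as conversion controls (they are
    unmethylated in every preset).
    """
    unit = motif.unit_c
    sequence = _FLANK_LEFT + unit * N_UNITS_1L0 + _FLANK_RIGHT
    unit_starts = tuple(
        len(_FLANK_LEFT) + i * motif.period for i in range(N_UNITS_1L0)
    )
    repeat_start = len(_FLANK_LEFT)
    repeat_end = repeat_start + N_UNITS_1L0 * motif.period
    controls = tuple(
        i
        for i, b in enumerate(sequence)
        if b == "C" and not repeat_start <= i < repeat_end
    )
    return BisulfiteRegion(
        name="1L-0'",
        sequence=sequence,
        unit_starts=unit_starts,
        control_positions=controls,
        downstream_context=_DOWNSTREAM,
        motif=motif,
    )


def preset_probabilities(region: BisulfiteRegion, preset: str) -> dict[int, float]:
    """Per-cytosine true methylation probabilities for a named preset.

    'wt-1L0': mean 0.45 over repeat cytosines, phase-3 enriched;
    'rdr2-1L0': flat 0.05.  Flank cytosines are unmethylated in both.
    """
    if preset == "wt-1L0":
        phase_probs = WT_PHASE_PROBS
    elif preset == "rdr2-1L0":
        phase_probs = RDR2_PHASE_PROBS
    else:
        raise ValueError(f"unknown preset {preset!r}")
    probs = {}
    for pos in region.cytosine_positions:
        phase = region.repeat_phase(pos)
        probs[pos] = phase_probs[phase - 1] if phase is not None else 0.0
    return probs


# ---------------------------------------------------------------------------
# Subtelomere references
# ---------------------------------------------------------------------------

def _clean_background(
    rng: np.random.Generator, n: int, motif: RepeatMotif, min_units: int
) -> str:
    """Random sequence free of telomeric tracts >= min_units repeat units."""
    seq = list(_random_seq(rng, n))
    for _ in range(50):
        tracts = find_telomeric_tracts("".join(seq), min_units, motif)
        if not tracts:
            return "".join(seq)
        for start, end, _strand in tracts:
            mid = (start + end) // 2
            seq[mid] = {"A": "G", "C": "G", "G": "C", "T": "C"}[seq[mid]]
    raise RuntimeError("could not generate tract-free background")


def _break_base(rng: np.random.Generator, forbidden: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in forbidden]
    return str(rng.choice(np.array(choices)))


def simulate_subtelomeres(
    config: SubtelomereSim,
    seed: int = 0,
    motif: RepeatMotif = TELOMERE_MOTIF,
    rng: np.random.Generator | None = None,
) -> tuple[list[SubtelomereRef], pd.DataFrame]:
    """Synthetic subtelomeric arms plus a truth table of planted tracts.

    Each arm is unique random sequence with a terminal telomeric tract
    (G-strand unit on the forward reference) on the declared telomere
    side, plus optional interstitial tracts.  The truth table records
    all planted intervals in 0-based half-open coordinates.
    """
    rng = rng if rng is not None else stage_rng(seed, "subtelomere")
    tract_len = config.tract_units * motif.period
    inter_len = config.interstitial_units * motif.period
    interior_needed = config.n_interstitial * (inter_len + 2)
    if config.length < tract_len + interior_needed + 200:
        raise ValueError(
            f"arm length {config.length} too small for tract {tract_len} "
            f"plus {config.n_interstitial} interstitial motifs"
        )
    refs: list[SubtelomereRef] = []
    truth_rows: list[dict] = []
    unit = motif.unit_g
    for a in range(config.n_arms):
        arm_id = f"{a + 1}L"
        side = config.telomere_sides[a % len(config.telomere_sides)]
        bg_len = config.length - tract_len
        bg = _clean_background(rng, bg_len, motif, config.min_units_clean)
        tract = (unit * (config.tract_units + 1))[:tract_len]
        # break periodicity at the tract/background junction: the base
        # left of the tract must not extend the phase (unit[-1]); the
        # base right of it must not either (unit[tract_len % period])
        if side == "right":
            seq = bg[:-1] + _break_base(rng, {unit[-1]}) + tract
            t_start = config.length - tract_len
        else:
            seq = tract + _break_base(rng, {unit[tract_len % motif.period]}) + bg[1:]
            t_start = 0
        seq = list(seq)
        truth_rows.append(
            {"arm_id": arm_id, "start": t_start, "end": t_start + tract_len,
             "strand": "G", "kind": "terminal"}
        )
        # interstitial motifs, away from the terminal tract and arm ends
        lo = 100 if side == "left" else 50
        hi = config.length - tract_len - inter_len - 100
        if side == "left":
            lo, hi = tract_len + 100, config.length - inter_len - 100
        placed: list[tuple[int, int]] = [(t_start, t_start + tract_len)]
        for _ in range(config.n_interstitial):
            for _attempt in range(200):
                pos = int(rng.integers(lo, hi))
                if all(pos + inter_len + 2 <= s or pos >= e + 2 for s, e in placed):
                    break
            else:
                raise RuntimeError("could not place interstitial motif")
            strand = str(rng.choice(np.array(["G", "C"])))
            u = motif.unit(strand)
            inter = (u * (config.interstitial_units + 1))[:inter_len]
            seq[pos : pos + inter_len] = list(inter)
            # periodicity breaks on both sides
            seq[pos - 1] = _break_base(rng, {u[-1]})
            seq[pos + inter_len] = _break_base(rng, {u[inter_len % motif.period]})
            placed.append((pos, pos + inter_len))
            truth_rows.append(
                {"arm_id": arm_id, "start": pos, "end": pos + inter_len,
                 "strand": strand, "kind": "interstitial"}
            )
        refs.append(SubtelomereRef(arm_id, "".join(seq), side))
    truth = pd.DataFrame(
        truth_rows, columns=["arm_id", "start", "end", "strand", "kind"]
    ).sort_values(["arm_id", "start"], ignore_index=True)
    return refs, truth


# ---------------------------------------------------------------------------
# Small-RNA libraries
# ---------------------------------------------------------------------------

def _count_occurrences(needle: str, refs: Sequence[SubtelomereRef]) -> int:
    """Occurrences of needle or its reverse complement across all refs."""
    rc = reverse_complement(needle)
    total = 0
    for r in refs:
        for target in {needle, rc}:
            start = 0
            while True:
                i = r.sequence.find(target, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def _plant_telomeric_read(
    rng: np.random.Generator,
    strand: str,
    homology: int,
    read_len: int,
    motif: RepeatMotif,
    max_attempts: int,
) -> str:
    """A read whose maximal telomeric homology is exactly ``homology``
    on ``strand``: a repeat substring at a random phase inside random
    flanks, rejection-sampled until the scan confirms the target.
    """
    unit = motif.unit(strand)
    tandem = unit * (homology // motif.period + 2)
    for _ in range(max_attempts):
        phase = int(rng.integers(motif.period))
        core = tandem[phase : phase + homology]
        left_len = int(rng.integers(0, read_len - homology + 1))
        read = (
            _random_seq(rng, left_len)
            + core
            + _random_seq(rng, read_len - homology - left_len)
        )
        s, h, _ = max_telomeric_homology(read, motif)
        if s == strand and h == homology:
            return read
    raise RuntimeError(
        f"failed to plant {strand}-read with homology {homology} in "
        f"{max_attempts} attempts"
    )


def simulate_smallrna_library(
    config: SmallRNASim,
    refs: Sequence[SubtelomereRef] = (),
    seed: int = 0,
    motif: RepeatMotif = TELOMERE_MOTIF,
    rng: np.random.Generator | None = None,
) -> tuple[list[SmallRNA], pd.DataFrame]:
    """One synthetic AGO library plus its per-read truth table.

    Planted telomeric reads carry exactly their drawn homology extent;
    subtelomere-derived reads are exact, reference-unique substrings at
    recorded positions; background reads contain no telomeric stretch
    of ``min_homology`` nt and no exact subtelomeric match.
    """
    rng = rng if rng is not None else stage_rng(seed, "smallrna")
    if config.n_subtelomeric and not refs:
        raise ValueError("subtelomeric reads requested but no references given")
    lo, hi = config.read_length_range
    reads: list[SmallRNA] = []
    truth: list[dict] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{config.library}_r{counter:04d}"

    for strand, homologies in (("G", config.g_homologies), ("C", config.c_homologies)):
        for h in homologies:
            read_len = max(h, int(rng.integers(lo, hi + 1)))
            for _attempt in range(config.max_attempts):
                seq = _plant_telomeric_read(
                    rng, strand, h, read_len, motif, config.max_attempts
                )
                # keep truth labels disjoint: a telomeric read must not
                # double as a reference-unique placement
                if not refs or _count_occurrences(seq, refs) != 1:
                    break
            else:
                raise RuntimeError(
                    "failed to plant a telomeric read without a unique "
                    "subtelomeric placement"
                )
            rid = next_id()
            reads.append(SmallRNA(rid, seq, config.library))
            truth.append(
                {"read_id": rid, "class": f"telomeric-{strand}",
                 "homology_length": h, "arm_id": "", "start": -1, "strand": ""}
            )

    for _ in range(config.n_subtelomeric):
        for _attempt in range(config.max_attempts):
            ref = refs[int(rng.integers(len(refs)))]
            read_len = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(0, len(ref.sequence) - read_len + 1))
            sub = ref.sequence[pos : pos + read_len]
            _, h, _ = max_telomeric_homology(sub, motif)
            if h >= config.min_homology or _count_occurrences(sub, refs) != 1:
                continue
            strand = str(rng.choice(np.array(["+", "-"])))
            seq = sub if strand == "+" else reverse_complement(sub)
            rid = next_id()
            reads.append(SmallRNA(rid, seq, config.library))
            truth.append(
                {"read_id": rid, "class": "subtelomeric", "homology_length": h,
                 "arm_id": ref.arm_id, "start": pos, "strand": strand}
            )
            break
        else:
            raise RuntimeError(
                "failed to draw a unique subtelomeric read (uniqueness or "
                "telomere-content constraint not satisfiable)"
            )

    for _ in range(config.n_background):
        for _attempt in range(config.max_attempts):
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            _, h, _ = max_telomeric_homology(seq, motif)
            if h >= config.min_homology:
                continue
            if refs and _count_occurrences(seq, refs) != 0:
                continue
            rid = next_id()
            reads.append(SmallRNA(rid, seq, config.library))
            truth.append(
                {"read_id": rid, "class": "background", "homology_length": h,
                 "arm_id": "", "start": -1, "strand": ""}
            )
            break
        else:
            raise RuntimeError(
                "failed to draw a background read free of telomeric 12-mers "
                "and subtelomeric matches"
            )

    truth_df = pd.DataFrame(
        truth,
        columns=["read_id", "class", "homology_length", "arm_id", "start", "strand"],
    )
    return reads, truth_df


# ---------------------------------------------------------------------------
# Bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    region: BisulfiteRegion,
    probabilities: Mapping[int, float],
    conversion: float = 0.99,
    n_clones: int = 30,
    seed: int = 0,
    sample: str = "wt",
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulated Sanger clones of a bisulfite-converted amplicon.

    Per clone, each reference cytosine is independently methylated with
    its per-position probability; unmethylated cytosines are converted
    C->T with probability ``conversion`` (methylated cytosines are
    never converted).  A uniform per-base sequencing error is applied
    afterwards.  Returns ``(clone_id, sample, sequence)`` records and a
    per-cell truth table of the drawn methylation states.
    """
    if not 0.0 <= conversion <= 1.0:
        raise ValueError(f"conversion must be in [0, 1], got {conversion}")
    missing = set(region.cytosine_positions) - set(probabilities)
    if missing:
        raise ValueError(f"no probability for cytosines {sorted(missing)[:5]}...")
    rng = rng if rng is not None else stage_rng(seed, "bisulfite")
    clones: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    cpos = region.cytosine_positions
    for c in range(n_clones):
        clone_id = f"{sample}_c{c + 1:03d}"
        seq = list(region.sequence)
        for pos in cpos:
            methylated = bool(rng.random() < probabilities[pos])
            if not methylated and rng.random() < conversion:
                seq[pos] = "T"
            truth_rows.append(
                {"clone_id": clone_id, "position": pos, "methylated": methylated}
            )
        if error_rate > 0:
            for i in range(len(seq)):
                if rng.random() < error_rate:
                    seq[i] = str(rng.choice(_BASES[_BASES != seq[i]]))
        clones.append((clone_id, sample, "".join(seq)))
    truth = pd.DataFrame(truth_rows, columns=["clone_id", "position", "methylated"])
    return clones, truth


# ---------------------------------------------------------------------------
# Signal panels
# ---------------------------------------------------------------------------

def simulate_signal_panels(
    config: SignalSim,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dot-blot and ChIP signal tables with multiplicative log-normal noise.

    Dot-blot: one sample panel with true methylation index
    ``true_fold * background_index`` and one converted-plasmid
    background panel with index ``background_index``, per replicate.
    ChIP: per-replicate antibody quantities with the configured true
    enrichments over histone H3.  Returns tidy (dotblot, chip) tables.
    """
    rng = rng if rng is not None else stage_rng(seed, "signals")

    def noisy(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, config.noise_sd)))

    dot_rows = []
    sample_index = config.true_fold * config.background_index
    for rep in range(1, config.n_replicates + 1):
        for sample, index in (("wt", sample_index), ("bs_plasmid", config.background_index)):
            ccctaaa = noisy(100.0)
            dot_rows.append(
                {"replicate": rep, "sample": sample, "probe": "CCCTAAA", "signal": ccctaaa}
            )
            for probe in ("TTTAGGG_oligo", "TTTAGGG_long"):
                dot_rows.append(
                    {"replicate": rep, "sample": sample, "probe": probe,
                     "signal": noisy(index) * ccctaaa}
                )
    dotblot = pd.DataFrame(dot_rows, columns=["replicate", "sample", "probe", "signal"])

    chip_rows = []
    h3_true = 0.2
    for rep in range(1, config.n_replicates + 1):
        h3 = noisy(h3_true)
        chip_rows.append(
            {"replicate": rep, "sample": "wt", "antibody": "H3", "signal": h3}
        )
        for ab, enr in config.chip_enrichments.items():
            chip_rows.append(
                {"replicate": rep, "sample": "wt", "antibody": ab,
                 "signal": noisy(enr) * h3}
            )
        chip_rows.append(
            {"replicate": rep, "sample": "wt", "antibody": "mock",
             "signal": noisy(0.01)}
        )
    chip = pd.DataFrame(chip_rows, columns=["replicate", "sample", "antibody", "signal"])
    return dotblot, chip
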