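"""Signal-normalization arithmetic for bisulfite dot-blots and ChIP.

Dot-blot methylation index: the signal of bisulfite-resistant
(i.e. methylated) telomeric DNA detected with a TTTAGGG probe is
normalized to total telomeric DNA detected with the CCCTAAA probe, and
expressed as fold over the same index of a fully converted,
non-methylated plasmid background.  ChIP enrichment: each antibody's
recovered quantity is divided by a normalizer (histone H3 occupancy or
a mock IP).  Replicate panels are normalized individually and then
averaged; the module consumes already-quantified signal tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOTBLOT_PROBES = ("AAAATTT", "TTTAGGG_oligo", "TTTAGGG_long", "CCCTAAA")
CHIP_ANTIBODIES = ("H3", "H3K4me3", "H3K9me2", "H3K27me1", "mock")


@dataclass(frozen=True)
class SignalPanel:
    """Dot-blot signal intensities (arbitrary units) for one sample."""

    sample: str
    signals: Mapping[str, float]

    def __post_init__(self) -> None:
        for probe, v in self.signals.items():
            if v < 0:
                raise ValueError(f"{self.sample}: negative signal for {probe}")

    def __getitem__(self, probe: str) -> float:
        try:
            return float(self.signals[probe])
        except KeyError:
            raise KeyError(f"panel {self.sample!r} has no probe {probe!r}") from None


@dataclass(frozen=True)
class ChIPPanel:
    """ChIP quantities per antibody for one sample at one locus."""

    sample: str
    quantities: Mapping[str, float]
    locus: str = ""

    def __post_init__(self) -> None:
        for ab, v in self.quantities.items():
            if v < 0:
                raise ValueError(f"{self.sample}: negative quantity for {ab}")

    def __getitem__(self, antibody: str) -> float:
        try:
            return float(self.quantities[antibody])
        except KeyError:
            raise KeyError(f"panel {self.sample!r} has no antibody {antibody!r}") from None


def dotblot_methylation_index(
    panel: SignalPanel,
    background: SignalPanel,
    probe: str = "TTTAGGG_oligo",
) -> tuple[float, float]:
    """Methylation index and fold over the converted-plasmid background.

    index = S_probe / S_CCCTAAA for the sample;
    fold  = index_sample / index_background.
    """
    for p in (panel, background):
        if p["CCCTAAA"] == 0:
            raise ZeroDivisionError(f"sample {p.sample!r}: CCCTAAA signal is zero")
    index = panel[probe] / panel["CCCTAAA"]
    bg_index = background[probe] / background["CCCTAAA"]
    if bg_index == 0:
        raise ZeroDivisionError(
            f"background {background.sample!r}: zero index for probe {probe!r}"
        )
    return index, index / bg_index


def chip_enrichment(panel: ChIPPanel, normalize_to: str = "H3") -> dict[str, float]:
    """Enrichment of each antibody relative to the normalizer.

    ``normalize_to`` is typically 'H3' (histone occupancy) or 'mock'.
    """
    norm = panel[normalize_to]
    if norm == 0:
        raise ZeroDivisionError(
            f"sample {panel.sample!r}: normalizer {normalize_to!r} is zero"
        )
    return {
        ab: panel[ab] / norm
        for ab in panel.quantities
        if ab != normalize_to
    }


def average_replicates(
    panels: Sequence[ChIPPanel], normalize_to: str = "H3"
) -> pd.DataFrame:
    """Per-replicate normalization followed by averaging.

    Each panel is normalized individually, then mean and standard
    deviation across replicates are reported per antibody.
    """
    if not panels:
        raise ValueError("no replicate panels provided")
    rows = [chip_enrichment(p, normalize_to) for p in panels]
    df = pd.DataFrame(rows)
    out = pd.DataFrame(
        {"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1) if len(df) > 1 else 0.0}
    )
    out.index.name = "antibody"
    return out


def panels_from_table(table: pd.DataFrame, kind: str = "dotblot") -> list:
    """Build panels from a tidy table (columns: sample, probe/antibody, signal).

    For kind='chip' an optional ``locus`` column is carried through.
    """
    key = "probe" if kind == "dotblot" else "antibody"
    required = {"sample", key, "signal"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    panels = []
    for sample, grp in table.groupby("sample", sort=True):
        signals = dict(zip(grp[key], grp["signal"].astype(float)))
        if kind == "dotblot":
            panels.append(SignalPanel(sample, signals))
        else:
            locus = grp["locus"].iloc[0] if "locus" in grp.columns else ""
            panels.append(ChIPPanel(sample, signals, locus))
    return panels
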