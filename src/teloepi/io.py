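"""File I/O: FASTA/FASTQ reads, reference sets, region definitions, tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from teloepi.bisulfite import BisulfiteRegion
from teloepi.repeat_scan import SmallRNA
from teloepi.subtel_align import SubtelomereRef


def _format_of(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_smallrna(
    path: str | Path,
    library: str | None = None,
    library_map: dict[str, str] | None = None,
) -> list[SmallRNA]:
    """Read small RNAs from FASTA/FASTQ.

    Library is taken per read from ``library_map`` (read_id -> library)
    when given, else from ``library``, else from the file stem.
    """
    path = Path(path)
    default = library if library is not None else path.stem
    reads = []
    for rec in SeqIO.parse(str(path), _format_of(path)):
        lib = (library_map or {}).get(rec.id, default)
        reads.append(SmallRNA(rec.id, str(rec.seq), lib))
    return reads


def read_library_map(path: str | Path) -> dict[str, str]:
    """Sidecar TSV mapping read_id -> library."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"read_id", "library"} <= set(df.columns):
        raise ValueError("library map needs columns read_id, library")
    return dict(zip(df["read_id"], df["library"]))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_refs(fasta: str | Path, sides: str | Path | dict[str, str]) -> list[SubtelomereRef]:
    """Subtelomeric references from FASTA plus a telomere-side table.

    ``sides`` is a TSV with columns arm_id, telomere_side, or an
    equivalent dict.
    """
    if not isinstance(sides, dict):
        df = pd.read_csv(sides, sep="\t", dtype=str)
        if not {"arm_id", "telomere_side"} <= set(df.columns):
            raise ValueError("sides table needs columns arm_id, telomere_side")
        sides = dict(zip(df["arm_id"], df["telomere_side"]))
    refs = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in sides:
            raise ValueError(f"no telomere_side entry for reference {rec.id!r}")
        refs.append(SubtelomereRef(rec.id, str(rec.seq), sides[rec.id]))
    return refs


def load_region(path: str | Path) -> BisulfiteRegion:
    """Bisulfite region from a YAML/JSON definition.

    Keys: name, sequence (inline) or fasta (path), unit_starts,
    control_positions, downstream_context.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "sequence" in data:
        sequence = data["sequence"]
    elif "fasta" in data:
        fasta = Path(data["fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        sequence = str(next(SeqIO.parse(str(fasta), "fasta")).seq)
    else:
        raise ValueError("region definition needs 'sequence' or 'fasta'")
    return BisulfiteRegion(
        name=data["name"],
        sequence=sequence,
        unit_starts=tuple(data.get("unit_starts", ())),
        control_positions=tuple(data.get("control_positions", ())),
        downstream_context=data.get("downstream_context", ""),
    )


def read_clones(
    fasta: str | Path, sample_map: str | Path | dict[str, str] | None = None
) -> list[tuple[str, str, str]]:
    """Bisulfite clones as (clone_id, sample, sequence) records.

    The sample label comes from ``sample_map`` (clone_id -> sample) or
    from a ``sample=<label>`` token in the FASTA description; default 'wt'.
    """
    if sample_map is not None and not isinstance(sample_map, dict):
        df = pd.read_csv(sample_map, sep="\t", dtype=str)
        if not {"clone_id", "sample"} <= set(df.columns):
            raise ValueError("sample map needs columns clone_id, sample")
        sample_map = dict(zip(df["clone_id"], df["sample"]))
    clones = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        sample = "wt"
        if isinstance(sample_map, dict) and rec.id in sample_map:
            sample = sample_map[rec.id]
        else:
            for token in rec.description.split():
                if token.startswith("sample="):
                    sample = token.split("=", 1)[1]
        clones.append((rec.id, sample, str(rec.seq)))
    return clones


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
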