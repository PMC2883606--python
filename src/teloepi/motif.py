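"""The telomeric repeat unit and its rotation/phase coordinate system.

The plant telomeric repeat is the 7-mer TTTAGGG on the G-rich strand and
its reverse complement CCCTAAA on the C-rich strand.  Both strands of a
telomeric tract are periodic with period 7, so any perfect stretch of
telomeric sequence inside a read is a substring of the infinite periodic
sequence built from one of the two units.  Rotations of the unit
(phase starts of the periodic sequence) define the matching alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def _smallest_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if len(s) % p == 0 and s == s[:p] * (len(s) // p):
            return p
    return len(s)


@dataclass(frozen=True)
class RepeatMotif:
    """A tandem-repeat unit with its two strand representations.

    Parameters
    ----------
    unit_g : str
        Repeat unit on the G-rich strand (default TTTAGGG).

    The C-strand unit is derived as the reverse complement and the
    period as the unit length.  The unit must be primitive (no smaller
    internal period), otherwise rotation counts would be wrong.
    """

    unit_g: str = "TTTAGGG"
    unit_c: str = field(init=False)
    period: int = field(init=False)

    def __post_init__(self) -> None:
        unit = normalize_sequence(self.unit_g)
        if not unit or set(unit) - set("ACGT"):
            raise ValueError(f"repeat unit must be non-empty A/C/G/T: {self.unit_g!r}")
        if _smallest_period(unit) != len(unit):
            raise ValueError(f"repeat unit {unit!r} is not primitive")
        object.__setattr__(self, "unit_g", unit)
        object.__setattr__(self, "unit_c", reverse_complement(unit))
        object.__setattr__(self, "period", len(unit))

    def unit(self, strand: str) -> str:
        """Repeat unit for strand 'G' or 'C'."""
        if strand == "G":
            return self.unit_g
        if strand == "C":
            return self.unit_c
        raise ValueError(f"strand must be 'G' or 'C', got {strand!r}")

    def rotations(self, strand: str) -> list[str]:
        """All cyclic rotations of the strand's unit (phase starts)."""
        u = self.unit(strand)
        return [u[i:] + u[:i] for i in range(self.period)]


#: The Arabidopsis-type telomeric repeat, (TTTAGGG)n / (CCCTAAA)n.
TELOMERE_MOTIF = RepeatMotif("TTTAGGG")
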