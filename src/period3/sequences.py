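"""DNA sequence input and numeric mapping schemes.

Spectral analysis of DNA requires converting the character string over
``{a, c, g, t}`` into a numeric signal.  This module provides the classic
Voss binary-indicator representation and three single-sequence complex
("quaternary") codes that assign each base one value from ``{+1, -1, +j, -j}``:

``proposed_quaternary``
    a = -1, c = -j, g = +1, t = +j.  The K-Quaternary Code-III flipped about
    the imaginary axis; the code used throughout this package by default.
``k_quaternary_I``
    a = +1, c = -1, g = -j, t = +j.
``k_quaternary_III``
    a = +1, c = -j, g = -1, t = +j.

All complex codes are bijections on ``{a, c, g, t}``, so the mapped signal
retains the full sequence information in a single complex series that is
directly amenable to Fourier and subspace spectral estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "ComplexSignal",
    "IndicatorSet",
    "MAPPING_SCHEMES",
    "read_fasta",
    "map_sequence",
    "inverse_map",
    "voss_indicators",
]

_VALID_BASES = frozenset("acgtn")

#: Complex value assigned to each base, per single-sequence scheme.
MAPPING_SCHEMES: dict[str, dict[str, complex]] = {
    "proposed_quaternary": {"a": -1 + 0j, "c": -1j, "g": 1 + 0j, "t": 1j},
    "k_quaternary_I": {"a": 1 + 0j, "c": -1 + 0j, "g": -1j, "t": 1j},
    "k_quaternary_III": {"a": 1 + 0j, "c": -1j, "g": -1 + 0j, "t": 1j},
}

#: Short CLI-friendly aliases.
SCHEME_ALIASES = {
    "proposed": "proposed_quaternary",
    "kq1": "k_quaternary_I",
    "kq3": "k_quaternary_III",
}


def resolve_scheme(name: str) -> str:
    """Normalize a mapping-scheme name, accepting short aliases."""
    key = SCHEME_ALIASES.get(name, name)
    if key not in MAPPING_SCHEMES:
        known = sorted(MAPPING_SCHEMES) + sorted(SCHEME_ALIASES)
        raise ValueError(f"unknown mapping scheme {name!r}; choose from {known}")
    return key


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    bases : str
        Lower-case sequence over ``{a, c, g, t, n}``.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        lowered = self.bases.lower()
        object.__setattr__(self, "bases", lowered)
        for pos, ch in enumerate(lowered, start=1):
            if ch not in _VALID_BASES:
                raise ValueError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos} "
                    "(allowed: a, c, g, t, n)"
                )
        if not lowered:
            warnings.warn(f"sequence {self.id!r} is empty", stacklevel=2)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ComplexSignal:
    """Complex-valued numeric series produced by a mapping scheme.

    ``origin_offset`` is the 0-based index of the first value within the
    source sequence, so that track positions can be reported in source
    coordinates after slicing.
    """

    values: np.ndarray
    scheme: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.ascontiguousarray(self.values, dtype=np.complex128)
        )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IndicatorSet:
    """Voss binary indicator sequences, one per base.

    At every position exactly one of the four indicators is 1 (the four
    series are redundant: any three determine the sequence).
    """

    x_a: np.ndarray
    x_c: np.ndarray
    x_g: np.ndarray
    x_t: np.ndarray

    def as_array(self) -> np.ndarray:
        """Stack the four indicators into a (4, N) array in a,c,g,t order."""
        return np.stack([self.x_a, self.x_c, self.x_g, self.x_t])


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    Ids are taken from headers up to the first whitespace; bases are
    lower-cased.  Characters outside ``{a, c, g, t, n}`` raise ``ValueError``
    naming the offending 1-based position.  An empty file (no records) is an
    error; a record with an empty sequence is accepted with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [NucleotideSequence(id=rec.id, bases=str(rec.seq)) for rec in records]


def write_fasta(path, sequences: list[NucleotideSequence], width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


def map_sequence(
    seq: NucleotideSequence, scheme: str = "proposed_quaternary"
) -> ComplexSignal:
    """Map a DNA sequence to a complex signal under a quaternary code.

    Ambiguous ``n`` bases map to ``0`` (with a warning): this keeps the
    signal aligned with sequence coordinates without biasing any base
    channel.
    """
    key = resolve_scheme(scheme)
    table = MAPPING_SCHEMES[key]
    lut = np.zeros(256, dtype=np.complex128)
    for base, value in table.items():
        lut[ord(base)] = value
    raw = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
    if raw.size and np.any(raw == ord("n")):
        warnings.warn(
            f"sequence {seq.id!r} contains 'n' bases; mapped to 0", stacklevel=2
        )
    return ComplexSignal(values=lut[raw], scheme=key)


def inverse_map(signal: ComplexSignal) -> str:
    """Invert a complex signal back to its base string.

    Only defined for the bijective single-sequence codes; a value of 0
    (an ambiguous base) becomes ``n``.
    """
    table = MAPPING_SCHEMES[resolve_scheme(signal.scheme)]
    inverse = {v: k for k, v in table.items()}
    out = []
    for v in signal.values:
        if v == 0:
            out.append("n")
            continue
        try:
            out.append(inverse[complex(v)])
        except KeyError:
            raise ValueError(f"value {v} is not in the {signal.scheme} code") from None
    return "".join(out)


def voss_indicators(seq: NucleotideSequence) -> IndicatorSet:
    """Build the four Voss binary indicator sequences.

    For pure ``{a, c, g, t}`` input the indicators sum to one at every
    position.  ``n`` bases yield all-zero columns and a warning.
    """
    raw = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
    if raw.size and np.any(raw == ord("n")):
        warnings.warn(
            f"sequence {seq.id!r} contains 'n' bases; indicator columns are all-zero "
            "there",
            stacklevel=2,
        )
    return IndicatorSet(
        x_a=(raw == ord("a")).astype(np.uint8),
        x_c=(raw == ord("c")).astype(np.uint8),
        x_g=(raw == ord("g")).astype(np.uint8),
        x_t=(raw == ord("t")).astype(np.uint8),
    )
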