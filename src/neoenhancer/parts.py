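"""Default cassette parts.

The minimal promoter, Kozak context, P2A linker and payload ORFs shipped
here are clearly-labelled placeholder sequences: the promoter is a generic
TATA-containing synthetic minimal promoter and the ORFs are arbitrary valid
stand-ins generated deterministically.  Only the P2A linker is the standard
porcine teschovirus 2A nucleotide sequence.  Every default is overridable;
the design engine's contracts are sequence-agnostic.

All defaults are screened so they cannot create a GGAA/TTCC run of >= 3
units or an exact ``ATTWGTCACGGT`` match at any junction.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass

__all__ = ["Part", "default_parts"]

ROLES = ("enhancer", "spacer", "min_promoter", "kozak", "orf", "linker")

_STOPS = {"TAA", "TAG", "TGA"}
_FORBIDDEN = re.compile(
    r"(?:GGAA){3}|(?:TTCC){3}|GTCACGGT|ACCGTGAC"
)


@dataclass(frozen=True)
class Part:
    """A named cassette building block with a fixed role."""

    name: str
    role: str
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown part role {self.role!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.role != "spacer" and not seq:
            raise ValueError(f"part {self.name!r} ({self.role}) must have a sequence")
        if seq and not set(seq) <= set("ACGT"):
            raise ValueError(f"part {self.name!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.sequence)


def _clean(seq: str) -> bool:
    return _FORBIDDEN.search(seq) is None


def _make_orf(name: str, n_codons: int, seed: int, terminal_stop: bool) -> Part:
    """Deterministic placeholder ORF: ATG + random sense codons (+ stop)."""
    rng = random.Random(seed)
    bases = "ACGT"
    codons = [
        a + b + c
        for a in bases for b in bases for c in bases
        if a + b + c not in _STOPS
    ]
    while True:
        body = "".join(rng.choice(codons) for _ in range(n_codons))
        seq = "ATG" + body + ("TAA" if terminal_stop else "")
        if _clean(seq):
            return Part(name=name, role="orf", sequence=seq)


# Synthetic TATA-box minimal promoter placeholder (not the published YB-TATA
# sequence, which is not printed in accessible form).
_YB_TATA = Part(
    name="YB_TATA",
    role="min_promoter",
    sequence="GCTAGCAGGTCGTCTATAAAAGGCGTGCAGTCGAGTCCTGCAGTACTGTGAACCGTCAGATCGC",
)

_KOZAK = Part(name="kozak", role="kozak", sequence="GCCACC")

# Standard P2A (porcine teschovirus-1 2A), 66 nt, frame-neutral.
_P2A = Part(
    name="P2A",
    role="linker",
    sequence=(
        "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
    ),
)

assert _clean(_YB_TATA.sequence) and _clean(_P2A.sequence)


def default_parts() -> dict[str, Part]:
    """Default part library keyed by short name.

    Payload stand-ins: ``HSV_TK`` and ``IL15`` are stopless internal ORFs;
    ``LUC`` and ``XCL1`` carry the terminal stop and close a cassette.
    """
    return {
        "YB_TATA": _YB_TATA,
        "kozak": _KOZAK,
        "P2A": _P2A,
        "HSV_TK": _make_orf("HSV_TK", 40, seed=101, terminal_stop=False),
        "LUC": _make_orf("LUC", 50, seed=202, terminal_stop=True),
        "IL15": _make_orf("IL15", 38, seed=303, terminal_stop=False),
        "XCL1": _make_orf("XCL1", 30, seed=404, terminal_stop=True),
    }
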