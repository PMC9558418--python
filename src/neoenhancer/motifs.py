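"""IUPAC consensus matching, mismatch scanning and minimal-edit repair.

The default consensus is the ``ATTWGTCACGGT`` fusion-TF binding motif
(W = A or T), with the invariant 3' core ``GTCACGGT``.  Matching is plain
per-position set membership: the score of a window is its mismatch count,
not a PWM log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .msat import revcomp

__all__ = [
    "IUPAC",
    "IupacConsensus",
    "MotifMatch",
    "match_consensus",
    "repair_to_consensus",
    "count_exact_matches",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

P3F1_CONSENSUS = "ATTWGTCACGGT"
P3F1_CORE = "GTCACGGT"


@dataclass(frozen=True)
class IupacConsensus:
    """A degenerate DNA consensus with per-position allowed base sets."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 4:
            raise ValueError("consensus must be at least 4 bases long")
        bad = [c for c in pat if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in consensus: {bad}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def expansion(self) -> tuple[frozenset[str], ...]:
        return tuple(IUPAC[c] for c in self.pattern)

    def concrete(self) -> str:
        """Resolve degenerate positions to the alphabetically first allowed base."""
        return "".join(min(IUPAC[c]) for c in self.pattern)

    def mismatches(self, window: str) -> int:
        return sum(b not in allowed for b, allowed in zip(window, self.expansion))


@dataclass(frozen=True)
class MotifMatch:
    """A consensus occurrence: forward-strand offset, strand, mismatch count.

    ``matched_seq`` is the window read in consensus orientation (i.e. the
    reverse complement of the forward window for minus-strand matches).
    """

    pos: int
    strand: str
    mismatches: int
    matched_seq: str


def _as_consensus(consensus: str | IupacConsensus) -> IupacConsensus:
    return consensus if isinstance(consensus, IupacConsensus) else IupacConsensus(consensus)


def match_consensus(
    seq: str,
    consensus: str | IupacConsensus,
    max_mismatch: int = 0,
) -> list[MotifMatch]:
    """Exhaustive both-strand window scan for consensus (near-)matches.

    Every window with at most ``max_mismatch`` incompatible positions is
    reported; overlapping windows are reported individually.  Output is
    sorted by position then strand (``+`` before ``-``).  A consensus longer
    than the sequence yields an empty list.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    cons = _as_consensus(consensus)
    seq = seq.upper()
    k = len(cons)
    out: list[MotifMatch] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = cons.mismatches(window)
        if mm <= max_mismatch:
            out.append(MotifMatch(pos=i, strand="+", mismatches=mm, matched_seq=window))
        window_rc = revcomp(window)
        mm_rc = cons.mismatches(window_rc)
        if mm_rc <= max_mismatch:
            out.append(MotifMatch(pos=i, strand="-", mismatches=mm_rc, matched_seq=window_rc))
    out.sort(key=lambda m: (m.pos, m.strand))
    return out


def repair_to_consensus(
    seq: str,
    match: MotifMatch,
    consensus: str | IupacConsensus,
) -> tuple[str, int]:
    """Minimally edit the matched window to a 0-mismatch consensus match.

    Positions already compatible with the consensus (including degenerate
    positions) are untouched; positions needing change take the
    alphabetically first allowed base.  Returns the edited sequence and the
    substitution count, which equals the window's prior mismatch count.
    """
    cons = _as_consensus(consensus)
    seq = seq.upper()
    k = len(cons)
    if match.pos < 0 or match.pos + k > len(seq):
        raise ValueError(
            f"match window [{match.pos}, {match.pos + k}) out of bounds for "
            f"sequence of length {len(seq)}"
        )
    window = seq[match.pos : match.pos + k]
    oriented = revcomp(window) if match.strand == "-" else window
    repaired = []
    edits = 0
    for base, allowed in zip(oriented, cons.expansion):
        if base in allowed:
            repaired.append(base)
        else:
            repaired.append(min(allowed))
            edits += 1
    fixed = "".join(repaired)
    if match.strand == "-":
        fixed = revcomp(fixed)
    return seq[: match.pos] + fixed + seq[match.pos + k :], edits


def count_exact_matches(seq: str, consensus: str | IupacConsensus) -> int:
    """Number of 0-mismatch consensus windows over both strands.

    Overlapping occurrences count individually.
    """
    return len(match_consensus(seq, consensus, max_mismatch=0))
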