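"""Maximal tandem-repeat (microsatellite) scanning.

Finds every maximal run of a short repeat unit (default ``GGAA``) in DNA
sequence, on one or both strands, subject to a minimum number of complete
unit copies.  Coordinates are 0-based half-open throughout; minus-strand
hits are reported in forward coordinates with strand ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "RepeatUnit",
    "MicrosatelliteHit",
    "revcomp",
    "scan_sequence",
    "scan_genome",
    "write_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_DNA = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _is_primitive(unit: str) -> bool:
    # A unit is primitive when it is not a whole-number power of a shorter
    # string, e.g. "GGAA" is primitive but "GAGA" = "GA" * 2 is not.
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit[:p] * (n // p) == unit:
            return False
    return True


@dataclass(frozen=True)
class RepeatUnit:
    """A repeat unit plus the minimum number of consecutive copies.

    The default (``GGAA`` with ``min_repeats=4``) is the conventional
    microsatellite definition used throughout this package.
    """

    unit: str = "GGAA"
    min_repeats: int = 4

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("repeat unit must be non-empty")
        if not set(self.unit) <= _DNA:
            raise ValueError(f"repeat unit must be over ACGT, got {self.unit!r}")
        if len(self.unit) < 2:
            raise ValueError("repeat unit must have length >= 2")
        if not _is_primitive(self.unit):
            raise ValueError(f"repeat unit {self.unit!r} is not primitive")
        if self.min_repeats < 1:
            raise ValueError("min_repeats must be >= 1")


@dataclass(frozen=True, order=True)
class MicrosatelliteHit:
    """One maximal repeat run.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``end - start == repeat_count * len(unit)`` always holds.
    """

    chrom: str
    start: int
    end: int
    strand: str
    unit: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.repeat_count * len(self.unit):
            raise ValueError("hit span inconsistent with repeat_count * unit length")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _occurrences(seq: str, unit: str) -> list[int]:
    """All start offsets of ``unit`` in ``seq`` (overlaps allowed)."""
    out = []
    i = seq.find(unit)
    while i != -1:
        out.append(i)
        i = seq.find(unit, i + 1)
    return out


def _chains(positions: list[int], step: int) -> Iterator[tuple[int, int]]:
    """Group unit occurrences into maximal same-phase chains.

    Yields (start, count) for each maximal arithmetic chain with spacing
    exactly ``step``.
    """
    pos_set = set(positions)
    for p in positions:
        if p - step in pos_set:
            continue  # not a chain head
        count = 1
        q = p
        while q + step in pos_set:
            q += step
            count += 1
        yield p, count


def scan_sequence(
    seq: str,
    spec: RepeatUnit = RepeatUnit(),
    *,
    chrom: str = "",
    strand: str = "+",
) -> list[MicrosatelliteHit]:
    """Scan one strand of one sequence for maximal repeat runs.

    Only complete unit copies count; partial copies at the flanks do not
    extend a hit.  Characters outside ACGT break runs.  When a self-
    overlapping unit admits overlapping candidate runs, the run with more
    complete copies wins (leftmost on ties) and overlapping losers are
    discarded, so reported hits never overlap.
    """
    seq = seq.upper()
    unit = spec.unit
    step = len(unit)
    candidates = sorted(
        _chains(_occurrences(seq, unit), step),
        key=lambda pc: (-pc[1], pc[0]),
    )
    taken: list[tuple[int, int]] = []
    hits: list[MicrosatelliteHit] = []
    for start, count in candidates:
        if count < spec.min_repeats:
            continue
        end = start + count * step
        if any(start < t_end and t_start < end for t_start, t_end in taken):
            continue
        taken.append((start, end))
        hits.append(
            MicrosatelliteHit(
                chrom=chrom, start=start, end=end, strand=strand,
                unit=unit, repeat_count=count,
            )
        )
    hits.sort(key=lambda h: h.start)
    return hits


def _iter_fasta(fasta: str | Path | Mapping[str, str]) -> Iterator[tuple[str, str]]:
    if isinstance(fasta, Mapping):
        yield from fasta.items()
        return
    from Bio import SeqIO

    for rec in SeqIO.parse(str(fasta), "fasta"):
        yield rec.id, str(rec.seq)


def scan_genome(
    fasta: str | Path | Mapping[str, str],
    spec: RepeatUnit = RepeatUnit(),
    *,
    both_strands: bool = True,
    respect_softmask: bool = False,
) -> list[MicrosatelliteHit]:
    """Scan a FASTA file (or dict of sequences) for repeat runs.

    Plus-strand hits come from scanning ``spec.unit`` directly; minus-strand
    hits from scanning ``revcomp(spec.unit)`` on the forward sequence and are
    reported with strand ``-`` in forward coordinates.  Chromosomes are
    processed one at a time (memory bounded by the largest record).

    With ``respect_softmask`` lowercase (soft-masked) bases break runs;
    by default they are uppercased and treated as ordinary sequence.
    """
    unit_rc = revcomp(spec.unit)
    seen: set[str] = set()
    hits: list[MicrosatelliteHit] = []
    for name, seq in _iter_fasta(fasta):
        if name in seen:
            raise ValueError(f"duplicate chromosome name in FASTA: {name!r}")
        seen.add(name)
        if respect_softmask:
            # masked bases must terminate runs: blank them before uppercasing
            seq = "".join(c if c.isupper() else "n" for c in seq)
        chrom_hits = scan_sequence(seq, spec, chrom=name, strand="+")
        if both_strands and unit_rc != spec.unit:
            minus_spec = replace(spec, unit=unit_rc)
            for h in scan_sequence(seq, minus_spec, chrom=name, strand="-"):
                chrom_hits.append(
                    MicrosatelliteHit(
                        chrom=name, start=h.start, end=h.end, strand="-",
                        unit=spec.unit, repeat_count=h.repeat_count,
                    )
                )
        chrom_hits.sort(key=lambda h: (h.start, h.strand))
        hits.extend(chrom_hits)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def write_bed(hits: Iterable[MicrosatelliteHit], path: str | Path) -> None:
    """Write hits as BED6: name ``<unit>x<count>``, score = repeat count."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.unit}x{h.repeat_count}"
                f"\t{h.repeat_count}\t{h.strand}\n"
            )


def read_bed_hits(path: str | Path, unit: str = "GGAA") -> list[MicrosatelliteHit]:
    """Read hits back from a BED6 file produced by :func:`write_bed`."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            u, _, count = name.rpartition("x")
            hits.append(
                MicrosatelliteHit(
                    chrom=chrom, start=int(start), end=int(end), strand=strand,
                    unit=u or unit, repeat_count=int(count),
                )
            )
    return hits
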