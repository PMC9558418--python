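"""Synthetic expression-cassette assembly and validation.

Two architectures are supported:

* GGAA-repeat cassettes — ``[GGAA x n][spacer][minimal promoter][kozak]
  [ORF1][P2A][ORF2]`` — where the enhancer block's repeat count is the
  design parameter (17/21/25-repeat actives, 0-repeat control).
* Consensus-motif cassettes — a base enhancer segment whose best near-match
  of the ``ATTWGTCACGGT`` consensus can be repaired to an exact match, with
  additional exact motif copies multimerized 5' of the base.

Every design passes a junction guard: re-scanning the assembled sequence
must reproduce the design parameters exactly (one repeat run of the
requested length, the expected exact-motif count), so part junctions cannot
silently create or extend functional elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .motifs import (
    IupacConsensus,
    MotifMatch,
    P3F1_CONSENSUS,
    count_exact_matches,
    match_consensus,
    repair_to_consensus,
)
from .msat import MicrosatelliteHit, RepeatUnit, scan_genome
from .parts import Part, default_parts

__all__ = [
    "Part",
    "CassetteDesign",
    "EnhancerScore",
    "JunctionGuardError",
    "FrameError",
    "ValidationReport",
    "design_ggaa_cassette",
    "design_p3f1_cassette",
    "validate_design",
    "score_enhancer",
    "write_genbank",
    "write_fasta",
]

MIN_REPEAT_THRESHOLD = 4
OPTIMAL_BAND = (15, 25)


class JunctionGuardError(ValueError):
    """Raised when part junctions create or extend an unintended element."""


class FrameError(ValueError):
    """Raised when the payload reading frame is broken at design time."""


@dataclass(frozen=True)
class CassetteDesign:
    """An assembled cassette: ordered parts, sequence, tiling features."""

    parts: tuple[Part, ...]
    assembled: str
    features: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_parts(cls, parts: Sequence[Part]) -> "CassetteDesign":
        parts = tuple(p for p in parts if p.sequence)
        assembled = "".join(p.sequence for p in parts)
        features = []
        offset = 0
        for p in parts:
            features.append((p.name, offset, offset + len(p.sequence)))
            offset += len(p.sequence)
        return cls(parts=parts, assembled=assembled, features=tuple(features))

    def part_interval(self, name: str) -> tuple[int, int]:
        for fname, s, e in self.features:
            if fname == name:
                return s, e
        raise KeyError(name)


@dataclass(frozen=True)
class EnhancerScore:
    """Repeat-count scoring against the binding-length preference band."""

    repeat_count: int
    in_optimal_band: bool
    meets_min_threshold: bool
    band: tuple[int, int] = OPTIMAL_BAND


def score_enhancer(repeat_count: int) -> EnhancerScore:
    """Score a GGAA-repeat count: >= 4 is functional, 15-25 is optimal."""
    if repeat_count < 0:
        raise ValueError("repeat_count must be >= 0")
    lo, hi = OPTIMAL_BAND
    return EnhancerScore(
        repeat_count=repeat_count,
        in_optimal_band=lo <= repeat_count <= hi,
        meets_min_threshold=repeat_count >= MIN_REPEAT_THRESHOLD,
    )


def _default(part: Part | None, key: str) -> Part:
    return part if part is not None else default_parts()[key]


def _default_payloads(payloads: Sequence[Part] | None) -> list[Part]:
    if payloads is not None:
        return list(payloads)
    lib = default_parts()
    return [lib["HSV_TK"], lib["LUC"]]


def _check_frame_parts(payloads: Sequence[Part], linker: Part) -> None:
    for p in payloads:
        if not p.sequence.startswith("ATG"):
            raise FrameError(f"payload ORF {p.name!r} does not start with ATG")
        if len(p.sequence) % 3:
            raise FrameError(f"payload ORF {p.name!r} length not divisible by 3")
    if len(linker.sequence) % 3:
        raise FrameError(f"linker {linker.name!r} length not divisible by 3")


def _payload_chain(payloads: Sequence[Part], linker: Part) -> list[Part]:
    chain: list[Part] = []
    for i, p in enumerate(payloads):
        if i:
            chain.append(linker)
        chain.append(p)
    return chain


def _scan_assembly(assembled: str, unit: str, min_repeats: int) -> list[MicrosatelliteHit]:
    spec = RepeatUnit(unit=unit, min_repeats=min_repeats)
    return scan_genome({"cassette": assembled}, spec, both_strands=True)


def _locate(design_features, pos: int) -> str:
    for name, s, e in design_features:
        if s <= pos < e:
            return name
    return "?"


def design_ggaa_cassette(
    n_repeats: int,
    min_promoter: Part | None = None,
    payloads: Sequence[Part] | None = None,
    linker: Part | None = None,
    kozak: Part | None = None,
    spacer: str = "",
    unit: str = "GGAA",
    scan_min_repeats: int = MIN_REPEAT_THRESHOLD,
    auto_spacer: bool = True,
) -> CassetteDesign:
    """Assemble a repeat-enhancer cassette with ``n_repeats`` unit copies.

    The enhancer block sits directly upstream of the minimal promoter
    (0-bp spacer by default).  The junction guard re-scans the assembly:
    it must contain exactly one repeat run of length ``n_repeats`` (none
    when below the scanner threshold).  If a junction extends the run and
    ``auto_spacer`` is set, a 1-bp neutral spacer is inserted after the
    enhancer block; otherwise a :class:`JunctionGuardError` is raised.
    """
    if n_repeats < 0:
        raise ValueError("n_repeats must be >= 0")
    promoter = _default(min_promoter, "YB_TATA")
    kozak_p = _default(kozak, "kozak")
    linker_p = _default(linker, "P2A")
    payload_list = _default_payloads(payloads)
    if not payload_list:
        raise ValueError("at least one payload ORF is required")
    _check_frame_parts(payload_list, linker_p)

    def build(extra_spacer: str) -> CassetteDesign:
        parts: list[Part] = []
        if n_repeats > 0:
            parts.append(Part(f"{unit}x{n_repeats}", "enhancer", unit * n_repeats))
        if spacer or extra_spacer:
            parts.append(Part("spacer", "spacer", extra_spacer + spacer))
        parts.append(promoter)
        parts.append(kozak_p)
        parts.extend(_payload_chain(payload_list, linker_p))
        return CassetteDesign.from_parts(parts)

    def guard_ok(design: CassetteDesign) -> tuple[bool, str]:
        hits = _scan_assembly(design.assembled, unit, scan_min_repeats)
        if n_repeats >= scan_min_repeats:
            expect_one = (
                len(hits) == 1
                and hits[0].repeat_count == n_repeats
                and hits[0].strand == "+"
            )
            if expect_one:
                return True, ""
        elif not hits:
            return True, ""
        detail = "; ".join(
            f"{h.unit}x{h.repeat_count} at [{h.start},{h.end}) strand {h.strand} "
            f"near part {_locate(design.features, h.start)!r}"
            for h in hits
        ) or "expected run missing"
        return False, detail

    design = build("")
    ok, detail = guard_ok(design)
    if ok:
        return design
    if auto_spacer and n_repeats > 0:
        for base in "TCGA":
            candidate = build(base)
            ok, _ = guard_ok(candidate)
            if ok:
                return candidate
    raise JunctionGuardError(
        f"junction guard failed for {n_repeats}-repeat cassette: {detail}"
    )


def design_p3f1_cassette(
    base_enhancer: str,
    repair: bool = True,
    extra_motifs: int = 0,
    motif_spacer: Part | None = None,
    min_promoter: Part | None = None,
    payloads: Sequence[Part] | None = None,
    linker: Part | None = None,
    kozak: Part | None = None,
    consensus: str | IupacConsensus = P3F1_CONSENSUS,
    max_mismatch: int = 3,
    spacer: str = "",
    unit: str = "GGAA",
    scan_min_repeats: int = MIN_REPEAT_THRESHOLD,
) -> CassetteDesign:
    """Assemble a consensus-motif enhancer cassette.

    With ``repair`` the best near-match of the consensus in the base
    enhancer (fewest mismatches, leftmost tie-break) is edited to an exact
    match.  ``extra_motifs`` exact consensus copies, separated by
    ``motif_spacer``, are appended 5' of the base enhancer.  The junction
    guard requires the assembly's exact-motif count to equal that of the
    processed base plus ``extra_motifs``, and that no repeat run at or above
    the scanner threshold is created.
    """
    if extra_motifs < 0:
        raise ValueError("extra_motifs must be >= 0")
    cons = consensus if isinstance(consensus, IupacConsensus) else IupacConsensus(consensus)
    base = base_enhancer.upper()
    if repair:
        matches = match_consensus(base, cons, max_mismatch=max_mismatch)
        if not matches:
            raise ValueError(
                f"repair requested but no consensus match within "
                f"{max_mismatch} mismatches found in base enhancer"
            )
        best = min(matches, key=lambda m: (m.mismatches, m.pos, m.strand))
        base, _ = repair_to_consensus(base, best, cons)

    promoter = _default(min_promoter, "YB_TATA")
    kozak_p = _default(kozak, "kozak")
    linker_p = _default(linker, "P2A")
    payload_list = _default_payloads(payloads)
    _check_frame_parts(payload_list, linker_p)
    spacer_p = motif_spacer if motif_spacer is not None else Part(
        "motif_spacer", "spacer", "CTGACTGCTA"
    )
    motif_seq = cons.concrete()

    parts: list[Part] = []
    for i in range(extra_motifs):
        parts.append(Part(f"motif_{i + 1}", "enhancer", motif_seq))
        parts.append(Part(f"{spacer_p.name}_{i + 1}", "spacer", spacer_p.sequence))
    parts.append(Part("base_enhancer", "enhancer", base))
    if spacer:
        parts.append(Part("spacer", "spacer", spacer))
    parts.append(promoter)
    parts.append(kozak_p)
    parts.extend(_payload_chain(payload_list, linker_p))
    design = CassetteDesign.from_parts(parts)

    expected = count_exact_matches(base, cons) + extra_motifs
    observed = count_exact_matches(design.assembled, cons)
    if observed != expected:
        raise JunctionGuardError(
            f"junction guard failed: expected {expected} exact motif matches "
            f"in assembly, found {observed}"
        )
    run_hits = _scan_assembly(design.assembled, unit, scan_min_repeats)
    base_hits = _scan_assembly(base, unit, scan_min_repeats)
    if len(run_hits) != len(base_hits):
        raise JunctionGuardError(
            f"junction guard failed: assembly contains {len(run_hits)} "
            f"{unit}-run(s) >= {scan_min_repeats} but base enhancer has {len(base_hits)}"
        )
    return design


@dataclass
class ValidationReport:
    msat_hits: list[tuple[int, int, str, int]]
    exact_motif_count: int
    frame_ok: bool
    frame_message: str
    features_tile_ok: bool
    unintended_motifs: dict[str, int]

    @property
    def passed(self) -> bool:
        return self.frame_ok and self.features_tile_ok

    def to_dict(self) -> dict:
        return {
            "msat_hits": [list(h) for h in self.msat_hits],
            "exact_motif_count": self.exact_motif_count,
            "frame_ok": self.frame_ok,
            "frame_message": self.frame_message,
            "features_tile_ok": self.features_tile_ok,
            "unintended_motifs": dict(self.unintended_motifs),
            "passed": self.passed,
        }


def _check_frame(design: CassetteDesign) -> tuple[bool, str]:
    """Verify one continuous reading frame across ORFs and linkers.

    Returns (ok, message); the message carries the offending assembly
    coordinate on failure.
    """
    cds_parts = [
        (p, s, e)
        for p, (name, s, e) in zip(design.parts, design.features)
        if p.role in ("orf", "linker")
    ]
    if not cds_parts:
        return False, "no ORF parts in design"
    offset = 0
    for p, s, e in cds_parts:
        if offset % 3:
            return False, (
                f"part {p.name!r} starts out of frame at assembly coordinate {s}"
            )
        if p.role == "orf" and not p.sequence.startswith("ATG"):
            return False, f"ORF {p.name!r} at assembly coordinate {s} lacks ATG start"
        offset += len(p.sequence)
    if offset % 3:
        last = cds_parts[-1]
        return False, (
            f"CDS length {offset} not divisible by 3; frame breaks at "
            f"assembly coordinate {last[2]}"
        )
    cds = "".join(p.sequence for p, _, _ in cds_parts)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    stops = {"TAA", "TAG", "TGA"}
    for i, codon in enumerate(codons[:-1]):
        if codon in stops:
            coord = cds_parts[0][1] + 3 * i
            return False, f"internal stop codon at assembly coordinate {coord}"
    if codons[-1] not in stops:
        return False, "missing terminal stop codon"
    return True, "single reading frame with terminal stop only"


def validate_design(
    design: CassetteDesign,
    consensus: str | IupacConsensus = P3F1_CONSENSUS,
    repeat_spec: RepeatUnit = RepeatUnit(),
) -> ValidationReport:
    """Machine-readable design report: repeat runs, motif dose, frame, tiling."""
    hits = _scan_assembly(design.assembled, repeat_spec.unit, repeat_spec.min_repeats)
    frame_ok, frame_msg = _check_frame(design)

    tiling_ok = True
    offset = 0
    for name, s, e in design.features:
        if s != offset or e <= s:
            tiling_ok = False
            break
        offset = e
    if offset != len(design.assembled):
        tiling_ok = False

    # motifs outside declared enhancer parts are unintended
    enhancer_ranges = [
        (s, e)
        for p, (name, s, e) in zip(design.parts, design.features)
        if p.role == "enhancer"
    ]
    unintended: dict[str, int] = {}
    for m in match_consensus(design.assembled, consensus, max_mismatch=0):
        k = len(consensus.pattern if isinstance(consensus, IupacConsensus) else consensus)
        if not any(s <= m.pos and m.pos + k <= e for s, e in enhancer_ranges):
            unintended["motif"] = unintended.get("motif", 0) + 1
    for h in hits:
        if not any(s <= h.start and h.end <= e for s, e in enhancer_ranges):
            unintended["msat"] = unintended.get("msat", 0) + 1

    return ValidationReport(
        msat_hits=[(h.start, h.end, h.strand, h.repeat_count) for h in hits],
        exact_motif_count=count_exact_matches(design.assembled, consensus),
        frame_ok=frame_ok,
        frame_message=frame_msg,
        features_tile_ok=tiling_ok,
        unintended_motifs=unintended,
    )


def write_fasta(design: CassetteDesign, path: str | Path, name: str = "cassette") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        seq = design.assembled
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_genbank(design: CassetteDesign, path: str | Path, name: str = "cassette") -> None:
    """Write a GenBank flat file with one feature per part."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rec = SeqRecord(Seq(design.assembled), id=name[:16], name=name[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    for part, (fname, s, e) in zip(design.parts, design.features):
        rec.features.append(
            SeqFeature(
                FeatureLocation(s, e),
                type="misc_feature",
                qualifiers={"label": [fname], "note": [f"role={part.role}"]},
            )
        )
    SeqIO.write(rec, str(path), "genbank")
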