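"""Peak-overlap flagging, genomic-context classification and census summary.

Each microsatellite hit is (a) flagged bound when it overlaps a peak by at
least ``min_overlap`` bp, (b) classified into exactly one genomic context
(promoter-proximal, exonic, intronic or intergenic, with that precedence),
and (c) given a distance to the nearest TSS.  The promoter window is
strand-aware: by default 1,000 bp upstream to 100 bp downstream of the TSS
in gene orientation.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .msat import MicrosatelliteHit

__all__ = [
    "Peak",
    "GeneModel",
    "PromoterWindow",
    "AnnotatedMsat",
    "CensusSummary",
    "flag_bound",
    "classify_context",
    "annotate_msats",
    "summarize_census",
]

CONTEXTS = ("promoter_proximal", "exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak must have start < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class GeneModel:
    """A flattened gene: one TSS per record, exons ordered and disjoint.

    ``start``/``end`` are the 0-based half-open gene span.  The TSS is the
    span start on ``+`` and ``end - 1`` (the last spanned base) on ``-``.
    Multi-TSS genes must be pre-flattened to one record per TSS.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError("gene span must be non-empty")
        prev_end = self.start
        for (s, e) in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise ValueError(
                    f"exons of {self.gene_id} must be ordered, disjoint and within the span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware promoter window around the TSS (both extents >= 0)."""

    upstream: int = 1000
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be >= 0")

    def genome_interval(self, gene: GeneModel) -> tuple[int, int]:
        """Half-open genome-coordinate interval covered by the window."""
        t = gene.tss
        if gene.strand == "+":
            return t - self.upstream, t + self.downstream + 1
        return t - self.downstream, t + self.upstream + 1


@dataclass(frozen=True)
class AnnotatedMsat:
    hit: MicrosatelliteHit
    bound: bool
    context: str
    interval_bp: int | None
    signed_tss_offset: int | None
    nearest_gene: str

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass
class CensusSummary:
    n_total: int
    n_bound: int
    fraction_by_context: dict[str, float] = field(default_factory=dict)
    n_promoter_proximal: int = 0
    min_interval_bp: int | None = None
    min_interval_gene: str | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_bound": self.n_bound,
            "fraction_by_context": dict(self.fraction_by_context),
            "n_promoter_proximal": self.n_promoter_proximal,
            "min_interval_bp": self.min_interval_bp,
            "min_interval_gene": self.min_interval_gene,
        }


def flag_bound(
    hits: Sequence[MicrosatelliteHit],
    peaks: Iterable[Peak],
    min_overlap: int = 1,
) -> list[bool]:
    """Flag each hit bound iff it overlaps any peak by >= ``min_overlap`` bp.

    Sweep-line per chromosome: hits and peaks are sorted by start and a
    moving window of active peaks is intersected with each hit.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    peaks_by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        peaks_by_chrom[p.chrom].append(p)
    for plist in peaks_by_chrom.values():
        plist.sort(key=lambda p: p.start)

    hit_chroms = {h.chrom for h in hits}
    missing = hit_chroms - set(peaks_by_chrom)
    if missing and peaks_by_chrom:
        warnings.warn(
            f"hits on chromosome(s) {sorted(missing)} have no peaks; flagged unbound",
            stacklevel=2,
        )

    order = sorted(range(len(hits)), key=lambda i: (hits[i].chrom, hits[i].start))
    flags = [False] * len(hits)
    cursor: dict[str, int] = defaultdict(int)
    for i in order:
        h = hits[i]
        plist = peaks_by_chrom.get(h.chrom, [])
        j = cursor[h.chrom]
        # retire peaks that end too early to ever satisfy min_overlap again
        while j < len(plist) and plist[j].end <= h.start + min_overlap - 1:
            j += 1
        cursor[h.chrom] = j
        k = j
        while k < len(plist) and plist[k].start <= h.end - min_overlap:
            p = plist[k]
            if min(h.end, p.end) - max(h.start, p.start) >= min_overlap:
                flags[i] = True
                break
            k += 1
    return flags


def _tss_gap(hit: MicrosatelliteHit, gene: GeneModel) -> int:
    """Bases strictly between the hit edge nearest the TSS and the TSS base.

    Zero when the hit overlaps or abuts the TSS base.
    """
    t = gene.tss
    if hit.end <= t:
        return t - hit.end
    if hit.start > t:
        return hit.start - t - 1
    return 0


def classify_context(
    hit: MicrosatelliteHit,
    genes: Sequence[GeneModel],
    window: PromoterWindow = PromoterWindow(),
    *,
    bound: bool = False,
) -> AnnotatedMsat:
    """Classify one hit against a gene model.

    Precedence: promoter_proximal > exonic > intronic > intergenic.  A hit
    is promoter-proximal when any part of it lies inside any gene's
    strand-aware promoter window.  ``interval_bp`` is the gap to the nearest
    TSS on the same chromosome (``None`` when the chromosome has no genes);
    ``signed_tss_offset`` is negative when the hit sits upstream of that TSS
    in gene orientation.
    """
    same_chrom = [g for g in genes if g.chrom == hit.chrom]
    if not same_chrom:
        return AnnotatedMsat(
            hit=hit, bound=bound, context="intergenic",
            interval_bp=None, signed_tss_offset=None, nearest_gene="",
        )

    nearest = min(same_chrom, key=lambda g: (_tss_gap(hit, g), g.gene_id))
    gap = _tss_gap(hit, nearest)

    if gap == 0:
        signed = 0
    else:
        t = nearest.tss
        hit_is_left = hit.end <= t
        upstream = hit_is_left if nearest.strand == "+" else not hit_is_left
        signed = -gap if upstream else gap

    in_promoter = False
    for g in same_chrom:
        ws, we = window.genome_interval(g)
        if hit.start < we and ws < hit.end:
            in_promoter = True
            break

    if in_promoter:
        context = "promoter_proximal"
    else:
        context = "intergenic"
        for g in same_chrom:
            if not (hit.start < g.end and g.start < hit.end):
                continue
            if any(hit.start < e and s < hit.end for s, e in g.exons):
                context = "exonic"
                break
            context = "intronic"
    return AnnotatedMsat(
        hit=hit, bound=bound, context=context,
        interval_bp=gap, signed_tss_offset=signed, nearest_gene=nearest.gene_id,
    )


def annotate_msats(
    hits: Sequence[MicrosatelliteHit],
    peaks: Iterable[Peak],
    genes: Sequence[GeneModel],
    window: PromoterWindow = PromoterWindow(),
    min_overlap: int = 1,
) -> list[AnnotatedMsat]:
    """Full annotation: bound flags plus context for every hit."""
    flags = flag_bound(hits, peaks, min_overlap=min_overlap)
    return [
        classify_context(h, genes, window, bound=b) for h, b in zip(hits, flags)
    ]


def summarize_census(annotated: Sequence[AnnotatedMsat]) -> CensusSummary:
    """Summarize an annotated hit set the way the bound-msat census is reported.

    Context fractions are computed over bound msats only.  The minimum TSS
    interval is taken over bound, promoter-proximal msats, breaking ties by
    the smallest gene id.  With zero bound msats the fractions are left
    empty (undefined).
    """
    bound = [a for a in annotated if a.bound]
    summary = CensusSummary(n_total=len(annotated), n_bound=len(bound))
    if not bound:
        return summary
    for ctx in CONTEXTS:
        n_ctx = sum(a.context == ctx for a in bound)
        summary.fraction_by_context[ctx] = n_ctx / len(bound)
    promoter = [a for a in bound if a.context == "promoter_proximal"]
    summary.n_promoter_proximal = len(promoter)
    candidates = [a for a in promoter if a.interval_bp is not None]
    if candidates:
        best = min(candidates, key=lambda a: (a.interval_bp, a.nearest_gene))
        summary.min_interval_bp = best.interval_bp
        summary.min_interval_gene = best.nearest_gene
    return summary
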