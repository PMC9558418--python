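"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline input can be generated here with a single integer seed:
a genome with planted repeat runs, a gene annotation that can pin a run
into a requested genomic context, ChIP-like peaks covering a known subset
of runs, a tumor-vs-normal-tissues log2 expression matrix with planted
overexpressed genes, and 3-parameter log-logistic dose-response tables.

Identical (config, seed) pairs give byte-identical outputs.  Accidental
repeat runs arising from the random background are not suppressed; they
are recorded by an exhaustive regex oracle scan so the truth stays exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel, Peak, PromoterWindow
from .msat import MicrosatelliteHit, revcomp

__all__ = [
    "GenomeSpec",
    "GenomeTruth",
    "PlantedRun",
    "LayoutPin",
    "ExpressionTruth",
    "DoseResponseTruth",
    "make_genome",
    "make_annotation",
    "make_peaks",
    "make_expression",
    "make_dose_response",
    "oracle_scan",
    "default_tissue_sizes",
]


# ---------------------------------------------------------------------------
# oracle scan (independent, regex-based; also used by tests)

def oracle_scan(
    seq: str,
    unit: str = "GGAA",
    min_repeats: int = 1,
    chrom: str = "",
) -> list[MicrosatelliteHit]:
    """Brute-force regex scan for maximal runs of ``unit`` on both strands.

    Deliberately independent of :mod:`neoenhancer.msat` (greedy regex vs the
    occurrence-chain scanner) so the two can cross-check each other.
    """
    seq = seq.upper()
    hits = []
    for strand, u in (("+", unit), ("-", revcomp(unit))):
        if strand == "-" and u == unit:
            continue
        pat = re.compile(f"(?:{u}){{{min_repeats},}}")
        for m in pat.finditer(seq):
            count = (m.end() - m.start()) // len(u)
            hits.append(
                MicrosatelliteHit(
                    chrom=chrom, start=m.start(), end=m.end(), strand=strand,
                    unit=unit, repeat_count=count,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# genome

@dataclass(frozen=True)
class PlantedRun:
    chrom: str
    start: int
    repeat_count: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.repeat_count < 1:
            raise ValueError("planted repeat_count must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout: chromosome lengths, GC content, runs to plant."""

    lengths: dict[str, int]
    planted: tuple[PlantedRun, ...] = ()
    gc: float = 0.41
    unit: str = "GGAA"

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")


@dataclass
class GenomeTruth:
    planted_runs: list[MicrosatelliteHit]
    accidental_runs: list[MicrosatelliteHit]
    genome_length: dict[str, int]
    gc_content: float

    @property
    def all_runs(self) -> list[MicrosatelliteHit]:
        runs = self.planted_runs + self.accidental_runs
        runs.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return runs

    def to_dict(self) -> dict:
        def enc(h: MicrosatelliteHit) -> dict:
            return {
                "chrom": h.chrom, "start": h.start, "end": h.end,
                "strand": h.strand, "repeat_count": h.repeat_count,
            }

        return {
            "planted_runs": [enc(h) for h in self.planted_runs],
            "accidental_runs": [enc(h) for h in self.accidental_runs],
            "genome_length": dict(self.genome_length),
            "gc_content": self.gc_content,
        }


def _run_interval(run: PlantedRun, unit_len: int) -> tuple[int, int]:
    return run.start, run.start + run.repeat_count * unit_len


def make_genome(spec: GenomeSpec, seed: int) -> tuple[dict[str, str], GenomeTruth]:
    """Generate i.i.d.-background chromosomes with planted repeat runs.

    Planted runs are written verbatim at their coordinates (minus-strand
    runs as the reverse complement of the unit on the forward strand).  The
    single flanking base on each side of a planted run is forced to a
    non-extending base so the planted repeat count is exact; everything the
    background creates by chance is recorded as an accidental run via
    :func:`oracle_scan`.
    """
    unit = spec.unit
    L = len(unit)
    by_chrom: dict[str, list[PlantedRun]] = {}
    for run in spec.planted:
        if run.chrom not in spec.lengths:
            raise ValueError(f"planted run on unknown chromosome {run.chrom!r}")
        s, e = _run_interval(run, L)
        if s < 1 or e > spec.lengths[run.chrom] - 1:
            raise ValueError(
                f"planted run {run} exceeds chromosome bounds (1 bp margin required)"
            )
        by_chrom.setdefault(run.chrom, []).append(run)
    for chrom, runs in by_chrom.items():
        runs.sort(key=lambda r: r.start)
        for a, b in zip(runs, runs[1:]):
            if _run_interval(a, L)[1] > _run_interval(b, L)[0]:
                raise ValueError(f"overlapping planted runs on {chrom}: {a} and {b}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    bases = np.array(list("ACGT"))

    sequences: dict[str, str] = {}
    planted_hits: list[MicrosatelliteHit] = []
    for chrom in spec.lengths:  # dict order is part of the config
        n = spec.lengths[chrom]
        arr = rng.choice(bases, size=n, p=p)
        for run in by_chrom.get(chrom, ()):
            s, e = _run_interval(run, L)
            block = unit * run.repeat_count if run.strand == "+" else revcomp(unit) * run.repeat_count
            # rotate minus-strand blocks? no: revcomp(unit * k) == revcomp(unit) * k
            arr[s:e] = list(block)
            # break the run at both flanks so the planted count is maximal-exact:
            # same-phase extension needs block[-1] just before s / block[0] at e
            if arr[s - 1] == block[-1]:
                arr[s - 1] = "C" if block[-1] != "C" else "G"
            if arr[e] == block[0]:
                arr[e] = "C" if block[0] != "C" else "G"
            planted_hits.append(
                MicrosatelliteHit(
                    chrom=chrom, start=s, end=e, strand=run.strand,
                    unit=unit, repeat_count=run.repeat_count,
                )
            )
        sequences[chrom] = "".join(arr)

    # verify + collect accidentals with the independent oracle
    planted_keys = {(h.chrom, h.start, h.end, h.strand) for h in planted_hits}
    accidental: list[MicrosatelliteHit] = []
    for chrom, seq in sequences.items():
        for h in oracle_scan(seq, unit=unit, min_repeats=1, chrom=chrom):
            key = (h.chrom, h.start, h.end, h.strand)
            if key not in planted_keys:
                accidental.append(h)
    found = {
        (h.chrom, h.start, h.end, h.strand)
        for chrom, seq in sequences.items()
        for h in oracle_scan(seq, unit=unit, min_repeats=1, chrom=chrom)
    }
    missing = planted_keys - found
    if missing:  # pragma: no cover - guarded by flank breaking
        raise AssertionError(f"planted runs not recovered by oracle: {missing}")

    planted_hits.sort(key=lambda h: (h.chrom, h.start))
    accidental.sort(key=lambda h: (h.chrom, h.start, h.strand))
    truth = GenomeTruth(
        planted_runs=planted_hits,
        accidental_runs=accidental,
        genome_length=dict(spec.lengths),
        gc_content=spec.gc,
    )
    return sequences, truth


# ---------------------------------------------------------------------------
# annotation

@dataclass(frozen=True)
class LayoutPin:
    """Pin a planted run into a requested genomic context.

    ``gap`` is the TSS interval (bases strictly between run edge and TSS)
    used for promoter pins.
    """

    run: MicrosatelliteHit
    context: str
    gene_strand: str = "+"
    gap: int = 49


def _pin_gene(
    pin: LayoutPin,
    gene_id: str,
    chrom_len: int,
    window: PromoterWindow,
    gene_length: int,
) -> GeneModel:
    run = pin.run
    chrom, strand = run.chrom, pin.gene_strand
    if pin.context == "promoter_proximal":
        if pin.gap >= window.upstream:
            raise ValueError(
                f"unsatisfiable layout: promoter gap {pin.gap} >= upstream "
                f"window {window.upstream}"
            )
        if strand == "+":
            tss = run.end + pin.gap
            start, end = tss, tss + gene_length
        else:
            tss = run.start - pin.gap - 1
            start, end = tss - gene_length + 1, tss + 1
        if start < 0 or end > chrom_len:
            raise ValueError(
                f"unsatisfiable layout: pinned gene {gene_id} exceeds chromosome bounds"
            )
        third = gene_length // 3
        exons = ((start, start + third), (end - third, end))
        return GeneModel(gene_id, chrom, strand, start, end, exons)
    if pin.context == "exonic":
        start = max(0, run.start - 200)
        end = run.end + 200
        if end > chrom_len:
            raise ValueError("unsatisfiable layout: exonic gene exceeds chromosome bounds")
        return GeneModel(gene_id, chrom, strand, start, end, ((start, end),))
    if pin.context == "intronic":
        # TSS far enough from the run that the promoter window cannot claim it
        lead = window.downstream + 150
        start = run.start - lead
        end = run.end + lead
        if start < 0 or end > chrom_len:
            raise ValueError("unsatisfiable layout: intronic gene exceeds chromosome bounds")
        exons = ((start, start + 50), (end - 50, end))
        return GeneModel(gene_id, chrom, strand, start, end, exons)
    if pin.context == "intergenic":
        offset = window.upstream + window.downstream + 5000
        start = run.end + offset
        end = start + gene_length
        if end > chrom_len:
            start = run.start - offset - gene_length
            end = start + gene_length
            if start < 0:
                raise ValueError(
                    "unsatisfiable layout: no room for an intergenic-distance gene"
                )
        return GeneModel(gene_id, chrom, strand, start, end, ((start, end),))
    raise ValueError(f"unknown layout context {pin.context!r}")


def make_annotation(
    n_genes: int,
    genome_length: dict[str, int],
    seed: int,
    layout: tuple[LayoutPin, ...] | list[LayoutPin] = (),
    window: PromoterWindow = PromoterWindow(),
    gene_length: int = 1500,
) -> list[GeneModel]:
    """Generate a gene model with optional context-pinned genes.

    Layout pins are honored first (gene ids ``pin_0001``...), then random
    genes are placed avoiding the pinned neighborhoods and each other.
    The TSS convention is the start of the first exon on ``+`` and the end
    of the last exon on ``-``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    genes: list[GeneModel] = []
    keepout: list[tuple[str, int, int]] = []
    margin = window.upstream + window.downstream + 200
    for i, pin in enumerate(layout):
        g = _pin_gene(pin, f"pin_{i + 1:04d}", genome_length[pin.run.chrom], window, gene_length)
        genes.append(g)
        keepout.append((g.chrom, g.start - margin, g.end + margin))
        keepout.append((pin.run.chrom, pin.run.start - margin, pin.run.end + margin))

    chroms = sorted(genome_length)
    tries = 0
    while len(genes) < n_genes + len(layout) and tries < 200 * n_genes + 100:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        glen = int(rng.integers(gene_length // 2, gene_length * 2))
        if genome_length[chrom] <= glen + 2:
            continue
        start = int(rng.integers(0, genome_length[chrom] - glen))
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        clash = any(
            c == chrom and start < ke and ks < end for c, ks, ke in keepout
        ) or any(g.chrom == chrom and start < g.end and g.start < end for g in genes)
        if clash:
            continue
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False)) if n_exons > 1 else []
        bounds = [0] + [int(c) for c in cuts] + [glen]
        exons = tuple(
            (start + bounds[2 * k], start + bounds[2 * k + 1]) for k in range(n_exons)
        )
        exons = tuple((s, e) for s, e in exons if e > s)
        if not exons or exons[0][0] != start or exons[-1][1] != end:
            continue
        genes.append(
            GeneModel(f"gene_{len(genes) + 1:04d}", chrom, strand, start, end, exons)
        )
    if len(genes) < n_genes + len(layout):
        raise ValueError("could not place requested number of genes; genome too small")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# peaks

def make_peaks(
    truth: GenomeTruth,
    bound_fraction: float,
    jitter: int = 0,
    seed: int = 0,
    extension: int = 50,
    planted_only: bool = False,
) -> tuple[list[Peak], list[MicrosatelliteHit]]:
    """Generate peaks overlapping an exact fraction of the truth's runs.

    Exactly ``round(bound_fraction * n_runs)`` runs receive a covering peak;
    the rest are guaranteed untouched.  The run universe is planted +
    accidental runs, or planted runs only with ``planted_only``.  ``jitter``
    perturbs peak edges by up to +/- jitter bp without breaking either
    guarantee; peaks are clipped where they would reach an unbound run.

    Returns the peak list and the bound runs.
    """
    if not 0 <= bound_fraction <= 1:
        raise ValueError("bound_fraction must be in [0, 1]")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter >= extension:
        raise ValueError(
            f"jitter {jitter} >= guaranteed margin {extension}; overlap contract would break"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    runs = sorted(
        truth.planted_runs, key=lambda h: (h.chrom, h.start, h.strand)
    ) if planted_only else truth.all_runs
    n_bound = round(bound_fraction * len(runs))
    order = rng.permutation(len(runs))
    bound_idx = set(order[:n_bound].tolist())
    bound_runs = [runs[i] for i in sorted(bound_idx)]

    by_chrom: dict[str, list[tuple[int, MicrosatelliteHit]]] = {}
    for i, r in enumerate(runs):
        by_chrom.setdefault(r.chrom, []).append((i, r))
    peaks: list[Peak] = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda ir: ir[1].start)
        for k, (i, r) in enumerate(items):
            if i not in bound_idx:
                continue
            j1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            j2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            start = r.start - extension + j1
            end = r.end + extension + j2
            # clip away from flanking unbound runs
            for kk in range(k - 1, -1, -1):
                ii, rr = items[kk]
                if ii not in bound_idx:
                    start = max(start, rr.end)
                    break
            for kk in range(k + 1, len(items)):
                ii, rr = items[kk]
                if ii not in bound_idx:
                    end = min(end, rr.start)
                    break
            start = max(0, start)
            end = min(truth.genome_length[chrom], end)
            peaks.append(Peak(chrom=chrom, start=start, end=end))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks, bound_runs


# ---------------------------------------------------------------------------
# expression

def default_tissue_sizes(n_tissues: int = 70, total: int = 928) -> dict[str, int]:
    """Split ``total`` normal samples across ``n_tissues`` near-evenly."""
    base, extra = divmod(total, n_tissues)
    return {
        f"tissue_{i + 1:02d}": base + (1 if i < extra else 0)
        for i in range(n_tissues)
    }


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted-overexpression design for the tumor-vs-tissues matrix."""

    planted_genes: dict[str, float] = field(default_factory=dict)
    n_tumor: int = 50
    tissue_sizes: dict[str, int] = field(default_factory=default_tissue_sizes)
    noise_sd: float = 0.5
    n_background_genes: int = 200

    def __post_init__(self) -> None:
        if any(eff <= 0 for eff in self.planted_genes.values()):
            raise ValueError("planted effect sizes must be > 0")
        if self.n_tumor < 1:
            raise ValueError("need at least one tumor sample")
        if any(n < 2 for n in self.tissue_sizes.values()):
            raise ValueError("every tissue needs >= 2 samples for testability")

    @property
    def n_normal(self) -> int:
        return sum(self.tissue_sizes.values())


def make_expression(
    truth: ExpressionTruth,
    seed: int,
    baseline_range: tuple[float, float] = (4.0, 10.0),
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x samples log2 matrix plus sample labels.

    Per-gene baselines are uniform in ``baseline_range``; every sample adds
    i.i.d. Gaussian noise; planted genes get their effect added to tumor
    samples only.  Tumor samples are labelled ``EwS``.
    """
    planted = list(truth.planted_genes)
    if len(set(planted)) != len(planted):
        raise ValueError("duplicate planted gene ids")
    gene_ids = planted + [f"gene_{i + 1:05d}" for i in range(truth.n_background_genes)]
    if len(set(gene_ids)) != len(gene_ids):
        dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    samples = [f"EwS_{i + 1:03d}" for i in range(truth.n_tumor)]
    labels = ["EwS"] * truth.n_tumor
    for tissue, n in truth.tissue_sizes.items():
        samples += [f"{tissue}_{i + 1:03d}" for i in range(n)]
        labels += [tissue] * n

    n_genes, n_samples = len(gene_ids), len(samples)
    baseline = rng.uniform(*baseline_range, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, truth.noise_sd, size=(n_genes, n_samples))
    for i, g in enumerate(planted):
        values[i, : truth.n_tumor] += truth.planted_genes[g]

    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    return matrix, pd.Series(labels, index=samples, name="group")


# ---------------------------------------------------------------------------
# dose-response

@dataclass(frozen=True)
class DoseResponseTruth:
    """Generating parameters for 3-parameter log-logistic curves."""

    d: float = 1.0
    b: float = 1.0
    e: float = 0.4
    doses: tuple[float, ...] = tuple(float(x) for x in np.logspace(-3, 2, 8))
    replicates: int = 4
    noise_sd: float = 0.05  # as a fraction of d

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("ed50 must be > 0")
        if any(x <= 0 for x in self.doses):
            raise ValueError("doses must be strictly positive (vehicle rows are added separately)")
        if list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def make_dose_response(
    truth: DoseResponseTruth,
    seed: int,
    vehicle: bool = True,
) -> pd.DataFrame:
    """Simulate a dose-response table (columns dose, replicate, response).

    response(x) = d / (1 + exp(b (ln x - ln e))) + N(0, noise_sd * d), one
    row per dose x replicate, plus one vehicle row (dose 0, response ~ d)
    per replicate when ``vehicle`` is set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    rows = []
    sd = truth.noise_sd * truth.d
    for rep in range(1, truth.replicates + 1):
        if vehicle:
            resp = truth.d + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append({"dose": 0.0, "replicate": rep, "response": resp})
        for x in truth.doses:
            mean = truth.d / (1.0 + np.exp(truth.b * (np.log(x) - np.log(truth.e))))
            resp = mean + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append({"dose": float(x), "replicate": rep, "response": float(resp)})
    return pd.DataFrame(rows, columns=["dose", "replicate", "response"])
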