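"""Readers and writers for the plain-text formats the pipeline consumes.

GFF3 handling is deliberately minimal: gene records with ``ID=`` plus exon
children with ``Parent=`` — exactly what the flattened one-TSS-per-gene
model requires.  Coordinates are converted between GFF3 1-based inclusive
and the package's 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotate import AnnotatedMsat, GeneModel, Peak

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_annotated_tsv",
    "write_json",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tneoenhancer\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tneoenhancer\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = cols
            a = _attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError(f"gene record without ID: {line!r}")
                genes[gid] = {
                    "chrom": chrom, "strand": strand,
                    "start": int(start) - 1, "end": int(end), "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent in genes:
                    genes[parent]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gid in order:
        rec = genes[gid]
        exons = tuple(sorted(rec["exons"]))
        out.append(
            GeneModel(
                gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                start=rec["start"], end=rec["end"], exons=exons,
            )
        )
    return out


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start)), 1):
            score = int(p.score) if p.score is not None else 0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
            peaks.append(Peak(chrom=chrom, start=start, end=end, score=score))
    return peaks


def write_annotated_tsv(annotated: Iterable[AnnotatedMsat], path: str | Path) -> None:
    rows = [
        {
            "chrom": a.hit.chrom,
            "start": a.hit.start,
            "end": a.hit.end,
            "strand": a.hit.strand,
            "repeat_count": a.hit.repeat_count,
            "bound": a.bound,
            "context": a.context,
            "interval_bp": a.interval_bp,
            "signed_tss_offset": a.signed_tss_offset,
            "nearest_gene": a.nearest_gene,
        }
        for a in annotated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
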