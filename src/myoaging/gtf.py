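"""Transcript models and GTF input/output.

Internally all coordinates are 0-based half-open intervals, which keeps
the interval arithmetic of event detection simple; GTF I/O converts to
and from the format's 1-based inclusive convention (pyranges performs
the shift on read).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pyranges

__all__ = ["TranscriptModel", "parse_gtf", "write_gtf"]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered, non-overlapping set of exons on a strand."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, genomic ascending

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(tuple(map(int, e)) for e in sorted(self.exons))
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s}, {e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons ({s0},{e0}) and ({s1},{e1})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (0-based half-open)."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def exons_gtf(self) -> tuple[tuple[int, int], ...]:
        """Exons in the GTF convention (1-based inclusive)."""
        return tuple((s + 1, e) for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def parse_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features of a GTF into transcript models.

    Only ``exon`` features are used; they must carry ``gene_id`` and
    ``transcript_id`` attributes (Ensembl dialect). An exon feature
    without a transcript_id raises with the offending line number;
    overlapping exons within one transcript also raise.
    """
    path = Path(path)
    gr = pyranges.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    exons = df[df["Feature"] == "exon"].copy()
    if "transcript_id" not in exons.columns or exons["transcript_id"].isna().any() or (
        exons["transcript_id"].astype(str) == ""
    ).any():
        raise ValueError(
            f"exon feature without transcript_id at line {_first_bad_exon_line(path)}"
        )
    models = []
    for tid, sub in exons.groupby("transcript_id", sort=True, observed=True):
        genes = sub["gene_id"].unique()
        models.append(
            TranscriptModel(
                gene_id=str(genes[0]),
                transcript_id=str(tid),
                chrom=str(sub["Chromosome"].iloc[0]),
                strand=str(sub["Strand"].iloc[0]),
                exons=tuple(
                    (int(s), int(e)) for s, e in sorted(zip(sub["Start"], sub["End"]))
                ),
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], source: str = "myoaging") -> str:
    """Serialize transcript models as Ensembl-dialect GTF text."""
    lines = []
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        lines.append(
            "\t".join(
                [m.chrom, source, "transcript", str(m.start + 1), str(m.end),
                 ".", m.strand, ".", attrs]
            )
        )
        for s, e in m.exons_gtf:
            lines.append(
                "\t".join(
                    [m.chrom, source, "exon", str(s), str(e), ".", m.strand, ".", attrs]
                )
            )
    return "\n".join(lines) + "\n"


def _first_bad_exon_line(path: Path) -> int:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) > 8 and fields[2] == "exon" and "transcript_id" not in fields[8]:
            return i
    return -1
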