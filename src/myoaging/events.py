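"""Local alternative-splicing event generation from transcript models.

Events are derived from pairwise comparison of the exon-intron
structures of a gene's transcripts, following the local-event
definitions used by SUPPA: skipped exon (SE), retained intron (RI),
alternative 3'/5' splice site (A3/A5), mutually exclusive exons (MX) and
alternative first/last exon (AF/AL). Events found in several transcript
pairs are merged by coordinates, with their transcript sets unioned.

Inclusion-form conventions (which transcripts count toward the PSI
numerator):

* SE — the exon-containing form;
* RI — the intron-retaining form;
* A3/A5 — the form with the shorter intron (longer exonic sequence);
* MX — the form using the genomically first of the two exclusive exons;
* AF/AL — the form whose alternative terminal exon is distal (farther
  from the shared splice site).

Event identifiers follow the ``.ioe`` style,
``<gene>;<TYPE>:<chrom>:<coordinates>:<strand>`` with 1-based splice-site
coordinates, so that outputs interoperate with existing PSI tooling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations

from .gtf import TranscriptModel

__all__ = ["ASEvent", "EVENT_TYPES", "generate_events", "generate_all_events"]

EVENT_TYPES = ("SE", "RI", "A3", "A5", "AF", "AL", "MX")


@dataclass(frozen=True)
class ASEvent:
    """One local alternative-splicing event.

    ``coords`` is a canonical tuple of 0-based boundary coordinates whose
    layout depends on the event type (see ``_format_coords``); equal
    coordinates define the same event regardless of which transcript
    pair produced it. For AF/AL events ``left_variant`` records whether
    the variable terminal exons sit at the genomic left end.
    """

    event_type: str
    gene_id: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    inclusion_transcripts: frozenset[str]
    total_transcripts: frozenset[str]
    left_variant: bool | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if not self.inclusion_transcripts or not self.total_transcripts:
            raise ValueError("transcript sets must be non-empty")
        if not self.inclusion_transcripts < self.total_transcripts:
            raise ValueError("inclusion set must be a proper subset of total set")
        if self.event_type in ("AF", "AL") and self.left_variant is None:
            raise ValueError("AF/AL events must set left_variant")

    @property
    def exclusion_transcripts(self) -> frozenset[str]:
        return self.total_transcripts - self.inclusion_transcripts

    @property
    def event_id(self) -> str:
        body = _format_coords(self.event_type, self.coords, self.left_variant)
        return f"{self.gene_id};{self.event_type}:{self.chrom}:{body}:{self.strand}"

    def key(self):
        return (self.event_type, self.chrom, self.strand, self.coords)


def _format_coords(etype: str, c: tuple[int, ...], left_variant: bool | None) -> str:
    """ioe-style coordinate body (0-based half-open -> 1-based sites).

    In a boundary written ``e-s``, e is the 1-based end of the exon left
    of a junction (equal to the half-open end) and s the 1-based start
    of the exon right of it (half-open start + 1).
    """
    if etype == "SE":      # (e1, xs, xe, s3): flank end, skipped exon, flank start
        e1, xs, xe, s3 = c
        return f"{e1}-{xs + 1}:{xe}-{s3 + 1}"
    if etype == "RI":      # (s1, e1, s2, e2): the two spliced exons
        s1, e1, s2, e2 = c
        return f"{s1 + 1}:{e1}-{s2 + 1}:{e2}"
    if etype in ("A3", "A5"):  # (d1, a1, d2, a2): intron variants, inclusion first
        d1, a1, d2, a2 = c
        return f"{d1}-{a1 + 1}:{d2}-{a2 + 1}"
    if etype == "MX":      # (fe, x1s, x1e, x2s, x2e, ns)
        fe, x1s, x1e, x2s, x2e, ns = c
        return f"{fe}-{x1s + 1}:{x1e}-{ns + 1}:{fe}-{x2s + 1}:{x2e}-{ns + 1}"
    if left_variant:       # (x1s, x1e, x2s, x2e, cs): variant exons, shared start
        x1s, x1e, x2s, x2e, cs = c
        return f"{x1s + 1}:{x1e}-{cs + 1}:{x2s + 1}:{x2e}-{cs + 1}"
    ce, x1s, x1e, x2s, x2e = c  # (ce, x1s, x1e, x2s, x2e): shared end, variants
    return f"{ce}-{x1s + 1}:{x1e}:{ce}-{x2s + 1}:{x2e}"


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def generate_events(transcripts: list[TranscriptModel]) -> list[ASEvent]:
    """All local events among the transcripts of one gene.

    Transcripts must share gene, chromosome and strand. A single
    transcript yields no events. Events are returned sorted by type and
    coordinates.
    """
    if len(transcripts) < 2:
        return []
    gene = transcripts[0].gene_id
    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    for t in transcripts:
        if (t.gene_id, t.chrom, t.strand) != (gene, chrom, strand):
            raise ValueError("transcripts of one gene must share gene/chrom/strand")

    # (type, coords) -> [inclusion tids, all tids, left_variant flag]
    acc: dict[tuple, list] = defaultdict(lambda: [set(), set(), None])

    def add(etype, coords, inc_tids, all_tids, left_variant=None):
        slot = acc[(etype, tuple(coords))]
        slot[0].update(inc_tids)
        slot[1].update(all_tids)
        if left_variant is not None:
            slot[2] = left_variant

    for a, b in combinations(transcripts, 2):
        _detect_se(a, b, add)
        _detect_se(b, a, add)
        _detect_ri(a, b, add)
        _detect_ri(b, a, add)
        _detect_alt_ss(a, b, strand, add)
        _detect_mx(a, b, add)
        _detect_terminal(a, b, strand, add)

    out = [
        ASEvent(etype, gene, chrom, strand, coords,
                frozenset(inc), frozenset(tot), left_variant=side)
        for (etype, coords), (inc, tot, side) in acc.items()
    ]
    out.sort(key=lambda e: (e.event_type, e.coords))
    return out


def generate_all_events(models: list[TranscriptModel]) -> list[ASEvent]:
    """Events for every gene in a mixed transcript collection."""
    by_gene = defaultdict(list)
    for m in models:
        by_gene[m.gene_id].append(m)
    out = []
    for gene in sorted(by_gene):
        out.extend(generate_events(by_gene[gene]))
    return out


def _detect_se(inc: TranscriptModel, exc: TranscriptModel, add):
    """Internal exon of `inc` strictly inside an intron of `exc`, both
    transcripts sharing the flanking splice sites."""
    introns = set(exc.introns)
    ex = inc.exons
    for i in range(1, len(ex) - 1):
        p_e = ex[i - 1][1]
        n_s = ex[i + 1][0]
        xs, xe = ex[i]
        if (p_e, n_s) in introns and p_e < xs and xe < n_s:
            add("SE", (p_e, xs, xe, n_s), {inc.transcript_id},
                {inc.transcript_id, exc.transcript_id})


def _detect_ri(ret: TranscriptModel, spl: TranscriptModel, add):
    """Single exon of `ret` spanning exactly two adjacent exons of `spl`."""
    ret_exons = set(ret.exons)
    ex = spl.exons
    for i in range(len(ex) - 1):
        (s1, e1), (s2, e2) = ex[i], ex[i + 1]
        if (s1, e2) in ret_exons:
            add("RI", (s1, e1, s2, e2), {ret.transcript_id},
                {ret.transcript_id, spl.transcript_id})


def _detect_alt_ss(a: TranscriptModel, b: TranscriptModel, strand, add):
    """Intron pairs sharing one boundary, with overlapping variable-side exons.

    On the plus strand the genomic start of an intron is the 5' (donor)
    site and the genomic end the 3' (acceptor) site; on the minus strand
    the roles swap, which flips the A3/A5 label.
    """
    for ia, intron_a in enumerate(a.introns):
        for ib, intron_b in enumerate(b.introns):
            (d1, a1), (d2, a2) = intron_a, intron_b
            if d1 == d2 and a1 != a2:
                # shared genomic start; right-side exons must overlap
                ra, rb = a.exons[ia + 1], b.exons[ib + 1]
                if ra[0] < rb[1] and rb[0] < ra[1]:
                    etype = "A3" if strand == "+" else "A5"
                    short, long_ = sorted(
                        [intron_a, intron_b], key=lambda iv: iv[1] - iv[0]
                    )
                    inc = a if short == intron_a else b
                    add(etype, (*short, *long_), {inc.transcript_id},
                        {a.transcript_id, b.transcript_id})
            elif a1 == a2 and d1 != d2:
                # shared genomic end; left-side exons must overlap
                la, lb = a.exons[ia], b.exons[ib]
                if la[0] < lb[1] and lb[0] < la[1]:
                    etype = "A5" if strand == "+" else "A3"
                    short, long_ = sorted(
                        [intron_a, intron_b], key=lambda iv: iv[1] - iv[0]
                    )
                    inc = a if short == intron_a else b
                    add(etype, (*short, *long_), {inc.transcript_id},
                        {a.transcript_id, b.transcript_id})


def _detect_mx(a: TranscriptModel, b: TranscriptModel, add):
    """Non-overlapping internal exons between shared flanking splice sites."""
    for i in range(1, len(a.exons) - 1):
        fe = a.exons[i - 1][1]
        ns = a.exons[i + 1][0]
        x1 = a.exons[i]
        for j in range(1, len(b.exons) - 1):
            if b.exons[j - 1][1] != fe or b.exons[j + 1][0] != ns:
                continue
            x2 = b.exons[j]
            if x1 == x2 or (x1[0] < x2[1] and x2[0] < x1[1]):
                continue  # identical or overlapping: not mutually exclusive
            e_first, e_second = sorted([x1, x2])
            inc = a if e_first == x1 else b
            add("MX", (fe, *e_first, *e_second, ns), {inc.transcript_id},
                {a.transcript_id, b.transcript_id})


def _detect_terminal(a: TranscriptModel, b: TranscriptModel, strand, add):
    """Alternative first/last exons: non-overlapping terminal exons joined to
    a shared splice site of the adjacent common exon."""
    if len(a.exons) < 2 or len(b.exons) < 2:
        return
    # variation at the genomic left end: shared start of the second exon
    fa, fb = a.exons[0], b.exons[0]
    if (
        fa != fb
        and a.exons[1][0] == b.exons[1][0]
        and not (fa[0] < fb[1] and fb[0] < fa[1])
    ):
        cs = a.exons[1][0]
        e_distal, e_prox = sorted([fa, fb])  # smaller start = farther from cs
        inc = a if e_distal == fa else b
        etype = "AF" if strand == "+" else "AL"
        add(etype, (*e_distal, *e_prox, cs), {inc.transcript_id},
            {a.transcript_id, b.transcript_id}, left_variant=True)
    # variation at the genomic right end: shared end of the penultimate exon
    la, lb = a.exons[-1], b.exons[-1]
    if (
        la != lb
        and a.exons[-2][1] == b.exons[-2][1]
        and not (la[0] < lb[1] and lb[0] < la[1])
    ):
        ce = a.exons[-2][1]
        e_prox, e_distal = sorted([la, lb])  # larger start = farther from ce
        inc = a if e_distal == la else b
        etype = "AL" if strand == "+" else "AF"
        add(etype, (ce, *e_distal, *e_prox), {inc.transcript_id},
            {a.transcript_id, b.transcript_id}, left_variant=False)
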