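"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive results from first principles (explicit
enumeration, hand-rolled step-up, direct formulas) rather than calling
the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up from the definition: sort ascending,
    multiply by m/rank, enforce monotonicity from the largest down."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def median_center_log2(values):
    """Two-step protein normalization oracle: log2, then subtract the
    median of the whole block."""
    log = np.log2(np.asarray(values, dtype=float))
    return log - np.median(log)


def column_median_polish(matrix):
    """Loading-correction oracle: explicit per-column median subtraction."""
    m = np.asarray(matrix, dtype=float)
    out = m.copy()
    for c in range(m.shape[1]):
        col = m[:, c]
        out[:, c] = col - np.nanmedian(col)
    return out


def psi_direct(inclusion_tpms, total_tpms, floor=1e-3):
    """PSI from the definition, one donor at a time."""
    out = []
    for inc, tot in zip(inclusion_tpms, total_tpms):
        out.append(np.nan if tot < floor else inc / tot)
    return np.array(out)


# ---------------------------------------------------------------------------
# event enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_events(transcripts):
    """Brute-force enumeration of local splicing events for one gene.

    Returns a dict keyed by (type, coords) with values
    (inclusion tids frozenset, total tids frozenset). Transcripts are
    objects with .transcript_id, .strand and .exons (0-based half-open,
    sorted).
    """
    strand = transcripts[0].strand
    found: dict[tuple, list[set]] = {}

    def emit(etype, coords, inc, tot):
        slot = found.setdefault((etype, tuple(coords)), [set(), set()])
        slot[0].update(inc)
        slot[1].update(tot)

    for t, u in combinations(transcripts, 2):
        pair = {t.transcript_id, u.transcript_id}
        for x, o in ((t, u), (u, t)):
            o_junctions = {
                (x1, s2)
                for (_, x1), (s2, _) in zip(o.exons, o.exons[1:])
            }
            # SE: internal exon of x inside a junction of o with shared flanks
            for i in range(1, len(x.exons) - 1):
                a = x.exons[i - 1][1]
                b = x.exons[i + 1][0]
                s, e = x.exons[i]
                if (a, b) in o_junctions and a < s and e < b:
                    emit("SE", (a, s, e, b), {x.transcript_id}, pair)
            # RI: exon of x spanning two adjacent exons of o exactly
            for s, e in x.exons:
                for (p1, p2), (q1, q2) in zip(o.exons, o.exons[1:]):
                    if s == p1 and e == q2:
                        emit("RI", (p1, p2, q1, q2), {x.transcript_id}, pair)
        # alternative splice sites
        t_introns = [(e, s) for (_, e), (s, _) in zip(t.exons, t.exons[1:])]
        u_introns = [(e, s) for (_, e), (s, _) in zip(u.exons, u.exons[1:])]
        for i, iv1 in enumerate(t_introns):
            for j, iv2 in enumerate(u_introns):
                if iv1 == iv2:
                    continue
                if iv1[0] == iv2[0] and iv1[1] != iv2[1]:
                    # shared genomic start: check right exons overlap
                    r1, r2 = t.exons[i + 1], u.exons[j + 1]
                    if _overlap(r1, r2):
                        etype = "A3" if strand == "+" else "A5"
                        short, long_ = sorted([iv1, iv2], key=lambda v: v[1] - v[0])
                        inc = t if short == iv1 else u
                        emit(etype, short + long_, {inc.transcript_id}, pair)
                if iv1[1] == iv2[1] and iv1[0] != iv2[0]:
                    l1, l2 = t.exons[i], u.exons[j]
                    if _overlap(l1, l2):
                        etype = "A5" if strand == "+" else "A3"
                        short, long_ = sorted([iv1, iv2], key=lambda v: v[1] - v[0])
                        inc = t if short == iv1 else u
                        emit(etype, short + long_, {inc.transcript_id}, pair)
        # MX
        for i in range(1, len(t.exons) - 1):
            for j in range(1, len(u.exons) - 1):
                e1, e2 = t.exons[i], u.exons[j]
                if (
                    t.exons[i - 1][1] == u.exons[j - 1][1]
                    and t.exons[i + 1][0] == u.exons[j + 1][0]
                    and e1 != e2
                    and not _overlap(e1, e2)
                ):
                    lo, hi = sorted([e1, e2])
                    inc = t if lo == e1 else u
                    emit(
                        "MX",
                        (t.exons[i - 1][1],) + lo + hi + (t.exons[i + 1][0],),
                        {inc.transcript_id},
                        pair,
                    )
        # AF / AL at either gene end
        if len(t.exons) >= 2 and len(u.exons) >= 2:
            f1, f2 = t.exons[0], u.exons[0]
            if f1 != f2 and not _overlap(f1, f2) and t.exons[1][0] == u.exons[1][0]:
                distal, prox = sorted([f1, f2])
                inc = t if distal == f1 else u
                etype = "AF" if strand == "+" else "AL"
                emit(etype, distal + prox + (t.exons[1][0],), {inc.transcript_id}, pair)
            l1, l2 = t.exons[-1], u.exons[-1]
            if l1 != l2 and not _overlap(l1, l2) and t.exons[-2][1] == u.exons[-2][1]:
                prox, distal = sorted([l1, l2])
                inc = t if distal == l1 else u
                etype = "AL" if strand == "+" else "AF"
                emit(etype, (t.exons[-2][1],) + distal + prox, {inc.transcript_id}, pair)

    return {
        key: (frozenset(inc), frozenset(tot)) for key, (inc, tot) in found.items()
    }


def _overlap(a, b):
    return a[0] < b[1] and b[0] < a[1]
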