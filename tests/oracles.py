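"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written along a different route than the
code it checks: naive nested loops over literal definitions, plain
string slicing, and direct numerical quadrature.
"""

from __future__ import annotations

import numpy as np

from splicegain.core import (
    GenomeSequence,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
)

STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Bayes factor by direct numerical integration
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)
_GL_P = (_GL_NODES + 1.0) / 2.0
_GL_W = _GL_WEIGHTS / 2.0


def bayes_factor_numeric(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Marginal-likelihood ratio of independent-PSI vs shared-PSI models
    by Gauss-Legendre quadrature over [0, 1] (the binomial coefficients
    cancel between numerator and denominator)."""

    def marginal(k: int, n: int) -> float:
        return float(np.sum(_GL_W * _GL_P**k * (1.0 - _GL_P) ** (n - k)))

    shared = float(
        np.sum(
            _GL_W
            * _GL_P ** (k_a + k_b)
            * (1.0 - _GL_P) ** (n_a - k_a + n_b - k_b)
        )
    )
    return marginal(k_a, n_a) * marginal(k_b, n_b) / shared


# ---------------------------------------------------------------------------
# AS event enumeration by literal definition checks
# ---------------------------------------------------------------------------

def as_event_signatures_oracle(t1: TranscriptModel, t2: TranscriptModel) -> set[tuple]:
    """Every typed event between two exon chains, found by exhaustively
    testing the definitional pattern of each type over all exon/intron
    combinations."""
    strand = t1.strand
    sigs: set[tuple] = set()
    ex = {
        1: [(iv.start, iv.end) for iv in t1.intervals],
        2: [(iv.start, iv.end) for iv in t2.intervals],
    }
    introns = {
        i: {(a[1], b[0]) for a, b in zip(ex[i], ex[i][1:])} for i in (1, 2)
    }
    exon_sets = {i: set(ex[i]) for i in (1, 2)}

    for a, b in ((1, 2), (2, 1)):
        # SE: internal exon with flank introns in one chain, the direct
        # junction in the other
        for idx in range(1, len(ex[a]) - 1):
            s, t = ex[a][idx]
            d = ex[a][idx - 1][1]
            acc = ex[a][idx + 1][0]
            if (d, acc) in introns[b]:
                sigs.add(("SE", s, t, d, acc))
        # RI: an intron of one chain strictly covered by an exon of the other
        for x, y in introns[a]:
            for u, v in exon_sets[b]:
                if u < x and v > y:
                    sigs.add(("RI", x, y))
        # MXE: internal exons sharing both flank boundaries, non-overlapping
        for ia in range(1, len(ex[a]) - 1):
            for ib in range(1, len(ex[b]) - 1):
                s1, t1e = ex[a][ia]
                s2, t2e = ex[b][ib]
                if (
                    ex[a][ia - 1][1] == ex[b][ib - 1][1]
                    and ex[a][ia + 1][0] == ex[b][ib + 1][0]
                    and (t1e <= s2 or t2e <= s1)
                ):
                    lo, hi = sorted([(s1, t1e), (s2, t2e)])
                    sigs.add(("MXE", *lo, *hi))

    # alternative 5'/3' splice sites: intron pairs sharing one boundary
    # whose varying boundary belongs to exons sharing their other boundary
    for x1, y1 in introns[1]:
        for x2, y2 in introns[2]:
            if y1 == y2 and x1 != x2:
                starts = {u for (u, v) in exon_sets[1] if v == x1}
                if any((u, x2) in exon_sets[2] for u in starts):
                    etype = "A5SS" if strand == "+" else "A3SS"
                    sigs.add((etype, min(x1, x2), max(x1, x2), y1, "end"))
            if x1 == x2 and y1 != y2:
                ends = {v for (u, v) in exon_sets[1] if u == y1}
                if any((y2, v) in exon_sets[2] for v in ends):
                    etype = "A3SS" if strand == "+" else "A5SS"
                    sigs.add((etype, x1, min(y1, y2), max(y1, y2), "start"))
    return sigs


# ---------------------------------------------------------------------------
# Splice-translate-scan consequence oracle
# ---------------------------------------------------------------------------

def _naive_mrna(t: TranscriptModel, g: GenomeSequence) -> str:
    s = "".join(g.sequence[iv.start : iv.end] for iv in t.intervals)
    return reverse_complement(s) if t.strand == "-" else s


def _bases_before(t: TranscriptModel, genomic_pos: int) -> int:
    """Exonic bases transcriptionally upstream of an exonic genomic
    position, counted exon by exon."""
    total = 0
    if t.strand == "+":
        for iv in t.intervals:
            if iv.end <= genomic_pos:
                total += iv.length
            elif iv.start <= genomic_pos:
                total += genomic_pos - iv.start
    else:
        for iv in t.intervals:
            if iv.start > genomic_pos:
                total += iv.length
            elif iv.end > genomic_pos:
                total += iv.end - 1 - genomic_pos
    return total


def orf_consequence_oracle(
    variant: TranscriptModel,
    canonical: TranscriptModel,
    g: GenomeSequence,
    domains=(),
) -> dict:
    """Splice, translate codon by codon, scan for the first stop, and
    classify -- all with plain string arithmetic."""
    V = _naive_mrna(variant, g)
    start_genomic = (
        canonical.cds_start if canonical.strand == "+" else canonical.cds_end - 1
    )
    sv = _bases_before(variant, start_genomic)

    canon_exons = {(iv.start, iv.end) for iv in canonical.intervals}
    novel = [iv for iv in variant.intervals if (iv.start, iv.end) not in canon_exons]
    assert len(novel) == 1
    exon = novel[0]
    first_base = exon.start if variant.strand == "+" else exon.end - 1
    ns = _bases_before(variant, first_base)
    ne = ns + exon.length

    cds_len = sum(
        min(iv.end, canonical.cds_end) - max(iv.start, canonical.cds_start)
        for iv in canonical.intervals
        if iv.start < canonical.cds_end and iv.end > canonical.cds_start
    )
    protein_len = cds_len // 3 - 1
    # genomic first base of the canonical stop codon, found by walking
    # the canonical mRNA
    C_utr5 = _bases_before(canonical, start_genomic)
    stop_mrna_offset = C_utr5 + cds_len - 3
    pos = 0
    stop_genomic = None
    exon_iter = (
        canonical.intervals if canonical.strand == "+" else canonical.intervals[::-1]
    )
    for iv in exon_iter:
        if pos + iv.length > stop_mrna_offset:
            off = stop_mrna_offset - pos
            stop_genomic = (
                iv.start + off if canonical.strand == "+" else iv.end - 1 - off
            )
            break
        pos += iv.length
    stop_variant = _bases_before(variant, stop_genomic)

    if ne <= sv:
        return {"category": "no_change"}
    if V[sv : sv + 3] != "ATG":
        return {"category": "no_change"}
    if ns >= stop_variant + 3:
        return {"category": "no_change"}

    q = sv
    p = None
    while q + 3 <= len(V):
        if V[q : q + 3] in STOPS:
            p = q
            break
        q += 3
    assert p is not None, "nonstop transcript in oracle"

    last_exon_len = (
        variant.intervals[-1].length
        if variant.strand == "+"
        else variant.intervals[0].length
    )
    distance = (len(V) - last_exon_len) - (p + 3)

    if ns <= p + 2 < ne:
        added = 0
        q = sv
        while q < p:
            if ns <= q + 2 < ne:
                added += 1
            q += 3
        trunc = (p - sv) // 3
        return {
            "category": "ptc_in_novel_exon",
            "added_codons": added,
            "ptc_position": p,
            "distance": distance,
            "truncated_protein_length": trunc,
            "lost_domains": tuple(d.name for d in domains if d.aa_end > trunc),
            "nmd": distance > 50,
        }
    if p == stop_variant:
        return {
            "category": "in_frame_addition",
            "truncated_protein_length": protein_len + exon.length // 3,
        }
    trunc = (p - sv) // 3
    return {
        "category": "frameshift_ptc",
        "ptc_position": p,
        "distance": distance,
        "truncated_protein_length": trunc,
        "lost_domains": tuple(d.name for d in domains if d.aa_end > trunc),
        "nmd": distance > 50,
    }


# ---------------------------------------------------------------------------
# Exhaustive score-track pairing oracle
# ---------------------------------------------------------------------------

def candidate_keys_oracle(
    track, transcripts, min_score=0.1, min_len=25, max_len=500
) -> set[tuple[int, int, int, int]]:
    """All (start, end, intron_start, intron_end) candidate keys by
    trying every position pair in every intron."""
    introns = []
    seen = set()
    for t in transcripts:
        for intr in t.introns():
            key = (intr.start, intr.end, intr.strand)
            if key not in seen:
                seen.add(key)
                introns.append(intr)
    out = set()
    for intr in introns:
        for i in range(len(track.positions)):
            for j in range(len(track.positions)):
                if track.acceptor_score[i] < min_score:
                    continue
                if track.donor_score[j] < min_score:
                    continue
                pa, pd_ = int(track.positions[i]), int(track.positions[j])
                if intr.strand == "+":
                    start, end = pa, pd_ + 1
                else:
                    start, end = pd_, pa + 1
                if start >= end:
                    continue
                if not (intr.start < start and end < intr.end):
                    continue
                if not (min_len <= end - start <= max_len):
                    continue
                out.add((start, end, intr.start, intr.end))
    return out
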