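"""Coding consequence of a novel exon and nonsense-mediated-decay calls.

Inserting an intron-internal exon into a mature mRNA can (i) introduce a
premature termination codon (PTC) inside the new exon, (ii) add amino
acids in frame, or (iii) shift the downstream reading frame until a new
stop is reached.  A PTC-bearing transcript is predicted to be a
nonsense-mediated decay (NMD) substrate by the 50-nt rule: the stop must
lie more than 50 nt upstream of the final exon-exon junction (strict
inequality; a stop in the last exon escapes NMD).

Stage-wise NMD efficiency is estimated from paired +/-translation-
inhibitor (e.g. cycloheximide) abundance measurements of a PTC-bearing
transcript: efficiency = 1 - untreated/treated, clipped at 0.  An
efficiency near zero means the transcript accumulates untouched, the
behaviour of meiotic spermatocytes and round spermatids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
    first_stop_codon,
    spliced_sequence,
    validate_canonical_cds,
)

logger = logging.getLogger(__name__)

CATEGORY_PTC_IN_NOVEL_EXON = "ptc_in_novel_exon"
CATEGORY_IN_FRAME = "in_frame_addition"
CATEGORY_FRAMESHIFT_PTC = "frameshift_ptc"
CATEGORY_NO_CHANGE = "no_change"
PTC_CATEGORIES = frozenset({CATEGORY_PTC_IN_NOVEL_EXON, CATEGORY_FRAMESHIFT_PTC})

NMD_RULE_DISTANCE_DEFAULT = 50
LOW_NMD_THRESHOLD_DEFAULT = 0.2


@dataclass(frozen=True)
class OrfConsequence:
    category: str
    added_codons_before_stop: int | None = None
    ptc_transcript_position: int | None = None
    distance_ptc_to_last_junction: int | None = None
    nmd_sensitive: bool = False
    truncated_protein_length: int = 0
    lost_domains: tuple[str, ...] = ()


@dataclass(frozen=True)
class NmdEfficiencyEstimate:
    stage: str
    abundance_untreated: float
    abundance_treated: float
    efficiency: float
    flagged_low_nmd: bool


def build_variant_transcript(
    t: TranscriptModel, novel_exon: GenomicInterval
) -> TranscriptModel:
    """Insert ``novel_exon`` between its flanking exons.

    The exon must lie strictly inside one intron of ``t``; CDS boundaries
    are inherited (translation is re-derived downstream).
    """
    if novel_exon.contig != t.contig or novel_exon.strand != t.strand:
        raise ValidationError("novel exon on a different contig or strand")
    if any(novel_exon.overlaps(iv) for iv in t.intervals):
        raise ValidationError(
            f"novel exon [{novel_exon.start}, {novel_exon.end}) overlaps an "
            f"annotated exon of {t.transcript_id}"
        )
    host = next(
        (
            intr
            for intr in t.introns()
            if intr.start < novel_exon.start and novel_exon.end < intr.end
        ),
        None,
    )
    if host is None:
        raise ValidationError(
            f"novel exon [{novel_exon.start}, {novel_exon.end}) is not strictly "
            f"inside an intron of {t.transcript_id}"
        )
    intervals = sorted(t.intervals + (novel_exon,), key=lambda iv: iv.start)
    return TranscriptModel(
        transcript_id=f"{t.transcript_id}|ins{novel_exon.start}_{novel_exon.end}",
        gene_id=t.gene_id,
        intervals=tuple(intervals),
        cds_start=t.cds_start,
        cds_end=t.cds_end,
    )


def _novel_exons(variant: TranscriptModel, canonical: TranscriptModel):
    canon = {(iv.start, iv.end) for iv in canonical.intervals}
    return [iv for iv in variant.intervals if (iv.start, iv.end) not in canon]


def annotate_orf_consequence(
    variant: TranscriptModel,
    canonical: TranscriptModel,
    g: GenomeSequence,
    domains: Sequence[DomainAnnotation] = (),
) -> OrfConsequence:
    """Translate the variant transcript and classify the consequence.

    Translation starts at the canonical start codon mapped into the
    variant's spliced sequence; the first in-frame stop decides the
    category: third base inside the novel exon -> PTC in the novel exon;
    coinciding with the canonical stop -> in-frame addition (or no change
    for a UTR insertion); anywhere else -> frameshift-induced PTC.
    """
    canonical_cds = validate_canonical_cds(canonical, g)
    protein_len = len(canonical_cds) // 3 - 1  # excluding the stop

    novel = _novel_exons(variant, canonical)
    if len(novel) != 1:
        raise ValidationError(
            f"expected exactly one novel exon in {variant.transcript_id}, "
            f"found {len(novel)}"
        )
    exon = novel[0]

    seq = spliced_sequence(variant, g)
    spans = variant.exon_spliced_spans()
    order = variant.exons_transcription_order()
    ns, ne = spans[order.index(exon)]
    exon_len = ne - ns

    # Canonical start and stop codon first bases, mapped genomically and
    # then into variant spliced coordinates.
    start_genomic = (
        canonical.cds_start if variant.strand == "+" else canonical.cds_end - 1
    )
    sv = variant.genomic_to_spliced(start_genomic)
    cds_s, cds_e = canonical.cds_spliced_span()
    stop_genomic = canonical.spliced_to_genomic(cds_e - 3)
    canonical_stop_variant = variant.genomic_to_spliced(stop_genomic)

    if ne <= sv:
        logger.info(
            "%s: insertion upstream of the CDS (UTR intron)", variant.transcript_id
        )
        return OrfConsequence(
            CATEGORY_NO_CHANGE, truncated_protein_length=protein_len
        )
    if seq[sv : sv + 3] != "ATG":
        logger.warning(
            "%s: start codon destroyed by the insertion", variant.transcript_id
        )
        return OrfConsequence(
            CATEGORY_NO_CHANGE, truncated_protein_length=protein_len
        )
    if ns >= canonical_stop_variant + 3:
        # entirely downstream of the canonical stop: 3'UTR insertion
        return OrfConsequence(
            CATEGORY_NO_CHANGE, truncated_protein_length=protein_len
        )

    p = first_stop_codon(seq, sv)
    if p is None:
        raise ValidationError(
            f"{variant.transcript_id}: no in-frame stop codon downstream of the "
            "start (nonstop transcript)"
        )

    last_junction = variant.last_junction_spliced_position()
    distance = None if last_junction is None else last_junction - (p + 3)

    if ns <= p + 2 < ne:
        # Count complete codons whose third base lies within the novel
        # exon ahead of the stop codon.
        added = sum(
            1 for q in range(sv, p, 3) if ns <= q + 2 < ne
        )
        trunc = (p - sv) // 3
        lost = tuple(d.name for d in domains if d.aa_end > trunc)
        cons = OrfConsequence(
            CATEGORY_PTC_IN_NOVEL_EXON,
            added_codons_before_stop=added,
            ptc_transcript_position=p,
            distance_ptc_to_last_junction=distance,
            truncated_protein_length=trunc,
            lost_domains=lost,
        )
    elif p == canonical_stop_variant:
        cons = OrfConsequence(
            CATEGORY_IN_FRAME,
            truncated_protein_length=protein_len + exon_len // 3,
        )
    else:
        trunc = (p - sv) // 3
        lost = tuple(d.name for d in domains if d.aa_end > trunc)
        cons = OrfConsequence(
            CATEGORY_FRAMESHIFT_PTC,
            ptc_transcript_position=p,
            distance_ptc_to_last_junction=distance,
            truncated_protein_length=trunc,
            lost_domains=lost,
        )
    if cons.category in PTC_CATEGORIES:
        cons = OrfConsequence(
            cons.category,
            added_codons_before_stop=cons.added_codons_before_stop,
            ptc_transcript_position=cons.ptc_transcript_position,
            distance_ptc_to_last_junction=cons.distance_ptc_to_last_junction,
            nmd_sensitive=predict_nmd(cons),
            truncated_protein_length=cons.truncated_protein_length,
            lost_domains=cons.lost_domains,
        )
    return cons


def predict_nmd(
    c: OrfConsequence, rule_distance: int = NMD_RULE_DISTANCE_DEFAULT
) -> bool:
    """50-nt rule: NMD-sensitive iff the PTC lies strictly more than
    ``rule_distance`` nt upstream of the last exon-exon junction."""
    if c.category not in PTC_CATEGORIES:
        raise ValidationError(
            f"NMD prediction applies to PTC-bearing categories, not {c.category}"
        )
    if c.distance_ptc_to_last_junction is None:
        return False
    return c.distance_ptc_to_last_junction > rule_distance


def ptc_fraction(consequences: Sequence[OrfConsequence]) -> dict[str, float]:
    """Fractions of PTC-introducing vs in-frame exon gains.

    Classified events are those with a PTC (in-exon or frameshift) or an
    in-frame addition; the in-exon and frameshift routes are also
    reported separately.
    """
    if not consequences:
        raise ValidationError("no consequences to summarize")
    relevant = [
        c
        for c in consequences
        if c.category in PTC_CATEGORIES or c.category == CATEGORY_IN_FRAME
    ]
    if not relevant:
        raise ValidationError("no classifiable exon-gain consequences")
    n = len(relevant)
    n_ptc_exon = sum(1 for c in relevant if c.category == CATEGORY_PTC_IN_NOVEL_EXON)
    n_fs = sum(1 for c in relevant if c.category == CATEGORY_FRAMESHIFT_PTC)
    return {
        "ptc_fraction": (n_ptc_exon + n_fs) / n,
        "in_frame_fraction": 1.0 - (n_ptc_exon + n_fs) / n,
        "ptc_in_exon_fraction": n_ptc_exon / n,
        "frameshift_fraction": n_fs / n,
    }


def estimate_nmd_efficiency(
    pairs: pd.DataFrame,
    low_nmd_threshold: float = LOW_NMD_THRESHOLD_DEFAULT,
) -> list[NmdEfficiencyEstimate]:
    """Per-stage NMD efficiency from +/-inhibitor abundances.

    ``pairs`` has columns stage, replicate, treated (0/1), abundance;
    replicates are averaged within stage x treatment.  Efficiency is
    1 - untreated/treated clipped to [0, 1); stages keep their input
    order.
    """
    if (pairs["abundance"] <= 0).any():
        raise ValidationError("abundances must be positive")
    out = []
    for stage in pd.unique(pairs["stage"]):
        grp = pairs[pairs["stage"] == stage]
        u = grp[grp["treated"] == 0]["abundance"].mean()
        t = grp[grp["treated"] == 1]["abundance"].mean()
        if np.isnan(u) or np.isnan(t):
            raise ValidationError(f"stage {stage}: need both treated and untreated")
        eff = min(max(0.0, 1.0 - u / t), np.nextafter(1.0, 0.0))
        out.append(
            NmdEfficiencyEstimate(
                str(stage), float(u), float(t), eff, eff < low_nmd_threshold
            )
        )
    return out


def consequences_to_dataframe(
    items: Iterable[tuple[str, OrfConsequence]]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": event_id,
                "category": c.category,
                "added_codons": c.added_codons_before_stop,
                "ptc_position": c.ptc_transcript_position,
                "ptc_distance_to_last_junction": c.distance_ptc_to_last_junction,
                "nmd_sensitive": c.nmd_sensitive,
                "truncated_protein_length": c.truncated_protein_length,
                "lost_domains": ",".join(c.lost_domains),
            }
            for event_id, c in items
        ]
    )
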