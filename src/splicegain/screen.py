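"""Screening of splice-site score tracks for novel intron-internal exons.

A score track assigns each genomic position an acceptor and a donor
probability in [0, 1] (SpliceAI-style output, consumed here, never
computed).  Candidate exons are nominated inside annotated introns by
pairing a high-scoring acceptor with a downstream (in transcription
order) high-scoring donor, and are binned into score bands: a site pair
whose weaker score is at least 0.9 behaves like a constitutive exon,
between 0.1 and 0.9 like an alternatively spliced exon, and below 0.1 is
rejected.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

BAND_CONSTITUTIVE = "constitutive"
BAND_ALTERNATIVE = "alternative"
BAND_REJECT = "reject"

CONSTITUTIVE_MIN = 0.9
ALTERNATIVE_MIN = 0.1


def classify_band(
    acceptor_score: float,
    donor_score: float,
    lower: float = ALTERNATIVE_MIN,
    upper: float = CONSTITUTIVE_MIN,
) -> str:
    """Bin a splice-site score pair by its weaker score.

    An exon needs both a functional acceptor and donor, so the minimum of
    the two scores decides the band: >= ``upper`` constitutive,
    [``lower``, ``upper``) alternative, < ``lower`` reject.
    """
    for s in (acceptor_score, donor_score):
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"splice-site score {s} outside [0, 1]")
    m = min(acceptor_score, donor_score)
    if m >= upper:
        return BAND_CONSTITUTIVE
    if m >= lower:
        return BAND_ALTERNATIVE
    return BAND_REJECT


@dataclass
class SpliceScoreTrack:
    """Per-position acceptor/donor probabilities for one contig+strand."""

    contig: str
    strand: str
    positions: np.ndarray
    acceptor_score: np.ndarray
    donor_score: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.acceptor_score = np.asarray(self.acceptor_score, dtype=float)
        self.donor_score = np.asarray(self.donor_score, dtype=float)
        if not (
            len(self.positions) == len(self.acceptor_score) == len(self.donor_score)
        ):
            raise ValidationError("score track arrays have mismatched lengths")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("score track positions must be strictly increasing")
        for arr in (self.acceptor_score, self.donor_score):
            if len(arr) and (arr.min() < 0 or arr.max() > 1):
                raise ValidationError("scores must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "position": self.positions,
                "strand": self.strand,
                "acceptor_score": self.acceptor_score,
                "donor_score": self.donor_score,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpliceScoreTrack":
        df = df.sort_values("position")
        contigs = df["contig"].unique()
        strands = df["strand"].unique()
        if len(contigs) != 1 or len(strands) != 1:
            raise ValidationError("score track must cover a single contig and strand")
        return cls(
            str(contigs[0]),
            str(strands[0]),
            df["position"].to_numpy(),
            df["acceptor_score"].to_numpy(),
            df["donor_score"].to_numpy(),
        )


def read_score_track(path: str | os.PathLike) -> SpliceScoreTrack:
    return SpliceScoreTrack.from_dataframe(pd.read_csv(path, sep="\t"))


def write_score_track(path: str | os.PathLike, track: SpliceScoreTrack) -> None:
    track.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExonCandidate:
    """A putative novel exon nominated inside an annotated intron."""

    interval: GenomicInterval
    host_intron: GenomicInterval
    acceptor_score: float
    donor_score: float
    band: str

    def __post_init__(self) -> None:
        if not (
            self.host_intron.start < self.interval.start
            and self.interval.end < self.host_intron.end
        ):
            raise ValidationError(
                "candidate exon must lie strictly inside its host intron"
            )
        if self.band != classify_band(self.acceptor_score, self.donor_score):
            raise ValidationError("band inconsistent with scores")


def find_exon_candidates(
    track: SpliceScoreTrack,
    transcripts: Sequence[TranscriptModel],
    min_score: float = 0.1,
    min_len: int = 25,
    max_len: int = 500,
) -> list[ExonCandidate]:
    """Nominate intron-internal exon candidates from a score track.

    For every annotated intron, every (acceptor, donor) position pair
    with both scores >= ``min_score``, the acceptor upstream of the donor
    in transcription order, and the implied exon strictly inside the
    intron with length in [``min_len``, ``max_len``], yields one
    candidate.  An acceptor score at position p marks p as the exon's
    first transcribed base; a donor score at position q marks q as its
    last.  All overlapping pairs are reported (no greedy selection);
    annotated exon boundaries at the intron edges are excluded by the
    strict-interior requirement.
    """
    if min_len < 1 or max_len < min_len:
        raise ValidationError("require 1 <= min_len <= max_len")
    introns: list[GenomicInterval] = []
    seen_introns = set()
    for t in transcripts:
        if t.contig != track.contig:
            raise ValidationError(
                f"transcript {t.transcript_id} on {t.contig}, track on {track.contig}"
            )
        for intr in t.introns():
            key = (intr.start, intr.end, intr.strand)
            if key not in seen_introns:
                seen_introns.add(key)
                introns.append(intr)
    if not introns:
        logger.warning("no annotated introns; returning no candidates")
        return []

    acc_mask = track.acceptor_score >= min_score
    don_mask = track.donor_score >= min_score
    acc_pos = track.positions[acc_mask]
    acc_sc = track.acceptor_score[acc_mask]
    don_pos = track.positions[don_mask]
    don_sc = track.donor_score[don_mask]

    out: list[ExonCandidate] = []
    seen: set[tuple[int, int, int, int]] = set()
    for intr in introns:
        in_acc = (acc_pos > intr.start) & (acc_pos < intr.end - 1)
        in_don = (don_pos > intr.start) & (don_pos < intr.end - 1)
        for ap, asc in zip(acc_pos[in_acc], acc_sc[in_acc]):
            for dp, dsc in zip(don_pos[in_don], don_sc[in_don]):
                if intr.strand == "+":
                    start, end = ap, dp + 1  # acceptor first, donor last base
                else:
                    start, end = dp, ap + 1  # transcription runs right to left
                if start >= end:
                    continue
                length = end - start
                if not (min_len <= length <= max_len):
                    continue
                if not (intr.start < start and end < intr.end):
                    continue
                start, end = int(start), int(end)
                key = (start, end, intr.start, intr.end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    ExonCandidate(
                        interval=GenomicInterval(intr.contig, start, end, intr.strand),
                        host_intron=intr,
                        acceptor_score=float(asc),
                        donor_score=float(dsc),
                        band=classify_band(float(asc), float(dsc)),
                    )
                )
    out.sort(key=lambda c: (c.interval.start, c.interval.end))
    return out


def candidates_to_dataframe(candidates: Iterable[ExonCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": c.interval.contig,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
                "length": c.interval.length,
                "host_intron_start": c.host_intron.start,
                "host_intron_end": c.host_intron.end,
                "acceptor_score": c.acceptor_score,
                "donor_score": c.donor_score,
                "band": c.band,
            }
            for c in candidates
        ]
    )
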