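"""Synthetic data generation with known ground truth.

Everything the pipeline consumes can be generated here: a genome with
planted gene models, SpliceAI-style score tracks, stage-resolved
junction counts whose PTC-bearing isoform abundance is suppressed by
stage-specific NMD, +/-inhibitor abundance tables, and a cohort of
events realizing configured type/direction/PTC/maintenance fractions.

The stage design emulates a five-stage male germ-cell series
(undifferentiated and differentiated spermatogonia, preleptotene and
pachytene spermatocytes, round spermatids).  NMD efficiency defaults to
high in the spermatogonial stages and zero in meiotic/post-meiotic
stages, so a constitutively produced PTC-bearing splice variant
accumulates only from the preleptotene stage onward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    JunctionCountRecord,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)
from .quant import SpliceEvent
from .screen import SpliceScoreTrack

logger = logging.getLogger(__name__)

STAGE_NAMES_DEFAULT = ("SG_und", "SG_diff", "SC_preL", "SC_pachy", "RS")
NMD_EFFICIENCY_DEFAULT = (0.75, 0.75, 0.0, 0.0, 0.0)
ACTIVE_TRANSITION_DEFAULT = 1  # SG_diff -> SC_preL

_SAFE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
# Contains a stop codon in each of the three reading frames; appended to
# the 3' end of synthetic transcripts so frameshifted translation always
# terminates within the transcript.
_TRIFRAME_STOP_TAIL = "TAGATAGATAGA"


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + a stop codon."""
    body = "".join(rng.choice(_SAFE_CODONS, size=n_codons - 2))
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + body + stop


@dataclass
class AssembledGene:
    genome: GenomeSequence
    transcript: TranscriptModel


def assemble_gene(
    contig_name: str,
    transcript_id: str,
    gene_id: str,
    exon_sense_seqs: Sequence[str],
    intron_sense_seqs: Sequence[str],
    cds_mrna_span: tuple[int, int],
    strand: str = "+",
    flank5: str = "",
    flank3: str = "",
) -> AssembledGene:
    """Lay out a gene on a fresh contig.

    ``exon_sense_seqs``/``intron_sense_seqs`` are mRNA-sense sequences in
    transcription order; ``cds_mrna_span`` is the half-open CDS span in
    spliced-transcript coordinates.  Minus-strand genes are written into
    the contig reverse-complemented with coordinates mirrored.
    """
    if len(intron_sense_seqs) != len(exon_sense_seqs) - 1:
        raise ValidationError("need exactly one intron between consecutive exons")
    sense_parts = [flank5]
    exon_sense_coords = []
    pos = len(flank5)
    for i, exon in enumerate(exon_sense_seqs):
        exon_sense_coords.append((pos, pos + len(exon)))
        sense_parts.append(exon)
        pos += len(exon)
        if i < len(intron_sense_seqs):
            sense_parts.append(intron_sense_seqs[i])
            pos += len(intron_sense_seqs[i])
    sense_parts.append(flank3)
    sense = "".join(sense_parts)

    # CDS boundaries on the sense axis.
    c0, c1 = cds_mrna_span
    mrna_offsets = np.cumsum([0] + [len(e) for e in exon_sense_seqs])
    def mrna_to_sense(m: int, end: bool = False) -> int:
        for i, (a, b) in enumerate(zip(mrna_offsets, mrna_offsets[1:])):
            if a <= m < b or (end and m == b):
                s, _ = exon_sense_coords[i]
                return s + (m - a)
        raise ValidationError(f"mRNA offset {m} outside transcript")
    cs = mrna_to_sense(c0)
    ce = mrna_to_sense(c1 - 1) + 1

    L = len(sense)
    if strand == "+":
        contig_seq = sense
        intervals = [
            GenomicInterval(contig_name, a, b, "+") for a, b in exon_sense_coords
        ]
        cds_start, cds_end = cs, ce
    else:
        contig_seq = reverse_complement(sense)
        intervals = [
            GenomicInterval(contig_name, L - b, L - a, "-")
            for a, b in exon_sense_coords
        ]
        intervals.sort(key=lambda iv: iv.start)
        cds_start, cds_end = L - ce, L - cs
    genome = GenomeSequence(contig_name, contig_seq)
    transcript = TranscriptModel(
        transcript_id, gene_id, tuple(intervals), cds_start, cds_end
    )
    return AssembledGene(genome, transcript)


# ---------------------------------------------------------------------------
# The Mga-like fixture
# ---------------------------------------------------------------------------

@dataclass
class MgaFixture:
    genome: GenomeSequence
    transcript: TranscriptModel
    novel_exon: GenomicInterval
    domains: tuple[DomainAnnotation, ...]
    track: SpliceScoreTrack
    event_id: str = "Mga_like:SE:novel"


def make_mga_fixture(seed: int = 0) -> MgaFixture:
    """A condensed Mga-like gene with a 145-nt exon planted in an intron.

    Three annotated exons stand in for exons 17/18/19 of the real gene;
    the second intron hosts a 145-nt exon whose incoming reading frame
    carries five complete codons followed by TAA.  A C-terminal bHLHZ
    domain lies downstream of the insertion point (lost on truncation)
    and a T-box domain upstream (retained).  The score track marks the
    annotated boundaries with scores above 0.9 and the planted exon with
    acceptor 0.695 / donor 0.761.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    utr5 = _random_bases(rng, 30)
    # 280 codons total: protein of 279 aa, stop at the end of exon 3.
    cds = _random_orf(rng, 280)
    assert len(cds) == 840
    utr3 = _random_bases(rng, 258) + _TRIFRAME_STOP_TAIL
    mrna = utr5 + cds + utr3  # 30 + 840 + 270 = 1140
    # exon1 300 nt (30 UTR + 270 CDS), exon2 240 nt CDS, exon3 600 nt
    exons = [mrna[:300], mrna[300:540], mrna[540:]]
    intron1 = _random_bases(rng, 400)
    # intron2 hosts the novel exon at offset 300
    novel = (
        "".join(rng.choice(_SAFE_CODONS, size=5))  # five amino acids
        + "TAA"                                    # the in-frame PTC
        + _random_bases(rng, 127)                  # 145 nt total
    )
    assert len(novel) == 145
    intron2 = _random_bases(rng, 300) + novel + _random_bases(rng, 355)
    gene = assemble_gene(
        "chrMga",
        "Mga_like.t1",
        "Mga_like",
        exons,
        [intron1, intron2],
        cds_mrna_span=(30, 870),
        strand="+",
        flank5=_random_bases(rng, 100),
        flank3=_random_bases(rng, 60),
    )
    t = gene.transcript
    intron2_iv = t.introns()[1]
    novel_iv = GenomicInterval(
        "chrMga", intron2_iv.start + 300, intron2_iv.start + 445, "+"
    )
    assert gene.genome.fetch(novel_iv.start, novel_iv.end) == novel

    domains = (
        DomainAnnotation("T-box", 30, 120),
        DomainAnnotation("bHLHZ", 200, 260),
    )

    scores: dict[int, tuple[float, float]] = {}
    for iv in t.intervals:
        scores[iv.start] = (float(rng.uniform(0.92, 0.98)), float(rng.uniform(0.0, 0.03)))
        scores[iv.end - 1] = (float(rng.uniform(0.0, 0.03)), float(rng.uniform(0.92, 0.98)))
    scores[novel_iv.start] = (0.695, 0.01)
    scores[novel_iv.end - 1] = (0.02, 0.761)
    n_background = 30
    while n_background > 0:
        pos = int(rng.integers(0, len(gene.genome)))
        if pos in scores:
            continue
        scores[pos] = (float(rng.uniform(0.0, 0.09)), float(rng.uniform(0.0, 0.09)))
        n_background -= 1
    positions = np.array(sorted(scores), dtype=np.int64)
    track = SpliceScoreTrack(
        "chrMga",
        "+",
        positions,
        np.array([scores[p][0] for p in positions]),
        np.array([scores[p][1] for p in positions]),
    )
    return MgaFixture(gene.genome, t, novel_iv, domains, track)


# ---------------------------------------------------------------------------
# Stage-resolved junction-count simulation
# ---------------------------------------------------------------------------

@dataclass
class StageSeries:
    """Ordered cell-stage samples with per-event ground truth.

    ``true_psi`` maps event_id to one production-level PSI per stage;
    for events flagged PTC-bearing, the sampled inclusion abundance is
    additionally suppressed by the stage's NMD efficiency
    (psi_effective = psi * (1 - nmd_efficiency)), the steady-state view
    of decay acting multiplicatively on the variant isoform.
    """

    stage_names: tuple[str, ...] = STAGE_NAMES_DEFAULT
    true_psi: dict[str, tuple[float, ...]] = field(default_factory=dict)
    nmd_efficiency: tuple[float, ...] = NMD_EFFICIENCY_DEFAULT
    ptc_bearing: dict[str, bool] = field(default_factory=dict)
    junction_structure: dict[str, tuple[int, int]] = field(default_factory=dict)
    sequencing_depth: float = 200.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_names) < 2:
            raise ValidationError("need at least two stages")
        if self.sequencing_depth <= 0:
            raise ValidationError("sequencing depth must be positive")
        if len(self.nmd_efficiency) != len(self.stage_names):
            raise ValidationError("one NMD efficiency per stage required")
        if any(not (0 <= e < 1) for e in self.nmd_efficiency):
            raise ValidationError("NMD efficiencies must lie in [0, 1)")
        for event_id, psis in self.true_psi.items():
            if len(psis) != len(self.stage_names):
                raise ValidationError(f"{event_id}: one PSI per stage required")
            if any(not (0 <= p <= 1) for p in psis):
                raise ValidationError(f"{event_id}: PSI outside [0, 1]")

    def effective_psi(self, event_id: str, stage_index: int) -> float:
        psi = self.true_psi[event_id][stage_index]
        if self.ptc_bearing.get(event_id, False):
            psi = psi * (1.0 - self.nmd_efficiency[stage_index])
        return psi


def simulate_junction_counts(series: StageSeries) -> list[JunctionCountRecord]:
    """Sample junction counts for every event at every stage.

    Reads are apportioned by per-junction isoform abundance: each of the
    ``n_inc`` inclusion junctions carries weight psi_eff and each of the
    ``n_skip`` skipping junctions weight (1 - psi_eff), so the total
    informative count has expectation ``sequencing_depth`` and the
    length-normalized PSI estimator is consistent for psi_eff.  Counts
    are multinomial across junctions; ``noise_cv`` adds optional
    log-normal depth jitter.
    """
    rng = np.random.default_rng(series.seed)
    records: list[JunctionCountRecord] = []
    for stage_index, stage in enumerate(series.stage_names):
        for event_id in series.true_psi:
            n_inc, n_skip = series.junction_structure.get(event_id, (2, 1))
            p = series.effective_psi(event_id, stage_index)
            w_inc, w_skip = n_inc * p, n_skip * (1.0 - p)
            p_inc = w_inc / (w_inc + w_skip) if (w_inc + w_skip) > 0 else 0.0
            depth = series.sequencing_depth
            if series.noise_cv > 0:
                depth *= rng.lognormal(
                    -0.5 * series.noise_cv**2, series.noise_cv
                )
            n = int(rng.poisson(depth)) if series.noise_cv > 0 else int(round(depth))
            inc_total = int(rng.binomial(n, p_inc))
            inc = rng.multinomial(inc_total, np.full(n_inc, 1.0 / n_inc))
            skip = rng.multinomial(n - inc_total, np.full(n_skip, 1.0 / n_skip))
            records.append(
                JunctionCountRecord(
                    event_id, stage, tuple(int(c) for c in inc),
                    tuple(int(c) for c in skip),
                )
            )
    return records


def default_mga_series(
    depth: float = 500.0, seed: int = 0, production_psi: float = 0.45
) -> StageSeries:
    """Stage series for the Mga-like fixture: constant production of the
    PTC-bearing variant, NMD suppressing it in spermatogonial stages."""
    return StageSeries(
        true_psi={"Mga_like:SE:novel": (production_psi,) * 5},
        ptc_bearing={"Mga_like:SE:novel": True},
        junction_structure={"Mga_like:SE:novel": (2, 1)},
        sequencing_depth=depth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# +/-inhibitor tables
# ---------------------------------------------------------------------------

def simulate_inhibitor_table(
    efficiencies: Mapping[str, float],
    n_replicates: int = 3,
    noise_cv: float = 0.1,
    base_abundance: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired +/-inhibitor abundances of a PTC-bearing transcript.

    Treated cells accumulate the full production level; untreated cells
    retain a (1 - efficiency) fraction.  Each measurement carries
    mean-preserving multiplicative log-normal noise of coefficient of
    variation ``noise_cv``.
    """
    rng = np.random.default_rng(seed)
    mu = -0.5 * noise_cv**2
    rows = []
    for stage, eff in efficiencies.items():
        if not (0 <= eff < 1):
            raise ValidationError(f"stage {stage}: efficiency outside [0, 1)")
        for rep in range(1, n_replicates + 1):
            treated = base_abundance * rng.lognormal(mu, noise_cv)
            untreated = base_abundance * (1.0 - eff) * rng.lognormal(mu, noise_cv)
            rows.append((stage, rep, 1, treated))
            rows.append((stage, rep, 0, untreated))
    return pd.DataFrame(rows, columns=["stage", "replicate", "treated", "abundance"])


# ---------------------------------------------------------------------------
# Random genes with random insertions (oracle fodder)
# ---------------------------------------------------------------------------

def make_random_gene_with_insertion(
    rng: np.random.Generator,
) -> tuple[GenomeSequence, TranscriptModel, GenomicInterval, tuple[DomainAnnotation, ...]]:
    """A random multi-exon coding gene plus a random intron-internal
    interval to insert as a novel exon.

    Strand, exon count, UTR layout, insertion intron/length/phase and
    exon content are all randomized, so translation consequences cover
    every category.
    """
    strand = "+" if rng.random() < 0.5 else "-"
    utr_first_exon = rng.random() < 0.2
    n_exons = int(rng.integers(3, 6))
    protein_len = int(rng.integers(60, 200))
    utr5 = _random_bases(rng, int(rng.integers(15, 60)))
    cds = _random_orf(rng, protein_len + 1)
    utr3 = _random_bases(rng, int(rng.integers(80, 200))) + _TRIFRAME_STOP_TAIL
    if utr_first_exon:
        utr5 = _random_bases(rng, int(rng.integers(60, 120)))
    mrna = utr5 + cds + utr3

    # cut the mRNA into n_exons pieces of >= 20 nt each; a UTR-only first
    # exon ends exactly at the 5'UTR boundary
    while True:
        if utr_first_exon:
            first = len(utr5)
            rest = sorted(rng.integers(first + 20, len(mrna) - 20, size=n_exons - 2))
            bounds = [0, first, *rest, len(mrna)]
        else:
            cuts = sorted(rng.integers(20, len(mrna) - 20, size=n_exons - 1))
            bounds = [0, *cuts, len(mrna)]
        if all(b - a >= 20 for a, b in zip(bounds, bounds[1:])):
            break
    exons = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = [_random_bases(rng, int(rng.integers(80, 400))) for _ in exons[:-1]]
    gene = assemble_gene(
        "ctg",
        "t1",
        "g1",
        exons,
        introns,
        cds_mrna_span=(len(utr5), len(utr5) + len(cds)),
        strand=strand,
        flank5=_random_bases(rng, 30),
        flank3=_random_bases(rng, 30),
    )
    intron_ivs = gene.transcript.introns()
    host = intron_ivs[int(rng.integers(0, len(intron_ivs)))]
    length = int(rng.integers(20, min(201, host.length - 2)))
    start = int(rng.integers(host.start + 1, host.end - length))
    novel = GenomicInterval(host.contig, start, start + length, strand)
    domains = (
        DomainAnnotation("domA", 5, int(rng.integers(10, protein_len // 2 + 1))),
        DomainAnnotation(
            "domB", int(rng.integers(protein_len // 2, protein_len)), protein_len
        ),
    )
    return gene.genome, gene.transcript, novel, domains


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

class SynthCohortConfig(BaseModel):
    """Configuration of a synthetic event cohort with planted fractions."""

    n_genes: int = Field(2000, gt=0)
    event_type_mixture: dict[str, float] = Field(
        default_factory=lambda: {
            "SE": 0.55, "RI": 0.15, "A5SS": 0.10, "A3SS": 0.10, "MXE": 0.10
        }
    )
    gain_loss_ratio: float = Field(2.0, ge=0)
    ptc_fraction_among_gains: float = Field(0.75, ge=0, le=1)
    maintained_fraction: float = Field(0.8, ge=0, le=1)
    noise_cv: float = Field(0.0, ge=0)
    sequencing_depth: float = Field(200.0, gt=0)
    psi_low: float = 0.12
    psi_high: float = 0.68
    psi_collapsed: float = 0.02
    stage_names: tuple[str, ...] = STAGE_NAMES_DEFAULT
    nmd_efficiency: tuple[float, ...] = NMD_EFFICIENCY_DEFAULT
    active_transition_index: int = ACTIVE_TRANSITION_DEFAULT
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthCohortConfig":
        total = sum(self.event_type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event type mixture sums to {total}, not 1")
        unknown = set(self.event_type_mixture) - {"SE", "RI", "A5SS", "A3SS", "MXE"}
        if unknown:
            raise ValueError(f"unknown event types {sorted(unknown)}")
        if self.ptc_fraction_among_gains > 0 and (
            self.event_type_mixture.get("SE", 0.0) == 0 or self.gain_loss_ratio == 0
        ):
            raise ValueError(
                "ptc_fraction_among_gains > 0 requires a non-zero rate of SE gains"
            )
        if not (
            0 <= self.active_transition_index < len(self.stage_names) - 1
        ):
            raise ValueError("active_transition_index out of range")
        return self


def _allocate(fractions: Mapping[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n items to labelled fractions."""
    labels = sorted(fractions)
    ideal = {lab: fractions[lab] * n for lab in labels}
    counts = {lab: int(np.floor(ideal[lab])) for lab in labels}
    short = n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: ideal[l] - counts[l], reverse=True)[
        :short
    ]:
        counts[lab] += 1
    out: list[str] = []
    for lab in labels:
        out.extend([lab] * counts[lab])
    return out


_JUNCTIONS_BY_TYPE = {
    "SE": (2, 1), "RI": (1, 1), "A5SS": (1, 1), "A3SS": (1, 1), "MXE": (2, 2)
}


@dataclass
class CohortBundle:
    """Everything simulate_cohort produced, with ground truth."""

    config: SynthCohortConfig
    truth: pd.DataFrame
    counts: list[JunctionCountRecord]
    series: StageSeries
    events: dict[str, SpliceEvent]
    genomes: dict[str, GenomeSequence]
    transcripts: dict[str, TranscriptModel]
    novel_exons: dict[str, GenomicInterval]
    domains: dict[str, tuple[DomainAnnotation, ...]]


def _make_gain_gene(
    rng: np.random.Generator, gene_id: str, ptc: bool
) -> tuple[GenomeSequence, TranscriptModel, GenomicInterval, tuple[DomainAnnotation, ...]]:
    """A compact three-exon gene whose second intron hosts a novel exon of
    controlled coding consequence (phase 0 at the insertion point)."""
    utr5 = _random_bases(rng, 30)
    cds = _random_orf(rng, 130)  # 120 + 120 + 147 + stop = 390 nt
    utr3 = _random_bases(rng, 48) + _TRIFRAME_STOP_TAIL
    mrna = utr5 + cds + utr3
    exons = [mrna[:150], mrna[150:270], mrna[270:]]
    if ptc:
        j = int(rng.integers(0, 16))
        novel = (
            "".join(rng.choice(_SAFE_CODONS, size=j))
            + str(rng.choice(["TAA", "TAG", "TGA"]))
            + _random_bases(rng, int(rng.integers(0, 90)))
        )
    else:
        m = int(rng.integers(10, 41))
        novel = "".join(rng.choice(_SAFE_CODONS, size=m))
    intron1 = _random_bases(rng, 120)
    intron2 = _random_bases(rng, 100) + novel + _random_bases(rng, 100)
    gene = assemble_gene(
        f"ctg_{gene_id}", f"{gene_id}.t1", gene_id,
        exons, [intron1, intron2],
        cds_mrna_span=(30, 420),
        flank5=_random_bases(rng, 20),
        flank3=_random_bases(rng, 20),
    )
    intron2_iv = gene.transcript.introns()[1]
    novel_iv = GenomicInterval(
        gene.genome.contig_name,
        intron2_iv.start + 100,
        intron2_iv.start + 100 + len(novel),
        "+",
    )
    domains = (
        DomainAnnotation("domN", 10, 60),
        DomainAnnotation("domC", 100, 125),
    )
    return gene.genome, gene.transcript, novel_iv, domains


def simulate_cohort(cfg: SynthCohortConfig) -> CohortBundle:
    """Simulate a cohort of splicing events with planted fractions.

    Every event switches PSI at the configured active stage transition
    (in the germ-cell series, splicing changes concentrate at the
    spermatogonia -> preleptotene transition).  SE events are gains
    or losses per ``gain_loss_ratio``; gains are PTC-bearing with
    probability ``ptc_fraction_among_gains`` and carry a sequence-backed
    gene model so their coding consequence is computable; events are
    maintained through later stages with probability
    ``maintained_fraction``.
    """
    rng = np.random.default_rng(cfg.seed)
    ti = cfg.active_transition_index
    n_stages = len(cfg.stage_names)
    lo, hi, col = cfg.psi_low, cfg.psi_high, cfg.psi_collapsed

    truth_rows = []
    true_psi: dict[str, tuple[float, ...]] = {}
    ptc_bearing: dict[str, bool] = {}
    junctions: dict[str, tuple[int, int]] = {}
    events: dict[str, SpliceEvent] = {}
    genomes: dict[str, GenomeSequence] = {}
    transcripts: dict[str, TranscriptModel] = {}
    novel_exons: dict[str, GenomicInterval] = {}
    domains: dict[str, tuple[DomainAnnotation, ...]] = {}

    # Planted attributes realize the configured fractions exactly (up to
    # rounding): category counts are allocated deterministically and then
    # shuffled across genes, so recovery error measures the pipeline, not
    # the generator's assignment noise.
    type_labels = _allocate(cfg.event_type_mixture, cfg.n_genes)
    rng.shuffle(type_labels)
    n_se = sum(1 for t in type_labels if t == "SE")
    p_gain = cfg.gain_loss_ratio / (1.0 + cfg.gain_loss_ratio)
    n_gain = int(round(n_se * p_gain))
    se_directions = ["gain"] * n_gain + ["loss"] * (n_se - n_gain)
    rng.shuffle(se_directions)
    n_ptc = int(round(n_gain * cfg.ptc_fraction_among_gains))
    gain_ptc = [True] * n_ptc + [False] * (n_gain - n_ptc)
    rng.shuffle(gain_ptc)
    n_maint = int(round(cfg.n_genes * cfg.maintained_fraction))
    maintained_flags = [True] * n_maint + [False] * (cfg.n_genes - n_maint)
    rng.shuffle(maintained_flags)

    se_i = gain_i = 0
    for i in range(cfg.n_genes):
        gene_id = f"G{i:05d}"
        etype = type_labels[i]
        event_id = f"{gene_id}:{etype}"
        maintained = maintained_flags[i]
        direction = "none"
        ptc = False
        if etype == "SE":
            direction = se_directions[se_i]
            se_i += 1
        if direction == "gain":
            ptc = gain_ptc[gain_i]
            gain_i += 1
            psis = [lo] * (ti + 1) + [hi] * (n_stages - ti - 1)
            if not maintained:
                psis = [lo] * (ti + 1) + [hi] + [col] * (n_stages - ti - 2)
        elif direction == "loss":
            psis = [hi] * (ti + 1) + [lo] * (n_stages - ti - 1)
            if not maintained:
                psis = [hi] * (ti + 1) + [lo] + [hi] * (n_stages - ti - 2)
        else:
            psis = [lo] * (ti + 1) + [hi] * (n_stages - ti - 1)
        true_psi[event_id] = tuple(psis)
        ptc_bearing[event_id] = ptc
        junctions[event_id] = _JUNCTIONS_BY_TYPE[etype]
        novel_iv = None
        if direction == "gain":
            genome, transcript, novel_iv, doms = _make_gain_gene(rng, gene_id, ptc)
            genomes[genome.contig_name] = genome
            transcripts[event_id] = transcript
            novel_exons[event_id] = novel_iv
            domains[gene_id] = doms
        events[event_id] = SpliceEvent(
            event_id=event_id, gene_id=gene_id, event_type=etype, novel_exon=novel_iv
        )
        truth_rows.append(
            {
                "event_id": event_id,
                "gene_id": gene_id,
                "event_type": etype,
                "direction": direction,
                "ptc": ptc,
                "maintained": maintained,
                **{f"psi_{s}": p for s, p in zip(cfg.stage_names, psis)},
            }
        )

    series = StageSeries(
        stage_names=cfg.stage_names,
        true_psi=true_psi,
        nmd_efficiency=cfg.nmd_efficiency,
        ptc_bearing=ptc_bearing,
        junction_structure=junctions,
        sequencing_depth=cfg.sequencing_depth,
        noise_cv=cfg.noise_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts = simulate_junction_counts(series)
    truth = pd.DataFrame(truth_rows).set_index("event_id")
    return CohortBundle(
        cfg, truth, counts, series, events, genomes, transcripts, novel_exons, domains
    )
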