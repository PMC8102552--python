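"""PSI estimation, Bayes-factor differential splicing, and AS event typing.

The percent-spliced-in (PSI, Greek Psi) of an exon is the fraction of a
gene's transcripts that include it, estimated from junction reads.  With
``n_inc`` inclusion-supporting junctions and ``n_skip`` skipping
junctions, each inclusion transcript contributes reads to every
inclusion junction, so counts are length-normalized per junction before
forming the ratio:

    i = sum(inclusion counts) / n_inc,  s = sum(skipping counts) / n_skip
    psi_hat = i / (i + s)

Inference is a conjugate Beta-Binomial on rounded effective counts
(k_eff = round(i), s_eff = round(s)): the posterior over Psi is
Beta(alpha0 + k_eff, beta0 + s_eff).  Differential splicing between two
samples is called by the Bayes factor of the independent-Psi model over
the shared-Psi model, both under Uniform(0, 1) priors:

    BF = B(kA+1, nA-kA+1) * B(kB+1, nB-kB+1) / B(kA+kB+1, nA+nB-kA-kB+1)

evaluated in log space.  Events with BF >= 10 are called differentially
spliced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .core import GenomicInterval, JunctionCountRecord, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

BF_THRESHOLD_DEFAULT = 10.0
MAINTENANCE_MARGIN_DEFAULT = 0.05

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass(frozen=True)
class PsiEstimate:
    event_id: str
    sample_id: str
    psi_hat: float | None
    posterior_alpha: float
    posterior_beta: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return self.psi_hat is not None

    @property
    def posterior_mean(self) -> float:
        return self.posterior_alpha / (self.posterior_alpha + self.posterior_beta)


@dataclass(frozen=True)
class DiffSpliceResult:
    event_id: str
    sample_a: str
    sample_b: str
    delta_psi: float | None
    bayes_factor: float
    significant: bool

    @property
    def log10_bf(self) -> float:
        return float(np.log10(self.bayes_factor))


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    event_type: str
    direction: str = "none"  # gain | loss | none
    novel_exon: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.direction not in ("gain", "loss", "none"):
            raise ValidationError(f"unknown direction {self.direction!r}")


# ---------------------------------------------------------------------------
# PSI estimation
# ---------------------------------------------------------------------------

def effective_counts(rec: JunctionCountRecord) -> tuple[int, int]:
    """Rounded length-normalized (inclusion, skipping) effective counts."""
    i = sum(rec.inclusion_counts) / len(rec.inclusion_counts)
    s = sum(rec.skipping_counts) / len(rec.skipping_counts)
    return int(np.rint(i)), int(np.rint(s))


def estimate_psi(
    rec: JunctionCountRecord,
    prior_alpha: float = 1.0,
    prior_beta: float = 1.0,
) -> PsiEstimate:
    """Length-normalized PSI point estimate with a Beta posterior.

    When no informative reads exist on either side, psi_hat is undefined
    and the posterior equals the prior.  The credible interval is the
    central 95% posterior interval, switching to the one-sided convention
    when an effective count is zero (so the interval always brackets the
    point estimate).
    """
    i = sum(rec.inclusion_counts) / len(rec.inclusion_counts)
    s = sum(rec.skipping_counts) / len(rec.skipping_counts)
    k_eff, s_eff = effective_counts(rec)
    a = prior_alpha + k_eff
    b = prior_beta + s_eff
    if i + s == 0:
        logger.debug("%s/%s: no informative reads", rec.event_id, rec.sample_id)
        lo, hi = beta_dist.ppf([0.025, 0.975], prior_alpha, prior_beta)
        return PsiEstimate(
            rec.event_id, rec.sample_id, None, prior_alpha, prior_beta,
            float(lo), float(hi),
        )
    psi_hat = i / (i + s)
    if k_eff == 0:
        lo, hi = 0.0, float(beta_dist.ppf(0.95, a, b))
    elif s_eff == 0:
        lo, hi = float(beta_dist.ppf(0.05, a, b)), 1.0
    else:
        lo, hi = (float(x) for x in beta_dist.ppf([0.025, 0.975], a, b))
    return PsiEstimate(rec.event_id, rec.sample_id, psi_hat, a, b, lo, hi)


# ---------------------------------------------------------------------------
# Bayes-factor differential splicing
# ---------------------------------------------------------------------------

def log_bayes_factor(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Natural-log Bayes factor, independent-Psi vs shared-Psi, Uniform
    priors; binomial coefficients cancel between the two marginals."""
    return float(
        betaln(k_a + 1, n_a - k_a + 1)
        + betaln(k_b + 1, n_b - k_b + 1)
        - betaln(k_a + k_b + 1, n_a + n_b - k_a - k_b + 1)
    )


def bayes_factor_diff(
    rec_a: JunctionCountRecord,
    rec_b: JunctionCountRecord,
    bf_threshold: float = BF_THRESHOLD_DEFAULT,
) -> DiffSpliceResult:
    """Call differential splicing between two samples of one event."""
    if rec_a.event_id != rec_b.event_id:
        raise ValidationError(
            f"records describe different events: {rec_a.event_id} vs {rec_b.event_id}"
        )
    if bf_threshold <= 0:
        raise ValidationError("bf_threshold must be positive")
    ka, sa = effective_counts(rec_a)
    kb, sb = effective_counts(rec_b)
    na, nb = ka + sa, kb + sb
    if na == 0 and nb == 0:
        return DiffSpliceResult(
            rec_a.event_id, rec_a.sample_id, rec_b.sample_id, None, 1.0, False
        )
    bf = float(np.exp(log_bayes_factor(ka, na, kb, nb)))
    psi_a = estimate_psi(rec_a).psi_hat
    psi_b = estimate_psi(rec_b).psi_hat
    delta = None if psi_a is None or psi_b is None else psi_b - psi_a
    return DiffSpliceResult(
        rec_a.event_id, rec_a.sample_id, rec_b.sample_id, delta, bf,
        bf >= bf_threshold,
    )


# ---------------------------------------------------------------------------
# AS event enumeration
# ---------------------------------------------------------------------------

def _chain(t: TranscriptModel) -> tuple[tuple[int, int], ...]:
    return tuple((iv.start, iv.end) for iv in t.intervals)


def _pair_events(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[str, tuple, GenomicInterval | None]]:
    """Typed events distinguishing two exon chains; returns
    (event_type, coordinate signature, variable exon) triples."""
    strand = t1.strand
    contig = t1.contig
    ex1, ex2 = _chain(t1), _chain(t2)
    in1 = {(a[1], b[0]) for a, b in zip(ex1, ex1[1:])}
    in2 = {(a[1], b[0]) for a, b in zip(ex2, ex2[1:])}
    events: list[tuple[str, tuple, GenomicInterval | None]] = []

    def internal(exons: tuple) -> Iterable[tuple[int, int, int, int]]:
        # (flank donor boundary d, exon start, exon end, flank acceptor a)
        for prev, exon, nxt in zip(exons, exons[1:], exons[2:]):
            yield prev[1], exon[0], exon[1], nxt[0]

    # SE: cassette exon in one chain, direct d->a junction in the other.
    for (exa, exb, other_introns) in ((ex1, ex2, in2), (ex2, ex1, in1)):
        for d, s, t, a in internal(exa):
            if (d, a) in other_introns:
                events.append(
                    ("SE", ("SE", s, t, d, a), GenomicInterval(contig, s, t, strand))
                )

    # RI: intron of one chain fully covered by a single exon of the other.
    for introns, exons in ((in1, ex2), (in2, ex1)):
        for x, y in introns:
            if any(u < x and v > y for u, v in exons):
                events.append(("RI", ("RI", x, y), None))

    # Alternative 5'/3' splice sites: introns sharing one boundary whose
    # varying boundary belongs to exons sharing their other boundary
    # (the flank-sharing guard keeps SE/MXE flanks from re-reporting).
    ends1 = {(u, v) for u, v in ex1}
    ends2 = {(u, v) for u, v in ex2}
    for x1, y in in1:
        for x2, y2 in in2:
            if y == y2 and x1 != x2:
                # varying exon end (genomic): donor side on '+'
                if any(
                    (u, x1) in ends1 and (u, x2) in ends2
                    for u in {e[0] for e in ex1 if e[1] == x1}
                ):
                    etype = "A5SS" if strand == "+" else "A3SS"
                    sig = (etype, min(x1, x2), max(x1, x2), y, "end")
                    events.append((etype, sig, None))
            if x1 == x2 and y != y2:
                # varying exon start (genomic): acceptor side on '+'
                if any(
                    (y, v) in ends1 and (y2, v) in ends2
                    for v in {e[1] for e in ex1 if e[0] == y}
                ):
                    etype = "A3SS" if strand == "+" else "A5SS"
                    sig = (etype, x1, min(y, y2), max(y, y2), "start")
                    events.append((etype, sig, None))

    # MXE: single internal exons of each chain sharing both flank
    # junction boundaries but mutually non-overlapping.
    for d1, s1, t1e, a1 in internal(ex1):
        for d2, s2, t2e, a2 in internal(ex2):
            if d1 == d2 and a1 == a2 and (t1e <= s2 or t2e <= s1):
                lo, hi = sorted([(s1, t1e), (s2, t2e)])
                events.append(("MXE", ("MXE", *lo, *hi), None))
    return events


def enumerate_as_events(transcripts: Sequence[TranscriptModel]) -> list[SpliceEvent]:
    """Pairwise comparison of a gene's transcripts into typed events.

    Event types follow the five classic alternative-splicing classes
    (cassette/skipped exon, retained intron, alternative 5'/3' splice
    site, mutually exclusive exons); A5SS/A3SS labels are strand-aware.
    Duplicate events across transcript pairs are deduplicated by
    coordinates.
    """
    if len(transcripts) < 2:
        return []
    gene_id = transcripts[0].gene_id
    for t in transcripts:
        if t.gene_id != gene_id:
            raise ValidationError("transcripts belong to different genes")
    seen: set[tuple] = set()
    out: list[SpliceEvent] = []
    for t1, t2 in combinations(transcripts, 2):
        for etype, sig, novel in _pair_events(t1, t2):
            if sig in seen:
                continue
            seen.add(sig)
            coord = "_".join(str(x) for x in sig[1:])
            out.append(
                SpliceEvent(
                    event_id=f"{gene_id}:{etype}:{coord}",
                    gene_id=gene_id,
                    event_type=etype,
                    novel_exon=novel,
                )
            )
    out.sort(key=lambda e: e.event_id)
    return out


# ---------------------------------------------------------------------------
# Direction, stage tallies, persistence, overlaps
# ---------------------------------------------------------------------------

def classify_gain_loss(event: SpliceEvent, diff: DiffSpliceResult) -> SpliceEvent:
    """Set exon gain/loss direction from the sign of delta-PSI (later
    stage minus earlier) of a significant SE event."""
    if event.event_type != "SE":
        logger.warning(
            "%s: gain/loss direction applies to SE events only", event.event_id
        )
        return replace(event, direction="none")
    if not diff.significant or diff.delta_psi is None or diff.delta_psi == 0:
        return replace(event, direction="none")
    return replace(event, direction="gain" if diff.delta_psi > 0 else "loss")


def tally_frequencies(
    calls: Iterable[tuple[str, SpliceEvent, DiffSpliceResult]]
) -> pd.DataFrame:
    """Per-transition tallies of significant events.

    ``calls`` yields (transition label, typed event, diff result)
    triples; the returned frame has one row per transition with counts
    and fractions per event type (fractions sum to 1 over significant
    events), gain/loss counts among SE events and their ratio.
    Transitions with zero significant events are flagged and carry NaN
    fractions.
    """
    rows: dict[str, dict] = {}
    for transition, event, diff in calls:
        row = rows.setdefault(
            transition,
            {f"n_{t}": 0 for t in EVENT_TYPES}
            | {"n_significant": 0, "n_gain": 0, "n_loss": 0},
        )
        if not diff.significant:
            continue
        row["n_significant"] += 1
        row[f"n_{event.event_type}"] += 1
        if event.event_type == "SE":
            directed = classify_gain_loss(event, diff)
            if directed.direction == "gain":
                row["n_gain"] += 1
            elif directed.direction == "loss":
                row["n_loss"] += 1
    table = []
    for transition, row in rows.items():
        n = row["n_significant"]
        rec = {"transition": transition, **row, "flagged_empty": n == 0}
        for t in EVENT_TYPES:
            rec[f"frac_{t}"] = row[f"n_{t}"] / n if n else np.nan
        rec["gain_loss_ratio"] = (
            row["n_gain"] / row["n_loss"] if row["n_loss"] else np.nan
        )
        table.append(rec)
    return pd.DataFrame(table).set_index("transition")


def persistence(
    psi_by_stage: Sequence[PsiEstimate],
    transition_index: int,
    maintenance_margin: float = MAINTENANCE_MARGIN_DEFAULT,
) -> bool:
    """Whether an event keeps its switched state through all later stages.

    ``psi_by_stage`` is one estimate per stage in stage order;
    ``transition_index`` indexes the pre-transition stage, so the switch
    happens between stages ``transition_index`` and
    ``transition_index + 1``.  True iff every later stage has a defined
    PSI on the post-transition side of the pre-transition baseline by at
    least ``maintenance_margin``.
    """
    if not (0 <= transition_index < len(psi_by_stage) - 1):
        raise ValidationError("transition_index out of range")
    pre = psi_by_stage[transition_index]
    post = psi_by_stage[transition_index + 1]
    if not pre.defined or not post.defined:
        logger.info("persistence undefined: PSI missing at the transition")
        return False
    side = np.sign(post.psi_hat - pre.psi_hat)
    if side == 0:
        return False
    for est in psi_by_stage[transition_index + 1 :]:
        if not est.defined:
            logger.info("persistence false: undefined PSI at %s", est.sample_id)
            return False
        if side * (est.psi_hat - pre.psi_hat) < maintenance_margin:
            return False
    return True


def diff_adjacent_stages(
    records: Sequence[JunctionCountRecord],
    stage_order: Sequence[str],
    bf_threshold: float = BF_THRESHOLD_DEFAULT,
) -> list[tuple[str, DiffSpliceResult]]:
    """Differential-splicing calls for every event at every adjacent
    stage transition; transitions are labelled ``earlier->later``."""
    by_event: dict[str, dict[str, JunctionCountRecord]] = {}
    for r in records:
        by_event.setdefault(r.event_id, {})[r.sample_id] = r
    out = []
    for event_id in sorted(by_event):
        samples = by_event[event_id]
        for a, b in zip(stage_order, stage_order[1:]):
            if a in samples and b in samples:
                out.append(
                    (
                        f"{a}->{b}",
                        bayes_factor_diff(samples[a], samples[b], bf_threshold),
                    )
                )
    return out


def overlap_sets(gene_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exact intersection cardinalities for every non-empty combination
    of named gene sets (Venn counts)."""
    if len(gene_sets) < 2:
        raise ValidationError("need at least two named sets")
    names = sorted(gene_sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set(gene_sets[combo[0]])
            for name in combo[1:]:
                inter &= set(gene_sets[name])
            out[frozenset(combo)] = len(inter)
    return out
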