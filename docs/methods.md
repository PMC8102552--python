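# Methods

This note documents the models, estimators, and numerical conventions
behind `splicegain`, together with what the synthetic generators do and
do not emulate.

## Problem setting

During male germ-cell development, alternative splicing peaks at the
transition from spermatogonia to preleptotene spermatocytes. Inclusion
of a novel intron-internal exon can insert a premature termination
codon (PTC) into a transcript; whether the truncated message survives
depends on the cell's nonsense-mediated decay (NMD) activity, which is
high in spermatogonia and nearly absent in meiotic spermatocytes and
round spermatids. The package models this chain end to end: nominate
novel exons from splice-site score tracks, quantify their inclusion
across a staged cell series, call differential splicing, translate the
variant transcript, and predict and estimate NMD.

## Coordinates and sequence handling

All internal coordinates are 0-based half-open on the forward genomic
strand; GFF3 I/O converts from 1-based inclusive at the file boundary.
Exons are stored in genomic order; transcription order is derived from
the strand where needed. `N` bases are permitted in genomes; a codon
containing `N` translates to `X` and never counts as a stop. Stop
codons are TAA, TAG, TGA on the mRNA-sense strand.

## Candidate screening

A score track gives each position an acceptor and a donor probability
in [0, 1] (SpliceAI-style output is consumed, never computed). Within
each annotated intron, every acceptor/donor position pair with both
scores >= `min_score` (default 0.1), the acceptor upstream of the donor
in transcription order, and an implied exon length in
[`min_len`, `max_len`] (defaults 25/500 nt, generous around the 145-nt
motivating case) becomes a candidate. Candidates must lie strictly
inside the intron, which automatically excludes annotated exon
boundaries; all overlapping pairs are reported rather than a greedy
best. The score band of a pair is decided by its *weaker* score — an
exon needs both sites — with >= 0.9 labelled constitutive, [0.1, 0.9)
alternative, and < 0.1 rejected. GT/AG dinucleotide checking is
deliberately not performed; the score track is treated as the sole
evidence for splice-site quality.

## PSI estimation

For an event with `n_inc` inclusion junctions and `n_skip` skipping
junctions, counts are length-normalized per junction,
`i = sum(inc)/n_inc`, `s = sum(skip)/n_skip`, and the point estimate is
`psi_hat = i/(i+s)` (undefined when no informative reads exist). A full
MCMC over read assignments is replaced by a conjugate Beta–Binomial on
rounded effective counts `k_eff = round(i)`, `s_eff = round(s)`:
posterior `Beta(alpha0 + k_eff, beta0 + s_eff)` with a uniform prior by
default. This keeps the estimator closed-form and exactly testable
while preserving the decision semantics. The 95% credible interval is
the central posterior interval; when an effective count is zero the
one-sided convention is used (`[0, q95]` or `[q05, 1]`) so the interval
always brackets the point estimate — the standard boundary behaviour of
binomial intervals. Rounding uses `numpy.rint` (ties to even).

## Differential splicing

Two samples of one event are compared by the Bayes factor of the
independent-PSI model over the shared-PSI model, both with Uniform(0,1)
priors over PSI. With effective counts (k_A, n_A) and (k_B, n_B):

    BF = B(k_A+1, n_A-k_A+1) · B(k_B+1, n_B-k_B+1)
         / B(k_A+k_B+1, n_A+n_B-k_A-k_B+1)

evaluated in log space with `scipy.special.betaln` (the binomial
coefficients cancel). BF >= 10 calls an event differentially spliced;
with no data in either sample BF = 1. ΔPSI is the later-stage PSI minus
the earlier-stage PSI; among significant cassette (SE) events,
ΔPSI > 0 is an exon gain and ΔPSI < 0 a loss. The test suite verifies
the closed form against direct Gauss–Legendre quadrature of both
marginal likelihoods (64 nodes are exact for these polynomial
integrands up to n = 30).

## Event typing

Two transcripts of a gene are compared by their exon chains; events are
found by explicit patterns: SE (cassette exon with its flank junctions
against the direct junction), RI (an intron strictly covered by a
single exon of the other isoform), A5SS/A3SS (intron pairs sharing one
boundary whose varying boundary belongs to exons sharing their other
boundary — this flank-sharing guard keeps SE and MXE flanks from being
re-reported as alternative splice sites), and MXE (single internal
exons sharing both flank junction boundaries but mutually
non-overlapping). Labels are strand-aware: a varying genomic exon end
is the donor side on `+` (A5SS) and the acceptor side on `-` (A3SS).
Events are deduplicated by coordinates across transcript pairs.
Patterns not matching any of the five classes (e.g. overlapping
non-boundary-sharing exon pairs) are intentionally not typed.

## ORF consequence

The candidate exon is inserted between its flanking exons, the variant
mRNA is spliced, and translation starts at the canonical start codon
mapped into variant coordinates. The first in-frame stop decides the
category:

- third base inside the novel exon → `ptc_in_novel_exon`;
  `added_codons_before_stop` counts the complete codons whose third
  base lies within the exon ahead of the stop, so a junction-spanning
  codon is not counted;
- coinciding with the canonical stop → `in_frame_addition` (requires
  exon length ≡ 0 mod 3 by construction);
- anywhere else → `frameshift_ptc`.

Insertions wholly upstream of the start codon or downstream of the
canonical stop are `no_change`; an insertion that disrupts the start
codon itself is reported as `no_change` with a warning. A transcript
whose shifted frame reaches the 3' end without any stop raises an
error rather than guessing (the synthetic generators terminate every
frame within the transcript). `truncated_protein_length` counts
residues before the stop; a domain is reported lost iff its 1-based
`aa_end` exceeds that length. For PTC-bearing exons that add a few
codons before the stop this is a slightly conservative comparison (the
added residues count toward the length), which matters only for
domains ending within that handful of residues.

## NMD

A PTC-bearing transcript is predicted NMD-sensitive iff the stop codon
ends strictly more than `rule_distance` = 50 nt upstream of the final
exon–exon junction of the spliced variant; a stop in the last exon
escapes. Stage-wise NMD efficiency is estimated from paired
±translation-inhibitor endpoint measurements as
`1 − abundance_untreated / abundance_treated`, clipped at 0 to absorb
noise, replicates averaged within stage × treatment; no decay kinetics
are modelled because only endpoint comparisons are available. Stages
with efficiency below 0.2 are flagged low-NMD.

## Synthetic data

`make_mga_fixture` builds a condensed three-exon analog of a large
transcription-factor gene: 2,500-bp contig, 840-nt CDS (279-residue
protein), a 145-nt exon planted in the second intron whose incoming
frame (phase 0) carries five non-stop codons then TAA, a T-box-like
domain upstream of the insertion point and a bHLHZ-like domain
downstream, and a score track with >0.9 scores at annotated boundaries,
0.695/0.761 at the planted exon, and sub-0.1 background. Everything is
deterministic per seed.

`simulate_junction_counts` samples reads by per-junction isoform
abundance: each inclusion junction carries weight psi_eff and each
skipping junction weight (1 − psi_eff), counts are multinomial over
junctions with the total at the configured depth (expected informative
reads per event; default 200, a realistic bulk junction yield), so the
length-normalized estimator is consistent for psi_eff. NMD acts
multiplicatively on the PTC-bearing isoform's sampling probability,
psi_eff = psi · (1 − nmd_efficiency) — a steady-state abundance view.
Stage defaults are the five-stage germ-cell series with NMD efficiency
0.75 in both spermatogonial stages and 0 in the meiotic and
post-meiotic stages. Optional log-normal depth jitter is available via
`noise_cv`; counts are otherwise binomial/multinomial without
overdispersion.

`simulate_cohort` plants event-type mixture (default SE 0.55, RI 0.15,
A5SS/A3SS/MXE 0.10 each), gain:loss 2:1 among SE, PTC in 75% of gains,
and 80% maintenance, with every event switching PSI 0.12 ↔ 0.68 at the
spermatogonia → preleptotene transition (non-maintained events revert
at the following stage; collapsed gains fall to 0.02). Category
attributes are allocated by largest-remainder rounding and shuffled
across genes, so planted fractions are realized exactly and recovery
error measures the pipeline rather than generator assignment noise.
Every gain event carries a compact sequence-backed gene so its coding
consequence is computable from sequence, not from a label.

What the generators do *not* emulate: read-level errors and mapping
ambiguity, exon-body (non-junction) evidence, overdispersion between
biological replicates, multi-isoform genes beyond two isoforms per
event, and transcriptome-wide co-regulation. Passing recovery tests
therefore demonstrates correctness of the estimators and decision
rules under the stated sampling model, not robustness to alignment
artefacts in real data.

## Persistence and summaries

An event significant at a transition is "maintained" iff every later
stage keeps a defined PSI on the post-transition side of the
pre-transition baseline by at least `maintenance_margin` = 0.05.
Stage-transition tallies count significant events per type (fractions
over significant events sum to 1 per transition) and the gain:loss
ratio among SE events; transitions with no significant events are
flagged. Gene-set overlaps are exact intersection cardinalities for
every combination of named sets.

## Known limitations

- The Bayes-factor model (independent vs shared PSI under uniform
  priors) is a deliberate, testable stand-in for MCMC-based isoform
  assignment; absolute BF values are not comparable to other tools,
  only the threshold semantics.
- The PSI recovery rate achievable at a given depth is bounded by
  binomial sampling noise (sd ≈ 0.035 at PSI = 0.5 and 200 informative
  reads); calibration statements in the test suite should be read
  against that bound.
- The 50-nt rule is the only NMD branch modelled; long-3'UTR-triggered
  NMD and UPF-protein regulation are out of scope.
- Domain loss is assessed by truncation length only, not by partial
  domain disruption.
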