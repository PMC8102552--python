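"""PSI estimation, Bayes-factor calls, event typing, and stage summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicegain.core import GenomicInterval, JunctionCountRecord, ValidationError
from splicegain.quant import (
    DiffSpliceResult,
    SpliceEvent,
    _pair_events,
    bayes_factor_diff,
    classify_gain_loss,
    diff_adjacent_stages,
    enumerate_as_events,
    estimate_psi,
    log_bayes_factor,
    overlap_sets,
    persistence,
    tally_frequencies,
)
from splicegain.synth import StageSeries, simulate_junction_counts

from .oracles import as_event_signatures_oracle, bayes_factor_numeric
from .test_core import toy_transcript


def rec(inc, skip, event="e", sample="s"):
    return JunctionCountRecord(event, sample, tuple(inc), tuple(skip))


class TestEstimatePsi:
    def test_length_normalized_ratio(self):
        # two inclusion junctions vs one skipping junction:
        # (20/2) / ((20/2) + (10/1)) = 0.5
        est = estimate_psi(rec([10, 10], [10]))
        assert est.psi_hat == pytest.approx(0.5)
        assert est.posterior_alpha == 11 and est.posterior_beta == 11
        assert est.ci_low <= est.psi_hat <= est.ci_high

    def test_no_inclusion_evidence_gives_zero(self):
        est = estimate_psi(rec([0, 0], [30]))
        assert est.psi_hat == 0.0
        assert est.ci_low == 0.0  # boundary convention brackets the estimate

    def test_all_zero_counts_is_undefined_with_prior_posterior(self):
        est = estimate_psi(rec([0, 0], [0]))
        assert not est.defined
        assert (est.posterior_alpha, est.posterior_beta) == (1, 1)

    def test_posterior_mean_converges_to_truth(self):
        # consistency of the Beta posterior at high depth
        rng_seed = 7
        for psi in (0.1, 0.3, 0.5, 0.7, 0.9):
            series = StageSeries(
                stage_names=("a", "b"),
                true_psi={"e": (psi, psi)},
                nmd_efficiency=(0.0, 0.0),
                junction_structure={"e": (2, 1)},
                sequencing_depth=2000,
                seed=rng_seed,
            )
            errs = []
            for rep in range(100):
                series.seed = rng_seed + rep
                r = simulate_junction_counts(series)[0]
                errs.append(abs(estimate_psi(r).posterior_mean - psi))
            assert np.mean(np.array(errs) <= 0.05) >= 0.95


class TestBayesFactor:
    def test_no_data_cannot_discriminate(self):
        d = bayes_factor_diff(rec([0, 0], [0]), rec([0], [0, 0]))
        assert d.bayes_factor == 1.0 and not d.significant

    def test_opposite_extremes_give_bf_77(self):
        # (k, n) = (5, 5) vs (0, 5): closed form is exactly 77
        d = bayes_factor_diff(rec([5], [0]), rec([0], [5]))
        assert d.bayes_factor == pytest.approx(77.0, rel=1e-9)
        assert d.significant

    def test_identical_data_favor_shared_model(self):
        d = bayes_factor_diff(rec([5], [5]), rec([5], [5]))
        assert d.bayes_factor == pytest.approx(0.505, abs=0.001)
        assert not d.significant

    def test_mismatched_events_rejected(self):
        with pytest.raises(ValidationError):
            bayes_factor_diff(rec([1], [1], event="a"), rec([1], [1], event="b"))

    def test_closed_form_matches_quadrature_on_a_grid(self):
        for na, nb in itertools.product((0, 1, 3, 8, 12), repeat=2):
            for ka in range(na + 1):
                for kb in range(nb + 1):
                    exact = np.exp(log_bayes_factor(ka, na, kb, nb))
                    numeric = bayes_factor_numeric(ka, na, kb, nb)
                    assert exact == pytest.approx(numeric, rel=1e-9)

    @given(
        k=st.integers(0, 30),
        n=st.integers(1, 30),
        k2=st.integers(0, 30),
        n2=st.integers(1, 30),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_symmetry_and_shared_data_bound(self, k, n, k2, n2):
        k, k2 = min(k, n), min(k2, n2)
        assert log_bayes_factor(k, n, k2, n2) == pytest.approx(
            log_bayes_factor(k2, n2, k, n)
        )
        # identical samples can never favor the independent model
        assert log_bayes_factor(k, n, k, n) <= 1e-12


def se_pair():
    a = toy_transcript([(0, 10), (20, 30), (40, 50)])
    b = toy_transcript([(0, 10), (40, 50)])
    return a, b


class TestEnumerateEvents:
    def test_cassette_exon_is_se_with_the_variable_exon(self):
        events = enumerate_as_events(se_pair())
        assert [e.event_type for e in events] == ["SE"]
        assert events[0].novel_exon == GenomicInterval("c", 20, 30, "+")

    def test_retained_intron(self):
        a = toy_transcript([(0, 10), (20, 30)])
        b = toy_transcript([(0, 30)])
        events = enumerate_as_events([a, b])
        assert [e.event_type for e in events] == ["RI"]

    def test_minus_strand_shifted_genomic_start_is_a5ss(self):
        # varying exon start = varying intron end; on '-' that is the
        # donor side, so the event is an alternative 5' splice site
        a = toy_transcript([(0, 10), (20, 30)], strand="-")
        b = toy_transcript([(0, 10), (24, 30)], strand="-")
        events = enumerate_as_events([a, b])
        assert [e.event_type for e in events] == ["A5SS"]
        plus = enumerate_as_events(
            [toy_transcript([(0, 10), (20, 30)]), toy_transcript([(0, 10), (24, 30)])]
        )
        assert [e.event_type for e in plus] == ["A3SS"]

    def test_mutually_exclusive_exons(self):
        a = toy_transcript([(0, 10), (20, 30), (60, 70)])
        b = toy_transcript([(0, 10), (40, 50), (60, 70)])
        events = enumerate_as_events([a, b])
        assert [e.event_type for e in events] == ["MXE"]

    def test_single_transcript_gene_has_no_events(self):
        assert enumerate_as_events([se_pair()[0]]) == []

    def test_exhaustive_agreement_with_definition_oracle(self):
        # all pairs of exon chains (<= 4 exons) over 8 boundary positions,
        # on both strands
        positions = [0, 10, 20, 30, 40, 50, 60, 70]
        chains = []
        for r in (2, 4, 6, 8):
            for combo in itertools.combinations(positions, r):
                chains.append(tuple(zip(combo[::2], combo[1::2])))
        assert len(chains) == 127
        for strand in "+-":
            for c1, c2 in itertools.combinations_with_replacement(chains, 2):
                t1 = toy_transcript(list(c1), strand)
                t2 = toy_transcript(list(c2), strand)
                got = {sig for _, sig, _ in _pair_events(t1, t2)}
                assert got == as_event_signatures_oracle(t1, t2), (c1, c2, strand)


class TestDirectionAndTallies:
    def diff(self, delta, bf):
        return DiffSpliceResult("e", "a", "b", delta, bf, bf >= 10)

    def test_sign_rule(self):
        ev = SpliceEvent("e", "g", "SE")
        assert classify_gain_loss(ev, self.diff(+0.6, 50)).direction == "gain"
        assert classify_gain_loss(ev, self.diff(-0.6, 50)).direction == "loss"
        assert classify_gain_loss(ev, self.diff(+0.6, 2)).direction == "none"

    def test_non_se_event_keeps_none_direction(self, caplog):
        ev = SpliceEvent("e", "g", "RI")
        assert classify_gain_loss(ev, self.diff(0.6, 50)).direction == "none"

    def test_tally_counts_types_and_gain_loss(self):
        calls = [
            ("t1", SpliceEvent("e1", "g1", "SE"), self.diff(0.5, 100)),
            ("t1", SpliceEvent("e2", "g2", "SE"), self.diff(-0.5, 100)),
            ("t1", SpliceEvent("e3", "g3", "SE"), self.diff(0.5, 100)),
            ("t1", SpliceEvent("e4", "g4", "RI"), self.diff(0.5, 100)),
            ("t1", SpliceEvent("e5", "g5", "MXE"), self.diff(0.5, 2)),
            ("t2", SpliceEvent("e1", "g1", "SE"), self.diff(0.1, 1)),
        ]
        tab = tally_frequencies(calls)
        row = tab.loc["t1"]
        assert row.n_significant == 4
        assert row.frac_SE == pytest.approx(0.75)
        assert row.n_gain == 2 and row.n_loss == 1
        assert row.gain_loss_ratio == pytest.approx(2.0)
        assert bool(tab.loc["t2"].flagged_empty)
        assert np.isnan(tab.loc["t2"].frac_SE)


def est(psi, sample="s"):
    from splicegain.quant import PsiEstimate

    if psi is None:
        return PsiEstimate("e", sample, None, 1, 1, 0.02, 0.98)
    return PsiEstimate("e", sample, psi, 1, 1, max(0, psi - 0.1), min(1, psi + 0.1))


class TestPersistence:
    def test_maintained_gain(self):
        assert persistence([est(0.1), est(0.1), est(0.7), est(0.7), est(0.6)], 1)

    def test_collapsed_gain(self):
        assert not persistence([est(0.1), est(0.1), est(0.7), est(0.12), est(0.1)], 1)

    def test_undefined_later_psi_fails(self):
        assert not persistence([est(0.1), est(0.1), est(0.7), est(None), est(0.7)], 1)

    def test_maintained_loss(self):
        assert persistence([est(0.8), est(0.8), est(0.2), est(0.25), est(0.2)], 1)


class TestOverlapSets:
    def test_disjoint_sets(self):
        out = overlap_sets({"a": {"x", "y"}, "b": {"z"}, "c": {"w"}})
        assert out[frozenset({"a", "b"})] == 0
        assert out[frozenset({"a", "b", "c"})] == 0

    def test_identical_sets(self):
        out = overlap_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        assert out[frozenset({"a", "b"})] == 2

    def test_planted_overlap_recovered(self):
        shared = {f"s{i}" for i in range(7)}
        out = overlap_sets(
            {"a": shared | {"a1", "a2"}, "b": shared | {"b1"}}
        )
        assert out[frozenset({"a", "b"})] == 7

    def test_needs_two_sets(self):
        with pytest.raises(ValidationError):
            overlap_sets({"a": set()})


class TestDiffAdjacentStages:
    def test_transitions_are_labelled_and_ordered(self, mga_counts):
        calls = diff_adjacent_stages(
            mga_counts, ("SG_und", "SG_diff", "SC_preL", "SC_pachy", "RS")
        )
        labels = [t for t, _ in calls]
        assert labels == [
            "SG_und->SG_diff",
            "SG_diff->SC_preL",
            "SC_preL->SC_pachy",
            "SC_pachy->RS",
        ]
        sig = {t: d.significant for t, d in calls}
        assert sig["SG_diff->SC_preL"]
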