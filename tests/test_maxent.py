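"""Maximum-entropy splice-site model: closed forms, IPF recovery, entropy."""

import itertools
import math

import numpy as np
import pytest

from splicescreen import (
    ACCEPTOR_SPEC,
    DONOR_SPEC,
    ExonRecord,
    SiteWindowSpec,
    SpliceSiteModel,
    classify_strength,
    extract_site_window,
    train_maxent,
)
from splicescreen.errors import FlankTooShortError
from splicescreen.maxent import (
    adjacent_pair_constraints,
    empirical_marginals,
    encode_windows,
    singleton_constraints,
)
from splicescreen.motifs import BASE_INDEX
from splicescreen import simulate as sim

from conftest import random_seq


def wmm_log_odds(windows, query, pseudocount=0.5):
    """Independent closed-form weight-matrix oracle (uniform background)."""
    width = len(query)
    counts = np.zeros((width, 4))
    for w in windows:
        for j, c in enumerate(w):
            counts[j, BASE_INDEX[c]] += 1
    counts += pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return sum(math.log2(probs[j, BASE_INDEX[c]] / 0.25)
               for j, c in enumerate(query))


class TestWindowExtraction:
    def test_acceptor_concatenates_intron_tail_and_exon_head(self):
        rec = ExonRecord("x", "CCCAAA", upstream_flank="GGGTTTAG")
        spec = SiteWindowSpec("acceptor", exonic_len=3, intronic_len=5)
        assert extract_site_window(rec, "acceptor", spec) == "TTTAGCCC"

    def test_donor_concatenates_exon_tail_and_intron_head(self):
        rec = ExonRecord("x", "CCCAAG", downstream_flank="GTAAGTCCC")
        assert extract_site_window(rec, "donor", DONOR_SPEC) == "AAGGTAAGT"

    def test_short_flank_error_names_deficit(self):
        rec = ExonRecord("x", "CCCAAG", downstream_flank="GTAA")
        with pytest.raises(FlankTooShortError) as exc:
            extract_site_window(rec, "donor", DONOR_SPEC)
        assert exc.value.deficit == 2


class TestTraining:
    def test_singleton_constraints_reproduce_weight_matrix(self):
        rng = np.random.default_rng(8)
        windows = [random_seq(rng, 5) for _ in range(400)]
        spec = SiteWindowSpec("donor", 2, 3)
        model = train_maxent(windows, None, spec, singleton_constraints(5))
        for query in [windows[0], "ACGTA", "TTTTT"]:
            assert model.score(query) == pytest.approx(
                wmm_log_odds(windows, query), abs=1e-9)

    def test_degenerate_corpus_concentrates_on_the_single_window(self):
        windows = ["ACGTA"] * 2000
        spec = SiteWindowSpec("donor", 2, 3)
        model = train_maxent(windows, None, spec)
        enc = encode_windows(["ACGTA"], 5)[0]
        # with n=2000 and pseudocount 0.5 per pair cell, each pair marginal
        # puts (n+0.5)/(n+8) on the observed pair
        assert 2 ** model.signal.log2_prob(enc) == pytest.approx(1.0, abs=0.02)

    def test_chain_fit_recovers_generating_pair_marginals(self):
        rng = np.random.default_rng(1)
        p0 = np.array([0.5, 0.2, 0.2, 0.1])
        trans = []
        for _ in range(8):
            T = rng.uniform(0.2, 1.0, size=(4, 4))
            trans.append(T / T.sum(axis=1, keepdims=True))
        windows = sim.gen_splice_training(
            {"kind": "chain", "p0": p0, "trans": trans}, 5000, seed=11)
        model = train_maxent(windows, None, DONOR_SPEC,
                             adjacent_pair_constraints(9))
        # generating pair marginals by forward recursion
        marg = p0
        for i, T in enumerate(trans):
            truth = marg[:, None] * T
            fitted = model.signal.pair_marginal(i)
            assert np.abs(fitted - truth).max() < 0.02
            marg = truth.sum(axis=0)

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            train_maxent([], None, DONOR_SPEC)

    def test_fitted_marginals_match_empirical_constraints(self):
        rng = np.random.default_rng(2)
        windows = [random_seq(rng, 23) for _ in range(200)]
        model = train_maxent(windows, None, ACCEPTOR_SPEC)
        enc = encode_windows(windows, 23)
        targets = empirical_marginals(enc, model.constraint_set, 0.5)
        for subset, target in targets.items():
            assert np.abs(model.signal.marginal(subset) - target).max() < 1e-7


class TestScoring:
    def test_identical_signal_and_background_score_zero(self):
        rng = np.random.default_rng(3)
        windows = [random_seq(rng, 5) for _ in range(100)]
        spec = SiteWindowSpec("donor", 2, 3)
        model = train_maxent(windows, windows, spec)
        for q in (windows[0], "AAAAA"):
            assert model.score(q) == pytest.approx(0.0, abs=1e-9)

    def test_modal_window_closed_form_under_uniform_background(self):
        # per-position modal probability p gives score sum log2(4p)
        windows = ["AC"] * 60 + ["AG"] * 20 + ["CC"] * 20
        spec = SiteWindowSpec("donor", 1, 1)
        model = train_maxent(windows, None, spec, singleton_constraints(2),
                             pseudocount=0.0)
        pA, pC = 80 / 100, 80 / 100
        assert model.score("AC") == pytest.approx(
            math.log2(4 * pA) + math.log2(4 * pC), abs=1e-9)

    def test_scores_match_full_table_enumeration(self):
        # width-4 chain model vs independent exhaustive joint reconstruction
        rng = np.random.default_rng(4)
        windows = [random_seq(rng, 4) for _ in range(300)]
        spec = SiteWindowSpec("donor", 2, 2)
        model = train_maxent(windows, None, spec, adjacent_pair_constraints(4))
        # oracle: materialise the Markov joint from the fitted pair marginals
        m01 = model.signal.pair_marginal(0)
        m12 = model.signal.pair_marginal(1)
        m23 = model.signal.pair_marginal(2)
        # P(abcd) = P01(ab) P(c|b) P(d|c)
        pb = m01.sum(axis=0)
        pc = m12.sum(axis=0)
        cond_cb = m12 / pb[:, None]
        cond_dc = m23 / pc[:, None]
        joint = np.einsum("ab,bc,cd->abcd", m01, cond_cb, cond_dc)
        assert joint.sum() == pytest.approx(1.0, abs=1e-9)
        for query in itertools.product("ACGT", repeat=4):
            q = "".join(query)
            idx = tuple(BASE_INDEX[c] for c in q)
            expect = math.log2(joint[idx]) - 4 * math.log2(0.25)
            assert model.score(q) == pytest.approx(expect, abs=1e-7)

    def test_wrong_width_rejected(self):
        windows = ["ACGTA"] * 10
        model = train_maxent(windows, None, SiteWindowSpec("donor", 2, 3))
        with pytest.raises(ValueError):
            model.score("ACGT")


class TestEntropyProperties:
    @staticmethod
    def _empirical_entropy(windows, width):
        counts = {}
        for w in windows:
            counts[w] = counts.get(w, 0) + 1
        n = len(windows)
        return -sum((c / n) * math.log2(c / n) for c in counts.values())

    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_fitted_entropy_at_least_empirical(self, width):
        rng = np.random.default_rng(width)
        # biased sampler so the empirical distribution is far from uniform
        windows = ["".join(rng.choice(list("ACGT"), p=[0.5, 0.3, 0.1, 0.1],
                                      size=width)) for _ in range(300)]
        spec = SiteWindowSpec("donor", 1, width - 1)
        model = train_maxent(windows, None, spec,
                             adjacent_pair_constraints(width), pseudocount=0.0)
        emp = self._empirical_entropy(windows, width)
        assert model.signal.entropy() >= emp - 1e-9

    def test_adding_constraints_never_raises_entropy(self):
        rng = np.random.default_rng(9)
        windows = [random_seq(rng, 4) for _ in range(500)]
        spec = SiteWindowSpec("donor", 2, 2)
        m_single = train_maxent(windows, None, spec, singleton_constraints(4))
        m_pairs = train_maxent(
            windows, None, spec,
            singleton_constraints(4) + adjacent_pair_constraints(4))
        assert m_pairs.signal.entropy() <= m_single.signal.entropy() + 1e-9

    def test_parameter_recovery_from_own_samples(self):
        rng = np.random.default_rng(10)
        base = [random_seq(rng, 9) for _ in range(800)]
        model = train_maxent(base, None, DONOR_SPEC)
        resampled = model.signal.sample(np.random.default_rng(0), 4000)
        windows = ["".join("ACGT"[i] for i in row) for row in resampled]
        refit = train_maxent(windows, None, DONOR_SPEC)
        for i in range(8):
            assert np.abs(refit.signal.pair_marginal(i)
                          - model.signal.pair_marginal(i)).max() < 0.04


class TestClassification:
    @pytest.mark.parametrize("score,label", [
        (8.0, "strong"), (2.9, "weak"), (4.5, "intermediate"),
        (6.0, "strong"), (3.0, "intermediate"),
    ])
    def test_labels(self, score, label):
        assert classify_strength(score, (3, 6)).label == label

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(1.0, (6, 3))


class TestModelRoundTrip:
    def test_save_load_bit_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        windows = [random_seq(rng, 9) for _ in range(150)]
        model = train_maxent(windows, None, DONOR_SPEC)
        path = tmp_path / "donor.model"
        model.save(path)
        loaded = SpliceSiteModel.load(path)
        assert loaded.spec == model.spec
        assert loaded.constraint_set == model.constraint_set
        for i in range(8):
            assert np.array_equal(loaded.signal.factors[i],
                                  model.signal.factors[i])
        for q in windows[:10]:
            assert loaded.score(q) == model.score(q)
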