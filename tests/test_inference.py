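"""State inference and expected-free-energy scoring against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpast.errors import DegenerateInputError
from cpast.inference import (
    EFEWeights,
    efe_landscape,
    expected_free_energy,
    infer_level1,
    infer_level2,
    predict_outcome,
    select_action,
)
from cpast.model import init_model
from cpast.remapping import PIGMENT, remap_likelihood


def bayes_oracle_level1(local, observation, prior):
    """Explicit Bayes rule over the nine local states."""
    post = [local.outcome_probs[k][observation] * prior[k] for k in range(9)]
    total = sum(post)
    return [p / total for p in post]


def bayes_oracle_level2(evidence, model, q2_prev):
    """Brute-force enumeration of the four-factor evidence product per motif."""
    prior = model.b2 @ np.asarray(q2_prev)
    post = []
    for m in range(model.n_motifs):
        lik = 1.0
        for loc, outcome in evidence:
            p = 1.0 - model.epsilon if model.motif_of[loc] == m else model.epsilon
            lik *= p if outcome == PIGMENT else 1.0 - p
        post.append(lik * prior[m])
    total = sum(post)
    return [p / total for p in post]


def efe_oracle(candidate, q2, model, weights, q2_from):
    """Term-by-term G over the two-outcome space, in plain python."""
    motif = int(model.motif_of[candidate])
    p_pig = sum(
        q2[m] * (1.0 if m == motif else model.epsilon) for m in range(model.n_motifs)
    )
    pred = [1.0 - p_pig, p_pig]
    cmax = max(model.C)
    z = sum(math.exp(c - cmax) for c in model.C)
    pref = [math.exp(c - cmax) / z for c in model.C]
    risk = sum(p * math.log(p / q) for p, q in zip(pred, pref) if p > 0)
    ambiguity = -sum(p * math.log(p) for p in pred if p > 0)
    if motif >= 0:
        col_tot = model.b2_counts.sum(axis=0)
        novelty = sum(
            q2_from[j] * (1.0 / model.b2_counts[motif, j] - 1.0 / col_tot[j])
            for j in range(model.n_motifs)
        )
    else:
        novelty = 0.0
    return weights.risk * risk + weights.ambiguity * ambiguity - weights.novelty * novelty


@pytest.fixture()
def model3(vases):
    return init_model(vases[3])


class TestLevel1:
    def test_single_pigment_patch_gives_delta(self, vases):
        vase = vases[0]
        band_row = int(np.nonzero(vase.pigment)[0][0])
        edge_col = int(np.nonzero(vase.pigment[band_row])[0][0])
        # centre one row below the band's first pigment: patch has pigment cells
        local = remap_likelihood(vase, vase.grid.index(band_row + 1, edge_col))
        q1 = infer_level1(local, PIGMENT, np.full(9, 1 / 9))
        assert set(np.flatnonzero(q1)) == set(
            np.flatnonzero(local.outcome_probs[:, PIGMENT])
        )
        assert q1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_patch_keeps_uniform(self, vases):
        local = remap_likelihood(vases[0], 0)  # all background
        q1 = infer_level1(local, 0, np.full(9, 1 / 9))
        assert np.allclose(q1, 1 / 9)

    @given(seed=st.integers(0, 500), loc=st.integers(0, 899))
    def test_matches_bayes_oracle(self, vases, seed, loc):
        vase = vases[3]
        rng = np.random.default_rng(seed)
        prior = rng.dirichlet(np.ones(9))
        local = remap_likelihood(vase, loc)
        obs = int(rng.integers(2))
        if local.outcome_probs[:, obs].sum() == 0:
            return  # degenerate evidence handled separately
        q1 = infer_level1(local, obs, prior)
        assert np.allclose(q1, bayes_oracle_level1(local, obs, prior), atol=1e-10)

    def test_impossible_evidence_resolved_by_floor(self, vases):
        local = remap_likelihood(vases[0], 0)  # background patch
        q1 = infer_level1(local, PIGMENT, np.full(9, 1 / 9))
        assert q1.sum() == pytest.approx(1.0)

    def test_unnormalised_prior_rejected(self, vases):
        local = remap_likelihood(vases[0], 0)
        with pytest.raises(DegenerateInputError):
            infer_level1(local, 0, np.full(9, 0.2))


class TestLevel2:
    def _cells_of(self, vase, motif, n=4):
        return [int(l) for l in np.flatnonzero(vase.motif_of() == motif)[:n]]

    def test_consistent_pigments_identify_motif(self, vases, model3):
        evidence = [(loc, PIGMENT) for loc in self._cells_of(vases[3], 0)]
        q2 = infer_level2(evidence, model3, np.full(4, 0.25))
        assert np.argmax(q2) == 0
        assert q2[0] > 0.99

    def test_background_evidence_is_uninformative(self, vases, model3):
        bg = [int(l) for l in np.flatnonzero(vases[3].motif_of() == -1)[:4]]
        q2_prev = np.array([0.4, 0.3, 0.2, 0.1])
        q2 = infer_level2([(loc, 0) for loc in bg], model3, q2_prev)
        assert np.allclose(q2, model3.b2 @ q2_prev, atol=1e-9)

    @given(seed=st.integers(0, 300))
    def test_mixed_evidence_matches_enumeration_oracle(self, vases, seed):
        vase = vases[3]
        model = init_model(vase)
        rng = np.random.default_rng(seed)
        model.b2_counts = rng.uniform(0.3, 2.0, size=(4, 4))
        locs = rng.integers(0, 900, size=4)
        evidence = [(int(l), vase.pigment_at(int(l))) for l in locs]
        q2_prev = rng.dirichlet(np.ones(4))
        q2 = infer_level2(evidence, model, q2_prev)
        assert np.allclose(q2, bayes_oracle_level2(evidence, model, q2_prev), atol=1e-10)

    def test_wrong_evidence_count_rejected(self, model3):
        with pytest.raises(DegenerateInputError):
            infer_level2([(0, 0)], model3, np.full(4, 0.25))


class TestPredictOutcome:
    def test_delta_belief_on_own_cell(self, vases, model3):
        loc = int(np.flatnonzero(vases[3].motif_of() == 2)[0])
        pred = predict_outcome(loc, np.eye(4)[2], model3)
        assert pred[PIGMENT] == pytest.approx(1.0)

    def test_delta_belief_on_background(self, vases, model3):
        loc = int(np.flatnonzero(vases[3].motif_of() == -1)[0])
        pred = predict_outcome(loc, np.eye(4)[2], model3)
        assert pred[PIGMENT] == pytest.approx(model3.epsilon)

    def test_uniform_mixture_hand_value(self, vases, model3):
        # P(pigment) = 1/4 * 1 + 3/4 * epsilon on any motif cell
        loc = int(np.flatnonzero(vases[3].motif_of() == 1)[0])
        pred = predict_outcome(loc, np.full(4, 0.25), model3)
        assert pred[PIGMENT] == pytest.approx(0.25 + 0.75 * model3.epsilon, abs=1e-12)


class TestExpectedFreeEnergy:
    def test_risk_prefers_likely_pigment(self, vases, model3):
        q2 = np.array([0.9, 0.1, 0.0, 0.0])
        on_0 = int(np.flatnonzero(vases[3].motif_of() == 0)[0])
        on_1 = int(np.flatnonzero(vases[3].motif_of() == 1)[0])
        w = EFEWeights(risk=1.0, ambiguity=0.0, novelty=0.0)
        assert expected_free_energy(on_0, q2, model3, w) < expected_free_energy(on_1, q2, model3, w)

    def test_flipping_preferences_reverses_ordering(self, vases):
        q2 = np.array([0.9, 0.1, 0.0, 0.0])
        on_0 = int(np.flatnonzero(vases[3].motif_of() == 0)[0])
        on_1 = int(np.flatnonzero(vases[3].motif_of() == 1)[0])
        w = EFEWeights(risk=1.0, ambiguity=0.0, novelty=0.0)
        like = init_model(vases[3], pref_pigment=4.0, pref_background=-4.0)
        hate = init_model(vases[3], pref_pigment=-4.0, pref_background=4.0)
        assert expected_free_energy(on_0, q2, like, w) < expected_free_energy(on_1, q2, like, w)
        assert expected_free_energy(on_0, q2, hate, w) > expected_free_energy(on_1, q2, hate, w)

    def test_deterministic_prediction_has_zero_ambiguity(self, vases, model3):
        loc = int(np.flatnonzero(vases[3].motif_of() == 0)[0])
        w_amb = EFEWeights(risk=0.0, ambiguity=1.0, novelty=0.0)
        assert expected_free_energy(loc, np.eye(4)[0], model3, w_amb) == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(0, 200))
    def test_matches_term_by_term_oracle(self, vases, seed):
        model = init_model(vases[3])
        rng = np.random.default_rng(seed)
        model.b2_counts = rng.uniform(0.3, 3.0, size=(4, 4))
        q2 = rng.dirichlet(np.ones(4))
        q2_from = rng.dirichlet(np.ones(4))
        weights = EFEWeights(risk=1.0, ambiguity=1.0, novelty=2.0)
        candidates = rng.integers(0, 900, size=5)
        for cand in candidates:
            got = expected_free_energy(int(cand), q2, model, weights, q2_from=q2_from)
            want = efe_oracle(int(cand), q2, model, weights, q2_from)
            assert got == pytest.approx(want, abs=1e-10)

    def test_landscape_agrees_with_scalar(self, vases, rng):
        model = init_model(vases[2])
        q2 = rng.dirichlet(np.ones(4))
        q2_from = rng.dirichlet(np.ones(4))
        land = efe_landscape(q2, model, q2_from=q2_from)
        for loc in rng.integers(0, 900, size=25):
            assert land[loc] == pytest.approx(
                expected_free_energy(int(loc), q2, model, q2_from=q2_from), abs=1e-12
            )


class TestSelectAction:
    def test_argmin(self, rng):
        assert select_action(np.array([3.0, 1.0, 2.0]), rng) == 1

    def test_tie_break_reproducible(self):
        G = np.zeros(5)
        picks = {select_action(G, np.random.default_rng(7)) for _ in range(10)}
        assert len(picks) == 1

    def test_tie_break_uniform(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        n = 1000
        for _ in range(n):
            counts[select_action(np.zeros(4), rng)] += 1
        # binomial 99% bounds around n/4
        sd = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 2.58 * sd)

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            select_action(np.array([]), rng)
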