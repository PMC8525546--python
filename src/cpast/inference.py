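"""Variational state inference and expected-free-energy action selection.

Perception is exact Bayesian updating of the factorised beliefs (which is what
free-energy minimisation reduces to for these small discrete factors):

* level 1 — ``q1 ∝ P(outcome | local state) * prior`` over the nine remapped
  local states;
* level 2 — once per cycle of four level-1 steps,
  ``q2 ∝ [∏ evidence P(outcome at loc | motif)] * (B2 @ q2_prev)``, where the
  motif-conditioned outcome probability is a per-cell Bernoulli derived from
  motif membership with an ``epsilon`` floor (so impossible evidence never
  zeroes the posterior).

Action selection scores every candidate saccade target with the expected free
energy

    G = w_risk * KL[predicted outcome || softmax(C)]
        + w_ambiguity * H[predicted outcome]
        - w_novelty * sum_j q2_from(j) * (1/alpha_ij - 1/alpha0_j)

where ``i`` is the motif the candidate cell belongs to (background candidates
carry no novelty: landing there evidences no motif transition) and the novelty
term is the expected Dirichlet information gain ``psi(a+1)-psi(a)`` telescoped
to ``1/a``.  The outcome prediction uses the belief about the *current* motif
(``q2``, typically ``B2 @ q2_prev``), while the novelty weighting uses
``q2_from`` — the previous cycle's posterior — because the Dirichlet update the
move will feed is ``outer(q2_now, q2_prev)``: the column being learned about is
indexed by where the agent believes it came *from*.  The policy is greedy: a single-step look-ahead and a hard argmin
of G with exact ties broken uniformly at random by the caller's seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .model import HierarchicalModel
from .remapping import PIGMENT, LocalLikelihood

__all__ = [
    "BeliefState",
    "infer_level1",
    "infer_level2",
    "predict_outcome",
    "expected_free_energy",
    "efe_landscape",
    "select_action",
    "EFEWeights",
]

_TOL = 1e-9


@dataclass(frozen=True)
class EFEWeights:
    """Relative weighting of the G terms (all configurable).

    The novelty default is calibrated so that parameter information gain
    dominates residual preference-risk differences among pigment-bearing
    candidates (which keeps exploration alive and transition learning
    dispersed on rich stimuli) while the pigment preference still dominates
    the pigment/background contrast; see the methods note for the scale
    analysis.
    """

    risk: float = 1.0
    ambiguity: float = 1.0
    novelty: float = 24.0


@dataclass
class BeliefState:
    """Normalised posteriors carried through a foraging episode."""

    q1: np.ndarray  # (9,) over local states
    q2: np.ndarray  # (n_motifs,) over motifs
    q_pi: np.ndarray | None = None  # over candidate actions, set after each EFE pass
    cycle_phase: int = 0  # 0..3 level-1 steps since the last level-2 update

    def check(self) -> None:
        for name, q in (("q1", self.q1), ("q2", self.q2)):
            if abs(q.sum() - 1.0) > _TOL or (q < -_TOL).any():
                raise DegenerateInputError(f"{name} is not a normalised distribution")


def _normalise(w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("posterior has zero total mass")
    return w / total


def infer_level1(
    local: LocalLikelihood,
    observation: int,
    prior1: np.ndarray,
    *,
    epsilon: float = 1e-3,
) -> np.ndarray:
    """Posterior over the nine local states given one outcome observation.

    With a deterministic likelihood the support is exactly the local states
    consistent with the observation; if the observation is impossible under
    every local state the ``epsilon`` floor resolves the degeneracy.
    """
    prior1 = np.asarray(prior1, dtype=float)
    if abs(prior1.sum() - 1.0) > _TOL:
        raise DegenerateInputError("prior1 is not normalised")
    lik = local.outcome_probs[:, observation]
    w = lik * prior1
    if w.sum() <= 0:
        w = (lik + epsilon) * prior1
    return _normalise(w)


def _evidence_bernoulli(model: HierarchicalModel, loc: int, motif: int) -> float:
    """Per-cell pigment probability at ``loc`` under ``motif`` (epsilon-floored)."""
    member = model.motif_of[loc] == motif
    return 1.0 - model.epsilon if member else model.epsilon


def infer_level2(
    evidence: list[tuple[int, int]],
    model: HierarchicalModel,
    q2_prev: np.ndarray,
) -> np.ndarray:
    """Motif posterior from one cycle's four (location, outcome) pairs.

    ``q2 ∝ [∏ P(outcome | motif, loc)] * (B2 @ q2_prev)``; computed in log
    space for numerical safety.
    """
    q2_prev = np.asarray(q2_prev, dtype=float)
    if abs(q2_prev.sum() - 1.0) > _TOL:
        raise DegenerateInputError("q2_prev is not normalised")
    if len(evidence) != 4:
        raise DegenerateInputError(f"a level-2 cycle aggregates exactly 4 evidence pairs, got {len(evidence)}")
    prior = model.b2 @ q2_prev
    log_lik = np.zeros(model.n_motifs)
    for loc, outcome in evidence:
        for m in range(model.n_motifs):
            p = _evidence_bernoulli(model, loc, m)
            log_lik[m] += np.log(p if outcome == PIGMENT else 1.0 - p)
    log_post = log_lik + np.log(prior)
    w = np.exp(log_post - log_post.max())
    return _normalise(w)


def predict_outcome(
    candidate_loc: int,
    q2: np.ndarray,
    model: HierarchicalModel,
) -> np.ndarray:
    """Top-down predicted outcome distribution ``[P(no-pig), P(pigment)]``.

    ``P(pigment) = Σ_m q2(m) * b(m, loc)`` with the per-cell Bernoulli
    ``b = 1`` on the motif's own cells and the epsilon floor elsewhere.
    """
    q2 = np.asarray(q2, dtype=float)
    motif = model.motif_of[candidate_loc]
    member = np.zeros(model.n_motifs, dtype=bool)
    if motif >= 0:
        member[motif] = True
    per_cell = np.where(member, 1.0, model.epsilon)
    p_pig = float(q2 @ per_cell)
    return np.array([1.0 - p_pig, p_pig])


def _xlogy(p: np.ndarray, q: np.ndarray) -> float:
    """sum p*log(q) with the 0*log0 convention."""
    mask = p > 0
    return float(np.sum(p[mask] * np.log(q[mask])))


def _novelty_per_motif(q2: np.ndarray, b2_counts: np.ndarray) -> np.ndarray:
    """Expected Dirichlet information gain of evidencing a transition into each motif.

    ``nov(i) = Σ_j q2(j) * (1/alpha_ij - 1/alpha0_j)`` — the digamma increment
    ``psi(a+1) - psi(a) = 1/a`` applied to the entry versus its column total.
    """
    col_tot = b2_counts.sum(axis=0)
    gain = 1.0 / b2_counts - 1.0 / col_tot  # (i, j)
    return gain @ q2


def expected_free_energy(
    candidate_loc: int,
    q2: np.ndarray,
    model: HierarchicalModel,
    weights: EFEWeights = EFEWeights(),
    q2_from: np.ndarray | None = None,
) -> float:
    """Scalar G for one candidate saccade target (lower is better).

    ``q2_from`` is the from-state belief weighting the novelty term (defaults
    to ``q2``; during an episode it is the previous cycle's posterior).
    """
    pred = predict_outcome(candidate_loc, q2, model)
    pref = model.preference_distribution()
    risk = _xlogy(pred, pred) - _xlogy(pred, pref)
    ambiguity = -_xlogy(pred, pred)
    motif = model.motif_of[candidate_loc]
    if motif >= 0:
        w_from = np.asarray(q2 if q2_from is None else q2_from, float)
        novelty = float(_novelty_per_motif(w_from, model.b2_counts)[motif])
    else:
        novelty = 0.0
    return weights.risk * risk + weights.ambiguity * ambiguity - weights.novelty * novelty


def efe_landscape(
    q2: np.ndarray,
    model: HierarchicalModel,
    weights: EFEWeights = EFEWeights(),
    candidates: np.ndarray | None = None,
    q2_from: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised G over candidate locations (default: every grid location).

    Same quantity as :func:`expected_free_energy` evaluated per candidate.
    """
    q2 = np.asarray(q2, dtype=float)
    motif = model.motif_of if candidates is None else model.motif_of[candidates]
    q2_of_cell = np.where(motif >= 0, q2[np.clip(motif, 0, None)], 0.0)
    p_pig = q2_of_cell * 1.0 + (1.0 - q2_of_cell) * model.epsilon
    pred = np.stack([1.0 - p_pig, p_pig], axis=-1)
    pref = model.preference_distribution()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pred > 0, pred * np.log(np.where(pred > 0, pred, 1.0)), 0.0)
    risk = plogp.sum(axis=-1) - pred @ np.log(pref)
    ambiguity = -plogp.sum(axis=-1)
    nov_m = _novelty_per_motif(np.asarray(q2 if q2_from is None else q2_from, float), model.b2_counts)
    novelty = np.where(motif >= 0, nov_m[np.clip(motif, 0, None)], 0.0)
    return weights.risk * risk + weights.ambiguity * ambiguity - weights.novelty * novelty


def select_action(
    G_values: np.ndarray,
    rng: np.random.Generator,
    candidates: np.ndarray | None = None,
    tie_tol: float = 1e-12,
) -> int:
    """Greedy argmin of G; exact ties broken uniformly with the seeded generator."""
    G_values = np.asarray(G_values, dtype=float)
    if G_values.size == 0:
        raise DegenerateInputError("empty candidate set")
    ties = np.flatnonzero(G_values <= G_values.min() + tie_tol)
    choice = int(ties[rng.integers(len(ties))])
    return choice if candidates is None else int(candidates[choice])
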