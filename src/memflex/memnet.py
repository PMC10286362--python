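"""Two-layer hippocampus-prefrontal (HC-PFC) Hebbian memory network.

A rate-free attractor model of systems memory consolidation in the
TraceLink tradition: a small, sparsely connected hippocampal layer with
fast Hebbian plasticity drives a larger prefrontal layer whose internal
connections strengthen slowly during consolidation.  Activity is binary
and competitive: in every update cycle only the ``k`` highest-input
nodes per layer fire (k-winners-take-all).  Cutting the directed
HC->PFC projection ("lesioning") models white-matter disconnection of
the fimbria/fornix and its consequences for memory extinction, new
learning and behavioral flexibility.

The module is organised in the order a simulation runs: configuration,
pattern sampling, network construction, the update cycle, Hebbian
learning, the acquisition/consolidation/recall phases, lesioning, and
the two experiment protocols (lesion protocol and flexibility sweep).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("memflex")

__all__ = [
    "ConfigError",
    "ModelConfig",
    "Pattern",
    "NetworkState",
    "RecallResult",
    "ChanceEstimate",
    "LesionProtocolResult",
    "FlexibilityResult",
    "FlexibilitySweepResult",
    "BLOCKS",
    "build_network",
    "sample_pattern",
    "sample_overlap_pair",
    "expected_overlap",
    "cycle",
    "hebbian_delta",
    "apply_learning",
    "acquire",
    "consolidate",
    "lesion_hc_to_pfc",
    "recall",
    "recall_score",
    "chance_score",
    "run_lesion_protocol",
    "consolidation_proportion",
    "flexibility_index",
    "run_flexibility_trial",
    "run_flexibility_sweep",
]

# The four directed weight blocks, named post<-pre.
BLOCKS = ("hc<-hc", "pfc<-hc", "hc<-pfc", "pfc<-pfc")


class ConfigError(ValueError):
    """Raised when a configuration field violates its constraint."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Parameters of the HC-PFC network.

    Defaults follow the published parameterisation: 42 hippocampal and
    200 prefrontal nodes, 50% connection probability within and between
    layers, additive uniform noise on [0, 0.5], encoding rate
    ``lambda+ = 0.4`` for associative connections (within HC and between
    layers), 0.06 within PFC during acquisition and 0.0025 within PFC
    during consolidation, with the forgetting rate ``lambda-`` at 75% of
    the corresponding ``lambda+``.
    """

    n_hc: int = 42
    n_pfc: int = 200
    k_hc: int = 7
    k_pfc: int = 10
    p_connect: float = 0.5
    noise_range: tuple[float, float] = (0.0, 0.5)
    lambda_plus_assoc: float = 0.4
    lambda_plus_pfc_acq: float = 0.06
    lambda_plus_pfc_consol: float = 0.0025
    forgetting_ratio: float = 0.75
    consolidation_cycles: int = 8
    consolidation_repeats: int = 3
    recall_cycles: int = 8
    recall_threshold: float = 0.75
    seed: int | None = None

    def __post_init__(self) -> None:
        self.noise_range = tuple(self.noise_range)  # type: ignore[assignment]
        checks = [
            ("n_hc", self.n_hc >= 1),
            ("n_pfc", self.n_pfc >= 1),
            ("k_hc", 0 < self.k_hc <= self.n_hc),
            ("k_pfc", 0 < self.k_pfc <= self.n_pfc),
            ("p_connect", 0.0 <= self.p_connect <= 1.0),
            ("noise_range", len(self.noise_range) == 2
             and self.noise_range[0] <= self.noise_range[1]),
            ("lambda_plus_assoc", self.lambda_plus_assoc >= 0),
            ("lambda_plus_pfc_acq", self.lambda_plus_pfc_acq >= 0),
            ("lambda_plus_pfc_consol", self.lambda_plus_pfc_consol >= 0),
            ("forgetting_ratio", self.forgetting_ratio >= 0),
            ("consolidation_cycles", self.consolidation_cycles >= 0),
            ("consolidation_repeats", self.consolidation_repeats >= 0),
            ("recall_cycles", self.recall_cycles >= 0),
            ("recall_threshold", 0.0 <= self.recall_threshold <= 1.0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(
                    f"invalid configuration field {name!r}: "
                    f"{getattr(self, name)!r}"
                )

    def acquisition_rates(self) -> dict[str, float]:
        """Per-block encoding rates used during acquisition."""
        lam = self.lambda_plus_assoc
        return {"hc<-hc": lam, "pfc<-hc": lam, "hc<-pfc": lam,
                "pfc<-pfc": self.lambda_plus_pfc_acq}

    def consolidation_rates(self) -> dict[str, float]:
        """Per-block encoding rates used during consolidation.

        Only intra-PFC connections learn; all other rates are 0.
        """
        return {"hc<-hc": 0.0, "pfc<-hc": 0.0, "hc<-pfc": 0.0,
                "pfc<-pfc": self.lambda_plus_pfc_consol}


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pattern:
    """A memory item: the set of active nodes in each layer."""

    id: int
    hc_nodes: frozenset[int]
    pfc_nodes: frozenset[int]

    def validate(self, config: ModelConfig) -> None:
        if len(self.hc_nodes) != config.k_hc:
            raise ValueError(
                f"pattern {self.id}: |hc_nodes|={len(self.hc_nodes)} "
                f"!= k_hc={config.k_hc}")
        if len(self.pfc_nodes) != config.k_pfc:
            raise ValueError(
                f"pattern {self.id}: |pfc_nodes|={len(self.pfc_nodes)} "
                f"!= k_pfc={config.k_pfc}")
        if self.hc_nodes and not (0 <= min(self.hc_nodes)
                                  <= max(self.hc_nodes) < config.n_hc):
            raise ValueError(f"pattern {self.id}: HC index out of range")
        if self.pfc_nodes and not (0 <= min(self.pfc_nodes)
                                   <= max(self.pfc_nodes) < config.n_pfc):
            raise ValueError(f"pattern {self.id}: PFC index out of range")


def sample_pattern(config: ModelConfig,
                   rng: np.random.Generator | int | None,
                   pattern_id: int = 0) -> Pattern:
    """Draw a uniformly random pattern (k-subset per layer)."""
    rng = _as_rng(rng)
    hc = rng.choice(config.n_hc, size=config.k_hc, replace=False)
    pfc = rng.choice(config.n_pfc, size=config.k_pfc, replace=False)
    return Pattern(pattern_id, frozenset(int(i) for i in hc),
                   frozenset(int(i) for i in pfc))


def sample_overlap_pair(config: ModelConfig, base: Pattern,
                        rng: np.random.Generator | int | None,
                        pattern_id: int = 0) -> Pattern:
    """Draw a pattern sharing exactly ``floor(k_pfc/2)`` PFC nodes with *base*.

    The shared subset is chosen uniformly from *base*'s PFC nodes, the
    remaining PFC nodes uniformly from outside *base*'s PFC set, and the
    HC part is freshly random (new context for the new association).
    """
    base.validate(config)
    rng = _as_rng(rng)
    if config.k_pfc % 2:
        warnings.warn(
            f"k_pfc={config.k_pfc} is odd; sharing floor(k_pfc/2)="
            f"{config.k_pfc // 2} PFC nodes", stacklevel=2)
    n_shared = config.k_pfc // 2
    base_pfc = np.array(sorted(base.pfc_nodes))
    shared = rng.choice(base_pfc, size=n_shared, replace=False)
    complement = np.setdiff1d(np.arange(config.n_pfc), base_pfc)
    fresh = rng.choice(complement, size=config.k_pfc - n_shared, replace=False)
    hc = rng.choice(config.n_hc, size=config.k_hc, replace=False)
    return Pattern(pattern_id, frozenset(int(i) for i in hc),
                   frozenset(int(i) for i in np.concatenate([shared, fresh])))


def expected_overlap(k: int, n: int) -> float:
    """Expected fraction of a pattern's nodes shared with an independent one.

    Two independent uniform k-subsets of n nodes share k*k/n nodes in
    expectation, i.e. a fraction k/n of either pattern (1/6 for the HC
    layer at k=7, n=42; 1/20 for the PFC layer at k=10, n=200).
    """
    if k <= 0 or k > n:
        raise ValueError(f"require 0 < k <= n, got k={k}, n={n}")
    return k / n


# ---------------------------------------------------------------------------
# Network state and construction
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Weights, connectivity masks and binary activity of the network.

    ``weights[b]`` and ``masks[b]`` for block ``b`` in :data:`BLOCKS` are
    (n_post, n_pre) arrays; weights are bounded in [0, 1] and are zero
    wherever the mask is absent.  ``a_hc``/``a_pfc`` are 0/1 vectors.
    """

    weights: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    a_hc: np.ndarray
    a_pfc: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(
            {b: w.copy() for b, w in self.weights.items()},
            {b: m.copy() for b, m in self.masks.items()},
            self.a_hc.copy(), self.a_pfc.copy())

    def set_activity(self, pattern: Pattern) -> None:
        self.a_hc[:] = 0
        self.a_pfc[:] = 0
        self.a_hc[sorted(pattern.hc_nodes)] = 1
        self.a_pfc[sorted(pattern.pfc_nodes)] = 1


def build_network(config: ModelConfig,
                  rng: np.random.Generator | int | None = None
                  ) -> NetworkState:
    """Construct a fresh network on random connectivity masks.

    Each of the four directed blocks gets an independent Bernoulli
    ``p_connect`` mask (no self-connections within a layer); all present
    weights start at 0, so structure is built entirely by learning.
    """
    rng = _as_rng(rng if rng is not None else config.seed)
    shapes = {
        "hc<-hc": (config.n_hc, config.n_hc),
        "pfc<-hc": (config.n_pfc, config.n_hc),
        "hc<-pfc": (config.n_hc, config.n_pfc),
        "pfc<-pfc": (config.n_pfc, config.n_pfc),
    }
    masks: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for block, shape in shapes.items():
        m = rng.random(shape) < config.p_connect
        if shape[0] == shape[1] and block in ("hc<-hc", "pfc<-pfc"):
            np.fill_diagonal(m, False)
        masks[block] = m
        weights[block] = np.zeros(shape)
    return NetworkState(weights, masks,
                        np.zeros(config.n_hc, dtype=np.uint8),
                        np.zeros(config.n_pfc, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Dynamics: the k-WTA update cycle
# ---------------------------------------------------------------------------

def _k_wta(inputs: np.ndarray, k: int,
           clamp: Sequence[int] | None) -> np.ndarray:
    """Binary k-winners-take-all with ties broken by lowest node index.

    Clamped nodes are forced active and count toward the k budget; the
    remaining winners are the highest-input unclamped nodes.
    """
    active = np.zeros(inputs.size, dtype=np.uint8)
    remaining = k
    if clamp is not None:
        idx = np.asarray(sorted(clamp), dtype=int)
        if idx.size > k:
            raise ValueError(f"clamp of size {idx.size} exceeds k={k}")
        active[idx] = 1
        remaining = k - idx.size
    if remaining:
        # stable argsort of -inputs: equal inputs keep index order
        order = np.argsort(-inputs, kind="stable")
        order = order[active[order] == 0]
        active[order[:remaining]] = 1
    return active


def cycle(state: NetworkState, config: ModelConfig,
          rng: np.random.Generator | int | None,
          clamp_hc: Sequence[int] | None = None,
          clamp_pfc: Sequence[int] | None = None) -> NetworkState:
    """One synchronous update of both layers (in place).

    Each node's input is the weighted sum over its present incoming
    connections from both layers, computed from the previous cycle's
    activity, plus a fresh uniform noise draw from ``noise_range``
    (HC noise drawn before PFC noise).  Exactly ``k_hc`` / ``k_pfc``
    nodes end up active per layer.
    """
    rng = _as_rng(rng)
    lo, hi = config.noise_range
    a_hc = state.a_hc.astype(float)
    a_pfc = state.a_pfc.astype(float)
    in_hc = (state.weights["hc<-hc"] @ a_hc
             + state.weights["hc<-pfc"] @ a_pfc
             + rng.uniform(lo, hi, size=config.n_hc))
    in_pfc = (state.weights["pfc<-hc"] @ a_hc
              + state.weights["pfc<-pfc"] @ a_pfc
              + rng.uniform(lo, hi, size=config.n_pfc))
    state.a_hc = _k_wta(in_hc, config.k_hc, clamp_hc)
    state.a_pfc = _k_wta(in_pfc, config.k_pfc, clamp_pfc)
    return state


# ---------------------------------------------------------------------------
# Hebbian learning
# ---------------------------------------------------------------------------

def hebbian_delta(a_post: int, a_pre: int,
                  lambda_plus: float, lambda_minus: float) -> float:
    """Weight change for one connection: lp*ai*aj - lm*ai*(1-aj).

    Potentiation when both nodes fire, depression when the postsynaptic
    node fires without presynaptic support, no change when the
    postsynaptic node is silent.
    """
    return lambda_plus * a_post * a_pre - lambda_minus * a_post * (1 - a_pre)


def apply_learning(state: NetworkState, rate_table: Mapping[str, float],
                   config: ModelConfig) -> NetworkState:
    """Apply one Hebbian update to every present connection (in place).

    ``rate_table`` maps block names to their encoding rate ``lambda+``;
    the forgetting rate is ``forgetting_ratio * lambda+`` per block.
    Weights are clipped to [0, 1]; masked-absent entries stay zero.
    """
    acts = {"hc": state.a_hc.astype(float), "pfc": state.a_pfc.astype(float)}
    for block in BLOCKS:
        lam_p = rate_table.get(block, 0.0)
        if lam_p == 0.0:
            continue
        lam_m = config.forgetting_ratio * lam_p
        post, pre = block.split("<-")
        a_post, a_pre = acts[post], acts[pre]
        delta = (lam_p * np.outer(a_post, a_pre)
                 - lam_m * np.outer(a_post, 1.0 - a_pre))
        w = state.weights[block]
        np.clip(w + delta * state.masks[block], 0.0, 1.0, out=w)
    return state


# ---------------------------------------------------------------------------
# Phases: acquisition, consolidation, lesion, recall
# ---------------------------------------------------------------------------

def acquire(state: NetworkState, pattern: Pattern,
            config: ModelConfig) -> NetworkState:
    """One-shot encoding: clamp activity to the pattern, update weights once.

    Associative connections (within HC and between layers) learn at
    ``lambda_plus_assoc``; intra-PFC connections at the much smaller
    ``lambda_plus_pfc_acq``.
    """
    pattern.validate(config)
    state.set_activity(pattern)
    return apply_learning(state, config.acquisition_rates(), config)


def consolidate(state: NetworkState, learned_patterns: Sequence[Pattern],
                config: ModelConfig,
                rng: np.random.Generator | int | None) -> NetworkState:
    """Off-line reactivation strengthening intra-PFC connections.

    One episode: impose a uniformly chosen already-learned pattern as
    the initial state, then run ``consolidation_cycles`` free cycles,
    applying intra-PFC learning (rate ``lambda_plus_pfc_consol``) after
    each cycle.  The free dynamics may drift to a different stored
    pattern mid-episode; whatever is active is what gets consolidated.
    Repeated ``consolidation_repeats`` times per call.
    """
    if not learned_patterns:
        raise ValueError("consolidate requires a non-empty pattern list")
    rng = _as_rng(rng)
    rates = config.consolidation_rates()
    for _ in range(config.consolidation_repeats):
        chosen = learned_patterns[int(rng.integers(len(learned_patterns)))]
        state.set_activity(chosen)
        for _ in range(config.consolidation_cycles):
            cycle(state, config, rng)
            apply_learning(state, rates, config)
    return state


def lesion_hc_to_pfc(state: NetworkState, fraction: float,
                     rng: np.random.Generator | int | None) -> NetworkState:
    """Permanently remove a fraction of the present HC->PFC connections.

    Exactly ``round(fraction * M)`` of the M present ``pfc<-hc``
    connections (rounding half away from zero, so 20% steps are exact
    for even M) are chosen uniformly without replacement; their mask
    bits are cleared and weights zeroed.  All other blocks untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"lesion fraction must be in [0, 1], got {fraction}")
    rng = _as_rng(rng)
    mask = state.masks["pfc<-hc"]
    present = np.flatnonzero(mask)
    n_remove = int(math.floor(fraction * present.size + 0.5))
    if n_remove == 0:
        return state
    removed = rng.choice(present, size=n_remove, replace=False)
    flat_mask = mask.reshape(-1)
    flat_w = state.weights["pfc<-hc"].reshape(-1)
    flat_mask[removed] = False
    flat_w[removed] = 0.0
    return state


@dataclass(frozen=True)
class RecallResult:
    """Outcome of one cued recall test."""

    pattern_id: int
    cue: frozenset[int]
    retrieved: frozenset[int]
    score: float
    success: bool


def default_cue(pattern: Pattern, config: ModelConfig) -> frozenset[int]:
    """Deterministic cue: the lowest-indexed floor(k_pfc/2) PFC nodes."""
    return frozenset(sorted(pattern.pfc_nodes)[: config.k_pfc // 2])


def recall_score(pattern_pfc: Iterable[int], cue: Iterable[int],
                 retrieved: Iterable[int]) -> float:
    """Fraction of the pattern's non-cued PFC nodes that were retrieved."""
    pattern_pfc, cue, retrieved = set(pattern_pfc), set(cue), set(retrieved)
    if not cue <= pattern_pfc:
        raise ValueError("cue must be a subset of the pattern's PFC nodes")
    target = pattern_pfc - cue
    if not target:
        raise ValueError("recall score undefined: cue covers whole pattern")
    return len(retrieved & target) / len(target)


def recall(state: NetworkState, pattern: Pattern, config: ModelConfig,
           rng: np.random.Generator | int | None,
           cue: Iterable[int] | None = None) -> RecallResult:
    """Cued pattern completion with learning disabled.

    Half of the pattern's PFC nodes (the deterministic
    :func:`default_cue` unless an explicit cue, e.g. the shared overlap,
    is given) are clamped for one cycle starting from silent activity;
    the network then runs ``recall_cycles`` free cycles and the final
    PFC active set is scored against the pattern.  Weights are never
    modified.
    """
    pattern.validate(config)
    cue_set = default_cue(pattern, config) if cue is None else frozenset(cue)
    rng = _as_rng(rng)
    state.a_hc = np.zeros(config.n_hc, dtype=np.uint8)
    state.a_pfc = np.zeros(config.n_pfc, dtype=np.uint8)
    cycle(state, config, rng, clamp_pfc=sorted(cue_set))
    for _ in range(config.recall_cycles):
        cycle(state, config, rng)
    retrieved = frozenset(int(i) for i in np.flatnonzero(state.a_pfc))
    score = recall_score(pattern.pfc_nodes, cue_set, retrieved)
    return RecallResult(pattern.id, cue_set, retrieved, score,
                        score >= config.recall_threshold)


@dataclass(frozen=True)
class ChanceEstimate:
    """Recall-score distribution for never-learned random patterns."""

    mean: float
    sd: float
    sem: float
    scores: tuple[float, ...]


def chance_score(state: NetworkState, config: ModelConfig,
                 rng: np.random.Generator | int | None, n_draws: int = 100,
                 learned: Sequence[Pattern] = ()) -> ChanceEstimate:
    """Estimate the chance recall level from fresh random patterns.

    Each drawn pattern is verified distinct (in PFC content) from every
    learned pattern before being recall-tested.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = _as_rng(rng)
    learned_pfc = {p.pfc_nodes for p in learned}
    scores = []
    for _ in range(n_draws):
        probe = sample_pattern(config, rng, pattern_id=-1)
        while probe.pfc_nodes in learned_pfc:
            probe = sample_pattern(config, rng, pattern_id=-1)
        scores.append(recall(state, probe, config, rng).score)
    arr = np.array(scores)
    sd = float(arr.std(ddof=1)) if n_draws > 1 else float("nan")
    sem = sd / math.sqrt(n_draws) if n_draws > 1 else float("nan")
    return ChanceEstimate(float(arr.mean()), sd, sem, tuple(scores))


# ---------------------------------------------------------------------------
# Experiment protocols
# ---------------------------------------------------------------------------

@dataclass
class LesionProtocolResult:
    """Recall trajectories and end-of-run scores for one protocol run.

    ``trajectory`` rows carry (probe_pattern, step, score, success) for
    each probe tested after each acquisition+consolidation step;
    ``final_scores[i]`` is the end-of-run recall score of pattern i+1.
    ``state`` is the trained (and lesioned) network, kept so further
    cued tests can be run on it.
    """

    lesion_fraction: float
    trajectory: pd.DataFrame
    final_scores: np.ndarray
    chance: ChanceEstimate | None
    patterns: tuple[Pattern, ...]
    state: NetworkState


def run_lesion_protocol(config: ModelConfig, lesion_fraction: float,
                        rng: np.random.Generator | int | None,
                        probes: Sequence[int] = (1, 10, 11),
                        overlap_pairs: bool = False,
                        n_patterns: int = 20, lesion_after: int = 10,
                        chance_draws: int = 50) -> LesionProtocolResult:
    """Acquire+consolidate 10 patterns, lesion HC->PFC, then 10 more.

    After every acquisition+consolidation step each already-learned
    probe pattern is recall-tested; at the end of the run all patterns
    are tested and the chance level is estimated from never-learned
    patterns.  With ``overlap_pairs`` the post-lesion patterns share
    half their PFC nodes with the corresponding pre-lesion patterns.
    """
    if not 0.0 <= lesion_fraction <= 1.0:
        raise ValueError("lesion_fraction must be in [0, 1]")
    rng = _as_rng(rng)
    state = build_network(config, rng)
    patterns: list[Pattern] = []
    for i in range(1, n_patterns + 1):
        if overlap_pairs and i > lesion_after:
            base = patterns[i - lesion_after - 1]
            patterns.append(sample_overlap_pair(config, base, rng, i))
        else:
            patterns.append(sample_pattern(config, rng, i))
    rows = []
    for step, pattern in enumerate(patterns, start=1):
        acquire(state, pattern, config)
        consolidate(state, patterns[:step], config, rng)
        for probe_id in probes:
            if probe_id <= step:
                res = recall(state, patterns[probe_id - 1], config, rng)
                rows.append((probe_id, step, res.score, res.success))
        if step == lesion_after:
            lesion_hc_to_pfc(state, lesion_fraction, rng)
    final = np.array([recall(state, p, config, rng).score for p in patterns])
    chance = None
    if chance_draws > 0:
        chance = chance_score(state, config, rng, n_draws=chance_draws,
                              learned=patterns)
    trajectory = pd.DataFrame(
        rows, columns=["probe_pattern", "step", "score", "success"])
    return LesionProtocolResult(lesion_fraction, trajectory, final,
                                chance, tuple(patterns), state)


def consolidation_proportion(final_scores: np.ndarray,
                             threshold: float = 0.75,
                             n_pre: int = 10) -> float:
    """Share of consolidated patterns that were learned after the lesion.

    A pattern counts as consolidated when its end-of-run recall score
    reaches ``threshold``.  Returns NaN (undefined) when no pattern
    consolidated at all.
    """
    consolidated = np.asarray(final_scores) >= threshold
    total = int(consolidated.sum())
    if total == 0:
        logger.warning("consolidation_proportion undefined: "
                       "no pattern reached threshold %.2f", threshold)
        return float("nan")
    return int(consolidated[n_pre:].sum()) / total


def flexibility_index(n_new: int, n_old: int) -> float:
    """(N_new - N_old) / (N_new + N_old): +1 only-new ... -1 only-old."""
    if n_new < 0 or n_old < 0:
        raise ValueError("recall counts must be non-negative")
    if n_new + n_old == 0:
        raise ValueError("flexibility undefined: no successful recalls")
    return (n_new - n_old) / (n_new + n_old)


@dataclass(frozen=True)
class FlexibilityResult:
    """Tallies and flexibility index for one condition (one block)."""

    n_new: int
    n_old: int
    flexibility: float
    forgetting_ratio: float
    lesion_fraction: float


def run_flexibility_trial(config: ModelConfig, lesion_fraction: float,
                          rng: np.random.Generator | int | None,
                          tie_policy: str = "both") -> tuple[int, int]:
    """One overlap-pair simulation; returns the (n_new, n_old) tallies.

    Patterns 11-20 share 50% of their PFC nodes with patterns 1-10.  At
    the end of the run each pair is cued with its shared PFC nodes and
    the same retrieved set is scored against the new and the old
    pattern; a score >= ``recall_threshold`` counts the trial toward the
    corresponding tally.  ``tie_policy`` decides trials where both
    exceed threshold: counted in ``"both"`` tallies (default, keeps the
    index antisymmetric) or in ``"neither"``.
    """
    if tie_policy not in ("both", "neither"):
        raise ValueError("tie_policy must be 'both' or 'neither'")
    rng = _as_rng(rng)
    result = run_lesion_protocol(config, lesion_fraction, rng, probes=(),
                                 overlap_pairs=True, chance_draws=0)
    n_pre = len(result.patterns) // 2
    n_new = n_old = 0
    for i in range(n_pre):
        old, new = result.patterns[i], result.patterns[i + n_pre]
        shared = old.pfc_nodes & new.pfc_nodes
        res = recall(result.state, new, config, rng, cue=shared)
        score_new = res.score
        score_old = recall_score(old.pfc_nodes, shared, res.retrieved)
        hit_new = score_new >= config.recall_threshold
        hit_old = score_old >= config.recall_threshold
        if hit_new and hit_old and tie_policy == "neither":
            continue
        n_new += int(hit_new)
        n_old += int(hit_old)
    return n_new, n_old


@dataclass
class FlexibilitySweepResult:
    """Per-block tallies and per-condition summary of a flexibility sweep.

    ``per_block`` has one row per (forgetting_ratio, lesion_fraction,
    block) with the pooled tallies over that block's simulations and the
    block's flexibility index (NaN, flagged, when no recall succeeded);
    ``summary`` aggregates mean flexibility +/- SEM over blocks.
    """

    per_block: pd.DataFrame
    summary: pd.DataFrame


def run_flexibility_sweep(config: ModelConfig,
                          forgetting_ratios: Sequence[float] = (
                              0.0, 0.25, 0.5, 0.75, 1.0),
                          lesion_fractions: Sequence[float] = (
                              0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                          blocks: int = 10, sims_per_block: int = 20,
                          rng: np.random.Generator | int | None = None,
                          tie_policy: str = "both") -> FlexibilitySweepResult:
    """Flexibility over a grid of forgetting ratios and lesion fractions.

    For each condition, ``blocks`` independent blocks of
    ``sims_per_block`` overlap-pair simulations are run; tallies are
    pooled within a block, the flexibility index is computed per block,
    and the summary reports mean +/- SEM across blocks.
    """
    if not forgetting_ratios or not lesion_fractions:
        raise ValueError("parameter grids must be non-empty")
    if blocks < 1 or sims_per_block < 1:
        raise ValueError("blocks and sims_per_block must be >= 1")
    rng = _as_rng(rng)
    rows = []
    for fr in forgetting_ratios:
        cond_config = replace(config, forgetting_ratio=fr)
        for lf in lesion_fractions:
            for b in range(blocks):
                n_new = n_old = 0
                for _ in range(sims_per_block):
                    dn, do = run_flexibility_trial(cond_config, lf, rng,
                                                   tie_policy=tie_policy)
                    n_new += dn
                    n_old += do
                if n_new + n_old > 0:
                    flex = flexibility_index(n_new, n_old)
                else:
                    logger.warning(
                        "flexibility undefined for forgetting=%.2f "
                        "lesion=%.2f block=%d (no successful recalls)",
                        fr, lf, b)
                    flex = float("nan")
                rows.append((fr, lf, b, n_new, n_old, flex))
    per_block = pd.DataFrame(rows, columns=[
        "forgetting_ratio", "lesion_fraction", "block",
        "n_new", "n_old", "flexibility"])
    grouped = per_block.groupby(["forgetting_ratio", "lesion_fraction"])
    summary = grouped["flexibility"].agg(
        mean_flexibility="mean",
        sem_flexibility=lambda s: s.sem(),
        n_blocks="count").reset_index()
    return FlexibilitySweepResult(per_block, summary)
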