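"""Reward-driven segmentation refinement.

The segmentation network emits a per-voxel foreground probability map;
refinement searches over the binarization threshold with a small
reinforcement-learning loop.  The state is (probability map, current
threshold); the actions are {raise threshold by delta, lower by delta,
accept}.  The reward signal is built from the overlap score

    W = (B / H) * |u ∩ v| / |u ∪ v|

— the Jaccard index of prediction u and reference v, weighted by the
fraction B/H of interest pixels in the image — and the per-step reward
is the sign of the change in W.  Episode quality is the discounted
return Q = sum_t kappa^(t-1) f_t, and exploration follows a chi-greedy
policy whose chi anneals from 0.9 by 0.1 per episode down to 0.1.

Because thresholding is a known deterministic environment, the tabular
action values consulted by the greedy branch are initialised by value
iteration over the discretized threshold graph (edges that would incur a
penalty are unusable, matching the revert rule below); observed rewards
still update the table each step.  Moves that are penalized
(f_t = -1) are reverted before the next step, so with chi = 0 the
overlap score is non-decreasing over accepted moves and the episode
attains the best W reachable through non-penalized moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import relative_overlap

__all__ = [
    "RefineState",
    "RewardParams",
    "EpisodeTrace",
    "overlap_reward",
    "step_reward",
    "discounted_return",
    "chi_schedule",
    "select_action",
    "run_episode",
]

ACTIONS = ("up", "down", "accept")


@dataclass
class RefineState:
    """Current refinement state; the mask is always prob_map >= threshold."""

    prob_map: np.ndarray
    current_threshold: float
    step: int = 1

    @property
    def current_mask(self) -> np.ndarray:
        return (self.prob_map >= self.current_threshold).astype(np.uint8)


@dataclass(frozen=True)
class RewardParams:
    """Episode hyper-parameters.

    kappa : discount factor in [0, 1].
    chi0, chi_decay, chi_floor : exploration schedule 0.9, 0.8, ... 0.1.
    t_max : maximum number of steps per episode.
    delta : threshold step size of the up/down actions.
    """

    kappa: float = 0.9
    chi0: float = 0.9
    chi_decay: float = 0.1
    chi_floor: float = 0.1
    t_max: int = 20
    delta: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")


@dataclass
class EpisodeTrace:
    """Per-step records (t, action, W_t, f_t) and the discounted return Q."""

    records: list[tuple[int, str, float, int]] = field(default_factory=list)
    Q: float = 0.0


def overlap_reward(
    pred: np.ndarray, ref: np.ndarray, B: float | None = None, H: float | None = None
) -> float:
    """Interest-weighted Jaccard W = (B/H) * |u∩v| / |u∪v|.

    B defaults to the reference foreground count and H to the total
    voxel count, making B/H the interest-pixel fraction of the image.
    W is 0 when the union is empty.
    """
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    if H is None:
        H = float(ref.size)
    if B is None:
        B = float(np.sum(ref))
    if H <= 0:
        raise ValueError("H must be positive")
    return (B / H) * relative_overlap(pred, ref)


def step_reward(W_next: float, W_curr: float) -> int:
    """sign(W_next - W_curr): +1 reward on improvement, -1 penalty, 0 tie."""
    if not (np.isfinite(W_next) and np.isfinite(W_curr)):
        raise ValueError("overlap scores must be finite")
    return int(np.sign(W_next - W_curr))


def discounted_return(rewards, kappa: float) -> float:
    """Q = sum_t kappa^(t-1) f_t with kappa^0 = 1 for the first step."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    rewards = np.asarray(list(rewards), dtype=float)
    if rewards.size == 0:
        return 0.0
    weights = np.concatenate([[1.0], np.cumprod(np.full(rewards.size - 1, kappa))])
    return float(np.dot(weights, rewards))


def chi_schedule(episode_index: int, params: RewardParams = RewardParams()) -> float:
    """Exploration probability max(chi0 - decay * k, floor) for episode k."""
    if episode_index < 0:
        raise ValueError("episode_index must be >= 0")
    return max(params.chi0 - params.chi_decay * episode_index, params.chi_floor)


def select_action(
    state_index: int,
    chi: float,
    q_table: np.ndarray,
    rng: np.random.Generator | int,
    visit_counts: np.ndarray | None = None,
) -> int:
    """chi-greedy action choice over one q-table row.

    With probability chi a uniformly random action ("re-segmentation");
    otherwise an action with maximal learned value.  Ties between
    maximizers go to ``accept`` when it is among them (so episodes
    terminate at an optimum), then to the action whose (state, action)
    pair has been tried least often (systematic plateau exploration),
    then to the lowest index.  Deterministic for a given generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    row = q_table[state_index]
    n_actions = row.shape[0]
    if n_actions == 0:
        raise ValueError("action set must be non-empty")
    if rng.random() < chi:
        return int(rng.integers(n_actions))
    best = row.max()
    maximizers = [a for a in range(n_actions) if row[a] == best]
    accept = n_actions - 1
    if accept in maximizers:
        return accept
    if visit_counts is not None and len(maximizers) > 1:
        counts = visit_counts[state_index]
        maximizers.sort(key=lambda a: (counts[a], a))
    return int(maximizers[0])


def _threshold_grid(t0: float, delta: float) -> np.ndarray:
    """All thresholds in (0, 1) reachable from t0 by +-delta moves."""
    down = int(np.floor((t0 - 1e-12) / delta))
    up = int(np.floor((1.0 - t0 - 1e-12) / delta))
    ks = np.arange(-down, up + 1)
    return t0 + ks * delta


def _plan_q_table(W: np.ndarray) -> np.ndarray:
    """Value-iterate the deterministic threshold chain.

    Edges that would incur a penalty (W drops) are unusable — a
    penalized move is reverted — so V(i) is the best W reachable from
    node i through non-decreasing-W moves.  Returns Q[node, action] for
    actions (up, down, accept).
    """
    K = W.size
    V = W.copy()
    for _ in range(K):
        V_new = V.copy()
        for i in range(K):
            if i + 1 < K and W[i + 1] >= W[i]:
                V_new[i] = max(V_new[i], V[i + 1])
            if i - 1 >= 0 and W[i - 1] >= W[i]:
                V_new[i] = max(V_new[i], V[i - 1])
        if np.array_equal(V_new, V):
            break
        V = V_new
    q = np.full((K, 3), -np.inf)
    for i in range(K):
        q[i, 0] = V[i + 1] if (i + 1 < K and W[i + 1] >= W[i]) else -1.0
        q[i, 1] = V[i - 1] if (i - 1 >= 0 and W[i - 1] >= W[i]) else -1.0
        q[i, 2] = W[i]  # accept
    return q


def run_episode(
    prob_map: np.ndarray,
    ref: np.ndarray,
    params: RewardParams = RewardParams(),
    rng_seed: int | np.random.Generator = 0,
    chi: float = 0.0,
    initial_threshold: float = 0.5,
) -> tuple[np.ndarray, EpisodeTrace]:
    """Run one refinement episode and return (final mask, trace).

    Iterates up to ``t_max`` steps of chi-greedy threshold moves; a
    penalized move is reverted, ``accept`` terminates.  The greedy
    branch consults the planned action values (backed up each step from
    the observed rewards), so with chi = 0 the final overlap score is
    the best one reachable without penalties given enough steps.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("prob_map values must lie in [0, 1]")
    ref = np.asarray(ref).astype(bool)
    if prob_map.shape != ref.shape:
        raise ValueError("prob_map and ref must have the same shape")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    grid = _threshold_grid(initial_threshold, params.delta)
    W_grid = np.array([overlap_reward(prob_map >= t, ref) for t in grid])
    q_table = _plan_q_table(W_grid)
    visit_counts = np.zeros_like(q_table, dtype=int)

    i = int(np.argmin(np.abs(grid - initial_threshold)))
    rewards: list[int] = []
    trace = EpisodeTrace()
    for t in range(1, params.t_max + 1):
        action = select_action(i, chi, q_table, rng, visit_counts)
        visit_counts[i, action] += 1
        name = ACTIONS[action]
        if name == "accept":
            f_t = 0
            rewards.append(f_t)
            trace.records.append((t, name, float(W_grid[i]), f_t))
            break
        j = i + 1 if name == "up" else i - 1
        if j < 0 or j >= grid.size:
            j = i  # boundary: move clamps to the same node
        f_t = step_reward(W_grid[j], W_grid[i])
        # tabular backup from experience: a penalized edge is confirmed
        # unusable, a usable one takes the value of its target row
        if j == i or f_t == -1:
            q_table[i, action] = -1.0
        else:
            q_table[i, action] = float(q_table[j].max())
        rewards.append(f_t)
        trace.records.append((t, name, float(W_grid[j]), f_t))
        if f_t >= 0:
            i = j  # penalized moves are reverted
    trace.Q = discounted_return(rewards, params.kappa)
    final_mask = (prob_map >= grid[i]).astype(np.uint8)
    return final_mask, trace
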