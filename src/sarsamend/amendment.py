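"""SARSA(lambda) curve traveling: closing gaps in detected boundaries.

Detected membrane curves are often interrupted by gaps. For every open
endpoint, the visible arm of its curve is traced and fitted with a
polynomial model (:mod:`sarsamend.fitting`); a walker then travels from
the endpoint through the 8-connected pixel grid, rewarded for landing on
marked pixels and penalised for blank ones, with the model's fit cost of
each candidate pixel subtracted as a shaping term so that the walk
follows the expected curve trend. Action values are learned on-policy by
SARSA(lambda) with replacing-free accumulating eligibility traces. When
the walker reaches a marked pixel outside its own arm the gap is
considered closed and the blank pixels of the successful trajectory are
committed to the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import CurveModel, FitConfig, InsufficientSupportError, fit_segment

__all__ = [
    "MOVES",
    "SarsaConfig",
    "QFunction",
    "EligibilityTrace",
    "find_endpoints",
    "travel_reward",
    "sarsa_update",
    "close_gap",
    "amend",
]

# The 8 unit moves, fixed order for deterministic tie-breaking.
MOVES: tuple[tuple[int, int], ...] = (
    (-1, 0), (1, 0), (0, -1), (0, 1),
    (-1, -1), (1, -1), (-1, 1), (1, 1),
)


@dataclass(frozen=True)
class SarsaConfig:
    """Learning and termination parameters of the gap-closing walker.

    gain / gap_penalty are the per-step rewards for landing on a marked
    resp. blank pixel; model_weight scales the fit-cost shaping term and
    target_weight scales the connection-cost shaping (distance to the
    nearest marked pixel outside the walker's own arm) that draws a
    near-miss track onto the opposite curve. q_threshold aborts a walk
    whose learned action value has collapsed, maximal_step caps the
    steps of one episode, and gaps whose grid length exceeds
    max_gap_len are skipped entirely.
    """

    alpha_lr: float = 0.1
    gamma: float = 0.95
    lam: float = 0.9
    epsilon: float = 0.1
    epsilon_decay: float = 0.95
    gap_penalty: float = 10.0
    gain: float = 1.0
    q_threshold: float = -100.0
    max_gap_len: float = 15.0
    maximal_step: int | None = None
    episodes: int = 1
    model_weight: float = 1.0
    target_weight: float = 0.5
    mask_uphill_moves: bool = False

    def __post_init__(self):
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must lie in [0, 1)")
        if not (0 <= self.lam <= 1):
            raise ValueError("lambda must lie in [0, 1]")
        if self.gap_penalty <= 0 or self.gain <= 0:
            raise ValueError("gap_penalty and gain must be positive")
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")

    @property
    def step_cap(self) -> int:
        if self.maximal_step is not None:
            return self.maximal_step
        return int(40 * self.max_gap_len)


class QFunction(dict):
    """State-action value table over (pixel, move); unseen pairs read 0."""

    def value(self, state, action) -> float:
        return self.get((state, action), 0.0)


class EligibilityTrace(dict):
    """Decaying per-(pixel, move) visit memory; unseen pairs read 0."""

    def value(self, state, action) -> float:
        return self.get((state, action), 0.0)


_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(b: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.convolve(b.astype(np.int32), _NEIGH_KERNEL, mode="constant", cval=0)


def find_endpoints(boundary_map) -> list[tuple[int, int]]:
    """Marked pixels with exactly one marked 8-neighbour, in raster order.

    Isolated marked pixels (no neighbours) are not endpoints: they carry
    no curve arm to extend.
    """
    b = np.asarray(boundary_map) != 0
    counts = _neighbor_counts(b)
    rows, cols = np.nonzero(b & (counts == 1))
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def travel_reward(next_is_marked: bool, model_dist: float, cfg: SarsaConfig) -> float:
    """Reward for stepping onto the next pixel.

    +gain for a marked pixel, -gap_penalty for a blank one, minus the
    model-weighted fit cost of the destination in either case.
    """
    if model_dist < 0:
        raise ValueError("model_dist must be non-negative")
    base = cfg.gain if next_is_marked else -cfg.gap_penalty
    return base - cfg.model_weight * model_dist


_TRACE_FLOOR = 1e-12


def sarsa_update(Q: QFunction, e: EligibilityTrace, s, a, r, s_next, a_next,
                 cfg: SarsaConfig) -> tuple[QFunction, EligibilityTrace]:
    """One SARSA(lambda) backup.

    delta = r + gamma Q(s', a') - Q(s, a); the visited pair's trace is
    incremented by 1, every stored pair receives alpha * delta * e, and
    all traces decay by gamma * lambda. A terminal next state is passed
    as ``a_next=None`` (its Q contribution is 0). Tables are updated in
    place and returned.
    """
    q_next = Q.value(s_next, a_next) if a_next is not None else 0.0
    delta = r + cfg.gamma * q_next - Q.value(s, a)
    e[(s, a)] = e.value(s, a) + 1.0
    decay = cfg.gamma * cfg.lam
    dead = []
    for pair, trace in e.items():
        Q[pair] = Q.get(pair, 0.0) + cfg.alpha_lr * delta * trace
        trace *= decay
        if trace < _TRACE_FLOOR:
            dead.append(pair)
        else:
            e[pair] = trace
    for pair in dead:
        del e[pair]
    return Q, e


def _model_dist(model: CurveModel | None, pos: tuple[int, int]) -> float:
    if model is None:
        return 0.0
    return model.pixel_distance(pos[0], pos[1])


def _shaped_reward(b, nxt, model, dt, cfg: SarsaConfig) -> float:
    """Travel reward plus the connection-cost shaping term.

    ``dt`` is the distance transform to the marked pixels outside the
    walker's own arm; subtracting it realises the goal of minimising the
    connection cost, pulling a near-miss track onto the opposite curve.
    """
    r = travel_reward(bool(b[nxt]), _model_dist(model, nxt), cfg)
    if dt is not None:
        r -= cfg.target_weight * float(dt[nxt])
    return r


def _legal_moves(pos, b, visited, forbidden, model, cfg):
    h, w = b.shape
    out = []
    cur_dist = _model_dist(model, pos) if cfg.mask_uphill_moves else 0.0
    for mv in MOVES:
        nxt = (pos[0] + mv[0], pos[1] + mv[1])
        if not (0 <= nxt[0] < h and 0 <= nxt[1] < w):
            continue
        if nxt in visited or nxt in forbidden:
            continue
        if cfg.mask_uphill_moves and not b[nxt] and _model_dist(model, nxt) > cur_dist:
            continue
        out.append((mv, nxt))
    return out


def _select_action(pos, b, visited, forbidden, model, Q, cfg, eps, rng, dt=None):
    """Epsilon-greedy action choice with a one-step shaped-reward lookahead.

    The greedy score of a move is Q(s, a) plus the shaped immediate
    reward of its destination, so the very first episode already follows
    the fitted curve model instead of wandering over an all-zero Q
    table. Ties break on the fixed move order.
    """
    legal = _legal_moves(pos, b, visited, forbidden, model, cfg)
    if not legal:
        return None, None
    if eps > 0 and rng.random() < eps:
        mv, nxt = legal[rng.integers(len(legal))]
        return mv, nxt
    best = None
    best_score = -np.inf
    for mv, nxt in legal:
        score = Q.value(pos, mv) + _shaped_reward(b, nxt, model, dt, cfg)
        if score > best_score:
            best, best_score = (mv, nxt), score
    return best


def close_gap(boundary_map, endpoint, model: CurveModel | None, cfg: SarsaConfig,
              seed: int, arm: frozenset | None = None):
    """Attempt to close the gap at one open endpoint.

    The walker starts on ``endpoint`` and travels over the grid; moves
    onto its own traced arm (``arm``) or onto already-visited pixels are
    disallowed. An episode ends in success when a marked pixel outside
    the arm is reached, and in failure when the chosen action value
    drops below ``cfg.q_threshold``, the step cap is hit, or no legal
    move remains. After a successful learning episode a purely greedy
    rollout of the learned policy produces the committed connection, so
    exploratory detours are not written into the map (the exploratory
    trajectory itself is committed only if the rollout fails). On
    failure the map is returned untouched.

    Returns ``(map', closed, Q)``.
    """
    from scipy import ndimage

    b = np.asarray(boundary_map) != 0
    endpoint = (int(endpoint[0]), int(endpoint[1]))
    if arm is None:
        arm = frozenset(_trace_walk(b, endpoint, 15))
    forbidden = frozenset(arm) | {endpoint}
    # connection-cost field: distance to the marked pixels of other arms
    target = b.copy()
    for p in forbidden:
        target[p] = False
    if target.any():
        dt = ndimage.distance_transform_edt(~target)
    else:
        dt = None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, endpoint[0], endpoint[1]]))
    Q = QFunction()

    for episode in range(cfg.episodes):
        e = EligibilityTrace()
        eps = cfg.epsilon * cfg.epsilon_decay**episode
        pos = endpoint
        visited = {endpoint}
        path: list[tuple[int, int]] = []
        action, nxt = _select_action(pos, b, visited, forbidden, model, Q, cfg, eps, rng, dt)
        steps = 0
        while action is not None:
            r = _shaped_reward(b, nxt, model, dt, cfg)
            steps += 1
            if steps > cfg.step_cap:
                sarsa_update(Q, e, pos, action, r, nxt, None, cfg)
                break
            success = bool(b[nxt])  # marked and outside the arm: gap closed
            if not success:
                path.append(nxt)
                visited.add(nxt)
            if success:
                sarsa_update(Q, e, pos, action, r, nxt, None, cfg)
                final = _greedy_rollout(b, endpoint, forbidden, model, cfg, dt)
                if final is None:
                    final = path
                if len(final) > 2 * cfg.max_gap_len:
                    break  # a wander this long is not a credible connection
                out = b.copy()
                for p in final:
                    out[p] = True
                return out, True, Q
            next_action, next_nxt = _select_action(nxt, b, visited, forbidden, model, Q, cfg, eps, rng, dt)
            sarsa_update(Q, e, pos, action, r, nxt, next_action, cfg)
            if next_action is None:
                break  # dead end
            if Q.value(nxt, next_action) < cfg.q_threshold:
                break
            pos, action, nxt = nxt, next_action, next_nxt
    return b.copy(), False, Q


def _greedy_rollout(b, endpoint, forbidden, model, cfg, dt=None) -> list[tuple[int, int]] | None:
    """Deterministic model-supervised walk committed after a successful
    episode: at each step the move with the best shaped immediate reward
    is taken, so the written connection follows the fitted curve without
    the learning episode's exploratory detours. Returns the blank pixels
    of the path on success, None on failure (the exploratory trajectory
    is the fallback)."""
    pos = endpoint
    visited = {endpoint}
    path: list[tuple[int, int]] = []
    rng = np.random.default_rng(0)  # never consulted at eps=0
    empty_q = QFunction()
    for _ in range(cfg.step_cap):
        action, nxt = _select_action(pos, b, visited, forbidden, model, empty_q, cfg, 0.0, rng, dt)
        if action is None:
            return None
        if b[nxt]:
            return path
        path.append(nxt)
        visited.add(nxt)
        pos = nxt
    return None


def _trace_walk(b: np.ndarray, endpoint: tuple[int, int], limit: int) -> list[tuple[int, int]]:
    """Full backward walk from an endpoint (endpoint first), up to ``limit`` px."""
    h, w = b.shape
    visited = {endpoint}
    walk = [endpoint]
    cur = endpoint
    while len(walk) < limit:
        r, c = cur
        nxt = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1) for dc in (-1, 0, 1)
            if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w
            and b[r + dr, c + dc] and (r + dr, c + dc) not in visited
        ]
        if len(nxt) != 1:
            break
        cur = nxt[0]
        visited.add(cur)
        walk.append(cur)
    return walk


def _gap_length(b: np.ndarray, endpoint: tuple[int, int], arm: frozenset) -> float:
    """Grid distance to the nearest marked pixel outside the arm.

    Measured in king moves (Chebyshev), the walker's own step metric, so
    a gap of g missing pixels on an 8-connected curve has length ~g+1
    regardless of its orientation.
    """
    marked = np.argwhere(b)
    if marked.size == 0:
        return np.inf
    mask = np.array([tuple(p) not in arm for p in marked])
    others = marked[mask]
    if others.size == 0:
        return np.inf
    d = np.maximum(
        np.abs(others[:, 0] - endpoint[0]), np.abs(others[:, 1] - endpoint[1])
    )
    return float(d.min())


def amend(boundary_map, fit_cfg: FitConfig | None = None,
          sarsa_cfg: SarsaConfig | None = None, seed: int = 0) -> np.ndarray:
    """Close the gaps of a boundary map, endpoint by endpoint.

    Endpoints are processed in raster order; for each one the curve arm
    is traced and fitted, the gap length (grid distance to the nearest
    marked pixel of a different arm) is estimated, gaps longer than
    ``sarsa_cfg.max_gap_len`` are skipped, and the remaining ones are
    attempted with :func:`close_gap`. Endpoints swallowed by an earlier
    closure are not revisited; a closure can leave a short stub when it
    joins the opposite curve mid-arm, so further passes run until a pass
    closes nothing. Marked pixels are never removed, and a map with no
    endpoints is returned unchanged.
    """
    if fit_cfg is None:
        fit_cfg = FitConfig()
    if sarsa_cfg is None:
        sarsa_cfg = SarsaConfig()
    b = (np.asarray(boundary_map) != 0).copy()
    idx = 0
    # endpoint -> marked-pixel count at its last attempt; an endpoint is
    # retried only after the map has changed since then
    last_attempt: dict[tuple[int, int], int] = {}
    for _pass in range(8):
        progress = False
        for ep in find_endpoints(b):
            n_marked = int(b.sum())
            if last_attempt.get(ep) == n_marked:
                continue
            idx += 1
            walk = _trace_walk(b, ep, fit_cfg.neighborhood)
            arm = frozenset(walk)
            if _gap_length(b, ep, arm) > sarsa_cfg.max_gap_len:
                continue
            last_attempt[ep] = n_marked
            kept = walk[fit_cfg.ignore_near_gap:]
            model: CurveModel | None
            if len(kept) >= fit_cfg.theta_dim:
                try:
                    model = fit_segment(np.asarray(kept[::-1]), fit_cfg)
                except InsufficientSupportError:
                    model = None
            else:
                model = None
            new_b, closed, _ = close_gap(b, ep, model, sarsa_cfg, seed=int(seed) + idx, arm=arm)
            if closed:
                b = new_b
                progress = True
        if not progress:
            break
    return b
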