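"""Particle-swarm search over (weight_decay, w_bce, w_dice).

The swarm minimizes a fitness callback — for hyperparameter tuning this is
the *negative* validation Dice of a training run, so lower is better.  The
IoU weight is derived as w_iou = max(0, 1 - w_bce - w_dice) so the loss
mixture stays on the unit simplex (``simplex_mode='literal'`` instead uses
w_iou = max(0, 1 - w_bce), which couples the IoU weight to BCE only).

Velocity/position updates follow the canonical PSO rule

    v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x);  x <- clip(x + v)

with positions clipped to the search box at every step.  The weight-decay
axis is sampled log-uniformly at initialization since plausible values span
three decades.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {
    "weight_decay": (1e-5, 1e-2),
    "w_bce": (0.1, 0.6),
    "w_dice": (0.2, 0.7),
}

_DIMS = ("weight_decay", "w_bce", "w_dice")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = np.inf


@dataclass
class SwarmConfig:
    n_pop: int = 10
    max_iter: int = 20
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0
    simplex_mode: str = "joint"   # joint: w_iou = 1 - w_bce - w_dice; literal: 1 - w_bce
    cache_decimals: int = 6

    def __post_init__(self):
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.simplex_mode not in ("joint", "literal"):
            raise ValueError("simplex_mode must be 'joint' or 'literal'")
        for dim in _DIMS:
            lo, hi = self.bounds[dim]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"infeasible bounds for {dim}: ({lo}, {hi})")

    @property
    def lo(self) -> np.ndarray:
        return np.array([self.bounds[d][0] for d in _DIMS])

    @property
    def hi(self) -> np.ndarray:
        return np.array([self.bounds[d][1] for d in _DIMS])


def iou_weight(w_bce: float, w_dice: float, mode: str = "joint") -> float:
    if mode == "literal":
        return max(0.0, 1.0 - w_bce)
    return max(0.0, 1.0 - w_bce - w_dice)


def _project_simplex(pos: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Rescale (w_bce, w_dice) onto the simplex boundary when their sum
    exceeds 1, respecting the lower bounds."""
    s = pos[1] + pos[2]
    if s > 1.0:
        excess = s - 1.0
        slack = np.array([pos[1] - lo[1], pos[2] - lo[2]])
        total = slack.sum()
        if total <= 0:
            pos[1:] = lo[1:]
        else:
            pos[1] -= excess * slack[0] / total
            pos[2] -= excess * slack[1] / total
    return pos


def init_swarm(cfg: SwarmConfig, rng: np.random.Generator) -> list[Particle]:
    """Uniform positions in the box (log-uniform on weight decay), feasible
    w.r.t. the simplex, velocities uniform in +-10% of each bound's width."""
    lo, hi = cfg.lo, cfg.hi
    particles = []
    for _ in range(cfg.n_pop):
        wd = float(np.exp(rng.uniform(np.log(lo[0]), np.log(hi[0]))))
        pos = np.array([wd,
                        rng.uniform(lo[1], hi[1]),
                        rng.uniform(lo[2], hi[2])])
        pos = _project_simplex(pos, lo)
        width = hi - lo
        vel = rng.uniform(-0.1, 0.1, size=3) * width
        particles.append(Particle(pos, vel, pos.copy()))
    return particles


def pso_step(particles: list[Particle], g_best_pos: np.ndarray, g_best_fit: float,
             objective, cfg: SwarmConfig, rng: np.random.Generator,
             cache: dict | None = None):
    """One swarm iteration: evaluate, update bests, then move every particle."""
    lo, hi = cfg.lo, cfg.hi
    for i, p in enumerate(particles):
        key = tuple(np.round(p.position, cfg.cache_decimals))
        try:
            if cache is not None and key in cache:
                fit = cache[key]
            else:
                fit = float(objective(p.position.copy()))
                if cache is not None:
                    cache[key] = fit
        except Exception as exc:  # a failed fitness run skips the particle
            logger.warning("fitness evaluation failed for particle %d at %s: %s",
                           i, p.position, exc)
            continue
        if fit < p.best_fitness:
            p.best_fitness = fit
            p.best_position = p.position.copy()
        if fit < g_best_fit:
            g_best_fit = fit
            g_best_pos = p.position.copy()
    for p in particles:
        r1 = rng.random(3)
        r2 = rng.random(3)
        p.velocity = (cfg.inertia * p.velocity
                      + cfg.c1 * r1 * (p.best_position - p.position)
                      + cfg.c2 * r2 * (g_best_pos - p.position))
        p.position = np.clip(p.position + p.velocity, lo, hi)
        p.position = _project_simplex(p.position, lo)
    return particles, g_best_pos, g_best_fit


def run_pso(objective, cfg: SwarmConfig):
    """Full swarm search.

    Returns ``(result, history)`` where ``result`` is a dict with keys
    weight_decay, w_bce, w_dice, w_iou and fitness (the best value of the
    objective ever observed), and ``history`` is a list of per-iteration
    records (iter, best fitness so far, best position so far) — monotone
    non-increasing in fitness.
    """
    rng = np.random.default_rng(cfg.seed)
    particles = init_swarm(cfg, rng)
    g_best_pos = particles[0].position.copy()
    g_best_fit = np.inf
    cache: dict = {}
    history = []
    for it in range(cfg.max_iter):
        particles, g_best_pos, g_best_fit = pso_step(
            particles, g_best_pos, g_best_fit, objective, cfg, rng, cache)
        history.append({"iter": it, "g_best_fitness": g_best_fit,
                        "g_best_position": g_best_pos.copy()})
    if not np.isfinite(g_best_fit):
        warnings.warn("no successful fitness evaluation; returning initial position")
    wd, w_bce, w_dice = (float(v) for v in g_best_pos)
    w_iou = iou_weight(w_bce, w_dice, cfg.simplex_mode)
    total = w_bce + w_dice + w_iou
    if cfg.simplex_mode == "joint" and total > 0:
        w_bce, w_dice, w_iou = (w / total for w in (w_bce, w_dice, w_iou))
    result = {"weight_decay": wd, "w_bce": w_bce, "w_dice": w_dice,
              "w_iou": w_iou, "fitness": float(g_best_fit)}
    return result, history
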