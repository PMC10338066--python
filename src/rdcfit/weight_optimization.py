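"""Sparsity-penalized optimization of ensemble member weights against RDCs.

For a local region of residues P..R with per-member predicted couplings
D_ij (member i, record j) and measurements D_j, the objective is

    F(w) = sqrt( sum_j (sum_i w_i D_ij - D_j)^2 / n_records )
           / sqrt( Da^2 (4 + 3 Rh^2) / 5 )
           - C * sum_i (w_i + eps)^2,        eps = 1e-4,

minimized over the probability simplex (w_i >= 0, sum w_i = 1).  The first
term is exactly the regional Q factor of the weighted-ensemble prediction,
with Da and Rh held fixed from an external tensor fit (a global fit excluding
the region, or a fixed reference structure).  The penalty term rewards
concentrating weight on few members — sum (w_i + eps)^2 is maximal at a vertex
of the simplex — so increasing the sparsity constant C trades fit quality for
a smaller ensemble.  Scanning C and keeping the largest value whose solution
still fits the data to within experimental uncertainty yields the minimal
ensemble that satisfies the couplings.

Minimization uses Metropolis simulated annealing with pairwise weight-transfer
moves, which preserve the simplex exactly; a brute-force simplex-grid search
is provided as an independent oracle for small member counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySelectionError, UndefinedNormalizationError
from .rdc_core import RDCTable, normalize_coupling_types

logger = logging.getLogger("rdcfit")


@dataclass
class WeightObjectiveConfig:
    """Configuration of the sparse-weight objective.

    ``region`` is the inclusive residue interval (P, R) the records belong to
    (bookkeeping only once predictions are extracted); ``c`` is the sparsity
    constant; ``epsilon`` the small weight offset inside the penalty;
    ``per_member_misfit=True`` switches to the alternative reading in which
    each member's misfit is weighted individually instead of misfitting the
    ensemble-averaged prediction.
    """

    region: tuple[int, int]
    c: float = 0.0
    epsilon: float = 1e-4
    per_member_misfit: bool = False
    selection_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.region[0] > self.region[1]:
            raise ValueError("region start must be <= region end")
        if self.c < 0:
            raise ValueError("sparsity constant C must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis weight search.

    ``t0=None`` sets the start temperature to 10x the spread of F over 100
    random simplex points; cooling multiplies T by ``cooling`` after
    ``moves_per_t`` proposed moves until T < ``t_min_frac * t0``.
    ``delta_max`` is the largest weight transfer per move at T = t0.
    """

    t0: float | None = None
    cooling: float = 0.95
    moves_per_t: int = 200
    t_min_frac: float = 1e-4
    delta_max: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.moves_per_t <= 0 or self.t_min_frac <= 0 or self.delta_max <= 0:
            raise ValueError("schedule parameters must be positive")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")


@dataclass
class WeightSolution:
    """Optimized weights and objective decomposition (F = misfit - penalty)."""

    weights: np.ndarray
    f: float
    misfit: float  # regional Q of the weighted prediction
    penalty: float  # C * sum (w_i + eps)^2
    selected: list[int]  # member indices with weight above the threshold
    seed: int | None = None
    trace: list[tuple[float, float]] = field(default_factory=list)  # (T, best F)

    def to_dict(self, member_ids: list[str] | None = None) -> dict:
        ids = member_ids or [str(i) for i in range(len(self.weights))]
        return {
            "weights": {ids[i]: float(w) for i, w in enumerate(self.weights)},
            "F": self.f,
            "misfit_q": self.misfit,
            "penalty": self.penalty,
            "selected": [ids[i] for i in self.selected],
            "seed": self.seed,
        }


def _normalization(da: float, rh: float) -> float:
    if da == 0:
        raise UndefinedNormalizationError("objective undefined: Da is zero")
    return math.sqrt(da**2 * (4.0 + 3.0 * rh**2) / 5.0)


def objective_f(
    weights: np.ndarray,
    d_members: np.ndarray,
    d_meas: np.ndarray,
    da: float,
    rh: float,
    config: WeightObjectiveConfig,
) -> tuple[float, float, float]:
    """Evaluate (F, misfit, penalty) for one weight vector.

    ``d_members`` has shape (n_members, n_records) and holds per-member
    predicted couplings for the region's records; ``d_meas`` the measured
    values.  Da and Rh are fixed externally.  With C = 0 the value equals the
    regional Q of the weighted ensemble prediction.
    """
    d_members = np.asarray(d_members, dtype=float)
    d_meas = np.asarray(d_meas, dtype=float)
    if d_members.ndim != 2 or d_members.shape[1] != d_meas.size:
        raise ValueError("d_members must be (n_members, n_records)")
    if d_meas.size == 0:
        raise EmptySelectionError("no records in the optimization region")
    weights = np.asarray(weights, dtype=float)
    norm = _normalization(da, rh)
    if config.per_member_misfit:
        sq = np.mean(weights @ (d_members - d_meas) ** 2)
    else:
        resid = weights @ d_members - d_meas
        sq = np.mean(resid**2)
    misfit = math.sqrt(sq) / norm
    penalty = config.c * float(np.sum((weights + config.epsilon) ** 2))
    return misfit - penalty, misfit, penalty


def _random_simplex(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.exponential(1.0, n)
    return w / w.sum()


_POLISH_STEPS = (0.2, 0.1, 0.03, 0.01, 0.003, 0.001, 0.0003, 0.0001)


def _greedy_polish(w: np.ndarray, f_of, f_cur: float) -> tuple[np.ndarray, float]:
    """Deterministic pairwise-transfer descent to finish the stochastic search.

    Sweeps all ordered member pairs with a geometric ladder of transfer sizes,
    accepting every strictly improving move, until one full sweep yields no
    improvement.  The misfit term is quadratic in the weights, so pairwise
    coordinate descent on the simplex converges to the basin's minimum.
    """
    n = w.size
    w = w.copy()
    improved = True
    while improved:
        improved = False
        for step in _POLISH_STEPS:
            for i in range(n):
                if w[i] == 0.0:
                    continue
                for j in range(n):
                    if i == j:
                        continue
                    delta = min(step, w[i])
                    w_new = w.copy()
                    w_new[i] -= delta
                    w_new[j] += delta
                    f_new = f_of(w_new)
                    if f_new < f_cur - 1e-15:
                        w, f_cur = w_new, f_new
                        improved = True
    return w, f_cur


def anneal_weights(
    d_members: np.ndarray,
    d_meas: np.ndarray,
    da: float,
    rh: float,
    config: WeightObjectiveConfig,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    n_starts: int = 1,
    init: np.ndarray | None = None,
) -> WeightSolution:
    """Minimize F over the simplex by Metropolis simulated annealing.

    Moves transfer delta ~ U(0, delta_max) * (T/T0) of weight from one member
    to another, clamped at zero, so the simplex constraint holds exactly at
    every step.  A deterministic greedy pairwise-transfer polish finishes the
    search from the annealed point.  The best-ever point is returned; runs are
    fully reproducible given ``seed``.  ``n_starts > 1`` restarts from random
    simplex points and keeps the best outcome.
    """
    d_members = np.asarray(d_members, dtype=float)
    d_meas = np.asarray(d_meas, dtype=float)
    n = d_members.shape[0]
    if n < 2:
        raise ValueError("annealing needs >=2 members")
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)

    def f_of(w: np.ndarray) -> float:
        return objective_f(w, d_members, d_meas, da, rh, config)[0]

    t0 = schedule.t0
    if t0 is None:
        probe = np.array([f_of(_random_simplex(rng, n)) for _ in range(100)])
        spread = float(probe.max() - probe.min())
        t0 = 10.0 * spread if spread > 0 else 1.0

    best_w, best_f = None, math.inf
    trace: list[tuple[float, float]] = []
    for start in range(n_starts):
        if init is not None and start == 0:
            w = np.asarray(init, dtype=float).copy()
        elif start == 0:
            w = np.full(n, 1.0 / n)
        else:
            w = _random_simplex(rng, n)
        f_cur = f_of(w)
        if f_cur < best_f:
            best_w, best_f = w.copy(), f_cur
        t = t0
        while t >= schedule.t_min_frac * t0:
            for _ in range(schedule.moves_per_t):
                i, j = rng.choice(n, size=2, replace=False)
                delta = rng.uniform(0.0, schedule.delta_max) * (t / t0)
                delta = min(delta, w[i])
                if delta == 0.0:
                    continue
                w_new = w.copy()
                w_new[i] -= delta
                w_new[j] += delta
                f_new = f_of(w_new)
                if f_new <= f_cur or rng.random() < math.exp(-(f_new - f_cur) / t):
                    w, f_cur = w_new, f_new
                    if f_cur < best_f:
                        best_w, best_f = w.copy(), f_cur
            trace.append((t, best_f))
            t *= schedule.cooling
        w_pol, f_pol = _greedy_polish(w, f_of, f_cur)
        if f_pol < best_f:
            best_w, best_f = w_pol, f_pol
    assert best_w is not None
    best_w, best_f = _greedy_polish(best_w, f_of, best_f)
    # exact re-evaluation of the decomposition at the best point
    f, misfit, penalty = objective_f(best_w, d_members, d_meas, da, rh, config)
    selected = [int(i) for i in np.flatnonzero(best_w > config.selection_threshold)]
    return WeightSolution(best_w, f, misfit, penalty, selected, seed, trace)


def simplex_grid_search(
    d_members: np.ndarray,
    d_meas: np.ndarray,
    da: float,
    rh: float,
    config: WeightObjectiveConfig,
    resolution: float = 0.01,
) -> WeightSolution:
    """Exhaustive search over the simplex grid (independent oracle, small N).

    Enumerates all weight vectors with components that are multiples of
    ``resolution``; exponential in the member count, intended for N <= 4.
    """
    d_members = np.asarray(d_members, dtype=float)
    n = d_members.shape[0]
    steps = int(round(1.0 / resolution))

    best_w, best_f = None, math.inf

    def recurse(prefix: list[int], remaining: int, depth: int) -> None:
        nonlocal best_w, best_f
        if depth == n - 1:
            counts = prefix + [remaining]
            w = np.array(counts, dtype=float) / steps
            f = objective_f(w, d_members, d_meas, da, rh, config)[0]
            if f < best_f:
                best_w, best_f = w, f
            return
        for k in range(remaining + 1):
            recurse(prefix + [k], remaining - k, depth + 1)

    recurse([], steps, 0)
    assert best_w is not None
    f, misfit, penalty = objective_f(best_w, d_members, d_meas, da, rh, config)
    selected = [int(i) for i in np.flatnonzero(best_w > config.selection_threshold)]
    return WeightSolution(best_w, f, misfit, penalty, selected, None)


@dataclass
class SparsityScan:
    """Trade-off curve over the sparsity constant C."""

    c_grid: list[float]
    solutions: list[WeightSolution]
    rms_misfit_hz: list[float]
    minimal_index: int | None  # index of the largest feasible C
    feasible: bool

    @property
    def minimal_solution(self) -> WeightSolution | None:
        return self.solutions[self.minimal_index] if self.feasible else None


def scan_sparsity(
    d_members: np.ndarray,
    d_meas: np.ndarray,
    da: float,
    rh: float,
    config: WeightObjectiveConfig,
    c_grid: list[float],
    sigma_bar: float,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    n_starts: int = 1,
) -> SparsityScan:
    """Anneal at each C (ascending) and locate the minimal ensemble.

    The minimal ensemble is the solution at the largest C whose regional rms
    misfit (Hz) stays within the experimental noise estimate ``sigma_bar``.
    Each C gets a deterministic sub-seed derived from ``seed``.
    """
    if any(b < a for a, b in zip(c_grid, c_grid[1:])):
        raise ValueError("c_grid must be ascending")
    d_members = np.asarray(d_members, dtype=float)
    d_meas = np.asarray(d_meas, dtype=float)
    norm = _normalization(da, rh)
    solutions, rms = [], []
    for k, c in enumerate(c_grid):
        cfg = WeightObjectiveConfig(
            config.region,
            c,
            config.epsilon,
            config.per_member_misfit,
            config.selection_threshold,
        )
        sol = anneal_weights(
            d_members,
            d_meas,
            da,
            rh,
            cfg,
            schedule,
            seed=(seed * 1000 + k) % (2**31),
            n_starts=n_starts,
        )
        solutions.append(sol)
        rms.append(sol.misfit * norm)
    feasible = [k for k, r in enumerate(rms) if r <= sigma_bar]
    if feasible:
        return SparsityScan(list(c_grid), solutions, rms, feasible[-1], True)
    logger.warning("no C on the grid keeps rms misfit within sigma_bar=%.3g Hz", sigma_bar)
    return SparsityScan(list(c_grid), solutions, rms, None, False)


@dataclass
class CrossValidationResult:
    free_q_mean: float
    free_q_sd: float
    train_q_mean: float
    details: list[dict]


def cross_validate_weights(
    d_members: np.ndarray,
    d_meas: np.ndarray,
    da: float,
    rh: float,
    config: WeightObjectiveConfig,
    holdout_fraction: float = 0.1,
    repeats: int = 10,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    n_starts: int = 1,
) -> CrossValidationResult:
    """Cross-validated weight optimization with frozen tensor parameters.

    Per repeat a random fraction of records is held out, weights are refit on
    the remainder (Da, Rh and the tensor orientation stay fixed — they were
    determined before the weight optimization), and the free Q is computed on
    the held-out records.  Repeats use disjoint sub-seeds of ``seed``.
    """
    if not (0.0 < holdout_fraction <= 0.5):
        raise ValueError("holdout fraction must be in (0, 0.5]")
    d_members = np.asarray(d_members, dtype=float)
    d_meas = np.asarray(d_meas, dtype=float)
    n_rec = d_meas.size
    n_hold = max(1, int(round(holdout_fraction * n_rec)))
    if n_rec - n_hold < 1:
        raise ValueError("degenerate split: no training records left")
    norm = _normalization(da, rh)
    rng = np.random.default_rng(seed)
    details = []
    for rep in range(repeats):
        hold = rng.choice(n_rec, size=n_hold, replace=False)
        mask = np.zeros(n_rec, dtype=bool)
        mask[hold] = True
        sol = anneal_weights(
            d_members[:, ~mask],
            d_meas[~mask],
            da,
            rh,
            config,
            schedule,
            seed=(seed * 10007 + rep) % (2**31),
            n_starts=n_starts,
        )
        resid_free = sol.weights @ d_members[:, mask] - d_meas[mask]
        free_q = float(np.sqrt(np.mean(resid_free**2)) / norm)
        details.append(
            {
                "repeat": rep,
                "held_out": hold.tolist(),
                "train_q": sol.misfit,
                "free_q": free_q,
                "weights": sol.weights.tolist(),
            }
        )
    free = np.array([d["free_q"] for d in details])
    train = np.array([d["train_q"] for d in details])
    return CrossValidationResult(
        float(free.mean()), float(free.std(ddof=1)) if repeats > 1 else 0.0,
        float(train.mean()), details
    )


def per_residue_rmsd(
    d_pred: np.ndarray | dict,
    table: RDCTable,
    region: tuple[int, int],
    scale_overrides: dict[str, float] | None = None,
) -> float:
    """rms deviation (Hz) between predictions and measurements over a region.

    Both predictions and measurements are first brought onto the NH scale
    (per-type factors, with ``scale_overrides`` taking precedence, e.g. the
    two-bond C'H upscaling), then the rms over the region's records is taken.
    ``d_pred`` is aligned with ``table.df`` rows (array) or keyed by
    (type, resid) pairs (dict).
    """
    from .couplings import nh_scale_factor

    scaled = normalize_coupling_types(table, scale_overrides)
    df = scaled.df
    if isinstance(d_pred, dict):
        pred = np.array([d_pred[(t, int(r))] for t, r in zip(df["type"], df["resid_i"])])
    else:
        pred = np.asarray(d_pred, dtype=float)
        if pred.size != len(df):
            raise ValueError("d_pred must align with table rows")
    # predictions arrive on native per-type scales; apply the same factors
    overrides = scale_overrides or {}
    factors = np.array([overrides.get(t, nh_scale_factor(t)) for t in df["type"]])
    pred = pred * factors
    mask = (df["resid_i"] >= region[0]) & (df["resid_i"] <= region[1])
    if not mask.any():
        raise EmptySelectionError(f"no records in region {region}")
    resid = pred[mask.to_numpy()] - df.loc[mask, "value_hz"].to_numpy()
    return float(np.sqrt(np.mean(resid**2)))
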