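"""Maintenance transition-matrix calibration.

The maintenance efficacy evidence arrives as a *target* distribution over
the CDAI states at the end of the maintenance period, not as a transition
matrix.  A per-cycle 3x3 row-stochastic matrix is therefore derived by
minimising the squared deviation between the propagated and target remission
and mild fractions:

    (remission_predicted - remission_target)^2
        + (mild_predicted - mild_target)^2

This mirrors the spreadsheet-Solver practice the model family descends
from, with two robustness improvements: rows are parameterised on the
simplex (softmax), so every iterate is a valid matrix, and the optimiser is
restarted from multiple seeded starting points, with a convergence record
reported.  With two targets and six free parameters the problem is
under-determined; the returned matrix is one member of the solution set, and
the result object says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "CalibrationTarget",
    "CalibrationConstraints",
    "CalibrationResult",
    "validate_matrix",
    "propagate",
    "calibration_objective",
    "calibrate_transition_matrix",
    "blend_matrices",
]

_TOL_ROW = 1e-9


def validate_matrix(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check a 3x3 row-stochastic matrix; returns it as float ndarray."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name}: expected shape (3, 3), got {m.shape}")
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        raise ValueError(f"{name}: entries must lie in [0, 1]")
    if np.abs(m.sum(axis=1) - 1.0).max() > _TOL_ROW:
        raise ValueError(f"{name}: rows must sum to 1")
    return m


@dataclass
class CalibrationTarget:
    """Start distribution, target fractions and the propagation length."""

    start_distribution: np.ndarray  # (3,) over (remission, mild, mod-severe)
    target_remission: float
    target_mild: float
    n_cycles: int

    def __post_init__(self):
        d = np.asarray(self.start_distribution, dtype=float)
        if d.shape != (3,) or abs(d.sum() - 1.0) > _TOL_ROW or (d < -1e-12).any():
            raise ValueError("start_distribution must be a length-3 distribution")
        self.start_distribution = d
        if not (0.0 <= self.target_remission <= 1.0
                and 0.0 <= self.target_mild <= 1.0
                and self.target_remission + self.target_mild <= 1.0 + 1e-9):
            raise ValueError("targets must be fractions with remission + mild <= 1")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")


@dataclass
class CalibrationConstraints:
    """Optional structure imposed on the calibrated matrix.

    ``fixed_entries`` maps (row, col) to an exact probability; the remaining
    free entries of each row share the leftover mass.  ``monotone_stay``
    adds a soft preference that the stay probability of each state is at
    least as large as every single leaving probability.
    """

    fixed_entries: dict[tuple[int, int], float] = field(default_factory=dict)
    monotone_stay: bool = False

    def validate(self) -> None:
        row_fixed: dict[int, float] = {}
        for (i, j), v in self.fixed_entries.items():
            if not (0 <= i < 3 and 0 <= j < 3):
                raise ValueError(f"fixed entry index out of range: {(i, j)}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fixed entry {(i, j)} outside [0,1]: {v}")
            row_fixed[i] = row_fixed.get(i, 0.0) + v
        for i, s in row_fixed.items():
            n_free = 3 - sum(1 for (r, _c) in self.fixed_entries if r == i)
            if s > 1.0 + 1e-12:
                raise ValueError(f"fixed entries of row {i} sum to {s} > 1")
            if n_free == 0 and abs(s - 1.0) > _TOL_ROW:
                raise ValueError(f"row {i} fully fixed but sums to {s}")


@dataclass
class CalibrationResult:
    """Calibrated matrix plus a convergence record."""

    matrix: np.ndarray
    objective: float
    converged: bool
    n_restarts: int
    best_restart: int
    n_iterations: int
    message: str = (
        "solution set is non-unique (two targets, up to six free parameters); "
        "the reported matrix is one constrained minimiser"
    )


def propagate(start: np.ndarray, matrix: np.ndarray, n_cycles: int) -> np.ndarray:
    """Distribution after applying the matrix for ``n_cycles`` cycles."""
    return np.asarray(start, dtype=float) @ np.linalg.matrix_power(
        np.asarray(matrix, dtype=float), n_cycles
    )


def calibration_objective(matrix: np.ndarray, target: CalibrationTarget) -> float:
    """Sum of squared remission and mild deviations after propagation."""
    m = validate_matrix(matrix)
    end = propagate(target.start_distribution, m, target.n_cycles)
    return float(
        (end[0] - target.target_remission) ** 2
        + (end[1] - target.target_mild) ** 2
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _build_matrix(theta: np.ndarray, free_pos: list[list[int]],
                  fixed: dict[tuple[int, int], float]) -> np.ndarray:
    m = np.zeros((3, 3))
    for (i, j), v in fixed.items():
        m[i, j] = v
    k = 0
    for i in range(3):
        pos = free_pos[i]
        if not pos:
            continue
        leftover = 1.0 - sum(fixed.get((i, j), 0.0) for j in range(3))
        w = _softmax(theta[k:k + len(pos)]) * leftover
        for p, j in enumerate(pos):
            m[i, j] = w[p]
        k += len(pos)
    return m


def _matrix_to_theta(matrix: np.ndarray, free_pos: list[list[int]]) -> np.ndarray:
    theta = []
    for i in range(3):
        for j in free_pos[i]:
            theta.append(np.log(max(matrix[i, j], 1e-9)))
    return np.asarray(theta)


def calibrate_transition_matrix(
    target: CalibrationTarget,
    constraints: CalibrationConstraints | None = None,
    start_values: np.ndarray | None = None,
    tol: float = 1e-8,
    n_restarts: int = 10,
    seed: int = 0,
) -> CalibrationResult:
    """Derive a per-cycle transition matrix hitting the maintenance target.

    A bounded local optimiser (L-BFGS-B on softmax row parameters) is run
    from ``n_restarts`` seeded starting points (plus ``start_values`` when
    supplied); the best solution by (objective, entry entropy) is returned.
    ``converged`` is True when the objective is at most ``tol``; otherwise
    the constrained local minimum is returned, flagged, never silently.
    """
    constraints = constraints or CalibrationConstraints()
    constraints.validate()
    fixed = dict(constraints.fixed_entries)
    free_pos = [[j for j in range(3) if (i, j) not in fixed] for i in range(3)]
    n_free = sum(len(p) for p in free_pos)

    def objective_theta(theta: np.ndarray) -> float:
        m = _build_matrix(theta, free_pos, fixed)
        end = propagate(target.start_distribution, m, target.n_cycles)
        obj = (end[0] - target.target_remission) ** 2 + (
            end[1] - target.target_mild
        ) ** 2
        if constraints.monotone_stay:
            # soft preference: staying >= each single leaving probability
            for i in range(3):
                for j in range(3):
                    if j != i and m[i, j] > m[i, i]:
                        obj += 1e3 * (m[i, j] - m[i, i]) ** 2
        return obj

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if start_values is not None:
        starts.append(_matrix_to_theta(validate_matrix(start_values), free_pos))
    # deterministic identity-leaning start, then random restarts
    ident = np.eye(3) * 0.8 + 0.1
    ident /= ident.sum(axis=1, keepdims=True)
    starts.append(_matrix_to_theta(ident, free_pos))
    while len(starts) < n_restarts + (start_values is not None):
        starts.append(rng.normal(0.0, 1.5, n_free))

    best = None
    total_iters = 0
    for idx, theta0 in enumerate(starts):
        if n_free == 0:
            res_x, res_nit = theta0, 0
        else:
            res = minimize(objective_theta, theta0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12})
            res_x, res_nit = res.x, res.nit
        total_iters += res_nit
        m = _build_matrix(res_x, free_pos, fixed)
        obj = objective_theta(res_x)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = float(np.nansum(-m * np.log(np.where(m > 0, m, 1.0))))
        key = (round(obj, 12), round(ent, 9))
        if best is None or key < best[0]:
            best = (key, m, obj, idx)

    _, matrix, obj, best_idx = best
    # the optimiser never worsens a supplied start
    if start_values is not None:
        start_obj = calibration_objective(start_values, target)
        if start_obj < obj:
            matrix, obj, best_idx = validate_matrix(start_values), start_obj, -1
    return CalibrationResult(
        matrix=matrix,
        objective=float(obj),
        converged=bool(obj <= tol),
        n_restarts=len(starts),
        best_restart=best_idx,
        n_iterations=total_iters,
    )


def blend_matrices(active: np.ndarray, soc: np.ndarray, progress: float) -> np.ndarray:
    """Entrywise blend ``(1 - progress) * active + progress * soc``.

    Models the gradual post-treatment decline of biologic efficacy toward
    standard-of-care dynamics; row-stochasticity is preserved for any
    ``progress`` in [0, 1].
    """
    if not (0.0 <= progress <= 1.0):
        raise ValueError(f"progress must be in [0,1], got {progress}")
    a = validate_matrix(active, "active")
    s = validate_matrix(soc, "soc")
    return (1.0 - progress) * a + progress * s
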