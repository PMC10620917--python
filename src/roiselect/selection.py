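"""Representative ROI selection by sparse and entropy-regularized
convex optimization.

The slide is summarized by a composition matrix ``A`` (clusters x
candidate ROIs, column j = pooled cluster composition of candidate j),
the slide-wide composition ``b``, and per-candidate Shannon entropies
``E``.  Three strategies pick a small set of ROIs whose pooled
composition matches ``b``:

* random sampling of k non-overlapping windows (the field's baseline);
* sparse matching: ``min ||x||_1 s.t. |Ax - b| <= eps, 0 <= x <= 1`` —
  the minimum number of ROIs reproducing the slide composition;
* entropy-regularized matching:
  ``min ||Ax - b||^2 - lambda * E'x  s.t.  0 <= x <= 1, sum(x) = 1`` —
  trades composition fit against tissue heterogeneity so the chosen
  regions are biologically diverse rather than homogeneous.

Selected ROIs are the candidates with weight above a cutoff (0.01 by
default).  The API follows the model/results idiom: build a
:class:`SelectionProblem` from a :class:`~roiselect.tilegrid.TileGrid`
(or matrices), call :meth:`~SelectionProblem.fit`, and read estimates and
diagnostics off the returned :class:`SelectionResult`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .metrics import evaluate_selection, shannon_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "ROIWindow",
    "SelectionProblem",
    "SelectionResult",
    "RandomSelectionResult",
    "enumerate_candidates",
    "select_l1",
    "select_entropy",
    "random_selection",
    "brute_force_select",
]

DEFAULT_THRESHOLD = 0.01
DEFAULT_EPSILON = 1e-3
MAX_EPSILON = 0.25


@dataclass(frozen=True)
class ROIWindow:
    """A square/rectangular ROI in tile coordinates, half-open on both
    axes: rows ``[row0, row0+height_tiles)``, cols ``[col0,
    col0+width_tiles)``."""

    row0: int
    col0: int
    height_tiles: int
    width_tiles: int

    def tile_indices(self, grid) -> np.ndarray:
        if (
            self.row0 < 0
            or self.col0 < 0
            or self.row0 + self.height_tiles > grid.n_rows
            or self.col0 + self.width_tiles > grid.n_cols
        ):
            raise ValueError(f"window {self} outside {grid.n_rows}x{grid.n_cols} grid")
        rows = np.arange(self.row0, self.row0 + self.height_tiles)
        cols = np.arange(self.col0, self.col0 + self.width_tiles)
        return (rows[:, None] * grid.n_cols + cols[None, :]).ravel()

    def overlaps(self, other: "ROIWindow") -> bool:
        return (
            self.row0 < other.row0 + other.height_tiles
            and other.row0 < self.row0 + self.height_tiles
            and self.col0 < other.col0 + other.width_tiles
            and other.col0 < self.col0 + self.width_tiles
        )

    def pixel_bounds(self, tile_size_px: int):
        """(y0, x0, y1, x1) pixel bounds, half-open."""
        return (
            self.row0 * tile_size_px,
            self.col0 * tile_size_px,
            (self.row0 + self.height_tiles) * tile_size_px,
            (self.col0 + self.width_tiles) * tile_size_px,
        )


class SelectionProblem:
    """The ROI-selection model: candidate windows, their composition
    matrix ``A`` (N clusters x M candidates), the WSI composition ``b``
    and the per-candidate entropy vector ``E``.

    Build from a tiled slide with :meth:`from_grid` (the usual route) or
    directly from matrices for synthetic problems.
    """

    def __init__(self, A, b, E=None, candidates=None, grid=None):
        self.A = np.asarray(A, dtype=float)
        self.b = np.asarray(b, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-D (clusters x candidates)")
        if self.b.shape != (self.A.shape[0],):
            raise ValueError("b length must equal the number of clusters")
        col_sums = self.A.sum(axis=0)
        if np.any(np.abs(col_sums - 1.0) > 1e-6):
            raise ValueError("every column of A must sum to 1")
        if abs(self.b.sum() - 1.0) > 1e-6:
            raise ValueError("b must sum to 1")
        if E is None:
            E = np.apply_along_axis(shannon_entropy, 0, self.A)
        self.E = np.asarray(E, dtype=float)
        if self.E.shape != (self.A.shape[1],):
            raise ValueError("E length must equal the number of candidates")
        if np.any(self.E < -1e-12):
            raise ValueError("entropies must be nonnegative")
        self.candidates = list(candidates) if candidates is not None else None
        self.grid = grid

    # -- construction -----------------------------------------------------

    @classmethod
    def from_grid(
        cls, grid, roi_side_tiles: int, stride_tiles: int | None = None
    ) -> "SelectionProblem":
        """Enumerate all grid-aligned square candidate windows of side
        ``roi_side_tiles`` at the given stride (default: the side, i.e.
        non-overlapping candidates) and assemble ``A``, ``b``, ``E``.

        Windows containing no valid tile are dropped.
        """
        if stride_tiles is None:
            stride_tiles = roi_side_tiles
        if stride_tiles < 1:
            raise ValueError("stride_tiles must be >= 1")
        if roi_side_tiles > min(grid.n_rows, grid.n_cols):
            raise ValueError("roi_side_tiles exceeds the grid")
        windows, cols = [], []
        for r0 in range(0, grid.n_rows - roi_side_tiles + 1, stride_tiles):
            for c0 in range(0, grid.n_cols - roi_side_tiles + 1, stride_tiles):
                w = ROIWindow(r0, c0, roi_side_tiles, roi_side_tiles)
                idx = w.tile_indices(grid)
                sel = idx[grid.valid[idx]]
                if sel.size == 0:
                    continue
                windows.append(w)
                cols.append(grid.compositions[sel].mean(axis=0))
        if not windows:
            raise ValueError("no candidate window contains a valid tile")
        A = np.array(cols).T
        return cls(A, grid.wsi_composition(), candidates=windows, grid=grid)

    @classmethod
    def from_pixel_roi_size(
        cls, grid, roi_size_px: int, stride_tiles: int | None = None
    ) -> "SelectionProblem":
        """As :meth:`from_grid` but with the ROI size given in pixels and
        mapped to the nearest whole number of tiles (1000 px -> 4 tiles of
        256 px, 1500 -> 6, 2000 -> 8, 2500 -> 10)."""
        side = max(1, round(roi_size_px / grid.tile_size_px))
        return cls.from_grid(grid, side, stride_tiles)

    @property
    def n_clusters(self) -> int:
        return self.A.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.A.shape[1]

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "entropy", **kwargs):
        """Solve the selection problem.

        ``method`` is one of ``"l1"`` (sparse composition matching),
        ``"entropy"`` (entropy-regularized quadratic program) or
        ``"random"`` (baseline draws; needs ``k``).  Keyword arguments are
        passed to :func:`select_l1`, :func:`select_entropy` or
        :func:`random_selection`.
        """
        if method == "l1":
            return select_l1(self, **kwargs)
        if method == "entropy":
            return select_entropy(self, **kwargs)
        if method == "random":
            return random_selection(self, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def equal_pooled_objective(self, support, lam: float = 1.0) -> float:
        """Discrete objective of a support under equal pooling:
        ``||A x_S - b||^2 - lam * E'x_S`` with ``x_S`` uniform on S."""
        support = np.asarray(list(support), dtype=int)
        if support.size == 0:
            raise ValueError("empty support")
        x = np.zeros(self.n_candidates)
        x[support] = 1.0 / support.size
        r = self.A @ x - self.b
        return float(r @ r - lam * (self.E @ x))


@dataclass
class SelectionResult:
    """Fitted ROI selection.

    Attributes
    ----------
    x : ndarray, shape (M,)
        Candidate weights in [0, 1].
    support : ndarray of int
        Indices of the selected candidates (weight above ``threshold``,
        possibly refined; see the solver docstrings).
    objective : float
        Optimal value of the mathematical program that was solved.
    support_objective : float
        The discrete objective of ``support`` (equal-pooled entropy
        objective, or the support size for the sparse program).
    status : str
        Solver status / mode (reports whether the LP or MILP route was
        used, and any epsilon retries).
    threshold : float
        The support cutoff applied to ``x``.
    """

    problem: SelectionProblem
    method: str
    x: np.ndarray
    objective: float
    status: str
    threshold: float
    support: np.ndarray
    support_objective: float
    params: dict

    @property
    def windows(self):
        if self.problem.candidates is None:
            raise AttributeError("problem was built without candidate windows")
        return [self.problem.candidates[j] for j in self.support]

    @property
    def n_selected(self) -> int:
        return int(self.support.size)

    def pooled_composition(self) -> np.ndarray:
        """Equal-pooled composition of the selected candidates."""
        return self.problem.A[:, self.support].mean(axis=1)

    def evaluate(self, entropy_base=None):
        """Score the selection against the slide (MSE / JSD / mean ROI
        entropy); requires the problem to carry its grid."""
        if self.problem.grid is None:
            raise AttributeError("problem was built without a grid")
        return evaluate_selection(
            self.problem.grid, self.windows, entropy_base=entropy_base
        )

    def summary(self) -> str:
        lines = [
            "ROI selection results",
            "=" * 54,
            f"method:            {self.method}",
            f"candidates (M):    {self.problem.n_candidates}",
            f"clusters (N):      {self.problem.n_clusters}",
            f"solver status:     {self.status}",
            f"objective:         {self.objective:.6g}",
            f"support cutoff:    {self.threshold:g}",
            f"selected ROIs:     {self.n_selected}",
            f"support objective: {self.support_objective:.6g}",
        ]
        for key, val in self.params.items():
            lines.append(f"{key + ':':<19}{val}")
        lines.append("-" * 54)
        lines.append("  j   weight   entropy   window")
        for j in self.support:
            w = (
                self.problem.candidates[j]
                if self.problem.candidates is not None
                else "-"
            )
            lines.append(
                f"{j:>3d}   {self.x[j]:.4f}   {self.problem.E[j]:.4f}   {w}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, cmap="tab10"):
        """Draw the tile label map with the selected windows outlined."""
        import matplotlib.patches as mpatches
        import matplotlib.pyplot as plt

        if self.problem.grid is None:
            raise AttributeError("problem was built without a grid")
        grid = self.problem.grid
        if ax is None:
            _, ax = plt.subplots()
        img = grid.labels.reshape(grid.n_rows, grid.n_cols).astype(float)
        img[~grid.valid.reshape(grid.n_rows, grid.n_cols)] = np.nan
        ax.imshow(img, cmap=cmap, interpolation="nearest")
        for w in self.windows:
            ax.add_patch(
                mpatches.Rectangle(
                    (w.col0 - 0.5, w.row0 - 0.5),
                    w.width_tiles,
                    w.height_tiles,
                    fill=False,
                    edgecolor="black",
                    linewidth=2,
                )
            )
        ax.set_xlabel("tile column")
        ax.set_ylabel("tile row")
        return ax

    def to_dict(self):
        return {
            "method": self.method,
            "status": self.status,
            "objective": self.objective,
            "support_objective": self.support_objective,
            "threshold": self.threshold,
            "support": self.support.tolist(),
            "x": self.x.tolist(),
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
        }


def enumerate_candidates(grid, roi_side_tiles, stride_tiles=None) -> SelectionProblem:
    """Functional alias of :meth:`SelectionProblem.from_grid`."""
    return SelectionProblem.from_grid(grid, roi_side_tiles, stride_tiles)


# -- sparse (L1) selection -------------------------------------------------


def _l1_lp(problem, epsilon):
    """Continuous relaxation: min 1'x s.t. |Ax-b| <= eps, 0 <= x <= 1."""
    A, b = problem.A, problem.b
    M = problem.n_candidates
    A_ub = np.vstack([A, -A])
    b_ub = np.concatenate([b + epsilon, -(b - epsilon)])
    res = optimize.linprog(
        c=np.ones(M),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(0, 1)] * M,
        method="highs",
    )
    return res


def _l1_milp(problem, epsilon):
    """Exact sparse program: binary indicators z, weights y <= z,
    sum(y) = 1, |Ay - b| <= eps; minimize sum(z)."""
    A, b = problem.A, problem.b
    N, M = A.shape
    # variables: [y_0..y_{M-1}, z_0..z_{M-1}]
    c = np.concatenate([np.zeros(M), np.ones(M)])
    cons = [
        optimize.LinearConstraint(
            np.hstack([A, np.zeros((N, M))]), b - epsilon, b + epsilon
        ),
        optimize.LinearConstraint(
            np.hstack([np.ones((1, M)), np.zeros((1, M))]), 1.0, 1.0
        ),
        optimize.LinearConstraint(
            np.hstack([np.eye(M), -np.eye(M)]), -np.inf, 0.0
        ),
    ]
    integrality = np.concatenate([np.zeros(M), np.ones(M)])
    bounds = optimize.Bounds(np.zeros(2 * M), np.ones(2 * M))
    return optimize.milp(
        c=c, constraints=cons, integrality=integrality, bounds=bounds
    )


def select_l1(
    problem: SelectionProblem,
    epsilon: float = DEFAULT_EPSILON,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "milp",
    max_epsilon: float = MAX_EPSILON,
) -> SelectionResult:
    """Sparse composition matching: the minimum set of ROIs whose weighted
    pooled composition reproduces the slide composition within ``epsilon``
    (elementwise).

    The exact equality constraint of the idealized program is generically
    infeasible with finitely many candidates, so it is relaxed to the
    elementwise slack ``epsilon``; on infeasibility the slack is doubled
    (each retry logged) up to ``max_epsilon``, after which a closest-fit
    diagnostic is raised.

    ``mode="milp"`` (default) solves the integer program exactly — binary
    selection indicators with continuous weights — matching the original
    integer-programming treatment; ``mode="lp"`` solves the continuous
    relaxation only.  The mode used is recorded in ``status``.
    """
    if mode not in ("milp", "lp"):
        raise ValueError("mode must be 'milp' or 'lp'")
    eps = float(epsilon)
    retries = []
    while True:
        res = _l1_milp(problem, eps) if mode == "milp" else _l1_lp(problem, eps)
        if res.status == 0:
            break
        retries.append(eps)
        if eps * 2 > max_epsilon:
            best = optimize.linprog(
                c=np.concatenate([np.zeros(problem.n_candidates), [1.0]]),
                A_ub=np.vstack(
                    [
                        np.hstack([problem.A, -np.ones((problem.n_clusters, 1))]),
                        np.hstack([-problem.A, -np.ones((problem.n_clusters, 1))]),
                    ]
                ),
                b_ub=np.concatenate([problem.b, -problem.b]),
                bounds=[(0, 1)] * problem.n_candidates + [(0, None)],
                method="highs",
            )
            closest = best.x[-1] if best.status == 0 else np.nan
            raise RuntimeError(
                f"sparse selection infeasible up to epsilon={max_epsilon}; "
                f"best achievable max deviation is {closest:.4g}"
            )
        eps *= 2
        logger.info("sparse selection infeasible; retrying with epsilon=%g", eps)
    M = problem.n_candidates
    if mode == "milp":
        y = np.clip(res.x[:M], 0.0, 1.0)
        support = np.flatnonzero((res.x[M:] > 0.5) & (y > threshold))
        objective = float(np.round(res.fun))
    else:
        y = np.clip(res.x, 0.0, 1.0)
        support = np.flatnonzero(y > threshold)
        objective = float(res.fun)
    status = f"{mode}:optimal"
    if retries:
        status += f" (epsilon doubled from {epsilon:g} to {eps:g})"
    return SelectionResult(
        problem=problem,
        method="l1",
        x=y,
        objective=objective,
        status=status,
        threshold=threshold,
        support=support,
        support_objective=float(support.size),
        params={"epsilon": eps, "mode": mode},
    )


# -- entropy-regularized selection ----------------------------------------


def _solve_qp_simplex(Q, c, x0, maxiter=2000):
    """min 0.5 x'Qx + c'x on the probability simplex via accelerated
    projected gradient (FISTA) with exact simplex projection."""

    def project(v):
        # Euclidean projection onto {x >= 0, sum x = 1}
        u = np.sort(v)[::-1]
        css = np.cumsum(u) - 1.0
        rho = np.nonzero(u - css / (np.arange(v.size) + 1) > 0)[0][-1]
        theta = css[rho] / (rho + 1.0)
        return np.maximum(v - theta, 0.0)

    L = np.linalg.eigvalsh(Q)[-1] + 1e-12
    x = project(x0)
    yk = x.copy()
    t = 1.0
    fprev = np.inf
    for _ in range(maxiter):
        grad = Q @ yk + c
        x_new = project(yk - grad / L)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        yk = x_new + ((t - 1) / t_new) * (x_new - x)
        x, t = x_new, t_new
        f = 0.5 * x @ Q @ x + c @ x
        if abs(fprev - f) < 1e-14 * max(1.0, abs(f)):
            break
        fprev = f
    return x


def select_entropy(
    problem: SelectionProblem,
    lam: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
    refine: bool = True,
    entropy_sign: float = +1.0,
) -> SelectionResult:
    """Entropy-regularized selection:
    ``min ||Ax - b||^2 - lam * E'x`` subject to ``0 <= x <= 1`` and
    ``sum(x) = 1``.

    With ``lam > 0`` the linear entropy bonus steers weight toward
    heterogeneous candidates while the quadratic term keeps the pooled
    composition close to the slide's.  ``entropy_sign=-1`` flips the
    regularizer to *prefer* homogeneous regions instead.

    The convex program yields fractional weights; the selected ROI set is
    the candidates with weight above ``threshold``.  With ``refine=True``
    (default) the final support is the subset of those candidates whose
    equal-pooled discrete objective is best — the fractional solve
    screens candidates, the exhaustive pass over the (small) screened set
    picks the deliverable.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    A, b, E = problem.A, problem.b, problem.E
    Q = 2.0 * (A.T @ A)
    c = -2.0 * (A.T @ b) - entropy_sign * lam * E
    x0 = np.full(problem.n_candidates, 1.0 / problem.n_candidates)
    x = _solve_qp_simplex(Q, c, x0)
    objective = float(x @ (A.T @ (A @ x)) - 2 * b @ (A @ x) + b @ b
                      - entropy_sign * lam * (E @ x))
    support = np.flatnonzero(x > threshold)
    status = "fista:converged"
    if support.size == 0:
        support = np.array([int(np.argmax(x))])
        status += " (no weight above cutoff; kept argmax)"

    def disc(sub):
        xs = np.zeros(problem.n_candidates)
        xs[list(sub)] = 1.0 / len(sub)
        r = A @ xs - b
        return float(r @ r - entropy_sign * lam * (E @ xs))

    if refine and 1 < support.size <= 16:
        best = min(
            (
                tuple(s)
                for k in range(1, support.size + 1)
                for s in itertools.combinations(support, k)
            ),
            key=disc,
        )
        support = np.asarray(best, dtype=int)
        status += "+refined"
    return SelectionResult(
        problem=problem,
        method="entropy",
        x=x,
        objective=objective,
        status=status,
        threshold=threshold,
        support=np.sort(support),
        support_objective=disc(support),
        params={"lambda": lam, "entropy_sign": entropy_sign, "refine": refine},
    )


# -- random baseline -------------------------------------------------------


@dataclass
class RandomSelectionResult:
    """Distribution of the evaluation metrics over random draws of k
    pairwise non-overlapping ROIs."""

    problem: SelectionProblem
    k: int
    draws: list
    metrics: pd.DataFrame
    seed: int

    def quantiles(self, q=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        return self.metrics.quantile(list(q))

    def summary(self) -> str:
        lines = [
            "Random ROI baseline",
            "=" * 44,
            f"k per draw:   {self.k}",
            f"draws:        {len(self.draws)}",
            f"seed:         {self.seed}",
            "",
            self.quantiles().to_string(float_format=lambda v: f"{v:.5f}"),
        ]
        return "\n".join(lines)


def random_selection(
    problem: SelectionProblem,
    k: int,
    n_draws: int = 1000,
    seed: int = 0,
    entropy_base=None,
    max_tries: int = 1000,
) -> RandomSelectionResult:
    """Baseline: repeatedly draw ``k`` pairwise non-overlapping candidate
    windows uniformly without replacement and score each draw.

    Draws violating non-overlap are rejected and redrawn (bounded); if a
    feasible draw cannot be found the grid cannot host ``k``
    non-overlapping windows and an error is raised.
    """
    if problem.candidates is None or problem.grid is None:
        raise ValueError("random_selection needs a problem built from a grid")
    M = problem.n_candidates
    if k < 1 or k > M:
        raise ValueError(f"k must be in 1..{M}")
    rng = np.random.default_rng(seed)
    cands = problem.candidates
    draws, rows = [], []
    for _ in range(n_draws):
        for _try in range(max_tries):
            pick = rng.choice(M, size=k, replace=False)
            ok = all(
                not cands[i].overlaps(cands[j])
                for a, i in enumerate(pick)
                for j in pick[a + 1 :]
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw {k} non-overlapping windows in {max_tries} tries"
            )
        draws.append(tuple(int(i) for i in pick))
        rep = evaluate_selection(
            problem.grid, [cands[i] for i in pick], entropy_base=entropy_base
        )
        rows.append((rep.mse, rep.jsd, rep.mean_entropy))
    metrics = pd.DataFrame(rows, columns=["mse", "jsd", "mean_entropy"])
    return RandomSelectionResult(
        problem=problem, k=k, draws=draws, metrics=metrics, seed=seed
    )


# -- exhaustive oracle -----------------------------------------------------


def brute_force_select(
    problem: SelectionProblem,
    max_k: int,
    objective: str = "entropy",
    lam: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    budget: int = 10**6,
):
    """Exhaustive search over candidate supports of size <= ``max_k``.

    For ``objective="entropy"`` every support is scored by the
    equal-pooled discrete objective ``||A x_S - b||^2 - lam*E'x_S`` and
    the minimizer is returned.  For ``objective="l1"`` supports are
    scanned in increasing cardinality and the first (hence smallest) one
    admitting weights ``0 <= x <= 1`` with ``|A_S x - b| <= epsilon`` is
    returned; its objective is its size.

    Intended as a testing oracle for small problems; raises when the
    number of supports exceeds ``budget``.

    Returns ``(support, objective_value)``.
    """
    M = problem.n_candidates
    from math import comb

    total = sum(comb(M, k) for k in range(1, max_k + 1))
    if total > budget:
        raise ValueError(f"{total} supports exceeds budget {budget}")
    if objective == "entropy":
        best_s, best_f = None, np.inf
        for k in range(1, max_k + 1):
            for sub in itertools.combinations(range(M), k):
                f = problem.equal_pooled_objective(sub, lam=lam)
                if f < best_f - 1e-15:
                    best_s, best_f = sub, f
        return np.asarray(best_s, dtype=int), best_f
    if objective == "l1":
        A, b = problem.A, problem.b
        for k in range(1, max_k + 1):
            for sub in itertools.combinations(range(M), k):
                As = A[:, list(sub)]
                res = optimize.linprog(
                    c=np.zeros(k),
                    A_ub=np.vstack([As, -As]),
                    b_ub=np.concatenate([b + epsilon, -(b - epsilon)]),
                    bounds=[(0, 1)] * k,
                    method="highs",
                )
                if res.status == 0:
                    return np.asarray(sub, dtype=int), float(k)
        return np.asarray([], dtype=int), np.inf
    raise ValueError("objective must be 'entropy' or 'l1'")
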