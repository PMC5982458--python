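"""Principal-component sorting of filament panels with varimax rotation.

The panel of normalized flexibility profiles is analysed with the filaments
as the *variables* and the distance stations as the *observations*: the
eigendecomposition of the filament-by-filament correlation matrix yields one
loading per filament per component, so each filament becomes a point in the
retained component space.  Components are retained by the Kaiser rule
(eigenvalue >= 1 of the correlation matrix) and then varimax-rotated with
Kaiser row normalization, the convention of the major statistics suites.
The rotated loadings are the coordinates of the 3-D space plot in which
feedable, tunable and non-feedable filaments separate into clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FeedscreenError
from .profile_io import NormalizedProfileVector

DEFAULT_MAX_ITERATIONS = 25
DEFAULT_TOLERANCE = 1e-6


@dataclass
class PcaSolution:
    """Eigenvalues, retained components and loadings for one panel."""

    variable_names: list[str]
    eigenvalues: np.ndarray
    n_retained: int
    loadings_unrotated: np.ndarray  # variables x retained components
    loadings_rotated: np.ndarray
    rotation_iterations: int
    converged: bool
    group_labels: dict[str, str] = field(default_factory=dict)

    def communalities(self, rotated: bool = True) -> np.ndarray:
        L = self.loadings_rotated if rotated else self.loadings_unrotated
        return (L**2).sum(axis=1)


def assemble_matrix(panel: list[NormalizedProfileVector]) -> pd.DataFrame:
    """Stack a panel into a stations-by-filaments matrix, each column
    standardized to zero mean and unit variance (ddof=1).

    A filament whose profile is perfectly flat has no variance to analyse
    and is reported by name as degenerate.
    """
    if len(panel) < 2:
        raise FeedscreenError("need at least 2 filaments to assemble a panel matrix")
    grid = panel[0].grid
    for p in panel[1:]:
        if not np.array_equal(p.grid, grid):
            raise FeedscreenError("panel profiles are on different grids")
    names = [p.filament_id for p in panel]
    X = np.column_stack([p.values for p in panel])
    sd = X.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise DegenerateInputError(
            f"zero-variance profile(s): {[names[i] for i in flat]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    return pd.DataFrame(Z, columns=names)


def pca_eigen(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the variables' correlation matrix.

    Returns ``(eigenvalues, loadings)`` with eigenvalues descending and
    loadings scaled so the squared loadings of each component sum to its
    eigenvalue (the factor-analysis convention).  Each loading vector is
    sign-flipped so its largest-magnitude entry is positive, for
    deterministic output across platforms.
    """
    Z = np.asarray(matrix, dtype=float)
    if Z.shape[0] < 2:
        raise FeedscreenError(
            f"need at least 2 observations for a correlation matrix, got {Z.shape[0]}"
        )
    n_obs = Z.shape[0]
    corr = (Z.T @ Z) / (n_obs - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]  # descending; eigh ties keep index order
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)
    # sign convention: dominant entry of each component positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return eigval, loadings


def kaiser_select(eigenvalues: np.ndarray) -> int:
    """Number of components with eigenvalue >= 1 (boundary inclusive)."""
    n = int(np.sum(np.asarray(eigenvalues, dtype=float) >= 1.0))
    if n == 0:
        warnings.warn("no component reaches eigenvalue 1; nothing to retain", stacklevel=2)
    return n


def varimax(
    loadings: np.ndarray,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    tolerance: float = DEFAULT_TOLERANCE,
    kaiser_normalize: bool = True,
) -> tuple[np.ndarray, int, bool]:
    """Varimax rotation of a variables-by-components loading matrix.

    Maximizes the variance of squared loadings within each component over
    orthogonal rotations, with Kaiser row normalization (each variable's
    loading row scaled to unit communality during the iteration, the SPSS
    default).  Orthogonality preserves per-variable communalities exactly.

    Returns ``(rotated_loadings, iterations, converged)``.  A single
    component cannot be rotated and is returned unchanged; an empty matrix
    is a no-op with a warning.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D matrix")
    p, k = L.shape
    if k == 0:
        warnings.warn("no components to rotate", stacklevel=2)
        return L.copy(), 0, True
    if k == 1:
        return L.copy(), 0, True

    h = np.sqrt((L**2).sum(axis=1))  # communality roots
    if kaiser_normalize:
        if np.any(h == 0):
            raise DegenerateInputError("variable with zero communality cannot be normalized")
        A = L / h[:, None]
    else:
        A = L.copy()

    R = np.eye(k)
    last = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        B = A @ R
        # gradient of the varimax criterion (Lawley & Maxwell form)
        G = A.T @ (B**3 - B * (B**2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(G)
        R = U @ Vt
        crit = s.sum()
        if crit <= last * (1.0 + tolerance):
            converged = True
            break
        last = crit
    rotated = (A @ R) * (h[:, None] if kaiser_normalize else 1.0)
    for j in range(rotated.shape[1]):
        col = rotated[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            rotated[:, j] = -col
    return rotated, iterations, converged


def varimax_criterion(loadings: np.ndarray) -> float:
    """The raw varimax objective: summed per-component variance of squared
    loadings.  Used for oracle comparisons and monotonicity checks."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


class VarimaxPCA:
    """Correlation-matrix PCA with Kaiser-rule retention and varimax rotation.

    sklearn-style estimator: ``fit`` on a panel (stations-by-filaments
    standardized matrix, an ``assemble_matrix`` output, or a list of
    :class:`NormalizedProfileVector`), then read the fitted attributes.

    Parameters
    ----------
    max_iterations : int
        Varimax iteration cap (default 25, the convention of the original
        analysis suite).
    tolerance : float
        Relative convergence tolerance on the rotation criterion.
    kaiser_normalize : bool
        Row-normalize loadings during rotation (default True).
    n_components : int or None
        Override the Kaiser rule with a fixed retention count.

    Attributes
    ----------
    variable_names_ : list of str
    eigenvalues_ : ndarray, descending; sums to the number of variables.
    n_components_ : int, retained by the Kaiser rule (eigenvalue >= 1).
    loadings_ : ndarray, variables x retained, unrotated.
    rotated_loadings_ : ndarray, same shape, after varimax.
    n_iter_ : int, rotation iterations used.
    converged_ : bool
    """

    def __init__(
        self,
        max_iterations: int = DEFAULT_MAX_ITERATIONS,
        tolerance: float = DEFAULT_TOLERANCE,
        kaiser_normalize: bool = True,
        n_components: int | None = None,
    ) -> None:
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.kaiser_normalize = kaiser_normalize
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "tolerance": self.tolerance,
            "kaiser_normalize": self.kaiser_normalize,
            "n_components": self.n_components,
        }

    def set_params(self, **params) -> "VarimaxPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "VarimaxPCA":
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], NormalizedProfileVector):
            X = assemble_matrix(list(X))
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        else:
            names = [f"var_{i}" for i in range(np.asarray(X).shape[1])]
        eigval, loadings = pca_eigen(X)
        n_ret = self.n_components if self.n_components is not None else kaiser_select(eigval)
        L = loadings[:, :n_ret]
        rotated, n_iter, converged = varimax(
            L,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            kaiser_normalize=self.kaiser_normalize,
        )
        self.variable_names_ = names
        self.eigenvalues_ = eigval
        self.n_components_ = n_ret
        self.loadings_ = L
        self.rotated_loadings_ = rotated
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the rotated loadings — each variable's (filament's)
        coordinates in the rotated component space."""
        return self.fit(X).rotated_loadings_

    def solution_(self, group_labels: dict[str, str] | None = None) -> PcaSolution:
        return PcaSolution(
            variable_names=self.variable_names_,
            eigenvalues=self.eigenvalues_,
            n_retained=self.n_components_,
            loadings_unrotated=self.loadings_,
            loadings_rotated=self.rotated_loadings_,
            rotation_iterations=self.n_iter_,
            converged=self.converged_,
            group_labels=dict(group_labels or {}),
        )


def space_plot_coordinates(
    solution: PcaSolution,
    out_csv: str | Path | None = None,
    out_plot: str | Path | None = None,
) -> pd.DataFrame:
    """Per-filament coordinates in rotated component space.

    Returns a table with one row per filament, columns ``PC1..PCk`` from the
    rotated loadings and an optional ``group`` column (feedable / tunable /
    non-feedable) for coloring.  With fewer than two retained components
    there is no space to plot and an error advises the 1-D fallback.
    """
    k = solution.n_retained
    if k < 2:
        raise FeedscreenError(
            f"only {k} retained component(s); a space plot needs >= 2 "
            "(plot the single rotated loading as a 1-D strip instead)"
        )
    coords = pd.DataFrame(
        solution.loadings_rotated[:, : min(k, 3)],
        index=pd.Index(solution.variable_names, name="filament_id"),
        columns=[f"PC{i + 1}" for i in range(min(k, 3))],
    )
    if solution.group_labels:
        coords["group"] = [solution.group_labels.get(n, "") for n in solution.variable_names]
    if out_csv is not None:
        coords.to_csv(out_csv)
    if out_plot is not None:
        _render_space_plot(coords, out_plot)
    return coords


def _render_space_plot(coords: pd.DataFrame, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    three_d = "PC3" in coords.columns
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    groups = coords["group"] if "group" in coords.columns else pd.Series("", index=coords.index)
    for g in sorted(set(groups)):
        sub = coords[groups == g]
        args = [sub["PC1"], sub["PC2"]] + ([sub["PC3"]] if three_d else [])
        ax.scatter(*args, label=g or None)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if three_d:
        ax.set_zlabel("PC3")
    if "group" in coords.columns:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
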