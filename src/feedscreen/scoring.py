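"""Correlation scoring of candidate profiles against a reference library.

A candidate filament's normalized flexibility profile is Pearson-correlated
with each profile in a library of known-feedable commercial filaments (ABS,
PLA and a dissolvable support filament in the original screening study).
The mean of the per-reference correlations is the filament's score; rounding
it to the nearest integer — scores below 0.5 go to 0, scores above 0.5 go
to 1 — yields the Boolean feedability call.  Feedability is deliberately
Boolean: a filament either threads through the printer's feeding rollers or
it does not, and no graded "more feedable" ranking is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, DegenerateInputError, GridMismatchError
from .profile_io import NormalizedProfileVector

DEFAULT_THRESHOLD = 0.5
DEFAULT_MARGIN = 0.05
DEFAULT_OUTLIER_THRESHOLD = 0.55


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching spreadsheet display rounding
    (e.g. -1.19/3 = -0.39666... prints as -0.40, not -0.39)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def correlate(
    candidate: NormalizedProfileVector | np.ndarray,
    reference: NormalizedProfileVector | np.ndarray,
    method: str = "pearson",
) -> float:
    """Correlation between two equal-length profile vectors.

    Pearson product-moment by default (the flavor of a spreadsheet's Data
    Analysis correlation tool); Spearman rank correlation is available for
    robustness studies.  Either vector having zero variance is an error: a
    perfectly flat profile has no shape to correlate.
    """
    a = np.asarray(getattr(candidate, "values", candidate), dtype=float)
    b = np.asarray(getattr(reference, "values", reference), dtype=float)
    if a.size != b.size:
        raise GridMismatchError(f"vector lengths differ: {a.size} vs {b.size}")
    for name, v in (("candidate", a), ("reference", b)):
        if np.ptp(v) == 0:
            raise DegenerateInputError(f"{name} vector has zero variance")
    if method == "pearson":
        r = stats.pearsonr(a, b).statistic
    elif method == "spearman":
        r = stats.spearmanr(a, b).statistic
    else:
        raise ConfigurationError(f"unknown correlation method {method!r}")
    return float(np.clip(r, -1.0, 1.0))


def mean_score(per_reference: dict[str, float], excluded: set[str] | None = None) -> float:
    """Arithmetic mean of the per-reference correlations over non-excluded
    references — the filament's feedability score, at full precision."""
    excluded = excluded or set()
    kept = [v for k, v in per_reference.items() if k not in excluded]
    if not kept:
        raise ConfigurationError("no references left after exclusion")
    return float(np.mean(kept))


@dataclass
class FeedabilityScore:
    """Scoring result for one filament: per-reference correlations, their
    mean, the rounded 0/1 call, and a borderline flag for means within
    ``margin`` of the 0.5 cut."""

    filament_id: str
    per_reference: dict[str, float]
    mean_score: float
    rounded_score: int
    feedable: bool
    borderline: bool

    @property
    def display_score(self) -> float:
        """Mean score rounded to 2 decimals for report tables."""
        return round_display(self.mean_score)


def classify(
    score: float,
    margin: float = DEFAULT_MARGIN,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[int, bool, bool]:
    """Apply the rounding rule to a mean score.

    Scores below the threshold round to 0 (non-feedable), above it to 1
    (feedable).  A score exactly at the threshold rounds up and is flagged
    borderline, as is any score within ``margin`` of the threshold.

    Returns ``(rounded_score, feedable, borderline)``.
    """
    if not -1.0 - 1e-9 <= score <= 1.0 + 1e-9:
        raise ValueError(f"mean score {score} outside [-1, 1]")
    rounded = 0 if score < threshold else 1
    borderline = abs(score - threshold) < margin or score == threshold
    return rounded, bool(rounded), borderline


@dataclass
class ReferenceLibrary:
    """Named set of normalized reference profiles with their internal
    consistency matrix (pairwise correlations).

    ``excluded`` marks references flagged as outliers against the rest of
    the library.  The treatment is deliberately asymmetric: an excluded
    reference still contributes to the mean feedability score, but is
    dropped from the PCA panel — mirroring how a dissimilar dissolvable
    filament is kept for scoring yet treated as an outlier for component
    analysis.
    """

    references: dict[str, NormalizedProfileVector]
    consistency_matrix: pd.DataFrame
    excluded: set[str] = field(default_factory=set)

    @property
    def names(self) -> list[str]:
        return list(self.references)

    @property
    def scoring_names(self) -> list[str]:
        """References used for the mean score (all of them)."""
        return self.names

    @property
    def pca_names(self) -> list[str]:
        """References entering PCA (outliers dropped)."""
        return [n for n in self.names if n not in self.excluded]


def build_reference_library(
    profiles: list[NormalizedProfileVector],
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    method: str = "pearson",
) -> ReferenceLibrary:
    """Assemble a reference library and flag outlier references.

    A reference whose mean correlation with all the other references falls
    below ``outlier_threshold`` is marked excluded (from PCA; it stays in
    the scoring mean).  Requires at least two uniquely named references on
    one grid.
    """
    if len(profiles) < 2:
        raise ConfigurationError("a reference library needs at least 2 profiles")
    names = [p.filament_id for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate reference names in {names}")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not np.array_equal(p.grid, grid):
            raise GridMismatchError("reference profiles are on different grids")

    n = len(profiles)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = correlate(profiles[i], profiles[j], method=method)
    consistency = pd.DataFrame(mat, index=names, columns=names)

    excluded = set()
    for i, name in enumerate(names):
        off_diag = np.delete(mat[i], i)
        if off_diag.mean() < outlier_threshold:
            excluded.add(name)
    return ReferenceLibrary(
        references={p.filament_id: p for p in profiles},
        consistency_matrix=consistency,
        excluded=excluded,
    )


def score_one(
    candidate: NormalizedProfileVector,
    library: ReferenceLibrary,
    method: str = "pearson",
    margin: float = DEFAULT_MARGIN,
    threshold: float = DEFAULT_THRESHOLD,
) -> FeedabilityScore:
    per_ref = {
        name: correlate(candidate, ref, method=method)
        for name, ref in library.references.items()
    }
    m = mean_score(per_ref)
    rounded, feedable, borderline = classify(m, margin=margin, threshold=threshold)
    return FeedabilityScore(
        filament_id=candidate.filament_id,
        per_reference=per_ref,
        mean_score=m,
        rounded_score=rounded,
        feedable=feedable,
        borderline=borderline,
    )


def score_panel(
    candidates: list[NormalizedProfileVector],
    library: ReferenceLibrary,
    method: str = "pearson",
    margin: float = DEFAULT_MARGIN,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score every candidate and return a report table: one row per
    filament with columns ``C_<reference>`` for each reference, the mean
    score (full precision and 2-dp display), the rounded 0/1 call and the
    feedable/borderline flags."""
    rows = []
    for cand in candidates:
        s = score_one(cand, library, method=method, margin=margin, threshold=threshold)
        row: dict = {"filament_id": s.filament_id}
        row.update({f"C_{name}": v for name, v in s.per_reference.items()})
        row.update(
            mean_score=s.mean_score,
            display_score=s.display_score,
            rounded_score=s.rounded_score,
            feedable=s.feedable,
            borderline=s.borderline,
        )
        rows.append(row)
    columns = ["filament_id"] + [f"C_{n}" for n in library.names] + [
        "mean_score", "display_score", "rounded_score", "feedable", "borderline",
    ]
    return pd.DataFrame(rows, columns=columns)


class FeedabilityClassifier(BaseEstimator, ClassifierMixin):
    """Reference-correlation feedability classifier.

    ``fit`` takes the reference profiles (rows of normalized forces on a
    common grid) of known-feedable filaments; ``predict`` correlates each
    candidate row with every reference, averages, and applies the rounding
    rule.  ``decision_function`` exposes the mean correlation score.

    Parameters
    ----------
    method : {"pearson", "spearman"}
        Correlation flavor.
    threshold : float
        Rounding cut on the mean score (default 0.5).
    margin : float
        Half-width of the borderline band around the threshold.
    outlier_threshold : float
        Mean-correlation level below which a reference is flagged as an
        outlier in ``library_``.

    Attributes
    ----------
    library_ : ReferenceLibrary
        Fitted reference library with consistency matrix and outlier flags.
    classes_ : ndarray
        ``[0, 1]`` (non-feedable, feedable).
    """

    def __init__(
        self,
        method: str = "pearson",
        threshold: float = DEFAULT_THRESHOLD,
        margin: float = DEFAULT_MARGIN,
        outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    ) -> None:
        self.method = method
        self.threshold = threshold
        self.margin = margin
        self.outlier_threshold = outlier_threshold

    def fit(self, X, y=None, reference_names: list[str] | None = None):
        """Build the reference library from rows of normalized profiles.

        ``X`` may be a list of :class:`NormalizedProfileVector` or a 2-D
        array (one row per reference, ``reference_names`` optional).
        """
        vectors = _as_vectors(X, reference_names, prefix="ref")
        self.library_ = build_reference_library(
            vectors, outlier_threshold=self.outlier_threshold, method=self.method
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(vectors[0])
        return self

    def decision_function(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "library_")
        vectors = _as_vectors(X, None, prefix="candidate")
        return np.array(
            [score_one(v, self.library_, method=self.method).mean_score for v in vectors]
        )

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.array(
            [classify(s, margin=self.margin, threshold=self.threshold)[0] for s in scores]
        )

    def score_panel(self, X, candidate_names: list[str] | None = None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "library_")
        vectors = _as_vectors(X, candidate_names, prefix="candidate")
        return score_panel(
            vectors, self.library_,
            method=self.method, margin=self.margin, threshold=self.threshold,
        )


def _as_vectors(X, names: list[str] | None, prefix: str) -> list[NormalizedProfileVector]:
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], NormalizedProfileVector):
        return list(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if names is None:
        names = [f"{prefix}_{i}" for i in range(arr.shape[0])]
    grid = np.arange(arr.shape[1], dtype=float)
    out = []
    for name, row in zip(names, arr):
        total = row.sum()
        out.append(
            NormalizedProfileVector(
                filament_id=name, grid=grid,
                values=row / total if total > 0 else row,
            )
        )
    return out
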