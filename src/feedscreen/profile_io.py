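"""Reading, validation, resampling and normalization of flexibility profiles.

A *flexibility profile* is the force-versus-distance curve recorded while a
filament specimen is axially compressed and released.  Raw curves from
different materials differ wildly in force scale (a stiff pre-plasticized PVA
filament can resist two orders of magnitude more force than a soft plasticized
blend), so before any comparison each curve is

1. resampled onto a fixed distance grid (compression stations followed by
   release stations), because correlation needs equal-length vectors, and
2. sum-normalized: each force value is divided by the total of the vector,
   so the result sums to one and only the *shape* of the curve remains.

The sum normalization is scale-free: multiplying every force by a positive
constant leaves the normalized vector (and any Pearson correlation computed
from it) unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    FormatError,
    GridMismatchError,
    NotTestableError,
    ParseError,
)
from .protocol import ProtocolConfig

PHASE_COMPRESSION = "compression"
PHASE_RELEASE = "release"
_REQUIRED_COLUMNS = ("distance_mm", "force_N", "phase")


@dataclass
class FlexibilityProfile:
    """One compress-and-release force-distance curve with metadata.

    ``samples`` is a DataFrame with columns ``distance_mm`` (float),
    ``force_N`` (float) and ``phase`` (``compression`` or ``release``).
    Distances are aligned so that zero is the first sample at or above the
    trigger force.  A profile whose force never reaches the trigger is
    *floppy*: the specimen was too flexible to register in the rig, it
    carries no samples and cannot enter the numerical pipeline.
    """

    filament_id: str
    replicate: int
    samples: pd.DataFrame
    floppy: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.floppy:
            return
        s = self.samples
        missing = [c for c in _REQUIRED_COLUMNS if c not in s.columns]
        if missing:
            raise FormatError(f"profile samples missing columns {missing}")
        if (s["force_N"] < 0).any():
            raise ValueError("negative forces are not physical for this rig")
        comp = s.loc[s["phase"] == PHASE_COMPRESSION, "distance_mm"].to_numpy()
        rel = s.loc[s["phase"] == PHASE_RELEASE, "distance_mm"].to_numpy()
        if comp.size and np.any(np.diff(comp) < 0):
            raise ValueError("compression-phase distance must be non-decreasing")
        if rel.size and np.any(np.diff(rel) > 0):
            raise ValueError("release-phase distance must be non-increasing")

    def phase_samples(self, phase: str) -> pd.DataFrame:
        return self.samples[self.samples["phase"] == phase]


@dataclass
class NormalizedProfileVector:
    """A profile resampled to the common grid and sum-normalized.

    ``grid`` holds the distance stations (compression stations ascending,
    then release stations descending); ``values`` are the dimensionless
    normalized forces, non-negative and summing to one.  This is the unit of
    comparison for scoring and PCA.
    """

    filament_id: str
    grid: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have identical shape")
        if (self.values < -1e-12).any():
            raise ValueError("normalized forces must be non-negative")

    def __len__(self) -> int:
        return self.values.size


def common_grid(config: ProtocolConfig) -> np.ndarray:
    """Distance stations for the full compress-and-release cycle."""
    comp = np.linspace(0.0, config.compression_distance, config.grid_points_compression)
    rel = np.linspace(config.compression_distance, 0.0, config.grid_points_release)
    return np.concatenate([comp, rel])


def read_profile(
    path: str | Path,
    config: ProtocolConfig | None = None,
    filament_id: str | None = None,
    replicate: int | None = None,
) -> FlexibilityProfile:
    """Read one canonical profile CSV (``distance_mm,force_N,phase``).

    Leading compression samples below the trigger force are trimmed and the
    distance axis is shifted so the first at-trigger sample sits at zero,
    mirroring the instrument's trigger semantics.  If no sample ever reaches
    the trigger the profile is returned flagged floppy, with no samples.

    The filament id and replicate index default to parsing the filename stem
    as ``<filament_id>__rep<k>``.
    """
    config = config or ProtocolConfig()
    path = Path(path)
    if filament_id is None or replicate is None:
        stem_id, stem_rep = _parse_stem(path.stem)
        filament_id = filament_id if filament_id is not None else stem_id
        replicate = replicate if replicate is not None else stem_rep
    try:
        table = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty profile file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if len(table) == 0:
        raise EmptyInputError(f"{path}: profile file has a header but no rows")

    for col in ("distance_mm", "force_N"):
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            row = int(np.flatnonzero(values.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {table[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        # numpy's string parsing is correctly rounded, so written `repr`
        # values round-trip bit-for-bit; pd.to_numeric above is lossier and
        # only locates bad cells
        table[col] = table[col].to_numpy(dtype="U").astype(np.float64)
    phases = set(table["phase"])
    unknown = phases - {PHASE_COMPRESSION, PHASE_RELEASE}
    if unknown:
        raise FormatError(f"{path}: unknown phase tag(s) {sorted(unknown)}")

    if float(table["force_N"].max()) < config.trigger_force:
        return FlexibilityProfile(
            filament_id=filament_id,
            replicate=replicate,
            samples=table.iloc[0:0].reset_index(drop=True),
            floppy=True,
            metadata={"source": str(path), "max_force_N": float(table["force_N"].max())},
        )

    # trigger alignment: drop leading sub-trigger compression points, re-zero
    comp_mask = (table["phase"] == PHASE_COMPRESSION).to_numpy()
    at_trigger = (table["force_N"].to_numpy() >= config.trigger_force) & comp_mask
    first = int(np.flatnonzero(at_trigger)[0]) if at_trigger.any() else 0
    trimmed = table.iloc[first:].reset_index(drop=True)
    offset = float(trimmed["distance_mm"].iloc[0])
    trimmed = trimmed.assign(distance_mm=trimmed["distance_mm"] - offset)

    return FlexibilityProfile(
        filament_id=filament_id,
        replicate=replicate,
        samples=trimmed,
        metadata={"source": str(path), "distance_offset_mm": offset},
    )


def write_profile(profile: FlexibilityProfile, path: str | Path) -> None:
    """Write a profile to the canonical CSV dialect (full float precision,
    so ``read_profile(write_profile(p))`` round-trips bit-for-bit)."""
    df = profile.samples[list(_REQUIRED_COLUMNS)].copy()
    df["distance_mm"] = [repr(float(v)) for v in df["distance_mm"]]
    df["force_N"] = [repr(float(v)) for v in df["force_N"]]
    df.to_csv(path, index=False)


def _parse_stem(stem: str) -> tuple[str, int]:
    if "__rep" in stem:
        fid, _, rep = stem.rpartition("__rep")
        try:
            return fid, int(rep)
        except ValueError:
            pass
    return stem, 1


def resample(profile: FlexibilityProfile, config: ProtocolConfig | None = None) -> np.ndarray:
    """Interpolate the recorded forces onto the common distance grid.

    Compression stations run 0 -> ``compression_distance``; release stations
    run back down to 0.  Stations beyond the recorded compression range are
    filled with the last recorded force when sampling terminated after a
    fracture drop (a fractured specimen keeps exerting whatever minor
    resistance was last recorded), and with zero when the phase simply ends
    without a drop.  An absent or single-point release phase yields zero
    release stations with a warning.
    """
    config = config or ProtocolConfig()
    if profile.floppy:
        raise NotTestableError(
            f"{profile.filament_id}: floppy (sub-trigger) profile has no curve to resample"
        )
    comp = profile.phase_samples(PHASE_COMPRESSION)
    if len(comp) < 2:
        raise DegenerateInputError(
            f"{profile.filament_id}: compression phase has {len(comp)} sample(s); "
            "need at least 2 to interpolate"
        )
    cd = comp["distance_mm"].to_numpy(float)
    cf = comp["force_N"].to_numpy(float)
    if cd[-1] - cd[0] <= 0:
        raise DegenerateInputError(
            f"{profile.filament_id}: compression phase spans zero distance"
        )

    comp_grid = np.linspace(0.0, config.compression_distance, config.grid_points_compression)
    comp_vals = np.interp(comp_grid, cd, cf)
    beyond = comp_grid > cd[-1]
    if beyond.any():
        dropped = cf[-1] < cf.max()  # sampling ended after a force drop
        comp_vals[beyond] = cf[-1] if dropped else 0.0

    rel_grid = np.linspace(config.compression_distance, 0.0, config.grid_points_release)
    rel = profile.phase_samples(PHASE_RELEASE)
    if len(rel) < 2:
        if len(rel) < 1:
            warnings.warn(
                f"{profile.filament_id}: no release phase recorded; "
                "release stations set to 0",
                stacklevel=2,
            )
            rel_vals = np.zeros_like(rel_grid)
        else:
            rel_vals = np.full_like(rel_grid, float(rel["force_N"].iloc[0]))
    else:
        rd = rel["distance_mm"].to_numpy(float)[::-1]  # ascending for interp
        rf = rel["force_N"].to_numpy(float)[::-1]
        rel_vals = np.interp(rel_grid, rd, rf)
    return np.concatenate([comp_vals, rel_vals])


def normalize(
    raw: np.ndarray,
    filament_id: str = "",
    config: ProtocolConfig | None = None,
    grid: np.ndarray | None = None,
    metadata: dict | None = None,
) -> NormalizedProfileVector:
    """Sum-normalize a raw force vector: each point divided by the vector
    total, so the output sums to one.  Scale-free by construction."""
    raw = np.asarray(raw, dtype=float)
    total = raw.sum()
    if not total > 0:
        raise DegenerateInputError(
            f"{filament_id or 'profile'}: force vector sums to {total}; "
            "cannot normalize an all-zero curve"
        )
    if grid is None:
        grid = common_grid(config or ProtocolConfig()) if raw.ndim == 1 else None
        if grid is None or grid.size != raw.size:
            grid = np.arange(raw.size, dtype=float)
    return NormalizedProfileVector(
        filament_id=filament_id,
        grid=grid,
        values=raw / total,
        metadata=dict(metadata or {}),
    )


def to_cumulative(vector: NormalizedProfileVector) -> NormalizedProfileVector:
    """Cumulative-area transform of a normalized profile.

    Returns the running sum of the normalized forces re-normalized to total
    one — the "normalized area under the curve" reading of the comparison
    input.  The plain curve remains the default elsewhere.
    """
    cum = np.cumsum(vector.values)
    return NormalizedProfileVector(
        filament_id=vector.filament_id,
        grid=vector.grid.copy(),
        values=cum / cum.sum(),
        metadata={**vector.metadata, "transform": "cumulative"},
    )


def aggregate_replicates(
    vectors: Sequence[NormalizedProfileVector],
) -> NormalizedProfileVector:
    """Combine replicate vectors by pointwise mean, renormalized to sum one.

    All replicates must share the grid exactly.  The replicate count is
    recorded in the result metadata so per-replicate disagreement stays
    visible upstream.
    """
    if len(vectors) == 0:
        raise EmptyInputError("no replicate vectors to aggregate")
    ref = vectors[0]
    for v in vectors[1:]:
        if not np.array_equal(v.grid, ref.grid):
            raise GridMismatchError(
                f"replicates of {ref.filament_id!r} are on different grids"
            )
    mean = np.mean([v.values for v in vectors], axis=0)
    return NormalizedProfileVector(
        filament_id=ref.filament_id,
        grid=ref.grid.copy(),
        values=mean / mean.sum(),
        metadata={"n_replicates": len(vectors)},
    )


class ProfileNormalizer(BaseEstimator, TransformerMixin):
    """Transformer turning flexibility profiles into normalized vectors.

    Stateless (``fit`` only validates); ``transform`` maps an iterable of
    :class:`FlexibilityProfile` to a ``(n_profiles, n_stations)`` array of
    normalized forces on the common grid.

    Parameters
    ----------
    config : ProtocolConfig
        Protocol constants, including grid sizes.
    include_release : bool
        If False, only compression stations enter the output (the
        compression-only reading of the comparison vector).
    cumulative : bool
        If True, apply the cumulative-area transform after normalization.
    """

    def __init__(
        self,
        config: ProtocolConfig | None = None,
        include_release: bool = True,
        cumulative: bool = False,
    ) -> None:
        self.config = config
        self.include_release = include_release
        self.cumulative = cumulative

    def _config(self) -> ProtocolConfig:
        return self.config or ProtocolConfig()

    def fit(self, X: Iterable[FlexibilityProfile], y=None) -> "ProfileNormalizer":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[FlexibilityProfile]) -> np.ndarray:
        return np.vstack([self.transform_one(p).values for p in X])

    def transform_one(self, profile: FlexibilityProfile) -> NormalizedProfileVector:
        config = self._config()
        raw = resample(profile, config)
        grid = common_grid(config)
        if not self.include_release:
            raw = raw[: config.grid_points_compression]
            grid = grid[: config.grid_points_compression]
        vec = normalize(raw, filament_id=profile.filament_id, grid=grid)
        return to_cumulative(vec) if self.cumulative else vec
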