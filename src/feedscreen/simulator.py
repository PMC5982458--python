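"""Physics-based synthetic flexibility profiles with ground-truth labels.

Screened filaments fall into four mechanical phenotypes, each with a
characteristic compress-and-release curve:

* ``sharp_brittle`` — an elastic ramp to a peak fracture force, then sudden
  discontinuation of force: the specimen snaps with no strain-bearing
  ability (highly friable pure polymers).
* ``strain_bearing_brittle`` — a longer ramp, then a drop to a small
  residual resistance that persists: the specimen fractures but only after
  bearing some strain (lightly plasticized brittle polymers).
* ``pliable`` — the ramp ends at the Euler critical load of the slender
  column, above which the specimen buckles rather than fractures; force
  then varies gently over the remaining travel, and on release the bent
  specimen partially recovers, retracing a fraction of the compression
  forces.  These filaments feed.
* ``floppy`` — an over-plasticized, string-like specimen that collapses
  under its own weight and never reaches the instrument's trigger force:
  no curve is recorded and the filament is not testable.

The Euler critical load of a pinned-pinned slender circular column,
``F_cr = pi^2 E I / L^2`` with ``I = pi d^4 / 64``, links a phenotype's
Young's modulus to the protocol geometry: a modulus low enough that
``F_cr`` falls below the 0.05 N trigger *is* the floppy phenotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .profile_io import PHASE_COMPRESSION, PHASE_RELEASE, FlexibilityProfile, write_profile
from .protocol import ProtocolConfig

PHENOTYPES = ("sharp_brittle", "strain_bearing_brittle", "pliable", "floppy")

#: Lumped rig/imperfection compliance: fraction of the ideal axial stiffness
#: E*A/L that the measured loading ramp exhibits.  An ideally straight column
#: would traverse its elastic ramp in tens of micrometres; real specimens are
#: slightly bowed and seated in conical end caps, so the observed ramp spans
#: millimetres.
DEFAULT_COMPLIANCE_FACTOR = 2e-2

#: Truth labels by phenotype.
TRUTH = {
    "pliable": "feedable",
    "sharp_brittle": "non-feedable",
    "strain_bearing_brittle": "non-feedable",
    "floppy": "not-testable",
}


def euler_critical_force(
    youngs_modulus_pa: float,
    diameter_mm: float,
    length_mm: float,
    end_factor: float = 1.0,
) -> float:
    """Euler critical load in N of a slender circular column.

    ``F_cr = pi^2 E I / (K L)^2`` with second moment ``I = pi d^4 / 64``.
    ``end_factor`` K is the effective-length factor; 1.0 is the
    pinned-pinned condition of conical end caps that allow free rotation.
    """
    if youngs_modulus_pa <= 0 or diameter_mm <= 0 or length_mm <= 0 or end_factor <= 0:
        raise ValueError("all Euler-load inputs must be strictly positive")
    d = diameter_mm * 1e-3
    length = length_mm * 1e-3
    inertia = math.pi * d**4 / 64.0
    return math.pi**2 * youngs_modulus_pa * inertia / (end_factor * length) ** 2


@dataclass(frozen=True)
class FilamentMechanics:
    """Mechanical parameters of one simulated filament.

    ``yield_force`` is the peak force a brittle specimen reaches before
    fracturing at ``fracture_distance``; for the pliable phenotype the ramp
    instead ends at the Euler load computed from ``youngs_modulus`` and the
    protocol geometry.  ``residual_force_fraction`` is the fraction of the
    peak that a strain-bearing brittle specimen keeps exerting after the
    drop; ``recovery_fraction`` scales the release-stroke forces relative
    to compression for the pliable phenotype.
    """

    phenotype: str
    youngs_modulus: float = 1.0e9  # Pa
    yield_force: float = 5.0  # N (brittle phenotypes)
    fracture_distance: float = 3.0  # mm (brittle phenotypes)
    residual_force_fraction: float = 0.0
    post_buckling_slope: float = 0.02  # N/mm
    recovery_fraction: float = 0.5
    noise_sd: float = 0.02  # N
    compliance_factor: float = DEFAULT_COMPLIANCE_FACTOR
    seed: int = 0

    def validate(self, config: ProtocolConfig) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if not 0.0 <= self.residual_force_fraction <= 1.0:
            raise ConfigurationError("residual_force_fraction must lie in [0, 1]")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ConfigurationError("recovery_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        f_cr = self.critical_force(config)
        if self.phenotype == "floppy":
            if f_cr >= config.trigger_force:
                raise ConfigurationError(
                    f"floppy phenotype requires a critical load below the "
                    f"{config.trigger_force} N trigger, got {f_cr:.3g} N"
                )
        else:
            if self.phenotype != "pliable" and self.yield_force <= config.trigger_force:
                raise ConfigurationError(
                    "yield_force must exceed the trigger force for testable phenotypes"
                )
            if self.phenotype in ("sharp_brittle", "strain_bearing_brittle"):
                if not 0 < self.fracture_distance <= config.compression_distance:
                    raise ConfigurationError(
                        "fracture_distance must lie in (0, compression_distance]"
                    )
            if self.phenotype == "sharp_brittle" and self.residual_force_fraction != 0.0:
                raise ConfigurationError(
                    "sharp_brittle fractures cleanly: residual_force_fraction must be 0"
                )
            if (
                self.phenotype == "strain_bearing_brittle"
                and not 0.0 < self.residual_force_fraction <= 0.3
            ):
                raise ConfigurationError(
                    "strain_bearing_brittle keeps minor resistance: "
                    "residual_force_fraction must lie in (0, 0.3]"
                )

    def critical_force(self, config: ProtocolConfig) -> float:
        return euler_critical_force(
            self.youngs_modulus, config.specimen_diameter, config.specimen_length
        )

    def ramp_slope(self, config: ProtocolConfig) -> float:
        """Loading-ramp slope in N/mm: the lumped-compliance fraction of the
        ideal axial stiffness E*A/L."""
        area = math.pi * (self.specimen_radius_m(config)) ** 2
        k_axial = self.youngs_modulus * area / (config.specimen_length * 1e-3)  # N/m
        return k_axial * 1e-3 * self.compliance_factor  # N/mm

    def specimen_radius_m(self, config: ProtocolConfig) -> float:
        return config.specimen_diameter * 1e-3 / 2.0


@dataclass
class LabeledPanel:
    """Simulated profiles plus the ground-truth feedability of each."""

    profiles: list[FlexibilityProfile]
    truth: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.profiles:
            label = self.truth.get(p.filament_id)
            expected = TRUTH[p.metadata["phenotype"]]
            if label != expected:
                raise ConfigurationError(
                    f"{p.filament_id}: phenotype {p.metadata['phenotype']!r} "
                    f"must be labeled {expected!r}, got {label!r}"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    def write(self, out_dir: str | Path) -> None:
        """Write canonical per-replicate CSVs plus truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p in self.profiles:
            write_profile(p, out / f"{p.filament_id}__rep{p.replicate}.csv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2) + "\n")


def simulate_profile(
    mech: FilamentMechanics,
    config: ProtocolConfig | None = None,
    filament_id: str | None = None,
    replicate: int = 1,
    n_points: int = 200,
) -> FlexibilityProfile:
    """Generate one compress-and-release curve for the given mechanics.

    The compression stroke is sampled at ``n_points`` uniformly spaced
    distances over the protocol travel, the release stroke over the reverse
    path.  Gaussian noise of ``mech.noise_sd`` N is added (clipped at zero
    force) from a generator seeded by ``mech.seed``, so identical mechanics
    give bit-identical profiles.
    """
    config = config or ProtocolConfig()
    mech.validate(config)
    fid = filament_id or f"{mech.phenotype}_{mech.seed}"
    rng = np.random.default_rng(mech.seed)

    if mech.phenotype == "floppy":
        # a sub-trigger wisp of a trace: kept so the file round-trip exercises
        # the floppy flag on read, but never enters the numerical pipeline
        d = np.linspace(0, config.compression_distance, n_points)
        f_cr = mech.critical_force(config)
        forces = np.clip(f_cr * 0.5 + rng.normal(0, mech.noise_sd * 0.1, n_points), 0, None)
        forces = np.minimum(forces, config.trigger_force * 0.8)
        samples = pd.DataFrame(
            {"distance_mm": d, "force_N": forces, "phase": PHASE_COMPRESSION}
        )
        return FlexibilityProfile(
            filament_id=fid,
            replicate=replicate,
            samples=samples,
            floppy=True,
            metadata={"phenotype": "floppy", "max_force_N": float(forces.max()),
                      "seed": mech.seed},
        )

    d = np.linspace(0.0, config.compression_distance, n_points)
    slope = mech.ramp_slope(config)

    if mech.phenotype == "pliable":
        f_cr = mech.critical_force(config)
        d_euler = f_cr / slope
        if d_euler < config.compression_distance:
            d = np.union1d(d, [d_euler])  # sample the Euler point exactly
        comp = np.where(
            d <= d_euler,
            slope * d,
            f_cr + mech.post_buckling_slope * (d - d_euler),
        )
        rel = mech.recovery_fraction * comp[::-1]
    else:
        # brittle: ramp chosen to reach the yield force exactly at fracture
        d = np.union1d(d, [mech.fracture_distance])
        ramp = mech.yield_force / mech.fracture_distance * d
        residual = mech.residual_force_fraction * mech.yield_force
        # minor post-fracture creep-down of the residual resistance
        creep = np.clip(1.0 - 0.05 * (d - mech.fracture_distance), 0.7, 1.0)
        comp = np.where(d <= mech.fracture_distance, ramp, residual * creep)
        rel = np.zeros(d.size)

    if mech.noise_sd > 0:
        comp = comp + rng.normal(0, mech.noise_sd, d.size)
        rel = rel + rng.normal(0, mech.noise_sd, d.size)
    comp = np.clip(comp, 0.0, None)
    rel = np.clip(rel, 0.0, None)

    samples = pd.DataFrame(
        {
            "distance_mm": np.concatenate([d, d[::-1]]),
            "force_N": np.concatenate([comp, rel]),
            "phase": [PHASE_COMPRESSION] * d.size + [PHASE_RELEASE] * d.size,
        }
    )
    return FlexibilityProfile(
        filament_id=fid,
        replicate=replicate,
        samples=samples,
        metadata={"phenotype": mech.phenotype, "seed": mech.seed,
                  "critical_force_N": mech.critical_force(config)},
    )


#: Commercial-filament stand-ins: three pliable presets with distinct
#: stiffness and post-buckling character.  The dissolvable-like preset is
#: deliberately dissimilar (much softer, decaying plateau, stronger
#: recovery) to exercise the library outlier rule the way a real dissolvable
#: support filament does.  Force scales are plausible ranges, not calibrated
#: measurements.
REFERENCE_PRESETS: dict[str, FilamentMechanics] = {
    "ABS": FilamentMechanics(
        phenotype="pliable", youngs_modulus=2.1e9, post_buckling_slope=0.03,
        recovery_fraction=0.55,
    ),
    "PLA": FilamentMechanics(
        phenotype="pliable", youngs_modulus=2.6e9, post_buckling_slope=0.05,
        recovery_fraction=0.50,
    ),
    "Dissolvable": FilamentMechanics(
        phenotype="pliable", youngs_modulus=0.35e9, post_buckling_slope=-0.005,
        recovery_fraction=0.75, compliance_factor=4.5e-3,
    ),
}

#: A stiff-but-pliable preset at a far larger force scale, its effective
#: modulus chosen so the buckling (deformation) force is 120 N — emulating a
#: pre-plasticized PVA filament that is feedable despite its stiffness
#: because normalization and correlation are scale-free.
MOWIFLEX_LIKE = FilamentMechanics(
    phenotype="pliable", youngs_modulus=66.0e9, post_buckling_slope=0.3,
    recovery_fraction=0.5, noise_sd=0.2,
)

#: Per-phenotype jitter ranges for panel generation: (low, high) bounds the
#: per-filament draws stay within so every draw is phenotype-valid.
JITTER_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "pliable": {
        "youngs_modulus": (0.8e9, 3.5e9),
        "post_buckling_slope": (-0.01, 0.06),
        "recovery_fraction": (0.3, 0.7),
        "compliance_factor": (1.2e-2, 3.0e-2),
    },
    "sharp_brittle": {
        "youngs_modulus": (1.5e9, 4.0e9),
        "yield_force": (2.0, 9.0),
        "fracture_distance": (0.5, 3.0),
    },
    "strain_bearing_brittle": {
        "youngs_modulus": (1.5e9, 4.0e9),
        "yield_force": (2.0, 9.0),
        "fracture_distance": (2.0, 6.0),
        "residual_force_fraction": (0.05, 0.3),
    },
    "floppy": {
        "youngs_modulus": (0.5e6, 4.0e6),
    },
}


def make_reference_library(
    config: ProtocolConfig | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
) -> LabeledPanel:
    """Simulate the three commercial-filament stand-ins (ABS-like, PLA-like,
    dissolvable-like), all pliable and labeled feedable."""
    config = config or ProtocolConfig()
    rng = np.random.default_rng(seed)
    profiles = []
    for name, preset in REFERENCE_PRESETS.items():
        mech = replace(
            preset,
            seed=int(rng.integers(0, 2**31 - 1)),
            **({"noise_sd": noise_sd} if noise_sd is not None else {}),
        )
        profiles.append(simulate_profile(mech, config, filament_id=name))
    return LabeledPanel(
        profiles=profiles, truth={name: "feedable" for name in REFERENCE_PRESETS}
    )


def make_panel(
    spec: list[tuple[str, int]],
    config: ProtocolConfig | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
) -> LabeledPanel:
    """Simulate a labeled panel: ``spec`` lists ``(phenotype, count)`` pairs
    and each filament's parameters are jittered uniformly within the
    phenotype-valid ranges.  Fully reproducible from ``seed``."""
    config = config or ProtocolConfig()
    rng = np.random.default_rng(seed)
    profiles: list[FlexibilityProfile] = []
    truth: dict[str, str] = {}
    for phenotype, count in spec:
        if phenotype not in PHENOTYPES:
            raise ConfigurationError(
                f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}"
            )
        if count < 0:
            raise ConfigurationError("phenotype counts must be >= 0")
        ranges = JITTER_RANGES[phenotype]
        for i in range(count):
            params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
            if noise_sd is not None:
                params["noise_sd"] = noise_sd
            mech = FilamentMechanics(
                phenotype=phenotype, seed=int(rng.integers(0, 2**31 - 1)), **params
            )
            fid = f"{phenotype}_{i:02d}"
            profiles.append(simulate_profile(mech, config, filament_id=fid))
            truth[fid] = TRUTH[phenotype]
    return LabeledPanel(profiles=profiles, truth=truth)
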