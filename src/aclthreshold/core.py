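"""Frontal-plane torque-balance model of non-contact ACL injury at landing.

The model treats a single-leg landing with the knee fully extended, viewed in
the frontal plane. The vertical ground-reaction-force component Fy, acting at
the foot, generates an abduction torque about the lateral femoral condyle with
moment arm ``ground_to_lateral_condyle * sin(alpha)``, where ``alpha`` is the
shin angle from the vertical. Resisting it are adduction torques from the ACL
and MCL (at their ultimate strengths), the quadriceps acting through the
patellar tendon, the semitendinosus-semimembranosus complex, and bodyweight
acting at the whole-body centre of gravity. The critical (threshold) GRF at a
given shin angle is the Fy at which the two sides balance; above it the model
flags a significant ACL injury risk. Shoe-surface traction enters as a Coulomb
friction coefficient mu: a horizontal component Fx = mu * Fy reduces the net
abduction torque, so higher traction raises the threshold.

Sections, in the order the method runs:

1. constants and defaults (literature tissue strengths, cohort statistics)
2. domain types (profile, population, tissue, activation, surface, scenario)
3. anthropometry: average profile, synthetic cohorts, cohort file I/O
4. torque model: moment arms, abduction/adduction/net torques
5. threshold solver: critical GRF, angle of damage, curve generation, risk
6. sensitivity: Monte Carlo cohort thresholds and one-at-a-time sweeps
7. run configuration and file outputs (curve/cohort pipelines)

Units: files and population statistics carry millimetres and kilograms; all
internal computation is in metres, kilograms, newtons and newton-metres.
Angles are degrees at every interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "STANDARD_GRAVITY",
    "COHORT_COLUMNS",
    "NoSolutionError",
    "GaussianSpec",
    "AnthropometricProfile",
    "PopulationParameters",
    "TissueParameters",
    "ActivationState",
    "SurfaceState",
    "LandingScenario",
    "ThresholdCurve",
    "RiskAssessment",
    "CohortResult",
    "RunConfig",
    "average_profile",
    "synthesize_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "grf_abduction_moment_arm",
    "cog_adduction_moment_arm",
    "abduction_torque",
    "adduction_torque",
    "net_abduction_torque",
    "critical_grf",
    "angle_of_damage",
    "generate_curve",
    "classify_risk",
    "cohort_thresholds",
    "sweep",
    "run_curve",
    "run_cohort",
]

logger = logging.getLogger("aclthreshold")

# ---------------------------------------------------------------------------
# 1. Constants and defaults
# ---------------------------------------------------------------------------

#: Gravitational acceleration, m/s^2. The model's reference bodyweight of
#: 802 N for an 80.2 kg subject implies g = 10; kept configurable via the
#: ``g`` keyword of every function where weight enters.
STANDARD_GRAVITY = 10.0

#: Fixed column schema for cohort files (mm for distances, kg for mass).
COHORT_COLUMNS = (
    "acl_mm",
    "mcl_mm",
    "intercondylar_mm",
    "ground_lc_mm",
    "thigh_mm",
    "half_biacetabular_mm",
    "mass_kg",
)

_MM_COLUMNS = COHORT_COLUMNS[:-1]

#: Profile attribute corresponding to each cohort column, in order.
_PROFILE_FIELDS = (
    "acl_moment_arm",
    "mcl_moment_arm",
    "intercondylar_distance",
    "ground_to_lateral_condyle",
    "thigh_length",
    "half_biacetabular",
    "body_mass",
)


class NoSolutionError(ValueError):
    """The torque balance has no finite solution for the requested query.

    Raised when the effective abduction lever ``sin(alpha) - mu*cos(alpha)``
    is non-positive (the foot cannot load the abduction axis, so the
    threshold is infinite), or when no shin angle up to 90 degrees brings the
    critical GRF down to the queried force.
    """


# ---------------------------------------------------------------------------
# 2. Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianSpec:
    """Mean and standard deviation of one anthropometric variable."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class AnthropometricProfile:
    """One subject's moment-arm geometry and mass, in metres and kilograms.

    Attributes
    ----------
    acl_moment_arm
        Lateral condyle to ACL distance (adduction moment arm of the ACL).
    mcl_moment_arm
        Lateral condyle to MCL distance; also serves as the semitendinosus
        moment arm, which shares the medial line of action in this geometry.
    intercondylar_distance
        Lateral to medial condyle distance; the patellar tendon acts midway
        between the condyles, so its moment arm is half this value.
    ground_to_lateral_condyle
        Shank length from the ground contact to the lateral condyle; the GRF
        abduction lever is this distance times sin(shin angle).
    thigh_length
        Lateral condyle to greater trochanter distance.
    half_biacetabular
        Half the bi-acetabular (hip-width) distance; offsets the bodyweight
        line of action from the stance knee even at zero shin angle.
    body_mass
        Whole-body mass in kg.
    """

    acl_moment_arm: float
    mcl_moment_arm: float
    intercondylar_distance: float
    ground_to_lateral_condyle: float
    thigh_length: float
    half_biacetabular: float
    body_mass: float

    def __post_init__(self) -> None:
        for name in _PROFILE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (
            self.acl_moment_arm < self.mcl_moment_arm < self.ground_to_lateral_condyle
        ):
            # Holds for the average cohort geometry; individual draws may
            # violate it without breaking the arithmetic, so warn only.
            warnings.warn(
                "unusual geometry: expected acl_moment_arm < mcl_moment_arm "
                "< ground_to_lateral_condyle",
                stacklevel=2,
            )

    def weight(self, g: float = STANDARD_GRAVITY) -> float:
        """Bodyweight in newtons, ``body_mass * g``."""
        return self.body_mass * g


@dataclass(frozen=True)
class PopulationParameters:
    """Per-variable Gaussian statistics of the measured cohort.

    Distances are in millimetres and mass in kilograms, matching the units
    the statistics were measured in. Defaults reproduce the reference cohort
    of 15 healthy male athletes: MRI-measured knee distances and external
    anthropometrics (mean, SD), literature bi-acetabular half-distance
    (123.78 mm, treated as a constant unless an SD is supplied), and body
    mass 80.2 +/- 6.8 kg.
    """

    acl_mm: GaussianSpec = GaussianSpec(26.06, 1.7)
    mcl_mm: GaussianSpec = GaussianSpec(68.8, 3.27)
    intercondylar_mm: GaussianSpec = GaussianSpec(58.46, 2.82)
    ground_lc_mm: GaussianSpec = GaussianSpec(594.86, 13.89)
    thigh_mm: GaussianSpec = GaussianSpec(461.8, 9.33)
    half_biacetabular_mm: GaussianSpec = GaussianSpec(123.78, 0.0)
    mass_kg: GaussianSpec = GaussianSpec(80.2, 6.8)
    gravitational_constant: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.gravitational_constant <= 0:
            raise ValueError("gravitational_constant must be > 0")

    def spec_for(self, column: str) -> GaussianSpec:
        return getattr(self, column)


@dataclass(frozen=True)
class TissueParameters:
    """Ultimate ligament strengths and maximal muscle forces, newtons.

    Defaults are literature maxima for young healthy adults: ACL 2300 N,
    MCL 799 N, quadriceps 8000 N, gastrocnemius medialis 931 N, and a
    semitendinosus-semimembranosus force of 2 bodyweights. The gastrocnemius
    does not enter the default torque balance (see ``adduction_torque``).
    """

    acl_max_force: float = 2300.0
    mcl_max_force: float = 799.0
    quad_max_force: float = 8000.0
    gastroc_max_force: float = 931.0
    semit_force_bw_multiple: float = 2.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class ActivationState:
    """Fractional activation of each adduction-side contributor, in [0, 1].

    The default of full activation everywhere is the conservative convention
    used to compute the injury threshold: every restraint contributes its
    maximum, so the threshold is an upper bound. Lowering a fraction models
    disturbed neuromuscular activation (fatigue, delayed onset, impaired
    proprioception) of that contributor.
    """

    quad_fraction: float = 1.0
    semit_fraction: float = 1.0
    gastroc_fraction: float = 1.0
    ligament_fraction: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SurfaceState:
    """Shoe-surface Coulomb friction coefficient; mu = 0 is the slippery
    boundary condition under which the original balance was derived."""

    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class LandingScenario:
    """A single landing query: shin angle, vertical GRF, subject, context."""

    shin_angle: float
    grf_vertical: float
    profile: AnthropometricProfile
    activation: ActivationState = ActivationState()
    surface: SurfaceState = SurfaceState()

    def __post_init__(self) -> None:
        if not 0.0 <= self.shin_angle <= 90.0:
            raise ValueError(f"shin_angle must be in [0, 90], got {self.shin_angle}")
        if self.grf_vertical < 0:
            raise ValueError("grf_vertical must be >= 0")


@dataclass(frozen=True)
class RiskAssessment:
    """Outcome of a risk classification: strict at-risk flag and the net
    abduction torque margin in N*m (positive means abduction exceeds the
    adduction restraints)."""

    at_risk: bool
    margin_nm: float


@dataclass
class ThresholdCurve:
    """Sampled critical-GRF curve: for each shin angle, the vertical GRF at
    which abduction and adduction torques balance.

    ``critical_grf_newton`` carries ``inf`` where the effective abduction
    lever is non-positive (no finite threshold). ``critical_grf_bw`` is the
    same curve in bodyweight multiples, Fy / (mass * g).
    """

    angles: np.ndarray
    critical_grf_newton: np.ndarray
    critical_grf_bw: np.ndarray
    mu: float
    activation: ActivationState
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.critical_grf_newton = np.asarray(self.critical_grf_newton, dtype=float)
        self.critical_grf_bw = np.asarray(self.critical_grf_bw, dtype=float)
        if not (
            len(self.angles)
            == len(self.critical_grf_newton)
            == len(self.critical_grf_bw)
        ):
            raise ValueError("angle and GRF sequences must have equal length")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": self.angles,
                "critical_grf_N": self.critical_grf_newton,
                "critical_grf_BW": self.critical_grf_bw,
                "mu": self.mu,
            }
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the curve as CSV plus a JSON sidecar of all parameters."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        if sidecar:
            sidecar_path = path.with_suffix(".json")
            sidecar_path.write_text(
                json.dumps(self.params, indent=2, sort_keys=True) + "\n"
            )
        return path

    def plot(self, path: str | Path | None = None, ax=None):
        """Plot the threshold curve (angle on x, BW multiples on y)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        finite = np.isfinite(self.critical_grf_bw)
        ax.plot(self.angles[finite], self.critical_grf_bw[finite], lw=1.5)
        ax.set_xlabel("shin angle from vertical (deg)")
        ax.set_ylabel("critical GRF (bodyweights)")
        ax.set_title(f"ACL injury threshold curve (mu = {self.mu:g})")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


@dataclass
class CohortResult:
    """Per-subject critical GRFs over an angle grid plus percentile bands.

    ``grf_newton`` is an (n_subjects, n_angles) matrix; ``bands`` holds one
    row per requested percentile (linear-interpolation definition) per angle.
    ``at_risk_fraction`` maps each queried (angle, GRF) pair to the fraction
    of the cohort whose threshold it exceeds.
    """

    angles: np.ndarray
    grf_newton: np.ndarray
    grf_bw: np.ndarray
    percentiles: tuple
    bands: pd.DataFrame
    at_risk_fraction: dict
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Tidy long-format export: percentile, angle_deg, value columns."""
        path = Path(path)
        self.bands.to_csv(path, index=False, lineterminator="\n")
        if sidecar:
            path.with_suffix(".json").write_text(
                json.dumps(self.params, indent=2, sort_keys=True) + "\n"
            )
        return path


# ---------------------------------------------------------------------------
# 3. Anthropometry: average profile, synthetic cohorts, file I/O
# ---------------------------------------------------------------------------


def average_profile(pop: PopulationParameters | None = None) -> AnthropometricProfile:
    """Build the cohort-average profile (means converted from mm to m).

    With the default population statistics the returned profile reproduces
    every coefficient of the reference torque balance: 0.02606 m ACL arm,
    0.0688 m MCL arm, 0.05846 m intercondylar distance, 0.59486 m ground to
    lateral condyle, 0.4618 m thigh, 0.12378 m bi-acetabular half-distance,
    80.2 kg mass.
    """
    pop = pop or PopulationParameters()
    values = {}
    for column, attr in zip(COHORT_COLUMNS, _PROFILE_FIELDS):
        mean = pop.spec_for(column).mean
        if not math.isfinite(mean) or mean <= 0:
            raise ValueError(f"mean for {column} must be strictly positive, got {mean}")
        values[attr] = mean / 1000.0 if column.endswith("_mm") else mean
    return AnthropometricProfile(**values)


def _truncation_floor(spec: GaussianSpec, floor: float | None) -> float:
    # Default floor: mean - 4 sd, but never below 1 mm (1e-3 of a unit for kg
    # would be nonphysical anyway; mass uses the same rule with 1 as floor
    # numerically negligible given 80.2 +/- 6.8).
    if floor is not None:
        return floor
    return max(spec.mean - 4.0 * spec.sd, 1.0)


def synthesize_cohort(
    pop: PopulationParameters | None = None,
    n: int = 15,
    seed: int = 0,
    floor: float | None = None,
    correlation: np.ndarray | None = None,
) -> list[AnthropometricProfile]:
    """Draw a synthetic cohort emulating the measured population.

    Each variable is drawn independently from a Gaussian with the population
    mean and SD, truncated below at ``max(mean - 4*sd, 1)`` in file units
    (mm / kg) so lengths and masses stay physical; with the default SDs the
    truncation is essentially never active. Identical seeds give
    bit-identical cohorts.

    Parameters
    ----------
    pop
        Population statistics; defaults to the reference cohort.
    n
        Number of subjects (>= 0).
    seed
        Seed for the independent per-variable streams.
    floor
        Override the truncation floor (same value for every variable).
    correlation
        Optional 7x7 correlation matrix over the cohort columns. When given,
        draws come from the corresponding multivariate normal and are clipped
        at the floor (approximate truncation); the default is independence,
        since no cross-variable covariances were measured.
    """
    pop = pop or PopulationParameters()
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    specs = [pop.spec_for(c) for c in COHORT_COLUMNS]
    floors = np.array([_truncation_floor(s, floor) for s in specs])
    means = np.array([s.mean for s in specs])
    sds = np.array([s.sd for s in specs])

    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (7, 7):
            raise ValueError("correlation must be a 7x7 matrix over the cohort columns")
        rng = np.random.default_rng(seed)
        cov = np.outer(sds, sds) * correlation
        # eigh factorisation: the covariance is merely PSD when any SD is 0
        draws = rng.multivariate_normal(means, cov, size=n, method="eigh")
        draws = np.maximum(draws, floors)
    else:
        streams = np.random.SeedSequence(seed).spawn(len(specs))
        columns = []
        for spec_, lo, stream in zip(specs, floors, streams):
            if spec_.sd == 0.0:
                columns.append(np.full(n, spec_.mean))
                continue
            a = (lo - spec_.mean) / spec_.sd
            columns.append(
                truncnorm.rvs(
                    a,
                    np.inf,
                    loc=spec_.mean,
                    scale=spec_.sd,
                    size=n,
                    random_state=np.random.default_rng(stream),
                )
            )
        draws = np.column_stack(columns) if n else np.empty((0, 7))

    profiles = []
    with warnings.catch_warnings():
        # Individual draws may transiently violate the average-geometry
        # ordering; that is expected sampling noise, not a data error.
        warnings.simplefilter("ignore")
        for row in draws:
            values = {
                attr: (v / 1000.0 if col.endswith("_mm") else v)
                for attr, col, v in zip(_PROFILE_FIELDS, COHORT_COLUMNS, row)
            }
            profiles.append(AnthropometricProfile(**values))
    return profiles


def cohort_to_frame(cohort: Sequence[AnthropometricProfile]) -> pd.DataFrame:
    """Cohort as a DataFrame in file units (mm distances, kg mass)."""
    data = {}
    for column, attr in zip(COHORT_COLUMNS, _PROFILE_FIELDS):
        values = np.array([getattr(p, attr) for p in cohort], dtype=float)
        data[column] = values * 1000.0 if column.endswith("_mm") else values
    return pd.DataFrame(data, columns=list(COHORT_COLUMNS))


def frame_to_cohort(frame: pd.DataFrame) -> list[AnthropometricProfile]:
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort frame missing columns: {sorted(missing)}")
    profiles = []
    for _, row in frame.iterrows():
        values = {
            attr: (row[col] / 1000.0 if col.endswith("_mm") else float(row[col]))
            for attr, col in zip(_PROFILE_FIELDS, COHORT_COLUMNS)
        }
        profiles.append(AnthropometricProfile(**values))
    return profiles


def write_cohort_csv(cohort: Sequence[AnthropometricProfile], path: str | Path) -> Path:
    path = Path(path)
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\n", float_format="%.9f")
    return path


def read_cohort_csv(path: str | Path) -> list[AnthropometricProfile]:
    return frame_to_cohort(pd.read_csv(path))


# ---------------------------------------------------------------------------
# 4. Torque model
# ---------------------------------------------------------------------------


def _check_angle(shin_angle: float) -> float:
    if not 0.0 <= shin_angle <= 90.0:
        raise ValueError(f"shin angle must be in [0, 90] degrees, got {shin_angle}")
    return math.radians(shin_angle)


def grf_abduction_moment_arm(
    profile: AnthropometricProfile, shin_angle: float
) -> float:
    """Moment arm (m) of the vertical GRF about the lateral condyle:
    ``ground_to_lateral_condyle * sin(alpha)``."""
    rad = _check_angle(shin_angle)
    return profile.ground_to_lateral_condyle * math.sin(rad)


def cog_adduction_moment_arm(
    profile: AnthropometricProfile, shin_angle: float
) -> float:
    """Bodyweight adduction moment arm (m):
    ``half_biacetabular + thigh_length * sin(alpha)``.

    The hip half-width offsets the centre of gravity medially from the stance
    knee even at alpha = 0; leaning the shank adds the thigh projection.
    """
    rad = _check_angle(shin_angle)
    return profile.half_biacetabular + profile.thigh_length * math.sin(rad)


def abduction_torque(scenario: LandingScenario) -> float:
    """Abduction torque (N*m) of the GRF about the lateral condyle.

    ``max(0, Fy*L*sin(alpha) - mu*Fy*L*cos(alpha))``: the frictional
    horizontal component Fx = mu*Fy opposes the lateral slide with lever
    L*cos(alpha), clamped so traction can cancel but never reverse the
    abduction load. With mu = 0 this is the frictionless expression.
    """
    rad = math.radians(scenario.shin_angle)
    L = scenario.profile.ground_to_lateral_condyle
    lever = math.sin(rad) - scenario.surface.mu * math.cos(rad)
    return max(0.0, scenario.grf_vertical * L * lever)


def _static_adduction_torque(
    profile: AnthropometricProfile,
    tissue: TissueParameters,
    activation: ActivationState,
    g: float,
    gastroc_moment_arm: float | None,
) -> float:
    """Angle-independent part of the adduction torque (N*m)."""
    weight = profile.body_mass * g
    total = activation.ligament_fraction * (
        tissue.acl_max_force * profile.acl_moment_arm
        + tissue.mcl_max_force * profile.mcl_moment_arm
    )
    # Patellar tendon acts midway between the condyles.
    total += (
        activation.quad_fraction
        * tissue.quad_max_force
        * profile.intercondylar_distance
        / 2.0
    )
    # Semitendinosus force is a bodyweight multiple; shares the MCL arm.
    total += (
        activation.semit_fraction
        * tissue.semit_force_bw_multiple
        * weight
        * profile.mcl_moment_arm
    )
    total += weight * profile.half_biacetabular
    if gastroc_moment_arm is not None:
        total += (
            activation.gastroc_fraction * tissue.gastroc_max_force * gastroc_moment_arm
        )
    return total


def adduction_torque(
    scenario: LandingScenario,
    tissue: TissueParameters | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
) -> float:
    """Total adduction torque (N*m) about the lateral condyle.

    Sum of the ligament terms (ACL + MCL at their moment arms), the
    quadriceps through the patellar tendon (half the intercondylar
    distance), the semitendinosus (bodyweight multiple at the MCL arm),
    and bodyweight at the centre-of-gravity arm. The gastrocnemius medialis
    term is off by default because no moment arm was measured for it; pass
    ``gastroc_moment_arm`` (m) to include it.
    """
    tissue = tissue or TissueParameters()
    static = _static_adduction_torque(
        scenario.profile, tissue, scenario.activation, g, gastroc_moment_arm
    )
    rad = math.radians(scenario.shin_angle)
    weight = scenario.profile.body_mass * g
    return static + weight * scenario.profile.thigh_length * math.sin(rad)


def net_abduction_torque(
    scenario: LandingScenario,
    tissue: TissueParameters | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
) -> float:
    """Abduction minus adduction torque (N*m); positive means the restraints
    are overloaded and the model flags injury risk."""
    return abduction_torque(scenario) - adduction_torque(
        scenario, tissue, g=g, gastroc_moment_arm=gastroc_moment_arm
    )


# ---------------------------------------------------------------------------
# 5. Threshold solver
# ---------------------------------------------------------------------------


def critical_grf(
    shin_angle,
    profile: AnthropometricProfile,
    tissue: TissueParameters | None = None,
    activation: ActivationState | None = None,
    surface: SurfaceState | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
):
    """Critical vertical GRF (N) at which abduction equals adduction torque.

    Closed form: ``Fy = (C + m*g*T*sin(alpha)) / (L*(sin(alpha) -
    mu*cos(alpha)))`` with C the angle-independent adduction sum, T the thigh
    length and L the ground-to-lateral-condyle distance.

    Scalars raise :class:`NoSolutionError` where the effective lever
    ``sin(alpha) - mu*cos(alpha)`` is non-positive (the threshold is
    infinite); array inputs carry ``inf`` sentinels instead so curve
    generation never aborts mid-grid.
    """
    tissue = tissue or TissueParameters()
    activation = activation or ActivationState()
    surface = surface or SurfaceState()
    angles = np.asarray(shin_angle, dtype=float)
    if np.any(angles < 0) or np.any(angles > 90):
        raise ValueError("shin angle must be in [0, 90] degrees")
    static = _static_adduction_torque(
        profile, tissue, activation, g, gastroc_moment_arm
    )
    rad = np.radians(angles)
    weight = profile.body_mass * g
    numerator = static + weight * profile.thigh_length * np.sin(rad)
    lever = np.sin(rad) - surface.mu * np.cos(rad)
    denominator = profile.ground_to_lateral_condyle * lever
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denominator > 0, numerator / np.maximum(denominator, 1e-300), np.inf)
    if np.ndim(shin_angle) == 0:
        value = float(out)
        if not math.isfinite(value):
            raise NoSolutionError(
                f"no finite threshold at alpha={float(angles):g} deg with "
                f"mu={surface.mu:g}: effective abduction lever is non-positive"
            )
        return value
    return out


def angle_of_damage(
    grf_vertical: float,
    profile: AnthropometricProfile,
    tissue: TissueParameters | None = None,
    activation: ActivationState | None = None,
    surface: SurfaceState | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
) -> float | None:
    """Smallest shin angle (deg) at which ``grf_vertical`` reaches the
    threshold; ``None`` when even 90 degrees requires more force.

    The frictionless case inverts the balance in closed form,
    ``alpha = arcsin(C / (Fy*L - m*g*T))``; with traction the root of the
    torque residual is bracketed between the lever singularity
    ``arctan(mu)`` and 90 degrees and found by scalar root-finding.
    """
    if grf_vertical <= 0:
        raise ValueError(f"grf_vertical must be > 0, got {grf_vertical}")
    tissue = tissue or TissueParameters()
    activation = activation or ActivationState()
    surface = surface or SurfaceState()
    static = _static_adduction_torque(
        profile, tissue, activation, g, gastroc_moment_arm
    )
    weight = profile.body_mass * g
    L = profile.ground_to_lateral_condyle
    T = profile.thigh_length

    if surface.mu == 0.0:
        # Extended precision: arcsin is ill-conditioned near 90 deg, and the
        # round-trip contract (1e-6 deg) is tighter than double rounding
        # allows there. The ulp-level clamp tolerates a queried GRF that is
        # the rounded threshold at exactly 90 deg.
        ld = np.longdouble
        slope = ld(grf_vertical) * ld(L) - ld(weight) * ld(T)
        if slope <= 0:
            return None
        s = ld(static) / slope
        if s > 1.0:
            if s > 1.0 + ld(1e-12):
                return None
            s = ld(1.0)
        return float(np.degrees(np.arcsin(s)))

    def residual(alpha_deg: float) -> float:
        rad = math.radians(alpha_deg)
        lever = math.sin(rad) - surface.mu * math.cos(rad)
        return grf_vertical * L * lever - (static + weight * T * math.sin(rad))

    if residual(90.0) < 0:
        return None
    lo = math.degrees(math.atan(surface.mu))  # lever == 0: residual < 0
    if lo >= 90.0:
        return None
    return float(brentq(residual, lo + 1e-12, 90.0, xtol=1e-12, rtol=8.9e-16))


def generate_curve(
    profile: AnthropometricProfile,
    tissue: TissueParameters | None = None,
    activation: ActivationState | None = None,
    surface: SurfaceState | None = None,
    angle_min: float = 0.01,
    angle_max: float = 90.0,
    step: float = 0.01,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
) -> ThresholdCurve:
    """Sample the threshold curve on a closed uniform angle grid.

    Defaults follow the reference procedure: 0.01-degree steps from 0.01 to
    90 degrees (9000 points). The grid starts above zero because the
    frictionless threshold diverges at alpha = 0. Grid cells where the
    effective lever is non-positive carry an ``inf`` sentinel.
    """
    tissue = tissue or TissueParameters()
    activation = activation or ActivationState()
    surface = surface or SurfaceState()
    if not (0.0 <= angle_min < angle_max <= 90.0):
        raise ValueError(
            f"need 0 <= angle_min < angle_max <= 90, got [{angle_min}, {angle_max}]"
        )
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    n = int(round((angle_max - angle_min) / step)) + 1
    angles = angle_min + step * np.arange(n)
    angles = angles[angles <= angle_max + 1e-12]
    newtons = critical_grf(
        angles,
        profile,
        tissue,
        activation,
        surface,
        g=g,
        gastroc_moment_arm=gastroc_moment_arm,
    )
    bw = newtons / (profile.body_mass * g)
    params = {
        "profile": dataclasses.asdict(profile),
        "tissue": dataclasses.asdict(tissue),
        "activation": dataclasses.asdict(activation),
        "surface": dataclasses.asdict(surface),
        "g": g,
        "gastroc_moment_arm": gastroc_moment_arm,
        "angle_min": angle_min,
        "angle_max": angle_max,
        "step": step,
    }
    return ThresholdCurve(angles, newtons, bw, surface.mu, activation, params)


#: Torque resolution of the risk classifier, N*m. Margins within floating
#: rounding of zero must classify as balanced (safe), so the strict
#: inequality is applied above this resolution rather than above 0.0 exactly.
RISK_TORQUE_RESOLUTION_NM = 1e-9


def classify_risk(
    scenario: LandingScenario,
    tissue: TissueParameters | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    gastroc_moment_arm: float | None = None,
) -> RiskAssessment:
    """Flag a scenario as at-risk when abduction torque strictly exceeds the
    adduction restraints; exact balance is classified safe (to within the
    classifier's torque resolution of 1e-9 N*m)."""
    margin = net_abduction_torque(
        scenario, tissue, g=g, gastroc_moment_arm=gastroc_moment_arm
    )
    return RiskAssessment(at_risk=margin > RISK_TORQUE_RESOLUTION_NM, margin_nm=margin)


# ---------------------------------------------------------------------------
# 6. Sensitivity: Monte Carlo cohorts and parameter sweeps
# ---------------------------------------------------------------------------


def _cohort_arrays(cohort: Sequence[AnthropometricProfile]) -> dict[str, np.ndarray]:
    return {
        attr: np.array([getattr(p, attr) for p in cohort], dtype=float)
        for attr in _PROFILE_FIELDS
    }


def _cohort_critical_matrix(
    arrays: Mapping[str, np.ndarray],
    angles: np.ndarray,
    tissue: TissueParameters,
    activation: ActivationState,
    surface: SurfaceState,
    g: float,
) -> np.ndarray:
    """(n_subjects, n_angles) critical GRF matrix, inf sentinel where the
    lever is non-positive. Vectorised transcription of ``critical_grf``."""
    weight = arrays["body_mass"] * g
    static = activation.ligament_fraction * (
        tissue.acl_max_force * arrays["acl_moment_arm"]
        + tissue.mcl_max_force * arrays["mcl_moment_arm"]
    )
    static = static + (
        activation.quad_fraction
        * tissue.quad_max_force
        * arrays["intercondylar_distance"]
        / 2.0
    )
    static = static + (
        activation.semit_fraction
        * tissue.semit_force_bw_multiple
        * weight
        * arrays["mcl_moment_arm"]
    )
    static = static + weight * arrays["half_biacetabular"]
    rad = np.radians(angles)[np.newaxis, :]
    numerator = static[:, np.newaxis] + (weight * arrays["thigh_length"])[
        :, np.newaxis
    ] * np.sin(rad)
    lever = np.sin(rad) - surface.mu * np.cos(rad)
    denominator = arrays["ground_to_lateral_condyle"][:, np.newaxis] * lever
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denominator > 0, numerator / np.maximum(denominator, 1e-300), np.inf)


def cohort_thresholds(
    cohort: Sequence[AnthropometricProfile],
    angles: Iterable[float],
    tissue: TissueParameters | None = None,
    activation: ActivationState | None = None,
    surface: SurfaceState | None = None,
    *,
    g: float = STANDARD_GRAVITY,
    percentiles: Sequence[float] = (5, 25, 50, 75, 95),
    grf_queries: Sequence[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> CohortResult:
    """Propagate anthropometric variability through the threshold model.

    Deterministic given the cohort; percentile bands use the linear
    interpolation definition. ``grf_queries`` is a sequence of
    (angle_deg, grf_N) pairs; for each, the at-risk fraction is the share of
    subjects whose critical GRF at that angle is strictly below the query.
    ``seed`` is recorded for provenance only (the cohort generator owns the
    randomness).
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    angles = np.atleast_1d(np.asarray(list(angles), dtype=float))
    if angles.size == 0:
        raise ValueError("angle list must be non-empty")
    tissue = tissue or TissueParameters()
    activation = activation or ActivationState()
    surface = surface or SurfaceState()
    arrays = _cohort_arrays(cohort)
    matrix = _cohort_critical_matrix(arrays, angles, tissue, activation, surface, g)
    bw = matrix / (arrays["body_mass"] * g)[:, np.newaxis]

    pcts = tuple(percentiles)
    band_values = np.percentile(matrix, pcts, axis=0, method="linear")
    bands = pd.DataFrame(
        {
            "percentile": np.repeat(pcts, angles.size),
            "angle_deg": np.tile(angles, len(pcts)),
            "critical_grf_N": band_values.ravel(),
        }
    )

    fractions = {}
    for angle, grf in grf_queries or ():
        col = _cohort_critical_matrix(
            arrays, np.array([angle], dtype=float), tissue, activation, surface, g
        )[:, 0]
        fractions[(float(angle), float(grf))] = float(np.mean(grf > col))

    params = {
        "n_subjects": len(cohort),
        "angles": angles.tolist(),
        "tissue": dataclasses.asdict(tissue),
        "activation": dataclasses.asdict(activation),
        "surface": dataclasses.asdict(surface),
        "g": g,
        "percentiles": list(pcts),
        "seed": seed,
    }
    return CohortResult(
        angles=angles,
        grf_newton=matrix,
        grf_bw=bw,
        percentiles=pcts,
        bands=bands,
        at_risk_fraction=fractions,
        seed=seed,
        params=params,
    )


_SWEEPABLE = {
    "mu": (0.0, math.inf),
    "quad_fraction": (0.0, 1.0),
    "semit_fraction": (0.0, 1.0),
    "ligament_fraction": (0.0, 1.0),
}


def sweep(
    parameter: str,
    values: Sequence[float],
    profile: AnthropometricProfile,
    angles: Iterable[float],
    tissue: TissueParameters | None = None,
    activation: ActivationState | None = None,
    surface: SurfaceState | None = None,
    *,
    g: float = STANDARD_GRAVITY,
) -> pd.DataFrame:
    """One-at-a-time sweep of a traction or activation parameter.

    Returns a tidy frame with columns ``parameter``, ``value``, ``angle_deg``
    and ``critical_grf_N`` (inf sentinel where the threshold is infinite);
    everything not swept stays at its default.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"parameter must be one of {sorted(_SWEEPABLE)}, got {parameter!r}"
        )
    lo, hi = _SWEEPABLE[parameter]
    values = [float(v) for v in values]
    for v in values:
        if not lo <= v <= hi:
            raise ValueError(f"{parameter}={v} outside legal range [{lo}, {hi}]")
    tissue = tissue or TissueParameters()
    activation = activation or ActivationState()
    surface = surface or SurfaceState()
    angles = np.atleast_1d(np.asarray(list(angles), dtype=float))

    rows = []
    for v in values:
        if parameter == "mu":
            surf_v, act_v = SurfaceState(mu=v), activation
        else:
            surf_v = surface
            act_v = dataclasses.replace(activation, **{parameter: v})
        grf = critical_grf(angles, profile, tissue, act_v, surf_v, g=g)
        for angle, value in zip(angles, np.atleast_1d(grf)):
            rows.append(
                {
                    "parameter": parameter,
                    "value": v,
                    "angle_deg": float(angle),
                    "critical_grf_N": float(value),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 7. Run configuration and file outputs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run; the JSON/YAML
    sidecar written next to every output re-runs to identical results."""

    population: PopulationParameters = field(default_factory=PopulationParameters)
    tissue: TissueParameters = field(default_factory=TissueParameters)
    activation: ActivationState = field(default_factory=ActivationState)
    surface: SurfaceState = field(default_factory=SurfaceState)
    angle_min: float = 0.01
    angle_max: float = 90.0
    step: float = 0.01
    cohort_size: int = 15
    seed: int = 0
    cohort_angles: tuple = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "population" in data:
            pop = dict(data["population"])
            for key, val in pop.items():
                if isinstance(val, Mapping):
                    pop[key] = GaussianSpec(**val)
            data["population"] = PopulationParameters(**pop)
        for key, cls_ in (
            ("tissue", TissueParameters),
            ("activation", ActivationState),
            ("surface", SurfaceState),
        ):
            if key in data and isinstance(data[key], Mapping):
                data[key] = cls_(**data[key])
        if "cohort_angles" in data:
            data["cohort_angles"] = tuple(data["cohort_angles"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _log_parameters(config: RunConfig) -> None:
    logger.info("resolved parameters:")
    logger.info(
        "  tissue (literature): %s", dataclasses.asdict(config.tissue)
    )
    logger.info(
        "  population (measured cohort + literature hip width): %s",
        dataclasses.asdict(config.population),
    )
    logger.info("  activation: %s", dataclasses.asdict(config.activation))
    logger.info("  surface: %s", dataclasses.asdict(config.surface))


def run_curve(config: RunConfig, out_dir: str | Path, plot: bool = True) -> dict:
    """Average-profile threshold curve pipeline: CSV + JSON sidecar (+ PNG)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _log_parameters(config)
    profile = average_profile(config.population)
    curve = generate_curve(
        profile,
        config.tissue,
        config.activation,
        config.surface,
        config.angle_min,
        config.angle_max,
        config.step,
        g=config.population.gravitational_constant,
    )
    paths = {"csv": curve.to_csv(out_dir / "threshold_curve.csv")}
    paths["sidecar"] = (out_dir / "threshold_curve.json")
    config.to_yaml(out_dir / "run_config.yaml")
    if plot:
        curve.plot(out_dir / "threshold_curve.png")
        paths["plot"] = out_dir / "threshold_curve.png"
    return {"curve": curve, "paths": paths}


def run_cohort(config: RunConfig, out_dir: str | Path) -> dict:
    """Cohort pipeline: synthesize, persist, and analyse in one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _log_parameters(config)
    cohort = synthesize_cohort(config.population, config.cohort_size, config.seed)
    cohort_path = write_cohort_csv(cohort, out_dir / "cohort.csv")
    frame = cohort_to_frame(cohort)
    for column in _MM_COLUMNS:
        spec_ = config.population.spec_for(column)
        logger.info(
            "cohort %s: sample mean %.3f mm (population %.3f mm)",
            column,
            frame[column].mean(),
            spec_.mean,
        )
    result = cohort_thresholds(
        cohort,
        config.cohort_angles,
        config.tissue,
        config.activation,
        config.surface,
        g=config.population.gravitational_constant,
        seed=config.seed,
    )
    bands_path = result.to_csv(out_dir / "cohort_bands.csv")
    config.to_yaml(out_dir / "run_config.yaml")
    return {
        "cohort": cohort,
        "result": result,
        "paths": {"cohort": cohort_path, "bands": bands_path},
    }
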