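"""Synthetic inputs with known ground truth.

Everything the measurement and statistics layers consume can be generated
here: two-site flow-curve pairs with a known wave-foot shift, carotid
contour stacks with known wall geometry, per-patient 27-segment stenosis
class vectors, and full cohorts driven by a Gaussian latent-variable model.

The latent model: a standard-normal atherosclerotic severity score per
patient, coupled to age; segment stenosis classes arise by thresholding
``lambda * severity + noise``; the continuous markers are linear in severity
and age plus independent noise, rescaled to their target marginals.  The
shipped default configuration was calibrated by Monte-Carlo coordinate
search (scripts/calibrate_cohort.py) against the published cohort summaries:
Mean SC 1.6 +/- 0.5, Max SC median 5, distal PWV 9.3 +/- 3.8 m/s,
NWI 0.46 +/- 0.07, r(Mean SC, distal PWV) ~ 0.64 with standardized
regression coefficients ~0.46 (distal PWV) and ~0.30 (age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from . import stenosis
from .carotid import CarotidSlice, ContourStack
from .errors import ConfigurationError
from .pwv import VelocityTimeCurve
from .stats import MARKER_COLUMNS, CohortTable

DEFAULT_SAMPLING_INTERVAL_MS = 9.8

# ordinal thresholds on the (unit-variance) segment latent scale; exceedance
# probabilities 0.33 / 0.13 / 0.08 / 0.06 for classes >=2 ... ==5
DEFAULT_THRESHOLDS = (
    0.4399131656732339,
    1.1263911290388007,
    1.4050715603096329,
    1.5547735945968535,
)

#: segment classes injected for the extreme Mean SC patient: 25 available
#: segments averaging exactly 3.6 (10x class 5, 10x class 3, 5x class 2),
#: two segments unavailable.
OUTLIER_SEGMENT_CLASSES = (5,) * 10 + (3,) * 10 + (2,) * 5 + (None, None)

OUTLIER_PROXIMAL_PWV = 45.3  # m/s, printed extreme


@dataclass(frozen=True)
class WaveformParams:
    """Piecewise flow-waveform parameters: baseline, linear rise, exponential decay."""

    baseline_velocity: float = 5.0  # cm/s
    onset_time: float = 100.0  # ms from the R-wave
    upslope: float = 1.0  # cm/s per ms
    peak_velocity: float = 105.0  # cm/s
    decay_time_constant: float = 100.0  # ms
    rr_interval: float = 980.0  # ms
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL_MS  # ms
    noise_sd: float = 0.0  # cm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be positive")
        if self.peak_velocity <= self.baseline_velocity:
            raise ConfigurationError("peak_velocity must exceed baseline_velocity")
        if self.upslope <= 0:
            raise ConfigurationError("upslope must be positive")
        if self.decay_time_constant <= 0:
            raise ConfigurationError("decay_time_constant must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.onset_time + self.rise_duration >= self.rr_interval:
            raise ConfigurationError(
                "onset_time plus rise duration must stay within rr_interval"
            )

    @property
    def rise_duration(self) -> float:
        return (self.peak_velocity - self.baseline_velocity) / self.upslope


def generate_flow_curve(params: WaveformParams, site_label: str = "") -> VelocityTimeCurve:
    """One cardiac cycle sampled at the configured interval.

    The noiseless curve is flat at baseline until the onset, rises linearly
    at ``upslope`` to the peak, then decays exponentially back toward
    baseline; Gaussian noise (seeded) is added on top.
    """
    # tolerance guards against fp division artefacts (980/9.8 -> 99.999...)
    n = math.floor(params.rr_interval / params.sampling_interval + 1e-9)
    t = np.arange(n) * params.sampling_interval
    t_peak = params.onset_time + params.rise_duration
    v = np.full(n, params.baseline_velocity, dtype=float)
    rising = (t >= params.onset_time) & (t < t_peak)
    v[rising] = params.baseline_velocity + params.upslope * (t[rising] - params.onset_time)
    decaying = t >= t_peak
    v[decaying] = params.baseline_velocity + (
        params.peak_velocity - params.baseline_velocity
    ) * np.exp(-(t[decaying] - t_peak) / params.decay_time_constant)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.noise_sd, size=n)
    return VelocityTimeCurve(t, v, params.rr_interval, site_label)


def generate_curve_pair(
    true_pwv: float, path_length: float, base: WaveformParams
) -> tuple:
    """Proximal/distal curve pair whose wave feet are shifted by dx / PWV.

    ``path_length`` in mm and ``true_pwv`` in m/s give the shift directly in
    ms (mm / (m/s) == ms).  All other waveform parameters are shared; noise,
    when enabled, uses decorrelated per-site seeds.
    """
    if true_pwv <= 0:
        raise ConfigurationError("true_pwv must be positive")
    if path_length <= 0:
        raise ConfigurationError("path_length must be positive")
    shift = path_length / true_pwv
    distal_params = replace(base, onset_time=base.onset_time + shift, seed=base.seed + 1)
    proximal = generate_flow_curve(base, site_label="proximal")
    distal = generate_flow_curve(distal_params, site_label="distal")
    return proximal, distal


def generate_carotid_stack(
    inner_radii,
    outer_radii,
    n_vertices: int = 64,
    center_jitter: float = 0.0,
    seed: int = 0,
) -> ContourStack:
    """Eight-slice stack of concentric near-circular contours.

    Per slice, inner and outer rings are regular ``n_vertices``-gons around a
    common centre that may be jittered slice-to-slice by a Gaussian offset of
    SD ``center_jitter`` mm.  Because both rings of a slice share the same
    vertex count, the polygon-area ratio equals the squared radius ratio
    exactly.
    """
    inner_radii = np.asarray(inner_radii, dtype=float)
    outer_radii = np.asarray(outer_radii, dtype=float)
    if inner_radii.shape != (8,) or outer_radii.shape != (8,):
        raise ConfigurationError("inner_radii and outer_radii must each have 8 entries")
    if not (inner_radii > 0).all():
        raise ConfigurationError("inner radii must be positive")
    if not (outer_radii > inner_radii).all():
        raise ConfigurationError("outer radii must exceed inner radii elementwise")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    unit = np.column_stack([np.cos(angles), np.sin(angles)])
    slices = []
    for i in range(8):
        centre = rng.normal(0.0, center_jitter, size=2) if center_jitter > 0 else np.zeros(2)
        slices.append(
            CarotidSlice(
                slice_index=i + 1,
                inner=centre + inner_radii[i] * unit,
                outer=centre + outer_radii[i] * unit,
            )
        )
    return ContourStack(tuple(slices))


@dataclass(frozen=True)
class CohortConfig:
    """Latent-variable cohort generator configuration (calibrated defaults).

    Path coefficients are on standardized latent scales: ``age_to_severity``
    is the correlation between the age z-score and the severity score;
    ``severity_to_*`` / ``age_to_*`` are loadings of the standardized marker
    latents, with residual variance filled in to keep each latent unit
    variance (negative residual variance is rejected as non-PSD).
    """

    n_patients: int = 42
    seed: int = 0

    # marginal targets
    age_mean: float = 64.0
    age_sd: float = 10.0
    pwv_distal_mean: float = 9.3
    pwv_distal_sd: float = 3.8
    pwv_proximal_mean: float = 9.3
    pwv_proximal_sd: float = 3.5
    nwi_mean: float = 0.46
    nwi_sd: float = 0.07

    # latent path coefficients
    age_to_severity: float = 0.6636
    severity_to_distal: float = 0.5970
    age_to_distal: float = 0.2038
    severity_to_proximal: float = 0.0797
    age_to_proximal: float = 0.3971
    severity_to_nwi: float = 0.04
    age_to_nwi: float = 0.28

    # segment model
    segment_loading: float = 0.52
    segment_noise_sd: float = 0.854166260162505
    thresholds: tuple = DEFAULT_THRESHOLDS

    gender_male_fraction: float = 23.0 / 42.0
    inject_outliers: bool = False

    # synthesizable ranges: the measurement stage clips latent true values
    # into these before building curves/contours (the stored cohort marginals
    # themselves are exactly linear-Gaussian and unclipped)
    pwv_distal_range: tuple = (0.5, 40.0)
    pwv_proximal_range: tuple = (0.5, 60.0)
    nwi_range: tuple = (0.02, 0.98)

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ConfigurationError("n_patients must be >= 3")
        if not 0.0 <= self.gender_male_fraction <= 1.0:
            raise ConfigurationError("gender_male_fraction must lie in [0, 1]")
        th = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", th)
        if len(th) != 4 or any(b <= a for a, b in zip(th, th[1:])):
            raise ConfigurationError("thresholds must be 4 strictly increasing values")
        for name in ("age_sd", "pwv_distal_sd", "pwv_proximal_sd", "nwi_sd",
                     "segment_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not -1.0 < self.age_to_severity < 1.0:
            raise ConfigurationError("age_to_severity must lie in (-1, 1)")
        for marker, (bs, ba) in self._loadings().items():
            if self._residual_variance(bs, ba) < 0:
                raise ConfigurationError(
                    f"implied latent correlation not positive semi-definite: "
                    f"loadings for {marker} leave negative residual variance"
                )

    def _loadings(self) -> dict:
        return {
            "pwv_distal": (self.severity_to_distal, self.age_to_distal),
            "pwv_proximal": (self.severity_to_proximal, self.age_to_proximal),
            "nwi": (self.severity_to_nwi, self.age_to_nwi),
        }

    def _residual_variance(self, bs: float, ba: float) -> float:
        a = self.age_to_severity
        return 1.0 - (bs * bs + ba * ba + 2.0 * a * bs * ba)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("thresholds", "pwv_distal_range", "pwv_proximal_range", "nwi_range"):
            if key in raw and isinstance(raw[key], list):
                raw = {**raw, key: tuple(raw[key])}
        return cls(**raw)


def _patient_ids(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def simulate_segment_classes(
    severity: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, 27) stenosis class matrix from the latent severity scores."""
    n = severity.size
    u = config.segment_loading * severity[:, None] + config.segment_noise_sd * (
        rng.standard_normal((n, stenosis.N_SEGMENTS))
    )
    th = np.asarray(config.thresholds)
    return 1.0 + (u[:, :, None] > th[None, None, :]).sum(axis=2).astype(float)


def generate_cohort(config: CohortConfig) -> tuple:
    """Cohort table plus the ground-truth latent record.

    Mean SC / Max SC are computed from the simulated segment classes through
    the stenosis module, never assigned directly.  Returns
    ``(CohortTable, truth)`` where ``truth`` carries the latent z-scores, the
    segment class matrix, and the true (pre-measurement) marker values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    a = config.age_to_severity

    z_age = rng.standard_normal(n)
    severity = a * z_age + math.sqrt(1.0 - a * a) * rng.standard_normal(n)

    def marker(bs: float, ba: float) -> np.ndarray:
        resid_sd = math.sqrt(config._residual_variance(bs, ba))
        return bs * severity + ba * z_age + resid_sd * rng.standard_normal(n)

    age = config.age_mean + config.age_sd * z_age
    pwv_distal = config.pwv_distal_mean + config.pwv_distal_sd * marker(
        config.severity_to_distal, config.age_to_distal
    )
    pwv_proximal = config.pwv_proximal_mean + config.pwv_proximal_sd * marker(
        config.severity_to_proximal, config.age_to_proximal
    )
    nwi = config.nwi_mean + config.nwi_sd * marker(
        config.severity_to_nwi, config.age_to_nwi
    )
    gender = (rng.random(n) < config.gender_male_fraction).astype(int)

    classes = simulate_segment_classes(severity, config, rng)

    outlier_ids = {}
    if config.inject_outliers:
        if n < 2:
            raise ConfigurationError("outlier injection needs n_patients >= 2")
        # one record with the extreme Mean SC (via its driving segments) and
        # one with the extreme proximal PWV, as printed
        classes[0, :] = [np.nan if c is None else c for c in OUTLIER_SEGMENT_CLASSES]
        pwv_proximal[1] = OUTLIER_PROXIMAL_PWV
        ids = _patient_ids(n)
        outlier_ids = {"mean_sc": ids[0], "pwv_proximal": ids[1]}

    summaries = stenosis.summarize_class_matrix(classes)

    data = pd.DataFrame(
        {
            "id": _patient_ids(n),
            "age": age,
            "gender": gender,
            "mean_sc": summaries["mean_sc"].to_numpy(),
            "max_sc": summaries["max_sc"].to_numpy(),
            "nwi": nwi,
            "pwv_proximal": pwv_proximal,
            "pwv_distal": pwv_distal,
        }
    )
    truth = {
        "z_age": z_age,
        "severity": severity,
        "segment_classes": classes,
        "true_pwv_distal": pwv_distal.copy(),
        "true_pwv_proximal": pwv_proximal.copy(),
        "true_nwi": nwi.copy(),
        "outlier_ids": outlier_ids,
        "config": config,
    }
    return CohortTable(data), truth


# printed marker values of the two extreme patients
PAPER_OUTLIER_A = {"mean_sc": 3.6, "pwv_proximal": 8.8, "pwv_distal": 9.2, "nwi": 0.48}
PAPER_OUTLIER_B = {"mean_sc": 1.6, "pwv_proximal": 45.3, "pwv_distal": 13.2, "nwi": 0.57}


def fixture_paper_cohort() -> CohortTable:
    """Deterministic 42-row cohort carrying the two printed outlier patients.

    Rows P001 and P002 hold the exact published marker values of the extreme
    Mean SC and extreme proximal PWV patients; the remaining 40 rows are
    plausible synthetic values from the default generator at a fixed seed.
    Intended for exercising cell-wise outlier flags and pairwise-complete Ns.
    """
    table, _ = generate_cohort(CohortConfig(n_patients=42, seed=20150120))
    data = table.data
    for row, values, max_sc in ((0, PAPER_OUTLIER_A, 5), (1, PAPER_OUTLIER_B, 4)):
        for col, val in values.items():
            data.loc[row, col] = val
        data.loc[row, "max_sc"] = max_sc
    return CohortTable(data)


#: cell-wise flags matching the published outlier handling
PAPER_OUTLIER_FLAGS = (("P001", "mean_sc"), ("P002", "pwv_proximal"))
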