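"""Synthetic phase-contrast phantoms and study cohorts.

Two generators make every downstream stage testable without scanner data:

``simulate_pc_series``
    A 2-D digital phantom of a vessel cross-section over one cardiac
    cycle: a bright lumen disc with partial-volume rim coverage on a
    dimmer static background, a laminar (parabolic) velocity profile
    scaled by a prescribed centerline waveform, phase encoded as
    pi * v / VENC and wrapped into (-pi, pi], Rician-style magnitude
    noise from complex Gaussian noise at a stated SNR.

``simulate_cohort``
    Subject tables with the statistical structure the damping analysis
    assumes: a latent Gaussian copula ties the damping factor (DF) to
    the basal-ganglia perivascular-space (PVS) count at a controllable
    rank correlation, with age/sex effects on both, Poisson-margin PVS
    counts, and cardiovascular covariates with realistic marginals.
    Default marginals put the PI and DF medians near the values typical
    of 7T studies of the lenticulostriate arteries (PI ~ 0.85-0.87,
    DF ~ 1.03).

Both are bit-deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
import pandas as pd
from scipy import stats as sps

from .pvs import count_to_score
from .velocimetry import VelocitySeries

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "simulate_pc_series",
    "simulate_cohort",
    "cardiac_waveform",
    "write_phantom",
    "write_cohort",
    "COHORT_COLUMNS",
]

_SUBPIXEL = 16  # sub-pixel sampling factor for partial-volume coverage


def cardiac_waveform(
    n_phases: int,
    v_mean: float,
    pi: float,
    systolic_phase: float = 0.2,
    harmonics: tuple[tuple[float, float], ...] = ((1.0, 0.0), (0.45, 0.55), (0.15, 1.2)),
) -> np.ndarray:
    """Smooth pulsatile waveform with a systolic peak.

    A truncated 3-harmonic Fourier series (amplitude, phase-lag pairs in
    ``harmonics``) is shifted so its peak sits at ``systolic_phase`` of
    the cycle, then affinely rescaled so the mean equals ``v_mean`` and
    Gosling's PI = (max - min) / mean equals ``pi`` exactly.
    """
    if n_phases < 2:
        raise ValueError("need at least 2 cardiac phases")
    if v_mean <= 0 or pi < 0:
        raise ValueError("v_mean must be positive and pi non-negative")
    t = np.arange(n_phases) / n_phases
    shape = np.zeros(n_phases)
    for k, (amp, lag) in enumerate(harmonics, start=1):
        shape += amp * np.cos(2 * np.pi * k * (t - systolic_phase) - lag)
    if pi == 0:
        return np.full(n_phases, v_mean)
    spread = shape.max() - shape.min()
    scale = pi * v_mean / spread
    return v_mean + scale * (shape - shape.mean())


@dataclass
class PhantomSpec:
    """Geometry, waveform, and acquisition settings for one phantom.

    vessel_center is a continuous (row, col) coordinate; pixel (r, c)
    is centred at (r, c).  background_level is the static-tissue
    magnitude relative to a lumen signal of 1.  snr = lumen magnitude /
    complex-noise SD (``np.inf`` for noiseless).  phase_offset is a
    constant residual background phase in radians.
    """

    grid_rows: int = 32
    grid_cols: int = 32
    vessel_center: tuple[float, float] = (15.0, 15.0)
    vessel_radius: float = 2.4
    waveform: np.ndarray = None
    n_phases: int = 20
    venc: float = 30.0
    snr: float = np.inf
    background_level: float = 0.15
    phase_offset: float = 0.0
    temporal_resolution: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.waveform is None:
            self.waveform = cardiac_waveform(self.n_phases, v_mean=8.4, pi=0.85)
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.waveform.shape != (self.n_phases,):
            raise ValueError("waveform length must equal n_phases")
        if self.vessel_radius <= 0:
            raise ValueError("vessel_radius must be positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if np.max(np.abs(self.waveform)) > 2 * self.venc:
            raise ValueError(
                "waveform exceeds 2*venc: more than one phase wrap is ambiguous"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless centerline waveform and the true peak voxel."""

    waveform: np.ndarray
    peak_voxel: tuple[int, int]
    coverage: np.ndarray = field(repr=False, default=None)
    velocity_profile: np.ndarray = field(repr=False, default=None)


def _disc_coverage(spec: PhantomSpec) -> np.ndarray:
    """Fractional disc coverage per pixel by sub-pixel sampling."""
    n = _SUBPIXEL
    offs = (np.arange(n) + 0.5) / n - 0.5
    rr = np.arange(spec.grid_rows)[:, None, None, None] + offs[None, None, :, None]
    cc = np.arange(spec.grid_cols)[None, :, None, None] + offs[None, None, None, :]
    d2 = (rr - spec.vessel_center[0]) ** 2 + (cc - spec.vessel_center[1]) ** 2
    return (d2 <= spec.vessel_radius**2).mean(axis=(2, 3))


def _parabolic_profile(spec: PhantomSpec) -> np.ndarray:
    """Laminar-flow velocity fraction at each pixel centre: 1 - (rho/R)^2
    inside the lumen, 0 outside."""
    rr = np.arange(spec.grid_rows)[:, None] - spec.vessel_center[0]
    cc = np.arange(spec.grid_cols)[None, :] - spec.vessel_center[1]
    rho2 = (rr**2 + cc**2) / spec.vessel_radius**2
    return np.where(rho2 < 1.0, 1.0 - rho2, 0.0)


def _wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    wrapped = np.angle(np.exp(1j * phase))
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def simulate_pc_series(spec: PhantomSpec) -> tuple[VelocitySeries, GroundTruth]:
    """Render one cardiac-gated magnitude/phase series from a phantom spec.

    The magnitude is ``background_level`` outside the lumen and 1 inside,
    blended by fractional disc coverage at the rim.  The velocity channel
    point-samples the parabolic profile at pixel centres (so a vessel
    centred on a pixel centre carries the exact centerline waveform) and
    is encoded as wrapped phase pi*v/venc + phase_offset.  Complex
    Gaussian noise of SD 1/snr is added to the complex image, making the
    magnitude Rician.  Deterministic given ``spec.seed``.
    """
    coverage = _disc_coverage(spec)
    profile = _parabolic_profile(spec)
    mag0 = spec.background_level + (1.0 - spec.background_level) * coverage
    velocity = profile[:, :, None] * spec.waveform[None, None, :]
    true_phase = np.pi * velocity / spec.venc + spec.phase_offset
    complex_img = mag0[:, :, None] * np.exp(1j * true_phase)
    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sd = 1.0 / spec.snr
        noise = rng.normal(0.0, sd, complex_img.shape) + 1j * rng.normal(
            0.0, sd, complex_img.shape
        )
        complex_img = complex_img + noise
    series = VelocitySeries(
        magnitude=np.abs(complex_img),
        phase=_wrap(np.angle(complex_img)),
        venc=spec.venc,
        temporal_resolution=spec.temporal_resolution,
        vessel_seed=(int(round(spec.vessel_center[0])), int(round(spec.vessel_center[1]))),
    )
    mean_vel = velocity.mean(axis=2)
    peak_flat = int(np.argmax(mean_vel))  # row-major argmax = tie rule
    peak = (peak_flat // spec.grid_cols, peak_flat % spec.grid_cols)
    truth = GroundTruth(
        waveform=spec.waveform.copy(),
        peak_voxel=peak,
        coverage=coverage,
        velocity_profile=profile,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

COHORT_COLUMNS = {
    "subject_id": "string identifier, sub-001 ...",
    "age": "years",
    "sex": "1 = male, 0 = female",
    "pi_lsa": "Gosling PI of the lenticulostriate artery (dimensionless)",
    "pi_mca": "Gosling PI of the middle cerebral artery (dimensionless)",
    "df": "damping factor PI_MCA / PI_LSA (dimensionless)",
    "pvs_bg_count": "PVS on the highest-burden slice, basal ganglia",
    "pvs_cso_count": "PVS on the highest-burden slice, centrum semiovale",
    "pvs_bg_score": "merged ordinal score, basal ganglia (0-2)",
    "pvs_cso_score": "merged ordinal score, centrum semiovale (1-3)",
    "hypertension": "1 = hypertensive",
    "pulse_pressure": "systolic minus diastolic blood pressure, mmHg",
    "bmi": "body mass index, kg/m^2",
    "smoking_history": "1 = ever smoked",
    "alcohol": "units per week",
    "brain_size": "grey + white matter volume, mL",
}


@dataclass
class CohortSpec:
    """Generative settings for one synthetic study cohort.

    ``latent_rho_df_bg`` is the Gaussian-copula correlation between the
    DF latent and the basal-ganglia PVS-count latent (signed, |rho|<=1);
    the realized rank correlation is attenuated by the Poisson count
    discretization.  Effect sizes are latent-scale loadings per SD of
    age (or for male sex) and default to modest values consistent with
    older age carrying more PVS and a lower DF.
    """

    n_subjects: int = 45
    latent_rho_df_bg: float = -0.35
    latent_rho_df_cso: float = 0.0
    age_range: tuple[float, float] = (40.0, 90.0)
    sex_ratio: float = 0.47
    age_effect_pvs: float = 0.35
    sex_effect_pvs: float = 0.20
    age_effect_pulsatility: float = -0.20
    # marginals
    pi_lsa_median: float = 0.85
    pi_lsa_log_sd: float = 0.15
    df_median: float = 1.03
    df_log_sd: float = 0.16
    pvs_bg_rate: float = 15.0
    pvs_cso_rate: float = 35.0
    hypertension_rate: float = 0.47
    pulse_pressure_mean: float = 50.0
    pulse_pressure_sd: float = 10.0
    pp_pi_lsa_loading: float = 0.45
    bmi_mean: float = 25.5
    bmi_sd: float = 3.2
    smoking_rate: float = 0.42
    alcohol_log_median: float = 3.5
    alcohol_log_sd: float = 1.0
    brain_size_mean: float = 1200.0
    brain_size_sd: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("n_subjects must be >= 5")
        if abs(self.latent_rho_df_bg) > 1 or abs(self.latent_rho_df_cso) > 1:
            raise ValueError("latent correlations must lie in [-1, 1]")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be a fraction")
        cov = self._latent_cov()
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "latent covariance is not positive definite for the requested "
                "correlations"
            ) from exc

    def _latent_cov(self) -> np.ndarray:
        # order: (df, bg, cso)
        c = np.eye(3)
        c[0, 1] = c[1, 0] = self.latent_rho_df_bg
        c[0, 2] = c[2, 0] = self.latent_rho_df_cso
        return c


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table (one row per subject, ``COHORT_COLUMNS``).

    Latent standard normals (u_df, u_bg, u_cso) are drawn from the
    copula covariance; age and sex loadings are added on the latent
    scale and the sums re-standardized.  PVS counts come from Poisson
    margins via the quantile transform count = F^-1(Phi(z)); DF and
    PI_LSA are log-normal with the configured medians; PI_MCA = DF *
    PI_LSA.  Pulse pressure shares a configurable loading with the
    PI_LSA latent so the pulse-pressure regression has signal.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = rng.uniform(*spec.age_range, size=n)
    age_z = (age - np.mean(spec.age_range)) / (
        (spec.age_range[1] - spec.age_range[0]) / np.sqrt(12.0)
    )
    sex = (rng.uniform(size=n) < spec.sex_ratio).astype(int)
    sex_c = sex - spec.sex_ratio

    chol = np.linalg.cholesky(spec._latent_cov())
    u = rng.standard_normal((n, 3)) @ chol.T
    u_df, u_bg, u_cso = u[:, 0], u[:, 1], u[:, 2]

    def _shift(latent: np.ndarray, age_load: float, sex_load: float) -> np.ndarray:
        z = latent + age_load * age_z + sex_load * sex_c
        return z / np.sqrt(1.0 + age_load**2 + sex_load**2 * spec.sex_ratio * (1 - spec.sex_ratio))

    z_df = _shift(u_df, spec.age_effect_pulsatility, 0.0)
    z_bg = _shift(u_bg, spec.age_effect_pvs, spec.sex_effect_pvs)
    z_cso = _shift(u_cso, spec.age_effect_pvs, spec.sex_effect_pvs)

    df = spec.df_median * np.exp(spec.df_log_sd * z_df)
    z_pi_lsa = rng.standard_normal(n)
    pi_lsa = spec.pi_lsa_median * np.exp(spec.pi_lsa_log_sd * z_pi_lsa)
    pi_mca = df * pi_lsa

    bg_count = sps.poisson.ppf(sps.norm.cdf(z_bg), spec.pvs_bg_rate).astype(int)
    cso_count = sps.poisson.ppf(sps.norm.cdf(z_cso), spec.pvs_cso_rate).astype(int)

    lam = spec.pp_pi_lsa_loading
    pp_z = lam * z_pi_lsa + np.sqrt(max(1.0 - lam**2, 0.0)) * rng.standard_normal(n)
    pulse_pressure = spec.pulse_pressure_mean + spec.pulse_pressure_sd * pp_z

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "pi_lsa": pi_lsa,
            "pi_mca": pi_mca,
            "df": df,
            "pvs_bg_count": bg_count,
            "pvs_cso_count": cso_count,
            "pvs_bg_score": [count_to_score(c, "BG").merged_score for c in bg_count],
            "pvs_cso_score": [count_to_score(c, "CSO").merged_score for c in cso_count],
            "hypertension": (rng.uniform(size=n) < spec.hypertension_rate).astype(int),
            "pulse_pressure": pulse_pressure,
            "bmi": rng.normal(spec.bmi_mean, spec.bmi_sd, size=n),
            "smoking_history": (rng.uniform(size=n) < spec.smoking_rate).astype(int),
            "alcohol": spec.alcohol_log_median
            * np.exp(spec.alcohol_log_sd * rng.standard_normal(n)),
            "brain_size": rng.normal(spec.brain_size_mean, spec.brain_size_sd, size=n),
        }
    )
    return table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_phantom(
    series: VelocitySeries,
    truth: GroundTruth,
    out_dir: str | Path,
    stem: str = "phantom",
    seed: int | None = None,
) -> dict[str, Path]:
    """Write paired NIfTI stacks plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mag": out / f"{stem}_mag.nii.gz",
        "phase": out / f"{stem}_phase.nii.gz",
        "sidecar": out / f"{stem}.json",
    }
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(series.magnitude.astype(np.float32), affine), paths["mag"])
    nib.save(nib.Nifti1Image(series.phase.astype(np.float32), affine), paths["phase"])
    sidecar = {
        "venc_cm_s": series.venc,
        "temporal_resolution_ms": series.temporal_resolution,
        "vessel_seed": list(series.vessel_seed) if series.vessel_seed else None,
        "seed": seed,
        "ground_truth": {
            "waveform_cm_s": truth.waveform.tolist(),
            "peak_voxel": list(truth.peak_voxel),
        },
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the cohort CSV next to a column-dictionary JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    dict_path = path.with_suffix(".columns.json")
    dict_path.write_text(json.dumps(COHORT_COLUMNS, indent=2))
    return path
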