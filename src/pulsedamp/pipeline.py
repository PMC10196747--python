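"""End-to-end study pipeline: simulate -> extract -> score -> analyze.

A ``StudyConfig`` (YAML-loadable) drives a reproducible run: a synthetic
cohort is drawn, each subject's two vessels (MCA, LSA) are rendered as
phase-contrast phantom series and pushed through the velocimetry stack,
PVS counts are scored, and the correlation/regression layer produces the
results tables.  All randomness flows from one top-level seed through
named substreams, so identical config + seed gives byte-identical
outputs.  Artifacts: measures CSV, scored cohort CSV, results CSV, and a
run log (JSON) recording versions, seeds, and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pvs import score_cohort
from .stats import format_report, run_table4, sensitivity_adjust, standardized_regression
from .synthetic import CohortSpec, PhantomSpec, cardiac_waveform, simulate_pc_series
from .velocimetry import damping_factor, extract_waveform

__all__ = ["StudyConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("pulsedamp")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class StudyConfig:
    """Settings for one synthetic study run.

    imaging.venc maps vessel name to VENC (cm/s); v_mean medians and
    log-SDs set each subject's time-averaged velocity scale per vessel.
    ``imaging_enabled=False`` skips phantom rendering and analyzes the
    cohort's generative PI/DF values directly.
    """

    seed: int = 0
    alpha: float = 0.05
    output_dir: str = "pulsedamp_run"
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    imaging_enabled: bool = True
    grid: tuple[int, int] = (32, 32)
    n_phases: int = 20
    venc: dict = field(default_factory=lambda: {"lsa": 30.0, "mca": 100.0})
    snr: float = 20.0
    noise_k: float = 3.0  # noise threshold = static-ROI mean + k*SD
    vessel_radius: float = 2.4
    background_level: float = 0.15
    v_mean_median: dict = field(default_factory=lambda: {"lsa": 8.4, "mca": 41.9})
    v_mean_log_sd: float = 0.2
    sensitivity: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def load_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    if "grid" in raw:
        raw["grid"] = tuple(raw["grid"])
    return StudyConfig(**raw)


_STATIC_ROI_MARGIN = 6  # top-left corner block used as static-tissue ROI


def _static_roi(shape: tuple[int, int]) -> np.ndarray:
    roi = np.zeros(shape, dtype=bool)
    roi[: _STATIC_ROI_MARGIN, : _STATIC_ROI_MARGIN] = True
    return roi


_VESSEL_CODE = {"lsa": 1, "mca": 2}


def _subject_seed(master: int, index: int, vessel: str) -> int:
    ss = np.random.SeedSequence([master, index, _VESSEL_CODE[vessel]])
    return int(ss.generate_state(1)[0] % 2**31)


def extract_subject_measures(config: StudyConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Render and decode both vessels for every subject.

    Each subject's generative PI values parameterize the phantom
    waveforms; the returned measures are what the velocimetry stack
    recovers from the noisy images (subject_id, vessel, v_min, v_max,
    v_mean, pi).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    rows = []
    center = ((config.grid[0] - 1) / 2.0, (config.grid[1] - 1) / 2.0)
    center = (round(center[0]), round(center[1]))  # pixel-centred vessel
    roi = _static_roi(config.grid)
    for idx, rec in cohort.iterrows():
        v_means = {
            v: config.v_mean_median[v] * np.exp(config.v_mean_log_sd * rng.standard_normal())
            for v in ("lsa", "mca")
        }
        for vessel, pi_true in (("lsa", rec["pi_lsa"]), ("mca", rec["pi_mca"])):
            wf = cardiac_waveform(config.n_phases, v_mean=v_means[vessel], pi=pi_true)
            spec = PhantomSpec(
                grid_rows=config.grid[0],
                grid_cols=config.grid[1],
                vessel_center=(float(center[0]), float(center[1])),
                vessel_radius=config.vessel_radius,
                waveform=wf,
                n_phases=config.n_phases,
                venc=float(config.venc[vessel]),
                snr=config.snr,
                background_level=config.background_level,
                seed=_subject_seed(config.seed, int(idx), vessel),
            )
            series, _ = simulate_pc_series(spec)
            m = extract_waveform(series, roi, seed_hint=center, k=config.noise_k)
            rows.append(
                {
                    "subject_id": rec["subject_id"],
                    "vessel": vessel,
                    "v_min": m.v_min,
                    "v_max": m.v_max,
                    "v_mean": m.v_mean,
                    "pi": m.pi,
                }
            )
    return pd.DataFrame(rows)


def _merge_measures(cohort: pd.DataFrame, measures: pd.DataFrame) -> pd.DataFrame:
    """Replace generative PI/DF columns with image-derived ones."""
    wide = measures.pivot(index="subject_id", columns="vessel", values="pi")
    out = cohort.copy().set_index("subject_id")
    out["pi_lsa"] = wide["lsa"]
    out["pi_mca"] = wide["mca"]
    out["df"] = [
        damping_factor(m, l).df for m, l in zip(out["pi_mca"], out["pi_lsa"])
    ]
    return out.reset_index()


def run_pipeline(config: StudyConfig) -> dict[str, Path]:
    """Run the full study; returns {artifact name -> path}.

    On any stage failure, partially written artifacts are removed and a
    ``PipelineError`` tagged with the failing stage is raised.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measures": out_dir / "measures.csv",
        "cohort": out_dir / "cohort_scored.csv",
        "results": out_dir / "results.csv",
        "report": out_dir / "report.txt",
        "log": out_dir / "run_log.json",
    }
    written: list[Path] = []
    try:
        log.info("stage simulate: cohort of %s subjects", config.cohort.get("n_subjects", 45))
        try:
            spec = CohortSpec(seed=config.seed, **config.cohort)
            cohort = simulate_cohort_stage(spec)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc

        try:
            if config.imaging_enabled:
                log.info("stage extract: rendering %d phantom pairs", len(cohort))
                measures = extract_subject_measures(config, cohort)
                cohort = _merge_measures(cohort, measures)
            else:
                measures = cohort.melt(
                    id_vars="subject_id",
                    value_vars=["pi_lsa", "pi_mca"],
                    var_name="vessel",
                    value_name="pi",
                ).assign(v_min=np.nan, v_max=np.nan, v_mean=np.nan)
                measures["vessel"] = measures["vessel"].str.removeprefix("pi_")
            measures.to_csv(paths["measures"], index=False)
            written.append(paths["measures"])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("extract", str(exc)) from exc

        try:
            log.info("stage score: mapping PVS counts to merged scores")
            cohort = score_cohort(cohort)
            cohort.to_csv(paths["cohort"], index=False)
            written.append(paths["cohort"])
        except Exception as exc:
            raise PipelineError("score", str(exc)) from exc

        try:
            log.info("stage analyze: partial Spearman matrix (alpha=%g)", config.alpha)
            results = run_table4(cohort, alpha=config.alpha)
            blocks = [results.assign(adjustment="age+sex")]
            if config.sensitivity:
                for factor, mat in sensitivity_adjust(cohort, alpha=config.alpha).items():
                    blocks.append(mat.assign(adjustment=f"age+sex+{factor}"))
            regs = [
                standardized_regression(cohort, "pulse_pressure", var)
                for var in ("pi_lsa", "pi_mca", "df")
            ]
            all_results = pd.concat(blocks, ignore_index=True)
            all_results.to_csv(paths["results"], index=False)
            written.append(paths["results"])
            report = format_report(results, alpha=config.alpha)
            report += "\n\nStandardized regressions of pulse pressure (adjusted for age and sex):\n"
            for r in regs:
                report += f"  {r.predictor:<8} beta = {r.beta: .3f}, P = {r.p:.3f} (n={r.n})\n"
            paths["report"].write_text(report)
            written.append(paths["report"])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

        run_log = {
            "pulsedamp_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.seed,
            "config": _jsonable(dataclasses.asdict(config)),
        }
        paths["log"].write_text(json.dumps(run_log, indent=2))
        written.append(paths["log"])
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    log.info("pipeline complete: %s", out_dir)
    return paths


def simulate_cohort_stage(spec: CohortSpec) -> pd.DataFrame:
    from .synthetic import simulate_cohort

    return simulate_cohort(spec)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
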