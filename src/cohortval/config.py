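"""Configuration objects for the simulator and the validation pipeline.

``SimConfig`` holds the cohort-design constants (enrollment window,
administrative censoring date, testing intensities, discordance-injection
rates) plus the shape parameters of the latent biomarker process.  The
latent-process parameters are explicit stand-ins: real registries do not
publish a generative model for CD4 trajectories or viral-load suppression,
so these defaults are chosen to be qualitatively realistic (rising CD4
means and falling detectability after treatment start), not fitted claims.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError

ANALYTES = ("CD4", "VL")

#: Pre-treatment observation period (days before cART start) over which
#: latent lab series begin; anchors "before cART" derived measures.
DEFAULT_PRE_CART_DAYS = 365


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class SimConfig:
    """Design constants for the paired-registry simulator.

    Parameters
    ----------
    n_patients :
        Cohort size (adults starting combined antiretroviral therapy).
    n_sites :
        Number of cohort sites; patients are assigned uniformly.
    enrollment_start, enrollment_end :
        Window within which cART start dates are drawn (default
        2003-01-01 .. 2013-12-31).
    admin_censor_date :
        Administrative censoring date of the cohort (default 2014-07-31).
    tests_per_py :
        Expected latent tests per analyte per person-year (Poisson
        intensity of the latent testing process each source observes).
    missing_prob_cohort, missing_prob_surveillance :
        Probability that a latent test is absent from the respective
        source (independent thinning).
    typo_rate :
        Probability, per surveillance identity string, of one injected
        single-character edit.
    date_jitter_days :
        Maximum symmetric integer jitter (days) on the surveillance copy
        of a collection date.
    value_noise_sd :
        Per-analyte perturbation SD on the surveillance copy: cells/mm3
        for CD4, log10 copies/ml for VL.
    lod_schedule :
        Year -> viral-load lower limit of detection in copies/ml; the
        limit in force is the entry with the largest year <= test year.
        Defaults step from 400 down to 40 copies/ml across the era.
    seed :
        Master seed; per-patient generators are spawned from
        ``(seed, patient_index)`` so runs are reproducible and patient
        streams are stable under changes of ``n_patients``.
    """

    n_patients: int = 2000
    n_sites: int = 13
    enrollment_start: dt.date = dt.date(2003, 1, 1)
    enrollment_end: dt.date = dt.date(2013, 12, 31)
    admin_censor_date: dt.date = dt.date(2014, 7, 31)
    tests_per_py: float = 2.5
    missing_prob_cohort: float = 0.10
    missing_prob_surveillance: float = 0.15
    typo_rate: float = 0.05
    date_jitter_days: int = 3
    value_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CD4": 10.0, "VL": 0.05}
    )
    lod_schedule: Mapping[int, float] = field(
        default_factory=lambda: {2003: 400.0, 2008: 80.0, 2013: 40.0}
    )
    pre_cart_days: int = DEFAULT_PRE_CART_DAYS
    mean_followup_years: float = 5.0
    min_followup_days: int = 30
    seed: int = 0

    # Latent biomarker process (stand-in shape parameters, see module
    # docstring): CD4 baseline lognormal, exponential post-treatment
    # recovery; VL log10-normal pre-treatment, detectability decaying
    # geometrically per post-treatment count index.
    cd4_baseline_log_mean: float = 5.4  # log cells/mm3 (~220 median)
    cd4_baseline_log_sd: float = 0.6
    cd4_recovery_rate: float = 0.20  # per year on the log scale
    cd4_within_sd: float = 0.25  # log-scale measurement dispersion
    vl_pre_log_mean: float = 4.3  # log10 copies/ml
    vl_pre_log_sd: float = 0.9
    vl_post_detect_p0: float = 0.30
    vl_post_detect_decay: float = 0.92
    vl_post_log_mean: float = 3.2
    vl_post_log_sd: float = 0.6

    def __post_init__(self):
        object.__setattr__(self, "enrollment_start", _parse_date(self.enrollment_start))
        object.__setattr__(self, "enrollment_end", _parse_date(self.enrollment_end))
        object.__setattr__(self, "admin_censor_date", _parse_date(self.admin_censor_date))
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be a positive integer")
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be a positive integer")
        if self.tests_per_py <= 0:
            raise ConfigError("tests_per_py must be positive")
        for name in ("missing_prob_cohort", "missing_prob_surveillance", "typo_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.date_jitter_days < 0:
            raise ConfigError("date_jitter_days must be >= 0")
        for analyte in ANALYTES:
            if analyte not in self.value_noise_sd:
                raise ConfigError(f"value_noise_sd missing entry for {analyte}")
            if self.value_noise_sd[analyte] < 0:
                raise ConfigError(f"value_noise_sd[{analyte}] must be >= 0")
        if not self.lod_schedule:
            raise ConfigError("lod_schedule must not be empty")
        for year, lod in self.lod_schedule.items():
            if not 40.0 <= float(lod) <= 400.0:
                raise ConfigError(
                    f"lod_schedule[{year}]={lod} outside the assay era range [40, 400]"
                )
        if self.enrollment_end >= self.admin_censor_date:
            raise ConfigError("enrollment_window must end before admin_censor_date")
        if self.enrollment_start > self.enrollment_end:
            raise ConfigError("enrollment_start must not exceed enrollment_end")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must lie in [0, 2^31)")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``sim`` (a :class:`SimConfig`, run on synthetic
    registries) or the four input paths (run on externally supplied
    delimited-text registries) must be supplied.
    """

    sim: SimConfig | None = None
    cohort_patients: str | None = None
    cohort_results: str | None = None
    surveillance_patients: str | None = None
    surveillance_results: str | None = None
    window_days: int = 30
    admin_censor_date: dt.date = dt.date(2014, 7, 31)
    pre_cart_inclusive: bool = False
    percent_convention: str = "half_up"  # or "truncate"
    bootstrap_samples: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "admin_censor_date", _parse_date(self.admin_censor_date))
        paths = (
            self.cohort_patients,
            self.cohort_results,
            self.surveillance_patients,
            self.surveillance_results,
        )
        has_paths = any(p is not None for p in paths)
        if has_paths and not all(p is not None for p in paths):
            raise ConfigError(
                "either all four registry paths or none must be supplied"
            )
        if (self.sim is None) == (not has_paths):
            raise ConfigError(
                "exactly one of {sim config, registry paths} must be supplied"
            )
        if self.window_days <= 0:
            raise ConfigError("window_days must be positive")
        if self.percent_convention not in ("half_up", "truncate"):
            raise ConfigError("percent_convention must be 'half_up' or 'truncate'")
        if self.bootstrap_samples <= 0:
            raise ConfigError("bootstrap_samples must be positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML/key-value text file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown simulator config fields: {sorted(unknown)}")
    return SimConfig(**raw)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` (with optional nested ``sim`` block)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    sim_raw = raw.pop("sim", None)
    sim = SimConfig(**sim_raw) if sim_raw is not None else None
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown pipeline config fields: {sorted(unknown)}")
    return PipelineConfig(sim=sim, **raw)
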