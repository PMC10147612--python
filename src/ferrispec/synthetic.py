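"""Seeded synthetic-data generators for offline testing.

Every tabular input the fitting code consumes can be generated here
with known ground truth: hyperbolic dose-response data (hemoglobin per
cell versus medium iron), Hill-shaped oxygen-saturation curves, and
noisy observations of simulated transferrin-fraction time-courses.

Noise is additive Gaussian truncated at the physical bounds, since the
experimental readouts are reported as mean +/- SD across donors with
approximately symmetric scatter.  All generators are deterministic for
a fixed seed, and every generated dataset can carry a manifest (seed +
config hash) sufficient for bit-identical regeneration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .doseresponse import DoseResponseDataset, OxygenSaturationCurve
from .errors import ValidationError
from .timecourse import TimeCourse

__all__ = [
    "DoseResponseDesign",
    "OxyCurveDesign",
    "TimecourseNoiseDesign",
    "SyntheticConfig",
    "gen_dose_response",
    "gen_oxy_curve",
    "gen_timecourse_observations",
    "manifest",
]

#: Medium iron concentrations (umol/L) of the standard titration design:
#: the holotransferrin dilution series equivalents plus the chelator
#: complex doses used on top of low-transferrin medium.
DEFAULT_CONCENTRATIONS = (0.0, 1.3, 2.6, 5.2, 13.0, 26.0, 52.0)


@dataclass(frozen=True)
class DoseResponseDesign:
    """Ground truth and sampling design for dose-response data.

    ``hb_max`` ~30 pg/cell (the hemoglobin content of a mature cell),
    ``ec50`` in umol/L, ``noise_sd`` as a fraction of ``hb_max``.
    ``n_points`` observations are assigned round-robin over
    ``concentrations``.
    """

    hb_max: float = 30.0
    ec50: float = 5.0
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_points: int = 24
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_points < len(self.concentrations):
            raise ValidationError("n_points must cover every concentration")


@dataclass(frozen=True)
class OxyCurveDesign:
    """Ground truth for a synthetic oxygen-saturation curve.

    Defaults: P50 26.8 mmHg (peripheral-blood reference), Hill
    coefficient 2.7, pO2 sampled 0-150 mmHg, absolute saturation noise
    SD 0.01.
    """

    p50: float = 26.8
    hill_n: float = 2.7
    po2_max: float = 150.0
    n_points: int = 76
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.p50 <= 0 or self.hill_n <= 0:
            raise ValidationError("p50 and hill_n must be positive")


@dataclass(frozen=True)
class TimecourseNoiseDesign:
    """Observation noise on simulated transferrin fractions."""

    noise_sd: float = 0.01

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Top-level generator configuration: one seed, three designs."""

    seed: int = 0
    dose_response: DoseResponseDesign = field(default_factory=DoseResponseDesign)
    oxy: OxyCurveDesign = field(default_factory=OxyCurveDesign)
    timecourse_obs: TimecourseNoiseDesign = field(
        default_factory=TimecourseNoiseDesign
    )


def _config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def manifest(cfg: SyntheticConfig) -> dict:
    """Reproducibility manifest: seed, config hash, full parameters."""
    return {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": asdict(cfg),
    }


def gen_dose_response(cfg: SyntheticConfig) -> DoseResponseDataset:
    """Hyperbolic response plus truncated Gaussian noise.

    hb = hb_max * c / (ec50 + c) + N(0, noise_sd * hb_max), clipped at
    zero.  Deterministic per seed.
    """
    d = cfg.dose_response
    rng = np.random.default_rng(cfg.seed)
    reps = -(-d.n_points // len(d.concentrations))  # ceil division
    c = np.tile(np.asarray(d.concentrations, dtype=float), reps)[: d.n_points]
    truth = d.hb_max * c / (d.ec50 + c)
    noise = rng.normal(0.0, d.noise_sd * d.hb_max, size=c.size)
    hb = np.clip(truth + noise, 0.0, None)
    return DoseResponseDataset(fe_conc=c, hb=hb)


def gen_oxy_curve(cfg: SyntheticConfig) -> OxygenSaturationCurve:
    """Hill-curve saturation plus truncated Gaussian noise, clipped to
    [0, 1]."""
    d = cfg.oxy
    rng = np.random.default_rng(cfg.seed + 1)  # decouple from dose-response
    po2 = np.linspace(0.0, d.po2_max, d.n_points)
    with np.errstate(divide="ignore"):
        ratio = np.where(po2 > 0, (po2 / d.p50) ** d.hill_n, 0.0)
    truth = ratio / (1.0 + ratio)
    sat = np.clip(truth + rng.normal(0.0, d.noise_sd, size=po2.size), 0.0, 1.0)
    return OxygenSaturationCurve(po2=po2, saturation=sat)


def gen_timecourse_observations(cfg: SyntheticConfig, tc: TimeCourse):
    """Noisy observation of a simulated fraction time-course.

    Adds truncated Gaussian noise to the (apo, mono, holo) fraction
    triple at each time and renormalizes it to sum to one.  Returns a
    DataFrame with columns time_h, frac_apo, frac_mono, frac_holo.
    """
    import pandas as pd

    sd = cfg.timecourse_obs.noise_sd
    rng = np.random.default_rng(cfg.seed + 2)
    fracs = np.array(
        [[s.frac_apo, s.frac_mono, s.frac_holo] for s in tc.states]
    )
    noisy = np.clip(fracs + rng.normal(0.0, sd, size=fracs.shape), 0.0, None)
    totals = noisy.sum(axis=1, keepdims=True)
    # an all-zero triple after truncation is vanishingly unlikely, but
    # fall back to the noise-free fractions rather than divide by zero
    bad = totals[:, 0] == 0.0
    noisy[bad] = fracs[bad]
    totals[bad] = 1.0
    noisy /= totals
    return pd.DataFrame(
        {
            "time_h": np.asarray(tc.times, dtype=float),
            "frac_apo": noisy[:, 0],
            "frac_mono": noisy[:, 1],
            "frac_holo": noisy[:, 2],
        }
    )
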