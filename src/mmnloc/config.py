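"""Run configuration: YAML-serialisable, schema-validated dataclasses.

Every analysis parameter of the pipeline surfaces as a named key with the
study default: 5% covariance regularisation, SNR 10, 10 mm grid, the
[100, 300) ms power window, the [105, 271] ms mismatch search window, the
±20 ms dipole fit window, FDR q = 0.1 and the Bonferroni family of 20.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field

import yaml

__all__ = [
    "ForwardConfig",
    "ParadigmConfig",
    "CohortConfig",
    "LcmvConfig",
    "EloretaConfig",
    "DipoleConfig",
    "StatsConfig",
    "RunConfig",
    "load_config",
    "save_config",
]

CONFIG_VERSION = 1


@dataclass
class ForwardConfig:
    n_sensors: int = 128
    spacing_mm: float = 10.0
    n_terms: int = 100
    normalise: bool = True


@dataclass
class ParadigmConfig:
    n_sessions: int = 3
    trials_per_session: int = 500
    deviant_fraction: float = 0.1
    min_standards_between_deviants: int = 2


@dataclass
class CohortConfig:
    n_controls: int = 39
    n_patients: int = 58
    noise_sd: float = 5.0
    gain_jitter_sd: float = 0.15
    patient_multipliers: dict = field(
        default_factory=lambda: {
            "IFG-L": 0.6,
            "IFG-R": 0.6,
            "STG-L": 0.6,
            "STG-R": 0.85,
            "PPC-L": 1.5,
            "M1-L": 1.5,
            "DLPFC-L": 1.5,
        }
    )
    control_multipliers: dict = field(default_factory=dict)


@dataclass
class LcmvConfig:
    window: tuple = (100.0, 300.0)
    reg_fraction: float = 0.05
    cov_mode: str = "per-trial-mean"


@dataclass
class EloretaConfig:
    snr: float = 10.0
    tol: float = 1e-6
    max_iter: int = 100
    window: tuple = (100.0, 300.0)


@dataclass
class DipoleConfig:
    search_window: tuple = (105.0, 271.0)
    half_width_ms: float = 20.0


@dataclass
class StatsConfig:
    q: float = 0.10
    alpha: float = 0.05
    bonferroni_m: int = 20  # 4 dipoles × 5 group contrasts
    n_boot: int = 10000
    orientation: tuple = ("control", "patient")  # AUROC > 0.5 = patients higher


@dataclass
class RunConfig:
    forward: ForwardConfig = field(default_factory=ForwardConfig)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lcmv: LcmvConfig = field(default_factory=LcmvConfig)
    eloreta: EloretaConfig = field(default_factory=EloretaConfig)
    dipole: DipoleConfig = field(default_factory=DipoleConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    methods: tuple = ("lcmv", "eloreta", "dipole")
    seed: int = 0
    save_subjects: bool = False
    version: int = CONFIG_VERSION

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if hasattr(obj, "item") and callable(obj.item):  # numpy scalars
                return obj.item()
            return obj

        return clean(asdict(self))

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def reduced_scale_config(seed: int = 0) -> RunConfig:
    """Desk-scale profile for end-to-end validation runs.

    Keeps the full cohort (39 controls / 58 patients) but reduces the
    simulation burden: one 100-trial session instead of three 500-trial
    sessions, a 64-sensor montage and a 12 mm grid.  Single-trial sensor
    noise is scaled by sqrt(100/1500) so the post-averaging ERP
    signal-to-noise ratio matches the full-scale paradigm, and only the
    beamformer and dipole stages (the ones the sign-recovery check needs)
    are run.
    """
    noise_sd = 5.0 * math.sqrt(100.0 / 1500.0)
    return RunConfig(
        forward=ForwardConfig(n_sensors=64, spacing_mm=12.0),
        paradigm=ParadigmConfig(n_sessions=1, trials_per_session=100),
        cohort=CohortConfig(noise_sd=noise_sd),
        methods=("lcmv", "dipole"),
        seed=seed,
    )


_SECTIONS = {
    "forward": ForwardConfig,
    "paradigm": ParadigmConfig,
    "cohort": CohortConfig,
    "lcmv": LcmvConfig,
    "eloreta": EloretaConfig,
    "dipole": DipoleConfig,
    "stats": StatsConfig,
}


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sub = dict(d.pop(name, {}) or {})
        valid = cls.__dataclass_fields__
        unknown = set(sub) - set(valid)
        if unknown:
            raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
        for k, v in sub.items():
            if isinstance(v, list):
                sub[k] = tuple(v)
        kwargs[name] = cls(**sub)
    top = {}
    for k in ("methods", "seed", "save_subjects", "version"):
        if k in d:
            top[k] = tuple(d.pop(k)) if k == "methods" else d.pop(k)
    unknown = set(d)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(**kwargs, **top)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
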