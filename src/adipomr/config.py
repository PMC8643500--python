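"""Simulation and run configuration objects, with JSON/YAML round-tripping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

VALID_PLEIOTROPY = ("none", "balanced", "directional", "inside_violating")
VALID_CAUSAL = ("linear", "quadratic", "threshold")
VALID_OUTCOME = ("continuous", "binary")


@dataclass
class SimulationConfig:
    """Generative model for a synthetic cohort.

    Defaults mirror the study population this package emulates: ~145.7k
    individuals, 72 independent BMI instruments explaining 1.6% of exposure
    variance, a rare binary outcome (current depression, prevalence 1.8%),
    and moderate confounding. Exposure is built on the standardized (SD)
    scale; a raw BMI-like scale (mean 27.4, SD 4.6 kg/m^2) is carried
    alongside for stratified analyses.
    """

    n_individuals: int = 145_668
    n_snps: int = 72
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.016
    confounder_effect_exposure: float = 0.3
    confounder_effect_outcome: float = 0.3
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    inside_rho: float = 0.0
    causal_function: str = "linear"
    # linear: (theta,); quadratic: (theta1, theta2); threshold: (theta, cutpoint)
    causal_coefficients: tuple[float, ...] = (0.405,)
    outcome_kind: str = "binary"
    binary_prevalence: float = 0.018
    sex_effect: float | None = None
    exposure_raw_mean: float = 27.4
    exposure_raw_sd: float = 4.6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if not 0 <= self.exposure_h2 < 1:
            raise ValueError("exposure_h2 must be in [0, 1)")
        if not 0 < self.binary_prevalence < 1:
            raise ValueError("binary_prevalence must be in (0, 1)")
        if self.pleiotropy_mode not in VALID_PLEIOTROPY:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.causal_function not in VALID_CAUSAL:
            raise ValueError(f"unknown causal_function {self.causal_function!r}")
        if self.outcome_kind not in VALID_OUTCOME:
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.exposure_h2 + self.confounder_effect_exposure**2 >= 1:
            raise ValueError("exposure_h2 + confounder_effect_exposure^2 must be < 1")
        self.maf_range = tuple(self.maf_range)  # type: ignore[assignment]
        self.causal_coefficients = tuple(self.causal_coefficients)  # type: ignore[assignment]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def small(cls, **kwargs) -> "SimulationConfig":
        """Desk-scale preset (n=20 000) used throughout the test suite."""
        kwargs.setdefault("n_individuals", 20_000)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["causal_coefficients"] = list(self.causal_coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(_load_config_file(path))

    def to_file(self, path: str | Path) -> None:
        _dump_config_file(self.to_dict(), path)


@dataclass
class OutcomeSpec:
    name: str
    kind: str  # continuous | binary
    prevalence: float | None = None
    causal_function: str = "linear"
    causal_coefficients: tuple[float, ...] = (0.0,)


@dataclass
class InstrumentSetSpec:
    name: str
    n_snps: int
    exposure_h2: float


@dataclass
class RunConfig:
    """Full analysis-matrix configuration for :func:`adipomr.pipeline.run`.

    Encodes the study's analysis grid: instrument sets x outcomes x strata x
    methods, with sensitivity blocks layered on top.
    """

    seed: int = 1
    n_individuals: int = 20_000
    instrument_sets: list[InstrumentSetSpec] = field(
        default_factory=lambda: [
            InstrumentSetSpec("bmi", 72, 0.016),
            InstrumentSetSpec("favourable_adiposity", 36, 0.002),
            InstrumentSetSpec("unfavourable_adiposity", 38, 0.006),
        ]
    )
    outcomes: list[OutcomeSpec] = field(
        default_factory=lambda: [
            OutcomeSpec("current_depression", "binary", 0.018, "linear", (0.405,)),
            OutcomeSpec("wellbeing", "continuous", None, "linear", (-0.15,)),
        ]
    )
    strata: list[str] = field(default_factory=lambda: ["all", "male", "female"])
    methods: list[str] = field(
        default_factory=lambda: [
            "observational",
            "tsls",
            "ivw",
            "egger",
            "weighted_median",
            "penalized_weighted_median",
            "nonlinear",
        ]
    )
    covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "centre", "tdi", "smoking"]
    )
    confounder_effect_exposure: float = 0.3
    confounder_effect_outcome: float = 0.3
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    split: float = 0.5
    n_strata: int = 10
    n_boot_median: int = 1000
    n_boot_curve: int = 500
    exclusion_rules: dict[str, str] = field(default_factory=dict)  # name -> query string
    bonferroni: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for o in d["outcomes"]:
            o["causal_coefficients"] = list(o["causal_coefficients"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "instrument_sets" in d:
            d["instrument_sets"] = [
                s if isinstance(s, InstrumentSetSpec) else InstrumentSetSpec(**s)
                for s in d["instrument_sets"]
            ]
        if "outcomes" in d:
            outs = []
            for o in d["outcomes"]:
                if not isinstance(o, OutcomeSpec):
                    o = dict(o)
                    if "causal_coefficients" in o:
                        o["causal_coefficients"] = tuple(o["causal_coefficients"])
                    o = OutcomeSpec(**o)
                outs.append(o)
            d["outcomes"] = outs
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(_load_config_file(path))

    def to_file(self, path: str | Path) -> None:
        _dump_config_file(self.to_dict(), path)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _load_config_file(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_config_file(d: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=False))
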