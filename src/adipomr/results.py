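"""Result containers shared across the MR estimators and the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass
class MREstimate:
    """A causal-effect estimate on the log-odds or SD-outcome scale.

    ``beta`` is always the effect per 1-SD higher exposure; for binary
    outcomes ``scale == "log-odds"`` and ``exp(beta)`` is the odds ratio.
    """

    method: str
    scale: str  # "log-odds per SD exposure" | "SD outcome per SD exposure" | ...
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    n_instruments: int | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["warnings"] = ";".join(self.warnings)
        return d


@dataclass
class ObservationalEstimate:
    """Covariate-adjusted observational association per 1-SD exposure."""

    outcome: str
    exposure: str
    stratum: str  # all | male | female
    scale: str
    effect: float  # odds ratio (binary) or slope (continuous)
    ci_low: float
    ci_high: float
    p: float
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None
    adjustment: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adjustment"] = ",".join(self.adjustment)
        return d


@dataclass
class LACEStratum:
    """Local average causal effect within one stratum of the IV-free exposure."""

    index: int  # 1-based stratum index
    low: float  # stratum range on the raw exposure scale, [low, high)
    high: float
    mean_exposure: float
    n: int
    n_cases: int | None
    beta_iv_exposure: float
    se_iv_exposure: float
    beta_iv_outcome: float
    se_iv_outcome: float
    lace: float
    se_lace: float
    flagged: bool = False
    flag_reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float


@dataclass
class QuadraticTest:
    slope: float
    se: float
    p: float


@dataclass
class PiecewiseCurve:
    """Continuity-constrained piecewise-linear causal curve over strata knots."""

    knots: list[float]  # S+1 boundaries on the raw exposure scale
    slopes: list[float]  # LACE per segment
    values: list[float]  # curve value at each knot; 0 at the first knot
    ci_low: list[float]
    ci_high: list[float]
    n_boot: int
    q_test: TestResult | None = None
    quadratic_test: QuadraticTest | None = None


def format_effect(beta: float, se: float, as_or: bool = True, z: float = 1.959963984540054) -> str:
    """Render a point estimate with its 95% CI, Table-style: ``1.50 (1.15, 1.95)``."""
    lo, hi = beta - z * se, beta + z * se
    if as_or:
        beta, lo, hi = math.exp(beta), math.exp(lo), math.exp(hi)
    return f"{beta:.2f} ({lo:.2f}, {hi:.2f})"
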