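"""Shared vocabulary: age bands, cause hierarchy, and index validation.

The burden calculation sums over 15 five-year age bands starting at 25
(younger ages are excluded from the exposure-outcome evidence base) and six
pollution-related causes of death organised in a three-level hierarchy:

* level 1 — all-cause mortality (the "envelope");
* level 2 — non-communicable diseases (NCD), communicable/maternal/neonatal/
  nutritional diseases (CMNND), and injuries;
* level 3 — the six PM2.5-related causes (COPD, lower respiratory infection,
  lung cancer, ischaemic heart disease, stroke, type-2 diabetes) plus
  explicit "rest" causes so that children always sum to their parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AGE_BANDS: tuple[str, ...] = (
    "25-30", "30-35", "35-40", "40-45", "45-50",
    "50-55", "55-60", "60-65", "65-70", "70-75",
    "75-80", "80-85", "85-90", "90-95", ">95",
)

#: Age bands whose lower bound is >= 65 years ("older adults").
OLDER_BANDS: tuple[str, ...] = AGE_BANDS[8:]

ALL_CAUSE = "all"
LEVEL2_CAUSES: tuple[str, ...] = ("ncd", "cmnnd", "injuries")

#: The six causes with exposure-response evidence for PM2.5.
PM25_CAUSES: tuple[str, ...] = (
    "copd", "lri", "lung_cancer", "ihd", "stroke", "diabetes_t2",
)

#: parent -> children, including residual ("rest") causes.
HIERARCHY: dict[str, tuple[str, ...]] = {
    ALL_CAUSE: LEVEL2_CAUSES,
    "ncd": ("copd", "lung_cancer", "ihd", "stroke", "diabetes_t2", "rest_ncd"),
    "cmnnd": ("lri", "rest_cmnnd"),
    "injuries": (),
}

#: cause -> hierarchy level (1, 2 or 3).
CAUSE_LEVEL: dict[str, int] = {ALL_CAUSE: 1}
CAUSE_LEVEL.update({c: 2 for c in LEVEL2_CAUSES})
for _parent in LEVEL2_CAUSES:
    CAUSE_LEVEL.update({c: 3 for c in HIERARCHY[_parent]})

#: cause -> parent cause (levels 2 and 3 only).
PARENT: dict[str, str] = {}
for _p, _children in HIERARCHY.items():
    for _c in _children:
        PARENT[_c] = _p

ALL_CAUSES: tuple[str, ...] = tuple(CAUSE_LEVEL)


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario configuration: label, years, and generator drifts.

    Parameters
    ----------
    name:
        Scenario label, e.g. ``"SSP2-4.5"``.  Labels are configuration
        values; no behaviour is keyed on them.
    years:
        Strictly increasing calendar years covered by the scenario.
    concentration_trend:
        Multiplicative year-over-year drift applied to aerosol component
        fields (0.0 means stationary concentrations).
    aging_drift:
        Per-year shift of age-proportion mass toward older bands
        (0.0 means a frozen age structure).
    n_models:
        Number of ensemble members emulating multi-model spread (>= 2).
    """

    name: str
    years: tuple[int, ...]
    concentration_trend: float = 0.0
    aging_drift: float = 0.0
    n_models: int = 3

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        if len(years) == 0:
            raise ValueError("ScenarioSpec.years must be non-empty")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("ScenarioSpec.years must be strictly increasing")
        if self.n_models < 2:
            raise ValueError("ScenarioSpec.n_models must be >= 2")
        import math

        if not (math.isfinite(self.concentration_trend)
                and math.isfinite(self.aging_drift)):
            raise ValueError("ScenarioSpec drifts must be finite")


@dataclass
class GroundTruth:
    """Known generative parameters for the mortality and risk generators.

    These are the quantities parameter-recovery tests check against:
    the two development-index slopes of the hinged regression, the per-age
    time trends, per-(region, age) intercepts, the AR(1) residual process
    (``phi``, innovation scale ``sigma``), and per-cause curve shapes.
    """

    beta1: float = -2.0
    beta2: float = -0.5
    theta_a: dict[str, float] = field(default_factory=dict)
    alpha_la: dict[tuple[str, str], float] = field(default_factory=dict)
    phi: float = 0.5
    sigma: float = 0.05
    rr_curve_params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import math

        for v in (self.beta1, self.beta2, self.phi, self.sigma):
            if not math.isfinite(v):
                raise ValueError("GroundTruth parameters must be finite")
        if abs(self.phi) >= 1:
            raise ValueError("AR(1) residual process must be stationary (|phi| < 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
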