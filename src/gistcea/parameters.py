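"""Model parameters for the rectal-GIST treatment-strategy comparison.

Every quantity the model consumes lives in a :class:`ParameterSet`: annual
transition probabilities, health-state utilities, annual and one-time costs
(2017 Singapore dollars), and the structural settings of the cohort
simulation (start age, cycle length, horizon, discount rate, willingness to
pay).  Each uncertain parameter also carries its deterministic sensitivity
range and the distribution family used in probabilistic sensitivity
analysis (beta for probabilities and utilities, gamma for costs, uniform
for the conditional local-recurrence probability).

Background (other-cause) mortality enters through a :class:`LifeTable`
mapping integer age to an annual death probability; the synthetic default
table is produced by :mod:`gistcea.fixtures`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "LifeTable",
    "ParameterSet",
    "background_mortality",
    "derive_secondary",
    "fit_distribution",
    "from_config_text",
    "load_config",
    "save_config",
    "to_config_text",
    "validate_parameters",
]

#: width of a central 95% normal interval, in standard deviations
_Z95 = 3.92

_FAMILIES = ("beta", "gamma", "uniform", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Marginal uncertainty distribution for a single parameter.

    ``shape1``/``shape2`` hold the fitted shape parameters: (alpha, beta)
    for the beta family, (shape, scale) for gamma, (low, high) for uniform.
    They are ``None`` until :func:`fit_distribution` has run.
    """

    name: str
    family: str
    base: float
    low: float
    high: float
    shape1: float | None = None
    shape2: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    @property
    def fitted(self) -> bool:
        return self.family == "fixed" or self.shape1 is not None

    def mean(self) -> float:
        """Analytic mean of the fitted distribution."""
        if self.family == "fixed":
            return self.base
        if not self.fitted:
            raise ValueError(f"{self.name}: distribution not fitted")
        if self.family == "beta":
            return self.shape1 / (self.shape1 + self.shape2)
        if self.family == "gamma":
            return self.shape1 * self.shape2
        return 0.5 * (self.shape1 + self.shape2)  # uniform

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the fitted distribution with ``rng``."""
        if self.family == "fixed":
            return self.base if size is None else np.full(size, self.base)
        if not self.fitted:
            raise ValueError(f"{self.name}: distribution not fitted")
        if self.family == "beta":
            return rng.beta(self.shape1, self.shape2, size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape1, self.shape2, size=size)
        return rng.uniform(self.shape1, self.shape2, size=size)


def fit_distribution(spec: DistributionSpec) -> DistributionSpec:
    """Fit shape parameters by moment matching.

    The sensitivity range is read as a central 95% interval, so the target
    standard deviation is ``(high - low) / 3.92`` and the target mean is
    the base value.  Beta and gamma shapes are solved in closed form;
    uniform distributions take the range bounds directly and their mean is
    the midpoint (which need not equal the base value).

    Raises :class:`ValueError`, naming the parameter, when the implied
    moments are infeasible for the family.
    """
    if spec.family == "fixed":
        return spec
    if spec.family == "uniform":
        if not spec.low < spec.high:
            raise ValueError(f"{spec.name}: degenerate uniform bounds")
        return replace(spec, shape1=spec.low, shape2=spec.high)

    m = spec.base
    sd = (spec.high - spec.low) / _Z95
    if sd <= 0:
        raise ValueError(f"{spec.name}: zero-width sensitivity range")
    v = sd * sd
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.name}: beta mean outside (0, 1)")
        if v >= m * (1.0 - m):
            raise ValueError(f"{spec.name}: infeasible beta moment match")
        nu = m * (1.0 - m) / v - 1.0
        return replace(spec, shape1=m * nu, shape2=(1.0 - m) * nu)
    # gamma
    if m <= 0:
        raise ValueError(f"{spec.name}: gamma mean must be positive")
    return replace(spec, shape1=m * m / v, shape2=v / m)


@dataclass(frozen=True)
class LifeTable:
    """Annual background (other-cause) death probability by integer age.

    A step function of age: ``q(age)`` returns the entry for
    ``floor(age)``.  Probabilities must lie in (0, 1) and be non-decreasing
    with age, the usual adult life-table shape.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1 or ages.size == 0:
            raise ValueError("life table needs matching 1-d age and qx columns")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life table ages must be consecutive integers")
        if np.any(qx <= 0.0) or np.any(qx >= 1.0):
            raise ValueError("life table probabilities must lie in (0, 1)")
        if np.any(np.diff(qx) < 0):
            raise ValueError("life table probabilities must be non-decreasing in age")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.ages[0]), int(self.ages[-1])

    def q(self, age: float) -> float:
        a = math.floor(age)
        lo, hi = self.span
        if not lo <= a <= hi:
            raise ValueError(f"age {age} outside life-table span [{lo}, {hi}]")
        return float(self.qx[a - lo])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("age,qx\n")
            for a, q in zip(self.ages, self.qx):
                fh.write(f"{a},{float(q)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        ages, qx = [], []
        with open(path) as fh:
            header = fh.readline().strip().lower().split(",")
            if header[:2] != ["age", "qx"]:
                raise ValueError(f"{path}: expected 'age,qx' header")
            for line in fh:
                if not line.strip():
                    continue
                a, q = line.split(",")[:2]
                ages.append(int(a))
                qx.append(float(q))
        return cls(np.asarray(ages), np.asarray(qx))


def background_mortality(life_table: LifeTable, age: float) -> float:
    """Annual probability of death from background causes at ``age``."""
    return life_table.q(age)


# ---------------------------------------------------------------------------
# Parameter table: name -> (base, low, high, PSA family)
# Costs in 2017 SGD.  Ranges: +-20% unless the source reported confidence
# intervals; +-50% for the two post-resection recurrence quantities; the
# imatinib cost lower bound is extended to -80% (anticipating generics).
# ---------------------------------------------------------------------------
_TABLE: dict[str, tuple[float, float, float, str]] = {
    "p_rec_post_apr": (0.0871, 0.0435, 0.130, "beta"),
    "p_local_given_rec": (0.135, 0.0675, 0.203, "uniform"),
    "p_prog1_met": (0.370, 0.296, 0.444, "beta"),
    "p_prog2_met": (0.811, 0.649, 0.973, "beta"),
    "p_prog3_met": (0.708, 0.566, 0.850, "beta"),
    "p_death_post_regorafenib": (0.405, 0.270, 0.410, "beta"),
    "p_surgical_mortality": (0.005, 0.005, 0.005, "fixed"),
    "u_post_apr": (0.830, 0.650, 1.0, "beta"),
    "u_ciup": (0.935, 0.750, 1.0, "beta"),
    "u_recurrence": (0.748, 0.598, 0.898, "beta"),
    "u_met_pd": (0.712, 0.685, 0.739, "beta"),
    "c_imatinib400": (37040.0, 7408.0, 44448.0, "gamma"),
    "c_sunitinib": (64063.0, 51250.0, 76876.0, "gamma"),
    "c_regorafenib": (72001.0, 57601.0, 86401.0, "gamma"),
    "c_apr": (38000.0, 30400.0, 45600.0, "gamma"),
    "c_salvage": (38000.0, 30400.0, 45600.0, "gamma"),
    "c_followup": (3000.0, 2400.0, 3600.0, "gamma"),
    # Progression risk while on continued imatinib: no published figure is
    # specific to this state, so it defaults to the first-line metastatic
    # progression probability and is exposed as its own dial.  It is held
    # "fixed" here because PSA links it to the sampled p_prog1_met instead
    # of drawing it independently (see gistcea.psa).
    "p_prog_ciup": (0.370, 0.296, 0.444, "fixed"),
    "p_local_given_prog_ciup": (0.135, 0.0675, 0.203, "fixed"),
}

_PROB_OR_UTILITY = tuple(
    n for n in _TABLE if n.startswith("p_") or n.startswith("u_")
)
_COSTS = tuple(n for n in _TABLE if n.startswith("c_"))


def _default_ranges() -> dict[str, tuple[float, float, str]]:
    return {k: (lo, hi, fam) for k, (_, lo, hi, fam) in _TABLE.items()}


@dataclass
class ParameterSet:
    """All inputs for one model run (defaults reproduce the base case)."""

    # -- probabilities (annual unless noted) --
    p_rec_post_apr: float = 0.0871          # recurrence after APR
    p_local_given_rec: float = 0.135        # recurrence is local | recurrence
    p_prog1_met: float = 0.370              # 1st progression, metastatic
    p_prog2_met: float = 0.811              # 2nd progression, metastatic
    p_prog3_met: float = 0.708              # 3rd progression, metastatic
    p_death_post_regorafenib: float = 0.405
    p_surgical_mortality: float = 0.005     # per operation
    p_prog_ciup: float = 0.370              # progression on continued imatinib
    p_local_given_prog_ciup: float = 0.135
    # -- utilities --
    u_post_apr: float = 0.830
    u_ciup: float = 0.935
    u_recurrence: float = 0.748
    u_met_pd: float = 0.712
    # -- costs, 2017 SGD --
    c_imatinib400: float = 37040.0          # annual
    c_sunitinib: float = 64063.0            # annual
    c_regorafenib: float = 72001.0          # annual
    c_apr: float = 38000.0                  # one-time
    c_salvage: float = 38000.0              # one-time
    c_followup: float = 3000.0              # annual surveillance
    # -- model settings --
    discount_rate: float = 0.03
    wtp: float = 50000.0                    # SGD per QALY
    start_age: int = 60
    horizon: int = 20                       # cycles
    cycle_length: float = 1.0               # years; structural, fixed at 1
    adjuvant_years_uapr: int = 2
    adjuvant_years_post_salvage: int = 3
    # The published cost table carries a single imatinib price and no
    # separate escalated-dose row, so the escalated-dose state reuses that
    # price by default; set 2.0 for a dose-proportional scenario.
    imatinib800_multiplier: float = 1.0
    half_cycle_correction: bool = True
    # sensitivity range and PSA family per uncertain parameter
    ranges: dict[str, tuple[float, float, str]] = field(
        default_factory=_default_ranges, repr=False, compare=True
    )

    # -- accessors ----------------------------------------------------------

    def spec(self, name: str) -> DistributionSpec:
        """Distribution specification for ``name`` at its current value."""
        if name not in self.ranges:
            raise KeyError(f"no sensitivity range recorded for {name!r}")
        lo, hi, fam = self.ranges[name]
        return DistributionSpec(name, fam, getattr(self, name), lo, hi)

    def sampled_names(self) -> tuple[str, ...]:
        """Parameters with a non-degenerate PSA distribution."""
        return tuple(n for n, (_, _, fam) in sorted(self.ranges.items())
                     if fam != "fixed")

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy with ``name`` set to ``value``.

        The recorded sensitivity range is widened if necessary so scenario
        values beyond the base range stay internally consistent.
        """
        if not any(f.name == name for f in fields(self)) or name == "ranges":
            raise KeyError(f"unknown parameter {name!r}")
        new = replace(self, ranges=dict(self.ranges))
        setattr(new, name, value)
        if name in new.ranges:
            lo, hi, fam = new.ranges[name]
            new.ranges[name] = (min(lo, value), max(hi, value), fam)
        return new

    def with_values(self, **updates: float) -> "ParameterSet":
        out = self
        for k, v in updates.items():
            out = out.with_value(k, v)
        return out


def validate_parameters(params: ParameterSet) -> list[str]:
    """Return every invariant violation (empty list means valid)."""
    bad: list[str] = []
    for name in _PROB_OR_UTILITY:
        v = getattr(params, name)
        if not 0.0 <= v <= 1.0:
            bad.append(f"{name}={v}: outside [0, 1]")
    for name in _COSTS:
        v = getattr(params, name)
        if v < 0.0:
            bad.append(f"{name}={v}: negative cost")
    if not 0.0 <= params.discount_rate < 1.0:
        bad.append(f"discount_rate={params.discount_rate}: outside [0, 1)")
    if params.wtp < 0.0:
        bad.append(f"wtp={params.wtp}: negative")
    if params.horizon < 1:
        bad.append(f"horizon={params.horizon}: must be >= 1")
    if params.cycle_length <= 0:
        bad.append(f"cycle_length={params.cycle_length}: must be positive")
    if params.start_age < 0:
        bad.append(f"start_age={params.start_age}: negative")
    if params.imatinib800_multiplier < 0:
        bad.append(f"imatinib800_multiplier={params.imatinib800_multiplier}: negative")
    for name, (lo, hi, _fam) in params.ranges.items():
        base = getattr(params, name)
        if not lo <= base <= hi:
            bad.append(f"{name}: range ordering violated (low={lo}, base={base}, high={hi})")
    return bad


def hard_violations(params: ParameterSet) -> list[str]:
    """Violations that make a model run meaningless (domain bounds only).

    Range-ordering problems are excluded: scenario sweeps legitimately
    evaluate values outside the tabulated sensitivity range.
    """
    return [v for v in validate_parameters(params) if "range ordering" not in v]


def derive_secondary(params: ParameterSet) -> dict[str, float]:
    """Quantities derived from the primary parameters.

    The total recurrence (or progression) probability is split into local
    and distant components by the conditional local probability; the split
    conserves probability mass exactly.  The escalated-dose imatinib cost
    is dose-proportional to the 400 mg cost.
    """
    p_local_post_apr = params.p_rec_post_apr * params.p_local_given_rec
    p_local_ciup = params.p_prog_ciup * params.p_local_given_prog_ciup
    return {
        "p_local_post_apr": p_local_post_apr,
        "p_distant_post_apr": params.p_rec_post_apr - p_local_post_apr,
        "p_local_ciup": p_local_ciup,
        "p_distant_ciup": params.p_prog_ciup - p_local_ciup,
        "c_imatinib800": params.imatinib800_multiplier * params.c_imatinib400,
    }


# ---------------------------------------------------------------------------
# Configuration file dialect: flat YAML mapping.  For each uncertain
# parameter there are four keys (value, _low, _high, _dist); settings are
# single keys.  Emitted deterministically so emit/parse/emit is byte-stable.
# ---------------------------------------------------------------------------

_SETTING_KEYS = (
    "discount_rate", "wtp", "start_age", "horizon", "cycle_length",
    "adjuvant_years_uapr", "adjuvant_years_post_salvage",
    "imatinib800_multiplier", "half_cycle_correction",
)

_HEADER = (
    "# gistcea parameter configuration\n"
    "# Annual probabilities/utilities, costs in 2017 SGD, model settings.\n"
    "# For each uncertain parameter: value, <name>_low/_high (deterministic\n"
    "# sensitivity range) and <name>_dist (PSA family).\n"
)


def to_config_text(params: ParameterSet) -> str:
    lines = [_HEADER]
    for name in _TABLE:
        lo, hi, fam = params.ranges.get(name, _TABLE[name][1:])
        if isinstance(lo, str):  # pragma: no cover - defensive
            raise TypeError("malformed range")
        items = {
            name: getattr(params, name),
            f"{name}_low": lo,
            f"{name}_high": hi,
            f"{name}_dist": fam,
        }
        lines.append(yaml.safe_dump(items, sort_keys=False, default_flow_style=False))
    setting_items = {k: getattr(params, k) for k in _SETTING_KEYS}
    lines.append(yaml.safe_dump(setting_items, sort_keys=False, default_flow_style=False))
    return "".join(lines)


def from_config_text(text: str) -> ParameterSet:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("configuration must be a flat key/value mapping")
    params = ParameterSet()
    ranges = dict(params.ranges)
    known_value_keys = set(_TABLE) | set(_SETTING_KEYS)
    for key, raw in data.items():
        if key in known_value_keys:
            default = getattr(params, key)
            if isinstance(default, bool):
                cast = bool
            elif isinstance(default, int):
                cast = int
            else:
                cast = float
            setattr(params, key, cast(raw))
        elif key.endswith("_low") and key[:-4] in _TABLE:
            name = key[:-4]
            lo, hi, fam = ranges[name]
            ranges[name] = (float(raw), hi, fam)
        elif key.endswith("_high") and key[:-5] in _TABLE:
            name = key[:-5]
            lo, hi, fam = ranges[name]
            ranges[name] = (lo, float(raw), fam)
        elif key.endswith("_dist") and key[:-5] in _TABLE:
            name = key[:-5]
            if raw not in _FAMILIES:
                raise ValueError(f"{key}: unknown family {raw!r}")
            lo, hi, fam = ranges[name]
            ranges[name] = (lo, hi, str(raw))
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    params.ranges = ranges
    return params


def load_config(path) -> ParameterSet:
    return from_config_text(Path(path).read_text())


def save_config(params: ParameterSet, path) -> None:
    Path(path).write_text(to_config_text(params))
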