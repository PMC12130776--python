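"""Synthetic pharmacy-claims bundles with known ground truth.

Generates a directory of monthly report files (medications ranked by
frequency and by cost, each truncated to the published top-N; therapeutic
groups untruncated), a scheme-eligibility table and a CPI series — in
exactly the CSV dialect the ingest module reads — together with a
``truth.json`` serialising the noise-free closed-form series every file
was drawn from. This makes every pipeline stage testable without any
download.

The phenomenology mirrors the national open data: multiplicative monthly
trend, cosine seasonality, policy step changes in volume or unit cost,
top-N rank censoring, a slowly drifting eligibility denominator, steady
CPI inflation, and an optional one-off disruption that shifts a fraction
of one month's claims into the next (emulating the May → June 2021
transmission outage).

The closed form for an entity's expected dispensing frequency in month
``t`` months after the start is::

    baseline × trend^t × (1 + amplitude·cos(2π·(calendar_month − peak)/12))
             × ∏ step multipliers active by that month

and expected cost is that frequency times the (step-adjusted) unit cost.
Noise is multiplicative lognormal with unit mean and coefficient of
variation ``noise_cv``, drawn from one RNG stream per entity so adding an
entity never perturbs the others' draws.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .atc import ancestor, parse_atc
from .errors import DataValidationError
from .months import Month, month_range

logger = logging.getLogger(__name__)

TAIL_GROUP_CODE = "V07"  # all-other-products mass lives in its own group


class StepChange(BaseModel):
    """A permanent multiplicative change from a given month onward."""

    model_config = ConfigDict(extra="forbid")

    month: str
    multiplier: float = Field(gt=0)
    applies_to: Literal["frequency", "unit_cost"] = "frequency"

    @field_validator("month")
    @classmethod
    def _valid_month(cls, v: str) -> str:
        return str(Month.parse(v))


class EntityConfig(BaseModel):
    """Ground-truth model of one medication (ATC level 5)."""

    model_config = ConfigDict(extra="forbid")

    atc: str
    name: str = ""
    parent: str = ""
    baseline: float = Field(gt=0)  # dispensings/month at the start month
    monthly_trend: float = Field(default=1.0, gt=0)
    seasonal_amplitude: float = Field(default=0.0, ge=0, lt=1)
    seasonal_peak_month: int = Field(default=1, ge=1, le=12)
    unit_cost: float = Field(gt=0)  # EUR per dispensing
    step_changes: list[StepChange] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_codes(self) -> "EntityConfig":
        code = parse_atc(self.atc)
        if code.level != 5:
            raise ValueError(f"entity {self.atc} must be an ATC level-5 code")
        derived_parent = ancestor(code, 2).code
        if self.parent and self.parent.upper() != derived_parent:
            raise ValueError(
                f"declared parent {self.parent} disagrees with ATC prefix {derived_parent}"
            )
        object.__setattr__(self, "atc", code.code)
        object.__setattr__(self, "parent", derived_parent)
        return self


class EligibilityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline: int = Field(gt=0)  # eligible persons at the start month
    monthly_drift: float = 0.0  # fractional change per month


class CpiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline: float = Field(default=100.0, gt=0)
    monthly_inflation: float = 0.0


class DisruptionConfig(BaseModel):
    """Transmission outage: part of month_a's claims appear in month_b."""

    model_config = ConfigDict(extra="forbid")
    month_a: str
    month_b: str
    carryover_fraction: float = Field(ge=0, le=1)

    @field_validator("month_a", "month_b")
    @classmethod
    def _valid_month(cls, v: str) -> str:
        return str(Month.parse(v))


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start: str
    end: str
    entities: list[EntityConfig]
    tail_total: float = Field(default=0.0, ge=0)  # dispensings/month outside modelled entities
    tail_unit_cost: float = Field(default=10.0, gt=0)
    top_n: int = Field(default=100, ge=1)
    eligibility: EligibilityConfig
    cpi: CpiConfig = CpiConfig()
    disruption: Optional[DisruptionConfig] = None
    noise_cv: float = Field(default=0.0, ge=0)
    seed: int = 0
    scheme: str = "GMS"

    @field_validator("start", "end")
    @classmethod
    def _valid_month(cls, v: str) -> str:
        return str(Month.parse(v))

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if Month.parse(self.start) > Month.parse(self.end):
            raise ValueError("start month after end month")
        codes = [e.atc for e in self.entities]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate entity ATC codes")
        return self

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        import yaml

        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yaml", ".yml"))
            else json.loads(text)
        )
        return cls.model_validate(data)


# ---------------------------------------------------------------------------
# closed-form ground truth


def _steps_factor(entity: EntityConfig, month: Month, applies_to: str) -> float:
    factor = 1.0
    for step in entity.step_changes:
        if step.applies_to == applies_to and Month.parse(step.month) <= month:
            factor *= step.multiplier
    return factor


def expected_frequency(entity: EntityConfig, month: Month | str, start: Month | str) -> float:
    """Noise-free expected dispensings of *entity* in *month* (the oracle)."""
    month, start = Month.parse(month), Month.parse(start)
    if month < start:
        raise DataValidationError(f"month {month} before series start {start}")
    t = month - start
    seasonal = 1.0 + entity.seasonal_amplitude * math.cos(
        2.0 * math.pi * (month.month - entity.seasonal_peak_month) / 12.0
    )
    return (
        entity.baseline
        * entity.monthly_trend**t
        * seasonal
        * _steps_factor(entity, month, "frequency")
    )


def expected_unit_cost(entity: EntityConfig, month: Month | str) -> float:
    """Step-adjusted EUR per dispensing (no trend or seasonality of its own)."""
    return entity.unit_cost * _steps_factor(entity, Month.parse(month), "unit_cost")


def expected_cost(entity: EntityConfig, month: Month | str, start: Month | str) -> float:
    return expected_frequency(entity, month, start) * expected_unit_cost(entity, month)


# ---------------------------------------------------------------------------
# generation


def _entity_rng(seed: int, code: str) -> np.random.Generator:
    # one independent stream per entity, keyed by a stable hash of the code
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(code.encode())])


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


class TruthBundle:
    """The noise-free ground truth written alongside a synthetic bundle."""

    def __init__(self, data: dict):
        self.data = data

    @classmethod
    def load(cls, path: str | Path) -> "TruthBundle":
        return cls(json.loads(Path(path).read_text()))

    @property
    def months(self) -> list[Month]:
        return [Month.parse(m) for m in self.data["months"]]

    @property
    def config(self) -> SyntheticConfig:
        return SyntheticConfig.model_validate(self.data["config"])

    def expected_series(self, code: str, quantity: str) -> dict[Month, float]:
        """Ground-truth series for an entity or group.

        *quantity* is one of ``frequency``, ``ingredient_cost``,
        ``cost_per_prescribing``, ``prescribing_rate``, ``cost_rate``.
        """
        section = "entities" if code in self.data["entities"] else "groups"
        series = self.data[section][code][quantity]
        return {Month.parse(m): v for m, v in series.items()}

    @property
    def eligibility(self) -> dict[Month, int]:
        return {Month.parse(m): v for m, v in self.data["eligibility"].items()}

    @property
    def cpi(self) -> dict[Month, float]:
        return {Month.parse(m): v for m, v in self.data["cpi"].items()}


def _report_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "entity_name",
            "atc_code",
            "frequency",
            "pct_frequency",
            "ingredient_cost",
            "pct_cost",
        ],
    )


def generate(config: SyntheticConfig, out_dir: str | Path) -> TruthBundle:
    """Write a complete synthetic claims bundle and its ground truth.

    Outputs, under *out_dir*: per-month medication reports (frequency- and
    cost-ranked, truncated to ``top_n``), therapeutic-group reports
    (untruncated), ``eligibility.csv``, ``cpi.csv`` and ``truth.json``.
    Identical config + seed gives byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start, end = Month.parse(config.start), Month.parse(config.end)
    months = month_range(start, end)
    n = len(months)

    if config.top_n > len(config.entities):
        logger.warning(
            "top_n=%d exceeds the %d configured entities; no truncation will occur",
            config.top_n,
            len(config.entities),
        )

    # eligibility: drifting total split over two areas; written as integers
    elig_total: dict[Month, int] = {}
    elig_rows = []
    for t, m in enumerate(months):
        level = config.eligibility.baseline * (1.0 + config.eligibility.monthly_drift) ** t
        total = int(round(level))
        east = int(round(0.6 * level))
        elig_rows.append({"month": str(m), "area": "Area East", "count": east})
        elig_rows.append({"month": str(m), "area": "Area West", "count": total - east})
        elig_total[m] = total
    pd.DataFrame(elig_rows).to_csv(out / "eligibility.csv", index=False)

    cpi: dict[Month, float] = {
        m: config.cpi.baseline * (1.0 + config.cpi.monthly_inflation) ** t
        for t, m in enumerate(months)
    }
    pd.DataFrame(
        [{"month": str(m), "cpi": v} for m, v in cpi.items()]
    ).to_csv(out / "cpi.csv", index=False)

    # per-entity observed (noisy) and expected (truth) series
    observed_f: dict[str, np.ndarray] = {}
    observed_c: dict[str, np.ndarray] = {}
    truth_f: dict[str, list[float]] = {}
    truth_uc: dict[str, list[float]] = {}
    for entity in config.entities:
        rng = _entity_rng(config.seed, entity.atc)
        f_noise = _lognormal_factors(rng, config.noise_cv, n)
        c_noise = _lognormal_factors(rng, config.noise_cv, n)
        exp_f = np.array([expected_frequency(entity, m, start) for m in months])
        exp_uc = np.array([expected_unit_cost(entity, m) for m in months])
        obs_f = exp_f * f_noise
        if config.noise_cv > 0:
            obs_f = np.round(obs_f)  # dispensings are counts
        obs_uc = exp_uc * c_noise
        observed_f[entity.atc] = obs_f
        observed_c[entity.atc] = obs_f * obs_uc
        truth_f[entity.atc] = exp_f.tolist()
        truth_uc[entity.atc] = exp_uc.tolist()

    # tail mass outside the modelled entities (deterministic)
    tail_f = np.full(n, float(config.tail_total))
    tail_c = tail_f * config.tail_unit_cost

    # disruption: move a fraction of month_a's volume into month_b
    if config.disruption is not None:
        a = months.index(Month.parse(config.disruption.month_a))
        b = months.index(Month.parse(config.disruption.month_b))
        frac = config.disruption.carryover_fraction
        for arr in list(observed_f.values()) + list(observed_c.values()) + [tail_f, tail_c]:
            moved = frac * arr[a]
            arr[a] -= moved
            arr[b] += moved

    total_f = tail_f + sum(observed_f.values()) if observed_f else tail_f
    total_c = tail_c + sum(observed_c.values()) if observed_c else tail_c

    groups = sorted({e.parent for e in config.entities})
    names = {e.atc: (e.name or e.atc) for e in config.entities}

    def entity_row(code: str, i: int) -> dict:
        return {
            "entity_name": names[code],
            "atc_code": code,
            "frequency": observed_f[code][i],
            "pct_frequency": 100.0 * observed_f[code][i] / total_f[i],
            "ingredient_cost": observed_c[code][i],
            "pct_cost": 100.0 * observed_c[code][i] / total_c[i],
        }

    scheme = config.scheme
    for i, m in enumerate(months):
        by_freq = sorted(observed_f, key=lambda c: (-observed_f[c][i], c))
        by_cost = sorted(observed_c, key=lambda c: (-observed_c[c][i], c))
        _report_frame([entity_row(c, i) for c in by_freq[: config.top_n]]).to_csv(
            out / f"{scheme}_medication_frequency_{m}.csv", index=False
        )
        _report_frame([entity_row(c, i) for c in by_cost[: config.top_n]]).to_csv(
            out / f"{scheme}_medication_cost_{m}.csv", index=False
        )

        group_rows = []
        for g in groups:
            children = [e.atc for e in config.entities if e.parent == g]
            gf = float(sum(observed_f[c][i] for c in children))
            gc = float(sum(observed_c[c][i] for c in children))
            group_rows.append(
                {
                    "entity_name": f"group {g}",
                    "atc_code": g,
                    "frequency": gf,
                    "pct_frequency": 100.0 * gf / total_f[i],
                    "ingredient_cost": gc,
                    "pct_cost": 100.0 * gc / total_c[i],
                }
            )
        if config.tail_total > 0:
            group_rows.append(
                {
                    "entity_name": "all other products",
                    "atc_code": TAIL_GROUP_CODE,
                    "frequency": float(tail_f[i]),
                    "pct_frequency": 100.0 * tail_f[i] / total_f[i],
                    "ingredient_cost": float(tail_c[i]),
                    "pct_cost": 100.0 * tail_c[i] / total_c[i],
                }
            )
        group_rows.sort(key=lambda r: (-r["frequency"], r["atc_code"]))
        _report_frame(group_rows).to_csv(
            out / f"{scheme}_therapeutic_group_frequency_{m}.csv", index=False
        )

    # ground truth: noise-free, disruption-free closed-form series
    def metric_block(freq: list[float], cost: list[float]) -> dict:
        return {
            "frequency": {str(m): freq[i] for i, m in enumerate(months)},
            "ingredient_cost": {str(m): cost[i] for i, m in enumerate(months)},
            "cost_per_prescribing": {
                str(m): (cost[i] / freq[i] if freq[i] > 0 else None)
                for i, m in enumerate(months)
            },
            "prescribing_rate": {
                str(m): 1000.0 * freq[i] / elig_total[m] for i, m in enumerate(months)
            },
            "cost_rate": {
                str(m): 1000.0 * cost[i] / elig_total[m] for i, m in enumerate(months)
            },
        }

    truth: dict = {
        "config": config.model_dump(mode="json"),
        "months": [str(m) for m in months],
        "eligibility": {str(m): elig_total[m] for m in months},
        "cpi": {str(m): cpi[m] for m in months},
        "entities": {},
        "groups": {},
    }
    for entity in config.entities:
        freq = truth_f[entity.atc]
        cost = [f * u for f, u in zip(freq, truth_uc[entity.atc])]
        truth["entities"][entity.atc] = metric_block(freq, cost)
    for g in groups:
        children = [e.atc for e in config.entities if e.parent == g]
        freq = [sum(truth_f[c][i] for c in children) for i in range(n)]
        cost = [
            sum(truth_f[c][i] * truth_uc[c][i] for c in children) for i in range(n)
        ]
        truth["groups"][g] = metric_block(freq, cost)
    if config.tail_total > 0:
        truth["groups"][TAIL_GROUP_CODE] = metric_block(
            [float(config.tail_total)] * n,
            [float(config.tail_total) * config.tail_unit_cost] * n,
        )

    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return TruthBundle(truth)


# ---------------------------------------------------------------------------
# default study conditions


def default_config(seed: int = 0) -> SyntheticConfig:
    """The bundled study-scale scenario: Jan 2016 – Oct 2024, GMS-like scale.

    Entity parameters are loosely calibrated to published national figures:
    ~1.5–1.6 million scheme-eligible persons (slowly declining coverage),
    proton-pump inhibitors with diverging trends, gabapentinoids with sharp
    unit-cost drops when reference pricing started (April/May 2020), a
    lidocaine-plaster-style reimbursement restriction in late 2017, winter
    seasonality for a systemic antibacterial and an inhaled bronchodilator,
    a May → June 2021 transmission disruption, and ~4.8 million dispensings
    per month of unmodelled tail mass so percentage shares stay realistic.
    """
    entities = [
        EntityConfig(
            atc="A02BC01", name="omeprazole", baseline=95000, monthly_trend=0.9985,
            unit_cost=9.0,
        ),
        EntityConfig(
            atc="A02BC02", name="pantoprazole", baseline=51500, monthly_trend=1.0058,
            unit_cost=12.0,
        ),
        EntityConfig(
            atc="A02BC03", name="lansoprazole", baseline=56000, monthly_trend=0.9990,
            unit_cost=11.0,
        ),
        EntityConfig(
            atc="A02BC05", name="esomeprazole", baseline=87000, monthly_trend=1.0060,
            unit_cost=10.0,
        ),
        EntityConfig(
            atc="N03AX12", name="gabapentin", baseline=30000, monthly_trend=1.0010,
            unit_cost=21.98,
            step_changes=[StepChange(month="2020-05", multiplier=0.544, applies_to="unit_cost")],
        ),
        EntityConfig(
            atc="N03AX16", name="pregabalin", baseline=55000, monthly_trend=1.0010,
            unit_cost=32.49,
            step_changes=[StepChange(month="2020-04", multiplier=0.312, applies_to="unit_cost")],
        ),
        EntityConfig(
            atc="N01BB02", name="lidocaine", baseline=24500, monthly_trend=1.0,
            unit_cost=60.0,
            step_changes=[
                StepChange(month="2017-09", multiplier=0.62, applies_to="frequency"),
                StepChange(month="2017-12", multiplier=0.55, applies_to="frequency"),
            ],
        ),
        EntityConfig(
            atc="J01CA04", name="amoxicillin", baseline=70000, monthly_trend=1.0,
            seasonal_amplitude=0.35, seasonal_peak_month=12, unit_cost=8.0,
        ),
        EntityConfig(
            atc="R03AC02", name="salbutamol", baseline=60000, monthly_trend=1.0,
            seasonal_amplitude=0.25, seasonal_peak_month=1, unit_cost=6.0,
        ),
    ]
    return SyntheticConfig(
        start="2016-01",
        end="2024-10",
        entities=entities,
        tail_total=4_800_000,
        tail_unit_cost=10.0,
        top_n=100,
        eligibility=EligibilityConfig(baseline=1_570_000, monthly_drift=-0.0002),
        cpi=CpiConfig(baseline=98.0, monthly_inflation=0.0018),
        disruption=DisruptionConfig(
            month_a="2021-05", month_b="2021-06", carryover_fraction=0.8
        ),
        noise_cv=0.05,
        seed=seed,
    )
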