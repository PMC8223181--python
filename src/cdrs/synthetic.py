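"""Synthetic cohorts with planted quality structure.

The generator emulates the kind of cohort the scoring framework was built
for: a few dozen administrative regions with strongly dispersed reporting
quality (overall scores spanning roughly 0 to 0.6, median near 0.26),
occasional privacy violations among the regions that report data, and a
small fraction of regions for which district stratification does not apply.

Each state draws a quality *tier*; within a tier every applicable
non-privacy cell independently attains its domain maximum with the tier's
reporting probability (the three-valued death-comorbidity cell draws 2
with that probability, else 1 with the same probability again, else 0).
The privacy cell is -1 with ``privacy_violation_rate`` among data-reporting
states and +1 otherwise; non-reporting states leave it NA.  An optional
dashboard flag couples all trend-graphic cells into one all-or-nothing
draw, mimicking dashboards that ship every trend plot at once.

A companion generator plants a development-index variable with a chosen
population correlation against any vector of true scores, for recovery
testing of the correlation stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .framework import FrameworkSpec, IndicatorId, enumerate_indicators
from .io import CohortTable, IndexRecord, ScoreSheet, StateMeta

#: Tier reporting probabilities emulating the observed dispersion:
#: a couple of silent states, a weak majority, and a good-but-imperfect top.
DEFAULT_TIER_PROBS: Mapping[str, float] = {
    "none": 0.0,
    "low": 0.12,
    "mid": 0.30,
    "high": 0.55,
}
DEFAULT_TIER_WEIGHTS: Mapping[str, float] = {
    "none": 0.07,
    "low": 0.28,
    "mid": 0.40,
    "high": 0.25,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate a 29-state cohort."""

    n_states: int = 29
    tier_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TIER_PROBS))
    tier_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TIER_WEIGHTS))
    privacy_violation_rate: float = 0.07
    no_districts_rate: float = 0.07
    dashboard_coupling: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if set(self.tier_probs) != set(self.tier_weights):
            raise ValueError("tier_probs and tier_weights must share tier labels")
        for p in (*self.tier_probs.values(), self.privacy_violation_rate, self.no_districts_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.tier_weights.values()) - 1.0) > 1e-9:
            raise ValueError("tier_weights must sum to 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for a generated cohort: one record per state."""

    tiers: Mapping[str, str]                # state -> tier label
    tier_probs: Mapping[str, float]         # tier label -> reporting probability
    privacy_violation: Mapping[str, bool]
    has_districts: Mapping[str, bool]
    seed: int

    def tier_prob(self, state_id: str) -> float:
        return self.tier_probs[self.tiers[state_id]]


def config_from_yaml(path) -> SyntheticConfig:
    with open(path, "r", encoding="utf-8") as fh:
        tree = yaml.safe_load(fh) or {}
    cfg = SyntheticConfig(**tree)
    cfg.validate()
    return cfg


def config_to_yaml(config: SyntheticConfig, path) -> None:
    tree = {
        "n_states": config.n_states,
        "tier_probs": dict(config.tier_probs),
        "tier_weights": dict(config.tier_weights),
        "privacy_violation_rate": config.privacy_violation_rate,
        "no_districts_rate": config.no_districts_rate,
        "dashboard_coupling": config.dashboard_coupling,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(tree, fh, sort_keys=False)


def _draw_cell(domain_values: list[int], p: float, rng: np.random.Generator) -> int:
    # walk positive values from the top; each step succeeds with probability p
    for v in sorted((v for v in domain_values if v > 0), reverse=True):
        if rng.random() < p:
            return v
    return 0


def generate_cohort(
    spec: FrameworkSpec, config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[CohortTable, PlantedTruth]:
    """Generate a cohort and its planted truth, fully reproducible from the seed."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)

    tier_labels = list(config.tier_probs)
    weights = np.array([config.tier_weights[t] for t in tier_labels], dtype=float)
    weights = weights / weights.sum()

    indicators = enumerate_indicators(spec)
    privacy_cells = [i for i in indicators if i.category == "privacy"]
    trend_cells = {i for i in indicators if i.metric.startswith("trend_")}

    sheets: list[ScoreSheet] = []
    meta: dict[str, StateMeta] = {}
    tiers: dict[str, str] = {}
    violations: dict[str, bool] = {}
    districts: dict[str, bool] = {}

    width = max(2, len(str(config.n_states)))
    for i in range(config.n_states):
        state = f"state{i:0{width}d}"
        tier = tier_labels[int(rng.choice(len(tier_labels), p=weights))]
        p = config.tier_probs[tier]
        has_districts = bool(rng.random() >= config.no_districts_rate)
        dashboard_on = rng.random() < p  # used only when trend cells are coupled

        values: dict[IndicatorId, int | None] = {}
        for ind in indicators:
            if ind in privacy_cells:
                continue
            if ind.metric == "districts" and not has_districts:
                values[ind] = None
                continue
            domain_values = sorted(spec.domain(ind).allowed_values)
            if config.dashboard_coupling and ind in trend_cells:
                values[ind] = domain_values[-1] if dashboard_on else 0
            else:
                values[ind] = _draw_cell(domain_values, p, rng)

        reports_data = any(v is not None and v >= 1 for v in values.values())
        violated = False
        for ind in privacy_cells:
            if reports_data:
                violated = rng.random() < config.privacy_violation_rate
                values[ind] = -1 if violated else 1
            else:
                values[ind] = None

        # confirmed caseload: heavy-tailed, all above a typical inclusion cutoff
        confirmed = 10 + int(rng.lognormal(mean=7.0, sigma=1.5))
        sheets.append(ScoreSheet(state_id=state, values=values))
        meta[state] = StateMeta(state, has_districts=has_districts, confirmed_at_cutoff=confirmed)
        tiers[state] = tier
        violations[state] = violated
        districts[state] = has_districts

    cohort = CohortTable(sheets=tuple(sheets), meta=meta)
    truth = PlantedTruth(
        tiers=tiers,
        tier_probs=dict(config.tier_probs),
        privacy_violation=violations,
        has_districts=districts,
        seed=config.seed,
    )
    return cohort, truth


def generate_index(
    truth_scores: Sequence[float],
    target_r: float,
    noise_sd: float | None = None,
    seed: int = 0,
    state_ids: Sequence[str] | None = None,
) -> list[IndexRecord]:
    """An index variable with planted population correlation against the scores.

    The index is an affine image of ``score + noise`` rescaled to mean 55,
    s.d. 12 on the 0-100 scale and clipped.  When ``noise_sd`` is omitted
    it is calibrated analytically from the score dispersion:
    ``noise_sd = sd_score * sqrt(1/r^2 - 1)``, which makes the population
    correlation equal ``target_r`` (affine maps with positive slope leave
    Pearson's r unchanged; clipping at 3.75 s.d. is negligible).
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("target_r must lie in [-1, 1]")
    scores = np.asarray(truth_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("truth_scores is empty")
    sd_score = float(np.std(scores))
    if sd_score == 0.0:
        raise ValueError("truth_scores have zero variance; correlation undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(scores.size)
    if target_r == 0.0:
        raw = noise
    else:
        if noise_sd is None:
            noise_sd = sd_score * math.sqrt(1.0 / target_r**2 - 1.0)
        raw = math.copysign(1.0, target_r) * scores + noise_sd * noise
    sd_raw = float(np.std(raw))
    if sd_raw == 0.0:
        standardized = np.zeros_like(raw)
    else:
        standardized = (raw - raw.mean()) / sd_raw
    index = np.clip(55.0 + 12.0 * standardized, 0.0, 100.0)
    if state_ids is None:
        width = max(2, len(str(scores.size)))
        state_ids = [f"state{i:0{width}d}" for i in range(scores.size)]
    return [IndexRecord(state_id=s, index_value=float(v)) for s, v in zip(state_ids, index)]
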