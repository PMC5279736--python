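"""Climate scenarios and the grid x taxon x scenario prediction cube.

A scenario is an additive water-temperature delta plus a multiplicative flow
factor ("-10% flow" means discharge x 0.9).  Predictor columns are tagged
``thermal`` / ``hydrological`` / ``static`` so perturbation is mechanical.
The runner predicts capture probabilities for every grid cell under every
scenario, derives richness and EQR against the cell's own baseline richness,
and applies the retention rule: a cell flagged outside the model's
environmental range in *any* scenario is dropped from all downstream
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction import DEFAULT_WFD_BANDS, WFDBands, expected_richness, probability_of_capture
from .reference_model import PredictiveModel
from .synthetic import PREDICTOR_TAGS

log = logging.getLogger(__name__)

__all__ = ["Scenario", "DEFAULT_SCENARIOS", "apply_scenario", "PredictionCube", "run_scenarios"]


@dataclass(frozen=True)
class Scenario:
    """A warming/drying perturbation of the riverscape environment."""

    label: str
    delta_t: float  # deg C, additive on thermal predictors
    flow_factor: float  # multiplier in (0, 1] on hydrological predictors

    def __post_init__(self) -> None:
        if self.flow_factor <= 0:
            raise ValueError("flow_factor must be positive")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    @property
    def is_baseline(self) -> bool:
        return self.delta_t == 0.0 and self.flow_factor == 1.0


#: Baseline plus the three projected warming/flow-reduction scenarios.
DEFAULT_SCENARIOS: list[Scenario] = [
    Scenario("S0", 0.0, 1.0),
    Scenario("S1", 1.70, 0.90),
    Scenario("S2", 2.45, 0.80),
    Scenario("S3", 3.30, 0.70),
]


def apply_scenario(
    env: pd.DataFrame,
    scenario: Scenario,
    tags: dict[str, str] | None = None,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Return a perturbed copy of an environment table.

    Thermal-tagged columns get ``+ delta_t``; hydrological-tagged columns get
    ``x flow_factor``; static columns pass through.  Numeric columns used as
    predictors must be tagged, otherwise a configuration error is raised.
    The input table is never modified.
    """
    tags = PREDICTOR_TAGS if tags is None else tags
    out = env.copy()
    check = predictors if predictors is not None else [
        c for c in env.columns if pd.api.types.is_numeric_dtype(env[c])
    ]
    untagged = [c for c in check if c not in tags]
    if untagged:
        raise KeyError(f"untagged predictors (tag as thermal/hydrological/static): {untagged}")
    for col in check:
        if tags[col] == "thermal":
            out[col] = out[col] + scenario.delta_t
        elif tags[col] == "hydrological":
            out[col] = out[col] * scenario.flow_factor
        elif tags[col] != "static":
            raise KeyError(f"unknown tag {tags[col]!r} for predictor {col!r}")
    return out


@dataclass
class PredictionCube:
    """Capture probabilities and per-grid summaries over all scenarios."""

    grid_ids: pd.Index
    taxa: list[str]
    scenario_labels: list[str]
    p: np.ndarray  # (grids, taxa, scenarios)
    richness: np.ndarray  # (grids, scenarios)
    eqr: np.ndarray  # (grids, scenarios); nan where baseline richness is 0
    status: np.ndarray  # (grids, scenarios), object
    retained: np.ndarray  # (grids,), bool
    grids: pd.DataFrame = field(repr=False, default=None)  # env/metadata per grid
    threshold: float = 0.5

    def scenario_index(self, label: str) -> int:
        return self.scenario_labels.index(label)

    def taxon_index(self, taxon: str) -> int:
        if taxon not in self.taxa:
            raise KeyError(f"unknown taxon: {taxon}")
        return self.taxa.index(taxon)

    def retained_ids(self) -> pd.Index:
        return self.grid_ids[self.retained]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (grid_id, scenario, taxon, probability) table."""
        g, t, s = self.p.shape
        return pd.DataFrame(
            {
                "grid_id": np.repeat(self.grid_ids.to_numpy(), t * s),
                "scenario": np.tile(np.repeat(self.scenario_labels, 1), g * t),
                "taxon": np.tile(np.repeat(self.taxa, s), g),
                "probability": self.p.reshape(-1),
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        """Wide per-grid summary: retention, per-scenario richness/EQR/status."""
        out = pd.DataFrame(index=self.grid_ids)
        out["retained"] = self.retained
        if self.grids is not None:
            for col in ("altitude", "basin"):
                if col in self.grids.columns:
                    out[col] = self.grids[col]
        for j, lab in enumerate(self.scenario_labels):
            out[f"richness_{lab}"] = self.richness[:, j]
            out[f"eqr_{lab}"] = self.eqr[:, j]
            out[f"status_{lab}"] = self.status[:, j]
        return out


def run_scenarios(
    grids: pd.DataFrame,
    pm: PredictiveModel,
    scenarios: list[Scenario] | None = None,
    threshold: float = 0.5,
    tags: dict[str, str] | None = None,
    bands: WFDBands = DEFAULT_WFD_BANDS,
    membership_mode: str = "best",
    richness_mode: str = "count",
) -> PredictionCube:
    """Predict the whole cube and apply the grid-retention rule.

    For each scenario the grid environments are perturbed, the m-model vote
    tests each cell against the model's environmental range, and capture
    probabilities follow from the top-ranked discriminant model's membership
    (``membership_mode="best"``) or the average over all ranked models
    (``"average"``).  EQR compares each cell's scenario richness with its own
    baseline (scenario-0) richness, so baseline EQR is exactly 1 wherever
    baseline richness is positive.  Cells out of range in at least one
    scenario are marked not retained.
    """
    scenarios = DEFAULT_SCENARIOS if scenarios is None else scenarios
    if not scenarios or not scenarios[0].is_baseline:
        raise ValueError("the scenario list must start with the baseline scenario")

    predictors = sorted({p for m in pm.models for p in m.predictor_subset})
    n_g, n_t, n_s = len(grids), len(pm.taxa), len(scenarios)
    p = np.empty((n_g, n_t, n_s))
    richness = np.empty((n_g, n_s))
    out_any = np.zeros(n_g, dtype=bool)

    for j, sc in enumerate(scenarios):
        env = apply_scenario(grids, sc, tags=tags, predictors=predictors)
        out_any |= pm.out_of_range(env)
        if membership_mode == "best":
            membership = pm.models[0].posterior(env)
        elif membership_mode == "average":
            membership = np.mean([m.posterior(env) for m in pm.models], axis=0)
        else:
            raise ValueError("membership_mode must be 'best' or 'average'")
        p[:, :, j] = probability_of_capture(membership, pm.frequencies)
        richness[:, j] = expected_richness(p[:, :, j], threshold, mode=richness_mode)

    with np.errstate(divide="ignore", invalid="ignore"):
        eqr = np.where(richness[:, :1] > 0, richness / richness[:, :1], np.nan)
    status = np.empty((n_g, n_s), dtype=object)
    for i in range(n_g):
        for j in range(n_s):
            status[i, j] = bands.classify(eqr[i, j])

    retained = ~out_any
    if not retained.any():
        raise RuntimeError("no grid cell is inside the model's environmental range")
    log.info(
        "scenario run: %d grids total, %d retained (%.1f%%), %d excluded by the range rule",
        n_g, retained.sum(), 100.0 * retained.sum() / n_g, out_any.sum(),
    )
    return PredictionCube(
        grid_ids=grids.index,
        taxa=pm.taxa,
        scenario_labels=[s.label for s in scenarios],
        p=p,
        richness=richness,
        eqr=eqr,
        status=status,
        retained=retained,
        grids=grids,
        threshold=threshold,
    )
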