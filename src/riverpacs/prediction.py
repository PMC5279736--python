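"""From environment to capture probabilities, richness, indices and status.

The probability of capturing a taxon at a site is the group-membership-
weighted average of the taxon's reference-group frequencies, the standard
RIVPACS/AUSRIVAS construction.  Expected richness counts taxa whose capture
probability meets a presence threshold (0.5 by default, i.e. ">= 50%").
EQR (Ecological Quality Ratio) is observed/expected richness, banded into
the five Water Framework Directive status classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference_model import DiscriminantModel

__all__ = [
    "ScoreTable",
    "WFDBands",
    "DEFAULT_WFD_BANDS",
    "group_membership",
    "probability_of_capture",
    "expected_richness",
    "biotic_indices",
    "compute_eqr",
    "classify_wfd_status",
]


def group_membership(env: pd.DataFrame, model: DiscriminantModel) -> np.ndarray:
    """LDA posterior membership probabilities (rows sum to 1)."""
    return model.posterior(env)


def probability_of_capture(membership: np.ndarray, freq: pd.DataFrame) -> np.ndarray:
    """Capture probability per taxon: membership-weighted group frequencies.

    ``p[t] = sum_g membership[g] * f[g, t]``; each value is therefore bounded
    by that taxon's extreme group frequencies.  ``membership`` may be a
    single vector or an (n, k) matrix; the result has matching shape with a
    taxon axis appended.
    """
    m = np.atleast_2d(np.asarray(membership, dtype=float))
    f = freq.to_numpy(dtype=float)
    if m.shape[1] != f.shape[0]:
        raise ValueError(
            f"membership has {m.shape[1]} groups but frequency table has {f.shape[0]}"
        )
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("membership rows must sum to 1")
    p = m @ f
    return p[0] if np.ndim(membership) == 1 else p


def expected_richness(capture_probs: np.ndarray, threshold: float = 0.5, mode: str = "count"):
    """Expected taxon richness from capture probabilities.

    ``count`` mode (default) counts taxa with p >= threshold (inclusive,
    matching the ">= 50%" presence rule); ``sum`` mode returns the classic
    RIVPACS sum of probabilities over taxa at/above the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    p = np.asarray(capture_probs, dtype=float)
    present = p >= threshold
    if mode == "count":
        return int(present.sum()) if p.ndim == 1 else present.sum(axis=-1)
    if mode == "sum":
        return float((p * present).sum()) if p.ndim == 1 else (p * present).sum(axis=-1)
    raise ValueError("mode must be 'count' or 'sum'")


class ScoreTable:
    """Per-taxon IBMWP sensitivity scores (integers 1-10)."""

    def __init__(self, scores: dict[str, int] | pd.Series):
        s = pd.Series(scores, dtype=int)
        if ((s < 1) | (s > 10)).any():
            bad = s[(s < 1) | (s > 10)].index.tolist()
            raise ValueError(f"IBMWP scores must lie in [1, 10]: {bad}")
        self.scores = s

    def __getitem__(self, taxon: str) -> int:
        return int(self.scores[taxon])

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.scores.index


def biotic_indices(present_taxa: set[str], scores: ScoreTable) -> tuple[int, float]:
    """IBMWP and IASPT biotic indices for a set of present taxa.

    IBMWP is the sum of per-family sensitivity scores; IASPT is IBMWP
    divided by the number of scored taxa (average score per taxon).  An empty
    community yields ``(0, nan)``.
    """
    if not present_taxa:
        return 0, math.nan
    unscored = [t for t in present_taxa if t not in scores]
    if unscored:
        raise KeyError(f"taxa without IBMWP score: {sorted(unscored)}")
    ibmwp = sum(scores[t] for t in present_taxa)
    return ibmwp, ibmwp / len(present_taxa)


def compute_eqr(observed_metric: float, expected_metric: float) -> float:
    """Ecological Quality Ratio = observed / expected; nan if expected <= 0."""
    if expected_metric <= 0:
        return math.nan
    return observed_metric / expected_metric


@dataclass(frozen=True)
class WFDBands:
    """Ordered WFD status classes with inclusive lower EQR bounds."""

    bands: tuple[tuple[str, float], ...] = (
        ("High", 0.85),
        ("Good", 0.70),
        ("Moderate", 0.50),
        ("Poor", 0.25),
        ("Bad", 0.0),
    )

    def __post_init__(self) -> None:
        bounds = [b for _, b in self.bands]
        if any(a <= b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("band lower bounds must be strictly decreasing")
        if bounds[0] > 1.0:
            raise ValueError("the top band must contain EQR = 1")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.bands]

    def classify(self, eqr: float) -> str:
        if math.isnan(eqr):
            return "undefined"
        if eqr < 0:
            raise ValueError("EQR must be >= 0")
        for label, lower in self.bands:
            if eqr >= lower:
                return label
        return self.bands[-1][0]


DEFAULT_WFD_BANDS = WFDBands()


def classify_wfd_status(eqr: float, bands: WFDBands = DEFAULT_WFD_BANDS) -> str:
    """WFD status of an EQR value: highest band whose lower bound <= eqr."""
    return bands.classify(eqr)
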