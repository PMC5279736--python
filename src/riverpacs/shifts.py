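"""Per-taxon range-shift statistics and community summaries.

Given the prediction cube (or a transcribed occupied-grid table), this
module computes each taxon's area of presence per scenario, percent changes
against the baseline, area-of-presence category, mean occupied altitude and
its shift, and a response-strategy class (reduce/expand x upstream/
downstream, stable, lost, mixed), plus community-level richness summaries
and the scenario x basin richness ANOVA.

All printed-style percentages are rounded half-away-from-zero at 2 decimals;
integer-count inputs use exact decimal arithmetic so rounding never depends
on binary-float representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scenarios import PredictionCube

__all__ = [
    "round2",
    "area_of_presence",
    "ap_category",
    "percent_change",
    "mean_altitude",
    "TaxonShiftSummary",
    "classify_strategy",
    "build_taxon_summaries",
    "summaries_from_tables",
    "strategy_counts",
    "summarize_community",
    "richness_anova",
    "tabulate_shift_report",
]


def round2(x):
    """Round to 2 decimals, ties away from zero (as in printed percentages).

    Exact ``Fraction`` inputs are rounded with decimal arithmetic; floats use
    the copysign/floor formulation.  NaN propagates.
    """
    if isinstance(x, Fraction):
        return float(
            (Decimal(x.numerator) / Decimal(x.denominator)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
    arr = np.asarray(x, dtype=float)
    out = np.where(
        np.isnan(arr), np.nan, np.copysign(np.floor(np.abs(arr) * 100.0 + 0.5), arr) / 100.0
    )
    return float(out) if np.ndim(x) == 0 else out


def _percent(count: int, total: int) -> float:
    return round2(Fraction(100 * count, total))


def area_of_presence(
    cube: PredictionCube, taxon: str, scenario: str, threshold: float | None = None
) -> tuple[int, float]:
    """Occupied-grid count and percentage for one taxon and scenario.

    A retained grid is occupied when the taxon's capture probability meets
    the presence threshold; the percentage is over all retained grids,
    rounded to 2 decimals.
    """
    th = cube.threshold if threshold is None else threshold
    ti, si = cube.taxon_index(taxon), cube.scenario_index(scenario)
    occ = (cube.p[:, ti, si] >= th) & cube.retained
    n_ret = int(cube.retained.sum())
    count = int(occ.sum())
    return count, _percent(count, n_ret)


def ap_category(percent_s0: float) -> int:
    """Area-of-presence category from the baseline percentage.

    1: >=75%; 2: <75 and >=50%; 3: <50 and >=25%; 4: <25% of grids occupied.
    """
    if not 0.0 <= percent_s0 <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    if percent_s0 >= 75.0:
        return 1
    if percent_s0 >= 50.0:
        return 2
    if percent_s0 >= 25.0:
        return 3
    return 4


def percent_change(count_k: int, count_0: int) -> float:
    """Percent change in occupied grids vs the baseline, 2-decimal rounded.

    Returns nan when the taxon occupies no baseline grid (undefined change;
    such taxa are excluded from change classification).
    """
    if count_0 < 0 or count_k < 0:
        raise ValueError("counts must be >= 0")
    if count_0 == 0:
        return math.nan
    return round2(Fraction(100 * (count_k - count_0), count_0))


def mean_altitude(
    cube: PredictionCube, taxon: str, scenario: str, threshold: float | None = None
) -> float:
    """Unweighted mean altitude of the retained grids a taxon occupies.

    NaN when the taxon occupies no retained grid in that scenario.
    """
    th = cube.threshold if threshold is None else threshold
    ti, si = cube.taxon_index(taxon), cube.scenario_index(scenario)
    occ = (cube.p[:, ti, si] >= th) & cube.retained
    if not occ.any():
        return math.nan
    return float(cube.grids["altitude"].to_numpy()[occ].mean())


@dataclass
class TaxonShiftSummary:
    """Everything the shift report states about one taxon."""

    taxon: str
    grids: list[int]  # occupied-grid count per scenario (S0 first)
    pct: list[float]  # percent of retained grids, 2 dp
    dif_pct: list[float]  # percent change vs S0 for S1.., 2 dp (nan if undefined)
    ap_cat: int
    mean_alt: list[float]  # m, per scenario (nan if unoccupied)
    alt_shift: list[float]  # m vs S0 for S1.. (nan if undefined)
    area_class: str = ""  # stable | reduce | expand | lost | mixed | undefined
    direction: str = ""  # up | down | unchanged | mixed | undefined
    strategy: str = ""


def _sign_set(values: list[float]) -> set[int] | None:
    """Distinct nonzero signs among defined values; None if none defined."""
    signs, any_defined = set(), False
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        any_defined = True
        if v > 0:
            signs.add(1)
        elif v < 0:
            signs.add(-1)
    return signs if any_defined else None


def classify_strategy(summary: TaxonShiftSummary) -> str:
    """Assign the taxon's response strategy; fills area_class and direction.

    ``lost``: occupied at baseline but unoccupied in the final scenario
    (direction left undefined).  ``stable``: all rounded percent changes are
    0.00 and all altitude shifts are 0.  Otherwise the area component is the
    uniform sign of the percent changes (reduce/expand) and the direction is
    the uniform sign of the altitude shifts (up/down); any sign disagreement
    across scenarios yields ``mixed``.
    """
    s = summary
    if s.grids[0] == 0:
        s.area_class, s.direction, s.strategy = "undefined", "undefined", "undefined"
        return s.strategy
    if s.grids[-1] == 0:
        s.area_class, s.direction, s.strategy = "lost", "undefined", "lost"
        return s.strategy

    area_signs = _sign_set(s.dif_pct)
    alt_signs = _sign_set(s.alt_shift)
    if area_signs is not None and not area_signs:
        s.area_class = "stable"
    elif area_signs == {-1}:
        s.area_class = "reduce"
    elif area_signs == {1}:
        s.area_class = "expand"
    else:
        s.area_class = "mixed"
    if alt_signs is None:
        s.direction = "undefined"
    elif not alt_signs:
        s.direction = "unchanged"
    elif alt_signs == {1}:
        s.direction = "up"
    elif alt_signs == {-1}:
        s.direction = "down"
    else:
        s.direction = "mixed"

    if s.area_class == "stable" and s.direction in ("unchanged", "undefined"):
        s.strategy = "stable"
    elif s.area_class == "reduce" and s.direction == "up":
        s.strategy = "reduce_up"
    elif s.area_class == "reduce" and s.direction == "down":
        s.strategy = "reduce_down"
    elif s.area_class == "expand" and s.direction == "up":
        s.strategy = "expand_up"
    elif s.area_class == "expand" and s.direction == "down":
        s.strategy = "expand_down"
    else:
        s.strategy = "mixed"
    return s.strategy


def _summaries_from_counts(
    taxa: list[str],
    counts: np.ndarray,  # (taxa, scenarios) ints
    n_retained: int,
    mean_alts: np.ndarray,  # (taxa, scenarios) floats, nan allowed
) -> list[TaxonShiftSummary]:
    out = []
    for i, taxon in enumerate(taxa):
        c = [int(v) for v in counts[i]]
        pct = [_percent(v, n_retained) for v in c]
        dif = [percent_change(ck, c[0]) for ck in c[1:]]
        alts = [float(v) for v in mean_alts[i]]
        shifts = [
            a - alts[0] if not (math.isnan(a) or math.isnan(alts[0])) else math.nan
            for a in alts[1:]
        ]
        s = TaxonShiftSummary(
            taxon=taxon,
            grids=c,
            pct=pct,
            dif_pct=dif,
            ap_cat=ap_category(pct[0]),
            mean_alt=alts,
            alt_shift=shifts,
        )
        classify_strategy(s)
        out.append(s)
    return out


def build_taxon_summaries(cube: PredictionCube, threshold: float | None = None) -> list[TaxonShiftSummary]:
    """Per-taxon shift summaries computed from a prediction cube."""
    th = cube.threshold if threshold is None else threshold
    n_ret = int(cube.retained.sum())
    occ = (cube.p >= th) & cube.retained[:, None, None]  # (g, t, s)
    counts = occ.sum(axis=0).astype(int)  # (t, s)
    alt = cube.grids["altitude"].to_numpy()[:, None, None]
    with np.errstate(invalid="ignore"):
        alt_sums = (occ * alt).sum(axis=0)
        mean_alts = np.where(counts > 0, alt_sums / np.maximum(counts, 1), np.nan)
    return _summaries_from_counts(cube.taxa, counts, n_ret, mean_alts)


def summaries_from_tables(
    counts: pd.DataFrame,
    n_retained: int,
    alt_s0: pd.Series | None = None,
    alt_shifts: pd.DataFrame | None = None,
) -> list[TaxonShiftSummary]:
    """Shift summaries from an occupied-grid count table.

    ``counts`` is taxa x scenarios (baseline first).  Mean altitudes per
    scenario are reconstructed from a baseline mean-altitude column plus a
    taxa x (scenarios-1) table of altitude shifts when given; either may be
    omitted (altitude fields then stay undefined).
    """
    n_scen = counts.shape[1]
    taxa = list(counts.index)
    mean_alts = np.full((len(taxa), n_scen), np.nan)
    if alt_s0 is not None:
        mean_alts[:, 0] = alt_s0.reindex(counts.index).to_numpy(dtype=float)
        if alt_shifts is not None:
            shifts = alt_shifts.reindex(counts.index).to_numpy(dtype=float)
            mean_alts[:, 1:] = mean_alts[:, :1] + shifts
    return _summaries_from_counts(taxa, counts.to_numpy(dtype=int), n_retained, mean_alts)


def strategy_counts(summaries: list[TaxonShiftSummary]) -> dict[str, int]:
    """Aggregate the classification the way the shift report states it."""
    n = len(summaries)
    by = lambda pred: sum(1 for s in summaries if pred(s))  # noqa: E731
    counts = {
        "n_taxa": n,
        "reducing": by(lambda s: s.area_class == "reduce"),
        "enlarging": by(lambda s: s.area_class == "expand"),
        "stable": by(lambda s: s.area_class == "stable"),
        "lost": by(lambda s: s.area_class == "lost"),
        "upstream": by(lambda s: s.direction == "up"),
        "downstream": by(lambda s: s.direction == "down"),
        "mixed_direction": by(lambda s: s.direction == "mixed"),
        "reducing_and_upstream": by(lambda s: s.area_class == "reduce" and s.direction == "up"),
        "reducing_and_downstream": by(lambda s: s.area_class == "reduce" and s.direction == "down"),
        "enlarging_and_upstream": by(lambda s: s.area_class == "expand" and s.direction == "up"),
        "enlarging_and_downstream": by(lambda s: s.area_class == "expand" and s.direction == "down"),
        "gain_over_20pct": by(
            lambda s: s.area_class == "expand"
            and s.dif_pct
            and not math.isnan(s.dif_pct[-1])
            and s.dif_pct[-1] > 20.0
        ),
    }
    return counts


def summarize_community(cube: PredictionCube) -> pd.DataFrame:
    """Mean retained-grid richness with 95% CI, overall and per basin.

    Normal-approximation interval (mean +/- 1.96 SE).  Basins with no
    retained grid are omitted.
    """
    rows = []
    ret = cube.retained
    basins = cube.grids["basin"].to_numpy()
    scopes = [("all", ret)] + [
        (b, ret & (basins == b)) for b in pd.unique(basins)
    ]
    for name, mask in scopes:
        n = int(mask.sum())
        if n == 0:
            continue
        for j, lab in enumerate(cube.scenario_labels):
            vals = cube.richness[mask, j]
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {
                    "basin": name,
                    "scenario": lab,
                    "n_grids": n,
                    "mean_richness": mean,
                    "ci_low": mean - 1.96 * se,
                    "ci_high": mean + 1.96 * se,
                }
            )
    return pd.DataFrame(rows)


def richness_anova(long_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of richness on scenario x basin.

    ``long_table`` needs columns ``richness``, ``scenario`` (exactly two
    levels: the baseline-vs-scenario contrast) and ``basin``.  Type III sums
    of squares with sum-to-zero contrasts.  Returns a table with terms
    scenario, basin, interaction and residual (sum_sq, df, F, p).
    """
    for col in ("richness", "scenario", "basin"):
        if col not in long_table.columns:
            raise KeyError(f"missing column: {col}")
    if long_table["scenario"].nunique() != 2:
        raise ValueError("the contrast needs exactly two scenario levels")
    crossing = pd.crosstab(long_table["basin"], long_table["scenario"])
    if (crossing == 0).any().any():
        raise ValueError("every basin must appear in both scenario levels")
    model = smf.ols(
        "richness ~ C(scenario, Sum) * C(basin, Sum)", data=long_table
    ).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    tab = tab.rename(
        index={
            "C(scenario, Sum)": "scenario",
            "C(basin, Sum)": "basin",
            "C(scenario, Sum):C(basin, Sum)": "interaction",
            "Residual": "residual",
        }
    )
    return tab.loc[["scenario", "basin", "interaction", "residual"], ["sum_sq", "df", "F", "PR(>F)"]]


def tabulate_shift_report(
    summaries: list[TaxonShiftSummary],
    scores: pd.Series | None = None,
    scenario_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Assemble the two per-taxon report tables plus the aggregate counts.

    The first table mirrors the area-of-presence accounting (counts and
    percentages per scenario); the second the shift table (percent changes,
    baseline mean altitude, altitude shifts, AP category, optional biotic
    score, strategy).  The third element is :func:`strategy_counts`.
    """
    n_scen = len(summaries[0].grids) if summaries else 0
    labs = scenario_labels or [f"S{i}" for i in range(n_scen)]
    t2 = pd.DataFrame(
        {
            "taxon": [s.taxon for s in summaries],
            **{f"grids_{lab.lower()}": [s.grids[j] for s in summaries] for j, lab in enumerate(labs)},
            **{f"pct_{lab.lower()}": [s.pct[j] for s in summaries] for j, lab in enumerate(labs)},
        }
    ).set_index("taxon")
    t3 = pd.DataFrame(
        {
            "taxon": [s.taxon for s in summaries],
            **{
                f"dif_pct_{lab.lower()}": [s.dif_pct[j - 1] for s in summaries]
                for j, lab in enumerate(labs)
                if j > 0
            },
            "mean_alt_s0": [round2(s.mean_alt[0]) for s in summaries],
            **{
                f"alt_shift_{lab.lower()}": [round2(s.alt_shift[j - 1]) for s in summaries]
                for j, lab in enumerate(labs)
                if j > 0
            },
            "ap_category": [s.ap_cat for s in summaries],
            "area_class": [s.area_class for s in summaries],
            "direction": [s.direction for s in summaries],
            "strategy": [s.strategy for s in summaries],
        }
    ).set_index("taxon")
    if scores is not None:
        t3.insert(0, "ibmwp_score", scores.reindex(t3.index))
    return t2, t3, strategy_counts(summaries)
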