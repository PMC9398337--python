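"""Physiological and agronomic trait derivations.

Lysimeter water-use partitioning, transpiration efficiency, harvest index,
residual yield (the yield component not explained by phenology and harvest
index), net transpiration ratio harvest rules, broad-sense heritability by
one-way variance components, qRT-PCR relative expression (2^-ddCt) and
specific leaf area/weight.

All daily-sum windows are half-open ``[start, end)``: "until flowering"
excludes the flowering-start day itself, so pre-anthesis, within-flowering
and post-anthesis water use always add up to the cumulative total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .io_formats import TraitTable

logger = logging.getLogger(__name__)

#: NTR threshold below which water-stressed plants are harvested
NTR_HARVEST_THRESHOLD = 0.10
#: lower NTR threshold used when sampling tissue for expression work
NTR_SAMPLING_THRESHOLD = 0.20


# ---------------------------------------------------------------------------
# Water use
# ---------------------------------------------------------------------------


@dataclass
class WaterUseSeries:
    """Daily water use (kg) of one plant/cylinder with phenology events.

    ``daily`` is indexed by day (integers or timestamps, ascending);
    events must satisfy imposition <= flowering_start <= flowering_end
    <= harvest and lie within the series range.
    """

    plant_id: str
    treatment: str
    daily: pd.Series
    imposition: object
    flowering_start: object
    flowering_end: object
    harvest: object

    def __post_init__(self) -> None:
        if (self.daily < 0).any():
            raise ValueError(f"{self.plant_id}: negative daily water use")
        ev = [self.imposition, self.flowering_start, self.flowering_end, self.harvest]
        if any(ev[i] > ev[i + 1] for i in range(3)):
            raise ValueError(f"{self.plant_id}: event dates out of order")
        if len(self.daily) and (self.imposition < self.daily.index[0]):
            raise ValueError(f"{self.plant_id}: imposition precedes the series")


class WaterUsePartition(NamedTuple):
    pre_anthesis: float
    during_flowering: float
    post_anthesis: float
    cumulative: float


def partition_water_use(series: WaterUseSeries) -> WaterUsePartition:
    """Split cumulative water use into pre-, within- and post-flowering.

    pre = sum over [imposition, flowering_start); during =
    [flowering_start, flowering_end); post = [flowering_end, harvest);
    cumulative = [imposition, harvest). Water used during the flowering
    window belongs to neither pre- nor post-anthesis and is reported as
    its own component, so the three parts always sum to the cumulative.
    """
    d = series.daily
    idx = d.index

    def window(a, b) -> float:
        return float(d[(idx >= a) & (idx < b)].sum())

    pre = window(series.imposition, series.flowering_start)
    during = window(series.flowering_start, series.flowering_end)
    post = window(series.flowering_end, series.harvest)
    cumulative = window(series.imposition, series.harvest)
    return WaterUsePartition(pre, during, post, cumulative)


def transpiration_efficiency(shoot_dw_g: float, water_kg: float) -> float:
    """Shoot dry weight produced per unit water transpired (g/kg)."""
    if water_kg <= 0:
        raise ValueError(f"total water extracted must be positive, got {water_kg}")
    return shoot_dw_g / water_kg


def net_transpiration_ratio(ws_daily: float, ww_daily_mean: float) -> float:
    """Transpiration of a stressed plant relative to well-watered controls."""
    if ww_daily_mean <= 0:
        raise ValueError("well-watered mean transpiration must be positive")
    return ws_daily / ww_daily_mean


def harvest_trigger(ntr_series: pd.Series, threshold: float = NTR_HARVEST_THRESHOLD):
    """First date at which NTR falls strictly below *threshold*.

    The default 0.10 is the harvest rule for water-stressed lysimeter
    plants; 0.20 (:data:`NTR_SAMPLING_THRESHOLD`) is used when harvesting
    tissue for expression assays.
    """
    below = ntr_series[ntr_series < threshold]
    if below.empty:
        raise ValueError(f"NTR never fell below {threshold}")
    return below.index[0]


# ---------------------------------------------------------------------------
# Yield components
# ---------------------------------------------------------------------------


def harvest_index(seed_yield_g: float, shoot_biomass_g: float) -> float:
    """Seed yield per plant over shoot biomass per plant (dimensionless)."""
    if shoot_biomass_g <= 0:
        raise ValueError("shoot biomass must be positive")
    if seed_yield_g > shoot_biomass_g:
        logger.warning("seed yield (%.3g) exceeds shoot biomass (%.3g)",
                       seed_yield_g, shoot_biomass_g)
    return seed_yield_g / shoot_biomass_g


def residual_yield(
    table: TraitTable | pd.DataFrame,
    yield_col: str = "seed_yield",
    flowering_col: str = "days_to_50pct_flowering",
    hi_col: str = "harvest_index",
) -> pd.Series:
    """Observed minus predicted yield, the drought-adaptation proxy.

    Predicted yield is an ordinary-least-squares fit of yield on days to
    50% flowering and harvest index, with intercept; residuals therefore
    sum to zero to machine precision and are orthogonal to both
    predictors.
    """
    df = table.data if isinstance(table, TraitTable) else table
    for col in (yield_col, flowering_col, hi_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not in table")
    if len(df) < 4:
        raise ValueError("need at least 4 rows to fit yield on two predictors")
    y = df[yield_col].to_numpy(float)
    X = np.column_stack([
        np.ones(len(df)),
        df[flowering_col].to_numpy(float),
        df[hi_col].to_numpy(float),
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear predictors: flowering and harvest index "
                         "do not span a full-rank design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    logger.debug("residual yield fit: intercept=%.4g, flowering=%.4g, HI=%.4g",
                 *beta)
    return pd.Series(y - X @ beta, index=df.index, name="residual_yield")


def specific_leaf_area(leaf_area_3d_cm2: float, shoot_dw_g: float) -> tuple[float, float]:
    """(SLA, SLW): 3D-leaf area per shoot dry weight (cm^2/g) and its
    reciprocal, specific leaf weight."""
    if shoot_dw_g <= 0:
        raise ValueError("shoot dry weight must be positive")
    sla = leaf_area_3d_cm2 / shoot_dw_g
    return sla, 1.0 / sla


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------


def broad_sense_heritability(
    table: TraitTable | pd.DataFrame,
    genotype_col: str = "genotype",
    value_col: str = "value",
) -> float:
    """h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) by one-way method of moments.

    Variance components come from the one-way random-effects ANOVA:
    sigma_e^2 = MS_within; sigma_g^2 = (MS_between - MS_within) / n0,
    truncated at zero, where n0 is the effective replicate number
    (n0 = (N - sum n_i^2 / N) / (k - 1), equal to the common replicate
    count in balanced designs).
    """
    df = table.data if isinstance(table, TraitTable) else table
    groups = df.groupby(genotype_col)[value_col]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least two genotypes")
    sizes = groups.size()
    if (sizes < 2).any():
        raise ValueError("every genotype needs at least two replicates")
    N = int(sizes.sum())
    grand = df[value_col].mean()
    means = groups.mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df[value_col] - df[genotype_col].map(means)) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    sigma_g2 = max(0.0, (ms_between - ms_within) / n0)
    sigma_e2 = ms_within
    if sigma_g2 + sigma_e2 == 0:
        return 0.0
    return sigma_g2 / (sigma_g2 + sigma_e2)


# ---------------------------------------------------------------------------
# Relative expression (2^-ddCt)
# ---------------------------------------------------------------------------


def relative_expression(
    assays: pd.DataFrame, calibrator: str,
    sample_col: str = "sample",
    target_col: str = "ct_target",
    control_col: str = "ct_control",
) -> pd.Series:
    """Fold change per sample by the 2^-ddCt method.

    Per sample, dCt = mean(Ct_target) - mean(Ct_control) over replicates
    (typically three); ddCt = dCt_sample - dCt_calibrator; fold change =
    2^(-ddCt), so the calibrator itself maps to 1.0.
    """
    for col in (sample_col, target_col, control_col):
        if col not in assays.columns:
            raise KeyError(f"column {col!r} not in assay table")
    if assays[[target_col, control_col]].isna().any().any():
        raise ValueError("missing Ct values in assay table")
    if ((assays[target_col] <= 0) | (assays[control_col] <= 0)).any():
        raise ValueError("Ct values must be positive")
    dct = (assays.groupby(sample_col)[target_col].mean()
           - assays.groupby(sample_col)[control_col].mean())
    if calibrator not in dct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in assay table")
    ddct = dct - dct[calibrator]
    fold = np.power(2.0, -ddct)
    fold.name = "fold_change"
    return fold
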