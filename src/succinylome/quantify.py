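"""Relative quantification and differential-site calling.

The label-free pipeline, for peptide intensities I_ij (sample i, peptide j):

1. **Centralization** — R_ij = I_ij / mean_i(I_ij), the mean taken over the
   samples in which the peptide was observed; each row becomes a relative
   profile centered at 1.
2. **Median normalization** — NR_ij = R_ij / median_j(R_ij), per sample,
   removing global loading/instrument scaling; afterwards every sample's
   median relative value is exactly 1.
3. **Aggregation** — the relative quantity of a unit k (a modification site,
   or a protein) is the median of its peptides: R_ik = median(NR_ij, j ∈ k).
4. **Fold change** — FC_k = mean(R_ik, i ∈ treated) / mean(R_ik, i ∈ control).
5. **Significance** — two-sided two-sample Student's t-test (equal variance)
   on the per-group R_ik values; optionally on log2 values.
6. **Call** — up if FC > fc_up and p < alpha; down if FC < fc_down and
   p < alpha; otherwise unchanged.  All inequalities strict.

Missing intensities stay missing throughout (they are never zero), and a
site must be observed in at least ``min_obs_per_group`` replicates of each
group to be testable.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FormatError, IntensityMatrix, SampleSheet

STAGE_CENTRALIZED = "centralized"
STAGE_NORMALIZED = "normalized"


@dataclass
class RelativeQuantMatrix:
    """Peptide-level relative quantities with their processing stage."""

    values: pd.DataFrame
    features: pd.DataFrame
    stage: str


@dataclass
class DssThresholds:
    """Differential-site decision rule: FC > fc_up or FC < fc_down, p < alpha."""

    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    min_obs_per_group: int = 2

    def __post_init__(self) -> None:
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_obs_per_group < 1:
            raise ValueError("min_obs_per_group must be >= 1")


def centralize(matrix: IntensityMatrix) -> RelativeQuantMatrix:
    """R_ij = I_ij / mean over observed samples of row j.

    Rows with no observed value are dropped with a warning.  The observed
    values of every surviving row average to 1.
    """
    values = matrix.values
    observed = values.notna().sum(axis=1)
    dead = observed == 0
    if dead.any():
        warnings.warn(
            f"dropping {int(dead.sum())} all-missing rows during centralization",
            stacklevel=2,
        )
        values = values.loc[~dead]
    row_mean = values.mean(axis=1, skipna=True)
    centered = values.div(row_mean, axis=0)
    return RelativeQuantMatrix(
        values=centered, features=matrix.features.loc[centered.index], stage=STAGE_CENTRALIZED
    )


def median_normalize(rq: RelativeQuantMatrix) -> RelativeQuantMatrix:
    """NR_ij = R_ij / median over observed rows of sample i.

    Removes per-sample global scaling; every output column has median 1.
    """
    if rq.stage != STAGE_CENTRALIZED:
        raise ValueError(f"expected a centralized matrix, got stage={rq.stage!r}")
    col_obs = rq.values.notna().sum(axis=0)
    empty = col_obs[col_obs == 0]
    if len(empty):
        raise FormatError(
            f"sample(s) with no observed values: {list(empty.index)}"
        )
    col_median = rq.values.median(axis=0, skipna=True)
    return RelativeQuantMatrix(
        values=rq.values.div(col_median, axis=1), features=rq.features, stage=STAGE_NORMALIZED
    )


def aggregate(
    rq: RelativeQuantMatrix, mapping: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse normalized peptide rows to units (sites or proteins).

    ``mapping`` sends each peptide row id to its unit id; ``None`` means one
    peptide form per site (identity pass-through).  A unit's value in a
    sample is the median of its observed peptides there; a unit with no
    observed peptide in a sample stays missing.
    """
    if rq.stage != STAGE_NORMALIZED:
        raise ValueError(f"expected a normalized matrix, got stage={rq.stage!r}")
    if mapping is None:
        return rq.values.copy()
    if not mapping:
        raise ValueError("empty peptide-to-unit mapping")
    missing = set(rq.values.index) - set(mapping)
    if missing:
        raise ValueError(f"mapping does not cover rows: {sorted(missing)[:5]}")
    units = pd.Series({row: mapping[row] for row in rq.values.index}, name="unit")
    return rq.values.groupby(units).median()


def _group_blocks(
    site_values: pd.DataFrame, sheet: SampleSheet, treated: str, control: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return (
        site_values[sheet.samples_in_group(treated)],
        site_values[sheet.samples_in_group(control)],
    )


def fold_change(
    site_values: pd.DataFrame,
    sheet: SampleSheet,
    treated: str,
    control: str,
    min_obs_per_group: int = 2,
) -> pd.Series:
    """FC_k = mean(treated observed) / mean(control observed); NaN when a
    group has fewer than ``min_obs_per_group`` observations (not testable)."""
    t_block, c_block = _group_blocks(site_values, sheet, treated, control)
    testable = (t_block.notna().sum(axis=1) >= min_obs_per_group) & (
        c_block.notna().sum(axis=1) >= min_obs_per_group
    )
    c_mean = c_block.mean(axis=1, skipna=True)
    if ((c_mean <= 0) & testable).any():  # intensities are positive; guarded anyway
        raise ValueError("non-positive control mean encountered")
    fc = t_block.mean(axis=1, skipna=True) / c_mean
    return fc.where(testable)


def test_significance(
    site_values: pd.DataFrame,
    sheet: SampleSheet,
    treated: str,
    control: str,
    min_obs_per_group: int = 2,
    log2: bool = False,
) -> pd.DataFrame:
    """Two-sided equal-variance Student's t-test per site.

    Returns a frame with columns ``p_value`` and ``degenerate``.  Zero
    variance in both groups is degenerate: equal means give p = 1, unequal
    means give the smallest positive float.  "Zero" is judged with a tiny
    relative tolerance (spread below 1e-9 of the magnitude) so that
    replicate values equal up to floating-point rounding do not feed a
    catastrophically-cancelling t statistic.  Sites under the observation
    floor get NaN.
    """
    t_block, c_block = _group_blocks(site_values, sheet, treated, control)
    if log2:
        t_block, c_block = np.log2(t_block), np.log2(c_block)

    def near_constant(v: np.ndarray) -> bool:
        return np.ptp(v) <= 1e-9 * max(abs(float(np.mean(v))), sys.float_info.min)

    p_values = np.full(len(site_values), np.nan)
    degenerate = np.zeros(len(site_values), dtype=bool)
    for row, (idx, _) in enumerate(site_values.iterrows()):
        x = t_block.loc[idx].dropna().to_numpy()
        y = c_block.loc[idx].dropna().to_numpy()
        if len(x) < min_obs_per_group or len(y) < min_obs_per_group:
            continue
        if near_constant(x) and near_constant(y):
            degenerate[row] = True
            close = abs(x.mean() - y.mean()) <= 1e-9 * max(
                abs(x.mean()), abs(y.mean()), sys.float_info.min
            )
            p_values[row] = 1.0 if close else sys.float_info.min
            continue
        p_values[row] = stats.ttest_ind(x, y, equal_var=True).pvalue
    return pd.DataFrame(
        {"p_value": p_values, "degenerate": degenerate}, index=site_values.index
    )


CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_NOT_TESTABLE = "not_testable"


def call_dss(fc: float, p: float, thresholds: DssThresholds | None = None) -> str:
    """Classify one site from its fold change and p-value (strict inequalities)."""
    thresholds = thresholds or DssThresholds()
    if fc is None or p is None or np.isnan(fc) or np.isnan(p):
        return CALL_NOT_TESTABLE
    if p < thresholds.alpha:
        if fc > thresholds.fc_up:
            return CALL_UP
        if fc < thresholds.fc_down:
            return CALL_DOWN
    return CALL_UNCHANGED


def differential_sites(
    matrix: IntensityMatrix,
    sheet: SampleSheet,
    treated: str,
    control: str,
    thresholds: DssThresholds | None = None,
    mapping: Mapping[str, str] | None = None,
    log2: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Run the full pipeline and return one row per site.

    Columns: protein, position, mean_<control>, mean_<treated>, fold_change,
    p_value, (p_adjusted when ``bh``), call.
    """
    thresholds = thresholds or DssThresholds()
    site_values = aggregate(median_normalize(centralize(matrix)), mapping)
    fc = fold_change(site_values, sheet, treated, control, thresholds.min_obs_per_group)
    sig = test_significance(
        site_values, sheet, treated, control, thresholds.min_obs_per_group, log2=log2
    )
    t_block, c_block = _group_blocks(site_values, sheet, treated, control)
    features = matrix.features
    if mapping is not None:
        rows = pd.Series(mapping)
        features = features.assign(unit=rows.reindex(features.index))
        features = features.groupby("unit").first()
    features = features.reindex(site_values.index)
    report = pd.DataFrame(
        {
            "protein": features["protein"],
            "position": features["position"],
            f"mean_{control}": c_block.mean(axis=1, skipna=True),
            f"mean_{treated}": t_block.mean(axis=1, skipna=True),
            "fold_change": fc,
            "p_value": sig["p_value"],
            "degenerate": sig["degenerate"],
        },
        index=site_values.index,
    )
    decision_p = report["p_value"]
    if bh:
        report["p_adjusted"] = adjust_bh_series(report["p_value"])
        decision_p = report["p_adjusted"]
    report["call"] = [
        call_dss(f, p, thresholds) for f, p in zip(report["fold_change"], decision_p)
    ]
    report.index.name = "site_id"
    return report


def adjust_bh_series(p_values: pd.Series) -> pd.Series:
    """Benjamini–Hochberg step-up, NaN-preserving."""
    out = pd.Series(np.nan, index=p_values.index)
    mask = p_values.notna()
    if mask.any():
        out[mask] = multipletests(p_values[mask], method="fdr_bh")[1]
    return out
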