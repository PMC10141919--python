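"""The 30 distributional features computed per task window.

For each of the six scalar streams (HR, TEMP, EDA, ACC_X, ACC_Y, ACC_Z)
five statistics are computed:

* ``mean_diff``   -- mean(task) - mean(baseline)
* ``median_diff`` -- median(task) - median(baseline)
* ``sd_diff``     -- sd(task) - sd(baseline)  (sample sd, n-1 denominator)
* ``skewness``    -- Fisher-Pearson g1 = m3 / m2**1.5 of the task samples
* ``kurtosis``    -- excess g2 = m4 / m2**2 - 3 of the task samples

where m_k are the biased central moments.  Excess kurtosis makes a
platykurtic stream negative, matching how the acceleration shape effects
are interpreted downstream; a ``kurtosis_excess=False`` switch reports raw
(non-excess) kurtosis for sensitivity analysis.  Zero-variance streams get
skewness and excess kurtosis 0 with a warning, so feature vectors stay
finite.

Feature names follow the frozen ``<stat>_<channel>`` convention, e.g.
``median_diff_TEMP``, ``kurtosis_ACC_Y``, so fitted coefficients are
portable across runs.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocessing import SCALAR_CHANNELS, TaskWindow

__all__ = [
    "Moments",
    "FeatureError",
    "STATS",
    "FEATURE_NAMES",
    "sample_moments",
    "extract_features",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

STATS = ("mean_diff", "median_diff", "sd_diff", "skewness", "kurtosis")

#: The frozen names and order of the 30 features.
FEATURE_NAMES = tuple(f"{stat}_{ch}" for ch in SCALAR_CHANNELS for stat in STATS)

TABLE_SCHEMA_VERSION = 1


class FeatureError(ValueError):
    pass


class Moments(NamedTuple):
    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    zero_variance: bool = False


def sample_moments(values: Sequence[float], excess: bool = True) -> Moments:
    """Mean, median, sample sd, skewness g1 and (excess) kurtosis g2.

    Skewness and kurtosis use the biased central moments m_k
    (population-style g statistics, no small-sample bias correction).
    A zero-variance input returns skewness and kurtosis 0 and sets
    ``zero_variance`` after warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise FeatureError("sample_moments expects a 1-d sequence")
    if x.size < 2:
        raise FeatureError(f"need at least 2 samples, got {x.size}")
    mean = float(np.mean(x))
    median = float(np.median(x))
    sd = float(np.std(x, ddof=1))
    m2 = float(np.mean((x - mean) ** 2))
    if m2 == 0.0:
        warnings.warn("zero-variance stream: skewness and kurtosis set to 0")
        return Moments(mean, median, 0.0, 0.0, 0.0, zero_variance=True)
    xc = x - mean  # shape moments are location invariant; centring avoids
    # precision loss when the variation is tiny relative to the level
    skew = float(sps.skew(xc, bias=True))
    kurt = float(sps.kurtosis(xc, fisher=excess, bias=True))
    if not (np.isfinite(skew) and np.isfinite(kurt)):
        # variance so small the moment ratios underflow (e.g. a stream
        # pinned at a sensor floor): same convention as exactly zero
        warnings.warn("zero-variance stream: skewness and kurtosis set to 0")
        return Moments(mean, median, sd, 0.0, 0.0 if excess else 3.0,
                       zero_variance=True)
    return Moments(mean, median, sd, skew, kurt)


def extract_features(window: TaskWindow, kurtosis_excess: bool = True) -> dict:
    """The 30 named features for one task window, plus identifiers.

    Diff statistics compare task to baseline; shape statistics (skewness,
    kurtosis) are computed on the task samples only.
    """
    out = {
        "participant_id": window.participant_id,
        "task_id": window.task_id,
    }
    for ch in SCALAR_CHANNELS:
        try:
            task_m = sample_moments(window.task[ch], excess=kurtosis_excess)
            base_m = sample_moments(window.baseline[ch], excess=kurtosis_excess)
        except FeatureError as exc:
            raise FeatureError(f"channel {ch}: {exc}") from exc
        out[f"mean_diff_{ch}"] = task_m.mean - base_m.mean
        out[f"median_diff_{ch}"] = task_m.median - base_m.median
        out[f"sd_diff_{ch}"] = task_m.sd - base_m.sd
        out[f"skewness_{ch}"] = task_m.skewness
        out[f"kurtosis_{ch}"] = task_m.kurtosis
    out["flow"] = window.flow
    return out


def build_feature_table(windows: Sequence[TaskWindow],
                        kurtosis_excess: bool = True) -> pd.DataFrame:
    """Tidy table: one row per task, id columns + 30 features + flow label.

    Column order is fixed: ``participant_id, task_id,`` the 30 features in
    :data:`FEATURE_NAMES` order, then ``flow``.
    """
    if len(windows) == 0:
        raise FeatureError("need at least one task window")
    rows = [extract_features(w, kurtosis_excess=kurtosis_excess) for w in windows]
    table = pd.DataFrame(rows)
    table = table[["participant_id", "task_id", *FEATURE_NAMES, "flow"]]
    keys = table[["participant_id", "task_id"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        dupes = sorted(set(keys[keys.duplicated()]))
        raise FeatureError(f"duplicate (participant, task) keys: {dupes}")
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# flowsense feature table schema v{TABLE_SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
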