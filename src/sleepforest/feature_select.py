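"""Gender-stratified Pearson feature selection with a self-adaptive
significance threshold.

For each gender separately, every normalized feature is correlated with
the ordinal sleep-stage code (0..k-1 in scheme order); features whose
two-sided p-value falls below the threshold form that gender's optimal
subset.  The threshold itself can be chosen adaptively: candidate
thresholds are scored by a cross-validated classifier on the subset each
induces, and the best (ties to the stricter threshold) wins.  The default
candidate list includes 0.005, the operating point used for the reference
subsets.  No multiple-testing correction is applied; the strict threshold
plays that role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epoch_io import CHANNELS, StageScheme, feature_columns, map_stage
from .errors import DegenerateInputError, InsufficientDataError, SelectionError

DEFAULT_THRESHOLD = 0.005
DEFAULT_CANDIDATES = (0.05, 0.01, 0.005, 0.001)


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    gender: str
    r: float
    p: float


@dataclass(frozen=True)
class FeatureSubset:
    gender: str
    features: tuple          # names sorted by |r| descending
    threshold: float

    @property
    def by_electrode(self) -> dict:
        out = {ch: [] for ch in CHANNELS}
        for name in self.features:
            ch = name.split(".")[0]
            out.setdefault(ch, []).append(name)
        return out


def pearson_r(x, y) -> tuple:
    """Pearson r with its two-sided p-value (t distribution, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InsufficientDataError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in one of the inputs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def stage_codes(matrix: pd.DataFrame, scheme: StageScheme | str = "five") -> np.ndarray:
    """Ordinal encoding of the stage column under a combination scheme."""
    if isinstance(scheme, str):
        scheme = StageScheme.by_name(scheme)
    return np.array([scheme.encode(map_stage(s, scheme)) for s in matrix["stage"]])


def correlate_features(
    matrix: pd.DataFrame,
    gender: str,
    scheme: StageScheme | str = "five",
) -> list:
    """One CorrelationResult per feature, on rows of the requested gender.

    Constant features get r = 0, p = 1 (they carry no stage information).
    """
    rows = matrix[matrix["gender"] == gender]
    if len(rows) < 3:
        raise InsufficientDataError(
            f"need at least 3 rows for gender {gender!r}, got {len(rows)}"
        )
    y = stage_codes(rows, scheme)
    results = []
    for name in feature_columns(matrix):
        x = rows[name].to_numpy(dtype=float)
        if x.std() == 0:
            results.append(CorrelationResult(name, gender, 0.0, 1.0))
            continue
        r, p = pearson_r(x, y)
        results.append(CorrelationResult(name, gender, r, p))
    return results


def select_subset(results: list, p_threshold: float, gender: str) -> FeatureSubset:
    """Features with p < threshold, sorted by |r| descending."""
    if p_threshold <= 0:
        raise SelectionError("threshold must be positive")
    chosen = [res for res in results if res.gender == gender and res.p < p_threshold]
    if not chosen:
        raise SelectionError(
            f"no feature passes p < {p_threshold} for gender {gender!r}; "
            "try a looser threshold"
        )
    chosen.sort(key=lambda res: (-abs(res.r), res.feature))
    return FeatureSubset(
        gender=gender, features=tuple(res.feature for res in chosen),
        threshold=p_threshold,
    )


def adaptive_threshold(
    results: list,
    candidates,
    evaluator,
    gender: str,
) -> float:
    """Self-adaptive threshold search: among candidate p-value cutoffs,
    return the one whose induced subset scores best under ``evaluator``
    (a callable subset -> score); ties break toward the stricter cutoff.
    Candidates inducing an empty subset are skipped."""
    if not candidates:
        raise SelectionError("no candidate thresholds supplied")
    scored = []
    for p in sorted(candidates):  # ascending: stricter first wins ties
        if not 0 < p < 1:
            raise SelectionError(f"candidate threshold {p} outside (0, 1)")
        try:
            subset = select_subset(results, p, gender)
        except SelectionError:
            continue
        scored.append((evaluator(subset), -p, p))
    if not scored:
        raise SelectionError("every candidate threshold yields an empty subset")
    return max(scored)[2]


def selection_report(results: list, subset: FeatureSubset) -> pd.DataFrame:
    """CSV-ready table: feature, gender, electrode, r, p, selected flag."""
    rows = [
        {
            "feature": res.feature,
            "gender": res.gender,
            "electrode": res.feature.split(".")[0],
            "r": res.r,
            "p": res.p,
            "selected": res.feature in subset.features,
        }
        for res in results
    ]
    return pd.DataFrame(rows)
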