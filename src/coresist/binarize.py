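"""Waterfall discretization of drug-response vectors into sensitive/resistant calls.

The waterfall method sorts a drug's response values (one per cell line) in
decreasing order and asks whether the resulting curve is essentially linear.
If it is — Pearson correlation of the sorted curve with its least-squares line
at or above a cutoff (default 0.95) — there is no natural break and the median
is used as the threshold.  Otherwise the threshold is placed at the major
inflection of the curve: the sorted value farthest (perpendicular distance,
both axes rescaled to [0, 1]) from the chord joining the first and last points.

Polarity is explicit because summary scores disagree about direction: on an
activity-area scale high values mean sensitive (``high_is_sensitive``), on a
log-IC50 scale low values mean sensitive (``low_is_sensitive``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateDataError, DrugLookupError, InsufficientDataError

HIGH_IS_SENSITIVE = "high_is_sensitive"
LOW_IS_SENSITIVE = "low_is_sensitive"
POLARITIES = (HIGH_IS_SENSITIVE, LOW_IS_SENSITIVE)

SENSITIVE = "sensitive"
RESISTANT = "resistant"

DEFAULT_LINEARITY_CUTOFF = 0.95


@dataclass(frozen=True)
class WaterfallResult:
    """Threshold record for one drug.

    ``linearity_r`` is the Pearson correlation of the sorted waterfall against
    its least-squares line (equivalently ``|r|`` of rank index vs. sorted
    value), so it lies in [0, 1] and equals 1 for an exactly linear vector.
    ``cutpoint_index`` is the 1-based position of the inflection in the
    decreasing sort; ``None`` under the median rule.
    """

    drug_id: str
    n_used: int
    linearity_r: float
    rule: str  # "median" | "inflection"
    threshold: float
    cutpoint_index: int | None = None


@dataclass
class ResponseMatrix:
    """Cell-line × drug continuous response scores with missingness.

    ``values`` is a DataFrame indexed by cell-line id with drug ids as
    columns; NaN marks a missing measurement.
    """

    values: pd.DataFrame
    polarity: str = HIGH_IS_SENSITIVE
    scale_label: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate cell-line ids in response matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate drug ids in response matrix")
        arr = self.values.to_numpy(dtype=float, na_value=np.nan)
        if np.isinf(arr).any():
            raise ValueError("non-finite (infinite) response values are not allowed")

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SensitivityCalls:
    """Binarized calls plus the thresholds that produced them.

    ``calls`` holds ``"sensitive"`` / ``"resistant"`` strings with NaN where
    the underlying response was missing.
    """

    calls: pd.DataFrame
    thresholds: dict[str, WaterfallResult] = field(default_factory=dict)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def resistant_mask(self) -> pd.DataFrame:
        """Boolean frame: True where the call is resistant (False if missing)."""
        return self.calls == RESISTANT

    @property
    def evaluable_mask(self) -> pd.DataFrame:
        """Boolean frame: True where a call (either way) exists."""
        return self.calls.notna()

    def resistant_lines(self, drug_id: str) -> frozenset[str]:
        self._check_drug(drug_id)
        col = self.calls[drug_id]
        return frozenset(col.index[col == RESISTANT])

    def _check_drug(self, drug_id: str) -> None:
        if drug_id not in self.calls.columns:
            raise DrugLookupError(drug_id)


def waterfall_threshold(
    values,
    linearity_cutoff: float = DEFAULT_LINEARITY_CUTOFF,
    drug_id: str = "",
) -> WaterfallResult:
    """Compute the waterfall threshold for one drug's response vector.

    Parameters
    ----------
    values : array-like
        Response scores; NaN entries are dropped. At least 3 finite values
        with nonzero spread are required.
    linearity_cutoff : float in (0, 1)
        If the sorted curve's linearity is at or above this value the median
        rule applies; below it the inflection rule applies.
    drug_id : str
        Identifier stored in the result (cosmetic).

    Returns
    -------
    WaterfallResult
    """
    if not 0.0 < linearity_cutoff < 1.0:
        raise ValueError("linearity_cutoff must lie strictly inside (0, 1)")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 3:
        raise InsufficientDataError(
            f"waterfall needs >= 3 finite values, got {n} for drug {drug_id!r}"
        )
    if np.ptp(v) == 0.0:
        raise DegenerateDataError(
            f"all response values equal ({v[0]}) for drug {drug_id!r}; no threshold exists"
        )

    s = np.sort(v)[::-1]  # decreasing waterfall, index 1..n
    idx = np.arange(1, n + 1, dtype=float)
    # Correlation with the least-squares line == |r(index, value)|.
    r = abs(np.corrcoef(idx, s)[0, 1])

    if r >= linearity_cutoff:
        return WaterfallResult(
            drug_id=drug_id,
            n_used=n,
            linearity_r=float(r),
            rule="median",
            threshold=float(np.median(v)),
            cutpoint_index=None,
        )

    # Inflection rule: both axes rescaled to [0,1]; perpendicular distance of
    # each point to the chord joining (x_1, y_1) and (x_n, y_n).
    x = (idx - 1.0) / (n - 1.0)
    y = (s - s[-1]) / (s[0] - s[-1])
    dx, dy = x[-1] - x[0], y[-1] - y[0]  # (1, -1)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    k = int(np.argmax(dist))  # first occurrence -> smallest index on ties
    return WaterfallResult(
        drug_id=drug_id,
        n_used=n,
        linearity_r=float(r),
        rule="inflection",
        threshold=float(s[k]),
        cutpoint_index=k + 1,
    )


def call_sensitivity(
    matrix: ResponseMatrix,
    thresholds: Mapping[str, WaterfallResult],
) -> SensitivityCalls:
    """Apply per-drug thresholds to a response matrix.

    Under ``high_is_sensitive`` a value >= threshold is sensitive and a value
    below it resistant; under ``low_is_sensitive`` the comparison is mirrored
    (<= threshold is sensitive). The boundary value is always sensitive.
    Missing responses propagate to missing calls.
    """
    out = {}
    for drug in matrix.drug_ids:
        if drug not in thresholds:
            raise DrugLookupError(drug)
        t = thresholds[drug].threshold
        col = matrix.values[drug]
        if matrix.polarity == HIGH_IS_SENSITIVE:
            sensitive = col >= t
        else:
            sensitive = col <= t
        calls = pd.Series(
            np.where(sensitive, SENSITIVE, RESISTANT), index=col.index, dtype=object
        )
        calls[col.isna()] = np.nan
        out[drug] = calls
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.drug_ids)
    return SensitivityCalls(calls=frame, thresholds=dict(thresholds))


class WaterfallBinarizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping the waterfall method.

    ``fit`` learns one threshold per drug (column); ``transform`` maps
    continuous responses to ``"sensitive"`` / ``"resistant"`` string calls
    (NaN preserved).  Accepts a :class:`ResponseMatrix`, a DataFrame, or a
    2-D array (drug ids then taken from ``drug_ids`` or invented).

    Parameters
    ----------
    polarity : {"high_is_sensitive", "low_is_sensitive"}
    linearity_cutoff : float in (0, 1), default 0.95

    Attributes
    ----------
    thresholds_ : dict[str, WaterfallResult]
    drug_ids_ : list[str]
    """

    def __init__(
        self,
        polarity: str = HIGH_IS_SENSITIVE,
        linearity_cutoff: float = DEFAULT_LINEARITY_CUTOFF,
    ):
        self.polarity = polarity
        self.linearity_cutoff = linearity_cutoff

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, ResponseMatrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D cell-line × drug array")
        return pd.DataFrame(arr, columns=[f"drug_{j}" for j in range(arr.shape[1])])

    def fit(self, X, y=None):
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        frame = self._as_frame(X)
        self.drug_ids_ = list(frame.columns)
        self.thresholds_ = {
            drug: waterfall_threshold(
                frame[drug].to_numpy(dtype=float),
                linearity_cutoff=self.linearity_cutoff,
                drug_id=str(drug),
            )
            for drug in self.drug_ids_
        }
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("WaterfallBinarizer is not fitted")
        frame = self._as_frame(X)
        matrix = ResponseMatrix(values=frame, polarity=self.polarity)
        return call_sensitivity(matrix, self.thresholds_).calls

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def binarize_response(
    matrix: ResponseMatrix,
    linearity_cutoff: float = DEFAULT_LINEARITY_CUTOFF,
) -> SensitivityCalls:
    """One-shot binarization: thresholds for every drug, then calls."""
    binarizer = WaterfallBinarizer(
        polarity=matrix.polarity, linearity_cutoff=linearity_cutoff
    ).fit(matrix)
    return call_sensitivity(matrix, binarizer.thresholds_)
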