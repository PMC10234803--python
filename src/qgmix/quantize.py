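"""Octile (quantile) coding of exposure columns.

Each exposure column is centered to zero mean (which cannot change the
codes but mirrors the standardization step of the motivating analysis) and
cut at its empirical quantiles at probabilities {1/q, ..., (q-1)/q} using
linear interpolation of order statistics.  Duplicate breakpoints -- common
for zero-inflated point-source burdens -- are collapsed, so heavily tied
columns occupy fewer than q codes.  A value's code is the number of
distinct breakpoints strictly below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class QuantizationError(ValueError):
    pass


@dataclass
class QuantizedExposureMatrix:
    """Integer octile codes plus the breakpoints that produced them."""

    codes: pd.DataFrame          # n x d integers in {0, ..., q-1}
    q: int
    breakpoints: dict[str, np.ndarray]   # distinct, non-decreasing, per column
    collapsed: dict[str, int]            # duplicate breaks removed per column

    @property
    def columns(self) -> list[str]:
        return list(self.codes.columns)

    def __len__(self) -> int:
        return len(self.codes)


def _column_codes(
    values: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray, int]:
    if np.ptp(values) == 0:
        return np.zeros(len(values), dtype=np.int64), np.empty(0), q - 1
    centered = values - values.mean()
    probs = np.arange(1, q) / q
    raw = np.quantile(centered, probs)            # linear interpolation
    breaks = np.unique(raw)
    collapsed = len(raw) - len(breaks)
    codes = np.searchsorted(breaks, centered, side="left")
    return codes.astype(np.int64), breaks, collapsed


def quantize_columns(
    x: pd.DataFrame, q: int = 8
) -> QuantizedExposureMatrix:
    """Quantize every column of an exposure matrix into ``q`` categories."""
    if q < 2:
        raise QuantizationError(f"q must be >= 2, got {q}")
    if len(x) < q:
        raise QuantizationError(f"need at least q={q} rows, got {len(x)}")
    vals = x.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise QuantizationError("exposure matrix contains non-finite values")
    codes = {}
    breakpoints = {}
    collapsed = {}
    for j, col in enumerate(x.columns):
        c, b, k = _column_codes(vals[:, j], q)
        codes[col] = c
        breakpoints[col] = b
        collapsed[col] = k
        if len(b) == 0:
            logger.warning("column %r is constant; all codes set to 0", col)
        elif k:
            logger.info("column %r: %d duplicate breakpoints collapsed", col, k)
    return QuantizedExposureMatrix(
        codes=pd.DataFrame(codes, index=x.index),
        q=q,
        breakpoints=breakpoints,
        collapsed=collapsed,
    )


def apply_breakpoints(
    x: pd.DataFrame, qx: QuantizedExposureMatrix
) -> QuantizedExposureMatrix:
    """Code new data with previously estimated breakpoints.

    Used by the bootstrap's reuse-original-breaks diagnostic mode.  The
    original column means are not re-subtracted because breakpoints are
    stored on the centered scale of the fitting data; new columns are
    centered with their own means, matching the original centering only in
    expectation.
    """
    codes = {}
    for j, col in enumerate(x.columns):
        centered = x[col].to_numpy(float)
        centered = centered - centered.mean()
        codes[col] = np.searchsorted(
            qx.breakpoints[col], centered, side="left"
        ).astype(np.int64)
    return QuantizedExposureMatrix(
        codes=pd.DataFrame(codes, index=x.index),
        q=qx.q,
        breakpoints=qx.breakpoints,
        collapsed=qx.collapsed,
    )
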