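"""Group summary statistics feeding the normal posterior approximation.

Three estimation routes mirror the three ANOVA flavours:

* ``ml_pooled`` — group sample means with one pooled unbiased residual
  variance (homogeneous-variance ANOVA);
* ``ml_groupwise`` — group sample means with per-group unbiased variances
  (Welch's heteroscedastic ANOVA);
* ``trimmed`` — 20% trimmed means with a dispersion built from the
  Winsorized variance, scaled so that the variance of the trimmed mean is
  s_w^2 / ((1 - 2*trim)^2 * N) (robust ANOVA).

Data are held as an ``(N, K)`` array: N observations per group, K groups in
columns, equal N per group.  Batch variants operating on ``(T, N, K)``
stacks are provided for the Monte-Carlo engine; the public single-dataset
functions delegate to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummaries",
    "summarize_ml_pooled",
    "summarize_ml_groupwise",
    "summarize_trimmed",
    "read_grouped_table",
]


class DegenerateDataError(ValueError):
    """Raised when the data carry no within-group variation to estimate from."""


@dataclass(frozen=True)
class GroupSummaries:
    """Per-group centre and per-observation dispersion, var(centre_k) = obs_variances[k]/N."""

    centers: np.ndarray
    obs_variances: np.ndarray
    N: int
    method: str

    @property
    def K(self) -> int:
        return len(self.centers)


def _as_data(data) -> np.ndarray:
    y = np.asarray(data, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("data must be an (N, K) array with K >= 2 groups")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 observations per group")
    return y


def summarize_ml_pooled(data) -> GroupSummaries:
    """Group means with the pooled unbiased residual variance replicated K times."""
    y = _as_data(data)
    centers, obsvar = _ml_pooled_batch(y[None])
    if not np.all(obsvar > 0):
        raise DegenerateDataError("zero within-group variation in every group")
    return GroupSummaries(centers[0], obsvar[0], N=y.shape[0], method="ml_pooled")


def summarize_ml_groupwise(data) -> GroupSummaries:
    """Group means with per-group unbiased variances (Welch)."""
    y = _as_data(data)
    centers, obsvar = _ml_groupwise_batch(y[None])
    if not np.all(obsvar > 0):
        raise DegenerateDataError("a group has zero within-group variation")
    return GroupSummaries(centers[0], obsvar[0], N=y.shape[0], method="ml_groupwise")


def summarize_trimmed(data, trim: float = 0.20) -> GroupSummaries:
    """20% trimmed means with Winsorized-variance-based dispersion.

    With g = floor(trim * N), the centre is the mean of the N - 2g central
    order statistics and the Winsorized variance s_w^2 is the unbiased
    (N - 1 divisor) variance of the sample with its g smallest values
    replaced by the (g+1)-th and its g largest by the (N-g)-th order
    statistic.  The per-observation dispersion is s_w^2 / (1 - 2*trim)^2 so
    that the variance of the trimmed mean is s_w^2 / ((1 - 2*trim)^2 N).
    """
    y = _as_data(data)
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    N = y.shape[0]
    if N - 2 * int(np.floor(trim * N)) < 1:
        raise ValueError(f"N={N} leaves no observations after {trim:.0%} trimming")
    centers, obsvar = _trimmed_batch(y[None], trim)
    if not np.all(obsvar > 0):
        raise DegenerateDataError("a group has zero Winsorized variation")
    return GroupSummaries(centers[0], obsvar[0], N=N, method="trimmed")


# --- batch internals on (T, N, K) stacks ---------------------------------


def _ml_pooled_batch(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T, N, K = y.shape
    centers = y.mean(axis=1)
    ss = ((y - centers[:, None, :]) ** 2).sum(axis=(1, 2))
    pooled = ss / (K * N - K)
    return centers, np.repeat(pooled[:, None], K, axis=1)


def _ml_groupwise_batch(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centers = y.mean(axis=1)
    return centers, y.var(axis=1, ddof=1)


def _trimmed_batch(y: np.ndarray, trim: float = 0.20) -> tuple[np.ndarray, np.ndarray]:
    T, N, K = y.shape
    g = int(np.floor(trim * N))
    ys = np.sort(y, axis=1)
    centers = ys[:, g : N - g, :].mean(axis=1)
    wins = ys.copy()
    if g > 0:
        wins[:, :g, :] = ys[:, g : g + 1, :]
        wins[:, N - g :, :] = ys[:, N - g - 1 : N - g, :]
    s_w2 = wins.var(axis=1, ddof=1)
    return centers, s_w2 / (1.0 - 2.0 * trim) ** 2


def batch_summaries(y: np.ndarray, anova_type: str, trim: float = 0.20):
    """Summaries for a (T, N, K) stack: (centers (T,K), obs_variances (T,K)).

    ``anova_type`` is ``"equal"`` (pooled), ``"unequal"`` (groupwise) or
    ``"robust"`` (trimmed/Winsorized).
    """
    if anova_type == "equal":
        return _ml_pooled_batch(y)
    if anova_type == "unequal":
        return _ml_groupwise_batch(y)
    if anova_type == "robust":
        return _trimmed_batch(y, trim)
    raise ValueError(f"unknown anova_type {anova_type!r}")


def read_grouped_table(path_or_buffer, equalize: str = "error") -> tuple[np.ndarray, list[str]]:
    """Read a two-column delimited table (group label, value) into an (N, K) array.

    The delimiter is sniffed (CSV/TSV/whitespace) and a header row is
    optional.  Groups must have equal N; with ``equalize="trim"`` unequal
    groups are truncated to the smallest group size instead (a warning is the
    caller's job).  Returns the data array and the group labels in column
    order (first-appearance order).
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"expected two columns (group, value), found {df.shape[1]}")
    first = df.iloc[0, 1]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    labels = [str(v) for v in dict.fromkeys(df.iloc[:, 0])]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    groups = [df.loc[df.iloc[:, 0] == lab].iloc[:, 1].astype(float).to_numpy() for lab in labels]
    sizes = {len(gr) for gr in groups}
    if len(sizes) > 1:
        if equalize != "trim":
            raise ValueError(f"groups have unequal sizes {sorted(len(g) for g in groups)}")
        n = min(sizes)
        groups = [gr[:n] for gr in groups]
    return np.column_stack(groups), labels
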