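"""Synchronous neural interactions (SNI) from multichannel recordings.

The SNI statistic quantifies zero-lag coupling between sensor time series.
Each channel is first "prewhitened": an ARIMA(p, d, q) model is fitted and
its residuals (the *innovations*) replace the raw series, removing temporal
autocorrelation so that instantaneous cross-channel correlations are
interpretable.  All C(channels, 2) pairwise zero-lag Pearson correlations
``r`` between innovation series are then Fisher z-transformed,

    r_z = arctanh(r) = 0.5 * ln((1 + r) / (1 - r)),

and the per-pair SNI is the magnitude ``|r_z|``, capturing coupling strength
irrespective of sign.  A per-scan scalar SNI is the arithmetic mean of the
per-pair values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArimaOrder",
    "MegRecording",
    "n_pairs",
    "PrewhitenResult",
    "SniResult",
    "prewhiten",
    "zero_lag_corr",
    "fisher_z",
    "compute_sni",
    "load_recording",
    "save_recording",
]


def n_pairs(n_channels: int) -> int:
    """Number of unordered sensor pairs, C(n, 2) (30,628 for 248 channels)."""
    if n_channels < 0:
        raise ValueError("n_channels must be non-negative")
    return n_channels * (n_channels - 1) // 2


@dataclass(frozen=True)
class ArimaOrder:
    """ARIMA model order (AR order p, differencing order d, MA order q).

    The default (50, 1, 3) is the order used for prewhitening full-length
    axial-gradiometer recordings; test suites typically pass a reduced order.
    """

    p: int = 50
    d: int = 1
    q: int = 3

    def __post_init__(self) -> None:
        for name in ("p", "d", "q"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"ARIMA order {name} must be a non-negative integer, got {v!r}")

    @classmethod
    def parse(cls, text: str) -> "ArimaOrder":
        """Parse an order string like ``"50,1,3"``."""
        parts = [int(x) for x in str(text).replace("(", "").replace(")", "").split(",")]
        if len(parts) != 3:
            raise ValueError(f"expected three comma-separated integers, got {text!r}")
        return cls(*parts)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class MegRecording:
    """A channels x samples recording with acquisition metadata."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match the number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_interval_ms(self) -> float:
        """Sampling interval in milliseconds (0.983 ms at 1017.25 Hz)."""
        return 1000.0 / self.sampling_rate


@dataclass
class PrewhitenResult:
    """Innovations of an ARIMA fit plus whiteness diagnostics."""

    innovations: np.ndarray
    order: ArimaOrder
    converged: bool
    lag1_autocorr: float
    ljung_box_stat: float
    ljung_box_p: float
    n_effective: int

    @property
    def is_white(self) -> bool:
        """Crude whiteness call: Ljung-Box does not reject at the 1% level."""
        return self.ljung_box_p > 0.01


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return 0.0
    return float(x[1:] @ x[:-1]) / denom


def prewhiten(
    series: Sequence[float] | np.ndarray,
    order: ArimaOrder = ArimaOrder(),
    method: str = "hannan_rissanen",
) -> PrewhitenResult:
    """Fit an ARIMA(p, d, q) model to one channel and return its innovations.

    The series is differenced ``d`` times and demeaned, then an ARMA(p, q)
    model is estimated on the differenced series.  ``method`` is passed to the
    statsmodels ARIMA estimator; the fast Hannan-Rissanen regression estimator
    is the default because per-channel full maximum likelihood at high AR
    orders is impractically slow (the model order, not the estimator, is what
    defines the statistic).  The first ``max(p, q)`` residuals are discarded
    as filter warm-up.

    With ``p == q == 0`` the innovations are exactly the demeaned (and, if
    d > 0, differenced) input.

    Raises
    ------
    ValueError
        If the series is too short, contains non-finite values, or is
        constant after differencing.
    """
    x = np.asarray(series, dtype=float).ravel()
    p, d, q = order.as_tuple()
    if x.size <= p + d + q + 1:
        raise ValueError(f"series length {x.size} too short for ARIMA order ({p},{d},{q})")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    y = np.diff(x, n=d) if d > 0 else x.copy()
    if np.ptp(y) == 0.0:
        raise ValueError("series is constant after differencing; degenerate ARIMA fit")
    y = y - y.mean()

    if p == 0 and q == 0:
        innov = y
        converged = True
    else:
        from statsmodels.tsa.arima.model import ARIMA

        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(
                    y,
                    order=(p, 0, q),
                    trend="n",
                    enforce_stationarity=False,
                    enforce_invertibility=False,
                ).fit(method=method)
            innov = np.asarray(res.resid, dtype=float)
            retvals = getattr(res, "mle_retvals", None)
            if isinstance(retvals, dict) and not retvals.get("converged", True):
                converged = False
        except Exception as exc:  # estimation blow-ups become flagged failures
            logger.warning("ARIMA estimation failed: %s", exc)
            innov = np.full_like(y, np.nan)
            converged = False
        warmup = max(p, q)
        innov = innov[warmup:]
        if not np.all(np.isfinite(innov)) or np.ptp(innov) == 0.0:
            converged = False

    if converged:
        from statsmodels.stats.diagnostic import acorr_ljungbox

        lags = max(1, min(10, innov.size // 5))
        lb = acorr_ljungbox(innov, lags=[lags], return_df=True)
        lb_stat = float(lb["lb_stat"].iloc[0])
        lb_p = float(lb["lb_pvalue"].iloc[0])
        lag1 = _lag1_autocorr(innov)
    else:
        lb_stat, lb_p, lag1 = np.nan, np.nan, np.nan

    return PrewhitenResult(
        innovations=innov,
        order=order,
        converged=converged,
        lag1_autocorr=lag1,
        ljung_box_stat=lb_stat,
        ljung_box_p=lb_p,
        n_effective=int(innov.size),
    )


def zero_lag_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation between two series at lag zero."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input has undefined correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def fisher_z(r):
    """Fisher z-transform, ``r_z = arctanh(r)``; requires ``|r| < 1``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z-transform is undefined for |r| >= 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class SniResult:
    """All-pairs SNI values for one scan.

    ``pair_index`` holds unordered channel index pairs (i < j); ``r``, ``z``
    and ``sni_pair`` are aligned per-pair arrays; ``sni_scalar`` is the mean
    of ``sni_pair`` over usable pairs.
    """

    pair_index: list[tuple[int, int]]
    channel_labels: list[str]
    r: np.ndarray
    z: np.ndarray
    sni_pair: np.ndarray
    sni_scalar: float
    n_effective: int
    failed_channels: list[int] = field(default_factory=list)
    failed_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    def to_frame(self) -> pd.DataFrame:
        """Per-pair table (ch_i, ch_j, r, z, sni)."""
        return pd.DataFrame(
            {
                "ch_i": [self.channel_labels[i] for i, _ in self.pair_index],
                "ch_j": [self.channel_labels[j] for _, j in self.pair_index],
                "r": self.r,
                "z": self.z,
                "sni": self.sni_pair,
            }
        )

    def summary(self) -> dict:
        return {
            "sni_scalar": self.sni_scalar,
            "n_pairs": self.n_pairs,
            "n_effective": self.n_effective,
            "n_failed_channels": len(self.failed_channels),
            "n_failed_pairs": len(self.failed_pairs),
        }


def compute_sni(
    recording: MegRecording,
    order: ArimaOrder = ArimaOrder(),
    summary: str = "mean",
    method: str = "hannan_rissanen",
    max_amplitude: float | None = None,
) -> SniResult:
    """Compute per-pair and per-scan SNI for a multichannel recording.

    Every channel is prewhitened independently with the same ARIMA order;
    channels whose estimation fails are excluded with a logged warning.  The
    innovation series are truncated to their common length before all-pairs
    zero-lag correlation.  Pairs with ``|r| >= 1`` (possible only for
    degenerate, e.g. duplicated, channels) are reported in ``failed_pairs``
    and excluded from the scalar summary.

    ``max_amplitude`` optionally excludes channels whose peak absolute value
    exceeds the threshold — a crude stand-in for visual artifact screening,
    off by default.
    """
    if summary != "mean":
        raise ValueError(f"unsupported summary {summary!r}; only 'mean' is implemented")

    usable: list[int] = []
    innovations: list[np.ndarray] = []
    failed: list[int] = []
    for i in range(recording.n_channels):
        ch = recording.data[i]
        if max_amplitude is not None and np.max(np.abs(ch)) > max_amplitude:
            logger.warning("channel %s exceeds amplitude threshold; excluded", recording.channel_labels[i])
            failed.append(i)
            continue
        try:
            pw = prewhiten(ch, order=order, method=method)
        except ValueError as exc:
            logger.warning("channel %s failed prewhitening: %s", recording.channel_labels[i], exc)
            failed.append(i)
            continue
        if not pw.converged:
            logger.warning("channel %s: non-convergent ARIMA fit; excluded", recording.channel_labels[i])
            failed.append(i)
            continue
        usable.append(i)
        innovations.append(pw.innovations)

    if len(usable) < 2:
        raise ValueError("fewer than 2 usable channels after prewhitening failures")

    n_eff = min(v.size for v in innovations)
    mat = np.vstack([v[-n_eff:] for v in innovations])
    corr = np.corrcoef(mat)

    pair_index: list[tuple[int, int]] = []
    r_vals: list[float] = []
    z_vals: list[float] = []
    sni_vals: list[float] = []
    failed_pairs: list[tuple[int, int]] = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            pair = (usable[a], usable[b])
            r = float(corr[a, b])
            if abs(r) >= 1.0:
                logger.warning("pair %s has |r| >= 1; Fisher z undefined, pair flagged", pair)
                failed_pairs.append(pair)
                pair_index.append(pair)
                r_vals.append(r)
                z_vals.append(np.nan)
                sni_vals.append(np.nan)
                continue
            z = fisher_z(r)
            pair_index.append(pair)
            r_vals.append(r)
            z_vals.append(z)
            sni_vals.append(abs(z))

    sni_arr = np.asarray(sni_vals)
    scalar = float(np.nanmean(sni_arr)) if np.any(np.isfinite(sni_arr)) else np.nan
    return SniResult(
        pair_index=pair_index,
        channel_labels=list(recording.channel_labels),
        r=np.asarray(r_vals),
        z=np.asarray(z_vals),
        sni_pair=sni_arr,
        sni_scalar=scalar,
        n_effective=n_eff,
        failed_channels=failed,
        failed_pairs=failed_pairs,
    )


def save_recording(recording: MegRecording, path: str | Path) -> None:
    """Write a recording as a delimited matrix (channels as rows) plus a
    JSON sidecar (``<path>.json``) holding the sampling rate and labels."""
    path = Path(path)
    np.savetxt(path, recording.data, delimiter="\t")
    sidecar = {"sampling_rate": recording.sampling_rate, "channel_labels": recording.channel_labels}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def load_recording(path: str | Path) -> MegRecording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        meta = {"sampling_rate": 1017.25, "channel_labels": []}
    return MegRecording(
        data=data,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta.get("channel_labels") or []),
    )
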