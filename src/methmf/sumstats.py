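"""Steady-state pattern statistics.

Each snapshot row is encoded as z = 1 (u), 2 (h), 3 (m).  The statistics
follow the estimator conventions used throughout this package's model
comparisons: the site-to-site variance of z uses denominator N - 1 per row,
while the neighbour covariance (between z and its cyclic shift) uses
denominator N per row; both are then averaged over rows, and the neighbour
correlation is their ratio.  The mixed denominators are intentional and are
preserved exactly, since the correlation is defined through them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SummaryStats",
    "ReplicateSummary",
    "STAT_NAMES",
    "encode_z",
    "decode_z",
    "level_means",
    "z_mean_var",
    "neighbour_stats",
    "summarize",
    "aggregate_replicates",
]

STAT_NAMES = ("mu_u", "mu_h", "mu_m", "mu_z", "var_z", "covar_z", "rho_z")


@dataclass
class SummaryStats:
    """Steady-state methylation pattern statistics.

    ``covar_z``/``rho_z`` are ``None`` when unavailable (one-site model) or
    undefined (zero variance, e.g. an absorbed all-u chain).
    """

    mu_u: float
    mu_h: float
    mu_m: float
    mu_z: float
    var_z: float
    covar_z: Optional[float]
    rho_z: Optional[float]

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    @classmethod
    def from_json(cls, text: str) -> "SummaryStats":
        return cls(**json.loads(text))


@dataclass
class ReplicateSummary:
    """Per-statistic mean and standard error over n replicate datasets.

    Standard errors are ``None`` for n = 1 and for statistics undefined in
    any replicate.
    """

    mean: dict
    se: dict
    n: int


def _raw(s) -> np.ndarray:
    if isinstance(s, np.ndarray):
        return s
    return np.asarray(s.data) if hasattr(s, "data") else np.asarray(s)


def encode_z(s) -> np.ndarray:
    """Encode a sample matrix (codes 0/1/2 or letters u/h/m) as z in {1,2,3}."""
    data = _raw(s)
    if data.dtype.kind in "US":
        lut = {"u": 1, "h": 2, "m": 3}
        try:
            return np.vectorize(lut.__getitem__, otypes=[np.int8])(data)
        except KeyError as e:
            raise ValueError(f"invalid state symbol {e.args[0]!r}") from e
    data = np.asarray(data)
    if data.size and (data.min() < 0 or data.max() > 2):
        raise ValueError("state codes must be in {0, 1, 2}")
    return (data + 1).astype(np.int8)


def decode_z(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_z`, back to 0/1/2 codes."""
    z = np.asarray(z)
    if z.size and (z.min() < 1 or z.max() > 3):
        raise ValueError("z entries must be in {1, 2, 3}")
    return (z - 1).astype(np.int8)


def _as_state_matrix(s) -> np.ndarray:
    data = np.atleast_2d(_raw(s))
    if data.size == 0:
        raise ValueError("empty sample matrix")
    return data


def level_means(s) -> tuple[float, float, float]:
    """Grand-mean u/h/m indicator levels over all T*N entries."""
    data = _as_state_matrix(s)
    total = data.size
    mu_u = float(np.count_nonzero(data == 0)) / total
    mu_h = float(np.count_nonzero(data == 1)) / total
    mu_m = float(np.count_nonzero(data == 2)) / total
    return mu_u, mu_h, mu_m


def z_mean_var(z: np.ndarray) -> tuple[float, float]:
    """Row-wise mean and (N-1)-denominator variance of z, averaged over rows."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] < 2:
        raise ValueError("need at least 2 sites for the site-to-site variance")
    mu_t = z.mean(axis=1)
    var_t = np.sum((z - mu_t[:, None]) ** 2, axis=1) / (z.shape[1] - 1)
    return float(mu_t.mean()), float(var_t.mean())


def neighbour_stats(z: np.ndarray) -> tuple[float, Optional[float]]:
    """Neighbour covariance and correlation of z on the circle.

    Per row, v is the row itself and w its cyclic shift by one site; the
    covariance uses the row mean of z and denominator N, then rows are
    averaged.  The correlation divides by the (N-1)-denominator variance
    from :func:`z_mean_var` and is ``None`` when that variance is zero.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] < 2:
        raise ValueError("need at least 2 sites for neighbour statistics")
    mu_t = z.mean(axis=1)
    v = z - mu_t[:, None]
    w = np.roll(z, -1, axis=1) - mu_t[:, None]
    covar = float(np.mean(np.sum(v * w, axis=1) / z.shape[1]))
    _, var_z = z_mean_var(z)
    rho = covar / var_z if var_z > 0 else None
    return covar, rho


def summarize(s) -> SummaryStats:
    """All seven statistics of a sample matrix."""
    data = _as_state_matrix(s)
    mu_u, mu_h, mu_m = level_means(data)
    z = encode_z(data)
    mu_z, var_z = z_mean_var(z)
    covar_z, rho_z = neighbour_stats(z)
    return SummaryStats(
        mu_u=mu_u, mu_h=mu_h, mu_m=mu_m,
        mu_z=mu_z, var_z=var_z, covar_z=covar_z, rho_z=rho_z,
    )


def aggregate_replicates(stats: Sequence[SummaryStats]) -> ReplicateSummary:
    """Mean and standard error of each statistic over replicate datasets.

    SE uses the (n-1)-denominator sample standard deviation divided by
    sqrt(n); it is ``None`` for n = 1.  A statistic undefined (``None``) in
    any replicate is reported as ``None``.
    """
    n = len(stats)
    if n == 0:
        raise ValueError("no replicates to aggregate")
    mean: dict = {}
    se: dict = {}
    for name in STAT_NAMES:
        vals = [getattr(s, name) for s in stats]
        if any(v is None for v in vals):
            mean[name] = None
            se[name] = None
            continue
        arr = np.asarray(vals, dtype=float)
        mean[name] = float(arr.mean())
        se[name] = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return ReplicateSummary(mean=mean, se=se, n=n)
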