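"""Two-sample Z tests on means and Pearson correlation with its P value.

These mirror the significance machinery used throughout the comparisons:
population means are compared with Z = (m1 - m2) / sqrt(SEM1^2 + SEM2^2)
against the standard normal, and correlations are tested by transforming r
to a t statistic with n-2 degrees of freedom (two-tailed throughout, no
multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ZTestResult:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    z: float
    p: float
    n_a: int
    n_b: int


@dataclass
class CorrelationResult:
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    method: str = "t"


def z_test(values_a, values_b) -> ZTestResult:
    """Two-sample Z test from group means and standard errors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("z_test requires at least 2 observations per group")
    sem_a = float(np.std(a, ddof=1) / np.sqrt(a.size))
    sem_b = float(np.std(b, ddof=1) / np.sqrt(b.size))
    denom = np.hypot(sem_a, sem_b)
    if denom == 0:
        z = 0.0 if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
    else:
        z = float((np.mean(a) - np.mean(b)) / denom)
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    p = min(p, 1.0)
    return ZTestResult(
        mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
        sem_a=sem_a, sem_b=sem_b, z=z, p=p, n_a=int(a.size), n_b=int(b.size),
    )


def z_test_from_summary(mean_a: float, sem_a: float, mean_b: float, sem_b: float) -> tuple[float, float]:
    """Z and two-tailed P from already-computed means and SEMs."""
    denom = np.hypot(sem_a, sem_b)
    z = float((mean_a - mean_b) / denom) if denom > 0 else (0.0 if mean_a == mean_b else np.inf)
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return z, min(p, 1.0)


def pearson_with_p(x, y, method: str = "t") -> CorrelationResult:
    """Pearson r with a two-tailed P value and the least-squares line.

    method='t' (default): t = r·sqrt(n-2)/sqrt(1-r^2) against Student t with
    n-2 df. method='fisher': Fisher z-transform against the standard normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    n = int(x.size)
    if n < 3:
        raise ValueError("pearson_with_p requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    p = p_from_r(r, n, method=method)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(n=n, r=r, p=p, slope=float(slope), intercept=float(intercept),
                             method=method)


def p_from_r(r: float, n: int, method: str = "t") -> float:
    """Two-tailed P for a Pearson correlation of ``r`` at sample size ``n``."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    if method == "t":
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        return float(2.0 * sps.t.sf(abs(t), df=n - 2))
    if method == "fisher":
        z = np.arctanh(r) * np.sqrt(n - 3)
        return float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")
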