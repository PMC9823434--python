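"""Dual-waveband emission ratio and the regression surface.

In cyanobacteria most chlorophyll *a* sits in photosystem I, which emits
near 730 nm and carries no variable fluorescence, so the dark-level
emission ratio F_o(730/685) rises with the cyanobacterial share of the
community — especially under the green-orange-red (GOR) excitation that
targets phycobilipigments.  The ratio (and other F_o markers) is related to
(relative) group abundance by ordinary least squares with a two-sided
t-test on the slope and the adjusted R^2 for a single predictor,
adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EmissionRatioRecord",
    "RegressionResult",
    "emission_ratio",
    "relative_abundance",
    "ols_regress",
    "format_p_value",
]


@dataclass(frozen=True)
class EmissionRatioRecord:
    """One sample's dual-waveband dark-level emission measurement."""

    sample_id: str
    protocol: str
    F_o_685: float
    F_o_730: float

    def __post_init__(self) -> None:
        if self.F_o_685 <= 0 or self.F_o_730 < 0:
            raise ValueError("F_o(685) must be > 0 and F_o(730) >= 0")

    @property
    def ratio_730_685(self) -> float:
        return emission_ratio(self.F_o_685, self.F_o_730)


def emission_ratio(F_o_685: float, F_o_730: float) -> float:
    """F_o(730) / F_o(685); elevated by cyanobacterial PSI chlorophyll."""
    if F_o_685 <= 0:
        raise ValueError("F_o(685) must be > 0")
    return F_o_730 / F_o_685


def relative_abundance(counts: dict[str, float]) -> dict[str, float]:
    """Group fractions of total cell density; sums to 1."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("total count must be > 0")
    return {k: v / total for k, v in counts.items()}


@dataclass
class RegressionResult:
    """Simple-linear-regression summary (slope t-test, adjusted R^2)."""

    n: int
    slope: float
    intercept: float
    p_value: float
    r2: float
    adj_R2: float
    predictor_name: str = "x"
    response_name: str = "y"

    def __str__(self) -> str:
        return (f"{self.response_name} ~ {self.predictor_name}: "
                f"n={self.n}, slope={self.slope:.4g}, "
                f"p={format_p_value(self.p_value)}, adj R^2={self.adj_R2:.3f}")


def format_p_value(p: float, floor: float = 1e-15) -> str:
    """Avoid spurious precision below the reporting floor."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"


def ols_regress(x, y, predictor_name: str = "x",
                response_name: str = "y") -> RegressionResult:
    """Closed-form simple OLS with a two-sided slope t-test.

    Implemented directly (normal equations + Student t on n-2 degrees of
    freedom) rather than through a model-fitting framework; the test suite
    cross-checks it against an independent reference implementation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    dof = n - 2
    if rss <= 0:
        p_value = 0.0
    else:
        se = np.sqrt(rss / dof / sxx)
        t_stat = slope / se
        p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(n=n, slope=slope, intercept=float(intercept),
                            p_value=p_value, r2=float(r2),
                            adj_R2=float(adj_r2),
                            predictor_name=predictor_name,
                            response_name=response_name)
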