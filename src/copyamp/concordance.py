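"""Agreement between WGS-derived and qPCR-derived copy-number estimates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
from scipy import stats


@dataclass
class ConcordanceResult:
    n: int
    r: float
    r_squared: float
    slope: float
    intercept: float
    strains: List[str]
    residuals: Dict[str, float]
    missing: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need >= 3 paired strains")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def concord(
    wgs: Mapping[str, float], qpcr: Mapping[str, float]
) -> ConcordanceResult:
    """Pearson correlation and ordinary least-squares fit of qPCR estimates
    on WGS estimates, paired by strain id.

    Strains missing from either map are listed, never imputed.  Zero
    variance in either variable is an error naming the variable.
    """
    shared = sorted(set(wgs) & set(qpcr))
    missing = sorted((set(wgs) | set(qpcr)) - set(shared))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired strains, got {len(shared)}")
    x = np.array([float(wgs[s]) for s in shared])
    y = np.array([float(qpcr[s]) for s in shared])
    for name, v in (("wgs", x), ("qpcr", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {name} estimates")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    residuals = {
        s: float(yi - (fit.slope * xi + fit.intercept))
        for s, xi, yi in zip(shared, x, y)
    }
    return ConcordanceResult(
        n=len(shared),
        r=r,
        r_squared=r * r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        strains=shared,
        residuals=residuals,
        missing=missing,
    )
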