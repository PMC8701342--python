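"""Relative quantification by the ΔΔCT method and rank-based group tests.

Fold difference = 2^-((Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator)
with amplification efficiency fixed at 1 (doubling per cycle) unless
overridden.  Technical triplicates are collapsed first; biological
replicates are the units entering group comparisons.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SPREAD_FLAG_CYCLES = 0.5  # max-min across technical replicates


@dataclass
class QpcrMeasurement:
    """Technical-replicate Ct values for one gene in one biological
    replicate of one sample."""

    sample: str
    replicate: int
    gene: str
    role: str  # "target" or "reference"
    cts: List[float]

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise ValueError(f"role must be target/reference, got {self.role!r}")
        if not self.cts:
            raise ValueError("at least one technical replicate required")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError("Ct values must be > 0")


@dataclass
class RelativeQuantity:
    sample: str
    delta_ct: float
    delta_delta_ct: float
    quantity: float  # 2 ** -ΔΔCt, fold vs calibrator
    calibrator: str


def collapse_triplicates(m: QpcrMeasurement) -> Tuple[float, bool]:
    """Arithmetic mean Ct; flag if max - min exceeds 0.5 cycles."""
    cts = np.asarray(m.cts, dtype=float)
    return float(cts.mean()), bool(cts.max() - cts.min() > SPREAD_FLAG_CYCLES)


def ddct(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
    sample: str = "sample",
    calibrator: str = "calibrator",
    efficiency: float = 1.0,
) -> RelativeQuantity:
    """ΔCt = target - reference; ΔΔCt vs the calibrator; quantity = base^-ΔΔCt
    with base = 1 + efficiency (2 at perfect efficiency)."""
    for v in (target_ct, reference_ct, calibrator_target_ct, calibrator_reference_ct):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    dct = target_ct - reference_ct
    dct_cal = calibrator_target_ct - calibrator_reference_ct
    ddct_val = dct - dct_cal
    quantity = (1.0 + efficiency) ** (-ddct_val)
    return RelativeQuantity(sample, dct, ddct_val, quantity, calibrator)


def quantify_plate(
    measurements: Iterable[QpcrMeasurement],
    calibrator: str,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Per-biological-replicate ΔΔCT quantities for a whole plate.

    Triplicates are collapsed per (sample, replicate, role); the calibrator
    ΔCt is the mean over the calibrator's biological replicates.  Returns a
    DataFrame with columns sample, replicate, delta_ct, delta_delta_ct,
    quantity, spread_flag.
    """
    collapsed: Dict[Tuple[str, int], Dict[str, Tuple[float, bool]]] = {}
    for m in measurements:
        entry = collapsed.setdefault((m.sample, m.replicate), {})
        if m.role in entry:
            raise ValueError(
                f"duplicate {m.role} measurement for {m.sample} replicate {m.replicate}"
            )
        entry[m.role] = collapse_triplicates(m)
    rows = []
    for (sample, rep), entry in collapsed.items():
        if "target" not in entry or "reference" not in entry:
            raise ValueError(
                f"{sample} replicate {rep}: need both target and reference"
            )
        dct = entry["target"][0] - entry["reference"][0]
        rows.append(
            {
                "sample": sample,
                "replicate": rep,
                "delta_ct": dct,
                "spread_flag": entry["target"][1] or entry["reference"][1],
            }
        )
    df = pd.DataFrame(rows)
    if calibrator not in set(df["sample"]):
        raise ValueError(f"calibrator {calibrator!r} absent from plate")
    dct_cal = float(df.loc[df["sample"] == calibrator, "delta_ct"].mean())
    df["delta_delta_ct"] = df["delta_ct"] - dct_cal
    df["quantity"] = (1.0 + efficiency) ** (-df["delta_delta_ct"])
    df["calibrator"] = calibrator
    return df.sort_values(["sample", "replicate"]).reset_index(drop=True)


def sample_quantities(per_replicate: pd.DataFrame) -> Dict[str, float]:
    """One quantity per sample: base^-(mean ΔΔCt over biological replicates)."""
    out = {}
    for sample, grp in per_replicate.groupby("sample"):
        out[str(sample)] = float(2.0 ** (-grp["delta_delta_ct"].mean()))
    return out


def compare_groups(
    quantities_a: Sequence[float], quantities_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact distribution when both groups have n <= 10; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(quantities_a, dtype=float)
    b = np.asarray(quantities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(a.size, b.size) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def adjust(pvals: Sequence[float], method: str = "fdr_bh") -> List[float]:
    """Multiple-testing adjustment (Benjamini-Hochberg by default; "holm"
    also supported)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("fdr_bh", "holm"):
        raise ValueError(f"unsupported adjustment method {method!r}")
    return list(multipletests(p, method=method)[1])


def read_qpcr_csv(path) -> List[QpcrMeasurement]:
    """Read a plate CSV with columns sample,target,role,replicate,ct
    (one row per technical Ct value)."""
    groups: Dict[Tuple[str, str, str, int], List[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "target", "role", "replicate", "ct"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            key = (row["sample"], row["target"], row["role"], int(row["replicate"]))
            groups.setdefault(key, []).append(float(row["ct"]))
    return [
        QpcrMeasurement(sample, rep, gene, role, cts)
        for (sample, gene, role, rep), cts in groups.items()
    ]
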