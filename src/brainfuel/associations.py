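"""Cross-sectional association layer.

Correlations between brain fuel uptake, cognition, structure and
peripheral insulin resistance are computed on per-subject averages
across visits.  Insulin resistance is indexed by HOMA-IR
(glucose[mM] * insulin[uU/mL] / 22.5); cognition is summarized per
domain as a composite z-score of population-normed scaled scores
(mean 10, SD 3).  Reported ``r`` is the Pearson coefficient, identical
to the standardized slope of the simple linear regression of y on x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COGNITIVE_TESTS

__all__ = [
    "COGNITIVE_DOMAINS",
    "homa_ir",
    "composite_z",
    "subject_average",
    "pearson_association",
    "AssociationResult",
    "association_matrix",
]

#: domain -> list of scaled-score test stems
COGNITIVE_DOMAINS: dict[str, list[str]] = {}
for _test, _domain in COGNITIVE_TESTS.items():
    COGNITIVE_DOMAINS.setdefault(_domain, []).append(_test)

_SCALED_MEAN = 10.0
_SCALED_SD = 3.0


def homa_ir(glucose_mM, insulin_uUI) -> float | np.ndarray:
    """HOMA-IR insulin-resistance index: glucose * insulin / 22.5."""
    glucose_mM = np.asarray(glucose_mM, dtype=float)
    insulin_uUI = np.asarray(insulin_uUI, dtype=float)
    if np.any(glucose_mM <= 0):
        raise ValueError("glucose must be positive")
    if np.any(insulin_uUI < 0):
        raise ValueError("insulin must be non-negative")
    out = glucose_mM * insulin_uUI / 22.5
    return out if out.ndim else float(out)


def composite_z(scores: dict[str, float] | pd.Series, domain: str) -> float:
    """Composite z-score of one cognitive domain.

    Each available scaled score s maps to (s - 10)/3; the composite is
    the mean over the domain's tests, missing tests excluded.
    """
    if domain not in COGNITIVE_DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {sorted(COGNITIVE_DOMAINS)}")
    zs = []
    for test in COGNITIVE_DOMAINS[domain]:
        val = scores.get(test, scores.get(f"scaled_{test}"))
        if val is not None and np.isfinite(val):
            zs.append((float(val) - _SCALED_MEAN) / _SCALED_SD)
    if not zs:
        raise ValueError(f"no scores available for domain {domain!r}")
    return float(np.mean(zs))


def subject_average(
    records: pd.DataFrame,
    subject_col: str = "subject_id",
    drop: tuple[str, ...] = ("visit",),
) -> pd.DataFrame:
    """Per-subject mean of every numeric column across available visits.

    A ``n_visits`` column records how many visits each average spans.
    """
    numeric = records.select_dtypes(include=[np.number]).columns.difference(drop)
    grouped = records.groupby(subject_col)
    out = grouped[list(numeric)].mean()
    out["n_visits"] = grouped.size()
    return out.reset_index()


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between two per-subject variables, with the
    equivalent simple-regression slope and intercept."""

    r: float
    p_value: float
    n: int
    x_label: str
    y_label: str
    slope: float
    intercept: float

    def summary(self) -> str:
        return (
            f"{self.y_label} ~ {self.x_label}: r={self.r:+.3f}, "
            f"p={self.p_value:.4g}, n={self.n}"
        )


def pearson_association(x, y, x_label: str = "x", y_label: str = "y") -> AssociationResult:
    """Pearson r with the two-sided t-test on n-2 df.

    Pairs with a missing value in either variable are dropped
    (pairwise-complete); the effective n is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    slope = r * y.std(ddof=1) / x.std(ddof=1)
    intercept = y.mean() - slope * x.mean()
    return AssociationResult(
        r=float(r), p_value=float(p), n=n,
        x_label=x_label, y_label=y_label,
        slope=float(slope), intercept=float(intercept),
    )


def association_matrix(subject_means: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Associations for a list of (x, y) column pairs of a per-subject
    table; returns a tidy frame (x_label, y_label, r, p, n, slope)."""
    rows = []
    for x_col, y_col in pairs:
        try:
            res = pearson_association(
                subject_means[x_col], subject_means[y_col], x_label=x_col, y_label=y_col
            )
            rows.append(dict(x_label=x_col, y_label=y_col, r=res.r, p=res.p_value,
                             n=res.n, slope=res.slope))
        except ValueError as exc:
            rows.append(dict(x_label=x_col, y_label=y_col, r=np.nan, p=np.nan,
                             n=0, slope=np.nan, note=str(exc)))
    return pd.DataFrame(rows)
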