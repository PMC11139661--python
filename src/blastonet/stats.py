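"""Group comparisons: Gardner-grade dichotomization, pooled two-sample
t-tests (raw and summary forms) and bootstrap Spearman correlation.

The pooled (Student) form is used rather than Welch: recomputing the
blastulation comparison from printed group summaries (means 2.54 vs 2.30,
SDs 0.46 vs 0.61, n 203 vs 35) reproduces the published statistic 2.713
under pooling, while Welch gives ~2.2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    GradeParseError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)

__all__ = [
    "OutcomeRecord",
    "TTestResult",
    "gardner_quality",
    "pooled_t_test",
    "pooled_t_from_summary",
    "spearman_bootstrap",
]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    group_summaries: tuple  # ((mean, sd, n), (mean, sd, n))


@dataclass
class OutcomeRecord:
    """Per-embryo clinical labels.

    ``quality`` is derived from the Gardner grade when absent.  Pregnancy,
    live-birth and miscarriage labels are meaningful only for transferred
    embryos.
    """

    embryo_id: str
    blastulated: bool | None = None
    gardner: str | None = None
    quality: str | None = None  # "good" | "poor"
    transferred: bool = False
    biochemical_pregnancy: bool | None = None
    live_birth: bool | None = None
    miscarriage: bool | None = None
    euploid: bool | None = None

    def __post_init__(self):
        if not self.transferred and (
            self.live_birth is not None or self.miscarriage is not None
        ):
            raise InvalidParameterError(
                f"{self.embryo_id}: live_birth/miscarriage set on a "
                "non-transferred embryo"
            )
        if self.quality is None and self.gardner is not None:
            self.quality = gardner_quality(self.gardner)
        if self.quality is not None and self.quality not in ("good", "poor"):
            raise InvalidParameterError(
                f"{self.embryo_id}: quality must be 'good' or 'poor'"
            )


_GRADE_RE = re.compile(r"^\s*([1-6])\s*([A-Ca-c])?\s*([A-Ca-c])?\s*$")


def gardner_quality(grade: str) -> str:
    """Dichotomize a Gardner grade: 'good' iff expansion >= 3, ICM in {A,B}
    and TE in {A,B}; otherwise 'poor'.

    Grades with expansion <= 2 may omit the ICM/TE letters (and are always
    'poor'); otherwise the letters are required.
    """
    if not isinstance(grade, str):
        raise GradeParseError(f"expected a grade string, got {grade!r}")
    m = _GRADE_RE.match(grade)
    if not m:
        raise GradeParseError(f"unparseable Gardner grade: {grade!r}")
    exp = int(m.group(1))
    icm, te = m.group(2), m.group(3)
    if exp <= 2:
        return "poor"
    if icm is None or te is None:
        raise GradeParseError(
            f"grade {grade!r}: ICM/TE letters required for expansion >= 3"
        )
    good = icm.upper() in ("A", "B") and te.upper() in ("A", "B")
    return "good" if good else "poor"


def _summaries(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), int(len(x))


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TTestResult:
    """Student's pooled-variance two-sample t-test from sufficient
    statistics; two-sided p-value."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise InsufficientDataError("SDs must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        raise InsufficientDataError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(
        t_statistic=float(t),
        degrees_of_freedom=int(df),
        p_value=float(p),
        group_summaries=((m1, s1, n1), (m2, s2, n2)),
    )


def pooled_t_test(x, y) -> TTestResult:
    """Student's pooled-variance two-sample t-test on raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs >= 2 values")
    m1, s1, n1 = _summaries(x)
    m2, s2, n2 = _summaries(y)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            # identical constants: no evidence of difference
            return TTestResult(0.0, n1 + n2 - 2, 1.0, ((m1, s1, n1), (m2, s2, n2)))
        raise InsufficientDataError("zero pooled variance with unequal means")
    return pooled_t_from_summary(m1, s1, n1, m2, s2, n2)


def spearman_bootstrap(
    x,
    y,
    n_boot: int = 10000,
    conf: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Spearman rank correlation with a percentile bootstrap CI.

    Pairs are resampled with replacement ``n_boot`` times; the CI is the
    percentile interval of the resampled correlations.  Ties get average
    ranks.  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be paired 1-d samples")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if not (0.0 < conf < 1.0):
        raise InvalidParameterError("conf must be in (0, 1)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant sample")

    rho = float(sps.spearmanr(x, y).statistic)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rx = sps.rankdata(x[idx], axis=1)
    ry = sps.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = (rx * ry).sum(axis=1) / denom
    boot = boot[np.isfinite(boot)]  # drop constant resamples
    if boot.size == 0:
        raise UndefinedCorrelationError("all bootstrap resamples degenerate")
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return rho, float(lo), float(hi)
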