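"""Validation-side statistics: qPCR relative quantification, IHC weighted
scoring, Spearman rank correlation and the Mann-Whitney U test.

Relative qPCR quantification uses the comparative threshold-cycle method:
dCt = Ct(target) - Ct(reference) per sample, ddCt = dCt(case) - dCt(control
calibrator), fold change = 2^(-ddCt). With several control records the
calibrator is the mean control dCt.

The IHC weighted score is c = a * b where a bins the percentage of positive
cells (0: <5%, 1: 5-25%, 2: 25-50%, 3: 50-75%, 4: >75%; boundaries resolved
lower-inclusive) and b grades staining intensity 0-3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str  # "case" | "control"
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("target", self.ct_target), ("reference", self.ct_reference)):
            if not 0 < ct < 50:
                raise ValueError(
                    f"{self.sample_id}: Ct ({name}) must lie in (0, 50), got {ct}"
                )

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class IHCRecord:
    sample_id: str
    percent_positive: float
    intensity: int  # b, 0..3

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValueError(f"{self.sample_id}: percent_positive out of [0, 100]")
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"{self.sample_id}: intensity must be 0..3")

    @property
    def a(self) -> int:
        return ihc_bin_percent(self.percent_positive)

    @property
    def score(self) -> int:
        return ihc_score(self.a, self.intensity)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float


def ddct_fold(
    case: CtRecord | Sequence[CtRecord], control: CtRecord | Sequence[CtRecord]
) -> float:
    """2^(-ddCt) fold change of the case group relative to control.

    Accepts single records or groups; groups are summarised by their mean
    dCt (the standard single-calibrator convention).
    """
    cases = [case] if isinstance(case, CtRecord) else list(case)
    controls = [control] if isinstance(control, CtRecord) else list(control)
    if not cases or not controls:
        raise ValueError("both groups need at least one record")
    ddct = float(np.mean([r.dct for r in cases]) - np.mean([r.dct for r in controls]))
    return float(2.0 ** (-ddct))


_IHC_BIN_EDGES = (5.0, 25.0, 50.0, 75.0)


def ihc_bin_percent(percent: float) -> int:
    """Bin percent positive cells into grade a (half-open, lower-inclusive)."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent out of [0, 100]: {percent}")
    a = 0
    for edge in _IHC_BIN_EDGES:
        if percent >= edge:
            a += 1
    return a


def ihc_score(a: int, b: int) -> int:
    """Weighted IHC score c = a * b."""
    if a not in range(5):
        raise ValueError(f"percent grade a must be 0..4, got {a}")
    if b not in range(4):
        raise ValueError(f"intensity b must be 0..3, got {b}")
    return a * b


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation: Pearson on mid-ranks, large-sample t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, n=int(n), p=p)


def _u_from_ranks(pooled_ranks: np.ndarray, n1: int) -> float:
    r1 = float(pooled_ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U (mid-ranks for ties) with two-sided p.

    Exact p by enumerating all group labelings of the pooled sample when
    n1 + n2 <= ``exact_threshold``; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = _u_from_ranks(ranks, n1)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= exact_threshold:
        # permutation-exact under the null: every assignment of n1 of the
        # pooled values to group 1 is equally likely
        dev = abs(u - mu)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_perm = float(ranks[mask].sum()) - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= dev - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return float(u), 1.0
        z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(max(z, 0.0)))
    return float(u), min(1.0, float(p))
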