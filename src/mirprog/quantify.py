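"""Expression normalisation and replicate-free differential expression.

The study design has one library per (patient, stage) with no biological
replicates, so differential expression between two libraries is assessed
with the Audic-Claverie exact count test: conditional on observing count x
in a library of size N1, the count y in an independent library of size N2
follows

    p(y | x) = r^y * (x+y)! / (x! * y! * (1+r)^(x+y+1)),   r = N2/N1,

which is the negative-binomial law NB(x+1, 1/(1+r)). Tail probabilities are
computed through that identity (log-space, safe for counts up to 1e7); the
two-sided p-value doubles the smaller tail and is capped at 1.

Normalisation is RPKM (1e9 * C / (N * L)) when feature lengths are known
(mRNA) and counts per million (1e6 * C / N) otherwise (miRNA tags).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_ABS_LOG2FC = 1.0  # the two-fold difference cutoff
DEFAULT_MAX_Q = 0.05


@dataclass
class ExpressionMatrix:
    """Normalised expression values (RPKM or counts per million)."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str  # "RPKM" | "per_million"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit not in ("RPKM", "per_million"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def value(self, feature_id: str, sample_id: str) -> float:
        return float(
            self.values[
                self.feature_ids.index(feature_id), self.sample_ids.index(sample_id)
            ]
        )

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass(frozen=True)
class DECountPair:
    """One feature's counts in two libraries with their library sizes."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library sizes must be >= 1")
        if self.x > self.n1 or self.y > self.n2:
            raise ValueError("count exceeds its library size")


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    log2fc: float  # condition 2 vs condition 1
    p: float
    q: float
    direction: str  # up | down | none


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """RPKM: 1e9 * C / (N * L); requires per-feature lengths."""
    if counts.feature_lengths is None:
        raise ValueError("RPKM requires feature lengths")
    values = (
        1e9
        * counts.counts
        / (counts.library_sizes[None, :] * counts.feature_lengths[:, None])
    )
    return ExpressionMatrix(counts.feature_ids, counts.sample_ids, values, "RPKM")


def compute_per_million(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million mapped tags: 1e6 * C / N."""
    values = 1e6 * counts.counts / counts.library_sizes[None, :]
    return ExpressionMatrix(counts.feature_ids, counts.sample_ids, values, "per_million")


def normalize(counts: CountMatrix) -> ExpressionMatrix:
    """RPKM when lengths are available, per-million otherwise."""
    if counts.feature_lengths is not None:
        return compute_rpkm(counts)
    return compute_per_million(counts)


def log2_ratio(a, b, pseudo: float = DEFAULT_PSEUDOCOUNT):
    """log2((a + pseudo) / (b + pseudo)); defined (0) for a = b = 0."""
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("expression values must be non-negative")
    out = np.log2((a + pseudo) / (b + pseudo))
    if out.ndim == 0:
        return float(out)
    return out


def ac_log_pmf(y, x, n1, n2):
    """Log point probability of the Audic-Claverie conditional law."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    log_r = np.log(n2) - np.log(n1)
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.logaddexp(0.0, log_r)
    )


def ac_exact_test(pair: DECountPair | None = None, alternative: str = "two_sided",
                  *, x=None, y=None, n1=None, n2=None):
    """Replicate-free exact test p-value for one count per condition.

    Accepts either a :class:`DECountPair` or vectorised keyword arrays.
    ``alternative``: two_sided (doubled smaller tail, capped at 1),
    greater (P(Y >= y | x)), or less (P(Y <= y | x)).
    """
    if pair is not None:
        x, y, n1, n2 = pair.x, pair.y, pair.n1, pair.n2
    x = np.asarray(x)
    y = np.asarray(y)
    r = np.asarray(n2, dtype=float) / np.asarray(n1, dtype=float)
    # Y | x ~ NB(x + 1, 1 / (1 + r))
    succ = 1.0 / (1.0 + r)
    lower = stats.nbinom.cdf(y, x + 1, succ)     # P(Y <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, succ)  # P(Y >= y)
    if alternative == "two_sided":
        p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    elif alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.maximum(p, np.finfo(float).tiny)  # exact test p is in (0, 1]
    if p.ndim == 0:
        return float(p)
    return p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_call(
    feature_id: str,
    pair: DECountPair,
    q: float | None = None,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_q: float = DEFAULT_MAX_Q,
) -> DEResult:
    """Call a feature up/down/none between two libraries.

    The fold change is taken on per-million-normalised values (condition 2
    vs condition 1) with a pseudocount; the p-value is the two-sided exact
    test. ``q`` is the FDR-adjusted p from the enclosing family; when the
    feature is tested alone it defaults to its own p.
    """
    a = 1e6 * pair.y / pair.n2
    b = 1e6 * pair.x / pair.n1
    lfc = log2_ratio(a, b, pseudo)
    p = ac_exact_test(pair, "two_sided")
    if q is None:
        q = p
    direction = "none"
    if abs(lfc) >= min_abs_log2fc and q <= max_q:
        direction = "up" if lfc > 0 else "down"
    return DEResult(feature_id, lfc, p, q, direction)


def write_de_table(results: Sequence[DEResult], pairs: Sequence[DECountPair], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "count_A": [pr.x for pr in pairs],
            "count_B": [pr.y for pr in pairs],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "direction": [r.direction for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
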