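"""Correlation and comparison statistics for effect measures.

Thin, typed wrappers over scipy.stats: Pearson and Spearman correlation
with two-sided p-values from the t transform, the Fisher r-to-z test for
comparing two independent correlation coefficients, and a paired test on
per-electrode slope pairs.  Sample sizes in AGF studies are small (often
n = 9 animals), so the p-values here are the standard large-sample
approximations and should be read accordingly; Spearman ties are handled
by average ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation coefficient with its sample size and p-value."""

    r: float
    n: int
    p: float
    method: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"|r| must be <= 1, got {self.r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.method} r = {self.r:.3f} (n = {self.n}, p = {self.p:.3g})"


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Requires equal-length finite sequences of at least 3 points and
    non-degenerate variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return CorrelationResult(
        r=float(res.statistic), n=int(x.size), p=float(res.pvalue), method=method
    )


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Compare two independent correlations via the Fisher z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.  Requires |r| < 1 and n >= 4 in each sample.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise DomainError(f"|r| must be < 1 for the z transform, got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValidationError(f"each sample needs n >= 4, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def paired_slope_test(slopes_a: Sequence[float], slopes_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on per-electrode slope pairs.

    A deliberate reduction of a subject-random-factor repeated-measures
    ANOVA to its paired core: with two conditions per electrode the
    paired t-test asks the same question (does condition shift the
    slope?) without modelling the unbalanced electrode-within-subject
    nesting.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("need two equal-length sequences of >= 2 pairs")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
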