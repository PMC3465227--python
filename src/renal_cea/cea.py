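"""Cost-effectiveness statistics.

Incremental comparisons are comparator-minus-reference deltas of
per-patient annual cost (ΔC, €) and QALY (ΔE); the incremental
cost-effectiveness ratio is ICER = ΔC/ΔE where defined.  At a
willingness-to-pay threshold λ, the comparator is *acceptable* when it is
dominant (no dearer, more effective) or efficient (more effective at
ICER ≤ λ, or cheaper while forgoing QALYs at more than λ apiece).
Acceptability curves report, over Monte-Carlo draws, the probability of
positive net monetary benefit NMB = λ·ΔE − ΔC as λ varies; the confidence
ellipse is the normal-theory χ²₂ contour of the (ΔE, ΔC) cloud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DegenerateCovarianceError
from .markov import OutcomeSummary


class Category(str, Enum):
    DOMINANT = "dominant"
    EFFICIENT_HIGHER_EFFECTIVENESS = "efficient_higher_effectiveness"
    EFFICIENT_LOWER_COST = "efficient_lower_cost"
    DOMINATED = "dominated"
    NOT_ACCEPTABLE = "not_acceptable"


#: Categories that count as "acceptable" at the threshold.
ACCEPTABLE = frozenset({Category.DOMINANT,
                        Category.EFFICIENT_HIGHER_EFFECTIVENESS,
                        Category.EFFICIENT_LOWER_COST})
#: Acceptable without any loss of effectiveness.
NO_EFFECTIVENESS_LOSS = frozenset({Category.DOMINANT,
                                   Category.EFFICIENT_HIGHER_EFFECTIVENESS})


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    category: Category


def classify(delta_cost: float, delta_qaly: float, wtpt: float) -> Category:
    """Assign the unique cost-effectiveness category of a (ΔC, ΔE) point.

    Dominant: no dearer and strictly more effective (or strictly cheaper
    and no less effective).  Dominated is the mirror image.  In the
    trade-off quadrants the threshold decides: more effectiveness bought
    at ICER ≤ λ is efficient, cost savings of at least λ per QALY forgone
    are efficient; everything else is not acceptable.
    """
    if wtpt < 0:
        raise ValueError("wtpt must be >= 0")
    dc, de = delta_cost, delta_qaly
    if (dc <= 0 and de > 0) or (dc < 0 and de >= 0):
        return Category.DOMINANT
    if (dc >= 0 and de < 0) or (dc > 0 and de <= 0):
        return Category.DOMINATED
    if dc > 0 and de > 0:
        return (Category.EFFICIENT_HIGHER_EFFECTIVENESS
                if dc / de <= wtpt else Category.NOT_ACCEPTABLE)
    if dc < 0 and de < 0:
        return (Category.EFFICIENT_LOWER_COST
                if dc / de >= wtpt else Category.NOT_ACCEPTABLE)
    return Category.NOT_ACCEPTABLE  # ΔC = ΔE = 0


def incremental(reference: OutcomeSummary, comparator: OutcomeSummary,
                wtpt: float = 45_000.0) -> IncrementalResult:
    """Comparator-minus-reference deltas on the per-patient annual basis."""
    for s in (reference, comparator):
        if s.per_patient_annual_cost is None or s.per_patient_annual_qaly is None:
            raise ValueError("summaries must be annualized before comparison")
    dc = comparator.per_patient_annual_cost - reference.per_patient_annual_cost
    de = comparator.per_patient_annual_qaly - reference.per_patient_annual_qaly
    icer = dc / de if de != 0 else None
    return IncrementalResult(delta_cost=dc, delta_qaly=de, icer=icer,
                             category=classify(dc, de, wtpt))


@dataclass
class CeacCurve:
    """Acceptance probability of each scenario over a threshold grid.

    At each λ the comparator's acceptance is the fraction of draws with
    positive net monetary benefit (ties split equally); the reference
    receives the complement, so the two curves sum to one everywhere.
    """

    wtpt_values: np.ndarray
    acceptance: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"wtpt": self.wtpt_values, **self.acceptance})


def ceac(samples: np.ndarray, wtpt_grid: np.ndarray,
         comparator: str = "T", reference: str = "L") -> CeacCurve:
    """Acceptability curves from Monte-Carlo (ΔC, ΔE) pairs.

    ``samples`` has one row per draw, columns (ΔC, ΔE), deltas taken
    comparator minus reference.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("ceac requires at least one sample")
    grid = np.asarray(wtpt_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("ceac requires a non-empty threshold grid")
    dc, de = samples[:, 0], samples[:, 1]
    nmb = grid[:, None] * de[None, :] - dc[None, :]
    acc = (np.mean(nmb > 0, axis=1) + 0.5 * np.mean(nmb == 0, axis=1))
    return CeacCurve(wtpt_values=grid,
                     acceptance={comparator: acc, reference: 1.0 - acc})


def restricted_acceptance(samples: np.ndarray, wtpt: float,
                          comparator: str = "T", reference: str = "L"
                          ) -> dict[str, float]:
    """Acceptance probabilities over the no-effectiveness-loss draws only.

    Keeps the draws in which one scenario is dominant or efficient with
    higher effectiveness (for the comparator as classified, for the
    reference after sign flip) and renormalizes so the two probabilities
    sum to one.
    """
    samples = np.asarray(samples, dtype=float)
    comp = sum(classify(dc, de, wtpt) in NO_EFFECTIVENESS_LOSS
               for dc, de in samples)
    ref = sum(classify(-dc, -de, wtpt) in NO_EFFECTIVENESS_LOSS
              for dc, de in samples)
    if comp + ref == 0:
        raise ValueError("no draws without loss of effectiveness for either scenario")
    return {comparator: comp / (comp + ref), reference: ref / (comp + ref)}


def category_frequencies(samples: np.ndarray, wtpt: float,
                         comparator: str = "T", reference: str = "L"
                         ) -> dict[str, dict[str, float]]:
    """Per-scenario relative frequency of each category at the threshold."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    out = {}
    for label, sign in ((comparator, 1.0), (reference, -1.0)):
        counts = {c.value: 0 for c in Category}
        for dc, de in samples:
            counts[classify(sign * dc, sign * de, wtpt).value] += 1
        freq = {c: counts[c] / n for c in counts}
        freq["acceptable"] = sum(freq[c.value] for c in ACCEPTABLE)
        out[label] = freq
    return out


@dataclass
class EllipseSpec:
    """Normal-theory confidence ellipse of a bivariate sample cloud.

    The boundary is ``(x - center)ᵀ Σ⁻¹ (x - center) = χ²₂(level)`` with Σ
    the sample covariance.
    """

    center: np.ndarray
    covariance: np.ndarray
    level: float
    chi2_quantile: float

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership test (boundary counts as inside)."""
        return self.mahalanobis_sq(points) <= self.chi2_quantile

    def boundary(self, n: int = 200) -> np.ndarray:
        """Polyline of ``n`` boundary points, for plotting."""
        theta = np.linspace(0.0, 2.0 * math.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        L = np.linalg.cholesky(self.covariance)
        return self.center + math.sqrt(self.chi2_quantile) * circle @ L.T


def confidence_ellipse(samples: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Fit the χ²₂ confidence ellipse to a bivariate sample."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] < 3:
        raise DegenerateCovarianceError(
            "confidence ellipse needs at least 3 bivariate samples")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    center = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise DegenerateCovarianceError("sample covariance is singular")
    return EllipseSpec(center=center, covariance=cov, level=level,
                       chi2_quantile=float(stats.chi2.ppf(level, df=2)))
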