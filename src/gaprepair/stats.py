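"""Between-strain statistical comparisons.

Efficiency comparisons operate on *scaled ratio distributions*: each
transformation's normalized His+:Leu+ ratio multiplied by a fixed
per-strain proportion (CO-type, NCO-type, unidirectional-type or
bidirectional-type), compared between strains with a two-tailed
pooled-variance Student's t-test.  Count comparisons (CO vs NCO tallies)
use the two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .efficiency import NormalizedRatio

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class ScaledRatioSample:
    strain: str
    values: tuple[float, ...]


def scaled_ratio_distribution(
    normalized: "list[NormalizedRatio] | np.ndarray", proportion: float
) -> ScaledRatioSample:
    """Multiply each normalized ratio by a fixed proportion.

    The sample mean of the result equals repair efficiency times the
    proportion, i.e. the corresponding decomposed efficiency.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if len(normalized) and isinstance(normalized[0], NormalizedRatio):
        strain = normalized[0].strain
        values = np.array([r.value for r in normalized], dtype=float)
    else:
        strain = ""
        values = np.asarray(normalized, dtype=float)
    return ScaledRatioSample(strain=strain, values=tuple(values * proportion))


def student_t_two_tailed(a, b, welch: bool = False) -> float:
    """Two-tailed two-sample t-test p-value.

    Pooled-variance Student's test by default (matching the published
    analysis); ``welch=True`` switches to the Welch-Satterthwaite
    variant.  Fully degenerate input (both samples constant and equal)
    returns p = 1 by convention and logs the event.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return _degenerate_p(diff)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        if se2 == 0:
            return _degenerate_p(diff)
        df = n1 + n2 - 2
    t = diff / math.sqrt(se2)
    return float(2.0 * _st.t.sf(abs(t), df))


def _degenerate_p(diff: float) -> float:
    if diff == 0:
        logger.warning("degenerate t-test: zero variance and equal means; p = 1 by convention")
        return 1.0
    logger.warning("degenerate t-test: zero variance with unequal means; p = 0")
    return 0.0


def fisher_exact_2x2(a1: int, a2: int, b1: int, b2: int) -> float:
    """Two-sided Fisher exact p for the table [[a1, a2], [b1, b2]].

    Uses the point-probability rule: the sum of hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Two-sided
    conventions differ between tools; this one matches common 2x2
    calculators.
    """
    cells = (a1, a2, b1, b2)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be nonnegative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    _, p = _st.fisher_exact([[a1, a2], [b1, b2]], alternative="two-sided")
    return float(p)


def is_significant(p: float, alpha: float = ALPHA) -> bool:
    """Asterisk convention of the published tables: p < 0.05."""
    return p < alpha
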