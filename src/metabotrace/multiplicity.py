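"""Effective number of tests via PCA and Bonferroni thresholding.

Metabolic measures are heavily collinear, so a Bonferroni correction
over the raw measure count is too conservative.  The effective number
of independent tests is taken as the smallest number of leading
principal components whose eigenvalues account for a target fraction
(default 99%) of the total variance of the standardized data; the
per-test significance threshold is ``alpha`` divided by that count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["effective_tests", "bonferroni_threshold", "MultiplicityResult",
           "multiplicity_summary"]


@dataclass
class MultiplicityResult:
    n_components: int
    variance_target: float
    n_effective_tests: int
    alpha: float
    threshold: float

    def to_json(self, path=None) -> str:
        text = json.dumps(vars(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def effective_tests(z, variance_target: float = 0.99) -> int:
    """Smallest k such that the top-k covariance eigenvalues reach the
    variance target.

    ``z`` is a complete (no NaN) matrix or DataFrame of standardized
    columns; covariance PCA is used, which coincides with correlation
    PCA for unit-variance columns.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    x = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    if np.isnan(x).any():
        raise ValueError("NaN in input; impute or drop before PCA")
    cov = np.cov(x, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    cum = np.cumsum(eig) / total
    # guard the exact-target case against float round-off
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return min(k, eig.size)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test p threshold: alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def multiplicity_summary(
    z, variance_target: float = 0.99, alpha: float = 0.05,
    n_effective_tests: int | None = None,
) -> MultiplicityResult:
    """PCA component count and the implied Bonferroni threshold.

    ``n_effective_tests`` overrides the PCA count when a more
    conservative external value is preferred.
    """
    k = effective_tests(z, variance_target)
    n_eff = k if n_effective_tests is None else int(n_effective_tests)
    return MultiplicityResult(
        n_components=k,
        variance_target=variance_target,
        n_effective_tests=n_eff,
        alpha=alpha,
        threshold=bonferroni_threshold(n_eff, alpha),
    )
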