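"""Shared permutation-test plumbing.

All permutation P-values in the package use the add-one estimator
p = (b + 1) / (B + 1), where b counts permuted statistics at least as
extreme as the observed one.  When b = 0 the result additionally carries
the reportable bound "< 1/B" (the paper-style "P < 1e-4" at B = 10000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    b: int
    n_perm: int

    @property
    def p_value(self) -> float:
        return (self.b + 1) / (self.n_perm + 1)

    @property
    def bound(self) -> float | None:
        """Reportable upper bound 1/B when no permutation reached the observed value."""
        return 1.0 / self.n_perm if self.b == 0 else None

    def __str__(self) -> str:
        s = f"perm P = {self.p_value:.4g} (b={self.b}, B={self.n_perm})"
        if self.bound is not None:
            s += f", P < {self.bound:g}"
        return s


def count_as_extreme(perm_stats: np.ndarray, observed: float) -> int:
    """b = #{permuted >= observed}; NaN permutations count as extreme (conservative)."""
    perm = np.asarray(perm_stats, dtype=float)
    return int((np.isnan(perm) | (perm >= observed)).sum())
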