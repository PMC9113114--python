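"""Benjamini-Hochberg step-up false-discovery-rate control.

Implements the step-up rule directly: with ordered p-values p(1) <= ... <=
p(m) and target rate q, reject all hypotheses up to the largest k with
p(k) <= k q / m.  ``p_crit`` is that largest passing threshold k q / m
(reported as q / m, the smallest rung, when nothing passes -- the bound the
minimum p failed to meet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BHFamily:
    family: str
    pvalues: tuple[float, ...]
    q: float
    p_crit: float
    rejected: tuple[bool, ...]  # in input order

    @property
    def n_rejected(self) -> int:
        return int(sum(self.rejected))


def benjamini_hochberg(pvalues, q: float = 0.05, family: str = "") -> BHFamily:
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresholds)
    if passing.size:
        k = int(passing[-1]) + 1
        p_crit = float(thresholds[k - 1])
        rejected = np.zeros(m, dtype=bool)
        rejected[order[:k]] = True
    else:
        p_crit = float(thresholds[0])
        rejected = np.zeros(m, dtype=bool)
    return BHFamily(
        family=family,
        pvalues=tuple(p.tolist()),
        q=q,
        p_crit=p_crit,
        rejected=tuple(rejected.tolist()),
    )
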