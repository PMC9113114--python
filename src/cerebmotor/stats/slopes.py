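"""Simple-slopes probing of interactions with a two-level moderator.

For a model containing ``focal`` and ``focal x moderator``, the slope of the
focal predictor at moderator level m (coded 0/1) is

    beta_focal + m * beta_interaction (+ m * any higher-order terms held at 0)

with standard error from the corresponding linear combination of the fixed
effect covariance.  The difference between the two level slopes equals the
interaction coefficient exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .design import FACTOR_LEVELS
from .lmm import FittedModel


@dataclass(frozen=True)
class SimpleSlope:
    moderator: str
    level: object  # original factor level, e.g. "TD"
    slope: float
    se: float
    df: float
    t: float
    p: float


def _match_term(names, parts: set[str]) -> str | None:
    for name in names:
        if name != "Intercept" and set(name.split(":")) == parts:
            return name
    return None


def simple_slopes(
    fitted: FittedModel, focal: str, moderator: str
) -> list[SimpleSlope]:
    """Slope of ``focal`` at each level of a two-level ``moderator``."""
    if moderator not in FACTOR_LEVELS:
        raise ValueError(
            f"moderator {moderator!r} is not a categorical design factor"
        )
    names = list(fitted.params.index)
    focal_term = _match_term(names, {focal})
    inter_term = _match_term(names, {focal, moderator})
    if focal_term is None:
        raise ValueError(f"no main effect for focal predictor {focal!r}")
    if inter_term is None:
        raise ValueError(f"model has no {focal} x {moderator} interaction")
    out = []
    for code, level in enumerate(FACTOR_LEVELS[moderator]):
        c = np.zeros(len(names))
        c[names.index(focal_term)] = 1.0
        c[names.index(inter_term)] = float(code)
        est, se, df = fitted.contrast(c)
        t = est / se
        out.append(
            SimpleSlope(
                moderator=moderator,
                level=level,
                slope=est,
                se=se,
                df=df,
                t=t,
                p=float(2 * sps.t.sf(abs(t), df)),
            )
        )
    return out
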