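"""Synthetic cohort generation.

Emulates a case-control sensorimotor study of autism spectrum disorder (ASD)
versus typically developing (TD) controls: demographics, per-hand maximum
voluntary contraction (MVC, in Newtons), and ASD-only clinical scores (ADOS-2
calibrated severity score on its 1-10 scale; RBS-R total).  Defaults are
calibrated to the published cohort table of the study this pipeline targets
(58 ASD / 34 TD, ages 8-30).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .._trunc import ppf_matched, rvs_matched

#: correlation between left- and right-hand MVC (Gaussian copula)
MVC_HAND_RHO = 0.9

AGE_RANGE_DEFAULT = (8.0, 30.0)
ADOS_CSS_RANGE = (1.0, 10.0)


@dataclass(frozen=True)
class GroupParams:
    """Per-group marginal moments (mean, sd) for cohort fields."""

    n: int
    age: tuple[float, float]
    prop_female: float
    prop_right_handed: float
    mvc_left: tuple[float, float]
    mvc_right: tuple[float, float]


@dataclass(frozen=True)
class CohortConfig:
    asd: GroupParams = GroupParams(
        n=58,
        age=(15.7, 4.9),
        prop_female=21 / 58,
        prop_right_handed=0.793,
        mvc_left=(57.8, 22.0),
        mvc_right=(55.0, 20.7),
    )
    td: GroupParams = GroupParams(
        n=34,
        age=(17.1, 5.6),
        prop_female=18 / 34,
        prop_right_handed=0.912,
        mvc_left=(71.3, 26.8),
        mvc_right=(70.8, 27.4),
    )
    age_range: tuple[float, float] = AGE_RANGE_DEFAULT
    ados_css: tuple[float, float] = (5.9, 2.3)
    rbsr_total: tuple[float, float] = (29.5, 19.0)
    seed: int = 0

    def __post_init__(self):
        for g in (self.asd, self.td):
            if g.n <= 0:
                raise ValueError("group sizes must be positive")
            for m, s in (g.age, g.mvc_left, g.mvc_right):
                if s < 0:
                    raise ValueError("SDs must be non-negative")
            if not (0.0 <= g.prop_female <= 1.0):
                raise ValueError("prop_female must be in [0, 1]")
        if self.ados_css[1] < 0 or self.rbsr_total[1] < 0:
            raise ValueError("SDs must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")


def _group_frame(
    label: str, p: GroupParams, cfg: CohortConfig, rng: np.random.Generator, start_id: int
) -> pd.DataFrame:
    n = p.n
    # deterministic sex / handedness counts: the design is matched, not sampled
    n_f = int(round(p.prop_female * n))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    n_r = int(round(p.prop_right_handed * n))
    handed = np.array(["right"] * n_r + ["left"] * (n - n_r))
    rng.shuffle(handed)  # decouple handedness from sex ordering

    lo, hi = cfg.age_range
    age = rvs_matched(p.age[0], p.age[1], lo, hi, n, rng)

    # correlated hands via Gaussian copula; marginals stay moment-matched
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, MVC_HAND_RHO], [MVC_HAND_RHO, 1.0]], size=n
    )
    u = norm.cdf(z)
    mvc_l = ppf_matched(u[:, 0], p.mvc_left[0], p.mvc_left[1], 0.0, np.inf)
    mvc_r = ppf_matched(u[:, 1], p.mvc_right[0], p.mvc_right[1], 0.0, np.inf)

    df = pd.DataFrame(
        {
            "participant_id": [f"P{start_id + i:04d}" for i in range(n)],
            "group": label,
            "sex": sex,
            "age": age,
            "handedness": handed,
            "mvc_left": mvc_l,
            "mvc_right": mvc_r,
        }
    )
    if label == "ASD":
        df["ados_css"] = rvs_matched(
            cfg.ados_css[0], cfg.ados_css[1], *ADOS_CSS_RANGE, n, rng
        )
        df["rbsr_total"] = rvs_matched(
            cfg.rbsr_total[0], cfg.rbsr_total[1], 0.0, np.inf, n, rng
        )
    else:
        df["ados_css"] = np.nan
        df["rbsr_total"] = np.nan
    return df


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """One record per participant; identical config+seed => identical frame."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    asd = _group_frame("ASD", cfg.asd, cfg, rng, start_id=1)
    td = _group_frame("TD", cfg.td, cfg, rng, start_id=1 + cfg.asd.n)
    return pd.concat([asd, td], ignore_index=True)
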