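"""Disease-specific time-lag functions.

A dietary change does not shift mortality instantly: the fraction of the
full hazard change realised ``t`` years after adoption follows an s-shaped
curve, modelled as a normal CDF rescaled onto the active interval so that
the weight is exactly 0 at the onset delay and exactly 1 at the
full-effect time.

Two disease classes are built in: cardiometabolic outcomes (coronary heart
disease, stroke, type 2 diabetes) reach full effect after 10 years with no
onset delay; cancers have a 10-year onset delay and reach full effect at
30 years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class LagFunction:
    """Fraction of a hazard change realised as a function of time.

    ``weight(t)`` is 0 for ``t <= onset_delay``, 1 for
    ``t >= full_effect_time``, and a rescaled normal CDF (location ``mean``,
    scale ``sd``) in between — continuous and non-decreasing throughout.
    """

    disease_class: str
    onset_delay: float
    full_effect_time: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.onset_delay < self.full_effect_time:
            raise ValueError("require 0 <= onset_delay < full_effect_time")
        if self.sd <= 0:
            raise ValueError("lag curve sd must be positive")

    def weight(self, t: float | np.ndarray) -> float | np.ndarray:
        """Lag weight in [0, 1] at time ``t`` (years since adoption)."""
        t_arr = np.asarray(t, float)
        if (t_arr < 0).any():
            raise ValueError("time since adoption must be non-negative")
        lo = norm.cdf(self.onset_delay, self.mean, self.sd)
        hi = norm.cdf(self.full_effect_time, self.mean, self.sd)
        raw = (norm.cdf(t_arr, self.mean, self.sd) - lo) / (hi - lo)
        out = np.clip(raw, 0.0, 1.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


#: Default lag curves per disease class.  The cardiometabolic curve rises
#: over (0, 10) years (CDF location 5, scale 2); the cancer curve over
#: (10, 30) years (location 20, scale 3.3).
CARDIOMETABOLIC_LAG = LagFunction("cardiometabolic", 0.0, 10.0, 5.0, 2.0)
CANCER_LAG = LagFunction("cancer", 10.0, 30.0, 20.0, 3.3)

#: Degenerate lag whose weight jumps to 1 immediately after adoption; used
#: for no-lag analyses and closed-form checks.
INSTANT_LAG = LagFunction("instant", 0.0, 1e-9, 5e-10, 1e-10)

#: Disease-class assignment for the modelled outcomes.
DISEASE_CLASSES: dict[str, str] = {
    "coronary_heart_disease": "cardiometabolic",
    "stroke": "cardiometabolic",
    "type2_diabetes": "cardiometabolic",
    "oral_cancer": "cancer",
    "oesophageal_cancer": "cancer",
    "lung_cancer": "cancer",
    "stomach_cancer": "cancer",
    "colorectal_cancer": "cancer",
}

_DEFAULTS = {"cardiometabolic": CARDIOMETABOLIC_LAG, "cancer": CANCER_LAG}


def default_lags(diseases: list[str] | tuple[str, ...]) -> dict[str, LagFunction]:
    """Map each disease to its class's default lag curve.

    Unknown diseases fall back on the cancer curve if their name contains
    ``cancer``, else the cardiometabolic curve.
    """
    out = {}
    for d in diseases:
        cls = DISEASE_CLASSES.get(d, "cancer" if "cancer" in d else "cardiometabolic")
        out[d] = _DEFAULTS[cls]
    return out
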