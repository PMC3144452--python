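"""Loss to follow-up imposed on an already-drawn sample.

Two scenarios are modelled: a purely random loss (non-informative censoring,
default 15%) and a loss differential by occupational stratum (default 8% for
professionals, 12% for technicians, 20% for administrative staff - the
hardest-hit stratum is also the highest-hazard one, making the censoring
informative).

Mechanism: loss converts *event* records to censored records.  Only records
with ``event == 1`` are eligible; each is independently selected with its
applicable rate and, under the default ``censor_at_event`` mechanism, keeps
its observed time but has the event flag set to 0 (the subject drops out
exactly when the event would have been recorded).  An alternative
``uniform_dropout`` mechanism instead redraws the observed time uniformly on
(0, t) for the lost records; it is available for sensitivity analysis and is
never the default.  Weights, strata and record counts are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError

__all__ = ["LossSpec", "apply_loss"]

#: the study's differential loss rates by stratum
DEFAULT_DIFFERENTIAL = {
    "professionals": 0.08,
    "technicians": 0.12,
    "administrative": 0.20,
}


@dataclass(frozen=True)
class LossSpec:
    """Loss-to-follow-up scenario.

    ``mode`` is ``none``, ``random`` (single ``rate``) or ``differential``
    (``rates_by_stratum``, one entry per stratum).  Rates are fractions of
    *event* individuals lost.
    """

    mode: str = "none"
    rate: float | None = None
    rates_by_stratum: dict | None = None
    mechanism: str = "censor_at_event"

    def __post_init__(self):
        if self.mode not in ("none", "random", "differential"):
            raise InvalidParameterError(f"unknown loss mode {self.mode!r}")
        if self.mechanism not in ("censor_at_event", "uniform_dropout"):
            raise InvalidParameterError(f"unknown loss mechanism {self.mechanism!r}")
        if self.mode == "random":
            if self.rate is None or not (0.0 <= self.rate <= 1.0):
                raise InvalidParameterError("random loss requires rate in [0, 1]")
        if self.mode == "differential":
            if not self.rates_by_stratum:
                raise InvalidParameterError("differential loss requires rates_by_stratum")
            for h, r in self.rates_by_stratum.items():
                if not (0.0 <= r <= 1.0):
                    raise InvalidParameterError(f"loss rate for {h!r} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {"mode": self.mode}
        if self.rate is not None:
            d["rate"] = self.rate
        if self.rates_by_stratum is not None:
            d["rates_by_stratum"] = dict(self.rates_by_stratum)
        if self.mechanism != "censor_at_event":
            d["mechanism"] = self.mechanism
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "LossSpec":
        known = {"mode", "rate", "rates_by_stratum", "mechanism"}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown loss keys: {sorted(unknown)}")
        return cls(**mapping)


def apply_loss(sample: pd.DataFrame, loss: LossSpec, seed: int) -> pd.DataFrame:
    """Return a copy of ``sample`` with loss to follow-up imposed.

    Deterministic under a fixed seed; ``mode='none'`` returns an unmodified
    copy.  Raises if a differential spec misses a stratum present in the
    sample.
    """
    out = sample.copy()
    if loss.mode == "none":
        return out

    event = np.asarray(out["event"], dtype=int)
    if loss.mode == "random":
        rates = np.full(len(out), float(loss.rate))
    else:
        strata = out["stratum"].astype(str)
        missing = set(strata.unique()) - set(loss.rates_by_stratum)
        if missing:
            raise InvalidParameterError(
                f"rates_by_stratum missing strata: {sorted(missing)}"
            )
        rates = strata.map(loss.rates_by_stratum).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    u = rng.random(len(out))
    lost = (event == 1) & (u < rates)
    out.loc[lost, "event"] = 0
    if loss.mechanism == "uniform_dropout":
        t = out.loc[lost, "time"].to_numpy(dtype=float)
        frac = rng.random(lost.sum())
        frac = np.maximum(frac, np.finfo(float).tiny)  # keep times > 0
        out.loc[lost, "time"] = frac * t
    return out
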