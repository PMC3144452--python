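"""Sample designs: simple random and non-proportional stratified sampling.

Both designs sample without replacement and attach the design weight
w_i = 1/pi_i (inverse selection probability) to every record: N/n under
simple random sampling and N_h/n_h within stratum h under stratified
sampling, so the weights always sum to the population size
(Horvitz-Thompson identity).  The study design these defaults emulate
oversamples the smaller, higher-hazard strata: 3,000 professionals, 4,500
technicians and 7,500 administrative staff out of a 52,750-person cohort.

A sample table is a cohort table plus ``weight`` and ``design_kind`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .population import COHORT_COLUMNS

__all__ = [
    "DesignSpec",
    "SAMPLE_COLUMNS",
    "draw_srs",
    "draw_stratified",
    "draw_sample",
    "write_sample",
    "read_sample",
]

SAMPLE_COLUMNS = COHORT_COLUMNS + ("weight", "design_kind")

#: the study's non-proportional allocation (n_h per stratum)
DEFAULT_ALLOCATION = {
    "professionals": 3000,
    "technicians": 4500,
    "administrative": 7500,
}


@dataclass(frozen=True)
class DesignSpec:
    """A sampling design: ``simple_random`` (total n) or ``stratified`` (n_h)."""

    kind: str
    sample_size: int | None = None
    allocation: dict | None = None

    def __post_init__(self):
        if self.kind not in ("simple_random", "stratified"):
            raise InvalidParameterError(f"unknown design kind {self.kind!r}")
        if self.kind == "simple_random":
            if not (isinstance(self.sample_size, int) and self.sample_size >= 1):
                raise InvalidParameterError("simple_random requires sample_size >= 1")
        else:
            if not self.allocation:
                raise InvalidParameterError("stratified requires an allocation")
            for h, nh in self.allocation.items():
                if not (isinstance(nh, int) and nh >= 1):
                    raise InvalidParameterError(f"allocation for {h!r} must be >= 1")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.sample_size is not None:
            d["sample_size"] = self.sample_size
        if self.allocation is not None:
            d["allocation"] = dict(self.allocation)
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "DesignSpec":
        known = {"kind", "sample_size", "allocation"}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown design keys: {sorted(unknown)}")
        return cls(**mapping)


def _take(cohort: pd.DataFrame, idx: np.ndarray, weight, kind: str) -> pd.DataFrame:
    out = cohort.iloc[np.sort(idx)].copy()
    out["weight"] = weight
    out["design_kind"] = kind
    return out.reset_index(drop=True)


def draw_srs(cohort: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Simple random sample of ``n`` records without replacement, weight N/n."""
    N = len(cohort)
    if not (1 <= n <= N):
        raise InvalidParameterError(f"sample size {n} outside [1, {N}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(N, size=n, replace=False)
    return _take(cohort, idx, N / n, "simple_random")


def draw_stratified(cohort: pd.DataFrame, allocation: dict, seed: int) -> pd.DataFrame:
    """Stratified sample without replacement, weight N_h/n_h within stratum h.

    ``allocation`` must name exactly the strata present in the cohort.
    Sub-seeds for the per-stratum draws are spawned deterministically from
    ``seed``, keyed by allocation order.
    """
    strata = cohort["stratum"].astype(str)
    present = set(strata.unique())
    if set(allocation) != present:
        raise InvalidParameterError(
            f"allocation strata {sorted(allocation)} do not match cohort strata "
            f"{sorted(present)}"
        )
    ss = np.random.SeedSequence(seed)
    parts = []
    for k, (h, n_h) in enumerate(allocation.items()):
        pos = np.flatnonzero((strata == h).to_numpy())
        N_h = len(pos)
        if n_h > N_h:
            raise InvalidParameterError(
                f"allocation {n_h} exceeds stratum {h!r} population {N_h}"
            )
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        take = rng.choice(N_h, size=n_h, replace=False)
        parts.append(_take(cohort, pos[take], N_h / n_h, "stratified"))
    return pd.concat(parts, ignore_index=True)


def draw_sample(cohort: pd.DataFrame, design: DesignSpec, seed: int) -> pd.DataFrame:
    """Dispatch on :class:`DesignSpec`."""
    if design.kind == "simple_random":
        return draw_srs(cohort, design.sample_size, seed)
    return draw_stratified(cohort, design.allocation, seed)


def write_sample(sample: pd.DataFrame, path) -> None:
    sample.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False)


def read_sample(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"sample table missing columns: {sorted(missing)}")
    return df
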