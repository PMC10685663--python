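"""Observed-data containers: individual survival times, aggregate external
survivor counts, known background hazards, and elicited survival judgements.

External aggregate data rows state that of ``n`` people alive at time ``u``,
``r`` were still alive at time ``v``.  An elicited Beta(a, b) judgement about
the survival probability over an interval carries the same information as
having observed ``r = a`` survivors out of ``n = a + b``, so elicitations are
converted to external-count rows and enter the model the same way.  Counts
may be real-valued since Beta shapes need not be integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndividualData",
    "ExternalData",
    "BackgroundHazard",
    "Elicitation",
    "elicitation_to_counts",
    "beta_interval",
    "read_individual",
    "read_external",
    "read_background",
    "write_individual",
    "write_external",
    "write_background",
]

_RESERVED_IND = ("time", "event")
_RESERVED_EXT = ("start", "stop", "n", "r")


def _as_cov_frame(covariates, nrow: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(nrow))
    df = pd.DataFrame(covariates)
    if len(df) != nrow:
        raise ValueError("covariate rows do not match data rows")
    return df.reset_index(drop=True)


@dataclass
class IndividualData:
    """Right-censored individual-level survival data.

    ``time`` holds the observed survival or censoring time (>= 0) and
    ``event`` is 1 for an observed event, 0 for right-censoring.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be 1-d and equal length")
        bad = np.where(self.time < 0)[0]
        if bad.size:
            raise ValueError(f"negative time in row {bad[0]}")
        if not np.isin(self.event, (0, 1)).all():
            bad = np.where(~np.isin(self.event, (0, 1)))[0]
            raise ValueError(f"event must be 0 or 1 (row {bad[0]})")
        self.event = self.event.astype(int)
        self.covariates = _as_cov_frame(self.covariates, len(self.time))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def event_times(self) -> np.ndarray:
        """Times of the uncensored observations."""
        return self.time[self.event == 1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        return pd.concat([df, self.covariates], axis=1)


@dataclass
class ExternalData:
    """Aggregate external survival counts: of ``n`` alive at ``u``, ``r``
    survived to ``v``.  Real-valued counts are allowed (elicited data)."""

    u: np.ndarray
    v: np.ndarray
    n: np.ndarray
    r: np.ndarray
    covariates: pd.DataFrame = None

    def __post_init__(self):
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        shapes = {a.shape for a in (self.u, self.v, self.n, self.r)}
        if len(shapes) != 1:
            raise ValueError("u, v, n, r must have equal length")
        for name, cond in [
            ("u must be >= 0", self.u < 0),
            ("u must be < v", self.u >= self.v),
            ("n must be >= 1", self.n < 1),
            ("r must be >= 0", self.r < 0),
            ("r must be <= n", self.r > self.n),
        ]:
            bad = np.where(cond)[0]
            if bad.size:
                raise ValueError(f"{name} (row {bad[0]})")
        self.covariates = _as_cov_frame(self.covariates, len(self.u))

    def __len__(self) -> int:
        return len(self.u)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"start": self.u, "stop": self.v, "n": self.n, "r": self.r})
        return pd.concat([df, self.covariates], axis=1)

    @staticmethod
    def concat(parts: list["ExternalData"]) -> "ExternalData":
        return ExternalData(
            u=np.concatenate([p.u for p in parts]),
            v=np.concatenate([p.v for p in parts]),
            n=np.concatenate([p.n for p in parts]),
            r=np.concatenate([p.r for p in parts]),
            covariates=pd.concat(
                [p.covariates for p in parts], ignore_index=True
            ),
        )


@dataclass
class BackgroundHazard:
    """Known piecewise-constant background hazard.

    ``rates[i]`` applies on ``[breakpoints[i], breakpoints[i+1])``; the last
    rate extends to infinity.  Breakpoints start at 0.
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.breakpoints.size != self.rates.size:
            raise ValueError("need one rate per breakpoint")
        if self.breakpoints[0] != 0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    def hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        return self.rates[np.clip(idx, 0, len(self.rates) - 1)]

    def cumhaz(self, t) -> np.ndarray:
        """Exact cumulative hazard: sum of rate x interval overlap."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ends = np.append(self.breakpoints[1:], np.inf)
        overlap = np.clip(
            t[:, None] - self.breakpoints[None, :], 0.0, None
        ) - np.clip(t[:, None] - ends[None, :], 0.0, None)
        return overlap @ self.rates

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cumhaz(t))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.breakpoints,
                "stop": np.append(self.breakpoints[1:], np.inf),
                "rate": self.rates,
            }
        )


@dataclass
class Elicitation:
    """A Beta(a, b) judgement about the probability of surviving (u, v]."""

    a: float
    b: float
    u: float
    v: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes must be positive")
        if not 0 <= self.u < self.v:
            raise ValueError("need 0 <= u < v")


def elicitation_to_counts(e: Elicitation) -> ExternalData:
    """Convert an elicited Beta(a, b) survival judgement to pseudo-counts.

    Reading the Beta as the posterior from a vague Beta(0, 0) prior and
    binomial data gives r = a survivors out of n = a + b at risk.
    """
    cov = pd.DataFrame([e.covariates]) if e.covariates else None
    return ExternalData(u=[e.u], v=[e.v], n=[e.a + e.b], r=[e.a], covariates=cov)


def beta_interval(a: float, b: float, level: float = 0.95) -> tuple[float, float]:
    """Central credible interval of a Beta(a, b) distribution."""
    if a <= 0 or b <= 0:
        raise ValueError("Beta shapes must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1 - level) / 2
    lo, hi = stats.beta.ppf([alpha, 1 - alpha], a, b)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_cols(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} data missing columns: {missing}")


def read_individual(source) -> IndividualData:
    df = pd.read_csv(source)
    _require_cols(df, _RESERVED_IND, "individual")
    extra = [c for c in df.columns if c not in _RESERVED_IND]
    return IndividualData(
        time=df["time"].to_numpy(),
        event=df["event"].to_numpy(),
        covariates=df[extra] if extra else None,
    )


def read_external(source) -> ExternalData:
    df = pd.read_csv(source)
    _require_cols(df, _RESERVED_EXT, "external")
    extra = [c for c in df.columns if c not in _RESERVED_EXT]
    return ExternalData(
        u=df["start"].to_numpy(),
        v=df["stop"].to_numpy(),
        n=df["n"].to_numpy(),
        r=df["r"].to_numpy(),
        covariates=df[extra] if extra else None,
    )


def read_background(source) -> BackgroundHazard:
    df = pd.read_csv(source)
    _require_cols(df, ("start", "stop", "rate"), "background")
    return BackgroundHazard(
        breakpoints=df["start"].to_numpy(), rates=df["rate"].to_numpy()
    )


def write_individual(data: IndividualData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_external(data: ExternalData, path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_background(bg: BackgroundHazard, path) -> None:
    bg.to_frame().to_csv(path, index=False)
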