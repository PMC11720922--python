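"""Case-base sampling of person-moments from right-censored survival data.

Case-base sampling turns a survival dataset into a binary-outcome dataset:
the *case series* holds one person-moment per observed event (at its event
time), and the *base series* holds ``b`` person-moments drawn uniformly from
the study base, i.e. uniformly over the total person-time ``B``.  A logistic
model fitted to the pooled series with the fixed offset ``log(B/b)`` added to
the linear predictor estimates the log-hazard directly, because the odds of a
sampled person-moment being a case equal ``h(t|X) / (b/B)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "SamplingSpec",
    "PersonMomentTable",
    "total_person_time",
    "offset_value",
    "case_base_sample",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """One row per individual: follow-up time, event indicator, covariates.

    Parameters
    ----------
    time:
        Strictly positive follow-up times (event or censoring), length n.
    event:
        0/1 event indicators, length n.
    covariates:
        DataFrame of numeric covariates, n rows, no missing values.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time must be a non-empty 1-d array")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("follow-up times must be strictly positive and finite")
        if event.shape != time.shape:
            raise ValueError("event and time must have the same length")
        if not np.all(np.isin(event, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        if len(self.covariates) != time.size:
            raise ValueError("covariates must have one row per individual")
        if self.covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        non_num = [
            c
            for c in self.covariates.columns
            if not np.issubdtype(self.covariates[c].dtype, np.number)
        ]
        if non_num:
            raise ValueError(f"non-numeric covariate columns: {non_num}")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        event_col: str = "event",
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalDataset":
        if covariate_cols is None:
            covariate_cols = [c for c in df.columns if c not in (time_col, event_col)]
        return cls(
            time=df[time_col].to_numpy(float),
            event=df[event_col].to_numpy(float),
            covariates=df[covariate_cols].reset_index(drop=True).astype(float),
        )

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        time_col: str = "time",
        event_col: str = "event",
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalDataset":
        return cls.from_dataframe(pd.read_csv(path), time_col, event_col, covariate_cols)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"time": self.time, "event": self.event})
        return pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        """Row subset by positional index (used for train/val/test splits)."""
        index = np.asarray(index)
        return SurvivalDataset(
            time=self.time[index],
            event=self.event[index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
        )


@dataclass(frozen=True)
class SamplingSpec:
    """Bookkeeping for one case-base sample.

    ``b = ratio * c`` base moments are drawn from total person-time ``B``;
    the offset ``log(B/b)`` corrects the sampling-induced bias of the odds.
    """

    ratio: int
    B: float
    b: int
    c: int
    offset: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.b != self.ratio * self.c:
            raise ValueError("b must equal ratio * c")
        expected = offset_value(self.B, self.b)
        if not np.isclose(self.offset, expected, rtol=0, atol=1e-12):
            raise ValueError("offset must equal log(B/b)")

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "B": self.B,
            "b": self.b,
            "c": self.c,
            "offset": self.offset,
            "seed": self.seed,
        }


@dataclass
class PersonMomentTable:
    """Pooled case and base series with the constant sampling offset.

    ``data`` has columns ``moment_time``, the covariates, ``label`` and
    ``source_index``; the offset is stored once (it is the same for every
    row).  Cases come first, in the order of the originating individuals.
    """

    data: pd.DataFrame
    offset: float
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return int((self.data["label"] == 1).sum())

    @property
    def n_base(self) -> int:
        return int((self.data["label"] == 0).sum())

    @property
    def moment_time(self) -> np.ndarray:
        return self.data["moment_time"].to_numpy(float)

    @property
    def label(self) -> np.ndarray:
        return self.data["label"].to_numpy(float)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    def write(self, path: str | Path, spec: SamplingSpec | None = None) -> None:
        """Write moments as CSV plus a JSON sidecar with sampling metadata."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        meta = {"offset": self.offset}
        if spec is not None:
            meta.update(spec.to_dict())
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def total_person_time(data: SurvivalDataset) -> float:
    """Sum of all follow-up times (the study base ``B``)."""
    return float(np.sum(data.time))


def offset_value(B: float, b: int) -> float:
    """The constant ``log(B/b)`` added to the linear predictor when fitting."""
    if B <= 0 or b <= 0:
        raise ValueError("B and b must be positive")
    return float(np.log(B) - np.log(b))


def case_base_sample(
    data: SurvivalDataset,
    ratio: int = 100,
    rng: np.random.Generator | int | None = None,
) -> tuple[PersonMomentTable, SamplingSpec]:
    """Draw the case series and a uniformly sampled base series.

    The case series contains every event at its event time.  Base moments are
    drawn uniformly over the study base by a two-stage draw: an individual is
    selected with probability proportional to its follow-up time (with
    replacement), and the moment within the selected individual is uniform on
    ``(0, time_i]``.

    Parameters
    ----------
    data:
        Survival data with at least one event.
    ratio:
        Base-to-case ratio; ``b = ratio * c`` base moments are drawn.
    rng:
        Seed or ``numpy.random.Generator``.

    Returns
    -------
    (PersonMomentTable, SamplingSpec)
    """
    if int(ratio) != ratio or ratio < 1:
        raise ValueError("ratio must be a positive integer")
    ratio = int(ratio)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    c = data.n_events
    if c == 0:
        raise ValueError("no case series: dataset contains no events")
    b = ratio * c
    B = total_person_time(data)
    offset = offset_value(B, b)

    case_idx = np.flatnonzero(data.event == 1)
    base_idx = rng.choice(data.n, size=b, replace=True, p=data.time / B)
    # uniform on (0, T]: 1 - U with U ~ Uniform[0, 1) avoids an exact zero
    base_t = (1.0 - rng.uniform(size=b)) * data.time[base_idx]

    rows = pd.DataFrame(
        {
            "moment_time": np.concatenate([data.time[case_idx], base_t]),
            "label": np.concatenate([np.ones(c), np.zeros(b)]),
            "source_index": np.concatenate([case_idx, base_idx]),
        }
    )
    cov = pd.concat(
        [data.covariates.iloc[case_idx], data.covariates.iloc[base_idx]],
        axis=0,
        ignore_index=True,
    )
    table = pd.concat([rows[["moment_time"]], cov, rows[["label", "source_index"]]], axis=1)
    spec = SamplingSpec(ratio=ratio, B=B, b=b, c=c, offset=offset, seed=seed)
    return PersonMomentTable(table, offset, data.covariate_names), spec
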