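"""Patient-level survival dataset container.

A :class:`SurvivalDataset` bundles follow-up time (years), the death
indicator and a covariate table (metabolite concentrations and optional
clinical variables).  Missing covariate values are encoded as NaN; the
outcome columns must be complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a named covariate table.

    Parameters
    ----------
    time:
        Follow-up in years, strictly positive.
    event:
        1 if the patient died at ``time``, 0 if censored there.
    covariates:
        One column per covariate; NaN marks a missing measurement.
    covariate_means:
        Optional centering constants stored by a fit (original units).
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    covariate_means: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValidationError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValidationError("follow-up times must be finite and strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) != len(self.time):
            raise ValidationError("covariate table length does not match outcomes")
        self.covariates = self.covariates.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def missing_rates(self) -> pd.Series:
        """Fraction of missing values per covariate."""
        return self.covariates.isna().mean()

    def require_columns(self, names: list[str]) -> None:
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise ValidationError(f"covariates not in dataset: {missing}")

    def complete_cases(self, names: list[str] | None = None) -> "SurvivalDataset":
        """Subset to patients with no missing value among ``names`` (default: all)."""
        names = self.covariate_names if names is None else names
        self.require_columns(names)
        keep = ~self.covariates[names].isna().any(axis=1).to_numpy()
        return self.subset(np.flatnonzero(keep))

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            covariate_means=self.covariate_means,
        )

    def matrix(self, names: list[str]) -> np.ndarray:
        """Covariate matrix (n, p) for the requested columns."""
        self.require_columns(names)
        return self.covariates[names].to_numpy(dtype=float)

    # -- round trip --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "patient_id": np.arange(1, self.n + 1),
                "time_years": self.time,
                "event": self.event,
            }
        )
        return pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalDataset":
        df = pd.read_csv(path)
        for col in ("time_years", "event"):
            if col not in df.columns:
                raise ValidationError(f"required column '{col}' absent from {path}")
        cov = df.drop(columns=[c for c in ("patient_id", "time_years", "event") if c in df])
        return cls(time=df["time_years"].to_numpy(), event=df["event"].to_numpy(), covariates=cov)
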