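"""Snapshot time-series datasets.

A snapshot dataset holds measurements ``y_ij`` of individuals ``i`` (patients,
cells) at times ``t_j``, where each (individual, time, observable) combination
appears at most once.  The canonical on-disk format is a long CSV with columns
``ID, Time, Observable, Value`` (plus an optional ``Covariate`` column); the
matrix form — one N x K matrix per observable, with NA for combinations that
were never measured — is an in-memory view only.  Missing entries contribute
nothing to any likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SnapshotDataset", "read_dataset", "write_dataset"]

_COLUMNS = ["ID", "Time", "Observable", "Value"]
DEFAULT_OBSERVABLE = "value"


@dataclass(frozen=True)
class SnapshotDataset:
    """Validated container for snapshot measurements.

    Parameters
    ----------
    frame
        Long-format table with columns ``ID`` (str), ``Time`` (float),
        ``Observable`` (str), ``Value`` (float) and optionally ``Covariate``
        (one value per individual).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if not np.isfinite(df["Value"].to_numpy(float)).all():
            raise ValueError("dataset values must be finite")
        if not np.isfinite(df["Time"].to_numpy(float)).all() or (
            df["Time"].to_numpy(float) < 0
        ).any():
            raise ValueError("measurement times must be finite and non-negative")
        dup = df.duplicated(subset=["ID", "Time", "Observable"])
        if dup.any():
            rows = df.loc[dup, ["ID", "Time", "Observable"]].head(3)
            raise ValueError(
                f"duplicate (ID, Time, Observable) records, e.g.\n{rows}"
            )
        if "Covariate" in df.columns:
            per_id = df.groupby("ID")["Covariate"].nunique()
            if (per_id > 1).any():
                raise ValueError("covariate must be constant within an individual")
        # deterministic order: IDs lexicographic, times ascending
        df = df.sort_values(["ID", "Time", "Observable"], kind="stable")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    # -- basic properties -------------------------------------------------
    @property
    def times(self) -> np.ndarray:
        """Sorted unique measurement times T (length K)."""
        return np.unique(self.frame["Time"].to_numpy(float))

    @property
    def observables(self) -> list[str]:
        return sorted(self.frame["Observable"].unique())

    @property
    def individual_ids(self) -> list[str]:
        return sorted(self.frame["ID"].unique())

    @property
    def n_individuals(self) -> int:
        return self.frame["ID"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def has_covariates(self) -> bool:
        return "Covariate" in self.frame.columns

    def covariates(self) -> np.ndarray:
        """Per-individual covariate values, ordered like ``individual_ids``."""
        if not self.has_covariates:
            raise ValueError("dataset has no covariate column")
        per_id = self.frame.groupby("ID")["Covariate"].first()
        return per_id.loc[self.individual_ids].to_numpy(float)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records, covariates=None) -> "SnapshotDataset":
        """Build a dataset from an iterable of (id, time, observable, value)."""
        df = pd.DataFrame(records, columns=_COLUMNS)
        df["ID"] = df["ID"].astype(str)
        if covariates is not None:
            df["Covariate"] = df["ID"].map(
                {str(k): v for k, v in covariates.items()}
            )
        return cls(df)

    @classmethod
    def from_arrays(cls, ids, times, values, observable=DEFAULT_OBSERVABLE,
                    covariates=None) -> "SnapshotDataset":
        df = pd.DataFrame(
            {
                "ID": np.asarray(ids).astype(str),
                "Time": np.asarray(times, float),
                "Observable": observable,
                "Value": np.asarray(values, float),
            }
        )
        if covariates is not None:
            df["Covariate"] = np.asarray(covariates, float)
        return cls(df)

    # -- views -------------------------------------------------------------
    def to_matrix(self, observable: str | None = None):
        """Matrix view ``Y`` (N x K, NaN for missing) and times ``T``.

        Rows follow lexicographically sorted IDs, columns ascending times.
        """
        if observable is None:
            obs = self.observables
            if len(obs) != 1:
                raise ValueError(
                    f"dataset has observables {obs}; specify one explicitly"
                )
            observable = obs[0]
        if observable not in self.observables:
            raise KeyError(f"unknown observable {observable!r}")
        sub = self.frame[self.frame["Observable"] == observable]
        ids = self.individual_ids
        times = self.times
        mat = np.full((len(ids), len(times)), np.nan)
        i_idx = pd.Index(ids).get_indexer(sub["ID"])
        j_idx = np.searchsorted(times, sub["Time"].to_numpy(float))
        mat[i_idx, j_idx] = sub["Value"].to_numpy(float)
        return mat, times

    def values_by_time(self, observable: str):
        """List of value arrays, one per time in ``times`` order."""
        mat, times = self.to_matrix(observable)
        return [mat[~np.isnan(mat[:, j]), j] for j in range(len(times))]

    def subset_individuals(self, ids) -> "SnapshotDataset":
        return SnapshotDataset(self.frame[self.frame["ID"].isin(list(ids))].copy())

    # -- io ----------------------------------------------------------------
    def write_csv(self, path) -> None:
        # %.17g round-trips doubles exactly
        self.frame.to_csv(path, index=False, float_format="%.17g")

    def write_wide_csv(self, path, observable: str | None = None) -> None:
        """Optional wide export (one column per time point) for inspection."""
        mat, times = self.to_matrix(observable)
        wide = pd.DataFrame(mat, index=self.individual_ids,
                            columns=[f"t={t:g}" for t in times])
        wide.index.name = "ID"
        wide.to_csv(path)

    def __eq__(self, other):
        if not isinstance(other, SnapshotDataset):
            return NotImplemented
        return self.frame.equals(other.frame)


def read_dataset(path) -> SnapshotDataset:
    """Read a long CSV (columns ID, Time, Observable, Value[, Covariate]).

    The ``Observable`` column may be omitted when there is a single observable.
    Rows with a missing ``Value`` are skipped (they count as NA).
    """
    df = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    if len(df) == 0 or len(df.columns) == 0:
        raise ValueError(f"{path}: empty dataset file")
    if "Observable" not in df.columns:
        df["Observable"] = DEFAULT_OBSERVABLE
    for col in ("ID", "Time", "Value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df[~df["Value"].isna()].copy()
    if len(df) == 0:
        raise ValueError(f"{path}: no non-missing measurement values")
    for col in ("Time", "Value"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "Covariate" in df.columns:
        df["Covariate"] = df["Covariate"].astype(float)
    df["ID"] = df["ID"].astype(str)
    keep = _COLUMNS + (["Covariate"] if "Covariate" in df.columns else [])
    return SnapshotDataset(df[keep])


def write_dataset(dataset: SnapshotDataset, path) -> None:
    dataset.write_csv(path)
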