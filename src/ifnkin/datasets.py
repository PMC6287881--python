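"""Time-resolved fold-change datasets and variance weighting.

The calibration data are replicate-averaged ISG fold changes indexed by
(IFN type, dose, time).  Each point carries a variance used as the weight in
the least-squares objective; following the study's recipe the variance of a
point is its mean fold change multiplied by the dataset's average
coefficient of variation (the ``literal`` mode below).  Because that recipe
is dimensionally a standard deviation, the squared reading
``(mean * CV)**2`` is provided as an alternative ``squared`` mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "TimeCourseDataset", "compute_weights"]

REQUIRED_COLUMNS = ("condition_id", "ifn_type", "dose_nM", "time_h",
                    "mean_fc", "n_rep", "cv")


class TimeCourseDataset:
    """Replicate-mean fold-change observations with per-point variances.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with columns ``condition_id, ifn_type, dose_nM,
        time_h, mean_fc, n_rep, cv``.
    weight_mode : {"literal", "squared"}
        How per-point variances are derived from the mean and the average
        coefficient of variation.
    """

    def __init__(self, df: pd.DataFrame, weight_mode: str = "literal"):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        df = df.reset_index(drop=True).copy()
        if (df["mean_fc"] <= 0).any():
            raise ValueError("mean fold changes must be positive")
        if (df["time_h"] < 0).any():
            raise ValueError("times must be non-negative")
        dup = df.duplicated(subset=["condition_id", "time_h"])
        if dup.any():
            raise ValueError("duplicate (condition, time) observations")
        self.df = df
        self.weight_mode = weight_mode
        self.df["sigma2"] = compute_weights(self, mode=weight_mode)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_points(self) -> int:
        return len(self.df)

    @property
    def average_cv(self) -> float:
        """Dataset-level average coefficient of variation."""
        return float(self.df["cv"].mean())

    @property
    def sigma2(self) -> np.ndarray:
        return self.df["sigma2"].to_numpy()

    def conditions(self) -> pd.DataFrame:
        """One row per stimulation condition, in first-appearance order."""
        return self.df.drop_duplicates("condition_id")[
            ["condition_id", "ifn_type", "dose_nM"]].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df[list(REQUIRED_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, weight_mode: str = "literal") -> "TimeCourseDataset":
        return cls(pd.read_csv(path), weight_mode=weight_mode)

    @classmethod
    def from_records(cls, records, weight_mode: str = "literal") -> "TimeCourseDataset":
        return cls(pd.DataFrame.from_records(records), weight_mode=weight_mode)


def compute_weights(dataset, mode: str = "literal", average_cv: float | None = None):
    """Per-point variances from the mean x average-CV recipe.

    ``literal`` implements the recipe exactly as stated (variance = mean
    fold change times the dataset's average CV); ``squared`` treats the
    product as a standard deviation and squares it.
    """
    df = dataset.df if isinstance(dataset, TimeCourseDataset) else dataset
    means = np.asarray(df["mean_fc"], dtype=float)
    if average_cv is None:
        average_cv = float(np.mean(np.asarray(df["cv"], dtype=float)))
    if average_cv <= 0:
        raise ValueError("average coefficient of variation must be positive")
    if np.any(means <= 0):
        raise ValueError("variance weighting requires positive mean fold changes")
    if mode == "literal":
        return means * average_cv
    if mode == "squared":
        return (means * average_cv) ** 2
    raise ValueError(f"unknown weight mode {mode!r}")
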