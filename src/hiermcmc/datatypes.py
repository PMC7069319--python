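"""Survey-data containers and their long-format CSV serialization.

DetectionData holds binary detection histories: ``y`` has shape
(site, season, visit) for single-species multiseason data, (species, site,
visit) for multispecies single-season data, or (species, site, season, visit)
for multispecies multiseason data.  CountData holds repeated counts with
shape (site, visit).  ``mask`` matches ``y``'s shape, 1 where the visit
occurred.  Optional covariate arrays ride along in a plain dict.

The on-disk format is a long CSV with columns
``site, [species,] [season,] visit, value, mask`` — diffable and free of any
binary dependency.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

__all__ = ["DetectionData", "CountData"]


def _dim_columns(ndim: int, multispecies: bool):
    if multispecies:
        if ndim == 3:
            return ["species", "site", "visit"]
        if ndim == 4:
            return ["species", "site", "season", "visit"]
    else:
        if ndim == 2:
            return ["site", "visit"]
        if ndim == 3:
            return ["site", "season", "visit"]
    raise ValueError(f"unsupported data array rank {ndim}")


@dataclasses.dataclass
class _SurveyData:
    y: np.ndarray
    mask: np.ndarray
    covariates: dict = dataclasses.field(default_factory=dict)
    multispecies: bool = False

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.mask = np.asarray(self.mask).astype(int)
        if self.mask.shape != self.y.shape:
            raise ValueError("mask shape must match data shape")
        if np.any((self.y != 0) & (self.mask == 0)):
            raise ValueError("nonzero observation on a masked visit")

    @property
    def value_column(self) -> str:
        return "value"

    def to_long(self) -> pd.DataFrame:
        cols = _dim_columns(self.y.ndim, self.multispecies)
        idx = np.indices(self.y.shape).reshape(self.y.ndim, -1)
        df = pd.DataFrame({c: idx[k] for k, c in enumerate(cols)})
        df[self.value_column] = self.y.ravel()
        df["mask"] = self.mask.ravel()
        return df

    def to_csv(self, path):
        self.to_long().to_csv(path, index=False)

    def write_covariates(self, path):
        payload = {k: np.asarray(v).tolist() for k, v in self.covariates.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def _from_long(cls, df: pd.DataFrame, value_col: str, **kw):
        multispecies = "species" in df.columns
        cols = [c for c in ("species", "site", "season", "visit") if c in df.columns]
        shape = tuple(int(df[c].max()) + 1 for c in cols)
        y = np.zeros(shape, dtype=float)
        mask = np.zeros(shape, dtype=int)
        ix = tuple(df[c].to_numpy() for c in cols)
        y[ix] = df[value_col].to_numpy()
        mask[ix] = df["mask"].to_numpy()
        return cls(y, mask, multispecies=multispecies, **kw)

    @classmethod
    def from_csv(cls, path, covariates_path=None):
        df = pd.read_csv(path)
        obj = cls._from_long(df, "value")
        if covariates_path is not None:
            with open(covariates_path) as fh:
                obj.covariates = {k: np.asarray(v) for k, v in json.load(fh).items()}
        return obj


@dataclasses.dataclass
class DetectionData(_SurveyData):
    """Binary detection histories with a missing-visit mask."""

    def __post_init__(self):
        super().__post_init__()
        if not np.all(np.isin(self.y[self.mask == 1], [0, 1])):
            raise ValueError("detections must be binary")
        self.y = self.y.astype(int)


@dataclasses.dataclass
class CountData(_SurveyData):
    """Repeated non-negative counts (site x visit) with a mask."""

    def __post_init__(self):
        super().__post_init__()
        v = self.y[self.mask == 1]
        if np.any(v < 0) or np.any(v != np.floor(v)):
            raise ValueError("counts must be non-negative integers")
        self.y = self.y.astype(int)

    @property
    def counts(self) -> np.ndarray:
        return self.y
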