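"""Feature x sample matrices tied to an experiment design."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stagewise.design import ExperimentDesign


def _check_frame(values: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    if list(values.columns) != list(design.samples):
        missing = [s for s in design.samples if s not in values.columns]
        if missing:
            raise ValueError(f"samples missing from matrix: {missing}")
        values = values.loc[:, list(design.samples)]
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature IDs: {dups[:5]}")
    return values


@dataclass
class CountMatrix:
    """Non-negative integer read counts, features x samples."""

    values: pd.DataFrame
    design: ExperimentDesign

    def __post_init__(self) -> None:
        self.values = _check_frame(self.values, self.design)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix contains non-integer values")
            self.values = self.values.astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(feature_ids)], self.design)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.design == other.design and self.values.equals(other.values)


@dataclass
class ExpressionMatrix:
    """Normalized non-negative real expression values (rpmqn units)."""

    values: pd.DataFrame
    design: ExperimentDesign

    def __post_init__(self) -> None:
        self.values = _check_frame(self.values, self.design).astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def stage_means(self) -> pd.DataFrame:
        """Per-feature mean over the replicates of each stage."""
        cols = {
            stage: self.values[self.design.samples_of(stage)].mean(axis=1)
            for stage in self.design.stage_order
        }
        return pd.DataFrame(cols, index=self.values.index)

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.design)
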