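"""Feature x sample intensity matrix with annotation and a scale marker.

The matrix is the hand-off object between ingestion, normalization and
quantitation. Rows are features (precursors or peptides, already
channel-collapsed), columns are sample units (``runH`` / ``runL``).
Missing values are NaN; zero intensities never appear (zeros are
converted to missing at ingestion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, TrapquantError

SCALES = ("linear", "log2", "glog")


@dataclass
class FeatureIntensityMatrix:
    """Intensities as a features x samples frame.

    Attributes
    ----------
    values
        DataFrame indexed by feature_id; columns are sample-unit names.
    features
        DataFrame indexed by feature_id with ``gene`` and ``protein_ids``.
    scale
        'linear', 'log2' or 'glog' (vsn output). Transform helpers keep
        this marker consistent.
    """

    values: pd.DataFrame = field(repr=False)
    features: pd.DataFrame = field(repr=False)
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise TrapquantError(f"unknown scale {self.scale!r}")
        if not self.values.index.equals(self.features.index):
            self.features = self.features.loc[self.values.index]
        if self.scale == "linear":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise TrapquantError("linear-scale intensities must be >= 0")

    # ------------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return len(self.values)

    def copy(self) -> "FeatureIntensityMatrix":
        return FeatureIntensityMatrix(
            self.values.copy(), self.features.copy(), self.scale
        )

    def to_log2(self) -> "FeatureIntensityMatrix":
        """Return a log2 view; identity if already log2."""
        if self.scale == "log2":
            return self.copy()
        if self.scale != "linear":
            raise TrapquantError(f"cannot log2-transform {self.scale} data")
        with np.errstate(divide="ignore"):
            vals = np.log2(self.values)
        vals = vals.replace(-np.inf, np.nan)
        return FeatureIntensityMatrix(vals, self.features.copy(), "log2")

    def to_linear(self) -> "FeatureIntensityMatrix":
        if self.scale == "linear":
            return self.copy()
        if self.scale != "log2":
            raise TrapquantError(f"cannot invert {self.scale} to linear")
        return FeatureIntensityMatrix(
            np.power(2.0, self.values), self.features.copy(), "linear"
        )

    def require_no_empty_samples(self) -> None:
        empty = [s for s in self.samples if self.values[s].notna().sum() == 0]
        if empty:
            raise DegenerateSampleError(f"all-missing sample column(s): {empty}")

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        """Write annotation + values as TSV, with an optional # comment line."""
        out = pd.concat([self.features, self.values], axis=1)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# scale={self.scale}\n")
            out.to_csv(fh, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureIntensityMatrix":
        scale = "linear"
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if line.strip().startswith("# scale="):
                    scale = line.strip().split("=", 1)[1]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col="feature_id")
        ann_cols = [c for c in ("gene", "protein_ids") if c in df.columns]
        features = df[ann_cols]
        values = df.drop(columns=ann_cols)
        return cls(values, features, scale)


def long_to_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (sample, feature, intensity) long frame to wide form."""
    return long.pivot(index="feature_id", columns="sample", values="intensity")
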