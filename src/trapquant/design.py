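"""Sample design: the map from MS runs to experimental conditions.

A SILAC run contains two multiplexed channels (light = treated, heavy =
mock control in the arsenite experiment). Each run therefore expands to
two *sample units*, named ``<run_id>H`` and ``<run_id>L``, which are the
column identities used throughout the intensity matrices.

Normalization groups follow the four-group scheme used for the
peptide-level normalization: Group 1 = 10 min light, Group 2 = 10 min
heavy, Group 3 = 1 h light, Group 4 = 1 h heavy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import DesignError

TIMEPOINTS = ("t10min", "t1h")
ACQUISITIONS = ("DDA", "DIA")
CHANNELS = ("light", "heavy")

#: Channel suffix appended to run_id to form a sample-unit name.
CHANNEL_SUFFIX = {"light": "L", "heavy": "H"}

_GROUP_SCHEME = {
    ("t10min", "light"): 1,
    ("t10min", "heavy"): 2,
    ("t1h", "light"): 3,
    ("t1h", "heavy"): 4,
}

_COLUMNS = [
    "run_id",
    "acquisition",
    "timepoint",
    "replicate",
    "light_condition",
    "heavy_condition",
    "crosslinked",
]


@dataclass
class SampleDesign:
    """Run-level design table plus derived per-channel sample units.

    Parameters
    ----------
    runs
        One row per MS run with columns ``run_id``, ``acquisition``
        (DDA/DIA), ``timepoint`` (t10min/t1h, or None for the CL vs
        non-CL arm), ``replicate`` (int >= 1), ``light_condition``,
        ``heavy_condition`` and ``crosslinked`` (bool).
    """

    runs: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.runs.columns]
        if missing:
            raise DesignError(f"design lacks columns: {missing}")
        self.runs = self.runs.reset_index(drop=True)
        if self.runs["run_id"].duplicated().any():
            dupes = self.runs.loc[self.runs["run_id"].duplicated(), "run_id"]
            raise DesignError(f"duplicate run_id(s): {sorted(set(dupes))}")
        bad_acq = set(self.runs["acquisition"]) - set(ACQUISITIONS)
        if bad_acq:
            raise DesignError(f"unknown acquisition value(s): {sorted(bad_acq)}")
        tp = self.runs["timepoint"]
        bad_tp = set(tp.dropna()) - set(TIMEPOINTS)
        if bad_tp:
            raise DesignError(f"unknown timepoint value(s): {sorted(bad_tp)}")
        if (self.runs["replicate"].dropna() < 1).any():
            raise DesignError("replicate numbers must be >= 1")
        key = self.runs.dropna(subset=["timepoint"])[
            ["acquisition", "timepoint", "replicate"]
        ]
        if key.duplicated().any():
            raise DesignError(
                "each (acquisition, timepoint, replicate) may appear at most once"
            )

    # ------------------------------------------------------------------
    @property
    def run_ids(self) -> list[str]:
        return list(self.runs["run_id"])

    def sample_units(self) -> pd.DataFrame:
        """Expand runs to per-channel sample units.

        Returns a frame indexed by sample-unit name with columns
        ``run_id, channel, acquisition, timepoint, replicate, condition,
        crosslinked, group_id``.
        """
        rows = []
        for _, r in self.runs.iterrows():
            for channel in CHANNELS:
                cond = r["light_condition"] if channel == "light" else r["heavy_condition"]
                tp = r["timepoint"]
                group = _GROUP_SCHEME.get((tp, channel)) if pd.notna(tp) else None
                rows.append(
                    {
                        "sample": f"{r['run_id']}{CHANNEL_SUFFIX[channel]}",
                        "run_id": r["run_id"],
                        "channel": channel,
                        "acquisition": r["acquisition"],
                        "timepoint": tp,
                        "replicate": r["replicate"],
                        "condition": cond,
                        "crosslinked": bool(r["crosslinked"]),
                        "group_id": group,
                    }
                )
        return pd.DataFrame(rows).set_index("sample")

    def run_for(self, timepoint: str, replicate: int) -> str:
        """run_id of the (timepoint, replicate) run; DesignError if absent."""
        sel = self.runs[
            (self.runs["timepoint"] == timepoint)
            & (self.runs["replicate"] == replicate)
        ]
        if len(sel) != 1:
            raise DesignError(
                f"expected exactly one run for ({timepoint}, rep {replicate}), "
                f"found {len(sel)}"
            )
        return str(sel.iloc[0]["run_id"])

    def timepoint_replicates(self) -> dict[str, list[int]]:
        """Replicate numbers available at each timepoint."""
        out: dict[str, list[int]] = {}
        for tp in TIMEPOINTS:
            reps = self.runs.loc[self.runs["timepoint"] == tp, "replicate"]
            if len(reps):
                out[tp] = sorted(int(x) for x in reps)
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t")
        if "crosslinked" in df.columns:
            df["crosslinked"] = df["crosslinked"].map(_parse_bool)
        return cls(df)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(pd.DataFrame(payload["runs"]))

    def to_tsv(self, path: str | Path) -> None:
        self.runs.to_csv(path, sep="\t", index=False)


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in {"true", "1", "yes", "+"}
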