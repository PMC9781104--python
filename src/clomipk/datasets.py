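"""Long-format observed datasets: schema validation and unit handling.

Time is stored in hours and concentrations in ng/mL (urine as cumulative
µg) at the I/O boundary; conversion to molar internal units goes through
the compound molecular weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkSpec

__all__ = ["ObservedDataset", "parse_observed", "SchemaError"]

REQUIRED_COLUMNS = (
    "study",
    "subject",
    "as_group",
    "period",
    "analyte",
    "matrix",
    "time_h",
    "value",
)
VALID_PERIODS = ("control", "clarithromycin", "paroxetine")
VALID_MATRICES = ("plasma", "urine")


class SchemaError(ValueError):
    pass


@dataclass
class ObservedDataset:
    """Validated long-format plasma/urine observations."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        bad = df.index[df["value"] < 0]
        if len(bad):
            raise SchemaError(f"negative value at row {bad[0]} (column 'value')")
        bad = df.index[~df["matrix"].isin(VALID_MATRICES)]
        if len(bad):
            raise SchemaError(
                f"invalid matrix {df.loc[bad[0], 'matrix']!r} at row {bad[0]} "
                "(column 'matrix')"
            )
        bad = df.index[~df["period"].isin(VALID_PERIODS)]
        if len(bad):
            raise SchemaError(
                f"invalid period {df.loc[bad[0], 'period']!r} at row {bad[0]} "
                "(column 'period')"
            )
        urine = df[df["matrix"] == "urine"]
        for key, g in urine.groupby(["study", "subject", "as_group", "period", "analyte"]):
            g = g.sort_values("time_h")
            diffs = np.diff(g["value"].to_numpy(dtype=float))
            if np.any(diffs < 0):
                row = g.index[int(np.argmax(diffs < 0)) + 1]
                raise SchemaError(
                    f"urine record decreasing in time at row {row} "
                    f"(subject/period/analyte {key})"
                )

    @property
    def plasma(self) -> pd.DataFrame:
        return self.frame[self.frame["matrix"] == "plasma"]

    @property
    def urine(self) -> pd.DataFrame:
        return self.frame[self.frame["matrix"] == "urine"]

    def to_internal(self, network: NetworkSpec) -> pd.DataFrame:
        """Add a molar value column (µmol/L for plasma, µmol for urine)."""
        mw = {c.id: c.molecular_weight for c in network.compounds}
        df = self.frame.copy()
        factors = df["analyte"].map(mw)
        if factors.isna().any():
            unknown = df.loc[factors.isna(), "analyte"].unique()
            raise SchemaError(f"analytes not in network: {sorted(unknown)}")
        df["value_molar"] = df["value"] / factors
        return df


def parse_observed(path) -> ObservedDataset:
    """Read and validate a long-format observations CSV."""
    df = pd.read_csv(path)
    return ObservedDataset(df)
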