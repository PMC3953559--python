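"""Tree-level measurement container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class TreeDataset:
    """(DBH, height) records for one measurement campaign.

    DBH in cm, height in m.  All DBH must be positive; heights must be
    positive (values below breast height can arise from measurement noise
    and are tolerated).
    """

    dbh: np.ndarray
    height: np.ndarray
    tree_id: np.ndarray | None = None
    plot: np.ndarray | None = None
    campaign_label: str = ""

    def __post_init__(self):
        self.dbh = np.asarray(self.dbh, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.dbh.shape != self.height.shape or self.dbh.ndim != 1:
            raise ValidationError("dbh and height must be 1-d arrays of equal length")
        if self.dbh.size and (not np.all(np.isfinite(self.dbh)) or np.any(self.dbh <= 0)):
            raise ValidationError("all dbh values must be finite and > 0")
        if self.height.size and (
            not np.all(np.isfinite(self.height)) or np.any(self.height <= 0)
        ):
            raise ValidationError("all height values must be finite and > 0")
        if self.tree_id is None:
            self.tree_id = np.arange(1, self.dbh.size + 1)
        else:
            self.tree_id = np.asarray(self.tree_id)
            if self.tree_id.shape != self.dbh.shape:
                raise ValidationError("tree_id length mismatch")
        if self.plot is not None:
            self.plot = np.asarray(self.plot)
            if self.plot.shape != self.dbh.shape:
                raise ValidationError("plot length mismatch")

    @property
    def n(self) -> int:
        return int(self.dbh.size)

    def __len__(self) -> int:
        return self.n

    def to_dataframe(self) -> pd.DataFrame:
        data = {"tree_id": self.tree_id, "dbh": self.dbh, "height": self.height}
        if self.plot is not None:
            data["plot"] = self.plot
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, campaign_label: str = "") -> "TreeDataset":
        cols = {c.lower(): c for c in df.columns}
        if "dbh" not in cols or "height" not in cols:
            raise ValidationError("dataframe needs 'dbh' and 'height' columns")
        return cls(
            dbh=df[cols["dbh"]].to_numpy(dtype=float),
            height=df[cols["height"]].to_numpy(dtype=float),
            tree_id=df[cols["tree_id"]].to_numpy() if "tree_id" in cols else None,
            plot=df[cols["plot"]].to_numpy() if "plot" in cols else None,
            campaign_label=campaign_label,
        )

    def summary(self) -> pd.DataFrame:
        """Min/max/mean/SD of DBH and height, inventory-report style."""
        return pd.DataFrame(
            {
                "dbh": [self.dbh.min(), self.dbh.max(), self.dbh.mean(), self.dbh.std(ddof=1)],
                "height": [
                    self.height.min(),
                    self.height.max(),
                    self.height.mean(),
                    self.height.std(ddof=1),
                ],
            },
            index=["min", "max", "mean", "sd"],
        )
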