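"""Containers for two-visit panel data and one-row-per-unit cross-sections.

A :class:`TwoPointPanel` holds a long-format table with exactly two rows per
individual (visits 0 and 1).  Estimators never work on the long table
directly; they pull aligned per-visit numpy arrays via :meth:`TwoPointPanel.column_pair`
or build a :class:`CrossSection` by choosing one visit per individual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IRandError

#: columns every panel table must carry
REQUIRED_COLUMNS = ("id", "visit")


class TwoPointPanel:
    """Two-visit longitudinal dataset (baseline t=0, follow-up t=1).

    Parameters
    ----------
    data:
        Long-format frame with one row per individual per visit.  Must contain
        ``id`` and ``visit`` (coded 0/1); every id must appear exactly once at
        each visit.  All other columns are treated as variables (treatment,
        outcome, covariates, mediator, ...).
    meta:
        Optional dict describing how the data were generated (true
        parameters, design name); written to the JSON sidecar on save.
    """

    def __init__(self, data: pd.DataFrame, meta: dict | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise IRandError(f"panel is missing required columns {missing}")
        df = data.sort_values(["id", "visit"], kind="stable").reset_index(drop=True)
        counts = df.groupby("id")["visit"].agg(["size", "min", "max"])
        if not ((counts["size"] == 2) & (counts["min"] == 0) & (counts["max"] == 1)).all():
            raise IRandError("every individual needs exactly two rows, visits 0 and 1")
        self.data = df
        self.meta = dict(meta or {})
        self._ids = df.loc[df["visit"] == 0, "id"].to_numpy()

    @property
    def n(self) -> int:
        """Number of individuals."""
        return len(self._ids)

    @property
    def ids(self) -> np.ndarray:
        return self._ids

    @property
    def columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_COLUMNS]

    def column_pair(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return the values of ``name`` at visit 0 and visit 1, id-aligned."""
        v0 = self.data.loc[self.data["visit"] == 0, name].to_numpy()
        v1 = self.data.loc[self.data["visit"] == 1, name].to_numpy()
        return v0, v1

    def arrays(self, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Stack several columns into (n, k) matrices for each visit."""
        pairs = [self.column_pair(c) for c in columns]
        x0 = np.column_stack([p[0] for p in pairs]).astype(float)
        x1 = np.column_stack([p[1] for p in pairs]).astype(float)
        return x0, x1

    def __repr__(self) -> str:  # pragma: no cover
        return f"TwoPointPanel(n={self.n}, columns={self.columns})"


@dataclass
class CrossSection:
    """One-row-per-individual working sample for matching.

    ``X`` is the (n, k) confounder matrix, ``T`` the binary treatment and
    ``Y`` the outcome; ``ids`` keeps track of which unit each row is.
    """

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1 and len(np.asarray(self.T)) != 1:
            self.X = self.X.T
        self.T = np.asarray(self.T, dtype=int)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.T))
        else:
            self.ids = np.asarray(self.ids)
        n = len(self.T)
        if self.X.shape[0] != n or len(self.Y) != n or len(self.ids) != n:
            raise IRandError("X, T, Y, ids must have one row per unit")
        if len(np.unique(self.ids)) != n:
            raise IRandError("unit ids must be unique within a cross-section")

    @property
    def n(self) -> int:
        return len(self.T)


def write_panel(panel: TwoPointPanel, path: str | Path) -> None:
    """Write the long-format CSV plus a ``.json`` sidecar with the meta dict."""
    path = Path(path)
    panel.data.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(panel.meta, fh, indent=2, default=_jsonify)


def read_panel(path: str | Path) -> TwoPointPanel:
    """Read a panel written by :func:`write_panel` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return TwoPointPanel(df, meta=meta)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
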