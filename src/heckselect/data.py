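"""Unit-level data container and delimited-text I/O for sample selection problems.

A dataset holds, for each unit, a binary selection indicator ``s_i``, an
outcome ``y_i`` that is observed exactly when ``s_i = 1``, and two covariate
matrices: one for the outcome equation (rows ``x_i``) and one for the
selection equation (rows ``w_i``).  The two covariate sets may overlap or
coincide; no exclusion restriction is required.

Missing outcomes are represented internally by NaN plus the selection mask;
sentinel tokens in files ("NA" or an empty field) are converted on read and
never enter arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionData", "load_dataset", "write_dataset"]


@dataclass
class SelectionData:
    """Covariates, selection indicator, and partially observed outcome.

    Parameters
    ----------
    outcome : (n,) ndarray
        Outcome values; NaN where the unit is not selected.
    selected : (n,) ndarray of {0, 1}
        Selection indicator ``s_i``.
    outcome_covariates : (n, p) ndarray
        Covariates entering the outcome equation (no intercept column).
    selection_covariates : (n, q) ndarray
        Covariates entering the selection equation (no intercept column).
    """

    outcome: np.ndarray
    selected: np.ndarray
    outcome_covariates: np.ndarray
    selection_covariates: np.ndarray
    outcome_names: list[str] = field(default_factory=list)
    selection_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.selected = np.asarray(self.selected)
        self.outcome_covariates = np.atleast_2d(
            np.asarray(self.outcome_covariates, dtype=float)
        )
        self.selection_covariates = np.atleast_2d(
            np.asarray(self.selection_covariates, dtype=float)
        )
        n = self.outcome.shape[0]
        if self.selected.shape != (n,):
            raise ValueError("selected and outcome must have equal length")
        if not np.isin(self.selected, [0, 1]).all():
            raise ValueError("selected must be binary 0/1")
        self.selected = self.selected.astype(int)
        if self.outcome_covariates.shape[0] != n or self.selection_covariates.shape[0] != n:
            raise ValueError("covariate matrices must have one row per unit")
        if n < 1 or self.n_outcome_covariates < 1 or self.n_selection_covariates < 1:
            raise ValueError("need n >= 1, p >= 1, q >= 1")
        if not np.isfinite(self.outcome_covariates).all() or not np.isfinite(
            self.selection_covariates
        ).all():
            raise ValueError("covariates must be fully observed and finite")
        observed = ~np.isnan(self.outcome)
        if not np.array_equal(observed, self.selected == 1):
            raise ValueError("outcome must be present exactly when selected == 1")
        if not self.outcome_names:
            self.outcome_names = [f"x{j + 1}" for j in range(self.n_outcome_covariates)]
        if not self.selection_names:
            self.selection_names = [f"w{k + 1}" for k in range(self.n_selection_covariates)]

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_outcome_covariates(self) -> int:
        return self.outcome_covariates.shape[1]

    @property
    def n_selection_covariates(self) -> int:
        return self.selection_covariates.shape[1]

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean mask of units with an observed outcome."""
        return self.selected == 1

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def standardized(self) -> tuple["SelectionData", dict]:
        """Return a copy with covariates standardized to mean 0, sd 1.

        Standardization constants are computed on the full sample (selected
        and non-selected units alike) and returned for back-transformation.
        """
        def _std(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            mu = m.mean(axis=0)
            sd = m.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("cannot standardize a constant covariate column")
            return (m - mu) / sd, mu, sd

        xs, x_mu, x_sd = _std(self.outcome_covariates)
        ws, w_mu, w_sd = _std(self.selection_covariates)
        out = SelectionData(
            self.outcome.copy(), self.selected.copy(), xs, ws,
            list(self.outcome_names), list(self.selection_names),
        )
        record = {
            "outcome_mean": x_mu, "outcome_sd": x_sd,
            "selection_mean": w_mu, "selection_sd": w_sd,
        }
        return out, record


def load_dataset(
    path,
    *,
    outcome: str,
    selected: str,
    outcome_covariates: list[str],
    selection_covariates: list[str],
    standardize: bool = False,
):
    """Read a header-delimited CSV into a :class:`SelectionData`.

    Missing outcomes may be encoded as an empty field or the token "NA" and
    must co-occur with ``selected == 0``; any other inconsistency raises with
    the offending row index.

    Returns ``(data, standardization_record)``; the record is ``None`` unless
    ``standardize`` is true.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    for col in [outcome, selected, *outcome_covariates, *selection_covariates]:
        if col not in df.columns:
            raise ValueError(f"unknown column {col!r}")
    sel = df[selected].to_numpy()
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(dtype=float)
    bad = np.flatnonzero((sel == 0) & ~np.isnan(y))
    if bad.size:
        raise ValueError(
            f"row {bad[0]}: outcome value present but selected == 0"
        )
    bad = np.flatnonzero((sel == 1) & np.isnan(y))
    if bad.size:
        raise ValueError(f"row {bad[0]}: outcome missing but selected == 1")
    X = df[outcome_covariates].to_numpy(dtype=float)
    W = df[selection_covariates].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(W).any():
        raise ValueError("covariate columns contain missing or non-numeric entries")
    data = SelectionData(y, sel, X, W, list(outcome_covariates), list(selection_covariates))
    if standardize:
        return data.standardized()
    return data, None


def write_dataset(data: SelectionData, path) -> None:
    """Write a dataset as CSV; missing outcomes become empty fields."""
    cols: dict[str, np.ndarray] = {"selected": data.selected, "outcome": data.outcome}
    shared = data.outcome_names == data.selection_names and (
        data.outcome_covariates.shape == data.selection_covariates.shape
        and np.array_equal(data.outcome_covariates, data.selection_covariates)
    )
    for j, name in enumerate(data.outcome_names):
        cols[name] = data.outcome_covariates[:, j]
    if not shared:
        for k, name in enumerate(data.selection_names):
            cols[name] = data.selection_covariates[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="")
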