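"""Functional-marker gating at a fixed false-positive rate.

A minority-positive marker (PD1) is called positive/negative per cell by a
dual-axis threshold on the cell's intensity mean and standard deviation:

1. arcsinh-transform both axes (cofactor 1), compressing the 16-bit range;
2. per specimen, locate the peak (mode) of each axis' distribution — the
   bulk negative population — and shift it to zero, removing per-specimen
   batch offsets;
3. standardize each pooled axis to zero mean, unit variance;
4. choose the least restrictive (smallest) threshold pair such that the
   fraction of annotated negative cells exceeding BOTH thresholds does not
   exceed the target false-positive rate;
5. a cell is positive iff both standardized axes exceed their thresholds.

The mode is estimated as the center of the tallest Freedman-Diaconis
histogram bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    DegenerateDistributionError,
    ParameterError,
    SchemaError,
)


def histogram_mode(values: np.ndarray) -> float:
    """Center of the tallest Freedman-Diaconis bin (ties: leftmost)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate the mode of an empty sample")
    if np.ptp(values) == 0:
        return float(values[0])
    counts, edges = np.histogram(values, bins="fd")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


@dataclass
class GateModel:
    """Fitted dual-axis gate for one marker."""

    marker: str
    target_fpr: float
    #: specimen -> (mean-axis shift, sd-axis shift) on the arcsinh scale
    peak_shift_per_specimen: dict[str, tuple[float, float]]
    #: pooled standardization (location, scale) per axis, post-shift
    scale_mean: tuple[float, float] = (0.0, 1.0)
    scale_sd: tuple[float, float] = (0.0, 1.0)
    mean_threshold: float = 0.0
    sd_threshold: float = 0.0

    def transform(self, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Standardized (mean-axis, sd-axis) values for each cell.

        Specimens unseen at fit time get their shift estimated from their
        own cells, keeping the gate shift-invariant on new data.
        """
        for col in (f"{self.marker}_mean", f"{self.marker}_sd", "specimen_id"):
            if col not in cells.columns:
                raise SchemaError(f"gating needs column {col!r}")
        a_mean = np.arcsinh(cells[f"{self.marker}_mean"].to_numpy(dtype=float))
        a_sd = np.arcsinh(cells[f"{self.marker}_sd"].to_numpy(dtype=float))
        spec_ids = cells["specimen_id"].to_numpy()
        for s in np.unique(spec_ids):
            mask = spec_ids == s
            if s in self.peak_shift_per_specimen:
                sh_m, sh_s = self.peak_shift_per_specimen[s]
            else:
                sh_m = histogram_mode(a_mean[mask])
                sh_s = histogram_mode(a_sd[mask])
            a_mean[mask] -= sh_m
            a_sd[mask] -= sh_s
        z_mean = (a_mean - self.scale_mean[0]) / self.scale_mean[1]
        z_sd = (a_sd - self.scale_sd[0]) / self.scale_sd[1]
        return z_mean, z_sd

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        z_mean, z_sd = self.transform(cells)
        return (z_mean > self.mean_threshold) & (z_sd > self.sd_threshold)

    def to_dict(self) -> dict:
        """JSON-serializable audit record of the fitted gate."""
        return {
            "marker": self.marker,
            "target_fpr": self.target_fpr,
            "mean_threshold": self.mean_threshold,
            "sd_threshold": self.sd_threshold,
            "peak_shift_per_specimen": {
                k: list(v) for k, v in sorted(self.peak_shift_per_specimen.items())
            },
            "scale_mean": list(self.scale_mean),
            "scale_sd": list(self.scale_sd),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GateModel":
        return cls(
            marker=payload["marker"],
            target_fpr=payload["target_fpr"],
            peak_shift_per_specimen={
                k: tuple(v) for k, v in payload["peak_shift_per_specimen"].items()
            },
            scale_mean=tuple(payload["scale_mean"]),
            scale_sd=tuple(payload["scale_sd"]),
            mean_threshold=payload["mean_threshold"],
            sd_threshold=payload["sd_threshold"],
        )


def _least_restrictive_pair(
    neg_mean: np.ndarray, neg_sd: np.ndarray, target_fpr: float, grid_size: int = 101
) -> tuple[float, float]:
    """Smallest (t_mean, t_sd) with joint negative exceedance <= target_fpr.

    Candidates are empirical quantiles of the negatives on each axis; among
    feasible pairs the one minimizing t_mean + t_sd wins, ties broken toward
    the lower t_mean.
    """
    qs = np.linspace(0.0, 1.0, grid_size)
    cand_m = np.unique(np.quantile(neg_mean, qs))
    cand_s = np.unique(np.quantile(neg_sd, qs))
    exceed_m = neg_mean[None, :] > cand_m[:, None]  # (n_cand_m, n_neg)
    exceed_s = neg_sd[None, :] > cand_s[:, None]
    # joint FPR for every candidate pair
    fpr = exceed_m.astype(np.float64) @ exceed_s.T.astype(np.float64) / len(neg_mean)
    feasible = np.argwhere(fpr <= target_fpr)
    if len(feasible) == 0:  # fall back to the strictest corner
        return float(cand_m[-1]), float(cand_s[-1])
    sums = cand_m[feasible[:, 0]] + cand_s[feasible[:, 1]]
    order = np.lexsort((cand_m[feasible[:, 0]], sums))
    i, j = feasible[order[0]]
    return float(cand_m[i]), float(cand_s[j])


def fit_gate(
    cells: pd.DataFrame,
    marker: str,
    annotations: pd.DataFrame,
    target_fpr: float = 0.01,
) -> GateModel:
    """Calibrate a gate on the full cohort, thresholding on annotated negatives.

    ``annotations`` must carry ``cell_id`` and a boolean truth column
    ``{marker}_true_pos`` (or a ``label``-style ``{marker}_pos``); cells with
    a False value are the known negatives.
    """
    if not 0.0 < target_fpr < 1.0:
        raise ParameterError("target_fpr must lie in (0, 1)")
    for col in (f"{marker}_mean", f"{marker}_sd"):
        if col not in cells.columns:
            raise SchemaError(f"cell table lacks column {col!r}")
    if "specimen_id" not in cells.columns:
        raise SchemaError("gating needs specimen_id (join patient metadata first)")
    raw = cells[f"{marker}_mean"].to_numpy(dtype=float)
    if np.ptp(raw) == 0:
        raise DegenerateDistributionError(f"{marker} is constant across cells")

    truth_col = next(
        (
            c
            for c in (f"{marker}_true_pos", f"{marker}_pos")
            if c in annotations.columns
        ),
        None,
    )
    if truth_col is None:
        raise CalibrationError(
            f"annotations lack a {marker} positivity column for calibration"
        )
    neg_ids = annotations.loc[~annotations[truth_col].astype(bool), "cell_id"]
    if neg_ids.empty:
        raise CalibrationError(f"no annotated {marker}-negative cells")

    # per-specimen peak shifts from the full cohort
    shifts: dict[str, tuple[float, float]] = {}
    a_mean = np.arcsinh(raw)
    a_sd = np.arcsinh(cells[f"{marker}_sd"].to_numpy(dtype=float))
    spec_ids = cells["specimen_id"].to_numpy()
    for s in np.unique(spec_ids):
        mask = spec_ids == s
        shifts[str(s)] = (histogram_mode(a_mean[mask]), histogram_mode(a_sd[mask]))

    model = GateModel(marker=marker, target_fpr=target_fpr, peak_shift_per_specimen=shifts)
    z_mean, z_sd = model.transform(cells)
    sd_m = z_mean.std()
    sd_s = z_sd.std()
    if sd_m == 0 or sd_s == 0:
        raise DegenerateDistributionError(f"{marker} has a degenerate axis")
    model.scale_mean = (float(z_mean.mean()), float(sd_m))
    model.scale_sd = (float(z_sd.mean()), float(sd_s))

    z_mean, z_sd = model.transform(cells)
    is_neg = cells["cell_id"].isin(set(neg_ids)).to_numpy()
    t_m, t_s = _least_restrictive_pair(z_mean[is_neg], z_sd[is_neg], target_fpr)
    model.mean_threshold = t_m
    model.sd_threshold = t_s
    return model


def gate_functional_marker(
    cells: pd.DataFrame,
    marker: str,
    annotations: pd.DataFrame,
    target_fpr: float = 0.01,
) -> tuple[GateModel, pd.DataFrame]:
    """Fit the gate and return (model, cells with a ``{marker}_pos`` flag)."""
    model = fit_gate(cells, marker, annotations, target_fpr)
    out = cells.copy()
    out[f"{marker}_pos"] = model.predict(cells)
    return model, out
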