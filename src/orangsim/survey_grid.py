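"""Gridding survey records and spatial-autocorrelation diagnostics.

Point nest-count records are aggregated to grid cells by averaging every
record falling in a cell over the whole monitoring period; pseudoabsences
sampled outside reserves stand in for the unsurveyed, unsuitable landscape.
Moran's I (global and local) quantifies the residual spatial autocorrelation
that motivates the choice of grid resolution, and a Spearman screen flags
collinear predictor pairs before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic_landscape import GridLandscape, NestSurvey


@dataclass
class MoranResult:
    global_I: float
    local_I: np.ndarray          # per-cell local Moran's I
    scheme: str                  # "queen" or "rook", row-standardized

    @property
    def mean_local_I(self) -> float:
        return float(self.local_I.mean())


# ---------------------------------------------------------------------------
# aggregation

def aggregate_counts(survey: NestSurvey, landscape: GridLandscape) -> pd.DataFrame:
    """Average survey records per grid cell and append pseudoabsence rows.

    Per cell the mean is taken over every record (all transects, all years)
    falling in the cell. Cells never surveyed and not drawn as
    pseudoabsences are excluded. Returns the gridded modelling dataset with
    columns ``cell_id, row, col, mean_count, n_records, presence, source``
    plus one column per predictor layer.

    presence is 1 iff mean_count > 0; pseudoabsence rows have
    mean_count 0, presence 0 and carry no record weight.
    """
    rows, cols = landscape.shape
    rec = survey.records
    off = rec[(rec["row"] < 0) | (rec["row"] >= rows) |
              (rec["col"] < 0) | (rec["col"] >= cols)]
    if len(off):
        r = off.iloc[0]
        raise ValueError(
            f"record off-grid: transect {r['transect_id']}, year {r['year']}, "
            f"cell ({r['row']}, {r['col']}) outside {rows}x{cols} grid")
    if (rec["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    grouped = rec.groupby(["row", "col"])["count"].agg(["mean", "size"])
    grouped = grouped.reset_index().rename(
        columns={"mean": "mean_count", "size": "n_records"})
    grouped["source"] = "observed"

    pa = survey.pseudoabsences
    if len(pa):
        pa_rows = pd.DataFrame({
            "row": pa["row"].to_numpy(), "col": pa["col"].to_numpy(),
            "mean_count": 0.0, "n_records": 0, "source": "pseudoabsence"})
        surveyed = set(zip(grouped["row"], grouped["col"]))
        dup = [i for i, rc in enumerate(zip(pa_rows["row"], pa_rows["col"]))
               if rc in surveyed]
        if dup:
            raise ValueError("pseudoabsence coincides with a surveyed cell")
        grouped = pd.concat([grouped, pa_rows], ignore_index=True)

    grouped["presence"] = (grouped["mean_count"] > 0).astype(int)
    grouped["cell_id"] = grouped["row"].to_numpy() * cols + grouped["col"].to_numpy()
    r_idx = grouped["row"].to_numpy()
    c_idx = grouped["col"].to_numpy()
    for name, layer in landscape.predictors.items():
        grouped[name] = layer[r_idx, c_idx]
    front = ["cell_id", "row", "col", "mean_count", "n_records", "presence", "source"]
    return grouped[front + [c for c in grouped.columns if c not in front]]


def sample_pseudoabsences(landscape: GridLandscape, n: int, seed: int,
                          surveyed: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw n unique cells uniformly from outside reserves (and surveys).

    Pseudoabsences represent unsurveyed, presumably unsuitable locations;
    sampling them outside reserves keeps them distinct from true absences
    (observed zero counts inside reserves).
    """
    eligible = ~landscape.reserve_mask
    if surveyed is not None and len(surveyed):
        eligible = eligible.copy()
        eligible[surveyed["row"].to_numpy(), surveyed["col"].to_numpy()] = False
    flat = np.flatnonzero(eligible.ravel())
    if n > flat.size:
        raise ValueError(f"requested {n} pseudoabsences but only {flat.size} "
                         "eligible cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    _, cols = landscape.shape
    return pd.DataFrame({"row": chosen // cols, "col": chosen % cols})


# ---------------------------------------------------------------------------
# Moran's I

_KERNELS = {
    "rook": np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float),
    "queen": np.ones((3, 3), dtype=float) * np.array([[1, 1, 1],
                                                      [1, 0, 1],
                                                      [1, 1, 1]]),
}


def _spatial_lag(values: np.ndarray, scheme: str) -> np.ndarray:
    """Row-standardized neighbour mean under rook/queen contiguity."""
    if scheme not in _KERNELS:
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    kern = _KERNELS[scheme]
    s = ndimage.convolve(values, kern, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(values), kern, mode="constant", cval=0.0)
    return s / counts


def global_morans_i(values: np.ndarray, scheme: str = "queen") -> MoranResult:
    """Global and local Moran's I with row-standardized contiguity weights.

    With row-standardized weights the global statistic reduces to
    ``sum(z_i * lag_i) / sum(z_i^2)`` where ``lag`` is the neighbour mean of
    the centred field z. The local statistic is ``z_i * lag_i / m2`` with
    ``m2 = sum(z^2) / n``; its unweighted mean is the "mean local I"
    diagnostic.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 cells")
    z = values - values.mean()
    ss = float((z ** 2).sum())
    if ss == 0.0:
        raise ValueError("constant field: Moran's I undefined")
    lag = _spatial_lag(z, scheme)
    global_i = float((z * lag).sum() / ss)
    m2 = ss / values.size
    local = z * lag / m2
    return MoranResult(global_I=global_i, local_I=local, scheme=scheme)


def local_morans_i(values: np.ndarray, scheme: str = "queen") -> MoranResult:
    """Alias computing the same result object as :func:`global_morans_i`."""
    return global_morans_i(values, scheme=scheme)


# ---------------------------------------------------------------------------
# predictor screening

def screen_predictors(dataset: pd.DataFrame, predictors: list[str],
                      threshold: float = 0.68) -> pd.DataFrame:
    """All pairwise Spearman correlations among predictors, flagging |rho|>threshold.

    Flagging only — whether to retain a flagged pair (as was done for
    elevation and slope) is the caller's choice. Constant predictors make
    the correlation undefined for their pairs; such pairs are reported with
    NaN rho and ``undefined=True``.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 rows to screen predictors")
    rows = []
    for i, a in enumerate(predictors):
        for b in predictors[i + 1:]:
            xa, xb = dataset[a].to_numpy(), dataset[b].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                rows.append((a, b, np.nan, False, True))
                continue
            rho = stats.spearmanr(xa, xb).statistic
            rows.append((a, b, float(rho), bool(abs(rho) > threshold), False))
    return pd.DataFrame(rows, columns=["predictor_a", "predictor_b", "rho",
                                       "flagged", "undefined"])
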