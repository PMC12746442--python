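"""Ensemble statistics: feature occupancies, SI-conditioned analyses,
cross-ensemble population tables, and block-averaging convergence.

Occupancy is the fraction of analyzable (non-sentinel) frames in which a
feature is present.  "Combined" pools frames across replicates, so the
combined occupancy is exactly the frame-weighted mean of the replicate
occupancies.  Frames where a feature is unresolvable are excluded from both
numerator and denominator: a missing atom is a data problem, not a
structural observation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SENTINEL = "unresolvable"

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyResult",
    "ConvergenceReport",
    "occupancy",
    "si_stable_mask",
    "conditioned_occupancy",
    "population_table",
    "block_convergence",
    "UndefinedOccupancy",
]


class UndefinedOccupancy:
    """Sentinel: no analyzable frames (all-sentinel or empty selection)."""

    def __repr__(self):
        return "UndefinedOccupancy"

    def __eq__(self, other):
        return isinstance(other, UndefinedOccupancy)

    def __hash__(self):
        return hash("UndefinedOccupancy")

    def __bool__(self):
        return False


UNDEFINED = UndefinedOccupancy()


def _predicate_mask(df: pd.DataFrame, feature):
    """(hit mask, valid mask) for a feature column, value test or callable."""
    if callable(feature):
        hits = feature(df)
        hits = np.asarray(hits, dtype=bool)
        valid = np.ones(len(df), dtype=bool)
        return hits, valid
    if isinstance(feature, tuple):
        column, value = feature
    else:
        column, value = feature, True
    if column not in df.columns:
        raise KeyError(f"feature column {column!r} not in table")
    col = df[column]
    valid = (col != SENTINEL) & col.notna()
    hits = (col == value) & valid
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("occupancy(%s): excluded %d sentinel frames",
                    column, n_bad)
    return hits.to_numpy(), valid.to_numpy()


@dataclass
class OccupancyResult:
    feature: str
    per_replicate: dict       # replicate -> (fraction | UNDEFINED, n_valid)
    combined: object          # fraction or UNDEFINED
    n_valid: int
    n_frames: int


def occupancy(table: pd.DataFrame, feature) -> OccupancyResult:
    """Occupancy of a feature over a per-frame feature table.

    *feature* is a column name (counted where the value is True), a
    ``(column, value)`` pair, or a callable mapping the table to a boolean
    series.  Returns per-replicate fractions and the combined (pooled)
    fraction.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    hits, valid = _predicate_mask(table, feature)
    if isinstance(feature, str):
        label = feature
    elif isinstance(feature, tuple):
        label = feature[0] if feature[1] is True else \
            f"{feature[0]}={feature[1]}"
    else:
        label = "<predicate>"
    reps = table["replicate"].to_numpy() if "replicate" in table.columns \
        else np.ones(len(table), dtype=int)
    per_rep = {}
    for rep in np.unique(reps):
        sel = reps == rep
        nv = int((valid & sel).sum())
        frac = float(hits[sel].sum() / nv) if nv else UNDEFINED
        per_rep[int(rep)] = (frac, nv)
    n_valid = int(valid.sum())
    combined = float(hits.sum() / n_valid) if n_valid else UNDEFINED
    return OccupancyResult(str(label), per_rep, combined, n_valid, len(table))


def si_stable_mask(table: pd.DataFrame) -> pd.Series:
    """True where the SI is formed in either arrangement (native or
    non-native); the conditioning mask for the additional analyses."""
    if "si_state" not in table.columns:
        raise KeyError("table has no si_state column")
    return table["si_state"].isin(["native", "non-native"])


def conditioned_occupancy(table: pd.DataFrame, feature, mask) -> object:
    """Occupancy restricted to mask-true frames (UNDEFINED on empty mask)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(table):
        raise ValueError("mask length does not match table")
    sub = table.loc[mask]
    if len(sub) == 0:
        return UNDEFINED
    return occupancy(sub, feature).combined


def population_table(ensembles: dict[str, pd.DataFrame],
                     features) -> pd.DataFrame:
    """One row per (ensemble label, replicate or 'combined', feature).

    Every ensemble must provide the same feature columns (consistency of
    catalogue/criterion across ensembles); row ordering is deterministic:
    by label, then replicate (combined last), then feature.
    """
    features = list(features)
    col_of = {}
    for f in features:
        col_of[f] = f[0] if isinstance(f, tuple) else f
    ref_cols = None
    for label, df in ensembles.items():
        cols = [c for c in col_of.values() if c in df.columns]
        if len(cols) != len(col_of):
            missing = set(col_of.values()) - set(df.columns)
            raise ValueError(
                f"ensemble {label!r} lacks feature columns {sorted(missing)}")
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ValueError("ensembles analyzed with differing catalogues")
    rows = []
    for label in sorted(ensembles):
        df = ensembles[label]
        for f in features:
            res = occupancy(df, f)
            for rep in sorted(res.per_replicate):
                frac, nv = res.per_replicate[rep]
                rows.append({"ensemble": label, "replicate": str(rep),
                             "feature": res.feature,
                             "occupancy": math.nan
                             if frac is UNDEFINED or frac == UNDEFINED
                             else frac,
                             "n_frames": nv})
            rows.append({"ensemble": label, "replicate": "combined",
                         "feature": res.feature,
                         "occupancy": math.nan
                         if res.combined == UNDEFINED else res.combined,
                         "n_frames": res.n_valid})
    return pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    feature: str
    block_sizes: list[int]
    standard_errors: list[float]
    plateau: float               # SE estimate at the largest usable block

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"block_size": self.block_sizes,
                             "standard_error": self.standard_errors})


def block_convergence(series, block_sizes=None,
                      feature: str = "") -> ConvergenceReport:
    """Block-averaging standard errors of a boolean/real time series.

    For block size b the series is cut into floor(n/b) contiguous blocks
    (tail discarded); the SE is the standard deviation of the block means
    divided by sqrt(number of blocks).  The SE rises with b until blocks
    exceed the correlation time, then plateaus at the true SE of the mean;
    the plateau estimate reported is the SE at the largest usable size.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if block_sizes is None:
        block_sizes = [2 ** k for k in range(0, max(int(np.log2(max(n // 2, 1))) + 1, 1))]
    usable, ses = [], []
    for b in sorted(set(int(b) for b in block_sizes)):
        if b < 1:
            continue
        nb = n // b
        if nb < 2:
            warnings.warn(f"block size {b} skipped (fewer than 2 blocks)",
                          stacklevel=2)
            continue
        if np.ptp(x) == 0.0:
            # a constant series has exactly zero block SE; avoid reporting
            # summation round-off as a spurious variance
            se = 0.0
        else:
            means = x[: nb * b].reshape(nb, b).mean(axis=1)
            se = float(means.std(ddof=1) / math.sqrt(nb))
        usable.append(b)
        ses.append(se)
    if not usable:
        raise ValueError("no usable block size for series of length "
                         f"{n}")
    return ConvergenceReport(feature, usable, ses, ses[-1])
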