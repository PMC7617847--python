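"""Partial-correlation connectomes.

Turns a per-subject ROI time-series matrix into the 66-entry vector of
absolute, hemisphere-averaged Pearson partial correlations.  The partial
correlation between two regions conditions on all remaining regions of the
conditioning set; by default the set is the 12 regions of one hemisphere
(so left and right connectomes are estimated separately and the homologous
absolute values averaged), with a joint 24-region conditioning mode as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import COLUMN_ORDER, CONNECTIONS, HEMISPHERES, ROI_TYPES, ConnectionIndex

#: Condition-number guard: a column correlation matrix worse than this is
#: treated as singular (no silent ridge regularisation).
MAX_CONDITION = 1e12


def partial_correlation_matrix(ts: np.ndarray, columns: list[str] | None = None) -> np.ndarray:
    """Pearson partial-correlation matrix of a T x k data matrix.

    Entry (i, j) is the correlation between the residuals of columns i and
    j after regressing each on all other k-2 columns; computed via the
    inverse of the column correlation matrix R as ``-inv(R)_ij /
    sqrt(inv(R)_ii inv(R)_jj)``.

    Raises on zero-variance columns (naming them) and on a singular or
    near-singular correlation matrix.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected 2-D matrix, got shape {ts.shape}")
    n_time, k = ts.shape
    if n_time <= k + 2:
        raise ValueError(f"need T > k + 2 (T={n_time}, k={k})")

    sd = ts.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [columns[i] if columns else str(i) for i in zero]
        raise ValueError(f"zero-variance columns: {names}")

    corr = np.corrcoef(ts, rowvar=False)
    cond = np.linalg.cond(corr)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(f"correlation matrix is singular (condition number {cond:.3g})")
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 1.0)
    return np.clip(pc, -1.0, 1.0)


@dataclass
class ConnectionVector:
    """Per-subject absolute, hemisphere-averaged partial correlations.

    ``values`` is keyed by connection id and holds the hemisphere mean of
    the absolute partial correlations; ``left`` and ``right`` keep the
    per-hemisphere provenance.  Values flagged missing (post-QC) are NaN.
    """

    subject_id: str
    values: dict[str, float]
    left: dict[str, float]
    right: dict[str, float]
    index: ConnectionIndex = field(default_factory=lambda: CONNECTIONS)

    def __post_init__(self) -> None:
        want = set(self.index.ids)
        if set(self.values) != want:
            raise ValueError("values must be keyed by exactly the connection index")
        for cid, v in self.values.items():
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"connection {cid} value outside [0, 1]: {v}")

    def as_series(self) -> pd.Series:
        return pd.Series({cid: self.values[cid] for cid in self.index.ids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "connection": list(self.index.ids),
                "r_left": [self.left[c] for c in self.index.ids],
                "r_right": [self.right[c] for c in self.index.ids],
                "r": [self.values[c] for c in self.index.ids],
            }
        )


def _column_indices(hemi: str) -> list[int]:
    return [COLUMN_ORDER.index(f"{roi}_{hemi}") for roi in ROI_TYPES]


def connection_vector(
    ts: np.ndarray | pd.DataFrame,
    subject_id: str = "subject",
    index: ConnectionIndex = CONNECTIONS,
    conditioning: str = "per_hemisphere",
) -> ConnectionVector:
    """Compute the 66-connection vector from a T x 24 time-series matrix.

    conditioning="per_hemisphere" (default)
        A 12 x 12 partial-correlation matrix is computed separately within
        each hemisphere's columns; absolute values are taken first and the
        homologous entries then averaged.
    conditioning="joint"
        One 24 x 24 matrix conditioning each pair on all 22 other regions;
        the two homologous absolute entries are averaged.

    Cross-hemisphere pairs are never emitted.
    """
    if conditioning not in ("per_hemisphere", "joint"):
        raise ValueError(f"unknown conditioning mode: {conditioning!r}")
    if isinstance(ts, pd.DataFrame):
        missing = [c for c in COLUMN_ORDER if c not in ts.columns]
        if missing:
            raise ValueError(f"time-series frame missing columns: {missing}")
        ts = ts[list(COLUMN_ORDER)].to_numpy(dtype=float)
    ts = np.asarray(ts, dtype=float)
    if ts.shape[1] != len(COLUMN_ORDER):
        raise ValueError(f"expected {len(COLUMN_ORDER)} columns, got {ts.shape[1]}")

    roi_pos = {roi: i for i, roi in enumerate(ROI_TYPES)}
    per_hemi: dict[str, dict[str, float]] = {}
    if conditioning == "per_hemisphere":
        for hemi in HEMISPHERES:
            cols = _column_indices(hemi)
            pc = partial_correlation_matrix(
                ts[:, cols], columns=[COLUMN_ORDER[c] for c in cols]
            )
            per_hemi[hemi] = {
                cid: abs(pc[roi_pos[a], roi_pos[b]])
                for cid, (a, b) in zip(index.ids, index.pairs)
            }
    else:
        pc = partial_correlation_matrix(ts, columns=list(COLUMN_ORDER))
        for hemi in HEMISPHERES:
            cols = _column_indices(hemi)
            per_hemi[hemi] = {
                cid: abs(pc[cols[roi_pos[a]], cols[roi_pos[b]]])
                for cid, (a, b) in zip(index.ids, index.pairs)
            }

    left, right = per_hemi["L"], per_hemi["R"]
    values = {cid: (left[cid] + right[cid]) / 2.0 for cid in index.ids}
    return ConnectionVector(
        subject_id=subject_id, values=values, left=left, right=right, index=index
    )


def cohort_connection_table(vectors: list[ConnectionVector]) -> pd.DataFrame:
    """Long-format table: one row per (subject, connection)."""
    return pd.concat([v.to_frame() for v in vectors], ignore_index=True)
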