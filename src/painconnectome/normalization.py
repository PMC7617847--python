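"""Outlier screening, adult normalisation, and connection presence calling.

The pipeline order is fixed: (1) per-connection quality screens — a
Cook-distance screen against the age trend for infants, a 3-SD screen for
adults; (2) per-connection adult reference means from the surviving adult
values; (3) normalisation of every value by the adult mean (r-norm, the
degree of adult-like connectivity); (4) a global presence threshold equal
to the mean thalamus-SI r-norm of the youngest infants (< 32 weeks PMA),
below which a connection is called absent (r-norm set to 0).

QC-discarded values are *missing* (NaN) and excluded from every downstream
mean and denominator; a value set to 0 by the presence threshold is
*absent*, which is a distinct state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .rois import CONNECTIONS, ConnectionIndex, connection_id

#: Multiplier on the mean Cook distance above which an infant value is
#: discarded, and on the adult SD for the adult screen. Strict inequality:
#: values exactly at the cut survive.
OUTLIER_MULTIPLIER = 3.0

#: Reference connection and age bound defining the presence threshold.
REFERENCE_CONNECTION = connection_id("thalamus", "SI")
REFERENCE_MAX_PMA = 32.0


def infant_outlier_mask(
    values: np.ndarray, pma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cook-distance keep-mask for one connection's infant values.

    Fits OLS of value on intercept + PMA and computes Cook's distance
    D_i = (e_i^2 / (p s^2)) * (h_ii / (1 - h_ii)^2) with p = 2 parameters.
    Values with D_i strictly above ``3 * mean(D)`` are discarded. Missing
    values are passed through as kept=False-irrelevant (they stay NaN).

    Returns ``(keep, cooks_d)`` aligned with the input; with fewer than 4
    non-missing pairs nothing is discarded and a warning is raised.
    """
    values = np.asarray(values, dtype=float)
    pma = np.asarray(pma, dtype=float)
    if values.shape != pma.shape:
        raise ValueError("values and pma must be aligned")
    ok = np.isfinite(values) & np.isfinite(pma)
    keep = ok.copy()
    cooks = np.full(values.shape, np.nan)
    if ok.sum() < 4:
        warnings.warn(
            f"only {int(ok.sum())} usable points; Cook-distance screen skipped",
            stacklevel=2,
        )
        return keep, cooks

    X = sm.add_constant(pma[ok])
    fit = sm.OLS(values[ok], X).fit()
    if fit.ssr <= 1e-30:  # perfect fit: zero residuals, nothing influential
        cooks[ok] = 0.0
        return keep, cooks
    d = OLSInfluence(fit).cooks_distance[0]
    cooks[ok] = d
    cut = OUTLIER_MULTIPLIER * d.mean()
    keep[ok] = d <= cut
    return keep, cooks


def adult_outlier_mask(values: np.ndarray) -> np.ndarray:
    """3-SD keep-mask for one connection's adult values (single pass).

    Discards values whose absolute deviation from the mean strictly
    exceeds 3 sample standard deviations. Zero variance keeps everything.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    keep = ok.copy()
    if ok.sum() < 3:
        warnings.warn(
            f"only {int(ok.sum())} usable adult values; SD screen skipped",
            stacklevel=2,
        )
        return keep
    v = values[ok]
    sd = v.std(ddof=1)
    if sd == 0:
        return keep
    keep[ok] = np.abs(v - v.mean()) <= OUTLIER_MULTIPLIER * sd
    return keep


@dataclass(frozen=True)
class AdultReference:
    """Per-connection mean adult absolute partial correlation (post-QC)."""

    means: dict[str, float]
    n_used: dict[str, int]

    def __post_init__(self) -> None:
        bad = [c for c, m in self.means.items() if not (np.isfinite(m) and m > 0)]
        if bad:
            raise ValueError(f"adult reference means must be positive: {bad[:5]}")


def adult_reference_means(
    adult_table: pd.DataFrame, index: ConnectionIndex = CONNECTIONS
) -> AdultReference:
    """Arithmetic per-connection mean over surviving adult values.

    ``adult_table`` is long-format with columns (subject, connection, r);
    QC-discarded values must already be NaN. A connection with zero
    survivors is an error.
    """
    means, n_used = {}, {}
    grouped = adult_table.groupby("connection")["r"]
    agg_mean = grouped.mean()
    agg_n = grouped.count()
    for cid in index.ids:
        n = int(agg_n.get(cid, 0))
        if n == 0:
            raise ValueError(f"connection {cid} has no surviving adult values")
        means[cid] = float(agg_mean[cid])
        n_used[cid] = n
    return AdultReference(means=means, n_used=n_used)


@dataclass
class NormalizedConnectome:
    """Per-subject adult-normalised connectivity (r-norm) with presence.

    ``r_norm`` maps connection id to r / adult mean; NaN marks a value the
    QC screens discarded (missing). ``present`` is None until the presence
    threshold has been applied; afterwards absent connections have
    r_norm = 0 and present = False, and missing connections stay NaN with
    present = None for that entry.
    """

    subject_id: str
    r_norm: dict[str, float]
    present: dict[str, bool | None] | None = None
    index: ConnectionIndex = field(default_factory=lambda: CONNECTIONS)


def normalize(vec_values: dict[str, float], ref: AdultReference, subject_id: str = "subject") -> NormalizedConnectome:
    """Eq.-style normalisation: r_norm_C = r_C / adult_mean_C, elementwise.

    Missing (NaN) input propagates to missing output.
    """
    r_norm = {}
    for cid, r in vec_values.items():
        if cid not in ref.means:
            raise ValueError(f"no adult reference for connection {cid}")
        r_norm[cid] = float(r / ref.means[cid]) if np.isfinite(r) else np.nan
    return NormalizedConnectome(subject_id=subject_id, r_norm=r_norm)


def apply_presence_threshold(
    cohort: list[NormalizedConnectome],
    reference_ids: set[str],
    reference_connection: str = REFERENCE_CONNECTION,
) -> float:
    """Compute and apply the global presence threshold, in place.

    The threshold is the mean r-norm of the reference (thalamus-SI)
    connection across the reference-group subjects (youngest infants),
    non-missing values only. In every subject — infant and adult alike —
    r-norm values *strictly below* the threshold are set to 0 and marked
    absent; values at or above it are marked present. Returns the
    threshold.
    """
    ref_vals = [
        c.r_norm[reference_connection]
        for c in cohort
        if c.subject_id in reference_ids and np.isfinite(c.r_norm[reference_connection])
    ]
    if not ref_vals:
        raise ValueError(
            "reference group is empty or has no usable "
            f"{reference_connection} values"
        )
    threshold = float(np.mean(ref_vals))
    for conn in cohort:
        present: dict[str, bool | None] = {}
        for cid, v in conn.r_norm.items():
            if not np.isfinite(v):
                present[cid] = None
            elif v < threshold:
                conn.r_norm[cid] = 0.0
                present[cid] = False
            else:
                present[cid] = True
        conn.present = present
    return threshold


@dataclass
class OutlierReport:
    """Counts and records of QC-discarded connectivity values."""

    infant_discarded: dict[str, int]
    adult_discarded: dict[str, int]
    infant_fraction: float
    adult_fraction: float
    records: pd.DataFrame  # subject, connection, value, statistic, cohort

    def to_json_dict(self) -> dict:
        return {
            "infant_fraction": self.infant_fraction,
            "adult_fraction": self.adult_fraction,
            "infant_discarded": self.infant_discarded,
            "adult_discarded": self.adult_discarded,
            "n_records": int(len(self.records)),
        }


@dataclass
class CohortNormalization:
    """Result bundle of the full QC -> reference -> r-norm -> presence chain."""

    data: pd.DataFrame  # subject, connection, r, r_norm, present, qc_flag
    reference: AdultReference
    threshold: float
    report: OutlierReport
    connectomes: dict[str, NormalizedConnectome]


def normalize_cohort(
    conn_table: pd.DataFrame,
    meta: pd.DataFrame,
    index: ConnectionIndex = CONNECTIONS,
    reference_connection: str = REFERENCE_CONNECTION,
    reference_max_pma: float = REFERENCE_MAX_PMA,
) -> CohortNormalization:
    """Run the full normalisation chain on a cohort.

    Parameters
    ----------
    conn_table
        Long-format (subject, connection, r) absolute hemisphere-averaged
        partial correlations for all subjects, infants and adults.
    meta
        Per-subject metadata with columns (subject, group, pma); adults
        have NaN PMA or group == "adult".

    The stage order is fixed: QC screens, then adult reference means from
    surviving adults, then r-norm, then the global presence threshold from
    infants younger than ``reference_max_pma`` weeks.
    """
    meta = meta.set_index("subject") if "subject" in meta.columns else meta
    df = conn_table.copy()
    df["pma"] = df["subject"].map(meta["pma"])
    df["is_adult"] = df["subject"].map(
        (meta["group"] == "adult") | meta["pma"].isna()
    )

    df["qc_keep"] = True
    df["qc_stat"] = np.nan
    infant_disc: dict[str, int] = {}
    adult_disc: dict[str, int] = {}
    for cid, sub in df.groupby("connection"):
        inf = sub[~sub["is_adult"]]
        if len(inf):
            keep, cooks = infant_outlier_mask(inf["r"].to_numpy(), inf["pma"].to_numpy())
            df.loc[inf.index, "qc_keep"] = keep
            df.loc[inf.index, "qc_stat"] = cooks
            infant_disc[cid] = int((~keep & np.isfinite(inf["r"].to_numpy())).sum())
        adu = sub[sub["is_adult"]]
        if len(adu):
            keep = adult_outlier_mask(adu["r"].to_numpy())
            df.loc[adu.index, "qc_keep"] = keep
            adult_disc[cid] = int((~keep & np.isfinite(adu["r"].to_numpy())).sum())

    n_inf = int((~df["is_adult"] & np.isfinite(df["r"])).sum())
    n_adu = int((df["is_adult"] & np.isfinite(df["r"])).sum())
    report = OutlierReport(
        infant_discarded=infant_disc,
        adult_discarded=adult_disc,
        infant_fraction=sum(infant_disc.values()) / n_inf if n_inf else 0.0,
        adult_fraction=sum(adult_disc.values()) / n_adu if n_adu else 0.0,
        records=df.loc[
            ~df["qc_keep"], ["subject", "connection", "r", "qc_stat", "is_adult"]
        ].reset_index(drop=True),
    )

    df["r_qc"] = np.where(df["qc_keep"], df["r"], np.nan)
    adult_post_qc = df.loc[df["is_adult"], ["subject", "connection"]].assign(
        r=df.loc[df["is_adult"], "r_qc"]
    )
    reference = adult_reference_means(adult_post_qc, index=index)

    connectomes: dict[str, NormalizedConnectome] = {}
    for sid, sub in df.groupby("subject"):
        values = dict(zip(sub["connection"], sub["r_qc"]))
        connectomes[sid] = normalize(values, reference, subject_id=sid)

    reference_ids = {
        sid
        for sid, row in meta.iterrows()
        if np.isfinite(row["pma"]) and row["pma"] < reference_max_pma
    }
    threshold = apply_presence_threshold(
        list(connectomes.values()), reference_ids, reference_connection
    )

    df["r_norm"] = [
        connectomes[s].r_norm[c] for s, c in zip(df["subject"], df["connection"])
    ]
    df["present"] = [
        connectomes[s].present[c] for s, c in zip(df["subject"], df["connection"])
    ]
    out = df[
        ["subject", "connection", "r", "r_norm", "present", "qc_keep", "qc_stat", "pma", "is_adult"]
    ].rename(columns={"qc_keep": "qc_pass"})
    return CohortNormalization(
        data=out,
        reference=reference,
        threshold=threshold,
        report=report,
        connectomes=connectomes,
    )
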