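"""Maturation statistics for the normalised pain connectome.

Per-subject summary metrics (proportion of present connections, mean
log10 strength of present connections) and the statistical battery used to
characterise maturation: linear regressions on postmenstrual age (PMA),
Dunnett many-to-one comparisons of infant age bins against the adult
control, two-way age x subnetwork ANOVA with Tukey pairwise follow-ups,
and per-connection Welch t-tests with Benjamini-Hochberg FDR control
within each subnetwork's connection family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .normalization import NormalizedConnectome
from .rois import SUBNETWORKS, SubnetworkDefinition

#: Infant PMA bins (weeks): half-open on the left except the last, which is
#: closed at 42; adults form their own group.
AGE_BINS: tuple[tuple[str, float, float], ...] = (
    ("<32", 0.0, 32.0),
    ("32-34", 32.0, 34.0),
    ("34-36", 34.0, 36.0),
    ("36-38", 36.0, 38.0),
    ("38-40", 38.0, 40.0),
    ("40-42", 40.0, 42.0),
)
AGE_GROUP_ORDER: tuple[str, ...] = tuple(b[0] for b in AGE_BINS) + ("adult",)


def age_bin(pma: float | None) -> str:
    """Map a PMA in weeks to its age-group label; None/NaN means adult."""
    if pma is None or not np.isfinite(pma):
        return "adult"
    for label, lo, hi in AGE_BINS:
        if lo <= pma < hi:
            return label
    if pma == AGE_BINS[-1][2]:  # last bin closed at the upper bound
        return AGE_BINS[-1][0]
    raise ValueError(f"PMA {pma} outside the supported range")


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject connectivity summary within a scope (all or subnetwork)."""

    subject_id: str
    scope: str
    proportion: float  # present / non-missing; NaN if no non-missing
    mean_log_strength: float  # mean log10(r_norm) over present; NaN if none
    n_present: int
    n_nonmissing: int


def subject_summary(
    norm: NormalizedConnectome, scope: SubnetworkDefinition | None = None
) -> SubjectSummary:
    """Proportion of present connections and mean log10 strength.

    The denominator of the proportion counts only non-missing connections
    (those the QC screens did not discard); the strength average runs over
    present connections only, keeping the log finite.
    """
    if norm.present is None:
        raise ValueError("presence threshold has not been applied")
    ids = scope.connections if scope is not None else norm.index.ids
    vals = [(norm.r_norm[c], norm.present[c]) for c in ids]
    nonmissing = [(v, p) for v, p in vals if p is not None]
    present = [v for v, p in nonmissing if p]
    n_nm = len(nonmissing)
    prop = len(present) / n_nm if n_nm else np.nan
    strength = float(np.mean(np.log10(present))) if present else np.nan
    return SubjectSummary(
        subject_id=norm.subject_id,
        scope=scope.name if scope is not None else "all",
        proportion=prop,
        mean_log_strength=strength,
        n_present=len(present),
        n_nonmissing=n_nm,
    )


def cohort_summaries(
    connectomes: dict[str, NormalizedConnectome],
    meta: pd.DataFrame,
    subnetworks: tuple[SubnetworkDefinition, ...] = SUBNETWORKS,
) -> pd.DataFrame:
    """Summary table: one row per subject x scope (all + each subnetwork)."""
    meta = meta.set_index("subject") if "subject" in meta.columns else meta
    rows = []
    for sid, norm in connectomes.items():
        pma = meta.loc[sid, "pma"] if sid in meta.index else np.nan
        group = age_bin(pma if np.isfinite(pma) else None)
        for scope in (None, *subnetworks):
            s = subject_summary(norm, scope)
            rows.append(
                {
                    "subject": sid,
                    "group": group,
                    "pma": pma,
                    "scope": s.scope,
                    "proportion": s.proportion,
                    "mean_log_strength": s.mean_log_strength,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_pma_regression(summaries: pd.DataFrame, metric: str) -> RegressionResult:
    """OLS of an infant summary metric on PMA.

    ``summaries`` needs columns ``pma`` and the metric. Rows with missing
    values are dropped; a constant metric yields slope 0 and R-squared 0.
    """
    sub = summaries[["pma", metric]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 infants with {metric}, got {len(sub)}")
    y = sub[metric].to_numpy(dtype=float)
    x = sub["pma"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(sub))
    res = st.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(sub),
    )


def groups_vs_adult(
    summaries: pd.DataFrame,
    metric: str,
    group_order: tuple[str, ...] = AGE_GROUP_ORDER,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons of each infant bin vs the adult control.

    Returns one row per infant group with the mean difference (group -
    adult), the Dunnett statistic, the familywise-corrected p-value and a
    95% simultaneous confidence interval. Groups with fewer than 2 usable
    values are excluded with a warning. The seed controls the multivariate-t
    integration used for the correction.
    """
    sub = summaries[["group", metric]].dropna()
    control = sub.loc[sub["group"] == "adult", metric].to_numpy(dtype=float)
    if control.size == 0:
        raise ValueError("adult control group is empty")
    samples, labels = [], []
    for g in group_order:
        if g == "adult":
            continue
        v = sub.loc[sub["group"] == g, metric].to_numpy(dtype=float)
        if v.size < 2:
            if v.size:
                warnings.warn(f"group {g} has n={v.size} < 2; excluded", stacklevel=2)
            continue
        samples.append(v)
        labels.append(g)
    if len(samples) < 2:
        raise ValueError("need at least 2 infant groups for Dunnett comparisons")

    res = st.dunnett(*samples, control=control, rng=np.random.default_rng(seed))
    ci = res.confidence_interval(confidence_level=0.95)
    return pd.DataFrame(
        {
            "group": labels,
            "n": [len(s) for s in samples],
            "estimate": [float(s.mean() - control.mean()) for s in samples],
            "statistic": res.statistic,
            "p_corrected": res.pvalue,
            "ci_low": ci.low,
            "ci_high": ci.high,
        }
    )


@dataclass
class AnovaResult:
    table: pd.DataFrame  # statsmodels Type II ANOVA table
    interaction_variance_share: float  # SS_interaction / SS_total
    tukey_subnetworks_within_age: pd.DataFrame
    tukey_ages_within_subnetwork: pd.DataFrame


def subnetwork_anova(
    summaries: pd.DataFrame, metric: str, tukey: bool = True
) -> AnovaResult:
    """Two-way fixed-effects age x subnetwork ANOVA with interaction.

    Expects the per-subnetwork rows of :func:`cohort_summaries` (scope !=
    "all"): each subject contributes one value per subnetwork, treated as
    independent observations. Type II sums of squares are used on the
    unbalanced layout. Tukey-corrected pairwise comparisons are run for
    subnetworks within each age group and for age groups within each
    subnetwork.
    """
    df = summaries.loc[summaries["scope"] != "all", ["group", "scope", metric]].dropna()
    df = df.rename(columns={metric: "y"})
    cells = df.groupby(["group", "scope"]).size()
    for g in df["group"].unique():
        for s in df["scope"].unique():
            if (g, s) not in cells.index:
                raise ValueError(f"empty ANOVA cell: age group {g!r} x subnetwork {s!r}")

    model = smf.ols("y ~ C(group) * C(scope)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    ss_inter = float(table.loc["C(group):C(scope)", "sum_sq"])
    share = ss_inter / ss_total if ss_total > 0 else np.nan

    rows_net, rows_age = [], []
    if not tukey:
        return AnovaResult(
            table=table,
            interaction_variance_share=share,
            tukey_subnetworks_within_age=pd.DataFrame(),
            tukey_ages_within_subnetwork=pd.DataFrame(),
        )
    for g, sub in df.groupby("group"):
        if sub["scope"].nunique() > 1:
            tk = pairwise_tukeyhsd(sub["y"], sub["scope"])
            t = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            t.insert(0, "group", g)
            rows_net.append(t)
    for s, sub in df.groupby("scope"):
        if sub["group"].nunique() > 1:
            tk = pairwise_tukeyhsd(sub["y"], sub["group"])
            t = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            t.insert(0, "scope", s)
            rows_age.append(t)

    return AnovaResult(
        table=table,
        interaction_variance_share=share,
        tukey_subnetworks_within_age=pd.concat(rows_net, ignore_index=True),
        tukey_ages_within_subnetwork=pd.concat(rows_age, ignore_index=True),
    )


@dataclass
class ConnectionTestResult:
    tests: pd.DataFrame  # subnetwork, connection, t, p_raw, p_fdr, direction
    tallies: pd.DataFrame  # subnetwork, pct_stronger, pct_weaker, n_connections


def connection_level_tests(
    norm_data: pd.DataFrame,
    term_ids: set[str],
    adult_ids: set[str],
    subnetworks: tuple[SubnetworkDefinition, ...] = SUBNETWORKS,
    alpha: float = 0.05,
    use_log: bool = False,
    fdr_scope: str = "subnetwork",
) -> ConnectionTestResult:
    """Per-connection term-infant vs adult Welch t-tests with FDR control.

    ``norm_data`` is the long-format output of the normalisation stage
    (columns subject, connection, r_norm). For every connection in a
    subnetwork's family, a two-sample unequal-variance t-test compares
    late-term infants with adults on r_norm (or log10 r_norm of present
    values when ``use_log``). Benjamini-Hochberg adjustment is applied
    within each subnetwork's connection family (``fdr_scope="subnetwork"``,
    default) or once across the union of all families
    (``fdr_scope="global"``); the tallies give the share of connections
    significantly stronger / weaker in term infants.
    """
    if fdr_scope not in ("subnetwork", "global"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope!r}")
    df = norm_data[["subject", "connection", "r_norm"]].dropna()
    if use_log:
        df = df[df["r_norm"] > 0].copy()
        df["r_norm"] = np.log10(df["r_norm"])

    cache: dict[str, tuple[float, float]] = {}

    def welch(cid: str) -> tuple[float, float]:
        if cid not in cache:
            sub = df[df["connection"] == cid]
            a = sub.loc[sub["subject"].isin(term_ids), "r_norm"].to_numpy()
            b = sub.loc[sub["subject"].isin(adult_ids), "r_norm"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(f"connection {cid}: need >= 2 subjects per group")
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                cache[cid] = (np.nan, np.nan)  # degenerate: flagged, not tested
            else:
                t, p = st.ttest_ind(a, b, equal_var=False)
                cache[cid] = (float(t), float(p))
        return cache[cid]

    global_q: dict[str, float] = {}
    if fdr_scope == "global":
        union = sorted({c for net in subnetworks for c in net.connections})
        raw = np.array([welch(c)[1] for c in union])
        ok = np.isfinite(raw)
        adj = np.full(len(union), np.nan)
        if ok.any():
            _, adj[ok], _, _ = multipletests(raw[ok], alpha=alpha, method="fdr_bh")
        global_q = dict(zip(union, adj))

    test_rows, tally_rows = [], []
    for net in subnetworks:
        fam = list(net.connections)
        stats = [welch(c) for c in fam]
        raw_p = np.array([p for _, p in stats])
        testable = np.isfinite(raw_p)
        p_fdr = np.full(len(fam), np.nan)
        if fdr_scope == "global":
            p_fdr = np.array([global_q[c] for c in fam])
        elif testable.any():
            _, adj, _, _ = multipletests(raw_p[testable], alpha=alpha, method="fdr_bh")
            p_fdr[testable] = adj
        stronger = weaker = 0
        for (cid, (t, p), q) in zip(fam, stats, p_fdr):
            sig = np.isfinite(q) and q < alpha
            direction = "stronger" if (np.isfinite(t) and t > 0) else "weaker"
            if sig and t > 0:
                stronger += 1
            elif sig and t < 0:
                weaker += 1
            test_rows.append(
                {
                    "subnetwork": net.name,
                    "connection": cid,
                    "t": t,
                    "p_raw": p,
                    "p_fdr": q,
                    "significant": bool(sig),
                    "direction": direction if np.isfinite(t) else "untestable",
                }
            )
        tally_rows.append(
            {
                "subnetwork": net.name,
                "n_connections": len(fam),
                "pct_stronger": 100.0 * stronger / len(fam),
                "pct_weaker": 100.0 * weaker / len(fam),
            }
        )
    return ConnectionTestResult(
        tests=pd.DataFrame(test_rows), tallies=pd.DataFrame(tally_rows)
    )


def connection_prevalence_maps(norm_data: pd.DataFrame) -> pd.DataFrame:
    """Per age bin and connection: share of subjects with the connection
    present and its mean strength among present subjects."""
    df = norm_data.copy()
    df["group"] = [
        age_bin(p if np.isfinite(p) else None) for p in df["pma"]
    ]
    rows = []
    for (g, cid), sub in df.groupby(["group", "connection"]):
        nm = sub["present"].notna()
        present = sub["present"].eq(True)
        n_nm = int(nm.sum())
        rows.append(
            {
                "group": g,
                "connection": cid,
                "prevalence": present.sum() / n_nm if n_nm else np.nan,
                "mean_strength": sub.loc[present, "r_norm"].mean(),
            }
        )
    return pd.DataFrame(rows)
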