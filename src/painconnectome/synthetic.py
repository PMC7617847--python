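"""Synthetic cohort generator for the pain-connectome pipeline.

Generates per-subject multivariate BOLD-like time series whose ground-truth
partial-correlation structure follows designed, age-dependent growth curves
toward adult targets.  The generator emulates the structure of the infant
and adult resting-state acquisitions the pipeline targets (infants: 2300
time points; adults: 1200), so every downstream stage — partial correlation,
adult normalisation, presence calling, maturation statistics — is testable
without external imaging data.

Signal model
------------
Each subject's series is a stationary zero-mean Gaussian process on 24
channels (12 ROI types x 2 hemispheres).  The two hemispheric 12-region
blocks are generated independently (block-diagonal precision); within a
hemisphere the precision matrix is constructed so that the absolute partial
correlation of each ROI pair equals a target set by that connection's
:class:`GrowthModel` at the subject's postmenstrual age (PMA), with small
hemispheric jitter.  Temporal autocorrelation is off by default (an AR(1)
coefficient is available as a knob); it changes only the effective sample
size, not the partial-correlation structure under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import (
    COLUMN_ORDER,
    CONNECTIONS,
    HEMISPHERES,
    ROI_TYPES,
    SUBNETWORKS,
    ConnectionIndex,
    connection_id,
)

MAX_TARGET = 0.9
_PD_EPS = 1e-6


@dataclass(frozen=True)
class GrowthModel:
    """Logistic growth of one connection's partial-correlation target.

    target(PMA) = floor + (adult_target - floor) * logistic(rate * (PMA - onset_pma))

    Parameters
    ----------
    connection_id
        Canonical ``"A-B"`` id of the unordered ROI-type pair.
    adult_target
        Asymptotic absolute partial correlation, in [0, 0.9].
    onset_pma
        PMA (weeks) at which the curve reaches its midpoint.
    rate
        Steepness in 1/weeks; ``rate >= 0`` so the curve is nondecreasing.
    floor
        Early-gestation baseline, in [0, adult_target].
    """

    connection_id: str
    adult_target: float
    onset_pma: float
    rate: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.adult_target <= MAX_TARGET:
            raise ValueError(
                f"adult_target must be in [0, {MAX_TARGET}], got {self.adult_target}"
            )
        if not 0.0 <= self.floor <= self.adult_target:
            raise ValueError(
                f"floor must be in [0, adult_target], got {self.floor}"
            )
        if self.rate < 0:
            raise ValueError(f"rate must be nonnegative, got {self.rate}")


def growth_target(model: GrowthModel, pma: float) -> float:
    """Evaluate a growth curve at a given PMA (weeks).

    Returns ``floor + (adult_target - floor) * expit(rate * (pma - onset))``,
    which lies in ``[floor, adult_target]`` and is nondecreasing in PMA.
    """
    if pma <= 0:
        raise ValueError(f"pma must be positive, got {pma}")
    from scipy.special import expit

    z = model.rate * (pma - model.onset_pma)
    return float(model.floor + (model.adult_target - model.floor) * expit(z))


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: an infant PMA bin or the adult reference group."""

    label: str
    n: int
    pma_range: tuple[float, float] | None = None  # None => adult group

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r} must have n >= 1, got {self.n}")
        if self.pma_range is not None:
            lo, hi = self.pma_range
            if not (0 < lo <= hi):
                raise ValueError(f"invalid PMA range for group {self.label!r}: {self.pma_range}")

    @property
    def is_adult(self) -> bool:
        return self.pma_range is None


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``growth_models`` must contain exactly one model per connection of
    ``connection_index``.  ``infant_target_scale`` optionally multiplies
    infant-group targets per connection (clipped to [0, 0.9]) without
    touching the adult group — this is how overshoot designs, where
    late-term infants exceed adult strength, are expressed.

    ``connection_signs`` fixes the sign of each generating partial
    correlation (the pipeline analyses absolute values, so signs only
    serve positive definiteness); if empty, the default balanced pattern
    of :func:`default_connection_signs` is used.
    """

    groups: tuple[GroupSpec, ...]
    growth_models: dict[str, GrowthModel]
    infant_series_length: int = 2300
    adult_series_length: int = 1200
    hemispheric_asymmetry_sd: float = 0.02
    ar1: float = 0.0
    seed: int = 0
    infant_target_scale: dict[str, float] = field(default_factory=dict)
    connection_signs: dict[str, int] = field(default_factory=dict)
    connection_index: ConnectionIndex = field(default_factory=lambda: CONNECTIONS)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort must have at least one group")
        want = set(self.connection_index.ids)
        have = set(self.growth_models)
        if want != have:
            missing, extra = sorted(want - have), sorted(have - want)
            raise ValueError(
                f"growth_models must cover every connection exactly once; "
                f"missing={missing[:5]} extra={extra[:5]}"
            )
        for tlen in (self.infant_series_length, self.adult_series_length):
            if tlen < 50:
                raise ValueError(f"series length must be >= 50, got {tlen}")
        if not 0 <= self.ar1 < 1:
            raise ValueError(f"ar1 must be in [0, 1), got {self.ar1}")
        unknown = set(self.infant_target_scale) - want
        if unknown:
            raise ValueError(f"infant_target_scale has unknown connections: {sorted(unknown)[:5]}")
        if not self.connection_signs:
            object.__setattr__(
                self, "connection_signs", default_connection_signs(self.connection_index)
            )
        if set(self.connection_signs) != want:
            raise ValueError("connection_signs must cover every connection exactly once")
        if any(s not in (-1, 1) for s in self.connection_signs.values()):
            raise ValueError("connection signs must be +/-1")


@dataclass
class SubjectRecord:
    """One simulated subject: metadata plus the T x 24 time-series matrix.

    Columns follow :data:`painconnectome.rois.COLUMN_ORDER` (12 left-
    hemisphere ROIs in canonical order, then the 12 right-hemisphere ROIs).
    """

    id: str
    group: str
    pma: float | None  # weeks; None for adults
    pna: float | None  # days; None for adults
    sex: str
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[1] != len(COLUMN_ORDER):
            raise ValueError(f"timeseries must be T x {len(COLUMN_ORDER)}, got {ts.shape}")
        if not np.all(np.isfinite(ts)):
            raise ValueError("timeseries contains non-finite values")
        self.timeseries = ts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.timeseries, columns=list(COLUMN_ORDER))


@dataclass(frozen=True)
class PrecisionResult:
    """Precision matrix with the shrinkage applied to make it positive definite."""

    matrix: np.ndarray
    shrinkage: float  # 1.0 when no diagonal loading was needed
    achieved_targets: dict[tuple[int, int], float]


def build_precision_matrix(
    targets: dict[tuple[int, int], float],
    n_regions: int,
    signs: dict[tuple[int, int], int] | None = None,
) -> PrecisionResult:
    """Build a symmetric positive-definite precision matrix realising the
    requested absolute partial correlations.

    The naive construction puts 1 on the diagonal and ``-s*t`` at each
    target pair (``s`` an optional sign, +1 by default), so that the
    partial correlation ``-P_ij / sqrt(P_ii P_jj)`` equals ``s*t`` and its
    absolute value equals ``t``.  A dense all-positive partial-correlation
    pattern is only positive definite for small targets (< 1/(R-1) when
    all pairs share one value), so realistic designs mix signs.  If the
    matrix is still not positive definite, uniform diagonal loading
    ``P + lam*I`` is applied, which shrinks every target by the factor
    ``1 / (1 + lam)``; the factor is reported so callers can record the
    achieved (shrunken) targets as ground truth.
    """
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    signs = signs or {}
    P = np.eye(n_regions)
    for (i, j), t in targets.items():
        if i == j or not (0 <= i < n_regions) or not (0 <= j < n_regions):
            raise ValueError(f"invalid pair index ({i}, {j}) for R={n_regions}")
        if not 0.0 <= t <= MAX_TARGET:
            raise ValueError(f"target for pair ({i}, {j}) outside [0, {MAX_TARGET}]: {t}")
        s = signs.get((i, j), signs.get((j, i), 1))
        if s not in (-1, 1):
            raise ValueError(f"sign for pair ({i}, {j}) must be +/-1, got {s}")
        P[i, j] = P[j, i] = -s * t

    min_eig = float(np.linalg.eigvalsh(P)[0])
    lam = 0.0
    if min_eig <= _PD_EPS:
        lam = _PD_EPS - min_eig
        P = P + lam * np.eye(n_regions)
    shrinkage = 1.0 / (1.0 + lam)
    achieved = {pair: t * shrinkage for pair, t in targets.items()}
    if np.linalg.eigvalsh(P)[0] <= 0:
        raise RuntimeError(
            "precision matrix not positive definite after diagonal loading "
            f"(lambda={lam:.3g}, min_eig={min_eig:.3g})"
        )
    return PrecisionResult(matrix=P, shrinkage=shrinkage, achieved_targets=achieved)


def partial_correlations_of_precision(P: np.ndarray) -> np.ndarray:
    """Analytic partial-correlation matrix of a precision matrix."""
    d = np.sqrt(np.diag(P))
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _hemisphere_targets(
    spec: CohortSpec, pma: float | None, rng: np.random.Generator, adult: bool
) -> dict[str, dict[str, float]]:
    """Per-connection generating targets for each hemisphere at this age.

    Adults sit at the asymptotic ``adult_target``; infants at the growth
    curve evaluated at their PMA, optionally rescaled by
    ``infant_target_scale``.  Hemispheric jitter N(0, sd) is added
    independently per hemisphere and the result clipped to [0, 0.9].
    """
    out: dict[str, dict[str, float]] = {h: {} for h in HEMISPHERES}
    for cid in spec.connection_index.ids:
        model = spec.growth_models[cid]
        if adult:
            base = model.adult_target
        else:
            base = growth_target(model, pma)
            base *= spec.infant_target_scale.get(cid, 1.0)
        for hemi in HEMISPHERES:
            jitter = rng.normal(0.0, spec.hemispheric_asymmetry_sd) if spec.hemispheric_asymmetry_sd > 0 else 0.0
            out[hemi][cid] = float(np.clip(base + jitter, 0.0, MAX_TARGET))
    return out


def _sample_block(
    targets: dict[str, float],
    signs: dict[str, int],
    index: ConnectionIndex,
    n_time: int,
    ar1: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, float]]:
    """Sample one hemisphere's T x 12 series; returns data and achieved targets."""
    pos = {roi: k for k, roi in enumerate(ROI_TYPES)}
    pair_targets = {
        (pos[a], pos[b]): targets[connection_id(a, b)] for a, b in index.pairs
    }
    pair_signs = {
        (pos[a], pos[b]): signs[connection_id(a, b)] for a, b in index.pairs
    }
    res = build_precision_matrix(pair_targets, len(ROI_TYPES), signs=pair_signs)
    cov = np.linalg.inv(res.matrix)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_time, len(ROI_TYPES))) @ L.T
    if ar1 > 0:
        # AR(1) filter with innovation scaling keeps the marginal covariance.
        x = np.empty_like(z)
        x[0] = z[0]
        c = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_time):
            x[t] = ar1 * x[t - 1] + c * z[t]
        z = x
    achieved = {
        connection_id(a, b): res.achieved_targets[(pos[a], pos[b])]
        for a, b in index.pairs
    }
    return z, achieved


def _subject_rng(spec_seed: int, subject_counter: int) -> np.random.Generator:
    """Deterministic per-subject stream: the cohort seed is the SeedSequence
    entropy and the subject's position in the cohort is the spawn key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec_seed, spawn_key=(subject_counter,))
    )


def simulate_subject(
    spec: CohortSpec,
    pma: float | None,
    seed_counter: int,
    *,
    group: str = "group",
    subject_id: str | None = None,
    adult: bool = False,
    pna: float | None = None,
    sex: str = "F",
    series_length: int | None = None,
) -> tuple[SubjectRecord, pd.DataFrame]:
    """Simulate one subject and return the record plus its ground truth.

    The ground-truth frame has one row per connection with the left, right
    and hemisphere-mean generating targets actually realised (after jitter,
    clipping, and any positive-definiteness shrinkage).
    """
    rng = _subject_rng(spec.seed, seed_counter)
    if not adult and (pma is None or pma <= 0):
        raise ValueError(f"infant subject needs a positive PMA, got {pma}")
    targets = _hemisphere_targets(spec, pma, rng, adult)
    if series_length is None:
        series_length = spec.adult_series_length if adult else spec.infant_series_length

    blocks, achieved = [], {}
    for hemi in HEMISPHERES:
        data, ach = _sample_block(
            targets[hemi],
            spec.connection_signs,
            spec.connection_index,
            series_length,
            spec.ar1,
            rng,
        )
        blocks.append(data)
        achieved[hemi] = ach
    ts = np.concatenate(blocks, axis=1)

    if subject_id is None:
        subject_id = f"sub-{seed_counter:04d}"
    record = SubjectRecord(
        id=subject_id, group=group, pma=pma, pna=pna, sex=sex, timeseries=ts
    )
    truth = pd.DataFrame(
        {
            "subject": subject_id,
            "group": group,
            "pma": np.nan if pma is None else pma,
            "connection": list(spec.connection_index.ids),
            "target_left": [achieved["L"][c] for c in spec.connection_index.ids],
            "target_right": [achieved["R"][c] for c in spec.connection_index.ids],
        }
    )
    truth["target_mean"] = (truth["target_left"] + truth["target_right"]) / 2.0
    return record, truth


def simulate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate every group of the cohort.

    Infant PMA is drawn uniformly within the group range; adults are
    generated at the asymptotic targets.  Returns the subject records and a
    ground-truth table with one row per subject x connection.
    """
    records: list[SubjectRecord] = []
    truths: list[pd.DataFrame] = []
    meta_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(2**20,))
    )
    counter = 0
    for grp in spec.groups:
        for _ in range(grp.n):
            if grp.is_adult:
                pma, pna = None, None
            else:
                lo, hi = grp.pma_range
                pma = float(meta_rng.uniform(lo, hi))
                pna = float(meta_rng.uniform(0, 14))
            sex = "F" if meta_rng.random() < 0.5 else "M"
            rec, truth = simulate_subject(
                spec,
                pma,
                counter,
                group=grp.label,
                subject_id=f"sub-{counter:04d}",
                adult=grp.is_adult,
                pna=pna,
                sex=sex,
            )
            records.append(rec)
            truths.append(truth)
            counter += 1
    return records, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# Default growth-curve design
# ---------------------------------------------------------------------------

#: Default midpoint PMA (weeks) per subnetwork: the sensory subnetwork
#: matures first, the cognitive last, matching the qualitative developmental
#: ordering the pipeline is designed to resolve.
DEFAULT_ONSETS = {"sensory": 31.0, "affective": 35.0, "cognitive": 39.0, "other": 36.0}

#: Sign-pattern seed chosen once (by eigenvalue margin of the implied
#: precision matrices) so the default design never needs diagonal loading,
#: even with sensory targets inflated 1.6x and hemispheric jitter.
_SIGN_SEED = 2301


def default_connection_signs(index: ConnectionIndex = CONNECTIONS) -> dict[str, int]:
    """Fixed, balanced sign pattern for the generating partial correlations.

    Mixed signs are what keep a dense 12-region partial-correlation
    pattern positive definite at realistic magnitudes; the analysis takes
    absolute values, so the pattern is otherwise inconsequential.
    """
    rng = np.random.default_rng(_SIGN_SEED)
    return {cid: int(rng.choice([-1, 1])) for cid in index.ids}


def default_growth_models(
    adult_target: float = 0.18,
    background_target: float = 0.03,
    floor: float = 0.02,
    rate: float = 0.45,
    onsets: dict[str, float] | None = None,
    index: ConnectionIndex = CONNECTIONS,
) -> dict[str, GrowthModel]:
    """One growth model per connection with subnetwork-ordered onsets.

    Connections inside a subnetwork grow toward ``adult_target``; the
    background connections outside every subnetwork sit near
    ``background_target``, giving the sparse structure a dense
    12-region partial-correlation matrix needs to stay positive definite
    at magnitudes well above estimation noise.  A connection inherits the
    earliest onset among the subnetworks that contain it; background
    connections get the ``"other"`` onset.  Defaults put the growth
    midpoints three weeks apart so the sensory < affective < cognitive
    maturation ordering is resolvable at realistic estimation noise.
    """
    onsets = dict(DEFAULT_ONSETS if onsets is None else onsets)
    membership: dict[str, list[str]] = {cid: [] for cid in index.ids}
    for net in SUBNETWORKS:
        for cid in net.connections:
            membership[cid].append(net.name)
    models = {}
    for cid in index.ids:
        nets = membership[cid]
        if nets:
            onset = min(onsets[n] for n in nets)
            target = adult_target
            cid_floor = min(floor, target)
        else:
            onset = onsets["other"]
            target = background_target
            cid_floor = min(floor, target / 2.0)
        models[cid] = GrowthModel(
            connection_id=cid,
            adult_target=target,
            onset_pma=onset,
            rate=rate,
            floor=cid_floor,
        )
    return models


#: Infant PMA bins and printed group sizes of the cohorts the generator
#: emulates, plus the adult reference group.
DHCP_LIKE_GROUPS: tuple[tuple[str, tuple[float, float] | None, int], ...] = (
    ("<32", (26.0, 32.0), 8),
    ("32-34", (32.0, 34.0), 8),
    ("34-36", (34.0, 36.0), 34),
    ("36-38", (36.0, 38.0), 40),
    ("38-40", (38.0, 40.0), 100),
    ("40-42", (40.0, 42.0), 182),
    ("adult", None, 98),
)


def dhcp_like_cohort_spec(
    seed: int = 0,
    scale: float = 1.0,
    infant_series_length: int = 2300,
    adult_series_length: int = 1200,
    growth_models: dict[str, GrowthModel] | None = None,
    **kwargs,
) -> CohortSpec:
    """CohortSpec mirroring the emulated cohorts' group structure.

    ``scale`` < 1 shrinks every group size for desk-scale runs; the bin
    boundaries and series lengths are kept.  Scaled groups are floored at
    6 subjects (or the printed size if smaller): the youngest bin seeds
    the presence threshold and anchors the Cook-distance age regression,
    and with fewer subjects those stages become degenerate rather than
    merely noisy.
    """
    groups = tuple(
        GroupSpec(label=lab, n=max(min(n, 6), round(n * scale)), pma_range=rng)
        for lab, rng, n in DHCP_LIKE_GROUPS
    )
    return CohortSpec(
        groups=groups,
        growth_models=growth_models or default_growth_models(),
        infant_series_length=infant_series_length,
        adult_series_length=adult_series_length,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Toy image rendering (fixtures for ROI extraction)
# ---------------------------------------------------------------------------


def render_toy_images(
    subject: SubjectRecord,
    atlas_layout: dict[str, list[tuple[int, int, int]]],
    shape: tuple[int, int, int] | None = None,
    voxel_noise_sd: float = 0.0,
    gm_mask: np.ndarray | None = None,
    seed: int = 0,
):
    """Render a subject's series into a toy 4D volume plus atlas and GM mask.

    Every voxel of a region carries that region's time series plus optional
    i.i.d. voxel noise.  ``atlas_layout`` maps column names (e.g.
    ``"thalamus_L"``) to voxel index triples; integer labels 1..24 are
    assigned in :data:`COLUMN_ORDER` order.  The gray-matter mask defaults
    to 1 at every labelled voxel; pass a custom mask to exercise
    gray-matter-restricted extraction.

    Returns ``(bold_img, label_img, gm_img, label_table)`` where the images
    are :class:`nibabel.Nifti1Image` and the table maps
    (roi_type, hemisphere) to label ids.
    """
    import nibabel as nib

    missing = [c for c in atlas_layout if c not in COLUMN_ORDER]
    if missing:
        raise ValueError(f"unknown columns in atlas layout: {missing}")
    for col, voxels in atlas_layout.items():
        if len(voxels) < 1:
            raise ValueError(f"region {col} has no voxels")

    all_vox = [v for voxels in atlas_layout.values() for v in voxels]
    if len(set(all_vox)) != len(all_vox):
        raise ValueError("overlapping labels: some voxels belong to multiple regions")
    if shape is None:
        maxes = np.max(np.array(all_vox), axis=0)
        shape = tuple(int(m) + 1 for m in maxes)

    n_time = subject.timeseries.shape[0]
    rng = np.random.default_rng(seed)
    bold = np.zeros(shape + (n_time,), dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)

    rows = []
    for col_idx, col in enumerate(COLUMN_ORDER):
        if col not in atlas_layout:
            continue
        label = col_idx + 1
        roi, hemi = col.rsplit("_", 1)
        rows.append({"roi_type": roi, "hemisphere": hemi, "label": label})
        series = subject.timeseries[:, col_idx]
        for x, y, z in atlas_layout[col]:
            noisy = series
            if voxel_noise_sd > 0:
                noisy = series + rng.normal(0.0, voxel_noise_sd, size=n_time)
            bold[x, y, z, :] = noisy
            labels[x, y, z] = label

    if gm_mask is None:
        gm = (labels > 0).astype(np.float32)
    else:
        gm = np.asarray(gm_mask, dtype=np.float32)
        if gm.shape != shape:
            raise ValueError(f"gm_mask shape {gm.shape} != volume shape {shape}")

    affine = np.eye(4)
    bold_img = nib.Nifti1Image(bold, affine)
    label_img = nib.Nifti1Image(labels, affine)
    gm_img = nib.Nifti1Image(gm, affine)
    label_table = pd.DataFrame(rows)
    return bold_img, label_img, gm_img, label_table
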