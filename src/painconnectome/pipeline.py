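"""End-to-end pipeline orchestration.

A single validated :class:`RunConfig` drives the chain
simulate/extract -> connect -> normalize -> stats; every intermediate table
is written to the run directory together with a manifest recording the
config hash, the seed, and per-stage counts, so identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, extraction, normalization, stats, synthetic

INFANT_PMA_RANGE = (26.0, 42.0)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a pipeline run.

    Unknown keys in a config file are rejected up front; every stage
    decision (conditioning mode, FDR family, boundary conventions) is
    recorded in the run manifest.
    """

    mode: str = "synthetic"
    seed: int = 0
    output_dir: str = "run"
    conditioning: str = "per_hemisphere"
    fdr_scope: str = "subnetwork"
    use_log_strength_tests: bool = False
    # synthetic-mode knobs
    cohort_scale: float = 1.0
    infant_series_length: int = 2300
    adult_series_length: int = 1200
    adult_target: float = 0.18
    background_target: float = 0.03
    growth_floor: float = 0.02
    growth_rate: float = 0.45
    growth_onsets: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_ONSETS))
    hemispheric_asymmetry_sd: float = 0.02
    ar1: float = 0.0
    infant_target_scale: dict = field(default_factory=dict)
    # real-mode inputs
    subject_table: str | None = None
    bold_dir: str | None = None
    atlas_image: str | None = None
    atlas_table: str | None = None
    gm_mask: str | None = None
    min_voxels: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be synthetic or real, got {self.mode!r}")
        if self.conditioning not in ("per_hemisphere", "joint"):
            raise ValueError(f"unknown conditioning mode: {self.conditioning!r}")
        if self.fdr_scope not in ("subnetwork", "global"):
            raise ValueError(f"unknown fdr_scope: {self.fdr_scope!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(config: RunConfig) -> list[str]:
    """Check a config's inputs and return every problem found (empty = ok)."""
    problems: list[str] = []
    if config.mode == "synthetic":
        try:
            _cohort_spec(config)
        except ValueError as exc:
            problems.append(str(exc))
        return problems

    for name in ("subject_table", "bold_dir", "atlas_image", "atlas_table", "gm_mask"):
        value = getattr(config, name)
        if value is None:
            problems.append(f"real mode requires {name}")
        elif not Path(value).exists():
            problems.append(f"{name} does not exist: {value}")
    table_path = config.subject_table
    if table_path and Path(table_path).exists():
        table = pd.read_csv(table_path)
        required = {"subject", "group", "pma"}
        missing = required - set(table.columns)
        if missing:
            problems.append(f"subject table missing columns: {sorted(missing)}")
        elif "pma" in table.columns:
            infants = table[table["group"] != "adult"]
            lo, hi = INFANT_PMA_RANGE
            bad = infants[(infants["pma"] < lo) | (infants["pma"] > hi)]
            for row in bad.itertuples():
                problems.append(
                    f"subject {row.subject}: PMA {row.pma} outside [{lo}, {hi}]"
                )
    return problems


def _cohort_spec(config: RunConfig) -> synthetic.CohortSpec:
    models = synthetic.default_growth_models(
        adult_target=config.adult_target,
        background_target=config.background_target,
        floor=config.growth_floor,
        rate=config.growth_rate,
        onsets=config.growth_onsets,
    )
    return synthetic.dhcp_like_cohort_spec(
        seed=config.seed,
        scale=config.cohort_scale,
        infant_series_length=config.infant_series_length,
        adult_series_length=config.adult_series_length,
        growth_models=models,
        hemispheric_asymmetry_sd=config.hemispheric_asymmetry_sd,
        ar1=config.ar1,
        infant_target_scale=dict(config.infant_target_scale),
    )


def _simulate_stage(config: RunConfig):
    spec = _cohort_spec(config)
    records, truth = synthetic.simulate_cohort(spec)
    meta = pd.DataFrame(
        {
            "subject": [r.id for r in records],
            "group": [r.group for r in records],
            "pma": [r.pma if r.pma is not None else np.nan for r in records],
            "pna": [r.pna if r.pna is not None else np.nan for r in records],
            "sex": [r.sex for r in records],
        }
    )
    return records, meta, truth


def _connect_stage(records, config: RunConfig) -> pd.DataFrame:
    vectors = [
        connectivity.connection_vector(
            r.timeseries, subject_id=r.id, conditioning=config.conditioning
        )
        for r in records
    ]
    return connectivity.cohort_connection_table(vectors)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and write all artifacts to the run directory.

    Returns the run directory path. Raises with the stage name on any
    stage failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        if config.mode == "synthetic":
            records, meta, truth = _simulate_stage(config)
            truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            stage = "extract"
            records, meta = _extract_stage(config)
        meta.to_csv(out / "subjects.csv", index=False)

        stage = "connect"
        conn_table = _connect_stage(records, config)
        conn_table.to_csv(out / "connections.csv", index=False)

        stage = "normalize"
        norm = normalization.normalize_cohort(conn_table, meta)
        norm.data.to_csv(out / "normalized.csv", index=False)
        (out / "outlier_report.json").write_text(
            json.dumps(norm.report.to_json_dict(), indent=1)
        )
        (out / "reference.json").write_text(
            json.dumps(
                {"threshold": norm.threshold, "adult_means": norm.reference.means},
                indent=1,
            )
        )

        stage = "stats"
        summaries = stats.cohort_summaries(norm.connectomes, meta)
        summaries.to_csv(out / "summaries.csv", index=False)

        infants_all = summaries[
            (summaries["scope"] == "all") & np.isfinite(summaries["pma"])
        ]
        reg_rows = []
        for metric in ("proportion", "mean_log_strength"):
            r = stats.fit_pma_regression(infants_all, metric)
            reg_rows.append({"metric": metric, **dataclasses.asdict(r)})
        pd.DataFrame(reg_rows).to_csv(out / "pma_regression.csv", index=False)

        dunnett_rows = []
        for metric in ("proportion", "mean_log_strength"):
            d = stats.groups_vs_adult(
                summaries[summaries["scope"] == "all"], metric, seed=config.seed
            )
            d.insert(0, "metric", metric)
            dunnett_rows.append(d)
        pd.concat(dunnett_rows, ignore_index=True).to_csv(
            out / "dunnett.csv", index=False
        )

        anova_rows, tukey_net, tukey_age = [], [], []
        for metric in ("proportion", "mean_log_strength"):
            try:
                a = stats.subnetwork_anova(summaries, metric)
            except ValueError as exc:
                # tiny cohorts can leave a cell empty (e.g. no present
                # connections in the youngest bin); skip the metric
                warnings.warn(f"ANOVA skipped for {metric}: {exc}", stacklevel=2)
                continue
            t = a.table.reset_index().rename(columns={"index": "term"})
            t.insert(0, "metric", metric)
            t["interaction_variance_share"] = a.interaction_variance_share
            anova_rows.append(t)
            a.tukey_subnetworks_within_age.insert(0, "metric", metric)
            a.tukey_ages_within_subnetwork.insert(0, "metric", metric)
            tukey_net.append(a.tukey_subnetworks_within_age)
            tukey_age.append(a.tukey_ages_within_subnetwork)
        for rows, name in (
            (anova_rows, "anova.csv"),
            (tukey_net, "tukey_subnetworks.csv"),
            (tukey_age, "tukey_age_groups.csv"),
        ):
            frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
            frame.to_csv(out / name, index=False)

        term_ids = set(meta.loc[meta["group"] == "40-42", "subject"])
        adult_ids = set(meta.loc[meta["group"] == "adult", "subject"])
        ct = stats.connection_level_tests(
            norm.data,
            term_ids,
            adult_ids,
            use_log=config.use_log_strength_tests,
            fdr_scope=config.fdr_scope,
        )
        ct.tests.to_csv(out / "connection_tests.csv", index=False)
        ct.tallies.to_csv(out / "connection_tallies.csv", index=False)

        maps = stats.connection_prevalence_maps(norm.data)
        maps.to_csv(out / "connection_maps.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": int(len(meta)),
        "n_connections_present_rows": int(norm.data["present"].eq(True).sum()),
        "infant_discard_fraction": norm.report.infant_fraction,
        "adult_discard_fraction": norm.report.adult_fraction,
        "presence_threshold": norm.threshold,
        "decisions": {
            "conditioning": config.conditioning,
            "fdr_scope": config.fdr_scope,
            "outlier_boundary": "strict (> 3x)",
            "presence_boundary": "strict (< threshold)",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _extract_stage(config: RunConfig):
    """Real-data mode: per-subject ROI extraction from NIfTI inputs."""
    meta = pd.read_csv(config.subject_table)
    atlas = extraction.load_atlas(config.atlas_image, config.atlas_table)
    records = []
    for row in meta.itertuples():
        bold_path = Path(config.bold_dir) / f"{row.subject}_bold.nii.gz"
        if not bold_path.exists():
            bold_path = Path(config.bold_dir) / f"{row.subject}_bold.nii"
        ts = extraction.extract_roi_timeseries(
            bold_path,
            atlas,
            config.gm_mask,
            min_voxels=config.min_voxels,
            subject_id=str(row.subject),
        )
        is_adult = getattr(row, "group", "") == "adult"
        pma = None if is_adult else float(row.pma)
        records.append(
            synthetic.SubjectRecord(
                id=str(row.subject),
                group=str(row.group),
                pma=pma,
                pna=float(getattr(row, "pna", np.nan)) if not is_adult else None,
                sex=str(getattr(row, "sex", "")),
                timeseries=ts.matrix,
            )
        )
    meta = meta.rename(columns=str.lower)
    return records, meta
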