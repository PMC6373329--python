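"""Readers, writers, image-space TAC extraction and the end-to-end pipeline.

File conventions: CSV (comma, UTF-8, mandatory header), frame times in seconds
in files and minutes in the math; TAC tables carry the columns
``region,frame_start_s,frame_end_s,value_kbq_ml``.  A cohort directory holds
one TAC table per subject, a ground-truth CSV, the clinical covariate table
and a JSON manifest recording config, seed and package version.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    CohortDataset,
    RegionSpec,
    SubjectData,
    SubjectKinetics,
    generate_cohort,
)
from .framing import FrameSchedule, TimeActivityCurve, build_schedule

logger = logging.getLogger("netpet")

TAC_COLUMNS = ("region", "frame_start_s", "frame_end_s", "value_kbq_ml")


def load_clinical_table(n_subjects: int | None = None) -> pd.DataFrame:
    """Packaged clinical covariate fixture (10 patients: sex, age, disease
    duration, H/Y stage, UPDRS-III off/on, LEDD).  With ``n_subjects`` the rows
    are recycled/truncated to the requested cohort size."""
    with importlib.resources.files("netpet.data").joinpath("clinical_covariates.csv").open() as fh:
        df = pd.read_csv(fh)
    if n_subjects is not None:
        reps = int(np.ceil(n_subjects / len(df)))
        df = pd.concat([df] * reps, ignore_index=True).iloc[:n_subjects].copy()
        df["patient"] = np.arange(1, n_subjects + 1)
    return df


# ---------------------------------------------------------------------------
# TAC tables
# ---------------------------------------------------------------------------


def write_tac_table(path, tacs: dict[str, TimeActivityCurve]) -> None:
    rows = []
    for name, tac in tacs.items():
        for s, e, v in zip(tac.schedule.starts_s, tac.schedule.ends_s, tac.values):
            rows.append((name, s, e, v))
    # %.17g round-trips doubles exactly; the cohort writer/reader pair is lossless
    pd.DataFrame(rows, columns=list(TAC_COLUMNS)).to_csv(path, index=False, float_format="%.17g")


def read_tac_table(path) -> dict[str, TimeActivityCurve]:
    """Parse a TAC CSV into per-region curves sharing one validated schedule.

    Rows whose frame grid disagrees with the first region's, and non-numeric
    cells, raise a parse error naming the offending CSV row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in TAC_COLUMNS[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise ValueError(f"{path}: non-numeric {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col])

    tacs: dict[str, TimeActivityCurve] = {}
    schedule: FrameSchedule | None = None
    for name, grp in df.groupby("region", sort=False):
        starts = tuple(grp["frame_start_s"].to_numpy(dtype=float))
        ends = tuple(grp["frame_end_s"].to_numpy(dtype=float))
        if schedule is None:
            schedule = FrameSchedule(starts, ends)
        elif starts != schedule.starts_s or ends != schedule.ends_s:
            first_bad = next(
                (i for i, (s, e) in enumerate(zip(starts, ends))
                 if i >= schedule.n_frames or (s, e) != (schedule.starts_s[i], schedule.ends_s[i])),
                0,
            )
            row = int(grp.index[min(first_bad, len(grp) - 1)]) + 2
            raise ValueError(
                f"{path}: region {name!r} schedule differs from the table's at row {row}"
            )
        tacs[name] = TimeActivityCurve(name, schedule, grp["value_kbq_ml"].to_numpy(dtype=float))
    if not tacs:
        raise ValueError(f"{path}: empty TAC table")
    return tacs


# ---------------------------------------------------------------------------
# cohort directories
# ---------------------------------------------------------------------------


def write_cohort(dataset: CohortDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for subj in dataset:
        write_tac_table(outdir / f"{subj.subject_id}_tacs.csv", subj.tacs)
        for r in subj.kinetics.regions:
            truth_rows.append(
                dict(
                    subject=subj.subject_id,
                    region=r.name,
                    true_bp=r.true_bp,
                    r1=r.r1,
                    is_reference=r.is_reference,
                    k2p=subj.kinetics.k2p,
                    k1p=subj.kinetics.k1p,
                )
            )
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False, float_format="%.17g")
    if dataset.clinical is not None:
        dataset.clinical.to_csv(outdir / "clinical.csv", index=False)
    manifest = dict(
        format="netpet-cohort",
        version=__version__,
        schedule_spec=dataset.schedule.to_spec(),
        config=asdict(dataset.config),
        subjects=[s.subject_id for s in dataset],
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def read_cohort(indir) -> CohortDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    cfg = CohortConfig(**manifest["config"])
    schedule = build_schedule(manifest["schedule_spec"])
    truth = pd.read_csv(indir / "ground_truth.csv", float_precision="round_trip")
    clinical_path = indir / "clinical.csv"
    clinical = pd.read_csv(clinical_path) if clinical_path.exists() else None
    subjects = []
    for sid in manifest["subjects"]:
        tacs = read_tac_table(indir / f"{sid}_tacs.csv")
        trows = truth[truth["subject"] == sid]
        regions = tuple(
            RegionSpec(r.region, r.true_bp, r.r1, bool(r.is_reference))
            for r in trows.itertuples()
        )
        kin = SubjectKinetics(
            k2p=float(trows["k2p"].iloc[0]), k1p=float(trows["k1p"].iloc[0]), regions=regions
        )
        subjects.append(SubjectData(sid, tacs, kin))
    return CohortDataset(cfg, schedule, tuple(subjects), clinical)


# ---------------------------------------------------------------------------
# image-space extraction (optional user-data path)
# ---------------------------------------------------------------------------


def extract_tacs_from_image(
    image4d, labels, schedule: FrameSchedule, legend: dict[int, str]
) -> dict[str, TimeActivityCurve]:
    """Per-label mean value per frame from a 4D volume and an integer label map.

    ``image4d``/``labels`` may be numpy arrays or anything with ``get_fdata()``
    (e.g. nibabel images); the 4th axis must equal the frame count.
    """
    img = image4d.get_fdata() if hasattr(image4d, "get_fdata") else np.asarray(image4d)
    lab = labels.get_fdata() if hasattr(labels, "get_fdata") else np.asarray(labels)
    lab = np.rint(lab).astype(int)
    if img.ndim != 4:
        raise ValueError("image must be 4-D (x, y, z, frame)")
    if img.shape[:3] != lab.shape:
        raise ValueError(f"label grid {lab.shape} does not match image grid {img.shape[:3]}")
    if img.shape[3] != schedule.n_frames:
        raise ValueError(
            f"image has {img.shape[3]} frames but the schedule has {schedule.n_frames}"
        )
    present = set(np.unique(lab)) - {0}
    unknown = present - set(legend)
    if unknown:
        raise ValueError(f"label map contains labels missing from the legend: {sorted(unknown)}")
    tacs = {}
    flat = img.reshape(-1, img.shape[3])
    lflat = lab.ravel()
    for value, name in legend.items():
        mask = lflat == value
        if not mask.any():
            raise ValueError(f"label {value} ({name!r}) has no voxels")
        tacs[name] = TimeActivityCurve(name, schedule, flat[mask].mean(axis=0))
    return tacs


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (defaults = the emulated protocol)."""

    schedule_spec: str = "6x30,3x60,2x120,22x300"
    model_window_end_min: float = 90.0
    static_window_starts: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0)
    k2p_policy: str | float = "estimate"  # "estimate" or a fixed value (1/min)
    reference_region: str = "occipital"
    icc_variant: str = "A1"
    correction: str = "bonferroni"
    seed: int = 0
    input_dir: str | None = None  # None -> simulate
    cohort: CohortConfig | None = None  # simulation config when input_dir is None

    def config_hash(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, CohortConfig) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Framing -> MRTM k2' -> population mean -> MRTM2/SRTM2 -> static BP ->
    agreement tables, with one structured log line per stage.

    Returns a bundle dict of DataFrames (and scalars); with ``outdir`` the
    bundle plus a reproducibility manifest are written as CSV/JSON.
    """
    from .agreement import build_agreement_tables, clinical_correlations
    from .kinetics import estimate_population_k2p, model_bp_table, pool_hemispheres
    from .staticbp import static_bp_table

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage=%s elapsed_s=%.3f", name, time.perf_counter() - t0)
        return out

    if config.input_dir is not None:
        dataset = stage("load", lambda: read_cohort(config.input_dir))
    else:
        cc = config.cohort or CohortConfig(seed=config.seed, schedule_spec=config.schedule_spec)
        dataset = stage("simulate", lambda: generate_cohort(cc))

    if config.k2p_policy == "estimate":
        pop = stage(
            "k2prime",
            lambda: estimate_population_k2p(
                dataset,
                reference=config.reference_region,
                t_end_min=config.model_window_end_min,
            ),
        )
        k2p_fixed = pop.mean
        k2p_df = pd.DataFrame(
            dict(subject=list(pop.per_subject), k2p=list(pop.per_subject.values()))
        )
    else:
        k2p_fixed = float(config.k2p_policy)
        k2p_df = pd.DataFrame(dict(subject=[], k2p=[]))

    model_df = stage(
        "kinetic_fits",
        lambda: model_bp_table(
            dataset,
            k2p_fixed,
            reference=config.reference_region,
            t_end_min=config.model_window_end_min,
        ),
    )
    static_df = stage(
        "static_bp",
        lambda: static_bp_table(
            dataset,
            window_starts=tuple(config.static_window_starts),
            reference=config.reference_region,
        ),
    )
    agreement_df, regression_df = stage(
        "agreement",
        lambda: build_agreement_tables(
            static_df, model_df, reference=config.reference_region, icc_variant=config.icc_variant
        ),
    )

    clinical_df = None
    if dataset.clinical is not None:
        thal = model_df[(model_df["region"] == "thalamus") & (model_df["method"] == "SRTM2")]
        thal = thal.sort_values("subject")["bp"].reset_index(drop=True)
        cov = dataset.clinical.reset_index(drop=True).iloc[: len(thal)]
        clinical_df = stage(
            "clinical",
            lambda: clinical_correlations(thal, cov, correction=config.correction),
        )

    bundle = dict(
        dataset=dataset,
        k2p_fixed=float(k2p_fixed),
        k2p_per_subject=k2p_df,
        model_bp=model_df,
        static_bp=static_df,
        agreement=agreement_df,
        regressions=regression_df,
        clinical=clinical_df,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if config.input_dir is None:
            write_cohort(dataset, outdir / "cohort")
        k2p_df.to_csv(outdir / "k2prime.csv", index=False)
        model_df.to_csv(outdir / "model_bp.csv", index=False)
        static_df.to_csv(outdir / "static_bp.csv", index=False)
        agreement_df.to_csv(outdir / "agreement.csv", index=False)
        regression_df.to_csv(outdir / "regressions.csv", index=False)
        if clinical_df is not None:
            clinical_df.to_csv(outdir / "clinical_correlations.csv", index=False)
        manifest = dict(
            package="netpet",
            version=__version__,
            seed=config.seed,
            k2p_fixed=float(k2p_fixed),
            config_hash=config.config_hash(),
            config={k: (asdict(v) if isinstance(v, CohortConfig) else v) for k, v in asdict(config).items()},
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return bundle


def plot_agreement(bundle: dict, outdir, fmt: str = "png") -> list[Path]:
    """Scatter plots of static vs model BP, one panel per window x model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_df, static_df = bundle["model_bp"], bundle["static_bp"]
    merged = static_df.merge(model_df, on=["subject", "region"], suffixes=("_static", "_model"))
    paths = []
    for (window, method), grp in merged.groupby(["window", "method"]):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(grp["bp_model"], grp["bp_static"], s=12, alpha=0.7)
        lims = [grp[["bp_model", "bp_static"]].min().min(), grp[["bp_model", "bp_static"]].max().max()]
        ax.plot(lims, lims, color="grey", lw=0.8, ls="--")
        ax.set_xlabel(f"BP {method}")
        ax.set_ylabel(f"BP {window} min")
        fig.tight_layout()
        path = outdir / f"scatter_{method}_{window.replace('-', '_')}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
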