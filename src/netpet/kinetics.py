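"""Reference-tissue kinetic models: MRTM, MRTM2 and SRTM2.

The estimation chain mirrors routine clinical practice for reversible tracers
without arterial sampling:

1. per subject, the three-coefficient multilinear reference-tissue model
   (MRTM) is fitted to a high-binding region (merged left+right thalamus)
   against the reference region to estimate the reference efflux rate k2'
   (``k2' = gamma1 / gamma3``);
2. the population mean k2' over all subjects is fixed and transferred to the
   two-coefficient MRTM2 and to SRTM2, which then yield the non-displaceable
   binding potential BPND for every region.

Operational equations (for a one-tissue target and one-tissue reference these
hold exactly at every time point):

    MRTM:   C_T(T) = g1 ∫C_R + g2 ∫C_T + g3 C_R(T),   k2' = g1/g3,
            BPND = -(g1/g2 + 1)
    MRTM2:  C_T(T) = g1 (∫C_R + C_R(T)/k2') + g2 ∫C_T, BPND = -(g1/g2 + 1)
    SRTM2:  C_T = R1 [C_R + (k2' - k2a) (C_R ⊗ e^{-k2a t})],
            BPND = R1 k2'/k2a - 1

SRTM2 is solved with a deterministic basis-function sweep over k2a (100
log-spaced points in [1e-4, 1] min⁻¹ by default) followed by a local
golden-section refinement — no nonlinear search, no initialization
sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortDataset, exp_conv
from .framing import FrameSchedule, TimeActivityCurve, bin_to_frames

#: condition-number limit on the column-scaled design matrix
COLLINEARITY_LIMIT = 1e8

DEFAULT_K2A_GRID = np.logspace(-4, 0, 100)


class CollinearityError(ValueError):
    """The multilinear design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class MRTMFit:
    gamma1: float
    gamma2: float
    gamma3: float
    k2p_hat: float  # gamma1/gamma3, 1/min
    bp: float  # -(gamma1/gamma2 + 1)
    rss: float
    cond: float
    n_frames: int
    t_star_min: float


@dataclass(frozen=True)
class MRTM2Fit:
    gamma1: float
    gamma2: float
    bp: float
    k2p_fixed: float
    rss: float
    cond: float
    n_frames: int
    t_star_min: float


@dataclass(frozen=True)
class SRTM2Fit:
    r1: float
    k2a: float  # 1/min
    k2p_fixed: float  # 1/min
    bp: float  # r1*k2p_fixed/k2a - 1
    rss: float
    boundary: bool  # optimum pinned at the k2a grid edge


@dataclass(frozen=True)
class PopulationK2p:
    """Per-subject MRTM k2' estimates and their arithmetic mean (1/min)."""

    per_subject: dict[str, float]
    mean: float


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running integral of the TAC from time 0 to each frame mid-time
    (kBq/mL·min).

    Frame values are within-frame averages, so the integral up to a frame
    start is exactly the duration-weighted sum of the preceding values; the
    final half frame contributes its average times the half duration.  Exact
    for constants, O(Δt²) accurate for smooth curves.
    """
    durations = tac.schedule.durations_min
    v = tac.values
    full = np.concatenate([[0.0], np.cumsum(v * durations)[:-1]])
    return full + v * durations / 2.0


def _scaled_lstsq(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares with column scaling; returns (beta, rss, cond)."""
    scale = np.linalg.norm(X, axis=0)
    if np.any(scale == 0):
        raise CollinearityError("design matrix has a zero column")
    Xs = X / scale
    cond = float(np.linalg.cond(Xs))
    if not np.isfinite(cond) or cond > COLLINEARITY_LIMIT:
        raise CollinearityError(
            f"design matrix condition number {cond:.3g} exceeds {COLLINEARITY_LIMIT:.0e} "
            "(target and reference carry no independent information)"
        )
    beta_s, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    beta = beta_s / scale
    resid = y - X @ beta
    return beta, float(resid @ resid), cond


def _fit_window(tac: TimeActivityCurve, t_star_min: float) -> np.ndarray:
    idx = np.nonzero(tac.mid_times_min >= t_star_min - 1e-12)[0]
    if idx.size < 4:
        raise ValueError(f"need >= 4 frames at or after t* = {t_star_min} min, have {idx.size}")
    return idx


def mrtm_fit(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star_min: float = 0.0,
    weights: np.ndarray | None = None,
) -> MRTMFit:
    """Three-coefficient MRTM by ordinary least squares over frames with
    mid-time >= t*; yields the reference efflux k2' and BPND.

    ``weights`` (optional, e.g. frame durations) multiply rows of the design.
    """
    if target.schedule.starts_s != reference.schedule.starts_s or (
        target.schedule.ends_s != reference.schedule.ends_s
    ):
        raise ValueError("target and reference must share a schedule")
    idx = _fit_window(target, t_star_min)
    icr = cumulative_integral(reference)[idx]
    ict = cumulative_integral(target)[idx]
    cr = reference.values[idx]
    y = target.values[idx]
    X = np.column_stack([icr, ict, cr])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[idx])
        X, y = X * w[:, None], y * w
    beta, rss, cond = _scaled_lstsq(X, y)
    g1, g2, g3 = beta
    return MRTMFit(
        gamma1=float(g1),
        gamma2=float(g2),
        gamma3=float(g3),
        k2p_hat=float(g1 / g3),
        bp=float(-(g1 / g2 + 1.0)),
        rss=rss,
        cond=cond,
        n_frames=int(idx.size),
        t_star_min=float(t_star_min),
    )


def mrtm2_fit(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2p_fixed: float,
    t_star_min: float = 0.0,
    weights: np.ndarray | None = None,
) -> MRTM2Fit:
    """Two-coefficient MRTM2 with the population k2' fixed."""
    if k2p_fixed <= 0:
        raise ValueError("k2p_fixed must be positive")
    idx = _fit_window(target, t_star_min)
    icr = cumulative_integral(reference)[idx]
    ict = cumulative_integral(target)[idx]
    cr = reference.values[idx]
    y = target.values[idx]
    X = np.column_stack([icr + cr / k2p_fixed, ict])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[idx])
        X, y = X * w[:, None], y * w
    beta, rss, cond = _scaled_lstsq(X, y)
    g1, g2 = beta
    return MRTM2Fit(
        gamma1=float(g1),
        gamma2=float(g2),
        bp=float(-(g1 / g2 + 1.0)),
        k2p_fixed=float(k2p_fixed),
        rss=rss,
        cond=cond,
        n_frames=int(idx.size),
        t_star_min=float(t_star_min),
    )


# ---------------------------------------------------------------------------
# SRTM2 basis-function fit
# ---------------------------------------------------------------------------


def _upsample_tac(tac: TimeActivityCurve, dt_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a continuous curve from frame averages.

    Linear interpolation through (0, 0) and the frame mid-time values, then a
    few mean-preserving correction sweeps so the reconstruction frame-bins back
    to the measured values (important for the sharp early frames).
    """
    sched = tac.schedule
    n = int(round(sched.total_duration_min / dt_min)) + 1
    t = np.linspace(0.0, sched.total_duration_min, n)
    nodes = np.concatenate([[0.0], sched.mid_times_min, [sched.total_duration_min]])
    vals = np.concatenate([[0.0], tac.values, [tac.values[-1]]])
    for _ in range(4):
        fine = np.interp(t, nodes, vals)
        binned = bin_to_frames(t, fine, sched).values
        vals[1:-1] += tac.values - binned
        vals[-1] = vals[-2]
    return t, np.interp(t, nodes, vals)


class SRTM2BasisFitter:
    """Precomputed SRTM2 basis for one reference TAC, reusable across targets.

    For each candidate k2a the convolution basis ``C_R ⊗ exp(-k2a t)`` is
    evaluated on a fine grid (the continuous reference if available, else an
    average-preserving reconstruction from the frames) and frame-binned.  The
    model is folded so R1 is the single free amplitude:
    ``C_T = R1 [C_R + (k2' - k2a) B(k2a)]``.
    """

    def __init__(
        self,
        reference: TimeActivityCurve,
        k2a_grid: np.ndarray | None = None,
        dt_min: float = 0.01,
        ref_fine: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.reference = reference
        self.grid = np.sort(np.asarray(DEFAULT_K2A_GRID if k2a_grid is None else k2a_grid, dtype=float))
        if np.any(self.grid <= 0):
            raise ValueError("k2a grid must be positive")
        if ref_fine is None:
            self._t, self._ref_fine = _upsample_tac(reference, dt_min)
        else:
            self._t, self._ref_fine = (np.asarray(a, dtype=float) for a in ref_fine)
        self._cr = reference.values
        self._basis = np.vstack([self._binned_basis(k) for k in self.grid])
        if not np.all(np.isfinite(self._basis)):
            raise ValueError("non-finite SRTM2 basis")

    def _binned_basis(self, k2a: float) -> np.ndarray:
        conv = exp_conv(self._ref_fine, k2a, self._t)
        return bin_to_frames(self._t, conv, self.reference.schedule).values

    def _profile(self, x: np.ndarray, ct: np.ndarray) -> tuple[float, float]:
        """Best amplitude and rss for one regressor x."""
        xx = float(x @ x)
        if xx == 0:
            return 0.0, float(ct @ ct)
        r1 = float(x @ ct) / xx
        resid = ct - r1 * x
        return r1, float(resid @ resid)

    def fit(self, target: TimeActivityCurve, k2p_fixed: float, refine: bool = True) -> SRTM2Fit:
        if k2p_fixed <= 0:
            raise ValueError("k2p_fixed must be positive")
        ct = target.values
        X = self._cr[None, :] + (k2p_fixed - self.grid)[:, None] * self._basis
        num = X @ ct
        den = np.einsum("ij,ij->i", X, X)
        rss = float(ct @ ct) - num**2 / den
        i = int(np.argmin(rss))
        boundary = i == 0 or i == self.grid.size - 1

        def rss_at(k2a: float) -> tuple[float, float]:
            x = self._cr + (k2p_fixed - k2a) * self._binned_basis(k2a)
            r1, r = self._profile(x, ct)
            return r, r1

        k2a = float(self.grid[i])
        if refine and not boundary:
            lo, hi = np.log(self.grid[i - 1]), np.log(self.grid[i + 1])
            gr = (np.sqrt(5.0) - 1.0) / 2.0
            a, b = lo, hi
            c, d = b - gr * (b - a), a + gr * (b - a)
            fc, fd = rss_at(np.exp(c))[0], rss_at(np.exp(d))[0]
            while (b - a) > 1e-4:
                if fc < fd:
                    b, d, fd = d, c, fc
                    c = b - gr * (b - a)
                    fc = rss_at(np.exp(c))[0]
                else:
                    a, c, fc = c, d, fd
                    d = a + gr * (b - a)
                    fd = rss_at(np.exp(d))[0]
            k2a = float(np.exp((a + b) / 2.0))
        rss_best, r1 = rss_at(k2a)
        return SRTM2Fit(
            r1=r1,
            k2a=k2a,
            k2p_fixed=float(k2p_fixed),
            bp=float(r1 * k2p_fixed / k2a - 1.0),
            rss=rss_best,
            boundary=boundary,
        )


def srtm2_fit(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    k2p_fixed: float,
    k2a_grid: np.ndarray | None = None,
    dt_min: float = 0.01,
    ref_fine: tuple[np.ndarray, np.ndarray] | None = None,
) -> SRTM2Fit:
    """SRTM2 basis-function fit of one target region (see the module notes).

    A boundary optimum (k2a pinned at the grid edge) is flagged on the returned
    fit rather than raised, so cohort sweeps can inspect it afterwards.
    """
    fitter = SRTM2BasisFitter(reference, k2a_grid=k2a_grid, dt_min=dt_min, ref_fine=ref_fine)
    fit = fitter.fit(target, k2p_fixed)
    if fit.boundary:
        warnings.warn(
            f"SRTM2 optimum for {target.region!r} sits at the k2a grid boundary",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# cohort-level estimation
# ---------------------------------------------------------------------------


def merge_tacs(
    tacs: dict[str, TimeActivityCurve],
    names: tuple[str, ...],
    merged_name: str,
    volumes: dict[str, float] | None = None,
) -> TimeActivityCurve:
    """Volume-weighted average TAC (equal weights by default)."""
    members = [tacs[n] for n in names]
    w = np.array([1.0 if volumes is None else volumes[n] for n in names], dtype=float)
    w = w / w.sum()
    vals = np.sum([wi * m.values for wi, m in zip(w, members)], axis=0)
    return TimeActivityCurve(merged_name, members[0].schedule, vals)


def estimate_population_k2p(
    cohort: CohortDataset,
    high_region: str = "thalamus",
    reference: str = "occipital",
    t_end_min: float = 90.0,
    t_star_min: float = 0.0,
    volumes: dict[str, float] | None = None,
) -> PopulationK2p:
    """Per-subject MRTM k2' from merged thalamus vs reference, and their mean.

    Any failing subject aborts the whole estimate with its id in the message —
    a silently shrunken population mean would bias every downstream BPND.
    """
    per_subject: dict[str, float] = {}
    for subj in cohort:
        try:
            sides = tuple(
                n for n in (f"{high_region}_l", f"{high_region}_r") if n in subj.tacs
            ) or (high_region,)
            merged = merge_tacs(subj.tacs, sides, f"{high_region}_merged", volumes)
            ref = subj.tacs[reference]
            if merged.schedule.total_duration_min > t_end_min:
                merged = merged.truncated(t_end_min)
                ref = ref.truncated(t_end_min)
            fit = mrtm_fit(merged, ref, t_star_min=t_star_min)
        except Exception as exc:  # noqa: BLE001 - re-raise with subject context
            raise RuntimeError(f"MRTM k2' fit failed for subject {subj.subject_id}: {exc}") from exc
        per_subject[subj.subject_id] = fit.k2p_hat
    return PopulationK2p(per_subject, float(np.mean(list(per_subject.values()))))


def model_bp_table(
    cohort: CohortDataset,
    k2p_fixed: float,
    methods: tuple[str, ...] = ("MRTM2", "SRTM2"),
    reference: str = "occipital",
    t_end_min: float = 90.0,
    t_star_min: float = 0.0,
    pool: str = "after",
    k2a_grid: np.ndarray | None = None,
):
    """Model-based BPND for every subject x target region x method.

    Returns a pandas DataFrame with columns subject, region, method, bp, r1,
    k2a, rss, boundary.  ``pool='after'`` averages the left/right BPND of
    paired regions into one row per base name (the layout the agreement stage
    consumes); ``pool='none'`` keeps sides separate.
    """
    import pandas as pd

    rows = []
    for subj in cohort:
        tacs = subj.tacs
        ref = tacs[reference]
        if ref.schedule.total_duration_min > t_end_min:
            tacs = {n: tac.truncated(t_end_min) for n, tac in tacs.items()}
            ref = tacs[reference]
        fitter = SRTM2BasisFitter(ref, k2a_grid=k2a_grid) if "SRTM2" in methods else None
        for name, tac in tacs.items():
            if name == reference:
                continue
            if "MRTM2" in methods:
                f2 = mrtm2_fit(tac, ref, k2p_fixed, t_star_min=t_star_min)
                rows.append(
                    dict(subject=subj.subject_id, region=name, method="MRTM2",
                         bp=f2.bp, r1=np.nan, k2a=np.nan, rss=f2.rss, boundary=False)
                )
            if "SRTM2" in methods:
                fs = fitter.fit(tac, k2p_fixed)
                rows.append(
                    dict(subject=subj.subject_id, region=name, method="SRTM2",
                         bp=fs.bp, r1=fs.r1, k2a=fs.k2a, rss=fs.rss, boundary=fs.boundary)
                )
    df = pd.DataFrame(rows)
    if pool == "after":
        df = pool_hemispheres(df, value_cols=("bp",))
    return df


def pool_hemispheres(df, value_cols: tuple[str, ...] = ("bp",), region_col: str = "region"):
    """Average ``_l``/``_r`` rows of paired regions into one base-name row.

    Non-value columns other than the grouping keys are dropped for pooled rows.
    """
    import pandas as pd

    base = df[region_col].str.replace(r"_(l|r)$", "", regex=True)
    out = df.copy()
    out[region_col] = base
    keys = [c for c in ("subject", region_col, "method", "window") if c in out.columns]
    pooled = out.groupby(keys, as_index=False)[list(value_cols)].mean()
    return pooled
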