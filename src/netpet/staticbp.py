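"""Static ratio binding potential over 30-min windows.

BP = (mean VOI concentration - mean reference concentration) / mean reference
concentration, computed per subject, region and window.  With the emulated
protocol the four windows start at 30, 40, 50 and 60 min post-injection and
each covers six consecutive 300-s frames.

For a reversible tracer approaching transient equilibrium, the static ratio
underestimates BPND early and converges toward it as the window moves later —
the mechanism that makes the late short scans a valid surrogate for full
kinetic modeling.
"""

from __future__ import annotations

import numpy as np

from .framing import TimeActivityCurve, extract_window

DEFAULT_WINDOW_STARTS: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0)


def window_label(start_min: float, duration_min: float = 30.0) -> str:
    return f"{start_min:g}-{start_min + duration_min:g}"


def static_bp(voi_mean: float, ref_mean: float) -> float:
    """Ratio binding potential ``(voi - ref)/ref`` from window-mean activities."""
    if ref_mean <= 0:
        raise ValueError("reference window mean must be positive")
    return (voi_mean - ref_mean) / ref_mean


def static_bp_table(
    subjects,
    window_starts: tuple[float, ...] = DEFAULT_WINDOW_STARTS,
    duration_min: float = 30.0,
    reference: str = "occipital",
    pool: str = "after",
):
    """Static BP for every subject x region x window as a pandas DataFrame.

    ``subjects`` is a CohortDataset or any iterable of objects with
    ``subject_id`` and ``tacs``.  Hemisphere pooling: ``'after'`` (default)
    averages the two per-side BP values into one base-name row, ``'before'``
    averages the left/right TACs before the ratio, ``'none'`` keeps sides.
    """
    import pandas as pd

    from .kinetics import merge_tacs, pool_hemispheres

    rows = []
    for subj in subjects:
        tacs: dict[str, TimeActivityCurve] = dict(subj.tacs)
        if pool == "before":
            bases = sorted({n[:-2] for n in tacs if n.endswith(("_l", "_r"))})
            for b in bases:
                tacs[b] = merge_tacs(tacs, (f"{b}_l", f"{b}_r"), b)
                del tacs[f"{b}_l"], tacs[f"{b}_r"]
        for start in window_starts:
            win = extract_window(tacs, start, duration_min)
            ref_mean = win.means[reference]
            for name, mean in win.means.items():
                rows.append(
                    dict(
                        subject=subj.subject_id,
                        region=name,
                        window=window_label(start, duration_min),
                        bp=static_bp(mean, ref_mean),
                    )
                )
    df = pd.DataFrame(rows)
    if pool == "after":
        from .kinetics import pool_hemispheres as _pool

        df = _pool(df, value_cols=("bp",))
        # groupby sorts; restore a stable subject/window ordering
        df = df.sort_values(["subject", "window", "region"], ignore_index=True)
    return df
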