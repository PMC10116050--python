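"""Descriptive statistics and histograms over reaching-time logs.

Per (cohort, method, DOF) condition: discarded and failed trials are dropped,
then mean, standard deviation and a fixed-width histogram of reaching times
are computed.  For multi-subject runs the per-(target, trial-index) reaching
times are first averaged across subjects and the averages pooled — mirroring
how a pooled-population histogram with N = targets x analysed-trials events is
built — with plain pooling available as an alternative.  Failures (timeouts)
never enter the mean; they are reported as a separate failure count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TrialResult

LOG_COLUMNS = [
    "subject",
    "cohort",
    "method",
    "dof",
    "target_id",
    "trial_index",
    "discarded",
    "success",
    "reaching_time_s",
    "n_switches",
]


def results_to_frame(
    results: list[TrialResult], subject: str = "s1"
) -> pd.DataFrame:
    """Flatten trial results into the canonical log table."""
    rows = [
        {
            "subject": subject,
            "cohort": r.cohort,
            "method": r.method,
            "dof": r.dof,
            "target_id": r.target_id,
            "trial_index": r.trial_index,
            "discarded": r.discarded,
            "success": r.success,
            "reaching_time_s": r.reaching_time_s,
            "n_switches": r.n_switches,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


@dataclass
class ConditionSummary:
    """Reaching-time descriptives for one (cohort, method, DOF) condition."""

    cohort: str
    method: str
    dof: int
    n_events: int
    n_failures: int
    mean_s: float  # nan when no events
    sd_s: float
    bin_edges: np.ndarray
    counts: np.ndarray


def summarize(
    log: pd.DataFrame,
    bin_width_s: float = 1.0,
    ddof: int = 1,
    average_subjects: bool = True,
) -> list[ConditionSummary]:
    """Per-condition descriptive statistics.

    ``average_subjects=True`` averages reaching times across subjects per
    (target, trial index) before pooling, so a ten-subject condition still
    yields one event per target presentation; single-subject logs are
    unaffected.  ``ddof=1`` gives the sample standard deviation.
    """
    summaries = []
    for (cohort, method, dof), grp in log.groupby(
        ["cohort", "method", "dof"], sort=True
    ):
        analyzed = grp[~grp["discarded"]]
        ok = analyzed[analyzed["success"]]
        n_failures = int((~analyzed["success"]).sum())
        if average_subjects and ok["subject"].nunique() > 1:
            times = (
                ok.groupby(["target_id", "trial_index"])["reaching_time_s"]
                .mean()
                .to_numpy()
            )
        else:
            times = ok["reaching_time_s"].to_numpy()
        if times.size:
            mean = float(np.mean(times))
            sd = float(np.std(times, ddof=ddof)) if times.size > ddof else float("nan")
            edges = np.arange(0.0, np.ceil(times.max() / bin_width_s) * bin_width_s + bin_width_s, bin_width_s)
            if edges.size < 2:
                edges = np.array([0.0, bin_width_s])
            counts, edges = np.histogram(times, bins=edges)
        else:
            mean = sd = float("nan")
            edges = np.array([0.0, bin_width_s])
            counts = np.zeros(1, dtype=int)
        summaries.append(
            ConditionSummary(
                cohort=cohort,
                method=method,
                dof=int(dof),
                n_events=int(times.size),
                n_failures=n_failures,
                mean_s=mean,
                sd_s=sd,
                bin_edges=edges,
                counts=counts,
            )
        )
    return summaries


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort": s.cohort,
                "method": s.method,
                "dof": s.dof,
                "n_events": s.n_events,
                "n_failures": s.n_failures,
                "mean_s": s.mean_s,
                "sd_s": s.sd_s,
            }
            for s in summaries
        ]
    )


def report(
    summaries: list[ConditionSummary],
    out_dir: str | Path,
    plot: bool = False,
) -> list[Path]:
    """Write the summary CSV (and optional per-condition histogram PNGs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out_dir / "summary.csv"
    summaries_to_frame(summaries).to_csv(csv_path, index=False)
    written.append(csv_path)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for s in summaries:
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar(
                s.bin_edges[:-1],
                s.counts,
                width=np.diff(s.bin_edges),
                align="edge",
                edgecolor="black",
            )
            if np.isfinite(s.mean_s):
                ax.axvline(s.mean_s, color="k")
                if np.isfinite(s.sd_s):
                    ax.axvline(s.mean_s - s.sd_s, color="k", linestyle="--")
                    ax.axvline(s.mean_s + s.sd_s, color="k", linestyle="--")
            ax.set_xlabel("reaching time (s)")
            ax.set_ylabel("events")
            ax.set_title(f"{s.cohort} {s.method} {s.dof}-DOF (n={s.n_events})")
            fig.tight_layout()
            path = out_dir / f"hist_{s.cohort}_{s.method}_{s.dof}dof.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    return written
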