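"""Report rendering and plotting.

Evaluation reports serialize deterministically to JSON, CSV or a short text
block; numeric output is printed to 2 decimal places (the precision of the
endogenous-ethanol comparison) with locale-independent decimal points.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import pandas as pd

from .pbpk import PBPKTrajectory
from .room import AirProfile
from .scenario import EvaluationReport

__all__ = ["render_report", "plot_air_profile", "plot_trajectory"]


def _report_dict(report: EvaluationReport) -> dict:
    d = report.model_dump()
    d["endogenous_reference"] = dict(d["endogenous_reference"])
    d["endogenous_reference"]["range"] = list(d["endogenous_reference"]["range"])
    d["air_windows"] = [list(w) for w in d["air_windows"]]
    d["blood_timepoints"] = [list(p) for p in d["blood_timepoints"]]
    return d


def render_report(report: EvaluationReport, format: str = "text") -> str:
    """Serialize an evaluation report; formats: json, csv, text."""
    if format == "json":
        return json.dumps(_report_dict(report), indent=2, sort_keys=True)
    if format == "csv":
        rows = [
            {"section": "air_window", "t_start_h": a, "t_end_h": b, "value": c}
            for a, b, c in report.air_windows
        ] + [
            {"section": "blood", "t_start_h": t, "t_end_h": t, "value": c}
            for t, c in report.blood_timepoints
        ]
        buf = io.StringIO()
        pd.DataFrame(rows, columns=["section", "t_start_h", "t_end_h", "value"]).to_csv(
            buf, index=False
        )
        return buf.getvalue()
    if format == "text":
        endo = report.endogenous_reference
        lines = [
            f"Scenario evaluation (mode: {report.mode})",
            "",
            "Air windows (mg/m3):",
            *(
                f"  {a:5.1f}-{b:5.1f} h : {c:8.2f}"
                for a, b, c in report.air_windows
            ),
            "",
            "Blood ethanol (mg/L):",
            *(f"  t = {t:5.1f} h : {c:8.2f}" for t, c in report.blood_timepoints),
            "",
            f"Peak blood ethanol: {report.peak_blood_mg_per_l:.2f} mg/L",
            "",
            "Endogenous blood ethanol in nondrinkers "
            f"({endo['source']}):",
            f"  mean {endo['mean']:.2f} mg/L, median {endo['median']:.2f} mg/L, "
            f"range {endo['range'][0]:.2f}-{endo['range'][1]:.2f} mg/L",
            f"  peak / endogenous mean : {report.peak_to_endogenous_mean:.2f}",
            f"  peak / endogenous upper: {report.peak_to_endogenous_upper:.2f}",
            "",
        ]
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}; use json, csv or text")


def plot_air_profile(profile: AirProfile, path: str | Path) -> None:
    """Concentration-vs-time figure for the room model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(profile.times, profile.concentrations, lw=1.5)
    for a, b, mean in profile.windows:
        ax.hlines(mean / 1000.0, a, b, color="C3", lw=2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("ethanol in air (g/m³)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(traj: PBPKTrajectory, path: str | Path) -> None:
    """Blood-concentration-vs-time figure for the PBPK model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(traj.times, traj.blood_conc, lw=1.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("blood ethanol (mg/L)")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
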