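"""Report and plot-data export.

Exports are data-first: every figure of a typical power-law writeup is
backed by a delimited file an external plotter can render —

* ``species_stats.csv`` — the per-species table (p, ε, δ, classification);
* ``powerlaw_points.csv`` / ``powerlaw_lines.csv`` — scatter points, the
  ``y = x`` identity line, the fitted line and its 95% confidence band;
* ``freq_delta.csv`` — the δ-vs-p scatter with the δ_c reference flag;
* ``residuals.csv`` — per-species ε bar-chart data;
* ``run_report.json`` — machine-readable fit coefficients, community
  indices, exclusions, and the full effective configuration so any number
  in the report can be re-derived.

Numbers in the delimited tables are rounded to a configurable number of
decimals (default 4); the JSON report keeps full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import CommunityIndices, FrequencyHeterogeneityFit
from .powerlaw import AnalysisResult, PowerLawFit

__all__ = ["RunConfig", "confidence_band", "export_reports"]


@dataclass
class RunConfig:
    """Effective options of one run; embedded verbatim in every report."""

    n_subquadrats: int = 4
    log_base: float = 10.0
    variance_estimator: str = "sample"
    classification_tolerance: float = 0.0
    pool_transects: bool = False
    seed: int | None = None
    rounding: int = 4


def confidence_band(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """OLS mean-prediction confidence band over a grid of x values."""
    model = sm.OLS(y, sm.add_constant(x)).fit()
    pred = model.get_prediction(sm.add_constant(grid))
    frame = pred.summary_frame(alpha=1.0 - level)
    return pd.DataFrame(
        {
            "x": grid,
            "y_fit": frame["mean"].to_numpy(),
            "ci_low": frame["mean_ci_lower"].to_numpy(),
            "ci_high": frame["mean_ci_upper"].to_numpy(),
            "y_identity": grid,
        }
    )


def _stats_frame(result: AnalysisResult, rounding: int) -> pd.DataFrame:
    rows = [
        {
            "species": s.species,
            "p": s.p,
            "v": s.v,
            "x": s.x,
            "y": s.y,
            "delta": s.delta,
            "epsilon": s.epsilon,
            "label": s.label,
            "excluded": s.excluded,
            "reason": s.reason,
        }
        for s in result.species_stats
    ]
    df = pd.DataFrame(rows)
    num = df.select_dtypes(include=[float]).columns
    df[num] = df[num].round(rounding)
    return df


def export_reports(
    out_dir: str | Path,
    result: AnalysisResult,
    comm: CommunityIndices | None,
    fh_fit: FrequencyHeterogeneityFit | None,
    config: RunConfig,
) -> dict[str, Any]:
    """Write the full report bundle into ``out_dir``; return the JSON payload."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = config.rounding

    _stats_frame(result, r).to_csv(out / "species_stats.csv", index=False)

    inc = result.included
    x = np.array([s.x for s in inc])
    y = np.array([s.y for s in inc])
    pd.DataFrame(
        {"species": [s.species for s in inc], "x": x.round(r), "y": y.round(r)}
    ).to_csv(out / "powerlaw_points.csv", index=False)
    grid = np.linspace(x.min(), x.max(), 100)
    confidence_band(x, y, grid).round(r).to_csv(
        out / "powerlaw_lines.csv", index=False
    )
    pd.DataFrame(
        {"species": [s.species for s in inc], "epsilon": [round(s.epsilon, r) for s in inc]}
    ).to_csv(out / "residuals.csv", index=False)

    if comm is not None:
        pd.DataFrame(
            {
                "species": [s.species for s in inc],
                "p": [round(s.p, r) for s in inc],
                "delta": [round(s.delta, r) for s in inc],
                "above_delta_c": [s.delta > comm.delta_c for s in inc],
            }
        ).to_csv(out / "freq_delta.csv", index=False)

    payload: dict[str, Any] = {
        "fit": {
            "alpha": result.fit.alpha,
            "beta": result.fit.beta,
            "r_squared": result.fit.r_squared,
            "n_points": result.fit.n_points,
        },
        "community": None
        if comm is None
        else {
            "delta_c": comm.delta_c,
            "shannon": comm.shannon,
            "species_count": comm.species_count,
        },
        "frequency_heterogeneity_fit": None
        if fh_fit is None
        else {
            "form": fh_fit.form,
            "a": fh_fit.a,
            "b": fh_fit.b,
            "r_squared": fh_fit.r_squared,
            "n_used": fh_fit.n_used,
        },
        "exclusions": {s.species: s.reason for s in result.excluded},
        "config": asdict(config),
    }
    (out / "run_report.json").write_text(json.dumps(payload, indent=2))
    return payload
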