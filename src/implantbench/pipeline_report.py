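"""Full stratified benchmarking runs, counts summaries and export.

Drives the analysis over the stratification grid (overall, by gender, and
by gender x age band) and the fixed horizons (3, 5, 7 and 10 years by
default), in either contemporary-reference mode (best construct at each
horizon) or historic-reference mode (the 10-year best, re-estimated at the
earlier horizons).  Strata/horizons without an eligible reference are
first-class "skipped" outputs, not silent omissions.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .km_survival import km_failure_at
from .noninferiority import (Classification, NonInferiorityResult,
                             StratumBenchmark, benchmark_stratum)
from .registry_io import ConstructKey, Stratum, default_strata

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    horizons: tuple[float, ...] = (3.0, 5.0, 7.0, 10.0)
    strata: tuple[Stratum, ...] = tuple(default_strata())
    margins: tuple[float, float] = (0.2, 1.0)
    min_reference: int = 1000
    min_display: int = 500
    min_tabular: int = 250
    alpha: float = 0.05
    reference_mode: str = "contemporary"  # or "historic"

    def __post_init__(self) -> None:
        hs = self.horizons
        if any(h <= 0 for h in hs) or list(hs) != sorted(set(hs)):
            raise ValueError("horizons must be positive and strictly increasing")
        if min(self.min_reference, self.min_display, self.min_tabular) <= 0:
            raise ValueError("thresholds must be positive")
        if not (self.min_reference >= self.min_display >= self.min_tabular):
            log.warning("unusual thresholds: reference %d, display %d, tabular %d",
                        self.min_reference, self.min_display, self.min_tabular)
        if self.reference_mode not in ("contemporary", "historic"):
            raise ValueError(f"unknown reference mode {self.reference_mode!r}")


@dataclass(frozen=True)
class CountsSummary:
    """Label counts among display-eligible constructs in one stratum x
    horizon cell.  ``n_at_least_20`` counts constructs inferior by at least
    the 20% margin (the 100%-inferior ones included); ``n_inferior_100`` is
    the subset also failing the 100% margin."""

    stratum: Stratum
    horizon: float
    n_eligible: int
    n_non_inferior: int
    n_inconclusive: int
    n_inferior_20_only: int
    n_inferior_100: int
    reference: Optional[ConstructKey]
    reference_failure: Optional[float]

    @property
    def n_at_least_20(self) -> int:
        return self.n_inferior_20_only + self.n_inferior_100


@dataclass
class AnalysisOutput:
    config: AnalysisConfig
    cells: dict[tuple[Stratum, float], StratumBenchmark]
    counts: dict[tuple[Stratum, float], CountsSummary]
    skipped: list[tuple[Stratum, float, str]]


def _grouped_arrays(df: pd.DataFrame
                    ) -> dict[ConstructKey, tuple[np.ndarray, np.ndarray]]:
    out: dict[ConstructKey, tuple[np.ndarray, np.ndarray]] = {}
    for (stem, cup, bearing), sub in df.groupby(["stem", "cup", "bearing"],
                                                sort=True):
        key = ConstructKey(stem, cup, bearing)
        out[key] = (sub["time"].to_numpy(float), sub["event"].to_numpy(bool))
    return out


def _stratum_frame(df: pd.DataFrame, stratum: Stratum) -> pd.DataFrame:
    mask = np.ones(len(df), dtype=bool)
    if stratum.gender != "all":
        mask &= (df["gender"] == stratum.gender).to_numpy()
    if stratum.age_band != "all":
        mask &= (df["age_band"] == stratum.age_band).to_numpy()
    return df[mask]


def run_full_analysis(event_table: pd.DataFrame,
                      config: AnalysisConfig = AnalysisConfig()
                      ) -> AnalysisOutput:
    """Benchmark every stratum at every horizon.

    ``event_table`` is the frame from
    :func:`implantbench.registry_io.build_event_table` (post-exclusion).
    In historic mode the reference at the earlier horizons is the construct
    selected at the last (longest) horizon; its estimate at each earlier
    horizon is recomputed from the same records, and the last-horizon
    results are identical to contemporary mode by construction.
    """
    cells: dict[tuple[Stratum, float], StratumBenchmark] = {}
    counts: dict[tuple[Stratum, float], CountsSummary] = {}
    skipped: list[tuple[Stratum, float, str]] = []
    historic = config.reference_mode == "historic"
    last_horizon = config.horizons[-1]

    for stratum in config.strata:
        sub = _stratum_frame(event_table, stratum)
        groups = _grouped_arrays(sub)
        if not groups:
            for h in config.horizons:
                skipped.append((stratum, h, "empty stratum"))
            continue

        historic_ref: Optional[ConstructKey] = None
        if historic:
            bench_last = benchmark_stratum(
                groups, last_horizon,
                min_reference=config.min_reference,
                min_display=config.min_display,
                min_tabular=config.min_tabular,
                margins=config.margins, alpha=config.alpha)
            if bench_last.status != "ok":
                for h in config.horizons:
                    skipped.append((stratum, h,
                                    f"no {last_horizon:g}-year reference"))
                log.info("stratum %s skipped: no %gy reference for historic mode",
                         stratum.label, last_horizon)
                continue
            historic_ref = bench_last.reference.construct

        for h in config.horizons:
            forced = None
            if historic and h != last_horizon:
                forced = historic_ref
            bench = benchmark_stratum(
                groups, h,
                min_reference=config.min_reference,
                min_display=config.min_display,
                min_tabular=config.min_tabular,
                margins=config.margins, alpha=config.alpha,
                forced_reference=forced)
            if bench.status != "ok":
                skipped.append((stratum, h, "no eligible reference"))
                log.info("stratum %s at %gy skipped: no eligible reference",
                         stratum.label, h)
                continue
            log.info("stratum %s at %gy: reference %s (F=%.4f, n=%d), "
                     "%d comparator rows",
                     stratum.label, h, bench.reference.construct.label,
                     bench.reference.estimate.failure,
                     bench.reference.estimate.n_at_risk_at_t,
                     len(bench.results))
            bench.results = [
                # attach the stratum for export
                _with_stratum(r, stratum) for r in bench.results]
            cells[(stratum, h)] = bench
            counts[(stratum, h)] = summarize_counts(
                bench.results, stratum, h,
                reference=bench.reference.construct,
                reference_failure=bench.reference.estimate.failure)
    return AnalysisOutput(config, cells, counts, skipped)


def _with_stratum(r: NonInferiorityResult, stratum: Stratum) -> NonInferiorityResult:
    from dataclasses import replace
    return replace(r, stratum=stratum)


def historic_reference_analysis(event_table: pd.DataFrame,
                                config: AnalysisConfig = AnalysisConfig()
                                ) -> AnalysisOutput:
    """The sensitivity analysis: re-run everything with the reference at
    the earlier horizons pinned to the construct selected at the longest
    horizon (conservative: preserves the status quo of implant choice)."""
    from dataclasses import replace
    return run_full_analysis(event_table,
                             replace(config, reference_mode="historic"))


def summarize_counts(results: Sequence[NonInferiorityResult],
                     stratum: Stratum, horizon: float,
                     reference: Optional[ConstructKey] = None,
                     reference_failure: Optional[float] = None
                     ) -> CountsSummary:
    """Count classification labels among display-eligible constructs.

    Both counting conventions are carried: ``n_at_least_20`` (inferior by
    at least 20%, including the 100%-inferior subset) and the subset count
    ``n_inferior_100`` itself.
    """
    disp = [r for r in results if r.display_eligible]
    by = {label: sum(1 for r in disp if r.classification is label)
          for label in Classification}
    return CountsSummary(
        stratum=stratum,
        horizon=horizon,
        n_eligible=len(disp),
        n_non_inferior=by[Classification.NON_INFERIOR],
        n_inconclusive=by[Classification.INCONCLUSIVE],
        n_inferior_20_only=by[Classification.INFERIOR_20],
        n_inferior_100=by[Classification.INFERIOR_100],
        reference=reference,
        reference_failure=reference_failure,
    )


# ---------------------------------------------------------------------------
# Export

_RESULT_COLUMNS = [
    "stratum", "horizon_years", "stem", "cup", "bearing", "n_at_risk",
    "failure_pct", "se_pct", "ref_stem", "ref_cup", "ref_bearing",
    "ref_failure_pct", "diff_pp", "ci_low_pp", "ci_high_pp", "z20", "z100",
    "classification", "is_reference", "display_eligible",
    # full-precision machine-readable columns
    "failure", "se", "ref_failure", "diff", "ci_low", "ci_high",
    "delta_20", "delta_100",
]


def results_frame(results: Sequence[NonInferiorityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        ref = r.ref_construct
        rows.append({
            "stratum": r.stratum.label if r.stratum else "",
            "horizon_years": r.t,
            "stem": r.construct.stem,
            "cup": r.construct.cup,
            "bearing": r.construct.bearing,
            "n_at_risk": r.n_at_risk,
            "failure_pct": round(100 * r.f_x, 2),
            "se_pct": round(100 * r.se_x, 2),
            "ref_stem": ref.stem if ref else "",
            "ref_cup": ref.cup if ref else "",
            "ref_bearing": ref.bearing if ref else "",
            "ref_failure_pct": round(100 * r.f_ref, 2),
            "diff_pp": round(100 * r.diff, 2),
            "ci_low_pp": round(100 * r.ci_low, 2),
            "ci_high_pp": round(100 * r.ci_high, 2),
            "z20": round(r.z_20, 3),
            "z100": round(r.z_100, 3),
            "classification": r.classification.value,
            "is_reference": r.is_reference,
            "display_eligible": r.display_eligible,
            "failure": repr(r.f_x),
            "se": repr(r.se_x),
            "ref_failure": repr(r.f_ref),
            "diff": repr(r.diff),
            "ci_low": repr(r.ci_low),
            "ci_high": repr(r.ci_high),
            "delta_20": repr(r.delta_20),
            "delta_100": repr(r.delta_100),
        })
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def _cell_name(stratum: Stratum, horizon: float) -> str:
    g = stratum.gender.lower() if stratum.gender != "all" else "all"
    b = stratum.age_band.replace("<", "lt").replace(">", "gt") \
        .replace("-", "_") if stratum.age_band != "all" else "all"
    return f"{g}_{b}_{horizon:g}y"


def export_results(output: AnalysisOutput, out_dir: str | Path,
                   seed: Optional[int] = None) -> dict[str, Path]:
    """Write the full output tree: one results CSV per stratum x horizon,
    a counts CSV, a skipped-cells CSV and a run manifest.  Deterministic:
    identical inputs give byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for (stratum, h), bench in sorted(
            output.cells.items(), key=lambda kv: (kv[0][0].gender, kv[0][0].age_band, kv[0][1])):
        p = out / f"results_{_cell_name(stratum, h)}.csv"
        results_frame(bench.results).to_csv(p, index=False)
        paths[p.name] = p

    counts_rows = []
    for (stratum, h), c in sorted(
            output.counts.items(), key=lambda kv: (kv[0][0].gender, kv[0][0].age_band, kv[0][1])):
        counts_rows.append({
            "stratum": stratum.label,
            "horizon_years": h,
            "n_eligible": c.n_eligible,
            "n_non_inferior": c.n_non_inferior,
            "n_inconclusive": c.n_inconclusive,
            "n_at_least_20_inferior": c.n_at_least_20,
            "n_of_which_100_inferior": c.n_inferior_100,
            "reference": c.reference.label if c.reference else "",
            "reference_failure_pct":
                round(100 * c.reference_failure, 2)
                if c.reference_failure is not None else "",
        })
    counts_path = out / "counts.csv"
    pd.DataFrame(counts_rows).to_csv(counts_path, index=False)
    paths["counts.csv"] = counts_path

    skipped_path = out / "skipped.csv"
    pd.DataFrame(
        [{"stratum": s.label, "horizon_years": h, "reason": why}
         for s, h, why in output.skipped],
        columns=["stratum", "horizon_years", "reason"],
    ).to_csv(skipped_path, index=False)
    paths["skipped.csv"] = skipped_path

    manifest = {
        "version": __version__,
        "reference_mode": output.config.reference_mode,
        "horizons": list(output.config.horizons),
        "margins": list(output.config.margins),
        "thresholds": {"reference": output.config.min_reference,
                       "display": output.config.min_display,
                       "tabular": output.config.min_tabular},
        "alpha": output.config.alpha,
        "seed": seed,
        "n_cells": len(output.cells),
        "n_skipped": len(output.skipped),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    paths["manifest.json"] = manifest_path
    return paths


def export_forest_data(results: Sequence[NonInferiorityResult],
                       csv_path: str | Path,
                       figure_path: Optional[str | Path] = None) -> None:
    """Plot-ready export of one stratum x horizon cell.

    The CSV holds one row per display-eligible construct (label in the
    ``bearing stem/cup`` convention), sorted by ascending difference, plus
    the two margin lines; the optional figure draws the differences with
    their intervals against the zero line and both margins.
    """
    disp = sorted((r for r in results if r.display_eligible),
                  key=lambda r: (r.diff, r.construct))
    if not disp:
        raise ValueError("no display-eligible results to export")
    d20, d100 = disp[0].delta_20, disp[0].delta_100
    df = pd.DataFrame([{
        "label": r.construct.label,
        "diff": r.diff,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "n_at_risk": r.n_at_risk,
        "classification": r.classification.value,
        "is_reference": r.is_reference,
        "delta_20": d20,
        "delta_100": d100,
    } for r in disp])
    df.to_csv(csv_path, index=False)

    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        n = len(df)
        fig, ax = plt.subplots(figsize=(7, max(3, 0.22 * n + 1.5)))
        y = np.arange(n)
        err = np.vstack([df["diff"] - df["ci_low"],
                         df["ci_high"] - df["diff"]])
        ax.errorbar(100 * df["diff"], y, xerr=100 * err, fmt="o",
                    ms=3, lw=1, color="k")
        ax.axvline(0, color="grey", lw=0.8)
        ax.axvline(100 * d20, color="tab:orange", lw=0.8, ls="--",
                   label="20% margin")
        ax.axvline(100 * d100, color="tab:red", lw=0.8, ls="--",
                   label="100% margin")
        ax.set_yticks(y)
        ax.set_yticklabels(df["label"], fontsize=6)
        ax.set_xlabel("failure difference vs reference (percentage points)")
        ax.legend(fontsize=7, loc="lower right")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
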