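"""Grid execution, difference summaries, reports and boxplots.

For every replicate of every scenario each candidate model's 25-measure
panel is computed on the test set and differenced against the true
model's panel from the same replicate (candidate minus true). Cells of
the report pool all scenario x replicate differences and show
"mean (2.5th, 97.5th percentile)", the empirical 95% range.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .measures import MEASURE_NAMES, measure_panel
from .models import CandidateSpec, build_candidates, default_catalog
from .scenario import (ScenarioSpec, SimDataset, build_grid, default_grid,
                       derive_seed, make_dataset)

logger = logging.getLogger("truthbench")

RECORD_COLUMNS = ("scenario_id", "rep_index", "candidate", "measure",
                  "value", "diff")


# ---------------------------------------------------------------------------
# per-scenario execution
# ---------------------------------------------------------------------------

def run_scenario(spec: ScenarioSpec,
                 catalog: Sequence[CandidateSpec] | None = None,
                 measures: tuple[str, ...] | None = None,
                 n_reps: int | None = None) -> pd.DataFrame:
    """All difference records for one scenario (long format).

    Per replicate: simulate the dataset, build every candidate, compute
    the measure panel, and difference each candidate against the true
    model of the same replicate. Replicate-level failures are logged and
    skipped; the scenario fails only if more than half its replicates do.
    """
    if catalog is None:
        catalog = default_catalog(spec.arity, spec.proxy_corrs)
    names = [c.name for c in catalog]
    if "TrueModel" not in names:
        raise ValueError("catalog must contain the TrueModel reference")
    wanted = MEASURE_NAMES if measures is None else tuple(measures)
    reps = spec.n_reps if n_reps is None else n_reps

    rows: list[tuple] = []
    failures = 0
    for rep in range(reps):
        try:
            ds = make_dataset(spec, rep)
            preds = build_candidates(ds, catalog)
            panels = {name: measure_panel(preds[name], wanted)
                      for name in names}
        except Exception as exc:
            failures += 1
            logger.warning("replicate %d of %s failed: %s",
                           rep, spec.scenario_id, exc)
            continue
        ref = panels["TrueModel"]
        for name in names:
            panel = panels[name]
            for m in wanted:
                v, r = panel[m], ref[m]
                # candidate minus true; NaN - NaN stays NaN (missing-vs-missing)
                rows.append((spec.scenario_id, rep, name, m, v, v - r))
    if failures > reps / 2:
        raise RuntimeError(
            f"scenario {spec.scenario_id}: {failures}/{reps} replicates failed")
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(records: pd.DataFrame, column: str = "diff") -> pd.DataFrame:
    """Mean and empirical 2.5/97.5 percentiles per (measure, candidate).

    Pools raw scenario x replicate values (missing excluded); quantiles
    use the linear-interpolation definition. The true model is summarised
    on its raw ``value`` column elsewhere; here ``column`` selects which
    column to aggregate.
    """
    def agg(s: pd.Series) -> pd.Series:
        v = s.to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return pd.Series({"mean": np.nan, "p2.5": np.nan,
                              "p97.5": np.nan, "n_nonmissing": 0})
        return pd.Series({
            "mean": float(np.mean(v)),
            "p2.5": float(np.percentile(v, 2.5)),
            "p97.5": float(np.percentile(v, 97.5)),
            "n_nonmissing": len(v),
        })

    out = (records.groupby(["measure", "candidate"], sort=False)[column]
           .apply(agg).unstack())
    out["n_nonmissing"] = out["n_nonmissing"].astype(int)
    return out


def _fmt(v: float) -> str:
    return "NA" if not np.isfinite(v) else f"{v:.2f}"


def format_summary(records: pd.DataFrame,
                   candidate_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Report-style wide table: rows = measures, columns = candidates,
    cells = "mean (p2.5, p97.5)". The TrueModel column shows the raw
    measure values; every other column shows differences to the true
    model. Values are rounded to 2 decimals at serialisation only
    (a "-0.00" is preserved)."""
    diffs = summarize(records, "diff")
    values = summarize(records, "value")
    if candidate_order is None:
        candidate_order = list(dict.fromkeys(records["candidate"]))
    measure_order = [m for m in MEASURE_NAMES
                     if m in set(records["measure"])]

    table = {}
    for cand in candidate_order:
        src = values if cand == "TrueModel" else diffs
        col = []
        for m in measure_order:
            try:
                row = src.loc[(m, cand)]
            except KeyError:
                col.append("NA")
                continue
            if row["n_nonmissing"] == 0:
                col.append("NA")
            else:
                col.append(f"{_fmt(row['mean'])} "
                           f"({_fmt(row['p2.5'])}, {_fmt(row['p97.5'])})")
        table[cand] = col
    return pd.DataFrame(table, index=pd.Index(measure_order, name="measure"))


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def boxplot_export(records: pd.DataFrame, measure: str, path: str | Path,
                   candidate_order: Sequence[str] | None = None
                   ) -> dict[str, np.ndarray]:
    """One box of candidate-minus-true differences per candidate, with a
    zero reference line. Returns the exact per-candidate arrays plotted."""
    present = set(records["measure"])
    if measure not in present:
        raise ValueError(f"unknown measure {measure!r}; records contain "
                         f"{sorted(present)}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = records[records["measure"] == measure]
    if candidate_order is None:
        candidate_order = list(dict.fromkeys(sub["candidate"]))
    data = {}
    for cand in candidate_order:
        v = sub.loc[sub["candidate"] == cand, "diff"].to_numpy(dtype=float)
        data[cand] = v[np.isfinite(v)]

    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(data)), 4.5))
    ax.boxplot([data[c] for c in candidate_order], tick_labels=candidate_order)
    ax.axhline(0.0, color="grey", linewidth=0.8, linestyle="--")
    ax.set_ylabel(f"Difference of {measure} to the true model")
    ax.set_xlabel("Type of model")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return data


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def _grid_from_config(config: Mapping, master_seed: int) -> list[ScenarioSpec]:
    if "grids" in config:
        specs = []
        for i, sub in enumerate(config["grids"]):
            specs += build_grid(sub, derive_seed(master_seed, i))
        return specs
    if "arity" in config and "betas" not in config:
        return default_grid(config["arity"], master_seed,
                            n_reps=int(config.get("n_reps", 100)))
    return build_grid(config, master_seed)


def run_experiment(config: Mapping, seed: int, out_dir: str | Path,
                   n_reps: int | None = None,
                   scenario_fraction: float | None = None,
                   fmt: str = "csv",
                   plot_measures: Sequence[str] | None = ("AUC",)) -> dict:
    """Execute a (possibly subsampled) grid and write the report bundle.

    Writes a long-format record file, a report-style summary table,
    per-measure boxplots and a provenance file. Subsampling (replicate
    override, scenario fraction) is recorded in the provenance so a run
    can be reproduced bitwise from it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    suffix = fmt

    specs = _grid_from_config(config, seed)
    if scenario_fraction is not None and scenario_fraction < 1:
        k = max(1, int(round(scenario_fraction * len(specs))))
        idx = np.random.default_rng(derive_seed(seed, 9999)).choice(
            len(specs), size=k, replace=False)
        specs = [specs[i] for i in sorted(idx)]

    catalog = None
    if "catalog" in config:
        catalog = [CandidateSpec(**c) for c in config["catalog"]]
    measures = tuple(config["measures"]) if "measures" in config else None

    frames, errors = [], []
    for spec in specs:
        try:
            frames.append(run_scenario(spec, catalog=catalog,
                                       measures=measures, n_reps=n_reps))
        except Exception as exc:
            logger.error("scenario %s failed: %s", spec.scenario_id, exc)
            errors.append({"scenario_id": spec.scenario_id, "error": str(exc)})
    if not frames:
        raise RuntimeError("every scenario failed; nothing to report")
    records = pd.concat(frames, ignore_index=True)

    records_path = out_dir / f"records.{suffix}"
    records.to_csv(records_path, sep=sep, index=False)
    summary = format_summary(records,
                             [c.name for c in catalog] if catalog else None)
    summary_path = out_dir / f"summary.{suffix}"
    summary.to_csv(summary_path, sep=sep)

    plots = []
    for m in (plot_measures or []):
        if m in set(records["measure"]):
            p = out_dir / f"boxplot_{m}.png"
            boxplot_export(records, m, p)
            plots.append(str(p))

    provenance = {
        "config": _jsonable(config),
        "master_seed": int(seed),
        "n_reps_override": n_reps,
        "scenario_fraction": scenario_fraction,
        "format": fmt,
        "n_scenarios_run": len(specs),
        "scenario_ids": [s.scenario_id for s in specs],
        "errors": errors,
        "versions": {
            "truthbench": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps({"config": provenance["config"], "seed": int(seed),
                    "n_reps": n_reps, "fraction": scenario_fraction},
                   sort_keys=True).encode()).hexdigest()
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2))

    return {"records": records, "summary": summary,
            "records_path": records_path, "summary_path": summary_path,
            "provenance_path": prov_path, "plots": plots,
            "provenance": provenance}


def rerun_from_provenance(provenance: Mapping | str | Path,
                          out_dir: str | Path) -> dict:
    """Reproduce a run bitwise from its provenance file."""
    if not isinstance(provenance, Mapping):
        provenance = json.loads(Path(provenance).read_text())
    return run_experiment(
        provenance["config"], provenance["master_seed"], out_dir,
        n_reps=provenance.get("n_reps_override"),
        scenario_fraction=provenance.get("scenario_fraction"),
        fmt=provenance.get("format", "csv"),
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
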