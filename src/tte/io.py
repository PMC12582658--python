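"""Reading and writing registry bundles and report outputs.

Bundles are directories of five tables (``admissions``, ``dispensations``,
``diagnoses``, ``deaths``, ``outcomes``) in CSV or Parquet. Dates are
ISO-8601; the missing sentinel in CSV is an empty field. A synthetic
bundle may carry a sixth ``truth`` table of generator labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from tte.synthetic_registry import RegistryBundle

_DATE_COLUMNS = {
    "admissions": ["admission_date", "discharge_date"],
    "dispensations": ["dispense_date"],
    "diagnoses": ["date"],
    "deaths": ["death_date"],
    "outcomes": ["event_date"],
    "truth": [],
}


def write_bundle(bundle: RegistryBundle, outdir: str | Path,
                 fmt: str = "csv") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = bundle.tables()
    if bundle.truth is not None:
        tables = dict(tables, truth=bundle.truth)
    for name, df in tables.items():
        if fmt == "csv":
            df.to_csv(outdir / f"{name}.csv", index=False)
        elif fmt == "parquet":
            df.to_parquet(outdir / f"{name}.parquet", index=False)
        else:
            raise ValueError(f"unknown bundle format {fmt!r}")


def read_bundle(indir: str | Path) -> RegistryBundle:
    indir = Path(indir)
    tables = {}
    for name, date_cols in _DATE_COLUMNS.items():
        csv = indir / f"{name}.csv"
        pq = indir / f"{name}.parquet"
        if pq.exists():
            tables[name] = pd.read_parquet(pq)
        elif csv.exists():
            try:
                tables[name] = pd.read_csv(csv, parse_dates=date_cols)
            except (ValueError, pd.errors.ParserError) as exc:
                raise ValueError(f"failed to parse {csv}: {exc}") from exc
        elif name != "truth":
            raise FileNotFoundError(f"bundle table {name!r} not found in {indir}")
    return RegistryBundle(
        admissions=tables["admissions"], dispensations=tables["dispensations"],
        diagnoses=tables["diagnoses"], deaths=tables["deaths"],
        outcomes=tables["outcomes"], truth=tables.get("truth"))


def write_report(report: dict, outdir: str | Path) -> None:
    """Write the run_analysis report bundle as CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["effects"].to_csv(outdir / "effects.csv", index=False)
    report["curves"].to_csv(outdir / "curves.csv", index=False)
    report["balance"].to_csv(outdir / "balance.csv", index=False)
    if report.get("adherence") is not None:
        report["adherence"].to_csv(outdir / "adherence.csv", index=False)
    report["cohort"].to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "flowchart.json", "w") as fh:
        json.dump(report["flowchart"].to_dict(), fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report["manifest"], fh, indent=2)
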