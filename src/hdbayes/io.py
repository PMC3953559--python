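"""Reading and writing tree tables, priors, chains and fit reports.

CSV (comma or tab delimited) is the canonical tree-data exchange format:
a header with at least ``dbh`` and ``height`` columns (case-insensitive),
optionally ``tree_id`` and ``plot``.  Rows with missing or non-positive
measurements are dropped with a logged count rather than aborting the
run, mirroring how inventory tables are cleaned in practice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .bayes import MCMCChains, PriorSpec
from .datasets import TreeDataset
from .evaluation import ComparisonReport
from .exceptions import FormatError, ValidationError
from .summaries import FitSummary

logger = logging.getLogger("hdbayes")

PACKAGE_VERSION = "0.1.0"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_dataset(path, campaign_label: str = "") -> TreeDataset:
    """Load a tree table from CSV/TSV, dropping invalid rows with a log note."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = {c.lower().strip(): c for c in df.columns}
    if "dbh" not in cols or "height" not in cols:
        raise FormatError(
            f"{path.name}: header must contain 'dbh' and 'height' columns "
            f"(found {list(df.columns)})"
        )
    dbh = pd.to_numeric(df[cols["dbh"]], errors="coerce")
    height = pd.to_numeric(df[cols["height"]], errors="coerce")
    ok = dbh.notna() & height.notna() & (dbh > 0) & (height > 0)
    n_rejected = int((~ok).sum())
    if n_rejected:
        for idx in df.index[~ok]:
            logger.info(
                "rejecting row %d: dbh=%r height=%r",
                idx, df.loc[idx, cols["dbh"]], df.loc[idx, cols["height"]],
            )
        logger.info("%s: rejected %d invalid row(s)", path.name, n_rejected)
    if not ok.any():
        raise ValidationError(f"{path.name}: no valid rows after filtering")
    kept = df[ok]
    return TreeDataset(
        dbh=dbh[ok].to_numpy(),
        height=height[ok].to_numpy(),
        tree_id=kept[cols["tree_id"]].to_numpy() if "tree_id" in cols else None,
        plot=kept[cols["plot"]].to_numpy() if "plot" in cols else None,
        campaign_label=campaign_label or path.stem,
    )


def write_dataset(dataset: TreeDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def provenance(seed=None, config=None) -> dict:
    """Provenance block attached to every serialised report."""
    block = {"package": "hdbayes", "version": PACKAGE_VERSION}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        block["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    return block


def write_report(report, path, format: str = "json", seed=None, config=None) -> None:
    """Serialise a FitSummary or ComparisonReport, round-trippably for JSON."""
    path = Path(path)
    if format == "json":
        if isinstance(report, (FitSummary, ComparisonReport)):
            payload = report.to_dict()
        elif isinstance(report, dict):
            payload = report
        else:
            raise ValidationError(f"cannot serialise {type(report).__name__}")
        payload = {"provenance": provenance(seed, config), **payload}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        if isinstance(report, FitSummary):
            report.to_frame().to_csv(path, index=False)
        elif isinstance(report, ComparisonReport):
            report.table().to_csv(path, index=False)
        elif isinstance(report, pd.DataFrame):
            report.to_csv(path, index=False)
        else:
            raise ValidationError(f"cannot serialise {type(report).__name__} as csv")
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_fit_summary(path) -> FitSummary:
    d = json.loads(Path(path).read_text())
    d.pop("provenance", None)
    return FitSummary.from_dict(d)


def read_comparison_report(path) -> ComparisonReport:
    d = json.loads(Path(path).read_text())
    d.pop("provenance", None)
    return ComparisonReport.from_dict(d)


def write_prior(prior: PriorSpec, path) -> None:
    Path(path).write_text(json.dumps(prior.to_dict(), indent=2) + "\n")


def read_prior(path) -> PriorSpec:
    return PriorSpec.from_dict(json.loads(Path(path).read_text()))


def write_chains(chains: MCMCChains, path) -> None:
    chains.to_dataframe().to_csv(path, index=False)


def read_simulation_config(path) -> dict:
    """Simulation settings from YAML or JSON."""
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of simulation fields")
    return data
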