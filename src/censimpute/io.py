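"""File input/output: survival CSVs, chains, curves, diagnostics, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import PosteriorDraws
from .dataset import SurvivalDataset
from .diagnostics import DiagnosticsReport
from .imputation import ImputationResult
from .km import CurveSet

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "write_augmented_csv",
    "write_chains_csv",
    "write_curves_tsv",
    "write_diagnostics_json",
    "write_config_yaml",
]


def read_survival_csv(path: str | Path) -> SurvivalDataset:
    """Read a delimited table with header columns time,status[,x].

    Times must be positive, status must be 0/1, and x (if present) binary.
    Errors name the offending data rows (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("time", "status") + (("x",) if "x" in df.columns else ()):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col!r} in data row(s) {[i + 1 for i in bad]}")
    time = df["time"].astype(float).to_numpy()
    status = df["status"].to_numpy()
    bad = np.where(~(time > 0) | ~np.isfinite(time))[0]
    if bad.size:
        raise ValueError(f"{path}: non-positive time in data row(s) {[int(i) + 1 for i in bad]}")
    if not np.isin(status, (0, 1)).all():
        bad = np.where(~np.isin(status, (0, 1)))[0]
        raise ValueError(f"{path}: status must be 0 or 1 in data row(s) {[int(i) + 1 for i in bad]}")
    cov = None
    if "x" in df.columns:
        cov = df["x"].to_numpy()
        if not np.isin(cov, (0, 1)).all():
            bad = np.where(~np.isin(cov, (0, 1)))[0]
            raise ValueError(f"{path}: x must be 0 or 1 in data row(s) {[int(i) + 1 for i in bad]}")
    return SurvivalDataset(time, status.astype(int), cov)


def write_survival_csv(data: SurvivalDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_augmented_csv(result: ImputationResult, path: str | Path) -> None:
    """Original columns plus imputed_time and was_censored."""
    df = result.original.to_frame()
    df["imputed_time"] = result.augmented.time
    df["was_censored"] = (result.original.event == 0).astype(int)
    df.to_csv(path, index=False)


def write_chains_csv(posterior: PosteriorDraws, path: str | Path) -> None:
    pd.DataFrame(posterior.draws, columns=list(posterior.parameter_names)).to_csv(
        path, index=False
    )


def read_chains_csv(path: str | Path, family: str, regression: bool) -> PosteriorDraws:
    from .bayes import LifetimeModel

    df = pd.read_csv(path)
    model = LifetimeModel(family, regression=regression)
    expected = list(model.parameter_names)
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    return PosteriorDraws(tuple(expected), df.to_numpy(float), float("nan"), -1, model)


def write_curves_tsv(curves: CurveSet, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, curve in curves.curves().items():
        curve.to_frame().to_csv(outdir / f"{prefix}km_{name}.tsv", sep="\t", index=False)
    curves.band.to_csv(outdir / f"{prefix}draw_band.tsv", sep="\t", index=False)


def write_diagnostics_json(
    report: DiagnosticsReport, path: str | Path, acceptance_rate: float | None = None
) -> None:
    payload = report.to_dict()
    payload["acf"] = {k: np.asarray(v).tolist() for k, v in report.acf.items()}
    if acceptance_rate is not None:
        payload["mcmc_acceptance_rate"] = acceptance_rate
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def write_config_yaml(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
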