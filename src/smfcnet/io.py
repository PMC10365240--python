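"""Reading and writing time series, manifests, configs, and result stacks.

Subject time series are delimited text (TSV/CSV), rows = time points,
columns = ROIs, with an optional header row of ROI names. A cohort is
described by a manifest table with columns ``subject_id``, ``path``,
``label``. Configuration is a YAML file; the sparsity-prior grid may be
written compactly as ``dyadic:<lo>:<hi>`` (exponents of 2).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fcn import TimeSeriesMatrix, normalize_series, dyadic_grid

__all__ = [
    "read_timeseries",
    "load_subject",
    "drop_burn_in",
    "read_manifest",
    "write_cohort",
    "parse_lam_grid",
    "load_config",
    "DEFAULT_CONFIG",
    "save_stacks",
    "load_stacks",
]

DEFAULT_CONFIG: dict = {
    "sigma": 0.2,
    "lam_grid": "dyadic:-4:5",
    "hard_threshold_percents": [10, 20, 30, 40, 50, 60, 70, 80, 90, 99],
    "model": {},          # ModelConfig overrides (H, V, D1, D2, epochs, ...)
    "cv": {},             # CVPlan overrides (outer_folds, outer_repetitions, ...)
    "variant": "smfc",    # smfc | htfc | ssfc:<k> (1-based grid position)
    "seed": 0,
}


def _sniff(path: Path) -> tuple[str, bool]:
    """Detect the delimiter and whether the first row is a header."""
    with open(path, newline="") as fh:
        sample = fh.read(65536)
        first = sample.splitlines()[0] if sample else ""
    try:
        delim = csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
    except csv.Error:
        delim = "\t"
    header = False
    for tok in first.split(delim):
        tok = tok.strip()
        if tok:
            try:
                float(tok)
            except ValueError:
                header = True
                break
    return delim, header


def read_timeseries(path, orientation: str = "time-by-roi") -> np.ndarray:
    """Read one subject's raw time-series matrix from delimited text.

    ``orientation='roi-by-time'`` transposes the file so the returned array
    is always time-by-ROI. Ragged rows, non-numeric cells and NaNs are
    rejected with a diagnostic naming the offending location.
    """
    if orientation not in ("time-by-roi", "roi-by-time"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    delim, header = _sniff(path)
    try:
        df = pd.read_csv(path, sep=delim, header=0 if header else None,
                         skipinitialspace=True)
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: ragged or malformed rows ({e})") from None
    non_numeric = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric cells in column(s) {list(non_numeric)}")
    raw = df.to_numpy(dtype=float)
    if np.isnan(raw).any():
        r, c = np.argwhere(np.isnan(raw))[0]
        raise ValueError(f"{path}: missing value at row {r}, column {c}")
    if orientation == "roi-by-time":
        raw = raw.T
    return raw


def drop_burn_in(raw: np.ndarray, n_volumes: int = 10) -> np.ndarray:
    """Discard the first ``n_volumes`` time points (scanner stabilization)."""
    if n_volumes < 0 or n_volumes >= raw.shape[0]:
        raise ValueError(f"cannot drop {n_volumes} of {raw.shape[0]} volumes")
    return raw[n_volumes:]


def load_subject(path, subject_id: str = "", label: int | None = None,
                 orientation: str = "time-by-roi",
                 roi_names: list[str] | None = None) -> TimeSeriesMatrix:
    raw = read_timeseries(path, orientation=orientation)
    return normalize_series(raw, roi_ids=roi_names, subject_id=subject_id, label=label)


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a cohort manifest (subject_id, path, label).

    Paths are resolved relative to the manifest's directory. Duplicate
    subject ids, unresolvable paths, and single-class cohorts are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks column(s) {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_id(s) {dup}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: labels must be 0/1")
    if df["label"].nunique() != 2:
        raise ValueError(f"{path}: both labels must be present")
    base = path.parent
    resolved = [Path(p) if Path(p).is_absolute() else base / p for p in df["path"]]
    for p in resolved:
        if not p.exists():
            raise FileNotFoundError(f"{path}: series file {p} not found")
    df = df.copy()
    df["path"] = [str(p) for p in resolved]
    return df


def write_cohort(outdir, subjects, y) -> Path:
    """Write per-subject TSVs plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, label in zip(subjects, y):
        fname = f"{ts.subject_id or 'subject'}.tsv"
        pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(
            outdir / fname, sep="\t", index=False)
        rows.append({"subject_id": ts.subject_id, "path": fname, "label": int(label)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def parse_lam_grid(value) -> np.ndarray:
    """Parse a lambda grid: a list of floats or ``dyadic:<lo>:<hi>``."""
    if isinstance(value, str):
        parts = value.split(":")
        if parts[0] != "dyadic" or len(parts) != 3:
            raise ValueError(f"unrecognized lam_grid spec {value!r}")
        return dyadic_grid(int(parts[1]), int(parts[2]))
    return np.asarray(value, dtype=float)


def load_config(path=None) -> dict:
    """Load a YAML config over the defaults; unknown keys are rejected."""
    cfg = {k: (v.copy() if isinstance(v, (dict, list)) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        for k, v in user.items():
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def save_stacks(path, stacks: np.ndarray, y, subject_ids, lam_grid,
                sigma: float | None = None, **meta) -> None:
    """Persist FCN stacks with their provenance in one portable .npz file."""
    np.savez_compressed(
        path, stacks=np.asarray(stacks), y=np.asarray(y),
        subject_ids=np.asarray(subject_ids, dtype=str),
        lam_grid=np.asarray(lam_grid, dtype=float),
        sigma=np.asarray(-1.0 if sigma is None else sigma),
        meta=np.asarray(yaml.safe_dump(meta), dtype=str))


def load_stacks(path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        out = {k: z[k] for k in z.files}
    out["subject_ids"] = [str(s) for s in out["subject_ids"]]
    out["meta"] = yaml.safe_load(str(out["meta"]))
    return out
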