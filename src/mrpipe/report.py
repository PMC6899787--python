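"""Human-readable report tables and run manifests.

The forest table is the flat, deterministic-order input a forest plot (or a
results section) is built from: one row per (outcome, method) with the
causal estimate, 95% CI and p-value, odds ratios exponentiated for binary
outcomes.  TSV output rounds to 6 significant digits; JSON keeps full
precision.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .mr import MRReport

FOREST_COLUMNS = ["outcome", "method", "beta", "ci_low", "ci_high", "p", "n_snps", "status"]


def forest_table(reports: list[MRReport], labels: list[str] | None = None) -> pd.DataFrame:
    """One row per (outcome, method) across a set of MR reports.

    For binary outcomes the estimate and CI are exponentiated from the
    log-odds to the odds-ratio scale.  Methods whose preconditions failed
    appear with status ``not applicable`` and NaN numerics.  Rows are sorted
    by outcome label then method name.
    """
    if not reports:
        raise ValueError("need at least one report")
    if labels is None:
        labels = [r.direction for r in reports]
    rows = []
    for report, label in zip(reports, labels):
        for est in report.estimates:
            beta, lo, hi = est.beta, est.ci_low, est.ci_high
            if report.binary_outcome and not est.method.startswith("egger_intercept"):
                beta, lo, hi = np.exp([beta, lo, hi])
            rows.append({
                "outcome": label, "method": est.method, "beta": beta,
                "ci_low": lo, "ci_high": hi, "p": est.p,
                "n_snps": est.n_snps, "status": "ok",
            })
        for method, reason in report.not_applicable.items():
            rows.append({
                "outcome": label, "method": method, "beta": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "n_snps": 0, "status": reason,
            })
    return (
        pd.DataFrame(rows, columns=FOREST_COLUMNS)
        .sort_values(["outcome", "method"], kind="stable")
        .reset_index(drop=True)
    )


def _round_sig(x: float, digits: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(
        x, precision=digits, unique=False, fractional=False))


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with numbers at 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: _round_sig(v) if pd.notna(v) else v)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int | None, inputs=()) -> Path:
    """Record what produced a run: config hash, seed, versions, input
    checksums.  Identical manifests imply byte-identical numeric outputs."""
    import mrpipe

    config_json = json.dumps(config, sort_keys=True, default=_json_default)
    manifest = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "mrpipe": mrpipe.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): _file_checksum(p) for p in inputs},
    }
    path = Path(out_dir) / "manifest.json"
    write_json(manifest, path)
    return path
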