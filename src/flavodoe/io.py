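"""CSV/JSON artifact I/O with provenance headers.

Design and response tables travel as UTF-8 CSV with a header row; numeric
content round-trips at full double precision (17 significant digits).
Every artifact written here starts with ``#``-prefixed provenance lines
(config hash, seeds) so a rerun with the same configuration is verifiably
byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design_space import DesignSpace
from .designs import DesignMatrix
from .fitting import AnovaTable, PolyModel

__all__ = [
    "config_hash",
    "write_design_csv",
    "read_design_csv",
    "write_response_csv",
    "read_response_csv",
    "write_anova_csv",
    "write_model_json",
    "read_model_json",
]

_FLOAT_FMT = "%.17g"


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _write_csv(df: pd.DataFrame, path, meta: dict | None) -> None:
    buf = _io.StringIO()
    buf.write(_provenance_lines(meta))
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_design_csv(design: DesignMatrix, path, meta: dict | None = None) -> None:
    _write_csv(design.to_dataframe(), path, meta)


def read_design_csv(path, space: DesignSpace | None = None, design_kind: str = "custom") -> DesignMatrix:
    """Read a design table; columns may be coded (``<name>_coded``) or actual.

    Actual-unit columns require ``space`` to supply the coded transform.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty design file")
    run_ids = df["run_id"].to_numpy() if "run_id" in df else None
    flags = df["is_center"].to_numpy(dtype=bool) if "is_center" in df else None
    coded_cols = [c for c in df.columns if c.endswith("_coded")]
    if coded_cols:
        names = [c[: -len("_coded")] for c in coded_cols]
        levels = df[coded_cols].to_numpy(dtype=float)
    else:
        if space is None:
            raise ValueError(f"{path}: no *_coded columns and no design space given")
        missing = [n for n in space.names if n not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing factor columns {missing}")
        names = space.names
        levels = space.encode(df[names].to_numpy(dtype=float))
    if np.isnan(levels).any():
        raise ValueError(f"{path}: non-numeric cells in factor columns")
    if flags is None:
        flags = np.all(np.abs(levels) < 1e-12, axis=1)
    return DesignMatrix(
        levels=levels,
        factor_names=names,
        design_kind=design_kind,
        center_point_flags=flags,
        run_ids=run_ids,
    )


def write_response_csv(y, path, meta: dict | None = None) -> None:
    _write_csv(pd.DataFrame({"response": np.asarray(y, dtype=float)}), path, meta)


def read_response_csv(path, expected_runs: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "response" not in df.columns:
        raise ValueError(f"{path}: missing 'response' column")
    y = df["response"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"{path}: non-numeric response cells")
    if expected_runs is not None and len(y) != expected_runs:
        raise ValueError(f"{path}: {len(y)} responses for a {expected_runs}-run design")
    return y


def write_anova_csv(anova_table: AnovaTable, path, meta: dict | None = None) -> None:
    """ANOVA table with Source/SS/df/MS/F/p columns plus a fit-statistics block."""
    buf = _io.StringIO()
    buf.write(_provenance_lines(meta))
    anova_table.table.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    buf.write("\n")
    stats = pd.DataFrame(
        {"statistic": list(anova_table.stats), "value": list(anova_table.stats.values())}
    )
    stats.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_model_json(model: PolyModel, path, meta: dict | None = None) -> None:
    payload = {
        "order": model.order,
        "factor_names": model.factor_names,
        "coef": model.coef,
        "coded_space": model.coded_space,
    }
    if meta:
        payload["provenance"] = meta
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_model_json(path) -> PolyModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return PolyModel(
        order=int(d["order"]),
        factor_names=list(d["factor_names"]),
        coef={k: float(v) for k, v in d["coef"].items()},
        coded_space=bool(d.get("coded_space", True)),
    )
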