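"""Readers/writers for the tabular formats and run manifests.

All tabular I/O is tab-delimited UTF-8 text with a header row; expression
matrices are genes-as-rows, samples-as-columns.  Writers emit a JSON
manifest alongside major outputs carrying the tool version, a configuration
hash and the seed, so every artifact is reproducible from its metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import CONDITIONS

CALL_COLUMNS = ["gene", "profile_id", "category", "p", "b", "score", "sign"]


class IOError_(ValueError):
    pass


def read_expression(path: Path | str) -> pd.DataFrame:
    """Genes x samples log2 expression matrix from TSV.

    Non-numeric cells raise an error naming the offending row and column.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise IOError_(f"{path}: duplicated gene/probe names {dupes[:5]}")
    if pd.Index(table.columns).duplicated().any():
        raise IOError_(f"{path}: duplicated sample names")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & table.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise IOError_(f"{path}: non-numeric expression value "
                       f"{table.iat[r, c]!r} at row {table.index[r]!r}, "
                       f"column {table.columns[c]!r}")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise IOError_(f"{path}: missing expression value at row "
                       f"{table.index[r]!r}, column {table.columns[c]!r}")
    return numeric


def write_expression(matrix: pd.DataFrame, path: Path | str) -> None:
    matrix.to_csv(path, sep="\t")


def read_design(path: Path | str) -> pd.Series:
    """sample -> condition map from a two-column TSV (sample, condition)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition"}
    if not required.issubset(table.columns):
        raise IOError_(f"{path}: design file needs columns "
                       f"{sorted(required)}")
    if table["sample"].duplicated().any():
        dupes = table.loc[table["sample"].duplicated(), "sample"].tolist()
        raise IOError_(f"{path}: duplicated sample names {dupes}")
    unknown = set(table["condition"]) - set(CONDITIONS)
    if unknown:
        raise IOError_(f"{path}: unknown condition tokens "
                       f"{sorted(unknown)}; expected {CONDITIONS}")
    design = pd.Series(table["condition"].to_numpy(),
                       index=table["sample"], name="condition")
    design.index.name = "sample"
    return design


def write_design(design: pd.Series, path: Path | str) -> None:
    frame = design.rename("condition").rename_axis("sample").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_probe_map(path: Path | str) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe", "gene"}.issubset(table.columns):
        raise IOError_(f"{path}: probe map needs columns probe, gene")
    return pd.Series(table["gene"].to_numpy(), index=table["probe"],
                     name="gene")


def write_calls(calls: pd.DataFrame, path: Path | str,
                manifest: dict | None = None) -> None:
    """Calls TSV plus a JSON manifest sidecar (<path>.manifest.json)."""
    path = Path(path)
    calls.to_csv(path, sep="\t", index=False)
    if manifest is not None:
        write_manifest(manifest, path.with_suffix(path.suffix
                                                  + ".manifest.json"))


def read_calls(path: Path | str) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise IOError_(f"{path}: calls table missing columns "
                       f"{sorted(missing)}")
    return calls[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ToolConfig:
    """All tunable thresholds of the workflow, YAML-serializable."""

    schema_version: str = "1.0"
    admissible_range: tuple = (-14.0, 14.0)
    min_signal: float = 0.5
    regimes: tuple = (4.0, 2.5, 2.0)
    instances_per_profile: int = 400
    n_reps: int = 4
    alpha: float = 0.05
    cv_filter: bool = True
    delta_filter: bool = True
    tau: float = 0.0
    max_term_size: int = 500
    min_coverage: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise IOError_("alpha must be in (0, 1)")
        if self.min_signal < 0 or self.tau < 0:
            raise IOError_("min_signal and tau must be >= 0")
        if self.n_reps < 2:
            raise IOError_("n_reps must be >= 2")
        if any(r <= 0 for r in self.regimes):
            raise IOError_("delta/sigma regimes must be > 0")
        if not (0 <= self.min_coverage <= 1):
            raise IOError_("min_coverage must be in [0, 1]")
        self.admissible_range = tuple(float(x)
                                      for x in self.admissible_range)
        self.regimes = tuple(float(r) for r in self.regimes)


def read_config(path: Path | str) -> ToolConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return ToolConfig(**data)


def write_config(config: ToolConfig, path: Path | str) -> None:
    data = asdict(config)
    data["admissible_range"] = list(config.admissible_range)
    data["regimes"] = list(config.regimes)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False),
                          encoding="utf-8")


def config_hash(config: ToolConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(manifest: dict, path: Path | str,
                   config: ToolConfig | None = None,
                   seed: int | None = None) -> None:
    out = {"tool_version": __version__}
    if config is not None:
        out["config_hash"] = config_hash(config)
    if seed is not None:
        out["seed"] = seed
    out.update(manifest)
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default)
                          + "\n", encoding="utf-8")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
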