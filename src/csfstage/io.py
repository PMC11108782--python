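"""Cohort table and configuration I/O.

Cohort tables are plain CSV/TSV, one row per subject-visit.  A schema maps
column roles onto arbitrary column names so differently-labelled cohort
tables run through one pipeline; by default the generator's own column
names are assumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import BiomarkerPanel, default_panel

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "visit_time")


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(
    path,
    panel: BiomarkerPanel | None = None,
    schema: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cohort table, validating structure and biomarker columns.

    ``schema`` maps canonical role names (e.g. ``subject_id`` or a panel
    biomarker) to the file's column names; columns are renamed to canonical
    form on read.  Missing values are preserved as NaN.
    """
    df = pd.read_csv(path, sep=_delimiter(path))
    if schema:
        rename = {src: role for role, src in schema.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise ValueError(f"schema names absent from file: {missing_src}")
        df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if panel is not None:
        missing += [n for n in panel.names if n not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    if panel is not None:
        for name in panel.names:
            raw = df[name]
            coerced = pd.to_numeric(raw, errors="coerce")
            bad = coerced.isna() & raw.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value {raw.iloc[row]!r} in biomarker column "
                    f"{name!r} at row {row}"
                )
            df[name] = coerced
    logger.info(
        "read %d rows (%d subjects) from %s; missing cells: %d",
        len(df), df["subject_id"].nunique(), path, int(df.isna().sum().sum()),
    )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep=_delimiter(path), index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable digest of a configuration mapping, embedded in artifacts."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def panel_from_config(cfg: dict) -> BiomarkerPanel:
    if "panel" in cfg:
        return BiomarkerPanel.from_dict(cfg["panel"])
    return default_panel()


def write_artifact(payload: dict, path, config: dict, seed: int) -> None:
    """JSON artifact stamped with the config hash and seed."""
    payload = dict(payload)
    payload["_meta"] = {"config_hash": config_hash(config), "seed": seed}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str))
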