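"""CSV / JSON / YAML input-output with schema validation.

Formats are pinned for cross-platform determinism: CSV files are UTF-8,
comma-delimited, with a header row and "." decimals; probabilities are
serialised with six decimal places (below every tolerance used in the
package); reports are JSON with an explicit schema version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from ._exceptions import ValidationError
from .evaluation import MetricsReport
from .prediction import (
    STUDY1_COLUMNS,
    STUDY1_CONDITIONS,
    STUDY2_COLUMNS,
    STUDY2_CONDITIONS,
)
from .simulation import SweepSpec
from .synthetic import BetaProfile, GeneratorConfig

__all__ = [
    "SCHEMA_VERSION",
    "read_trials",
    "write_table",
    "write_report",
    "read_report",
    "load_sweep_spec",
    "load_generator_config",
]

SCHEMA_VERSION = 1

logger = logging.getLogger("biasnet")

_SLIDER_COLUMNS = {
    "S1": ("sl_prior", "bi_prior", "e_prior", "h_posterior_obs"),
    "S2": (
        "h_tax_prior",
        "sl_prior",
        "bi_prior",
        "e_prior",
        "sl_posterior_obs",
        "bi_posterior_obs",
        "e_posterior_obs",
        "h_crime_prior",
        "h_crime_posterior_obs",
    ),
}


def read_trials(path: str | Path, study: str) -> pd.DataFrame:
    """Read and validate a long-format trials CSV for one design.

    Hard-fails on missing required columns; reports malformed slider
    values and unknown condition labels with 1-based data row numbers.
    Observed-posterior columns are optional on input (prediction does
    not need them) but validated when present.
    """
    study = study.upper()
    if study not in ("S1", "S2"):
        raise ValidationError(f"unknown study label {study!r}")
    df = pd.read_csv(path, encoding="utf-8")
    required = STUDY1_COLUMNS if study == "S1" else STUDY2_COLUMNS
    conditions = STUDY1_CONDITIONS if study == "S1" else STUDY2_CONDITIONS
    missing = [
        c for c in required if c not in df.columns and not c.endswith("_obs")
    ]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: file contains a header but no data rows", path)
        return df

    problems = []
    for col in _SLIDER_COLUMNS[study]:
        if col not in df.columns:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values > 100)
        for idx in df.index[bad]:
            problems.append(f"row {idx + 1}: {col}={df.at[idx, col]!r}")
        df[col] = values
    for col, levels in conditions.items():
        bad = ~df[col].isin(levels)
        for idx in df.index[bad]:
            problems.append(f"row {idx + 1}: {col}={df.at[idx, col]!r}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} malformed value(s): "
            + "; ".join(problems[:20])
        )
    logger.info("%s: read %d trial rows (%s)", path, len(df), study)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as pinned-dialect CSV, probabilities to 6 d.p."""
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.6f")
    logger.info("%s: wrote %d rows", path, len(df))


def write_report(
    metrics: MetricsReport, path: str | Path, config: dict | None = None
) -> None:
    """Write a metrics report as versioned JSON (lossless round-trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config": config or {},
        "metrics": metrics.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    logger.info("%s: wrote metrics report", path)


def read_report(path: str | Path) -> MetricsReport:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: unsupported schema version {doc.get('schema_version')!r}"
        )
    return MetricsReport(**doc["metrics"])


def load_sweep_spec(path: str | Path) -> SweepSpec:
    """Load a sweep specification from YAML.

    Keys: ``target`` (H/HL/SL/BI/E/BD), ``testimony`` (TRUE/FALSE), and
    ``axes`` mapping prior names to a scalar, an explicit list, or a
    ``{start, stop, step}`` inclusive grid.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "target" not in doc:
        raise ValidationError(f"{path}: sweep spec needs a 'target' key")
    axes = {}
    for name, value in (doc.get("axes") or {}).items():
        if isinstance(value, dict):
            try:
                start, stop, step = value["start"], value["stop"], value["step"]
            except KeyError as exc:
                raise ValidationError(
                    f"{path}: grid axis {name!r} needs start/stop/step"
                ) from exc
            n = int(round((stop - start) / step)) + 1
            axes[name] = [round(start + k * step, 12) for k in range(n)]
        else:
            axes[name] = value
    return SweepSpec(
        target=str(doc["target"]).upper(),
        testimony=doc.get("testimony", "TRUE"),
        axes=axes,
    )


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a synthetic-table generator configuration from YAML.

    Keys: ``design`` (S1/S2), ``n_participants``, ``seed``, optional
    ``noise_sd`` and ``profiles`` (name -> [a, b] Beta parameters).
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: generator config must be a mapping")
    try:
        kwargs = {
            "design": str(doc["design"]),
            "n_participants": int(doc["n_participants"]),
            "seed": int(doc["seed"]),
        }
    except KeyError as exc:
        raise ValidationError(
            f"{path}: generator config needs design/n_participants/seed"
        ) from exc
    if "noise_sd" in doc:
        kwargs["noise_sd"] = float(doc["noise_sd"])
    profiles = {
        name: BetaProfile(*map(float, ab))
        for name, ab in (doc.get("profiles") or {}).items()
    }
    return GeneratorConfig(profiles=profiles, **kwargs)
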