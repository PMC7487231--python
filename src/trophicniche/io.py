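"""CSV readers/writers and the run manifest.

All tables are UTF-8 CSV with a header row, comma delimiter and ``.``
decimal mark.  Readers validate rows against the data-model invariants
and report offending row numbers (1-based, excluding the header).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    FecalItemRecord,
    IsotopeRecord,
    SchemaError,
    SourceGroup,
    ValidationError,
)

log = logging.getLogger("trophicniche")

FECAL_COLUMNS = ("sample_id", "species", "taxon", "category", "count", "volume")
ISOTOPE_COLUMNS = ("individual_id", "group", "d13c", "d15n")
SOURCE_COLUMNS = ("name", "guild", "mean_d13c", "sd_d13c", "mean_d15n", "sd_d15n")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_fecal_table(
    path: str | Path, categories: Sequence[str] | None = None
) -> list[FecalItemRecord]:
    """Read a long-format fecal-content table.

    If ``categories`` is given, every row's category must belong to it.
    """
    df = pd.read_csv(path)
    _require_columns(df, FECAL_COLUMNS, path)
    records: list[FecalItemRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            count = int(row.count)
            volume = float(row.volume)
            if count != float(row.count):
                raise ValidationError(f"non-integer count {row.count!r}")
            rec = FecalItemRecord(
                sample_id=str(row.sample_id),
                species=str(row.species),
                taxon=str(row.taxon),
                category=str(row.category),
                count=count,
                volume=volume,
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        if categories is not None and rec.category not in categories:
            raise ValidationError(
                f"{path}: row {i}: unknown category {rec.category!r}"
            )
        records.append(rec)
    return records


def read_isotope_table(path: str | Path) -> list[IsotopeRecord]:
    """Read a consumer/source isotope table (δ values in ‰)."""
    df = pd.read_csv(path)
    _require_columns(df, ISOTOPE_COLUMNS, path)
    if df.empty:
        log.warning("%s: empty isotope table", path)
        return []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                IsotopeRecord(
                    individual_id=str(row.individual_id),
                    group=str(row.group),
                    d13c=float(row.d13c),
                    d15n=float(row.d15n),
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def partition_by_group(
    records: Iterable[IsotopeRecord],
) -> dict[str, list[IsotopeRecord]]:
    out: dict[str, list[IsotopeRecord]] = {}
    for rec in records:
        out.setdefault(rec.group, []).append(rec)
    return out


def read_sources_table(path: str | Path) -> list[SourceGroup]:
    """Read a source-group table (per-element mean ± SD, ‰)."""
    df = pd.read_csv(path)
    _require_columns(df, SOURCE_COLUMNS, path)
    sources = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sources.append(
                SourceGroup(
                    name=str(row.name),
                    guild=str(row.guild),
                    mean={"d13c": float(row.mean_d13c), "d15n": float(row.mean_d15n)},
                    sd={"d13c": float(row.sd_d13c), "d15n": float(row.sd_d15n)},
                    n_specimens=int(getattr(row, "n_specimens", 0) or 0),
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return sources


def write_results(
    results: pd.DataFrame, path: str | Path, precision: int = 6
) -> None:
    """Write a result table deterministically.

    Columns keep their construction order; floats are serialised with
    ``precision`` significant digits so repeated runs are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False, float_format=f"%.{precision}g")


def posterior_summary_long(summary: dict[str, dict[str, dict[str, float]]]) -> pd.DataFrame:
    """Flatten a nested {species: {source: {statistic: value}}} summary
    into a long table (species, source, statistic, value)."""
    rows = []
    for species in sorted(summary):
        for source in summary[species]:
            for stat, value in summary[species][source].items():
                rows.append((species, source, stat, value))
    return pd.DataFrame(rows, columns=["species", "source", "statistic", "value"])


def write_manifest(out_dir: str | Path, config, extra: dict | None = None) -> Path:
    """Write a JSON run manifest (config hash, seed, library versions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_repr = repr(config)
    manifest = {
        "config": cfg_repr,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "seed": getattr(config, "rng_seed", None),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
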