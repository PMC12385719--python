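"""Reading and writing accession trait tables.

Files are plain CSV/TSV with a header row. The three metadata columns
are named exactly ``accession_id``, ``origin`` and ``period``; the 34
trait columns are named by registry code and may appear in any order on
read. On write, columns are canonicalized to registry order and numbers
are serialized at a fixed decimal precision with round-half-even, so
that write -> read -> write is byte-stable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import TraitRegistry, default_registry
from .table import META_COLUMNS, TraitTable

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("error", "impute_mean")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_trait_table(
    path: str | Path,
    registry: TraitRegistry | None = None,
    missing_policy: str = "error",
    delimiter: str | None = None,
) -> TraitTable:
    """Read and validate a trait table.

    Parameters
    ----------
    path
        CSV (``.csv``) or TSV (``.tsv``/``.tab``) file; override the
        extension-based delimiter with ``delimiter``.
    missing_policy
        ``"error"`` rejects any missing/non-numeric trait cell;
        ``"impute_mean"`` replaces missing cells with the column mean
        (logged).
    """
    registry = registry or default_registry()
    path = Path(path)
    if missing_policy not in MISSING_POLICIES:
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    if not path.exists():
        raise ValidationError(f"no such file: {path}")

    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str)
    expected = [*META_COLUMNS, *registry.codes]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing column(s): {', '.join(missing_cols)}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        logger.warning("ignoring %d unknown column(s): %s", len(extra), ", ".join(extra))

    counts: dict[str, int] = {}
    for a in df["accession_id"].astype(str):
        counts[a] = counts.get(a, 0) + 1
    dups = sorted(a for a, c in counts.items() if c > 1)
    if dups:
        raise ValidationError(f"duplicate accession ids: {', '.join(dups)}")

    n = len(df)
    values = np.empty((n, len(registry)), dtype=float)
    n_imputed = 0
    for j, code in enumerate(registry.codes):
        col = pd.to_numeric(df[code], errors="coerce").to_numpy(dtype=float)
        raw_blank = df[code].isna() | (df[code].astype(str).str.strip() == "")
        bad = np.isnan(col)
        if bad.any():
            if missing_policy == "error":
                i = int(np.argmax(bad))
                kind = "missing" if bool(raw_blank.iloc[i]) else "non-numeric"
                raise ValidationError(
                    f"{kind} value in trait column {code!r}, row {i + 1} "
                    f"(accession {df['accession_id'].iloc[i]!r})"
                )
            not_blank_bad = bad & ~raw_blank.to_numpy()
            if not_blank_bad.any():
                i = int(np.argmax(not_blank_bad))
                raise ValidationError(
                    f"non-numeric value in trait column {code!r}, row {i + 1}"
                )
            col[bad] = np.nanmean(col) if (~bad).any() else np.nan
            n_imputed += int(bad.sum())
        values[:, j] = col
    if n_imputed:
        logger.info("imputed %d missing cell(s) with column means", n_imputed)

    return TraitTable(
        accession_ids=[str(a) for a in df["accession_id"]],
        origin=df["origin"].to_numpy(dtype=object),
        period=df["period"].to_numpy(dtype=object),
        values=values,
        registry=registry,
    )


def write_trait_table(
    table: TraitTable,
    path: str | Path,
    precision: int = 6,
    delimiter: str | None = None,
) -> None:
    """Write a trait table with columns in canonical registry order.

    Numbers are formatted with ``precision`` decimals using IEEE
    round-half-even (Python's fixed-point float formatting), so golden
    files are byte-reproducible.
    """
    path = Path(path)
    df = table.to_dataframe()
    try:
        df.to_csv(
            path,
            sep=_delimiter_for(path, delimiter),
            index=False,
            float_format=lambda v: format(v, f".{precision}f"),
        )
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from exc
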