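"""The accession x trait table — the currency every pipeline stage consumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import TraitRegistry, default_registry

#: Geographic origin groups: Yangtze River Basin, Yellow River Basin,
#: northern extra-early-maturing region, northwest inland region,
#: landraces, foreign accessions.
ORIGIN_LEVELS = ("YZR", "YER", "NER", "NIR", "LAN", "FOR")

#: Breeding periods.
PERIOD_LEVELS = ("foreign_introduction", "1953-2000", "2001-2010", "2011-2022")

#: Metadata column names in files.
META_COLUMNS = ("accession_id", "origin", "period")


@dataclass
class TraitTable:
    """A validated panel of accessions with origin/period metadata and the
    34 trait measurements in registry order.

    Parameters
    ----------
    accession_ids
        Unique accession identifiers, one per row of ``values``.
    origin
        Geographic origin per accession, levels in :data:`ORIGIN_LEVELS`.
    period
        Breeding period per accession, levels in :data:`PERIOD_LEVELS`.
    values
        ``(n_accessions, 34)`` float matrix aligned to ``registry`` order.
    """

    accession_ids: list[str]
    origin: np.ndarray
    period: np.ndarray
    values: np.ndarray
    registry: TraitRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.origin = np.asarray(self.origin, dtype=object)
        self.period = np.asarray(self.period, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        n = len(self.accession_ids)
        counts: dict[str, int] = {}
        for a in self.accession_ids:
            counts[a] = counts.get(a, 0) + 1
        dups = sorted(a for a, c in counts.items() if c > 1)
        if dups:
            raise ValidationError(f"duplicate accession ids: {', '.join(dups)}")
        if self.origin.shape != (n,) or self.period.shape != (n,):
            raise ValidationError("origin/period length must match accession count")
        if self.values.shape != (n, len(self.registry)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({n}, {len(self.registry)})"
            )
        bad_origin = sorted({str(o) for o in self.origin} - set(ORIGIN_LEVELS))
        if bad_origin:
            raise ValidationError(f"unknown origin level(s): {', '.join(bad_origin)}")
        bad_period = sorted({str(p) for p in self.period} - set(PERIOD_LEVELS))
        if bad_period:
            raise ValidationError(f"unknown period level(s): {', '.join(bad_period)}")
        if n and not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for accession {self.accession_ids[i]!r}, "
                f"trait {self.registry.codes[j]!r}"
            )
        for j, entry in enumerate(self.registry):
            if entry.units == "%" and n:
                col = self.values[:, j]
                if col.min() < 0.0 or col.max() > 100.0:
                    raise ValidationError(
                        f"percentage trait {entry.code!r} outside [0, 100]"
                    )

    # -- convenience ----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def column(self, code: str) -> np.ndarray:
        """Values of one trait, by code."""
        return self.values[:, self.registry.index(code)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.registry.codes)
        df.insert(0, "period", self.period)
        df.insert(0, "origin", self.origin)
        df.insert(0, "accession_id", self.accession_ids)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, registry: TraitRegistry | None = None
    ) -> "TraitTable":
        registry = registry or default_registry()
        missing = [c for c in (*META_COLUMNS, *registry.codes) if c not in df.columns]
        if missing:
            raise ValidationError(f"missing column(s): {', '.join(missing)}")
        return cls(
            accession_ids=[str(a) for a in df["accession_id"]],
            origin=df["origin"].to_numpy(dtype=object),
            period=df["period"].to_numpy(dtype=object),
            values=df[registry.codes].to_numpy(dtype=float),
            registry=registry,
        )

    def equals(self, other: "TraitTable", atol: float = 0.0) -> bool:
        return (
            self.accession_ids == other.accession_ids
            and list(self.origin) == list(other.origin)
            and list(self.period) == list(other.period)
            and self.values.shape == other.values.shape
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )
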