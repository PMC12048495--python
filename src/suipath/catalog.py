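"""Variable catalog: the dictionary of short node codes used throughout the pipeline.

Every cohort column, network node and pathway milestone is identified by a short
code (``a`` … ``bj``).  The catalog maps each code to a human-readable name, the
study period it belongs to (1 = baseline, 2 = three-month follow-up, 3 = one-year
follow-up), its measurement type, and per-arm target moments (mean/SD for
continuous variables, prevalence for binary ones) that the synthetic-cohort
generator emulates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CatalogEntry",
    "VariableCatalog",
    "load_catalog",
    "default_catalog",
    "ALIASES",
    "MILESTONES",
    "EXCLUDED_NODES",
]

#: Codes whose printed label duplicates another code's label; each alias is
#: generated as an exact copy of its canonical column.
ALIASES: dict[str, str] = {
    "p": "ai",   # testosterone (resting, early morning)
    "k": "an",   # PFMT frequency per week
    "be": "bi",  # incontinence dry after 1 year
    "bf": "bj",  # return after 1 year
    "o": "bh",   # pad test improved over 1 year
    "aj": "bg",  # ICIQ-SF improved over 1 year
    "j": "bj",   # return after 1 year (baseline-block duplicate)
}

#: Canonical treatment-pathway milestones: initial assessment -> 3-month
#: follow-up -> 1-year dryness -> return to elite competition.
MILESTONES: tuple[str, str, str, str] = ("ap", "av", "bi", "bj")

#: Nodes dropped from the final variable network (low connectivity / weak
#: correlation with the clinically meaningful outcomes).
EXCLUDED_NODES: tuple[str, ...] = ("y", "t", "ad", "ae", "v", "e", "ac", "f", "ab", "u")


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    name: str
    period: int
    dtype: str  # "continuous" | "binary"
    mean_treat: float
    sd_treat: float
    mean_ctrl: float
    sd_ctrl: float

    @property
    def is_binary(self) -> bool:
        return self.dtype == "binary"


@dataclass
class VariableCatalog:
    """Ordered collection of :class:`CatalogEntry`, keyed by code."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        if dupes:
            raise ValueError(f"duplicate codes in catalog: {', '.join(dupes)}")
        for e in self.entries:
            if e.period not in (1, 2, 3):
                raise ValueError(f"code {e.code!r}: period must be 1, 2 or 3 (got {e.period!r})")
            if e.is_binary:
                for prev in (e.mean_treat, e.mean_ctrl):
                    if not 0.0 <= prev <= 1.0:
                        raise ValueError(
                            f"code {e.code!r}: binary prevalence {prev} outside [0, 1]"
                        )
            else:
                if e.sd_treat < 0 or e.sd_ctrl < 0:
                    raise ValueError(f"code {e.code!r}: negative SD")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return any(e.code == code for e in self.entries)

    def __getitem__(self, code: str) -> CatalogEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(code)

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    def by_period(self, period: int) -> list[CatalogEntry]:
        return [e for e in self.entries if e.period == period]

    def period_of(self, code: str) -> int:
        return self[code].period


def _parse_rows(rows: Iterable[dict], source: str) -> VariableCatalog:
    entries = []
    for row in rows:
        code = (row.get("code") or "").strip()
        if not code:
            continue
        period_raw = (row.get("period") or "").strip()
        if not period_raw:
            raise ValueError(f"{source}: code {code!r} is missing a period")
        try:
            period = int(period_raw)
        except ValueError as exc:
            raise ValueError(f"{source}: code {code!r} has non-integer period {period_raw!r}") from exc
        entries.append(
            CatalogEntry(
                code=code,
                name=(row.get("name") or "").strip(),
                period=period,
                dtype=(row.get("dtype") or "continuous").strip(),
                mean_treat=float(row.get("mean_treat") or 0.0),
                sd_treat=float(row.get("sd_treat") or 0.0),
                mean_ctrl=float(row.get("mean_ctrl") or 0.0),
                sd_ctrl=float(row.get("sd_ctrl") or 0.0),
            )
        )
    if not entries:
        raise ValueError("catalog has no entries")
    return VariableCatalog(entries)


def load_catalog(path: str | Path) -> VariableCatalog:
    """Load a catalog from a CSV file.

    Expected header: ``code,name,period,dtype,mean_treat,sd_treat,mean_ctrl,sd_ctrl``.
    Raises :class:`ValueError` on duplicate codes, missing periods, or binary
    prevalences outside ``[0, 1]``; an empty file raises "catalog has no entries".
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        return _parse_rows(reader, source=str(path))


def default_catalog() -> VariableCatalog:
    """The packaged 62-code catalog (codes ``a`` … ``bj``)."""
    ref = resources.files("suipath.data").joinpath("catalog.csv")
    with ref.open(newline="") as fh:
        return _parse_rows(csv.DictReader(fh), source="packaged catalog")
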