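"""Feasible basal concentration ranges and initial-condition sampling.

Each monitored species has a literature-derived feasible interval
``[c_min, c_max]`` for its unperturbed (basal) concentration.  The error
function normalizes deviations by sigma_s = (c_max - c_min)/8, i.e. the
feasible interval is read as ``c_mean ± 4 sigma_s`` with
``c_mean = (c_min + c_max)/2``.

Initial conditions for ensemble simulation are drawn independently and
uniformly within each species' interval; complex species start at zero.
Species without curated data default to 0–100 nM.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .mechanism import Mechanism
from .units import NM_TO_MOLCM3, MOLCM3_TO_NM

__all__ = [
    "SpeciesRange",
    "BasalRangeSet",
    "DEFAULT_RANGE_NM",
    "read_ranges_csv",
    "write_ranges_csv",
    "sample_initial_conditions",
]

#: default feasible interval for species with no curated literature value (nM)
DEFAULT_RANGE_NM = (0.0, 100.0)


@dataclass(frozen=True)
class SpeciesRange:
    """Feasible interval for one species, internal units (mol/cm^3)."""

    species_id: str
    c_min: float
    c_max: float
    monitored: bool = True
    source_note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.c_min <= self.c_max):
            raise ValueError(
                f"{self.species_id}: invalid range [{self.c_min}, {self.c_max}]"
            )

    @property
    def c_mean(self) -> float:
        return 0.5 * (self.c_min + self.c_max)

    @property
    def sigma(self) -> float:
        """One eighth of the interval width — the error-function normalizer."""
        return (self.c_max - self.c_min) / 8.0


class BasalRangeSet:
    """Mapping species id -> :class:`SpeciesRange` with sampling helpers."""

    def __init__(self, ranges: Iterable[SpeciesRange], allow_default: bool = True):
        self._ranges: dict[str, SpeciesRange] = {}
        for r in ranges:
            if r.species_id in self._ranges:
                raise ValueError(f"duplicate range for species {r.species_id}")
            self._ranges[r.species_id] = r
        self.allow_default = allow_default

    def __contains__(self, sid: str) -> bool:
        return sid in self._ranges

    def __getitem__(self, sid: str) -> SpeciesRange:
        return self._ranges[sid]

    def __iter__(self):
        return iter(self._ranges.values())

    def __len__(self) -> int:
        return len(self._ranges)

    def get(self, sid: str) -> SpeciesRange:
        """Range for ``sid``, falling back to the 0–100 nM default."""
        if sid in self._ranges:
            return self._ranges[sid]
        if not self.allow_default:
            raise KeyError(f"no basal range for species {sid!r} and defaults disabled")
        lo, hi = DEFAULT_RANGE_NM
        return SpeciesRange(
            sid, lo * NM_TO_MOLCM3, hi * NM_TO_MOLCM3, monitored=False,
            source_note="default 0-100 nM",
        )

    @classmethod
    def from_nm(
        cls,
        ranges_nm: Mapping[str, tuple[float, float]],
        monitored: Iterable[str] | None = None,
        **kw,
    ) -> "BasalRangeSet":
        mon = set(monitored) if monitored is not None else None
        out = []
        for sid, (lo, hi) in ranges_nm.items():
            out.append(
                SpeciesRange(
                    sid,
                    lo * NM_TO_MOLCM3,
                    hi * NM_TO_MOLCM3,
                    monitored=(sid in mon) if mon is not None else True,
                )
            )
        return cls(out, **kw)


def read_ranges_csv(path: str | Path, allow_default: bool = True) -> BasalRangeSet:
    """Read a ranges CSV (species_id, c_min_nM, c_max_nM, monitored, source_note)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SpeciesRange(
                    species_id=row["species_id"],
                    c_min=float(row["c_min_nM"]) * NM_TO_MOLCM3,
                    c_max=float(row["c_max_nM"]) * NM_TO_MOLCM3,
                    monitored=row.get("monitored", "1").strip().lower() in ("1", "true", "yes"),
                    source_note=row.get("source_note", ""),
                )
            )
    return BasalRangeSet(out, allow_default=allow_default)


def write_ranges_csv(ranges: BasalRangeSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id", "c_min_nM", "c_max_nM", "monitored", "source_note"])
        for r in ranges:
            w.writerow(
                [
                    r.species_id,
                    repr(r.c_min * MOLCM3_TO_NM),
                    repr(r.c_max * MOLCM3_TO_NM),
                    int(r.monitored),
                    r.source_note,
                ]
            )


def sample_initial_conditions(
    ranges: BasalRangeSet,
    mech: Mechanism,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` initial-state vectors for the dynamic species of ``mech``.

    Each coordinate is independent uniform on its species' feasible interval;
    complex species are forced to zero.  Returns an ``(n, n_dynamic)`` array
    in mol/cm^3, ordered like ``mech.dynamic_species``.  Deterministic per
    seed.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    dyn = mech.dynamic_species
    lo = np.empty(len(dyn))
    hi = np.empty(len(dyn))
    for j, s in enumerate(dyn):
        if s.is_complex:
            lo[j] = hi[j] = 0.0
        else:
            r = ranges.get(s.id)
            lo[j], hi[j] = r.c_min, r.c_max
    u = rng.random((n, len(dyn)))
    return lo + u * (hi - lo)
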