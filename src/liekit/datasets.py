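"""Per-ligand dataset container: the unit on which gamma is fitted.

A :class:`LIEDataset` holds, for every ligand, the four ensemble averages
(bound/free x vdw/ele), plus the experimental record (IC50, hydroxyl count,
net charge, docking score) needed for coefficient assignment and fitting.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energies import DeltaEnergies, EnergySeries, EnsembleEstimate, delta_interaction, ensemble_average
from .exceptions import ValidationError

__all__ = ["LigandEntry", "LIEEntry", "LIEDataset"]


@dataclass(frozen=True)
class LigandEntry:
    """Experimental and chemical record of one ligand.

    All fields but the identifier are optional; IC50 is in micromolar.
    """

    ligand_id: str
    ic50_um: float | None = None
    hydroxyl_count: int | None = None
    net_charge: int | None = None
    docking_score: float | None = None

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise ValidationError("ligand_id must be non-empty")
        if self.ic50_um is not None and not (
            math.isfinite(self.ic50_um) and self.ic50_um > 0
        ):
            raise ValidationError(
                f"ligand {self.ligand_id!r}: IC50 must be positive, got {self.ic50_um}"
            )


@dataclass(frozen=True)
class LIEEntry:
    """One ligand's four ensemble averages plus its experimental record."""

    ligand: LigandEntry
    bound_vdw: EnsembleEstimate
    bound_ele: EnsembleEstimate
    free_vdw: EnsembleEstimate
    free_ele: EnsembleEstimate

    @property
    def ligand_id(self) -> str:
        return self.ligand.ligand_id

    def deltas(self) -> DeltaEnergies:
        return delta_interaction(self.bound_vdw, self.bound_ele, self.free_vdw, self.free_ele)


_AVERAGE_COLS = ("free_vdw", "free_ele", "bound_vdw", "bound_ele")


@dataclass(frozen=True)
class LIEDataset:
    """Ordered, uniquely-keyed collection of :class:`LIEEntry`."""

    entries: tuple[LIEEntry, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for i, entry in enumerate(self.entries):
            if entry.ligand_id in index:
                raise ValidationError(f"duplicate ligand id {entry.ligand_id!r}")
            index[entry.ligand_id] = i
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self._index

    def __getitem__(self, ligand_id: str) -> LIEEntry:
        try:
            return self.entries[self._index[ligand_id]]
        except KeyError:
            raise KeyError(f"no ligand {ligand_id!r} in dataset") from None

    @property
    def ligand_ids(self) -> tuple[str, ...]:
        return tuple(e.ligand_id for e in self.entries)

    def subset(self, keep: Iterable[str]) -> "LIEDataset":
        """Dataset restricted to ``keep``, preserving the original order."""
        keep = set(keep)
        unknown = keep - set(self.ligand_ids)
        if unknown:
            raise ValidationError(f"unknown ligand ids: {sorted(unknown)}")
        return LIEDataset(tuple(e for e in self.entries if e.ligand_id in keep))

    def drop(self, remove: Iterable[str]) -> "LIEDataset":
        """Dataset with ``remove`` excluded, preserving the original order."""
        remove = set(remove)
        return LIEDataset(tuple(e for e in self.entries if e.ligand_id not in remove))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LIEDataset":
        """Build from a table with one row per ligand.

        Required columns: ``ligand_id`` and the four averages ``free_vdw``,
        ``free_ele``, ``bound_vdw``, ``bound_ele``.  Optional columns:
        per-average ``*_sem``, ``ic50_um``, ``hydroxyl_count``,
        ``net_charge``, ``docking_score``.
        """
        missing = [c for c in ("ligand_id", *_AVERAGE_COLS) if c not in df.columns]
        if missing:
            raise ValidationError(f"dataset table is missing columns: {missing}")

        def opt(row, col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        entries = []
        for _, row in df.iterrows():
            ligand = LigandEntry(
                ligand_id=str(row["ligand_id"]),
                ic50_um=opt(row, "ic50_um"),
                hydroxyl_count=opt(row, "hydroxyl_count", int),
                net_charge=opt(row, "net_charge", int),
                docking_score=opt(row, "docking_score"),
            )
            estimates = {
                col: EnsembleEstimate(mean=float(row[col]), sem=opt(row, f"{col}_sem"))
                for col in _AVERAGE_COLS
            }
            entries.append(LIEEntry(ligand=ligand, **estimates))
        return cls(tuple(entries))

    @classmethod
    def from_energy_series(
        cls,
        series: Iterable[EnergySeries],
        ligands: Mapping[str, LigandEntry] | Iterable[LigandEntry] = (),
    ) -> "LIEDataset":
        """Assemble from raw per-frame series (one bound + one free per ligand).

        ``ligands`` supplies the experimental records; ligands without a
        record get a bare :class:`LigandEntry`.
        """
        if not isinstance(ligands, Mapping):
            ligands = {lig.ligand_id: lig for lig in ligands}
        by_ligand: dict[str, dict[str, EnergySeries]] = {}
        for s in series:
            states = by_ligand.setdefault(s.ligand_id, {})
            if s.state in states:
                raise ValidationError(f"duplicate {s.state} series for ligand {s.ligand_id!r}")
            states[s.state] = s
        entries = []
        for ligand_id, states in by_ligand.items():
            missing = {"bound", "free"} - set(states)
            if missing:
                raise ValidationError(
                    f"ligand {ligand_id!r}: missing {sorted(missing)} state series"
                )
            entries.append(
                LIEEntry(
                    ligand=ligands.get(ligand_id, LigandEntry(ligand_id=ligand_id)),
                    bound_vdw=ensemble_average(states["bound"], "vdw"),
                    bound_ele=ensemble_average(states["bound"], "ele"),
                    free_vdw=ensemble_average(states["free"], "vdw"),
                    free_ele=ensemble_average(states["free"], "ele"),
                )
            )
        return cls(tuple(entries))

    def to_dataframe(self) -> pd.DataFrame:
        """One row per ligand; averages, sems and the experimental record."""
        rows = []
        for e in self.entries:
            row: dict[str, object] = {"ligand_id": e.ligand_id}
            for col in _AVERAGE_COLS:
                est: EnsembleEstimate = getattr(e, col)
                row[col] = est.mean
                row[f"{col}_sem"] = np.nan if est.sem is None else est.sem
            lig = e.ligand
            row["ic50_um"] = np.nan if lig.ic50_um is None else lig.ic50_um
            row["hydroxyl_count"] = np.nan if lig.hydroxyl_count is None else lig.hydroxyl_count
            row["net_charge"] = np.nan if lig.net_charge is None else lig.net_charge
            row["docking_score"] = np.nan if lig.docking_score is None else lig.docking_score
            rows.append(row)
        return pd.DataFrame(rows)
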