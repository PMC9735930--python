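"""Per-residue decomposition of the ligand-surrounding interaction energy.

MD engines can split the total ligand-surrounding energy of each frame into
contributions from individual residues (and metal ions, treated here as
ordinary residue labels such as ``"Cu2A"``/``"Cu2B"``).  Averaging those per
frame and replica yields decomposition tables that show which residues drive
binding, and differences between two ligands' tables rank the residues that
explain their affinity gap.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd

from .energies import EnergySeries
from .exceptions import ValidationError

__all__ = [
    "PerResidueSeries",
    "PerResidueTable",
    "ClosureReport",
    "aggregate_residue_contributions",
    "contribution_difference",
    "top_contributors",
    "check_closure",
]

_COL = {"vdw": 0, "ele": 1}


@dataclass(frozen=True)
class PerResidueSeries:
    """Per-frame, per-residue (vdw, ele) energies for one ligand.

    ``replicas`` holds one array per replica of shape
    ``(n_frames, n_residues, 2)``, residue axis ordered as ``residue_ids``.
    """

    ligand_id: str
    residue_ids: tuple[str, ...]
    replicas: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.residue_ids) == 0:
            raise ValidationError("residue_ids must be non-empty")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ValidationError("residue_ids must be unique")
        if len(self.replicas) == 0:
            raise ValidationError("at least one replica required")
        arrays = []
        n_res = len(self.residue_ids)
        for i, rep in enumerate(self.replicas):
            arr = np.asarray(rep, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != n_res or arr.shape[2] != 2:
                raise ValidationError(
                    f"replica {i}: expected shape (n_frames, {n_res}, 2), got {arr.shape}"
                )
            if arr.shape[0] == 0:
                raise ValidationError(f"replica {i} is empty")
            if not np.isfinite(arr).all():
                raise ValidationError(f"replica {i} contains non-finite energies")
            arrays.append(arr)
        object.__setattr__(self, "replicas", tuple(arrays))
        object.__setattr__(self, "residue_ids", tuple(self.residue_ids))

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


@dataclass(frozen=True)
class PerResidueTable:
    """Aggregated per-residue means and standard errors (kcal/mol).

    ``rows`` is a DataFrame indexed by residue id with columns
    ``mean_vdw``, ``mean_ele``, ``sem_vdw``, ``sem_ele`` (sems NaN when a
    single replica makes them undefined).
    """

    ligand_id: str
    rows: pd.DataFrame

    def mean(self, component: str) -> pd.Series:
        return self.rows[f"mean_{component}"]


def aggregate_residue_contributions(series: PerResidueSeries) -> PerResidueTable:
    """Per-residue grand means with replica-spread standard errors.

    Same convention as the total-energy ensemble average: the mean pools all
    frames of all replicas; the sem is the standard deviation of per-replica
    means over ``sqrt(n_replicas)``, undefined (NaN) for one replica.
    """
    pooled = np.concatenate(series.replicas, axis=0)  # (frames, res, 2)
    means = pooled.mean(axis=0)
    if series.n_replicas >= 2:
        rep_means = np.stack([r.mean(axis=0) for r in series.replicas])
        sems = rep_means.std(axis=0, ddof=1) / sqrt(series.n_replicas)
    else:
        sems = np.full_like(means, np.nan)
    rows = pd.DataFrame(
        {
            "mean_vdw": means[:, 0],
            "mean_ele": means[:, 1],
            "sem_vdw": sems[:, 0],
            "sem_ele": sems[:, 1],
        },
        index=pd.Index(series.residue_ids, name="residue_id"),
    )
    return PerResidueTable(ligand_id=series.ligand_id, rows=rows)


def contribution_difference(
    a: PerResidueTable, b: PerResidueTable, component: str = "vdw"
) -> pd.Series:
    """Per-residue change "from a to b": ``value(b) - value(a)``.

    A negative change means the residue's interaction is more favorable for
    ``b`` than for ``a``.
    """
    if component not in _COL:
        raise ValidationError(f"unknown component {component!r}")
    set_a, set_b = set(a.rows.index), set(b.rows.index)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValidationError(f"residue sets differ; unmatched: {diff}")
    col = f"mean_{component}"
    return (b.rows[col] - a.rows[col]).reindex(a.rows.index)


def top_contributors(table: PerResidueTable, n: int, component: str = "vdw") -> list[str]:
    """The ``n`` residues with the most favorable (most negative) mean.

    Ties break by residue id.
    """
    if component not in _COL:
        raise ValidationError(f"unknown component {component!r}")
    if n > len(table.rows):
        raise ValidationError(f"n={n} exceeds the {len(table.rows)} residues available")
    order = sorted(table.rows.index, key=lambda rid: (table.rows.at[rid, f"mean_{component}"], rid))
    return order[:n]


@dataclass(frozen=True)
class ClosureReport:
    """Frames where the decomposition fails to sum to the total energy.

    ``vdw_ok``/``ele_ok`` hold one boolean array per replica (True = frame
    closes within tolerance).
    """

    vdw_ok: tuple[np.ndarray, ...]
    ele_ok: tuple[np.ndarray, ...]
    tolerance: float

    def n_flagged(self, component: str) -> int:
        oks = {"vdw": self.vdw_ok, "ele": self.ele_ok}[component]
        return int(sum((~ok).sum() for ok in oks))

    @property
    def all_closed(self) -> bool:
        return self.n_flagged("vdw") == 0 and self.n_flagged("ele") == 0


def check_closure(
    series: PerResidueSeries, total: EnergySeries, tolerance: float
) -> ClosureReport:
    """Verify that per-residue energies sum to the total series frame-wise."""
    if series.ligand_id != total.ligand_id:
        raise ValidationError(
            f"ligand mismatch: {series.ligand_id!r} vs {total.ligand_id!r}"
        )
    if series.n_replicas != total.n_replicas:
        raise ValidationError(
            f"replica count mismatch: {series.n_replicas} vs {total.n_replicas}"
        )
    vdw_ok, ele_ok = [], []
    for i, (res_rep, tot_rep) in enumerate(zip(series.replicas, total.replicas)):
        if res_rep.shape[0] != tot_rep.shape[0]:
            raise ValidationError(
                f"replica {i}: frame count mismatch ({res_rep.shape[0]} vs {tot_rep.shape[0]})"
            )
        sums = res_rep.sum(axis=1)  # (frames, 2)
        ok = np.abs(sums - tot_rep) <= tolerance
        vdw_ok.append(ok[:, 0])
        ele_ok.append(ok[:, 1])
    return ClosureReport(vdw_ok=tuple(vdw_ok), ele_ok=tuple(ele_ok), tolerance=tolerance)
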