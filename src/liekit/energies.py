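"""Core quantities of the linear interaction energy (LIE) method.

The LIE method estimates the absolute binding free energy of a ligand from
two molecular-dynamics ensembles: the ligand bound in the protein site and
the ligand free in water.  For each state the ligand-surrounding interaction
energy is split into a van der Waals ("vdw") and an electrostatic ("ele")
component, averaged over all production frames, and the binding free energy
is the linear combination

    dG_LIE = alpha * (<U_vdw>_bound - <U_vdw>_free)
           + beta  * (<U_ele>_bound - <U_ele>_free)
           + gamma

with empirical coefficients ``alpha`` (non-polar scaling), ``beta`` (polar
scaling, dependent on the chemical nature of the ligand) and a constant
offset ``gamma`` that absorbs assay- and model-specific terms.

Experimental reference values come from half-maximal inhibitory
concentrations through

    dG_EXP = R * T * ln(IC50) + c

with IC50 converted to mol/L and an assay constant ``c`` that cancels in
relative free energies.

All energies are in kcal/mol; concentrations enter in micromolar (the unit
inhibition assays report) and are converted internally.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "VDW",
    "ELE",
    "COMPONENTS",
    "GAS_CONSTANT_KCAL",
    "EnergySample",
    "EnergySeries",
    "EnsembleEstimate",
    "DeltaEnergies",
    "LIEParameters",
    "ThermoConfig",
    "BindingEstimate",
    "ensemble_average",
    "delta_interaction",
    "assign_beta",
    "lie_energy",
    "dg_from_ic50",
    "ic50_from_dg",
]

VDW = "vdw"
ELE = "ele"
COMPONENTS = (VDW, ELE)
_COL = {VDW: 0, ELE: 1}

#: Molar gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Polar scaling factors of the FEP-derived assignment scheme: charged
#: ligands take 0.50; neutral ligands take 0.43 / 0.37 / 0.33 for zero,
#: one, or two-or-more hydroxyl groups.
FEP_DERIVED_BETA = {"charged": 0.50, 0: 0.43, 1: 0.37, "2+": 0.33}


def _require_component(component: str) -> int:
    if component not in _COL:
        raise ValidationError(f"unknown energy component {component!r}; expected 'vdw' or 'ele'")
    return _COL[component]


class EnergySample(NamedTuple):
    """One MD frame's ligand-surrounding interaction energies (kcal/mol)."""

    frame_index: int
    u_vdw: float
    u_ele: float


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame interaction energies for one ligand in one state.

    Parameters
    ----------
    ligand_id
        Identifier of the ligand.
    state
        ``"bound"`` (ligand in the protein site) or ``"free"`` (ligand in
        water).
    replicas
        One array per independent replica, each of shape ``(n_frames, 2)``
        with columns ``(u_vdw, u_ele)`` in kcal/mol.
    """

    ligand_id: str
    state: str
    replicas: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.state not in ("bound", "free"):
            raise ValidationError(f"state must be 'bound' or 'free', got {self.state!r}")
        if len(self.replicas) == 0:
            raise ValidationError(f"{self.ligand_id}/{self.state}: at least one replica required")
        arrays = []
        for i, rep in enumerate(self.replicas):
            arr = np.asarray(rep, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValidationError(
                    f"{self.ligand_id}/{self.state}: replica {i} must have shape (n_frames, 2)"
                )
            if arr.shape[0] == 0:
                raise ValidationError(f"{self.ligand_id}/{self.state}: replica {i} is empty")
            if not np.isfinite(arr).all():
                raise ValidationError(
                    f"{self.ligand_id}/{self.state}: replica {i} contains non-finite energies"
                )
            arrays.append(arr)
        object.__setattr__(self, "replicas", tuple(arrays))

    @classmethod
    def from_samples(
        cls, ligand_id: str, state: str, replicas: Iterable[Iterable[EnergySample]]
    ) -> "EnergySeries":
        """Build a series from per-replica sequences of :class:`EnergySample`."""
        arrays = []
        for rep in replicas:
            samples = sorted(rep, key=lambda s: s.frame_index)
            arrays.append(np.array([[s.u_vdw, s.u_ele] for s in samples], dtype=float))
        return cls(ligand_id=ligand_id, state=state, replicas=tuple(arrays))

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_frames(self) -> int:
        """Total frame count across replicas."""
        return int(sum(r.shape[0] for r in self.replicas))

    def component(self, component: str) -> list[np.ndarray]:
        """Per-replica 1-D arrays of one energy component."""
        col = _require_component(component)
        return [r[:, col] for r in self.replicas]


@dataclass(frozen=True)
class EnsembleEstimate:
    """An ensemble average ``<U>`` with its replica-based standard error.

    ``sem`` is ``None`` (undefined, never silently zero) when the series has
    a single replica; counts are ``None`` for literature-derived estimates
    whose provenance is a printed table rather than raw frames.
    """

    mean: float
    sem: float | None = None
    n_replicas: int | None = None
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValidationError("ensemble mean must be finite")
        if self.sem is not None:
            if not math.isfinite(self.sem) or self.sem < 0:
                raise ValidationError(f"sem must be finite and >= 0, got {self.sem}")
        if self.n_replicas == 1 and self.sem is not None:
            raise ValidationError("sem is undefined for a single replica; use sem=None")


@dataclass(frozen=True)
class DeltaEnergies:
    """Bound-minus-free interaction-energy differences (kcal/mol)."""

    d_vdw: float
    d_ele: float
    d_vdw_sem: float | None = None
    d_ele_sem: float | None = None

    def __post_init__(self) -> None:
        for label, v in (("d_vdw", self.d_vdw), ("d_ele", self.d_ele)):
            if not math.isfinite(v):
                raise ValidationError(f"{label} must be finite")
        for label, v in (("d_vdw_sem", self.d_vdw_sem), ("d_ele_sem", self.d_ele_sem)):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{label} must be finite and >= 0")


@dataclass(frozen=True)
class LIEParameters:
    """Coefficients of the LIE equation.

    ``beta`` is either a single scalar applied to every ligand or a mapping
    ``ligand_id -> beta`` for per-ligand assignment.
    """

    alpha: float
    beta: float | Mapping[str, float]
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        betas = self.beta.values() if isinstance(self.beta, Mapping) else (self.beta,)
        for b in betas:
            if not (0.0 < b <= 1.0):
                raise ValidationError(f"beta must be in (0, 1], got {b}")
        if not math.isfinite(self.gamma):
            raise ValidationError("gamma must be finite")

    def beta_for(self, ligand_id: str) -> float:
        """Resolve the polar coefficient for one ligand."""
        if isinstance(self.beta, Mapping):
            try:
                return self.beta[ligand_id]
            except KeyError:
                raise ValidationError(f"no beta assigned for ligand {ligand_id!r}") from None
        return self.beta


@dataclass(frozen=True)
class ThermoConfig:
    """Constants of the IC50 -> free-energy conversion.

    Defaults: T = 300 K, R in kcal/(mol K), assay constant c = 0 kcal/mol
    (c only shifts all experimental values rigidly and is absorbed by the
    fitted gamma).
    """

    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 300.0
    assay_constant_c: float = 0.0

    def __post_init__(self) -> None:
        if self.gas_constant <= 0:
            raise ValidationError("gas_constant must be > 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if not math.isfinite(self.assay_constant_c):
            raise ValidationError("assay_constant_c must be finite")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class BindingEstimate:
    """Predicted binding free energy for one ligand (kcal/mol)."""

    ligand_id: str
    dg_lie: float
    dg_lie_sem: float | None = None
    dg_exp: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg_lie):
            raise ValidationError(f"{self.ligand_id}: dg_lie must be finite")
        if self.dg_exp is not None and not math.isfinite(self.dg_exp):
            raise ValidationError(f"{self.ligand_id}: dg_exp must be finite")


def ensemble_average(series: EnergySeries, component: str) -> EnsembleEstimate:
    """Average one energy component over all frames of all replicas.

    The mean is the grand mean over pooled frames.  The standard error is
    the sample standard deviation of the per-replica means divided by
    ``sqrt(n_replicas)`` — the spread between independent replicas, which is
    robust to the strong frame-to-frame autocorrelation of MD energies.
    With a single replica the standard error is undefined and reported as
    ``None``.
    """
    values = series.component(component)
    pooled = np.concatenate(values)
    mean = float(pooled.mean())
    if len(values) >= 2:
        replica_means = np.array([v.mean() for v in values])
        sem = float(replica_means.std(ddof=1) / math.sqrt(len(values)))
    else:
        sem = None
    return EnsembleEstimate(mean=mean, sem=sem, n_replicas=len(values), n_frames=pooled.size)


def _sem_quadrature(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return math.hypot(a, b)


def delta_interaction(
    bound_vdw: EnsembleEstimate,
    bound_ele: EnsembleEstimate,
    free_vdw: EnsembleEstimate,
    free_ele: EnsembleEstimate,
) -> DeltaEnergies:
    """Bound-minus-free differences of the two ensemble averages.

    Standard errors combine in quadrature (bound and free ensembles are
    independent simulations); an undefined input sem yields an undefined
    difference sem.
    """
    return DeltaEnergies(
        d_vdw=bound_vdw.mean - free_vdw.mean,
        d_ele=bound_ele.mean - free_ele.mean,
        d_vdw_sem=_sem_quadrature(bound_vdw.sem, free_vdw.sem),
        d_ele_sem=_sem_quadrature(bound_ele.sem, free_ele.sem),
    )


def assign_beta(ligand, scheme: str = "fep_derived", fixed_value: float | None = None) -> float:
    """Polar scaling coefficient for one ligand.

    ``scheme="fep_derived"`` applies the standard chemistry-based table:
    any net charge -> 0.50; otherwise 0.43 / 0.37 / 0.33 for zero, one, or
    two-or-more hydroxyl groups.  ``scheme="fixed"`` returns ``fixed_value``
    for every ligand.
    """
    if scheme == "fixed":
        if fixed_value is None:
            raise ValidationError("scheme='fixed' requires fixed_value")
        return float(fixed_value)
    if scheme != "fep_derived":
        raise ValidationError(f"unknown beta scheme {scheme!r}")
    missing = [
        name
        for name in ("hydroxyl_count", "net_charge")
        if getattr(ligand, name, None) is None
    ]
    if missing:
        raise ValidationError(
            f"ligand {ligand.ligand_id!r}: fep_derived beta requires {', '.join(missing)}"
        )
    if ligand.net_charge != 0:
        return FEP_DERIVED_BETA["charged"]
    if ligand.hydroxyl_count >= 2:
        return FEP_DERIVED_BETA["2+"]
    return FEP_DERIVED_BETA[ligand.hydroxyl_count]


def lie_energy(
    delta: DeltaEnergies,
    params: LIEParameters,
    ligand_id: str = "",
    dg_exp: float | None = None,
) -> BindingEstimate:
    """Evaluate the LIE equation for one ligand.

    ``dG = alpha * d_vdw + beta * d_ele + gamma``; the uncertainty
    propagates the component standard errors in quadrature.
    """
    beta = params.beta_for(ligand_id)
    dg = params.alpha * delta.d_vdw + beta * delta.d_ele + params.gamma
    if delta.d_vdw_sem is None or delta.d_ele_sem is None:
        sem = None
    else:
        sem = math.hypot(params.alpha * delta.d_vdw_sem, beta * delta.d_ele_sem)
    return BindingEstimate(ligand_id=ligand_id, dg_lie=dg, dg_lie_sem=sem, dg_exp=dg_exp)


def dg_from_ic50(ic50_um: float, thermo: ThermoConfig = ThermoConfig()) -> float:
    """Experimental binding free energy from an IC50 in micromolar.

    ``dG = R*T*ln(IC50 [mol/L]) + c``.  The micromolar input is converted
    to molar before the logarithm, so 1 mol/L gives exactly ``c``.
    """
    if not (isinstance(ic50_um, (int, float)) and math.isfinite(ic50_um)) or ic50_um <= 0:
        raise ValidationError(f"IC50 must be a positive finite concentration, got {ic50_um!r}")
    return thermo.rt * math.log(ic50_um * 1e-6) + thermo.assay_constant_c


def ic50_from_dg(dg: float, thermo: ThermoConfig = ThermoConfig()) -> float:
    """Inverse of :func:`dg_from_ic50`: the IC50 (µM) implying ``dg``."""
    return math.exp((dg - thermo.assay_constant_c) / thermo.rt) * 1e6
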