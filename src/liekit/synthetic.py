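"""Synthetic inputs with known ground truth.

Every generator is a pure function of its parameters and an integer seed
(byte-identical reruns), and each emulates one input of the pipeline:

* :func:`gen_energy_series` — stationary AR(1) interaction-energy series,
  the minimal model of autocorrelated MD energy fluctuations, organized as
  independent replicas (default protocol: 5 replicas of 2000 frames,
  mirroring 5 x 2 ns production runs sampled every picosecond).
* :func:`gen_lie_dataset` — per-ligand datasets built from known LIE
  coefficients, with IC50 values constructed by inverting the free-energy
  conversion so the downstream pipeline can recover the truth exactly.
* :func:`gen_residue_breakdown` — per-residue splits of a total energy
  series with exact per-frame closure.
* :func:`gen_toy_trajectory` — coordinate frames with Gaussian atomic
  displacement and optional per-frame rigid motions.

Replica sub-seeds derive deterministically from ``(seed, replica_index)``
via numpy's SeedSequence, so replicas are independent but reproducible.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .datasets import LIEDataset, LIEEntry, LigandEntry
from .energies import (
    EnergySeries,
    EnsembleEstimate,
    LIEParameters,
    ThermoConfig,
    ic50_from_dg,
)
from .exceptions import ValidationError
from .geometry import AtomTable, CoordinateSet, Trajectory
from .residues import PerResidueSeries

__all__ = [
    "SimulationSpec",
    "SyntheticLIETruth",
    "ToyTrajectory",
    "gen_energy_series",
    "gen_lie_dataset",
    "gen_residue_breakdown",
    "gen_toy_trajectory",
    "random_rigid_motions",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and statistics of a synthetic energy series.

    ``ar1_phi`` is the lag-1 autocorrelation of the stationary AR(1)
    process; the marginal standard deviations ``sd_vdw``/``sd_ele`` are the
    stationary ones (innovations are scaled by ``sqrt(1 - phi^2)``).
    """

    n_replicas: int = 5
    n_frames: int = 2000
    mean_vdw: float = -50.0
    mean_ele: float = -85.0
    sd_vdw: float = 2.0
    sd_ele: float = 3.0
    ar1_phi: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValidationError("n_replicas must be >= 1")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not abs(self.ar1_phi) < 1:
            raise ValidationError(f"|ar1_phi| must be < 1 for stationarity, got {self.ar1_phi}")
        if self.sd_vdw < 0 or self.sd_ele < 0:
            raise ValidationError("standard deviations must be >= 0")


def _replica_rng(seed: int, replica: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(replica))))


def _ar1(rng: np.random.Generator, n: int, mu: float, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1): x_t = mu + phi (x_{t-1} - mu) + eps_t."""
    x0 = rng.normal(mu, sd)
    if n == 1:
        return np.array([x0])
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n - 1)
    tail, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * (x0 - mu)]))
    return np.concatenate(([x0], mu + tail))


def gen_energy_series(spec: SimulationSpec, ligand_id: str, state: str) -> EnergySeries:
    """Autocorrelated per-frame energies for one ligand and state."""
    replicas = []
    for r in range(spec.n_replicas):
        rng = _replica_rng(spec.seed, r)
        vdw = _ar1(rng, spec.n_frames, spec.mean_vdw, spec.sd_vdw, spec.ar1_phi)
        ele = _ar1(rng, spec.n_frames, spec.mean_ele, spec.sd_ele, spec.ar1_phi)
        replicas.append(np.column_stack([vdw, ele]))
    return EnergySeries(ligand_id=ligand_id, state=state, replicas=tuple(replicas))


@dataclass(frozen=True)
class SyntheticLIETruth:
    """Ground truth behind a generated dataset, for assertions."""

    params: LIEParameters
    thermo: ThermoConfig
    deltas: dict[str, tuple[float, float]]  # ligand -> (d_vdw, d_ele)
    dg_noiseless: dict[str, float]
    dg_observed: dict[str, float]  # noiseless + Gaussian noise; encoded in the IC50s


def gen_lie_dataset(
    n_ligands: int,
    true_params: LIEParameters,
    thermo: ThermoConfig = ThermoConfig(),
    delta_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (-35.0, -20.0),
        (-65.0, -40.0),
    ),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[LIEDataset, SyntheticLIETruth]:
    """Dataset drawn from known LIE coefficients.

    Interaction-energy differences are uniform in ``delta_ranges``; the
    observed free energy is the noiseless LIE value plus Gaussian noise of
    ``noise_sd``, and the IC50 is its exact exponential inverse, so
    converting back downstream reproduces the observed value to machine
    precision.
    """
    if n_ligands < 3:
        raise ValidationError("n_ligands must be >= 3")
    (v_lo, v_hi), (e_lo, e_hi) = delta_ranges
    if not (v_lo < v_hi and e_lo < e_hi):
        raise ValidationError("delta_ranges must be non-empty intervals")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
    entries = []
    deltas: dict[str, tuple[float, float]] = {}
    dg_true: dict[str, float] = {}
    dg_obs: dict[str, float] = {}
    for i in range(n_ligands):
        lig = f"L{i + 1:02d}"
        d_vdw = rng.uniform(v_lo, v_hi)
        d_ele = rng.uniform(e_lo, e_hi)
        beta = true_params.beta_for(lig)
        dg = true_params.alpha * d_vdw + beta * d_ele + true_params.gamma
        observed = dg + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        free_vdw = rng.uniform(-32.0, -26.0)
        free_ele = rng.uniform(-45.0, -25.0)
        entries.append(
            LIEEntry(
                ligand=LigandEntry(
                    ligand_id=lig,
                    ic50_um=ic50_from_dg(observed, thermo),
                    hydroxyl_count=1,
                    net_charge=0,
                ),
                free_vdw=EnsembleEstimate(mean=free_vdw),
                free_ele=EnsembleEstimate(mean=free_ele),
                bound_vdw=EnsembleEstimate(mean=free_vdw + d_vdw),
                bound_ele=EnsembleEstimate(mean=free_ele + d_ele),
            )
        )
        deltas[lig] = (d_vdw, d_ele)
        dg_true[lig] = dg
        dg_obs[lig] = observed
    truth = SyntheticLIETruth(
        params=true_params,
        thermo=thermo,
        deltas=deltas,
        dg_noiseless=dg_true,
        dg_observed=dg_obs,
    )
    return LIEDataset(tuple(entries)), truth


def gen_residue_breakdown(
    total: EnergySeries,
    residue_weights: Mapping[str, float],
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> PerResidueSeries:
    """Split a total energy series into per-residue shares with exact closure.

    Residue ``i`` receives ``w_i * total + jitter_i`` where the jitter is
    Gaussian noise re-centered to zero sum across residues, so every frame
    of the decomposition sums exactly to the total.
    """
    residues = tuple(residue_weights)
    weights = np.array([residue_weights[r] for r in residues], dtype=float)
    if (weights < 0).any():
        raise ValidationError("residue weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValidationError(f"residue weights must sum to 1, got {weights.sum()!r}")
    replicas = []
    for r, rep in enumerate(total.replicas):
        rng = _replica_rng(seed, r)
        # (frames, residues, 2): weighted share of the frame total
        shares = rep[:, None, :] * weights[None, :, None]
        if jitter_sd > 0 and len(residues) > 1:
            jitter = rng.normal(0.0, jitter_sd, size=shares.shape)
            jitter -= jitter.mean(axis=1, keepdims=True)
            shares = shares + jitter
        replicas.append(shares)
    return PerResidueSeries(
        ligand_id=total.ligand_id, residue_ids=residues, replicas=tuple(replicas)
    )


@dataclass(frozen=True)
class ToyTrajectory:
    """A generated trajectory plus the noise-free base coordinates."""

    trajectory: Trajectory
    base: CoordinateSet
    rigid_motions: tuple[tuple[np.ndarray, np.ndarray], ...] | None


def random_rigid_motions(n: int, seed: int = 0) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    """``n`` random proper rotations + translations, deterministic in seed."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 303)))
    rotations = Rotation.random(n, random_state=rng)
    return tuple(
        (rotations[i].as_matrix(), rng.uniform(-10.0, 10.0, size=3)) for i in range(n)
    )


def gen_toy_trajectory(
    n_atoms: int,
    n_frames: int,
    displacement_sd: float = 0.0,
    rigid_motions: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    seed: int = 0,
) -> ToyTrajectory:
    """Frames of a random base structure under Gaussian displacement.

    Each frame is ``R @ (base + noise) + t`` with an optional per-frame
    rigid motion ``(R, t)``; without motions the frames are just noisy
    copies of the base, so the expected RMSD to the base is about
    ``displacement_sd * sqrt(3)`` for many atoms.
    """
    if n_atoms < 3:
        raise ValidationError("n_atoms must be >= 3")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if rigid_motions is not None and len(rigid_motions) != n_frames:
        raise ValidationError("need one rigid motion per frame")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 202)))
    base = rng.uniform(-10.0, 10.0, size=(n_atoms, 3))
    frames = []
    for i in range(n_frames):
        xyz = base + rng.normal(0.0, displacement_sd, size=(n_atoms, 3))
        if rigid_motions is not None:
            rot, trans = rigid_motions[i]
            xyz = xyz @ np.asarray(rot).T + np.asarray(trans)
        frames.append(xyz)
    atoms = AtomTable(
        ids=np.arange(1, n_atoms + 1),
        names=np.array(["CA"] * n_atoms),
        residue_ids=np.array([f"ALA{i + 1}" for i in range(n_atoms)]),
        elements=np.array(["C"] * n_atoms),
        groups=np.array(["protein"] * n_atoms),
    )
    traj = Trajectory(atoms=atoms, coords=np.stack(frames))
    return ToyTrajectory(
        trajectory=traj,
        base=CoordinateSet(atoms=atoms, xyz=base),
        rigid_motions=None if rigid_motions is None else tuple(rigid_motions),
    )
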