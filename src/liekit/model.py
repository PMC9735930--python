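"""LIE model fitting and prediction.

The public surface follows the modelling-object convention: build an
:class:`LIEModel` from a :class:`~liekit.datasets.LIEDataset` (or a
DataFrame), call :meth:`LIEModel.fit` to obtain an :class:`LIEResults`
carrying the fitted offset gamma, per-ligand predictions, residuals and a
``summary()`` table.  The underlying operations (:func:`fit_gamma`,
:func:`predict_dataset`, :func:`resolve_betas`) are plain functions and can
be used directly.

Fitting: alpha and the per-ligand betas are taken from the literature-based
assignment scheme (they are properties of the ligand chemistry), so the
only free coefficient is the offset gamma.  Its least-squares optimum with
slope fixed at one is the mean residual

    gamma = mean_i( dG_EXP,i - alpha * d_vdw,i - beta_i * d_ele,i )

An optional slope+intercept variant regresses dG_EXP on the alpha/beta
combination; it is provided for diagnostics and is not the default.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LIEDataset
from .energies import (
    BindingEstimate,
    LIEParameters,
    ThermoConfig,
    assign_beta,
    dg_from_ic50,
    lie_energy,
)
from .exceptions import ValidationError

__all__ = ["GammaFit", "resolve_betas", "fit_gamma", "predict_dataset", "LIEModel", "LIEResults"]

#: Non-polar scaling coefficient from the LIE literature.
DEFAULT_ALPHA = 0.181
#: Global polar coefficient of the reproduction profile (neutral,
#: one-hydroxyl ligand class).
DEFAULT_BETA = 0.37
#: Offset calibrated against the inhibition-assay free energies of the
#: kojic-acid analog set; absorbs the assay constant and the metal-centre
#: model's systematic shift.
DEFAULT_GAMMA = 17.33


@dataclass(frozen=True)
class GammaFit:
    """Result of the offset fit.

    ``residuals`` maps ligand id to ``dG_EXP - prediction`` (kcal/mol);
    ``slope`` is 1.0 unless the slope+intercept variant was requested.
    """

    gamma: float
    residuals: dict[str, float]
    rmse: float
    slope: float = 1.0

    @property
    def n(self) -> int:
        return len(self.residuals)


def resolve_betas(
    dataset: LIEDataset,
    scheme: str = "fep_derived",
    fixed_value: float | None = None,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-ligand polar coefficients for a whole dataset.

    ``overrides`` wins over the scheme for the listed ligands.
    """
    overrides = dict(overrides or {})
    betas = {}
    for entry in dataset:
        lig = entry.ligand_id
        if lig in overrides:
            betas[lig] = float(overrides[lig])
        else:
            betas[lig] = assign_beta(entry.ligand, scheme=scheme, fixed_value=fixed_value)
    return betas


def _linear_cores(
    dataset: LIEDataset, alpha: float, beta_assignments: Mapping[str, float] | float
):
    """Per-ligand alpha*d_vdw + beta*d_ele (the gamma-free part of the model)."""
    cores = {}
    for entry in dataset:
        beta = (
            beta_assignments[entry.ligand_id]
            if isinstance(beta_assignments, Mapping)
            else float(beta_assignments)
        )
        d = entry.deltas()
        cores[entry.ligand_id] = alpha * d.d_vdw + beta * d.d_ele
    return cores


def fit_gamma(
    dataset: LIEDataset,
    alpha: float,
    beta_assignments: Mapping[str, float] | float,
    thermo: ThermoConfig = ThermoConfig(),
    fit_slope: bool = False,
) -> GammaFit:
    """Least-squares offset of the LIE equation against experimental dG.

    Only ligands with an IC50 participate.  With ``fit_slope=False`` the
    optimum of ``sum_i (dG_EXP,i - core_i - gamma)^2`` is the mean residual
    before offset; with ``fit_slope=True`` an ordinary least-squares line
    ``dG_EXP = slope * core + gamma`` is fitted instead.
    """
    cores = _linear_cores(dataset, alpha, beta_assignments)
    ids = [e.ligand_id for e in dataset if e.ligand.ic50_um is not None]
    if len(ids) < 2:
        raise ValidationError(
            f"gamma fit requires >=2 ligands with an IC50; found {len(ids)}"
        )
    x = np.array([cores[i] for i in ids])
    y = np.array([dg_from_ic50(dataset[i].ligand.ic50_um, thermo) for i in ids])
    if fit_slope:
        slope, gamma = np.polyfit(x, y, 1)
    else:
        slope, gamma = 1.0, float(np.mean(y - x))
    resid = y - (slope * x + gamma)
    return GammaFit(
        gamma=float(gamma),
        residuals=dict(zip(ids, resid.astype(float))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        slope=float(slope),
    )


def predict_dataset(
    dataset: LIEDataset,
    params: LIEParameters,
    thermo: ThermoConfig = ThermoConfig(),
) -> list[BindingEstimate]:
    """Apply the LIE equation to every ligand, in dataset order.

    ``dg_exp`` is attached whenever the ligand has an IC50.
    """
    estimates = []
    for entry in dataset:
        try:
            dg_exp = (
                None
                if entry.ligand.ic50_um is None
                else dg_from_ic50(entry.ligand.ic50_um, thermo)
            )
            estimates.append(
                lie_energy(entry.deltas(), params, ligand_id=entry.ligand_id, dg_exp=dg_exp)
            )
        except ValidationError as exc:
            raise ValidationError(f"ligand {entry.ligand_id!r}: {exc}") from exc
    return estimates


class LIEModel:
    """Linear interaction energy model over a per-ligand dataset.

    Parameters
    ----------
    dataset
        The per-ligand averages and experimental records.
    alpha
        Non-polar scaling coefficient.
    beta
        Either a scalar, a per-ligand mapping, or a scheme name
        (``"fep_derived"``); resolved to a per-ligand map at construction.
    thermo
        Constants of the IC50 conversion.
    """

    def __init__(
        self,
        dataset: LIEDataset,
        alpha: float = DEFAULT_ALPHA,
        beta: float | str | Mapping[str, float] = "fep_derived",
        thermo: ThermoConfig = ThermoConfig(),
    ):
        self.dataset = dataset
        self.alpha = float(alpha)
        self.thermo = thermo
        if isinstance(beta, str):
            self.betas = resolve_betas(dataset, scheme=beta)
        elif isinstance(beta, Mapping):
            self.betas = {e.ligand_id: float(beta[e.ligand_id]) for e in dataset}
        else:
            self.betas = {e.ligand_id: float(beta) for e in dataset}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LIEModel":
        return cls(LIEDataset.from_dataframe(df), **kwargs)

    def fit(self, gamma: float | None = None, fit_slope: bool = False) -> "LIEResults":
        """Fit gamma (or freeze it) and return the results object.

        ``gamma=None`` estimates the offset by least squares; a numeric
        ``gamma`` skips fitting and evaluates the model at that offset.
        """
        if gamma is None:
            gamma_fit = fit_gamma(
                self.dataset, self.alpha, self.betas, self.thermo, fit_slope=fit_slope
            )
            gamma_value = gamma_fit.gamma
        else:
            gamma_fit = None
            gamma_value = float(gamma)
        params = LIEParameters(alpha=self.alpha, beta=dict(self.betas), gamma=gamma_value)
        return LIEResults(model=self, params=params, gamma_fit=gamma_fit)


class LIEResults:
    """Fitted (or frozen) LIE model: predictions, residuals, diagnostics."""

    def __init__(self, model: LIEModel, params: LIEParameters, gamma_fit: GammaFit | None):
        self.model = model
        self.params = params
        self.gamma_fit = gamma_fit
        self.predictions = predict_dataset(model.dataset, params, model.thermo)

    @property
    def gamma(self) -> float:
        return self.params.gamma

    def to_dataframe(self) -> pd.DataFrame:
        """Per-ligand predictions: dg_lie, its sem, dg_exp, residual."""
        rows = []
        for est in self.predictions:
            rows.append(
                {
                    "ligand_id": est.ligand_id,
                    "dg_lie": est.dg_lie,
                    "dg_lie_sem": np.nan if est.dg_lie_sem is None else est.dg_lie_sem,
                    "dg_exp": np.nan if est.dg_exp is None else est.dg_exp,
                    "residual": (
                        np.nan if est.dg_exp is None else est.dg_exp - est.dg_lie
                    ),
                }
            )
        return pd.DataFrame(rows)

    def correlation(self):
        """Correlation report of predicted vs experimental dG."""
        from .stats import correlation_report

        calc = {e.ligand_id: e.dg_lie for e in self.predictions if e.dg_exp is not None}
        exp = {e.ligand_id: e.dg_exp for e in self.predictions if e.dg_exp is not None}
        return correlation_report(calc, exp)

    def summary(self) -> str:
        """Aligned plain-text summary of parameters, fit and predictions."""
        lines = ["LIE binding free-energy model", "=" * 45]
        lines.append(f"n ligands:            {len(self.model.dataset)}")
        lines.append(f"alpha:                {self.params.alpha:.3f}")
        betas = sorted(set(self.model.betas.values()))
        lines.append(f"beta (per ligand):    {', '.join(f'{b:.2f}' for b in betas)}")
        source = "fitted" if self.gamma_fit is not None else "fixed"
        lines.append(f"gamma ({source}):       {self.gamma:8.3f} kcal/mol")
        if self.gamma_fit is not None:
            lines.append(f"fit rmse:             {self.gamma_fit.rmse:8.3f} kcal/mol")
            if self.gamma_fit.slope != 1.0:
                lines.append(f"fit slope:            {self.gamma_fit.slope:8.3f}")
        try:
            rep = self.correlation()
            lines.append(
                f"pearson r (r^2):      {rep.pearson_r:6.3f} ({rep.r_squared:.3f})"
            )
            lines.append(f"mue / rmse:           {rep.mue:.3f} / {rep.rmse:.3f} kcal/mol")
        except ValidationError:
            pass
        lines.append("-" * 45)
        lines.append(f"{'ligand':<8}{'dG_LIE':>9}{'+/-':>7}{'dG_EXP':>9}{'resid':>8}")
        for est in self.predictions:
            sem = "  n/a" if est.dg_lie_sem is None else f"{est.dg_lie_sem:7.2f}"
            if est.dg_exp is None:
                exp_s, res_s = "      --", "      --"
            else:
                exp_s = f"{est.dg_exp:9.2f}"
                res_s = f"{est.dg_exp - est.dg_lie:8.2f}"
            lines.append(f"{est.ligand_id:<8}{est.dg_lie:9.2f}{sem:>7}{exp_s}{res_s}")
        return "\n".join(lines)
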