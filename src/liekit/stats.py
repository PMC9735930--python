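"""Correlation, error metrics and exhaustive leave-k-out outlier exclusion.

Predicted binding free energies are judged against IC50-derived experimental
values with the Pearson correlation, the mean unsigned error (MUE) and the
root-mean-square error (RMSE).  `exclude_outliers` enumerates every subset
obtained by removing up to ``max_k`` ligands, refits the LIE offset on each,
and returns the subset with the best correlation — the systematic version of
the common practice of dropping a few poorly-modelled ligands before
reporting a fit.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .datasets import LIEDataset
from .energies import LIEParameters, ThermoConfig
from .exceptions import ValidationError
from .model import fit_gamma, predict_dataset

__all__ = [
    "CorrelationReport",
    "ExclusionResult",
    "pearson_r",
    "correlation_report",
    "exclude_outliers",
    "plot_correlation",
]


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation.

    Raises on length mismatch, fewer than three points, or zero variance in
    either argument (never returns NaN).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need >=3 points for a correlation, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the inputs")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CorrelationReport:
    """Correlation and error metrics between calculated and reference values.

    ``slope``/``intercept`` are the ordinary least-squares line of the
    calculated values on the reference values; errors are calculated minus
    reference.
    """

    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    mue: float
    rmse: float

    def __str__(self) -> str:
        return (
            f"n={self.n}  r={self.pearson_r:.3f}  r^2={self.r_squared:.3f}  "
            f"slope={self.slope:.3f}  intercept={self.intercept:.3f}  "
            f"MUE={self.mue:.3f}  RMSE={self.rmse:.3f}"
        )


def correlation_report(
    calc: Mapping[str, float], exp: Mapping[str, float]
) -> CorrelationReport:
    """Metrics over the id intersection of two per-ligand maps (sorted order)."""
    ids = sorted(set(calc) & set(exp))
    if len(ids) < 3:
        raise ValidationError(f"need >=3 shared ligand ids, got {len(ids)}")
    x = np.array([exp[i] for i in ids])  # reference
    y = np.array([calc[i] for i in ids])  # calculated
    r = pearson_r(y, x)
    slope, intercept = np.polyfit(x, y, 1)
    err = y - x
    return CorrelationReport(
        n=len(ids),
        pearson_r=r,
        r_squared=r * r,
        slope=float(slope),
        intercept=float(intercept),
        mue=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
    )


@dataclass(frozen=True)
class ExclusionResult:
    """Best leave-k-out subset found by exhaustive enumeration."""

    excluded_ids: tuple[str, ...]
    report_before: CorrelationReport
    report_after: CorrelationReport
    refitted_gamma: float
    n_candidates: int


def _report_for(dataset, alpha, beta_assignments, thermo):
    fit = fit_gamma(dataset, alpha, beta_assignments, thermo)
    params = LIEParameters(
        alpha=alpha,
        beta=beta_assignments if isinstance(beta_assignments, Mapping) else float(beta_assignments),
        gamma=fit.gamma,
    )
    preds = predict_dataset(dataset, params, thermo)
    calc = {p.ligand_id: p.dg_lie for p in preds if p.dg_exp is not None}
    exp = {p.ligand_id: p.dg_exp for p in preds if p.dg_exp is not None}
    return correlation_report(calc, exp), fit.gamma


def exclude_outliers(
    dataset: LIEDataset,
    alpha: float,
    beta_assignments: Mapping[str, float] | float,
    thermo: ThermoConfig = ThermoConfig(),
    max_k: int = 3,
) -> ExclusionResult:
    """Exhaustive search for the leave-k-out subset maximizing Pearson r.

    For every subset obtained by removing exactly ``k`` ligands,
    ``k = 0..max_k``, gamma is refitted on the remaining ligands and the
    correlation between prediction and experiment recomputed.  The winner
    is the subset with the highest correlation; ties break toward fewer
    exclusions, then lexicographic id order.  ``max_k`` defaults to 3 as a
    combinatorial guard.
    """
    ids = [e.ligand_id for e in dataset if e.ligand.ic50_um is not None]
    if len(ids) < max_k + 3:
        raise ValidationError(
            f"dataset has {len(ids)} ligands with IC50; need >= max_k + 3 = {max_k + 3}"
        )
    report_before, _ = _report_for(dataset, alpha, beta_assignments, thermo)
    best = None  # (r, k, excluded tuple, report, gamma)
    n_candidates = 0
    for k in range(max_k + 1):
        for excluded in itertools.combinations(sorted(ids), k):
            n_candidates += 1
            sub = dataset.drop(excluded)
            report, gamma = _report_for(sub, alpha, beta_assignments, thermo)
            # strict > keeps the first (smallest k, lexicographically first) tie winner
            if best is None or report.pearson_r > best[0]:
                best = (report.pearson_r, k, excluded, report, gamma)
    _, _, excluded, report_after, gamma = best
    return ExclusionResult(
        excluded_ids=excluded,
        report_before=report_before,
        report_after=report_after,
        refitted_gamma=gamma,
        n_candidates=n_candidates,
    )


def plot_correlation(calc: Mapping[str, float], exp: Mapping[str, float], path: str) -> None:
    """Scatter of calculated vs experimental dG with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = sorted(set(calc) & set(exp))
    x = [exp[i] for i in ids]
    y = [calc[i] for i in ids]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, color="tab:blue")
    lo = min(min(x), min(y)) - 0.5
    hi = max(max(x), max(y)) + 0.5
    ax.plot([lo, hi], [lo, hi], "r--", lw=1)
    for i, xi, yi in zip(ids, x, y):
        ax.annotate(i, (xi, yi), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("experimental dG (kcal/mol)")
    ax.set_ylabel("calculated dG (kcal/mol)")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
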