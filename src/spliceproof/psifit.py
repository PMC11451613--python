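"""Fitting the proofreading PSI equation to binned PSI-vs-ddG tables.

RNA-seq yields, per alternative 3' splice-site pair, a percent-spliced-in
value and a binding free-energy difference from the sequence model.  Binned
medians of PSI against ddG trace a sigmoid whose shape identifies the
proofreading regime.  Two fits are provided:

* :class:`PsiCurveModel` — with ``Ks`` fixed from single-molecule
  measurements, profile the weighted least-squares objective over ``Kf``.
  ``Kf`` is one-sided identifiable: above some value the curve stops
  changing, so the result is a point estimate plus the lower edge of the
  flat region (all ``Kf`` with objective within 1 unit of the minimum).
* :class:`KsFoldChangeModel` — two conditions fit jointly with a common
  ``Kf`` (fixed) and per-condition ``Ks``; the ratio quantifies how a
  perturbation rescales the second checkpoint.

Binned tables need columns ``ddg``, ``psi`` (bin median), ``se``, ``n``.
Bin weights are ``1 / (se^2 + floor)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .kinetics import EnergyContext, ProofreadingParams, psi

__all__ = [
    "PsiCurveResults",
    "PsiCurveModel",
    "fit_psi_model",
    "KsFoldChangeResults",
    "KsFoldChangeModel",
    "fit_ks_fold_change",
]

_SE_FLOOR = 1e-4  # variance floor so zero-SE bins cannot dominate


def _check_binned(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("ddg", "psi"):
        if col not in table:
            raise ValueError(f"binned table must contain column {col!r}")
    tab = table.copy()
    if "se" not in tab:
        tab["se"] = 0.0
    if np.all(tab["ddg"] >= 0) or np.all(tab["ddg"] <= 0):
        raise ValueError("bins must span both signs of ddG for the fit to be identifiable")
    return tab


def _objective(table: pd.DataFrame, params: ProofreadingParams, ctx: EnergyContext) -> float:
    pred = np.asarray(psi(table["ddg"].to_numpy(), params, ctx))
    w = 1.0 / (table["se"].to_numpy() ** 2 + _SE_FLOOR)
    return float(np.sum(w * (table["psi"].to_numpy() - pred) ** 2))


@dataclass
class PsiCurveResults:
    kf: float
    ks: float
    kf_profile: pd.DataFrame  # columns: kf, objective
    kf_lower_bound: float
    kf_upper_bounded: bool
    objective: float

    def plot_profile(self, ax=None):
        """Objective profile over Kf with the flat-region threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.kf_profile["kf"], self.kf_profile["objective"])
        ax.axhline(self.objective + 1.0, linestyle="--", color="grey")
        ax.axvline(self.kf_lower_bound, linestyle=":", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("Kf")
        ax.set_ylabel("weighted SSE")
        return ax

    def summary(self) -> str:
        ub = "" if self.kf_upper_bounded else " (upper side unbounded: flat profile)"
        return (
            f"PSI-curve fit at Ks = {self.ks:.3g}: Kf = {self.kf:.3g}, "
            f"flat-region lower bound Kf >= {self.kf_lower_bound:.3g}{ub}, "
            f"objective = {self.objective:.4g}"
        )


class PsiCurveModel:
    """Profile the PSI equation over Kf with Ks held at its measured value."""

    def __init__(
        self,
        binned_table: pd.DataFrame,
        ks: float = 0.15,
        ctx: EnergyContext = EnergyContext(),
        kf_grid: Optional[np.ndarray] = None,
    ) -> None:
        self.table = _check_binned(binned_table)
        self.ks = ks
        self.ctx = ctx
        self.kf_grid = (
            np.logspace(-2, 4, 121) if kf_grid is None else np.asarray(kf_grid, dtype=float)
        )

    def fit(self) -> PsiCurveResults:
        objs = np.array(
            [
                _objective(self.table, ProofreadingParams(Kf=kf, Ks=self.ks), self.ctx)
                for kf in self.kf_grid
            ]
        )
        i_best = int(np.argmin(objs))
        flat = objs <= objs[i_best] + 1.0
        lower = float(self.kf_grid[np.flatnonzero(flat)[0]])
        upper_bounded = not bool(flat[-1])
        return PsiCurveResults(
            kf=float(self.kf_grid[i_best]),
            ks=self.ks,
            kf_profile=pd.DataFrame({"kf": self.kf_grid, "objective": objs}),
            kf_lower_bound=lower,
            kf_upper_bounded=upper_bounded,
            objective=float(objs[i_best]),
        )


def fit_psi_model(
    binned_table: pd.DataFrame, ks: float = 0.15, ctx: EnergyContext = EnergyContext()
) -> PsiCurveResults:
    """Functional wrapper around :class:`PsiCurveModel`."""
    return PsiCurveModel(binned_table, ks=ks, ctx=ctx).fit()


@dataclass
class KsFoldChangeResults:
    ks1: float
    ks2: float
    kf: float
    fold_change: float
    fold_change_ci: Tuple[float, float]
    objective: float

    def summary(self) -> str:
        return (
            f"Joint PSI fit (Kf = {self.kf:.3g} fixed): "
            f"Ks = {self.ks1:.3g} -> {self.ks2:.3g}, "
            f"fold change = {self.fold_change:.3g} "
            f"[{self.fold_change_ci[0]:.3g}, {self.fold_change_ci[1]:.3g}]"
        )


class KsFoldChangeModel:
    """Per-condition Ks from two binned PSI tables sharing a fixed Kf."""

    def __init__(
        self,
        table1: pd.DataFrame,
        table2: pd.DataFrame,
        kf: float = 10.0,
        ctx: EnergyContext = EnergyContext(),
    ) -> None:
        self.tables = (_check_binned(table1), _check_binned(table2))
        self.kf = kf
        self.ctx = ctx

    def _joint_objective(self, log_ks: np.ndarray) -> float:
        total = 0.0
        for tab, lk in zip(self.tables, log_ks):
            params = ProofreadingParams(Kf=self.kf, Ks=float(np.exp(lk)))
            total += _objective(tab, params, self.ctx)
        return total

    def _fit_once(self) -> Tuple[float, float, float]:
        best = None
        for ks0 in (0.05, 0.15, 0.5, 2.0):
            res = minimize(
                self._joint_objective,
                np.log([ks0, ks0]),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        ks1, ks2 = np.exp(best.x)
        return float(ks1), float(ks2), float(best.fun)

    def fit(self, n_bootstrap: int = 200, seed: int = 0) -> KsFoldChangeResults:
        ks1, ks2, obj = self._fit_once()
        rng = np.random.default_rng(seed)
        folds = []
        for _ in range(n_bootstrap):
            resampled = []
            for tab in self.tables:
                idx = rng.integers(0, len(tab), size=len(tab))
                boot = tab.iloc[idx].reset_index(drop=True)
                if np.all(boot["ddg"] >= 0) or np.all(boot["ddg"] <= 0):
                    break
                resampled.append(boot)
            if len(resampled) != 2:
                continue
            sub = KsFoldChangeModel.__new__(KsFoldChangeModel)
            sub.tables = tuple(resampled)
            sub.kf = self.kf
            sub.ctx = self.ctx
            b1, b2, _ = sub._fit_once()
            folds.append(b2 / b1)
        ci = (
            tuple(float(v) for v in np.percentile(folds, [2.5, 97.5]))
            if folds
            else (np.nan, np.nan)
        )
        return KsFoldChangeResults(
            ks1=ks1, ks2=ks2, kf=self.kf, fold_change=ks2 / ks1, fold_change_ci=ci, objective=obj
        )


def fit_ks_fold_change(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    kf: float = 10.0,
    n_bootstrap: int = 200,
    seed: int = 0,
    ctx: EnergyContext = EnergyContext(),
) -> KsFoldChangeResults:
    """Functional wrapper around :class:`KsFoldChangeModel`."""
    return KsFoldChangeModel(table1, table2, kf=kf, ctx=ctx).fit(
        n_bootstrap=n_bootstrap, seed=seed
    )
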