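"""Equilibrium titration fitting: the non-cooperative binding isotherm.

A PIFE titration reports relative fluorescence
``F(c) = 1 + (fmax - 1) * c / (c + KD)`` — a Hill function with the Hill
coefficient fixed at 1.  ``fmax`` is the saturating fluorescence
enhancement (about 1.5-fold for U2AF next to a Cy3 dye) and ``KD`` the
dissociation constant in the concentration units of the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["HillResults", "HillModel", "fit_hill", "hill_curve"]


def hill_curve(c, kd, fmax):
    return 1.0 + (fmax - 1.0) * c / (c + kd)


@dataclass
class HillResults:
    kd: float
    fmax: float
    kd_ci: Tuple[float, float]
    fmax_ci: Tuple[float, float]
    n_points: int
    saturation_warning: bool

    def summary(self) -> str:
        note = "  [warning: titration does not reach saturation]" if self.saturation_warning else ""
        return (
            f"Hill fit (n = 1): KD = {self.kd:.3g} "
            f"[{self.kd_ci[0]:.3g}, {self.kd_ci[1]:.3g}], "
            f"fmax = {self.fmax:.3g} [{self.fmax_ci[0]:.3g}, {self.fmax_ci[1]:.3g}]" + note
        )


class HillModel:
    """Least-squares fit of the non-cooperative isotherm to a titration table.

    The table needs columns ``concentration_nM`` and ``rel_fluorescence``
    (replicates are simply additional rows).  CIs come from residual
    bootstrap.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        self.conc = table["concentration_nM"].to_numpy(dtype=float)
        self.f = table["rel_fluorescence"].to_numpy(dtype=float)
        if len(set(self.conc)) < 5:
            raise ValueError("need at least 5 distinct concentrations spanning KD")

    def _fit_once(self, f: np.ndarray) -> Tuple[float, float]:
        p0 = (np.median(self.conc[self.conc > 0]), max(float(f.max()), 1.1))
        popt, _ = curve_fit(
            hill_curve, self.conc, f, p0=p0, bounds=([1e-9, 1.0], [np.inf, np.inf]), maxfev=20000
        )
        return float(popt[0]), float(popt[1])

    def fit(self, n_bootstrap: int = 500, seed: int = 0) -> HillResults:
        kd, fmax = self._fit_once(self.f)
        resid = self.f - hill_curve(self.conc, kd, fmax)
        rng = np.random.default_rng(seed)
        kds, fmaxes = [], []
        for _ in range(n_bootstrap):
            f_star = hill_curve(self.conc, kd, fmax) + rng.choice(resid, size=resid.size)
            try:
                k, fm = self._fit_once(f_star)
            except RuntimeError:
                continue
            kds.append(k)
            fmaxes.append(fm)
        if kds:
            kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
            fmax_ci = tuple(np.percentile(fmaxes, [2.5, 97.5]))
        else:
            kd_ci = fmax_ci = (np.nan, np.nan)
        saturation = self.conc.max() < 2 * kd
        if saturation:
            warnings.warn("highest concentration < 2*KD: KD weakly constrained")
        return HillResults(
            kd=kd,
            fmax=fmax,
            kd_ci=(float(kd_ci[0]), float(kd_ci[1])),
            fmax_ci=(float(fmax_ci[0]), float(fmax_ci[1])),
            n_points=self.conc.size,
            saturation_warning=bool(saturation),
        )


def fit_hill(table: pd.DataFrame, n_bootstrap: int = 500, seed: int = 0) -> HillResults:
    """Functional wrapper around :class:`HillModel`."""
    return HillModel(table).fit(n_bootstrap=n_bootstrap, seed=seed)
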