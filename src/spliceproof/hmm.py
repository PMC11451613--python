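"""Two-state hidden-Markov analysis of single-molecule binding traces.

Fluorescence traces from the smPIFE assay alternate between a low (free
RNA) and a high (protein-bound) emission level; a two-state HMM with
Gaussian emissions segments them, and the per-frame transition
probabilities convert to binding and dissociation rates via
``k = -ln(1 - p) / dt``.  Pooled expectation-maximisation across traces is
delegated to hmmlearn; dwell lists come from the posterior-decoded state
path with a minimum-dwell cutoff (single-frame states are dominated by
noise misassignment) and an optional complete-event rule (keep only bound
events flanked by two unbound events, the criterion used at fast frame
rates where photobleaching ends many tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .simulate import IntensityTrace

__all__ = ["HmmResults", "TwoStateHMM", "fit_two_state_hmm", "KonEstimate", "estimate_kon"]


@dataclass
class HmmResults:
    """Emission model, kinetics and decoded paths of a two-state HMM fit."""

    means: np.ndarray  # (low, high)
    sds: np.ndarray
    transmat: np.ndarray  # per-frame, rows sum to 1; state 0 = low
    dt: float
    loglike: float
    converged: bool
    state_paths: List[np.ndarray] = field(default_factory=list)
    bound_dwells: np.ndarray = field(default_factory=lambda: np.empty(0))
    unbound_dwells: np.ndarray = field(default_factory=lambda: np.empty(0))

    def _rates(self) -> Tuple[float, float]:
        """Exact rate inversion of the sampled two-state chain.

        For a continuous-time telegraph observed every dt, the frame
        transition matrix is exp(Q dt); inverting it exactly gives
        lambda = -ln(1 - p01 - p10) / dt and splits it by the branching
        fractions.  (The naive -ln(1-p)/dt underestimates each rate once
        the other transition is non-negligible within a frame.)
        """
        p01, p10 = self.transmat[0, 1], self.transmat[1, 0]
        s = min(p01 + p10, 1 - 1e-12)
        if s <= 0:
            return 0.0, 0.0
        lam = -np.log1p(-s) / self.dt
        return float(lam * p01 / s), float(lam * p10 / s)

    @property
    def k_on_conc(self) -> float:
        """Pseudo-first-order binding rate (s^-1) from the low->high transition."""
        return self._rates()[0]

    @property
    def k_off(self) -> float:
        """Dissociation rate (s^-1) from the high->low transition."""
        return self._rates()[1]

    @property
    def emission_contrast(self) -> float:
        return float(self.means[1] / self.means[0])

    def summary(self) -> str:
        return (
            "Two-state HMM fit\n"
            f"  emission means: low = {self.means[0]:.3f}, high = {self.means[1]:.3f} "
            f"(contrast {self.emission_contrast:.2f})\n"
            f"  k_on*[P] = {self.k_on_conc:.4g} /s, k_off = {self.k_off:.4g} /s\n"
            f"  log-likelihood = {self.loglike:.1f}, converged = {self.converged}"
        )


def _dwells_from_path(
    path: np.ndarray, dt: float, min_frames: int, complete_only: bool
) -> Tuple[list, list]:
    """Run-length encode a 0/1 path into bound and unbound dwell durations."""
    bound, unbound = [], []
    if path.size == 0:
        return bound, unbound
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [path.size]])
    n_runs = starts.size
    for i, (s, e) in enumerate(zip(starts, ends)):
        frames = e - s
        if frames < min_frames:
            continue
        interior = 0 < i < n_runs - 1
        if complete_only and not interior:
            continue
        (bound if path[s] == 1 else unbound).append(frames * dt)
    return bound, unbound


class TwoStateHMM:
    """Pooled Gaussian-emission two-state HMM over a set of intensity traces."""

    def __init__(
        self,
        traces: Sequence[IntensityTrace],
        min_dwell_frames: int = 2,
        complete_events_only: bool = False,
    ) -> None:
        if len(traces) == 0:
            raise ValueError("need at least one trace")
        if sum(t.time.size for t in traces) < 100:
            raise ValueError("need at least 100 frames in total")
        self.traces = list(traces)
        self.min_dwell_frames = min_dwell_frames
        self.complete_events_only = complete_events_only
        self.dt = float(np.median([t.dt for t in traces]))

    def fit(self, max_iter: int = 200, tol: float = 1e-4, seed: int = 0) -> HmmResults:
        x = np.concatenate([t.intensity for t in self.traces]).reshape(-1, 1)
        lengths = [t.intensity.size for t in self.traces]
        if np.std(x) == 0:
            raise ValueError("degenerate single-level data: zero variance")
        model = GaussianHMM(
            n_components=2,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            random_state=seed,
            init_params="st",  # keep our quantile-based means/vars
        )
        lo, hi = np.quantile(x, [0.25, 0.75])
        model.means_ = np.array([[lo], [hi]])
        spread = max(float(np.std(x)) / 2, 1e-6)
        model.covars_ = np.full((2, 1), spread**2)
        model.fit(x, lengths)
        order = np.argsort(model.means_.ravel())
        means = model.means_.ravel()[order]
        sds = np.sqrt(model.covars_.ravel()[order])
        transmat = model.transmat_[np.ix_(order, order)]
        # well-separated states sit several noise widths apart; overlapping
        # components mean the mixture is splitting a single emission level
        if abs(means[1] - means[0]) < 2.0 * max(float(sds.mean()), 1e-12):
            import warnings

            warnings.warn("emission levels collapsed: data may contain a single state")
        paths = []
        bound_all, unbound_all = [], []
        # decode with the state order fixed (low = 0, high = 1)
        model.means_ = means.reshape(-1, 1)
        model.covars_ = (sds**2).reshape(-1, 1)
        model.transmat_ = transmat
        model.startprob_ = model.startprob_[order]
        for t in self.traces:
            path = model.predict(t.intensity.reshape(-1, 1))
            paths.append(path)
            b, u = _dwells_from_path(
                path, self.dt, self.min_dwell_frames, self.complete_events_only
            )
            bound_all.extend(b)
            unbound_all.extend(u)
        return HmmResults(
            means=means,
            sds=sds,
            transmat=transmat,
            dt=self.dt,
            loglike=float(model.score(x, lengths)),
            converged=bool(model.monitor_.converged),
            state_paths=paths,
            bound_dwells=np.asarray(bound_all),
            unbound_dwells=np.asarray(unbound_all),
        )


def fit_two_state_hmm(
    traces: Sequence[IntensityTrace],
    max_iter: int = 200,
    tol: float = 1e-4,
    min_dwell_frames: int = 2,
    complete_events_only: bool = False,
    seed: int = 0,
) -> HmmResults:
    """Functional wrapper around :class:`TwoStateHMM`."""
    return TwoStateHMM(traces, min_dwell_frames, complete_events_only).fit(
        max_iter=max_iter, tol=tol, seed=seed
    )


@dataclass
class KonEstimate:
    """Association rate constant from the concentration dependence of binding."""

    slope: float  # nM^-1 s^-1
    slope_se: float
    intercept: float
    concentrations: np.ndarray
    rates: np.ndarray

    def summary(self) -> str:
        return (
            f"kon = {self.slope:.4g} +/- {self.slope_se:.2g} nM^-1 s^-1 "
            f"(intercept {self.intercept:.3g} s^-1, "
            f"{len(self.concentrations)} concentrations)"
        )


def estimate_kon(
    results: Sequence[HmmResults],
    concentrations: Sequence[float],
    rate_ses: Optional[Sequence[float]] = None,
    through_origin: bool = True,
) -> KonEstimate:
    """Association rate constant by regression of binding rate on concentration.

    The observed low->high rate is pseudo-first-order, ``kon * [protein]``,
    so its slope against concentration is ``kon``.  Weighted least squares
    with optional per-point SEs; through the origin by default.
    """
    conc = np.asarray(concentrations, dtype=float)
    if len(set(conc)) < len(conc):
        raise ValueError("concentrations must be distinct")
    rates = np.array([r.k_on_conc for r in results])
    if conc.size != rates.size:
        raise ValueError("one HMM result per concentration required")
    w = np.ones_like(rates) if rate_ses is None else 1.0 / np.asarray(rate_ses) ** 2
    if through_origin:
        slope = float(np.sum(w * conc * rates) / np.sum(w * conc**2))
        resid = rates - slope * conc
        dof = max(conc.size - 1, 1)
        var = np.sum(w * resid**2) / dof / np.sum(w * conc**2)
        return KonEstimate(slope, float(np.sqrt(var)), 0.0, conc, rates)
    x = np.column_stack([conc, np.ones_like(conc)])
    wx = x * w[:, None]
    beta, *_ = np.linalg.lstsq(wx.T @ x, wx.T @ rates, rcond=None)
    resid = rates - x @ beta
    dof = max(conc.size - 2, 1)
    cov = np.linalg.inv(wx.T @ x) * (np.sum(w * resid**2) / dof)
    return KonEstimate(float(beta[0]), float(np.sqrt(cov[0, 0])), float(beta[1]), conc, rates)
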