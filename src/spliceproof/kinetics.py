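"""Closed-form kinetics of early spliceosome assembly at the 3' splice site.

The model tracks a single U2AF heterodimer through three sequential bound
states, ``E -> Intermediate -> A``, with irreversible forward steps
(``k_fwd1``, ``k_fwd2``) competing against dissociation at every state
(``k_off_E``, ``k_off_int``, ``k_off_A``).  Repeating the
forward-vs-dissociation race at two checkpoints is the kinetic-proofreading
motif: discrimination between competing splice sites can exceed the
equilibrium binding-affinity difference.

Two closed forms anchor everything else in the package:

* :func:`survival_bound` — the probability that a molecule observed entering
  the Intermediate state is still bound at time ``t`` (a two-phase
  hypoexponential mixture), the model fitted to slow single-molecule
  tracking dwell times.
* :func:`psi` — the percent-spliced-in of one of two competing 3' splice
  sites as a function of the binding free-energy difference and the
  dimensionless checkpoint ratios ``Kf = k_fwd1/k_off_E`` and
  ``Ks = k_fwd2/k_off_int``.

All free energies are handled in units of RT by default; an
:class:`EnergyContext` converts to physical units when needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KineticScheme",
    "ProofreadingParams",
    "EnergyContext",
    "SitePair",
    "PsaDistribution",
    "survival_bound",
    "bound_dwell_pdf",
    "mean_bound_time",
    "psi",
    "psi_thermodynamic",
    "psi_full_proofreading",
    "delta_psi",
    "predicted_splicing_accuracy",
    "fraction_bound_in_A",
]

# relative tolerance below which lambda and k_off_A are treated as equal and
# the removable singularity of the survival curve is evaluated by its limit
_SINGULARITY_RTOL = 1e-9


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants (s^-1) of the U2AF bound-state scheme.

    ``k_on_conc`` is the pseudo-first-order association rate
    (kon * [U2AF]); it only enters steady-state occupancy calculations,
    never the bound-state survival curve.
    """

    k_off_E: float = 0.0
    k_fwd1: float = 0.0
    k_off_int: float = 0.0
    k_fwd2: float = 0.0
    k_off_A: float = 0.0
    k_on_conc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_off_E", "k_fwd1", "k_off_int", "k_fwd2", "k_off_A", "k_on_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.k_off_E == self.k_off_int == self.k_off_A == 0:
            raise ValueError("at least one dissociation rate must be positive")

    @property
    def lam(self) -> float:
        """Total exit rate from the Intermediate state."""
        return self.k_fwd2 + self.k_off_int

    @property
    def Kf(self) -> float:
        if self.k_off_E == 0:
            return math.inf if self.k_fwd1 > 0 else 0.0
        return self.k_fwd1 / self.k_off_E

    @property
    def Ks(self) -> float:
        if self.k_off_int == 0:
            return math.inf if self.k_fwd2 > 0 else 0.0
        return self.k_fwd2 / self.k_off_int

    def to_dict(self) -> dict:
        return {
            "k_off_E": self.k_off_E,
            "k_fwd1": self.k_fwd1,
            "k_off_int": self.k_off_int,
            "k_fwd2": self.k_fwd2,
            "k_off_A": self.k_off_A,
            "k_on_conc": self.k_on_conc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        known = {"k_off_E", "k_fwd1", "k_off_int", "k_fwd2", "k_off_A", "k_on_conc"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown rate keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "KineticScheme":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ProofreadingParams:
    """Dimensionless checkpoint ratios Kf = k_fwd1/k_off_E, Ks = k_fwd2/k_off_int."""

    Kf: float
    Ks: float

    def __post_init__(self) -> None:
        if self.Kf < 0 or self.Ks < 0:
            raise ValueError("Kf and Ks must be >= 0")

    @classmethod
    def from_scheme(cls, scheme: KineticScheme) -> "ProofreadingParams":
        return cls(Kf=scheme.Kf, Ks=scheme.Ks)

    def to_dict(self) -> dict:
        return {"Kf": self.Kf, "Ks": self.Ks}


@dataclass(frozen=True)
class EnergyContext:
    """Unit system for binding free energies.

    With the default ``RT = 1`` all ddG values are in units of RT.  For
    kcal/mol at 310.15 K use ``EnergyContext(RT=0.61633)``.
    """

    RT: float = 1.0

    def __post_init__(self) -> None:
        if not (self.RT > 0):
            raise ValueError("RT must be > 0")


@dataclass(frozen=True)
class SitePair:
    """A pair of competing 3' splice sites.

    ``ddG`` is the free-energy difference of U2AF binding to the S3 site
    relative to S2, with the sign convention
    ``-ddG = RT * ln(k_off_S3 / k_off_S2)``: positive ddG means U2AF binds
    S3 more tightly (dissociates more slowly).
    """

    ddG: float
    label_s2: str = "S2"
    label_s3: str = "S3"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddG):
            raise ValueError("ddG must be finite")

    def swapped(self) -> "SitePair":
        return SitePair(ddG=-self.ddG, label_s2=self.label_s3, label_s3=self.label_s2)


def _as_time_grid(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("t must be finite and >= 0")
    return t


def survival_bound(t, scheme: KineticScheme) -> np.ndarray:
    """Survival probability of the bound state entered at the Intermediate.

    S(t) = exp(-lam t) - [k_fwd2/(lam - k_off_A)] * (exp(-lam t) - exp(-k_off_A t))

    with ``lam = k_fwd2 + k_off_int``.  When ``lam`` and ``k_off_A`` coincide
    the removable singularity is evaluated as
    ``S(t) = (1 + k_fwd2 t) exp(-lam t)``.

    Only ``k_fwd2``, ``k_off_int`` and ``k_off_A`` enter; the observation
    starts after the molecule has already passed the E-complex checkpoint.
    """
    t = _as_time_grid(t)
    lam = scheme.lam
    a = scheme.k_off_A
    if lam == 0 and a == 0:
        raise ValueError("degenerate scheme: k_fwd2, k_off_int and k_off_A all zero")
    if abs(lam - a) < _SINGULARITY_RTOL * max(lam, a):
        return (1.0 + scheme.k_fwd2 * t) * np.exp(-lam * t)
    c = scheme.k_fwd2 / (lam - a)
    return (1.0 - c) * np.exp(-lam * t) + c * np.exp(-a * t)


def bound_dwell_pdf(t, scheme: KineticScheme) -> np.ndarray:
    """Density -dS/dt of the bound dwell time; companion of :func:`survival_bound`."""
    t = _as_time_grid(t)
    lam = scheme.lam
    a = scheme.k_off_A
    if lam == 0 and a == 0:
        raise ValueError("degenerate scheme: k_fwd2, k_off_int and k_off_A all zero")
    if abs(lam - a) < _SINGULARITY_RTOL * max(lam, a):
        return (scheme.k_off_int + lam * scheme.k_fwd2 * t) * np.exp(-lam * t)
    c = scheme.k_fwd2 / (lam - a)
    return (1.0 - c) * lam * np.exp(-lam * t) + c * a * np.exp(-a * t)


def mean_bound_time(scheme: KineticScheme) -> float:
    """Mean total bound time starting from the Intermediate state.

    1/lam + (k_fwd2/lam) / k_off_A, i.e. the Intermediate lifetime plus the
    A-complex lifetime weighted by the probability of ever reaching A.
    """
    lam = scheme.lam
    if lam <= 0:
        raise ValueError("lam = k_fwd2 + k_off_int must be > 0")
    if scheme.k_fwd2 > 0 and scheme.k_off_A == 0:
        raise ValueError("infinite mean: k_off_A = 0 while k_fwd2 > 0")
    mean = 1.0 / lam
    if scheme.k_fwd2 > 0:
        mean += (scheme.k_fwd2 / lam) / scheme.k_off_A
    return mean


def _r_factor(ddG, ctx: EnergyContext) -> np.ndarray:
    ddG = np.asarray(ddG, dtype=float)
    if not np.all(np.isfinite(ddG)):
        raise ValueError("ddG must be finite")
    return np.exp(-ddG / ctx.RT)


def psi(ddG, params: ProofreadingParams, ctx: EnergyContext = EnergyContext()) -> np.ndarray:
    """Percent spliced in of the S3 site under two-checkpoint proofreading.

    With ``r = exp(-ddG/RT)`` (both S3 dissociation rates carry the factor
    ``r`` relative to S2):

        PSI = (Kf+1)(Ks+1) / [2 Kf Ks + (Kf+Ks)(1+r) + 1 + r^2]

    The complement satisfies ``1 - PSI = (Kf+r)(Ks+r) / denominator``.
    Association is assumed sequence-independent, so the two sites are bound
    with equal probability per attempt and all discrimination comes from
    dissociation.
    """
    r = _r_factor(ddG, ctx)
    kf, ks = params.Kf, params.Ks
    denom = 2.0 * kf * ks + (kf + ks) * (1.0 + r) + 1.0 + r * r
    out = (kf + 1.0) * (ks + 1.0) / denom
    return out if out.ndim else float(out)


def psi_thermodynamic(ddG, ctx: EnergyContext = EnergyContext()) -> np.ndarray:
    """Equilibrium expectation: site usage set by Boltzmann occupancy alone."""
    ddG = np.asarray(ddG, dtype=float)
    out = 1.0 / (1.0 + np.exp(-ddG / ctx.RT))
    return out if out.ndim else float(out)


def psi_full_proofreading(ddG, ctx: EnergyContext = EnergyContext()) -> np.ndarray:
    """Kf, Ks -> 0 limit: the affinity difference is read at both checkpoints,
    doubling the exponent of the logistic (squared discrimination)."""
    ddG = np.asarray(ddG, dtype=float)
    out = 1.0 / (1.0 + np.exp(-2.0 * ddG / ctx.RT))
    return out if out.ndim else float(out)


def delta_psi(
    ddG,
    params: ProofreadingParams,
    ks_scale: float,
    ctx: EnergyContext = EnergyContext(),
) -> np.ndarray:
    """PSI change when Ks is rescaled (e.g. a knockdown slowing dissociation).

    Returns ``psi(ddG, Kf, Ks*ks_scale) - psi(ddG, Kf, Ks)``.
    """
    if not (ks_scale > 0):
        raise ValueError("ks_scale must be > 0")
    scaled = ProofreadingParams(Kf=params.Kf, Ks=params.Ks * ks_scale)
    return np.asarray(psi(ddG, scaled, ctx)) - np.asarray(psi(ddG, params, ctx))


@dataclass
class PsaDistribution:
    """Predicted splicing accuracy over a set of annotated-site/decoy pairs."""

    values: np.ndarray
    pairs: list = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def fraction_above_090(self) -> float:
        return float(np.mean(self.values > 0.9))

    def summary(self) -> str:
        return (
            f"PSA over {self.values.size} site pairs: "
            f"median = {self.median:.3f}, fraction > 0.9 = {self.fraction_above_090:.3f}"
        )


def predicted_splicing_accuracy(
    pairs: Sequence[SitePair],
    params: ProofreadingParams,
    ctx: EnergyContext = EnergyContext(),
) -> PsaDistribution:
    """PSI with the annotated 3' splice site in the S3 role, per pair.

    Measures how often spliceosome assembly completes at the annotated site
    rather than a nearby downstream decoy, given the free-energy gap of each
    pair and the proofreading regime.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one site pair")
    ddg = np.array([p.ddG for p in pairs], dtype=float)
    vals = np.asarray(psi(ddg, params, ctx))
    return PsaDistribution(values=vals, pairs=list(pairs))


def fraction_bound_in_A(scheme: KineticScheme) -> float:
    """Stationary fraction of *bound* U2AF molecules that sit in the A complex.

    Solves the four-state chain U <-> E -> Int -> A (A recycles to U at
    ``k_off_A``) for its stationary distribution and returns
    ``pi_A / (pi_E + pi_Int + pi_A)``.
    """
    if not (scheme.k_on_conc > 0):
        raise ValueError("k_on_conc must be > 0 for occupancy calculations")
    # generator matrix over states [U, E, I, A]
    kon, koe, kf1 = scheme.k_on_conc, scheme.k_off_E, scheme.k_fwd1
    koi, kf2, koa = scheme.k_off_int, scheme.k_fwd2, scheme.k_off_A
    if kf1 > 0 and kf2 > 0 and koa == 0:
        raise ValueError("A complex is absorbing (k_off_A = 0): no stationary occupancy")
    q = np.array(
        [
            [-kon, kon, 0.0, 0.0],
            [koe, -(koe + kf1), kf1, 0.0],
            [koi, 0.0, -(koi + kf2), kf2],
            [koa, 0.0, 0.0, -koa],
        ]
    )
    # restrict to states reachable from U; unreachable states carry no mass
    # (and, with zero exit rates, would make the linear system degenerate)
    reachable = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(4):
            if j != i and q[i, j] > 0 and j not in reachable:
                reachable.add(j)
                frontier.append(j)
    idx = sorted(reachable)
    qr = q[np.ix_(idx, idx)]
    # stationary distribution: pi Q = 0 with normalisation replacing one row
    a = np.vstack([qr.T[:-1], np.ones(len(idx))])
    b = np.zeros(len(idx))
    b[-1] = 1.0
    try:
        pi_r = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("no valid stationary distribution (degenerate scheme)") from exc
    if np.any(pi_r < -1e-9) or not np.all(np.isfinite(pi_r)):
        raise ValueError("no valid stationary distribution (degenerate scheme)")
    pi = np.zeros(4)
    pi[idx] = np.clip(pi_r, 0.0, None)
    bound = pi[1] + pi[2] + pi[3]
    if bound == 0:
        return 0.0
    return float(pi[3] / bound)
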