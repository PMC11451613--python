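"""Synthetic-data generators emulating the study's measurement modalities.

Every generator is deterministic given its seed, records the generating
("truth") parameters in its output, and reproduces the statistical structure
the downstream fits assume: exponential state dwell times from the kinetic
scheme, frame discretisation, photobleaching as an independent exponential
censoring process, a 1.5-fold protein-induced fluorescence enhancement
(PIFE) emission contrast, and binomial/beta-binomial noise on PSI tables.

Acquisition presets mirror the imaging modalities: fast single-molecule
tracking at 100 Hz, slow tracking at 1 frame / 3 s over 20 min, smPIFE at
1 Hz over 500 frames, and orbital tracking at 4 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import EnergyModel, score_sequence
from .kinetics import EnergyContext, KineticScheme, ProofreadingParams, psi

__all__ = [
    "AcquisitionSettings",
    "DwellDataset",
    "IntensityTrace",
    "FAST_SMT",
    "SLOW_SMT",
    "SMPIFE",
    "ORBITAL",
    "simulate_dwell_times",
    "simulate_pife_traces",
    "simulate_titration",
    "simulate_site_competition",
    "simulate_psi_dataset",
    "bin_psi_table",
    "simulate_rbns_reads",
    "simulate_transcription_splicing_traces",
    "simulate_metagene",
]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Imaging parameters shared by the trace and dwell generators."""

    frame_interval: float  # s per frame
    n_frames: int
    photobleach_rate: float = 0.0  # s^-1, independent exponential loss
    emission_low: float = 1.0
    emission_high: float = 1.5  # PIFE contrast: ~1.5-fold over the low state
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be > 0")
        if not (self.emission_high > self.emission_low):
            raise ValueError("emission_high must exceed emission_low")

    @property
    def duration(self) -> float:
        return self.frame_interval * self.n_frames

    def to_dict(self) -> dict:
        return {
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "photobleach_rate": self.photobleach_rate,
            "emission_low": self.emission_low,
            "emission_high": self.emission_high,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


FAST_SMT = AcquisitionSettings(frame_interval=0.01, n_frames=1000, seed=0)
SLOW_SMT = AcquisitionSettings(frame_interval=3.0, n_frames=400, seed=0)
SMPIFE = AcquisitionSettings(frame_interval=1.0, n_frames=500, seed=0)
ORBITAL = AcquisitionSettings(frame_interval=0.25, n_frames=4800, seed=0)


@dataclass
class DwellDataset:
    """Censoring-aware dwell-time observations for one experimental condition."""

    condition: str
    durations: np.ndarray  # s, frame-discretised
    censored: np.ndarray  # True if the event outlived observation/photobleach
    acquisition: AcquisitionSettings
    truth: Optional[KineticScheme] = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")

    @property
    def n(self) -> int:
        return self.durations.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "duration_s": self.durations,
                "censored": self.censored.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "condition": self.condition,
            "acquisition": self.acquisition.to_dict(),
            "truth": self.truth.to_dict() if self.truth is not None else None,
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass
class IntensityTrace:
    """Time-stamped single- or dual-channel fluorescence series."""

    trace_id: str
    time: np.ndarray
    intensity: np.ndarray
    intensity2: Optional[np.ndarray] = None
    true_state: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.intensity2 is not None:
            self.intensity2 = np.asarray(self.intensity2, dtype=float)
            if self.intensity2.shape != self.time.shape:
                raise ValueError("ragged channels: intensity2 length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_dwell_times(
    scheme: KineticScheme,
    n: int,
    acq: AcquisitionSettings,
    condition: str = "condition",
    start_state: str = "intermediate",
) -> DwellDataset:
    """Frame-discretised bound dwell times from the kinetic scheme.

    Each event enters the Intermediate state (slow-SMT regime) or the E
    complex (``start_state='E'``) and accumulates bound time through
    exponential races until dissociation.  Observation ends at the video
    limit or an independent exponential photobleach, whichever is first;
    either records the event as censored.  Events shorter than one frame
    are unobserved and dropped.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if start_state not in {"intermediate", "E"}:
        raise ValueError("start_state must be 'intermediate' or 'E'")
    rng = _rng(acq.seed)
    lam = scheme.lam
    if lam <= 0:
        raise ValueError("Intermediate exit rate must be > 0")
    total = np.zeros(n)
    if start_state == "E":
        exit_e = scheme.k_off_E + scheme.k_fwd1
        if exit_e <= 0:
            raise ValueError("E-state exit rate must be > 0")
        t_e = rng.exponential(1.0 / exit_e, size=n)
        to_int = rng.random(n) < scheme.k_fwd1 / exit_e
        total += t_e
        alive = to_int
    else:
        alive = np.ones(n, dtype=bool)
    t_int = rng.exponential(1.0 / lam, size=n)
    to_a = rng.random(n) < (scheme.k_fwd2 / lam if lam > 0 else 0.0)
    total[alive] += t_int[alive]
    reach_a = alive & to_a
    if scheme.k_fwd2 > 0:
        if scheme.k_off_A <= 0:
            raise ValueError("k_off_A must be > 0 when k_fwd2 > 0")
        t_a = rng.exponential(1.0 / scheme.k_off_A, size=n)
        total[reach_a] += t_a[reach_a]
    # observation limits: video end and photobleaching
    limit = np.full(n, acq.duration)
    if acq.photobleach_rate > 0:
        bleach = rng.exponential(1.0 / acq.photobleach_rate, size=n)
        limit = np.minimum(limit, bleach)
    observed = np.minimum(total, limit)
    censored = limit < total
    frames = np.floor(observed / acq.frame_interval).astype(int)
    keep = frames >= 1
    return DwellDataset(
        condition=condition,
        durations=frames[keep] * acq.frame_interval,
        censored=censored[keep],
        acquisition=acq,
        truth=scheme,
    )


def _telegraph_path(rng, rate_on: float, rate_off: float, times: np.ndarray) -> np.ndarray:
    """Exact two-state continuous-time telegraph sampled at ``times``.

    State 1 = bound; leaves at ``rate_off``.  State 0 = unbound; leaves at
    ``rate_on``.  Initial state drawn from the stationary distribution.
    """
    t_end = times[-1]
    p_on = rate_on / (rate_on + rate_off) if (rate_on + rate_off) > 0 else 0.0
    state = int(rng.random() < p_on)
    jumps = [0.0]
    states = [state]
    t = 0.0
    while t < t_end:
        rate = rate_off if state else rate_on
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        state = 1 - state
        jumps.append(t)
        states.append(state)
    idx = np.searchsorted(np.asarray(jumps), times, side="right") - 1
    return np.asarray(states)[idx]


def simulate_pife_traces(
    k_on_conc: float,
    k_off: float,
    acq: AcquisitionSettings,
    n_traces: int,
    condition: str = "pife",
) -> List[IntensityTrace]:
    """Two-state telegraph binding traces with Gaussian PIFE emissions.

    The high state (bound) emits around ``emission_high``, the low state
    around ``emission_low`` (default contrast 1.5-fold).  An optional Cy3
    photobleach (``acq.photobleach_rate``) truncates the trace.  The true
    state path is retained for parameter-recovery tests.
    """
    rng = _rng(acq.seed)
    times = (np.arange(acq.n_frames) + 1) * acq.frame_interval
    out = []
    for i in range(n_traces):
        path = _telegraph_path(rng, k_on_conc, k_off, times)
        emis = np.where(path == 1, acq.emission_high, acq.emission_low)
        if acq.noise_sd > 0:
            emis = emis + rng.normal(0.0, acq.noise_sd, size=emis.shape)
        if acq.photobleach_rate > 0:
            t_bleach = rng.exponential(1.0 / acq.photobleach_rate)
            keep = times <= t_bleach
            if keep.sum() < 2:
                continue
            times_i, emis, path = times[keep], emis[keep], path[keep]
        else:
            times_i = times
        out.append(
            IntensityTrace(
                trace_id=f"{condition}_{i:04d}",
                time=times_i,
                intensity=emis,
                true_state=path,
            )
        )
    return out


def simulate_titration(
    kd: float,
    fmax: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-fluorescence titration following a non-cooperative binding
    isotherm: F(c) = 1 + (fmax - 1) c / (c + KD) + Gaussian noise."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    rng = _rng(seed)
    rows = []
    for rep in range(replicates):
        for c in concentrations:
            f = 1.0 + (fmax - 1.0) * c / (c + kd)
            if noise_sd > 0:
                f += rng.normal(0.0, noise_sd)
            rows.append({"concentration_nM": c, "replicate": rep, "rel_fluorescence": f})
    return pd.DataFrame(rows)


def simulate_site_competition(
    params: ProofreadingParams,
    ddG: float,
    n_trials: int = 100_000,
    seed: int = 0,
    ctx: EnergyContext = EnergyContext(),
    max_rounds: int = 1_000_000,
) -> tuple:
    """Monte-Carlo splitting probability of the two-site competition chain.

    Each trial: U2AF binds S2 or S3 with probability 1/2 (association is
    sequence-independent); at the E complex the forward step (rate propto Kf)
    races dissociation (rate 1 at S2, r at S3 with r = exp(-ddG/RT)); at the
    Intermediate the race repeats with Ks.  Races are decided by sampling
    exponential waiting times.  Losing either race returns the molecule to
    the unbound pool for another attempt.  Returns (fraction of trials that
    complete assembly at S3, binomial SE).
    """
    rng = _rng(seed)
    r = float(np.exp(-ddG / ctx.RT))
    kf, ks = params.Kf, params.Ks
    active = np.arange(n_trials)
    success_s3 = np.zeros(n_trials, dtype=bool)
    for _ in range(max_rounds):
        m = active.size
        if m == 0:
            break
        pick_s3 = rng.random(m) < 0.5
        off_scale = np.where(pick_s3, r, 1.0)
        # E-complex checkpoint: forward (rate Kf) vs dissociation (rate off_scale)
        t_fwd1 = rng.exponential(1.0, size=m) / max(kf, 1e-300)
        t_off1 = rng.exponential(1.0, size=m) / off_scale
        pass1 = t_fwd1 < t_off1
        # Intermediate checkpoint
        t_fwd2 = rng.exponential(1.0, size=m) / max(ks, 1e-300)
        t_off2 = rng.exponential(1.0, size=m) / off_scale
        done = pass1 & (t_fwd2 < t_off2)
        success_s3[active[done & pick_s3]] = True
        active = active[~done]
    else:
        raise RuntimeError("simulate_site_competition did not resolve all trials")
    p = float(np.mean(success_s3))
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_trials))
    return p, se


def simulate_psi_dataset(
    params: ProofreadingParams,
    ddg_grid: Sequence[float],
    n_sites_per_bin: int = 50,
    depth: int = 200,
    seed: int = 0,
    overdispersion: float = 0.0,
    ks_scale: float = 1.0,
    condition: str = "control",
    ctx: EnergyContext = EnergyContext(),
) -> pd.DataFrame:
    """Per-site PSI observations on a ddG grid with read-depth noise.

    True PSI comes from the proofreading equation; the observed PSI of each
    site is Binomial(depth, p)/depth where, with overdispersion rho > 0, the
    site-level p is Beta-distributed around the true PSI (intraclass
    correlation rho), emulating transcript-to-transcript variation.
    """
    rng = _rng(seed)
    eff = ProofreadingParams(Kf=params.Kf, Ks=params.Ks * ks_scale)
    rows = []
    for ddg in ddg_grid:
        p_true = float(psi(ddg, eff, ctx))
        for s in range(n_sites_per_bin):
            if overdispersion > 0:
                nu = (1.0 - overdispersion) / overdispersion
                a = np.clip(p_true * nu, 1e-6, None)
                b = np.clip((1.0 - p_true) * nu, 1e-6, None)
                p_site = rng.beta(a, b)
            else:
                p_site = p_true
            obs = rng.binomial(depth, p_site) / depth
            rows.append(
                {
                    "condition": condition,
                    "ddg": float(ddg),
                    "site": s,
                    "psi_true": p_true,
                    "psi_obs": obs,
                    "depth": depth,
                }
            )
    return pd.DataFrame(rows)


def bin_psi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Median observed PSI per ddG bin with a bootstrap-free SE of the median
    (1.2533 * SE of the mean, the asymptotic normal-factor approximation)."""
    def per_bin(g: pd.DataFrame) -> pd.Series:
        med = g["psi_obs"].median()
        se = 1.2533 * g["psi_obs"].std(ddof=1) / np.sqrt(len(g))
        return pd.Series({"psi": med, "se": se, "n": len(g)})

    out = (
        table.groupby(["condition", "ddg"]).apply(per_bin, include_groups=False).reset_index()
    )
    return out


def simulate_rbns_reads(
    model: EnergyModel,
    conc: float,
    n_reads: int,
    read_len: int = 40,
    seed: int = 0,
    k0: float = 20.0,
) -> tuple:
    """Input and protein-selected (IP) read pools for an RBNS-style assay.

    The input pool is uniform random RNA.  The IP pool is resampled from the
    input pool with Boltzmann occupancy weights
    ``p propto conc * A / (conc * A + K0)`` where ``A`` is the best-window
    relative affinity of the read under the energy model.  ``K0 = 20`` puts
    the consensus site at half occupancy at 20 nM, the assay's informative
    regime.  Returns (input_reads, ip_reads) as lists of strings.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = _rng(seed)
    bases = np.array(list("ACGU"))
    pool = ["".join(rng.choice(bases, size=read_len)) for _ in range(n_reads)]
    if conc == np.inf:
        occ = np.ones(n_reads)
    else:
        aff = np.array([score_sequence(model, s).best_affinity for s in pool])
        occ = conc * aff / (conc * aff + k0)
    weights = occ / occ.sum()
    idx = rng.choice(n_reads, size=n_reads, replace=True, p=weights)
    ip = [pool[i] for i in idx]
    return pool, ip


def simulate_transcription_splicing_traces(
    tau_splice: float,
    burst_rate: float,
    u2af_dwell: float,
    u2af_offset: float,
    acq: AcquisitionSettings,
    n_traces: int,
    time_unit: str = "min",
    duration_dist: str = "exponential",
) -> List[IntensityTrace]:
    """Dual-channel transcription/splicing traces for correlation analysis.

    Channel 1 (MS2 stem loops): renewal on/off telegraph; high-state
    durations are exponential with mean ``tau_splice`` (the time from stem-
    loop synthesis to intron removal), off periods exponential with rate
    ``burst_rate``.  Channel 2 (U2AF): one binding pulse per cycle with
    exponential duration of mean ``u2af_dwell``, centred ``u2af_offset``
    before the splicing down-step.  Gaussian noise on both channels.  Times
    are in ``time_unit`` (minutes by convention for these assays) and
    ``acq.frame_interval`` is interpreted in the same unit.

    ``duration_dist='fixed'`` makes every high state exactly ``tau_splice``
    long (rectangular events), the reference construction used to calibrate
    the cross-correlation width estimator.
    """
    if duration_dist not in {"exponential", "fixed"}:
        raise ValueError("duration_dist must be 'exponential' or 'fixed'")
    rng = _rng(acq.seed)
    times = np.arange(acq.n_frames) * acq.frame_interval
    t_end = times[-1]
    traces = []
    for i in range(n_traces):
        ms2 = np.zeros_like(times)
        u2af = np.zeros_like(times)
        t = rng.exponential(1.0 / burst_rate) if burst_rate > 0 else 0.0
        while t < t_end:
            dur = rng.exponential(tau_splice) if duration_dist == "exponential" else tau_splice
            up, down = t, t + dur
            ms2[(times >= up) & (times < down)] = 1.0
            if u2af_dwell > 0:
                d = rng.exponential(u2af_dwell)
                center = down - u2af_offset
                u2af[(times >= center - d / 2) & (times < center + d / 2)] = 1.0
            t = down + (rng.exponential(1.0 / burst_rate) if burst_rate > 0 else np.inf)
        lo, hi = acq.emission_low, acq.emission_high
        ch1 = lo + (hi - lo) * ms2
        ch2 = lo + (hi - lo) * u2af
        if acq.noise_sd > 0:
            ch1 = ch1 + rng.normal(0.0, acq.noise_sd, size=ch1.shape)
            ch2 = ch2 + rng.normal(0.0, acq.noise_sd, size=ch2.shape)
        traces.append(
            IntensityTrace(
                trace_id=f"orbital_{i:04d}",
                time=times + acq.frame_interval,
                intensity=ch1,
                intensity2=ch2,
                true_state=ms2.astype(int),
            )
        )
    return traces


def simulate_metagene(
    n_introns: int,
    half_life: float,
    seed: int = 0,
    observation_limit: Optional[float] = None,
) -> pd.DataFrame:
    """Per-intron splicing times with exponential kinetics.

    Times are exponential with median ``half_life`` (rate ln2 / half_life).
    With an ``observation_limit``, slower introns are right-censored, as in
    time-lapse imaging of a gene-trap reporter population.
    """
    if n_introns <= 0 or half_life <= 0:
        raise ValueError("n_introns and half_life must be > 0")
    rng = _rng(seed)
    t = rng.exponential(half_life / np.log(2.0), size=n_introns)
    censored = np.zeros(n_introns, dtype=bool)
    if observation_limit is not None:
        censored = t > observation_limit
        t = np.minimum(t, observation_limit)
    return pd.DataFrame(
        {"intron": np.arange(n_introns), "splice_time": t, "censored": censored.astype(int)}
    )
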