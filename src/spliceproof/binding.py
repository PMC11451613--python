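"""Sequence-level U2AF binding: k-mer enrichment, additive energy model, site scoring.

RNA Bind-n-Seq (RBNS) style analysis works on k-mer count tables from an
input pool and a protein-selected (IP) pool; the enrichment
``R = freq_IP / freq_input`` of a k-mer measures binding preference.  An
additive per-position, per-base free-energy model converts sequences to
relative affinities (consensus = 1), and affinity ratios between competing
sites convert to binding free-energy differences via
``-ddG = RT ln(k_off_S3 / k_off_S2)`` under sequence-independent association.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinetics import EnergyContext, SitePair

__all__ = [
    "KmerCountTable",
    "EnrichmentTable",
    "EnergyModel",
    "BindingSiteRecord",
    "WindowScores",
    "normalize_rna",
    "compute_enrichment",
    "ag_positional_preference",
    "score_sequence",
    "ddg_between_sites",
    "find_downstream_competitor",
    "u2af_like_model",
]

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}

# Relative-affinity floor below which the additive model was never validated
# against direct binding measurements; site pairs involving weaker sites are
# excluded from accuracy predictions.
VALIDATED_AFFINITY_FLOOR = 1.0 / 370.0


def normalize_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U; reject characters outside ACGU(T)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass
class KmerCountTable:
    """Counts of overlapping k-mers in a read pool."""

    k: int
    counts: dict
    library_label: str = "input"

    def __post_init__(self) -> None:
        for kmer, c in self.counts.items():
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} does not have length {self.k}")
            if c < 0:
                raise ValueError("counts must be >= 0")
        self.counts = {normalize_rna(km): float(c) for km, c in self.counts.items()}

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @classmethod
    def from_reads(cls, reads: Iterable[str], k: int, library_label: str = "input") -> "KmerCountTable":
        counts: Counter = Counter()
        for read in reads:
            s = normalize_rna(str(read))
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
        return cls(k=k, counts=dict(counts), library_label=library_label)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"kmer": list(self.counts), "count": list(self.counts.values())}
        ).sort_values("kmer")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, library_label: str = "input") -> "KmerCountTable":
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df["kmer"], df["count"]))
        k = len(next(iter(counts)))
        return cls(k=k, counts=counts, library_label=library_label)


@dataclass
class EnrichmentTable:
    """Per-k-mer enrichment R = freq_IP / freq_input with significance calls."""

    k: int
    table: pd.DataFrame  # columns: kmer, r, pvalue, qvalue, significant

    def r(self, kmer: str) -> float:
        kmer = normalize_rna(kmer)
        row = self.table.loc[self.table["kmer"] == kmer]
        if row.empty:
            raise KeyError(kmer)
        return float(row["r"].iloc[0])

    def significant_kmers(self) -> list:
        return list(self.table.loc[self.table["significant"], "kmer"])


def compute_enrichment(
    ip: KmerCountTable,
    input_table: KmerCountTable,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> EnrichmentTable:
    """Enrichment R per k-mer with a binomial test against R = 1.

    R uses pseudocounted frequencies so unobserved k-mers remain defined:
    ``R = [(c_ip + p) / (N_ip + p 4^k)] / [(c_in + p) / (N_in + p 4^k)]``.
    Significance is a two-sided binomial test of the IP count given the
    input frequency, Benjamini-Hochberg adjusted at ``alpha``.  R is
    invariant to rescaling both libraries by a common factor (at p = 0).
    """
    if ip.k != input_table.k:
        raise ValueError(f"k mismatch: {ip.k} vs {input_table.k}")
    if ip.total <= 0 or input_table.total <= 0:
        raise ValueError("both tables must have positive totals")
    k = ip.k
    n_kmers = 4**k
    kmers = sorted(set(ip.counts) | set(input_table.counts))
    c_ip = np.array([ip.counts.get(km, 0.0) for km in kmers])
    c_in = np.array([input_table.counts.get(km, 0.0) for km in kmers])
    n_ip, n_in = ip.total, input_table.total
    f_ip = (c_ip + pseudocount) / (n_ip + pseudocount * n_kmers)
    f_in = (c_in + pseudocount) / (n_in + pseudocount * n_kmers)
    r = f_ip / f_in
    # two-sided binomial test of the raw IP count at the raw input frequency
    p_null = np.clip(c_in / n_in, 1e-300, 1.0)
    n_trials = int(round(n_ip))
    x = np.round(c_ip).astype(int)
    lo = stats.binom.cdf(x, n_trials, p_null)
    hi = stats.binom.sf(x - 1, n_trials, p_null)
    pvals = np.clip(2.0 * np.minimum(lo, hi), 0.0, 1.0)
    pvals[c_in == 0] = 1.0  # R undefined without input observations
    reject, qvals, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    df = pd.DataFrame(
        {"kmer": kmers, "r": r, "pvalue": pvals, "qvalue": qvals, "significant": reject}
    )
    return EnrichmentTable(k=k, table=df)


def ag_positional_preference(enr: EnrichmentTable) -> pd.DataFrame:
    """Mean R(AG variant) / R(GA variant) per AG position within the k-mer.

    Each k-mer containing ``AG`` starting at position p is matched to its
    twin with ``GA`` at the same position; the ratio of their enrichments
    isolates the positional contribution of the AG dinucleotide (the 3'
    splice-site mark read by the small U2AF subunit).
    """
    tab = enr.table.set_index("kmer")["r"]
    k = enr.k
    rows = []
    for pos in range(k - 1):
        ratios = []
        for kmer in tab.index:
            if kmer[pos : pos + 2] == "AG":
                twin = kmer[:pos] + "GA" + kmer[pos + 2 :]
                if twin in tab.index and tab[twin] > 0:
                    ratios.append(tab[kmer] / tab[twin])
        if ratios:
            rows.append({"position": pos, "mean_ratio": float(np.mean(ratios)), "n_pairs": len(ratios)})
    if not rows:
        raise ValueError("no AG/GA k-mer pairs found in the enrichment table")
    return pd.DataFrame(rows)


@dataclass
class EnergyModel:
    """Additive per-position, per-base binding free-energy model (RT units).

    ``penalties[p, b]`` is the free-energy cost of base ``b`` (order ACGU)
    at window position ``p`` relative to the consensus base; each row
    contains at least one zero, so the consensus window has energy 0 and
    relative affinity exactly 1 (the maximum of the model).
    """

    penalties: np.ndarray
    consensus_affinity: float = 1.0

    def __post_init__(self) -> None:
        self.penalties = np.asarray(self.penalties, dtype=float)
        if self.penalties.ndim != 2 or self.penalties.shape[1] != 4:
            raise ValueError("penalties must have shape (k, 4) over bases ACGU")
        if np.any(self.penalties < 0):
            raise ValueError("penalties are free-energy costs and must be >= 0")
        # anchor each position at its best base so the consensus scores 1
        self.penalties = self.penalties - self.penalties.min(axis=1, keepdims=True)

    @property
    def k(self) -> int:
        return self.penalties.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_BASES[i] for i in self.penalties.argmin(axis=1))

    def window_energy(self, window: str) -> float:
        w = normalize_rna(window)
        if len(w) != self.k:
            raise ValueError(f"window length {len(w)} != k = {self.k}")
        return float(sum(self.penalties[i, _BASE_INDEX[b]] for i, b in enumerate(w)))

    def relative_affinity(self, window: str) -> float:
        return float(np.exp(-self.window_energy(window)))

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "bases": list(RNA_BASES),
            "penalties_rt": [
                {b: float(self.penalties[p, i]) for i, b in enumerate(RNA_BASES)}
                for p in range(self.k)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EnergyModel":
        with open(path) as fh:
            payload = json.load(fh)
        pen = np.array(
            [[row[b] for b in RNA_BASES] for row in payload["penalties_rt"]], dtype=float
        )
        return cls(penalties=pen)


def u2af_like_model(
    k: int = 12,
    u_penalty: float = 0.8,
    c_discount: float = 0.5,
    ag_bonus: float = 1.5,
) -> EnergyModel:
    """A pyrimidine-tract + 3'-AG energy model emulating the U2AF preference.

    Positions 0..k-3 favour U (pyrimidine tract: C is penalised less than
    A/G by ``c_discount``); the two 3'-most positions favour the AG
    dinucleotide with a deeper penalty ``ag_bonus`` for any other base,
    mirroring the AG preference detected at the 3' end of the binding site.
    """
    pen = np.zeros((k, 4))
    for p in range(k - 2):
        pen[p] = [u_penalty, u_penalty * c_discount, u_penalty, 0.0]  # A C G U
    pen[k - 2] = [0.0, ag_bonus, ag_bonus, ag_bonus]  # A
    pen[k - 1] = [ag_bonus, ag_bonus, 0.0, ag_bonus]  # G
    return EnergyModel(penalties=pen)


@dataclass
class WindowScores:
    """Per-window relative affinities of one sequence under an EnergyModel."""

    affinities: np.ndarray
    best_affinity: float
    best_start: int
    best_kmer: str


def score_sequence(model: EnergyModel, seq: str) -> WindowScores:
    """Relative affinity of every k-length window; the peak affinity is the
    site's affinity (the convention used to assign affinities to binding-site
    peaks)."""
    s = normalize_rna(seq)
    k = model.k
    if len(s) < k:
        raise ValueError(f"sequence length {len(s)} < window length {k}")
    idx = np.array([_BASE_INDEX[b] for b in s])
    n_win = len(s) - k + 1
    pos = np.arange(k)
    energies = model.penalties[pos[None, :], np.stack([idx[i : i + k] for i in range(n_win)])].sum(axis=1)
    aff = np.exp(-energies)
    best = int(np.argmax(aff))
    return WindowScores(
        affinities=aff,
        best_affinity=float(aff[best]),
        best_start=best,
        best_kmer=s[best : best + k],
    )


def ddg_between_sites(
    aff_s2: float,
    aff_s3: float,
    ctx: EnergyContext = EnergyContext(),
    label_s2: str = "S2",
    label_s3: str = "S3",
) -> SitePair:
    """Binding free-energy difference between competing sites from affinities.

    Assuming k_off is inversely proportional to relative affinity
    (association is sequence-independent),
    ``-ddG = RT ln(k_off_S3/k_off_S2) = RT ln(aff_s2/aff_s3)``, i.e.
    ``ddG = RT ln(aff_s3/aff_s2)``: positive when S3 is the tighter site.
    """
    if not (aff_s2 > 0 and aff_s3 > 0):
        raise ValueError("affinities must be > 0")
    ddg = ctx.RT * float(np.log(aff_s3 / aff_s2))
    return SitePair(ddG=ddg, label_s2=label_s2, label_s3=label_s3)


@dataclass
class BindingSiteRecord:
    """A binding site in BED-like coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    relative_affinity: float = 1.0
    best_kmer: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 < self.relative_affinity <= 1):
            raise ValueError("relative_affinity must be in (0, 1]")


def find_downstream_competitor(
    site: BindingSiteRecord,
    candidates: Sequence[BindingSiteRecord],
    window: tuple = (10, 50),
    affinity_floor: float = VALIDATED_AFFINITY_FLOOR,
    secondary_floor: float = 1e-3,
    ctx: EnergyContext = EnergyContext(),
) -> Optional[SitePair]:
    """Nearest decoy site 10-50 nt downstream of an annotated 3' splice site.

    Strand-aware: downstream means 3' of the site.  Both sites must clear
    both affinity floors (the validation floor of the energy model and a
    configurable secondary floor).  Returns the SitePair with the annotated
    site in the S3 role, or None when no candidate qualifies.
    """
    floor = max(affinity_floor, secondary_floor)
    if site.relative_affinity < floor:
        return None
    lo, hi = window
    best = None
    best_dist = None
    for cand in candidates:
        if cand.chrom != site.chrom or cand.strand != site.strand:
            continue
        if cand is site:
            continue
        if site.strand == "+":
            dist = cand.start - site.end
        else:
            dist = site.start - cand.end
        if lo <= dist <= hi and cand.relative_affinity >= floor:
            if best_dist is None or dist < best_dist:
                best, best_dist = cand, dist
    if best is None:
        return None
    return ddg_between_sites(
        aff_s2=best.relative_affinity,
        aff_s3=site.relative_affinity,
        ctx=ctx,
        label_s2=best.name,
        label_s3=site.name,
    )
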