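"""Forward simulation of hydrogen/deuterium exchange under the EX2 limit.

The simulator is the pipeline's stand-in for raw HDX-MS measurements: it
takes per-residue intrinsic rates and state-specific protection factors,
integrates the Linderstrøm-Lang EX2 kinetics k_obs = k_int / PF, sums
residue occupancies over pepsin-like peptides, applies a per-peptide back
exchange factor and Gaussian measurement noise, and emits uptake and
full-deuteration (FD) reference tables in the same shape a real experiment
would produce.  Ground-truth protection factors are emitted alongside so
that downstream stages can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chains import ProteinChain
from .intrinsic import default_intrinsic_rates
from .uptake import theoretical_maxd

#: labeling-buffer D2O fraction used in the experiments this emulates
DEFAULT_F_D2O = 0.75
#: exchange time course in seconds
DEFAULT_TIMEPOINTS = (10.0, 100.0, 300.0, 1000.0, 3000.0)
DEFAULT_STATES = ("free", "droplet")

UPTAKE_COLUMNS = [
    "peptide_id", "chain", "start", "end", "sequence", "charge",
    "state", "time_s", "replicate", "deuterons",
]
FD_COLUMNS = [
    "peptide_id", "chain", "start", "end", "sequence", "charge",
    "replicate", "deuterons",
]


@dataclass
class ExchangeModel:
    """Ground truth for one chain: intrinsic rates and per-state protection.

    ``k_int`` and each protection-factor vector are aligned to
    ``chain.sequence``.  Protection factors are >= 1 (PF = 1 means fully
    unprotected); observed exchange follows k_obs = k_int / PF.
    """

    chain: ProteinChain
    k_int: np.ndarray
    protection_factor: Mapping[str, np.ndarray]
    f_D2O: float = DEFAULT_F_D2O

    def __post_init__(self) -> None:
        self.k_int = np.asarray(self.k_int, dtype=float)
        n = len(self.chain)
        if self.k_int.shape != (n,):
            raise ValueError(f"k_int length {self.k_int.shape} != chain length {n}")
        if np.any(self.k_int < 0):
            raise ValueError("k_int must be nonnegative")
        if self.k_int[0] != 0.0:
            raise ValueError("k_int must be 0 at the chain's first residue")
        for i, aa in enumerate(self.chain.sequence):
            if aa == "P" and self.k_int[i] != 0.0:
                raise ValueError(f"k_int must be 0 at proline (position {i + 1})")
        self.protection_factor = {
            state: np.asarray(pf, dtype=float) for state, pf in self.protection_factor.items()
        }
        for state, pf in self.protection_factor.items():
            if pf.shape != (n,):
                raise ValueError(f"protection_factor[{state!r}] length != chain length")
            if np.any(pf < 1.0):
                raise ValueError(f"protection_factor[{state!r}] must be >= 1 everywhere")
        if not 0.0 < self.f_D2O <= 1.0:
            raise ValueError("f_D2O must be in (0, 1]")

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.protection_factor)


@dataclass(frozen=True)
class Peptide:
    peptide_id: str
    chain_id: str
    start: int
    end: int
    sequence: str
    charges: tuple[int, ...] = (2,)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.peptide_id}: start > end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"{self.peptide_id}: sequence length != span")
        if any(z < 1 for z in self.charges):
            raise ValueError(f"{self.peptide_id}: charges must be positive")


@dataclass
class PeptideMap:
    """An ordered collection of (possibly overlapping) peptides."""

    entries: list[Peptide]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("peptide map is empty")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, chains: Mapping[str, ProteinChain]) -> None:
        for pep in self.entries:
            if pep.chain_id not in chains:
                raise ValueError(f"{pep.peptide_id}: unknown chain {pep.chain_id!r}")
            sub = chains[pep.chain_id].subsequence(pep.start, pep.end)
            if sub != pep.sequence:
                raise ValueError(
                    f"{pep.peptide_id}: sequence does not match chain "
                    f"{pep.chain_id!r} residues {pep.start}-{pep.end}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.peptide_id, p.chain_id, p.start, p.end, p.sequence,
                 ";".join(map(str, p.charges)))
                for p in self.entries
            ],
            columns=["peptide_id", "chain", "start", "end", "sequence", "charges"],
        )


@dataclass
class BackExchangeSpec:
    """Distribution of the per-peptide back-exchange fraction.

    ``uniform`` draws from [low, high); ``fixed`` uses ``low`` for every
    peptide.  Support must stay within [0, 0.5).
    """

    kind: str = "uniform"
    low: float = 0.10
    high: float = 0.26

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "fixed"):
            raise ValueError(f"unknown back-exchange distribution {self.kind!r}")
        if not (0.0 <= self.low < 0.5) or not (0.0 <= self.high < 0.5):
            raise ValueError("back-exchange support must lie within [0, 0.5)")
        if self.kind == "uniform" and self.high < self.low:
            raise ValueError("uniform back exchange needs low <= high")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.low)
        return rng.uniform(self.low, self.high, size=n)


@dataclass
class SimulationConfig:
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    noise_sd: float = 0.05
    back_exchange: BackExchangeSpec = field(default_factory=BackExchangeSpec)
    random_seed: int = 0
    states: Sequence[str] = DEFAULT_STATES
    n_term_excluded: int = 1

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.ndim != 1 or len(tp) == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and positive")
        self.timepoints = tuple(tp)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_term_excluded not in (1, 2):
            raise ValueError("n_term_excluded must be 1 or 2")


def residue_uptake(k_int: float, pf: float, t: float, f_D2O: float) -> float:
    """Deuterium occupancy of one amide after time ``t`` (EX2 limit).

    Returns ``f_D2O * (1 - exp(-(k_int/pf) * t))``: 0 at t=0, saturating at
    the labeling fraction, nondecreasing in t and nonincreasing in PF.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if pf < 1:
        raise ValueError("protection factor must be >= 1")
    if not 0.0 < f_D2O <= 1.0:
        raise ValueError("f_D2O must be in (0, 1]")
    return f_D2O * -np.expm1(-(k_int / pf) * t)


def _models_by_chain(model) -> dict[str, ExchangeModel]:
    if isinstance(model, ExchangeModel):
        return {model.chain.chain_id: model}
    if isinstance(model, Mapping):
        return dict(model)
    return {m.chain.chain_id: m for m in model}


def _exchanging_indices(model: ExchangeModel, pep: Peptide, n_term_excluded: int) -> np.ndarray:
    """0-based chain indices of a peptide's label-retaining amides."""
    chain = model.chain
    idx = np.arange(chain.index_of(pep.start), chain.index_of(pep.end) + 1)
    idx = idx[n_term_excluded:]  # N-terminal residue(s) lose label to back exchange
    seq = chain.sequence
    return np.array([i for i in idx if seq[i] != "P"], dtype=int)


def peptide_theoretical_uptake(
    model: ExchangeModel, pep: Peptide, state: str, t: float, n_term_excluded: int = 1
) -> float:
    """Noise-free, back-exchange-free deuteron count of a peptide at time t."""
    idx = _exchanging_indices(model, pep, n_term_excluded)
    pf = model.protection_factor[state]
    k = model.k_int
    return float(
        np.sum(model.f_D2O * -np.expm1(-(k[idx] / np.maximum(pf[idx], 1.0)) * t))
    )


def _rngs(config: SimulationConfig) -> dict[str, np.random.Generator]:
    # separate child streams so uptake and FD share back-exchange draws
    return {
        name: np.random.default_rng(np.random.SeedSequence([config.random_seed, i]))
        for i, name in enumerate(("bx", "uptake", "fd"))
    }


def draw_back_exchange(map_: PeptideMap, config: SimulationConfig) -> dict[str, float]:
    """Per-peptide back-exchange fractions, deterministic under the seed."""
    rng = _rngs(config)["bx"]
    values = config.back_exchange.draw(rng, len(map_))
    return {pep.peptide_id: float(v) for pep, v in zip(map_, values)}


def simulate_peptide_uptake(model, map_: PeptideMap, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the labeled time-course uptake table.

    For every peptide x charge x state x timepoint x replicate the deuteron
    count is the closed-form residue-occupancy sum, attenuated by the
    peptide's back-exchange factor, plus truncated Gaussian noise.
    """
    models = _models_by_chain(model)
    chains = {cid: m.chain for cid, m in models.items()}
    map_.validate_against(chains)
    for m in models.values():
        for state in config.states:
            if state not in m.protection_factor:
                raise ValueError(
                    f"state {state!r} has no protection-factor vector on chain "
                    f"{m.chain.chain_id!r}"
                )
    bx = draw_back_exchange(map_, config)
    rng = _rngs(config)["uptake"]
    rows = []
    for pep in map_:
        m = models[pep.chain_id]
        for state in config.states:
            for t in config.timepoints:
                clean = peptide_theoretical_uptake(m, pep, state, t, config.n_term_excluded)
                clean *= 1.0 - bx[pep.peptide_id]
                for z in pep.charges:
                    noise = rng.normal(0.0, config.noise_sd, size=config.n_replicates)
                    for rep in range(1, config.n_replicates + 1):
                        d = max(0.0, clean + (noise[rep - 1] if config.noise_sd > 0 else 0.0))
                        rows.append(
                            (pep.peptide_id, pep.chain_id, pep.start, pep.end,
                             pep.sequence, z, state, t, rep, d)
                        )
    return pd.DataFrame(rows, columns=UPTAKE_COLUMNS)


def simulate_fd_reference(model, map_: PeptideMap, config: SimulationConfig) -> pd.DataFrame:
    """Simulate the full-deuteration reference table (t -> infinity).

    Every label-retaining amide reaches the labeling fraction, so the clean
    FD level is the peptide's theoretical maxD attenuated by its
    back-exchange factor.
    """
    models = _models_by_chain(model)
    map_.validate_against({cid: m.chain for cid, m in models.items()})
    bx = draw_back_exchange(map_, config)
    rng = _rngs(config)["fd"]
    rows = []
    for pep in map_:
        m = models[pep.chain_id]
        maxd = theoretical_maxd(pep.sequence, m.f_D2O, config.n_term_excluded)
        clean = maxd * (1.0 - bx[pep.peptide_id])
        for z in pep.charges:
            noise = rng.normal(0.0, config.noise_sd, size=config.n_replicates)
            for rep in range(1, config.n_replicates + 1):
                d = max(0.0, clean + (noise[rep - 1] if config.noise_sd > 0 else 0.0))
                rows.append(
                    (pep.peptide_id, pep.chain_id, pep.start, pep.end,
                     pep.sequence, z, rep, d)
                )
    return pd.DataFrame(rows, columns=FD_COLUMNS)


def ground_truth_table(model) -> pd.DataFrame:
    """Ground-truth protection factors as a tidy chain/residue/state table."""
    rows = []
    for cid, m in _models_by_chain(model).items():
        for state, pf in m.protection_factor.items():
            for i, v in enumerate(pf):
                rows.append((cid, m.chain.first_residue_number + i, state, float(v)))
    return pd.DataFrame(rows, columns=["chain", "residue", "state", "pf"])


def sliding_window_map(
    chains: Iterable[ProteinChain],
    min_len: int = 8,
    max_len: int = 20,
    step: int = 3,
    charges: Sequence[Sequence[int]] = ((2,), (2, 3), (3,)),
    seed: int = 0,
) -> PeptideMap:
    """Overlapping pepsin-like peptide map: sliding windows of varying length.

    Window lengths and charge-state sets are drawn deterministically from
    ``seed``, emulating the redundant overlapping coverage of a real pepsin
    digest.  The final window of each chain is anchored to the chain end so
    coverage never has a trailing gap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    entries = []
    for chain in chains:
        first, last = chain.first_residue_number, chain.last_residue_number
        start = first
        while start <= last - min_len + 1:
            length = int(rng.integers(min_len, max_len + 1))
            end = min(start + length - 1, last)
            if last - end < min_len and end != last:
                end = last  # absorb a too-short tail into the final window
            zset = tuple(charges[int(rng.integers(0, len(charges)))])
            pid = f"{chain.chain_id}_{start}_{end}"
            entries.append(
                Peptide(pid, chain.chain_id, start, end, chain.subsequence(start, end), zset)
            )
            if end == last:
                break
            start += step
    # drop duplicate ids that the tail-anchoring can create
    seen: dict[str, Peptide] = {}
    for pep in entries:
        seen.setdefault(pep.peptide_id, pep)
    return PeptideMap(list(seen.values()))
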