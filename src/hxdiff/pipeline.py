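"""End-to-end orchestration: simulate -> uptake -> diff -> consensus -> contacts -> report.

Every stage reads and writes TSV artifacts in a run directory, so each is
idempotent given identical inputs and configuration, and any stage can be
re-run alone provided its upstream artifacts exist.  Defaults are
materialized into the run report: nothing numeric stays implicit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as consensus_mod
from . import differential as diff_mod
from . import lattice as lattice_mod
from .chains import ProteinChain, read_fasta_chains, write_fasta_chains
from .forward import (
    BackExchangeSpec,
    ExchangeModel,
    PeptideMap,
    Peptide,
    SimulationConfig,
    ground_truth_table,
    simulate_fd_reference,
    simulate_peptide_uptake,
    sliding_window_map,
)
from .intrinsic import default_intrinsic_rates
from .synthetic_sequences import default_isb_chains
from .synthetic_structure import write_synthetic_pdb
from .tsvio import read_tsv, write_tsv
from .uptake import back_exchange_summary, fd_normalize

logger = logging.getLogger(__name__)

STAGES = ("simulate", "uptake", "diff", "consensus", "contacts", "report")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DependencyError(RuntimeError):
    """A required upstream artifact is missing (CLI exit code 3)."""


@dataclass
class ProtectionRegion:
    chain: str
    start: int
    end: int
    pf: float


@dataclass
class RunConfig:
    outdir: Path = Path("hxdiff_run")
    random_seed: int = 0
    f_D2O: float = 0.75
    timepoints: Sequence[float] = (10.0, 100.0, 300.0, 1000.0, 3000.0)
    states: Sequence[str] = ("free", "droplet")
    n_replicates: int = 3
    noise_sd: float = 0.05
    back_exchange_kind: str = "uniform"
    back_exchange_low: float = 0.10
    back_exchange_high: float = 0.26
    n_term_excluded: int = 1
    rate_model: str = "uniform"
    pD: float = 7.5
    temperature: float = 298.0
    fasta_path: str | None = None
    # droplet-state protection; default emulates localized protection of the
    # INCENP and Borealin interface helices plus the Borealin 140-150 patch
    protection: Mapping[str, Sequence[ProtectionRegion]] = field(
        default_factory=lambda: {
            "droplet": (
                ProtectionRegion("INCENP", 30, 47, 50.0),
                ProtectionRegion("Borealin", 30, 60, 20.0),
                ProtectionRegion("Borealin", 140, 150, 8.0),
            )
        }
    )
    test_method: str = "welch"
    correction: str = "none"
    bin_edges: Sequence[float] = diff_mod.DEFAULT_BIN_EDGES
    consensus_time: float = 100.0
    span: str = "residue"
    protection_threshold: float = -5.0
    timeshift_levels: Sequence[float] = diff_mod.DEFAULT_TIMESHIFT_LEVELS
    structure_path: str | None = None  # None -> synthetic stand-in lattice
    structure_chain_mapping: Mapping[str, tuple[str, int]] = field(
        default_factory=lambda: {"A": ("Survivin", 0), "B": ("Borealin", 0), "C": ("INCENP", 0)}
    )
    salt_bridge_cutoff: float = 4.0
    contact_cutoff: float = 4.0
    shell: int = 1
    operator_override: Sequence[str] | None = None

    def validate(self) -> None:
        if len(self.states) != 2:
            raise ConfigError("differential runs need exactly two states")
        if self.fasta_path and not Path(self.fasta_path).exists():
            raise ConfigError(f"fasta_path {self.fasta_path} does not exist")
        if self.structure_path and not Path(self.structure_path).exists():
            raise ConfigError(f"structure_path {self.structure_path} does not exist")
        if self.consensus_time not in tuple(self.timepoints):
            raise ConfigError(
                f"consensus_time {self.consensus_time} is not one of the timepoints"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "protection" in raw:
            raw["protection"] = {
                state: tuple(ProtectionRegion(**r) for r in regions)
                for state, regions in raw["protection"].items()
            }
        if "structure_chain_mapping" in raw:
            raw["structure_chain_mapping"] = {
                k: tuple(v) for k, v in raw["structure_chain_mapping"].items()
            }
        if "outdir" in raw:
            raw["outdir"] = Path(raw["outdir"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def materialized(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, Mapping):
                value = {k: v for k, v in value.items()}
            out[name] = value
        return out


def build_chains(config: RunConfig) -> list[ProteinChain]:
    if config.fasta_path:
        return read_fasta_chains(config.fasta_path)
    return default_isb_chains()


def build_models(config: RunConfig, chains: Sequence[ProteinChain]) -> dict[str, ExchangeModel]:
    models = {}
    by_id = {c.chain_id: c for c in chains}
    for chain in chains:
        k_int = default_intrinsic_rates(chain, config.pD, config.temperature, config.rate_model)
        pf = {state: np.ones(len(chain)) for state in config.states}
        for state, regions in config.protection.items():
            if state not in pf:
                raise ConfigError(f"protection given for unknown state {state!r}")
            for region in regions:
                if region.chain != chain.chain_id:
                    continue
                if region.chain not in by_id:
                    raise ConfigError(f"protection region on unknown chain {region.chain!r}")
                lo = chain.index_of(region.start)
                hi = chain.index_of(region.end)
                pf[state][lo : hi + 1] = region.pf
        models[chain.chain_id] = ExchangeModel(chain, k_int, pf, config.f_D2O)
    return models


def _sim_config(config: RunConfig) -> SimulationConfig:
    return SimulationConfig(
        timepoints=tuple(config.timepoints),
        n_replicates=config.n_replicates,
        noise_sd=config.noise_sd,
        back_exchange=BackExchangeSpec(
            config.back_exchange_kind, config.back_exchange_low, config.back_exchange_high
        ),
        random_seed=config.random_seed,
        states=tuple(config.states),
        n_term_excluded=config.n_term_excluded,
    )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"missing artifact {path.name}: run the {producer!r} stage first"
        )
    return path


def _meta(config: RunConfig, **extra) -> dict:
    meta = {
        "f_D2O": config.f_D2O,
        "n_term_excluded": config.n_term_excluded,
        "random_seed": config.random_seed,
        "rate_model": config.rate_model,
    }
    meta.update(extra)
    return meta


def map_from_frame(frame: pd.DataFrame) -> PeptideMap:
    entries = [
        Peptide(r.peptide_id, r.chain, int(r.start), int(r.end), r.sequence,
                tuple(int(z) for z in str(r.charges).split(";")))
        for r in frame.itertuples(index=False)
    ]
    return PeptideMap(entries)


def run_pipeline(config: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Execute the requested stages in dependency order; return report keys."""
    config.validate()
    for stage in stages:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, object] = {}
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        _STAGE_FUNCS[stage](config, out, report)
    return report


def _stage_simulate(config: RunConfig, out: Path, report: dict) -> None:
    chains = build_chains(config)
    models = build_models(config, chains)
    map_ = sliding_window_map(chains, seed=config.random_seed)
    sim = _sim_config(config)
    uptake = simulate_peptide_uptake(models, map_, sim)
    fd = simulate_fd_reference(models, map_, sim)
    write_fasta_chains(chains, out / "chains.fasta")
    write_tsv(map_.to_frame(), out / "peptide_map.tsv", _meta(config))
    write_tsv(uptake, out / "uptake.tsv", _meta(config, states=",".join(config.states)))
    write_tsv(fd, out / "fd.tsv", _meta(config))
    write_tsv(ground_truth_table(models), out / "ground_truth_pf.tsv", _meta(config))
    report["peptides_simulated"] = len(map_)
    report["uptake_records"] = len(uptake)


def _stage_uptake(config: RunConfig, out: Path, report: dict) -> None:
    uptake, _ = read_tsv(_require(out / "uptake.tsv", "simulate"))
    fd, _ = read_tsv(_require(out / "fd.tsv", "simulate"))
    normalized = fd_normalize(uptake, fd, config.f_D2O, config.n_term_excluded)
    write_tsv(normalized, out / "normalized.tsv", _meta(config))
    bx = back_exchange_summary(normalized)
    report["peptides_normalized"] = bx["n_peptides"]
    report["back_exchange_median_percent"] = round(bx["median_percent"], 2)
    report["back_exchange_q1"] = round(100 * bx["q1"], 2)
    report["back_exchange_q3"] = round(100 * bx["q3"], 2)


def _stage_diff(config: RunConfig, out: Path, report: dict) -> None:
    normalized, _ = read_tsv(_require(out / "normalized.tsv", "uptake"))
    state_a, state_b = config.states
    diff = diff_mod.percent_difference(
        normalized, state_a, state_b,
        test_method=config.test_method,
        correction=config.correction,
        bin_edges=tuple(config.bin_edges),
    )
    write_tsv(
        diff, out / "differences.tsv",
        _meta(config, state_a=state_a, state_b=state_b,
              bin_edges=",".join(map(str, config.bin_edges)),
              test=config.test_method, correction=config.correction),
    )
    shifts = _time_shifts(normalized, state_a, state_b, config)
    write_tsv(shifts, out / "timeshift.tsv",
              _meta(config, levels=",".join(map(str, config.timeshift_levels))))
    report["difference_records"] = len(diff)
    report["significant_p05"] = int((diff["p_value"] < 0.05).sum())


def _time_shifts(normalized: pd.DataFrame, state_a: str, state_b: str, config: RunConfig) -> pd.DataFrame:
    rows = []
    for (pid, charge), grp in normalized.groupby(["peptide_id", "charge"], sort=False):
        curves = {}
        for state, sub in grp.groupby("state"):
            curves[state] = (
                sub.groupby("time_s", as_index=False)["percent_D"].mean()
            )
        if state_a not in curves or state_b not in curves:
            continue
        ts = diff_mod.time_shift_factor(
            curves[state_a], curves[state_b], tuple(config.timeshift_levels), label=pid
        )
        rows.append((pid, charge, ts.factor, ";".join(map(str, ts.levels_used)), ts.computable))
    return pd.DataFrame(
        rows, columns=["peptide_id", "charge", "factor", "levels_used", "computable"]
    )


def _stage_consensus(config: RunConfig, out: Path, report: dict) -> None:
    diff, _ = read_tsv(_require(out / "differences.tsv", "diff"))
    chains = {c.chain_id: c for c in build_chains(config)}
    track = consensus_mod.consensus_track(diff, chains, config.consensus_time, config.span)
    write_tsv(track, out / "consensus.tsv",
              _meta(config, time_s=config.consensus_time, span=config.span))
    intervals = consensus_mod.protected_intervals(track, config.protection_threshold)
    report["residues_covered"] = int(track["covered"].sum())
    report["residues_total"] = len(track)
    report["protected_intervals"] = ";".join(
        f"{c}:{lo}-{hi}" for c, lo, hi in intervals
    ) or "none"


def _stage_contacts(config: RunConfig, out: Path, report: dict) -> None:
    if config.structure_path:
        structure_file = Path(config.structure_path)
    else:
        structure_file = out / "synthetic_lattice.pdb"
        if not structure_file.exists():
            write_synthetic_pdb(structure_file)
    structure = lattice_mod.read_structure(str(structure_file))
    copies = lattice_mod.expand_lattice(
        structure, shell=config.shell, operator_override=config.operator_override
    )
    contacts = lattice_mod.find_contacts(structure.atoms, copies, config.contact_cutoff)
    bridges = lattice_mod.classify_salt_bridges(contacts, config.salt_bridge_cutoff)
    write_tsv(lattice_mod.residue_contact_summary(contacts), out / "contacts.tsv",
              _meta(config, cutoff=config.contact_cutoff, shell=config.shell))
    write_tsv(bridges, out / "salt_bridges.tsv",
              _meta(config, cutoff=config.salt_bridge_cutoff))
    track_path = out / "consensus.tsv"
    if track_path.exists():
        track, _ = read_tsv(track_path)
        candidates = lattice_mod.intersect_with_track(
            bridges, track, config.structure_chain_mapping, config.protection_threshold
        )
        write_tsv(candidates, out / "candidates.tsv",
                  _meta(config, protection_threshold=config.protection_threshold))
        annotated = out / "consensus_on_structure.pdb"
        consensus_mod.write_structure_track(
            track, str(structure_file), str(annotated), config.structure_chain_mapping
        )
        report["candidates_both_protected"] = int(candidates["both_protected"].sum())
    report["lattice_copies"] = len(copies)
    report["residue_contacts"] = len(lattice_mod.residue_contact_summary(contacts))
    report["salt_bridges"] = len(bridges)


def _stage_report(config: RunConfig, out: Path, report: dict) -> None:
    lines = []
    for name, value in sorted(config.materialized().items()):
        if name == "outdir":  # location-independent reports stay comparable
            continue
        lines.append(f"config.{name}={value}")
    for artifact in sorted(out.glob("*.tsv")):
        digest = hashlib.sha256(artifact.read_bytes()).hexdigest()[:16]
        lines.append(f"sha256.{artifact.name}={digest}")
    for key, value in sorted(report.items()):
        lines.append(f"{key}={value}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "uptake": _stage_uptake,
    "diff": _stage_diff,
    "consensus": _stage_consensus,
    "contacts": _stage_contacts,
    "report": _stage_report,
}
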