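"""Residue-level consensus protection tracks and structure export.

The consensus value at a residue is the plain average of the percent
differences of every peptide measurement spanning it; charge states count
as independent measurements.  Span semantics default to the full peptide
extent start..end (matching the display convention of peptide bar plots)
with an amide-span mode (start+1..end) available.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .chains import ProteinChain

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chain", "residue", "mean_delta", "n_peptides", "covered"]

#: B-factor fill for residues without HX coverage; outside any plausible
#: percent-difference color range so missing data cannot masquerade as
#: "no change"
DEFAULT_UNCOVERED_FILL = -199.0


def coverage_profile(map_frame: pd.DataFrame, chains: Mapping[str, ProteinChain]) -> pd.DataFrame:
    """Per-residue count of peptide entries spanning each residue."""
    rows = []
    for cid, chain in chains.items():
        resn = np.arange(chain.first_residue_number, chain.last_residue_number + 1)
        counts = np.zeros(len(resn), dtype=int)
        sub = map_frame[map_frame["chain"] == cid]
        for start, end in zip(sub["start"], sub["end"]):
            counts[(resn >= start) & (resn <= end)] += 1
        rows.append(pd.DataFrame({"chain": cid, "residue": resn, "n_peptides": counts}))
    return pd.concat(rows, ignore_index=True)


def consensus_track(
    differences: pd.DataFrame,
    chains: Mapping[str, ProteinChain],
    time_s: float,
    span: str = "residue",
) -> pd.DataFrame:
    """Per-residue mean protection difference at one timepoint.

    ``span`` — "residue" counts a peptide as spanning start..end inclusive;
    "amide" uses start+1..end (the label-retaining amides only).
    """
    if span not in ("residue", "amide"):
        raise ValueError(f"unknown span mode {span!r}")
    sel = differences[differences["time_s"] == time_s]
    if sel.empty:
        raise ValueError(f"no difference records at t = {time_s} s")
    for _, row in sel.iterrows():
        chain = chains.get(row["chain"])
        if chain is None:
            raise ValueError(f"peptide {row['peptide_id']}: unknown chain {row['chain']!r}")
        if row["start"] < chain.first_residue_number or row["end"] > chain.last_residue_number:
            raise ValueError(
                f"peptide {row['peptide_id']}: coordinates {row['start']}-{row['end']} "
                f"outside chain {row['chain']!r}"
            )
    rows = []
    for cid, chain in chains.items():
        resn = np.arange(chain.first_residue_number, chain.last_residue_number + 1)
        total = np.zeros(len(resn))
        count = np.zeros(len(resn), dtype=int)
        sub = sel[sel["chain"] == cid]
        for start, end, delta in zip(sub["start"], sub["end"], sub["delta_percent"]):
            lo = start + 1 if span == "amide" else start
            mask = (resn >= lo) & (resn <= end)
            total[mask] += delta
            count[mask] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chain": cid,
                    "residue": resn,
                    "mean_delta": mean,
                    "n_peptides": count,
                    "covered": count > 0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def protected_intervals(track: pd.DataFrame, threshold: float = -5.0) -> list[tuple[str, int, int]]:
    """Maximal runs of covered residues with mean_delta below ``threshold``."""
    intervals = []
    for cid, sub in track.groupby("chain", sort=False):
        sub = sub.sort_values("residue")
        run_start = None
        prev = None
        for _, row in sub.iterrows():
            hit = bool(row["covered"]) and row["mean_delta"] <= threshold
            if hit and run_start is None:
                run_start = int(row["residue"])
            if not hit and run_start is not None:
                intervals.append((cid, run_start, int(prev)))
                run_start = None
            prev = row["residue"]
        if run_start is not None:
            intervals.append((cid, run_start, int(prev)))
    return intervals


def write_structure_track(
    track: pd.DataFrame,
    structure_path: str,
    out_path: str,
    chain_mapping: Mapping[str, tuple[str, int]],
    uncovered_fill: float = DEFAULT_UNCOVERED_FILL,
) -> int:
    """Write a PDB whose B-factor column carries the consensus track.

    ``chain_mapping`` maps structure chain id -> (construct chain id,
    offset) with construct residue = structure residue + offset.  Only the
    temperature-factor field of ATOM/HETATM lines in mapped chains is
    rewritten (clamped to [-99.99, 99.99]); every other record is preserved
    byte for byte.  Residues absent from the track keep ``uncovered_fill``.
    Returns the number of atoms annotated with a track value.
    """
    if not chain_mapping:
        raise ValueError("empty chain mapping")
    values: dict[tuple[str, int], float] = {}
    for _, row in track.iterrows():
        if row["covered"]:
            values[(row["chain"], int(row["residue"]))] = float(row["mean_delta"])
    n_set = 0
    missing: set[tuple[str, int]] = set()
    out_lines = []
    with open(structure_path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
                struct_chain = line[21]
                if struct_chain in chain_mapping:
                    construct_chain, offset = chain_mapping[struct_chain]
                    resid = int(line[22:26])
                    key = (construct_chain, resid + offset)
                    if key in values:
                        b = float(np.clip(values[key], -99.99, 99.99))
                        n_set += 1
                    else:
                        b = uncovered_fill
                        missing.add(key)
                    line = line[:60] + f"{b:6.2f}" + line[66:]
            out_lines.append(line)
    for key in sorted(missing):
        logger.info("structure residue %s:%d has no covered track value", *key)
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)
    return n_set


def read_structure_track(path: str) -> pd.DataFrame:
    """Recover per-residue B-factor values from a PDB written above."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
                key = (line[21], int(line[22:26]))
                rows.setdefault(key, float(line[60:66]))
    return pd.DataFrame(
        [(c, r, b) for (c, r), b in rows.items()],
        columns=["chain", "residue", "b_factor"],
    )
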