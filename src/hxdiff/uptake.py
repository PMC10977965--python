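"""Peptide-level deuterium uptake quantification.

Converts spectra to centroid masses, centroid differences to deuteron
counts, and normalizes uptake to each peptide's measured full-deuteration
(FD) level — the denominator the percent-exchange scale is defined on.
Theoretical maxD enters only for back-exchange reporting, never as the
normalization denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DELTA_MASS_D, PROTON_MASS, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

#: centroid differences slightly below zero (early-timepoint noise) are
#: clamped; anything more negative signals swapped inputs
NEGATIVE_UPTAKE_TOLERANCE = -0.2

NORMALIZED_COLUMNS = [
    "peptide_id", "chain", "start", "end", "sequence", "charge",
    "state", "time_s", "replicate", "deuterons",
    "percent_D", "fd_deuterons", "max_d", "back_exchange",
]


@dataclass(frozen=True)
class Spectrum:
    """A stick spectrum (centroided m/z, intensity pairs) of one peptide."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


def centroid(spectrum: Spectrum) -> tuple[float, float]:
    """Intensity-weighted mean m/z and the corresponding neutral mass (Da)."""
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ValueError("cannot centroid an all-zero spectrum")
    c_mz = float(np.dot(spectrum.mz, spectrum.intensity) / total)
    neutral = spectrum.charge * (c_mz - PROTON_MASS)
    return c_mz, neutral


def deuterons_from_centroids(centroid_labeled: float, centroid_unlabeled: float) -> float:
    """Deuteron count from the neutral centroid-mass shift.

    The shift is divided by the H->D mass increment; counts are fractional.
    Shifts within -0.2 D of zero are clamped to 0 with a warning (centroid
    noise on early timepoints); larger negative shifts indicate swapped
    labeled/unlabeled inputs and raise.
    """
    if centroid_labeled <= 0 or centroid_unlabeled <= 0:
        raise ValueError("neutral centroid masses must be positive")
    d = (centroid_labeled - centroid_unlabeled) / DELTA_MASS_D
    if d < NEGATIVE_UPTAKE_TOLERANCE:
        raise ValueError(
            f"labeled centroid is {-d:.2f} D below unlabeled — inputs look swapped"
        )
    if d < 0:
        warnings.warn(f"negative uptake {d:.3f} D clamped to 0", stacklevel=2)
        return 0.0
    return d


def theoretical_maxd(sequence: str, f_D2O: float, n_term_excluded: int = 1) -> float:
    """Maximum retainable deuterons of a peptide.

    Backbone amides minus the excluded N-terminal residue(s) minus prolines
    past the exclusion, scaled by the labeling D2O fraction.  Floors at 0
    for degenerate peptides (e.g. all-proline).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    if n_term_excluded not in (1, 2):
        raise ValueError("n_term_excluded must be 1 or 2")
    n_pro = sequence[n_term_excluded:].count("P")
    sites = len(sequence) - n_term_excluded - n_pro
    return max(0, sites) * f_D2O


def fd_average(fd_table: pd.DataFrame, outlier_sd: float = 3.0) -> pd.DataFrame:
    """Mean FD deuteron level per peptide x charge, averaging replicates.

    Replicates farther than ``outlier_sd`` standard deviations from their
    peptide's mean are flagged in the log (they are not removed; flagging
    mirrors manual spectrum-quality review).
    """
    g = fd_table.groupby(["peptide_id", "charge"], sort=False)["deuterons"]
    stats = g.agg(fd_deuterons="mean", fd_sd="std", n="size").reset_index()
    flagged = fd_table.merge(stats, on=["peptide_id", "charge"])
    with np.errstate(invalid="ignore"):
        z = (flagged["deuterons"] - flagged["fd_deuterons"]).abs() / flagged["fd_sd"]
    for _, row in flagged[z > outlier_sd].iterrows():
        logger.warning(
            "FD outlier: %s z=%d replicate %d (%.2f D vs mean %.2f D)",
            row["peptide_id"], row["charge"], row["replicate"],
            row["deuterons"], row["fd_deuterons"],
        )
    return stats[["peptide_id", "charge", "fd_deuterons"]]


def fd_normalize(
    records: pd.DataFrame,
    fd_table: pd.DataFrame,
    f_D2O: float,
    n_term_excluded: int = 1,
) -> pd.DataFrame:
    """Normalize uptake records to each peptide's measured FD level.

    percent_D = 100 * deuterons / mean FD deuterons (per peptide x charge);
    back_exchange = 1 - FD / theoretical maxD.  Peptides without a usable
    FD entry (missing, or FD <= 0) are dropped and logged.  Charge states
    remain separate measurement series.
    """
    fd = fd_average(fd_table)
    bad = fd[fd["fd_deuterons"] <= 0]
    for _, row in bad.iterrows():
        logger.warning(
            "dropping %s z=%d: nonpositive FD level %.3f",
            row["peptide_id"], row["charge"], row["fd_deuterons"],
        )
    fd = fd[fd["fd_deuterons"] > 0]
    merged = records.merge(fd, on=["peptide_id", "charge"], how="left")
    missing = merged["fd_deuterons"].isna()
    if missing.any():
        for key in merged.loc[missing, ["peptide_id", "charge"]].drop_duplicates().itertuples(index=False):
            logger.warning("dropping %s z=%d: no FD reference", key.peptide_id, key.charge)
        merged = merged[~missing].copy()
    if merged.empty:
        raise ValueError("no peptide has a usable FD reference")
    merged["max_d"] = [
        theoretical_maxd(s, f_D2O, n_term_excluded) for s in merged["sequence"]
    ]
    merged["percent_D"] = 100.0 * merged["deuterons"] / merged["fd_deuterons"]
    merged["back_exchange"] = 1.0 - merged["fd_deuterons"] / merged["max_d"]
    return merged[NORMALIZED_COLUMNS]


def back_exchange_summary(normalized: pd.DataFrame) -> dict[str, float]:
    """Dataset-level back-exchange statistics over peptides (not records).

    Each peptide contributes one value (its charge-state series averaged)
    so heavily sampled peptides do not dominate the median.
    """
    if normalized.empty:
        raise ValueError("empty normalized table")
    per_series = normalized.groupby(["peptide_id", "charge"], sort=False)["back_exchange"].first()
    per_peptide = per_series.groupby("peptide_id").mean()
    q1, med, q3 = np.percentile(per_peptide, [25, 50, 75])
    return {
        "n_peptides": int(per_peptide.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "median_percent": float(100.0 * med),
    }
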