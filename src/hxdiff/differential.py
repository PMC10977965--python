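"""State-vs-state comparison of normalized uptake.

Sign convention: delta = perturbed (droplet) minus reference (free), so
protection acquired on phase separation appears as negative percentage
points.  Charge states are compared as separate measurement series and
only merged at the residue-consensus stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: percentage-point bin edges of the display color key, symmetric about 0
DEFAULT_BIN_EDGES = (3.0, 6.0, 10.0, 20.0)
#: significance bands and their star labels
STAR_BANDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))
#: mid-curve percent-D levels used for time-shift estimation
DEFAULT_TIMESHIFT_LEVELS = (30.0, 40.0, 50.0, 60.0, 70.0)

DIFF_COLUMNS = [
    "peptide_id", "chain", "start", "end", "charge", "time_s",
    "mean_a", "mean_b", "delta_percent", "p_value", "stars", "category",
]

_SERIES_KEY = ["peptide_id", "chain", "start", "end", "charge", "time_s"]


def stars_for_p(p: float) -> str:
    if np.isnan(p):
        return "n/a"
    for cutoff, label in STAR_BANDS:
        if p < cutoff:
            return label
    return "ns"


def welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Two-sided unpaired Welch t-test p-value.

    Returns (p, degenerate) where degenerate marks zero variance on both
    sides: equal means give p = 1, separated means p = 0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), False
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (1.0, True) if a[0] == b[0] else (0.0, True)
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue), False


def replicate_test(
    replicates_a: np.ndarray, replicates_b: np.ndarray, method: str = "welch"
) -> tuple[float, str]:
    """p-value and significance stars for one peptide x timepoint."""
    if method == "welch":
        p, _ = welch_p(replicates_a, replicates_b)
    elif method == "student":
        a, b = np.asarray(replicates_a, float), np.asarray(replicates_b, float)
        if len(a) < 2 or len(b) < 2:
            p = float("nan")
        elif np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if a[0] == b[0] else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return p, stars_for_p(p)


def classify_difference(delta_percent: float, bin_edges=DEFAULT_BIN_EDGES) -> str:
    """Signed category label for a percent difference.

    Edges are the positive half of a symmetric scale; e.g. with edges
    (3, 6, 10, 20) a delta of -12 falls in "protected_3" (bin 3 of 4) and
    +25 in "deprotected_4".  |delta| below the innermost edge is
    "no_change".
    """
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) == 0 or np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be positive, strictly increasing (symmetric half-scale)")
    mag = abs(delta_percent)
    if mag < edges[0]:
        return "no_change"
    level = int(np.searchsorted(edges, mag, side="right"))
    level = min(level, len(edges))
    side = "protected" if delta_percent < 0 else "deprotected"
    return f"{side}_{level}"


def percent_difference(
    normalized: pd.DataFrame,
    state_a: str,
    state_b: str,
    test_method: str = "welch",
    correction: str = "none",
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-peptide percent-difference table between two states.

    delta = mean percent_D of ``state_b`` - mean of ``state_a`` per peptide
    x charge x timepoint, with a replicate significance test.  Series
    present in only one state are skipped and logged.  ``correction``:
    "none" (per-test p-values, as plotted in the source experiments) or
    "holm" (family-wise over timepoints within each peptide series).
    """
    for s in (state_a, state_b):
        if s not in set(normalized["state"]):
            raise ValueError(f"state {s!r} not present in normalized table")
    # FD provenance guard: a series must be normalized against one FD level
    fd_check = normalized.groupby(["peptide_id", "charge"])["fd_deuterons"].nunique()
    if (fd_check > 1).any():
        bad = fd_check[fd_check > 1].index[0]
        raise ValueError(
            f"peptide {bad[0]} z={bad[1]}: states normalized against different FD "
            "references; differences would not be comparable"
        )
    rows = []
    for key, grp in normalized.groupby(_SERIES_KEY, sort=False):
        a = grp.loc[grp["state"] == state_a, "percent_D"].to_numpy()
        b = grp.loc[grp["state"] == state_b, "percent_D"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            logger.info("skipping %s z=%s t=%s: present in one state only", key[0], key[4], key[5])
            continue
        p, _ = welch_p(a, b) if test_method == "welch" else (replicate_test(a, b, test_method)[0], False)
        rows.append((*key, float(a.mean()), float(b.mean()), p))
    if not rows:
        raise ValueError("no peptide series shared between the two states")
    out = pd.DataFrame(rows, columns=_SERIES_KEY[:5] + ["time_s", "mean_a", "mean_b", "p_value"])
    # restore column order: key is peptide_id, chain, start, end, charge, time_s
    out = out.rename(columns={_SERIES_KEY[5]: "time_s"})
    out["delta_percent"] = out["mean_b"] - out["mean_a"]
    if correction == "holm":
        out["p_value"] = _holm_within_peptide(out)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    out["stars"] = [stars_for_p(p) for p in out["p_value"]]
    out["category"] = [classify_difference(d, bin_edges) for d in out["delta_percent"]]
    return out[DIFF_COLUMNS]


def _holm_within_peptide(diff: pd.DataFrame) -> np.ndarray:
    adjusted = diff["p_value"].to_numpy(copy=True)
    for _, idx in diff.groupby(["peptide_id", "charge"]).groups.items():
        p = diff.loc[idx, "p_value"].to_numpy()
        ok = ~np.isnan(p)
        if ok.sum() > 0:
            adj = multipletests(p[ok], method="holm")[1]
            sub = adjusted[diff.index.get_indexer(idx)]
            sub[ok] = adj
            adjusted[diff.index.get_indexer(idx)] = sub
    return adjusted


@dataclass
class TimeShift:
    label: str
    factor: float
    levels_used: tuple[float, ...]
    computable: bool = True


def time_shift_factor(
    curve_a: pd.DataFrame,
    curve_b: pd.DataFrame,
    levels=DEFAULT_TIMESHIFT_LEVELS,
    label: str = "",
) -> TimeShift:
    """Fold slowing of curve_b relative to curve_a at matched uptake levels.

    Each curve is a (time_s, percent_D) table (replicates already
    averaged).  For every requested percent-D level inside both curves'
    ranges the time to reach it is interpolated on a log-time axis after a
    first-order-kinetics linearization, w = log(-log(1 - percent/100)):
    a single-exponential uptake curve is exactly linear in (w, log t), so
    the inversion is exact for such curves and a controlled approximation
    for multi-exponential peptides.  The factor is the geometric mean of
    t_b / t_a over usable levels; a factor of 3 means curve_b takes three
    times as long to reach the same deuteration.
    """
    ta, ya = _monotone_curve(curve_a)
    tb, yb = _monotone_curve(curve_b)
    if len(ta) < 3 or len(tb) < 3:
        raise ValueError("time-shift estimation needs >= 3 timepoints per curve")
    ratios, used = [], []
    for lev in levels:
        t_a = _invert_level(ta, ya, lev)
        t_b = _invert_level(tb, yb, lev)
        if t_a is None or t_b is None:
            logger.info("level %.1f%% outside curve overlap; skipped", lev)
            continue
        ratios.append(t_b / t_a)
        used.append(lev)
    if not ratios:
        return TimeShift(label, float("nan"), (), computable=False)
    factor = float(np.exp(np.mean(np.log(ratios))))
    return TimeShift(label, factor, tuple(used))


def _invert_level(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Time at which a monotone uptake curve crosses ``level`` percent."""
    ok = (y > 0.0) & (y < 99.99)  # the linearization diverges at 0 and 100%
    t, y = t[ok], y[ok]
    if len(t) < 2 or not (y[0] <= level <= y[-1]):
        return None
    w = np.log(-np.log1p(-y / 100.0))
    w_level = np.log(-np.log1p(-level / 100.0))
    return float(10.0 ** np.interp(w_level, w, np.log10(t)))


def _monotone_curve(curve: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    c = curve.sort_values("time_s")
    t = c["time_s"].to_numpy(float)
    y = c["percent_D"].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("timepoints must be positive")
    y_mono = np.maximum.accumulate(y)
    if np.any(y_mono - y > 1e-6):
        logger.debug("uptake curve not monotone; enforcing cumulative maximum")
    return t, y_mono
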