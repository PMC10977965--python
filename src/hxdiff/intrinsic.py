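"""Intrinsic amide exchange rates.

Two selectable models:

``uniform``
    Every exchange-competent amide gets the same rate, anchored so that an
    unprotected residue is ~63% exchanged after 100 s at pD 7.5, 298 K
    (k = 0.01 /s).  This is the model used throughout the test suite: it
    makes peptide-level sums and time-shift factors exactly analytic.

``neighbor``
    The standard empirical poly-alanine-referenced scheme: acid-, base- and
    water-catalysed pathways, each modulated by multiplicative side-chain
    factors of the residue itself and of its left neighbor, with Arrhenius
    temperature scaling.  The coefficient table follows the values commonly
    distributed with HX analysis tools and is approximate; downstream
    analysis normalizes to a measured full-deuteration reference, so
    absolute intrinsic rates never enter any reported quantity.

Both models return 0 exactly at prolines (no amide H) and at the first
residue of the chain (free amine, label lost to back exchange).
"""

from __future__ import annotations

import numpy as np

from .chains import ProteinChain

R_GAS_KCAL = 1.987204e-3  # kcal / (mol K)
_T_REF = 293.0
# activation energies (kcal/mol) for acid, base, water catalysis
_EA = {"acid": 14.0, "base": 17.0, "water": 19.0}
# poly-DL-alanine reference rate constants at 293 K, per minute
_K_ACID_REF = 10.0**1.62   # 1/(M min)
_K_BASE_REF = 10.0**10.18  # 1/(M min)
_K_WATER_REF = 10.0**-1.5  # 1/min
_PKD = 15.05  # ion product of D2O

# log10 side-chain factors (acid_left, acid_right, base_left, base_right);
# "left" = factor contributed when the residue owns the amide, "right" =
# when it precedes the amide.  Approximate rendering of the standard table.
_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (-0.10, -0.51, 0.80, 0.83),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}


def _check_conditions(pD: float, temperature: float) -> None:
    if not 2.0 <= pD <= 12.0:
        raise ValueError(f"pD {pD} outside supported range [2, 12]")
    if not 273.0 <= temperature <= 320.0:
        raise ValueError(f"temperature {temperature} K outside supported range [273, 320]")


def default_intrinsic_rates(
    chain: ProteinChain,
    pD: float = 7.5,
    temperature: float = 298.0,
    model: str = "uniform",
) -> np.ndarray:
    """Per-residue intrinsic exchange rates k_int in 1/s.

    The returned vector is aligned to ``chain.sequence`` (index 0 is the
    chain's first residue).  Entries are 0 exactly at prolines and at the
    first residue, positive elsewhere.  Deterministic given its inputs.
    """
    _check_conditions(pD, temperature)
    seq = chain.sequence
    n = len(seq)
    if model == "uniform":
        # anchored at 0.01 /s for pD 7.5, 298 K
        base = 0.01 * 10.0 ** (pD - 7.5)
        base *= np.exp(-_EA["base"] / R_GAS_KCAL * (1.0 / temperature - 1.0 / 298.0))
        k = np.full(n, base)
    elif model == "neighbor":
        k = _neighbor_rates(seq, pD, temperature)
    else:
        raise ValueError(f"unknown intrinsic-rate model {model!r}")
    k[0] = 0.0
    for i, aa in enumerate(seq):
        if aa == "P":
            k[i] = 0.0
    return k


def _neighbor_rates(seq: str, pD: float, temperature: float) -> np.ndarray:
    conc_d = 10.0**-pD
    conc_od = 10.0 ** (pD - _PKD)
    arr = {
        path: np.exp(-_EA[path] / R_GAS_KCAL * (1.0 / temperature - 1.0 / _T_REF))
        for path in _EA
    }
    k = np.zeros(len(seq))
    for i in range(1, len(seq)):
        own, prev = seq[i], seq[i - 1]
        fa = 10.0 ** (_FACTORS[own][0] + _FACTORS[prev][1])
        fb = 10.0 ** (_FACTORS[own][2] + _FACTORS[prev][3])
        k_min = (
            fa * _K_ACID_REF * conc_d * arr["acid"]
            + fb * _K_BASE_REF * conc_od * arr["base"]
            + fb * _K_WATER_REF * arr["water"]
        )
        k[i] = k_min / 60.0
    return k
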