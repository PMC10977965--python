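"""Isotopic envelope simulation for deuterated peptides.

The simulated envelope is the convolution of two distributions:

* the peptide's natural isotopic distribution, computed from its elemental
  formula by stick convolution over element isotope patterns, and
* the Poisson-binomial distribution of incorporated deuterons given one
  occupancy probability per exchangeable amide.

Sticks carry exact masses; merging of near-coincident sticks uses
probability-weighted mean masses, which preserves the envelope centroid
exactly.  Hence the simulated centroid shift equals
sum(site probabilities) * delta-m(D) to numerical precision — the identity
the centroiding stage is tested against.
"""

from __future__ import annotations

import numpy as np

from .constants import DELTA_MASS_D, ISOTOPES, PROTON_MASS, peptide_formula, peptide_mono_mass
from .uptake import Spectrum

#: sticks closer than this (Da) are merged with probability-weighted masses
_MERGE_WIDTH = 0.2
_PRUNE = 1e-12


def _merge(masses: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(masses)
    masses, probs = masses[order], probs[order]
    out_m: list[float] = []
    out_p: list[float] = []
    for m, p in zip(masses, probs):
        if p <= 0.0:
            continue
        if out_m and m - out_m[-1] < _MERGE_WIDTH:
            tot = out_p[-1] + p
            out_m[-1] = (out_m[-1] * out_p[-1] + m * p) / tot
            out_p[-1] = tot
        else:
            out_m.append(m)
            out_p.append(p)
    m_arr, p_arr = np.array(out_m), np.array(out_p)
    keep = p_arr > _PRUNE
    return m_arr[keep], p_arr[keep] / p_arr[keep].sum()


def _convolve(m1, p1, m2, p2) -> tuple[np.ndarray, np.ndarray]:
    masses = (m1[:, None] + m2[None, :]).ravel()
    probs = (p1[:, None] * p2[None, :]).ravel()
    return _merge(masses, probs)


def natural_isotopic_distribution(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Stick distribution (neutral masses, probabilities) of a peptide.

    Masses are absolute neutral masses in Da; probabilities sum to 1.
    """
    masses = np.array([peptide_mono_mass(sequence)])
    probs = np.array([1.0])
    for element, count in peptide_formula(sequence).items():
        iso = ISOTOPES[element]
        em = np.array([m for m, _ in iso])
        ep = np.array([p for _, p in iso])
        # binary exponentiation over atom count
        acc_m, acc_p = np.array([0.0]), np.array([1.0])
        base_m, base_p = em, ep
        n = count
        while n:
            if n & 1:
                acc_m, acc_p = _convolve(acc_m, acc_p, base_m, base_p)
            n >>= 1
            if n:
                base_m, base_p = _convolve(base_m, base_p, base_m, base_p)
        masses, probs = _convolve(masses, probs, acc_m, acc_p)
    return masses, probs


def poisson_binomial(probabilities: np.ndarray) -> np.ndarray:
    """PMF of the number of successes of independent Bernoulli trials."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("site probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for pi in p:
        pmf = np.convolve(pmf, [1.0 - pi, pi])
    return pmf


def simulate_envelope(
    sequence: str,
    site_probabilities: np.ndarray,
    charge: int,
    n_exchangeable: int | None = None,
) -> Spectrum:
    """Stick spectrum of a peptide with partially deuterated amides.

    ``site_probabilities`` holds one deuterium-occupancy probability per
    exchangeable amide (their count may be passed explicitly for
    validation).  m/z values follow
    (neutral mass + k * delta-m(D) + z * m(proton)) / z for each deuteron
    count k; intensities are normalized to sum 1.
    """
    p = np.asarray(site_probabilities, dtype=float)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if n_exchangeable is not None and len(p) != n_exchangeable:
        raise ValueError(
            f"{len(p)} site probabilities given for {n_exchangeable} exchangeable sites"
        )
    nat_m, nat_p = natural_isotopic_distribution(sequence)
    pmf = poisson_binomial(p)
    d_m = np.arange(len(pmf)) * DELTA_MASS_D
    masses, probs = _convolve(nat_m, nat_p, d_m, pmf)
    mz = (masses + charge * PROTON_MASS) / charge
    return Spectrum(mz=mz, intensity=probs, charge=charge)


def spectrum_centroid_shift(labeled: Spectrum, sequence: str) -> float:
    """Neutral centroid mass of a spectrum minus the natural centroid."""
    from .uptake import centroid

    nat_m, nat_p = natural_isotopic_distribution(sequence)
    _, neutral = centroid(labeled)
    return neutral - float(np.dot(nat_m, nat_p))
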