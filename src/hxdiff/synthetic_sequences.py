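"""Synthetic stand-in sequences for the ISB heterotrimer.

These are NOT the real INCENP/Survivin/Borealin sequences (which are
deposited data this package does not bundle); they are deterministic
pseudo-random sequences with protein-like composition, with the charged
residues named in the phase-separation interface analysis pinned at their
construct positions (INCENP D27/E35/E36/E39/E40/E42; Borealin K37/K63 and
a basic patch at 140-150).  Everything downstream — exchange simulation,
normalization, consensus mapping — depends only on lengths, proline
placement and these identities, so the stand-ins exercise the pipeline
exactly as the real constructs would.
"""

from __future__ import annotations

import numpy as np

from .chains import ProteinChain

# near-average composition, prolines slightly downweighted
_AA = "ACDEFGHIKLMNQRSTVWY"
_WEIGHTS = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.9, 9.7, 2.4, 4.0, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9]
)
_P_FRACTION = 0.04
_SEQ_SEED = 20220513  # fixed: the stand-in world is stated once, not tuned

_PINNED = {
    "INCENP": {27: "D", 35: "E", 36: "E", 39: "E", 40: "E", 42: "E"},
    "Borealin": {37: "K", 63: "K", 140: "K", 142: "R", 145: "K", 148: "K", 150: "R"},
    "Survivin": {},
}

_LENGTHS = {"INCENP": 58, "Survivin": 142, "Borealin": 280}


def _random_sequence(rng: np.random.Generator, length: int, pinned: dict[int, str]) -> str:
    w = _WEIGHTS / _WEIGHTS.sum() * (1.0 - _P_FRACTION)
    letters = list(_AA) + ["P"]
    probs = np.append(w, _P_FRACTION)
    seq = list(rng.choice(letters, size=length, p=probs))
    seq[0] = "M"
    for pos, aa in pinned.items():
        seq[pos - 1] = aa
    return "".join(seq)


def default_isb_chains() -> list[ProteinChain]:
    """The three synthetic stand-in chains (INCENP 1-58, Survivin, Borealin)."""
    rng = np.random.default_rng(_SEQ_SEED)
    chains = []
    for name in ("INCENP", "Survivin", "Borealin"):
        chains.append(ProteinChain(name, _random_sequence(rng, _LENGTHS[name], _PINNED[name])))
    return chains
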