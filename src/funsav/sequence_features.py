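"""Sequence-derived per-position features.

Covers the features computed directly from sequence-level inputs: the
conservation score (Shannon entropy of the PSSM frequency row — low values
mean high conservation), the residue mass change upon mutation, and the
sliding-window PSSM block with V-position naming.  Externally computed
per-position predictors (PSIPRED, DISOPRED, SSpro, PSIC, TANGO) are passed
through as optional columns, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PSSM_AA_ORDER, PSSMProfile

#: Average (isotope-averaged) residue masses in Da, i.e. amino acid minus water.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


class AlphabetError(ValueError):
    """Raised for residues outside the 20-letter standard alphabet."""


def conservation_score(profile: PSSMProfile, position: int) -> float:
    """Shannon entropy (nats) of the frequency row at a 1-based position.

    0 for a perfectly conserved (one-hot) position, ln(20) for a uniform
    one; lower values mean higher conservation.
    """
    if not 1 <= position <= len(profile):
        raise IndexError(f"position {position} outside profile of length {len(profile)}")
    p = profile.freqs[position - 1]
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def mass_weight_change(wild: str, mutant: str,
                       table: dict[str, float] | None = None) -> float:
    """Signed residue mass change mass(mutant) − mass(wild) in Da."""
    table = table or RESIDUE_MASSES
    for letter in (wild, mutant):
        if letter not in table:
            raise AlphabetError(f"non-standard residue {letter!r}")
    return table[mutant] - table[wild]


@dataclass
class WindowEncoding:
    """A windowed feature block with V-position names and range flags."""

    values: np.ndarray
    names: list[str]
    in_range: np.ndarray  # bool per window position


def encode_pssm_window(profile: PSSMProfile, position: int, window: int = 15,
                       matrix: str = "logodds") -> WindowEncoding:
    """Flatten the PSSM rows of a window centred on ``position`` (1-based).

    Rows are ordered N→C and the result is named PSSM_V1 … PSSM_V(window*20);
    at a window of 15, element V160 is the 20th column of the 8th (centre)
    row.  ``matrix`` selects the log-odds scores (the matrix elements proper,
    default) or the frequency rows.  Window positions that overhang the chain
    are zero-padded, with the per-position ``in_range`` flag cleared.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if not 1 <= position <= len(profile):
        raise IndexError(f"position {position} outside profile of length {len(profile)}")
    if matrix not in ("logodds", "freqs"):
        raise ValueError(f"matrix must be 'logodds' or 'freqs', got {matrix!r}")
    source = profile.logodds if matrix == "logodds" else profile.freqs
    half = window // 2
    values = np.zeros(window * 20)
    in_range = np.zeros(window, dtype=bool)
    for k in range(window):
        pos = position - half + k  # 1-based
        if 1 <= pos <= len(profile):
            values[k * 20:(k + 1) * 20] = source[pos - 1]
            in_range[k] = True
    names = [f"PSSM_V{i + 1}" for i in range(window * 20)]
    return WindowEncoding(values=values, names=names, in_range=in_range)
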