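"""Column-pair coevolution statistics over a multiple sequence alignment.

Four measures are computed for every column pair: raw mutual information
(MI, in nats), MI normalized by the pair's joint entropy (MIr), MI with the
average-product correction subtracted (MIp), and the Pearson chi-squared
association statistic of the 20×20 pair-count table (Kai).  Pairwise
statistics are reduced to a per-site scalar (mean or max over partners)
for use as a variant feature.

Frequencies are unweighted counts with pairwise-complete gap deletion;
columns exceeding the gap-fraction filter are masked entirely (missing, not
zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MSAlignment

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


@dataclass
class CoevolutionMatrices:
    """Symmetric L×L matrices (NaN where undefined, including the diagonal)."""

    mi: np.ndarray
    mir: np.ndarray
    mip: np.ndarray
    kai: np.ndarray
    n_eff: np.ndarray  # usable (ungapped-in-both) rows per pair

    @property
    def n_cols(self) -> int:
        return self.mi.shape[0]


def _encode(msa: MSAlignment) -> np.ndarray:
    """Rows×columns integer matrix; gaps / non-standard letters are -1."""
    return np.array(
        [[_AA_INDEX.get(ch, -1) for ch in seq] for seq in msa.sequences], dtype=np.int64
    )


def column_entropy(msa: MSAlignment, column: int) -> float:
    """Shannon entropy (nats) of a 1-based alignment column, gaps excluded."""
    enc = _encode(msa)[:, column - 1]
    enc = enc[enc >= 0]
    if enc.size == 0:
        return float("nan")
    counts = np.bincount(enc, minlength=20).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _pair_stats(ci: np.ndarray, cj: np.ndarray) -> tuple[float, float, float, int]:
    """MI, joint entropy, chi-squared for two encoded columns (gap == -1)."""
    ok = (ci >= 0) & (cj >= 0)
    n = int(ok.sum())
    if n < 2:
        return np.nan, np.nan, np.nan, n
    joint = np.zeros((20, 20))
    np.add.at(joint, (ci[ok], cj[ok]), 1.0)
    pj = joint / n
    pi_m = pj.sum(axis=1)
    pj_m = pj.sum(axis=0)
    nz = pj > 0
    h_joint = float(-(pj[nz] * np.log(pj[nz])).sum())
    outer = np.outer(pi_m, pj_m)
    mi = float((pj[nz] * np.log(pj[nz] / outer[nz])).sum())
    expected = outer * n
    enz = expected > 0
    kai = float(((joint[enz] - expected[enz]) ** 2 / expected[enz]).sum())
    return mi, h_joint, kai, n


def pairwise_coevolution(msa: MSAlignment, max_gap_fraction: float = 0.5) -> CoevolutionMatrices:
    """Compute MI / MIr / MIp / Kai for all column pairs.

    Columns whose gap fraction exceeds ``max_gap_fraction`` yield missing
    cells everywhere they appear.  MIp subtracts the average-product
    correction APC(i,j) = MI̅(i,·)·MI̅(·,j)/MI̿ computed over defined
    off-diagonal cells.
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    enc = _encode(msa)
    n_rows, n_cols = enc.shape
    gap_frac = (enc < 0).mean(axis=0)
    usable = gap_frac <= max_gap_fraction

    shape = (n_cols, n_cols)
    mi = np.full(shape, np.nan)
    mir = np.full(shape, np.nan)
    kai = np.full(shape, np.nan)
    n_eff = np.zeros(shape, dtype=int)

    for i in range(n_cols):
        if not usable[i]:
            continue
        for j in range(i + 1, n_cols):
            if not usable[j]:
                continue
            m, h, k, n = _pair_stats(enc[:, i], enc[:, j])
            mi[i, j] = mi[j, i] = m
            kai[i, j] = kai[j, i] = k
            n_eff[i, j] = n_eff[j, i] = n
            if np.isfinite(m):
                r = 0.0 if h == 0.0 else m / h  # 0/0 := 0 (both columns constant)
                mir[i, j] = mir[j, i] = r

    # average-product correction on the defined off-diagonal cells
    mip = np.full(shape, np.nan)
    defined = np.isfinite(mi)
    if defined.any():
        counts = defined.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row_mean = np.where(defined, mi, 0.0).sum(axis=1) / counts
        overall = mi[defined].mean()
        if overall != 0:
            apc = np.outer(row_mean, row_mean) / overall
            mip = np.where(defined, mi - apc, np.nan)
        else:
            mip = np.where(defined, mi, np.nan)
    return CoevolutionMatrices(mi=mi, mir=mir, mip=mip, kai=kai, n_eff=n_eff)


def site_coevolution(matrices: CoevolutionMatrices, position: int,
                     reducer: str = "mean") -> dict[str, float]:
    """Reduce the pairwise statistics of a 1-based column to per-site scalars.

    Returns ``{"mi": …, "mir": …, "mip": …, "kai": …}``; a fully missing row
    yields NaN.  ``reducer`` is "mean" or "max" over the defined partners.
    """
    if not 1 <= position <= matrices.n_cols:
        raise IndexError(f"position {position} outside alignment of {matrices.n_cols} columns")
    if reducer not in ("mean", "max"):
        raise ValueError(f"reducer must be 'mean' or 'max', got {reducer!r}")
    fn = np.nanmean if reducer == "mean" else np.nanmax
    out = {}
    for name in ("mi", "mir", "mip", "kai"):
        row = getattr(matrices, name)[position - 1]
        with np.errstate(invalid="ignore"):
            out[name] = float(fn(row)) if np.isfinite(row).any() else float("nan")
    return out
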