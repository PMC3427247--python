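"""Synthetic fixture generation.

Generates every input the pipeline consumes — toy protein structures with
full backbones, PSI-BLAST-style profiles, alignments with planted
covariation, labeled feature datasets with planted informative features,
and external-tool score tables — so each stage is testable without
downloads.  Generators are pure functions of their spec: the same seed
yields byte-identical files.

The emulation targets the statistical structure the features assume
(helical vs extended geometry, conserved vs variable columns, class-shifted
feature distributions, complementary tool signal), not real-protein
realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .io_formats import (
    AA1, AA1_TO_3, Atom, Chain, MSAlignment, PSSMProfile, PSSM_AA_ORDER, Residue,
    Structure, TOOL_COLUMNS, CATEGORICAL_TOOLS, VariantRecord,
    write_msa, write_pssm, write_structure, write_variant_table,
)

GEOMETRIES = ("ideal-helix", "extended", "random-coil")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    n_residues: int = 40
    geometry: str = "ideal-helix"
    n_variants: int = 12
    class_balance: float = 0.5
    msa_rows: int = 200
    msa_cols: int | None = None       # defaults to n_residues
    covarying_pairs: list = field(default_factory=list)  # [(i, j, eps), ...] 1-based
    n_informative: int = 3
    n_noise: int = 50
    effect_sizes: list = field(default_factory=lambda: [2.0, 2.0, 2.0])
    n_samples: int = 400
    tool_signal: float = 1.0
    tool_noise: float = 1.0
    tool_missingness: dict = field(default_factory=dict)  # column -> rate


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def make_structure(spec: SyntheticSpec, protein_id: str = "synth",
                   chain_id: str = "A") -> Structure:
    """Toy protein: full backbone + Cβ on the requested geometry.

    ideal-helix uses canonical α-helix torsions (rise ≈ 1.5 Å, ≈ 100° twist
    per residue); extended is the fully stretched chain; random-coil draws
    torsions from broad allowed regions.  Sequences are uniform over the 20
    residues; B-factors are lognormal (median ≈ 20 Å², σ_log 0.3) shared
    within a residue.
    """
    if spec.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if spec.geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {spec.geometry!r}; options {GEOMETRIES}")
    rng = _rng(spec.seed)
    n = spec.n_residues
    if spec.geometry == "ideal-helix":
        phi, psi = geometry.HELIX_PHI_PSI
        phi = np.full(n, phi)
        psi = np.full(n, psi)
    elif spec.geometry == "extended":
        phi = np.full(n, geometry.EXTENDED_PHI_PSI[0])
        psi = np.full(n, geometry.EXTENDED_PHI_PSI[1])
    else:
        phi = rng.uniform(-150, -50, size=n)
        psi = rng.uniform(-60, 160, size=n)
    backbone = geometry.build_backbone(n, phi, psi)
    sequence = rng.choice(list(AA1), size=n)
    bfac = np.exp(rng.normal(np.log(20.0), 0.3, size=n))
    residues = []
    for i, coords in enumerate(backbone):
        resname = AA1_TO_3[sequence[i]]
        atoms = [
            Atom("N", "N", coords["N"], bfactor=bfac[i]),
            Atom("CA", "C", coords["CA"], bfactor=bfac[i]),
            Atom("C", "C", coords["C"], bfactor=bfac[i]),
            Atom("O", "O", coords["O"], bfactor=bfac[i]),
        ]
        if resname != "GLY":
            atoms.append(Atom("CB", "C", coords["CB"], bfactor=bfac[i]))
        residues.append(Residue(seqnum=i + 1, icode=" ", name=resname, atoms=atoms))
    return Structure(id=protein_id, chains=[Chain(id=chain_id, residues=residues)])


# ---------------------------------------------------------------------------
# alignments and profiles
# ---------------------------------------------------------------------------

def make_msa(spec: SyntheticSpec) -> MSAlignment:
    """Alignment with independent Dirichlet-profile columns and planted
    covarying pairs.

    Each independent column draws a 20-state profile from Dirichlet(0.5)
    and samples rows i.i.d.  A planted pair (i, j, ε) copies column i's
    states through a fixed residue bijection, each row decoupled to an
    independent draw with probability 2ε (flip noise ε ∈ [0, 0.5]): ε=0
    yields a deterministic coupling whose MI equals the column entropy,
    ε=0.5 a fully independent pair.
    """
    rng = _rng(spec.seed + 1)
    n_rows = spec.msa_rows
    n_cols = spec.msa_cols or spec.n_residues
    if n_rows < 2:
        raise ValueError("alignment needs >= 2 rows")
    letters = np.array(list(AA1))
    cols = np.empty((n_rows, n_cols), dtype="U1")
    for c in range(n_cols):
        profile = rng.dirichlet(np.full(20, 0.5))
        cols[:, c] = rng.choice(letters, size=n_rows, p=profile)
    for pair in spec.covarying_pairs:
        i, j, eps = pair
        if not (1 <= i <= n_cols and 1 <= j <= n_cols):
            raise ValueError(f"covarying pair {pair} out of range 1..{n_cols}")
        mapping = dict(zip(letters, rng.permutation(letters)))
        source = cols[:, i - 1]
        target = np.array([mapping[a] for a in source])
        if not 0 <= eps <= 0.5:
            raise ValueError(f"flip noise must be in [0, 0.5], got {eps}")
        flip = rng.random(n_rows) < 2 * eps
        if flip.any():
            profile = rng.dirichlet(np.full(20, 0.5))
            target[flip] = rng.choice(letters, size=int(flip.sum()), p=profile)
        cols[:, j - 1] = target
    return MSAlignment(
        ids=[f"seq{r + 1}" for r in range(n_rows)],
        sequences=["".join(cols[r]) for r in range(n_rows)],
    )


def make_pssm(sequence: str, seed: int = 0, concentration: float = 2.0) -> PSSMProfile:
    """Profile for a sequence: Dirichlet frequency rows biased toward the
    native residue, with integer log-odds against a uniform background."""
    rng = _rng(seed + 2)
    L = len(sequence)
    freqs = np.zeros((L, 20))
    order = {aa: k for k, aa in enumerate(PSSM_AA_ORDER)}
    for i, aa in enumerate(sequence):
        alpha = np.full(20, 0.3)
        if aa in order:
            alpha[order[aa]] += concentration
        freqs[i] = rng.dirichlet(alpha)
    # integer percentages (the file dialect) then renormalized frequencies
    pct = np.rint(freqs * 100).astype(int)
    with np.errstate(divide="ignore"):
        logodds = np.where(pct > 0, np.rint(2 * np.log2(np.maximum(pct, 1) / 5.0)), -4)
    rowsum = pct.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1
    return PSSMProfile(sequence=sequence, logodds=logodds.astype(int),
                       freqs=pct / rowsum)


# ---------------------------------------------------------------------------
# labeled dataset with planted signal
# ---------------------------------------------------------------------------

def make_labeled_dataset(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix with planted informative features plus a tool-score table.

    Informative feature k is N(y·d_k/2, 1) with effect size d_k (class-mean
    separation in SD units); noise features are standard normal.  Tool
    scores are y·s + N(0, σ) with signal s = ``tool_signal`` (0 → pure
    noise) and σ = ``tool_noise``; categorical tools are thresholded to
    {1, −1}; missingness is applied per column at the stated rate.
    """
    if not 0 < spec.class_balance < 1:
        raise ValueError("class balance must be in (0, 1)")
    if spec.n_informative and len(spec.effect_sizes) != spec.n_informative:
        raise ValueError("need one effect size per informative feature")
    rng = _rng(spec.seed + 3)
    n = spec.n_samples
    n_pos = int(round(n * spec.class_balance))
    y = np.array([1] * n_pos + [-1] * (n - n_pos))
    rng.shuffle(y)
    cols = {}
    for k in range(spec.n_informative):
        cols[f"informative_{k}"] = y * spec.effect_sizes[k] / 2.0 + rng.normal(size=n)
    for k in range(spec.n_noise):
        cols[f"noise_{k:03d}"] = rng.normal(size=n)
    df = pd.DataFrame(cols, index=pd.Index([f"v{i}" for i in range(n)], name="variant"))
    df["label"] = y

    tools = {}
    for col in TOOL_COLUMNS:
        raw = y * spec.tool_signal + rng.normal(scale=spec.tool_noise, size=n)
        if col in CATEGORICAL_TOOLS:
            raw = np.where(raw >= 0, 1.0, -1.0)
        tools[col] = raw
    tool_df = pd.DataFrame(tools, index=df.index)
    for col, rate in spec.tool_missingness.items():
        mask = rng.random(n) < rate
        tool_df.loc[mask, col] = np.nan
    return df, tool_df


# ---------------------------------------------------------------------------
# variants, scores and complete fixture directories
# ---------------------------------------------------------------------------

def make_variants(structure: Structure, spec: SyntheticSpec) -> list[VariantRecord]:
    """Variants at spread positions with alternating labels."""
    rng = _rng(spec.seed + 4)
    chain = structure.chains[0]
    n = len(chain.residues)
    k = min(spec.n_variants, n)
    positions = np.linspace(1, n, k).round().astype(int)
    positions = np.unique(positions)
    records = []
    for i, pos in enumerate(positions):
        res = chain.residues[pos - 1]
        wt = res.one_letter
        mut = rng.choice([a for a in AA1 if a != wt])
        label = "disease" if i % 2 == 0 else "neutral"
        records.append(VariantRecord(protein_id=structure.id, chain=chain.id,
                                     position=int(res.seqnum), wild_type=wt,
                                     mutant=mut, label=label))
    return records


def make_tool_scores(variants: list[VariantRecord], spec: SyntheticSpec) -> pd.DataFrame:
    rng = _rng(spec.seed + 5)
    rows = []
    for v in variants:
        y = 1.0 if v.label == "disease" else -1.0
        row = {"protein_id": v.protein_id, "chain": v.chain,
               "position": v.position, "mutant": v.mutant}
        for col in TOOL_COLUMNS:
            raw = y * spec.tool_signal + rng.normal(scale=spec.tool_noise)
            row[col] = (1.0 if raw >= 0 else -1.0) if col in CATEGORICAL_TOOLS else raw
        rows.append(row)
    return pd.DataFrame(rows)


def make_annotations(structure: Structure, spec: SyntheticSpec) -> pd.DataFrame:
    """A couple of plausible FT-style site records inside the chain."""
    rng = _rng(spec.seed + 6)
    n = len(structure.chains[0].residues)
    rows = []
    for key in ("ACT_SITE", "BINDING", "METAL"):
        pos = int(rng.integers(1, n + 1))
        rows.append({"protein_id": structure.id, "ft_key": key,
                     "start": pos, "end": pos})
    return pd.DataFrame(rows)


def make_fixture_dir(out_dir, spec: SyntheticSpec) -> dict:
    """Emit a complete fixture directory (PDB, PSSM, MSA, variant, score and
    annotation tables plus a manifest) and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure = make_structure(spec)
    chain = structure.chains[0]
    write_structure(structure, out / "synth.pdb")

    pssm = make_pssm(chain.sequence(), seed=spec.seed)
    write_pssm(pssm, out / "synth.pssm")

    msa_spec = SyntheticSpec(**{**spec.__dict__, "msa_cols": spec.n_residues})
    msa = make_msa(msa_spec)
    # first row mirrors the chain sequence so columns align with positions
    msa.sequences[0] = chain.sequence()
    write_msa(msa, out / "synth.msa.fasta")

    variants = make_variants(structure, spec)
    write_variant_table(variants, out / "variants.tsv")
    make_tool_scores(variants, spec).to_csv(out / "tool_scores.tsv", sep="\t", index=False)
    make_annotations(structure, spec).to_csv(out / "annotations.tsv", sep="\t", index=False)

    manifest = {
        "protein_id": structure.id,
        "chain": chain.id,
        "structure": "synth.pdb",
        "pssm": "synth.pssm",
        "msa": "synth.msa.fasta",
        "variants": "variants.tsv",
        "tool_scores": "tool_scores.tsv",
        "annotations": "annotations.tsv",
        "seed": spec.seed,
        "n_residues": spec.n_residues,
        "geometry": spec.geometry,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
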