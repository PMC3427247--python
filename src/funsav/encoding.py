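"""Per-variant feature-vector assembly.

Every per-residue feature family is replicated across a sliding window of
(default) 15 positions named V1…V15, with the mutated residue at the centre
(V8).  The PSSM block is flattened to PSSM_V1…PSSM_V300.  Scalar features
(mass change, residue identities, annotation distances) are emitted once.
Missing values are preserved into the matrix — imputation happens only
inside the model stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AA1, PSSMProfile, Structure, VariantRecord
from . import coevolution as coev
from . import sequence_features as seqf
from . import structure_features as strf


class EncodingError(ValueError):
    """Raised when a variant cannot be mapped onto its feature sources."""


@dataclass
class ProteinFeatureSet:
    """All per-residue feature sources for one protein chain.

    ``per_residue`` is indexed by chain position 1…L with one named column
    per feature family (network, exposure, accessibility, backbone,
    conservation, coevolution, auxiliary scores...).
    """

    protein_id: str
    chain: str
    sequence: str
    per_residue: pd.DataFrame
    pssm: PSSMProfile | None = None
    seqnum_to_pos: dict[int, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)


def featurize_protein(structure: Structure, chain: str,
                      pssm: PSSMProfile | None = None,
                      msa=None, aux_scores: pd.DataFrame | None = None,
                      contact_cutoff: float = 6.5, hse_radius: float = 13.0,
                      sasa_probe: float = 1.4, sasa_points: int = 960,
                      coevolution_reducer: str = "mean") -> ProteinFeatureSet:
    """Compute every per-residue feature family for one chain.

    The MSA (when given) must be a gap-free-coordinate alignment whose
    columns correspond to chain positions; the PSSM likewise.  Auxiliary
    per-position tool scores are joined by position and passed through.
    """
    ch = structure.chain(chain)
    n = len(ch.residues)
    frames = []

    net = strf.build_contact_network(structure, chain, cutoff=contact_cutoff)
    props = strf.network_properties(net)
    props.index = pd.RangeIndex(1, n + 1, name="position")
    frames.append(props)

    acc = strf.sasa(structure, chain, probe=sasa_probe, n_points=sasa_points)
    frames.append(acc.table)
    frames.append(strf.half_sphere_exposure(structure, chain, radius=hse_radius,
                                            surface_points=acc.surface_points))
    frames.append(strf.backbone_geometry(structure, chain))
    frames.append(strf.hydrogen_bonds(structure, chain).to_frame())

    bfac = pd.Series([r.mean_bfactor() for r in ch.residues],
                     index=pd.RangeIndex(1, n + 1, name="position"), name="B_factor")
    frames.append(bfac.to_frame())

    per_residue = pd.concat(frames, axis=1)

    if pssm is not None:
        if len(pssm) != n:
            raise EncodingError(
                f"PSSM length {len(pssm)} != chain length {n} for {structure.id}/{chain}")
        per_residue["Con"] = [seqf.conservation_score(pssm, p) for p in range(1, n + 1)]

    if msa is not None:
        if msa.n_cols != n:
            raise EncodingError(
                f"MSA width {msa.n_cols} != chain length {n} for {structure.id}/{chain}")
        mats = coev.pairwise_coevolution(msa)
        site = [coev.site_coevolution(mats, p, reducer=coevolution_reducer)
                for p in range(1, n + 1)]
        per_residue["Co_MI"] = [s["mi"] for s in site]
        per_residue["Co_MIr"] = [s["mir"] for s in site]
        per_residue["Co_MIp"] = [s["mip"] for s in site]
        per_residue["Co_Kai"] = [s["kai"] for s in site]

    if aux_scores is not None:
        for col in aux_scores.columns:
            series = pd.Series(np.nan, index=per_residue.index)
            for pos in per_residue.index:
                key = (structure.id, pos)
                if key in aux_scores.index:
                    series[pos] = aux_scores.at[key, col]
            per_residue[col.capitalize() if col.islower() else col] = series

    return ProteinFeatureSet(
        protein_id=structure.id, chain=chain, sequence=ch.sequence(),
        per_residue=per_residue, pssm=pssm,
        seqnum_to_pos={r.seqnum: i + 1 for i, r in enumerate(ch.residues)},
    )


def map_variant_position(features: ProteinFeatureSet, variant: VariantRecord) -> int:
    """Chain position (1…L) of a variant given in author residue numbering.

    Raises :class:`EncodingError` (the mapping report) when the numbered
    residue is absent or its wild type disagrees with the structure.
    """
    pos = features.seqnum_to_pos.get(variant.position)
    if pos is None:
        raise EncodingError(
            f"variant {variant.key()}: residue number {variant.position} not in chain "
            f"{features.chain} (numbering range "
            f"{min(features.seqnum_to_pos)}–{max(features.seqnum_to_pos)})")
    observed = features.sequence[pos - 1]
    if observed != "X" and observed != variant.wild_type:
        raise EncodingError(
            f"variant {variant.key()}: wild type {variant.wild_type} does not match "
            f"structure residue {observed} at {variant.position}")
    return pos


def encode_variant(variant: VariantRecord, features: ProteinFeatureSet,
                   window: int = 15,
                   site_features: pd.Series | None = None) -> dict[str, float]:
    """Named feature vector for one variant.

    Per-residue families contribute ``window`` columns suffixed _V1…_V15
    (centre = V⌈window/2⌉); the PSSM block contributes window×20 columns;
    residue identities are one-hot encoded (wt_*/mut_*); scalar features
    (MW_ch, annotation-site features) appear once.  Off-chain window
    positions yield missing values (PSSM: zeros) plus in_range flags.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    center = map_variant_position(features, variant)
    half = window // 2

    vec: dict[str, float] = {}
    for k in range(window):
        pos = center - half + k
        suffix = f"_V{k + 1}"
        in_range = 1 <= pos <= features.length
        vec[f"in_range{suffix}"] = float(in_range)
        for col in features.per_residue.columns:
            vec[f"{col}{suffix}"] = (
                float(features.per_residue.at[pos, col]) if in_range else np.nan
            )

    if features.pssm is not None:
        enc = seqf.encode_pssm_window(features.pssm, center, window=window)
        vec.update(zip(enc.names, enc.values.tolist()))

    vec["MW_ch"] = seqf.mass_weight_change(variant.wild_type, variant.mutant)
    for aa in AA1:
        vec[f"wt_{aa}"] = float(variant.wild_type == aa)
        vec[f"mut_{aa}"] = float(variant.mutant == aa)

    if site_features is not None:
        for name, value in site_features.items():
            vec[name] = float(value) if value is not None else np.nan
    return vec


@dataclass
class AssemblyReport:
    constant_columns: list[str]
    n_rows: int
    n_columns: int


def assemble_matrix(vectors: list[dict[str, float]], variants: list[VariantRecord],
                    ) -> tuple[pd.DataFrame, AssemblyReport]:
    """Stack per-variant vectors into a labeled feature matrix.

    Labels map disease → 1, neutral → −1 (unknown → 0, excluded from
    supervised operations).  Columns absent from some vectors become
    missing values; all-constant columns are flagged in the report.
    Duplicate variant keys raise.
    """
    if len(vectors) != len(variants):
        raise ValueError("one vector per variant required")
    keys = [v.key() for v in variants]
    if len(set(keys)) != len(keys):
        raise ValueError("conflicting duplicate variant rows")
    index = pd.Index(["|".join(map(str, k)) for k in keys], name="variant")
    df = pd.DataFrame(list(vectors), index=index)
    label_map = {"disease": 1, "neutral": -1, "unknown": 0}
    df["label"] = [label_map[v.label] for v in variants]
    feature_cols = [c for c in df.columns if c != "label"]
    constant = [c for c in feature_cols if df[c].nunique(dropna=True) <= 1]
    report = AssemblyReport(constant_columns=constant, n_rows=len(df),
                            n_columns=len(feature_cols))
    return df, report


def feature_manifest(df: pd.DataFrame) -> dict[str, dict]:
    """Column manifest: family, window position and block index per column."""
    manifest = {}
    for col in df.columns:
        if col == "label":
            continue
        entry: dict = {"family": col, "position": None}
        if "_V" in col:
            family, _, vpos = col.rpartition("_V")
            if vpos.isdigit():
                entry = {"family": family, "position": int(vpos)}
        manifest[col] = entry
    return manifest


def write_manifest(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_manifest(df), fh, indent=1)
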