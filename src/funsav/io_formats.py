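"""File-format ingestion and export for the variant-effect pipeline.

Reads the external dialects the pipeline consumes — PDB structures,
PSI-BLAST ASCII PSSM profiles, aligned FASTA alignments, classic DSSP
output, and delimited variant / tool-score / annotation tables — and writes
feature matrices and reports.

Positions are 1-based at every I/O boundary (PDB convention); internal
arrays are 0-based.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser

log = logging.getLogger(__name__)

AA1 = "ACDEFGHIKLMNPQRSTVWY"
#: PSI-BLAST PSSM column order
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

WATER_NAMES = {"HOH", "WAT", "DOD"}

#: UniProt FT keys accepted in annotation tables
FT_KEYS = (
    "ACT_SITE", "BINDING", "CA_BIND", "DISULFID", "DNA_BIND",
    "LIPID", "METAL", "NP_BIND", "MOD_RES",
)

TOOL_COLUMNS = ("sift", "snap", "polyphen2", "panther", "nssnpanalyzer", "phdsnp")
#: tools whose native output is a class call, encoded as disease=1 / neutral=-1
CATEGORICAL_TOOLS = ("nssnpanalyzer", "phdsnp")


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


class EmptyStructureError(FormatError):
    """Raised when a PDB file contains no protein atoms."""


# ---------------------------------------------------------------------------
# structure model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Å
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise FormatError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    seqnum: int
    icode: str
    name: str  # 3-letter
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def center(self, mode: str = "heavy") -> np.ndarray | None:
        """Residue center: heavy-atom centroid (default) or Cα."""
        if mode == "ca":
            ca = self.get_atom("CA")
            return None if ca is None else ca.coord
        heavy = self.heavy_atoms()
        if not heavy:
            return None
        return np.mean([a.coord for a in heavy], axis=0)

    def mean_bfactor(self) -> float:
        heavy = self.heavy_atoms()
        return float(np.mean([a.bfactor for a in heavy])) if heavy else float("nan")

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def by_seqnum(self, seqnum: int, icode: str = " ") -> Residue | None:
        for r in self.residues:
            if r.seqnum == seqnum and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")


def read_structure(path, model_policy: str = "first") -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Altlocs are resolved to the highest-occupancy conformer, waters and
    hydrogens are dropped, and only residues retaining at least one heavy
    atom are kept.

    Parameters
    ----------
    model_policy : "first" keeps model 1 of a multi-model file;
        "error-on-multi" refuses multi-model files.
    """
    path = Path(path)
    if model_policy not in ("first", "error-on-multi"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises several exception types
        raise FormatError(f"{path}: unparsable PDB record: {exc}") from exc
    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no models")
    if len(models) > 1 and model_policy == "error-on-multi":
        raise FormatError(f"{path}: {len(models)} models present, policy forbids")
    model = models[0]

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            het, seqnum, icode = bio_res.get_id()
            if het.strip() and (het == "W" or bio_res.get_resname() in WATER_NAMES):
                continue
            atoms = []
            for bio_atom in bio_res.get_atoms():  # disordered resolved by Bio.PDB
                if bio_atom.element == "H":
                    continue
                atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "C").upper(),
                        coord=np.array(bio_atom.get_coord(), dtype=float),
                        bfactor=float(bio_atom.get_bfactor() or 0.0),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        altloc=bio_atom.get_altloc().strip(),
                    )
                )
            if atoms:
                residues.append(Residue(seqnum=seqnum, icode=icode, name=bio_res.get_resname(), atoms=atoms))
        if residues:
            chains.append(Chain(id=bio_chain.id, residues=residues))
    structure = Structure(id=path.stem, chains=chains)
    if not structure.chains:
        raise EmptyStructureError(f"{path}: no protein atoms")
    return structure


def write_structure(structure: Structure, path) -> None:
    """Write a Structure as fixed-width PDB ATOM records."""
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB column rules: 4-char names start at col 13, shorter at 14
                name_field = name.ljust(4) if len(name) == 4 else f" {name}".ljust(4)
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{atom.altloc or ' '}"
                    f"{res.name:>3s} {chain.id}{res.seqnum:4d}{res.icode or ' '}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.bfactor:6.2f}          "
                    f"{atom.element:>2s}  "
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.id}{chain.residues[-1].seqnum:4d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass
class PSSMProfile:
    """PSI-BLAST profile: per-position log-odds and residue frequencies.

    ``freqs[i, j]`` is the frequency of amino acid ``PSSM_AA_ORDER[j]`` at
    1-based position ``i+1``; each row sums to 1.
    """

    sequence: str
    logodds: np.ndarray  # L×20 int
    freqs: np.ndarray    # L×20 float, rows sum to 1
    fallback_rows: list[int] = field(default_factory=list)  # 1-based

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect).

    Percentage columns are divided by 100 and renormalized; an all-zero
    percentage row falls back to a softmax over the log-odds row (recorded
    in ``fallback_rows`` and logged).
    """
    seq = []
    logodds_rows = []
    pct_rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 42 or not tokens[0].isdigit() or len(tokens[1]) != 1:
            continue
        nums = tokens[2:42]
        try:
            values = [int(t) for t in nums]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad PSSM row: {exc}") from exc
        seq.append(tokens[1])
        logodds_rows.append(values[:20])
        pct_rows.append(values[20:40])
    if not seq:
        raise FormatError(f"{path}: no PSSM rows found (expected 40 numeric columns)")
    logodds = np.array(logodds_rows, dtype=int)
    pct = np.array(pct_rows, dtype=float)
    freqs = pct / 100.0
    fallback = []
    for i in range(len(seq)):
        total = freqs[i].sum()
        if total <= 0:
            ez = np.exp(logodds[i] - logodds[i].max())
            freqs[i] = ez / ez.sum()
            fallback.append(i + 1)
        else:
            freqs[i] = freqs[i] / total
    if fallback:
        log.warning("%s: %d all-zero frequency rows replaced by log-odds softmax: %s",
                    path, len(fallback), fallback)
    return PSSMProfile(sequence="".join(seq), logodds=logodds, freqs=freqs,
                       fallback_rows=fallback)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (integer percentages)."""
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    cols = "            " + "   ".join(PSSM_AA_ORDER) + "   " + "   ".join(PSSM_AA_ORDER)
    lines = [header, cols]
    pct = np.rint(profile.freqs * 100).astype(int)
    for i, aa in enumerate(profile.sequence):
        lo = " ".join(f"{v:3d}" for v in profile.logodds[i])
        pc = " ".join(f"{v:3d}" for v in pct[i])
        lines.append(f"{i + 1:5d} {aa} {lo} {pc}  0.00 0.00")
    Path(path).write_text("\n".join(lines) + "\n\n")


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------

@dataclass
class MSAlignment:
    ids: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise FormatError("alignment needs >= 2 rows")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"aligned rows differ in length: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])


def read_msa(path) -> MSAlignment:
    """Read an aligned-FASTA multiple sequence alignment."""
    aln = AlignIO.read(str(path), "fasta")
    return MSAlignment(ids=[r.id for r in aln], sequences=[str(r.seq).upper() for r in aln])


def write_msa(msa: MSAlignment, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

LABELS = ("disease", "neutral", "unknown")
_LABEL_ALIASES = {
    "disease": "disease", "disease-associated": "disease", "deleterious": "disease",
    "pathogenic": "disease", "1": "disease",
    "neutral": "neutral", "polymorphism": "neutral", "benign": "neutral", "-1": "neutral",
    "unknown": "unknown", "": "unknown", "nan": "unknown",
}


@dataclass(frozen=True)
class VariantRecord:
    protein_id: str
    chain: str
    position: int  # 1-based
    wild_type: str
    mutant: str
    label: str = "unknown"

    def __post_init__(self):
        if self.wild_type == self.mutant:
            raise ValueError(f"wild-type equals mutant for {self.key()}")
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")

    def key(self) -> tuple:
        return (self.protein_id, self.chain, self.position, self.mutant)


class VariantTable(list):
    """List of VariantRecord with a rejection/collapse report attached."""

    def __init__(self, records=(), rejected=None, collapsed=None):
        super().__init__(records)
        self.rejected: list[tuple[dict, str]] = rejected or []
        self.collapsed: list[tuple] = collapsed or []


def read_variant_table(path, allow_unlabeled: bool = False) -> VariantTable:
    """Read a delimited variant table (protein, chain, position, wt, mut, label).

    Rows where the wild type equals the mutant are rejected and reported;
    duplicate (protein, chain, position, mutant) rows are collapsed with a
    warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    colmap = {}
    for want, aliases in {
        "protein_id": ("protein_id", "protein", "pdb", "id"),
        "chain": ("chain",),
        "position": ("position", "pos", "resnum"),
        "wild_type": ("wild_type", "wt", "wild"),
        "mutant": ("mutant", "mut", "mt"),
        "label": ("label", "class", "effect"),
    }.items():
        for alias in aliases:
            if alias in df.columns:
                colmap[want] = alias
                break
    missing = {"protein_id", "chain", "position", "wild_type", "mutant"} - set(colmap)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "label" not in colmap and not allow_unlabeled:
        raise FormatError(f"{path}: no label column (pass allow_unlabeled=True)")

    table = VariantTable()
    seen: dict[tuple, VariantRecord] = {}
    for _, row in df.iterrows():
        raw = {k: (row[v] if v in row else None) for k, v in colmap.items()}
        label_raw = str(raw.get("label", "unknown")).strip().lower()
        label = _LABEL_ALIASES.get(label_raw)
        if label is None:
            table.rejected.append((dict(raw), f"unrecognized label {label_raw!r}"))
            continue
        try:
            rec = VariantRecord(
                protein_id=str(raw["protein_id"]).strip(),
                chain=str(raw["chain"]).strip(),
                position=int(raw["position"]),
                wild_type=str(raw["wild_type"]).strip().upper(),
                mutant=str(raw["mutant"]).strip().upper(),
                label=label,
            )
        except (ValueError, TypeError) as exc:
            table.rejected.append((dict(raw), str(exc)))
            continue
        if rec.key() in seen:
            table.collapsed.append(rec.key())
            warnings.warn(f"duplicate variant row collapsed: {rec.key()}")
            continue
        seen[rec.key()] = rec
        table.append(rec)
    if table.rejected:
        log.warning("%s: rejected %d variant rows", path, len(table.rejected))
    return table


def write_variant_table(variants, path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": v.protein_id, "chain": v.chain, "position": v.position,
                "wild_type": v.wild_type, "mutant": v.mutant, "label": v.label,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tool scores / annotations / auxiliary per-position scores
# ---------------------------------------------------------------------------

def read_tool_scores(path) -> pd.DataFrame:
    """Read external predictor scores keyed by variant.

    Returns a DataFrame indexed by (protein_id, chain, position, mutant) with
    the six tool columns.  Categorical tools (nsSNPAnalyzer, PhD-SNP) must be
    encoded as disease=1 / neutral=-1; other values raise.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    keys = ["protein_id", "chain", "position", "mutant"]
    if not set(keys) <= set(df.columns):
        raise FormatError(f"{path}: tool-score table needs key columns {keys}")
    df = df.set_index(keys)
    for col in TOOL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in CATEGORICAL_TOOLS:
        vals = df[col].dropna().unique()
        bad = [v for v in vals if v not in (1.0, -1.0)]
        if bad:
            raise FormatError(f"{path}: categorical column {col} has values {bad}; "
                              "expected 1 / -1 / missing")
    return df[list(TOOL_COLUMNS)]


def read_annotations(path) -> pd.DataFrame:
    """Read a UniProt-FT-style functional-site table.

    Columns: protein_id, ft_key, start [, end].  Unknown FT keys are dropped
    with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    need = {"protein_id", "ft_key", "start"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: annotation table needs columns {sorted(need)}")
    df["ft_key"] = df["ft_key"].str.upper()
    unknown = sorted(set(df["ft_key"]) - set(FT_KEYS))
    if unknown:
        warnings.warn(f"ignoring unknown FT keys: {unknown}")
        df = df[df["ft_key"].isin(FT_KEYS)]
    if "end" not in df.columns:
        df["end"] = df["start"]
    df["end"] = df["end"].fillna(df["start"])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.reset_index(drop=True)


def read_aux_scores(path) -> pd.DataFrame:
    """Per-position external scores (PSIPRED, DISOPRED, SSpro, PSIC, TANGO ...)
    keyed by (protein_id, position); absent columns stay missing."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"protein_id", "position"} <= set(df.columns):
        raise FormatError(f"{path}: auxiliary score table needs protein_id and position")
    return df.set_index(["protein_id", "position"])


# ---------------------------------------------------------------------------
# classic DSSP
# ---------------------------------------------------------------------------

@dataclass
class DsspRecord:
    seqnum: int
    chain: str
    aa: str
    ss: str
    acc: int
    kappa: float
    alpha: float
    tco: float
    ca_coord: np.ndarray


def read_dssp(path) -> list[DsspRecord]:
    """Parse classic fixed-column DSSP output (an optional override source
    for SS/ACC/KAPPA/ALPHA/TCO)."""
    records = []
    in_body = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("  #  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 115:
            continue
        if line[13] == "!":  # chain break
            continue
        try:
            records.append(
                DsspRecord(
                    seqnum=int(line[5:10]),
                    chain=line[11].strip(),
                    aa=line[13],
                    ss=line[16].strip(),
                    acc=int(line[34:38]),
                    tco=float(line[85:91]),
                    kappa=float(line[91:97]),
                    alpha=float(line[97:103]),
                    ca_coord=np.array(
                        [float(line[115:122]), float(line[122:129]), float(line[129:136])]
                    ),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: bad DSSP record {line[:20]!r}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no DSSP residue records found")
    for rec in records:
        if rec.acc < 0:
            raise FormatError(f"{path}: negative ACC at residue {rec.seqnum}")
    return records


# ---------------------------------------------------------------------------
# feature matrix I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(df: pd.DataFrame, path) -> None:
    """Write a feature matrix as TSV (deterministic float formatting)."""
    df.to_csv(path, sep="\t", index=True, float_format="%.10g")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
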