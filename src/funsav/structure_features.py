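"""Structure-derived features.

Residue-contact network with twelve per-node graph properties, half-sphere
exposure and residue depth, Shrake–Rupley solvent accessibility with
category splits, backbone virtual angles (KAPPA/ALPHA/TCO), Kabsch–Sander
hydrogen bonds, and disulfide / annotated-site distance features.

Residue "centers" default to the heavy-atom centroid; a Cα-only mode is
available for sensitivity checks.  The contact cutoff comparison is
inclusive (edge iff distance ≤ cutoff).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geometry
from .io_formats import Chain, Residue, Structure, VariantRecord

#: van der Waals radii (Å) by element for surface calculations
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20,
}

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}


class RadiusTableError(KeyError):
    """Raised when an atom's element has no packaged van der Waals radius."""


# ---------------------------------------------------------------------------
# residue-contact network
# ---------------------------------------------------------------------------

def build_contact_network(structure: Structure, chain: str, cutoff: float = 6.5,
                          center: str = "heavy") -> nx.Graph:
    """Residue-contact graph of one chain.

    Nodes are 1…N in chain order (attributes ``seqnum``, ``resname``); an
    edge joins residues whose centers (heavy-atom centroid, or Cα for
    ``center="ca"``) lie within ``cutoff`` Å inclusive.
    """
    ch = structure.chain(chain)
    if len(ch.residues) < 2:
        raise ValueError(f"chain {chain!r} has fewer than 2 residues")
    centers = []
    nodes = []
    for idx, res in enumerate(ch.residues, start=1):
        c = res.center(mode="ca" if center == "ca" else "heavy")
        nodes.append((idx, res))
        centers.append(c)
    g = nx.Graph()
    for idx, res in nodes:
        g.add_node(idx, seqnum=res.seqnum, resname=res.name)
    coords = [(i, c) for (i, _), c in zip(nodes, centers) if c is not None]
    for a in range(len(coords)):
        ia, ca = coords[a]
        for b in range(a + 1, len(coords)):
            ib, cb = coords[b]
            if np.linalg.norm(ca - cb) <= cutoff:
                g.add_edge(ia, ib)
    return g


def _cyclic_coefficient(g: nx.Graph, node) -> float:
    """Mean of 1/ℓ over the smallest cycles through ``node`` and each
    neighbor pair; pairs on no common cycle contribute 0; < 2 neighbors → 0."""
    nbrs = list(g.neighbors(node))
    if len(nbrs) < 2:
        return 0.0
    h = g.copy()
    h.remove_node(node)
    total = 0.0
    pairs = 0
    for a in range(len(nbrs)):
        for b in range(a + 1, len(nbrs)):
            pairs += 1
            try:
                d = nx.shortest_path_length(h, nbrs[a], nbrs[b])
                total += 1.0 / (d + 2)
            except nx.NetworkXNoPath:
                pass
    return total / pairs


def network_properties(g: nx.Graph) -> pd.DataFrame:
    """Twelve per-node properties of a residue-contact graph.

    Geodesic quantities are per connected component: status S_i is the sum
    of shortest-path distances to the component's other nodes, closeness
    C_i = (n_comp − 1)/S_i (0 for isolated nodes), eccentricity the largest
    geodesic.  Hubscore and eigenvector are both the principal-eigenvector
    centrality (identical up to scaling on undirected graphs; emitted
    unit-norm).  Cocitation is the mean shared-neighbor count with the
    node's neighbors; constraint is Burt's constraint with equal tie
    weights (0 for isolated nodes).
    """
    if g.number_of_nodes() < 1:
        raise ValueError("graph has no nodes")
    nodes = list(g.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    status = np.zeros(n)
    closeness = np.zeros(n)
    eccentricity = np.zeros(n)
    for comp in nx.connected_components(g):
        comp = set(comp)
        size = len(comp)
        for node in comp:
            lengths = nx.single_source_shortest_path_length(g, node)
            s = sum(d for t, d in lengths.items() if t in comp)
            i = idx[node]
            status[i] = s
            eccentricity[i] = max(lengths.values()) if size > 1 else 0
            closeness[i] = (size - 1) / s if s > 0 else 0.0

    a = nx.to_numpy_array(g, nodelist=nodes)
    if g.number_of_edges() > 0:
        w, v = np.linalg.eigh(a)
        principal = v[:, np.argmax(w)]
        principal = np.abs(principal)
        norm = np.linalg.norm(principal)
        eig = principal / norm if norm > 0 else principal
    else:
        eig = np.zeros(n)

    shared = a @ a  # shared-neighbor counts
    cocitation = np.zeros(n)
    for node in nodes:
        nbrs = list(g.neighbors(node))
        if nbrs:
            cocitation[idx[node]] = float(
                np.mean([shared[idx[node], idx[m]] for m in nbrs])
            )

    constraint = nx.constraint(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g)
    coreness = nx.core_number(g)

    return pd.DataFrame(
        {
            "Degree": [g.degree(v) for v in nodes],
            "Closeness": closeness,
            "Status": status,
            "Hubscore": eig,
            "Clustering": [clustering[v] for v in nodes],
            "Cyclic": [_cyclic_coefficient(g, v) for v in nodes],
            "Constraint": [0.0 if np.isnan(constraint[v]) else constraint[v] for v in nodes],
            "Betweenness": [betweenness[v] for v in nodes],
            "Eigenvector": eig,
            "Cocitation": cocitation,
            "Coreness": [coreness[v] for v in nodes],
            "Eccentricity": eccentricity,
        },
        index=pd.Index(nodes, name="node"),
    )


# ---------------------------------------------------------------------------
# solvent accessibility (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class AccessibilityBundle:
    """Per-residue absolute (Å²) and relative (%) accessible surface areas.

    Categories: all atoms, side chain, main chain, non-polar side chain
    (side-chain atoms that are neither O nor N) and all-polar side chain.
    ``surface_points`` holds the retained (solvent-exposed) sample points,
    reused for residue-depth calculations.
    """

    table: pd.DataFrame            # index: residue position 1..N
    atom_asa: list[list[float]]    # per residue, per heavy atom
    surface_points: np.ndarray     # (M, 3)


def _atom_radius(atom) -> float:
    try:
        return VDW_RADII[atom.element.upper()]
    except KeyError:
        raise RadiusTableError(
            f"no van der Waals radius for element {atom.element!r} (atom {atom.name})"
        ) from None


def sasa(structure: Structure, chain: str, probe: float = 1.4,
         n_points: int = 960, relative: bool = True) -> AccessibilityBundle:
    """Shrake–Rupley accessible surface areas for one chain.

    Each heavy atom's solvent-accessible sphere (radius r_vdw + probe) is
    sampled at ``n_points`` golden-spiral points; points falling inside any
    neighbor's expanded sphere are buried.  Relative values are normalized
    by extended Gly-X-Gly reference maxima built with the same sampler.
    """
    ch = structure.chain(chain)
    atoms = []
    owner = []
    for ridx, res in enumerate(ch.residues):
        for atom in res.heavy_atoms():
            atoms.append(atom)
            owner.append(ridx)
    if not atoms:
        raise ValueError(f"chain {chain!r} has no heavy atoms")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([_atom_radius(a) + probe for a in atoms])
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)

    atom_asa_flat = np.zeros(len(atoms))
    surface_chunks = []
    max_r = radii.max()
    for i in range(len(atoms)):
        sample = coords[i] + radii[i] * pts
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                        if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d = np.linalg.norm(sample - coords[j], axis=1)
            exposed &= d >= radii[j]
        frac = exposed.sum() / n_points
        atom_asa_flat[i] = frac * 4.0 * np.pi * radii[i] ** 2
        if exposed.any():
            surface_chunks.append(sample[exposed])
    surface = np.vstack(surface_chunks) if surface_chunks else np.empty((0, 3))

    rows = []
    atom_asa: list[list[float]] = [[] for _ in ch.residues]
    for i, ridx in enumerate(owner):
        atom_asa[ridx].append(float(atom_asa_flat[i]))
    for ridx, res in enumerate(ch.residues):
        cats = {"all": 0.0, "sc": 0.0, "mc": 0.0, "npa": 0.0, "pa": 0.0}
        for atom, asa_val in zip(res.heavy_atoms(), atom_asa[ridx]):
            cats["all"] += asa_val
            if atom.name in MAIN_CHAIN_ATOMS:
                cats["mc"] += asa_val
            else:
                cats["sc"] += asa_val
                if atom.element.upper() in ("O", "N"):
                    cats["pa"] += asa_val
                else:
                    cats["npa"] += asa_val
        rows.append(cats)
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, len(ch.residues) + 1, name="position"))
    table.columns = [f"NAC_{c}_abs" for c in table.columns]

    if relative:
        ref = _gxg_reference(probe, n_points)
        for cat in ("all", "sc", "mc", "npa", "pa"):
            rel = []
            for pos, res in enumerate(ch.residues, start=1):
                maxima = ref.get(res.name)
                if maxima is None or maxima[cat] <= 0:
                    rel.append(np.nan)
                else:
                    rel.append(100.0 * table.at[pos, f"NAC_{cat}_abs"] / maxima[cat])
            table[f"NAC_{cat}"] = rel
    return AccessibilityBundle(table=table, atom_asa=atom_asa, surface_points=surface)


def _tripeptide(center_resname: str) -> Structure:
    """Extended Gly-X-Gly tripeptide with side chains truncated at Cβ."""
    phi, psi = geometry.EXTENDED_PHI_PSI
    backbone = geometry.build_backbone(3, phi, psi)
    names = ["GLY", center_resname, "GLY"]
    residues = []
    from .io_formats import Atom  # local import to avoid cycle at module load
    for i, (resname, coords) in enumerate(zip(names, backbone), start=1):
        atoms = [
            Atom("N", "N", coords["N"]), Atom("CA", "C", coords["CA"]),
            Atom("C", "C", coords["C"]), Atom("O", "O", coords["O"]),
        ]
        if resname != "GLY":
            atoms.append(Atom("CB", "C", coords["CB"]))
            if resname == "CYS":
                # crude γ-position stand-in so sulfur has a radius entry
                atoms.append(Atom("SG", "S", coords["CB"] + (coords["CB"] - coords["CA"])))
        residues.append(Residue(seqnum=i, icode=" ", name=resname, atoms=atoms))
    return Structure(id=f"GXG_{center_resname}", chains=[Chain(id="A", residues=residues)])


@functools.lru_cache(maxsize=8)
def _gxg_reference(probe: float, n_points: int) -> dict[str, dict[str, float]]:
    """Reference maxima: category ASA of X in extended Gly-X-Gly, per residue."""
    from .io_formats import AA1_TO_3
    ref = {}
    for resname in sorted(set(AA1_TO_3.values())):
        bundle = sasa(_tripeptide(resname), "A", probe=probe, n_points=n_points,
                      relative=False)
        row = bundle.table.loc[2]
        ref[resname] = {c: float(row[f"NAC_{c}_abs"]) for c in ("all", "sc", "mc", "npa", "pa")}
    return ref


# ---------------------------------------------------------------------------
# half-sphere exposure and depth
# ---------------------------------------------------------------------------

def _cbeta_coord(res: Residue) -> np.ndarray | None:
    cb = res.get_atom("CB")
    if cb is not None:
        return cb.coord
    n, ca, c = res.get_atom("N"), res.get_atom("CA"), res.get_atom("C")
    if None in (n, ca, c):
        return None
    return geometry.pseudo_cbeta(n.coord, ca.coord, c.coord)


def half_sphere_exposure(structure: Structure, chain: str, radius: float = 13.0,
                         surface_points: np.ndarray | None = None) -> pd.DataFrame:
    """Half-sphere exposure family plus residue depth for one chain.

    A sphere of ``radius`` Å around each residue's Cα is split by the plane
    through Cα normal to the Cα→Cβ vector (glycine uses an ideal
    tetrahedral pseudo-Cβ).  HSEAU/HSEAD count other residues' Cα atoms in
    the upper/lower half; HSEBU/HSEBD count Cβ atoms; CN counts all Cα in
    the sphere (CN = HSEAU + HSEAD).  RD is the mean distance of the
    residue's heavy atoms to the nearest solvent-accessible surface point,
    RDa that of Cα; when ``surface_points`` is not given the surface is
    sampled internally.

    Residues without a resolvable Cα/pseudo-Cβ get missing values.
    """
    ch = structure.chain(chain)
    if surface_points is None:
        surface_points = sasa(structure, chain, relative=False).surface_points
    surf_tree = cKDTree(surface_points) if len(surface_points) else None

    ca = []
    cb = []
    for res in ch.residues:
        ca_atom = res.get_atom("CA")
        ca.append(None if ca_atom is None else ca_atom.coord)
        cb.append(_cbeta_coord(res))

    rows = []
    for i, res in enumerate(ch.residues):
        if ca[i] is None or cb[i] is None:
            rows.append(dict.fromkeys(("CN", "HSEAU", "HSEBU", "HSEAD", "HSEBD", "RD", "RDa"),
                                      np.nan))
            continue
        up = geometry.unit(cb[i] - ca[i])
        hseau = hsead = hsebu = hsebd = 0
        for j in range(len(ch.residues)):
            if j == i:
                continue
            if ca[j] is not None and np.linalg.norm(ca[j] - ca[i]) <= radius:
                if np.dot(ca[j] - ca[i], up) > 0:
                    hseau += 1
                else:
                    hsead += 1
            if cb[j] is not None and np.linalg.norm(cb[j] - ca[i]) <= radius:
                if np.dot(cb[j] - ca[i], up) > 0:
                    hsebu += 1
                else:
                    hsebd += 1
        rd = rda = np.nan
        if surf_tree is not None:
            depths = [surf_tree.query(a.coord)[0] for a in res.heavy_atoms()]
            rd = float(np.mean(depths)) if depths else np.nan
            rda = float(surf_tree.query(ca[i])[0])
        rows.append({"CN": hseau + hsead, "HSEAU": hseau, "HSEBU": hsebu,
                     "HSEAD": hsead, "HSEBD": hsebd, "RD": rd, "RDa": rda})
    return pd.DataFrame(rows, index=pd.RangeIndex(1, len(ch.residues) + 1, name="position"))


# ---------------------------------------------------------------------------
# backbone virtual angles
# ---------------------------------------------------------------------------

def backbone_geometry(structure: Structure, chain: str) -> pd.DataFrame:
    """Per-residue KAPPA, ALPHA and TCO.

    KAPPA is the virtual bend angle at Cα(i) between the rays to Cα(i−2)
    and Cα(i+2) (180° for a collinear trace); ALPHA the signed virtual
    torsion of Cα(i−1, i, i+1, i+2) in (−180, 180]; TCO the cosine of the
    angle between the C=O vectors of residues i and i−1.  Missing neighbor
    atoms propagate as missing values.
    """
    ch = structure.chain(chain)
    n = len(ch.residues)
    ca = [r.get_atom("CA") for r in ch.residues]
    ca = [a.coord if a is not None else None for a in ca]
    co = []
    for r in ch.residues:
        c, o = r.get_atom("C"), r.get_atom("O")
        co.append(None if c is None or o is None else o.coord - c.coord)

    kappa = np.full(n, np.nan)
    alpha = np.full(n, np.nan)
    tco = np.full(n, np.nan)
    for i in range(n):
        if 2 <= i < n - 2 and all(ca[j] is not None for j in (i - 2, i, i + 2)):
            kappa[i] = geometry.bond_angle(ca[i - 2], ca[i], ca[i + 2])
        if 1 <= i < n - 2 and all(ca[j] is not None for j in (i - 1, i, i + 1, i + 2)):
            alpha[i] = geometry.dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
        if i >= 1 and co[i] is not None and co[i - 1] is not None:
            tco[i] = float(np.clip(
                np.dot(geometry.unit(co[i]), geometry.unit(co[i - 1])), -1.0, 1.0))
    return pd.DataFrame({"KAPPA": kappa, "ALPHA": alpha, "TCO": tco},
                        index=pd.RangeIndex(1, n + 1, name="position"))


# ---------------------------------------------------------------------------
# Kabsch–Sander hydrogen bonds
# ---------------------------------------------------------------------------

_KS_Q1Q2_F = 0.084 * 332.0  # kcal/mol·Å, electrostatic H-bond model


def hydrogen_bonds(structure: Structure, chain: str,
                   energy_cutoff: float = -0.5) -> pd.Series:
    """Backbone H-bond count per residue by the Kabsch–Sander criterion.

    E = 0.084·332·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN) kcal/mol between a
    donor amide (N−H, H placed along the bisector convention when absent)
    and an acceptor carbonyl (C=O); a bond is counted when E < cutoff.
    Residues closer than two positions in sequence are skipped, as are
    proline donors.  Counts sum donor and acceptor roles.
    """
    ch = structure.chain(chain)
    n = len(ch.residues)
    counts = np.zeros(n, dtype=int)

    donors = {}
    for i in range(1, n):
        res = ch.residues[i]
        if res.name == "PRO":
            continue
        n_at, ca_at = res.get_atom("N"), res.get_atom("CA")
        c_prev = ch.residues[i - 1].get_atom("C")
        if None in (n_at, ca_at, c_prev):
            continue
        h_at = res.get_atom("H")
        if h_at is not None:
            h = h_at.coord
        else:
            direction = geometry.unit(
                geometry.unit(n_at.coord - c_prev.coord)
                + geometry.unit(n_at.coord - ca_at.coord)
            )
            h = n_at.coord + 1.01 * direction
        donors[i] = (n_at.coord, h)

    acceptors = {}
    for j in range(n):
        res = ch.residues[j]
        c_at, o_at = res.get_atom("C"), res.get_atom("O")
        if c_at is not None and o_at is not None:
            acceptors[j] = (c_at.coord, o_at.coord)

    for i, (n_xyz, h_xyz) in donors.items():
        for j, (c_xyz, o_xyz) in acceptors.items():
            if abs(i - j) < 2:
                continue
            d_on = np.linalg.norm(o_xyz - n_xyz)
            d_ch = np.linalg.norm(c_xyz - h_xyz)
            d_oh = np.linalg.norm(o_xyz - h_xyz)
            d_cn = np.linalg.norm(c_xyz - n_xyz)
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:  # clashing geometry, skip
                continue
            energy = _KS_Q1Q2_F * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            if energy < energy_cutoff:
                counts[i] += 1
                counts[j] += 1
    return pd.Series(counts, index=pd.RangeIndex(1, n + 1, name="position"),
                     name="Hbonds")


# ---------------------------------------------------------------------------
# disulfides, metal sites and annotated-site distances
# ---------------------------------------------------------------------------

DISULFIDE_SG_CUTOFF = 2.3  # Å


def disulfide_and_site_distances(structure: Structure, variants: list[VariantRecord],
                                 annotations: pd.DataFrame | None) -> pd.DataFrame:
    """Per-variant disulfide/metal flags and distances to functional sites.

    With no annotation table supplied all four outputs are missing (the
    family is treated as absent).  Otherwise: the disulfide flag is 1 when
    the variant residue is a cysteine with an SG–SG partner within 2.3 Å;
    the metal flag is 1 when the position lies in a METAL record; sequence
    and 3D distances are minima over all annotated site positions of the
    variant's protein (3D between residue heavy-atom centers).
    """
    rows = []
    for var in variants:
        out = {"Disulfide": np.nan, "Metal": np.nan,
               "SeqDist_site": np.nan, "D3_site": np.nan}
        if annotations is not None:
            try:
                ch = structure.chain(var.chain)
                res = ch.by_seqnum(var.position)
            except KeyError:
                res = None
            # structure-derived disulfide
            out["Disulfide"] = 0.0
            if res is not None and res.name == "CYS":
                sg = res.get_atom("SG")
                if sg is not None:
                    for other in ch.residues:
                        if other is res or other.name != "CYS":
                            continue
                        sg2 = other.get_atom("SG")
                        if sg2 is not None and np.linalg.norm(sg.coord - sg2.coord) <= DISULFIDE_SG_CUTOFF:
                            out["Disulfide"] = 1.0
                            break
            ann = annotations[annotations["protein_id"] == var.protein_id]
            if len(ann):
                metal = ann[ann["ft_key"] == "METAL"]
                out["Metal"] = float(
                    ((metal["start"] <= var.position) & (var.position <= metal["end"])).any()
                )
                site_positions = sorted(
                    {p for _, row in ann.iterrows()
                     for p in range(int(row["start"]), int(row["end"]) + 1)}
                )
                out["SeqDist_site"] = float(min(abs(var.position - p) for p in site_positions))
                if res is not None:
                    centers = []
                    for p in site_positions:
                        site_res = structure.chain(var.chain).by_seqnum(p) if res else None
                        if site_res is not None:
                            c = site_res.center()
                            if c is not None:
                                centers.append(c)
                    vc = res.center()
                    if centers and vc is not None:
                        out["D3_site"] = float(
                            min(np.linalg.norm(vc - c) for c in centers)
                        )
        rows.append(out)
    return pd.DataFrame(rows, index=[v.key() for v in variants])


def distance_to_origin(structure: Structure, chain: str) -> pd.Series:
    """‖residue center‖ per residue.

    Frame-dependent (it echoes the crystallographic coordinate frame) and
    therefore excluded from default feature sets.
    """
    ch = structure.chain(chain)
    vals = []
    for res in ch.residues:
        c = res.center()
        vals.append(np.nan if c is None else float(np.linalg.norm(c)))
    return pd.Series(vals, index=pd.RangeIndex(1, len(ch.residues) + 1, name="position"),
                     name="Dist_origin")
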