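"""Structure I/O and geometric interface analysis.

Implements the structural measurements used to characterise dual-paratope
Fabs in complex with their antigens:

* Shrake–Rupley solvent-accessible surface area (quasi-uniform sphere
  points on expanded atomic spheres; probe 1.4 Å, 960 points by default);
* interface footprints: the buried surface area ΔSASA = SASA(group alone)
  − SASA(group in complex), per atom, per residue and attributed to CDR /
  framework regions on the antibody side;
* Kabsch least-squares rigid-body superposition (reflection-corrected);
* ternary co-binding models: superpose a second antibody–antigen complex
  onto a first via shared Fab Cα atoms and scan the two antigens for
  van-der-Waals clashes — a steric feasibility test for simultaneous
  binding of both targets;
* Matthews coefficient and solvent content of a crystal form.

Coordinates are in Å throughout.  Hydrogens are ignored by default since
crystal structures typically lack them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import StructureError
from .fv_numbering import RegionAnnotation, label_key

# Protein van-der-Waals radii (Å); config-overridable.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "H": 1.20, "P": 1.80, "SE": 1.90, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
CLASH_TOLERANCE = 0.4  # Å of allowed vdW overlap before a pair counts as severe

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass(frozen=True)
class Structure:
    """A flat atom table: parallel arrays plus optional cell metadata."""

    chain_ids: tuple[str, ...]
    res_seq: tuple[int, ...]
    icodes: tuple[str, ...]
    res_names: tuple[str, ...]
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float64, Å
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None

    def __post_init__(self):
        if self.coords.shape != (len(self.chain_ids), 3):
            raise StructureError("coordinate array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return tuple(seen)

    def residue_ids(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for c, r, i in zip(self.chain_ids, self.res_seq, self.icodes):
            seen.setdefault((c, r, i))
        return list(seen)

    def mask(self, mask: np.ndarray) -> "Structure":
        idx = np.flatnonzero(mask)
        pick = lambda t: tuple(t[i] for i in idx)
        return Structure(
            pick(self.chain_ids), pick(self.res_seq), pick(self.icodes),
            pick(self.res_names), pick(self.atom_names), pick(self.elements),
            self.coords[idx], self.cell, self.spacegroup,
        )

    def select_chains(self, chains: Iterable[str]) -> "Structure":
        cs = set(chains)
        return self.mask(np.array([c in cs for c in self.chain_ids]))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return replace(self, coords=self.coords @ rotation.T + translation)

    def radii(self, table: Mapping[str, float] | None = None) -> np.ndarray:
        table = table or DEFAULT_RADII
        out = np.empty(len(self))
        for i, el in enumerate(self.elements):
            try:
                out[i] = table[el.upper()]
            except KeyError:
                raise StructureError(f"unknown element {el!r} (no radius)") from None
        return out


def from_atoms(atoms: Sequence[tuple], cell=None, spacegroup=None) -> Structure:
    """Build a Structure from (chain, resseq, icode, resname, atomname, element, x, y, z) rows."""
    cols = list(zip(*atoms))
    coords = np.array(cols[6:9], dtype=float).T
    return Structure(
        tuple(cols[0]), tuple(int(r) for r in cols[1]), tuple(cols[2]),
        tuple(cols[3]), tuple(cols[4]), tuple(cols[5]), coords, cell, spacegroup,
    )


# ---------------------------------------------------------------------------
# I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def read_structure(
    path,
    fmt: str | None = None,
    strip_waters: bool = True,
    strip_hydrogens: bool = True,
    strip_hetero: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a Structure (first model only).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by altloc letter).  Author chain ids are used.
    """
    import gemmi

    path = str(path)
    if fmt is None:
        fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif if fmt == "mmcif" else gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if not len(st):
        raise StructureError(f"{path}: no models")
    model = st[0]

    best: dict[tuple, tuple[float, str, tuple]] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            if strip_waters and res.is_water():
                continue
            if strip_hetero and res.het_flag == "H" and not res.is_water():
                continue
            for atom in res:
                el = atom.element.name.upper()
                if strip_hydrogens and el in ("H", "D"):
                    continue
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), atom.name)
                row = (
                    chain.name, res.seqid.num, res.seqid.icode.strip(), res.name,
                    atom.name, el, atom.pos.x, atom.pos.y, atom.pos.z,
                )
                cand = (-atom.occ, atom.altloc or "", row)
                if key not in best:
                    order.append(key)
                    best[key] = cand
                elif cand < best[key]:
                    best[key] = cand
    if not order:
        raise StructureError(f"{path}: no atoms after filtering")
    cell = st.cell
    cell_t = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma) if cell.a > 1 else None
    return from_atoms([best[k][2] for k in order], cell=cell_t,
                      spacegroup=st.spacegroup_hm or None)


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as a minimal PDB file."""
    lines = []
    serial = 0
    for i in range(len(s)):
        serial += 1
        name = s.atom_names[i]
        pname = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {serial:5d} {pname:<4s} {s.res_names[i]:<3s} "
            f"{s.chain_ids[i][:1]}{s.res_seq[i]:4d}{s.icodes[i] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{s.elements[i]:>2s}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray
    per_residue: dict[ResidueId, float]
    total: float
    probe: float
    n_points: int


def _sphere_points(m: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(m) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / m
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    s: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom i, the fraction of `n_points` quasi-uniform points on the
    sphere of radius r_i + probe not inside any neighbour's expanded sphere,
    times 4π(r_i + probe)².
    """
    r = s.radii(radii) + probe
    coords = s.coords
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = float(r.max())
    per_atom = np.empty(len(s))
    pairs = tree.query_ball_tree(tree, 2.0 * r_max)
    for i in range(len(s)):
        ci, ri = coords[i], r[i]
        neigh = [j for j in pairs[i] if j != i]
        if neigh:
            nc = coords[neigh]
            nr = r[np.asarray(neigh)]
            keep = np.linalg.norm(nc - ci, axis=1) < ri + nr
            nc, nr = nc[keep], nr[keep]
        else:
            nc = np.empty((0, 3))
            nr = np.empty(0)
        sphere = ci + ri * pts
        if len(nc):
            d2 = ((sphere[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr**2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * ri * ri
    per_res: dict[ResidueId, float] = {}
    for i, rid in enumerate(zip(s.chain_ids, s.res_seq, s.icodes)):
        per_res[rid] = per_res.get(rid, 0.0) + per_atom[i]
    return SasaResult(per_atom, per_res, float(per_atom.sum()), probe, n_points)


# ---------------------------------------------------------------------------
# interface footprints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FootprintResult:
    side_a_buried: float
    side_b_buried: float
    per_residue_a: dict[ResidueId, float]
    per_residue_b: dict[ResidueId, float]
    contact_residues_a: tuple[ResidueId, ...]
    contact_residues_b: tuple[ResidueId, ...]
    cdr_attribution: dict[str, float] | None = None


def _delta_per_residue(alone: SasaResult, complexed: SasaResult, which: set[ResidueId]):
    out = {}
    for rid in which:
        d = alone.per_residue.get(rid, 0.0) - complexed.per_residue.get(rid, 0.0)
        out[rid] = max(d, 0.0) if d > -1e-6 else d  # clamp numerical dust only
    return out


def interface_footprint(
    s: Structure,
    group_a: Iterable[str],
    group_b: Iterable[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
    annotation: RegionAnnotation | None = None,
    antibody_chain_map: Mapping[str, str] | None = None,
    contact_cutoff: float = 1e-3,
) -> FootprintResult:
    """Buried surface areas of two chain groups upon complex formation.

    buried(A) = SASA(A alone) − SASA(A within A∪B), likewise for B.  With an
    `annotation` and an `antibody_chain_map` (structure chain id → "H"/"L",
    assuming author residue numbers follow the numbering-frame labels), the
    antibody-side buried area is attributed per CDR/framework region.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise StructureError("both groups must be non-empty")
    if ga & gb:
        raise StructureError(f"groups overlap: {sorted(ga & gb)}")
    present = set(s.chains)
    missing = (ga | gb) - present
    if missing:
        raise StructureError(f"chains absent from structure: {sorted(missing)}")

    sub_a, sub_b = s.select_chains(ga), s.select_chains(gb)
    both = s.select_chains(ga | gb)
    res_a = sasa(sub_a, probe, n_points, radii)
    res_b = sasa(sub_b, probe, n_points, radii)
    res_ab = sasa(both, probe, n_points, radii)

    ids_a = set(sub_a.residue_ids())
    ids_b = set(sub_b.residue_ids())
    per_a = _delta_per_residue(res_a, res_ab, ids_a)
    per_b = _delta_per_residue(res_b, res_ab, ids_b)
    buried_a = max(sum(per_a.values()), 0.0)
    buried_b = max(sum(per_b.values()), 0.0)
    contacts_a = tuple(sorted(r for r, d in per_a.items() if d > contact_cutoff))
    contacts_b = tuple(sorted(r for r, d in per_b.items() if d > contact_cutoff))

    attribution = None
    if annotation is not None and antibody_chain_map is not None:
        attribution = {}
        for (cid, num, icode), d in per_a.items():
            fv_chain = antibody_chain_map.get(cid)
            if fv_chain is None or d <= 0:
                continue
            label = f"{num}{icode}"
            try:
                region = annotation.region_of(fv_chain, label)
            except Exception:
                region = f"{fv_chain}-unmapped"
            attribution[region] = attribution.get(region, 0.0) + d
    return FootprintResult(buried_a, buried_b, per_a, per_b, contacts_a, contacts_b,
                           attribution)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of `mobile` onto `reference`.

    Returns the proper rotation (reflection corrected via the SVD
    determinant sign) and translation minimising the RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise StructureError("coordinate sets must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise StructureError("need at least 3 atom pairs")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - cm, ref - cr
    h = p.T @ q
    u, sv, vt = np.linalg.svd(h)
    # degenerate (collinear/coincident) sets leave the rotation underdetermined
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise StructureError("degenerate (collinear) coordinate configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / n))
    return Superposition(rot, trans, rmsd, n)


# ---------------------------------------------------------------------------
# clash detection and ternary models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClashPair:
    index_a: int
    index_b: int
    distance: float
    overlap: float  # (r_a + r_b) - distance


def detect_clashes(
    s_a: Structure,
    s_b: Structure,
    tolerance: float = CLASH_TOLERANCE,
    radii: Mapping[str, float] | None = None,
) -> tuple[ClashPair, ...]:
    """Inter-group atom pairs with vdW overlap exceeding `tolerance` Å."""
    ra, rb = s_a.radii(radii), s_b.radii(radii)
    tree = cKDTree(s_b.coords)
    cutoff = float(ra.max() + rb.max() - tolerance)
    out = []
    for i, hits in enumerate(tree.query_ball_point(s_a.coords, cutoff)):
        for j in hits:
            d = float(np.linalg.norm(s_a.coords[i] - s_b.coords[j]))
            if d < ra[i] + rb[j] - tolerance:
                out.append(ClashPair(i, j, d, float(ra[i] + rb[j] - d)))
    return tuple(sorted(out, key=lambda c: -c.overlap))


@dataclass(frozen=True)
class TernaryModel:
    model: Structure            # complex_1 + transplanted antigen of complex_2
    superposition: Superposition
    clashes: tuple[ClashPair, ...]
    antigen_chains_1: tuple[str, ...]
    antigen_chains_2: tuple[str, ...]


def _ca_map(s: Structure, chains: set[str]) -> dict[ResidueId, np.ndarray]:
    out = {}
    for i in range(len(s)):
        if s.chain_ids[i] in chains and s.atom_names[i] == "CA":
            out[(s.chain_ids[i], s.res_seq[i], s.icodes[i])] = s.coords[i]
    return out


def build_ternary_model(
    complex_1: Structure,
    complex_2: Structure,
    fab_chains_1: Iterable[str],
    fab_chains_2: Iterable[str] | None = None,
    fab_atom_map: Sequence[tuple[int, int]] | None = None,
    min_mapped: int = 50,
    clash_tolerance: float = CLASH_TOLERANCE,
    rename_prefix: str = "x",
) -> TernaryModel:
    """Superpose complex_2 onto complex_1 via their shared Fab and test whether
    both antigens can be bound simultaneously.

    By default equivalent Fab atoms are the Cα atoms shared by residue id
    (chain, number, insertion code) across the two complexes; an explicit
    `fab_atom_map` of (index_in_1, index_in_2) pairs overrides this.  The
    output model contains complex_1 plus the transplanted antigen chains of
    complex_2 (renamed with `rename_prefix`); the clash report covers
    antigen-1 vs transplanted antigen-2 atom pairs.
    """
    fab1 = set(fab_chains_1)
    fab2 = set(fab_chains_2) if fab_chains_2 is not None else fab1
    if fab_atom_map is not None:
        idx1, idx2 = zip(*fab_atom_map)
        ref = complex_1.coords[list(idx1)]
        mob = complex_2.coords[list(idx2)]
    else:
        ca1 = _ca_map(complex_1, fab1)
        ca2 = _ca_map(complex_2, fab2)
        # allow differing fab chain ids by pairing in sorted-chain order
        if fab1 != fab2:
            order1, order2 = sorted(fab1), sorted(fab2)
            if len(order1) != len(order2):
                raise StructureError("fab chain sets have different sizes")
            remap = dict(zip(order2, order1))
            ca2 = {(remap[c], n, i): xyz for (c, n, i), xyz in ca2.items()}
        shared = sorted(set(ca1) & set(ca2))
        ref = np.array([ca1[k] for k in shared]) if shared else np.empty((0, 3))
        mob = np.array([ca2[k] for k in shared]) if shared else np.empty((0, 3))
    if len(ref) < min_mapped:
        raise StructureError(
            f"too few mapped Fab atoms ({len(ref)} < {min_mapped})"
        )
    sup = kabsch_superpose(mob, ref)
    moved_2 = complex_2.transformed(sup.rotation, sup.translation)

    ag1_chains = tuple(c for c in complex_1.chains if c not in fab1)
    ag2_chains = tuple(c for c in complex_2.chains if c not in fab2)
    ag1 = complex_1.select_chains(ag1_chains) if ag1_chains else None
    ag2 = moved_2.select_chains(ag2_chains) if ag2_chains else None
    clashes: tuple[ClashPair, ...] = ()
    if ag1 is not None and ag2 is not None:
        clashes = detect_clashes(ag1, ag2, tolerance=clash_tolerance)

    if ag2 is not None:
        renamed = replace(
            ag2, chain_ids=tuple(f"{rename_prefix}{c}" for c in ag2.chain_ids)
        )
        model = _concat(complex_1, renamed)
    else:
        model = complex_1
    return TernaryModel(model, sup, clashes, ag1_chains, ag2_chains)


def _concat(a: Structure, b: Structure) -> Structure:
    return Structure(
        a.chain_ids + b.chain_ids, a.res_seq + b.res_seq, a.icodes + b.icodes,
        a.res_names + b.res_names, a.atom_names + b.atom_names,
        a.elements + b.elements, np.vstack([a.coords, b.coords]),
        a.cell, a.spacegroup,
    )


# ---------------------------------------------------------------------------
# Matthews coefficient / solvent content
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrystalForm:
    """Crystal-form bookkeeping for the Matthews analysis.

    cell_volume in Å³, `copies` complexes per asymmetric unit, space-group
    multiplicity `z`, molecular weight per complex in Da, partial specific
    volume v̄ in cm³/g (0.74 is the usual protein value).
    """

    cell_volume: float
    copies: int
    z: int
    mw: float
    vbar: float = 0.74

    def __post_init__(self):
        if min(self.cell_volume, self.copies, self.z, self.mw, self.vbar) <= 0:
            raise StructureError("crystal-form parameters must be positive")


def matthews_coefficient(cf: CrystalForm) -> float:
    """V_M = V / (z · n · MW) in Å³/Da."""
    return cf.cell_volume / (cf.z * cf.copies * cf.mw)


def solvent_content(vm: float, vbar: float = 0.74) -> float:
    """Solvent fraction S = 1 − 1.66054·v̄ / V_M, clamped to [0, 1]."""
    if vm <= 0 or vbar <= 0:
        raise StructureError("V_M and v̄ must be positive")
    return min(max(1.0 - 1.66054 * vbar / vm, 0.0), 1.0)


def matthews(cf: CrystalForm) -> tuple[float, float]:
    """(Matthews coefficient V_M in Å³/Da, solvent fraction S)."""
    vm = matthews_coefficient(cf)
    return vm, solvent_content(vm, cf.vbar)


def cell_volume(a: float, b: float, c: float, alpha: float, beta: float, gamma: float) -> float:
    """Unit-cell volume in Å³ from lengths (Å) and angles (degrees)."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise StructureError("invalid cell angles")
    return a * b * c * math.sqrt(arg)
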