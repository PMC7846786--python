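"""Seeded synthetic-data generators.

Everything the test suite needs is generated here, download-free:
rule-compliant scaffold Fvs, monospecific binders with known ground-truth
deviation sets, toy two-group atomic complexes whose surface areas and
clash counts are known by construction, and noisy dose-response curves.

The toy complexes use pseudo-atoms with standard protein vdW radii rather
than real protein geometry: that is sufficient to validate surface-area,
footprint and clash computations exactly, which is their only purpose.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DutafabError
from .fv_numbering import (
    AMINO_ACIDS,
    VH3_TEMPLATE,
    VK1_TEMPLATE,
    FvSequence,
    NumberedFv,
    annotate_regions,
    assign_numbering,
    write_fasta,
)
from .paratope_model import (
    Position,
    ScaffoldRuleSet,
    check_scaffold_compliance,
    default_rules,
    default_scheme_pair,
    resolve_paratope_positions,
)
from .structure_tools import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    DEFAULT_RADII,
    Structure,
    from_atoms,
    interface_footprint,
    sasa,
    write_pdb,
)

DENSE_N_POINTS = 5000  # point count for attached dense-oracle expectations


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------


def _mutable_positions(nfv: NumberedFv, side: str | None, rules: ScaffoldRuleSet,
                       include_enhancing: bool = True) -> list[Position]:
    h_scheme, l_scheme = default_scheme_pair()
    schemes = {"H-side": [h_scheme], "L-side": [l_scheme], None: [h_scheme, l_scheme]}[side]
    ann = annotate_regions(nfv, h_scheme.cdr_scheme)
    pool: set[Position] = set()
    for scheme in schemes:
        pool |= set(resolve_paratope_positions(scheme, ann, include_enhancing))
    pool -= rules.rule_positions()
    frame = {(c, r.label) for c in "HL" for r in nfv.residues(c)}
    return sorted(pool & frame)


def make_scaffold(seed: int, n_mutations_per_side: int = 3,
                  rules: ScaffoldRuleSet | None = None) -> FvSequence:
    """A rule-compliant VH3-Vk1 scaffold: the template lightly mutated inside
    the diversifiable paratope positions (rule positions untouched)."""
    rules = rules or default_rules()
    rng = _rng(seed)
    template = assign_numbering(FvSequence(VH3_TEMPLATE, VK1_TEMPLATE, f"scaffold-{seed}"))
    repl: dict[Position, str] = {}
    for side in ("H-side", "L-side"):
        pool = _mutable_positions(template, side, rules)
        picks = rng.choice(len(pool), size=min(n_mutations_per_side, len(pool)),
                           replace=False)
        for i in sorted(picks):
            chain, label = pool[i]
            current = template.aa_at(chain, label)
            choices = [a for a in AMINO_ACIDS if a != current and a not in "C"]
            repl[(chain, label)] = choices[rng.integers(len(choices))]
    scaffold = template.with_replacements(repl)
    report = check_scaffold_compliance(scaffold, rules)
    assert report.overall, "fixture construction violated scaffold rules"
    return scaffold.source


def make_binder(
    scaffold: FvSequence | NumberedFv,
    side: str,
    n_mutations: int,
    seed: int,
    include_enhancing: bool = True,
    rules: ScaffoldRuleSet | None = None,
) -> tuple[FvSequence, frozenset[Position]]:
    """A monospecific binder deviating from the scaffold at exactly
    `n_mutations` positions, all inside `side`'s resolved paratope set.

    Returns the binder and its ground-truth deviation label set.
    """
    rules = rules or default_rules()
    nfv = scaffold if isinstance(scaffold, NumberedFv) else assign_numbering(scaffold)
    pool = _mutable_positions(nfv, side, rules, include_enhancing)
    if n_mutations > len(pool):
        raise DutafabError(
            f"n_mutations={n_mutations} exceeds {len(pool)} mutable {side} positions"
        )
    rng = _rng(seed)
    picks = sorted(rng.choice(len(pool), size=n_mutations, replace=False))
    repl: dict[Position, str] = {}
    for i in picks:
        chain, label = pool[i]
        current = nfv.aa_at(chain, label)
        choices = [a for a in AMINO_ACIDS if a != current and a != "C"]
        repl[(chain, label)] = choices[rng.integers(len(choices))]
    binder = nfv.with_replacements(repl)
    tag = "h" if side == "H-side" else "l"
    fv = FvSequence(binder.source.heavy, binder.source.light,
                    f"{nfv.source.id}-{tag}binder-{seed}")
    return fv, frozenset(repl)


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S")


def _blob(rng, chain: str, n_atoms: int, center, radius: float, res_start: int = 1):
    """Random pseudo-atom cloud inside a sphere, grouped into 8-atom residues."""
    atoms = []
    pts = []
    while len(pts) < n_atoms:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            pts.append(p + np.asarray(center, dtype=float))
    for i, p in enumerate(pts):
        el = _ELEMENTS[rng.integers(len(_ELEMENTS))]
        atoms.append(
            (chain, res_start + i // 8, "", "TOY", f"{el}{i % 8 + 1}", el,
             float(p[0]), float(p[1]), float(p[2]))
        )
    return atoms


def make_toy_complex(
    seed: int,
    geometry: str = "contacting",
    n_atoms: tuple[int, int] = (40, 40),
    n_clashes: int = 5,
) -> tuple[Structure, dict]:
    """A two-chain-group pseudo-atom complex with analytic expectations.

    geometry:
      * "separated"  — groups farther apart than any probe-expanded spheres
        can reach: both buried areas are exactly zero;
      * "contacting" — groups interpenetrate slightly; expectations carry
        dense-point recomputations of the buried areas;
      * "clashing"   — groups well separated except for `n_clashes`
        engineered atom pairs with known severe vdW overlap.
    """
    rng = _rng(seed)
    na, nb = n_atoms
    blob_r = 6.0
    r_max = max(DEFAULT_RADII[e] for e in _ELEMENTS)
    expectations: dict = {"geometry": geometry, "seed": seed}

    if geometry == "separated":
        gap = 2.0 * (r_max + DEFAULT_PROBE) + 5.0
        atoms = _blob(rng, "A", na, (0, 0, 0), blob_r) + _blob(
            rng, "B", nb, (2 * blob_r + gap, 0, 0), blob_r
        )
        s = from_atoms(atoms)
        expectations["buried_a"] = 0.0
        expectations["buried_b"] = 0.0
    elif geometry == "contacting":
        atoms = _blob(rng, "A", na, (0, 0, 0), blob_r) + _blob(
            rng, "B", nb, (2 * blob_r - 1.5, 0, 0), blob_r
        )
        s = from_atoms(atoms)
        dense = interface_footprint(s, ["A"], ["B"], n_points=DENSE_N_POINTS)
        expectations["buried_a_dense"] = dense.side_a_buried
        expectations["buried_b_dense"] = dense.side_b_buried
        expectations["dense_n_points"] = DENSE_N_POINTS
    elif geometry == "clashing":
        gap = 2.0 * (r_max + DEFAULT_PROBE) + 5.0
        atoms = _blob(rng, "A", na, (0, 0, 0), blob_r) + _blob(
            rng, "B", nb, (2 * blob_r + gap, 0, 0), blob_r
        )
        # engineered isolated clash pairs on a line far below the blobs
        base_y = -(blob_r + gap + 20.0)
        overlaps = []
        for k in range(n_clashes):
            ea = _ELEMENTS[rng.integers(len(_ELEMENTS))]
            eb = _ELEMENTS[rng.integers(len(_ELEMENTS))]
            contact = DEFAULT_RADII[ea] + DEFAULT_RADII[eb]
            d = contact - 0.6  # overlap 0.6 Å > 0.4 Å tolerance: severe
            x = 25.0 * k
            atoms.append(("A", 500 + k, "", "CLH", f"{ea}1", ea, x, base_y, 0.0))
            atoms.append(("B", 500 + k, "", "CLH", f"{eb}1", eb, x + d, base_y, 0.0))
            overlaps.append(contact - d)
        s = from_atoms(atoms)
        expectations["n_clashes"] = n_clashes
        expectations["overlaps"] = overlaps
    else:
        raise DutafabError(f"unknown geometry {geometry!r}")
    return s, expectations


def make_cobinding_pair(
    seed: int,
    opposite: bool = True,
    n_fab: int = 60,
    n_antigen: int = 30,
) -> tuple[Structure, Structure, dict]:
    """Two synthetic Fab-antigen complexes sharing the same Fab (chain F).

    Complex 1 carries antigen G on the +x face of the Fab.  Complex 2 carries
    its antigen on the -x face (`opposite=True`, co-binding sterically
    feasible: zero expected inter-antigen clashes after Fab superposition) or
    on the same +x face (`opposite=False`, guaranteed clashes).  Complex 2 is
    returned under a random rigid motion so the superposition is non-trivial.
    """
    rng = _rng(seed)
    # Fab: one CA pseudo-atom per residue, shared between both complexes
    fab_atoms = []
    pts = rng.uniform(-8.0, 8.0, size=(n_fab, 3))
    for i, p in enumerate(pts):
        fab_atoms.append(("F", i + 1, "", "ALA", "CA", "C",
                          float(p[0]), float(p[1]), float(p[2])))
    ag1 = _blob(rng, "G", n_antigen, (16.0, 0.0, 0.0), 4.0)
    center2 = (-16.0, 0.0, 0.0) if opposite else (16.5, 0.5, 0.0)
    ag2 = _blob(rng, "G", n_antigen, center2, 4.0)
    c1 = from_atoms(fab_atoms + ag1)
    c2 = from_atoms(fab_atoms + ag2)
    # random proper rotation + translation applied to complex 2
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    c2 = c2.transformed(rot, rng.uniform(-30.0, 30.0, size=3))
    expectations = {"seed": seed, "opposite": opposite,
                    "expected_clashes": 0 if opposite else None}
    return c1, c2, expectations


# ---------------------------------------------------------------------------
# dose-response fixtures
# ---------------------------------------------------------------------------


def make_dose_response(
    seed: int,
    top: float = 2.0,
    bottom: float = 0.1,
    ic50: float = 1e-10,
    hill: float = 1.2,
    n_doses: int = 11,
    sigma: float = 0.0,
    span_decades: float = 5.0,
):
    """Half-log dose series around IC50 with optional Gaussian signal noise."""
    rng = _rng(seed)
    x = ic50 * np.power(10.0, np.linspace(-span_decades / 2, span_decades / 2, n_doses))
    y = bottom + (top - bottom) / (1.0 + np.power(x / ic50, hill))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=len(y))
    return x, y


# ---------------------------------------------------------------------------
# manifest-driven fixture suite
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    items: tuple[dict, ...]

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "items": list(self.items)}, indent=2)


def make_fixtures(seed: int, outdir: str | os.PathLike) -> FixtureManifest:
    """Write the standard fixture suite (FASTA, PDB, JSON manifest) to a
    directory; byte-identical for a given seed."""
    os.makedirs(outdir, exist_ok=True)
    items: list[dict] = []

    scaffold = make_scaffold(seed)
    h_binder, h_set = make_binder(scaffold, "H-side", 6, seed + 1)
    l_binder, l_set = make_binder(scaffold, "L-side", 6, seed + 2)
    fasta_path = os.path.join(outdir, "fv_fixtures.fasta")
    write_fasta([scaffold, h_binder, l_binder], fasta_path)
    items.append(
        {"kind": "fv_set", "id": scaffold.id, "path": "fv_fixtures.fasta",
         "h_deviation": sorted(f"{c}{l}" for c, l in h_set),
         "l_deviation": sorted(f"{c}{l}" for c, l in l_set)}
    )

    for geometry in ("separated", "contacting", "clashing"):
        s, exp = make_toy_complex(seed, geometry)
        name = f"toy_{geometry}.pdb"
        write_pdb(s, os.path.join(outdir, name))
        items.append({"kind": "toy_complex", "id": geometry, "path": name,
                      "expectations": exp})

    x, y = make_dose_response(seed, sigma=0.03)
    dr_path = os.path.join(outdir, "dose_response.tsv")
    with open(dr_path, "w") as fh:
        fh.write("dose\tsignal\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.6e}\t{yi:.6f}\n")
    items.append({"kind": "dose_response", "id": "noisy-4pl", "path": "dose_response.tsv",
                  "true_params": {"top": 2.0, "bottom": 0.1, "ic50": 1e-10, "hill": 1.2,
                                  "sigma": 0.03}})

    manifest = FixtureManifest(seed, tuple(items))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest
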