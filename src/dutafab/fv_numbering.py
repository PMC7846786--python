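"""Fv sequence parsing, template-anchored Kabat-style numbering and CDR annotation.

The toolkit targets human VH3-Vk1 Fv scaffolds only.  Numbering is therefore
template-based: each chain is globally aligned (BLOSUM62, affine gaps 11/1)
to an embedded VH3/Vk1 consensus template whose residues carry fixed
Kabat-style labels H1..H113 and L1..L107.  Length differences relative to
the template are absorbed exclusively at a small set of permitted anchor
positions (the canonical CDR/framework insertion points); extra residues
receive insertion-coded labels ("100A", "100B", ...) directly after the
anchor and missing residues delete labels counting back from the anchor.
Any required indel away from a permitted anchor is an error rather than a
guess — the platform deliberately refuses sequences it cannot place on the
VH3-Vk1 frame.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import FastaError, NumberingError, SchemeError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# label helpers
# ---------------------------------------------------------------------------


def label_key(label: str) -> tuple[int, str]:
    """Sort key for a scheme label: ("100A") -> (100, "A").  "" < "A" < "B"."""
    num = label.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    ins = label[len(num):]
    if not num.isdigit():
        raise SchemeError(f"malformed position label {label!r}")
    return int(num), ins


def _ins_labels(anchor: int, count: int) -> list[str]:
    return [f"{anchor}{chr(ord('A') + i)}" for i in range(count)]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FvSequence:
    """A paired heavy/light variable-domain amino-acid sequence."""

    heavy: str
    light: str
    id: str = ""

    def __post_init__(self) -> None:
        for name, seq in (("heavy", self.heavy), ("light", self.light)):
            if not seq:
                raise FastaError(f"{name} chain of {self.id!r} is empty")
            bad = sorted({c for c in seq if c not in AMINO_ACIDS})
            if bad:
                raise FastaError(
                    f"illegal residue {','.join(bad)} in {name} chain of {self.id!r}"
                )

    def chain(self, chain: str) -> str:
        if chain == "H":
            return self.heavy
        if chain == "L":
            return self.light
        raise SchemeError(f"unknown chain {chain!r}")


@dataclass(frozen=True)
class NumberedResidue:
    chain: str          # "H" or "L"
    label: str          # e.g. "35", "100A"
    aa: str
    ordinal: int        # 0-based index into the raw chain sequence


@dataclass(frozen=True)
class NumberedFv:
    """An FvSequence with per-residue scheme labels on both chains."""

    source: FvSequence
    heavy_residues: tuple[NumberedResidue, ...]
    light_residues: tuple[NumberedResidue, ...]
    template_id: str

    def residues(self, chain: str) -> tuple[NumberedResidue, ...]:
        return self.heavy_residues if chain == "H" else self.light_residues

    def label_map(self, chain: str) -> dict[str, str]:
        """Ordered mapping label -> amino acid for one chain."""
        return {r.label: r.aa for r in self.residues(chain)}

    def aa_at(self, chain: str, label: str) -> str | None:
        return self.label_map(chain).get(label)

    def with_replacements(self, repl: Mapping[tuple[str, str], str]) -> "NumberedFv":
        """Return a copy with amino acids replaced at (chain, label) keys."""
        chains = {}
        for chain in "HL":
            chains[chain] = tuple(
                NumberedResidue(r.chain, r.label, repl.get((chain, r.label), r.aa), r.ordinal)
                for r in self.residues(chain)
            )
        src = FvSequence(
            heavy="".join(r.aa for r in chains["H"]),
            light="".join(r.aa for r in chains["L"]),
            id=self.source.id,
        )
        return NumberedFv(src, chains["H"], chains["L"], self.template_id)


@dataclass(frozen=True)
class RegionAnnotation:
    """Framework/CDR partition of a numbered Fv under one CDR scheme."""

    scheme: str
    regions: dict[str, tuple[str, ...]]  # region name -> ordered labels

    def region_of(self, chain: str, label: str) -> str:
        for name, labels in self.regions.items():
            if name.startswith(chain) and label in labels:
                return name
        raise SchemeError(f"label {chain}{label} not in annotation")


# ---------------------------------------------------------------------------
# embedded templates
# ---------------------------------------------------------------------------

# Segment table: (name, first label, last label, permitted indel anchor or None).
# Anchors are the canonical Kabat insertion points H35/H52/H82/H100, L27/L95/L106.
HEAVY_SEGMENTS: tuple[tuple[str, int, int, int | None], ...] = (
    ("HFR1", 1, 30, None),
    ("HCDR1", 31, 35, 35),
    ("HFR2", 36, 49, None),
    ("HCDR2", 50, 65, 52),
    ("HFR3", 66, 94, 82),
    ("HCDR3", 95, 102, 100),
    ("HFR4", 103, 113, None),
)
LIGHT_SEGMENTS: tuple[tuple[str, int, int, int | None], ...] = (
    ("LFR1", 1, 23, None),
    ("LCDR1", 24, 34, 27),
    ("LFR2", 35, 49, None),
    ("LCDR2", 50, 56, None),
    ("LFR3", 57, 88, None),
    ("LCDR3", 89, 97, 95),
    ("LFR4", 98, 107, 106),
)

# VH3 consensus (VH3-23-like), 113 residues = labels 1..113.
VH3_TEMPLATE = (
    "EVQLLESGGGLVQPGGSLRLSCAASGFTFS"  # HFR1   1-30
    "SYAMS"                            # HCDR1 31-35
    "WVRQAPGKGLEWVS"                   # HFR2  36-49
    "AISGSGGSTYYADSVK"                 # HCDR2 50-65
    "RFTISRDNSKNTLYLQMRAEDTAVYYCAR"    # HFR3  66-94
    "GSSYYGDY"                         # HCDR3 95-102 (Y99, D101 kinked motif)
    "WGQGTLVTVSS"                      # HFR4  103-113
)
# Vk1 consensus (Vk1-39-like), 107 residues = labels 1..107.
VK1_TEMPLATE = (
    "DIQMTQSPSSLSASVGDRVTITC"          # LFR1   1-23
    "RASQSISSYLN"                      # LCDR1 24-34
    "WYQQKPGKAPKLLIY"                  # LFR2  35-49 (Y49 aromatic pair partner)
    "AASSLQS"                          # LCDR2 50-56
    "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # LFR3 57-88
    "QQSYSTPLT"                        # LCDR3 89-97
    "FGQGTKLEIK"                       # LFR4  98-107
)

assert len(VH3_TEMPLATE) == 113 and len(VK1_TEMPLATE) == 107

DEFAULT_TEMPLATE_ID = "VH3-consensus/Vk1-consensus"
_TEMPLATES: dict[str, tuple[str, tuple]] = {
    "H": (VH3_TEMPLATE, HEAVY_SEGMENTS),
    "L": (VK1_TEMPLATE, LIGHT_SEGMENTS),
}

FRAMEWORK_IDENTITY_THRESHOLD = 0.55


def template_sequence(chain: str) -> str:
    return _TEMPLATES[chain][0]


def template_aa(chain: str, label: str) -> str:
    """Template residue at a plain label (insertion-coded labels have none)."""
    num, ins = label_key(label)
    if ins:
        raise SchemeError(f"template has no insertion-coded label {label}")
    seq = template_sequence(chain)
    if not 1 <= num <= len(seq):
        raise SchemeError(f"label {chain}{label} outside template frame")
    return seq[num - 1]


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def parse_fasta(path_or_text: str | os.PathLike, sep: str = "|") -> list[FvSequence]:
    """Parse paired VH/VL records from FASTA.

    Headers follow the dialect ``id|H`` / ``id|L`` (separator configurable).
    Records may appear in any order; both chains must be present exactly once
    per id.  Record order of first appearance is preserved.
    """
    text = None
    if isinstance(path_or_text, str) and path_or_text.lstrip().startswith(">"):
        text = path_or_text
    handle = io.StringIO(text) if text is not None else open(path_or_text)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        handle.close()
    if not records:
        raise FastaError("no FASTA records found")

    chains: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in records:
        head = rec.id
        if sep not in head:
            raise FastaError(f"header {head!r} lacks chain tag (expected id{sep}H/L)")
        fv_id, _, tag = head.rpartition(sep)
        tag = tag.upper()
        if tag not in ("H", "L"):
            raise FastaError(f"header {head!r}: chain tag must be H or L")
        entry = chains.setdefault(fv_id, {})
        if fv_id not in order:
            order.append(fv_id)
        if tag in entry:
            raise FastaError(f"duplicate record for ({fv_id!r}, {tag})")
        entry[tag] = str(rec.seq).upper()

    out = []
    for fv_id in order:
        entry = chains[fv_id]
        for tag in "HL":
            if tag not in entry:
                raise FastaError(f"missing {tag} chain for id {fv_id!r}")
        out.append(FvSequence(heavy=entry["H"], light=entry["L"], id=fv_id))
    return out


def write_fasta(fvs: Iterable[FvSequence], path=None, sep: str = "|") -> str:
    lines = []
    for fv in fvs:
        lines += [f">{fv.id}{sep}H", fv.heavy, f">{fv.id}{sep}L", fv.light]
    out = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# numbering
# ---------------------------------------------------------------------------


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def _alignment_columns(template: str, query: str):
    """Yield (t_idx | None, q_idx | None) per alignment column, deterministic."""
    aln = _ALIGNER.align(template, query)[0]
    coords = aln.coordinates
    cols = []
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 and q1 > q0:
            cols += [(t0 + i, q0 + i) for i in range(t1 - t0)]
        elif t1 > t0:
            cols += [(t0 + i, None) for i in range(t1 - t0)]
        else:
            cols += [(None, q0 + i) for i in range(q1 - q0)]
    return cols


def _segment_of(segments, t_idx: int) -> int:
    num = t_idx + 1  # template labels are 1-based and contiguous
    for i, (_, start, end, _) in enumerate(segments):
        if start <= num <= end:
            return i
    raise AssertionError("template index outside segment table")


def _number_chain(chain: str, seq: str) -> tuple[NumberedResidue, ...]:
    template, segments = _TEMPLATES[chain]
    cols = _alignment_columns(template, seq)

    # framework identity gate
    fr_total = fr_match = 0
    for t_idx, q_idx in cols:
        if t_idx is None:
            continue
        name = segments[_segment_of(segments, t_idx)][0]
        if "FR" in name:
            fr_total += 1
            if q_idx is not None and seq[q_idx] == template[t_idx]:
                fr_match += 1
    if fr_total == 0 or fr_match / fr_total < FRAMEWORK_IDENTITY_THRESHOLD:
        raise NumberingError(
            f"{chain} chain framework identity "
            f"{fr_match}/{fr_total} below threshold: not a supported "
            f"{'VH3' if chain == 'H' else 'Vk1'}-like domain"
        )

    # assign every query residue to a segment
    seg_members: dict[int, list[int]] = {i: [] for i in range(len(segments))}
    n_cols = len(cols)
    for ci, (t_idx, q_idx) in enumerate(cols):
        if q_idx is None:
            continue
        if t_idx is not None:
            seg_members[_segment_of(segments, t_idx)].append(q_idx)
            continue
        # insertion column: find flanking template positions
        prev_t = next((cols[j][0] for j in range(ci - 1, -1, -1) if cols[j][0] is not None), None)
        next_t = next((cols[j][0] for j in range(ci + 1, n_cols) if cols[j][0] is not None), None)
        seg_prev = _segment_of(segments, prev_t) if prev_t is not None else None
        seg_next = _segment_of(segments, next_t) if next_t is not None else None
        if seg_prev is None:
            target = seg_next
        elif seg_next is None or seg_prev == seg_next:
            target = seg_prev
        else:
            # run sits on a segment boundary: prefer the elastic segment
            if segments[seg_prev][3] is not None:
                target = seg_prev
            elif segments[seg_next][3] is not None:
                target = seg_next
            else:
                target = seg_prev
        seg_members[target].append(q_idx)

    # canonicalise labels per segment
    residues: list[NumberedResidue] = []
    for i, (name, start, end, anchor) in enumerate(segments):
        members = sorted(seg_members[i])
        m = end - start + 1
        n = len(members)
        if n != m and anchor is None:
            raise NumberingError(
                f"{chain} chain: length change of {n - m:+d} in {name} "
                f"requires an indel at a non-permitted anchor"
            )
        if n == m:
            labels = [str(p) for p in range(start, end + 1)]
        elif n > m:
            k = anchor - start + 1
            labels = (
                [str(p) for p in range(start, anchor + 1)]
                + _ins_labels(anchor, n - m)
                + [str(p) for p in range(anchor + 1, end + 1)]
            )
            assert len(labels) == n and k <= m
        else:
            d = m - n
            if anchor - d + 1 < start:
                raise NumberingError(
                    f"{chain} chain: {name} too short to place on the template"
                )
            labels = [str(p) for p in range(start, anchor - d + 1)] + [
                str(p) for p in range(anchor + 1, end + 1)
            ]
        for label, q_idx in zip(labels, members):
            residues.append(NumberedResidue(chain, label, seq[q_idx], q_idx))

    residues.sort(key=lambda r: r.ordinal)
    # contract: ordinals are the full chain, labels unique and ordered
    assert [r.ordinal for r in residues] == list(range(len(seq)))
    assert len({r.label for r in residues}) == len(residues)
    keys = [label_key(r.label) for r in residues]
    assert keys == sorted(keys)
    return tuple(residues)


def assign_numbering(fv: FvSequence) -> NumberedFv:
    """Number both chains of an Fv on the embedded VH3/Vk1 templates."""
    heavy = _number_chain("H", fv.heavy)
    light = _number_chain("L", fv.light)
    return NumberedFv(fv, heavy, light, DEFAULT_TEMPLATE_ID)


# ---------------------------------------------------------------------------
# CDR scheme tables and region annotation
# ---------------------------------------------------------------------------

# CDR extents expressed in the template label frame, inclusive.
SCHEME_CDRS: dict[str, dict[str, tuple[int, int]]] = {
    "kabat": {
        "HCDR1": (31, 35), "HCDR2": (50, 65), "HCDR3": (95, 102),
        "LCDR1": (24, 34), "LCDR2": (50, 56), "LCDR3": (89, 97),
    },
    "chothia": {
        "HCDR1": (26, 32), "HCDR2": (52, 56), "HCDR3": (95, 102),
        "LCDR1": (26, 32), "LCDR2": (50, 52), "LCDR3": (91, 96),
    },
    "contact": {
        "HCDR1": (30, 35), "HCDR2": (47, 58), "HCDR3": (93, 101),
        "LCDR1": (30, 36), "LCDR2": (46, 55), "LCDR3": (89, 96),
    },
}


def _union_cdrs() -> dict[str, tuple[int, int]]:
    out = {}
    for cdr in SCHEME_CDRS["kabat"]:
        starts, ends = zip(*(SCHEME_CDRS[s][cdr] for s in SCHEME_CDRS))
        out[cdr] = (min(starts), max(ends))
    return out


SCHEME_CDRS["union"] = _union_cdrs()
SCHEME_NAMES = tuple(SCHEME_CDRS)


def cdr_extents(scheme: str, overrides: Mapping[str, tuple[int, int]] | None = None):
    if scheme not in SCHEME_CDRS:
        raise SchemeError(f"unknown CDR scheme {scheme!r}")
    table = dict(SCHEME_CDRS[scheme])
    if overrides:
        table.update(overrides)
    return table


def annotate_regions(
    nfv: NumberedFv,
    scheme: str = "kabat",
    overrides: Mapping[str, tuple[int, int]] | None = None,
) -> RegionAnnotation:
    """Partition each chain into FR1..FR4 / CDR1..3 under a CDR scheme.

    An insertion-coded label belongs to the region of its integer anchor
    (e.g. "100A" lies inside any CDR whose extent covers 100..).
    """
    table = cdr_extents(scheme, overrides)
    regions: dict[str, tuple[str, ...]] = {}
    for chain in "HL":
        cdrs = sorted(
            ((table[f"{chain}CDR{i}"], i) for i in (1, 2, 3)), key=lambda t: t[0]
        )
        buckets: dict[str, list[str]] = {f"{chain}FR{i}": [] for i in (1, 2, 3, 4)}
        buckets.update({f"{chain}CDR{i}": [] for i in (1, 2, 3)})
        for res in nfv.residues(chain):
            num, _ = label_key(res.label)
            placed = None
            fr = 1
            for (start, end), i in cdrs:
                if num < start:
                    placed = f"{chain}FR{fr}"
                    break
                if num <= end:
                    placed = f"{chain}CDR{i}"
                    break
                fr += 1
            if placed is None:
                placed = f"{chain}FR4"
            buckets[placed].append(res.label)
        for name, labels in buckets.items():
            regions[name] = tuple(labels)
    return RegionAnnotation(scheme=scheme, regions=regions)


def numbering_table(nfv: NumberedFv, annotation: RegionAnnotation):
    """Per-residue table (chain, label, aa, region) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for chain in "HL":
        for res in nfv.residues(chain):
            rows.append(
                {
                    "chain": chain,
                    "label": res.label,
                    "aa": res.aa,
                    "region": annotation.region_of(chain, res.label),
                }
            )
    return pd.DataFrame(rows)
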