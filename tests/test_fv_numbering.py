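"""Numbering engine: FASTA pairing, template alignment, region schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dutafab import (
    FastaError,
    FvSequence,
    NumberingError,
    SchemeError,
    annotate_regions,
    assign_numbering,
    parse_fasta,
    write_fasta,
)
from dutafab.fv_numbering import (
    HEAVY_SEGMENTS,
    LIGHT_SEGMENTS,
    SCHEME_CDRS,
    VH3_TEMPLATE,
    VK1_TEMPLATE,
    label_key,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParseFasta:
    def test_minimal_pair(self):
        text = f">x|H\n{VH3_TEMPLATE}\n>x|L\n{VK1_TEMPLATE}\n"
        fvs = parse_fasta(text)
        assert len(fvs) == 1 and fvs[0].id == "x"
        assert fvs[0].heavy == VH3_TEMPLATE and fvs[0].light == VK1_TEMPLATE

    def test_illegal_residue(self):
        with pytest.raises(FastaError, match="illegal residue"):
            parse_fasta(f">x|H\nABC\n>x|L\n{VK1_TEMPLATE}\n")

    def test_shuffled_records_pair_correctly(self, tmp_path):
        ids = ["a", "b", "c"]
        records = []
        for i, fv_id in enumerate(ids):
            records.append((f"{fv_id}|H", VH3_TEMPLATE[:-1] + AA[i]))
            records.append((f"{fv_id}|L", VK1_TEMPLATE))
        order = [1, 4, 0, 3, 5, 2]  # interleave H/L across ids
        path = tmp_path / "fv.fasta"
        path.write_text("".join(f">{records[i][0]}\n{records[i][1]}\n" for i in order))
        fvs = parse_fasta(path)
        assert len(fvs) == 3
        by_id = {fv.id: fv for fv in fvs}
        for i, fv_id in enumerate(ids):
            assert by_id[fv_id].heavy.endswith(AA[i])
            assert by_id[fv_id].light == VK1_TEMPLATE

    @pytest.mark.parametrize(
        "text,msg",
        [
            (f">x|H\n{VH3_TEMPLATE}\n", "missing L chain"),
            (f">x|H\n{VH3_TEMPLATE}\n>x|H\n{VH3_TEMPLATE}\n", "duplicate"),
            (f">x\n{VH3_TEMPLATE}\n", "chain tag"),
        ],
    )
    def test_error_paths(self, text, msg):
        with pytest.raises(FastaError, match=msg):
            parse_fasta(text)

    def test_roundtrip(self, template_fv, tmp_path):
        path = tmp_path / "out.fasta"
        write_fasta([template_fv], path)
        assert parse_fasta(path) == [template_fv]


class TestAssignNumbering:
    def test_template_self_numbering(self, template_nfv):
        for chain, n in (("H", 113), ("L", 107)):
            labels = [r.label for r in template_nfv.residues(chain)]
            assert labels == [str(i) for i in range(1, n + 1)]

    def test_hcdr3_insertion_gets_100A(self, template_fv):
        heavy = VH3_TEMPLATE[:100] + "W" + VH3_TEMPLATE[100:]
        nfv = assign_numbering(FvSequence(heavy, VK1_TEMPLATE, "ins"))
        labels = [r.label for r in nfv.heavy_residues]
        assert "100A" in labels
        assert nfv.aa_at("H", "100A") == "W"
        # all framework labels unchanged
        for seg, start, end, _ in HEAVY_SEGMENTS:
            if "FR" in seg:
                assert all(str(p) in labels for p in range(start, end + 1))

    def test_hcdr3_deletion_skips_100(self):
        heavy = VH3_TEMPLATE[:99] + VH3_TEMPLATE[100:]  # drop the residue at H100
        nfv = assign_numbering(FvSequence(heavy, VK1_TEMPLATE, "del"))
        labels = {r.label for r in nfv.heavy_residues}
        assert "100" not in labels and "101" in labels
        assert nfv.aa_at("H", "101") == "D"

    def test_non_vh3_sequence_rejected(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list(AA), size=113))
        with pytest.raises(NumberingError, match="not a supported"):
            assign_numbering(FvSequence(junk, VK1_TEMPLATE, "junk"))

    def test_indel_at_non_permitted_anchor_rejected(self):
        heavy = VH3_TEMPLATE[:10] + "W" + VH3_TEMPLATE[10:]  # insertion inside HFR1
        with pytest.raises(NumberingError, match="non-permitted anchor"):
            assign_numbering(FvSequence(heavy, VK1_TEMPLATE, "bad"))

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_roundtrip_on_perturbed_fvs(self, data):
        """sequence -> numbering -> region concatenation reproduces the input."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        heavy, light = list(VH3_TEMPLATE), list(VK1_TEMPLATE)
        for seq in (heavy, light):
            for i in rng.choice(len(seq), size=8, replace=False):
                seq[i] = AA[rng.integers(20)]
        ins = data.draw(st.integers(0, 3))
        heavy[100:100] = ["G"] * ins  # grow HCDR3 after the anchor
        fv = FvSequence("".join(heavy), "".join(light), "p")
        nfv = assign_numbering(fv)
        scheme = data.draw(st.sampled_from(list(SCHEME_CDRS)))
        ann = annotate_regions(nfv, scheme)
        for chain, raw in (("H", fv.heavy), ("L", fv.light)):
            order = [f"{chain}FR1", f"{chain}CDR1", f"{chain}FR2", f"{chain}CDR2",
                     f"{chain}FR3", f"{chain}CDR3", f"{chain}FR4"]
            labels = [lab for name in order for lab in ann.regions[name]]
            assert len(labels) == len(raw)
            rebuilt = "".join(nfv.aa_at(chain, lab) for lab in labels)
            assert rebuilt == raw

    def test_framework_point_mutation_changes_no_label(self, template_nfv):
        base_labels = {c: [r.label for r in template_nfv.residues(c)] for c in "HL"}
        rng = np.random.default_rng(5)
        ann = annotate_regions(template_nfv, "kabat")
        fr_labels = [("H", lab) for name in ann.regions if "HFR" in name
                     for lab in ann.regions[name]]
        for chain, label in [fr_labels[i] for i in rng.choice(len(fr_labels), 10, replace=False)]:
            cur = template_nfv.aa_at(chain, label)
            sub = AA[(AA.index(cur) + 1) % 20]
            mut = template_nfv.with_replacements({(chain, label): sub})
            renum = assign_numbering(mut.source)
            assert [r.label for r in renum.residues(chain)] == base_labels[chain]

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_insertion_monotonicity(self, k):
        """k extra residues at the H100 anchor add exactly k insertion labels."""
        heavy = VH3_TEMPLATE[:100] + "A" * k + VH3_TEMPLATE[100:]
        nfv = assign_numbering(FvSequence(heavy, VK1_TEMPLATE, "m"))
        labels = [r.label for r in nfv.heavy_residues]
        base = [r.label for r in
                assign_numbering(FvSequence(VH3_TEMPLATE, VK1_TEMPLATE, "t")).heavy_residues]
        inserted = [lab for lab in labels if lab not in base]
        assert inserted == [f"100{chr(ord('A') + i)}" for i in range(k)]
        assert [lab for lab in labels if lab in base] == base


class TestRegions:
    def test_kabat_lcdr2_extent(self, template_nfv):
        ann = annotate_regions(template_nfv, "kabat")
        assert ann.regions["LCDR2"] == tuple(str(i) for i in range(50, 57))

    def test_union_contains_each_scheme(self, template_nfv):
        union = annotate_regions(template_nfv, "union")
        for scheme in ("kabat", "chothia", "contact"):
            single = annotate_regions(template_nfv, scheme)
            for cdr in ("HCDR1", "HCDR2", "HCDR3", "LCDR1", "LCDR2", "LCDR3"):
                assert set(single.regions[cdr]) <= set(union.regions[cdr])

    def test_chothia_vs_kabat_hcdr1_differ(self, template_nfv):
        kabat = annotate_regions(template_nfv, "kabat")
        chothia = annotate_regions(template_nfv, "chothia")
        assert set(kabat.regions["HCDR1"]) != set(chothia.regions["HCDR1"])

    def test_unknown_scheme(self, template_nfv):
        with pytest.raises(SchemeError, match="unknown CDR scheme"):
            annotate_regions(template_nfv, "imgt")

    def test_label_key_ordering(self):
        keys = [label_key(s) for s in ["99", "100", "100A", "100B", "101"]]
        assert keys == sorted(keys)
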