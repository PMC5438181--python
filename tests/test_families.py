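"""Family loading, paralog filtering and residue-to-column maps."""

import numpy as np
import pandas as pd
import pytest

from codoncons.families import (
    FamilyMember,
    HomologFamily,
    filter_paralogs,
    load_family,
    map_peaks_to_columns,
)
from codoncons.orfeome import OrfRecord

def encode_trivial(protein: str) -> str:
    """Any valid CDS for a protein (most alphabetical codon per residue)."""
    from codoncons.code import SENSE_CODONS, SYN_SETS

    return "".join(SENSE_CODONS[min(SYN_SETS[aa])] for aa in protein)


def make_family(aligned_by_species: dict[str, str], family_id="f1") -> HomologFamily:
    members = []
    for sp, aligned in aligned_by_species.items():
        protein = aligned.replace("-", "")
        rec = OrfRecord(f"{sp}_g", sp, encode_trivial(protein))
        members.append(FamilyMember(species_id=sp, gene_id=f"{sp}_g", aligned=aligned, record=rec))
    return HomologFamily(family_id=family_id, members=members)


class TestHomologFamily:
    def test_gapless_family_all_columns_eligible(self):
        fam = make_family({"a": "MKLV", "b": "MKLV", "c": "MKLV"})
        assert fam.L == 4
        assert list(fam.eligible_cols) == [0, 1, 2, 3]

    def test_gap_in_one_member_excludes_column(self):
        fam = make_family({"a": "MKLV", "b": "MK-V"})
        assert list(fam.eligible_cols) == [0, 1, 3]

    def test_unequal_row_lengths_error(self):
        with pytest.raises(ValueError, match="unequal"):
            make_family({"a": "MKLV", "b": "MKL"})

    def test_two_members_same_species_error(self):
        rec = OrfRecord("g", "a", encode_trivial("MK"))
        members = [
            FamilyMember("a", "g1", "MK", rec),
            FamilyMember("a", "g2", "MK", rec),
        ]
        with pytest.raises(ValueError, match="one member per species"):
            HomologFamily(family_id="f", members=members)

    def test_colmap_roundtrip_identity(self):
        fam = make_family({"a": "M-KL-V", "b": "MQK--V", "c": "MQKLPV"})
        for member, cmap in zip(fam.members, fam.col_maps):
            assert np.all(np.diff(cmap) > 0)  # strictly increasing
            rebuilt = "".join(member.aligned[c] for c in cmap)
            assert rebuilt == member.protein


class TestLoadFamily:
    def write_inputs(self, tmp_path, rows, aligned):
        membership = pd.DataFrame(rows, columns=["family_id", "species_id", "gene_id"])
        fasta = tmp_path / "f1.fasta"
        fasta.write_text("".join(f">{sp}|{g}\n{seq}\n" for sp, g, seq in aligned))
        return membership, fasta

    def orfeomes_for(self, aligned):
        out = {}
        for sp, g, seq in aligned:
            out.setdefault(sp, {})[g] = OrfRecord(g, sp, encode_trivial(seq.replace("-", "")))
        return out

    def test_basic_load(self, tmp_path):
        aligned = [("a", "ga", "MKLV"), ("b", "gb", "MKLV"), ("c", "gc", "MK-V")]
        membership, fasta = self.write_inputs(
            tmp_path, [("f1", sp, g) for sp, g, _ in aligned], aligned
        )
        fam = load_family("f1", membership, fasta, self.orfeomes_for(aligned))
        assert fam is not None and fam.n == 3 and fam.L == 4
        assert 2 not in set(fam.eligible_cols)

    def test_cds_alignment_mismatch_drops_member(self, tmp_path):
        aligned = [("a", "ga", "MKLV"), ("b", "gb", "MKLV"), ("c", "gc", "MKLV")]
        membership, fasta = self.write_inputs(
            tmp_path, [("f1", sp, g) for sp, g, _ in aligned], aligned
        )
        orfeomes = self.orfeomes_for(aligned)
        orfeomes["c"]["gc"] = OrfRecord("gc", "c", encode_trivial("MKLW"))  # wrong protein
        fam = load_family("f1", membership, fasta, orfeomes)
        assert fam.n == 2 and {m.species_id for m in fam.members} == {"a", "b"}

    def test_family_below_two_members_skipped(self, tmp_path):
        aligned = [("a", "ga", "MKLV"), ("b", "gb", "MKLV")]
        membership, fasta = self.write_inputs(
            tmp_path, [("f1", sp, g) for sp, g, _ in aligned], aligned
        )
        orfeomes = self.orfeomes_for(aligned[:1])  # species b missing entirely
        assert load_family("f1", membership, fasta, orfeomes) is None


class TestFilterParalogs:
    def members(self, species_counts):
        out = []
        for sp, k in species_counts.items():
            for i in range(k):
                out.append(FamilyMember(sp, f"{sp}_g{i}", "MK", None))
        return out

    def test_deterministic_under_seed(self):
        members = self.members({"a": 3, "b": 1})
        picks = {
            tuple(m.gene_id for m in filter_paralogs(members, np.random.default_rng(7)))
            for _ in range(5)
        }
        assert len(picks) == 1

    def test_unique_species_identity(self):
        members = self.members({"a": 1, "b": 1, "c": 1})
        assert filter_paralogs(members, np.random.default_rng(0)) == members

    def test_uniform_choice_over_paralogs(self):
        members = self.members({"a": 4})
        rng = np.random.default_rng(42)
        counts = {m.gene_id: 0 for m in members}
        n = 1000
        for _ in range(n):
            (chosen,) = filter_paralogs(members, rng)
            counts[chosen.gene_id] += 1
        p = 0.25
        sigma = (n * p * (1 - p)) ** 0.5
        for c in counts.values():
            assert abs(c - n * p) <= 3 * sigma


class TestMapPeaks:
    def test_gapless_all_members_same_column(self):
        fam = make_family({s: "MKLVAQERTYIPASDF" for s in "abc"})
        cols = map_peaks_to_columns(fam, [np.array([10])] * 3)
        assert all(list(c) == [10] for c in cols)

    def test_gap_offset_shifts_column(self):
        # member b has a 5-column gap before residue 10
        fam = make_family({"a": "MKLVAQERTYIPASDFGHKL", "b": "MKLVA-----QERTYIPASD"})
        cols = map_peaks_to_columns(fam, [np.array([10]), np.array([10])])
        assert list(cols[0]) == [10]
        assert list(cols[1]) == [15]

    def test_no_peaks_empty(self):
        fam = make_family({"a": "MKLV", "b": "MKLV"})
        cols = map_peaks_to_columns(fam, [np.array([], dtype=int)] * 2)
        assert all(c.size == 0 for c in cols)

    def test_out_of_range_peak_errors(self):
        fam = make_family({"a": "MKLV", "b": "MKLV"})
        with pytest.raises(ValueError):
            map_peaks_to_columns(fam, [np.array([4]), np.array([], dtype=int)])

    def test_removing_member_preserves_other_colmaps(self):
        rows = {"a": "M-KL-V", "b": "MQK--V", "c": "MQKLPV"}
        fam_all = make_family(rows)
        fam_two = make_family({k: rows[k] for k in ["a", "b"]})
        np.testing.assert_array_equal(fam_all.col_maps[0], fam_two.col_maps[0])
        np.testing.assert_array_equal(fam_all.col_maps[1], fam_two.col_maps[1])
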