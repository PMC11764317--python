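import pytest

from delscape.classify import (
    DelKey,
    events_from_calls,
    gene_del_status,
    partition_by_coordinate,
    partition_by_gene,
    subtype_associated_dels,
    top_genes,
)
from delscape.errors import ValidationError
from delscape.io import (
    GeneMap,
    Material,
    SampleRecord,
    TissueClass,
    TumorSubtype,
)


def key(start, seq="A", chrom="chr1"):
    return DelKey(chrom, start, start + len(seq) - 1, seq)


def records_for(patients, subtype=TumorSubtype.BCC, tissue=TissueClass.tumor):
    out = []
    for p in patients:
        out.append(SampleRecord(p, f"{p}-T", Material.tissue, tissue, subtype, 100))
        out.append(
            SampleRecord(p, f"{p}-B", Material.blood, TissueClass.none, TumorSubtype.none, 100)
        )
    return out


class TestDelKey:
    def test_same_start_different_length_are_distinct(self):
        """chr5:112111310 del A and chr5:112111310-112111312 del AAA differ."""
        a = DelKey("chr5", 112111310, 112111310, "A")
        b = DelKey("chr5", 112111310, 112111312, "AAA")
        assert a != b and a < b

    def test_span_must_match_sequence(self):
        with pytest.raises(ValidationError):
            DelKey("chr1", 10, 12, "A")

    def test_total_ordering_is_deterministic(self):
        keys = [key(5), key(1, "TT"), key(1), DelKey("chr0", 9, 9, "G")]
        assert sorted(keys) == sorted(keys[::-1])


class TestPartitionByCoordinate:
    def test_three_way_split(self):
        k1, k2, k3, k4 = key(1), key(2), key(3), key(4)
        part = partition_by_coordinate(
            [("P1", k1), ("P1", k2), ("P2", k3)], [("H1", k2), ("H1", k4)]
        )
        assert part.tumor_only == {k1, k3}
        assert part.shared == {k2}
        assert part.healthy_only == {k4}

    def test_venn_arithmetic(self):
        """tumor_only + shared = unique tumor; healthy_only + shared = unique healthy."""
        tumor = [(f"P{i}", key(i % 7)) for i in range(20)]
        healthy = [(f"H{i}", key(3 + i % 6)) for i in range(15)]
        part = partition_by_coordinate(tumor, healthy)
        assert part.n_unique_tumor == len({k for _, k in tumor})
        assert part.n_unique_healthy == len({k for _, k in healthy})

    def test_event_conservation(self):
        tumor = [("P1", key(1)), ("P2", key(1)), ("P1", key(2))]
        healthy = [("H1", key(2)), ("H2", key(9))]
        part = partition_by_coordinate(tumor, healthy)
        assert sum(part.event_counts.values()) == len(tumor) + len(healthy)
        # key(2) occurs once in tumor and once in healthy: both events shared
        assert part.event_counts == {"tumor_only": 2, "shared": 2, "healthy_only": 1}

    def test_disjoint_inputs(self):
        part = partition_by_coordinate([("P1", key(1))], [("H1", key(2))])
        assert part.shared == set()
        assert part.event_counts == {"tumor_only": 1, "shared": 0, "healthy_only": 1}


class TestPartitionByGene:
    @pytest.fixture()
    def gene_map(self):
        gm = GeneMap()
        gm.add("chr1", 1, 100, "A_GENE")
        gm.add("chr1", 101, 200, "B_GENE")
        gm.add("chr1", 201, 300, "C_GENE")
        return gm

    def test_same_gene_different_dels_is_both(self, gene_map):
        """A gene hit by one DEL in tumor and a different DEL in healthy is 'both'."""
        part = partition_by_gene(
            [("P1", key(110))], [("H1", key(150))], gene_map
        )
        assert part.both == {"B_GENE"} and not part.tumor_only

    def test_toy_three_way(self, gene_map):
        part = partition_by_gene(
            [("P1", key(10)), ("P1", key(110))],
            [("H1", key(120)), ("H1", key(210))],
            gene_map,
        )
        assert part.tumor_only == {"A_GENE"}
        assert part.both == {"B_GENE"}
        assert part.healthy_only == {"C_GENE"}
        observed = part.tumor_only | part.both | part.healthy_only
        assert observed == {"A_GENE", "B_GENE", "C_GENE"}

    def test_unmapped_key_rejected(self, gene_map):
        with pytest.raises(ValidationError, match="999"):
            partition_by_gene([("P1", key(999))], [], gene_map)


class TestSubtypeAssociated:
    def test_membership_rules(self):
        manifest = records_for(["P1", "P2"], TumorSubtype.BCC) + records_for(
            ["P3"], TumorSubtype.SCC
        )
        tumor = [("P1", key(1)), ("P2", key(1)), ("P1", key(2)), ("P3", key(3))]
        healthy = [("H1", key(2))]
        bcc = subtype_associated_dels(tumor, manifest, "BCC", healthy)
        assert key(1) in bcc  # two BCC patients, no healthy
        assert key(2) not in bcc  # also in healthy
        assert key(3) not in bcc  # SCC-only coordinate
        scc = subtype_associated_dels(tumor, manifest, "SCC", healthy)
        assert scc == {key(3)}

    def test_subtype_sets_within_tumor_only(self):
        manifest = records_for(["P1"], TumorSubtype.BCC) + records_for(
            ["P2"], TumorSubtype.SCC
        )
        tumor = [("P1", key(1)), ("P2", key(2)), ("P1", key(5))]
        healthy = [("H1", key(5))]
        part = partition_by_coordinate(tumor, healthy)
        union = subtype_associated_dels(
            tumor, manifest, "BCC", healthy
        ) | subtype_associated_dels(tumor, manifest, "SCC", healthy)
        assert union <= part.tumor_only


class TestGeneDelStatus:
    @pytest.fixture()
    def gene_map(self):
        gm = GeneMap()
        gm.add("chr1", 1, 100, "APC")
        gm.add("chr1", 101, 200, "MTR")
        return gm

    def test_multiple_dels_idempotent(self, gene_map):
        manifest = records_for(["P1", "P2"])
        tumor = [("P1", key(10)), ("P1", key(20)), ("P2", key(110))]
        associated = {key(10), key(20), key(110)}
        m = gene_del_status(associated, tumor, gene_map, manifest, "BCC")
        assert m.carries("P1", "APC")
        assert not m.carries("P2", "APC")
        assert m.carrier_counts()["APC"] == 1

    def test_carrier_frequency(self, gene_map):
        patients = [f"P{i}" for i in range(1, 27)]
        manifest = records_for(patients)
        tumor = [(p, key(110)) for p in patients[:13]]
        m = gene_del_status({key(110)}, tumor, gene_map, manifest, "BCC")
        assert m.carrier_frequency()["MTR"] == pytest.approx(0.5)

    def test_noncarrier_row_all_false(self, gene_map):
        manifest = records_for(["P1", "P2"])
        m = gene_del_status({key(10)}, [("P1", key(10))], gene_map, manifest, "BCC")
        assert not m.to_frame().loc["P2"].any()

    def test_monotone_in_associated_set(self, gene_map):
        manifest = records_for(["P1", "P2"])
        tumor = [("P1", key(10)), ("P2", key(110))]
        small = gene_del_status({key(10)}, tumor, gene_map, manifest, "BCC")
        big = gene_del_status({key(10), key(110)}, tumor, gene_map, manifest, "BCC")
        sf, bf = small.to_frame(), big.to_frame()
        for p in sf.index:
            for g in sf.columns:
                assert not sf.loc[p, g] or bf.loc[p, g]


class TestTopGenes:
    def _matrix(self, counts):
        gm = GeneMap()
        manifest_patients = [f"P{i}" for i in range(1, 7)]
        manifest = records_for(manifest_patients)
        pos = 1
        tumor, associated = [], set()
        for gene, n in counts.items():
            gm.add("chr1", pos, pos + 9, gene)
            for p in manifest_patients[:n]:
                k = key(pos)
                tumor.append((p, k))
                associated.add(k)
            pos += 10
        return gene_del_status(associated, tumor, gm, manifest, "BCC")

    def test_tie_break_alphabetical(self):
        m = self._matrix({"B": 5, "A": 5, "C": 1})
        assert top_genes(m, 2) == ["A", "B"]

    def test_k_larger_than_genes_returns_all(self):
        m = self._matrix({"A": 2, "B": 1})
        assert top_genes(m, 40) == ["A", "B"]

    def test_all_zero_matrix_empty(self):
        m = self._matrix({"A": 1})
        m.status[:] = False
        assert top_genes(m, 3) == []


def test_events_from_calls_dedupes_per_patient():
    from delscape.io import VariantCall, VarType

    c = VariantCall("S1", "chr1", 5, 5, "A", "-", VarType.DEL, 50, 5, 10.0, 80.0)
    again = VariantCall("S1", "chr1", 5, 5, "A", "-", VarType.DEL, 60, 6, 10.0, 82.0)
    events = events_from_calls([c, again], {"S1": "P1"})
    assert events == [("P1", DelKey("chr1", 5, 5, "A"))]
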