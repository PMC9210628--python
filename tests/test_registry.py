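import numpy as np
import pytest

from pathburden.registry import (
    PathwayCollection,
    PathwaySet,
    RegistryError,
    load_gmt,
    read_gene_lengths,
)
from pathburden.simulate import demo_pathway_collection


def write_gmt_file(tmp_path, sets):
    p = tmp_path / "sets.gmt"
    with open(p, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "desc", *genes]) + "\n")
    return p


def write_lengths_file(tmp_path, lengths):
    p = tmp_path / "lengths.tsv"
    with open(p, "w") as fh:
        for g, bp in lengths.items():
            fh.write(f"{g}\t{bp}\n")
    return p


class TestLoadGmt:
    def test_five_sets_with_canonical_sizes(self, tmp_path):
        rng = np.random.default_rng(5)
        sizes = {"adr": 236, "glu": 153, "dop": 138, "ser": 125, "cho": 235}
        universe = [f"G{i:04d}" for i in range(600)]
        sets = {
            name: list(rng.choice(universe, size=k, replace=False))
            for name, k in sizes.items()
        }
        lengths = {g: 1000 for g in universe}
        coll = load_gmt(
            write_gmt_file(tmp_path, sets), write_lengths_file(tmp_path, lengths)
        )
        assert [len(p) for p in coll] == list(sizes.values())
        # union cardinality equals the brute-force set union
        union = set()
        for genes in sets.values():
            union |= set(genes)
        assert coll.all_genes == union

    def test_total_length_is_sum_of_members(self, tmp_path):
        coll = load_gmt(
            write_gmt_file(tmp_path, {"s": ["A", "B"]}),
            write_lengths_file(tmp_path, {"A": 1000, "B": 2000}),
        )
        assert coll["s"].total_coding_length_bp == 3000

    def test_shared_genes_derived_from_membership(self, tmp_path):
        coll = load_gmt(
            write_gmt_file(tmp_path, {"s1": ["A", "B"], "s2": ["B", "C"]}),
            write_lengths_file(tmp_path, {"A": 1, "B": 2, "C": 3}),
        )
        assert coll.shared_genes == {"B": {"s1", "s2"}}

    def test_missing_lengths_listed_in_error(self, tmp_path):
        gmt = write_gmt_file(tmp_path, {"s": ["A", "B", "C"]})
        lengths = write_lengths_file(tmp_path, {"A": 10})
        with pytest.raises(RegistryError, match="B, C"):
            load_gmt(gmt, lengths)

    def test_duplicate_pathway_names_rejected(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("s\td\tA\ns\td\tB\n")
        with pytest.raises(RegistryError, match="duplicate"):
            load_gmt(p, {"A": 1, "B": 1})

    def test_empty_set_rejected(self, tmp_path):
        p = tmp_path / "empty.gmt"
        p.write_text("s\tdesc\n")
        with pytest.raises(RegistryError):
            load_gmt(p, {})


class TestGeneLengths:
    def test_bed_intervals_summed_per_gene(self, tmp_path):
        p = tmp_path / "cds.bed"
        p.write_text(
            "chr1\t100\t200\tA\nchr1\t300\t450\tA\nchr2\t0\t50\tB\n"
        )
        assert read_gene_lengths(p) == {"A": 250, "B": 50}

    def test_nonpositive_coding_length_rejected(self):
        with pytest.raises(RegistryError, match="non-positive"):
            PathwaySet("s", frozenset({"A"}), {"A": 0})


class TestDropSharedGenes:
    def test_overlap_removed(self, small_coll):
        ex = small_coll.drop_shared_genes()
        assert ex["alpha"].genes == {"A"}
        assert ex["beta"].genes == {"C", "D"}
        assert ex["alpha"].total_coding_length_bp == 1000
        assert ex["beta"].total_coding_length_bp == 2000

    def test_disjoint_collection_unchanged(self):
        lengths = {"A": 1, "B": 2}
        coll = PathwayCollection(
            [
                PathwaySet("p1", frozenset({"A"}), lengths),
                PathwaySet("p2", frozenset({"B"}), lengths),
            ]
        )
        ex = coll.drop_shared_genes()
        assert [p.genes for p in ex] == [p.genes for p in coll]

    def test_idempotent(self, demo_coll):
        once = demo_coll.drop_shared_genes()
        twice = once.drop_shared_genes()
        assert [p.genes for p in once] == [p.genes for p in twice]

    def test_matches_bruteforce_exclusive_membership(self, demo_coll):
        # brute force: count per-gene memberships over all pathways
        counts = {}
        for p in demo_coll:
            for g in p.genes:
                counts[g] = counts.get(g, 0) + 1
        ex = demo_coll.drop_shared_genes()
        for p_orig, p_ex in zip(demo_coll, ex):
            expected = {g for g in p_orig.genes if counts[g] == 1}
            assert p_ex.genes == expected

    def test_error_when_pathway_emptied(self):
        lengths = {"A": 1, "B": 2}
        coll = PathwayCollection(
            [
                PathwaySet("sub", frozenset({"A"}), lengths),
                PathwaySet("super", frozenset({"A", "B"}), lengths),
            ]
        )
        with pytest.raises(RegistryError, match="sub"):
            coll.drop_shared_genes()


def test_demo_collection_structure():
    coll = demo_pathway_collection(seed=3)
    assert [len(p) for p in coll] == [236, 153, 138, 125, 235]
    assert len(coll.all_genes) == 544
    assert all(
        bp > 0 for p in coll for bp in p.coding_length_bp.values()
    )
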