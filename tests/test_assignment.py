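"""Reference sets, nearest-reference assignment, count tables, depletion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mobactag as m
from mobactag.counts import CountTableError
from mobactag.references import ReferenceError


def test_reference_set_feature_count_for_a_syncom_layout(make_reference_set):
    specs = (
        [(f"R{i}_16S", "endogenous_16S", f"R{i}") for i in range(15)]
        + [(t, "barcode_tag", "WCS358") for t in ("tag119", "tag120", "tag190")]
        + [("spike_16S", "spike_tag", None), ("plant_ITS", "plant_ITS", "Col0")]
    )
    refs = make_reference_set(specs)
    assert len(refs) == 20
    assert len(refs.of_class("endogenous_16S")) == 15


def test_reference_set_rejects_duplicates():
    seq = "ACGT" * 50
    with pytest.raises(ReferenceError, match="duplicate feature id"):
        m.build_reference_set(
            [
                m.ReferenceFeature("x", "barcode_tag", seq),
                m.ReferenceFeature("x", "barcode_tag", "TTGC" * 50),
            ]
        )
    with pytest.raises(ReferenceError, match="tagA.*tagB|tagB.*tagA"):
        m.build_reference_set(
            [
                m.ReferenceFeature("tagA", "barcode_tag", seq),
                m.ReferenceFeature("tagB", "barcode_tag", seq),
            ]
        )
    # Reverse complements are the same molecule.
    with pytest.raises(ReferenceError, match="identical sequence"):
        m.build_reference_set(
            [
                m.ReferenceFeature("tagA", "barcode_tag", "AACGTAGCTT" * 10),
                m.ReferenceFeature("tagB", "barcode_tag", m.reverse_complement("AACGTAGCTT" * 10)),
            ]
        )
    with pytest.raises(ReferenceError, match="empty"):
        m.build_reference_set([])


def test_reference_fasta_round_trip(make_reference_set, tmp_path):
    refs = make_reference_set(
        [("tag119", "barcode_tag", "WCS358"), ("R1_16S", "endogenous_16S", "R1")]
    )
    path = tmp_path / "refs.fasta"
    m.references.write_reference_fasta(refs, path)
    loaded = m.build_reference_set(str(path))
    assert loaded == refs


@pytest.fixture
def small_refs(make_reference_set):
    return make_reference_set(
        [
            ("tag119", "barcode_tag", "WCS358"),
            ("R1_16S", "endogenous_16S", "R1"),
            ("spike_16S", "spike_tag", None),
        ],
        seed=1,
    )


def test_exact_and_reverse_complement_reads_assigned(small_refs):
    ref = {f.feature_id: f.sequence for f in small_refs}
    reads = [
        ("r0", ref["tag119"]),
        ("r1", m.reverse_complement(ref["tag119"])),
        ("r2", ref["R1_16S"]),
    ]
    results, counts = m.assign_reads(reads, small_refs)
    assert [r.label for r in results] == ["tag119", "tag119", "R1_16S"]
    assert all(r.distance == 0 for r in results)
    assert counts["tag119"] == 2 and counts["R1_16S"] == 1
    assert counts.sum() == 3


def test_equidistant_read_is_unassigned():
    # Two references at distance 2 from each other; a read one edit from each.
    refs = m.build_reference_set(
        [
            m.ReferenceFeature("f1", "barcode_tag", "AACCGGTTACGTACGTAAGG"),
            m.ReferenceFeature("f2", "barcode_tag", "AACCGGTTACGTACGTCATG"),
        ]
    )
    read = "AACCGGTTACGTACGTCAGG"  # distance 1 from both (brute-force verified)
    def dp(a, b):
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]

    assert dp(read, "AACCGGTTACGTACGTAAGG") == dp(read, "AACCGGTTACGTACGTCATG") == 1
    results, counts = m.assign_reads([("r", read)], refs, max_distance=3, margin=1)
    assert results[0].label == "unassigned"
    assert results[0].ambiguous
    assert counts["unassigned"] == 1


def test_non_dna_read_skipped_with_warning(small_refs, caplog):
    with caplog.at_level("WARNING"):
        results, counts = m.assign_reads([("bad", "ACGTNNNN")], small_refs)
    assert results[0].label == "unassigned"
    assert counts["unassigned"] == 1
    assert "non-DNA" in caplog.text


def test_assignment_order_invariant_and_conserved(small_refs):
    rng = np.random.default_rng(5)
    ref_seqs = [f.sequence for f in small_refs]
    reads = []
    for i in range(60):
        seq = list(ref_seqs[i % 3])
        for pos in rng.choice(len(seq), size=rng.integers(0, 3), replace=False):
            seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
        reads.append((f"r{i}", "".join(seq)))
    _, counts_fwd = m.assign_reads(reads, small_refs)
    _, counts_rev = m.assign_reads(reads[::-1], small_refs)
    assert counts_fwd.equals(counts_rev)
    assert counts_fwd.sum() == len(reads)
    shuffled = m.build_reference_set(tuple(reversed(small_refs.features)))
    _, counts_shuf = m.assign_reads(reads, shuffled)
    assert counts_fwd.sort_index().equals(counts_shuf.sort_index())


def test_noisy_read_unassignment_matches_binomial_tail(make_reference_set, spike_design):
    # Closed-form oracle: P(unassigned) = P(Bin(L, eps) > max_distance).
    eps, max_distance, n_strains = 0.003, 3, 4
    refs = make_reference_set(
        [(f"S{i}_16S", "endogenous_16S", f"S{i}") for i in range(n_strains)]
        + [("spike_16S", "spike_tag", None), ("plant_ITS", "plant_ITS", None),
           ("spike_pITS", "spike_tag", None), ("spike2", "spike_tag", None)],
        seed=2,
    )
    strains = tuple(m.StrainSpec(f"S{i}", 1 / n_strains) for i in range(n_strains))
    spec = m.CommunitySpec(
        strains=strains, spike=spike_design, depth=8000, error_rate=eps, seed=17
    )
    reads, truth = m.generate_reads(spec, refs)
    results, counts = m.assign_reads(reads, refs, max_distance=max_distance)
    assert counts.sum() == len(reads)
    # No misassignment: every assigned read matches its truth label.
    for r in results:
        if r.label != "unassigned":
            assert r.label == truth[r.read_id]
    L = len(refs.features[0].sequence)
    p_tail = stats.binom.sf(max_distance, L, eps)
    n = len(reads)
    observed = counts["unassigned"]
    se = np.sqrt(n * p_tail * (1 - p_tail))
    assert abs(observed - n * p_tail) <= 3 * se


# -- count tables -------------------------------------------------------

def make_table():
    counts = pd.DataFrame(
        {
            "WCS358_16S": [120, 80],
            "tag119": [40, 10],
            "spike_16S": [30, 20],
            "unassigned": [10, 5],
        },
        index=["s0", "s1"],
    )
    classes = pd.Series(
        {
            "WCS358_16S": "endogenous_16S",
            "tag119": "barcode_tag",
            "spike_16S": "spike_tag",
            "unassigned": "unassigned",
        }
    )
    return m.CountTable(counts=counts, feature_classes=classes)


def test_count_table_invariants():
    table = make_table()
    assert table.depth.tolist() == [200, 115]
    with pytest.raises(CountTableError, match="negative"):
        m.CountTable(counts=table.counts - 50, feature_classes=table.feature_classes)
    with pytest.raises(CountTableError, match="non-integral"):
        m.CountTable(counts=table.counts + 0.5, feature_classes=table.feature_classes)
    with pytest.raises(CountTableError, match="class"):
        m.CountTable(counts=table.counts, feature_classes=table.feature_classes.iloc[:2])
    with pytest.raises(CountTableError, match="depth"):
        m.CountTable(
            counts=table.counts,
            feature_classes=table.feature_classes,
            depth=pd.Series([1, 1], index=["s0", "s1"]),
        )


def test_count_table_tsv_round_trip(tmp_path):
    table = make_table()
    table.provenance["seed"] = 7
    counts_path, classes_path = tmp_path / "c.tsv", tmp_path / "k.tsv"
    table.to_tsv(counts_path, classes_path)
    assert counts_path.read_text().startswith("# seed: 7\n")
    loaded = m.CountTable.from_tsv(counts_path, classes_path)
    assert loaded.counts.equals(table.counts)
    assert loaded.feature_classes.equals(table.feature_classes)


def test_depletion_preserves_other_entries_and_provenance():
    table = make_table()
    depleted = m.deplete_features(table, ["WCS358_16S"])
    assert "WCS358_16S" not in depleted.features
    for f in depleted.features:
        assert depleted.counts[f].equals(table.counts[f])
    assert depleted.depth.tolist() == [80, 35]
    assert depleted.provenance["original_depth"] == {"s0": 200, "s1": 115}
    # Depleting nothing is the identity; depleting everything is valid.
    assert m.deplete_features(table, []).counts.equals(table.counts)
    empty = m.deplete_features(table, table.features)
    assert empty.depth.tolist() == [0, 0]
    with pytest.raises(CountTableError, match="unknown"):
        m.deplete_features(table, ["nope"])
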