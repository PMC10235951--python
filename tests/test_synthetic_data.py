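"""Ground-truthed cohort generator: determinism, event bookkeeping, anatomy."""

import math

import numpy as np
import pytest

from euplofs.seqcore import TreeTable, read_tree
from euplofs.synthetic_data import (
    SimParams,
    cds_with_fs,
    evolve_orthogroup,
    generate_dataset,
    make_transcript,
    random_root_cds,
    truth_alignment,
    write_dataset,
)

SMALL = dict(n_orthogroups=4, cds_len=120)


def small_params(**kw):
    return SimParams(**{**SMALL, **kw})


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(small_params(seed=9)), a)
        write_dataset(generate_dataset(small_params(seed=9)), b)
        for f in sorted(a.iterdir()):
            assert f.read_bytes() == (b / f.name).read_bytes(), f.name

    def test_different_seed_different_data(self):
        d1 = generate_dataset(small_params(seed=1))
        d2 = generate_dataset(small_params(seed=2))
        assert d1.transcripts[0].seq != d2.transcripts[0].seq


class TestEvolveOrthogroup:
    def test_zero_rates_no_events(self):
        rng = np.random.default_rng(0)
        params = small_params(u_gain=0, u_gain2=0, u_loss=0, root_fs_prob=0)
        tt = TreeTable(read_tree(params.tree))
        root = random_root_cds(120, 0.72, rng)
        states, events, _ = evolve_orthogroup(root, tt, params, rng)
        assert events == []
        assert all(not st.fs for st in states.values())

    def test_zero_branch_lengths_leaves_identical_to_root(self):
        rng = np.random.default_rng(0)
        params = SimParams(
            tree="((A:0,B:0):0,(C:0,D:0):0);", n_orthogroups=1, cds_len=120
        )
        tt = TreeTable(read_tree(params.tree))
        root = random_root_cds(120, 0.72, rng)
        states, events, _ = evolve_orthogroup(root, tt, params, rng)
        assert events == []
        for leaf in "ABCD":
            assert "".join(states[leaf].codons) == root

    def test_leaf_state_has_odd_event_parity(self):
        """FS present at a leaf <=> odd number of events on its root path."""
        ds = generate_dataset(small_params(seed=3, n_orthogroups=12))
        tt = ds.tree_table
        parents = {n.name: tt.nodes[n.parent].name for n in tt.branches()}

        def root_path(leaf):
            path = []
            node = leaf
            while node in parents:
                path.append(node)
                node = parents[node]
            return path

        for og_id in ds.orthogroups.orthogroup_id.unique():
            ev = ds.truth.events[ds.truth.events.orthogroup_id == og_id]
            root_fs = ds.truth.node_states[(og_id, tt.nodes[0].name)].fs
            for leaf in tt.leaf_names:
                st = ds.truth.node_states[(og_id, leaf)]
                path = set(root_path(leaf))
                for j in set(ev.junction) | set(root_fs):
                    n_events = int(
                        ((ev.junction == j) & ev.branch.isin(path)).sum()
                    )
                    present_at_root = j in root_fs
                    expected = (n_events + int(present_at_root)) % 2 == 1
                    assert (j in st.fs) == expected

    def test_gain_count_matches_thinning_expectation(self):
        """Mean planted gains over seeds ~ closed-form exposure expectation."""
        tree = "((A:0.5,B:0.5):0.5,C:1.0);"
        tt = TreeTable(read_tree(tree))
        params = SimParams(
            tree=tree,
            n_orthogroups=1,
            cds_len=120,
            sub_rate=0.0,  # freeze contexts so the expectation is exact
            u_gain=0.01,
            u_gain_other_scale=1.0,  # uniform rate over all contexts
            u_gain2=0.0,
            u_loss=0.0,
            root_fs_prob=0.0,
        )
        rng = np.random.default_rng(42)
        root = random_root_cds(120, 0.72, rng)
        codons = [root[i : i + 3] for i in range(0, len(root), 3)]
        n_ctx = sum(
            1
            for j in range(1, len(codons))
            if codons[j][0] == "A" and codons[j][1] in "AG"
        )
        # per context: expected events = sum over branches of
        # P(not yet gained at parent) * (1 - exp(-u*l))
        p_branch = {}
        for node in tt.branches():
            p_branch[node.name] = -math.expm1(-params.u_gain * node.length)
        # tree: root -> N2(A,B) and C
        pN2 = p_branch["N2"]
        expected_per_ctx = (
            pN2
            + (1 - pN2) * (p_branch["A"] + p_branch["B"])
            + p_branch["C"]
        )
        expected = n_ctx * expected_per_ctx
        totals = []
        for seed in range(400):
            r = np.random.default_rng(seed)
            _, events, _ = evolve_orthogroup(root, tt, params, r)
            totals.append(len(events))
        mean = np.mean(totals)
        se = np.std(totals) / math.sqrt(len(totals))
        assert abs(mean - expected) < 3 * se + 1e-9

    def test_substitutions_never_create_stops_or_break_sites(self):
        ds = generate_dataset(small_params(seed=4, n_orthogroups=10))
        for (og, node), st in ds.truth.node_states.items():
            assert not any(c in ("TAA", "TAG") for c in st.codons)
            for j, shift in st.fs.items():
                nxt = st.codons[j]
                if shift == 1:
                    assert nxt[0] == "A" and nxt[1] in "AG"
                else:
                    assert nxt[0] in "AG"

    def test_stop_codon_string_in_truth(self):
        ds = generate_dataset(small_params(seed=5, n_orthogroups=10))
        assert set(ds.truth.fs_records.stop_codon) <= {"TAA", "TAG"}


class TestMakeTranscript:
    def test_zero_utr3(self):
        params = small_params(utr3_len_mean=0.0, polyA_len=15)
        rng = np.random.default_rng(0)
        t, anatomy = make_transcript("ATGAAACCC", params, rng, "t1", "sp")
        assert t.seq.endswith("A" * 15)
        term = t.seq[anatomy["terminator_pos"] : anatomy["terminator_pos"] + 3]
        assert term in ("TAA", "TAG")
        assert anatomy["utr3_len"] == 0
        assert t.seq[anatomy["cds_start"] : anatomy["cds_start"] + 9] == "ATGAAACCC"

    def test_truth_positions_locate_stops_in_fasta(self):
        ds = generate_dataset(small_params(seed=6, n_orthogroups=8))
        tmap = ds.transcript_by_id()
        for rec in ds.truth.fs_records.itertuples():
            seq = tmap[rec.transcript_id].seq
            assert seq[rec.pos : rec.pos + 3] == rec.stop_codon

    def test_utr_at_content_exceeds_cds(self):
        ds = generate_dataset(small_params(seed=7, n_orthogroups=20))
        tmap = ds.transcript_by_id()
        utr_at, cds_at = [], []
        for a in ds.truth.anatomy.itertuples():
            seq = tmap[a.transcript_id].seq
            utr = seq[: a.cds_start]
            cds = seq[a.cds_start : a.cds_start + a.cds_nt_len]
            if len(utr) >= 10:
                utr_at.append((utr.count("A") + utr.count("T")) / len(utr))
            cds_at.append((cds.count("A") + cds.count("T")) / len(cds))
        # both target the same AT bias; the UTR should not be less AT-rich
        assert np.mean(utr_at) > np.mean(cds_at) - 0.02


class TestCdsWithFs:
    def test_plus1_insertion_creates_tar_stop(self):
        codons = ["ATG", "AAA", "AGG", "TTC"]
        seq = cds_with_fs(codons, {2: 1})
        assert seq == "ATGAAA" + "T" + "AGGTTC"
        assert seq[6:9] == "TAG"

    def test_plus2_insertion_creates_tar_stop(self):
        codons = ["ATG", "ATA", "GGG"]
        seq = cds_with_fs(codons, {2: 2})
        assert seq == "ATGATA" + "TA" + "GGG"
        assert seq[6:9] == "TAG"


class TestTruthAlignment:
    def test_alignment_rows_match_leaf_sequences(self):
        ds = generate_dataset(small_params(seed=8, n_orthogroups=6))
        og = ds.orthogroups.orthogroup_id.iloc[0]
        aln = truth_alignment(ds, og)
        widths = {len(r) for r in aln.values()}
        assert len(widths) == 1
        for sp, row in aln.items():
            st = ds.truth.node_states[(og, sp)]
            assert row.replace("-", "") == cds_with_fs(st.codons, st.fs)


class TestQcPlanting:
    def test_zero_fraction_is_noop(self):
        params = small_params(seed=10, contam_fraction=0.0)
        ds = generate_dataset(params)
        assert set(ds.truth.labels.label) == {"clean"}
        assert not ds.contaminant_hits and not ds.chimera_hits

    def test_planted_classes_have_guaranteed_margins(self):
        ds = generate_dataset(SimParams(n_orthogroups=12, seed=11, contam_fraction=0.05))
        labels = ds.truth.labels.set_index("transcript_id").label
        tmap = ds.transcript_by_id()
        ats = [t.at_fraction for t in ds.transcripts]
        mean, sd = np.mean(ats), np.std(ats, ddof=1)
        for tid, lab in labels.items():
            if lab == "low_at":
                assert tmap[tid].at_fraction < mean - 4 * sd
        assert (labels == "duplicate").sum() >= 1
        assert (labels == "decoy").sum() >= 1
        assert (labels == "chimera").sum() >= 1
        # chimera hit pairs: different organisms, query overlap <= 15 nt
        by_query = {}
        for h in ds.chimera_hits:
            by_query.setdefault(h.query_id, []).append(h)
        for hits in by_query.values():
            assert len(hits) == 2
            a, b = hits
            assert a.subject_organism != b.subject_organism
            overlap = max(
                0, min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
            )
            assert overlap <= 15
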