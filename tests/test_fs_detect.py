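"""ORF stitching and frameshift detection on constructed and simulated data."""

import numpy as np
import pandas as pd
import pytest

from euplofs.fs_detect import (
    DetectParams,
    FrameshiftSite,
    build_reference_peptides,
    candidate_joins,
    detect_all,
    validate_segment,
)
from euplofs.seqcore import Transcript, find_orfs
from euplofs.synthetic_data import SimParams, cds_with_fs, generate_dataset

STOP_FREE = [c for c in map("".join, __import__("itertools").product("ACGT", repeat=3)) if c not in ("TAA", "TAG")]


def make_codons(rng, n):
    """Random stop-free codons biased like an AT-rich transcriptome."""
    probs = np.array([0.36, 0.14, 0.14, 0.36])
    out = []
    while len(out) < n:
        c = "".join(np.array(list("ACGT"))[rng.choice(4, 3, p=probs)])
        if c not in ("TAA", "TAG"):
            out.append(c)
    return out


def diverge(codons, rng, protected, rate=0.15):
    """Third-position substitutions (never creating stops) at some codons."""
    out = list(codons)
    for i in range(len(out)):
        if i in protected or rng.random() > rate:
            continue
        for base in "TCAG":
            cand = out[i][:2] + base
            if cand not in ("TAA", "TAG") and cand != out[i]:
                if rng.random() < 0.5:
                    out[i] = cand
                break
    return out


def build_family(rng, fs=None, n_species=5, n_codons=120):
    """One orthogroup: species sp0 carries the planted sites, others do not."""
    fs = fs or {}
    codons = make_codons(rng, n_codons)
    for j, shift in fs.items():
        codons[j - 1] = "AAA" if shift == 1 else "ATA"
        codons[j] = "AAG"  # junction followed by A,G (and G for +2 stops)
    protected = set(fs) | {j - 1 for j in fs}
    transcripts = []
    rows = []
    for s in range(n_species):
        sp = f"sp{s}"
        my = diverge(codons, rng, protected) if s else codons
        seq = cds_with_fs(my, fs if s == 0 else {})
        utr5 = "GCTGC"
        full = utr5 + seq + "TAA" + "GCATTAGC" + "A" * 15
        tid = f"{sp}|OG1"
        transcripts.append(Transcript(tid, sp, full, "sense", "polyA"))
        rows.append({"orthogroup_id": "OG1", "species": sp, "transcript_id": tid})
    og = pd.DataFrame(rows)
    positions = {}
    offset = 0
    for j in sorted(fs):
        positions[j] = len("GCTGC") + 3 * j + offset
        offset += fs[j]
    return transcripts, og, positions


class TestCandidateJoins:
    def test_plus1_candidate_at_aaa_taa(self):
        #          0        9   13
        seq = "ATGAAAAAATAAAAAGGGATTTTTGGG"
        # frame-0 ORF ends where TAA begins at 9; +1 resumes at 10
        orfs = find_orfs(seq)
        upstream = next(o for o in orfs if o.frame == 0 and o.end == 9)
        cands = candidate_joins(seq, orfs, upstream, "3p")
        plus1 = [c for c in cands if c["join"] == "+1"]
        assert plus1
        assert plus1[0]["stop_start"] == 9
        assert plus1[0]["segment"].start == 10
        assert plus1[0]["segment"].frame == 1

    def test_plus2_requires_ata_context(self):
        # ...ATA TAG GG...: +2 resumes 2 nt into the stop
        seq = "ATGAAAATATAGGGTTTGGGTTTGGG"
        orfs = find_orfs(seq)
        upstream = next(o for o in orfs if o.frame == 0 and o.end == 9)
        cands = candidate_joins(seq, orfs, upstream, "3p")
        assert any(c["join"] == "+2" for c in cands)
        # same geometry with AAA context is rejected for +2
        seq2 = "ATGAAAAAATAGGGTTTGGGTTTGGG"
        orfs2 = find_orfs(seq2)
        upstream2 = next(o for o in orfs2 if o.frame == 0 and o.end == 9)
        cands2 = candidate_joins(seq2, orfs2, upstream2, "3p")
        assert not any(c["join"] == "+2" for c in cands2)

    def test_no_orfs_beyond_stop_gives_no_candidates(self):
        seq = "ATGAAAAAATAA"
        orfs = find_orfs(seq)
        upstream = next(o for o in orfs if o.frame == 0)
        assert candidate_joins(seq, orfs, upstream, "3p") == []


class TestValidateSegment:
    def setup_method(self):
        self.rng = np.random.default_rng(21)
        self.transcripts, self.og, _ = build_family(self.rng)
        self.params = DetectParams(seed=0)
        self.refs = [
            r
            for r in build_reference_peptides(self.transcripts[1:], self.params)
        ]

    def test_long_identical_segment_passes(self):
        target = self.transcripts[0]
        seg = target.seq[5 : 5 + 150]
        v = validate_segment(seg, self.refs, self.params, np.random.default_rng(0))
        assert v.passed
        assert v.identity > 0.8

    def test_short_segment_fails_on_length(self):
        v = validate_segment(
            "ATGAAA", self.refs, self.params, np.random.default_rng(0)
        )
        assert not v.passed and v.reason == "length"

    def test_random_segment_fails(self):
        junk = "".join(make_codons(np.random.default_rng(99), 40))
        v = validate_segment(junk, self.refs, self.params, np.random.default_rng(0))
        assert not v.passed

    def test_no_orthologs(self):
        v = validate_segment(
            "ATGAAA" * 20, [], self.params, np.random.default_rng(0)
        )
        assert not v.passed and v.reason == "no_ortholog"


class TestStitchPlantedSites:
    @pytest.mark.parametrize("shift", [1, 2], ids=["plus1", "plus2"])
    def test_single_planted_site_recovered(self, shift):
        rng = np.random.default_rng(31 + shift)
        transcripts, og, positions = build_family(rng, fs={60: shift})
        fs_table, decoded, summary = detect_all(
            transcripts, og, DetectParams(seed=1)
        )
        mine = fs_table[fs_table.transcript_id == "sp0|OG1"]
        assert len(mine) == 1
        rec = mine.iloc[0]
        assert int(rec.pos) == positions[60]
        assert int(rec["shift"]) == shift
        assert rec.context == ("AAA" if shift == 1 else "ATA")
        assert rec.stop_codon in ("TAA", "TAG")

    def test_no_internal_stops_means_no_sites(self):
        rng = np.random.default_rng(41)
        transcripts, og, _ = build_family(rng, fs={})
        fs_table, decoded, summary = detect_all(transcripts, og, DetectParams(seed=1))
        assert len(fs_table) == 0
        model = decoded["sp0|OG1"]
        assert model.terminator is not None
        # terminator close to the polyA tail: the 3' UTR here is 8 nt
        assert model.utr3_len == 8


@pytest.fixture(scope="module")
def simulated():
    ds = generate_dataset(SimParams(n_orthogroups=8, cds_len=200, seed=17))
    fs_table, decoded, summary = detect_all(
        ds.transcripts, ds.orthogroups, DetectParams(seed=18)
    )
    return ds, fs_table, decoded


class TestDetectorInvariants:
    def test_all_stops_are_taa_or_tag(self, simulated):
        _, fs_table, _ = simulated
        assert set(fs_table.stop_codon) <= {"TAA", "TAG"}

    def test_frame_relation(self, simulated):
        _, fs_table, _ = simulated
        for r in fs_table.itertuples():
            assert r.downstream_frame == (r.upstream_frame + r.shift) % 3

    def test_no_internal_stop_in_proteins(self, simulated):
        _, _, decoded = simulated
        for model in decoded.values():
            assert "*" not in model.protein

    def test_segments_are_chained_at_stops(self, simulated):
        ds, _, decoded = simulated
        tmap = ds.transcript_by_id()
        for tid, model in decoded.items():
            seq = tmap[tid].seq
            for a, b in zip(model.segments, model.segments[1:]):
                shift = (b.frame - a.frame) % 3
                gap = b.start - a.end
                assert (shift, gap) in {(1, 1), (2, 2), (0, 3)}
                stop = seq[a.end : a.end + 3]
                assert stop in ("TAA", "TAG")

    def test_input_order_invariance(self, simulated):
        ds, fs_table, _ = simulated
        reversed_fs, _, _ = detect_all(
            list(reversed(ds.transcripts)), ds.orthogroups, DetectParams(seed=18)
        )
        pd.testing.assert_frame_equal(
            fs_table.reset_index(drop=True), reversed_fs.reset_index(drop=True)
        )


class TestFrameshiftSiteType:
    def test_rejects_tga(self):
        with pytest.raises(ValueError):
            FrameshiftSite("t", 10, "TGA", 1, "AAA", 0, 1)

    def test_rejects_inconsistent_frames(self):
        with pytest.raises(ValueError):
            FrameshiftSite("t", 10, "TAA", 1, "AAA", 0, 2)
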