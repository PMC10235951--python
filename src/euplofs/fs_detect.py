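"""Frameshift-site detection by ORF stitching.

In *Euplotes*, an internal UAA/UAG does not terminate translation: the
ribosome resumes in the +1 frame (canonically after an AAA codon, i.e.
AAA_UAR) or the +2 frame (AUA_UAR), so a transcript's coding region is a
chain of stop-free ORF segments joined at stop codons.  The detector seeds
with the longest ORF that validates against the transcript's orthologs and
greedily extends it in both directions with adjacent or overlapping ORFs
joined by +1/+2 frameshifts (or stop-codon readthrough, enumerated but not
expected to validate in euplotid data).

Every candidate segment must pass four ortholog-based criteria: a minimal
length in codons; high local-alignment protein identity against the best
ortholog ORF peptide, with the alignment covering at least half of the
candidate; Nei-Gojobori dN/dS < 1 with high Poisson-resampling support
(purifying selection); and a dN/dS uniformity metric relative to the seed
segment inside an acceptance band.  The polyA tail is masked before ORF
scanning — it is template-poly(A), not coding sequence, and would otherwise
seed spurious poly-lysine ORFs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pairwise_evo import (
    NGCounts,
    align_sw,
    dnds_purifying_support,
    dnds_uniformity,
    protein_identity,
)
from .seqcore import EUPLOTID, OrfSegment, Transcript, find_orfs, translate

__all__ = [
    "DetectParams",
    "FrameshiftSite",
    "DecodedCDS",
    "RefPeptide",
    "ValidationResult",
    "build_reference_peptides",
    "candidate_joins",
    "validate_segment",
    "stitch_cds",
    "detect_all",
]

STOPS = ("TAA", "TAG")


@dataclass(frozen=True)
class DetectParams:
    """Detection thresholds.

    These are tunable parameters, calibrated on ground-truthed synthetic
    cohorts (the uniformity metric is ~uniform under the null, so the band
    is a two-sided test whose width trades sensitivity for junk rejection;
    the minimal segment length bounds the shortest detectable inter-site
    segment).  With ``n_passes`` > 1, later passes re-validate against
    ortholog peptides taken from the previous pass's decoded models only,
    which removes wrong-frame ORF references — homologous DNA is ~0.8
    amino-acid-identical in *any* shared reading frame, so raw ORF peptides
    from the wrong frame can validate spurious joins that no identity
    threshold separates; junk that leaked into one model can still support
    the same junk elsewhere one pass later, so the refinement is iterated.
    """

    min_codons: int = 10
    id_min: float = 0.5
    cov_min: float = 0.5  # aligned fraction of the candidate's codons
    min_identical: int = 8  # identically aligned codons; a random local match
    #   of that length is ~20^-8 per window, so short junk segments cannot
    #   fluke past the identity criterion while a short true segment clears it
    conf_min: float = 0.95  # resampling support required for dN/dS < 1
    uniformity_low: float = 0.01
    uniformity_high: float = 0.99
    rounds: int = 1000
    min_ref_species: int = 2  # distinct ortholog species that must support a
    #   segment in the FINAL refinement pass: a wrong-frame read of conserved
    #   DNA can match the same wrong-frame read in one sister species, but its
    #   identity collapses with nucleotide divergence (~id^3), while
    #   true-frame identity is held high by purifying selection across the
    #   whole tree.  Earlier passes accept single-species support so that
    #   genuine segments can propagate into every ortholog's model first.
    min_ref_codons: int = 15  # ortholog ORF peptides shorter than this ignored
    max_ref_peptides: int = 4  # per ortholog transcript, longest first
    max_seed_attempts: int = 5
    polyA_min_run: int = 10
    plus2_context: str | None = "ATA"  # +2 repairing needs an AUA codon
    #   5' of the stop (AUA_UAR); None lifts the constraint
    n_passes: int = 3  # reference-refinement iterations (see class docstring)
    anchor_slack: int = 3  # codons; a join candidate's reference alignment
    #   must reach this close to the boundary shared with the stop codon
    seed: int = 0


@dataclass(frozen=True)
class FrameshiftSite:
    transcript_id: str
    stop_codon_start: int  # 0-based nt of the stop codon's T
    stop_codon: str  # TAA | TAG (TGA is a sense codon and never appears)
    shift: int  # +1 | +2 (0 would be readthrough, reported separately)
    context_codon: str  # in-frame codon immediately 5' of the stop
    upstream_frame: int
    downstream_frame: int

    def __post_init__(self) -> None:
        if self.stop_codon not in STOPS:
            raise ValueError(f"frameshift stop must be TAA/TAG, got {self.stop_codon}")
        if self.downstream_frame != (self.upstream_frame + self.shift) % 3:
            raise ValueError("downstream frame must be (upstream + shift) mod 3")


@dataclass
class ValidationResult:
    passed: bool
    reason: str = ""
    identity: float | None = None
    coverage: float | None = None
    ng: NGCounts | None = None
    support: float | None = None
    uniformity: float | None = None
    ref_id: str | None = None
    aln_start: int | None = None  # codon offset of the aligned region within
    #   the candidate: marks where its ortholog-supported coding begins


@dataclass
class DecodedCDS:
    """A stitched coding model for one transcript."""

    transcript_id: str
    segments: list[OrfSegment]
    joins: list[dict]  # {"site": FrameshiftSite|None, "type": "+1"|"+2"|"rt"}
    protein: str
    terminator_pos: int | None
    terminator: str | None
    utr3_len: int | None
    seed_stats: ValidationResult | None = None
    segment_stats: list[ValidationResult] = field(default_factory=list)

    @property
    def frameshifts(self) -> list[FrameshiftSite]:
        return [j["site"] for j in self.joins if j["site"] is not None]

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end


@dataclass(frozen=True)
class RefPeptide:
    """An ortholog ORF peptide used for validation."""

    transcript_id: str
    species: str
    segment: OrfSegment
    protein: str
    cds: str  # nucleotide sequence of the segment


TERMINAL_WINDOW = 100  # nt; ORFs this close to the masked 3' end are kept as
# references even when short: the terminal coding segment downstream of the
# last frameshift is short exactly when that site sits near the CDS end,
# and in Euplotes the terminator is always polyA-proximal


def build_reference_peptides(
    transcripts: Sequence[Transcript], params: DetectParams
) -> list[RefPeptide]:
    """Candidate ortholog ORF peptides: the longest ORFs of each transcript
    plus any ORF near the masked 3' end (candidate terminal segments)."""
    out: list[RefPeptide] = []
    for t in sorted(transcripts, key=lambda x: x.id):
        scan_len = _scan_length(t.seq, params.polyA_min_run)
        orfs = find_orfs(t.seq[:scan_len])
        chosen = [
            o for o in orfs if o.n_codons >= params.min_ref_codons
        ][: params.max_ref_peptides]
        for o in orfs:
            if o in chosen or o.n_codons < 6:
                continue
            if o.end >= scan_len - TERMINAL_WINDOW:
                chosen.append(o)
        for o in chosen:
            cds = t.seq[o.start : o.end]
            out.append(
                RefPeptide(
                    transcript_id=t.id,
                    species=t.species,
                    segment=o,
                    protein=translate(cds, EUPLOTID, 0),
                    cds=cds,
                )
            )
    return out


def _scan_length(seq: str, polyA_min_run: int) -> int:
    """Length of the transcript with any terminal polyA run masked."""
    n = 0
    for ch in reversed(seq):
        if ch != "A":
            break
        n += 1
    return len(seq) - n if n >= polyA_min_run else len(seq)


def _codon_alignment(
    seg_cds: str, ref: RefPeptide, aln
) -> tuple[str, str]:
    """Back-map a local protein alignment to gap-free codon columns."""
    ia, ib = aln.start_a, aln.start_b
    cols_a: list[str] = []
    cols_b: list[str] = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            cols_a.append(seg_cds[3 * ia : 3 * ia + 3])
            cols_b.append(ref.cds[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(cols_a), "".join(cols_b)


def validate_segment(
    seg_cds: str,
    refs: Sequence[RefPeptide],
    params: DetectParams,
    rng: np.random.Generator,
    primary: NGCounts | None = None,
    anchor: str | None = None,
    enforce_ref_species: bool = True,
) -> ValidationResult:
    """Score one candidate segment against ortholog ORF peptides.

    Pass requires: length >= min_codons; best ortholog identity >= id_min
    on an alignment covering >= cov_min of the candidate's codons; dN/dS
    resampling support for purifying selection >= conf_min; and, when a
    primary (seed) segment is given, the dN/dS uniformity metric within
    the acceptance band.
    """
    n_codons = len(seg_cds) // 3
    if n_codons < params.min_codons:
        return ValidationResult(False, "length")
    if not refs:
        return ValidationResult(False, "no_ortholog")
    protein = translate(seg_cds, EUPLOTID, 0)
    best: tuple[float, float, RefPeptide, object] | None = None
    needed_species = min(
        params.min_ref_species if enforce_ref_species else 1,
        len({r.species for r in refs}),
    )
    qualifying_species: set[str] = set()
    for ref in refs:
        aln = align_sw(protein, ref.protein)
        pairs = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != "-" and y != "-"
        )
        if pairs == 0:
            continue
        # a join candidate's coding portion abuts the frameshift stop, so
        # the supporting alignment must reach that boundary; a chance local
        # match elsewhere in the segment is not evidence for the join
        if anchor == "5p":
            end_a = aln.start_a + sum(1 for x in aln.aligned_a if x != "-")
            if end_a < n_codons - params.anchor_slack:
                continue
        elif anchor == "3p" and aln.start_a > params.anchor_slack:
            continue
        coverage = pairs / n_codons
        if coverage < params.cov_min:
            continue
        ident = protein_identity(aln)
        if ident * pairs < params.min_identical:
            continue
        if ident >= params.id_min:
            qualifying_species.add(ref.species)
        if best is None or ident > best[0]:
            best = (ident, coverage, ref, aln)
        if (
            best[0] >= 0.9
            and best[1] >= 0.9
            and len(qualifying_species) >= needed_species
        ):
            break  # cannot be meaningfully beaten; saves alignments
    if best is None:
        return ValidationResult(False, "identity", identity=0.0, coverage=0.0)
    ident, coverage, ref, aln = best
    aln_start = aln.start_a
    if ident < params.id_min:
        return ValidationResult(
            False, "identity", identity=ident, coverage=coverage, ref_id=ref.transcript_id
        )
    if len(qualifying_species) < needed_species:
        return ValidationResult(
            False,
            "ref_species",
            identity=ident,
            coverage=coverage,
            ref_id=ref.transcript_id,
            aln_start=aln_start,
        )
    cds_a, cds_b = _codon_alignment(seg_cds, ref, aln)
    from .pairwise_evo import ng_dnds

    ng = ng_dnds(cds_a, cds_b, EUPLOTID)
    support = dnds_purifying_support(ng, params.rounds, rng)
    if support < params.conf_min:
        return ValidationResult(
            False,
            "dnds",
            identity=ident,
            coverage=coverage,
            ng=ng,
            support=support,
            ref_id=ref.transcript_id,
        )
    uniformity = None
    if primary is not None:
        uniformity = dnds_uniformity(primary, ng, params.rounds, rng)
        if not params.uniformity_low <= uniformity <= params.uniformity_high:
            return ValidationResult(
                False,
                "uniformity",
                identity=ident,
                coverage=coverage,
                ng=ng,
                support=support,
                uniformity=uniformity,
                ref_id=ref.transcript_id,
            )
    return ValidationResult(
        True,
        "",
        identity=ident,
        coverage=coverage,
        ng=ng,
        support=support,
        uniformity=uniformity,
        ref_id=ref.transcript_id,
        aln_start=aln_start,
    )


def candidate_joins(
    seq: str,
    orfs: Sequence[OrfSegment],
    segment: OrfSegment,
    direction: str,
    plus2_context: str | None = "ATA",
) -> list[dict]:
    """Enumerate +1/+2/readthrough joins at one boundary of the model.

    "3p": the bounding stop is seq[end:end+3] in the model's frame; a
    downstream ORF whose frame is shifted by +1/+2 (or 0 for readthrough)
    and which contains the resume point — 1 or 2 nt into the stop (the
    ribosome re-pairs inside the stop codon), or just after it — is trimmed
    to start at the resume point.

    "5p": an upstream ORF U ends where a stop codon in U's own frame leads
    into the model; the shift is fixed by the frame offset, the resume
    point (1/2 nt into that stop, or after it) must fall within the model's
    first segment, which the caller trims to the resume point.

    Sorted by join priority +1 > +2 > readthrough, then extension length:
    a +1 join is the mechanistically preferred explanation of a stop, and a
    rare stop-free wrong-frame bridge across two consecutive +1 sites would
    otherwise outrank the true short middle segment by sheer length.
    """
    out: list[dict] = []
    priority = {"+1": 0, "+2": 1, "rt": 2}
    join_of_shift = {1: "+1", 2: "+2", 0: "rt"}
    if direction == "3p":
        end = segment.end
        stop = seq[end : end + 3]
        if len(stop) == 3 and stop in STOPS:
            for shift in (1, 2, 0):
                if shift == 2 and plus2_context and seq[end - 3 : end] != plus2_context:
                    continue
                resume = end + (shift if shift else 3)
                new_frame = resume % 3
                for o in orfs:
                    if o.frame != new_frame or not (o.start <= resume < o.end):
                        continue
                    seg = OrfSegment(resume, o.end, new_frame)
                    out.append(
                        {
                            "join": join_of_shift[shift],
                            "shift": shift,
                            "segment": seg,
                            "stop_start": end,
                            "stop": stop,
                            "resume": resume,
                            "direction": "3p",
                        }
                    )
                    break
    elif direction == "5p":
        first = segment
        for o in orfs:
            if o.start >= first.start or o.end < 3:
                continue
            stop = seq[o.end : o.end + 3]
            if len(stop) < 3 or stop not in STOPS:
                continue
            shift = (first.frame - o.end) % 3
            if (
                shift == 2
                and plus2_context
                and seq[o.end - 3 : o.end] != plus2_context
            ):
                continue
            resume = o.end + (shift if shift else 3)
            if not (first.start <= resume < first.end):
                continue
            out.append(
                {
                    "join": join_of_shift[shift],
                    "shift": shift,
                    "segment": o,
                    "stop_start": o.end,
                    "stop": stop,
                    "resume": resume,
                    "direction": "5p",
                }
            )
    else:
        raise ValueError("direction must be '3p' or '5p'")
    out.sort(key=lambda c: (priority[c["join"]], -c["segment"].n_codons))
    return out


def _make_site(seq: str, tid: str, cand: dict) -> FrameshiftSite | None:
    if cand["shift"] == 0:
        return None
    stop_start = cand["stop_start"]
    upstream_frame = stop_start % 3
    return FrameshiftSite(
        transcript_id=tid,
        stop_codon_start=stop_start,
        stop_codon=cand["stop"],
        shift=cand["shift"],
        context_codon=seq[stop_start - 3 : stop_start],
        upstream_frame=upstream_frame,
        downstream_frame=(upstream_frame + cand["shift"]) % 3,
    )


def stitch_cds(
    transcript: Transcript,
    refs: Sequence[RefPeptide],
    params: DetectParams,
    rng: np.random.Generator,
    extend_5p: bool = True,
    enforce_ref_species: bool = True,
) -> DecodedCDS | None:
    """Build the coding model of one oriented transcript.

    Seeds with the longest ORF that validates against the orthologs, then
    repeatedly applies the best validated join at either boundary (largest
    extension first; +1 > +2 > readthrough on ties) until no candidate
    validates.  Returns None when no seed ORF validates ("no CDS").
    """
    seq = transcript.seq
    scan_len = _scan_length(seq, params.polyA_min_run)
    orfs = find_orfs(seq[:scan_len])
    refs = [r for r in refs if r.transcript_id != transcript.id]

    seed = None
    seed_val = None
    for o in orfs[: params.max_seed_attempts]:
        v = validate_segment(
            seq[o.start : o.end],
            refs,
            params,
            rng,
            enforce_ref_species=enforce_ref_species,
        )
        if v.passed:
            seed, seed_val = o, v
            break
    if seed is None:
        return None

    segments = [seed]
    joins: list[dict] = []
    primary = seed_val.ng
    cache: dict[tuple, ValidationResult] = {}

    while True:
        cands = candidate_joins(
            seq[:scan_len], orfs, segments[-1], "3p", params.plus2_context
        )
        if extend_5p:
            cands = cands + candidate_joins(
                seq[:scan_len], orfs, segments[0], "5p", params.plus2_context
            )
        applied = False
        for cand in cands:
            seg = cand["segment"]
            key = (seg.start, seg.end, seg.frame)
            key = key + (cand["direction"],)
            if key not in cache:
                cache[key] = validate_segment(
                    seq[seg.start : seg.end],
                    refs,
                    params,
                    rng,
                    primary=primary,
                    anchor=cand["direction"],
                    enforce_ref_species=enforce_ref_species,
                )
            v = cache[key]
            if not v.passed:
                continue
            site = _make_site(seq, transcript.id, cand)
            if cand["direction"] == "3p":
                segments.append(seg)
            else:
                # re-pairing consumes part of the old first codon run:
                # trim the model's first segment to the resume point
                first = segments[0]
                segments[0] = OrfSegment(cand["resume"], first.end, first.frame)
                segments.insert(0, seg)
            joins.append({"site": site, "type": cand["join"], "stats": v})
            applied = True
            break
        if not applied:
            break

    end = segments[-1].end
    terminator = seq[end : end + 3] if end + 3 <= len(seq) else None
    if terminator not in STOPS:
        terminator = None
    protein = "".join(
        translate(seq[s.start : s.end], EUPLOTID, 0) for s in segments
    )
    utr3_len = max(0, scan_len - (end + 3)) if terminator else None
    return DecodedCDS(
        transcript_id=transcript.id,
        segments=segments,
        joins=joins,
        protein=protein,
        terminator_pos=end if terminator else None,
        terminator=terminator,
        utr3_len=utr3_len,
        seed_stats=seed_val,
        segment_stats=[j["stats"] for j in joins],
    )


def _transcript_rng(base_seed: int, transcript_id: str) -> np.random.Generator:
    # order-invariant: each transcript's resampling stream depends only on
    # the base seed and its own id
    return np.random.default_rng(
        [base_seed & 0x7FFFFFFF, zlib.crc32(transcript_id.encode())]
    )


FS_TABLE_COLUMNS = [
    "transcript_id",
    "orthogroup_id",
    "species",
    "pos",
    "stop_codon",
    "shift",
    "context",
    "upstream_frame",
    "downstream_frame",
    "identity",
    "support",
    "uniformity",
]


def detect_all(
    transcripts: Sequence[Transcript],
    orthogroups: pd.DataFrame,
    params: DetectParams | None = None,
) -> tuple[pd.DataFrame, dict[str, DecodedCDS], dict]:
    """Decode every transcript with identifiable orthologs.

    Returns the frameshift-site table, per-transcript coding models, and a
    cohort summary (per-shift counts, FS-bearing fractions, terminator and
    3' UTR statistics, context-codon frequencies).
    """
    params = params or DetectParams()
    tmap = {t.id: t for t in transcripts}
    members: dict[str, list[str]] = {}
    og_of: dict[str, str] = {}
    for row in orthogroups.itertuples():
        if row.transcript_id in tmap:
            members.setdefault(row.orthogroup_id, []).append(row.transcript_id)
            og_of[row.transcript_id] = row.orthogroup_id

    def run_pass(ref_cache_builder, final: bool) -> dict[str, DecodedCDS]:
        ref_cache: dict[str, list[RefPeptide]] = {}
        out: dict[str, DecodedCDS] = {}
        for tid in sorted(tmap):
            og = og_of.get(tid)
            if og is None:
                continue
            if og not in ref_cache:
                ref_cache[og] = ref_cache_builder(og)
            species = tmap[tid].species
            refs = [r for r in ref_cache[og] if r.species != species]
            if not refs:
                continue
            rng = _transcript_rng(params.seed, tid)
            model = stitch_cds(
                tmap[tid], refs, params, rng, enforce_ref_species=final
            )
            if model is not None:
                out[tid] = model
        return out

    def pass1_refs(og: str) -> list[RefPeptide]:
        return build_reference_peptides([tmap[m] for m in members[og]], params)

    decoded = run_pass(pass1_refs, final=params.n_passes == 1)

    for i_pass in range(max(0, params.n_passes - 1)):
        prev = decoded

        def refined_refs(og: str) -> list[RefPeptide]:
            # only peptides from the previous pass's decoded coding models:
            # wrong-frame ORF peptides of orthologs are excluded structurally
            refs: list[RefPeptide] = []
            for tid in sorted(members[og]):
                t = tmap[tid]
                model = prev.get(tid)
                scan_len = _scan_length(t.seq, params.polyA_min_run)
                if model is not None:
                    segs = list(model.segments)
                else:  # undecoded ortholog: trust only its longest ORF
                    orfs = find_orfs(t.seq[:scan_len])
                    segs = orfs[:1] if orfs else []
                for seg in segs:
                    if seg.n_codons < params.min_ref_codons and model is None:
                        continue
                    cds = t.seq[seg.start : seg.end]
                    refs.append(
                        RefPeptide(
                            transcript_id=tid,
                            species=t.species,
                            segment=seg,
                            protein=translate(cds, EUPLOTID, 0),
                            cds=cds,
                        )
                    )
            return refs

        decoded = run_pass(refined_refs, final=i_pass == params.n_passes - 2)

    fs_rows: list[dict] = []
    for tid in sorted(decoded):
        model = decoded[tid]
        for join in model.joins:
            site = join["site"]
            if site is None:
                continue
            stats: ValidationResult = join["stats"]
            fs_rows.append(
                {
                    "transcript_id": tid,
                    "orthogroup_id": og_of[tid],
                    "species": tmap[tid].species,
                    "pos": site.stop_codon_start,
                    "stop_codon": site.stop_codon,
                    "shift": site.shift,
                    "context": site.context_codon,
                    "upstream_frame": site.upstream_frame,
                    "downstream_frame": site.downstream_frame,
                    "identity": stats.identity,
                    "support": stats.support,
                    "uniformity": stats.uniformity,
                }
            )
    fs_table = pd.DataFrame(fs_rows, columns=FS_TABLE_COLUMNS)

    with_fs = set(fs_table.transcript_id)
    og_with_fs = set(fs_table.orthogroup_id)
    n_decoded = len(decoded)
    utr3 = [m.utr3_len for m in decoded.values() if m.utr3_len is not None]
    context_counts = (
        fs_table.context.value_counts().to_dict() if len(fs_table) else {}
    )
    summary = {
        "n_transcripts": len(tmap),
        "n_decoded": n_decoded,
        "n_transcripts_with_fs": len(with_fs),
        "frac_transcripts_with_fs": len(with_fs) / n_decoded if n_decoded else 0.0,
        "n_orthogroups": len(members),
        "n_orthogroups_with_fs": len(og_with_fs),
        "frac_orthogroups_with_fs": len(og_with_fs) / len(members)
        if members
        else 0.0,
        "n_fs_plus1": int((fs_table["shift"] == 1).sum()),
        "n_fs_plus2": int((fs_table["shift"] == 2).sum()),
        "n_readthrough": sum(
            1 for m in decoded.values() for j in m.joins if j["type"] == "rt"
        ),
        "utr3_mean": float(np.mean(utr3)) if utr3 else None,
        "utr3_median": float(np.median(utr3)) if utr3 else None,
        "context_codon_counts": context_counts,
    }
    return fs_table, decoded, summary
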