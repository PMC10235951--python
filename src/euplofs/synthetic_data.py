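"""Ground-truthed synthetic euplotid transcriptome cohorts.

The generator produces what the downstream analysis assumes about real
*Euplotes* data: AT-rich codon sequences evolved along a rooted 9-leaf tree
(branch lengths in synonymous substitutions per site), with context-dependent
thymine insertions at codon boundaries followed by A-purine (NNN_AR ->
NNN_TAR, a +1 frameshift site) and T deletions reverting them, transcripts
with short stop-rich AT-rich UTRs and polyA tails, and optional planted
contamination/chimera artefacts for the QC screen.

A frameshift site is represented as an inserted T (shift +1) or TA (shift
+2, at ATA_R junctions, mirroring the repairing-compatible AUA_UAR class)
at a codon boundary; the underlying codon sequence keeps evolving in its
own reading frame on both sides of the junction, which is exactly the
biology of an efficient +1/+2 frameshift.  Every event (branch, junction,
context) is recorded, so parsimony inference downstream can be scored
against the exact planted history.

Rates keep the ratios the analysis is sensitive to (loss/gain rate ratio
e^2, i.e. scaled selection S = -2; AAA contexts strongly preferred for
gains; ancestral contexts greatly outnumbering existing sites) while the
absolute per-context rates are set so that cohorts of ~100 orthogroups
carry measurable event counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qc_filter import HitRecord
from .seqcore import EUPLOTID, Transcript, TreeTable, read_tree, write_fasta

__all__ = [
    "DEFAULT_TREE",
    "SimParams",
    "TreeTable",
    "TruthTable",
    "SyntheticDataset",
    "evolve_orthogroup",
    "make_transcript",
    "plant_qc_violations",
    "generate_dataset",
    "truth_alignment",
    "cds_with_fs",
    "write_dataset",
]

# Nine-species study-shaped tree; branch lengths in synonymous subs/site.
DEFAULT_TREE = (
    "((E_octocarinatus:0.18,E_harpa:0.16):0.25,"
    "((E_focardii:0.20,E_petzi:0.22):0.18,"
    "((E_euryhalinus:0.15,E_rariseta:0.16):0.12,"
    "(E_crassus:0.18,(E_minuta:0.15,E_raikovi:0.16):0.08):0.10):0.15):0.12);"
)

STOPS = ("TAA", "TAG")
PURINES = "AG"


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions; a fixed seed gives byte-identical output."""

    tree: str = DEFAULT_TREE
    n_orthogroups: int = 100
    cds_len: int = 450  # codons
    omega: float = 0.05  # dN/dS acceptance for nonsynonymous substitutions
    sub_rate: float = 1.0  # substitution proposals per nt site per unit length
    u_gain: float = 0.03  # T insertions per AAA_AR context per unit length
    u_gain_other_scale: float = 0.02  # relative gain rate at non-AAA contexts
    #   (~4 AAA_AR vs ~77 other NNN_AR contexts per 450 codons puts ~72% of
    #   gains in the canonical AAA_[T]AR context)
    u_gain2: float = 0.0012  # TA insertions per ATA_R junction (+2 sites,
    #   ~7% of gains)
    u_loss: float = 0.222  # T(A) deletions per existing site (= u_gain * e^2)
    root_fs_prob: float = 0.0135  # root +1 site probability per AAA_AR
    #   context (scaled by u_gain_other_scale elsewhere): ancestral AAA_AR
    #   contexts outnumber standing AAA_TAR sites ~74-fold at the root
    at_bias: float = 0.72
    utr5_len_mean: float = 30.0
    utr3_len_mean: float = 25.0
    polyA_len: int = 15
    species_presence: float = 1.0
    contam_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "omega",
            "sub_rate",
            "u_gain",
            "u_gain2",
            "u_loss",
            "root_fs_prob",
            "contam_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.cds_len < 30:
            raise ValueError("cds_len must be >= 30 codons")


@dataclass
class LineageState:
    codons: list[str]
    fs: dict[int, int]  # junction (codon index of the following codon) -> shift

    def copy(self) -> "LineageState":
        return LineageState(list(self.codons), dict(self.fs))


def _base_probs(at_bias: float) -> np.ndarray:
    gc = 1.0 - at_bias
    return np.array([at_bias / 2, gc / 2, gc / 2, at_bias / 2])  # A C G T


def _random_seq(n: int, at_bias: float, rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=n, p=_base_probs(at_bias))])


def random_root_cds(n_codons: int, at_bias: float, rng: np.random.Generator) -> str:
    """Stop-free AT-rich codon sequence; AAA is naturally the top codon."""
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(3, at_bias, rng)
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def _is_gain1_context(codons: list[str], j: int) -> bool:
    nxt = codons[j]
    return nxt[0] == "A" and nxt[1] in PURINES


def _is_gain2_context(codons: list[str], j: int) -> bool:
    return codons[j - 1] == "ATA" and codons[j][0] in PURINES


def _gain1_rate(codons: list[str], j: int, params: SimParams) -> float:
    scale = 1.0 if codons[j - 1] == "AAA" else params.u_gain_other_scale
    return params.u_gain * scale


def cds_with_fs(codons: list[str], fs: dict[int, int]) -> str:
    """Nucleotide CDS with the frameshift insertions realised."""
    parts: list[str] = []
    for j, codon in enumerate(codons):
        shift = fs.get(j)
        if shift == 1:
            parts.append("T")
        elif shift == 2:
            parts.append("TA")
        parts.append(codon)
    return "".join(parts)


def fs_nt_positions(codons: list[str], fs: dict[int, int]) -> dict[int, int]:
    """Junction -> nt offset of the stop codon's T in the realised CDS."""
    out: dict[int, int] = {}
    offset = 0
    for j in range(len(codons)):
        shift = fs.get(j)
        if shift is not None:
            out[j] = 3 * j + offset
            offset += shift
    return out


def _evolve_branch(
    state: LineageState,
    length: float,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[LineageState, list[dict], int]:
    """Substitutions, then losses, then gains, along one branch.

    At most one indel event per junction per branch.  Substitutions that
    would create an in-frame stop, or would destroy the stop context of an
    active frameshift site, are rejected (and counted).
    """
    state = state.copy()
    codons = state.codons
    L = len(codons)
    events: list[dict] = []
    n_rejected = 0

    # --- substitutions
    n_prop = rng.poisson(3 * L * length * params.sub_rate) if params.sub_rate else 0
    if n_prop:
        positions = rng.integers(0, 3 * L, size=n_prop)
        bases = np.array(list("ACGT"))[
            rng.choice(4, size=n_prop, p=_base_probs(params.at_bias))
        ]
        omega_draws = rng.random(n_prop)
        for p, base, om in zip(positions, bases, omega_draws):
            c, o = divmod(int(p), 3)
            old = codons[c]
            if old[o] == base:
                continue
            new = old[:o] + base + old[o + 1 :]
            if new in STOPS:
                n_rejected += 1
                continue
            shift = state.fs.get(c)
            if shift == 1 and o < 2 and not (new[0] == "A" and new[1] in PURINES):
                n_rejected += 1
                continue
            if shift == 2 and o == 0 and new[0] not in PURINES:
                n_rejected += 1
                continue
            # an active +2 site needs its AUA context codon for tRNA
            # re-pairing; purifying selection maintains it
            if state.fs.get(c + 1) == 2 and old == "ATA":
                n_rejected += 1
                continue
            if EUPLOTID.codon_to_aa[new] != EUPLOTID.codon_to_aa[old] and om >= params.omega:
                continue
            codons[c] = new

    # --- losses of existing sites
    p_loss = -math.expm1(-params.u_loss * length)
    touched: set[int] = set()
    for j in sorted(state.fs):
        if rng.random() < p_loss:
            shift = state.fs.pop(j)
            touched.add(j)
            events.append(
                {"junction": j, "kind": "loss", "shift": shift, "context": codons[j - 1]}
            )

    # --- gains at currently suitable junctions
    for j in range(1, L):
        if j in state.fs or j in touched:
            continue
        p1 = (
            -math.expm1(-_gain1_rate(codons, j, params) * length)
            if _is_gain1_context(codons, j)
            else 0.0
        )
        p2 = (
            -math.expm1(-params.u_gain2 * length)
            if _is_gain2_context(codons, j)
            else 0.0
        )
        if p1 == 0.0 and p2 == 0.0:
            continue
        u = rng.random()
        if u < p1:
            state.fs[j] = 1
            events.append(
                {"junction": j, "kind": "gain", "shift": 1, "context": codons[j - 1]}
            )
        elif u < p1 + p2:
            state.fs[j] = 2
            events.append(
                {"junction": j, "kind": "gain", "shift": 2, "context": codons[j - 1]}
            )
    return state, events, n_rejected


def evolve_orthogroup(
    root_cds: str,
    tree_table: TreeTable,
    params: SimParams,
    rng: np.random.Generator,
    root_fs: dict[int, int] | None = None,
) -> tuple[dict[str, LineageState], list[dict], int]:
    """Evolve one orthogroup along the tree.

    Returns per-node states (keyed by node name, internal nodes included),
    the per-branch event list, and the count of rejected substitutions.
    """
    if len(root_cds) % 3:
        raise ValueError("root CDS length must be a codon multiple")
    codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
    if any(c in STOPS for c in codons):
        raise ValueError("root CDS must be stop-free in frame 0")
    states: dict[int, LineageState] = {
        0: LineageState(codons, dict(root_fs or {}))
    }
    by_name: dict[str, LineageState] = {tree_table.nodes[0].name: states[0]}
    events: list[dict] = []
    n_rejected = 0
    for node in tree_table.branches():
        child, ev, rej = _evolve_branch(
            states[node.parent], node.length, params, rng
        )
        states[node.index] = child
        by_name[node.name] = child
        n_rejected += rej
        for e in ev:
            e["branch"] = node.name
        events.extend(ev)
    return by_name, events, n_rejected


def plant_root_fs(
    codons: list[str], params: SimParams, rng: np.random.Generator
) -> dict[int, int]:
    """Standing +1 sites at the root, preferring AAA_AR contexts."""
    fs: dict[int, int] = {}
    for j in range(1, len(codons)):
        if not _is_gain1_context(codons, j):
            continue
        scale = 1.0 if codons[j - 1] == "AAA" else params.u_gain_other_scale
        if rng.random() < params.root_fs_prob * scale:
            fs[j] = 1
    return fs


def make_transcript(
    cds: str,
    params: SimParams,
    rng: np.random.Generator,
    transcript_id: str,
    species: str,
) -> tuple[Transcript, dict]:
    """Wrap a realised CDS in euplotid transcript anatomy.

    Adds an AT-rich 5' UTR, a terminating stop codon at the CDS end, a short
    AT-rich (hence stop-rich) 3' UTR, and a polyA tail.  Returns the
    transcript and an anatomy record with the coordinate shifts.
    """
    utr5_len = int(rng.poisson(params.utr5_len_mean)) if params.utr5_len_mean else 0
    utr5 = _random_seq(utr5_len, params.at_bias, rng)
    while utr5.startswith("T" * 10):  # a leading polyT run would flip orientation
        utr5 = _random_seq(utr5_len, params.at_bias, rng)
    terminator = "TAA" if rng.random() < 0.8 else "TAG"
    if params.utr3_len_mean > 0:
        utr3_len = int(rng.geometric(1.0 / (params.utr3_len_mean + 1.0))) - 1
    else:
        utr3_len = 0
    utr3 = _random_seq(utr3_len, params.at_bias, rng)
    seq = utr5 + cds + terminator + utr3 + "A" * params.polyA_len
    anatomy = {
        "transcript_id": transcript_id,
        "species": species,
        "cds_start": len(utr5),
        "cds_nt_len": len(cds),
        "terminator_pos": len(utr5) + len(cds),
        "terminator": terminator,
        "utr3_len": utr3_len,
        "polyA_len": params.polyA_len,
    }
    return (
        Transcript(
            id=transcript_id,
            species=species,
            seq=seq,
            orientation="sense",
            orientation_method="polyA",
        ),
        anatomy,
    )


@dataclass
class TruthTable:
    """Planted ground truth: per-leaf sites, per-branch events, ancestors."""

    fs_records: pd.DataFrame
    events: pd.DataFrame
    anatomy: pd.DataFrame
    labels: pd.DataFrame
    node_states: dict[tuple[str, str], LineageState] = field(repr=False, default_factory=dict)
    n_rejected_substitutions: int = 0

    def leaf_sites(self) -> set[tuple[str, int, int]]:
        """(transcript_id, stop nt position on transcript, shift) triples."""
        return {
            (r.transcript_id, int(r.pos), int(r.shift))
            for r in self.fs_records.itertuples()
        }


@dataclass
class SyntheticDataset:
    params: SimParams
    tree_table: TreeTable
    transcripts: list[Transcript]
    orthogroups: pd.DataFrame
    truth: TruthTable
    contaminant_hits: list[HitRecord] = field(default_factory=list)
    chimera_hits: list[HitRecord] = field(default_factory=list)

    @property
    def newick(self) -> str:
        return self.params.tree

    def transcript_by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}


FS_COLUMNS = [
    "orthogroup_id",
    "species",
    "transcript_id",
    "junction",
    "shift",
    "cds_pos",
    "pos",
    "stop_codon",
    "context",
]
EVENT_COLUMNS = ["orthogroup_id", "branch", "junction", "kind", "shift", "context"]


def generate_dataset(params: SimParams) -> SyntheticDataset:
    """Generate a full cohort: transcripts, orthogroups, truth, QC artefacts."""
    rng = np.random.default_rng(params.seed)
    tree_table = TreeTable(read_tree(params.tree))
    leaf_names = tree_table.leaf_names

    transcripts: list[Transcript] = []
    og_rows: list[dict] = []
    fs_rows: list[dict] = []
    event_rows: list[dict] = []
    anatomy_rows: list[dict] = []
    node_states: dict[tuple[str, str], LineageState] = {}
    total_rejected = 0

    for og_idx in range(params.n_orthogroups):
        og_id = f"OG{og_idx:04d}"
        root_cds = random_root_cds(params.cds_len, params.at_bias, rng)
        root_codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
        root_fs = plant_root_fs(root_codons, params, rng)
        states, events, rejected = evolve_orthogroup(
            root_cds, tree_table, params, rng, root_fs
        )
        total_rejected += rejected
        for name, st in states.items():
            node_states[(og_id, name)] = st
        for e in events:
            event_rows.append({"orthogroup_id": og_id, **e})

        present = list(leaf_names)
        if params.species_presence < 1.0:
            present = [
                s for s in leaf_names if rng.random() < params.species_presence
            ]
            if len(present) < 2:
                present = leaf_names[:2]
        for species in present:
            st = states[species]
            cds = cds_with_fs(st.codons, st.fs)
            tid = f"{species}|{og_id}"
            transcript, anatomy = make_transcript(cds, params, rng, tid, species)
            transcripts.append(transcript)
            anatomy["orthogroup_id"] = og_id
            anatomy_rows.append(anatomy)
            og_rows.append(
                {"orthogroup_id": og_id, "species": species, "transcript_id": tid}
            )
            positions = fs_nt_positions(st.codons, st.fs)
            for j, shift in sorted(st.fs.items()):
                cds_pos = positions[j]
                pos = anatomy["cds_start"] + cds_pos
                stop = transcript.seq[pos : pos + 3]
                fs_rows.append(
                    {
                        "orthogroup_id": og_id,
                        "species": species,
                        "transcript_id": tid,
                        "junction": j,
                        "shift": shift,
                        "cds_pos": cds_pos,
                        "pos": pos,
                        "stop_codon": stop,
                        "context": st.codons[j - 1],
                    }
                )

    labels = pd.DataFrame(
        {"transcript_id": [t.id for t in transcripts], "label": "clean"}
    )
    truth = TruthTable(
        fs_records=pd.DataFrame(fs_rows, columns=FS_COLUMNS),
        events=pd.DataFrame(event_rows, columns=EVENT_COLUMNS),
        anatomy=pd.DataFrame(anatomy_rows),
        labels=labels,
        node_states=node_states,
        n_rejected_substitutions=total_rejected,
    )
    dataset = SyntheticDataset(
        params=params,
        tree_table=tree_table,
        transcripts=transcripts,
        orthogroups=pd.DataFrame(og_rows),
        truth=truth,
    )
    if params.contam_fraction > 0:
        dataset = plant_qc_violations(dataset, params, rng)
    return dataset


# ---------------------------------------------------------------------------
# QC-violation planting


def _mutate(seq: str, fraction: float, at_bias: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    n = int(round(fraction * len(seq)))
    idx = rng.choice(len(seq), size=n, replace=False)
    bases = np.array(list("ACGT"))
    arr[idx] = bases[rng.choice(4, size=n, p=_base_probs(at_bias))]
    return "".join(arr)


def _path_length(tree_table: TreeTable, a: str, b: str) -> float:
    idx = {n.name: n for n in tree_table.nodes}
    def ancestors(name: str) -> dict[int, float]:
        out = {}
        node = idx[name]
        dist = 0.0
        while node.parent >= 0:
            dist += node.length
            node = tree_table.nodes[node.parent]
            out[node.index] = dist
        return out
    anc_a = ancestors(a)
    node = idx[b]
    dist = 0.0
    while node.parent >= 0:
        dist += node.length
        node = tree_table.nodes[node.parent]
        if node.index in anc_a:
            return dist + anc_a[node.index]
    return dist


def plant_qc_violations(
    dataset: SyntheticDataset, params: SimParams, rng: np.random.Generator
) -> SyntheticDataset:
    """Add labelled QC violations: low-AT contaminants, near-identical
    cross-species duplicates, diverged decoys, contaminant-hit carriers and
    chimeras with compatible hit records.  No-op when contam_fraction = 0."""
    if params.contam_fraction == 0:
        return dataset
    n_bad = max(5, int(round(params.contam_fraction * len(dataset.transcripts))))
    per_class = max(1, n_bad // 5)
    leaf_names = dataset.tree_table.leaf_names
    clean = list(dataset.transcripts)
    og = dataset.orthogroups
    by_og: dict[str, list[Transcript]] = {}
    tmap = dataset.transcript_by_id()
    for row in og.itertuples():
        by_og.setdefault(row.orthogroup_id, []).append(tmap[row.transcript_id])

    new_transcripts: list[Transcript] = []
    new_og_rows: list[dict] = []
    label_rows: list[dict] = []
    contaminant_hits: list[HitRecord] = []
    chimera_hits: list[HitRecord] = []

    # (a) low-AT contaminants (GC-rich foreign transcripts)
    for i in range(per_class):
        seq = _random_seq(1000, 0.25, rng)
        tid = f"CONTAM_AT_{i:03d}"
        species = leaf_names[i % len(leaf_names)]
        new_transcripts.append(
            Transcript(tid, species, seq, "sense", "polyA")
        )
        label_rows.append({"transcript_id": tid, "label": "low_at"})

    og_ids = sorted(by_og)
    # (b) near-identical cross-species duplicate pairs (identity > 0.95).
    # Each pair lives in its own fresh orthogroup: identity is symmetric, so
    # planting a near-copy into a clean orthogroup would drag its clean
    # source over the band's upper bound as well.
    for i in range(per_class):
        src_seq = _random_seq(1200, params.at_bias, rng) + "A" * params.polyA_len
        sp_a, sp_b = leaf_names[i % len(leaf_names)], leaf_names[(i + 1) % len(leaf_names)]
        og_id = f"OG_DUP{i:03d}"
        for suffix, sp in (("a", sp_a), ("b", sp_b)):
            tid = f"DUP_{i:03d}{suffix}"
            seq = _mutate(src_seq, 0.01, params.at_bias, rng)
            seq = seq[: -params.polyA_len] + "A" * params.polyA_len
            new_transcripts.append(Transcript(tid, sp, seq, "sense", "polyA"))
            new_og_rows.append(
                {"orthogroup_id": og_id, "species": sp, "transcript_id": tid}
            )
            label_rows.append({"transcript_id": tid, "label": "duplicate"})

    # (c) diverged decoys (identity < 0.65)
    for i in range(per_class):
        src = by_og[og_ids[(i + 3) % len(og_ids)]][0]
        other = next(s for s in leaf_names if s != src.species)
        tid = f"DECOY_{i:03d}"
        # 60% of positions redrawn; with ~30% chance redraws match, expected
        # nucleotide identity ~0.58, safely below the 0.65 band edge
        seq = _mutate(src.seq, 0.60, params.at_bias, rng)
        new_transcripts.append(Transcript(tid, other, seq, "sense", "polyA"))
        og_id = og.loc[og.transcript_id == src.id, "orthogroup_id"].iloc[0]
        new_og_rows.append(
            {"orthogroup_id": og_id, "species": other, "transcript_id": tid}
        )
        label_rows.append({"transcript_id": tid, "label": "decoy"})

    # (d) clean transcripts that hit the declared contaminant set
    marked: set[str] = set()
    for i in range(per_class):
        src = by_og[og_ids[(i + 7) % len(og_ids)]][1]
        marked.add(src.id)
        contaminant_hits.append(
            HitRecord(
                query_id=src.id,
                subject_id=f"contaminant_seq_{i}",
                subject_organism="Dunaliella_sp",
                pct_identity=85.0,
                align_len=min(500, len(src.seq)),
                query_start=0,
                query_end=min(500, len(src.seq)),
                e_value=1e-30,
            )
        )
        label_rows.append({"transcript_id": src.id, "label": "contaminant_hit"})

    # (e) chimeras: halves of two deep-divergence orthologs, hits overlap 0 nt
    pair = ("E_octocarinatus", "E_crassus")
    for i in range(per_class):
        members = by_og[og_ids[(i + 11) % len(og_ids)]]
        src_a = next(t for t in members if t.species == pair[0])
        src_b = next(t for t in members if t.species == pair[1])
        half_a = src_a.seq[: len(src_a.seq) // 2]
        half_b = src_b.seq[len(src_b.seq) // 2 :]
        tid = f"CHIM_{i:03d}"
        seq = half_a + half_b
        species = leaf_names[(i + 4) % len(leaf_names)]
        new_transcripts.append(Transcript(tid, species, seq, "sense", "polyA"))
        og_id = og.loc[og.transcript_id == src_a.id, "orthogroup_id"].iloc[0]
        new_og_rows.append(
            {"orthogroup_id": og_id, "species": species, "transcript_id": tid}
        )
        label_rows.append({"transcript_id": tid, "label": "chimera"})
        chimera_hits.append(
            HitRecord(tid, src_a.id, pair[0], 95.0, len(half_a), 0, len(half_a), 1e-40)
        )
        chimera_hits.append(
            HitRecord(
                tid, src_b.id, pair[1], 95.0, len(half_b), len(half_a), len(seq), 1e-40
            )
        )

    labels = pd.concat(
        [dataset.truth.labels, pd.DataFrame(label_rows)], ignore_index=True
    )
    # a clean transcript carrying a planted contaminant hit is no longer clean
    labels = labels.drop_duplicates("transcript_id", keep="last")
    truth = replace(dataset.truth, labels=labels)
    return SyntheticDataset(
        params=dataset.params,
        tree_table=dataset.tree_table,
        transcripts=clean + new_transcripts,
        orthogroups=pd.concat(
            [og, pd.DataFrame(new_og_rows)], ignore_index=True
        )
        if new_og_rows
        else og,
        truth=truth,
        contaminant_hits=contaminant_hits,
        chimera_hits=chimera_hits,
    )


# ---------------------------------------------------------------------------
# Truth alignments (exact, because non-FS indels do not occur)


def truth_alignment(dataset: SyntheticDataset, og_id: str) -> dict[str, str]:
    """Exact codon alignment of one orthogroup's realised CDSs.

    Junctions carrying a frameshift site in any species contribute indel
    columns: a two-column TA block (+2 carriers) followed by a one-column T
    block (+1 carriers); non-carriers hold gaps there.
    """
    members = dataset.orthogroups[dataset.orthogroups.orthogroup_id == og_id]
    # planted QC artefacts can list a species twice; one row per species
    species = [
        s
        for s in dict.fromkeys(members.species)
        if (og_id, s) in dataset.truth.node_states
    ]
    states = {s: dataset.truth.node_states[(og_id, s)] for s in species}
    L = len(next(iter(states.values())).codons)
    cols_plus1 = sorted(
        {j for st in states.values() for j, sh in st.fs.items() if sh == 1}
    )
    cols_plus2 = sorted(
        {j for st in states.values() for j, sh in st.fs.items() if sh == 2}
    )
    rows: dict[str, list[str]] = {s: [] for s in species}
    for j in range(L):
        has1 = j in cols_plus1
        has2 = j in cols_plus2
        for s in species:
            shift = states[s].fs.get(j)
            block = ""
            if has2:
                block += "TA" if shift == 2 else "--"
            if has1:
                block += "T" if shift == 1 else "-"
            rows[s].append(block + states[s].codons[j])
    return {s: "".join(parts) for s, parts in rows.items()}


# ---------------------------------------------------------------------------
# Serialisation


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Emit per-species FASTA, orthogroup TSV, newick, truth tables, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list[tuple[str, str]]] = {}
    for t in dataset.transcripts:
        by_species.setdefault(t.species, []).append((t.id, t.seq))
    for species in sorted(by_species):
        write_fasta(by_species[species], outdir / f"{species}.fasta")
    dataset.orthogroups.to_csv(outdir / "orthogroups.tsv", sep="\t", index=False)
    (outdir / "tree.nwk").write_text(dataset.params.tree + "\n")
    dataset.truth.fs_records.to_csv(outdir / "truth_fs.tsv", sep="\t", index=False)
    dataset.truth.events.to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    dataset.truth.anatomy.to_csv(outdir / "truth_anatomy.tsv", sep="\t", index=False)
    dataset.truth.labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    summary = {
        "n_transcripts": len(dataset.transcripts),
        "n_orthogroups": int(dataset.orthogroups.orthogroup_id.nunique()),
        "n_fs_leaf_records": int(len(dataset.truth.fs_records)),
        "n_events": int(len(dataset.truth.events)),
        "n_rejected_substitutions": int(dataset.truth.n_rejected_substitutions),
    }
    (outdir / "truth_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    (outdir / "sim_config.yaml").write_text(
        yaml.safe_dump(
            {k: v for k, v in vars(dataset.params).items()}, sort_keys=True
        )
    )
    if dataset.contaminant_hits or dataset.chimera_hits:
        from .qc_filter import HIT_COLUMNS

        for name, hits in (
            ("contaminant_hits.tsv", dataset.contaminant_hits),
            ("chimera_hits.tsv", dataset.chimera_hits),
        ):
            rows = []
            for h in hits:
                rows.append(
                    {
                        "query_id": h.query_id,
                        "subject_id": h.subject_id,
                        "subject_organism": h.subject_organism,
                        "pct_identity": h.pct_identity,
                        "align_len": h.align_len,
                        "query_start": h.query_start + 1,  # back to 1-based
                        "query_end": h.query_end,
                        "e_value": h.e_value,
                    }
                )
            pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
                outdir / name, sep="\t", index=False
            )
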