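"""Gain/loss inference for frameshift sites on a species phylogeny.

Each frameshift site maps to an alignment column (the stop codon's T).
Leaf states are binary: 1 when the T is present and completes a TAR stop,
0 when the column is gapped but the NNN_AR gain context is intact, missing
otherwise.  To avoid scoring misalignment artefacts as indel events, only
sites whose 10 alignment columns on each side of the indel block are
gap-free in every sequence are used.

Ancestral presence/absence is reconstructed with Fitch maximum parsimony
(ties at the root resolve to absence; ties below resolve to the parent
state, so reconstructions are unique and deterministic).  A 0->1 change on
a branch is a gain (T insertion), 1->0 a loss (T deletion).  Event
probabilities are exposure-normalised: P_gain = n_gain / K with K the
branch-length-weighted mean count of ancestral NNN_AR motifs, and
P_loss = n_loss / F with F the corresponding count of existing NNN_TAR
sites, so that expected event counts are rate x exposure x tree length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import TreeTable

__all__ = [
    "SiteColumn",
    "EventTable",
    "fitch_states",
    "map_columns",
    "count_contexts",
    "branch_exposures",
    "reconstruct_ancestors",
    "infer_events",
    "build_event_table",
    "event_probabilities",
    "ratio_test",
]

STOPS = ("TAA", "TAG")
PURINES = "AG"
FLANK_COLUMNS = 10


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_states(
    tree_table: TreeTable, leaf_states: Mapping[str, int]
) -> tuple[dict[str, int], int]:
    """Most-parsimonious ancestral 0/1 states for one site.

    Leaves absent from ``leaf_states`` are ignored (pruned).  Requires at
    least two scored leaves.  Returns resolved states for every node with
    information below it, and the parsimony score (number of set unions).
    """
    scored = {k: v for k, v in leaf_states.items() if v in (0, 1)}
    if len(scored) < 2:
        raise ValueError("need at least 2 scored leaves")
    nodes = tree_table.nodes
    sets: list[frozenset | None] = [None] * len(nodes)
    score = 0
    for node in reversed(nodes):  # postorder: parents precede children in preorder
        if node.is_leaf:
            if node.name in scored:
                sets[node.index] = frozenset({scored[node.name]})
            continue
        child_sets = [
            sets[c] for c in tree_table.children(node.index) if sets[c] is not None
        ]
        if not child_sets:
            continue
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[node.index] = inter
        else:
            sets[node.index] = frozenset.union(*child_sets)
            score += 1
    resolved: dict[str, int] = {}
    for node in nodes:  # preorder: parent resolved before children
        s = sets[node.index]
        if s is None:
            continue
        if node.parent < 0:
            resolved[node.name] = 0 if len(s) > 1 else next(iter(s))
        else:
            parent_name = nodes[node.parent].name
            parent_state = resolved.get(parent_name)
            if parent_state is not None and parent_state in s:
                resolved[node.name] = parent_state
            else:
                resolved[node.name] = min(s)
    return resolved, score


# ---------------------------------------------------------------------------
# Mapping detected sites onto alignments


@dataclass
class SiteColumn:
    """One frameshift site located in an orthogroup alignment."""

    orthogroup_id: str
    column: int  # alignment column of the stop codon's T
    shift: int
    context: str
    states: dict[str, int | None] = field(default_factory=dict)
    flank_ok: bool = True
    junction: int | None = None  # codon-boundary index in the ungapped frame

    def scored_states(self) -> dict[str, int]:
        return {k: v for k, v in self.states.items() if v in (0, 1)}


def _ungapped_to_column(row: str, q: int) -> int:
    """Alignment column of the q-th (0-based) non-gap character of ``row``."""
    seen = -1
    for col, ch in enumerate(row):
        if ch != "-":
            seen += 1
            if seen == q:
                return col
    raise ValueError("ungapped position beyond row length")


def _next_nongap(row: str, col: int, n: int) -> str:
    out = []
    for ch in row[col:]:
        if ch != "-":
            out.append(ch)
            if len(out) == n:
                break
    return "".join(out)


def _indel_block(alignment: Mapping[str, str], col: int) -> tuple[int, int]:
    """Maximal run of gap-containing columns around ``col`` (half-open)."""
    rows = list(alignment.values())
    n_col = len(rows[0])

    def gappy(c: int) -> bool:
        return any(r[c] == "-" for r in rows)

    lo = col
    while lo > 0 and gappy(lo - 1):
        lo -= 1
    hi = col + 1 if gappy(col) else col
    while hi < n_col and gappy(hi):
        hi += 1
    if hi <= lo:
        hi = lo + 1
    return lo, hi


def _leaf_state(row: str, col: int, shift: int) -> int | None:
    """1: T present completing a TAR stop; 0: gap with intact AR context."""
    ch = row[col]
    if ch == "T":
        if shift == 1:
            nxt = _next_nongap(row, col + 1, 2)
            return 1 if len(nxt) == 2 and nxt[0] == "A" and nxt[1] in PURINES else None
        nxt = _next_nongap(row, col + 1, 2)
        return 1 if len(nxt) == 2 and nxt[0] == "A" and nxt[1] in PURINES else None
    if ch == "-":
        nxt = _next_nongap(row, col + 1, 2)
        if shift == 1:
            if len(nxt) == 2 and nxt[0] == "A" and nxt[1] in PURINES:
                return 0
            return None
        if len(nxt) >= 1 and nxt[0] in PURINES:
            return 0
        return None
    return None


def map_columns(
    alignment: Mapping[str, str],
    fs_records: pd.DataFrame,
    transcript_seqs: Mapping[str, str],
    orthogroup_id: str,
) -> list[SiteColumn]:
    """Locate each frameshift site of one orthogroup in its alignment.

    ``fs_records`` needs columns species, transcript_id, pos, shift, context;
    ``pos`` is the stop codon's T on the transcript.  The alignment rows are
    the orthogroup CDS sequences (with frameshift Ts realised), which must
    occur verbatim within their transcripts — the offset found by string
    search converts transcript coordinates to row coordinates.  Sites whose
    stop cannot be located are dropped with a note; sites failing the
    ±10-gap-free-column flank rule are returned with ``flank_ok=False``.
    """
    sites: dict[tuple[int, int], SiteColumn] = {}
    for rec in fs_records.itertuples():
        row = alignment.get(rec.species)
        if row is None:
            continue
        row_ungapped = row.replace("-", "")
        seq = transcript_seqs[rec.transcript_id]
        offset = seq.find(row_ungapped)
        if offset < 0:
            continue
        q = int(rec.pos) - offset
        if not 0 <= q < len(row_ungapped):
            continue
        col = _ungapped_to_column(row, q)
        key = (col, int(rec.shift))
        if key not in sites:
            sites[key] = SiteColumn(
                orthogroup_id=orthogroup_id,
                column=col,
                shift=int(rec.shift),
                context=str(rec.context),
            )
    out = []
    for (col, shift), site in sorted(sites.items()):
        lo, hi = _indel_block(alignment, col)
        n_col = len(next(iter(alignment.values())))
        flank_ok = lo >= FLANK_COLUMNS and hi + FLANK_COLUMNS <= n_col
        if flank_ok:
            for c in range(lo - FLANK_COLUMNS, lo):
                if any(r[c] == "-" for r in alignment.values()):
                    flank_ok = False
                    break
        if flank_ok:
            for c in range(hi, hi + FLANK_COLUMNS):
                if any(r[c] == "-" for r in alignment.values()):
                    flank_ok = False
                    break
        site.flank_ok = flank_ok
        gapfree_before = sum(
            1
            for c in range(lo)
            if all(r[c] != "-" for r in alignment.values())
        )
        site.junction = gapfree_before // 3
        site.states = {
            sp: _leaf_state(row, col, shift) for sp, row in alignment.items()
        }
        out.append(site)
    return out


# ---------------------------------------------------------------------------
# Context exposures


def count_contexts(
    codons: Sequence[str], fs: Mapping[int, int] | None = None
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-context exposure counts of one coding sequence.

    K[ctx] counts codon boundaries where the preceding codon is ``ctx`` and
    the next codon starts with A followed by a purine (a T insertion there
    creates an NNN_TAR site); junctions already carrying a site are not gain
    contexts.  F[ctx] counts the existing sites by their preceding codon.
    """
    fs = dict(fs or {})
    K: dict[str, int] = {}
    F: dict[str, int] = {}
    for j in range(1, len(codons)):
        ctx = codons[j - 1]
        if j in fs:
            F[ctx] = F.get(ctx, 0) + 1
        elif codons[j][0] == "A" and codons[j][1] in PURINES:
            K[ctx] = K.get(ctx, 0) + 1
    return K, F


# the gap state carries the lowest bit so that ties at the root resolve
# toward absence of an insert, consistent with the binary Fitch convention
_CHAR_BITS = {"-": 1, "A": 2, "C": 4, "G": 8, "T": 16, "N": 30}
_BIT_CHAR = {1: "-", 2: "A", 4: "C", 8: "G", 16: "T"}


def reconstruct_ancestors(
    tree_table: TreeTable, alignment: Mapping[str, str]
) -> dict[str, tuple[list[str], dict[int, int]]]:
    """MP ancestral coding states (codons + frameshift junctions).

    Column-wise Fitch over {A, C, G, T, -} on bitmask arrays (ties resolve
    to the parent state, root ties to the first state in A<C<G<T<- order).
    Assumes alignment gaps occur only at frameshift junctions — true for
    the exact orthogroup alignments this pipeline consumes; regions with
    other indels must be masked upstream.  Returns, per node (leaves
    included), the gap-free codon list and the junction->shift map implied
    by reconstructed indel columns: one reconstructed insert base before a
    codon is a +1 T, two are a +2 TA.
    """
    species = [s for s in tree_table.leaf_names if s in alignment]
    if not species:
        return {}
    n_col = len(next(iter(alignment.values())))
    nodes = tree_table.nodes
    sets = np.zeros((len(nodes), n_col), dtype=np.uint8)
    for node in nodes:
        if node.is_leaf and node.name in alignment:
            sets[node.index] = np.frombuffer(
                alignment[node.name]
                .translate(str.maketrans("ACGTN-", "\x02\x04\x08\x10\x1e\x01"))
                .encode("latin1"),
                dtype=np.uint8,
            )
    for node in reversed(nodes):
        if node.is_leaf:
            continue
        acc = None
        for c in tree_table.children(node.index):
            row = sets[c]
            if not row.any():
                continue
            if acc is None:
                acc = row.copy()
            else:
                inter = acc & row
                acc = np.where(inter > 0, inter, acc | row).astype(np.uint8)
        if acc is not None:
            sets[node.index] = acc
    low = sets & (-sets.astype(np.int16)).astype(np.uint8)  # lowest set bit
    resolved = np.zeros_like(sets)
    for node in nodes:
        s = sets[node.index]
        if node.parent < 0:
            resolved[node.index] = low[node.index]  # ties: gap < A < C < G < T
        else:
            p = resolved[nodes[node.parent].index]
            resolved[node.index] = np.where((s & p) > 0, p, low[node.index]).astype(
                np.uint8
            )
    gappy = np.zeros(n_col, dtype=bool)
    for s in species:
        gappy |= np.frombuffer(alignment[s].encode("latin1"), dtype=np.uint8) == ord(
            "-"
        )
    out: dict[str, tuple[list[str], dict[int, int]]] = {}
    for node in nodes:
        row = resolved[node.index]
        if not row.any():
            continue
        chars = [_BIT_CHAR.get(int(b), "-") for b in row]
        codons: list[str] = []
        fs: dict[int, int] = {}
        buf: list[str] = []
        pending_insert = 0
        for c in range(n_col):
            if gappy[c]:
                if chars[c] != "-":
                    pending_insert += 1
                continue
            buf.append(chars[c])
            if len(buf) == 3:
                if pending_insert:
                    fs[len(codons)] = min(pending_insert, 2)
                    pending_insert = 0
                codons.append("".join(buf))
                buf = []
        out[node.name] = (codons, fs)
    return out


def branch_exposures(
    tree_table: TreeTable,
    ancestor_states: Mapping[str, tuple[Sequence[str], Mapping[int, int]]],
    orthogroup_id: str,
) -> pd.DataFrame:
    """Per-branch, per-context K and F counted on the branch's parent node."""
    rows = []
    for node in tree_table.branches():
        parent_name = tree_table.nodes[node.parent].name
        if parent_name not in ancestor_states:
            continue
        codons, fs = ancestor_states[parent_name]
        K, F = count_contexts(codons, fs)
        for ctx in sorted(set(K) | set(F)):
            rows.append(
                {
                    "orthogroup_id": orthogroup_id,
                    "branch": node.name,
                    "context": ctx,
                    "K": K.get(ctx, 0),
                    "F": F.get(ctx, 0),
                }
            )
    return pd.DataFrame(
        rows, columns=["orthogroup_id", "branch", "context", "K", "F"]
    )


# ---------------------------------------------------------------------------
# Event inference


def infer_events(
    tree_table: TreeTable, site_columns: Sequence[SiteColumn]
) -> pd.DataFrame:
    """Per-branch gains and losses from MP ancestral states of each site."""
    rows = []
    name_of_parent = {
        n.name: tree_table.nodes[n.parent].name for n in tree_table.branches()
    }
    for site in site_columns:
        if not site.flank_ok:
            continue
        scored = site.scored_states()
        if len(scored) < 2:
            continue
        try:
            resolved, _ = fitch_states(tree_table, scored)
        except ValueError:
            continue
        for child, parent in name_of_parent.items():
            if child not in resolved or parent not in resolved:
                continue
            a, b = resolved[parent], resolved[child]
            if a == b:
                continue
            rows.append(
                {
                    "orthogroup_id": site.orthogroup_id,
                    "branch": child,
                    "context": site.context,
                    "kind": "gain" if b == 1 else "loss",
                    "shift": site.shift,
                    "column": site.column,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["orthogroup_id", "branch", "context", "kind", "shift", "column"],
    )


@dataclass
class EventTable:
    """Branch/context-resolved events with their exposures."""

    events: pd.DataFrame  # orthogroup_id, branch, context, kind, shift
    exposures: pd.DataFrame  # orthogroup_id, branch, context, K, F
    branch_lengths: dict[str, float]

    @property
    def total_branch_length(self) -> float:
        return sum(self.branch_lengths.values())

    def _select(self, df: pd.DataFrame, contexts) -> pd.DataFrame:
        if contexts is None:
            return df
        if isinstance(contexts, str):
            contexts = [contexts]
        return df[df.context.isin(contexts)]

    def counts(self, contexts=None) -> tuple[int, int]:
        ev = self._select(self.events, contexts)
        return int((ev.kind == "gain").sum()), int((ev.kind == "loss").sum())

    def mean_exposures(self, contexts=None) -> tuple[float, float]:
        """Branch-length-weighted mean ancestral K and F, summed over
        orthogroups, so that E[n_gain] = P_gain * K with P_gain = u * T."""
        ex = self._select(self.exposures, contexts)
        T = self.total_branch_length
        if T == 0 or ex.empty:
            return 0.0, 0.0
        by_branch = ex.groupby("branch")[["K", "F"]].sum()
        k_bar = f_bar = 0.0
        for branch, row in by_branch.iterrows():
            w = self.branch_lengths.get(branch, 0.0) / T
            k_bar += w * float(row.K)
            f_bar += w * float(row.F)
        return k_bar, f_bar

    def probabilities(self, contexts=None) -> dict:
        """P_gain = n_gain/K, P_loss = n_loss/F; zero counts become
        pseudo-count-1 upper bounds, flagged."""
        n_gain, n_loss = self.counts(contexts)
        K, F = self.mean_exposures(contexts)
        out: dict = {"n_gain": n_gain, "n_loss": n_loss, "K": K, "F": F}
        # pseudo-count-1 upper bounds for zero counts, capped at 1 (mean
        # exposures below one event would otherwise exceed probability 1)
        out["p_gain"] = min(1.0, max(n_gain, 1) / K) if K > 0 else None
        out["p_gain_is_bound"] = n_gain == 0
        out["p_loss"] = min(1.0, max(n_loss, 1) / F) if F > 0 else None
        out["p_loss_is_bound"] = n_loss == 0
        return out

    def per_orthogroup_arrays(self, contexts=None):
        """Per-orthogroup event counts and length-weighted exposures, for
        bootstrap resampling."""
        ev = self._select(self.events, contexts)
        ex = self._select(self.exposures, contexts)
        ogs = sorted(set(ex.orthogroup_id) | set(ev.orthogroup_id))
        idx = {og: i for i, og in enumerate(ogs)}
        n = len(ogs)
        gains = np.zeros(n)
        losses = np.zeros(n)
        k_w = np.zeros(n)
        f_w = np.zeros(n)
        for r in ev.itertuples():
            (gains if r.kind == "gain" else losses)[idx[r.orthogroup_id]] += 1
        T = self.total_branch_length
        for r in ex.itertuples():
            w = self.branch_lengths.get(r.branch, 0.0) / T if T else 0.0
            k_w[idx[r.orthogroup_id]] += w * r.K
            f_w[idx[r.orthogroup_id]] += w * r.F
        return gains, losses, k_w, f_w


def build_event_table(
    tree_table: TreeTable,
    events: pd.DataFrame,
    exposures: pd.DataFrame,
    exclude_root_edges: bool = False,
) -> EventTable:
    """Package events and exposures with their branch lengths.

    With ``exclude_root_edges`` the two branches incident to the root are
    dropped from events, exposures and the time base: event polarity there
    is unidentifiable to parsimony (a gain on one root edge and a root
    presence lost on the sibling edge are equally parsimonious, and the
    root-tie convention would convert every deep loss into a gain, biasing
    P_gain/P_loss upward).  Rate and selection estimation should use the
    identifiable branch set.
    """
    lengths = {n.name: n.length for n in tree_table.branches()}
    if exclude_root_edges:
        root_adjacent = {
            n.name for n in tree_table.branches() if n.parent == 0
        }
        events = events[~events.branch.isin(root_adjacent)].reset_index(drop=True)
        exposures = exposures[~exposures.branch.isin(root_adjacent)].reset_index(
            drop=True
        )
        lengths = {k: v for k, v in lengths.items() if k not in root_adjacent}
    return EventTable(events=events, exposures=exposures, branch_lengths=lengths)


def event_probabilities(ev: EventTable) -> pd.DataFrame:
    """Per-context and pooled gain/loss probabilities."""
    contexts = sorted(set(ev.exposures.context) | set(ev.events.context))
    rows = []
    for ctx in contexts + [None]:
        p = ev.probabilities(ctx)
        p["context"] = ctx if ctx is not None else "pooled"
        rows.append(p)
    return pd.DataFrame(rows)


def bootstrap_S(
    ev: EventTable,
    contexts=None,
    rounds: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap samples of S = ln(P_gain/P_loss), resampling orthogroups."""
    rng = np.random.default_rng() if rng is None else rng
    gains, losses, k_w, f_w = ev.per_orthogroup_arrays(contexts)
    n = len(gains)
    if n == 0:
        return np.array([])
    idx = rng.integers(0, n, size=(rounds, n))
    g = gains[idx].sum(axis=1)
    l = losses[idx].sum(axis=1)
    K = k_w[idx].sum(axis=1)
    F = f_w[idx].sum(axis=1)
    valid = (K > 0) & (F > 0)
    g = np.maximum(g[valid], 1.0)
    l = np.maximum(l[valid], 1.0)
    return np.log((g / K[valid]) / (l / F[valid]))


def ratio_test(
    ev: EventTable,
    contexts=None,
    rounds: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """One-sided permutation test of P_loss > P_gain, plus a bootstrap CI.

    Null: each observed event is independently a gain with probability
    K/(K+F) (exposure-proportional allocation).  The p-value is the
    fraction of rounds whose loss/gain probability ratio is at least the
    observed one.  The CI for P_loss/P_gain resamples orthogroups.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_gain, n_loss = ev.counts(contexts)
    n_total = n_gain + n_loss
    p = ev.probabilities(contexts)
    out = {
        "n_gain": n_gain,
        "n_loss": n_loss,
        "K": p["K"],
        "F": p["F"],
    }
    if n_total == 0 or p["p_gain"] is None or p["p_loss"] is None:
        out.update({"p_value": 1.0, "ratio": None, "ci_low": None, "ci_high": None})
        return out
    ratio_obs = p["p_loss"] / p["p_gain"]
    K, F = p["K"], p["F"]
    w = K / (K + F)
    g = rng.binomial(n_total, w, size=rounds).astype(float)
    l = n_total - g
    with np.errstate(divide="ignore", invalid="ignore"):
        r_null = np.where(g > 0, (l / F) / np.where(g > 0, g, 1) * K, np.inf)
    p_value = float(np.mean(r_null >= ratio_obs))
    s_samples = bootstrap_S(ev, contexts, rounds=1000, rng=rng)
    if len(s_samples):
        lo, hi = np.quantile(np.exp(-s_samples), [0.025, 0.975])
    else:
        lo = hi = None
    out.update(
        {
            "p_value": p_value,
            "ratio": ratio_obs,
            "ci_low": float(lo) if lo is not None else None,
            "ci_high": float(hi) if hi is not None else None,
        }
    )
    return out
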