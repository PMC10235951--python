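"""Pairwise protein alignment, identity, and Nei-Gojobori dN/dS.

dN/dS is computed with the Nei-Gojobori (1986) counting method under an
arbitrary genetic code, which matters here: under the euplotid code TGA
encodes cysteine, so e.g. TGT gains a synonymous mutational neighbour that
the standard code lacks.  Mutational neighbours that are stop codons are
excluded from the site denominators (the position contributes fewer
countable mutants), which keeps syn + nonsyn sites equal to 3 per codon.

The uniformity metric compares dN/dS between two segments of one coding
model (the seed ORF and a candidate extension): each of dN, N, dS, S is
resampled from a Poisson distribution with the observed value as mean, the
two ratios are formed, and the fraction of rounds in which the extension's
ratio exceeds the seed's is returned.  Under uniform evolution this is ~0.5.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from .seqcore import EUPLOTID, GeneticCode

__all__ = [
    "Alignment",
    "NGCounts",
    "align_sw",
    "protein_identity",
    "ng_site_counts",
    "ng_dnds",
    "dnds_purifying_support",
    "dnds_uniformity",
]

BASES = "ACGT"


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float
    start_a: int = 0  # offset of the aligned region within input a (local mode)
    start_b: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


def align_sw(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Optimal Smith-Waterman local alignment of two protein strings."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:  # no positive-scoring local alignment exists
        return Alignment(aligned_a="", aligned_b="", score=0.0)
    return Alignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        score=aln.score,
        start_a=int(aln.coordinates[0][0]),
        start_b=int(aln.coordinates[1][0]),
    )


def protein_identity(aln: Alignment) -> float:
    """Identical residues over nongap columns; gap columns are removed."""
    pairs = [
        (x, y)
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x != "-" and y != "-"
    ]
    if not pairs:
        raise ValueError("alignment has no nongap columns")
    return sum(x == y for x, y in pairs) / len(pairs)


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, code_name: str) -> tuple[float, float]:
    code = EUPLOTID if code_name == EUPLOTID.name else _CODES[code_name]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue
            n_valid += 1
            if code.codon_to_aa[mutant] == code.codon_to_aa[codon]:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


_CODES: dict[str, GeneticCode] = {}


def ng_site_counts(
    codon: str, code: GeneticCode = EUPLOTID
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3.

    Per position, the synonymous fraction of the single-nucleotide mutants is
    counted; mutants that are stop codons are excluded from the denominator.
    """
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site counts")
    _CODES.setdefault(code.name, code)
    return _site_counts_cached(codon, code.name)


def _pathway_diffs(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float]:
    """Syn/nonsyn difference counts averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, the average is taken over all pathways (standard fallback).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                hits_stop = True
            if code.codon_to_aa.get(cur) == code.codon_to_aa.get(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if hits_stop else paths).append((syn, nonsyn))
    pool = paths if paths else blocked
    syn = sum(p[0] for p in pool) / len(pool)
    nonsyn = sum(p[1] for p in pool) / len(pool)
    return syn, nonsyn


def _jukes_cantor(p: float) -> float | None:
    if p < 0.75:
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    return None


@dataclass(frozen=True)
class NGCounts:
    """Nei-Gojobori site/difference counts and corrected distances."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def pS(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else float("nan")

    @property
    def pN(self) -> float:
        return (
            self.nonsyn_diffs / self.nonsyn_sites
            if self.nonsyn_sites
            else float("nan")
        )

    @property
    def dS(self) -> float | None:
        if not self.syn_sites:
            return None
        return _jukes_cantor(self.pS)

    @property
    def dN(self) -> float | None:
        if not self.nonsyn_sites:
            return None
        return _jukes_cantor(self.pN)

    @property
    def dnds(self) -> float | None:
        dn, ds = self.dN, self.dS
        if dn is None or ds is None or ds == 0.0:
            return None
        return dn / ds


def ng_dnds(
    cds_a: str, cds_b: str, code: GeneticCode = EUPLOTID
) -> NGCounts:
    """Nei-Gojobori counts for two aligned, gap-free, in-frame CDS strings.

    Site counts are averaged over the two sequences; multi-hit codons are
    resolved by averaging over minimal mutational pathways.  Codon pairs in
    which either codon is a stop or contains N are skipped.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    if len(cds_a) % 3:
        raise ValueError("length must be a multiple of 3")
    if "-" in cds_a or "-" in cds_b:
        raise ValueError("gap characters not allowed; pass gap-free columns")
    syn_sites = nonsyn_sites = syn_diffs = nonsyn_diffs = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if "N" in ca or "N" in cb or code.is_stop(ca) or code.is_stop(cb):
            continue
        sa, na = ng_site_counts(ca, code)
        sb, nb = ng_site_counts(cb, code)
        syn_sites += (sa + sb) / 2
        nonsyn_sites += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb, code)
        syn_diffs += sd
        nonsyn_diffs += nd
        n_codons += 1
    return NGCounts(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs, n_codons)


def _informative(c: NGCounts) -> bool:
    return (
        c.syn_sites > 0
        and c.nonsyn_sites > 0
        and c.syn_diffs > 0
        and c.nonsyn_diffs > 0
    )


def dnds_purifying_support(
    counts: NGCounts,
    rounds: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Resampling support for dN/dS < 1 (purifying selection).

    Draws (dN, N, dS, S) from Poisson distributions with the observed
    values as means and returns the fraction of rounds with
    (dN/N)/(dS/S) < 1.  Zero observed nonsynonymous differences give
    support 1.0 (no evidence against purifying selection is possible);
    zero synonymous differences with nonsynonymous ones present give 0.0
    (dS = 0, the ratio cannot support purifying selection).
    """
    if counts.nonsyn_diffs == 0:
        return 1.0
    if counts.syn_diffs == 0 or counts.syn_sites == 0 or counts.nonsyn_sites == 0:
        return 0.0
    rng = np.random.default_rng() if rng is None else rng
    got = wins = attempts = 0
    while got < rounds and attempts < 50:
        attempts += 1
        batch = max(rounds - got, 256)
        dn = rng.poisson(counts.nonsyn_diffs, batch)
        n = rng.poisson(counts.nonsyn_sites, batch)
        ds = rng.poisson(counts.syn_diffs, batch)
        s = rng.poisson(counts.syn_sites, batch)
        valid = (n > 0) & (ds > 0) & (s > 0)
        if not valid.any():
            continue
        ratio = (dn[valid] / n[valid]) / (ds[valid] / s[valid])
        take = min(int(valid.sum()), rounds - got)
        wins += int((ratio[:take] < 1.0).sum())
        got += take
    return wins / got if got else 0.0


def dnds_uniformity(
    primary: NGCounts,
    adjacent: NGCounts,
    rounds: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of resampling rounds with adjacent dN/dS > primary dN/dS.

    Each of (dN, N, dS, S) for both segments is drawn from Poisson
    distributions with the observed values as means.  Rounds in which any
    denominator draw is zero are resampled.  If either segment has no
    synonymous or no nonsynonymous differences the resampling scheme is
    degenerate and 0.5 (uninformative, "uniform") is returned.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not (_informative(primary) and _informative(adjacent)):
        return 0.5
    rng = np.random.default_rng() if rng is None else rng
    got = 0
    wins = 0
    attempts = 0
    while got < rounds and attempts < 50:
        attempts += 1
        batch = max(rounds - got, 256)
        draws = {}
        for tag, c in (("p", primary), ("a", adjacent)):
            draws[tag] = (
                rng.poisson(c.nonsyn_diffs, batch),  # dN
                rng.poisson(c.nonsyn_sites, batch),  # N
                rng.poisson(c.syn_diffs, batch),  # dS
                rng.poisson(c.syn_sites, batch),  # S
            )
        valid = np.ones(batch, dtype=bool)
        for tag in ("p", "a"):
            _, n, ds, s = draws[tag]
            valid &= (n > 0) & (ds > 0) & (s > 0)
        if not valid.any():
            continue
        ratios = {}
        for tag in ("p", "a"):
            dn, n, ds, s = (x[valid].astype(float) for x in draws[tag])
            ratios[tag] = (dn / n) / (ds / s)
        take = min(int(valid.sum()), rounds - got)
        wins += int((ratios["a"][:take] > ratios["p"][:take]).sum())
        got += take
    if got == 0:
        return 0.5
    return wins / got
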