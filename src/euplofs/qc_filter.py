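"""Contamination screen and chimera flagging for assembled transcriptomes.

Ciliate transcriptomes cannot be physically separated from prey/symbiont
RNA, so contaminant transcripts are removed by deterministic rules:

1. AT content below the cohort mean minus 4 SD (ciliate transcripts are
   AT-rich; contaminants form a low-AT mode),
2. singletons without cross-species homologs,
3. closest-homolog nucleotide identity outside the between-ciliate band
   [0.65, 0.95] (below: too diverged; above: cross-species index bleed or
   duplicated contaminant),
4. similarity hits against a declared contaminant set (>70% identity at
   E < 1e-25).

Finally, transcripts with two strong hits (>70% identity, E < 1e-10) from
different organisms overlapping by at most 15 nt on the query are flagged
as assembly chimeras.  Similarity searches themselves are out of scope: the
module consumes tabular hit records (BLAST outfmt-6-like, plus an organism
column).
"""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqcore import Transcript

__all__ = [
    "HitRecord",
    "QcReport",
    "QcThresholds",
    "read_hit_table",
    "filter_at",
    "filter_singletons",
    "filter_identity_band",
    "filter_contaminants",
    "flag_chimeras",
    "closest_homolog_identities",
    "apply_qc",
]

FILTER_ORDER = ("at", "singleton", "identity_band", "contaminant", "chimera")


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit; query coordinates 0-based half-open internally."""

    query_id: str
    subject_id: str
    subject_organism: str
    pct_identity: float
    align_len: int
    query_start: int
    query_end: int
    e_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.query_start >= self.query_end:
            raise ValueError("query_start must be < query_end after conversion")

    @classmethod
    def from_table_row(cls, row: Mapping) -> "HitRecord":
        # input dialect is 1-based inclusive, as in BLAST outfmt 6
        return cls(
            query_id=str(row["query_id"]),
            subject_id=str(row["subject_id"]),
            subject_organism=str(row["subject_organism"]),
            pct_identity=float(row["pct_identity"]),
            align_len=int(row["align_len"]),
            query_start=int(row["query_start"]) - 1,
            query_end=int(row["query_end"]),
            e_value=float(row["e_value"]),
        )


HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "subject_organism",
    "pct_identity",
    "align_len",
    "query_start",
    "query_end",
    "e_value",
]


def read_hit_table(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [HitRecord.from_table_row(row) for _, row in df.iterrows()]


@dataclass(frozen=True)
class QcThresholds:
    at_sd_multiplier: float = 4.0
    identity_low: float = 0.65
    identity_high: float = 0.95
    contaminant_identity: float = 70.0
    contaminant_evalue: float = 1e-25
    chimera_identity: float = 70.0
    chimera_evalue: float = 1e-10
    chimera_max_overlap: int = 15


@dataclass
class QcReport:
    """Per-transcript QC status; statuses partition the input set."""

    status: dict[str, str] = field(default_factory=dict)
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    cohort_stats: dict[str, float] = field(default_factory=dict)
    order_applied: list[str] = field(default_factory=list)

    def kept_ids(self) -> list[str]:
        return [t for t, s in self.status.items() if s == "kept"]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.status.values():
            out[s] = out.get(s, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": list(self.status), "status": list(self.status.values())}
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts(),
            "thresholds": vars(self.thresholds),
            "cohort_stats": self.cohort_stats,
            "order_applied": self.order_applied,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _active(report: QcReport, transcripts: Sequence[Transcript]) -> list[Transcript]:
    return [t for t in transcripts if report.status.get(t.id) == "kept"]


def _init_report(
    transcripts: Sequence[Transcript], thresholds: QcThresholds
) -> QcReport:
    report = QcReport(thresholds=thresholds)
    for t in transcripts:
        report.status[t.id] = "kept"
    return report


def filter_at(
    transcripts: Sequence[Transcript], report: QcReport
) -> QcReport:
    """Remove transcripts with AT fraction < cohort mean - k*SD (sample SD)."""
    active = _active(report, transcripts)
    if len(active) < 2:
        raise ValueError("AT filter needs at least 2 transcripts")
    values = [t.at_fraction for t in active]
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    cutoff = mean - report.thresholds.at_sd_multiplier * sd
    report.cohort_stats.update(
        {"at_mean": mean, "at_sd": sd, "at_cutoff": cutoff}
    )
    for t in active:
        if t.at_fraction < cutoff:  # strictly below: equality keeps
            report.status[t.id] = "removed_at"
    report.order_applied.append("at")
    return report


def filter_singletons(
    transcripts: Sequence[Transcript],
    orthogroups: pd.DataFrame,
    report: QcReport,
) -> QcReport:
    """Remove transcripts not in any orthogroup spanning >= 2 species."""
    multi = orthogroups.groupby("orthogroup_id")["species"].nunique()
    good_groups = set(multi[multi >= 2].index)
    member_of_good = set(
        orthogroups.loc[
            orthogroups["orthogroup_id"].isin(good_groups), "transcript_id"
        ]
    )
    for t in _active(report, transcripts):
        if t.id not in member_of_good:
            report.status[t.id] = "removed_singleton"
    report.order_applied.append("singleton")
    return report


def filter_identity_band(
    transcripts: Sequence[Transcript],
    identities: Mapping[str, float],
    report: QcReport,
) -> QcReport:
    """Keep transcripts whose closest-homolog nucleotide identity lies in the band.

    Removal is strict: identity < low bound or > high bound; band endpoints
    are kept.  Transcripts with no identity value are skipped with a warning.
    """
    low = report.thresholds.identity_low
    high = report.thresholds.identity_high
    for t in _active(report, transcripts):
        ident = identities.get(t.id)
        if ident is None:
            warnings.warn(f"no closest-homolog identity for {t.id}; skipped")
            continue
        if ident < low or ident > high:
            report.status[t.id] = "removed_identity_band"
    report.order_applied.append("identity_band")
    return report


def filter_contaminants(
    transcripts: Sequence[Transcript],
    hits: Iterable[HitRecord],
    report: QcReport,
) -> QcReport:
    """Remove transcripts with a contaminant hit >70% identity at E < 1e-25."""
    th = report.thresholds
    flagged = {
        h.query_id
        for h in hits
        if h.pct_identity > th.contaminant_identity
        and h.e_value < th.contaminant_evalue
    }
    for t in _active(report, transcripts):
        if t.id in flagged:
            report.status[t.id] = "removed_contaminant"
    report.order_applied.append("contaminant")
    return report


def _query_overlap(a: HitRecord, b: HitRecord) -> int:
    return max(0, min(a.query_end, b.query_end) - max(a.query_start, b.query_start))


def flag_chimeras(
    transcripts: Sequence[Transcript],
    hits: Iterable[HitRecord],
    report: QcReport,
) -> QcReport:
    """Flag transcripts with two strong hits from different organisms whose
    query intervals overlap by at most 15 nt."""
    th = report.thresholds
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.pct_identity > th.chimera_identity and h.e_value < th.chimera_evalue:
            by_query.setdefault(h.query_id, []).append(h)
    for t in _active(report, transcripts):
        qhits = by_query.get(t.id, [])
        found = False
        for i in range(len(qhits)):
            for j in range(i + 1, len(qhits)):
                a, b = qhits[i], qhits[j]
                if a.subject_organism == b.subject_organism:
                    continue
                if _query_overlap(a, b) <= th.chimera_max_overlap:
                    found = True
                    break
            if found:
                break
        if found:
            report.status[t.id] = "flagged_chimera"
    report.order_applied.append("chimera")
    return report


def closest_homolog_identities(
    transcripts: Sequence[Transcript], orthogroups: pd.DataFrame
) -> dict[str, float]:
    """Nucleotide identity of each transcript with its closest cross-species
    homolog (global edit-distance identity; no value for transcripts without
    cross-species orthogroup partners)."""
    import edlib

    tmap = {t.id: t for t in transcripts}
    out: dict[str, float] = {}
    for og_id, grp in orthogroups.groupby("orthogroup_id"):
        rows = [r for r in grp.itertuples() if r.transcript_id in tmap]
        for i, a in enumerate(rows):
            best = None
            for j, b in enumerate(rows):
                if i == j or a.species == b.species:
                    continue
                sa, sb = tmap[a.transcript_id].seq, tmap[b.transcript_id].seq
                dist = edlib.align(sa, sb, task="distance")["editDistance"]
                ident = 1.0 - dist / max(len(sa), len(sb))
                if best is None or ident > best:
                    best = ident
            if best is not None:
                prev = out.get(a.transcript_id)
                if prev is None or best > prev:
                    out[a.transcript_id] = best
    return out


def apply_qc(
    transcripts: Sequence[Transcript],
    orthogroups: pd.DataFrame,
    identities: Mapping[str, float],
    contaminant_hits: Iterable[HitRecord] = (),
    chimera_hits: Iterable[HitRecord] = (),
    thresholds: QcThresholds | None = None,
) -> QcReport:
    """Run the full screen in the canonical order:
    AT -> singleton -> identity band -> contaminant -> chimera."""
    report = _init_report(transcripts, thresholds or QcThresholds())
    filter_at(transcripts, report)
    filter_singletons(transcripts, orthogroups, report)
    filter_identity_band(transcripts, identities, report)
    filter_contaminants(transcripts, list(contaminant_hits), report)
    flag_chimeras(transcripts, list(chimera_hits), report)
    return report
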