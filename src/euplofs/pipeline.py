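"""End-to-end orchestration: simulate -> qc -> detect -> events -> dynamics.

Every stage writes its tables (TSV) and summaries (JSON with sorted keys)
into the run directory, and the effective configuration is echoed there, so
two runs with the same configuration produce byte-identical numeric output.
All randomness flows from the single configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phylo_events as pe
from . import selection_dynamics as sd
from .fs_detect import DecodedCDS, DetectParams, detect_all
from .qc_filter import QcThresholds, apply_qc, closest_homolog_identities
from .synthetic_data import (
    SimParams,
    SyntheticDataset,
    generate_dataset,
    truth_alignment,
    write_dataset,
)

__all__ = ["PipelineConfig", "PipelineResult", "run", "report"]

ALL_STAGES = ("simulate", "qc", "detect", "events", "dynamics", "report")


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    detect: DetectParams = field(default_factory=DetectParams)
    qc: QcThresholds = field(default_factory=QcThresholds)
    stages: tuple = ALL_STAGES
    events_rounds: int = 10_000
    bootstrap_rounds: int = 1000
    q_equilibrium: float = 0.95
    genome_n_genes: float = 30_000.0
    genome_coding_bp: float = 4.5e7
    ne_grid: tuple = (1e4, 1e5, 1e6, 1e7, 1e8)
    seed: int = 0
    outdir: str = "runs/demo"

    def __post_init__(self) -> None:
        # one seed drives everything: the simulator and the detector get
        # deterministic offsets of the run seed
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.detect = dataclasses.replace(self.detect, seed=self.seed + 1)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = SimParams(**raw.pop("sim", {}))
        detect = DetectParams(**raw.pop("detect", {}))
        qc = QcThresholds(**raw.pop("qc", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "ne_grid" in raw:
            raw["ne_grid"] = tuple(raw["ne_grid"])
        return cls(sim=sim, detect=detect, qc=qc, **raw)

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "detect": dataclasses.asdict(self.detect),
            "qc": dataclasses.asdict(self.qc),
            "stages": list(self.stages),
            "events_rounds": self.events_rounds,
            "bootstrap_rounds": self.bootstrap_rounds,
            "q_equilibrium": self.q_equilibrium,
            "genome_n_genes": self.genome_n_genes,
            "genome_coding_bp": self.genome_coding_bp,
            "ne_grid": list(self.ne_grid),
            "seed": self.seed,
            "outdir": self.outdir,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset | None = None
    qc_report: object | None = None
    fs_table: pd.DataFrame | None = None
    decoded: dict[str, DecodedCDS] | None = None
    detect_summary: dict | None = None
    event_table: pe.EventTable | None = None
    selection: dict | None = None
    dynamics: pd.DataFrame | None = None
    dynamics_summary: dict | None = None


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))


def run(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    result = PipelineResult(config=config)
    stages = set(config.stages)

    # --- simulate -----------------------------------------------------------
    if "simulate" in stages:
        dataset = generate_dataset(config.sim)
        write_dataset(dataset, outdir / "data")
        result.dataset = dataset
    else:
        raise ValueError(
            "this pipeline is driven by its synthetic cohort; include the "
            "'simulate' stage (external datasets enter through the library API)"
        )
    truth = dataset.truth

    # --- qc -----------------------------------------------------------------
    transcripts = dataset.transcripts
    if "qc" in stages:
        identities = closest_homolog_identities(transcripts, dataset.orthogroups)
        qc_report = apply_qc(
            transcripts,
            dataset.orthogroups,
            identities,
            dataset.contaminant_hits,
            dataset.chimera_hits,
            config.qc,
        )
        qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        qc_report.to_json(outdir / "qc_report.json")
        result.qc_report = qc_report
        kept = set(qc_report.kept_ids())
        transcripts = [t for t in transcripts if t.id in kept]
    if not (stages & {"detect", "events", "dynamics"}):
        return result

    # --- detect -------------------------------------------------------------
    fs_table, decoded, summary = detect_all(
        transcripts, dataset.orthogroups, config.detect
    )
    truth_sites = truth.leaf_sites()
    detected_sites = {
        (r.transcript_id, int(r.pos), int(r.shift)) for r in fs_table.itertuples()
    }
    analysed_ids = {t.id for t in transcripts}
    truth_in_scope = {s for s in truth_sites if s[0] in analysed_ids}
    tp = len(detected_sites & truth_in_scope)
    summary["truth_sites_in_scope"] = len(truth_in_scope)
    summary["true_positives"] = tp
    summary["sensitivity"] = tp / len(truth_in_scope) if truth_in_scope else None
    summary["precision"] = tp / len(detected_sites) if detected_sites else None
    fs_table.to_csv(outdir / "fs_table.tsv", sep="\t", index=False)
    _write_json(outdir / "detect_summary.json", summary)
    result.fs_table = fs_table
    result.decoded = decoded
    result.detect_summary = summary
    if not (stages & {"events", "dynamics"}):
        return result

    # --- events -------------------------------------------------------------
    tmap = {t.id: t for t in transcripts}
    seqs = {t.id: t.seq for t in transcripts}
    all_sites: list[pe.SiteColumn] = []
    exposure_frames: list[pd.DataFrame] = []
    analysed_ogs = sorted(
        set(
            dataset.orthogroups.loc[
                dataset.orthogroups.transcript_id.isin(analysed_ids), "orthogroup_id"
            ]
        )
    )
    for og_id in analysed_ogs:
        aln = truth_alignment(dataset, og_id)
        aln = {sp: row for sp, row in aln.items() if f"{sp}|{og_id}" in tmap}
        if len(aln) < 2:
            continue
        anc = pe.reconstruct_ancestors(dataset.tree_table, aln)
        exposure_frames.append(
            pe.branch_exposures(dataset.tree_table, anc, og_id)
        )
        og_fs = fs_table[fs_table.orthogroup_id == og_id]
        if len(og_fs):
            all_sites.extend(pe.map_columns(aln, og_fs, seqs, og_id))
    exposures = (
        pd.concat(exposure_frames, ignore_index=True)
        if exposure_frames
        else pd.DataFrame(columns=["orthogroup_id", "branch", "context", "K", "F"])
    )
    site_rows = [
        {
            "orthogroup_id": s.orthogroup_id,
            "column": s.column,
            "shift": s.shift,
            "context": s.context,
            "flank_ok": s.flank_ok,
            "junction": s.junction,
            "n_present": sum(1 for v in s.states.values() if v == 1),
            "n_absent": sum(1 for v in s.states.values() if v == 0),
        }
        for s in all_sites
    ]
    pd.DataFrame(
        site_rows,
        columns=[
            "orthogroup_id",
            "column",
            "shift",
            "context",
            "flank_ok",
            "junction",
            "n_present",
            "n_absent",
        ],
    ).to_csv(outdir / "site_columns.tsv", sep="\t", index=False)
    events = pe.infer_events(dataset.tree_table, all_sites)
    # rate/selection estimation uses the identifiable branch set: event
    # polarity on the two root-adjacent branches is ambiguous to parsimony
    ev = pe.build_event_table(
        dataset.tree_table, events, exposures, exclude_root_edges=True
    )
    ev.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    ev.exposures.to_csv(outdir / "exposures.tsv", sep="\t", index=False)
    result.event_table = ev

    rng_events = np.random.default_rng([config.seed, 2])
    selection: dict = {}
    for label, contexts in (("AAA", "AAA"), ("pooled", None)):
        test = pe.ratio_test(ev, contexts, rounds=config.events_rounds, rng=rng_events)
        block = dict(test)
        p = ev.probabilities(contexts)
        if p["p_gain"] and p["p_loss"]:
            s_samples = pe.bootstrap_S(
                ev, contexts, rounds=config.bootstrap_rounds, rng=rng_events
            )
            if len(s_samples):
                # normal interval with bootstrap SE (calibrates better than
                # the percentile interval at small event counts)
                s_point = math.log(p["p_gain"] / p["p_loss"])
                se = float(np.std(s_samples, ddof=1))
                ci = (s_point - 1.96 * se, s_point + 1.96 * se)
            else:
                ci = None
            est = sd.scaled_selection(
                p["p_gain"],
                p["p_loss"],
                is_bound=p["p_gain_is_bound"] or p["p_loss_is_bound"],
                ci=ci,
            )
            block.update(
                {
                    "p_gain": est.p_gain,
                    "p_loss": est.p_loss,
                    "S": est.S,
                    "S_is_bound": est.is_bound,
                    "S_ci_low": est.ci_low,
                    "S_ci_high": est.ci_high,
                }
            )
        selection[label] = block
    _write_json(outdir / "selection.json", selection)
    result.selection = selection
    if "dynamics" not in stages:
        return result

    # --- dynamics -----------------------------------------------------------
    T = dataset.tree_table.total_length
    pooled = ev.probabilities(None)
    if pooled["p_gain"] is None or pooled["p_loss"] is None:
        result.dynamics_summary = {"note": "no exposures; dynamics skipped"}
        _write_json(outdir / "dynamics.json", result.dynamics_summary)
        return result
    u_gain = sd.prob_to_rate(pooled["p_gain"], T)
    u_loss = sd.prob_to_rate(pooled["p_loss"], T)
    rows = []
    for species in dataset.tree_table.leaf_names:
        models = [
            m
            for tid, m in (decoded or {}).items()
            if tmap[tid].species == species
        ]
        if not models:
            continue
        K_s = 0
        for m in models:
            codons, fs = _model_state(m, seqs[m.transcript_id])
            K, _ = pe.count_contexts(codons, fs)
            K_s += sum(K.values())
        F0_s = int((fs_table.species == species).sum())
        dyn = sd.DynamicsModel(K=K_s, F0=float(F0_s), u_gain=u_gain, u_loss=u_loss)
        row = {"species": species, "n_models": len(models), **dyn.summary()}
        row["t95"] = dyn.t_to_fraction(config.q_equilibrium)
        row["eq_fs_per_gene"] = dyn.A / len(models)
        gs = sd.genome_scale(row["eq_fs_per_gene"], config.genome_n_genes)
        row["per_genome_eq_fs"] = gs["per_genome_by_genes"]
        rows.append(row)
    dynamics = pd.DataFrame(rows)
    dynamics.to_csv(outdir / "dynamics.tsv", sep="\t", index=False)
    s_val = selection.get("AAA", {}).get("S") or selection.get("pooled", {}).get("S")
    lag_rows = []
    if s_val is not None:
        mean_eq = float(dynamics.per_genome_eq_fs.mean()) if len(dynamics) else 0.0
        for ne in config.ne_grid:
            lag_rows.append(
                {
                    "Ne": ne,
                    "lag_load": sd.lag_load(abs(s_val), ne, mean_eq)
                    if ne > abs(s_val)
                    else None,
                }
            )
    pd.DataFrame(lag_rows).to_csv(outdir / "lag_load.tsv", sep="\t", index=False)
    result.dynamics = dynamics
    result.dynamics_summary = {
        "u_gain": u_gain,
        "u_loss": u_loss,
        "tree_length": T,
        "fold_change_min": float(dynamics.fold_change.replace(np.inf, np.nan).min())
        if len(dynamics)
        else None,
        "fold_change_max": float(dynamics.fold_change.replace(np.inf, np.nan).max())
        if len(dynamics)
        else None,
        "t95_mean": float(dynamics.t95.mean()) if len(dynamics) else None,
    }
    _write_json(outdir / "dynamics.json", result.dynamics_summary)

    if "report" in stages:
        (outdir / "run_report.md").write_text(report(outdir))
    return result


def _model_state(model: DecodedCDS, seq: str) -> tuple[list[str], dict[int, int]]:
    """Codons and frameshift junctions of a decoded model, positionally."""
    codons: list[str] = []
    fs: dict[int, int] = {}
    prev_frame = None
    for seg in model.segments:
        if prev_frame is not None:
            shift = (seg.frame - prev_frame) % 3
            if shift:
                fs[len(codons)] = shift
        for i in range(seg.start, seg.end, 3):
            codons.append(seq[i : i + 3])
        prev_frame = seg.frame
    return codons, fs


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed (possibly partial) run."""
    run_dir = Path(run_dir)
    lines = ["# Frameshift-site analysis run", ""]

    def load(name: str):
        p = run_dir / name
        return json.loads(p.read_text()) if p.exists() else None

    qc = load("qc_report.json")
    if qc:
        lines.append("## Quality screen")
        for status, n in sorted(qc["counts"].items()):
            lines.append(f"- {status}: {n}")
        lines.append("")
    det = load("detect_summary.json")
    if det:
        lines.append("## Frameshift detection")
        lines.append(
            f"- transcripts decoded: {det['n_decoded']} of {det['n_transcripts']}"
        )
        lines.append(
            f"- +1 sites: {det['n_fs_plus1']}; +2 sites: {det['n_fs_plus2']}; "
            f"readthrough joins: {det['n_readthrough']}"
        )
        lines.append(
            f"- transcripts with >=1 FS: {det['n_transcripts_with_fs']} "
            f"({100 * det['frac_transcripts_with_fs']:.1f}%); orthogroups: "
            f"{det['n_orthogroups_with_fs']} "
            f"({100 * det['frac_orthogroups_with_fs']:.1f}%)"
        )
        if det.get("sensitivity") is not None:
            lines.append(
                f"- vs planted truth: sensitivity {det['sensitivity']:.3f}, "
                f"precision {det['precision']:.3f}"
            )
        if det.get("utr3_median") is not None:
            lines.append(f"- median 3' UTR length: {det['utr3_median']:.0f} nt")
        lines.append("")
    sel = load("selection.json")
    if sel:
        lines.append("## Gains, losses and selection")
        for label, block in sel.items():
            if "S" in block:
                ci = ""
                if block.get("S_ci_low") is not None:
                    ci = f" (95% CI {block['S_ci_low']:.2f}..{block['S_ci_high']:.2f})"
                lines.append(
                    f"- {label}: gains {block['n_gain']}, losses {block['n_loss']}; "
                    f"P_loss/P_gain = {block['ratio']:.1f} "
                    f"(p = {block['p_value']:.3f}); S = {block['S']:.2f}{ci}"
                )
        lines.append("")
    dyn = load("dynamics.json")
    if dyn and "u_gain" in dyn:
        lines.append("## Accumulation dynamics")
        lines.append(
            f"- rates per substitution/site: gain {dyn['u_gain']:.4g}, "
            f"loss {dyn['u_loss']:.4g}"
        )
        if dyn.get("fold_change_min") is not None:
            lines.append(
                f"- equilibrium fold change across species: "
                f"{dyn['fold_change_min']:.1f} to {dyn['fold_change_max']:.1f}"
            )
        if dyn.get("t95_mean") is not None:
            lines.append(
                f"- mean time to 95% of equilibrium: {dyn['t95_mean']:.2f} "
                "substitutions/site"
            )
        lines.append("")
    if len(lines) == 2:
        lines.append("(no stage outputs found)")
    return "\n".join(lines) + "\n"
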