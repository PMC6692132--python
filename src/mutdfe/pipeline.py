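"""End-to-end orchestration: simulate -> fitness -> DFE -> covariates ->
regressions -> phylogenetic presence, from one config, with a manifest and a
machine-readable report.

Every tunable of the analysis (30-colony filter, 10,000 permutations,
10,000 null simulations, 100 tree resolutions, 42-nt folding windows) is a
config field with that value as its default; reruns with the same config
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimConfig
from .dfe import DFESample, beneficial_tail, build_dfe, ks_compare, lrt_exponential
from .fitness import estimate_fitness_table
from .mutations import (CodingSequence, CodonUsageTable, PointMutation,
                        TRNACopyTable, delta_metrics, extract_mrna_window,
                        ramp_test)
from .permreg import expression_fitness_regression, permlm
from .phylo import PresenceAnalysis, load_tree, presence_model
from .simulate import MARKER_CONTROL_ID, write_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mutdfe.pipeline")

ALL_STAGES = ("simulate", "fitness", "dfe", "covariates", "regressions", "phylo")


class PipelineError(RuntimeError):
    """A stage failed; the stage name is carried for exit-code handling."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full pipeline parameterisation (paths or a simulation block)."""

    outdir: str = "mutdfe-run"
    simulate: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0
    min_colonies: int = 30
    marker_correct: bool = False
    include_nonsense: bool = True
    drop_minimum: bool = True
    B_ks: int = 10_000
    n_null_sims: int = 10_000
    B_perm: int = 10_000
    B_presence: int = 999
    n_resolutions: int = 100
    window_width: int = 42

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.simulate is not None:
            self.simulate.validate()
        needed = {"fitness": ["competitions"],
                  "covariates": ["gene", "mutations", "cai_reference", "trna_copies"],
                  "regressions": ["expression"],
                  "phylo": ["tree", "tip_states"]}
        if "simulate" not in self.stages:
            for stage, keys in needed.items():
                if stage not in self.stages:
                    continue
                for k in keys:
                    path = self.inputs.get(k)
                    if path is None or not Path(path).exists():
                        raise ValueError(
                            f"stage {stage!r} needs input {k!r} "
                            f"({path or 'unset'}) before execution starts")

    def stage_seed(self, name: str) -> int:
        """Per-stage 31-bit seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimConfig.from_dict(raw["simulate"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_gene_fasta(path) -> CodingSequence:
    """FASTA with one record; ``cds_start``/``cds_end`` (1-based, inclusive)
    in the description mark the CDS span, otherwise the whole record is the CDS."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    seq = str(rec.seq).upper()
    fields = dict(kv.split("=") for kv in rec.description.split()
                  if "=" in kv)
    start = int(fields.get("cds_start", 1))
    end = int(fields.get("cds_end", len(seq)))
    return CodingSequence(id=rec.id, seq=seq[start - 1:end],
                          flank5=seq[:start - 1], flank3=seq[end:])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the enabled stages; returns the aggregated report dict.

    Writes ``manifest.json`` (config echo, versions, seeds, input hashes,
    per-stage record counts), each stage's tabular outputs, and
    ``report.json``.  A stage failure raises :class:`PipelineError` naming
    the stage; outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs)
    report: dict[str, Any] = {}
    counts: dict[str, Any] = {}

    def _run(stage, fn):
        if stage not in config.stages:
            log.info("stage %s skipped", stage)
            return
        try:
            fn()
        except Exception as e:         # noqa: BLE001 - named re-raise
            raise PipelineError(stage, e) from e

    # ---- simulate -----------------------------------------------------
    def _simulate():
        sim = config.simulate or SimConfig(seed=config.seed)
        paths = write_dataset(sim, outdir / "synthetic")
        for key, name in [("gene", "gene.fasta"), ("mutations", "mutations.csv"),
                          ("competitions", "competitions.csv"),
                          ("expression", "expression.csv"), ("tree", "tree.nwk"),
                          ("tip_states", "tip_states.csv"),
                          ("cai_reference", "cai_reference.fasta"),
                          ("trna_copies", "trna_copies.csv")]:
            inputs.setdefault(key, str(paths[name]))
        counts["simulate"] = {"files": sorted(paths)}

    _run("simulate", _simulate)

    # ---- fitness ------------------------------------------------------
    def _fitness():
        comp = pd.read_csv(inputs["competitions"])
        if "class" not in comp.columns and "mutations" in inputs:
            cls = pd.read_csv(inputs["mutations"])[["mutation_id", "class"]]
            comp = comp.merge(cls, on="mutation_id", how="left")
        fit = estimate_fitness_table(comp, min_colonies=config.min_colonies,
                                     control_id=MARKER_CONTROL_ID,
                                     marker_correct=config.marker_correct)
        fit.to_csv(outdir / "fitness.csv", index=False, lineterminator="\n")
        inputs["fitness"] = str(outdir / "fitness.csv")
        counts["fitness"] = {
            "rows_in": len(comp), "mutations": int(fit["mutation_id"].nunique()),
            "excluded_replicates": int(fit["n_excluded"].sum()),
            "missing_mutations": int(fit["w_mean"].isna().sum())}
        report["marker_control"] = fit.attrs.get("marker_control")

    _run("fitness", _fitness)

    # ---- dfe ----------------------------------------------------------
    def _dfe():
        fit = pd.read_csv(inputs["fitness"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            samples = build_dfe(fit, include_nonsense=config.include_nonsense)
            ks = ks_compare(samples["synonymous"], samples["nonsynonymous"],
                            B=config.B_ks, seed=config.stage_seed("ks"))
            ben_syn = samples["synonymous"].w[samples["synonymous"].s > 0]
            no_nonsense = build_dfe(fit, include_nonsense=False)
            ben_nonsyn = no_nonsense["nonsynonymous"].w[no_nonsense["nonsynonymous"].s > 0]
            ks_ben = None
            if ben_syn.size and ben_nonsyn.size:
                ks_ben = ks_compare(ben_syn, ben_nonsyn, B=config.B_ks,
                                    seed=config.stage_seed("ks_beneficial"))
            pooled = np.concatenate([no_nonsense["synonymous"].w,
                                     no_nonsense["nonsynonymous"].w])
            tail = beneficial_tail(pooled, drop_minimum=config.drop_minimum)
            test = lrt_exponential(tail.x, n_null_sims=config.n_null_sims,
                                   seed=config.stage_seed("lrt"))
        pd.DataFrame({"x": tail.x}).to_csv(outdir / "tail_diagnostics.csv",
                                           index=False, lineterminator="\n")
        rep = {"n_by_class": {k: v.n for k, v in samples.items()},
               "n_beneficial_pooled": tail.n_beneficial,
               "tail_threshold_s": tail.threshold,
               "ks_full": _jsonable(ks),
               "ks_beneficial": _jsonable(ks_ben) if ks_ben else None,
               "tail_test": _jsonable(test),
               "evt_domain": test.domain}
        (outdir / "dfe_report.json").write_text(json.dumps(rep, indent=1) + "\n")
        report["dfe"] = rep
        counts["dfe"] = {"n_tail": int(test.free_fit.n_tail)}

    _run("dfe", _dfe)

    # ---- covariates ---------------------------------------------------
    def _covariates():
        cds = _read_gene_fasta(inputs["gene"])
        muts = pd.read_csv(inputs["mutations"])
        from Bio import SeqIO
        usage = CodonUsageTable.from_sequences(
            str(r.seq) for r in SeqIO.parse(inputs["cai_reference"], "fasta"))
        trna_df = pd.read_csv(inputs["trna_copies"])
        trna = TRNACopyTable(dict(zip(trna_df["anticodon"].astype(str),
                                      trna_df["copies"].astype(float))))
        rows = []
        for r in muts.to_dict("records"):
            mut = PointMutation(cds_position=int(r["cds_position"]),
                                ref_base=str(r["ref_base"]),
                                alt_base=str(r["alt_base"]))
            win = extract_mrna_window(cds, mut, width=config.window_width)
            row = {"mutation_id": str(r["mutation_id"]),
                   "class": str(r.get("class", "")),
                   "window_ref": win.reference, "window_mut": win.mutant,
                   "window_truncated": int(win.truncated_left or win.truncated_right)}
            if row["class"] != "nonsense":
                row.update({k: v for k, v in
                            delta_metrics(cds, mut, usage, trna).items()
                            if k != "class"})
            rows.append(row)
        cov = pd.DataFrame(rows)
        cov.to_csv(outdir / "covariates.csv", index=False, lineterminator="\n")
        inputs["covariates"] = str(outdir / "covariates.csv")
        ramp = ramp_test(cds, usage, B=min(config.B_perm, 2000),
                         seed=config.stage_seed("ramp"))
        report["ramp_test"] = _jsonable(ramp)
        counts["covariates"] = {"mutations": len(cov),
                                "nonsense_skipped": int((muts["class"] == "nonsense").sum())}

    _run("covariates", _covariates)

    # ---- regressions --------------------------------------------------
    def _regressions():
        fit = pd.read_csv(inputs["fitness"])
        regs: dict[str, Any] = {}
        if "covariates" in inputs and Path(inputs["covariates"]).exists():
            cov = pd.read_csv(inputs["covariates"])
            df = fit.merge(cov.drop(columns=["class"], errors="ignore"),
                           on="mutation_id")
            df = df[df["class"] != "nonsense"].dropna(subset=["w_mean"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for name, formula in [
                        ("fitness_vs_distance", "w_mean ~ distance_from_start_nt"),
                        ("fitness_vs_delta_cai", "w_mean ~ delta_cai"),
                        ("fitness_vs_delta_tai", "w_mean ~ delta_tai")]:
                    res = permlm(df, formula, B=config.B_perm,
                                 seed=config.stage_seed(name))
                    regs[name] = _jsonable(res)
        expr = pd.read_csv(inputs["expression"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = expression_fitness_regression(
                fit, expr, B=config.B_perm,
                seed=config.stage_seed("expression"))
        regs["fitness_vs_expression"] = _jsonable(res)
        (outdir / "regressions.json").write_text(json.dumps(regs, indent=1) + "\n")
        report["regressions"] = regs
        counts["regressions"] = {"models": len(regs)}

    _run("regressions", _regressions)

    # ---- phylo --------------------------------------------------------
    def _phylo():
        tree = load_tree(inputs["tree"])
        states = pd.read_csv(inputs["tip_states"])
        analysis = PresenceAnalysis(tree, states,
                                    n_resolutions=config.n_resolutions,
                                    seed=config.stage_seed("resolve"))
        frame = analysis.to_frame()
        frame.to_csv(outdir / "phylo_presence.csv", index=False,
                     lineterminator="\n")
        fit = pd.read_csv(inputs["fitness"])
        res = presence_model(frame, fit, rule="origin",
                             B=config.B_presence,
                             seed=config.stage_seed("presence"))
        out = {"model": _jsonable(res),
               "n_sites_present_tip": int(frame["presence_tip"].sum()),
               "n_sites_present_origin": int(frame["presence_origin"].sum())}
        (outdir / "presence_model.json").write_text(json.dumps(out, indent=1) + "\n")
        report["phylo"] = out
        counts["phylo"] = {"sites": len(frame),
                           "resolutions": config.n_resolutions}

    _run("phylo", _phylo)

    # ---- manifest & report -------------------------------------------
    manifest = {
        "mutdfe_version": __version__,
        "numpy_version": np.__version__,
        "config": _jsonable(config.to_dict()),
        "stage_seeds": {s: config.stage_seed(s) for s in
                        ("ks", "ks_beneficial", "lrt", "ramp", "resolve",
                         "presence", "expression")},
        "input_hashes": {k: _sha256(Path(v)) for k, v in sorted(inputs.items())
                         if Path(v).exists()},
        "record_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True) + "\n")
    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True) + "\n")
    return report
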