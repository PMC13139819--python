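"""Orchestration: run the analysis stages from one declarative configuration.

A :class:`RunConfig` names the input files, the stages to run (any subset of
``bands``, ``conservation``, ``serology``, ``expression``) and the parameter
overrides; :func:`run_pipeline` validates every referenced path up front,
executes the stages in order, writes per-stage TSV/Newick/JSON outputs plus a
machine-readable ``report.json`` and a plain-text log, and raises
:class:`PipelineError` with a stage-qualified diagnostic on failure.  Given
the same configuration and seed the outputs are identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import band_profiles as bp
from . import conservation as cons
from . import expression as expr
from . import serology as sero
from .trees import to_newick, write_newick

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("bands", "conservation", "serology", "expression")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # inputs (only those needed by the requested stages are required)
    band_calls: str | None = None
    alignment: str | None = None
    epitopes: str | None = None
    plate: str | None = None
    inhibition: str | None = None
    quant_dir: str | None = None
    mapping: str | None = None
    samples: str | None = None
    # parameter overrides; defaults mirror the study conditions
    metric: str = "si"  # si | pearson
    linkage: str = "upgma"
    threshold_count: int | None = None  # None -> strict majority (4 of 6)
    similar_cutoff: int = 1
    cutoff_multiplier: float = 3.0
    scale_columns: bool = False
    antigen: str | None = None

    _STAGE_INPUTS = {
        "bands": ("band_calls",),
        "conservation": ("alignment", "epitopes"),
        "serology": ("plate", "inhibition"),
        "expression": ("quant_dir", "mapping", "samples"),
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid stages are {STAGES}")
        if self.cutoff_multiplier <= 0:
            raise ValueError("cutoff_multiplier must be positive")
        for stage in self.stages:
            for key in self._STAGE_INPUTS[stage]:
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"stage {stage!r} requires input {key!r}")
                if not Path(value).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r}: input {key}={value!r} does not exist"
                    )


def _stage_bands(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    matrix = bp.read_band_calls(cfg.band_calls)
    if cfg.metric == "pearson":
        sim = bp.pearson_similarity_matrix(matrix)
    elif cfg.metric == "si":
        sim = bp.pairwise_si_matrix(matrix)
    else:
        raise ValueError(f"unknown metric {cfg.metric!r}")
    tree = bp.build_dendrogram(sim, linkage=cfg.linkage)
    stage_dir = out / "bands"
    bp.write_band_bundle(
        stage_dir, sim, tree, {"metric": cfg.metric, "linkage": cfg.linkage}
    )
    log.append(
        f"bands: {len(matrix.species_ids)} species x {len(matrix.band_labels)} bands, "
        f"metric={cfg.metric}, linkage={cfg.linkage}"
    )
    return {
        "labels": sim.labels,
        "scale": sim.scale,
        "similarity": np.round(sim.values, 4).tolist(),
        "newick": to_newick(tree),
    }


def _stage_conservation(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    aln = cons.read_alignment(cfg.alignment)
    epitopes = cons.read_epitopes(cfg.epitopes)
    matrix = cons.load_substitution_matrix("BLOSUM62")
    protein = cons.consensus_similarity_table(
        aln, matrix, cfg.threshold_count, cfg.similar_cutoff
    )
    table = cons.epitope_similarity_table(
        aln, epitopes, matrix, cfg.threshold_count, cfg.similar_cutoff
    )
    stage_dir = out / "conservation"
    stage_dir.mkdir(parents=True, exist_ok=True)
    protein.round(1).to_csv(stage_dir / "protein_similarity.tsv", sep="\t")
    table.round(1).to_csv(
        stage_dir / "epitope_similarity.tsv", sep="\t", index_label="epitope_id"
    )
    log.append(
        f"conservation: alignment of {len(aln.seq_ids)} rows x {aln.length} columns, "
        f"{len(epitopes)} epitopes, matrix={matrix.name}"
    )
    return {
        "protein_similarity": protein.round(4).to_dict(),
        "epitope_similarity": {
            eid: {k: (None if np.isnan(v) else round(v, 4)) for k, v in row.items()}
            for eid, row in table.to_dict(orient="index").items()
        },
    }


def _stage_serology(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    plate = sero.read_plate(cfg.plate)
    cutoff = sero.elisa_cutoff(
        plate.negative_ods(cfg.antigen), multiplier=cfg.cutoff_multiplier
    )
    calls = sero.call_positives(plate, cutoff, cfg.antigen)
    means = plate.mean_od(cfg.antigen)
    allergic = means["status"] == "allergic"
    result = sero.sensitization_rate(
        calls[means[allergic]["serum_id"]], antigen=cfg.antigen or "all"
    )
    summaries = [
        sero.inhibition_summary(s) for s in sero.read_inhibition(cfg.inhibition)
    ]
    stage_dir = out / "serology"
    stage_dir.mkdir(parents=True, exist_ok=True)
    call_table = means.assign(positive=calls.to_numpy())
    call_table.to_csv(stage_dir / "calls.tsv", sep="\t", index=False)
    for s in sero.read_inhibition(cfg.inhibition):
        s.to_frame().to_csv(
            stage_dir / f"inhibition_{s.inhibitor}.tsv", sep="\t", index=False
        )
    log.append(
        f"serology: cutoff={cutoff:.4f}, {result.n_positive}/{result.n_tested} "
        f"positive ({result.rate}%), {len(summaries)} inhibition series"
    )
    return {
        "cutoff": round(cutoff, 6),
        "n_tested": result.n_tested,
        "n_positive": result.n_positive,
        "sensitization_rate": result.rate,
        "inhibition": [
            {
                "inhibitor": s.inhibitor,
                "max_inhibition": round(s.max_inhibition, 1),
                "concentration_at_max": s.concentration_at_max,
                "dose_dependent": s.dose_dependent,
                "any_negative": s.any_negative,
            }
            for s in summaries
        ],
    }


def _stage_expression(cfg: RunConfig, out: Path, log: list[str]) -> dict:
    samples = expr.read_samples(cfg.samples)
    mapping = expr.read_mapping(cfg.mapping)
    quant_dir = Path(cfg.quant_dir)
    paths = {}
    for sid in samples["sample_id"]:
        qf = quant_dir / str(sid) / "quant.sf"
        if not qf.is_file():
            raise FileNotFoundError(f"missing quant file {qf}")
        paths[str(sid)] = qf
    table = expr.read_quant(paths, mapping, samples)
    agg = expr.aggregate_to_allergen(table)
    heatmap = expr.heatmap_normalize(agg, scale_columns=cfg.scale_columns)

    # cross-species allergen comparison within species having >= 2 muscle samples
    muscle = table.muscle_samples()
    codes = {}
    for species, grp in samples[samples["sample_id"].isin(muscle)].groupby("species"):
        ids = list(grp["sample_id"])
        if len(ids) < 2:
            continue
        groups = {
            a: agg.loc[a, ids].to_numpy()
            for a in agg.index
            if not agg.loc[a, ids].isna().any()
        }
        comparison = expr.group_compare(groups)
        codes[str(species)] = {
            "anova_p": comparison.anova_p,
            "codes": expr.significance_codes(comparison.pairwise_p).to_dict(),
        }
    stage_dir = out / "expression"
    stage_dir.mkdir(parents=True, exist_ok=True)
    heatmap.values.round(2).to_csv(
        stage_dir / "heatmap.tsv", sep="\t", index_label="allergen"
    )
    log.append(
        f"expression: {agg.shape[0]} allergens x {agg.shape[1]} samples, "
        f"normalization={heatmap.normalization}, "
        f"group comparisons for {sorted(codes)}"
    )
    return {
        "normalization": heatmap.normalization,
        "heatmap": {
            a: {s: (None if np.isnan(v) else round(float(v), 4)) for s, v in row.items()}
            for a, row in heatmap.values.to_dict(orient="index").items()
        },
        "comparisons": codes,
    }


_STAGE_FUNCS = {
    "bands": _stage_bands,
    "conservation": _stage_conservation,
    "serology": _stage_serology,
    "expression": _stage_expression,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"stages={','.join(config.stages)}"]
    report: dict = {"seed": config.seed, "stages": {}}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, out, log)
        except Exception as err:
            log.append(f"{stage}: FAILED ({err})")
            (out / "run.log").write_text("\n".join(log) + "\n")
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report
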