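"""End-to-end orchestration of the analysis from a single config.

Stages (fixed order): simulate-or-load -> preprocess -> per-protein
statistics (ANOVA, moderated fit, partial correlation, PCA) -> batch
correction comparison -> error model and power analysis -> GSEA.  Every
stage writes its artifacts (TSV/JSON) into the output directory and the
consolidated :class:`RunReport` summarises significant counts before and
after each correction, retention fractions, overlap counts, the fitted
error model, the power/coverage tables and enrichment results.

In simulate mode the GSEA stage compares the up-/down-regulated protein
signatures from the corrected data against a synthetic transcriptome-like
ranked signature built from the generator's ground-truth fold-changes
plus noise — a stand-in (labelled as such) for an external mRNA dataset,
so that the enrichment machinery is exercised with known concordance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batchfix, diffstats, gsea, powermodel, prep, synthdata
from .containers import ExpressionMatrix, SampleMetadata, ValidationError

log = logging.getLogger("proteopower")


@dataclass
class PipelineConfig:
    """One config block per stage; ``simulate`` or ``load`` input mode."""

    mode: str = "simulate"                       # "simulate" | "load"
    matrix_path: str | None = None               # load mode
    metadata_path: str | None = None
    mapping_path: str | None = None
    out_dir: str = "results/pipeline"
    seed: int = 0
    fdr_threshold: float = 0.10
    stages: tuple[str, ...] = (
        "preprocess", "diffstats", "batchfix", "power", "gsea"
    )
    synth: synthdata.SyntheticConfig = field(
        default_factory=synthdata.SyntheticConfig
    )
    prep: prep.PrepConfig = field(default_factory=prep.PrepConfig)
    batch_methods: tuple[str, ...] = batchfix.KNOWN_METHODS
    power: powermodel.PowerSpec | None = None
    loess_span: float = 0.75
    gsea_n_perm: int = 1000

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            for p in (self.matrix_path, self.metadata_path):
                if p is None or not Path(p).exists():
                    raise ValidationError(f"load mode requires existing path, got {p!r}")
        unknown = set(self.stages) - {"preprocess", "diffstats", "batchfix", "power", "gsea"}
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_cfg = raw.pop("synth", {})
        if "cv_curve_params" in synth_cfg:
            synth_cfg["cv_curve_params"] = synthdata.CvCurveParams(
                **synth_cfg["cv_curve_params"]
            )
        if "prep_batch_scale_range" in synth_cfg:
            synth_cfg["prep_batch_scale_range"] = tuple(
                synth_cfg["prep_batch_scale_range"]
            )
        prep_cfg = raw.pop("prep", {})
        power_cfg = raw.pop("power", None)
        for key in ("stages", "batch_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(
            **raw,
            synth=synthdata.SyntheticConfig(**synth_cfg),
            prep=prep.PrepConfig(**prep_cfg),
        )
        if power_cfg:
            for key in ("n_per_group_grid", "power_targets"):
                if key in power_cfg:
                    power_cfg[key] = tuple(power_cfg[key])
            cfg.power = powermodel.PowerSpec(**power_cfg)
        return cfg


@dataclass
class RunReport:
    seed: int
    out_dir: str
    stages_run: list[str]
    n_proteins: int
    n_samples: int
    comparison: dict | None = None
    coverage_table: dict | None = None
    gsea: list[dict] | None = None
    error_model_span: float | None = None
    timings: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict_safe(self), indent=1, sort_keys=True))


def asdict_safe(obj) -> dict:
    d = asdict(obj)

    def conv(x):
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return conv(d)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def run(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order, writing every artifact."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []
    timings: dict[str, float] = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1702]))

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.perf_counter()
                try:
                    result = fn(*a, **kw)
                except Exception as exc:  # noqa: BLE001
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                timings[name] = round(time.perf_counter() - t0, 3)
                stages_run.append(name)
                log.info("stage %s done in %.2fs", name, timings[name])
                return result
            return wrapped
        return deco

    # ---- input -----------------------------------------------------------
    @stage("input")
    def load_input():
        if config.mode == "simulate":
            cfg = synthdata.SyntheticConfig(
                **{**asdict(config.synth), "seed": config.seed,
                   "cv_curve_params": config.synth.cv_curve_params}
            )
            matrix, metadata, truth = synthdata.generate_study(cfg)
            prep.write_matrix(matrix, out / "matrix_raw.tsv")
            prep.write_metadata(metadata, out / "metadata.tsv")
            truth.to_json(out / "ground_truth.json")
            return matrix, metadata, truth
        matrix = prep.read_matrix(config.matrix_path)
        metadata = prep.read_metadata(config.metadata_path)
        return matrix, metadata, None

    matrix, metadata, truth = load_input()
    report = RunReport(
        seed=config.seed, out_dir=str(out), stages_run=stages_run,
        n_proteins=matrix.n_proteins, n_samples=matrix.n_samples,
        timings=timings,
    )

    # ---- preprocess ------------------------------------------------------
    if "preprocess" in config.stages:
        @stage("preprocess")
        def do_prep():
            mapping = (
                prep.read_mapping(config.mapping_path)
                if config.mapping_path else None
            )
            cfg = prep.PrepConfig(
                filter_quantile=config.prep.filter_quantile,
                impute_seed=config.seed,
                impute_max_iter=config.prep.impute_max_iter,
                impute_n_estimators=config.prep.impute_n_estimators,
            )
            m = prep.preprocess(matrix, mapping=mapping, config=cfg)
            prep.write_matrix(m, out / "matrix_log2.tsv")
            return m

        log2m = do_prep()
    else:
        log2m = prep.log2_transform(prep.normalize_total_area(matrix))
        if log2m.has_missing():
            raise StageError("missing values present but preprocess stage disabled")

    report.n_proteins = log2m.n_proteins

    # ---- diffstats -------------------------------------------------------
    if "diffstats" in config.stages:
        @stage("diffstats")
        def do_diff():
            design = diffstats.DesignSpec(fdr_threshold=config.fdr_threshold)
            res = diffstats.anova_per_protein(log2m, metadata, design)
            for f, r in res.items():
                r.table.to_csv(out / f"anova_{f}.tsv", sep="\t")
            pcorr = diffstats.partial_correlation(
                log2m, metadata, fdr_threshold=config.fdr_threshold
            )
            pcorr.table.to_csv(out / "partial_correlation.tsv", sep="\t")
            scores = diffstats.pca(log2m).scores.iloc[:, :5]
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            return res

        do_diff()

    # ---- batchfix --------------------------------------------------------
    corrected = None
    if "batchfix" in config.stages:
        @stage("batchfix")
        def do_batch():
            rep = batchfix.compare_methods(
                log2m, metadata, methods=config.batch_methods,
                fdr_threshold=config.fdr_threshold,
            )
            rep.counts.to_csv(out / "comparison_counts.tsv", sep="\t")
            (out / "comparison_report.json").write_text(
                json.dumps(rep.to_dict(), indent=1, sort_keys=True)
            )
            return rep

        comparison = do_batch()
        report.comparison = {
            "counts": {
                m: {k: int(v) for k, v in row.dropna().items()}
                for m, row in comparison.counts.iterrows()
            },
            "retention": comparison.retention,
        }
        if "combat_s" in config.batch_methods:
            corrected = batchfix.correct(log2m, metadata, "combat_s")
            prep.write_matrix(corrected, out / "matrix_combat_s.tsv")

    # ---- power -----------------------------------------------------------
    if "power" in config.stages:
        @stage("power")
        def do_power():
            source = corrected if corrected is not None else log2m
            raw_back = source.copy_with(
                np.power(2.0, source.values), scale="raw"
            )
            stats_ = powermodel.protein_stats(raw_back)
            model = powermodel.fit_error_model(stats_, span=config.loess_span)
            spec = config.power or powermodel.PowerSpec(n_tests=source.n_proteins)
            model.to_frame().to_csv(out / "error_model.tsv", sep="\t", index=False)
            surface = powermodel.power_surface(model, spec)
            surface.to_csv(out / "power_surface.tsv", sep="\t")
            sigmas = powermodel.protein_sigmas(stats_, model, smoothed=True)
            table = powermodel.coverage_table(sigmas, spec)
            table.to_csv(out / "coverage_table.tsv", sep="\t")
            return model, table

        model, cov_table = do_power()
        report.error_model_span = model.span
        report.coverage_table = {
            str(n): {c: float(v) for c, v in row.items()}
            for n, row in cov_table.iterrows()
        }

    # ---- gsea ------------------------------------------------------------
    if "gsea" in config.stages and truth is not None and corrected is not None:
        @stage("gsea")
        def do_gsea():
            # synthetic transcriptome-like ranked signature: ground-truth
            # fold changes plus unit noise, acting as the external dataset
            common = corrected.protein_ids.intersection(truth.true_log2fc.index)
            score = (
                2.5 * truth.true_log2fc.loc[common]
                + rng.normal(0.0, 1.0, size=len(common))
            )
            signature = gsea.RankedSignature.from_scores(score)
            res = diffstats.moderated_fit(
                corrected, metadata,
                diffstats.DesignSpec(
                    factors=("ighv_status", "wbc_class", "gender"),
                    contrast=("ighv_status", "UM", "M"),
                    fdr_threshold=config.fdr_threshold,
                ),
            )
            sig = res.table[res.table["significant"]]
            up = set(sig.index[sig["effect"] > 0])
            down = set(sig.index[sig["effect"] < 0])
            sets = []
            if up:
                sets.append(gsea.GeneSet("up_UM_combat_s", frozenset(up)))
            if down:
                sets.append(gsea.GeneSet("down_UM_combat_s", frozenset(down)))
            if not sets:
                return []
            results = gsea.gsea_multi(
                signature, sets, n_perm=config.gsea_n_perm, seed=config.seed
            )
            rows = [
                {
                    "set": r.set_name, "es": r.es, "nes": r.nes,
                    "p_value": r.p_value, "fdr": r.fdr,
                    "n_core_genes": len(r.core_genes),
                }
                for r in results
            ]
            pd.DataFrame(rows).to_csv(out / "gsea_results.tsv", sep="\t", index=False)
            return rows

        report.gsea = do_gsea()

    report.to_json(out / "run_report.json")
    return report
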