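"""End-to-end orchestration of the marker-coexpression analysis.

Stages: discover coexpression modules from seed markers, score every sample
against the modules, classify samples into marker subtypes, test
subtype-by-mutation and subtype-by-label associations, run preranked GSEA on
the marker correlation profiles, and fit per-subtype treatment survival
models.  Each stage writes reloadable TSV outputs plus a JSON manifest with
parameters and input checksums, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    association_stats,
    coexpression,
    io_formats,
    preranked_gsea,
    sample_scoring,
    survival_analysis,
    synthetic_data,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigurationError", "DataError", "run_discover",
           "run_score", "run_classify", "run_associate", "run_gsea",
           "run_survival", "run_all", "run_simulate"]

DEFAULT_MARKERS = ("PROM1", "CD44", "FUT4", "ITGA6", "L1CAM", "ALDH1A3")


class ConfigurationError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Input data violates a contract (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    expression: str | None = None
    gene_sets: str | None = None
    clinical: str | None = None
    mutations: str | None = None
    markers: tuple[str, ...] = DEFAULT_MARKERS
    sd_mult: float = 2.0
    fdr_max: float = 0.05
    positive_only: bool = True
    correlation_method: str = "pearson"
    tau: float = 1.0
    es_mode: str = "difference"
    classify_candidates: tuple[str, ...] = ()  # default: first two markers
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_weight: float = 1.0
    survival_covariates: tuple[str, ...] = survival_analysis.DEFAULT_COVARIATES
    rng_seed: int = 0
    output_dir: str = "coexsig_out"
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
        version = raw.pop("schema_version", 1)
        if version != 1:
            raise ConfigurationError(f"unsupported config schema_version {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("markers", "classify_candidates", "survival_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(schema_version=version, **raw)

    def candidates(self) -> tuple[str, ...]:
        return self.classify_candidates or self.markers[:2]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = outdir / "manifest.json"
        self.data: dict = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in config.__dict__.items()},
            "inputs": {},
            "stages": {},
        }
        for key in ("expression", "gene_sets", "clinical", "mutations"):
            p = getattr(config, key)
            if p and Path(p).exists():
                self.data["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    def record(self, stage: str, outputs: Sequence[Path], t0: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "wall_seconds": round(time.time() - t0, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _load_expression(config: PipelineConfig) -> pd.DataFrame:
    if not config.expression:
        raise ConfigurationError("no expression matrix configured")
    try:
        matrix = io_formats.read_expression(config.expression)
    except FileNotFoundError as exc:
        raise ConfigurationError(f"expression file not found: {exc}") from exc
    except io_formats.FormatError as exc:
        raise DataError(str(exc)) from exc
    return matrix


def run_simulate(config: PipelineConfig, sim: synthetic_data.SimulationConfig | None = None
                 ) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the pipeline's own formats."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim is None:
        # demonstration cohort: two marker programs, a radiotherapy benefit
        # confined to the CD133-like subtype, and a subtype-enriched mutation
        sim = synthetic_data.two_program_config(rng_seed=config.rng_seed)
        sim.survival.treatment_log_hr = {("A", "radiotherapy"): -1.25}
        sim.mutation = {"IDH1": {"A": 0.35, "B": 0.04}}
        sim.gcimp_subtype = "A"
    matrix, clinical, mutations, truth = synthetic_data.simulate_cohort(sim)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "mutations": outdir / "mutations.tsv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_expression(matrix, paths["expression"])
    io_formats.write_clinical(clinical, paths["clinical"])
    mutations.index.name = "gene"
    mutations.to_csv(paths["mutations"], sep="\t", lineterminator="\n")
    paths["truth"].write_text(json.dumps(
        {"sample_subtype": truth.sample_subtype,
         "module_membership": truth.module_membership}, indent=2))
    return paths


def run_discover(config: PipelineConfig) -> list[coexpression.CoexpressionModule]:
    """Correlate each marker seed with the matrix and select its module."""
    matrix = _load_expression(config)
    matrix = io_formats.collapse_duplicate_genes(matrix)
    absent = [m for m in config.markers if m not in matrix.index]
    if absent:
        raise DataError(f"marker seed gene(s) absent from the matrix: {absent}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    t0 = time.time()
    modules, outputs = [], []
    for marker in config.markers:
        profile = coexpression.correlate_with_seed(
            matrix, marker, method=config.correlation_method
        )
        module = coexpression.select_module(
            profile, sd_mult=config.sd_mult, fdr_max=config.fdr_max,
            positive_only=config.positive_only,
        )
        modules.append(module)
        ppath = outdir / f"profile_{marker}.tsv"
        out = profile.table.copy()
        out.index.name = "gene"
        out.to_csv(ppath, sep="\t", lineterminator="\n", float_format="%.10g")
        outputs.append(ppath)
    mpath = outdir / "modules.tsv"
    coexpression.write_modules(modules, mpath)
    outputs += [mpath, Path(str(mpath) + ".json")]
    manifest.record("discover", outputs, t0)
    return modules


def run_score(config: PipelineConfig,
              modules: Sequence[coexpression.CoexpressionModule] | None = None
              ) -> pd.DataFrame:
    """Score all samples against discovered modules (plus any GMT sets)."""
    matrix = _load_expression(config)
    matrix = io_formats.collapse_duplicate_genes(matrix)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if modules is None:
        mpath = outdir / "modules.tsv"
        if not mpath.exists():
            raise ConfigurationError("no modules given and no saved modules.tsv; run discover first")
        modules = coexpression.read_modules(mpath)
    coll = io_formats.GeneSetCollection.from_dict(
        {m.marker: m.genes for m in modules if m.genes}
    )
    if config.gene_sets:
        for gs in io_formats.read_gmt(config.gene_sets):
            if gs.name not in coll:
                coll.add(gs)
    t0 = time.time()
    scores = sample_scoring.score_samples(
        matrix, coll, tau=config.tau, es_mode=config.es_mode
    )
    spath = outdir / "scores.tsv"
    scores.index.name = "set"
    scores.to_csv(spath, sep="\t", lineterminator="\n", float_format="%.10g")
    _Manifest(outdir, config).record("score", [spath], t0)
    return scores


def run_classify(config: PipelineConfig, scores: pd.DataFrame | None = None
                 ) -> sample_scoring.SubtypeCall:
    outdir = Path(config.output_dir)
    if scores is None:
        spath = outdir / "scores.tsv"
        if not spath.exists():
            raise ConfigurationError("no scores given and no saved scores.tsv; run score first")
        scores = pd.read_csv(spath, sep="\t", index_col=0)
    t0 = time.time()
    call = sample_scoring.classify(scores, config.candidates())
    cpath = outdir / "subtype_calls.tsv"
    call.table.to_csv(cpath, sep="\t", lineterminator="\n", float_format="%.10g")
    _Manifest(outdir, config).record("classify", [cpath], t0)
    return call


def run_associate(config: PipelineConfig, call: sample_scoring.SubtypeCall
                  ) -> pd.DataFrame:
    """Association tests of the subtype call against mutations and labels.

    Per mutated gene: Fisher's exact test of mutation x called subtype.
    If the clinical table carries a ``subtype`` column, each label's split
    across the call is tested with a binomial test.  BH-FDR across all rows.
    """
    rows = []
    labels = call.labels
    first, second = call.candidates[:2]
    if config.mutations:
        mut = pd.read_csv(config.mutations, sep="\t", index_col=0)
        common = [s for s in labels.index if s in mut.columns]
        if not common:
            raise DataError("mutation table shares no samples with the score matrix")
        for gene in mut.index:
            m = mut.loc[gene, common].astype(int)
            lab = labels.loc[common]
            a = int(((m == 1) & (lab == first)).sum())
            b = int(((m == 1) & (lab == second)).sum())
            c = int(((m == 0) & (lab == first)).sum())
            d = int(((m == 0) & (lab == second)).sum())
            res = association_stats.fisher_exact([[a, b], [c, d]])
            rows.append({"test": "fisher_mutation", "item": gene,
                         "statistic": res.statistic, "effect": res.effect,
                         "or_cmle": res.extra.get("or_cmle"), "p": res.p})
    if config.clinical:
        clin = io_formats.read_clinical(config.clinical)
        if "subtype" in clin.columns:
            common = [s for s in labels.index if s in clin.index]
            for lab_value in sorted(clin.loc[common, "subtype"].dropna().unique()):
                sel = clin.loc[common, "subtype"] == lab_value
                k = int((labels.loc[common][sel.to_numpy()] == first).sum())
                n = int(sel.sum())
                if n == 0:
                    continue
                rows.append({"test": "binomial_split", "item": str(lab_value),
                             "statistic": k, "effect": k / n,
                             "or_cmle": np.nan, "p": association_stats.binomial_test(k, n)})
    if not rows:
        raise ConfigurationError("associate stage needs a mutation table or labelled clinical data")
    out = pd.DataFrame(rows)
    out["q"] = association_stats.bh_fdr(out["p"].to_numpy())
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    apath = outdir / "associations.tsv"
    out.to_csv(apath, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    _Manifest(outdir, config).record("associate", [apath], time.time())
    return out


def run_gsea(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Preranked GSEA of each marker's correlation profile against the GMT sets."""
    if not config.gene_sets:
        raise ConfigurationError("gsea stage requires a gene_sets GMT file")
    matrix = io_formats.collapse_duplicate_genes(_load_expression(config))
    sets = io_formats.read_gmt(config.gene_sets)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    t0 = time.time()
    outputs = []
    for i, marker in enumerate(config.markers):
        if marker not in matrix.index:
            raise DataError(f"marker {marker!r} absent from the matrix")
        profile = coexpression.correlate_with_seed(
            matrix, marker, method=config.correlation_method
        )
        ranked = preranked_gsea.make_ranked_list(
            profile.table["r"], source=f"{config.correlation_method} r with {marker}"
        )
        res = preranked_gsea.gsea_preranked(
            ranked, sets, n_perm=config.gsea_n_perm,
            seed=config.rng_seed + i,
            weight_exponent=config.gsea_weight,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
        )
        results[marker] = res
        gpath = outdir / f"gsea_{marker}.tsv"
        res.to_csv(gpath, sep="\t", lineterminator="\n", float_format="%.6g")
        outputs.append(gpath)
    _Manifest(outdir, config).record("gsea", outputs, t0)
    return results


def run_survival(config: PipelineConfig, call: sample_scoring.SubtypeCall | None
                 ) -> pd.DataFrame:
    """KM + log-rank between called subtypes and per-subtype Cox treatment HRs."""
    if not config.clinical:
        raise ConfigurationError("survival stage requires a clinical table")
    clin = io_formats.read_clinical(config.clinical)
    if call is not None:
        common = [s for s in call.labels.index if s in clin.index]
        if not common:
            raise DataError("clinical table shares no samples with the subtype calls")
        clin = clin.loc[common].copy()
        clin["subtype"] = call.labels.loc[common]
    elif "subtype" not in clin.columns:
        raise DataError("no subtype calls supplied and clinical table lacks 'subtype'")

    covs = [c for c in config.survival_covariates if c in clin.columns]
    if not covs:
        raise DataError("clinical table has none of the configured survival covariates")
    groups = [
        (grp["time"].to_numpy(), grp["event"].to_numpy())
        for _, grp in clin.groupby("subtype", sort=True)
    ]
    lr = survival_analysis.logrank_test(groups)
    report, fits = survival_analysis.subtype_treatment_analysis(
        clin, covariates=covs,
        treatments=[t for t in ("radiotherapy", "temozolomide") if t in covs],
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rpath = outdir / "treatment_hr.tsv"
    report.to_csv(rpath, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    lpath = outdir / "logrank.json"
    lpath.write_text(json.dumps(
        {"statistic": lr.statistic, "p": lr.p, "df": lr.extra["df"],
         "group_sizes": list(lr.n)}, indent=2))
    _Manifest(outdir, config).record("survival", [rpath, lpath], t0)
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run every configured stage; stage failures halt with the stage name."""
    report: dict = {}
    stage = "discover"
    try:
        modules = run_discover(config)
        report["modules"] = {m.marker: len(m) for m in modules}
        stage = "score"
        scores = run_score(config, modules)
        report["n_sets_scored"] = int(scores.shape[0])
        stage = "classify"
        call = run_classify(config, scores)
        report["label_counts"] = call.labels.value_counts().to_dict()
        if config.mutations or config.clinical:
            stage = "associate"
            try:
                assoc = run_associate(config, call)
                report["n_association_tests"] = int(len(assoc))
            except ConfigurationError as exc:
                logger.info("associate stage skipped: %s", exc)
        if config.gene_sets:
            stage = "gsea"
            gsea = run_gsea(config)
            report["gsea_top"] = {
                m: res.index[0] if len(res) else None for m, res in gsea.items()
            }
        if config.clinical:
            stage = "survival"
            surv = run_survival(config, call)
            report["treatment_hr"] = surv.to_dict(orient="records")
        else:
            logger.info("no clinical file configured; survival stage skipped")
    except (ConfigurationError, DataError):
        raise
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    outdir = Path(config.output_dir)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
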