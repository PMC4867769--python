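"""End-to-end orchestration: simulate -> qc -> normalize -> dmp ->
specificity -> longitudinal -> enrich -> meta, as one reproducible run.

``run_pipeline`` executes the stages in dependency order into a plain output
directory, stamps every table with the tool version and seed, logs stage
timings, and writes a manifest listing every file with its SHA-256 checksum
and the configuration hash.  Re-running with the same configuration
reproduces byte-identical result tables.  Any stage failure aborts the run
with a machine-readable error record naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import core_io
from .comparisons import LongitudinalModel, SpecificityModel
from .dmp import DiscordantPairModel
from .enrichment import GeneSetEnrichment
from .meta import FixedEffectsMeta
from .preprocess import (
    compute_beta,
    confirm_monozygosity,
    dasen_normalize,
    filter_probes,
    filter_samples,
)
from .simulate import (
    SimulationConfig,
    simulate_brain_cohorts,
    simulate_gene_sets,
    simulate_intensities,
    simulate_twin_methylome,
)

log = logging.getLogger("twinmeth")


@dataclass
class RunConfig:
    """All tuning constants of one pipeline run."""

    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection_p_threshold: float = 0.05
    fail_fraction: float = 0.05
    min_beads: int = 3
    fail_on_high_detection_p: bool = True
    primary_threshold: float = 5e-5
    extended_threshold: float = 1e-3
    enrichment_de_threshold: float = 1e-3
    n_perm_discovery: int = 10000
    n_perm_specificity: int = 1000
    covariates: tuple[str, ...] = ("internalizing", "externalizing", "depression")
    n_specificity_probes: int = 10
    candidate_n_tests: int | None = None
    brain_effect_size: float = -0.021
    n_gene_sets: int = 50
    beta_offset: float = 100.0
    normalize_intensities: bool = True
    sep: str = "\t"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        self.sim = replace(self.sim, seed=self.seed)
        for name, lo, hi in (
            ("detection_p_threshold", 0.0, 1.0),
            ("fail_fraction", 0.0, 1.0),
            ("primary_threshold", 0.0, 1.0),
            ("extended_threshold", 0.0, 1.0),
            ("enrichment_de_threshold", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not lo < value <= hi:
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        if "covariates" in payload:
            payload["covariates"] = tuple(payload["covariates"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages into ``out_dir``; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "error.json").unlink(missing_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    seed, sep = config.seed, config.sep
    timings: dict[str, float] = {}
    current_stage = "setup"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s started", name)
        timings[name] = time.perf_counter()

    def done() -> None:
        timings[current_stage] = time.perf_counter() - timings[current_stage]
        log.info("stage %s finished in %.2fs", current_stage, timings[current_stage])

    try:
        # ---------------- simulate ---------------------------------------
        stage("simulate")
        study = simulate_twin_methylome(config.sim)
        gene_sets = simulate_gene_sets(study.annotation, n_sets=config.n_gene_sets, seed=seed)
        core_io.write_beta_matrix(study.beta_age10, out / "beta_age10.tsv", sep, seed)
        core_io.write_beta_matrix(study.beta_age5, out / "beta_age5.tsv", sep, seed)
        core_io.write_design(study.design, out / "design.tsv", sep, seed)
        core_io.write_probe_annotation(study.annotation, out / "annotation.tsv", sep, seed)
        core_io.write_qc_metrics(
            study.qc_age10, out / "detection_p_age10.tsv", out / "bead_count_age10.tsv", sep, seed
        )
        core_io.write_gene_sets(gene_sets, out / "gene_sets.gmt")
        truth = study.truth.copy()
        with open(out / "truth.tsv", "w") as fh:
            fh.write(core_io.tool_stamp(seed) + "\n")
            truth.to_csv(fh, sep=sep, na_rep="NA")
        done()

        # ---------------- qc ----------------------------------------------
        stage("qc")
        snp_ids = study.snp_control_probe_ids
        zygosity = confirm_monozygosity(
            study.beta_age10.subset(probes=snp_ids), study.design, age_wave=10
        )
        zygosity.to_csv(out / "zygosity.tsv", sep=sep)
        sample_report10 = filter_samples(
            study.qc_age10,
            study.design.wave(10),
            config.detection_p_threshold,
            config.fail_fraction,
            config.min_beads,
            config.fail_on_high_detection_p,
        )
        design10 = study.design.wave(10).subset_samples(sample_report10.retained_samples)
        beta10 = study.beta_age10.subset(samples=list(design10.frame["sample_id"]))
        probe_report = filter_probes(study.annotation, beta10)
        retained_probes = probe_report.retained_probes
        sample_report5 = filter_samples(
            study.qc_age5,
            study.design.wave(5),
            config.detection_p_threshold,
            config.fail_fraction,
            config.min_beads,
            config.fail_on_high_detection_p,
        )
        design5 = study.design.wave(5).subset_samples(sample_report5.retained_samples)
        core_io.write_json_record(
            {
                "age10_samples": sample_report10.to_dict(),
                "age5_samples": sample_report5.to_dict(),
                "probes": probe_report.to_dict(),
            },
            out / "filter_report.json",
            seed,
        )
        done()

        # ---------------- normalize --------------------------------------
        stage("normalize")
        def normalized(beta_raw, design_w, wave_name):
            samples = list(design_w.frame["sample_id"])
            raw = beta_raw.subset(samples=samples)
            if config.normalize_intensities and len(samples) >= 2:
                intens = simulate_intensities(raw, study.annotation, seed)
                intens = dasen_normalize(intens, study.annotation)
                norm = compute_beta(intens, offset=config.beta_offset)
            else:
                norm = raw
            return norm.subset(probes=retained_probes)

        beta10_n = normalized(study.beta_age10, design10, "age10")
        beta5_n = normalized(study.beta_age5, design5, "age5") if len(design5.frame) else None
        core_io.write_beta_matrix(beta10_n, out / "beta_age10_normalized.tsv", sep, seed)
        if beta5_n is not None:
            core_io.write_beta_matrix(beta5_n, out / "beta_age5_normalized.tsv", sep, seed)
        done()

        # ---------------- dmp ---------------------------------------------
        stage("dmp")
        def scan(beta_n, design_w, wave):
            model = DiscordantPairModel(beta_n, design_w, age_wave=wave)
            res = model.fit(config.primary_threshold, config.extended_threshold)
            res.add_empirical_p(n_perm=config.n_perm_discovery, seed=seed)
            return res

        res10 = scan(beta10_n, design10, 10)
        res5 = scan(beta5_n, design5, 5) if beta5_n is not None else None

        def discovery_table(res, other):
            table = res.table.copy()
            if other is not None:
                cross = other.table[["delta_beta", "p_value"]].rename(
                    columns={"delta_beta": "other_wave_delta_beta", "p_value": "other_wave_p_value"}
                )
                table = table.join(cross, how="left")
            ann = study.annotation.frame.loc[table.index]
            table["chromosome"] = ann["chromosome"]
            table["position"] = ann["position"]
            table["gene_annotation"] = [";".join(g) for g in ann["gene_labels"]]
            table["probe_type"] = ann["design_type"]
            return table

        table10 = discovery_table(res10, res5)
        with open(out / "dmp_age10.tsv", "w") as fh:
            fh.write(core_io.tool_stamp(seed) + "\n")
            table10.head(5000).to_csv(fh, sep=sep, na_rep="NA")
        with open(out / "dmp_age10_top.tsv", "w") as fh:
            fh.write(core_io.tool_stamp(seed) + "\n")
            discovery_table(res10, res5).loc[res10.primary.index].to_csv(fh, sep=sep, na_rep="NA")
        res10.qq_table.to_csv(out / "qq_age10.tsv", sep=sep, index=False)
        core_io.write_json_record(
            {"lambda": res10.inflation_lambda}, out / "inflation_age10.json", seed
        )
        if res5 is not None:
            with open(out / "dmp_age5_top.tsv", "w") as fh:
                fh.write(core_io.tool_stamp(seed) + "\n")
                discovery_table(res5, res10).loc[res5.primary.index].to_csv(fh, sep=sep, na_rep="NA")

        # covariate-adjusted re-test of the candidate probes
        candidates = list(res10.primary.index)
        if candidates and len(config.covariates):
            adj_model = DiscordantPairModel(
                beta10_n.subset(probes=candidates),
                design10,
                age_wave=10,
                covariates=list(config.covariates),
            )
            adj = adj_model.fit(config.primary_threshold, config.extended_threshold)
            with open(out / "dmp_age10_adjusted.tsv", "w") as fh:
                fh.write(core_io.tool_stamp(seed) + "\n")
                adj.table.to_csv(fh, sep=sep, na_rep="NA")
        done()

        # ---------------- specificity -------------------------------------
        stage("specificity")
        spec_probes = candidates[: config.n_specificity_probes] or list(
            res10.table.index[: config.n_specificity_probes]
        )
        spec = SpecificityModel(beta10_n, design10, spec_probes, age_wave=10).fit(
            n_perm=config.n_perm_specificity, seed=seed
        )
        with open(out / "specificity.tsv", "w") as fh:
            fh.write(core_io.tool_stamp(seed) + "\n")
            spec.table.to_csv(fh, sep=sep, na_rep="NA")
        done()

        # ---------------- longitudinal -------------------------------------
        stage("longitudinal")
        longitudinal = None
        if beta5_n is not None:
            longitudinal = LongitudinalModel(beta5_n, beta10_n, study.design).fit(
                config.primary_threshold
            )
            with open(out / "longitudinal.tsv", "w") as fh:
                fh.write(core_io.tool_stamp(seed) + "\n")
                longitudinal.table.head(5000).to_csv(fh, sep=sep, na_rep="NA")
            with open(out / "longitudinal_top.tsv", "w") as fh:
                fh.write(core_io.tool_stamp(seed) + "\n")
                longitudinal.top.to_csv(fh, sep=sep, na_rep="NA")
        done()

        # ---------------- enrichment ---------------------------------------
        stage("enrich")
        de_probes = list(
            res10.table.index[res10.table["p_value"] < config.enrichment_de_threshold]
        )
        enrichment = None
        if de_probes:
            try:
                enrichment = GeneSetEnrichment(
                    study.annotation, retained_probes, de_probes, gene_sets
                ).fit()
                with open(out / "enrichment.tsv", "w") as fh:
                    fh.write(core_io.tool_stamp(seed) + "\n")
                    enrichment.table.to_csv(fh, sep=sep, na_rep="NA")
            except ValueError as err:
                log.warning("enrichment skipped: %s", err)
        done()

        # ---------------- meta replication ---------------------------------
        stage("meta")
        meta_results = None
        if candidates:
            top_probe = candidates[0]
            summaries = simulate_brain_cohorts(
                candidates,
                effect_probe=top_probe,
                effect_size=config.brain_effect_size,
                seed=seed,
                cohort_ids=("brainbank1", "brainbank2"),
            )
            core_io.write_cohort_summaries(summaries, out / "brain_cohort_summaries.tsv", sep, seed)
            meta_results = FixedEffectsMeta(
                summaries, candidates, n_tests=config.candidate_n_tests
            ).fit()
            with open(out / "meta_replication.tsv", "w") as fh:
                fh.write(core_io.tool_stamp(seed) + "\n")
                meta_results.table.to_csv(fh, sep=sep, na_rep="NA")
            meta_results.forest_frame(top_probe).to_csv(out / "forest_top_probe.tsv", sep=sep, index=False)
            core_io.write_json_record(
                {p: asdict(r) for p, r in meta_results.per_probe.items()},
                out / "meta_replication.json",
                seed,
            )
        done()

        # ---------------- manifest -----------------------------------------
        stage("manifest")
        config.to_yaml(out / "config.yaml")
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name not in {"manifest.json", "run.log"}
        )
        manifest = {
            "tool": f"twinmeth {core_io.__version__}",
            "seed": seed,
            "config_hash": config.digest(),
            "timings_s": {k: round(v, 3) for k, v in timings.items() if k != "manifest"},
            "files": {p.name: _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
            fh.write("\n")
        done()
        return manifest
    except Exception as err:  # noqa: BLE001 - error record then re-raise
        record = {"stage": current_stage, "error": type(err).__name__, "message": str(err)}
        with open(out / "error.json", "w") as fh:
            json.dump(record, fh, indent=1)
        log.error("stage %s failed: %s", current_stage, err)
        raise StageError(current_stage, err) from err
    finally:
        log.removeHandler(handler)
        handler.close()
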