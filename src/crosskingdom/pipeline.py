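"""End-to-end orchestration: simulate or load tables, filter, run diversity,
the differential-abundance screen, both association networks, and the panel
classifier, writing TSV outputs plus a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from crosskingdom import __version__
from crosskingdom import diversity, lefse, networks, classifier, simulate, table_io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, seeds, and input locations in one place."""

    out_dir: str = "pipeline_out"
    # input: either a scenario name ("default" | "null") or explicit paths
    scenario: str | None = "default"
    bact_table: str | None = None
    fungi_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    group_column: str = "group"
    case_group: str | None = None          # defaults to first level alphabetically
    reference_group: str | None = None     # defaults to the other level
    major_genus_threshold: float = 0.01
    within_prevalence: float = 0.5
    inter_prevalence: float = 0.2
    alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    beta_metric: str = "bray_curtis"
    n_perm_beta: int = 999
    n_perm_dcor: int = 199
    n_bootstrap_auc: int = 500
    seed: int = 0

    def validate(self) -> None:
        for name, value in (("major_genus_threshold", self.major_genus_threshold),
                            ("within_prevalence", self.within_prevalence),
                            ("inter_prevalence", self.inter_prevalence),
                            ("alpha", self.alpha)):
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        if self.lda_threshold < 0:
            raise ValueError("lda_threshold must be non-negative")
        if self.scenario is None:
            missing = [n for n, v in (("bact_table", self.bact_table),
                                      ("fungi_table", self.fungi_table),
                                      ("metadata", self.metadata)) if v is None]
            if missing:
                raise ValueError(f"no scenario and missing inputs: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        factory = {"default": simulate.default_scenario,
                   "null": simulate.null_scenario}.get(config.scenario)
        if factory is None:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        scenario = factory(seed=config.seed)
        bact, fungi, meta, truth = simulate.simulate_tables(scenario)
        return bact, fungi, meta, truth
    bact = table_io.read_table(config.bact_table, kingdom="bacteria")
    fungi = table_io.read_table(config.fungi_table, kingdom="fungi")
    meta = table_io.read_metadata(config.metadata, config.group_column)
    return bact, fungi, meta, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts the run, reporting the stage name, and removes
    the partially written output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    timings: dict[str, float] = {}
    manifest: dict = {"version": __version__, "config": asdict(config), "outputs": {}}
    try:
        t0 = time.perf_counter()
        stage = "load"
        bact, fungi, meta, truth = _load_inputs(config)
        meta.validate_two_groups()
        levels = meta.group_levels()
        case = config.case_group or levels[0]
        reference = config.reference_group or next(lv for lv in levels if lv != case)
        bact, fungi, meta = table_io.align_kingdoms(bact, fungi, meta)
        timings[stage] = time.perf_counter() - t0

        def _write(name: str, frame: pd.DataFrame, index=True):
            path = out / name
            frame.to_csv(path, sep="\t", index=index)
            manifest["outputs"][name] = _sha256(path)

        stage = "tables"
        t0 = time.perf_counter()
        table_io.write_table(bact, out / "bacteria_counts.tsv")
        table_io.write_table(fungi, out / "fungi_counts.tsv")
        table_io.write_metadata(meta, out / "metadata.tsv")
        for name in ("bacteria_counts.tsv", "fungi_counts.tsv", "metadata.tsv"):
            manifest["outputs"][name] = _sha256(out / name)
        timings[stage] = time.perf_counter() - t0

        stage = "alpha_diversity"
        t0 = time.perf_counter()
        for label, table in (("bacteria", bact), ("fungi", fungi)):
            res = diversity.alpha_indices(table, meta)
            _write(f"alpha_{label}.tsv", res.values)
            _write(f"alpha_{label}_pvalues.tsv",
                   pd.DataFrame({"p": pd.Series(res.p_values)}))
        timings[stage] = time.perf_counter() - t0

        stage = "beta_diversity"
        t0 = time.perf_counter()
        for label, table in (("bacteria", bact), ("fungi", fungi)):
            res = diversity.beta_distance(table, metric=config.beta_metric, meta=meta,
                                          n_perm=config.n_perm_beta, seed=config.seed)
            diversity.write_distance_matrix(res, out / f"beta_{label}.tsv")
            manifest["outputs"][f"beta_{label}.tsv"] = _sha256(out / f"beta_{label}.tsv")
            _write(f"pcoa_{label}.tsv", res.pcoa_coordinates)
            manifest.setdefault("beta_tests", {})[label] = {
                "metric": config.beta_metric,
                "pseudo_F": res.test_statistic,
                "p": res.p_value,
            }
        timings[stage] = time.perf_counter() - t0

        stage = "differential_abundance"
        t0 = time.perf_counter()
        reports = []
        for table in (bact, fungi):
            features = lefse.run_lefse(table, meta, reference_group=reference,
                                       alpha=config.alpha,
                                       lda_threshold=config.lda_threshold,
                                       n_boot=config.n_boot, seed=config.seed)
            reports.append(lefse.report_frame(features))
        _write("lefse_report.tsv", pd.concat(reports, ignore_index=True), index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "networks"
        t0 = time.perf_counter()
        net_rows = {}
        for group in (case, reference):
            keep = meta.groups[meta.groups == group].index
            b_g = table_io.filter_prevalence(bact.select_samples(keep),
                                             config.within_prevalence)
            net_within = networks.spearman_edges(
                table_io.relative_abundance(b_g), alpha=config.alpha,
                group_label=group, prevalence=config.within_prevalence)
            networks.write_edges(net_within, out / f"network_bacteria_{group}.tsv")
            manifest["outputs"][f"network_bacteria_{group}.tsv"] = _sha256(
                out / f"network_bacteria_{group}.tsv")

            b_i = table_io.filter_prevalence(bact.select_samples(keep),
                                             config.inter_prevalence)
            f_i = table_io.filter_prevalence(fungi.select_samples(keep),
                                             config.inter_prevalence)
            net_inter = networks.dcor_edges(
                table_io.relative_abundance(b_i), table_io.relative_abundance(f_i),
                alpha=config.alpha, n_perm=config.n_perm_dcor, seed=config.seed,
                group_label=group, prevalence=config.inter_prevalence)
            networks.write_edges(net_inter, out / f"network_interkingdom_{group}.tsv")
            manifest["outputs"][f"network_interkingdom_{group}.tsv"] = _sha256(
                out / f"network_interkingdom_{group}.tsv")
            net_rows[group] = {"within": networks.network_stats(net_within),
                               "inter": networks.network_stats(net_inter)}
        manifest["network_stats"] = net_rows
        timings[stage] = time.perf_counter() - t0

        stage = "classifier"
        t0 = time.perf_counter()
        results = []
        for panel_name in ("bacterial4", "fungal4", "combined8"):
            panel = classifier.PANEL_PRESETS[panel_name]
            try:
                res = classifier.fit_panel(bact, fungi, meta, panel,
                                           case_group=case,
                                           n_bootstrap=config.n_bootstrap_auc,
                                           seed=config.seed)
            except KeyError:
                logger.warning("panel %s not resolvable in the tables; skipped",
                               panel_name)
                continue
            results.append(res)
        if results:
            _write("classifier.tsv", classifier.compare_panels(results))
        timings[stage] = time.perf_counter() - t0

        manifest["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
        manifest["manifest_hash"] = _hash_manifest(manifest)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _hash_manifest(manifest: dict) -> str:
    payload = {k: v for k, v in manifest.items() if k not in ("timings_s", "manifest_hash")}
    # the output location is not part of the result identity
    payload["config"] = {k: v for k, v in payload["config"].items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
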