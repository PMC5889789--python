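"""End-to-end orchestration: simulate/load -> cluster -> contrast -> PLS.

A single :class:`RunConfig` drives the full analysis in the order of the
behavioral study: validity filtering, age residualization, child-by-child
correlation network, consensus community detection, group contrasts and
diagnosis enrichment, the bootstrap homogeneity statistic against the
diagnosis-based grouping, and (when connectome data are configured) the
node-degree PLS analysis.  Every stochastic stage derives its seed from the
global seed, so a config and seed fully determine the report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .community import consensus_cluster
from .network import build_network, write_network_tsv
from .pls import (
    bootstrap_loadings,
    compare_group_scores,
    crossval_rmse,
    evaluate_split,
    fit_pls,
    node_degree,
    retain_components,
    top_loading_report,
)
from .preprocess import filter_validity, residualize_age
from .stats import (
    contrast_groups,
    contrasts_frame,
    diagnosis_enrichment,
    diagnosis_partition,
    homogeneity_bootstrap,
)
from .synthetic import CohortSpec, ConnectomeSpec, generate_cohort, generate_connectomes

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``cohort_path`` (a cohort CSV) or ``simulate_cohort=True`` must
    be set; connectome analysis runs when ``connectome_manifest`` is given
    or ``simulate_connectomes`` is set.
    """

    out_dir: str = "efsubtype_run"
    seed: int = 0
    # inputs
    cohort_path: str | None = None
    simulate_cohort: bool = True
    n_per_group: int = 150
    connectome_manifest: str | None = None
    simulate_connectomes: bool = False
    # preprocessing
    exclude_negative: bool = True
    # network + clustering
    correlation_method: str = "pearson"
    runs_per_round: int = 100
    tau: float = 0.3
    max_rounds: int = 50
    # stats
    homogeneity_reps: int = 1000
    subsample_m: int | None = None
    # PLS
    max_components: int = 3
    retention_floor: float = 5.0
    n_boot: int = 1000
    n_perm: int = 1000
    degree_threshold: float = 0.0
    train_frac: float = 0.6
    k_folds: int = 10
    # sensitivity reruns (with/without validity filter, half/quarter sample)
    sensitivity: bool = False
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        config = cls(**kwargs)
        config.extra = extra
        return config

    def validate(self) -> None:
        if self.cohort_path is None and not self.simulate_cohort:
            raise ValueError("either cohort_path or simulate_cohort is required")
        for attr in ("cohort_path", "connectome_manifest"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")


def _cluster_q(residuals, config, seed):
    net = build_network(residuals, method=config.correlation_method)
    result = consensus_cluster(
        net,
        runs=config.runs_per_round,
        tau=config.tau,
        seed=seed,
        max_rounds=config.max_rounds,
    )
    return net, result


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and return the run report.

    Intermediate artifacts (cohort, residuals, network, partition, result
    tables) are written under ``config.out_dir``; the report itself is
    saved as ``report.json`` there and returned as a dict.
    """
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        return _StageTimer(name, report)

    # --- cohort -----------------------------------------------------------
    with stage("cohort"):
        if config.cohort_path:
            cohort = io.read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(
                CohortSpec(
                    n_per_group=config.n_per_group,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            io.write_cohort(cohort, out / "cohort.csv")
        report["stages"]["cohort"]["n_children"] = len(cohort)

    # --- preprocess -------------------------------------------------------
    with stage("preprocess"):
        retained = filter_validity(cohort, exclude_negative=config.exclude_negative)
        residuals = residualize_age(retained)
        io.write_cohort(residuals, out / "residuals.csv")
        report["stages"]["preprocess"]["n_retained"] = len(retained)

    # --- network + clustering --------------------------------------------
    with stage("cluster"):
        net, consensus = _cluster_q(
            residuals, config, int(rng.integers(0, 2**31 - 1))
        )
        write_network_tsv(net, out / "network.tsv")
        partition = consensus.partition
        io.write_partition(net.node_ids, partition.labels, out / "partition.csv")
        report["stages"]["cluster"].update(
            {
                "q": partition.q_value,
                "n_communities": partition.n_communities,
                "sizes": partition.sizes().tolist(),
                "n_rounds": consensus.n_rounds,
            }
        )

    if partition.n_communities < 2:
        logger.warning("single community found; skipping group comparisons")
        io.write_json(report, out / "report.json")
        return report

    # --- contrasts + enrichment ------------------------------------------
    with stage("contrasts"):
        contrasts = contrast_groups(residuals, partition.labels)
        frame = contrasts_frame(contrasts)
        frame.to_csv(out / "contrasts.csv", index=False)
        report["stages"]["contrasts"]["n_significant"] = int(
            (frame["p_corrected"] < 0.05).sum()
        )
        if "diagnosis" in retained.columns:
            enrich = diagnosis_enrichment(
                partition.labels, retained["diagnosis"].to_numpy()
            )
            enrich.to_csv(out / "enrichment.csv", index=False)
            report["stages"]["contrasts"]["enrichment"] = enrich.to_dict("records")

    # --- homogeneity ------------------------------------------------------
    if "diagnosis" in retained.columns:
        with stage("homogeneity"):
            diag_part = diagnosis_partition(retained["diagnosis"].to_numpy())
            hom = homogeneity_bootstrap(
                residuals,
                partition.labels,
                diag_part,
                m=config.subsample_m,
                reps=config.homogeneity_reps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            report["stages"]["homogeneity"].update(
                {
                    "mean_diff": hom.mean_diff,
                    "se": hom.se,
                    "p_value": hom.p_value,
                    "subsample_size": hom.subsample_size,
                }
            )

    # --- sensitivity reruns ----------------------------------------------
    if config.sensitivity:
        with stage("sensitivity"):
            q_values = {"full": partition.q_value}
            alt = filter_validity(
                cohort, exclude_negative=not config.exclude_negative
            )
            _, alt_res = _cluster_q(
                residualize_age(alt), config, int(rng.integers(0, 2**31 - 1))
            )
            q_values["filter_toggled"] = alt_res.partition.q_value
            for name, frac in (("half", 0.5), ("quarter", 0.25)):
                idx = rng.choice(
                    len(residuals), size=max(10, int(frac * len(residuals))),
                    replace=False,
                )
                sub = residuals.iloc[np.sort(idx)].reset_index(drop=True)
                _, sub_res = _cluster_q(
                    sub, config, int(rng.integers(0, 2**31 - 1))
                )
                q_values[name] = sub_res.partition.q_value
            report["stages"]["sensitivity"].update(q_values)

    # --- connectome PLS ---------------------------------------------------
    if config.connectome_manifest or config.simulate_connectomes:
        with stage("pls"):
            if config.connectome_manifest:
                conn = io.read_connectomes(config.connectome_manifest)
            else:
                conn = generate_connectomes(
                    ConnectomeSpec(seed=int(rng.integers(0, 2**31 - 1)))
                )
                io.write_connectomes(conn, out / "connectomes")
            degrees = node_degree(conn, threshold=config.degree_threshold)
            x = degrees.to_numpy(dtype=float)
            model = fit_pls(x, conn.groups, max_components=config.max_components)
            n_retained = retain_components(
                model.y_explained, floor=config.retention_floor
            )
            rmse, rmse_null, p_perm = evaluate_split(
                x,
                conn.groups,
                train_frac=config.train_frac,
                n_perm=config.n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_components=config.max_components,
            )
            cv_mean, cv_se = crossval_rmse(
                x,
                conn.groups,
                k_folds=config.k_folds,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_components=config.max_components,
            )
            bsr = bootstrap_loadings(
                x,
                conn.groups,
                n_boot=config.n_boot,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_components=config.max_components,
                reference=model,
            )
            top = top_loading_report(bsr, conn.node_labels)
            top.to_csv(out / "pls_top_nodes.csv", index=False)
            score_tests = compare_group_scores(
                model.scores, conn.groups, n_components=max(n_retained, 1)
            )
            score_tests.to_csv(out / "pls_score_tests.csv", index=False)
            report["stages"]["pls"].update(
                {
                    "y_explained": model.y_explained.tolist(),
                    "n_retained": n_retained,
                    "rmse_test": rmse,
                    "rmse_null_mean": rmse_null,
                    "p_perm": p_perm,
                    "rmse_cv_mean": cv_mean,
                    "rmse_cv_se": cv_se,
                    "n_significant_nodes": int(top["significant"].sum()),
                }
            )

    io.write_json(report, out / "report.json")
    return report


class _StageTimer:
    def __init__(self, name, report):
        self.name = name
        self.report = report

    def __enter__(self):
        self.start = time.perf_counter()
        self.report["stages"][self.name] = {}
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report["stages"][self.name]["wall_time_s"] = round(
            time.perf_counter() - self.start, 3
        )
        if exc is not None:
            raise PipelineError(self.name, exc) from exc
        return False
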