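"""End-to-end orchestration and group comparisons.

``run_pipeline`` drives ingest -> pooling -> repertoire metrics ->
clone dynamics -> CDR3 clustering -> (optional) tumour metrics ->
responder vs non-responder comparisons, writing deterministic TSV
tables to an output directory.  All randomness (control draws for the
normalised cluster count, cohort simulation) flows from a single seed
through deterministically spawned child seeds, so identical inputs and
seed give byte-identical numeric outputs.

Group comparisons use the two-sided Mann-Whitney / Wilcoxon rank-sum
test, evaluated exactly (full enumeration over rank assignments) when
both groups have at most 12 members and by the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata, spearmanr

from . import clustering, dynamics, genomics, metrics
from .clustering import KernelConfig
from .dynamics import ExpansionConfig
from .io import Repertoire, load_cohort, pool_repertoires, read_manifest
from .simulate import CohortConfig, SimulatedCohort, simulate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float | None
    method: str


def exact_rank_sum_p(a: list[float], b: list[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p-value by full enumeration.

    Enumerates every assignment of the pooled midranks to group A and
    computes P(|S - E[S]| >= |s_obs - E[S]|) for the rank-sum statistic
    S.  Handles ties through midranks.  Returns (rank_sum, p).
    """
    na, nb = len(a), len(b)
    pooled = np.asarray(list(a) + list(b), dtype=float)
    ranks = rankdata(pooled)
    s_obs = ranks[:na].sum()
    expect = na * (na + nb + 1) / 2.0
    dev = abs(s_obs - expect)
    total = math.comb(na + nb, na)
    n_extreme = 0
    for combo in itertools.combinations(range(na + nb), na):
        s = ranks[list(combo)].sum()
        if abs(s - expect) >= dev - 1e-9:
            n_extreme += 1
    return float(s_obs), n_extreme / total


def group_compare(
    values_a: list[float], values_b: list[float], metric: str = "",
    exact_max_n: int = 12,
) -> GroupComparison:
    """Two-sided rank-sum comparison of one metric between two groups.

    Exact enumeration when both groups have <= ``exact_max_n`` members,
    tie-corrected normal approximation otherwise; the method used is
    recorded in the result.  Empty groups yield an undefined p-value.
    """
    a = [v for v in values_a if v is not None and not (isinstance(v, float) and math.isnan(v))]
    b = [v for v in values_b if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not a or not b:
        logger.info("group_compare(%s): empty group, p undefined", metric)
        return GroupComparison(
            metric=metric, n_a=len(a), n_b=len(b),
            median_a=float(np.median(a)) if a else float("nan"),
            median_b=float(np.median(b)) if b else float("nan"),
            statistic=float("nan"), p_value=None, method="undefined",
        )
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        stat, p = exact_rank_sum_p(a, b)
        method = "exact_enumeration"
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
        method = "normal_approx_tie_corrected"
    return GroupComparison(
        metric=metric, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        statistic=stat, p_value=p, method=method,
    )


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs.

    Exactly one of ``manifest`` (path to a samples manifest TSV) or
    ``cohort`` (simulation config) must be provided.  ``response`` maps
    patient_id to 'responder'/'nonresponder'; for simulated cohorts it
    is taken from the generator truth when omitted.
    """

    manifest: str | Path | None = None
    cohort: CohortConfig | None = None
    response: dict[str, str] | None = None
    expansion: ExpansionConfig = field(default_factory=ExpansionConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    key_mode: str = "auto"
    pair_key_mode: str = "full_key"
    n_controls: int = 10
    seed: int = 0
    out_dir: str | Path = "tcrdyn_out"
    mutations: str | Path | None = None
    segments: str | Path | None = None
    purity: float | None = None
    exome_mb: float | None = None

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.cohort is None):
            raise ValueError("provide exactly one of manifest or cohort")


@dataclass
class PipelineResult:
    sample_metrics: pd.DataFrame
    spatial: pd.DataFrame
    patient_summary: pd.DataFrame
    dynamics_calls: pd.DataFrame
    cluster_summary: pd.DataFrame
    comparisons: pd.DataFrame
    expansion_sweep: pd.DataFrame
    tumor_metrics: pd.DataFrame | None
    out_dir: Path


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: AnalysisConfig) -> PipelineResult:
    """Run the full repertoire-dynamics analysis and write report tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(cfg.seed)
    log_lines = [f"seed\t{cfg.seed}", f"key_mode\t{cfg.key_mode}",
                 f"expansion_threshold\t{cfg.expansion.freq_threshold}",
                 f"alpha\t{cfg.expansion.alpha}",
                 f"kernel_edge_threshold\t{cfg.kernel.edge_threshold}"]

    if cfg.cohort is not None:
        sim: SimulatedCohort = simulate_cohort(cfg.cohort)
        reps = sim.repertoires
        response = cfg.response or sim.response
        log_lines.append("input\tsimulated_cohort")
    else:
        manifest = read_manifest(cfg.manifest)
        reps = load_cohort(manifest, key_mode=cfg.key_mode)
        response = cfg.response or {}
        log_lines.append(f"input\t{cfg.manifest}")

    # ---- per-sample metrics and pooled repertoires -------------------
    sample_rows = []
    pooled: dict[tuple[str, str, str], Repertoire] = {}
    groups: dict[tuple[str, str, str], list[Repertoire]] = {}
    for rep in reps:
        m = rep.meta
        groups.setdefault((m.patient_id, m.timepoint, m.compartment), []).append(rep)
        c = metrics.clonality(rep)
        sample_rows.append(
            {
                "patient_id": m.patient_id, "timepoint": m.timepoint,
                "compartment": m.compartment, "region_id": m.region_id,
                "n_clones": rep.n_clones, "total_umi": rep.total_umi,
                "clonality": c.value, "entropy_nats": c.entropy_nats,
            }
        )
    for key in sorted(groups):
        pooled[key] = pool_repertoires(groups[key])
        c = metrics.clonality(pooled[key])
        sample_rows.append(
            {
                "patient_id": key[0], "timepoint": key[1], "compartment": key[2],
                "region_id": "pooled", "n_clones": pooled[key].n_clones,
                "total_umi": pooled[key].total_umi,
                "clonality": c.value, "entropy_nats": c.entropy_nats,
            }
        )
    sample_metrics = pd.DataFrame(sample_rows).sort_values(
        ["patient_id", "compartment", "timepoint", "region_id"]
    ).reset_index(drop=True)

    # ---- spatial similarity ------------------------------------------
    spatial_rows = []
    for key in sorted(groups):
        regions = sorted(groups[key], key=lambda r: r.meta.region_id)
        if len(regions) < 2:
            continue
        mat = metrics.spatial_similarity(regions, key_mode=cfg.pair_key_mode)
        for i, ra in enumerate(mat.index):
            for rb in mat.columns[i + 1:]:
                spatial_rows.append(
                    {
                        "patient_id": key[0], "timepoint": key[1], "compartment": key[2],
                        "region_a": ra, "region_b": rb,
                        "cosine": mat.loc[ra, rb],
                    }
                )
    spatial = pd.DataFrame(
        spatial_rows,
        columns=["patient_id", "timepoint", "compartment", "region_a", "region_b", "cosine"],
    )

    # ---- expansion sweep vs clonality --------------------------------
    sweep_thresholds = [0.0005, 0.001, 0.002, 0.005, 0.01]
    sweep_rows = []
    for key in sorted(pooled):
        rep = pooled[key]
        sw = dynamics.expanded_mass_sweep(rep, sweep_thresholds)
        sw.insert(0, "patient_id", key[0])
        sw.insert(1, "timepoint", key[1])
        sw.insert(2, "compartment", key[2])
        sw["clonality"] = metrics.clonality(rep).value
        sweep_rows.append(sw)
    expansion_sweep = pd.concat(sweep_rows, ignore_index=True)
    corr_rows = []
    for t in sweep_thresholds:
        sub = expansion_sweep[expansion_sweep["threshold"] == t]
        rho, p = spearmanr(sub["mass_fraction"], sub["clonality"])
        corr_rows.append({"threshold": t, "spearman_rho": float(rho), "p_value": float(p)})
    sweep_corr = pd.DataFrame(corr_rows)

    # ---- dynamics + fates + frequency ratio (tumour compartment) -----
    patients = sorted({m[0] for m in pooled})
    dyn_tables, summary_rows = [], []
    child_seeds = {p: s for p, s in zip(patients, rng_root.spawn(len(patients)))}
    cluster_rows = []
    for pid in patients:
        pre = pooled.get((pid, "pre", "tumor"))
        post = pooled.get((pid, "post", "tumor"))
        row: dict = {"patient_id": pid, "response": response.get(pid, "NA")}
        if pre is not None and post is not None:
            calls = dynamics.classify_dynamics(pre, post, cfg.expansion, cfg.pair_key_mode)
            calls.insert(0, "patient_id", pid)
            dyn_tables.append(calls)
            fates, fsum = dynamics.label_fates(pre, post, cfg.expansion)
            row.update(
                {k: v for k, v in fsum.items() if k != "patient_id"}
            )
            row["mean_frequency_ratio"] = dynamics.mean_frequency_ratio(
                pre, post, cfg.expansion
            )
            row["longitudinal_cosine"] = metrics.longitudinal_similarity(
                pre, post, key_mode=cfg.pair_key_mode
            ).value
            row["clonality_pre"] = metrics.clonality(pre).value
            row["clonality_post"] = metrics.clonality(post).value

            # CDR3 clustering on the pre-treatment pooled repertoire
            cdr3_of = pre.cdr3_of()
            rng = np.random.default_rng(child_seeds[pid])
            net = clustering.build_network(list(cdr3_of.values()), cfg.kernel)
            expanded_keys = dynamics.classify_expanded(pre, cfg.expansion)
            expanded_cdr3 = {cdr3_of[k] for k in expanded_keys}
            ncc = clustering.normalized_cluster_count(
                net, expanded_cdr3, n_controls=cfg.n_controls, seed=rng
            )
            fate_by_cdr3: dict[str, str] = {}
            for r in fates.itertuples(index=False):
                if r.fate in ("maintained", "replaced") and r.clone_key in cdr3_of:
                    fate_by_cdr3[cdr3_of[r.clone_key]] = r.fate
            props = clustering.fate_cluster_proportions(net, fate_by_cdr3)
            cluster_rows.append(
                {
                    "patient_id": pid, "response": response.get(pid, "NA"),
                    "n_nodes": len(net.nodes), "n_edges": len(net.edges),
                    "n_clusters": len(net.clusters),
                    "n_real": ncc.n_real, "n_control_mean": ncc.n_control_mean,
                    "normalized_cluster_count": ncc.ratio,
                    "prop_maintained_clustered": props["maintained"],
                    "prop_replaced_clustered": props["replaced"],
                }
            )
            row["normalized_cluster_count"] = ncc.ratio
        else:
            logger.info("patient %s: missing timepoint, longitudinal stages skipped", pid)
        summary_rows.append(row)
    dynamics_calls = (
        pd.concat(dyn_tables, ignore_index=True) if dyn_tables else pd.DataFrame()
    )
    patient_summary = pd.DataFrame(summary_rows)
    cluster_summary = pd.DataFrame(cluster_rows)

    # ---- group comparisons -------------------------------------------
    comparisons = pd.DataFrame()
    if response:
        comp_metrics = [
            "clonality_pre", "longitudinal_cosine", "prop_maintained",
            "mean_frequency_ratio", "normalized_cluster_count",
        ]
        comp_rows = []
        for metric_name in comp_metrics:
            if metric_name not in patient_summary.columns:
                continue
            sub = patient_summary[["patient_id", "response", metric_name]].dropna()
            a = sub.loc[sub["response"] == "responder", metric_name].tolist()
            b = sub.loc[sub["response"] == "nonresponder", metric_name].tolist()
            gc = group_compare(a, b, metric=metric_name)
            comp_rows.append(
                {
                    "metric": gc.metric, "n_responder": gc.n_a, "n_nonresponder": gc.n_b,
                    "median_responder": gc.median_a, "median_nonresponder": gc.median_b,
                    "rank_sum": gc.statistic, "p_value": gc.p_value, "method": gc.method,
                }
            )
        comparisons = pd.DataFrame(comp_rows)

    # ---- optional tumour metrics -------------------------------------
    tumor = None
    if cfg.mutations is not None:
        muts = pd.read_csv(cfg.mutations, sep="\t")
        purity = cfg.purity if cfg.purity is not None else genomics.PURITY_FALLBACK
        muts = genomics.annotate_ccf(muts, purity)
        tumor = genomics.burden_metrics(muts, exome_mb=cfg.exome_mb)
        if cfg.segments is not None:
            segs = pd.read_csv(cfg.segments, sep="\t")
            tumor["wgii"] = genomics.wgii(segs, ploidy=2.0)
        _write(muts, out / "mutations_ccf.tsv")
        _write(tumor, out / "tumor_metrics.tsv")

    # ---- write report bundle -----------------------------------------
    _write(sample_metrics, out / "sample_metrics.tsv")
    _write(spatial, out / "spatial_similarity.tsv")
    _write(patient_summary, out / "patient_summary.tsv")
    _write(dynamics_calls, out / "dynamics_calls.tsv")
    _write(cluster_summary, out / "cluster_summary.tsv")
    _write(comparisons, out / "group_comparisons.tsv")
    _write(expansion_sweep, out / "expansion_sweep.tsv")
    _write(sweep_corr, out / "expansion_sweep_correlation.tsv")
    (out / "run_log.tsv").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        sample_metrics=sample_metrics, spatial=spatial,
        patient_summary=patient_summary, dynamics_calls=dynamics_calls,
        cluster_summary=cluster_summary, comparisons=comparisons,
        expansion_sweep=expansion_sweep, tumor_metrics=tumor, out_dir=out,
    )
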