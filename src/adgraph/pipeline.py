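"""End-to-end study orchestration.

Runs the whole analysis in the order the method prescribes: read cohort
-> per-subject correlation matrices -> sparsity sweep (explicit range or
selected from the NC group) -> global and subnetwork metric curves and
AUCs -> group comparisons at three levels (global metric AUCs by
permutation test, edge weights and inter-network FC by Welch t-test, all
BH-FDR corrected per contrast and level) -> trajectory pattern
classification -> MMSE correlations.  Every random choice derives from
one base seed, so a fixed config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import sys
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import SparsityRange, correlation_matrix, select_sparsity_range
from .metrics import METRIC_NAMES, ReferenceCache
from .stats import (ComparisonResult, PermutationConfig, bh_fdr, edge_t_test,
                    mmse_correlation, permutation_test, welch_t_test, fisher_z)
from .subnetworks import all_inter_network_fc, metric_sweep, subnetwork_metric_sweep
from .synthetic import (STAGES, CohortConfig, ROITimeSeries, default_partition,
                        generate_cohort, read_cohort, read_partition)
from .trajectory import StageTrajectory, classify_pattern, group_homogeneous

__all__ = ["RunConfig", "StudyReport", "run_study", "demo", "write_report"]

log = logging.getLogger("adgraph")

CONTRASTS = tuple(itertools.combinations(STAGES, 2))


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one study run (fully determines its outputs).

    With ``manifest=None`` a synthetic cohort is generated from
    ``cohort_config`` (or the defaults).  The sparsity sweep is either the
    explicit ``(s_min, s_max, step)`` range or, when ``select_range`` is
    True, derived from the NC group by the degree and small-worldness
    criteria.
    """

    manifest: str | None = None
    partition_file: str | None = None
    output_dir: str = "adgraph_out"
    s_min: float = 0.08
    s_max: float = 0.52
    step: float = 0.01
    select_range: bool = False
    degree_factor: float = 2.0
    sw_floor: float = 1.1
    log_base: str = "e"
    rank: str = "signed"
    n_random: int = 100
    n_permutations_metrics: int = 10_000
    permutation_tail: str = "two_tailed"
    alpha: float = 0.05
    fisher: bool = True
    subnetwork_mode: str = "own_budget"
    per_sparsity_tests: bool = False
    trajectory_tol: float | None = None  # None -> noise-scaled default
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class StudyReport:
    """All result tables of one run, plus the metadata that produced them."""

    sparsity: SparsityRange
    global_auc: pd.DataFrame
    subnet_auc: pd.DataFrame
    inter_fc: pd.DataFrame
    comparisons: pd.DataFrame
    trajectories: pd.DataFrame
    homogeneous: pd.DataFrame
    mmse: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "global_auc": self.global_auc,
            "subnet_auc": self.subnet_auc,
            "inter_fc": self.inter_fc,
            "comparisons": self.comparisons,
            "trajectories": self.trajectories,
            "homogeneous": self.homogeneous,
            "mmse": self.mmse,
        }


def _feature_seed(base_seed: int, *parts: str) -> int:
    """Stable per-feature permutation seed below 2**31."""
    digest = hashlib.sha256(("|".join(parts) + f"|{base_seed}").encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_cohort(cfg: RunConfig) -> list[ROITimeSeries]:
    if cfg.manifest is None:
        log.info("no manifest given: generating default synthetic cohort (seed=%d)", cfg.seed)
        return generate_cohort(CohortConfig(seed=cfg.seed))
    return read_cohort(cfg.manifest)


def _permutation_family(contrast: tuple[str, str], features: list[str],
                        values_a: list[list[float]], values_b: list[list[float]],
                        cfg: RunConfig, level: str) -> list[ComparisonResult]:
    """Permutation tests for one contrast at one level, BH over the family."""
    pcfg_base = PermutationConfig(
        n_permutations=cfg.n_permutations_metrics, tail=cfg.permutation_tail,
        alpha=cfg.alpha, seed=0)
    results = []
    for feat, va, vb in zip(features, values_a, values_b):
        if not (np.isfinite(va).all() and np.isfinite(vb).all()):
            log.warning("%s %s/%s: feature %s has undefined values; excluded from family",
                        level, *contrast, feat)
            continue
        pcfg = replace(pcfg_base, seed=_feature_seed(cfg.seed, level, feat, *contrast))
        res = permutation_test(va, vb, pcfg)
        results.append((feat, res))
    if not results:
        return []
    q, reject = bh_fdr([r.p_value for _, r in results], alpha=cfg.alpha)
    return [
        ComparisonResult(contrast=contrast, feature=feat, observed_diff=r.observed_diff,
                         p_value=r.p_value, q_value=float(qv), reject=bool(rj))
        for (feat, r), qv, rj in zip(results, q, reject)
    ]


def run_study(cfg: RunConfig, cohort: list[ROITimeSeries] | None = None) -> StudyReport:
    """Execute the full analysis described by ``cfg``.

    Stages with fewer than 2 subjects are skipped from the pairwise
    contrasts (with a warning); the run continues with the remaining
    ones.
    """
    if cohort is None:
        cohort = _load_cohort(cfg)
    if not cohort:
        raise ValueError("empty cohort")
    if cfg.partition_file is not None:
        partition = read_partition(cfg.partition_file)
    else:
        partition = default_partition(cohort[0].data.shape[1])
    n_rois = cohort[0].data.shape[1]
    partition.validate_cover(n_rois)

    by_stage: dict[str, list[int]] = {s: [] for s in STAGES}
    for i, subj in enumerate(cohort):
        by_stage[subj.stage].append(i)
    usable_stages = [s for s in STAGES if len(by_stage[s]) >= 2]
    if len(usable_stages) < 2:
        raise ValueError("need at least 2 stages with >= 2 subjects each")
    for s in STAGES:
        if 0 < len(by_stage[s]) < 2:
            log.warning("stage %s has %d subject(s); its contrasts are skipped",
                        s, len(by_stage[s]))
    log.info("cohort: %d subjects, %d ROIs, stages %s", len(cohort), n_rois,
             {s: len(v) for s, v in by_stage.items()})

    conn = [correlation_matrix(subj.data) for subj in cohort]

    if cfg.select_range:
        nc = [conn[i] for i in by_stage["NC"]]
        sparsity = select_sparsity_range(
            nc, cfg.step, degree_factor=cfg.degree_factor, sw_floor=cfg.sw_floor,
            log_base=cfg.log_base, rank=cfg.rank, n_random=cfg.n_random, seed=cfg.seed)
    else:
        sparsity = SparsityRange(s_min=cfg.s_min, s_max=cfg.s_max, step=cfg.step)
    log.info("sparsity sweep: [%g, %g] step %g (%d points)",
             sparsity.s_min, sparsity.s_max, sparsity.step, len(sparsity))

    ref_cache = ReferenceCache(n_random=cfg.n_random, seed=cfg.seed)

    # --- per-subject sweeps -------------------------------------------------
    global_rows, subnet_rows, fc_rows = [], [], []
    global_curves: dict[int, dict[str, np.ndarray]] = {}
    for i, subj in enumerate(cohort):
        sweep = metric_sweep(conn[i], sparsity, rank=cfg.rank, ref_cache=ref_cache)
        global_curves[i] = {m: sweep.curves[m].values for m in METRIC_NAMES}
        for m in METRIC_NAMES:
            global_rows.append({
                "subject_id": subj.subject_id, "stage": subj.stage, "metric": m,
                "auc": sweep.aucs[m].value, "fully_connected": bool(sweep.connected.all()),
            })
        subsweeps = subnetwork_metric_sweep(conn[i], partition, sparsity,
                                            rank=cfg.rank, mode=cfg.subnetwork_mode,
                                            ref_cache=ref_cache)
        for net, res in subsweeps.items():
            for m in METRIC_NAMES:
                subnet_rows.append({
                    "subject_id": subj.subject_id, "stage": subj.stage, "network": net,
                    "metric": m, "auc": res.aucs[m].value,
                    "valid_points": int(res.valid.sum()),
                })
        for fc in all_inter_network_fc(conn[i], partition):
            fc_rows.append({
                "subject_id": subj.subject_id, "stage": subj.stage,
                "network_a": fc.pair[0], "network_b": fc.pair[1], "fc": fc.value,
            })
    global_auc = pd.DataFrame(global_rows)
    subnet_auc = pd.DataFrame(subnet_rows)
    inter_fc = pd.DataFrame(fc_rows)

    # --- group comparisons --------------------------------------------------
    comparisons: list[dict] = []
    contrasts = [c for c in CONTRASTS if c[0] in usable_stages and c[1] in usable_stages]
    for ga, gb in contrasts:
        ia, ib = by_stage[ga], by_stage[gb]
        # global metric AUCs: permutation test, BH over the 5 metrics
        feats, va, vb = [], [], []
        for m in METRIC_NAMES:
            feats.append(m)
            va.append(global_auc.query("stage == @ga and metric == @m")["auc"].tolist())
            vb.append(global_auc.query("stage == @gb and metric == @m")["auc"].tolist())
        for r in _permutation_family((ga, gb), feats, va, vb, cfg, "global"):
            comparisons.append({"contrast": f"{ga}_vs_{gb}", "level": "global",
                                "feature": r.feature, "observed_diff": r.observed_diff,
                                "p": r.p_value, "q": r.q_value, "reject": r.reject})
        # optional: permutation test at every sparsity, BH across the grid
        if cfg.per_sparsity_tests:
            for m in METRIC_NAMES:
                feats = [f"{m}@S={s:.2f}" for s in sparsity.grid]
                va = [[global_curves[i][m][gi] for i in ia] for gi in range(len(sparsity))]
                vb = [[global_curves[i][m][gi] for i in ib] for gi in range(len(sparsity))]
                for r in _permutation_family((ga, gb), feats, va, vb, cfg, "global_per_sparsity"):
                    comparisons.append({
                        "contrast": f"{ga}_vs_{gb}", "level": "global_per_sparsity",
                        "feature": r.feature, "observed_diff": r.observed_diff,
                        "p": r.p_value, "q": r.q_value, "reject": r.reject})
        # subnetwork metric AUCs: permutation test, BH over networks x metrics
        feats, va, vb = [], [], []
        for net in partition.networks:
            for m in METRIC_NAMES:
                feats.append(f"{net}:{m}")
                sel = subnet_auc.query("network == @net and metric == @m")
                va.append(sel.query("stage == @ga")["auc"].tolist())
                vb.append(sel.query("stage == @gb")["auc"].tolist())
        for r in _permutation_family((ga, gb), feats, va, vb, cfg, "intra_rsn"):
            comparisons.append({"contrast": f"{ga}_vs_{gb}", "level": "intra_rsn",
                                "feature": r.feature, "observed_diff": r.observed_diff,
                                "p": r.p_value, "q": r.q_value, "reject": r.reject})
        # edge-wise FC: Welch t-test, BH over all edges
        for r in edge_t_test([conn[i].values for i in ia], [conn[i].values for i in ib],
                             (ga, gb), fisher=cfg.fisher, alpha=cfg.alpha):
            comparisons.append({"contrast": f"{ga}_vs_{gb}", "level": "edge",
                                "feature": r.feature, "observed_diff": r.observed_diff,
                                "p": r.p_value, "q": r.q_value, "reject": r.reject})
        # inter-network FC: Welch t-test over the network pairs
        pair_names = sorted({(r["network_a"], r["network_b"]) for r in fc_rows})
        amat, bmat, pf = [], [], []
        for na_, nb_ in pair_names:
            sel = inter_fc.query("network_a == @na_ and network_b == @nb_")
            amat.append(sel.query("stage == @ga")["fc"].to_numpy())
            bmat.append(sel.query("stage == @gb")["fc"].to_numpy())
            pf.append(f"{na_}-{nb_}")
        astack, bstack = np.array(amat).T, np.array(bmat).T
        ta, tb = (fisher_z(astack), fisher_z(bstack)) if cfg.fisher else (astack, bstack)
        _, pvals, _ = welch_t_test(ta, tb)
        q, reject = bh_fdr(pvals, alpha=cfg.alpha)
        diffs = astack.mean(axis=0) - bstack.mean(axis=0)
        for feat, d, p_, q_, rj in zip(pf, diffs, pvals, q, reject):
            comparisons.append({"contrast": f"{ga}_vs_{gb}", "level": "inter_rsn",
                                "feature": feat, "observed_diff": float(d),
                                "p": float(p_), "q": float(q_), "reject": bool(rj)})
    comparisons_df = pd.DataFrame(comparisons)
    n_rej = int(comparisons_df["reject"].sum()) if len(comparisons_df) else 0
    log.info("comparisons: %d contrasts, %d features tested, %d rejections",
             len(contrasts), len(comparisons_df), n_rej)

    # --- trajectory classification -----------------------------------------
    traj_rows, labels = [], {}
    for net in partition.networks:
        for m in METRIC_NAMES:
            sel = subnet_auc.query("network == @net and metric == @m")
            means, ses = [], []
            for s in STAGES:
                vals = sel.query("stage == @s")["auc"].to_numpy()
                means.append(float(vals.mean()) if len(vals) else np.nan)
                ses.append(float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan)
            if not np.isfinite(means).all():
                continue
            traj = StageTrajectory(feature=(net, m), values=tuple(means),
                                   dispersion=tuple(ses))
            label = classify_pattern(traj, tol=cfg.trajectory_tol)
            labels[(net, m)] = label
            row = {"network": net, "metric": m, "label": label.label.value,
                   "peak_stage": label.peak_stage or ""}
            row.update({f"mean_{s}": mu for s, mu in zip(STAGES, means)})
            row.update({f"se_{s}": se for s, se in zip(STAGES, ses)})
            traj_rows.append(row)
    trajectories = pd.DataFrame(traj_rows)
    homogeneous = pd.DataFrame(
        [{"network": net, "pattern": pat.value}
         for net, pat in group_homogeneous(labels).items()]) if labels else pd.DataFrame()

    # --- MMSE correlations --------------------------------------------------
    mmse_rows = []
    mmse_by_stage = {s: np.array([cohort[i].mmse for i in by_stage[s]]) for s in STAGES}
    for s in usable_stages:
        if len(by_stage[s]) < 4 or np.std(mmse_by_stage[s]) == 0:
            log.warning("stage %s: MMSE correlation skipped (n<4 or constant scores)", s)
            continue
        for m in METRIC_NAMES:
            vals = global_auc.query("stage == @s and metric == @m")["auc"].to_numpy()
            if not np.isfinite(vals).all() or (vals == vals[0]).all():
                continue
            r_, p_ = mmse_correlation(vals, mmse_by_stage[s])
            mmse_rows.append({"stage": s, "level": "global", "feature": m, "r": r_, "p": p_})
        for net in partition.networks:
            for m in METRIC_NAMES:
                vals = subnet_auc.query(
                    "stage == @s and network == @net and metric == @m")["auc"].to_numpy()
                if not np.isfinite(vals).all() or (vals == vals[0]).all():
                    continue
                r_, p_ = mmse_correlation(vals, mmse_by_stage[s])
                mmse_rows.append({"stage": s, "level": "subnetwork",
                                  "feature": f"{net}:{m}", "r": r_, "p": p_})
    mmse_df = pd.DataFrame(mmse_rows)

    metadata = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "package_version": __version__,
        "python_version": sys.version.split()[0],
        "n_subjects": len(cohort),
        "n_rois": n_rois,
        "stages": {s: len(by_stage[s]) for s in STAGES},
        "sparsity": {"s_min": sparsity.s_min, "s_max": sparsity.s_max,
                     "step": sparsity.step, "n_points": len(sparsity)},
        "n_contrasts": len(contrasts),
        "n_features_tested": int(len(comparisons_df)),
        "n_rejections": n_rej,
    }
    return StudyReport(sparsity=sparsity, global_auc=global_auc, subnet_auc=subnet_auc,
                       inter_fc=inter_fc, comparisons=comparisons_df,
                       trajectories=trajectories, homogeneous=homogeneous,
                       mmse=mmse_df, metadata=metadata)


def write_report(report: StudyReport, output_dir: str | Path) -> Path:
    """Write all report tables as TSV plus a JSON metadata file.

    Every table file starts with a ``# config_hash=`` comment line tying
    it to the configuration that produced it (readable with
    ``pd.read_csv(..., sep='\\t', comment='#')``).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = report.metadata["config_hash"]
    for name, df in report.tables().items():
        path = out / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True, default=str)
    return out


def demo(seed: int = 0, output_dir: str | Path | None = None,
         cfg: RunConfig | None = None, *, plots: bool = False) -> StudyReport:
    """Generate the default synthetic cohort, run the full study, write tables.

    ``cfg`` overrides the default run configuration (its seed is replaced
    by ``seed``).  With ``plots=True`` a trajectory panel figure is also
    written (requires matplotlib).
    """
    cfg = replace(cfg if cfg is not None else RunConfig(), seed=seed, manifest=None)
    report = run_study(cfg)
    if output_dir is not None:
        write_report(report, output_dir)
        if plots:
            plot_trajectories(report, Path(output_dir) / "trajectories.png")
    return report


def plot_trajectories(report: StudyReport, path: str | Path) -> None:
    """One panel per network: stage means of each metric AUC (normalized)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.trajectories
    networks = df["network"].unique()
    fig, axes = plt.subplots(2, (len(networks) + 1) // 2, figsize=(4 * ((len(networks) + 1) // 2), 7),
                             squeeze=False)
    x = np.arange(len(STAGES))
    for ax, net in zip(axes.ravel(), networks):
        sub = df[df["network"] == net]
        for _, row in sub.iterrows():
            means = np.array([row[f"mean_{s}"] for s in STAGES])
            norm = (means - means.min()) / (means.max() - means.min() + 1e-15)
            ax.plot(x, norm, marker="o", label=row["metric"])
        ax.set_title(net)
        ax.set_xticks(x, STAGES)
    axes.ravel()[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
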