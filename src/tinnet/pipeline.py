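"""Pipeline orchestration and CLI.

A single JSON config drives: synthetic-data generation -> denoising ->
static/dynamic network construction -> graph metrics -> clinical-score
generation (coupled to measured modularity changes) -> longitudinal
statistics -> RESBM community comparison -> (optional) voxel/MAGEE.
Every stage derives its RNG seed from the root seed and a stable stage
name, so toggling stages never perturbs the others, and identical
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import denoise as dn
from . import graphmetrics as gm
from . import longstats as ls
from . import magee as mg
from . import netbuild as nb
from . import resbm as rb
from . import synth
from .containers import SESSIONS, ROITimeSeriesPanel, ScoreTable

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable under stage toggling)."""
    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Run configuration; defaults mirror the emulated study."""

    seed: int
    out_dir: str = "tinnet_out"
    # synthetic cohort
    n_subjects: int = 12
    sessions: tuple[str, ...] = SESSIONS
    n_rois: int = 90
    n_blocks: int = 5
    n_time: int = 300
    tr_seconds: float = 2.0
    rho_within: float = 0.45
    rho_between: float = 0.05
    subject_sigma: float = 0.04
    score_coupling: float = 0.7
    # denoising band (Hz)
    band_low_hz: float = 0.008
    band_high_hz: float = 0.08
    # networks
    density_grid: tuple[float, ...] = nb.DEFAULT_DENSITY_GRID
    window_width_tr: int = nb.DEFAULT_WINDOW_WIDTH
    window_step_tr: int = nb.DEFAULT_WINDOW_STEP
    window_density: float = nb.DEFAULT_DYNAMIC_DENSITY
    n_discard_initial: int = 0
    louvain_restarts: int = 20
    dynamic_louvain_restarts: int = 1
    # resbm
    resbm_densities: tuple[float, ...] = (0.10, 0.20)
    resbm_k: str | int = "auto"
    resbm_lambda: float = 1.0
    resbm_restarts: int = 5
    resbm_perm: int = 99
    # stats
    fdr_q: float = 0.05
    stats_n_perm: int = 9999
    # magee
    magee_enabled: bool = True
    magee_grid: tuple[int, int, int] = (12, 12, 12)
    magee_n_time: int = 60
    magee_n_iter: int = mg.DEFAULT_N_ITER
    magee_height_p: float = mg.DEFAULT_HEIGHT_P
    magee_min_extent: int = mg.DEFAULT_MIN_EXTENT
    magee_effect_beta: float = -0.01
    stages: tuple[str, ...] = ("synth", "denoise", "metrics", "scores",
                               "dynamic", "longstats", "resbm", "magee")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a root seed is mandatory (reproducibility)")
        for d in (*self.density_grid, self.window_density,
                  *self.resbm_densities):
            if not (0 < d <= 1):
                raise ValueError(f"density {d} outside (0, 1]")
        for p in (self.fdr_q, self.magee_height_p):
            if not (0 < p < 1):
                raise ValueError(f"threshold {p} outside (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("sessions", "density_grid", "resbm_densities",
                     "magee_grid", "stages"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    failed: bool = False

    def add_artifact(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[str(path)] = digest

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "artifacts": self.artifacts, "failed": self.failed},
            indent=1, sort_keys=True))


def _write_tsv(df: pd.DataFrame, path: Path, report: RunReport) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    report.add_artifact(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute enabled stages in dependency order; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    state: dict = {}
    order = ["synth", "denoise", "metrics", "scores", "dynamic",
             "longstats", "resbm", "magee"]
    deps = {"denoise": ["synth"], "metrics": ["denoise"],
            "scores": ["metrics"], "dynamic": ["denoise"],
            "longstats": ["metrics", "scores"],
            "resbm": ["denoise"], "magee": ["scores"]}
    enabled = [s for s in order if s in config.stages]
    done: set[str] = set()
    for stage in enabled:
        if any(d not in done for d in deps.get(stage, [])):
            report.stages[stage] = {"status": "skipped",
                                    "reason": "unmet dependency"}
            continue
        t0 = time.time()
        try:
            _STAGES[stage](config, state, out, report)
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            logger.exception("stage %s failed", stage)
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            report.failed = True
            break
        report.stages[stage] = {"status": "ok",
                                "seconds": round(time.time() - t0, 3)}
        done.add(stage)
    report.to_json(out / "run_report.json")
    return report


def _stage_synth(cfg: RunConfig, state: dict, out: Path,
                 report: RunReport) -> None:
    sizes = [cfg.n_rois // cfg.n_blocks] * cfg.n_blocks
    sizes[-1] += cfg.n_rois - sum(sizes)
    spec = synth.CommunitySpec(sizes, cfg.rho_within, cfg.rho_between,
                               cfg.n_time, cfg.tr_seconds)
    panel = synth.gen_roi_panel(
        cfg.n_subjects, list(cfg.sessions), spec,
        synth.default_session_effects(),
        seed=stage_seed(cfg.seed, "synth"),
        subject_sigma=cfg.subject_sigma)
    state["panel"] = panel
    for p in panel.write_tsv(out / "panels"):
        report.add_artifact(p)
    truth = out / "panels" / "truth.json"
    truth.write_text(json.dumps({
        "block_sizes": sizes, "rho_within": cfg.rho_within,
        "rho_between": cfg.rho_between,
        "membership": spec.membership().tolist()}, indent=1))
    report.add_artifact(truth)


def _stage_denoise(cfg: RunConfig, state: dict, out: Path,
                   report: RunReport) -> None:
    panel = state["panel"]
    entries = {}
    for key, ts in panel.entries.items():
        drop = ts.values[cfg.n_discard_initial:]
        entries[key] = dn.bandpass(ts.copy_with(drop), cfg.band_low_hz,
                                   cfg.band_high_hz)
    state["clean"] = ROITimeSeriesPanel(entries, panel.roi_labels,
                                        panel.tr_seconds)


def _stage_metrics(cfg: RunConfig, state: dict, out: Path,
                   report: RunReport) -> None:
    clean: ROITimeSeriesPanel = state["clean"]
    seed = stage_seed(cfg.seed, "metrics")
    frames = []
    graphs: dict = {}
    for i, (key, ts) in enumerate(sorted(clean.entries.items())):
        corr = nb.correlation_matrix(ts)
        for d in cfg.density_grid:
            g = nb.threshold_to_density(corr, d)
            graphs[(key, d)] = g
            frames.append(gm.metric_record(
                g, key[0], key[1], d, seed=seed + 97 * i,
                restarts=cfg.louvain_restarts))
    metrics = pd.concat(frames, ignore_index=True)
    state["metrics"] = metrics
    state["graphs"] = graphs
    _write_tsv(metrics, out / "graph_metrics.tsv", report)


def _stage_scores(cfg: RunConfig, state: dict, out: Path,
                  report: RunReport) -> None:
    metrics = state["metrics"]
    density = cfg.density_grid[1] if len(cfg.density_grid) > 1 \
        else cfg.density_grid[0]
    sub = metrics[(metrics.metric == "Q")
                  & np.isclose(metrics.density, density)
                  & (metrics.node == "")]
    w = sub.pivot(index="subject", columns="session", values="value")
    present = [s for s in SESSIONS if s in w.columns]
    deltas = {subj: [w.loc[subj, later] - w.loc[subj, earlier]
                     for earlier, later in zip(present[:-1], present[1:])]
              for subj in w.index}
    scores = synth.gen_clinical_scores(
        deltas, coupling=cfg.score_coupling,
        seed=stage_seed(cfg.seed, "scores"))
    state["scores"] = scores
    scores.to_tsv(out / "scores.tsv")
    report.add_artifact(out / "scores.tsv")


def _stage_dynamic(cfg: RunConfig, state: dict, out: Path,
                   report: RunReport) -> None:
    clean: ROITimeSeriesPanel = state["clean"]
    seed = stage_seed(cfg.seed, "dynamic")
    rows = []
    for i, (key, ts) in enumerate(sorted(clean.entries.items())):
        series = nb.dynamic_graphs(ts, cfg.window_width_tr,
                                   cfg.window_density, cfg.window_step_tr)
        for w, g in enumerate(series.graphs):
            if g is None:
                rows.append({"subject": key[0], "session": key[1],
                             "window": w, "metric": "flagged", "value": 1.0})
                continue
            part = gm.louvain_communities(
                g, seed=seed + 1013 * i + w,
                restarts=cfg.dynamic_louvain_restarts)
            q = gm.modularity(g, part)
            rows.append({"subject": key[0], "session": key[1], "window": w,
                         "metric": "Q",
                         "value": np.nan if q is None else q})
            rows.append({"subject": key[0], "session": key[1], "window": w,
                         "metric": "E_glob",
                         "value": gm.global_efficiency(g)})
            rows.append({"subject": key[0], "session": key[1], "window": w,
                         "metric": "C_glob",
                         "value": gm.global_clustering(g)})
    dyn = pd.DataFrame(rows)
    state["dynamic"] = dyn
    _write_tsv(dyn, out / "dynamic_metrics.tsv", report)
    # kernel-density summaries per subject/session/metric
    kde_rows = []
    for (subj, sess, metric), grp in dyn[dyn.metric != "flagged"].groupby(
            ["subject", "session", "metric"]):
        res = ls.kde_summary(grp.value.dropna())
        if res.degenerate:
            continue
        kde_rows.append({"subject": subj, "session": sess, "metric": metric,
                         "bandwidth": res.bandwidth,
                         "mode": float(res.grid[np.argmax(res.density)])})
    _write_tsv(pd.DataFrame(kde_rows), out / "dynamic_kde.tsv", report)


def _stage_longstats(cfg: RunConfig, state: dict, out: Path,
                     report: RunReport) -> None:
    metrics, scores = state["metrics"], state["scores"]
    seed = stage_seed(cfg.seed, "longstats")
    # paired session t-tests on the score
    w = scores.wide()
    t_rows = []
    present = [s for s in SESSIONS if s in w.columns]
    for earlier, later in [(a, b) for i, a in enumerate(present)
                           for b in present[i + 1:]]:
        res = ls.paired_t(w[earlier], w[later])
        t_rows.append({"analysis": "paired_t", "pair": f"{earlier}-{later}",
                       "t": res.t, "df": res.df, "p": res.p,
                       "n": res.n_pairs})
    _write_tsv(pd.DataFrame(t_rows), out / "score_ttests.tsv", report)
    # delta correlations across the density grid
    table = ls.delta_correlation_table(metrics, scores,
                                       densities=cfg.density_grid,
                                       n_perm=cfg.stats_n_perm, seed=seed)
    _write_tsv(table, out / "delta_correlations.tsv", report)
    state["delta_table"] = table
    # regression of score changes on graph-measure changes
    recs = {}
    for name, metric in (("dQ", "Q"), ("dE_glob", "E_glob"),
                         ("dC_glob", "C_glob")):
        r = ls.build_delta_records(metrics, scores, metric,
                                   cfg.density_grid[0])
        recs[name] = r.set_index(["subject", "earlier", "later"])["delta_metric"]
    base = ls.build_delta_records(metrics, scores, "Q", cfg.density_grid[0])
    base = base.set_index(["subject", "earlier", "later"])
    df = pd.DataFrame({"delta_score": base["delta_score"], **recs}).reset_index()
    reg = ls.regress_delta_scores(df)
    reg_df = pd.DataFrame({"term": reg.params.index,
                           "coef": reg.params.to_numpy(),
                           "se": reg.bse.to_numpy(),
                           "p": reg.pvalues.to_numpy()})
    reg_df["r_squared"] = reg.r_squared
    _write_tsv(reg_df, out / "delta_regression.tsv", report)
    # nodal comparisons pre vs post at the dynamic density (fall back to
    # the first grid density if the grid does not include it)
    density = (cfg.window_density
               if any(np.isclose(cfg.window_density, d)
                      for d in cfg.density_grid)
               else cfg.density_grid[0])
    nod = metrics[(metrics.metric == "E_nodal")
                  & np.isclose(metrics.density, density)
                  & (metrics.node != "")]
    wide_a = nod[nod.session == "pre"].pivot(index="subject",
                                             columns="node", values="value")
    wide_b = nod[nod.session == "post"].pivot(index="subject",
                                              columns="node", values="value")
    nodal = ls.nodal_compare(wide_a, wide_b[wide_a.columns],
                             fdr_q=cfg.fdr_q)
    _write_tsv(nodal, out / "nodal_efficiency_tests.tsv", report)


def _stage_resbm(cfg: RunConfig, state: dict, out: Path,
                 report: RunReport) -> None:
    graphs = state["graphs"]
    clean = state["clean"]
    subjects = sorted({k[0] for k in clean.entries})
    seed = stage_seed(cfg.seed, "resbm")
    rows = []
    for density in cfg.resbm_densities:
        ga = [graphs[((s, "pre"), density)] for s in subjects]
        gb = [graphs[((s, "post"), density)] for s in subjects]
        if cfg.resbm_k == "auto":
            k = rb.select_k(ga + gb, seed=seed)
        else:
            k = int(cfg.resbm_k)
        k = max(k, 2)
        model_a = rb.fit_cosontf(ga, k, lam=cfg.resbm_lambda, seed=seed,
                                 restarts=cfg.resbm_restarts)
        model_b = rb.fit_cosontf(gb, k, lam=cfg.resbm_lambda, seed=seed + 1,
                                 restarts=cfg.resbm_restarts)
        model_a.to_dir(out / f"resbm_d{density:.2f}_pre")
        model_b.to_dir(out / f"resbm_d{density:.2f}_post")
        test = rb.test_global_difference(
            ga, gb, k, n_perm=cfg.resbm_perm, seed=seed,
            lam=cfg.resbm_lambda, restarts=2, max_iter=100,
            collect_node_scores=True)
        nodes = rb.test_node_membership_change(
            model_a, model_b, test.null_node_scores, fdr_q=cfg.fdr_q)
        _write_tsv(nodes, out / f"resbm_d{density:.2f}_nodes.tsv", report)
        rows.append({"density": density, "k": k,
                     "distance": test.observed_d,
                     "distance_rand": test.observed_rand_d,
                     "p": test.p_value,
                     "exact": test.exact,
                     "n_perm": len(test.null_d)})
    _write_tsv(pd.DataFrame(rows), out / "resbm_global_tests.tsv", report)
    state["resbm"] = rows


def _stage_magee(cfg: RunConfig, state: dict, out: Path,
                 report: RunReport) -> None:
    if not cfg.magee_enabled:
        return
    scores: ScoreTable = state["scores"]
    seed = stage_seed(cfg.seed, "magee")
    ds = synth.gen_voxel_dataset(cfg.magee_grid, scores,
                                 effect_beta=cfg.magee_effect_beta,
                                 seed=seed, n_time=cfg.magee_n_time)
    zmaps = {key: mg.seed_to_voxel_map(vol, ds.seed_mask, ds.affine)
             for key, vol in ds.data.items()}
    res = mg.MAGEE(zmaps, scores, n_iter=cfg.magee_n_iter).fit()
    res.wald_map.to_nifti(out / "magee_wald.nii")
    report.add_artifact(out / "magee_wald.nii")
    clusters = res.clusters(cfg.magee_height_p, cfg.magee_min_extent)
    _write_tsv(clusters, out / "magee_clusters.tsv", report)
    # paired session contrast pre vs post on the z-maps
    subjects = sorted({k[0] for k in zmaps})
    maps_a = [zmaps[(s, "pre")] for s in subjects
              if (s, "pre") in zmaps and (s, "post") in zmaps]
    maps_b = [zmaps[(s, "post")] for s in subjects
              if (s, "pre") in zmaps and (s, "post") in zmaps]
    if len(maps_a) >= 5:
        contrast = mg.paired_contrast(maps_a, maps_b,
                                      height_p=1e-3, min_extent=5,
                                      n_perm=500, seed=seed)
        _write_tsv(contrast.clusters, out / "paired_contrast_clusters.tsv",
                   report)
    state["magee"] = res


_STAGES = {
    "synth": _stage_synth,
    "denoise": _stage_denoise,
    "metrics": _stage_metrics,
    "scores": _stage_scores,
    "dynamic": _stage_dynamic,
    "longstats": _stage_longstats,
    "resbm": _stage_resbm,
    "magee": _stage_magee,
}


def validate_inputs(panel_dir: str | Path | None = None,
                    scores_path: str | Path | None = None) -> list[dict]:
    """Structural validation of on-disk inputs.

    Returns findings as dicts with keys (severity, message); never
    raises for content problems.
    """
    findings: list[dict] = []
    if panel_dir is not None:
        panel_dir = Path(panel_dir)
        files = sorted(panel_dir.glob("*_roi.tsv"))
        if not files:
            findings.append({"severity": "error",
                             "message": f"no ROI TSVs in {panel_dir}"})
        headers: dict[str, list[str]] = {}
        seen: dict[str, set[str]] = {}
        for f in files:
            cols = list(pd.read_csv(f, sep="\t", nrows=0).columns)
            subj, sess, _ = f.stem.rsplit("_", 2)
            if sess not in SESSIONS:
                findings.append({"severity": "error",
                                 "message": f"{f.name}: unknown session "
                                            f"label {sess!r}"})
            seen.setdefault(subj, set()).add(sess)
            for other, oc in headers.items():
                if oc != cols:
                    findings.append({"severity": "error",
                                     "message": f"ROI label mismatch between "
                                                f"{other} and {f.name}"})
                    break
            headers[f.name] = cols
        for subj, sess_set in seen.items():
            missing = [s for s in SESSIONS if s not in sess_set]
            if missing:
                findings.append({
                    "severity": "warning",
                    "message": f"subject {subj} missing session(s) "
                               f"{missing} (paired/GEE stages handle "
                               f"missingness)"})
    if scores_path is not None:
        try:
            ScoreTable.read_tsv(scores_path)
        except Exception as exc:  # noqa: BLE001
            findings.append({"severity": "error",
                             "message": f"scores table invalid: {exc}"})
    return findings


# ---------------------------------------------------------------------------
# CLI


def cli() -> None:
    import click

    @click.group(name="tinnet")
    def group() -> None:
        """Longitudinal brain-network analysis pipeline."""

    @group.command("run")
    @click.option("--config", "config_path", required=True,
                  type=click.Path(exists=True))
    def _run(config_path: str) -> None:
        cfg = RunConfig.from_json(config_path)
        report = run_pipeline(cfg)
        click.echo(json.dumps(report.stages, indent=1))
        raise SystemExit(1 if report.failed else 0)

    @group.command("synth")
    @click.option("--config", "config_path", required=True,
                  type=click.Path(exists=True))
    def _synth(config_path: str) -> None:
        cfg = RunConfig.from_json(config_path)
        cfg.stages = ("synth",)
        report = run_pipeline(cfg)
        click.echo(json.dumps(report.stages, indent=1))
        raise SystemExit(1 if report.failed else 0)

    @group.command("validate")
    @click.option("--in", "in_dir", required=True, type=click.Path())
    @click.option("--scores", "scores_path", default=None,
                  type=click.Path())
    def _validate(in_dir: str, scores_path: str | None) -> None:
        findings = validate_inputs(in_dir, scores_path)
        click.echo(json.dumps(findings, indent=1))

    group()
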