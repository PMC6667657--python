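"""Synthetic-data generators for the full pipeline.

The study this pipeline emulates imaged ~12 tinnitus subjects at three
sessions (pre / post / follow-up of an 8-week mindfulness course),
extracted 90 AAL ROI time series per scan, and related between-session
changes in network segregation to changes in the Tinnitus Functional
Index (TFI). No subject-level data are deposited, so every input is
generated here: ROI panels with planted block (community) covariance and
session-wise segregation shifts, clinical scores whose between-session
changes are coupled to network changes, stochastic-block-model
adjacencies, and small 4-D voxel datasets with a seed-coupled target
region for the seed-to-voxel / GEE stages.

Generators are deterministic under a fixed seed. Defaults mirror the
study's scale: 12 subjects, 3 sessions, 90 ROIs, 300 time points at
TR = 2 s, pre-intervention TFI centred at mean 50.92 (SD 15.57).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (SESSIONS, BinaryGraph, ROITimeSeriesPanel,
                         ScoreTable, TimeSeries, VoxelDataset)

#: Pre-intervention TFI marginals (study cohort moments).
TFI_PRE_MEAN = 50.92
TFI_PRE_SD = 15.57

DEFAULT_N_SUBJECTS = 12
DEFAULT_N_ROIS = 90
DEFAULT_N_TIME = 300
DEFAULT_TR = 2.0


@dataclass
class CommunitySpec:
    """Planted community structure for ROI time-series covariance.

    The implied ROI covariance has unit variances, correlation
    ``rho_within`` inside each block and ``rho_between`` across blocks.
    """

    block_sizes: list[int]
    rho_within: float = 0.5
    rho_between: float = 0.05
    n_time: int = DEFAULT_N_TIME
    tr_seconds: float = DEFAULT_TR

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (self.rho_within > self.rho_between):
            raise ValueError("rho_within must exceed rho_between")
        if not (0 <= self.rho_within < 1):
            raise ValueError("rho_within must lie in [0, 1)")

    @property
    def n_rois(self) -> int:
        return int(sum(self.block_sizes))

    def membership(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)

    def covariance(self, within_shift: float = 0.0) -> np.ndarray:
        """Block correlation matrix (optionally with a within-block shift).

        Raises if the implied matrix is not positive definite.
        """
        m = self.membership()
        same = m[:, None] == m[None, :]
        rho_w = self.rho_within + within_shift
        cov = np.where(same, rho_w, self.rho_between)
        np.fill_diagonal(cov, 1.0)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"implied covariance is not positive definite "
                f"(rho_within={rho_w:.3f}, rho_between={self.rho_between:.3f})"
            ) from exc
        return cov


@dataclass
class SessionEffect:
    """Session-specific shift of the segregation/integration balance.

    ``segregation_shift`` is added to the within-block correlation for
    that session (the study observed modularity and clustering dropping
    post-intervention and rebounding at follow-up). ``score_coupling``
    is the target correlation between per-subject modularity changes and
    TFI changes into this session.
    """

    session_label: str
    segregation_shift: float = 0.0
    score_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.session_label not in SESSIONS:
            raise ValueError(f"unknown session label {self.session_label!r}")
        if abs(self.score_coupling) > 1:
            raise ValueError("|score_coupling| must be <= 1")


def default_session_effects() -> list[SessionEffect]:
    """Pre/post/follow-up effects emulating the observed trajectory:
    segregation dips post-intervention and largely rebounds."""
    return [
        SessionEffect("pre", 0.0, 0.0),
        SessionEffect("post", -0.10, 0.7),
        SessionEffect("followup", -0.02, 0.7),
    ]


def gen_roi_panel(n_subjects: int,
                  sessions: Sequence[str],
                  spec: CommunitySpec,
                  effects: Sequence[SessionEffect],
                  seed: int,
                  ar_coef: float = 0.0,
                  subject_sigma: float = 0.02) -> ROITimeSeriesPanel:
    """Generate zero-mean Gaussian ROI panels with planted block covariance.

    Each subject-session matrix is drawn from N(0, Sigma) where Sigma is
    the spec's block correlation plus the session's segregation shift and
    a small per-subject-session jitter of the within-block correlation
    (``subject_sigma``), which creates genuine between-subject spread in
    graph measures. ``ar_coef`` optionally imposes AR(1) temporal
    autocorrelation with the same stationary covariance.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if spec.n_time < 30:
        raise ValueError("need at least 30 time points")
    if not (0 <= ar_coef < 1):
        raise ValueError("ar_coef must lie in [0, 1)")
    eff = {e.session_label: e for e in effects}
    for s in sessions:
        if s not in eff:
            raise ValueError(f"no SessionEffect supplied for session {s!r}")
    rng = np.random.default_rng(seed)
    labels = [f"roi{i:03d}" for i in range(spec.n_rois)]
    entries: dict[tuple[str, str], TimeSeries] = {}
    for si in range(n_subjects):
        subj = f"sub{si + 1:02d}"
        for sess in sessions:
            jitter = rng.normal(0.0, subject_sigma) if subject_sigma > 0 else 0.0
            cov = spec.covariance(within_shift=eff[sess].segregation_shift
                                  + jitter)
            chol = np.linalg.cholesky(cov)
            innov = rng.standard_normal((spec.n_time, spec.n_rois))
            x = innov @ chol.T
            if ar_coef > 0:
                # AR(1) with innovations scaled to keep stationary cov = Sigma
                y = np.empty_like(x)
                y[0] = x[0]
                scale = np.sqrt(1 - ar_coef ** 2)
                for t in range(1, spec.n_time):
                    y[t] = ar_coef * y[t - 1] + scale * x[t]
                x = y
            entries[(subj, sess)] = TimeSeries(x, spec.tr_seconds, labels)
    return ROITimeSeriesPanel(entries, labels, spec.tr_seconds)


def gen_clinical_scores(panel_deltas: Mapping[str, Sequence[float]] | pd.DataFrame,
                        coupling: float,
                        base_mean: float = TFI_PRE_MEAN,
                        base_sd: float = TFI_PRE_SD,
                        delta_means: Sequence[float] | None = None,
                        delta_sd: float = 10.0,
                        seed: int = 0,
                        score: str = "TFI") -> ScoreTable:
    """Generate TFI scores whose between-session changes are coupled to
    the supplied per-subject network changes.

    ``panel_deltas`` maps subject -> sequence of network-measure deltas,
    one per consecutive session transition (pre->post[, post->followup]).
    Each generated score delta has population correlation ``coupling``
    with the corresponding network delta, via the Gaussian construction
    z_score = coupling * z_net + sqrt(1 - coupling^2) * eps. Scores are
    built cumulatively from a pre-session draw centred at ``base_mean``.
    ``delta_means`` gives the mean score change per transition (default:
    study-like drop of -15.5 pre->post, then ~0).
    """
    if abs(coupling) > 1:
        raise ValueError("|coupling| must be <= 1")
    if isinstance(panel_deltas, pd.DataFrame):
        panel_deltas = {str(s): panel_deltas.loc[s].to_numpy()
                        for s in panel_deltas.index}
    subjects = sorted(panel_deltas)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    deltas = np.array([np.atleast_1d(np.asarray(panel_deltas[s], dtype=float))
                       for s in subjects])
    n_subj, n_trans = deltas.shape
    if n_trans >= len(SESSIONS):
        raise ValueError("more transitions than available sessions")
    if delta_means is None:
        delta_means = ([-15.5] + [0.0] * (n_trans - 1))
    rng = np.random.default_rng(seed)
    values: dict[str, dict[str, float]] = {}
    pre = base_mean + base_sd * rng.standard_normal(n_subj)
    cur = pre.copy()
    for s, subj in enumerate(subjects):
        values[subj] = {"pre": float(pre[s])}
    for t in range(n_trans):
        d = deltas[:, t]
        sd = d.std(ddof=0)
        z_net = (d - d.mean()) / sd if sd > 0 else np.zeros(n_subj)
        eps = rng.standard_normal(n_subj)
        z = coupling * z_net + np.sqrt(max(0.0, 1 - coupling ** 2)) * eps
        cur = cur + delta_means[t] + delta_sd * z
        sess = SESSIONS[t + 1]
        for s, subj in enumerate(subjects):
            values[subj][sess] = float(cur[s])
    return ScoreTable.from_wide(values, score=score)


def gen_sbm_adjacency(block_sizes: Sequence[int],
                      p_in: float,
                      p_out: float,
                      seed: int,
                      labels: Sequence[str] | None = None) -> BinaryGraph:
    """Planted-partition stochastic-block-model adjacency.

    Symmetric zero-diagonal Bernoulli graph with edge probability
    ``p_in`` inside blocks and ``p_out`` across blocks; the planted
    membership is stored on the returned graph.
    """
    if any(b <= 0 for b in block_sizes):
        raise ValueError("empty blocks are not allowed")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    membership = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = len(membership)
    same = membership[:, None] == membership[None, :]
    prob = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < prob, 1)
    adj = (upper | upper.T).astype(np.uint8)
    return BinaryGraph(adj, list(labels) if labels else [],
                       planted_membership=membership)


def gen_sbm_group(n_subjects: int,
                  block_sizes: Sequence[int],
                  p_in: float,
                  p_out: float,
                  seed: int) -> list[BinaryGraph]:
    """Independent SBM draws from a common planted partition, one per
    subject (the random-effects SBM's data-generating regime with no
    subject-level membership deviation)."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_subjects) % (2 ** 31)
    return [gen_sbm_adjacency(block_sizes, p_in, p_out, int(s)) for s in seeds]


def _sphere_mask(shape: tuple[int, int, int], center: Sequence[float],
                 radius_vox: float) -> np.ndarray:
    grid = np.indices(shape)
    d2 = sum((grid[k] - center[k]) ** 2 for k in range(3))
    return d2 <= radius_vox ** 2


def gen_voxel_dataset(grid_shape: tuple[int, int, int],
                      scores: ScoreTable,
                      effect_beta: float,
                      noise_sd: float = 1.0,
                      seed: int = 0,
                      n_time: int = 100,
                      tr_seconds: float = DEFAULT_TR,
                      affine: np.ndarray | None = None,
                      seed_center: Sequence[float] | None = None,
                      seed_radius_vox: float = 2.0,
                      target_center: Sequence[float] | None = None,
                      target_radius_vox: float = 3.0,
                      base_rho: float = 0.3,
                      score_center: float | None = None) -> VoxelDataset:
    """Small 4-D voxel dataset with a seed-coupled target region.

    Voxels inside ``target_mask`` carry signal correlated with the mean
    seed time course; the correlation for subject-session (i, j) is
    ``base_rho + effect_beta * (score_ij - score_center)`` (clipped to
    (-0.95, 0.95)), so connectivity varies linearly with the clinical
    score. All other voxels are independent N(0, noise_sd^2) noise.
    With ``effect_beta = 0`` the score carries no information about any
    voxel, giving an exact null for GEE calibration.
    """
    if min(grid_shape) < 8:
        raise ValueError("grid must be at least 8x8x8")
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic
    if seed_center is None:
        seed_center = [s // 4 for s in grid_shape]
    if target_center is None:
        target_center = [3 * s // 4 for s in grid_shape]
    for c in (seed_center, target_center):
        if any(not (0 <= c[k] < grid_shape[k]) for k in range(3)):
            raise ValueError("mask centre lies outside the grid")
    seed_mask = _sphere_mask(grid_shape, seed_center, seed_radius_vox)
    target_mask = _sphere_mask(grid_shape, target_center, target_radius_vox)
    if not seed_mask.any() or not target_mask.any():
        raise ValueError("mask is empty on this grid")
    if seed_mask.sum() + target_mask.sum() == 0 or (seed_mask & target_mask).any():
        raise ValueError("seed and target masks must not overlap")

    wide = scores.wide()
    pairs = [(subj, sess) for subj in wide.index for sess in wide.columns
             if np.isfinite(wide.loc[subj, sess])]
    n_with_2 = sum((wide.loc[s].notna().sum() >= 2) for s in wide.index)
    if n_with_2 < len(wide.index) / 2:
        raise ValueError("need >= 2 sessions for at least half the subjects")
    all_scores = np.array([wide.loc[s, j] for s, j in pairs])
    if score_center is None:
        score_center = float(all_scores.mean())

    rng = np.random.default_rng(seed)
    data: dict[tuple[str, str], np.ndarray] = {}
    for (subj, sess) in pairs:
        score = wide.loc[subj, sess]
        rho = np.clip(base_rho + effect_beta * (score - score_center),
                      -0.95, 0.95)
        vol = rng.normal(0.0, noise_sd, size=(*grid_shape, n_time))
        latent = rng.standard_normal(n_time)
        latent = (latent - latent.mean()) / latent.std()
        # seed voxels: shared latent plus small voxel noise
        sd_ix = np.where(seed_mask)
        vol[sd_ix] = latent + 0.1 * rng.standard_normal((len(sd_ix[0]), n_time))
        tg_ix = np.where(target_mask)
        eps = rng.standard_normal((len(tg_ix[0]), n_time))
        vol[tg_ix] = rho * latent + np.sqrt(1 - rho ** 2) * eps
        data[(subj, sess)] = vol
    return VoxelDataset(data=data, affine=np.asarray(affine, dtype=float),
                        tr_seconds=tr_seconds, seed_mask=seed_mask,
                        target_mask=target_mask, scores=scores)
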