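"""Shared in-memory containers for the analysis pipeline.

These are thin, validated data holders passed between pipeline stages:
ROI time series, correlation matrices, binary graphs at a target
connection density, clinical score tables, and voxel statistic maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed session vocabulary, in temporal order.
SESSIONS = ("pre", "post", "followup")

SESSION_ORDER = {s: i for i, s in enumerate(SESSIONS)}


def _check_session(label: str) -> str:
    if label not in SESSION_ORDER:
        raise ValueError(
            f"unknown session label {label!r}; expected one of {SESSIONS}"
        )
    return label


@dataclass
class TimeSeries:
    """A time x channel matrix sampled at a fixed repetition time.

    Parameters
    ----------
    values : ndarray, shape (n_time, n_channels)
        Signal values (arbitrary units). Must be finite.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    channel_labels : sequence of str
        One label per channel (e.g. ROI names).
    """

    values: np.ndarray
    tr_seconds: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x channel) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.values.shape[1])]
        if len(self.channel_labels) != self.values.shape[1]:
            raise ValueError("channel_labels length does not match n_channels")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(values=np.array(values, dtype=float),
                          tr_seconds=self.tr_seconds,
                          channel_labels=list(self.channel_labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_labels)


@dataclass
class ROITimeSeriesPanel:
    """ROI time series for every (subject, session) pair.

    ``entries`` maps ``(subject, session)`` to a :class:`TimeSeries`; all
    entries share the ROI label set.
    """

    entries: dict[tuple[str, str], TimeSeries]
    roi_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        for (subj, sess), ts in self.entries.items():
            _check_session(sess)
            if list(ts.channel_labels) != list(self.roi_labels):
                raise ValueError(
                    f"ROI labels of {subj}/{sess} disagree with the panel"
                )

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.entries})

    @property
    def sessions(self) -> list[str]:
        present = {sess for _, sess in self.entries}
        return [s for s in SESSIONS if s in present]

    def get(self, subject: str, session: str) -> TimeSeries:
        return self.entries[(subject, session)]

    def write_tsv(self, out_dir: str | Path) -> list[Path]:
        """One TSV per subject-session (header row = ROI labels)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for (subj, sess) in sorted(self.entries):
            p = out_dir / f"{subj}_{sess}_roi.tsv"
            self.entries[(subj, sess)].to_frame().to_csv(
                p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
        meta = out_dir / "panel.json"
        meta.write_text(json.dumps({"tr_seconds": self.tr_seconds,
                                    "roi_labels": self.roi_labels}, indent=1))
        written.append(meta)
        return written

    @classmethod
    def read_tsv(cls, in_dir: str | Path) -> "ROITimeSeriesPanel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "panel.json").read_text())
        entries: dict[tuple[str, str], TimeSeries] = {}
        for p in sorted(in_dir.glob("*_roi.tsv")):
            subj, sess, _ = p.stem.rsplit("_", 2)
            df = pd.read_csv(p, sep="\t")
            entries[(subj, sess)] = TimeSeries(
                df.to_numpy(), meta["tr_seconds"], list(df.columns))
        return cls(entries, meta["roi_labels"], meta["tr_seconds"])


@dataclass
class CorrMatrix:
    """ROI x ROI Pearson correlation matrix."""

    r: np.ndarray
    n_time: int
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if not self.node_labels:
            self.node_labels = [f"roi{i:03d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.node_labels,
                     columns=self.node_labels).to_csv(
            path, sep="\t", float_format="%.10g")


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph at a stated connection density."""

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    #: planted community membership, when generated synthetically
    planted_membership: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.uint8)
        if not self.node_labels:
            self.node_labels = [f"roi{i:03d}" for i in range(a.shape[0])]
        if self.planted_membership is not None:
            self.planted_membership = np.asarray(self.planted_membership, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency.astype(int))
        return g

    def edge_list(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, 1)
        keep = self.adjacency[iu] == 1
        return np.column_stack([iu[0][keep], iu[1][keep]])

    def to_edge_tsv(self, path: str | Path) -> None:
        edges = self.edge_list()
        pd.DataFrame({
            "node_i": [self.node_labels[i] for i in edges[:, 0]],
            "node_j": [self.node_labels[j] for j in edges[:, 1]],
        }).to_csv(path, sep="\t", index=False)

    def to_tsv(self, path: str | Path) -> None:
        """Square labeled adjacency matrix."""
        pd.DataFrame(self.adjacency.astype(int), index=self.node_labels,
                     columns=self.node_labels).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinaryGraph":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy().astype(np.uint8),
                   node_labels=[str(c) for c in df.columns])


@dataclass
class DynamicGraphSeries:
    """Ordered per-window binary graphs from a sliding-window analysis.

    ``graphs[w]`` is ``None`` when window ``w`` was flagged (e.g. a
    zero-variance channel inside the window).
    """

    graphs: list[BinaryGraph | None]
    window_width_tr: int
    step_tr: int
    node_labels: list[str]

    @property
    def n_windows(self) -> int:
        return len(self.graphs)

    @property
    def flagged(self) -> list[int]:
        return [w for w, g in enumerate(self.graphs) if g is None]

    def write_dir(self, out_dir: str | Path) -> list[Path]:
        """Numbered per-window edge lists plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for w, g in enumerate(self.graphs):
            if g is None:
                continue
            p = out / f"window{w:04d}_edges.tsv"
            g.to_edge_tsv(p)
            written.append(p)
        manifest = out / "manifest.json"
        manifest.write_text(json.dumps({
            "n_windows": self.n_windows,
            "window_width_tr": self.window_width_tr,
            "step_tr": self.step_tr,
            "flagged_windows": self.flagged,
            "node_labels": self.node_labels,
        }, indent=1))
        written.append(manifest)
        return written


class ScoreTable:
    """Long-format subject x session clinical scores (TFI etc.).

    Backed by a DataFrame with columns (subject, session, score, value);
    at most one value per (subject, session, score); missing sessions
    are simply absent rows.
    """

    COLUMNS = ["subject", "session", "score", "value"]

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, self.COLUMNS].copy()
        df["subject"] = df["subject"].astype(str)
        for s in df["session"]:
            _check_session(s)
        if df.duplicated(["subject", "session", "score"]).any():
            raise ValueError("duplicate (subject, session, score) rows")
        order = df["session"].map(SESSION_ORDER)
        self.df = df.assign(_o=order).sort_values(
            ["score", "subject", "_o"]).drop(columns="_o").reset_index(drop=True)

    @classmethod
    def from_wide(cls, values: Mapping[str, Mapping[str, float]],
                  score: str = "TFI") -> "ScoreTable":
        rows = [
            {"subject": subj, "session": sess, "score": score, "value": v}
            for subj, per_sess in values.items()
            for sess, v in per_sess.items()
        ]
        return cls(pd.DataFrame(rows))

    def get(self, subject: str, session: str, score: str = "TFI") -> float:
        m = self.df[(self.df.subject == str(subject))
                    & (self.df.session == session)
                    & (self.df.score == score)]
        if m.empty:
            raise KeyError((subject, session, score))
        return float(m["value"].iloc[0])

    def subjects(self, score: str = "TFI") -> list[str]:
        return sorted(self.df.loc[self.df.score == score, "subject"].unique())

    def wide(self, score: str = "TFI") -> pd.DataFrame:
        """subject x session table with NaN for missing sessions."""
        sub = self.df[self.df.score == score]
        w = sub.pivot(index="subject", columns="session", values="value")
        return w.reindex(columns=[s for s in SESSIONS if s in w.columns])

    def deltas(self, score: str = "TFI",
               pairs: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
        """Later-minus-earlier score changes per subject for session pairs.

        Defaults to consecutive pairs among the sessions present. Only
        subjects observed at both sessions of a pair appear.
        """
        w = self.wide(score)
        if pairs is None:
            present = list(w.columns)
            pairs = list(zip(present[:-1], present[1:]))
        rows = []
        for earlier, later in pairs:
            if earlier not in w.columns or later not in w.columns:
                continue
            ok = w[[earlier, later]].dropna()
            for subj, r in ok.iterrows():
                rows.append({"subject": subj, "earlier": earlier,
                             "later": later,
                             "delta_score": r[later] - r[earlier]})
        return pd.DataFrame(rows, columns=["subject", "earlier", "later",
                                           "delta_score"])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class StatMap:
    """A 3-D voxel grid of statistics with a voxel-to-mm affine.

    ``stat_kind`` is one of ``{"z", "beta", "t", "wald", "var"}``;
    ``df`` carries the degrees of freedom for ``t`` maps (Wald maps are
    referred to chi-squared with 1 df).
    """

    values: np.ndarray
    affine: np.ndarray
    stat_kind: str = "z"
    df: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        homog = np.column_stack([ijk, np.ones(len(ijk))])
        return (self.affine @ homog.T).T[:, :3]

    def mm_to_ijk(self, mm: np.ndarray) -> np.ndarray:
        mm = np.atleast_2d(mm)
        inv = np.linalg.inv(self.affine)
        homog = np.column_stack([mm, np.ones(len(mm))])
        return (inv @ homog.T).T[:, :3]

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float64), self.affine),
                 str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, stat_kind: str = "z",
                   df: float | None = None) -> "StatMap":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine, stat_kind, df)


@dataclass
class VoxelDataset:
    """Synthetic 4-D voxel data per subject-session with ground truth.

    ``data[(subject, session)]`` is an (x, y, z, t) array; ``seed_mask``
    and ``target_mask`` record the planted seed and coupled regions.
    """

    data: dict[tuple[str, str], np.ndarray]
    affine: np.ndarray
    tr_seconds: float
    seed_mask: np.ndarray
    target_mask: np.ndarray
    scores: "ScoreTable"

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        first = next(iter(self.data.values()))
        return first.shape[:3]

    def write_nifti(self, out_dir: str | Path) -> list[Path]:
        import nibabel as nib

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for (subj, sess) in sorted(self.data):
            p = out_dir / f"{subj}_{sess}_bold.nii"
            nib.save(nib.Nifti1Image(self.data[(subj, sess)].astype(np.float32),
                                     self.affine), str(p))
            written.append(p)
        for name, mask in (("seed", self.seed_mask), ("target", self.target_mask)):
            p = out_dir / f"{name}_mask.nii"
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), self.affine), str(p))
            written.append(p)
        return written
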