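"""Random-effects stochastic block model via co-regularized orthogonal
symmetric nonnegative matrix tri-factorization (Co-OSNTF).

Each subject's binary network A_s is factored as H_s S_s H_s^T with
nonnegative H_s (node x k memberships) and symmetric nonnegative core
S_s (k x k block connectivity); a co-regularization term pulls every
subject's projection H_s H_s^T toward a shared group projection H H^T,
so the group factor H captures the common community structure while
subjects deviate around it (the random effect). The objective is

    sum_s ||A_s - H_s S_s H_s^T||_F^2
    + lambda * sum_s ||H_s H_s^T - H H^T||_F^2
    + mu * (sum_s ||H_s^T H_s - I||_F^2 + ||H^T H - I||_F^2)

minimized by multiplicative updates (all factors stay nonnegative) with
a monotonicity safeguard: the recorded objective trace never increases.
lambda and mu are specified on a loss-normalized scale - each penalty is
rescaled by the data-fit term's value at initialization - so lambda=1
weights co-regularization comparably to the fit.

Group community comparison between sessions uses 1 - adjusted Rand
index between group memberships as the distance, with a within-subject
session-label sign-flip permutation null (exact enumeration when
2^n_subjects <= 1024). Node-level membership changes are scored after
optimal community label matching and tested against the same
permutation null with Benjamini-Hochberg control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .containers import BinaryGraph
from .graphmetrics import Partition, louvain_communities

_EPS = 1e-12


def select_k(graphs: list[BinaryGraph], seed: int,
             restarts: int = 20) -> int:
    """Community count for Co-OSNTF: median of per-graph Louvain counts,
    rounded half-up."""
    if not graphs:
        raise ValueError("need at least one graph")
    counts = []
    for i, g in enumerate(graphs):
        part = louvain_communities(g, seed=seed + 1000 * i, restarts=restarts)
        counts.append(part.n_communities)
    med = float(np.median(counts))
    return int(math.floor(med + 0.5))


@dataclass
class CommunityModel:
    """Fitted Co-OSNTF results.

    ``memberships`` is the argmax community per node of the shared basis
    H; ``subject_memberships[s]`` the same for subject s.
    """

    H: np.ndarray
    subject_H: list[np.ndarray]
    subject_S: list[np.ndarray]
    k: int
    objective_trace: np.ndarray
    converged: bool
    node_labels: list[str] = field(default_factory=list)

    @property
    def objective_value(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def memberships(self) -> np.ndarray:
        return np.asarray(self.H.argmax(axis=1), dtype=int)

    @property
    def subject_memberships(self) -> list[np.ndarray]:
        return [np.asarray(h.argmax(axis=1), dtype=int)
                for h in self.subject_H]

    @property
    def n_nodes(self) -> int:
        return self.H.shape[0]

    def orthogonality_error(self) -> float:
        return float(np.linalg.norm(self.H.T @ self.H - np.eye(self.k)))

    def summary(self) -> str:
        sizes = np.bincount(self.memberships, minlength=self.k)
        lines = [
            "Co-OSNTF random-effects stochastic block model",
            f"  nodes: {self.n_nodes}   subjects: {len(self.subject_H)}   "
            f"k: {self.k}",
            f"  final objective: {self.objective_value:.6g}   "
            f"converged: {self.converged}",
            f"  ||H'H - I||_F: {self.orthogonality_error():.3g}",
            f"  group community sizes: {sizes.tolist()}",
        ]
        return "\n".join(lines)

    def to_dir(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labels = self.node_labels or [f"roi{i:03d}"
                                      for i in range(self.n_nodes)]
        cols = [f"c{j}" for j in range(self.k)]
        pd.DataFrame(self.H, index=labels, columns=cols).to_csv(
            out / "H.tsv", sep="\t", float_format="%.10g")
        for s, h in enumerate(self.subject_H):
            pd.DataFrame(h, index=labels, columns=cols).to_csv(
                out / f"H_sub{s:02d}.tsv", sep="\t", float_format="%.10g")
        pd.DataFrame({"node": labels, "community": self.memberships}).to_csv(
            out / "memberships.tsv", sep="\t", index=False)
        (out / "fit.json").write_text(json.dumps({
            "k": self.k, "objective": self.objective_value,
            "converged": self.converged,
            "n_iterations": int(len(self.objective_trace)),
        }, indent=1))


def _objective(A, Hs, Ss, H, lam_eff, mu_eff):
    fit = sum(np.linalg.norm(a - h @ s @ h.T) ** 2
              for a, h, s in zip(A, Hs, Ss))
    HH = H @ H.T
    co = sum(np.linalg.norm(h @ h.T - HH) ** 2 for h in Hs)
    eye = np.eye(H.shape[1])
    ortho = sum(np.linalg.norm(h.T @ h - eye) ** 2 for h in Hs)
    ortho += np.linalg.norm(H.T @ H - eye) ** 2
    return fit + lam_eff * co + mu_eff * ortho


def _fit_once(A: list[np.ndarray], k: int, lam: float, mu: float,
              max_iter: int, tol: float, rng: np.random.Generator,
              init: tuple | None = None):
    n = A[0].shape[0]
    n_sub = len(A)
    if init is not None:
        H, Hs, Ss = init
        H = H.copy()
        Hs = [h.copy() for h in Hs]
        Ss = [s.copy() for s in Ss]
    else:
        Abar = np.mean(A, axis=0)
        w, v = np.linalg.eigh(Abar)
        top = v[:, np.argsort(np.abs(w))[::-1][:k]]
        # nonnegative projection: positive and negative parts of each
        # leading eigenvector are separate candidate columns; keep the k
        # with the largest norm (preserves community contrasts)
        cands = np.concatenate([np.clip(top, 0, None),
                                np.clip(-top, 0, None)], axis=1)
        norms = np.linalg.norm(cands, axis=0)
        base = cands[:, np.argsort(norms)[::-1][:k]]
        base = base / np.clip(np.linalg.norm(base, axis=0), _EPS, None)
        scale = 0.5 * base.max()
        H = base + scale * rng.random((n, k)) + _EPS
        Hs = [base + scale * rng.random((n, k)) + _EPS
              for _ in range(n_sub)]
        Ss = [np.clip(h.T @ a @ h, _EPS, None) for a, h in zip(A, Hs)]
        Ss = [(s + s.T) / 2 for s in Ss]

    # loss-normalized penalty weights, frozen at initialization
    fit0 = sum(np.linalg.norm(a - h @ s @ h.T) ** 2
               for a, h, s in zip(A, Hs, Ss))
    HH = H @ H.T
    co0 = sum(np.linalg.norm(h @ h.T - HH) ** 2 for h in Hs)
    eye = np.eye(k)
    or0 = sum(np.linalg.norm(h.T @ h - eye) ** 2 for h in Hs)
    or0 += np.linalg.norm(H.T @ H - eye) ** 2
    lam_eff = lam * fit0 / max(co0, 1e-3 * fit0, _EPS)
    mu_eff = mu * fit0 / max(or0, 1e-3 * fit0, _EPS)

    def _sweep(H, Hs, Ss, eta):
        """One damped multiplicative sweep; ratios are raised to the
        exponent ``eta`` (symmetric factorizations need damping)."""
        Ss = [s.copy() for s in Ss]
        Hs = [h.copy() for h in Hs]
        for s_ix in range(n_sub):
            h, a = Hs[s_ix], A[s_ix]
            hth = h.T @ h
            num = h.T @ a @ h + _EPS
            den = hth @ Ss[s_ix] @ hth + _EPS
            s_new = Ss[s_ix] * (num / den) ** eta
            Ss[s_ix] = (s_new + s_new.T) / 2
        HHt = H @ H.T
        for s_ix in range(n_sub):
            h, a, s = Hs[s_ix], A[s_ix], Ss[s_ix]
            hs = h @ s
            num = a @ hs + lam_eff * (HHt @ h) + mu_eff * h + _EPS
            den = (hs @ (h.T @ hs) + (lam_eff + mu_eff) * h @ (h.T @ h)
                   + _EPS)
            Hs[s_ix] = h * (num / den) ** eta
        sum_HsHst_H = np.zeros((n, k))
        for h in Hs:
            sum_HsHst_H += h @ (h.T @ H)
        num = lam_eff * sum_HsHst_H + mu_eff * H + _EPS
        den = ((lam_eff * n_sub + mu_eff) * H @ (H.T @ H) + _EPS)
        H = H * (num / den) ** eta
        return H, Hs, Ss

    trace = [_objective(A, Hs, Ss, H, lam_eff, mu_eff)]
    converged = False
    eta = 0.5
    for _ in range(max_iter):
        accepted = False
        step = eta
        for _try in range(5):
            H2, Hs2, Ss2 = _sweep(H, Hs, Ss, step)
            obj = _objective(A, Hs2, Ss2, H2, lam_eff, mu_eff)
            if obj <= trace[-1] * (1 + 1e-12):
                H, Hs, Ss = H2, Hs2, Ss2
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        rel = (trace[-1] - obj) / max(trace[-1], _EPS)
        trace.append(obj)
        if rel < tol:
            converged = True
            break
    return H, Hs, Ss, np.array(trace), converged


class CoOSNTF:
    """Co-OSNTF model over a group of subject networks.

    Parameters
    ----------
    graphs : list of BinaryGraph
        One network per subject, on a shared node set.
    k : int
        Number of communities (>= 2); see :func:`select_k`.
    lam : float
        Co-regularization weight on the loss-normalized scale.
    ortho_mu : float
        Orthogonality penalty weight (same scale).
    restarts : int
        Random restarts; the best final objective is kept.
    """

    def __init__(self, graphs: list[BinaryGraph], k: int, lam: float = 1.0,
                 ortho_mu: float = 1.0, max_iter: int = 300,
                 tol: float = 1e-6, restarts: int = 20, seed: int = 0):
        if k < 2:
            raise ValueError("k must be >= 2")
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        n = graphs[0].n_nodes
        labels = graphs[0].node_labels
        for g in graphs:
            if g.n_nodes != n or list(g.node_labels) != list(labels):
                raise ValueError("all graphs must share the node set")
        self.graphs = graphs
        self.k = k
        self.lam = lam
        self.ortho_mu = ortho_mu
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.seed = seed
        self.node_labels = list(labels)

    def fit(self, init: tuple | None = None) -> CommunityModel:
        A = [g.adjacency.astype(float) for g in self.graphs]
        best = None
        n_restarts = 1 if init is not None else self.restarts
        for r in range(n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, r]))
            H, Hs, Ss, trace, conv = _fit_once(
                A, self.k, self.lam, self.ortho_mu, self.max_iter,
                self.tol, rng, init=init)
            if best is None or trace[-1] < best[3][-1]:
                best = (H, Hs, Ss, trace, conv)
        H, Hs, Ss, trace, conv = best
        if not conv:
            import warnings

            warnings.warn("Co-OSNTF did not converge within max_iter",
                          UserWarning, stacklevel=2)
        return CommunityModel(H=H, subject_H=Hs, subject_S=Ss, k=self.k,
                              objective_trace=trace, converged=conv,
                              node_labels=self.node_labels)


def fit_cosontf(graphs: list[BinaryGraph], k: int, lam: float = 1.0,
                max_iter: int = 300, tol: float = 1e-6,
                seed: int = 0, restarts: int = 20,
                init: tuple | None = None) -> CommunityModel:
    """Functional wrapper around :class:`CoOSNTF`."""
    return CoOSNTF(graphs, k, lam=lam, max_iter=max_iter, tol=tol,
                   restarts=restarts, seed=seed).fit(init=init)


def group_structure_distance(model_a: CommunityModel,
                             model_b: CommunityModel) -> float:
    """d = 1 - adjusted Rand index between group memberships."""
    if model_a.n_nodes != model_b.n_nodes:
        raise ValueError("models must share the node set")
    return 1.0 - adjusted_rand_score(model_a.memberships,
                                     model_b.memberships)


def projection_distance(model_a: CommunityModel,
                        model_b: CommunityModel) -> float:
    """Continuous structure distance ||H_A H_A' - H_B H_B'||_F^2 / (2k).

    Label-permutation invariant and 0 for identical structures, like
    the Rand-based distance, but it does not saturate when the two
    structures share nothing: partial overlap still moves it. This is
    the permutation-test statistic (the Rand-based distance pins at its
    ceiling for disjoint structures, which destroys test power).
    """
    if model_a.n_nodes != model_b.n_nodes or model_a.k != model_b.k:
        raise ValueError("models must share node set and k")
    pa = model_a.H @ model_a.H.T
    pb = model_b.H @ model_b.H.T
    return float(np.linalg.norm(pa - pb) ** 2 / (2 * model_a.k))


def _match_labels(member_a: np.ndarray, member_b: np.ndarray,
                  k: int) -> np.ndarray:
    """Permutation pi maximizing agreement: community c of B maps to
    pi[c] of A (maximum-agreement assignment)."""
    confusion = np.zeros((k, k))
    for a, b in zip(member_a, member_b):
        confusion[a, b] += 1
    rows, cols = linear_sum_assignment(-confusion)
    pi = np.arange(k)
    pi[cols] = rows
    return pi


def node_change_scores(model_a: CommunityModel,
                       model_b: CommunityModel) -> np.ndarray:
    """Per-node change score between two fitted group structures.

    After optimal community label matching: 1 if the hard membership
    differs, plus the 2-norm of the (column-matched, row-normalized)
    basis row difference as a soft component.
    """
    if model_a.k != model_b.k or model_a.n_nodes != model_b.n_nodes:
        raise ValueError("models must share node set and k")
    k = model_a.k
    ma, mb = model_a.memberships, model_b.memberships
    pi = _match_labels(ma, mb, k)
    mb_matched = pi[mb]
    # reorder B's columns so B's column j sits where A's community pi[j] is
    order = np.empty(k, dtype=int)
    order[pi] = np.arange(k)
    Hb = model_b.H[:, order]

    def _rownorm(h):
        nrm = np.linalg.norm(h, axis=1, keepdims=True)
        return h / np.clip(nrm, _EPS, None)

    soft = np.linalg.norm(_rownorm(model_a.H) - _rownorm(Hb), axis=1)
    hard = (ma != mb_matched).astype(float)
    return hard + soft


@dataclass
class GlobalDifferenceResult:
    """Permutation test of a group community-structure difference.

    ``observed_d`` is the projection-distance statistic the p-value is
    computed from; ``observed_rand_d`` is the descriptive 1 - adjusted
    Rand distance between the two observed group structures.
    """

    p_value: float
    observed_d: float
    observed_rand_d: float
    null_d: np.ndarray
    exact: bool
    observed_node_scores: np.ndarray | None = None
    null_node_scores: np.ndarray | None = None

    def summary(self) -> str:
        kind = "exact sign-flip" if self.exact else "sampled sign-flip"
        return (f"global community-structure difference: d = "
                f"{self.observed_d:.4f} (1-ARI = {self.observed_rand_d:.4f})"
                f", p = {self.p_value:.4g} "
                f"({kind}, {len(self.null_d)} permutations)")


def test_global_difference(graphs_a: list[BinaryGraph],
                           graphs_b: list[BinaryGraph],
                           k: int,
                           n_perm: int = 199,
                           seed: int = 0,
                           lam: float = 1.0,
                           restarts: int = 3,
                           max_iter: int = 150,
                           collect_node_scores: bool = False,
                           max_exact: int = 1024) -> GlobalDifferenceResult:
    """Paired-session permutation test of group structure difference.

    Null: within each subject, session labels are exchangeable, so the
    null distribution of d is built by refitting after randomly swapping
    each subject's two networks. All fits (observed and permuted) use
    identical settings, preserving exchangeability. Exact enumeration of
    the 2^n swap patterns when that space is <= ``max_exact``; otherwise
    ``n_perm`` sampled patterns with the add-one p-value.
    """
    n_sub = len(graphs_a)
    if len(graphs_b) != n_sub:
        raise ValueError("paired sessions require equal-length lists")
    if n_sub < 3:
        raise ValueError("fewer than 3 paired subjects is untestable")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    def _d_for(flips: np.ndarray, fit_seed: int):
        import warnings as _warnings

        ga = [gb if f else ga_ for ga_, gb, f in zip(graphs_a, graphs_b, flips)]
        gb = [ga_ if f else gb_ for ga_, gb_, f in zip(graphs_a, graphs_b, flips)]
        with _warnings.catch_warnings():
            # reduced-budget fits; non-convergence is expected and benign
            _warnings.simplefilter("ignore", UserWarning)
            m_a = fit_cosontf(ga, k, lam=lam, seed=fit_seed,
                              restarts=restarts, max_iter=max_iter)
            m_b = fit_cosontf(gb, k, lam=lam, seed=fit_seed + 1,
                              restarts=restarts, max_iter=max_iter)
        d = projection_distance(m_a, m_b)
        rand_d = group_structure_distance(m_a, m_b)
        scores = (node_change_scores(m_a, m_b)
                  if collect_node_scores else None)
        return d, rand_d, scores

    exact = 2 ** n_sub <= max_exact
    if exact:
        patterns = [np.array([(i >> s) & 1 for s in range(n_sub)], bool)
                    for i in range(2 ** n_sub)]
    else:
        rng = np.random.default_rng(seed)
        patterns = [rng.random(n_sub) < 0.5 for _ in range(n_perm)]

    d_obs, rand_obs, s_obs = _d_for(np.zeros(n_sub, bool), seed)
    null_d, null_s = [], []
    for idx, pat in enumerate(patterns):
        d, _, s = _d_for(pat, seed + 7919 * (idx + 1))
        null_d.append(d)
        if collect_node_scores:
            null_s.append(s)
    null_d = np.array(null_d)
    if exact:
        # identity pattern is in the enumeration; p >= 1/2^n
        p = float(np.mean(null_d >= d_obs - 1e-12))
    else:
        p = float((1 + np.sum(null_d >= d_obs - 1e-12)) / (1 + len(null_d)))
    return GlobalDifferenceResult(
        p_value=p, observed_d=d_obs, observed_rand_d=rand_obs,
        null_d=null_d, exact=exact, observed_node_scores=s_obs,
        null_node_scores=np.array(null_s) if collect_node_scores else None)


def test_node_membership_change(model_a: CommunityModel,
                                model_b: CommunityModel,
                                perm_null: np.ndarray,
                                fdr_q: float = 0.05) -> pd.DataFrame:
    """Per-node membership-change test with BH control.

    ``perm_null`` is an (n_perm, n_nodes) array of null change scores
    from sign-flip refits (see :func:`test_global_difference` with
    ``collect_node_scores=True``).
    """
    from statsmodels.stats.multitest import multipletests

    obs = node_change_scores(model_a, model_b)
    perm_null = np.asarray(perm_null)
    n_perm = perm_null.shape[0]
    p = (1 + (perm_null >= obs[None, :] - 1e-12).sum(axis=0)) / (1 + n_perm)
    _, p_bh, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    labels = model_a.node_labels or [f"roi{i:03d}"
                                     for i in range(model_a.n_nodes)]
    return pd.DataFrame({
        "node": labels,
        "changed": (model_a.memberships
                    != _match_labels(model_a.memberships,
                                     model_b.memberships,
                                     model_a.k)[model_b.memberships]),
        "score": obs,
        "p_raw": p,
        "p_bh": p_bh,
        "flag": p_bh <= fdr_q,
    })
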