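"""Supervised admixture estimation and the admixture genomic distance d.

`estimate_admixture` projects an individual's dosage vector onto the
K-simplex of mixing proportions over a *fixed* panel of ancestral allele
frequencies by constrained least squares,

    minimize  sum_l (dosage_l / 2 - sum_k q_k F_lk)^2
    s.t.      q >= 0,  sum(q) = 1,

solved with a monotone projected-gradient scheme (Euclidean simplex
projection, fixed 1/Lipschitz step).  `admixture_distance` is the minimal
Euclidean distance from one admixture vector to any member of a target
cohort; `build_graph` links every pair of individuals closer than a strict
threshold (default 0.075).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import MISSING
from .synthetic_data import AncestralFrequencies, validate_admixture_vector

__all__ = [
    "ConvergenceError",
    "project_to_simplex",
    "estimate_admixture",
    "estimate_admixture_matrix",
    "admixture_distance",
    "build_graph",
    "graph_components",
    "cohort_component_summary",
]

DEFAULT_THRESHOLD = 0.075
_IDENT_TOL = 1e-12


class ConvergenceError(RuntimeError):
    pass


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of v onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, len(v) + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def _check_identifiable(F: np.ndarray, names: Sequence[str] | None = None) -> None:
    K = F.shape[1]
    for a in range(K):
        for b in range(a + 1, K):
            if np.linalg.norm(F[:, a] - F[:, b]) < _IDENT_TOL:
                la = names[a] if names else str(a)
                lb = names[b] if names else str(b)
                raise ValueError(f"duplicate ancestral columns {la!r}/{lb!r}")


def estimate_admixture(
    dosages: np.ndarray,
    F: AncestralFrequencies | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Estimate the simplex-constrained mixing vector for one individual.

    Missing dosage cells are dropped from the objective.  Iterates projected
    gradient steps until the objective decreases by less than ``tol``;
    deterministic (fixed uniform start).  The objective trace is
    non-increasing by construction of the 1/L step.
    """
    names = F.component_names if isinstance(F, AncestralFrequencies) else None
    Fm = F.F if isinstance(F, AncestralFrequencies) else np.asarray(F, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if d.shape[0] != Fm.shape[0]:
        raise ValueError(
            f"dosage length {d.shape[0]} != F rows {Fm.shape[0]}"
        )
    _check_identifiable(Fm, names)
    ok = (d != MISSING) & ~np.isnan(d)
    y = d[ok] / 2.0
    X = Fm[ok, :]
    K = Fm.shape[1]

    # quadratic form: f(q) = q'Aq - 2 b'q + const
    A = X.T @ X
    b = X.T @ y
    lip = 2.0 * float(np.linalg.eigvalsh(A)[-1])
    if lip <= 0.0:  # no informative markers; flat answer
        q = np.full(K, 1.0 / K)
        return (q, [0.0]) if return_trace else q
    step = 1.0 / lip

    q = np.full(K, 1.0 / K)

    def objective(qv: np.ndarray) -> float:
        r = X @ qv - y
        return float(r @ r)

    trace = [objective(q)]
    for _ in range(max_iter):
        grad = 2.0 * (A @ q - b)
        q_new = project_to_simplex(q - step * grad)
        f_new = objective(q_new)
        if f_new > trace[-1] + 1e-15:  # cannot happen with a 1/L step
            break
        decrease = trace[-1] - f_new
        q = q_new
        trace.append(f_new)
        if decrease < tol:
            return (q, trace) if return_trace else q
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations; final objective {trace[-1]:.6g}"
    )


def estimate_admixture_matrix(
    dosage_matrix: np.ndarray,
    F: AncestralFrequencies | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Row-wise `estimate_admixture` over an n x L dosage matrix."""
    dosage_matrix = np.asarray(dosage_matrix)
    return np.stack(
        [
            estimate_admixture(dosage_matrix[i], F, tol=tol, max_iter=max_iter)
            for i in range(dosage_matrix.shape[0])
        ]
    )


def admixture_distance(
    q: np.ndarray, population_Q: Sequence[np.ndarray] | np.ndarray
) -> float:
    """Minimal Euclidean distance from q to any member of the population."""
    q = validate_admixture_vector(q)
    P = np.atleast_2d(np.asarray(population_Q, dtype=float))
    if P.shape[0] == 0:
        raise ValueError("population is empty")
    if P.shape[1] != q.shape[0]:
        raise ValueError("q and population members must share K")
    return float(np.min(np.linalg.norm(P - q[None, :], axis=1)))


def build_graph(
    Q_all: Mapping[str, np.ndarray],
    threshold: float = DEFAULT_THRESHOLD,
    populations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected graph with an edge wherever pairwise distance < threshold.

    The cutoff is strict; node attribute ``population`` carries the tag when
    provided.  The edge set is invariant under node reordering.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids = list(Q_all)
    M = np.stack([validate_admixture_vector(Q_all[i]) for i in ids]) if ids else (
        np.empty((0, 0))
    )
    g = nx.Graph()
    for i in ids:
        g.add_node(i, population=(populations or {}).get(i, ""))
    for a in range(len(ids)):
        diffs = M[a + 1 :] - M[a]
        dists = np.linalg.norm(diffs, axis=1)
        for off in np.flatnonzero(dists < threshold):
            b = a + 1 + off
            g.add_edge(ids[a], ids[b], weight=float(dists[off]))
    return g


def graph_components(g: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties broken by smallest member)."""
    comps = [set(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def cohort_component_summary(
    Q_all: Mapping[str, np.ndarray],
    grouping: Mapping[str, str],
    component_names: Sequence[str],
) -> pd.DataFrame:
    """Per-group mean +/- SD of each component, in percent.

    Mirrors the layout of published per-community admixture summaries; SD is
    the sample standard deviation (ddof=1), reported as 0 with a warning for
    singleton groups.  Group means sum to 100% by linearity.
    """
    import warnings

    rows = []
    groups = sorted(set(grouping.values()))
    for grp in groups:
        member_ids = [i for i in Q_all if grouping.get(i) == grp]
        M = np.stack([validate_admixture_vector(Q_all[i]) for i in member_ids]) * 100.0
        if M.shape[0] < 2:
            warnings.warn(f"group {grp!r} has < 2 members; SD reported as 0")
            sd = np.zeros(M.shape[1])
        else:
            sd = M.std(axis=0, ddof=1)
        mean = M.mean(axis=0)
        for k, name in enumerate(component_names):
            rows.append(
                {
                    "group": grp,
                    "component": name,
                    "mean_percent": mean[k],
                    "sd_percent": sd[k],
                    "n": M.shape[0],
                }
            )
    return pd.DataFrame(rows)


def population_distance(
    Q_members: Sequence[np.ndarray], Q_target: Sequence[np.ndarray]
) -> float:
    """Median member-wise d to the target cohort (a repo convention, not a
    published aggregate)."""
    ds = [admixture_distance(q, Q_target) for q in Q_members]
    return float(np.median(ds))
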