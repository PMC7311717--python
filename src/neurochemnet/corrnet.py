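"""Per-state Pearson coexpression networks over the analyte panel.

Correlations are computed from each state's time-series observation
vectors (one row per mouse x sample, ordered by mouse then sample).
Networks keep edges with r >= tau (signed, default tau = 0.5, boundary
inclusive) or |r| >= tau in absolute mode. A random-matrix-theory
threshold selector is provided for larger panels: it picks the smallest
threshold at which the eigenvalue nearest-neighbor spacing statistics of
the thresholded matrix look Poisson (uncorrelated blocks) rather than
Wigner-Dyson (one mixed bulk); for small panels such as the default
8-analyte one the spacing statistics are unstable and the selector falls
back to the fixed 0.5 rule with a warning. Topological overlap (TOM)
summarizes shared neighborhood structure, and cross-network reports
compare wake vs. anesthesia topologies by edge Jaccard, TOM cosine
similarity and per-node degree change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from .panel import ValidationError
from .preprocess import FeatureMatrix

__all__ = [
    "CorrMatrix",
    "pearson_matrix",
    "build_network",
    "select_threshold_rmt",
    "topological_overlap",
    "cross_network_overlap",
]

DEFAULT_TAU = 0.5
RMT_MIN_NODES = 20


@dataclass
class CorrMatrix:
    """Symmetric analyte x analyte Pearson matrix with pair counts."""

    values: pd.DataFrame
    n_pairs: pd.DataFrame
    state: str | None = None

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


def pearson_matrix(features: FeatureMatrix, state: str | None = None) -> CorrMatrix:
    """Pearson correlations over one state's observation rows.

    Pairwise-complete if any absences remain; a constant column has no
    defined correlation and raises an error naming the analyte.
    """
    frame = features.rows_for_state(state)
    frame = frame.sort_index(level=["mouse_id", "sample_index"])
    sd = frame.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValidationError(
            f"correlation undefined for constant analyte column: {constant.index[0]}"
        )
    n = frame.notna().astype(int)
    n_pairs = n.T @ n
    if (n_pairs.to_numpy()[np.triu_indices(len(n_pairs), 1)] < 3).any():
        raise ValidationError("need >= 3 complete pairs per correlation cell")
    corr = frame.corr(method="pearson", min_periods=3)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr.values, 1.0)
    return CorrMatrix(values=corr, n_pairs=n_pairs, state=state)


def build_network(corr: CorrMatrix, tau: float = DEFAULT_TAU, signed: bool = True) -> nx.Graph:
    """Threshold a correlation matrix into an undirected network.

    Edge (i, j) iff r_ij >= tau (signed mode, the default: "0.5 or
    greater") or |r_ij| >= tau (absolute mode); edge weights carry r.
    """
    if not (0 < tau <= 1):
        raise ValidationError(f"tau must lie in (0, 1], got {tau}")
    g = nx.Graph(tau=float(tau), signed=bool(signed), state=corr.state or "")
    g.add_nodes_from(corr.analytes)
    vals = corr.values
    for i, a in enumerate(corr.analytes):
        for b in corr.analytes[i + 1 :]:
            r = float(vals.loc[a, b])
            keep = (r >= tau) if signed else (abs(r) >= tau)
            if keep:
                g.add_edge(a, b, weight=r)
    return g


def _wigner_cdf(s: np.ndarray) -> np.ndarray:
    # Wigner surmise (GOE) spacing CDF: 1 - exp(-pi s^2 / 4)
    return 1.0 - np.exp(-np.pi * s**2 / 4.0)


def _ks_distance(spacings: np.ndarray, cdf) -> float:
    s = np.sort(spacings)
    ecdf_hi = np.arange(1, len(s) + 1) / len(s)
    ecdf_lo = np.arange(0, len(s)) / len(s)
    model = cdf(s)
    return float(np.max(np.maximum(np.abs(ecdf_hi - model), np.abs(ecdf_lo - model))))


def eigen_spacings(matrix: np.ndarray, trim: float = 0.05, window: int = 7) -> np.ndarray:
    """Unfolded nearest-neighbor eigenvalue spacings.

    The spectrum tails are trimmed (``trim`` per side) and each spacing is
    normalized by a moving-average local mean spacing, the simplest stable
    unfolding; the result has unit local mean so its distribution can be
    compared against the Poisson and Wigner-Dyson spacing laws.
    """
    w = np.sort(np.linalg.eigvalsh(matrix))
    n = len(w)
    k = int(np.floor(trim * n))
    if k:
        w = w[k : n - k]
    d = np.diff(w)
    if len(d) == 0:
        return d
    pad = window // 2
    padded = np.pad(d, pad, mode="edge")
    local = np.convolve(padded, np.ones(window) / window, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        s = d / np.where(local > 0, local, np.nan)
    return s[np.isfinite(s)]


def select_threshold_rmt(
    corr: CorrMatrix | pd.DataFrame | np.ndarray,
    grid=None,
    fallback: float = DEFAULT_TAU,
    min_nodes: int = RMT_MIN_NODES,
) -> float:
    """Pick a correlation threshold by random-matrix-theory spacing tests.

    For each candidate tau (ascending) the sub-threshold entries are
    zeroed and the nearest-neighbor spacing distribution of the resulting
    matrix's eigenvalues is compared (Kolmogorov-Smirnov) with the Poisson
    law 1 - exp(-s) and the Wigner-Dyson surmise. The smallest tau whose
    spacings are closer to Poisson is returned. Matrices with fewer than
    ``min_nodes`` nodes (e.g., the default 8-analyte panel) have too few
    spacings for a stable decision: the fixed default is returned with a
    warning.
    """
    if isinstance(corr, CorrMatrix):
        values = corr.values.to_numpy(float)
    else:
        values = np.asarray(corr, dtype=float) if not isinstance(corr, pd.DataFrame) else corr.to_numpy(float)
    if grid is None:
        grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("candidate threshold grid is empty")
    grid = np.sort(grid)
    n = values.shape[0]
    if n < min_nodes:
        warnings.warn(
            f"{n} nodes is too small for stable eigenvalue spacing statistics; "
            f"falling back to tau = {fallback}",
            stacklevel=2,
        )
        return float(fallback)
    poisson_cdf = lambda s: 1.0 - np.exp(-s)  # noqa: E731
    for tau in grid:
        m = np.where(np.abs(values) >= tau, values, 0.0)
        np.fill_diagonal(m, 1.0)
        s = eigen_spacings(m)
        if len(s) < max(10, n // 4):  # spectrum collapsed to degeneracies
            continue
        d_poisson = _ks_distance(s, poisson_cdf)
        d_wigner = _ks_distance(s, _wigner_cdf)
        if d_poisson < d_wigner:
            return float(tau)
    warnings.warn(
        f"no candidate threshold reached Poisson spacing statistics; "
        f"falling back to tau = {fallback}",
        stacklevel=2,
    )
    return float(fallback)


def topological_overlap(network: nx.Graph) -> pd.DataFrame:
    """Unweighted topological overlap matrix of a thresholded network.

    TOM_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (0/0 := 0), and 1 on the diagonal.
    """
    nodes = list(network.nodes)
    a = nx.to_numpy_array(network, nodelist=nodes, weight=None)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    numer = shared + a
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    tom = np.where(numer == 0, 0.0, tom)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=nodes, columns=nodes)


def cross_network_overlap(net_a: nx.Graph, net_b: nx.Graph) -> dict:
    """Compare two same-panel networks: edge Jaccard, TOM cosine
    similarity over off-diagonal entries, and per-node degree change."""
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValidationError("networks must share the same analyte panel")
    edges_a = {frozenset(e) for e in net_a.edges}
    edges_b = {frozenset(e) for e in net_b.edges}
    union = edges_a | edges_b
    jaccard = 1.0 if not union else len(edges_a & edges_b) / len(union)

    nodes = sorted(net_a.nodes)
    tom_a = topological_overlap(net_a).loc[nodes, nodes].to_numpy()
    tom_b = topological_overlap(net_b).loc[nodes, nodes].to_numpy()
    iu = np.triu_indices(len(nodes), 1)
    va, vb = tom_a[iu], tom_b[iu]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 and nb == 0:
        tom_cosine = 1.0
    elif na == 0 or nb == 0:
        tom_cosine = 0.0
    else:
        tom_cosine = float(va @ vb / (na * nb))

    degree_change = {
        n: int(net_b.degree(n)) - int(net_a.degree(n)) for n in nodes
    }
    return {
        "edge_jaccard": float(jaccard),
        "tom_cosine": tom_cosine,
        "degree_change": degree_change,
        "n_edges_a": len(edges_a),
        "n_edges_b": len(edges_b),
    }
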