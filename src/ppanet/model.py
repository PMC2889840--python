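"""Stage-wise dynamic-model fitting and AIC pruning of the rough network.

For a target protein *p* with candidate interactors *q = 1..Q* (its rough-
network neighbourhood), protein abundance follows a linear stochastic
update::

    y_p[t+1] = y_p[t] + sum_q b_pq * y_q[t] + alpha_p * x_p[t]
               - beta_p * y_p[t] + omega_p[t]

where ``x_p`` is the mRNA track, ``alpha_p >= 0`` the translation gain,
``beta_p in [0, 1]`` the degradation rate, ``b_pq`` signed association
coefficients and ``omega_p`` zero-mean Gaussian noise.  Within each stage
window the coefficients are identified by constrained least squares over
the window's transitions, and the Akaike Information Criterion selects how
many interactors to retain (the most parsimonious model order).  Only
retained associations survive into that stage's refined network.

Two fitting modes exist.  *Full* mode uses distinct protein and mRNA
tracks; the unit coefficient on ``y_p[t]`` is absorbed into the response
(``y_p[t+1] - y_p[t]``) so alpha and beta are identifiable and all
constrained coefficients are nonnegative.  *Proxy* mode — the default for
microarray input, where protein abundance is unobserved and measured mRNA
stands in for it — collapses translation and degradation into a single
unconstrained self-coefficient ``a_p = 1 + alpha_p - beta_p``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .network import RoughPPAN
from .timecourse import ExpressionMatrix, StageWindow

logger = logging.getLogger(__name__)

PROXY = "proxy"
FULL = "full"

#: Floor for RSS/N inside the AIC log, guarding exact fits.
RSS_FLOOR = 1e-12


@dataclass
class RegressionSystem:
    """One target's design matrix over a window's transitions."""

    target: str
    X: np.ndarray  # (N transitions) x (c self columns + k candidates)
    y: np.ndarray  # response, length N
    columns: list[str]  # self-column tags then candidate symbols
    lower: np.ndarray
    upper: np.ndarray
    n_self: int  # c: always-included self columns
    candidates: list[str]  # candidate symbols, in column order
    excluded: list[str] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.y)


def build_regression_system(
    target: str,
    window: StageWindow,
    data: dict[str, np.ndarray],
    candidates: list[str],
    mode: str = PROXY,
    mrna: dict[str, np.ndarray] | None = None,
) -> RegressionSystem:
    """Assemble the least-squares system for one target over one window.

    ``data`` maps symbols to full-grid profiles (protein tracks, or mRNA
    standing in for them in proxy mode); ``mrna`` supplies the mRNA track
    of the target in full mode.  One row per transition t -> t+1 inside the
    window.  Candidates lacking a profile are excluded with a warning.
    """
    if mode not in (PROXY, FULL):
        raise ValueError(f"unknown mode {mode!r}")
    if target not in data:
        raise KeyError(f"no profile for target {target!r}")
    idx = np.asarray(window.point_indices)
    cur, nxt = idx[:-1], idx[1:]
    yp = data[target]
    kept, excluded = [], []
    for q in candidates:
        (kept if q in data else excluded).append(q)
    if excluded:
        logger.warning(
            "target %s: candidates without profiles excluded: %s",
            target,
            ", ".join(excluded),
        )
    cols, names, lo, hi = [], [], [], []
    if mode == PROXY:
        response = yp[nxt]
        cols.append(yp[cur])
        names.append("self")
        lo.append(-np.inf)
        hi.append(np.inf)
        n_self = 1
    else:
        if mrna is None or target not in mrna:
            raise KeyError(f"full mode requires an mRNA track for {target!r}")
        response = yp[nxt] - yp[cur]
        cols.append(mrna[target][cur])  # alpha: translation gain
        names.append("alpha")
        lo.append(0.0)
        hi.append(np.inf)
        cols.append(-yp[cur])  # beta: degradation rate
        names.append("beta")
        lo.append(0.0)
        hi.append(1.0)
        n_self = 2
    for q in kept:
        cols.append(data[q][cur])
        names.append(q)
        lo.append(-np.inf)
        hi.append(np.inf)
    X = np.column_stack(cols) if cols else np.empty((len(cur), 0))
    return RegressionSystem(
        target=target,
        X=X,
        y=np.asarray(response, dtype=float),
        columns=names,
        lower=np.array(lo),
        upper=np.array(hi),
        n_self=n_self,
        candidates=kept,
        excluded=excluded,
    )


def constrained_least_squares(
    X: np.ndarray,
    y: np.ndarray,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Box-constrained least squares: minimise ||X theta - y||^2, lo<=theta<=hi.

    Returns (theta_hat, RSS, degenerate).  With no finite bounds the exact
    minimum-norm solution is used; ``degenerate`` flags rank deficiency.
    Deterministic for a given system.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("design matrix must have at least one row")
    ncol = X.shape[1]
    if ncol == 0:
        return np.empty(0), float(y @ y), False
    lo = np.full(ncol, -np.inf) if lower is None else np.asarray(lower, float)
    hi = np.full(ncol, np.inf) if upper is None else np.asarray(upper, float)
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound")
    rank = np.linalg.matrix_rank(X)
    degenerate = rank < ncol
    if not np.any(np.isfinite(lo)) and not np.any(np.isfinite(hi)):
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        res = lsq_linear(X, y, bounds=(lo, hi), method="bvls" if rank == ncol else "trf")
        theta = res.x
    resid = y - X @ theta
    return theta, float(resid @ resid), degenerate


@dataclass
class FitResult:
    """Outcome of AIC model selection for one target in one stage window."""

    target: str
    stage: int
    selected: tuple[str, ...]  # the Q' retained interactors
    coefficients: dict[str, float]  # b_pq for selected q
    self_terms: dict[str, float]  # {'a': ...} or {'alpha': ..., 'beta': ...}
    rss: float
    n_transitions: int
    aic_trace: list[tuple[int, float]]
    k_star: int

    @property
    def aic(self) -> float:
        return dict(self.aic_trace)[self.k_star]


def aic(n: int, rss: float, n_params: int, corrected: bool = True) -> float:
    """Gaussian-likelihood AIC up to an additive constant.

    With ``corrected=True`` (the default) the small-sample correction
    ``2 p (p + 1) / (n - p - 1)`` is added; stage windows supply very few
    transitions, where the uncorrected criterion badly overfits.  The
    correction is infinite when ``n - p - 1 <= 0``.
    """
    base = n * np.log(max(rss / n, RSS_FLOOR)) + 2.0 * n_params
    if not corrected:
        return base
    dof = n - n_params - 1
    return base + (2.0 * n_params * (n_params + 1) / dof if dof > 0 else np.inf)


def _fit_subset(
    system: RegressionSystem, cols: list[int]
) -> tuple[np.ndarray, float]:
    theta, rss, _ = constrained_least_squares(
        system.X[:, cols], system.y, system.lower[cols], system.upper[cols]
    )
    return theta, rss


def _greedy_order(system: RegressionSystem, k_max: int) -> list[str]:
    """Forward-selection ordering: each step adds the candidate giving the
    largest residual-sum-of-squares drop (ties to the smaller symbol)."""
    c = system.n_self
    col = {s: c + j for j, s in enumerate(system.candidates)}
    order: list[str] = []
    remaining = sorted(system.candidates)
    current = list(range(c))
    while remaining and len(order) < k_max:
        best: tuple[float, str] | None = None
        for q in remaining:
            _, rss = _fit_subset(system, current + [col[q]])
            if best is None or rss < best[0] - 1e-15:
                best = (rss, q)
        order.append(best[1])
        remaining.remove(best[1])
        current.append(col[best[1]])
    return order


def _model_family(
    system: RegressionSystem, k_max: int, exhaustive_limit: int
) -> list[list[tuple[str, ...]]]:
    """Candidate subsets to evaluate at each order k = 0..k_max.

    Small neighbourhoods are searched exhaustively (best subset per order);
    larger ones fall back to the nested prefixes of a greedy forward-
    selection ordering.
    """
    cand = sorted(system.candidates)
    if len(cand) <= exhaustive_limit:
        return [
            [tuple(sub) for sub in itertools.combinations(cand, k)]
            for k in range(k_max + 1)
        ]
    order = _greedy_order(system, k_max)
    return [[tuple(sorted(order[:k]))] for k in range(k_max + 1)]


def aic_model_selection(
    target: str,
    window: StageWindow,
    data: dict[str, np.ndarray],
    candidates: list[str],
    mode: str = PROXY,
    mrna: dict[str, np.ndarray] | None = None,
    corrected: bool = True,
    exhaustive_limit: int = 12,
) -> FitResult | None:
    """Select the most parsimonious interactor set for one target.

    Evaluates model orders k = 0..k_max (k_max = min(Q, N - c - 1)): at
    each order the best candidate subset by constrained least squares is
    scored with AIC(k) = N ln(RSS_k / N) + 2 (k + c) (plus the small-sample
    correction unless ``corrected=False``), and the minimum-AIC order wins
    (ties to smaller k).  Neighbourhoods up to ``exhaustive_limit``
    candidates are searched exhaustively per order; larger ones use the
    nested prefixes of a greedy forward-selection ordering.  Returns None
    when the window is too short (N < c + 1), which is logged and skipped.
    """
    system = build_regression_system(target, window, data, candidates, mode, mrna)
    n, c = system.n_transitions, system.n_self
    if n < c + 1:
        logger.warning(
            "target %s stage %d: %d transitions < %d; skipped",
            target,
            window.index,
            n,
            c + 1,
        )
        return None
    k_max = min(len(system.candidates), n - c - 1)
    col_of = {sym: c + j for j, sym in enumerate(system.candidates)}
    family = _model_family(system, k_max, exhaustive_limit)
    trace: list[tuple[int, float]] = []
    best: tuple[float, int, np.ndarray, list[int]] | None = None
    for k, subsets in enumerate(family):
        best_k: tuple[float, np.ndarray, list[int]] | None = None
        for subset in subsets:
            cols = list(range(c)) + sorted(col_of[s] for s in subset)
            theta, rss = _fit_subset(system, cols)
            if best_k is None or rss < best_k[0] - 1e-15:
                best_k = (rss, theta, cols)
        rss_k, theta_k, cols_k = best_k
        a = aic(n, rss_k, k + c, corrected)
        trace.append((k, a))
        if best is None or a < best[0] - 1e-12:
            best = (a, k, theta_k, cols_k)
    _, k_star, theta, cols = best
    names = [system.columns[j] for j in cols]
    selected = tuple(nm for nm in names if nm not in ("self", "alpha", "beta"))
    coeffs = {
        nm: float(th)
        for nm, th in zip(names, theta)
        if nm not in ("self", "alpha", "beta")
    }
    self_terms = {
        ("a" if nm == "self" else nm): float(th)
        for nm, th in zip(names, theta)
        if nm in ("self", "alpha", "beta")
    }
    resid = system.y - system.X[:, cols] @ theta
    rss_val = float(resid @ resid)
    return FitResult(
        target=target,
        stage=window.index,
        selected=selected,
        coefficients=coeffs,
        self_terms=self_terms,
        rss=rss_val,
        n_transitions=n,
        aic_trace=trace,
        k_star=k_star,
    )


@dataclass
class RefinedPPAN:
    """One stage's pruned association network.

    Undirected edges carry a ``direction`` annotation recording which
    selections produced them: ``"a->b"``, ``"b->a"`` (alphabetical pair
    order) or ``"both"``.  Only non-isolated proteins are nodes.
    """

    stage: int
    label: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def top_hubs(self, n: int = 5) -> list[str]:
        """Highest-degree proteins (ties broken alphabetically)."""
        deg = sorted(self.graph.degree, key=lambda kv: (-kv[1], kv[0]))
        return [sym for sym, _ in deg[:n]]


def refine_stage(
    rough: RoughPPAN,
    window: StageWindow,
    data: dict[str, np.ndarray],
    mode: str = PROXY,
    mrna: dict[str, np.ndarray] | None = None,
) -> tuple[RefinedPPAN, list[FitResult]]:
    """Prune the rough network within one stage window, target by target.

    Each pool protein with a profile is fitted; the association (q, p) is
    retained iff q is in the target's selected set.  Directed selections
    are then symmetrised into undirected edges with a direction annotation.
    """
    fits: list[FitResult] = []
    directed: dict[tuple[str, str], float] = {}
    for target in rough.nodes:
        if target not in data:
            continue
        candidates = [q for q in rough.neighborhood(target) if q in data]
        fit = aic_model_selection(target, window, data, candidates, mode, mrna)
        if fit is None:
            continue
        fits.append(fit)
        for q in fit.selected:
            directed[(q, target)] = fit.coefficients[q]
    g = nx.Graph()
    for (q, p), b in directed.items():
        a, bnode = sorted((q, p))
        if g.has_edge(a, bnode):
            g.edges[a, bnode]["direction"] = "both"
        else:
            g.add_edge(a, bnode, direction=f"{q}->{p}")
        g.edges[a, bnode][f"b_{q}_to_{p}"] = b
    refined = RefinedPPAN(stage=window.index, label=window.label(), graph=g)
    return refined, fits


def refine_all_stages(
    rough: RoughPPAN,
    windows: list[StageWindow],
    data: dict[str, np.ndarray],
    mode: str = PROXY,
    mrna: dict[str, np.ndarray] | None = None,
) -> tuple[list[RefinedPPAN], list[FitResult], pd.DataFrame]:
    """Refine every stage window; also build the stage summary table.

    The summary has one row per stage: duration label, node count, edge
    count and the five highest-degree hub proteins.
    """
    networks, all_fits, rows = [], [], []
    for window in windows:
        refined, fits = refine_stage(rough, window, data, mode, mrna)
        networks.append(refined)
        all_fits.extend(fits)
        rows.append(
            {
                "stage": window.index,
                "duration": window.label(),
                "nodes": refined.n_nodes,
                "edges": refined.n_edges,
                "hubs": " ".join(refined.top_hubs(5)),
            }
        )
    summary = pd.DataFrame(rows)
    return networks, all_fits, summary


def profiles_dict(matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
    """Expression matrix -> {symbol: full-grid profile} for the fitters."""
    return {rid: matrix.frame.loc[rid].to_numpy(dtype=float) for rid in matrix.row_ids}
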