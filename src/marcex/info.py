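"""Entropy / mutual-information dependency analysis of factors and responses.

Quantifies, in bits, how much knowing one variable reduces uncertainty about
another: the extraction temperature versus each yield response, and the
responses among themselves.  All quantities use the plug-in (maximum
likelihood) estimator on discretized values with base-2 logarithms:

    H(X)    = −Σ p(x) log2 p(x)
    MI(X,Y) = H(X) + H(Y) − H(X,Y)  ≥ 0,  symmetric, ≤ min(H(X), H(Y))

No small-sample bias correction is applied — the factorial experiment has
only 15 condition means, and the analysis is read as an ordering of
dependencies, not as unbiased effect sizes.  Because the bit values depend
on how continuous responses are binned, the discretization is an explicit
:class:`DiscretizationSpec`, is recorded in every output, and
:func:`mi_sensitivity` sweeps bin counts to check that the qualitative
ordering survives.

Defaults: the temperature factor keeps its natural distinct levels; each
response is cut into 3 equal-width bins (mirroring the 3-level factor).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import ExtractionDataset

__all__ = [
    "DiscretizationSpec",
    "JointDistribution",
    "DependencyGraph",
    "MutualInformationModel",
    "DependencyResults",
    "discretize",
    "entropy",
    "mutual_information",
    "joint_distribution",
    "dependency_graph",
    "mi_sensitivity",
    "permutation_null",
]

EDGE_SNAP_TOL = 1e-12  # values this close to an interior bin edge fall in the lower bin


@dataclass(frozen=True)
class DiscretizationSpec:
    """How a continuous (or leveled) variable becomes labels.

    ``distinct_levels`` maps every unique value to its own label (intended
    for a designed factor with a few levels); ``equal_width`` and
    ``equal_frequency`` cut into ``n_bins`` bins.
    """

    method: Literal["equal_width", "equal_frequency", "distinct_levels"] = "equal_width"
    n_bins: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("equal_width", "equal_frequency", "distinct_levels"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.method != "distinct_levels" and self.n_bins < 2:
            raise ValueError(f"n_bins must be ≥ 2, got {self.n_bins}")


def discretize(
    values: Sequence[float] | np.ndarray, spec: DiscretizationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Map values to integer labels; returns ``(labels, edges_or_levels)``.

    Binned methods use right-open bins [e_i, e_{i+1}) with the last bin
    closed; a value within 1e−12 of an interior edge is assigned to the bin
    below that edge.  A constant vector yields a single bin (entropy 0) with
    a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")

    if spec.method == "distinct_levels":
        levels = np.unique(x)
        labels = np.searchsorted(levels, x)
        return labels.astype(np.intp), levels

    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        warnings.warn(
            "constant vector: single-bin discretization (entropy 0)", stacklevel=2
        )
        return np.zeros(x.size, dtype=np.intp), np.array([lo, hi])

    if spec.method == "equal_width":
        edges = np.linspace(lo, hi, spec.n_bins + 1)
    else:  # equal_frequency
        qs = np.linspace(0, 1, spec.n_bins + 1)
        edges = np.unique(np.quantile(x, qs))
        if len(edges) < 2:
            warnings.warn("degenerate quantile edges: single bin", stacklevel=2)
            return np.zeros(x.size, dtype=np.intp), np.array([lo, hi])

    # right-open: index of the last edge ≤ x
    labels = np.searchsorted(edges, x, side="right") - 1
    labels = np.clip(labels, 0, len(edges) - 2)
    # snap: values within tolerance of an interior edge belong to the lower bin
    for ei in range(1, len(edges) - 1):
        snap = np.abs(x - edges[ei]) <= EDGE_SNAP_TOL
        labels[snap] = ei - 1
    return labels.astype(np.intp), edges


def entropy(labels: Sequence[int] | np.ndarray) -> float:
    """Plug-in Shannon entropy of a label vector, in bits."""
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(lab, return_counts=True)
    p = counts / lab.size
    return float(-(p * np.log2(p)).sum())


def _joint_labels(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # collision-free pairing for the joint entropy
    return x.astype(np.int64) * (int(y.max()) + 1) + y.astype(np.int64)


def mutual_information(
    x: Sequence[int] | np.ndarray, y: Sequence[int] | np.ndarray
) -> float:
    """MI(X, Y) = H(X) + H(Y) − H(X, Y) in bits, clamped at 0.

    Symmetric and non-negative; equals H(X) when y is a relabeling of x.
    """
    xa, ya = np.asarray(x), np.asarray(y)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    mi = entropy(xa) + entropy(ya) - entropy(_joint_labels(xa, ya))
    if mi < -1e-12:  # beyond numerical round-off something is wrong
        raise AssertionError(f"mutual information {mi} < 0")
    return max(mi, 0.0)


@dataclass
class JointDistribution:
    """Empirical joint probability table of two labeled variables."""

    name_x: str
    name_y: str
    support_x: np.ndarray
    support_y: np.ndarray
    joint: np.ndarray  # shape (|X|, |Y|), sums to 1

    def __post_init__(self) -> None:
        if np.any(self.joint < 0):
            raise ValueError("negative joint probabilities")
        if abs(self.joint.sum() - 1.0) > 1e-12:
            raise ValueError(f"joint probabilities sum to {self.joint.sum()}, not 1")

    @property
    def marginal_x(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def mutual_information(self) -> float:
        """Direct Σ p log2(p / (p_x p_y)) over all cells, in bits."""
        px, py = self.marginal_x, self.marginal_y
        mi = 0.0
        for i in range(self.joint.shape[0]):
            for j in range(self.joint.shape[1]):
                p = self.joint[i, j]
                if p > 0:
                    mi += p * np.log2(p / (px[i] * py[j]))
        return max(float(mi), 0.0)


def joint_distribution(
    x: np.ndarray, y: np.ndarray, name_x: str = "x", name_y: str = "y"
) -> JointDistribution:
    xa, ya = np.asarray(x), np.asarray(y)
    sx, xi = np.unique(xa, return_inverse=True)
    sy, yi = np.unique(ya, return_inverse=True)
    joint = np.zeros((sx.size, sy.size))
    np.add.at(joint, (xi, yi), 1.0)
    return JointDistribution(name_x, name_y, sx, sy, joint / xa.size)


# ---------------------------------------------------------------------------
# dependency graph over a dataset
# ---------------------------------------------------------------------------

@dataclass
class DependencyGraph:
    """Undirected graph: nodes are variables, edge weights are MI in bits.

    Self-information H(X) is stored per node; the discretization used is
    recorded so the bit values are interpretable.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]  # keys sorted pairs
    node_entropy: dict[str, float]
    discretization: dict[str, str]

    def mi(self, u: str, v: str) -> float:
        if u == v:
            return self.node_entropy[u]
        return self.edges[tuple(sorted((u, v)))]

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "mi_bits": w}
            for (u, v), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {"name": n, "entropy_bits": self.node_entropy[n]} for n in self.nodes
            ],
            "edges": [
                {"source": u, "target": v, "mi_bits": w}
                for (u, v), w in sorted(self.edges.items())
            ],
            "discretization": self.discretization,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_dot(self) -> str:
        lines = ["graph dependencies {"]
        for n in self.nodes:
            lines.append(f'  "{n}" [entropy_bits={self.node_entropy[n]:.3f}];')
        for (u, v), w in sorted(self.edges.items()):
            lines.append(f'  "{u}" -- "{v}" [label="{w:.3f}"];')
        lines.append("}")
        return "\n".join(lines)


FACTOR_NODE = "temperature"

DEFAULT_FACTOR_SPEC = DiscretizationSpec("distinct_levels")
DEFAULT_RESPONSE_SPEC = DiscretizationSpec("equal_width", 3)


def dependency_graph(
    ds: ExtractionDataset,
    spec_factor: DiscretizationSpec = DEFAULT_FACTOR_SPEC,
    spec_response: DiscretizationSpec = DEFAULT_RESPONSE_SPEC,
) -> DependencyGraph:
    """Pairwise MI between temperature and all responses, on condition means."""
    labels: dict[str, np.ndarray] = {}
    disc: dict[str, str] = {}

    temps = np.array([c.temperature for c in ds.conditions])
    labels[FACTOR_NODE], _ = discretize(temps, spec_factor)
    disc[FACTOR_NODE] = f"{spec_factor.method}"

    for name, values in ds.responses.items():
        means = np.array([v.mean for v in values])
        labels[name], _ = discretize(means, spec_response)
        disc[name] = (
            spec_response.method
            if spec_response.method == "distinct_levels"
            else f"{spec_response.method}/{spec_response.n_bins}"
        )

    nodes = [FACTOR_NODE, *ds.responses]
    edges = {
        tuple(sorted((u, v))): mutual_information(labels[u], labels[v])
        for ai, u in enumerate(nodes)
        for v in nodes[ai + 1 :]
    }
    node_entropy = {n: entropy(lab) for n, lab in labels.items()}
    return DependencyGraph(nodes, edges, node_entropy, disc)


def _ordering_holds(g: DependencyGraph, responses: Sequence[str]) -> dict[str, bool]:
    """Qualitative orderings of interest for the grape-marc analysis."""
    temp_edges = [g.mi(FACTOR_NODE, r) for r in responses]
    out = {}
    if {"TPC", "TAC"} <= set(responses):
        out["tpc_tac_gt_temp_tpc"] = g.mi("TPC", "TAC") > g.mi(FACTOR_NODE, "TPC")
        out["tpc_tac_gt_all_temp"] = g.mi("TPC", "TAC") > max(temp_edges)
    if {"TPC", "TFC"} <= set(responses):
        out["tpc_tfc_gt_all_temp"] = g.mi("TPC", "TFC") > max(temp_edges)
    return out


def mi_sensitivity(
    ds: ExtractionDataset,
    n_bins_range: Sequence[int] = (2, 3, 4, 5),
    spec_factor: DiscretizationSpec = DEFAULT_FACTOR_SPEC,
    method: str = "equal_width",
) -> pd.DataFrame:
    """Recompute the dependency graph across response bin counts.

    One row per (n_bins, edge) with the MI in bits, plus per-binning flags
    for whether the response–response dependencies still dominate the
    temperature–response ones.
    """
    rows = []
    for nb in n_bins_range:
        g = dependency_graph(ds, spec_factor, DiscretizationSpec(method, nb))
        flags = _ordering_holds(g, ds.response_names)
        for (u, v), w in sorted(g.edges.items()):
            rows.append({"n_bins": nb, "source": u, "target": v, "mi_bits": w, **flags})
    return pd.DataFrame(rows)


def permutation_null(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Null MI distribution from shuffling y against x (seeded)."""
    rng = np.random.default_rng(seed)
    ya = np.asarray(y)
    return np.array(
        [mutual_information(x, rng.permutation(ya)) for _ in range(n_permutations)]
    )


# ---------------------------------------------------------------------------
# model / results front-end
# ---------------------------------------------------------------------------

class MutualInformationModel:
    """Dependency analysis of an extraction dataset, statsmodels-style.

    ``fit()`` discretizes temperature and the responses, computes all
    pairwise MI edges and returns a :class:`DependencyResults`.
    """

    def __init__(
        self,
        dataset: ExtractionDataset,
        factor_spec: DiscretizationSpec = DEFAULT_FACTOR_SPEC,
        response_spec: DiscretizationSpec = DEFAULT_RESPONSE_SPEC,
    ):
        self.dataset = dataset
        self.factor_spec = factor_spec
        self.response_spec = response_spec

    def fit(self) -> "DependencyResults":
        graph = dependency_graph(self.dataset, self.factor_spec, self.response_spec)
        return DependencyResults(self, graph)


@dataclass
class DependencyResults:
    model: MutualInformationModel
    graph: DependencyGraph
    _edges: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def edges(self) -> pd.DataFrame:
        if self._edges is None:
            self._edges = self.graph.to_edge_list()
        return self._edges

    @property
    def ordering_flags(self) -> dict[str, bool]:
        return _ordering_holds(self.graph, self.model.dataset.response_names)

    def sensitivity(self, n_bins_range: Sequence[int] = (2, 3, 4, 5)) -> pd.DataFrame:
        return mi_sensitivity(
            self.model.dataset, n_bins_range, self.model.factor_spec
        )

    def summary(self) -> str:
        g = self.graph
        lines = [
            "Mutual-information dependency analysis (plug-in estimator, bits)",
            "================================================================",
            f"observations:   {len(self.model.dataset.conditions)} condition means",
            f"discretization: {g.discretization}",
            "",
            f"{'edge':<24}{'MI (bits)':>10}",
        ]
        for (u, v), w in sorted(g.edges.items(), key=lambda kv: -kv[1]):
            lines.append(f"{u + ' -- ' + v:<24}{w:>10.3f}")
        lines.append("")
        for k, v in self.ordering_flags.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)
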