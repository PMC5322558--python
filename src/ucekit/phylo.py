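"""Phylogenetic substitution models and conservation tests.

Implements JC69 and HKY85 continuous-time substitution models on a fixed
rooted topology, Felsenstein pruning for column likelihoods, maximum
likelihood fitting of a genome-wide background model (global branch scale,
transition/transversion ratio kappa, and equilibrium frequencies pi), the
probability of perfect conservation of an element of length L, and a
rate-deceleration likelihood-ratio test with the standard 50:50
chi2_0/chi2_1 boundary mixture null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "Tree",
    "parse_newick",
    "PhyloModel",
    "build_rate_matrix",
    "transition_matrix",
    "column_log_likelihood",
    "alignment_log_likelihood",
    "fit_background_model",
    "prob_perfect_conservation",
    "deceleration_lrt",
    "ConservationTestResult",
    "encode_columns",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = -1


class Tree:
    """Rooted tree with branch lengths, stored in postorder arrays.

    ``parent[i]`` is the parent index of node i (root has -1), ``blen[i]``
    the length of the branch above node i, ``postorder`` lists node indices
    children-before-parents. Leaves carry names.
    """

    def __init__(self, parent, blen, names, postorder):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.names = list(names)
        self.postorder = list(postorder)
        self.n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.leaves = [i for i in range(self.n_nodes) if not self.children[i]]
        self.leaf_index = {self.names[i]: i for i in self.leaves}
        self.root = int(np.nonzero(self.parent < 0)[0][0])
        if (self.blen[np.arange(self.n_nodes) != self.root] < 0).any():
            raise ValueError("negative branch length")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    @property
    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.blen[mask].sum())

    def scaled(self, factor: float) -> "Tree":
        t = Tree(self.parent.copy(), self.blen * factor, self.names, self.postorder)
        t.blen[t.root] = 0.0
        return t

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                label = self.names[i]
            else:
                label = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i == self.root:
                return label
            return f"{label}:{self.blen[i]:g}"

        return render(self.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree` (via dendropy).

    Leaf names are preserved; write->parse round-trips up to formatting.
    Raises ValueError on malformed input.
    """
    if not text or not text.strip():
        raise ValueError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    if len(nodes) < 2:
        raise ValueError("Newick tree must have at least two nodes")
    index = {id(n): i for i, n in enumerate(nodes)}
    parent, blen, names = [], [], []
    for n in nodes:
        parent.append(index[id(n.parent_node)] if n.parent_node else -1)
        blen.append(float(n.edge.length) if n.edge.length is not None else 0.0)
        names.append(n.taxon.label if n.taxon else "")
    postorder = [index[id(n)] for n in dtree.postorder_node_iter()]
    return Tree(parent, blen, names, postorder)


def build_rate_matrix(kind: str, pi: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """HKY85 (or JC69) rate matrix Q normalized so -sum_b pi_b Q_bb = 1."""
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must sum to 1")
    if kind.upper() == "JC":
        pi = np.full(4, 0.25)
        kappa = 1.0
    elif kind.upper() != "HKY":
        raise ValueError(f"unknown model kind {kind!r}")
    Q = np.tile(pi, (4, 1)).astype(float)
    # transitions: A<->G (0,2), C<->T (1,3)
    for a, b in ((0, 2), (2, 0), (1, 3), (3, 1)):
        Q[a, b] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


@dataclass
class PhyloModel:
    """A substitution model on a fixed tree.

    ``tree`` carries branch lengths in expected substitutions per site under
    the normalized rate matrix; ``kind`` is 'JC' or 'HKY'.
    """

    tree: Tree
    kind: str = "HKY"
    kappa: float = 1.0
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    log_likelihood: float | None = None
    scale: float | None = None
    converged: bool = True

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = build_rate_matrix(self.kind, self.pi, self.kappa)
        if self.kind.upper() == "JC":
            self.pi = np.full(4, 0.25)
            self.kappa = 1.0

    def transition_matrices(self, scale: float = 1.0) -> list[np.ndarray]:
        return [
            transition_matrix(self, t * scale) if i != self.tree.root else np.eye(4)
            for i, t in enumerate(self.tree.blen)
        ]

    def to_text(self) -> str:
        lines = [
            f"kind\t{self.kind}",
            f"kappa\t{self.kappa:.10g}",
            "pi\t" + "\t".join(f"{p:.10g}" for p in self.pi),
            f"scale\t{self.scale if self.scale is not None else 1.0:.10g}",
            f"tree\t{self.tree.to_newick()}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PhyloModel":
        fields = {}
        for line in text.strip().splitlines():
            key, _, rest = line.partition("\t")
            fields[key] = rest
        return cls(
            tree=parse_newick(fields["tree"]),
            kind=fields.get("kind", "HKY"),
            kappa=float(fields.get("kappa", 1.0)),
            pi=np.array([float(x) for x in fields["pi"].split("\t")])
            if "pi" in fields
            else np.full(4, 0.25),
            scale=float(fields["scale"]) if "scale" in fields else None,
        )


def transition_matrix(model: PhyloModel, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, P(0) = I, Chapman-Kolmogorov holds."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(4)
    return expm(model.Q * t)


def encode_columns(
    columns: Sequence[Mapping[str, str]] | np.ndarray, tree: Tree
) -> np.ndarray:
    """Encode columns as an int array (n_leaves_in_tree_order, n_cols).

    Accepts either an already-encoded array or a sequence of
    leaf-name -> base mappings; absent leaves and non-ACGT characters become
    the missing marker.
    """
    if isinstance(columns, np.ndarray):
        return columns
    ncol = len(columns)
    out = np.full((tree.n_leaves, ncol), MISSING, dtype=np.int8)
    order = {name: k for k, name in enumerate(tree.leaf_names)}
    for j, col in enumerate(columns):
        for name, base in col.items():
            if name not in order:
                raise ValueError(f"leaf {name!r} not in tree")
            out[order[name], j] = _BASE_INDEX.get(base.upper(), MISSING)
    return out


def _partials(tree: Tree, P: list[np.ndarray], leaf_states: np.ndarray) -> np.ndarray:
    """Felsenstein pruning: root partial likelihoods, shape (n_cols, 4)."""
    ncol = leaf_states.shape[1]
    L = {}
    eye = np.eye(4)
    ones = np.ones(4)
    leaf_pos = {leaf: k for k, leaf in enumerate(tree.leaves)}
    for node in tree.postorder:
        if not tree.children[node]:
            states = leaf_states[leaf_pos[node]]
            vec = np.where(states[:, None] >= 0, eye[np.clip(states, 0, 3)], ones)
            L[node] = vec
        else:
            acc = np.ones((ncol, 4))
            for child in tree.children[node]:
                acc *= L.pop(child) @ P[child].T
            L[node] = acc
    return L[tree.root]


def alignment_log_likelihood(
    columns, model: PhyloModel, scale: float = 1.0, weights: np.ndarray | None = None
) -> float:
    """Sum of per-column log-likelihoods under the model (branch scale applied)."""
    states = encode_columns(columns, model.tree)
    P = model.transition_matrices(scale)
    root = _partials(model.tree, P, states)
    site = root @ model.pi
    logs = np.log(site)
    if weights is not None:
        logs = logs * weights
    return float(logs.sum())


def column_log_likelihood(column: Mapping[str, str], model: PhyloModel) -> float:
    """Log-probability of a single column; missing leaves are marginalized."""
    return alignment_log_likelihood([column], model)


def _compress(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate column patterns; returns (unique_states, counts)."""
    uniq, counts = np.unique(states.T, axis=0, return_counts=True)
    return uniq.T, counts


def fit_background_model(
    columns,
    tree: Tree,
    model_kind: str = "HKY",
    scale_bounds: tuple[float, float] = (1e-4, 100.0),
    n_restarts: int = 1,
    seed: int = 0,
) -> PhyloModel:
    """Fit (global branch scale, kappa, pi) by maximum likelihood.

    The supplied tree provides relative branch lengths; a single global
    scale is optimized rather than free per-branch lengths. pi is
    parameterized by softmax logits initialized at the observed base
    frequencies; optimization is L-BFGS-B on log-transformed parameters with
    one random restart. The returned model's tree carries the scaled branch
    lengths, and ``model.log_likelihood`` is reproducible from the returned
    parameters.
    """
    kind = model_kind.upper()
    states = encode_columns(columns, tree)
    if states.size == 0 or (states < 0).all():
        raise ValueError("no usable alignment columns")
    states, counts = _compress(states)
    obs = np.bincount(states[states >= 0].ravel(), minlength=4).astype(float)
    obs_pi = (obs + 1.0) / (obs + 1.0).sum()
    lo, hi = np.log(scale_bounds[0]), np.log(scale_bounds[1])

    def unpack(params):
        log_scale = params[0]
        if kind == "JC":
            return np.exp(log_scale), 1.0, np.full(4, 0.25)
        kappa = np.exp(params[1])
        logits = np.concatenate(([0.0], params[2:5]))
        expl = np.exp(logits - logits.max())
        return np.exp(log_scale), kappa, expl / expl.sum()

    def negloglik(params):
        scale, kappa, pi = unpack(params)
        model = PhyloModel(tree=tree, kind=kind, kappa=kappa, pi=pi)
        try:
            ll = alignment_log_likelihood(states, model, scale=scale, weights=counts)
        except FloatingPointError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    base_logits = np.log(obs_pi[1:] / obs_pi[0])
    if kind == "JC":
        x0s = [np.array([0.0])]
        bounds = [(lo, hi)]
    else:
        x0s = [np.concatenate(([0.0, np.log(2.0)], base_logits))]
        bounds = [(lo, hi), (np.log(0.05), np.log(100.0))] + [(-8.0, 8.0)] * 3
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        x0s.append(x0s[0] + rng.normal(0, 0.5, size=len(x0s[0])))

    best = None
    any_converged = False
    for x0 in x0s:
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    scale, kappa, pi = unpack(best.x)
    model = PhyloModel(
        tree=tree.scaled(scale), kind=kind, kappa=kappa, pi=pi,
        log_likelihood=-float(best.fun), scale=float(scale),
        converged=any_converged,
    )
    return model


def prob_perfect_conservation(model: PhyloModel, L: int) -> dict:
    """Probability that L columns are perfectly conserved under the model.

    ``q_identity`` is the per-column probability that all leaves show the
    same base (computed by pruning with point-mass leaf vectors);
    ``q_zero_event`` is the probability of literally zero substitution
    events anywhere on the tree, sum_b pi_b exp(Q_bb * T_total). Parallel or
    reverting substitutions can restore leaf identity, so q_zero_event <=
    q_identity. The reported p-value is q_identity ** L, the probability of
    the observable the scan conditions on.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    tree = model.tree
    states = np.tile(np.arange(4, dtype=np.int8), (tree.n_leaves, 1))
    P = model.transition_matrices()
    root = _partials(tree, P, states)
    q_identity = float((root @ model.pi).sum())
    q_identity = min(q_identity, 1.0)
    T = tree.total_length
    q_zero = float((model.pi * np.exp(np.diag(model.Q) * T)).sum())
    return {
        "q_identity": q_identity,
        "q_zero_event": q_zero,
        "p_value": q_identity ** L,
    }


@dataclass
class ConservationTestResult:
    """Per-element conservation statistics (identity p-value and LRT)."""

    name: str
    L: int
    q_identity: float
    p_value: float
    lambda_hat: float
    lrt_stat: float
    lrt_p: float


def deceleration_lrt(
    element_columns,
    model: PhyloModel,
    element_name: str = "",
    lambda_min: float = 1e-6,
) -> ConservationTestResult:
    """Likelihood-ratio test for rate deceleration on an element.

    The alternative scales all branch lengths by lambda in
    [lambda_min, 1]; the null fixes lambda = 1. The statistic
    2*(lnL(lambda_hat) - lnL(1)) is compared with the 50:50 mixture of
    chi2_0 and chi2_1 appropriate for a one-sided test at the boundary.
    """
    states = encode_columns(element_columns, model.tree)
    if states.shape[1] < 1:
        raise ValueError("element must have at least one column")
    states, counts = _compress(states)

    def neg(lam):
        return -alignment_log_likelihood(states, model, scale=lam, weights=counts)

    res = minimize_scalar(
        neg, bounds=(lambda_min, 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    # the optimum can sit at the boundary; compare against both endpoints
    cands = [(res.fun, res.x), (neg(lambda_min), lambda_min), (neg(1.0), 1.0)]
    fun, lam = min(cands, key=lambda c: c[0])
    ll1 = -neg(1.0)
    lrt = max(0.0, 2.0 * (-fun - ll1))
    p = 1.0 if lrt <= 0 else 0.5 * float(chi2.sf(lrt, df=1))
    cons = prob_perfect_conservation(model, int(counts.sum()))
    return ConservationTestResult(
        name=element_name,
        L=int(counts.sum()),
        q_identity=cons["q_identity"],
        p_value=cons["p_value"],
        lambda_hat=float(lam),
        lrt_stat=float(lrt),
        lrt_p=float(p),
    )
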