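"""Phylogenetic likelihood for codon models M0 and branch-site Model A.

The likelihood of an alignment is the product over codon sites of a
mixture over site classes; within a class, the site likelihood is
computed by Felsenstein pruning over the 61-state codon chain.  Model A
uses four classes: class 0 (omega0 < 1 everywhere), class 1 (neutral
everywhere), and classes 2a/2b where the foreground branch switches to
omega2 while the background keeps omega0 (2a) or 1 (2b).  Gap and
missing codons are fully ambiguous (summed over all 61 states).

Because classes 2a/2b differ from classes 0/1 only on the foreground
edge, their site likelihoods are obtained by recomputing just the path
from the foreground edge to the root on top of the cached background
pruning — roughly halving the cost of a Model A evaluation.  For M0 the
engine also provides the analytic gradient with respect to branch
lengths (one extra pass instead of one finite difference per branch),
which is what makes joint branch-length optimization affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment, estimate_f3x4
from .genetic_code import N_CODONS
from .matrices import build_q_matrix, transition_matrix
from .trees import LabeledTree, PruningArrays

__all__ = [
    "M0Spec",
    "ModelASpec",
    "ModelAParams",
    "SitePatterns",
    "LikelihoodEngine",
    "log_likelihood",
]


@dataclass(frozen=True)
class M0Spec:
    """Single-ratio model: one omega shared by all sites and branches."""

    kappa: float
    omega: float

    def site_classes(self):
        return [(1.0, self.omega, self.omega)]


@dataclass(frozen=True)
class ModelAParams:
    """Branch-site Model A parameters.

    p0, p1 are the proportions of the purifying and neutral classes;
    the remaining mass 1 - p0 - p1 is split between classes 2a and 2b
    in proportion p0:p1.  The null model fixes omega2 = 1.
    """

    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    null: bool = False

    def __post_init__(self):
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1 and self.p0 + self.p1 <= 1 + 1e-12):
            raise ValueError("invalid class proportions")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1 - 1e-12:
            raise ValueError("omega2 must be >= 1")
        if self.null and abs(self.omega2 - 1.0) > 1e-12:
            raise ValueError("null model requires omega2 == 1")

    @property
    def p2a(self) -> float:
        return (1 - self.p0 - self.p1) * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        return (1 - self.p0 - self.p1) * self.p1 / (self.p0 + self.p1)

    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


@dataclass(frozen=True)
class ModelASpec:
    """Model A evaluated at a fixed parameter point (alt or null)."""

    params: ModelAParams

    def site_classes(self):
        p = self.params
        w2 = 1.0 if p.null else p.omega2
        return [
            (p.p0, p.omega0, p.omega0),
            (p.p1, 1.0, 1.0),
            (p.p2a, p.omega0, w2),
            (p.p2b, 1.0, w2),
        ]


@dataclass(frozen=True)
class SitePatterns:
    """Unique site patterns of an alignment with multiplicities."""

    states: np.ndarray  # (n_taxa, n_patterns)
    counts: np.ndarray  # (n_patterns,)
    site_to_pattern: np.ndarray  # (n_codons,)

    @classmethod
    def from_alignment(cls, aln: CodonAlignment) -> "SitePatterns":
        patterns, inverse, counts = np.unique(
            aln.states, axis=1, return_inverse=True, return_counts=True
        )
        return cls(states=patterns, counts=counts.astype(float), site_to_pattern=inverse.ravel())

    @property
    def n_patterns(self) -> int:
        return self.states.shape[1]


class _Downpass:
    """One full postorder pruning with cached per-edge messages.

    Messages are peak-normalized per pattern; ``node_scale[n]`` carries
    the accumulated log normalizers of all edges inside n's subtree, so
    ``log site lik = log(pi @ partial[root]) + node_scale[root]``.
    """

    __slots__ = ("messages", "msg_scale", "partials", "node_scale")

    def __init__(self, engine: "LikelihoodEngine", arrays: PruningArrays, P_edges):
        n_pat = engine.patterns.n_patterns
        self.messages = [None] * arrays.n_edges
        self.msg_scale = [None] * arrays.n_edges
        partials = [None] * arrays.n_nodes
        node_scale = [None] * arrays.n_nodes
        for leaf in range(arrays.n_leaves):
            partials[leaf] = engine.leaf_partials[leaf]
            node_scale[leaf] = engine._zero_scale
        for k in range(arrays.n_edges):
            child = arrays.child_index[k]
            parent = arrays.parent_index[k]
            msg = P_edges[k] @ partials[child]
            peak = msg.max(axis=0)
            peak = np.where(peak > 0, peak, 1.0)
            msg = msg / peak
            self.messages[k] = msg
            self.msg_scale[k] = node_scale[child] + np.log(peak)
            if partials[parent] is None:
                partials[parent] = msg
                node_scale[parent] = self.msg_scale[k]
            else:
                partials[parent] = partials[parent] * msg
                node_scale[parent] = node_scale[parent] + self.msg_scale[k]
        self.partials = partials
        self.node_scale = node_scale

    def root_log_lik(self, engine, arrays) -> np.ndarray:
        lik = engine.codon_freqs @ self.partials[arrays.root_index]
        with np.errstate(divide="ignore"):
            return np.log(lik) + self.node_scale[arrays.root_index]


class LikelihoodEngine:
    """Caches the site patterns, tree arrays and leaf partials of one
    gene for repeated likelihood evaluations during optimization."""

    def __init__(
        self,
        aln: CodonAlignment,
        ltree: LabeledTree,
        codon_freqs: np.ndarray | None = None,
    ):
        self.alignment = aln
        self.ltree = ltree
        self.patterns = SitePatterns.from_alignment(aln)
        self.arrays = ltree.pruning_arrays(aln.taxon_ids)
        self.codon_freqs = (
            np.asarray(codon_freqs, dtype=float)
            if codon_freqs is not None
            else estimate_f3x4(aln)
        )
        n_pat = self.patterns.n_patterns
        self.leaf_partials = []
        for leaf in range(self.arrays.n_leaves):
            part = np.zeros((N_CODONS, n_pat))
            states = self.patterns.states[leaf]
            ambiguous = states < 0
            part[:, ambiguous] = 1.0
            observed = np.where(~ambiguous)[0]
            part[states[observed], observed] = 1.0
            self.leaf_partials.append(part)
        self._zero_scale = np.zeros(n_pat)
        arr = self.arrays
        self._children_edges: list[list[int]] = [[] for _ in range(arr.n_nodes)]
        self._incoming_edge = [None] * arr.n_nodes
        for k in range(arr.n_edges):
            self._children_edges[arr.parent_index[k]].append(k)
            self._incoming_edge[arr.child_index[k]] = k
        fg = np.where(arr.is_foreground)[0]
        self._fg_edge = int(fg[0]) if fg.size else None
        # edges on the path from the foreground edge up to the root
        self._fg_path: list[int] = []
        if self._fg_edge is not None:
            k = self._fg_edge
            while True:
                self._fg_path.append(k)
                parent = arr.parent_index[k]
                if parent == arr.root_index:
                    break
                k = self._incoming_edge[parent]

    # ------------------------------------------------------------------
    # class-level site likelihoods

    def _reroute_foreground(
        self, down: _Downpass, arrays: PruningArrays, P_edges, P_fg: np.ndarray
    ) -> np.ndarray:
        """Per-pattern log-lik after swapping the foreground edge's P.

        Reuses every cached message except those on the foreground-to-
        root path, which are recomputed with the replacement matrix.
        """
        arr = arrays
        new_msg = None
        new_scale = None
        for step, k in enumerate(self._fg_path):
            child = arr.child_index[k]
            if step == 0:
                partial = down.partials[child]
                scale = down.node_scale[child]
                P = P_fg
            else:
                # rebuild the child's partial with one replaced message
                prev = self._fg_path[step - 1]
                partial = new_msg
                scale = new_scale
                for j in self._children_edges[child]:
                    if j != prev:
                        partial = partial * down.messages[j]
                        scale = scale + down.msg_scale[j]
                P = P_edges[k]
            msg = P @ partial
            peak = msg.max(axis=0)
            peak = np.where(peak > 0, peak, 1.0)
            new_msg = msg / peak
            new_scale = scale + np.log(peak)
        # combine at the root
        last = self._fg_path[-1]
        partial = new_msg
        scale = new_scale
        for j in self._children_edges[arr.root_index]:
            if j != last:
                partial = partial * down.messages[j]
                scale = scale + down.msg_scale[j]
        lik = self.codon_freqs @ partial
        with np.errstate(divide="ignore"):
            return np.log(lik) + scale

    def class_site_log_likelihoods(
        self, spec, branch_lengths: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Log-likelihood per (site class, pattern).

        Returns (class proportions, matrix of shape (n_classes,
        n_patterns)).
        """
        classes = spec.site_classes()
        is_model_a = isinstance(spec, ModelASpec)
        if is_model_a and self._fg_edge is None:
            raise ValueError("Model A requires a foreground edge on the tree")
        arrays = (
            self.arrays
            if branch_lengths is None
            else self.arrays.with_lengths(branch_lengths)
        )
        kappa = spec.kappa if isinstance(spec, M0Spec) else spec.params.kappa
        omegas = {w for _, w_bg, w_fg in classes for w in (w_bg, w_fg)}
        models = {w: build_q_matrix(kappa, w, self.codon_freqs) for w in omegas}
        props = np.array([c[0] for c in classes])
        # Branch lengths are expected substitutions per codon averaged
        # over the site-class mixture (codeml convention): every class
        # shares one scale per branch type, so high-omega classes
        # genuinely evolve faster than purifying ones.
        r_bg = sum(p * models[w_bg].prescale_rate for p, w_bg, _ in classes)
        r_fg = sum(p * models[w_fg].prescale_rate for p, _, w_fg in classes)

        def edge_P(w: float, k: int):
            rho = models[w].prescale_rate
            scale = r_fg if arrays.is_foreground[k] else r_bg
            return transition_matrix(models[w], arrays.branch_lengths[k] * rho / scale)

        loglik = np.empty((len(classes), self.patterns.n_patterns))
        downpasses: dict[float, tuple[_Downpass, list]] = {}
        for ci, (_, w_bg, w_fg) in enumerate(classes):
            if w_bg not in downpasses:
                P_edges = [edge_P(w_bg, k) for k in range(arrays.n_edges)]
                downpasses[w_bg] = (_Downpass(self, arrays, P_edges), P_edges)
            down, P_edges = downpasses[w_bg]
            if w_fg == w_bg:
                loglik[ci] = down.root_log_lik(self, arrays)
            else:
                loglik[ci] = self._reroute_foreground(
                    down, arrays, P_edges, edge_P(w_fg, self._fg_edge)
                )
        return props, loglik

    def log_likelihood(self, spec, branch_lengths: np.ndarray | None = None) -> float:
        """Total log-likelihood: sum over sites of the log class mixture."""
        props, loglik = self.class_site_log_likelihoods(spec, branch_lengths)
        return float(
            np.dot(self.patterns.counts, mixture_site_log_lik(props, loglik))
        )

    # ------------------------------------------------------------------
    # M0 with analytic branch-length gradient

    def m0_loglik_and_length_grad(
        self, kappa: float, omega: float, branch_lengths: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """M0 log-likelihood and its gradient w.r.t. branch lengths.

        The gradient uses the standard two-pass (downpass/uppass)
        scheme: for edge e with parent-side complement u and child-side
        partial v, d lnL/d t_e = u^T (Q P) v / (u^T P v) per site.
        """
        arrays = self.arrays.with_lengths(branch_lengths)
        model = build_q_matrix(kappa, omega, self.codon_freqs)
        P_edges = [
            transition_matrix(model, arrays.branch_lengths[k])
            for k in range(arrays.n_edges)
        ]
        down = _Downpass(self, arrays, P_edges)
        site_log = down.root_log_lik(self, arrays)
        lnL = float(np.dot(self.patterns.counts, site_log))

        # scaled per-pattern likelihood at the root (shares the
        # normalizers of the cached messages)
        lik_hat = self.codon_freqs @ down.partials[arrays.root_index]

        # uppass: complement vectors per edge
        up = [None] * arrays.n_nodes  # parent-side vector per node
        up[arrays.root_index] = np.broadcast_to(
            self.codon_freqs[:, None], down.partials[arrays.root_index].shape
        )
        grad = np.empty(arrays.n_edges)
        QP = {}
        for k in reversed(range(arrays.n_edges)):  # preorder (root to tips)
            parent = arrays.parent_index[k]
            child = arrays.child_index[k]
            excl = up[parent]
            for j in self._children_edges[parent]:
                if j != k:
                    excl = excl * down.messages[j]
            t = arrays.branch_lengths[k]
            # QP(t) via the cached symmetric eigendecomposition
            V = model._eigvecs
            lam = model._eigvals
            inner = (V * (lam * np.exp(lam * t))) @ V.T
            QPk = inner / model._sqrt_pi[:, None] * model._sqrt_pi[None, :]
            # per pattern: d lnL_s/dt_k = (excl . QP v) / (excl . P v);
            # all shared scale factors cancel in the ratio, but the
            # cached message is (P v)/peak, so restore peak in the
            # denominator: peak = exp(msg_scale - child's subtree scale).
            v = down.partials[child]
            num = np.einsum("ij,ij->j", excl, QPk @ v)
            den = np.einsum("ij,ij->j", excl, down.messages[k])
            peak = np.exp(down.msg_scale[k] - down.node_scale[child])
            with np.errstate(divide="ignore", invalid="ignore"):
                dlog = np.where(den > 0, num / (den * peak), 0.0)
            grad[k] = float(np.dot(self.patterns.counts, dlog))
            if not arrays.child_index[k] < arrays.n_leaves:
                up[child] = P_edges[k].T @ excl
                peak = up[child].max(axis=0)
                peak = np.where(peak > 0, peak, 1.0)
                up[child] = up[child] / peak
        return lnL, grad


def mixture_site_log_lik(props: np.ndarray, loglik: np.ndarray) -> np.ndarray:
    """Log of the class mixture per pattern."""
    keep = props > 0
    if keep.sum() == 1:
        return loglik[keep][0]
    return logsumexp(loglik[keep] + np.log(props[keep])[:, None], axis=0)


def log_likelihood(
    aln: CodonAlignment,
    ltree: LabeledTree,
    spec,
    codon_freqs: np.ndarray | None = None,
    branch_lengths: np.ndarray | None = None,
) -> float:
    """One-shot log-likelihood of an alignment under M0 or Model A.

    ``spec`` is an :class:`M0Spec` or :class:`ModelASpec`; branch
    lengths default to those stored on the tree.
    """
    return LikelihoodEngine(aln, ltree, codon_freqs).log_likelihood(spec, branch_lengths)
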