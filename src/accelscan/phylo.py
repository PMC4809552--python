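"""Phylogenetic numerics: trees, substitution models, pruning likelihoods,
sequence simulation, branch-scale fitting and marginal ancestral reconstruction.

This is the numerical engine shared by conserved-element detection (rate-scaled
emission likelihoods), the lineage-acceleration likelihood ratio test, and the
ancestral-sequence step of the binding-site screen.

Conventions
-----------
* Branch lengths are expected substitutions per site under the neutral model.
* Rate matrices are normalized to one expected substitution per site per unit
  branch length.
* Alignment rows use the alphabet {A, C, G, T, -, N}; ``-`` and ``N`` are both
  treated as missing data (a partial-likelihood vector of ones), following the
  usual convention of phylogenetic HMM toolkits.
* An edge is identified by the name of the node below it (its child).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING_CODE = 4

# 256-entry byte -> state code lookup; anything unrecognized is missing.
_CODE_TABLE = np.full(256, MISSING_CODE, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i

# Leaf partial likelihoods by state code: identity rows for observed bases,
# all-ones row for missing.
_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 state codes (A=0..T=3, missing=4)."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


class NewickError(ValueError):
    """Malformed or invalid newick input."""


@dataclass
class PhyloTree:
    """Rooted tree stored as parallel arrays indexed by node id.

    Attributes
    ----------
    names : list[str]
        Node names; leaves carry species names, internal nodes carry their
        newick label or an auto-assigned ``node<i>``.
    parent : np.ndarray
        Parent index per node, -1 at the root.
    length : np.ndarray
        Length of the edge above each node (0.0 at the root).
    children : list[list[int]]
        Child indices per node.
    """

    names: list[str]
    parent: np.ndarray
    length: np.ndarray
    children: list[list[int]]

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.names)}
        if len(self._index) != len(self.names):
            raise NewickError("duplicate node names in tree")
        if np.any(self.length < 0):
            raise NewickError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise NewickError("tree must have exactly one root")
        self.root = int(roots[0])
        self.postorder = self._postorder()

    # -- structure helpers -------------------------------------------------

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"node {name!r} not in tree") from None

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices]

    def leaves_below(self, i: int) -> set[str]:
        out: set[str] = set()
        stack = [i]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.add(self.names[n])
            else:
                stack.extend(self.children[n])
        return out

    def total_length(self) -> float:
        return float(self.length.sum())

    def mrca(self, leaf_names: Iterable[str]) -> str:
        """Name of the most recent common ancestor of the given leaves."""
        wanted = set(leaf_names)
        if not wanted:
            raise ValueError("empty leaf set")
        missing = wanted - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        # ancestor paths intersect; walk up from one leaf until subtree covers all
        node = self.index(next(iter(wanted)))
        while not wanted <= self.leaves_below(node):
            node = int(self.parent[node])
        return self.names[node]

    def is_monophyletic(self, leaf_names: Iterable[str]) -> bool:
        wanted = set(leaf_names)
        return self.leaves_below(self.index(self.mrca(wanted))) == wanted

    def stem_edge(self, clade_leaves: Iterable[str]) -> str:
        """Edge id (child-node name) of the branch subtending a clade's MRCA."""
        clade_leaves = set(clade_leaves)
        node = self.mrca(clade_leaves)
        if self.leaves_below(self.index(node)) != clade_leaves:
            raise ValueError(f"clade {sorted(clade_leaves)} is not monophyletic")
        if self.index(node) == self.root:
            raise ValueError("clade spans the whole tree; no stem edge exists")
        return node

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf(i):
                body = self.names[i]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")" + self.names[i]
            if i == self.root:
                return body
            return f"{body}:{self.length[i]:.10g}"

        return fmt(self.root) + ";"

    # -- editing -----------------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            list(self.names),
            self.parent.copy(),
            self.length.copy(),
            [list(c) for c in self.children],
        )

    def _rebuild(self, keep: list[int], parent_of: dict[int, int], length_of: dict[int, float],
                 extra: list[tuple[str, int, float]] = ()) -> "PhyloTree":
        """Reindex a modified node set. `keep` lists surviving old indices;
        `extra` adds (name, parent_old_index, length) new nodes."""
        old_to_new = {o: n for n, o in enumerate(keep)}
        names = [self.names[o] for o in keep]
        parent = []
        length = []
        for o in keep:
            p = parent_of.get(o, int(self.parent[o]))
            parent.append(old_to_new[p] if p >= 0 else -1)
            length.append(length_of.get(o, float(self.length[o])))
        for name, p_old, ln in extra:
            names.append(name)
            parent.append(old_to_new[p_old])
            length.append(ln)
        n = len(names)
        children: list[list[int]] = [[] for _ in range(n)]
        parent_arr = np.array(parent, dtype=int)
        for i, p in enumerate(parent_arr):
            if p >= 0:
                children[p].append(i)
        return PhyloTree(names, parent_arr, np.array(length, dtype=float), children)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted newick string with branch lengths.

    Raises :class:`NewickError` on malformed input or duplicate leaf names,
    naming the offending token.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed newick: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    names: list[str] = []
    seen_leaves: set[str] = set()
    seen: set[str] = set()
    auto = 0
    index_of: dict[int, int] = {}
    parent: list[int] = []
    length: list[float] = []
    for i, nd in enumerate(dnodes):
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("leaf without a name")
            name = nd.taxon.label
            if name in seen_leaves:
                raise NewickError(f"duplicate leaf name {name!r}")
            seen_leaves.add(name)
        else:
            name = nd.label
            if not name or name in seen:
                while True:
                    name = f"node{auto}"
                    auto += 1
                    if name not in seen:
                        break
        if name in seen:
            raise NewickError(f"duplicate node name {name!r}")
        seen.add(name)
        names.append(name)
        index_of[id(nd)] = i
        if nd.parent_node is None:
            parent.append(-1)
            length.append(0.0)
        else:
            parent.append(index_of[id(nd.parent_node)])
            ln = nd.edge.length
            length.append(0.0 if ln is None else float(ln))

    n = len(names)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    if not any(len(c) == 0 for c in children):
        raise NewickError("tree has no leaves")
    return PhyloTree(names, np.array(parent, dtype=int), np.array(length, dtype=float), children)


def graft_leaf(tree: PhyloTree, sister_leaf: str, new_leaf: str,
               stem_fraction: float, new_branch_length: float) -> PhyloTree:
    """Attach `new_leaf` on the branch above `sister_leaf`.

    A new internal node splits the sister's branch of length t into
    ``stem_fraction * t`` (kept by the sister) and ``(1 - stem_fraction) * t``
    (toward the sister's former parent); the new leaf hangs off that node with
    branch ``new_branch_length``.  With ``stem_fraction = 0`` and
    ``new_branch_length = 0`` the new leaf is a zero-distance duplicate of its
    sister. All other leaf-to-leaf path lengths are preserved.
    """
    if new_leaf in tree.names:
        raise ValueError(f"node name {new_leaf!r} already present")
    if not 0.0 <= stem_fraction <= 1.0:
        raise ValueError("stem_fraction must lie in [0, 1]")
    if new_branch_length < 0:
        raise ValueError("negative branch length")
    s = tree.index(sister_leaf)
    if not tree.is_leaf(s):
        raise ValueError(f"{sister_leaf!r} is not a leaf")
    if s == tree.root:
        raise ValueError("cannot graft onto the root")
    t = float(tree.length[s])

    # new internal node takes the sister's place under its old parent
    auto = 0
    while f"graft{auto}" in tree.names:
        auto += 1
    split_name = f"graft{auto}"

    keep = list(range(tree.n_nodes))
    new = tree._rebuild(
        keep,
        parent_of={},
        length_of={},
        extra=[(split_name, int(tree.parent[s]), (1.0 - stem_fraction) * t),
               (new_leaf, int(tree.parent[s]), new_branch_length)],
    )
    # rewire: split node adopts sister and new leaf
    split = new.index(split_name)
    si = new.index(sister_leaf)
    ni = new.index(new_leaf)
    old_parent = int(new.parent[si])
    new.children[old_parent].remove(si)
    new.children[old_parent].remove(ni)
    new.parent[si] = split
    new.parent[ni] = split
    new.children[split] = [si, ni]
    new.length[si] = stem_fraction * t
    return PhyloTree(new.names, new.parent, new.length, new.children)


def prune_leaf(tree: PhyloTree, leaf: str) -> PhyloTree:
    """Remove a leaf and suppress the resulting degree-two node, summing the
    two merged branch lengths (the inverse of :func:`graft_leaf`)."""
    li = tree.index(leaf)
    if not tree.is_leaf(li):
        raise ValueError(f"{leaf!r} is not a leaf")
    p = int(tree.parent[li])
    if p < 0:
        raise ValueError("cannot prune the root")
    siblings = [c for c in tree.children[p] if c != li]
    parent_of: dict[int, int] = {}
    length_of: dict[int, float] = {}
    drop = {li}
    if len(siblings) == 1 and tree.parent[p] >= 0:
        # suppress unifurcation: sibling reattaches above, lengths sum
        sib = siblings[0]
        parent_of[sib] = int(tree.parent[p])
        length_of[sib] = float(tree.length[sib] + tree.length[p])
        drop.add(p)
    keep = [i for i in range(tree.n_nodes) if i not in drop]
    return tree._rebuild(keep, parent_of, length_of)


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------


class SubstitutionModel:
    """Time-reversible nucleotide model with a unit-rate normalized generator.

    Supports JC69 and HKY85.  The generator Q satisfies rows-sum-to-zero and
    stationarity (piQ = 0) and is scaled so the expected substitution rate at
    equilibrium is 1 per site per unit branch length, making branch lengths
    interpretable as expected substitutions per site.
    """

    def __init__(self, family: str, pi: Sequence[float] | None = None,
                 kappa: float | None = None):
        family = family.upper()
        if family not in {"JC69", "HKY85"}:
            raise ValueError(f"unknown model family {family!r}")
        self.family = family
        if family == "JC69":
            pi = np.full(4, 0.25)
            kappa = 1.0
        else:
            pi = np.full(4, 0.25) if pi is None else np.asarray(pi, dtype=float)
            kappa = 4.0 if kappa is None else float(kappa)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a positive 4-vector summing to 1")
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.pi = pi / pi.sum()
        self.kappa = kappa
        self.Q = self._build_q()
        self._decompose()

    def _build_q(self) -> np.ndarray:
        # transitions: A<->G (0,2), C<->T (1,3)
        kappa, pi = self.kappa, self.pi
        Q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = pi[j]
                if (i, j) in {(0, 2), (2, 0), (1, 3), (3, 1)}:
                    rate *= kappa
                Q[i, j] = rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        return Q / mean_rate

    def _decompose(self) -> None:
        # symmetrize: S = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        sq = np.sqrt(self.pi)
        S = (sq[:, None] * self.Q) / sq[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2.0)
        self._eigvals = w
        self._left = V.T * sq[None, :]        # V^T D^{1/2}
        self._right = (V / sq[:, None])       # D^{-1/2} V  (transposed use below)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._right * np.exp(self._eigvals * t)[None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls("JC69")

    @classmethod
    def hky85(cls, kappa: float = 4.0, pi: Sequence[float] | None = None) -> "SubstitutionModel":
        return cls("HKY85", pi=pi, kappa=kappa)


def estimate_base_frequencies(sequences: Iterable[str], pseudocount: float = 1.0) -> np.ndarray:
    """Empirical equilibrium frequencies from observed bases (missing ignored)."""
    counts = np.full(4, pseudocount, dtype=float)
    for seq in sequences:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------


def _edge_matrices(tree: PhyloTree, model: SubstitutionModel,
                   scales: Mapping[str, float] | None, rate_scale: float) -> list[np.ndarray | None]:
    mats: list[np.ndarray | None] = [None] * tree.n_nodes
    scales = scales or {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        mult = float(scales.get(tree.names[i], 1.0))
        if mult < 0:
            raise ValueError(f"negative branch scale on edge {tree.names[i]!r}")
        mats[i] = model.transition_matrix(tree.length[i] * mult * rate_scale)
    return mats


def _pattern_logliks(tree: PhyloTree, model: SubstitutionModel,
                     leaf_codes: Mapping[str, np.ndarray],
                     P: list[np.ndarray | None]) -> np.ndarray:
    """Per-column log-likelihood via post-order partial propagation with
    per-column rescaling; species absent from `leaf_codes` contribute missing
    data."""
    n = len(next(iter(leaf_codes.values()))) if leaf_codes else 0
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    logscale = np.zeros(n)
    for node in tree.postorder:
        if tree.is_leaf(node):
            codes = leaf_codes.get(tree.names[node])
            if codes is None:
                partial[node] = np.ones((n, 4))
            else:
                partial[node] = _LEAF_PARTIALS[codes]
            continue
        prod = np.ones((n, 4))
        for c in tree.children[node]:
            prod *= partial[c] @ P[c].T
            partial[c] = None
        m = prod.max(axis=1)
        np.maximum(m, 1e-300, out=m)
        prod /= m[:, None]
        logscale += np.log(m)
        partial[node] = prod
    lik = partial[tree.root] @ model.pi
    return np.log(lik) + logscale


def _compress_columns(leaf_codes: Mapping[str, np.ndarray]):
    """Unique-column (site-pattern) compression.

    Returns (species order, pattern matrix dict, inverse index, counts)."""
    species = sorted(leaf_codes)
    mat = np.vstack([leaf_codes[s] for s in species])
    patterns, inverse, counts = np.unique(
        mat, axis=1, return_inverse=True, return_counts=True
    )
    pattern_codes = {s: patterns[k] for k, s in enumerate(species)}
    return pattern_codes, inverse.ravel(), counts


def column_loglikelihoods(tree: PhyloTree, model: SubstitutionModel,
                          leaf_codes: Mapping[str, np.ndarray],
                          scales: Mapping[str, float] | None = None,
                          rate_scale: float = 1.0) -> np.ndarray:
    """Log-likelihood of every alignment column (pattern-compressed)."""
    unknown = set(leaf_codes) - set(tree.leaf_names)
    if unknown:
        raise KeyError(f"alignment rows not in tree: {sorted(unknown)}")
    P = _edge_matrices(tree, model, scales, rate_scale)
    pattern_codes, inverse, _ = _compress_columns(leaf_codes)
    return _pattern_logliks(tree, model, pattern_codes, P)[inverse]


def prune_loglik(tree: PhyloTree, model: SubstitutionModel,
                 column: Mapping[str, str],
                 scales: Mapping[str, float] | None = None,
                 strict: bool = False) -> float:
    """Felsenstein-pruning log-likelihood of a single alignment column.

    `column` maps leaf name -> base in {A,C,G,T,-,N}; '-' and 'N' are missing.
    With ``strict=True`` every tree leaf must appear in the column.
    """
    if strict:
        absent = set(tree.leaf_names) - set(column)
        if absent:
            raise KeyError(f"column missing leaves: {sorted(absent)}")
    codes = {s: encode_sequence(b) for s, b in column.items() if s in set(tree.leaf_names)}
    if not codes:
        return 0.0
    P = _edge_matrices(tree, model, scales, 1.0)
    return float(_pattern_logliks(tree, model, codes, P)[0])


def alignment_loglik(tree: PhyloTree, model: SubstitutionModel,
                     leaf_codes: Mapping[str, np.ndarray],
                     scales: Mapping[str, float] | None = None,
                     rate_scale: float = 1.0) -> float:
    """Total log-likelihood of an alignment (sum over columns)."""
    P = _edge_matrices(tree, model, scales, rate_scale)
    pattern_codes, _, counts = _compress_columns(leaf_codes)
    return float(_pattern_logliks(tree, model, pattern_codes, P) @ counts)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_codes(tree: PhyloTree, model: SubstitutionModel, n_sites: int,
                   rng: np.random.Generator,
                   scales: Mapping[str, float] | None = None,
                   rate_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Simulate state codes at every node (leaves and ancestors).

    Root states are drawn from the equilibrium distribution; each edge evolves
    by P(scale * t). Returns node name -> length-n uint8 code array.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    P = _edge_matrices(tree, model, scales, rate_scale)
    states: list[np.ndarray | None] = [None] * tree.n_nodes
    states[tree.root] = rng.choice(4, size=n_sites, p=model.pi).astype(np.uint8)
    for node in reversed(tree.postorder):  # preorder
        if node == tree.root:
            continue
        cum = np.cumsum(P[int(node)], axis=1)
        u = rng.random(n_sites)
        parent_states = states[int(tree.parent[node])]
        states[node] = (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.uint8)
    return {tree.names[i]: states[i] for i in range(tree.n_nodes)}


def simulate_leaf_codes(tree: PhyloTree, model: SubstitutionModel, n_sites: int,
                        seed_or_rng, scales: Mapping[str, float] | None = None,
                        rate_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Leaf-only view of :func:`simulate_codes`; accepts a seed or Generator."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    all_states = simulate_codes(tree, model, n_sites, rng, scales, rate_scale)
    return {name: all_states[name] for name in tree.leaf_names}


# ---------------------------------------------------------------------------
# Branch-scale fitting
# ---------------------------------------------------------------------------


def fit_branch_scale(tree: PhyloTree, model: SubstitutionModel,
                     leaf_codes: Mapping[str, np.ndarray], branch_id: str,
                     lower_bound: float = 1.0, upper_bound: float = 100.0,
                     base_scales: Mapping[str, float] | None = None,
                     rate_scale: float = 1.0,
                     tol: float = 1e-6) -> tuple[float, float]:
    """Maximum-likelihood multiplier for one branch, bounded below.

    Optimizes the log-likelihood over the scale applied to the branch above
    node `branch_id` using a bounded scalar search on log-scale; a tie with the
    lower bound (flat likelihood) resolves to the bound.  Returns
    ``(scale_hat, max_loglik)``.
    """
    bi = tree.index(branch_id)
    if bi == tree.root:
        raise ValueError("the root has no branch to scale")
    if not (0 < lower_bound <= upper_bound):
        raise ValueError("need 0 < lower_bound <= upper_bound")

    pattern_codes, _, counts = _compress_columns(leaf_codes)
    P = _edge_matrices(tree, model, base_scales, rate_scale)
    branch_t = float(tree.length[bi]) * float(
        (base_scales or {}).get(branch_id, 1.0)) * rate_scale

    def negloglik(log_lam: float) -> float:
        P[bi] = model.transition_matrix(branch_t * float(np.exp(log_lam)))
        return -float(_pattern_logliks(tree, model, pattern_codes, P) @ counts)

    lo, hi = np.log(lower_bound), np.log(upper_bound)
    f_lo = negloglik(lo)
    if hi - lo < 1e-12:
        return lower_bound, -f_lo
    res = minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                          options={"xatol": min(tol, 1e-7)})
    lam, f_opt = float(np.exp(res.x)), float(res.fun)
    # snap flat or boundary-preferring fits to the lower bound
    if f_lo <= f_opt + 1e-9:
        return lower_bound, -f_lo
    return lam, -f_opt


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------


def reconstruct_ancestor(tree: PhyloTree, model: SubstitutionModel,
                         leaf_codes: Mapping[str, np.ndarray], node_id: str,
                         scales: Mapping[str, float] | None = None,
                         rate_scale: float = 1.0) -> tuple[str, np.ndarray]:
    """Marginal MAP sequence and per-site posteriors at an internal node.

    Computes the marginal posterior distribution over bases at `node_id` for
    every site by combining the inside (pruning) partials with the outside
    partials propagated from the root.  Sites where every leaf below the node
    is missing are reported as ``N`` (their posterior is still returned).  MAP
    ties break by fixed base order A < C < G < T.
    """
    target = tree.index(node_id)
    if tree.is_leaf(target):
        raise ValueError(f"{node_id!r} is a leaf; reconstruction targets internal nodes")

    n = len(next(iter(leaf_codes.values())))
    P = _edge_matrices(tree, model, scales, rate_scale)

    # inside pass (keep all partials, per-site normalized; constants cancel)
    inside: list[np.ndarray] = [None] * tree.n_nodes  # type: ignore[assignment]
    for node in tree.postorder:
        if tree.is_leaf(node):
            codes = leaf_codes.get(tree.names[node])
            inside[node] = np.ones((n, 4)) if codes is None else _LEAF_PARTIALS[codes].astype(float)
            continue
        prod = np.ones((n, 4))
        for c in tree.children[node]:
            prod *= inside[c] @ P[c].T
        m = np.maximum(prod.max(axis=1), 1e-300)
        inside[node] = prod / m[:, None]

    # outside pass
    outside: list[np.ndarray | None] = [None] * tree.n_nodes
    outside[tree.root] = np.broadcast_to(model.pi, (n, 4)).copy()
    for node in reversed(tree.postorder):  # preorder
        if tree.is_leaf(node):
            continue
        msgs = {c: inside[c] @ P[c].T for c in tree.children[node]}
        for c in tree.children[node]:
            sib = np.ones((n, 4))
            for s in tree.children[node]:
                if s != c:
                    sib *= msgs[s]
            out_c = (outside[node] * sib) @ P[c]
            m = np.maximum(out_c.max(axis=1), 1e-300)
            outside[c] = out_c / m[:, None]

    post = outside[target] * inside[target]
    post /= post.sum(axis=1, keepdims=True)

    # sites with no observed data below the target -> N
    has_data = np.zeros(n, dtype=bool)
    below = tree.leaves_below(target)
    for name in below:
        codes = leaf_codes.get(name)
        if codes is not None:
            has_data |= codes < 4
    map_codes = post.argmax(axis=1).astype(np.uint8)
    map_codes[~has_data] = MISSING_CODE
    return decode_codes(map_codes), post
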