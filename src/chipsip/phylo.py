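"""Phylogenetic signal of trophic guilds by parsimony and tip-label permutation.

A guild is phylogenetically clustered when its members sit on few branches of
the 16S tree: the minimum number of character-state changes (the Fitch
parsimony score) of the membership character is small compared to what random
placement of the same number of members would give. The null distribution is
built by reshuffling the observed tip states across leaves (preserving state
counts) and rescoring; the one-sided empirical p-value
``(1 + #{null <= observed}) / (1 + n)`` is the headline statistic, and an
F-style variance-ratio statistic comparing the observed deviation to the null
spread is reported alongside it.

Scoring uses Hartigan's frequency generalization of the Fitch algorithm: at
each internal node the state set is the set of states carried by the largest
number of child state-sets, at a cost of (number of children − that count).
On strictly bifurcating trees this is exactly Fitch's intersection rule; on
polytomies it still returns the true minimum. The score is invariant to where
the (unrooted) tree is rooted for the traversal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np
from scipy import stats

from .errors import ParameterError, ValidationError


class TreeIndex:
    """Flat postorder representation of a tree, compiled once for fast scoring.

    Leaves are numbered 0..n_leaves-1 (traversal order); internal nodes
    follow in postorder, so every node's children precede it.
    """

    def __init__(self, tree: dendropy.Tree):
        leaves: list[str] = []
        node_id: dict = {}
        internal: list[tuple[int, tuple[int, ...]]] = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None:
                    raise ValidationError("tree has an unlabeled leaf")
                node_id[node] = len(leaves)
                leaves.append(node.taxon.label)
        next_id = len(leaves)
        for node in tree.postorder_node_iter():
            if not node.is_leaf():
                node_id[node] = next_id
                children = tuple(node_id[c] for c in node.child_nodes())
                internal.append((next_id, children))
                next_id += 1
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate leaf labels in tree")
        self.leaf_labels: list[str] = leaves
        self.leaf_index: dict[str, int] = {l: i for i, l in enumerate(leaves)}
        self.n_leaves = len(leaves)
        self.n_nodes = next_id
        self.internal = internal

    @classmethod
    def from_states(cls, tree: dendropy.Tree, states: Mapping[str, int],
                    missing: str = "error") -> tuple["TreeIndex", np.ndarray]:
        """Compile a tree and align a leaf-state map to its leaf order.

        ``missing='error'`` rejects leaves without a state;
        ``missing='exclude'`` prunes them (the tree must keep >= 2 leaves).
        Returns (index, state vector).
        """
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        absent = sorted(labels - set(states))
        if absent:
            if missing == "error":
                raise ValidationError(f"leaves without a character state: {absent}")
            keep = sorted(labels & set(states))
            if len(keep) < 2:
                raise ValidationError("fewer than 2 scored leaves after exclusion")
            tree = tree.extract_tree_with_taxa_labels(keep)
        index = cls(tree)
        vec = np.array([states[l] for l in index.leaf_labels], dtype=np.int64)
        return index, vec

    def score_matrix(self, states: np.ndarray, n_states: Optional[int] = None
                     ) -> np.ndarray:
        """Parsimony scores for many characters at once.

        ``states`` has shape (n_leaves, B): column b is one character's
        leaf states (integers 0..k-1). Returns an integer array of B scores.
        """
        states = np.atleast_2d(np.asarray(states, dtype=np.int64))
        if states.shape[0] != self.n_leaves:
            if states.shape[1] == self.n_leaves:  # allow (B, n_leaves)
                states = states.T
            else:
                raise ParameterError(
                    f"states shape {states.shape} does not match {self.n_leaves} leaves"
                )
        k = int(n_states if n_states is not None else states.max() + 1)
        k = max(k, 1)
        if k > 32:
            raise ParameterError("more than 32 character states not supported")
        B = states.shape[1]
        masks = np.zeros((self.n_nodes, B), dtype=np.uint32)
        masks[: self.n_leaves] = np.uint32(1) << states.astype(np.uint32)
        scores = np.zeros(B, dtype=np.int64)
        for node, children in self.internal:
            counts = np.zeros((k, B), dtype=np.int32)
            for c in children:
                child = masks[c]
                for s in range(k):
                    counts[s] += (child >> np.uint32(s)) & np.uint32(1)
            m = counts.max(axis=0)
            scores += len(children) - m
            node_mask = np.zeros(B, dtype=np.uint32)
            for s in range(k):
                node_mask |= (counts[s] == m).astype(np.uint32) << np.uint32(s)
            masks[node] = node_mask
        return scores


def fitch_score(tree: dendropy.Tree, states: Mapping[str, int],
                missing: str = "error") -> int:
    """Minimum number of state changes of a discrete character on a tree.

    ``states`` maps leaf label -> integer state (k >= 2 states supported).
    The tree may be multifurcating; rooting is irrelevant to the score.
    """
    index, vec = TreeIndex.from_states(tree, states, missing=missing)
    return int(index.score_matrix(vec[:, None])[0])


def reshuffle_null(tree_or_index, states: Mapping[str, int] | np.ndarray,
                   n_reshuffles: int = 1000,
                   rng: Optional[np.random.Generator] = None,
                   rng_seed: Optional[int] = None) -> np.ndarray:
    """Null parsimony scores from uniform tip-label reshuffling.

    Permutes the observed multiset of leaf states across leaves (state
    counts preserved) ``n_reshuffles`` times and scores each permutation.
    Reproducible given a seed or Generator.
    """
    if n_reshuffles < 1:
        raise ParameterError("n_reshuffles must be >= 1")
    if isinstance(tree_or_index, TreeIndex):
        index = tree_or_index
        vec = np.asarray(states, dtype=np.int64)
        if vec.shape != (index.n_leaves,):
            raise ParameterError("state vector length does not match tree leaves")
    else:
        index, vec = TreeIndex.from_states(tree_or_index, states)
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    tiled = np.tile(vec, (n_reshuffles, 1))
    perms = rng.permuted(tiled, axis=1)
    return index.score_matrix(perms.T, n_states=int(vec.max()) + 1)


def signal_pvalues(observed: int, null_scores: np.ndarray) -> dict:
    """Significance of phylogenetic clustering against a permutation null.

    ``p_empirical`` = (1 + #{null <= observed}) / (1 + n); one-sided,
    since clustering means fewer changes than random placement. ``p_ftest``
    is the variance-ratio fidelity statistic
    F = (observed − null mean)² / null variance on (1, n−1) degrees of
    freedom; it is NaN (undefined) for a zero-variance null.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ParameterError("null_scores must be nonempty")
    n = null.size
    p_emp = (1.0 + float(np.sum(null <= observed))) / (1.0 + n)
    mean = float(null.mean())
    var = float(null.var(ddof=1)) if n > 1 else 0.0
    if var > 0.0:
        f = (observed - mean) ** 2 / var
        p_f = float(stats.f.sf(f, 1, n - 1))
    else:
        f, p_f = float("nan"), float("nan")
    return {
        "p_empirical": p_emp,
        "p_ftest": p_f,
        "f_stat": f,
        "null_mean": mean,
        "null_sd": float(np.sqrt(var)),
    }


@dataclass
class AncestralReconstruction:
    """One most-parsimonious internal-state assignment.

    ``node_states`` maps every node (dendropy Node) to its assigned state;
    ``ambiguous`` holds nodes whose Hartigan state set had more than one
    member (other most-parsimonious choices exist there).
    """

    node_states: dict
    ambiguous: set
    score: int

    def changes(self) -> int:
        """State changes implied by this assignment (equals ``score``)."""
        n = 0
        for node, state in self.node_states.items():
            for child in node.child_nodes():
                if self.node_states[child] != state:
                    n += 1
        return n


def ancestral_states(tree: dendropy.Tree, states: Mapping[str, int]
                     ) -> AncestralReconstruction:
    """Most-parsimonious ancestral states by Hartigan's up/down passes.

    Up-pass: each internal node keeps the states attaining the maximum
    count over its children's sets. Down-pass: the root takes any state in
    its set (lowest index, for determinism); a child inherits its parent's
    state when possible, otherwise the lowest-index state in its own set.
    """
    sets: dict = {}
    score = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in states:
                raise ValidationError(f"leaf {label!r} has no character state")
            sets[node] = frozenset({int(states[label])})
        else:
            counts: dict[int, int] = {}
            children = node.child_nodes()
            for c in children:
                for s in sets[c]:
                    counts[s] = counts.get(s, 0) + 1
            m = max(counts.values())
            sets[node] = frozenset(s for s, c in counts.items() if c == m)
            score += len(children) - m

    assignment: dict = {}
    ambiguous: set = set()
    for node in tree.preorder_node_iter():
        node_set = sets[node]
        parent = node.parent_node
        if parent is None:
            state = min(node_set)
        else:
            pstate = assignment[parent]
            state = pstate if pstate in node_set else min(node_set)
        if len(node_set) > 1:
            ambiguous.add(node)
        assignment[node] = state
    return AncestralReconstruction(node_states=assignment, ambiguous=ambiguous,
                                   score=score)


@dataclass
class PhyloCharacter:
    """Result of the clustering test for one guild-membership character."""

    guild: str
    n_members: int
    n_leaves: int
    observed_score: int
    null_scores: np.ndarray
    p_empirical: float
    p_ftest: float
    null_mean: float
    null_sd: float
    excluded_taxa: tuple = ()

    def to_dict(self) -> dict:
        return {
            "guild": self.guild,
            "n_members": self.n_members,
            "n_leaves": self.n_leaves,
            "observed_score": int(self.observed_score),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_empirical": self.p_empirical,
            "p_ftest": None if np.isnan(self.p_ftest) else self.p_ftest,
        }


def test_guild_character(tree: dendropy.Tree, members: Iterable[str],
                         universe: Iterable[str], guild: str = "",
                         n_reshuffles: int = 1000,
                         rng: Optional[np.random.Generator] = None,
                         rng_seed: Optional[int] = None
                         ) -> Optional[PhyloCharacter]:
    """Clustering test for one binary membership character.

    ``universe`` is the set of classified taxa eligible to carry the
    character (members get state 1, the rest 0); tree leaves outside the
    universe are pruned, members missing from the tree are reported in
    ``excluded_taxa``. Returns ``None`` (with a warning) when the character
    is constant or has fewer than 2 members on the tree.
    """
    members = set(members)
    universe = set(universe)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    excluded = tuple(sorted((members | universe) - labels))
    usable = labels & universe
    states = {l: (1 if l in members else 0) for l in usable}
    n1 = sum(states.values())
    n0 = len(states) - n1
    if n1 < 2 or n0 < 1:
        warnings.warn(
            f"guild {guild!r}: {n1} members / {n0} non-members on the tree; "
            "clustering test skipped", stacklevel=2,
        )
        return None
    index, vec = TreeIndex.from_states(tree, states, missing="exclude")
    observed = int(index.score_matrix(vec[:, None])[0])
    null = reshuffle_null(index, vec, n_reshuffles=n_reshuffles, rng=rng,
                          rng_seed=rng_seed)
    pv = signal_pvalues(observed, null)
    return PhyloCharacter(
        guild=guild, n_members=n1, n_leaves=len(states),
        observed_score=observed, null_scores=null,
        p_empirical=pv["p_empirical"], p_ftest=pv["p_ftest"],
        null_mean=pv["null_mean"], null_sd=pv["null_sd"],
        excluded_taxa=excluded,
    )


def test_all_guilds(tree: dendropy.Tree, guild_of: Mapping[str, str],
                    n_reshuffles: int = 1000,
                    rng: Optional[np.random.Generator] = None,
                    rng_seed: Optional[int] = None,
                    exclude_labels: tuple = ("OTHER",)
                    ) -> dict[str, PhyloCharacter]:
    """Run the clustering test once per guild label present.

    ``guild_of`` maps taxon -> guild label. Taxa labeled in
    ``exclude_labels`` (default: OTHER, whose pattern lies outside the
    guild taxonomy) do not form characters and are dropped from the
    universe. Guilds whose character is constant or too small are skipped.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    universe = {t for t, g in guild_of.items() if g not in exclude_labels}
    results: dict[str, PhyloCharacter] = {}
    for guild in sorted({guild_of[t] for t in universe}):
        members = [t for t in universe if guild_of[t] == guild]
        res = test_guild_character(tree, members, universe, guild=guild,
                                   n_reshuffles=n_reshuffles, rng=rng)
        if res is not None:
            results[guild] = res
    return results


def plot_null_histogram(character: PhyloCharacter, path: str) -> None:
    """Null-score histogram with an arrow marking the observed score."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    null = character.null_scores
    fig, ax = plt.subplots(figsize=(5.5, 4))
    lo = int(min(null.min(), character.observed_score))
    hi = int(max(null.max(), character.observed_score))
    bins = np.arange(lo - 0.5, hi + 1.5)
    ax.hist(null, bins=bins, color="#88aacc", edgecolor="black", lw=0.4)
    ymax = ax.get_ylim()[1]
    ax.annotate(
        f"observed = {character.observed_score}",
        xy=(character.observed_score, 0.02 * ymax),
        xytext=(character.observed_score, 0.35 * ymax),
        ha="center", arrowprops=dict(arrowstyle="->", color="firebrick"),
        color="firebrick",
    )
    ax.set_xlabel("parsimony score (state changes)")
    ax.set_ylabel("reshuffles")
    ax.set_title(
        f"{character.guild}: p_emp = {character.p_empirical:.3g} "
        f"(n = {null.size})"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
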