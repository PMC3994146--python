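"""Synthetic Chip-SIP datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
taxon has a probe set with lognormal fluorescence shared across treatments
(the fluorescent labeling pools all treatments, so a probe has one
fluorescence value), and spot delta values that are linear in fluorescence
with a per-treatment slope (the true HCE) plus Gaussian noise. The slope
triplet across H/M/L is set by the taxon's true trophic guild, and guild
membership can be scattered randomly over a simulated tree or seeded into
whole clades to create a phylogenetically clustered character.

Defaults define the standard test conditions: 100 taxa, 20 probes per taxon,
slope triplets (10,10,10) / (10,10,2) / (10,5,1) permil per fluorescence
unit for the saturated / intermediate / copiotrophic guilds, lognormal
fluorescence with log-mean log(30) and log-sd 0.6, and noise_sd = 10 permil
— calibrated so the weakest slope (1 permil/fluor) still has an expected
slope-to-standard-error ratio near 9, i.e. every true slope is individually
well determined (slope/SE >= 5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import TREATMENTS
from .errors import ParameterError
from .guilds import GUILD_COPIOTROPH, GUILD_INTERMEDIATE, GUILD_NULL, GUILD_OTHER
from .io import read_tree, validate_probe_table

#: True HCE triplet (H, M, L), permil per fluorescence unit, by guild.
DEFAULT_SLOPES = {
    GUILD_NULL: (10.0, 10.0, 10.0),
    GUILD_INTERMEDIATE: (10.0, 10.0, 2.0),
    GUILD_COPIOTROPH: (10.0, 5.0, 1.0),
    GUILD_OTHER: (10.0, 2.0, 2.0),  # the unobserved H>M≈L response
}

DEFAULT_N_PROBES = 20
DEFAULT_NOISE_SD = 10.0
DEFAULT_FLUOR_LOG_MEAN = math.log(30.0)
DEFAULT_FLUOR_LOG_SD = 0.6


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated taxon."""

    taxon_id: str
    guild: str
    hce: tuple[float, float, float]  # (H, M, L)
    n_probes: int
    noise_sd: float
    clustering_mode: str = "random"


def _taxon_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"t{i:0{width}d}" for i in range(1, n + 1)]


def simulate_tree(n_taxa: int, rng_seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None):
    """Random unrooted binary tree by sequential random edge attachment.

    Starts from the unique 3-leaf topology and attaches each further leaf
    to a uniformly chosen edge. Reproducible per seed; returns a dendropy
    tree (leaf labels t001, t002, ...).
    """
    if n_taxa < 3:
        raise ParameterError(f"n_taxa must be >= 3, got {n_taxa}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    labels = _taxon_labels(n_taxa)

    # rooted representation of the unrooted tree: root = degree-3 node
    children: dict[int, list[int]] = {0: [1, 2, 3]}
    leaf_name: dict[int, str] = {1: labels[0], 2: labels[1], 3: labels[2]}
    edges: list[tuple[int, int]] = [(0, 1), (0, 2), (0, 3)]
    next_id = 4
    for label in labels[3:]:
        u, v = edges[int(rng.integers(len(edges)))]
        w, leaf = next_id, next_id + 1
        next_id += 2
        children[u] = [w if c == v else c for c in children.get(u, [])]
        children[w] = [v, leaf]
        leaf_name[leaf] = label
        edges.remove((u, v))
        edges.extend([(u, w), (w, v), (w, leaf)])

    def newick(node: int) -> str:
        if node in leaf_name:
            return leaf_name[node]
        return "(" + ",".join(newick(c) for c in children[node]) + ")"

    return read_tree(newick(0) + ";")


def _target_counts(n: int, proportions: Sequence[float], guilds: Sequence[str]
                   ) -> dict[str, int]:
    """Integer guild targets by largest-remainder apportionment."""
    props = np.asarray(proportions, dtype=float)
    if props.size != len(guilds) or np.any(props < 0):
        raise ParameterError("proportions must be nonnegative, one per guild")
    if not np.isclose(props.sum(), 1.0):
        raise ParameterError(f"proportions must sum to 1, got {props.sum()}")
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(guilds, (int(c) for c in counts)))


def assign_guilds(tree, proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                  clustering_mode: str = "random",
                  rng_seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  slopes: Optional[dict] = None,
                  n_probes: int = DEFAULT_N_PROBES,
                  noise_sd: float = DEFAULT_NOISE_SD) -> list[SyntheticTruth]:
    """Assign a true guild to every leaf of ``tree``.

    ``proportions`` covers (NULL_HML, INTERMEDIATE, COPIOTROPH) and may
    carry a fourth entry for OTHER-patterned taxa. ``random`` mode draws
    labels i.i.d. from the proportions; ``clade_seeded`` fills whole clades
    (greedily chosen to approach the target counts) with one guild so the
    membership characters are phylogenetically clustered. Unattainable
    clade splits fall back to the nearest feasible assignment (warned).
    """
    if clustering_mode not in ("random", "clade_seeded"):
        raise ParameterError("clustering_mode must be 'random' or 'clade_seeded'")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    slopes = dict(DEFAULT_SLOPES, **(slopes or {}))
    guild_names = [GUILD_NULL, GUILD_INTERMEDIATE, GUILD_COPIOTROPH, GUILD_OTHER]
    props = list(proportions)
    if len(props) == 3:
        props = props + [0.0]
    if len(props) != 4:
        raise ParameterError("proportions must have 3 or 4 entries")

    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(leaves)

    if clustering_mode == "random":
        p = np.asarray(props, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ParameterError(f"proportions must sum to 1, got {p.sum()}")
        draws = rng.choice(len(guild_names), size=n, p=p)
        guild_of = {leaf: guild_names[d] for leaf, d in zip(leaves, draws)}
    else:
        targets = _target_counts(n, props, guild_names)
        # largest-target guild is the background; others are seeded as clades
        background = max(targets, key=targets.get)
        clades = []
        for node in tree.preorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(clade) < n:
                clades.append(clade)
        clades.sort(key=len, reverse=True)
        assigned: dict[str, str] = {}
        for guild in sorted((g for g in guild_names if g != background),
                            key=lambda g: -targets[g]):
            remaining = targets[guild]
            while remaining >= 2:
                feasible = [c for c in clades
                            if len(c) <= remaining and not (c & assigned.keys())]
                if not feasible:
                    break
                best = max(feasible, key=len)
                for leaf in best:
                    assigned[leaf] = guild
                remaining -= len(best)
            if remaining > 0:
                free = [l for l in leaves if l not in assigned]
                if remaining > len(free):
                    warnings.warn(
                        f"guild {guild}: target short by {remaining - len(free)}; "
                        "nearest feasible split used", stacklevel=2)
                fill = list(rng.choice(free, size=min(remaining, len(free)),
                                       replace=False))
                for leaf in fill:
                    assigned[leaf] = guild
        guild_of = {leaf: assigned.get(leaf, background) for leaf in leaves}

    return [
        SyntheticTruth(taxon_id=leaf, guild=guild_of[leaf],
                       hce=tuple(slopes[guild_of[leaf]]), n_probes=n_probes,
                       noise_sd=noise_sd, clustering_mode=clustering_mode)
        for leaf in leaves
    ]


def simulate_probe_table(truths: Sequence[SyntheticTruth],
                         fluor_log_mean: float = DEFAULT_FLUOR_LOG_MEAN,
                         fluor_log_sd: float = DEFAULT_FLUOR_LOG_SD,
                         heteroscedastic: bool = False,
                         rng_seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None
                         ) -> pd.DataFrame:
    """Long-format probe-spot table for the given ground truths.

    Per probe: one lognormal fluorescence value shared by all three
    treatments (pooled fluorescent labeling); per treatment t:
    delta = true_hce_t * fluorescence + N(0, noise_sd). The optional
    heteroscedastic mode scales the noise sd by fluorescence relative to
    the lognormal median, mimicking signal-proportional NanoSIMS error.

    noise_sd = 0 produces exact lines (useful for identity checks);
    negative noise_sd is a parameter error.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    rows: dict[str, list] = {k: [] for k in
                             ("probe_id", "taxon_id", "treatment",
                              "fluorescence", "delta_permil")}
    median_fluor = math.exp(fluor_log_mean)
    for truth in truths:
        if truth.noise_sd < 0:
            raise ParameterError(f"{truth.taxon_id}: noise_sd must be >= 0")
        if truth.n_probes < 3:
            raise ParameterError(f"{truth.taxon_id}: n_probes must be >= 3")
        fluor = rng.lognormal(fluor_log_mean, fluor_log_sd, truth.n_probes)
        probe_ids = [f"{truth.taxon_id}_p{j + 1:02d}" for j in range(truth.n_probes)]
        for treatment, slope in zip(TREATMENTS, truth.hce):
            sd = truth.noise_sd * (fluor / median_fluor) if heteroscedastic \
                else truth.noise_sd
            noise = rng.normal(0.0, 1.0, truth.n_probes) * sd
            delta = slope * fluor + noise
            rows["probe_id"].extend(probe_ids)
            rows["taxon_id"].extend([truth.taxon_id] * truth.n_probes)
            rows["treatment"].extend([treatment] * truth.n_probes)
            rows["fluorescence"].extend(fluor.tolist())
            rows["delta_permil"].extend(delta.tolist())
    df = pd.DataFrame(rows)
    df["count_14N"] = pd.NA
    df["count_15N"] = pd.NA
    return validate_probe_table(df, source="<synthetic>")


def simulate_dataset(n_taxa: int = 100,
                     proportions: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                     clustering_mode: str = "random",
                     n_probes: int = DEFAULT_N_PROBES,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     fluor_log_mean: float = DEFAULT_FLUOR_LOG_MEAN,
                     fluor_log_sd: float = DEFAULT_FLUOR_LOG_SD,
                     heteroscedastic: bool = False,
                     slopes: Optional[dict] = None,
                     rng_seed: int = 0):
    """Full synthetic dataset from one master seed.

    Returns ``(probe_table, tree, truths)``; the tree, guild assignment and
    probe table each consume an independent stream spawned from
    ``rng_seed``, so the whole dataset is deterministic per seed.
    """
    ss = np.random.SeedSequence(rng_seed)
    rng_tree, rng_guilds, rng_table = (np.random.default_rng(s)
                                       for s in ss.spawn(3))
    tree = simulate_tree(n_taxa, rng=rng_tree)
    truths = assign_guilds(tree, proportions=proportions,
                           clustering_mode=clustering_mode, rng=rng_guilds,
                           slopes=slopes, n_probes=n_probes, noise_sd=noise_sd)
    table = simulate_probe_table(truths, fluor_log_mean=fluor_log_mean,
                                 fluor_log_sd=fluor_log_sd,
                                 heteroscedastic=heteroscedastic,
                                 rng=rng_table)
    return table, tree, truths


def truths_to_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    """Ground-truth table (one row per taxon) for writing alongside a dataset."""
    return pd.DataFrame({
        "taxon_id": [t.taxon_id for t in truths],
        "guild": [t.guild for t in truths],
        "hce_H": [t.hce[0] for t in truths],
        "hce_M": [t.hce[1] for t in truths],
        "hce_L": [t.hce[2] for t in truths],
        "n_probes": [t.n_probes for t in truths],
        "noise_sd": [t.noise_sd for t in truths],
        "clustering_mode": [t.clustering_mode for t in truths],
    })
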