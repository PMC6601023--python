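"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates (i) scale-free confidence-weighted networks with a planted disease
module, (ii) seed/validation gene sets with exactly controlled module overlap
and mutual overlap, (iii) log-normal paired expression with planted fold
changes, and (iv) qPCR Ct tables with a known group shift.  Every generator is
a pure function of (spec, seed).

Defaults mirror the study design the pipeline targets: 13 tissue pairs,
fold-change signals at the 1.5-2x screening scale with a handful of strong
(4x) planted miRs, and Ct shifts around 1.6-2.1 cycles (relative expression
0.33x / 0.23x).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import CtTable, GeneSet, PairedExpressionMatrix, WeightedGeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSimSpec:
    """Scale-free network with a planted, densified disease module.

    ``attachment`` is the preferential-attachment edge count per new node;
    ``module_extra_density`` is the probability of adding each missing
    within-module edge.  ``topology`` may be set to ``erdos_renyi`` (matched
    mean degree) for null checks.
    """

    n_genes: int = 500
    attachment: int = 2
    module_size: int = 25
    module_extra_density: float = 0.4
    weight_range: tuple = (0.4, 1.0)
    topology: str = "preferential_attachment"

    def __post_init__(self):
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        if not (0.0 <= self.module_extra_density <= 1.0):
            raise ValueError("module_extra_density must be in [0, 1]")
        lo, hi = self.weight_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("weight_range must satisfy 0 < low <= high <= 1")
        if self.topology not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class SeedSimSpec:
    """Seed and validation gene sets with controlled overlaps.

    ``overlap_with_module`` is the fraction of each set drawn from the planted
    module; ``seed_validation_overlap`` is the exact number of genes placed in
    both sets (the analogue of target genes that are also known disease genes).
    """

    n_seed: int = 40
    n_validation: int = 12
    overlap_with_module: float = 0.6
    seed_validation_overlap: int = 1

    def __post_init__(self):
        if not (0.0 <= self.overlap_with_module <= 1.0):
            raise ValueError("overlap_with_module must be in [0, 1]")
        if self.seed_validation_overlap > min(self.n_seed, self.n_validation):
            raise ValueError("seed_validation_overlap exceeds a set size")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Paired log-normal expression with planted two-sided fold changes."""

    n_features: int = 500
    n_pairs: int = 13
    n_de: int = 6
    planted_fc: float = 4.0
    sigma_subject: float = 1.0
    sigma_noise: float = 0.3

    def __post_init__(self):
        if self.n_de > self.n_features:
            raise ValueError("n_de cannot exceed n_features")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must be > 1")
        if self.sigma_subject <= 0 or self.sigma_noise <= 0:
            raise ValueError("standard deviations must be > 0")


def _gene_ids(n: int) -> list:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_network(spec: NetworkSimSpec, seed: int) -> tuple:
    """Generate a weighted network and the planted-module gene list.

    Returns ``(WeightedGeneNetwork, module_genes)`` with ``module_genes``
    sorted.  The module receives each missing internal edge with probability
    ``module_extra_density``; edge weights are uniform in ``weight_range``.
    """
    rng = np.random.default_rng(seed)
    if spec.topology == "preferential_attachment":
        base = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=int(seed))
    else:
        p = min(1.0, 2.0 * spec.attachment / max(spec.n_genes - 1, 1))
        base = nx.gnp_random_graph(spec.n_genes, p, seed=int(seed))
    ids = _gene_ids(spec.n_genes)
    g = nx.relabel_nodes(base, dict(enumerate(ids)))
    module = sorted(rng.choice(ids, size=spec.module_size, replace=False))
    for u, v in itertools.combinations(module, 2):
        if not g.has_edge(u, v) and rng.random() < spec.module_extra_density:
            g.add_edge(u, v)
    lo, hi = spec.weight_range
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        g.edges[u, v]["weight"] = float(rng.uniform(lo, hi))
    net = WeightedGeneNetwork(g, confidence_threshold=0,
                              load_summary={"simulated": True, "module_size": spec.module_size})
    return net, module


def simulate_gene_sets(module: list, network: WeightedGeneNetwork,
                       spec: SeedSimSpec, seed: int) -> tuple:
    """Draw seed and validation gene sets with the requested overlaps, exactly.

    ``round(overlap_with_module * size)`` members of each set come from the
    planted module; ``seed_validation_overlap`` genes are placed in both sets
    (drawn from the module when both sets sample it, otherwise from outside);
    all remaining members are sampled uniformly from non-module nodes.

    Set sizes and the seed/validation overlap are always achieved exactly.
    If a single set's module quota exceeds the module it is a spec error;
    when the two quotas are individually feasible but jointly exceed the
    module (they must draw distinct genes apart from the shared ones), both
    are shrunk proportionally to fit and a warning is logged.
    """
    rng = np.random.default_rng(seed)
    module = sorted(module)
    nodes = network.nodes()
    if not set(module) <= set(nodes):
        raise ValueError("module must be a subset of the network nodes")
    outside = sorted(set(nodes) - set(module))

    s_mod = round(spec.overlap_with_module * spec.n_seed)
    v_mod = round(spec.overlap_with_module * spec.n_validation)
    if max(s_mod, v_mod) > len(module):
        raise ValueError(
            f"requested module overlap ({max(s_mod, v_mod)}) exceeds module size {len(module)}"
        )
    shared_mod = min(spec.seed_validation_overlap, s_mod, v_mod)
    shared_out = spec.seed_validation_overlap - shared_mod
    excess = s_mod + v_mod - shared_mod - len(module)
    if excess > 0:
        cut_s = min(round(excess * s_mod / (s_mod + v_mod)), s_mod - shared_mod)
        cut_v = excess - cut_s
        s_mod, v_mod = s_mod - cut_s, v_mod - cut_v
        logger.warning(
            "module quotas jointly exceed the module by %d genes; "
            "shrunk to %d (seed) and %d (validation)", excess, s_mod, v_mod)
    need_out = (spec.n_seed - s_mod) + (spec.n_validation - v_mod) - shared_out
    if need_out > len(outside):
        raise ValueError("not enough non-module nodes for the requested set sizes")

    def draw(pool: list, k: int) -> list:
        pool = sorted(pool)
        picked = sorted(rng.choice(pool, size=k, replace=False)) if k else []
        return [str(p) for p in picked]

    shared_m = draw(module, shared_mod)
    remaining_mod = sorted(set(module) - set(shared_m))
    seed_mod = draw(remaining_mod, s_mod - shared_mod)
    remaining_mod = sorted(set(remaining_mod) - set(seed_mod))
    val_mod = draw(remaining_mod, v_mod - shared_mod)

    shared_o = draw(outside, shared_out)
    remaining_out = sorted(set(outside) - set(shared_o))
    seed_out = draw(remaining_out, spec.n_seed - s_mod - shared_out)
    remaining_out = sorted(set(remaining_out) - set(seed_out))
    val_out = draw(remaining_out, spec.n_validation - v_mod - shared_out)

    seed_set = GeneSet.from_iterable(
        "seed", shared_m + shared_o + seed_mod + seed_out, source="simulated seed set")
    val_set = GeneSet.from_iterable(
        "validation", shared_m + shared_o + val_mod + val_out, source="simulated validation set")
    assert len(seed_set) == spec.n_seed and len(val_set) == spec.n_validation
    assert len(seed_set.intersect(val_set)) == spec.seed_validation_overlap
    return seed_set, val_set


def simulate_paired_expression(spec: ExpressionSimSpec, seed: int) -> tuple:
    """Paired log2 expression with planted fold changes.

    log2 value = feature baseline + per-(feature,subject) effect
    N(0, sigma_subject^2), shared by the pair + condition effect
    (+-log2(planted_fc) on case samples of planted features; half up, half
    down) + residual N(0, sigma_noise^2).  Returns the matrix and a truth
    table (feature_id, direction, fc).
    """
    rng = np.random.default_rng(seed)
    n_f, n_p = spec.n_features, spec.n_pairs
    features = [f"F{i + 1:05d}" for i in range(n_f)]
    subjects = [f"P{i + 1:02d}" for i in range(n_p)]

    baseline = rng.uniform(6.0, 12.0, size=n_f)
    subject_eff = rng.normal(0.0, spec.sigma_subject, size=(n_f, n_p))
    noise_case = rng.normal(0.0, spec.sigma_noise, size=(n_f, n_p))
    noise_ctrl = rng.normal(0.0, spec.sigma_noise, size=(n_f, n_p))

    effect = np.zeros(n_f)
    de_idx = np.array([], dtype=int)
    if spec.n_de:
        de_idx = np.sort(rng.choice(n_f, size=spec.n_de, replace=False))
        signs = np.where(np.arange(spec.n_de) % 2 == 0, 1.0, -1.0)
        effect[de_idx] = signs * math.log2(spec.planted_fc)

    case = baseline[:, None] + subject_eff + effect[:, None] + noise_case
    ctrl = baseline[:, None] + subject_eff + noise_ctrl

    sample_ids, cols, meta = [], [], []
    for j, subj in enumerate(subjects):
        sample_ids += [f"{subj}_case", f"{subj}_ctrl"]
        cols += [case[:, j], ctrl[:, j]]
        meta += [(f"{subj}_case", subj, "case"), (f"{subj}_ctrl", subj, "control")]
    values = pd.DataFrame(np.column_stack(cols), index=features, columns=sample_ids)
    pairing = pd.DataFrame(meta, columns=["sample_id", "subject_id", "condition"]).set_index("sample_id")
    matrix = PairedExpressionMatrix(values=values, pairing=pairing, log2_scale=True)

    truth = pd.DataFrame({
        "feature_id": [features[i] for i in de_idx],
        "direction": ["up" if effect[i] > 0 else "down" for i in de_idx],
        "fc": [spec.planted_fc] * len(de_idx),
    })
    return matrix, truth


def simulate_ct_table(n_per_group: int, delta_delta_ct: float, sd: float, seed: int,
                      n_replicates: int = 3, reference_ct: float = 20.0,
                      control_target_ct: float = 25.0) -> CtTable:
    """Ct table with a planted group shift.

    Case target Ct = control target Ct + ``delta_delta_ct`` (a positive shift
    means fewer transcripts, i.e. lower expression).  The reference gene is
    held at its constant mean; Gaussian replicate noise with standard
    deviation ``sd`` is applied to the target Ct.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group, target_mean in (("control", control_target_ct),
                               ("case", control_target_ct + delta_delta_ct)):
        for i in range(n_per_group):
            sample = f"{group}{i + 1:02d}"
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                rows.append((sample, group, target_mean + noise, reference_ct, rep))
    return CtTable(pd.DataFrame(rows, columns=["sample_id", "group", "target_ct",
                                               "reference_ct", "replicate"]))
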