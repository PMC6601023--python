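"""Core containers and file formats.

Gene sets come as plain one-identifier-per-line lists or GMT rows; interaction
networks as STRING-style edge lists (``node TAB node TAB combined_score`` with
integer scores 0-1000); expression as a features-by-samples TSV plus a
sample-metadata TSV describing the paired case/control design; qPCR input as a
tidy Ct table (one row per sample x replicate).

Gene identifiers are upper-cased, whitespace-trimmed symbols throughout; no
alias or ortholog mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_CONDITIONS = ("case", "control")

CT_COLUMNS = ("sample_id", "group", "target_ct", "reference_ct", "replicate")


class ParseError(ValueError):
    """A file row could not be interpreted in the declared format."""


class PairingError(ValueError):
    """The sample metadata does not describe a complete paired design."""


def normalize_gene_id(raw: str) -> str:
    """Upper-case, whitespace-trimmed gene symbol."""
    return str(raw).strip().upper()


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers with a provenance label.

    Construct via :meth:`from_iterable`, which normalizes identifiers and
    collapses duplicates.
    """

    name: str
    genes: frozenset
    source: str = ""

    def __post_init__(self):
        if any((not isinstance(g, str)) or (not g) for g in self.genes):
            raise ValueError("gene identifiers must be non-empty strings")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], source: str = "") -> "GeneSet":
        norm = {normalize_gene_id(g) for g in genes}
        norm.discard("")
        return cls(name=name, genes=frozenset(norm), source=source)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_id(gene) in self.genes

    def __iter__(self):
        return iter(self.sorted())

    def sorted(self) -> list:
        return sorted(self.genes)

    def intersect(self, other: "GeneSet") -> frozenset:
        return self.genes & other.genes


def read_gene_set(path, format: str = "plain", name: str | None = None) -> GeneSet:
    """Read a gene set from a plain list (one symbol per line) or a GMT row.

    For GMT files with several rows, ``name`` selects the row; without it the
    first row is returned.  Blank lines and ``#`` comments are skipped in plain
    format.
    """
    path = Path(path)
    if format == "plain":
        genes = []
        for line in path.read_text().splitlines():
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            genes.append(token)
        if not genes:
            raise ParseError(f"empty gene set: {path}")
        return GeneSet.from_iterable(name or path.stem, genes, source=str(path))
    if format == "gmt":
        sets = read_gmt(path)
        if name is None:
            return sets[0]
        for gs in sets:
            if gs.name == name:
                return gs
        raise KeyError(f"gene set {name!r} not found in {path}")
    raise ValueError(f"unknown gene set format: {format!r}")


def read_gmt(path) -> list:
    """Read all rows of a GMT file (name TAB description TAB members...)."""
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT row needs >= 3 tab-separated fields, got {len(fields)}"
            )
        name, description = fields[0], fields[1]
        sets.append(GeneSet.from_iterable(name, fields[2:], source=description))
    if not sets:
        raise ParseError(f"empty gene set: {path}")
    return sets


def write_gene_set(gene_set: GeneSet, path, format: str = "plain") -> None:
    """Write a gene set; members are emitted sorted so output is canonical."""
    path = Path(path)
    if format == "plain":
        path.write_text("\n".join(gene_set.sorted()) + "\n")
    elif format == "gmt":
        row = "\t".join([gene_set.name, gene_set.source or "na", *gene_set.sorted()])
        path.write_text(row + "\n")
    else:
        raise ValueError(f"unknown gene set format: {format!r}")


# ---------------------------------------------------------------------------
# Weighted gene network
# ---------------------------------------------------------------------------


@dataclass
class WeightedGeneNetwork:
    """Undirected gene network with per-edge confidence weights in (0, 1].

    Weights are STRING-style combined scores divided by 1000.  Self-loops are
    forbidden; duplicate edges are collapsed by maximum weight at load time.
    """

    graph: nx.Graph
    confidence_threshold: int = 0
    load_summary: dict = field(default_factory=dict)

    def __post_init__(self):
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u},{v}) weight {w!r} outside (0,1]")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def filter_min_score(self, min_score: int) -> "WeightedGeneNetwork":
        """New network keeping edges with combined score >= ``min_score``.

        Matches the loader's behaviour: nodes survive only through kept edges,
        so filtering after a permissive load equals loading at the stricter
        threshold.
        """
        g = nx.Graph()
        for u, v, w in self.graph.edges(data="weight"):
            if round(w * 1000) >= min_score:
                g.add_edge(u, v, weight=w)
        return WeightedGeneNetwork(g, confidence_threshold=max(min_score, self.confidence_threshold))

    def write_edge_list(self, path) -> None:
        lines = []
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
            score = int(round(self.graph.edges[u, v]["weight"] * 1000))
            lines.append(f"{u}\t{v}\t{score}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edge_list(path, min_score: int = 700) -> WeightedGeneNetwork:
    """Load a STRING-style edge list, keeping edges with score >= ``min_score``.

    The default 700 is the conventional "high confidence" cut-off for STRING
    combined scores.  Thresholding is inclusive.  Self-loops are dropped;
    symmetric duplicates are merged keeping the maximum score; zero-score rows
    are dropped (a zero weight would violate the (0,1] edge invariant).  All
    drop counts are recorded in ``load_summary`` so no row disappears silently.
    """
    path = Path(path)
    if not (0 <= min_score <= 1000):
        raise ValueError("min_score must be in [0, 1000]")
    g = nx.Graph()
    summary = {
        "rows_total": 0,
        "edges_kept": 0,
        "dropped_below_threshold": 0,
        "dropped_self_loops": 0,
        "dropped_zero_score": 0,
        "duplicates_merged": 0,
    }
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected node, node, score; got {line!r}")
        u, v = normalize_gene_id(fields[0]), normalize_gene_id(fields[1])
        try:
            score = int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer score {fields[2]!r}") from exc
        if not (0 <= score <= 1000):
            raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1000]")
        summary["rows_total"] += 1
        if u == v:
            summary["dropped_self_loops"] += 1
            continue
        if score == 0:
            summary["dropped_zero_score"] += 1
            continue
        if score < min_score:
            summary["dropped_below_threshold"] += 1
            continue
        w = score / 1000.0
        if g.has_edge(u, v):
            summary["duplicates_merged"] += 1
            g.edges[u, v]["weight"] = max(g.edges[u, v]["weight"], w)
        else:
            g.add_edge(u, v, weight=w)
    summary["edges_kept"] = g.number_of_edges()
    if g.number_of_edges() == 0:
        logger.warning("edge list %s yielded an empty network at min_score=%d", path, min_score)
    return WeightedGeneNetwork(g, confidence_threshold=min_score, load_summary=summary)


# ---------------------------------------------------------------------------
# Paired expression
# ---------------------------------------------------------------------------


@dataclass
class PairedExpressionMatrix:
    """Features x samples expression with a paired case/control design.

    ``values`` is indexed by feature id with sample ids as columns; ``pairing``
    is indexed by sample id with columns ``subject_id`` and ``condition``.
    Every subject must contribute exactly one case and one control sample.
    ``log2_scale`` flags whether values are log2 intensities (the default) or
    linear intensities.
    """

    values: pd.DataFrame
    pairing: pd.DataFrame
    log2_scale: bool = True

    def __post_init__(self):
        missing_cols = {"subject_id", "condition"} - set(self.pairing.columns)
        if missing_cols:
            raise PairingError(f"metadata missing columns: {sorted(missing_cols)}")
        meta_samples = set(self.pairing.index)
        value_samples = set(self.values.columns)
        if meta_samples != value_samples:
            only_values = sorted(value_samples - meta_samples)
            only_meta = sorted(meta_samples - value_samples)
            raise PairingError(
                f"sample mismatch: in values only {only_values}, in metadata only {only_meta}"
            )
        bad_cond = sorted(set(self.pairing["condition"]) - set(VALID_CONDITIONS))
        if bad_cond:
            raise PairingError(f"conditions must be in {VALID_CONDITIONS}; got {bad_cond}")
        broken = []
        for subject, grp in self.pairing.groupby("subject_id"):
            counts = grp["condition"].value_counts()
            if counts.get("case", 0) != 1 or counts.get("control", 0) != 1:
                broken.append(str(subject))
        if broken:
            raise PairingError(f"subjects without exactly one case and one control: {sorted(broken)}")
        if self.pairing["subject_id"].isna().any():
            raise PairingError("missing subject labels")
        # canonical column order: per subject, case then control
        order = []
        for subject in self.subjects:
            order.append(self.sample_of(subject, "case"))
            order.append(self.sample_of(subject, "control"))
        self.values = self.values.loc[:, order]
        self.pairing = self.pairing.loc[order]

    @property
    def subjects(self) -> list:
        return sorted(map(str, self.pairing["subject_id"].unique()))

    @property
    def n_pairs(self) -> int:
        return len(self.subjects)

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    def sample_of(self, subject: str, condition: str) -> str:
        mask = (self.pairing["subject_id"].astype(str) == str(subject)) & (
            self.pairing["condition"] == condition
        )
        return self.pairing.index[mask][0]

    def case_matrix(self) -> pd.DataFrame:
        """Features x subjects matrix of case samples, columns sorted by subject."""
        cols = [self.sample_of(s, "case") for s in self.subjects]
        out = self.values.loc[:, cols]
        out.columns = self.subjects
        return out

    def control_matrix(self) -> pd.DataFrame:
        cols = [self.sample_of(s, "control") for s in self.subjects]
        out = self.values.loc[:, cols]
        out.columns = self.subjects
        return out

    def write(self, path_values, path_metadata) -> None:
        self.values.to_csv(path_values, sep="\t", index_label="feature_id", float_format="%.6f")
        self.pairing.to_csv(path_metadata, sep="\t", index_label="sample_id")


def read_expression(path_values, path_metadata, log2_scale: bool = True) -> PairedExpressionMatrix:
    """Read a features x samples TSV and its sample-metadata TSV."""
    values = pd.read_csv(path_values, sep="\t", index_col=0)
    meta = pd.read_csv(path_metadata, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise PairingError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    return PairedExpressionMatrix(values=values, pairing=meta, log2_scale=log2_scale)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """qPCR threshold cycles, one row per sample x replicate.

    Columns: sample_id, group (case/control), target_ct, reference_ct,
    replicate.  Ct values must be finite and in (0, 45] (the usual cycle cap).
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        bad_groups = sorted(set(self.data["group"]) - set(VALID_CONDITIONS))
        if bad_groups:
            raise ValueError(f"Ct groups must be in {VALID_CONDITIONS}; got {bad_groups}")
        for col in ("target_ct", "reference_ct"):
            ct = pd.to_numeric(self.data[col], errors="coerce")
            if not np.isfinite(ct).all():
                raise ValueError(f"non-finite values in {col}")
            if ((ct <= 0) | (ct > 45)).any():
                raise ValueError(f"{col} values must lie in (0, 45]")

    @property
    def groups(self) -> list:
        return sorted(self.data["group"].unique())

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_ct_table(path) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


DEFAULT_PROPAGATION = {"method": "naive_bayes", "alpha": 0.5, "tol": 1e-8, "max_iter": 1000}


@dataclass
class AnalysisConfig:
    """Flat run configuration; CLI flags override file values."""

    fc_cutoffs: tuple = (1.5, 2.0)
    fdr_alpha: float = 0.05
    string_confidence_min: int = 700
    propagation: dict = field(default_factory=lambda: dict(DEFAULT_PROPAGATION))
    rng_seed: int = 1

    def __post_init__(self):
        self.fc_cutoffs = tuple(float(c) for c in self.fc_cutoffs)
        if any(c <= 1 for c in self.fc_cutoffs):
            raise ValueError("fold-change cutoffs must each be > 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not (0 <= self.string_confidence_min <= 1000):
            raise ValueError("string_confidence_min must be in [0, 1000]")
        merged = dict(DEFAULT_PROPAGATION)
        merged.update(self.propagation)
        self.propagation = merged

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        """Load from YAML or JSON (JSON being a YAML subset)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
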