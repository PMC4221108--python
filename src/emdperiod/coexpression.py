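"""Protein-complex coexpression validation of periodicity calls.

Members of a protein complex tend to be transcribed together, so a complex
whose gene pairs are strongly coexpressed corroborates periodicity calls on
its members.  For each complex every unordered member pair is scored
(Pearson correlation over the expression matrix by default; a precomputed
pair-score table such as SPELL adjusted correlation scores can be plugged
in), and a pair counts as coexpressed when its score reaches at least the
95th percentile of a background distribution of randomly drawn gene pairs.
The per-complex coexpression ratio is coexpressed pairs / C(m, 2).

Gene-level validation crosses the coexpression layer with the periodicity
classification: PERIODIC_BOTH (called by the raw test), PERIODIC_EMD_ONLY
(rescued by the IMF-subset search), PERIODIC_NEITHER (non-detectable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from emdperiod.combinatorics import NON_DETECTABLE, PERIODIC, PUTATIVE_PERIODIC

__all__ = [
    "ComplexDefinition",
    "PairRecord",
    "CoexpressionSummary",
    "GeneValidation",
    "read_complexes",
    "enumerate_pairs",
    "pair_score",
    "background_distribution",
    "coexpression_threshold",
    "coexpression_test",
    "summarize_complex",
    "validate_genes",
    "coexpression_ratio",
    "build_network",
]

logger = logging.getLogger(__name__)

PERIODIC_BOTH = "PERIODIC_BOTH"
PERIODIC_EMD_ONLY = "PERIODIC_EMD_ONLY"
PERIODIC_NEITHER = "PERIODIC_NEITHER"

_LABEL_TO_CATEGORY = {
    PERIODIC: PERIODIC_BOTH,
    PUTATIVE_PERIODIC: PERIODIC_EMD_ONLY,
    NON_DETECTABLE: PERIODIC_NEITHER,
}


@dataclass(frozen=True)
class ComplexDefinition:
    """A curated protein complex: dotted numeric id, name, member genes."""

    complex_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"complex {self.complex_id} needs at least 2 members")


def read_complexes(path) -> list[ComplexDefinition]:
    """Load a membership TSV with columns complex_id, complex_name, gene_id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"complex_id", "complex_name", "gene_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"membership table missing columns: {sorted(missing)}")
    out = []
    for (cid, name), group in table.groupby(["complex_id", "complex_name"], sort=True):
        genes = group["gene_id"].tolist()
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate gene ids in complex {cid}")
        out.append(ComplexDefinition(complex_id=str(cid), name=str(name), members=frozenset(genes)))
    return out


def enumerate_pairs(members_in_matrix) -> list[tuple[str, str]]:
    """All C(m, 2) unordered gene pairs, sorted for determinism."""
    genes = sorted(set(members_in_matrix))
    if len(genes) < 2:
        logger.warning("fewer than 2 genes available; no pairs to enumerate")
        return []
    return [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]


def pair_score(x_a, x_b) -> float:
    """Pearson correlation of two expression profiles.

    Raises
    ------
    ValueError
        If either profile has zero variance (score undefined).
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined for a zero-variance profile")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(np.dot(ac, bc) / np.sqrt(np.dot(ac, ac) * np.dot(bc, bc)))


def _standardize_rows(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    ok = norms > 0
    z = np.zeros_like(xc)
    z[ok] = xc[ok] / norms[ok, None]
    return z, ok


def background_distribution(
    matrix: pd.DataFrame, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Sorted scores of uniformly random distinct gene pairs, genome-wide.

    Zero-variance genes are excluded from sampling (their correlation is
    undefined).  Reproducible given the seed.
    """
    if matrix.shape[0] < 10:
        raise ValueError("background sampling needs at least 10 genes")
    z, ok = _standardize_rows(matrix)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d zero-variance genes from the background", n_excluded)
    idx = np.flatnonzero(ok)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samples)
    done = 0
    chunk = 200_000
    while done < n_samples:
        m = min(chunk, n_samples - done)
        i = rng.integers(0, idx.size, m)
        j = rng.integers(0, idx.size, m)
        clash = i == j
        while np.any(clash):
            j[clash] = rng.integers(0, idx.size, int(clash.sum()))
            clash = i == j
        scores[done : done + m] = np.einsum("ij,ij->i", z[idx[i]], z[idx[j]])
        done += m
    scores.sort()
    return scores


def coexpression_threshold(background: np.ndarray, percentile: float = 95.0) -> float:
    """Empirical score quantile above which a pair counts as coexpressed."""
    if len(background) == 0:
        raise ValueError("background distribution is empty")
    return float(np.quantile(background, percentile / 100.0))


def coexpression_test(score: float, background: np.ndarray, percentile: float = 95.0) -> bool:
    """True iff the score ranks at least at the given background percentile (ties included)."""
    return bool(score >= coexpression_threshold(background, percentile))


@dataclass(frozen=True)
class PairRecord:
    gene_a: str
    gene_b: str
    score: float
    coexpressed: bool


@dataclass(frozen=True)
class CoexpressionSummary:
    """Per-complex pair bookkeeping (one summary-table row per complex)."""

    complex_id: str
    name: str
    n_members: int
    n_members_in_matrix: int
    n_total_pairs: int
    n_coexpressed: int
    pairs: tuple[PairRecord, ...] = field(repr=False, default=())
    n_excluded_pairs: int = 0

    @property
    def ratio(self) -> float | None:
        """Coexpressed / total pairs; None when no pair could be scored."""
        if self.n_total_pairs == 0:
            return None
        return coexpression_ratio(self.n_coexpressed, self.n_total_pairs)


def coexpression_ratio(n_coexpressed: int, n_total_pairs: int) -> float:
    """Coexpression ratio rounded to the 3 decimals used in summary tables."""
    if not 0 <= n_coexpressed <= n_total_pairs:
        raise ValueError("coexpressed pair count outside [0, total pairs]")
    if n_total_pairs == 0:
        raise ValueError("ratio undefined without pairs")
    return round(n_coexpressed / n_total_pairs, 3)


def summarize_complex(
    complex_def: ComplexDefinition,
    matrix: pd.DataFrame,
    background: np.ndarray,
    percentile: float = 95.0,
    score_fn=pair_score,
) -> CoexpressionSummary:
    """Score all member pairs present in the matrix and tally coexpression.

    Pairs whose score is undefined (zero-variance member) are excluded and
    counted in ``n_excluded_pairs``; ``score_fn`` may be swapped for a
    lookup into a precomputed pair-score table.
    """
    present = sorted(complex_def.members & set(map(str, matrix.index)))
    pairs = enumerate_pairs(present)
    threshold = coexpression_threshold(background, percentile) if pairs else float("nan")
    records: list[PairRecord] = []
    excluded = 0
    for a, b in pairs:
        try:
            s = float(score_fn(matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy()))
        except ValueError as exc:
            logger.info("excluding pair (%s, %s) of %s: %s", a, b, complex_def.complex_id, exc)
            excluded += 1
            continue
        records.append(PairRecord(gene_a=a, gene_b=b, score=s, coexpressed=bool(s >= threshold)))
    return CoexpressionSummary(
        complex_id=complex_def.complex_id,
        name=complex_def.name,
        n_members=len(complex_def.members),
        n_members_in_matrix=len(present),
        n_total_pairs=len(pairs),
        n_coexpressed=sum(r.coexpressed for r in records),
        pairs=tuple(records),
        n_excluded_pairs=excluded,
    )


@dataclass(frozen=True)
class GeneValidation:
    gene_id: str
    category: str  # PERIODIC_BOTH | PERIODIC_EMD_ONLY | PERIODIC_NEITHER
    mean_expression: float


def validate_genes(
    complex_def: ComplexDefinition,
    classifications: dict[str, str],
    matrix: pd.DataFrame,
    summary: CoexpressionSummary,
) -> tuple[list[GeneValidation], list[str], pd.DataFrame, pd.DataFrame]:
    """Cross periodicity labels with complex membership; export the network.

    ``classifications`` maps gene id to a PERIODIC / PUTATIVE_PERIODIC /
    NON_DETECTABLE label.  Returns (validations, unmapped, edges, nodes):
    unmapped genes (present in the matrix but absent from the
    classification) are listed, never dropped silently; edges hold one row
    per coexpressed pair (gene_a, gene_b, score); nodes hold per-gene
    category and mean expression.
    """
    present = sorted(complex_def.members & set(map(str, matrix.index)))
    validations: list[GeneValidation] = []
    unmapped: list[str] = []
    for gene in present:
        label = classifications.get(gene)
        if label is None:
            unmapped.append(gene)
            continue
        if label not in _LABEL_TO_CATEGORY:
            raise ValueError(f"unknown classification label {label!r} for {gene}")
        validations.append(
            GeneValidation(
                gene_id=gene,
                category=_LABEL_TO_CATEGORY[label],
                mean_expression=float(matrix.loc[gene].mean()),
            )
        )
    edges = pd.DataFrame(
        [
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "score": p.score}
            for p in summary.pairs
            if p.coexpressed
        ],
        columns=["gene_a", "gene_b", "score"],
    )
    nodes = pd.DataFrame(
        [
            {
                "gene_id": v.gene_id,
                "category": v.category,
                "mean_expression": v.mean_expression,
            }
            for v in validations
        ],
        columns=["gene_id", "category", "mean_expression"],
    )
    return validations, unmapped, edges, nodes


def build_network(edges: pd.DataFrame, nodes: pd.DataFrame) -> nx.Graph:
    """Coexpression graph: nodes carry category and mean expression, edges the score."""
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.gene_id, category=row.category, mean_expression=row.mean_expression)
    for row in edges.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, score=row.score)
    return g
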