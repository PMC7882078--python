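"""Assembly of the miRNA→mRNA reference network from interaction evidence.

The reference network combines two kinds of evidence about a miRNA→gene
interaction:

* experimentally **validated** records from curated databases (miRTarBase,
  TarBase, miRecords, miR2Disease), optionally restricted to interactions
  verified by low-throughput experiments (e.g. qPCR);
* computationally **predicted** records from expression-aware prediction
  tools (HOCTAR, ExprTarget, starBase), each filtered by its own score
  threshold, with a pair accepted only when a minimum number of distinct
  tools agree.

The resulting network is a directed bipartite graph with miRNAs on one side
and target genes on the other.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Source",
    "EvidenceClass",
    "InteractionEvidence",
    "RegulatoryNetwork",
    "NetworkSummary",
    "PredictionFilterConfig",
    "load_interactions",
    "harmonize_mirna_name",
    "filter_predictions",
    "build_reference_network",
    "summarize_network",
    "write_edge_list",
    "read_edge_list",
]


class Source(str, Enum):
    """Databases an interaction-evidence record can come from."""

    MIRTARBASE = "miRTarBase"
    TARBASE = "TarBase"
    MIRECORDS = "miRecords"
    MIR2DISEASE = "miR2Disease"
    HOCTAR = "HOCTAR"
    EXPRTARGET = "ExprTarget"
    STARBASE = "starBase"


#: Sources that carry experimentally validated interactions.
VALIDATED_SOURCES = frozenset(
    {Source.MIRTARBASE, Source.TARBASE, Source.MIRECORDS, Source.MIR2DISEASE}
)
#: Sources that carry computational predictions.
PREDICTION_SOURCES = frozenset({Source.HOCTAR, Source.EXPRTARGET, Source.STARBASE})


class EvidenceClass(str, Enum):
    VALIDATED_LOW_THROUGHPUT = "validated_low_throughput"
    VALIDATED_HIGH_THROUGHPUT = "validated_high_throughput"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class InteractionEvidence:
    """One miRNA→gene claim with its source and source-specific scores."""

    mirna_id: str
    gene_id: str
    source: Source
    evidence_class: EvidenceClass
    hoctar_score: float | None = None
    exprtarget_score: float | None = None
    starbase_readnum: int | None = None
    starbase_bc: int | None = None

    def __post_init__(self) -> None:
        if self.hoctar_score is not None and self.source is not Source.HOCTAR:
            raise ValueError("hoctar_score only valid for HOCTAR records")
        if self.exprtarget_score is not None and self.source is not Source.EXPRTARGET:
            raise ValueError("exprtarget_score only valid for ExprTarget records")
        if (
            self.starbase_readnum is not None or self.starbase_bc is not None
        ) and self.source is not Source.STARBASE:
            raise ValueError("starBase scores only valid for starBase records")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed bipartite miRNA→gene network."""

    edges: frozenset[tuple[str, str]]
    mirnas: frozenset[str] = field(default=None)  # type: ignore[assignment]
    genes: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mirnas = frozenset(m for m, _ in self.edges)
        genes = frozenset(g for _, g in self.edges)
        if self.mirnas is None:
            object.__setattr__(self, "mirnas", mirnas)
        if self.genes is None:
            object.__setattr__(self, "genes", genes)
        if mirnas - self.mirnas or genes - self.genes:
            raise ValueError("edge endpoint missing from node sets")
        if self.mirnas & self.genes:
            raise ValueError("network is not bipartite: id on both sides")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        return cls(edges=frozenset((str(m), str(g)) for m, g in edges))

    def targets(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.edges if m == mirna)

    def regulators(self, gene: str) -> frozenset[str]:
        return frozenset(m for m, g in self.edges if g == gene)

    def out_degree(self, mirna: str) -> int:
        return sum(1 for m, _ in self.edges if m == mirna)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class NetworkSummary:
    n_mirnas: int
    n_genes: int
    n_edges: int
    avg_mirna_degree: float
    avg_gene_degree: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_mirnas": self.n_mirnas,
                "n_genes": self.n_genes,
                "n_edges": self.n_edges,
                "avg_mirna_degree": self.avg_mirna_degree,
                "avg_gene_degree": self.avg_gene_degree,
            }
        )


@dataclass(frozen=True)
class PredictionFilterConfig:
    """Thresholds for the per-tool prediction filters.

    hoctar_top_fraction
        Keep the HOCTAR pairs whose score ranks in the top fraction
        (descending score, rank ≤ ceil(fraction·n); lexicographic pair-id
        tie-break).
    exprtarget_min
        ExprTarget prediction score must be strictly greater than this.
    starbase_min_readnum, starbase_min_bc
        starBase read count and biological-complex count, both inclusive.
    min_tool_agreement
        A pair must pass the filter of at least this many distinct tools.
    """

    hoctar_top_fraction: float = 0.5
    exprtarget_min: float = 1.0
    starbase_min_readnum: int = 10
    starbase_min_bc: int = 2
    min_tool_agreement: int = 2


_COLUMNS = {
    "mirna": "mirna",
    "gene": "gene",
    "source": "source",
    "evidence_class": "evidence_class",
    "hoctar_score": "hoctar_score",
    "exprtarget_score": "exprtarget_score",
    "starbase_readnum": "starbase_readnum",
    "starbase_bc": "starbase_bc",
}

_MANDATORY = ("mirna", "gene", "source", "evidence_class")


class EvidenceFormatError(ValueError):
    """Raised when the evidence table is malformed."""


def load_interactions(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[InteractionEvidence]:
    """Parse a tab-separated interaction-evidence table.

    ``schema`` maps the canonical column names (mirna, gene, source,
    evidence_class and the four score columns) onto the file's header
    names; by default the canonical names are used directly. Rows with an
    unknown source are rejected with the offending row number.
    """
    colmap = dict(_COLUMNS)
    if schema:
        colmap.update(schema)
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        index: dict[str, int] = {}
        for canon, name in colmap.items():
            if name in header:
                index[canon] = header.index(name)
        for canon in _MANDATORY:
            if canon not in index:
                raise EvidenceFormatError(
                    f"{path}: missing mandatory column {colmap[canon]!r}"
                )
        records: list[InteractionEvidence] = []
        for rownum, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")

            def cell(canon: str) -> str | None:
                i = index.get(canon)
                if i is None or i >= len(fields):
                    return None
                v = fields[i].strip()
                return v or None

            try:
                source = Source(cell("source"))
            except ValueError:
                raise EvidenceFormatError(
                    f"{path} row {rownum}: unknown source {cell('source')!r}"
                ) from None
            try:
                eclass = EvidenceClass(cell("evidence_class"))
            except ValueError:
                raise EvidenceFormatError(
                    f"{path} row {rownum}: unknown evidence class "
                    f"{cell('evidence_class')!r}"
                ) from None

            def num(canon: str, cast):
                v = cell(canon)
                if v is None:
                    return None
                try:
                    return cast(v)
                except ValueError:
                    raise EvidenceFormatError(
                        f"{path} row {rownum}: non-numeric {canon} {v!r}"
                    ) from None

            records.append(
                InteractionEvidence(
                    mirna_id=cell("mirna"),
                    gene_id=cell("gene"),
                    source=source,
                    evidence_class=eclass,
                    hoctar_score=num("hoctar_score", float),
                    exprtarget_score=num("exprtarget_score", float),
                    starbase_readnum=num("starbase_readnum", int),
                    starbase_bc=num("starbase_bc", int),
                )
            )
    return records


def evidence_from_frame(frame) -> list[InteractionEvidence]:
    """Build evidence records from a DataFrame in the evidence-table layout.

    Empty strings and NaN in score cells mean absent.
    """

    def val(row, col, cast):
        v = row.get(col)
        if v is None or v == "" or (isinstance(v, float) and v != v):
            return None
        return cast(v)

    records = []
    for _, row in frame.iterrows():
        records.append(
            InteractionEvidence(
                mirna_id=str(row["mirna"]),
                gene_id=str(row["gene"]),
                source=Source(row["source"]),
                evidence_class=EvidenceClass(row["evidence_class"]),
                hoctar_score=val(row, "hoctar_score", float),
                exprtarget_score=val(row, "exprtarget_score", float),
                starbase_readnum=val(row, "starbase_readnum", lambda v: int(float(v))),
                starbase_bc=val(row, "starbase_bc", lambda v: int(float(v))),
            )
        )
    return records


def harmonize_mirna_name(name: str, alias_table: Mapping[str, str] | None = None) -> str:
    """Map a miRNA name to its canonical form.

    A user-supplied alias table (old name → canonical name, e.g. a miRBase
    alias dump) takes precedence. Unknown names pass through with only the
    ``hsa-miR`` prefix case-normalized; arm suffixes (-3p/-5p) are never
    stripped.
    """
    if alias_table and name in alias_table:
        return alias_table[name]
    lowered = name.lower()
    if lowered.startswith("hsa-mir-") or lowered.startswith("hsa-let-"):
        prefix = "hsa-miR-" if lowered.startswith("hsa-mir-") else "hsa-let-"
        normalized = prefix + lowered[len(prefix):]
        if alias_table and normalized in alias_table:
            return alias_table[normalized]
        return normalized
    return name


def _tool_pass_sets(
    evidence: Iterable[InteractionEvidence], config: PredictionFilterConfig
) -> dict[Source, set[tuple[str, str]]]:
    """Per-tool sets of pairs passing that tool's threshold."""
    passed: dict[Source, set[tuple[str, str]]] = {s: set() for s in PREDICTION_SOURCES}
    hoctar: dict[tuple[str, str], float] = {}
    for rec in evidence:
        if rec.source is Source.HOCTAR and rec.hoctar_score is not None:
            # keep the best score if a pair is reported twice
            prev = hoctar.get(rec.pair)
            if prev is None or rec.hoctar_score > prev:
                hoctar[rec.pair] = rec.hoctar_score
        elif rec.source is Source.EXPRTARGET and rec.exprtarget_score is not None:
            if rec.exprtarget_score > config.exprtarget_min:
                passed[Source.EXPRTARGET].add(rec.pair)
        elif rec.source is Source.STARBASE:
            if (
                rec.starbase_readnum is not None
                and rec.starbase_bc is not None
                and rec.starbase_readnum >= config.starbase_min_readnum
                and rec.starbase_bc >= config.starbase_min_bc
            ):
                passed[Source.STARBASE].add(rec.pair)
    if hoctar:
        # rank by descending score; ties broken lexicographically by pair id
        ranked = sorted(hoctar.items(), key=lambda kv: (-kv[1], kv[0]))
        keep = math.ceil(config.hoctar_top_fraction * len(ranked))
        passed[Source.HOCTAR] = {pair for pair, _ in ranked[:keep]}
    return passed


def filter_predictions(
    evidence: Iterable[InteractionEvidence], config: PredictionFilterConfig | None = None
) -> set[tuple[str, str]]:
    """Pairs supported by at least ``min_tool_agreement`` prediction tools.

    Each tool contributes the pairs that pass its own threshold (HOCTAR:
    top-fraction rank; ExprTarget: score strictly over the minimum;
    starBase: readNUM and BC both at/above their minima).
    """
    config = config or PredictionFilterConfig()
    passed = _tool_pass_sets(evidence, config)
    votes: dict[tuple[str, str], int] = {}
    for pairs in passed.values():
        for pair in pairs:
            votes[pair] = votes.get(pair, 0) + 1
    return {pair for pair, n in votes.items() if n >= config.min_tool_agreement}


_CLASS_STRENGTH = {
    EvidenceClass.VALIDATED_LOW_THROUGHPUT: 2,
    EvidenceClass.VALIDATED_HIGH_THROUGHPUT: 1,
    EvidenceClass.PREDICTED: 0,
}


def build_reference_network(
    validated: Iterable[InteractionEvidence],
    predicted_pairs: Iterable[tuple[str, str]],
    require_low_throughput: bool = True,
) -> RegulatoryNetwork:
    """Union of validated interactions and agreed predictions.

    With ``require_low_throughput`` (the default) only validated records
    whose evidence class is low-throughput are kept. When the same pair
    carries conflicting validated classes the strongest class wins and the
    conflict is reported as a warning.
    """
    best: dict[tuple[str, str], EvidenceClass] = {}
    for rec in validated:
        if rec.source not in VALIDATED_SOURCES:
            continue
        prev = best.get(rec.pair)
        if prev is not None and prev is not rec.evidence_class:
            warnings.warn(
                f"conflicting evidence classes for {rec.pair}; keeping strongest",
                stacklevel=2,
            )
            if _CLASS_STRENGTH[rec.evidence_class] > _CLASS_STRENGTH[prev]:
                best[rec.pair] = rec.evidence_class
        elif prev is None:
            best[rec.pair] = rec.evidence_class
    if require_low_throughput:
        kept = {
            p for p, c in best.items() if c is EvidenceClass.VALIDATED_LOW_THROUGHPUT
        }
    else:
        kept = set(best)
    return RegulatoryNetwork.from_edges(kept | set(predicted_pairs))


def summarize_network(net: RegulatoryNetwork) -> NetworkSummary:
    if not net.edges:
        raise ValueError("cannot summarize an empty network")
    return NetworkSummary(
        n_mirnas=len(net.mirnas),
        n_genes=len(net.genes),
        n_edges=net.n_edges,
        avg_mirna_degree=net.n_edges / len(net.mirnas),
        avg_gene_degree=net.n_edges / len(net.genes),
    )


def write_edge_list(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the network as a two-column TSV (mirna TAB gene), sorted."""
    with Path(path).open("w") as fh:
        for m, g in sorted(net.edges):
            fh.write(f"{m}\t{g}\n")


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    edges = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            m, g = line.split("\t")
            edges.append((m, g))
    return RegulatoryNetwork.from_edges(edges)
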