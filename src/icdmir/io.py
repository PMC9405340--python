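"""Readers and writers for the external formats the pipeline touches.

Counts and sample metadata arrive as TSV, gene sets as GMT, miRNA/transcript
sequences as FASTA (read in :mod:`icdmir.targets`), and per-contrast fold
change / p-value summaries in the twelve-column "contrast table" dialect used
by the packaged fixtures: one row per feature, six signed-fold-change columns
followed by six p-value columns (Mino gIrr/DXR/RA_IFNa then MDA-MB-231
gIrr/DXR/RA_IFNa).  Cells may read ``NS`` or ``NaN`` (no differential call)
and p-values may be printed in the ``a.bc × 10^−k`` typeset form; both parse
to *missing*, never to 0.

Two fixtures transcribing published miRNA and mRNA ICD contrast tables are
packaged under ``icdmir/data`` and exposed via :func:`load_mirna_contrasts`
and :func:`load_mrna_contrasts`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, FormatError

log = logging.getLogger(__name__)

#: Valid treatment conditions. ``gIrr`` (gamma irradiation) is the non-ICD
#: control treatment; ``DXR`` (doxorubicin) and ``RA_IFNa`` (retinoic acid +
#: interferon-alpha) are the two ICD inducers.
CONDITIONS = ("untreated", "gIrr", "DXR", "RA_IFNa")

#: Treatments contrasted against ``untreated``.
TREATMENTS = ("gIrr", "DXR", "RA_IFNa")

#: ICD-inducing treatments.
ICD_TREATMENTS = ("DXR", "RA_IFNa")

#: Cell lines of the experimental design (a B-cell lymphoma and a breast
#: cancer line).
CELL_LINES = ("Mino", "MDA")


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequencing library."""

    sample_id: str
    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"unknown condition {self.condition!r} for sample "
                f"{self.sample_id!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise FormatError(
                f"replicate must be a positive integer for sample {self.sample_id!r}"
            )


# ---------------------------------------------------------------------------
# counts + metadata
# ---------------------------------------------------------------------------

def read_counts(path, metadata_path) -> tuple[pd.DataFrame, list[SampleInfo]]:
    """Read a feature × sample count matrix and its sample metadata.

    The counts TSV has a header row of sample ids and a first column of
    feature ids; the metadata TSV has columns ``sample_id``, ``cell_line``,
    ``condition``, ``replicate``.  Matrix columns are reordered to match the
    metadata row order.

    Raises
    ------
    FormatError
        If any cell is negative or non-integer (the offending feature and
        sample are named).
    ConsistencyError
        If the two files disagree on the sample ids.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ConsistencyError(f"duplicate feature_id {dup!r} in {path}")

    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype="int64")
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"count cell for feature {feat!r}, sample {col!r} is not a "
                f"non-negative integer: {raw.loc[feat, col]!r}"
            )
        counts[col] = numeric.astype("int64")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"metadata {metadata_path} must have columns {sorted(required)}"
        )
    samples = [
        SampleInfo(
            sample_id=row.sample_id.strip(),
            cell_line=row.cell_line.strip(),
            condition=row.condition.strip(),
            replicate=int(row.replicate),
        )
        for row in meta.itertuples()
    ]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ConsistencyError(f"duplicate sample_id in {metadata_path}")
    if set(ids) != set(counts.columns):
        raise ConsistencyError(
            "sample ids differ between counts and metadata: "
            f"{sorted(set(ids) ^ set(counts.columns))}"
        )
    return counts[ids], samples


def write_counts(counts: pd.DataFrame, samples: Iterable[SampleInfo],
                 path, metadata_path) -> None:
    """Write a count matrix and metadata in the dialect :func:`read_counts` reads."""
    counts.to_csv(path, sep="\t", index_label="feature_id")
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "cell_line": s.cell_line,
                "condition": s.condition,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contrast tables
# ---------------------------------------------------------------------------

_MISSING_MARKERS = {"NS", "NAN", "NA", ""}

# "1.20 × 10^−70" and plain/typeset variants; group 1 mantissa, group 2 exponent
_TYPESET_SCI = re.compile(
    r"^([+-]?\d+(?:\.\d+)?)\s*[×xX*]\s*10\s*\^?\s*([+-]?\d+)$"
)


def parse_table_number(cell: str | float | None) -> float | None:
    """Parse one contrast-table cell to a float, or ``None`` when missing.

    Handles the typeset scientific notation ``1.20 × 10^−70``, plain floats,
    E-notation, and Unicode minus signs.  ``NS``/``NaN`` and empty cells mean
    "no value"; consumers must treat that as *no differential call*, never as
    p = 0.
    """
    if cell is None:
        return None
    if isinstance(cell, float):
        return None if pd.isna(cell) else cell
    text = str(cell).strip().replace("−", "-").replace("–", "-")
    if text.upper() in _MISSING_MARKERS:
        return None
    text = text.replace("^^", "^")
    m = _TYPESET_SCI.match(text)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"unparseable numeric cell: {cell!r}") from exc


class ContrastTable:
    """Per-feature signed fold change and p-value for each of six contrasts.

    Wraps a DataFrame with a (cell_line, treatment, field) column MultiIndex,
    ``field`` in {"fc", "p"}; missing cells are NaN.  Fold changes follow the
    signed-ratio convention (|fc| >= 1; a ratio r < 1 is printed as -1/r).
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    # -- accessors ---------------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.frame.index)

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        return sorted({(c[0], c[1]) for c in self.frame.columns})

    def fc(self, feature: str, cell_line: str, treatment: str) -> float | None:
        v = self.frame.loc[feature, (cell_line, treatment, "fc")]
        return None if pd.isna(v) else float(v)

    def p(self, feature: str, cell_line: str, treatment: str) -> float | None:
        v = self.frame.loc[feature, (cell_line, treatment, "p")]
        return None if pd.isna(v) else float(v)

    def __len__(self) -> int:
        return len(self.frame)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read(cls, path) -> "ContrastTable":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        raw.columns = [c.strip() for c in raw.columns]
        if "feature_id" not in raw.columns:
            raise FormatError(f"{path}: first column must be feature_id")
        raw["feature_id"] = raw["feature_id"].str.strip()
        if raw["feature_id"].duplicated().any():
            raise ConsistencyError(f"{path}: duplicate feature_id")

        value_cols = [
            c for c in raw.columns
            if c.startswith("fc_") or c.startswith("p_")
        ]
        data: dict[tuple[str, str, str], list[float | None]] = {}
        for col in value_cols:
            field, line, treatment = col.split("_", 2)
            parsed = []
            for cell in raw[col]:
                value = parse_table_number(cell)
                if (
                    field == "fc"
                    and value is not None
                    and abs(value) < 1.0
                ):
                    log.warning(
                        "%s: |signed fc| < 1 in column %s (%r); tables use the "
                        "signed-ratio convention", path, col, cell,
                    )
                parsed.append(value)
            data[(line, treatment, field)] = parsed

        frame = pd.DataFrame(data, index=raw["feature_id"].tolist(), dtype=float)
        frame.columns = pd.MultiIndex.from_tuples(
            frame.columns, names=["cell_line", "treatment", "field"]
        )
        frame.index.name = "feature_id"
        return cls(frame)

    def write(self, path) -> None:
        out = pd.DataFrame(index=self.frame.index)
        for line, treatment, field in self.frame.columns:
            out[f"{field}_{line}_{treatment}"] = self.frame[(line, treatment, field)]
        out.to_csv(path, sep="\t", index_label="feature_id", na_rep="NS")

    @classmethod
    def from_records(
        cls,
        records: Mapping[tuple[str, str], pd.DataFrame],
        use_adjusted: bool = True,
    ) -> "ContrastTable":
        """Assemble a table from per-contrast results of the NB test.

        ``records`` maps (cell_line, treatment) to a DataFrame indexed by
        feature_id with columns ``signed_fc``, ``p`` and ``p_adj``.  The p
        column carried into the table is ``p_adj`` when *use_adjusted* (the
        default for internally generated contrasts), else raw ``p``.
        """
        pcol = "p_adj" if use_adjusted else "p"
        pieces = {}
        for (line, treatment), df in records.items():
            pieces[(line, treatment, "fc")] = df["signed_fc"]
            pieces[(line, treatment, "p")] = df[pcol]
        frame = pd.DataFrame(pieces)
        frame.columns = pd.MultiIndex.from_tuples(
            frame.columns, names=["cell_line", "treatment", "field"]
        )
        frame.index.name = "feature_id"
        return cls(frame)


def read_contrast_table(path) -> ContrastTable:
    """Read a contrast table in the twelve-column fixture dialect."""
    return ContrastTable.read(path)


def load_mirna_contrasts() -> ContrastTable:
    """The packaged miRNA ICD contrast fixture (16 rows, 6 contrasts)."""
    with resources.as_file(
        resources.files("icdmir") / "data" / "mirna_icd_contrasts.tsv"
    ) as p:
        return ContrastTable.read(p)


def load_mrna_contrasts() -> ContrastTable:
    """The packaged mRNA ICD contrast fixture (41 rows, 6 contrasts)."""
    with resources.as_file(
        resources.files("icdmir") / "data" / "mrna_icd_contrasts.tsv"
    ) as p:
        return ContrastTable.read(p)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file into ``{term_id: member set}``.

    Raises :class:`ConsistencyError` on duplicate term ids; empty member
    lists are allowed but logged.
    """
    gene_sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = [f.strip() for f in line.split("\t")]
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: GMT line needs id and description")
        term_id = parts[0]
        if term_id in gene_sets:
            raise ConsistencyError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        members = {g for g in parts[2:] if g}
        if not members:
            log.warning("%s:%d: term %s has no members", path, lineno, term_id)
        gene_sets[term_id] = members
    return gene_sets


def write_gene_sets(gene_sets: Mapping[str, Iterable[str]], path,
                    descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets as GMT (term, description, members...)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term_id in sorted(gene_sets):
            desc = descriptions.get(term_id, "na")
            fields = [term_id, desc, *sorted(gene_sets[term_id])]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bipartite networks (TSV edge list)
# ---------------------------------------------------------------------------

_NET_HEADER = "# icdmir bipartite network v1"


def write_network(graph: nx.Graph, path) -> None:
    """Write a miRNA–gene graph as a TSV edge list with node-kind annotations.

    The file starts with a two-line header; isolated nodes are recorded as
    node lines so the round trip reproduces the node set exactly.
    """
    with open(path, "w") as fh:
        fh.write(_NET_HEADER + "\n")
        fh.write("source\tsource_kind\ttarget\ttarget_kind\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\t{graph.nodes[node].get('kind', 'gene')}\t\t\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(
                f"{u}\t{graph.nodes[u].get('kind', 'gene')}\t"
                f"{v}\t{graph.nodes[v].get('kind', 'gene')}\n"
            )


def read_network(path) -> nx.Graph:
    """Read a graph written by :func:`write_network`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _NET_HEADER:
        raise FormatError(f"{path}: missing network header line")
    graph = nx.Graph()
    for lineno, line in enumerate(lines[2:], 3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
        u, ukind, v, vkind = (p.strip() for p in parts)
        graph.add_node(u, kind=ukind)
        if v:
            graph.add_node(v, kind=vkind)
            graph.add_edge(u, v)
    return graph
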