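"""Deterministic seed-match miRNA target prediction.

Canonical target sites are reverse complements of subranges of the miRNA
seed (nucleotides 2-8, 5'->3'):

========  =====================================  ======
type      site string on the transcript (5'->3')  score
========  =====================================  ======
8mer      rc(seed 2-8) + A                        1.00
7mer-m8   rc(seed 2-8)                            0.95
7mer-A1   rc(seed 2-6) ... rc(seed 2-7) + A       0.92
6mer      rc(seed 2-7)                            0.80
========  =====================================  ======

This transparent scoring is a stand-in for machine-learned interaction
scores: the default map is chosen so that a 0.9 score threshold keeps
7mer/8mer sites and drops 6mer-only interactions.  Externally computed
prediction tables can be imported via :func:`import_predictions` when
fidelity to a specific prediction service matters.

Transcripts may use the DNA or RNA alphabet; everything is canonicalized to
DNA internally.  The search region is the complete transcript (5'UTR + CDS +
3'UTR), not the 3'UTR alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError, FormatError, ParameterError, SequenceError

#: Default site-type score map; higher score = stronger canonical site.
DEFAULT_SITE_SCORES = {"8mer": 1.00, "7mer_m8": 0.95, "7mer_A1": 0.92, "6mer": 0.80}

#: Site types from strongest to weakest.
SITE_RANK = ("8mer", "7mer_m8", "7mer_A1", "6mer")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match site on a transcript (0-based offset)."""

    transcript_id: str
    start: int
    site_type: str
    matched: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched)


@dataclass(frozen=True)
class TargetPrediction:
    """Predicted miRNA -> gene interaction with its supporting sites."""

    mirna_id: str
    gene_id: str
    score: float
    sites: tuple[SeedSite, ...] = ()


def _canonical_dna(seq: str, what: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise SequenceError(
            f"{what} contains characters outside the A/C/G/T/U alphabet: {seq!r}"
        )
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_site_strings(mirna_seq: str) -> dict[str, str]:
    """The four canonical site strings for a miRNA (transcript 5'->3')."""
    m = _canonical_dna(mirna_seq, "miRNA")
    if len(m) < 8:
        raise SequenceError(f"miRNA must be at least 8 nt, got {len(m)}")
    seed_2_8 = m[1:8]
    seed_2_7 = m[1:7]
    return {
        "8mer": _revcomp(seed_2_8) + "A",
        "7mer_m8": _revcomp(seed_2_8),
        "7mer_A1": _revcomp(seed_2_7) + "A",
        "6mer": _revcomp(seed_2_7),
    }


def find_seed_sites(
    mirna_seq: str, transcript_seq: str, transcript_id: str = ""
) -> list[SeedSite]:
    """All canonical seed sites of ``mirna_seq`` on ``transcript_seq``.

    Every occurrence of each site string is located; when matches of
    different types overlap the same locus, only the highest-ranking type is
    reported (an 8mer occurrence is one 8mer site, not also the 7mer/6mer
    matches nested inside its span).  Sites are returned sorted by offset.
    """
    t = _canonical_dna(transcript_seq, "transcript")
    strings = seed_site_strings(mirna_seq)

    candidates: list[SeedSite] = []
    for site_type in SITE_RANK:
        s = strings[site_type]
        start = t.find(s)
        while start != -1:
            candidates.append(SeedSite(transcript_id, start, site_type, s))
            start = t.find(s, start + 1)

    kept: list[SeedSite] = []
    for site in candidates:  # already in rank order (then by offset)
        shadowed = any(
            site.start < other.end and other.start < site.end
            for other in kept
            if SITE_RANK.index(other.site_type) < SITE_RANK.index(site.site_type)
        )
        if not shadowed:
            kept.append(site)
    return sorted(kept, key=lambda s: (s.start, SITE_RANK.index(s.site_type)))


def score_target(
    sites: list[SeedSite], score_map: dict[str, float] | None = None
) -> float:
    """Maximum site score over ``sites``; 0.0 for an empty list."""
    score_map = DEFAULT_SITE_SCORES if score_map is None else score_map
    unknown = {s.site_type for s in sites} - set(score_map)
    if unknown:
        raise ParameterError(f"unknown site types: {sorted(unknown)}")
    return max((score_map[s.site_type] for s in sites), default=0.0)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (ids must be unique)."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ConsistencyError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def predict_targets(
    mirnas: dict[str, str] | str | Path,
    transcripts: dict[str, str] | str | Path,
    threshold: float = 0.9,
    score_map: dict[str, float] | None = None,
) -> list[TargetPrediction]:
    """Scan every (miRNA, transcript) pair and keep scores >= ``threshold``.

    ``mirnas`` and ``transcripts`` may be FASTA paths or id -> sequence
    mappings.  Output order is deterministic: (mirna_id, gene_id)
    lexicographic.
    """
    if not isinstance(mirnas, dict):
        mirnas = read_fasta(mirnas)
    if not isinstance(transcripts, dict):
        transcripts = read_fasta(transcripts)
    predictions = []
    for mirna_id in sorted(mirnas):
        for gene_id in sorted(transcripts):
            sites = find_seed_sites(
                mirnas[mirna_id], transcripts[gene_id], transcript_id=gene_id
            )
            if not sites:
                continue
            score = score_target(sites, score_map)
            if score >= threshold:
                predictions.append(
                    TargetPrediction(mirna_id, gene_id, score, tuple(sites))
                )
    return predictions


def export_predictions(predictions: list[TargetPrediction], path) -> None:
    """Write predictions as TSV (mirna_id, gene_id, score, n_sites, offsets)."""
    rows = [
        {
            "mirna_id": p.mirna_id,
            "gene_id": p.gene_id,
            "score": p.score,
            "n_sites": len(p.sites),
            "site_offsets": ";".join(str(s.start) for s in p.sites),
        }
        for p in predictions
    ]
    pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "score", "n_sites", "site_offsets"]
    ).to_csv(path, sep="\t", index=False)


def import_predictions(path) -> list[TargetPrediction]:
    """Import an externally computed prediction table.

    Expects TSV columns ``mirna_id``, ``gene_id``, ``score``; scores outside
    [0, 1] or malformed rows raise :class:`FormatError` with the line number.
    Imported predictions carry no sites.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    predictions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {i}: unparseable score {row.score!r}"
            ) from None
        if not (0.0 <= score <= 1.0):
            raise FormatError(
                f"{path}: line {i}: score {score} outside [0, 1]"
            )
        predictions.append(TargetPrediction(str(row.mirna_id), str(row.gene_id), score))
    return predictions
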