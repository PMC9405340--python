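"""Synthetic dataset generator with the statistical structure the analysis assumes.

The generator emulates the study design end to end: two cell lines, four
conditions (untreated, gamma irradiation, doxorubicin, RA/IFNα) with
replicated negative-binomial counts for miRNAs and mRNAs; a planted
ICD-specific signature (features shifted by ±``effect_log2fc`` under both
ICD inducers in both cell lines, untouched by gamma irradiation); a set of
gamma-irradiation-only confounder features that the exclusion rule must
reject; planted 8mer seed sites linking each signature miRNA to an
inversely regulated target gene; and a gene-set file whose immune term
covers the planted target genes.

Counts are NB with variance mu + dispersion * mu^2; per-sample library
factors are log-normal (sigma 0.2) around 1 to exercise normalization, and
per-feature abundances are log-normal around ``library_size_mean / n
features``.  Background transcript sequence is uniform over {A,C,G,T};
planted sites overwrite fixed offsets, and a rejection pass re-randomizes
any accidental canonical site of a planted regulator in a non-target
transcript so the truth table stays exact.

All draws come from one seeded generator in a fixed, documented order
(miRNA abundances, mRNA abundances, library factors, confounder signs,
miRNA counts, mRNA counts, miRNA sequences, transcript sequences, gene-set
background), so equal specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import SampleInfo, write_counts, write_gene_sets
from .signature import ICDSignature
from .targets import seed_site_strings

#: GO identifier of the immune-system-process term used by the pair filter.
IMMUNE_TERM = "GO:0002376"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_mirna: int = 100
    n_mrna: int = 500
    n_replicates: int = 3
    cell_lines: tuple[str, ...] = ("Mino", "MDA")
    library_size_mean: float = 2e5
    dispersion: float = 0.05
    icd_up_mirnas: int = 10
    icd_down_mirnas: int = 10
    icd_up_genes: int = 10
    icd_down_genes: int = 10
    effect_log2fc: float = 2.0
    girr_confounder_fraction: float = 0.05
    immune_term_coverage: float = 1.0
    seed_sites_per_pair: int = 2
    transcript_length: int = 500
    mirna_length: int = 22
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.icd_up_mirnas + self.icd_down_mirnas > self.n_mirna:
            raise ConfigurationError("planted miRNAs exceed n_mirna")
        if self.icd_up_genes + self.icd_down_genes > self.n_mrna:
            raise ConfigurationError("planted genes exceed n_mrna")
        if not (0 <= self.girr_confounder_fraction <= 1):
            raise ConfigurationError("girr_confounder_fraction must be in [0, 1]")
        if not (0 <= self.immune_term_coverage <= 1):
            raise ConfigurationError("immune_term_coverage must be in [0, 1]")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be non-negative")
        if self.mirna_length < 8:
            raise ConfigurationError("mirna_length must be at least 8")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the planted ground truth."""

    spec: SyntheticSpec
    mirna_counts: pd.DataFrame
    mrna_counts: pd.DataFrame
    samples: list[SampleInfo]
    mirna_fasta: dict[str, str]
    transcript_fasta: dict[str, str]
    gene_sets: dict[str, set[str]]
    truth_mirnas: pd.DataFrame  # feature_id, direction
    truth_genes: pd.DataFrame   # feature_id, direction
    truth_pairs: pd.DataFrame   # mirna_id, gene_id, directions, offsets

    @property
    def truth_mirna_signature(self) -> ICDSignature:
        t = self.truth_mirnas
        return ICDSignature(
            up=set(t.loc[t.direction == "up", "feature_id"]),
            down=set(t.loc[t.direction == "down", "feature_id"]),
        )

    @property
    def truth_gene_signature(self) -> ICDSignature:
        t = self.truth_genes
        return ICDSignature(
            up=set(t.loc[t.direction == "up", "feature_id"]),
            down=set(t.loc[t.direction == "down", "feature_id"]),
        )

    @property
    def truth_pair_set(self) -> set[tuple[str, str]]:
        return {
            (r.mirna_id, r.gene_id) for r in self.truth_pairs.itertuples()
        }


def _sample_sheet(spec: SyntheticSpec) -> list[SampleInfo]:
    conditions = ("untreated", "gIrr", "DXR", "RA_IFNa")
    return [
        SampleInfo(f"{line}_{cond}_r{rep}", line, cond, rep)
        for line in spec.cell_lines
        for cond in conditions
        for rep in range(1, spec.n_replicates + 1)
    ]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with variance mu + alpha mu^2 (Poisson limit for tiny alpha)."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _count_matrix(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    feature_ids: list[str],
    samples: list[SampleInfo],
    beta: dict[tuple[str, str, str], float],
    abundance: np.ndarray,
    lib_factors: np.ndarray,
) -> pd.DataFrame:
    """Draw one feature x sample NB matrix from mean mu = s * q * 2^beta."""
    mat = np.zeros((len(feature_ids), len(samples)), dtype="int64")
    for j, sample in enumerate(samples):
        log2_shift = np.array(
            [
                beta.get((f, sample.cell_line, sample.condition), 0.0)
                for f in feature_ids
            ]
        )
        mu = lib_factors[j] * abundance * np.exp2(log2_shift)
        mat[:, j] = _nb_draw(rng, mu, spec.dispersion)
    return pd.DataFrame(
        mat, index=pd.Index(feature_ids, name="feature_id"),
        columns=[s.sample_id for s in samples],
    )


def _random_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate counts, sequences, gene sets and truth tables for ``spec``."""
    site_span = 8
    gap = 4
    first_offset = 20
    needed = first_offset + spec.seed_sites_per_pair * (site_span + gap)
    if needed > spec.transcript_length:
        raise ConfigurationError(
            f"transcript_length {spec.transcript_length} cannot host "
            f"{spec.seed_sites_per_pair} non-overlapping sites (needs >= {needed})"
        )

    rng = np.random.default_rng(spec.rng_seed)
    samples = _sample_sheet(spec)

    mirna_ids = [f"syn-miR-{i:04d}" for i in range(1, spec.n_mirna + 1)]
    gene_ids = [f"GENE{i:04d}" for i in range(1, spec.n_mrna + 1)]

    # Planted blocks are the leading features, in a fixed layout.
    up_mirnas = mirna_ids[: spec.icd_up_mirnas]
    down_mirnas = mirna_ids[spec.icd_up_mirnas: spec.icd_up_mirnas + spec.icd_down_mirnas]
    up_genes = gene_ids[: spec.icd_up_genes]
    down_genes = gene_ids[spec.icd_up_genes: spec.icd_up_genes + spec.icd_down_genes]

    # Draw order 1-2: per-feature abundances.
    mirna_abund = rng.lognormal(
        math.log(spec.library_size_mean / max(spec.n_mirna, 1)), 1.0, spec.n_mirna
    )
    mrna_abund = rng.lognormal(
        math.log(spec.library_size_mean / max(spec.n_mrna, 1)), 1.0, spec.n_mrna
    )
    # Draw order 3: library factors (shared across the two matrices).
    lib_factors = rng.lognormal(0.0, 0.2, len(samples))

    # Effects: planted ICD features move under both inducers in every line.
    beta_mirna: dict[tuple[str, str, str], float] = {}
    beta_mrna: dict[tuple[str, str, str], float] = {}
    for line in spec.cell_lines:
        for cond in ("DXR", "RA_IFNa"):
            for f in up_mirnas:
                beta_mirna[(f, line, cond)] = spec.effect_log2fc
            for f in down_mirnas:
                beta_mirna[(f, line, cond)] = -spec.effect_log2fc
            for g in up_genes:
                beta_mrna[(g, line, cond)] = spec.effect_log2fc
            for g in down_genes:
                beta_mrna[(g, line, cond)] = -spec.effect_log2fc

    # Draw order 4: gamma-irradiation-only confounders among the background.
    def plant_confounders(ids: list[str], n_planted: int, beta: dict) -> list[str]:
        background = ids[n_planted:]
        n_conf = int(round(spec.girr_confounder_fraction * len(ids)))
        n_conf = min(n_conf, len(background))
        chosen = background[:n_conf]
        signs = rng.choice([-1.0, 1.0], size=n_conf)
        for f, s in zip(chosen, signs):
            for line in spec.cell_lines:
                beta[(f, line, "gIrr")] = s * spec.effect_log2fc
        return chosen

    girr_mirnas = plant_confounders(
        mirna_ids, spec.icd_up_mirnas + spec.icd_down_mirnas, beta_mirna
    )
    girr_genes = plant_confounders(
        gene_ids, spec.icd_up_genes + spec.icd_down_genes, beta_mrna
    )
    del girr_mirnas, girr_genes

    # Draw order 5-6: count matrices.
    mirna_counts = _count_matrix(
        rng, spec, mirna_ids, samples, beta_mirna, mirna_abund, lib_factors
    )
    mrna_counts = _count_matrix(
        rng, spec, gene_ids, samples, beta_mrna, mrna_abund, lib_factors
    )

    # Draw order 7: miRNA sequences (RNA alphabet), distinct seeds for the
    # planted regulators so their canonical sites do not collide.
    planted_mirnas = up_mirnas + down_mirnas
    mirna_fasta: dict[str, str] = {}
    used_seeds: set[str] = set()
    for mid in mirna_ids:
        for _ in range(200):
            seq = _random_seq(rng, spec.mirna_length, "ACGU")
            seed = seq[1:8]
            if mid not in planted_mirnas or seed not in used_seeds:
                break
        else:  # pragma: no cover - would need a pathological spec
            raise ConfigurationError("could not draw distinct miRNA seeds")
        if mid in planted_mirnas:
            used_seeds.add(seed)
        mirna_fasta[mid] = seq

    # Pair planted miRNAs with inversely regulated genes (index-cycled when
    # the class sizes differ) and embed 8mer sites at fixed offsets.
    pair_rows = []
    site_offsets = [
        first_offset + i * (site_span + gap)
        for i in range(spec.seed_sites_per_pair)
    ]

    def make_pairs(mirnas: list[str], genes: list[str], dm: str) -> None:
        if not mirnas or not genes:
            return
        for i in range(max(len(mirnas), len(genes))):
            pair_rows.append(
                {
                    "mirna_id": mirnas[i % len(mirnas)],
                    "gene_id": genes[i % len(genes)],
                    "mirna_direction": dm,
                    "gene_direction": "down" if dm == "up" else "up",
                    "site_offsets": ";".join(str(o) for o in site_offsets),
                }
            )

    make_pairs(up_mirnas, down_genes, "up")
    make_pairs(down_mirnas, up_genes, "down")
    targets_of: dict[str, list[str]] = {}
    for row in pair_rows:
        targets_of.setdefault(row["gene_id"], []).append(row["mirna_id"])

    # Draw order 8: transcripts; planted sites overwrite fixed offsets, then a
    # rejection pass removes accidental canonical sites of planted regulators
    # from every transcript they do not target.
    planted_site_strings = {
        mid: seed_site_strings(mirna_fasta[mid]) for mid in planted_mirnas
    }
    transcript_fasta: dict[str, str] = {}
    for gid in gene_ids:
        seq = list(_random_seq(rng, spec.transcript_length, "ACGT"))
        protected: list[tuple[int, int]] = []
        for mid in targets_of.get(gid, []):
            site = planted_site_strings[mid]["8mer"]
            for off in site_offsets:
                seq[off: off + site_span] = site
                protected.append((off, off + site_span))
        regulators = set(targets_of.get(gid, []))
        for _ in range(100):
            dirty = False
            text = "".join(seq)
            for mid in planted_mirnas:
                if mid in regulators:
                    continue
                for s in planted_site_strings[mid].values():
                    start = text.find(s)
                    while start != -1:
                        span = range(start, start + len(s))
                        redraw = [
                            i for i in span
                            if not any(a <= i < b for a, b in protected)
                        ]
                        if redraw:
                            for i in redraw:
                                seq[i] = str(rng.choice(list("ACGT")))
                            dirty = True
                        start = text.find(s, start + 1)
            if not dirty:
                break
            text = "".join(seq)
        else:  # pragma: no cover - 100 passes always suffice in practice
            raise ConfigurationError(
                f"could not scrub accidental sites from transcript {gid}"
            )
        transcript_fasta[gid] = "".join(seq)

    # Draw order 9: gene sets.  The immune term covers a fraction of the
    # planted genes plus a slice of background genes; decoy terms are random.
    planted_genes = up_genes + down_genes
    n_cover = math.ceil(spec.immune_term_coverage * len(planted_genes))
    background_pool = [g for g in gene_ids if g not in planted_genes]
    n_bg = max(5, len(background_pool) // 10)
    immune_members = set(planted_genes[:n_cover]) | set(
        rng.choice(background_pool, size=min(n_bg, len(background_pool)),
                   replace=False)
    )
    gene_sets: dict[str, set[str]] = {IMMUNE_TERM: immune_members}
    for d in range(1, 4):
        size = min(20, len(gene_ids))
        gene_sets[f"SYN:{d:04d}"] = set(
            rng.choice(gene_ids, size=size, replace=False)
        )

    truth_mirnas = pd.DataFrame(
        {
            "feature_id": up_mirnas + down_mirnas,
            "direction": ["up"] * len(up_mirnas) + ["down"] * len(down_mirnas),
        }
    )
    truth_genes = pd.DataFrame(
        {
            "feature_id": up_genes + down_genes,
            "direction": ["up"] * len(up_genes) + ["down"] * len(down_genes),
        }
    )
    truth_pairs = pd.DataFrame(
        pair_rows,
        columns=["mirna_id", "gene_id", "mirna_direction", "gene_direction",
                 "site_offsets"],
    )

    return SyntheticDataset(
        spec=spec,
        mirna_counts=mirna_counts,
        mrna_counts=mrna_counts,
        samples=samples,
        mirna_fasta=mirna_fasta,
        transcript_fasta=transcript_fasta,
        gene_sets=gene_sets,
        truth_mirnas=truth_mirnas,
        truth_genes=truth_genes,
        truth_pairs=truth_pairs,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every artifact in the formats the io module reads.

    Returns a name -> path mapping of the files written.  Output is
    byte-identical for equal specs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": out / "mirna_counts.tsv",
        "mrna_counts": out / "mrna_counts.tsv",
        "metadata": out / "samples.tsv",
        "mirna_fasta": out / "mirnas.fasta",
        "transcript_fasta": out / "transcripts.fasta",
        "gene_sets": out / "gene_sets.gmt",
        "truth_mirnas": out / "truth_mirna_signature.tsv",
        "truth_genes": out / "truth_gene_signature.tsv",
        "truth_pairs": out / "truth_pairs.tsv",
    }
    write_counts(
        dataset.mirna_counts, dataset.samples,
        paths["mirna_counts"], paths["metadata"],
    )
    dataset.mrna_counts.to_csv(
        paths["mrna_counts"], sep="\t", index_label="feature_id"
    )
    for key, fasta in (
        ("mirna_fasta", dataset.mirna_fasta),
        ("transcript_fasta", dataset.transcript_fasta),
    ):
        with open(paths[key], "w") as fh:
            for name in fasta:
                fh.write(f">{name}\n{fasta[name]}\n")
    write_gene_sets(
        dataset.gene_sets, paths["gene_sets"],
        descriptions={IMMUNE_TERM: "immune system process"},
    )
    dataset.truth_mirnas.to_csv(paths["truth_mirnas"], sep="\t", index=False)
    dataset.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    dataset.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    return paths


def truth_recovery_report(
    planted: set, called: set
) -> tuple[float, float]:
    """Sensitivity and false discovery rate of a called set against truth.

    sensitivity = |called ∩ planted| / |planted| (0 when nothing planted);
    FDR = |called \\ planted| / max(|called|, 1).
    """
    planted = set(planted)
    called = set(called)
    sensitivity = len(called & planted) / len(planted) if planted else 0.0
    fdr = len(called - planted) / max(len(called), 1)
    return sensitivity, fdr


def signature_recovery(
    truth: ICDSignature, called: ICDSignature
) -> dict[str, tuple[float, float]]:
    """Per-direction and pooled (sensitivity, FDR) of a called signature."""
    return {
        "up": truth_recovery_report(truth.up, called.up),
        "down": truth_recovery_report(truth.down, called.down),
        "pooled": truth_recovery_report(truth.members, called.members),
    }
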