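"""Consensus miRNA target prediction with de-novo seed-site scanning.

The cascade mirrors the screening workflow: (1) keep genes predicted by at
least k independent prediction tools; (2) intersect with the progressively
up-regulated genes (a suppressed miRNA's targets are expected to rise);
(3) require a canonical seed-match site in the gene's 3'-UTR; (4) rank the
survivors by peak abundance and anti-correlation with the miRNA.

Seed-site classes follow the canonical taxonomy. With the mature miRNA
written 5'->3', the UTR match strings (sense strand, 5'->3', DNA alphabet)
are:

    6mer     reverse complement of miRNA nt 2-7
    7mer-m8  reverse complement of miRNA nt 2-8
    7mer-A1  reverse complement of nt 2-7, followed by 'A'
    8mer     reverse complement of nt 2-8, followed by 'A'

The 7mer-A1/8mer classes require a literal adenosine in the UTR opposite
miRNA position 1, hence the trailing 'A'. Coordinates are 1-based
inclusive on the sense strand of the supplied UTR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import STAGES, GeneList, SampleManifest
from .quantify import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, log2_ratio

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: specificity precedence for collapsing nested matches
_SPECIFICITY = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA; sequence given 5'->3', stored on the DNA alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if len(self.sequence) < 8:
            raise ValueError(f"{self.id}: mature miRNA shorter than 8 nt")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: illegal characters {sorted(bad)}")


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match occurrence, 1-based inclusive coordinates."""

    utr_id: str
    start: int
    end: int
    site_class: str
    matched_seq: str

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        if self.end - self.start + 1 != len(self.matched_seq):
            raise ValueError("site coordinates do not match matched_seq length")
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_class]
        if len(self.matched_seq) != expected:
            raise ValueError(
                f"{self.site_class} site must be {expected} nt, "
                f"got {len(self.matched_seq)}"
            )


@dataclass(frozen=True)
class PredictionSet:
    tool_name: str
    mirna_id: str
    genes: GeneList


@dataclass(frozen=True)
class CandidateTarget:
    gene: str
    support_count: int
    upregulated: bool
    seed_sites: tuple[SeedSite, ...]
    peak_expression: float
    anticorr: float  # nan when undefined (fewer than 2 points or zero variance)


def derive_seed_matches(mirna: MatureMiRNA) -> dict[str, str]:
    """UTR match strings for each canonical site class of one miRNA."""
    seq = mirna.sequence
    seed_2_7 = seq[1:7]
    seed_2_8 = seq[1:8]
    return {
        "6mer": revcomp(seed_2_7),
        "7mer-m8": revcomp(seed_2_8),
        "7mer-A1": revcomp(seed_2_7) + "A",
        "8mer": revcomp(seed_2_8) + "A",
    }


def scan_utr(utr_id: str, utr_seq: str, mirna: MatureMiRNA) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` in a sense-strand 3'-UTR.

    Overlapping matches at the same locus collapse to the most specific
    class (8mer > 7mer-m8 >= 7mer-A1 > 6mer): a site wholly contained in a
    retained, more specific site is suppressed. Output is sorted by start.
    """
    utr = utr_seq.upper().replace("U", "T")
    matches = derive_seed_matches(mirna)
    raw: list[SeedSite] = []
    for cls in SITE_CLASSES:  # most specific first
        pattern = matches[cls]
        start = utr.find(pattern)
        while start != -1:
            raw.append(
                SeedSite(utr_id, start + 1, start + len(pattern), cls, pattern)
            )
            start = utr.find(pattern, start + 1)
    kept: list[SeedSite] = []
    for site in sorted(raw, key=lambda s: (-_SPECIFICITY[s.site_class], s.start)):
        contained = any(
            k.start <= site.start
            and site.end <= k.end
            and _SPECIFICITY[k.site_class] > _SPECIFICITY[site.site_class]
            for k in kept
        )
        duplicate = any((k.start, k.end) == (site.start, site.end) for k in kept)
        if not contained and not duplicate:
            kept.append(site)
    return sorted(kept, key=lambda s: (s.start, -_SPECIFICITY[s.site_class]))


def consensus_targets(sets: Sequence[PredictionSet], k: int = 3) -> GeneList:
    """Genes predicted by at least ``k`` tools for the same miRNA."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sets:
        return GeneList("consensus", frozenset())
    mirnas = {s.mirna_id for s in sets}
    if len(mirnas) > 1:
        raise ValueError(f"prediction sets mix miRNAs: {sorted(mirnas)}")
    names = [s.tool_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("tool names must be unique within a run")
    support: dict[str, int] = {}
    for s in sets:
        for g in s.genes.genes:
            support[g] = support.get(g, 0) + 1
    return GeneList("consensus", frozenset(g for g, c in support.items() if c >= k))


def support_counts(sets: Sequence[PredictionSet]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in sets:
        for g in s.genes.genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def intersect_upregulated(predicted: GeneList, upregulated: GeneList) -> GeneList:
    """Case-insensitive intersection of predictions with up-regulated genes."""
    return predicted.intersect(upregulated, name="predicted_upregulated")


MIN_SITE_CLASSES = {
    "6mer": {"6mer", "7mer-A1", "7mer-m8", "8mer"},
    "7mer": {"7mer-A1", "7mer-m8", "8mer"},
    "8mer": {"8mer"},
}


def seed_filter(
    genes: GeneList,
    utrs: Mapping[str, str],
    mirna: MatureMiRNA,
    min_site_class: str = "7mer",
) -> GeneList:
    """Keep genes whose 3'-UTR carries at least one site of the minimum class.

    Genes without a UTR record are dropped with a warning.
    """
    accepted = MIN_SITE_CLASSES[min_site_class]
    utrs_upper = {g.upper(): seq for g, seq in utrs.items()}
    kept = set()
    for gene in genes.genes:
        if gene not in utrs_upper:
            warnings.warn(f"no UTR record for gene {gene}; dropped", stacklevel=2)
            continue
        sites = scan_utr(gene, utrs_upper[gene], mirna)
        if any(s.site_class in accepted for s in sites):
            kept.add(gene)
    return GeneList("seed_filtered", frozenset(kept))


def _stagewise_log2_ratios(
    expr: ExpressionMatrix,
    feature_id: str,
    manifest: SampleManifest,
    assay: str,
    pseudo: float,
) -> np.ndarray:
    """Per-patient stage-wise log2 ratios relative to the normal stage.

    Two points per patient (OLP/normal, OSCC/normal), concatenated over
    patients — the co-expression profile a log2-ratio trajectory plot shows.
    """
    sub = manifest.subset(assay)
    ratios = []
    for patient in sub.patients(assay):
        vals = [
            expr.value(feature_id, sub.sample_for(patient, stage, assay))
            for stage in STAGES
        ]
        ratios.append(log2_ratio(vals[1], vals[0], pseudo))
        ratios.append(log2_ratio(vals[2], vals[0], pseudo))
    return np.array(ratios)


def rank_candidates(
    genes: GeneList,
    mrna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    mirna: MatureMiRNA,
    manifest: SampleManifest,
    utrs: Mapping[str, str] | None = None,
    support: Mapping[str, int] | None = None,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
) -> list[CandidateTarget]:
    """Rank cascade survivors: peak abundance first, then anti-correlation.

    ``anticorr`` is the Pearson correlation between the gene's and the
    miRNA's per-patient stage-wise log2 ratios relative to normal (2 points
    per patient); undefined (nan, ranked last) when either vector has zero
    variance. Ties break on the gene symbol for determinism.
    """
    mirna_ratios = _stagewise_log2_ratios(
        mirna_expr, mirna.id, manifest, "miRNA", pseudo
    )
    feature_index = {f.upper(): f for f in mrna_expr.feature_ids}
    candidates = []
    for gene in genes.genes:
        fid = feature_index.get(gene)
        if fid is None:
            warnings.warn(f"no expression for gene {gene}; dropped", stacklevel=2)
            continue
        gene_ratios = _stagewise_log2_ratios(mrna_expr, fid, manifest, "mRNA", pseudo)
        anticorr = float("nan")
        if (
            len(gene_ratios) >= 2
            and np.std(gene_ratios) > 0
            and np.std(mirna_ratios) > 0
        ):
            anticorr = float(np.corrcoef(gene_ratios, mirna_ratios)[0, 1])
        peak = float(mrna_expr.values[mrna_expr.feature_ids.index(fid)].max())
        sites: tuple[SeedSite, ...] = ()
        if utrs is not None:
            utr = {g.upper(): s for g, s in utrs.items()}.get(gene)
            if utr is not None:
                sites = tuple(scan_utr(gene, utr, mirna))
        candidates.append(
            CandidateTarget(
                gene=gene,
                support_count=(support or {}).get(gene, 0),
                upregulated=True,
                seed_sites=sites,
                peak_expression=peak,
                anticorr=anticorr,
            )
        )
    return sorted(
        candidates,
        key=lambda c: (
            -c.peak_expression,
            np.isnan(c.anticorr),  # defined correlations first
            c.anticorr if not np.isnan(c.anticorr) else 0.0,
            c.gene,
        ),
    )


def downstream_intersection(
    upregulated: GeneList, regulator_targets: GeneList
) -> GeneList:
    """Up-regulated genes that are also known targets of a regulator.

    Mirrors the final narrowing step: intersecting the progression-screen
    up list with a regulator's curated target list (e.g. a pathway-analysis
    export) to find downstream effectors.
    """
    return upregulated.intersect(regulator_targets, name="downstream")
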