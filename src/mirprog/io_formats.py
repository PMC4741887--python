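"""Readers and writers for every external artifact the pipeline touches.

All tabular inputs are tab-separated text; sequences are FASTA. Readers
validate aggressively and raise :class:`FormatError` or
:class:`ManifestError` with a located message rather than propagating a
half-parsed object. Writer/reader pairs round-trip exactly on the domain
types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

STAGES = ("normal", "OLP", "OSCC")
ASSAYS = ("miRNA", "mRNA")

#: Stage index used wherever stage order matters (progression filtering,
#: simulation effects): normal < OLP < OSCC.
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

_SEQ_ALPHABET = set("ACGTUN")


class FormatError(ValueError):
    """An input file violates the expected dialect or a type invariant."""


class ManifestError(ValueError):
    """A sample manifest is inconsistent with itself or with a count table."""


@dataclass(frozen=True)
class SampleManifest:
    """Maps sequencing samples to (patient, tissue stage, assay).

    Stages follow the fixed progression order normal < OLP < OSCC; each
    (patient, assay) group may contain at most one sample per stage.
    """

    samples: pd.DataFrame  # columns: sample_id, patient_id, stage, assay

    def __post_init__(self) -> None:
        df = self.samples
        required = {"sample_id", "patient_id", "stage", "assay"}
        missing = required - set(df.columns)
        if missing:
            raise ManifestError(f"manifest missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ManifestError(f"duplicate sample_id {dup!r}")
        bad_stage = set(df["stage"]) - set(STAGES)
        if bad_stage:
            raise ManifestError(f"unknown stage(s) {sorted(bad_stage)}; expected {STAGES}")
        bad_assay = set(df["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ManifestError(f"unknown assay(s) {sorted(bad_assay)}; expected {ASSAYS}")
        dup_cell = df.duplicated(subset=["patient_id", "assay", "stage"])
        if dup_cell.any():
            row = df.loc[dup_cell].iloc[0]
            raise ManifestError(
                f"patient {row['patient_id']!r} assay {row['assay']!r} has more "
                f"than one {row['stage']!r} sample"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def patients(self, assay: str) -> list[str]:
        sub = self.samples[self.samples["assay"] == assay]
        return sorted(sub["patient_id"].unique())

    def sample_for(self, patient_id: str, stage: str, assay: str) -> str:
        """Sample id for one (patient, stage, assay) cell; error if absent."""
        df = self.samples
        hit = df[
            (df["patient_id"] == patient_id)
            & (df["stage"] == stage)
            & (df["assay"] == assay)
        ]
        if len(hit) == 0:
            raise ManifestError(
                f"no {assay} sample for patient {patient_id!r} at stage {stage!r}"
            )
        return hit["sample_id"].iloc[0]

    def subset(self, assay: str) -> "SampleManifest":
        sub = self.samples[self.samples["assay"] == assay].reset_index(drop=True)
        return SampleManifest(sub)


@dataclass
class CountMatrix:
    """Non-negative integer feature-by-sample read counts.

    ``library_sizes`` holds total mapped reads/tags per sample (N in the
    normalisation formulas) and must be at least the column sum — counted
    features are a subset of everything that mapped. ``feature_lengths``
    (base pairs, L) is present for mRNA only and switches normalisation
    from per-million to RPKM.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray
    feature_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for feature {self.feature_ids[i]!r} "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            seen: set[str] = set()
            dup = next(f for f in self.feature_ids if f in seen or seen.add(f))
            raise FormatError(f"duplicate feature_id {dup!r}")
        self.library_sizes = np.asarray(self.library_sizes)
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise FormatError("library_sizes must have one entry per sample")
        if (self.library_sizes < 1).any():
            raise FormatError("library_sizes must be positive")
        colsum = self.counts.sum(axis=0)
        if (self.library_sizes < colsum).any():
            j = int(np.argwhere(self.library_sizes < colsum)[0][0])
            raise FormatError(
                f"library size for sample {self.sample_ids[j]!r} "
                f"({self.library_sizes[j]}) is below its column sum ({colsum[j]})"
            )
        if self.feature_lengths is not None:
            self.feature_lengths = np.asarray(self.feature_lengths)
            if self.feature_lengths.shape != (len(self.feature_ids),):
                raise FormatError("feature_lengths must have one entry per feature")
            if (self.feature_lengths < 1).any():
                raise FormatError("feature_lengths must be positive")

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def library_size(self, sample_id: str) -> int:
        return int(self.library_sizes[self.sample_ids.index(sample_id)])


@dataclass(frozen=True)
class GeneList:
    """A named set of gene symbols, compared case-insensitively (uppercased)."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str]) -> "GeneList":
        return cls(name, frozenset(g.strip().upper() for g in genes if g.strip()))

    def intersect(self, other: "GeneList", name: str | None = None) -> "GeneList":
        return GeneList(name or f"{self.name}&{other.name}", self.genes & other.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def sorted(self) -> list[str]:
        return sorted(self.genes)


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.samples.to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path,
    manifest: SampleManifest | None = None,
    library_sizes: Mapping[str, int] | str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count table (header of sample ids, first column feature_id).

    An optional ``length`` column supplies per-feature lengths (mRNA).
    ``library_sizes`` may be a mapping sample->N or a 2-column sidecar TSV;
    when omitted it defaults to the column sums (recorded behaviour).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no features")
    first = df.columns[0]
    feature_ids = [str(f) for f in df[first]]
    length_col = "length" if "length" in df.columns else None
    sample_cols = [c for c in df.columns[1:] if c != length_col]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    if manifest is not None:
        known = set(manifest.sample_ids)
        unknown = [c for c in sample_cols if c not in known]
        if unknown:
            raise ManifestError(
                f"{path}: sample column(s) {unknown} absent from manifest"
            )
    counts = np.empty((len(feature_ids), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at feature "
                    f"{feature_ids[i]!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count at feature {feature_ids[i]!r}, "
                    f"sample {col!r}"
                )
            counts[i, j] = value
    lengths = None
    if length_col is not None:
        lengths = df[length_col].astype(int).to_numpy()
    if library_sizes is None:
        lib = counts.sum(axis=0)
    elif isinstance(library_sizes, (str, Path)):
        side = pd.read_csv(library_sizes, sep="\t", header=None, names=["sample", "N"])
        mapping = dict(zip(side["sample"].astype(str), side["N"].astype(int)))
        lib = np.array([mapping[c] for c in sample_cols])
    else:
        lib = np.array([int(library_sizes[c]) for c in sample_cols])
    return CountMatrix(feature_ids, sample_cols, counts, lib, lengths)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, columns=matrix.sample_ids)
    df.insert(0, "feature_id", matrix.feature_ids)
    if matrix.feature_lengths is not None:
        df["length"] = matrix.feature_lengths
    df.to_csv(path, sep="\t", index=False)


def write_library_sizes(matrix: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, n in zip(matrix.sample_ids, matrix.library_sizes):
            fh.write(f"{s}\t{int(n)}\n")


def read_fasta(path: str | Path, return_alphabet: bool = False):
    """Read FASTA into {id: sequence}, normalised to uppercase DNA (U->T).

    Alphabet is restricted to {A,C,G,T,U,N} case-insensitively; the original
    alphabet (RNA or DNA) per record is returned when ``return_alphabet``.
    """
    seqs: dict[str, str] = {}
    alphabet: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        raw = str(rec.seq).upper()
        for pos, ch in enumerate(raw, start=1):
            if ch not in _SEQ_ALPHABET:
                raise FormatError(
                    f"{path}: illegal character {ch!r} in record {rec.id!r} "
                    f"at position {pos}"
                )
        alphabet[rec.id] = "RNA" if "U" in raw else "DNA"
        seqs[rec.id] = raw.replace("U", "T")
    if return_alphabet:
        return seqs, alphabet
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """One gene symbol per line (optional 'gene' header); uppercased, deduped."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].lower() == "gene":
        lines = lines[1:]
    if not lines:
        warnings.warn(f"{path}: empty gene list", stacklevel=2)
    return GeneList.from_iterable(name or Path(path).stem, lines)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\n")
        for g in genes.sorted():
            fh.write(g + "\n")


def write_seed_sites(sites, path: str | Path, mirna_id: str) -> None:
    """BED-like 1-based TSV of seed-site occurrences."""
    with open(path, "w") as fh:
        fh.write("utr_id\tstart\tend\tsite_class\tmatched_seq\tmirna_id\n")
        for s in sites:
            fh.write(
                f"{s.utr_id}\t{s.start}\t{s.end}\t{s.site_class}\t"
                f"{s.matched_seq}\t{mirna_id}\n"
            )


def read_prediction_table(path: str | Path, tool_name: str, mirna_id: str):
    """A per-tool target-prediction export: a plain gene list per miRNA."""
    from .target_predict import PredictionSet

    genes = read_gene_list(path, name=tool_name)
    return PredictionSet(tool_name=tool_name, mirna_id=mirna_id, genes=genes)
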