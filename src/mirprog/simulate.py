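"""Synthetic-data generator with planted ground truth.

Emulates the study design the pipeline targets: paired miRNA and mRNA
sequencing libraries over P patients x 3 tissue stages (normal, OLP, OSCC),
with a set of planted progressively suppressed miRNAs, planted up-regulated
target mRNAs, 3'-UTRs carrying canonical seed sites for the true pairs, and
noisy multi-tool prediction exports.

Counts follow a negative-binomial model: for feature i in patient p at
stage s (index 0, 1, 2),

    mean_ips = baseline_i * 2**(delta_i * s) * patient_effect_p
    var      = mean + phi * mean**2

Decoys have delta = 0. The stage effect enters as a per-stage geometric
factor, so planted trajectories are monotone by construction. Baseline
abundances are heavy-tailed lognormal, mirroring real small-RNA libraries
where a few dominant miRNAs absorb most tags; planted miRNAs are drawn from
the high-abundance regime (the biological archetype is a highly expressed,
progressively silenced suppressor miRNA) and planted target genes from the
high-RPKM regime. Library sizes are the configured sequencing depth; the
counted features sum to less than it, as mapped tags always exceed the
annotated-feature subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import ASSAYS, STAGES, CountMatrix, GeneList, SampleManifest
from .target_predict import MatureMiRNA, PredictionSet, derive_seed_matches
from .validation_stats import CtRecord, IHCRecord


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 2
    n_mirnas: int = 500
    n_genes: int = 5000
    n_planted_mirnas: int = 10  # planted direction: down
    n_planted_targets_per_mirna: int = 2
    delta_mirna: float = -1.5  # log2 change per stage for planted miRNAs
    delta_target: float = 1.5  # log2 change per stage for their targets
    library_size: int = 1_000_000
    dispersion: float = 0.1  # phi in var = mu + phi*mu^2
    # heavy-tailed baselines; decoys low/medium, planted high-abundance
    mirna_baseline_logmean: float = float(np.log(30.0))
    mirna_baseline_logsd: float = 1.5
    mirna_planted_logmean: float = float(np.log(1000.0))
    mirna_planted_logsd: float = 0.5
    gene_baseline_logmean: float = float(np.log(20.0))
    gene_baseline_logsd: float = 1.2
    gene_planted_logmean: float = float(np.log(200.0))
    gene_planted_logsd: float = 0.5
    patient_effect_logsd: float = 0.1
    utr_length_min: int = 500
    utr_length_max: int = 2000
    gene_length_min: int = 500
    gene_length_max: int = 5000
    n_tools: int = 6
    tool_sensitivity: float = 0.9
    tool_fp_rate: float = 0.02
    ct_noise_sd: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_planted_mirnas > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.n_planted_mirnas * self.n_planted_targets_per_mirna > self.n_genes:
            raise ValueError("more planted targets than genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.tool_sensitivity <= 1 or not 0 <= self.tool_fp_rate <= 1:
            raise ValueError("tool rates must lie in [0, 1]")
        if self.utr_length_min < 20 or self.utr_length_max < self.utr_length_min:
            raise ValueError("invalid UTR length range")


@dataclass
class SimTruth:
    planted_mirnas: GeneList
    planted_pairs: list[tuple[str, str]]
    planted_site_positions: dict[str, tuple[int, int, str]] = field(
        default_factory=dict
    )
    mirna_sequences: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_mirnas": self.planted_mirnas.sorted(),
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "planted_site_positions": {
                g: list(v) for g, v in self.planted_site_positions.items()
            },
            "mirna_sequences": self.mirna_sequences,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_mirnas=GeneList.from_iterable(
                "planted_mirnas", payload["planted_mirnas"]
            ),
            planted_pairs=[tuple(p) for p in payload["planted_pairs"]],
            planted_site_positions={
                g: tuple(v) for g, v in payload["planted_site_positions"].items()
            },
            mirna_sequences=payload.get("mirna_sequences", {}),
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with var = mu + phi*mu^2 (Poisson when phi = 0)."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi  # NB shape parameter
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _mirna_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    planted = [f"MIR-P{i:03d}" for i in range(config.n_planted_mirnas)]
    decoys = [
        f"MIR-D{i:03d}" for i in range(config.n_mirnas - config.n_planted_mirnas)
    ]
    return planted, decoys


def _gene_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    n_planted = config.n_planted_mirnas * config.n_planted_targets_per_mirna
    planted = [f"GENE-P{i:04d}" for i in range(n_planted)]
    decoys = [f"GENE-D{i:04d}" for i in range(config.n_genes - n_planted)]
    return planted, decoys


def planted_pairs(config: SimConfig) -> list[tuple[str, str]]:
    mir_planted, _ = _mirna_ids(config)
    gene_planted, _ = _gene_ids(config)
    pairs = []
    for i, mir in enumerate(mir_planted):
        for j in range(config.n_planted_targets_per_mirna):
            pairs.append((mir, gene_planted[i * config.n_planted_targets_per_mirna + j]))
    return pairs


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, SampleManifest, SimTruth]:
    """Draw paired miRNA/mRNA count matrices with planted progression."""
    rng = np.random.default_rng(config.rng_seed)
    mir_planted, mir_decoys = _mirna_ids(config)
    gene_planted, gene_decoys = _gene_ids(config)
    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]

    rows = []
    for patient in patients:
        for assay in ASSAYS:
            for stage in STAGES:
                rows.append(
                    {
                        "sample_id": f"{patient}_{stage}_{assay}",
                        "patient_id": patient,
                        "stage": stage,
                        "assay": assay,
                    }
                )
    manifest = SampleManifest(pd.DataFrame(rows))

    def build_matrix(
        planted_ids, decoy_ids, planted_logmean, planted_logsd,
        decoy_logmean, decoy_logsd, delta_planted, lengths,
    ) -> CountMatrix:
        ids = planted_ids + decoy_ids
        n = len(ids)
        baselines = np.concatenate(
            [
                rng.lognormal(planted_logmean, planted_logsd, len(planted_ids)),
                rng.lognormal(decoy_logmean, decoy_logsd, len(decoy_ids)),
            ]
        )
        delta = np.zeros(n)
        delta[: len(planted_ids)] = delta_planted
        assay = "mRNA" if lengths is not None else "miRNA"
        sample_ids = []
        columns = []
        for patient in patients:
            effect = rng.lognormal(0.0, config.patient_effect_logsd)
            for s, stage in enumerate(STAGES):
                mean = baselines * (2.0 ** (delta * s)) * effect
                columns.append(_nb_draw(rng, mean, config.dispersion))
                sample_ids.append(f"{patient}_{stage}_{assay}")
        counts = np.stack(columns, axis=1).astype(np.int64)
        lib = np.maximum(config.library_size, counts.sum(axis=0))
        return CountMatrix(ids, sample_ids, counts, lib, lengths)

    mirna_counts = build_matrix(
        mir_planted, mir_decoys,
        config.mirna_planted_logmean, config.mirna_planted_logsd,
        config.mirna_baseline_logmean, config.mirna_baseline_logsd,
        config.delta_mirna, lengths=None,
    )
    gene_lengths = rng.integers(
        config.gene_length_min, config.gene_length_max + 1, config.n_genes
    )
    mrna_counts = build_matrix(
        gene_planted, gene_decoys,
        config.gene_planted_logmean, config.gene_planted_logsd,
        config.gene_baseline_logmean, config.gene_baseline_logsd,
        config.delta_target, lengths=gene_lengths,
    )

    # synthetic mature miRNA sequences (5'->3' RNA); fixed per planted miRNA
    mirna_sequences = {
        mir: "".join(rng.choice(list("ACGU"), size=22)) for mir in mir_planted
    }
    truth = SimTruth(
        planted_mirnas=GeneList.from_iterable("planted_mirnas", mir_planted),
        planted_pairs=planted_pairs(config),
        mirna_sequences=mirna_sequences,
    )
    return mirna_counts, mrna_counts, manifest, truth


def simulate_utrs(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Random 3'-UTRs; planted pairs get a 7mer-A1 or 8mer site at a
    recorded position, and decoy UTRs are regenerated until they carry no
    >=7mer site for any planted miRNA (a cleaning step so chance hits do
    not contaminate the planted truth)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    gene_planted, gene_decoys = _gene_ids(config)
    site_by_gene = {g: m for m, g in truth.planted_pairs}
    mirnas = {
        mid: MatureMiRNA(mid, seq) for mid, seq in truth.mirna_sequences.items()
    }
    # a UTR is "clean" when it contains none of the >=7mer match strings of
    # any planted miRNA; the 8mer contains both 7mers, so two checks suffice
    forbidden = sorted(
        {
            derive_seed_matches(m)[cls]
            for m in mirnas.values()
            for cls in ("7mer-m8", "7mer-A1")
        }
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def random_seq(length: int) -> str:
        return bytes(bases[rng.integers(0, 4, size=length)]).decode("ascii")

    utrs: dict[str, str] = {}
    for gene in gene_planted + gene_decoys:
        length = int(rng.integers(config.utr_length_min, config.utr_length_max + 1))
        mir_id = site_by_gene.get(gene)
        for _ in range(200):
            seq = random_seq(length)
            if not any(pat in seq for pat in forbidden):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not generate a clean UTR for {gene}")
        if mir_id is not None:
            matches = derive_seed_matches(mirnas[mir_id])
            cls = "8mer" if rng.random() < 0.5 else "7mer-A1"
            insert = matches[cls]
            start0 = int(rng.integers(0, length - len(insert) + 1))
            seq = seq[:start0] + insert + seq[start0 + len(insert):]
            truth.planted_site_positions[gene] = (
                start0 + 1,
                start0 + len(insert),
                cls,
            )
        utrs[gene] = seq
    return utrs


def simulate_prediction_sets(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator | None = None
) -> dict[str, list[PredictionSet]]:
    """Noisy per-tool target exports for each planted miRNA.

    Each tool reports a true target independently with probability
    ``tool_sensitivity`` and each decoy gene with probability
    ``tool_fp_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    _, gene_decoys = _gene_ids(config)
    targets_by_mir: dict[str, list[str]] = {}
    for mir, gene in truth.planted_pairs:
        targets_by_mir.setdefault(mir, []).append(gene)
    tools = [f"tool{i + 1}" for i in range(config.n_tools)]
    out: dict[str, list[PredictionSet]] = {}
    for mir in sorted(targets_by_mir):
        sets = []
        for tool in tools:
            genes = [
                g
                for g in targets_by_mir[mir]
                if rng.random() < config.tool_sensitivity
            ]
            fp_mask = rng.random(len(gene_decoys)) < config.tool_fp_rate
            genes.extend(g for g, hit in zip(gene_decoys, fp_mask) if hit)
            sets.append(
                PredictionSet(tool, mir, GeneList.from_iterable(tool, genes))
            )
        out[mir] = sets
    return out


def simulate_validation_tables(
    config: SimConfig,
    truth: SimTruth,
    n_per_group: int = 15,
    planted_fold: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CtRecord], list[CtRecord], pd.DataFrame]:
    """qPCR Ct records and an IHC score table consistent with the planting.

    Case-group target Ct values are shifted by -log2(fold) relative to
    controls (reference gene flat), plus Gaussian noise of sd
    ``ct_noise_sd`` (0 reproduces the planted fold exactly). The IHC table
    draws case percent/intensity stochastically above controls, with two
    correlated markers per sample (a regulator and its downstream effector).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 3)
    if planted_fold is None:
        # overall normal->OSCC fold for a planted target: 2**(2*delta)
        planted_fold = float(2.0 ** (2 * config.delta_target))
    shift = -np.log2(planted_fold)
    sd = config.ct_noise_sd
    controls = [
        CtRecord(
            f"ctrl{i:02d}",
            "control",
            25.0 + rng.normal(0, sd),
            20.0 + rng.normal(0, sd),
        )
        for i in range(n_per_group)
    ]
    cases = [
        CtRecord(
            f"case{i:02d}",
            "case",
            25.0 + shift + rng.normal(0, sd),
            20.0 + rng.normal(0, sd),
        )
        for i in range(n_per_group)
    ]
    ihc_rows = []
    for i in range(n_per_group):
        for group, lo, hi, intensities in (
            ("control", 0.0, 30.0, (0, 1)),
            ("case", 50.0, 100.0, (2, 3)),
        ):
            base = rng.uniform(lo, hi)
            for marker in ("regulator", "effector"):
                pct = float(np.clip(base + rng.normal(0, 5.0), 0, 100))
                rec = IHCRecord(
                    f"{group}{i:02d}", pct, int(rng.choice(intensities))
                )
                ihc_rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "group": group,
                        "marker": marker,
                        "percent_positive": rec.percent_positive,
                        "intensity": rec.intensity,
                        "a": rec.a,
                        "score": rec.score,
                    }
                )
    return cases, controls, pd.DataFrame(ihc_rows)


def write_ct_table(cases, controls, path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "group": r.group,
            "ct_target": r.ct_target,
            "ct_reference": r.ct_reference,
        }
        for r in list(cases) + list(controls)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> tuple[list[CtRecord], list[CtRecord]]:
    df = pd.read_csv(path, sep="\t")
    records = [
        CtRecord(str(r.sample_id), str(r.group), float(r.ct_target), float(r.ct_reference))
        for r in df.itertuples()
    ]
    cases = [r for r in records if r.group == "case"]
    controls = [r for r in records if r.group == "control"]
    return cases, controls


def config_to_json(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, sort_keys=True))
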