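"""End-to-end orchestration: simulate -> screen -> predict -> validate -> report.

The run report is a machine-readable JSON object containing every threshold
used, the screen's up/down counts, the target-prediction cascade
cardinalities (consensus, intersection with up-regulated genes, seed
filter, final candidates), the downstream regulator intersection, the
validation statistics, and — when planted truth is available — sensitivity
and false-discovery metrics against it. Reports are byte-identical across
reruns with the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .io_formats import (
    GeneList,
    write_count_table,
    write_fasta,
    write_gene_list,
    write_library_sizes,
    write_manifest,
    write_seed_sites,
)
from .progression_screen import (
    ScreenThresholds,
    screen_mirnas,
    screen_upregulated_mrnas,
)
from .quantify import normalize
from .simulate import (
    SimConfig,
    SimTruth,
    simulate_counts,
    simulate_prediction_sets,
    simulate_utrs,
    simulate_validation_tables,
    write_ct_table,
)
from .target_predict import (
    MatureMiRNA,
    consensus_targets,
    downstream_intersection,
    intersect_upregulated,
    rank_candidates,
    seed_filter,
    support_counts,
)
from .validation_stats import ddct_fold, mann_whitney_u, spearman_rho


@dataclass
class RunConfig:
    out_dir: str = "mirprog_run"
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    consensus_k: int = 3
    min_site_class: str = "7mer"
    rng_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "sim": asdict(self.sim),
                "thresholds": asdict(self.thresholds),
                "consensus_k": self.consensus_k,
                "min_site_class": self.min_site_class,
                "rng_seed": self.rng_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _screen_truth_metrics(result, truth: SimTruth) -> dict:
    planted = truth.planted_mirnas.genes
    called = result.up.genes | result.down.genes
    recovered = planted & result.down.genes  # planted direction is down
    false_calls = called - planted
    return {
        "n_planted": len(planted),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(planted) if planted else float("nan"),
        "n_called": len(called),
        "n_false_calls": len(false_calls),
        "screen_fdr": len(false_calls) / len(called) if called else 0.0,
    }


def run_full_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the whole simulated screen and return the run report."""
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(**{**asdict(config.sim), "rng_seed": config.rng_seed})
    stage = "simulate"
    try:
        mirna_counts, mrna_counts, manifest, truth = simulate_counts(sim)
        utrs = simulate_utrs(sim, truth)
        predictions = simulate_prediction_sets(sim, truth)
        ct_cases, ct_controls, ihc = simulate_validation_tables(sim, truth)
        if write_outputs:
            write_manifest(manifest, out / "manifest.tsv")
            write_count_table(mirna_counts, out / "mirna_counts.tsv")
            write_count_table(mrna_counts, out / "mrna_counts.tsv")
            write_library_sizes(mirna_counts, out / "mirna_library_sizes.tsv")
            write_library_sizes(mrna_counts, out / "mrna_library_sizes.tsv")
            write_fasta(utrs, out / "utrs.fasta")
            write_fasta(
                {m: s for m, s in sorted(truth.mirna_sequences.items())},
                out / "mature_mirnas.fasta",
            )
            write_ct_table(ct_cases, ct_controls, out / "ct_table.tsv")
            ihc.to_csv(out / "ihc_table.tsv", sep="\t", index=False)
            truth.to_json(out / "truth.json")
            for mir, sets in predictions.items():
                tool_dir = out / "predictions" / mir
                tool_dir.mkdir(parents=True, exist_ok=True)
                for s in sets:
                    write_gene_list(s.genes, tool_dir / f"{s.tool_name}.tsv")

        stage = "screen"
        screen = screen_mirnas(mirna_counts, manifest, config.thresholds)
        upregulated = screen_upregulated_mrnas(
            mrna_counts, manifest, config.thresholds
        )
        if write_outputs:
            write_gene_list(screen.up, out / "mirnas_up.tsv")
            write_gene_list(screen.down, out / "mirnas_down.tsv")
            write_gene_list(upregulated, out / "genes_upregulated.tsv")

        stage = "predict"
        mirna_expr = normalize(mirna_counts)
        mrna_expr = normalize(mrna_counts)
        cascade = {}
        candidates_by_mir = {}
        screened_mirs = [
            m for m in sorted(predictions) if m.upper() in screen.down.genes
        ]
        for mir in screened_mirs:
            sets = predictions[mir]
            consensus = consensus_targets(sets, config.consensus_k)
            intersected = intersect_upregulated(consensus, upregulated)
            filtered = seed_filter(
                intersected,
                utrs,
                MatureMiRNA(mir, truth.mirna_sequences[mir]),
                config.min_site_class,
            )
            ranked = rank_candidates(
                filtered,
                mrna_expr,
                mirna_expr,
                MatureMiRNA(mir, truth.mirna_sequences[mir]),
                manifest,
                utrs=utrs,
                support=support_counts(sets),
            )
            cascade[mir] = {
                "n_consensus": len(consensus),
                "n_intersected": len(intersected),
                "n_seed_filtered": len(filtered),
                "n_candidates": len(ranked),
            }
            candidates_by_mir[mir] = ranked
            if write_outputs and ranked:
                sites = [s for c in ranked for s in c.seed_sites]
                write_seed_sites(sites, out / f"seed_sites_{mir}.tsv", mir)

        # simulated regulator->target export for the downstream narrowing
        rng = np.random.default_rng(config.rng_seed + 4)
        regulator_genes: set[str] = set()
        if candidates_by_mir:
            first_mir = screened_mirs[0]
            top = candidates_by_mir[first_mir][:1]
            regulator_genes |= {c.gene for c in top}
        decoy_pool = [f for f in mrna_counts.feature_ids if f.startswith("GENE-D")]
        extra = rng.choice(len(decoy_pool), size=min(49, len(decoy_pool)), replace=False)
        regulator_genes |= {decoy_pool[i] for i in extra}
        regulator_list = GeneList.from_iterable("regulator_targets", regulator_genes)
        downstream = downstream_intersection(upregulated, regulator_list)
        if write_outputs:
            write_gene_list(regulator_list, out / "regulator_targets_synthetic.tsv")
            write_gene_list(downstream, out / "downstream_intersection.tsv")

        stage = "validate"
        fold = ddct_fold(ct_cases, ct_controls)
        ihc_case = ihc[ihc["group"] == "case"]["score"].to_numpy()
        ihc_ctrl = ihc[ihc["group"] == "control"]["score"].to_numpy()
        u, u_p = mann_whitney_u(ihc_case, ihc_ctrl)
        reg = ihc[ihc["marker"] == "regulator"].sort_values("sample_id")
        eff = ihc[ihc["marker"] == "effector"].sort_values("sample_id")
        corr = spearman_rho(reg["score"].to_numpy(), eff["score"].to_numpy())

        stage = "truth"
        truth_metrics = _screen_truth_metrics(screen, truth)
        pair_stats = _pair_recovery(
            truth, screen, upregulated, candidates_by_mir
        )

        report = {
            "schema_version": 1,
            "tool_version": __version__,
            "config_hash": config.config_hash(),
            "rng_seed": config.rng_seed,
            "thresholds": asdict(config.thresholds),
            "consensus_k": config.consensus_k,
            "min_site_class": config.min_site_class,
            "screen": {
                "n_mirnas_tested": len(mirna_counts.feature_ids),
                "n_up": len(screen.up),
                "n_down": len(screen.down),
                "n_genes_tested": len(mrna_counts.feature_ids),
                "n_genes_upregulated": len(upregulated),
            },
            "cascade": cascade,
            "candidates": {
                mir: [
                    {
                        "gene": c.gene,
                        "support_count": c.support_count,
                        "peak_expression": c.peak_expression,
                        "anticorr": None if np.isnan(c.anticorr) else c.anticorr,
                        "n_seed_sites": len(c.seed_sites),
                    }
                    for c in ranked
                ]
                for mir, ranked in candidates_by_mir.items()
            },
            "downstream_intersection": downstream.sorted(),
            "validation": {
                "ddct_fold": fold,
                "ihc_mannwhitney_u": u,
                "ihc_mannwhitney_p": u_p,
                "ihc_marker_spearman_rho": corr.rho,
                "ihc_marker_spearman_p": corr.p,
            },
            "truth_metrics": {**truth_metrics, **pair_stats},
        }
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if write_outputs:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "run.log").write_text(
            f"mirprog {__version__}\nconfig_hash {config.config_hash()}\n"
            f"seed {config.rng_seed}\n"
        )
    return report


def _pair_recovery(truth, screen, upregulated, candidates_by_mir) -> dict:
    """Planted-pair recovery through the full cascade.

    A pair is *eligible* when its miRNA was screened down and its mRNA was
    recovered by the up-regulation screen; an eligible pair is *recovered*
    when the gene appears in the miRNA's final candidate list.
    """
    eligible = 0
    recovered = 0
    for mir, gene in truth.planted_pairs:
        if mir.upper() not in screen.down.genes:
            continue
        if gene.upper() not in upregulated.genes:
            continue
        eligible += 1
        ranked = candidates_by_mir.get(mir, [])
        if any(c.gene == gene.upper() for c in ranked):
            recovered += 1
    return {
        "n_pairs_planted": len(truth.planted_pairs),
        "n_pairs_eligible": eligible,
        "n_pairs_recovered": recovered,
        "pair_recovery": recovered / eligible if eligible else float("nan"),
    }
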