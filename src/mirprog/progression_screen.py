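"""Monotone progression screening across normal -> OLP -> OSCC.

A feature is called "progressively" changed for one patient when its
stage-to-stage fold changes agree in sign across both transitions, its
overall (normal vs OSCC) fold change passes the two-fold cutoff, and the
replicate-free exact test on the extreme contrast survives FDR control.
OLP enters only through the monotonicity requirement; the statistical test
is run on the normal-vs-OSCC contrast, the extreme of the progression.
A feature is reported only when every patient agrees on the direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import STAGES, CountMatrix, GeneList, ManifestError, SampleManifest
from .quantify import (
    DEFAULT_MAX_Q,
    DEFAULT_MIN_ABS_LOG2FC,
    DEFAULT_PSEUDOCOUNT,
    ac_exact_test,
    bh_fdr,
    log2_ratio,
    normalize,
)


@dataclass(frozen=True)
class ScreenThresholds:
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC
    max_q: float = DEFAULT_MAX_Q
    pseudo: float = DEFAULT_PSEUDOCOUNT
    #: require each individual transition to pass the two-fold cutoff too
    strict_transitions: bool = False
    #: treat a transition log2fc of exactly 0 as monotone
    allow_flat_transition: bool = False


@dataclass(frozen=True)
class ProgressionCall:
    feature_id: str
    patient_id: str
    stage_values: tuple[float, float, float]  # normal, OLP, OSCC (normalised)
    transition_log2fc: tuple[float, float]  # normal->OLP, OLP->OSCC
    overall_log2fc: float  # normal->OSCC
    direction: str  # up | down | none


@dataclass
class ScreenResult:
    up: GeneList
    down: GeneList
    per_feature_calls: list[ProgressionCall] = field(default_factory=list)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)

    def __post_init__(self) -> None:
        if self.up.genes & self.down.genes:
            raise ValueError("up and down sets must be disjoint")


def progression_call(
    feature_id: str,
    patient_id: str,
    stage_values: tuple[float, float, float],
    q_extreme: float,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> ProgressionCall:
    """Classify one feature in one patient from its three stage values.

    ``stage_values`` are normalised expression at (normal, OLP, OSCC);
    ``q_extreme`` is the FDR-adjusted exact-test p for normal vs OSCC,
    computed over the whole feature family for that patient contrast.
    """
    v_n, v_olp, v_oscc = (float(v) for v in stage_values)
    if any(v is None or np.isnan(v) for v in (v_n, v_olp, v_oscc)):
        raise ManifestError(
            f"missing stage value for feature {feature_id!r}, patient {patient_id!r}"
        )
    t1 = log2_ratio(v_olp, v_n, thresholds.pseudo)
    t2 = log2_ratio(v_oscc, v_olp, thresholds.pseudo)
    overall = log2_ratio(v_oscc, v_n, thresholds.pseudo)

    def monotone(sign: int) -> bool:
        ok = lambda t: sign * t > 0 or (thresholds.allow_flat_transition and t == 0)
        if not (ok(t1) and ok(t2)):
            return False
        if thresholds.strict_transitions and not (
            abs(t1) >= thresholds.min_abs_log2fc and abs(t2) >= thresholds.min_abs_log2fc
        ):
            return False
        return True

    direction = "none"
    if abs(overall) >= thresholds.min_abs_log2fc and q_extreme <= thresholds.max_q:
        if overall > 0 and monotone(+1):
            direction = "up"
        elif overall < 0 and monotone(-1):
            direction = "down"
    return ProgressionCall(
        feature_id,
        patient_id,
        (v_n, v_olp, v_oscc),
        (t1, t2),
        overall,
        direction,
    )


def cross_patient_consensus(calls: list[ProgressionCall]) -> str:
    """A direction only when every patient's call shares it; else none."""
    if not calls:
        raise ValueError("consensus requires at least one patient call")
    directions = {c.direction for c in calls}
    if len(directions) == 1 and directions != {"none"}:
        return directions.pop()
    return "none"


def _screen(
    counts: CountMatrix,
    manifest: SampleManifest,
    assay: str,
    thresholds: ScreenThresholds,
) -> ScreenResult:
    sub = manifest.subset(assay)
    patients = sub.patients(assay)
    if not patients:
        raise ManifestError(f"manifest has no {assay} samples")
    missing = set(sub.sample_ids) ^ set(counts.sample_ids)
    if missing:
        raise ManifestError(
            f"manifest/count-table sample mismatch for assay {assay}: {sorted(missing)}"
        )
    expr = normalize(counts)
    n_feat = len(counts.feature_ids)

    per_patient_calls: dict[str, list[ProgressionCall]] = {}
    for patient in patients:
        cols = {s: sub.sample_for(patient, s, assay) for s in STAGES}
        x = counts.column(cols["normal"])
        y = counts.column(cols["OSCC"])
        n1 = counts.library_size(cols["normal"])
        n2 = counts.library_size(cols["OSCC"])
        # family-wide FDR within this patient's extreme contrast
        p = ac_exact_test(x=x, y=y, n1=n1, n2=n2)
        q = bh_fdr(np.atleast_1d(p))
        values = {s: expr.column(cols[s]) for s in STAGES}
        calls = [
            progression_call(
                counts.feature_ids[i],
                patient,
                (values["normal"][i], values["OLP"][i], values["OSCC"][i]),
                q[i],
                thresholds,
            )
            for i in range(n_feat)
        ]
        per_patient_calls[patient] = calls

    up, down = set(), set()
    all_calls: list[ProgressionCall] = []
    for i, fid in enumerate(counts.feature_ids):
        calls = [per_patient_calls[p][i] for p in patients]
        all_calls.extend(calls)
        consensus = cross_patient_consensus(calls)
        if consensus == "up":
            up.add(fid.upper())
        elif consensus == "down":
            down.add(fid.upper())
    return ScreenResult(
        GeneList("up", frozenset(up)),
        GeneList("down", frozenset(down)),
        all_calls,
        thresholds,
    )


def screen_mirnas(
    mirna_counts: CountMatrix,
    manifest: SampleManifest,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> ScreenResult:
    """Progression screen over the miRNA tag counts (both directions)."""
    return _screen(mirna_counts, manifest, "miRNA", thresholds)


def screen_upregulated_mrnas(
    mrna_counts: CountMatrix,
    manifest: SampleManifest,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> GeneList:
    """Genes progressively up-regulated in every patient (candidate targets)."""
    result = _screen(mrna_counts, manifest, "mRNA", thresholds)
    return GeneList("upregulated", result.up.genes)
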