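"""End-to-end orchestration: cohort -> split -> TFNBS -> metrics -> statistics.

A single root seed drives every stage through numpy SeedSequence spawning
(stream indices are fixed per stage), so reruns with the same configuration
produce identical report bundles and any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph_metrics, group_stats, tfnbs
from .core_io import (
    ClinicalRecord,
    Connectome,
    HemisphericPair,
    clinical_frame,
    read_clinical_table,
    read_connectome,
    split_hemispheres,
)
from .synthetic_cohort import Cohort, GeneratorConfig, simulate_cohort
from .tfnbs import TfnbsParams

__all__ = ["AnalysisConfig", "run_pipeline", "summarize", "write_bundle", "load_file_cohort"]

logger = logging.getLogger(__name__)

CLINICAL_VARIABLES = ("mrc", "nihss", "rmt_ratio", "tumor_volume_cm3", "who_grade")
ALGORITHMS = ("algA", "algB")  # probabilistic-like, deterministic-like replicate
SUBGROUP_CHOICES = ("all", "precentral", "postcentral", "insular", "frontal")


@dataclass
class AnalysisConfig:
    """Pipeline configuration; exactly one input mode (synthetic or files)."""

    mode: str = "synthetic"  # synthetic | files
    input_dir: str | None = None  # required for mode="files"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    tfnbs_params: TfnbsParams = field(default_factory=TfnbsParams)
    subgroups: tuple[str, ...] = ("all", "precentral", "postcentral", "insular", "frontal")
    n_rand: int = 100  # small-world null count
    compute_metrics: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("mode='files' requires input_dir")
        unknown = set(self.subgroups) - set(SUBGROUP_CHOICES)
        if unknown:
            raise ValueError(f"unknown subgroup filters: {sorted(unknown)}")

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class SubjectData:
    subject_id: str
    clinical: ClinicalRecord
    connectomes: dict[str, Connectome]  # per algorithm


def load_file_cohort(input_dir) -> list[SubjectData]:
    """Load a cohort written by the generator (or hand-prepared likewise):
    <subject_id>_algA.tsv / _algB.tsv plus clinical.csv."""
    root = Path(input_dir)
    records = read_clinical_table(root / "clinical.csv")
    subjects = []
    for rec in records:
        conns = {
            alg: read_connectome(root / f"{rec.subject_id}_{alg}.tsv")
            for alg in ALGORITHMS
        }
        subjects.append(SubjectData(rec.subject_id, rec, conns))
    return subjects


def _cohort_subjects(config: AnalysisConfig) -> tuple[list[SubjectData], Cohort | None]:
    if config.mode == "files":
        return load_file_cohort(config.input_dir), None
    gen = dataclasses.replace(config.generator, seed=config.generator.seed)
    cohort = simulate_cohort(gen)
    subjects = [
        SubjectData(
            s.clinical.subject_id,
            s.clinical,
            {"algA": s.connectome_a, "algB": s.connectome_b},
        )
        for s in cohort.subjects
    ]
    return subjects, cohort


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis and return the report bundle.

    For each algorithm and configured subgroup: hemispheric split, TFNBS in
    both contrast directions, per-hemisphere topology metrics, paired
    hemisphere comparisons, FDR-corrected Spearman tables over the
    TFNBS-significant edges (ipsilesional, contralesional and
    contra-minus-ipsi views), and a cross-algorithm Pearson table.
    Subgroups with fewer than 3 subjects are skipped with a warning.
    """
    subjects, cohort = _cohort_subjects(config)
    clinical = clinical_frame([s.clinical for s in subjects])
    root_ss = np.random.SeedSequence(config.seed)
    tfnbs_ss, metrics_ss = root_ss.spawn(2)

    # hemispheric split once per subject and algorithm
    pairs: dict[str, list[HemisphericPair]] = {
        alg: [split_hemispheres(s.connectomes[alg], s.clinical.lesion_side) for s in subjects]
        for alg in ALGORITHMS
    }

    # per-subject, per-hemisphere scalar metrics (shared across subgroups)
    metrics_rows: list[dict] = []
    metric_sets: dict[tuple[str, str], list] = {}
    if config.compute_metrics:
        met_rngs = iter(metrics_ss.spawn(len(subjects) * len(ALGORITHMS) * 2))
        for alg in ALGORITHMS:
            for hemi in ("ipsi", "contra"):
                sets = []
                for s, pair in zip(subjects, pairs[alg]):
                    conn = getattr(pair, hemi)
                    ms = graph_metrics.metric_set(
                        conn, n_rand=config.n_rand, seed=np.random.default_rng(next(met_rngs))
                    )
                    sets.append(ms)
                    metrics_rows.append(
                        dict(
                            subject_id=s.subject_id,
                            algorithm=alg,
                            hemisphere=hemi,
                            **ms.scalar_row(),
                        )
                    )
                metric_sets[(alg, hemi)] = sets
    metrics_table = pd.DataFrame(metrics_rows)

    blocks: dict[str, dict] = {}
    block_index = 0
    for subgroup in config.subgroups:
        if subgroup == "all":
            mask = [True] * len(subjects)
        else:
            mask = [subgroup in s.clinical.subgroup for s in subjects]
        idx = [i for i, m in enumerate(mask) if m]
        if len(idx) < 3:
            logger.warning(
                "subgroup %r has n=%d < 3 subjects; block skipped", subgroup, len(idx)
            )
            continue
        sub_clinical = clinical.iloc[idx].reset_index(drop=True)
        block: dict[str, dict] = {"n": len(idx), "algorithms": {}}
        for alg in ALGORITHMS:
            sub_pairs = [pairs[alg][i] for i in idx]
            params = dataclasses.replace(
                config.tfnbs_params,
                seed=int(tfnbs_ss.generate_state(1)[0] % 2**31) + block_index,
            )
            tf_results = {
                direction: tfnbs.permutation_fwe(sub_pairs, params, direction)
                for direction in tfnbs.DIRECTIONS
            }
            sig = {
                direction: tfnbs.significant_edges(res)
                for direction, res in tf_results.items()
            }
            correlations = _edge_clinical_correlations(sub_pairs, sub_clinical, sig)
            paired = {}
            if config.compute_metrics:
                for metric in ("global_efficiency", "local_efficiency"):
                    ipsi_vals = [metric_sets[(alg, "ipsi")][i].scalar_row()[metric] for i in idx]
                    contra_vals = [metric_sets[(alg, "contra")][i].scalar_row()[metric] for i in idx]
                    paired[metric] = group_stats.paired_compare(ipsi_vals, contra_vals)
            block["algorithms"][alg] = dict(
                tfnbs=tf_results,
                significant_edges=sig,
                correlations=correlations,
                paired_metrics=paired,
            )
        blocks[subgroup] = block
        block_index += 1

    agreement = []
    if config.compute_metrics and not metrics_table.empty:
        a = metrics_table[metrics_table.algorithm == "algA"].reset_index(drop=True)
        b = metrics_table[metrics_table.algorithm == "algB"].reset_index(drop=True)
        agreement = group_stats.cross_algorithm_agreement(
            a.drop(columns=["algorithm"]),
            b.drop(columns=["algorithm"]),
            group_columns=["hemisphere"],
        )
        agreement += group_stats.cross_algorithm_agreement(
            a.drop(columns=["algorithm", "hemisphere", "subject_id"]),
            b.drop(columns=["algorithm", "hemisphere", "subject_id"]),
        )

    manifest = dict(
        seed=config.seed,
        config_hash=config.config_hash(),
        config=_as_jsonable(config),
        n_subjects=len(subjects),
    )
    bundle = dict(
        manifest=manifest,
        clinical=clinical,
        metrics=metrics_table,
        blocks=blocks,
        agreement=agreement,
        cohort=cohort,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _edge_clinical_correlations(sub_pairs, sub_clinical, sig):
    """Three FDR families (ipsi / contra / contra-minus-ipsi edge weights x
    clinical variables) over the union of TFNBS-significant edges."""
    regions = sub_pairs[0].region_labels
    index = {r: i for i, r in enumerate(regions)}
    edges = sorted(
        {(r[0], r[1]) for rows in sig.values() for r in rows}
    )
    out = {}
    for view in ("ipsi", "contra", "diff"):
        if not edges:
            out[view] = []
            continue
        cols = {}
        for a, b in edges:
            i, j = index[a], index[b]
            if view == "ipsi":
                vals = [p.ipsi.weights[i, j] for p in sub_pairs]
            elif view == "contra":
                vals = [p.contra.weights[i, j] for p in sub_pairs]
            else:
                vals = [p.contra.weights[i, j] - p.ipsi.weights[i, j] for p in sub_pairs]
            cols[f"edge:{a}|{b}"] = vals
        feats = pd.DataFrame(cols)
        family = [(c, v) for c in feats.columns for v in CLINICAL_VARIABLES]
        out[view] = group_stats.spearman_fdr(feats, sub_clinical, family)
    return out


# ---------------------------------------------------------------------------
# reporting


def summarize(bundle: dict) -> str:
    """Deterministic human-readable markdown summary of a report bundle."""
    lines = ["# hemiconn analysis summary", ""]
    man = bundle.get("manifest", {})
    lines.append(f"seed: {man.get('seed', 'MISSING')}  config hash: {man.get('config_hash', 'MISSING')}")
    lines.append(f"subjects: {man.get('n_subjects', 'MISSING')}")
    lines.append("")
    blocks = bundle.get("blocks", {})
    if not blocks:
        lines.append("no analysis blocks (gap: all subgroups skipped or absent)")
    for subgroup, block in blocks.items():
        lines.append(f"## subgroup: {subgroup} (n={block['n']})")
        for alg, res in block["algorithms"].items():
            for direction, rows in res["significant_edges"].items():
                lines.append(
                    f"- {alg} {direction}: {len(rows)} significant edges"
                )
            for metric, pr in res.get("paired_metrics", {}).items():
                lines.append(
                    f"- {alg} {metric}: ipsi {pr.mean_ipsi:.1f} ± {pr.sd_ipsi:.1f}, "
                    f"contra {pr.mean_contra:.1f} ± {pr.sd_contra:.1f}, "
                    f"t({pr.df}) = {pr.statistic_t:.2f}, p = {pr.p_t:.4g}, "
                    f"Wilcoxon W = {pr.statistic_wilcoxon:.1f}, p = {pr.p_wilcoxon:.4g}"
                )
            n_corr = sum(len(v) for v in res["correlations"].values())
            n_sig_corr = sum(
                sum(1 for c in v if c.p_fdr < 0.05) for v in res["correlations"].values()
            )
            lines.append(
                f"- {alg} clinical correlations: {n_sig_corr} FDR-significant of {n_corr}"
            )
        lines.append("")
    agreement = bundle.get("agreement", [])
    if agreement:
        lines.append("## cross-algorithm agreement (Pearson)")
        for c in agreement:
            lines.append(f"- {c.variable_x}: r = {c.rho:.3f} (n={c.n}, p={c.p_raw:.3g})")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the bundle's text artifacts (TSVs, JSON manifest, summary)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=1, sort_keys=True)
    if isinstance(bundle.get("metrics"), pd.DataFrame) and not bundle["metrics"].empty:
        bundle["metrics"].to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    rows = []
    for subgroup, block in bundle.get("blocks", {}).items():
        for alg, res in block["algorithms"].items():
            for direction, edges in res["significant_edges"].items():
                for a, b, t, score, p in edges:
                    rows.append(
                        dict(subgroup=subgroup, algorithm=alg, direction=direction,
                             node_i=a, node_j=b, t=t, score=score, p_fwe=p)
                    )
    pd.DataFrame(
        rows, columns=["subgroup", "algorithm", "direction", "node_i", "node_j", "t", "score", "p_fwe"]
    ).to_csv(out / "significant_edges.tsv", sep="\t", index=False, float_format="%.10g")
    stats = {}
    for subgroup, block in bundle.get("blocks", {}).items():
        stats[subgroup] = {}
        for alg, res in block["algorithms"].items():
            stats[subgroup][alg] = dict(
                paired={m: vars(v) for m, v in res.get("paired_metrics", {}).items()},
                correlations={
                    view: [vars(c) for c in corrs]
                    for view, corrs in res["correlations"].items()
                },
            )
    with open(out / "stats.json", "w") as fh:
        json.dump(_as_jsonable(stats), fh, indent=1, sort_keys=True)
    with open(out / "summary.md", "w") as fh:
        fh.write(summarize(bundle))
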