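"""End-to-end orchestration: simulate/load -> date duplicates -> call CNV
genes -> rank replication timing -> stratify regions -> test battery.

The report mirrors the analyses a duplication-age/CNV/replication-timing
study runs on a real genome: the CNV-fraction-by-age table, rank-sum tests
of replication timing between CNV and non-CNV genes (overall, and split by
duplicate/singleton and young/old), the age-vs-timing Spearman correlation
(overall and per chromosomal region), and the region enrichment tests.
Every test draws on the per-gene master table, and genes missing an
annotation (e.g. no probe within 10 kb) are dropped only from the tests
that need it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import stats as st
from .cnv import CNVCallParameters, CopyNumberMatrix, call_cnv_genes, cnv_by_age_table
from .errors import DataError, PipelineStageError
from .regions import ChromosomeMap, RegionParameters, classify_gene_region
from .replication_timing import HIGHER_IS_EARLIER, RTProbeSet, assign_gene_rt
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset
from .timelines import PhylostratumTimeline, get_timeline
from .trees import assign_duplication_age, assignments_to_frame, read_tree_file

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_full_analysis", "young_old_split"]

# default young/old boundary per timeline: the oldest lineage-specific class
_DEFAULT_SPLIT = {"human": "Simiiformes", "mouse": "Glires"}


@dataclass
class PipelineConfig:
    """Inputs and parameters for one full analysis run.

    Either ``simulation`` is set (self-generated inputs) or the five input
    paths are.  ``young_split_class`` is the oldest class still counted as
    "young"; genes in that class or younger are young, strictly older ones
    are old.
    """

    simulation: Optional[SimulationConfig] = None
    trees_dir: Optional[str] = None
    genes_bed: Optional[str] = None
    cn_matrix_tsv: Optional[str] = None
    probes_tsv: Optional[str] = None
    chrom_map_tsv: Optional[str] = None
    timeline_name: str = "human"
    score_threshold: float = 0.3
    cnv_params: CNVCallParameters = field(default_factory=CNVCallParameters)
    max_distance: int = 10_000
    sign_convention: str = HIGHER_IS_EARLIER
    window: int = 5_000_000
    young_split_class: Optional[str] = None
    outdir: Optional[str] = None
    seed: int = 0

    def resolved_split_class(self, timeline: PhylostratumTimeline) -> str:
        if self.young_split_class is not None:
            if self.young_split_class not in timeline.classes:
                raise DataError(
                    f"young_split_class {self.young_split_class!r} not in timeline"
                )
            return self.young_split_class
        for key, cls in _DEFAULT_SPLIT.items():
            if key in self.timeline_name and cls in timeline.classes:
                return cls
        # fall back: the 5th-youngest class
        return timeline.classes[max(0, timeline.n_classes - 5)]


@dataclass
class AnalysisReport:
    """Master table, report tables and the test battery of one run."""

    master: pd.DataFrame
    cnv_by_age: pd.DataFrame
    tests: dict
    dropped_counts: dict
    config_echo: dict

    def tests_frame(self) -> pd.DataFrame:
        return st.results_to_frame(self.tests)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        master = self.master.copy()
        self.cnv_by_age.to_csv(
            outdir / "cnv_by_age.tsv", sep="\t", index=False, float_format="%.6g"
        )
        master.to_csv(outdir / "master_table.tsv", sep="\t", index=False,
                      float_format="%.6g")
        self.tests_frame().to_csv(
            outdir / "tests.tsv", sep="\t", index=False, float_format="%.6g"
        )
        log = {
            "config": self.config_echo,
            "dropped_counts": self.dropped_counts,
            "n_master_rows": int(len(master)),
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))


def young_old_split(
    ages: pd.DataFrame,
    timeline: PhylostratumTimeline,
    split_class: str,
) -> pd.Series:
    """Label PDGs 'young' (split class or younger) or 'old' (strictly
    older); singletons and unassigned genes get NA."""
    split_idx = timeline.index_of(split_class)
    idx = ages["age_class_index"]
    out = pd.Series(pd.NA, index=ages.index, dtype="object")
    is_pdg = ages["status"] == "PDG"
    out[is_pdg & (idx >= split_idx)] = "young"
    out[is_pdg & (idx < split_idx)] = "old"
    return out


def _load_inputs(config: PipelineConfig):
    from .io import read_bed, read_chrom_map, read_copy_number, read_probes

    if config.simulation is not None:
        data = simulate_dataset(config.simulation)
        return data.genes, data.chrom_map, data.trees, data.cn_matrix, data.probe_set
    needed = {
        "trees_dir": config.trees_dir,
        "genes_bed": config.genes_bed,
        "cn_matrix_tsv": config.cn_matrix_tsv,
        "probes_tsv": config.probes_tsv,
        "chrom_map_tsv": config.chrom_map_tsv,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise DataError(f"pipeline config missing inputs: {missing}")
    genes = read_bed(config.genes_bed)
    chrom_map = read_chrom_map(config.chrom_map_tsv)
    trees = [
        read_tree_file(p) for p in sorted(Path(config.trees_dir).glob("*.nhx"))
    ]
    cn_matrix = read_copy_number(config.cn_matrix_tsv, genes)
    probe_set = read_probes(config.probes_tsv, sign_convention=config.sign_convention)
    return genes, chrom_map, trees, cn_matrix, probe_set


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Run every stage in order and assemble the analysis report."""
    timeline = get_timeline(config.timeline_name)
    dropped = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc

    genes, chrom_map, trees, cn_matrix, probe_set = stage(
        "load_inputs", _load_inputs, config
    )

    def _assign_all():
        assignments = []
        for tree in trees:
            assignments.extend(
                assign_duplication_age(tree, timeline, config.score_threshold)
            )
        return assignments_to_frame(assignments)

    ages = stage("phylostrat", _assign_all)
    calls = stage("cnv", call_cnv_genes, cn_matrix, config.cnv_params)
    rt = stage(
        "replication_timing", assign_gene_rt, genes, probe_set, config.max_distance
    )
    region = stage(
        "genome_regions",
        classify_gene_region,
        genes,
        chrom_map,
        RegionParameters(config.window),
    )

    master = (
        genes[["gene_id", "chrom", "start", "end"]]
        .merge(ages, on="gene_id", how="left")
        .merge(
            calls.rename(columns={"status": "cnv_status"}), on="gene_id", how="left"
        )
        .merge(rt, on="gene_id", how="left")
        .merge(region, on="gene_id", how="left")
    )
    if master.empty:
        raise PipelineStageError("report", "empty master table")
    split_class = config.resolved_split_class(timeline)
    master["age_group"] = young_old_split(master, timeline, split_class)
    dropped["genes_without_age"] = int(master["status"].isna().sum())
    dropped["genes_without_rt"] = int(master["order_of_replication"].isna().sum())
    dropped["genes_excluded_cnv"] = int((master["cnv_status"] == "EXCLUDED").sum())
    dropped["genes_unassigned_age"] = int((master["status"] == "UNASSIGNED").sum())

    table = stage("report", cnv_by_age_table, calls, ages, timeline)
    tests = stage(
        "stats", _test_battery, master, table, timeline
    )

    report = AnalysisReport(
        master=master,
        cnv_by_age=table,
        tests=tests,
        dropped_counts=dropped,
        config_echo={
            "timeline": timeline.name,
            "score_threshold": config.score_threshold,
            "cnv_params": asdict(config.cnv_params),
            "max_distance": config.max_distance,
            "window": config.window,
            "young_split_class": split_class,
            "seed": config.seed,
            "simulated": config.simulation is not None,
        },
    )
    if config.outdir:
        report.write(config.outdir)
    return report


def _cnv_usable(master: pd.DataFrame) -> pd.DataFrame:
    return master[master["cnv_status"].isin(["CNV", "NON_CNV"])]


def _rt_wilcoxon(sub: pd.DataFrame) -> Optional[st.TestResult]:
    """CNV-vs-non-CNV rank-sum on order of replication; None when a group
    is empty."""
    sub = sub.dropna(subset=["order_of_replication"])
    a = sub.loc[sub["cnv_status"] == "CNV", "order_of_replication"]
    b = sub.loc[sub["cnv_status"] == "NON_CNV", "order_of_replication"]
    if len(a) == 0 or len(b) == 0:
        return None
    return st.wilcoxon_rank_sum(a, b)


def _test_battery(
    master: pd.DataFrame, cnv_table: pd.DataFrame, timeline: PhylostratumTimeline
) -> dict:
    tests: dict = {}
    usable = _cnv_usable(master)

    # CNV fraction across phylostrata (excluding the singleton row)
    classes = cnv_table[cnv_table["age_class_index"].notna()]
    mat = classes[["n_cnv", "n_noncnv"]].to_numpy()
    keep_rows = mat.sum(axis=1) > 0
    if keep_rows.sum() >= 2:
        tests["cnv_fraction_by_age_chi2"] = st.chi_squared_independence(
            mat[keep_rows]
        )

    # duplicated vs singleton CNV proportions
    pdg = usable[usable["status"] == "PDG"]
    sing = usable[usable["status"] == "SINGLETON"]
    if len(pdg) and len(sing):
        tests["pdg_vs_singleton_cnv"] = st.two_proportion_test(
            int((pdg["cnv_status"] == "CNV").sum()), len(pdg),
            int((sing["cnv_status"] == "CNV").sum()), len(sing),
        )

    # replication timing of CNV vs non-CNV genes, in the panel's universes
    for key, sub in {
        "rt_cnv_all_genes": usable,
        "rt_cnv_pdg": pdg,
        "rt_cnv_singletons": sing,
        "rt_cnv_young_pdg": pdg[pdg["age_group"] == "young"],
        "rt_cnv_old_pdg": pdg[pdg["age_group"] == "old"],
    }.items():
        res = _rt_wilcoxon(sub)
        if res is not None:
            tests[key] = res

    # young vs old PDG replication timing
    pdg_rt = master[(master["status"] == "PDG")].dropna(
        subset=["order_of_replication"]
    )
    young = pdg_rt.loc[pdg_rt["age_group"] == "young", "order_of_replication"]
    old = pdg_rt.loc[pdg_rt["age_group"] == "old", "order_of_replication"]
    if len(young) and len(old):
        tests["rt_young_vs_old_pdg"] = st.wilcoxon_rank_sum(young, old)

    # age vs replication timing: overall and per chromosomal region.
    # age enters as the ordinal phylostratum index (1 = oldest), so a
    # positive rho means younger genes replicate later.
    def _spearman(sub, name):
        sub = sub.dropna(subset=["order_of_replication", "age_class_index"])
        if len(sub) >= 3 and sub["age_class_index"].nunique() >= 2:
            tests[name] = st.spearman_correlation(
                sub["age_class_index"].astype(float), sub["order_of_replication"]
            )

    _spearman(pdg_rt, "age_rt_spearman")
    for region in ("pericentromeric", "interstitial", "subtelomeric"):
        _spearman(pdg_rt[pdg_rt["region"] == region], f"age_rt_spearman_{region}")

    # enrichment of young PDGs and of CNV PDGs in the two repeat-rich regions
    all_pdg = master[master["status"] == "PDG"]
    n_pdg = len(all_pdg)
    n_young = int((all_pdg["age_group"] == "young").sum())
    for region in ("pericentromeric", "subtelomeric"):
        reg = all_pdg[all_pdg["region"] == region]
        if len(reg) and n_young:
            tests[f"young_pdg_in_{region}"] = st.fold_enrichment(
                int((reg["age_group"] == "young").sum()), len(reg), n_young, n_pdg
            )
        reg_u = pdg[pdg["region"] == region]
        n_cnv_pdg = int((pdg["cnv_status"] == "CNV").sum())
        if len(reg_u) and n_cnv_pdg:
            tests[f"cnv_pdg_in_{region}"] = st.fold_enrichment(
                int((reg_u["cnv_status"] == "CNV").sum()), len(reg_u),
                n_cnv_pdg, len(pdg),
            )
    return tests
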