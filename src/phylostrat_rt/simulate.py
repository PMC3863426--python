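"""Synthetic-data generator with planted truth.

Emulates the three data layers the pipeline consumes, each with a known
ground truth so every downstream stage is testable by planted-truth
recovery, without any external download:

* **gene-family trees** (NHX) — each focal-species gene is planted either
  as a singleton (no duplication node on its root path) or as a duplicate
  whose most recent duplication node carries a known age class and a
  consistency score drawn from a configurable distribution; the tree
  backbone is a caterpillar of speciation nodes following the timeline,
  since age assignment only ever inspects the focal leaf's root path;
* **copy-number matrix** — per-gene CNV status drawn with an age-dependent
  probability (diploid baseline 2; planted CNV genes get >= 4 or < 2 copies
  in at least ``min_cnv_individuals`` individuals);
* **replication-timing probes** — probes tile each chromosome; a probe's
  latent value is ``baseline - rt_age_effect * (age_index - 1)`` of the
  nearest gene (younger class => larger index => later replication under
  the higher-is-earlier sign convention; singletons behave like the oldest
  class) and every sample adds i.i.d. Gaussian noise.

Determinism: each generator derives its own child RNG stream from
``config.seed``, so the full dataset and every individual layer are
reproducible bit-for-bit for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import CopyNumberMatrix
from .errors import CapacityError, ConfigurationError
from .regions import ChromosomeMap
from .replication_timing import HIGHER_IS_EARLIER, HIGHER_IS_LATER, RTProbeSet
from .timelines import PhylostratumTimeline, get_timeline
from .trees import GeneTree, GeneTreeNode, write_gene_tree

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genome_annotation",
    "simulate_gene_trees",
    "simulate_copy_number_matrix",
    "simulate_rt_probes",
    "simulate_dataset",
    "default_age_distribution",
    "default_cnv_prob_by_age",
]

SINGLETON = "SINGLETON"


def default_age_distribution(n_classes: int, singleton_prob: float = 0.28) -> tuple:
    """Uniform mass over age classes plus a singleton atom.

    Real duplication-age spectra are old-heavy, but a uniform spread gives
    every class comparable statistical power in recovery tests.  The
    singleton fraction matches the rough 1:2.6 singleton:duplicate ratio
    seen in mammalian gene-family catalogues.
    """
    per_class = (1.0 - singleton_prob) / n_classes
    return tuple([per_class] * n_classes + [singleton_prob])


def default_cnv_prob_by_age(n_classes: int) -> tuple:
    """Age-dependent CNV probability: rare (3%) for old classes and
    singletons, rising steeply over the youngest five classes — the
    qualitative pattern of copy-number variability concentrating in recent
    duplicates."""
    young = [0.4, 0.5, 0.6, 0.65, 0.7][-min(5, n_classes):]
    probs = [0.03] * (n_classes - len(young)) + young
    return tuple(probs + [0.03])  # trailing entry = singletons


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world.

    ``age_distribution`` and ``cnv_prob_by_age`` are vectors of length
    ``n_classes + 1``: one entry per phylostratum (oldest -> youngest)
    followed by one for singletons.  ``None`` selects the defaults above.
    """

    seed: int = 0
    timeline_name: str = "human"
    n_families: int = 100
    n_genes: int = 10_000
    n_individuals: int = 159
    n_rt_samples: int = 4
    age_distribution: Optional[Sequence[float]] = None
    score_distribution: dict = field(
        default_factory=lambda: {"kind": "uniform", "low": 0.5, "high": 1.0}
    )
    cnv_prob_by_age: Optional[Sequence[float]] = None
    min_cnv_individuals: int = 2
    rt_age_effect: float = 0.5
    rt_noise_sd: float = 1.0
    rt_baseline: float = 0.0
    sign_convention: str = HIGHER_IS_EARLIER
    probe_spacing: int = 5_000
    n_chromosomes: int = 4
    chromosome_length: int = 100_000_000
    centromere_position: float = 0.5
    centromere_width: int = 2_000_000
    include_sex_chromosome: bool = False
    gene_length_range: tuple = (2_000, 20_000)
    min_gene_spacing: int = 1_000
    decoy_zero_prob: float = 0.0

    def __post_init__(self):
        for name in ("n_families", "n_individuals", "n_rt_samples",
                     "probe_spacing", "n_chromosomes", "chromosome_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        if not 0.0 <= self.centromere_position <= 1.0:
            raise ConfigurationError("centromere_position must be in [0, 1]")
        if self.rt_noise_sd < 0:
            raise ConfigurationError("rt_noise_sd must be non-negative")
        if not 0.0 <= self.decoy_zero_prob <= 1.0:
            raise ConfigurationError("decoy_zero_prob must be in [0, 1]")
        if self.sign_convention not in (HIGHER_IS_EARLIER, HIGHER_IS_LATER):
            raise ConfigurationError(
                f"unknown sign convention {self.sign_convention!r}"
            )

    def timeline(self) -> PhylostratumTimeline:
        return get_timeline(self.timeline_name)

    def resolved_age_distribution(self, n_classes: int) -> np.ndarray:
        dist = (
            np.asarray(self.age_distribution, dtype=float)
            if self.age_distribution is not None
            else np.asarray(default_age_distribution(n_classes))
        )
        if dist.size != n_classes + 1:
            raise ConfigurationError(
                f"age_distribution needs {n_classes + 1} entries "
                f"({n_classes} classes + singleton), got {dist.size}"
            )
        if (dist < 0).any() or (dist > 1).any():
            raise ConfigurationError("age_distribution entries must be in [0, 1]")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ConfigurationError("age_distribution must sum to 1")
        return dist

    def resolved_cnv_prob(self, n_classes: int) -> np.ndarray:
        probs = (
            np.asarray(self.cnv_prob_by_age, dtype=float)
            if self.cnv_prob_by_age is not None
            else np.asarray(default_cnv_prob_by_age(n_classes))
        )
        if probs.size != n_classes + 1:
            raise ConfigurationError(
                f"cnv_prob_by_age needs {n_classes + 1} entries, got {probs.size}"
            )
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("cnv_prob_by_age entries must be in [0, 1]")
        return probs

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# RNG stream keys, one per generator
_STREAM_ANNOTATION = 1
_STREAM_AGES = 2
_STREAM_TREES = 3
_STREAM_CNV = 4
_STREAM_RT = 5


def _chromosome_names(config: SimulationConfig) -> list[str]:
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.include_sex_chromosome:
        names.append("chrX")
    return names


def simulate_chromosome_map(config: SimulationConfig) -> ChromosomeMap:
    length = config.chromosome_length
    width = min(config.centromere_width, length)
    mid = int(config.centromere_position * length)
    cen_start = int(np.clip(mid - width // 2, 0, length - width))
    rows = [
        {
            "chrom": name,
            "length": length,
            "cen_start": cen_start,
            "cen_end": cen_start + width,
        }
        for name in _chromosome_names(config)
    ]
    return ChromosomeMap(pd.DataFrame(rows))


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, ChromosomeMap]:
    """Place genes on the simulated chromosomes (BED-like table).

    Genes are distributed round-robin over chromosomes and placed uniformly
    within disjoint slots so that neighbours never overlap and keep at
    least ``min_gene_spacing`` between them; raises
    :class:`CapacityError` when the requested genes cannot fit.
    """
    chrom_map = simulate_chromosome_map(config)
    rng = config.rng(_STREAM_ANNOTATION)
    chroms = _chromosome_names(config)
    lo, hi = config.gene_length_range
    if not 0 < lo <= hi:
        raise ConfigurationError("gene_length_range must satisfy 0 < lo <= hi")

    counts = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        counts[chroms[i % len(chroms)]] += 1

    records = []
    for chrom in chroms:
        k = counts[chrom]
        if k == 0:
            continue
        slot = config.chromosome_length // k
        if slot < hi + config.min_gene_spacing:
            raise CapacityError(
                f"{k} genes do not fit on {chrom} "
                f"({config.chromosome_length} bp) at max length {hi} bp "
                f"with {config.min_gene_spacing} bp spacing"
            )
        lengths = rng.integers(lo, hi + 1, size=k)
        jitter_room = slot - lengths - config.min_gene_spacing
        offsets = (rng.random(k) * (jitter_room + 1)).astype(np.int64)
        starts = np.arange(k, dtype=np.int64) * slot + offsets
        strands = np.where(rng.random(k) < 0.5, "+", "-")
        for j in range(k):
            records.append(
                (chrom, int(starts[j]), int(starts[j] + lengths[j]), strands[j])
            )

    genes = pd.DataFrame(records, columns=["chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes.insert(3, "gene_id", [f"g{i:06d}" for i in range(len(genes))])
    genes.insert(4, "score", 0)
    genes = genes[["chrom", "start", "end", "gene_id", "score", "strand"]]
    return genes, chrom_map


def simulate_true_ages(
    config: SimulationConfig,
    timeline: PhylostratumTimeline,
    gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Draw each gene's planted age class (or singleton) and, for
    duplicates, a consistency score."""
    rng = config.rng(_STREAM_AGES)
    n_classes = timeline.n_classes
    dist = config.resolved_age_distribution(n_classes)
    draws = rng.choice(n_classes + 1, size=len(gene_ids), p=dist)
    is_singleton = draws == n_classes
    age = np.where(is_singleton, 0, draws + 1)  # 1-based; 0 = singleton
    scores = _draw_scores(config.score_distribution, rng, len(gene_ids))
    scores[is_singleton] = np.nan
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "true_age_class": pd.array(
                [None if s else int(a) for s, a in zip(is_singleton, age)],
                dtype="Int64",
            ),
            "true_singleton": is_singleton,
            "planted_score": scores,
        }
    )


def _draw_scores(spec: dict, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = spec.get("kind", "uniform")
    if kind == "point":
        return np.full(n, float(spec["value"]))
    if kind == "uniform":
        lo, hi = float(spec.get("low", 0.0)), float(spec.get("high", 1.0))
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("score distribution bounds must be in [0, 1]")
        return rng.uniform(lo, hi, size=n)
    if kind == "mixture":
        comps = spec["components"]
        weights = np.array([c["weight"] for c in comps], dtype=float)
        weights = weights / weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for i, comp in enumerate(comps):
            mask = which == i
            out[mask] = _draw_scores(comp, rng, int(mask.sum()))[: int(mask.sum())]
        return out
    raise ConfigurationError(f"unknown score distribution kind {kind!r}")


def simulate_gene_trees(
    config: SimulationConfig,
    timeline: Optional[PhylostratumTimeline] = None,
    gene_ids: Optional[Sequence[str]] = None,
    truth_ages: Optional[pd.DataFrame] = None,
) -> tuple[list[GeneTree], pd.DataFrame]:
    """Build one annotated NHX-ready gene tree per family.

    Every focal-species gene appears as a leaf in exactly one tree.  A
    duplicated gene hangs below a duplication node spliced into the
    caterpillar backbone at its planted class, annotated with that class's
    taxon and the planted score; with probability ``decoy_zero_prob`` an
    extra zero-score duplication node (a reconstruction artifact, planted
    at a younger class) is inserted between the gene and its true node.
    Singleton genes attach directly to a backbone speciation node.
    """
    timeline = timeline or config.timeline()
    if timeline.n_classes == 0:
        raise ConfigurationError("timeline is empty")
    for label in timeline.classes:
        if label not in timeline.classes:  # pragma: no cover - tautology guard
            raise ConfigurationError(f"unknown taxon {label!r} in timeline")
    if gene_ids is None:
        gene_ids = [f"g{i:06d}" for i in range(config.n_genes)]
    if truth_ages is None:
        truth_ages = simulate_true_ages(config, timeline, gene_ids)
    rng = config.rng(_STREAM_TREES)
    n_classes = timeline.n_classes
    focal = timeline.focal_species

    n_fam = min(config.n_families, max(len(gene_ids), 1))
    members: list[list[int]] = [[] for _ in range(n_fam)]
    for i in range(len(gene_ids)):
        members[i % n_fam].append(i)

    ages = truth_ages.set_index("gene_id")
    trees = []
    node_counter = [0]

    def new_id() -> str:
        node_counter[0] += 1
        return f"s{node_counter[0]}"

    for fam_idx in range(n_fam):
        node_counter[0] = 0
        # caterpillar backbone: one speciation node per class, oldest at root
        backbone = []
        for ci in range(n_classes):
            node = GeneTreeNode(
                node_id=new_id(),
                event="speciation",
                taxon=timeline.classes[ci],
            )
            if backbone:
                backbone[-1].add_child(node)
            backbone.append(node)
        for gi in members[fam_idx]:
            gid = gene_ids[gi]
            row = ages.loc[gid]
            leaf = GeneTreeNode(node_id=gid, gene_id=gid, species=focal)
            if row["true_singleton"]:
                attach_at = int(rng.integers(0, n_classes))
                backbone[attach_at].add_child(leaf)
                continue
            age_idx = int(row["true_age_class"])  # 1-based
            subtree = leaf
            if (
                config.decoy_zero_prob > 0
                and age_idx < n_classes
                and rng.random() < config.decoy_zero_prob
            ):
                decoy_class = int(rng.integers(age_idx + 1, n_classes + 1))
                decoy = GeneTreeNode(
                    node_id=new_id(),
                    event="duplication",
                    taxon=timeline.classes[decoy_class - 1],
                    score=0.0,
                )
                decoy.add_child(subtree)
                decoy.add_child(
                    GeneTreeNode(
                        node_id=f"{gid}_art",
                        gene_id=f"{gid}_art",
                        species="UnsampledLineage",
                    )
                )
                subtree = decoy
            dup = GeneTreeNode(
                node_id=new_id(),
                event="duplication",
                taxon=timeline.classes[age_idx - 1],
                score=float(row["planted_score"]),
            )
            dup.add_child(subtree)
            dup.add_child(
                GeneTreeNode(
                    node_id=f"{gid}_par",
                    gene_id=f"{gid}_par",
                    species="UnsampledLineage",
                )
            )
            backbone[age_idx - 1].add_child(dup)
        # give every backbone node an outgroup leaf so no node is unary
        for ci, node in enumerate(backbone):
            if len(node.children) < 2:
                node.add_child(
                    GeneTreeNode(
                        node_id=f"f{fam_idx}_og{ci}",
                        gene_id=f"f{fam_idx}_og{ci}",
                        species=f"Outgroup_{timeline.classes[ci].replace(' ', '_')}",
                    )
                )
        trees.append(GeneTree(root=backbone[0], family_id=f"family_{fam_idx}"))
    return trees, truth_ages.copy()


def simulate_copy_number_matrix(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    timeline: Optional[PhylostratumTimeline] = None,
) -> tuple[CopyNumberMatrix, pd.DataFrame]:
    """Draw the gene x individual integer copy-number matrix.

    Planted CNV genes (drawn per age class from ``cnv_prob_by_age``) get a
    gain (>= 4 copies) or a loss (< 2) in at least
    ``min_cnv_individuals`` individuals; every other gene stays in {2, 3}
    with at most one individual carrying a sub-threshold excursion.
    Returns the matrix and the truth table extended with ``true_cnv``.
    """
    if config.n_individuals < 2:
        raise ConfigurationError(
            "need at least 2 individuals to plant a callable CNV"
        )
    timeline = timeline or config.timeline()
    probs = config.resolved_cnv_prob(timeline.n_classes)
    rng = config.rng(_STREAM_CNV)

    truth = truth.set_index("gene_id").loc[genes["gene_id"]].reset_index()
    age_idx = truth["true_age_class"].to_numpy(dtype=object)
    p_gene = np.array(
        [
            probs[-1] if truth["true_singleton"].iat[i] else probs[int(age_idx[i]) - 1]
            for i in range(len(truth))
        ]
    )
    true_cnv = rng.random(len(truth)) < p_gene

    n_ind = config.n_individuals
    copies = np.full((len(truth), n_ind), 2, dtype=int)
    for i in range(len(truth)):
        if true_cnv[i]:
            extra = rng.binomial(n_ind - config.min_cnv_individuals, 0.15)
            n_carriers = config.min_cnv_individuals + int(extra)
            carriers = rng.choice(n_ind, size=n_carriers, replace=False)
            if rng.random() < 0.5:
                copies[i, carriers] = rng.integers(4, 7, size=n_carriers)
            else:
                copies[i, carriers] = rng.integers(0, 2, size=n_carriers)
        else:
            # benign variation within {2,3}; rarely one individual strays
            n_three = rng.binomial(n_ind, 0.05)
            if n_three:
                copies[i, rng.choice(n_ind, size=n_three, replace=False)] = 3
            if rng.random() < 0.05:
                copies[i, rng.integers(0, n_ind)] = int(
                    rng.choice([0, 1, 4, 5])
                )
    individuals = [f"ind{j:03d}" for j in range(n_ind)]
    matrix = CopyNumberMatrix(
        copies=pd.DataFrame(copies, index=list(genes["gene_id"]), columns=individuals),
        genes=genes.set_index("gene_id")[["chrom", "start", "end"]],
    )
    truth = truth.assign(true_cnv=true_cnv)
    return matrix, truth


def simulate_rt_probes(
    genes: pd.DataFrame,
    truth: pd.DataFrame,
    chrom_map: ChromosomeMap,
    config: SimulationConfig,
    timeline: Optional[PhylostratumTimeline] = None,
) -> tuple[RTProbeSet, pd.DataFrame]:
    """Tile probes along each chromosome and emit per-sample log-ratios.

    A probe's latent value is that of the nearest gene:
    ``baseline - rt_age_effect * (age_index - 1)`` (singletons use age
    distance 0, i.e. they replicate like the oldest class); each sample
    adds independent N(0, rt_noise_sd) noise.  Under ``higher_is_later``
    the latent sign flips.  Returns the probe set and the truth table
    extended with ``true_rt_latent``.
    """
    if config.probe_spacing > config.chromosome_length:
        raise ConfigurationError("probe_spacing exceeds chromosome length")
    timeline = timeline or config.timeline()
    rng = config.rng(_STREAM_RT)

    truth = truth.set_index("gene_id").loc[genes["gene_id"]].reset_index()
    age_dist = np.where(
        truth["true_singleton"].to_numpy(),
        0,
        truth["true_age_class"].fillna(1).to_numpy(dtype=float) - 1,
    )
    latent_gene = config.rt_baseline - config.rt_age_effect * age_dist
    if config.sign_convention == HIGHER_IS_LATER:
        latent_gene = -latent_gene

    frames = []
    centers = ((genes["start"] + genes["end"]) // 2).to_numpy(dtype=np.int64)
    for _, row in chrom_map.table.iterrows():
        chrom, length = row["chrom"], int(row["length"])
        positions = np.arange(
            config.probe_spacing // 2, length, config.probe_spacing, dtype=np.int64
        )
        mask = (genes["chrom"] == chrom).to_numpy()
        if mask.any():
            g_centers = centers[mask]
            order = np.argsort(g_centers, kind="stable")
            g_sorted = g_centers[order]
            lat_sorted = latent_gene[mask][order]
            right = np.searchsorted(g_sorted, positions)
            left = np.clip(right - 1, 0, len(g_sorted) - 1)
            right = np.clip(right, 0, len(g_sorted) - 1)
            use_left = np.abs(positions - g_sorted[left]) <= np.abs(
                g_sorted[right] - positions
            )
            latent = np.where(use_left, lat_sorted[left], lat_sorted[right])
        else:
            latent = np.full(len(positions), config.rt_baseline)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": positions, "_latent": latent}))
    probes = pd.concat(frames, ignore_index=True)

    sample_ids = [f"rt_sample_{k}" for k in range(config.n_rt_samples)]
    for sid in sample_ids:
        noise = rng.normal(0.0, config.rt_noise_sd, size=len(probes)) \
            if config.rt_noise_sd > 0 else 0.0
        probes[sid] = probes["_latent"] + noise
    probes = probes.drop(columns="_latent")

    probe_set = RTProbeSet(
        probes=probes, sample_ids=sample_ids, sign_convention=config.sign_convention
    )
    truth = truth.assign(true_rt_latent=latent_gene)
    return probe_set, truth


@dataclass
class SyntheticDataset:
    """All simulated inputs plus the truth table."""

    config: SimulationConfig
    timeline: PhylostratumTimeline
    genes: pd.DataFrame
    chrom_map: ChromosomeMap
    trees: list[GeneTree]
    cn_matrix: CopyNumberMatrix
    probe_set: RTProbeSet
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        """Write every layer as plain-text files (NHX / BED6 / TSV)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        trees_dir = outdir / "trees"
        trees_dir.mkdir(exist_ok=True)
        for tree in self.trees:
            (trees_dir / f"{tree.family_id}.nhx").write_text(
                write_gene_tree(tree) + "\n"
            )
        self.genes.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False)
        self.cn_matrix.copies.to_csv(
            outdir / "copy_number.tsv", sep="\t", index_label="gene_id"
        )
        self.probe_set.probes.to_csv(outdir / "rt_probes.tsv", sep="\t", index=False)
        self.chrom_map.table.to_csv(outdir / "chrom_map.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all four generators in sequence on one config."""
    timeline = config.timeline()
    genes, chrom_map = simulate_genome_annotation(config)
    cfg = replace(config, n_genes=len(genes))
    trees, truth = simulate_gene_trees(cfg, timeline, list(genes["gene_id"]))
    cn_matrix, truth = simulate_copy_number_matrix(genes, truth, cfg, timeline)
    probe_set, truth = simulate_rt_probes(genes, truth, chrom_map, cfg, timeline)
    return SyntheticDataset(
        config=config,
        timeline=timeline,
        genes=genes,
        chrom_map=chrom_map,
        trees=trees,
        cn_matrix=cn_matrix,
        probe_set=probe_set,
        truth=truth,
    )
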