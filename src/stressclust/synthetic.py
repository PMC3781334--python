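"""Synthetic factorial expression datasets with planted, machine-readable truth.

The generator emulates a 2 genotype (WT/KO) x 2 treatment (vehicle/TM) x
2 time (8 h / 34 h) liver ER-stress study with 3 animals per group.  Genes
are partitioned into the named expression groups (A-I, ATF6) plus an
unregulated null pool; each group's defining 4-tuple of three-state calls
is planted as signed log2 effects on condition-group means, and replicate
values are drawn with multiplicative log-normal noise.  Companion
generators emit promoter sequences with motif instances planted in
designated groups, pathway annotations with planted over-representation,
and a truth table recording every planted fact for recovery testing.

The planted effects compose along the comparison chain: the KO-TM mean
inherits the WT-TM effect and adds the genotype-difference effect on top,
so each of the four canonical comparisons reads back exactly its planted
signed effect when noise vanishes.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calls import DOWN, UNCHANGED, UP
from .errors import ConfigError, StressclustError
from .motifs import BASES, PWM
from .profiles import COMPARISON_NAMES, DEFAULT_GROUP_PROFILES, Profile

logger = logging.getLogger(__name__)

_SIGN = {UP: 1.0, DOWN: -1.0, UNCHANGED: 0.0}

#: which synthetic factor is planted into which groups' promoters.
DEFAULT_MOTIF_PLAN = {
    "NFYA_SYN": ("ATF6",),
    "HNF4A_SYN": ("B", "D", "F"),
    "ELK4_SYN": ("A", "C", "E"),
}

_PWM_CONSENSI = {
    "NFYA_SYN": "TTAGCCAATCAGAG",
    "HNF4A_SYN": "CAAAGGTCAAAGGT",
    "ELK4_SYN": "ACAGGAAGTGGGTA",
    "DECOY1_SYN": "TGACGTCATCGATG",
    "DECOY2_SYN": "GATCCGGGCGTTAC",
}


def default_pwms(dominant: float = 0.97, total: float = 100.0) -> list[PWM]:
    """The built-in synthetic motif set: three planted factors, two decoys.

    Each matrix is 14 bp with the consensus base carrying ``dominant`` of
    the column mass — sharp enough that sampled sites score above the 0.85
    relative-score threshold while random-sequence hits stay rare.
    """
    pwms = []
    minor = total * (1.0 - dominant) / 3.0
    for name, consensus in _PWM_CONSENSI.items():
        counts = np.full((4, len(consensus)), minor)
        for j, base in enumerate(consensus):
            counts[BASES.index(base), j] = total * dominant
        pwms.append(PWM(name, counts))
    return pwms


def _default_group_sizes() -> dict[str, int]:
    return {label: 30 for label in DEFAULT_GROUP_PROFILES}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 replicates per condition group,
    planted |log2 fold change| 1.5, 10% replicate coefficient of variation,
    promoters of 4001 bp so the TSS sits on the center base of a +/-2000 bp
    window.
    """

    n_genes: int = 600
    n_replicates: int = 3
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    effect_size: float = 1.5
    noise_cv: float = 0.10
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    promoter_length: int = 4001
    gc_fraction: float = 0.5
    planted_motif_rate: float = 0.9
    sites_per_promoter: int = 2
    motif_plan: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PLAN))
    pathway_plan: dict[str, str] = field(
        default_factory=lambda: {f"PW_{g}": g for g in DEFAULT_GROUP_PROFILES})
    pathway_fold: float = 5.0
    pathway_background_rate: float = 0.05
    n_background_pathways: int = 20
    times: tuple[float, float] = (8.0, 34.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_replicates", "effect_size", "noise_cv",
                     "baseline_log2_sd", "promoter_length", "sites_per_promoter"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ConfigError("group_sizes entries must be positive")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ConfigError("group_sizes sum exceeds n_genes")
        if self.promoter_length % 2 == 0:
            raise ConfigError("promoter_length must be odd (TSS on the center base)")
        if not 0.0 <= self.planted_motif_rate <= 1.0:
            raise ConfigError("planted_motif_rate must be in [0, 1]")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0, 1]")
        unknown = set().union(*self.motif_plan.values()) - set(self.group_sizes) \
            if self.motif_plan else set()
        if unknown:
            raise ConfigError(f"motif_plan names unknown group(s) {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["motif_plan"] = {k: list(v) for k, v in self.motif_plan.items()}
        data["times"] = list(self.times)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthTable:
    """Planted ground truth: profiles, pathway memberships, motif sites."""

    profiles: pd.DataFrame  # index gene; columns c1..c4, group
    pathways: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "pathway"]))
    motif_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "factor", "position", "strand", "site"]))

    def true_profile(self, gene: str) -> Profile:
        return tuple(self.profiles.loc[gene, list(COMPARISON_NAMES)])

    def write(self, prefix) -> None:
        self.profiles.to_csv(f"{prefix}_profiles.tsv", sep="\t")
        self.pathways.to_csv(f"{prefix}_pathways.tsv", sep="\t", index=False)
        self.motif_sites.to_csv(f"{prefix}_motif_sites.tsv", sep="\t", index=False)
        logger.info("wrote truth tables (%d genes, %d pathway rows, %d sites)",
                    len(self.profiles), len(self.pathways), len(self.motif_sites))


def generate_design(config: GeneratorConfig) -> pd.DataFrame:
    """Sample table for the full 2 x 2 x 2 factorial with n replicates."""
    rows = []
    for time in config.times:
        for genotype in ("WT", "KO"):
            for treatment in ("vehicle", "TM"):
                for rep in range(1, config.n_replicates + 1):
                    tag = f"{genotype}_{'veh' if treatment == 'vehicle' else 'TM'}_{time:g}h_r{rep}"
                    rows.append({"sample_id": tag, "genotype": genotype,
                                 "treatment": treatment, "time": time,
                                 "replicate": rep})
    return pd.DataFrame(rows)


def _assign_groups(config: GeneratorConfig) -> pd.DataFrame:
    """Per-gene true profile and group label (null pool = all-unchanged)."""
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    labels: list[str | None] = []
    profiles: list[Profile] = []
    for label, size in config.group_sizes.items():
        prof = DEFAULT_GROUP_PROFILES.get(label)
        if prof is None:
            raise ConfigError(f"group_sizes names unknown group {label!r}")
        labels += [label] * size
        profiles += [prof] * size
    n_null = config.n_genes - len(labels)
    labels += [None] * n_null
    profiles += [(UNCHANGED,) * 4] * n_null
    df = pd.DataFrame(profiles, columns=list(COMPARISON_NAMES), index=genes)
    df["group"] = labels
    df.index.name = "gene"
    return df


def generate_expression(config: GeneratorConfig, design: pd.DataFrame
                        ) -> tuple[pd.DataFrame, TruthTable]:
    """Expression matrix with planted group effects plus its truth table.

    Group log2 means chain along the comparisons: WT-TM = baseline + c1/c3
    effect, KO-TM = WT-TM + c2/c4 effect, vehicle groups sit at baseline.
    Replicates multiply the group mean by 2^N(0, log2(1+cv)).
    """
    rng = np.random.default_rng(config.seed)
    truth_profiles = _assign_groups(config)
    genes = truth_profiles.index
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=len(genes))
    signs = truth_profiles[list(COMPARISON_NAMES)].apply(
        lambda col: col.map(_SIGN)).to_numpy(dtype=float)
    e = config.effect_size
    t_early, t_late = config.times
    group_mean = {}
    for time, s_wt, s_ko in ((t_early, signs[:, 0], signs[:, 1]),
                             (t_late, signs[:, 2], signs[:, 3])):
        group_mean[("WT", "vehicle", time)] = baseline
        group_mean[("KO", "vehicle", time)] = baseline
        group_mean[("WT", "TM", time)] = baseline + e * s_wt
        group_mean[("KO", "TM", time)] = baseline + e * s_wt + e * s_ko
    sd = math.log2(1.0 + config.noise_cv)
    columns = {}
    for _, row in design.iterrows():
        mean = group_mean[(row["genotype"], row["treatment"], row["time"])]
        noise = rng.normal(0.0, sd, size=len(genes))
        columns[row["sample_id"]] = np.exp2(mean + noise)
    matrix = pd.DataFrame(columns, index=genes)
    matrix.index.name = "gene"
    logger.info("generated expression: %d genes x %d samples", *matrix.shape)
    return matrix, TruthTable(profiles=truth_profiles)


def _sample_site(rng: np.random.Generator, pwm: PWM) -> str:
    probs = pwm.probabilities()
    return "".join(BASES[rng.choice(4, p=probs[:, j])] for j in range(pwm.width))


def generate_promoters(config: GeneratorConfig, truth: TruthTable,
                       pwms: list[PWM] | None = None
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoter sequences with motif instances planted per the motif plan.

    Background bases are i.i.d. with the configured GC fraction.  Genes in a
    planted factor's designated groups receive, with probability
    ``planted_motif_rate``, ``sites_per_promoter`` non-overlapping instances
    sampled from the factor's PWM at uniform positions, on a random strand.
    Site records (TSS-relative start, strand, sequence) are appended to
    ``truth.motif_sites``.  Returns (promoters, TSS table).
    """
    if pwms is None:
        pwms = default_pwms()
    by_name = {p.name: p for p in pwms}
    for factor in config.motif_plan:
        if factor not in by_name:
            raise ConfigError(f"motif_plan factor {factor!r} has no PWM")
        if by_name[factor].width >= config.promoter_length:
            raise ConfigError(f"PWM {factor!r} wider than the promoter")
    rng = np.random.default_rng(config.seed + 1)
    L = config.promoter_length
    center = (L - 1) // 2
    gc = config.gc_fraction
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    promoters: dict[str, str] = {}
    site_rows = []
    group_of = truth.profiles["group"]
    for gene in truth.profiles.index:
        seq = rng.choice(4, size=L, p=base_p)
        chars = np.frombuffer(BASES.encode(), dtype=np.uint8)[seq]
        seq_list = list(chars.tobytes().decode())
        occupied: list[tuple[int, int]] = []
        for factor, groups in config.motif_plan.items():
            if group_of[gene] not in groups:
                continue
            if rng.random() >= config.planted_motif_rate:
                continue
            pwm = by_name[factor]
            w = pwm.width
            for _ in range(config.sites_per_promoter):
                for _attempt in range(100):
                    start = int(rng.integers(0, L - w + 1))
                    if all(start + w <= s or start >= s + sw
                           for s, sw in occupied):
                        break
                else:
                    raise StressclustError(
                        f"gene {gene}: could not place non-overlapping sites")
                site = _sample_site(rng, pwm)
                strand = "+" if rng.random() < 0.5 else "-"
                planted = site if strand == "+" else str(Seq(site).reverse_complement())
                seq_list[start:start + w] = list(planted)
                occupied.append((start, w))
                site_rows.append({"gene": gene, "factor": factor,
                                  "position": start - center, "strand": strand,
                                  "site": site})
        promoters[gene] = "".join(seq_list)
    tss = pd.DataFrame({"chrom": list(promoters), "start": center,
                        "end": center + 1, "name": list(promoters),
                        "score": 0, "strand": "+"})
    truth.motif_sites = pd.DataFrame(
        site_rows, columns=["gene", "factor", "position", "strand", "site"])
    logger.info("generated %d promoters, %d planted sites",
                len(promoters), len(site_rows))
    return promoters, tss


def generate_annotations(config: GeneratorConfig, truth: TruthTable) -> pd.DataFrame:
    """Pathway annotation table with planted per-group over-representation.

    Planted pathways annotate genes of their designated group only, each
    with probability ``pathway_fold x pathway_background_rate`` (capped at
    1), so a fold of 1 matches the background rate in expectation.
    Background pathways annotate every gene uniformly at the background
    rate.  Membership is recorded in ``truth.pathways``.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.profiles.index
    group_of = truth.profiles["group"]
    rows = []
    p0 = config.pathway_background_rate
    planted_rate = min(1.0, config.pathway_fold * p0)
    for pathway, group in sorted(config.pathway_plan.items()):
        if group not in set(config.group_sizes):
            continue
        members = [g for g in genes
                   if group_of[g] == group and rng.random() < planted_rate]
        rows += [{"gene": g, "pathway": pathway,
                  "pathway_name": f"planted process {group}"} for g in members]
    for i in range(1, config.n_background_pathways + 1):
        members = [g for g in genes if rng.random() < p0]
        rows += [{"gene": g, "pathway": f"BG{i:03d}",
                  "pathway_name": f"background process {i}"} for g in members]
    annotations = pd.DataFrame(rows, columns=["gene", "pathway", "pathway_name"])
    truth.pathways = annotations[["gene", "pathway"]].copy()
    logger.info("generated %d annotation rows over %d pathways",
                len(annotations), annotations["pathway"].nunique())
    return annotations


def write_promoters_fasta(promoters: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")
    logger.info("wrote %d promoter records to %s", len(records), path)


def read_promoters_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", header=False, index=False)
    logger.info("wrote %d TSS records to %s", len(tss), path)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d annotation rows to %s", len(annotations), path)
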