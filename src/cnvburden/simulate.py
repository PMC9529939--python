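"""Synthetic genomes, frequency panels, CNV calls, and phenotypes.

The generator emulates, at desk scale, the study design of a rare-CNV
gene-set burden analysis in a case-control cohort:

* a scaled-down autosomal genome with non-overlapping coding genes, a
  circadian-pathway set, a (mostly disjoint) insomnia-risk set, and a
  small high-confidence ASD-risk set;
* LOEUF scores drawn from a gnomAD-like clipped lognormal, with sleep
  genes shifted toward intolerance, and DS brain-expression scores from
  a Beta distribution on [0, 1];
* per-individual CNV calls (Poisson counts, log-uniform sizes >= 50 kb,
  uniform placement over autosomes avoiding masked regions);
* phenotypes generated from the same model families the analysis fits:
  case status from a logistic model on burden terms, sleep duration from
  a linear model (minutes), and a 0-2 insomnia-trait count from a
  proportional-odds model — so planted coefficients can be recovered.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
seeded from the config; a fixed seed reproduces every output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneIndex, annotate_cnvs, build_profiles
from .errors import ConfigError, SizingError
from .intervals import CnvCall, FrequencyPanelEntry, GeneRecord, GenomicInterval

BURDEN_TERMS = ("DEL_target", "DUP_target", "DEL_other", "DUP_other")
_METRIC_OF_WEIGHTING = {"count": "n_genes", "inv_loeuf": "inv_loeuf", "ds": "ds"}


@dataclass
class GenomeModel:
    """A simulated genome: chromosomes, genes, masks, recurrent hotspots."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneRecord]
    masked_regions: list[tuple[GenomicInterval, str]]
    recurrent_regions: list[GenomicInterval]

    @property
    def mask_intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _tag in self.masked_regions]

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids are not unique")
        for g in self.genes:
            L = lengths.get(g.interval.chrom)
            if L is None or g.interval.end > L:
                raise ValueError(f"gene {g.gene_id} lies outside its chromosome")


DEFAULT_LOEUF_PARAMS = {
    "mu": -0.45,          # log-scale location of the lognormal
    "sigma": 0.55,
    "min": 0.03,          # clip range, gnomAD-like (0, 2]
    "max": 2.0,
    "sleep_multiplier": 0.7,  # <1 shifts sleep genes toward intolerance
}
DEFAULT_DS_PARAMS = {
    "a": 2.0,
    "b": 3.0,
    "sleep_a": 2.8,       # sleep genes skew to higher brain-expression DS
    "sleep_b": 2.2,
}
# ~1/16 of the coding genome: gene-set sizes scale the real circadian (312)
# and insomnia-risk (1053) lists against ~19k coding genes, with minimal
# circadian/insomnia overlap.
DEFAULT_GENE_SET_SIZES = {"circadian": 20, "insomnia": 66, "asd_risk": 12, "overlap": 2}


def simulate_genome(
    n_genes: int = 1200,
    n_chroms: int = 22,
    gene_set_sizes: dict[str, int] | None = None,
    loeuf_params: dict | None = None,
    ds_params: dict | None = None,
    seed: int = 0,
    chrom_length: int = 12_000_000,
    gene_length_range: tuple[int, int] = (5_000, 120_000),
) -> GenomeModel:
    """Lay down a scaled autosomal genome with flagged gene sets.

    Genes are placed without overlap along each chromosome with random
    gaps; raises SizingError if the requested genes cannot fit.
    """
    sizes = dict(DEFAULT_GENE_SET_SIZES, **(gene_set_sizes or {}))
    lp = dict(DEFAULT_LOEUF_PARAMS, **(loeuf_params or {}))
    dp = dict(DEFAULT_DS_PARAMS, **(ds_params or {}))
    n_circ, n_ins = sizes["circadian"], sizes["insomnia"]
    n_overlap = sizes.get("overlap", 0)
    if n_overlap > min(n_circ, n_ins):
        raise ConfigError("overlap cannot exceed either set size")
    if n_circ + n_ins - n_overlap > n_genes or sizes.get("asd_risk", 0) > n_genes:
        raise ConfigError("gene set sizes exceed n_genes")

    rng = np.random.default_rng(seed)
    chromosomes = [(str(i + 1), int(chrom_length)) for i in range(n_chroms)]

    # round-robin gene allocation across chromosomes
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    genes: list[GeneRecord] = []
    gid = 0
    for (chrom, clen), k in zip(chromosomes, per_chrom):
        if k == 0:
            continue
        lens = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=k)
        free = clen - int(lens.sum())
        if free < k + 1:
            raise SizingError(
                f"chromosome {chrom}: total gene span {int(lens.sum())} bp does not fit in {clen} bp"
            )
        # k+1 gaps summing to `free`, drawn from sorted uniforms
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        gaps = np.diff(np.concatenate(([0], cuts)))
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start, end = pos, pos + int(lens[j])
            genes.append(
                GeneRecord(
                    gene_id=f"G{gid:05d}",
                    interval=GenomicInterval(chrom, start, end),
                    loeuf=1.0,  # placeholder, overwritten below
                    ds_score=0.5,
                    sets=frozenset(),
                )
            )
            pos = end
            gid += 1

    # gene-set membership: insomnia overlaps circadian by exactly n_overlap
    idx = rng.permutation(len(genes)) if genes else np.array([], dtype=int)
    circ = set(idx[:n_circ].tolist())
    ins = set(idx[n_circ - n_overlap : n_circ - n_overlap + n_ins].tolist())
    asd = set(rng.choice(len(genes), size=sizes.get("asd_risk", 0), replace=False).tolist()) if genes else set()

    sleepish = circ | ins
    final: list[GeneRecord] = []
    for i, g in enumerate(genes):
        is_sleep = i in sleepish
        mult = lp["sleep_multiplier"] if is_sleep else 1.0
        loeuf = float(np.clip(mult * rng.lognormal(lp["mu"], lp["sigma"]), lp["min"], lp["max"]))
        if is_sleep:
            ds = float(rng.beta(dp["sleep_a"], dp["sleep_b"]))
        else:
            ds = float(rng.beta(dp["a"], dp["b"]))
        sets = set()
        if i in circ:
            sets.add("circadian")
        if i in ins:
            sets.add("insomnia")
        if i in asd:
            sets.add("asd_risk")
        final.append(
            GeneRecord(g.gene_id, g.interval, loeuf=loeuf, ds_score=ds, sets=frozenset(sets))
        )

    masked: list[tuple[GenomicInterval, str]] = []
    for chrom, clen in chromosomes:
        masked.append((GenomicInterval(chrom, 0, min(250_000, clen // 10)), "segdup"))
        mid = clen // 2
        masked.append((GenomicInterval(chrom, mid, min(mid + 300_000, clen)), "centromere"))
    if n_chroms >= 6:
        masked.append((GenomicInterval("6", 1_000_000, 1_600_000), "HLA"))

    # stand-ins for recurrent neuropsychiatric hotspots (16p11.2-like etc.)
    recurrent = []
    for chrom in ("15", "16", "22"):
        if any(c == chrom for c, _ in chromosomes):
            clen = dict(chromosomes)[chrom]
            start = clen // 4
            recurrent.append(GenomicInterval(chrom, start, start + 600_000))

    model = GenomeModel(chromosomes, final, masked, recurrent)
    model.validate()
    return model


def simulate_panel(
    genome: GenomeModel,
    n_common: int = 30,
    n_rare: int = 120,
    seed: int = 0,
    size_range: tuple[int, int] = (50_000, 1_000_000),
) -> list[FrequencyPanelEntry]:
    """A DGV-style population frequency panel over the simulated genome.

    Common entries (frequency 2-20%) stand in for polymorphic CNV regions;
    rare entries sit below the 1/1000 rarity threshold and never disqualify
    a call.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lens = np.array([L for _, L in genome.chromosomes], dtype=float)
    p = chrom_lens / chrom_lens.sum()
    entries = []
    for n, lo, hi in ((n_common, 0.02, 0.20), (n_rare, 1e-5, 8e-4)):
        for _ in range(n):
            ci = int(rng.choice(len(chrom_names), p=p))
            length = int(np.exp(rng.uniform(np.log(size_range[0]), np.log(size_range[1]))))
            length = min(length, int(chrom_lens[ci]) - 1)
            start = int(rng.integers(0, int(chrom_lens[ci]) - length))
            entries.append(
                FrequencyPanelEntry(
                    interval=GenomicInterval(chrom_names[ci], start, start + length),
                    dosage="DEL" if rng.random() < 0.5 else "DUP",
                    frequency=float(rng.uniform(lo, hi)),
                )
            )
    return entries


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    planted_betas maps burden-term names (DEL_target, DUP_target,
    DEL_other, DUP_other, plus "intercept") to log-odds per unit burden in
    the case-status logistic model; ``planted_weighting`` selects which
    burden metric (gene count, sum 1/LOEUF, or sum DS) the planted model
    acts on. ``sleep_model`` and ``insomnia_model`` play the same role for
    the linear sleep-duration model (minutes) and the proportional-odds
    insomnia-trait model.

    Phenotype defaults mirror the cohorts being emulated: mean sleep
    duration 660 min with residual SD 76 min, and insomnia-trait base
    rates of 39% (>= 1 trait) and 10% (2 traits), i.e. proportional-odds
    thresholds logit(0.61) and logit(0.90).
    """

    n_cases: int = 1000
    n_controls: int = 1000
    cnv_rate: float = 0.4                 # mean CNVs per individual
    size_distribution: dict = field(
        default_factory=lambda: {"min": 50_000, "max": 1_500_000}
    )
    del_fraction: float = 0.4             # proportion of CNVs that are deletions
    planted_betas: dict = field(default_factory=dict)
    planted_weighting: str = "count"
    target_set: str = "union"
    sleep_model: dict = field(
        default_factory=lambda: {"intercept": 660.0, "slopes": {}, "noise_sd": 76.0}
    )
    insomnia_model: dict = field(
        default_factory=lambda: {"thresholds": [0.4473, 2.1972], "slopes": {}}
    )
    covariate_model: dict = field(
        default_factory=lambda: {"age_mean": 9.0, "age_sd": 3.5, "male_fraction": 0.8}
    )
    family_size: int = 1
    family_rate_sd: float = 0.0           # lognormal SD of family CNV-rate multiplier
    missing_item_rate: float = 0.05
    contaminate_fraction: float = 0.0     # sub-threshold (size/probe) calls
    avoid_masks: bool = True
    probe_spacing_bp: int = 5_000
    cohort: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("n_cases and n_controls must be positive")
        if self.cnv_rate < 0:
            raise ConfigError("cnv_rate must be >= 0")
        for p in (self.del_fraction, self.missing_item_rate, self.contaminate_fraction):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.family_size < 1:
            raise ConfigError("family_size must be >= 1")
        if self.planted_weighting not in _METRIC_OF_WEIGHTING:
            raise ConfigError(f"unknown planted_weighting {self.planted_weighting!r}")
        allowed = set(BURDEN_TERMS) | {"intercept"}
        cov_allowed = allowed | {"age", "sex", "cognitive_z"}
        unknown = set(self.planted_betas) - allowed
        if unknown:
            raise ConfigError(f"planted_betas references unknown terms: {sorted(unknown)}")
        for name, model in (("sleep_model", self.sleep_model), ("insomnia_model", self.insomnia_model)):
            unknown = set(model.get("slopes", {})) - cov_allowed
            if unknown:
                raise ConfigError(f"{name} slopes reference unknown terms: {sorted(unknown)}")
        smin = int(self.size_distribution.get("min", 50_000))
        smax = int(self.size_distribution.get("max", 1_500_000))
        if not (0 < smin <= smax):
            raise ConfigError("size_distribution must satisfy 0 < min <= max")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _place_cnvs(genome: GenomeModel, n: int, config: SimulationConfig, rng) -> list[CnvCall]:
    """Draw n CNV intervals; placement uniform over autosome bases."""
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lens = np.array([L for _, L in genome.chromosomes], dtype=float)
    p = chrom_lens / chrom_lens.sum()
    smin = int(config.size_distribution.get("min", 50_000))
    smax = int(config.size_distribution.get("max", 1_500_000))
    masks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in genome.mask_intervals:
        masks_by_chrom.setdefault(iv.chrom, []).append(iv)
    calls = []
    for _ in range(n):
        contaminated = config.contaminate_fraction > 0 and rng.random() < config.contaminate_fraction
        for _attempt in range(200):
            ci = int(rng.choice(len(chrom_names), p=p))
            if contaminated:
                length = int(rng.integers(5_000, smin))
            else:
                length = int(np.exp(rng.uniform(np.log(smin), np.log(smax))))
            length = max(1, min(length, int(chrom_lens[ci]) - 1))
            start = int(rng.integers(0, int(chrom_lens[ci]) - length))
            iv = GenomicInterval(chrom_names[ci], start, start + length)
            if config.avoid_masks and any(
                m.start < iv.end and m.end > iv.start for m in masks_by_chrom.get(iv.chrom, [])
            ):
                continue
            break
        probes = max(10, length // config.probe_spacing_bp)
        if contaminated and rng.random() < 0.5:
            probes = int(rng.integers(3, 10))
        calls.append(
            CnvCall(
                sample_id="",  # filled by caller
                interval=iv,
                dosage="DEL" if rng.random() < config.del_fraction else "DUP",
                n_probes=probes,
                cohort=config.cohort,
            )
        )
    return calls


def simulate_cohort(
    genome: GenomeModel, config: SimulationConfig
) -> tuple[list[CnvCall], pd.DataFrame]:
    """Generate CNV calls and phenotypes with planted model parameters.

    Burden features are drawn first (CNVs are placed, annotated against
    the genome's genes, and summed into per-individual profiles); case
    status, sleep duration, and insomnia traits are then sampled from the
    planted logistic, linear, and proportional-odds models on those
    features. The realized case/control split is therefore stochastic
    around ``n_cases / (n_cases + n_controls)``.
    """
    if not genome.genes:
        raise ConfigError("genome has no genes; simulate_genome first")
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"S{i:06d}" for i in range(n)]
    family_ids = [f"F{i // config.family_size:06d}" for i in range(n)]

    # family-level CNV-rate multiplier induces within-family correlation
    n_fam = len(set(family_ids))
    if config.family_rate_sd > 0:
        fam_mult = rng.lognormal(
            -0.5 * config.family_rate_sd**2, config.family_rate_sd, size=n_fam
        )
    else:
        fam_mult = np.ones(n_fam)
    mult = fam_mult[[i // config.family_size for i in range(n)]]

    counts = rng.poisson(config.cnv_rate * mult)
    placed = _place_cnvs(genome, int(counts.sum()), config, rng)
    calls: list[CnvCall] = []
    k = 0
    for sid, c in zip(sample_ids, counts):
        for _ in range(int(c)):
            base = placed[k]
            calls.append(
                CnvCall(sid, base.interval, base.dosage, base.n_probes, base.cohort)
            )
            k += 1

    index = GeneIndex(genome.genes)
    annotated = annotate_cnvs(calls, index, target_set=config.target_set)
    profiles = build_profiles(annotated, sample_ids)

    metric = _METRIC_OF_WEIGHTING[config.planted_weighting]
    x = {term: profiles[f"{term}_{metric}"].to_numpy() for term in BURDEN_TERMS}

    cm = config.covariate_model
    age = rng.normal(cm.get("age_mean", 9.0), cm.get("age_sd", 3.5), size=n).clip(4.0, 18.0)
    sex = (rng.random(n) < cm.get("male_fraction", 0.8)).astype(int)  # 1 = male
    cognitive_z = rng.normal(0.0, 1.0, size=n)
    covs = {"age": age, "sex": sex.astype(float), "cognitive_z": cognitive_z}

    def linear_predictor(slopes: dict) -> np.ndarray:
        eta = np.zeros(n)
        for term, beta in slopes.items():
            if term == "intercept":
                continue
            eta += beta * (x[term] if term in x else covs[term])
        return eta

    base_rate = config.n_cases / n
    intercept = config.planted_betas.get("intercept", math.log(base_rate / (1 - base_rate)))
    eta_case = intercept + linear_predictor(config.planted_betas)
    case_status = rng.binomial(1, _sigmoid(eta_case))

    sm = config.sleep_model
    sleep = (
        sm.get("intercept", 660.0)
        + linear_predictor(sm.get("slopes", {}))
        + rng.normal(0.0, sm.get("noise_sd", 76.0), size=n)
    )

    im = config.insomnia_model
    tau1, tau2 = im.get("thresholds", [0.4473, 2.1972])
    eta_ins = linear_predictor(im.get("slopes", {}))
    u = rng.random(n)
    p_ge1 = _sigmoid(eta_ins - tau1)
    p_ge2 = _sigmoid(eta_ins - tau2)
    traits = (u < p_ge1).astype(int) + (u < p_ge2).astype(int)

    # parent-report items consistent with the trait count, with missingness
    pick_first = rng.random(n) < 0.5
    item1 = np.where(traits == 2, "yes", np.where((traits == 1) & pick_first, "yes", "no"))
    item2 = np.where(traits == 2, "yes", np.where((traits == 1) & ~pick_first, "yes", "no"))
    item1 = np.where(rng.random(n) < config.missing_item_rate, "missing", item1)
    item2 = np.where(rng.random(n) < config.missing_item_rate, "missing", item2)
    observed = pd.array(
        [t if a != "missing" and b != "missing" else pd.NA for t, a, b in zip(traits, item1, item2)],
        dtype="Int64",
    )

    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "family_id": family_ids,
            "cohort": config.cohort,
            "case_status": case_status,
            "age": np.round(age, 2),
            "sex": sex,
            "cognitive_z": np.round(cognitive_z, 4),
            "sleep_duration_min": np.round(sleep, 1),
            "item_falling_asleep": item1,
            "item_awakenings": item2,
            "insomnia_traits": observed,
        }
    )
    return calls, phenotypes
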