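"""Synthetic multi-species datasets with known ground truth.

The generator emits everything the pipeline consumes — per-species count
matrices, gene tables, pairwise protein hit tables and per-sample CpG
reports — together with the planted truth needed to score recovery.

Count model, gene g / species s / sample j:

    count ~ NB(mean = L_j * q_gs / sum_g q_gs, dispersion phi)
    q_gs  = base_g * (length_gs / 1000) * 2**e_gs * 2**(d_g if s focal)

with base_g log-normal, species effects e_gs ~ Normal(0, species_effect_sd)
shared by all samples of a species (this is what makes replicates cluster
by species), lengths uniform integers per species, and d_g = +/- the
planted effect for convergent genes in the two focal species. Variance
follows mean + phi * mean**2. All randomness flows from one seeded
generator, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import CountMatrix, CpGRecord, GeneRecord, HitRecord
from .methylation import PromoterRegion

__all__ = [
    "MethylationConfig",
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_hit_tables",
    "simulate_methylation",
    "score_calls",
]


@dataclass
class MethylationConfig:
    n_promoters: int = 200
    cpgs_per_promoter: int = 10
    depth_mean: float = 30.0
    level_high: float = 0.8
    level_low: float = 0.2
    n_differential: int = 50
    samples_per_group: int = 3


@dataclass
class SimConfig:
    n_species: int = 8
    n_focal: int = 2
    samples_per_species: int | tuple[int, ...] = 4
    n_genes: int = 2000
    n_convergent_up: int = 20
    n_convergent_down: int = 20
    effect_log2fc: float = 2.0
    baseline_log_mean: float = 3.5
    baseline_log_sd: float = 1.0
    species_effect_sd: float = 0.20  # sd of per-gene loadings on the latent axes
    # planted genes are drawn from genes whose baseline expression exceeds
    # this quantile, so that a 2**-effect down-shift cannot push a planted
    # gene under the all-samples > 0 expression filter
    plant_min_base_quantile: float = 0.5
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8.0e5, 1.6e6)
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0
    tissue: str = "liver"
    methylation: MethylationConfig = field(default_factory=MethylationConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_focal < 2 or self.n_focal > self.n_species:
            raise ValidationError("need 2 <= n_focal <= n_species")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be >= 0")
        if self.n_convergent_up + self.n_convergent_down > self.n_genes:
            raise ValidationError("more planted genes than genes")
        if isinstance(self.methylation, dict):
            self.methylation = MethylationConfig(**self.methylation)

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def focal_species(self) -> list[str]:
        return self.species_ids[: self.n_focal]

    def replicates(self, species_index: int) -> int:
        if isinstance(self.samples_per_species, int):
            return self.samples_per_species
        return self.samples_per_species[species_index]


@dataclass
class SimTruth:
    """Planted truth, keyed by the first focal species' gene ids."""

    convergent_up_ids: set[str]
    convergent_down_ids: set[str]
    orthology: pd.DataFrame  # one column per species, row = true orthogroup
    expected_means: pd.DataFrame | None = None  # genes x species relative means
    promoter_levels: pd.DataFrame | None = None  # promoter truth per group

    def __post_init__(self) -> None:
        if self.convergent_up_ids & self.convergent_down_ids:
            raise ValidationError("planted up/down sets overlap")


def _gene_id(species: str, index: int) -> str:
    return f"{species}_g{index:05d}"


def simulate_counts(
    config: SimConfig,
) -> tuple[list[CountMatrix], dict[str, list[GeneRecord]], SimTruth]:
    """Simulate per-species counts, gene tables and the planted truth."""
    rng = np.random.default_rng(config.seed)
    species = config.species_ids
    g = config.n_genes

    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=g))
    # species effects are low-rank: each species sits at an angle on a unit
    # circle in a 2-D latent space and every gene carries a random loading on
    # each axis. Expression programs are therefore correlated across genes,
    # which is what separates species (not replicates) in the leading
    # principal components.
    angles = 2.0 * np.pi * np.arange(len(species)) / len(species)
    coords = np.column_stack([np.cos(angles), np.sin(angles)])  # (S, 2)
    loadings = rng.normal(0.0, config.species_effect_sd, size=(g, 2))
    species_effect = 2.0 ** (loadings @ coords.T)

    eligible = np.where(base >= np.quantile(base, config.plant_min_base_quantile))[0]
    planted = rng.choice(
        eligible, size=config.n_convergent_up + config.n_convergent_down, replace=False
    )
    up_idx = np.sort(planted[: config.n_convergent_up])
    down_idx = np.sort(planted[config.n_convergent_up :])
    shift = np.zeros(g)
    shift[up_idx] = config.effect_log2fc
    shift[down_idx] = -config.effect_log2fc

    lo_len, hi_len = config.gene_length_range
    lengths = rng.integers(lo_len, hi_len + 1, size=(g, len(species)))

    gene_tables: dict[str, list[GeneRecord]] = {}
    matrices: list[CountMatrix] = []
    expected = np.zeros((g, len(species)))
    for s_idx, sp in enumerate(species):
        is_focal = sp in config.focal_species
        q = base * (lengths[:, s_idx] / 1000.0) * species_effect[:, s_idx]
        if is_focal:
            q = q * 2.0**shift
        q_rel = q / q.sum()
        expected[:, s_idx] = q_rel

        n_rep = config.replicates(s_idx)
        lib = rng.uniform(*config.library_size_range, size=n_rep)
        counts = np.empty((g, n_rep), dtype=np.int64)
        for j in range(n_rep):
            mean = lib[j] * q_rel
            if config.dispersion > 0:
                r = 1.0 / config.dispersion
                counts[:, j] = rng.negative_binomial(r, r / (r + mean))
            else:
                counts[:, j] = rng.poisson(mean)
        sample_ids = [f"{sp}_rep{j + 1}" for j in range(n_rep)]
        matrices.append(
            CountMatrix(
                species=sp,
                tissue=config.tissue,
                gene_ids=[_gene_id(sp, i) for i in range(g)],
                sample_ids=sample_ids,
                counts=counts,
            )
        )

        records = []
        pos = 1000  # leave headroom so promoters never clip
        for i in range(g):
            length = int(lengths[i, s_idx])
            strand = "+" if (i + s_idx) % 2 == 0 else "-"
            records.append(
                GeneRecord(
                    gene_id=_gene_id(sp, i),
                    isoform_id=f"{_gene_id(sp, i)}_t1",
                    chrom=f"{sp}_chr1",
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    protein_length=max(1, length // 3),
                )
            )
            pos += length + 2500
        gene_tables[sp] = records

    focal1 = species[0]
    truth = SimTruth(
        convergent_up_ids={_gene_id(focal1, i) for i in up_idx},
        convergent_down_ids={_gene_id(focal1, i) for i in down_idx},
        orthology=pd.DataFrame(
            {sp: [_gene_id(sp, i) for i in range(g)] for sp in species}
        ),
        expected_means=pd.DataFrame(
            expected, index=[_gene_id(focal1, i) for i in range(g)], columns=species
        ),
    )
    return matrices, gene_tables, truth


def simulate_hit_tables(
    truth: SimTruth,
    config: SimConfig,
    decoy_fraction: float = 0.1,
) -> dict[tuple[str, str], list[HitRecord]]:
    """Pairwise hit tables whose RBH structure reconstructs the truth.

    True orthologue pairs receive mutual hits at E-values around 1e-50 with
    high bit scores; decoy hits between mismatched genes are drawn at
    E-values >= 1e-8 with lower bit scores, so the best hit of every query
    is always its true partner.
    """
    rng = np.random.default_rng(config.seed + 1)
    species = list(truth.orthology.columns)
    g = len(truth.orthology)
    tables: dict[tuple[str, str], list[HitRecord]] = {}

    def make_hit(q: str, s: str, evalue: float, bits: float) -> HitRecord:
        return HitRecord(
            query_id=q,
            subject_id=s,
            percent_identity=round(float(rng.uniform(70, 99)), 2),
            alignment_length=int(rng.integers(100, 500)),
            mismatches=int(rng.integers(0, 50)),
            gap_opens=int(rng.integers(0, 5)),
            q_start=1,
            q_end=100,
            s_start=1,
            s_end=100,
            evalue=evalue,
            bit_score=bits,
        )

    ids = {sp: truth.orthology[sp].tolist() for sp in species}
    n_decoys = int(g * decoy_fraction)
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            fwd, rev = [], []
            for k in range(g):
                qa = ids[sa][k]
                qb = ids[sb][k]
                e = 10.0 ** rng.uniform(-60, -40)
                bits = float(rng.uniform(400, 900))
                fwd.append(make_hit(qa, qb, e, bits))
                rev.append(make_hit(qb, qa, 10.0 ** rng.uniform(-60, -40), float(rng.uniform(400, 900))))
            for _ in range(n_decoys):
                ka, kb = rng.integers(0, g, size=2)
                if ka == kb:
                    continue
                qa = ids[sa][int(ka)]
                qb = ids[sb][int(kb)]
                e = 10.0 ** rng.uniform(-8, -2)
                fwd.append(make_hit(qa, qb, e, float(rng.uniform(30, 100))))
                rev.append(make_hit(qb, qa, 10.0 ** rng.uniform(-8, -2), float(rng.uniform(30, 100))))
            tables[(sa, sb)] = fwd
            tables[(sb, sa)] = rev
    return tables


def simulate_methylation(
    config: SimConfig,
    promoters: list[PromoterRegion],
    group_a_samples: list[str] | None = None,
    group_b_samples: list[str] | None = None,
) -> tuple[dict[str, list[CpGRecord]], pd.DataFrame]:
    """Binomial CpG reads over promoters for two sample groups.

    The first ``n_differential`` promoters are truly differential (group A
    at ``level_high``, group B at ``level_low``); the rest share
    ``level_low``. Per CpG: depth ~ Poisson(depth_mean), methylated reads ~
    Binomial(depth, level). Returns per-sample CpG record lists and a truth
    table with columns gene_id, level_a, level_b, differential.
    """
    mc = config.methylation
    rng = np.random.default_rng(config.seed + 2)
    proms = promoters[: mc.n_promoters]
    if group_a_samples is None:
        group_a_samples = [f"methA_{i + 1}" for i in range(mc.samples_per_group)]
    if group_b_samples is None:
        group_b_samples = [f"methB_{i + 1}" for i in range(mc.samples_per_group)]

    truth_rows = []
    levels: dict[str, tuple[float, float]] = {}
    for idx, prom in enumerate(proms):
        differential = idx < mc.n_differential
        la = mc.level_high if differential else mc.level_low
        lb = mc.level_low
        levels[prom.gene_id] = (la, lb)
        truth_rows.append((prom.gene_id, la, lb, differential))

    reports: dict[str, list[CpGRecord]] = {}
    for group, samples in (("a", group_a_samples), ("b", group_b_samples)):
        for sample_id in samples:
            recs: list[CpGRecord] = []
            for prom in proms:
                la, lb = levels[prom.gene_id]
                level = la if group == "a" else lb
                span = prom.end - prom.start
                step = max(1, span // (mc.cpgs_per_promoter + 1))
                positions = [prom.start + (k + 1) * step for k in range(mc.cpgs_per_promoter)]
                depth = rng.poisson(mc.depth_mean, size=len(positions))
                meth = rng.binomial(depth, level)
                for pos0, d, m in zip(positions, depth, meth):
                    recs.append(
                        CpGRecord(
                            sample_id=sample_id,
                            chrom=prom.chrom,
                            position=int(pos0) + 1,  # 1-based report coordinate
                            strand="+",
                            count_methylated=int(m),
                            count_unmethylated=int(d - m),
                        )
                    )
            reports[sample_id] = recs
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "level_a", "level_b", "differential"])
    return reports, truth


def score_calls(
    called_up: set[str],
    called_down: set[str],
    truth_up: set[str],
    truth_down: set[str],
) -> dict[str, float]:
    """Sensitivity and empirical FDR of direction-aware convergence calls."""
    tp = len(called_up & truth_up) + len(called_down & truth_down)
    called = len(called_up) + len(called_down)
    planted = len(truth_up) + len(truth_down)
    sensitivity = tp / planted if planted else float("nan")
    fdr = (called - tp) / called if called else 0.0
    return {
        "true_positives": float(tp),
        "called": float(called),
        "planted": float(planted),
        "sensitivity": sensitivity,
        "fdr": fdr,
    }
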