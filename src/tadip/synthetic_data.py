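"""Desk-scale hit-summary simulator with known per-read truth.

Emulates a metagenomic read simulator + aligner pipeline at the level the
mixture model consumes — matched length and alignment length per (read,
candidate genome) — rather than at the nucleotide level.  Each read draws
its true genome from the configured abundances, a length from a truncated
normal, and a matched length that is binomial with the genome's per-base
match probability.  Sequence homology between genome pairs is modelled by
its aggregate effect: with some probability a read also receives a hit on a
homologous genome, whose match probability is reduced by the pair's extra
per-base divergence.

Two study designs are provided as constructors:

* ``fixed_error_config`` — every genome shares one mismatch probability
  (the null of the model-choice tests; used for type-I-error studies);
* ``varying_two_error_config`` — two genomes carry two different mismatch
  probabilities (used for power studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import RANKS, AlignmentTable, HitRecord, TaxonomyTable
from .hypothesis_tests import WeightConfig, burden_test, null_p0, vct_test
from .mixture_model import fit_em

__all__ = [
    "GenomeSpec",
    "SimConfig",
    "TruthTable",
    "simulate_dataset",
    "fixed_error_config",
    "varying_two_error_config",
    "StudyResult",
    "run_test_study",
]

#: Minimum simulated read length (base pairs).
MIN_READ_LENGTH = 50


@dataclass(frozen=True)
class GenomeSpec:
    """One genome in a simulated community."""

    genome_id: str
    abundance: float
    error_rate: float
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"{self.genome_id}: abundance outside [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError(f"{self.genome_id}: error rate outside [0, 1]")
        if len(self.lineage) != len(RANKS):
            raise ValueError(f"{self.genome_id}: lineage needs {len(RANKS)} ranks")


@dataclass
class SimConfig:
    """Full description of one simulated dataset."""

    n_reads: int
    genomes: Sequence[GenomeSpec]
    read_length_mean: float = 500.0
    read_length_sd: float = 50.0
    #: (genome_a, genome_b) -> extra per-base divergence d_ab; a read truly
    #: from a that also hits b matches each base with prob (1-p_b)(1-d_ab).
    homology: Mapping[tuple[str, str], float] = field(default_factory=dict)
    #: probability that a read from a also receives a hit on homologous b.
    homology_hit_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(g.abundance for g in self.genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.homology_hit_prob <= 1.0:
            raise ValueError("homology_hit_prob outside [0, 1]")
        ids = {g.genome_id for g in self.genomes}
        for (a, b), d in dict(self.homology).items():
            if a not in ids or b not in ids:
                raise ValueError(f"homology pair ({a}, {b}) names unknown genome")
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"homology divergence d[{a},{b}]={d} outside [0, 1]")

    def taxonomy(self) -> TaxonomyTable:
        """Lineage table for the configured genomes."""
        return TaxonomyTable({g.genome_id: g.lineage for g in self.genomes})


@dataclass
class TruthTable:
    """True source genome (and lineage) of every simulated read."""

    true_genome: dict[str, str]
    lineages: dict[str, tuple[str, ...]]

    def __getitem__(self, read_id: str) -> str:
        return self.true_genome[read_id]

    def __len__(self) -> int:
        return len(self.true_genome)


def simulate_dataset(cfg: SimConfig) -> tuple[AlignmentTable, TruthTable]:
    """Draw one dataset; deterministic given ``cfg.seed``.

    Every read gets a hit on its true genome with matched length
    ``Binomial(L, 1 − p_true)``; homologous genomes contribute additional
    (lower-identity) hits.
    """
    rng = np.random.default_rng(cfg.seed)
    genomes = list(cfg.genomes)
    k = len(genomes)
    abundances = np.array([g.abundance for g in genomes])
    rates = np.array([g.error_rate for g in genomes])
    by_id = {g.genome_id: i for i, g in enumerate(genomes)}
    # homologs of each source genome: (target index, divergence)
    homologs: dict[int, list[tuple[int, float]]] = {i: [] for i in range(k)}
    for (a, b), d in cfg.homology.items():
        homologs[by_id[a]].append((by_id[b], d))

    true_idx = rng.choice(k, size=cfg.n_reads, p=abundances)
    lengths = np.maximum(
        np.rint(rng.normal(cfg.read_length_mean, cfg.read_length_sd, cfg.n_reads)),
        MIN_READ_LENGTH,
    ).astype(int)

    records: list[HitRecord] = []
    truth: dict[str, str] = {}
    width = len(str(cfg.n_reads))
    for j in range(cfg.n_reads):
        read_id = f"r{j + 1:0{width}d}"
        i = int(true_idx[j])
        L = int(lengths[j])
        truth[read_id] = genomes[i].genome_id
        M = int(rng.binomial(L, 1.0 - rates[i]))
        records.append(
            HitRecord(read_id, genomes[i].genome_id, f"tax{i + 1}", M, L)
        )
        for b, d in homologs[i]:
            if rng.random() < cfg.homology_hit_prob:
                match_prob = (1.0 - rates[b]) * (1.0 - d)
                Mb = int(rng.binomial(L, match_prob))
                records.append(
                    HitRecord(read_id, genomes[b].genome_id, f"tax{b + 1}", Mb, L)
                )
    table = AlignmentTable.from_records(records)
    return table, TruthTable(truth, {g.genome_id: g.lineage for g in genomes})


def _default_lineage(i: int) -> tuple[str, ...]:
    """Distinct taxa at every rank below Kingdom."""
    return tuple(f"{rank}_{i}" for rank in RANKS[:-1]) + ("Bacteria",)


def _chain_homology(
    ids: Sequence[str], divergence: float
) -> dict[tuple[str, str], float]:
    """Symmetric homology between consecutive genome pairs."""
    out: dict[tuple[str, str], float] = {}
    for a, b in zip(ids, ids[1:]):
        out[(a, b)] = divergence
        out[(b, a)] = divergence
    return out


def fixed_error_config(
    k: int = 2,
    n_reads: int = 1000,
    p_common: float = 0.01,
    read_length_mean: float = 500.0,
    read_length_sd: float = 50.0,
    homology_divergence: float = 0.02,
    homology_hit_prob: float = 0.3,
    seed: int = 0,
) -> SimConfig:
    """Null design: ``k`` equally abundant genomes sharing one error rate."""
    if not 0.0 < p_common < 1.0:
        raise ValueError("p_common must lie in (0, 1)")
    genomes = [
        GenomeSpec(f"g{i + 1}", 1.0 / k, p_common, _default_lineage(i + 1))
        for i in range(k)
    ]
    ids = [g.genome_id for g in genomes]
    return SimConfig(
        n_reads=n_reads,
        genomes=genomes,
        read_length_mean=read_length_mean,
        read_length_sd=read_length_sd,
        homology=_chain_homology(ids, homology_divergence),
        homology_hit_prob=homology_hit_prob,
        seed=seed,
    )


def varying_two_error_config(
    n_reads: int = 1000,
    p_a: float = 0.005,
    p_b: float = 0.015,
    read_length_mean: float = 500.0,
    read_length_sd: float = 50.0,
    homology_divergence: float = 0.02,
    homology_hit_prob: float = 0.3,
    seed: int = 0,
) -> SimConfig:
    """Alternative design: two equally abundant genomes with distinct rates."""
    for p in (p_a, p_b):
        if not 0.0 < p < 1.0:
            raise ValueError("error rates must lie in (0, 1)")
    genomes = [
        GenomeSpec("g1", 0.5, p_a, _default_lineage(1)),
        GenomeSpec("g2", 0.5, p_b, _default_lineage(2)),
    ]
    return SimConfig(
        n_reads=n_reads,
        genomes=genomes,
        read_length_mean=read_length_mean,
        read_length_sd=read_length_sd,
        homology=_chain_homology(["g1", "g2"], homology_divergence),
        homology_hit_prob=homology_hit_prob,
        seed=seed,
    )


@dataclass
class StudyResult:
    """Empirical rejection rates of the model-choice tests over replicates."""

    design: str
    n_reps: int
    alpha: float
    rejection_rate: dict[str, float]
    p_values: dict[str, np.ndarray]

    def summary(self) -> str:
        lines = [f"design={self.design} reps={self.n_reps} alpha={self.alpha}"]
        for name, rate in self.rejection_rate.items():
            lines.append(f"  {name}: rejection rate {rate:.3f}")
        return "\n".join(lines)


def run_test_study(
    design: str = "fixed",
    n_reps: int = 100,
    alpha: float = 0.05,
    cfg: SimConfig | None = None,
    seed: int = 0,
    weight_cfg: WeightConfig = WeightConfig(),
) -> StudyResult:
    """Replicate the simulate → fit → test pipeline and tally rejections.

    For each replicate a fresh dataset is drawn (replicate seeds are
    spawned deterministically from ``seed``), per-genome mismatch
    probabilities are fitted by EM, the shared-probability null is fitted,
    and both the burden and variance component tests are run.  The
    empirical rejection rate is the fraction of replicates with
    ``p < alpha`` — the type I error under the fixed design, the power
    under the varying design.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if cfg is None:
        if design == "fixed":
            cfg = fixed_error_config()
        elif design == "varying_two":
            cfg = varying_two_error_config()
        else:
            raise ValueError(f"unknown design {design!r}")
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    pvals = {"burden": np.empty(n_reps), "vct": np.empty(n_reps)}
    for r in range(n_reps):
        rep_cfg = SimConfig(
            n_reads=cfg.n_reads,
            genomes=cfg.genomes,
            read_length_mean=cfg.read_length_mean,
            read_length_sd=cfg.read_length_sd,
            homology=cfg.homology,
            homology_hit_prob=cfg.homology_hit_prob,
            seed=int(rep_seeds[r]),
        )
        try:
            table, _ = simulate_dataset(rep_cfg)
            fit = fit_em(table, mode="per_genome_p")
            p0, E = null_p0(table)
            pvals["burden"][r] = burden_test(fit.params.p, p0, E, weight_cfg).p_value
            pvals["vct"][r] = vct_test(fit.params.p, p0, E, weight_cfg).p_value
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
    rates = {name: float((p < alpha).mean()) for name, p in pvals.items()}
    return StudyResult(
        design=design,
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rates,
        p_values=pvals,
    )
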