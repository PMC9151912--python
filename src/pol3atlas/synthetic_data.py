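"""Multi-assay count simulator with a planted POLR3G-enhanced gene subset.

The generator emulates the statistical structure the analysis pipeline
assumes: a latent per-sample POLR3G-availability variable ``a_s`` in
[0, 1] (high in monocyte-like samples, low after macrophage
differentiation), a set of occupied Pol III genes with elevated ChIP
signal across every subunit, and a planted "enhanced" subset whose mean
signal in the POLR3G ChIP, ATAC and small-RNA tracks scales as
``2**(beta * a_s)``, so the expected differential log2 fold change
between two conditions equals ``beta * (a_A - a_B)``.

Noise model: each gene's biological rate per track is drawn once from a
Gamma distribution with squared coefficient of variation equal to the
dispersion, and per-sample counts are Poisson around that fixed rate
(scaled by a lognormal library-size factor and the availability effect).
Marginally across genes a count is therefore negative binomial
NB(mu, dispersion), while repeated measurements of the same gene are
conditionally Poisson — the regime in which the exact conditional
binomial test of the differential module is calibrated. Per-sample
biological excess variability beyond the shared rate is deliberately not
simulated; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .annotation import AnnotationSet, GeneRecord
from .quant import CountMatrix, SampleMeta, write_count_tsv, write_samples_tsv

__all__ = ["SimConfig", "SimTruth", "Simulation", "simulate", "emit_fixture",
           "nb_counts", "load_sim_config"]


@dataclass
class SimConfig:
    """Simulation settings; defaults define the standard study conditions."""

    n_genes: int = 2000
    n_enhanced: int = 20
    n_occupied: int = 350
    n_samples: int = 6                      # per condition, per assay
    conditions: tuple[str, ...] = ("monocyte", "macrophage", "stimulated")
    availability: Mapping[str, float] = field(
        default_factory=lambda: {
            "monocyte": 1.0, "macrophage": 0.2, "stimulated": 0.9,
        }
    )
    subunits: tuple[str, ...] = (
        "POLR3A", "POLR3B", "POLR1D", "POLR3D", "POLR3E", "POLR3G", "POLR3GL",
    )
    beta: float = 2.0                       # log2 effect per unit availability
    baseline_mu: float = 100.0              # mean count of a background gene
    dispersion: float = 0.2                 # NB dispersion (CV^2 of gene rates)
    occupied_boost: float = 6.0             # rate multiplier for occupied genes
    gl_dampening: float = 0.3               # POLR3GL ChIP damping at enhanced genes
    availability_jitter: float = 0.05       # per-sample sd around the condition value
    library_sigma: float = 0.2              # lognormal sd of library-size factors
    n_accessible_background: int = 20       # super-accessible non-Pol III loci
    accessible_boost: float = 50.0          # their ATAC rate multiplier
    expr_floor: float = 5.0                 # POLR3G expression at availability 0
    expr_scale: float = 200.0               # POLR3G expression slope vs availability
    polr3gl_mu: float = 100.0               # constant POLR3GL expression mean
    n_expr_background: int = 10
    seed: int = 7

    def validate(self) -> None:
        problems = []
        if self.n_genes < 2:
            problems.append("n_genes must be >= 2")
        if not 0 <= self.n_enhanced <= self.n_genes:
            problems.append("n_enhanced must lie in [0, n_genes]")
        if not self.n_enhanced <= self.n_occupied <= self.n_genes:
            problems.append("n_occupied must lie in [n_enhanced, n_genes]")
        if self.n_samples < 1:
            problems.append("n_samples must be >= 1")
        if not self.conditions:
            problems.append("conditions must be nonempty")
        missing = [c for c in self.conditions if c not in self.availability]
        if missing:
            problems.append(f"availability missing for conditions {missing}")
        bad = [c for c, a in self.availability.items() if not 0 <= a <= 1]
        if bad:
            problems.append(f"availability outside [0, 1] for {bad}")
        if len(self.subunits) < 2 or "POLR3G" not in self.subunits \
                or "POLR3GL" not in self.subunits:
            problems.append("subunits must include POLR3G and POLR3GL")
        if self.beta < 0:
            problems.append("beta must be >= 0")
        for name in ("baseline_mu", "occupied_boost", "gl_dampening",
                     "expr_floor", "expr_scale", "polr3gl_mu"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.dispersion <= 0:
            problems.append("dispersion must be > 0")
        if self.availability_jitter < 0 or self.library_sigma < 0:
            problems.append("jitter/library sigma must be >= 0")
        if self.n_accessible_background < 0 or self.accessible_boost <= 0:
            problems.append(
                "n_accessible_background must be >= 0 and accessible_boost > 0"
            )
        if self.n_accessible_background > self.n_genes - self.n_occupied:
            problems.append(
                "n_accessible_background exceeds the non-occupied gene count"
            )
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Planted labels and latent availability emitted alongside the counts."""

    enhanced_gene_ids: set[str]
    occupied_gene_ids: set[str]
    availability: dict[str, float]          # biological sample key -> a_s
    gene_rates: dict[str, np.ndarray]       # track -> per-gene baseline rate


@dataclass
class Simulation:
    chip: dict[str, CountMatrix]
    atac: CountMatrix
    smallrna: CountMatrix
    expr: CountMatrix
    truth: SimTruth
    config: SimConfig


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Draw negative-binomial counts via the Gamma-Poisson mixture.

    Variance is ``mean + dispersion * mean**2``; ``dispersion`` below 1e-12
    degenerates to Poisson.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float),
                           size if size is not None else np.shape(mean))
    if dispersion < 1e-12:
        return rng.poisson(mean)
    rates = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(rates)


def _gene_rates(rng, cfg: SimConfig, occupied_idx: np.ndarray) -> np.ndarray:
    lam = rng.gamma(
        shape=1.0 / cfg.dispersion,
        scale=cfg.baseline_mu * cfg.dispersion,
        size=cfg.n_genes,
    )
    lam[occupied_idx] *= cfg.occupied_boost
    return lam


def simulate(cfg: SimConfig | None = None) -> Simulation:
    """Generate the full multi-assay bundle; bit-identical under a fixed seed."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"URS{i:08d}" for i in range(cfg.n_genes)]
    occupied_idx = np.sort(rng.choice(cfg.n_genes, cfg.n_occupied, replace=False))
    enhanced_idx = np.sort(rng.choice(occupied_idx, cfg.n_enhanced, replace=False))
    enhanced_mask = np.zeros(cfg.n_genes, dtype=bool)
    enhanced_mask[enhanced_idx] = True

    # One latent availability value per biological sample, shared by every
    # assay performed on that sample.
    sample_keys: list[tuple[str, int]] = [
        (c, j + 1) for c in cfg.conditions for j in range(cfg.n_samples)
    ]
    avail = np.clip(
        np.array([cfg.availability[c] for c, _ in sample_keys])
        + rng.normal(0.0, cfg.availability_jitter, len(sample_keys)),
        0.0, 1.0,
    )
    availability = {f"{c}_{j:02d}": float(a)
                    for (c, j), a in zip(sample_keys, avail)}

    def _sample_meta(assay: str, factor: str, prefix: str) -> list[SampleMeta]:
        return [
            SampleMeta(
                sample_id=f"{prefix}{c}_{j:02d}", assay=assay, factor=factor,
                condition=c, replicate=j,
            )
            for c, j in sample_keys
        ]

    def _finalize(gene_rates, effect, assay, factor, prefix="") -> CountMatrix:
        sf = rng.lognormal(0.0, cfg.library_sigma, len(sample_keys))
        mean = gene_rates[:, None] * effect * sf[None, :]
        counts = rng.poisson(mean)
        metas = _sample_meta(assay, factor, prefix)
        for j, m in enumerate(metas):
            m.library_size = int(counts[:, j].sum())
        return CountMatrix(list(gene_ids), metas, counts)

    enhancement = np.ones((cfg.n_genes, len(sample_keys)))
    enhancement[enhanced_mask, :] = 2.0 ** (cfg.beta * avail)[None, :]

    gene_rates: dict[str, np.ndarray] = {}
    chip: dict[str, CountMatrix] = {}
    for sub in cfg.subunits:
        lam = _gene_rates(rng, cfg, occupied_idx)
        gene_rates[f"chip_{sub}"] = lam
        if sub == "POLR3G":
            effect = enhancement
        elif sub == "POLR3GL":
            lam = lam.copy()
            lam[enhanced_mask] *= cfg.gl_dampening
            effect = np.ones_like(enhancement)
        else:
            effect = np.ones_like(enhancement)
        chip[sub] = _finalize(lam, effect, "chip", sub, prefix=f"{sub}_")

    lam_atac = _gene_rates(rng, cfg, occupied_idx)
    # A handful of non-Pol III loci sit in broadly accessible chromatin and
    # own the top of the accessibility scale, as in real consolidated ncRNA
    # annotations; without them rank normalization would pin high-rate
    # occupied genes at rank 1 in every sample.
    if cfg.n_accessible_background:
        non_occ = np.setdiff1d(np.arange(cfg.n_genes), occupied_idx)
        hot = rng.choice(non_occ, cfg.n_accessible_background, replace=False)
        lam_atac[hot] *= cfg.accessible_boost
    gene_rates["atac"] = lam_atac
    atac = _finalize(lam_atac, enhancement, "atac", "")

    lam_srna = _gene_rates(rng, cfg, occupied_idx)
    gene_rates["smallrna"] = lam_srna
    smallrna = _finalize(lam_srna, enhancement, "smallrna", "")

    # Expression matrix: the two identity subunits plus background genes.
    expr_gene_ids = ["POLR3G", "POLR3GL"] + [
        f"EXPRBG{i:03d}" for i in range(cfg.n_expr_background)
    ]
    bg_rates = rng.gamma(
        1.0 / cfg.dispersion, cfg.baseline_mu * cfg.dispersion,
        cfg.n_expr_background,
    )
    expr_mean = np.vstack(
        [
            cfg.expr_floor + cfg.expr_scale * avail[None, :],
            np.full((1, len(sample_keys)), cfg.polr3gl_mu),
            np.repeat(bg_rates[:, None], len(sample_keys), axis=1),
        ]
    )
    sf = rng.lognormal(0.0, cfg.library_sigma, len(sample_keys))
    expr_counts = rng.poisson(expr_mean * sf[None, :])
    expr_metas = _sample_meta("rnaseq", "", "")
    for j, m in enumerate(expr_metas):
        m.library_size = int(expr_counts[:, j].sum())
    expr = CountMatrix(expr_gene_ids, expr_metas, expr_counts)

    truth = SimTruth(
        enhanced_gene_ids={gene_ids[i] for i in enhanced_idx},
        occupied_gene_ids={gene_ids[i] for i in occupied_idx},
        availability=availability,
        gene_rates=gene_rates,
    )
    return Simulation(chip=chip, atac=atac, smallrna=smallrna, expr=expr,
                      truth=truth, config=cfg)


def synthetic_annotation(cfg: SimConfig) -> AnnotationSet:
    """Deterministic synthetic gene windows matching the simulated gene ids."""
    records = [
        GeneRecord(
            gene_id=f"URS{i:08d}", chrom="chrS", start=1000 + 1000 * i,
            end=1100 + 1000 * i, strand="+",
        )
        for i in range(cfg.n_genes)
    ]
    return AnnotationSet(records, genome_label="synthetic")


def emit_fixture(cfg: SimConfig | None = None, out_dir: str | Path = ".") -> list[Path]:
    """Write the full simulated input bundle consumable by every CLI stage.

    Emits gene windows (BED6), one counts TSV per ChIP subunit, ATAC,
    small-RNA and expression TSVs, a combined sample sheet (with the latent
    availability column) and the truth table. Re-running with the same
    config produces byte-identical files.
    """
    cfg = cfg or SimConfig()
    sim = simulate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    from .annotation import write_bed

    bed = out / "genes.bed"
    write_bed(synthetic_annotation(cfg), bed)
    written.append(bed)

    matrices: list[tuple[str, CountMatrix]] = [
        (f"chip_{sub}.tsv", m) for sub, m in sim.chip.items()
    ] + [("atac.tsv", sim.atac), ("smallrna.tsv", sim.smallrna),
         ("expr.tsv", sim.expr)]
    for fname, cm in matrices:
        p = out / fname
        write_count_tsv(cm, p)
        written.append(p)

    # The same biological sample id recurs across the atac/smallrna/expr
    # assays (that is what lets profiles be matched by sample ID), so sample
    # sheets are written per assay family.
    sheets: dict[str, list[SampleMeta]] = {
        "chip": [s for m in sim.chip.values() for s in m.samples],
        "atac": list(sim.atac.samples),
        "smallrna": list(sim.smallrna.samples),
        "expr": list(sim.expr.samples),
    }
    for name, metas in sheets.items():
        p = out / f"samples_{name}.tsv"
        write_samples_tsv(metas, p)
        written.append(p)

    avail_path = out / "availability.tsv"
    with avail_path.open("w") as fh:
        fh.write("sample_key\tavailability\n")
        for key in sorted(sim.truth.availability):
            fh.write(f"{key}\t{sim.truth.availability[key]:.6f}\n")
    written.append(avail_path)

    truth_path = out / "truth.tsv"
    with truth_path.open("w") as fh:
        fh.write("gene_id\tenhanced\toccupied\n")
        for i in range(cfg.n_genes):
            gid = f"URS{i:08d}"
            fh.write(
                f"{gid}\t{int(gid in sim.truth.enhanced_gene_ids)}"
                f"\t{int(gid in sim.truth.occupied_gene_ids)}\n"
            )
    written.append(truth_path)
    return written


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from YAML; unknown keys raise."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "conditions" in data:
        data["conditions"] = tuple(data["conditions"])
    if "subunits" in data:
        data["subunits"] = tuple(data["subunits"])
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg
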