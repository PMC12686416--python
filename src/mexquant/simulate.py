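"""Synthetic-data generation with known ground truth.

Everything the pipeline consumes can be generated here: donor-anchored
splice-junction tables with multinomial read counts, group-structured cohorts
(per-subtype Dirichlet means, e.g. an ER+/ER- contrast), a continuous feature
coupled to one isoform's proportion at a target Pearson r, control/treated
perturbation pairs with a planted fold change, and random sequences with
planted motifs.  Electropherogram simulation lives in
:func:`mexquant.fragments.simulate_trace`.

Reproducibility: a single master seed is expanded into per-stream sub-seeds
keyed by sample index, so generating additional samples never perturbs
existing ones, and identical configurations produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import MicroexonGeneModel, acceptor_map, donor_site, load_gene_model
from .sj import SpliceJunctionRecord

__all__ = [
    "GeneratorConfig",
    "CohortSim",
    "PerturbationSim",
    "simulate_sample",
    "simulate_cohort",
    "simulate_perturbation",
    "simulate_motif_sequence",
]


def _stream_rng(seed: int, *key) -> np.random.Generator:
    """Derived sub-stream: stable under addition of other streams."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic generators.

    The group means encode the ER contrast the cell-line panel shows (the
    3-bp-microexon isoform around 0.40 of donor reads in ER+ lines vs 0.10 in
    ER-, the 18-bp junction absent, the 22-bp isoform roughly flat); the
    perturbation defaults encode the splicing-factor-knockdown design (control
    proportion 0.2 raised 2.25-fold to 0.45, three replicates per arm).
    """

    seed: int = 0
    model: MicroexonGeneModel | None = None
    # sequencing depth at the donor: negative-binomial around the mean
    mean_depth: float = 5000.0
    depth_dispersion: float = 0.3  # gamma-Poisson; 0 -> Poisson
    # per-group mean proportions over the junction categories
    group_means: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "ER+": {"ex4:3bp": 0.40, "ex4:18bp": 0.0, "ex4:22bp": 0.25, "ex4:ex6": 0.35},
            "ER-": {"ex4:3bp": 0.10, "ex4:18bp": 0.0, "ex4:22bp": 0.30, "ex4:ex6": 0.60},
        }
    )
    concentration: float = 50.0  # Dirichlet concentration (between-sample spread)
    # feature coupled to one label's true proportion
    feature_label: str = "ex4:3bp"
    feature_r: float = 0.7
    # perturbation design
    perturb_label: str = "ex4:3bp"
    perturb_fold: float = 2.25
    perturb_control_p: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"ex4:3bp": 0.2, "ex4:18bp": 0.0, "ex4:22bp": 0.1, "ex4:ex6": 0.7}
    )
    n_per_arm: int = 3
    replicate_noise_sd: float = 0.01
    # trace parameters
    base_amplicon: float = 160.0
    trace_sigma: float = 0.35
    trace_snr: float = 50.0
    decoys: bool = True

    def resolved_model(self) -> MicroexonGeneModel:
        if self.model is None:
            self.model = load_gene_model("RPS24")
        return self.model


def _draw_depth(rng: np.random.Generator, config: GeneratorConfig) -> int:
    mean = config.mean_depth
    if config.depth_dispersion <= 0:
        return int(rng.poisson(mean))
    shape = 1.0 / config.depth_dispersion
    lam = rng.gamma(shape, mean / shape)
    return int(rng.poisson(lam))


def _decoy_records(model: MicroexonGeneModel, rng: np.random.Generator) -> list[SpliceJunctionRecord]:
    """Junctions that must be excluded by classification: a microexon-donor
    junction inside the locus and a junction on another chromosome."""
    strand_code = 1 if model.strand == "+" else 2
    recs = []
    if model.microexons:
        m = model.microexons[-1]
        term = model.terminal_exon
        if model.strand == "+":
            start, end = m.end + 1, term.start - 1
        else:
            start, end = term.end + 1, m.start - 1
        recs.append(
            SpliceJunctionRecord(
                chrom=model.chrom, intron_start=start, intron_end=end,
                strand_code=strand_code, motif_code=1, annotated=1,
                unique_reads=int(rng.integers(5, 50)), multi_reads=0, max_overhang=50,
            )
        )
    other_chrom = "chr2" if model.chrom != "chr2" else "chr3"
    pos = int(rng.integers(1_000_000, 2_000_000))
    recs.append(
        SpliceJunctionRecord(
            chrom=other_chrom, intron_start=pos, intron_end=pos + int(rng.integers(100, 5000)),
            strand_code=1, motif_code=1, annotated=1,
            unique_reads=int(rng.integers(5, 50)), multi_reads=0, max_overhang=50,
        )
    )
    return recs


def _sample_records(
    true_p: Mapping[str, float],
    depth: int,
    model: MicroexonGeneModel,
    rng: np.random.Generator,
    decoys: bool = True,
) -> list[SpliceJunctionRecord]:
    if depth < 0:
        raise ValueError("depth must be non-negative")
    labels = model.junction_labels
    p = np.array([float(true_p.get(label, 0.0)) for label in labels])
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"true proportions must sum to 1, got {p.sum()}")
    counts = rng.multinomial(depth, p / p.sum()) if depth > 0 else np.zeros(len(p), dtype=int)
    site = donor_site(model)
    amap = {label: pos for pos, label in acceptor_map(model).items()}
    strand_code = 1 if model.strand == "+" else 2
    recs = []
    for label, n in zip(labels, counts):
        if n == 0:
            continue
        acceptor = amap[label]
        start, end = (site, acceptor) if model.strand == "+" else (acceptor, site)
        multi = int(rng.poisson(0.02 * n))
        recs.append(
            SpliceJunctionRecord(
                chrom=model.chrom, intron_start=start, intron_end=end,
                strand_code=strand_code, motif_code=1, annotated=1,
                unique_reads=int(n), multi_reads=multi, max_overhang=50,
            )
        )
    if decoys:
        recs.extend(_decoy_records(model, rng))
    recs.sort(key=lambda r: (r.chrom, r.intron_start, r.intron_end))
    return recs


def _records_to_text(records: Sequence[SpliceJunctionRecord]) -> str:
    lines = [
        "\t".join(
            str(v)
            for v in (
                r.chrom, r.intron_start, r.intron_end, r.strand_code, r.motif_code,
                r.annotated, r.unique_reads, r.multi_reads, r.max_overhang,
            )
        )
        for r in records
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def simulate_sample(
    true_p: Mapping[str, float],
    depth: int,
    config: GeneratorConfig,
    stream: int = 0,
) -> str:
    """One synthetic ``SJ.out.tab`` file (returned as text).

    Donor-anchored junction records get multinomial(depth, true_p) unique-read
    counts at the model's acceptor positions; decoy junctions (a
    microexon-donor junction and one on another chromosome) exercise the
    classification filter when ``config.decoys`` is on.
    """
    model = config.resolved_model()
    rng = _stream_rng(config.seed, 0, stream)
    return _records_to_text(_sample_records(true_p, depth, model, rng, config.decoys))


@dataclasses.dataclass
class CohortSim:
    sj: dict[str, str]  # sample_id -> SJ.out.tab text
    records: dict[str, list[SpliceJunctionRecord]]
    metadata: pd.DataFrame  # sample_id, group
    feature: pd.Series  # indexed by sample_id
    truth: pd.DataFrame  # sample_id, group, depth, true proportions per label


def _dirichlet_proportions(
    mean: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet draw around a mean vector; zero-mean components stay exactly zero."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    p = np.zeros_like(mean)
    pos = mean > 0
    alpha = mean[pos] * concentration
    p[pos] = rng.dirichlet(alpha)
    return p


def simulate_cohort(
    config: GeneratorConfig,
    n_per_group: Mapping[str, int] | None = None,
) -> CohortSim:
    """Group-structured cohort with per-sample junction files and a coupled feature.

    Per-sample true proportions are Dirichlet draws around the group mean; the
    continuous feature is built from the standardized true proportion of
    ``config.feature_label`` mixed with independent Gaussian noise so its
    truth-level Pearson correlation targets ``config.feature_r``.
    """
    model = config.resolved_model()
    if n_per_group is None:
        n_per_group = {g: 20 for g in config.group_means}
    if not n_per_group:
        raise ValueError("need at least one group")
    labels = model.junction_labels
    sj: dict[str, str] = {}
    records: dict[str, list[SpliceJunctionRecord]] = {}
    meta_rows, truth_rows = [], []
    true_vals = []
    sample_idx = 0
    for group in sorted(n_per_group):
        mean = np.array([config.group_means[group].get(label, 0.0) for label in labels])
        if not np.isclose(mean.sum(), 1.0, atol=1e-6):
            raise ValueError(f"group {group!r} mean proportions must sum to 1")
        for _ in range(n_per_group[group]):
            sid = f"S{sample_idx:04d}"
            rng = _stream_rng(config.seed, 1, sample_idx)
            p = _dirichlet_proportions(mean, config.concentration, rng)
            depth = _draw_depth(rng, config)
            recs = _sample_records(dict(zip(labels, p)), depth, model, rng, config.decoys)
            records[sid] = recs
            sj[sid] = _records_to_text(recs)
            meta_rows.append({"sample_id": sid, "group": group})
            truth_rows.append({"sample_id": sid, "group": group, "depth": depth,
                               **dict(zip(labels, p))})
            true_vals.append(p[list(labels).index(config.feature_label)])
            sample_idx += 1
    truth = pd.DataFrame(truth_rows)
    metadata = pd.DataFrame(meta_rows)
    # feature coupled to the chosen label's true proportion at target r:
    # Gaussian noise residualized against the truth in-sample, so the
    # realized truth-level Pearson correlation hits the target exactly
    tv = np.asarray(true_vals)
    rng_f = _stream_rng(config.seed, 2)
    sd = tv.std()
    zt = (tv - tv.mean()) / sd if sd > 0 else np.zeros_like(tv)
    r = float(np.clip(config.feature_r, -1.0, 1.0))
    noise = rng_f.normal(size=tv.size)
    if sd > 0 and tv.size > 2:
        noise = noise - (noise @ zt) / (zt @ zt) * zt
        nsd = noise.std()
        if nsd > 0:
            noise = (noise - noise.mean()) / nsd
    feature_vals = r * zt + np.sqrt(1 - r**2) * noise
    feature = pd.Series(feature_vals, index=metadata["sample_id"].to_numpy(), name="feature")
    return CohortSim(sj=sj, records=records, metadata=metadata, feature=feature, truth=truth)


@dataclasses.dataclass
class PerturbationSim:
    sj: dict[str, str]
    records: dict[str, list[SpliceJunctionRecord]]
    metadata: pd.DataFrame  # sample_id, condition
    truth: pd.DataFrame


def simulate_perturbation(config: GeneratorConfig, depth: int | None = None) -> PerturbationSim:
    """Control/treated pair with a planted fold change on one isoform.

    The treated mean proportion of ``perturb_label`` is control x fold, the
    remaining labels renormalized proportionally.  Each replicate jitters the
    perturbed label with Gaussian noise (``replicate_noise_sd``) before
    multinomial sampling at the configured depth.
    """
    model = config.resolved_model()
    labels = model.junction_labels
    control_p = np.array([config.perturb_control_p.get(label, 0.0) for label in labels])
    if not np.isclose(control_p.sum(), 1.0, atol=1e-6):
        raise ValueError("control proportions must sum to 1")
    li = list(labels).index(config.perturb_label)
    if control_p[li] <= 0:
        raise ValueError("control mean proportion for the perturbed label must be > 0")
    target = control_p[li] * config.perturb_fold
    if target > 1:
        raise ValueError(
            f"fold pushes proportion above 1: {control_p[li]} x {config.perturb_fold} = {target}"
        )
    treated_p = control_p * (1 - target) / (1 - control_p[li])
    treated_p[li] = target

    sj, records, meta_rows, truth_rows = {}, {}, [], []
    for arm, base_p in (("control", control_p), ("treated", treated_p)):
        for rep in range(config.n_per_arm):
            idx = rep if arm == "control" else config.n_per_arm + rep
            sid = f"{arm}_{rep + 1}"
            rng = _stream_rng(config.seed, 3, idx)
            p = base_p.copy()
            jit = rng.normal(0.0, config.replicate_noise_sd)
            p_li = float(np.clip(p[li] + jit, 1e-6, 1 - 1e-6))
            others = 1 - p[li]
            p = p * (1 - p_li) / others if others > 0 else p
            p[li] = p_li
            d = depth if depth is not None else _draw_depth(rng, config)
            recs = _sample_records(dict(zip(labels, p)), d, model, rng, config.decoys)
            records[sid] = recs
            sj[sid] = _records_to_text(recs)
            meta_rows.append({"sample_id": sid, "condition": arm})
            truth_rows.append({"sample_id": sid, "condition": arm, "depth": d,
                               **dict(zip(labels, p))})
    return PerturbationSim(
        sj=sj,
        records=records,
        metadata=pd.DataFrame(meta_rows),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_motif_sequence(
    length: int,
    planted: Sequence[tuple[str, int]] = (),
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[str, list[tuple[str, int]]]:
    """Random RNA sequence with exact planted motif substrings.

    Background bases are i.i.d. from ``composition`` (uniform by default);
    each (motif, position) pair is written verbatim at its 0-based position.
    Overlapping or out-of-bounds plants raise.  Returns the sequence and the
    truth list.
    """
    bases = "ACGU"
    if composition is None:
        probs = np.full(4, 0.25)
    else:
        probs = np.array([composition.get(b, 0.0) for b in bases], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(bases), size=length, p=probs))
    occupied: list[tuple[int, int]] = []
    for motif, pos in planted:
        motif = motif.upper().replace("T", "U")
        if pos < 0 or pos + len(motif) > length:
            raise ValueError(f"planted motif at {pos} out of bounds")
        for a, b in occupied:
            if pos < b and pos + len(motif) > a:
                raise ValueError(f"planted motifs overlap at {pos}")
        occupied.append((pos, pos + len(motif)))
        seq[pos : pos + len(motif)] = list(motif)
    truth = [(m.upper().replace("T", "U"), p) for m, p in planted]
    return "".join(seq), truth
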