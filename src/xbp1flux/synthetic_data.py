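"""Synthetic data generators with known ground truth for every stage.

Emulates the structure of a paired-perturbation transcriptome study of
IRE1a-XBP1s inhibition — two contrasts (siRNA knockdown vs control;
small-molecule inhibitor vs vehicle) sharing a core of down-regulated
genes, splice-junction tables in which a focal spliced junction is
depleted by treatment, survival cohorts whose hazard follows a signature
score, and drug-combination fractional responses — entirely from a single
root seed, so the full pipeline is testable offline with every generating
parameter recorded.

Default scale is a desk-scale shadow of a triplicate RNA-seq design:
10,000 genes, 3 samples per group, ~5e6 unique spliced reads per sample.
One root seed expands to fixed per-component child streams via
``numpy.random.default_rng([seed, component_index])`` (counts=1,
junctions=2, survival=3, combos=4), so components regenerate
independently and deterministically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneSetCollection,
    JunctionRecord,
    JunctionTable,
    SurvivalCohort,
    ValidationError,
    write_counts,
    write_gmt,
    write_sj_tab,
    write_survival,
)
from .junction_splicing import DEFAULT_FOCAL

__all__ = [
    "SimulationConfig",
    "JunctionSimConfig",
    "SurvivalSimConfig",
    "ComboSimConfig",
    "simulate_counts",
    "simulate_junctions",
    "simulate_survival",
    "simulate_combos",
    "write_simulation",
]

_COMPONENT_STREAMS = {"counts": 1, "junctions": 2, "survival": 3, "combos": 4}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([seed, _COMPONENT_STREAMS[component]])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB2 counts with var = mu + dispersion * mu^2 (Poisson if ~0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


@dataclass
class JunctionSimConfig:
    """Splice-junction table generator settings.

    ``depth`` is the expected total unique spliced reads per sample;
    the focal junction carries ``focal_control_fraction`` of them in
    control samples and is ``depletion_factor`` times lower under
    treatment. Focal counts are NB with the given dispersion; background
    junction abundances are log-normal with Poisson sampling noise.
    """

    n_background: int = 2000
    depth: float = 5e6
    focal_control_fraction: float = 1e-4  # ~500 focal reads at 5e6 depth
    depletion_factor: float = 10.0
    dispersion: float = 0.05
    depth_jitter_sd: float = 0.1  # log-normal sd of per-sample depth


@dataclass
class SurvivalSimConfig:
    """Survival cohort generator settings (exponential PH model)."""

    n_patients: int = 300
    baseline_hazard: float = 0.1
    signature_log_hr: float = float(np.log(3.0))  # per SD of latent score
    censoring_rate: float = 0.3
    n_background_genes: int = 200
    gene_loading: float = 1.0
    gene_noise_sd: float = 0.5


@dataclass
class ComboSimConfig:
    """Fractional-response generator settings."""

    n_combos: int = 100
    fa_range: tuple[float, float] = (0.2, 0.8)
    fb_range: tuple[float, float] = (0.2, 0.8)
    interaction: float = 0.1
    noise_sd: float = 0.05
    mode: str = "literal"


@dataclass
class SimulationConfig:
    """Root configuration; the seed fully determines every output."""

    seed: int = 0
    n_genes: int = 10_000
    samples_per_group: int = 3
    nb_dispersion: float = 0.1
    baseline_log_mean: float = 4.0  # natural-log scale of log-normal means
    baseline_log_sd: float = 1.5
    de_fraction: float = 0.1
    lfc_sd: float = 1.0
    shared_down_fraction: float = 0.3  # of DE genes, down in BOTH contrasts
    set_shift_map: dict[str, float] = field(default_factory=dict)
    set_size: int = 200
    n_null_sets: int = 10
    depth_jitter_sd: float = 0.1
    junction: JunctionSimConfig = field(default_factory=JunctionSimConfig)
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    combo: ComboSimConfig = field(default_factory=ComboSimConfig)

    def __post_init__(self) -> None:
        # allow plain dicts (e.g. from YAML) for the nested configs
        if isinstance(self.junction, dict):
            self.junction = JunctionSimConfig(**self.junction)
        if isinstance(self.survival, dict):
            self.survival = SurvivalSimConfig(**self.survival)
        if isinstance(self.combo, dict):
            if isinstance(self.combo.get("fa_range"), list):
                self.combo["fa_range"] = tuple(self.combo["fa_range"])
            if isinstance(self.combo.get("fb_range"), list):
                self.combo["fb_range"] = tuple(self.combo["fb_range"])
            self.combo = ComboSimConfig(**self.combo)
        for name in ("de_fraction", "shared_down_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if not 0.0 <= self.survival.censoring_rate < 1.0:
            raise ValidationError("censoring rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# counts


def _one_contrast(
    rng: np.random.Generator,
    genes: list[str],
    baseline: np.ndarray,
    lfc: np.ndarray,
    groups: tuple[str, str],
    n_per_group: int,
    dispersion: float,
    depth_jitter_sd: float,
) -> CountMatrix:
    ref, trt = groups
    samples = [f"{ref}_{i + 1}" for i in range(n_per_group)] + [
        f"{trt}_{i + 1}" for i in range(n_per_group)
    ]
    design = pd.Series([ref] * n_per_group + [trt] * n_per_group, index=samples)
    depth = np.exp(rng.normal(0.0, depth_jitter_sd, size=len(samples)))
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        fold = np.exp2(lfc) if design[s] == trt else 1.0
        mu = baseline * fold * depth[j]
        counts[:, j] = _nb_draw(rng, mu, dispersion)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), design=design
    )


def simulate_counts(cfg: SimulationConfig) -> dict:
    """Two-contrast NB count matrices with a shared down-regulated core.

    Returns a dict with keys ``contrast1`` (siXBP1 vs siCtrl),
    ``contrast2`` (MKC8866 vs vehicle), ``truth`` (per-gene generating
    parameters) and ``gene_sets`` (shifted sets from ``set_shift_map``
    plus null sets, as a hallmark-style collection).
    """
    rng = _rng(cfg.seed, "counts")
    G = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(G)]
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=G))

    n_de = int(round(cfg.de_fraction * G))
    n_shared = int(round(cfg.shared_down_fraction * n_de))
    de_genes = rng.choice(G, size=n_de, replace=False)
    shared = de_genes[:n_shared]
    rest = de_genes[n_shared:]
    only1 = rest[: len(rest) // 2]
    only2 = rest[len(rest) // 2 :]

    lfc1 = np.zeros(G)
    lfc2 = np.zeros(G)
    # shared core: clearly down in both contrasts
    lfc1[shared] = -np.abs(rng.normal(1.0, 0.5, size=n_shared))
    lfc2[shared] = -np.abs(rng.normal(1.0, 0.5, size=n_shared))
    for idx, lfc in ((only1, lfc1), (only2, lfc2)):
        draw = rng.normal(0.0, cfg.lfc_sd, size=len(idx))
        draw = np.where(np.abs(draw) < 0.25, np.sign(draw + 1e-12) * 0.25, draw)
        lfc[idx] = draw

    # gene sets: shifted sets get an extra mean lfc shift in both contrasts
    sets: dict[str, tuple[str, list[str]]] = {}
    membership: dict[str, list[str]] = {}
    for set_name, shift in cfg.set_shift_map.items():
        members = rng.choice(G, size=min(cfg.set_size, G), replace=False)
        lfc1[members] += shift
        lfc2[members] += shift
        sets[set_name] = ("shifted synthetic set", [genes[i] for i in members])
        membership[set_name] = [genes[i] for i in members]
    for k in range(cfg.n_null_sets):
        members = rng.choice(G, size=min(cfg.set_size, G), replace=False)
        sets[f"NULL_SET_{k + 1:02d}"] = (
            "unshifted synthetic set",
            [genes[i] for i in members],
        )

    c1 = _one_contrast(
        rng, genes, baseline, lfc1, ("siCtrl", "siXBP1"),
        cfg.samples_per_group, cfg.nb_dispersion, cfg.depth_jitter_sd,
    )
    c2 = _one_contrast(
        rng, genes, baseline, lfc2, ("vehicle", "MKC8866"),
        cfg.samples_per_group, cfg.nb_dispersion, cfg.depth_jitter_sd,
    )

    is_de1 = np.zeros(G, dtype=bool)
    is_de2 = np.zeros(G, dtype=bool)
    is_de1[np.concatenate([shared, only1])] = True
    is_de2[np.concatenate([shared, only2])] = True
    shared_mask = np.zeros(G, dtype=bool)
    shared_mask[shared] = True
    truth = pd.DataFrame(
        {
            "gene": genes,
            "baseline_mean": baseline,
            "lfc_contrast1": lfc1,
            "lfc_contrast2": lfc2,
            "is_de_contrast1": is_de1,
            "is_de_contrast2": is_de2,
            "shared_down": shared_mask,
        }
    )
    gene_sets = GeneSetCollection(sets=sets) if sets else None
    return {"contrast1": c1, "contrast2": c2, "truth": truth, "gene_sets": gene_sets}


# ---------------------------------------------------------------------------
# junctions


def simulate_junctions(cfg: SimulationConfig) -> dict:
    """Per-sample junction tables with a treatment-depleted focal junction.

    Background junctions have log-normal abundances with Poisson sampling
    noise; the focal junction (default chr22:28,796,122-28,796,147, '+')
    is NB-distributed with mean depleted ``depletion_factor``-fold in
    treated samples. Returns ``tables`` (sample -> JunctionTable),
    ``design`` and ``truth``.
    """
    jc = cfg.junction
    rng = _rng(cfg.seed, "junctions")
    chrom_pool = [f"chr{i}" for i in range(1, 23)]
    keys: set[tuple] = set()
    backgrounds: list[tuple[str, int, int, int]] = []
    while len(backgrounds) < jc.n_background:
        chrom = chrom_pool[rng.integers(len(chrom_pool))]
        start = int(rng.integers(10_000, 200_000_000))
        end = start + int(rng.integers(60, 5000))
        strand = int(rng.integers(1, 3))
        key = (chrom, start, end, strand)
        if key in keys or key[:3] == DEFAULT_FOCAL[:3]:
            continue
        keys.add(key)
        backgrounds.append(key)
    backgrounds.sort()
    weights = np.exp(rng.normal(0.0, 1.0, size=jc.n_background))
    weights /= weights.sum()

    n = cfg.samples_per_group
    samples = [f"vehicle_{i + 1}" for i in range(n)] + [
        f"MKC8866_{i + 1}" for i in range(n)
    ]
    design = pd.Series(["vehicle"] * n + ["MKC8866"] * n, index=samples)
    focal_mean_ctrl = jc.depth * jc.focal_control_fraction
    if focal_mean_ctrl < 1:
        import logging

        logging.getLogger("xbp1flux").warning(
            "depth too low for integer focal counts (mean %.2f)", focal_mean_ctrl
        )
    tables: dict[str, JunctionTable] = {}
    focal_truth = {}
    for s in samples:
        depth_factor = float(np.exp(rng.normal(0.0, jc.depth_jitter_sd)))
        treated = design[s] == "MKC8866"
        focal_mu = focal_mean_ctrl * depth_factor / (
            jc.depletion_factor if treated else 1.0
        )
        focal_count = int(_nb_draw(rng, np.array([focal_mu]), jc.dispersion)[0])
        bg_mu = weights * (jc.depth - focal_mean_ctrl) * depth_factor
        bg_counts = rng.poisson(bg_mu)
        records = []
        focal_chrom, focal_start, focal_end, focal_strand = DEFAULT_FOCAL
        inserted = False
        for (chrom, start, end, strand), c in zip(backgrounds, bg_counts):
            if not inserted and (chrom, start, end) > (
                focal_chrom, focal_start, focal_end
            ):
                records.append(
                    JunctionRecord(
                        chrom=focal_chrom, intron_start=focal_start,
                        intron_end=focal_end, strand=focal_strand, motif_code=1,
                        annotated=1, unique_reads=focal_count, multi_reads=0,
                        max_overhang=50,
                    )
                )
                inserted = True
            records.append(
                JunctionRecord(
                    chrom=chrom, intron_start=start, intron_end=end, strand=strand,
                    motif_code=1, annotated=1, unique_reads=int(c), multi_reads=0,
                    max_overhang=50,
                )
            )
        if not inserted:
            records.append(
                JunctionRecord(
                    chrom=focal_chrom, intron_start=focal_start,
                    intron_end=focal_end, strand=focal_strand, motif_code=1,
                    annotated=1, unique_reads=focal_count, multi_reads=0,
                    max_overhang=50,
                )
            )
        tables[s] = JunctionTable(sample_id=s, records=records)
        focal_truth[s] = {"focal_mean": focal_mu, "focal_count": focal_count}
    truth = {
        "depletion_factor": jc.depletion_factor,
        "expected_group_coefficient": -float(np.log(jc.depletion_factor)),
        "focal_key": DEFAULT_FOCAL,
        "per_sample": focal_truth,
    }
    return {"tables": tables, "design": design, "truth": truth}


# ---------------------------------------------------------------------------
# survival


def simulate_survival(cfg: SimulationConfig, signature_genes: list[str]) -> dict:
    """Exponential proportional-hazards cohort driven by a latent score.

    Signature genes load on a standard-normal latent activity z with
    independent Gaussian noise; event times are exponential with hazard
    ``baseline_hazard * exp(signature_log_hr * z)`` and censoring is an
    independent exponential calibrated to the configured marginal rate.
    """
    sc = cfg.survival
    rng = _rng(cfg.seed, "survival")
    n = sc.n_patients
    samples = [f"P{i:04d}" for i in range(n)]
    z = rng.normal(0.0, 1.0, size=n)

    sig = list(dict.fromkeys(signature_genes))
    expr_rows = {g: sc.gene_loading * z + rng.normal(0.0, sc.gene_noise_sd, n)
                 for g in sig}
    for k in range(sc.n_background_genes):
        expr_rows[f"BG{k:04d}"] = rng.normal(0.0, 1.0, size=n)
    expression = pd.DataFrame(expr_rows, index=samples).T

    hazard = sc.baseline_hazard * np.exp(sc.signature_log_hr * z)
    event_time = rng.exponential(1.0 / hazard)
    if sc.censoring_rate > 0:
        cens_rate = sc.baseline_hazard * sc.censoring_rate / (1.0 - sc.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    cohort = SurvivalCohort(
        sample_ids=samples, time=time, event=event, expression=expression
    )
    truth = {
        "latent_score": pd.Series(z, index=samples),
        "signature_log_hr": sc.signature_log_hr,
        "censoring_fraction": float(1 - event.mean()),
    }
    return {"cohort": cohort, "truth": truth}


# ---------------------------------------------------------------------------
# drug combinations


def simulate_combos(cfg: SimulationConfig) -> pd.DataFrame:
    """Fractional-response triplets with a known interaction offset.

    Fc = reference(mode) + interaction + Gaussian noise, clipped to
    [0, 1]; the truth column records whether the generating interaction
    is positive.
    """
    from .synergy import expected_combination

    cc = cfg.combo
    rng = _rng(cfg.seed, "combos")
    fa = rng.uniform(*cc.fa_range, size=cc.n_combos)
    fb = rng.uniform(*cc.fb_range, size=cc.n_combos)
    noise = rng.normal(0.0, cc.noise_sd, size=cc.n_combos) if cc.noise_sd > 0 else 0.0
    base = np.array([expected_combination(a, b, mode=cc.mode) for a, b in zip(fa, fb)])
    fc = np.clip(base + cc.interaction + noise, 0.0, 1.0)
    return pd.DataFrame(
        {
            "label": [f"combo_{i + 1:04d}" for i in range(cc.n_combos)],
            "fa": fa,
            "fb": fb,
            "fc": fc,
            "true_interaction": cc.interaction,
            "truth_synergistic": cc.interaction > 0,
        }
    )


# ---------------------------------------------------------------------------
# on-disk bundle


def write_simulation(
    cfg: SimulationConfig,
    out_dir: str | os.PathLike,
    signature_genes: list[str] | None = None,
) -> dict[str, str]:
    """Generate every input the pipeline consumes and write it to disk.

    Writes counts TSV + design CSV per contrast, SJ.out.tab per sample
    with a junction design CSV, a GMT collection, a survival CSV with its
    expression TSV, a combos CSV and truth tables. Returns the path map.
    """
    from .signatures_survival import FIVE_GENE_SIGNATURE

    if signature_genes is None:
        signature_genes = FIVE_GENE_SIGNATURE
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths: dict[str, str] = {}

    counts = simulate_counts(cfg)
    for label, key in (("contrast1", "contrast1"), ("contrast2", "contrast2")):
        cpath = os.path.join(out, f"counts_{label}.tsv")
        dpath = os.path.join(out, f"design_{label}.csv")
        write_counts(counts[key], cpath, dpath)
        paths[f"counts_{label}"] = cpath
        paths[f"design_{label}"] = dpath
    tpath = os.path.join(out, "truth_counts.tsv")
    counts["truth"].to_csv(tpath, sep="\t", index=False)
    paths["truth_counts"] = tpath
    if counts["gene_sets"] is not None:
        gpath = os.path.join(out, "gene_sets.gmt")
        write_gmt(counts["gene_sets"], gpath)
        paths["gene_sets"] = gpath

    junctions = simulate_junctions(cfg)
    sj_dir = os.path.join(out, "sj")
    os.makedirs(sj_dir, exist_ok=True)
    for sample, table in junctions["tables"].items():
        spath = os.path.join(sj_dir, f"{sample}.SJ.out.tab")
        write_sj_tab(table, spath)
    paths["sj_dir"] = sj_dir
    jd = os.path.join(out, "design_junctions.csv")
    pd.DataFrame(
        {"sample": junctions["design"].index, "group": junctions["design"].to_numpy()}
    ).to_csv(jd, index=False)
    paths["design_junctions"] = jd

    surv = simulate_survival(cfg, signature_genes)
    cpath = os.path.join(out, "cohort.csv")
    write_survival(surv["cohort"], cpath)
    paths["cohort"] = cpath
    epath = os.path.join(out, "cohort_expression.tsv")
    surv["cohort"].expression.to_csv(epath, sep="\t", index_label="gene")
    paths["cohort_expression"] = epath
    sigpath = os.path.join(out, "signature.txt")
    with open(sigpath, "wt") as fh:
        fh.write("\n".join(signature_genes) + "\n")
    paths["signature"] = sigpath

    combos = simulate_combos(cfg)
    cpath = os.path.join(out, "combos.csv")
    combos[["label", "fa", "fb", "fc"]].to_csv(cpath, index=False)
    paths["combos"] = cpath
    tpath = os.path.join(out, "truth_combos.csv")
    combos.to_csv(tpath, index=False)
    paths["truth_combos"] = tpath
    return paths
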