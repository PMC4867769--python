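"""Synthetic twin-methylome generator.

Emulates the statistical structure of a discordant monozygotic-twin
methylation-array study so that every downstream stage is testable without
any external data:

* probe baselines drawn from a bimodal mixture (hypomethylated /
  hypermethylated / intermediate components) on the logit scale, giving the
  canonical two-humped beta-value distribution;
* a pair-shared Gaussian effect plus individual Gaussian noise added on the
  logit scale and mapped back to [0, 1] through the logistic function, so no
  truncation artifacts occur;
* per-probe variance heterogeneity: most CpGs are tightly regulated while a
  small hypervariable fraction carries much larger individual noise.  The two
  noise tiers are calibrated jointly so that co-twins' across-probe beta
  profiles correlate at r ~ 0.98 while within-pair differences at a typical
  CpG have the small per-pair SD (~0.02-0.03 beta units) that an array study
  of 24 pairs needs to call effects of |delta beta| ~ 0.03-0.09;
* spiked within-pair effects: at a chosen set of probes the affected twin's
  logit mean is shifted so the *expected beta-scale* within-pair difference
  equals a drawn delta (sign randomized), via Gauss-Hermite mean matching;
* QC artifacts (detection P values, bead counts, optional injected sample
  failures), 65 genotype-like SNP control probes identical within a pair,
  probe annotation with sex-chromosome / cross-reactive flags and gene
  labels, covariates independent of spike status, and case-control "brain"
  cohort summaries for the replication stage.

Randomness: one global integer seed drives named streams (one per artifact),
so each artifact is reproducible independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import t as t_dist

from .core_io import (
    BetaMatrix,
    CohortSummary,
    IntensityPair,
    ProbeAnnotation,
    QcMetrics,
    TwinDesign,
)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream: independent generator per artifact under one seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def expected_beta(mu, sigma):
    """E[expit(X)] for X ~ N(mu, sigma^2), by 80-node Gauss-Hermite quadrature."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z = mu[..., None] + np.sqrt(2.0) * sigma[..., None] * _GH_NODES
    return (expit(z) * _GH_WEIGHTS).sum(axis=-1) / np.sqrt(np.pi)


def solve_logit_shift(mu: float, sigma: float, target_delta: float) -> float:
    """Logit shift s with E[expit(mu+s+e)] - E[expit(mu+e)] = target_delta.

    ``sigma`` is the SD of the total Gaussian perturbation e.  Raises if the
    target is unattainable from this baseline.
    """
    if target_delta == 0.0:
        return 0.0
    base = float(expected_beta(mu, sigma))
    if not (0.0 < base + target_delta < 1.0):
        raise ValueError(f"delta {target_delta} unattainable from baseline mean {base:.3f}")
    f = lambda s: float(expected_beta(mu + s, sigma)) - base - target_delta
    return brentq(f, -30.0, 30.0, xtol=1e-12)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic twin study.

    Cohort sizes default to the study design being emulated: 24 discordant +
    20 concordant pairs at age 10, 18 discordant pairs re-profiled at age 5.
    ``spike_delta_range`` is the |delta beta| interval of the planted
    within-pair effects.  ``sigma_pair`` / ``sigma_noise`` are logit-scale
    SDs of the pair-shared effect and the individual noise at a typical CpG;
    a ``hypervariable_fraction`` of probes has its noise inflated by
    ``hypervariable_scale``.  ``persistence`` is the fraction of the age-10
    spike already present at age 5 (0 = effect absent at age 5).
    """

    n_discordant_pairs: int = 24
    n_concordant_pairs: int = 20
    n_pairs_age5: int = 18
    n_probes: int = 20000
    n_spiked: int = 20
    spike_delta_range: tuple[float, float] = (0.02, 0.09)
    sigma_pair: float = 0.12
    sigma_noise: float = 0.12
    hypervariable_fraction: float = 0.10
    hypervariable_scale: float = 9.25
    persistence: float = 0.0
    qc_fail_samples: int = 0
    qc_fail_fraction: float = 0.08
    n_snp_controls: int = 65
    mixture_weights: tuple[float, float, float] = (0.35, 0.45, 0.20)
    mixture_centers: tuple[float, float, float] = (0.10, 0.90, 0.50)
    mixture_logit_sd: tuple[float, float, float] = (0.55, 0.55, 0.80)
    n_genes: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_discordant_pairs", "n_concordant_pairs", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_pairs_age5 <= self.n_discordant_pairs:
            raise ValueError("n_pairs_age5 must be in [0, n_discordant_pairs]")
        if self.n_spiked > self.n_probes:
            raise ValueError("n_spiked exceeds n_probes")
        lo, hi = self.spike_delta_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("spike_delta_range must lie inside (0, 0.5)")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must be in [0, 1]")
        if not 0.0 <= self.hypervariable_fraction <= 1.0:
            raise ValueError("hypervariable_fraction must be in [0, 1]")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass
class SimulatedTwinStudy:
    """Bundle returned by :func:`simulate_twin_methylome`."""

    beta_age10: BetaMatrix
    beta_age5: BetaMatrix
    design: TwinDesign
    annotation: ProbeAnnotation
    qc_age10: QcMetrics
    qc_age5: QcMetrics
    truth: pd.DataFrame  # probe_id-indexed: spiked, delta, sign, logit_shift
    config: SimulationConfig

    @property
    def analysis_probe_ids(self) -> list[str]:
        frame = self.annotation.frame
        return list(frame.index[~frame["snp_control"]])

    @property
    def snp_control_probe_ids(self) -> list[str]:
        frame = self.annotation.frame
        return list(frame.index[frame["snp_control"]])


def _draw_baselines(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_probes
    comp = rng.choice(3, size=n, p=np.asarray(config.mixture_weights))
    centers = logit(np.asarray(config.mixture_centers))
    sds = np.asarray(config.mixture_logit_sd)
    mu = centers[comp] + sds[comp] * rng.standard_normal(n)
    return mu, comp


def simulate_twin_methylome(config: SimulationConfig) -> SimulatedTwinStudy:
    """Generate the full twin-study input bundle for one seed.

    Deterministic under a fixed ``config.seed``; every artifact is drawn from
    its own named stream.
    """
    cfg = config
    seed = cfg.seed

    probe_ids = np.array([f"cg{i:08d}" for i in range(cfg.n_probes)])
    snp_ids = np.array([f"rs{i:06d}" for i in range(cfg.n_snp_controls)])

    # --- probe baselines, noise tiers, spikes -----------------------------
    rng_base = stream(seed, "baseline")
    mu, comp = _draw_baselines(cfg, rng_base)

    rng_spike = stream(seed, "spikes")
    hyper = stream(seed, "noise-tier").random(cfg.n_probes) < cfg.hypervariable_fraction
    spiked_idx = rng_spike.choice(cfg.n_probes, size=cfg.n_spiked, replace=False)
    spiked_mask = np.zeros(cfg.n_probes, dtype=bool)
    spiked_mask[spiked_idx] = True
    # spiked probes sit at typical (non-hypervariable) intermediate CpGs;
    # re-draw their baselines from the intermediate component so the target
    # delta is attainable without saturation
    hyper[spiked_mask] = False
    inter_center = logit(cfg.mixture_centers[2])
    for j in spiked_idx:
        draw = inter_center + cfg.mixture_logit_sd[2] * rng_spike.standard_normal()
        while abs(draw) > 1.4:  # keep expected beta comfortably inside (0.2, 0.8)
            draw = inter_center + cfg.mixture_logit_sd[2] * rng_spike.standard_normal()
        mu[j] = draw

    noise_sd = np.where(hyper, cfg.sigma_noise * cfg.hypervariable_scale, cfg.sigma_noise)

    deltas = rng_spike.uniform(*cfg.spike_delta_range, size=cfg.n_spiked)
    signs = rng_spike.choice([-1.0, 1.0], size=cfg.n_spiked)
    sigma_tot = np.sqrt(cfg.sigma_pair**2 + cfg.sigma_noise**2)
    shifts = np.zeros(cfg.n_probes)
    for j, delta, sign in zip(spiked_idx, deltas, signs):
        shifts[j] = solve_logit_shift(mu[j], sigma_tot, sign * delta)

    truth = pd.DataFrame(
        {
            "spiked": spiked_mask,
            "delta": np.where(spiked_mask, 0.0, np.nan),
            "sign": np.where(spiked_mask, 0.0, np.nan),
            "logit_shift": shifts,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth.loc[probe_ids[spiked_idx], "delta"] = signs * deltas
    truth.loc[probe_ids[spiked_idx], "sign"] = signs

    # --- sample layout ----------------------------------------------------
    disc_pairs = [f"D{i + 1:02d}" for i in range(cfg.n_discordant_pairs)]
    conc_pairs = [f"C{i + 1:02d}" for i in range(cfg.n_concordant_pairs)]
    rows = []
    for pair in disc_pairs:
        rows.append((f"{pair}A", pair, "affected", "discordant"))
        rows.append((f"{pair}U", pair, "unaffected", "discordant"))
    for pair in conc_pairs:
        rows.append((f"{pair}T1", pair, "twin1", "concordant"))
        rows.append((f"{pair}T2", pair, "twin2", "concordant"))
    layout = pd.DataFrame(rows, columns=["sample_id", "pair_id", "role", "group"])

    age5_pairs = set(disc_pairs[: cfg.n_pairs_age5])
    design_rows = [layout.assign(age_wave=10)]
    layout5 = layout[layout["pair_id"].isin(age5_pairs)]
    if len(layout5):
        design_rows.append(layout5.assign(age_wave=5))
    design_frame = pd.concat(design_rows, ignore_index=True)

    # covariates: per individual, independent of spike status
    rng_cov = stream(seed, "covariates")
    covs = pd.DataFrame(
        {
            "sample_id": layout["sample_id"],
            "internalizing": rng_cov.standard_normal(len(layout)),
            "externalizing": rng_cov.standard_normal(len(layout)),
            "depression": (rng_cov.random(len(layout)) < 0.10).astype(float),
        }
    )
    design_frame = design_frame.merge(covs, on="sample_id", how="left")
    design = TwinDesign(design_frame)

    # --- beta values per wave ---------------------------------------------
    def draw_wave(pairs_layout: pd.DataFrame, rng: np.random.Generator, shift_scale: float):
        pair_ids = list(dict.fromkeys(pairs_layout["pair_id"]))
        n_pairs = len(pair_ids)
        a = cfg.sigma_pair * rng.standard_normal((cfg.n_probes, n_pairs))
        values = {}
        wave_shift = shifts * shift_scale
        for k, pair in enumerate(pair_ids):
            members = pairs_layout[pairs_layout["pair_id"] == pair]
            for _, member in members.iterrows():
                e = noise_sd * rng.standard_normal(cfg.n_probes)
                lv = mu + a[:, k] + e
                if member["role"] == "affected":
                    lv = lv + wave_shift
                values[member["sample_id"]] = expit(lv)
        return pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"))

    beta10 = draw_wave(layout, stream(seed, "beta-age10"), 1.0)

    if cfg.persistence > 0:
        # attenuated age-5 effect: re-solve so the expected age-5 delta is
        # persistence * delta on the beta scale
        shifts5 = np.zeros(cfg.n_probes)
        for j, delta, sign in zip(spiked_idx, deltas, signs):
            shifts5[j] = solve_logit_shift(mu[j], sigma_tot, cfg.persistence * sign * delta)
        saved = shifts.copy()
        shifts[:] = shifts5
        beta5 = draw_wave(layout5, stream(seed, "beta-age5"), 1.0)
        shifts[:] = saved
    else:
        beta5 = draw_wave(layout5, stream(seed, "beta-age5"), 0.0)

    # --- SNP control probes: genotype-like, identical within a pair --------
    rng_snp = stream(seed, "snp-controls")
    all_pairs = disc_pairs + conc_pairs
    geno_levels = np.array([0.05, 0.50, 0.95])
    genotype = rng_snp.choice(3, size=(cfg.n_snp_controls, len(all_pairs)), p=[0.25, 0.5, 0.25])
    pair_index = {p: k for k, p in enumerate(all_pairs)}

    def snp_block(pairs_layout: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        values = {}
        for _, member in pairs_layout.iterrows():
            g = genotype[:, pair_index[member["pair_id"]]]
            vals = geno_levels[g] + 0.01 * rng.standard_normal(cfg.n_snp_controls)
            values[member["sample_id"]] = np.clip(vals, 0.0, 1.0)
        return pd.DataFrame(values, index=pd.Index(snp_ids, name="probe_id"))

    snp10 = snp_block(layout, rng_snp)
    snp5 = snp_block(layout5, rng_snp)

    beta10 = pd.concat([beta10, snp10])
    beta5 = pd.concat([beta5, snp5])

    # --- annotation --------------------------------------------------------
    rng_ann = stream(seed, "annotation")
    chroms = rng_ann.choice([str(c) for c in range(1, 23)], size=cfg.n_probes)
    sex = rng_ann.random(cfg.n_probes)
    chroms = np.where(sex < 0.02, "X", chroms)
    chroms = np.where((sex >= 0.02) & (sex < 0.025), "Y", chroms)
    cross = rng_ann.random(cfg.n_probes) < 0.01
    # planted effects live on clean autosomal probes
    chroms[spiked_mask & np.isin(chroms, ["X", "Y"])] = "7"
    cross[spiked_mask] = False
    design_type = np.where(rng_ann.random(cfg.n_probes) < 0.28, "I", "II")
    positions = rng_ann.integers(10_000, 240_000_000, size=cfg.n_probes)

    gene_names = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    gene_weights = rng_ann.lognormal(0.0, 1.0, size=cfg.n_genes)
    gene_weights /= gene_weights.sum()
    n_genes_per_probe = rng_ann.choice([0, 1, 2], size=cfg.n_probes, p=[0.25, 0.70, 0.05])
    gene_labels: list[list[str]] = []
    for count in n_genes_per_probe:
        if count == 0:
            gene_labels.append([])
        else:
            picks = rng_ann.choice(cfg.n_genes, size=count, replace=False, p=gene_weights)
            gene_labels.append(sorted(gene_names[picks]))

    ann_frame = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "design_type": design_type,
            "gene_labels": gene_labels,
            "cross_reactive": cross,
            "snp_control": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    snp_frame = pd.DataFrame(
        {
            "chromosome": rng_ann.choice([str(c) for c in range(1, 23)], size=cfg.n_snp_controls),
            "position": rng_ann.integers(10_000, 240_000_000, size=cfg.n_snp_controls),
            "design_type": "I",
            "gene_labels": [[] for _ in range(cfg.n_snp_controls)],
            "cross_reactive": False,
            "snp_control": True,
        },
        index=pd.Index(snp_ids, name="probe_id"),
    )
    annotation = ProbeAnnotation(pd.concat([ann_frame, snp_frame]))

    # --- QC metrics ---------------------------------------------------------
    def qc_block(columns: Sequence[str], rng: np.random.Generator) -> QcMetrics:
        shape = (len(beta10.index), len(columns))
        detp = rng.uniform(0.0, 0.01, size=shape)
        sporadic = rng.random(shape) < 0.005
        detp[sporadic] = rng.uniform(0.05, 1.0, size=int(sporadic.sum()))
        beads = 3 + rng.poisson(11.0, size=shape)
        low = rng.random(shape) < 0.002
        beads[low] = rng.integers(0, 3, size=int(low.sum()))
        index = beta10.index
        return QcMetrics(
            pd.DataFrame(detp, index=index, columns=list(columns)),
            pd.DataFrame(beads, index=index, columns=list(columns)),
        )

    qc10 = qc_block(beta10.columns, stream(seed, "qc-age10"))
    qc5 = qc_block(beta5.columns, stream(seed, "qc-age5"))

    study = SimulatedTwinStudy(
        beta_age10=BetaMatrix(beta10),
        beta_age5=BetaMatrix(beta5),
        design=design,
        annotation=annotation,
        qc_age10=qc10,
        qc_age5=qc5,
        truth=truth,
        config=cfg,
    )
    if cfg.qc_fail_samples > 0:
        qc10_failed, failed = inject_qc_failures(qc10, cfg)
        study.qc_age10 = qc10_failed
        study.truth.attrs["qc_failed_samples"] = failed
    return study


def inject_qc_failures(
    metrics: QcMetrics, config: SimulationConfig
) -> tuple[QcMetrics, list[str]]:
    """Give ``config.qc_fail_samples`` samples a failing detection-P profile.

    Each chosen sample gets ``qc_fail_fraction`` (> the 5% filter rule) of its
    probes set to detection P >= 0.05.  Returns the new metrics and the list
    of injected sample ids (the truth for filter tests).
    """
    n_samples = len(metrics.detection_p.columns)
    if config.qc_fail_samples > n_samples:
        raise ValueError("qc_fail_samples exceeds the number of samples")
    if config.qc_fail_samples == 0:
        return metrics, []
    rng = stream(config.seed, "qc-failures")
    cols = rng.choice(n_samples, size=config.qc_fail_samples, replace=False)
    detp = metrics.detection_p.copy()
    n_probes = len(detp.index)
    n_fail = int(np.ceil(config.qc_fail_fraction * n_probes))
    failed = []
    for col in cols:
        rows = rng.choice(n_probes, size=n_fail, replace=False)
        detp.iloc[rows, col] = rng.uniform(0.05, 1.0, size=n_fail)
        failed.append(detp.columns[col])
    return QcMetrics(detp, metrics.bead_count.copy()), failed


def simulate_intensities(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    seed: int,
    mean_total: float = 5000.0,
    type_i_background: float = 600.0,
) -> IntensityPair:
    """Invert beta values into plausible M/U fluorescence intensities.

    Total intensity is lognormal per probe/sample with a per-sample scale
    factor (so between-sample quantile normalization has real work to do) and
    type I probes carry an additive background offset (so the background
    equalization step has real work to do).
    """
    rng = stream(seed, "intensities")
    values = beta.values.to_numpy()
    shape = values.shape
    sample_scale = rng.lognormal(0.0, 0.10, size=shape[1])
    total = rng.lognormal(np.log(mean_total), 0.15, size=shape) * sample_scale
    meth = values * total
    unmeth = (1.0 - values) * total
    type_i = (annotation.frame.loc[beta.values.index, "design_type"] == "I").to_numpy()
    meth[type_i, :] += type_i_background
    unmeth[type_i, :] += type_i_background
    index = beta.values.index
    cols = beta.values.columns
    return IntensityPair(
        pd.DataFrame(meth, index=index, columns=cols),
        pd.DataFrame(unmeth, index=index, columns=cols),
    )


def simulate_brain_cohorts(
    probe_ids: Sequence[str],
    effect_probe: str,
    effect_size: float,
    cohort_shapes: Sequence[tuple[int, int]] = ((20, 23), (18, 15)),
    seed: int = 0,
    cohort_ids: Sequence[str] | None = None,
    baseline: Mapping[str, float] | None = None,
    noise_sd: float = 0.04,
) -> dict[str, list[CohortSummary]]:
    """Per-probe case-control group summaries for replication cohorts.

    Cases are shifted by ``effect_size`` (case minus control, beta units) at
    ``effect_probe`` and unshifted elsewhere.  Individual values are drawn
    normal around the probe baseline with SD ``noise_sd`` and summarized into
    group means/SDs, so meta-analysis of summaries matches meta-analysis of
    the underlying per-sample data.
    """
    probe_ids = list(probe_ids)
    if effect_probe not in probe_ids:
        raise ValueError(f"effect probe {effect_probe!r} not among probe_ids")
    for n_case, n_control in cohort_shapes:
        if n_case < 2 or n_control < 2:
            raise ValueError("cohort groups need n >= 2")
    if cohort_ids is None:
        cohort_ids = [f"cohort{k + 1}" for k in range(len(cohort_shapes))]
    rng = stream(seed, "brain-cohorts")
    if baseline is None:
        baseline = dict(zip(probe_ids, rng.uniform(0.25, 0.75, size=len(probe_ids))))
    out: dict[str, list[CohortSummary]] = {p: [] for p in probe_ids}
    for cohort_id, (n_case, n_control) in zip(cohort_ids, cohort_shapes):
        for probe in probe_ids:
            mu = baseline[probe]
            shift = effect_size if probe == effect_probe else 0.0
            cases = np.clip(rng.normal(mu + shift, noise_sd, size=n_case), 0.0, 1.0)
            controls = np.clip(rng.normal(mu, noise_sd, size=n_control), 0.0, 1.0)
            out[probe].append(
                CohortSummary(
                    cohort_id=cohort_id,
                    n_case=n_case,
                    n_control=n_control,
                    mean_case=float(cases.mean()),
                    mean_control=float(controls.mean()),
                    sd_case=float(cases.std(ddof=1)),
                    sd_control=float(controls.std(ddof=1)),
                )
            )
    return out


def simulate_gene_sets(
    annotation: ProbeAnnotation,
    n_sets: int = 50,
    size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene categories drawn from the annotated gene universe.

    Stands in for an ontology file so the enrichment stage can run without a
    database; sets are drawn uniformly, so they carry no real signal beyond
    the probe-count bias the weighting function corrects.
    """
    genes = sorted({g for labels in annotation.frame["gene_labels"] for g in labels})
    if len(genes) < size_range[1]:
        size_range = (min(size_range[0], max(2, len(genes) // 5)), max(2, len(genes) // 2))
    rng = stream(seed, "gene-sets")
    sets: dict[str, set[str]] = {}
    for k in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SET{k:04d}"] = {genes[i] for i in members}
    return sets


@dataclass
class PowerEstimate:
    power: float
    standard_error: float
    n_sim: int
    alpha: float


def power_estimate(
    n_pairs: int,
    delta: float,
    config: SimulationConfig | None = None,
    alpha: float = 5e-5,
    n_sim: int = 1000,
    seed: int = 0,
) -> PowerEstimate:
    """Monte-Carlo power of the within-pair paired t-test at one spiked probe.

    Simulates a typical (intermediate, non-hypervariable) CpG under the
    generator's noise model and counts the fraction of replicates whose
    two-sided paired-test P falls below ``alpha``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    cfg = config or SimulationConfig()
    rng = stream(seed, "power")
    mu = 0.0  # intermediate CpG
    sigma_tot = np.sqrt(cfg.sigma_pair**2 + cfg.sigma_noise**2)
    shift = solve_logit_shift(mu, sigma_tot, delta)
    a = cfg.sigma_pair * rng.standard_normal((n_sim, n_pairs))
    e1 = cfg.sigma_noise * rng.standard_normal((n_sim, n_pairs))
    e2 = cfg.sigma_noise * rng.standard_normal((n_sim, n_pairs))
    d = expit(mu + a + shift + e1) - expit(mu + a + e2)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    t = mean / (sd / np.sqrt(n_pairs))
    p = 2.0 * t_dist.sf(np.abs(t), df=n_pairs - 1)
    power = float(np.mean(p < alpha))
    se = float(np.sqrt(power * (1.0 - power) / n_sim))
    return PowerEstimate(power=power, standard_error=se, n_sim=n_sim, alpha=alpha)


def within_pair_correlation(study: SimulatedTwinStudy, group: str = "discordant") -> float:
    """Mean across pairs of the Pearson r between co-twins' beta profiles.

    Computed across all analysis probes (SNP control probes excluded) at the
    age-10 wave — the generator-calibration summary.
    """
    values = study.beta_age10.values.loc[study.analysis_probe_ids]
    pairs = study.design.wave(10).group(group).pair_table()
    rs = []
    for _, row in pairs.iterrows():
        x = values[row["first"]].to_numpy()
        y = values[row["second"]].to_numpy()
        rs.append(np.corrcoef(x, y)[0, 1])
    return float(np.mean(rs))


def calibration_summary(
    config: SimulationConfig | None = None, seeds: Sequence[int] = range(1, 11)
) -> pd.DataFrame:
    """Within-pair correlation per seed at a given calibration.

    Used to set the default variance components (the documented calibration
    targets mean r = 0.98 at defaults).
    """
    cfg = config or SimulationConfig()
    rows = []
    for seed in seeds:
        study = simulate_twin_methylome(replace(cfg, seed=int(seed)))
        rows.append({"seed": int(seed), "within_pair_r": within_pair_correlation(study)})
    return pd.DataFrame(rows)
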