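"""Sample/probe QC filters and dasen-style intensity normalization.

The filters reproduce the standard 450K pipeline rules for a twin design: a
probe-call fails for a sample when its detection P value is at or above the
threshold or its bead count is below the minimum; a sample is removed when
more than ``fail_fraction`` of its calls fail, and — because every statistic
downstream is within-pair — its co-twin is removed with it.  Cross-reactive
probes, probes on the sex chromosomes, SNP control probes and probes with
missing values are dropped from testing.  The 65 genotype-like SNP control
probes are kept aside to confirm monozygosity: a pair passes when its mean
absolute within-pair difference at those probes is small.

Normalization follows the dasen recipe in spirit: per sample, the type I
intensity distribution is shifted so its 5th percentile (a background proxy)
matches the type II 5th percentile, separately for the methylated and
unmethylated channels and floored at zero; then between-sample quantile
normalization is applied separately within each of the four strata
{M, U} x {type I, type II}, with ties resolved by averaging the tied ranks'
reference values.  Beta values are computed as M / (M + U + offset) with the
platform-standard offset of 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import (
    BetaMatrix,
    IntensityPair,
    ProbeAnnotation,
    QcMetrics,
    TwinDesign,
)


@dataclass
class FilterReport:
    """What was removed and why; retained counts for the audit trail.

    ``removed_samples`` rows: sample_id, reason ('own failure' or 'co-twin
    removal'), partner (the failing co-twin for secondary removals).
    ``removed_probes`` rows: probe_id, reason.
    """

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason", "partner"])
    )
    removed_probes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "reason"])
    )
    n_samples_retained: int = 0
    n_probes_retained: int = 0
    retained_samples: list[str] = field(default_factory=list)
    retained_probes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples.to_dict(orient="records"),
            "removed_probes": self.removed_probes.to_dict(orient="records"),
            "n_samples_retained": self.n_samples_retained,
            "n_probes_retained": self.n_probes_retained,
        }


def filter_samples(
    metrics: QcMetrics,
    design: TwinDesign,
    detection_p_threshold: float = 0.05,
    fail_fraction: float = 0.05,
    min_beads: int = 3,
    fail_on_high_detection_p: bool = True,
) -> FilterReport:
    """Remove samples with too many failing probe-calls, plus their co-twins.

    A call fails when detection P >= ``detection_p_threshold`` (the
    conventional direction; set ``fail_on_high_detection_p=False`` for the
    inverted reading) or bead count < ``min_beads``.  A sample is removed
    when its failing fraction exceeds ``fail_fraction``; each removed
    sample's co-twin is removed too, since unpaired samples carry no
    information for within-pair statistics.
    """
    samples = list(metrics.detection_p.columns)
    design_samples = set(design.frame["sample_id"])
    if not design_samples.issubset(samples):
        missing = sorted(design_samples - set(samples))
        raise ValueError(f"QC metrics missing design samples {missing[:5]}")
    detp = metrics.detection_p.to_numpy(dtype=float)
    beads = metrics.bead_count.to_numpy()
    if fail_on_high_detection_p:
        failing = detp >= detection_p_threshold
    else:
        failing = detp < detection_p_threshold
    failing |= beads < min_beads
    frac = failing.mean(axis=0)
    own_fail = {s for s, f in zip(samples, frac) if f > fail_fraction}

    co_twin = design.co_twin_map()
    rows = []
    removed = set()
    for sample in samples:
        if sample in own_fail:
            rows.append({"sample_id": sample, "reason": "own failure", "partner": ""})
            removed.add(sample)
    for sample in sorted(own_fail):
        partner = co_twin.get(sample)
        if partner is not None and partner not in removed:
            rows.append({"sample_id": partner, "reason": "co-twin removal", "partner": sample})
            removed.add(partner)
    retained = [s for s in samples if s not in removed]
    if not retained:
        raise ValueError("all samples removed by QC filtering")
    return FilterReport(
        removed_samples=pd.DataFrame(rows, columns=["sample_id", "reason", "partner"]),
        removed_probes=pd.DataFrame(columns=["probe_id", "reason"]),
        n_samples_retained=len(retained),
        n_probes_retained=len(metrics.detection_p.index),
        retained_samples=retained,
        retained_probes=list(metrics.detection_p.index),
    )


def filter_probes(
    annotation: ProbeAnnotation,
    beta: BetaMatrix,
    drop_missing: bool = True,
) -> FilterReport:
    """Drop cross-reactive, sex-chromosome, SNP-control and incomplete probes.

    Retained probe order follows the input matrix.  SNP control probes are
    excluded from testing here; keep them separately (see
    :func:`confirm_monozygosity`) for the zygosity check.
    """
    probes = beta.probe_ids
    missing_ann = [p for p in probes if p not in annotation.frame.index]
    if missing_ann:
        raise ValueError(f"probes missing from annotation: {missing_ann[:5]}")
    ann = annotation.frame.loc[probes]
    rows = []
    removed = set()

    def mark(mask: pd.Series, reason: str) -> None:
        for probe in ann.index[mask]:
            if probe not in removed:
                rows.append({"probe_id": probe, "reason": reason})
                removed.add(probe)

    mark(ann["cross_reactive"], "cross-reactive")
    mark(ann["chromosome"].isin(["X", "Y"]), "sex chromosome")
    mark(ann["snp_control"], "snp control")
    if drop_missing:
        has_na = beta.values.isna().any(axis=1)
        mark(has_na, "missingness")
    retained = [p for p in probes if p not in removed]
    return FilterReport(
        removed_samples=pd.DataFrame(columns=["sample_id", "reason", "partner"]),
        removed_probes=pd.DataFrame(rows, columns=["probe_id", "reason"]),
        n_samples_retained=len(beta.sample_ids),
        n_probes_retained=len(retained),
        retained_samples=beta.sample_ids,
        retained_probes=retained,
    )


def confirm_monozygosity(
    snp_betas: BetaMatrix,
    design: TwinDesign,
    max_discordance: float = 0.1,
    age_wave: int | None = None,
) -> pd.DataFrame:
    """Check pairwise genotype concordance at the SNP control probes.

    A pair passes when the mean absolute within-pair beta difference at the
    SNP control probes is at most ``max_discordance`` (monozygotic twins
    share genotype, so these probes should be near-identical within a pair).
    Failing pairs are flagged, not removed.  Returns a frame indexed by
    pair_id with columns ``discordance`` and ``passed``.
    """
    if len(snp_betas.probe_ids) < 10:
        raise ValueError("need >= 10 SNP control probes for a zygosity check")
    pairs = design.pair_table(age_wave)
    available = set(snp_betas.sample_ids)
    rows = []
    for pair_id, row in pairs.iterrows():
        if row["first"] not in available or row["second"] not in available:
            raise ValueError(f"pair {pair_id!r} missing a co-twin in the SNP beta matrix")
        diff = (snp_betas.values[row["first"]] - snp_betas.values[row["second"]]).abs()
        discordance = float(diff.mean())
        rows.append(
            {
                "pair_id": pair_id,
                "discordance": discordance,
                "passed": discordance <= max_discordance,
            }
        )
    return pd.DataFrame(rows).set_index("pair_id")


def _quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization (rank-wise reference means).

    The reference distribution is the across-sample mean of the sorted
    columns; each sample's values are replaced by the reference value at
    their rank, with ties averaged.  Preserves each sample's rank order.
    """
    arr = frame.to_numpy(dtype=float)
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def dasen_normalize(
    intensities: IntensityPair,
    annotation: ProbeAnnotation,
    background_quantile: float = 0.05,
) -> IntensityPair:
    """Background-equalize type I vs type II, then quantile-normalize.

    Step 1: per sample and channel, shift type I intensities so their
    ``background_quantile`` quantile matches the type II one, flooring at 0.
    Step 2: between-sample quantile normalization within each of the four
    {M, U} x {type I, II} strata; afterwards every sample's sorted vector in
    a stratum is identical.
    """
    if len(intensities.sample_ids) < 2:
        raise ValueError("normalization needs >= 2 samples")
    ann = annotation.frame.loc[intensities.probe_ids]
    type_i = ann["design_type"] == "I"
    type_ii = ~type_i
    if type_i.sum() < 2 or type_ii.sum() < 2:
        raise ValueError("each design-type stratum needs >= 2 probes")

    out = {}
    for name, frame in (("M", intensities.methylated), ("U", intensities.unmethylated)):
        frame = frame.copy().astype(float)
        q_i = frame.loc[type_i.to_numpy()].quantile(background_quantile)
        q_ii = frame.loc[type_ii.to_numpy()].quantile(background_quantile)
        shift = q_ii - q_i  # per-sample
        frame.loc[type_i.to_numpy()] = (frame.loc[type_i.to_numpy()] + shift).clip(lower=0.0)
        frame.loc[type_i.to_numpy()] = _quantile_normalize(frame.loc[type_i.to_numpy()])
        frame.loc[type_ii.to_numpy()] = _quantile_normalize(frame.loc[type_ii.to_numpy()])
        out[name] = frame
    return IntensityPair(out["M"], out["U"])


def compute_beta(intensities: IntensityPair, offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset), the methylation proportion in [0, 1)."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    meth = intensities.methylated.to_numpy(dtype=float)
    unmeth = intensities.unmethylated.to_numpy(dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("negative intensities")
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, meth / denom, 0.0)
    return BetaMatrix(
        pd.DataFrame(beta, index=intensities.methylated.index, columns=intensities.methylated.columns)
    )
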