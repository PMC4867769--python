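"""Concordant-twin specificity analysis and longitudinal delta-beta contrast.

Specificity: within-pair differences at candidate probes should be a feature
of symptom-discordant pairs, not of monozygotic twinning per se.  Concordant
unaffected pairs have no meaningful twin ordering, so each permutation
randomly labels the members Twin1/Twin2, the signed within-pair difference
``beta_1 - beta_2`` is computed per pair and averaged across permutations.
The signed permutation average is ~0 by symmetry, so the orientation-free
absolute variant (the permutation average of |delta-beta|, which equals the
pair's |beta_1 - beta_2| because the magnitude is labeling-invariant) is the
default unit of comparison.  Per probe, a Welch two-sample t-test compares
the discordant pairs' per-pair values against the concordant pairs'
permutation-averaged values — per-pair values in both groups, avoiding
pseudo-replication across permutations.

Longitudinal contrast: per individual the change ``beta_age10 - beta_age5``
(longitudinal delta-beta) is computed, then per pair the difference between
the affected twin's change and the unaffected co-twin's change; a one-sample
t-test on those per-pair contrasts (algebraically the paired t-test) asks
whether methylation *trajectories* diverge with the phenotype even where
cross-sectional levels do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .core_io import BetaMatrix, TwinDesign
from .dmp import PairedDeltas, _one_sample_t, paired_deltas


@dataclass
class ConcordantPermutation:
    """Permutation-averaged within-twin differences for concordant pairs.

    ``signed`` / ``absolute`` are probes x pairs frames of the per-pair
    averages over permutations; ``n_perm`` the number used (``exhaustive``
    marks full enumeration of the 2^n labelings).
    """

    signed: pd.DataFrame
    absolute: pd.DataFrame
    n_perm: int
    exhaustive: bool


def concordant_permutation(
    beta: BetaMatrix,
    design: TwinDesign,
    probe_ids: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    age_wave: int | None = None,
) -> ConcordantPermutation:
    """Randomly orient each concordant pair ``n_perm`` times and average.

    Signed differences average the random orientation ``+/-(beta_1 -
    beta_2)`` per pair; the absolute variant averages the orientation-free
    magnitude.  When 2^n_pairs <= n_perm the labelings are enumerated
    exhaustively (per-pair signed average exactly 0).
    """
    if age_wave is not None:
        design = design.wave(age_wave)
    conc = design.group("concordant")
    pairs = conc.pair_table()
    if len(pairs) < 2:
        raise ValueError("need >= 2 concordant pairs")
    values = beta.values if probe_ids is None else beta.values.loc[probe_ids]
    diff = values[pairs["first"]].to_numpy() - values[pairs["second"]].to_numpy()
    n_pairs = len(pairs)
    exhaustive = 2**n_pairs <= n_perm
    if exhaustive:
        # over all 2^n labelings every pair is oriented each way equally often
        mean_sign = np.zeros(n_pairs)
        n_used = 2**n_pairs
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_pairs))
        mean_sign = signs.mean(axis=0)
        n_used = n_perm
    index = values.index
    signed = pd.DataFrame(diff * mean_sign[None, :], index=index, columns=pairs.index)
    absolute = pd.DataFrame(np.abs(diff), index=index, columns=pairs.index)
    return ConcordantPermutation(signed=signed, absolute=absolute, n_perm=n_used, exhaustive=exhaustive)


def specificity_test(
    discordant: PairedDeltas,
    concordant: ConcordantPermutation,
    variant: str = "absolute",
) -> pd.DataFrame:
    """Welch two-sample t-test: discordant vs concordant per-pair differences.

    ``variant='absolute'`` (default) compares |within-pair delta-beta|;
    ``'signed'`` compares the signed values.  Returns per-probe group means
    and SDs (the error bars of a specificity figure), t, df, P and a
    ``degenerate`` flag where both groups have zero variance.
    """
    if variant not in {"absolute", "signed"}:
        raise ValueError("variant must be 'absolute' or 'signed'")
    d_disc = discordant.deltas
    d_conc = concordant.absolute if variant == "absolute" else concordant.signed
    common = d_disc.index.intersection(d_conc.index)
    if common.empty:
        raise ValueError("no probes shared between the two groups")
    a = d_disc.loc[common].to_numpy(dtype=float)
    if variant == "absolute":
        a = np.abs(a)
    b = d_conc.loc[common].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 pairs")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    t = np.full(len(common), np.nan)
    df = np.full(len(common), np.nan)
    p = np.full(len(common), np.nan)
    ok = ~degenerate
    t[ok] = (m1[ok] - m2[ok]) / np.sqrt(se2[ok])
    df[ok] = se2[ok] ** 2 / ((v1[ok] / n1) ** 2 / (n1 - 1) + (v2[ok] / n2) ** 2 / (n2 - 1))
    p[ok] = 2.0 * t_dist.sf(np.abs(t[ok]), df=df[ok])
    return pd.DataFrame(
        {
            "discordant_mean": m1,
            "discordant_sd": np.sqrt(v1),
            "concordant_mean": m2,
            "concordant_sd": np.sqrt(v2),
            "t_stat": t,
            "df": df,
            "p_value": p,
            "variant": variant,
            "degenerate": degenerate,
        },
        index=pd.Index(common, name="probe_id"),
    )


@dataclass
class LongitudinalDeltas:
    """Within-individual changes and their within-pair contrasts.

    ``individual`` is probes x individuals (beta_age10 - beta_age5);
    ``pair_contrast`` is probes x pairs (affected change minus unaffected
    change); ``affected_change``/``unaffected_change`` split ``individual``
    by role.
    """

    individual: pd.DataFrame
    affected_change: pd.DataFrame
    unaffected_change: pd.DataFrame

    @property
    def pair_contrast(self) -> pd.DataFrame:
        return self.affected_change - self.unaffected_change

    @property
    def pair_ids(self) -> list[str]:
        return list(self.affected_change.columns)


def longitudinal_deltas(
    beta_age5: BetaMatrix, beta_age10: BetaMatrix, design: TwinDesign
) -> LongitudinalDeltas:
    """Per-individual longitudinal change and per-pair contrast.

    Individuals are matched by sample id across waves; only probes present
    in both matrices and individuals profiled at both waves contribute.
    """
    shared_probes = beta_age10.values.index.intersection(beta_age5.values.index)
    if shared_probes.empty:
        raise ValueError("the two waves share no probes")
    shared_samples = [s for s in beta_age10.sample_ids if s in set(beta_age5.sample_ids)]
    if not shared_samples:
        raise ValueError("no individual is present in both waves")
    change = (
        beta_age10.values.loc[shared_probes, shared_samples]
        - beta_age5.values.loc[shared_probes, shared_samples]
    )
    disc = design.group("discordant")
    pairs = disc.pair_table()
    keep = pairs[
        pairs["first"].isin(shared_samples) & pairs["second"].isin(shared_samples)
    ]
    if keep.empty:
        raise ValueError("no complete discordant pair is present in both waves")
    affected = change[keep["first"]].copy()
    affected.columns = keep.index
    unaffected = change[keep["second"]].copy()
    unaffected.columns = keep.index
    return LongitudinalDeltas(
        individual=change, affected_change=affected, unaffected_change=unaffected
    )


def longitudinal_test(deltas: LongitudinalDeltas) -> pd.DataFrame:
    """Paired t-test on within-pair contrasts of longitudinal change.

    Returns per-probe mean change in each role, their difference
    (``mean_change``), t, df and two-sided P — the longitudinal results
    table.
    """
    contrast = deltas.pair_contrast.to_numpy(dtype=float)
    mean, t, df, p = _one_sample_t(contrast)
    return pd.DataFrame(
        {
            "mean_long_delta_affected": deltas.affected_change.mean(axis=1),
            "mean_long_delta_unaffected": deltas.unaffected_change.mean(axis=1),
            "mean_change": mean,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "n_pairs": np.sum(~np.isnan(contrast), axis=1),
        },
        index=deltas.pair_contrast.index,
    )


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class SpecificityModel:
    """Discordant-vs-concordant comparison of within-pair differences."""

    def __init__(
        self, beta: BetaMatrix, design: TwinDesign, probe_ids: list[str], age_wave: int = 10
    ) -> None:
        self.beta = beta
        self.design = design.wave(age_wave)
        self.probe_ids = [p for p in probe_ids if p in beta.values.index]
        if not self.probe_ids:
            raise ValueError("none of the requested probes are in the beta matrix")

    def fit(self, n_perm: int = 1000, seed: int = 0, variant: str = "absolute") -> "SpecificityResults":
        disc = paired_deltas(self.beta.subset(probes=self.probe_ids), self.design)
        conc = concordant_permutation(
            self.beta, self.design, probe_ids=self.probe_ids, n_perm=n_perm, seed=seed
        )
        table = specificity_test(disc, conc, variant=variant)
        alt = specificity_test(disc, conc, variant="signed" if variant == "absolute" else "absolute")
        return SpecificityResults(model=self, table=table, alternate_variant=alt, permutation=conc)


@dataclass
class SpecificityResults:
    model: SpecificityModel
    table: pd.DataFrame
    alternate_variant: pd.DataFrame
    permutation: ConcordantPermutation

    def summary(self) -> str:
        lines = [
            "Concordant-twin specificity analysis",
            "=" * 57,
            f"probes: {len(self.table)}   permutations: {self.permutation.n_perm}"
            + ("  (exhaustive)" if self.permutation.exhaustive else ""),
            self.table[
                ["discordant_mean", "concordant_mean", "t_stat", "p_value"]
            ].to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class LongitudinalModel:
    """Within-pair contrast of age-5 to age-10 methylation change."""

    def __init__(self, beta_age5: BetaMatrix, beta_age10: BetaMatrix, design: TwinDesign) -> None:
        self.beta_age5 = beta_age5
        self.beta_age10 = beta_age10
        self.design = design

    def fit(self, threshold: float = 5e-5) -> "LongitudinalResults":
        deltas = longitudinal_deltas(self.beta_age5, self.beta_age10, self.design)
        table = longitudinal_test(deltas)
        table = table.sort_values("p_value", kind="mergesort")
        return LongitudinalResults(
            model=self, deltas=deltas, table=table, top=table[table["p_value"] < threshold]
        )


@dataclass
class LongitudinalResults:
    model: LongitudinalModel
    deltas: LongitudinalDeltas
    table: pd.DataFrame
    top: pd.DataFrame

    def summary(self, n: int = 10) -> str:
        lines = [
            "Longitudinal delta-beta contrast (age 10 - age 5)",
            "=" * 57,
            f"pairs with both waves: {len(self.deltas.pair_ids)}   probes: {len(self.table)}",
            f"probes at P < 5e-05: {len(self.top)}",
            self.table.head(n)[
                ["mean_long_delta_affected", "mean_long_delta_unaffected", "mean_change", "p_value"]
            ].to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
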