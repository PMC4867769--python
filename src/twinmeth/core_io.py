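"""Domain containers and text-format I/O shared by every pipeline stage.

The in-memory lingua franca is the pandas DataFrame: methylation matrices are
probes x samples frames of beta values (the methylation proportion
``beta = M / (M + U + offset)`` computed from methylated/unmethylated probe
intensities), sample metadata is a tidy frame with one row per sample per age
wave, and probe annotation is a frame indexed by probe identifier.  The thin
dataclass wrappers below exist to enforce the structural invariants the
downstream statistics rely on (values in [0, 1], unique identifiers, exactly
two twins per pair per wave, one affected + one unaffected member in a
discordant pair) at construction time rather than deep inside an analysis.

On disk everything is plain delimited text (tab by default, separator
configurable), GMT for gene sets, and JSON for result records.  Writers stamp
a ``# twinmeth <version> [seed=...]`` comment line; readers skip ``#`` lines.
Missing values are encoded as ``NA``.  Probes with a missing value in any
retained sample are dropped before testing (complete-case: paired statistics
are undefined on incomplete pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__

DEFAULT_SEP = "\t"
NA_TOKEN = "NA"

ROLES = frozenset({"affected", "unaffected", "twin1", "twin2"})
GROUPS = frozenset({"discordant", "concordant"})
DESIGN_CORE_COLUMNS = ["sample_id", "pair_id", "role", "group", "age_wave"]


def tool_stamp(seed: int | None = None) -> str:
    stamp = f"# twinmeth {__version__}"
    if seed is not None:
        stamp += f" seed={seed}"
    return stamp


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation proportions in [0, 1].

    ``values`` is indexed by probe_id with sample_id columns; missing entries
    are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        if np.any(bad & ~np.isnan(arr)):
            raise ValueError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "BetaMatrix":
        frame = self.values
        if probes is not None:
            frame = frame.loc[list(probes)]
        if samples is not None:
            frame = frame[list(samples)]
        return BetaMatrix(frame.copy())


@dataclass
class IntensityPair:
    """Methylated / unmethylated fluorescence intensity matrices.

    Both frames share probe index and sample columns; intensities are
    nonnegative arbitrary fluorescence units.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index):
            raise ValueError("M and U probe axes differ")
        if not self.methylated.columns.equals(self.unmethylated.columns):
            raise ValueError("M and U sample axes differ")
        for name, frame in (("methylated", self.methylated), ("unmethylated", self.unmethylated)):
            arr = frame.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((arr < 0) & ~np.isnan(arr)):
                    raise ValueError(f"negative {name} intensities")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.methylated.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylated.columns)


@dataclass
class TwinDesign:
    """Sample sheet: pair membership, roles, age wave and covariates.

    One row per sample per age wave.  Discordant pairs carry exactly one
    ``affected`` and one ``unaffected`` member per wave; concordant pairs are
    labelled ``twin1``/``twin2``.  Any column beyond the core five is treated
    as a numeric covariate (internalizing, externalizing, depression, ...).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_CORE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design is missing columns {missing}")
        frame = self.frame.reset_index(drop=True)
        bad_roles = set(frame["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")
        bad_groups = set(frame["group"]) - GROUPS
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}")
        if frame.duplicated(["sample_id", "age_wave"]).any():
            raise ValueError("duplicate (sample_id, age_wave) rows")
        for (pair, wave), members in frame.groupby(["pair_id", "age_wave"]):
            if len(members) != 2:
                raise ValueError(
                    f"pair {pair!r} has {len(members)} samples in wave {wave} (expected 2)"
                )
            roles = sorted(members["role"])
            groups = set(members["group"])
            if len(groups) != 1:
                raise ValueError(f"pair {pair!r} has inconsistent group labels")
            if groups == {"discordant"} and roles != ["affected", "unaffected"]:
                raise ValueError(
                    f"discordant pair {pair!r} must have one affected and one "
                    f"unaffected member, got {roles}"
                )
            if groups == {"concordant"} and roles != ["twin1", "twin2"]:
                raise ValueError(
                    f"concordant pair {pair!r} must be labelled twin1/twin2, got {roles}"
                )
        object.__setattr__(self, "frame", frame)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in DESIGN_CORE_COLUMNS]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def wave(self, age_wave: int) -> "TwinDesign":
        return TwinDesign(self.frame[self.frame["age_wave"] == age_wave].copy())

    def group(self, which: str) -> "TwinDesign":
        if which not in GROUPS:
            raise ValueError(f"unknown group {which!r}")
        return TwinDesign(self.frame[self.frame["group"] == which].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "TwinDesign":
        """Restrict to the given samples, dropping pairs left incomplete."""
        keep = set(sample_ids)
        frame = self.frame[self.frame["sample_id"].isin(keep)]
        complete = frame.groupby(["pair_id", "age_wave"])["sample_id"].transform("size") == 2
        return TwinDesign(frame[complete].copy())

    def pair_table(self, age_wave: int | None = None) -> pd.DataFrame:
        """One row per pair: columns pair_id, group, and the two member ids.

        For discordant pairs the members are reported as (affected,
        unaffected); for concordant pairs as (twin1, twin2).
        """
        frame = self.frame if age_wave is None else self.frame[self.frame["age_wave"] == age_wave]
        rows = []
        for pair, members in frame.groupby("pair_id"):
            # an individual profiled at both waves appears once per wave
            members = members.drop_duplicates(["role", "sample_id"])
            if members["role"].duplicated().any():
                raise ValueError(
                    f"pair {pair!r}: ambiguous sample ids across waves; pass age_wave"
                )
            members = members.set_index("role")["sample_id"]
            group = frame.loc[frame["pair_id"] == pair, "group"].iloc[0]
            if group == "discordant":
                first, second = members["affected"], members["unaffected"]
            else:
                first, second = members["twin1"], members["twin2"]
            rows.append({"pair_id": pair, "group": group, "first": first, "second": second})
        if not rows:
            return pd.DataFrame(columns=["group", "first", "second"], index=pd.Index([], name="pair_id"))
        return pd.DataFrame(rows).set_index("pair_id").sort_index()

    def co_twin_map(self, age_wave: int | None = None) -> dict[str, str]:
        pairs = self.pair_table(age_wave)
        mapping: dict[str, str] = {}
        for _, row in pairs.iterrows():
            mapping[row["first"]] = row["second"]
            mapping[row["second"]] = row["first"]
        return mapping


@dataclass
class ProbeAnnotation:
    """Per-probe annotation: position, design type, genes, QC flags.

    ``frame`` is indexed by probe_id with columns chromosome (str), position
    (1-based bp), design_type ('I'/'II'), gene_labels (list of symbols),
    cross_reactive (bool), snp_control (bool).
    """

    frame: pd.DataFrame

    REQUIRED = ["chromosome", "position", "design_type", "gene_labels", "cross_reactive", "snp_control"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"annotation is missing columns {missing}")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate probe ids in annotation")
        bad = set(self.frame["design_type"]) - {"I", "II"}
        if bad:
            raise ValueError(f"unknown design types {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, probes: Sequence[str]) -> "ProbeAnnotation":
        return ProbeAnnotation(self.frame.loc[list(probes)].copy())


@dataclass
class QcMetrics:
    """Per-probe per-sample detection P values and bead counts."""

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.detection_p.index.equals(self.bead_count.index):
            raise ValueError("detection_p and bead_count probe axes differ")
        if not self.detection_p.columns.equals(self.bead_count.columns):
            raise ValueError("detection_p and bead_count sample axes differ")
        detp = self.detection_p.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(((detp < 0) | (detp > 1)) & ~np.isnan(detp)):
                raise ValueError("detection P values outside [0, 1]")
        beads = self.bead_count.to_numpy()
        if np.any(beads < 0):
            raise ValueError("negative bead counts")

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "QcMetrics":
        detp, beads = self.detection_p, self.bead_count
        if probes is not None:
            detp, beads = detp.loc[list(probes)], beads.loc[list(probes)]
        if samples is not None:
            detp, beads = detp[list(samples)], beads[list(samples)]
        return QcMetrics(detp.copy(), beads.copy())


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass
class DmpRecord:
    """Per-probe paired-test result, mirroring the discovery table columns."""

    probe_id: str
    mean_affected: float
    mean_unaffected: float
    delta_beta: float
    t_stat: float
    df: int
    p_value: float
    n_pairs: int
    empirical_p: float | None = None


@dataclass
class LongitudinalRecord:
    """Per-probe contrast of within-individual change between age waves."""

    probe_id: str
    mean_long_delta_affected: float
    mean_long_delta_unaffected: float
    mean_change: float
    t_stat: float
    df: int
    p_value: float


@dataclass
class CohortSummary:
    """Group summary statistics for one probe in one case-control cohort."""

    cohort_id: str
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("cohort groups need n >= 2")
        if self.sd_case < 0 or self.sd_control < 0:
            raise ValueError("negative SD")


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects pooling with heterogeneity statistics."""

    per_cohort: list[dict]  # cohort_id, md, se, weight
    pooled_md: float
    pooled_se: float
    z_stat: float
    p_value: float
    q_stat: float
    het_df: int
    het_p: float
    i_squared: float

    def forest_frame(self) -> pd.DataFrame:
        """Per-cohort rows plus the pooled row, with 95% CIs and weight %."""
        total_w = sum(c["weight"] for c in self.per_cohort)
        rows = []
        for c in self.per_cohort:
            rows.append(
                {
                    "cohort": c["cohort_id"],
                    "md": c["md"],
                    "ci_lower": c["md"] - 1.959963984540054 * c["se"],
                    "ci_upper": c["md"] + 1.959963984540054 * c["se"],
                    "weight_pct": 100.0 * c["weight"] / total_w,
                }
            )
        rows.append(
            {
                "cohort": "pooled (fixed effects)",
                "md": self.pooled_md,
                "ci_lower": self.pooled_md - 1.959963984540054 * self.pooled_se,
                "ci_upper": self.pooled_md + 1.959963984540054 * self.pooled_se,
                "weight_pct": 100.0,
            }
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------


def _read_table(path, sep: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=sep,
        comment="#",
        index_col=index_col,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )


def _write_table(frame: pd.DataFrame, path, sep: str, seed: int | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(tool_stamp(seed) + "\n")
        # %.17g round-trips float64 exactly
        frame.to_csv(handle, sep=sep, index=index, na_rep=NA_TOKEN, float_format="%.17g")


def read_beta_matrix(path, sep: str = DEFAULT_SEP) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    The first column holds probe ids, the header row sample ids.  Raises on
    duplicate ids, non-numeric or out-of-range values, and ragged rows.
    """
    frame = _read_table(path, sep, index_col=0)
    frame = frame.astype(float)
    frame.index = frame.index.astype(str)
    frame.index.name = "probe_id"
    return BetaMatrix(frame)


def write_beta_matrix(matrix: BetaMatrix, path, sep: str = DEFAULT_SEP, seed: int | None = None) -> None:
    _write_table(matrix.values, path, sep, seed, index=True)


def read_design(path, sep: str = DEFAULT_SEP) -> TwinDesign:
    """Read a sample sheet; pair/role invariants are validated on load."""
    frame = _read_table(path, sep)
    for col in ("sample_id", "pair_id", "role", "group"):
        if col in frame.columns:
            frame[col] = frame[col].astype(str)
    if "age_wave" in frame.columns:
        frame["age_wave"] = frame["age_wave"].astype(int)
    return TwinDesign(frame)


def write_design(design: TwinDesign, path, sep: str = DEFAULT_SEP, seed: int | None = None) -> None:
    _write_table(design.frame, path, sep, seed, index=False)


def read_probe_annotation(path, sep: str = DEFAULT_SEP) -> ProbeAnnotation:
    frame = _read_table(path, sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "probe_id"
    frame["gene_labels"] = [
        [] if (not isinstance(genes, str) or genes == "") else genes.split(";")
        for genes in frame["gene_labels"].fillna("")
    ]
    frame["cross_reactive"] = frame["cross_reactive"].astype(int).astype(bool)
    frame["snp_control"] = frame["snp_control"].astype(int).astype(bool)
    frame["position"] = frame["position"].astype(int)
    frame["chromosome"] = frame["chromosome"].astype(str)
    return ProbeAnnotation(frame)


def write_probe_annotation(
    annotation: ProbeAnnotation, path, sep: str = DEFAULT_SEP, seed: int | None = None
) -> None:
    frame = annotation.frame.copy()
    frame["gene_labels"] = [";".join(genes) for genes in frame["gene_labels"]]
    frame["cross_reactive"] = frame["cross_reactive"].astype(int)
    frame["snp_control"] = frame["snp_control"].astype(int)
    _write_table(frame, path, sep, seed, index=True)


def read_qc_metrics(detection_p_path, bead_count_path, sep: str = DEFAULT_SEP) -> QcMetrics:
    detp = _read_table(detection_p_path, sep, index_col=0).astype(float)
    beads = _read_table(bead_count_path, sep, index_col=0).astype(int)
    detp.index = detp.index.astype(str)
    beads.index = beads.index.astype(str)
    return QcMetrics(detp, beads)


def write_qc_metrics(
    metrics: QcMetrics, detection_p_path, bead_count_path, sep: str = DEFAULT_SEP, seed: int | None = None
) -> None:
    _write_table(metrics.detection_p, detection_p_path, sep, seed, index=True)
    _write_table(metrics.bead_count, bead_count_path, sep, seed, index=True)


def read_intensity_pair(methylated_path, unmethylated_path, sep: str = DEFAULT_SEP) -> IntensityPair:
    meth = _read_table(methylated_path, sep, index_col=0).astype(float)
    unmeth = _read_table(unmethylated_path, sep, index_col=0).astype(float)
    meth.index = meth.index.astype(str)
    unmeth.index = unmeth.index.astype(str)
    return IntensityPair(meth, unmeth)


def write_intensity_pair(
    pair: IntensityPair, methylated_path, unmethylated_path, sep: str = DEFAULT_SEP, seed: int | None = None
) -> None:
    _write_table(pair.methylated, methylated_path, sep, seed, index=True)
    _write_table(pair.unmethylated, unmethylated_path, sep, seed, index=True)


COHORT_SUMMARY_COLUMNS = [
    "probe_id",
    "cohort_id",
    "n_case",
    "n_control",
    "mean_case",
    "mean_control",
    "sd_case",
    "sd_control",
]


def read_cohort_summaries(path, sep: str = DEFAULT_SEP) -> dict[str, list[CohortSummary]]:
    """Read a flat per-probe per-cohort summary table into probe -> cohorts."""
    frame = _read_table(path, sep)
    missing = [c for c in COHORT_SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort summary table missing columns {missing}")
    out: dict[str, list[CohortSummary]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["probe_id"]), []).append(
            CohortSummary(
                cohort_id=str(row["cohort_id"]),
                n_case=int(row["n_case"]),
                n_control=int(row["n_control"]),
                mean_case=float(row["mean_case"]),
                mean_control=float(row["mean_control"]),
                sd_case=float(row["sd_case"]),
                sd_control=float(row["sd_control"]),
            )
        )
    return out


def write_cohort_summaries(
    summaries: Mapping[str, Sequence[CohortSummary]], path, sep: str = DEFAULT_SEP, seed: int | None = None
) -> None:
    rows = []
    for probe_id, cohorts in summaries.items():
        for summary in cohorts:
            row = {"probe_id": probe_id, **asdict(summary)}
            rows.append(row)
    frame = pd.DataFrame(rows, columns=COHORT_SUMMARY_COLUMNS)
    _write_table(frame, path, sep, seed, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read GMT (term <tab> description <tab> gene ...) into term -> gene set.

    Duplicate term ids and empty gene sets are rejected.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            term, genes = fields[0], [g for g in fields[2:] if g]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set for {term!r}")
            sets[term] = set(genes)
    return sets


def write_gene_sets(
    sets: Mapping[str, Iterable[str]],
    path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as handle:
        for term, genes in sets.items():
            desc = (descriptions or {}).get(term, "na")
            handle.write("\t".join([term, desc, *sorted(set(genes))]) + "\n")


# ---------------------------------------------------------------------------
# JSON records
# ---------------------------------------------------------------------------


def write_json_record(record, path, seed: int | None = None) -> None:
    """Serialize a result record (dataclass / dict / DataFrame) to JSON."""
    if hasattr(record, "__dataclass_fields__"):
        payload = asdict(record)
    elif isinstance(record, pd.DataFrame):
        payload = record.to_dict(orient="records")
    else:
        payload = record
    doc = {"_tool": f"twinmeth {__version__}", "_seed": seed, "data": payload}
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, default=_json_default)
        handle.write("\n")


def read_json_record(path):
    with open(path) as handle:
        return json.load(handle)["data"]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
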