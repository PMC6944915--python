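"""Statistics for a plate-based siRNA checkpoint-recovery screen.

The screen measures, per well, the fraction of mitotic cells (phospho-histone
H3 or MPM2 positive) after irradiation of G2-synchronized cells.  Gene
knockdowns that change the fraction of cells re-entering mitosis are ranked
by a Z-score against the plate (or screen) readout distribution, called as
hits with asymmetric cutoffs, and validated by single-oligo deconvolution
against the negative-control (luciferase) wells.  The module also provides
the normalized ratios used downstream of the screen: relative mitotic entry
(RME), clonogenic survival, and reporter repair efficiency, each normalized
to the negative control, plus the unpaired two-tailed t-test used for group
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("recoverkit.screen")

#: Columns a screen table must carry.  ``readout`` is a mitotic fraction in
#: [0, 1]; tables supplying ``positive``/``total`` counts are converted with
#: :func:`as_fractions`.
SCREEN_COLUMNS = (
    "plate_id",
    "well_id",
    "gene",
    "sirna_id",
    "condition",
    "replicate",
    "readout",
    "is_control",
)

CONTROL_LEVELS = ("none", "negative_control", "positive_control")


class DegeneratePlateError(ValueError):
    """A scope group's readouts have zero spread, so Z-scores are undefined."""


@dataclass(frozen=True)
class ZScoreResult:
    gene: str
    sirna_id: str
    z_per_replicate: tuple[float, ...]
    z_mean: float
    n_replicates: int


@dataclass(frozen=True)
class HitCall:
    gene: str
    direction: Literal["increased", "decreased", "none"]
    z_mean: float
    validated: bool = False
    n_oligos_altered: int = 0


@dataclass(frozen=True)
class NormalizedRatio:
    gene: str
    raw_ratio: float
    normalized: float
    kind: Literal["RME", "survival", "repair_efficiency"]


# ---------------------------------------------------------------------------
# table handling
# ---------------------------------------------------------------------------

def as_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``readout`` fraction column.

    Tables may supply either ``readout`` directly or ``positive``/``total``
    counts; counts are converted to positive/total before any statistic.
    """
    df = table.copy()
    if "readout" not in df.columns:
        if not {"positive", "total"}.issubset(df.columns):
            raise ValueError("table needs either 'readout' or 'positive'+'total' columns")
        totals = df["total"].to_numpy(dtype=float)
        if (totals <= 0).any():
            raise ValueError("'total' counts must be positive")
        df["readout"] = df["positive"].to_numpy(dtype=float) / totals
    if "is_control" not in df.columns:
        df["is_control"] = "none"
    return df


def validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants of a screen table; returns the fraction table."""
    df = as_fractions(table)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    bad_ctrl = set(df["is_control"].unique()) - set(CONTROL_LEVELS)
    if bad_ctrl:
        raise ValueError(f"unknown is_control levels: {sorted(bad_ctrl)}")
    x = df["readout"].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("readouts must be finite")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("readout fractions must lie in [0, 1]")
    keys = df[["plate_id", "well_id", "replicate", "condition"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].to_dict()
        raise ValueError(f"duplicate well entry: {dup}")
    for plate, sub in df.groupby("plate_id"):
        if not (sub["is_control"] == "negative_control").any():
            raise ValueError(f"plate {plate!r} has no negative_control well")
    return df


def read_screen_table(path) -> pd.DataFrame:
    """Read a CSV/TSV screen table (UTF-8, '.' decimal) and validate it."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return validate_screen_table(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# Z-scores and hit calling
# ---------------------------------------------------------------------------

def compute_zscores(
    table: pd.DataFrame,
    scope: Literal["per_plate", "per_screen"] = "per_plate",
    include_controls: bool = False,
    condition: str = "treated",
    aggregate: Literal["mean", "median"] = "mean",
) -> list[ZScoreResult]:
    """Standardize well readouts against their scope group.

    For each well, ``z = (x - m) / s`` where ``m`` and ``s`` are the mean and
    sample standard deviation (ddof=1) of the scope group's readouts within
    the same replicate.  The reference population is the non-control wells of
    the plate by default (``include_controls=True`` adds control wells to the
    reference); per-screen scope pools all plates of a replicate.  Z-scores
    are aggregated across replicates into ``z_mean`` (unweighted mean by
    default, median optionally).  One result is emitted per non-control
    (gene, sirna_id); genes missing in some replicates are reported with
    reduced ``n_replicates`` and a logged warning.
    """
    if scope not in ("per_plate", "per_screen"):
        raise ValueError(f"unknown scope {scope!r}")
    df = validate_screen_table(table)
    df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError(f"no wells with condition {condition!r}")

    group_cols = ["replicate"] if scope == "per_screen" else ["replicate", "plate_id"]
    zcol = np.full(len(df), np.nan)
    for _, idx in df.groupby(group_cols).indices.items():
        sub = df.iloc[idx]
        ref = sub if include_controls else sub[sub["is_control"] == "none"]
        ref_x = ref["readout"].to_numpy(dtype=float)
        if len(ref_x) < 3:
            raise ValueError("scope group has fewer than 3 reference wells")
        m = ref_x.mean()
        s = ref_x.std(ddof=1)
        if s == 0:
            raise DegeneratePlateError(
                "degenerate scope group: reference readouts have zero standard deviation"
            )
        zcol[idx] = (sub["readout"].to_numpy(dtype=float) - m) / s
    df = df.assign(z=zcol)

    agg_fn = np.mean if aggregate == "mean" else np.median
    out: list[ZScoreResult] = []
    samples = df[df["is_control"] == "none"]
    n_expected = samples["replicate"].nunique()
    for (gene, sirna), sub in samples.groupby(["gene", "sirna_id"], sort=True):
        zs = tuple(float(v) for v in sub.sort_values("replicate")["z"])
        if len(zs) < n_expected:
            logger.warning(
                "gene %s oligo %s present in %d/%d replicates", gene, sirna, len(zs), n_expected
            )
        out.append(
            ZScoreResult(
                gene=str(gene),
                sirna_id=str(sirna),
                z_per_replicate=zs,
                z_mean=float(agg_fn(zs)),
                n_replicates=len(zs),
            )
        )
    return out


def call_hits(
    z: Iterable[ZScoreResult],
    up_cutoff: float = 2.0,
    down_cutoff: float = 1.0,
) -> list[HitCall]:
    """Call hits from aggregated Z-scores with asymmetric inclusive cutoffs.

    ``z_mean >= up_cutoff`` calls "increased" recovery (more mitotic entry
    after knockdown), ``z_mean <= -down_cutoff`` calls "decreased"; boundary
    values are hits.
    """
    if up_cutoff <= 0 or down_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    calls = []
    for r in z:
        if r.z_mean >= up_cutoff:
            direction = "increased"
        elif r.z_mean <= -down_cutoff:
            direction = "decreased"
        else:
            direction = "none"
        calls.append(HitCall(gene=r.gene, direction=direction, z_mean=r.z_mean))
    return calls


def deconvolve(
    table: pd.DataFrame,
    sd_threshold: float = 0.5,
    min_oligos: int = 2,
    min_experiments: int = 2,
    condition: str = "treated",
) -> list[HitCall]:
    """Validate hits from single-oligo wells against the luciferase controls.

    Within one experiment (replicate), an oligo's recovery value is "altered"
    when it deviates from the mean of the negative-control wells by more than
    ``sd_threshold`` times the controls' sample SD.  An oligo validates when
    altered in at least ``min_experiments`` experiments; a gene validates
    when at least ``min_oligos`` of its oligos validate.  ``z_mean`` on the
    returned calls is the mean control-SD displacement across experiments and
    oligos; ``direction`` summarizes its sign for validated genes.
    """
    df = validate_screen_table(table)
    df = df[df["condition"] == condition]
    samples = df[df["is_control"] == "none"]

    # per-experiment control statistics
    ctrl_stats: dict = {}
    for rep, sub in df.groupby("replicate"):
        ctrl = sub[sub["is_control"] == "negative_control"]["readout"].to_numpy(dtype=float)
        if len(ctrl) < 2:
            raise ValueError(
                f"experiment {rep!r} has {len(ctrl)} negative-control wells; "
                "at least 2 are needed to estimate the control SD"
            )
        sd = ctrl.std(ddof=1)
        if sd == 0:
            raise DegeneratePlateError(
                f"experiment {rep!r}: negative-control readouts have zero SD"
            )
        ctrl_stats[rep] = (ctrl.mean(), sd)

    calls: list[HitCall] = []
    for gene, gsub in samples.groupby("gene", sort=True):
        n_validated = 0
        displacements: list[float] = []
        for _, osub in gsub.groupby("sirna_id"):
            n_altered_exps = 0
            for rep, wells in osub.groupby("replicate"):
                m, s = ctrl_stats[rep]
                x = float(wells["readout"].mean())
                displacements.append((x - m) / s)
                if abs(x - m) > sd_threshold * s:
                    n_altered_exps += 1
            if n_altered_exps >= min_experiments:
                n_validated += 1
        validated = n_validated >= min_oligos
        mean_disp = float(np.mean(displacements)) if displacements else 0.0
        direction = "none"
        if validated:
            direction = "increased" if mean_disp > 0 else "decreased"
        calls.append(
            HitCall(
                gene=str(gene),
                direction=direction,
                z_mean=mean_disp,
                validated=validated,
                n_oligos_altered=n_validated,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# normalized ratios
# ---------------------------------------------------------------------------

def normalized_ratio(
    treated: float,
    untreated: float,
    control_ratio: float,
    kind: Literal["RME", "survival", "repair_efficiency"] = "RME",
    gene: str = "",
) -> NormalizedRatio:
    """Treated/untreated ratio normalized to the negative-control ratio.

    For RME this is the mitotic-cell count after IR divided by the untreated
    mitotic-cell count, divided again by the same ratio for the luciferase
    control (so the control is exactly 1).
    """
    if untreated <= 0:
        raise ValueError("untreated denominator must be positive (empty untreated gate?)")
    if control_ratio <= 0:
        raise ValueError("control ratio must be positive")
    if treated < 0:
        raise ValueError("treated readout must be nonnegative")
    raw = treated / untreated
    return NormalizedRatio(gene=gene, raw_ratio=raw, normalized=raw / control_ratio, kind=kind)


def repair_efficiency(
    marker_pos_in_transfected: int,
    transfected: int,
    control_fraction: float,
    gene: str = "",
) -> NormalizedRatio:
    """Reporter repair efficiency relative to the negative control.

    The raw value is the fraction of marker-positive (CD4 for NHEJ, GFP for
    HR) cells among transfected (mCherry-positive) cells; it is normalized to
    the same fraction measured in the control knockdown.
    """
    if transfected <= 0:
        raise ValueError("transfected count must be positive")
    if not 0 <= marker_pos_in_transfected <= transfected:
        raise ValueError("marker-positive count must lie in [0, transfected]")
    if control_fraction <= 0:
        raise ValueError("control fraction must be positive")
    raw = marker_pos_in_transfected / transfected
    return NormalizedRatio(
        gene=gene, raw_ratio=raw, normalized=raw / control_fraction, kind="repair_efficiency"
    )


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> dict:
    """Classical unpaired equal-variance t-test, two-tailed.

    Returns ``{"t", "p", "df"}`` with ``df = n_a + n_b - 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": len(a) + len(b) - 2}


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def zscores_frame(results: Iterable[ZScoreResult], bh_adjust: bool = False) -> pd.DataFrame:
    """Z-score results as a DataFrame in deterministic (gene, sirna_id) order.

    ``bh_adjust=True`` appends Benjamini-Hochberg-adjusted two-sided Gaussian
    tail probabilities as ``p_adj_bh`` — an optional extension, not part of
    the primary hit-calling procedure.
    """
    rows = [
        {
            "gene": r.gene,
            "sirna_id": r.sirna_id,
            "z_mean": r.z_mean,
            "n_replicates": r.n_replicates,
            "z_per_replicate": ";".join(f"{z:.6g}" for z in r.z_per_replicate),
        }
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(["gene", "sirna_id"]).reset_index(drop=True)
    if bh_adjust and len(df):
        p = 2 * stats.norm.sf(np.abs(df["z_mean"].to_numpy()))
        df["p_adj_bh"] = stats.false_discovery_control(p, method="bh")
    return df


def hits_frame(calls: Iterable[HitCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "direction": c.direction,
                "z_mean": c.z_mean,
                "validated": c.validated,
                "n_oligos_altered": c.n_oligos_altered,
            }
            for c in calls
        ]
    )
    return df.sort_values("gene").reset_index(drop=True)
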