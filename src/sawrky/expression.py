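"""Expression profiling: RPKM tissue matrices and qPCR relative-expression
calling.

RPKM = count / (gene length in kb) / (mapped reads in millions); heat-map
values are log2(RPKM + 1). Hormone-response calls use the 2^-ddCq method:
per replicate, dCq = Cq(target) - mean(Cq of the reference genes); ddCq is
the mean dCq at a treatment timepoint minus the mean at the 0 h
calibrator; relative expression is 2^-ddCq. Significance comes from a
Welch two-sample t-test on replicate dCq values against the calibrator. A
gene is called up when relative expression exceeds the up threshold
(default 1.5-fold, strict) with p below alpha, down below the down
threshold (default 0.5-fold), otherwise unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CountMatrix:
    """Gene × sample read counts with gene lengths (bp) and library-wide
    mapped-read totals per sample."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    counts: np.ndarray
    lengths_bp: np.ndarray
    mapped_totals: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.mapped_totals <= 0).any():
            raise ValueError("library totals must be positive")


def rpkm(count: float, length_bp: float, mapped_total: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return count / (length_bp / 1e3) / (mapped_total / 1e6)


def rpkm_matrix(cm: CountMatrix) -> pd.DataFrame:
    """RPKM for every gene × sample of a count matrix."""
    vals = (
        cm.counts
        / (cm.lengths_bp[:, None] / 1e3)
        / (cm.mapped_totals[None, :] / 1e6)
    )
    return pd.DataFrame(vals, index=list(cm.genes), columns=list(cm.samples))


def heat_matrix(values) -> pd.DataFrame:
    """Elementwise log2(x + 1) of an RPKM matrix (monotone, 0 → 0)."""
    df = pd.DataFrame(values)
    if (df.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(df + 1.0)


@dataclass(frozen=True)
class RegulationCallConfig:
    up_threshold: float = 1.5
    down_threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (self.down_threshold < 1.0 < self.up_threshold):
            raise ValueError("need down_threshold < 1 < up_threshold")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    hormone: str
    timepoint: int
    rel_expr: float
    p_value: float
    call: str


# Expected long-format Cq columns
CQ_COLUMNS = [
    "gene", "hormone", "timepoint", "replicate", "cq_target", "cq_ref1", "cq_ref2",
]


def _delta_cq(sub: pd.DataFrame) -> np.ndarray:
    refs = sub[["cq_ref1", "cq_ref2"]].to_numpy(float)
    return sub["cq_target"].to_numpy(float) - refs.mean(axis=1)


def relative_expression(
    cq: pd.DataFrame,
    gene: str,
    hormone: str,
    calibrator: int = 0,
    timepoints: Sequence[int] = (3, 6),
    n_replicates: int = 3,
) -> list[tuple[int, float, float]]:
    """Per-timepoint relative expression (2^-ddCq) and Welch-t p-value for
    one gene under one hormone, against the calibrator timepoint.

    Raises if any condition is missing the full replicate set, naming the
    gap.
    """
    sub = cq[(cq["gene"] == gene) & (cq["hormone"] == hormone)]
    base = sub[sub["timepoint"] == calibrator]
    if len(base) != n_replicates:
        raise ValueError(
            f"{gene}/{hormone}: {len(base)} replicates at {calibrator} h, "
            f"expected {n_replicates}"
        )
    d0 = _delta_cq(base)
    out = []
    for t in timepoints:
        cond = sub[sub["timepoint"] == t]
        if len(cond) != n_replicates:
            raise ValueError(
                f"{gene}/{hormone}: {len(cond)} replicates at {t} h, "
                f"expected {n_replicates}"
            )
        dt = _delta_cq(cond)
        ddcq = dt.mean() - d0.mean()
        rel = 2.0 ** (-ddcq)
        if np.allclose(dt, dt[0]) and np.allclose(d0, d0[0]):
            # degenerate (noise-free) input: t statistic undefined
            p = 0.0 if not math.isclose(dt[0], d0[0]) else 1.0
        else:
            p = float(stats.ttest_ind(dt, d0, equal_var=False).pvalue)
        out.append((t, float(rel), p))
    return out


def call_regulation(
    rel_expr: float, p: float, cfg: RegulationCallConfig = RegulationCallConfig()
) -> str:
    """Call one timepoint: ``up`` iff rel_expr strictly exceeds the up
    threshold with p < alpha, ``down`` iff strictly below the down
    threshold with p < alpha, else ``unchanged``."""
    if p < cfg.alpha:
        if rel_expr > cfg.up_threshold:
            return "up"
        if rel_expr < cfg.down_threshold:
            return "down"
    return "unchanged"


def gene_hormone_call(timepoint_calls: Iterable[str]) -> str:
    """Aggregate per-timepoint calls to one call per gene and hormone:
    a direction wins if called at one or more timepoints and the opposite
    direction is never called; contradictions are ``unchanged``."""
    calls = set(timepoint_calls)
    if "up" in calls and "down" not in calls:
        return "up"
    if "down" in calls and "up" not in calls:
        return "down"
    return "unchanged"


def call_table(
    cq: pd.DataFrame,
    cfg: RegulationCallConfig = RegulationCallConfig(),
    timepoints: Sequence[int] = (3, 6),
) -> pd.DataFrame:
    """Run the full calling pipeline on a long-format Cq table.

    Returns one row per gene × hormone with per-timepoint relative
    expression, p-values and calls, plus the aggregated gene-level call.
    """
    rows = []
    for (gene, hormone), _ in cq.groupby(["gene", "hormone"], sort=True):
        per_t = relative_expression(cq, gene, hormone, timepoints=timepoints)
        t_calls = [call_regulation(rel, p, cfg) for _, rel, p in per_t]
        row: dict = {"gene": gene, "hormone": hormone}
        for (t, rel, p), c in zip(per_t, t_calls):
            row[f"rel_{t}h"] = rel
            row[f"p_{t}h"] = p
            row[f"call_{t}h"] = c
        row["call"] = gene_hormone_call(t_calls)
        rows.append(row)
    return pd.DataFrame(rows)


def responsive_summary(
    calls: pd.DataFrame, hormones: Sequence[str] = ("SA", "MeJA")
) -> dict:
    """Set cardinalities of the hormone responses.

    Returns counts (``SA_up``, ``SA_down``, ``MeJA_up``, ``MeJA_down``,
    ``both_up``, ``SA_total``, ``MeJA_total``) and the underlying gene
    sets; totals are up + down per hormone.
    """
    sets: dict[str, frozenset[str]] = {}
    for hormone in hormones:
        sub = calls[calls["hormone"] == hormone]
        for direction in ("up", "down"):
            sets[f"{hormone}_{direction}"] = frozenset(
                sub[sub["call"] == direction]["gene"]
            )
    up_sets = [sets[f"{h}_up"] for h in hormones]
    both_up = frozenset.intersection(*up_sets) if up_sets else frozenset()
    out: dict = {"sets": sets, "both_up_set": both_up, "both_up": len(both_up)}
    for hormone in hormones:
        up, down = sets[f"{hormone}_up"], sets[f"{hormone}_down"]
        out[f"{hormone}_up"] = len(up)
        out[f"{hormone}_down"] = len(down)
        out[f"{hormone}_total"] = len(up) + len(down)
    return out


def read_cq_table(path) -> pd.DataFrame:
    """Read a long-format Cq TSV with the columns in :data:`CQ_COLUMNS`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return df
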