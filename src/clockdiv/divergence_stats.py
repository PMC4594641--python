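"""The relative-rate statistic and the study's group-level comparisons.

For each gene, the focal taxon's mean patristic distance to every other
taxon present in that gene's tree is divided by the grand mean pairwise
distance over all taxa and genes:

    relative_rate(g) = mean_j d_g(focal, j) / grand_mean

    grand_mean = mean over genes of [ mean over unordered taxon pairs of d_g ]

A ratio above 1 means the gene's protein is diverging faster along the
focal lineage than the study-wide average; below 1, slower.  Genes missing
a taxon contribute the pair means over the taxa they do have; the grand
mean is unweighted across genes.

Group comparisons: one-sample t of each group's rates against 1.0, a 2xk
Fisher exact test on best-fit model frequencies, OLS of rate on transcript
length, ANCOVA of rate on group plus length, and a one-way ANOVA of the
regression residuals by group.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneTableRow
from .tree_build import DistanceMatrix

logger = logging.getLogger(__name__)

GROUPS = ("TTFL", "PTM")


@dataclass(frozen=True)
class RelativeRateRecord:
    gene: str
    group: str
    focal_mean: float
    relative_rate: float
    nucleotides: int | None = None
    model_name: str | None = None


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    se: float
    t: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# The statistic


def focal_mean_distance(dm: DistanceMatrix, focal_id: str) -> float:
    """Mean patristic distance from the focal taxon to every other taxon."""
    if focal_id not in dm.taxa:
        raise ValueError(f"focal taxon {focal_id!r} not in matrix (taxa: {dm.taxa})")
    i = dm.taxa.index(focal_id)
    others = [j for j in range(len(dm.taxa)) if j != i]
    if not others:
        raise ValueError("need at least one non-focal taxon")
    return float(dm.d[i, others].mean())


def mean_pairwise_distance(dm: DistanceMatrix) -> float:
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    iu = np.triu_indices(n, k=1)
    return float(dm.d[iu].mean())


def grand_mean_distance(matrices: Sequence[DistanceMatrix]) -> float:
    """Unweighted mean over genes of the within-gene mean pairwise distance.

    Genes with missing taxa contribute the mean over the pairs they have.
    """
    if not matrices:
        raise ValueError("no distance matrices supplied")
    return float(np.mean([mean_pairwise_distance(dm) for dm in matrices]))


def relative_rates(
    matrices: Mapping[str, DistanceMatrix],
    focal_id: str,
    groups: Mapping[str, str] | None = None,
    covariates: Mapping[str, Mapping] | None = None,
) -> list[RelativeRateRecord]:
    """Per-gene relative rates from per-gene patristic distance matrices.

    Genes whose matrix lacks the focal taxon are excluded with a warning
    (they still do not contribute to the denominator).  The statistic is
    scale invariant: multiplying every distance by c > 0 changes nothing.
    """
    usable = {}
    for gene, dm in matrices.items():
        if focal_id not in dm.taxa:
            logger.warning("gene %s lacks focal taxon %s; excluded", gene, focal_id)
            continue
        usable[gene] = dm
    if not usable:
        raise ValueError(f"no gene matrix contains the focal taxon {focal_id!r}")
    grand = grand_mean_distance(list(usable.values()))
    if grand <= 0:
        raise ValueError("grand mean distance is zero; rates undefined")
    records = []
    for gene, dm in usable.items():
        fm = focal_mean_distance(dm, focal_id)
        cov = (covariates or {}).get(gene, {})
        records.append(
            RelativeRateRecord(
                gene=gene,
                group=(groups or {}).get(gene, ""),
                focal_mean=fm,
                relative_rate=fm / grand,
                nucleotides=cov.get("nucleotides"),
                model_name=cov.get("model_name"),
            )
        )
    return records


def records_from_table(rows: Sequence[GeneTableRow]) -> list[RelativeRateRecord]:
    """Wrap a printed study table (with precomputed rates) as rate records."""
    out = []
    for r in rows:
        if r.relative_rate is None:
            raise ValueError(f"gene {r.gene} has no relative rate in the table")
        out.append(
            RelativeRateRecord(
                gene=r.gene,
                group=r.group,
                focal_mean=float("nan"),
                relative_rate=r.relative_rate,
                nucleotides=r.nucleotides,
                model_name=r.model_name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Group statistics


def one_sample_t(values: Sequence[float], mu0: float = 1.0) -> GroupSummary:
    """Two-sided one-sample t test of the mean against ``mu0``."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t statistic undefined")
    se = sd / math.sqrt(n)
    t = (x.mean() - mu0) / se
    p = 2 * sps.t.sf(abs(t), n - 1)
    return GroupSummary(n=n, mean=float(x.mean()), se=float(se), t=float(t), df=n - 1, p=float(p))


def group_summaries(records: Sequence[RelativeRateRecord], mu0: float = 1.0) -> dict[str, GroupSummary]:
    """One-sample t summaries for all genes combined and per group."""
    for r in records:
        if r.group not in GROUPS:
            raise ValueError(f"gene {r.gene} has no TTFL/PTM label")
    out = {"combined": one_sample_t([r.relative_rate for r in records], mu0)}
    for g in GROUPS:
        vals = [r.relative_rate for r in records if r.group == g]
        if not vals:
            raise ValueError(f"group {g} has no genes")
        out[g] = one_sample_t(vals, mu0)
    return out


def model_frequency_table(records: Sequence[RelativeRateRecord]) -> pd.DataFrame:
    """2xk counts of best-fit model names by group (distinct full strings)."""
    names = sorted({r.model_name for r in records if r.model_name})
    data = {
        g: [sum(1 for r in records if r.group == g and r.model_name == m) for m in names]
        for g in GROUPS
    }
    return pd.DataFrame(data, index=names).T


def model_diversity_table(records: Sequence[RelativeRateRecord]) -> np.ndarray:
    """2x2 counts: (distinct best-fit models, remaining genes) per group.

    This is the "frequency of different models" comparison in the coarse
    sense — how many different models each group needed relative to its
    gene count (e.g. six distinct among nine genes vs five among eight).
    """
    rows = []
    for g in GROUPS:
        names = [r.model_name for r in records if r.group == g and r.model_name]
        rows.append([len(set(names)), len(names) - len(set(names))])
    return np.array(rows, dtype=np.int64)


def fisher_exact_2xk(table) -> float:
    """Two-sided Fisher exact test for a 2xk contingency table.

    Conditions on both margins and sums the multivariate hypergeometric
    probability of every table no more probable than the observed one
    (probability-mass ordering, with a 1e-12 relative tolerance), by full
    enumeration over column fillings.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()

    # log-probability of a table given margins: conditioning on row/column
    # sums, P(table) = prod_j C(col_j, a_j) / C(total, row_0)
    from math import lgamma

    def lchoose(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -math.inf
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    denom = lchoose(total, row[0])

    def logp(top: Sequence[int]) -> float:
        return sum(lchoose(col[j], top[j]) for j in range(len(col))) - denom

    obs_logp = logp(obs[0])
    tol = 1e-12

    k = len(col)
    p_sum = 0.0
    # enumerate top-row fillings summing to row[0], bounded by column sums
    def rec(j: int, remaining: int, acc_logp: float) -> None:
        nonlocal p_sum
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                lp = acc_logp + lchoose(col[j], remaining) - denom
                if lp <= obs_logp + tol + abs(obs_logp) * tol:
                    p_sum += math.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1 :].sum()))
        hi = min(col[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, acc_logp + lchoose(col[j], a))

    rec(0, int(row[0]), 0.0)
    return float(min(p_sum, 1.0))


def regress_rate_on_length(records: Sequence[RelativeRateRecord]):
    """OLS of relative rate on nucleotide count.

    Returns (slope, Pearson r, t, two-sided p) with t = r sqrt(n-2)/sqrt(1-r^2).
    """
    x = np.array([r.nucleotides for r in records], dtype=float)
    y = np.array([r.relative_rate for r in records], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    if np.var(x) == 0:
        raise ValueError("no variance in nucleotide counts")
    res = sps.linregress(x, y)
    n = x.size
    r = res.rvalue
    t = r * math.sqrt(n - 2) / math.sqrt(max(1 - r * r, 1e-300))
    return float(res.slope), float(r), float(t), float(res.pvalue)


def _design(records: Sequence[RelativeRateRecord]):
    y = np.array([r.relative_rate for r in records], dtype=float)
    g = np.array([1.0 if r.group == "TTFL" else 0.0 for r in records])
    x = np.array([r.nucleotides for r in records], dtype=float)
    if len(set(g)) < 2:
        raise ValueError("both groups must be present")
    if len(records) < 4:
        raise ValueError("need at least 4 genes")
    return y, g, x


def ancova_group_effect(records: Sequence[RelativeRateRecord]) -> tuple[float, float]:
    """t and two-sided p for the group term in rate ~ group + nucleotides.

    The t magnitude is invariant to how the group indicator is coded;
    residual df is n - 3.
    """
    import statsmodels.api as sm

    y, g, x = _design(records)
    X = sm.add_constant(np.column_stack([g, x]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def residual_anova(records: Sequence[RelativeRateRecord]) -> tuple[float, float]:
    """One-way ANOVA by group on the residuals of rate ~ nucleotides.

    Reports F(1, n-2) and its p; with two groups F equals the square of the
    pooled t on the residuals.
    """
    y, g, x = _design(records)
    res = sps.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    a, b = resid[g == 1], resid[g == 0]
    n = len(resid)
    ss_between = len(a) * (a.mean() - resid.mean()) ** 2 + len(b) * (b.mean() - resid.mean()) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ss_within == 0:  # degenerate: residuals constant within groups
        F = 0.0 if ss_between <= 1e-24 else math.inf
        return F, 1.0 if F == 0.0 else 0.0
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), p


def summaries_frame(summaries: Mapping[str, GroupSummary]) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        rows.append({"category": name, "n": s.n, "mean": s.mean, "se": s.se, "t": s.t, "df": s.df, "p": s.p})
    return pd.DataFrame(rows)
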