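"""Selection statistics on stratified indel sets.

Implements the deletion/insertion ratio (rDI), the indel-adapted
McDonald-Kreitman 2x2 contrast with an underflow-safe Fisher exact test,
derived allele frequency spectrum comparisons (Wilcoxon rank-sum),
region-class enrichment with Benjamini-Hochberg FDR control, the
per-category binomial contrast with Bonferroni FWER control, C-score
candidate filtering and Hudson's per-site FST.

The MK-style contrast compares the deletion:insertion ratio between an
older class (fixed, or archaic-shared) and a younger class (polymorphic,
or modern-human-specific).  Under neutrality both ratios reflect only
the mutation-rate ratio (deletions arise roughly twice as often as
insertions); a deficit of deletions in the older class indicates
stronger purifying selection on deletions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "mk_table",
    "fisher_exact_2x2",
    "rdi",
    "afs_compare",
    "region_class_contrast",
    "category_contrast",
    "score_filter",
    "fst_hudson",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = two indel classes, columns = deletions/insertions."""

    a: int  # row 1 deletions
    b: int  # row 1 insertions
    c: int  # row 2 deletions
    d: int  # row 2 insertions
    row_labels: tuple[str, str] = ("class1", "class2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def row_rdi(self) -> tuple[float, float]:
        return (rdi(self.a, self.b), rdi(self.c, self.d))

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def rdi(deletions: int, insertions: int) -> float:
    """Ratio of deletion to insertion counts within one indel class."""
    if insertions <= 0:
        raise ValueError("rDI undefined for zero insertions")
    return deletions / insertions


def mk_table(
    indels: pd.DataFrame,
    split_by: str = "fixation",
    by_length: bool = False,
):
    """Tabulate the MK-style 2x2 from a stratified indel table.

    ``split_by='fixation'`` contrasts fixed vs polymorphic;
    ``split_by='sharing'`` contrasts archaic_shared vs modern_specific
    (uncovered sites are excluded).  With ``by_length=True`` a dict of
    per-length tables (keys 1..5) plus the pooled table (key 'pooled')
    is returned.
    """
    if split_by == "fixation":
        classes = ("fixed", "polymorphic")
    elif split_by == "sharing":
        classes = ("archaic_shared", "modern_specific")
    else:
        raise ValueError(f"unknown stratifier {split_by!r}")

    def tab(df: pd.DataFrame) -> ContingencyTable:
        def n(cls: str, ev: str) -> int:
            return int(((df[split_by] == cls) & (df["event"] == ev)).sum())

        return ContingencyTable(
            a=n(classes[0], "deletion"),
            b=n(classes[0], "insertion"),
            c=n(classes[1], "deletion"),
            d=n(classes[1], "insertion"),
            row_labels=classes,
        )

    sub = indels[indels[split_by].isin(classes)]
    if not by_length:
        return tab(sub)
    out = {L: tab(sub[sub["length"] == L]) for L in range(1, 6)}
    out["pooled"] = tab(sub)
    return out


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    log10_p: float
    odds_ratio_sample: float
    odds_ratio_cmle: float


def _log_hypergeom_pmf(a_vals: np.ndarray, t: ContingencyTable) -> np.ndarray:
    n1 = t.a + t.b  # row 1 margin
    k = t.a + t.c  # deletion column margin
    N = t.total
    return stats.hypergeom.logpmf(a_vals, N, n1, k)


def fisher_exact_2x2(t: ContingencyTable, compute_cmle: bool = True) -> FisherResult:
    """Two-sided Fisher exact test computed in log space.

    The two-sided p sums hypergeometric probabilities of all tables (with
    the observed margins) whose probability does not exceed the observed
    one (with the customary (1 + 1e-7) slack for float ties, as in R's
    fisher.test).  Working in log space keeps the p-value meaningful far
    below double underflow; ``log10_p`` is always finite.  The sample
    odds ratio is (a*d)/(b*c); the conditional-MLE odds ratio maximizes
    the noncentral hypergeometric likelihood.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n1, k, N = a + b, a + c, t.total
    if min(n1, N - n1, k, N - k) == 0:
        # a zero margin: only one table is possible
        import warnings

        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        orr = (a * d) / (b * c) if b * c > 0 else math.nan
        return FisherResult(1.0, 0.0, orr, math.nan)

    lo, hi = max(0, k - (N - n1)), min(n1, k)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, t)
    obs = logp[a - lo]
    mask = logp <= obs + math.log1p(1e-7)
    log_p = float(logsumexp(logp[mask]))
    log_p = min(log_p, 0.0)
    p = float(math.exp(log_p))

    orr = (a * d) / (b * c) if b * c > 0 else math.inf
    cmle = math.nan
    if compute_cmle:
        cmle = float(
            stats.contingency.odds_ratio(t.counts, kind="conditional").statistic
        )
    return FisherResult(p, log_p / math.log(10), orr, cmle)


# ---------------------------------------------------------------------------
# allele frequency spectra


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Mid-ranks handle ties; two-sidedness is |T - E[T]| >= |T_obs - E[T]|
    over the permutation null.  Exponential in n, intended for small
    samples only.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    t_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    dev = abs(t_obs - mu) - 1e-12
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        t = ranks[list(combo)].sum()
        total += 1
        if abs(t - mu) >= dev:
            hits += 1
    return hits / total


def afs_compare(
    freqs_a,
    freqs_b,
    method: str = "auto",
    n_bins: int = 20,
    exact_limit: int = 24,
):
    """Compare two derived allele frequency spectra by rank-sum test.

    Returns ``(W, p, spectra)`` where W is the rank-sum statistic of the
    first sample (the Mann-Whitney U of sample A, matching R's wilcox.test
    W) and ``spectra`` holds the binned AFS of both samples for plotting.
    ``method='asymptotic'`` uses the normal approximation with tie and
    continuity corrections; ``'exact'`` enumerates the permutation null
    with mid-ranks (small samples); ``'auto'`` picks exact when
    n_a + n_b <= ``exact_limit``.
    """
    x = np.asarray(freqs_a, dtype=float)
    y = np.asarray(freqs_b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both frequency samples must be non-empty")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= exact_limit else "asymptotic"

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    w = float(res.statistic)
    if method == "exact":
        p = _rank_sum_exact_p(x, y)
    elif method == "asymptotic":
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    spectra = {
        "edges": edges,
        "counts_a": np.histogram(x, bins=edges)[0],
        "counts_b": np.histogram(y, bins=edges)[0],
    }
    return w, p, spectra


# ---------------------------------------------------------------------------
# region-class enrichment


def _class_mask(df: pd.DataFrame, cls: str) -> pd.Series:
    """Resolve a contrast class name to a row mask."""
    if cls in ("insertion", "deletion"):
        return df["event"] == cls
    if cls in ("modern_specific", "archaic_shared"):
        m = df["sharing"] == cls
        if cls == "archaic_shared" and "introgressed" in df:
            # shared class excludes introgressed variants when the
            # contrast involves introgression
            return m
        return m
    if cls == "introgressed":
        return df["introgressed"].astype(bool)
    if cls == "shared_not_introgressed":
        return (df["sharing"] == "archaic_shared") & ~df["introgressed"].astype(bool)
    raise ValueError(f"unknown contrast class {cls!r}")


DEFAULT_CONTRASTS = [("insertion", "deletion"), ("modern_specific", "archaic_shared")]


def region_class_contrast(
    indels: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    region_col: str = "region",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region 2x2 enrichment tests with a single FDR adjustment.

    For each region class and each (classA, classB) contrast, a 2x2 of
    (in-region / out-of-region) x (classA / classB) counts is tested with
    the Fisher exact test.  All raw p-values across regions and contrasts
    are Benjamini-Hochberg adjusted together.  The 95% CI is the Wald
    interval on the log sample odds ratio; degenerate tables (a zero
    cell) are flagged and excluded from the adjustment.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    regions = sorted(indels[region_col].dropna().unique())
    rows = []
    for region in regions:
        in_region = indels[region_col] == region
        for cls_a, cls_b in contrasts:
            ma, mb = _class_mask(indels, cls_a), _class_mask(indels, cls_b)
            a = int((ma & in_region).sum())
            b = int((mb & in_region).sum())
            c = int((ma & ~in_region).sum())
            d = int((mb & ~in_region).sum())
            degenerate = min(a, b, c, d) == 0
            if degenerate:
                rows.append(
                    dict(
                        region=region, class_a=cls_a, class_b=cls_b,
                        a=a, b=b, c=c, d=d, odds_ratio=np.nan,
                        ci_low=np.nan, ci_high=np.nan, p=np.nan,
                        degenerate=True,
                    )
                )
                continue
            orr = (a * d) / (b * c)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            res = fisher_exact_2x2(
                ContingencyTable(a, b, c, d), compute_cmle=False
            )
            rows.append(
                dict(
                    region=region, class_a=cls_a, class_b=cls_b,
                    a=a, b=b, c=c, d=d, odds_ratio=orr,
                    ci_low=orr * math.exp(-1.96 * se),
                    ci_high=orr * math.exp(1.96 * se),
                    p=res.p_two_sided, degenerate=False,
                )
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] < alpha
    return out


def assign_region_class(
    indels: pd.DataFrame, annotation: pd.DataFrame, default: str = "intergenic"
) -> pd.DataFrame:
    """Assign each indel the region class of the BED interval covering it.

    ``annotation`` is BED-like (chrom, start, end, region) with 0-based
    half-open intervals; the first covering interval wins (a most-severe
    ordering is assumed to have been applied upstream).  Uncovered indels
    get ``default``.
    """
    ann = annotation.sort_values(["chrom", "start"])
    out = indels.copy()
    classes = []
    by_chrom = {c: g for c, g in ann.groupby("chrom")}
    for _, r in out.iterrows():
        g = by_chrom.get(r["chrom"])
        label = default
        if g is not None:
            hit = g[(g["start"] < r["pos"]) & (r["pos"] <= g["end"])]
            if len(hit):
                label = hit.iloc[0]["region"]
        classes.append(label)
    out["region"] = classes
    return out


# ---------------------------------------------------------------------------
# per-category (GO-style) binomial contrast


def category_contrast(
    cats: pd.DataFrame, fwer_alpha: float = 0.05
) -> pd.DataFrame:
    """Binomial contrast of two indel classes across gene categories.

    For each category with countA + countB > 0, a two-sided binomial test
    of countA out of (countA + countB) against the global proportion
    p0 = totalA/(totalA + totalB); Bonferroni-controlled FWER over the
    tested categories.  Columns: category, countA, countB, p, p_fwer,
    direction, enriched.
    """
    df = cats.copy()
    df = df[(df["countA"] + df["countB"]) > 0].reset_index(drop=True)
    if df.empty:
        return df.assign(p=[], p_fwer=[], direction=[], enriched=[])
    t_a = df["totalA"].iloc[0]
    t_b = df["totalB"].iloc[0]
    if t_a + t_b <= 0:
        raise ValueError("global totals must be positive")
    p0 = t_a / (t_a + t_b)
    ps, direction = [], []
    for _, r in df.iterrows():
        n = int(r["countA"] + r["countB"])
        res = stats.binomtest(int(r["countA"]), n, p0, alternative="two-sided")
        ps.append(res.pvalue)
        direction.append("A" if r["countA"] / n > p0 else "B")
    m = len(ps)
    df["p"] = ps
    df["p_fwer"] = np.minimum(np.asarray(ps) * m, 1.0)
    df["direction"] = direction
    df["enriched"] = df["p_fwer"] <= fwer_alpha
    return df


# ---------------------------------------------------------------------------
# candidate filtering and differentiation


def score_filter(
    indels: pd.DataFrame, scores: pd.DataFrame, cutoff: float = 20.0
) -> tuple[pd.DataFrame, int]:
    """Keep indels whose phred-scaled deleteriousness C-score >= cutoff.

    ``scores`` joins on (chrom, pos, ancestral, derived); duplicate score
    rows keep the highest score.  Returns the retained table sorted by
    descending score and the count of unjoinable indels.
    """
    key = ["chrom", "pos", "ancestral", "derived"]
    sc = (
        scores.sort_values("score", ascending=False)
        .drop_duplicates(subset=key)
        .loc[:, key + ["score"]]
    )
    joined = indels.merge(sc, on=key, how="left")
    n_unjoined = int(joined["score"].isna().sum())
    kept = joined[joined["score"] >= cutoff].sort_values(
        "score", ascending=False
    ).reset_index(drop=True)
    return kept, n_unjoined


def fst_hudson(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson's per-site FST estimator (Bhatia et al. ratio form), clipped to [0,1].

    ``n1``/``n2`` are chromosome (not individual) counts.  Undefined when
    the site is monomorphic in both populations (raises ValueError).
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("frequencies must be in [0,1]")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 chromosomes per population")
    if (p1 in (0.0, 1.0)) and (p2 in (0.0, 1.0)) and p1 == p2:
        raise ValueError("FST undefined for a site monomorphic in both populations")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den == 0:
        raise ValueError("FST undefined (zero denominator)")
    return float(min(1.0, max(0.0, num / den)))
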