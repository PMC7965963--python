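"""Replicate concordance, trait correlation, heritability, and marker association.

Statistical conventions used throughout:

* Pearson correlations are tested with the Fisher z transform
  (z = atanh(r), SE = 1/sqrt(n-3), two-sided normal p).
* Heritability is on the entry-mean basis from a one-way random-effects
  model fitted by REML, H2 = sigma2_g / (sigma2_g + sigma2_e / r_bar) with
  r_bar the harmonic-mean replicate count — the correction for unbalanced
  replicate numbers.
* Marker-trait association uses the two-sided Fisher exact test on the
  2x2 table of allele state (non-reference / reference) by pod-number
  class (high / low); heterozygous and missing calls are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.special import gammaln
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .annotation_io import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects variance components and entry-mean heritability."""

    sigma2_g: float
    sigma2_e: float
    r_bar: float
    H2: float


class UntestableTableError(ValueError):
    """A 2x2 table with an empty row or column marginal cannot be tested."""


# ---------------------------------------------------------------------------
# correlation


def pearson_fisher_z(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value from the Fisher z transform.

    Pairs with a missing value in either vector are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-14:  # exact linear dependence up to rounding
        r = math.copysign(1.0, r)
    if abs(r) == 1.0:
        return CorrelationResult(r, n, 0.0)
    z = math.atanh(r) * math.sqrt(n - 3)
    p = 2.0 * norm.sf(abs(z))
    return CorrelationResult(r, n, p)


def replicate_concordance(
    image_table: pd.DataFrame, traits: list[str]
) -> pd.DataFrame:
    """Front-vs-back Pearson correlation per trait over paired images.

    ``image_table`` holds one row per image with ``accession_id``,
    ``replicate_id`` and ``side`` columns.  Traits with fewer than four
    complete pairs are skipped with a warning.
    """
    wide = image_table.pivot_table(
        index=["accession_id", "replicate_id"],
        columns="side",
        values=[t for t in traits if t in image_table.columns],
        aggfunc="first",
    )
    rows = []
    for trait in traits:
        if (trait, "front") not in wide.columns or (trait, "back") not in wide.columns:
            logger.warning("concordance: trait %s missing on one side, skipped", trait)
            continue
        try:
            res = pearson_fisher_z(wide[(trait, "front")], wide[(trait, "back")])
        except ValueError as exc:
            logger.warning("concordance: trait %s skipped (%s)", trait, exc)
            continue
        rows.append({"trait": trait, "r": res.r, "n": res.n, "p": res.p})
    return pd.DataFrame(rows, columns=["trait", "r", "n", "p"])


def trait_correlation_cluster(
    trait_table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise trait correlation matrix plus a clustered leaf order.

    Hierarchical clustering uses complete linkage on Euclidean distances
    between rows of the correlation matrix, so traits with similar
    correlation profiles sit on adjacent leaves.  Constant traits are
    excluded with a warning.
    """
    if traits is None:
        traits = [
            c for c in trait_table.columns
            if c not in ("accession_id", "replicate_id")
        ]
    numeric = trait_table[traits].astype(float)
    keep = []
    for t in traits:
        col = numeric[t].dropna()
        if len(col) >= 4 and col.std() > 0:
            keep.append(t)
        else:
            logger.warning("correlation: trait %s constant or too sparse, excluded", t)
    if len(keep) < 2:
        raise ValueError("fewer than two usable traits")
    corr = numeric[keep].corr(method="pearson", min_periods=4)
    filled = corr.fillna(0.0).values
    link = sch.linkage(filled, method="complete", metric="euclidean")
    order = [keep[i] for i in sch.leaves_list(link)]
    return corr, order


# ---------------------------------------------------------------------------
# heritability


def heritability(values, groups) -> VarianceComponents:
    """Entry-mean heritability from a one-way random-effects REML fit.

    The model is y_ij = mu + g_i + e_ij with g_i ~ N(0, sigma2_g) per
    accession and e_ij ~ N(0, sigma2_e) per plant.  The REML criterion is
    profiled down to the single variance ratio lambda = sigma2_g/sigma2_e
    and minimized numerically (tolerance 1e-8); a boundary solution at
    lambda = 0 yields sigma2_g = 0.  H2 uses the harmonic-mean replicate
    count, which corrects for unbalanced replication.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    df = df.dropna()
    sizes = df.groupby("g")["y"].size()
    if len(sizes) < 2:
        raise ValueError("need at least two accessions")
    if (sizes < 2).all():
        raise ValueError(
            "all accessions have a single replicate: variance components "
            "are unidentifiable"
        )
    n_i = sizes.values.astype(float)
    ybar_i = df.groupby("g")["y"].mean().values
    ssw = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum())
    n_tot = float(n_i.sum())

    def neg2_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        w = n_i / (1.0 + lam * n_i)
        mu = float(np.sum(w * ybar_i) / np.sum(w))
        q = ssw + float(np.sum(w * (ybar_i - mu) ** 2))
        q = max(q, 1e-300)
        return (
            (n_tot - 1.0) * math.log(q)
            + float(np.sum(np.log1p(lam * n_i)))
            + math.log(float(np.sum(w)))
        )

    res = minimize_scalar(
        neg2_reml, bounds=(-30.0, 30.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = math.exp(res.x)
    # Boundary check: lambda -> 0 means no genetic variance.
    if neg2_reml(-30.0) <= res.fun + 1e-12:
        lam = 0.0
    w = n_i / (1.0 + lam * n_i)
    mu = float(np.sum(w * ybar_i) / np.sum(w))
    q = ssw + float(np.sum(w * (ybar_i - mu) ** 2))
    sigma2_e = q / (n_tot - 1.0)
    sigma2_g = lam * sigma2_e
    r_bar = len(n_i) / float(np.sum(1.0 / n_i))
    denom = sigma2_g + sigma2_e / r_bar
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return VarianceComponents(sigma2_g, sigma2_e, r_bar, h2)


def heritability_table(
    trait_table: pd.DataFrame, traits: list[str]
) -> pd.DataFrame:
    """Per-trait variance components over the plant trait table."""
    rows = []
    for t in traits:
        if t not in trait_table.columns:
            continue
        try:
            vc = heritability(
                trait_table[t].astype(float), trait_table["accession_id"]
            )
        except ValueError as exc:
            logger.warning("heritability: trait %s skipped (%s)", t, exc)
            continue
        rows.append(
            {"trait": t, "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e,
             "r_bar": vc.r_bar, "H2": vc.H2}
        )
    return pd.DataFrame(rows, columns=["trait", "sigma2_g", "sigma2_e", "r_bar", "H2"])


# ---------------------------------------------------------------------------
# marker association


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass convention: the p-value sums the hypergeometric
    probabilities of every table with the same margins whose probability
    does not exceed that of the observed table.  Computed with
    log-factorials, so it is exact to double precision for any table size.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2) == 0 or min(c1, c2) == 0:
        raise UntestableTableError("table has an empty row or column marginal")
    n = r1 + r2

    logc = gammaln(np.arange(n + 1) + 1.0)  # logc[k] = log k!

    def log_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom with margins (r1, r2; c1, c2)
        return (
            logc[r1] - logc[x] - logc[r1 - x]
            + logc[r2] - logc[c1 - x] - logc[r2 - (c1 - x)]
            - (logc[n] - logc[c1] - logc[n - c1])
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= lp_obs + 1e-9:  # relative slack for float ties
            total += math.exp(lp)
    return min(total, 1.0)


def classify_pod_number(accession_means: pd.Series, split: str = "mean") -> pd.Series:
    """Label each accession 'high' or 'low' pod number.

    ``mean`` split: high iff strictly above the population mean (ties and
    the all-equal case fall to 'low').  ``median`` split available as an
    alternative convention.
    """
    if len(accession_means) < 2:
        raise ValueError("need at least two accessions")
    if split == "mean":
        cut = accession_means.mean()
    elif split == "median":
        cut = accession_means.median()
    else:
        raise ValueError(f"unknown split rule {split!r}")
    return pd.Series(
        np.where(accession_means > cut, "high", "low"),
        index=accession_means.index,
    )


def marker_association(
    genotypes: GenotypeTable,
    labels: pd.Series,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-marker 2x2 table (pod class x allele state) and Fisher p-value.

    Heterozygous and missing calls are excluded from the counts.  Markers
    whose table has an empty marginal (e.g. all accessions carry the
    reference allele) are flagged untestable with p = NaN.  Output is
    sorted by p-value.
    """
    common = [acc for acc in genotypes.accessions if acc in labels.index]
    if not common:
        raise ValueError("no genotyped accession has a pod-number label")
    rows = []
    for marker_id, calls in genotypes.calls[common].iterrows():
        high = calls[labels[common] == "high"]
        low = calls[labels[common] == "low"]
        a = int((high == "non_reference").sum())
        b = int((high == "reference").sum())
        c = int((low == "non_reference").sum())
        d = int((low == "reference").sum())
        try:
            p = fisher_exact_2x2(a, b, c, d)
            flag = "ok"
        except UntestableTableError:
            p, flag = math.nan, "untestable"
        rows.append(
            {"marker_id": marker_id, "high_nr": a, "high_ref": b,
             "low_nr": c, "low_ref": d, "p": p, "flag": flag}
        )
    out = pd.DataFrame(rows).merge(genotypes.markers, on="marker_id")
    if fdr:
        from scipy.stats import false_discovery_control

        ok = out["flag"] == "ok"
        out.loc[ok, "p_adj"] = false_discovery_control(out.loc[ok, "p"], method="bh")
    return out.sort_values("p", na_position="last").reset_index(drop=True)


def marker_window_match(
    published: pd.DataFrame,
    markers: pd.DataFrame,
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Array markers within ``window_bp`` (inclusive) of published QTL markers.

    Both inputs need ``chrom`` and ``pos`` columns with the same chromosome
    naming and 1-based positions.  Returns one row per (published, array)
    pair, nearest first within each published marker.
    """
    unmatched = sorted(set(published["chrom"]) - set(markers["chrom"]))
    if unmatched:
        raise ValueError(
            f"chromosome names not present in the genotype data: {unmatched}"
        )
    rows = []
    for _, pub in published.iterrows():
        near = markers[markers["chrom"] == pub["chrom"]].copy()
        near["distance_bp"] = (near["pos"] - pub["pos"]).abs()
        near = near[near["distance_bp"] <= window_bp].sort_values(
            ["distance_bp", "pos"]
        )
        for _, m in near.iterrows():
            rows.append(
                {"published_chrom": pub["chrom"], "published_pos": pub["pos"],
                 "marker_id": m["marker_id"], "pos": m["pos"],
                 "distance_bp": int(m["distance_bp"])}
            )
    return pd.DataFrame(
        rows,
        columns=["published_chrom", "published_pos", "marker_id", "pos", "distance_bp"],
    )


# ---------------------------------------------------------------------------
# bundled reference tables


def load_published_marker_tables() -> pd.DataFrame:
    """Published pod-number QTL marker contingency data bundled with the package.

    Each row is one 50K-array SNP marker reported as significantly
    associated with pod number in a 24-accession edamame panel: the counts
    of non-reference/reference accessions within the high and low
    pod-number classes, and the reported two-sided Fisher p-value.
    """
    with resources.files("shootarch.data").joinpath(
        "pod_qtl_marker_tables.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def contingency_tables_from_csv(path) -> pd.DataFrame:
    """Read 2x2 tables (columns high_nr, high_ref, low_nr, low_ref) and test each."""
    df = pd.read_csv(path)
    ps = []
    for _, row in df.iterrows():
        try:
            ps.append(
                fisher_exact_2x2(
                    row["high_nr"], row["high_ref"], row["low_nr"], row["low_ref"]
                )
            )
        except UntestableTableError:
            ps.append(math.nan)
    df = df.copy()
    df["p"] = ps
    return df
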