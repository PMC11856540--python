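"""Nonparametric statistics for NUMT distribution patterns.

The distribution questions are paired by design (the same 13 source genes,
or the same species, appear on both sides), so the workhorse is the
Wilcoxon signed-rank test with Benjamini-Hochberg control of the false
discovery rate across the family of comparisons: X chromosome versus
autosomes within each species, and ATP8 versus every other gene across
species.  Exact p-values are used at small effective n, where the normal
approximation is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    test: str
    statistic: float | None
    p_value: float
    n: int
    p_adjusted: float | None = None
    notes: str = ""


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped (Wilcoxon's convention).  The exact null
    distribution is used when the effective n is at most ``exact_max_n``;
    beyond that, the normal approximation with continuity correction.
    All differences zero gives the degenerate p = 1.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size == 0:
        raise ValueError("empty input")
    d = d[~np.isnan(d)]
    nz = d[d != 0]
    n_eff = nz.size
    if n_eff == 0:
        return StatResult(test="wilcoxon", statistic=None, p_value=1.0,
                          n=0, notes="degenerate")
    method = "exact" if n_eff <= exact_max_n else "approx"
    if method == "exact":
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    else:
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
    return StatResult(test="wilcoxon", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=int(n_eff), notes=method)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR adjustment; input order preserved, values capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate(u, v, method: str = "pearson") -> tuple[float | None, str]:
    """Correlation coefficient with pairwise-complete handling of NaNs.

    Returns (coefficient, note); zero-variance input gives (None,
    "undefined: zero variance").
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(u) | np.isnan(v))
    u, v = u[mask], v[mask]
    if u.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(u) == 0 or np.std(v) == 0:
        return None, "undefined: zero variance"
    if method == "pearson":
        r = float(sps.pearsonr(u, v).statistic)
    elif method == "spearman":
        r = float(sps.spearmanr(u, v).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, ""


# ---------------------------------------------------------------------------
# chromosome profiles

def build_profiles(classified_df: pd.DataFrame, chrom_meta_df: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-(species, chromosome, gene) NUMT counts and densities.

    ``classified_df`` needs columns species_id/gene/chrom; ``chrom_meta_df``
    needs species_id/chrom/length_bp/category.  Chromosomes without hits get
    explicit zero counts so densities are well defined everywhere.
    """
    counts = (classified_df.groupby(["species_id", "chrom", "gene"])
              .size().rename("count").reset_index())
    genes = sorted(classified_df["gene"].unique())
    frame = chrom_meta_df.merge(pd.DataFrame({"gene": genes}), how="cross")
    prof = frame.merge(counts, on=["species_id", "chrom", "gene"], how="left")
    prof["count"] = prof["count"].fillna(0).astype(int)
    prof["density_per_mb"] = prof["count"] / (prof["length_bp"] / 1e6)
    return prof


def sex_vs_autosome_test(
    profiles: pd.DataFrame,
    unit: str = "density",
    alpha: float = 0.05,
    min_autosomes: int = 3,
) -> pd.DataFrame:
    """Per-species paired test of X-chromosome vs autosome NUMT load.

    The pairing unit is the 13 source genes: for each gene, the value on the
    X chromosome is paired with the mean across autosomes.  ``unit`` selects
    densities per Mb (default, robust to chromosome-length differences) or
    raw counts.  BH adjustment is applied across species; species without an
    annotated X, or with fewer than ``min_autosomes`` autosomes, are skipped
    with a note.
    """
    value = "density_per_mb" if unit == "density" else "count"
    rows = []
    for sp, sub in profiles.groupby("species_id"):
        x_chr = sub[sub["category"] == "X"]
        autos = sub[sub["category"] == "autosome"]
        if x_chr.empty:
            rows.append({"species_id": sp, "statistic": np.nan, "p_value": np.nan,
                         "n": 0, "note": "no X chromosome annotated"})
            continue
        if autos["chrom"].nunique() < min_autosomes:
            rows.append({"species_id": sp, "statistic": np.nan, "p_value": np.nan,
                         "n": 0, "note": "fewer than %d autosomes" % min_autosomes})
            continue
        x_vals = x_chr.groupby("gene")[value].mean()
        a_vals = autos.groupby("gene")[value].mean()
        genes = sorted(set(x_vals.index) & set(a_vals.index))
        res = wilcoxon_signed_rank(x_vals[genes].to_numpy(), a_vals[genes].to_numpy())
        rows.append({"species_id": sp, "statistic": res.statistic,
                     "p_value": res.p_value, "n": res.n, "note": res.notes})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = benjamini_hochberg(out.loc[tested, "p_value"])
    out["significant"] = out["p_adjusted"] < alpha
    return out


def atp8_vs_others_test(
    c1_counts: pd.DataFrame,
    reference_gene: str = "ATP8",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon of the reference gene against every other gene.

    ``c1_counts`` is species x gene (rows species, columns the 13 PCGs).
    Pairing is across species; BH is applied over the 12 comparisons.
    """
    if reference_gene not in c1_counts.columns:
        raise ValueError(f"missing column {reference_gene!r}")
    if len(c1_counts) < 2:
        raise ValueError("need at least 2 species")
    others = [g for g in c1_counts.columns if g != reference_gene]
    rows = []
    for g in others:
        res = wilcoxon_signed_rank(c1_counts[reference_gene].to_numpy(),
                                   c1_counts[g].to_numpy())
        rows.append({"gene": g, "statistic": res.statistic,
                     "p_value": res.p_value, "n": res.n, "note": res.notes})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_value"])
    out["significant"] = out["p_adjusted"] < alpha
    return out
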