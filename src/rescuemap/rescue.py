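"""Rescue classification, directional fidelity, rescue strength and overlaps.

The core question of a knockdown/rescue profile is, gene by gene: does a
construct reproduce the endogenous factor's regulation?  Each gene is placed
in a four-way status from the 2x2 of endogenous and construct significance
(the red/gray/yellow/black convention of rescue scatterplots), direction
concordance is summarized per construct and response-element class, rescue
strength is the Pearson correlation and OLS slope of construct versus
endogenous log2 fold changes over co-significant genes, and gene-set
overlaps are tested with a 2x2 chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnalysisParams",
    "RescueStrength",
    "VennResult",
    "classify_rescue_status",
    "direction_fidelity",
    "rescue_strength",
    "twofold_gene_sets",
    "venn_overlap_test",
    "strata_rescue_summary",
]

STATUSES = ("both_significant", "kd_only", "rescue_only", "neither")


@dataclass
class AnalysisParams:
    """Significance and fold-change thresholds (strict inequalities).

    ``alpha`` applies to BH-adjusted p-values with no fold-change cutoff for
    rescue status; ``fc_cutoff`` is the linear fold-change threshold used
    only for the two-fold gene sets of Venn-style overlap analyses.
    """

    alpha: float = 0.05
    fc_cutoff: float = 2.0
    control: str = "iEF"
    endo_label: str = "iLuc"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.fc_cutoff < 1.0:
            raise ValueError("fc_cutoff must be >= 1")


@dataclass
class RescueStrength:
    n: int
    pearson_r: float
    r_pvalue: float
    slope: float
    intercept: float


@dataclass
class VennResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    chi2: float
    p: float
    reason: str = ""


def _significant(table: pd.DataFrame, alpha: float) -> pd.Series:
    padj = table["padj"]
    return padj.notna() & (padj < alpha)


def classify_rescue_status(endo: pd.DataFrame, construct: pd.DataFrame,
                           params: AnalysisParams | None = None) -> pd.DataFrame:
    """Four-way rescue status per gene over the union of both tables.

    Genes testable in only one table are treated conservatively (missing
    adjusted p counts as not significant) and flagged.  Directions are
    defined from the log2 fold-change sign of each significant side;
    concordance is defined only when both directions are.
    """
    params = params or AnalysisParams()
    params.validate()
    e = endo.set_index("gene")
    c = construct.set_index("gene")
    if not len(e.index.intersection(c.index)):
        raise ValueError("endogenous and construct tables share no genes")
    genes = e.index.union(c.index, sort=False)

    e = e.reindex(genes)
    c = c.reindex(genes)
    sig_e = _significant(e, params.alpha).to_numpy()
    sig_c = _significant(c, params.alpha).to_numpy()
    status = np.where(sig_e & sig_c, "both_significant",
             np.where(sig_e, "kd_only",
             np.where(sig_c, "rescue_only", "neither")))

    def _dir(lfc: pd.Series, sig: np.ndarray) -> np.ndarray:
        return np.where(sig & lfc.notna().to_numpy(),
                        np.where(lfc.to_numpy() >= 0, "up", "down"), "na")

    endo_dir = _dir(e["log2fc"], sig_e)
    cons_dir = _dir(c["log2fc"], sig_c)
    both = (endo_dir != "na") & (cons_dir != "na")
    concordant = pd.array(np.where(both, endo_dir == cons_dir, None), dtype="boolean")
    flagged = e["padj"].isna().to_numpy() | c["padj"].isna().to_numpy()

    return pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "status": status,
            "endo_dir": endo_dir,
            "construct_dir": cons_dir,
            "concordant": concordant,
            "flagged": flagged,
        }
    )


def direction_fidelity(calls_by_construct: dict[str, pd.DataFrame],
                       classes: pd.DataFrame | None = None,
                       params: AnalysisParams | None = None) -> pd.DataFrame:
    """Concordant / paradoxical / unchanged fractions per construct x class.

    Restricted to endogenously regulated genes (the red-and-gray scatterplot
    population: status ``both_significant`` or ``kd_only``; rescue-only genes
    are excluded).  With ``classes`` None all genes form a single ``all``
    class.  Classes with zero endogenously regulated genes are omitted.
    """
    import logging

    rows = []
    for construct, calls in calls_by_construct.items():
        df = calls.copy()
        if classes is not None:
            df = df.merge(classes[["gene", "element_class"]], on="gene", how="left")
            df["element_class"] = df["element_class"].fillna("none")
        else:
            df["element_class"] = "all"
        endo_reg = df[df["status"].isin(["both_significant", "kd_only"])]
        for klass, sub in endo_reg.groupby("element_class", sort=True):
            n = len(sub)
            if n == 0:
                logging.getLogger(__name__).info(
                    "class %s has no endogenously regulated genes for %s", klass, construct)
                continue
            both = (sub["status"] == "both_significant").to_numpy()
            concordant = sub["concordant"].fillna(False).to_numpy(dtype=bool)
            conc = both & concordant
            para = both & ~concordant
            rows.append((construct, klass, n,
                         conc.sum() / n, para.sum() / n,
                         (sub["status"] == "kd_only").sum() / n))
    return pd.DataFrame(rows, columns=["construct", "element_class", "n_endo_regulated",
                                       "frac_rescued_concordant", "frac_paradoxical",
                                       "frac_unchanged"])


def rescue_strength(endo: pd.DataFrame, construct: pd.DataFrame,
                    calls: pd.DataFrame | None = None,
                    params: AnalysisParams | None = None) -> RescueStrength:
    """Pearson r and OLS slope of construct vs endogenous log2 fold change.

    Computed only over co-significant (``both_significant``) genes — the line
    of best fit describes the "volume" of rescued activity.  The regression
    includes an intercept, which is reported but carries no interpretation.
    Fewer than 3 usable genes yields NaN statistics with ``n`` reported.
    """
    params = params or AnalysisParams()
    if calls is None:
        calls = classify_rescue_status(endo, construct, params)
    keep = calls.loc[calls["status"] == "both_significant", "gene"]
    x = endo.set_index("gene")["log2fc"].reindex(keep).to_numpy(dtype=float)
    y = construct.set_index("gene")["log2fc"].reindex(keep).to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        return RescueStrength(n, float("nan"), float("nan"), float("nan"), float("nan"))

    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0.0:
        return RescueStrength(n, float("nan"), float("nan"), float("nan"), float("nan"))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        r = float("nan")
    elif sxy * sxy >= sxx * syy:  # numerically perfect colinearity => exact +-1
        r = float(np.sign(sxy))
    else:
        r = sxy / np.sqrt(sxx * syy)
    if np.isnan(r):
        p = float("nan")
    elif abs(r) >= 1.0:
        r = float(np.sign(r))
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return RescueStrength(n, float(r), p, float(slope), intercept)


def twofold_gene_sets(de: pd.DataFrame,
                      params: AnalysisParams | None = None) -> tuple[set, set]:
    """Activated / repressed gene sets at |fold change| > cutoff and padj < alpha.

    Both inequalities are strict: a gene at exactly the fold-change cutoff is
    excluded.
    """
    params = params or AnalysisParams()
    params.validate()
    sig = _significant(de, params.alpha)
    lim = float(np.log2(params.fc_cutoff))
    activated = set(de.loc[sig & (de["log2fc"] > lim), "gene"])
    repressed = set(de.loc[sig & (de["log2fc"] < -lim), "gene"])
    return activated, repressed


def venn_overlap_test(set_a: set, set_b: set, universe: set) -> VennResult:
    """Pearson chi-square (1 df, no continuity correction) for set overlap.

    The 2x2 table counts membership in A crossed with membership in B over
    the universe.  Degenerate margins (an empty set or a set equal to the
    universe) leave the statistic undefined.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    if n < 2:
        raise ValueError("universe must contain at least 2 genes")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    n_a, n_b = len(set_a), len(set_b)
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return VennResult(n_a, n_b, a, n, float("nan"), float("nan"),
                          "degenerate margin: empty set or full universe")
    chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1))
    return VennResult(n_a, n_b, a, n, float(chi2), p)


def strata_rescue_summary(calls_by_construct: dict[str, pd.DataFrame],
                          classes: pd.DataFrame | None,
                          endo: pd.DataFrame,
                          construct_tables: dict[str, pd.DataFrame],
                          params: AnalysisParams | None = None) -> pd.DataFrame:
    """Tidy per-stratum report: counts, proportions and rescue strength.

    One row per construct x element class x (status, direction) with the
    count, the proportion within the construct x class stratum, and the
    stratum's rescue strength (r, p, slope over its co-significant genes)
    attached to every row of the stratum.
    """
    params = params or AnalysisParams()
    rows = []
    for construct, calls in calls_by_construct.items():
        df = calls.copy()
        if classes is not None:
            df = df.merge(classes[["gene", "element_class"]], on="gene", how="left")
            df["element_class"] = df["element_class"].fillna("none")
        else:
            df["element_class"] = "all"
        for klass, sub in df.groupby("element_class", sort=True):
            strength = rescue_strength(
                endo, construct_tables[construct],
                calls=sub[["gene", "status"]],
                params=params,
            )
            n_total = len(sub)
            concordant = sub["concordant"].fillna(False).to_numpy(dtype=bool)
            direction = np.where(
                (sub["status"] == "both_significant").to_numpy(),
                np.where(concordant, "concordant", "paradoxical"),
                "na",
            )
            grp = pd.DataFrame({"status": sub["status"].to_numpy(), "direction": direction})
            counts = grp.value_counts().sort_index()
            for (status, dirn), k in counts.items():
                rows.append((construct, klass, status, dirn, int(k), k / n_total,
                             strength.n, strength.pearson_r, strength.r_pvalue,
                             strength.slope))
    return pd.DataFrame(rows, columns=["construct", "element_class", "status",
                                       "direction", "n", "proportion",
                                       "strength_n", "pearson_r", "r_pvalue", "slope"])
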