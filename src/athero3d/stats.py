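"""Nonparametric group statistics for plaque measurements.

Plaque volumes are strongly right-skewed (animals on low-fat or chow diets
carry little plaque), so all inference is rank-based: Spearman correlation,
the Mann-Whitney U test for independent groups, the Wilcoxon signed-rank
test for within-animal (paired) compartment contrasts — the standard paired
nonparametric procedure — and Benjamini-Hochberg FDR adjustment wherever a
family of contrasts is tested.  All tests are two-sided; exact p-values are
used for small samples and a tie-corrected normal approximation beyond.
Zero within-pair differences are dropped in the signed-rank test (Wilcoxon
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined sample size up to which exact Mann-Whitney / Wilcoxon p-values
#: are enumerated
EXACT_N = 25

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple
    paired: bool
    q_value: float | None = None

    def as_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "p_value": self.p_value,
                "n": self.n, "paired": self.paired, "q_value": self.q_value}


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rank correlation r_s with a two-sided p-value.

    Equivalent to Pearson correlation on average ranks; a constant input
    vector leaves r_s undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def mann_whitney(a, b, paired: bool = False) -> TestResult:
    """Two-sided Mann-Whitney U test; the paired variant is the Wilcoxon
    signed-rank test on within-animal differences.

    Exact p-values are enumerated for small samples (combined n <=
    ``EXACT_N`` without ties); otherwise a tie-corrected normal
    approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError(f"paired test needs equal lengths, got {len(a)} vs {len(b)}")
        d = a - b
        d = d[d != 0]                      # drop zero differences
        if len(d) == 0:
            return TestResult(test="wilcoxon-signed-rank", statistic=0.0, p_value=1.0,
                              n=(len(a), len(b)), paired=True)
        ties = len(np.unique(np.abs(d))) < len(d)
        method = "exact" if (len(d) <= EXACT_N and not ties) else "approx"
        stat, p = sps.wilcoxon(d, alternative="two-sided", method=method,
                               correction=(method == "approx"))
        return TestResult(test="wilcoxon-signed-rank", statistic=float(stat),
                          p_value=float(p), n=(len(a), len(b)), paired=True)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= EXACT_N and not ties) else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(test="mann-whitney", statistic=float(stat), p_value=float(p),
                      n=(len(a), len(b)), paired=False)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p}")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the study's analysis battery

REQUIRED_COLUMNS = ("animal_id", "genotype", "diet", "total_volume_mm3")


def run_paper_analyses(table: pd.DataFrame) -> pd.DataFrame:
    """Run the full contrast battery on a cohort measurement table.

    Expected columns: ``animal_id``, ``genotype``, ``diet``,
    ``total_volume_mm3``, per-compartment ``volume_<COMP>_mm3`` and
    optionally ``cd45_<COMP>_mm3``.  Contrasts:

    * diet effect on total plaque volume within each genotype (unpaired);
    * genotype effect on total plaque volume within each diet (unpaired);
    * all pairwise compartment contrasts within animal (paired signed-rank,
      BH-FDR within the family, per genotype);
    * diet effect on CD45-in-plaque volume per compartment (unpaired,
      BH-FDR within the family, per genotype).

    Returns a tidy table with test name, groups, n, statistic, p, q and a
    significance flag at 0.05 on the adjusted value where FDR applies.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks required columns: {missing}")
    if table["genotype"].nunique() < 1 or table["diet"].nunique() < 2:
        raise ValueError("need at least two diet groups to run the contrast battery")
    rows = []

    def record(family, contrast, res: TestResult):
        rows.append({"family": family, "contrast": contrast, "test": res.test,
                     "n": res.n, "statistic": res.statistic, "p_value": res.p_value})

    diets = sorted(table["diet"].unique())
    genotypes = sorted(table["genotype"].unique())
    for g in genotypes:
        sub = table[table.genotype == g]
        if sub["diet"].nunique() == 2:
            a = sub[sub.diet == diets[0]]["total_volume_mm3"].to_numpy()
            b = sub[sub.diet == diets[1]]["total_volume_mm3"].to_numpy()
            record("diet", f"{g}: {diets[0]} vs {diets[1]}", mann_whitney(a, b))
    if len(genotypes) == 2:
        for d in diets:
            sub = table[table.diet == d]
            a = sub[sub.genotype == genotypes[0]]["total_volume_mm3"].to_numpy()
            b = sub[sub.genotype == genotypes[1]]["total_volume_mm3"].to_numpy()
            if len(a) and len(b):
                record("genotype", f"{d}: {genotypes[0]} vs {genotypes[1]}",
                       mann_whitney(a, b))
    comp_cols = [c for c in table.columns if c.startswith("volume_") and c.endswith("_mm3")]
    comps = [c.removeprefix("volume_").removesuffix("_mm3") for c in comp_cols]
    for g in genotypes:
        sub = table[table.genotype == g]
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a = sub[comp_cols[i]].to_numpy()
                b = sub[comp_cols[j]].to_numpy()
                record("compartment", f"{g}: {comps[i]} vs {comps[j]}",
                       mann_whitney(a, b, paired=True))
    cd_cols = [c for c in table.columns if c.startswith("cd45_") and c.endswith("_mm3")]
    for g in genotypes:
        sub = table[table.genotype == g]
        if sub["diet"].nunique() != 2:
            continue
        for c in cd_cols:
            a = sub[sub.diet == diets[0]][c].to_numpy()
            b = sub[sub.diet == diets[1]][c].to_numpy()
            comp = c.removeprefix("cd45_").removesuffix("_mm3")
            record("cd45", f"{g}: {comp} {diets[0]} vs {diets[1]}", mann_whitney(a, b))

    report = pd.DataFrame(rows)
    if report.empty:
        return report
    report["q_value"] = np.nan
    for family in ("compartment", "cd45"):      # FDR within each corrected family
        sel = report["family"] == family
        if sel.any():
            report.loc[sel, "q_value"] = fdr_adjust(report.loc[sel, "p_value"].to_numpy())
    adj = report["q_value"].fillna(report["p_value"])
    report["significant"] = adj < ALPHA
    return report
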